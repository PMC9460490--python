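"""WAV audio I/O and overlapping-slice framing.

Audio is handled as mono float arrays in [-1, 1] at a canonical 16 kHz
sample rate (the rate the classifier was designed for).  A continuous
stream is cut into 30 ms analysis slices advanced by a 20 ms stride,
emulating the microphone front end of the detector.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.io import wavfile
from scipy.signal import resample_poly

CANONICAL_RATE = 16_000
#: analysis slice length, ms
SLICE_MS = 30
#: hop between consecutive slices, ms
STRIDE_MS = 20


class Label(enum.IntEnum):
    """Classifier classes, in fixed score-vector order."""

    SILENCE = 0
    NOISE = 1
    MOSQUITO = 2
    UNLABELED = 3


@dataclass
class AudioClip:
    """Mono audio with amplitudes in [-1, 1].

    Parameters
    ----------
    samples : np.ndarray
        1-D float array of amplitudes.
    sample_rate : int
        Sampling rate in Hz (canonical: 16 kHz).
    label : Label
        Ground-truth class of the clip, if known.
    """

    samples: np.ndarray
    sample_rate: int = CANONICAL_RATE
    label: Label = Label.UNLABELED

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1:
            raise ValueError("AudioClip samples must be 1-D (mono)")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples must be finite")

    @property
    def duration_s(self) -> float:
        return len(self.samples) / self.sample_rate

    def rms(self) -> float:
        return float(np.sqrt(np.mean(np.square(self.samples)))) if len(self.samples) else 0.0


def read_wav(path: str | Path, target_rate: int = CANONICAL_RATE) -> AudioClip:
    """Read a PCM WAV file as a mono clip at ``target_rate``.

    Multi-channel audio is downmixed by channel averaging; other sample
    rates are polyphase-resampled.  Integer PCM is rescaled to [-1, 1].
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    rate, data = wavfile.read(str(path))
    if data.size == 0:
        raise ValueError(f"zero-length audio: {path}")
    if data.ndim == 2:  # downmix
        data = data.mean(axis=1)
    if data.dtype == np.int16:
        samples = data / 32768.0  # matches write_wav's x*32768 quantization
    elif data.dtype == np.int32:
        samples = data / 2147483648.0
    elif data.dtype == np.uint8:
        samples = (data.astype(np.float64) - 128.0) / 128.0
    elif np.issubdtype(data.dtype, np.floating):
        samples = data.astype(np.float64)
    else:
        raise ValueError(f"unsupported WAV encoding {data.dtype} in {path}")
    if rate != target_rate:
        g = np.gcd(int(rate), int(target_rate))
        samples = resample_poly(samples, target_rate // g, rate // g)
    return AudioClip(np.asarray(samples, dtype=np.float64), target_rate)


def write_wav(clip: AudioClip, path: str | Path) -> None:
    """Write a clip as 16-bit PCM mono WAV; out-of-range samples are clipped."""
    samples = clip.samples
    peak = np.max(np.abs(samples)) if len(samples) else 0.0
    if peak > 1.0:
        warnings.warn("samples outside [-1, 1] clipped on write", stacklevel=2)
        samples = np.clip(samples, -1.0, 1.0)
    pcm = np.clip(np.round(samples * 32768.0), -32768, 32767).astype(np.int16)
    wavfile.write(str(path), clip.sample_rate, pcm)


@dataclass
class SliceStream:
    """Overlapping fixed-length windows over a clip.

    Invariant: slice_len > stride > 0; every window has exactly
    ``slice_len * sample_rate / 1000`` samples.
    """

    source: AudioClip
    slice_ms: int = SLICE_MS
    stride_ms: int = STRIDE_MS

    def __post_init__(self) -> None:
        if not (self.slice_ms >= self.stride_ms > 0):
            raise ValueError("require slice_ms >= stride_ms > 0")

    @property
    def window_samples(self) -> int:
        return self.slice_ms * self.source.sample_rate // 1000

    @property
    def hop_samples(self) -> int:
        return self.stride_ms * self.source.sample_rate // 1000


def n_windows(duration_samples: int, window: int, hop: int) -> int:
    """Number of full windows: floor((D - W)/S) + 1 for D >= W, else 0."""
    if duration_samples < window:
        return 0
    return (duration_samples - window) // hop + 1


def emit_slices(stream: SliceStream) -> np.ndarray:
    """All full windows of the stream as an (n, window_samples) array.

    Windows are ordered by start time; a trailing partial window is
    discarded (the classifier needs fixed-size frames).
    """
    x = stream.source.samples
    w, h = stream.window_samples, stream.hop_samples
    n = n_windows(len(x), w, h)
    if n == 0:
        raise ValueError("clip shorter than one slice")
    idx = np.arange(n)[:, None] * h + np.arange(w)[None, :]
    return x[idx]
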