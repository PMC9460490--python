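"""Log-mel feature extraction and the rolling 49x40 spectrogram image.

Each 30 ms slice (480 samples at 16 kHz) becomes one row of 40 log-mel
band energies quantized to 0..255.  Because the deployed front end uses a
256-point FFT while a slice holds 480 samples, each slice is analysed as
two overlapping 256-sample Hann blocks (starting at samples 0 and 224 so
the slice is fully covered) whose power spectra are averaged before the
mel filter bank.

One second of audio at the 20 ms stride yields 49 rows, so the classifier
input is a 49x40 image.  In streaming operation the image is a ring
buffer: each new slice appends a row and drops the oldest; the buffer is
warm-started with floor-value rows so classification can begin with the
first slice.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .audio_io import AudioClip, SliceStream, emit_slices

N_MELS = 40
N_FRAMES = 49
FFT_SIZE = 256
WINDOW_SAMPLES = 480
#: start offsets of the two FFT blocks inside a 480-sample slice
_BLOCK_STARTS = (0, WINDOW_SAMPLES - FFT_SIZE)

# Fixed affine quantization of log power energies to 0..255.  The floor is
# the log of the additive epsilon (an all-zero slice maps to 0); the
# ceiling leaves headroom above a full-scale tone's strongest band.
LOG_EPS = 1e-6
LOG_FLOOR = float(np.log(LOG_EPS))  # ~ -13.82
LOG_CEIL = float(np.log(2e4))  # ~ 9.90

MEL_FMIN = 125.0
MEL_FMAX = 7500.0


def hz_to_mel(f):
    return 2595.0 * np.log10(1.0 + np.asarray(f, dtype=np.float64) / 700.0)


def mel_to_hz(m):
    return 700.0 * (10.0 ** (np.asarray(m, dtype=np.float64) / 2595.0) - 1.0)


def mel_filterbank(
    n_mels: int = N_MELS,
    n_fft: int = FFT_SIZE,
    sample_rate: int = 16_000,
    fmin: float = MEL_FMIN,
    fmax: float = MEL_FMAX,
) -> np.ndarray:
    """Triangular mel filters (HTK mel scale, unit peak) as (n_mels, n_fft//2+1)."""
    edges_hz = mel_to_hz(np.linspace(hz_to_mel(fmin), hz_to_mel(fmax), n_mels + 2))
    fft_hz = np.arange(n_fft // 2 + 1) * sample_rate / n_fft
    fb = np.zeros((n_mels, n_fft // 2 + 1))
    for i in range(n_mels):
        lo, ctr, hi = edges_hz[i], edges_hz[i + 1], edges_hz[i + 2]
        up = (fft_hz - lo) / (ctr - lo)
        down = (hi - fft_hz) / (hi - ctr)
        fb[i] = np.clip(np.minimum(up, down), 0.0, None)
    return fb


@dataclass
class FeatureExtractor:
    """Slice -> quantized 40-bin log-mel row."""

    sample_rate: int = 16_000
    n_mels: int = N_MELS
    fmin: float = MEL_FMIN
    fmax: float = MEL_FMAX

    def __post_init__(self) -> None:
        self._fb = mel_filterbank(self.n_mels, FFT_SIZE, self.sample_rate, self.fmin, self.fmax)
        self._hann = np.hanning(FFT_SIZE + 1)[:-1]

    def log_mel(self, window: np.ndarray) -> np.ndarray:
        """Unquantized log-mel energies of one 480-sample slice (or a batch)."""
        window = np.atleast_2d(np.asarray(window, dtype=np.float64))
        if window.shape[-1] != WINDOW_SAMPLES:
            raise ValueError(f"slice must have {WINDOW_SAMPLES} samples, got {window.shape[-1]}")
        power = np.zeros((window.shape[0], FFT_SIZE // 2 + 1))
        for start in _BLOCK_STARTS:
            block = window[:, start : start + FFT_SIZE] * self._hann
            power += np.abs(np.fft.rfft(block, axis=-1)) ** 2
        power /= len(_BLOCK_STARTS)
        energies = power @ self._fb.T
        return np.squeeze(np.log(energies + LOG_EPS))

    def quantize(self, log_energies: np.ndarray) -> np.ndarray:
        scaled = (log_energies - LOG_FLOOR) / (LOG_CEIL - LOG_FLOOR) * 255.0
        return np.clip(np.round(scaled), 0, 255).astype(np.uint8)

    def slice_to_feature_row(self, window: np.ndarray) -> np.ndarray:
        """One 30 ms slice -> 40 uint8 log-mel energies."""
        return self.quantize(self.log_mel(window))

    def clip_to_image(self, clip: AudioClip) -> np.ndarray:
        """Batch 49x40 image of a clip's first second (needs >= 49 slices)."""
        windows = emit_slices(SliceStream(clip))
        if windows.shape[0] < N_FRAMES:
            raise ValueError(f"need >= {N_FRAMES} slices, got {windows.shape[0]}")
        rows = self.quantize(np.atleast_2d(self.log_mel(windows[:N_FRAMES])))
        return rows.reshape(N_FRAMES, self.n_mels)


class Spectrogram:
    """Rolling 49x40 feature image (ring buffer of the latest 49 rows).

    Starts pre-filled with floor-value (0) rows; ``push`` appends the
    newest row and drops the oldest.
    """

    def __init__(self, n_frames: int = N_FRAMES, n_mels: int = N_MELS):
        self.n_frames = n_frames
        self.n_mels = n_mels
        self._rows = np.zeros((n_frames, n_mels), dtype=np.uint8)

    def push(self, row: np.ndarray) -> "Spectrogram":
        row = np.asarray(row, dtype=np.uint8)
        if row.shape != (self.n_mels,):
            raise ValueError(f"row must have shape ({self.n_mels},)")
        self._rows = np.vstack([self._rows[1:], row[None, :]])
        return self

    @property
    def image(self) -> np.ndarray:
        """Rows oldest -> newest, shape (n_frames, n_mels), uint8."""
        return self._rows.copy()


def update_spectrogram(spec: Spectrogram, row: np.ndarray) -> Spectrogram:
    """Functional alias for ``spec.push(row)``."""
    return spec.push(row)


def dump_rows_csv(rows: np.ndarray, path) -> None:
    """Debug dump: one feature row per line, 40 integers."""
    np.savetxt(path, np.atleast_2d(rows), fmt="%d", delimiter=",")
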