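"""Seeded synthetic wingbeat, ambient-noise and silence audio.

Stands in for the field corpora the detector was designed around: 1 s
training clips (mosquito wingbeats, living-room noises, white/pink
background) and longer test clips played at a calibrated source level
over a range of distances.  Mosquito flight tones are modelled as a
harmonic series on the sex-specific wingbeat fundamental (females
400-500 Hz, males 700-800 Hz) with per-harmonic rolloff, slow flight
amplitude modulation and a smooth frequency jitter.  Noise templates are
stylized spectral/temporal caricatures of the named sources, not
recordings; a real WAV corpus can be dropped in through ``audio_io``.

Sound levels are nominal dB SPL values mapped linearly onto digital RMS
with the 30 dB background-silence floor anchored at RMS 1.5e-3; only
relative levels (SNR) are meaningful.  Propagation uses the free-field
inverse-distance law anchored at the 9 cm calibration distance.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal

from .audio_io import CANONICAL_RATE, AudioClip, Label

#: digital RMS of the 30 dB anchor level
RMS_AT_30DB = 1.5e-3
REFERENCE_DISTANCE_CM = 9.0

FEMALE_BAND = (400.0, 500.0)
MALE_BAND = (700.0, 800.0)


def db_to_rms(level_db: float) -> float:
    """Nominal dB SPL -> digital RMS (linear map anchored at 30 dB)."""
    return RMS_AT_30DB * 10.0 ** ((level_db - 30.0) / 20.0)


def _set_rms(x: np.ndarray, rms: float) -> np.ndarray:
    cur = np.sqrt(np.mean(np.square(x)))
    return x * (rms / cur) if cur > 0 else x


# ------------------------------------------------------------- wingbeat


@dataclass
class WingbeatSpec:
    sex: str = "female"  # "female" | "male"
    fundamental_hz: float | None = None  # drawn within the sex band if None
    n_harmonics: int = 4  # partials including the fundamental
    harmonic_rolloff_db: float = 6.0  # attenuation per successive harmonic
    am_rate_hz: float | None = None  # flight modulation, drawn in [5, 10] if None
    am_depth: float = 0.3
    freq_jitter_hz: float = 5.0  # scale of the slow random fundamental drift
    duration_s: float = 1.0
    level_db: float = 33.0
    seed: int = 0

    def band(self) -> tuple[float, float]:
        if self.sex == "female":
            return FEMALE_BAND
        if self.sex == "male":
            return MALE_BAND
        raise ValueError(f"unknown sex {self.sex!r}")


def _smooth_noise(rng, n: int, sr: int, cutoff_hz: float = 1.0) -> np.ndarray:
    """Unit-std low-passed Gaussian noise (slow modulation track)."""
    raw = rng.standard_normal(n)
    sos = signal.butter(2, cutoff_hz, fs=sr, output="sos")
    out = signal.sosfilt(sos, raw)
    std = out.std()
    return out / std if std > 0 else out


def gen_mosquito(spec: WingbeatSpec, sample_rate: int = CANONICAL_RATE) -> AudioClip:
    """Synthesize one wingbeat clip; deterministic under ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.band()
    f0 = spec.fundamental_hz if spec.fundamental_hz is not None else rng.uniform(lo, hi)
    if not (lo <= f0 <= hi):
        raise ValueError(f"fundamental {f0} Hz outside {spec.sex} band {lo}-{hi}")
    if spec.duration_s <= 0:
        raise ValueError("duration must be positive")
    n = int(round(spec.duration_s * sample_rate))
    t = np.arange(n) / sample_rate

    if spec.freq_jitter_hz > 0:
        f_inst = f0 + spec.freq_jitter_hz * _smooth_noise(rng, n, sample_rate)
    else:
        f_inst = np.full(n, f0)
    phase = 2.0 * np.pi * (np.cumsum(f_inst) - f_inst) / sample_rate  # phase[0] = 0

    x = np.zeros(n)
    for h in range(1, spec.n_harmonics + 1):
        gain = 10.0 ** (-(h - 1) * spec.harmonic_rolloff_db / 20.0)
        x += gain * np.sin(h * phase)

    if spec.am_depth > 0:
        rate = spec.am_rate_hz if spec.am_rate_hz is not None else rng.uniform(5.0, 10.0)
        if rate > 0:
            x *= 1.0 + spec.am_depth * np.sin(2.0 * np.pi * rate * t + rng.uniform(0, 2 * np.pi))

    x = np.clip(_set_rms(x, db_to_rms(spec.level_db)), -1.0, 1.0)
    return AudioClip(x, sample_rate, Label.MOSQUITO)


# ---------------------------------------------------------------- noise


class NoiseKind(str, enum.Enum):
    SILENCE_WHITE = "silence_white"
    SILENCE_PINK = "silence_pink"
    CLOCK = "clock"
    CONVERSATION = "conversation"
    SNORING = "snoring"
    SIZZLING_PAN = "sizzling_pan"
    REFRIGERATOR = "refrigerator"
    WATER = "water"
    DISHWASHER = "dishwasher"
    RAIN = "rain"


#: nominal level ranges (dB) per source, as measured at the device
LEVEL_RANGES_DB: dict[NoiseKind, tuple[float, float]] = {
    NoiseKind.SILENCE_WHITE: (30, 35),
    NoiseKind.SILENCE_PINK: (30, 35),
    NoiseKind.CLOCK: (30, 40),
    NoiseKind.CONVERSATION: (45, 65),
    NoiseKind.SNORING: (45, 65),
    NoiseKind.SIZZLING_PAN: (55, 75),
    NoiseKind.REFRIGERATOR: (35, 45),
    NoiseKind.WATER: (55, 70),
    NoiseKind.DISHWASHER: (50, 60),
    NoiseKind.RAIN: (40, 60),
}

LIVING_KINDS = [
    NoiseKind.CLOCK,
    NoiseKind.CONVERSATION,
    NoiseKind.SNORING,
    NoiseKind.SIZZLING_PAN,
    NoiseKind.REFRIGERATOR,
    NoiseKind.WATER,
    NoiseKind.DISHWASHER,
    NoiseKind.RAIN,
]


@dataclass
class NoiseSpec:
    kind: NoiseKind = NoiseKind.SILENCE_WHITE
    level_db: float | None = None  # drawn within the kind's range if None
    duration_s: float = 1.0
    seed: int = 0

    def __post_init__(self):
        self.kind = NoiseKind(self.kind)
        if self.level_db is not None:
            lo, hi = LEVEL_RANGES_DB[self.kind]
            if not (lo <= self.level_db <= hi):
                raise ValueError(f"{self.kind.value} level {self.level_db} outside {lo}-{hi} dB")


def _pink(rng, n: int) -> np.ndarray:
    """1/f-power noise via spectral shaping (slope ~ -3 dB/octave)."""
    spec = np.fft.rfft(rng.standard_normal(n))
    f = np.fft.rfftfreq(n)
    shaping = np.ones_like(f)
    shaping[1:] = 1.0 / np.sqrt(f[1:])
    shaping[0] = 0.0
    return np.fft.irfft(spec * shaping, n)


def _bandpass(rng, n: int, sr: int, lo: float, hi: float, order: int = 4) -> np.ndarray:
    sos = signal.butter(order, [lo, hi], btype="band", fs=sr, output="sos")
    return signal.sosfilt(sos, rng.standard_normal(n))


def gen_noise(spec: NoiseSpec, sample_rate: int = CANONICAL_RATE) -> AudioClip:
    """Synthesize one ambient-noise/silence clip from its stylized template."""
    rng = np.random.default_rng(spec.seed)
    n = int(round(spec.duration_s * sample_rate))
    t = np.arange(n) / sample_rate
    k = spec.kind

    if k == NoiseKind.SILENCE_WHITE:
        x = rng.standard_normal(n)
    elif k == NoiseKind.SILENCE_PINK:
        x = _pink(rng, n)
    elif k == NoiseKind.CLOCK:
        # 1 Hz tick train: 4 ms damped high-band bursts over a faint floor
        x = 0.02 * rng.standard_normal(n)
        tick = np.exp(-np.arange(int(0.004 * sample_rate)) / (0.001 * sample_rate))
        burst = tick * np.sin(2 * np.pi * 2000.0 * np.arange(len(tick)) / sample_rate)
        phase0 = int(rng.uniform(0, sample_rate))
        for start in range(phase0, n, sample_rate):
            seg = burst[: n - start]
            x[start : start + len(seg)] += 30.0 * seg
    elif k == NoiseKind.CONVERSATION:
        # speech-band noise with syllabic (~4 Hz) amplitude bursts
        carrier = _bandpass(rng, n, sample_rate, 100, 3000)
        envelope = np.clip(_smooth_noise(rng, n, sample_rate, 4.0), 0, None)
        x = carrier * envelope
    elif k == NoiseKind.SNORING:
        carrier = _bandpass(rng, n, sample_rate, 50, 500)
        envelope = np.clip(np.sin(2 * np.pi * 0.4 * t + rng.uniform(0, 2 * np.pi)), 0, None) ** 2
        x = carrier * (0.1 + envelope)
    elif k == NoiseKind.SIZZLING_PAN:
        hiss = _bandpass(rng, n, sample_rate, 1500, 7500)
        crackle = (rng.random(n) < 0.002) * rng.standard_normal(n) * 8.0
        x = hiss + crackle
    elif k == NoiseKind.REFRIGERATOR:
        x = 0.3 * rng.standard_normal(n)
        for h, g in ((60, 1.0), (120, 0.6), (180, 0.4), (240, 0.25)):
            x += g * np.sin(2 * np.pi * h * t + rng.uniform(0, 2 * np.pi))
    elif k == NoiseKind.WATER:
        base = _bandpass(rng, n, sample_rate, 500, 4000)
        drops = (rng.random(n) < 0.001) * rng.standard_normal(n) * 10.0
        x = base + signal.sosfilt(
            signal.butter(2, [800, 3000], btype="band", fs=sample_rate, output="sos"), drops
        )
    elif k == NoiseKind.DISHWASHER:
        hum = 0.8 * np.sin(2 * np.pi * 50 * t) + 0.4 * np.sin(2 * np.pi * 100 * t)
        broadband = _bandpass(rng, n, sample_rate, 200, 4000)
        swish = 1.0 + 0.5 * np.sin(2 * np.pi * 0.7 * t + rng.uniform(0, 2 * np.pi))
        x = hum + broadband * swish
    elif k == NoiseKind.RAIN:
        base = _bandpass(rng, n, sample_rate, 200, 6000)
        patter = (rng.random(n) < 0.005) * rng.standard_normal(n) * 4.0
        x = base + patter
    else:  # pragma: no cover
        raise ValueError(f"unknown noise kind {k}")

    lo, hi = LEVEL_RANGES_DB[k]
    level = spec.level_db if spec.level_db is not None else rng.uniform(lo, hi)
    x = np.clip(_set_rms(x, db_to_rms(level)), -1.0, 1.0)
    label = Label.SILENCE if k in (NoiseKind.SILENCE_WHITE, NoiseKind.SILENCE_PINK) else Label.NOISE
    return AudioClip(x, sample_rate, label)


# -------------------------------------------------------------- dataset


#: per-split (mosquito, living noise, silence) clip counts of the
#: emulated development corpus
DEFAULT_SPLIT_COUNTS = {
    "training": (806, 282, 282),
    "validation": (97, 34, 34),
    "test": (97, 34, 34),
}

#: training wingbeat level range, dB — spans loud close-range tones down
#: to faint ones comparable to the distance-sweep test conditions
TRAIN_MOSQUITO_DB = (15.0, 45.0)
#: background floor mixed into training wingbeat clips, dB
TRAIN_FLOOR_DB = (15.0, 25.0)


@dataclass
class DatasetSpec:
    split_counts: dict = field(default_factory=lambda: dict(DEFAULT_SPLIT_COUNTS))
    duration_s: float = 1.0
    seed: int = 0


def _training_mosquito(rng, duration_s: float) -> AudioClip:
    sex = "female" if rng.random() < 0.5 else "male"
    clip = gen_mosquito(
        WingbeatSpec(
            sex=sex,
            level_db=rng.uniform(*TRAIN_MOSQUITO_DB),
            duration_s=duration_s,
            seed=int(rng.integers(2**31)),
        )
    )
    floor_kind = NoiseKind.SILENCE_WHITE if rng.random() < 0.5 else NoiseKind.SILENCE_PINK
    floor = gen_noise(
        NoiseSpec(floor_kind, duration_s=duration_s, seed=int(rng.integers(2**31)))
    )
    mixed = clip.samples + _set_rms(floor.samples, db_to_rms(rng.uniform(*TRAIN_FLOOR_DB)))
    return AudioClip(mixed, clip.sample_rate, Label.MOSQUITO)


def build_dataset(spec: DatasetSpec | None = None) -> dict[str, list[AudioClip]]:
    """Labelled 1 s clips per split, with the emulated corpus composition.

    Deterministic under ``spec.seed``; different seeds give different
    clip content with identical counts.
    """
    spec = spec or DatasetSpec()
    rng = np.random.default_rng(spec.seed)
    dataset: dict[str, list[AudioClip]] = {}
    for split, (n_mos, n_noise, n_sil) in spec.split_counts.items():
        clips = []
        for _ in range(n_mos):
            clips.append(_training_mosquito(rng, spec.duration_s))
        for i in range(n_noise):
            kind = LIVING_KINDS[i % len(LIVING_KINDS)]
            clips.append(
                gen_noise(NoiseSpec(kind, duration_s=spec.duration_s, seed=int(rng.integers(2**31))))
            )
        for i in range(n_sil):
            kind = NoiseKind.SILENCE_WHITE if i % 2 == 0 else NoiseKind.SILENCE_PINK
            clips.append(
                gen_noise(NoiseSpec(kind, duration_s=spec.duration_s, seed=int(rng.integers(2**31))))
            )
        dataset[split] = clips
    return dataset


def write_dataset(dataset: dict[str, list[AudioClip]], outdir) -> "pandas.DataFrame":
    """WAV fixture tree split/class/clip_NNNN.wav plus a CSV manifest."""
    import pandas as pd
    from pathlib import Path

    from .audio_io import write_wav

    outdir = Path(outdir)
    records = []
    for split, clips in dataset.items():
        for i, clip in enumerate(clips):
            cls = clip.label.name.lower()
            path = outdir / split / cls / f"clip_{i:04d}.wav"
            path.parent.mkdir(parents=True, exist_ok=True)
            write_wav(clip, path)
            records.append(
                {"path": str(path), "label": clip.label.name, "split": split,
                 "duration_s": clip.duration_s}
            )
    manifest = pd.DataFrame.from_records(records)
    manifest.to_csv(outdir / "manifest.csv", index=False)
    return manifest


# ------------------------------------------------------------- distance


@dataclass
class DistanceModel:
    """Free-field 1/r propagation anchored at the calibration distance.

    ``noise_floor_db`` is the quiet-room background mixed into the
    received signal (a bedroom at night).
    """

    reference_level_db: float = 33.0  # source level at 9 cm
    reference_distance_cm: float = REFERENCE_DISTANCE_CM
    noise_floor_db: float = 20.0

    def gain(self, distance_cm: float) -> float:
        if distance_cm < self.reference_distance_cm:
            raise ValueError(f"distance must be >= {self.reference_distance_cm} cm")
        return self.reference_distance_cm / distance_cm


def attenuate(
    clip: AudioClip,
    model: DistanceModel,
    distance_cm: float,
    rng: np.random.Generator | None = None,
) -> AudioClip:
    """Received signal at ``distance_cm``: 1/r-scaled source + floor noise."""
    scaled = clip.samples * model.gain(distance_cm)
    if model.noise_floor_db is not None:
        rng = rng or np.random.default_rng(0)
        floor = _set_rms(rng.standard_normal(len(scaled)), db_to_rms(model.noise_floor_db))
        scaled = scaled + floor
    return AudioClip(scaled, clip.sample_rate, clip.label)
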