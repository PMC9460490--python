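"""End-to-end workflows tying the modules together.

These are the library-level equivalents of the command-line workflows:
generate the synthetic corpus, featurize it, train the CNN, and build
the standard test suites (ambient-noise streams for the false positive
characterization, distance-swept wingbeat clips for the false negative
characterization).
"""

from __future__ import annotations

import numpy as np

from .audio_io import AudioClip
from .cnn import ModelConfig, TinyConvNet, accuracy, build_model, train
from .features import FeatureExtractor
from .synth import (
    DatasetSpec,
    DistanceModel,
    NoiseKind,
    NoiseSpec,
    WingbeatSpec,
    attenuate,
    build_dataset,
    gen_mosquito,
    gen_noise,
)

#: distance grid of the false negative sweep, cm
DISTANCE_GRID_CM = tuple(range(10, 150, 10))


def dataset_to_arrays(
    dataset: dict[str, list[AudioClip]], extractor: FeatureExtractor | None = None
):
    """Featurize a clip dataset: split -> (uint8 images (n,49,40), labels (n,))."""
    extractor = extractor or FeatureExtractor()
    out = {}
    for split, clips in dataset.items():
        images = np.stack([extractor.clip_to_image(c) for c in clips])
        labels = np.array([int(c.label) for c in clips], dtype=np.int64)
        out[split] = (images, labels)
    return out


def train_with_restarts(
    arrays: dict,
    seed: int = 0,
    steps: int = 750,
    n_restarts: int = 3,
    config: ModelConfig | None = None,
):
    """Train ``n_restarts`` candidates, keep the best by validation accuracy.

    Plain SGD on this short budget occasionally converges to a poor
    solution (an unlearned class boundary); selecting among a few
    restarts on the held-out validation split is the standard remedy and
    emulates the manual model-development loop.  Deterministic given
    ``seed``.  Returns (model, info).
    """
    best = None
    for r in range(n_restarts):
        cfg = config or ModelConfig()
        cfg = ModelConfig(**{**cfg.__dict__, "seed": (seed * 1000 + r) % 2**31})
        model = build_model(cfg)
        model, trace, checkpoints = train(model, *arrays["training"], steps=steps)
        val = accuracy(model, *arrays["validation"])
        if best is None or val > best[1]:
            best = (model, val, trace, checkpoints)
    model, val, trace, checkpoints = best
    info = {
        "trace": trace,
        "n_checkpoints": len(checkpoints),
        "validation_accuracy": val,
        "test_accuracy": accuracy(model, *arrays["test"]),
    }
    return model, info


def train_default_model(
    seed: int = 0,
    steps: int = 750,
    dataset_spec: DatasetSpec | None = None,
    n_restarts: int = 3,
):
    """Generate the default corpus, train the default CNN, report accuracies.

    Returns (model, info) where info holds the training trace and the
    held-out validation/test accuracies.
    """
    dataset_spec = dataset_spec or DatasetSpec(seed=seed)
    arrays = dataset_to_arrays(build_dataset(dataset_spec))
    return train_with_restarts(arrays, seed=seed, steps=steps, n_restarts=n_restarts)


def make_noise_suite(
    seed: int = 0, clips_per_kind: int = 4, duration_s: float = 10.0
) -> list[AudioClip]:
    """Ambient-noise/silence streams for the false positive test, all kinds."""
    rng = np.random.default_rng(seed)
    clips = []
    for kind in NoiseKind:
        for _ in range(clips_per_kind):
            clips.append(
                gen_noise(
                    NoiseSpec(kind, duration_s=duration_s, seed=int(rng.integers(2**31)))
                )
            )
    return clips


def make_distance_clips(
    seed: int = 0,
    distances_cm=DISTANCE_GRID_CM,
    clips_per_distance: int = 4,
    duration_s: float = 10.0,
    sex: str = "female",
    distance_model: DistanceModel | None = None,
) -> dict[int, list[AudioClip]]:
    """Wingbeat clips at calibrated source level, attenuated per distance.

    The source level is drawn in the calibrated 30-33 dB range; the
    received clip mixes the 1/r-scaled tone with the room noise floor.
    """
    rng = np.random.default_rng(seed)
    dm = distance_model or DistanceModel()
    out: dict[int, list[AudioClip]] = {}
    for d in distances_cm:
        out[d] = []
        for _ in range(clips_per_distance):
            source = gen_mosquito(
                WingbeatSpec(
                    sex=sex,
                    level_db=rng.uniform(30.0, 33.0),
                    duration_s=duration_s,
                    seed=int(rng.integers(2**31)),
                )
            )
            out[d].append(attenuate(source, dm, d, rng=rng))
    return out
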