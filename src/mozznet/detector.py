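"""Per-segment detection decisions from averaged slice scores.

The stream is cut into 330 ms segments.  Within each segment only the
first four 30 ms slices (20 ms stride) are featurized and classified —
the remaining slices are discarded, keeping the decision rate at three
per second.  The four quantized score vectors are averaged; the segment
is positive iff Mosquito is the winning class AND its mean score is
strictly greater than the detection threshold theta (deployed value 210
on the 0..256 score scale).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .audio_io import AudioClip, Label
from .cnn import ScoreVector, TinyConvNet, classify
from .features import FeatureExtractor, Spectrogram


@dataclass
class DetectorConfig:
    l_seg_ms: int = 330
    max_proc: int = 4  # slices scored per segment
    theta: int = 210
    l_slice_ms: int = 30
    stride_ms: int = 20

    def __post_init__(self) -> None:
        if not (0 < self.theta < 256):
            raise ValueError("theta must be in (0, 256)")
        span = self.max_proc * self.stride_ms + (self.l_slice_ms - self.stride_ms)
        if span > self.l_seg_ms:
            raise ValueError("scored slices must fit inside one segment")


@dataclass
class SegmentDecision:
    start_time_s: float
    mean_scores: np.ndarray  # (silence, noise, mosquito) means, floats
    label: Label
    positive: bool

    @property
    def time_s(self) -> float:
        """Decision instant = segment start (one decision per L_seg)."""
        return self.start_time_s


def decide_segment(
    scores: list[ScoreVector], config: DetectorConfig, start_time_s: float = 0.0
) -> SegmentDecision:
    """Average ``max_proc`` slice score vectors into one segment decision.

    Positive requires the strict inequality mean_mosquito > theta (a mean
    of exactly theta is rejected) and Mosquito winning the argmax, ties
    resolving away from Mosquito.
    """
    if len(scores) != config.max_proc:
        raise ValueError(f"expected {config.max_proc} score vectors, got {len(scores)}")
    stacked = np.stack([s.as_array() for s in scores])
    mean = stacked.sum(axis=0) / config.max_proc
    label = Label(int(np.argmax(mean)))  # ties -> earlier class, away from Mosquito
    positive = label == Label.MOSQUITO and mean[Label.MOSQUITO] > config.theta
    return SegmentDecision(start_time_s, mean, label, positive)


def stream_decisions(
    clip: AudioClip,
    model: TinyConvNet,
    config: DetectorConfig | None = None,
    extractor: FeatureExtractor | None = None,
) -> list[SegmentDecision]:
    """One decision per full 330 ms segment of a clip.

    The rolling 49x40 spectrogram persists across segments and is
    warm-started with floor rows, so classification begins with the very
    first slice.  A trailing partial segment is discarded.
    """
    config = config or DetectorConfig()
    extractor = extractor or FeatureExtractor(clip.sample_rate)
    sr = clip.sample_rate
    seg = config.l_seg_ms * sr // 1000
    hop = config.stride_ms * sr // 1000
    win = config.l_slice_ms * sr // 1000
    n_seg = len(clip.samples) // seg
    if n_seg == 0:
        raise ValueError("clip shorter than one segment")
    # featurize all scored slices in one batch, then classify sequentially
    starts = (
        np.arange(n_seg)[:, None] * seg + np.arange(config.max_proc)[None, :] * hop
    ).ravel()
    idx = starts[:, None] + np.arange(win)[None, :]
    rows = extractor.quantize(np.atleast_2d(extractor.log_mel(clip.samples[idx])))

    spec = Spectrogram()
    images = np.empty((len(rows), spec.n_frames, spec.n_mels), dtype=np.uint8)
    for i, row in enumerate(rows):
        spec.push(row)
        images[i] = spec.image
    logits = model.forward(images, train=False)

    decisions = []
    for s in range(n_seg):
        from .cnn import quantize_scores

        vecs = [
            quantize_scores(logits[s * config.max_proc + j])
            for j in range(config.max_proc)
        ]
        decisions.append(decide_segment(vecs, config, s * config.l_seg_ms / 1000.0))
    return decisions


def decisions_to_csv(decisions: list[SegmentDecision], path) -> None:
    """Decision log: timestamp_s, silence_mean, noise_mean, mosquito_mean, positive."""
    import csv

    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["timestamp_s", "silence_mean", "noise_mean", "mosquito_mean", "positive"])
        for d in decisions:
            w.writerow(
                [f"{d.start_time_s:.2f}"]
                + [f"{v:.2f}" for v in d.mean_scores]
                + [int(d.positive)]
            )
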