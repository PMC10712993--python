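"""Inference over segment batches, probability filtering and beat calling.

``infer`` runs the network on every segment and rejoins the per-segment
outputs into one probability track of exactly the original signal length
(the zero-padding of the final segment is stripped).  ``filter_probabilities``
applies a short moving average to the per-sample class probabilities, which
suppresses one-sample flickers and sharpens run boundaries before
``call_beats`` turns supra-threshold runs into localized, labelled beat
calls with a refractory merge.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import uniform_filter1d

from ..preprocess import SegmentBatch, SEGMENT_LENGTH
from .network import CLASS_NONE, CLASS_NORMAL, CLASS_PVC, PvcNet

__all__ = ["ProbabilityTrack", "BeatCall", "infer", "filter_probabilities", "call_beats"]


@dataclass
class ProbabilityTrack:
    """Per-sample class probabilities over {none, normal QRS, PVC QRS}."""

    probs: np.ndarray  # (L, 3)
    fs: float

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.ndim != 2 or self.probs.shape[1] != 3:
            raise ValueError("probability track must be (L, 3)")
        sums = self.probs.sum(axis=1)
        if np.any(np.abs(sums - 1.0) > 1e-5):
            raise ValueError("per-sample probabilities must sum to 1")

    def __len__(self) -> int:
        return len(self.probs)


@dataclass
class BeatCall:
    """One called beat: location, label and confidence."""

    r_sample: int
    label: str  # 'N' or 'V'
    confidence: float


def infer(model: PvcNet, batch: SegmentBatch) -> ProbabilityTrack:
    """Run the detector and rejoin segments into a full-length track."""
    if batch.n_segments == 0:
        raise ValueError("empty segment batch")
    if batch.segments.shape[1] != SEGMENT_LENGTH:
        raise ValueError(f"segments must have length {SEGMENT_LENGTH}")
    probs = model.predict_proba(batch.segments)  # (n, 2048, 3)
    track = probs.reshape(-1, probs.shape[-1])[: batch.total_length]
    return ProbabilityTrack(track, fs=250.0)


def filter_probabilities(track: ProbabilityTrack, window_ms: float = 40.0) -> ProbabilityTrack:
    """Moving-average smoothing of each class channel, renormalised."""
    w = int(round(window_ms / 1000.0 * track.fs))
    if w < 1:
        raise ValueError("smoothing window shorter than one sample")
    sm = uniform_filter1d(track.probs, size=w, axis=0, mode="nearest")
    sm /= sm.sum(axis=1, keepdims=True)
    return ProbabilityTrack(sm, track.fs)


def call_beats(
    track: ProbabilityTrack,
    threshold: float = 0.5,
    refractory_ms: float = 200.0,
) -> list[BeatCall]:
    """Beat calls from contiguous supra-threshold runs.

    A run is a maximal stretch where the non-background probability exceeds
    ``threshold``.  Its location is the probability-weighted centre, its
    label the class with the larger integrated probability over the run,
    and its confidence the mean non-background probability.  Calls closer
    than the refractory period are merged, keeping the higher-confidence
    call.
    """
    p_beat = 1.0 - track.probs[:, CLASS_NONE]
    above = p_beat > threshold
    if not above.any():
        return []
    edges = np.flatnonzero(np.diff(np.concatenate(([False], above, [False])).astype(int)))
    starts, stops = edges[::2], edges[1::2]

    calls = []
    for lo, hi in zip(starts, stops):
        w = p_beat[lo:hi]
        center = int(round(np.sum(np.arange(lo, hi) * w) / np.sum(w)))
        p_n = track.probs[lo:hi, CLASS_NORMAL].sum()
        p_v = track.probs[lo:hi, CLASS_PVC].sum()
        calls.append(BeatCall(center, "V" if p_v > p_n else "N", float(np.mean(w))))

    refractory = refractory_ms / 1000.0 * track.fs
    merged: list[BeatCall] = []
    for call in calls:
        if merged and call.r_sample - merged[-1].r_sample < refractory:
            if call.confidence > merged[-1].confidence:
                merged[-1] = call
        else:
            merged.append(call)
    return merged
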