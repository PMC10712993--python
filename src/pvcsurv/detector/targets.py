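"""Per-sample training targets from beat annotations.

Each sample inside the QRS support window of a beat is labelled with the
beat's class; everything else is the background class.  Normal beats use a
fixed ±60 ms window around the R peak; PVCs use their full annotated QRS
duration (they are wide by definition, >= 120 ms).
"""

from __future__ import annotations

import numpy as np

from .network import CLASS_NONE, CLASS_NORMAL, CLASS_PVC

__all__ = ["make_targets", "NORMAL_HALF_WIDTH_MS"]

NORMAL_HALF_WIDTH_MS = 60.0


def make_targets(beats, length: int, fs: float) -> np.ndarray:
    """Int class mask of ``length`` samples (0 none / 1 normal / 2 PVC).

    Raises ``ValueError`` if any beat index falls outside the signal or if
    two beats' QRS windows overlap (which would merge complexes and violate
    the beat-spacing contract).
    """
    labels = np.asarray(beats.labels, dtype="<U1")
    r = np.asarray(beats.r_samples, dtype=np.int64)
    qrs_ms = np.asarray(beats.qrs_durations_ms, dtype=float)
    if len(r) and (r.min() < 0 or r.max() >= length):
        raise ValueError("beat index outside the signal")

    mask = np.full(length, CLASS_NONE, dtype=np.int64)
    prev_hi = -1
    for ri, lab, q in zip(r, labels, qrs_ms):
        half = (NORMAL_HALF_WIDTH_MS if lab == "N" else q / 2.0) / 1000.0 * fs
        lo, hi = int(round(ri - half)), int(round(ri + half))
        if lo <= prev_hi:
            raise ValueError(f"QRS windows overlap at sample {ri}")
        mask[max(lo, 0) : min(hi + 1, length)] = CLASS_NORMAL if lab == "N" else CLASS_PVC
        prev_hi = hi
    return mask
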