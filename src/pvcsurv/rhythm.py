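"""PVC burden summaries from a beat sequence.

Turns ground-truth or detector-called beats into the exposure variables the
survival analysis uses: per-phase PVC counts, burden categories
(exercise: 0 / 1–5 / 6–10 / 11–20 / >20; recovery: 0 / 1–5 / >5),
couplet/triplet/run tallies, bigeminy, frequent-PVC (>10 per minute),
short-coupling (R-on-T candidate, <400 ms), multifocality (pairwise
waveform correlation <0.75), heart-rate change metrics and the composite
high-grade flag (frequent or multifocal or run >2 or R-on-T candidate).

Phase membership uses half-open intervals [phase_start, next_phase_start)
on 0-based sample indices.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

__all__ = [
    "PvcSummary",
    "count_by_phase",
    "categorize",
    "detect_runs",
    "detect_bigeminy",
    "frequent_flag",
    "coupling_intervals",
    "multifocal_flag",
    "heart_rate_metrics",
    "summarize",
]

PHASES = ("rest", "exercise", "recovery")
EXERCISE_CATEGORIES = ("0", "1-5", "6-10", "11-20", ">20")
RECOVERY_CATEGORIES = ("0", "1-5", ">5")

FREQUENT_PER_MIN = 10  # strict: > 10 PVCs in any 60-s window
SHORT_COUPLING_MS = 400.0  # strict: < 400 ms flags an R-on-T candidate
MULTIFOCAL_CORR = 0.75  # strict: any pairwise correlation < 0.75


@dataclass
class PvcSummary:
    """One recording's PVC exposure variables."""

    count_rest: int
    count_exercise: int
    count_recovery: int
    category_exercise: str
    category_recovery: str
    n_beats_rest: int
    n_beats_exercise: int
    n_beats_recovery: int
    hr_increase_exercise: float
    hr_decrease_recovery: float
    couplet_count: int
    triplet_count: int
    max_run_length: int
    frequent: bool
    multifocal: bool
    run_gt2: bool
    r_on_t_candidate: bool
    bigeminy: bool
    couplet: bool
    triplet: bool
    high_grade: bool
    resting_pvc: bool

    def to_dict(self) -> dict:
        return asdict(self)


def _labels_and_samples(beats):
    return np.asarray(beats.labels, dtype="<U1"), np.asarray(beats.r_samples, dtype=np.int64)


def count_by_phase(beats, phase_bounds: np.ndarray) -> dict:
    """Per-phase PVC and total beat counts.

    ``phase_bounds`` holds [rest_start, exercise_start, recovery_start, end];
    each beat is assigned to exactly one phase by half-open interval, so the
    per-phase counts always sum to the totals.
    """
    labels, r = _labels_and_samples(beats)
    b = np.asarray(phase_bounds, dtype=np.int64)
    if np.any(np.diff(b) <= 0):
        raise ValueError("phase bounds must be strictly increasing")
    if len(r) and (r.min() < b[0] or r.max() >= b[-1]):
        raise ValueError("beat sample index outside the recording")
    out = {}
    for i, phase in enumerate(PHASES):
        sel = (r >= b[i]) & (r < b[i + 1])
        out[f"count_{phase}"] = int(np.sum(sel & (labels == "V")))
        out[f"n_beats_{phase}"] = int(np.sum(sel))
    return out


def categorize(count: int, phase: str) -> str:
    """Burden category for a per-phase PVC count (boundary-inclusive)."""
    if count < 0:
        raise ValueError("PVC count must be non-negative")
    if phase == "exercise":
        if count == 0:
            return "0"
        if count <= 5:
            return "1-5"
        if count <= 10:
            return "6-10"
        if count <= 20:
            return "11-20"
        return ">20"
    if phase == "recovery":
        if count == 0:
            return "0"
        if count <= 5:
            return "1-5"
        return ">5"
    raise ValueError(f"unknown phase {phase!r}")


def detect_runs(labels) -> tuple[int, int, int]:
    """(couplet_count, triplet_count, max_run_length) over maximal PVC runs.

    A couplet is a maximal run of exactly 2 consecutive PVCs, a triplet
    exactly 3; a 4-run is neither (it is one run of length 4).
    """
    labels = np.asarray(labels, dtype="<U1")
    if len(labels) == 0:
        raise ValueError("empty label sequence")
    bad = set(labels) - {"N", "V"}
    if bad:
        raise ValueError(f"unknown beat label(s): {bad}")
    couplets = triplets = max_run = run = 0
    for lab in labels:
        if lab == "V":
            run += 1
        else:
            couplets += run == 2
            triplets += run == 3
            max_run = max(max_run, run)
            run = 0
    couplets += run == 2
    triplets += run == 3
    max_run = max(max_run, run)
    return couplets, triplets, max_run


def detect_bigeminy(labels, min_pairs: int = 3) -> bool:
    """True iff >= ``min_pairs`` consecutive alternating N-V pairs occur
    (contiguous 'N V N V N V' for the default of 3)."""
    labels = np.asarray(labels, dtype="<U1")
    if len(labels) == 0:
        return False
    target = "NV" * min_pairs
    return target in "".join(labels)


def frequent_flag(beats, fs: float) -> bool:
    """True iff any sliding 60-s window contains more than 10 PVCs.

    Windows are anchored at each PVC; over a 60-s recovery phase this
    reduces to the plain phase count.
    """
    labels, r = _labels_and_samples(beats)
    v = r[labels == "V"]
    if len(v) <= FREQUENT_PER_MIN:
        return False
    w = 60.0 * fs
    # count PVCs in [t, t + 60 s) anchored at each PVC
    hi = np.searchsorted(v, v + w, side="left")
    lo = np.arange(len(v))
    return bool(np.any(hi - lo > FREQUENT_PER_MIN))


def coupling_intervals(beats, fs: float) -> tuple[np.ndarray, bool]:
    """Per-PVC coupling interval (ms) and the R-on-T candidate flag.

    The coupling interval is the R-to-R time from the immediately preceding
    beat to the PVC.  A PVC that is the first beat of the recording has no
    interval and contributes nothing to the flag.  The candidate flag
    considers only PVCs whose preceding beat is a normal (sinus) beat:
    intra-run intervals inside couplets/triplets are short by construction
    and are not coupling intervals.
    """
    labels, r = _labels_and_samples(beats)
    idx = np.where(labels == "V")[0]
    idx = idx[idx > 0]
    if len(idx) == 0:
        return np.empty(0), False
    ci_ms = (r[idx] - r[idx - 1]) * 1000.0 / fs
    coupled = labels[idx - 1] == "N"
    return ci_ms, bool(np.any(ci_ms[coupled] < SHORT_COUPLING_MS))


def multifocal_flag(pvc_snippets: np.ndarray, threshold: float = MULTIFOCAL_CORR) -> bool:
    """True iff any pair of R-aligned PVC waveforms correlates below 0.75.

    With fewer than 2 PVCs multifocality is undefined and reported False.
    """
    snips = np.asarray(pvc_snippets, dtype=float)
    if snips.ndim != 2 or snips.shape[0] < 2:
        return False
    centered = snips - snips.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(centered, axis=1)
    norms[norms == 0] = 1.0
    corr = (centered / norms[:, None]) @ (centered / norms[:, None]).T
    iu = np.triu_indices(len(snips), k=1)
    return bool(np.any(corr[iu] < threshold))


def _mean_hr_in_window(labels: np.ndarray, all_r: np.ndarray, lo: float, hi: float, fs: float, name: str) -> float:
    """Mean HR (bpm) from clean sinus RR intervals inside [lo, hi) samples.

    Only RR intervals between consecutive normal beats count: intervals into
    or out of a PVC (the premature interval and the compensatory pause) are
    excluded so ectopy does not distort the rate estimate.
    """
    # consecutive-normal RR intervals whose midpoint lies in the window
    rr = []
    for i in range(1, len(all_r)):
        if labels[i] == "N" and labels[i - 1] == "N":
            mid = 0.5 * (all_r[i] + all_r[i - 1])
            if lo <= mid < hi:
                rr.append((all_r[i] - all_r[i - 1]) / fs)
    if len(rr) < 1:
        raise ValueError(f"not enough normal beats in window '{name}' to estimate heart rate")
    return 60.0 / float(np.mean(rr))


def heart_rate_metrics(beats, phase_bounds: np.ndarray, fs: float, window_s: float = 15.0) -> dict:
    """Exercise HR increase and recovery HR decrease.

    increase = mean HR over the final ``window_s`` of exercise minus mean HR
    over the rest phase; decrease = mean HR over the final window of
    exercise minus mean HR over the final window of recovery.  Rates come
    from consecutive-normal RR intervals only.
    """
    labels, r = _labels_and_samples(beats)
    b = np.asarray(phase_bounds, dtype=float)
    w = window_s * fs
    hr_rest = _mean_hr_in_window(labels, r, b[0], b[1], fs, "rest")
    hr_ex_end = _mean_hr_in_window(labels, r, b[2] - w, b[2], fs, "exercise end")
    hr_rec_end = _mean_hr_in_window(labels, r, b[3] - w, b[3], fs, "recovery end")
    return {
        "hr_increase_exercise": hr_ex_end - hr_rest,
        "hr_decrease_recovery": hr_ex_end - hr_rec_end,
    }


def summarize(beats, phase_bounds: np.ndarray, fs: float, pvc_snippets: np.ndarray | None = None) -> PvcSummary:
    """Full per-recording exposure summary.

    ``pvc_snippets`` (R-aligned PVC waveforms) enable the multifocality
    flag; without them multifocal is reported False.
    """
    labels, _ = _labels_and_samples(beats)
    counts = count_by_phase(beats, phase_bounds)
    couplets, triplets, max_run = detect_runs(labels) if len(labels) else (0, 0, 0)
    _, r_on_t = coupling_intervals(beats, fs)
    freq = frequent_flag(beats, fs)
    multi = multifocal_flag(pvc_snippets) if pvc_snippets is not None else False
    run_gt2 = max_run > 2
    hr = heart_rate_metrics(beats, phase_bounds, fs)
    return PvcSummary(
        count_rest=counts["count_rest"],
        count_exercise=counts["count_exercise"],
        count_recovery=counts["count_recovery"],
        category_exercise=categorize(counts["count_exercise"], "exercise"),
        category_recovery=categorize(counts["count_recovery"], "recovery"),
        n_beats_rest=counts["n_beats_rest"],
        n_beats_exercise=counts["n_beats_exercise"],
        n_beats_recovery=counts["n_beats_recovery"],
        hr_increase_exercise=hr["hr_increase_exercise"],
        hr_decrease_recovery=hr["hr_decrease_recovery"],
        couplet_count=couplets,
        triplet_count=triplets,
        max_run_length=max_run,
        frequent=freq,
        multifocal=multi,
        run_gt2=run_gt2,
        r_on_t_candidate=r_on_t,
        bigeminy=detect_bigeminy(labels) if len(labels) else False,
        couplet=couplets > 0,
        triplet=triplets > 0,
        high_grade=freq or multi or run_gt2 or r_on_t,
        resting_pvc=counts["count_rest"] >= 1,
    )
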