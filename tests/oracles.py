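"""Independent brute-force reference implementations for rhythm analysis.

These are deliberately naive (loops, explicit enumeration) and share no
code with the package, so they can serve as oracles in equivalence tests.
"""

from __future__ import annotations

import numpy as np


def oracle_count_by_phase(labels, r_samples, bounds):
    out = {}
    for i, phase in enumerate(("rest", "exercise", "recovery")):
        pvc = beats = 0
        for lab, r in zip(labels, r_samples):
            if bounds[i] <= r < bounds[i + 1]:
                beats += 1
                if lab == "V":
                    pvc += 1
        out[f"count_{phase}"] = pvc
        out[f"n_beats_{phase}"] = beats
    return out


def oracle_categorize(count, phase):
    table = {
        "exercise": [((0, 0), "0"), ((1, 5), "1-5"), ((6, 10), "6-10"), ((11, 20), "11-20"), ((21, None), ">20")],
        "recovery": [((0, 0), "0"), ((1, 5), "1-5"), ((6, None), ">5")],
    }[phase]
    for (lo, hi), name in table:
        if count >= lo and (hi is None or count <= hi):
            return name
    raise AssertionError


def oracle_runs(labels):
    """(couplets, triplets, max_run) by explicit run enumeration."""
    runs = []
    i = 0
    labels = list(labels)
    while i < len(labels):
        if labels[i] == "V":
            j = i
            while j < len(labels) and labels[j] == "V":
                j += 1
            runs.append(j - i)
            i = j
        else:
            i += 1
    return (
        sum(1 for r in runs if r == 2),
        sum(1 for r in runs if r == 3),
        max(runs) if runs else 0,
    )


def oracle_bigeminy(labels, min_pairs=3):
    labels = list(labels)
    pat = ["N", "V"] * min_pairs
    for i in range(len(labels) - len(pat) + 1):
        if labels[i : i + len(pat)] == pat:
            return True
    return False


def oracle_frequent(labels, r_samples, fs, per_min=10):
    v = [r for lab, r in zip(labels, r_samples) if lab == "V"]
    for anchor in v:
        n = sum(1 for r in v if anchor <= r < anchor + 60 * fs)
        if n > per_min:
            return True
    return False


def oracle_coupling(labels, r_samples, fs, thresh_ms=400.0):
    intervals = []
    flag = False
    for i in range(1, len(labels)):
        if labels[i] == "V":
            ms = (r_samples[i] - r_samples[i - 1]) * 1000.0 / fs
            intervals.append(ms)
            if labels[i - 1] == "N" and ms < thresh_ms:
                flag = True
    return intervals, flag


def oracle_multifocal(snippets, thresh=0.75):
    snippets = np.asarray(snippets, dtype=float)
    if len(snippets) < 2:
        return False
    for i in range(len(snippets)):
        for j in range(i + 1, len(snippets)):
            if np.corrcoef(snippets[i], snippets[j])[0, 1] < thresh:
                return True
    return False


def random_beat_sequence(rng, n_max=120, fs=250.0):
    """A random labelled beat train with plausible spacing (>=200 ms)."""
    n = int(rng.integers(2, n_max))
    labels = np.where(rng.random(n) < rng.uniform(0.05, 0.5), "V", "N")
    gaps = rng.integers(int(0.21 * fs), int(1.2 * fs), size=n)
    r = np.cumsum(gaps) + int(rng.integers(0, fs))
    return labels.astype("<U1"), r.astype(np.int64)
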