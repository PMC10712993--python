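"""Protocol-faithful synthetic single-lead exercise ECG with ground-truth beats.

The generator emulates a submaximal cycle-ergometer test: a short pretest
resting phase, a graded exercise phase during which heart rate ramps from
``hr_rest`` to ``hr_peak``, and a recovery phase during which heart rate
decays by ``hr_recovery_drop``.  Normal sinus beats are placed along this
heart-rate profile; premature ventricular contractions (PVCs) are injected
on request with exact per-phase counts and configurable rhythm patterns
(isolated, couplet, triplet, run, bigeminy), short or normal coupling
intervals, and one of several distinct wide-QRS morphologies.

Beat waveforms are sums of Gaussians (P-QRS-T for normal beats; a wide
biphasic QRS without a P wave and with a discordant T wave for PVCs), which
is the standard lightweight approach for ECG synthesis.  Every beat written
into the signal is returned as ground truth, so downstream detector and
rhythm code can be scored exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import butter, sosfiltfilt

__all__ = [
    "ProtocolSpec",
    "PvcInjectionSpec",
    "NoiseSpec",
    "EcgRecording",
    "BeatSet",
    "generate_ecg",
    "extract_pvc_snippets",
]

PATTERNS = ("isolated", "couplet", "triplet", "run", "bigeminy")

# slots consumed / PVCs contributed by one injected group of each pattern
_PATTERN_SPAN = {"isolated": 1, "couplet": 2, "triplet": 3, "run": 4, "bigeminy": 6}
_PATTERN_PVCS = {"isolated": 1, "couplet": 2, "triplet": 3, "run": 4, "bigeminy": 3}
# relative slot offsets that become PVCs within the group span
_PATTERN_OFFSETS = {
    "isolated": (0,),
    "couplet": (0, 1),
    "triplet": (0, 1, 2),
    "run": (0, 1, 2, 3),
    "bigeminy": (1, 3, 5),  # N V N V N V
}


@dataclass(frozen=True)
class ProtocolSpec:
    """Timing and heart-rate profile of the exercise test.

    Defaults follow the submaximal protocol: 15 s rest, 6 min graded
    exercise, 1 min recovery, single-lead signal sampled at 500 Hz, at
    either 35% or 50% of the predicted maximum workload.  The predicted
    workload itself is not modelled; the heart-rate end points are
    specified directly.
    """

    rest_duration: float = 15.0
    exercise_duration: float = 360.0
    recovery_duration: float = 60.0
    fs: float = 500.0
    workload_tier: float = 0.50
    hr_rest: float = 65.0
    hr_peak: float = 110.0
    hr_recovery_drop: float = 25.0

    def __post_init__(self) -> None:
        for name in ("rest_duration", "exercise_duration", "recovery_duration"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.fs <= 0:
            raise ValueError("fs must be > 0")
        if self.workload_tier not in (0.35, 0.50):
            raise ValueError("workload_tier must be 0.35 or 0.50")
        if self.hr_peak < self.hr_rest:
            raise ValueError("hr_peak must be >= hr_rest")

    @property
    def total_duration(self) -> float:
        return self.rest_duration + self.exercise_duration + self.recovery_duration

    @property
    def n_samples(self) -> int:
        return int(round(self.total_duration * self.fs))

    def phase_bounds(self) -> np.ndarray:
        """Sample indices [rest_start, exercise_start, recovery_start, end]."""
        b = np.array(
            [
                0,
                round(self.rest_duration * self.fs),
                round((self.rest_duration + self.exercise_duration) * self.fs),
                self.n_samples,
            ],
            dtype=np.int64,
        )
        return b

    def hr_at(self, t: float | np.ndarray) -> float | np.ndarray:
        """Instantaneous heart rate (bpm) at time t seconds from test start.

        Exercise ramps linearly and plateaus at ``hr_peak`` over the final
        10% of the phase; recovery decays linearly to
        ``hr_peak - hr_recovery_drop`` over its first half, then plateaus.
        """
        t = np.asarray(t, dtype=float)
        t1 = self.rest_duration
        t2 = t1 + self.exercise_duration
        ramp_end = t1 + 0.9 * self.exercise_duration
        drop_end = t2 + 0.5 * self.recovery_duration
        hr = np.full_like(t, self.hr_rest)
        in_ex = (t >= t1) & (t < t2)
        frac = np.clip((t - t1) / (ramp_end - t1), 0.0, 1.0)
        hr = np.where(in_ex, self.hr_rest + (self.hr_peak - self.hr_rest) * frac, hr)
        in_rec = t >= t2
        rec_frac = np.clip((t - t2) / (drop_end - t2), 0.0, 1.0)
        hr = np.where(in_rec, self.hr_peak - self.hr_recovery_drop * rec_frac, hr)
        return float(hr) if hr.ndim == 0 else hr


@dataclass(frozen=True)
class PvcInjectionSpec:
    """How many PVCs to plant per phase and in what rhythm patterns.

    ``pattern_mix`` gives proportions over isolated / couplet / triplet /
    run (>3 consecutive) / bigeminy groups; counts are decomposed into whole
    groups and topped up with isolated PVCs so per-phase totals are exact.
    ``r_on_t_fraction`` of PVC groups receive a short (<400 ms) coupling
    interval, which is what flags R-on-T candidates downstream.
    """

    count_rest: int = 0
    count_exercise: int = 0
    count_recovery: int = 0
    pattern_mix: dict = field(
        default_factory=lambda: {"isolated": 1.0, "couplet": 0.0, "triplet": 0.0, "run": 0.0, "bigeminy": 0.0}
    )
    n_morphologies: int = 1
    coupling_interval_ms: float = 440.0
    short_coupling_interval_ms: float = 320.0
    r_on_t_fraction: float = 0.0

    def __post_init__(self) -> None:
        for name in ("count_rest", "count_exercise", "count_recovery"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if set(self.pattern_mix) - set(PATTERNS):
            raise ValueError(f"unknown pattern(s): {set(self.pattern_mix) - set(PATTERNS)}")
        total = sum(self.pattern_mix.values())
        if self.total_count > 0 and not np.isclose(total, 1.0):
            raise ValueError("pattern_mix proportions must sum to 1")
        if self.n_morphologies < 1:
            raise ValueError("n_morphologies must be >= 1")
        if self.coupling_interval_ms <= 0 or self.short_coupling_interval_ms <= 0:
            raise ValueError("coupling intervals must be > 0")
        if not 0.0 <= self.r_on_t_fraction <= 1.0:
            raise ValueError("r_on_t_fraction must be in [0, 1]")

    @property
    def total_count(self) -> int:
        return self.count_rest + self.count_exercise + self.count_recovery


@dataclass(frozen=True)
class NoiseSpec:
    """Additive noise: slow baseline wander plus band-limited Gaussian noise."""

    snr_db: float = 20.0
    baseline_amp_mv: float = 0.08
    baseline_max_hz: float = 0.45
    noise_bandwidth_hz: float = 100.0


@dataclass
class EcgRecording:
    """Single-lead ECG with sampling rate and phase boundaries.

    ``phase_bounds`` holds sample indices
    [rest_start, exercise_start, recovery_start, end]; phases are the
    half-open intervals between consecutive entries.
    """

    samples: np.ndarray
    fs: float
    phase_bounds: np.ndarray

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        self.phase_bounds = np.asarray(self.phase_bounds, dtype=np.int64)
        if self.phase_bounds.shape != (4,):
            raise ValueError("phase_bounds must have 4 entries")
        if np.any(np.diff(self.phase_bounds) <= 0):
            raise ValueError("phase_bounds must be strictly increasing")
        if self.phase_bounds[0] < 0 or self.phase_bounds[-1] != len(self.samples):
            raise ValueError("phase_bounds must span [0, len(samples)]")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    def phase_slice(self, phase: str) -> slice:
        i = {"rest": 0, "exercise": 1, "recovery": 2}[phase]
        return slice(int(self.phase_bounds[i]), int(self.phase_bounds[i + 1]))

    def rescaled_bounds(self, fs_out: float) -> np.ndarray:
        """Phase boundaries mapped to another sampling rate."""
        return np.round(self.phase_bounds * (fs_out / self.fs)).astype(np.int64)


@dataclass
class BeatSet:
    """Ordered ground-truth (or called) beat events.

    ``labels`` are 'N' (normal) or 'V' (PVC); ``qrs_duration_ms`` is the
    annotated QRS width (>= 120 ms for PVCs).
    """

    r_samples: np.ndarray
    labels: np.ndarray
    morph_ids: np.ndarray
    qrs_durations_ms: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        self.r_samples = np.asarray(self.r_samples, dtype=np.int64)
        self.labels = np.asarray(self.labels, dtype="<U1")
        self.morph_ids = np.asarray(self.morph_ids, dtype=np.int64)
        self.qrs_durations_ms = np.asarray(self.qrs_durations_ms, dtype=float)
        n = len(self.r_samples)
        if not (len(self.labels) == len(self.morph_ids) == len(self.qrs_durations_ms) == n):
            raise ValueError("beat arrays must have equal length")
        if n > 1:
            dr = np.diff(self.r_samples)
            if np.any(dr <= 0):
                raise ValueError("r_samples must be strictly increasing")
            if np.any(dr < 0.2 * self.fs):
                raise ValueError("successive beats closer than 200 ms")
        bad = ~np.isin(self.labels, ("N", "V"))
        if np.any(bad):
            raise ValueError(f"unknown beat label(s): {set(self.labels[bad])}")
        if np.any(self.qrs_durations_ms[self.labels == "V"] < 120.0):
            raise ValueError("PVC beats must have QRS duration >= 120 ms")

    def __len__(self) -> int:
        return len(self.r_samples)

    @property
    def n_pvc(self) -> int:
        return int(np.sum(self.labels == "V"))

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "sample_index": self.r_samples,
                "label": self.labels,
                "morph_id": self.morph_ids,
                "qrs_duration_ms": self.qrs_durations_ms,
            }
        )

    def resampled(self, fs_out: float) -> "BeatSet":
        """Beat indices mapped to another sampling rate (e.g. 500 -> 250 Hz)."""
        r = np.round(self.r_samples * (fs_out / self.fs)).astype(np.int64)
        return BeatSet(r, self.labels.copy(), self.morph_ids.copy(), self.qrs_durations_ms.copy(), fs_out)


# ---------------------------------------------------------------------------
# waveform templates


def _gaussians(t: np.ndarray, components) -> np.ndarray:
    out = np.zeros_like(t)
    for amp, mu, sigma in components:
        out += amp * np.exp(-0.5 * ((t - mu) / sigma) ** 2)
    return out


_NORMAL_COMPONENTS = (
    (0.12, -0.200, 0.025),  # P
    (-0.10, -0.026, 0.009),  # Q
    (1.00, 0.000, 0.013),  # R
    (-0.22, 0.026, 0.010),  # S
    (0.30, 0.240, 0.055),  # T
)
_NORMAL_QRS_MS = 92.0


def _pvc_template(morph_id: int, seed: int):
    """Wide biphasic QRS, no P wave, discordant T; distinct per morph_id."""
    rng = np.random.default_rng(np.array([seed % (2**31), 7919 + morph_id], dtype=np.uint64))
    sign = 1.0 if morph_id % 2 == 0 else -1.0
    w1 = rng.uniform(0.040, 0.055)
    amp1 = sign * rng.uniform(1.15, 1.50)
    lobe_dt = rng.uniform(0.055, 0.075)
    amp2 = -sign * rng.uniform(0.55, 0.85)
    w2 = rng.uniform(0.035, 0.050)
    t_amp = -sign * rng.uniform(0.30, 0.45)
    comps = (
        (amp1, 0.0, w1),
        (amp2, lobe_dt, w2),
        (t_amp, 0.33, 0.080),
    )
    qrs_ms = float(np.clip(1000.0 * (lobe_dt + 1.4 * w2 + 1.4 * w1), 130.0, 180.0))
    return comps, qrs_ms


# ---------------------------------------------------------------------------
# injection planning


def _plan_groups(count: int, mix: dict, rng: np.random.Generator):
    """Decompose a PVC count into whole pattern groups (exact total)."""
    if count == 0:
        return []
    groups: list[str] = []
    remaining = count
    # largest patterns first so proportions get a chance before top-up
    for pat in ("bigeminy", "run", "triplet", "couplet"):
        p = mix.get(pat, 0.0)
        n_pvc = _PATTERN_PVCS[pat]
        n_groups = int(round(count * p / n_pvc))
        n_groups = min(n_groups, remaining // n_pvc)
        groups.extend([pat] * n_groups)
        remaining -= n_groups * n_pvc
    # pair up leftovers as couplets only if the mix asked for multi-PVC groups
    groups.extend(["isolated"] * remaining)
    rng.shuffle(groups)
    return groups


def _feasibility_error(phase: str, count: int, available: int, needed: int) -> ValueError:
    return ValueError(
        f"cannot place {count} PVCs in phase '{phase}': "
        f"{needed} beat slots needed but only {available} available at this heart-rate profile"
    )


def generate_ecg(
    protocol: ProtocolSpec,
    pvc: PvcInjectionSpec,
    noise: NoiseSpec | None = NoiseSpec(),
    seed: int = 0,
) -> tuple[EcgRecording, BeatSet]:
    """Synthesize one exercise recording plus its exact ground-truth beats.

    Identical arguments and seed give bit-identical output.  Raises
    ``ValueError`` naming the phase if the requested PVC count cannot be
    placed within the phase duration at the protocol heart-rate profile.
    """
    rng = np.random.default_rng(seed)
    fs = protocol.fs
    total = protocol.total_duration
    bounds_t = np.array(
        [0.0, protocol.rest_duration, protocol.rest_duration + protocol.exercise_duration, total]
    )

    # --- pass 1: provisional all-normal beat grid along the HR profile
    jitter_sd = 0.015
    slot_times = []
    t = 0.35
    while t < total - 0.35:
        slot_times.append(t)
        rr = 60.0 / protocol.hr_at(t)
        t += rr * (1.0 + jitter_sd * rng.standard_normal())
    slot_times = np.array(slot_times)
    n_slots = len(slot_times)
    slot_phase = np.searchsorted(bounds_t[1:3], slot_times, side="right")  # 0,1,2

    # --- choose PVC group placements per phase on the provisional grid
    labels = np.array(["N"] * n_slots, dtype="<U1")
    group_of_slot = np.full(n_slots, -1)
    groups_meta = []  # (group_index, pattern, short_coupling)
    counts = {"rest": pvc.count_rest, "exercise": pvc.count_exercise, "recovery": pvc.count_recovery}
    margin = 2  # keep groups away from phase boundaries
    next_gid = 0
    for phase_idx, phase in enumerate(("rest", "exercise", "recovery")):
        count = counts[phase]
        if count == 0:
            continue
        groups = _plan_groups(count, pvc.pattern_mix, rng)
        phase_slots = np.where(slot_phase == phase_idx)[0]
        if len(phase_slots) <= 2 * margin:
            raise _feasibility_error(phase, count, 0, count)
        usable = phase_slots[margin:-margin]
        needed = sum(_PATTERN_SPAN[g] for g in groups) + (len(groups) - 1)
        if needed > len(usable):
            raise _feasibility_error(phase, count, len(usable), needed)
        # sequential placement with random gaps: distribute the slack
        slack = len(usable) - needed
        gaps = rng.multinomial(slack, np.ones(len(groups) + 1) / (len(groups) + 1))
        pos = 0
        for gi, pat in enumerate(groups):
            pos += gaps[gi] + (1 if gi > 0 else 0)
            start = usable[pos]
            for off in _PATTERN_OFFSETS[pat]:
                labels[start + off] = "V"
                group_of_slot[start + off] = next_gid
            short = bool(rng.random() < pvc.r_on_t_fraction)
            groups_meta.append((next_gid, pat, short))
            next_gid += 1
            pos += _PATTERN_SPAN[pat]

    group_short = {gid: short for gid, _, short in groups_meta}
    morph_of_group = {gid: int(rng.integers(pvc.n_morphologies)) for gid, _, _ in groups_meta}

    # --- pass 2: re-time the beat train applying coupling and pause rules
    r_times = np.empty(n_slots)
    morphs = np.zeros(n_slots, dtype=np.int64)
    qrs_ms = np.full(n_slots, _NORMAL_QRS_MS)
    pvc_templates = {m: _pvc_template(m, seed) for m in range(pvc.n_morphologies)}

    t_prev = slot_times[0]
    group_ci: dict[int, float] = {}
    for i in range(n_slots):
        rr_local = 60.0 / protocol.hr_at(t_prev)
        if i == 0:
            r_times[i] = slot_times[0]
        elif labels[i] == "V":
            gid = group_of_slot[i]
            if i > 0 and labels[i - 1] == "V" and group_of_slot[i - 1] == gid:
                # intra-run interval: short but above the 200 ms refractory floor
                dt = max(0.25, 0.001 * pvc.short_coupling_interval_ms * 0.9)
            else:
                ci = pvc.short_coupling_interval_ms if group_short.get(gid, False) else pvc.coupling_interval_ms
                dt = np.clip(0.001 * ci, 0.25, 0.88 * rr_local)
                group_ci[gid] = float(dt)
            r_times[i] = t_prev + dt
        elif i > 0 and labels[i - 1] == "V":
            # full compensatory pause: RR after the PVC group = 2*RR_local - CI
            ci = group_ci.get(group_of_slot[i - 1], 0.001 * pvc.coupling_interval_ms)
            r_times[i] = t_prev + max(0.30, 2.0 * rr_local - ci)
        else:
            # re-anchor plain sinus beats to the provisional grid so local
            # retiming around PVC groups never accumulates across phases
            t_grid = slot_times[i]
            if t_grid >= t_prev + 0.30:
                r_times[i] = t_grid
            else:
                r_times[i] = t_prev + max(0.30, rr_local * (1.0 + jitter_sd * rng.standard_normal()))
        if labels[i] == "V":
            m = morph_of_group[group_of_slot[i]]
            morphs[i] = m
            qrs_ms[i] = pvc_templates[m][1]
        t_prev = r_times[i]

    keep = r_times < total - 0.30
    r_times, labels, morphs, qrs_ms = r_times[keep], labels[keep], morphs[keep], qrs_ms[keep]

    # --- render the waveform
    n = protocol.n_samples
    sig = np.zeros(n)
    tgrid = np.arange(n) / fs
    half = 0.45  # seconds of template support around each R peak
    for rt, lab, m in zip(r_times, labels, morphs):
        lo = max(0, int((rt - half) * fs))
        hi = min(n, int((rt + half) * fs) + 1)
        tt = tgrid[lo:hi] - rt
        comps = _NORMAL_COMPONENTS if lab == "N" else pvc_templates[int(m)][0]
        sig[lo:hi] += _gaussians(tt, comps)

    if noise is not None:
        p_signal = float(np.mean(sig**2))
        wander = np.zeros(n)
        for _ in range(3):
            f = rng.uniform(0.05, noise.baseline_max_hz)
            ph = rng.uniform(0, 2 * np.pi)
            wander += (noise.baseline_amp_mv / 3) * np.sin(2 * np.pi * f * tgrid + ph)
        white = rng.standard_normal(n)
        if noise.noise_bandwidth_hz < fs / 2:
            sos = butter(4, noise.noise_bandwidth_hz, btype="low", fs=fs, output="sos")
            white = sosfiltfilt(sos, white)
        noise_std = np.sqrt(p_signal / 10 ** (noise.snr_db / 10.0))
        white *= noise_std / max(np.std(white), 1e-12)
        sig = sig + wander + white

    recording = EcgRecording(sig, fs, protocol.phase_bounds())
    beats = BeatSet(
        np.round(r_times * fs).astype(np.int64),
        labels,
        morphs,
        qrs_ms,
        fs,
    )

    # exact-count contract: verify against final (re-timed) beat positions
    b = recording.phase_bounds
    got = {
        ph: int(np.sum((beats.r_samples >= b[i]) & (beats.r_samples < b[i + 1]) & (beats.labels == "V")))
        for i, ph in enumerate(("rest", "exercise", "recovery"))
    }
    want = {"rest": pvc.count_rest, "exercise": pvc.count_exercise, "recovery": pvc.count_recovery}
    if got != want:  # pragma: no cover - guarded by placement margins
        raise RuntimeError(f"PVC placement drifted across phase bounds: wanted {want}, got {got}")
    return recording, beats


def extract_pvc_snippets(
    signal: np.ndarray,
    beats: BeatSet,
    fs: float,
    half_width_ms: float = 120.0,
) -> np.ndarray:
    """R-aligned PVC QRS snippets, shape (n_pvc, 2*half_width+1) — input to
    the multifocality (pairwise-correlation) test."""
    hw = int(round(half_width_ms / 1000.0 * fs))
    rs = beats.r_samples[beats.labels == "V"]
    rs = rs[(rs >= hw) & (rs < len(signal) - hw)]
    if len(rs) == 0:
        return np.empty((0, 2 * hw + 1))
    return np.stack([signal[r - hw : r + hw + 1] for r in rs])
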