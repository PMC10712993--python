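import numpy as np
import pytest

from pvcsurv import rhythm
from pvcsurv.synthetic import BeatSet, NoiseSpec, ProtocolSpec, PvcInjectionSpec, extract_pvc_snippets, generate_ecg

from oracles import (
    oracle_bigeminy,
    oracle_categorize,
    oracle_count_by_phase,
    oracle_coupling,
    oracle_frequent,
    oracle_multifocal,
    oracle_runs,
    random_beat_sequence,
)

FS = 250.0


class FakeBeats:
    """Minimal beat container (labels + sample indices) for oracle tests."""

    def __init__(self, labels, r_samples):
        self.labels = np.asarray(labels, dtype="<U1")
        self.r_samples = np.asarray(r_samples, dtype=np.int64)


def beats_from_times(times_s, labels, fs=FS):
    return FakeBeats(labels, (np.asarray(times_s) * fs).round().astype(int))


class TestCategorize:
    @pytest.mark.parametrize(
        "count,expected",
        [(0, "0"), (3, "1-5"), (5, "1-5"), (6, "6-10"), (7, "6-10"), (10, "6-10"), (15, "11-20"), (20, "11-20"), (21, ">20"), (25, ">20")],
    )
    def test_exercise_boundaries(self, count, expected):
        assert rhythm.categorize(count, "exercise") == expected

    @pytest.mark.parametrize("count,expected", [(0, "0"), (5, "1-5"), (6, ">5"), (40, ">5")])
    def test_recovery_boundaries(self, count, expected):
        assert rhythm.categorize(count, "recovery") == expected

    def test_negative_rejected_and_monotone(self):
        with pytest.raises(ValueError):
            rhythm.categorize(-1, "exercise")
        for phase, cats in (("exercise", rhythm.EXERCISE_CATEGORIES), ("recovery", rhythm.RECOVERY_CATEGORIES)):
            seq = [cats.index(rhythm.categorize(c, phase)) for c in range(60)]
            assert seq == sorted(seq)  # total and monotone in count


class TestCountByPhase:
    BOUNDS = np.array([0, int(15 * FS), int(375 * FS), int(435 * FS)])

    def test_constructed_counts(self):
        beats = beats_from_times(
            [5, 20, 30, 40, 380, 381, 382, 383, 384, 385],
            ["N", "V", "V", "V", "V", "V", "V", "V", "V", "V"],
        )
        out = rhythm.count_by_phase(beats, self.BOUNDS)
        assert (out["count_rest"], out["count_exercise"], out["count_recovery"]) == (0, 3, 6)

    def test_partition_conservation(self, rng):
        labels, r = random_beat_sequence(rng)
        r = np.clip(r, 0, self.BOUNDS[-1] - 1)
        r = np.unique(r)
        beats = FakeBeats(labels[: len(r)], r)
        out = rhythm.count_by_phase(beats, self.BOUNDS)
        assert sum(out[f"n_beats_{p}"] for p in rhythm.PHASES) == len(r)

    def test_out_of_range_beat_rejected(self):
        beats = FakeBeats(["N"], [self.BOUNDS[-1] + 10])
        with pytest.raises(ValueError):
            rhythm.count_by_phase(beats, self.BOUNDS)


class TestRunsAndBigeminy:
    def test_run_examples(self):
        assert rhythm.detect_runs(list("NVVNVVVN")) == (1, 1, 3)
        assert rhythm.detect_runs(list("NNNN")) == (0, 0, 0)
        # a 4-run is one run, not two couplets
        assert rhythm.detect_runs(list("VVVV")) == (0, 0, 4)

    def test_bigeminy_examples(self):
        assert rhythm.detect_bigeminy(list("NVNVNVN")) is True
        assert rhythm.detect_bigeminy(list("NVNVN")) is False  # only 2 pairs
        assert rhythm.detect_bigeminy(list("NNNNNN")) is False

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError):
            rhythm.detect_runs(["N", "X"])


class TestFrequent:
    def test_eleven_in_recovery_minute(self):
        times = 376 + np.arange(11) * 4.0
        beats = beats_from_times(times, ["V"] * 11)
        assert rhythm.frequent_flag(beats, FS) is True

    def test_ten_in_sixty_seconds_is_not_frequent(self):
        beats = beats_from_times(np.arange(10) * 5.0, ["V"] * 10)
        assert rhythm.frequent_flag(beats, FS) is False

    def test_spread_pvcs_are_not_frequent(self):
        # 12 PVCs over 6 min = 2/min: no 60-s window holds more than 10
        beats = beats_from_times(np.arange(12) * 30.0, ["V"] * 12)
        assert rhythm.frequent_flag(beats, FS) is False


class TestCoupling:
    def test_360ms_interval_flags_candidate(self):
        beats = FakeBeats(["N", "V"], [10_000, 10_090])
        ci, flag = rhythm.coupling_intervals(beats, FS)
        assert ci[0] == pytest.approx(360.0)
        assert flag is True

    def test_exactly_400ms_is_not_short(self):
        beats = FakeBeats(["N", "V"], [10_000, 10_100])
        _, flag = rhythm.coupling_intervals(beats, FS)
        assert flag is False

    def test_first_beat_pvc_has_no_interval(self):
        beats = FakeBeats(["V"], [100])
        ci, flag = rhythm.coupling_intervals(beats, FS)
        assert len(ci) == 0 and flag is False


class TestMultifocal:
    def test_identical_and_anticorrelated_pairs(self, rng):
        s = rng.standard_normal(60)
        assert rhythm.multifocal_flag(np.stack([s, s])) is False
        assert rhythm.multifocal_flag(np.stack([s, -s])) is True

    def test_single_pvc_is_not_multifocal(self, rng):
        assert rhythm.multifocal_flag(rng.standard_normal((1, 60))) is False

    def test_generated_morphologies(self):
        proto = ProtocolSpec()
        two, _ = generate_ecg(proto, PvcInjectionSpec(count_exercise=5, n_morphologies=2), noise=NoiseSpec(snr_db=20), seed=1)
        rec2, beats2 = generate_ecg(proto, PvcInjectionSpec(count_exercise=5, n_morphologies=2), noise=NoiseSpec(snr_db=20), seed=1)
        snips = extract_pvc_snippets(rec2.samples, beats2, proto.fs)
        assert rhythm.multifocal_flag(snips) is True
        rec1, beats1 = generate_ecg(proto, PvcInjectionSpec(count_exercise=5, n_morphologies=1), noise=NoiseSpec(snr_db=20), seed=2)
        snips1 = extract_pvc_snippets(rec1.samples, beats1, proto.fs)
        assert rhythm.multifocal_flag(snips1) is False


class TestHeartRateMetrics:
    def make_constant(self, bpm=60.0, total=435.0):
        times = np.arange(0.5, total - 0.5, 60.0 / bpm)
        return beats_from_times(times, ["N"] * len(times))

    BOUNDS = np.array([0, int(15 * FS), int(375 * FS), int(435 * FS)])

    def test_constant_rate_gives_zero_changes(self):
        out = rhythm.heart_rate_metrics(self.make_constant(), self.BOUNDS, FS)
        assert out["hr_increase_exercise"] == pytest.approx(0.0, abs=0.5)
        assert out["hr_decrease_recovery"] == pytest.approx(0.0, abs=0.5)

    def test_piecewise_rate_recovers_planted_changes(self):
        # rest 60 bpm, exercise end 120 bpm, recovery end 90 bpm
        t, times = 0.5, []
        while t < 435:
            times.append(t)
            bpm = 60 if t < 15 else (120 if t < 375 else 90)
            t += 60.0 / bpm
        beats = beats_from_times(times, ["N"] * len(times))
        out = rhythm.heart_rate_metrics(beats, self.BOUNDS, FS)
        assert out["hr_increase_exercise"] == pytest.approx(60.0, abs=2.0)
        assert out["hr_decrease_recovery"] == pytest.approx(30.0, abs=2.0)

    def test_pvc_intervals_excluded(self):
        """Metrics equal the clean-signal metrics when PVCs distort the train."""
        clean = self.make_constant(60.0)
        ref = rhythm.heart_rate_metrics(clean, self.BOUNDS, FS)
        labels = clean.labels.copy()
        r = clean.r_samples.copy().astype(float)
        for i in range(10, 360, 40):  # turn some beats premature
            labels[i] = "V"
            r[i] -= 0.4 * FS
        dirty = FakeBeats(labels, r.astype(int))
        out = rhythm.heart_rate_metrics(dirty, self.BOUNDS, FS)
        assert out["hr_increase_exercise"] == pytest.approx(ref["hr_increase_exercise"], abs=0.5)

    def test_insufficient_beats_errors_with_window_name(self):
        beats = beats_from_times([100.0, 101.0], ["N", "N"])
        with pytest.raises(ValueError, match="rest"):
            rhythm.heart_rate_metrics(beats, self.BOUNDS, FS)


class TestSummarize:
    def test_end_to_end_against_injection_spec(self):
        proto = ProtocolSpec()
        inj = PvcInjectionSpec(
            count_rest=1,
            count_exercise=12,
            count_recovery=11,
            pattern_mix={"isolated": 0.6, "couplet": 0.2, "triplet": 0.2, "run": 0.0, "bigeminy": 0.0},
            n_morphologies=2,
        )
        rec, beats = generate_ecg(proto, inj, seed=13)
        snips = extract_pvc_snippets(rec.samples, beats, proto.fs)
        s = rhythm.summarize(beats, rec.phase_bounds, proto.fs, pvc_snippets=snips)
        assert (s.count_rest, s.count_exercise, s.count_recovery) == (1, 12, 11)
        assert s.category_exercise == "11-20" and s.category_recovery == ">5"
        assert s.resting_pvc is True
        assert s.frequent is True  # 11 PVCs inside the 60-s recovery
        assert s.high_grade is True
        assert s.multifocal is True

    def test_zero_pvc_recording_has_all_flags_false(self):
        proto = ProtocolSpec()
        rec, beats = generate_ecg(proto, PvcInjectionSpec(), seed=14)
        s = rhythm.summarize(beats, rec.phase_bounds, proto.fs)
        assert s.count_exercise == 0 and s.category_exercise == "0"
        assert not any([s.frequent, s.multifocal, s.run_gt2, s.r_on_t_candidate, s.bigeminy, s.couplet, s.triplet, s.high_grade, s.resting_pvc])


def test_full_oracle_equivalence_on_random_sequences(rng):
    """Every count and flag matches the brute-force reference on 1,000
    random beat sequences."""
    for _ in range(1000):
        labels, r = random_beat_sequence(rng)
        beats = FakeBeats(labels, r)
        end = int(r[-1] + 1000)
        bounds = np.sort(rng.choice(np.arange(1, end), size=2, replace=False))
        bounds = np.array([0, bounds[0], bounds[1], end])

        assert rhythm.count_by_phase(beats, bounds) == oracle_count_by_phase(labels, r, bounds)
        assert rhythm.detect_runs(labels) == oracle_runs(labels)
        assert rhythm.detect_bigeminy(labels) == oracle_bigeminy(labels)
        assert rhythm.frequent_flag(beats, FS) == oracle_frequent(labels, r, FS)
        ci, flag = rhythm.coupling_intervals(beats, FS)
        o_ci, o_flag = oracle_coupling(labels, r, FS)
        assert np.allclose(ci, o_ci) and flag == o_flag
        for c in rng.integers(0, 40, size=3):
            assert rhythm.categorize(int(c), "exercise") == oracle_categorize(int(c), "exercise")
            assert rhythm.categorize(int(c), "recovery") == oracle_categorize(int(c), "recovery")

    for _ in range(50):
        snips = rng.standard_normal((int(rng.integers(2, 6)), 40))
        assert rhythm.multifocal_flag(snips) == oracle_multifocal(snips)
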