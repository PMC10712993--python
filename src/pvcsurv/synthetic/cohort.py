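"""Synthetic exercise-test cohort with planted proportional-hazards structure.

One row per participant: clinical covariates, exercise/recovery PVC burden
categories (with the heavily zero-inflated distribution such cohorts show),
an event time drawn from a sex-stratified exponential-baseline proportional
hazards model with planted log hazard ratios, an event type assigned by a
multinomial draw, administrative right-censoring at the follow-up horizon,
and optional MCAR missingness on the variables a real analysis would impute.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["CohortSpec", "generate_cohort", "apply_exclusions", "EXERCISE_CATEGORIES", "RECOVERY_CATEGORIES"]

EXERCISE_CATEGORIES = ("0", "1-5", "6-10", "11-20", ">20")
RECOVERY_CATEGORIES = ("0", "1-5", ">5")

EVENT_TYPES = ("MI", "HF", "LTVA", "CV_death", "nonCV_death")
COMPOSITE_TYPES = ("MI", "HF", "LTVA")
DEATH_TYPES = ("CV_death", "nonCV_death")

#: variables eligible for missingness / imputation, with default MCAR rates
#: mirroring the missing fractions typical of biobank exercise cohorts
DEFAULT_MISSINGNESS = {
    "smoking": 0.004,
    "ldl": 0.082,
    "hdl": 0.132,
    "triglycerides": 0.082,
    "bmi": 0.0001,
    "qrs_ms": 0.009,
    "qtc_ms": 0.046,
    "st_depression": 0.0002,
}

# observed marginal category mass: ~80% / ~90% zero PVC counts for
# exercise / recovery respectively
DEFAULT_EXERCISE_MASS = (0.797, 0.147, 0.028, 0.014, 0.014)
DEFAULT_RECOVERY_MASS = (0.901, 0.084, 0.015)

DEFAULT_EXERCISE_LOG_HR = {
    "1-5": np.log(1.2),
    "6-10": np.log(1.3),
    "11-20": np.log(1.5),
    ">20": np.log(1.8),
}
DEFAULT_RECOVERY_LOG_HR = {"1-5": np.log(1.3), ">5": np.log(1.6)}

DEFAULT_COVARIATE_LOG_HR = {
    "age": 0.055,  # per year, centered at 57
    "diabetes": 0.45,
    "hypertension": 0.30,
    "beta_blocker": 0.15,
    "smoking": 0.35,
    "ldl": 0.10,
    "hdl": -0.30,
    "triglycerides": 0.05,
    "bmi": 0.02,
    "qrs_ms": 0.004,
    "qtc_ms": 0.003,
    "st_depression": 0.30,
    "hr_increase_exercise": -0.008,
    "n_beats_exercise": 0.0,
}

DEFAULT_EVENT_TYPE_MIX = {"MI": 0.33, "HF": 0.20, "LTVA": 0.07, "CV_death": 0.09, "nonCV_death": 0.31}


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of the synthetic cohort.

    ``exposure_log_hr`` plants hazard ratios per exercise PVC category
    (reference "0"); ``recovery_log_hr`` likewise for recovery categories.
    ``confounding`` couples the exposure latent to age and male sex, so that
    omitting those covariates biases a naive fit (0 disables).
    ``exposure_correlation`` couples the exercise and recovery latents so
    high-burden participants tend to have PVCs in both phases.
    """

    n: int = 10_000
    exercise_mass: tuple = DEFAULT_EXERCISE_MASS
    recovery_mass: tuple = DEFAULT_RECOVERY_MASS
    exposure_log_hr: dict = field(default_factory=lambda: dict(DEFAULT_EXERCISE_LOG_HR))
    recovery_log_hr: dict = field(default_factory=lambda: dict(DEFAULT_RECOVERY_LOG_HR))
    covariate_log_hr: dict = field(default_factory=lambda: dict(DEFAULT_COVARIATE_LOG_HR))
    baseline_rate_female: float = 0.0045  # events / person-year at covariate reference
    baseline_rate_male: float = 0.0065
    event_type_mix: dict = field(default_factory=lambda: dict(DEFAULT_EVENT_TYPE_MIX))
    horizon_years: float = 13.0
    missingness: dict = field(default_factory=lambda: dict(DEFAULT_MISSINGNESS))
    confounding: float = 0.25
    exposure_correlation: float = 0.7
    prev_copd: float = 0.010
    prev_ckd: float = 0.031
    prev_resting_pvc: float = 0.030

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("cohort must have n >= 2")
        if not np.isclose(sum(self.exercise_mass), 1.0) or not np.isclose(sum(self.recovery_mass), 1.0):
            raise ValueError("exposure category masses must sum to 1")
        if self.horizon_years <= 0:
            raise ValueError("censoring horizon must be > 0")
        if any(not 0 <= r <= 1 for r in self.missingness.values()):
            raise ValueError("missingness rates must be in [0, 1]")
        if not np.isclose(sum(self.event_type_mix.values()), 1.0):
            raise ValueError("event type mix must sum to 1")
        if self.baseline_rate_female <= 0 or self.baseline_rate_male <= 0:
            raise ValueError("baseline hazard rates must be > 0")


def _categorize_latent(z: np.ndarray, mass: tuple, categories: tuple) -> np.ndarray:
    """Map a standard-normal latent to categories with given marginal mass."""
    from scipy.stats import norm

    cuts = norm.ppf(np.cumsum(mass)[:-1])
    idx = np.searchsorted(cuts, z, side="left")
    return np.asarray(categories, dtype=object)[idx]


def _representative_count(cat: str, rng: np.random.Generator) -> int:
    lo_hi = {"0": (0, 0), "1-5": (1, 5), "6-10": (6, 10), "11-20": (11, 20), ">20": (21, 60), ">5": (6, 40)}[cat]
    return int(rng.integers(lo_hi[0], lo_hi[1] + 1))


def generate_cohort(spec: CohortSpec, seed: int = 0) -> pd.DataFrame:
    """Draw a cohort table; identical spec and seed give identical output.

    Raises ``ValueError`` for degenerate specs (guaranteed all-censored,
    or fewer than 2 participants).
    """
    rng = np.random.default_rng(seed)
    n = spec.n

    age = rng.normal(56.8, 8.2, n).clip(40, 75)
    male = (rng.random(n) < 0.489).astype(int)
    bmi = rng.normal(27.2, 4.5, n).clip(16, 55)
    ldl = rng.normal(3.6, 0.85, n).clip(1.0, 8.0)
    hdl = rng.normal(1.45, 0.38, n).clip(0.5, 3.5)
    trig = np.exp(rng.normal(0.45, 0.45, n)).clip(0.3, 10.0)
    smoking = (rng.random(n) < 0.095).astype(int)
    diabetes = (rng.random(n) < 0.045).astype(int)
    sbp = rng.normal(137, 18, n)
    dbp = rng.normal(82, 10, n)
    prior_htn_dx = rng.random(n) < 0.12
    hypertension = ((sbp >= 140) | (dbp >= 90) | prior_htn_dx).astype(int)
    beta_blocker = (rng.random(n) < 0.05).astype(int)
    qtc = rng.normal(418, 24, n)
    qrs = rng.normal(92, 10, n)
    st_dep = (rng.random(n) < 0.02).astype(int)
    hr_inc = rng.normal(32, 10, n).clip(0, 80)
    hr_dec = rng.normal(20, 8, n).clip(0, 60)
    n_beats_ex = rng.normal(560, 70, n).clip(300, 900).round()
    n_beats_rec = rng.normal(100, 12, n).clip(50, 180).round()
    copd = (rng.random(n) < spec.prev_copd).astype(int)
    ckd = (rng.random(n) < spec.prev_ckd).astype(int)
    resting_pvc = (rng.random(n) < spec.prev_resting_pvc).astype(int)

    # exposure latents: optionally confounded by age and male sex, and
    # correlated between exercise and recovery
    c = spec.confounding
    scale = np.sqrt(max(1.0 - 2 * c**2, 0.05))
    z_ex = c * (age - 56.8) / 8.2 + c * (male - 0.489) / 0.5 + scale * rng.standard_normal(n)
    rho = spec.exposure_correlation
    z_rec = rho * z_ex + np.sqrt(1 - rho**2) * rng.standard_normal(n)
    cat_ex = _categorize_latent(z_ex, spec.exercise_mass, EXERCISE_CATEGORIES)
    cat_rec = _categorize_latent(z_rec, spec.recovery_mass, RECOVERY_CATEGORIES)
    count_ex = np.array([_representative_count(c_, rng) for c_ in cat_ex])
    count_rec = np.array([_representative_count(c_, rng) for c_ in cat_rec])

    # linear predictor of the proportional-hazards model
    chr_ = spec.covariate_log_hr
    lp = np.zeros(n)
    lp += chr_.get("age", 0.0) * (age - 56.8)
    for name, x, center in (
        ("diabetes", diabetes, 0.0),
        ("hypertension", hypertension, 0.0),
        ("beta_blocker", beta_blocker, 0.0),
        ("smoking", smoking, 0.0),
        ("ldl", ldl, 3.6),
        ("hdl", hdl, 1.45),
        ("triglycerides", trig, 1.75),
        ("bmi", bmi, 27.2),
        ("qrs_ms", qrs, 92.0),
        ("qtc_ms", qtc, 418.0),
        ("st_depression", st_dep, 0.0),
        ("hr_increase_exercise", hr_inc, 32.0),
        ("n_beats_exercise", n_beats_ex, 560.0),
    ):
        lp += chr_.get(name, 0.0) * (x - center)
    for cat, b in spec.exposure_log_hr.items():
        lp += b * (cat_ex == cat)
    for cat, b in spec.recovery_log_hr.items():
        lp += b * (cat_rec == cat)

    rate = np.where(male == 1, spec.baseline_rate_male, spec.baseline_rate_female) * np.exp(lp)
    t_event = rng.exponential(1.0 / rate)
    event = (t_event < spec.horizon_years).astype(int)
    time = np.minimum(t_event, spec.horizon_years)
    if event.sum() == 0 and n >= 1000:
        raise ValueError("degenerate spec: event hazard so low the cohort is all-censored")

    types = np.array(list(spec.event_type_mix.keys()), dtype=object)
    probs = np.array(list(spec.event_type_mix.values()))
    drawn = types[rng.choice(len(types), size=n, p=probs / probs.sum())]
    event_type = np.where(event == 1, drawn, "censored")

    df = pd.DataFrame(
        {
            "age": age,
            "sex": np.where(male == 1, "male", "female"),
            "bmi": bmi,
            "ldl": ldl,
            "hdl": hdl,
            "triglycerides": trig,
            "smoking": smoking.astype(float),
            "diabetes": diabetes.astype(float),
            "hypertension": hypertension.astype(float),
            "beta_blocker": beta_blocker.astype(float),
            "qtc_ms": qtc,
            "qrs_ms": qrs,
            "st_depression": st_dep.astype(float),
            "n_beats_exercise": n_beats_ex,
            "n_beats_recovery": n_beats_rec,
            "hr_increase_exercise": hr_inc,
            "hr_decrease_recovery": hr_dec,
            "copd": copd,
            "ckd": ckd,
            "resting_pvc": resting_pvc,
            "count_exercise": count_ex,
            "count_recovery": count_rec,
            "exercise_category": pd.Categorical(cat_ex, categories=list(EXERCISE_CATEGORIES)),
            "recovery_category": pd.Categorical(cat_rec, categories=list(RECOVERY_CATEGORIES)),
            "time_years": time,
            "event": event,
            "event_type": event_type,
        }
    )

    for col, rate_m in spec.missingness.items():
        if rate_m > 0:
            mask = rng.random(n) < rate_m
            df.loc[mask, col] = np.nan
    return df


def apply_exclusions(cohort: pd.DataFrame, rules: set[str] | list[str] | tuple = ()) -> pd.DataFrame:
    """Drop participants with any of the named prevalent-condition flags set.

    ``rules`` names binary flag columns (e.g. ``{"copd", "ckd"}``); the
    result keeps exactly the rows where all requested flags are 0.
    """
    rules = list(rules)
    unknown = [r for r in rules if r not in cohort.columns]
    if unknown:
        raise KeyError(f"unknown exclusion flag(s): {unknown}")
    if not rules:
        return cohort.copy()
    keep = np.ones(len(cohort), dtype=bool)
    for r in rules:
        keep &= cohort[r].to_numpy().astype(bool) == False  # noqa: E712
    return cohort.loc[keep].reset_index(drop=True)
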