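"""Sex-stratified Cox proportional hazards models for PVC-burden exposures.

Two covariate sets mirror the staged adjustment of the analysis:

* ``minimal`` — age plus the number of heartbeats in the relevant phase
  (so the exposure effect is independent of how many beats were observed),
  with sex handled by stratification;
* ``full`` — adds the clinical variables (diabetes, hypertension,
  beta-blocker, smoking, LDL, HDL, triglycerides, BMI) and the exercise-ECG
  variables (QRS duration, QTc, ST-depression flag, and the heart-rate
  change in the relevant phase).

Endpoints are cause-specific: events of other types are censored at their
occurrence.  Ties use the Efron approximation (lifelines' default).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import proportional_hazard_test
from statsmodels.duration.hazard_regression import PHReg

__all__ = ["CoxResult", "fit_cox", "ENDPOINTS", "schoenfeld_test", "MINIMAL_COVARIATES", "FULL_EXTRA_COVARIATES"]

ENDPOINTS = {
    "composite": ("MI", "HF", "LTVA"),
    "all_cause_death": ("CV_death", "nonCV_death"),
    "MI": ("MI",),
    "HF": ("HF",),
    "LTVA": ("LTVA",),
    "CV_death": ("CV_death",),
}

CLINICAL_COVARIATES = [
    "diabetes",
    "hypertension",
    "beta_blocker",
    "smoking",
    "ldl",
    "hdl",
    "triglycerides",
    "bmi",
    "qrs_ms",
    "qtc_ms",
    "st_depression",
]


def _phase_of(exposure: str) -> str:
    return "recovery" if "recovery" in exposure else "exercise"


def MINIMAL_COVARIATES(phase: str) -> list[str]:
    return ["age", f"n_beats_{phase}"]


def FULL_EXTRA_COVARIATES(phase: str) -> list[str]:
    hr = "hr_increase_exercise" if phase == "exercise" else "hr_decrease_recovery"
    return CLINICAL_COVARIATES + [hr]


@dataclass
class CoxResult:
    """Per-exposure-category hazard ratios with model metadata.

    ``beta``/``se``/``cov`` cover the exposure indicator coefficients
    (reference category absent, its coefficient being 0 by construction);
    ``floated`` is filled by :func:`pvcsurv.survival.floated_ci`.
    """

    exposure: str
    categories: list
    reference: str
    beta: pd.Series
    se: pd.Series
    cov: pd.DataFrame
    p: pd.Series
    covariate_set: str
    endpoint: str
    strata: str
    n: int
    n_events: int
    full_summary: pd.DataFrame | None = None
    floated: pd.DataFrame | None = None
    df_inference: float = np.inf  # t-reference df after Rubin pooling

    @property
    def hr(self) -> pd.Series:
        return np.exp(self.beta)

    def conventional_ci(self, alpha: float = 0.05) -> pd.DataFrame:
        from scipy.stats import norm, t as t_dist

        q = (
            norm.ppf(1 - alpha / 2)
            if not np.isfinite(self.df_inference)
            else t_dist.ppf(1 - alpha / 2, self.df_inference)
        )
        return pd.DataFrame(
            {
                "hr": np.exp(self.beta),
                "lo": np.exp(self.beta - q * self.se),
                "hi": np.exp(self.beta + q * self.se),
            }
        )


def _exposure_design(df: pd.DataFrame, exposure: str) -> tuple[pd.DataFrame, list, str]:
    """Indicator columns for the exposure; returns (design, categories, ref)."""
    col = df[exposure]
    if isinstance(col.dtype, pd.CategoricalDtype):
        cats = list(col.cat.categories)
    elif col.dropna().nunique() <= 2:
        x = pd.DataFrame({f"{exposure}::1": col.astype(float)})
        return x, [0, 1], 0
    else:
        cats = sorted(col.dropna().unique())
    # an unobserved category has no estimable coefficient (all-zero column)
    cats = [c for c in cats if (col == c).any()]
    if len(cats) < 2:
        raise ValueError(f"exposure {exposure!r} has fewer than 2 observed categories")
    ref = cats[0]
    design = pd.DataFrame(
        {f"{exposure}::{c}": (col == c).astype(float) for c in cats[1:]}, index=df.index
    )
    return design, cats, ref


def fit_cox(
    cohort: pd.DataFrame,
    exposure: str = "exercise_category",
    covariate_set: str = "full",
    endpoint: str = "composite",
    strata: str = "sex",
    extra_covariates: tuple = (),
    covariates: tuple | None = None,
) -> CoxResult:
    """Fit one sex-stratified cause-specific Cox model.

    ``covariates`` overrides the standard minimal/full sets entirely (used
    e.g. to demonstrate confounding by omitting an adjustment variable).
    Raises ``ValueError`` on an unknown endpoint/covariate set and a
    ``ConvergenceError`` with diagnostics if the partial-likelihood fit
    fails (e.g. monotone likelihood from separation).
    """
    if endpoint not in ENDPOINTS:
        raise ValueError(f"unknown endpoint {endpoint!r}; one of {sorted(ENDPOINTS)}")
    if covariate_set not in ("minimal", "full"):
        raise ValueError("covariate_set must be 'minimal' or 'full'")
    phase = _phase_of(exposure)
    if covariates is not None:
        covs = list(covariates)
    else:
        covs = MINIMAL_COVARIATES(phase)
        if covariate_set == "full":
            covs = covs + FULL_EXTRA_COVARIATES(phase)
        covs = covs + [c for c in extra_covariates if c not in covs]

    expo, cats, ref = _exposure_design(cohort, exposure)
    event = cohort["event_type"].isin(ENDPOINTS[endpoint]).astype(int)
    X = pd.concat([expo, cohort[covs].astype(float)], axis=1)
    if X.isna().any().any():
        bad = list(X.columns[X.isna().any()])
        raise ValueError(f"NaNs in model covariates {bad}; impute before fitting")

    n_events = int(event.sum())
    n_params = X.shape[1]
    if n_events < 10 * n_params:
        warnings.warn(
            f"only {n_events} events for {n_params} parameters (<10 per parameter); "
            "estimates may be unstable",
            stacklevel=2,
        )

    strata_codes = cohort[strata].astype(str).to_numpy()
    try:
        model = PHReg(
            cohort["time_years"].to_numpy(),
            X,
            status=event.to_numpy(),
            strata=strata_codes,
            ties="efron",
        )
        fit = model.fit(method="newton", maxiter=200, disp=False)
        if not np.all(np.isfinite(fit.bse)):
            raise ValueError("non-finite standard errors")
    except Exception as err:
        counts = {c: int(expo[c].sum()) for c in expo.columns}
        raise ConvergenceError(
            f"Cox fit failed for exposure={exposure}, endpoint={endpoint}: {err}. "
            f"Events={n_events}, exposure-group sizes={counts}; "
            "check for separation or empty categories."
        ) from err

    names = list(X.columns)
    expo_cols = list(expo.columns)
    params = pd.Series(fit.params, index=names)
    bse = pd.Series(fit.bse, index=names)
    cov_all = pd.DataFrame(fit.cov_params(), index=names, columns=names)
    pvals = pd.Series(fit.pvalues, index=names)
    summary = pd.DataFrame({"coef": params, "se(coef)": bse, "hr": np.exp(params), "p": pvals})

    res = CoxResult(
        exposure=exposure,
        categories=cats,
        reference=ref,
        beta=params[expo_cols].copy(),
        se=bse[expo_cols].copy(),
        cov=cov_all.loc[expo_cols, expo_cols].copy(),
        p=pvals[expo_cols].copy(),
        covariate_set=covariate_set,
        endpoint=endpoint,
        strata=strata,
        n=len(cohort),
        n_events=n_events,
        full_summary=summary,
    )
    res._design = pd.concat(
        [X, cohort[[strata]], pd.DataFrame({"time": cohort["time_years"], "event": event})], axis=1
    )
    return res


def schoenfeld_test(result: CoxResult) -> pd.DataFrame:
    """Schoenfeld-residual test of proportional hazards per covariate.

    The one diagnostic the analysis relies on: a small p-value for a
    covariate (typically sex, when unstratified) argues for stratifying on
    it rather than modelling it.
    """
    if not hasattr(result, "_design"):
        raise ValueError("schoenfeld_test needs a freshly fitted (not pooled) CoxResult")
    design = result._design.copy()
    # unstratified fit with the stratification variable as a covariate:
    # its Schoenfeld test is what motivates stratifying on it
    codes = pd.Categorical(design.pop(result.strata).astype(str)).codes.astype(float)
    design[result.strata] = codes
    cph = CoxPHFitter()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cph.fit(design, duration_col="time", event_col="event")
        out = proportional_hazard_test(cph, design, time_transform="rank")
    return out.summary
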