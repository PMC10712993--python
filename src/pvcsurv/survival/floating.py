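"""Floated absolute-risk confidence intervals for a categorical exposure.

A Cox model with K exposure categories estimates K-1 log hazard ratios
against the reference, so the reference group conventionally gets no CI and
every other CI absorbs the reference group's sampling noise.  Floated
variances v_0 … v_{K-1} re-express the uncertainty so that each group —
including the reference — carries its own variance, with the defining
property that v_i + v_j reproduces Var(beta_i - beta_j) for every pair.

The model-based decomposition used here exploits the structure such
covariance matrices actually have: every contrast shares the reference
group's variability, so Cov(beta_i, beta_j) ≈ v_0 for i != j and
Var(beta_i) ≈ v_0 + v_i.  A closed-form fit (v_0 = mean off-diagonal
covariance) is refined by bounded least squares on the relative error of
all pairwise contrast variances.  In the independence limit (all
off-diagonal covariances zero) v_0 hits a small floor rather than 0, and
with K=2 the single contrast forces only the sum v_0 + v_1, which the
floor convention closes.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from scipy.stats import norm, t as t_dist

__all__ = ["floated_variances", "floated_ci"]


def _contrast_variances(cov: np.ndarray) -> np.ndarray:
    """Var(beta_i - beta_j) for all pairs over groups 0..K-1 (beta_0 = 0).

    Returns a (K, K) matrix; entry (0, j) is Var(beta_j) itself.
    """
    K = cov.shape[0] + 1
    out = np.zeros((K, K))
    d = np.diag(cov)
    out[0, 1:] = d
    out[1:, 0] = d
    for i in range(1, K):
        for j in range(1, K):
            if i != j:
                out[i, j] = d[i - 1] + d[j - 1] - 2 * cov[i - 1, j - 1]
    return out


def floated_variances(cov: np.ndarray, floor: float | None = None) -> np.ndarray:
    """Floated variances (length K) from the (K-1, K-1) coefficient
    covariance of the non-reference exposure indicators.

    Raises ``ValueError`` if the covariance block is not positive definite.
    """
    cov = np.asarray(cov, dtype=float)
    if cov.ndim != 2 or cov.shape[0] != cov.shape[1] or cov.shape[0] < 1:
        raise ValueError("covariance must be a square matrix with K-1 >= 1")
    if np.any(np.linalg.eigvalsh((cov + cov.T) / 2) <= 0):
        raise ValueError("exposure coefficient covariance is not positive definite")
    K = cov.shape[0] + 1
    if floor is None:
        floor = 1e-6 * float(np.mean(np.diag(cov)))

    d = np.diag(cov)
    if K == 2:
        # one free contrast: only v_0 + v_1 = Var(beta_1) is identified;
        # the floor convention closes the split
        return np.array([floor, max(d[0] - floor, floor)])
    iu = np.triu_indices(K - 1, k=1)
    v0 = max(float(np.mean(cov[iu])), floor)
    v = np.concatenate(([v0], np.maximum(d - v0, floor)))

    cv = _contrast_variances(cov)
    pairs = [(i, j) for i in range(K) for j in range(i + 1, K)]

    def resid(logv):
        vv = np.exp(logv)
        return np.array([(vv[i] + vv[j]) / cv[i, j] - 1.0 for i, j in pairs])

    sol = least_squares(resid, np.log(v), method="lm", xtol=1e-12, ftol=1e-12)
    v = np.exp(sol.x)
    return np.maximum(v, floor)


def floated_ci(result, alpha: float = 0.05) -> pd.DataFrame:
    """Attach floated per-group CIs (reference included) to a CoxResult.

    Returns a DataFrame indexed by category with columns
    ``hr, lo, hi, floated_var`` and stores it on ``result.floated``.
    ``result.df_inference`` (finite after Rubin pooling) selects a t
    instead of a normal reference.
    """
    v = floated_variances(result.cov.to_numpy())
    beta = np.concatenate(([0.0], result.beta.to_numpy()))
    if np.isfinite(result.df_inference):
        q = t_dist.ppf(1 - alpha / 2, result.df_inference)
    else:
        q = norm.ppf(1 - alpha / 2)
    out = pd.DataFrame(
        {
            "hr": np.exp(beta),
            "lo": np.exp(beta - q * np.sqrt(v)),
            "hi": np.exp(beta + q * np.sqrt(v)),
            "floated_var": v,
        },
        index=pd.Index(result.categories, name=result.exposure),
    )
    result.floated = out
    return out
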