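"""Rubin's rules for combining Cox fits across imputed datasets.

Pooled point estimate: the mean of the per-imputation coefficients.
Total variance: mean within-imputation variance plus (1 + 1/m) times the
between-imputation variance.  Interval inference uses a t reference with
the Barnard–Rubin small-sample degrees of freedom, which is safe at any
sample size and reduces to the classic large-sample formula as n grows.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .cox import CoxResult

__all__ = ["pool_rubin", "barnard_rubin_df"]


def barnard_rubin_df(lam: float, m: int, nu_com: float) -> float:
    """Barnard–Rubin adjusted degrees of freedom.

    ``lam`` is the fraction of variance attributable to missingness,
    ``nu_com`` the complete-data degrees of freedom.
    """
    if lam <= 0:
        return nu_com
    nu_old = (m - 1) / lam**2
    nu_obs = (nu_com + 1) / (nu_com + 3) * nu_com * (1 - lam)
    return 1.0 / (1.0 / nu_old + 1.0 / nu_obs)


def pool_rubin(results: list[CoxResult]) -> CoxResult:
    """Pool exposure coefficients (and their covariance) across imputations.

    All results must share the model specification.  The pooled covariance
    block (used for floated CIs) follows the same decomposition:
    mean within-covariance + (1 + 1/m) x between-covariance.
    """
    if len(results) < 1:
        raise ValueError("nothing to pool")
    first = results[0]
    for r in results[1:]:
        same = (
            r.exposure == first.exposure
            and r.categories == first.categories
            and r.covariate_set == first.covariate_set
            and r.endpoint == first.endpoint
            and r.strata == first.strata
            and list(r.beta.index) == list(first.beta.index)
        )
        if not same:
            raise ValueError("cannot pool results with mismatched model specifications")
    m = len(results)
    names = first.beta.index
    betas = np.stack([r.beta.to_numpy() for r in results])
    covs = np.stack([r.cov.to_numpy() for r in results])

    qbar = betas.mean(axis=0)
    wbar = covs.mean(axis=0)
    if m > 1:
        dev = betas - qbar
        b_cov = (dev[:, :, None] * dev[:, None, :]).sum(axis=0) / (m - 1)
    else:
        b_cov = np.zeros_like(wbar)
    total_cov = wbar + (1 + 1 / m) * b_cov
    total_var = np.diag(total_cov)

    # per-coefficient missing-information fraction and Barnard-Rubin df;
    # the scalar df for the result is the most conservative (smallest)
    nu_com = max(first.n_events - len(names), 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        lam = (1 + 1 / m) * np.diag(b_cov) / total_var
    dfs = np.array([barnard_rubin_df(float(l), m, nu_com) for l in lam]) if m > 1 else np.full(len(names), nu_com)

    se = np.sqrt(total_var)
    from scipy.stats import t as t_dist

    p = 2 * t_dist.sf(np.abs(qbar) / se, dfs)

    return CoxResult(
        exposure=first.exposure,
        categories=first.categories,
        reference=first.reference,
        beta=pd.Series(qbar, index=names),
        se=pd.Series(se, index=names),
        cov=pd.DataFrame(total_cov, index=names, columns=names),
        p=pd.Series(p, index=names),
        covariate_set=first.covariate_set,
        endpoint=first.endpoint,
        strata=first.strata,
        n=first.n,
        n_events=int(np.mean([r.n_events for r in results])),
        df_inference=float(dfs.min()),
    )
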