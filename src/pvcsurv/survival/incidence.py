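"""Cumulative incidence (Kaplan-Meier complement) curves and log-rank test."""

from __future__ import annotations

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test

from .cox import ENDPOINTS

__all__ = ["cumulative_incidence"]


def cumulative_incidence(
    cohort: pd.DataFrame,
    group_var: str,
    endpoint: str = "composite",
) -> tuple[dict, float]:
    """Per-group cumulative incidence curves and the log-rank p across groups.

    Returns ``(curves, p)`` where ``curves`` maps group label to a
    DataFrame with columns ``time`` and ``cum_incidence`` (0 at time 0).
    Raises ``ValueError`` with a single group or no events.
    """
    if endpoint not in ENDPOINTS:
        raise ValueError(f"unknown endpoint {endpoint!r}")
    event = cohort["event_type"].isin(ENDPOINTS[endpoint]).astype(int)
    groups = cohort[group_var]
    labels = [g for g in (groups.cat.categories if hasattr(groups, "cat") else sorted(groups.unique())) if (groups == g).any()]
    if len(labels) < 2:
        raise ValueError("cumulative incidence needs at least 2 groups")
    if event.sum() == 0:
        raise ValueError("no events for this endpoint")

    curves = {}
    for g in labels:
        sel = groups == g
        kmf = KaplanMeierFitter()
        kmf.fit(cohort.loc[sel, "time_years"], event.loc[sel])
        sf = kmf.survival_function_
        curves[g] = pd.DataFrame({"time": sf.index.to_numpy(), "cum_incidence": 1.0 - sf.iloc[:, 0].to_numpy()})

    lr = multivariate_logrank_test(cohort["time_years"], groups.astype(str), event)
    return curves, float(lr.p_value)
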