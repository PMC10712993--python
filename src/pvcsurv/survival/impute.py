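"""Multiple imputation by chained equations with predictive mean matching.

Defaults follow common practice for cohort analyses of this kind: m=5
completed datasets, 10 chained-equation iterations per dataset, PMM with a
donor pool of 5 nearest predicted neighbours, and all baseline variables
(plus the outcome columns) informing each conditional model.  Each
completed dataset is an independent chain, so between-imputation
variability is honest.

The chained-equation engine is statsmodels' ``MICEData`` (PMM is its
native imputation method); this module wraps it behind the cohort-table
interface and guarantees observed cells are never touched.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from statsmodels.imputation.mice import MICEData

__all__ = ["impute", "IMPUTABLE_COLUMNS"]

#: variables the analysis imputes when missing
IMPUTABLE_COLUMNS = ["smoking", "ldl", "hdl", "triglycerides", "bmi", "qrs_ms", "qtc_ms", "st_depression"]

_PREDICTORS = [
    "age",
    "diabetes",
    "hypertension",
    "beta_blocker",
    "hr_increase_exercise",
    "n_beats_exercise",
    "time_years",
    "event",
]


def impute(
    cohort: pd.DataFrame,
    m: int = 5,
    iterations: int = 10,
    k_pmm: int = 5,
    seed: int = 0,
) -> list[pd.DataFrame]:
    """Return ``m`` completed copies of the cohort table.

    Missingness is only allowed in ``IMPUTABLE_COLUMNS``; a column that is
    entirely missing cannot be imputed and raises ``ValueError``.  With no
    missing data the result is ``m`` identical copies.
    """
    missing_cols = [c for c in cohort.columns if cohort[c].isna().any()]
    illegal = set(missing_cols) - set(IMPUTABLE_COLUMNS)
    if illegal:
        raise ValueError(f"missing values in non-imputable column(s): {sorted(illegal)}")
    fully_missing = [c for c in missing_cols if cohort[c].isna().all()]
    if fully_missing:
        raise ValueError(f"column(s) fully missing, nothing to match on: {fully_missing}")
    if not missing_cols:
        return [cohort.copy() for _ in range(m)]

    predictors = [c for c in _PREDICTORS if c in cohort.columns]
    work_cols = list(dict.fromkeys(missing_cols + [c for c in IMPUTABLE_COLUMNS if c in cohort.columns] + predictors))
    base = cohort[work_cols].astype(float).copy()
    base["male"] = (cohort["sex"] == "male").astype(float)

    observed_mask = {c: cohort[c].notna().to_numpy() for c in missing_cols}
    completed = []
    for j in range(m):
        np.random.seed((seed + 104729 * (j + 1)) % 2**31)  # MICEData uses the global RNG
        md = MICEData(base.copy(), k_pmm=k_pmm)
        md.update_all(iterations)
        out = cohort.copy()
        for c in missing_cols:
            filled = md.data[c].to_numpy()
            # observed cells must be byte-identical to the input
            assert np.allclose(filled[observed_mask[c]], cohort[c].to_numpy()[observed_mask[c]])
            out[c] = filled
        completed.append(out)
    return completed
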