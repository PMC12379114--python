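"""Human Population Laboratory (HPL) depression scale.

An 18-item self-report screen for depressive symptoms used in
epidemiological studies.  Each item is a binary indicator (1 = the answer
indicates a depressive symptom); the total is the count of symptom answers
(0-18), and a total of 5 or more flags clinically significant depressive
symptoms.  Items arrive already dichotomized; any missing item makes the
whole outcome missing (the conservative rule used for exclusion).
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "N_ITEMS",
    "CLINICAL_CUTOFF",
    "HPL_ITEM_COLUMNS",
    "hpl_total",
    "classify_depression",
    "score_hpl",
]

N_ITEMS = 18
CLINICAL_CUTOFF = 5
HPL_ITEM_COLUMNS = tuple(f"hpl_{i:02d}" for i in range(1, N_ITEMS + 1))


def hpl_total(items: Sequence[int]) -> int:
    """Sum an 18-item response vector: one point per symptom answer."""
    arr = np.asarray(items)
    if arr.shape != (N_ITEMS,):
        raise ValueError(f"expected exactly {N_ITEMS} item responses, got shape {arr.shape}")
    if pd.isna(arr.astype(object)).any():
        raise ValueError("missing item response: HPL total is undefined (outcome missing)")
    arr = arr.astype(float)
    if not np.isin(arr, (0.0, 1.0)).all():
        raise ValueError("item responses must be binary 0/1")
    return int(arr.sum())


def classify_depression(total: int) -> bool:
    """True when the HPL total reaches the clinical cut-off (>= 5)."""
    if not 0 <= total <= N_ITEMS:
        raise ValueError(f"HPL total must be in [0, {N_ITEMS}], got {total}")
    return total >= CLINICAL_CUTOFF


def score_hpl(cohort: pd.DataFrame) -> pd.DataFrame:
    """Score hpl_01..hpl_18 columns for a whole cohort.

    Returns a DataFrame indexed like ``cohort`` with ``hpl_total`` and the
    boolean ``hpl_case`` flag.  Rows with any missing item get a missing
    total and flag (outcome missing as a block; exclusion is handled
    upstream).  Non-binary responses raise.
    """
    missing_cols = [c for c in HPL_ITEM_COLUMNS if c not in cohort.columns]
    if missing_cols:
        raise ValueError(f"cohort is missing HPL item columns: {missing_cols}")
    items = cohort.loc[:, list(HPL_ITEM_COLUMNS)].astype(float)
    observed = items.notna()
    vals = items.to_numpy()
    bad = ~np.isin(vals, (0.0, 1.0)) & observed.to_numpy()
    if bad.any():
        r, c = np.argwhere(bad)[0]
        raise ValueError(
            f"non-binary HPL response {vals[r, c]!r} for participant "
            f"{cohort.index[r]!r}, item {HPL_ITEM_COLUMNS[c]}"
        )
    complete = observed.all(axis=1)
    out = pd.DataFrame(index=cohort.index)
    total = items.sum(axis=1)
    total[~complete] = np.nan
    out["hpl_total"] = total
    out["hpl_case"] = (total >= CLINICAL_CUTOFF).astype(float)
    out.loc[~complete, "hpl_case"] = np.nan
    return out
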