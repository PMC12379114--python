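"""Healthy Nordic diet score (HNDS).

The HNDS is an a priori diet-quality index adapted from the Baltic Sea Diet
Score.  Nine components are scored from 4-day mean intakes:

* six food groups — fruits and berries, vegetables, cereals, low-fat milk,
  fish, meat products — and two nutrients — total fat (E%) and the fat
  ratio PUFA / (SFA + TFA) — are scored 0-3 points by within-cohort
  quartile of consumption.  For the six positive components and the fat
  ratio the highest quartile earns 3 points; for the two negative
  components (meat products, total fat) the order is reversed.
* alcohol is scored 0 points when ethanol intake is >= 20 g/d and 1 point
  otherwise.

The total (0-25) sums the nine component points; higher means closer
adherence to a healthy Nordic-style diet.  Quartile cut-points are always
computed *within the supplied cohort*, so a participant's points depend on
the roster they are scored with.
"""

from __future__ import annotations

from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "POSITIVE_COMPONENTS",
    "NEGATIVE_COMPONENTS",
    "INTAKE_COLUMNS",
    "component_quartile_points",
    "alcohol_points",
    "fat_ratio",
    "compute_hnds",
    "quartile_of",
]

#: quartile-scored components where a higher intake earns more points
POSITIVE_COMPONENTS = (
    "fruits_berries",
    "vegetables",
    "cereals",
    "lowfat_milk",
    "fish",
    "fat_ratio",
)

#: quartile-scored components where a higher intake earns fewer points
NEGATIVE_COMPONENTS = ("meat_products", "total_fat")

#: raw intake columns a cohort table must provide for scoring
INTAKE_COLUMNS = (
    "fruits_berries",
    "vegetables",
    "cereals",
    "lowfat_milk",
    "fish",
    "meat_products",
    "total_fat",
    "pufa",
    "sfa",
    "tfa",
    "ethanol",
)

ALCOHOL_THRESHOLD_G_PER_DAY = 20.0


def quartile_of(values: Sequence[float] | np.ndarray) -> np.ndarray:
    """Assign each value its within-sample quartile (1-4).

    Cut-points are the empirical 25th/50th/75th percentiles by the
    median-unbiased estimator; assignment is half-open: below Q1 -> 1,
    [Q1, Q2) -> 2, [Q2, Q3) -> 3, >= Q3 -> 4.  Tied values always share a
    quartile, so group sizes may be unequal; when every value is identical
    all land in quartile 4.
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("cannot assign quartiles to an empty value list")
    bad = np.flatnonzero(~np.isfinite(v))
    if bad.size:
        raise ValueError(f"non-finite value at index {bad[0]}")
    q1, q2, q3 = np.quantile(v, [0.25, 0.50, 0.75], method="median_unbiased")
    return 1 + (v >= q1).astype(int) + (v >= q2).astype(int) + (v >= q3).astype(int)


def component_quartile_points(
    values: Sequence[float] | np.ndarray,
    direction: Literal["positive", "negative"],
) -> np.ndarray:
    """Quartile points (0-3) for one score component across a cohort.

    Parameters
    ----------
    values
        The component intake for every participant in the cohort (>= 0,
        finite).  Cut-points come from this list only.
    direction
        ``"positive"``: quartile q earns q-1 points (highest intake -> 3).
        ``"negative"``: quartile q earns 4-q points (highest intake -> 0).
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("component values must be non-empty")
    bad = np.flatnonzero(~np.isfinite(v) | (v < 0))
    if bad.size:
        raise ValueError(
            f"invalid component value {v[bad[0]]!r} at index {bad[0]}: "
            "values must be finite and >= 0"
        )
    quart = quartile_of(v)
    if direction == "positive":
        return quart - 1
    if direction == "negative":
        return 4 - quart
    raise ValueError(f"direction must be 'positive' or 'negative', got {direction!r}")


def alcohol_points(ethanol: float) -> int:
    """Alcohol component: 0 points if ethanol intake >= 20 g/d, else 1."""
    if not np.isfinite(ethanol) or ethanol < 0:
        raise ValueError(f"ethanol intake must be finite and >= 0, got {ethanol!r}")
    return 0 if ethanol >= ALCOHOL_THRESHOLD_G_PER_DAY else 1


def fat_ratio(pufa: float, sfa: float, tfa: float) -> float:
    """Dietary fat-quality ratio PUFA / (SFA + TFA), from gram intakes."""
    for name, val in (("pufa", pufa), ("sfa", sfa), ("tfa", tfa)):
        if not np.isfinite(val) or val < 0:
            raise ValueError(f"{name} must be finite and >= 0, got {val!r}")
    denom = sfa + tfa
    if denom <= 0:
        raise ValueError("fat ratio undefined: SFA + TFA is zero")
    return pufa / denom


def compute_hnds(cohort: pd.DataFrame) -> pd.DataFrame:
    """Score a cohort: per-component points and the HNDS total (0-25).

    ``cohort`` must contain the columns in :data:`INTAKE_COLUMNS`, complete
    for every row (participants with missing diet data are excluded
    upstream, never dropped silently here).  Returns a DataFrame indexed
    like ``cohort`` with nine ``*_points`` columns and ``hnds_total``.
    """
    missing_cols = [c for c in INTAKE_COLUMNS if c not in cohort.columns]
    if missing_cols:
        raise ValueError(f"cohort is missing intake columns: {missing_cols}")
    intake = cohort.loc[:, list(INTAKE_COLUMNS)]
    incomplete = intake.isna().any(axis=1)
    if incomplete.any():
        ids = list(cohort.index[incomplete][:20])
        raise ValueError(
            f"{int(incomplete.sum())} participant(s) have missing diet "
            f"components (first ids: {ids}); apply exclusions first"
        )

    ratio = np.empty(len(cohort), dtype=float)
    denom = intake["sfa"].to_numpy() + intake["tfa"].to_numpy()
    undefined = denom <= 0
    if undefined.any():
        ids = list(cohort.index[undefined][:20])
        raise ValueError(f"fat ratio undefined (SFA + TFA = 0) for participants {ids}")
    ratio = intake["pufa"].to_numpy() / denom

    out = pd.DataFrame(index=cohort.index)
    component_values = {
        "fruits_berries": intake["fruits_berries"],
        "vegetables": intake["vegetables"],
        "cereals": intake["cereals"],
        "lowfat_milk": intake["lowfat_milk"],
        "fish": intake["fish"],
        "fat_ratio": ratio,
        "meat_products": intake["meat_products"],
        "total_fat": intake["total_fat"],
    }
    for comp in POSITIVE_COMPONENTS:
        out[f"{comp}_points"] = component_quartile_points(component_values[comp], "positive")
    for comp in NEGATIVE_COMPONENTS:
        out[f"{comp}_points"] = component_quartile_points(component_values[comp], "negative")
    out["alcohol_points"] = [alcohol_points(e) for e in intake["ethanol"]]
    out["hnds_total"] = out.sum(axis=1)
    return out
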