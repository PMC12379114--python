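"""Synthetic cohort generation.

One latent diet-quality factor per participant drives correlated component
intakes (positive loadings on fruits/vegetables/cereals/low-fat milk/fish
and the fat-quality inputs, negative on meat products, total fat and
ethanol).  A depression liability combines a configurable loading on that
factor with confounder contributions (smoking, SES, marital status) and
noise, and generates the 18 HPL items as conditionally independent
Bernoulli draws with a logistic link.  Randomness is organised as named
substreams of one seed, so adding a variable never perturbs the draws of
another.
"""

from __future__ import annotations

import zlib

import numpy as np
import pandas as pd

from .config import SyntheticConfig
from .diet_score import INTAKE_COLUMNS
from .hpl import HPL_ITEM_COLUMNS, N_ITEMS

__all__ = ["generate_cohort", "inject_missingness", "COHORT_COLUMNS", "write_cohort_csv", "read_cohort_csv"]

#: documented CSV header for a cohort table, one row per participant;
#: missing values are written as empty fields
COHORT_COLUMNS = (
    ("participant_id", "age", "exam_year", "energy_kj", "ltpa_kj", "ses",
     "smoking", "marital", "bmi", "cvd_history", "mental_illness_history")
    + INTAKE_COLUMNS
    + HPL_ITEM_COLUMNS
    + ("latent_diet", "latent_liability")
)

_SMOKING_LEVELS = ("never", "previous", "current")
_MARITAL_LEVELS = ("couple", "other")


def _rng(seed: int, stream: str) -> np.random.Generator:
    """Independent substream keyed by (seed, crc32(stream name))."""
    return np.random.default_rng([int(seed) & 0x7FFFFFFF, zlib.crc32(stream.encode())])


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def _loaded_normal(rng: np.random.Generator, factor: np.ndarray, loading: float) -> np.ndarray:
    """Standard normal with correlation ``loading`` to ``factor``."""
    noise = rng.standard_normal(factor.shape[0])
    return loading * factor + np.sqrt(max(0.0, 1.0 - loading**2)) * noise


def generate_cohort(config: SyntheticConfig) -> pd.DataFrame:
    """Draw one synthetic cohort under the given study conditions.

    Deterministic given ``config.seed``.  Returns a DataFrame with the
    columns in :data:`COHORT_COLUMNS`; the two ``latent_*`` columns carry
    simulation ground truth (diet-quality factor and depression liability)
    and are ignored by every scoring/analysis routine.
    """
    config.validate()
    n = config.n_participants
    if n == 0:
        return pd.DataFrame(columns=list(COHORT_COLUMNS))

    factor = _rng(config.seed, "diet_factor").standard_normal(n)

    df = pd.DataFrame({"participant_id": np.arange(1, n + 1)})
    df["age"] = _rng(config.seed, "age").choice(
        list(config.age_levels), size=n, p=list(config.age_weights)
    )
    lo, hi = config.exam_year_range
    df["exam_year"] = _rng(config.seed, "exam_year").integers(lo, hi + 1, size=n)
    df["energy_kj"] = np.exp(
        config.energy_mu
        + config.energy_sigma * _rng(config.seed, "energy").standard_normal(n)
    )
    df["ltpa_kj"] = np.exp(
        config.ltpa_mu
        + config.ltpa_sigma
        * _loaded_normal(_rng(config.seed, "ltpa"), factor, config.ltpa_loading)
    )
    ses_z = _loaded_normal(_rng(config.seed, "ses"), factor, config.ses_loading)
    df["ses"] = config.ses_mean + config.ses_sd * ses_z

    # ordered smoking categories through a gaussian copula on the diet factor
    smoke_latent = _loaded_normal(_rng(config.seed, "smoking"), factor, config.smoking_loading)
    from scipy.stats import norm

    p_never, p_prev, _ = config.smoking_probs
    cuts = norm.ppf([p_never, p_never + p_prev])
    df["smoking"] = np.select(
        [smoke_latent < cuts[0], smoke_latent < cuts[1]],
        [_SMOKING_LEVELS[0], _SMOKING_LEVELS[1]],
        default=_SMOKING_LEVELS[2],
    )
    marital_latent = _loaded_normal(_rng(config.seed, "marital"), factor, config.marital_loading)
    df["marital"] = np.where(
        marital_latent > norm.ppf(1.0 - config.marital_other_prob),
        _MARITAL_LEVELS[1],
        _MARITAL_LEVELS[0],
    )
    df["bmi"] = config.bmi_mean + config.bmi_sd * _loaded_normal(
        _rng(config.seed, "bmi"), factor, config.bmi_loading
    )
    df["cvd_history"] = (
        _rng(config.seed, "cvd").random(n) < config.cvd_history_prob
    ).astype(int)

    # component intakes: log-normal (logit-normal for total fat E%)
    for name in INTAKE_COLUMNS:
        spec = config.intake_distributions[name]
        z = _loaded_normal(_rng(config.seed, f"intake:{name}"), factor, spec.loading)
        if name == "total_fat":
            df[name] = 100.0 * _sigmoid(spec.mu + spec.sigma * z)
        else:
            df[name] = np.exp(spec.mu + spec.sigma * z)

    # depression liability: diet factor + confounders + noise, centred so the
    # confounder terms do not shift the marginal HPL distribution
    current = (df["smoking"] == "current").to_numpy()
    previous = (df["smoking"] == "previous").to_numpy()
    other = (df["marital"] == "other").to_numpy()
    conf = (
        config.smoking_current_effect * current
        + config.smoking_previous_effect * previous
        + config.marital_other_effect * other
        + config.ses_z_effect * ses_z
    )
    conf_mean = (
        config.smoking_current_effect * config.smoking_probs[2]
        + config.smoking_previous_effect * config.smoking_probs[1]
        + config.marital_other_effect * config.marital_other_prob
    )
    liability = (
        config.effect_size * factor
        + (conf - conf_mean)
        + config.liability_noise_sd * _rng(config.seed, "liability").standard_normal(n)
    )

    item_logits = (
        config.hpl_base_intercept
        + np.asarray(config.item_offsets)[None, :]
        + liability[:, None]
    )
    items = (
        _rng(config.seed, "hpl_items").random((n, N_ITEMS)) < _sigmoid(item_logits)
    ).astype(int)
    for j, col in enumerate(HPL_ITEM_COLUMNS):
        df[col] = items[:, j]

    # mental-illness history correlated with the (standardised) liability
    lia_sd = float(np.sqrt(config.effect_size**2 + config.liability_noise_sd**2)) or 1.0
    mental_latent = _loaded_normal(
        _rng(config.seed, "mental"), liability / lia_sd, config.mental_history_liability_corr
    )
    df["mental_illness_history"] = (
        mental_latent > norm.ppf(1.0 - config.mental_history_prob)
    ).astype(int)

    df["latent_diet"] = factor
    df["latent_liability"] = liability
    return df.loc[:, list(COHORT_COLUMNS)]


def inject_missingness(cohort: pd.DataFrame, config: SyntheticConfig) -> pd.DataFrame:
    """Blank cells per the configured missingness rates (new frame returned).

    Per-variable rates act independently cell by cell; the ``"block"`` rate
    marks a record's diet components and HPL items missing jointly,
    emulating participants excluded for missing exposure/outcome data.
    """
    for key, rate in config.missingness_rates.items():
        if not 0.0 <= rate <= 1.0:
            raise ValueError(f"missingness_rates[{key!r}] must be in [0, 1], got {rate}")
    out = cohort.copy()
    n = len(out)
    if n == 0:
        return out
    for key, rate in config.missingness_rates.items():
        if key == "block":
            continue
        if key not in out.columns:
            raise ValueError(f"missingness rate given for unknown column {key!r}")
        mask = _rng(config.seed, f"missing:{key}").random(n) < rate
        out.loc[mask, key] = np.nan
    block_rate = config.missingness_rates.get("block", 0.0)
    if block_rate > 0:
        mask = _rng(config.seed, "missing:block").random(n) < block_rate
        block_cols = list(INTAKE_COLUMNS) + list(HPL_ITEM_COLUMNS)
        out.loc[mask, block_cols] = np.nan
    return out


def write_cohort_csv(cohort: pd.DataFrame, path) -> None:
    """Write a cohort table to CSV (missing values as empty fields)."""
    cohort.to_csv(path, index=False)


def read_cohort_csv(path) -> pd.DataFrame:
    """Read a cohort table written by :func:`write_cohort_csv`."""
    return pd.read_csv(path)
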