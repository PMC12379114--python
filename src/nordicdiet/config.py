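"""Configuration for the synthetic-cohort simulator.

The simulator emulates the baseline examination of a population cohort of
middle-aged eastern-Finnish men (ages 42/48/54/60, examinations 1984-1989):
4-day mean intakes of the nine diet-score components, the covariates used
for adjustment, and the 18 HPL depression items.  A single latent
diet-quality factor drives correlated component intakes; a depression
liability combines a configurable (negative, for realistic runs) loading on
that factor with confounder contributions and noise, and drives the HPL
items through a logistic item model.

The numeric defaults below were fitted once, by simulation, so that a
default cohort reproduces the marginal statistics the analysis is
calibrated to (mean HNDS 12.8 / SD 4.0, mean HPL 1.9 / SD 2.1, depressive-
symptom prevalence 10.9%, and an extreme-quartile HPL difference around a
third of a point); they are frozen here and should be treated as the
reference study conditions, not tuning knobs.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import yaml

__all__ = ["IntakeSpec", "SyntheticConfig"]

_EPS = 1e-9


@dataclass(frozen=True)
class IntakeSpec:
    """Log-normal spec for one intake component.

    ``mu``/``sigma`` are on the log scale (for ``total_fat`` they are on the
    logit scale of the energy fraction, which keeps E% inside [0, 100]);
    ``loading`` is the correlation of the log (logit) intake with the latent
    diet-quality factor — positive for components a healthy Nordic diet
    emphasises, negative for the ones it limits.
    """

    mu: float
    sigma: float
    loading: float = 0.0

    def validate(self, name: str) -> None:
        if not math.isfinite(self.mu):
            raise ValueError(f"intake_distributions[{name!r}].mu must be finite")
        if not (self.sigma > 0):
            raise ValueError(f"intake_distributions[{name!r}].sigma must be > 0")
        if not -1.0 <= self.loading <= 1.0:
            raise ValueError(f"intake_distributions[{name!r}].loading must be in [-1, 1]")


# Loading magnitude for the main food-group components, fitted so the HNDS
# spread matches the reference SD of 4.0 points.
_L = 0.30
# Fat-quality inputs share a slightly weaker loading so the derived
# PUFA/(SFA+TFA) ratio does not dominate the score correlation structure.
_LF = 0.225

_DEFAULT_INTAKES: dict[str, IntakeSpec] = {
    # medians (g/d) chosen as realistic 4-day food-diary means for Finnish
    # men of the mid-1980s; right-skewed log-normal shapes throughout
    "fruits_berries": IntakeSpec(mu=math.log(120.0), sigma=0.75, loading=_L),
    "vegetables": IntakeSpec(mu=math.log(110.0), sigma=0.55, loading=_L),
    "cereals": IntakeSpec(mu=math.log(220.0), sigma=0.35, loading=_L),
    "lowfat_milk": IntakeSpec(mu=math.log(300.0), sigma=0.90, loading=_L),
    "fish": IntakeSpec(mu=math.log(35.0), sigma=0.80, loading=_L),
    "meat_products": IntakeSpec(mu=math.log(150.0), sigma=0.45, loading=-_L),
    # total fat as a logit-normal energy fraction, median 38 E%
    "total_fat": IntakeSpec(mu=math.log(0.38 / 0.62), sigma=0.22, loading=-_L),
    "pufa": IntakeSpec(mu=math.log(12.0), sigma=0.35, loading=_LF),
    "sfa": IntakeSpec(mu=math.log(40.0), sigma=0.30, loading=-_LF),
    "tfa": IntakeSpec(mu=math.log(2.0), sigma=0.40, loading=-_LF),
    # ethanol: sigma 1.1 and the location set so P(ethanol < 20 g/d) = 0.80,
    # the abstinence-leaning drinking profile that puts the alcohol point's
    # cohort mean at 0.80 (and hence the HNDS mean at 12.8)
    "ethanol": IntakeSpec(
        mu=math.log(20.0) - 0.8416212335729143 * 1.1, sigma=1.1, loading=-0.25
    ),
}

# Fixed per-item logit offsets (sum ~0): the 18 HPL items span common,
# middling and rare symptom endorsements rather than one shared prevalence.
_DEFAULT_ITEM_OFFSETS = (
    1.00, 0.85, 0.70, 0.55, 0.40, 0.28, 0.16, 0.05, -0.05,
    -0.16, -0.28, -0.40, -0.55, -0.70, -0.85, -1.00, -1.15, 1.15,
)


def _as_tuple(x) -> tuple:
    return tuple(x) if not isinstance(x, tuple) else x


@dataclass
class SyntheticConfig:
    """Study conditions for one synthetic cohort draw."""

    n_participants: int = 2603
    seed: int = 0

    # recruitment structure
    age_levels: tuple[int, ...] = (42, 48, 54, 60)
    age_weights: tuple[float, ...] = (0.10, 0.26, 0.36, 0.28)
    exam_year_range: tuple[int, int] = (1984, 1989)

    # dietary intakes
    intake_distributions: dict[str, IntakeSpec] = field(
        default_factory=lambda: dict(_DEFAULT_INTAKES)
    )
    # total daily energy, kJ/d (log-normal)
    energy_mu: float = math.log(9600.0)
    energy_sigma: float = 0.22

    # covariates
    ltpa_mu: float = math.log(450.0)     # leisure-time physical activity, kJ/d
    ltpa_sigma: float = 0.90
    ltpa_loading: float = 0.20
    ses_mean: float = 8.5                # adulthood SES score; higher = lower status
    ses_sd: float = 4.2
    ses_loading: float = -0.20
    smoking_probs: tuple[float, float, float] = (0.350, 0.333, 0.317)  # never/previous/current
    smoking_loading: float = -0.25       # gaussian-copula link to diet factor
    marital_other_prob: float = 0.131    # 1 - P(married / living as a couple)
    marital_loading: float = -0.20
    bmi_mean: float = 26.8
    bmi_sd: float = 3.6
    bmi_loading: float = -0.10
    cvd_history_prob: float = 0.36
    mental_history_prob: float = 0.055
    mental_history_liability_corr: float = 0.35

    # depression model
    effect_size: float = -0.16           # loading of diet factor on liability (<= 0 realistic)
    liability_noise_sd: float = 1.10     # residual SD of the liability
    hpl_base_intercept: float = -2.75    # shared logit intercept of the 18 items
    item_offsets: tuple[float, ...] = _DEFAULT_ITEM_OFFSETS
    # confounder contributions to the liability (logit scale)
    smoking_current_effect: float = 0.25
    smoking_previous_effect: float = 0.05
    marital_other_effect: float = 0.30
    ses_z_effect: float = 0.10

    # missingness (used by inject_missingness, not by generate_cohort)
    missingness_rates: dict[str, float] = field(
        default_factory=lambda: {
            "ltpa_kj": 8 / 2603,      # LTPA missing for n=8 in the reference cohort
            "marital": 2 / 2603,      # marital status missing for n=2
            "block": 79 / 2682,       # diet/HPL block missing -> excluded (n=79 of 2682)
        }
    )

    def __post_init__(self) -> None:
        self.age_levels = _as_tuple(self.age_levels)
        self.age_weights = _as_tuple(self.age_weights)
        self.exam_year_range = _as_tuple(self.exam_year_range)
        self.smoking_probs = _as_tuple(self.smoking_probs)
        self.item_offsets = _as_tuple(self.item_offsets)
        self.intake_distributions = {
            k: (v if isinstance(v, IntakeSpec) else IntakeSpec(**v))
            for k, v in self.intake_distributions.items()
        }
        self.validate()

    def validate(self) -> None:
        if self.n_participants < 0:
            raise ValueError("n_participants must be >= 0")
        if not set(self.age_levels) <= {42, 48, 54, 60}:
            raise ValueError("age_levels must be a subset of {42, 48, 54, 60}")
        if len(self.age_weights) != len(self.age_levels):
            raise ValueError("age_weights must match age_levels in length")
        if any(w < 0 for w in self.age_weights) or abs(sum(self.age_weights) - 1.0) > _EPS:
            raise ValueError("age_weights must be non-negative and sum to 1")
        lo, hi = self.exam_year_range
        if lo > hi:
            raise ValueError("exam_year_range must be (first, last) with first <= last")
        for name, spec in self.intake_distributions.items():
            spec.validate(name)
        for fname in ("energy_sigma", "ltpa_sigma", "ses_sd", "bmi_sd", "liability_noise_sd"):
            if not (getattr(self, fname) > 0):
                raise ValueError(f"{fname} must be > 0")
        if any(p < 0 for p in self.smoking_probs) or abs(sum(self.smoking_probs) - 1.0) > _EPS:
            raise ValueError("smoking_probs must be non-negative and sum to 1")
        for fname in ("marital_other_prob", "cvd_history_prob", "mental_history_prob"):
            p = getattr(self, fname)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{fname} must be in [0, 1]")
        for fname in ("ltpa_loading", "ses_loading", "smoking_loading", "marital_loading",
                      "bmi_loading", "mental_history_liability_corr"):
            if not -1.0 <= getattr(self, fname) <= 1.0:
                raise ValueError(f"{fname} must be in [-1, 1]")
        if len(self.item_offsets) != 18:
            raise ValueError("item_offsets must have exactly 18 entries")
        for key, rate in self.missingness_rates.items():
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"missingness_rates[{key!r}] must be in [0, 1]")

    # ------------------------------------------------------------------ I/O
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["intake_distributions"] = {
            k: dataclasses.asdict(v) for k, v in self.intake_distributions.items()
        }
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "SyntheticConfig":
        return cls(**dict(d))

    def to_yaml(self, path) -> None:
        def _plain(obj):
            if isinstance(obj, dict):
                return {k: _plain(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [_plain(v) for v in obj]
            if isinstance(obj, (np.floating, np.integer)):
                return obj.item()
            return obj

        with open(path, "w") as fh:
            yaml.safe_dump(_plain(self.to_dict()), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SyntheticConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))
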