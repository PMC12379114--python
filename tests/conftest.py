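import numpy as np
import pandas as pd
import pytest

import nordicdiet as nd


@pytest.fixture(scope="session")
def default_cohort() -> pd.DataFrame:
    """One default-calibration cohort draw at the reference size."""
    return nd.generate_cohort(nd.SyntheticConfig(n_participants=2603, seed=0))


@pytest.fixture(scope="session")
def scored_cohort(default_cohort) -> pd.DataFrame:
    return nd.score_cohort(default_cohort)


def make_diet_fixture() -> pd.DataFrame:
    """8-participant hand-scored diet fixture (distinct values per component)."""
    return pd.DataFrame({
        "fruits_berries": [10, 80, 30, 50, 70, 20, 60, 40],
        "vegetables": [15, 75, 35, 55, 65, 25, 45, 85],
        "cereals": [100, 800, 300, 500, 700, 200, 600, 400],
        "lowfat_milk": [50, 700, 200, 400, 600, 100, 500, 300],
        "fish": [5, 80, 20, 40, 60, 10, 50, 30],
        "meat_products": [210, 30, 150, 90, 60, 240, 120, 180],
        "total_fat": [44, 30, 38, 34, 32, 46, 36, 40],
        "pufa": [6, 16, 8, 12, 14, 4, 10, 9],
        "sfa": [40, 28, 36, 30, 29, 42, 33, 35],
        "tfa": [2, 2, 2, 2, 1, 3, 2, 1],
        "ethanol": [25, 5, 30, 10, 2, 40, 15, 19],
    }, dtype=float)


#: hand-computed totals for make_diet_fixture (brute-force quartile rule)
DIET_FIXTURE_TOTALS = [0, 25, 8, 17, 24, 0, 16, 11]


@pytest.fixture()
def diet_fixture() -> pd.DataFrame:
    return make_diet_fixture()


def make_quade_fixture():
    """16-observation, 4-group, one-covariate instance with a frozen oracle F.

    The golden value was computed by an independent brute-force script
    (explicit mid-ranks by sorting, 2x2 normal equations, ANOVA by loops).
    """
    y = [3.1, 5.2, 4.8, 6.0, 2.2, 4.1, 3.3, 5.5,
         1.9, 2.8, 3.0, 4.4, 1.0, 2.0, 2.5, 3.8]
    x = [10., 14., 12., 18., 11., 15., 9., 17.,
         8., 13., 10., 16., 7., 12., 9., 15.]
    g = np.repeat([1, 2, 3, 4], 4)
    df = pd.DataFrame({"hpl_total": y, "cov": x})
    return df, g


QUADE_FIXTURE_F = 3.32806971458136
QUADE_FIXTURE_P = 0.05647640534399488
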