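"""Synthetic cohort generator: reproducibility, calibration, missingness."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import nordicdiet as nd
from nordicdiet.cohort import COHORT_COLUMNS
from nordicdiet.config import SyntheticConfig


class TestGenerateCohort:
    def test_empty_cohort(self):
        cohort = nd.generate_cohort(SyntheticConfig(n_participants=0, seed=1))
        assert cohort.empty and list(cohort.columns) == list(COHORT_COLUMNS)

    def test_same_seed_bit_identical(self):
        a = nd.generate_cohort(SyntheticConfig(n_participants=500, seed=11))
        b = nd.generate_cohort(SyntheticConfig(n_participants=500, seed=11))
        pd.testing.assert_frame_equal(a, b)

    def test_different_seeds_differ(self):
        a = nd.generate_cohort(SyntheticConfig(n_participants=500, seed=11))
        b = nd.generate_cohort(SyntheticConfig(n_participants=500, seed=12))
        assert not a["fruits_berries"].equals(b["fruits_berries"])

    def test_value_ranges(self, default_cohort):
        c = default_cohort
        assert set(c["age"]) <= {42, 48, 54, 60}
        assert c["exam_year"].between(1984, 1989).all()
        assert (c[list(nd.INTAKE_COLUMNS)] >= 0).all().all()
        assert c["total_fat"].between(0, 100).all()
        assert (c["energy_kj"] > 0).all()
        assert set(c["smoking"]) <= {"never", "previous", "current"}
        assert set(c["marital"]) <= {"couple", "other"}

    def test_invalid_config_names_field(self):
        with pytest.raises(ValueError, match="age_weights"):
            SyntheticConfig(age_weights=(0.5, 0.5, 0.2, 0.1))
        with pytest.raises(ValueError, match="smoking_probs"):
            SyntheticConfig(smoking_probs=(0.9, 0.2, 0.1))
        with pytest.raises(ValueError, match="n_participants"):
            SyntheticConfig(n_participants=-1)
        with pytest.raises(ValueError, match="sigma"):
            SyntheticConfig(intake_distributions={"fish": {"mu": 1.0, "sigma": -1.0}})

    def test_covariate_marginals_match_config_within_3_se(self):
        cfg = SyntheticConfig(n_participants=5000, seed=5)
        c = nd.generate_cohort(cfg)
        n = len(c)
        assert c["ses"].mean() == pytest.approx(cfg.ses_mean, abs=3 * cfg.ses_sd / np.sqrt(n))
        assert c["bmi"].mean() == pytest.approx(cfg.bmi_mean, abs=3 * cfg.bmi_sd / np.sqrt(n))
        for level, p in zip(("never", "previous", "current"), cfg.smoking_probs):
            se = np.sqrt(p * (1 - p) / n)
            assert (c["smoking"] == level).mean() == pytest.approx(p, abs=3 * se)
        p = cfg.marital_other_prob
        assert (c["marital"] == "other").mean() == pytest.approx(
            p, abs=3 * np.sqrt(p * (1 - p) / n)
        )

    def test_zero_effect_size_decouples_diet_and_symptoms(self):
        cfg = SyntheticConfig(
            n_participants=5000, seed=9, effect_size=0.0,
            # switch off the confounder paths so diet and liability share no cause
            ltpa_loading=0.0, ses_loading=0.0, smoking_loading=0.0, marital_loading=0.0,
        )
        c = nd.generate_cohort(cfg)
        s = nd.score_hpl(c)
        r, p = stats.pearsonr(c["latent_diet"], s["hpl_total"])
        # oracle: under independence r ~ N(0, 1/sqrt(n)); stay within 3 SE
        assert abs(r) < 3 / np.sqrt(len(c))
        assert p > 1e-3

    def test_negative_effect_gives_nonincreasing_hpl_across_quartiles(self):
        s = nd.score_cohort(nd.generate_cohort(SyntheticConfig(n_participants=20_000, seed=4)))
        means = s.groupby("hnds_quartile")["hpl_total"].mean()
        # monotone in expectation; allow MC slack of 0.05 points per step
        assert all(np.diff(means.to_numpy()) < 0.05)
        assert means.iloc[0] > means.iloc[-1]

    def test_adding_a_variable_does_not_perturb_other_streams(self):
        # counter-based substreams: changing the HPL item model must leave
        # the dietary intake draws untouched
        base = nd.generate_cohort(SyntheticConfig(n_participants=200, seed=7))
        other = nd.generate_cohort(
            SyntheticConfig(n_participants=200, seed=7, hpl_base_intercept=-1.0)
        )
        pd.testing.assert_frame_equal(
            base[list(nd.INTAKE_COLUMNS)], other[list(nd.INTAKE_COLUMNS)]
        )
        assert not base[list(nd.HPL_ITEM_COLUMNS)].equals(other[list(nd.HPL_ITEM_COLUMNS)])


class TestInjectMissingness:
    def test_zero_rates_identity(self, default_cohort):
        cfg = SyntheticConfig(missingness_rates={"ltpa_kj": 0.0, "marital": 0.0, "block": 0.0})
        pd.testing.assert_frame_equal(
            nd.inject_missingness(default_cohort, cfg), default_cohort
        )

    def test_rate_one_saturates(self, default_cohort):
        cfg = SyntheticConfig(missingness_rates={"ltpa_kj": 1.0})
        out = nd.inject_missingness(default_cohort, cfg)
        assert out["ltpa_kj"].isna().all()

    def test_block_missing_count_matches_reference_exclusions(self):
        # 79 of 2682 expected; binomial MC check at a fixed seed
        cfg = SyntheticConfig(n_participants=2682, seed=13,
                              missingness_rates={"block": 79 / 2682})
        out = nd.inject_missingness(nd.generate_cohort(cfg), cfg)
        _, n_excluded = nd.apply_exclusions(out)
        se = np.sqrt(2682 * (79 / 2682) * (1 - 79 / 2682))
        assert abs(n_excluded - 79) <= 3 * se

    def test_block_missingness_blanks_diet_and_hpl_jointly(self):
        cfg = SyntheticConfig(n_participants=300, seed=2, missingness_rates={"block": 0.2})
        out = nd.inject_missingness(nd.generate_cohort(cfg), cfg)
        diet_na = out[list(nd.INTAKE_COLUMNS)].isna().all(axis=1)
        hpl_na = out[list(nd.HPL_ITEM_COLUMNS)].isna().all(axis=1)
        assert diet_na.any()
        assert (diet_na == hpl_na).all()

    def test_invalid_rate_rejected(self, default_cohort):
        cfg = SyntheticConfig()
        cfg.missingness_rates["ltpa_kj"] = 1.5
        with pytest.raises(ValueError, match="ltpa_kj"):
            nd.inject_missingness(default_cohort, cfg)


class TestConfigIO:
    def test_yaml_round_trip(self, tmp_path):
        cfg = SyntheticConfig(n_participants=123, seed=42, effect_size=-0.1)
        path = tmp_path / "cfg.yaml"
        cfg.to_yaml(path)
        loaded = SyntheticConfig.from_yaml(path)
        assert loaded.n_participants == 123 and loaded.seed == 42
        assert loaded.effect_size == pytest.approx(-0.1)
        pd.testing.assert_frame_equal(
            nd.generate_cohort(loaded), nd.generate_cohort(cfg)
        )

    def test_csv_round_trip_preserves_missing_as_empty(self, tmp_path):
        cfg = SyntheticConfig(n_participants=50, seed=3, missingness_rates={"ltpa_kj": 0.3})
        cohort = nd.inject_missingness(nd.generate_cohort(cfg), cfg)
        path = tmp_path / "cohort.csv"
        nd.write_cohort_csv(cohort, path)
        assert ",," in path.read_text()  # empty field for missing
        loaded = nd.read_cohort_csv(path)
        assert loaded["ltpa_kj"].isna().sum() == cohort["ltpa_kj"].isna().sum()
        np.testing.assert_allclose(loaded["fish"], cohort["fish"])
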