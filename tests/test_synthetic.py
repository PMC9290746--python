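"""2PL generator: item bank construction, simulation, calibration, defect injection."""

import numpy as np
import pandas as pd
import pytest

import ravenshort as rs
from ravenshort.errors import ConfigurationError, ConvergenceError
from ravenshort.items import ALL_ITEMS
from ravenshort.simulate import response_probabilities

from conftest import make_matrix


class TestItemBank:
    def test_set_means_strictly_increase(self, default_bank):
        means = default_bank.set_mean_difficulties().to_numpy()
        assert np.all(np.diff(means) > 0)

    def test_zero_jitter_gives_equally_spaced_grid(self):
        bank = rs.build_item_bank(difficulty_range=(-2.5, 2.5), jitter=0.0)
        b = bank.b.to_numpy()
        assert np.allclose(np.diff(b), 5.0 / 59.0)
        assert b[0] == -2.5 and b[-1] == 2.5

    def test_seeds_change_discriminations_not_difficulty_order(self):
        b1 = rs.build_item_bank(seed=1)
        b2 = rs.build_item_bank(seed=2)
        assert not np.allclose(b1.a.to_numpy(), b2.a.to_numpy())
        assert np.array_equal(np.argsort(b1.b.to_numpy()), np.argsort(b2.b.to_numpy()))

    def test_jittered_bank_keeps_invariants(self):
        bank = rs.build_item_bank(jitter=0.2, seed=4)
        # constructor enforces the invariants; spot-check within-set monotonicity
        for s in "ABCDE":
            bs = bank.b[[l for l in ALL_ITEMS if l[0] == s]].to_numpy()
            assert np.all(np.diff(bs) >= 0)

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"difficulty_range": (2.0, -2.0)},
            {"discrimination_median": 0.0},
            {"discrimination_median": -1.0},
            {"discrimination_log_sd": -0.1},
            {"jitter": -0.5},
        ],
    )
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(ConfigurationError):
            rs.build_item_bank(**kwargs)

    def test_nonpositive_discrimination_rejected_by_bank(self, default_bank):
        a = default_bank.a.copy()
        a.iloc[0] = 0.0
        with pytest.raises(ConfigurationError):
            rs.ItemBank(a=a, b=default_bank.b)


class TestSimulation:
    def test_determinism_bit_identical(self, default_bank):
        cfg = rs.GeneratorConfig(n_persons=50, item_bank=default_bank, seed=77)
        m1 = rs.simulate_responses(cfg)
        m2 = rs.simulate_responses(cfg)
        assert m1.equals(m2)

    def test_different_seeds_differ(self, default_bank):
        cfg = rs.GeneratorConfig(n_persons=50, item_bank=default_bank, seed=77)
        m2 = rs.simulate_responses(cfg.replace(seed=78))
        assert not rs.simulate_responses(cfg).responses.equals(m2.responses)

    def test_logistic_saturation_theta_far_above_difficulty(self, default_bank):
        # θ = b + 10 with a = 1: P(correct) > 0.999 for every item
        a = pd.Series(1.0, index=ALL_ITEMS)
        bank = rs.ItemBank(a=a, b=default_bank.b)
        theta = default_bank.b.max() + 10.0
        p = response_probabilities(bank, np.array([theta]))
        assert p.min() > 0.999

    def test_near_zero_discrimination_is_a_coin_flip(self):
        # a → 0 flattens the curve; empirical rate within 3 binomial SE of 0.5
        a = pd.Series(1e-9, index=ALL_ITEMS[:1] * 1)
        bank_a = pd.Series(np.r_[1e-9, np.ones(59)], index=ALL_ITEMS)
        bank = rs.ItemBank(a=bank_a, b=rs.build_item_bank().b)
        cfg = rs.GeneratorConfig(n_persons=10_000, item_bank=bank, seed=5)
        m = rs.simulate_responses(cfg)
        phat = m.responses["A1"].mean()
        assert abs(phat - 0.5) < 3 * np.sqrt(0.25 / 10_000)

    def test_empirical_rates_match_2pl_probabilities(self, default_bank):
        # fixed θ for everyone: per-item empirical rate within 3 SE of closed form
        cfg = rs.GeneratorConfig(
            n_persons=10_000, item_bank=default_bank, theta_mean=0.4, theta_sd=1e-12, seed=6
        )
        # theta_sd must be positive; a tiny value pins θ at theta_mean
        m = rs.simulate_responses(cfg)
        p = response_probabilities(default_bank, np.array([0.4]))[0]
        phat = m.responses.to_numpy().mean(axis=0)
        se = np.sqrt(p * (1 - p) / 10_000)
        assert np.all(np.abs(phat - p) <= 3 * se + 1e-9)

    def test_guessing_floor(self, default_bank):
        cfg = rs.GeneratorConfig(
            n_persons=5000, item_bank=default_bank, theta_mean=-8.0, theta_sd=0.1,
            guessing=0.25, seed=8,
        )
        m = rs.simulate_responses(cfg)
        # far below every difficulty, the correct rate sits at the guessing floor
        assert abs(m.responses.to_numpy().mean() - 0.25) < 0.02

    def test_sources_and_ages(self, default_bank):
        cfg = rs.GeneratorConfig(
            n_persons=30,
            item_bank=default_bank,
            sources={"x": 10, "y": 20},
            age_models={"x": rs.AgeModel(13.0, 0.4, 12.5, 14.5)},
            seed=9,
        )
        m = rs.simulate_responses(cfg)
        assert (m.sources == "x").sum() == 10 and (m.sources == "y").sum() == 20
        x_ages = m.ages[m.sources == "x"]
        assert x_ages.between(12.5, 14.5).all()
        assert m.ages[m.sources == "y"].isna().all()

    def test_source_sizes_must_sum(self, default_bank):
        with pytest.raises(ConfigurationError):
            rs.GeneratorConfig(
                n_persons=10, item_bank=default_bank, sources={"x": 3, "y": 3}
            )


class TestAnalyticMoments:
    def test_agree_with_monte_carlo_at_large_n(self, default_bank):
        mu, sd = 0.3, 0.9
        am, asd = rs.analytic_score_moments(default_bank, mu, sd)
        cfg = rs.GeneratorConfig(
            n_persons=100_000, item_bank=default_bank, theta_mean=mu, theta_sd=sd, seed=13
        )
        scores = rs.sum_score(rs.simulate_responses(cfg)).to_numpy().astype(float)
        se_mean = asd / np.sqrt(100_000)
        se_sd = asd / np.sqrt(2 * 100_000)
        assert abs(scores.mean() - am) < 3 * se_mean
        assert abs(scores.std(ddof=1) - asd) < 3 * se_sd


class TestCalibration:
    def test_fixed_point(self, default_bank):
        cfg = rs.GeneratorConfig(
            n_persons=100, item_bank=default_bank, theta_mean=0.2, theta_sd=0.8
        )
        m, s = rs.analytic_score_moments(default_bank, 0.2, 0.8)
        cal = rs.calibrate_to_marginals(cfg, m, s, tol=1e-4)
        assert abs(cal.theta_mean - 0.2) < 1e-4
        assert abs(cal.theta_sd - 0.8) < 1e-4

    @pytest.mark.parametrize("target", [(37.17, 6.91), (43.83, 6.97)])
    def test_reaches_published_marginals_analytically(self, default_bank, target):
        mean, sd = target
        cfg = rs.GeneratorConfig(n_persons=100, item_bank=default_bank)
        cal = rs.calibrate_to_marginals(cfg, mean, sd)
        m, s = rs.analytic_score_moments(default_bank, cal.theta_mean, cal.theta_sd)
        assert abs(m - mean) < 1e-4 and abs(s - sd) < 1e-4
        # the bank itself is untouched
        assert cal.item_bank is cfg.item_bank

    def test_out_of_range_targets_rejected(self, default_bank):
        cfg = rs.GeneratorConfig(n_persons=10, item_bank=default_bank)
        with pytest.raises(ConfigurationError):
            rs.calibrate_to_marginals(cfg, 61.0, 5.0)
        with pytest.raises(ConfigurationError):
            rs.calibrate_to_marginals(cfg, 30.0, -1.0)

    def test_unreachable_targets_raise_with_best_achieved(self, default_bank):
        cfg = rs.GeneratorConfig(n_persons=10, item_bank=default_bank)
        # mean 0.5 bounds the total-score SD far below 20
        with pytest.raises(ConvergenceError) as excinfo:
            rs.calibrate_to_marginals(cfg, 0.5, 20.0)
        assert "mean" in str(excinfo.value)
        assert excinfo.value.best is not None


class TestDefectInjection:
    def test_zero_spec_is_identity(self, default_bank):
        m = rs.simulate_responses(rs.GeneratorConfig(n_persons=20, item_bank=default_bank, seed=1))
        out = rs.inject_defects(m, rs.DefectSpec(), seed=2)
        assert out.equals(m)

    def test_counts_roundtrip_through_cleaning(self, default_bank):
        cfg = rs.GeneratorConfig(
            n_persons=80,
            item_bank=default_bank,
            sources={"s": 80},
            age_models={"s": rs.AgeModel(14.0, 0.5, 13.0, 16.0)},
            seed=21,
        )
        m = rs.simulate_responses(cfg)
        spec = rs.DefectSpec(n_missing_rows=7, n_duplicate_rows=3, n_underage_rows=5)
        dirty = rs.inject_defects(m, spec, seed=22)
        assert dirty.n_persons == 83  # duplicates are appended
        cleaned, report = rs.clean_responses(dirty, min_age=12.5)
        assert report.n_missing_removed == spec.n_missing_rows
        assert report.n_duplicates_removed == spec.n_duplicate_rows
        assert report.n_underage_removed == spec.n_underage_rows
        assert cleaned.n_persons == 80 - spec.n_missing_rows - spec.n_underage_rows

    def test_infeasible_spec_rejected(self, default_bank):
        m = rs.simulate_responses(rs.GeneratorConfig(n_persons=5, item_bank=default_bank, seed=1))
        with pytest.raises(ConfigurationError):
            rs.inject_defects(m, rs.DefectSpec(3, 2, 1), seed=0)

    def test_negative_counts_rejected(self):
        with pytest.raises(ConfigurationError):
            rs.DefectSpec(n_missing_rows=-1)
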