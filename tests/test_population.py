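import numpy as np
import pytest

from slopesem import (
    PopulationSpec,
    calibrate_effect,
    implied_icc,
    implied_slope_reliability,
    make_unbalanced,
    simulate,
)

SLOPE_COV = np.array([[0.1, 0.02], [0.02, 0.1]])


class TestCalibration:
    @pytest.mark.parametrize(
        "hypothesis, r2, expected_idx, expected",
        [
            ("ushape", 0.25, 3, -4.0824829),
            ("ushape", 0.09, 3, -2.2237479),
            ("moderation", 0.25, 4, -5.6613852),
            ("moderation", 0.09, 4, -3.0837836),
            ("congruence", 0.25, 3, -2.5515518),
        ],
    )
    def test_analytic_values(self, hypothesis, r2, expected_idx, expected):
        b = calibrate_effect(hypothesis, r2, SLOPE_COV, 1.0)
        assert b[expected_idx] == pytest.approx(expected, abs=1e-6)

    def test_congruence_constraints(self):
        b = calibrate_effect("congruence", 0.25, SLOPE_COV, 1.0)
        assert b[1] == b[2] == 0
        assert b[5] == b[3] < 0
        assert b[4] == pytest.approx(-2 * b[3])

    def test_zero_effect_gives_zero_coefficients(self):
        for hyp in ("ushape", "moderation", "congruence"):
            assert np.all(calibrate_effect(hyp, 0.0, SLOPE_COV, 1.0) == 0)

    def test_paper_replication_mode_uses_printed_values(self):
        b = calibrate_effect("congruence", 0.25, SLOPE_COV, 1.0, paper_values=True)
        assert b[3] == -2.5

    def test_calibration_verified_by_monte_carlo_r2(self):
        """The calibrated coefficient explains the target share of variance."""
        rng = np.random.default_rng(0)
        draws = rng.multivariate_normal([0, 0], SLOPE_COV, size=2_000_000)
        for hyp in ("ushape", "moderation", "congruence"):
            b = calibrate_effect(hyp, 0.25, SLOPE_COV, 1.0)
            by, bv = draws[:, 0], draws[:, 1]
            effect = (
                b[1] * by + b[2] * bv + b[3] * by**2 + b[4] * by * bv + b[5] * bv**2
            )
            r2 = effect.var() / (effect.var() + 1.0)
            assert r2 == pytest.approx(0.25, abs=0.005)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            calibrate_effect("banana", 0.25, SLOPE_COV, 1.0)
        with pytest.raises(ValueError):
            calibrate_effect("ushape", 1.0, SLOPE_COV, 1.0)


class TestImpliedQuantities:
    def test_slope_reliability_matches_study_design(self):
        assert implied_slope_reliability(0.1, 1.0, 1.0, 40) == pytest.approx(0.7959, abs=5e-4)
        assert implied_slope_reliability(0.1, 1.0, 1.0, 15) == pytest.approx(0.5833, abs=5e-4)

    def test_reliability_limits(self):
        assert implied_slope_reliability(0.1, 1e-12, 1.0, 15) == pytest.approx(1.0)
        with pytest.raises(ValueError):
            implied_slope_reliability(0.1, 1.0, 1.0, 2)

    def test_icc_of_outcome(self):
        assert implied_icc(1.1, 0.1, 1.0, 1.0) == pytest.approx(0.5)
        assert implied_icc(1.0, 0.0, 1.0, 1.0) == pytest.approx(0.5)
        assert implied_icc(0.0, 0.1, 1.0, 1.0) == 0.0
        with pytest.raises(ValueError):
            implied_icc(0.0, 0.0, 0.0, 0.0)


class TestSimulate:
    def test_latent_moments_match_population(self):
        """Sample moments of the latent draws converge to the Phi_B entries."""
        spec = PopulationSpec(P=100_000, T=2, hypothesis="congruence", r2_target=0.25, seed=1)
        data = simulate(spec)
        t = data.truth
        # 3 MC standard errors for a correlation at P=1e5 is about 0.01
        assert np.cov(t["x_b"], t["y_b"])[0, 1] == pytest.approx(0.21, abs=0.015)
        assert np.corrcoef(t["x_b"], t["y_b"])[0, 1] == pytest.approx(0.2, abs=0.015)
        assert t["beta_y"].var() == pytest.approx(0.1, abs=0.005)
        # restricted pairs remain uncorrelated
        assert abs(np.corrcoef(t["x_b"], t["beta_y"])[0, 1]) < 0.015
        assert abs(np.corrcoef(t["x_b"], t["u_b"])[0, 1]) < 0.015
        assert abs(np.corrcoef(t["y_b"], t["beta_v"])[0, 1]) < 0.015

    def test_congruence_identity_recovers_b3(self):
        """z regressed on the true squared slope difference recovers b3."""
        spec = PopulationSpec(P=50_000, T=2, hypothesis="congruence", r2_target=0.25, seed=2)
        data = simulate(spec)
        d2 = (data.truth["beta_y"] - data.truth["beta_v"]) ** 2
        z = data.level2["z"]
        slope = np.cov(d2, z)[0, 1] / d2.var()
        assert slope == pytest.approx(spec.b[3], rel=0.05)

    def test_null_effect_r2_near_zero(self):
        spec = PopulationSpec(P=20_000, T=2, hypothesis="ushape", r2_target=0.0, seed=3)
        data = simulate(spec)
        by = data.truth["beta_y"]
        z = data.level2["z"]
        r2 = np.corrcoef(by**2, z)[0, 1] ** 2
        assert r2 < 0.001

    def test_ushape_data_has_no_uv(self):
        data = simulate(PopulationSpec(P=20, T=5, hypothesis="ushape", seed=4))
        assert not data.bivariate
        assert data.n_persons == 20

    def test_deterministic_under_seed(self):
        spec = PopulationSpec(P=30, T=5, hypothesis="moderation", seed=5)
        a, b = simulate(spec), simulate(spec)
        assert a.level1.equals(b.level1)
        assert a.level2.equals(b.level2)


class TestUnbalanced:
    def test_occasion_counts_in_range(self):
        spec = PopulationSpec(P=100, T=40, hypothesis="ushape", seed=6)
        unb = make_unbalanced(simulate(spec), seed=6)
        counts = unb.occasion_counts()
        assert counts.min() >= 16
        assert counts.max() <= 40
        assert counts.nunique() > 5  # genuinely varying

    def test_deterministic_and_requires_t40(self):
        spec = PopulationSpec(P=50, T=40, hypothesis="ushape", seed=7)
        data = simulate(spec)
        u1 = make_unbalanced(data, seed=8)
        u2 = make_unbalanced(data, seed=8)
        assert u1.level1.equals(u2.level1)
        with pytest.raises(ValueError):
            make_unbalanced(simulate(PopulationSpec(P=20, T=15, hypothesis="ushape", seed=9)), seed=1)
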