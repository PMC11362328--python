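import numpy as np
import pandas as pd
import pytest

from slopesem import (
    PopulationSpec,
    RandomSlopeModel,
    TwoLevelData,
    person_center,
    simulate,
)


class TestPersonCenter:
    def test_basic_arithmetic(self):
        level1 = pd.DataFrame(
            {"id": [0, 0, 0, 1, 1], "t": [0, 1, 2, 0, 1],
             "x": [1.0, 2.0, 3.0, 5.0, 5.0], "y": [0.0] * 5}
        )
        level2 = pd.DataFrame({"id": [0, 1], "z": [0.0, 0.0]})
        data = TwoLevelData(level1=level1, level2=level2)
        xc, means = person_center(data, "x")
        assert np.allclose(xc[:3], [-1, 0, 1])
        assert np.allclose(xc[3:], [0, 0])  # constant series centers to zero
        assert means.loc[0] == 2.0 and means.loc[1] == 5.0

    def test_centered_means_are_zero_unbalanced(self, ushape_data):
        xc, _ = person_center(ushape_data, "x")
        per_person = xc.groupby(ushape_data.level1["id"]).mean()
        assert np.allclose(per_person, 0.0, atol=1e-12)


class TestRandomSlopeModel:
    def test_matches_general_mixed_model_software(self):
        """REML estimates agree with statsmodels MixedLM (independent route)."""
        import statsmodels.formula.api as smf

        spec = PopulationSpec(P=200, T=15, hypothesis="ushape", r2_target=0.25, seed=1)
        data = simulate(spec)
        fit = RandomSlopeModel(data, "y", "x").fit()
        df = data.level1.copy()
        df["xc"] = df.groupby("id")["x"].transform(lambda s: s - s.mean())
        df["xbar"] = df.groupby("id")["x"].transform("mean")
        ref = smf.mixedlm(
            "y ~ xbar + xc", df, groups=df["id"], re_formula="~xc"
        ).fit(reml=True)
        assert fit.fixed_effects["g10"] == pytest.approx(ref.fe_params["xc"], abs=1e-4)
        assert fit.cov_re[1, 1] == pytest.approx(ref.cov_re.values[1, 1], abs=1e-3)
        assert fit.sigma2 == pytest.approx(ref.scale, rel=1e-3)
        re = pd.DataFrame(ref.random_effects).T
        eap_ref = re["xc"].to_numpy() + ref.fe_params["xc"]
        assert np.abs(fit.eap_slope - eap_ref).max() < 1e-3

    def test_eap_equals_dense_conjugate_posterior(self, toy_data):
        """EAP slopes match the textbook conjugate-normal formula computed
        with dense per-person matrices at the same parameter values."""
        model = RandomSlopeModel(toy_data, "y", "x")
        fit = model.fit()
        G, s2 = fit.cov_re, fit.sigma2
        gam = np.array(list(fit.fixed_effects.values()))
        df = toy_data.level1
        xc, xbar = person_center(toy_data, "x")
        for pid in toy_data.level2["id"]:
            sel = df["id"] == pid
            Z = np.column_stack([np.ones(sel.sum()), xc[sel]])
            X = np.column_stack(
                [np.ones(sel.sum()), np.full(sel.sum(), xbar.loc[pid]), xc[sel]]
            )
            y = df.loc[sel, "y"].to_numpy()
            V = s2 * np.eye(len(y)) + Z @ G @ Z.T
            u = G @ Z.T @ np.linalg.solve(V, y - X @ gam)
            cond = G - G @ Z.T @ np.linalg.solve(V, Z @ G)
            i = list(toy_data.level2["id"]).index(pid)
            assert fit.eap_slope[i] == pytest.approx(gam[2] + u[1], abs=1e-7)
            assert fit.cond_sd[i] == pytest.approx(np.sqrt(cond[1, 1]), abs=1e-7)

    def test_shrinkage_toward_fixed_effect(self):
        """EAP slopes shrink toward the mean slope relative to per-person OLS.

        With a freely estimated intercept-slope covariance the EAP borrows
        a little strength from the intercept residual, so the inequality is
        asserted on data whose population intercept-slope covariance is
        zero, with a tolerance for the residual coupling of the estimated
        covariance.
        """
        phi_b = PopulationSpec().phi_b.copy()
        phi_b[2, 4] = phi_b[4, 2] = 0.0  # no intercept-slope covariance
        phi_b[3, 5] = phi_b[5, 3] = 0.0
        spec = PopulationSpec(P=150, T=12, hypothesis="ushape", phi_b=phi_b, seed=21)
        data = simulate(spec)
        fit = RandomSlopeModel(data, "y", "x").fit()
        df = data.level1
        xc, _ = person_center(data, "x")
        g10 = fit.fixed_effects["g10"]
        ols = np.empty(len(fit.ids))
        for i, pid in enumerate(fit.ids):
            sel = df["id"] == pid
            ols[i] = np.sum(xc[sel] * df.loc[sel, "y"]) / np.sum(xc[sel] ** 2)
        # ensemble shrinkage: EAPs are strictly less dispersed than OLS
        assert np.var(fit.eap_slope) < 0.8 * np.var(ols)
        assert np.corrcoef(fit.eap_slope, ols)[0, 1] > 0.9
        # pointwise shrinkage away from the center (the intercept channel
        # can cause tiny overshoots only for slopes already near g10)
        far = np.abs(ols - g10) > 0.2
        assert far.sum() > 20
        assert np.all(
            np.abs(fit.eap_slope[far] - g10) <= np.abs(ols[far] - g10) + 1e-8
        )

    def test_cond_sd_structure(self):
        """Conditional SDs track the per-person slope information: in
        balanced data they vary only with the within-person predictor sum
        of squares, and in unbalanced data they decrease with T_i."""
        from slopesem import make_unbalanced

        spec = PopulationSpec(P=80, T=40, hypothesis="ushape", seed=10)
        bal = simulate(spec)
        fit = RandomSlopeModel(bal, "y", "x").fit()
        xc, _ = person_center(bal, "x")
        sxx = (xc**2).groupby(bal.level1["id"]).sum().loc[fit.ids].to_numpy()
        assert np.corrcoef(fit.cond_sd, 1.0 / np.sqrt(sxx))[0, 1] > 0.99

        unb = make_unbalanced(bal, seed=11)
        ufit = RandomSlopeModel(unb, "y", "x").fit()
        uxc, _ = person_center(unb, "x")
        usxx = (uxc**2).groupby(unb.level1["id"]).sum().loc[ufit.ids].to_numpy()
        assert np.corrcoef(ufit.cond_sd, 1.0 / np.sqrt(usxx))[0, 1] > 0.98
        counts = unb.occasion_counts().loc[ufit.ids].to_numpy()
        assert np.corrcoef(counts, ufit.cond_sd)[0, 1] < -0.2

    def test_eap_variance_reflects_reliability(self):
        """Var(EAP) ~ reliability * Var(U1) in balanced data."""
        from slopesem import implied_slope_reliability

        spec = PopulationSpec(P=2000, T=15, hypothesis="ushape", seed=12)
        fit = RandomSlopeModel(simulate(spec), "y", "x").fit()
        rel = implied_slope_reliability(
            fit.cov_re[1, 1], fit.sigma2, 1.0, 15
        )
        ratio = np.var(fit.eap_slope, ddof=1) / (rel * fit.cov_re[1, 1])
        assert ratio == pytest.approx(1.0, abs=0.1)

    def test_variance_component_recovery(self):
        """Across replications, Var(U1) and the mean slope recover truth."""
        g10s, v1s = [], []
        for seed in range(60):
            spec = PopulationSpec(P=300, T=20, hypothesis="ushape", seed=100 + seed)
            fit = RandomSlopeModel(simulate(spec), "y", "x").fit()
            g10s.append(fit.fixed_effects["g10"])
            v1s.append(fit.cov_re[1, 1])
        assert np.mean(g10s) == pytest.approx(0.0, abs=0.01)
        assert np.mean(v1s) == pytest.approx(0.1, abs=0.01)

    def test_conditioned_model_tracks_outcome(self):
        """Slopes from the z-conditioned model correlate more with z."""
        spec = PopulationSpec(P=400, T=8, hypothesis="ushape", r2_target=0.0, seed=13)
        data = simulate(spec)
        # inject a linear slope-z association
        data.level2["z"] = (
            2.0 * data.truth["beta_y"].to_numpy()
            + np.random.default_rng(14).normal(0, 0.5, len(data.level2))
        )
        plain = RandomSlopeModel(data, "y", "x").fit()
        cond = RandomSlopeModel(data, "y", "x", l2_covariates=("z",)).fit()
        z = data.level2["z"].to_numpy()
        assert np.corrcoef(cond.eap_slope, z)[0, 1] > np.corrcoef(plain.eap_slope, z)[0, 1]
        assert "g1_z" in cond.fixed_effects
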