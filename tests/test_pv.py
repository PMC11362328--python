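import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from slopesem import (
    PlausibleValuesModel,
    PopulationSpec,
    draw_pvs,
    pool_rubin,
    simulate,
)
from slopesem.lmm import RandomSlopeModel
from slopesem.twostep import step1_slopes
from slopesem.results import build_design
import statsmodels.api as sm


class TestDrawPVs:
    def test_moments_and_determinism(self, ushape_data):
        fit = RandomSlopeModel(ushape_data, "y", "x", l2_covariates=("z",)).fit()
        pvs = draw_pvs({"cy": fit}, M=5000, seed=1)
        d = pvs.draws["cy"]
        assert np.allclose(d.mean(axis=1), fit.eap_slope, atol=4 * fit.cond_sd.max() / np.sqrt(5000))
        assert np.allclose(d.var(axis=1, ddof=1), fit.cond_sd**2, rtol=0.2)
        again = draw_pvs({"cy": fit}, M=5000, seed=1)
        assert np.array_equal(d, again.draws["cy"])

    def test_degenerate_sd_returns_eap(self, ushape_data):
        fit = RandomSlopeModel(ushape_data, "y", "x").fit()
        fit.cond_sd = np.zeros_like(fit.cond_sd)
        pvs = draw_pvs({"cy": fit}, M=3, seed=2)
        assert np.allclose(pvs.draws["cy"], fit.eap_slope[:, None])

    def test_m_below_two_rejected(self, ushape_data):
        fit = RandomSlopeModel(ushape_data, "y", "x").fit()
        with pytest.raises(ValueError):
            draw_pvs({"cy": fit}, M=1, seed=0)


class TestPoolRubin:
    def test_hand_computed_example(self):
        """Three draws with estimates (1,2,3) and unit variances."""
        pooled = pool_rubin([1.0, 2.0, 3.0], [1.0, 1.0, 1.0])
        assert pooled.point[0] == pytest.approx(2.0)
        assert pooled.within[0] == pytest.approx(1.0)
        assert pooled.between[0] == pytest.approx(1.0)
        assert pooled.total[0] == pytest.approx(1.0 + 4.0 / 3.0)
        assert pooled.se[0] == pytest.approx(np.sqrt(7.0 / 3.0), abs=1e-6)
        assert pooled.se[0] == pytest.approx(1.528, abs=1e-3)
        # Rubin df: (M-1)(1 + W/((1+1/M)B))^2 = 2*(1+3/4)^2
        assert pooled.df[0] == pytest.approx(2 * (1 + 0.75) ** 2)

    def test_identical_estimates_collapse_to_within(self):
        pooled = pool_rubin([1.5, 1.5, 1.5], [0.2, 0.4, 0.6])
        assert pooled.between[0] == 0.0
        assert pooled.total[0] == pytest.approx(0.4)
        assert np.isinf(pooled.df[0])

    def test_single_draw_rejected(self):
        with pytest.raises(ValueError):
            pool_rubin([1.0], [1.0])

    @settings(derandomize=True, max_examples=30)
    @given(
        est=st.lists(st.floats(-5, 5), min_size=3, max_size=12),
        v=st.floats(0.01, 2.0),
    )
    def test_pooling_identities(self, est, v):
        """Total variance dominates the within part and the interval is
        symmetric about the pooled point."""
        var = [v] * len(est)
        pooled = pool_rubin(est, var)
        assert pooled.total[0] >= pooled.within[0] - 1e-12
        lo, hi = pooled.conf_int[0]
        assert (pooled.point[0] - lo) == pytest.approx(hi - pooled.point[0], rel=1e-9, abs=1e-9)


class TestPlausibleValuesModel:
    def test_degenerate_draws_equal_conditioned_twostep(self, ushape_data, monkeypatch):
        """With zero conditional SDs every PV equals the EAP, so the PV fit
        equals the (conditioned-slope) OLS fit exactly."""
        from slopesem import pv as pv_mod

        real_draw = pv_mod.draw_pvs

        def degenerate(slopefits, M, seed=None):
            for f in slopefits.values():
                f.cond_sd = np.zeros_like(f.cond_sd)
            return real_draw(slopefits, M, seed)

        monkeypatch.setattr(pv_mod, "draw_pvs", degenerate)
        fit = PlausibleValuesModel(ushape_data, "ushape", M=5).fit(seed=3)

        cfit, _ = step1_slopes(ushape_data, "quadratic", l2_covariates=("z",))
        X, idx = build_design(cfit.eap_slope, None, "quadratic")
        z = ushape_data.level2.set_index("id").loc[cfit.ids, "z"].to_numpy()
        ols = sm.OLS(z, X).fit()
        assert fit.params[[0, 1, 3]] == pytest.approx(np.asarray(ols.params), abs=1e-8)

    def test_pooled_width_exceeds_mean_per_draw_width(self, ushape_data):
        """Between-draw variability widens the pooled interval beyond the
        average per-draw interval."""
        model = PlausibleValuesModel(ushape_data, "ushape", M=20)
        fit = model.fit(seed=4)
        # reproduce the identical draws and fit each separately
        pvset = draw_pvs(model.step1(), 20, seed=4)
        z = ushape_data.level2.sort_values("id")["z"].to_numpy()
        widths = []
        for m in range(20):
            X, _ = build_design(pvset.draws["cy"][:, m], None, "quadratic")
            ols = sm.OLS(z, X).fit()
            widths.append(ols.conf_int()[2, 1] - ols.conf_int()[2, 0])
        pooled_width = fit.conf_int[3, 1] - fit.conf_int[3, 0]
        assert pooled_width >= np.mean(widths)

    def test_attenuation_stronger_than_twostep(self):
        """PV nonlinear coefficients are attenuated more than two-step."""
        from slopesem import TwoStepModel

        pv_est, ts_est = [], []
        for seed in range(60):
            spec = PopulationSpec(
                P=200, T=15, hypothesis="ushape", r2_target=0.25,
                paper_values=True, seed=20_000 + seed,
            )
            data = simulate(spec)
            pv_est.append(PlausibleValuesModel(data, "ushape", M=20).fit(seed=seed).params[3])
            ts_est.append(TwoStepModel(data, "ushape").fit().params[3])
        assert abs(np.mean(pv_est)) < abs(np.mean(ts_est))
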