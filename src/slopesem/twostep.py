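"""Simple two-step estimator: EAP slopes, then ordinary least squares.

Step 1 fits the random-slope mixed model separately for each
predictor/outcome pair — (x, y) for the first within-person association and
(u, v) for the second — and extracts EAP (empirical-Bayes) estimates of the
person-specific slopes.  Step 2 regresses the person-level outcome ``z`` on
the polynomial terms of those slope estimates with a regular OLS fit.  The
slope estimates are treated as known quantities, so the approach ignores
their unreliability; the resulting attenuation of nonlinear coefficients
and overly narrow intervals are exactly what the Monte-Carlo harness in
:mod:`slopesem.evaluate` quantifies.
"""

from __future__ import annotations

import numpy as np
import statsmodels.api as sm

from .data import TwoLevelData
from .lmm import RandomSlopeModel, SlopeFit
from .results import PolyFit, build_design, model_kind, polyfit_from_ols


def step1_slopes(
    data: TwoLevelData, kind: str, l2_covariates: tuple[str, ...] = ()
) -> tuple[SlopeFit, SlopeFit | None]:
    """Fit the step-1 mixed model(s) and return the slope fits."""
    kind = model_kind(kind)
    fit_y = RandomSlopeModel(data, "y", "x", l2_covariates).fit()
    fit_v = None
    if kind != "quadratic":
        if not data.bivariate:
            raise ValueError(f"model kind {kind!r} needs u/v data")
        fit_v = RandomSlopeModel(data, "v", "u", l2_covariates).fit()
    return fit_y, fit_v


class TwoStepModel:
    """Two-step polynomial model for nonlinear effects of random slopes."""

    def __init__(self, data: TwoLevelData, kind: str, robust: bool = False) -> None:
        self.data = data
        self.kind = model_kind(kind)
        self.robust = robust

    def fit(self) -> PolyFit:
        fit_y, fit_v = step1_slopes(self.data, self.kind)
        cy = fit_y.eap_slope
        cv = fit_v.eap_slope if fit_v is not None else None
        z = self.data.level2.set_index("id").loc[fit_y.ids, "z"].to_numpy()
        X, idx = build_design(cy, cv, self.kind)
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise np.linalg.LinAlgError(
                "singular step-2 design (near-zero slope variance)"
            )
        ols = sm.OLS(z, X).fit(cov_type="HC1" if self.robust else "nonrobust")
        fit = polyfit_from_ols(ols, idx, "twostep", self.kind, len(z))
        fit.diagnostics["step1_converged"] = bool(
            fit_y.converged and (fit_v is None or fit_v.converged)
        )
        fit.diagnostics["slope_fit_y"] = fit_y
        if fit_v is not None:
            fit.diagnostics["slope_fit_v"] = fit_v
        return fit


def run_twostep(data: TwoLevelData, kind: str, robust: bool = False) -> PolyFit:
    """Convenience wrapper mirroring :class:`TwoStepModel`."""
    return TwoStepModel(data, kind, robust=robust).fit()
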