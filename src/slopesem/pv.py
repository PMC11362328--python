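"""Plausible-values estimator with Rubin pooling.

Step 1 fits the random-slope model *conditioned on the outcome*: ``z`` (and
its product with the person mean) enters the level-2 equations for the
intercept and the slope, so the conditional slope distribution reflects the
linear part of the slope–outcome association.  For each person, M plausible
values are drawn from ``N(c'_i, s'^2_i)`` around the conditioned EAP
estimate.  The polynomial analysis model is then fitted once per draw and
the per-draw estimates are combined with Rubin's rules:

    Qbar = mean of estimates          W = mean within-draw variance
    B    = between-draw variance      T = W + (1 + 1/M) * B
    df   = (M - 1) * (1 + W / ((1 + 1/M) * B))^2

Intervals use t quantiles with the Rubin degrees of freedom.  The same
pooling is applied to the per-draw response-surface auxiliary parameters
(with delta-method within-draw variances) in the congruence model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from scipy import stats

from .data import TwoLevelData
from .lmm import SlopeFit
from .results import PolyFit, build_design, expand_to_full, model_kind
from .rsa import AUX_NAMES, RSAParams, aux_params, delta_se
from .twostep import step1_slopes


@dataclass
class PVSet:
    """Matrix of plausible slope values: one row per person, M columns."""

    draws: dict
    M: int
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.M < 2:
            raise ValueError("need at least M = 2 plausible values")


@dataclass
class PooledEstimate:
    """Rubin-pooled quantities for a vector of parameters."""

    point: np.ndarray
    within: np.ndarray
    between: np.ndarray
    total: np.ndarray
    df: np.ndarray
    conf_int: np.ndarray
    M: int

    @property
    def se(self) -> np.ndarray:
        return np.sqrt(self.total)


def draw_pvs(
    slopefits: dict, M: int, seed: int | None = None
) -> PVSet:
    """Draw M plausible values per person from the conditioned slope fits.

    ``slopefits`` maps slope names (e.g. ``"cy"``) to :class:`SlopeFit`
    objects produced by the conditioned step-1 model.
    """
    if M < 2:
        raise ValueError("need at least M = 2 plausible values")
    rng = np.random.default_rng(seed)
    draws = {}
    for name, fit in slopefits.items():
        if not isinstance(fit, SlopeFit):
            raise TypeError("slopefits values must be SlopeFit objects")
        eps = rng.standard_normal((len(fit.ids), M))
        draws[name] = fit.eap_slope[:, None] + fit.cond_sd[:, None] * eps
    return PVSet(draws=draws, M=M, seed=seed)


def pool_rubin(
    estimates: np.ndarray, variances: np.ndarray, alpha: float = 0.05
) -> PooledEstimate:
    """Combine per-draw estimates and sampling variances with Rubin's rules."""
    est = np.asarray(estimates, dtype=float)
    var = np.asarray(variances, dtype=float)
    if est.ndim == 1:  # a single parameter: rows are draws
        est = est[:, None]
        var = var[:, None]
    if est.shape != var.shape:
        raise ValueError("estimates and variances must have matching shapes")
    M = est.shape[0]
    if M < 2:
        raise ValueError("Rubin pooling needs at least two draws")
    qbar = est.mean(axis=0)
    w = var.mean(axis=0)
    b = est.var(axis=0, ddof=1)
    total = w + (1.0 + 1.0 / M) * b
    with np.errstate(divide="ignore", invalid="ignore"):
        df = (M - 1.0) * (1.0 + w / ((1.0 + 1.0 / M) * b)) ** 2
    df = np.where(b > 0, df, np.inf)
    crit = np.where(
        np.isinf(df),
        stats.norm.ppf(1 - alpha / 2),
        stats.t.ppf(1 - alpha / 2, np.clip(df, 1e-8, None)),
    )
    half = crit * np.sqrt(total)
    ci = np.stack([qbar - half, qbar + half], axis=-1)
    return PooledEstimate(
        point=qbar, within=w, between=b, total=total, df=df, conf_int=ci, M=M
    )


class PlausibleValuesModel:
    """Plausible-values polynomial model for nonlinear slope effects."""

    def __init__(self, data: TwoLevelData, kind: str, M: int = 20) -> None:
        self.data = data
        self.kind = model_kind(kind)
        self.M = int(M)

    def step1(self) -> dict:
        fit_y, fit_v = step1_slopes(self.data, self.kind, l2_covariates=("z",))
        fits = {"cy": fit_y}
        if fit_v is not None:
            fits["cv"] = fit_v
        return fits

    def fit(self, seed: int | None = None) -> PolyFit:
        fits = self.step1()
        pvset = draw_pvs(fits, self.M, seed=seed)
        ids = fits["cy"].ids
        z = self.data.level2.set_index("id").loc[ids, "z"].to_numpy()

        est, var, aux_pts, aux_var = [], [], [], []
        idx = None
        for m in range(self.M):
            cy = pvset.draws["cy"][:, m]
            cv = pvset.draws["cv"][:, m] if "cv" in pvset.draws else None
            X, idx = build_design(cy, cv, self.kind)
            ols = sm.OLS(z, X).fit()
            b6 = expand_to_full(np.asarray(ols.params), idx)
            v6 = expand_to_full(np.diag(ols.cov_params()), idx)
            est.append(b6)
            var.append(v6)
            if self.kind == "full_poly":
                cov6 = np.zeros((6, 6))
                cov6[np.ix_(idx, idx)] = np.asarray(ols.cov_params())
                pts = aux_params(b6)
                ses = delta_se(b6, cov6)
                aux_pts.append([pts[n] for n in AUX_NAMES])
                aux_var.append([ses[n] ** 2 for n in AUX_NAMES])

        est = np.asarray(est)
        var = np.asarray(var)
        pooled = pool_rubin(est, var)
        free = list(idx)
        cov6 = np.zeros((6, 6))
        bcov = np.cov(est[:, free], rowvar=False)
        wcov = np.zeros_like(bcov)
        np.fill_diagonal(wcov, pooled.within[free])
        cov6[np.ix_(free, free)] = wcov + (1.0 + 1.0 / self.M) * bcov
        # keep pooled per-coefficient totals on the diagonal exactly
        cov6[np.arange(6), np.arange(6)] = pooled.total

        fit = PolyFit(
            method="pv",
            kind=self.kind,
            params=pooled.point,
            cov=cov6,
            conf_int=pooled.conf_int,
            n_persons=len(ids),
            diagnostics={
                "M": self.M,
                "df": pooled.df,
                "step1_converged": all(f.converged for f in fits.values()),
            },
        )
        if self.kind == "full_poly":
            fit.diagnostics["rsa"] = _pooled_rsa(
                np.asarray(aux_pts), np.asarray(aux_var)
            )
        return fit


def _pooled_rsa(points: np.ndarray, variances: np.ndarray) -> RSAParams:
    ok = np.isfinite(points).all(axis=1) & np.isfinite(variances).all(axis=1)
    if ok.sum() < 2:
        return RSAParams(
            points={n: np.nan for n in AUX_NAMES},
            se={n: np.nan for n in AUX_NAMES},
            conf_int={n: (np.nan, np.nan) for n in AUX_NAMES},
            source="pooled",
            undefined="auxiliary parameters undefined in most draws",
        )
    pooled = pool_rubin(points[ok], variances[ok])
    return RSAParams(
        points=dict(zip(AUX_NAMES, pooled.point)),
        se=dict(zip(AUX_NAMES, pooled.se)),
        conf_int={n: tuple(pooled.conf_int[i]) for i, n in enumerate(AUX_NAMES)},
        source="pooled",
    )


def run_pv(data: TwoLevelData, kind: str, M: int = 20, seed: int | None = None) -> PolyFit:
    """Convenience wrapper mirroring :class:`PlausibleValuesModel`."""
    return PlausibleValuesModel(data, kind, M=M).fit(seed=seed)
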