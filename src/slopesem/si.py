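"""Simplified single-indicator SEM for nonlinear effects of random slopes.

Each estimated slope is treated as the single indicator of a latent slope
factor.  With the indicators standardized to unit total latent variance,
the measurement parameters are fixed from the averaged conditional slope
variance ``s2bar`` (the simplified variant that ignores person-specific
reliabilities):

    w_i = lambda * eta_i + xi_i,   Var(eta) = 1,
    lambda = 1 - s2bar,            Var(xi) = s2bar * (1 - s2bar)

The structural model is the polynomial in the latent factors,
``z = b0 + b1*eta_y + ... + b5*eta_v^2 + eps``, estimated by MCMC
(Gibbs steps for the regression coefficients and residual variance,
a Metropolis step for the latent factor correlation, and per-person
independence-Metropolis updates of the latent factors).  Structural
coefficients are back-transformed to the raw slope metric so results are
comparable across methods.

Standardization is required because fixing ``Var(eta) = 1`` presupposes a
standardized slope metric: EAP slopes are divided by the estimated total
latent-slope SD ``sqrt(Var(c_hat) + s2bar_raw)`` before the measurement
model is built, and the polynomial coefficients are mapped back to the raw
metric afterwards.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import TwoLevelData
from .results import (
    PolyFit,
    affine_backtransform,
    build_design,
    draws_summary,
    expand_to_full,
    model_kind,
)
from .twostep import step1_slopes


@dataclass
class SIMeasurement:
    """Fixed measurement parameters of the simplified single-indicator model."""

    indicators: np.ndarray  # (P, d) standardized slope estimates
    s2bar: np.ndarray  # (d,) mean standardized conditional variance
    loading: np.ndarray  # (d,) lambda = 1 - s2bar
    error_var: np.ndarray  # (d,) s2bar * (1 - s2bar)
    mean: np.ndarray  # (d,) raw slope means used for standardization
    scale: np.ndarray  # (d,) raw total latent-slope SDs
    ids: np.ndarray


def si_measurement_params(s2bar: float) -> tuple[float, float]:
    """Loading and error variance implied by a mean conditional variance."""
    if not 0.0 <= s2bar < 1.0:
        raise ValueError("mean conditional variance must be in [0, 1)")
    return 1.0 - s2bar, s2bar * (1.0 - s2bar)


def build_si_measurement(
    slopefits: dict, s2bar_override: dict | None = None
) -> SIMeasurement:
    """Standardize EAP slopes and fix the single-indicator parameters.

    ``s2bar_override`` optionally replaces the standardized mean conditional
    variance per slope (useful for sensitivity analyses).
    """
    names = list(slopefits)
    P = len(next(iter(slopefits.values())).ids)
    w = np.empty((P, len(names)))
    s2 = np.empty(len(names))
    lam = np.empty(len(names))
    ev = np.empty(len(names))
    mean = np.empty(len(names))
    scale = np.empty(len(names))
    for j, name in enumerate(names):
        fit = slopefits[name]
        if fit.slope_variance <= 0:
            raise ValueError("slope variance estimated at zero; SI model degenerate")
        raw_s2 = float(np.mean(fit.cond_sd**2))
        eap_var = float(np.var(fit.eap_slope, ddof=1))
        mean[j] = float(np.mean(fit.eap_slope))
        if s2bar_override and name in s2bar_override:
            # treat the injected value as the standardized mean conditional
            # variance and back out the implied total slope variance, so the
            # indicator variance stays consistent with the measurement model
            s2[j] = float(s2bar_override[name])
            total_var = eap_var / max(1.0 - s2[j], 1e-12)
        else:
            total_var = eap_var + raw_s2
            s2[j] = raw_s2 / total_var
        scale[j] = np.sqrt(total_var)
        w[:, j] = (fit.eap_slope - mean[j]) / scale[j]
        lam[j], ev[j] = si_measurement_params(s2[j])
    return SIMeasurement(
        indicators=w,
        s2bar=s2,
        loading=lam,
        error_var=ev,
        mean=mean,
        scale=scale,
        ids=next(iter(slopefits.values())).ids,
    )


class SingleIndicatorSEM:
    """Single-indicator SEM estimated by MCMC.

    Parameters follow the reference settings of the simulation study this
    package reproduces: 12,000 iterations per chain with the first half
    discarded as burn-in, two chains, and weakly-informative priors
    (N(0, 10^2) on standardized structural coefficients, inverse-gamma
    (0.001, 0.001) on the residual variance, flat on the latent
    correlation).
    """

    def __init__(
        self,
        data: TwoLevelData,
        kind: str,
        iterations: int = 12_000,
        burnin: float = 0.5,
        chains: int = 2,
        b_prior_sd: float = 10.0,
    ) -> None:
        self.data = data
        self.kind = model_kind(kind)
        self.iterations = int(iterations)
        self.burnin = float(burnin)
        self.chains = int(chains)
        self.b_prior_sd = float(b_prior_sd)

    def fit(
        self, seed: int | None = None, s2bar_override: dict | None = None
    ) -> PolyFit:
        fit_y, fit_v = step1_slopes(self.data, self.kind)
        fits = {"cy": fit_y}
        if fit_v is not None:
            fits["cv"] = fit_v
        meas = build_si_measurement(fits, s2bar_override=s2bar_override)
        ids = meas.ids
        z = self.data.level2.set_index("id").loc[ids, "z"].to_numpy(dtype=float)

        ss = np.random.SeedSequence(seed)
        chain_draws = []
        accept = []
        for child in ss.spawn(self.chains):
            draws, acc = self._run_chain(meas, z, np.random.default_rng(child))
            chain_draws.append(draws)
            accept.append(acc)

        rhat = _split_rhat(chain_draws)
        all_std = np.concatenate(chain_draws, axis=0)

        if self.kind == "quadratic":
            means = np.array([meas.mean[0], 0.0])
            scales = np.array([meas.scale[0], 1.0])
        else:
            means, scales = meas.mean, meas.scale
        raw = np.array([affine_backtransform(b, means, scales) for b in all_std])
        params, cov, ci = draws_summary(raw)
        return PolyFit(
            method="si",
            kind=self.kind,
            params=params,
            cov=cov,
            conf_int=ci,
            n_persons=len(ids),
            draws=raw,
            diagnostics={
                "rhat_max": float(np.nanmax(rhat)),
                "converged": bool(np.nanmax(rhat) < 1.05),
                "accept_eta": float(np.mean(accept)),
                "s2bar": meas.s2bar,
                "scale": meas.scale,
                "iterations": self.iterations,
                "chains": self.chains,
            },
        )

    # -- sampler -----------------------------------------------------------

    def _run_chain(self, meas: SIMeasurement, z: np.ndarray, rng) -> tuple:
        w = meas.indicators
        P, d = w.shape
        lam, ev = meas.loading, meas.error_var
        exact = ev <= 1e-12  # perfect-reliability limit: eta pinned to w/lambda

        eta = np.where(exact[None, :], w / lam[None, :], w)
        rho = 0.0
        if d == 2:
            rho = float(np.clip(np.corrcoef(w.T)[0, 1], -0.9, 0.9))
        X, idx = build_design(eta[:, 0], eta[:, 1] if d == 2 else None, self.kind)
        k = X.shape[1]
        b = np.linalg.lstsq(X, z, rcond=None)[0]
        tau2 = max(float(np.var(z - X @ b)), 1e-6)

        n_keep = self.iterations - int(self.iterations * self.burnin)
        out = np.empty((n_keep, 6))
        kept = 0
        acc_n = acc_d = 0
        prior_prec = 1.0 / self.b_prior_sd**2
        rho_step = 0.2

        for it in range(self.iterations):
            # (a) latent factors: independence-MH from the measurement posterior
            if not exact.all():
                psi = np.eye(d)
                if d == 2:
                    psi[0, 1] = psi[1, 0] = rho
                psi_inv = np.linalg.inv(psi)
                ev_safe = np.maximum(ev, 1e-12)
                prec = psi_inv + np.diag(lam**2 / ev_safe)
                cov_p = np.linalg.inv(prec)
                mean_p = ((lam / ev_safe) * w) @ cov_p.T
                L = np.linalg.cholesky(cov_p)
                prop = mean_p + rng.standard_normal((P, d)) @ L.T
                prop[:, exact] = w[:, exact] / lam[exact]
                ll_new = _z_loglik(prop, z, b, idx, tau2, self.kind)
                ll_old = _z_loglik(eta, z, b, idx, tau2, self.kind)
                u = rng.random(P)
                take = np.log(u) < ll_new - ll_old
                eta[take] = prop[take]
                acc_n += int(take.sum())
                acc_d += P

            # (b) structural coefficients and residual variance (conjugate)
            X, idx = build_design(
                eta[:, 0], eta[:, 1] if d == 2 else None, self.kind
            )
            prec_b = X.T @ X / tau2 + prior_prec * np.eye(k)
            cov_b = np.linalg.inv(prec_b)
            mean_b = cov_b @ (X.T @ z) / tau2
            b = mean_b + np.linalg.cholesky(cov_b) @ rng.standard_normal(k)
            rss = float(np.sum((z - X @ b) ** 2))
            tau2 = 1.0 / rng.gamma(0.001 + P / 2.0, 1.0 / (0.001 + rss / 2.0))

            # (c) latent correlation (random-walk MH on atanh rho)
            if d == 2 and not exact.all():
                zeta = np.arctanh(rho)
                zeta_new = zeta + rho_step * rng.standard_normal()
                rho_new = np.tanh(zeta_new)
                lp_new = _rho_loglik(eta, rho_new) + 2.0 * np.log1p(-rho_new**2 + 1e-300)
                lp_old = _rho_loglik(eta, rho) + 2.0 * np.log1p(-rho**2 + 1e-300)
                if np.log(rng.random()) < lp_new - lp_old:
                    rho = rho_new

            if it >= self.iterations - n_keep:
                out[kept] = expand_to_full(b, idx)
                kept += 1
        acc = acc_n / acc_d if acc_d else 1.0
        return out, acc


def _z_loglik(eta, z, b, idx, tau2, kind) -> np.ndarray:
    X, _ = build_design(eta[:, 0], eta[:, 1] if eta.shape[1] == 2 else None, kind)
    mu = X @ b
    return -0.5 * (z - mu) ** 2 / tau2


def _rho_loglik(eta, rho) -> float:
    P = eta.shape[0]
    det = 1.0 - rho**2
    if det <= 0:
        return -np.inf
    q = (
        np.sum(eta[:, 0] ** 2) - 2 * rho * np.sum(eta[:, 0] * eta[:, 1]) + np.sum(eta[:, 1] ** 2)
    ) / det
    return -0.5 * (P * np.log(det) + q)


def _split_rhat(chain_draws: list) -> np.ndarray:
    """Split-Rhat per coefficient over the post-burn-in chains."""
    import arviz as az

    arr = np.stack(chain_draws)  # (chains, draws, 6)
    if arr.shape[0] == 1:  # split the single chain into halves
        half = arr.shape[1] // 2
        arr = np.stack([arr[0, :half], arr[0, half : 2 * half]])
    keep = arr.std(axis=(0, 1)) > 0
    rhat = np.full(arr.shape[-1], np.nan)
    for j in np.where(keep)[0]:
        rhat[j] = float(az.rhat(az.convert_to_dataset(arr[:, :, j]))["x"].values)
    return rhat


def run_si(
    data: TwoLevelData, kind: str, seed: int | None = None, **kwargs
) -> PolyFit:
    """Convenience wrapper mirroring :class:`SingleIndicatorSEM`."""
    return SingleIndicatorSEM(data, kind, **kwargs).fit(seed=seed)
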