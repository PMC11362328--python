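"""Fully latent Bayesian multilevel SEM for nonlinear random-slope effects.

The model decomposes the level-1 predictors into latent person means and
within-person fluctuations, specifies person-specific slopes on the
fluctuations, and regresses the person-level outcome ``z`` on a polynomial
in the *latent* slopes:

    x_it = x_Bi + x_Wit                    (latent decomposition)
    y_it = y_Bi + beta_yi * x_Wit + zeta_Wyit
    z_i  = b0 + b1*beta_y + ... + b5*beta_v^2 + zeta_zi

with multivariate-normal level-1 and level-2 covariance matrices.  The
level-2 covariance is restricted: only the variances, the within-pair
mean covariances (x-y, u-v), the mean-mean covariance y-v, the
intercept-slope covariances (y-beta_y, v-beta_v) and the slope-slope
covariance are free; all other entries are fixed to zero, and the z
residual is uncorrelated with everything.

Estimation is by MCMC with Gibbs and Metropolis-Hastings steps:

* person means given slopes — conjugate multivariate normal;
* slopes given person means — independence-MH with the Gaussian
  (prior x level-1 likelihood) conditional as proposal and the nonlinear
  z likelihood in the acceptance ratio;
* structural coefficients, residual variances, level-1 covariance — conjugate;
* free level-2 covariance entries — componentwise random-walk MH with
  step sizes adapted during burn-in.

Because every conditional reduces to per-person sufficient statistics, the
cost per iteration is O(P) regardless of the number of occasions.
Priors are weakly informative: N(0, 10^2) on structural coefficients,
inverse-gamma(0.001, 0.001) on scalar variances, inverse-Wishart with
minimal degrees of freedom on the level-1 residual block, and flat
(positivity/PD-constrained) on the level-2 covariance.  Convergence is
judged by split-Rhat (< 1.05 by default) and effective sample size.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .data import TwoLevelData
from .lmm import RandomSlopeModel
from .results import (
    PolyFit,
    MODEL_TERMS,
    build_design,
    draws_summary,
    expand_to_full,
    model_kind,
)

UNI_LATENTS = ("x_b", "y_b", "beta_y")
BI_LATENTS = ("x_b", "u_b", "y_b", "v_b", "beta_y", "beta_v")

#: free lower-triangular entries of the level-2 latent covariance
UNI_FREE = ((0, 0), (1, 1), (2, 2), (1, 0), (2, 1))
BI_FREE = (
    (0, 0), (1, 1), (2, 2), (3, 3), (4, 4), (5, 5),
    (2, 0),  # tau_xy
    (3, 1),  # tau_uv
    (3, 2),  # tau_yv
    (4, 2),  # tau_y_beta_y
    (5, 3),  # tau_v_beta_v
    (5, 4),  # tau_beta_y_beta_v
)

_PHI_B_LABELS = {
    (0, 0): "tau2_x", (1, 1): "tau2_u", (2, 2): "tau2_y", (3, 3): "tau2_v",
    (4, 4): "tau2_beta_y", (5, 5): "tau2_beta_v",
    (2, 0): "tau_xy", (3, 1): "tau_uv", (3, 2): "tau_yv",
    (4, 2): "tau_y_beta_y", (5, 3): "tau_v_beta_v", (5, 4): "tau_beta_y_beta_v",
}
_UNI_LABELS = {
    (0, 0): "tau2_x", (1, 1): "tau2_y", (2, 2): "tau2_beta_y",
    (1, 0): "tau_xy", (2, 1): "tau_y_beta_y",
}


@dataclass
class MsemModel:
    """Symbolic description of the MSEM variant to estimate."""

    kind: str
    univariate: bool
    latent_names: tuple
    free_phi_b: tuple
    phi_b_labels: dict
    struct_idx: tuple

    @property
    def free_parameter_names(self) -> list:
        names = [f"b{i}" for i in self.struct_idx]
        names += [self.phi_b_labels[ij] for ij in self.free_phi_b]
        names += ["tau2_z"]
        if self.univariate:
            names += ["sigma2_x", "sigma2_y"]
        else:
            names += ["sigma2_x", "sigma2_u", "sigma2_y", "sigma2_v", "sigma_yv"]
        return names

    def zero_mask(self) -> np.ndarray:
        """Boolean matrix marking the restricted (zero) level-2 entries."""
        q = len(self.latent_names)
        mask = np.ones((q, q), dtype=bool)
        for i, j in self.free_phi_b:
            mask[i, j] = mask[j, i] = False
        return mask


def build_msem(kind: str) -> MsemModel:
    """Construct the MSEM specification for a hypothesis/model label."""
    kind = model_kind(kind)
    if kind == "quadratic":
        return MsemModel(
            kind=kind,
            univariate=True,
            latent_names=UNI_LATENTS,
            free_phi_b=UNI_FREE,
            phi_b_labels=_UNI_LABELS,
            struct_idx=MODEL_TERMS[kind],
        )
    return MsemModel(
        kind=kind,
        univariate=False,
        latent_names=BI_LATENTS,
        free_phi_b=BI_FREE,
        phi_b_labels=_PHI_B_LABELS,
        struct_idx=MODEL_TERMS[kind],
    )


@dataclass
class McmcResult:
    """Posterior draws and convergence diagnostics."""

    draws: dict  # name -> (chains, kept) array
    rhat: dict
    ess: dict
    converged: bool
    accept_beta: float
    accept_phi_b: float
    seed: int | None
    model: MsemModel = field(repr=False, default=None)

    def stacked(self, name: str) -> np.ndarray:
        return np.concatenate(self.draws[name])

    def phi_b_matrices(self) -> np.ndarray:
        """Reconstruct full level-2 latent covariance matrices per draw
        (restricted entries are structural zeros)."""
        q = len(self.model.latent_names)
        n = self.stacked(self.model.phi_b_labels[self.model.free_phi_b[0]]).shape[0]
        out = np.zeros((n, q, q))
        for ij in self.model.free_phi_b:
            v = self.stacked(self.model.phi_b_labels[ij])
            out[:, ij[0], ij[1]] = v
            out[:, ij[1], ij[0]] = v
        return out


@dataclass
class MsemResults:
    """Results object pairing the posterior with the polynomial summary."""

    polyfit: PolyFit
    mcmc: McmcResult

    def summary(self) -> str:
        lines = [self.polyfit.summary(), ""]
        lines.append(
            f"MCMC: max Rhat {max(self.mcmc.rhat.values()):.3f}, "
            f"converged={self.mcmc.converged}, "
            f"accept(beta)={self.mcmc.accept_beta:.2f}"
        )
        for name in self.mcmc.draws:
            if name.startswith("b"):
                continue
            d = self.mcmc.stacked(name)
            lines.append(
                f"  {name:>18s}  median {np.median(d): .4f}  "
                f"[{np.quantile(d, 0.025): .4f}, {np.quantile(d, 0.975): .4f}]"
            )
        return "\n".join(lines)


class LatentSlopeMSEM:
    """Bayesian MSEM estimator.

    Parameters
    ----------
    data : TwoLevelData
    kind : str
        Hypothesis or model label (``ushape``/``quadratic``,
        ``moderation``/``interaction``, ``congruence``/``full_poly``).
    chains, iterations, burnin
        MCMC settings; ``iterations`` counts total sweeps per chain and the
        first ``burnin`` fraction is discarded.
    rhat_threshold : float
        Split-Rhat cutoff for the ``converged`` flag.
    """

    def __init__(
        self,
        data: TwoLevelData,
        kind: str,
        chains: int = 2,
        iterations: int = 2000,
        burnin: float = 0.5,
        rhat_threshold: float = 1.05,
        b_prior_sd: float = 10.0,
        prior_only: bool = False,
    ) -> None:
        self.model = build_msem(kind)
        self.data = data
        self.chains = int(chains)
        self.iterations = int(iterations)
        self.burnin = float(burnin)
        self.rhat_threshold = float(rhat_threshold)
        self.b_prior_sd = float(b_prior_sd)
        self.prior_only = bool(prior_only)
        if not self.model.univariate and not data.bivariate:
            raise ValueError("bivariate model requires u/v data")
        self._prepare()

    # -- data preparation --------------------------------------------------

    def _prepare(self) -> None:
        df = self.data.level1
        ids = df["id"].to_numpy()
        uids, idx = np.unique(ids, return_inverse=True)
        self.uids = uids
        P = len(uids)
        self.P = P
        self.z = self.data.level2.set_index("id").loc[uids, "z"].to_numpy(dtype=float)

        cols = ["x", "y"] if self.model.univariate else ["x", "u", "y", "v"]
        arrs = {c: df[c].to_numpy(dtype=float) for c in cols}
        self.T = np.bincount(idx, minlength=P).astype(float)
        self.S = {c: np.bincount(idx, weights=arrs[c], minlength=P) for c in cols}
        for a in cols:
            for b_ in cols:
                if a <= b_:
                    self.S[a + b_] = np.bincount(
                        idx, weights=arrs[a] * arrs[b_], minlength=P
                    )
        self.N = float(self.T.sum())

    # -- public API --------------------------------------------------------

    def fit(self, seed: int | None = None) -> MsemResults:
        ss = np.random.SeedSequence(seed)
        chains = []
        acc_b, acc_p = [], []
        for child in ss.spawn(self.chains):
            rec, ab, ap = self._run_chain(np.random.default_rng(child))
            chains.append(rec)
            acc_b.append(ab)
            acc_p.append(ap)

        draws = {
            name: np.stack([c[name] for c in chains]) for name in chains[0]
        }
        rhat, ess = _diagnostics(draws)
        converged = bool(max(rhat.values()) < self.rhat_threshold)
        mcmc = McmcResult(
            draws=draws,
            rhat=rhat,
            ess=ess,
            converged=converged,
            accept_beta=float(np.mean(acc_b)),
            accept_phi_b=float(np.mean(acc_p)),
            seed=seed,
            model=self.model,
        )

        b_draws = np.stack(
            [np.concatenate(draws[f"b{i}"]) for i in self.model.struct_idx], axis=1
        )
        full = np.array([expand_to_full(row, self.model.struct_idx) for row in b_draws])
        params, cov, ci = draws_summary(full)
        poly = PolyFit(
            method="msem",
            kind=self.model.kind,
            params=params,
            cov=cov,
            conf_int=ci,
            n_persons=self.P,
            draws=full,
            diagnostics={
                "rhat_max": float(max(rhat.values())),
                "converged": converged,
                "accept_beta": mcmc.accept_beta,
            },
        )
        return MsemResults(polyfit=poly, mcmc=mcmc)

    # -- sampler -----------------------------------------------------------

    def _init_state(self, rng) -> dict:
        m = self.model
        P, T = self.P, self.T
        slope_y = RandomSlopeModel(self.data, "y", "x").fit()
        beta_y = slope_y.eap_slope.copy()
        x_b = self.S["x"] / T
        y_b = self.S["y"] / T
        if m.univariate:
            theta = np.column_stack([x_b, y_b, beta_y])
        else:
            slope_v = RandomSlopeModel(self.data, "v", "u").fit()
            theta = np.column_stack(
                [x_b, self.S["u"] / T, y_b, self.S["v"] / T,
                 beta_y, slope_v.eap_slope]
            )
        theta = theta + 0.05 * rng.standard_normal(theta.shape)
        alpha = theta.mean(axis=0)
        q = theta.shape[1]
        phi = np.cov(theta, rowvar=False) + 0.05 * np.eye(q)
        phi_b = np.zeros((q, q))
        for i, j in m.free_phi_b:
            phi_b[i, j] = phi_b[j, i] = phi[i, j]
        X, _ = self._design(theta)
        b = np.linalg.lstsq(X, self.z, rcond=None)[0]
        b = b + 0.1 * rng.standard_normal(b.shape)
        tau2z = max(float(np.var(self.z - X @ b)), 1e-3)
        state = {
            "theta": theta, "alpha": alpha, "phi_b": phi_b,
            "b": b, "tau2z": tau2z,
            "s2x": max(float(slope_y.sigma2), 0.1), "s2y": float(slope_y.sigma2),
        }
        if not m.univariate:
            state["s2u"] = state["s2x"]
            state["Sw"] = np.array([[slope_y.sigma2, 0.0], [0.0, slope_v.sigma2]])
        # within-person predictor variances, a better start than sigma2
        sxx_w = (self.S["xx"] - self.S["x"] ** 2 / T).sum() / (self.N - P)
        state["s2x"] = float(sxx_w)
        if not m.univariate:
            state["s2u"] = float((self.S["uu"] - self.S["u"] ** 2 / T).sum() / (self.N - P))
        return state

    def _design(self, theta: np.ndarray):
        if self.model.univariate:
            return build_design(theta[:, 2], None, self.model.kind)
        return build_design(theta[:, 4], theta[:, 5], self.model.kind)

    def _beta_cols(self) -> slice:
        return slice(2, 3) if self.model.univariate else slice(4, 6)

    def _run_chain(self, rng):
        m = self.model
        P, T = self.P, self.T
        st = self._init_state(rng)
        n_keep = self.iterations - int(self.iterations * self.burnin)
        warmup = self.iterations - n_keep

        names = [f"b{i}" for i in m.struct_idx]
        names += [m.phi_b_labels[ij] for ij in m.free_phi_b]
        names += ["tau2_z", "sigma2_x", "sigma2_y"]
        if not m.univariate:
            names += ["sigma2_u", "sigma2_v", "sigma_yv"]
        rec = {n: np.empty(n_keep) for n in names}

        steps = {ij: 0.5 * max(abs(st["phi_b"][ij]), 0.05) / np.sqrt(P) for ij in m.free_phi_b}
        acc_phi = {ij: 0 for ij in m.free_phi_b}
        try_phi = {ij: 0 for ij in m.free_phi_b}
        acc_beta = tot_beta = 0
        kept = 0

        for it in range(self.iterations):
            if self.prior_only:
                k = len(m.struct_idx)
                bdraw = self.b_prior_sd * rng.standard_normal(k)
                if it >= warmup:
                    for j, i in enumerate(m.struct_idx):
                        rec[f"b{i}"][kept] = bdraw[j]
                    for n in names:
                        if not n.startswith("b"):
                            rec[n][kept] = 0.0
                    kept += 1
                continue

            if m.univariate:
                self._update_means_uni(st, rng)
                a, t = self._update_beta_uni(st, rng)
            else:
                self._update_means_bi(st, rng)
                a, t = self._update_beta_bi(st, rng)
            acc_beta += a
            tot_beta += t

            # level-2 means
            theta = st["theta"]
            chol = np.linalg.cholesky(_nearest_pd(st["phi_b"]) / P)
            st["alpha"] = theta.mean(axis=0) + chol @ rng.standard_normal(theta.shape[1])

            # level-2 covariance (componentwise random-walk MH)
            D = theta - st["alpha"]
            S6 = D.T @ D
            phi = st["phi_b"]
            ld, qf = _gauss_terms(phi, S6)
            for ij in m.free_phi_b:
                try_phi[ij] += 1
                prop = phi.copy()
                delta = steps[ij] * rng.standard_normal()
                prop[ij] += delta
                if ij[0] != ij[1]:
                    prop[ij[1], ij[0]] += delta
                terms = _gauss_terms(prop, S6)
                if terms is None:
                    continue
                ld_new, qf_new = terms
                logr = -0.5 * (P * (ld_new - ld) + (qf_new - qf))
                if np.log(rng.random()) < logr:
                    phi = prop
                    ld, qf = ld_new, qf_new
                    acc_phi[ij] += 1
            st["phi_b"] = phi
            if it < warmup and (it + 1) % 50 == 0:
                for ij in m.free_phi_b:
                    rate = acc_phi[ij] / max(try_phi[ij], 1)
                    steps[ij] *= float(np.exp(np.clip(rate - 0.44, -0.5, 0.5)))
                    acc_phi[ij] = try_phi[ij] = 0

            # structural model
            X, _ = self._design(theta)
            k = X.shape[1]
            prec = X.T @ X / st["tau2z"] + np.eye(k) / self.b_prior_sd**2
            cov = np.linalg.inv(prec)
            mean = cov @ (X.T @ self.z) / st["tau2z"]
            st["b"] = mean + np.linalg.cholesky(cov) @ rng.standard_normal(k)
            rss = float(np.sum((self.z - X @ st["b"]) ** 2))
            st["tau2z"] = 1.0 / rng.gamma(0.001 + P / 2, 1.0 / (0.001 + rss / 2))

            # level-1 covariance
            self._update_phi_w(st, rng)

            if it >= warmup:
                for j, i in enumerate(m.struct_idx):
                    rec[f"b{i}"][kept] = st["b"][j]
                for ij in m.free_phi_b:
                    rec[m.phi_b_labels[ij]][kept] = st["phi_b"][ij]
                rec["tau2_z"][kept] = st["tau2z"]
                rec["sigma2_x"][kept] = st["s2x"]
                if m.univariate:
                    rec["sigma2_y"][kept] = st["s2y"]
                else:
                    rec["sigma2_u"][kept] = st["s2u"]
                    rec["sigma2_y"][kept] = st["Sw"][0, 0]
                    rec["sigma2_v"][kept] = st["Sw"][1, 1]
                    rec["sigma_yv"][kept] = st["Sw"][0, 1]
                kept += 1

        return rec, acc_beta / max(tot_beta, 1), float(
            np.mean([acc_phi[ij] / max(try_phi[ij], 1) for ij in m.free_phi_b])
        )

    # -- conditional updates (univariate) ----------------------------------

    def _update_means_uni(self, st, rng) -> None:
        T, S = self.T, self.S
        beta = st["theta"][:, 2]
        phi = st["phi_b"]
        sig_bb = phi[:2, :2]
        sig_bs = phi[:2, 2]
        v_s = phi[2, 2]
        gain = sig_bs / v_s
        cond = sig_bb - np.outer(sig_bs, sig_bs) / v_s
        prior_prec = np.linalg.inv(_nearest_pd(cond))
        prior_mean = st["alpha"][:2] + np.outer(beta - st["alpha"][2], gain)

        s2x, s2y = st["s2x"], st["s2y"]
        prec = np.empty((self.P, 2, 2))
        prec[:, 0, 0] = T / s2x + T * beta**2 / s2y
        prec[:, 0, 1] = prec[:, 1, 0] = -T * beta / s2y
        prec[:, 1, 1] = T / s2y
        prec += prior_prec
        dy = S["y"] - beta * S["x"]
        lin = np.empty((self.P, 2))
        lin[:, 0] = S["x"] / s2x - beta * dy / s2y
        lin[:, 1] = dy / s2y
        lin += prior_mean @ prior_prec
        cov = np.linalg.inv(prec)
        mean = np.einsum("pab,pb->pa", cov, lin)
        L = np.linalg.cholesky(cov)
        st["theta"][:, :2] = mean + np.einsum(
            "pab,pb->pa", L, rng.standard_normal((self.P, 2))
        )

    def _update_beta_uni(self, st, rng):
        T, S = self.T, self.S
        theta = st["theta"]
        x_b, y_b = theta[:, 0], theta[:, 1]
        phi = st["phi_b"]
        sig_bb = phi[:2, :2]
        sig_bs = phi[:2, 2]
        v_s = phi[2, 2]
        gain = np.linalg.solve(_nearest_pd(sig_bb), sig_bs)
        cond_var = max(v_s - sig_bs @ gain, 1e-10)
        prior_mean = st["alpha"][2] + (theta[:, :2] - st["alpha"][:2]) @ gain

        sxx_c = S["xx"] - 2 * x_b * S["x"] + T * x_b**2
        sxy_c = S["xy"] - x_b * S["y"] - y_b * S["x"] + T * x_b * y_b
        prec = 1.0 / cond_var + sxx_c / st["s2y"]
        mean = (prior_mean / cond_var + sxy_c / st["s2y"]) / prec
        prop = mean + rng.standard_normal(self.P) / np.sqrt(prec)

        ll_new = self._z_loglik(prop[:, None], st)
        ll_old = self._z_loglik(theta[:, 2:3], st)
        take = np.log(rng.random(self.P)) < ll_new - ll_old
        theta[take, 2] = prop[take]
        return int(take.sum()), self.P

    # -- conditional updates (bivariate) ------------------------------------

    def _update_means_bi(self, st, rng) -> None:
        T, S = self.T, self.S
        theta = st["theta"]
        beta = theta[:, 4:6]
        phi = st["phi_b"]
        sig_bb = phi[:4, :4]
        sig_bs = phi[:4, 4:6]
        sig_ss = phi[4:6, 4:6]
        gain = np.linalg.solve(_nearest_pd(sig_ss), sig_bs.T).T  # (4, 2)
        cond = sig_bb - gain @ sig_ss @ gain.T
        prior_prec = np.linalg.inv(_nearest_pd(cond))
        prior_mean = st["alpha"][:4] + (beta - st["alpha"][4:6]) @ gain.T

        s2x, s2u = st["s2x"], st["s2u"]
        Sinv = np.linalg.inv(_nearest_pd(st["Sw"]))
        p11, p12, p22 = Sinv[0, 0], Sinv[0, 1], Sinv[1, 1]
        by, bv = beta[:, 0], beta[:, 1]
        prec = np.zeros((self.P, 4, 4))
        prec[:, 0, 0] = 1.0 / s2x + by**2 * p11
        prec[:, 0, 1] = prec[:, 1, 0] = by * bv * p12
        prec[:, 0, 2] = prec[:, 2, 0] = -by * p11
        prec[:, 0, 3] = prec[:, 3, 0] = -by * p12
        prec[:, 1, 1] = 1.0 / s2u + bv**2 * p22
        prec[:, 1, 2] = prec[:, 2, 1] = -bv * p12
        prec[:, 1, 3] = prec[:, 3, 1] = -bv * p22
        prec[:, 2, 2] = p11
        prec[:, 2, 3] = prec[:, 3, 2] = p12
        prec[:, 3, 3] = p22
        prec *= T[:, None, None]
        prec += prior_prec

        dy = S["y"] - by * S["x"]
        dv = S["v"] - bv * S["u"]
        e_y = p11 * dy + p12 * dv
        e_v = p12 * dy + p22 * dv
        lin = np.empty((self.P, 4))
        lin[:, 0] = S["x"] / s2x - by * e_y
        lin[:, 1] = S["u"] / s2u - bv * e_v
        lin[:, 2] = e_y
        lin[:, 3] = e_v
        lin += prior_mean @ prior_prec
        cov = np.linalg.inv(prec)
        mean = np.einsum("pab,pb->pa", cov, lin)
        L = np.linalg.cholesky(cov)
        theta[:, :4] = mean + np.einsum(
            "pab,pb->pa", L, rng.standard_normal((self.P, 4))
        )

    def _update_beta_bi(self, st, rng):
        T, S = self.T, self.S
        theta = st["theta"]
        x_b, u_b, y_b, v_b = (theta[:, j] for j in range(4))
        phi = st["phi_b"]
        sig_bb = phi[:4, :4]
        sig_bs = phi[:4, 4:6]
        sig_ss = phi[4:6, 4:6]
        gain = np.linalg.solve(_nearest_pd(sig_bb), sig_bs).T  # (2, 4)
        cond = _nearest_pd(sig_ss - gain @ sig_bb @ gain.T)
        prior_prec = np.linalg.inv(cond)
        prior_mean = st["alpha"][4:6] + (theta[:, :4] - st["alpha"][:4]) @ gain.T

        Sinv = np.linalg.inv(_nearest_pd(st["Sw"]))
        p11, p12, p22 = Sinv[0, 0], Sinv[0, 1], Sinv[1, 1]
        sxx = S["xx"] - 2 * x_b * S["x"] + T * x_b**2
        suu = S["uu"] - 2 * u_b * S["u"] + T * u_b**2
        sxu = S["ux"] - x_b * S["u"] - u_b * S["x"] + T * x_b * u_b
        sxy = S["xy"] - x_b * S["y"] - y_b * S["x"] + T * x_b * y_b
        sxv = S["vx"] - x_b * S["v"] - v_b * S["x"] + T * x_b * v_b
        suy = S["uy"] - u_b * S["y"] - y_b * S["u"] + T * u_b * y_b
        suv = S["uv"] - u_b * S["v"] - v_b * S["u"] + T * u_b * v_b

        prec = np.empty((self.P, 2, 2))
        prec[:, 0, 0] = p11 * sxx
        prec[:, 0, 1] = prec[:, 1, 0] = p12 * sxu
        prec[:, 1, 1] = p22 * suu
        prec += prior_prec
        lin = np.empty((self.P, 2))
        lin[:, 0] = p11 * sxy + p12 * sxv
        lin[:, 1] = p12 * suy + p22 * suv
        lin += prior_mean @ prior_prec
        cov = np.linalg.inv(prec)
        mean = np.einsum("pab,pb->pa", cov, lin)
        L = np.linalg.cholesky(cov)
        prop = mean + np.einsum("pab,pb->pa", L, rng.standard_normal((self.P, 2)))

        ll_new = self._z_loglik(prop, st)
        ll_old = self._z_loglik(theta[:, 4:6], st)
        take = np.log(rng.random(self.P)) < ll_new - ll_old
        theta[take, 4:6] = prop[take]
        return int(take.sum()), self.P

    def _z_loglik(self, beta: np.ndarray, st) -> np.ndarray:
        if self.model.univariate:
            X, _ = build_design(beta[:, 0], None, self.model.kind)
        else:
            X, _ = build_design(beta[:, 0], beta[:, 1], self.model.kind)
        mu = X @ st["b"]
        return -0.5 * (self.z - mu) ** 2 / st["tau2z"]

    def _update_phi_w(self, st, rng) -> None:
        T, S, N = self.T, self.S, self.N
        theta = st["theta"]
        x_b = theta[:, 0]
        sxx_c = (S["xx"] - 2 * x_b * S["x"] + T * x_b**2).sum()
        st["s2x"] = 1.0 / rng.gamma(0.001 + N / 2, 1.0 / (0.001 + sxx_c / 2))
        if self.model.univariate:
            y_b, beta = theta[:, 1], theta[:, 2]
            syy_c = S["yy"] - 2 * y_b * S["y"] + T * y_b**2
            sxy_c = S["xy"] - x_b * S["y"] - y_b * S["x"] + T * x_b * y_b
            sxx_ci = S["xx"] - 2 * x_b * S["x"] + T * x_b**2
            rss = (syy_c - 2 * beta * sxy_c + beta**2 * sxx_ci).sum()
            st["s2y"] = 1.0 / rng.gamma(0.001 + N / 2, 1.0 / (0.001 + rss / 2))
            return
        u_b, y_b, v_b = theta[:, 1], theta[:, 2], theta[:, 3]
        by, bv = theta[:, 4], theta[:, 5]
        suu_c = (S["uu"] - 2 * u_b * S["u"] + T * u_b**2).sum()
        st["s2u"] = 1.0 / rng.gamma(0.001 + N / 2, 1.0 / (0.001 + suu_c / 2))

        sxx_ci = S["xx"] - 2 * x_b * S["x"] + T * x_b**2
        suu_ci = S["uu"] - 2 * u_b * S["u"] + T * u_b**2
        sxu_ci = S["ux"] - x_b * S["u"] - u_b * S["x"] + T * x_b * u_b
        syy_c = S["yy"] - 2 * y_b * S["y"] + T * y_b**2
        svv_c = S["vv"] - 2 * v_b * S["v"] + T * v_b**2
        syv_c = S["vy"] - y_b * S["v"] - v_b * S["y"] + T * y_b * v_b
        sxy_c = S["xy"] - x_b * S["y"] - y_b * S["x"] + T * x_b * y_b
        sxv_c = S["vx"] - x_b * S["v"] - v_b * S["x"] + T * x_b * v_b
        suy_c = S["uy"] - u_b * S["y"] - y_b * S["u"] + T * u_b * y_b
        suv_c = S["uv"] - u_b * S["v"] - v_b * S["u"] + T * u_b * v_b

        r_yy = (syy_c - 2 * by * sxy_c + by**2 * sxx_ci).sum()
        r_vv = (svv_c - 2 * bv * suv_c + bv**2 * suu_ci).sum()
        r_yv = (syv_c - bv * suy_c - by * sxv_c + by * bv * sxu_ci).sum()
        scale = np.array([[r_yy, r_yv], [r_yv, r_vv]]) + 1e-3 * np.eye(2)
        st["Sw"] = stats.invwishart.rvs(df=3 + N, scale=scale, random_state=rng)


def _gauss_terms(phi: np.ndarray, S: np.ndarray):
    """(logdet, trace(phi^-1 S)) via Cholesky; None when phi is not PD."""
    try:
        L = np.linalg.cholesky(phi)
    except np.linalg.LinAlgError:
        return None
    ld = 2.0 * float(np.sum(np.log(np.diag(L))))
    Y = np.linalg.solve(L, S)
    X = np.linalg.solve(L.T, Y)  # phi^-1 S  (via L L' X = S)
    return ld, float(np.trace(X))


def _nearest_pd(mat: np.ndarray, eps: float = 1e-10) -> np.ndarray:
    """Clip tiny negative eigenvalues so Cholesky-based draws succeed."""
    mat = (mat + mat.T) / 2.0
    try:
        np.linalg.cholesky(mat)
        return mat
    except np.linalg.LinAlgError:
        w, V = np.linalg.eigh(mat)
        w = np.clip(w, eps, None)
        return V @ np.diag(w) @ V.T


def _diagnostics(draws: dict):
    import arviz as az

    rhat, ess = {}, {}
    for name, arr in draws.items():
        if arr.shape[0] == 1:  # split a single chain into halves
            half = arr.shape[1] // 2
            arr = np.stack([arr[0, :half], arr[0, half : 2 * half]])
        if np.std(arr) == 0:
            rhat[name] = 1.0
            ess[name] = float(arr.size)
            continue
        ds = az.convert_to_dataset(arr)
        rhat[name] = float(az.rhat(ds)["x"].values)
        ess[name] = float(az.ess(ds)["x"].values)
    return rhat, ess


def fit_msem(
    data: TwoLevelData, kind: str, seed: int | None = None, **kwargs
) -> MsemResults:
    """Convenience wrapper mirroring :class:`LatentSlopeMSEM`."""
    return LatentSlopeMSEM(data, kind, **kwargs).fit(seed=seed)
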