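"""Random-intercept/random-slope linear mixed model with EAP slope predictions.

This is the shared step 1 of the two-step, single-indicator and
plausible-values estimators: person-mean centering of the level-1 predictor,
restricted maximum likelihood (REML) estimation of the variance components,
and empirical-Bayes (EAP / BLUP) prediction of each person's slope together
with its conditional standard deviation.

The model for outcome ``y`` with centered predictor ``xC`` is

    y_it   = iota_i + c_i * xC_it + R_it,          R ~ N(0, sigma2)
    iota_i = g00 + g01 * xbar_i [+ g02*z + g03*xbar*z] + U0_i
    c_i    = g10 [+ g11*z] + U1_i,                 (U0, U1) ~ MVN(0, G)

The optional person-level covariate terms in brackets are used by the
plausible-values approach, which conditions the slope distribution on the
outcome ``z`` before drawing plausible values.

The solver profiles out the residual variance and the fixed effects and
optimizes the three free elements of the scaled random-effect Cholesky
factor.  Because the random-effect design per person is just ``[1, xC]``,
all quantities reduce to per-person 2x2 sufficient statistics, which makes a
fit run in milliseconds — fast enough for Monte-Carlo studies with
thousands of replications.  Estimates agree with general-purpose mixed-model
software (see the test suite, which cross-checks against statsmodels
MixedLM).

EAP predictions and conditional SDs are computed from the conditional
distribution of the random effects at the REML estimates; uncertainty in the
fixed effects and variance components is deliberately not propagated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize

from .data import TwoLevelData


def person_center(data: TwoLevelData, variable: str) -> tuple[pd.Series, pd.Series]:
    """Center a level-1 variable at the person means.

    Returns the centered values (aligned with ``data.level1``) and the
    person means indexed by id.  Means are taken over the available
    occasions, so unbalanced designs are handled naturally.
    """
    if variable not in data.level1.columns:
        raise ValueError(f"variable {variable!r} not in level-1 data")
    values = data.level1[variable]
    if values.isna().groupby(data.level1["id"]).all().any():
        raise ValueError("a person has no non-missing values")
    means = values.groupby(data.level1["id"]).transform("mean")
    person_means = values.groupby(data.level1["id"]).mean()
    return values - means, person_means


@dataclass
class SlopeFit:
    """Results of the random-slope model.

    Attributes
    ----------
    ids : ndarray
        Person identifiers, aligned with the per-person arrays.
    eap_slope, cond_sd, eap_intercept : ndarray
        EAP prediction of each person's slope / intercept and the
        conditional posterior SD of the slope.
    fixed_effects : dict
        Named fixed-effect estimates (g00, g01, g10, and the primed
        covariate terms when present).
    cov_re : ndarray
        2x2 covariance of the random intercept and slope.
    sigma2 : float
        Level-1 residual variance.
    """

    ids: np.ndarray
    eap_slope: np.ndarray
    cond_sd: np.ndarray
    eap_intercept: np.ndarray
    fixed_effects: dict
    fe_cov: np.ndarray
    cov_re: np.ndarray
    sigma2: float
    person_means: np.ndarray
    converged: bool
    boundary: bool
    reml: float
    n_persons: int = 0

    def __post_init__(self) -> None:
        self.n_persons = len(self.ids)

    @property
    def slope_variance(self) -> float:
        return float(self.cov_re[1, 1])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"id": self.ids, "eap": self.eap_slope, "cond_sd": self.cond_sd}
        )

    def to_json(self) -> dict:
        """Fixed effects and variance components as a JSON-ready dict."""
        return {
            "fixed_effects": {k: float(v) for k, v in self.fixed_effects.items()},
            "cov_re": self.cov_re.tolist(),
            "sigma2": float(self.sigma2),
            "converged": bool(self.converged),
            "boundary": bool(self.boundary),
            "n_persons": int(self.n_persons),
        }

    def summary(self) -> str:
        fe = "\n".join(f"  {k:>10s} {v: .4f}" for k, v in self.fixed_effects.items())
        return (
            "Random-slope model (REML)\n"
            f"persons: {self.n_persons}   converged: {self.converged}"
            f"   boundary: {self.boundary}\n"
            f"fixed effects:\n{fe}\n"
            f"Var(U0)={self.cov_re[0, 0]:.4f}  Var(U1)={self.cov_re[1, 1]:.4f}  "
            f"Cov={self.cov_re[0, 1]:.4f}  Var(R)={self.sigma2:.4f}\n"
        )


class RandomSlopeModel:
    """Two-level random-intercept + random-slope model.

    Parameters
    ----------
    data : TwoLevelData
    l1_outcome, l1_predictor : str
        Level-1 column names; the predictor is person-mean centered
        internally.
    l2_covariates : sequence of str
        Person-level columns (from ``data.level2``) entering the intercept
        equation (together with their product with the person mean) and the
        slope equation.  The plausible-values step 1 passes ``["z"]``.
    """

    def __init__(
        self,
        data: TwoLevelData,
        l1_outcome: str,
        l1_predictor: str,
        l2_covariates: tuple[str, ...] = (),
    ) -> None:
        self.data = data
        self.l1_outcome = l1_outcome
        self.l1_predictor = l1_predictor
        self.l2_covariates = tuple(l2_covariates)
        self._prepare()

    def _prepare(self) -> None:
        d = self.data
        xc, xbar = person_center(d, self.l1_predictor)
        df = d.level1
        ids = df["id"].to_numpy()
        uids, idx = np.unique(ids, return_inverse=True)
        P = len(uids)
        y = df[self.l1_outcome].to_numpy(dtype=float)
        xc = xc.to_numpy(dtype=float)

        # per-person sufficient statistics for Z_i = [1, xC]
        T = np.bincount(idx, minlength=P).astype(float)
        sx = np.bincount(idx, weights=xc, minlength=P)
        sxx = np.bincount(idx, weights=xc * xc, minlength=P)
        sy = np.bincount(idx, weights=y, minlength=P)
        sxy = np.bincount(idx, weights=xc * y, minlength=P)
        syy = np.bincount(idx, weights=y * y, minlength=P)

        K = np.empty((P, 2, 2))
        K[:, 0, 0] = T
        K[:, 0, 1] = K[:, 1, 0] = sx
        K[:, 1, 1] = sxx
        k = np.stack([sy, sxy], axis=1)

        # fixed-effect design in "cell" form X_i = Z_i @ C_i
        l2 = d.level2.set_index("id").loc[uids]
        xbar = xbar.loc[uids].to_numpy(dtype=float)
        icols = [np.ones(P), xbar]
        inames = ["g00", "g01"]
        scols = [np.ones(P)]
        snames = ["g10"]
        for name in self.l2_covariates:
            w = l2[name].to_numpy(dtype=float)
            icols += [w, xbar * w]
            inames += [f"g0_{name}", f"g0_{name}:xbar"]
            scols += [w]
            snames += [f"g1_{name}"]
        p = len(icols) + len(scols)
        C = np.zeros((P, 2, p))
        for j, col in enumerate(icols):
            C[:, 0, j] = col
        for j, col in enumerate(scols):
            C[:, 1, len(icols) + j] = col

        self._uids, self._P, self._p = uids, P, p
        self._K, self._k, self._syy, self._T = K, k, syy, T
        self._C = C
        self._xbar = xbar
        self._fe_names = inames + snames
        self._n = float(T.sum())

    # -- profiled REML -----------------------------------------------------

    @staticmethod
    def _chol(theta: np.ndarray) -> np.ndarray:
        L = np.zeros((2, 2))
        L[0, 0] = np.exp(theta[0])
        L[1, 1] = np.exp(theta[1])
        L[1, 0] = theta[2]
        return L

    def _pieces(self, L: np.ndarray):
        """Per-person M = Z'V~^-1 Z, m = Z'V~^-1 y, q = y'V~^-1 y and log|V~|
        for V~ = I + Z (LL') Z' (residual variance profiled to 1)."""
        K, k = self._K, self._k
        # W = (G~^-1 + K)^-1 = L (I + L'KL)^-1 L'
        LtKL = np.einsum("ab,pbc,cd->pad", L.T, K, L)
        A = LtKL + np.eye(2)
        det = A[:, 0, 0] * A[:, 1, 1] - A[:, 0, 1] * A[:, 1, 0]
        logdet = np.log(det)
        Ainv = np.empty_like(A)
        Ainv[:, 0, 0] = A[:, 1, 1]
        Ainv[:, 1, 1] = A[:, 0, 0]
        Ainv[:, 0, 1] = -A[:, 0, 1]
        Ainv[:, 1, 0] = -A[:, 1, 0]
        Ainv /= det[:, None, None]
        W = np.einsum("ab,pbc,cd->pad", L, Ainv, L.T)
        KW = np.einsum("pab,pbc->pac", K, W)
        M = K - np.einsum("pab,pbc->pac", KW, K)
        m = k - np.einsum("pab,pb->pa", KW, k)
        q = self._syy - np.einsum("pa,pab,pb->p", k, W, k)
        return M, m, q, logdet, W

    def _moment_start(self) -> np.ndarray:
        """Method-of-moments starting values from per-person OLS fits.

        The predictor is person-mean centered, so each person's Z'Z is
        diagonal and the per-person regressions have closed forms.
        """
        T = self._T
        sxx = np.maximum(self._K[:, 1, 1], 1e-10)
        sy, sxy = self._k[:, 0], self._k[:, 1]
        ols = sxy / sxx
        rss = np.maximum(self._syy - sy**2 / T - sxy**2 / sxx, 0.0)
        s2 = max(rss.sum() / max((T - 2).sum(), 1.0), 1e-8)
        tau_slope = max(np.var(ols) - s2 * np.mean(1.0 / sxx), 0.01 * s2)
        tau_int = max(np.var(sy / T) - s2 * np.mean(1.0 / T), 0.01 * s2)
        return np.array(
            [0.5 * np.log(tau_int / s2), 0.5 * np.log(tau_slope / s2), 0.0]
        )

    def _objective(self, theta: np.ndarray) -> float:
        L = self._chol(theta)
        M, m, q, logdet, _ = self._pieces(L)
        C = self._C
        F = np.einsum("pia,pij,pjb->ab", C, M, C)
        f = np.einsum("pia,pi->a", C, m)
        sign, logdetF = np.linalg.slogdet(F)
        if sign <= 0:
            return 1e12
        try:
            gamma = np.linalg.solve(F, f)
        except np.linalg.LinAlgError:
            return 1e12
        qtot = q.sum() - f @ gamma
        if qtot <= 0:
            return 1e12
        ndof = self._n - self._p
        return float(logdet.sum() + logdetF + ndof * np.log(qtot))

    def fit(self, start: np.ndarray | None = None) -> SlopeFit:
        if start is None:
            start = self._moment_start()
        res = optimize.minimize(
            self._objective, start, method="BFGS", options={"gtol": 1e-6}
        )
        # status 2 is "precision loss" from the numerical gradient at the
        # optimum; accept it when the gradient is small, else polish
        converged = bool(res.success) or (
            getattr(res, "status", None) == 2
            and np.linalg.norm(res.jac) < 1.0
        )
        if not converged:
            res = optimize.minimize(
                self._objective, res.x, method="Nelder-Mead",
                options={"xatol": 1e-7, "fatol": 1e-9, "maxiter": 2000},
            )
            converged = bool(res.success)
        theta = res.x
        L = self._chol(theta)
        M, m, q, logdet, W = self._pieces(L)
        C = self._C
        F = np.einsum("pia,pij,pjb->ab", C, M, C)
        f = np.einsum("pia,pi->a", C, m)
        gamma = np.linalg.solve(F, f)
        ndof = self._n - self._p
        sigma2 = float((q.sum() - f @ gamma) / ndof)
        Gtil = L @ L.T
        G = sigma2 * Gtil

        # EAP and conditional covariance at the REML estimates
        Cg = np.einsum("pia,a->pi", C, gamma)  # per-person fixed (iota, slope)
        Zr = self._k - np.einsum("pab,pb->pa", self._K, Cg)
        t1 = Zr - np.einsum("pab,pbc,pc->pa", self._K, W, Zr)
        u = np.einsum("ab,pb->pa", Gtil, t1)
        cond = sigma2 * (
            Gtil - np.einsum("ab,pbc,cd->pad", Gtil, M, Gtil)
        )
        cond_sd = np.sqrt(np.maximum(cond[:, 1, 1], 0.0))

        eigs = np.linalg.eigvalsh(Gtil)
        boundary = bool(eigs.min() < 1e-8 * max(eigs.max(), 1e-12))
        fe = dict(zip(self._fe_names, gamma))
        return SlopeFit(
            ids=self._uids,
            eap_slope=Cg[:, 1] + u[:, 1],
            cond_sd=cond_sd,
            eap_intercept=Cg[:, 0] + u[:, 0],
            fixed_effects=fe,
            fe_cov=sigma2 * np.linalg.inv(F),
            cov_re=G,
            sigma2=sigma2,
            person_means=self._xbar,
            converged=converged,
            boundary=boundary,
            reml=float(res.fun),
        )


def fit_random_slope_model(
    data: TwoLevelData,
    l1_outcome: str,
    l1_predictor: str,
    l2_covariates: tuple[str, ...] = (),
) -> SlopeFit:
    """Convenience wrapper: construct and fit a :class:`RandomSlopeModel`."""
    return RandomSlopeModel(data, l1_outcome, l1_predictor, l2_covariates).fit()
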