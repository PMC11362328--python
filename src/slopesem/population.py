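"""Population model and simulator for two-level data with latent random slopes.

The generating model decomposes each repeatedly measured variable into a
latent person mean and a within-person fluctuation.  Momentary well-being
``y`` responds to fluctuations of the level-1 predictor ``x`` with a
person-specific slope ``beta_y`` (the within-person association, WPA), and
analogously ``v`` responds to ``u`` with slope ``beta_v``.  The person-level
outcome ``z`` is a second-order polynomial in the latent slopes:

    z_i = b0 + b1*beta_y + b2*beta_v + b3*beta_y^2 + b4*beta_y*beta_v
          + b5*beta_v^2 + zeta_z

Special cases of the polynomial encode the three hypotheses of interest:
a quadratic (U-shape) effect of one slope, an interaction (moderation)
effect of two slopes, and a congruence effect, where the coefficients
satisfy b1 = b2 = 0, b5 = b3 < 0, b4 = -2*b3 so that z is maximal along the
line beta_y = beta_v.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .data import TwoLevelData

HYPOTHESES = ("ushape", "moderation", "congruence", "null")

# Index order of the level-2 covariance Phi_B: latent person means of
# (x, u, y, v), the two slopes, and the z residual.
PHI_B_NAMES = ("x_b", "u_b", "y_b", "v_b", "beta_y", "beta_v", "zeta_z")
PHI_W_NAMES = ("x_w", "u_w", "zeta_y", "zeta_v")

#: coefficients printed to one decimal in the source simulation study,
#: keyed by (hypothesis, r2_target) -> headline coefficient value
_PRINTED_COEFFICIENTS = {
    ("ushape", 0.25): -4.1,
    ("ushape", 0.09): -2.2,
    ("moderation", 0.25): -5.7,
    ("moderation", 0.09): -3.1,
    ("congruence", 0.25): -2.5,
    ("congruence", 0.09): -1.4,
}


def implied_slope_reliability(
    tau2_beta: float, sigma2_resid: float, sigma2_xw: float, T: int
) -> float:
    """Reliability of person-specific slope estimates in a balanced design.

    The sampling variance of a per-person least-squares slope is
    ``sigma2_resid / ((T - 1) * sigma2_xw)`` (the predictor is centered
    within person, which costs one degree of freedom), so the reliability is

        tau2_beta / (tau2_beta + sigma2_resid / ((T - 1) * sigma2_xw))

    With slope variance 0.1, unit residual and predictor variances this
    gives .80 at T = 40 and .58 at T = 15.
    """
    if T < 3:
        raise ValueError("need at least T = 3 occasions")
    if tau2_beta <= 0 or sigma2_xw <= 0 or sigma2_resid < 0:
        raise ValueError("variances must be positive")
    err = sigma2_resid / ((T - 1) * sigma2_xw)
    return tau2_beta / (tau2_beta + err)


def implied_icc(
    tau2_between: float, tau2_beta: float, sigma2_xw: float, sigma2_resid: float
) -> float:
    """Intraclass correlation of a level-1 outcome under the slope model.

    Total variance decomposes into the between-person part ``tau2_between``
    and the within part ``tau2_beta * sigma2_xw + sigma2_resid`` (slope
    heterogeneity inflates within-person variance because the slopes have
    zero mean in the population model).
    """
    if min(tau2_between, tau2_beta, sigma2_xw, sigma2_resid) < 0:
        raise ValueError("variances must be non-negative")
    denom = tau2_between + tau2_beta * sigma2_xw + sigma2_resid
    if denom == 0:
        raise ValueError("all variance components are zero")
    return tau2_between / denom


def calibrate_effect(
    hypothesis: str,
    r2_target: float,
    slope_cov: np.ndarray | float,
    tau2_z: float = 1.0,
    paper_values: bool = False,
) -> np.ndarray:
    """Solve for the polynomial coefficients that explain ``r2_target``.

    Under zero-mean normal slopes with covariance ``slope_cov`` the
    nonlinear terms have closed-form variances::

        Var(beta^2)            = 2 * tau^4
        Var(beta_y * beta_v)   = tau_y^2 * tau_v^2 + cov^2
        Var((beta_y-beta_v)^2) = 2 * (tau_y^2 + tau_v^2 - 2*cov)^2

    and the headline coefficient is the negative root of
    ``coef^2 * V / (coef^2 * V + tau2_z) = r2_target``.

    Parameters
    ----------
    hypothesis : {"ushape", "moderation", "congruence", "null"}
    r2_target : float
        Proportion of level-2 outcome variance explained, in [0, 1).
    slope_cov : float or (2, 2) array
        Latent slope variance (ushape) or slope covariance matrix.
    tau2_z : float
        Residual variance of the outcome.
    paper_values : bool
        If True, substitute the one-decimal coefficients used verbatim in
        the source simulation study (replication mode) where available.

    Returns
    -------
    numpy.ndarray
        Length-6 coefficient vector (b0, b1, b2, b3, b4, b5).
    """
    if hypothesis not in HYPOTHESES:
        raise ValueError(f"unknown hypothesis {hypothesis!r}")
    if not 0 <= r2_target < 1:
        raise ValueError("r2_target must be in [0, 1)")
    if tau2_z <= 0:
        raise ValueError("tau2_z must be positive")

    b = np.zeros(6)
    if hypothesis == "null" or r2_target == 0:
        return b

    cov = np.atleast_2d(np.asarray(slope_cov, dtype=float))
    if cov.shape == (1, 1):
        cov = np.diag([cov[0, 0], cov[0, 0]])
    if cov.shape != (2, 2):
        raise ValueError("slope_cov must be scalar or 2x2")
    if np.linalg.eigvalsh(cov).min() <= 0:
        raise ValueError("slope_cov must be positive definite")
    ty2, tv2, c = cov[0, 0], cov[1, 1], cov[0, 1]

    if hypothesis == "ushape":
        var_term = 2.0 * ty2**2
    elif hypothesis == "moderation":
        var_term = ty2 * tv2 + c**2
    else:  # congruence: z = b3 * (beta_y - beta_v)^2 + residual
        var_term = 2.0 * (ty2 + tv2 - 2.0 * c) ** 2

    coef = -math.sqrt(r2_target / (1.0 - r2_target) * tau2_z / var_term)
    if paper_values:
        printed = _PRINTED_COEFFICIENTS.get((hypothesis, round(r2_target, 2)))
        if printed is not None:
            coef = printed

    if hypothesis == "ushape":
        b[3] = coef
    elif hypothesis == "moderation":
        b[4] = coef
    else:
        b[3] = coef
        b[4] = -2.0 * coef
        b[5] = coef
    return b


def _default_phi_w() -> np.ndarray:
    phi = np.eye(4)
    phi[2, 3] = phi[3, 2] = 0.2  # level-1 residual covariance sigma_yv
    return phi


def _default_phi_b() -> np.ndarray:
    phi = np.zeros((7, 7))
    np.fill_diagonal(phi, [1.0, 1.0, 1.1, 1.1, 0.1, 0.1, 1.0])
    pairs = {  # correlations of .20 throughout
        (0, 2): 0.21,  # tau_xy
        (1, 3): 0.21,  # tau_uv
        (2, 3): 0.22,  # tau_yv
        (2, 4): 0.07,  # tau_y,beta_y
        (3, 5): 0.07,  # tau_v,beta_v
        (4, 5): 0.02,  # tau_beta_y,beta_v
    }
    for (i, j), v in pairs.items():
        phi[i, j] = phi[j, i] = v
    return phi


@dataclass
class PopulationSpec:
    """Complete description of a simulation condition.

    Defaults reproduce the study conditions of the simulation design this
    simulator emulates: unit level-1 variances, slope variances of 0.1,
    ICCs of .5, correlations of .20 among the nonzero level-2 covariances.
    """

    P: int = 200
    T: int | np.ndarray = 15
    hypothesis: str = "ushape"
    r2_target: float = 0.25
    b: np.ndarray | None = None
    phi_w: np.ndarray = field(default_factory=_default_phi_w)
    phi_b: np.ndarray = field(default_factory=_default_phi_b)
    alphas: np.ndarray = field(default_factory=lambda: np.zeros(6))
    seed: int | None = None
    paper_values: bool = False
    keep_truth: bool = True

    def __post_init__(self) -> None:
        if self.hypothesis not in HYPOTHESES:
            raise ValueError(f"unknown hypothesis {self.hypothesis!r}")
        self.phi_w = np.asarray(self.phi_w, dtype=float)
        self.phi_b = np.asarray(self.phi_b, dtype=float)
        for name, m in (("phi_w", self.phi_w), ("phi_b", self.phi_b)):
            if not np.allclose(m, m.T):
                raise ValueError(f"{name} must be symmetric")
            if np.linalg.eigvalsh(m).min() < -1e-10:
                raise ValueError(f"{name} must be positive semi-definite")
        if self.b is None:
            self.b = calibrate_effect(
                self.hypothesis,
                self.r2_target,
                self.slope_cov,
                self.tau2_z,
                paper_values=self.paper_values,
            )
        self.b = np.asarray(self.b, dtype=float)

    @property
    def slope_cov(self) -> np.ndarray:
        return self.phi_b[np.ix_([4, 5], [4, 5])]

    @property
    def tau2_z(self) -> float:
        return float(self.phi_b[6, 6])

    @property
    def bivariate(self) -> bool:
        return self.hypothesis != "ushape"

    def with_(self, **kwargs) -> "PopulationSpec":
        """Return a copy with fields replaced (b is re-calibrated unless given)."""
        if not {"b", "r2_target", "hypothesis"}.isdisjoint(kwargs) and "b" not in kwargs:
            kwargs.setdefault("b", None)
        return replace(self, **kwargs)


def simulate(spec: PopulationSpec, seed: int | None = None) -> TwoLevelData:
    """Generate a :class:`TwoLevelData` sample from the population model.

    Level-2 deviations (person means, slopes, z residual) are drawn from
    ``MVN(0, phi_b)``, level-1 deviations per occasion from
    ``MVN(0, phi_w)``; the outcomes compose as ``y = y_B + beta_y*x_W + zeta``
    and ``z`` follows the level-2 polynomial.
    """
    if seed is None:
        seed = spec.seed
    rng = np.random.default_rng(seed)
    P = spec.P
    T = np.asarray(spec.T)
    if T.ndim == 0:
        T = np.full(P, int(T))
    if len(T) != P or (T < 2).any():
        raise ValueError("occasion counts must give every person at least 2 occasions")

    mean_b = np.concatenate([spec.alphas, [0.0]])
    l2 = rng.multivariate_normal(mean_b, spec.phi_b, size=P)
    x_b, u_b, y_b, v_b, beta_y, beta_v, zeta_z = l2.T

    b = spec.b
    z = (
        b[0]
        + b[1] * beta_y
        + b[2] * beta_v
        + b[3] * beta_y**2
        + b[4] * beta_y * beta_v
        + b[5] * beta_v**2
        + zeta_z
    )

    n = int(T.sum())
    ids = np.repeat(np.arange(P), T)
    occ = np.concatenate([np.arange(t) for t in T])
    l1 = rng.multivariate_normal(np.zeros(4), spec.phi_w, size=n)
    x_w, u_w, zeta_y, zeta_v = l1.T

    x = x_b[ids] + x_w
    y = y_b[ids] + beta_y[ids] * x_w + zeta_y
    level1 = {"id": ids, "t": occ, "x": x, "y": y}
    truth = {
        "id": np.arange(P),
        "x_b": x_b,
        "y_b": y_b,
        "beta_y": beta_y,
    }
    if spec.bivariate:
        u = u_b[ids] + u_w
        v = v_b[ids] + beta_v[ids] * u_w + zeta_v
        level1["u"] = u
        level1["v"] = v
        truth.update({"u_b": u_b, "v_b": v_b, "beta_v": beta_v})

    cols = ["id", "t", "x", "u", "y", "v"] if spec.bivariate else ["id", "t", "x", "y"]
    return TwoLevelData(
        level1=pd.DataFrame(level1)[cols],
        level2=pd.DataFrame({"id": np.arange(P), "z": z}),
        truth=pd.DataFrame(truth) if spec.keep_truth else None,
    )


def make_unbalanced(
    data: TwoLevelData,
    seed: int | None = None,
    max_prop: float = 0.6,
    beta_shape: tuple[float, float] = (1.5, 4.0),
) -> TwoLevelData:
    """Delete occasions at random to mimic an unbalanced diary design.

    Each person's deletion proportion is drawn from a positively skewed
    Beta(1.5, 4) distribution rescaled to [0, ``max_prop``]; with T = 40
    input the retained counts fall in [16, 40].  Deletions are occasion-wise
    at random and reproducible under ``seed``.
    """
    counts = data.occasion_counts()
    if (counts < 40).any():
        raise ValueError("unbalanced designs are derived from balanced T = 40 data")
    rng = np.random.default_rng(seed)
    keep_parts = []
    for pid, grp in data.level1.groupby("id", sort=True):
        prop = rng.beta(*beta_shape) * max_prop
        n_del = int(np.floor(prop * len(grp)))
        if n_del > 0:
            drop = rng.choice(len(grp), size=n_del, replace=False)
            keep = np.setdiff1d(np.arange(len(grp)), drop)
            keep_parts.append(grp.iloc[keep])
        else:
            keep_parts.append(grp)
    level1 = pd.concat(keep_parts, ignore_index=True)
    return TwoLevelData(level1=level1, level2=data.level2.copy(), truth=data.truth)
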