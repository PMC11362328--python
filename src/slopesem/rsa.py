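"""Response-surface analysis: auxiliary parameters and the congruence test.

A second-order polynomial surface ``z = b0 + b1*X + b2*Y + b3*X^2 + b4*X*Y
+ b5*Y^2`` is interpreted through six auxiliary parameters:

* ``a1 = b1 + b2`` and ``a2 = b3 + b4 + b5`` — slope and curvature of the
  surface along the line of congruence X = Y;
* ``a3 = b1 - b2`` and ``a4 = b3 - b4 + b5`` — slope and curvature along
  the line of incongruence X = -Y;
* ``p10`` and ``p11`` — intercept and slope of the first principal axis of
  the surface.

A strict congruence effect (outcome maximal where X = Y, falling off with
any discrepancy) holds exactly when ``a1 = a2 = a3 = p10 = 0``, ``p11 = 1``
and ``a4 < 0``; the decision rule tests these six conditions jointly, with
the first five required to be non-significant and the last significantly
negative.

Standard errors come from the multivariate delta method with analytic
gradients; Bayesian fits instead summarise the auxiliary parameters over
posterior draws.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

AUX_NAMES = ("a1", "a2", "a3", "a4", "p10", "p11")

_RIDGE_TOL = 1e-10


def vertex_x(b1: float, b3: float) -> float:
    """Stationary point -b1/(2*b3) of the quadratic model z = b0+b1*c+b3*c^2."""
    if b3 == 0:
        raise ValueError("no vertex: quadratic coefficient is zero")
    return -b1 / (2.0 * b3)


def aux_params(b: np.ndarray) -> dict:
    """Point values of the six auxiliary surface parameters.

    ``p11`` uses the "+sqrt" branch of the principal-axis equation (first
    principal axis), which equals 1 for a congruence-shaped surface.  On a
    ridge surface (degenerate stationary point, ``4*b3*b5 - b4^2`` at zero)
    ``p10`` is reported through its ridge limit ``-b1/b4`` and flagged.
    """
    b = np.asarray(b, dtype=float)
    if b.shape != (6,):
        raise ValueError("b must be the full 6-vector (b0..b5)")
    b0, b1, b2, b3, b4, b5 = b
    out = {
        "a1": b1 + b2,
        "a2": b3 + b4 + b5,
        "a3": b1 - b2,
        "a4": b3 - b4 + b5,
        "p10": np.nan,
        "p11": np.nan,
        "ridge": False,
        "undefined": None,
    }
    scale = max(b3 * b3, b4 * b4, b5 * b5, 1e-300)
    if abs(b4) < _RIDGE_TOL * np.sqrt(scale):
        out["undefined"] = "principal axes undefined (b4 = 0)"
        return out
    r = np.hypot(b3 - b5, b4)
    out["p11"] = (b5 - b3 + r) / b4
    den = 4.0 * b3 * b5 - b4 * b4
    if abs(den) < _RIDGE_TOL * scale:
        out["ridge"] = True
        out["p10"] = -b1 / b4  # stationary ridge line intercept
        return out
    x0 = (b2 * b4 - 2.0 * b1 * b5) / den
    y0 = (b1 * b4 - 2.0 * b2 * b3) / den
    out["p10"] = y0 - out["p11"] * x0
    return out


def aux_gradients(b: np.ndarray) -> dict:
    """Analytic gradients of the auxiliary parameters w.r.t. (b0..b5)."""
    b = np.asarray(b, dtype=float)
    _, b1, b2, b3, b4, b5 = b
    g = {
        "a1": np.array([0.0, 1, 1, 0, 0, 0]),
        "a2": np.array([0.0, 0, 0, 1, 1, 1]),
        "a3": np.array([0.0, 1, -1, 0, 0, 0]),
        "a4": np.array([0.0, 0, 0, 1, -1, 1]),
    }
    r = np.hypot(b3 - b5, b4)
    if b4 == 0 or r == 0:
        g["p11"] = np.full(6, np.nan)
        g["p10"] = np.full(6, np.nan)
        return g
    p11 = (b5 - b3 + r) / b4
    dp11 = np.zeros(6)
    dp11[3] = (-1.0 + (b3 - b5) / r) / b4
    dp11[4] = 1.0 / r - p11 / b4
    dp11[5] = (1.0 - (b3 - b5) / r) / b4
    g["p11"] = dp11

    den = 4.0 * b3 * b5 - b4 * b4
    if den == 0:
        g["p10"] = np.full(6, np.nan)
        return g
    num_x = b2 * b4 - 2.0 * b1 * b5
    num_y = b1 * b4 - 2.0 * b2 * b3
    x0 = num_x / den
    y0 = num_y / den
    dx0 = np.zeros(6)
    dx0[1] = -2.0 * b5 / den
    dx0[2] = b4 / den
    dx0[3] = -4.0 * b5 * num_x / den**2
    dx0[4] = b2 / den + 2.0 * b4 * num_x / den**2
    dx0[5] = -2.0 * b1 / den - 4.0 * b3 * num_x / den**2
    dy0 = np.zeros(6)
    dy0[1] = b4 / den
    dy0[2] = -2.0 * b3 / den
    dy0[3] = -2.0 * b2 / den - 4.0 * b5 * num_y / den**2
    dy0[4] = b1 / den + 2.0 * b4 * num_y / den**2
    dy0[5] = -4.0 * b3 * num_y / den**2
    g["p10"] = dy0 - p11 * dx0 - x0 * dp11
    return g


def delta_se(b: np.ndarray, cov_b: np.ndarray) -> dict:
    """Delta-method standard errors of the auxiliary parameters.

    Undefined parameters (degenerate surfaces) propagate as NaN.
    """
    cov_b = np.asarray(cov_b, dtype=float)
    if cov_b.shape != (6, 6):
        raise ValueError("cov_b must be 6x6 on the b0..b5 layout")
    eigs = np.linalg.eigvalsh((cov_b + cov_b.T) / 2.0)
    if eigs.min() < -1e-8 * max(eigs.max(), 1e-12):
        raise ValueError("cov_b must be positive semi-definite")
    grads = aux_gradients(b)
    return {
        name: float(np.sqrt(max(grad @ cov_b @ grad, 0.0)))
        if np.isfinite(grad).all()
        else np.nan
        for name, grad in grads.items()
    }


@dataclass
class RSAParams:
    """Auxiliary surface parameters with uncertainty."""

    points: dict
    se: dict
    conf_int: dict
    source: str
    ridge: bool = False
    undefined: str | None = None

    def congruence_test(self, alpha: float = 0.05) -> "CongruenceVerdict":
        return congruence_test(self, alpha=alpha)

    def summary(self) -> str:
        lines = [f"RSA auxiliary parameters ({self.source})"]
        for n in AUX_NAMES:
            ci = self.conf_int.get(n)
            if ci is None or not np.all(np.isfinite(ci)):
                lines.append(f"  {n:>4s}  undefined")
            else:
                lines.append(
                    f"  {n:>4s}  {self.points[n]: .4f}  [{ci[0]: .4f}, {ci[1]: .4f}]"
                )
        return "\n".join(lines)


@dataclass
class CongruenceVerdict:
    """Outcome of the six-condition congruence decision rule."""

    accepted: bool
    conditions: dict
    reason: str | None = None


def rsa_from_fit(
    b: np.ndarray, cov_b: np.ndarray, alpha: float = 0.05, df: float | None = None
) -> RSAParams:
    """Delta-method RSA summary from a frequentist polynomial fit."""
    pts = aux_params(b)
    ses = delta_se(b, cov_b)
    crit = stats.norm.ppf(1 - alpha / 2) if df is None else stats.t.ppf(1 - alpha / 2, df)
    ci = {}
    for n in AUX_NAMES:
        if np.isfinite(pts[n]) and np.isfinite(ses[n]):
            ci[n] = (pts[n] - crit * ses[n], pts[n] + crit * ses[n])
        else:
            ci[n] = (np.nan, np.nan)
    return RSAParams(
        points={n: pts[n] for n in AUX_NAMES},
        se=ses,
        conf_int=ci,
        source="delta",
        ridge=bool(pts["ridge"]),
        undefined=pts["undefined"],
    )


def rsa_from_draws(draws: np.ndarray, alpha: float = 0.05) -> RSAParams:
    """Posterior RSA summary: auxiliary parameters per draw, quantile CIs."""
    draws = np.asarray(draws, dtype=float)
    b1, b2, b3, b4, b5 = (draws[:, i] for i in range(1, 6))
    vals = {
        "a1": b1 + b2,
        "a2": b3 + b4 + b5,
        "a3": b1 - b2,
        "a4": b3 - b4 + b5,
    }
    r = np.hypot(b3 - b5, b4)
    with np.errstate(divide="ignore", invalid="ignore"):
        p11 = (b5 - b3 + r) / b4
        den = 4.0 * b3 * b5 - b4 * b4
        x0 = (b2 * b4 - 2.0 * b1 * b5) / den
        y0 = (b1 * b4 - 2.0 * b2 * b3) / den
        vals["p10"] = y0 - p11 * x0
        vals["p11"] = p11
    points, se, ci = {}, {}, {}
    for n in AUX_NAMES:
        v = vals[n]
        v = v[np.isfinite(v)]
        if len(v) == 0:
            points[n], se[n], ci[n] = np.nan, np.nan, (np.nan, np.nan)
            continue
        points[n] = float(np.median(v))
        se[n] = float(np.std(v, ddof=1))
        ci[n] = (
            float(np.quantile(v, alpha / 2)),
            float(np.quantile(v, 1 - alpha / 2)),
        )
    return RSAParams(points=points, se=se, conf_int=ci, source="draws")


def congruence_test(params: RSAParams, alpha: float = 0.05) -> CongruenceVerdict:
    """Apply the six-condition congruence rule to RSA parameters.

    Accepted iff the intervals for a1, a2, a3, p10 and p11 - 1 all contain
    zero and the interval for a4 lies entirely below zero.
    """
    if params.undefined is not None:
        return CongruenceVerdict(False, {}, reason=params.undefined)
    ci = params.conf_int
    if any(not np.all(np.isfinite(ci[n])) for n in AUX_NAMES):
        return CongruenceVerdict(False, {}, reason="undefined auxiliary parameter")
    conditions = {
        "a1_ns": ci["a1"][0] <= 0.0 <= ci["a1"][1],
        "a2_ns": ci["a2"][0] <= 0.0 <= ci["a2"][1],
        "a3_ns": ci["a3"][0] <= 0.0 <= ci["a3"][1],
        "p10_ns": ci["p10"][0] <= 0.0 <= ci["p10"][1],
        "p11_eq_1": ci["p11"][0] <= 1.0 <= ci["p11"][1],
        "a4_neg": ci["a4"][1] < 0.0,
    }
    return CongruenceVerdict(all(conditions.values()), conditions)
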