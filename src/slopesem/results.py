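"""Polynomial-fit results shared by the four estimators.

All estimators report their level-2 analysis model as the global
second-order polynomial ``z = b0 + b1*cy + b2*cv + b3*cy^2 + b4*cy*cv +
b5*cv^2`` with the terms absent from the chosen model fixed at zero, so
that results from different model kinds and methods are directly
comparable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

COEF_NAMES = ("b0", "b1", "b2", "b3", "b4", "b5")

#: indices of the free coefficients per analysis model
MODEL_TERMS = {
    "quadratic": (0, 1, 3),
    "interaction": (0, 1, 2, 4),
    "full_poly": (0, 1, 2, 3, 4, 5),
}

_KIND_ALIASES = {
    "ushape": "quadratic",
    "quadratic": "quadratic",
    "moderation": "interaction",
    "interaction": "interaction",
    "congruence": "full_poly",
    "full_poly": "full_poly",
}


def model_kind(label: str) -> str:
    """Map a hypothesis label or model name to the analysis-model kind."""
    try:
        return _KIND_ALIASES[label]
    except KeyError:
        raise ValueError(f"unknown model kind {label!r}") from None


def build_design(cy: np.ndarray, cv: np.ndarray | None, kind: str):
    """Design matrix of the analysis model and the b-indices of its columns."""
    kind = model_kind(kind)
    idx = MODEL_TERMS[kind]
    cols = {0: np.ones_like(cy), 1: cy}
    if cv is not None:
        cols[2] = cv
        cols[4] = cy * cv
        cols[5] = cv * cv
    cols[3] = cy * cy
    try:
        X = np.column_stack([cols[i] for i in idx])
    except KeyError:
        raise ValueError(f"model kind {kind!r} needs a second slope") from None
    return X, idx


def expand_to_full(values: np.ndarray, idx, fill: float = 0.0) -> np.ndarray:
    """Embed per-term values into a length-6 vector at positions ``idx``."""
    out = np.full(6, fill)
    out[list(idx)] = values
    return out


def affine_backtransform(b: np.ndarray, means: np.ndarray, scales: np.ndarray) -> np.ndarray:
    """Re-express polynomial coefficients after an affine predictor change.

    If the polynomial was fitted on standardized predictors
    ``eta_j = (c_j - m_j) / s_j``, return the equivalent coefficients on the
    raw metric ``c``.  Works on a length-6 vector (b0..b5); the second
    predictor's entries may be zero for the quadratic model.
    """
    b = np.asarray(b, dtype=float)
    m = np.asarray(means, dtype=float)
    s = np.asarray(scales, dtype=float)
    Dinv = np.diag(1.0 / s)
    B = np.array([[b[3], b[4] / 2.0], [b[4] / 2.0, b[5]]])
    bl = np.array([b[1], b[2]])
    Bc = Dinv @ B @ Dinv
    blc = Dinv @ bl - 2.0 * Bc @ m
    b0c = b[0] - bl @ (m / s) + m @ Bc @ m
    return np.array([b0c, blc[0], blc[1], Bc[0, 0], 2.0 * Bc[0, 1], Bc[1, 1]])


@dataclass
class PolyFit:
    """Estimated level-2 polynomial with uncertainty.

    ``params``, ``cov`` and ``conf_int`` are on the full b0..b5 layout with
    structural zeros for absent terms.  Bayesian methods additionally carry
    posterior ``draws`` (rows are draws, columns b0..b5); interval and RSA
    summaries then use posterior quantiles instead of Wald intervals.
    """

    method: str
    kind: str
    params: np.ndarray
    cov: np.ndarray
    conf_int: np.ndarray
    n_persons: int
    df_resid: float | None = None
    draws: np.ndarray | None = None
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.kind = model_kind(self.kind)
        self.params = np.asarray(self.params, dtype=float)
        self.cov = np.asarray(self.cov, dtype=float)
        self.conf_int = np.asarray(self.conf_int, dtype=float)
        if self.params.shape != (6,) or self.cov.shape != (6, 6):
            raise ValueError("params/cov must use the full b0..b5 layout")

    @property
    def free(self) -> np.ndarray:
        mask = np.zeros(6, dtype=bool)
        mask[list(MODEL_TERMS[self.kind])] = True
        return mask

    @property
    def bse(self) -> np.ndarray:
        return np.sqrt(np.clip(np.diag(self.cov), 0.0, None))

    def rsa(self, alpha: float = 0.05):
        """Response-surface auxiliary parameters and the congruence verdict."""
        from . import rsa as _rsa

        if self.kind != "full_poly":
            raise ValueError("RSA requires the full second-order polynomial")
        if "rsa" in self.diagnostics:  # pre-pooled (plausible values)
            return self.diagnostics["rsa"]
        if self.draws is not None:
            return _rsa.rsa_from_draws(self.draws, alpha=alpha)
        return _rsa.rsa_from_fit(self.params, self.cov, alpha=alpha)

    def summary(self) -> str:
        rows = []
        for i, name in enumerate(COEF_NAMES):
            if not self.free[i]:
                continue
            rows.append(
                f"  {name}  {self.params[i]: .4f}  "
                f"[{self.conf_int[i, 0]: .4f}, {self.conf_int[i, 1]: .4f}]"
            )
        head = (
            f"Level-2 polynomial ({self.kind}), method={self.method}, "
            f"n={self.n_persons}"
        )
        diag = ", ".join(f"{k}={v}" for k, v in self.diagnostics.items()
                         if np.isscalar(v))
        return head + "\n" + "\n".join(rows) + ("\n" + diag if diag else "")

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "kind": self.kind,
            "params": dict(zip(COEF_NAMES, self.params.tolist())),
            "conf_int": {
                n: self.conf_int[i].tolist() for i, n in enumerate(COEF_NAMES)
            },
            "n_persons": self.n_persons,
            "diagnostics": {
                k: (float(v) if np.isscalar(v) else v)
                for k, v in self.diagnostics.items()
                if np.isscalar(v) or isinstance(v, (str, bool))
            },
        }

    def plot_surface(self, ax=None, grid: int = 41, span: float = 1.0):
        """Contour plot of the fitted response surface (full polynomial)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        g = np.linspace(-span, span, grid)
        X, Y = np.meshgrid(g, g)
        b = self.params
        Z = (
            b[0] + b[1] * X + b[2] * Y + b[3] * X**2 + b[4] * X * Y + b[5] * Y**2
        )
        cs = ax.contourf(X, Y, Z, levels=15)
        ax.plot(g, g, "k--", lw=1)
        ax.set_xlabel("slope 1")
        ax.set_ylabel("slope 2")
        plt.colorbar(cs, ax=ax)
        return ax


def polyfit_from_ols(result, idx, method: str, kind: str, n: int) -> PolyFit:
    """Wrap a statsmodels OLS result on the analysis design into a PolyFit."""
    params = expand_to_full(np.asarray(result.params), idx)
    cov6 = np.zeros((6, 6))
    cov6[np.ix_(idx, idx)] = np.asarray(result.cov_params())
    ci = np.zeros((6, 2))
    ci[list(idx)] = np.asarray(result.conf_int())
    return PolyFit(
        method=method,
        kind=kind,
        params=params,
        cov=cov6,
        conf_int=ci,
        n_persons=n,
        df_resid=float(result.df_resid),
        diagnostics={"r_squared": float(result.rsquared)},
    )


def draws_summary(draws: np.ndarray, alpha: float = 0.05):
    """Posterior medians, covariance and quantile intervals from b-draws."""
    med = np.median(draws, axis=0)
    cov = np.cov(draws, rowvar=False)
    if cov.ndim == 0:
        cov = cov.reshape(1, 1)
    lo = np.quantile(draws, alpha / 2, axis=0)
    hi = np.quantile(draws, 1 - alpha / 2, axis=0)
    return med, cov, np.column_stack([lo, hi])
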