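"""Monte-Carlo harness: bias, CI widths, coverage, RMSE and acceptance rates.

Runs replications of simulate -> fit for each requested method and
aggregates the evaluation criteria per coefficient:

* bias and relative bias of the estimates;
* empirical CI width — ``2 * z_.975 * SD(estimates)`` for the frequentist
  methods (two-step, PV) and the 2.5–97.5% range of the sampling
  distribution for the Bayesian ones (MSEM, SI);
* mean estimated CI width and the relative CI-width difference
  ``(est - emp) / emp`` (negative values mean intervals that are too
  narrow);
* coverage of the true value and RMSE;
* the acceptance rate of the hypothesis-specific decision rule: the CI of
  the headline coefficient excluding zero (U-shape: b3, moderation: b4) or
  the six-condition response-surface congruence verdict.  This is the power
  when the effect exists and the false-positive rate under the null.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .population import PopulationSpec, make_unbalanced, simulate
from .results import COEF_NAMES, MODEL_TERMS, model_kind
from .msem import LatentSlopeMSEM
from .pv import PlausibleValuesModel
from .si import SingleIndicatorSEM
from .twostep import TwoStepModel

Z975 = stats.norm.ppf(0.975)

BAYESIAN_METHODS = frozenset({"msem", "si"})
HEADLINE = {"quadratic": 3, "interaction": 4}


def empirical_ci_width(estimates: np.ndarray, method: str) -> float:
    """Width of the empirical 95% interval of a sampling distribution."""
    estimates = np.asarray(estimates, dtype=float)
    if len(estimates) < 2:
        raise ValueError("need at least two replications")
    if method in BAYESIAN_METHODS:
        return float(np.quantile(estimates, 0.975) - np.quantile(estimates, 0.025))
    return float(2.0 * Z975 * np.std(estimates, ddof=1))


def relative_ci_diff(est_width: float, emp_width: float) -> float:
    """Signed relative difference of estimated vs empirical CI width."""
    if emp_width <= 0:
        raise ValueError("empirical width must be positive")
    return (est_width - emp_width) / emp_width


def _fit_one(method: str, data, kind: str, seed: int, mcmc_opts: dict):
    if method == "twostep":
        return TwoStepModel(data, kind).fit()
    if method == "pv":
        return PlausibleValuesModel(data, kind, M=mcmc_opts.get("pv_draws", 20)).fit(
            seed=seed
        )
    if method == "si":
        return SingleIndicatorSEM(
            data,
            kind,
            iterations=mcmc_opts.get("si_iterations", 12_000),
            chains=mcmc_opts.get("si_chains", 2),
        ).fit(seed=seed)
    if method == "msem":
        res = LatentSlopeMSEM(
            data,
            kind,
            iterations=mcmc_opts.get("msem_iterations", 2000),
            chains=mcmc_opts.get("msem_chains", 2),
        ).fit(seed=seed)
        return res.polyfit
    raise ValueError(f"unknown method {method!r}")


def _accepted(fit, kind: str, alpha: float = 0.05) -> bool:
    if kind == "full_poly":
        try:
            return bool(fit.rsa(alpha=alpha).congruence_test(alpha=alpha).accepted)
        except (ValueError, np.linalg.LinAlgError):
            return False
    i = HEADLINE[kind]
    lo, hi = fit.conf_int[i]
    return not (lo <= 0.0 <= hi)


def run_condition(
    spec: PopulationSpec,
    methods: tuple[str, ...] = ("twostep",),
    reps: int = 1000,
    seed: int | None = None,
    unbalanced: bool = False,
    mcmc_opts: dict | None = None,
    drop_width_outliers: bool = False,
    keep_replicates: bool = False,
):
    """Run a simulation condition and aggregate the evaluation criteria.

    Returns a metrics DataFrame with one row per method and coefficient
    (plus ``rmse_check`` inputs); when ``keep_replicates`` is True, also
    returns the per-replication estimates.
    """
    if reps < 2:
        raise ValueError("need at least two replications")
    mcmc_opts = mcmc_opts or {}
    kind = model_kind(spec.hypothesis if spec.hypothesis != "null" else "ushape")
    free = list(MODEL_TERMS[kind])
    truth = spec.b

    ss = np.random.SeedSequence(seed)
    rep_seeds = ss.spawn(reps)
    records = []  # per rep/method: params, ci, accepted, converged
    failures = {m: 0 for m in methods}
    nonconverged = {m: 0 for m in methods}
    for r, child in enumerate(rep_seeds):
        s1, s2, s3 = child.spawn(3)
        data = simulate(spec, seed=s1)
        if unbalanced:
            data = make_unbalanced(data, seed=s2)
        fit_seed = int(s3.generate_state(1)[0] % (2**31 - 1))
        for method in methods:
            try:
                fit = _fit_one(method, data, kind, fit_seed, mcmc_opts)
            except (np.linalg.LinAlgError, ValueError):
                failures[method] += 1
                continue
            if not fit.diagnostics.get(
                "converged", fit.diagnostics.get("step1_converged", True)
            ):
                nonconverged[method] += 1
            records.append(
                {
                    "rep": r,
                    "method": method,
                    "params": fit.params.copy(),
                    "ci": fit.conf_int.copy(),
                    "accepted": _accepted(fit, kind),
                }
            )

    rows = []
    raw_rows = []
    for method in methods:
        recs = [rec for rec in records if rec["method"] == method]
        if len(recs) < 2:
            continue
        est = np.array([rec["params"] for rec in recs])
        ci = np.array([rec["ci"] for rec in recs])
        acc = np.mean([rec["accepted"] for rec in recs])
        widths = ci[:, :, 1] - ci[:, :, 0]
        n_outl = 0
        if drop_width_outliers:
            med = np.median(widths, axis=0)
            bad = (widths > 100.0 * np.maximum(med, 1e-12)).any(axis=1)
            n_outl = int(bad.sum())
            widths = widths[~bad]
        for i in free:
            emp = empirical_ci_width(est[:, i], method)
            est_w = float(widths[:, i].mean())
            bias = float(est[:, i].mean() - truth[i])
            covered = (ci[:, i, 0] <= truth[i]) & (truth[i] <= ci[:, i, 1])
            rows.append(
                {
                    "hypothesis": spec.hypothesis,
                    "r2": spec.r2_target,
                    "P": spec.P,
                    "T": "unbalanced" if unbalanced else spec.T,
                    "method": method,
                    "parameter": COEF_NAMES[i],
                    "truth": truth[i],
                    "bias": bias,
                    "rel_bias": bias / truth[i] if truth[i] != 0 else np.nan,
                    "emp_ci_width": emp,
                    "est_ci_width": est_w,
                    "rel_ci_diff": relative_ci_diff(est_w, emp) if emp > 0 else np.nan,
                    "coverage": float(covered.mean()),
                    "rmse": float(np.sqrt(np.mean((est[:, i] - truth[i]) ** 2))),
                    "acceptance_rate": float(acc),
                    "reps": len(recs),
                    "n_failed": failures[method],
                    "n_nonconverged": nonconverged[method],
                    "n_width_outliers": n_outl,
                }
            )
        if keep_replicates:
            for rec in recs:
                raw_rows.append(
                    {
                        "rep": rec["rep"],
                        "method": method,
                        **{COEF_NAMES[i]: rec["params"][i] for i in free},
                        "accepted": rec["accepted"],
                    }
                )
    metrics = pd.DataFrame(rows)
    if keep_replicates:
        return metrics, pd.DataFrame(raw_rows)
    return metrics
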