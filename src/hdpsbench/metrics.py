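"""Simulation performance measures with Monte Carlo standard errors.

Given R replicate estimates theta_hat_r with model-based SEs and 95% CIs,
and the true value theta, the seven measures are

* bias                 : mean(theta_hat) - theta
* average model SE     : mean of the reported SEs (the arithmetic mean,
                         exactly as defined, not the root-mean variance)
* empirical SE         : SD of theta_hat across replicates (R-1 denominator)
* MSE                  : mean((theta_hat - theta)^2)
* coverage             : % of CIs containing theta
* bias-eliminated      : % of CIs containing mean(theta_hat) — isolates
  coverage               variance calibration from bias
* relative error in SE : 100 * (avg model SE / empirical SE - 1)

together with the standard Monte Carlo SEs (bias: empSE/sqrt(R);
coverage: sqrt(c(1-c)/R); empSE: empSE/sqrt(2(R-1)); MSE: SD of squared
errors / sqrt(R)).  The zip-plot table stacks replicate CIs by the
centile of their standardized error |(theta_hat - theta)/SE| so that
non-covering intervals concentrate at the top when inference is
calibrated.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["compute_metrics", "metric_table", "zip_plot_data"]


def _as_arrays(records) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Accept a DataFrame or EstimateRecord list; return est, se, lo, hi."""
    if isinstance(records, pd.DataFrame):
        df = records
    else:
        df = pd.DataFrame([r.__dict__ for r in records])
    return (
        df["rd_hat"].to_numpy(dtype=float),
        df["rd_se"].to_numpy(dtype=float),
        df["rd_ci_lo"].to_numpy(dtype=float),
        df["rd_ci_hi"].to_numpy(dtype=float),
    )


def compute_metrics(
    records,
    truth: float,
    est: np.ndarray | None = None,
    se: np.ndarray | None = None,
    ci_lo: np.ndarray | None = None,
    ci_hi: np.ndarray | None = None,
) -> dict[str, float]:
    """One row of the performance table (RD scale by default).

    Pass explicit ``est``/``se``/``ci_lo``/``ci_hi`` arrays to compute the
    measures on another scale (e.g. log-OR); otherwise the RD columns of
    ``records`` are used.
    """
    if est is None:
        est, se, ci_lo, ci_hi = _as_arrays(records)
    est = np.asarray(est, dtype=float)
    se = np.asarray(se, dtype=float)
    ci_lo = np.asarray(ci_lo, dtype=float)
    ci_hi = np.asarray(ci_hi, dtype=float)
    r = len(est)
    if r < 2:
        raise ValueError("need at least 2 converged replicates")

    mean_est = float(est.mean())
    bias = mean_est - truth
    emp_se = float(est.std(ddof=1))
    avg_model_se = float(se.mean())
    sq_err = (est - truth) ** 2
    mse = float(sq_err.mean())
    cover = (ci_lo <= truth) & (truth <= ci_hi)
    coverage = float(cover.mean())
    cover_be = (ci_lo <= mean_est) & (mean_est <= ci_hi)
    coverage_be = float(cover_be.mean())
    if emp_se > 0:
        rel_err_se = 100.0 * (avg_model_se / emp_se - 1.0)
        rel_err_flag = False
    else:
        rel_err_se = float("nan")
        rel_err_flag = True

    return {
        "n_converged": r,
        "bias": bias,
        "bias_mcse": emp_se / np.sqrt(r),
        "avg_model_se": avg_model_se,
        "empirical_se": emp_se,
        "empirical_se_mcse": emp_se / np.sqrt(2.0 * (r - 1)),
        "relative_error_se_pct": rel_err_se,
        "relative_error_se_undefined": rel_err_flag,
        "mse": mse,
        "mse_mcse": float(sq_err.std(ddof=1)) / np.sqrt(r),
        "coverage_pct": 100.0 * coverage,
        "coverage_mcse_pct": 100.0 * float(np.sqrt(coverage * (1 - coverage) / r)),
        "bias_eliminated_coverage_pct": 100.0 * coverage_be,
        "bias_eliminated_coverage_mcse_pct": 100.0
        * float(np.sqrt(coverage_be * (1 - coverage_be) / r)),
    }


def metric_table(records: pd.DataFrame, truth: float) -> pd.DataFrame:
    """Aggregate an estimate table to one metrics row per (method, scenario)."""
    rows = []
    for (method, scenario), grp in records.groupby(["method", "scenario"], sort=True):
        row = {"method": method, "scenario": scenario}
        row.update(compute_metrics(grp, truth))
        rows.append(row)
    return pd.DataFrame(rows)


def zip_plot_data(records, truth: float) -> pd.DataFrame:
    """Per-replicate standardized errors, centiles and coverer flags."""
    est, se, ci_lo, ci_hi = (
        _as_arrays(records)
        if not isinstance(records, tuple)
        else records
    )
    r = len(est)
    if r < 2:
        raise ValueError("need at least 2 records")
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, (est - truth) / se, np.inf)
    order = np.argsort(np.abs(z), kind="stable")
    rank = np.empty(r, dtype=int)
    rank[order] = np.arange(1, r + 1)
    return pd.DataFrame(
        {
            "replicate": np.arange(r),
            "estimate": est,
            "se": se,
            "ci_lo": ci_lo,
            "ci_hi": ci_hi,
            "z": z,
            "abs_z_centile": rank / r,
            "covers": (ci_lo <= truth) & (truth <= ci_hi),
        }
    )
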