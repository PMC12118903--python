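"""Propensity-score fitting, inverse-probability weights, and ATE estimation.

The propensity score is fit by maximum-likelihood logistic regression of
exposure on the investigator covariates, the (untransformed) labs, and
whatever proxy set a selection method returned.  Each subject is weighted
by the inverse probability of the exposure status actually observed
(``1/ps`` if exposed, ``1/(1-ps)`` otherwise), targeting the average
treatment effect.

Effects are estimated from weighted marginal structural models with
exposure as the only regressor: a linear-probability model for the risk
difference and a logistic model for the odds ratio.  Standard errors are
robust (HC0 sandwich) with the weights treated as known, the standard
singly-robust IPW practice; 95% confidence intervals are Wald intervals
(on the log scale for the OR).  This variance estimator ignores the
uncertainty in the fitted propensity score, which for the ATE makes the
intervals conservative when the PS model is correct.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.linear_model import LogisticRegression

from .cohort import Cohort

__all__ = ["EstimateRecord", "EstimationError", "fit_ps", "ipw_weights", "estimate_effects"]

_Z975 = 1.959963984540054


class EstimationError(RuntimeError):
    """PS or MSM fit failed (separation / non-convergence / empty stratum)."""


@dataclass(frozen=True)
class EstimateRecord:
    """One replicate's effect estimates for one method."""

    method: str
    scenario: str
    replicate: int
    rd_hat: float
    rd_se: float
    rd_ci_lo: float
    rd_ci_hi: float
    or_hat: float
    log_or_se: float
    or_ci_lo: float
    or_ci_hi: float
    ps_min: float
    ps_max: float
    ps_extreme_frac: float  # share of scores outside [0.01, 0.99]

    def __post_init__(self) -> None:
        if not (self.rd_ci_lo <= self.rd_hat <= self.rd_ci_hi):
            raise ValueError("RD estimate outside its own CI")
        if self.or_hat <= 0:
            raise ValueError("odds ratio must be positive")
        if not (self.or_ci_lo <= self.or_hat <= self.or_ci_hi):
            raise ValueError("OR estimate outside its own CI")


def _ps_design(cohort: Cohort, selected_proxies: list[str] | tuple[str, ...]) -> pd.DataFrame:
    cols = list(cohort.roles.investigator_cols) + list(cohort.roles.lab_cols) + list(selected_proxies)
    bad = [c for c in selected_proxies if c not in cohort.roles.proxy_cols]
    if bad:
        raise KeyError(f"selected proxies not declared in cohort roles: {bad}")
    return cohort.table[cols].astype(float)


def fit_ps(
    cohort: Cohort,
    selected_proxies: list[str] | tuple[str, ...] = (),
    design: pd.DataFrame | None = None,
    max_iter: int = 2000,
) -> np.ndarray:
    """MLE logistic propensity scores; ``design`` overrides the default
    investigator + labs + selected-proxies regressor set (used by the
    oracle analysis, whose regressors are the true-model covariates)."""
    e = cohort.exposure
    if len(np.unique(e)) < 2:
        raise EstimationError("exposure has a single class; propensity model undefined")
    X = design if design is not None else _ps_design(cohort, selected_proxies)
    X = np.asarray(X, dtype=float)
    if X.shape[1] == 0:
        p = float(e.mean())
        return np.full(len(e), p)
    model = LogisticRegression(C=np.inf, solver="lbfgs", max_iter=max_iter, tol=1e-8)
    model.fit(X, e)
    if model.n_iter_[0] >= max_iter:
        raise EstimationError("propensity model did not converge (possible separation)")
    ps = model.predict_proba(X)[:, 1]
    eps = 1e-12
    if ps.min() < eps or ps.max() > 1 - eps:
        raise EstimationError("propensity scores degenerate at 0/1 (separation)")
    return ps


def ipw_weights(
    ps: np.ndarray,
    exposure: np.ndarray,
    truncation: tuple[float, float] | None = None,
) -> np.ndarray:
    """Inverse probability of the observed exposure status.

    ``truncation=(lo_pct, hi_pct)`` optionally winsorizes the weights at
    those percentiles of their own distribution (off by default).
    """
    ps = np.asarray(ps, dtype=float)
    if np.any((ps <= 0) | (ps >= 1)):
        raise ValueError("propensity scores must lie strictly in (0,1)")
    e = np.asarray(exposure, dtype=float)
    w = np.where(e == 1, 1.0 / ps, 1.0 / (1.0 - ps))
    if truncation is not None:
        lo, hi = np.percentile(w, truncation)
        w = np.clip(w, lo, hi)
    return w


def _wald_ci(est: float, se: float) -> tuple[float, float]:
    return est - _Z975 * se, est + _Z975 * se


def _sandwich_se(X: np.ndarray, w: np.ndarray, resid: np.ndarray,
                 deriv: np.ndarray) -> np.ndarray:
    """Robust SEs for the weighted estimating equation sum w x (y - mu) = 0.

    Bread uses the mean-model derivative ``deriv`` (1 for identity link,
    mu(1-mu) for logit); meat uses squared weighted scores, i.e. the
    weights enter squared, as appropriate when weights are treated as
    known constants rather than frequencies.
    """
    bread = np.linalg.inv((X * (w * deriv)[:, None]).T @ X)
    meat = (X * ((w * resid) ** 2)[:, None]).T @ X
    cov = bread @ meat @ bread
    return np.sqrt(np.diag(cov))


def estimate_effects(
    cohort: Cohort,
    weights: np.ndarray,
    method: str = "",
    scenario: str = "",
    replicate: int = 0,
    ps: np.ndarray | None = None,
) -> EstimateRecord:
    """ATE as risk difference and odds ratio from weighted MSMs."""
    w = np.asarray(weights, dtype=float)
    if np.any(~np.isfinite(w)) or np.any(w <= 0):
        raise ValueError("weights must be positive and finite")
    e = cohort.exposure
    y = cohort.outcome
    if not (e == 1).any() or not (e == 0).any():
        raise EstimationError("a weighted exposure stratum is empty")
    X = sm.add_constant(e)

    lin = sm.GLM(y, X, family=sm.families.Gaussian(), freq_weights=w).fit()
    rd = float(lin.params[1])
    mu_lin = np.asarray(X @ lin.params, dtype=float)
    rd_se = float(_sandwich_se(X, w, y - mu_lin, np.ones(len(y)))[1])

    try:
        logit = sm.GLM(y, X, family=sm.families.Binomial(), freq_weights=w).fit()
    except Exception as exc:  # perfect separation in the weighted MSM
        raise EstimationError(f"weighted logistic MSM failed: {exc}") from exc
    log_or = float(logit.params[1])
    mu_log = np.asarray(logit.predict(X), dtype=float)
    log_or_se = float(_sandwich_se(X, w, y - mu_log, mu_log * (1 - mu_log))[1])
    if not np.isfinite(log_or) or not np.isfinite(log_or_se):
        raise EstimationError("weighted logistic MSM produced non-finite estimates")

    rd_lo, rd_hi = _wald_ci(rd, rd_se)
    lo_lo, lo_hi = _wald_ci(log_or, log_or_se)
    if ps is None:
        ps_min = ps_max = float("nan")
        ps_frac = float("nan")
    else:
        ps = np.asarray(ps, dtype=float)
        ps_min, ps_max = float(ps.min()), float(ps.max())
        ps_frac = float(np.mean((ps < 0.01) | (ps > 0.99)))
    return EstimateRecord(
        method=method, scenario=scenario, replicate=replicate,
        rd_hat=rd, rd_se=rd_se, rd_ci_lo=rd_lo, rd_ci_hi=rd_hi,
        or_hat=float(np.exp(log_or)), log_or_se=log_or_se,
        or_ci_lo=float(np.exp(lo_lo)), or_ci_hi=float(np.exp(lo_hi)),
        ps_min=ps_min, ps_max=ps_max, ps_extreme_frac=ps_frac,
    )


def records_to_frame(records: list[EstimateRecord]) -> pd.DataFrame:
    """Tabulate estimate records (one row per method x scenario x replicate)."""
    return pd.DataFrame([r.__dict__ for r in records])
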