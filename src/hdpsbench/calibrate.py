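"""Intercept calibration for logistic generating models.

Both the base-cohort generator and the plasmode outcome model fix every
slope coefficient first and then choose the intercept so that the mean of
the inverse-logit over the (fixed) linear predictor hits a target
prevalence.  That mean is strictly increasing in the intercept, so the
root is found by scalar bracketing (Brent's method) to 1e-4 on the
prevalence scale.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import brentq
from scipy.special import expit

__all__ = ["calibrate_logit_intercept", "CalibrationError"]


class CalibrationError(ValueError):
    """Target prevalence is unreachable for the given linear predictor."""


def calibrate_logit_intercept(
    linear_predictor: np.ndarray,
    target_prev: float,
    tol: float = 1e-4,
    bracket: float = 30.0,
    weights: np.ndarray | None = None,
) -> float:
    """Return ``b0`` with ``mean(expit(b0 + lp)) = target_prev`` within ``tol``.

    ``weights`` (non-negative, need not sum to 1) switch the mean to a
    weighted mean — used to calibrate against a reweighted covariate
    distribution, e.g. the exposure mix of a resampling design.
    Raises :class:`CalibrationError`, reporting the achievable prevalence
    range, if the target cannot be bracketed.
    """
    lp = np.asarray(linear_predictor, dtype=float)
    if not 0.0 < target_prev < 1.0:
        raise CalibrationError(f"target prevalence must be in (0,1), got {target_prev}")
    if not np.all(np.isfinite(lp)):
        raise CalibrationError("linear predictor contains non-finite values")
    if weights is not None:
        weights = np.asarray(weights, dtype=float)
        if np.any(weights < 0) or weights.sum() <= 0:
            raise CalibrationError("calibration weights must be non-negative, not all zero")

    def realized(b0: float) -> float:
        probs = expit(b0 + lp)
        if weights is None:
            return float(np.mean(probs))
        return float(np.average(probs, weights=weights))

    lo, hi = realized(-bracket), realized(bracket)
    if not lo <= target_prev <= hi:
        raise CalibrationError(
            f"target prevalence {target_prev} outside achievable range [{lo:.6g}, {hi:.6g}]"
        )
    b0 = brentq(lambda b: realized(b) - target_prev, -bracket, bracket, xtol=1e-10)
    if abs(realized(b0) - target_prev) > tol:
        raise CalibrationError("intercept calibration did not reach requested tolerance")
    return float(b0)
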