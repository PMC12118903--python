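"""Bross-formula bias ranking of proxy covariates (the hdPS prioritization core).

For each binary proxy ``C`` the algorithm computes, from simple 2x2
proportions,

* ``pc1`` — prevalence of the proxy among the exposed,
* ``pc0`` — prevalence among the unexposed,
* ``rr_cd`` — the unadjusted outcome relative risk
  ``Pr(D=1 | C=1) / Pr(D=1 | C=0)``,

and the multiplicative bias that failing to adjust for ``C`` would
introduce in the exposure-outcome relative risk::

    RR*  = max(rr_cd, 1/rr_cd)
    B_m  = (pc1 * (RR* - 1) + 1) / (pc0 * (RR* - 1) + 1)

Proxies are ranked by ``|log10(B_m)|`` (direction-agnostic), and the top
``k`` (default 100) enter the propensity-score model.  ``B_m = 1`` exactly
when the proxy carries no exposure association (``pc1 = pc0``) or no
outcome association (``rr_cd = 1``).

The same 2x2 machinery supports the relative-risk filter used by the
simulation's true outcome model: a proxy with unadjusted outcome RR
strictly below 0.8 or strictly above 1.2 is treated as a genuine
confounder surrogate, anything inside the band as noise.
"""

from __future__ import annotations

import time
from dataclasses import dataclass

import numpy as np

from .cohort import Cohort

__all__ = [
    "ProxyAssociation",
    "proxy_association",
    "bross_bias_multiplier",
    "rank_proxies",
    "rr_filter",
]


@dataclass(frozen=True)
class ProxyAssociation:
    """2x2 summaries and Bross bias quantities for one proxy."""

    proxy: str
    pc1: float
    pc0: float
    rr_cd: float
    bias_multiplier: float
    rank_score: float
    constant: bool = False  # proxy takes a single value in the cohort

    def __post_init__(self) -> None:
        if not (0.0 <= self.pc1 <= 1.0 and 0.0 <= self.pc0 <= 1.0):
            raise ValueError("prevalences must lie in [0,1]")


def bross_bias_multiplier(pc1: float, pc0: float, rr_cd: float) -> float:
    """Multiplicative confounding bias from not adjusting for the proxy."""
    if not all(np.isfinite([pc1, pc0, rr_cd])):
        raise ValueError("bross_bias_multiplier requires finite inputs")
    if rr_cd <= 0:
        raise ValueError("rr_cd must be positive")
    rr_star = max(rr_cd, 1.0 / rr_cd)
    return (pc1 * (rr_star - 1.0) + 1.0) / (pc0 * (rr_star - 1.0) + 1.0)


def _outcome_rr(outcome: np.ndarray, proxy: np.ndarray) -> float:
    """Unadjusted outcome RR with a 0.5 continuity correction when needed.

    The correction is applied to all four cells of the outcome-by-proxy
    table only when some cell is empty, so populated tables are untouched.
    """
    n1 = proxy.sum()
    n0 = len(proxy) - n1
    d1 = float(outcome[proxy == 1].sum())
    d0 = float(outcome[proxy == 0].sum())
    cells = np.array([d1, n1 - d1, d0, n0 - d0], dtype=float)
    if (cells == 0).any():
        d1, d0 = d1 + 0.5, d0 + 0.5
        n1, n0 = n1 + 1.0, n0 + 1.0
    return (d1 / n1) / (d0 / n0)


def proxy_association(cohort: Cohort, proxy: str) -> ProxyAssociation:
    """Compute the full Bross summary for one declared proxy column."""
    if proxy not in cohort.roles.proxy_cols:
        raise KeyError(f"{proxy!r} is not a declared proxy column")
    c = cohort.table[proxy].to_numpy(dtype=float)
    e = cohort.exposure
    d = cohort.outcome
    if len(np.unique(c)) == 1:
        # degenerate proxy: no information, rank it last with a flag
        return ProxyAssociation(proxy, float(c.mean()), float(c.mean()), 1.0, 1.0, 0.0, constant=True)
    pc1 = float(c[e == 1].mean()) if (e == 1).any() else 0.0
    pc0 = float(c[e == 0].mean()) if (e == 0).any() else 0.0
    rr_cd = _outcome_rr(d, c)
    bm = bross_bias_multiplier(pc1, pc0, rr_cd)
    return ProxyAssociation(proxy, pc1, pc0, rr_cd, bm, abs(float(np.log10(bm))))


def rank_proxies(cohort: Cohort, k: int = 100) -> list[ProxyAssociation]:
    """Top-``k`` proxies by descending ``|log10(B_m)|``; name breaks ties."""
    if k < 0:
        raise ValueError("k must be >= 0")
    assocs = [proxy_association(cohort, p) for p in cohort.roles.proxy_cols]
    assocs.sort(key=lambda a: (-a.rank_score, a.proxy))
    return assocs[: min(k, len(assocs))]


def rr_filter(
    cohort: Cohort, lo: float = 0.8, hi: float = 1.2
) -> tuple[list[str], list[str]]:
    """Partition proxies into (confounder, noise) by unadjusted outcome RR.

    A proxy is a confounder surrogate iff its RR is strictly below ``lo``
    or strictly above ``hi``; RR exactly on a threshold counts as noise.
    """
    if not 0 < lo < hi:
        raise ValueError("thresholds must satisfy 0 < lo < hi")
    d = cohort.outcome
    confounders, noise = [], []
    for p in cohort.roles.proxy_cols:
        c = cohort.table[p].to_numpy(dtype=float)
        if len(np.unique(c)) == 1:
            noise.append(p)
            continue
        rr = _outcome_rr(d, c)
        (confounders if (rr < lo or rr > hi) else noise).append(p)
    return confounders, noise
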