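"""Plasmode simulation engine.

A plasmode simulation keeps real (or realistic) covariate and exposure
data untouched and regenerates only the outcome from a known,
investigator-controlled model, so the true treatment effect is known
while the covariate correlation structure stays realistic.

Per replicate the engine

1. resamples subjects with replacement from the base cohort, stratified
   on exposure so that each replicate has *exactly* ``round(n * p_E)``
   exposed rows (this is how a 5%-exposure scenario is realized from a
   ~49%-exposure base without altering any subject's values);
2. drops the base outcome and redraws it from a Bernoulli whose logit is

   ``b0 + ln(true_OR) * E + investigator terms + transformed-lab terms
   + burden_coef * comorbidity burden``

   where the comorbidity burden is the per-subject count of the
   confounder proxies retained by the outcome-RR filter, and the lab
   terms apply deliberately complex transformations (log, exp, square
   root, centered square, pairwise interaction) that downstream analyses
   do not know about;
3. calibrates ``b0`` on the *base* cohort so the mean outcome
   probability matches the scenario's target outcome prevalence.

Replicate ``r`` of a scenario draws all of its randomness from
``numpy.random.SeedSequence([scenario.seed, r])``, so the mapping
(seed, replicate index) -> dataset is a pure function and replicates can
be generated in any order or in parallel.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator

import numpy as np
import pandas as pd
from scipy.special import expit

from .bross import rr_filter
from .calibrate import calibrate_logit_intercept
from .cohort import Cohort

__all__ = [
    "ScenarioConfig",
    "DGMSpec",
    "ReplicateDataset",
    "comorbidity_burden",
    "build_dgm",
    "calibrate_intercept",
    "resample_cohort",
    "generate_outcome",
    "simulate_scenario",
    "dgm_design_matrix",
    "DEFAULT_SCENARIOS",
]

_LAB_TRANSFORMS = ("log", "exp", "sqrt", "poly2", "interaction")


@dataclass(frozen=True)
class ScenarioConfig:
    """One simulation scenario: prevalences, true conditional OR, size, seed."""

    name: str
    exposure_prev: float
    outcome_prev: float
    true_or: float = 1.0
    n: int = 3000
    n_iter: int = 500
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.exposure_prev < 1 and 0 < self.outcome_prev < 1):
            raise ValueError("prevalences must lie in (0,1)")
        if self.true_or <= 0:
            raise ValueError("true_or must be positive")
        if self.n < 1 or self.n_iter < 1:
            raise ValueError("n and n_iter must be >= 1")


#: The three study scenarios: frequent/frequent (base), rare exposure,
#: rare outcome; all null (OR = 1, hence RD = 0) at n = 3,000.
DEFAULT_SCENARIOS: tuple[ScenarioConfig, ...] = (
    ScenarioConfig("base", 0.30, 0.30),
    ScenarioConfig("rare_exposure", 0.05, 0.30),
    ScenarioConfig("rare_outcome", 0.30, 0.05),
)


@dataclass(frozen=True)
class DGMSpec:
    """The true outcome-generating model of a plasmode scenario."""

    exposure_coef: float
    investigator_coefs: dict[str, float]
    lab_terms: tuple[tuple[str, tuple[str, ...], float], ...]  # (transform, columns, coef)
    burden_coef: float
    burden_proxies: tuple[str, ...]
    intercept: float = 0.0
    lab_stats: dict[str, tuple[float, float, float]] = field(default_factory=dict)
    # per lab: (mean, sd, min) frozen from the base cohort so the same
    # transformation is applied identically to every resample

    def with_intercept(self, b0: float) -> "DGMSpec":
        return replace(self, intercept=float(b0))


@dataclass
class ReplicateDataset:
    """One simulated dataset: resampled covariates+exposure, fresh outcome."""

    cohort: Cohort
    replicate: int
    scenario: str
    seed_key: tuple[int, int]


def comorbidity_burden(cohort: Cohort, burden_proxies: list[str] | tuple[str, ...]) -> np.ndarray:
    """Row sum of the listed binary proxies (count of active comorbidities)."""
    unknown = [p for p in burden_proxies if p not in cohort.roles.proxy_cols]
    if unknown:
        raise KeyError(f"unknown burden proxies: {unknown}")
    if not burden_proxies:
        return np.zeros(cohort.n, dtype=int)
    return cohort.table[list(burden_proxies)].to_numpy(dtype=int).sum(axis=1)


def _transform_lab(tag: str, cols: tuple[str, ...], cohort: Cohort,
                   stats: dict[str, tuple[float, float, float]]) -> np.ndarray:
    """Evaluate one transformed-lab term using base-cohort statistics.

    log/sqrt operate on the column shifted by ``1 - base_min`` so the
    argument is >= 1 on the base cohort; poly2 is the centered square of
    the standardized lab; interaction is the product of two standardized
    labs.
    """
    def z(col: str) -> np.ndarray:
        mean, sd, _ = stats[col]
        return (cohort.table[col].to_numpy(dtype=float) - mean) / (sd if sd > 0 else 1.0)

    def shifted(col: str) -> np.ndarray:
        _, _, mn = stats[col]
        out = cohort.table[col].to_numpy(dtype=float) + (1.0 - mn)
        if (out <= 0).any():
            raise ValueError(
                f"lab {col!r} has values below its base-cohort minimum; "
                "shift by (1 - base min) does not keep the transform domain valid"
            )
        return out

    if tag == "log":
        return np.log(shifted(cols[0]))
    if tag == "exp":
        return np.exp(np.clip(z(cols[0]), -5.0, 5.0))
    if tag == "sqrt":
        return np.sqrt(shifted(cols[0]))
    if tag == "poly2":
        return z(cols[0]) ** 2 - 1.0
    if tag == "interaction":
        return z(cols[0]) * z(cols[1])
    raise ValueError(f"unknown lab transform {tag!r}")


def dgm_design_matrix(dgm: DGMSpec, cohort: Cohort) -> pd.DataFrame:
    """The true-model covariates (everything except exposure) for a cohort.

    Used both to evaluate the DGM linear predictor and as the regressor
    set of the oracle (correctly specified) propensity-score model.
    """
    cols: dict[str, np.ndarray] = {}
    for name in dgm.investigator_coefs:
        cols[name] = cohort.table[name].to_numpy(dtype=float)
    for tag, term_cols, _ in dgm.lab_terms:
        cols[f"{tag}({','.join(term_cols)})"] = _transform_lab(tag, term_cols, cohort, dgm.lab_stats)
    cols["comorbidity_burden"] = comorbidity_burden(cohort, dgm.burden_proxies).astype(float)
    return pd.DataFrame(cols, index=cohort.table.index)


def _linear_predictor(dgm: DGMSpec, cohort: Cohort, exposure: np.ndarray) -> np.ndarray:
    lp = np.full(cohort.n, dgm.intercept, dtype=float)
    lp += dgm.exposure_coef * exposure
    for name, coef in dgm.investigator_coefs.items():
        lp += coef * cohort.table[name].to_numpy(dtype=float)
    for tag, term_cols, coef in dgm.lab_terms:
        lp += coef * _transform_lab(tag, term_cols, cohort, dgm.lab_stats)
    lp += dgm.burden_coef * comorbidity_burden(cohort, dgm.burden_proxies)
    if not np.all(np.isfinite(lp)):
        raise ValueError("non-finite linear predictor in outcome model")
    return lp


def calibrate_intercept(
    dgm: DGMSpec,
    base: Cohort,
    target_prev: float,
    exposure_prev: float | None = None,
) -> float:
    """Intercept making the mean outcome probability hit ``target_prev``.

    With ``exposure_prev`` given, base subjects are reweighted to that
    exposure mix (the stratified-resampling design), so the *replicate*
    outcome prevalence is calibrated rather than the base-cohort one.
    """
    zero = dgm.with_intercept(0.0)
    lp = _linear_predictor(zero, base, base.exposure)
    weights = None
    if exposure_prev is not None:
        e = base.exposure
        p_base = float(e.mean())
        if not 0 < p_base < 1:
            raise ValueError("base cohort must contain both exposure classes")
        weights = np.where(e == 1, exposure_prev / p_base, (1 - exposure_prev) / (1 - p_base))
    return calibrate_logit_intercept(lp, target_prev, weights=weights)


def build_dgm(
    base: Cohort,
    scenario: ScenarioConfig,
    investigator_coef_range: tuple[float, float] = (0.1, 0.5),
    lab_coef_range: tuple[float, float] = (0.1, 0.3),
    burden_coef: float = 0.1,
    coefficients: dict | None = None,
    rng: np.random.Generator | None = None,
) -> DGMSpec:
    """Construct and calibrate the true outcome model for a scenario.

    Coefficients are drawn from the seeded ``rng`` (signs random, magnitudes
    uniform in the given ranges) unless an explicit ``coefficients`` mapping
    with keys ``investigator``, ``lab_terms``, ``burden`` overrides them.
    One transformed term per family is built over the base labs; the
    burden-proxy list comes from the outcome-RR filter on the base cohort.
    """
    if rng is None:
        rng = np.random.default_rng(scenario.seed)
    labs = list(base.roles.lab_cols)
    lab_stats = {
        c: (
            float(base.table[c].mean()),
            float(base.table[c].std()),
            float(base.table[c].min()),
        )
        for c in labs
    }

    def draw(lo: float, hi: float) -> float:
        return float(rng.choice([-1.0, 1.0]) * rng.uniform(lo, hi))

    if coefficients and "investigator" in coefficients:
        inv_coefs = dict(coefficients["investigator"])
    else:
        inv_coefs = {c: draw(*investigator_coef_range) for c in base.roles.investigator_cols}

    lab_terms: list[tuple[str, tuple[str, ...], float]] = []
    if coefficients and "lab_terms" in coefficients:
        lab_terms = [(t, tuple(c), float(v)) for t, c, v in coefficients["lab_terms"]]
    elif labs:
        for i, tag in enumerate(_LAB_TRANSFORMS):
            if tag == "interaction":
                if len(labs) < 2:
                    continue
                cols = tuple(rng.choice(labs, size=2, replace=False))
            else:
                cols = (labs[i % len(labs)],)
            lab_terms.append((tag, cols, draw(*lab_coef_range)))

    if coefficients and "burden" in coefficients:
        burden_coef = float(coefficients["burden"])

    burden_proxies, _ = rr_filter(base)
    dgm = DGMSpec(
        exposure_coef=float(np.log(scenario.true_or)),
        investigator_coefs=inv_coefs,
        lab_terms=tuple(lab_terms),
        burden_coef=burden_coef,
        burden_proxies=tuple(burden_proxies),
        lab_stats=lab_stats,
    )
    return dgm.with_intercept(
        calibrate_intercept(dgm, base, scenario.outcome_prev, scenario.exposure_prev)
    )


def resample_cohort(
    base: Cohort, n: int, exposure_prev: float, rng: np.random.Generator
) -> Cohort:
    """Exposure-stratified resample with replacement; outcome column zeroed."""
    e = base.exposure
    n_exp = int(round(n * exposure_prev))
    if n_exp <= 0 or n_exp >= n:
        raise ValueError(
            f"degenerate exposure stratum: {n_exp} exposed of {n} requested"
        )
    idx_exp = np.flatnonzero(e == 1)
    idx_unexp = np.flatnonzero(e == 0)
    if len(idx_exp) == 0 or len(idx_unexp) == 0:
        raise ValueError("base cohort must contain both exposed and unexposed subjects")
    take = np.concatenate(
        [rng.choice(idx_exp, size=n_exp, replace=True),
         rng.choice(idx_unexp, size=n - n_exp, replace=True)]
    )
    tab = base.table.iloc[take].reset_index(drop=True).copy()
    tab[base.roles.outcome_col] = 0
    return Cohort(tab, base.roles)


def generate_outcome(
    sample: Cohort, dgm: DGMSpec, rng: np.random.Generator,
    replicate: int = 0, scenario: str = "", seed_key: tuple[int, int] = (0, 0),
) -> ReplicateDataset:
    """Draw the outcome from the DGM's Bernoulli-logistic model."""
    lp = _linear_predictor(dgm, sample, sample.exposure)
    y = rng.binomial(1, expit(lp)).astype(int)
    tab = sample.table.copy()
    tab[sample.roles.outcome_col] = y
    return ReplicateDataset(Cohort(tab, sample.roles), replicate, scenario, seed_key)


def replicate_rng(scenario_seed: int, replicate: int) -> np.random.Generator:
    """Independent, reproducible stream for one replicate."""
    return np.random.default_rng(np.random.SeedSequence([scenario_seed, replicate]))


def simulate_scenario(
    base: Cohort, scenario: ScenarioConfig, dgm: DGMSpec,
    n_iter: int | None = None,
) -> Iterator[ReplicateDataset]:
    """Yield ``n_iter`` independent replicate datasets for a scenario."""
    total = scenario.n_iter if n_iter is None else n_iter
    for r in range(total):
        rng = replicate_rng(scenario.seed, r)
        sample = resample_cohort(base, scenario.n, scenario.exposure_prev, rng)
        yield generate_outcome(
            sample, dgm, rng, replicate=r, scenario=scenario.name,
            seed_key=(scenario.seed, r),
        )
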