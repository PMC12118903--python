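"""End-to-end study runner.

``run_simulation_study`` reproduces the simulation design: per scenario it
builds the true outcome model once from the base cohort, then per
replicate resamples covariates+exposure, regenerates the outcome, lets
each selection method pick proxies, fits the propensity model, weights,
and estimates the ATE; replicate estimates are aggregated to the
performance-measure table.  ``run_real_analysis`` is the single-dataset
analogue: every method analyses one observed cohort and the report
contains effect estimates, selected-set overlap tables and timings.

Randomness: replicate ``r`` of a scenario uses
``SeedSequence([scenario.seed, r])`` for resampling and outcome draws,
and each stochastic selector gets an integer seed derived from
``(scenario.seed, r, method)``; results are therefore reproducible and
independent of execution order.  Failures (non-convergence, separation)
are recorded per (method, scenario, replicate) and the study continues.

The special method label ``"Oracle"`` fits the propensity model on the
true outcome-model covariates (investigator covariates, transformed lab
terms, comorbidity burden) instead of running a selector — the correctly
specified benchmark used for calibration checks.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import Cohort
from .ipw import EstimationError, estimate_effects, fit_ps, ipw_weights, records_to_frame
from .metrics import metric_table
from .plasmode import (
    DGMSpec,
    ScenarioConfig,
    DEFAULT_SCENARIOS,
    build_dgm,
    dgm_design_matrix,
    generate_outcome,
    replicate_rng,
    resample_cohort,
)
from . import selectors as sel

__all__ = ["StudyConfig", "run_simulation_study", "run_real_analysis", "true_rd"]

_SELECTOR_FNS = {
    "KS": lambda c, seed, **kw: sel.select_kitchen_sink(c),
    "Bross": lambda c, seed, **kw: sel.select_bross(c, **kw),
    "Hybrid": lambda c, seed, **kw: sel.select_hybrid(c, seed=seed, **kw),
    "LASSO": lambda c, seed, **kw: sel.select_lasso(c, seed=seed, **kw),
    "EN": lambda c, seed, **kw: sel.select_elastic_net(c, seed=seed, **kw),
    "RF": lambda c, seed, **kw: sel.select_random_forest(c, seed=seed, **kw),
    "XGB": lambda c, seed, **kw: sel.select_xgboost(c, seed=seed, **kw),
    "FS": lambda c, seed, **kw: sel.select_forward(c, **kw),
    "BE": lambda c, seed, **kw: sel.select_backward(c, **kw),
    "GA": lambda c, seed, **kw: sel.select_genetic(c, seed=seed, **kw),
}

#: Hyperparameter overrides that trade fidelity for speed (smaller GA/RF
#: budgets, coarser CV); useful for smoke runs and constrained hardware.
REDUCED_PROFILE: dict[str, dict] = {
    "RF": {"n_trees": 100},
    "XGB": {"n_rounds": 100},
    "LASSO": {"cv_folds": 5, "n_lambda": 20},
    "Hybrid": {"cv_folds": 5, "n_lambda": 20},
    "EN": {"cv_folds": 5, "n_lambda": 15, "l1_ratios": (0.2, 0.5, 0.8)},
    "GA": {"pop_size": 20, "n_generations": 10, "cv_folds": 3},
}


@dataclass
class StudyConfig:
    """Everything needed to reproduce a simulation study."""

    base: Cohort
    scenarios: tuple[ScenarioConfig, ...] = DEFAULT_SCENARIOS
    methods: tuple[str, ...] = tuple(sel.METHOD_LABELS)
    method_params: dict[str, dict] = field(default_factory=dict)
    master_seed: int = 0
    dgm_kwargs: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        names = [s.name for s in self.scenarios]
        if len(set(names)) != len(names):
            raise ValueError("scenario names must be unique")
        unknown = [m for m in self.methods if m not in (*sel.METHOD_LABELS, "Oracle")]
        if unknown:
            raise ValueError(f"unknown methods: {unknown}")


def _method_seed(scenario_seed: int, replicate: int, method: str) -> int:
    """Deterministic 31-bit seed for a stochastic selector."""
    ss = np.random.SeedSequence([scenario_seed, replicate, zlib.crc32(method.encode())])
    return int(ss.generate_state(1)[0] % (2**31))


def true_rd(dgm: DGMSpec, base: Cohort) -> float:
    """Model-implied marginal risk difference over the base covariates.

    Averages the DGM outcome probability with exposure forced to 1 vs 0
    for every base subject; exactly 0 when the exposure coefficient is 0.
    """
    from scipy.special import expit

    design = dgm_design_matrix(dgm, base)
    lp = dgm.intercept + design.to_numpy() @ np.array(
        [*dgm.investigator_coefs.values()]
        + [c for *_rest, c in dgm.lab_terms]
        + [dgm.burden_coef]
    )
    return float(np.mean(expit(lp + dgm.exposure_coef) - expit(lp)))


def _analyse_one(
    dataset: Cohort,
    method: str,
    seed: int,
    params: dict,
    dgm: DGMSpec | None,
    scenario: str,
    replicate: int,
) -> tuple[object, object]:
    """Run selection + PS + IPW for one method on one dataset."""
    if method == "Oracle":
        if dgm is None:
            raise ValueError("Oracle method requires a DGM")
        design = dgm_design_matrix(dgm, dataset)
        ps = fit_ps(dataset, design=design)
        selection = None
    else:
        selection = _SELECTOR_FNS[method](dataset, seed, **params)
        ps = fit_ps(dataset, selection.selected_proxies)
    w = ipw_weights(ps, dataset.exposure)
    record = estimate_effects(
        dataset, w, method=method, scenario=scenario, replicate=replicate, ps=ps
    )
    return record, selection


def run_simulation_study(
    config: StudyConfig,
    n_iter: int | None = None,
) -> dict:
    """Run the full scenario x replicate x method grid.

    Returns a dict with ``metrics`` (performance table), ``records``
    (per-replicate estimates), ``failures`` (error log) and ``truth``
    (per-scenario true RD).
    """
    all_records = []
    failures = []
    truths: dict[str, float] = {}
    for s_idx, scenario in enumerate(config.scenarios):
        scen = ScenarioConfig(
            name=scenario.name, exposure_prev=scenario.exposure_prev,
            outcome_prev=scenario.outcome_prev, true_or=scenario.true_or,
            n=scenario.n, n_iter=scenario.n_iter,
            seed=scenario.seed + config.master_seed * 1000 + s_idx,
        )
        dgm = build_dgm(config.base, scen, **config.dgm_kwargs)
        truths[scen.name] = true_rd(dgm, config.base)
        total = scen.n_iter if n_iter is None else n_iter
        for r in range(total):
            rng = replicate_rng(scen.seed, r)
            sample = resample_cohort(config.base, scen.n, scen.exposure_prev, rng)
            dataset = generate_outcome(sample, dgm, rng, r, scen.name).cohort
            for method in config.methods:
                params = dict(config.method_params.get(method, {}))
                seed = _method_seed(scen.seed, r, method)
                try:
                    record, _ = _analyse_one(
                        dataset, method, seed, params, dgm, scen.name, r
                    )
                    all_records.append(record)
                except (EstimationError, ValueError) as exc:
                    failures.append(
                        {"method": method, "scenario": scen.name,
                         "replicate": r, "error": str(exc)}
                    )
    records = records_to_frame(all_records) if all_records else pd.DataFrame()
    metrics = pd.DataFrame()
    if len(records):
        parts = []
        for scen_name, truth in truths.items():
            part = records[records["scenario"] == scen_name]
            if len(part):
                m = metric_table(part, truth)
                m["truth_rd"] = truth
                parts.append(m)
        metrics = pd.concat(parts, ignore_index=True)
    return {
        "metrics": metrics,
        "records": records,
        "failures": pd.DataFrame(failures),
        "truth": truths,
    }


def run_real_analysis(
    cohort: Cohort,
    methods: tuple[str, ...] = tuple(sel.METHOD_LABELS),
    method_params: dict[str, dict] | None = None,
    seed: int = 0,
) -> dict:
    """Analyse one observed cohort with every method.

    Returns ``effects`` (per-method OR and RD with 95% CIs, runtimes,
    ordered by selected-set size), ``overlap`` (pairwise intersection
    matrix) and ``agreement`` (per-method overlap rate with Bross).
    """
    method_params = method_params or {}
    rows = []
    selections: list[sel.SelectionResult] = []
    for m_idx, method in enumerate(methods):
        params = dict(method_params.get(method, {}))
        try:
            record, selection = _analyse_one(
                cohort, method, _method_seed(seed, 0, method), params, None, "real", 0
            )
        except (EstimationError, ValueError) as exc:
            rows.append({"method": method, "error": str(exc)})
            continue
        if selection is not None:
            selections.append(selection)
        rows.append(
            {
                "method": method,
                "n_selected": len(selection.selected_proxies) if selection else np.nan,
                "or_hat": record.or_hat,
                "or_ci_lo": record.or_ci_lo,
                "or_ci_hi": record.or_ci_hi,
                "rd_hat": record.rd_hat,
                "rd_ci_lo": record.rd_ci_lo,
                "rd_ci_hi": record.rd_ci_hi,
                "runtime_seconds": selection.runtime_seconds if selection else 0.0,
            }
        )
    effects = pd.DataFrame(rows)
    if "n_selected" in effects:
        effects = effects.sort_values(
            "n_selected", ascending=False, kind="stable"
        ).reset_index(drop=True)
    overlap, agreement = (None, None)
    if selections:
        overlap, agreement = sel.overlap_matrix(selections)
    return {"effects": effects, "overlap": overlap, "agreement": agreement,
            "selections": selections}
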