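"""Synthetic base-cohort generator.

Emulates the statistical structure of a survey-derived analytic cohort
(~7,585 adults, binary exposure at 48.8% prevalence, binary outcome at
23.7%, 142 binary proxy covariates of which 94 carry a marginal outcome
relative risk outside [0.8, 1.2] and 48 are noise) so the whole pipeline
runs without any external data.

Structure
---------
A single latent standard-normal "health burden" factor ``U`` per subject
induces the confounding:

* continuous labs load linearly on ``U`` plus independent noise;
* binary and categorical investigator covariates depend weakly on ``U``;
* exposure follows a logistic model in ``U``, standardized labs and
  investigator covariates, intercept calibrated to the target prevalence;
* confounder proxies are Bernoulli draws from a logistic model in ``U``
  with a signed loading, so each proxy is a genuine surrogate for the
  unmeasured factor that also drives exposure;
* noise proxies are Bernoulli draws independent of everything;
* the base outcome follows a logistic model in ``U``, labs, investigator
  covariates and small direct proxy effects — exposure-free, so a
  downstream data-generating model can impose any conditional odds ratio.

Because every confounder proxy shares the latent factor, its *marginal*
outcome relative risk is dominated by the factor loading rather than by
its small direct coefficient; this mirrors administrative-data cohorts
where dozens of comorbidity indicators are each marginally associated
with the outcome through shared underlying morbidity.  The generator
records the model-implied marginal log-RR of every proxy (averaging the
outcome probabilities over subjects, i.e. free of Bernoulli noise) as the
ground truth that recovery tests target.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from .calibrate import calibrate_logit_intercept
from .cohort import Cohort, ColumnRoles

__all__ = ["GeneratorConfig", "GeneratorTruth", "generate_base_cohort", "truth_report"]

# Latent-factor coefficients of the base models.  The outcome loading is
# strong enough that proxies (factor loadings 0.6-1.0) land comfortably
# outside the RR in [0.8, 1.2] noise band at the default cohort size.
# Exposure depends on the latent factor only through the confounder-proxy
# burden (plus labs and investigator covariates), i.e. the confounding
# pathway runs entirely through observables; the burden loading is
# moderate so that propensity-score overlap resembles an applied cohort
# rather than a near-deterministic treatment rule.
_OUTCOME_U_COEF = 1.0
_EXPOSURE_BURDEN_COEF = 0.5
_PROXY_U_LOADING = (0.6, 1.0)


@dataclass(frozen=True)
class GeneratorConfig:
    """Dials of the synthetic cohort; defaults emulate the reference cohort."""

    n: int = 7585
    exposure_prev_target: float = 0.488
    outcome_prev_target: float = 0.237
    n_proxies: int = 142
    n_confounder_proxies: int = 94
    n_investigator_binary: int = 12
    n_investigator_categorical: int = 4
    n_labs: int = 6
    proxy_effect_range: tuple[float, float] = (0.05, 0.15)
    proxy_prevalence_range: tuple[float, float] = (0.05, 0.5)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.exposure_prev_target < 1:
            raise ValueError("exposure prevalence target must be in (0,1)")
        if not 0 < self.outcome_prev_target < 1:
            raise ValueError("outcome prevalence target must be in (0,1)")
        if self.n_confounder_proxies > self.n_proxies:
            raise ValueError("n_confounder_proxies cannot exceed n_proxies")
        if min(self.n, self.n_proxies, self.n_confounder_proxies, self.n_labs,
               self.n_investigator_binary, self.n_investigator_categorical) < 0:
            raise ValueError("counts must be non-negative")


@dataclass
class GeneratorTruth:
    """Ground truth emitted alongside a generated cohort, for recovery tests."""

    latent: np.ndarray
    proxy_names: list[str]
    labels: dict[str, str]                  # proxy -> "confounder" | "noise"
    direct_effect: dict[str, float]         # conditional log-odds effect in the outcome model
    u_loading: dict[str, float]             # signed loading of the proxy on the latent factor
    marginal_log_rr: dict[str, float]       # model-implied marginal log-RR vs outcome
    prevalence: dict[str, float]            # target proxy prevalence
    outcome_intercept: float = 0.0
    exposure_intercept: float = 0.0
    extra: dict = field(default_factory=dict)


def _standardize(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    return (x - x.mean()) / (sd if sd > 0 else 1.0)


def generate_base_cohort(
    config: GeneratorConfig = GeneratorConfig(),
    rng: np.random.Generator | None = None,
) -> tuple[Cohort, GeneratorTruth]:
    """Generate a base cohort and its ground truth.

    ``rng`` defaults to ``np.random.default_rng(config.seed)``; passing an
    explicit generator lets callers embed this in a wider seeded stream.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n = config.n
    if n < 1:
        raise ValueError("n must be >= 1")
    u = rng.standard_normal(n)

    table: dict[str, np.ndarray] = {}

    # --- continuous labs: linear in U plus noise, shifted to positive scales
    lab_names = [f"lab{j + 1}" for j in range(config.n_labs)]
    lab_z: dict[str, np.ndarray] = {}
    for name in lab_names:
        loading = rng.uniform(0.3, 0.6)
        mu = rng.uniform(5.0, 60.0)
        sigma = rng.uniform(0.1, 0.3) * mu
        raw = loading * u + np.sqrt(1.0 - loading**2) * rng.standard_normal(n)
        table[name] = mu + sigma * raw
        lab_z[name] = _standardize(table[name])

    # --- investigator-specified binary covariates, weakly dependent on U
    inv_names: list[str] = []
    inv_values: dict[str, np.ndarray] = {}
    for i in range(config.n_investigator_binary):
        name = f"inv{i + 1}"
        prev = rng.uniform(0.15, 0.6)
        coef = rng.choice([-1.0, 1.0]) * rng.uniform(0.2, 0.5)
        b0 = calibrate_logit_intercept(coef * u, prev)
        vals = rng.binomial(1, expit(b0 + coef * u)).astype(int)
        table[name] = vals
        inv_values[name] = vals.astype(float)
        inv_names.append(name)

    # --- categorical investigator covariates: latent cut of a U-correlated score
    for i in range(config.n_investigator_categorical):
        name = f"cat{i + 1}"
        n_levels = int(rng.integers(3, 5))
        score = 0.4 * u + rng.standard_normal(n)
        cuts = np.quantile(score, np.linspace(0, 1, n_levels + 1)[1:-1])
        level_idx = np.searchsorted(cuts, score, side="right")
        table[name] = level_idx.astype(int)  # stored as integer level codes
        # reference-cell indicators are what the models see
        for lev in range(1, n_levels):
            ind_name = f"{name}_L{lev}"
            vals = (level_idx == lev).astype(int)
            table[ind_name] = vals
            inv_values[ind_name] = vals.astype(float)
            inv_names.append(ind_name)
    # the raw categorical code columns are dropped from the cohort table;
    # only the expanded indicators enter (keeps roles binary-coded)
    for i in range(config.n_investigator_categorical):
        table.pop(f"cat{i + 1}")

    # --- proxies
    proxy_names = [f"proxy{j + 1:03d}" for j in range(config.n_proxies)]
    labels: dict[str, str] = {}
    direct: dict[str, float] = {}
    loading: dict[str, float] = {}
    prevalence: dict[str, float] = {}
    proxy_vals: dict[str, np.ndarray] = {}
    lo_eff, hi_eff = config.proxy_effect_range
    lo_q, hi_q = config.proxy_prevalence_range
    for j, name in enumerate(proxy_names):
        q = rng.uniform(lo_q, hi_q)
        prevalence[name] = q
        if j < config.n_confounder_proxies:
            sign = float(rng.choice([-1.0, 1.0]))
            b = sign * rng.uniform(*_PROXY_U_LOADING)
            g = sign * rng.uniform(lo_eff, hi_eff)
            b0 = calibrate_logit_intercept(b * u, q)
            vals = rng.binomial(1, expit(b0 + b * u)).astype(int)
            labels[name] = "confounder"
        else:
            b, g = 0.0, 0.0
            vals = rng.binomial(1, q, size=n).astype(int)
            labels[name] = "noise"
        direct[name] = g
        loading[name] = b
        proxy_vals[name] = vals
        table[name] = vals

    # --- exposure: logistic in the confounder-proxy burden and the
    # investigator covariates.  The latent factor reaches exposure only
    # through the burden, and labs only correlate with exposure through
    # that shared pathway; consequently P(E=1 | burden, investigator) is
    # exactly logistic, which keeps a propensity model fitted on the
    # true outcome-model covariates correctly specified.
    burden = np.zeros(n)
    for name in proxy_names:
        if labels[name] == "confounder":
            burden = burden + proxy_vals[name]
    exp_lp = _EXPOSURE_BURDEN_COEF * _standardize(burden) if burden.std() > 0 else np.zeros(n)
    for name in inv_names:
        coef = rng.choice([-1.0, 1.0]) * rng.uniform(0.05, 0.2)
        exp_lp = exp_lp + coef * inv_values[name]
    exp_b0 = calibrate_logit_intercept(exp_lp, config.exposure_prev_target)
    exposure = rng.binomial(1, expit(exp_b0 + exp_lp)).astype(int)
    table["exposure"] = exposure

    # --- base outcome: exposure-free logistic model
    out_lp = _OUTCOME_U_COEF * u
    for name in lab_names:
        out_lp = out_lp + 0.1 * lab_z[name]
    for name in inv_names:
        coef = rng.choice([-1.0, 1.0]) * rng.uniform(0.05, 0.2)
        out_lp = out_lp + coef * inv_values[name]
    for name in proxy_names:
        if direct[name] != 0.0:
            out_lp = out_lp + direct[name] * proxy_vals[name]
    out_b0 = calibrate_logit_intercept(out_lp, config.outcome_prev_target)
    p_outcome = expit(out_b0 + out_lp)
    table["outcome"] = rng.binomial(1, p_outcome).astype(int)

    # --- model-implied marginal log-RR per proxy (outcome-noise-free truth)
    marginal: dict[str, float] = {}
    for name in proxy_names:
        mask = proxy_vals[name] == 1
        if mask.all() or not mask.any():
            marginal[name] = 0.0
            continue
        marginal[name] = float(np.log(p_outcome[mask].mean() / p_outcome[~mask].mean()))

    roles = ColumnRoles(
        exposure_col="exposure",
        outcome_col="outcome",
        investigator_cols=tuple(inv_names),
        lab_cols=tuple(lab_names),
        proxy_cols=tuple(proxy_names),
    )
    order = ["exposure", "outcome", *inv_names, *lab_names, *proxy_names]
    cohort = Cohort(pd.DataFrame({k: table[k] for k in order}), roles)
    truth = GeneratorTruth(
        latent=u,
        proxy_names=proxy_names,
        labels=labels,
        direct_effect=direct,
        u_loading=loading,
        marginal_log_rr=marginal,
        prevalence=prevalence,
        outcome_intercept=out_b0,
        exposure_intercept=exp_b0,
    )
    return cohort, truth


def truth_report(truth: GeneratorTruth) -> pd.DataFrame:
    """One row per proxy: label, direct effect, loading, implied marginal log-RR."""
    rows = [
        {
            "proxy": name,
            "label": truth.labels[name],
            "direct_effect": truth.direct_effect[name],
            "u_loading": truth.u_loading[name],
            "marginal_log_rr": truth.marginal_log_rr[name],
            "prevalence": truth.prevalence[name],
        }
        for name in truth.proxy_names
    ]
    return pd.DataFrame(rows)
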