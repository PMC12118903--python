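"""Shared fixtures: hand-built toy cohorts and seeded synthetic cohorts."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from hdpsbench.cohort import Cohort, ColumnRoles
from hdpsbench.synthetic import GeneratorConfig, generate_base_cohort


def make_cohort(
    exposure,
    outcome,
    proxies: dict[str, list[int]] | None = None,
    investigator: dict[str, list] | None = None,
    labs: dict[str, list[float]] | None = None,
) -> Cohort:
    """Assemble a cohort from explicit column lists."""
    data = {"E": list(exposure), "D": list(outcome)}
    proxies = proxies or {}
    investigator = investigator or {}
    labs = labs or {}
    data.update(investigator)
    data.update(labs)
    data.update(proxies)
    roles = ColumnRoles(
        exposure_col="E",
        outcome_col="D",
        investigator_cols=tuple(investigator),
        lab_cols=tuple(labs),
        proxy_cols=tuple(proxies),
    )
    return Cohort(pd.DataFrame(data), roles)


@pytest.fixture(scope="session")
def default_cohort():
    """The default-configuration synthetic cohort (n=7,585, 142 proxies)."""
    cohort, truth = generate_base_cohort(GeneratorConfig(seed=1))
    return cohort, truth


@pytest.fixture(scope="session")
def small_base():
    """A smaller base cohort for pipeline tests (n=3,000, 30 proxies)."""
    cfg = GeneratorConfig(
        n=3000, n_proxies=30, n_confounder_proxies=20,
        n_investigator_binary=5, n_investigator_categorical=2, n_labs=3, seed=5,
    )
    cohort, truth = generate_base_cohort(cfg)
    return cohort, truth


def informative_proxy_cohort(seed: int, n: int = 2000, n_noise: int = 5,
                             effect: float = 1.5, duplicate: bool = False) -> Cohort:
    """One strongly outcome-associated proxy among pure-noise proxies."""
    rng = np.random.default_rng(seed)
    inv = rng.binomial(1, 0.4, n)
    lab = rng.normal(10, 2, n)
    signal = rng.binomial(1, 0.3, n)
    noise = {f"noise{i}": rng.binomial(1, 0.3, n).tolist() for i in range(n_noise)}
    from scipy.special import expit

    p = expit(-1.2 + effect * signal + 0.2 * inv)
    d = rng.binomial(1, p)
    e = rng.binomial(1, 0.4, n)
    proxies = {"aaa_signal": signal.tolist(), **noise}
    if duplicate:
        proxies["aab_signal_copy"] = signal.tolist()
    return make_cohort(e, d, proxies=proxies,
                       investigator={"inv": inv.tolist()},
                       labs={"lab": lab.tolist()})
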