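"""The ten proxy-selection strategies, behind one uniform interface.

Every selector receives a :class:`~hdpsbench.cohort.Cohort` and returns a
:class:`SelectionResult` whose ``selected_proxies`` is a subset of the
declared proxy columns.  Investigator covariates and labs are *forced*
covariates: they condition every supervised selector but are never
themselves selected or dropped.

Methods (labels follow the field's shorthand):

==========  ===========================================================
KS          kitchen sink — all proxies, no selection
Bross       top-k (default 100) by the Bross bias-multiplier ranking
Hybrid      Bross top-k, then lasso refinement within that set
LASSO       CV-tuned L1 logistic regression; selected = nonzero coefs
EN          CV-tuned elastic net (mixing chosen on a grid)
RF          random-forest impurity importance, top-k proxies
XGB         gradient boosting; selected = proxies with positive gain
FS / BE     forward / backward stepwise on adjusted R-squared
GA          genetic algorithm maximizing CV classification accuracy
==========  ===========================================================

Supervised selectors model the *outcome* by default (the stepwise
criterion, an outcome-model adjusted R-squared, and the outcome-RR proxy
filter both point that way); ``target="exposure"`` switches them to an
exposure model.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from xgboost import XGBClassifier

from .bross import rank_proxies
from .cohort import Cohort
from .regpath import cv_en_logistic

__all__ = [
    "SelectionResult",
    "select_kitchen_sink",
    "select_bross",
    "select_lasso",
    "select_hybrid",
    "select_elastic_net",
    "select_random_forest",
    "select_xgboost",
    "select_forward",
    "select_backward",
    "select_genetic",
    "overlap_matrix",
    "METHOD_LABELS",
]

METHOD_LABELS = ("KS", "Bross", "Hybrid", "LASSO", "EN", "RF", "XGB", "FS", "BE", "GA")


@dataclass
class SelectionResult:
    method: str
    selected_proxies: list[str]
    scores: dict[str, float] = field(default_factory=dict)
    runtime_seconds: float = 0.0
    settings: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.selected_proxies)) != len(self.selected_proxies):
            raise ValueError("selected proxy list contains duplicates")


def _target(cohort: Cohort, target: str) -> np.ndarray:
    if target == "outcome":
        return cohort.outcome
    if target == "exposure":
        return cohort.exposure
    raise ValueError(f"unknown selection target {target!r}")


def _design(
    cohort: Cohort,
    proxy_subset: list[str] | tuple[str, ...] | None = None,
    standardize_labs: bool = False,
) -> tuple[np.ndarray, list[str], list[str]]:
    """Forced covariates (investigator + labs) then candidate proxies."""
    proxies = list(cohort.roles.proxy_cols if proxy_subset is None else proxy_subset)
    forced = list(cohort.roles.investigator_cols) + list(cohort.roles.lab_cols)
    X = cohort.table[forced + proxies].astype(float).to_numpy()
    if standardize_labs and cohort.roles.lab_cols:
        i0 = len(cohort.roles.investigator_cols)
        i1 = i0 + len(cohort.roles.lab_cols)
        block = X[:, i0:i1]
        sd = block.std(axis=0)
        X[:, i0:i1] = (block - block.mean(axis=0)) / np.where(sd > 0, sd, 1.0)
    return X, forced, proxies


def _timed(method: str, settings: dict):
    """Decorator-free timing helper: returns (start_time, closer)."""
    t0 = time.perf_counter()

    def close(selected: list[str], scores: dict[str, float]) -> SelectionResult:
        return SelectionResult(method, selected, scores, time.perf_counter() - t0, settings)

    return close


# ---------------------------------------------------------------- KS / Bross

def select_kitchen_sink(cohort: Cohort) -> SelectionResult:
    """All declared proxies, no selection."""
    close = _timed("KS", {})
    return close(list(cohort.roles.proxy_cols), {})


def select_bross(cohort: Cohort, k: int = 100) -> SelectionResult:
    """Top-``k`` proxies by the Bross bias ranking."""
    close = _timed("Bross", {"k": k})
    ranked = rank_proxies(cohort, k)
    return close([a.proxy for a in ranked], {a.proxy: a.rank_score for a in ranked})


# ------------------------------------------------------------ penalized fits

def _penalized_select(
    cohort: Cohort,
    method: str,
    l1_ratios: tuple[float, ...],
    proxy_subset=None,
    cv_folds: int = 10,
    seed: int = 0,
    n_lambda: int = 30,
    target: str = "outcome",
) -> SelectionResult:
    settings = {"l1_ratios": l1_ratios, "cv_folds": cv_folds, "seed": seed,
                "n_lambda": n_lambda, "target": target}
    close = _timed(method, settings)
    y = _target(cohort, target)
    X, forced, proxies = _design(cohort, proxy_subset, standardize_labs=True)
    pf = np.r_[np.zeros(len(forced)), np.ones(len(proxies))]
    fit = cv_en_logistic(X, y, pf, l1_ratios=l1_ratios, cv_folds=cv_folds,
                         seed=seed, n_lambda=n_lambda)
    coefs = fit["coef"][len(forced):]
    selected = [p for p, c in zip(proxies, coefs) if c != 0.0]
    res = close(selected, {p: float(c) for p, c in zip(proxies, coefs)})
    res.settings.update({"lambda": fit["lambda"], "l1_ratio": fit["l1_ratio"]})
    return res


def select_lasso(cohort: Cohort, cv_folds: int = 10, seed: int = 0,
                 n_lambda: int = 30, target: str = "outcome") -> SelectionResult:
    """CV-optimal L1 logistic model; proxies with nonzero coefficients."""
    res = _penalized_select(cohort, "LASSO", (1.0,), None, cv_folds, seed, n_lambda, target)
    return res


def select_hybrid(cohort: Cohort, k: int = 100, cv_folds: int = 10, seed: int = 0,
                  n_lambda: int = 30, target: str = "outcome") -> SelectionResult:
    """Bross top-``k`` filtering, then lasso refinement within that set."""
    top = select_bross(cohort, k).selected_proxies
    res = _penalized_select(cohort, "Hybrid", (1.0,), top, cv_folds, seed, n_lambda, target)
    res.settings["k"] = k
    return res


def select_elastic_net(
    cohort: Cohort,
    l1_ratios: tuple[float, ...] = (0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9),
    cv_folds: int = 10,
    seed: int = 0,
    n_lambda: int = 30,
    target: str = "outcome",
) -> SelectionResult:
    """Elastic net with the mixing parameter chosen on a grid by CV."""
    return _penalized_select(cohort, "EN", tuple(l1_ratios), None, cv_folds, seed, n_lambda, target)


# ------------------------------------------------------------- tree ensembles

def select_random_forest(cohort: Cohort, n_trees: int = 500, k: int = 100,
                         seed: int = 0, target: str = "outcome") -> SelectionResult:
    """Impurity (Gini) importance ranking; top-``k`` proxies selected."""
    settings = {"n_trees": n_trees, "k": k, "seed": seed, "target": target}
    close = _timed("RF", settings)
    y = _target(cohort, target)
    X, forced, proxies = _design(cohort)
    rf = RandomForestClassifier(n_estimators=n_trees, random_state=seed, n_jobs=1)
    rf.fit(X, y)
    imp = rf.feature_importances_[len(forced):]
    order = sorted(range(len(proxies)), key=lambda i: (-imp[i], proxies[i]))
    chosen = [proxies[i] for i in order[: min(k, len(proxies))]]
    return close(chosen, {proxies[i]: float(imp[i]) for i in range(len(proxies))})


def select_xgboost(
    cohort: Cohort,
    max_depth: int = 3,
    n_rounds: int = 200,
    learning_rate: float = 0.1,
    seed: int = 0,
    target: str = "outcome",
) -> SelectionResult:
    """Gradient boosting; selected = proxies with strictly positive gain.

    Unlike the fixed top-k selectors, the selection count here is
    data-dependent: a proxy never used in any split has zero gain.
    """
    settings = {"max_depth": max_depth, "n_rounds": n_rounds,
                "learning_rate": learning_rate, "seed": seed, "target": target}
    close = _timed("XGB", settings)
    y = _target(cohort, target)
    X, forced, proxies = _design(cohort)
    if len(np.unique(y)) < 2:
        # constant outcome: no split can reduce impurity, nothing is selected
        return close([], {p: 0.0 for p in proxies})
    names = [f"f{i}" for i in range(X.shape[1])]
    model = XGBClassifier(
        max_depth=max_depth, n_estimators=n_rounds, learning_rate=learning_rate,
        random_state=seed, n_jobs=1, tree_method="hist", verbosity=0,
        base_score=0.5, eval_metric="logloss",
    )
    model.fit(pd.DataFrame(X, columns=names), y)
    gain = model.get_booster().get_score(importance_type="gain")
    scores = {}
    for i, p in enumerate(proxies):
        scores[p] = float(gain.get(f"f{len(forced) + i}", 0.0))
    selected = sorted([p for p, g in scores.items() if g > 0.0])
    return close(selected, scores)


# ------------------------------------------------------------------ stepwise

def _gram_rss(G: np.ndarray, Xy: np.ndarray, yy: float, idx: list[int]) -> float:
    """Residual sum of squares of OLS on the columns ``idx`` (Gram form)."""
    sub = np.ix_(idx, idx)
    b, *_ = np.linalg.lstsq(G[sub], Xy[idx], rcond=None)
    return float(yy - Xy[idx] @ b)


def _adj_r2(rss: float, tss: float, n: int, n_predictors: int) -> float:
    dof = n - n_predictors - 1
    if dof <= 0:
        return -np.inf
    return 1.0 - (rss / dof) / (tss / (n - 1))


def _stepwise(cohort: Cohort, forward: bool, target: str) -> SelectionResult:
    settings = {"criterion": "adjusted R2", "target": target}
    close = _timed("FS" if forward else "BE", settings)
    y = _target(cohort, target)
    X, forced, proxies = _design(cohort)
    n, p_total = X.shape
    Xc = np.column_stack([np.ones(n), X])  # intercept in column 0
    G = Xc.T @ Xc
    Xy = Xc.T @ y
    yy = float(y @ y)
    tss = float(((y - y.mean()) ** 2).sum())
    base_idx = list(range(1 + len(forced)))  # intercept + forced covariates
    proxy_col = {p: 1 + len(forced) + i for i, p in enumerate(proxies)}
    # candidates iterated in sorted name order => lexicographic tie-break
    ordered = sorted(proxies)

    if not forward and n <= p_total + 1:
        raise ValueError(
            "backward elimination needs n > number of predictors at the start; "
            "use forward selection instead"
        )

    current = set() if forward else set(ordered)

    def score(members: set[str]) -> float:
        idx = base_idx + [proxy_col[p] for p in sorted(members)]
        rss = _gram_rss(G, Xy, yy, idx)
        return _adj_r2(rss, tss, n, len(idx) - 1)

    best = score(current)
    improved = True
    while improved:
        improved = False
        if forward:
            moves = [p for p in ordered if p not in current]
            candidates = ((p, current | {p}) for p in moves)
        else:
            moves = [p for p in ordered if p in current]
            candidates = ((p, current - {p}) for p in moves)
        best_move, best_new = None, best
        for p, members in candidates:
            s = score(members)
            if s > best_new:  # strict improvement; ties keep earlier (lexicographic) move
                best_move, best_new = p, s
        if best_move is not None:
            current = current | {best_move} if forward else current - {best_move}
            best = best_new
            improved = True
    selected = sorted(current)
    return close(selected, {p: float(best) for p in selected})


def select_forward(cohort: Cohort, target: str = "outcome") -> SelectionResult:
    """Greedy additions while adjusted R-squared strictly increases."""
    return _stepwise(cohort, forward=True, target=target)


def select_backward(cohort: Cohort, target: str = "outcome") -> SelectionResult:
    """Greedy removals while adjusted R-squared strictly increases."""
    return _stepwise(cohort, forward=False, target=target)


# ----------------------------------------------------------- genetic algorithm

def _cv_accuracy(X: np.ndarray, y: np.ndarray, folds) -> float:
    accs = []
    for tr, te in folds:
        if len(np.unique(y[tr])) < 2:
            accs.append(float((y[te] == y[tr].mean().round()).mean()))
            continue
        model = LogisticRegression(C=np.inf, max_iter=500)
        model.fit(X[tr], y[tr])
        accs.append(float(model.score(X[te], y[te])))
    return float(np.mean(accs))


def select_genetic(
    cohort: Cohort,
    pop_size: int = 50,
    n_generations: int = 40,
    crossover_rate: float = 0.8,
    mutation_rate: float | None = None,
    cv_folds: int = 5,
    seed: int = 0,
    tournament_size: int = 3,
    target: str = "outcome",
    initial_population: np.ndarray | None = None,
) -> SelectionResult:
    """Binary-chromosome GA maximizing CV classification accuracy.

    Tournament selection, uniform crossover, per-bit flip mutation,
    elitism of one.  Fitness of a chromosome is the seeded ``cv_folds``-fold
    CV accuracy of an unpenalized logistic model on the forced covariates
    plus the chromosome's active proxies; fitness values are memoized so
    revisited chromosomes cost nothing.
    """
    if pop_size < 2:
        raise ValueError("pop_size must be >= 2")
    y = _target(cohort, target)
    X, forced, proxies = _design(cohort, standardize_labs=True)
    n_bits = len(proxies)
    if mutation_rate is None:
        mutation_rate = 1.0 / max(n_bits, 1)
    settings = {
        "pop_size": pop_size, "n_generations": n_generations,
        "crossover_rate": crossover_rate, "mutation_rate": mutation_rate,
        "cv_folds": cv_folds, "seed": seed, "target": target,
    }
    close = _timed("GA", settings)
    rng = np.random.default_rng(seed)
    folds = list(StratifiedKFold(cv_folds, shuffle=True, random_state=seed).split(X, y))
    nf = len(forced)
    cache: dict[bytes, float] = {}

    def fitness(chrom: np.ndarray) -> float:
        key = chrom.tobytes()
        if key not in cache:
            cols = np.r_[np.arange(nf), nf + np.flatnonzero(chrom)]
            cache[key] = _cv_accuracy(X[:, cols], y, folds)
        return cache[key]

    if initial_population is not None:
        pop = np.asarray(initial_population, dtype=np.uint8).copy()
        if pop.shape != (pop_size, n_bits):
            raise ValueError("initial_population must have shape (pop_size, n_proxies)")
    else:
        pop = (rng.random((pop_size, n_bits)) < 0.5).astype(np.uint8)
    fits = np.array([fitness(c) for c in pop])
    for _ in range(n_generations):
        elite = pop[int(np.argmax(fits))].copy()
        children = [elite]
        while len(children) < pop_size:
            parents = []
            for _ in range(2):
                contenders = rng.integers(0, pop_size, size=tournament_size)
                parents.append(pop[contenders[int(np.argmax(fits[contenders]))]].copy())
            a, b = parents
            if rng.random() < crossover_rate and n_bits > 0:
                mask = rng.random(n_bits) < 0.5
                a[mask], b[mask] = b[mask].copy(), a[mask]
            for child in (a, b):
                flips = rng.random(n_bits) < mutation_rate
                child[flips] ^= 1
                if len(children) < pop_size:
                    children.append(child)
        pop = np.array(children, dtype=np.uint8)
        fits = np.array([fitness(c) for c in pop])
    winner = pop[int(np.argmax(fits))]
    selected = [proxies[i] for i in np.flatnonzero(winner)]
    res = close(selected, {p: 1.0 for p in selected})
    res.settings["best_fitness"] = float(fits.max())
    return res


# ---------------------------------------------------------------- overlap

def overlap_matrix(
    results: list[SelectionResult],
) -> tuple[pd.DataFrame, pd.DataFrame | None]:
    """Pairwise intersection counts, plus agreement with the Bross set.

    The square matrix has set sizes on the diagonal and intersection
    counts off it.  The agreement table reports, per method,
    ``|method ∩ Bross| / |method|`` — ``None`` if no Bross result is given.
    """
    labels = [r.method for r in results]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate method labels in results")
    sets = {r.method: set(r.selected_proxies) for r in results}
    mat = pd.DataFrame(
        [[len(sets[a] & sets[b]) for b in labels] for a in labels],
        index=labels, columns=labels, dtype=int,
    )
    agreement = None
    if "Bross" in sets:
        rows = []
        for r in results:
            common = len(sets[r.method] & sets["Bross"])
            size = len(sets[r.method])
            rows.append({
                "method": r.method,
                "total_count": size,
                "common_with_bross": common,
                "rate_in_common": common / size if size else float("nan"),
            })
        agreement = pd.DataFrame(rows)
    return mat, agreement
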