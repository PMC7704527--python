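"""Genetic function approximation: GA search over descriptor subsets.

Candidate equations are multiple linear regressions on small descriptor
subsets; their fitness is Friedman's lack-of-fit (LOF), a mean squared error
penalised for equation size, so the search prefers equations that are both
accurate and small.  Only linear terms are considered — no splines or
quadratics — matching the shape of published QSAR equations this package
reproduces.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import DomainError
from .regression import FitStats, LinearModel, fit_ols

__all__ = ["GfaConfig", "RankedModel", "GfaResult", "lof", "evolve", "rank_models"]


def lof(sse: float, m: int, c: int, p: int, d: float = 0.5) -> float:
    """Friedman lack-of-fit score (SSE/M) / (1 - (c + d*p)/M)^2.

    ``m`` is the number of training compounds, ``c`` the number of
    non-intercept basis terms, ``p`` the total number of fitted parameters
    (intercept included) and ``d`` the user smoothing parameter controlling
    how strongly extra terms are penalised.
    """
    if m <= 0:
        raise DomainError(f"train count must be positive, got {m}")
    if sse < 0:
        raise DomainError(f"SSE must be non-negative, got {sse}")
    denom = 1.0 - (c + d * p) / m
    if denom <= 0:
        raise DomainError(
            f"over-parameterised equation: 1 - (c + d*p)/M = {denom:.4g} <= 0 "
            f"(c={c}, p={p}, d={d}, M={m})"
        )
    return (sse / m) / denom**2


@dataclass(frozen=True)
class GfaConfig:
    """Knobs of the genetic search.

    ``model_size_*`` bound the number of descriptors per equation;
    ``smoothing_d`` is Friedman's d.  ``count_intercept_in_p`` keeps the
    convention that c counts non-intercept terms while p counts every fitted
    parameter; switch it off to penalise descriptors only.
    A single ``seed`` drives all randomness.
    """

    population_size: int = 100
    generations: int = 200
    model_size_min: int = 3
    model_size_max: int = 5
    mutation_prob: float = 0.15
    smoothing_d: float = 0.5
    seed: int = 0
    n_elite: int = 2
    tournament_size: int = 2
    keep_top: int = 50
    count_intercept_in_p: bool = True

    def __post_init__(self):
        if self.model_size_min < 1 or self.model_size_max < self.model_size_min:
            raise ValueError("need 1 <= model_size_min <= model_size_max")
        if not 0 <= self.mutation_prob <= 1:
            raise ValueError("mutation_prob must be a probability")
        if self.smoothing_d < 0:
            raise ValueError("smoothing_d must be >= 0")
        if self.population_size < 2 or self.generations < 1:
            raise ValueError("population_size >= 2 and generations >= 1 required")

    def with_seed(self, seed: int) -> "GfaConfig":
        return replace(self, seed=seed)


@dataclass(frozen=True)
class RankedModel:
    """One candidate equation with its fit statistics and LOF score."""

    model: LinearModel
    stats: FitStats
    lof: float


@dataclass
class GfaResult:
    """Outcome of a GFA run: distinct candidate equations, best first."""

    ranked_models: list[RankedModel]
    best_lof_history: list[float]
    n_evaluated: int
    config: GfaConfig

    @property
    def best(self) -> RankedModel:
        return self.ranked_models[0]


def rank_models(candidates: list[RankedModel]) -> list[RankedModel]:
    """Sort candidates by ascending LOF; ties keep input order (stable)."""
    return sorted(candidates, key=lambda rm: rm.lof)


class _Evaluator:
    """Caches LOF evaluations of descriptor supports on one dataset."""

    def __init__(self, A: np.ndarray, y: np.ndarray, config: GfaConfig):
        self.A = A  # [1 | descriptors] design, full descriptor set
        self.y = y
        self.m = len(y)
        self.config = config
        self.cache: dict[tuple[int, ...], float] = {}
        self.order: dict[tuple[int, ...], int] = {}  # insertion index for ties

    def score(self, support: tuple[int, ...]) -> float:
        key = tuple(sorted(support))
        if key in self.cache:
            return self.cache[key]
        cols = np.concatenate(([0], np.asarray(key) + 1))
        A = self.A[:, cols]
        beta, _, rank, _ = np.linalg.lstsq(A, self.y, rcond=None)
        if rank < A.shape[1]:
            score = float("inf")  # collinear support: never competitive
        else:
            resid = self.y - A @ beta
            sse = float(resid @ resid)
            c = len(key)
            p = c + 1 if self.config.count_intercept_in_p else c
            score = lof(sse, self.m, c, p, self.config.smoothing_d)
        self.cache[key] = score
        self.order[key] = len(self.order)
        return score


def _random_support(rng, n_desc, config) -> tuple[int, ...]:
    size = int(rng.integers(config.model_size_min, config.model_size_max + 1))
    return tuple(sorted(rng.choice(n_desc, size=size, replace=False)))


def _crossover(rng, p1, p2, config) -> tuple[int, ...]:
    """Child support drawn from the union of two parents' descriptors."""
    union = sorted(set(p1) | set(p2))
    size = len(p1) if rng.random() < 0.5 else len(p2)
    size = min(max(size, config.model_size_min), config.model_size_max, len(union))
    idx = rng.choice(len(union), size=size, replace=False)
    return tuple(sorted(union[i] for i in idx))


def _mutate(rng, support, n_desc, config) -> tuple[int, ...]:
    support = list(support)
    outside = [j for j in range(n_desc) if j not in support]
    ops = []
    if len(support) < config.model_size_max and outside:
        ops.append("add")
    if len(support) > config.model_size_min:
        ops.append("remove")
    if outside:
        ops.append("swap")
    if not ops:
        return tuple(support)
    op = ops[rng.integers(len(ops))]
    if op == "add":
        support.append(outside[rng.integers(len(outside))])
    elif op == "remove":
        support.pop(rng.integers(len(support)))
    else:
        support[rng.integers(len(support))] = outside[rng.integers(len(outside))]
    return tuple(sorted(support))


def _tournament(rng, population, scores, k) -> tuple[int, ...]:
    idx = rng.integers(len(population), size=k)
    best = min(idx, key=lambda i: scores[i])
    return population[best]


def evolve(
    X: pd.DataFrame,
    y: pd.Series | np.ndarray,
    config: GfaConfig | None = None,
    initial_population: list[tuple] | None = None,
) -> GfaResult:
    """Run the genetic search for low-LOF descriptor subsets.

    ``X`` should already be pretreated (no constant or near-duplicate
    columns).  The run is fully reproducible from ``config.seed``.  An
    explicit ``initial_population`` (supports given as descriptor-name or
    column-index tuples) overrides the random initialisation; seeding it
    with *all* supports of one size and setting ``mutation_prob=0`` turns
    the search into an exhaustive enumeration of that size.

    Returns the distinct evaluated equations ranked by ascending LOF
    (capped at ``config.keep_top``) and the per-generation best-so-far LOF
    trace, which is non-increasing.
    """
    config = config or GfaConfig()
    n, n_desc = X.shape
    if config.model_size_max > n_desc:
        raise ValueError(
            f"model_size_max={config.model_size_max} exceeds descriptor "
            f"count {n_desc}"
        )
    if n < config.model_size_max + 2:
        raise ValueError(
            f"need more than {config.model_size_max + 2} compounds, got {n}"
        )
    if isinstance(y, pd.Series):
        y = y.reindex(X.index).to_numpy(dtype=float)
    else:
        y = np.asarray(y, dtype=float)

    rng = np.random.default_rng(config.seed)
    A = np.column_stack([np.ones(n), X.to_numpy(dtype=float)])
    ev = _Evaluator(A, y, config)
    name_to_col = {name: j for j, name in enumerate(X.columns)}

    if initial_population is not None:
        population = []
        for supp in initial_population:
            cols = tuple(
                sorted(name_to_col[s] if isinstance(s, str) else int(s) for s in supp)
            )
            population.append(cols)
    else:
        population = [
            _random_support(rng, n_desc, config)
            for _ in range(config.population_size)
        ]
    scores = [ev.score(s) for s in population]

    best_so_far = min(scores)
    history = [best_so_far]
    for _ in range(config.generations):
        new_pop: list[tuple[int, ...]] = []
        # elitism: carry the current best supports over unchanged
        elite_idx = sorted(range(len(population)), key=lambda i: scores[i])
        for i in elite_idx[: config.n_elite]:
            new_pop.append(population[i])
        while len(new_pop) < config.population_size:
            p1 = _tournament(rng, population, scores, config.tournament_size)
            p2 = _tournament(rng, population, scores, config.tournament_size)
            child = _crossover(rng, p1, p2, config)
            if rng.random() < config.mutation_prob:
                child = _mutate(rng, child, n_desc, config)
            new_pop.append(child)
        population = new_pop
        scores = [ev.score(s) for s in population]
        best_so_far = min(best_so_far, min(scores))
        history.append(best_so_far)

    # rank every distinct support ever evaluated; ties keep first-seen order
    finite = [
        (score, ev.order[supp], supp)
        for supp, score in ev.cache.items()
        if np.isfinite(score)
    ]
    finite.sort(key=lambda t: (t[0], t[1]))
    ranked: list[RankedModel] = []
    for score, _, supp in finite[: config.keep_top]:
        support_names = [X.columns[j] for j in supp]
        model, stats = fit_ols(X, y, support=support_names)
        ranked.append(RankedModel(model=model, stats=stats, lof=score))
    return GfaResult(
        ranked_models=ranked,
        best_lof_history=history,
        n_evaluated=len(ev.cache),
        config=config,
    )
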