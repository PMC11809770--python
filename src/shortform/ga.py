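"""Genetic-algorithm item selection.

Candidate short forms are bitstrings over the non-core items of a pool of
K items (core items are locked on in every member).  Fitness is
Cronbach's alpha of the subset multiplied by a polynomial length penalty

    penalty(k) = 1 - (k / K)**order,   order in {2, 3, 4, 5},

which lies in [0, 1]: the empty subset is unpenalized, the full pool is
fully penalized, and the polynomial order controls how hard long forms
are punished (order 3 is the default).  Internal consistency pushes the
subset to grow; the penalty pushes it to shrink; their product is the
selection criterion.

Each generation the worst ``cull_fraction`` of the population is removed,
the survivors breed by uniform crossover, offspring are mutated per bit,
and the single best member is carried over unchanged (elitism), so the
best-ever fitness trace is non-decreasing.  Evolution stops once the best
fitness has not improved for ``stagnation_limit`` generations.  Because
alpha depends on the data only through the item covariance matrix, the
full-pool covariance is computed once and subset alphas are read off
submatrices, with memoisation over revisited bitstrings.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .instrument import InstrumentError, ResponseMatrix
from .reliability import alpha_from_covariance

__all__ = ["GaParams", "SubsetSolution", "penalty", "fitness", "evolve", "multi_start"]


@dataclass(frozen=True)
class GaParams:
    """Tuning knobs of the evolutionary search.

    ``max_items`` is K, the size of the full item pool the penalty is
    measured against (46 for the CLCF Part A pool).  ``mutation_rate=None``
    resolves to 1/K at run time.
    """

    population_size: int = 200
    cull_fraction: float = 0.5
    mutation_rate: float | None = None  # None -> 1/K
    crossover: str = "uniform"
    stagnation_limit: int = 100
    penalty_order: int = 3
    penalty_formula: str = "ratio"  # "ratio" (default) or "raw" for audit
    max_items: int | None = None  # None -> pool size of the supplied data
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.cull_fraction < 1:
            raise ValueError("cull_fraction must be in (0, 1)")
        if self.mutation_rate is not None and not 0 <= self.mutation_rate <= 1:
            raise ValueError("mutation_rate must be in [0, 1]")
        if self.penalty_order not in (2, 3, 4, 5):
            raise ValueError("penalty_order must be one of 2, 3, 4, 5")
        if self.stagnation_limit < 1:
            raise ValueError("stagnation_limit must be >= 1")


@dataclass(frozen=True)
class SubsetSolution:
    """An item subset with its fitness decomposition."""

    item_ids: frozenset[str]
    alpha: float
    penalty: float
    fitness: float
    generation_found: int = 0

    @property
    def size(self) -> int:
        return len(self.item_ids)


def penalty(k: int, K: int, order: int = 3, formula: str = "ratio") -> float:
    """Length penalty for a subset of ``k`` items out of a pool of ``K``.

    The default ``"ratio"`` form is 1 - (k/K)**order, clamped to [0, 1].
    ``"raw"`` evaluates the literal difference form 1 - (k - K)**order,
    retained only for auditing; it is unbounded and not used by default.
    """
    if K <= 0:
        raise ValueError("K must be positive")
    if not 0 <= k <= K:
        raise ValueError(f"subset size {k} outside [0, {K}]")
    if formula == "ratio":
        return float(np.clip(1.0 - (k / K) ** order, 0.0, 1.0))
    if formula == "raw":
        return float(1.0 - (k - K) ** order)
    raise ValueError(f"unknown penalty formula {formula!r}")


def _subset_alpha(cov: np.ndarray, idx: np.ndarray) -> float:
    sub = cov[np.ix_(idx, idx)]
    total = sub.sum()
    if total <= 0:
        return -np.inf
    k = idx.size
    return k / (k - 1) * (1.0 - np.trace(sub) / total)


def fitness(
    subset,
    responses: ResponseMatrix,
    params: GaParams,
    core=frozenset(),
) -> SubsetSolution:
    """Evaluate one subset: alpha times the length penalty.

    ``subset`` must contain every core item and at least two items.
    """
    subset = frozenset(subset)
    core = frozenset(core)
    if not core <= subset:
        raise InstrumentError(f"subset is missing core item(s) {sorted(core - subset)}")
    if len(subset) < 2:
        raise InstrumentError("fitness needs at least 2 items")
    if not responses.is_complete:
        raise InstrumentError("GA fitness requires complete data; impute first")
    K = params.max_items if params.max_items is not None else responses.n_items
    cov = np.cov(responses.values, rowvar=False, ddof=1)
    idx = np.array([responses.item_ids.index(i) for i in sorted(subset)])
    a = _subset_alpha(cov, idx)
    p = penalty(len(subset), K, params.penalty_order, params.penalty_formula)
    return SubsetSolution(item_ids=subset, alpha=a, penalty=p, fitness=a * p)


def _solution_key(sol: SubsetSolution) -> tuple:
    # ranking key: fitness desc, then fewer items, then lexicographic ids
    return (-sol.fitness, sol.size, tuple(sorted(sol.item_ids)))


def evolve(
    responses: ResponseMatrix,
    core=frozenset(),
    params: GaParams = GaParams(),
) -> tuple[SubsetSolution, np.ndarray]:
    """Run the GA; return the best-ever solution and the per-generation
    best-fitness trace.

    Fully reproducible from ``params.seed``.  Members with fewer than two
    items score -inf rather than erroring.  Ties in fitness are broken by
    preferring fewer items, then lexicographically smaller id sets.
    """
    if not responses.is_complete:
        raise InstrumentError("evolve requires complete data; impute first")
    item_ids = list(responses.item_ids)
    core = frozenset(core)
    unknown = core - set(item_ids)
    if unknown:
        raise InstrumentError(f"core contains unknown item id(s): {sorted(unknown)}")
    free_ids = [i for i in item_ids if i not in core]
    if len(free_ids) < 1:
        raise InstrumentError("pool must contain at least one non-core item")
    cov = np.cov(responses.values, rowvar=False, ddof=1)
    if np.any(np.diag(cov) <= 0):
        dead = [item_ids[j] for j in np.flatnonzero(np.diag(cov) <= 0)]
        raise InstrumentError(f"zero-variance item(s) in pool: {dead}")

    K = params.max_items if params.max_items is not None else len(item_ids)
    mut = params.mutation_rate if params.mutation_rate is not None else 1.0 / K
    core_idx = np.array([item_ids.index(i) for i in sorted(core)], dtype=int)
    free_idx = np.array([item_ids.index(i) for i in free_ids], dtype=int)
    n_free = free_idx.size
    rng = np.random.default_rng(params.seed)

    pen = np.array(
        [penalty(k, K, params.penalty_order, params.penalty_formula) for k in range(K + 1)]
    )
    cache: dict[bytes, tuple[float, float, float]] = {}

    def score(bits: np.ndarray) -> tuple[float, float, float]:
        key = bits.tobytes()
        hit = cache.get(key)
        if hit is not None:
            return hit
        idx = np.concatenate([core_idx, free_idx[bits.astype(bool)]])
        k = idx.size
        if k < 2:
            out = (-np.inf, np.nan, np.nan)
        else:
            a = _subset_alpha(cov, idx)
            p = pen[k]
            out = (a * p, a, p)
        cache[key] = out
        return out

    pop = rng.integers(0, 2, size=(params.population_size, n_free), dtype=np.int8)
    n_cull = max(1, int(round(params.cull_fraction * params.population_size)))
    n_keep = params.population_size - n_cull

    def bits_to_solution(bits: np.ndarray, gen: int) -> SubsetSolution:
        f, a, p = score(bits)
        ids = frozenset(
            [item_ids[j] for j in core_idx]
            + [item_ids[j] for j in free_idx[bits.astype(bool)]]
        )
        return SubsetSolution(item_ids=ids, alpha=a, penalty=p, fitness=f,
                              generation_found=gen)

    best: SubsetSolution | None = None
    trace: list[float] = []
    stagnant = 0
    gen = 0
    while True:
        fits = np.array([score(b)[0] for b in pop])
        # rank: fitness desc, then fewer items, then lexicographic bits
        sizes = pop.sum(axis=1)
        order = sorted(
            range(len(pop)),
            key=lambda i: (-fits[i], sizes[i], tuple(pop[i])),
        )
        gen_best = bits_to_solution(pop[order[0]], gen)
        improved = best is None or gen_best.fitness > best.fitness
        if best is None or _solution_key(gen_best) < _solution_key(best):
            best = gen_best
        stagnant = 0 if improved else stagnant + 1
        trace.append(best.fitness)
        if stagnant >= params.stagnation_limit:
            break
        # breed next generation: survivors + offspring, elite preserved
        survivors = pop[order[:n_keep]]
        children = np.empty((n_cull, n_free), dtype=np.int8)
        pa = rng.integers(0, n_keep, size=n_cull)
        pb = rng.integers(0, n_keep, size=n_cull)
        mask = rng.random((n_cull, n_free)) < 0.5
        children[:] = np.where(mask, survivors[pa], survivors[pb])
        nxt = np.vstack([survivors, children])
        flip = rng.random(nxt.shape) < mut
        flip[0, :] = False  # elitism: best member untouched
        nxt = np.where(flip, 1 - nxt, nxt).astype(np.int8)
        pop = nxt
        gen += 1
    return best, np.asarray(trace)


@dataclass(frozen=True)
class MultiStartResult:
    solutions: list[SubsetSolution]
    agreement: bool

    @property
    def best(self) -> SubsetSolution:
        return min(self.solutions, key=_solution_key)


def multi_start(
    responses: ResponseMatrix,
    core=frozenset(),
    params: GaParams = GaParams(),
    n_starts: int = 6,
) -> MultiStartResult:
    """Independent GA runs from ``n_starts`` seeds.

    ``agreement`` is True iff every run returned the identical item set —
    the convergence check used to rule out local optima.  Seeds are derived
    deterministically from ``params.seed``.
    """
    if n_starts < 2:
        raise ValueError("multi_start needs n_starts >= 2")
    sols = []
    for s in range(n_starts):
        run_seed = int(np.random.SeedSequence([params.seed, s]).generate_state(1)[0] % (2**31))
        sol, _ = evolve(responses, core, replace(params, seed=run_seed))
        sols.append(sol)
    agreement = len({sol.item_ids for sol in sols}) == 1
    return MultiStartResult(solutions=sols, agreement=agreement)
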