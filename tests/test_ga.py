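"""Genetic-algorithm item selection: penalty, fitness and evolution."""

import itertools

import numpy as np
import pytest

import shortform as sf
from shortform.ga import MultiStartResult, _solution_key
from shortform.instrument import InstrumentError


def exhaustive_best(rm, core, params):
    """Brute-force oracle: evaluate every subset of the non-core items."""
    free = [i for i in rm.item_ids if i not in core]
    best = None
    for r in range(len(free) + 1):
        for combo in itertools.combinations(free, r):
            subset = frozenset(core) | frozenset(combo)
            if len(subset) < 2:
                continue
            sol = sf.fitness(subset, rm, params, core=core)
            if best is None or _solution_key(sol) < _solution_key(best):
                best = sol
    return best


class TestPenalty:
    @pytest.mark.parametrize("k,K,order,expected", [
        (0, 46, 3, 1.0),
        (46, 46, 3, 0.0),
        (15, 46, 3, 1 - (15 / 46) ** 3),
    ])
    def test_ratio_form(self, k, K, order, expected):
        assert sf.penalty(k, K, order) == pytest.approx(expected)

    def test_order_controls_length_pressure(self):
        # higher order -> weaker penalty at the same length -> longer forms
        vals = [sf.penalty(15, 46, o) for o in (2, 3, 4, 5)]
        assert all(np.diff(vals) > 0)

    def test_raw_variant_is_literal_difference(self):
        assert sf.penalty(15, 46, 3, formula="raw") == 1 - (15 - 46) ** 3

    def test_oversized_subset_rejected(self):
        with pytest.raises(ValueError):
            sf.penalty(47, 46, 3)

    def test_bounded_on_admissible_sizes(self):
        for k in range(47):
            assert 0.0 <= sf.penalty(k, 46, 3) <= 1.0


class TestFitness:
    def test_full_pool_fitness_zero(self, rng, likert_factory):
        rm = likert_factory(rng, 100, np.full(6, 0.6))
        params = sf.GaParams()
        sol = sf.fitness(frozenset(rm.item_ids), rm, params)
        assert sol.fitness == 0.0 and sol.penalty == 0.0

    def test_equal_size_ranking_matches_alpha(self, rng, likert_factory):
        rm = likert_factory(rng, 100, np.array([0.8, 0.8, 0.8, 0.3, 0.3, 0.3]))
        params = sf.GaParams()
        strong = sf.fitness(frozenset(rm.item_ids[:3]), rm, params)
        weak = sf.fitness(frozenset(rm.item_ids[3:]), rm, params)
        assert (strong.fitness > weak.fitness) == (strong.alpha > weak.alpha)

    def test_decomposes_as_alpha_times_penalty(self, rng, likert_factory):
        rm = likert_factory(rng, 100, np.full(8, 0.6))
        params = sf.GaParams(max_items=46)
        subset = frozenset(rm.item_ids[:5])
        sol = sf.fitness(subset, rm, params)
        alpha = sf.cronbach_alpha(rm.subset(sorted(subset)).values)
        assert sol.fitness == pytest.approx(alpha * sf.penalty(5, 46, 3), abs=1e-12)

    def test_missing_core_item_rejected(self, rng, likert_factory):
        rm = likert_factory(rng, 50, np.full(4, 0.6))
        with pytest.raises(InstrumentError, match="core"):
            sf.fitness(frozenset(rm.item_ids[1:]), rm, sf.GaParams(),
                       core=frozenset([rm.item_ids[0]]))


class TestEvolve:
    def test_matches_exhaustive_search(self, rng, likert_factory):
        # small pool (10 items): GA must hit the global optimum
        for seed in range(3):
            loadings = rng.uniform(0.2, 0.8, size=10)
            rm = likert_factory(rng, 300, loadings)
            params = sf.GaParams(seed=seed)
            best, _ = sf.evolve(rm, frozenset(), params)
            oracle = exhaustive_best(rm, frozenset(), params)
            assert best.fitness == pytest.approx(oracle.fitness, abs=1e-12)
            assert best.item_ids == oracle.item_ids

    def test_core_items_always_selected(self, rng, likert_factory):
        rm = likert_factory(rng, 200, np.full(12, 0.5))
        core = frozenset(rm.item_ids[:3])
        best, _ = sf.evolve(rm, core, sf.GaParams(seed=1))
        assert core <= best.item_ids

    def test_best_fitness_trace_nondecreasing(self, rng, likert_factory):
        rm = likert_factory(rng, 150, rng.uniform(0.2, 0.7, size=10))
        _, trace = sf.evolve(rm, frozenset(), sf.GaParams(seed=5))
        assert np.all(np.diff(trace) >= 0)

    def test_stagnation_stopping_contract(self, rng, likert_factory):
        rm = likert_factory(rng, 150, rng.uniform(0.2, 0.7, size=8))
        limit = 40
        _, trace = sf.evolve(rm, frozenset(), sf.GaParams(seed=2, stagnation_limit=limit))
        assert len(trace) > limit
        tail = trace[-limit:]
        assert np.all(tail == tail[0])

    def test_reproducible_from_seed(self, rng, likert_factory):
        rm = likert_factory(rng, 150, rng.uniform(0.3, 0.7, size=9))
        params = sf.GaParams(seed=11)
        a, trace_a = sf.evolve(rm, frozenset(), params)
        b, trace_b = sf.evolve(rm, frozenset(), params)
        assert a.item_ids == b.item_ids
        assert np.array_equal(trace_a, trace_b)

    def test_zero_variance_pool_rejected(self):
        vals = np.ones((30, 4))
        vals[:, 0] = np.tile([1, 2], 15)
        rm = sf.ResponseMatrix(vals, list("abcd"))
        with pytest.raises(InstrumentError, match="zero-variance"):
            sf.evolve(rm, frozenset(), sf.GaParams())


class TestMultiStart:
    def test_identical_seeds_identical_solutions(self, rng, likert_factory):
        rm = likert_factory(rng, 150, rng.uniform(0.3, 0.7, size=8))
        params = sf.GaParams(seed=4)
        a, _ = sf.evolve(rm, frozenset(), params)
        b, _ = sf.evolve(rm, frozenset(), params)
        assert a.item_ids == b.item_ids

    def test_flat_landscape_reports_disagreement_without_error(self, rng):
        # all-noise items: many near-ties; agreement may be False but the
        # indicator is reported, never an error
        vals = rng.integers(1, 6, size=(80, 10)).astype(float)
        rm = sf.ResponseMatrix(vals, [f"n{j}" for j in range(10)])
        result = sf.multi_start(rm, frozenset(), sf.GaParams(seed=0), n_starts=3)
        assert isinstance(result, MultiStartResult)
        assert isinstance(result.agreement, bool)

    def test_requires_two_starts(self, rng, likert_factory):
        rm = likert_factory(rng, 60, np.full(5, 0.5))
        with pytest.raises(ValueError):
            sf.multi_start(rm, frozenset(), sf.GaParams(), n_starts=1)
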