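"""Rating Scale Model estimation and the caregiver/child comparison table."""

import numpy as np
import pandas as pd
import pytest
from scipy import optimize, stats

import shortform as sf
from shortform.rsm import rsm_category_probs


@pytest.fixture(scope="module")
def small_fit():
    rng = np.random.default_rng(7)
    diffs = np.linspace(-1.5, 1.5, 5)
    tau = np.array([-0.9, 0.1, 0.8])
    tau = tau - tau.mean()
    persons = rng.standard_normal(800)
    X = sf.simulate_rsm(diffs, tau, persons, seed=3)
    return diffs, tau, sf.fit_rsm(X)


class TestCategoryProbs:
    def test_probabilities_normalize(self):
        P = rsm_category_probs([-1.0, 0.0, 2.0], [0.5, -0.5], [-0.6, 0.0, 0.6])
        assert P.sum(axis=2) == pytest.approx(np.ones((3, 2)))

    def test_extreme_person_hits_top_category(self):
        P = rsm_category_probs([30.0], [0.0], [-0.5, 0.5])
        assert P[0, 0, -1] == pytest.approx(1.0, abs=1e-8)

    def test_symmetric_distribution_at_item_location(self):
        # symmetric thresholds, person at the item difficulty: category
        # distribution symmetric around the middle category
        P = rsm_category_probs([0.7], [0.7], [-0.8, 0.0, 0.8])[0, 0]
        assert P[0] == pytest.approx(P[3])
        assert P[1] == pytest.approx(P[2])


class TestSimulateRsm:
    def test_empirical_frequencies_match_model(self):
        rng = np.random.default_rng(11)
        diffs = np.linspace(-2, 2, 7)
        tau = np.array([-0.5, 0.0, 0.5])
        theta = 0.3
        persons = np.full(2000, theta)
        X = sf.simulate_rsm(diffs, tau, persons, seed=5)
        P = rsm_category_probs([theta], diffs, tau)[0]
        for i in range(7):
            for x in range(4):
                assert (X[:, i] == x).mean() == pytest.approx(P[i, x], abs=0.02)

    def test_missing_design_cells_are_nan(self):
        mask = np.zeros((10, 3), dtype=bool)
        mask[0, 0] = mask[5, 2] = True
        X = sf.simulate_rsm([0, 0.5, -0.5], [-0.3, 0.3],
                            np.zeros(10), missing_design=mask, seed=1)
        assert np.isnan(X[0, 0]) and np.isnan(X[5, 2])
        assert np.isnan(X).sum() == 2


class TestFit:
    def test_identical_items_get_equal_difficulties(self):
        rng = np.random.default_rng(2)
        col = rng.integers(0, 4, size=300).astype(float)
        X = np.column_stack([col, col, rng.integers(0, 4, size=300)])
        fit = sf.fit_rsm(X)
        d = fit.item_difficulties.to_numpy()
        assert d[0] == pytest.approx(d[1], abs=1e-4)

    def test_loglik_nondecreasing_over_em(self, small_fit):
        _, _, fit = small_fit
        assert np.all(np.diff(fit.loglik_trace) >= -1e-8)

    def test_difficulty_recovery(self, small_fit):
        diffs, tau, fit = small_fit
        err = np.abs(fit.item_difficulties.to_numpy() - diffs).mean()
        assert err < 0.15
        assert fit.category_thresholds.sum() == pytest.approx(0.0, abs=1e-8)
        assert (fit.difficulty_se > 0).all()

    def test_reversed_categories_negate_difficulties(self, small_fit):
        diffs, tau, _ = small_fit
        rng = np.random.default_rng(9)
        persons = rng.standard_normal(1500)
        X = sf.simulate_rsm(diffs, tau, persons, seed=13)
        m = 4
        fit_fwd = sf.fit_rsm(X)
        fit_rev = sf.fit_rsm((m - 1) - X)
        assert fit_rev.item_difficulties.to_numpy() == pytest.approx(
            -fit_fwd.item_difficulties.to_numpy(), abs=0.02
        )

    def test_dichotomous_case_matches_independent_rasch_mml(self):
        # special-case oracle: a from-scratch dichotomous Rasch marginal ML
        # fit (direct quadrature + optimizer), written independently here
        rng = np.random.default_rng(21)
        diffs = np.array([-1.0, -0.3, 0.4, 1.1])
        persons = rng.standard_normal(1500)
        p = 1 / (1 + np.exp(-(persons[:, None] - diffs[None, :])))
        X = (rng.random((1500, 4)) < p).astype(float)

        nodes = np.linspace(-6, 6, 61)
        w = stats.norm.pdf(nodes)
        w /= w.sum()

        def negll(beta):
            pr = 1 / (1 + np.exp(-(nodes[:, None] - beta[None, :])))  # (Q, I)
            logl = X[None, :, :] * np.log(pr[:, None, :]) + (
                1 - X[None, :, :]
            ) * np.log(1 - pr[:, None, :])
            L = logl.sum(axis=2)  # (Q, n)
            return -np.log(np.einsum("q,qn->n", w, np.exp(L))).sum()

        oracle = optimize.minimize(negll, np.zeros(4), method="BFGS").x
        fit = sf.fit_rsm(X)
        assert fit.item_difficulties.to_numpy() == pytest.approx(oracle, abs=0.05)

    def test_single_category_item_excluded_with_warning(self):
        rng = np.random.default_rng(3)
        X = rng.integers(0, 3, size=(100, 3)).astype(float)
        X[:, 1] = 2.0
        with pytest.warns(UserWarning, match="single observed category"):
            fit = sf.fit_rsm(X, n_categories=3)
        assert fit.excluded_items == ["item2"]
        assert len(fit.item_ids) == 2

    def test_person_scores_track_totals(self, small_fit):
        # EAP scores should order persons like their observed sum scores
        diffs, tau, fit = small_fit
        rng = np.random.default_rng(7)
        persons = rng.standard_normal(800)
        X = sf.simulate_rsm(diffs, tau, persons, seed=3)
        totals = X.sum(axis=1)
        r = np.corrcoef(totals, fit.person_scores.to_numpy())[0, 1]
        assert r > 0.95


class TestDifficultyComparison:
    def test_self_comparison_zero_differences(self, small_fit):
        _, _, fit = small_fit
        table, dropped = sf.difficulty_comparison(fit, fit)
        assert table["difference"].to_numpy() == pytest.approx(np.zeros(len(table)))
        assert dropped == []

    def test_planted_shift_items_show_largest_differences(self):
        rng = np.random.default_rng(17)
        diffs = np.linspace(-1, 1, 6)
        tau = np.array([-0.6, 0.0, 0.6])
        persons_a = rng.standard_normal(1500)
        persons_b = rng.standard_normal(1500)
        shifted = diffs.copy()
        shifted[[1, 4]] += 0.8
        Xa = sf.simulate_rsm(diffs, tau, persons_a, seed=1)
        Xb = sf.simulate_rsm(shifted, tau, persons_b, seed=2)
        fit_a, fit_b = sf.fit_rsm(Xa), sf.fit_rsm(Xb)
        table, _ = sf.difficulty_comparison(fit_a, fit_b)
        top2 = set(table["difference"].nlargest(2).index)
        assert top2 == {"item2", "item5"}

    def test_nonoverlapping_items_listed(self, small_fit):
        _, _, fit = small_fit
        rng = np.random.default_rng(5)
        X = sf.simulate_rsm([0.0, 0.5], [-0.5, 0.0, 0.5],
                            rng.standard_normal(400), seed=4)
        other = sf.fit_rsm(pd.DataFrame(X, columns=["item1", "extra"]))
        table, dropped = sf.difficulty_comparison(fit, other)
        assert list(table.index) == ["item1"]
        assert "extra" in dropped
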