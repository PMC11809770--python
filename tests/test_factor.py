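"""Polychoric correlation and ML exploratory factor analysis."""

import numpy as np
import pandas as pd
import pytest
from scipy import optimize, stats

import shortform as sf
from shortform.factor import PolychoricMatrix, _cell_probs
from shortform.instrument import InstrumentError


def discretize(z, thresholds):
    return np.searchsorted(np.asarray(thresholds), z)


class TestBvnCdf:
    def test_matches_scipy_reference(self, rng):
        for _ in range(50):
            h, k = rng.normal(0, 1.5, size=2)
            rho = rng.uniform(-0.95, 0.95)
            ref = stats.multivariate_normal.cdf(
                [h, k], mean=[0, 0], cov=[[1, rho], [rho, 1]]
            )
            assert float(sf.bvn_cdf(h, k, rho)) == pytest.approx(ref, abs=1e-10)

    def test_infinite_edges_reduce_to_univariate(self):
        assert float(sf.bvn_cdf(np.inf, 0.3, 0.5)) == pytest.approx(stats.norm.cdf(0.3))
        assert float(sf.bvn_cdf(-np.inf, 0.3, 0.5)) == 0.0

    def test_cell_probabilities_sum_to_one(self):
        P = _cell_probs(np.array([-1.0, 0.5]), np.array([-0.3, 0.2, 1.1]), 0.4)
        assert P.sum() == pytest.approx(1.0)


class TestPolychoricPair:
    def test_independent_items_near_zero(self, rng):
        x = rng.integers(0, 4, size=5000)
        y = rng.integers(0, 5, size=5000)
        rho, _, _ = sf.polychoric_pair(pd.crosstab(x, y).to_numpy())
        assert abs(rho) < 0.05

    def test_identical_columns_approach_one(self, rng):
        x = rng.integers(0, 4, size=500)
        rho, _, _ = sf.polychoric_pair(pd.crosstab(x, x).to_numpy())
        assert rho > 0.99

    def test_recovers_latent_correlation(self, rng):
        z = rng.multivariate_normal([0, 0], [[1, 0.5], [0.5, 1]], size=5000)
        x = discretize(z[:, 0], [-1.0, 0.0, 1.0])
        y = discretize(z[:, 1], [-0.5, 0.5])
        rho, _, _ = sf.polychoric_pair(pd.crosstab(x, y).to_numpy())
        assert rho == pytest.approx(0.5, abs=0.05)

    def test_two_by_two_equals_tetrachoric(self, rng):
        # independent tetrachoric oracle: solve P(X=1,Y=1) = upper orthant
        # probability of the bivariate normal at the marginal thresholds
        z = rng.multivariate_normal([0, 0], [[1, 0.4], [0.4, 1]], size=2000)
        x = (z[:, 0] > 0.3).astype(int)
        y = (z[:, 1] > -0.2).astype(int)
        table = pd.crosstab(x, y).to_numpy().astype(float)
        n = table.sum()
        t1 = stats.norm.ppf(table[0].sum() / n)
        t2 = stats.norm.ppf(table[:, 0].sum() / n)
        p11 = table[1, 1] / n

        def gap(rho):
            upper = (1 - stats.norm.cdf(t1) - stats.norm.cdf(t2)
                     + stats.multivariate_normal.cdf(
                         [t1, t2], mean=[0, 0], cov=[[1, rho], [rho, 1]]))
            return upper - p11

        tetra = optimize.brentq(gap, -0.999, 0.999)
        rho, _, _ = sf.polychoric_pair(table)
        assert rho == pytest.approx(tetra, abs=1e-4)

    def test_invariant_to_empty_boundary_categories(self, rng):
        z = rng.multivariate_normal([0, 0], [[1, 0.5], [0.5, 1]], size=1000)
        x = discretize(z[:, 0], [-1.0, 1.0])
        y = discretize(z[:, 1], [-1.0, 1.0])
        table = pd.crosstab(x, y).to_numpy()
        padded = np.zeros((table.shape[0] + 1, table.shape[1] + 1), dtype=int)
        padded[:-1, 1:] = table  # empty last row, empty first column
        rho_a, _, _ = sf.polychoric_pair(table)
        rho_b, _, _ = sf.polychoric_pair(padded)
        assert rho_a == pytest.approx(rho_b, abs=1e-10)

    def test_degenerate_margin_flagged(self):
        with pytest.raises(InstrumentError, match="one category"):
            sf.polychoric_pair(np.array([[10, 20], [0, 0]]))


class TestPolychoricMatrix:
    def test_two_item_matrix_consistent_with_pair(self, rng, likert_factory):
        rm = likert_factory(rng, 400, np.array([0.7, 0.7]))
        poly = sf.polychoric_matrix(rm)
        X = rm.values.astype(int)
        rho, _, _ = sf.polychoric_pair(pd.crosstab(X[:, 0], X[:, 1]).to_numpy())
        assert poly.values[0, 1] == pytest.approx(rho, abs=1e-10)

    def test_one_factor_offdiagonals_near_loading_product(self, rng, likert_factory):
        lam = 0.7
        rm = likert_factory(rng, 5000, np.full(4, lam))
        poly = sf.polychoric_matrix(rm)
        off = poly.values[np.triu_indices(4, 1)]
        assert np.all(np.abs(off - lam**2) < 0.05)

    def test_smoothed_matrix_is_psd(self):
        R = np.array([[1.0, 0.9, -0.9], [0.9, 1.0, 0.9], [-0.9, 0.9, 1.0]])
        from shortform.factor import _nearest_psd_corr

        S = _nearest_psd_corr(R)
        assert np.linalg.eigvalsh(S).min() >= -1e-10
        assert np.allclose(np.diag(S), 1.0)


class TestEfa:
    def test_identity_matrix_eigenvalues_all_one(self):
        poly = PolychoricMatrix(item_ids=list("abcd"), values=np.eye(4), thresholds={})
        res = sf.efa_ml(poly, n_factors=1, n_obs=100)
        assert res.eigenvalues == pytest.approx(np.ones(4))

    def test_single_factor_loading_recovery(self, rng, likert_factory):
        lam = 0.7
        rm = likert_factory(rng, 5000, np.full(6, lam))
        poly = sf.polychoric_matrix(rm)
        res = sf.efa_ml(poly, n_factors=1, n_obs=5000)
        assert np.all(np.abs(res.loadings.to_numpy().ravel() - lam) < 0.05)

    def test_two_factor_structure_fails_unidimensionality(self, rng):
        # two orthogonal factors, 4 items each
        n = 2000
        t1, t2 = rng.standard_normal((2, n))
        thr = stats.norm.ppf(np.arange(1, 5) / 5)
        cols = []
        for t in (t1, t2):
            for _ in range(4):
                y = 0.8 * t + 0.6 * rng.standard_normal(n)
                cols.append(1 + np.searchsorted(thr, y))
        rm = sf.ResponseMatrix(np.array(cols, dtype=float).T,
                               [f"i{j}" for j in range(8)])
        poly = sf.polychoric_matrix(rm)
        ok, info = sf.unidimensionality_check(np.linalg.eigvalsh(poly.values))
        assert not ok
        assert info["second_eigenvalue"] > 1


class TestUnidimensionalityCheck:
    @pytest.mark.parametrize("ev,expected", [
        ([6.1, 0.98, 0.5], True),
        ([3.0, 1.5, 0.5], False),
        (np.ones(5), False),  # boundary: exactly 1 fails the strict rule
    ])
    def test_second_eigenvalue_rule(self, ev, expected):
        ok, info = sf.unidimensionality_check(ev)
        assert ok is expected

    def test_needs_two_eigenvalues(self):
        with pytest.raises(InstrumentError):
            sf.unidimensionality_check([2.0])
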