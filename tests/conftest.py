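import numpy as np
import pytest

import shortform as sf


@pytest.fixture(scope="session")
def clcf() -> sf.Instrument:
    return sf.load_packaged_instrument()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20230705)


@pytest.fixture(scope="session")
def likert_factory():
    """Factory fixture building one-factor ordinal matrices."""
    return make_likert_matrix


def make_likert_matrix(
    rng: np.random.Generator,
    n: int,
    loadings,
    n_categories: int = 5,
    ids=None,
) -> sf.ResponseMatrix:
    """One-factor ordinal data with equal-probability thresholds (codes from 1)."""
    loadings = np.asarray(loadings, dtype=float)
    k = loadings.size
    from scipy.stats import norm

    thr = norm.ppf(np.arange(1, n_categories) / n_categories)
    trait = rng.standard_normal(n)
    cols = np.empty((n, k))
    for j, lam in enumerate(loadings):
        y = lam * trait + np.sqrt(1 - lam * lam) * rng.standard_normal(n)
        cols[:, j] = 1 + np.searchsorted(thr, y)
    if ids is None:
        ids = [f"it{j + 1:02d}" for j in range(k)]
    return sf.ResponseMatrix(cols, ids)
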