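"""Polychoric correlations and exploratory factor analysis.

The polychoric correlation treats two ordinal items as discretizations of
a latent bivariate normal and estimates the latent correlation by two-step
maximum likelihood: thresholds come from the inverse-normal of the
marginal cumulative proportions, then the correlation maximizes the
multinomial likelihood of the observed cross-table, with cell
probabilities from the bivariate normal CDF (evaluated via Owen's T
function, which is fast and vectorised).  The 2x2 case reduces to the
tetrachoric correlation.

ML factor extraction on the resulting correlation matrix is delegated to
``statsmodels.multivariate.factor.Factor``; eigenvalues of the polychoric
matrix itself are reported alongside the factor solution, and a scale is
declared unidimensional when the second eigenvalue is strictly below 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import owens_t

from .instrument import InstrumentError, ResponseMatrix

__all__ = [
    "bvn_cdf",
    "polychoric_pair",
    "polychoric_matrix",
    "PolychoricMatrix",
    "efa_ml",
    "EfaResult",
    "unidimensionality_check",
]

_RHO_BOUND = 0.9999


def bvn_cdf(h, k, rho: float):
    """Standard bivariate normal CDF P(X <= h, Y <= k) at correlation rho.

    Uses the Owen's T representation; accurate to ~1e-13 and vectorised in
    h and k.  Infinite arguments are handled (reducing to univariate CDFs).
    """
    h = np.asarray(h, dtype=float)
    k = np.asarray(k, dtype=float)
    rho = float(rho)
    if abs(rho) < 1e-13:
        return stats.norm.cdf(h) * stats.norm.cdf(k)
    if abs(rho) >= 1.0:
        rho = np.sign(rho) * _RHO_BOUND
    # Owen's T formula is singular at exactly 0; a 1e-13 nudge is far below
    # the accuracy of the representation itself.
    h = np.where(h == 0, 1e-13, h)
    k = np.where(k == 0, 1e-13, k)
    denom = np.sqrt(1.0 - rho * rho)
    with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
        ah = np.where(np.isfinite(h), (k - rho * h) / np.where(h == 0, 1, h) / denom, 0.0)
        ak = np.where(np.isfinite(k), (h - rho * k) / np.where(k == 0, 1, k) / denom, 0.0)
    out = 0.5 * (stats.norm.cdf(h) + stats.norm.cdf(k))
    out = out - np.where(np.isfinite(h), owens_t(np.where(np.isfinite(h), h, 0.0), ah), 0.0)
    out = out - np.where(np.isfinite(k), owens_t(np.where(np.isfinite(k), k, 0.0), ak), 0.0)
    out = out - np.where(h * k < 0, 0.5, 0.0)
    # infinite edges: P(X<=inf, Y<=k) = Phi(k), etc.
    out = np.where(h == np.inf, stats.norm.cdf(k), out)
    out = np.where(k == np.inf, stats.norm.cdf(h), out)
    out = np.where((h == -np.inf) | (k == -np.inf), 0.0, out)
    return np.clip(out, 0.0, 1.0)


def _cell_probs(row_thr: np.ndarray, col_thr: np.ndarray, rho: float) -> np.ndarray:
    """Rectangle probabilities of the bivariate normal over a threshold grid."""
    a = np.concatenate([[-np.inf], row_thr, [np.inf]])
    b = np.concatenate([[-np.inf], col_thr, [np.inf]])
    A, B = np.meshgrid(a, b, indexing="ij")
    F = bvn_cdf(A, B, rho)
    P = F[1:, 1:] - F[:-1, 1:] - F[1:, :-1] + F[:-1, :-1]
    return np.clip(P, 1e-300, None)


def polychoric_pair(table: np.ndarray) -> tuple[float, np.ndarray, np.ndarray]:
    """Two-step ML polychoric correlation from a 2-way count table.

    Returns ``(rho, row_thresholds, col_thresholds)``.  Margins with all
    mass in a single category are degenerate and raise an error.
    """
    table = np.asarray(table, dtype=float)
    table = table[table.sum(axis=1) > 0][:, table.sum(axis=0) > 0]
    if table.shape[0] < 2 or table.shape[1] < 2:
        raise InstrumentError(
            "polychoric correlation undefined: a margin has all mass in one category"
        )
    n = table.sum()
    row_thr = stats.norm.ppf(np.cumsum(table.sum(axis=1))[:-1] / n)
    col_thr = stats.norm.ppf(np.cumsum(table.sum(axis=0))[:-1] / n)

    def negll(rho: float) -> float:
        return -float(np.sum(table * np.log(_cell_probs(row_thr, col_thr, rho))))

    res = optimize.minimize_scalar(
        negll, bounds=(-_RHO_BOUND, _RHO_BOUND), method="bounded",
        options={"xatol": 1e-8},
    )
    return float(res.x), row_thr, col_thr


@dataclass(frozen=True)
class PolychoricMatrix:
    item_ids: list[str]
    values: np.ndarray  # symmetric, unit diagonal
    thresholds: dict[str, np.ndarray]
    smoothed: bool = False

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.item_ids, columns=self.item_ids)


def _nearest_psd_corr(R: np.ndarray) -> np.ndarray:
    """Eigenvalue-clipped positive-semidefinite projection, rescaled to unit
    diagonal."""
    w, V = np.linalg.eigh(R)
    w = np.clip(w, 1e-8, None)
    S = V @ np.diag(w) @ V.T
    d = np.sqrt(np.diag(S))
    return S / np.outer(d, d)


def polychoric_matrix(responses: ResponseMatrix) -> PolychoricMatrix:
    """All pairwise polychoric correlations of a complete response matrix.

    If the assembled matrix is not positive semidefinite it is smoothed by
    eigenvalue clipping (recorded in the ``smoothed`` flag).
    """
    if not responses.is_complete:
        raise InstrumentError("polychoric_matrix requires complete data; impute first")
    X = responses.values.astype(int)
    p = responses.n_items
    R = np.eye(p)
    thresholds: dict[str, np.ndarray] = {}
    for i in range(p):
        vals_i = np.unique(X[:, i])
        props = np.array([(X[:, i] == v).mean() for v in vals_i])
        thresholds[responses.item_ids[i]] = stats.norm.ppf(np.cumsum(props)[:-1])
    for i in range(p):
        for j in range(i + 1, p):
            table = pd.crosstab(X[:, i], X[:, j]).to_numpy()
            try:
                rho, _, _ = polychoric_pair(table)
            except InstrumentError as exc:
                raise InstrumentError(
                    f"polychoric failed for pair ({responses.item_ids[i]!r}, "
                    f"{responses.item_ids[j]!r}): {exc}"
                ) from exc
            R[i, j] = R[j, i] = rho
    smoothed = False
    if np.linalg.eigvalsh(R).min() < 0:
        R = _nearest_psd_corr(R)
        smoothed = True
    return PolychoricMatrix(
        item_ids=list(responses.item_ids), values=R,
        thresholds=thresholds, smoothed=smoothed,
    )


@dataclass(frozen=True)
class EfaResult:
    loadings: pd.DataFrame  # item x factor
    eigenvalues: np.ndarray  # of the correlation matrix, descending
    factor_ss_loadings: np.ndarray  # sum of squared loadings per factor
    n_factors: int
    extraction: str
    converged: bool
    heywood: bool  # any uniqueness at or below zero


def efa_ml(matrix: PolychoricMatrix, n_factors: int = 1, n_obs: int | None = None) -> EfaResult:
    """Maximum-likelihood factor extraction on a correlation matrix.

    Eigenvalues of the correlation matrix itself are reported (descending)
    alongside the factor solution's sums of squared loadings, since
    unidimensionality rules may refer to either.
    """
    p = len(matrix.item_ids)
    if not 1 <= n_factors < p:
        raise InstrumentError(f"n_factors must be in [1, {p - 1}]")
    from statsmodels.multivariate.factor import Factor

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fac = Factor(corr=matrix.values, n_factor=n_factors, method="ml",
                     nobs=n_obs, smc=True)
        try:
            res = fac.fit()
            converged = True
        except Exception as exc:  # non-convergence surfaces as an exception
            raise InstrumentError(f"ML factor extraction failed: {exc}") from exc
    loadings = np.asarray(res.loadings)
    # orient each factor so its loading sum is nonnegative (sign is arbitrary)
    signs = np.where(loadings.sum(axis=0) < 0, -1.0, 1.0)
    loadings = loadings * signs
    eigenvalues = np.sort(np.linalg.eigvalsh(matrix.values))[::-1]
    heywood = bool(np.any(np.asarray(res.uniqueness) <= 1e-6))
    return EfaResult(
        loadings=pd.DataFrame(
            loadings, index=matrix.item_ids,
            columns=[f"factor{i + 1}" for i in range(n_factors)],
        ),
        eigenvalues=eigenvalues,
        factor_ss_loadings=(loadings**2).sum(axis=0),
        n_factors=n_factors,
        extraction="ml",
        converged=converged,
        heywood=heywood,
    )


def unidimensionality_check(eigenvalues) -> tuple[bool, dict]:
    """Second-eigenvalue rule: unidimensional iff the second eigenvalue < 1.

    The threshold is strict: a second eigenvalue of exactly 1 (e.g. an
    identity correlation matrix) fails the check.
    """
    ev = np.sort(np.asarray(eigenvalues, dtype=float))[::-1]
    if ev.size < 2:
        raise InstrumentError("need at least 2 eigenvalues")
    second = float(ev[1])
    return second < 1.0, {"second_eigenvalue": second, "eigenvalues": ev}
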