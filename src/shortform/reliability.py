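"""Classical test theory reliability statistics.

Cronbach's alpha ``k/(k-1) * (1 - sum(item variances) / total variance)``
with unbiased (n-1 denominator) sample variances throughout, a Bonett
log(1-alpha) confidence interval (Feldt's F interval as an alternative),
alpha-if-item-deleted, and corrected item-total correlations.  A report
object mirrors the per-item table a scale-development write-up prints:
scaled mean rating, alpha if deleted, corrected item-total correlation,
with a flag for discriminations under the conventional 0.20 inclusion
guideline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .instrument import Instrument, InstrumentError, ResponseMatrix
from .preprocess import scaled_mean_rating

__all__ = [
    "ReliabilityReport",
    "cronbach_alpha",
    "alpha_from_covariance",
    "alpha_ci",
    "alpha_if_deleted",
    "corrected_item_total",
    "reliability_report",
]

ITEM_TOTAL_FLAG_THRESHOLD = 0.20  # conventional guideline for item inclusion


def _as_array(responses) -> np.ndarray:
    if isinstance(responses, ResponseMatrix):
        if not responses.is_complete:
            raise InstrumentError("reliability statistics require complete data")
        return responses.values
    return np.asarray(responses, dtype=float)


def alpha_from_covariance(cov: np.ndarray) -> float:
    """Cronbach's alpha from an item covariance matrix."""
    cov = np.asarray(cov, dtype=float)
    k = cov.shape[0]
    if k < 2:
        raise InstrumentError("alpha needs at least 2 items")
    total_var = cov.sum()
    if total_var <= 0:
        raise InstrumentError("total-score variance is zero; alpha undefined")
    return k / (k - 1) * (1.0 - np.trace(cov) / total_var)


def cronbach_alpha(responses, standardized: bool = False) -> float:
    """Cronbach's alpha of a complete respondents x items matrix.

    ``standardized=True`` computes alpha on the correlation matrix instead
    (items rescaled to unit variance before summation).
    """
    X = _as_array(responses)
    if X.shape[0] < 3:
        raise InstrumentError("alpha needs at least 3 respondents")
    if X.shape[1] < 2:
        raise InstrumentError("alpha needs at least 2 items")
    mat = np.corrcoef(X, rowvar=False) if standardized else np.cov(X, rowvar=False, ddof=1)
    return alpha_from_covariance(mat)


def alpha_ci(
    responses=None,
    level: float = 0.95,
    method: str = "bonett",
    *,
    alpha: float | None = None,
    n: int | None = None,
    k: int | None = None,
) -> tuple[float, float]:
    """Confidence interval for Cronbach's alpha.

    Either pass the data, or ``alpha``/``n``/``k`` directly.  ``"bonett"``
    uses the log(1-alpha) transformation with variance 2k/((k-1)(n-2));
    ``"feldt"`` uses the exact F-distribution interval.  Both are returned
    on the alpha scale as (lower, upper).
    """
    if responses is not None:
        X = _as_array(responses)
        alpha = cronbach_alpha(X)
        n, k = X.shape
    if alpha is None or n is None or k is None:
        raise InstrumentError("provide either data or alpha, n and k")
    if n <= 2:
        raise InstrumentError("confidence interval needs n > 2")
    if method == "bonett":
        z = stats.norm.ppf(0.5 + level / 2)
        se = np.sqrt(2.0 * k / ((k - 1) * (n - 2)))
        log_one_minus = np.log(1.0 - alpha)
        lo = 1.0 - np.exp(log_one_minus + z * se)
        hi = 1.0 - np.exp(log_one_minus - z * se)
        return float(lo), float(hi)
    if method == "feldt":
        gamma = 1.0 - level
        df1, df2 = n - 1, (n - 1) * (k - 1)
        lo = 1.0 - (1.0 - alpha) * stats.f.ppf(1 - gamma / 2, df1, df2)
        hi = 1.0 - (1.0 - alpha) * stats.f.ppf(gamma / 2, df1, df2)
        return float(lo), float(hi)
    raise ValueError(f"unknown CI method {method!r}")


def alpha_if_deleted(responses) -> np.ndarray:
    """Alpha recomputed with each item removed in turn."""
    X = _as_array(responses)
    if X.shape[1] < 3:
        raise InstrumentError("alpha-if-deleted needs at least 3 items")
    cov = np.cov(X, rowvar=False, ddof=1)
    out = np.empty(X.shape[1])
    for j in range(X.shape[1]):
        keep = np.delete(np.arange(X.shape[1]), j)
        out[j] = alpha_from_covariance(cov[np.ix_(keep, keep)])
    return out


def corrected_item_total(responses) -> np.ndarray:
    """Pearson correlation of each item with the sum of the other items.

    A zero-variance item (or rest-score) yields NaN for that entry rather
    than an error, so a report over many items can still be assembled.
    """
    X = _as_array(responses)
    if X.shape[1] < 3:
        raise InstrumentError("corrected item-total needs at least 3 items")
    total = X.sum(axis=1)
    out = np.empty(X.shape[1])
    for j in range(X.shape[1]):
        rest = total - X[:, j]
        if X[:, j].std(ddof=1) == 0 or rest.std(ddof=1) == 0:
            out[j] = np.nan
        else:
            out[j] = np.corrcoef(X[:, j], rest)[0, 1]
    return out


@dataclass(frozen=True)
class ReliabilityReport:
    """Scale-level and per-item internal-consistency summary."""

    alpha: float
    alpha_ci: tuple[float, float]
    ci_level: float
    ci_method: str
    n_respondents: int
    n_items: int
    items: pd.DataFrame  # scaled_mean_rating, alpha_if_deleted, corrected_item_total, flag

    def to_frame(self) -> pd.DataFrame:
        return self.items.copy()


def reliability_report(
    responses: ResponseMatrix,
    instrument: Instrument,
    subset=None,
    level: float = 0.95,
    ci_method: str = "bonett",
) -> ReliabilityReport:
    """The full CTT table for a (complete) response matrix.

    Flags items whose corrected item-total correlation falls below the 0.20
    inclusion guideline.
    """
    ids = subset if subset is not None else responses.item_ids
    sub = responses.subset(list(ids))
    X = _as_array(sub)
    a = cronbach_alpha(X)
    ci = alpha_ci(alpha=a, n=X.shape[0], k=X.shape[1], level=level, method=ci_method)
    table = pd.DataFrame(
        {
            "scaled_mean_rating": scaled_mean_rating(sub, instrument),
            "alpha_if_deleted": pd.Series(alpha_if_deleted(X), index=sub.item_ids),
            "corrected_item_total": pd.Series(
                corrected_item_total(X), index=sub.item_ids
            ),
        }
    )
    table["below_0.20_guideline"] = table["corrected_item_total"] < ITEM_TOTAL_FLAG_THRESHOLD
    return ReliabilityReport(
        alpha=a,
        alpha_ci=ci,
        ci_level=level,
        ci_method=ci_method,
        n_respondents=X.shape[0],
        n_items=X.shape[1],
        items=table,
    )
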