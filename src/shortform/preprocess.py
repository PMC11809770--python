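"""Missing-data handling and item-level descriptive rescaling.

Missing ordinal responses are replaced by the per-item median of the
observed responses (suitable for the small, patternless missingness the
workflow assumes, ~1-2% of cells).  With an even number of observations the
lower median is used by default so the imputed value is always an attained
category code; the conventional midpoint (rounded to the nearest code) is
available via ``convention="midpoint"``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .instrument import Instrument, InstrumentError, ResponseMatrix

__all__ = ["ImputationReport", "median_impute", "scaled_mean_rating"]


@dataclass(frozen=True)
class ImputationReport:
    """Audit record of a median-imputation pass."""

    n_cells: int
    n_missing: int
    per_item_medians: dict[str, float] = field(default_factory=dict)

    @property
    def fraction_missing(self) -> float:
        return self.n_missing / self.n_cells if self.n_cells else 0.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"median_used": pd.Series(self.per_item_medians, dtype=float)}
        )


def _item_median(observed: np.ndarray, convention: str) -> float:
    observed = np.sort(observed)
    n = observed.size
    if convention == "lower":
        return float(observed[(n - 1) // 2])
    if convention == "midpoint":
        return float(np.rint(np.median(observed)))
    raise ValueError(f"unknown median convention {convention!r}")


def median_impute(
    responses: ResponseMatrix, convention: str = "lower"
) -> tuple[ResponseMatrix, ImputationReport]:
    """Replace each missing cell by that item's median over observed values.

    Observed cells are unchanged; the operation is idempotent.  An item with
    no observed values at all cannot be imputed and raises an error naming it.
    """
    values = responses.values.copy()
    medians: dict[str, float] = {}
    n_missing = int(np.isnan(values).sum())
    for j, iid in enumerate(responses.item_ids):
        col = values[:, j]
        obs = col[~np.isnan(col)]
        if obs.size == 0:
            raise InstrumentError(f"item {iid!r} has no observed values to impute from")
        med = _item_median(obs, convention)
        medians[iid] = med
        col[np.isnan(col)] = med
    report = ImputationReport(
        n_cells=values.size, n_missing=n_missing, per_item_medians=medians
    )
    return (
        ResponseMatrix(values, responses.item_ids, responses.respondent_ids),
        report,
    )


def scaled_mean_rating(
    responses: ResponseMatrix, instrument: Instrument
) -> pd.Series:
    """Per-item mean rating divided by its number of response options.

    Normalises 4- and 5-point items onto a common (0, 1] scale so their
    average endorsement levels are comparable.  Requires complete data.
    """
    if not responses.is_complete:
        raise InstrumentError("scaled_mean_rating requires complete data; impute first")
    out = {}
    for j, iid in enumerate(responses.item_ids):
        item = instrument[iid]
        out[iid] = responses.values[:, j].mean() / item.n_categories
    return pd.Series(out, name="scaled_mean_rating")
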