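"""Instruments, items and scoring rules for ordinal (Likert) questionnaires.

An :class:`Instrument` is an ordered collection of :class:`Item` records,
each carrying its response-scale size, domain label and a ``core`` flag
marking items that are locked into every candidate subset during item
selection.  A :class:`ResponseMatrix` holds respondent x item integer
category codes with an explicit missingness mask (NaN in the value array).

Scoring is summative: each item contributes its raw category code, starting
at ``min_code`` (1 by default, so a 15-item form with thirteen 5-point and
two 4-point items spans totals 15..73).  An alternative zero-based scoring
is obtained by setting ``min_code=0`` per item in the definition document.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "Item",
    "Instrument",
    "ResponseMatrix",
    "load_instrument",
    "load_packaged_instrument",
    "sum_score",
    "score_range",
    "treatment_count_score",
]


class InstrumentError(ValueError):
    """Raised for invalid instrument definitions or scoring requests."""


@dataclass(frozen=True)
class Item:
    """A single questionnaire item.

    Parameters
    ----------
    id : str
        Unique identifier within the instrument.
    text : str
        Item wording.
    domain : str
        Content-domain label.
    n_categories : int
        Number of ordered response options (>= 2).
    core : bool
        Whether the item is locked into every candidate subset during
        item selection.
    min_code : int
        Lowest score a response contributes (default 1).
    reverse : bool
        Whether the item is reverse-keyed: a response ``x`` is scored as
        ``min_code + max_code - x`` before summation (default False).
    """

    id: str
    text: str = ""
    domain: str = ""
    n_categories: int = 5
    core: bool = False
    min_code: int = 1
    reverse: bool = False

    def __post_init__(self) -> None:
        if self.n_categories < 2:
            raise InstrumentError(
                f"item {self.id!r}: n_categories must be >= 2, got {self.n_categories}"
            )

    @property
    def max_code(self) -> int:
        return self.min_code + self.n_categories - 1


@dataclass(frozen=True)
class Instrument:
    """An ordered list of items with a name."""

    items: tuple[Item, ...]
    name: str = "instrument"

    def __post_init__(self) -> None:
        if len(self.items) == 0:
            raise InstrumentError("an instrument needs at least one item")
        ids = [it.id for it in self.items]
        dupes = {i for i in ids if ids.count(i) > 1}
        if dupes:
            raise InstrumentError(f"duplicate item id(s): {sorted(dupes)}")

    def __len__(self) -> int:
        return len(self.items)

    @property
    def item_ids(self) -> list[str]:
        return [it.id for it in self.items]

    @property
    def core_ids(self) -> list[str]:
        return [it.id for it in self.items if it.core]

    def __getitem__(self, item_id: str) -> Item:
        for it in self.items:
            if it.id == item_id:
                return it
        raise KeyError(item_id)

    def subset(self, item_ids: Iterable[str]) -> "Instrument":
        """A new instrument restricted to ``item_ids``, keeping this order."""
        wanted = set(item_ids)
        unknown = wanted - set(self.item_ids)
        if unknown:
            raise InstrumentError(f"unknown item id(s): {sorted(unknown)}")
        return Instrument(
            items=tuple(it for it in self.items if it.id in wanted),
            name=f"{self.name}-subset",
        )


class ResponseMatrix:
    """Respondents x items ordinal data with a missingness mask.

    Values are stored as a float array where NaN marks a missing cell;
    observed cells hold integer category codes.
    """

    def __init__(
        self,
        values: np.ndarray,
        item_ids: Sequence[str],
        respondent_ids: Sequence | None = None,
    ) -> None:
        values = np.asarray(values, dtype=float)
        if values.ndim != 2:
            raise InstrumentError("values must be a 2-D respondents x items array")
        if values.shape[1] != len(item_ids):
            raise InstrumentError(
                f"{values.shape[1]} columns but {len(item_ids)} item ids"
            )
        if respondent_ids is None:
            respondent_ids = list(range(values.shape[0]))
        if len(respondent_ids) != values.shape[0]:
            raise InstrumentError(
                f"{values.shape[0]} rows but {len(respondent_ids)} respondent ids"
            )
        obs = ~np.isnan(values)
        if not np.allclose(values[obs], np.round(values[obs])):
            raise InstrumentError("observed response codes must be integers")
        self.values = values
        self.item_ids = list(item_ids)
        self.respondent_ids = list(respondent_ids)

    # -- construction helpers -------------------------------------------------

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "ResponseMatrix":
        return cls(frame.to_numpy(dtype=float), list(frame.columns), list(frame.index))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values.copy(), index=self.respondent_ids, columns=self.item_ids
        )

    # -- basic views ----------------------------------------------------------

    @property
    def n_respondents(self) -> int:
        return self.values.shape[0]

    @property
    def n_items(self) -> int:
        return self.values.shape[1]

    @property
    def mask(self) -> np.ndarray:
        """Boolean array, True where the cell is missing."""
        return np.isnan(self.values)

    @property
    def is_complete(self) -> bool:
        return not self.mask.any()

    def subset(self, item_ids: Sequence[str]) -> "ResponseMatrix":
        idx = [self.item_ids.index(i) for i in item_ids]
        return ResponseMatrix(self.values[:, idx], list(item_ids), self.respondent_ids)

    def copy(self) -> "ResponseMatrix":
        return ResponseMatrix(
            self.values.copy(), list(self.item_ids), list(self.respondent_ids)
        )

    def validate_against(self, instrument: Instrument) -> None:
        """Check every observed code lies in its item's admissible range."""
        for j, iid in enumerate(self.item_ids):
            item = instrument[iid]
            col = self.values[:, j]
            obs = ~np.isnan(col)
            bad = obs & ((col < item.min_code) | (col > item.max_code))
            if bad.any():
                rows = [self.respondent_ids[r] for r in np.flatnonzero(bad)]
                raise InstrumentError(
                    f"item {iid!r}: code(s) outside [{item.min_code}, "
                    f"{item.max_code}] for respondent(s) {rows[:5]}"
                )


# -- loading ------------------------------------------------------------------

_REQUIRED_FIELDS = {"id", "n_categories"}
_KNOWN_FIELDS = {"id", "text", "domain", "n_categories", "core", "min_code", "reverse"}


def load_instrument(source) -> Instrument:
    """Build an :class:`Instrument` from a structured definition document.

    ``source`` may be a path to a YAML file or an already-parsed mapping with
    keys ``name`` and ``items`` (a list of per-item records).  Validation
    errors name the offending item id.
    """
    if isinstance(source, Mapping):
        doc = dict(source)
    else:
        with open(source, "r") as fh:
            doc = yaml.safe_load(fh)
    if not isinstance(doc, Mapping) or "items" not in doc:
        raise InstrumentError("definition document must contain an 'items' list")
    items = []
    for rec in doc["items"]:
        rec = dict(rec)
        missing = _REQUIRED_FIELDS - rec.keys()
        if missing:
            raise InstrumentError(
                f"item record {rec.get('id', '?')!r}: missing field(s) {sorted(missing)}"
            )
        unknown = rec.keys() - _KNOWN_FIELDS
        if unknown:
            raise InstrumentError(
                f"item {rec['id']!r}: unknown field(s) {sorted(unknown)}"
            )
        items.append(Item(**rec))
    return Instrument(items=tuple(items), name=doc.get("name", "instrument"))


def load_packaged_instrument(name: str = "clcf_sf") -> Instrument:
    """Load a definition shipped with the package.

    ``"clcf_sf"`` is the 15-item CLCF-SF (Challenge of Living with Cystic
    Fibrosis, short form): five core items, thirteen 5-point and two 4-point
    items, scored from 1, totals spanning 15..73.  Item wording in the
    fixture is a paraphrased reconstruction (synthetic stand-in); the
    structural fields (scale sizes, domains, core flags) follow the
    published instrument.
    """
    fname = {"clcf_sf": "clcf_sf_reconstructed.yaml"}[name]
    ref = importlib.resources.files("shortform.data").joinpath(fname)
    with ref.open("r") as fh:
        return load_instrument(yaml.safe_load(fh))


# -- scoring ------------------------------------------------------------------


def _resolve_subset(instrument: Instrument, subset: Iterable[str] | None) -> list[str]:
    if subset is None:
        return instrument.item_ids
    subset = list(subset)
    unknown = set(subset) - set(instrument.item_ids)
    if unknown:
        raise InstrumentError(f"subset contains unknown item id(s): {sorted(unknown)}")
    # keep instrument order for determinism
    wanted = set(subset)
    return [i for i in instrument.item_ids if i in wanted]


def sum_score(
    responses: ResponseMatrix,
    instrument: Instrument,
    subset: Iterable[str] | None = None,
) -> pd.Series:
    """Per-respondent summative total over ``subset`` (default: all items).

    Higher totals indicate greater challenge.  Missing values inside the
    subset are an error: impute first (see :func:`shortform.preprocess.median_impute`).
    """
    ids = _resolve_subset(instrument, subset)
    sub = responses.subset(ids)
    if sub.mask.any():
        n_miss = int(sub.mask.sum())
        raise InstrumentError(
            f"{n_miss} missing value(s) inside the scored subset; "
            "impute first (e.g. shortform.preprocess.median_impute)"
        )
    vals = sub.values.copy()
    for j, iid in enumerate(ids):
        item = instrument[iid]
        if item.reverse:
            vals[:, j] = item.min_code + item.max_code - vals[:, j]
    return pd.Series(vals.sum(axis=1), index=responses.respondent_ids, name="total")


def score_range(
    instrument: Instrument, subset: Iterable[str] | None = None
) -> tuple[int, int]:
    """(min, max) total attainable by any response pattern over ``subset``."""
    ids = _resolve_subset(instrument, subset)
    if not ids:
        raise InstrumentError("score_range requires a non-empty subset")
    lo = sum(instrument[i].min_code for i in ids)
    hi = sum(instrument[i].max_code for i in ids)
    return lo, hi


def treatment_count_score(usage: pd.DataFrame) -> pd.Series:
    """Number of distinct treatments with nonzero usage per respondent.

    ``usage`` holds nonnegative frequencies or 0/1 indicators, one column per
    treatment.  NaN cells (treatment not asked about) count as unused.
    """
    arr = usage.to_numpy(dtype=float)
    if arr.size and np.nanmin(arr) < 0:
        raise InstrumentError("treatment usage must be nonnegative")
    counts = np.nansum(np.nan_to_num(arr) > 0, axis=1).astype(int)
    return pd.Series(counts, index=usage.index, name="n_treatments")
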