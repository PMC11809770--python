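"""Seeded synthetic cohorts with the statistical structure the analyses assume.

Likert responses follow the standard factor-analytic data-generating model
that underlies polychoric correlation: a standard-normal latent trait t,
per-item latent responses y_j = lambda_j * t + sqrt(1 - lambda_j^2) * e_j
(so y_j is standard normal), discretized at per-item ordered thresholds
into integer category codes.  Missing cells are inserted completely at
random.  External covariates are generated conditionally on the latent
trait (or, optionally, on the standardized observed total score) to hit
target correlations in expectation, and binary groupings shift the latent
trait by a stated standardized amount.

Defaults emulate the validation cohort the workflow was designed around:
135 respondents on the 15-item CLCF-SF (thirteen 5-point, two 4-point
items), common-factor loadings 0.55, ~1.6% missingness, covariate
correlations of 0.48 / 0.41 / 0.43 / -0.37 (depression-, state-anxiety-,
trait-anxiety- and lung-function-like measures) and group shifts of 0.37
(wellness) and 0.26 (hospital admission) standard deviations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .instrument import Instrument, ResponseMatrix, load_packaged_instrument
from .rsm import rsm_category_probs

__all__ = ["CohortSpec", "SimulatedCohort", "simulate_likert", "simulate_cohort", "simulate_rsm"]

DEFAULT_LOADING = 0.55
DEFAULT_MISSING_RATE = 0.016
DEFAULT_COVARIATE_CORRELATIONS = {
    "depression": 0.48,
    "state_anxiety": 0.41,
    "trait_anxiety": 0.43,
    "lung_function": -0.37,
}
DEFAULT_GROUP_EFFECTS = {"unwell": 0.37, "admission": 0.26}


def default_thresholds(n_categories: int) -> np.ndarray:
    """Equal-probability cut-points on the standard-normal scale."""
    return stats.norm.ppf(np.arange(1, n_categories) / n_categories)


@dataclass(frozen=True)
class CohortSpec:
    """Generator settings; defaults are the emulated study conditions."""

    n_respondents: int = 135
    instrument: Instrument | None = None  # None -> packaged CLCF-SF
    loadings: float | dict[str, float] = DEFAULT_LOADING
    thresholds: dict[str, np.ndarray] | None = None  # None -> equal-probability
    missing_rate: float = DEFAULT_MISSING_RATE
    covariate_correlations: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_COVARIATE_CORRELATIONS)
    )
    group_effects: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_GROUP_EFFECTS)
    )
    seed: int = 0

    def resolve_instrument(self) -> Instrument:
        return self.instrument if self.instrument is not None else load_packaged_instrument()

    def loading_of(self, item_id: str) -> float:
        if isinstance(self.loadings, dict):
            lam = self.loadings[item_id]
        else:
            lam = float(self.loadings)
        if not 0 <= lam < 1:
            raise ValueError(f"loading for {item_id!r} must be in [0, 1), got {lam}")
        return lam

    def thresholds_of(self, item_id: str, n_categories: int) -> np.ndarray:
        if self.thresholds is not None and item_id in self.thresholds:
            thr = np.asarray(self.thresholds[item_id], dtype=float)
        else:
            thr = default_thresholds(n_categories)
        if np.any(np.diff(thr) <= 0):
            raise ValueError(f"thresholds for {item_id!r} must be strictly increasing")
        return thr

    def validate(self) -> None:
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must be in [0, 1)")
        for name, r in self.covariate_correlations.items():
            if not -1 < r < 1:
                raise ValueError(
                    f"covariate correlation {name!r}={r} infeasible (|r| must be < 1)"
                )


@dataclass(frozen=True)
class SimulatedCohort:
    responses: ResponseMatrix
    covariates: pd.DataFrame
    groups: pd.DataFrame
    trait: np.ndarray
    truth: dict


def _draw_responses(
    spec: CohortSpec, trait: np.ndarray, rng: np.random.Generator
) -> ResponseMatrix:
    instrument = spec.resolve_instrument()
    n = trait.size
    values = np.empty((n, len(instrument)), dtype=float)
    for j, item in enumerate(instrument.items):
        lam = spec.loading_of(item.id)
        y = lam * trait + np.sqrt(1.0 - lam * lam) * rng.standard_normal(n)
        thr = spec.thresholds_of(item.id, item.n_categories)
        values[:, j] = item.min_code + np.searchsorted(thr, y)
        # searchsorted on a sorted threshold grid == count of thresholds below y
    if spec.missing_rate > 0:
        miss = rng.random(values.shape) < spec.missing_rate
        values[miss] = np.nan
    return ResponseMatrix(values, instrument.item_ids)


def simulate_likert(spec: CohortSpec) -> ResponseMatrix:
    """Ordinal responses only (no covariates); identical seed, identical output."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    trait = rng.standard_normal(spec.n_respondents)
    return _draw_responses(spec, trait, rng)


def simulate_cohort(spec: CohortSpec, anchor: str = "trait") -> SimulatedCohort:
    """Responses plus covariate table and binary group labels.

    ``anchor`` selects what the covariate correlation targets refer to:
    ``"trait"`` (default) correlates covariates with the latent trait;
    ``"total"`` correlates them with the standardized observed total score
    (computed before missingness is inserted), which is the relevant anchor
    when the targets describe correlations with the questionnaire total.
    """
    spec.validate()
    if anchor not in ("trait", "total"):
        raise ValueError("anchor must be 'trait' or 'total'")
    rng = np.random.default_rng(spec.seed)
    n = spec.n_respondents
    instrument = spec.resolve_instrument()

    groups = {}
    trait = rng.standard_normal(n)
    for name, delta in spec.group_effects.items():
        g = rng.integers(0, 2, size=n)
        trait = trait + delta * (g - 0.5)
        groups[name] = g
    groups = pd.DataFrame(groups)

    # draw complete responses, then insert missingness afterwards so the
    # total-score anchor is well defined
    complete_spec = CohortSpec(
        n_respondents=n, instrument=instrument, loadings=spec.loadings,
        thresholds=spec.thresholds, missing_rate=0.0,
        covariate_correlations=spec.covariate_correlations,
        group_effects=spec.group_effects, seed=spec.seed,
    )
    responses = _draw_responses(complete_spec, trait, rng)
    totals = responses.values.sum(axis=1)

    anchor_var = trait if anchor == "trait" else totals
    z = (anchor_var - anchor_var.mean()) / anchor_var.std()
    covariates = {}
    for name, r in spec.covariate_correlations.items():
        covariates[name] = r * z + np.sqrt(1.0 - r * r) * rng.standard_normal(n)
    covariates = pd.DataFrame(covariates)

    values = responses.values.copy()
    if spec.missing_rate > 0:
        miss = rng.random(values.shape) < spec.missing_rate
        values[miss] = np.nan
    responses = ResponseMatrix(values, instrument.item_ids)

    truth = {
        "loadings": {it.id: spec.loading_of(it.id) for it in instrument.items},
        "covariate_correlations": dict(spec.covariate_correlations),
        "group_effects": dict(spec.group_effects),
        "missing_rate": spec.missing_rate,
        "anchor": anchor,
        "seed": spec.seed,
    }
    return SimulatedCohort(
        responses=responses, covariates=covariates, groups=groups,
        trait=trait, truth=truth,
    )


def simulate_rsm(
    difficulties,
    category_thresholds,
    persons,
    missing_design: np.ndarray | None = None,
    seed: int = 0,
) -> np.ndarray:
    """Draw ordinal responses from the Rating Scale Model.

    ``category_thresholds`` are the m-1 step parameters shared across items
    (the RSM constraint).  ``missing_design`` is a persons x items boolean
    mask of structurally absent cells (True = missing), returned as NaN.
    """
    difficulties = np.asarray(difficulties, dtype=float)
    persons = np.asarray(persons, dtype=float)
    P = rsm_category_probs(persons, difficulties, category_thresholds)
    rng = np.random.default_rng(seed)
    u = rng.random((persons.size, difficulties.size))
    cum = P.cumsum(axis=2)
    X = (u[:, :, None] > cum).sum(axis=2).astype(float)
    if missing_design is not None:
        missing_design = np.asarray(missing_design, dtype=bool)
        if missing_design.shape != X.shape:
            raise ValueError("missing_design shape must match persons x items")
        X[missing_design] = np.nan
    return X
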