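"""File I/O, run configuration and end-to-end pipeline orchestration.

Response data are delimited text: a header row of item ids, one respondent
per row, integer category codes, empty cell = missing.  All tabular
outputs are delimited text with headers; every artifact directory gets a
run log recording resolved parameters, per-stage seeds and timings.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import factor, ga, precision, reliability, rsm, simulate, validity
from .instrument import (
    Instrument,
    InstrumentError,
    ResponseMatrix,
    load_instrument,
    load_packaged_instrument,
    sum_score,
)
from .preprocess import median_impute

__all__ = ["read_responses", "write_responses", "RunConfig", "run_pipeline"]

logger = logging.getLogger("shortform")

STAGES = ("select", "reliability", "efa", "irt", "validity", "samplesize")


def read_responses(path, instrument: Instrument | None = None) -> ResponseMatrix:
    """Read a delimited response file; validate codes against the instrument.

    Unknown item ids in the header and non-integer or out-of-range cells
    are reported with their position.
    """
    frame = pd.read_csv(path)
    if instrument is not None:
        unknown = set(frame.columns) - set(instrument.item_ids)
        if unknown:
            raise InstrumentError(f"unknown item id(s) in header: {sorted(unknown)}")
    try:
        rm = ResponseMatrix.from_frame(frame)
    except InstrumentError as exc:
        raise InstrumentError(f"{path}: {exc}") from exc
    if instrument is not None:
        rm.validate_against(instrument)
    return rm


def write_responses(rm: ResponseMatrix, path) -> None:
    frame = rm.to_frame()
    # keep observed codes as integers in the file; blank = missing
    frame.to_csv(path, index=False, float_format="%.0f")


def _stage_seed(global_seed: int, stage: str) -> int:
    digest = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass
class RunConfig:
    """Paths, analysis switches and parameter overrides for one run."""

    responses: str | None = None
    instrument: str | None = None  # None -> packaged CLCF-SF
    covariates: str | None = None
    groupings: str | None = None
    output_dir: str = "shortform_out"
    stages: tuple[str, ...] = ("reliability",)
    seed: int = 0
    ga_params: dict = field(default_factory=dict)
    core_items: list[str] | None = None  # None -> instrument core flags
    n_starts: int = 6
    samplesize: dict = field(
        default_factory=lambda: {"k": 15, "planning_alpha": 0.7, "half_width": 0.1,
                                 "level": 0.95}
    )
    irt_responses: str | None = None  # ordinal matrix for the RSM stage

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        cfg = cls(**{k: v for k, v in doc.items() if k in cls.__dataclass_fields__})
        if "stages" in doc:
            cfg.stages = tuple(doc["stages"])
        return cfg

    def config_hash(self) -> str:
        payload = json.dumps(self.__dict__, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _preflight(config: RunConfig) -> None:
    for attr in ("responses", "instrument", "covariates", "groupings", "irt_responses"):
        p = getattr(config, attr)
        if p is not None and not Path(p).exists():
            raise FileNotFoundError(f"{attr} file not found: {p}")
    bad = set(config.stages) - set(STAGES)
    if bad:
        raise ValueError(f"unknown stage(s): {sorted(bad)}")
    if "validity" in config.stages and config.covariates is None and config.groupings is None:
        raise ValueError("validity stage requested but no covariates or groupings given")
    if config.responses is None and set(config.stages) & {"select", "reliability", "efa", "validity"}:
        raise ValueError("these stages need a responses file")


def run_pipeline(config: RunConfig) -> dict:
    """Run the requested stages in workflow order; return a report bundle.

    Order: impute -> select -> reliability -> EFA -> IRT -> validity ->
    samplesize.  A stage failure halts its downstream dependents.  Every
    artifact is stamped with the config hash and per-stage seed.
    """
    _preflight(config)
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle: dict = {"config_hash": config.config_hash(), "seed": config.seed}
    log_lines = [f"config_hash={config.config_hash()}", f"seed={config.seed}"]
    for name, value in sorted(config.__dict__.items()):
        log_lines.append(f"param {name}={value!r}")

    instrument = (
        load_instrument(config.instrument) if config.instrument
        else load_packaged_instrument()
    )

    responses = imputed = None
    if config.responses:
        responses = read_responses(config.responses, instrument)
        imputed, imp_report = median_impute(responses)
        bundle["imputation"] = imp_report
        imp_report.to_frame().to_csv(out / "imputation_report.csv")
        log_lines.append(
            f"impute: {imp_report.n_missing}/{imp_report.n_cells} cells "
            f"({imp_report.fraction_missing:.4f})"
        )

    selected_ids = None
    for stage in [s for s in ("select", "reliability", "efa", "irt", "validity", "samplesize")
                  if s in config.stages]:
        t0 = time.time()
        seed = _stage_seed(config.seed, stage)
        try:
            if stage == "select":
                core = (config.core_items if config.core_items is not None
                        else instrument.core_ids)
                params = ga.GaParams(**{**config.ga_params, "seed": seed})
                result = ga.multi_start(imputed, frozenset(core), params,
                                        n_starts=config.n_starts)
                best = result.best
                selected_ids = sorted(best.item_ids)
                bundle["select"] = result
                pd.DataFrame(
                    {"item_id": selected_ids,
                     "core": [i in set(core) for i in selected_ids]}
                ).to_csv(out / "selected_items.csv", index=False)
                _, trace = ga.evolve(imputed, frozenset(core), params)
                pd.DataFrame({"generation": np.arange(trace.size),
                              "best_fitness": trace}).to_csv(
                    out / "fitness_trace.csv", index=False)
                log_lines.append(
                    f"select: {len(selected_ids)} items, fitness={best.fitness:.4f}, "
                    f"agreement={result.agreement}"
                )
            elif stage == "reliability":
                ids = selected_ids or imputed.item_ids
                rep = reliability.reliability_report(imputed, instrument, subset=ids)
                bundle["reliability"] = rep
                rep.to_frame().to_csv(out / "reliability_items.csv")
                log_lines.append(
                    f"reliability: alpha={rep.alpha:.3f} "
                    f"CI=({rep.alpha_ci[0]:.3f}, {rep.alpha_ci[1]:.3f})"
                )
            elif stage == "efa":
                ids = selected_ids or imputed.item_ids
                poly = factor.polychoric_matrix(imputed.subset(ids))
                efa = factor.efa_ml(poly, n_factors=1, n_obs=imputed.n_respondents)
                ok, info = factor.unidimensionality_check(efa.eigenvalues)
                bundle["efa"] = efa
                bundle["unidimensional"] = ok
                poly.to_frame().to_csv(out / "polychoric_matrix.csv")
                efa.loadings.to_csv(out / "efa_loadings.csv")
                log_lines.append(
                    f"efa: second eigenvalue={info['second_eigenvalue']:.3f} "
                    f"unidimensional={ok}"
                )
            elif stage == "irt":
                if config.irt_responses is None:
                    log_lines.append("irt: skipped (no irt_responses file)")
                    continue
                mat = pd.read_csv(config.irt_responses)
                fit = rsm.fit_rsm(mat)
                bundle["irt"] = fit
                pd.DataFrame({"difficulty": fit.item_difficulties,
                              "se": fit.difficulty_se}).to_csv(out / "rsm_items.csv")
                fit.person_scores.to_csv(out / "rsm_person_scores.csv")
                log_lines.append(
                    f"irt: {len(fit.item_ids)} items, loglik={fit.loglik:.2f}, "
                    f"converged={fit.converged}"
                )
            elif stage == "validity":
                ids = selected_ids or imputed.item_ids
                totals = sum_score(imputed, instrument, ids)
                cov = pd.read_csv(config.covariates) if config.covariates else None
                grp = pd.read_csv(config.groupings) if config.groupings else None
                rep = validity.validity_battery(totals.reset_index(drop=True), cov, grp)
                bundle["validity"] = rep
                rep.to_frame().to_csv(out / "validity_report.csv", index=False)
                log_lines.append(f"validity: {len(rep.correlations)} correlations, "
                                 f"{len(rep.group_comparisons)} group tests")
            elif stage == "samplesize":
                plan = precision.bonett_required_n(**config.samplesize)
                bundle["samplesize"] = plan
                log_lines.append(f"samplesize: required n={plan.required_n}")
        except Exception as exc:
            log_lines.append(f"{stage}: FAILED ({exc}); downstream stages halted")
            (out / "run.log").write_text("\n".join(log_lines) + "\n")
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
        log_lines.append(f"{stage}: done in {time.time() - t0:.2f}s (seed {seed})")
    (out / "run.log").write_text("\n".join(log_lines) + "\n")
    return bundle
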