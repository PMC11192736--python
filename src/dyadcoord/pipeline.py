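"""End-to-end orchestration over a study directory.

``compute_metrics`` walks a study directory (the layout written by
:func:`dyadcoord.simulate.generate_study`), preprocesses every trial and
produces the long-format study table: one row per participant x trial with
rho, Fisher-z rho, weighted coherence, %REC, MaxLine and gaze proportion
next to the condition codes and covariates. A single bad trial never
aborts the batch: its metrics are rowed as missing and the failure is
logged.

``run_analysis`` fits the configured mixed-model families on that table
(condition-only; condition x questionnaire; participant-gaze; participant
gaze x questionnaire), writes tidy coefficient/contrast/slope CSVs plus a
human-readable summary per model, and records every analysis decision in
effect (filter order, coherence weighting, df method, radius source) in
``run.log``.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import crqa as crqa_mod
from .errors import DyadCoordError, ModelSpecError
from .gaze import gaze_proportion, trim_aoi
from .io import read_aoi_csv, read_covariates_csv, read_pair_csv
from .models import ModelSpec, center_predictors, fit_lmm, pairwise_contrasts, simple_slopes
from .phase import phase_coordination
from .preprocess import PreprocessConfig, preprocess_trial
from .spectral import SpectralConfig, coherence_pair
from .trace import COORDINATION_CONDITIONS

log = logging.getLogger(__name__)

__all__ = ["RunConfig", "compute_metrics", "run_analysis"]

OUTCOMES = ("rho_z", "coherence", "rec_pct", "maxline")


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one end-to-end run."""

    input_dir: str = "."
    out_dir: str = "out"
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    spectral: SpectralConfig = field(default_factory=SpectralConfig)
    crqa: crqa_mod.CRQAParams = field(default_factory=crqa_mod.CRQAParams)
    edge_discard_s: float = 1.0
    missing_policy: str = "exclude"
    outcomes: tuple[str, ...] = OUTCOMES
    questionnaires: tuple[str, ...] = ("lsas", "aq")
    seed: int = 0
    verbosity: int = 1


def _shared_embedding(cfg: RunConfig, processed: dict) -> tuple[int, int, str]:
    """One (delay, dim) for the whole study.

    If the config fixes both, use them; otherwise estimate AMI/FNN per
    trial (participant and avatar series) and take the median across
    trials, mirroring a single-setting analysis estimated from the data.
    """
    p = cfg.crqa
    if p.delay is not None and p.dim is not None:
        return p.delay, p.dim, "config"
    delays, dims = [], []
    for pair in processed.values():
        for trace in (pair.participant, pair.avatar):
            try:
                d, m = crqa_mod.estimate_embedding_params(
                    (trace.x - trace.x.mean()) / trace.x.std(), p
                )
                delays.append(d)
                dims.append(m)
            except DyadCoordError as exc:
                log.warning("embedding estimation failed for %s/%s: %s",
                            pair.trial_id, trace.actor, exc)
    if not delays:
        raise DyadCoordError("embedding parameters could not be estimated on any trial")
    delay = p.delay if p.delay is not None else int(np.median(delays))
    dim = p.dim if p.dim is not None else int(np.median(dims))
    return delay, dim, f"median across {len(delays)} series"


def compute_metrics(cfg: RunConfig) -> pd.DataFrame:
    """Study table: one row per participant x trial with all metrics."""
    root = Path(cfg.input_dir)
    covariates = read_covariates_csv(root / "covariates.csv")
    if len(covariates) == 0:
        raise DyadCoordError(f"{root}: empty covariate table")

    # pass 1: load + preprocess what we can
    processed: dict[tuple[str, str], object] = {}
    failures: dict[tuple[str, str], str] = {}
    for _, row in covariates.iterrows():
        pid = str(row["participant_id"])
        for trial_type in COORDINATION_CONDITIONS:
            key = (pid, trial_type)
            path = root / "movement" / f"{pid}_{trial_type}.csv"
            try:
                pair = read_pair_csv(path, gaze_condition=row["gaze_condition"],
                                     coordination=trial_type)
                processed[key] = preprocess_trial(pair, cfg.preprocess)
            except (DyadCoordError, OSError) as exc:
                failures[key] = str(exc)
                log.warning("trial %s_%s unusable: %s", pid, trial_type, exc)

    if not processed:
        raise DyadCoordError(f"{root}: no usable trials")
    delay, dim, source = _shared_embedding(cfg, processed)
    log.info("shared CRQA embedding: delay=%d, dim=%d (%s)", delay, dim, source)

    rows = []
    for _, row in covariates.iterrows():
        pid = str(row["participant_id"])
        for trial_type in COORDINATION_CONDITIONS:
            key = (pid, trial_type)
            rec = {
                "participant_id": pid,
                "trial": trial_type,
                "coord_code": COORDINATION_CONDITIONS.index(trial_type),
                "gaze_condition": row["gaze_condition"],
                "gaze_code": 0 if row["gaze_condition"] == "direct" else 1,
                "lsas": row["lsas"],
                "aq": row["aq"],
                "rho": np.nan, "rho_z": np.nan, "coherence": np.nan,
                "rec_pct": np.nan, "maxline": np.nan, "crqa_radius": np.nan,
                "gaze_prop": np.nan,
            }
            pair = processed.get(key)
            if pair is None:
                rec["note"] = failures.get(key, "missing")
            else:
                try:
                    stab, _ = phase_coordination(pair, cfg.edge_discard_s)
                    rec["rho"], rec["rho_z"] = stab.rho, stab.rho_z
                    rec["coherence"] = coherence_pair(pair, cfg.spectral)
                    res = crqa_mod.crqa_metrics(
                        pair.participant.x, pair.avatar.x, cfg.crqa,
                        delay=delay, dim=dim,
                    )
                    rec["rec_pct"] = res.rec_pct
                    rec["maxline"] = res.maxline
                    rec["crqa_radius"] = res.radius_used
                    rec["note"] = ""
                except DyadCoordError as exc:
                    rec["note"] = str(exc)
                    log.warning("metrics failed for %s_%s: %s", pid, trial_type, exc)
            aoi_path = root / "aoi" / f"{pid}_{trial_type}.csv"
            if aoi_path.exists():
                try:
                    aoi = read_aoi_csv(aoi_path)
                    aoi = trim_aoi(aoi, cfg.preprocess.trim_s,
                                   cfg.preprocess.trim_s + cfg.preprocess.target_s)
                    rec["gaze_prop"] = gaze_proportion(aoi, cfg.missing_policy)
                except DyadCoordError as exc:
                    log.warning("gaze failed for %s_%s: %s", pid, trial_type, exc)
            rows.append(rec)
    return pd.DataFrame(rows)


def _model_plan(cfg: RunConfig) -> list[ModelSpec]:
    plan = []
    for outcome in cfg.outcomes:
        plan.append(ModelSpec(outcome=outcome, fixed="gaze_code * coord_code",
                              name=f"{outcome}__conditions"))
    for quest in cfg.questionnaires:
        for outcome in cfg.outcomes:
            plan.append(ModelSpec(
                outcome=outcome, fixed=f"{quest}_c * gaze_code * coord_code",
                name=f"{outcome}__{quest}"))
    # participant-gaze models
    plan.append(ModelSpec(outcome="gaze_prop", fixed="gaze_code * coord_code",
                          name="gaze_prop__conditions"))
    for quest in cfg.questionnaires:
        plan.append(ModelSpec(
            outcome="gaze_prop", fixed=f"{quest}_c * gaze_code * coord_code",
            name=f"gaze_prop__{quest}"))
    for outcome in cfg.outcomes:
        plan.append(ModelSpec(
            outcome=outcome, fixed="gaze_prop_c * gaze_code * coord_code",
            name=f"{outcome}__participant_gaze"))
        for quest in cfg.questionnaires:
            plan.append(ModelSpec(
                outcome=outcome,
                fixed=f"gaze_prop_c * {quest}_c + gaze_code + coord_code",
                name=f"{outcome}__gaze_x_{quest}"))
    return plan


def run_analysis(cfg: RunConfig, table: pd.DataFrame | None = None) -> dict:
    """Fit the model families and write the report bundle.

    Returns a dict of model name -> ModelResult (failed models map to the
    exception). Outputs land in ``cfg.out_dir``: ``metrics.csv``,
    ``models/*.csv``, ``run.log``.
    """
    out = Path(cfg.out_dir)
    (out / "models").mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="a")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    root_logger = logging.getLogger("dyadcoord")
    root_logger.addHandler(handler)
    root_logger.setLevel(logging.INFO)
    try:
        if table is None:
            metrics_path = out / "metrics.csv"
            if not metrics_path.exists():
                table = compute_metrics(cfg)
                table.to_csv(metrics_path, index=False)
            else:
                table = pd.read_csv(metrics_path)
        log.info("analysis decisions: filter order=%d (zero-phase), coherence "
                 "weighting=%s band=%s, df method=residual, CRQA radius=%s, "
                 "edge discard=%.3g s, missing gaze policy=%s",
                 cfg.preprocess.filter_order, cfg.spectral.weighting,
                 cfg.spectral.band,
                 "fixed" if cfg.crqa.radius is not None
                 else f"tuned to {cfg.crqa.target_rr}% recurrence",
                 cfg.edge_discard_s, cfg.missing_policy)

        to_center = [q for q in cfg.questionnaires if q in table.columns]
        if "gaze_prop" in table.columns:
            to_center.append("gaze_prop")
        table, centers = center_predictors(table, to_center)
        log.info("centring constants: %s", centers)

        results: dict[str, object] = {}
        for spec in _model_plan(cfg):
            if spec.outcome not in table.columns:
                raise ModelSpecError(f"outcome {spec.outcome!r} not in study table")
            try:
                res = fit_lmm(table, spec)
            except DyadCoordError as exc:
                log.error("model %s failed: %s", spec.name, exc)
                results[spec.name] = exc
                continue
            results[spec.name] = res
            res.terms.to_csv(out / "models" / f"{spec.name}_coefs.csv", index=False)
            (out / "models" / f"{spec.name}_summary.txt").write_text(
                res.summary_text() + "\n")
            try:
                if "gaze_code * coord_code" == spec.fixed:
                    pairwise_contrasts(res, ["gaze_code", "coord_code"]).to_csv(
                        out / "models" / f"{spec.name}_contrasts.csv", index=False)
                quest = next((q for q in cfg.questionnaires
                              if f"{q}_c" in spec.fixed), None)
                if quest and "gaze_code" in spec.fixed:
                    slopes = pd.concat([
                        simple_slopes(res, focal=f"{quest}_c", moderator="gaze_code",
                                      at={"coord_code": code})
                        .assign(coord_code=code)
                        for code in (0, 1)
                    ], ignore_index=True)
                    slopes.to_csv(out / "models" / f"{spec.name}_slopes.csv",
                                  index=False)
                if "gaze_prop_c" in spec.fixed and quest:
                    simple_slopes(res, focal="gaze_prop_c", moderator=f"{quest}_c"
                                  ).to_csv(
                        out / "models" / f"{spec.name}_slopes.csv", index=False)
            except DyadCoordError as exc:
                log.error("decomposition for %s failed: %s", spec.name, exc)
        n_ok = sum(1 for v in results.values() if not isinstance(v, Exception))
        log.info("fitted %d/%d models", n_ok, len(results))
        return results
    finally:
        root_logger.removeHandler(handler)
        handler.close()
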