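"""End-to-end pipeline: simulate/ingest -> calibrate -> label ->
preprocess -> features -> SQI -> statistics -> classification.

Every run writes its artifacts plus a fully serialised ``run_config``
into the output directory, so two runs with the same config and seed
produce byte-identical CSVs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import io as eio
from .calibration import WeightScheme
from .classify import (
    CVScheme,
    ModelSpec,
    compare_reports,
    evaluate_cross_subject,
    evaluate_within_subject,
)
from .exceptions import ConfigurationError, EngagEEGError
from .flow import DEFAULT_NEUTRAL_BAND, retained_subjects
from .preprocess import bandpass_filter, epoch, remove_artifact_components
from .quality import sqi_report
from .simulate import SESSIONS, SimulationConfig, simulate_cohort
from .spectral import BandDefinition, DEFAULT_NW, build_feature_table
from .stats import friedman_test, normality_screen, posthoc_pairwise

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline", "PipelineError"]


class PipelineError(EngagEEGError):
    """A stage failed; carries the stage name for diagnostics."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}': {message}")


@dataclass(frozen=True)
class RunConfig:
    """Serializable configuration of one pipeline run."""

    out_dir: str = "engageeg_run"
    seed: int = 0
    simulation: SimulationConfig | None = None
    label_source: str = "flow"
    weights_mode: str = "paper-rounded-4dp"
    neutral_band: tuple[float, float] | None = DEFAULT_NEUTRAL_BAND
    ica: bool = False
    sqi: bool = True
    stats: bool = True
    ml: bool = True
    nw: float = DEFAULT_NW
    bands: BandDefinition = field(default_factory=BandDefinition)
    families: tuple[str, ...] = ("svm", "random-forest")
    feature_sets: tuple[str, ...] = ("combined",)
    holdout_fraction: float = 0.2
    log_level: str = "INFO"

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        d = dict(d)
        if isinstance(d.get("simulation"), dict):
            d["simulation"] = SimulationConfig(**d["simulation"])
        if isinstance(d.get("bands"), dict):
            d["bands"] = BandDefinition(**{k: tuple(v) if isinstance(v, list) else v
                                           for k, v in d["bands"].items()})
        for key in ("families", "feature_sets"):
            if isinstance(d.get(key), list):
                d[key] = tuple(d[key])
        if isinstance(d.get("neutral_band"), list):
            d["neutral_band"] = tuple(d["neutral_band"])
        return cls(**d)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if self.simulation is not None:
            d["simulation"] = dataclasses.asdict(self.simulation)
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the full pipeline, writing artifacts under ``cfg.out_dir``.

    Returns a dict of the in-memory results (calibrations, labels,
    feature table, SQI report, stats, evaluation reports). Raises
    :class:`PipelineError` naming the failing stage; artifacts written
    before the failure are retained.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    provenance = {"config": cfg.to_dict(), "config_hash": cfg.config_hash()}
    with open(out / "run_config.json", "w", encoding="utf-8") as fh:
        json.dump(provenance, fh, indent=2, sort_keys=True, default=str)

    results: dict = {}
    sim = cfg.simulation or SimulationConfig(seed=cfg.seed)
    weights = WeightScheme(rounding_mode=cfg.weights_mode)

    # --- simulate ---------------------------------------------------
    stage = "simulate"
    try:
        cohort = simulate_cohort(sim, label_source=cfg.label_source, weights=weights)
        results["cohort"] = cohort
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc

    # --- calibrate --------------------------------------------------
    stage = "calibrate"
    try:
        calib_rows = []
        for s in cohort.subjects:
            t = s.calibration.table.copy()
            t.insert(0, "subject_id", s.subject_id)
            for k, v in s.calibration.assigned_levels.items():
                t[f"{k}_level"] = v
            calib_rows.append(t)
        calib_table = pd.concat(calib_rows, ignore_index=True)
        eio.write_table(calib_table, out / "calibration.csv",
                        sidecar={"weights_mode": cfg.weights_mode, **provenance})
        results["calibration"] = calib_table
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc

    # --- label ------------------------------------------------------
    stage = "label"
    try:
        labels = cohort.label_table()
        eio.write_table(labels, out / "labels.csv", sidecar=provenance)
        retained = retained_subjects(labels)
        results["labels"] = labels
        results["retained_subjects"] = retained
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc

    # --- preprocess + features -------------------------------------
    stage = "features"
    try:
        epoch_arrays = []
        ica_reports = {}
        for s in cohort.subjects:
            for sess in SESSIONS:
                rec = bandpass_filter(s.recordings[sess])
                if cfg.ica:
                    rec, rep = remove_artifact_components(rec, method="ica-infomax")
                    ica_reports[f"{s.subject_id}/{sess}"] = rep
                ep = epoch(rec)
                ep = dataclasses.replace(ep, label=s.labels[sess])
                epoch_arrays.append(ep)
        feats, meta = build_feature_table(
            epoch_arrays, bands=cfg.bands, feature_set="combined",
            channel_mode="per-channel", nw=cfg.nw,
        )
        feats_mean, _ = build_feature_table(
            epoch_arrays, bands=cfg.bands, feature_set="combined",
            channel_mode="channel-mean", nw=cfg.nw,
        )
        eio.write_table(feats, out / "features.csv", sidecar={**meta, **provenance})
        eio.write_table(feats_mean, out / "features_channel_mean.csv", sidecar=provenance)
        if ica_reports:
            with open(out / "ica_reports.json", "w", encoding="utf-8") as fh:
                json.dump(ica_reports, fh, indent=2)
        results["features"] = feats
        results["features_channel_mean"] = feats_mean
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc

    # --- sqi --------------------------------------------------------
    if cfg.sqi:
        stage = "sqi"
        try:
            recs = {s.subject_id: [s.recordings[sess] for sess in SESSIONS]
                    for s in cohort.subjects}
            sqi = sqi_report(recs, bands=cfg.bands)
            eio.write_table(sqi.table, out / "sqi.csv",
                            sidecar={**sqi.metadata, **provenance}, index=True)
            results["sqi"] = sqi
        except Exception as exc:
            raise PipelineError(stage, str(exc)) from exc

    # --- stats ------------------------------------------------------
    if cfg.stats:
        stage = "stats"
        try:
            results["stats"] = _stats_stage(labels, results["features_channel_mean"], out)
        except Exception as exc:
            raise PipelineError(stage, str(exc)) from exc

    # --- ml ---------------------------------------------------------
    if cfg.ml:
        stage = "classify"
        try:
            results["evaluations"] = _ml_stage(cfg, results, cohort, out)
        except Exception as exc:
            raise PipelineError(stage, str(exc)) from exc

    logger.info("pipeline run complete: %s", out)
    return results


def _stats_stage(labels: pd.DataFrame, feats_mean: pd.DataFrame, out: Path) -> dict:
    stats: dict = {}
    wide = labels.pivot(index="subject_id", columns="session", values="rated_score")
    wide = wide[list(SESSIONS)].dropna()
    if len(wide) >= 3:
        stats["normality_rated"] = normality_screen(
            {sess: wide[sess].to_numpy() for sess in SESSIONS}
        )
    fr = friedman_test(wide.to_numpy(), condition_names=SESSIONS)
    stats["friedman_rated"] = fr
    stats["posthoc_rated"] = posthoc_pairwise(fr)

    # channel-mean engagement indices, averaged over epochs per session
    for idx in ("e1", "e2", "e3"):
        col = f"{idx}_mean"
        agg = (
            feats_mean.groupby(["subject_id", "session"])[col]
            .mean()
            .unstack("session")
        )
        agg = agg[[s for s in SESSIONS if s in agg.columns]].dropna()
        if agg.shape[1] == len(SESSIONS) and len(agg) >= 2:
            stats[f"friedman_{idx}"] = friedman_test(
                agg.to_numpy(), condition_names=tuple(agg.columns)
            )

    lines = [stats["friedman_rated"].summary()]
    for pc in stats["posthoc_rated"]:
        lines.append(
            f"  {pc.pair[0]} vs {pc.pair[1]}: z={pc.z:.2f}, p_adj={pc.p_adjusted:.3f}"
        )
    for idx in ("e1", "e2", "e3"):
        key = f"friedman_{idx}"
        if key in stats:
            lines.append(f"index {idx}: " + stats[key].summary())
    (out / "stats_report.txt").write_text("\n".join(lines) + "\n", encoding="utf-8")
    return stats


def _ml_stage(cfg: RunConfig, results: dict, cohort, out: Path) -> dict:
    feats = results["features"]
    retained = results["retained_subjects"]
    usable = feats[feats["subject_id"].isin(retained)] if retained else feats
    if usable.empty or usable["subject_id"].nunique() < 2:
        logger.warning("too few retained subjects for ML; skipping")
        return {}
    age_groups = cohort.age_groups()
    evaluations = {}
    reports = []
    for family in cfg.families:
        model = ModelSpec(family=family)
        within = evaluate_within_subject(
            usable, model,
            CVScheme(mode="within-subject", nested=True, seed=cfg.seed,
                     holdout_fraction=cfg.holdout_fraction),
            age_groups=age_groups,
        )
        cross = evaluate_cross_subject(
            usable, model,
            CVScheme(mode="cross-subject", tuning_folds=5, seed=cfg.seed,
                     holdout_fraction=cfg.holdout_fraction),
        )
        evaluations[f"{family}_within"] = within
        evaluations[f"{family}_cross"] = cross
        reports.append(within)
        eio.write_table(within.per_unit, out / f"eval_within_{family}.csv",
                        sidecar=within.metadata)
        eio.write_table(cross.per_unit, out / f"eval_cross_{family}.csv",
                        sidecar=cross.metadata)
    if len(reports) > 1:
        comparison = compare_reports(reports, grouping="classifier")
        eio.write_table(comparison, out / "classifier_comparison.csv")
        evaluations["comparison"] = comparison
    return evaluations
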