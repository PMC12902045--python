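"""End-to-end orchestration: simulate -> preprocess -> extract -> label ->
stats -> classify, with per-phase isolation and a reproducibility manifest.

In vivo and ex vivo phases share every code path but no data: each phase
gets its own run subdirectory, cohort, weights, statistics and classifier
report. Rerunning with an unchanged config and seed reproduces all
deterministic outputs.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as fio
from .classify import FeatureCombo, grid_search_combos, evaluate_patient, summarize_cohort
from .coregister import assign_labels, label_summary
from .features import extract_features, feature_columns, FEATURE_GROUPS
from .instrument import InstrumentModel
from .laguerre import LaguerreConfig
from .features import PhasorConfig
from .mlwpca import mlwpca_feature_blocks, multilevel_weighted_pca
from .preprocess import QualityThresholds, apply_quality_filters, subtract_background, upsample
from .screen import univariable_screen
from .selection import backward_select
from .synthetic import CohortConfig, generate_cohort, preset_tissue_models
from .transforms import transform_features
from .weights import compute_weights

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass(frozen=True)
class PipelineConfig:
    """Structured configuration for one pipeline run."""

    out_dir: str = "runs/demo"
    phases: tuple[str, ...] = ("in_vivo", "ex_vivo")
    seed: int = 0
    n_patients: int = 15
    n_mixed: int = 13
    n_healthy_only: int = 2
    points_per_class: int = 2000
    interface_buffer_mm: float = 0.5
    snr_min_db: float = 20.0
    skew_threshold: float = 1.0
    vif_threshold: float = 10.0
    p_threshold: float = 0.05
    classifier_family: str = "tree"
    classifier_combo: str = "auto"
    cohort_overrides: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "phases" in raw:
            raw["phases"] = tuple(raw["phases"])
        return cls(**raw)


def _prepare_phase_features(cohort, instrument: InstrumentModel, thresholds: QualityThresholds) -> pd.DataFrame:
    """Preprocess + extract features for every patient scan in a cohort."""
    frames = []
    for patient in cohort.patients:
        ws = patient.waveforms
        bg = instrument.background_waveform
        if bg is not None:
            per_point = (ws.gains / 100.0)[:, :, None] * bg[None, :, :]
            ws = subtract_background(ws, per_point)
        ws = upsample(ws, instrument.sample_rate_up)
        kept, _rejected = apply_quality_filters(ws, thresholds)
        if kept.n_points == 0:
            continue
        frames.append(extract_features(kept, instrument))
    return pd.concat(frames, ignore_index=True)


def _run_phase(cfg: PipelineConfig, phase: str, run_dir: Path, digest: str) -> dict:
    phase_dir = run_dir / phase
    phase_dir.mkdir(parents=True, exist_ok=True)
    outputs: dict = {}

    # simulate ------------------------------------------------------------
    t0 = time.time()
    cohort_cfg = CohortConfig(
        phase=phase,
        n_patients=cfg.n_patients,
        n_mixed=cfg.n_mixed,
        n_healthy_only=cfg.n_healthy_only,
        points_per_class=cfg.points_per_class,
        rng_seed=cfg.seed + {"in_vivo": 0, "ex_vivo": 1}.get(phase, 2),
        **cfg.cohort_overrides,
    )
    instrument = InstrumentModel()
    cohort = generate_cohort(cohort_cfg, instrument, preset_tissue_models(phase))
    # generate_cohort attaches the background template it used
    if cohort.patients[0].waveforms is not None:
        from .synthetic import _background_template

        instrument = replace(instrument, background_waveform=_background_template(instrument, cohort_cfg))
    fio.write_cohort(cohort, phase_dir / "cohort")
    fio.update_manifest(run_dir, f"{phase}/simulate", {"seconds": round(time.time() - t0, 2)})

    # extract -------------------------------------------------------------
    t0 = time.time()
    thresholds = QualityThresholds(snr_min_db=cfg.snr_min_db)
    features = _prepare_phase_features(cohort, instrument, thresholds)
    fio.write_table(features, phase_dir / "features.csv", cfg.seed, digest)
    fio.update_manifest(run_dir, f"{phase}/extract", {"seconds": round(time.time() - t0, 2), "n_points": len(features)})

    # label ---------------------------------------------------------------
    t0 = time.time()
    labeled_parts = []
    for patient in cohort.patients:
        part = features[features["patient_id"] == patient.patient_id].copy()
        lab = assign_labels(part[["x_mm", "y_mm"]].to_numpy(), patient.mask, cfg.interface_buffer_mm)
        part[["label", "excluded", "exclusion_reason"]] = lab.to_numpy()
        labeled_parts.append(part)
    labeled = pd.concat(labeled_parts, ignore_index=True)
    summary = label_summary(labeled)
    fio.write_table(labeled, phase_dir / "features_labeled.csv", cfg.seed, digest)
    fio.write_table(summary, phase_dir / "label_summary.csv", cfg.seed, digest)
    analysis = labeled[(~labeled["excluded"].astype(bool)) & (~labeled["incomplete"].astype(bool))].reset_index(drop=True)
    fio.update_manifest(run_dir, f"{phase}/label", {"seconds": round(time.time() - t0, 2), "n_analyzed": len(analysis)})

    # stats ---------------------------------------------------------------
    t0 = time.time()
    scheme = compute_weights(analysis)
    feat_cols = feature_columns(analysis.columns, FEATURE_GROUPS)
    transformed, tlog = transform_features(analysis, feat_cols, scheme.weights, cfg.skew_threshold)
    fio.write_table(tlog, phase_dir / "transform_log.csv", cfg.seed, digest)

    effects = univariable_screen(transformed, feat_cols, scheme.weights)
    fio.write_table(effects, phase_dir / "effect_sizes.csv", cfg.seed, digest)

    blocks = mlwpca_feature_blocks(feat_cols)
    pca_report = {}
    pc_scores = {}
    for name, cols in blocks.items():
        model = multilevel_weighted_pca(transformed, cols, scheme.weights)
        scores = model.transform(transformed, scheme.weights)
        for c in scores.columns:
            pc_scores[f"{name}_{c}"] = scores[c].to_numpy()
        pca_report[name] = {
            "between_varexp": model.between_varexp.tolist(),
            "within_varexp": model.within_varexp.tolist(),
            "fit_subjects": list(map(str, model.fit_subjects)),
        }
    import json

    (phase_dir / "mlwpca.json").write_text(json.dumps(pca_report, indent=2))

    design = pd.DataFrame(
        {
            **{c: transformed[c].to_numpy() for c in feature_columns(feat_cols, ("intensity_ratios", "lifetimes"))},
            **pc_scores,
        }
    )
    y = (transformed["label"].astype(str) == "cancer").to_numpy(dtype=int)
    sel = backward_select(
        y, design, transformed["patient_id"].to_numpy(), scheme.weights,
        cfg.vif_threshold, cfg.p_threshold,
    )
    if sel.model is not None:
        fio.write_table(
            sel.model.summary_frame().reset_index(names="predictor"),
            phase_dir / "logistic_model.csv", cfg.seed, digest,
        )
    (phase_dir / "selection_audit.json").write_text(json.dumps(sel.audit_trail, indent=2))
    fio.update_manifest(run_dir, f"{phase}/stats", {"seconds": round(time.time() - t0, 2)})

    # classify ------------------------------------------------------------
    t0 = time.time()
    if cfg.classifier_combo == "auto":
        ranking = grid_search_combos(transformed, cfg.classifier_family, None, scheme.weights, cfg.seed)
        fio.write_table(ranking, phase_dir / "combo_ranking.csv", cfg.seed, digest)
        best = ranking.iloc[0]["combo"]
    elif cfg.classifier_combo == "all":
        best = "+".join(FEATURE_GROUPS)
    else:
        best = cfg.classifier_combo
    combo = FeatureCombo(groups=tuple(best.split("+")))
    cols = combo.resolve(transformed.columns)
    reports = []
    roc_rows = []
    for pid in sorted(transformed["patient_id"].unique()):
        rep = evaluate_patient(transformed, cols, pid, cfg.classifier_family, None, scheme.weights, cfg.seed)
        if rep.get("excluded"):
            continue
        for fpr, tpr in zip(rep.pop("roc_fpr"), rep.pop("roc_tpr")):
            roc_rows.append({"patient_id": pid, "fpr": fpr, "tpr": tpr})
        reports.append(rep)
    per_patient = pd.DataFrame(reports)
    rollup = summarize_cohort(per_patient)
    fio.write_table(per_patient, phase_dir / "classifier_per_patient.csv", cfg.seed, digest)
    fio.write_table(pd.DataFrame(roc_rows), phase_dir / "roc_points.csv", cfg.seed, digest)
    (phase_dir / "classifier_report.json").write_text(
        json.dumps({"combo": best, "family": cfg.classifier_family, "seed": cfg.seed, **rollup}, indent=2)
    )
    fio.update_manifest(run_dir, f"{phase}/classify", {"seconds": round(time.time() - t0, 2), "combo": best})

    outputs.update(
        {
            "effects": effects,
            "selection": sel,
            "classifier_rollup": rollup,
            "label_summary": summary,
            "n_analyzed": len(analysis),
        }
    )
    return outputs


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run every stage for every configured phase; returns per-phase outputs."""
    run_dir = Path(cfg.out_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    # digest covers the analysis-relevant settings, not the output location
    digest = fio.config_digest({k: v for k, v in cfg.__dict__.items() if k != "out_dir"})
    fio.write_manifest(run_dir, cfg.seed, digest)
    results: dict = {}
    for phase in cfg.phases:
        try:
            results[phase] = _run_phase(cfg, phase, run_dir, digest)
        except Exception as exc:
            fio.update_manifest(run_dir, f"{phase}/FAILED", {"error": repr(exc)})
            raise
    return results
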