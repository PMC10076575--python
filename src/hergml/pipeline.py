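"""Config-driven experiment orchestration.

An experiment curates an activity table, builds the requested feature
assembly (ligand-based, structure-based best-pose or average, their
combinations, or a multi-engine consensus), runs seeded ten-fold
cross-validation, fits a final model, and — when an external set is
configured — scores it and reports applicability-domain verdicts plus
the accuracy-vs-similarity trend.  All outputs land in one directory
with a JSON manifest sufficient to reproduce the run.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .applicability import (
    ADThresholds,
    assess,
    fit_ad_reference,
    trend_report,
    verdicts_to_frame,
)
from .curation import CuratedCompound, curate, read_activity_table, write_curated_table
from .evaluation import comparison_table
from .feature_selection import SelectionConfig, best_first_select, write_selection
from .lb_features import (
    FeatureMatrix,
    compute_lb_features,
    compute_pca_descriptors,
    ecfp6,
)
from .modeling import ModelSpec, evaluate_on, predict, ten_fold_cv, train
from .sb_features import (
    AggregationSpec,
    assemble_consensus_features,
    best_pose_features,
    average_pose_features,
    read_pose_table,
)

logger = logging.getLogger(__name__)

FEATURE_MODES = ("lb", "sb_bp", "sb_av", "lb+sb_bp", "lb+sb_av", "consensus")


@dataclass
class PipelineConfig:
    activity_table: str
    mode: str = "lb"
    pose_tables: dict[str, str] = field(default_factory=dict)
    engines: list[str] = field(default_factory=list)
    aggregation: str = "average"  # consensus mode: best_pose | average
    external_activity_table: str | None = None
    external_pose_tables: dict[str, str] = field(default_factory=dict)
    n_trees: int = 100
    max_depth: int = 0
    select_lb_features: bool = True
    pk_threshold: float = 5.0
    ad_min_methods: int = 3
    output_dir: str = "experiment"
    seed: int = 0

    def __post_init__(self):
        if self.mode not in FEATURE_MODES:
            raise ValueError(f"mode must be one of {FEATURE_MODES}, got {self.mode!r}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)


def _labels_for(curated: list[CuratedCompound], ids) -> pd.Series:
    by_id = {c.compound_id: c.label for c in curated}
    return pd.Series([by_id[i] for i in ids], index=ids)


def _sb_matrix(pose_table, mode_suffix: str) -> FeatureMatrix:
    if mode_suffix == "bp" or mode_suffix == "best_pose":
        return best_pose_features(pose_table)
    return average_pose_features(pose_table)


def build_features(
    config: PipelineConfig,
    curated: list[CuratedCompound],
    pose_tables: dict[str, object],
    lb_selected: list[str] | None = None,
) -> tuple[FeatureMatrix, list[str] | None]:
    """Assemble the feature matrix for the configured mode.

    Returns (matrix, selected LB feature names or None).  For combined
    modes the LB block is restricted to the selected subset; SB rows
    limit the matrix to compounds docked by the required engines.
    """
    mode = config.mode
    needs_lb = mode in ("lb", "lb+sb_bp", "lb+sb_av")
    lb_matrix = None
    if needs_lb:
        lb_matrix = compute_lb_features(curated)
        if config.select_lb_features:
            if lb_selected is None:
                labels = _labels_for(curated, lb_matrix.compound_ids)
                lb_selected = best_first_select(
                    lb_matrix, labels, SelectionConfig()
                )
            if lb_selected:
                lb_matrix = lb_matrix.subset(lb_selected)

    if mode == "lb":
        return lb_matrix, lb_selected

    engines = config.engines or list(pose_tables)
    if mode == "consensus":
        if len(engines) < 2:
            raise ValueError("consensus mode needs at least two engines")
        per_engine = {
            e: _sb_matrix(pose_tables[e], config.aggregation) for e in engines
        }
        return assemble_consensus_features(per_engine), lb_selected

    suffix = mode.split("sb_")[-1]  # bp | av
    if len(engines) != 1:
        raise ValueError(f"mode {mode!r} uses exactly one engine, got {engines}")
    sb = _sb_matrix(pose_tables[engines[0]], suffix)
    if mode.startswith("lb+"):
        return lb_matrix.join(sb), lb_selected
    return sb, lb_selected


def run_experiment(config: PipelineConfig) -> Path:
    """Execute the configured experiment; returns the output directory."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    records = read_activity_table(config.activity_table)
    curated = curate(records, threshold=config.pk_threshold)
    write_curated_table(curated, out / "curated.tsv")

    pose_tables = {
        engine: read_pose_table(path, engine=engine)
        for engine, path in config.pose_tables.items()
    }

    features, lb_selected = build_features(config, curated, pose_tables)
    features.write(out / "features.tsv")
    if lb_selected is not None:
        write_selection(lb_selected, out / "selected_lb_features.txt")

    labels = _labels_for(curated, features.compound_ids)
    spec = ModelSpec(
        n_trees=config.n_trees, max_depth=config.max_depth, seed=config.seed
    )
    cv_report = ten_fold_cv(features, labels, spec, seed=config.seed)
    (out / "cv_report.json").write_text(cv_report.to_json(indent=1))

    smiles_by_id = {c.compound_id: c.canonical_smiles for c in curated}
    train_fps = np.stack([ecfp6(smiles_by_id[i]) for i in features.compound_ids])
    train_desc = compute_pca_descriptors(
        [(i, smiles_by_id[i]) for i in features.compound_ids]
    )
    ad_ref = fit_ad_reference(
        train_fps, train_desc, ADThresholds(min_methods=config.ad_min_methods)
    )
    bundle = train(
        features, labels, spec,
        training_fingerprints=train_fps, ad_reference=ad_ref,
    )
    bundle.save(out / "model.joblib")
    bundle.feature_importances.to_csv(out / "feature_importances.tsv", sep="\t")

    reports = {"cv": cv_report}
    if config.external_activity_table:
        ext_report = _external_validation(
            config, curated, bundle, ad_ref, lb_selected, out
        )
        reports["external"] = ext_report

    comparison_table(reports).to_csv(out / "metrics.tsv", sep="\t")
    manifest = {
        "version": __version__,
        "config": asdict(config),
        "n_curated": len(curated),
        "n_features": len(features.feature_names),
        "n_train": len(labels),
        "selected_lb_features": lb_selected,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return out


def _external_validation(config, curated, bundle, ad_ref, lb_selected, out: Path):
    ext_records = read_activity_table(config.external_activity_table)
    ext_curated = curate(ext_records, threshold=config.pk_threshold)
    write_curated_table(ext_curated, out / "external_curated.tsv")

    ext_pose = {
        engine: read_pose_table(path, engine=engine)
        for engine, path in config.external_pose_tables.items()
    }
    ext_features, _ = build_features(config, ext_curated, ext_pose, lb_selected)
    ext_labels = _labels_for(ext_curated, ext_features.compound_ids)
    ext_report = evaluate_on(bundle, ext_features, ext_labels.to_numpy())
    (out / "external_report.json").write_text(ext_report.to_json(indent=1))

    smiles_by_id = {c.compound_id: c.canonical_smiles for c in ext_curated}
    ids = ext_features.compound_ids
    ext_fps = np.stack([ecfp6(smiles_by_id[i]) for i in ids])
    ext_desc = compute_pca_descriptors([(i, smiles_by_id[i]) for i in ids])
    verdicts = assess(ext_fps, ext_desc, ad_ref)
    vframe = verdicts_to_frame(verdicts, index=ids)
    vframe.to_csv(out / "ad_verdicts.tsv", sep="\t", index_label="compound_id")

    preds = predict(bundle, ext_features)
    trend = trend_report(
        vframe["nearest_neighbor_tc"].to_numpy(),
        ext_labels.to_numpy(),
        preds["label"].to_numpy(),
    )
    trend.to_csv(out / "similarity_trend.tsv", sep="\t", index=False)
    return ext_report
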