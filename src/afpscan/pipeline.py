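"""End-to-end orchestration: filter, encode, balance, rank, select, train, report.

Two modes are supported.  ``paper-faithful`` oversamples the whole training
partition once with MWMOTE before ranking and cross-validation, so CV folds
may contain synthetic rows derived from each other (the historically common
but leaky protocol).  ``leakage-safe`` ranks on the raw training partition
and applies MWMOTE inside each CV training fold only.  In both modes the
independent test partition is fixed before any oversampling and never
contains synthetic rows, and the final model for test evaluation is trained
on the balanced training partition.

All randomness flows from the single top-level seed through fixed per-stage
offsets, so a run is bit-reproducible from its manifest.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from . import classify, encoding, feature_selection, pca_analysis, pssm_io, resampling
from .containers import FeatureTable
from .synthetic import SimulationConfig, simulate_pssm_profiles

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "RunArtifacts", "run_pipeline"]

_STAGE_OFFSETS = {
    "split": 1,
    "resample": 2,
    "rank": 3,
    "select": 4,
    "train": 5,
    "simulate": 6,
}


def _stage_seed(seed: int, stage: str) -> int:
    return (seed * 1009 + _STAGE_OFFSETS[stage]) % 2**31


@dataclass
class PipelineConfig:
    """One fully specified run.  Exactly one input source must be set."""

    fasta: str | None = None
    pssm_dir: str | None = None
    feature_table: str | None = None
    simulate: SimulationConfig | None = None
    train_fraction: float = 0.8
    target_ratio: float = 0.78
    n_ensemble: int = 20
    K_max: int = 200
    monitor: str = "auc"
    mode: str = "leakage-safe"
    grid: list | None = None
    cv_folds: int = 5
    seed: int = 0
    out_dir: str = "afpscan_run"

    def __post_init__(self) -> None:
        if self.mode not in ("paper-faithful", "leakage-safe"):
            raise ValueError(f"unknown mode {self.mode!r}")
        sources = [
            self.feature_table is not None,
            self.fasta is not None and self.pssm_dir is not None,
            self.simulate is not None,
        ]
        if sum(sources) != 1:
            raise ValueError(
                "exactly one input source required: feature_table, "
                "fasta+pssm_dir, or simulate"
            )

    def to_dict(self) -> dict:
        payload = dataclasses.asdict(self)
        if self.simulate is not None:
            payload["simulate"] = dataclasses.asdict(self.simulate)
        return payload


@dataclass
class RunArtifacts:
    """Paths of every report a run wrote, plus the manifest."""

    out_dir: Path
    paths: dict[str, Path]
    manifest_path: Path
    checksums: dict[str, str] = field(default_factory=dict)

    def checksum(self, name: str) -> str:
        return self.checksums[name]


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _acquire_table(config: PipelineConfig) -> tuple[FeatureTable, dict]:
    """Stage 1: load or simulate the 400-feature table; report filtering counts."""
    if config.feature_table is not None:
        table = pssm_io.read_feature_table(config.feature_table)
        report = {"source": "feature_table", "n_samples": table.n_samples}
        return table, report
    if config.simulate is not None:
        sim = dataclasses.replace(
            config.simulate, seed=_stage_seed(config.seed, "simulate")
        )
        profiles, labels = simulate_pssm_profiles(sim)
        table = encoding.encode_dataset(profiles, labels)
        report = {
            "source": "simulate",
            "n_samples": table.n_samples,
            "planted_indices": sim.planted_indices,
        }
        return table, report
    sequences = pssm_io.read_fasta(config.fasta)
    retained, rejected = pssm_io.filter_ambiguous(sequences)
    profiles, skipped = pssm_io.load_profiles(retained, config.pssm_dir)
    kept_ids = {p.id for p in profiles}
    labels_path = Path(config.pssm_dir) / "labels.json"
    if not labels_path.exists():
        raise FileNotFoundError(
            f"expected a labels.json next to the PSSMs: {labels_path}"
        )
    label_map = json.loads(labels_path.read_text())
    labels = [int(label_map[p.id]) for p in profiles]
    table = encoding.encode_dataset(profiles, labels)
    report = {
        "source": "fasta",
        "n_input": len(sequences),
        "n_ambiguous_rejected": len(rejected),
        "rejected_ids": [s.id for s in rejected],
        "n_missing_pssm": len(skipped),
        "n_encoded": len(kept_ids),
    }
    return table, report


def run_pipeline(config: PipelineConfig) -> RunArtifacts:
    """Execute every stage and write all artifacts under ``config.out_dir``."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    def stage(name):
        logger.info("pipeline stage: %s", name)

    # 1. acquire + filter + encode -------------------------------------
    stage("acquire")
    try:
        table, input_report = _acquire_table(config)
    except Exception as exc:
        raise RuntimeError(f"stage 'acquire' failed: {exc}") from exc
    paths["input_report"] = out_dir / "input_report.json"
    paths["input_report"].write_text(json.dumps(input_report, indent=2))
    paths["feature_table"] = out_dir / "features.csv"
    pssm_io.write_feature_table(table, paths["feature_table"])

    # 2. split ----------------------------------------------------------
    stage("split")
    train, test = classify.stratified_split(
        table, config.train_fraction, seed=_stage_seed(config.seed, "split")
    )
    logger.info(
        "split: %d train (%d afp) / %d test (%d afp)",
        train.n_samples, train.n_minority, test.n_samples, test.n_minority,
    )

    # 3. balance the training partition ---------------------------------
    stage("resample")
    plan = resampling.ResamplePlan(
        target_ratio=config.target_ratio, seed=_stage_seed(config.seed, "resample")
    )
    balanced = resampling.mwmote_oversample(train, plan)
    paths["balanced_table"] = out_dir / "train_balanced.csv"
    pssm_io.write_feature_table(balanced, paths["balanced_table"])

    paper_faithful = config.mode == "paper-faithful"
    rank_table = balanced if paper_faithful else train
    cv_table = balanced if paper_faithful else train

    # 4. ensemble mRMR ranking ------------------------------------------
    stage("rank")
    ranking = feature_selection.ensemble_rank(
        rank_table,
        n_ensemble=config.n_ensemble,
        K=config.K_max,
        seed=_stage_seed(config.seed, "rank"),
    )
    paths["ranking"] = out_dir / "ranking.json"
    paths["ranking"].write_text(json.dumps(ranking.to_dict()))

    # 5. incremental selection ------------------------------------------
    stage("select")
    selection = feature_selection.incremental_select(
        ranking,
        train=balanced,
        test=test,
        K_max=config.K_max,
        monitor=config.monitor,
        cv_folds=config.cv_folds,
        seed=_stage_seed(config.seed, "select"),
        grid=config.grid if config.grid is not None else classify.fast_grid(),
        cv_table=cv_table,
        resample_inside=not paper_faithful,
        resample_plan=plan if not paper_faithful else None,
    )
    paths["selection"] = out_dir / "selection.json"
    paths["selection"].write_text(json.dumps(selection.to_dict()))

    # 6. final model + reports ------------------------------------------
    stage("train")
    model = classify.train_svm(
        balanced,
        grid=config.grid if config.grid is not None else classify.fast_grid(),
        cv_folds=config.cv_folds,
        seed=_stage_seed(config.seed, "train"),
        feature_indices=selection.selected_indices,
    )
    paths["model"] = out_dir / "model.json"
    model.to_json(paths["model"])

    cv_report = classify.cross_validate(
        cv_table,
        folds=config.cv_folds,
        seed=_stage_seed(config.seed, "select"),
        feature_indices=selection.selected_indices,
        C=model.C,
        gamma=model.gamma,
        resample_inside=not paper_faithful,
        resample_plan=plan if not paper_faithful else None,
    )
    test_report = classify.evaluate(
        test.labels, classify.decision_values(model, test), context="test"
    )
    paths["cv_report"] = out_dir / "cv_report.json"
    paths["cv_report"].write_text(json.dumps(cv_report.to_dict(), indent=2))
    paths["test_report"] = out_dir / "test_report.json"
    paths["test_report"].write_text(json.dumps(test_report.to_dict(), indent=2))

    # 7. PCA of the selected key features -------------------------------
    stage("pca")
    pca = pca_analysis.fit_pca(balanced, feature_indices=selection.selected_indices)
    paths["pca_report"] = out_dir / "pca_report.json"
    paths["pca_report"].write_text(json.dumps(pca.to_dict()))

    # 8. manifest --------------------------------------------------------
    checksums = {name: _sha256(path) for name, path in paths.items()}
    manifest = {
        "config": config.to_dict(),
        "seed": config.seed,
        "afpscan_version": __version__,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "k_selected": int(selection.k_selected),
        "selected_features": [
            balanced.feature_names[i] for i in selection.selected_indices
        ],
        "checksums": checksums,
    }
    manifest_path = out_dir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2))
    return RunArtifacts(
        out_dir=out_dir, paths=paths, manifest_path=manifest_path, checksums=checksums
    )
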