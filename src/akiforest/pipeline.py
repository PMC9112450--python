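"""End-to-end orchestration: cohort -> split -> select -> tune -> train ->
prune -> evaluate -> report, with a manifest for reproducibility."""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np

from . import __version__
from .boolmin import prune_forest
from .evaluate import DEFAULT_GRID, grid_search, kfold_cv, optimized_split
from .features import greedy_select, oof_surrogate
from .forest import fit_forest, serialize_model
from .records import PREOP_FEATURES, LabeledDataset, read_patients_csv

log = logging.getLogger("akiforest")


@dataclass(frozen=True)
class RunConfig:
    """Configuration for one pipeline run. ``seed`` is mandatory."""

    input_csv: str
    output_dir: str
    seed: int
    split_ratio: float = 0.8
    split_repeats: int = 1000
    select_features: bool = False
    min_gain: float = 0.01
    grid: Mapping[str, tuple] = field(default_factory=lambda: dict(DEFAULT_GRID))
    cv_folds: int = 5
    surrogate_k: int = 5
    egfr_formula: str = "ckd-epi"

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("a seed is required for every stochastic stage")

    def digest(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def run_pipeline(config: RunConfig, data: LabeledDataset | None = None) -> dict:
    """Execute every stage and write artifacts + manifest to the output dir.

    Deterministic: re-running with an identical config (and input) produces
    byte-identical metrics and manifest.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    t_start = time.time()
    stage = "load"
    try:
        if data is None:
            data = read_patients_csv(config.input_csv)
        log.info("loaded %d records", len(data))

        stage = "split"
        split = optimized_split(
            data, ratio=config.split_ratio, repeats=config.split_repeats,
            seed=config.seed,
        )
        train = data.subset(split.train_indices)
        valid = data.subset(split.valid_indices)
        log.info("split balance score %.4f (warning=%s)",
                 split.balance_score, split.significant_imbalance)

        stage = "select"
        if config.select_features:
            subset = greedy_select(
                train, candidates=train.feature_names,
                min_gain=config.min_gain, seed=config.seed,
            )
            train = train.with_features(subset.features)
            valid = valid.with_features(subset.features)
            selected = list(subset.features)
            trace = list(subset.accuracy_trace)
        else:
            selected = list(train.feature_names)
            trace = []

        stage = "grid-search"
        best_hyper, score_table = grid_search(
            train, grid=config.grid, k=config.cv_folds, seed=config.seed
        )
        score_table.to_csv(out / "grid_scores.csv", index=False)

        stage = "train"
        model = fit_forest(train, best_hyper, seed=config.seed)
        (out / "model.json").write_text(serialize_model(model))

        stage = "prune"
        pruned = prune_forest(model)
        (out / "model_pruned.json").write_text(serialize_model(pruned))

        stage = "evaluate"
        cv = kfold_cv(
            train, builder=lambda d, s: fit_forest(d, best_hyper, s),
            k=config.cv_folds, seed=config.seed,
        )
        np.savetxt(out / "roc_points.csv", cv.roc_points,
                   delimiter=",", header="fpr,tpr,threshold", comments="")
        v_labels, v_scores = pruned.predict_batch(valid.X)
        valid_accuracy = float((v_labels == valid.y).mean())
        u_labels, _ = model.predict_batch(valid.X)
        assert (u_labels == v_labels).all(), "pruning must not change predictions"

        metrics = {
            "n_records": len(data),
            "n_train": len(train),
            "n_valid": len(valid),
            "selected_features": selected,
            "selection_trace": trace,
            "best_hyper": {
                "depth": best_hyper.depth, "MSPL": best_hyper.MSPL,
                "LC": best_hyper.LC, "n": best_hyper.n,
            },
            "cv_precision_mean": cv.precision_mean,
            "cv_precision_sd": cv.precision_sd,
            "cv_recall_mean": cv.recall_mean,
            "cv_recall_sd": cv.recall_sd,
            "cv_accuracy_mean": cv.accuracy_mean,
            "cv_auc": cv.auc,
            "confusion_pred_layout": cv.confusion.tolist(),
            "confusion_standard": cv.confusion_standard.tolist(),
            "validation_accuracy": valid_accuracy,
            "leaves_before_pruning": [t.n_leaves for t in model.trees],
            "leaves_after_pruning": [t.n_leaves for t in pruned.trees],
            "split_balance_score": split.balance_score,
            "split_p_values": split.p_values,
            "split_warning": split.significant_imbalance,
        }
        (out / "metrics.json").write_text(json.dumps(metrics, indent=1, sort_keys=True))

        manifest = {
            "version": __version__,
            "config": asdict(config),
            "config_digest": config.digest(),
            "seed": config.seed,
            "artifacts": sorted(
                p.name for p in out.iterdir() if p.name != "manifest.json"
            ),
            "metrics_sha256": hashlib.sha256(
                (out / "metrics.json").read_bytes()
            ).hexdigest(),
        }
        manifest = {k: v for k, v in manifest.items()}
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True, default=str))
        log.info("pipeline finished in %.1fs", time.time() - t_start)
        return metrics
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc
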