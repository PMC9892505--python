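"""End-to-end orchestration: ingest → annotate → augment → select → evaluate.

The stages mirror the model-building flow: audiograms are ingested (or
synthesized), normal-hearing audiograms dropped, shape classes assigned by
spectral clustering with weak members cleaned away, the labelled set
augmented with every normalization method, the methods gated statistically,
features computed per retained dataset, and the 1-NN classifier evaluated
per dataset and on the combined training set.  Every artifact is written
under the output directory and a machine-readable manifest records the
configuration, per-stage counts and timings.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Union

import numpy as np

from audioshape.annotate import (
    choose_k,
    clean_weak_members,
    drop_normal_hearing,
    spectral_cluster,
)
from audioshape.classify import EvalReport, cross_validate, metrics_from_confusion
from audioshape.core import Audiogram, PipelineConfig, ReferenceSet, negate, read_audiograms, write_audiograms
from audioshape.features import base_features, reduce_all
from audioshape.normalization import augment, list_methods
from audioshape.stat_selection import select_normalizations
from audioshape.synth import bisgaard_like_archetypes, make_dataset, make_reference_set

logger = logging.getLogger("audioshape")

__all__ = ["RunManifest", "run_pipeline", "featurize_dataset", "evaluate_datasets"]


@dataclass
class RunManifest:
    """Machine-readable record of one pipeline run."""

    config: dict
    input_path: Optional[str]
    out_dir: str
    counts: Dict[str, object] = field(default_factory=dict)
    timings_s: Dict[str, float] = field(default_factory=dict)
    artifacts: Dict[str, str] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "config": self.config,
            "input_path": self.input_path,
            "out_dir": self.out_dir,
            "counts": self.counts,
            "timings_s": self.timings_s,
            "artifacts": self.artifacts,
        }


def featurize_dataset(
    audiograms: Sequence[Audiogram],
    refs: ReferenceSet,
    reduced: bool = True,
) -> list:
    """Base (optionally fully reduced) feature vectors for a dataset."""
    out = []
    for a in audiograms:
        fv = base_features(a, refs)
        out.append(reduce_all(fv) if reduced else fv)
    return out


def _common_ids(datasets) -> list:
    """Ids present in every dataset (some methods may skip degenerate rows)."""
    common = None
    for d in datasets:
        ids = {a.id for a in d.audiograms}
        common = ids if common is None else common & ids
    return sorted(common or set())


def _restrict(datasets, ids: Sequence[str]):
    """Filter each dataset to the given ids, preserving order."""
    from audioshape.normalization import NormalizedDataset

    wanted = set(ids)
    out = []
    for d in datasets:
        out.append(
            NormalizedDataset(
                method_name=d.method_name,
                audiograms=[a for a in d.audiograms if a.id in wanted],
                scope=d.scope,
                skipped_ids=d.skipped_ids,
            )
        )
    return out


def evaluate_datasets(
    training_sets: Dict[str, list],
    config: PipelineConfig,
) -> dict:
    """Cross-validate each training set and the combined pool.

    ``training_sets`` maps a dataset name to its labelled reduced feature
    vectors.  Returns per-dataset reports, the per-class average across
    datasets, and the report of the combined pool.
    """
    per_dataset: Dict[str, EvalReport] = {}
    for name, vectors in training_sets.items():
        per_dataset[name] = cross_validate(
            vectors, n_folds=config.n_folds, seed=config.seed, knn_k=config.knn_k,
            whole_set_fitting=config.whole_set_fitting,
        )
    combined_vectors = [fv for vectors in training_sets.values() for fv in vectors]
    combined = cross_validate(
        combined_vectors, n_folds=config.n_folds, seed=config.seed, knn_k=config.knn_k,
        whole_set_fitting=config.whole_set_fitting,
    )

    # per-class average over the per-dataset reports
    classes = combined.classes
    averaged = {}
    for c in classes:
        averaged[c] = {
            m: float(np.mean([
                r.per_class[c][m] for r in per_dataset.values() if c in r.per_class
            ]))
            for m in ("accuracy", "precision", "recall", "specificity", "f_score")
        }
    averaged_overall = {
        m: float(np.mean([v[m] for v in averaged.values()]))
        for m in ("accuracy", "precision", "recall", "specificity", "f_score")
    }
    return {
        "per_dataset": per_dataset,
        "class_average": {"per_class": averaged, "overall": averaged_overall},
        "combined": combined,
    }


def run_pipeline(
    config: PipelineConfig,
    in_path: Optional[Union[str, Path]] = None,
    out_dir: Union[str, Path] = "audioshape_run",
) -> RunManifest:
    """Execute the full pipeline; deterministic given ``config.seed``.

    With ``in_path`` None a synthetic quantized dataset is generated.
    Writes into ``out_dir``: the labelled audiogram CSV, the selection
    report, the feature CSV of the combined training pool, the evaluation
    JSON and the run manifest.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=config.to_dict(),
                           input_path=str(in_path) if in_path else None,
                           out_dir=str(out_dir))
    t_all = time.perf_counter()

    def stage(name):
        logger.info("stage %s", name)
        return time.perf_counter()

    # -- ingest -------------------------------------------------------------
    t = stage("ingest")
    if in_path is None:
        data = make_dataset(bisgaard_like_archetypes(), seed=config.seed)
    else:
        data = read_audiograms(in_path)
    refs = make_reference_set(seed=config.seed)
    manifest.counts["audiograms_in"] = len(data)
    manifest.timings_s["ingest"] = time.perf_counter() - t

    # -- drop normal hearing ------------------------------------------------
    t = stage("drop_normal")
    data = drop_normal_hearing(data, cutoff_db=config.normal_hearing_cutoff_db)
    manifest.counts["audiograms_after_normal_removal"] = len(data)
    manifest.timings_s["drop_normal"] = time.perf_counter() - t

    # -- annotate -----------------------------------------------------------
    t = stage("annotate")
    k = choose_k(data, config.k_range, seed=config.seed)
    result = spectral_cluster(data, k, seed=config.seed)
    cleaned = clean_weak_members(result, data, threshold=config.silhouette_threshold)
    removed = set(cleaned.removed_ids)
    labelled = [
        a.replace(label=int(lab))
        for a, lab in zip([a for a in data if a.id not in removed], cleaned.labels)
    ]
    manifest.counts["chosen_k"] = k
    manifest.counts["audiograms_after_cleaning"] = len(labelled)
    manifest.counts["cleaning_removed"] = sorted(removed)
    labelled_path = out_dir / "labelled.csv"
    write_audiograms(labelled, labelled_path)
    manifest.artifacts["labelled_csv"] = str(labelled_path)
    manifest.timings_s["annotate"] = time.perf_counter() - t

    # -- augment with all methods and select --------------------------------
    t = stage("select")
    methods = list_methods(minmax_new_range=config.minmax_new_range)
    datasets = augment(labelled, methods, scope=config.normalization_scope, on_error="skip")
    manifest.counts["augmented_total"] = sum(len(d.audiograms) for d in datasets)
    common = _common_ids(datasets)
    report = select_normalizations(
        _restrict(datasets, common), reference=config.reference_method, alpha=config.alpha
    )
    manifest.counts["methods_retained"] = len(report.retained)
    manifest.counts["pairwise_comparisons"] = len(report.all_pairwise)
    selection_path = out_dir / "selection.json"
    selection_path.write_text(json.dumps(report.to_dict(), indent=2), encoding="utf-8")
    manifest.artifacts["selection_json"] = str(selection_path)
    manifest.timings_s["select"] = time.perf_counter() - t

    # -- featurize retained training sets -----------------------------------
    t = stage("featurize")
    retained_sets = {d.method_name: d.audiograms for d in datasets
                     if d.method_name in set(report.retained)}
    training: Dict[str, list] = {}
    training["positive_original"] = featurize_dataset(labelled, refs)
    training["negative_original"] = featurize_dataset([negate(a) for a in labelled], refs)
    for name, audiograms in retained_sets.items():
        training[name] = featurize_dataset(audiograms, refs)
    n_training = sum(len(v) for v in training.values())
    manifest.counts["training_samples"] = n_training
    manifest.counts["training_sets"] = {k_: len(v) for k_, v in training.items()}
    features_path = out_dir / "features.csv"
    _write_features_csv(training, features_path)
    manifest.artifacts["features_csv"] = str(features_path)
    manifest.timings_s["featurize"] = time.perf_counter() - t

    # -- evaluate -----------------------------------------------------------
    t = stage("evaluate")
    evaluation = evaluate_datasets(training, config)
    eval_payload = {
        "per_dataset": {k_: v.to_dict() for k_, v in evaluation["per_dataset"].items()},
        "class_average": {
            "per_class": {str(c): m for c, m in evaluation["class_average"]["per_class"].items()},
            "overall": evaluation["class_average"]["overall"],
        },
        "combined": evaluation["combined"].to_dict(),
    }
    eval_path = out_dir / "eval.json"
    eval_path.write_text(json.dumps(eval_payload, indent=2, sort_keys=True), encoding="utf-8")
    manifest.artifacts["eval_json"] = str(eval_path)
    manifest.counts["combined_macro_f"] = evaluation["combined"].overall["f_score"]
    manifest.timings_s["evaluate"] = time.perf_counter() - t

    manifest.timings_s["total"] = time.perf_counter() - t_all
    manifest_path = out_dir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest.to_dict(), indent=2), encoding="utf-8")
    manifest.artifacts["manifest_json"] = str(manifest_path)
    return manifest


def _write_features_csv(training: Dict[str, list], path: Path) -> None:
    """Combined feature table: dataset, id, label, then the feature columns."""
    rows = []
    header: Optional[list] = None
    for name, vectors in training.items():
        for fv in vectors:
            if header is None:
                header = ["dataset", "id", "label"] + list(fv.names)
            rows.append([name, fv.id, str(fv.label)] + [repr(float(v)) for v in fv.values])
    lines = [",".join(header or ["dataset", "id", "label"])]
    lines += [",".join(r) for r in rows]
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
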