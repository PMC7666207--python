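"""Classifier-based cluster-matching accuracy framework.

A random forest trained on the high-depth reference (features: log-
normalised expression of the reference HVGs) predicts a reference cluster
for every cell of a subsampled dataset. Each subsampled cluster adopts
the identity receiving the largest share of its cells' predictions, and
accuracy is the fraction of evaluated cells whose adopted cluster
identity matches their own cluster in the reference — so accuracy
measures whether the subsampled *clustering* still resolves the reference
populations, not per-cell classifier skill.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from .containers import CountMatrix, ReadMultiplicities
from .cluster import ClusterLabels
from .embed import NormalizedMatrix
from .pipeline import PipelineConfig, ProcessedSample, cluster_pipeline
from .subsample import (
    CellGrid,
    DepthGrid,
    fraction_for_target_depth,
    subsample_cells,
    subsample_reads,
)

__all__ = [
    "ReferenceModel",
    "ClusterIdentityMap",
    "BenchmarkRecord",
    "train_reference_classifier",
    "predict_cells",
    "assign_cluster_identities",
    "evaluate",
    "run_grid",
    "records_to_frame",
    "median_accuracy_table",
]

log = logging.getLogger(__name__)


@dataclass
class ReferenceModel:
    classifier: RandomForestClassifier
    feature_genes: list
    labels: pd.Series  # barcode -> reference cluster id
    seed: int
    oob_accuracy: float | None = None


@dataclass
class ClusterIdentityMap:
    mapping: dict            # subsampled cluster id -> reference cluster id
    vote_proportion: dict    # subsampled cluster id -> modal fraction
    ties: set = field(default_factory=set)


@dataclass
class BenchmarkRecord:
    condition: str
    depth_target: float
    n_cells_target: int
    replicate: int
    seed: int
    n_evaluated: int
    accuracy: float
    confusion: pd.DataFrame          # reference identity x assigned identity
    per_class: pd.DataFrame          # sensitivity/specificity per reference class
    median_sensitivity: float
    median_specificity: float


def train_reference_classifier(
    norm: NormalizedMatrix,
    hvgs,
    labels: ClusterLabels | pd.Series,
    n_trees: int = 500,
    seed: int = 0,
) -> ReferenceModel:
    """Fit the reference random forest on HVG log-normalised expression."""
    if isinstance(labels, ClusterLabels):
        labels = labels.as_series()
    labels = labels.dropna()
    classes, counts = np.unique(labels.to_numpy(), return_counts=True)
    if len(classes) < 2:
        raise ValueError("need at least two reference classes to train")
    if counts.min() < 2:
        raise ValueError("every reference class needs at least 2 cells")
    if n_trees < 50:
        log.warning("n_trees=%d is very small; out-of-bag estimates will be noisy", n_trees)
    hvgs = [g for g in hvgs if g in set(norm.gene_symbols)]
    pos = {b: i for i, b in enumerate(norm.barcodes)}
    cols = np.array([pos[b] for b in labels.index], dtype=int)
    X = norm.dense(hvgs)[:, cols].T  # cells x features
    clf = RandomForestClassifier(
        n_estimators=n_trees,
        oob_score=True,
        random_state=seed,
        n_jobs=1,
    )
    clf.fit(X, labels.to_numpy())
    oob = float(clf.oob_score_) if n_trees > 1 else None
    if oob is not None:
        log.info("reference classifier out-of-bag accuracy: %.3f", oob)
    return ReferenceModel(clf, list(hvgs), labels, seed, oob)


def predict_cells(model: ReferenceModel, norm: NormalizedMatrix) -> pd.Series:
    """Predict a reference cluster for every cell of a subsampled dataset.

    The subsample is re-indexed to the model's feature list; genes absent
    from the subsample contribute zeros. Gene order of the subsample is
    irrelevant.
    """
    present = set(norm.gene_symbols)
    overlap = [g for g in model.feature_genes if g in present]
    if not overlap:
        raise ValueError("no overlap between model features and subsample genes")
    X = np.zeros((norm.n_cells, len(model.feature_genes)))
    col_of = {g: j for j, g in enumerate(model.feature_genes)}
    dense = norm.dense(overlap)
    for i, g in enumerate(overlap):
        X[:, col_of[g]] = dense[i]
    preds = model.classifier.predict(X)
    return pd.Series(preds, index=pd.Index(norm.barcodes, name="barcode"), name="predicted")


def assign_cluster_identities(
    sub_labels: ClusterLabels, predictions: pd.Series
) -> ClusterIdentityMap:
    """Majority-vote identity for each subsampled cluster.

    Ties are broken toward the reference cluster with more predicted cells
    across the whole dataset, then the lowest id, and flagged.
    """
    preds = predictions.reindex(sub_labels.barcodes)
    if preds.isna().any():
        raise ValueError("predictions must cover all labelled barcodes")
    global_votes = preds.value_counts()
    mapping, vote_prop, ties = {}, {}, set()
    for cid in sorted(np.unique(sub_labels.labels)):
        votes = preds[sub_labels.labels == cid].value_counts()
        if votes.empty:
            raise ValueError(f"empty subsampled cluster {cid}")
        top = votes.max()
        candidates = sorted(votes[votes == top].index)
        if len(candidates) > 1:
            ties.add(cid)
            candidates.sort(key=lambda c: (-global_votes.get(c, 0), c))
        mapping[cid] = candidates[0]
        vote_prop[cid] = float(top / votes.sum())
    return ClusterIdentityMap(mapping, vote_prop, ties)


def evaluate(
    idmap: ClusterIdentityMap,
    sub_labels: ClusterLabels,
    reference_labels: pd.Series,
    condition: str = "",
    depth_target: float = float("nan"),
    n_cells_target: int = 0,
    replicate: int = 0,
    seed: int = 0,
) -> BenchmarkRecord:
    """Confusion matrix and accuracy over the shared barcode set.

    Evaluation is restricted to barcodes holding a cluster in both the
    reference and the subsample (cells lost to either side's QC or
    non-target exclusion are not counted). ``accuracy`` is the fraction of
    evaluated cells whose mapped cluster identity equals their reference
    cluster; per-class sensitivity/specificity are one-vs-rest on the
    confusion matrix.
    """
    sub = sub_labels.as_series()
    common = sub.index.intersection(reference_labels.dropna().index)
    if len(common) == 0:
        raise ValueError("no barcodes shared between subsample and reference")
    truth = reference_labels.loc[common].to_numpy()
    assigned = np.array([idmap.mapping[c] for c in sub.loc[common].to_numpy()])
    ref_classes = sorted(pd.unique(reference_labels.dropna()))
    confusion = pd.DataFrame(
        0, index=pd.Index(ref_classes, name="reference"),
        columns=pd.Index(ref_classes, name="assigned"), dtype=int,
    )
    for t, a in zip(truth, assigned):
        confusion.loc[t, a] += 1
    n_eval = len(common)
    accuracy = float((truth == assigned).mean())

    rows = []
    total = confusion.to_numpy().sum()
    for c in ref_classes:
        tp = confusion.loc[c, c]
        fn = confusion.loc[c].sum() - tp
        fp = confusion[c].sum() - tp
        tn = total - tp - fn - fp
        sens = tp / (tp + fn) if (tp + fn) else np.nan
        spec = tn / (tn + fp) if (tn + fp) else np.nan
        rows.append({"class": c, "sensitivity": sens, "specificity": spec})
    per_class = pd.DataFrame(rows).set_index("class")
    return BenchmarkRecord(
        condition=condition,
        depth_target=depth_target,
        n_cells_target=n_cells_target,
        replicate=replicate,
        seed=seed,
        n_evaluated=n_eval,
        accuracy=accuracy,
        confusion=confusion,
        per_class=per_class,
        median_sensitivity=float(per_class["sensitivity"].median()),
        median_specificity=float(per_class["specificity"].median()),
    )


def _reference_bundle(
    sample: ProcessedSample, cfg: PipelineConfig, seed: int
) -> tuple[ReferenceModel, pd.Series]:
    model = train_reference_classifier(
        sample.norm, sample.hvgs, sample.labels, n_trees=cfg.rf_n_trees, seed=seed
    )
    return model, sample.labels.as_series()


def _compare(
    sub: ProcessedSample,
    model: ReferenceModel,
    ref_labels: pd.Series,
    **meta,
) -> BenchmarkRecord:
    preds = predict_cells(model, sub.norm)
    idmap = assign_cluster_identities(sub.labels, preds)
    return evaluate(idmap, sub.labels, ref_labels, **meta)


def run_grid(
    cm: CountMatrix,
    reads: ReadMultiplicities,
    cfg: PipelineConfig,
    depth_grid: DepthGrid | None = None,
    cell_grid: CellGrid | None = None,
    cell_arm_depths: tuple = ("full",),
    condition: str = "unstimulated",
) -> list[BenchmarkRecord]:
    """Run the depth x cell-number benchmark grid.

    The read-depth arm thins reads to each target, re-runs the full
    clustering pipeline and compares against the full-depth reference.
    The cell-number arm, for each depth in ``cell_arm_depths`` ("full" or
    a numeric mean-reads/cell target), takes the clustering of all cells
    at that depth as the reference and evaluates independent clusterings
    of random cell subsets. Failures at a grid point are logged and the
    grid continues.
    """
    full = cluster_pipeline(cm, cfg, seed=cfg.seed)
    full_model, full_ref_labels = _reference_bundle(full, cfg, cfg.seed)
    realized = reads.total_reads / cm.n_cells
    records: list[BenchmarkRecord] = []

    if depth_grid is not None:
        for target in depth_grid.targets:
            if target > realized:
                log.warning("depth target %s above realized depth %.0f; skipped", target, realized)
                continue
            f = fraction_for_target_depth(reads, target)
            for rep in range(depth_grid.n_replicates):
                seed = depth_grid.replicate_seed(target, rep)
                try:
                    thin_cm, _ = subsample_reads(cm, reads, f, seed)
                    sub = cluster_pipeline(thin_cm, cfg, seed=seed)
                    records.append(
                        _compare(
                            sub, full_model, full_ref_labels,
                            condition=condition, depth_target=float(target),
                            n_cells_target=0, replicate=rep, seed=seed,
                        )
                    )
                except Exception:
                    log.exception("depth arm failed at target=%s rep=%d", target, rep)

    if cell_grid is not None:
        for depth in cell_arm_depths:
            if depth == "full":
                ref, model, ref_labels = full, full_model, full_ref_labels
                depth_value = float(realized)
            else:
                f = fraction_for_target_depth(reads, depth)
                thin_cm, _ = subsample_reads(cm, reads, f, cfg.seed)
                ref = cluster_pipeline(thin_cm, cfg, seed=cfg.seed)
                model, ref_labels = _reference_bundle(ref, cfg, cfg.seed)
                depth_value = float(depth)
            available = ref.cm_qc.n_cells
            for n in cell_grid.targets:
                if n > available:
                    log.warning("cell target %d above available %d; skipped", n, available)
                    continue
                for rep in range(cell_grid.n_replicates):
                    seed = int(cell_grid.base_seed + 7919 * n % 2**20 + rep)
                    try:
                        sub_cm, _ = subsample_cells(ref.cm_qc, n, seed, cfg.qc)
                        sub = cluster_pipeline(sub_cm, cfg, seed=seed, skip_qc=True)
                        records.append(
                            _compare(
                                sub, model, ref_labels,
                                condition=condition, depth_target=depth_value,
                                n_cells_target=n, replicate=rep, seed=seed,
                            )
                        )
                    except Exception:
                        log.exception("cell arm failed at depth=%s n=%d rep=%d", depth, n, rep)
    return records


def records_to_frame(records) -> pd.DataFrame:
    """Flatten benchmark records to the grid-results table."""
    rows = [
        {
            "condition": r.condition,
            "depth_target": r.depth_target,
            "n_cells_target": r.n_cells_target,
            "replicate": r.replicate,
            "seed": r.seed,
            "n_evaluated": r.n_evaluated,
            "accuracy": r.accuracy,
            "median_sensitivity": r.median_sensitivity,
            "median_specificity": r.median_specificity,
        }
        for r in records
    ]
    return pd.DataFrame(rows)


def median_accuracy_table(records) -> pd.DataFrame:
    """Median accuracy per (depth, n_cells) tile across replicates."""
    frame = records_to_frame(records)
    if frame.empty:
        return frame
    return (
        frame.groupby(["condition", "depth_target", "n_cells_target"])["accuracy"]
        .median()
        .reset_index()
        .rename(columns={"accuracy": "median_accuracy"})
    )
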