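"""Evaluation protocols: metrics, Top/Avg/MIL comparison, good-pose
stratification, pairwise-RMSD consistency and the bag-size ablation.

The metric set is RMSE, MAE, coefficient of determination (r2), Pearson r and
Spearman rho, all computed on entity-level predictions in pK units.  A
"good" docking pose has RMSD strictly below 2.5 A to the reference pose, and
evaluation entities are stratified into groups with no good poses, 1-4 good
poses and more than 4 good poses.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import mean_absolute_error, mean_squared_error, r2_score

from .backbones import BackboneModel
from .errors import DataError
from .graphs import pose_rmsd
from .mil import AttentionHead, baseline_avg, baseline_top, predict_bag
from .structio import Bag, EmbeddingStore
from .train import bag_instance_graphs, extract_embeddings

logger = logging.getLogger(__name__)

__all__ = [
    "MetricsReport",
    "compute_metrics",
    "count_good_poses",
    "GOOD_POSE_THRESHOLD",
    "pairwise_rmsd_stats",
    "compare_methods",
    "group_metrics",
    "bag_size_ablation",
]

GOOD_POSE_THRESHOLD = 2.5  # Angstrom, strict "less than"
METRIC_COLUMNS = ("rmse", "mae", "r2", "pearson_r", "spearman_rho")


@dataclass
class MetricsReport:
    rmse: float
    mae: float
    r2: float | None
    pearson_r: float | None
    spearman_rho: float | None
    n: int = 0

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in METRIC_COLUMNS}


def compute_metrics(y_hat, y) -> MetricsReport:
    """Standard regression metrics; correlation-type metrics are reported as
    missing (None) when the reference has zero variance."""
    y_hat = np.asarray(y_hat, dtype=float)
    y = np.asarray(y, dtype=float)
    if y_hat.shape != y.shape:
        raise DataError(f"shape mismatch: {y_hat.shape} vs {y.shape}")
    if y.ndim != 1 or y.size < 2:
        raise DataError("need 1-D vectors of length >= 2")
    if not (np.all(np.isfinite(y_hat)) and np.all(np.isfinite(y))):
        raise DataError("non-finite values in inputs")
    rmse = float(np.sqrt(mean_squared_error(y, y_hat)))
    mae = float(mean_absolute_error(y, y_hat))
    if np.var(y) == 0:
        return MetricsReport(rmse, mae, None, None, None, n=y.size)
    r2 = float(r2_score(y, y_hat))
    if np.var(y_hat) == 0:
        return MetricsReport(rmse, mae, r2, None, None, n=y.size)
    pearson = float(stats.pearsonr(y_hat, y).statistic)
    spearman = float(stats.spearmanr(y_hat, y).statistic)
    return MetricsReport(rmse, mae, r2, pearson, spearman, n=y.size)


def count_good_poses(bag_rmsds, threshold: float = GOOD_POSE_THRESHOLD):
    """Count poses with RMSD strictly below the threshold; return the count
    and the stratification label ('none', '1-4' or '>4')."""
    rmsds = np.asarray(list(bag_rmsds), dtype=float)
    if np.any(rmsds < 0):
        raise ValueError("negative RMSD")
    count = int(np.sum(rmsds < threshold))
    if count == 0:
        label = "none"
    elif count <= 4:
        label = "1-4"
    else:
        label = ">4"
    return count, label


def pairwise_rmsd_stats(
    bag: Bag, bins: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """All K(K-1)/2 pairwise pose RMSDs of one bag plus a density histogram.

    Default binning: 0.5 A bins over [0, 15] A.  Returns
    ``(rmsds, density, bin_edges)``; a K<2 bag yields empty arrays with a
    warning.
    """
    if bins is None:
        bins = np.arange(0.0, 15.0 + 0.5, 0.5)
    poses = bag.instances
    if len(poses) < 2:
        warnings.warn(f"bag {bag.entity_id} has K<2; no pairwise RMSDs")
        return np.zeros(0), np.zeros(len(bins) - 1), np.asarray(bins)
    vals = [
        pose_rmsd(poses[i], poses[j])
        for i in range(len(poses))
        for j in range(i + 1, len(poses))
    ]
    density, edges = np.histogram(vals, bins=bins, density=True)
    return np.asarray(vals), density, edges


# ---------------------------------------------------------------------------
# Top / Avg / MIL comparison
# ---------------------------------------------------------------------------


def compare_methods(
    backbone: BackboneModel,
    head: AttentionHead,
    bags: list[Bag],
    instance_graphs: list | None = None,
    store: EmbeddingStore | None = None,
):
    """Evaluate Top, Avg and MIL on the same entities.

    Top predicts from the rank-1 docking pose via the backbone's scalar head;
    Avg averages the scalar-head predictions over all instances (crystal
    included when present); MIL pools the frozen embeddings with the
    attention head.  Returns ``(table, details)`` where ``table`` is a
    3-row DataFrame over the five metrics.
    """
    if instance_graphs is None:
        instance_graphs = bag_instance_graphs(bags, backbone.config, "both")
    if store is None:
        store = extract_embeddings(backbone, bags, instance_graphs=instance_graphs)

    scalar = {}
    chunk = 64
    for start in range(0, len(instance_graphs), chunk):
        part = instance_graphs[start : start + chunk]
        preds = backbone.predict_scalar([g for _, _, _, g in part])
        for (eid, rank, _, _), p in zip(part, preds):
            scalar[(eid, rank)] = float(p)

    is_crystal = {
        (b.entity_id, p.pose_rank): p.is_crystal for b in bags for p in b.instances
    }
    y, top, avg, mil = [], [], [], []
    top_y = []
    details = {"per_entity": {}}
    for bag in bags:
        pairs = [(p.pose_rank, scalar[(bag.entity_id, p.pose_rank)])
                 for p in bag.instances]
        docking_pairs = [
            (r, v) for r, v in pairs if not is_crystal[(bag.entity_id, r)]
        ]
        H = np.array([v for _, v in store.read(bag.entity_id)])
        pred = predict_bag(H, head, bag.entity_id)
        avg_v = baseline_avg(pairs)
        y.append(bag.label)
        avg.append(avg_v)
        mil.append(pred.y_hat)
        try:
            top.append(baseline_top(docking_pairs))
            top_y.append(bag.label)
        except DataError:
            logger.warning("entity %s lacks a rank-1 pose; excluded from Top",
                           bag.entity_id)
        details["per_entity"][bag.entity_id] = {
            "y": bag.label,
            "avg": avg_v,
            "mil": pred.y_hat,
            "attention": pred.attention_weights,
        }
    table = pd.DataFrame(
        [
            compute_metrics(top, top_y).as_dict(),
            compute_metrics(avg, y).as_dict(),
            compute_metrics(mil, y).as_dict(),
        ],
        index=["Top", "Avg", "MIL"],
    )
    return table, details


def group_metrics(
    predictions: dict[str, float],
    labels: dict[str, float],
    good_counts: dict[str, int],
) -> dict[str, MetricsReport | None]:
    """Stratify entities by good-pose group and compute per-group metrics.

    Groups partition the entities; a group with fewer than 2 entities is
    reported as None.
    """
    groups: dict[str, list[str]] = {"none": [], "1-4": [], ">4": []}
    for e in predictions:
        c = good_counts[e]
        label = "none" if c == 0 else ("1-4" if c <= 4 else ">4")
        groups[label].append(e)
    out: dict[str, MetricsReport | None] = {}
    for label, ents in groups.items():
        if len(ents) < 2:
            out[label] = None
            continue
        out[label] = compute_metrics(
            [predictions[e] for e in ents], [labels[e] for e in ents]
        )
    return out


# ---------------------------------------------------------------------------
# bag-size ablation
# ---------------------------------------------------------------------------


def bag_size_ablation(
    head: AttentionHead,
    store: EmbeddingStore,
    labels: dict[str, float],
    k_values: tuple[int, ...] = (1, 3, 5, 7, 9),
    trials: int = 10,
    seed: int = 0,
) -> dict[int, dict[str, dict[str, float]]]:
    """Evaluate MIL with K instances randomly subsampled per bag.

    For each k and each of ``trials`` trials, k instances are sampled without
    replacement from every eligible bag (bags with fewer than max(k_values)
    instances are excluded and logged), the MIL prediction is computed, and
    the metrics recorded; per-k mean/min/max across trials are returned.
    """
    kmax = max(k_values)
    bags_H, y = [], []
    for e in sorted(labels):
        H = np.array([v for _, v in store.read(e)])
        if H.shape[0] < kmax:
            logger.warning("entity %s has %d < %d poses; excluded from ablation",
                           e, H.shape[0], kmax)
            continue
        bags_H.append(H)
        y.append(labels[e])
    if not bags_H:
        raise DataError(f"no bag has >= {kmax} poses")
    y = np.array(y)
    rng = np.random.default_rng(seed)
    out: dict[int, dict[str, dict[str, float]]] = {}
    for k in k_values:
        rmses, r2s = [], []
        for _ in range(trials):
            preds = []
            for H in bags_H:
                idx = rng.choice(H.shape[0], size=k, replace=False)
                preds.append(predict_bag(H[idx], head).y_hat)
            rep = compute_metrics(preds, y)
            rmses.append(rep.rmse)
            r2s.append(rep.r2)
        out[k] = {
            "rmse": {"mean": float(np.mean(rmses)), "min": float(np.min(rmses)),
                     "max": float(np.max(rmses))},
            "r2": {"mean": float(np.mean(r2s)), "min": float(np.min(r2s)),
                   "max": float(np.max(r2s))},
        }
    return out
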