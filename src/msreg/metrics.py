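"""Registration and segmentation quality metrics and their aggregation.

IoU (Jaccard index) and the normalized coefficient of correlation (NCC) score
how well a registered mask overlaps the reference-band mask; the non-overlap
error is the symmetric fraction of the union left uncovered (1 - IoU).
Confusion counts, precision/recall/F1 and average precision evaluate
instance predictions against ground-truth masks.

NCC here is plain cosine similarity of the flattened rasters,
``i1.T @ i2 / (||i1|| ||i2||)``, with no mean-centering; a mean-centered
(Pearson) variant is available separately as :func:`pearson_ncc`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .scene_io import ensure_binary_mask

__all__ = [
    "ConfusionCounts",
    "MetricsTable",
    "iou",
    "ncc",
    "pearson_ncc",
    "nonoverlap_error",
    "confusion",
    "precision_recall_f1",
    "average_precision",
    "aggregate",
    "boxplot_stats",
]


class UndefinedMetricError(ValueError):
    """A metric is undefined for the given input (e.g. a zero vector)."""


def _check_shapes(a: np.ndarray, b: np.ndarray) -> None:
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")


def iou(a: np.ndarray, b: np.ndarray, both_empty: float = 1.0) -> float:
    """Intersection over union of two binary masks.

    Two empty masks agree vacuously: the convention returns ``both_empty``
    (default 1.0, configurable).
    """
    a = ensure_binary_mask(a)
    b = ensure_binary_mask(b)
    _check_shapes(a, b)
    inter = int(np.logical_and(a, b).sum())
    union = int(np.logical_or(a, b).sum())
    if union == 0:
        return both_empty
    return inter / union


def ncc(a: np.ndarray, b: np.ndarray) -> float:
    """Normalized coefficient of correlation: cosine similarity of the
    flattened rasters.  A zero vector makes the metric undefined."""
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.shape != b.shape:
        raise ValueError("rasters must have the same number of elements")
    na = np.linalg.norm(a)
    nb = np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise UndefinedMetricError("NCC is undefined for an all-zero raster")
    return float(a @ b / (na * nb))


def pearson_ncc(a: np.ndarray, b: np.ndarray) -> float:
    """Mean-centered variant (Pearson correlation of flattened rasters).

    Provided for comparison only; :func:`ncc` is the metric used throughout.
    """
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    return ncc(a - a.mean(), b - b.mean())


def nonoverlap_error(a: np.ndarray, b: np.ndarray) -> float:
    """Symmetric non-overlap fraction of the union: (FP+FN)/(TP+FP+FN) = 1 - IoU."""
    return 1.0 - iou(a, b)


@dataclass(frozen=True)
class ConfusionCounts:
    """Pixel-level confusion counts between a predicted and a truth mask."""

    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def confusion(predicted: np.ndarray, truth: np.ndarray) -> ConfusionCounts:
    """Pixelwise TP/FP/FN/TN counts of ``predicted`` against ``truth``."""
    p = ensure_binary_mask(predicted).astype(bool)
    t = ensure_binary_mask(truth).astype(bool)
    _check_shapes(p, t)
    tp = int(np.logical_and(p, t).sum())
    fp = int(np.logical_and(p, ~t).sum())
    fn = int(np.logical_and(~p, t).sum())
    tn = p.size - tp - fp - fn
    return ConfusionCounts(tp=tp, fp=fp, fn=fn, tn=tn)


def precision_recall_f1(c: ConfusionCounts) -> tuple[float, float, float]:
    """P = TP/(TP+FP), R = TP/(TP+FN), F1 = 2PR/(P+R).

    Zero-denominator cases are reported as NaN (undefined), never as silent
    zeros.
    """
    p = c.tp / (c.tp + c.fp) if (c.tp + c.fp) > 0 else float("nan")
    r = c.tp / (c.tp + c.fn) if (c.tp + c.fn) > 0 else float("nan")
    if np.isnan(p) or np.isnan(r) or (p + r) == 0:
        f1 = float("nan") if (np.isnan(p) or np.isnan(r)) else 0.0
    else:
        f1 = 2 * p * r / (p + r)
    return p, r, f1


def average_precision(
    detections: Sequence[tuple[float, np.ndarray]],
    truths: Sequence[np.ndarray],
    iou_threshold: float = 0.5,
) -> float:
    """Single-class mask-level average precision (AP == mAP here).

    ``detections`` are (score, mask) pairs.  They are matched greedily in
    descending score order, one-to-one, to the unmatched truth of highest
    mask IoU, counting a true positive when that IoU reaches the threshold.
    AP is the area under the right-envelope (monotone) precision-recall
    curve with all-points interpolation.

    With no ground-truth instances AP is undefined and NaN is returned.
    """
    n_truth = len(truths)
    if n_truth == 0:
        return float("nan")
    if len(detections) == 0:
        return 0.0
    order = sorted(range(len(detections)), key=lambda i: -detections[i][0])
    matched = [False] * n_truth
    tps = []
    for i in order:
        _, mask = detections[i]
        best_j, best_iou = -1, 0.0
        for j, t in enumerate(truths):
            if matched[j]:
                continue
            v = iou(mask, t, both_empty=0.0)
            if v > best_iou:
                best_j, best_iou = j, v
        if best_j >= 0 and best_iou >= iou_threshold:
            matched[best_j] = True
            tps.append(1.0)
        else:
            tps.append(0.0)
    tps = np.asarray(tps)
    cum_tp = np.cumsum(tps)
    precision = cum_tp / np.arange(1, len(tps) + 1)
    recall = cum_tp / n_truth
    # right envelope: precision at recall r is the max precision at recall >= r
    env = np.maximum.accumulate(precision[::-1])[::-1]
    # integrate over recall steps (all-points interpolation)
    recall = np.concatenate([[0.0], recall])
    env = np.concatenate([[env[0] if len(env) else 0.0], env])
    return float(np.sum((recall[1:] - recall[:-1]) * env[1:]))


# ---------------------------------------------------------------------------
# Aggregation
# ---------------------------------------------------------------------------

def boxplot_stats(values: Iterable[float]) -> dict:
    """Median, quartiles, whiskers and 1.5xIQR outliers for one group."""
    v = np.asarray([x for x in values if np.isfinite(x)], dtype=float)
    if len(v) == 0:
        return {
            "median": np.nan,
            "q1": np.nan,
            "q3": np.nan,
            "whisker_low": np.nan,
            "whisker_high": np.nan,
            "outliers": [],
        }
    q1, med, q3 = np.percentile(v, [25, 50, 75])
    iqr = q3 - q1
    lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = v[(v >= lo) & (v <= hi)]
    return {
        "median": float(med),
        "q1": float(q1),
        "q3": float(q3),
        "whisker_low": float(inside.min()) if len(inside) else np.nan,
        "whisker_high": float(inside.max()) if len(inside) else np.nan,
        "outliers": sorted(float(x) for x in v[(v < lo) | (v > hi)]),
    }


@dataclass
class MetricsTable:
    """Per-(scene, band, strategy) records plus the standard aggregation views."""

    records: pd.DataFrame
    by_strategy: pd.DataFrame = field(init=False)
    by_band_strategy: pd.DataFrame = field(init=False)

    _VALUE_COLS = ("iou", "ncc", "nonoverlap_error")

    def __post_init__(self) -> None:
        if len(self.records) == 0:
            raise ValueError("cannot aggregate an empty record list")
        vals = [c for c in self._VALUE_COLS if c in self.records.columns]
        self.by_strategy = (
            self.records.groupby("strategy", sort=True, observed=True)[vals]
            .agg(["mean", "std", "count"])
            .sort_index()
        )
        if "band" in self.records.columns:
            self.by_band_strategy = (
                self.records.groupby(["strategy", "band"], sort=True, observed=True)[
                    vals
                ]
                .agg(["mean", "std"])
                .sort_index()
            )
        else:
            self.by_band_strategy = pd.DataFrame()

    def strategy_boxplots(self, column: str = "iou") -> dict[str, dict]:
        return {
            strat: boxplot_stats(grp[column])
            for strat, grp in self.records.groupby("strategy", observed=True)
        }

    def to_csv(self, path) -> None:
        self.records.to_csv(path, index=False, float_format="%.10g")


def aggregate(records: pd.DataFrame | list[dict]) -> MetricsTable:
    """Build a :class:`MetricsTable` (group means/SDs, boxplot views) from
    per-run records."""
    if not isinstance(records, pd.DataFrame):
        records = pd.DataFrame(list(records))
    return MetricsTable(records=records)
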