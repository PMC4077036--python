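"""Detection-accuracy evaluation and region-similarity metrics.

A detection matches a ground-truth nucleus when the two are mutual nearest
neighbours and closer than a threshold (5 um by default).  Per stage, the
error rate is (FP + FN) / N_gt averaged over the three adjacent time points
around the stage's selected frame; across stages the totals accumulate as
the sum of per-stage mean errors, reported both as a count and as a
fraction of the total ground-truth nuclei.

Region similarity uses two standard measures on voxel sets in physical
coordinates: the volume overlap |C ∩ M| / ((|C| + |M|) / 2), and the
symmetric Hausdorff distance max(h(C, M), h(M, C)) with
h(C, M) = max_c min_m ||c - m||.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist, directed_hausdorff

from .imgdata import VoxelSpacing

__all__ = [
    "MatchResult",
    "StageMetrics",
    "match_points",
    "stage_error_rate",
    "cumulative_errors",
    "volume_overlap",
    "hausdorff_distance",
    "write_metrics_report",
]

DEFAULT_MATCH_THRESHOLD_UM = 5.0


@dataclass(frozen=True)
class MatchResult:
    """Outcome of matching one frame's detections against ground truth."""

    tp_pairs: tuple[tuple[int, int], ...]  # (detection index, gt index)
    fp_ids: tuple[int, ...]
    fn_ids: tuple[int, ...]
    threshold: float

    @property
    def tp(self) -> int:
        return len(self.tp_pairs)

    @property
    def fp(self) -> int:
        return len(self.fp_ids)

    @property
    def fn(self) -> int:
        return len(self.fn_ids)


@dataclass(frozen=True)
class StageMetrics:
    """Per-stage detection accuracy over the three adjacent time points."""

    stage: int  # nominal cell count
    tp: tuple[int, int, int]
    fp: tuple[int, int, int]
    fn: tuple[int, int, int]
    gt: tuple[int, int, int]
    error_rate: float  # mean over the three frames of (FP+FN)/N_gt

    @property
    def mean_errors(self) -> float:
        """Mean over the three frames of FP + FN."""
        return float(np.mean([f + n for f, n in zip(self.fp, self.fn)]))

    @property
    def mean_gt(self) -> float:
        return float(np.mean(self.gt))


def match_points(
    pred: np.ndarray,
    gt: np.ndarray,
    threshold: float = DEFAULT_MATCH_THRESHOLD_UM,
) -> MatchResult:
    """Match detections to ground truth by mutual nearest neighbours.

    ``pred`` and ``gt`` are (n, 3) arrays of um coordinates.  A pair is a
    true positive iff each is the other's nearest point and their distance
    is strictly below ``threshold``; nearest-neighbour ties resolve to the
    smallest input index.  Unmatched detections are false positives,
    unmatched ground-truth points false negatives.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    pred = np.asarray(pred, dtype=np.float64).reshape(-1, 3)
    gt = np.asarray(gt, dtype=np.float64).reshape(-1, 3)
    if len(pred) == 0 or len(gt) == 0:
        return MatchResult(
            tp_pairs=(),
            fp_ids=tuple(range(len(pred))),
            fn_ids=tuple(range(len(gt))),
            threshold=threshold,
        )
    d = cdist(pred, gt)
    nearest_gt = d.argmin(axis=1)    # first index wins ties
    nearest_pred = d.argmin(axis=0)
    tp_pairs = []
    matched_gt = set()
    for i in range(len(pred)):
        j = int(nearest_gt[i])
        if int(nearest_pred[j]) == i and d[i, j] < threshold:
            tp_pairs.append((i, j))
            matched_gt.add(j)
    matched_pred = {i for i, _ in tp_pairs}
    return MatchResult(
        tp_pairs=tuple(tp_pairs),
        fp_ids=tuple(i for i in range(len(pred)) if i not in matched_pred),
        fn_ids=tuple(j for j in range(len(gt)) if j not in matched_gt),
        threshold=threshold,
    )


def stage_error_rate(
    frames: tuple[MatchResult, MatchResult, MatchResult] | list[MatchResult],
    gt_counts: tuple[int, int, int] | list[int],
    stage: int = 0,
) -> StageMetrics:
    """Stage error rate: mean over the three adjacent frames of (FP+FN)/N_gt."""
    if len(frames) != 3 or len(gt_counts) != 3:
        raise ValueError("a stage uses exactly three adjacent time points")
    if any(g == 0 for g in gt_counts):
        raise ZeroDivisionError("error rate undefined for a frame with no ground truth")
    rates = [(m.fp + m.fn) / g for m, g in zip(frames, gt_counts)]
    return StageMetrics(
        stage=stage,
        tp=tuple(m.tp for m in frames),
        fp=tuple(m.fp for m in frames),
        fn=tuple(m.fn for m in frames),
        gt=tuple(int(g) for g in gt_counts),
        error_rate=float(np.mean(rates)),
    )


def cumulative_errors(stages: list[StageMetrics]) -> tuple[float, float]:
    """Total errors across stages and their fraction of total nuclei.

    The total is the sum over stages of the three-frame mean of FP + FN;
    the fraction divides by the sum over stages of the three-frame mean
    ground-truth count.
    """
    if not stages:
        raise ValueError("need at least one stage")
    total = float(sum(s.mean_errors for s in stages))
    total_gt = float(sum(s.mean_gt for s in stages))
    if total_gt == 0:
        raise ZeroDivisionError("no ground-truth nuclei across stages")
    return total, total / total_gt


# ---------------------------------------------------------------------------
# Region similarity
# ---------------------------------------------------------------------------

def _region_coords_um(region: np.ndarray, spacing: VoxelSpacing) -> np.ndarray:
    """(n, 3) physical (z, y, x) um coordinates of a boolean region's voxels."""
    idx = np.argwhere(np.asarray(region, bool))
    return idx * np.asarray(spacing.zyx)


def volume_overlap(comp: np.ndarray, manual: np.ndarray) -> float:
    """Volume overlap O = |C ∩ M| / ((|C| + |M|) / 2) on voxel sets.

    1.0 for identical regions, 0.0 for disjoint ones; symmetric.
    """
    comp = np.asarray(comp, bool)
    manual = np.asarray(manual, bool)
    n_c, n_m = int(comp.sum()), int(manual.sum())
    if n_c == 0 or n_m == 0:
        raise ValueError("volume overlap undefined for an empty region")
    inter = int((comp & manual).sum())
    return inter / ((n_c + n_m) / 2.0)


def hausdorff_distance(
    comp: np.ndarray,
    manual: np.ndarray,
    spacing: VoxelSpacing | None = None,
) -> float:
    """Symmetric Hausdorff distance (um) between two voxel regions.

    Accepts either boolean volumes (voxel centers converted to um with the
    anisotropic spacing) or (n, 3) um coordinate arrays.
    """
    comp = np.asarray(comp)
    manual = np.asarray(manual)
    if comp.ndim == 3 or comp.dtype == bool:
        spacing = spacing or VoxelSpacing()
        c = _region_coords_um(comp, spacing)
        m = _region_coords_um(manual, spacing)
    else:
        c = comp.reshape(-1, 3).astype(np.float64)
        m = manual.reshape(-1, 3).astype(np.float64)
    if len(c) == 0 or len(m) == 0:
        raise ValueError("Hausdorff distance undefined for an empty set")
    return max(directed_hausdorff(c, m)[0], directed_hausdorff(m, c)[0])


# ---------------------------------------------------------------------------
# Reporting
# ---------------------------------------------------------------------------

def write_metrics_report(stages: list[StageMetrics], path: str | Path) -> None:
    """CSV report: one row per stage frame plus a cumulative summary row."""
    rows = []
    for s in stages:
        for k in range(3):
            rate = (s.fp[k] + s.fn[k]) / s.gt[k]
            rows.append(
                {
                    "stage": s.stage,
                    "frame": k,
                    "tp": s.tp[k],
                    "fp": s.fp[k],
                    "fn": s.fn[k],
                    "gt": s.gt[k],
                    "error_rate": round(rate, 6),
                }
            )
    total, frac = cumulative_errors(stages)
    rows.append(
        {
            "stage": "total",
            "frame": "",
            "tp": "",
            "fp": "",
            "fn": "",
            "gt": round(sum(s.mean_gt for s in stages), 3),
            "error_rate": round(frac, 6),
        }
    )
    pd.DataFrame(rows).to_csv(path, index=False)
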