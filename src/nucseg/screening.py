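"""Parameter screening: grid evaluation on a reference stage, top-10%
selection with tie inclusion, single-pass gap filling, and per-stage best
selection.

The screening procedure evaluates every parameter set of a Cartesian grid
on one crowded reference stage (three adjacent frames), ranks sets by
stage error rate, keeps the top 10% (ceil, expanding through ties at the
cutoff), completes single-axis gaps between kept sets, and finally
evaluates the surviving candidates on all stages to report per-stage
minima and the overall winner by cumulative errors.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .dogfilter import DoGSpec, filter_frame
from .evalmetrics import (
    MatchResult,
    StageMetrics,
    cumulative_errors,
    match_points,
    stage_error_rate,
)
from .imgdata import GroundTruth, ImageSeries, ImageStack
from .segmenters import MethodParams, region_centroids, segment

__all__ = [
    "ParameterGrid",
    "ScreeningResult",
    "build_parameter_grid",
    "screen_stage",
    "fill_gaps",
    "select_best",
    "evaluate_params_on_stage",
    "write_screening_report",
]

# axes that parameterize the DoG spec rather than MethodParams
_DOG_AXES = {"l_xy", "sigma_ratio", "t_len", "dim"}


@dataclass(frozen=True)
class ParameterGrid:
    """Full Cartesian grid over ordered per-parameter candidate values."""

    method: str
    axes: tuple[tuple[str, tuple, ...], ...]  # ((name, values), ...)

    @property
    def axis_names(self) -> tuple[str, ...]:
        return tuple(name for name, _ in self.axes)

    def points(self) -> list[dict]:
        """All parameter sets, lexicographic in axis order (deterministic)."""
        names = self.axis_names
        value_lists = [vals for _, vals in self.axes]
        return [dict(zip(names, combo)) for combo in itertools.product(*value_lists)]

    def __len__(self) -> int:
        n = 1
        for _, vals in self.axes:
            n *= len(vals)
        return n


@dataclass
class ScreeningResult:
    """Evaluated grid with the selected (and gap-filled) subset."""

    grid: ParameterGrid
    errors: list[float]           # stage error rate per grid point, grid order
    selected: list[dict]          # top-10% sets (ties included)
    gap_filled: list[dict] = field(default_factory=list)

    @property
    def candidates(self) -> list[dict]:
        return self.selected + self.gap_filled

    @property
    def min_error(self) -> float:
        return min(self.errors)


def build_parameter_grid(method: str, ranges: Mapping[str, Sequence]) -> ParameterGrid:
    """Build the full Cartesian grid; values on each axis sorted ascending."""
    if not ranges:
        raise ValueError("parameter ranges must not be empty")
    axes = []
    for name, values in ranges.items():
        vals = list(values)
        if not vals:
            raise ValueError(f"axis {name!r} has no candidate values")
        try:
            vals = sorted(vals)
        except TypeError:
            pass  # non-orderable axis (e.g. dim strings): keep given order
        axes.append((name, tuple(vals)))
    return ParameterGrid(method=method, axes=tuple(axes))


def _split_point(point: Mapping, base_spec: DoGSpec) -> tuple[DoGSpec, MethodParams]:
    dog_kwargs = {k: v for k, v in point.items() if k in _DOG_AXES}
    mp_kwargs = {k: v for k, v in point.items() if k not in _DOG_AXES}
    spec = DoGSpec(
        l_xy=dog_kwargs.get("l_xy", base_spec.l_xy),
        dim=dog_kwargs.get("dim", base_spec.dim),
        t_len=dog_kwargs.get("t_len", base_spec.t_len),
        sigma_ratio=dog_kwargs.get("sigma_ratio", base_spec.sigma_ratio),
    )
    return spec, MethodParams(**mp_kwargs)


class _FilterCache:
    """Memoize DoG responses: the costliest step depends only on the spec."""

    def __init__(self, series: ImageSeries):
        self.series = series
        self._cache: dict[tuple, ImageStack] = {}

    def get(self, spec: DoGSpec, t: int) -> ImageStack:
        key = (spec.dim, spec.l_xy, spec.t_len, spec.sigma_ratio, t)
        if key not in self._cache:
            self._cache[key] = ImageStack(
                filter_frame(self.series, spec, t), self.series.spacing
            )
        return self._cache[key]


def evaluate_params_on_stage(
    method: str,
    point: Mapping,
    series: ImageSeries,
    gt: GroundTruth,
    stage_frames: tuple[int, int, int],
    base_spec: DoGSpec,
    cache: _FilterCache | None = None,
    stage: int = 0,
    threshold_um: float = 5.0,
) -> StageMetrics:
    """Segment + match + stage error for one parameter set on one stage."""
    spec, params = _split_point(point, base_spec)
    cache = cache or _FilterCache(series)
    matches: list[MatchResult] = []
    counts: list[int] = []
    for t in stage_frames:
        filtered = cache.get(spec, t)
        vol = segment(method, filtered, params)
        dets = region_centroids(vol)
        pred = [d.centroid for d in dets]
        matches.append(match_points(pred, gt.coords(t), threshold=threshold_um))
        counts.append(gt.count(t))
    return stage_error_rate(matches, counts, stage=stage)


def select_top_indices(errors: Sequence[float], fraction: float = 0.10) -> list[int]:
    """Indices of the best ceil(fraction * n) error rates, ascending rank.

    Entries tied with the last kept error rate are all included, so the
    outcome does not depend on evaluation order; the returned indices are
    sorted (grid order) and always contain the global minimum.
    """
    n = len(errors)
    if n == 0:
        raise ValueError("no error rates to rank")
    n_keep = math.ceil(fraction * n)
    order = sorted(range(n), key=lambda i: (errors[i], i))
    cutoff = errors[order[n_keep - 1]]
    return sorted(i for i in range(n) if errors[i] <= cutoff)


def screen_stage(
    method: str,
    grid: ParameterGrid,
    series: ImageSeries,
    gt: GroundTruth,
    stage_frames: tuple[int, int, int],
    base_spec: DoGSpec | None = None,
    threshold_um: float = 5.0,
) -> ScreeningResult:
    """Evaluate every grid point on the reference stage and keep the top 10%.

    ceil(0.1 * grid size) sets are kept after ranking ascending by error
    rate; sets tied with the last kept error rate are all kept, so the
    selection is order-independent and always contains the grid optimum.
    """
    if len(grid) == 0:
        raise ValueError("empty parameter grid")
    base_spec = base_spec or DoGSpec(l_xy=4.0, dim="3D")
    cache = _FilterCache(series)
    points = grid.points()
    errors = [
        evaluate_params_on_stage(
            method, pt, series, gt, stage_frames, base_spec, cache,
            threshold_um=threshold_um,
        ).error_rate
        for pt in points
    ]
    selected = [points[i] for i in select_top_indices(errors)]
    result = ScreeningResult(grid=grid, errors=errors, selected=selected)
    result.gap_filled = fill_gaps(selected, grid)
    return result


def fill_gaps(selected: list[dict], grid: ParameterGrid) -> list[dict]:
    """Single-axis interval completion of the selected subset.

    If two selected sets differ on exactly one axis and unselected grid
    values lie strictly between them on that axis, the intermediate grid
    points are added.  Applied once, no fixpoint iteration.  Returns only
    the additions, in grid order.
    """
    names = grid.axis_names
    values = {name: list(vals) for name, vals in grid.axes}
    sel_keys = {tuple(pt[n] for n in names) for pt in selected}
    added: set[tuple] = set()
    sel_list = [tuple(pt[n] for n in names) for pt in selected]
    for a, b in itertools.combinations(sel_list, 2):
        diff_axes = [k for k in range(len(names)) if a[k] != b[k]]
        if len(diff_axes) != 1:
            continue
        k = diff_axes[0]
        axis_vals = values[names[k]]
        ia, ib = axis_vals.index(a[k]), axis_vals.index(b[k])
        lo, hi = min(ia, ib), max(ia, ib)
        for j in range(lo + 1, hi):
            key = a[:k] + (axis_vals[j],) + a[k + 1:]
            if key not in sel_keys and key not in added:
                added.add(key)
    all_keys = [tuple(pt[n] for n in names) for pt in grid.points()]
    return [dict(zip(names, key)) for key in all_keys if key in added]


def select_best(
    method: str,
    candidates: list[dict],
    series: ImageSeries,
    gt: GroundTruth,
    stages: Mapping[int, tuple[int, int, int]],
    base_spec: DoGSpec | None = None,
    threshold_um: float = 5.0,
) -> tuple[dict[int, float], dict, list[StageMetrics]]:
    """Evaluate candidates on every stage.

    Returns (per-stage minimum error rates, the candidate minimizing
    cumulative errors across the stages — first in grid order on ties —
    and that winner's per-stage metrics).
    """
    if not candidates:
        raise ValueError("need at least one candidate parameter set")
    base_spec = base_spec or DoGSpec(l_xy=4.0, dim="3D")
    cache = _FilterCache(series)
    per_candidate: list[list[StageMetrics]] = []
    for pt in candidates:
        per_candidate.append(
            [
                evaluate_params_on_stage(
                    method, pt, series, gt, frames, base_spec, cache,
                    stage=stage, threshold_um=threshold_um,
                )
                for stage, frames in stages.items()
            ]
        )
    stage_list = list(stages)
    best_per_stage = {
        stage: min(mets[k].error_rate for mets in per_candidate)
        for k, stage in enumerate(stage_list)
    }
    totals = [cumulative_errors(mets)[0] for mets in per_candidate]
    winner_idx = min(range(len(candidates)), key=lambda i: (totals[i], i))
    return best_per_stage, candidates[winner_idx], per_candidate[winner_idx]


def write_screening_report(
    result: ScreeningResult, path: str | Path
) -> None:
    """CSV of parameter set -> reference-stage error, flagged selected/gap-filled."""
    names = result.grid.axis_names
    sel_keys = {tuple(pt[n] for n in names) for pt in result.selected}
    gap_keys = {tuple(pt[n] for n in names) for pt in result.gap_filled}
    rows = []
    for pt, err in zip(result.grid.points(), result.errors):
        key = tuple(pt[n] for n in names)
        rows.append(
            {
                **pt,
                "error_rate": round(err, 6),
                "selected": key in sel_keys,
                "gap_filled": key in gap_keys,
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)
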