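"""Synthetic 4D embryo movies with exact ground truth.

The generator emulates the data regime of early *C. elegans* embryogenesis
recordings: a fixed field of view (default 256 x 256 x 30 voxels at
0.25 x 0.25 x 1 um, i.e. 64 x 64 x 30 um) imaged at 1-min intervals, in
which the nucleus count rises from ~50 towards ~500 by divisions while the
nuclear diameter shrinks from ~4.5 um to ~2 um, so crowding increases over
time.  Nuclei are rendered as isotropic Gaussian intensity blobs
(sigma = diameter / 4) sampled on the anisotropic voxel grid, on a uniform
background, with additive Gaussian noise plus a mean-scaled shot-noise
term.  Per-nucleus, per-frame intensity flicker events reproduce the
within-nucleus intensity fluctuation that defeats purely spatial
filtering on single frames.

Everything is driven by one integer seed and is fully reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .imgdata import GroundTruth, ImageSeries, ImageStack, VoxelSpacing

__all__ = [
    "SynthConfig",
    "PlacementError",
    "render_frame",
    "generate_series",
    "select_stage_frames",
]


class PlacementError(RuntimeError):
    """Nuclei could not be placed at the requested count and separation."""


def _default_schedule() -> list[tuple[int, int]]:
    # ten stages, 50..500 nuclei, three frames each (1-min interval)
    return [(3 * i, 50 * (i + 1)) for i in range(10)]


@dataclass(frozen=True)
class SynthConfig:
    """Study conditions for one synthetic movie.

    shape: volume size in voxels, (z, y, x).
    schedule: (frame, nucleus count) pairs; the count holds from that frame
        until the next entry.  Counts must be non-decreasing.
    diameter_um: nuclear diameter; a (d_lo_count, d_hi_count) pair is
        interpolated linearly in nucleus count between the schedule's
        smallest and largest counts (4.5 um at 50 cells -> 2 um at 500).
    min_separation_um: smallest allowed center-to-center distance.
    drift_um: per-frame random-walk step for each nucleus center.
    flicker: (nucleus id, frame, multiplier) events scaling that nucleus's
        peak intensity in that frame only.
    """

    shape: tuple[int, int, int] = (30, 256, 256)
    spacing: VoxelSpacing = field(default_factory=VoxelSpacing)
    dt: float = 1.0
    schedule: list[tuple[int, int]] = field(default_factory=_default_schedule)
    n_frames: int | None = None
    diameter_um: float | tuple[float, float] = (4.5, 2.0)
    min_separation_um: float = 4.0
    peak_intensity: float = 0.7
    background: float = 0.1
    noise_sigma: float = 0.01
    shot_scale: float = 0.02
    drift_um: float = 0.15
    flicker: list[tuple[int, int, float]] = field(default_factory=list)
    seed: int = 0
    max_place_tries: int = 2000

    def __post_init__(self) -> None:
        if not self.schedule or self.schedule[0][0] != 0:
            raise ValueError("schedule must start at frame 0")
        counts = [c for _, c in self.schedule]
        if any(c < 1 for c in counts):
            raise ValueError("nucleus counts must be >= 1")
        if any(b < a for a, b in zip(counts, counts[1:])):
            raise ValueError("schedule counts must be non-decreasing")
        if self.min_separation_um < 0:
            raise ValueError("min separation must be >= 0")
        d = self.diameter_um
        if (min(d) if isinstance(d, tuple) else d) <= 0:
            raise ValueError("diameter must be positive")

    @property
    def frames_total(self) -> int:
        """Series length; default gives the last schedule entry three frames."""
        return self.n_frames if self.n_frames is not None else self.schedule[-1][0] + 3

    def count_at(self, t: int) -> int:
        count = self.schedule[0][1]
        for f, c in self.schedule:
            if f <= t:
                count = c
        return count

    def diameter_at(self, t: int) -> float:
        if not isinstance(self.diameter_um, tuple):
            return float(self.diameter_um)
        d_lo, d_hi = self.diameter_um
        counts = [c for _, c in self.schedule]
        c_min, c_max = min(counts), max(counts)
        if c_max == c_min:
            return float(d_lo)
        w = (self.count_at(t) - c_min) / (c_max - c_min)
        return float(d_lo + w * (d_hi - d_lo))

    def physical_size(self) -> np.ndarray:
        """(z, y, x) extent in um."""
        return np.asarray(self.shape) * np.asarray(self.spacing.zyx)


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------

def render_frame(
    centers_um: np.ndarray,
    cfg: SynthConfig,
    diameter_um: float | None = None,
    flicker_mult: np.ndarray | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[ImageStack, np.ndarray]:
    """Render one stack from (n, 3) um centers in (z, y, x) order.

    Each nucleus is an isotropic Gaussian blob of sigma = diameter / 4
    scaled by the peak intensity (times its flicker multiplier), added to
    the background; Gaussian plus mean-scaled shot noise is applied and
    the result clipped to [0, 1].  Returns the stack and the centers it
    rendered (the exact ground truth).
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    centers_um = np.asarray(centers_um, dtype=np.float64).reshape(-1, 3)
    diameter = float(diameter_um if diameter_um is not None else cfg.diameter_at(0))
    sigma = diameter / 4.0
    radius = diameter / 2.0
    steps = np.asarray(cfg.spacing.zyx)
    size_um = cfg.physical_size()
    if len(centers_um) and (
        (centers_um < radius - 1e-9).any() or (centers_um > size_um - radius + 1e-9).any()
    ):
        raise PlacementError("a nucleus center lies closer than one radius to the volume face")

    mult = np.ones(len(centers_um)) if flicker_mult is None else np.asarray(flicker_mult)
    img = np.full(cfg.shape, cfg.background, dtype=np.float64)
    cut = 3.0 * sigma
    for c, m in zip(centers_um, mult):
        lo = np.maximum(np.floor((c - cut) / steps).astype(int), 0)
        hi = np.minimum(np.ceil((c + cut) / steps).astype(int) + 1, np.asarray(cfg.shape))
        if (hi <= lo).any():
            continue
        ax = [np.arange(l, h) * s - cc for l, h, s, cc in zip(lo, hi, steps, c)]
        r2 = (
            ax[0][:, None, None] ** 2
            + ax[1][None, :, None] ** 2
            + ax[2][None, None, :] ** 2
        )
        img[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] += (
            cfg.peak_intensity * m * np.exp(-r2 / (2.0 * sigma**2))
        )
    noise = cfg.noise_sigma * rng.standard_normal(cfg.shape)
    if cfg.shot_scale > 0:
        noise += cfg.shot_scale * np.sqrt(np.clip(img, 0, None)) * rng.standard_normal(cfg.shape)
    img = np.clip(img + noise, 0.0, 1.0)
    return ImageStack(img, cfg.spacing), centers_um.copy()


# ---------------------------------------------------------------------------
# Placement, drift, division
# ---------------------------------------------------------------------------

def _sep_ok(pos: np.ndarray, others: np.ndarray, min_sep: float) -> bool:
    if len(others) == 0:
        return True
    return bool((np.sum((others - pos) ** 2, axis=1) >= min_sep**2 - 1e-12).all())


def _place_initial(cfg: SynthConfig, count: int, radius: float, rng: np.random.Generator) -> np.ndarray:
    size = cfg.physical_size()
    lo, hi = radius, size - radius
    if (hi <= lo).any():
        raise PlacementError("volume too small for the nuclear radius margin")
    placed = np.empty((0, 3))
    for _ in range(count):
        for _try in range(cfg.max_place_tries):
            pos = rng.uniform(lo, hi)
            if _sep_ok(pos, placed, cfg.min_separation_um):
                placed = np.vstack([placed, pos])
                break
        else:
            raise PlacementError(
                f"could not place {count} nuclei at separation "
                f"{cfg.min_separation_um} um; lower the count or separation"
            )
    return placed


def _drift(
    centers: np.ndarray, cfg: SynthConfig, radius: float, rng: np.random.Generator
) -> np.ndarray:
    """Bounded random walk preserving the minimum separation.

    Each nucleus proposes a normal step of scale ``drift_um``; a proposal
    violating the separation or the face margin keeps the old position.
    """
    if cfg.drift_um <= 0:
        return centers.copy()
    size = cfg.physical_size()
    lo, hi = radius, size - radius
    out = centers.copy()
    for i in range(len(out)):
        step = rng.normal(0.0, cfg.drift_um / np.sqrt(3.0), size=3)
        prop = np.clip(out[i] + step, lo, hi)
        others = np.delete(out, i, axis=0)
        if _sep_ok(prop, others, cfg.min_separation_um):
            out[i] = prop
    return out


def _split(
    centers: np.ndarray,
    ids: list[int],
    n_new: int,
    cfg: SynthConfig,
    radius: float,
    next_id: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, list[int], int]:
    """Divide ``n_new`` randomly chosen nuclei into daughter pairs.

    Daughters sit at +/- max(radius, min_separation / 2) from the mother
    along a random direction, so the separation invariant survives the
    division; directions are re-drawn when a daughter would collide with
    another nucleus or leave the margin.
    """
    size = cfg.physical_size()
    lo, hi = radius, size - radius
    offset = max(radius, cfg.min_separation_um / 2.0)
    out = centers.copy()
    out_ids = list(ids)
    for _ in range(n_new):
        order = rng.permutation(len(out))
        done = False
        for mi in order:
            mother = out[mi]
            others = np.delete(out, mi, axis=0)
            for _try in range(cfg.max_place_tries):
                direction = rng.standard_normal(3)
                direction /= np.linalg.norm(direction)
                d1 = mother + offset * direction
                d2 = mother - offset * direction
                if ((d1 < lo) | (d1 > hi) | (d2 < lo) | (d2 > hi)).any():
                    continue
                if _sep_ok(d1, others, cfg.min_separation_um) and _sep_ok(
                    d2, np.vstack([others, d1]), cfg.min_separation_um
                ):
                    out[mi] = d1
                    out = np.vstack([out, d2])
                    out_ids.append(next_id)
                    next_id += 1
                    done = True
                    break
            if done:
                break
        if not done:
            raise PlacementError(
                "could not divide a nucleus without violating the separation; "
                "lower the count or separation"
            )
    return out, out_ids, next_id


def generate_series(cfg: SynthConfig) -> tuple[ImageSeries, GroundTruth]:
    """Generate the full movie and its exact ground truth.

    Centers are placed by rejection sampling at the minimum separation,
    drift by a bounded random walk each frame, and divide when the stage
    schedule raises the count.  Every frame is paired with the exact
    centers used for rendering (ids persist through drift; a division
    keeps the mother's id for one daughter and mints a new id).
    """
    rng = np.random.default_rng(cfg.seed)
    n_frames = cfg.frames_total
    flicker = {(nid, t): m for nid, t, m in cfg.flicker}

    frames: list[ImageStack] = []
    gt = GroundTruth()
    centers: np.ndarray | None = None
    ids: list[int] = []
    next_id = 0
    for t in range(n_frames):
        diameter = cfg.diameter_at(t)
        radius = diameter / 2.0
        target = cfg.count_at(t)
        if centers is None:
            centers = _place_initial(cfg, target, radius, rng)
            ids = list(range(target))
            next_id = target
        else:
            centers = _drift(centers, cfg, radius, rng)
            if target > len(centers):
                centers, ids, next_id = _split(
                    centers, ids, target - len(centers), cfg, radius, next_id, rng
                )
        mult = np.asarray([flicker.get((nid, t), 1.0) for nid in ids])
        stack, exact = render_frame(centers, cfg, diameter_um=diameter, flicker_mult=mult, rng=rng)
        frames.append(stack)
        for nid, (z, y, x) in zip(ids, exact):
            gt.add(t, nid, float(x), float(y), float(z))
    return ImageSeries(frames, dt=cfg.dt), gt


def select_stage_frames(
    counts_by_frame: list[int] | dict[int, int], stage_counts: list[int]
) -> dict[int, tuple[int, int, int]]:
    """Map each requested stage to its three adjacent time points.

    The selected frame is the first whose nucleus count reaches or exceeds
    the stage; the previous and next frames complete the triple (clamped
    at the series ends).
    """
    if isinstance(counts_by_frame, dict):
        n = max(counts_by_frame) + 1
        counts = [counts_by_frame.get(t, 0) for t in range(n)]
    else:
        counts = list(counts_by_frame)
    out: dict[int, tuple[int, int, int]] = {}
    for stage in stage_counts:
        sel = next((t for t, c in enumerate(counts) if c >= stage), None)
        if sel is None:
            raise ValueError(f"no frame reaches the {stage}-cell stage")
        prev = max(sel - 1, 0)
        nxt = min(sel + 1, len(counts) - 1)
        out[stage] = (prev, sel, nxt)
    return out
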