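"""Six simple nuclei-segmentation methods and their shared building blocks.

All methods consume a DoG-filtered stack and produce an integer label
volume (0 = background), followed by size thresholding:

- ``int``    intensity watershed: flood the negated filtered intensity.
- ``dst``    distance watershed: local-threshold, Euclidean distance
             transform, flood the negated distance map.
- ``hyb``    hybrid watershed: alpha-blend of rescaled intensity and
             distance map, flooded within the thresholded mask.
- ``mul``    multiple watershed: flood the intensity masked by the local
             threshold.
- ``locwat`` local-maxima seeded watershed.
- ``locreg`` local-maxima based region detection (no watershed): voxels
             within a designated distance of their nearest maximum.

The watershed is a deterministic priority flood: voxels leave a heap
ordered by ``(landscape value, lexicographic (z, y, x) index)`` and pass
their label to unlabeled 26-connected neighbours.  Without seeds, flooding
starts from the regional minima of the landscape.  All distances are
physical (um) and respect anisotropic voxel spacing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numba as nb
import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree
from skimage.morphology import local_minima

from .imgdata import ImageStack, LabelVolume, NucleusDetection, VoxelSpacing

__all__ = [
    "MethodParams",
    "METHOD_NAMES",
    "local_threshold",
    "distance_map",
    "find_local_maxima",
    "watershed_transform",
    "segment",
    "segment_int",
    "segment_dst",
    "segment_hyb",
    "segment_mul",
    "segment_locwat",
    "segment_locreg",
    "size_filter",
    "region_centroids",
    "default_params_for_diameter",
]

METHOD_NAMES = ("int", "dst", "hyb", "mul", "locwat", "locreg")

_CONN26 = np.ones((3, 3, 3), dtype=bool)


@dataclass(frozen=True)
class MethodParams:
    """Tunable parameters shared by the six methods.

    intensity_threshold: filtered-intensity cutoff used as foreground /
        maxima threshold by int, locwat and locreg.
    win: local-threshold window length, um.
    offset: local-threshold offset added to the windowed mean.
    alpha: hybrid mixing ratio in [0, 1] (1 = pure intensity).
    maxima_radius: designated distance for local maxima, um.
    region_radius: designated distance for locreg regions, um.
    min_voxels: size threshold; 26-connected regions strictly smaller
        are removed as false positives.
    """

    intensity_threshold: float = 0.0
    win: float = 4.0
    offset: float = 0.0
    alpha: float = 0.5
    maxima_radius: float = 2.0
    region_radius: float = 2.5
    min_voxels: int = 0

    def __post_init__(self) -> None:
        if self.win <= 0:
            raise ValueError("win must be positive")
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must lie in [0, 1]")
        for name in ("offset", "maxima_radius", "region_radius", "min_voxels"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")


def default_params_for_diameter(
    diameter_um: float,
    spacing: VoxelSpacing | None = None,
    contrast: float = 0.6,
) -> MethodParams:
    """Physically motivated parameters for nuclei of a given diameter.

    ``contrast`` is the peak-above-background intensity of a nucleus on
    the [0, 1] scale.  The intensity threshold and local-threshold offset
    are set to contrast/30 — far above the DoG-filtered noise floor, far
    below the blob response (~contrast/6 when the filter length matches
    the diameter).  The maxima radius is the nuclear radius, the region
    radius slightly larger, the threshold window ~1.5 diameters (so the
    window sees background around each nucleus), and the size threshold
    5% of the nuclear sphere volume in voxels — enough to kill speckle,
    far below a real nucleus.
    """
    spacing = spacing or VoxelSpacing()
    r = diameter_um / 2.0
    sphere_vox = (4.0 / 3.0) * np.pi * r**3 / (spacing.dx * spacing.dy * spacing.dz)
    return MethodParams(
        intensity_threshold=contrast / 30.0,
        win=1.5 * diameter_um,
        offset=contrast / 30.0,
        alpha=0.5,
        maxima_radius=r,
        region_radius=1.2 * r,
        min_voxels=max(2, int(0.05 * sphere_vox)),
    )


# ---------------------------------------------------------------------------
# Building blocks
# ---------------------------------------------------------------------------

def _window_sizes(win_um: float, spacing: VoxelSpacing, shape: tuple[int, int, int]) -> list[int]:
    sizes = []
    for d, n in zip(spacing.zyx, shape):
        hw = max(1, round(win_um / (2.0 * d)))
        size = 2 * hw + 1
        if size > n:  # clip to the largest odd window that fits
            size = n if n % 2 == 1 else n - 1
            size = max(1, size)
        sizes.append(size)
    return sizes


def local_threshold(stack: ImageStack, win: float, offset: float) -> np.ndarray:
    """Binarize by a windowed-mean threshold: fg iff I > mean_win + offset.

    The box window is physically ``win`` um long on each axis (rounded to
    an odd voxel count per axis, so it is anisotropy-aware) and
    reflect-padded at borders.  A window at least as large as the whole
    volume on every axis degenerates to the global mean.
    """
    if win <= 0:
        raise ValueError("win must be positive")
    arr = stack.intensities
    hw_ge_vol = all(
        2 * max(1, round(win / (2.0 * d))) + 1 >= n for d, n in zip(stack.spacing.zyx, arr.shape)
    )
    if hw_ge_vol:
        mean = np.full_like(arr, arr.mean())
    else:
        sizes = _window_sizes(win, stack.spacing, arr.shape)
        mean = ndimage.uniform_filter(arr, size=sizes, mode="reflect")
    return arr > mean + offset


def distance_map(mask: np.ndarray, spacing: VoxelSpacing | None = None) -> np.ndarray:
    """Anisotropic Euclidean distance (um) to the nearest background voxel.

    The volume border counts as background, so an all-foreground volume
    still carries finite distances to the faces.
    """
    spacing = spacing or VoxelSpacing()
    padded = np.pad(np.asarray(mask, dtype=bool), 1, mode="constant", constant_values=False)
    dist = ndimage.distance_transform_edt(padded, sampling=spacing.zyx)
    return dist[1:-1, 1:-1, 1:-1]


def _ball_footprint(radius_um: float, spacing: VoxelSpacing) -> np.ndarray:
    """Boolean ellipsoid footprint covering the physical ball of ``radius_um``."""
    hw = [int(np.floor(radius_um / d)) for d in spacing.zyx]
    zz, yy, xx = np.meshgrid(
        *[np.arange(-h, h + 1) * d for h, d in zip(hw, spacing.zyx)], indexing="ij"
    )
    return zz**2 + yy**2 + xx**2 <= radius_um**2 + 1e-12


def find_local_maxima(
    stack: ImageStack, radius: float, min_intensity: float
) -> np.ndarray:
    """Detect intensity peaks: voxels above ``min_intensity`` that no voxel
    within physical ``radius`` strictly exceeds.

    Among equal-intensity candidates within ``radius`` of each other only
    the lexicographically smallest (z, y, x) index is kept (greedy
    suppression in lexicographic order, so a small plateau yields one
    point).  Returns an (n, 3) int array of voxel indices, lexicographically
    sorted.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    arr = stack.intensities
    fp = _ball_footprint(radius, stack.spacing)
    local_max = ndimage.maximum_filter(arr, footprint=fp, mode="constant", cval=-np.inf)
    cand = np.argwhere((arr > min_intensity) & (arr == local_max))  # lex order
    if len(cand) == 0:
        return cand.astype(np.int64)
    steps = np.asarray(stack.spacing.zyx)
    kept: list[np.ndarray] = []
    kept_um = np.empty((0, 3))
    for c in cand:
        c_um = c * steps
        if kept and (np.sum((kept_um - c_um) ** 2, axis=1) <= radius**2 + 1e-12).any():
            continue
        kept.append(c)
        kept_um = np.vstack([kept_um, c_um])
    return np.asarray(kept, dtype=np.int64)


# ---------------------------------------------------------------------------
# Priority-flood watershed
# ---------------------------------------------------------------------------

@nb.njit(cache=False)
def _flood(vals, labels, mask, nz, ny, nx):  # pragma: no cover - jitted
    """In-place priority flood on flat arrays.

    Heap ordered by (landscape value, flat index); flat C-order index is
    the lexicographic (z, y, x) order, giving the documented tie-break.
    """
    n = vals.size
    heap = np.empty(n, np.int64)
    hs = 0
    for i in range(n):
        if labels[i] > 0 and mask[i]:
            heap[hs] = i
            hs += 1
            c = hs - 1
            while c > 0:
                p = (c - 1) // 2
                a, b = heap[c], heap[p]
                if vals[a] < vals[b] or (vals[a] == vals[b] and a < b):
                    heap[c], heap[p] = heap[p], heap[c]
                    c = p
                else:
                    break
    plane = ny * nx
    while hs > 0:
        v = heap[0]
        hs -= 1
        heap[0] = heap[hs]
        c = 0
        while True:
            l = 2 * c + 1
            r = l + 1
            s = c
            if l < hs:
                a, b = heap[l], heap[s]
                if vals[a] < vals[b] or (vals[a] == vals[b] and a < b):
                    s = l
            if r < hs:
                a, b = heap[r], heap[s]
                if vals[a] < vals[b] or (vals[a] == vals[b] and a < b):
                    s = r
            if s == c:
                break
            heap[c], heap[s] = heap[s], heap[c]
            c = s
        lab = labels[v]
        vz = v // plane
        rem = v - vz * plane
        vy = rem // nx
        vx = rem - vy * nx
        for dz in range(-1, 2):
            z = vz + dz
            if z < 0 or z >= nz:
                continue
            for dy in range(-1, 2):
                y = vy + dy
                if y < 0 or y >= ny:
                    continue
                for dx in range(-1, 2):
                    if dz == 0 and dy == 0 and dx == 0:
                        continue
                    x = vx + dx
                    if x < 0 or x >= nx:
                        continue
                    u = (z * ny + y) * nx + x
                    if mask[u] and labels[u] == 0:
                        labels[u] = lab
                        heap[hs] = u
                        hs += 1
                        c = hs - 1
                        while c > 0:
                            p = (c - 1) // 2
                            a, b = heap[c], heap[p]
                            if vals[a] < vals[b] or (vals[a] == vals[b] and a < b):
                                heap[c], heap[p] = heap[p], heap[c]
                                c = p
                            else:
                                break


def regional_minima_seeds(landscape: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Label the regional minima (26-connected plateaus) of the masked landscape."""
    work = np.where(mask, landscape, np.inf)
    minima = local_minima(work, connectivity=3) & mask
    seeds, _ = ndimage.label(minima, structure=_CONN26)
    return seeds.astype(np.int32)


def _relabel_contiguous(labels: np.ndarray) -> np.ndarray:
    present = np.unique(labels)
    present = present[present > 0]
    lut = np.zeros(int(labels.max(initial=0)) + 1, dtype=np.int32)
    lut[present] = np.arange(1, len(present) + 1, dtype=np.int32)
    return lut[labels]


def watershed_transform(
    landscape: np.ndarray,
    seeds: np.ndarray | LabelVolume | None = None,
    mask: np.ndarray | None = None,
    spacing: VoxelSpacing | None = None,
) -> LabelVolume:
    """Flood a scalar landscape from its regional minima (or given seeds).

    Flooding is restricted to ``mask`` when given and uses 26-connectivity;
    labels partition the reachable mask.  Flood order is by ``(value,
    lexicographic (z, y, x) index)``, making the result deterministic and
    implementation-independent.
    """
    landscape = np.asarray(landscape, dtype=np.float64)
    if landscape.ndim != 3:
        raise ValueError("landscape must be 3D")
    if not np.isfinite(landscape).all():
        raise ValueError("landscape must be finite")
    mask_arr = np.ones(landscape.shape, bool) if mask is None else np.asarray(mask, bool)
    if mask_arr.shape != landscape.shape:
        raise ValueError("mask shape mismatch")

    if seeds is None:
        seed_arr = regional_minima_seeds(landscape, mask_arr)
    else:
        seed_arr = seeds.labels if isinstance(seeds, LabelVolume) else np.asarray(seeds)
        seed_arr = seed_arr.astype(np.int32, copy=True)
        if seed_arr.shape != landscape.shape:
            raise ValueError("seed shape mismatch")
        if ((seed_arr > 0) & ~mask_arr).any():
            raise ValueError("seed voxel outside mask")

    labels = seed_arr.copy()
    nz, ny, nx = landscape.shape
    _flood(
        np.ascontiguousarray(landscape).ravel(),
        labels.reshape(-1),
        np.ascontiguousarray(mask_arr).ravel(),
        nz, ny, nx,
    )
    return LabelVolume(_relabel_contiguous(labels), spacing or VoxelSpacing())


# ---------------------------------------------------------------------------
# The six methods
# ---------------------------------------------------------------------------

def _rescale01(arr: np.ndarray) -> np.ndarray:
    lo, hi = float(arr.min()), float(arr.max())
    if hi <= lo:
        return np.zeros_like(arr)
    return (arr - lo) / (hi - lo)


def _seed_volume(maxima: np.ndarray, shape: tuple[int, int, int]) -> np.ndarray:
    seeds = np.zeros(shape, dtype=np.int32)
    for i, (z, y, x) in enumerate(maxima, start=1):
        seeds[z, y, x] = i
    return seeds


def segment_int(filtered: ImageStack, p: MethodParams) -> LabelVolume:
    """Intensity watershed on the negated filtered image, foreground =
    voxels with response above the intensity threshold."""
    mask = filtered.intensities > p.intensity_threshold
    vol = watershed_transform(-filtered.intensities, mask=mask, spacing=filtered.spacing)
    return size_filter(vol, p.min_voxels)


def segment_dst(filtered: ImageStack, p: MethodParams) -> LabelVolume:
    """Distance watershed: local threshold, distance transform, flood."""
    mask = local_threshold(filtered, p.win, p.offset)
    dist = distance_map(mask, filtered.spacing)
    vol = watershed_transform(-dist, mask=mask, spacing=filtered.spacing)
    return size_filter(vol, p.min_voxels)


def segment_hyb(filtered: ImageStack, p: MethodParams) -> LabelVolume:
    """Hybrid watershed: alpha-blend of rescaled intensity and distance map.

    Both terms are min-max rescaled to [0, 1] (their units are
    incommensurate); alpha = 1 reduces to intensity within the mask,
    alpha = 0 to the distance watershed.
    """
    mask = local_threshold(filtered, p.win, p.offset)
    dist = distance_map(mask, filtered.spacing)
    landscape = p.alpha * _rescale01(filtered.intensities) + (1.0 - p.alpha) * _rescale01(dist)
    vol = watershed_transform(-landscape, mask=mask, spacing=filtered.spacing)
    return size_filter(vol, p.min_voxels)


def segment_mul(filtered: ImageStack, p: MethodParams) -> LabelVolume:
    """Multiple watershed: intensity multiplied by the binary mask, flooded
    within the mask."""
    mask = local_threshold(filtered, p.win, p.offset)
    vol = watershed_transform(-(filtered.intensities * mask), mask=mask, spacing=filtered.spacing)
    return size_filter(vol, p.min_voxels)


def segment_locwat(filtered: ImageStack, p: MethodParams) -> LabelVolume:
    """Watershed seeded at the local maxima ('catchment basins')."""
    maxima = find_local_maxima(filtered, p.maxima_radius, p.intensity_threshold)
    mask = filtered.intensities > p.intensity_threshold
    seeds = _seed_volume(maxima, filtered.shape)
    vol = watershed_transform(-filtered.intensities, seeds=seeds, mask=mask, spacing=filtered.spacing)
    return size_filter(vol, p.min_voxels)


def segment_locreg(filtered: ImageStack, p: MethodParams) -> LabelVolume:
    """Region around each local maximum: voxels above threshold within the
    designated distance, assigned to their nearest maximum (ties go to the
    lexicographically smallest seed)."""
    maxima = find_local_maxima(filtered, p.maxima_radius, p.intensity_threshold)
    labels = np.zeros(filtered.shape, dtype=np.int32)
    if len(maxima) > 0:
        steps = np.asarray(filtered.spacing.zyx)
        seed_um = maxima * steps
        fg = np.argwhere(filtered.intensities > p.intensity_threshold)
        if len(fg) > 0:
            tree = cKDTree(seed_um)
            k = min(3, len(maxima))
            dists, idx = tree.query(fg * steps, k=k)
            if k == 1:
                dists, idx = dists[:, None], idx[:, None]
            nearest = idx[:, 0].copy()
            # exact-tie resolution: lexicographically smallest seed wins
            for j in range(1, k):
                tie = np.isclose(dists[:, j], dists[:, 0], rtol=0.0, atol=1e-9)
                nearest[tie] = np.minimum(nearest[tie], idx[tie, j])
            keep = dists[:, 0] <= p.region_radius + 1e-12
            sel = fg[keep]
            labels[sel[:, 0], sel[:, 1], sel[:, 2]] = nearest[keep] + 1
    vol = LabelVolume(_relabel_contiguous(labels), filtered.spacing)
    return size_filter(vol, p.min_voxels)


_SEGMENTERS = {
    "int": segment_int,
    "dst": segment_dst,
    "hyb": segment_hyb,
    "mul": segment_mul,
    "locwat": segment_locwat,
    "locreg": segment_locreg,
}


def segment(method: str, filtered: ImageStack, p: MethodParams) -> LabelVolume:
    """Run one of the six methods by name (int|dst|hyb|mul|locwat|locreg)."""
    try:
        fn = _SEGMENTERS[method.lower()]
    except KeyError:
        raise ValueError(
            f"unknown method {method!r}; valid names: {', '.join(METHOD_NAMES)}"
        ) from None
    return fn(filtered, p)


# ---------------------------------------------------------------------------
# Post-processing
# ---------------------------------------------------------------------------

def size_filter(vol: LabelVolume, min_voxels: int) -> LabelVolume:
    """Remove regions with fewer than ``min_voxels`` 26-connected voxels.

    Region sizes are re-derived per label as 26-connected components, so a
    label whose voxels are disconnected splits into separate regions, while
    adjacent distinct labels are never merged.  Survivors are relabeled
    1..K (strictly-below removal: a region of exactly ``min_voxels`` stays).
    """
    if min_voxels < 0:
        raise ValueError("min_voxels must be >= 0")
    src = vol.labels
    out = np.zeros_like(src)
    next_label = 1
    for lab, sl in enumerate(ndimage.find_objects(src), start=1):
        if sl is None:
            continue
        sub = src[sl] == lab
        comps, n = ndimage.label(sub, structure=_CONN26)
        for c in range(1, n + 1):
            m = comps == c
            if int(m.sum()) >= max(min_voxels, 1):
                region = out[sl]
                region[m] = next_label
                next_label += 1
    return LabelVolume(out, vol.spacing)


def region_centroids(vol: LabelVolume) -> list[NucleusDetection]:
    """Unweighted centroid (um, x/y/z) and voxel count per labeled region."""
    labels = vol.labels
    n = vol.n_labels
    if n == 0:
        return []
    dz, dy, dx = vol.spacing.zyx
    zz, yy, xx = np.nonzero(labels)
    lab = labels[zz, yy, xx]
    counts = np.bincount(lab, minlength=n + 1)
    sum_z = np.bincount(lab, weights=zz, minlength=n + 1)
    sum_y = np.bincount(lab, weights=yy, minlength=n + 1)
    sum_x = np.bincount(lab, weights=xx, minlength=n + 1)
    out = []
    for k in range(1, n + 1):
        if counts[k] == 0:
            continue
        cnt = int(counts[k])
        out.append(
            NucleusDetection(
                label=k,
                centroid=(
                    float(sum_x[k] / cnt * dx),
                    float(sum_y[k] / cnt * dy),
                    float(sum_z[k] / cnt * dz),
                ),
                voxels=cnt,
            )
        )
    return out
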