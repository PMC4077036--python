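"""Independent brute-force oracles used to validate the package.

These deliberately avoid the code paths of the implementation: direct
shift-and-add correlation instead of separable scipy passes, linear-scan
priority flood instead of the jitted heap, exhaustive pairwise search
instead of KD-trees / distance transforms.
"""

from __future__ import annotations

import numpy as np


def naive_correlate3d(arr: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Direct correlation with symmetric (edge-including) reflection padding."""
    kz, ky, kx = kernel.shape
    hz, hy, hx = (kz - 1) // 2, (ky - 1) // 2, (kx - 1) // 2
    p = np.pad(arr.astype(np.float64), ((hz, hz), (hy, hy), (hx, hx)), mode="symmetric")
    nz, ny, nx = arr.shape
    out = np.zeros(arr.shape, dtype=np.float64)
    for iz in range(kz):
        for iy in range(ky):
            for ix in range(kx):
                out += kernel[iz, iy, ix] * p[iz:iz + nz, iy:iy + ny, ix:ix + nx]
    return out


def naive_correlate4d(frames: np.ndarray, kernel4: np.ndarray) -> np.ndarray:
    """Direct 4D correlation (reflection on every axis incl. time).

    ``frames`` is (T, Z, Y, X); returns the response of every frame.
    """
    kt, kz, ky, kx = kernel4.shape
    ht, hz, hy, hx = (kt - 1) // 2, (kz - 1) // 2, (ky - 1) // 2, (kx - 1) // 2
    p = np.pad(
        frames.astype(np.float64),
        ((ht, ht), (hz, hz), (hy, hy), (hx, hx)),
        mode="symmetric",
    )
    nt, nz, ny, nx = frames.shape
    out = np.zeros(frames.shape, dtype=np.float64)
    for it in range(kt):
        for iz in range(kz):
            for iy in range(ky):
                for ix in range(kx):
                    out += kernel4[it, iz, iy, ix] * p[
                        it:it + nt, iz:iz + nz, iy:iy + ny, ix:ix + nx
                    ]
    return out


def windowed_mean(arr: np.ndarray, sizes: tuple[int, int, int]) -> np.ndarray:
    """Brute-force reflect-padded box mean with odd per-axis window sizes."""
    hz, hy, hx = [(s - 1) // 2 for s in sizes]
    p = np.pad(arr.astype(np.float64), ((hz, hz), (hy, hy), (hx, hx)), mode="symmetric")
    out = np.empty(arr.shape, dtype=np.float64)
    nz, ny, nx = arr.shape
    for z in range(nz):
        for y in range(ny):
            for x in range(nx):
                out[z, y, x] = p[z:z + 2 * hz + 1, y:y + 2 * hy + 1, x:x + 2 * hx + 1].mean()
    return out


def nearest_background_um(mask: np.ndarray, spacing_zyx: tuple[float, float, float]) -> np.ndarray:
    """Exhaustive anisotropic distance to the nearest background voxel.

    The volume border counts as background (distance to the nearest face
    plane half a step beyond the outermost voxel row is handled by padding).
    """
    padded = np.pad(np.asarray(mask, bool), 1, constant_values=False)
    steps = np.asarray(spacing_zyx)
    bg = np.argwhere(~padded) - 1  # back to unpadded coordinates
    bg_um = bg * steps
    out = np.zeros(mask.shape, dtype=np.float64)
    for idx in np.argwhere(mask):
        d2 = np.sum((bg_um - idx * steps) ** 2, axis=1)
        out[tuple(idx)] = np.sqrt(d2.min())
    return out


def _neighbors26(idx, shape):
    z, y, x = idx
    for dz in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dx in (-1, 0, 1):
                if dz == dy == dx == 0:
                    continue
                u = (z + dz, y + dy, x + dx)
                if all(0 <= u[k] < shape[k] for k in range(3)):
                    yield u


def regional_minima_oracle(landscape: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Label 26-connected equal-value plateaus with no lower masked neighbour.

    Components are numbered by first-encountered voxel in lexicographic
    scan order.
    """
    shape = landscape.shape
    labels = np.zeros(shape, dtype=np.int32)
    comp_id = 0
    visited = np.zeros(shape, dtype=bool)
    for start in map(tuple, np.argwhere(mask)):
        if visited[start]:
            continue
        # flood the equal-value plateau containing `start`
        value = landscape[start]
        plateau = [start]
        visited[start] = True
        queue = [start]
        is_min = True
        while queue:
            v = queue.pop()
            for u in _neighbors26(v, shape):
                if not mask[u]:
                    continue
                if landscape[u] < value:
                    is_min = False
                elif landscape[u] == value and not visited[u]:
                    visited[u] = True
                    plateau.append(u)
                    queue.append(u)
        if is_min:
            comp_id += 1
            for v in plateau:
                labels[v] = comp_id
    return labels


def priority_flood_oracle(
    landscape: np.ndarray,
    seeds: np.ndarray | None = None,
    mask: np.ndarray | None = None,
) -> np.ndarray:
    """Linear-scan priority flood: repeatedly process the active voxel with
    the smallest (value, lexicographic index) key, labelling unlabeled
    masked 26-neighbours."""
    shape = landscape.shape
    mask = np.ones(shape, bool) if mask is None else np.asarray(mask, bool)
    if seeds is None:
        labels = regional_minima_oracle(landscape, mask)
    else:
        labels = np.asarray(seeds, dtype=np.int32).copy()
    flat = lambda v: (v[0] * shape[1] + v[1]) * shape[2] + v[2]
    active = [tuple(v) for v in np.argwhere((labels > 0) & mask)]
    while active:
        v = min(active, key=lambda i: (landscape[i], flat(i)))
        active.remove(v)
        for u in _neighbors26(v, shape):
            if mask[u] and labels[u] == 0:
                labels[u] = labels[v]
                active.append(u)
    return labels


def canonical_labels(labels: np.ndarray) -> np.ndarray:
    """Relabel by order of first occurrence in flat scan (partition form)."""
    out = np.zeros_like(labels)
    mapping: dict[int, int] = {}
    flat = labels.ravel()
    canon = out.ravel()
    for i, lab in enumerate(flat):
        if lab > 0:
            if lab not in mapping:
                mapping[lab] = len(mapping) + 1
            canon[i] = mapping[lab]
    return out


def mutual_nn_oracle(pred: np.ndarray, gt: np.ndarray, threshold: float):
    """Exhaustive mutual-nearest-neighbour matching; returns (tp, fp, fn) and
    the matched pairs."""
    pred = np.asarray(pred, float).reshape(-1, 3)
    gt = np.asarray(gt, float).reshape(-1, 3)
    pairs = []
    for i, p in enumerate(pred):
        if len(gt) == 0:
            break
        d_to_gt = [float(np.linalg.norm(p - g)) for g in gt]
        j = int(np.argmin(d_to_gt))  # first index on ties
        d_back = [float(np.linalg.norm(gt[j] - q)) for q in pred]
        if int(np.argmin(d_back)) == i and d_to_gt[j] < threshold:
            pairs.append((i, j))
    tp = len(pairs)
    return tp, len(pred) - tp, len(gt) - tp, pairs


def local_maxima_oracle(
    arr: np.ndarray,
    spacing_zyx: tuple[float, float, float],
    radius: float,
    min_intensity: float,
) -> list[tuple[int, int, int]]:
    """Exhaustive peak detection with greedy lexicographic suppression."""
    steps = np.asarray(spacing_zyx)
    coords = np.argwhere(np.ones_like(arr, bool))
    um = coords * steps
    vals = arr.reshape(-1)
    candidates = []
    for k, c in enumerate(coords):
        if vals[k] <= min_intensity:
            continue
        d2 = np.sum((um - um[k]) ** 2, axis=1)
        within = d2 <= radius**2 + 1e-12
        if (vals[within] > vals[k]).any():
            continue
        candidates.append(tuple(c))
    kept = []
    for c in candidates:  # argwhere order is lexicographic
        c_um = np.asarray(c) * steps
        if any(np.sum((np.asarray(k) * steps - c_um) ** 2) <= radius**2 + 1e-12 for k in kept):
            continue
        kept.append(c)
    return kept
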