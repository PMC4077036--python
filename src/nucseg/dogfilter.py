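"""Difference-of-Gaussian (DoG) pre-filters in 2D, 3D and 4D.

The DoG is a band-pass blob detector: a narrow Gaussian blur minus a wider
one.  The filter is parameterized by its spatial XY length ``l_xy`` in um;
the inner Gaussian has sigma = l_xy / 4 (physical um, converted to voxels
per axis) and the outer sigma is ``sigma_ratio`` times that (default 1.6,
the classic blob-detection choice).  Both truncated Gaussians are
normalized to unit sum before subtraction, so the kernel sums to exactly
zero and a constant image maps to zero response.

Anisotropy rule: at the recording spacing (0.25, 0.25, 1 um) the kernel's
voxel length along z is one quarter of its xy voxel length, preserving the
physical 3D aspect of the filter.

The 4D filter extends a 3D DoG along time: a truncated unit-sum Gaussian
temporal profile of half-width ``t_len`` frames (sigma_t = max(t_len/2,
0.5)) multiplies the spatial kernel, so a frame's response pools its
temporal neighbours.  Borders are reflect-padded on every axis, including
time.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .imgdata import ImageSeries, ImageStack, VoxelSpacing

__all__ = ["DoGSpec", "Kernel", "build_dog_kernel", "apply_dog", "apply_dog_4d"]


@dataclass(frozen=True)
class DoGSpec:
    """Parameters of a 2D/3D/4D DoG filter.

    l_xy: spatial XY filter length, um.
    dim: "2D", "3D" or "4D".
    t_len: temporal half-width in frames (0 unless dim == "4D"; the 4D
        kernel spans 2*t_len + 1 frames).
    sigma_ratio: outer/inner Gaussian width ratio, > 1.
    """

    l_xy: float
    dim: str = "3D"
    t_len: int = 0
    sigma_ratio: float = 1.6

    def __post_init__(self) -> None:
        if self.l_xy <= 0:
            raise ValueError(f"filter length must be positive, got {self.l_xy}")
        if self.dim not in ("2D", "3D", "4D"):
            raise ValueError(f"dim must be 2D, 3D or 4D, got {self.dim!r}")
        if self.dim == "4D":
            if not 1 <= self.t_len <= 5:
                raise ValueError("4D filter needs t_len in 1..5")
        elif self.t_len != 0:
            raise ValueError("t_len must be 0 for 2D/3D filters")
        if self.sigma_ratio <= 1:
            raise ValueError(f"sigma_ratio must exceed 1, got {self.sigma_ratio}")


@dataclass
class Kernel:
    """Discrete DoG kernel over (t, z, y, x) offsets.

    ``weights`` always carries four axes; 2D/3D kernels have singleton t
    (and z, for 2D).  The separable 1D profiles used for fast application
    are kept alongside the dense array.
    """

    weights: np.ndarray
    profiles_inner: tuple[np.ndarray, np.ndarray, np.ndarray]  # z, y, x unit-sum
    profiles_outer: tuple[np.ndarray, np.ndarray, np.ndarray]
    temporal: np.ndarray  # unit-sum profile of length 2*t_len+1 (len 1 for 2D/3D)

    @property
    def extents(self) -> tuple[int, int, int, int]:
        return self.weights.shape

    @property
    def spatial(self) -> np.ndarray:
        """Dense 3D spatial DoG (z, y, x)."""
        return self.weights.sum(axis=0) if self.weights.shape[0] > 1 else self.weights[0]


def _gauss_profile(sigma_vox: float, half_width: int) -> np.ndarray:
    """Truncated sampled Gaussian on offsets -hw..hw, normalized to unit sum."""
    x = np.arange(-half_width, half_width + 1, dtype=np.float64)
    g = np.exp(-0.5 * (x / sigma_vox) ** 2)
    return g / g.sum()


def kernel_half_widths(spec: DoGSpec, spacing: VoxelSpacing) -> tuple[int, int, int]:
    """Voxel half-widths (z, y, x) of the kernel support.

    XY half-width = round(l_xy / (2 dx)); z half-width keeps the voxel
    length ratio z:xy at 1:4 (2D filters have zero z extent).
    """
    hw_x = max(1, round(spec.l_xy / (2 * spacing.dx)))
    hw_y = max(1, round(spec.l_xy / (2 * spacing.dy)))
    if spec.dim == "2D":
        hw_z = 0
    else:
        hw_z = max(1, round(hw_x / 4))
    return hw_z, hw_y, hw_x


def build_dog_kernel(spec: DoGSpec, spacing: VoxelSpacing | None = None) -> Kernel:
    """Realize a DoG spec as a discrete zero-sum kernel on the voxel grid."""
    spacing = spacing or VoxelSpacing()
    hw_z, hw_y, hw_x = kernel_half_widths(spec, spacing)
    sigma_um = spec.l_xy / 4.0
    steps = spacing.zyx
    hws = (hw_z, hw_y, hw_x)

    inner = tuple(_gauss_profile(sigma_um / d, hw) for d, hw in zip(steps, hws))
    outer = tuple(
        _gauss_profile(spec.sigma_ratio * sigma_um / d, hw) for d, hw in zip(steps, hws)
    )
    # unit-sum separable profiles => each dense Gaussian is unit-sum => zero-sum DoG
    dense_inner = inner[0][:, None, None] * inner[1][None, :, None] * inner[2][None, None, :]
    dense_outer = outer[0][:, None, None] * outer[1][None, :, None] * outer[2][None, None, :]
    dog3 = dense_inner - dense_outer

    if spec.dim == "4D":
        sigma_t = max(spec.t_len / 2.0, 0.5)
        temporal = _gauss_profile(sigma_t, spec.t_len)
    else:
        temporal = np.ones(1)
    weights = temporal[:, None, None, None] * dog3[None]
    return Kernel(weights=weights, profiles_inner=inner, profiles_outer=outer, temporal=temporal)


def _check_fits(shape: tuple[int, int, int], kernel: Kernel) -> None:
    kt, kz, ky, kx = kernel.extents
    for n, k, ax in zip(shape, (kz, ky, kx), "zyx"):
        if k > n:
            raise ValueError(f"kernel extent {k} exceeds image size {n} on axis {ax}")


def _correlate_separable(arr: np.ndarray, kernel: Kernel) -> np.ndarray:
    """Reflect-padded correlation with the spatial DoG via separable passes."""
    out_i = arr
    out_o = arr
    for axis, (pi, po) in enumerate(zip(kernel.profiles_inner, kernel.profiles_outer)):
        if len(pi) > 1:
            out_i = ndimage.correlate1d(out_i, pi, axis=axis, mode="reflect")
            out_o = ndimage.correlate1d(out_o, po, axis=axis, mode="reflect")
        else:  # singleton profile: identity (2D kernel z axis)
            pass
    return out_i - out_o


def apply_dog(stack: ImageStack, spec: DoGSpec) -> ImageStack:
    """Filter one stack with a 2D or 3D DoG; 2D filters each z-slice alone.

    Output has the same shape; borders are reflect-padded.  The response
    is signed (band-pass): positive over blobs of the matching scale,
    negative in the surround.
    """
    return ImageStack(dog_response(stack, spec), stack.spacing)


def dog_response(stack: ImageStack, spec: DoGSpec) -> np.ndarray:
    """Raw (signed) DoG response of one stack for a 2D or 3D spec."""
    if spec.dim == "4D":
        raise ValueError("use apply_dog_4d for 4D specs")
    kernel = build_dog_kernel(spec, stack.spacing)
    _check_fits(stack.shape, kernel)
    return _correlate_separable(stack.intensities, kernel)


def _reflect_index(i: int, n: int) -> int:
    """Reflect an out-of-range index into [0, n) with edge duplication.

    Matches scipy.ndimage mode="reflect": (d c b a | a b c d | d c b a).
    """
    if n == 1:
        return 0
    period = 2 * n
    i %= period
    if i < 0:
        i += period
    return i if i < n else period - 1 - i


def dog_response_4d(series: ImageSeries, spec: DoGSpec, t: int) -> np.ndarray:
    """Raw 4D DoG response at frame t: temporally weighted 3D responses.

    Frames beyond the series boundary are handled by temporal reflection.
    With identical frames the result equals the 3D response of one frame
    (the temporal profile sums to 1).
    """
    if spec.dim != "4D":
        raise ValueError("spec must be 4D")
    if not 0 <= t < len(series):
        raise IndexError(f"frame {t} out of range for series of {len(series)}")
    kernel = build_dog_kernel(spec, series.spacing)
    _check_fits(series[0].shape, kernel)

    spec3 = DoGSpec(l_xy=spec.l_xy, dim="3D", sigma_ratio=spec.sigma_ratio)
    cache: dict[int, np.ndarray] = {}
    out = np.zeros(series[0].shape, dtype=np.float64)
    for k, w in enumerate(kernel.temporal):
        off = k - spec.t_len
        ti = _reflect_index(t + off, len(series))
        if ti not in cache:
            cache[ti] = dog_response(series[ti], spec3)
        out += w * cache[ti]
    return out


def apply_dog_4d(series: ImageSeries, spec: DoGSpec, t: int) -> ImageStack:
    """4D-filtered stack at frame t (signed response, same shape)."""
    return ImageStack(dog_response_4d(series, spec, t), series.spacing)


def filter_frame(series: ImageSeries, spec: DoGSpec, t: int) -> np.ndarray:
    """Raw DoG response at frame t for any spec dimensionality."""
    if spec.dim == "4D":
        return dog_response_4d(series, spec, t)
    return dog_response(series[t], spec)
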