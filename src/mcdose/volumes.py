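"""Volume geometry handling.

All dose and CT grids in this package live on a regular Cartesian grid
described by a :class:`Volume`: a 3D scalar array plus voxel size and origin
in cm.  Axes are ordered (x, y, z), with z the slice/rotation axis; voxel
indices are 0-based and positions are voxel-centre offsets from ``origin``.

The module provides the geometric plumbing of the denoising workflow:
integral-conserving resampling to the working voxel size (0.25 cm
isotropic by default), central cropping / zero-padding to the network's
xy footprint, dataset-level intensity scale constants, and NIfTI I/O.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
import nibabel as nib
from scipy.interpolate import PchipInterpolator

__all__ = [
    "Volume",
    "ScaleConstants",
    "Placement",
    "VolumeFormatError",
    "HU_AIR",
    "HU_BODY_THRESHOLD",
    "resample_conservative",
    "crop_or_pad_xy",
    "restore_xy",
    "compute_scale_constants",
    "read_volume",
    "write_volume",
]

HU_AIR = -1000.0
#: HU above which a voxel is considered part of the body.
HU_BODY_THRESHOLD = -400.0


class VolumeFormatError(ValueError):
    """Raised when a volume file cannot be parsed."""


@dataclasses.dataclass
class Volume:
    """A scalar field on a regular 3D grid.

    Parameters
    ----------
    values : ndarray, shape (nx, ny, nz)
        Finite scalar values (HU or Gy/MU).
    voxel_size : tuple of float
        Voxel edge lengths in cm, all positive.
    origin : tuple of float
        Position of the centre of voxel (0, 0, 0) in cm.
    """

    values: np.ndarray
    voxel_size: tuple[float, float, float] = (0.25, 0.25, 0.25)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise ValueError(f"expected a 3D array, got ndim={self.values.ndim}")
        self.voxel_size = tuple(float(v) for v in self.voxel_size)
        self.origin = tuple(float(v) for v in self.origin)
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError(f"voxel_size must be positive, got {self.voxel_size}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("volume contains non-finite values")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def voxel_volume(self) -> float:
        """Voxel volume in cm^3."""
        return float(np.prod(self.voxel_size))

    def integral(self) -> float:
        """Total integrated value (sum * voxel volume)."""
        return float(self.values.sum(dtype=np.float64) * self.voxel_volume)

    def same_grid(self, other: "Volume", tol: float = 1e-6) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.voxel_size, other.voxel_size, atol=tol)
            and np.allclose(self.origin, other.origin, atol=tol)
        )

    def copy(self) -> "Volume":
        return Volume(self.values.copy(), self.voxel_size, self.origin)


@dataclasses.dataclass(frozen=True)
class ScaleConstants:
    """Dataset-level intensity scale factors.

    ``ct_scale`` divides the (HU + 1000)-shifted CT so air maps to 0 and the
    densest calibration tissue to ~1; ``dose_scale`` divides the dose.  Both
    are fixed constants obtained once from calibration cases and applied
    identically to every subsequent volume.
    """

    ct_scale: float
    dose_scale: float

    def __post_init__(self) -> None:
        if self.ct_scale <= 0 or self.dose_scale <= 0:
            raise ValueError("scale constants must be positive")

    def pow2(self) -> "ScaleConstants":
        """Snap both factors to the nearest power of two.

        Power-of-two scaling is lossless in floating point, so the
        scale -> network -> unscale chain of the inference pipeline is an
        exact round trip for an identity network.  The snapped factors stay
        within a factor sqrt(2) of the calibrated ones, preserving the
        "approximately 0 to 1" input range.
        """
        return ScaleConstants(
            2.0 ** round(math.log2(self.ct_scale)),
            2.0 ** round(math.log2(self.dose_scale)),
        )


def _resample_axis_conservative(
    values: np.ndarray, axis: int, h_src: float, n_tgt: int, h_tgt: float
) -> np.ndarray:
    """Resample one axis by monotone-cubic interpolation of the cumulative integral."""
    n_src = values.shape[axis]
    extent = n_src * h_src
    # cumulative integral at source voxel edges, 0 .. extent
    edges_src = np.arange(n_src + 1) * h_src
    cum = np.concatenate(
        [
            np.zeros_like(np.take(values, [0], axis=axis)),
            np.cumsum(values, axis=axis) * h_src,
        ],
        axis=axis,
    )
    interp = PchipInterpolator(edges_src, cum, axis=axis, extrapolate=False)
    edges_tgt = np.minimum(np.arange(n_tgt + 1) * h_tgt, extent)
    cum_tgt = interp(edges_tgt)  # scipy keeps the interpolation axis in place
    return np.diff(cum_tgt, axis=axis) / h_tgt


def resample_conservative(
    volume: Volume, target_voxel_size: tuple[float, float, float]
) -> Volume:
    """Resample to a new voxel size, conserving the total integral.

    Separable per-axis scheme: the cumulative 1D integral along each axis is
    interpolated with a monotone cubic Hermite spline (PCHIP) and differenced
    on the target edge grid.  Because the spline interpolates the cumulative
    values at both endpoints exactly, the total integral is preserved to
    floating-point precision.  The output grid covers at least the physical
    extent of the input (the last target voxel may extend beyond it; the
    cumulative integral is clamped there, contributing zero).

    An identical target voxel size returns a bit-wise copy of the input.
    """
    target_voxel_size = tuple(float(v) for v in target_voxel_size)
    if any(v <= 0 for v in target_voxel_size):
        raise ValueError("target_voxel_size must be positive")
    if target_voxel_size == volume.voxel_size:
        return volume.copy()

    values = np.asarray(volume.values, dtype=np.float64)
    new_shape = []
    for ax in range(3):
        extent = volume.shape[ax] * volume.voxel_size[ax]
        if target_voxel_size[ax] > extent * (1 + 1e-9):
            raise ValueError(
                f"target voxel size {target_voxel_size[ax]} cm on axis {ax} is "
                f"coarser than the full extent {extent} cm"
            )
        ratio = extent / target_voxel_size[ax]
        n_tgt = round(ratio) if abs(ratio - round(ratio)) < 1e-9 else math.ceil(ratio)
        new_shape.append(n_tgt)

    for ax in range(3):
        if target_voxel_size[ax] == volume.voxel_size[ax] and new_shape[ax] == values.shape[ax]:
            continue
        values = _resample_axis_conservative(
            values, ax, volume.voxel_size[ax], new_shape[ax], target_voxel_size[ax]
        )

    # voxel-centre origin shifts by half the voxel-size difference
    origin = tuple(
        volume.origin[ax] - volume.voxel_size[ax] / 2 + target_voxel_size[ax] / 2
        for ax in range(3)
    )
    return Volume(values, target_voxel_size, origin)


@dataclasses.dataclass(frozen=True)
class Placement:
    """Record of a crop/pad operation, sufficient to invert it exactly.

    ``src_slices`` index the original array, ``dst_slices`` the resized one;
    the retained region satisfies ``out[dst] = in[src]``.
    """

    original_shape: tuple[int, int, int]
    src_slices: tuple[tuple[int, int], tuple[int, int]]
    dst_slices: tuple[tuple[int, int], tuple[int, int]]

    def to_dict(self) -> dict:
        return {
            "original_shape": list(self.original_shape),
            "src_slices": [list(s) for s in self.src_slices],
            "dst_slices": [list(s) for s in self.dst_slices],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Placement":
        return cls(
            original_shape=tuple(d["original_shape"]),
            src_slices=tuple(tuple(s) for s in d["src_slices"]),
            dst_slices=tuple(tuple(s) for s in d["dst_slices"]),
        )


def _split_center(n: int, target: int) -> tuple[tuple[int, int], tuple[int, int]]:
    """Central crop/pad bounds for one axis, left-biased on odd differences."""
    if n >= target:  # crop
        lo = (n - target) // 2
        return (lo, lo + target), (0, target)
    lo = (target - n) // 2
    return (0, n), (lo, lo + n)


def crop_or_pad_xy(volume: Volume, xy_size: int = 192) -> tuple[Volume, Placement]:
    """Centrally crop or zero-pad the x and y axes to ``xy_size`` voxels.

    Cropping removes ``(n - xy_size) // 2`` voxels from the low side (one
    fewer than from the high side when the surplus is odd); padding is the
    mirror operation with zeros.  The returned :class:`Placement` allows
    exact restoration of results into the original frame via
    :func:`restore_xy`.
    """
    if xy_size < 1:
        raise ValueError("xy_size must be >= 1")
    nx, ny, nz = volume.shape
    (sx, dx), (sy, dy) = _split_center(nx, xy_size), _split_center(ny, xy_size)
    out = np.zeros((xy_size, xy_size, nz), dtype=volume.values.dtype)
    out[dx[0] : dx[1], dy[0] : dy[1]] = volume.values[sx[0] : sx[1], sy[0] : sy[1]]
    placement = Placement((nx, ny, nz), (sx, sy), (dx, dy))
    origin = (
        volume.origin[0] + (sx[0] - dx[0]) * volume.voxel_size[0],
        volume.origin[1] + (sy[0] - dy[0]) * volume.voxel_size[1],
        volume.origin[2],
    )
    return Volume(out, volume.voxel_size, origin), placement


def restore_xy(values: np.ndarray, placement: Placement) -> np.ndarray:
    """Place a processed ``xy_size`` array back into the original xy frame.

    Voxels that were cropped away are filled with zeros.
    """
    (sx, sy), (dx, dy) = placement.src_slices, placement.dst_slices
    nx, ny, _ = placement.original_shape
    out = np.zeros((nx, ny, values.shape[2]), dtype=values.dtype)
    out[sx[0] : sx[1], sy[0] : sy[1]] = values[dx[0] : dx[1], dy[0] : dy[1]]
    return out


def compute_scale_constants(
    calibration_cases: list[tuple[Volume, Volume]],
) -> ScaleConstants:
    """Derive dataset-level scale constants from calibration (CT, dose) cases.

    The per-case normalization factor is the maximum absolute value of the
    case's volume, with the CT first shifted by +1000 HU so that air maps to
    zero.  The returned constant is the arithmetic mean over cases and is
    applied identically to all subsequent data.
    """
    if not calibration_cases:
        raise ValueError("need at least one calibration case")
    ct_maxima, dose_maxima = [], []
    for ct, dose in calibration_cases:
        ct_max = float(np.abs(ct.values + 1000.0).max())
        dose_max = float(np.abs(dose.values).max())
        if ct_max == 0.0 or dose_max == 0.0:
            raise ValueError("all-zero calibration volume")
        ct_maxima.append(ct_max)
        dose_maxima.append(dose_max)
    return ScaleConstants(float(np.mean(ct_maxima)), float(np.mean(dose_maxima)))


def write_volume(volume: Volume, path) -> None:
    """Write a volume as NIfTI; the affine encodes voxel size and origin in mm."""
    affine = np.diag([*(10.0 * v for v in volume.voxel_size), 1.0])
    affine[:3, 3] = [10.0 * o for o in volume.origin]
    nib.save(nib.Nifti1Image(np.asarray(volume.values), affine), str(path))


def read_volume(path) -> Volume:
    """Read a NIfTI volume written by :func:`write_volume`.

    Raises :class:`VolumeFormatError` on malformed or truncated files.
    """
    try:
        img = nib.load(str(path))
        data = np.asarray(img.dataobj)
        affine = img.affine
    except Exception as exc:  # nibabel raises a zoo of error types
        raise VolumeFormatError(f"cannot read NIfTI volume {path}: {exc}") from exc
    if data.ndim != 3:
        raise VolumeFormatError(f"{path}: expected 3D data, got shape {data.shape}")
    scales = np.abs(np.diag(affine)[:3])
    if np.any(scales <= 0):
        raise VolumeFormatError(f"{path}: non-positive voxel size in affine")
    return Volume(data, tuple(scales / 10.0), tuple(affine[:3, 3] / 10.0))
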