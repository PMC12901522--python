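"""CT-like phantom generation and radiological depth.

Phantoms stand in for planning CTs: an ellipsoidal water-equivalent body
(HU ~ 0) surrounded by air (HU -1000), optionally with low-density
(lung-like, ~ -700 HU) and high-density (bone-like, ~ +700 HU) ellipsoidal
inserts.  The body mask -- the network's notion of "patient" -- is derived
by thresholding at -400 HU, and dose is defined as zero outside it.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.ndimage import map_coordinates

from .volumes import HU_AIR, HU_BODY_THRESHOLD, Volume

__all__ = [
    "Insert",
    "PhantomSpec",
    "Phantom",
    "InvalidSpecError",
    "generate_phantom",
    "radiological_depth",
    "hu_to_density",
]

#: HU values for the supported insert kinds.
INSERT_HU = {"lung": -700.0, "bone": 700.0}


class InvalidSpecError(ValueError):
    """Raised when a phantom specification cannot be realized."""


@dataclasses.dataclass(frozen=True)
class Insert:
    """An ellipsoidal tissue insert inside the body.

    ``center`` is in cm relative to the body centre; ``semi_axes`` in cm.
    """

    kind: str  # "lung" or "bone"
    center: tuple[float, float, float]
    semi_axes: tuple[float, float, float]

    def __post_init__(self) -> None:
        if self.kind not in INSERT_HU:
            raise InvalidSpecError(f"unknown insert kind {self.kind!r}")


@dataclasses.dataclass(frozen=True)
class PhantomSpec:
    """Specification of a synthetic phantom.

    ``semi_axes`` are the body-ellipsoid semi-axes in cm; the body is
    centred in the grid.  ``hu_noise_sd`` adds seeded Gaussian HU texture
    inside the body (0 by default, giving exactly uniform tissue values).
    """

    shape: tuple[int, int, int] = (64, 64, 48)
    voxel_size: tuple[float, float, float] = (0.25, 0.25, 0.25)
    semi_axes: tuple[float, float, float] = (6.0, 5.0, 5.0)
    inserts: tuple[Insert, ...] = ()
    hu_noise_sd: float = 0.0


@dataclasses.dataclass
class Phantom:
    """A CT-like HU grid plus geometry and body mask."""

    hu: np.ndarray
    voxel_size: tuple[float, float, float]
    origin: tuple[float, float, float]
    body_mask: np.ndarray

    def __post_init__(self) -> None:
        if self.hu.shape != self.body_mask.shape:
            raise ValueError("hu and body_mask shapes differ")
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError("voxel_size must be positive")
        if not self.body_mask.any():
            raise ValueError("phantom has no body voxels")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.hu.shape

    def ct_volume(self) -> Volume:
        return Volume(self.hu, self.voxel_size, self.origin)

    def voxel_centers(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Per-axis voxel-centre coordinates in cm."""
        return tuple(
            self.origin[ax] + np.arange(self.shape[ax]) * self.voxel_size[ax]
            for ax in range(3)
        )

    def center(self) -> np.ndarray:
        """Geometric centre of the grid in cm."""
        return np.array(
            [
                self.origin[ax] + (self.shape[ax] - 1) / 2 * self.voxel_size[ax]
                for ax in range(3)
            ]
        )

    def contains_point(self, point) -> bool:
        """True if ``point`` (cm) falls inside a body voxel."""
        idx = np.round(
            (np.asarray(point, dtype=float) - self.origin) / self.voxel_size
        ).astype(int)
        if np.any(idx < 0) or np.any(idx >= self.shape):
            return False
        return bool(self.body_mask[tuple(idx)])


def _ellipsoid_mask(spec_shape, voxel_size, center_cm, semi_axes_cm) -> np.ndarray:
    grids = np.ogrid[[slice(0, n) for n in spec_shape]]
    r2 = sum(
        ((g * voxel_size[ax] - center_cm[ax]) / semi_axes_cm[ax]) ** 2
        for ax, g in enumerate(grids)
    )
    return r2 <= 1.0


def generate_phantom(spec: PhantomSpec, seed: int = 0) -> Phantom:
    """Build a phantom from a :class:`PhantomSpec`, deterministically in ``seed``.

    The body is a water-equivalent ellipsoid (HU 0) centred in the grid,
    air (-1000 HU) outside, with optional lung/bone ellipsoidal inserts.
    The body mask is HU > -400.
    """
    shape = tuple(int(n) for n in spec.shape)
    if any(n < 16 for n in shape):
        raise InvalidSpecError(f"grid shape must be >= 16 per axis, got {shape}")
    vox = spec.voxel_size
    center = np.array([(n - 1) / 2 * v for n, v in zip(shape, vox)])
    half_extent = np.array([(n - 1) / 2 * v for n, v in zip(shape, vox)])
    if np.any(np.asarray(spec.semi_axes) > half_extent + 1e-9):
        raise InvalidSpecError(
            f"body ellipsoid semi-axes {spec.semi_axes} exceed grid half-extent "
            f"{tuple(half_extent)}"
        )

    rng = np.random.default_rng(seed)
    hu = np.full(shape, HU_AIR, dtype=np.float32)
    body = _ellipsoid_mask(shape, vox, center, spec.semi_axes)
    hu[body] = 0.0
    for ins in spec.inserts:
        ins_center = center + np.asarray(ins.center)
        if np.any(np.abs(ins.center) + np.asarray(ins.semi_axes) > np.asarray(spec.semi_axes)):
            raise InvalidSpecError(f"insert {ins.kind} extends outside the body")
        mask = _ellipsoid_mask(shape, vox, ins_center, ins.semi_axes)
        hu[mask & body] = INSERT_HU[ins.kind]
    if spec.hu_noise_sd > 0:
        hu[body] += rng.normal(0.0, spec.hu_noise_sd, int(body.sum())).astype(np.float32)
    body_mask = hu > HU_BODY_THRESHOLD
    return Phantom(hu=hu, voxel_size=vox, origin=(0.0, 0.0, 0.0), body_mask=body_mask)


def hu_to_density(hu: np.ndarray) -> np.ndarray:
    """Linear HU -> mass density map: -1000 HU -> 0, 0 HU -> 1 g/cm^3."""
    return np.maximum((np.asarray(hu, dtype=np.float64) + 1000.0) / 1000.0, 0.0)


def radiological_depth(
    phantom: Phantom,
    source,
    target_voxel: tuple[int, int, int],
    step_fraction: float = 0.5,
) -> float:
    """Density-weighted path length (g/cm^2) from ``source`` to a voxel centre.

    Marches the ray in steps no longer than ``step_fraction`` times the
    smallest voxel dimension, sampling density (trilinear) at step midpoints.
    Positions outside the grid contribute zero density.
    """
    source = np.asarray(source, dtype=float)
    target = np.array(
        [
            phantom.origin[ax] + target_voxel[ax] * phantom.voxel_size[ax]
            for ax in range(3)
        ]
    )
    if np.any(np.asarray(target_voxel) < 0) or np.any(
        np.asarray(target_voxel) >= phantom.shape
    ):
        raise ValueError(f"target voxel {target_voxel} outside grid {phantom.shape}")
    if phantom.contains_point(source):
        raise ValueError("ray source must lie outside the body")
    length = float(np.linalg.norm(target - source))
    if length == 0.0:
        raise ValueError("degenerate ray of zero length")
    step = step_fraction * min(phantom.voxel_size)
    n_steps = max(1, int(np.ceil(length / step)))
    t_mid = (np.arange(n_steps) + 0.5) / n_steps
    points = source[None, :] + t_mid[:, None] * (target - source)[None, :]
    coords = (points - np.asarray(phantom.origin)) / np.asarray(phantom.voxel_size)
    density = hu_to_density(phantom.hu)
    rho = map_coordinates(density, coords.T, order=1, mode="constant", cval=0.0)
    return float(rho.sum() * length / n_steps)
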