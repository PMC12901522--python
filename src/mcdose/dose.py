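"""Analytic arc-dose engine.

A deliberately simple, deterministic photon-dose model that produces
arc-like dose morphology on a phantom: for each control point the dose is
the rotated rectangular aperture indicator convolved with an isotropic
Gaussian penumbra, attenuated exponentially with radiological depth and by
the inverse-square distance law, summed over control points with MU
weights and normalized to Gy per MU.  It replaces a Monte Carlo transport
engine as the source of *clean* (noise-free) dose distributions; the MC
noise itself is modelled separately (:mod:`mcdose.noise`).

Physics constants (attenuation per energy, penumbra widths) are plausible
monotone trends, not commissioning data; their magnitudes are irrelevant
to denoising correctness.
"""

from __future__ import annotations

import numpy as np
from scipy.ndimage import rotate as nd_rotate
from scipy.special import erf

from .phantoms import Phantom, hu_to_density
from .plans import ArcPlan, ControlPoint
from .volumes import Volume

__all__ = ["compute_clean_dose", "MU_PER_ENERGY", "SIGMA_PER_ENERGY", "DOSE_PER_MU"]

#: Effective linear attenuation coefficients (cm^2/g), decreasing with energy.
MU_PER_ENERGY = {6: 0.050, 10: 0.045, 15: 0.040}
#: Penumbra Gaussian sigma (cm), increasing with energy.
SIGMA_PER_ENERGY = {6: 0.4, 10: 0.5, 15: 0.6}
#: Nominal output calibration: dose (Gy) per MU at the reference point.
DOSE_PER_MU = 0.01


def _parallel_radiological_depth(
    density: np.ndarray, voxel_size, gantry_angle: float
) -> np.ndarray:
    """Water-equivalent depth (g/cm^2) along the beam for every voxel.

    Parallel-beam approximation: the density grid is rotated about z so the
    beam runs along +y, the cumulative density is integrated along y, and
    the result rotated back.  Depth at a voxel excludes half of the voxel's
    own contribution (midpoint convention).
    """
    rotated = nd_rotate(
        density,
        -gantry_angle,
        axes=(0, 1),
        reshape=False,
        order=1,
        mode="constant",
        cval=0.0,
    )
    depth = (np.cumsum(rotated, axis=1) - 0.5 * rotated) * voxel_size[1]
    return nd_rotate(
        depth,
        gantry_angle,
        axes=(0, 1),
        reshape=False,
        order=1,
        mode="constant",
        cval=0.0,
    )


def _soft_aperture(t: np.ndarray, halfwidth: float, sigma: float) -> np.ndarray:
    """1D rectangular indicator of halfwidth ``halfwidth`` convolved with a Gaussian."""
    s = sigma * np.sqrt(2.0)
    return 0.5 * (erf((halfwidth - t) / s) + erf((halfwidth + t) / s))


def _control_point_dose(
    phantom: Phantom,
    plan: ArcPlan,
    cp: ControlPoint,
    density: np.ndarray,
    coords: tuple[np.ndarray, np.ndarray, np.ndarray],
) -> np.ndarray:
    g = np.deg2rad(cp.gantry_angle)
    # beam direction (source -> isocenter) and transverse basis; z is the
    # rotation axis, so the beam lies in the xy plane
    e_beam = np.array([-np.sin(g), np.cos(g), 0.0])
    e_u = np.array([np.cos(g), np.sin(g), 0.0])
    iso = np.asarray(plan.isocenter)

    x, y, z = coords
    rx = x[:, None, None] - iso[0]
    ry = y[None, :, None] - iso[1]
    rz = z[None, None, :] - iso[2]

    zeta = rx * e_beam[0] + ry * e_beam[1]  # depth past the isocenter plane
    u = rx * e_u[0] + ry * e_u[1]
    w = rz  # broadcasts against the xy-plane arrays

    # project transverse coordinates onto the isocenter plane (beam divergence)
    proj = plan.sad / (plan.sad + zeta)
    u_iso = u * proj
    w_iso = w * proj

    theta = np.deg2rad(cp.collimator_rotation)
    u_c = u_iso * np.cos(theta) + w_iso * np.sin(theta)
    w_c = -u_iso * np.sin(theta) + w_iso * np.cos(theta)

    sigma = SIGMA_PER_ENERGY[cp.energy]
    transmission = _soft_aperture(u_c, cp.aperture_halfwidth_x, sigma) * _soft_aperture(
        w_c, cp.aperture_halfwidth_y, sigma
    )

    depth = _parallel_radiological_depth(density, phantom.voxel_size, cp.gantry_angle)
    attenuation = np.exp(-MU_PER_ENERGY[cp.energy] * depth)
    inverse_square = proj**2
    return transmission * attenuation * inverse_square


def compute_clean_dose(phantom: Phantom, plan: ArcPlan) -> Volume:
    """Deterministic arc dose in Gy/MU on the phantom grid.

    Sums the per-control-point model weighted by MU fraction; the result is
    exactly zero outside the body mask and non-negative everywhere.
    Raises if the isocenter is not inside the body.
    """
    if not phantom.contains_point(plan.isocenter):
        raise ValueError(f"isocenter {plan.isocenter} is outside the body")
    density = hu_to_density(phantom.hu)
    coords = phantom.voxel_centers()
    total_mu = plan.total_mu
    dose = np.zeros(phantom.shape, dtype=np.float64)
    for cp in plan.control_points:
        if cp.mu_weight == 0:
            continue
        dose += (cp.mu_weight / total_mu) * _control_point_dose(
            phantom, plan, cp, density, coords
        )
    dose *= DOSE_PER_MU
    dose[~phantom.body_mask] = 0.0
    np.maximum(dose, 0.0, out=dose)
    return Volume(dose.astype(np.float32), phantom.voxel_size, phantom.origin)
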