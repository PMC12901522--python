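"""Full-volume and whole-plan denoising.

The network sees fixed-size inputs (xy footprint x z patch).  A volume is
scaled to the network's input range, centrally cropped or zero-padded in
xy, covered by the minimal number of z patches (equalized overlaps, first
patch at 0 and last flush with the top), denoised patch by patch, and
reassembled by unweighted averaging of overlapping voxels; the result is
placed back in the original frame, unscaled, clipped at zero and masked
to the body.

The applied scale factors are the calibrated constants snapped to the
nearest power of two, which makes scaling/unscaling lossless in floating
point: with an identity network the whole chain reproduces the input
bit-exactly on body voxels (the assembly contract the tests pin down).
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .volumes import ScaleConstants, Volume, crop_or_pad_xy, restore_xy

__all__ = [
    "PatchLayout",
    "plan_patches",
    "denoise_volume",
    "denoise_plan",
    "IdentityNet",
]


@dataclasses.dataclass(frozen=True)
class PatchLayout:
    """Sorted z-corners of the patches covering an extent."""

    corners: tuple[int, ...]
    patch_z: int
    z_extent: int

    @property
    def overlaps(self) -> tuple[int, ...]:
        """Overlap (voxels) at each junction between consecutive patches."""
        return tuple(
            self.corners[i] + self.patch_z - self.corners[i + 1]
            for i in range(len(self.corners) - 1)
        )


def plan_patches(z_extent: int, patch_z: int) -> PatchLayout:
    """Minimal-count equalized placement of z patches.

    A volume not exceeding the patch size gets a single patch at 0 (the
    volume is zero-padded up to the patch); otherwise
    ``ceil(z_extent / patch_z)`` patches are placed with the first at 0,
    the last at ``z_extent - patch_z`` and the rest spaced as evenly as
    integer corners allow, so every z index is covered at least once.
    """
    if patch_z < 1:
        raise ValueError("patch_z must be >= 1")
    if z_extent <= patch_z:
        return PatchLayout(corners=(0,), patch_z=patch_z, z_extent=z_extent)
    n = -(-z_extent // patch_z)  # ceil
    span = z_extent - patch_z
    corners = tuple(round(i * span / (n - 1)) for i in range(n))
    return PatchLayout(corners=corners, patch_z=patch_z, z_extent=z_extent)


class IdentityNet:
    """Diagnostic stand-in network returning its first input channel.

    Used to validate that the complete pre/post-processing chain
    (scale, crop/pad, patch, aggregate, restore, unscale, mask) is an
    exact round trip.
    """

    def __init__(self, xy_size: int = 192, patch_z: int = 64, in_channels: int = 2):
        self.config = dataclasses.make_dataclass(
            "IdentityConfig", ["in_channels", "xy_size", "z_size"]
        )(in_channels, xy_size, patch_z)

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        return x[:, :1]

    __call__ = forward


def denoise_volume(
    network,
    noisy: Volume,
    ct: Volume,
    scales: ScaleConstants,
    body_mask: np.ndarray | None = None,
) -> Volume:
    """Denoise one dose volume with its CT companion channel.

    The noisy dose and CT must share a grid.  ``body_mask`` defaults to
    the CT-derived body (HU > -400); the output is zero outside it and
    clipped to be non-negative.
    """
    from .volumes import HU_BODY_THRESHOLD

    if noisy.values.shape != ct.values.shape:
        raise ValueError(
            f"dose grid {noisy.values.shape} and CT grid {ct.values.shape} differ"
        )
    if not noisy.same_grid(ct):
        raise ValueError("dose and CT geometry differ")
    if body_mask is None:
        body_mask = np.asarray(ct.values) > HU_BODY_THRESHOLD
    cfg = network.config
    xy_size, patch_z = cfg.xy_size, cfg.z_size
    use_ct = cfg.in_channels == 2
    applied = scales.pow2()

    dose_scaled = Volume(
        np.asarray(noisy.values) / np.asarray(noisy.values).dtype.type(applied.dose_scale),
        noisy.voxel_size,
        noisy.origin,
    )
    dose_xy, placement = crop_or_pad_xy(dose_scaled, xy_size)
    if use_ct:
        ct_vals = np.asarray(ct.values, dtype=dose_xy.values.dtype)
        ct_scaled = Volume(
            (ct_vals + 1000.0) / ct_vals.dtype.type(applied.ct_scale),
            ct.voxel_size,
            ct.origin,
        )
        ct_xy, _ = crop_or_pad_xy(ct_scaled, xy_size)

    nz = dose_xy.values.shape[2]
    layout = plan_patches(nz, patch_z)
    pad_z = max(0, patch_z - nz)
    dvals = np.pad(dose_xy.values, ((0, 0), (0, 0), (0, pad_z)))
    if use_ct:
        cvals = np.pad(ct_xy.values, ((0, 0), (0, 0), (0, pad_z)))

    accum = np.zeros_like(dvals, dtype=np.float64)
    count = np.zeros(dvals.shape[2], dtype=np.int64)
    for corner in layout.corners:
        sl = slice(corner, corner + patch_z)
        channels = [dvals[:, :, sl]] + ([cvals[:, :, sl]] if use_ct else [])
        x = np.stack(channels)[None].astype(np.float32)
        y = network.forward(x, training=False)[0, 0]
        accum[:, :, sl] += y
        count[sl] += 1
    # unweighted mean over the patches covering each voxel
    out = (accum / count[None, None, :]).astype(dvals.dtype)
    out = out[:, :, :nz]

    restored = restore_xy(out, placement)
    restored = restored * restored.dtype.type(applied.dose_scale)
    restored[~body_mask] = 0
    np.maximum(restored, 0, out=restored)
    return Volume(restored.astype(noisy.values.dtype), noisy.voxel_size, noisy.origin)


def denoise_plan(
    network,
    field_doses: list[Volume],
    ct: Volume,
    scales: ScaleConstants,
    body_mask: np.ndarray | None = None,
) -> Volume:
    """Denoise a whole plan: per-field noisy doses are summed, then the
    plan dose is denoised in a single pass."""
    if not field_doses:
        raise ValueError("empty field list")
    first = field_doses[0]
    total = np.zeros_like(np.asarray(first.values), dtype=np.float64)
    for f in field_doses:
        if not f.same_grid(ct):
            raise ValueError("field dose not on the CT grid")
        total += f.values
    plan_dose = Volume(
        total.astype(first.values.dtype), first.voxel_size, first.origin
    )
    return denoise_volume(network, plan_dose, ct, scales, body_mask)
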