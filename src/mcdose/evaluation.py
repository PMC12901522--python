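"""Dosimetric evaluation: gamma analysis, masked RMSE, ISNR, DVH metrics.

The gamma index combines a dose-difference criterion (percent of the
global normalization dose, i.e. the maximum of the reference
distribution) with a distance-to-agreement criterion (mm): for a
reference point r the index is

    gamma(r) = min over r' of sqrt( |r - r'|^2 / dta^2
                                    + (D_eval(r') - D_ref(r))^2 / dD^2 )

where the minimum runs over evaluated-dose positions within a search
radius, with the evaluated dose interpolated trilinearly on a fine grid
(a tenth of the distance criterion per step).  A voxel passes when
gamma <= 1.  Only reference voxels at or above the low-dose threshold
(10% of the reference maximum by default) are evaluated, and the passing
rate is reported over those voxels.

The remaining metrics follow common radiotherapy reporting conventions:
RMSE over voxels above 10% of the reference maximum, its translation to a
whole treatment course, the improved signal-to-noise ratio (ISNR, the
decibel ratio of the noisy input's MSE to the denoised output's MSE
against the reference) and cumulative dose-volume histograms with Dx%,
Vx% and mean-dose readouts.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np

from .volumes import Volume

__all__ = [
    "GammaCriteria",
    "GammaResult",
    "gamma_map",
    "rmse_masked",
    "whole_treatment_rmse",
    "isnr",
    "UnboundedImprovementError",
    "DVHCurve",
    "dvh",
    "dose_at_volume",
    "volume_at_dose",
    "mean_dose",
]

#: Numerical slack on the gamma <= 1 pass decision, so that analytically
#: exact boundary cases (dose offset equal to the criterion) pass.
PASS_EPS = 1e-9


@dataclasses.dataclass(frozen=True)
class GammaCriteria:
    """Gamma-analysis parameters.

    ``dose_percent`` is global: the dose criterion is that percentage of
    the maximum reference dose.  ``search_factor`` bounds the
    distance-to-agreement search at that multiple of the distance
    criterion; ``interp_fraction`` subdivides the distance criterion to
    set the interpolation step.

    ``gamma_max`` optionally clamps reported gamma values.  Because a
    passing voxel's optimum always lies within one distance criterion of
    the reference point, any cap >= 1 leaves the pass/fail decision of
    every voxel exact while letting the search stop early on grossly
    failing voxels; None searches the full radius.
    """

    dose_percent: float = 2.0
    distance_mm: float = 2.0
    low_dose_fraction: float = 0.10
    search_factor: float = 3.0
    interp_fraction: int = 10
    gamma_max: float | None = None

    def __post_init__(self) -> None:
        if min(self.dose_percent, self.distance_mm) <= 0:
            raise ValueError("criteria must be positive")
        if self.search_factor < 1.0:
            raise ValueError("search radius must cover the distance criterion")
        if self.gamma_max is not None and self.gamma_max < 1.0:
            raise ValueError("gamma_max below 1 would corrupt pass decisions")

    @property
    def search_radius_mm(self) -> float:
        return self.search_factor * self.distance_mm

    @property
    def interp_step_mm(self) -> float:
        return self.distance_mm / self.interp_fraction


@dataclasses.dataclass
class GammaResult:
    """Per-voxel gamma map (NaN below the dose threshold) and pass rate (%)."""

    gamma: np.ndarray
    pass_rate: float
    criteria: GammaCriteria
    n_evaluated: int


def _upsample_axis_linear(values: np.ndarray, axis: int, f: int) -> np.ndarray:
    """Linear upsampling along one axis to (n-1)*f + 1 samples."""
    if f == 1:
        return values
    n = values.shape[axis]
    out_shape = list(values.shape)
    out_shape[axis] = (n - 1) * f + 1
    out = np.empty(out_shape, dtype=np.float64)
    lo = [slice(None)] * values.ndim
    hi = [slice(None)] * values.ndim
    dst = [slice(None)] * values.ndim
    lo[axis], hi[axis] = slice(0, n - 1), slice(1, n)
    a, b = values[tuple(lo)], values[tuple(hi)]
    for s in range(f):
        w = s / f
        dst[axis] = slice(s, (n - 1) * f, f)
        out[tuple(dst)] = (1.0 - w) * a + w * b if s else a
    dst[axis] = slice((n - 1) * f, None)
    lo[axis] = slice(n - 1, n)
    out[tuple(dst)] = values[tuple(lo)]
    return out


def _fine_grid(values: np.ndarray, factors: tuple[int, int, int]) -> np.ndarray:
    """Trilinearly upsample so voxel centres land on a lattice with
    ``factors`` subdivisions per voxel; original centres stay on-lattice."""
    out = np.asarray(values, dtype=np.float64)
    for ax, f in enumerate(factors):
        out = _upsample_axis_linear(out, ax, f)
    return out


def gamma_map(
    reference: Volume, evaluated: Volume, criteria: GammaCriteria | None = None
) -> GammaResult:
    """Global gamma analysis of ``evaluated`` against ``reference``.

    Both volumes must share a grid and the reference maximum must be
    positive.  The search is reference-point-centred: for each reference
    voxel at or above the low-dose threshold, candidate evaluated-dose
    positions on the interpolated fine lattice are visited in order of
    increasing distance, with an early exit once the pure distance term
    exceeds the current worst still-improvable gamma.
    """
    criteria = criteria or GammaCriteria()
    if reference.values.shape != evaluated.values.shape:
        raise ValueError("reference and evaluated grids differ")
    ref = np.asarray(reference.values, dtype=np.float64)
    ev = np.asarray(evaluated.values, dtype=np.float64)
    peak = ref.max()
    if peak <= 0:
        raise ValueError("all-zero reference distribution")

    dd = criteria.dose_percent / 100.0 * peak  # Gy
    dta = criteria.distance_mm
    vox_mm = tuple(10.0 * v for v in reference.voxel_size)
    factors = tuple(
        max(1, math.ceil(v / criteria.interp_step_mm)) for v in vox_mm
    )
    step_mm = tuple(v / f for v, f in zip(vox_mm, factors))
    fine = _fine_grid(ev, factors)

    threshold = criteria.low_dose_fraction * peak
    active = ref >= threshold
    n_eval = int(active.sum())
    ref_active = ref[active]

    # candidate offsets on the fine lattice, sorted by physical distance
    max_off = tuple(int(criteria.search_radius_mm // s) for s in step_mm)
    grids = np.meshgrid(
        *[np.arange(-m, m + 1) for m in max_off], indexing="ij", sparse=False
    )
    off_arr = np.stack([g.ravel() for g in grids], axis=1)
    d2_arr = np.sum((off_arr * np.asarray(step_mm)) ** 2, axis=1)
    keep = d2_arr <= criteria.search_radius_mm**2 + 1e-12
    off_arr, d2_arr = off_arr[keep], d2_arr[keep]
    order = np.argsort(d2_arr, kind="stable")
    off_arr, d2_arr = off_arr[order], d2_arr[order]
    offs = list(zip(d2_arr.tolist(), off_arr.tolist()))

    shape = ref.shape
    active_idx = [idx * f for idx, f in zip(np.nonzero(active), factors)]
    fine_max = [(shape[ax] - 1) * factors[ax] for ax in range(3)]
    best = np.full(ref_active.shape, np.inf)

    # visit offsets in distance-ordered bands, each evaluated as one
    # vectorized (voxels x offsets) block; a voxel whose best gamma^2 is
    # already below a band's minimum pure distance term is finalized (no
    # later offset can improve it) and leaves the search
    block_elems = 2_000_000
    cap_sq = np.inf if criteria.gamma_max is None else criteria.gamma_max**2
    remaining = np.arange(ref_active.size)
    band_start = 0
    n_offs = len(d2_arr)
    while band_start < n_offs and remaining.size:
        min_dist_term = d2_arr[band_start] / dta**2
        if min_dist_term >= cap_sq:
            break  # no offset this far out can push a voxel below the cap
        undecided = best[remaining] > min_dist_term
        remaining = remaining[undecided]
        if not remaining.size:
            break
        band_size = max(64, block_elems // remaining.size)
        band_end = min(n_offs, band_start + band_size)
        band = off_arr[band_start:band_end]
        band_dist = d2_arr[band_start:band_end] / dta**2
        idx = [a[remaining] for a in active_idx]
        pos = [idx[ax][:, None] + band[None, :, ax] for ax in range(3)]
        valid = np.ones(pos[0].shape, dtype=bool)
        for ax in range(3):
            valid &= (pos[ax] >= 0) & (pos[ax] <= fine_max[ax])
            np.clip(pos[ax], 0, fine_max[ax], out=pos[ax])
        dvals = fine[tuple(pos)]
        g2 = band_dist[None, :] + (dvals - ref_active[remaining, None]) ** 2 / dd**2
        g2[~valid] = np.inf
        np.minimum(best[remaining], g2.min(axis=1), out=g2[:, 0])
        best[remaining] = g2[:, 0]
        band_start = band_end

    gamma_active = np.sqrt(best)
    if criteria.gamma_max is not None:
        np.minimum(gamma_active, criteria.gamma_max, out=gamma_active)
    gamma = np.full(shape, np.nan)
    gamma[active] = gamma_active
    pass_rate = float(np.mean(gamma_active <= 1.0 + PASS_EPS) * 100.0)
    return GammaResult(
        gamma=gamma, pass_rate=pass_rate, criteria=criteria, n_evaluated=n_eval
    )


def rmse_masked(
    reference: Volume, evaluated: Volume, threshold_fraction: float = 0.10
) -> float:
    """RMSE (Gy/MU) over voxels with reference dose above the threshold."""
    if reference.values.shape != evaluated.values.shape:
        raise ValueError("grids differ")
    ref = np.asarray(reference.values, dtype=np.float64)
    peak = ref.max()
    if peak <= 0:
        raise ValueError("all-zero reference")
    mask = ref > threshold_fraction * peak
    if not mask.any():
        raise ValueError("empty evaluation mask")
    diff = np.asarray(evaluated.values, dtype=np.float64)[mask] - ref[mask]
    return float(np.sqrt(np.mean(diff * diff)))


def whole_treatment_rmse(
    rmse_per_mu: float,
    mu_per_fraction: float,
    prescription: float,
    fraction_dose: float,
) -> float:
    """Translate a per-MU RMSE (Gy/MU) to a whole treatment course (Gy).

    The per-fraction error is ``rmse_per_mu * mu_per_fraction``; over
    ``prescription / fraction_dose`` fractions the error scales linearly
    (the error of the single calculated dose distribution is delivered
    identically every fraction).
    """
    if min(rmse_per_mu, mu_per_fraction, prescription) < 0 or fraction_dose <= 0:
        raise ValueError("inputs must be positive (fraction dose strictly)")
    n_fractions = prescription / fraction_dose
    return rmse_per_mu * mu_per_fraction * n_fractions


class UnboundedImprovementError(ArithmeticError):
    """The denoised distribution matches the reference exactly: the
    MSE-ratio ISNR is unbounded."""


def isnr(
    noisy: Volume,
    denoised: Volume,
    reference: Volume,
    mask: np.ndarray | None = None,
) -> float:
    """Improved signal-to-noise ratio in dB.

    ``10 * log10(MSE(noisy, reference) / MSE(denoised, reference))`` over
    the masked voxels; positive values mean denoising moved the
    distribution closer to the reference.
    """
    for v in (denoised, reference):
        if v.values.shape != noisy.values.shape:
            raise ValueError("grids differ")
    if mask is None:
        mask = np.ones(noisy.values.shape, dtype=bool)
    ref = np.asarray(reference.values, dtype=np.float64)[mask]
    mse_noisy = float(np.mean((np.asarray(noisy.values, dtype=np.float64)[mask] - ref) ** 2))
    mse_denoised = float(
        np.mean((np.asarray(denoised.values, dtype=np.float64)[mask] - ref) ** 2)
    )
    if mse_denoised == 0.0:
        raise UnboundedImprovementError(
            "denoised distribution equals the reference on the mask"
        )
    return float(10.0 * np.log10(mse_noisy / mse_denoised))


@dataclasses.dataclass
class DVHCurve:
    """Cumulative dose-volume histogram of one structure."""

    bin_edges: np.ndarray  # Gy, ascending from 0
    volume_percent: np.ndarray  # % of structure with dose >= edge
    structure: str = ""

    def __post_init__(self) -> None:
        if np.any(np.diff(self.volume_percent) > 1e-12):
            raise ValueError("cumulative DVH must be non-increasing")


def dvh(
    dose: Volume,
    structure_mask: np.ndarray,
    bin_width: float = 0.01,
    structure: str = "",
) -> DVHCurve:
    """Cumulative DVH: V(d) = % of structure voxels with dose >= d.

    Edges run from 0 to one bin beyond the maximum structure dose, so the
    curve starts at 100% and ends at 0%.
    """
    mask = np.asarray(structure_mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty structure")
    doses = np.asarray(dose.values, dtype=np.float64)[mask]
    top = doses.max()
    n_bins = int(math.floor(top / bin_width)) + 2
    edges = np.arange(n_bins) * bin_width
    volume = (doses[None, :] >= edges[:, None] - 1e-12).mean(axis=1) * 100.0
    return DVHCurve(bin_edges=edges, volume_percent=volume, structure=structure)


def dose_at_volume(curve: DVHCurve, volume_percent: float) -> float:
    """Dx%: the largest dose received by at least x% of the structure.

    Linear interpolation between bin edges, clamped to the curve range.
    """
    if not 0 < volume_percent <= 100:
        raise ValueError("volume percent must be in (0, 100]")
    v = curve.volume_percent
    d = curve.bin_edges
    if volume_percent <= v[-1]:
        return float(d[-1])
    # walk from the high-dose end to the first edge meeting the volume level
    idx = np.nonzero(v >= volume_percent)[0]
    i = idx[-1]
    if i + 1 >= len(v) or v[i] == v[i + 1]:
        return float(d[i])
    frac = (v[i] - volume_percent) / (v[i] - v[i + 1])
    dose = d[i] + frac * (d[i + 1] - d[i])
    return float(min(dose, d[-2] if len(d) > 1 else d[-1]))


def volume_at_dose(
    dose: Volume, structure_mask: np.ndarray, dose_level: float
) -> float:
    """Vx: % of the structure receiving at least ``dose_level`` Gy."""
    mask = np.asarray(structure_mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty structure")
    doses = np.asarray(dose.values, dtype=np.float64)[mask]
    return float(np.mean(doses >= dose_level - 1e-12) * 100.0)


def mean_dose(dose: Volume, structure_mask: np.ndarray) -> float:
    """Dm: arithmetic mean dose over the structure."""
    mask = np.asarray(structure_mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty structure")
    return float(np.asarray(dose.values, dtype=np.float64)[mask].mean())
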