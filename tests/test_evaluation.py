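import numpy as np
import pytest
from scipy.interpolate import RegularGridInterpolator

from mcdose.evaluation import (
    DVHCurve,
    GammaCriteria,
    UnboundedImprovementError,
    dose_at_volume,
    dvh,
    gamma_map,
    isnr,
    mean_dose,
    rmse_masked,
    volume_at_dose,
    whole_treatment_rmse,
)
from mcdose.volumes import Volume


def gamma_oracle(reference: Volume, evaluated: Volume, criteria: GammaCriteria):
    """Exhaustive-search gamma, implemented independently of the optimized
    path: dense offset grid per reference voxel, trilinear interpolation via
    RegularGridInterpolator, direct minimisation (no pruning, no shells).

    The only shortcut is the mathematically safe per-voxel radius bound
    min-gamma <= gamma at zero offset."""
    ref = np.asarray(reference.values, dtype=np.float64)
    ev = np.asarray(evaluated.values, dtype=np.float64)
    peak = ref.max()
    dd = criteria.dose_percent / 100.0 * peak
    dta = criteria.distance_mm
    vox_mm = np.asarray(reference.voxel_size) * 10.0
    axes = [np.arange(n) * v for n, v in zip(ref.shape, vox_mm)]
    interp = RegularGridInterpolator(axes, ev, method="linear",
                                     bounds_error=False, fill_value=None)
    step = criteria.interp_step_mm
    offsets_1d = [
        np.arange(-criteria.search_radius_mm, criteria.search_radius_mm + step / 2,
                  step)
        for _ in range(3)
    ]
    og = np.meshgrid(*offsets_1d, indexing="ij")
    offsets = np.stack([g.ravel() for g in og], axis=1)
    dist2 = np.sum(offsets**2, axis=1)
    inside_sphere = dist2 <= criteria.search_radius_mm**2 + 1e-12
    offsets, dist2 = offsets[inside_sphere], dist2[inside_sphere]

    gamma = np.full(ref.shape, np.nan)
    active = ref >= criteria.low_dose_fraction * peak
    extent = np.array([a[-1] for a in axes])
    for idx in np.argwhere(active):
        pos = idx * vox_mm
        g0 = abs(ev[tuple(idx)] - ref[tuple(idx)]) / dd
        radius2 = min((g0 * dta) ** 2, criteria.search_radius_mm**2)
        use = dist2 <= radius2 + 1e-12
        pts = pos + offsets[use]
        ok = np.all((pts >= -1e-9) & (pts <= extent + 1e-9), axis=1)
        vals = interp(pts[ok])
        g2 = dist2[use][ok] / dta**2 + (vals - ref[tuple(idx)]) ** 2 / dd**2
        gamma[tuple(idx)] = np.sqrt(min(g2.min(initial=np.inf), g0**2))
    rate = float(np.mean(gamma[active] <= 1.0 + 1e-9) * 100.0)
    return gamma, rate


class TestGammaMap:
    def test_identity_pair(self, rng):
        ref = Volume(rng.uniform(0.2, 1.0, (12, 12, 12)), (0.2, 0.2, 0.2))
        result = gamma_map(ref, ref)
        assert np.nanmax(result.gamma) == 0.0
        assert result.pass_rate == 100.0

    def test_uniform_two_percent_boundary(self):
        """A uniform +2% dose offset sits exactly on the 2%/2mm boundary."""
        ref = Volume(np.full((8, 8, 8), 2.0), (0.2, 0.2, 0.2))
        ev = Volume(ref.values * 1.02, (0.2, 0.2, 0.2))
        result = gamma_map(ref, ev, GammaCriteria(2.0, 2.0))
        assert np.nanmax(result.gamma) == pytest.approx(1.0, abs=1e-9)
        assert result.pass_rate == 100.0

    def test_spatial_shift_equal_to_dta_passes(self):
        base = np.zeros((20, 20, 8))
        base[6:14, 6:14, :] = 1.0
        ref = Volume(base, (0.2, 0.2, 0.2))
        shifted = Volume(np.roll(base, 1, axis=0), (0.2, 0.2, 0.2))
        result = gamma_map(ref, shifted, GammaCriteria(2.0, 2.0))
        assert result.pass_rate == 100.0

    def test_matches_exhaustive_oracle(self, rng):
        """Optimized gamma equals the independent exhaustive search within
        0.01 on random noisy pairs."""
        for trial in range(2):
            ref = Volume(rng.uniform(0.2, 1.0, (9, 9, 7)), (0.2, 0.2, 0.2))
            ev = Volume(
                ref.values * (1 + rng.normal(0, 0.04, ref.values.shape)),
                (0.2, 0.2, 0.2),
            )
            crit = GammaCriteria(2.0, 2.0)
            result = gamma_map(ref, ev, crit)
            oracle_gamma, oracle_rate = gamma_oracle(ref, ev, crit)
            active = ~np.isnan(oracle_gamma)
            assert np.nanmax(np.abs(result.gamma[active] - oracle_gamma[active])) < 0.01
            assert result.pass_rate == pytest.approx(oracle_rate, abs=0.5)

    def test_criteria_monotonicity(self, rng):
        """Gamma-2 never passes more voxels than gamma-3."""
        for _ in range(5):
            ref = Volume(rng.uniform(0.2, 1.0, (12, 12, 10)), (0.2, 0.2, 0.2))
            ev = Volume(
                ref.values * (1 + rng.normal(0, 0.05, ref.values.shape)),
                (0.2, 0.2, 0.2),
            )
            g2 = gamma_map(ref, ev, GammaCriteria(2.0, 2.0)).pass_rate
            g3 = gamma_map(ref, ev, GammaCriteria(3.0, 3.0)).pass_rate
            assert g2 <= g3 + 1e-9

    def test_all_zero_reference_rejected(self):
        zero = Volume(np.zeros((8, 8, 8)), (0.2, 0.2, 0.2))
        with pytest.raises(ValueError):
            gamma_map(zero, zero)


class TestRmse:
    def test_identical_volumes(self, rng):
        v = Volume(rng.uniform(0, 1, (8, 8, 8)))
        assert rmse_masked(v, v) == 0.0

    def test_constant_offset(self, rng):
        ref = Volume(rng.uniform(0.5, 1.0, (8, 8, 8)))
        ev = Volume(ref.values + 0.037)
        assert rmse_masked(ref, ev) == pytest.approx(0.037)

    def test_matches_naive_formula(self, rng):
        ref = Volume(rng.uniform(0, 1, (10, 10, 10)))
        ev = Volume(rng.uniform(0, 1, (10, 10, 10)))
        mask = ref.values > 0.1 * ref.values.max()
        naive = np.sqrt(
            np.sum((ev.values[mask] - ref.values[mask]) ** 2) / mask.sum()
        )
        assert rmse_masked(ref, ev) == pytest.approx(naive, rel=1e-12)


class TestWholeTreatmentRmse:
    def test_representative_arc(self):
        """1.19e-4 Gy/MU over a 300 MU arc and 25 fractions is 0.9 Gy."""
        value = whole_treatment_rmse(1.19e-4, 300.0, 50.0, 2.0)
        assert value == pytest.approx(0.8925)
        assert round(value, 1) == 0.9

    def test_zero_rmse(self):
        assert whole_treatment_rmse(0.0, 300.0, 50.0, 2.0) == 0.0

    def test_single_fraction(self):
        assert whole_treatment_rmse(2e-4, 150.0, 2.0, 2.0) == pytest.approx(0.03)

    def test_nonpositive_fraction_dose_rejected(self):
        with pytest.raises(ValueError):
            whole_treatment_rmse(1e-4, 300.0, 50.0, 0.0)


class TestIsnr:
    def test_no_improvement_is_zero_db(self, rng):
        ref = Volume(rng.uniform(0, 1, (8, 8, 8)))
        noisy = Volume(ref.values + rng.normal(0, 0.1, ref.values.shape))
        assert isnr(noisy, noisy, ref) == pytest.approx(0.0)

    @pytest.mark.parametrize("ratio,db", [(10.0, 10.0), (100.0, 20.0)])
    def test_mse_ratio_decibels(self, rng, ratio, db):
        ref = Volume(np.zeros((8, 8, 8)))
        e = rng.normal(0, 1, (8, 8, 8))
        noisy = Volume(np.sqrt(ratio) * e)
        den = Volume(e)
        assert isnr(noisy, den, ref) == pytest.approx(db)

    def test_perfect_denoising_signalled(self, rng):
        ref = Volume(rng.uniform(0, 1, (8, 8, 8)))
        noisy = Volume(ref.values + 0.1)
        with pytest.raises(UnboundedImprovementError):
            isnr(noisy, ref, ref)


class TestDvh:
    def test_uniform_dose_step_function(self):
        dose = Volume(np.full((10, 10, 10), 5.0))
        mask = np.ones((10, 10, 10), dtype=bool)
        curve = dvh(dose, mask, bin_width=0.1)
        assert curve.volume_percent[0] == 100.0
        assert curve.volume_percent[-1] == 0.0
        below = curve.bin_edges <= 5.0 + 1e-9
        assert np.all(curve.volume_percent[below] == 100.0)

    def test_linear_ramp_median(self, rng):
        vals = np.linspace(0, 10, 1000).reshape(10, 10, 10)
        curve = dvh(Volume(vals), np.ones_like(vals, dtype=bool), bin_width=0.05)
        mid = np.argmin(np.abs(curve.volume_percent - 50.0))
        assert curve.bin_edges[mid] == pytest.approx(5.0, abs=0.05)

    def test_v0_is_100(self, rng):
        vals = rng.uniform(0, 2, (8, 8, 8))
        curve = dvh(Volume(vals), np.ones_like(vals, dtype=bool))
        assert curve.volume_percent[0] == 100.0

    def test_curve_non_increasing(self, rng):
        vals = rng.uniform(0, 2, (8, 8, 8))
        curve = dvh(Volume(vals), np.ones_like(vals, dtype=bool))
        assert np.all(np.diff(curve.volume_percent) <= 1e-12)

    def test_empty_structure_rejected(self, rng):
        with pytest.raises(ValueError):
            dvh(Volume(np.ones((4, 4, 4))), np.zeros((4, 4, 4), dtype=bool))


class TestDoseVolumeMetrics:
    def test_uniform_dose_all_quantiles_equal(self):
        dose = Volume(np.full((8, 8, 8), 3.0))
        mask = np.ones((8, 8, 8), dtype=bool)
        curve = dvh(dose, mask)
        assert dose_at_volume(curve, 98.0) == pytest.approx(3.0, abs=0.01)
        assert dose_at_volume(curve, 2.0) == pytest.approx(3.0, abs=0.01)
        assert mean_dose(dose, mask) == pytest.approx(3.0)

    def test_ramp_d50_is_midpoint(self):
        vals = np.linspace(0, 10, 1000).reshape(10, 10, 10)
        curve = dvh(Volume(vals), np.ones_like(vals, dtype=bool))
        assert dose_at_volume(curve, 50.0) == pytest.approx(5.0, abs=0.02)

    def test_quantile_ordering(self, rng):
        vals = rng.gamma(3.0, 1.0, (10, 10, 10))
        curve = dvh(Volume(vals), np.ones_like(vals, dtype=bool))
        d98 = dose_at_volume(curve, 98.0)
        d50 = dose_at_volume(curve, 50.0)
        d2 = dose_at_volume(curve, 2.0)
        assert d98 <= d50 <= d2

    def test_volume_at_dose_consistent_with_curve(self, rng):
        vals = rng.uniform(0, 4, (10, 10, 10))
        mask = np.ones_like(vals, dtype=bool)
        vol = Volume(vals)
        curve = dvh(vol, mask, bin_width=0.01)
        for level in (0.5, 1.7, 3.2):
            i = int(round(level / 0.01))
            assert volume_at_dose(vol, mask, curve.bin_edges[i]) == pytest.approx(
                curve.volume_percent[i]
            )

    def test_out_of_range_percent_rejected(self, rng):
        curve = dvh(Volume(rng.uniform(0, 1, (4, 4, 4))),
                    np.ones((4, 4, 4), dtype=bool))
        with pytest.raises(ValueError):
            dose_at_volume(curve, 0.0)
        with pytest.raises(ValueError):
            dose_at_volume(curve, 120.0)
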