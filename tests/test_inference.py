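import numpy as np
import pytest

from mcdose.inference import IdentityNet, denoise_plan, denoise_volume, plan_patches
from mcdose.volumes import ScaleConstants, Volume


class TestPlanPatches:
    def test_exact_fit_single_patch(self):
        layout = plan_patches(64, 64)
        assert layout.corners == (0,)

    def test_small_volume_single_patch(self):
        assert plan_patches(16, 64).corners == (0,)

    def test_two_patch_equalized(self):
        layout = plan_patches(100, 64)
        assert layout.corners == (0, 36)
        assert layout.overlaps == (28,)

    @pytest.mark.parametrize("z_extent", list(range(1, 501, 7)))
    def test_full_coverage(self, z_extent):
        patch = 64
        layout = plan_patches(z_extent, patch)
        covered = np.zeros(max(z_extent, patch), dtype=int)
        for c in layout.corners:
            covered[c : c + patch] += 1
        assert np.all(covered[:z_extent] >= 1)
        assert layout.corners[0] == 0
        if z_extent > patch:
            assert layout.corners[-1] == z_extent - patch
            assert len(layout.corners) == -(-z_extent // patch)


def make_pair(rng, shape=(32, 32, 20), vox=(0.25, 0.25, 0.25)):
    """A float32 dose + CT pair with a central body region."""
    ct = np.full(shape, -1000.0, dtype=np.float32)
    ct[4:-4, 4:-4, 2:-2] = 0.0
    body = ct > -400.0
    dose = np.zeros(shape, dtype=np.float32)
    dose[body] = rng.uniform(0, 0.01, int(body.sum())).astype(np.float32)
    return Volume(dose, vox), Volume(ct, vox), body


SCALES = ScaleConstants(2000.0, 0.0125)


class TestDenoiseVolume:
    @pytest.mark.parametrize("z_extent", [16, 64, 100, 200])
    def test_identity_network_round_trip_bitexact(self, z_extent):
        """Scale -> pad -> patch -> aggregate -> restore -> unscale -> mask
        is the exact identity on body voxels for an identity network."""
        rng = np.random.default_rng(z_extent)
        noisy, ct, body = make_pair(rng, (32, 32, z_extent))
        net = IdentityNet(xy_size=48, patch_z=64)
        out = denoise_volume(net, noisy, ct, SCALES, body)
        assert np.array_equal(out.values[body], noisy.values[body])
        assert np.all(out.values[~body] == 0)

    def test_single_patch_equals_patched(self, rng):
        """For z <= patch the result is identical whether the layout is a
        single or a trivially-overlapping patch chain."""
        noisy, ct, body = make_pair(rng, (32, 32, 20))
        out_a = denoise_volume(IdentityNet(48, 64), noisy, ct, SCALES, body)
        out_b = denoise_volume(IdentityNet(48, 20), noisy, ct, SCALES, body)
        assert np.array_equal(out_a.values, out_b.values)

    def test_overlap_is_mean_of_patch_predictions(self, rng):
        """Overlapping voxels equal the arithmetic mean of the two patch
        outputs, checked against a brute-force assembly oracle."""

        class HalfNet:
            """A network whose output depends on absolute patch content."""

            def __init__(self):
                self.config = IdentityNet(32, 64).config
                self.config.xy_size = 32

            def forward(self, x, training=False):
                out = x[:, :1] * 0.5
                out[..., 0] += 1.0  # first slice marker breaks translation
                return out

            __call__ = forward

        rng2 = np.random.default_rng(0)
        noisy, ct, body = make_pair(rng2, (32, 32, 100))
        applied = SCALES.pow2()
        net = HalfNet()
        net.config.z_size = 64
        out = denoise_volume(net, noisy, ct, SCALES, body)

        # brute-force oracle: run the two patches directly and average
        scaled = noisy.values / np.float32(applied.dose_scale)
        ctv = (ct.values + 1000.0) / np.float32(applied.ct_scale)
        pred = np.zeros((32, 32, 100), dtype=np.float64)
        count = np.zeros(100)
        for corner in (0, 36):
            x = np.stack([scaled[:, :, corner : corner + 64],
                          ctv[:, :, corner : corner + 64]])[None]
            y = net.forward(x)[0, 0]
            pred[:, :, corner : corner + 64] += y
            count[corner : corner + 64] += 1
        pred /= count
        expected = (pred * applied.dose_scale).astype(np.float32)
        expected[~body] = 0
        np.maximum(expected, 0, out=expected)
        assert np.allclose(out.values, expected, atol=1e-7)

    def test_geometry_mismatch_rejected(self, rng):
        noisy, ct, body = make_pair(rng)
        other_ct = Volume(ct.values, (0.3, 0.25, 0.25))
        with pytest.raises(ValueError):
            denoise_volume(IdentityNet(48, 64), noisy, other_ct, SCALES, body)

    def test_output_nonnegative_with_negative_predictions(self, rng):
        class NegativeNet:
            def __init__(self):
                self.config = IdentityNet(48, 64).config

            def forward(self, x, training=False):
                return x[:, :1] - 10.0

            __call__ = forward

        noisy, ct, body = make_pair(rng)
        out = denoise_volume(NegativeNet(), noisy, ct, SCALES, body)
        assert np.all(out.values >= 0)


class TestDenoisePlan:
    def test_single_field_equals_volume_path(self, rng):
        noisy, ct, body = make_pair(rng)
        net = IdentityNet(48, 64)
        a = denoise_plan(net, [noisy], ct, SCALES, body)
        b = denoise_volume(net, noisy, ct, SCALES, body)
        assert np.array_equal(a.values, b.values)

    def test_field_order_irrelevant(self, rng):
        f1, ct, body = make_pair(rng)
        f2 = Volume(f1.values[::-1].copy(), f1.voxel_size)
        net = IdentityNet(48, 64)
        a = denoise_plan(net, [f1, f2], ct, SCALES, body)
        b = denoise_plan(net, [f2, f1], ct, SCALES, body)
        assert np.array_equal(a.values, b.values)

    def test_half_weight_fields_sum(self, rng):
        f, ct, body = make_pair(rng)
        half = Volume((f.values / 2).astype(np.float32), f.voxel_size)
        net = IdentityNet(48, 64)
        a = denoise_plan(net, [half, half], ct, SCALES, body)
        b = denoise_plan(net, [f], ct, SCALES, body)
        assert np.allclose(a.values, b.values, atol=1e-9)

    def test_empty_field_list_rejected(self, rng):
        _, ct, body = make_pair(rng)
        with pytest.raises(ValueError):
            denoise_plan(IdentityNet(48, 64), [], ct, SCALES, body)
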