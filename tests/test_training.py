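import numpy as np
import pytest

from mcdose.nn import UNet3D, UNetConfig
from mcdose.training import (
    PlateauScheduler,
    TrainConfig,
    augment_patch,
    sample_patch,
    split_by_case,
    sse_loss,
    train,
)


class TestSplitByCase:
    def test_29_cases_give_23_3_3(self):
        split = split_by_case(list(range(29)), seed=0)
        assert (len(split.train), len(split.val), len(split.test)) == (23, 3, 3)

    def test_10_cases_give_8_1_1(self):
        split = split_by_case(list(range(10)), seed=1)
        assert (len(split.train), len(split.val), len(split.test)) == (8, 1, 1)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_disjoint_and_covering(self, seed):
        ids = [f"case{i}" for i in range(17)]
        split = split_by_case(ids, seed=seed)
        all_ids = set(split.train) | set(split.val) | set(split.test)
        assert all_ids == set(ids)
        assert len(split.train) + len(split.val) + len(split.test) == 17

    def test_deterministic(self):
        a = split_by_case(list(range(12)), seed=5)
        b = split_by_case(list(range(12)), seed=5)
        assert a == b

    def test_too_few_cases_rejected(self):
        with pytest.raises(ValueError):
            split_by_case([1, 2], seed=0)


class TestSamplePatch:
    def test_exact_size_volume_returns_whole(self, rng):
        v = rng.normal(size=(8, 8, 4))
        (p,) = sample_patch((v,), (8, 8, 4), rng)
        assert np.array_equal(p, v)

    def test_corner_distribution_hits_both_ends(self):
        rng = np.random.default_rng(0)
        v = np.arange(128 * 4 * 4).reshape(4, 4, 128).transpose(2, 0, 1)
        v = np.ascontiguousarray(v)  # (128, 4, 4), values encode position
        corners = set()
        for _ in range(1000):
            (p,) = sample_patch((v,), (64, 4, 4), rng)
            corners.add(int(p[0, 0, 0]))
        assert min(corners) == 0
        assert max(corners) == 64

    def test_same_window_for_all_volumes(self, rng):
        base = rng.normal(size=(16, 16, 8))
        a, b = sample_patch((base, base + 1.0), (8, 8, 4), rng)
        assert np.allclose(b - a, 1.0)

    def test_undersized_volume_rejected(self, rng):
        with pytest.raises(ValueError, match="smaller than patch"):
            sample_patch((np.zeros((4, 8, 8)),), (8, 8, 8), rng)


class TestAugmentPatch:
    def test_identity_draw(self):
        class FakeRng:
            def random(self):
                return 0.9  # no flips

            def integers(self, lo, hi):
                return 0  # no rotation

        v = np.arange(8.0).reshape(2, 2, 2)
        (out,) = augment_patch((v,), FakeRng())
        assert np.array_equal(out, v)

    def test_four_rotations_compose_to_identity(self):
        v = np.random.default_rng(0).normal(size=(4, 4, 2))
        out = v
        for _ in range(4):
            out = np.rot90(out, k=1, axes=(0, 1))
        assert np.array_equal(out, v)

    def test_pairs_move_together(self, rng):
        """Voxelwise correspondence between the triplet members survives any
        transform: a marker voxel lands at the same index in all of them."""
        a = np.zeros((6, 6, 4))
        b = np.zeros((6, 6, 4))
        a[1, 2, 3] = 1.0
        b[1, 2, 3] = 2.0
        for _ in range(20):
            ta, tb = augment_patch((a, b), rng)
            assert np.argmax(ta) == np.argmax(tb)

    def test_non_square_odd_rotation_rejected(self):
        class FakeRng:
            def random(self):
                return 0.9

            def integers(self, lo, hi):
                return 1  # 90 degrees

        with pytest.raises(ValueError, match="square"):
            augment_patch((np.zeros((4, 6, 2)),), FakeRng())


class TestSseLoss:
    def test_identical_is_zero(self, rng):
        x = rng.normal(size=(4, 4, 4))
        assert sse_loss(x, x) == 0.0

    def test_unit_offset_counts_voxels(self):
        a = np.zeros((2, 2, 2))
        assert sse_loss(a + 1.0, a) == 8.0

    def test_equals_mse_times_count(self, rng):
        a, b = rng.normal(size=(5, 5, 5)), rng.normal(size=(5, 5, 5))
        assert sse_loss(a, b) == pytest.approx(np.mean((a - b) ** 2) * a.size)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            sse_loss(np.zeros((2, 2, 2)), np.zeros((2, 2, 3)))


class TestPlateauScheduler:
    def test_decay_after_four_flat_epochs(self):
        """Losses [5, 4, 4, 4, 4, 4]: the best is at epoch 2; four non-
        improving epochs later (epoch 6) the rate drops by 5x."""
        sched = PlateauScheduler(1e-4)
        lrs = []
        for epoch, loss in enumerate([5.0, 4.0, 4.0, 4.0, 4.0, 4.0], start=1):
            actions = sched.update(epoch, loss)
            lrs.append(actions["lr"])
        assert lrs[:5] == [1e-4] * 5
        assert lrs[5] == pytest.approx(2e-5)
        assert sched.best_epoch == 2

    def test_early_stop_after_thirty(self):
        sched = PlateauScheduler(1e-4)
        stopped_at = None
        for epoch in range(1, 60):
            loss = 1.0 if epoch == 1 else 2.0
            if sched.update(epoch, loss)["stop"]:
                stopped_at = epoch
                break
        assert stopped_at == 31

    def test_counter_resets_on_improvement(self):
        sched = PlateauScheduler(1e-4)
        losses = [5.0, 4.9, 4.9, 4.9, 4.0, 4.0, 4.0, 4.0, 4.0]
        lr_at = [sched.update(e, l)["lr"] for e, l in enumerate(losses, 1)]
        # improvement at epoch 5 resets the plateau counter; decay only at
        # epoch 9 (four flat epochs after the new best)
        assert lr_at[7] == 1e-4
        assert lr_at[8] == pytest.approx(2e-5)

    def test_tiny_decrease_not_an_improvement(self):
        sched = PlateauScheduler(1e-4)
        sched.update(1, 1.0)
        actions = sched.update(2, 1.0 - 1e-12)
        assert not actions["improved"]


@pytest.fixture(scope="module")
def toy_setup():
    """Eight synthetic pairs on small grids: learn to undo noise toward a
    smooth target."""
    rng = np.random.default_rng(5)
    cfg = UNetConfig(
        xy_size=12, z_size=4, levels=2, channel_widths=(4, 8, 16),
    )
    triplets = []
    for _ in range(8):
        clean = rng.uniform(0.3, 0.7, (12, 12, 4)).astype(np.float32)
        noisy = (clean * rng.gamma(20.0, 1 / 20.0, clean.shape)).astype(
            np.float32
        )
        ct = np.ones_like(clean) * 0.5
        triplets.append((noisy, clean, ct))
    return cfg, triplets


class TestTrainLoop:
    def test_toy_convergence(self, toy_setup):
        """Final train loss falls below 10% of the first epoch's."""
        cfg, triplets = toy_setup
        net = UNet3D(cfg, seed=0)
        tc = TrainConfig(
            patch_size=(12, 12, 4), max_epochs=30, seed=0, initial_lr=1e-3
        )
        net, history = train(net, triplets[:6], triplets[6:], tc)
        assert history.train_loss[-1] < 0.1 * history.train_loss[0]

    def test_reproducible_epoch_one(self, toy_setup):
        cfg, triplets = toy_setup

        def first_epoch_loss():
            net = UNet3D(cfg, seed=0)
            tc = TrainConfig(patch_size=(12, 12, 4), max_epochs=1, seed=0)
            _, history = train(net, triplets[:6], triplets[6:], tc)
            return history.train_loss[0], history.val_loss[0]

        assert first_epoch_loss() == first_epoch_loss()

    def test_returns_best_epoch_weights(self, toy_setup):
        """The returned network reproduces the best (not last) val loss."""
        cfg, triplets = toy_setup
        net = UNet3D(cfg, seed=1)
        tc = TrainConfig(patch_size=(12, 12, 4), max_epochs=12, seed=1,
                         initial_lr=1e-3)
        net, history = train(net, triplets[:6], triplets[6:], tc)
        from mcdose.training import _validation_loss

        val = _validation_loss(net, triplets[6:], tc.patch_size)
        assert val == pytest.approx(min(history.val_loss), rel=1e-5)
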