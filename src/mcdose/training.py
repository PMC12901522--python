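"""Training protocol: case-level splitting, patch sampling, augmentation,
and the optimization loop.

The optimization protocol is: summed-squared-error loss, batch size 2,
Adam at an initial learning rate of 1e-4, learning rate divided by 5 when
the validation loss has not improved for 4 consecutive epochs, early
termination after 30 epochs without improvement, and the weights of the
best-validation epoch returned.  One random patch is drawn per training
triplet per epoch; patches are augmented on the fly by random axis
mirroring and xy-plane rotations in multiples of 90 degrees.

Splitting is performed on a case (phantom/CT) basis so that all variants
of one case land in the same split, preventing test leakage.
"""

from __future__ import annotations

import dataclasses

import numpy as np

__all__ = [
    "SplitSpec",
    "TrainConfig",
    "TrainingHistory",
    "split_by_case",
    "sample_patch",
    "augment_patch",
    "sse_loss",
    "PlateauScheduler",
    "train",
]


@dataclasses.dataclass(frozen=True)
class SplitSpec:
    """Disjoint case-id sets per split; together they cover all cases."""

    train: tuple
    val: tuple
    test: tuple
    seed: int

    def split_of(self, case_id) -> str:
        for name in ("train", "val", "test"):
            if case_id in getattr(self, name):
                return name
        raise KeyError(f"case {case_id!r} not in any split")


@dataclasses.dataclass(frozen=True)
class TrainConfig:
    """Optimization hyperparameters (defaults are the full protocol)."""

    batch_size: int = 2
    initial_lr: float = 1e-4
    lr_decay_factor: float = 5.0
    lr_patience: int = 4
    early_stop_patience: int = 30
    max_epochs: int = 10_000
    patch_size: tuple[int, int, int] = (192, 192, 64)
    mirror_axes: tuple[int, ...] = (0, 1, 2)
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.batch_size, self.lr_patience, self.early_stop_patience) < 1:
            raise ValueError("counts must be positive")
        if self.initial_lr <= 0 or self.lr_decay_factor <= 1:
            raise ValueError("invalid learning-rate settings")


def split_by_case(
    case_ids: list,
    fractions: tuple[float, float, float] = (0.8, 0.1, 0.1),
    seed: int = 0,
) -> SplitSpec:
    """Shuffle case ids and split ~80/10/10 with val/test at least 1 each.

    Sizes are ``round(n * fraction)`` for val and test (minimum 1), with
    the remainder going to train.  Deterministic given ``seed``.
    """
    if len(case_ids) < 3:
        raise ValueError(f"need at least 3 cases, got {len(case_ids)}")
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    rng = np.random.default_rng(seed)
    order = [case_ids[i] for i in rng.permutation(len(case_ids))]
    n = len(order)
    n_val = max(1, round(n * fractions[1]))
    n_test = max(1, round(n * fractions[2]))
    return SplitSpec(
        train=tuple(order[: n - n_val - n_test]),
        val=tuple(order[n - n_val - n_test : n - n_test]),
        test=tuple(order[n - n_test :]),
        seed=seed,
    )


def sample_patch(
    volumes: tuple[np.ndarray, ...],
    patch_size: tuple[int, int, int],
    rng: np.random.Generator,
) -> tuple[np.ndarray, ...]:
    """Extract one uniformly-random patch window, identical for all volumes."""
    shape = volumes[0].shape
    for v in volumes[1:]:
        if v.shape != shape:
            raise ValueError("volumes must share a shape")
    for ax in range(3):
        if shape[ax] < patch_size[ax]:
            raise ValueError(
                f"volume axis {ax} ({shape[ax]}) smaller than patch "
                f"({patch_size[ax]}); pad first"
            )
    corner = tuple(
        int(rng.integers(0, shape[ax] - patch_size[ax] + 1)) for ax in range(3)
    )
    window = tuple(slice(c, c + p) for c, p in zip(corner, patch_size))
    return tuple(v[window] for v in volumes)


def augment_patch(
    patches: tuple[np.ndarray, ...],
    rng: np.random.Generator,
    mirror_axes: tuple[int, ...] = (0, 1, 2),
) -> tuple[np.ndarray, ...]:
    """Random mirroring and xy-plane rotation by a multiple of 90 degrees.

    The same transform is applied to every patch of the triplet, so
    voxel-wise correspondence between noisy, clean and CT is preserved.
    Odd rotations require a square xy footprint.
    """
    flips = tuple(ax for ax in mirror_axes if rng.random() < 0.5)
    k = int(rng.integers(0, 4))
    if k % 2 and patches[0].shape[0] != patches[0].shape[1]:
        raise ValueError("90-degree rotation requires a square xy footprint")
    out = []
    for p in patches:
        if flips:
            p = np.flip(p, axis=flips)
        if k:
            p = np.rot90(p, k=k, axes=(0, 1))
        out.append(np.ascontiguousarray(p))
    return tuple(out)


def sse_loss(prediction: np.ndarray, target: np.ndarray) -> float:
    """Summed squared error over all voxels."""
    if prediction.shape != target.shape:
        raise ValueError(
            f"shape mismatch: {prediction.shape} vs {target.shape}"
        )
    diff = np.asarray(prediction, dtype=np.float64) - target
    return float(np.sum(diff * diff))


#: Relative tolerance below which a validation-loss decrease does not count
#: as an improvement.
IMPROVEMENT_RTOL = 1e-8


class PlateauScheduler:
    """Plateau learning-rate decay plus early stopping.

    "Improvement" is a strict decrease of the epoch validation loss by more
    than a 1e-8 relative tolerance.  The plateau counter resets on
    improvement and after each decay; the early-stop counter resets only on
    improvement.
    """

    def __init__(
        self,
        initial_lr: float,
        decay_factor: float = 5.0,
        patience: int = 4,
        early_stop_patience: int = 30,
    ):
        self.lr = initial_lr
        self.decay_factor = decay_factor
        self.patience = patience
        self.early_stop_patience = early_stop_patience
        self.best = np.inf
        self.best_epoch = -1
        self._since_improvement = 0
        self._since_decay_or_improvement = 0

    def update(self, epoch: int, val_loss: float) -> dict:
        """Register an epoch's validation loss; returns scheduler actions."""
        improved = val_loss < self.best * (1.0 - IMPROVEMENT_RTOL)
        decayed = False
        if improved:
            self.best = val_loss
            self.best_epoch = epoch
            self._since_improvement = 0
            self._since_decay_or_improvement = 0
        else:
            self._since_improvement += 1
            self._since_decay_or_improvement += 1
            if self._since_decay_or_improvement >= self.patience:
                self.lr /= self.decay_factor
                self._since_decay_or_improvement = 0
                decayed = True
        stop = self._since_improvement >= self.early_stop_patience
        return {"improved": improved, "decayed": decayed, "stop": stop, "lr": self.lr}


@dataclasses.dataclass
class TrainingHistory:
    """Per-epoch log: train loss, validation loss, learning rate."""

    epochs: list[int] = dataclasses.field(default_factory=list)
    train_loss: list[float] = dataclasses.field(default_factory=list)
    val_loss: list[float] = dataclasses.field(default_factory=list)
    lr: list[float] = dataclasses.field(default_factory=list)
    best_epoch: int = -1

    def append(self, epoch, train_loss, val_loss, lr) -> None:
        self.epochs.append(epoch)
        self.train_loss.append(train_loss)
        self.val_loss.append(val_loss)
        self.lr.append(lr)

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "epoch": self.epochs,
                "train_loss": self.train_loss,
                "val_loss": self.val_loss,
                "lr": self.lr,
            }
        )


def _validation_loss(network, val_triplets, patch_size) -> float:
    """Deterministic validation SSE using tiled, non-overlapping-equivalent
    patched inference over each full volume."""
    total = 0.0
    for noisy, clean, ct in val_triplets:
        pred = _predict_full(network, noisy, ct, patch_size)
        total += sse_loss(pred, clean)
    return total


def _predict_full(network, noisy, ct, patch_size) -> np.ndarray:
    """Patched full-volume prediction in the network's scaled space."""
    from .inference import plan_patches

    in_channels = network.config.in_channels
    nz = noisy.shape[2]
    layout = plan_patches(nz, patch_size[2])
    pred = np.zeros_like(noisy, dtype=np.float64)
    weight = np.zeros(nz, dtype=np.float64)
    for corner in layout.corners:
        sl = slice(corner, corner + patch_size[2])
        channels = [noisy[:, :, sl]] + ([ct[:, :, sl]] if in_channels == 2 else [])
        x = np.stack(channels)[None].astype(np.float32)
        y = network.forward(x, training=False)[0, 0]
        pred[:, :, sl] += y
        weight[sl] += 1.0
    pred /= weight[None, None, :]
    return pred.astype(np.float32)


def train(
    network,
    train_triplets: list[tuple[np.ndarray, np.ndarray, np.ndarray]],
    val_triplets: list[tuple[np.ndarray, np.ndarray, np.ndarray]],
    config: TrainConfig,
    callback=None,
):
    """Run the full optimization protocol.

    ``train_triplets`` and ``val_triplets`` are (noisy, clean, ct) arrays in
    the network's scaled space, already padded to at least the patch size
    in every axis.  Returns ``(network, history)`` with the network holding
    the weights of the best-validation epoch.
    """
    from .nn.optim import Adam

    if not train_triplets or not val_triplets:
        raise ValueError("need non-empty train and validation sets")
    rng = np.random.default_rng(config.seed)
    params = network.parameters()
    optimizer = Adam(params, lr=config.initial_lr)
    scheduler = PlateauScheduler(
        config.initial_lr,
        config.lr_decay_factor,
        config.lr_patience,
        config.early_stop_patience,
    )
    history = TrainingHistory()
    best_state = None
    in_channels = network.config.in_channels

    for epoch in range(1, config.max_epochs + 1):
        order = rng.permutation(len(train_triplets))
        epoch_loss = 0.0
        n_voxels = 0
        for start in range(0, len(order), config.batch_size):
            batch_idx = order[start : start + config.batch_size]
            xs, ts = [], []
            for i in batch_idx:
                noisy, clean, ct = train_triplets[i]
                patches = sample_patch((noisy, clean, ct), config.patch_size, rng)
                noisy_p, clean_p, ct_p = augment_patch(
                    patches, rng, config.mirror_axes
                )
                channels = [noisy_p] + ([ct_p] if in_channels == 2 else [])
                xs.append(np.stack(channels))
                ts.append(clean_p[None])
            x = np.stack(xs).astype(np.float32)
            t = np.stack(ts).astype(np.float32)
            y = network.forward(x, training=True)
            diff = y - t
            loss = float(np.sum(diff.astype(np.float64) ** 2))
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite training loss at epoch {epoch}"
                )
            optimizer.lr = scheduler.lr
            optimizer.zero_grad()
            network.backward(2.0 * diff)
            optimizer.step()
            epoch_loss += loss
            n_voxels += diff.size

        val = _validation_loss(network, val_triplets, config.patch_size)
        if not np.isfinite(val):
            raise FloatingPointError(f"non-finite validation loss at epoch {epoch}")
        actions = scheduler.update(epoch, val)
        history.append(epoch, epoch_loss, val, actions["lr"])
        if actions["improved"]:
            best_state = {k: v.copy() for k, v in network.state_dict().items()}
            history.best_epoch = epoch
        if callback is not None:
            callback(epoch, epoch_loss, val, actions)
        if actions["stop"]:
            break

    if best_state is not None:
        network.load_state_dict(best_state)
    return network, history
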