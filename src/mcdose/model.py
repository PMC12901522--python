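"""Model/Results facade over the denoising workflow.

:class:`DoseDenoiser` is constructed from a dataset of (phantom, dose
pair) triplets -- typically the output of
:func:`mcdose.dataset.build_augmented_dataset` -- plus architecture and
training configurations.  Its :meth:`~DoseDenoiser.fit` runs the full
optimization protocol and returns a :class:`DenoisingResult` carrying the
trained network, the training history, the case split and the scale
constants; the result object denoises new volumes, evaluates the held-out
test cases with the dosimetric metric suite, and prints a summary table.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .dataset import Roster
from .evaluation import GammaCriteria, gamma_map, isnr, rmse_masked
from .inference import denoise_volume
from .nn import UNet3D, UNetConfig
from .noise import DosePair
from .phantoms import Phantom
from .training import SplitSpec, TrainConfig, split_by_case, train
from .volumes import ScaleConstants, Volume, compute_scale_constants, crop_or_pad_xy

__all__ = ["DoseDenoiser", "DenoisingResult"]


def _scaled_triplet(
    phantom: Phantom, pair: DosePair, scales: ScaleConstants, xy_size: int, z_min: int
):
    """(noisy, clean, ct) float32 arrays in network space, xy-fitted and
    z-padded to at least the patch size."""
    applied = scales.pow2()
    vols = []
    for vol, scale, shift in (
        (pair.noisy, applied.dose_scale, 0.0),
        (pair.clean, applied.dose_scale, 0.0),
        (phantom.ct_volume(), applied.ct_scale, 1000.0),
    ):
        vals = (np.asarray(vol.values, dtype=np.float32) + np.float32(shift)) / np.float32(
            scale
        )
        fitted, _ = crop_or_pad_xy(Volume(vals, vol.voxel_size, vol.origin), xy_size)
        v = fitted.values
        if v.shape[2] < z_min:
            v = np.pad(v, ((0, 0), (0, 0), (0, z_min - v.shape[2])))
        vols.append(v)
    return tuple(vols)


class DoseDenoiser:
    """A 3D U-net dose-denoising model bound to a training dataset.

    Parameters
    ----------
    triplets : list of (Phantom, DosePair)
        The augmented dataset; each phantom object identifies a case for
        the case-level split (all arc variants of one phantom share its
        split).
    unet_config, train_config : configuration objects
        Architecture and optimization settings; the patch xy footprint is
        taken from ``unet_config``.
    roster : Roster, optional
        The augmentation manifest, kept for provenance.
    scales : ScaleConstants, optional
        Pre-computed dataset scale constants; derived from the dataset
        when omitted.
    """

    def __init__(
        self,
        triplets: list[tuple[Phantom, DosePair]],
        unet_config: UNetConfig | None = None,
        train_config: TrainConfig | None = None,
        roster: Roster | None = None,
        scales: ScaleConstants | None = None,
    ):
        if not triplets:
            raise ValueError("empty dataset")
        self.triplets = triplets
        self.unet_config = unet_config or UNetConfig.tiny()
        self.train_config = train_config or TrainConfig(
            patch_size=(
                self.unet_config.xy_size,
                self.unet_config.xy_size,
                self.unet_config.z_size,
            )
        )
        self.roster = roster
        if scales is None:
            scales = compute_scale_constants(
                [(ph.ct_volume(), pair.clean) for ph, pair in triplets]
            )
        self.scales = scales
        # a case = one phantom object (one CT)
        self._case_of_triplet = []
        seen: dict[int, int] = {}
        for ph, _ in triplets:
            case = seen.setdefault(id(ph), len(seen))
            self._case_of_triplet.append(case)
        self._n_cases = len(seen)

    @property
    def n_cases(self) -> int:
        return self._n_cases

    def fit(
        self,
        seed: int = 0,
        fractions: tuple[float, float, float] = (0.8, 0.1, 0.1),
        callback=None,
    ) -> "DenoisingResult":
        """Split by case, train the network, return the fitted result."""
        split = split_by_case(list(range(self._n_cases)), fractions, seed)
        cfg = self.train_config
        z_min = cfg.patch_size[2]
        by_split: dict[str, list] = {"train": [], "val": [], "test": []}
        for i, (ph, pair) in enumerate(self.triplets):
            name = split.split_of(self._case_of_triplet[i])
            by_split[name].append(i)
        prepared = {
            name: [
                _scaled_triplet(
                    self.triplets[i][0],
                    self.triplets[i][1],
                    self.scales,
                    self.unet_config.xy_size,
                    z_min,
                )
                for i in idxs
            ]
            for name, idxs in by_split.items()
            if name != "test"
        }
        network = UNet3D(self.unet_config, seed=seed)
        network, history = train(
            network,
            prepared["train"],
            prepared["val"],
            dataclasses.replace(cfg, seed=seed),
            callback=callback,
        )
        return DenoisingResult(
            model=self,
            network=network,
            history=history,
            split=split,
            test_indices=tuple(by_split["test"]),
        )


@dataclasses.dataclass
class DenoisingResult:
    """The fitted denoiser: trained weights, history, split, evaluation."""

    model: DoseDenoiser
    network: UNet3D
    history: object
    split: SplitSpec
    test_indices: tuple[int, ...]

    def denoise(self, noisy: Volume, ct: Volume, body_mask=None) -> Volume:
        """Denoise a dose volume on its CT grid."""
        return denoise_volume(self.network, noisy, ct, self.model.scales, body_mask)

    def evaluate(
        self,
        criteria: tuple[GammaCriteria, ...] = (
            GammaCriteria(2.0, 2.0, gamma_max=1.5),
            GammaCriteria(3.0, 3.0, gamma_max=1.5),
        ),
        indices: tuple[int, ...] | None = None,
    ):
        """Per-test-case metrics: gamma pass rates, masked RMSE, ISNR.

        Returns a pandas DataFrame with one row per evaluated triplet.
        """
        import pandas as pd

        indices = self.test_indices if indices is None else indices
        rows = []
        for i in indices:
            phantom, pair = self.model.triplets[i]
            denoised = self.denoise(pair.noisy, phantom.ct_volume(), phantom.body_mask)
            row = {"triplet": i, "case": self.model._case_of_triplet[i]}
            for crit in criteria:
                label = f"gamma_{crit.dose_percent:g}_{crit.distance_mm:g}mm"
                row[f"{label}_denoised"] = gamma_map(pair.clean, denoised, crit).pass_rate
                row[f"{label}_noisy"] = gamma_map(pair.clean, pair.noisy, crit).pass_rate
            row["rmse_denoised"] = rmse_masked(pair.clean, denoised)
            row["rmse_noisy"] = rmse_masked(pair.clean, pair.noisy)
            row["isnr_db"] = isnr(pair.noisy, denoised, pair.clean, phantom.body_mask)
            rows.append(row)
        return pd.DataFrame(rows)

    def summary(self) -> str:
        """Human-readable fit summary."""
        h = self.history
        lines = [
            "Dose-denoising U-net fit",
            "=" * 50,
            f"cases: {self.model.n_cases}   triplets: {len(self.model.triplets)}",
            f"split: {len(self.split.train)}/{len(self.split.val)}/"
            f"{len(self.split.test)} cases (train/val/test)",
            f"parameters: {self.network.num_parameters:,}",
            f"epochs run: {len(h.epochs)}   best epoch: {h.best_epoch}",
            f"train SSE (first -> last): {h.train_loss[0]:.4g} -> {h.train_loss[-1]:.4g}",
            f"val SSE (first -> best): {h.val_loss[0]:.4g} -> {min(h.val_loss):.4g}",
            f"final lr: {h.lr[-1]:.3g}",
        ]
        return "\n".join(lines)

    def plot_history(self, ax=None):
        """Training and validation loss curves."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.semilogy(self.history.epochs, self.history.train_loss, label="train SSE")
        ax.semilogy(self.history.epochs, self.history.val_loss, label="val SSE")
        ax.axvline(self.history.best_epoch, ls="--", c="gray", lw=0.8)
        ax.set_xlabel("epoch")
        ax.set_ylabel("summed squared error")
        ax.legend()
        return ax
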