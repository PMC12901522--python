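"""Statistical-uncertainty noise model for Monte Carlo dose.

MC dose estimates are non-negative and heteroscedastic, with per-voxel
relative noise proportional to 1/sqrt(N) in the number of simulated
particle histories N and decreasing with local dose (more histories score
in high-dose voxels).  Both properties are reproduced by multiplicative
unit-mean Gamma noise whose shape parameter grows linearly with N and with
the voxel's relative dose:

    noisy(v) = clean(v) * g_v,   g_v ~ Gamma(k_v, 1/k_v),
    k_v = k0 * N * clean(v) / max(clean),

so the per-voxel relative standard deviation is 1/sqrt(k_v).  No particle
transport is simulated; the model supplies only the statistical structure
of MC dose that the denoiser is trained against.

Statistical uncertainty (SU) is reported the conventional way for MC dose:
the mean relative standard error of the mean dose over voxels receiving
more than 50% of the maximum mean dose, in percent.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .volumes import Volume

__all__ = [
    "NoiseModel",
    "DosePair",
    "sample_noisy_dose",
    "estimate_su",
    "HISTORIES_HIGH_SU",
    "HISTORIES_LOW_SU",
]

#: Particle-history counts of the fast ("noisy") and reference ("low-noise")
#: MC dose calculations the model emulates.
HISTORIES_HIGH_SU = 1_500_000
HISTORIES_LOW_SU = 300_000_000


@dataclasses.dataclass(frozen=True)
class NoiseModel:
    """Calibration of the history-count -> Gamma-shape map.

    ``k0`` is chosen so that a single realization at
    ``su_reference_histories`` (the fast-calculation setting) has SU around
    60%; the 200x larger reference count then lands below 5% by the
    1/sqrt(N) law.
    """

    k0: float = 2.2e-6
    su_reference_histories: int = HISTORIES_HIGH_SU

    def __post_init__(self) -> None:
        if self.k0 <= 0:
            raise ValueError("k0 must be > 0")

    def shape_parameter(self, clean: np.ndarray, histories: int) -> np.ndarray:
        """Per-voxel Gamma shape k_v; zero-dose voxels get shape 0 (unused)."""
        peak = float(clean.max())
        if peak <= 0:
            return np.zeros_like(clean, dtype=np.float64)
        return self.k0 * histories * np.asarray(clean, dtype=np.float64) / peak

    def single_realization_su(self, clean: np.ndarray, histories: int) -> float:
        """Analytic SU (%) of one realization at a given history count.

        Mean of the per-voxel relative standard deviation 1/sqrt(k_v) over
        voxels above 50% of the maximum dose.
        """
        clean = np.asarray(clean, dtype=np.float64)
        peak = clean.max()
        if peak <= 0:
            raise ValueError("all-zero dose")
        counted = clean > 0.5 * peak
        k = self.shape_parameter(clean, histories)[counted]
        return float(np.mean(100.0 / np.sqrt(k)))


@dataclasses.dataclass
class DosePair:
    """A paired noisy/clean dose realization at a given history count."""

    clean: Volume
    noisy: Volume
    histories: int
    seed: int


def sample_noisy_dose(
    clean: Volume, histories: int, model: NoiseModel, seed: int
) -> Volume:
    """Draw one noisy MC-like realization of a clean dose distribution.

    Voxels with zero clean dose stay exactly zero; all others are scaled by
    unit-mean Gamma noise with shape ``k0 * histories * relative_dose``.
    Reproducible given ``seed``.
    """
    if histories <= 0:
        raise ValueError("histories must be > 0")
    values = np.asarray(clean.values)
    if not np.all(np.isfinite(values)):
        raise ValueError("clean dose contains non-finite values")
    if np.any(values < 0):
        raise ValueError("clean dose must be non-negative")
    rng = np.random.default_rng(seed)
    k = NoiseModel.shape_parameter(model, values, histories)
    noisy = np.zeros_like(values, dtype=np.float64)
    hot = k > 0
    # Gamma(shape k, scale 1/k) has mean 1 and variance 1/k
    noisy[hot] = values[hot] * rng.gamma(k[hot], 1.0 / k[hot])
    return Volume(noisy.astype(values.dtype), clean.voxel_size, clean.origin)


def estimate_su(realizations: list[Volume]) -> float:
    """Statistical uncertainty (%) of the mean of independent realizations.

    SU = mean over voxels whose mean dose exceeds 50% of the maximum mean
    dose of the per-voxel relative standard error of the mean, in percent.
    Requires at least two realizations on a common grid.
    """
    if len(realizations) < 2:
        raise ValueError("need at least 2 realizations")
    first = realizations[0]
    for r in realizations[1:]:
        if not first.same_grid(r):
            raise ValueError("realizations are not on a common grid")
    stack = np.stack([np.asarray(r.values, dtype=np.float64) for r in realizations])
    mean = stack.mean(axis=0)
    peak = mean.max()
    if peak <= 0:
        raise ValueError("all-zero mean dose")
    counted = mean > 0.5 * peak
    if not counted.any():
        raise ValueError("no voxel above 50% of the maximum mean dose")
    sem = stack.std(axis=0, ddof=1)[counted] / np.sqrt(stack.shape[0])
    return float(np.mean(sem / mean[counted]) * 100.0)
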