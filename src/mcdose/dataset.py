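"""Augmented training-set construction.

A base roster of single VMAT-like arcs, each assigned to a phantom, is
augmented by an integer factor: every variant re-randomizes the MU weight
of each control point, the beam energy, the isocenter position (shifted
within +/-9 cm in x, +/-5 cm in y and +/-10 cm in z, rejection-resampled
until it lies inside the body) and the collimator rotation.  The aperture
halfwidths -- the stand-in for clinically optimized MLC shapes -- are
never modified.  Every random draw is recorded in a roster that
round-trips losslessly through its JSON manifest.
"""

from __future__ import annotations

import dataclasses
import json

import numpy as np

from .dose import compute_clean_dose
from .noise import HISTORIES_HIGH_SU, DosePair, NoiseModel, sample_noisy_dose
from .phantoms import Phantom
from .plans import ENERGIES_MV, ArcPlan, ControlPoint

__all__ = [
    "AugmentationRanges",
    "RosterEntry",
    "Roster",
    "build_roster",
    "build_augmented_dataset",
    "materialize_entry",
    "apply_variant",
]

#: Maximum isocenter shifts (cm) along x, y, z.
ISO_SHIFT_BOUNDS = (9.0, 5.0, 10.0)
_MAX_ISO_ATTEMPTS = 100


@dataclasses.dataclass(frozen=True)
class AugmentationRanges:
    """Randomization ranges for one augmentation variant.

    ``mu_jitter`` bounds the per-control-point multiplicative MU factor;
    ``total_mu_factor`` rescales the arc's total MU; ``energies`` is the
    pool to draw the beam energy from (None keeps the base arc's energy);
    ``isocenter_shift`` gives the maximum absolute shift per axis in cm;
    ``collimator_offset`` bounds the rotation added to the base collimator
    angle in degrees.  All-degenerate ranges reproduce the base arc
    exactly.
    """

    mu_jitter: tuple[float, float] = (0.2, 2.0)
    total_mu_factor: tuple[float, float] = (0.5, 2.0)
    energies: tuple[int, ...] | None = ENERGIES_MV
    isocenter_shift: tuple[float, float, float] = ISO_SHIFT_BOUNDS
    collimator_offset: tuple[float, float] = (0.0, 360.0)

    def __post_init__(self) -> None:
        if self.mu_jitter[0] <= 0 or self.mu_jitter[0] > self.mu_jitter[1]:
            raise ValueError(f"invalid mu_jitter range {self.mu_jitter}")
        for ax, (shift, bound) in enumerate(zip(self.isocenter_shift, ISO_SHIFT_BOUNDS)):
            if shift < 0 or shift > bound + 1e-9:
                raise ValueError(
                    f"isocenter shift {shift} cm on axis {ax} outside [0, {bound}]"
                )
        if self.energies is not None:
            bad = set(self.energies) - set(ENERGIES_MV)
            if bad:
                raise ValueError(f"unsupported energies {sorted(bad)}")

    @classmethod
    def identity(cls) -> "AugmentationRanges":
        """Degenerate ranges: every variant equals its base arc."""
        return cls(
            mu_jitter=(1.0, 1.0),
            total_mu_factor=(1.0, 1.0),
            energies=None,
            isocenter_shift=(0.0, 0.0, 0.0),
            collimator_offset=(0.0, 0.0),
        )


@dataclasses.dataclass(frozen=True)
class RosterEntry:
    """One augmented triplet: which base arc/phantom, and every draw made."""

    index: int
    base_arc: int
    variant: int
    phantom: int
    noise_seed: int
    histories: int
    mu_factors: tuple[float, ...]
    total_mu: float
    energy: int
    isocenter: tuple[float, float, float]
    collimator_offset: float

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["mu_factors"] = list(self.mu_factors)
        d["isocenter"] = list(self.isocenter)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RosterEntry":
        d = dict(d)
        d["mu_factors"] = tuple(d["mu_factors"])
        d["isocenter"] = tuple(d["isocenter"])
        return cls(**d)


@dataclasses.dataclass
class Roster:
    """The full augmentation record: dataset manifest sans volume files."""

    seed: int
    factor: int
    n_base_arcs: int
    entries: list[RosterEntry]

    def __len__(self) -> int:
        return len(self.entries)

    def to_json(self, path=None) -> str:
        payload = json.dumps(
            {
                "seed": self.seed,
                "factor": self.factor,
                "n_base_arcs": self.n_base_arcs,
                "entries": [e.to_dict() for e in self.entries],
            },
            indent=1,
        )
        if path is not None:
            with open(path, "w") as fh:
                fh.write(payload)
        return payload

    @classmethod
    def from_json(cls, text_or_path) -> "Roster":
        try:
            data = json.loads(text_or_path)
        except (ValueError, TypeError):
            with open(text_or_path) as fh:
                data = json.load(fh)
        return cls(
            seed=data["seed"],
            factor=data["factor"],
            n_base_arcs=data["n_base_arcs"],
            entries=[RosterEntry.from_dict(e) for e in data["entries"]],
        )


def _draw_variant(
    base: ArcPlan,
    phantom: Phantom,
    ranges: AugmentationRanges,
    rng: np.random.Generator,
) -> dict:
    n_cp = len(base.control_points)
    factors = rng.uniform(*ranges.mu_jitter, n_cp)
    total = base.total_mu * float(rng.uniform(*ranges.total_mu_factor))
    if ranges.energies is None:
        energy = base.control_points[0].energy
    else:
        energy = int(rng.choice(ranges.energies))
    collimator_offset = float(rng.uniform(*ranges.collimator_offset))

    shift_max = np.asarray(ranges.isocenter_shift)
    base_iso = np.asarray(base.isocenter)
    for _ in range(_MAX_ISO_ATTEMPTS):
        shift = rng.uniform(-shift_max, shift_max)
        iso = base_iso + shift
        if phantom.contains_point(iso):
            break
    else:
        raise RuntimeError(
            f"no isocenter inside the body after {_MAX_ISO_ATTEMPTS} attempts "
            f"(shift range {ranges.isocenter_shift} cm)"
        )
    return {
        "mu_factors": tuple(float(f) for f in factors),
        "total_mu": total,
        "energy": energy,
        "isocenter": tuple(float(c) for c in iso),
        "collimator_offset": collimator_offset,
    }


def apply_variant(base: ArcPlan, entry: RosterEntry) -> ArcPlan:
    """Reconstruct the augmented arc described by a roster entry."""
    raw = np.array([cp.mu_weight for cp in base.control_points]) * np.array(
        entry.mu_factors
    )
    weights = raw / raw.sum() * entry.total_mu
    cps = tuple(
        ControlPoint(
            gantry_angle=cp.gantry_angle,
            mu_weight=float(w),
            aperture_halfwidth_x=cp.aperture_halfwidth_x,
            aperture_halfwidth_y=cp.aperture_halfwidth_y,
            collimator_rotation=(cp.collimator_rotation + entry.collimator_offset)
            % 360.0,
            energy=entry.energy,
        )
        for cp, w in zip(base.control_points, weights)
    )
    return ArcPlan(control_points=cps, isocenter=entry.isocenter, sad=base.sad)


def build_roster(
    base_arcs: list[ArcPlan],
    phantoms: list[Phantom],
    factor: int,
    ranges: AugmentationRanges | None = None,
    seed: int = 0,
    histories: int = HISTORIES_HIGH_SU,
) -> Roster:
    """Draw the full augmentation roster without computing any dose.

    Produces exactly ``len(base_arcs) * factor`` entries.  Arc ``i`` is
    assigned to phantom ``i % len(phantoms)``; each variant's draws come
    from an independent, deterministic sub-stream of ``seed``.
    """
    if factor < 1:
        raise ValueError("factor must be >= 1")
    if not base_arcs or not phantoms:
        raise ValueError("need at least one base arc and one phantom")
    ranges = AugmentationRanges() if ranges is None else ranges
    entries = []
    index = 0
    for a, arc in enumerate(base_arcs):
        phantom_idx = a % len(phantoms)
        phantom = phantoms[phantom_idx]
        for j in range(factor):
            rng = np.random.default_rng(
                np.random.SeedSequence(seed, spawn_key=(a, j))
            )
            draws = _draw_variant(arc, phantom, ranges, rng)
            entries.append(
                RosterEntry(
                    index=index,
                    base_arc=a,
                    variant=j,
                    phantom=phantom_idx,
                    noise_seed=int(rng.integers(2**31)),
                    histories=histories,
                    **draws,
                )
            )
            index += 1
    return Roster(seed=seed, factor=factor, n_base_arcs=len(base_arcs), entries=entries)


def materialize_entry(
    entry: RosterEntry,
    base_arcs: list[ArcPlan],
    phantoms: list[Phantom],
    noise_model: NoiseModel | None = None,
    histories_low: int | None = None,
) -> tuple[Phantom, DosePair]:
    """Compute the (phantom, clean/noisy dose pair) triplet for one entry.

    The reference dose is the analytic clean dose unless ``histories_low``
    is given, in which case a low-SU realization at that history count is
    drawn instead (emulating a finite-history reference calculation).
    """
    noise_model = NoiseModel() if noise_model is None else noise_model
    phantom = phantoms[entry.phantom]
    plan = apply_variant(base_arcs[entry.base_arc], entry)
    clean = compute_clean_dose(phantom, plan)
    noisy = sample_noisy_dose(clean, entry.histories, noise_model, entry.noise_seed)
    if histories_low is not None:
        clean = sample_noisy_dose(
            clean, histories_low, noise_model, entry.noise_seed + 1
        )
    return phantom, DosePair(
        clean=clean, noisy=noisy, histories=entry.histories, seed=entry.noise_seed
    )


def build_augmented_dataset(
    base_arcs: list[ArcPlan],
    phantoms: list[Phantom],
    factor: int,
    ranges: AugmentationRanges | None = None,
    seed: int = 0,
    histories: int = HISTORIES_HIGH_SU,
    histories_low: int | None = None,
    noise_model: NoiseModel | None = None,
) -> tuple[list[tuple[Phantom, DosePair]], Roster]:
    """Build the augmented dataset: triplets plus the roster manifest."""
    roster = build_roster(base_arcs, phantoms, factor, ranges, seed, histories)
    triplets = [
        materialize_entry(e, base_arcs, phantoms, noise_model, histories_low)
        for e in roster.entries
    ]
    return triplets, roster
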