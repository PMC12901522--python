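"""VMAT-like arc plans.

An arc is an ordered list of control points on an isocentric gantry
rotation about the z axis.  Each control point carries a gantry angle, a
monitor-unit (MU) weight, a rectangular aperture (the stand-in for an MLC
shape), a collimator rotation and a nominal beam energy.  Dose grids are
normalized to Gy per MU, so the MU weights enter as fractions of the
plan's total MU.
"""

from __future__ import annotations

import dataclasses

import numpy as np

__all__ = ["ControlPoint", "ArcPlan", "ENERGIES_MV", "random_arc"]

#: Available nominal beam energies (MV).
ENERGIES_MV = (6, 10, 15)


@dataclasses.dataclass(frozen=True)
class ControlPoint:
    """One gantry position of an arc."""

    gantry_angle: float  # degrees
    mu_weight: float  # dimensionless, >= 0
    aperture_halfwidth_x: float  # cm at isocenter, collimator frame
    aperture_halfwidth_y: float  # cm at isocenter (z-ish direction)
    collimator_rotation: float = 0.0  # degrees
    energy: int = 6  # MV

    def __post_init__(self) -> None:
        if self.mu_weight < 0:
            raise ValueError("mu_weight must be >= 0")
        if self.aperture_halfwidth_x <= 0 or self.aperture_halfwidth_y <= 0:
            raise ValueError("aperture halfwidths must be > 0")
        if self.energy not in ENERGIES_MV:
            raise ValueError(f"energy must be one of {ENERGIES_MV}, got {self.energy}")


@dataclasses.dataclass(frozen=True)
class ArcPlan:
    """An isocentric arc: control points, isocenter (cm) and SAD (cm)."""

    control_points: tuple[ControlPoint, ...]
    isocenter: tuple[float, float, float]
    sad: float = 100.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "control_points", tuple(self.control_points))
        if not self.control_points:
            raise ValueError("arc needs at least one control point")
        if self.total_mu <= 0:
            raise ValueError("total MU must be > 0")
        if self.sad <= 0:
            raise ValueError("SAD must be > 0")

    @property
    def total_mu(self) -> float:
        return float(sum(cp.mu_weight for cp in self.control_points))

    def replace(self, **kwargs) -> "ArcPlan":
        return dataclasses.replace(self, **kwargs)

    def to_dict(self) -> dict:
        return {
            "isocenter": list(self.isocenter),
            "sad": self.sad,
            "control_points": [dataclasses.asdict(cp) for cp in self.control_points],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ArcPlan":
        return cls(
            control_points=tuple(ControlPoint(**cp) for cp in d["control_points"]),
            isocenter=tuple(d["isocenter"]),
            sad=d["sad"],
        )


def random_arc(
    isocenter,
    rng: np.random.Generator,
    n_control_points: int = 12,
    energy: int | None = None,
    full_arc: bool = True,
) -> ArcPlan:
    """Draw a random clinically-plausible single arc around ``isocenter``.

    The aperture halfwidths are drawn once per arc (the beam shape is the
    arc's identity and is never modified by augmentation); MU weights vary
    per control point.
    """
    if energy is None:
        energy = int(rng.choice(ENERGIES_MV))
    span = 360.0 if full_arc else float(rng.uniform(120.0, 360.0))
    start = float(rng.uniform(0.0, 360.0))
    angles = start + np.linspace(0.0, span, n_control_points, endpoint=False)
    hwx = float(rng.uniform(1.0, 3.5))
    hwy = float(rng.uniform(1.0, 3.0))
    collimator = float(rng.uniform(0.0, 360.0))
    weights = rng.uniform(0.5, 1.5, n_control_points)
    cps = tuple(
        ControlPoint(
            gantry_angle=float(a % 360.0),
            mu_weight=float(w),
            aperture_halfwidth_x=hwx,
            aperture_halfwidth_y=hwy,
            collimator_rotation=collimator,
            energy=energy,
        )
        for a, w in zip(angles, weights)
    )
    return ArcPlan(control_points=cps, isocenter=tuple(float(c) for c in isocenter))
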