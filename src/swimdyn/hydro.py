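"""Hydrodynamic forces on the swimmer's palm.

The drag and propulsion forces acting on a body moving through water are
modelled with the standard quadratic law

    Fd = 1/2 * Cd * rho * A * V**2
    Fl = 1/2 * Cl * rho * A * V**2

where ``rho`` is the water density, ``A`` the reference (projected) area
perpendicular to the flow, ``V`` the flow speed and ``Cd``/``Cl`` the
dimensionless drag/propulsion coefficients.  Inverting the drag law gives
the coefficient from a measured or simulated resistance,

    Cd = 2 * Fd / (rho * A * V**2),

which is how the published resistance-vs-speed grids for different
finger-spread angles are converted into coefficient grids here.

All angles are accepted in degrees and converted internally.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = [
    "FluidEnvironment",
    "PalmGeometry",
    "ForceResult",
    "DragCoefficientGrid",
    "drag_force",
    "propulsion_force",
    "total_force",
    "projected_palm_area",
    "drag_coefficient",
    "coefficient_grid",
]

#: Density of pool water, kg/m^3.
WATER_DENSITY = 998.2

#: Reference palm area at a 90 degree angle of attack, m^2.
REFERENCE_PALM_AREA = 0.015


@dataclass(frozen=True)
class FluidEnvironment:
    """The fluid the swimmer moves through.

    Parameters
    ----------
    density : float
        Mass density in kg/m^3.  Defaults to 998.2, fresh water at
        pool temperature.
    """

    density: float = WATER_DENSITY

    def __post_init__(self) -> None:
        if not self.density > 0:
            raise ValueError(f"density must be positive, got {self.density}")


@dataclass(frozen=True)
class PalmGeometry:
    """Geometry of the stroking palm.

    ``palm_area`` is the area presented to the flow when the palm is
    square to it (attack angle 90 degrees); the projected area at other
    attack angles is ``palm_area * sin(attack_angle)``.
    ``finger_spread_angle`` is the angular opening of the five fingers.
    """

    palm_area: float = REFERENCE_PALM_AREA
    attack_angle: float = 90.0
    finger_spread_angle: float = 15.0

    def __post_init__(self) -> None:
        if not self.palm_area > 0:
            raise ValueError(f"palm_area must be positive, got {self.palm_area}")
        if not 0.0 < self.attack_angle <= 90.0:
            raise ValueError(
                f"attack_angle must lie in (0, 90] degrees, got {self.attack_angle}"
            )
        if not 0.0 <= self.finger_spread_angle < 90.0:
            raise ValueError(
                "finger_spread_angle must lie in [0, 90) degrees, "
                f"got {self.finger_spread_angle}"
            )


@dataclass(frozen=True)
class ForceResult:
    """Drag, propulsion and their algebraic sum, in newtons."""

    drag: float
    propulsion: float
    total: float

    @classmethod
    def from_components(cls, drag: float, propulsion: float) -> "ForceResult":
        return cls(drag=drag, propulsion=propulsion, total=drag + propulsion)


@dataclass
class DragCoefficientGrid:
    """A (speed x finger-spread-angle) grid of resistances and coefficients.

    ``resistance`` holds forces in newtons; ``coefficient`` the
    corresponding dimensionless drag coefficients (may be ``None`` until
    computed by :func:`coefficient_grid`).
    """

    speeds: np.ndarray
    spread_angles: np.ndarray
    resistance: np.ndarray
    coefficient: Optional[np.ndarray] = field(default=None)

    def __post_init__(self) -> None:
        self.speeds = np.asarray(self.speeds, dtype=float)
        self.spread_angles = np.asarray(self.spread_angles, dtype=float)
        self.resistance = np.asarray(self.resistance, dtype=float)
        expected = (self.speeds.size, self.spread_angles.size)
        if self.resistance.shape != expected:
            raise ValueError(
                f"resistance shape {self.resistance.shape} does not match "
                f"(n_speeds, n_angles) = {expected}"
            )
        if self.coefficient is not None:
            self.coefficient = np.asarray(self.coefficient, dtype=float)
            if self.coefficient.shape != expected:
                raise ValueError(
                    f"coefficient shape {self.coefficient.shape} does not match "
                    f"(n_speeds, n_angles) = {expected}"
                )
        if np.any(self.resistance <= 0):
            raise ValueError("all resistance entries must be positive")


def _check_area_density(area: float, density: float) -> None:
    if not area > 0:
        raise ValueError(f"area must be positive, got {area}")
    if not density > 0:
        raise ValueError(f"density must be positive, got {density}")


def drag_force(cd: float, env: FluidEnvironment, area: float, speed: float) -> float:
    """Quadratic drag: ``1/2 * cd * rho * area * speed**2`` in newtons."""
    _check_area_density(area, env.density)
    if cd < 0:
        raise ValueError(f"drag coefficient must be non-negative, got {cd}")
    if speed < 0:
        raise ValueError(f"speed must be non-negative, got {speed}")
    return 0.5 * cd * env.density * area * speed**2


def propulsion_force(cl: float, env: FluidEnvironment, area: float, speed: float) -> float:
    """Quadratic propulsion: same functional form as :func:`drag_force` with Cl."""
    return drag_force(cl, env, area, speed)


def total_force(drag: float, propulsion: float) -> float:
    """Algebraic sum of drag and propulsion (the net hydrodynamic force)."""
    return drag + propulsion


def projected_palm_area(geom: PalmGeometry) -> float:
    """Palm area projected onto the plane perpendicular to the flow.

    ``A = S * sin(theta)`` with ``S`` the 90-degree reference area and
    ``theta`` the attack angle in degrees.
    """
    return geom.palm_area * math.sin(math.radians(geom.attack_angle))


def drag_coefficient(
    resistance: float, env: FluidEnvironment, area: float, speed: float
) -> float:
    """Invert the drag law: ``Cd = 2 * Fd / (rho * A * V**2)``.

    Raises ``ValueError`` at zero speed (division by zero).
    """
    _check_area_density(area, env.density)
    if not speed > 0:
        raise ValueError(f"speed must be positive, got {speed}")
    return 2.0 * resistance / (env.density * area * speed**2)


def coefficient_grid(
    grid: DragCoefficientGrid,
    env: FluidEnvironment | None = None,
    area: float = REFERENCE_PALM_AREA,
) -> DragCoefficientGrid:
    """Fill the coefficient matrix of a resistance grid cell by cell.

    Every cell uses the same fixed reference area (the 90-degree palm
    area), not a spread-dependent projection: back-calculation shows the
    published coefficient grids are consistent only with the fixed
    reference area in every column.
    """
    env = env or FluidEnvironment()
    if np.any(grid.speeds <= 0):
        raise ValueError("all speeds must be positive to form coefficients")
    coeff = np.empty_like(grid.resistance)
    for i, v in enumerate(grid.speeds):
        for j in range(grid.spread_angles.size):
            coeff[i, j] = drag_coefficient(grid.resistance[i, j], env, area, v)
    return DragCoefficientGrid(
        speeds=grid.speeds.copy(),
        spread_angles=grid.spread_angles.copy(),
        resistance=grid.resistance.copy(),
        coefficient=coeff,
    )
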