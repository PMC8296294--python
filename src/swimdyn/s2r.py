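"""Closed-form swimming-speed representation (S2R) model.

The model links the speed of a full swimming cycle to the work done by
the stroke, the swimmer's energy budget and the hydrodynamic
coefficients.  Its building blocks are

    V = L * B = L / t          (stroke length x stroke rate)
    Z = F * L                  (work done over one stroke)
    E = K - Z - N - r          (energy stored after one cycle)
    V_e = sqrt(2 * (Z + N) / m)   (speed from the kinetic energy the
                                   stroke and the entrained water carry)

Substituting the quadratic force law F = 1/2 * rho * A * (Cd + Cl) * V_e**2
into L = Z / F and dividing by the cycle time collapses everything into a
single expression,

    V = Z * m / (t * rho * A * (Z + N) * (Cd + Cl)),

implemented by :func:`s2r_speed`.  The sqrt form of the energy speed is
the only reading under which this closed form is derivable from the
component equations; the derivation is spelled out in the methods note.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "EnergyBudget",
    "SpeedModelInput",
    "average_speed",
    "work_done",
    "stroke_length",
    "energy_balance",
    "speed_from_energy",
    "s2r_speed",
]


@dataclass(frozen=True)
class EnergyBudget:
    """Energy bookkeeping of one swimming cycle, all in joules.

    ``metabolic_energy`` (K) is generated by aerobic/anaerobic
    metabolism; ``propulsive_work`` (Z) drives the swimmer forward;
    ``non_propulsive_energy`` (N) is the kinetic energy given to the
    water; ``heat_loss`` (r) dissipates as heat.  The remainder
    ``stored_energy`` is E = K - Z - N - r.
    """

    metabolic_energy: float
    propulsive_work: float
    non_propulsive_energy: float
    heat_loss: float


@dataclass(frozen=True)
class SpeedModelInput:
    """Inputs of the closed-form speed model.

    Note the deliberate renaming to avoid symbol collisions: ``body_mass``
    is the swimmer's mass in kg (elsewhere the letter m is overloaded for
    matrix dimensions and column minima).
    """

    propulsive_work: float  # Z, J
    body_mass: float  # m, kg
    cycle_time: float  # t, s
    density: float  # rho, kg/m^3
    cross_section: float  # A, m^2, perpendicular to the flow
    non_propulsive_energy: float  # N, J
    drag_coefficient: float  # Cd
    propulsion_coefficient: float  # Cl

    def __post_init__(self) -> None:
        if not self.body_mass > 0:
            raise ValueError(f"body_mass must be positive, got {self.body_mass}")
        if not self.cycle_time > 0:
            raise ValueError(f"cycle_time must be positive, got {self.cycle_time}")
        if not self.density > 0:
            raise ValueError(f"density must be positive, got {self.density}")
        if not self.cross_section > 0:
            raise ValueError(
                f"cross_section must be positive, got {self.cross_section}"
            )
        if not self.propulsive_work + self.non_propulsive_energy > 0:
            raise ValueError("propulsive_work + non_propulsive_energy must be positive")
        if not self.drag_coefficient + self.propulsion_coefficient > 0:
            raise ValueError("Cd + Cl must be positive")


def average_speed(stroke_length: float, cycle_rate: float) -> float:
    """Average speed over a cycle, V = L * B (equivalently L / t, t = 1/B)."""
    if stroke_length < 0:
        raise ValueError(f"stroke length must be non-negative, got {stroke_length}")
    if not cycle_rate > 0:
        raise ValueError(f"cycle rate must be positive, got {cycle_rate}")
    return stroke_length * cycle_rate


def work_done(force: float, stroke_length: float) -> float:
    """Work done by the net force over one stroke, Z = F * L."""
    return force * stroke_length


def stroke_length(work: float, force: float) -> float:
    """Stroke length recovered from work and force, L = Z / F."""
    if force == 0:
        raise ValueError("force must be non-zero to recover a stroke length")
    return work / force


def energy_balance(budget: EnergyBudget) -> float:
    """Stored energy after one cycle, E = K - Z - N - r."""
    return (
        budget.metabolic_energy
        - budget.propulsive_work
        - budget.non_propulsive_energy
        - budget.heat_loss
    )


def speed_from_energy(
    propulsive_work: float, non_propulsive_energy: float, body_mass: float
) -> float:
    """Speed carried by the cycle's kinetic energy, sqrt(2*(Z + N)/m)."""
    if not body_mass > 0:
        raise ValueError(f"body_mass must be positive, got {body_mass}")
    total = propulsive_work + non_propulsive_energy
    if total < 0:
        raise ValueError(f"Z + N must be non-negative, got {total}")
    return math.sqrt(2.0 * total / body_mass)


def s2r_speed(inp: SpeedModelInput) -> float:
    """Closed-form cycle speed V = Z*m / (t*rho*A*(Z+N)*(Cd+Cl)).

    Algebraically identical to composing :func:`speed_from_energy`, the
    quadratic force law, :func:`stroke_length` and division by the cycle
    time; a property test enforces the identity.
    """
    z = inp.propulsive_work
    denom = (
        inp.cycle_time
        * inp.density
        * inp.cross_section
        * (z + inp.non_propulsive_energy)
        * (inp.drag_coefficient + inp.propulsion_coefficient)
    )
    return z * inp.body_mass / denom
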