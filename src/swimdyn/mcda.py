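"""Improved TOPSIS ranking of swimming alternatives.

TOPSIS (Technique for Order Preference by Similarity to Ideal Solution)
scores each alternative by its relative closeness

    C_i = D_i^- / (D_i^+ + D_i^-)

to a positive ideal (column-wise best) and a negative ideal (column-wise
worst) of the vector-normalised decision matrix, with weighted Euclidean
separations

    D_i^+- = sqrt( sum_j w_j * (Z_j^+- - z_ij)^2 ).

The "improved" part is the positivisation step applied before
normalisation, which converts minimisation, intermediate-is-best and
interval-is-best criteria into maximisation form:

    minimize_reciprocal : x' = 1/x              (x > 0)
    minimize_subtract   : x' = max(x) - x
    intermediate        : tent map onto [0, 1], peaking at (max+min)/2
    interval            : 1 inside the best interval [a, b], linear decay
                          to 0 at the tolerable bounds (a*, b*), clamped

Here the alternatives are athletes/strokes and the criteria are joint
and link angles measured at the peak of the stroke cycle.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "Direction",
    "CriterionSpec",
    "DecisionMatrix",
    "TopsisResult",
    "DegenerateColumnError",
    "positivize",
    "vector_normalize",
    "ideal_solutions",
    "separations",
    "closeness",
    "rank_alternatives",
]

DIRECTIONS = (
    "maximize",
    "minimize_reciprocal",
    "minimize_subtract",
    "intermediate",
    "interval",
)

Direction = str


class DegenerateColumnError(ValueError):
    """A criterion column cannot be transformed or normalised."""


@dataclass(frozen=True)
class CriterionSpec:
    """One criterion: its optimisation direction and weight.

    For ``interval`` criteria, ``interval_bounds`` is
    ``(a, b, a_star, b_star)``: values in ``[a, b]`` are ideal, values
    beyond ``a_star``/``b_star`` intolerable (score 0).
    """

    name: str
    direction: Direction = "maximize"
    weight: float = 1.0
    interval_bounds: Optional[tuple[float, float, float, float]] = None

    def __post_init__(self) -> None:
        if self.direction not in DIRECTIONS:
            raise ValueError(
                f"unknown direction {self.direction!r}; expected one of {DIRECTIONS}"
            )
        if self.weight < 0:
            raise ValueError(f"weight must be non-negative, got {self.weight}")
        if self.direction == "interval":
            if self.interval_bounds is None:
                raise ValueError("interval direction requires interval_bounds")
            a, b, a_star, b_star = self.interval_bounds
            if not (a <= b and a_star < a and b_star > b):
                raise ValueError(
                    "interval_bounds must satisfy a_star < a <= b < b_star, "
                    f"got {self.interval_bounds}"
                )


@dataclass
class DecisionMatrix:
    """Alternatives x criteria matrix of raw criterion values."""

    alternatives: list[str]
    criteria: list[CriterionSpec]
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n, m = len(self.alternatives), len(self.criteria)
        if self.values.shape != (n, m):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"(n_alternatives, n_criteria) = {(n, m)}"
            )
        if n < 2:
            raise ValueError("need at least two alternatives to rank")
        if np.isnan(self.values).any():
            raise ValueError("decision matrix contains missing values")
        if not any(c.weight > 0 for c in self.criteria):
            raise ValueError("at least one criterion weight must be positive")

    @property
    def weights(self) -> np.ndarray:
        return np.array([c.weight for c in self.criteria], dtype=float)


@dataclass
class TopsisResult:
    """Full output of one TOPSIS run."""

    alternatives: list[str]
    normalized: np.ndarray
    ideal_best: np.ndarray
    ideal_worst: np.ndarray
    separation_best: np.ndarray
    separation_worst: np.ndarray
    closeness: np.ndarray
    rank: np.ndarray  # rank[i] = 1 for the best alternative


def positivize(column: Sequence[float], spec: CriterionSpec) -> np.ndarray:
    """Convert one criterion column to larger-is-better form."""
    x = np.asarray(column, dtype=float)
    d = spec.direction
    if d == "maximize":
        return x.copy()
    if d == "minimize_reciprocal":
        if np.any(x <= 0):
            raise DegenerateColumnError(
                f"criterion {spec.name!r}: reciprocal transform requires strictly "
                "positive values"
            )
        return 1.0 / x
    if d == "minimize_subtract":
        return x.max() - x
    if d == "intermediate":
        lo, hi = x.min(), x.max()
        if hi == lo:
            raise DegenerateColumnError(
                f"criterion {spec.name!r}: intermediate transform is undefined on a "
                "constant column"
            )
        mid = 0.5 * (hi + lo)
        span = hi - lo
        return np.where(x <= mid, 2.0 * (x - lo) / span, 2.0 * (hi - x) / span)
    # interval
    a, b, a_star, b_star = spec.interval_bounds  # type: ignore[misc]
    out = np.ones_like(x)
    below = x < a
    above = x > b
    out[below] = 1.0 - (a - x[below]) / (a - a_star)
    out[above] = 1.0 - (x[above] - b) / (b_star - b)
    # the linear arms go negative outside the tolerable interval; clamp
    return np.clip(out, 0.0, None)


def vector_normalize(X: np.ndarray) -> np.ndarray:
    """Divide every column by its Euclidean norm (output columns have norm 1)."""
    X = np.asarray(X, dtype=float)
    norms = np.linalg.norm(X, axis=0)
    if np.any(norms == 0):
        bad = int(np.flatnonzero(norms == 0)[0])
        raise DegenerateColumnError(f"column {bad} is all zero; cannot normalise")
    return X / norms


def ideal_solutions(Z: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Column-wise best (max) and worst (min) of the normalised matrix."""
    Z = np.asarray(Z, dtype=float)
    return Z.max(axis=0), Z.min(axis=0)


def separations(
    Z: np.ndarray,
    ideal_best: np.ndarray,
    ideal_worst: np.ndarray,
    weights: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Weighted Euclidean distances to the ideal best and worst points.

    The weights sit inside the square root:
    ``D_i = sqrt(sum_j w_j * (Z_j - z_ij)**2)``.
    """
    Z = np.asarray(Z, dtype=float)
    w = np.asarray(weights, dtype=float)
    if w.shape != (Z.shape[1],):
        raise ValueError(
            f"weights shape {w.shape} does not match {Z.shape[1]} criteria"
        )
    if np.any(w < 0):
        raise ValueError("weights must be non-negative")
    d_best = np.sqrt(((ideal_best - Z) ** 2 * w).sum(axis=1))
    d_worst = np.sqrt(((ideal_worst - Z) ** 2 * w).sum(axis=1))
    return d_best, d_worst


def closeness(separation_best: np.ndarray, separation_worst: np.ndarray) -> np.ndarray:
    """Relative closeness C = D^- / (D^+ + D^-), in [0, 1]."""
    d_plus = np.atleast_1d(np.asarray(separation_best, dtype=float))
    d_minus = np.atleast_1d(np.asarray(separation_worst, dtype=float))
    denom = d_plus + d_minus
    if np.any(denom == 0):
        raise DegenerateColumnError(
            "D+ + D- is zero for some alternative (all alternatives identical?)"
        )
    return d_minus / denom


def rank_alternatives(dm: DecisionMatrix) -> TopsisResult:
    """Run the full pipeline: positivise, normalise, ideal points, closeness.

    Ranks are by descending closeness; ties are broken stably in favour
    of the first-listed alternative.
    """
    pos = np.column_stack(
        [positivize(dm.values[:, j], spec) for j, spec in enumerate(dm.criteria)]
    )
    Z = vector_normalize(pos)
    z_best, z_worst = ideal_solutions(Z)
    d_best, d_worst = separations(Z, z_best, z_worst, dm.weights)
    C = closeness(d_best, d_worst)
    order = np.argsort(-C, kind="stable")
    rank = np.empty(len(C), dtype=int)
    rank[order] = np.arange(1, len(C) + 1)
    return TopsisResult(
        alternatives=list(dm.alternatives),
        normalized=Z,
        ideal_best=z_best,
        ideal_worst=z_worst,
        separation_best=d_best,
        separation_worst=d_worst,
        closeness=C,
        rank=rank,
    )
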