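"""Seeded generators for every input the analysis pipeline consumes.

Real inputs — athlete anthropometrics, stroke-cycle joint/link angles,
centre-of-gravity velocity curves, link angular-velocity curves and
CFD-derived resistance grids — are not redistributable, so each has a
generator that reproduces its statistical and feature structure:

* athlete tables with normally distributed height (1.85 +- 0.1 m) and
  weight (72 +- 13 kg), joint/link angles uniform over the observed
  ranges, and stroke labels drawn from a configurable mix;
* one-cycle centre-of-gravity velocity curves with a planted maximum
  followed by the characteristic sharp post-stroke drop (the body lift
  raises drag right after the arm stroke) and a partial recovery;
* link angular-velocity curves with a planted maximum peak, a shallow
  first valley and a planted deepest valley, supporting peak-to-valley
  timing fixtures;
* resistance grids generated from a known drag-coefficient model of
  speed, so the coefficient computation can be round-tripped exactly.

Every generator is a pure function of its config (seed included), and
returns the planted ground truth alongside the data so recovery can be
tested.  Planted event times are snapped to the sample grid, so at zero
noise the features sit exactly on samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np
from scipy.interpolate import PchipInterpolator

from .hydro import DragCoefficientGrid, FluidEnvironment, REFERENCE_PALM_AREA
from .kinematics import DEFAULT_SAMPLING_RATE, SampledCurve
from .mcda import CriterionSpec, DecisionMatrix

__all__ = [
    "STROKES",
    "AthleteRecord",
    "AthleteGeneratorConfig",
    "CurveGeneratorConfig",
    "PlantedFeatures",
    "generate_athlete_table",
    "generate_cog_velocity_curve",
    "generate_link_angular_velocity_curve",
    "generate_resistance_grid",
]

STROKES = ("breaststroke", "freestyle", "backstroke", "butterfly")

# observed composition of the 15-athlete reference sample
_DEFAULT_MIX = {
    "breaststroke": 6 / 15,
    "freestyle": 4 / 15,
    "backstroke": 3 / 15,
    "butterfly": 2 / 15,
}

_LEVELS = (
    "International swimming master",
    "Swimming master",
    "Swimming level 1",
    "Swimming level 2",
    "Swimming level 3",
)

ANGLE_COLUMNS = ("right_knee", "right_thigh", "right_calf", "finger_spread")


@dataclass(frozen=True)
class AthleteRecord:
    """One synthetic athlete: anthropometrics plus stroke-cycle angles."""

    athlete_id: str
    gender: str
    birth_year: int
    height: float  # m
    weight: float  # kg
    level: str
    stroke: str
    right_knee_angle: float  # deg, joint angle at the peak of the cycle
    right_thigh_link_angle: float  # deg, link axis vs vertical
    right_calf_link_angle: float  # deg
    finger_spread_angle: float  # deg


@dataclass(frozen=True)
class AthleteGeneratorConfig:
    """Conditions emulating the reference 15-athlete sample.

    Angle ranges are the observed ranges of the measured sample; angles
    are drawn uniformly within them (no distributional information
    beyond the range is available).  Height and weight are normal with
    the published mean +- one standard deviation.
    """

    n_athletes: int = 15
    stroke_mix: dict[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_MIX)
    )
    knee_angle_range: tuple[float, float] = (50.0, 68.0)
    thigh_link_range: tuple[float, float] = (-56.0, -38.0)
    calf_link_range: tuple[float, float] = (-186.0, -149.0)
    finger_angles: tuple[float, ...] = (15.0, 20.0, 25.0, 30.0)
    height_mean: float = 1.85
    height_sd: float = 0.1
    weight_mean: float = 72.0
    weight_sd: float = 13.0
    male_fraction: float = 13 / 15
    birth_year_range: tuple[int, int] = (1959, 1988)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_athletes < 1:
            raise ValueError("n_athletes must be at least 1")
        total = sum(self.stroke_mix.values())
        if not np.isclose(total, 1.0):
            raise ValueError(f"stroke_mix proportions must sum to 1, got {total}")
        for name in self.stroke_mix:
            if name not in STROKES:
                raise ValueError(f"unknown stroke {name!r}")
        for rng_ in (self.knee_angle_range, self.thigh_link_range, self.calf_link_range):
            if not rng_[0] < rng_[1]:
                raise ValueError(f"empty angle range {rng_}")
        if not self.finger_angles:
            raise ValueError("finger_angles must be non-empty")


@dataclass(frozen=True)
class CurveGeneratorConfig:
    """Shape parameters of one synthetic kinematic curve.

    Defaults emulate a one-second stroke cycle at 50 Hz with the
    velocity maximum mid-cycle and a post-peak drop of slightly more
    than half the peak value (peak velocities near 1.45 m/s dropping
    to roughly 0.65 m/s are typical of the measured cycles).
    """

    cycle_duration: float = 1.0  # s
    sampling_rate: float = DEFAULT_SAMPLING_RATE  # Hz
    peak_time: float = 0.5  # s
    peak_value: float = 1.45  # curve units
    post_peak_drop_fraction: float = 0.55
    noise_sd: float = 0.0  # curve units
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.peak_time < self.cycle_duration:
            raise ValueError("peak_time must lie strictly inside the cycle")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if not 0 <= self.post_peak_drop_fraction <= 1:
            raise ValueError("post_peak_drop_fraction must lie in [0, 1]")
        if not self.sampling_rate > 0:
            raise ValueError("sampling_rate must be positive")


@dataclass(frozen=True)
class PlantedFeatures:
    """Ground truth planted into a generated curve (times on the grid)."""

    peak_time: float
    peak_value: float
    valley_time: Optional[float] = None
    valley_value: Optional[float] = None


def _snap(t: float, rate: float) -> float:
    """Snap a time to the nearest sample instant."""
    return round(t * rate) / rate


def generate_athlete_table(
    cfg: AthleteGeneratorConfig,
) -> tuple[DecisionMatrix, list[AthleteRecord]]:
    """Synthetic athlete sample: a TOPSIS decision matrix plus full records.

    The decision matrix holds the four angle criteria (all-maximize,
    equal weights by default; re-specify criteria downstream for other
    configurations).  Identical config (seed included) gives identical
    output.
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_athletes
    heights = rng.normal(cfg.height_mean, cfg.height_sd, size=n)
    weights = rng.normal(cfg.weight_mean, cfg.weight_sd, size=n)
    knee = rng.uniform(*cfg.knee_angle_range, size=n)
    thigh = rng.uniform(*cfg.thigh_link_range, size=n)
    calf = rng.uniform(*cfg.calf_link_range, size=n)
    fingers = rng.choice(np.asarray(cfg.finger_angles, dtype=float), size=n)
    mix_names = list(cfg.stroke_mix)
    mix_p = np.array([cfg.stroke_mix[s] for s in mix_names])
    strokes = rng.choice(mix_names, size=n, p=mix_p)
    genders = np.where(rng.random(n) < cfg.male_fraction, "Male", "Female")
    birth_years = rng.integers(
        cfg.birth_year_range[0], cfg.birth_year_range[1] + 1, size=n
    )
    levels = rng.choice(_LEVELS, size=n)

    records = [
        AthleteRecord(
            athlete_id=f"S{i + 1}",
            gender=str(genders[i]),
            birth_year=int(birth_years[i]),
            height=float(heights[i]),
            weight=float(weights[i]),
            level=str(levels[i]),
            stroke=str(strokes[i]),
            right_knee_angle=float(knee[i]),
            right_thigh_link_angle=float(thigh[i]),
            right_calf_link_angle=float(calf[i]),
            finger_spread_angle=float(fingers[i]),
        )
        for i in range(n)
    ]
    matrix = DecisionMatrix(
        alternatives=[r.athlete_id for r in records],
        criteria=[
            CriterionSpec(name=c, direction="maximize", weight=1.0 / len(ANGLE_COLUMNS))
            for c in ANGLE_COLUMNS
        ],
        values=np.column_stack([knee, thigh, calf, fingers]),
    )
    return matrix, records


def _cycle_grid(cfg: CurveGeneratorConfig) -> np.ndarray:
    n = int(round(cfg.cycle_duration * cfg.sampling_rate)) + 1
    return np.arange(n) / cfg.sampling_rate


def generate_cog_velocity_curve(
    cfg: CurveGeneratorConfig,
) -> tuple[SampledCurve, PlantedFeatures]:
    """One-cycle centre-of-gravity horizontal velocity curve.

    Monotone-segment shape through control points: rise from a low
    baseline to ``peak_value`` at ``peak_time``, sharp drop by
    ``post_peak_drop_fraction`` shortly after the peak (drag rise from
    body lift), then partial recovery.  A monotone piecewise-cubic
    interpolant guarantees the global maximum sits exactly at the
    planted (grid-snapped) peak time when noise is zero.
    """
    t = _cycle_grid(cfg)
    tp = _snap(cfg.peak_time, cfg.sampling_rate)
    T = t[-1]
    baseline = 0.3 * cfg.peak_value
    trough = cfg.peak_value * (1.0 - cfg.post_peak_drop_fraction)
    knots = [0.0]
    vals = [baseline]
    # steep final rise into the peak (the stroke's propulsive burst),
    # which keeps the maximum well defined against measurement noise
    t_rise = _snap(tp - 0.2 * cfg.cycle_duration, cfg.sampling_rate)
    if 0.0 < t_rise < tp:
        knots.append(t_rise)
        vals.append(0.55 * cfg.peak_value)
    knots.append(tp)
    vals.append(cfg.peak_value)
    # sharp drop completed within ~15% of the cycle after the peak
    t_drop = _snap(min(tp + 0.15 * cfg.cycle_duration, 0.5 * (tp + T)),
                   cfg.sampling_rate)
    if tp < t_drop < T:
        knots.append(t_drop)
        vals.append(trough)
    knots.append(T)
    vals.append(min(0.5 * cfg.peak_value, cfg.peak_value))
    base = PchipInterpolator(knots, vals)(t)
    rng = np.random.default_rng(cfg.seed)
    y = base + rng.normal(0.0, cfg.noise_sd, size=t.size)
    curve = SampledCurve(values=y, sampling_rate=cfg.sampling_rate)
    truth = PlantedFeatures(peak_time=tp, peak_value=cfg.peak_value)
    return curve, truth


def generate_link_angular_velocity_curve(
    cfg: CurveGeneratorConfig, planted_valley_time: float
) -> tuple[SampledCurve, PlantedFeatures]:
    """Link angular-velocity curve with a planted peak and deepest valley.

    The curve starts and ends at zero, rises to ``peak_value`` at
    ``peak_time``, dips into a shallow first valley, then reaches its
    deepest (second) valley at ``planted_valley_time`` — the structure
    seen in measured calf-link curves, where the retraction burst is
    followed by the extension counter-rotation.
    """
    if not cfg.peak_time < planted_valley_time < cfg.cycle_duration:
        raise ValueError(
            "planted_valley_time must lie between peak_time and cycle end"
        )
    t = _cycle_grid(cfg)
    tp = _snap(cfg.peak_time, cfg.sampling_rate)
    tv = _snap(planted_valley_time, cfg.sampling_rate)
    T = t[-1]
    amp = cfg.peak_value
    deepest = -1.2 * amp
    shallow = -0.3 * amp
    t_mid = _snap(0.5 * (tp + tv), cfg.sampling_rate)
    knots = [0.0, tp]
    vals = [0.0, amp]
    # shallow first valley needs room on the grid between peak and deep valley
    if t_mid > tp and t_mid < tv:
        t_bump = _snap(0.5 * (t_mid + tv), cfg.sampling_rate)
        knots.append(t_mid)
        vals.append(shallow)
        if t_bump > t_mid and t_bump < tv:
            knots.append(t_bump)
            vals.append(0.2 * amp if amp != 0 else 0.0)
    knots.append(tv)
    vals.append(deepest)
    if tv < T:
        knots.append(T)
        vals.append(0.0)
    base = PchipInterpolator(knots, vals)(t) if amp != 0 else np.zeros_like(t)
    rng = np.random.default_rng(cfg.seed)
    y = base + rng.normal(0.0, cfg.noise_sd, size=t.size)
    curve = SampledCurve(values=y, sampling_rate=cfg.sampling_rate)
    truth = PlantedFeatures(
        peak_time=tp, peak_value=amp, valley_time=tv, valley_value=deepest
    )
    return curve, truth


def generate_resistance_grid(
    speeds: np.ndarray,
    spread_angles: np.ndarray,
    cd_model: Callable[[float], float],
    env: FluidEnvironment | None = None,
    area: float = REFERENCE_PALM_AREA,
) -> DragCoefficientGrid:
    """Resistance grid from a known drag-coefficient model of speed.

    Each cell holds ``Fd = 1/2 * cd_model(V) * rho * area * V**2``, so
    recomputing coefficients from the grid recovers ``cd_model`` at the
    grid speeds exactly.  Realistic models are decreasing in speed
    (steeply at low speed, flattening at high speed).
    """
    env = env or FluidEnvironment()
    speeds = np.asarray(speeds, dtype=float)
    spread_angles = np.asarray(spread_angles, dtype=float)
    if np.any(speeds <= 0):
        raise ValueError("all speeds must be positive")
    cds = np.array([cd_model(float(v)) for v in speeds])
    fd = 0.5 * cds[:, None] * env.density * area * speeds[:, None] ** 2
    fd = np.broadcast_to(fd, (speeds.size, spread_angles.size)).copy()
    return DragCoefficientGrid(
        speeds=speeds, spread_angles=spread_angles, resistance=fd
    )
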