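"""Timing analysis of stroke-cycle kinematic curves.

Works on uniformly sampled series (50 Hz by default): centre-of-gravity
horizontal velocity within one stroke cycle, body-link angles and their
angular velocities.  Provides cubic smoothing-spline denoising,
finite-difference differentiation, prominence-gated peak/valley
detection, and the two timing metrics of interest in arm-leg
coordination analysis:

* the signed lag between the leg-retraction event and the moment of
  maximum centre-of-gravity velocity (negative = the legs were retracted
  before the velocity peaked, the "early retraction" pattern), and
* the duration from an angular-velocity curve's maximum peak to the
  deepest valley that follows it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.interpolate import UnivariateSpline
from scipy.signal import find_peaks

__all__ = [
    "SampledCurve",
    "CurveFeatures",
    "TimingReport",
    "FeatureNotFoundError",
    "smooth",
    "differentiate",
    "find_extrema",
    "leg_retraction_lag",
    "peak_to_valley_duration",
]

DEFAULT_SAMPLING_RATE = 50.0  # Hz, video and speedometer acquisition rate

#: Default extremum prominence threshold as a fraction of the curve range.
DEFAULT_PROMINENCE_FRACTION = 0.05


class FeatureNotFoundError(LookupError):
    """A requested curve feature (peak, valley) does not exist."""


@dataclass
class SampledCurve:
    """A uniformly sampled kinematic series.

    ``values`` may be m/s (velocities), degrees (angles) or rad/s
    (angular velocities); the operations do not care, except
    :func:`differentiate` which assumes degrees in and returns rad/s.
    """

    values: np.ndarray = field(repr=False)
    sampling_rate: float = DEFAULT_SAMPLING_RATE
    start_time: float = 0.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("values must be one-dimensional")
        if self.values.size < 3:
            raise ValueError(f"need at least 3 samples, got {self.values.size}")
        if not self.sampling_rate > 0:
            raise ValueError(
                f"sampling_rate must be positive, got {self.sampling_rate}"
            )

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds."""
        return self.start_time + np.arange(self.values.size) / self.sampling_rate

    @property
    def span(self) -> float:
        """Duration covered by the samples, s."""
        return (self.values.size - 1) / self.sampling_rate


@dataclass
class CurveFeatures:
    """Detected peaks and valleys of one curve, in time order."""

    peak_times: np.ndarray
    peak_values: np.ndarray
    valley_times: np.ndarray
    valley_values: np.ndarray
    global_max_time: float


@dataclass
class TimingReport:
    """Arm-leg coordination timing metrics, in seconds."""

    leg_retraction_lag: Optional[float] = None
    peak_to_valley_duration: Optional[float] = None


def smooth(curve: SampledCurve, smoothing_parameter: float) -> SampledCurve:
    """Cubic smoothing-spline fit, evaluated back at the sample times.

    ``smoothing_parameter`` is the spline's residual budget (sum of
    squared residuals allowed); 0 reproduces the input exactly.
    """
    if smoothing_parameter < 0:
        raise ValueError("smoothing parameter must be non-negative")
    if curve.values.size < 4:
        raise ValueError("cubic spline smoothing needs at least 4 samples")
    t = curve.times
    spl = UnivariateSpline(t, curve.values, k=3, s=smoothing_parameter)
    return SampledCurve(
        values=spl(t), sampling_rate=curve.sampling_rate, start_time=curve.start_time
    )


def differentiate(angle_curve: SampledCurve) -> SampledCurve:
    """Angular velocity (rad/s) from a link-angle curve in degrees.

    Central differences in the interior, one-sided at the ends.
    """
    dt = 1.0 / angle_curve.sampling_rate
    omega = np.gradient(np.deg2rad(angle_curve.values), dt)
    return SampledCurve(
        values=omega,
        sampling_rate=angle_curve.sampling_rate,
        start_time=angle_curve.start_time,
    )


def find_extrema(
    curve: SampledCurve, min_prominence: Optional[float] = None
) -> CurveFeatures:
    """Local maxima and minima with prominence above a threshold.

    The default threshold is 5% of the curve's range, which suppresses
    sample-noise wiggles at the 50 Hz acquisition rate.  A monotone
    curve simply yields empty peak/valley lists.
    """
    y = curve.values
    if min_prominence is None:
        rng = float(y.max() - y.min())
        min_prominence = DEFAULT_PROMINENCE_FRACTION * rng
    if min_prominence < 0:
        raise ValueError("min_prominence must be non-negative")
    t = curve.times
    # find_peaks with prominence=0 rejects everything; use None for "any"
    kw = {"prominence": min_prominence} if min_prominence > 0 else {}
    peaks, _ = find_peaks(y, **kw)
    valleys, _ = find_peaks(-y, **kw)
    return CurveFeatures(
        peak_times=t[peaks],
        peak_values=y[peaks],
        valley_times=t[valleys],
        valley_values=y[valleys],
        global_max_time=float(t[int(np.argmax(y))]),
    )


def leg_retraction_lag(cog_velocity: SampledCurve, leg_event_time: float) -> float:
    """Signed lag of the leg-retraction event against the velocity maximum.

    Returns ``leg_event_time - argmax-time`` of the centre-of-gravity
    velocity curve; negative means the legs were retracted before the
    body reached peak speed.
    """
    t = cog_velocity.times
    if not t[0] <= leg_event_time <= t[-1]:
        raise ValueError(
            f"leg_event_time {leg_event_time} outside curve span "
            f"[{t[0]}, {t[-1]}]"
        )
    t_max = float(t[int(np.argmax(cog_velocity.values))])
    return leg_event_time - t_max


def peak_to_valley_duration(
    angular_velocity: SampledCurve, min_prominence: Optional[float] = None
) -> float:
    """Time from the maximum peak to the deepest valley after it.

    The "maximum peak" is the highest detected local maximum; the valley
    is the lowest local minimum occurring later in the cycle.  Raises
    :class:`FeatureNotFoundError` when either feature is absent.
    """
    feats = find_extrema(angular_velocity, min_prominence=min_prominence)
    if feats.peak_times.size == 0:
        raise FeatureNotFoundError("curve has no detectable peak")
    i_peak = int(np.argmax(feats.peak_values))
    t_peak = float(feats.peak_times[i_peak])
    after = feats.valley_times > t_peak
    if not after.any():
        raise FeatureNotFoundError("no valley follows the maximum peak")
    vt = feats.valley_times[after]
    vv = feats.valley_values[after]
    t_valley = float(vt[int(np.argmin(vv))])
    return abs(t_valley - t_peak)
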