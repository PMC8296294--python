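# Methods

## Palm drag model

Forces on the palm follow the standard quadratic law Fd = ½·Cd·ρ·A·V²
(and the same form with Cl for the propulsive component); the net
hydrodynamic force is their algebraic sum.  The projected palm area is
A = S·sin θ with S = 0.015 m² the palm area square to the flow and θ
the angle of attack in degrees.  Angles are degrees at every interface
and converted internally; this matches how the source measurements are
reported and avoids unit mix-ups at the CSV boundary.

The drag coefficient is computed as the inverse of the force law,
Cd = 2·Fd/(ρ·A·V²).  The source material also prints the reciprocal
expression (ρ·A·V²/(2·Fd)) for the hand's coefficient; that form is
inconsistent with every cell of the published resistance/coefficient
grid, which back-calculates exactly (to within rounding) under the
conventional definition.  The conventional definition is therefore
implemented, and this note records the discrepancy.

When converting a resistance grid to coefficients, every finger-spread
column uses the fixed 0.015 m² reference area rather than a
spread-dependent projection.  Back-calculation shows the published grid
is consistent only with the fixed reference area in all four columns;
whether the underlying CFD used a spread-dependent area internally is
unknowable from the printed table.  Residual deviations up to ±0.02
(~1%) are attributed to the "approximately 0.015 m²" reference area and
two-decimal rounding of the printed values; the reproduction test uses
±0.02 absolute.

## Speed model

The cycle speed is assembled from V = L·B (equivalently L/t), work
Z = F·L, the energy budget E = K − Z − N − r, and the energy-balance
speed.  The published energy-balance expression is typeset ambiguously
("V = 2(Z+N)m"); it is read as V = √(2(Z+N)/m), the kinetic-energy
form, because that is the only reading under which the closed form

    V = Z·m / (t·ρ·A·(Z+N)·(Cd+Cl))

is derivable: substituting V_e = √(2(Z+N)/m) into
F = ½·ρ·A·(Cd+Cl)·V_e² gives F = ρ·A·(Cd+Cl)·(Z+N)/m, hence
L = Z/F = Z·m/(ρ·A·(Cd+Cl)·(Z+N)) and V = L/t, which is exactly the
closed form.  A property test enforces this composition identity at
1e−12 relative error on randomised valid inputs, so the two readings
cannot silently diverge.

The source overloads the letter *m* (body mass, criteria count, column
minimum) and writes heat loss both as lowercase r and uppercase R; the
package gives every symbol a distinct named field and treats the heat
term as one quantity.  No procedure exists for estimating Z, N, K or r
from physiological measurements, so the model is exposed as a pure
function of its parameters.

## Improved TOPSIS

The ranking pipeline is: per-column positivisation → column-wise
Euclidean (vector) normalisation → ideal best/worst = column max/min →
weighted Euclidean separations with the weights inside the square
root → closeness C = D⁻/(D⁺+D⁻) → descending sort with stable
tie-breaking (first-listed wins, for determinism).

Positivisation choices:

* Two minimisation transforms exist (reciprocal and subtract-from-max)
  with no stated rule for when each applies.  Both are exposed;
  subtract-from-max is the recommended default since it is linear and
  defined for zero/negative values, while the reciprocal fails there.
* The intermediate transform is the tent map 2(x−min)/(max−min) below
  the midpoint and 2(max−x)/(max−min) above it, undefined on a constant
  column (raised as a degenerate-column error).
* The interval transform scores 1 inside the best interval [a, b] and
  decays linearly to 0 at the tolerable bounds (a\*, b\*).  The raw
  linear arms go negative beyond the tolerable bounds, so the score is
  clamped at 0 there.

Criterion weights are never published for the athlete rankings; the
default is equal weights, overridable via the YAML criteria config.
Which angle columns feed a "speed" versus a "thrust" ranking, and with
which directions, is likewise unpublished, so both are user
configuration; the packaged `criteria_example.yaml` documents one
defensible configuration rather than claiming to be *the*
configuration.

The published per-athlete score tables are internally inconsistent:
applying C = D⁻/(D⁺+D⁻) to their own printed separation columns does
not return the printed scores (first athlete: 0.1611 vs printed
0.4421).  The formula is treated as authoritative, the printed tables
are not used as oracles, and a dedicated test asserts the discrepancy
so it cannot be "fixed" silently.  Per-alternative scores can be
aggregated by stroke downstream, but no statistical claim about which
stroke is best is built in.

## Kinematics

The acquisition model is 50 Hz uniformly sampled series.  The analysis
software behind the original measurements is named but its algorithms
are not, so the standard reconstruction is used, each step
parameterised:

* **Smoothing** — cubic smoothing spline, with the smoothing parameter
  the residual budget (scipy's `UnivariateSpline` convention); 0
  reproduces the input exactly, and the conventional choice is
  n·σ² for noise level σ.
* **Differentiation** — central differences in the interior, one-sided
  at the ends, with degrees converted to rad/s.
* **Extrema** — prominence-gated local maxima/minima; the default
  threshold is 5% of the curve range, which suppresses noise-scale
  wiggles at 50 Hz without rejecting genuine features.  Monotone curves
  return empty feature lists rather than erroring.

The leg-retraction lag is signed (event time minus velocity-maximum
time): negative means the legs were retracted before the body reached
peak speed.  The source reports magnitudes only; the sign is added
because the direction carries the coaching content.  The peak-to-valley
duration is measured from the highest detected peak to the lowest
valley occurring after it, raising a not-found error when no such
valley exists.

## Synthetic data

Real stroke-cycle curves and the original athletes' raw data are not
redistributable, so generators reproduce the structure the pipeline
consumes, with planted ground truth returned alongside:

* **Athletes** — height ~ N(1.85, 0.1²) m and weight ~ N(72, 13²) kg
  (the published "±" values read as one standard deviation, the
  conventional interpretation, overridable); joint/link angles uniform
  over the observed ranges (knee 50–68°, thigh −56 to −38°, calf −186
  to −149°, finger spread in {15, 20, 25, 30}°), since no
  distributional information beyond the ranges exists; stroke labels
  from a configurable mix defaulting to the observed 6:4:3:2
  breaststroke:freestyle:backstroke:butterfly composition.
* **Velocity curves** — a monotone piecewise-cubic (PCHIP) backbone
  through control points: baseline 30% of peak, a steep rise into the
  peak over the last fifth of the pre-peak phase (the stroke's
  propulsive burst), a sharp drop by the configured fraction within
  ~15% of the cycle after the peak (drag rise from body lift), then
  partial recovery to 50% of peak.  Defaults: 1 s cycle, 50 Hz, peak
  1.45 m/s at mid-cycle, 55% drop — matching the magnitudes typical of
  measured cycles (peaks ≈ 1.3–1.6 m/s falling to ≈ 0.5–0.8 m/s).
  PCHIP does not overshoot, and planted times are snapped to the sample
  grid, so at zero noise every planted extremum sits exactly on a
  sample.  Gaussian noise is added from the config seed.
* **Angular-velocity curves** — same backbone idea with a planted
  maximum peak, a shallow first valley, a small rebound, and the
  planted deepest (second) valley, the structure seen in measured
  calf-link curves.
* **Resistance grids** — Fd = ½·cd_model(V)·ρ·A·V² per cell for a
  caller-supplied coefficient model, so coefficient recomputation
  round-trips the model exactly.

What passing tests on synthetic data do and do not show: they verify
that the feature-extraction machinery recovers planted truth under the
stated noise (exact on the grid noise-free; within ±2 samples at 5%
noise after spline smoothing) and that the pipeline's algebra is
correct.  They do not validate the generators as biomechanical
simulations — the curves reproduce feature structure (peak placement,
drop sharpness, valley ordering), not muscle or fluid dynamics — and
recovery on real footage with soft-tissue artefacts, digitisation error
or non-Gaussian noise may be worse.

## Numerical choices and problem sizes

Determinism: all generators are pure functions of their config
including the seed (`numpy.random.default_rng`); the pipeline derives
per-stage seeds from one top-level seed; rank ties break by row order.
Degenerate inputs (zero columns, constant columns under the tent map,
identical alternatives, zero speeds, monotone curves where a valley is
required) raise typed errors rather than returning NaNs.

The randomised checks use 1000 parameter draws for the speed-model
identity, 50–100 random matrices for TOPSIS oracle agreement, and
1000 synthetic athletes for the moment checks — sizes at which the
law-of-large-numbers bounds (3σ/√n) are tight enough to be meaningful
while the whole suite runs in seconds.

## Known limitations

* CFD is out of scope: resistance grids are consumed, never produced;
  the attack-angle dependence of the published coefficient-vs-speed
  curve families exists only graphically and is not reproduced.
* The speed model is never evaluated against a measured speed — no
  published parameter set exists — so only its internal algebra is
  testable.
* Per-athlete timing values from the original footage (0.02 s, 0.06 s,
  0.46 s, …) guide the synthetic fixtures' defaults but cannot be
  validated on real data without the raw curves.
* The TOPSIS criteria configuration shipping with the package is an
  example, not a reconstruction of the unpublished original one.
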