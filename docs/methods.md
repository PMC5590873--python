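# Methods

## Frames and transforms

All quantities live in a right-handed x-y-z frame with z along the
axial load axis. Three frames are distinguished and carried as
mandatory tags on every wrench: `transducer_origin` (where a six-axis
cell measures), `head_center` (displaced by `r = (Δx, Δy, Δz)`, where
all friction metrics are defined) and `taper` (rotated about +y by the
taper inclination `α`). The moment transfer is the exact rigid-body
relation `M = M0 − r × F`; the specialization for a centered rig
(`Δx = Δy = 0`) is provided separately because centering is part of
the measurement protocol, not an approximation. Mixing frames is an
error by construction: with in-plane forces of a few hundred newtons
and `Δz` of order 0.1 m, the transfer changes `Mx`/`My` by tens of Nm
— far above the friction signal.

Centering solves `dy = mean(Mx0)/mean(Fz)`, `dx = −mean(My0)/mean(Fz)`
under a static axial load (≥ 100 N by default; below that the
lever-arm torques drown in noise). The problem is linear, so the
closed form already nulls the mean torques; an optional iteration (≤ 5
rounds, 1e-9 m threshold) mirrors the load-translate-repeat procedure
used on a physical X/Y table.

The anatomical sign convention (which rotation maps to which torque
axis) is not standardized across rigs; this package fixes
extension-flexion about x, abduction-adduction about y,
internal-external rotation about z, and documents rather than asserts
the phase relations between channels.

`Δz` is rig-specific and defaults to 0.15 m (a plausible
chamber-plus-fixture height); it is configurable everywhere it is
used.

## Pendulum model

Equation of motion `J φ̈ = −W s sin φ ∓ M_f` with the friction torque
opposing the angular velocity. `W = mg` is the arm weight (default
2000 N), `s` the fulcrum-to-center-of-gravity distance (default
0.238 m), and `J` the moment of inertia — never measured directly,
derived by default from the small-angle frequency `f` (default
0.75 Hz) via `J = W s/(2π f)²` and flagged as derived.

The small-angle solution per half cycle is a cosine about a shifted
equilibrium `±A`, `A = M_f/(W s)`, giving the signed peak recursion
`a_{k+1} = −(a_k − 2A·sign a_k)` and motion until `|a_k| ≤ A`. A final
same-sign turnaround (the arm failing to cross the equilibrium before
sticking) falls out of the same recursion.

**Integrator.** Fixed-step classical Runge-Kutta at ≥ 4096 steps/s
(and ≥ 4× the output rate), friction sign held constant between
zero-velocity events to prevent chattering, each turnaround located by
80 bisection steps on the step size, and the static stick condition
`|W s sin φ| ≤ M_f` checked at every turnaround. The work-energy
audit (energy lost per half cycle = `M_f` × angle swept) closes to a
few 1e-3 relative, limited by the linear interpolation onto the output
grid, not the integrator.

**Peak detection.** The oscillation frequency is estimated from the
FFT, the trace Savitzky-Golay smoothed (window ≈ 1/8 period, order 3),
and extrema located with a prominence gate of 6× the smoothing
residual so sensor noise cannot spawn spurious peaks. Each peak is
refined by a quartic least-squares fit of the raw samples over ±0.06
periods; the quartic keeps the truncation bias of the vertex value
below 1e-6 rad while a plain parabola would already bias it at the
1e-3 level. Near the release boundary the window is completed by even
reflection about t = 0 (legitimate because a release from rest has
φ̇(0) = 0). Peak timing for extrema whose amplitude approaches the
noise scale is intrinsically noise-limited; tests therefore assert
timing accuracy for peaks above 2°.

**Friction estimation.** Two estimators, both reported. The envelope
regression takes the least-squares slope of |peak| vs half-cycle index
(after truncating any trailing same-sign turnaround, which would break
the linear recursion) and maps it through `M_f = W s · |slope|/2`; it
is the fast screening estimator. The full-trace least squares fits the
stitched analytic solution over `(M_f, release amplitude)`, trying
both release sides, initialized from the envelope; the objective is
the sum of squared angle residuals over the whole trace (the
literature's "best fit" never states its objective; this is the
natural choice). Because the analytic model is the small-angle
linearization, it over-reads `M_f` by ≈ 2% for a 30° release; the fit
is therefore debiased by simulating the nonlinear ODE at the fitted
parameters, re-fitting that trace with the same small-angle model, and
subtracting the measured estimator bias — exact to first order and
negligible at small amplitudes. A non-decaying envelope returns
`M_f = 0` with a warning rather than an error. At least 3 alternating
peaks are required (2 decrements); high-friction releases can stick
after exactly 3 turnarounds.

Recovery performance under the study conditions (5° release, 1024 Hz):
injected torques of 1–8 Nm come back within ≈ 0.01% on clean traces
and well under 1% with 0.05° Gaussian angle noise.

## Gait analysis

Cycles are exact `1/f` slices starting at the heel strike (0% of
cycle); a trailing partial cycle is dropped. Per cycle: resultant
torque (pythagorean sum, rotation invariant), its maximum and cycle
position in percent, component maxima (of absolute value), and
taper-axis extrema/peak-to-peak after the `α` rotation. Aggregation
over the last k cycles reports mean and sample SD (SD = 0 for k = 1,
where scatter is undefined).

The running-in schedule samples cycles 1, 10, 25, 50, 75, then every
100. The plateau rule is this package's own (the observed behaviour —
a plateau after roughly 200–400 cycles — comes without a criterion):
leading-window running means of length 3 must change by less than 1%
relative for every subsequent window; the onset is the first sampled
cycle where that holds, and a never-settling curve returns a
none-marker. The rule is invariant under uniform scaling of the curve.

Literature torques measured at other head diameters and loads are
placed on a common footing by assuming torque linear in diameter and
in axial load: piecewise-linear interpolation between the two nearest
known diameters, then multiplication by the load ratio. Two-nearest
interpolation (not a global regression) is what reproduces the
published 5.53 Nm benchmark at 40 mm; extrapolation outside the known
diameter range is refused. Rounding to two decimals happens only at
the report layer.

## Synthetic rig

The generator's defaults are the study conditions. Walking kinematics:
extension-flexion −18…+25°, abduction-adduction −4…+7°,
internal-external rotation −2…+10°, axial load 0.3–3.0 kN at 1 Hz.
The licensed standard waveform tables are not reproduced; angles are
single sinusoids and the load is a two-bump periodic profile (von
Mises-style kernels, exactly periodic, rescaled to hit the extrema
exactly) with peaks near 12.5% and 50% of the cycle. Extension-flexion
modes: ±25° at 0.75 Hz under a static 2 kN, or ±20° at 1 Hz under an
in-vivo-like 0.24–1.95 kN profile.

Friction synthesis is velocity-direction Coulomb with tanh
regularization (width 0.05 rad/s), chosen because the observed damping
is speed-independent: `M = −μ R_eff F(t) tanh(|ω|/w) ω/|ω|` with the
angular velocity assembled from the three rotation rates. Defaults
`μ = 0.09`, `R_eff = 0.018 m` put the peak resultant at
`μ R_eff F_max ≈ 4.9 Nm` under the 3 kN walking load — inside the
measured range for ceramic-on-polyethylene bearings of this size
class. Optional running-in multiplies `μ` by `1 + 0.3·e^(−c/100)`
(cycle c), which under the 1% plateau rule yields an onset near cycle
300, matching the reported 200–400-cycle settling. Sensor noise
defaults (torque 0.05 Nm, force 0.2 N, inclinometer 0.05°) are sized
from the quoted transducer accuracy class (±0.02% of a ~1.1 kN /
56 Nm full scale) and the reported 0.2 Nm resultant detection limit.
Small sinusoidal in-plane forces (25 N) stand in for lateral rig
dynamics so the `Δz` lever-arm coupling is actually exercised.

What the generator does *not* emulate: lubrication-regime (lambda
ratio) physics, serum rheology and temperature, squeeze-film effects
under dynamic load, centrifugal and vibration artefacts of a physical
pendulum, transducer crosstalk, and wear. Passing tests therefore
demonstrate that the *analysis* is correct for Coulomb-type friction
under the standard kinematics — not that a real bearing behaves like
the Coulomb model.

All randomness flows from the single seed in `NoiseSpec`; generators
are pure functions of configuration plus seed, and procedure runs are
byte-identical for identical config and seed.

## Numerical choices

- Data-rate reduction by non-overlapping block means (1024 → 256 Hz by
  default). Block means are adequate anti-aliasing for the ≤ 5-harmonic
  gait signals (per-cycle maxima shift by < 0.5%); timestamps keep the
  block's left edge so cycle boundaries remain on sample instants.
- CSV round trips are exact: 17-significant-digit output and
  round-trip float parsing on input.
- Uniform-step validation at 1e-9 relative; frame tags validated on
  every container.
- `least_squares` tolerances at 1e-14; fit bounds `M_f ≥ 0`,
  release amplitude in (0, π/2).

## Problem sizes

Default procedure sizes follow the emulated protocols: 1000 walking
cycles (five trials of 1000 for repeatability), 60 extension-flexion
cycles with the last 10 analysed, 10 zero-friction cycles, pendulum
decay to stick at 1024 Hz. The acceptance script runs the full
1000-cycle walking test and the 2 × 8-point recovery grid in seconds.

## Known limitations

- The Coulomb synthesis torque is anti-parallel to the angular
  velocity, which makes the synthetic taper torque pattern differ in
  detail from measured bearings (real contact mechanics distribute the
  torque differently across axes); component-level comparisons with
  hardware data are therefore qualitative.
- The analytic pendulum model is the small-angle linearization;
  beyond ~30° release the ODE-based debias step carries the accuracy.
- The plateau criterion and the running-in time constant are
  conventions, not measurements; both are configurable.
- `repeatability` trial scatter (8% relative on μ) is a modelling
  choice sized to the reported trial-to-trial SDs, not a calibrated
  rig property.
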