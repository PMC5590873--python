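"""Coulomb-damped physical pendulum: simulation and friction estimation.

The bearing under test forms the fulcrum of a gravity-driven pendulum
with arm weight W = m*g and lever arm s.  A constant-magnitude friction
torque Mf opposes the angular velocity, giving the equation of motion

    J * phi''(t) = -W*s*sin(phi) -+ Mf

whose small-angle solution is a cosine about a shifted equilibrium
+-A, with A = Mf/(W*s) and omega = sqrt(W*s/J) = 2*pi*f.  The peak
amplitude then decreases by exactly 2A per half cycle -- the hallmark
linear (speed-independent) decay of Coulomb damping -- until the
restoring torque can no longer overcome friction and the arm sticks.

Two friction estimators are provided: a fast envelope regression
(slope of |peak| vs half-cycle index = -2A) and a full-trace least
squares of the stitched analytic solution, initialized from the
envelope.  The nonlinear ODE integrator serves as ground truth for
both; the analytic form is the fitting model, mirroring the small
(<= 30 degree) amplitudes of a physical screening rig.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares
from scipy.signal import find_peaks, savgol_filter

__all__ = [
    "PendulumParams",
    "AngleTrace",
    "FrictionFit",
    "InsufficientDataError",
    "simulate_pendulum_ode",
    "analytic_pendulum",
    "peak_sequence",
    "envelope_peaks",
    "fit_friction_torque",
]


class InsufficientDataError(ValueError):
    """Trace too short / too few oscillations for the requested analysis."""


@dataclass
class PendulumParams:
    """Physical constants of the pendulum rig.

    Parameters
    ----------
    weight : arm weight W = m*g in N (default 2000 N).
    lever_arm : distance s from the head center to the arm's center of
        gravity, in m (default 0.238 m).
    frequency : small-angle oscillation frequency f in Hz (default
        0.75 Hz); used to derive the inertia when none is given.
    friction_torque : Coulomb friction torque Mf about the fulcrum, Nm.
    initial_amplitude : release amplitude in rad (default 30 degrees).
    phase : 0 releases from +initial_amplitude, pi from the negative side.
    inertia : moment of inertia J in kg*m^2; if None it is derived from
        the frequency via J = W*s/(2*pi*f)^2 (derived, not measured).
    """

    weight: float = 2000.0
    lever_arm: float = 0.238
    frequency: float = 0.75
    friction_torque: float = 0.0
    initial_amplitude: float = math.radians(30.0)
    phase: float = 0.0
    gravity: float = 9.81
    inertia: float | None = None

    def __post_init__(self) -> None:
        if self.weight <= 0 or self.lever_arm <= 0 or self.frequency <= 0:
            raise ValueError("weight, lever_arm and frequency must be > 0")
        if self.friction_torque < 0:
            raise ValueError("friction torque must be >= 0")
        if not 0.0 < self.initial_amplitude < math.pi / 2:
            raise ValueError("initial amplitude must lie in (0, pi/2) rad")
        if self.phase not in (0.0, math.pi):
            raise ValueError("phase must be 0 or pi")
        if self.inertia is not None and self.inertia <= 0:
            raise ValueError("inertia must be > 0")

    @property
    def restoring_torque(self) -> float:
        """W*s, the gravity restoring torque per radian (small angle), Nm."""
        return self.weight * self.lever_arm

    @property
    def inertia_effective(self) -> float:
        if self.inertia is not None:
            return self.inertia
        return self.restoring_torque / (2.0 * math.pi * self.frequency) ** 2

    @property
    def omega(self) -> float:
        """Small-angle angular frequency sqrt(W*s/J), rad/s."""
        return math.sqrt(self.restoring_torque / self.inertia_effective)

    @property
    def amplitude_offset(self) -> float:
        """A = Mf/(W*s): equilibrium shift and half the per-half-cycle decay."""
        return self.friction_torque / self.restoring_torque


@dataclass
class AngleTrace:
    """Uniformly sampled pendulum inclination angle, radians."""

    t: np.ndarray
    phi: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.t = np.ascontiguousarray(self.t, dtype=float)
        self.phi = np.ascontiguousarray(self.phi, dtype=float)
        if self.t.ndim != 1 or self.t.shape != self.phi.shape:
            raise ValueError("t and phi must be 1-D arrays of equal length")
        if self.t.shape[0] >= 2 and np.any(np.diff(self.t) <= 0):
            raise ValueError("time must be strictly increasing")
        if np.any(np.abs(self.phi) >= math.pi / 2):
            raise ValueError("|phi| must stay below pi/2")

    def __len__(self) -> int:
        return self.t.shape[0]

    @property
    def rate(self) -> float:
        return 1.0 / float(self.t[1] - self.t[0])


def simulate_pendulum_ode(p: PendulumParams, duration: float,
                          rate: float = 1024.0,
                          steps_per_second: float = 4096.0) -> AngleTrace:
    """Integrate the nonlinear Coulomb-damped pendulum.

    Fixed-step classical Runge-Kutta at ``steps_per_second`` (at least
    4096 and at least 4x the output rate), with the friction sign held
    constant between zero-velocity events and each turnaround located by
    bisection on the step size.  At a turnaround the arm sticks when the
    static condition ``|W*s*sin(phi)| <= Mf`` holds; the rest angle is
    retained for the remainder of the trace.

    A release from an amplitude already inside the stick cone is valid
    and flagged via ``meta['immediate_stick']``.

    Returns an :class:`AngleTrace` sampled at ``rate`` with
    ``meta['turnarounds']`` holding the (time, angle) of every
    zero-velocity event including the release point.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    sps = max(float(steps_per_second), 4.0 * rate, 4096.0)
    h = 1.0 / sps
    Ws = p.restoring_torque
    Mf = p.friction_torque
    J = p.inertia_effective
    sgn0 = 1.0 if p.phase == 0.0 else -1.0

    phi = sgn0 * p.initial_amplitude
    t = 0.0
    ts = [0.0]
    phis = [phi]
    turn_t = [0.0]
    turn_phi = [phi]
    stuck = False
    immediate = False

    def accel(ph: float, sig: float) -> float:
        return (-Ws * math.sin(ph) - sig * Mf) / J

    def step(ph: float, v: float, hh: float, sig: float) -> tuple[float, float]:
        k1v = accel(ph, sig)
        k2p = v + 0.5 * hh * k1v
        k2v = accel(ph + 0.5 * hh * v, sig)
        k3p = v + 0.5 * hh * k2v
        k3v = accel(ph + 0.5 * hh * k2p, sig)
        k4p = v + hh * k3v
        k4v = accel(ph + hh * k3p, sig)
        return (ph + hh * (v + 2.0 * k2p + 2.0 * k3p + k4p) / 6.0,
                v + hh * (k1v + 2.0 * k2v + 2.0 * k3v + k4v) / 6.0)

    while t < duration:
        if abs(Ws * math.sin(phi)) <= Mf:
            stuck = True
            immediate = len(turn_t) == 1
            break
        sig = -1.0 if phi > 0.0 else 1.0  # impending velocity direction
        v = 0.0
        while t < duration:
            ph1, v1 = step(phi, v, h, sig)
            if v1 * sig <= 0.0:  # crossed the turnaround inside this step
                lo, hi = 0.0, h
                for _ in range(80):
                    mid = 0.5 * (lo + hi)
                    _, vm = step(phi, v, mid, sig)
                    if vm * sig <= 0.0:
                        hi = mid
                    else:
                        lo = mid
                ph1, _ = step(phi, v, hi, sig)
                t += hi
                phi, v = ph1, 0.0
                ts.append(t)
                phis.append(phi)
                turn_t.append(t)
                turn_phi.append(phi)
                break
            t += h
            phi, v = ph1, v1
            ts.append(t)
            phis.append(phi)

    n_out = int(round(duration * rate))
    t_out = np.arange(n_out + 1) / rate
    phi_out = np.interp(t_out, ts, phis)  # holds the rest angle beyond stick
    meta = {
        "turnarounds": np.column_stack([turn_t, turn_phi]),
        "stuck": stuck,
        "immediate_stick": immediate,
        "rest_angle": phi if stuck else None,
    }
    return AngleTrace(t=t_out, phi=phi_out, meta=meta)


def _signed_amplitudes(a0: float, A: float, max_halfcycles: int) -> list[float]:
    """Signed peak recursion a_{k+1} = -(a_k - 2A*sign(a_k)) while |a_k| > A."""
    amps: list[float] = []
    a = a0
    while abs(a) > A and len(amps) < max_halfcycles:
        amps.append(a)
        a = -(a - 2.0 * A * math.copysign(1.0, a))
    amps.append(a)  # rest angle / first amplitude failing the motion test
    return amps


def _eval_analytic(t: np.ndarray, omega: float, A: float, a0: float,
                   max_halfcycles: int | None = None) -> np.ndarray:
    """Stitched small-angle solution phi(t) for release from rest at a0."""
    t = np.asarray(t, dtype=float)
    Th = math.pi / omega
    n_needed = int(np.floor(t.max() / Th)) + 1
    if max_halfcycles is not None:
        n_needed = min(n_needed, max_halfcycles)
    amps = _signed_amplitudes(a0, A, n_needed)
    seg, rest = amps[:-1], amps[-1]
    if not seg:
        return np.full_like(t, rest)
    segs = np.asarray(seg)
    k = np.minimum((t / Th).astype(int), len(segs) - 1)
    ak = segs[k]
    sg = np.sign(ak)
    phi = (ak - A * sg) * np.cos(omega * (t - k * Th)) + A * sg
    return np.where(t < len(segs) * Th, phi, rest)


def peak_sequence(p: PendulumParams,
                  max_halfcycles: int = 10_000) -> np.ndarray:
    """Signed turnaround amplitudes predicted by the -2A-per-half-cycle
    recursion, starting at the release amplitude and ending with the rest
    angle."""
    a0 = (1.0 if p.phase == 0.0 else -1.0) * p.initial_amplitude
    return np.asarray(_signed_amplitudes(a0, p.amplitude_offset,
                                         max_halfcycles))


def analytic_pendulum(p: PendulumParams,
                      n_halfcycles: int | None = None,
                      rate: float = 1024.0,
                      duration: float | None = None) -> AngleTrace:
    """Sample the stitched small-angle analytic solution.

    Per half cycle k the motion is a cosine of amplitude (amp_k - A)
    about the shifted equilibrium sign(amp_k)*A, so successive peak
    amplitudes drop by exactly 2A until |amp| <= A, where the arm rests.
    Give either ``n_halfcycles`` (duration defaults to that many half
    periods) or an explicit ``duration``.
    """
    if n_halfcycles is None and duration is None:
        raise ValueError("give n_halfcycles or duration")
    Th = math.pi / p.omega
    if duration is None:
        duration = n_halfcycles * Th
    n_out = int(round(duration * rate))
    t = np.arange(n_out + 1) / rate
    a0 = (1.0 if p.phase == 0.0 else -1.0) * p.initial_amplitude
    phi = _eval_analytic(t, p.omega, p.amplitude_offset, a0,
                         max_halfcycles=n_halfcycles)
    amps = _signed_amplitudes(
        a0, p.amplitude_offset,
        n_halfcycles if n_halfcycles is not None
        else int(np.floor(duration / Th)) + 1)
    peaks = np.column_stack([np.arange(len(amps) - 1) * Th, amps[:-1]])
    return AngleTrace(t=t, phi=phi,
                      meta={"peaks": peaks, "rest_angle": amps[-1]})


def _dominant_frequency(t: np.ndarray, phi: np.ndarray, rate: float) -> float:
    x = phi - phi.mean()
    spec = np.abs(np.fft.rfft(x * np.hanning(len(x))))
    freqs = np.fft.rfftfreq(len(x), 1.0 / rate)
    if len(spec) < 3:
        raise InsufficientDataError("trace too short for frequency estimation")
    k = int(np.argmax(spec[1:])) + 1
    f_est = float(freqs[k])
    if f_est <= 0:
        raise InsufficientDataError("could not identify an oscillation frequency")
    return f_est


def envelope_peaks(tr: AngleTrace,
                   fit_halfwidth: float = 0.06) -> np.ndarray:
    """Locate the signed oscillation extrema of an angle trace.

    Extrema are first detected on a Savitzky-Golay-smoothed copy (peak
    prominence gated at 6x the smoothing residual so sensor noise does
    not spawn spurious peaks), then each is refined by a local quartic
    least-squares fit of the *raw* samples over ``+-fit_halfwidth``
    oscillation periods; the polynomial vertex gives sub-sample peak
    time and amplitude.  The release extremum at t = 0 is included.

    Returns an ``(k, 2)`` array of (time, signed amplitude), time-ordered
    with alternating signs for a decaying oscillation.

    Raises
    ------
    InsufficientDataError
        If fewer than three extrema are found.
    """
    t, phi = tr.t, tr.phi
    n = len(phi)
    if n < 16:
        raise InsufficientDataError("trace too short for envelope analysis")
    rate = tr.rate
    f_est = _dominant_frequency(t, phi, rate)

    win = int(round(rate / (8.0 * f_est)))
    win = max(5, win | 1)  # odd
    distance = max(1, int(round(0.3 * rate / f_est)))

    # A release-from-rest trace has its largest extremum exactly at t=0,
    # where find_peaks cannot see it; phi'(0)=0 makes an even mirror
    # extension smooth, turning the boundary into an interior extremum.
    npad = min(distance, n - 1)
    padded = np.concatenate([phi[npad:0:-1], phi])
    if win < len(padded):
        smooth = savgol_filter(padded, win, 3)
    else:
        smooth = padded.copy()
    resid_sd = float(np.std(padded - smooth))
    prominence = max(1e-9, 6.0 * resid_sd)

    hi, _ = find_peaks(smooth, prominence=prominence, distance=distance)
    lo, _ = find_peaks(-smooth, prominence=prominence, distance=distance)
    idxs = sorted(set(hi.tolist()) | set(lo.tolist()))
    idxs = [i - npad for i in idxs]
    # detections jittered just inside the mirrored pad belong to t=0
    idxs = [0 if -distance // 2 < i < 0 else i for i in idxs if i > -distance // 2]
    idxs = sorted(set(idxs))

    if len(idxs) < 3:
        raise InsufficientDataError(
            f"only {len(idxs)} extrema found; need at least 3"
        )

    half_w = max(2, int(round(fit_halfwidth * rate / f_est)))
    out = []
    for idx in idxs:
        if 0 <= idx < half_w and idx + half_w + 1 <= n:
            # near the release boundary the fit window would be one-sided;
            # fill the left side by even reflection about t=0 (phi'(0)=0
            # for a release from rest makes the trace even there)
            ext = np.concatenate([phi[half_w:0:-1], phi])
            seg = ext[idx: idx + 2 * half_w + 1]
            tau = np.arange(-half_w, half_w + 1) / rate
            coef = np.polyfit(tau, seg, 4)
            droots = np.roots(np.polyder(coef))
            droots = droots[np.abs(droots.imag) < 1e-12].real
            droots = droots[np.abs(droots) <= half_w / rate]
            tau_star = float(droots[np.argmin(np.abs(droots))]) \
                if droots.size else 0.0
            out.append((t[idx] + tau_star,
                        float(np.polyval(coef, tau_star))))
            continue
        a = max(0, idx - half_w)
        b = min(n, idx + half_w + 1)
        if b - a < 6:
            out.append((t[idx], phi[idx]))
            continue
        tau = t[a:b] - t[idx]
        coef = np.polyfit(tau, phi[a:b], 4)
        droots = np.roots(np.polyder(coef))
        droots = droots[np.abs(droots.imag) < 1e-12].real
        span = max(t[b - 1] - t[idx], t[idx] - t[a])
        droots = droots[np.abs(droots) <= span]
        if droots.size:
            tau_star = float(droots[np.argmin(np.abs(droots))])
        else:
            tau_star = 0.0
        out.append((t[idx] + tau_star, float(np.polyval(coef, tau_star))))
    return np.asarray(out)


@dataclass
class FrictionFit:
    """Result of the friction-torque estimation from an angle trace.

    ``friction_torque`` is the full-trace least-squares estimate (the
    'best fit'); ``envelope_friction_torque`` is the fast envelope
    regression used to initialize it.  Both are reported.
    """

    friction_torque: float
    envelope_friction_torque: float
    amplitude_offset: float
    initial_amplitude: float
    phase: float
    omega: float
    residual_rms: float
    n_peaks: int
    warnings: list[str] = field(default_factory=list)


def _truncate_alternating(peaks: np.ndarray) -> np.ndarray:
    """Keep the leading run of sign-alternating peaks.

    A final same-sign turnaround (the arm failing to cross the
    equilibrium before sticking) breaks the linear -2A recursion and
    would bias the envelope slope.
    """
    vals = peaks[:, 1]
    keep = 1
    for i in range(1, len(vals)):
        if np.sign(vals[i]) == -np.sign(vals[i - 1]) != 0:
            keep = i + 1
        else:
            break
    return peaks[:keep]


def fit_friction_torque(tr: AngleTrace, p: PendulumParams,
                        fit_amplitude: bool = True,
                        fit_phase: bool = True,
                        debias: bool = True) -> FrictionFit:
    """Estimate the Coulomb friction torque from a measured angle trace.

    Two estimators, both reported:

    (a) *envelope regression*: least-squares slope of |peak| vs
        half-cycle index; the peak decrement per half cycle is 2A, so
        ``Mf = W*s * |slope| / 2``.
    (b) *full-trace least squares*: the stitched analytic solution is
        fitted to the whole trace over (Mf, initial amplitude), with the
        release side chosen by trying both phases; initialized from (a).

    The analytic fitting model is the small-angle linearization, which
    over-reads the friction torque slightly at large release amplitudes
    (about 2% at 30 degrees).  With ``debias=True`` (default) the fit is
    calibrated against the nonlinear ODE: a trace is simulated at the
    fitted parameters, re-fitted with the same small-angle model, and
    the measured estimator bias subtracted -- exact to first order and
    negligible at small amplitudes.

    ``fit_amplitude``/``fit_phase`` pin the release amplitude / side to
    the values in ``p`` instead of fitting them (measured traces start
    mid-release, so fitting both is the default).

    A non-decaying envelope yields ``friction_torque = 0`` with a
    warning diagnostic instead of an error.
    """
    fit = _fit_small_angle(tr, p, fit_amplitude, fit_phase)
    if debias and fit.friction_torque > 0 and not fit.warnings:
        p_sim = PendulumParams(
            weight=p.weight, lever_arm=p.lever_arm, frequency=p.frequency,
            friction_torque=fit.friction_torque,
            initial_amplitude=min(fit.initial_amplitude, math.pi / 2 - 1e-6),
            phase=fit.phase, gravity=p.gravity, inertia=p.inertia,
        )
        sim = simulate_pendulum_ode(p_sim, duration=float(tr.t[-1]),
                                    rate=tr.rate)
        try:
            ref = _fit_small_angle(sim, p, fit_amplitude, fit_phase)
        except InsufficientDataError:
            return fit
        bias = ref.friction_torque - fit.friction_torque
        fit.friction_torque = max(0.0, fit.friction_torque - bias)
        fit.amplitude_offset = fit.friction_torque / p.restoring_torque
    return fit


def _fit_small_angle(tr: AngleTrace, p: PendulumParams,
                     fit_amplitude: bool, fit_phase: bool) -> FrictionFit:
    peaks = envelope_peaks(tr)
    peaks = _truncate_alternating(peaks)
    n_peaks = len(peaks)
    if n_peaks < 3:
        raise InsufficientDataError(
            f"only {n_peaks} alternating peaks; need at least 3 to fit"
        )
    Ws = p.restoring_torque
    omega = p.omega
    warnings: list[str] = []

    mags = np.abs(peaks[:, 1])
    slope, intercept = np.polyfit(np.arange(n_peaks), mags, 1)
    if slope >= 0.0:
        warnings.append("non-decaying envelope; friction torque set to 0")
        return FrictionFit(
            friction_torque=0.0,
            envelope_friction_torque=0.0,
            amplitude_offset=0.0,
            initial_amplitude=float(mags[0]),
            phase=0.0 if peaks[0, 1] >= 0 else math.pi,
            omega=omega,
            residual_rms=float("nan"),
            n_peaks=n_peaks,
            warnings=warnings,
        )
    A_env = -slope / 2.0
    mf_env = A_env * Ws

    amp0 = float(mags[0]) if fit_amplitude else p.initial_amplitude
    t = tr.t
    phi_obs = tr.phi

    def residual(x: np.ndarray, s0: float) -> np.ndarray:
        mf, amp = x
        model = _eval_analytic(t, omega, mf / Ws, s0 * amp)
        return model - phi_obs

    if fit_phase:
        signs = (1.0, -1.0)
    else:
        signs = (1.0 if p.phase == 0.0 else -1.0,)
    best = None
    for s0 in signs:
        try:
            sol = least_squares(
                residual, x0=[max(mf_env, 1e-9), amp0],
                args=(s0,),
                bounds=([0.0, 1e-6], [Ws * math.pi / 2, math.pi / 2 - 1e-9]),
                xtol=1e-14, ftol=1e-14, gtol=1e-14,
            )
        except ValueError:
            continue
        if best is None or sol.cost < best[0].cost:
            best = (sol, s0)
    if best is None:
        raise RuntimeError("full-trace fit failed for both release sides")
    sol, s0 = best
    mf_hat, amp_hat = sol.x
    rms = float(np.sqrt(np.mean(sol.fun ** 2)))
    return FrictionFit(
        friction_torque=float(mf_hat),
        envelope_friction_torque=float(mf_env),
        amplitude_offset=float(mf_hat / Ws),
        initial_amplitude=float(amp_hat),
        phase=0.0 if s0 > 0 else math.pi,
        omega=omega,
        residual_rms=rms,
        n_peaks=n_peaks,
        warnings=warnings,
    )
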