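"""Synthetic rig: gait waveforms, wrench synthesis and pendulum traces.

The generator emulates what the instrumented hip simulator and the
physical pendulum would record, so every analysis stage is testable
without hardware.  Gait kinematics follow the three-rotation walking
profile (extension-flexion, abduction-adduction, internal-external
rotation) with a dynamic axial load between 0.3 and 3.0 kN at 1 Hz;
the exact standardized waveform tables are licensed, so documented
sinusoid / periodic-bump approximations pinned to the standard's
extrema are used instead -- adequate because the analysis pipeline is
waveform-agnostic.

Friction physics for synthesis is a velocity-direction Coulomb model
with tanh regularization: the head-center friction torque is

    M(t) = -mu * R_eff * F(t) * tanh(|w|/w_reg) * w/|w|

with w the relative angular velocity assembled from the three rotation
rates (extension-flexion about x, abduction-adduction about y,
internal-external rotation about z).  Signals are expressed at the
transducer origin by the inverse moment transfer, lateral rig-dynamics
forces and zero-mean Gaussian sensor noise are added, and heel-strike
markers are embedded in the metadata.  All randomness flows from the
single seed in :class:`NoiseSpec`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .frames import FRAME_TRANSDUCER, FrameOffset, WrenchSeries
from .pendulum import AngleTrace, PendulumParams, simulate_pendulum_ode

__all__ = [
    "GaitWaveforms",
    "FrictionModelSpec",
    "NoiseSpec",
    "ConfigError",
    "DegenerateInputError",
    "generate_iso_waveforms",
    "generate_extension_flexion_profile",
    "synthesize_wrench_series",
    "synthesize_static_axial_series",
    "synthesize_pendulum_trace",
]


class ConfigError(ValueError):
    """Invalid waveform / generator configuration."""


class DegenerateInputError(ValueError):
    """Inputs make the requested friction synthesis meaningless."""


@dataclass
class GaitWaveforms:
    """Per-channel kinematic and load waveforms over one gait cycle.

    The angle channels are callables of absolute time returning degrees;
    ``load`` returns newtons.  All are exactly periodic with period
    ``1/frequency``.
    """

    frequency: float
    flexion_extension: Callable[[np.ndarray], np.ndarray]
    abduction_adduction: Callable[[np.ndarray], np.ndarray]
    internal_external: Callable[[np.ndarray], np.ndarray]
    load: Callable[[np.ndarray], np.ndarray]
    meta: dict = field(default_factory=dict)


@dataclass
class FrictionModelSpec:
    """Stand-in friction physics for wrench synthesis.

    ``mode='zero'`` emulates an ideal (hydrostatically separated)
    bearing: no friction torque regardless of ``mu``.  ``run_in_excess``
    and ``run_in_tau`` optionally modulate the friction factor as
    ``mu * (1 + excess * exp(-cycle/tau))`` to emulate running-in.
    """

    mode: str = "coulomb"
    mu: float = 0.09
    effective_radius: float = 0.018
    velocity_regularization: float = 0.05
    run_in_excess: float = 0.0
    run_in_tau: float = 100.0

    def __post_init__(self) -> None:
        if self.mode not in ("coulomb", "zero"):
            raise ConfigError(f"unknown friction mode {self.mode!r}")
        if self.mu < 0 or self.effective_radius <= 0:
            raise ConfigError("mu must be >= 0 and effective_radius > 0")
        if self.velocity_regularization <= 0:
            raise ConfigError("velocity_regularization must be > 0")
        if self.mode == "zero":
            self.mu = 0.0

    def mu_at_cycle(self, cycle_number: np.ndarray) -> np.ndarray:
        """Effective friction factor at 1-based cycle numbers."""
        c = np.asarray(cycle_number, dtype=float)
        return self.mu * (1.0 + self.run_in_excess * np.exp(-c / self.run_in_tau))


@dataclass
class NoiseSpec:
    """Zero-mean Gaussian sensor noise; the seed governs all randomness."""

    torque_sd: float = 0.05
    force_sd: float = 0.2
    angle_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.torque_sd, self.force_sd, self.angle_sd) < 0:
            raise ConfigError("noise standard deviations must be >= 0")


def _sinusoid(lo: float, hi: float, frequency: float,
              phase: float) -> Callable[[np.ndarray], np.ndarray]:
    if lo >= hi:
        raise ConfigError(f"invalid range [{lo}, {hi}]: min must be < max")
    mid = 0.5 * (hi + lo)
    amp = 0.5 * (hi - lo)

    def f(t):
        return mid + amp * np.sin(2.0 * math.pi * frequency * np.asarray(t)
                                  + phase)

    return f


def _periodic_bump_profile(lo: float, hi: float, frequency: float,
                           centers: tuple[float, ...],
                           widths: tuple[float, ...],
                           weights: tuple[float, ...],
                           ) -> Callable[[np.ndarray], np.ndarray]:
    """Smooth periodic profile of Gaussian-like bumps rescaled to hit
    exactly [lo, hi].  Bumps use the periodic kernel
    exp((cos(2*pi*d) - 1) / (2*pi*w)^2), which reduces to a Gaussian of
    width ``w`` (cycle fraction) for narrow bumps."""
    if lo >= hi:
        raise ConfigError(f"invalid range [{lo}, {hi}]: min must be < max")

    def shape(x):
        s = np.zeros_like(x, dtype=float)
        for c, w, a in zip(centers, widths, weights):
            s += a * np.exp((np.cos(2.0 * math.pi * (x - c)) - 1.0)
                            / (2.0 * math.pi * w) ** 2)
        return s

    xg = np.linspace(0.0, 1.0, 8192, endpoint=False)
    sg = shape(xg)
    s_min, s_max = float(sg.min()), float(sg.max())

    def f(t):
        x = np.asarray(t, dtype=float) * frequency
        return lo + (hi - lo) * (shape(x) - s_min) / (s_max - s_min)

    return f


def generate_iso_waveforms(
    frequency: float = 1.0,
    fe_range: tuple[float, float] = (-18.0, 25.0),
    aa_range: tuple[float, float] = (-4.0, 7.0),
    ie_range: tuple[float, float] = (-2.0, 10.0),
    load_range: tuple[float, float] = (300.0, 3000.0),
    load_peaks: tuple[float, float] = (0.125, 0.5),
    load_widths: tuple[float, float] = (0.08, 0.09),
    load_balance: float = 0.92,
    fe_phase: float = math.pi / 2,
    aa_phase: float = 0.0,
    ie_phase: float = math.pi,
) -> GaitWaveforms:
    """Three-rotation walking kinematics with a dynamic axial load.

    Defaults pin the waveform extrema to the standard walking profile:
    extension-flexion -18..+25 deg, abduction-adduction -4..+7 deg,
    internal-external rotation -2..+10 deg, axial load 0.3..3.0 kN at
    1 Hz with load peaks near 12.5% and 50% of the cycle (heel strike
    at 0%).  Channel phases are configurable; the defaults put peak
    flexion at heel strike.
    """
    return GaitWaveforms(
        frequency=frequency,
        flexion_extension=_sinusoid(*fe_range, frequency, fe_phase),
        abduction_adduction=_sinusoid(*aa_range, frequency, aa_phase),
        internal_external=_sinusoid(*ie_range, frequency, ie_phase),
        load=_periodic_bump_profile(*load_range, frequency,
                                    centers=load_peaks, widths=load_widths,
                                    weights=(1.0, load_balance)),
        meta={"profile": "iso_3d"},
    )


def generate_extension_flexion_profile(
    mode: str = "static",
    frequency: float | None = None,
    amplitude_deg: float | None = None,
    load_range: tuple[float, float] | None = None,
    static_load: float = 2000.0,
) -> GaitWaveforms:
    """Single-rotation extension-flexion profile (AA = IE = 0).

    ``mode='static'``: +-25 deg at 0.75 Hz under a constant 2 kN load.
    ``mode='dynamic'``: +-20 deg at 1 Hz under an in-vivo-like two-bump
    load profile between 0.24 and 1.95 kN.
    """
    if mode == "static":
        frequency = 0.75 if frequency is None else frequency
        amplitude_deg = 25.0 if amplitude_deg is None else amplitude_deg
        lvl = float(static_load)

        def load(t):
            return np.full_like(np.asarray(t, dtype=float), lvl)

    elif mode == "dynamic":
        frequency = 1.0 if frequency is None else frequency
        amplitude_deg = 20.0 if amplitude_deg is None else amplitude_deg
        load_range = (240.0, 1950.0) if load_range is None else load_range
        load = _periodic_bump_profile(*load_range, frequency,
                                      centers=(0.15, 0.5),
                                      widths=(0.1, 0.11),
                                      weights=(1.0, 0.85))
    else:
        raise ConfigError(f"unknown extension-flexion mode {mode!r}")

    def zero(t):
        return np.zeros_like(np.asarray(t, dtype=float))

    return GaitWaveforms(
        frequency=frequency,
        flexion_extension=_sinusoid(-amplitude_deg, amplitude_deg,
                                    frequency, 0.0),
        abduction_adduction=zero,
        internal_external=zero,
        load=load,
        meta={"profile": f"extension_flexion_{mode}"},
    )


def _channel_rate(f: Callable, t: np.ndarray, dt: float = 1e-5) -> np.ndarray:
    """Central-difference rate of an angle channel, deg/s -> rad/s."""
    return np.deg2rad((np.asarray(f(t + dt)) - np.asarray(f(t - dt)))
                      / (2.0 * dt))


def synthesize_wrench_series(
    gw: GaitWaveforms,
    fm: FrictionModelSpec,
    off: FrameOffset,
    ns: NoiseSpec,
    n_cycles: int = 10,
    rate: float = 1024.0,
    inplane_force_amp: tuple[float, float] = (25.0, 25.0),
) -> WrenchSeries:
    """Produce the transducer-frame wrench record of a simulated test.

    The head-center friction torque follows the regularized Coulomb
    model (see module docstring), the axial load acts along +z, and
    small sinusoidal in-plane forces (``inplane_force_amp``, N) stand in
    for lateral rig dynamics so the lever-arm coupling over ``off.dz``
    is exercised.  Torques are moved to the transducer origin by the
    inverse moment transfer M0 = M + r x F, sensor noise is added, and
    heel-strike times plus the noise-free head-center truth are stored
    in ``meta``.
    """
    if n_cycles < 1:
        raise ConfigError("n_cycles must be >= 1")
    f = gw.frequency
    n_per = rate / f
    if abs(n_per - round(n_per)) > 1e-9:
        raise ConfigError("rate must be an integer multiple of the gait "
                          "frequency")
    n_per = int(round(n_per))
    n = n_per * n_cycles
    t = np.arange(n) / rate

    omega = np.column_stack([
        _channel_rate(gw.flexion_extension, t),
        _channel_rate(gw.abduction_adduction, t),
        _channel_rate(gw.internal_external, t),
    ])
    speed = np.linalg.norm(omega, axis=1)
    load = np.asarray(gw.load(t), dtype=float)

    if fm.mode == "zero":
        torque_head = np.zeros((n, 3))
    else:
        if speed.max() < 1e-12:
            raise DegenerateInputError(
                "coulomb synthesis needs nonzero angular velocity somewhere"
            )
        unit = omega / np.maximum(speed, 1e-300)[:, None]
        cycle_number = np.floor(t * f).astype(int) + 1
        mu_eff = fm.mu_at_cycle(cycle_number)
        mag = mu_eff * fm.effective_radius * load * np.tanh(
            speed / fm.velocity_regularization)
        torque_head = -mag[:, None] * unit

    ax, ay = inplane_force_amp
    force = np.column_stack([
        ax * np.sin(2.0 * math.pi * f * t),
        ay * np.sin(4.0 * math.pi * f * t + math.pi / 3),
        load,
    ])

    torque_0 = torque_head + np.cross(off.vector, force)

    rng = np.random.default_rng(ns.seed)
    force_meas = force + rng.normal(0.0, ns.force_sd, size=force.shape) \
        if ns.force_sd > 0 else force.copy()
    torque_meas = torque_0 + rng.normal(0.0, ns.torque_sd, size=torque_0.shape) \
        if ns.torque_sd > 0 else torque_0.copy()

    meta = {
        "heel_strike_times": np.arange(n_cycles) / f,
        "true_head_torque": torque_head,
        "true_axial_load": load,
        "frequency": f,
    }
    return WrenchSeries(t=t, force=force_meas, torque=torque_meas,
                        frame=FRAME_TRANSDUCER, meta=meta)


def synthesize_static_axial_series(
    axial_force: float = 1000.0,
    off: FrameOffset = None,
    ns: NoiseSpec = None,
    duration: float = 1.0,
    rate: float = 256.0,
) -> WrenchSeries:
    """Static pure-axial-load record for centering studies.

    The head-center torque is identically zero; the transducer sees only
    the lever-arm torques of the in-plane offset (plus noise), i.e.
    Mx0 = dy*Fz, My0 = -dx*Fz.
    """
    off = FrameOffset() if off is None else off
    ns = NoiseSpec(torque_sd=0.0, force_sd=0.0) if ns is None else ns
    n = max(2, int(round(duration * rate)))
    t = np.arange(n) / rate
    force = np.tile([0.0, 0.0, axial_force], (n, 1))
    torque = np.tile(np.cross(off.vector, [0.0, 0.0, axial_force]), (n, 1))
    rng = np.random.default_rng(ns.seed)
    if ns.force_sd > 0:
        force = force + rng.normal(0.0, ns.force_sd, size=force.shape)
    if ns.torque_sd > 0:
        torque = torque + rng.normal(0.0, ns.torque_sd, size=torque.shape)
    return WrenchSeries(t=t, force=force, torque=torque,
                        frame=FRAME_TRANSDUCER)


def synthesize_pendulum_trace(p: PendulumParams, ns: NoiseSpec,
                              rate: float = 1024.0,
                              duration: float | None = None) -> AngleTrace:
    """Simulated inclinometer record of a free pendulum release.

    The nonlinear ODE trace plus seeded Gaussian angle noise
    (``ns.angle_sd``, radians).  The default duration covers the decay
    to stick plus a short rest tail.
    """
    if duration is None:
        A = p.amplitude_offset
        if A > 0:
            n_hc = int(math.ceil(p.initial_amplitude / (2.0 * A))) + 2
        else:
            n_hc = 20
        duration = n_hc * math.pi / p.omega
    tr = simulate_pendulum_ode(p, duration=duration, rate=rate)
    if ns.angle_sd > 0:
        rng = np.random.default_rng(ns.seed)
        phi = tr.phi + rng.normal(0.0, ns.angle_sd, size=tr.phi.shape)
        tr = AngleTrace(t=tr.t, phi=phi, meta=dict(tr.meta))
    return tr
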