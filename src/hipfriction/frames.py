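"""Reference frames and rigid-body wrench transforms.

A six-axis transducer below the test chamber of an instrumented hip
simulator records forces (Fx, Fy, Fz) and torques (Mx, My, Mz) about its
own origin.  Friction metrics, however, are defined about the center of
the femoral head, a distance ``dz`` above the transducer along the load
axis, and about the stem-head taper axis, which is inclined by an angle
``alpha`` to the vertical.  This module provides the frame-tagged
containers and the moment-transfer / rotation operations linking the
three frames, plus the in-plane centering estimate used to null the
lever-arm torques produced by the axial load.

Conventions
-----------
Right-handed x-y-z frame with z along the axial load axis (transducer
vertical).  The taper frame is obtained by a rotation about +y by
``alpha``.  Offsets are stored in meters, forces in newtons, torques in
newton-meters; unit conversion is the caller's job.  Frame tags are
mandatory metadata: operations refuse mixed-frame arithmetic, because
the moment transfer materially changes Mx and My whenever in-plane
forces act over the lever arm ``dz``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Union

import numpy as np

__all__ = [
    "FRAME_TRANSDUCER",
    "FRAME_HEAD_CENTER",
    "FRAME_TAPER",
    "FrameError",
    "PreconditionError",
    "InsufficientLoadError",
    "Wrench",
    "WrenchSeries",
    "FrameOffset",
    "TaperFrame",
    "translate_to_head_center",
    "general_moment_transfer",
    "rotate_about_y",
    "rotate_to_taper",
    "resultant_torque",
    "estimate_center_offset",
]

FRAME_TRANSDUCER = "transducer_origin"
FRAME_HEAD_CENTER = "head_center"
FRAME_TAPER = "taper"
KNOWN_FRAMES = frozenset({FRAME_TRANSDUCER, FRAME_HEAD_CENTER, FRAME_TAPER})


class FrameError(ValueError):
    """A wrench was supplied in the wrong (or an unknown) reference frame."""


class PreconditionError(ValueError):
    """An operation's precondition was violated."""


class InsufficientLoadError(ValueError):
    """Axial load too small for a reliable center-offset estimate."""


def _check_known_frame(frame: str) -> None:
    if frame not in KNOWN_FRAMES:
        raise FrameError(
            f"unknown frame tag {frame!r}; expected one of {sorted(KNOWN_FRAMES)}"
        )


def _require_frame(obj: "WrenchLike", expected: str) -> None:
    if obj.frame != expected:
        raise FrameError(
            f"expected a wrench in frame {expected!r}, got {obj.frame!r}"
        )


@dataclass(frozen=True)
class Wrench:
    """A single 6-component force/torque sample tagged with its frame.

    Forces in N, torques in Nm.
    """

    fx: float
    fy: float
    fz: float
    mx: float
    my: float
    mz: float
    frame: str

    def __post_init__(self) -> None:
        _check_known_frame(self.frame)
        vals = (self.fx, self.fy, self.fz, self.mx, self.my, self.mz)
        if not all(math.isfinite(v) for v in vals):
            raise ValueError("wrench components must be finite")

    @property
    def force(self) -> np.ndarray:
        return np.array([self.fx, self.fy, self.fz], dtype=float)

    @property
    def torque(self) -> np.ndarray:
        return np.array([self.mx, self.my, self.mz], dtype=float)

    @classmethod
    def from_vectors(cls, force, torque, frame: str) -> "Wrench":
        f = np.asarray(force, dtype=float)
        m = np.asarray(torque, dtype=float)
        return cls(f[0], f[1], f[2], m[0], m[1], m[2], frame)

    def __add__(self, other: "Wrench") -> "Wrench":
        if not isinstance(other, Wrench):
            return NotImplemented
        if other.frame != self.frame:
            raise FrameError(
                f"cannot add wrenches in different frames "
                f"({self.frame!r} + {other.frame!r})"
            )
        return Wrench.from_vectors(
            self.force + other.force, self.torque + other.torque, self.frame
        )

    def __sub__(self, other: "Wrench") -> "Wrench":
        if not isinstance(other, Wrench):
            return NotImplemented
        if other.frame != self.frame:
            raise FrameError(
                f"cannot subtract wrenches in different frames "
                f"({self.frame!r} - {other.frame!r})"
            )
        return Wrench.from_vectors(
            self.force - other.force, self.torque - other.torque, self.frame
        )


@dataclass
class FrameOffset:
    """Displacement (dx, dy, dz) in meters from one frame origin to another."""

    dx: float = 0.0
    dy: float = 0.0
    dz: float = 0.0

    def __post_init__(self) -> None:
        for name in ("dx", "dy", "dz"):
            v = getattr(self, name)
            if not math.isfinite(v):
                raise ValueError(f"offset component {name} must be finite")
            if abs(v) >= 1.0:  # sanity bound: desk-scale rig geometry
                raise ValueError(
                    f"offset component {name}={v} m exceeds the 1 m sanity bound"
                )

    @property
    def vector(self) -> np.ndarray:
        return np.array([self.dx, self.dy, self.dz], dtype=float)


@dataclass
class TaperFrame:
    """Taper-axis frame: rotated about +y by ``alpha`` (radians).

    The default 30 degrees is the typical inclination of the stem-head
    taper axis relative to the vertical load axis.
    """

    alpha: float = math.pi / 6

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha < math.pi / 2:
            raise ValueError("taper angle must satisfy 0 <= alpha < pi/2")

    @property
    def rotation_matrix(self) -> np.ndarray:
        c, s = math.cos(self.alpha), math.sin(self.alpha)
        return np.array([[c, 0.0, -s], [0.0, 1.0, 0.0], [s, 0.0, c]])


@dataclass
class WrenchSeries:
    """Uniformly sampled 6-channel force/torque record in one frame.

    Attributes
    ----------
    t : (n,) array, seconds, strictly increasing, uniform step
    force : (n, 3) array, N
    torque : (n, 3) array, Nm
    frame : frame tag shared by all samples
    meta : free-form metadata (e.g. heel-strike times from the generator)
    """

    t: np.ndarray
    force: np.ndarray
    torque: np.ndarray
    frame: str
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.t = np.ascontiguousarray(self.t, dtype=float)
        self.force = np.ascontiguousarray(self.force, dtype=float)
        self.torque = np.ascontiguousarray(self.torque, dtype=float)
        _check_known_frame(self.frame)
        n = self.t.shape[0]
        if self.t.ndim != 1 or n < 1:
            raise ValueError("t must be a non-empty 1-D array")
        if self.force.shape != (n, 3) or self.torque.shape != (n, 3):
            raise ValueError("force and torque must have shape (n, 3)")
        if not (np.all(np.isfinite(self.t))
                and np.all(np.isfinite(self.force))
                and np.all(np.isfinite(self.torque))):
            raise ValueError("series values must be finite")
        if n >= 2:
            dt = np.diff(self.t)
            if np.any(dt <= 0):
                raise ValueError("time must be strictly increasing")
            dt0 = dt.mean()
            if np.max(np.abs(dt - dt0)) > 1e-9 * dt0:
                raise ValueError("time step must be uniform to 1e-9 relative")

    def __len__(self) -> int:
        return self.t.shape[0]

    @property
    def dt(self) -> float:
        if len(self) < 2:
            raise ValueError("need at least two samples to define a time step")
        return float(self.t[1] - self.t[0])

    @property
    def rate(self) -> float:
        """Sampling rate in Hz (1/dt)."""
        return 1.0 / self.dt

    def __getitem__(self, key) -> "WrenchSeries":
        if not isinstance(key, slice):
            raise TypeError("WrenchSeries supports slice indexing only")
        return WrenchSeries(
            t=self.t[key],
            force=self.force[key],
            torque=self.torque[key],
            frame=self.frame,
            meta=dict(self.meta),
        )


WrenchLike = Union[Wrench, WrenchSeries]


def _split(w: WrenchLike) -> tuple[np.ndarray, np.ndarray, bool]:
    if isinstance(w, Wrench):
        return w.force[None, :], w.torque[None, :], True
    return w.force, w.torque, False


def _join(w: WrenchLike, force: np.ndarray, torque: np.ndarray,
          frame: str) -> WrenchLike:
    if isinstance(w, Wrench):
        return Wrench.from_vectors(force[0], torque[0], frame)
    return WrenchSeries(t=w.t, force=force, torque=torque, frame=frame,
                        meta=dict(w.meta))


def general_moment_transfer(w: WrenchLike, r: FrameOffset,
                            new_frame: str | None = None) -> WrenchLike:
    """Transfer the moment to a point displaced by ``r``: M = M0 - r x F.

    The full three-component cross product; forces are unchanged by a
    pure translation of the reference point.  ``new_frame`` retags the
    result (defaults to keeping the input tag).
    """
    F, M, _ = _split(w)
    M_new = M - np.cross(r.vector, F)
    frame = w.frame if new_frame is None else new_frame
    return _join(w, F.copy(), M_new, frame)


def translate_to_head_center(w: WrenchLike, off: FrameOffset) -> WrenchLike:
    """Move the torque reference from the transducer origin to the head center.

    Specialization of :func:`general_moment_transfer` for an offset purely
    along the load axis (dz), valid once the in-plane offsets have been
    nulled by centering::

        Mx = Mx0 + dz * Fy
        My = My0 - dz * Fx
        Mz = Mz0

    Raises
    ------
    FrameError
        If ``w`` is not in the transducer frame.
    PreconditionError
        If ``off`` has nonzero in-plane components (use
        :func:`general_moment_transfer` for those).
    """
    _require_frame(w, FRAME_TRANSDUCER)
    if off.dx != 0.0 or off.dy != 0.0:
        raise PreconditionError(
            "translate_to_head_center requires dx = dy = 0 (centered rig); "
            "use general_moment_transfer for in-plane offsets"
        )
    return general_moment_transfer(w, off, new_frame=FRAME_HEAD_CENTER)


def rotate_about_y(w: WrenchLike, angle: float,
                   new_frame: str | None = None) -> WrenchLike:
    """Rotate force and torque components into a frame rotated about +y."""
    c, s = math.cos(angle), math.sin(angle)
    R = np.array([[c, 0.0, -s], [0.0, 1.0, 0.0], [s, 0.0, c]])
    F, M, _ = _split(w)
    frame = w.frame if new_frame is None else new_frame
    return _join(w, F @ R.T, M @ R.T, frame)


def rotate_to_taper(w: WrenchLike, tf: TaperFrame) -> WrenchLike:
    """Rotate head-center components into the taper-aligned frame.

    With alpha = 30 degrees this is the familiar::

        Mx' = 0.866 Mx - 0.5 Mz
        My' = My
        Mz' = 0.5 Mx + 0.866 Mz

    where Mz' is the torque about the stem-head taper axis.  The
    Euclidean torque norm is preserved.
    """
    _require_frame(w, FRAME_HEAD_CENTER)
    return rotate_about_y(w, tf.alpha, new_frame=FRAME_TAPER)


def resultant_torque(w: WrenchLike):
    """Euclidean norm sqrt(Mx^2 + My^2 + Mz^2); rotation invariant.

    Returns a float for a single :class:`Wrench`, an ``(n,)`` array for a
    :class:`WrenchSeries`.
    """
    _, M, scalar = _split(w)
    res = np.linalg.norm(M, axis=1)
    return float(res[0]) if scalar else res


def estimate_center_offset(series: WrenchSeries,
                           min_axial_force: float = 100.0,
                           max_rounds: int = 5,
                           tol: float = 1e-9) -> FrameOffset:
    """Estimate the in-plane (dx, dy) misalignment from a static axial load.

    Under a pure axial load Fz, an in-plane offset produces the lever-arm
    torques Mx0 = dy*Fz and My0 = -dx*Fz at the transducer, so the closed
    form is ``dy = mean(Mx0)/mean(Fz)``, ``dx = -mean(My0)/mean(Fz)``.
    The estimate mirrors the physical rig's iterative load-and-translate
    centering: up to ``max_rounds`` refinement rounds until the update
    falls below ``tol`` meters (the problem is linear, so one round
    already nulls the mean torques on clean data).

    Raises
    ------
    InsufficientLoadError
        If ``|mean(Fz)|`` is below ``min_axial_force`` (default 100 N).
    """
    _require_frame(series, FRAME_TRANSDUCER)
    mean_fz = float(series.force[:, 2].mean())
    if abs(mean_fz) < min_axial_force:
        raise InsufficientLoadError(
            f"|mean axial force| = {abs(mean_fz):.3g} N is below the "
            f"{min_axial_force:.3g} N minimum for centering"
        )
    dx = dy = 0.0
    work = series
    for _ in range(max_rounds):
        d_dy = float(work.torque[:, 0].mean()) / mean_fz
        d_dx = -float(work.torque[:, 1].mean()) / mean_fz
        dx += d_dx
        dy += d_dy
        if max(abs(d_dx), abs(d_dy)) < tol:
            break
        work = general_moment_transfer(series, FrameOffset(dx, dy, 0.0))
    return FrameOffset(dx, dy, 0.0)
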