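"""Per-cycle friction metrics for three-dimensional hip simulation data.

Operates on head-center wrench series: resultant and taper torques per
gait cycle, peak statistics with cycle position in percent (heel strike
at 0%), running-in / steady-state plateau detection, repeatability
summaries across dismantle/re-setup trials, and the linear
diameter-and-load scaling used to compare static-load literature
torques.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields as dc_fields
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .frames import (
    FRAME_HEAD_CENTER,
    TaperFrame,
    WrenchSeries,
    resultant_torque,
    rotate_to_taper,
)

__all__ = [
    "CycleMetrics",
    "RunningInCurve",
    "ExtrapolationError",
    "segment_cycles",
    "cycle_metrics",
    "metrics_to_dataframe",
    "aggregate_last_cycles",
    "running_in_schedule",
    "detect_steady_state",
    "repeatability_summary",
    "format_repeatability",
    "scale_literature_torque",
]


class ExtrapolationError(ValueError):
    """Requested diameter lies outside the known literature range."""


@dataclass
class CycleMetrics:
    """Friction metrics of one gait cycle (torques in Nm, position in %)."""

    cycle_index: int
    max_resultant: float
    percent_of_cycle_at_max: float
    max_mx: float
    max_my: float
    max_mz: float
    taper_min: float
    taper_max: float
    taper_ptp: float


_METRIC_FIELDS = [f.name for f in dc_fields(CycleMetrics)
                  if f.name != "cycle_index"]


@dataclass
class RunningInCurve:
    """Per-sampled-cycle maximum resultant torque over a test's duration."""

    cycles: np.ndarray
    max_resultant: np.ndarray

    def __post_init__(self) -> None:
        self.cycles = np.asarray(self.cycles, dtype=int)
        self.max_resultant = np.asarray(self.max_resultant, dtype=float)
        if self.cycles.shape != self.max_resultant.shape or self.cycles.ndim != 1:
            raise ValueError("cycles and max_resultant must be equal-length 1-D")
        if self.cycles.size and np.any(np.diff(self.cycles) <= 0):
            raise ValueError("cycle indices must be strictly increasing")


def segment_cycles(ws: WrenchSeries, frequency: float,
                   t0: float = 0.0) -> list[WrenchSeries]:
    """Cut a series into whole gait cycles of duration 1/frequency.

    Cycles start at ``t0`` (the first heel strike); any partial trailing
    cycle is dropped.  The sample rate must be an integer multiple of
    the gait frequency.
    """
    if frequency <= 0:
        raise ValueError("frequency must be positive")
    rate = ws.rate
    n_per = rate / frequency
    if abs(n_per - round(n_per)) > 1e-6:
        raise ValueError(
            f"rate {rate:g} Hz is not an integer multiple of the gait "
            f"frequency {frequency:g} Hz"
        )
    n_per = int(round(n_per))
    start = (t0 - ws.t[0]) * rate
    if abs(start - round(start)) > 1e-6:
        raise ValueError("t0 does not fall on a sample instant")
    start = int(round(start))
    if start < 0 or start >= len(ws):
        raise ValueError("t0 lies outside the series")
    n_cycles = (len(ws) - start) // n_per
    if n_cycles < 1:
        raise ValueError("series shorter than one gait period")
    return [ws[start + i * n_per: start + (i + 1) * n_per]
            for i in range(n_cycles)]


def cycle_metrics(cycle: WrenchSeries, tf: TaperFrame,
                  cycle_index: int = 0) -> CycleMetrics:
    """Compute the per-cycle friction metrics of one head-center cycle.

    The resultant is the pythagorean sum of the three torque components
    per sample; component maxima are maxima of absolute value; taper
    extrema refer to the torque about the taper axis (Mz') after
    rotation by the taper inclination.
    """
    if cycle.frame != FRAME_HEAD_CENTER:
        raise ValueError("cycle_metrics expects a head-center series")
    res = resultant_torque(cycle)
    i_max = int(np.argmax(res))
    taper = rotate_to_taper(cycle, tf)
    mzp = taper.torque[:, 2]
    return CycleMetrics(
        cycle_index=cycle_index,
        max_resultant=float(res[i_max]),
        percent_of_cycle_at_max=100.0 * i_max / len(cycle),
        max_mx=float(np.max(np.abs(cycle.torque[:, 0]))),
        max_my=float(np.max(np.abs(cycle.torque[:, 1]))),
        max_mz=float(np.max(np.abs(cycle.torque[:, 2]))),
        taper_min=float(mzp.min()),
        taper_max=float(mzp.max()),
        taper_ptp=float(mzp.max() - mzp.min()),
    )


def metrics_to_dataframe(metrics: Sequence[CycleMetrics]) -> pd.DataFrame:
    return pd.DataFrame([vars(m) for m in metrics])


def aggregate_last_cycles(metrics: Sequence[CycleMetrics],
                          k: int) -> dict[str, tuple[float, float]]:
    """Mean and sample SD of every metric over the final ``k`` cycles.

    With ``k = 1`` the SD is reported as 0 (a single cycle has no
    scatter to estimate).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > len(metrics):
        raise ValueError(f"requested last {k} cycles but only "
                         f"{len(metrics)} available")
    tail = metrics[-k:]
    out: dict[str, tuple[float, float]] = {}
    for name in _METRIC_FIELDS:
        vals = np.array([getattr(m, name) for m in tail], dtype=float)
        sd = float(np.std(vals, ddof=1)) if k > 1 else 0.0
        out[name] = (float(vals.mean()), sd)
    return out


def running_in_schedule(n_total: int = 1000) -> list[int]:
    """Recording schedule for running-in evaluation: cycles 1, 10, 25,
    50, 75, then every 100 up to ``n_total``."""
    sched = [c for c in (1, 10, 25, 50, 75) if c <= n_total]
    sched += list(range(100, n_total + 1, 100))
    return sched


def detect_steady_state(curve: RunningInCurve, window: int = 3,
                        rel_tol: float = 0.01) -> int | None:
    """First sampled cycle from which the friction level has settled.

    The curve is reduced to leading-window running means of length
    ``window``; the onset is the first sampled index whose subsequent
    windowed means all change by less than ``rel_tol`` (relative).
    Returns the cycle number, or None if the curve never settles.
    Invariant under uniform scaling of the torque values.
    """
    v = curve.max_resultant
    if v.size < 3:
        raise ValueError("need at least 3 sampled points")
    window = min(window, v.size)
    means = np.array([v[i:i + window].mean()
                      for i in range(v.size - window + 1)])
    if means.size < 2:
        return int(curve.cycles[0])
    rel = np.abs(np.diff(means)) / np.maximum(np.abs(means[:-1]), 1e-300)
    ok = rel < rel_tol
    # first index i with ok[j] True for all j >= i
    settled = np.flip(np.logical_and.accumulate(np.flip(ok)))
    idx = np.nonzero(settled)[0]
    if idx.size == 0:
        return None
    return int(curve.cycles[idx[0]])


def repeatability_summary(
    per_trial_max: Mapping[str, Sequence[float]],
) -> dict[str, tuple[float, float]]:
    """Component-wise mean and sample SD of per-trial torque maxima.

    One trial corresponds to one dismantle/re-setup of the test chamber;
    at least two trials are required.
    """
    out: dict[str, tuple[float, float]] = {}
    for comp, vals in per_trial_max.items():
        arr = np.asarray(vals, dtype=float)
        if arr.size < 2:
            raise ValueError(
                f"component {comp!r}: need at least 2 trials, got {arr.size}"
            )
        out[comp] = (float(arr.mean()), float(np.std(arr, ddof=1)))
    return out


def format_repeatability(summary: Mapping[str, tuple[float, float]]) -> str:
    """Render a repeatability summary as 'comp: mean ± SD Nm' lines."""
    return "\n".join(
        f"{comp}: {mean:.2f} ± {sd:.2f} Nm"
        for comp, (mean, sd) in summary.items()
    )


def scale_literature_torque(
    known: Sequence[tuple[float, float]],
    target_diameter: float,
    target_load: float,
    reference_load: float,
) -> float:
    """Scale literature friction torques to another head diameter and load.

    Assumes friction torque grows linearly with head diameter and with
    axial load: the torque at ``target_diameter`` is piecewise-linearly
    interpolated between the two nearest known diameters (measured at
    ``reference_load``), then multiplied by ``target_load /
    reference_load``.  Extrapolation beyond the known diameter range is
    refused.  No rounding is applied here; that belongs to the report
    layer.
    """
    if reference_load <= 0 or target_load <= 0:
        raise ValueError("loads must be positive")
    if not known:
        raise ValueError("need at least one known (diameter, torque) point")
    pts = sorted(known)
    d = np.array([p[0] for p in pts], dtype=float)
    tq = np.array([p[1] for p in pts], dtype=float)
    if not (d[0] <= target_diameter <= d[-1]):
        raise ExtrapolationError(
            f"target diameter {target_diameter:g} mm outside the known "
            f"range [{d[0]:g}, {d[-1]:g}] mm; only interpolation is supported"
        )
    base = float(np.interp(target_diameter, d, tq))
    return base * target_load / reference_load
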