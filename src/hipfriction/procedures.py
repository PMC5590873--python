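"""End-to-end test procedures tying synthesis, transforms and analysis.

Each procedure mirrors one validation or measurement protocol of the
friction rig:

- ``repeatability``: repeated dismantle/re-setup trials of one bearing
  under the walking profile; component-wise mean ± SD of the last-cycle
  torque maxima.
- ``hydrostatic_zero``: ideal (zero-friction) bearing under walking
  kinematics at 3% axial load; establishes the detection floor.
- ``pendulum_static``: free pendulum release; friction torque recovered
  from the angular damping.
- ``ef_dynamic``: extension-flexion oscillation under a dynamic load
  profile; signed torque extrema about the rotation axis.
- ``iso_3d``: 1000-cycle three-dimensional walking test; running-in
  curve, steady-state onset, and steady-state resultant/taper metrics.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .config import RunConfig
from .frames import FrameOffset, TaperFrame, translate_to_head_center
from .gait import (
    aggregate_last_cycles,
    cycle_metrics,
    detect_steady_state,
    format_repeatability,
    metrics_to_dataframe,
    repeatability_summary,
    running_in_schedule,
    segment_cycles,
    RunningInCurve,
)
from .io import decimate, write_angle_csv
from .pendulum import PendulumParams, fit_friction_torque
from .synthetic import (
    FrictionModelSpec,
    NoiseSpec,
    generate_extension_flexion_profile,
    generate_iso_waveforms,
    synthesize_pendulum_trace,
    synthesize_wrench_series,
)

__all__ = ["ReportBundle", "run_procedure"]

log = logging.getLogger("hipfriction")


@dataclass
class ReportBundle:
    procedure: str
    seed: int
    values: dict[str, float]
    tables: dict[str, pd.DataFrame] = field(default_factory=dict)
    summary: str = ""


def _sub_seed(rng: np.random.Generator) -> int:
    return int(rng.integers(0, 2**31 - 1))


def _pipeline_metrics(ws, cfg: RunConfig, frequency: float):
    """Decimate, move to the head center, segment, per-cycle metrics."""
    factor = cfg.acquisition.simulator_rate / cfg.acquisition.output_rate
    if abs(factor - round(factor)) > 1e-9:
        raise ValueError("simulator_rate must be an integer multiple of "
                         "output_rate")
    ws = decimate(ws, int(round(factor)))
    ws = translate_to_head_center(ws, FrameOffset(dz=cfg.geometry.dz))
    tf = TaperFrame(math.radians(cfg.geometry.taper_angle_deg))
    cycles = segment_cycles(ws, frequency)
    return [cycle_metrics(c, tf, cycle_index=i)
            for i, c in enumerate(cycles)], cycles


def _friction_spec(cfg: RunConfig, mu: float | None = None,
                   mode: str = "coulomb") -> FrictionModelSpec:
    s = cfg.synth
    return FrictionModelSpec(
        mode=mode,
        mu=s.mu if mu is None else mu,
        effective_radius=s.effective_radius,
        velocity_regularization=s.velocity_regularization,
        run_in_excess=s.run_in_excess,
        run_in_tau=s.run_in_tau,
    )


def _run_repeatability(cfg: RunConfig, rng: np.random.Generator) -> ReportBundle:
    s = cfg.synth
    n_cycles = s.n_cycles or 1000
    gw = generate_iso_waveforms()
    per_trial: dict[str, list[float]] = {"Mx": [], "My": [], "Mz": []}
    rows = []
    for trial in range(s.n_trials):
        mu_trial = s.mu * max(0.05, 1.0 + s.trial_scatter_rel * rng.normal())
        fm = _friction_spec(cfg, mu=mu_trial)
        ns = NoiseSpec(torque_sd=s.torque_sd, force_sd=s.force_sd,
                       seed=_sub_seed(rng))
        ws = synthesize_wrench_series(gw, fm, FrameOffset(dz=cfg.geometry.dz),
                                      ns, n_cycles=n_cycles,
                                      rate=cfg.acquisition.simulator_rate)
        metrics, _ = _pipeline_metrics(ws, cfg, gw.frequency)
        last = metrics[-1]
        per_trial["Mx"].append(last.max_mx)
        per_trial["My"].append(last.max_my)
        per_trial["Mz"].append(last.max_mz)
        rows.append({"trial": trial, "max_mx": last.max_mx,
                     "max_my": last.max_my, "max_mz": last.max_mz,
                     "max_resultant": last.max_resultant})
    summary_stats = repeatability_summary(per_trial)
    values = {}
    for comp, (mean, sd) in summary_stats.items():
        values[f"{comp.lower()}_mean"] = mean
        values[f"{comp.lower()}_sd"] = sd
    text = ("Repeatability over repeated dismantle/re-setup trials\n"
            "(last-cycle torque maxima, mean ± SD):\n"
            + format_repeatability(summary_stats))
    return ReportBundle("repeatability", s.seed, values,
                        {"metrics": pd.DataFrame(rows)}, text)


def _run_hydrostatic(cfg: RunConfig, rng: np.random.Generator) -> ReportBundle:
    s = cfg.synth
    n_cycles = s.n_cycles or 10
    # ideal bearing: axial load reduced to 3% of the walking profile
    gw = generate_iso_waveforms(load_range=(0.03 * 300.0, 0.03 * 3000.0))
    fm = _friction_spec(cfg, mode="zero")
    ns = NoiseSpec(torque_sd=s.torque_sd, force_sd=s.force_sd,
                   seed=_sub_seed(rng))
    ws = synthesize_wrench_series(gw, fm, FrameOffset(dz=cfg.geometry.dz),
                                  ns, n_cycles=n_cycles,
                                  rate=cfg.acquisition.simulator_rate)
    metrics, _ = _pipeline_metrics(ws, cfg, gw.frequency)
    agg = aggregate_last_cycles(metrics, min(cfg.analysis.last_cycles,
                                             len(metrics)))
    max_res = agg["max_resultant"][0]
    values = {
        "max_resultant_mean": max_res,
        "torque_noise_sd": s.torque_sd,
        "noise_floor_3sigma": 3.0 * s.torque_sd,
    }
    text = (f"Zero-friction (ideal bearing) run: mean max resultant torque "
            f"over the last cycles = {max_res:.4f} Nm\n"
            f"3-sigma noise floor of the injected torque noise = "
            f"{3.0 * s.torque_sd:.4f} Nm")
    return ReportBundle("hydrostatic_zero", s.seed, values,
                        {"metrics": metrics_to_dataframe(metrics)}, text)


def _run_pendulum(cfg: RunConfig, rng: np.random.Generator) -> ReportBundle:
    s = cfg.synth
    p = PendulumParams(friction_torque=s.pendulum_friction_torque,
                       initial_amplitude=math.radians(30.0))
    ns = NoiseSpec(angle_sd=math.radians(s.angle_sd_deg),
                   seed=_sub_seed(rng))
    tr = synthesize_pendulum_trace(p, ns, rate=cfg.acquisition.pendulum_rate)
    fit = fit_friction_torque(tr, p)
    values = {
        "friction_torque_true": s.pendulum_friction_torque,
        "friction_torque_fit": fit.friction_torque,
        "friction_torque_envelope": fit.envelope_friction_torque,
        "amplitude_offset": fit.amplitude_offset,
        "residual_rms_deg": math.degrees(fit.residual_rms),
        "n_peaks": float(fit.n_peaks),
    }
    text = ("Pendulum friction estimation (best fit of the damped "
            "oscillation):\n"
            f"  injected Mf = {s.pendulum_friction_torque:.3f} Nm\n"
            f"  full-trace fit Mf = {fit.friction_torque:.3f} Nm\n"
            f"  envelope regression Mf = "
            f"{fit.envelope_friction_torque:.3f} Nm\n"
            f"  residual RMS = {math.degrees(fit.residual_rms):.4f} deg")
    bundle = ReportBundle("pendulum_static", s.seed, values, {}, text)
    bundle.tables["trace"] = pd.DataFrame(
        {"t": tr.t, "phi_deg": np.rad2deg(tr.phi)})
    return bundle


def _run_ef_dynamic(cfg: RunConfig, rng: np.random.Generator) -> ReportBundle:
    s = cfg.synth
    n_cycles = s.n_cycles or 60
    gw = generate_extension_flexion_profile("dynamic")
    fm = _friction_spec(cfg)
    ns = NoiseSpec(torque_sd=s.torque_sd, force_sd=s.force_sd,
                   seed=_sub_seed(rng))
    ws = synthesize_wrench_series(gw, fm, FrameOffset(dz=cfg.geometry.dz),
                                  ns, n_cycles=n_cycles,
                                  rate=cfg.acquisition.simulator_rate)
    metrics, cycles = _pipeline_metrics(ws, cfg, gw.frequency)
    last_k = min(10, len(cycles))  # data of the last 10 cycles
    mx = np.concatenate([c.torque[:, 0] for c in cycles[-last_k:]])
    agg = aggregate_last_cycles(metrics, last_k)
    values = {
        "mx_min": float(mx.min()),
        "mx_max": float(mx.max()),
        "max_resultant_mean": agg["max_resultant"][0],
    }
    text = ("Extension-flexion with dynamic load profile "
            f"(last {last_k} cycles):\n"
            f"  torque about the rotation axis: {mx.min():.2f} to "
            f"{mx.max():.2f} Nm\n"
            f"  mean max resultant torque: "
            f"{agg['max_resultant'][0]:.2f} Nm")
    return ReportBundle("ef_dynamic", s.seed, values,
                        {"metrics": metrics_to_dataframe(metrics)}, text)


def _run_iso3d(cfg: RunConfig, rng: np.random.Generator) -> ReportBundle:
    s = cfg.synth
    n_cycles = s.n_cycles or 1000
    gw = generate_iso_waveforms()
    fm = _friction_spec(cfg)
    ns = NoiseSpec(torque_sd=s.torque_sd, force_sd=s.force_sd,
                   seed=_sub_seed(rng))
    ws = synthesize_wrench_series(gw, fm, FrameOffset(dz=cfg.geometry.dz),
                                  ns, n_cycles=n_cycles,
                                  rate=cfg.acquisition.simulator_rate)
    metrics, _ = _pipeline_metrics(ws, cfg, gw.frequency)
    sched = [c for c in running_in_schedule(n_cycles) if c <= len(metrics)]
    curve = RunningInCurve(
        cycles=np.array(sched),
        max_resultant=np.array([metrics[c - 1].max_resultant for c in sched]),
    )
    if len(sched) >= 3:
        onset = detect_steady_state(curve, cfg.analysis.plateau_window,
                                    cfg.analysis.plateau_rel_tol)
    else:
        onset = None  # too few sampled cycles to judge a plateau
    agg = aggregate_last_cycles(metrics, cfg.analysis.last_cycles)
    values = {
        "max_resultant_mean": agg["max_resultant"][0],
        "max_resultant_sd": agg["max_resultant"][1],
        "taper_min_mean": agg["taper_min"][0],
        "taper_max_mean": agg["taper_max"][0],
        "taper_ptp_mean": agg["taper_ptp"][0],
        "percent_of_cycle_at_max": agg["percent_of_cycle_at_max"][0],
        "steady_state_onset_cycle": float(onset) if onset is not None
        else float("nan"),
    }
    onset_txt = f"cycle {onset}" if onset is not None else "not reached"
    text = (f"Three-dimensional walking test, {n_cycles} cycles:\n"
            f"  steady-state plateau onset: {onset_txt}\n"
            f"  steady-state max resultant torque: "
            f"{agg['max_resultant'][0]:.2f} ± {agg['max_resultant'][1]:.2f} "
            f"Nm\n"
            f"  taper torque range: {agg['taper_min'][0]:.2f} "
            f"to {agg['taper_max'][0]:.2f} Nm "
            f"(peak-to-peak {agg['taper_ptp'][0]:.2f} Nm)\n"
            f"  position of max resultant: "
            f"{agg['percent_of_cycle_at_max'][0]:.1f}% of cycle")
    tables = {
        "metrics": metrics_to_dataframe(metrics),
        "running_in": pd.DataFrame({"cycle": curve.cycles,
                                    "max_resultant": curve.max_resultant}),
    }
    return ReportBundle("iso_3d", s.seed, values, tables, text)


_RUNNERS = {
    "repeatability": _run_repeatability,
    "hydrostatic_zero": _run_hydrostatic,
    "pendulum_static": _run_pendulum,
    "ef_dynamic": _run_ef_dynamic,
    "iso_3d": _run_iso3d,
}


def run_procedure(cfg: RunConfig, out_dir=None,
                  seed: int | None = None) -> ReportBundle:
    """Execute one configured procedure end to end.

    ``seed`` overrides ``cfg.synth.seed``.  If ``out_dir`` is given the
    metrics tables (CSV), a human-readable summary and a log of the full
    configuration are written there; identical config + seed yields
    byte-identical outputs.
    """
    if seed is not None:
        cfg = cfg.model_copy(deep=True)
        cfg.synth.seed = seed
    rng = np.random.default_rng(cfg.synth.seed)
    log.info("running procedure %s (seed=%d)", cfg.procedure, cfg.synth.seed)
    bundle = _RUNNERS[cfg.procedure](cfg, rng)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, df in bundle.tables.items():
            df.to_csv(out / f"{name}.csv", index=False,
                      float_format="%.17g")
        (out / "summary.txt").write_text(bundle.summary + "\n")
        logdoc = {
            "package_version": __version__,
            "seed": cfg.synth.seed,
            "config": cfg.model_dump(),
        }
        (out / "run.log").write_text(yaml.safe_dump(logdoc, sort_keys=True))
        log.info("report written to %s", out)
    return bundle
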