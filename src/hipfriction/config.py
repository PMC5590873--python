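"""Run configuration: schema-validated YAML for the five test procedures.

Unknown keys are rejected so a typo in a config file fails loudly
rather than silently falling back to a default.
"""

from __future__ import annotations

from pathlib import Path
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, ConfigDict

__all__ = [
    "GeometryConfig",
    "AcquisitionConfig",
    "AnalysisConfig",
    "SynthesisConfig",
    "RunConfig",
    "load_run_config",
]

PROCEDURES = ("repeatability", "hydrostatic_zero", "pendulum_static",
              "ef_dynamic", "iso_3d")


class _Model(BaseModel):
    model_config = ConfigDict(extra="forbid")


class GeometryConfig(_Model):
    """Rig geometry: transducer-to-head offset (m) and taper angle (deg)."""

    dz: float = 0.15
    dx: float = 0.0
    dy: float = 0.0
    taper_angle_deg: float = 30.0


class AcquisitionConfig(_Model):
    """Sampling: capture at ``simulator_rate``, analyse at ``output_rate``."""

    simulator_rate: float = 1024.0
    output_rate: float = 256.0
    pendulum_rate: float = 1024.0


class AnalysisConfig(_Model):
    last_cycles: int = 3
    plateau_window: int = 3
    plateau_rel_tol: float = 0.01


class SynthesisConfig(_Model):
    """Synthetic-rig conditions (see the methods note for rationale)."""

    mu: float = 0.09
    effective_radius: float = 0.018
    velocity_regularization: float = 0.05
    run_in_excess: float = 0.3
    run_in_tau: float = 100.0
    torque_sd: float = 0.05
    force_sd: float = 0.2
    angle_sd_deg: float = 0.05
    seed: int = 0
    n_cycles: Optional[int] = None
    n_trials: int = 5
    trial_scatter_rel: float = 0.08
    pendulum_friction_torque: float = 5.0


class RunConfig(_Model):
    procedure: Literal["repeatability", "hydrostatic_zero",
                       "pendulum_static", "ef_dynamic", "iso_3d"]
    geometry: GeometryConfig = GeometryConfig()
    acquisition: AcquisitionConfig = AcquisitionConfig()
    analysis: AnalysisConfig = AnalysisConfig()
    synth: SynthesisConfig = SynthesisConfig()


def load_run_config(path) -> RunConfig:
    with open(Path(path)) as fh:
        data = yaml.safe_load(fh) or {}
    return RunConfig(**data)
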