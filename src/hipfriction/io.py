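"""CSV readers/writers and block-mean decimation.

Wrench series use the dialect::

    # frame=transducer_origin
    t,Fx,Fy,Fz,Mx,My,Mz
    0,0,0,1000,0.1,...

(SI units) with the frame tag on a leading comment line.  Pendulum
angle traces use ``t,phi_deg`` (degrees on disk, radians in memory).
Floats are written with 17 significant digits so a write/read round
trip is exact.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .frames import WrenchSeries
from .pendulum import AngleTrace

__all__ = [
    "ParseError",
    "EmptyInputError",
    "read_wrench_csv",
    "write_wrench_csv",
    "read_angle_csv",
    "write_angle_csv",
    "decimate",
]

WRENCH_COLUMNS = ["t", "Fx", "Fy", "Fz", "Mx", "My", "Mz"]
_FLOAT_FMT = "%.17g"


class ParseError(ValueError):
    """Malformed input file."""


class EmptyInputError(ParseError):
    """The input file contains no data."""


def write_wrench_csv(ws: WrenchSeries, path) -> None:
    path = Path(path)
    df = pd.DataFrame(
        np.column_stack([ws.t, ws.force, ws.torque]), columns=WRENCH_COLUMNS
    )
    with open(path, "w") as fh:
        fh.write(f"# frame={ws.frame}\n")
        df.to_csv(fh, index=False, float_format=_FLOAT_FMT)


def read_wrench_csv(path) -> WrenchSeries:
    path = Path(path)
    text_head = path.read_text()[:4096] if path.exists() else ""
    if not text_head.strip():
        raise EmptyInputError(f"{path}: empty input file")
    first = text_head.splitlines()[0].strip()
    if not first.startswith("# frame="):
        raise ParseError(
            f"{path}: line 1: expected a '# frame=<tag>' comment, "
            f"got {first!r}"
        )
    frame = first.split("=", 1)[1].strip()
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    missing = [c for c in WRENCH_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(
            f"{path}: line 2: missing column(s) {', '.join(missing)}"
        )
    if len(df) == 0:
        raise EmptyInputError(f"{path}: header but no samples")
    return WrenchSeries(
        t=df["t"].to_numpy(),
        force=df[["Fx", "Fy", "Fz"]].to_numpy(),
        torque=df[["Mx", "My", "Mz"]].to_numpy(),
        frame=frame,
    )


def write_angle_csv(tr: AngleTrace, path) -> None:
    df = pd.DataFrame({"t": tr.t, "phi_deg": np.rad2deg(tr.phi)})
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_angle_csv(path) -> AngleTrace:
    path = Path(path)
    if not path.exists() or not path.read_text().strip():
        raise EmptyInputError(f"{path}: empty input file")
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    missing = [c for c in ("t", "phi_deg") if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing column(s) {', '.join(missing)}")
    return AngleTrace(t=df["t"].to_numpy(),
                      phi=np.deg2rad(df["phi_deg"].to_numpy()))


def decimate(ws: WrenchSeries, factor: int) -> WrenchSeries:
    """Reduce the data rate by non-overlapping block means of ``factor``
    samples (e.g. 1024 Hz -> 256 Hz with factor 4).  Trailing samples
    that do not fill a block are dropped."""
    if factor < 1 or int(factor) != factor:
        raise ValueError("decimation factor must be a positive integer")
    factor = int(factor)
    if factor == 1:
        return ws[:]
    nb = len(ws) // factor
    if nb < 1:
        raise ValueError("series shorter than one decimation block")
    m = nb * factor

    def blocks(a: np.ndarray) -> np.ndarray:
        return a[:m].reshape(nb, factor, -1).mean(axis=1)

    # timestamps keep the block's left edge so cycle boundaries stay on
    # sample instants; values are the block means
    return WrenchSeries(
        t=ws.t[:m:factor],
        force=blocks(ws.force),
        torque=blocks(ws.torque),
        frame=ws.frame,
        meta=dict(ws.meta),
    )
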