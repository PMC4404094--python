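"""Calibration: raw-units-per-kilogram gain from weekly standard-weight placements.

Combinations of two 2 kg weights and one 5 kg weight give applied forces of
2, 4, 5, 7 and 9 kg, placed over each load cell in turn.  The gain is the
slope of a least-squares regression through the origin of the net
(offset-subtracted) readings on applied mass, pooled over all placements of a
deployment; a per-position slope difference is reported as a diagnostic but
not acted on.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .bridge_io import ForceTrace

#: standard mass combinations available from 2+2+5 kg weights
STANDARD_MASSES_KG = (2.0, 4.0, 5.0, 7.0, 9.0)

#: minimum usable plateau after the settling transient, seconds
MIN_PLATEAU_S = 0.25


class DegenerateDesignError(ValueError):
    """The calibration events cannot identify a slope."""


@dataclass(frozen=True)
class CalibrationEvent:
    event_time: object  # pd.Timestamp or logger seconds
    applied_mass: float  # kg
    cell_position: str  # "sea" | "land"
    raw_reading: float  # mean raw wgt1 over the stable plateau
    offset_raw: float  # raw wgt1 of the empty bridge just before placement

    def __post_init__(self):
        if self.applied_mass <= 0:
            raise ValueError("applied_mass must be positive")
        if self.cell_position not in ("sea", "land"):
            raise ValueError("cell_position must be 'sea' or 'land'")
        if self.raw_reading <= self.offset_raw:
            raise ValueError("raw_reading must exceed offset_raw")


@dataclass(frozen=True)
class CalibrationModel:
    gain: float  # raw units per kg
    fit_n: int
    residual_sd: float  # raw units
    position_gain_diff: float | None = None  # land slope minus sea slope

    def __post_init__(self):
        if self.gain <= 0:
            raise ValueError("gain must be positive")
        if self.fit_n < 2:
            raise ValueError("fit needs at least two events")


def extract_calibration_reading(trace: ForceTrace, settle_time: float = 2.0) -> float:
    """Mean raw wgt1 after the bridge oscillation has settled.

    A placed weight rings the platform; the oscillation dies out within a
    couple of seconds, after which the plateau is usable.
    """
    t = trace.sample_times - trace.sample_times[0]
    keep = t >= settle_time
    if keep.sum() < 2 or (t[keep][-1] - t[keep][0]) < MIN_PLATEAU_S:
        raise ValueError(
            f"stable plateau after {settle_time} s shorter than {MIN_PLATEAU_S} s"
        )
    return float(trace.wgt1[keep].mean())


def fit_gain(events: list[CalibrationEvent]) -> CalibrationModel:
    """Least-squares slope (through the origin) of net reading on applied mass.

    All weekly events of the deployment are pooled, both cell positions
    together.  Offsets are subtracted per event before fitting, so the model
    has no intercept.
    """
    if len(events) < 2:
        raise DegenerateDesignError("need at least two calibration events")
    masses = np.array([e.applied_mass for e in events])
    if np.unique(masses).size < 2:
        raise DegenerateDesignError("need at least two distinct applied masses")
    net = np.array([e.raw_reading - e.offset_raw for e in events])

    slope, *_ = np.linalg.lstsq(masses[:, None], net, rcond=None)
    gain = float(slope[0])
    resid = net - gain * masses
    residual_sd = float(np.sqrt((resid**2).sum() / (len(events) - 1)))

    diff = None
    by_pos = {}
    for pos in ("land", "sea"):
        m = np.array([e.applied_mass for e in events if e.cell_position == pos])
        r = np.array([e.raw_reading - e.offset_raw for e in events if e.cell_position == pos])
        if len(m):
            by_pos[pos] = float((m * r).sum() / (m * m).sum())
    if len(by_pos) == 2:
        diff = by_pos["land"] - by_pos["sea"]
    return CalibrationModel(gain=gain, fit_n=len(events), residual_sd=residual_sd,
                            position_gain_diff=diff)


def raw_to_kg(net_force_raw: float, model: CalibrationModel) -> float:
    """Convert a net (offset-subtracted) raw force to kilograms."""
    return net_force_raw / model.gain


# -- calibration log persistence ------------------------------------------------

LOG_COLUMNS = ["event_time", "applied_mass_kg", "cell_position", "raw_reading", "offset_raw"]


def read_calibration_log(path: str | Path) -> list[CalibrationEvent]:
    df = pd.read_csv(path)
    missing = set(LOG_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"calibration log missing columns: {sorted(missing)}")
    return [
        CalibrationEvent(
            event_time=pd.to_datetime(row.event_time),
            applied_mass=float(row.applied_mass_kg),
            cell_position=str(row.cell_position),
            raw_reading=float(row.raw_reading),
            offset_raw=float(row.offset_raw),
        )
        for row in df.itertuples()
    ]


def write_calibration_log(events: list[CalibrationEvent], path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "event_time": [e.event_time for e in events],
            "applied_mass_kg": [e.applied_mass for e in events],
            "cell_position": [e.cell_position for e in events],
            "raw_reading": [e.raw_reading for e in events],
            "offset_raw": [e.offset_raw for e in events],
        }
    )
    df.to_csv(path, index=False)
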