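"""Processing configuration.

Every "set value" of the processing chain lives here as a flat, named key so a
deployment can be re-processed under different validity criteria without
touching code.  Thresholds that physically scale with the calibration gain are
expressed in kilograms and converted to raw units per crossing; thresholds on
the auxiliary channel are raw units because that channel's scale is a property
of the installation.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import yaml


@dataclass
class Config:
    # peak detection (seconds / kilograms above the empty-bridge level)
    peaks_bin_width_s: float = 0.2
    peaks_shift_s: float = 0.025
    peaks_empty_threshold_kg: float = 0.5
    # hop landings reach ~1.8x body weight after the oscillator's overshoot, and
    # they are ordinary single-bird features (the window excludes them); the
    # multiple-penguin level must clear them for the heaviest expected bird
    peaks_overload_threshold_kg: float = 8.5

    # weight estimation
    weight_g: float = 9.8
    weight_min_empty_duration_s: float = 0.25
    weight_empty_value_threshold_kg: float = 0.5
    weight_channel_agreement_tol: float = 12.0  # raw units

    # direction calls (raw units on the auxiliary channel)
    direction_peak_diff_threshold: float = 60.0
    direction_entry_low: float = 200.0
    direction_entry_high: float = 300.0
    direction_head_s: float = 0.25

    # installation geometry: which load cell feeds the auxiliary channel
    geometry_wgt2_cell: str = "land"

    # RFID matching
    rfid_slack_s: float = 2.0

    # calibration
    calibration_settle_s: float = 2.0

    # trip pairing
    trips_max_duration_days: float = 14.0

    def __post_init__(self) -> None:
        if self.geometry_wgt2_cell not in ("land", "sea"):
            raise ValueError("geometry_wgt2_cell must be 'land' or 'sea'")

    # Flat YAML uses dotted keys (`peaks.bin_width_s`); attributes use
    # underscores.  The first dot separates the section.
    @classmethod
    def from_yaml(cls, path: str | Path) -> "Config":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kwargs = {}
        valid = {f.name for f in dataclasses.fields(cls)}
        for key, value in raw.items():
            attr = key.replace(".", "_", 1)
            if attr not in valid:
                raise KeyError(f"unknown config key: {key!r}")
            kwargs[attr] = value
        return cls(**kwargs)

    def to_yaml(self, path: str | Path) -> None:
        out = {}
        for f in dataclasses.fields(self):
            key = f.name.replace("_", ".", 1)
            out[key] = getattr(self, f.name)
        Path(path).write_text(yaml.safe_dump(out, sort_keys=True))
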