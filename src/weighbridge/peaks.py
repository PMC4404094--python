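"""Step-peak detection and the empty-bridge / multiple-penguin filters.

The crossing is chopped into 0.2 s bins (about one penguin step) and the
maximum of each bin is a candidate peak; a candidate counts only if it is
still a bin maximum when the bin grid is shifted by ±0.025 s, which rejects
false peaks at bin boundaries.  A peak below the empty level means the bird
has left: it and everything after are dropped.  A peak above the overload
level means more than one bird is aboard: it and everything after are
dropped.  The integration window runs from the second to the second-to-last
surviving peak, excluding the oversized hop-on/hop-off forces.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np

from .bridge_io import ForceTrace


class UnmeasurableCrossingError(ValueError):
    """The crossing does not support a weight estimate."""

    def __init__(self, message: str, flags: set[str] | None = None):
        super().__init__(message)
        self.flags = set(flags or ())


class Peak(NamedTuple):
    time: float
    value: float


@dataclass(frozen=True)
class PeakSet:
    times: np.ndarray
    values: np.ndarray
    flags: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self):
        times = np.asarray(self.times, dtype=float)
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "flags", frozenset(self.flags))
        if len(times) != len(values):
            raise ValueError("times and values must have equal length")
        if len(times) > 1 and np.any(np.diff(times) <= 0):
            raise ValueError("peak times must be strictly increasing")

    @property
    def peaks(self) -> list[Peak]:
        return [Peak(t, v) for t, v in zip(self.times, self.values)]

    def __len__(self) -> int:
        return len(self.times)


@dataclass(frozen=True)
class IntegrationWindow:
    t1: float
    t2: float

    def __post_init__(self):
        if self.t2 <= self.t1:
            raise ValueError("t2 must exceed t1")

    @property
    def duration(self) -> float:
        return self.t2 - self.t1


def _is_bin_max(values: np.ndarray, bins: np.ndarray) -> np.ndarray:
    """True where a sample's value equals the maximum of its bin (tie-inclusive)."""
    order = np.argsort(bins, kind="stable")
    sorted_bins = bins[order]
    boundaries = np.flatnonzero(np.diff(sorted_bins)) + 1
    binmax_sorted = np.concatenate(
        [np.full(len(g), values[order][g].max())
         for g in np.split(np.arange(len(values)), boundaries)]
    )
    binmax = np.empty(len(values))
    binmax[order] = binmax_sorted
    return values >= binmax


def detect_peaks(
    trace: ForceTrace, bin_width: float = 0.2, shift: float = 0.025
) -> PeakSet:
    """Samples that are bin maxima under the base grid and both shifted grids.

    A sample qualifies under a grid when its value equals the maximum of its
    bin; quantized records tie freely, so qualification is by value, and ties
    within a base-grid bin break to the earliest sample.
    """
    if bin_width <= 2 * trace.dt:
        raise ValueError("bin_width must exceed two sample intervals")
    if not 0 < shift < bin_width / 2:
        raise ValueError("shift must lie in (0, bin_width/2)")
    t = trace.sample_times
    if trace.duration < bin_width:
        return PeakSet(np.empty(0), np.empty(0))
    keep = np.ones(len(t), dtype=bool)
    base_bins = None
    for offset in (0.0, shift, -shift):
        bins = np.floor((t - t[0] - offset) / bin_width).astype(np.int64)
        keep &= _is_bin_max(trace.wgt1, bins)
        if offset == 0.0:
            base_bins = bins
    idx = np.flatnonzero(keep)
    if len(idx):
        # earliest qualifying sample per base-grid bin
        first = np.ones(len(idx), dtype=bool)
        first[1:] = base_bins[idx][1:] != base_bins[idx][:-1]
        idx = idx[first]
    return PeakSet(t[idx], trace.wgt1[idx])


def filter_empty(peaks: PeakSet, empty_threshold: float) -> PeakSet:
    """Truncate at the first peak below the empty level (the bird has left)."""
    below = peaks.values < empty_threshold
    if not below.any():
        return peaks
    cut = int(np.argmax(below))
    return PeakSet(peaks.times[:cut], peaks.values[:cut],
                   peaks.flags | {"empty_truncated"})


def filter_overload(peaks: PeakSet, overload_threshold: float) -> PeakSet:
    """Truncate at the first peak above the overload level (second bird aboard)."""
    above = peaks.values > overload_threshold
    if not above.any():
        return peaks
    cut = int(np.argmax(above))
    return PeakSet(peaks.times[:cut], peaks.values[:cut],
                   peaks.flags | {"overload_truncated"})


def integration_window(peaks: PeakSet) -> IntegrationWindow:
    """Second to second-to-last peak; hop-on/hop-off extremes are excluded."""
    if len(peaks) < 4:
        raise UnmeasurableCrossingError(
            f"only {len(peaks)} validated peaks; need at least 4",
            flags=peaks.flags | {"too_few_peaks"},
        )
    return IntegrationWindow(t1=float(peaks.times[1]), t2=float(peaks.times[-2]))
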