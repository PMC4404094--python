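"""Travel-direction assignment from the position-sensitive auxiliary channel.

The auxiliary channel (wgt2) is fed by the land-side load cell, so its share
of the total force falls as the bird walks toward the sea.  Two independent
rules are applied and combined:

* peak difference — wgt2 at the second peak minus wgt2 at the second-to-last
  peak; clearly positive means the bird moved land → sea ("out"), clearly
  negative sea → land ("in");
* entry mean — mean wgt2 over the first 0.25 s; a high value means the bird
  stepped on at the land end (going out), a low value at the sea end
  (coming in).

Agreement of both definite calls carries high confidence; a single definite
call is kept but flagged lower-confidence; opposite calls are a conflict.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .bridge_io import ForceTrace
from .config import Config
from .peaks import PeakSet

OUT, IN, UNKNOWN, CONFLICT = "out", "in", "unknown", "conflict"


@dataclass(frozen=True)
class DirectionCall:
    method_peak_diff: str  # out | in | unknown
    method_entry_mean: str  # out | in | unknown
    consensus: str  # out | in | unknown | conflict
    diff_value: float  # raw wgt2 units (nan when unavailable)
    entry_mean_value: float  # raw wgt2 units
    low_confidence: bool = False


def direction_by_peak_difference(
    trace: ForceTrace, peaks: PeakSet, threshold: float = 60.0
) -> tuple[str, float]:
    """wgt2(second peak) − wgt2(second-to-last peak), against a dead band."""
    if len(peaks) < 4:
        return UNKNOWN, float("nan")
    w2_first = _wgt2_at(trace, peaks.times[1])
    w2_last = _wgt2_at(trace, peaks.times[-2])
    diff = w2_first - w2_last
    if diff > threshold:
        return OUT, diff
    if diff < -threshold:
        return IN, diff
    return UNKNOWN, diff


def _wgt2_at(trace: ForceTrace, time: float) -> float:
    idx = int(np.argmin(np.abs(trace.sample_times - time)))
    return float(trace.wgt2[idx])


def direction_by_entry_mean(
    trace: ForceTrace, low: float = 200.0, high: float = 300.0, head: float = 0.25
) -> tuple[str, float]:
    """Mean wgt2 over the first `head` seconds against a low/high dead band."""
    t = trace.sample_times - trace.sample_times[0]
    sel = t <= head
    mean = float(trace.wgt2[sel].mean())
    if mean < low:
        return IN, mean
    if mean > high:
        return OUT, mean
    return UNKNOWN, mean


def consensus_direction(call1: str, call2: str) -> tuple[str, bool]:
    """Combine the two method calls; returns (consensus, low_confidence)."""
    definite = {OUT, IN}
    if call1 in definite and call2 in definite:
        if call1 == call2:
            return call1, False
        return CONFLICT, False
    if call1 in definite:
        return call1, True
    if call2 in definite:
        return call2, True
    return UNKNOWN, False


def classify_direction(
    trace: ForceTrace, peaks: PeakSet, config: Config | None = None
) -> DirectionCall:
    """Both methods plus their consensus, honouring the installation geometry.

    With the auxiliary cell on the sea side instead (mirrored installation)
    both raw calls flip.
    """
    cfg = config or Config()
    pd_call, diff = direction_by_peak_difference(
        trace, peaks, cfg.direction_peak_diff_threshold
    )
    em_call, entry_mean = direction_by_entry_mean(
        trace, cfg.direction_entry_low, cfg.direction_entry_high, cfg.direction_head_s
    )
    if cfg.geometry_wgt2_cell == "sea":
        pd_call = _flip(pd_call)
        em_call = _flip(em_call)
    consensus, low_conf = consensus_direction(pd_call, em_call)
    return DirectionCall(
        method_peak_diff=pd_call,
        method_entry_mean=em_call,
        consensus=consensus,
        diff_value=diff,
        entry_mean_value=entry_mean,
        low_confidence=low_conf,
    )


def _flip(call: str) -> str:
    return {OUT: IN, IN: OUT}.get(call, call)
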