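"""Two-stage weight estimation from the main-channel force record.

Newton's second law in integral form over an interval [t1, t2] of the
crossing,

    m [v(t2) - v(t1)] = ∫ [F(t) - F0 - m g] dt ,

gives the mean net force as a first approximation W1 of the static weight
(mean-value theorem); its error is m·[v(t2)-v(t1)]/(t2-t1), which is small
when t1 and t2 sit at the same phase of the quasi-periodic stepping.  The
vertical centre-of-mass velocity is then reconstructed from the same record,

    v(t) = v(t1) + (g/W1) ∫ [F(t) - F0 - W1] dt ,

and the slope a of its least-squares linear trend measures the relative
error of W1, yielding the second approximation

    W2 = W1 (1 + a/g) .

F0 is the empty-bridge reading, re-estimated for every crossing that contains
an empty stretch (at least 0.25 s of low, position-stable signal); otherwise
the nearest available offset is carried over.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .bridge_io import CrossingEvent, ForceTrace
from .calibration import CalibrationModel, raw_to_kg
from .config import Config
from .peaks import (
    IntegrationWindow,
    PeakSet,
    UnmeasurableCrossingError,
    detect_peaks,
    filter_empty,
    filter_overload,
    integration_window,
)

#: gravitational acceleration, m/s^2
G = 9.8


class MissingOffsetError(ValueError):
    """No empty-bridge offset is available for a crossing."""


@dataclass(frozen=True)
class OffsetEstimate:
    f0: float  # raw wgt1 units
    window: tuple[float, float] | None  # seconds within the trace, if measured
    source: str  # measured | nearest_prior | nearest_any


@dataclass(frozen=True)
class VelocitySeries:
    times: np.ndarray
    v: np.ndarray  # m/s, relative vertical CoM velocity, v[0] == 0

    def __post_init__(self):
        times = np.asarray(self.times, dtype=float)
        v = np.asarray(self.v, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "v", v)
        if len(times) != len(v):
            raise ValueError("times and v must have equal length")
        if len(v) and v[0] != 0.0:
            raise ValueError("v must start at zero")


@dataclass(frozen=True)
class WeightEstimate:
    w1_raw: float | None
    trend_a: float | None  # m/s^2
    rel_error: float | None  # a/g
    w1_kg: float | None
    w2_kg: float | None
    window: IntegrationWindow | None
    duration: float | None  # t2 - t1, seconds
    offset: OffsetEstimate | None
    flags: frozenset[str]

    @property
    def measurable(self) -> bool:
        return self.w2_kg is not None


def estimate_offset(
    trace: ForceTrace,
    *,
    empty_value_threshold: float,
    channel_agreement_tol: float | None = None,
    min_empty_duration: float = 0.25,
    channel_map: tuple[float, float] | None = None,
    fallback: OffsetEstimate | None = None,
    fallback_source: str = "nearest_prior",
) -> OffsetEstimate:
    """Empty-bridge offset F0 for one crossing.

    The offset is the mean wgt1 over the longest contiguous run of at least
    ``min_empty_duration`` where wgt1 is below ``empty_value_threshold`` and,
    when a channel map (k, c with wgt1 ≈ k·wgt2 + c on the empty bridge) is
    supplied, the two channels agree to ``channel_agreement_tol`` — a still,
    empty platform loads both cells in a fixed ratio, so agreement rules out
    a stationary bird.  Without such a run the ``fallback`` offset (from the
    nearest other crossing) is used; with neither, the crossing has no offset
    and no weight can be computed.
    """
    w1, w2, t = trace.wgt1, trace.wgt2, trace.sample_times
    ok = w1 < empty_value_threshold
    if channel_map is not None and channel_agreement_tol is not None:
        k, c = channel_map
        ok &= np.abs(w1 - (k * w2 + c)) < channel_agreement_tol

    best = _longest_run(ok)
    if best is not None:
        i0, i1 = best
        if t[i1] - t[i0] >= min_empty_duration:
            return OffsetEstimate(
                f0=float(w1[i0 : i1 + 1].mean()),
                window=(float(t[i0]), float(t[i1])),
                source="measured",
            )
    if fallback is not None:
        return OffsetEstimate(f0=fallback.f0, window=None, source=fallback_source)
    raise MissingOffsetError("no empty-bridge interval and no nearby offset available")


def _longest_run(mask: np.ndarray) -> tuple[int, int] | None:
    """(start, end) inclusive indices of the longest True run, or None."""
    if not mask.any():
        return None
    padded = np.concatenate(([False], mask, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    starts, ends = edges[::2], edges[1::2] - 1
    i = int(np.argmax(ends - starts))
    return int(starts[i]), int(ends[i])


def _window_slice(trace: ForceTrace, window: IntegrationWindow) -> slice:
    t = trace.sample_times
    if window.t1 < t[0] or window.t2 > t[-1]:
        raise ValueError("integration window outside trace span")
    i1 = int(np.searchsorted(t, window.t1, side="left"))
    i2 = int(np.searchsorted(t, window.t2, side="right")) - 1
    if i2 - i1 < 1:
        raise ValueError("integration window contains fewer than two samples")
    return slice(i1, i2 + 1)


def first_approximation(trace: ForceTrace, window: IntegrationWindow, f0: float) -> float:
    """W1 in raw units: trapezoidal mean of (wgt1 - F0) over [t1, t2]."""
    sl = _window_slice(trace, window)
    t = trace.sample_times[sl]
    net = trace.wgt1[sl] - f0
    return float(np.trapezoid(net, t) / (t[-1] - t[0]))


def reconstruct_velocity(
    trace: ForceTrace, window: IntegrationWindow, f0: float, w1_raw: float, g: float = G
) -> VelocitySeries:
    """Relative vertical CoM velocity over the window (cumulative trapezoid).

    The raw force units cancel in (wgt1 - F0 - W1)/W1, so v is in m/s even
    though the inputs are uncalibrated.
    """
    if w1_raw <= 0:
        raise ValueError("w1_raw must be positive (no physical bird)")
    sl = _window_slice(trace, window)
    t = trace.sample_times[sl]
    excess = (trace.wgt1[sl] - f0 - w1_raw) * (g / w1_raw)
    dv = (excess[1:] + excess[:-1]) / 2 * np.diff(t)
    v = np.concatenate(([0.0], np.cumsum(dv)))
    return VelocitySeries(times=t, v=v)


def velocity_trend(series: VelocitySeries) -> float:
    """Least-squares slope of v on t (centred sums)."""
    t, v = series.times, series.v
    if len(t) < 3:
        raise ValueError("need at least three samples for a trend")
    tc = t - t.mean()
    denom = (tc**2).sum()
    if denom == 0:
        raise ValueError("all sample times equal")
    return float((tc * (v - v.mean())).sum() / denom)


def second_approximation(w1_kg: float, trend_a: float, g: float = G) -> float:
    """W2 = W1 (1 + a/g)."""
    if w1_kg <= 0:
        raise ValueError("w1_kg must be positive")
    return w1_kg * (1 + trend_a / g)


def fit_channel_map(
    traces: list[ForceTrace], empty_value_thresholds: list[float], min_samples: int = 20
) -> tuple[float, float] | None:
    """Per-deployment map wgt1 ≈ k·wgt2 + c over candidate empty samples.

    The two channels are digitized at different scales, so emptiness agreement
    is checked through this fitted map.  With too few candidates or a
    constant wgt2 the map degenerates to (0, mean wgt1) — a plain closeness
    check of wgt1 to its empty baseline.
    """
    w1_parts, w2_parts = [], []
    for trace, thr in zip(traces, empty_value_thresholds):
        mask = trace.wgt1 < thr
        w1_parts.append(trace.wgt1[mask])
        w2_parts.append(trace.wgt2[mask])
    if not w1_parts:
        return None
    w1 = np.concatenate(w1_parts)
    w2 = np.concatenate(w2_parts)
    if len(w1) < min_samples:
        return None
    if np.ptp(w2) < 1e-9:
        return 0.0, float(w1.mean())
    design = np.column_stack([w2, np.ones_like(w2)])
    (k, c), *_ = np.linalg.lstsq(design, w1, rcond=None)
    return float(k), float(c)


def provisional_baseline(trace: ForceTrace) -> float:
    """Coarse empty-bridge level used to place kg-denominated thresholds.

    The 1st percentile of wgt1 is robust to noise spikes and, when the trace
    contains any empty stretch, sits at the offset; thresholds expressed
    relative to it survive offset drift between crossings.
    """
    return float(np.percentile(trace.wgt1, 1))


def estimate_weight(
    event: CrossingEvent,
    calib: CalibrationModel,
    config: Config | None = None,
    prior_offset: OffsetEstimate | None = None,
    channel_map: tuple[float, float] | None = None,
    fallback_source: str = "nearest_prior",
) -> WeightEstimate:
    """Full per-crossing chain: peaks → filters → window → offset → W1 → W2.

    Unmeasurable crossings (too few validated peaks, no offset anywhere)
    come back as flagged records with no weight rather than being dropped.
    """
    cfg = config or Config()
    trace = event.trace
    base = provisional_baseline(trace)
    gain = calib.gain

    ps = detect_peaks(trace, cfg.peaks_bin_width_s, cfg.peaks_shift_s)
    ps = filter_empty(ps, base + cfg.peaks_empty_threshold_kg * gain)
    ps = filter_overload(ps, base + cfg.peaks_overload_threshold_kg * gain)

    try:
        window = integration_window(ps)
    except UnmeasurableCrossingError as exc:
        return _unmeasurable(exc.flags)

    try:
        offset = estimate_offset(
            trace,
            empty_value_threshold=base + cfg.weight_empty_value_threshold_kg * gain,
            channel_agreement_tol=cfg.weight_channel_agreement_tol,
            min_empty_duration=cfg.weight_min_empty_duration_s,
            channel_map=channel_map,
            fallback=prior_offset,
            fallback_source=fallback_source,
        )
    except MissingOffsetError:
        return _unmeasurable(ps.flags | {"missing_offset"})

    w1_raw = first_approximation(trace, window, offset.f0)
    if w1_raw <= 0:
        return _unmeasurable(ps.flags | {"nonpositive_weight"}, window=window, offset=offset)

    vel = reconstruct_velocity(trace, window, offset.f0, w1_raw, g=cfg.weight_g)
    trend = velocity_trend(vel)
    rel = trend / cfg.weight_g
    w1_kg = raw_to_kg(w1_raw, calib)
    w2_kg = second_approximation(w1_kg, trend, g=cfg.weight_g)
    return WeightEstimate(
        w1_raw=w1_raw,
        trend_a=trend,
        rel_error=rel,
        w1_kg=w1_kg,
        w2_kg=w2_kg,
        window=window,
        duration=window.duration,
        offset=offset,
        flags=ps.flags,
    )


def _unmeasurable(
    flags, window: IntegrationWindow | None = None, offset: OffsetEstimate | None = None
) -> WeightEstimate:
    return WeightEstimate(
        w1_raw=None, trend_a=None, rel_error=None, w1_kg=None, w2_kg=None,
        window=window, duration=window.duration if window else None,
        offset=offset, flags=frozenset(flags),
    )


def peaks_for_event(event: CrossingEvent, calib: CalibrationModel, config: Config | None = None) -> PeakSet:
    """Detected-and-filtered peaks as used by `estimate_weight` (for direction calls)."""
    cfg = config or Config()
    base = provisional_baseline(event.trace)
    ps = detect_peaks(event.trace, cfg.peaks_bin_width_s, cfg.peaks_shift_s)
    ps = filter_empty(ps, base + cfg.peaks_empty_threshold_kg * calib.gain)
    ps = filter_overload(ps, base + cfg.peaks_overload_threshold_kg * calib.gain)
    return ps
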