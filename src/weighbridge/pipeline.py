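"""Deployment-scale processing: crossings → weights/directions → trips → summaries.

Every input file yields exactly one result row (flagged when unreadable or
unmeasurable, never silently dropped).  Empty-bridge offsets propagate from
the nearest prior crossing when a crossing has no empty stretch, with the
nearest following offset as a last resort.  Outward and inward crossings of
the same tagged bird pair into foraging trips whose weight difference proxies
the meal brought back to the chick.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .bridge_io import CrossingEvent, read_crossing_csv
from .calibration import CalibrationModel, fit_gain, read_calibration_log
from .config import Config
from .direction import classify_direction
from .weight import (
    OffsetEstimate,
    estimate_weight,
    fit_channel_map,
    peaks_for_event,
    provisional_baseline,
)


@dataclass
class CrossingResult:
    source_name: str
    event_time: object
    tag_ids: list[str]
    w1_kg: float | None
    w2_kg: float | None
    rel_error: float | None
    duration_s: float | None
    direction: str
    direction_low_confidence: bool
    diff_value: float
    entry_mean_value: float
    offset_source: str | None
    offset_raw: float | None
    flags: frozenset[str]
    error: str | None = None

    @property
    def measurable(self) -> bool:
        return self.w2_kg is not None


@dataclass(frozen=True)
class TripRecord:
    tag_id: str
    out_time: object
    in_time: object
    trip_duration_h: float
    weight_out_kg: float | None
    weight_in_kg: float | None
    meal_proxy_kg: float | None


def _failed_result(name: str, message: str) -> CrossingResult:
    return CrossingResult(
        source_name=name, event_time=None, tag_ids=[], w1_kg=None, w2_kg=None,
        rel_error=None, duration_s=None, direction="unknown",
        direction_low_confidence=False, diff_value=float("nan"),
        entry_mean_value=float("nan"), offset_source=None, offset_raw=None,
        flags=frozenset({"unreadable"}), error=message,
    )


def list_crossing_files(directory: str | Path) -> list[Path]:
    """Crossing files in a deployment directory, by their timestamp-named stems.

    Companion RFID files and side tables (truth, logs, outputs) do not follow
    the event-time naming convention and are skipped.
    """
    from .bridge_io import _parse_stem

    directory = Path(directory)
    out = []
    for path in sorted(directory.glob("*.csv")):
        if path.name.endswith(".rfid.csv") or _parse_stem(path.stem) is None:
            continue
        out.append(path)
    return out


def process_deployment(
    crossing_dir: str | Path,
    calibration_log: str | Path | CalibrationModel,
    config: Config | None = None,
) -> list[CrossingResult]:
    """Process every crossing file of a deployment in time order."""
    cfg = config or Config()
    if isinstance(calibration_log, CalibrationModel):
        calib = calibration_log
    else:
        calib = fit_gain(read_calibration_log(calibration_log))

    events: list[CrossingEvent | None] = []
    results: list[CrossingResult | None] = []
    names = []
    for path in list_crossing_files(crossing_dir):
        names.append(path.stem)
        try:
            events.append(read_crossing_csv(path))
            results.append(None)
        except Exception as exc:  # malformed file: record and continue
            events.append(None)
            results.append(_failed_result(path.stem, str(exc)))

    readable = [e for e in events if e is not None]
    channel_map = fit_channel_map(
        [e.trace for e in readable],
        [provisional_baseline(e.trace) + cfg.weight_empty_value_threshold_kg * calib.gain
         for e in readable],
    )

    prior: OffsetEstimate | None = None
    pending: list[int] = []  # indices processed before any offset existed
    for i, event in enumerate(events):
        if event is None:
            continue
        results[i] = _process_one(event, calib, cfg, prior, channel_map)
        est_offset = results[i].offset_source
        if est_offset == "measured":
            prior = OffsetEstimate(f0=results[i].offset_raw, window=None, source="measured")
            # crossings before the first measured offset: use it as nearest-any
            for j in pending:
                results[j] = _process_one(events[j], calib, cfg, prior, channel_map,
                                          fallback_source="nearest_any")
            pending.clear()
        elif est_offset is None and "missing_offset" in results[i].flags:
            pending.append(i)
    return [r for r in results if r is not None]


def _process_one(
    event: CrossingEvent,
    calib: CalibrationModel,
    cfg: Config,
    prior: OffsetEstimate | None,
    channel_map,
    fallback_source: str = "nearest_prior",
) -> CrossingResult:
    est = estimate_weight(event, calib, cfg, prior_offset=prior,
                          channel_map=channel_map, fallback_source=fallback_source)
    ps = peaks_for_event(event, calib, cfg)
    call = classify_direction(event.trace, ps, cfg)
    return CrossingResult(
        source_name=event.source_name,
        event_time=event.event_time,
        tag_ids=[d.tag_id for d in event.rfid],
        w1_kg=est.w1_kg,
        w2_kg=est.w2_kg,
        rel_error=est.rel_error,
        duration_s=est.duration,
        direction=call.consensus,
        direction_low_confidence=call.low_confidence,
        diff_value=call.diff_value,
        entry_mean_value=call.entry_mean_value,
        offset_source=est.offset.source if est.offset else None,
        offset_raw=est.offset.f0 if est.offset else None,
        flags=est.flags | event.flags,
    )


RESULT_COLUMNS = [
    "source_name", "event_time", "tag_ids", "w1_kg", "w2_kg", "rel_error",
    "duration_s", "direction", "direction_low_confidence", "diff_value",
    "entry_mean_value", "offset_source", "offset_raw", "flags", "error",
]


def results_to_frame(results: list[CrossingResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        row = {c: getattr(r, c) for c in RESULT_COLUMNS}
        row["tag_ids"] = "|".join(r.tag_ids)
        row["flags"] = "|".join(sorted(r.flags))
        rows.append(row)
    return pd.DataFrame(rows, columns=RESULT_COLUMNS)


def frame_to_results(df: pd.DataFrame) -> list[CrossingResult]:
    out = []
    for row in df.itertuples():
        out.append(
            CrossingResult(
                source_name=str(row.source_name),
                event_time=pd.to_datetime(row.event_time) if pd.notna(row.event_time) else None,
                tag_ids=[t for t in str(row.tag_ids).split("|") if t and t != "nan"],
                w1_kg=None if pd.isna(row.w1_kg) else float(row.w1_kg),
                w2_kg=None if pd.isna(row.w2_kg) else float(row.w2_kg),
                rel_error=None if pd.isna(row.rel_error) else float(row.rel_error),
                duration_s=None if pd.isna(row.duration_s) else float(row.duration_s),
                direction=str(row.direction),
                direction_low_confidence=bool(row.direction_low_confidence),
                diff_value=float(row.diff_value) if pd.notna(row.diff_value) else float("nan"),
                entry_mean_value=float(row.entry_mean_value) if pd.notna(row.entry_mean_value) else float("nan"),
                offset_source=None if pd.isna(row.offset_source) else str(row.offset_source),
                offset_raw=None if pd.isna(row.offset_raw) else float(row.offset_raw),
                flags=frozenset(f for f in str(row.flags).split("|") if f and f != "nan"),
                error=None if pd.isna(row.error) else str(row.error),
            )
        )
    return out


def derive_trips(
    results: list[CrossingResult], max_trip_days: float = 14.0
) -> list[TripRecord]:
    """Pair each outward crossing with the bird's next inward crossing.

    Only definite, tag-bearing crossings take part.  A second outward crossing
    before any inward one replaces the pending departure (the earlier one
    stays unpaired); pairs further apart than `max_trip_days` are discarded.
    Pairs lacking either weight are still emitted, without a meal proxy.
    """
    by_tag: dict[str, list[CrossingResult]] = {}
    for r in results:
        if r.direction not in ("out", "in") or r.event_time is None:
            continue
        for tag in r.tag_ids:
            by_tag.setdefault(tag, []).append(r)

    trips = []
    for tag, rows in sorted(by_tag.items()):
        rows.sort(key=lambda r: r.event_time)
        pending: CrossingResult | None = None
        for r in rows:
            if r.direction == "out":
                pending = r
            elif pending is not None:
                hours = (r.event_time - pending.event_time).total_seconds() / 3600.0
                if hours <= max_trip_days * 24.0:
                    meal = None
                    if r.w2_kg is not None and pending.w2_kg is not None:
                        meal = r.w2_kg - pending.w2_kg
                    trips.append(
                        TripRecord(
                            tag_id=tag, out_time=pending.event_time, in_time=r.event_time,
                            trip_duration_h=hours, weight_out_kg=pending.w2_kg,
                            weight_in_kg=r.w2_kg, meal_proxy_kg=meal,
                        )
                    )
                pending = None
    trips.sort(key=lambda tr: (tr.out_time, tr.tag_id))
    return trips


def trips_to_frame(trips: list[TripRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "tag_id": tr.tag_id, "out_time": tr.out_time, "in_time": tr.in_time,
                "trip_duration_h": tr.trip_duration_h, "weight_out_kg": tr.weight_out_kg,
                "weight_in_kg": tr.weight_in_kg, "meal_proxy_kg": tr.meal_proxy_kg,
            }
            for tr in trips
        ],
        columns=["tag_id", "out_time", "in_time", "trip_duration_h",
                 "weight_out_kg", "weight_in_kg", "meal_proxy_kg"],
    )


def summarize(
    results: list[CrossingResult],
    duration_tiers: tuple[float, ...] = (1.0, 1.5, 2.0, 2.5),
    weight_bin_kg: float = 0.25,
) -> dict:
    """Counts by direction, duration-tier fractions, weight histogram, per-tag counts."""
    n = len(results)
    directions = {"out": 0, "in": 0, "unknown": 0, "conflict": 0}
    for r in results:
        directions[r.direction] = directions.get(r.direction, 0) + 1
    measurable = [r for r in results if r.measurable]
    durations = np.array([r.duration_s for r in measurable], dtype=float)
    tier_counts = {f">={tier:g}s": int((durations >= tier).sum()) for tier in duration_tiers}
    tier_fractions = {
        k: (v / len(measurable) if measurable else 0.0) for k, v in tier_counts.items()
    }
    weights = np.array([r.w2_kg for r in measurable], dtype=float)
    if len(weights):
        hi = math.ceil(weights.max() / weight_bin_kg) * weight_bin_kg
        edges = np.arange(0.0, hi + weight_bin_kg / 2, weight_bin_kg)
        hist, _ = np.histogram(weights, bins=edges)
    else:
        edges = np.array([0.0])
        hist = np.array([], dtype=int)
    per_tag: dict[str, int] = {}
    for r in results:
        for tag in r.tag_ids:
            per_tag[tag] = per_tag.get(tag, 0) + 1
    return {
        "n_crossings": n,
        "n_measurable": len(measurable),
        "directions": directions,
        "duration_tier_counts": tier_counts,
        "duration_tier_fractions": tier_fractions,
        "weight_hist_edges_kg": edges.tolist(),
        "weight_hist_counts": hist.tolist(),
        "per_tag_counts": per_tag,
    }


def validate_against_manual(
    results: list[CrossingResult],
    manual_weights: list[tuple[str, object, float]] | pd.DataFrame,
    max_hours: float = 6.0,
) -> dict:
    """Compare estimated weights against hand-weighed (spring dynamometer) birds.

    Each manual record (tag, time, kg) matches the nearest-in-time measurable
    crossing of the same tag within `max_hours`; unmatched records are
    reported, not dropped.
    """
    if isinstance(manual_weights, pd.DataFrame):
        manual = [
            (str(r.tag_id), pd.to_datetime(r.time), float(r.weight_kg))
            for r in manual_weights.itertuples()
        ]
    else:
        manual = [(str(t), pd.Timestamp(when), float(kg)) for t, when, kg in manual_weights]

    pairs = []
    unmatched = []
    for tag, when, kg in manual:
        candidates = [
            r for r in results
            if r.measurable and tag in r.tag_ids and r.event_time is not None
            and abs((r.event_time - when).total_seconds()) <= max_hours * 3600.0
        ]
        if not candidates:
            unmatched.append((tag, when, kg))
            continue
        best = min(candidates, key=lambda r: abs((r.event_time - when).total_seconds()))
        pairs.append((tag, when, kg, best.w2_kg, best.w2_kg - kg))

    table = pd.DataFrame(
        pairs, columns=["tag_id", "time", "manual_kg", "estimated_kg", "difference_kg"]
    )
    out = {"pairs": table, "unmatched": unmatched, "n_pairs": len(pairs)}
    if len(pairs):
        diff = table["difference_kg"].to_numpy()
        out.update(
            mean_abs_difference_kg=float(np.abs(diff).mean()),
            mean_difference_kg=float(diff.mean()),
            min_abs_difference_kg=float(np.abs(diff).min()),
            max_abs_difference_kg=float(np.abs(diff).max()),
        )
        if len(pairs) >= 3 and table["manual_kg"].nunique() > 1:
            fit = stats.linregress(table["manual_kg"], table["estimated_kg"])
            out.update(slope=float(fit.slope), intercept=float(fit.intercept),
                       r_squared=float(fit.rvalue**2))
    return out


def compare_windows(
    event: CrossingEvent,
    calib: CalibrationModel,
    manual_window: tuple[float, float],
    config: Config | None = None,
) -> dict:
    """Automatic-vs-manual window check for one crossing.

    Re-runs the weight chain with a hand-picked (t1, t2) and reports both
    estimates, mirroring the manual audit of automatically selected start and
    end points.
    """
    from .peaks import IntegrationWindow
    from .weight import (
        first_approximation, reconstruct_velocity, second_approximation,
        velocity_trend, estimate_offset,
    )
    from .calibration import raw_to_kg

    cfg = config or Config()
    auto = estimate_weight(event, calib, cfg)
    base = provisional_baseline(event.trace)
    offset = estimate_offset(
        event.trace,
        empty_value_threshold=base + cfg.weight_empty_value_threshold_kg * calib.gain,
        channel_agreement_tol=cfg.weight_channel_agreement_tol,
        min_empty_duration=cfg.weight_min_empty_duration_s,
    )
    window = IntegrationWindow(*manual_window)
    w1_raw = first_approximation(event.trace, window, offset.f0)
    vel = reconstruct_velocity(event.trace, window, offset.f0, w1_raw, g=cfg.weight_g)
    trend = velocity_trend(vel)
    w1 = raw_to_kg(w1_raw, calib)
    w2 = second_approximation(w1, trend, g=cfg.weight_g)
    return {
        "automatic_w2_kg": auto.w2_kg,
        "manual_w2_kg": w2,
        "difference_kg": None if auto.w2_kg is None else w2 - auto.w2_kg,
        "automatic_window": None if auto.window is None else (auto.window.t1, auto.window.t2),
        "manual_window": manual_window,
    }
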