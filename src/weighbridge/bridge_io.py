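"""Crossing and RFID file I/O, clock correction, and RFID-to-crossing matching.

One crossing event is stored as one CSV file (``time_s,wgt1,wgt2``) named with
an ISO-8601 basic timestamp; RFID tags read during the crossing live in a
``<stem>.rfid.csv`` companion (``time_s,tag_id``).  The logger has no real-time
clock, so raw event times are seconds since power-up and are mapped to real
time from one or two known anchor events (a pure shift, or an affine map that
absorbs internal-clock drift).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

#: tolerated deviation from uniform sample spacing, seconds
SPACING_TOL = 1e-6
_TIME_STAMP_FMT = "%Y%m%dT%H%M%S"


class ParseError(ValueError):
    """A crossing or RFID file contains a malformed row."""


class DialectError(ValueError):
    """A file does not follow the declared crossing-CSV dialect."""


@dataclass(frozen=True)
class ForceTrace:
    """Uniformly sampled two-channel raw force record of one crossing.

    ``wgt1`` is the main channel (sum of both load cells, used for weight);
    ``wgt2`` the auxiliary channel (one cell, position-sensitive, used for
    direction).  ``sample_times`` are seconds from crossing start; ``event_time``
    is the absolute start (``pd.Timestamp``), uncorrected logger seconds
    (``float``), or ``None`` when unknown.
    """

    sample_times: np.ndarray
    wgt1: np.ndarray
    wgt2: np.ndarray
    event_time: pd.Timestamp | float | None = None

    def __post_init__(self):
        times = np.asarray(self.sample_times, dtype=float)
        w1 = np.asarray(self.wgt1, dtype=float)
        w2 = np.asarray(self.wgt2, dtype=float)
        object.__setattr__(self, "sample_times", times)
        object.__setattr__(self, "wgt1", w1)
        object.__setattr__(self, "wgt2", w2)
        if times.ndim != 1 or len(times) < 2:
            raise ValueError("trace needs at least two samples")
        if len(w1) != len(times) or len(w2) != len(times):
            raise ValueError("wgt1/wgt2 length must match sample_times")
        steps = np.diff(times)
        if np.any(steps <= 0):
            raise ValueError("sample_times must be strictly increasing")
        if steps.max() - steps.min() > SPACING_TOL:
            raise DialectError(
                f"non-uniform sampling: spacing varies by {steps.max() - steps.min():.3g} s"
            )
        if not (np.all(np.isfinite(w1)) and np.all(np.isfinite(w2))):
            raise ValueError("raw values must be finite")
        if w1.min() < 0 or w2.min() < 0:
            raise ValueError("raw values must be non-negative")

    @property
    def dt(self) -> float:
        return float(self.sample_times[1] - self.sample_times[0])

    @property
    def duration(self) -> float:
        return float(self.sample_times[-1] - self.sample_times[0])

    def __len__(self) -> int:
        return len(self.sample_times)


@dataclass(frozen=True)
class RfidDetection:
    tag_id: str
    detect_time: pd.Timestamp | float

    def __post_init__(self):
        if not self.tag_id:
            raise ValueError("tag_id must be non-empty")


@dataclass(frozen=True)
class TimeAnchor:
    """A moment known on both the internal clock and in real time."""

    logger_time: float
    real_time: pd.Timestamp


@dataclass
class CrossingEvent:
    trace: ForceTrace
    rfid: list[RfidDetection] = field(default_factory=list)
    source_name: str = ""
    flags: set[str] = field(default_factory=set)

    @property
    def event_time(self):
        return self.trace.event_time


def _parse_stem(stem: str):
    """Timestamp stems like 20111201T083015 or 20111201T083015.250000;
    plain floats are logger seconds; anything else -> None."""
    for fmt in (_TIME_STAMP_FMT, _TIME_STAMP_FMT + ".%f"):
        try:
            return pd.Timestamp(pd.to_datetime(stem, format=fmt))
        except (ValueError, TypeError):
            pass
    try:
        return float(stem)
    except ValueError:
        return None


def _format_stem(event_time) -> str:
    if isinstance(event_time, pd.Timestamp):
        base = event_time.strftime(_TIME_STAMP_FMT)
        if event_time.microsecond:
            base += f".{event_time.microsecond:06d}"
        return base
    if event_time is None:
        raise ValueError("cannot derive a file name without an event time")
    return f"{float(event_time):.3f}"


def read_crossing_csv(path: str | Path) -> CrossingEvent:
    """Read one crossing file (and its RFID companion when present)."""
    path = Path(path)
    times, w1, w2 = [], [], []
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header != ["time_s", "wgt1", "wgt2"]:
            raise DialectError(f"{path.name}: expected header time_s,wgt1,wgt2, got {header}")
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != 3:
                raise ParseError(f"{path.name}:{lineno}: expected 3 fields, got {len(row)}")
            try:
                times.append(float(row[0]))
                w1.append(float(row[1]))
                w2.append(float(row[2]))
            except ValueError as exc:
                raise ParseError(f"{path.name}:{lineno}: {exc}") from None
    event_time = _parse_stem(path.stem)
    try:
        trace = ForceTrace(np.array(times), np.array(w1), np.array(w2), event_time)
    except ValueError as exc:
        raise type(exc)(f"{path.name}: {exc}") from None

    rfid: list[RfidDetection] = []
    companion = path.with_name(path.stem + ".rfid.csv")
    if companion.exists():
        rfid = _read_rfid_companion(companion, event_time)
    return CrossingEvent(trace=trace, rfid=rfid, source_name=path.stem)


def _read_rfid_companion(path: Path, event_time) -> list[RfidDetection]:
    out = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header != ["time_s", "tag_id"]:
            raise DialectError(f"{path.name}: expected header time_s,tag_id, got {header}")
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != 2:
                raise ParseError(f"{path.name}:{lineno}: expected 2 fields")
            try:
                offset = float(row[0])
            except ValueError as exc:
                raise ParseError(f"{path.name}:{lineno}: {exc}") from None
            if isinstance(event_time, pd.Timestamp):
                when = event_time + pd.Timedelta(seconds=offset)
            elif event_time is None:
                when = offset
            else:
                when = event_time + offset
            out.append(RfidDetection(tag_id=row[1], detect_time=when))
    return out


def write_crossing_csv(event: CrossingEvent, directory: str | Path) -> Path:
    """Write a crossing (and RFID companion) under its timestamp-derived name.

    Times carry 6 decimals; raw values use shortest round-trip formatting so
    read(write(x)) reproduces in-range values exactly.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    stem = event.source_name or _format_stem(event.event_time)
    path = directory / f"{stem}.csv"
    trace = event.trace
    with open(path, "w", newline="") as fh:
        fh.write("time_s,wgt1,wgt2\n")
        for t, a, b in zip(trace.sample_times, trace.wgt1, trace.wgt2):
            fh.write(f"{t:.6f},{float(a)!r},{float(b)!r}\n")
    if event.rfid:
        ref = trace.event_time
        with open(directory / f"{stem}.rfid.csv", "w", newline="") as fh:
            fh.write("time_s,tag_id\n")
            for det in event.rfid:
                if isinstance(det.detect_time, pd.Timestamp) and isinstance(ref, pd.Timestamp):
                    offset = (det.detect_time - ref).total_seconds()
                elif ref is None:
                    offset = float(det.detect_time)
                else:
                    offset = float(det.detect_time) - float(ref)
                fh.write(f"{offset:.6f},{det.tag_id}\n")
    return path


def correct_timestamps(
    events: list[CrossingEvent], anchors: list[TimeAnchor]
) -> list[CrossingEvent]:
    """Map logger-second event times to real time.

    One anchor gives a constant shift; two give the affine map through both,
    which absorbs internal-clock drift.  Event order is preserved (the map is
    monotone increasing).
    """
    if not anchors:
        raise ValueError("at least one time anchor required: the logger has no real-time clock")
    if len(anchors) > 2:
        raise ValueError("at most two anchors per deployment")
    if len(anchors) == 2 and anchors[0].logger_time == anchors[1].logger_time:
        raise ValueError("anchors must have distinct logger times")

    a0 = anchors[0]
    if len(anchors) == 1:
        rate = 1.0
    else:
        a1 = anchors[1]
        rate = (a1.real_time - a0.real_time).total_seconds() / (a1.logger_time - a0.logger_time)
        if rate <= 0:
            raise ValueError("anchors imply a non-increasing clock")

    def to_real(logger_seconds: float) -> pd.Timestamp:
        return a0.real_time + pd.Timedelta(seconds=(logger_seconds - a0.logger_time) * rate)

    out = []
    for ev in events:
        if not isinstance(ev.event_time, (int, float)):
            raise TypeError(
                f"{ev.source_name or 'event'}: event_time must be logger seconds, got {type(ev.event_time).__name__}"
            )
        new_trace = replace(ev.trace, event_time=to_real(float(ev.event_time)))
        new_rfid = [
            replace(det, detect_time=to_real(float(det.detect_time))) for det in ev.rfid
        ]
        out.append(
            CrossingEvent(trace=new_trace, rfid=new_rfid, source_name=ev.source_name,
                          flags=set(ev.flags))
        )
    return out


def _seconds_between(later, earlier) -> float:
    if isinstance(later, pd.Timestamp) or isinstance(earlier, pd.Timestamp):
        return (later - earlier).total_seconds()
    return float(later) - float(earlier)


def match_rfid(
    crossings: list[CrossingEvent],
    detections: list[RfidDetection],
    slack: float = 2.0,
) -> tuple[list[CrossingEvent], list[RfidDetection]]:
    """Attach each detection to the crossing whose interval (± slack) contains it.

    Returns new crossings plus the list of unmatched detections.  A detection
    inside two overlapping crossing windows goes to the nearer event time and
    that crossing is flagged ``ambiguous_rfid``.
    """
    out = [
        CrossingEvent(trace=c.trace, rfid=list(c.rfid), source_name=c.source_name,
                      flags=set(c.flags))
        for c in crossings
    ]
    unmatched: list[RfidDetection] = []
    for det in detections:
        hits = []
        for idx, c in enumerate(out):
            offset = _seconds_between(det.detect_time, c.event_time)
            if -slack <= offset <= c.trace.duration + slack:
                hits.append(idx)
        if not hits:
            unmatched.append(det)
            continue
        if len(hits) > 1:
            hits.sort(key=lambda i: abs(_seconds_between(det.detect_time, out[i].event_time)))
            out[hits[0]].flags.add("ambiguous_rfid")
        out[hits[0]].rfid.append(det)
    return out, unmatched
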