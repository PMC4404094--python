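"""Crossing-file round trips, clock-drift correction, RFID matching."""

import numpy as np
import pandas as pd
import pytest

import weighbridge as wb
from weighbridge.bridge_io import DialectError, ParseError

from conftest import constant_trace


class TestReadWrite:
    def test_three_row_file(self, tmp_path):
        p = tmp_path / "x.csv"
        p.write_text("time_s,wgt1,wgt2\n0.000,100,50\n0.005,100,50\n0.010,100,50\n")
        ev = wb.read_crossing_csv(p)
        assert len(ev.trace) == 3
        assert ev.trace.dt == pytest.approx(0.005)
        assert list(ev.trace.wgt1) == [100, 100, 100]

    def test_mode2_sampling_interval_accepted(self, tmp_path):
        # 0.005 s is the crossing-mode sampling interval
        n = 400
        t = np.round(np.arange(n) * 0.005, 6)
        tr = wb.ForceTrace(t, np.full(n, 80.0), np.full(n, 90.0))
        assert tr.dt == pytest.approx(0.005)

    def test_round_trip_preserves_everything(self, tmp_path, single_sim):
        ev = single_sim.event
        ev2 = wb.CrossingEvent(
            trace=ev.trace, source_name="20111201T080000",
            rfid=[wb.RfidDetection("tagA", 1.25)],
        )
        path = wb.write_crossing_csv(ev2, tmp_path)
        back = wb.read_crossing_csv(path)
        assert np.array_equal(back.trace.sample_times, ev.trace.sample_times)
        assert np.array_equal(back.trace.wgt1, ev.trace.wgt1)
        assert np.array_equal(back.trace.wgt2, ev.trace.wgt2)
        assert back.source_name == "20111201T080000"
        assert back.event_time == pd.Timestamp("2011-12-01T08:00:00")
        assert len(back.rfid) == 1 and back.rfid[0].tag_id == "tagA"

    def test_malformed_row_names_line(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("time_s,wgt1,wgt2\n0.000,100,50\n0.005,oops,50\n")
        with pytest.raises(ParseError, match="bad.csv:3"):
            wb.read_crossing_csv(p)

    def test_wrong_header_rejected(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("t,a,b\n0.000,100,50\n")
        with pytest.raises(DialectError):
            wb.read_crossing_csv(p)

    def test_non_uniform_spacing_rejected(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("time_s,wgt1,wgt2\n0.000,100,50\n0.005,100,50\n0.020,100,50\n")
        with pytest.raises(DialectError, match="non-uniform"):
            wb.read_crossing_csv(p)

    def test_trace_invariants(self):
        with pytest.raises(ValueError):
            wb.ForceTrace([0.0, 0.005], [1.0], [1.0, 1.0])
        with pytest.raises(ValueError):
            wb.ForceTrace([0.0, 0.005], [1.0, -2.0], [1.0, 1.0])
        with pytest.raises(ValueError):
            wb.ForceTrace([0.0, 0.005], [1.0, np.nan], [1.0, 1.0])


class TestTimestampCorrection:
    def _events(self, logger_times):
        return [
            wb.CrossingEvent(trace=constant_trace(event_time=lt), source_name=str(lt))
            for lt in logger_times
        ]

    def test_single_anchor_is_pure_shift(self):
        anchor = wb.TimeAnchor(0.0, pd.Timestamp("2009-12-01T08:00:00"))
        events = self._events([10.0, 250.0])
        out = wb.correct_timestamps(events, [anchor])
        assert out[0].event_time == pd.Timestamp("2009-12-01T08:00:10")
        assert out[1].event_time == pd.Timestamp("2009-12-01T08:04:10")

    def test_two_anchors_zero_drift_equals_shift(self):
        a0 = wb.TimeAnchor(0.0, pd.Timestamp("2009-12-01T08:00:00"))
        a1 = wb.TimeAnchor(1000.0, pd.Timestamp("2009-12-01T08:16:40"))
        events = self._events([500.0])
        one = wb.correct_timestamps(events, [a0])
        two = wb.correct_timestamps(events, [a0, a1])
        assert one[0].event_time == two[0].event_time

    def test_two_anchors_affine_drift(self):
        # logger runs slow: 1000 logger seconds cover 1001 real seconds
        a0 = wb.TimeAnchor(0.0, pd.Timestamp("2009-12-01T08:00:00"))
        a1 = wb.TimeAnchor(1000.0, a0.real_time + pd.Timedelta(seconds=1001.0))
        out = wb.correct_timestamps(self._events([500.0]), [a0, a1])
        expected = a0.real_time + pd.Timedelta(seconds=500.0 * 1.001)
        assert abs((out[0].event_time - expected).total_seconds()) < 1e-9

    def test_anchors_map_exactly(self):
        a0 = wb.TimeAnchor(12.0, pd.Timestamp("2010-01-01T00:00:00"))
        a1 = wb.TimeAnchor(604800.0, pd.Timestamp("2010-01-08T00:00:55"))
        out = wb.correct_timestamps(self._events([12.0, 604800.0]), [a0, a1])
        assert abs((out[0].event_time - a0.real_time).total_seconds()) < 1e-3
        assert abs((out[1].event_time - a1.real_time).total_seconds()) < 1e-3

    def test_ordering_preserved(self):
        a0 = wb.TimeAnchor(0.0, pd.Timestamp("2010-01-01T00:00:00"))
        a1 = wb.TimeAnchor(1000.0, pd.Timestamp("2010-01-01T00:16:42"))
        logger = [5.0, 100.0, 300.0, 999.0]
        out = wb.correct_timestamps(self._events(logger), [a0, a1])
        times = [ev.event_time for ev in out]
        assert times == sorted(times)

    def test_no_anchor_is_an_error(self):
        with pytest.raises(ValueError, match="real-time clock"):
            wb.correct_timestamps(self._events([1.0]), [])

    def test_rfid_times_corrected_too(self):
        anchor = wb.TimeAnchor(0.0, pd.Timestamp("2009-12-01T08:00:00"))
        ev = wb.CrossingEvent(
            trace=constant_trace(event_time=10.0),
            rfid=[wb.RfidDetection("t1", 11.5)],
        )
        out = wb.correct_timestamps([ev], [anchor])
        assert out[0].rfid[0].detect_time == pd.Timestamp("2009-12-01T08:00:11.5")


class TestMatchRfid:
    def _crossing(self, start_s):
        t0 = pd.Timestamp("2011-12-01T08:00:00") + pd.Timedelta(seconds=start_s)
        return wb.CrossingEvent(trace=constant_trace(event_time=t0), source_name=str(start_s))

    def test_detection_inside_window_attached(self):
        c = self._crossing(0.0)
        det = wb.RfidDetection("tagX", c.event_time + pd.Timedelta(seconds=0.5))
        out, unmatched = wb.match_rfid([c], [det], slack=2.0)
        assert out[0].rfid[0].tag_id == "tagX"
        assert unmatched == []

    def test_far_detection_unmatched(self):
        c = self._crossing(0.0)
        det = wb.RfidDetection("tagX", c.event_time + pd.Timedelta(minutes=10))
        out, unmatched = wb.match_rfid([c], [det], slack=2.0)
        assert out[0].rfid == []
        assert unmatched == [det]

    def test_ambiguous_detection_goes_to_nearest(self):
        c1, c2 = self._crossing(0.0), self._crossing(4.0)
        det = wb.RfidDetection("tagX", c2.event_time - pd.Timedelta(seconds=0.5))
        out, unmatched = wb.match_rfid([c1, c2], [det], slack=2.0)
        assert out[1].rfid and not out[0].rfid
        assert "ambiguous_rfid" in out[1].flags
        assert unmatched == []

    def test_simulated_day_full_attachment(self, bridge):
        script = [
            {"kind": "single", "mass": 3.5 + 0.1 * i, "tag": f"tag{i:02d}",
             "direction": "out" if i % 2 == 0 else "in"}
            for i in range(20)
        ]
        sims = wb.simulate_scenarios(script, bridge, base_seed=4)
        crossings = [wb.CrossingEvent(trace=s.event.trace, source_name=s.event.source_name)
                     for s in sims]
        detections = [d for s in sims for d in s.event.rfid]
        out, unmatched = wb.match_rfid(crossings, detections, slack=2.0)
        assert unmatched == []
        assert sum(len(c.rfid) for c in out) == 20
        for c, s in zip(out, sims):
            assert [d.tag_id for d in c.rfid] == [d.tag_id for d in s.event.rfid]
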