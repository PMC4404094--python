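"""Offset estimation, the mean-force and velocity-trend estimators (W1, W2)."""

import numpy as np
import pytest

import weighbridge as wb
from weighbridge.peaks import IntegrationWindow
from weighbridge.weight import G, MissingOffsetError, OffsetEstimate, estimate_offset


def _trace(wgt1, wgt2=None, dt=0.005):
    t = np.round(np.arange(len(wgt1)) * dt, 6)
    w1 = np.asarray(wgt1, dtype=float)
    w2 = np.zeros_like(w1) if wgt2 is None else np.asarray(wgt2, dtype=float)
    return wb.ForceTrace(t, w1, w2)


class TestEstimateOffset:
    def test_constant_empty_tail_measured(self):
        w = np.concatenate([np.full(400, 350.0), np.full(80, 102.0)])  # 0.4 s tail
        off = estimate_offset(_trace(w), empty_value_threshold=150.0)
        assert off.f0 == pytest.approx(102.0)
        assert off.source == "measured"
        assert off.window is not None

    def test_tail_shorter_than_quarter_second_not_used(self):
        w = np.concatenate([np.full(400, 350.0), np.full(30, 102.0)])  # 0.145 s tail
        prior = OffsetEstimate(f0=99.0, window=None, source="measured")
        off = estimate_offset(_trace(w), empty_value_threshold=150.0, fallback=prior)
        assert off.source == "nearest_prior"
        assert off.f0 == 99.0

    def test_no_offset_anywhere_is_error(self):
        with pytest.raises(MissingOffsetError):
            estimate_offset(_trace(np.full(300, 350.0)), empty_value_threshold=150.0)

    def test_channel_agreement_vetoes_still_bird(self):
        # wgt1 low-ish but wgt2 inconsistent with the empty-bridge map
        w1 = np.full(300, 120.0)
        w2 = np.full(300, 400.0)
        prior = OffsetEstimate(f0=101.0, window=None, source="measured")
        off = estimate_offset(
            _trace(w1, w2), empty_value_threshold=150.0,
            channel_agreement_tol=12.0, channel_map=(0.0, 100.0), fallback=prior,
        )
        assert off.source == "nearest_prior"


class TestFirstApproximation:
    def test_constant_net_force_exact(self):
        tr = _trace(np.full(400, 400.0))
        w = IntegrationWindow(0.2, 1.8)
        assert wb.first_approximation(tr, w, 100.0) == pytest.approx(300.0, abs=1e-12)

    def test_sinusoid_whole_periods(self):
        t = np.arange(0, 1.0 + 0.005 / 2, 0.005)
        y = 100.0 + 300.0 + 50.0 * np.sin(2 * np.pi * 3.0 * t)
        tr = _trace(y)
        w1 = wb.first_approximation(tr, IntegrationWindow(0.0, 1.0), 100.0)
        # trapezoid error for 3 whole periods at dt=0.005 is far below 0.1 raw
        assert w1 == pytest.approx(300.0, abs=0.05)

    def test_window_outside_trace_is_error(self):
        tr = _trace(np.full(100, 400.0))
        with pytest.raises(ValueError):
            wb.first_approximation(tr, IntegrationWindow(0.0, 2.0), 100.0)


class TestReconstructVelocity:
    def test_constant_force_zero_velocity(self):
        tr = _trace(np.full(400, 400.0))
        vel = wb.reconstruct_velocity(tr, IntegrationWindow(0.2, 1.8), 100.0, 300.0)
        assert np.allclose(vel.v, 0.0, atol=1e-12)
        assert vel.v[0] == 0.0

    def test_sinusoid_closed_form(self):
        # wgt1 = f0 + W1 + A sin(wt)  =>  v = (gA/(W1 w)) (1 - cos wt)
        f0, w1, amp, freq = 100.0, 300.0, 40.0, 2.0
        omega = 2 * np.pi * freq
        t = np.arange(0, 2.0 + 0.0025, 0.005)
        tr = _trace(f0 + w1 + amp * np.sin(omega * t))
        vel = wb.reconstruct_velocity(tr, IntegrationWindow(0.0, 2.0), f0, w1)
        expected = (G * amp / (w1 * omega)) * (1 - np.cos(omega * vel.times))
        assert np.allclose(vel.v, expected, atol=2e-4)

    def test_nonpositive_w1_is_error(self):
        tr = _trace(np.full(400, 400.0))
        with pytest.raises(ValueError):
            wb.reconstruct_velocity(tr, IntegrationWindow(0.2, 1.8), 100.0, 0.0)


class TestVelocityTrend:
    def test_linear_series(self):
        t = np.arange(0, 2, 0.005)
        vel = wb.VelocitySeries(t, 0.2 * t)
        assert wb.velocity_trend(vel) == pytest.approx(0.2, rel=1e-12)

    def test_constant_series_zero_slope(self):
        t = np.arange(0, 2, 0.005)
        assert wb.velocity_trend(wb.VelocitySeries(t, np.zeros_like(t))) == 0.0

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            n = rng.integers(10, 500)
            t = np.arange(n) * 0.005
            v = rng.normal(0, 0.1, n)
            v -= v[0]
            design = np.column_stack([t, np.ones(n)])
            oracle = np.linalg.lstsq(design, v, rcond=None)[0][0]
            assert wb.velocity_trend(wb.VelocitySeries(t, v)) == pytest.approx(oracle, abs=1e-10)

    def test_too_short_is_error(self):
        with pytest.raises(ValueError):
            wb.velocity_trend(wb.VelocitySeries(np.array([0.0, 1.0]), np.array([0.0, 1.0])))


class TestSecondApproximation:
    def test_zero_trend_identity(self):
        assert wb.second_approximation(4.0, 0.0) == 4.0

    def test_correction_arithmetic(self):
        assert wb.second_approximation(4.0, 0.098) == pytest.approx(4.04)

    def test_identity_holds_on_ensemble(self, ensemble_estimates):
        for _, est in ensemble_estimates:
            if est.measurable:
                assert est.w2_kg == pytest.approx(est.w1_kg * (1 + est.rel_error), abs=1e-12)
                assert est.rel_error == pytest.approx(est.trend_a / 9.8, abs=1e-15)


class TestOffsetCancellation:
    def test_constant_shift_of_wgt1_leaves_w1_unchanged(self):
        rng = np.random.default_rng(3)
        body = 350.0 + 30 * np.sin(2 * np.pi * 5 * np.arange(700) * 0.005)
        w = np.concatenate([body, np.full(100, 100.0)]) + rng.normal(0, 0.3, 800)
        window = IntegrationWindow(0.5, 3.0)

        def net_w1(shift):
            tr = _trace(w + shift)
            off = estimate_offset(tr, empty_value_threshold=150.0 + shift)
            return wb.first_approximation(tr, window, off.f0)

        assert net_w1(0.0) == pytest.approx(net_w1(57.0), abs=1e-9)


class TestEstimateWeight:
    def test_typical_crossing_recovers_mass(self, bridge, calib):
        gp = wb.GaitParams(mass=4.5, crossing_speed=0.8 / 2.5, direction="out", seed=21)
        sim = wb.simulate_crossing(gp, bridge, rng=np.random.default_rng(21))
        est = wb.estimate_weight(sim.event, calib, wb.ensemble_config())
        assert est.measurable
        assert est.w2_kg == pytest.approx(4.5, rel=1e-3)

    def test_bird_stopping_mid_bridge_near_zero_error(self, bridge, calib):
        gp = wb.GaitParams(mass=4.5, crossing_speed=0.32, pause=(1.2, 1.0), direction="out")
        sim = wb.simulate_crossing(gp, bridge, rng=np.random.default_rng(11))
        est = wb.estimate_weight(sim.event, calib, wb.ensemble_config())
        assert est.measurable
        assert abs(est.rel_error) < 2e-3
        assert est.w2_kg == pytest.approx(4.5, rel=1e-3)

    def test_too_few_peaks_gives_flagged_record(self, calib):
        # bridge occupied for well under four steps
        w = np.concatenate([np.full(60, 100.0), np.full(90, 280.0), np.full(110, 100.0)])
        ev = wb.CrossingEvent(trace=_trace(w), source_name="short")
        est = wb.estimate_weight(ev, calib, wb.Config())
        assert not est.measurable
        assert "too_few_peaks" in est.flags

    def test_missing_offset_flagged_not_raised(self, bridge, calib):
        gp = wb.GaitParams(mass=4.0, crossing_speed=0.25, direction="out", seed=5)
        sim = wb.simulate_crossing(gp, bridge, rng=np.random.default_rng(5), post_roll=0.1)
        est = wb.estimate_weight(sim.event, calib, wb.ensemble_config())
        assert not est.measurable
        assert "missing_offset" in est.flags

    def test_prior_offset_rescues_missing(self, bridge, calib):
        gp = wb.GaitParams(mass=4.0, crossing_speed=0.25, direction="out", seed=5)
        sim = wb.simulate_crossing(gp, bridge, rng=np.random.default_rng(5), post_roll=0.1)
        prior = OffsetEstimate(f0=bridge.f0, window=None, source="measured")
        est = wb.estimate_weight(sim.event, calib, wb.ensemble_config(), prior_offset=prior)
        assert est.measurable
        assert est.offset.source == "nearest_prior"
        assert est.w2_kg == pytest.approx(4.0, rel=5e-3)

    def test_reconstructed_velocity_tracks_truth(self, single_sim, calib):
        est = wb.estimate_weight(single_sim.event, calib, wb.ensemble_config())
        tr = single_sim.event.trace
        vel = wb.reconstruct_velocity(tr, est.window, est.offset.f0, est.w1_raw)
        i1 = int(np.searchsorted(tr.sample_times, est.window.t1))
        truth = single_sim.truth_velocity[i1 : i1 + len(vel.v)]
        # the reconstruction carries a small linear ramp (the W1 error that the
        # trend correction later removes) on top of the true oscillation
        resid = vel.v - (truth - truth[0])
        assert np.sqrt((resid**2).mean()) < 0.03
        assert np.abs(resid).max() < 0.08
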