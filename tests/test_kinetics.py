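"""Refill segmentation, differentiation and load-bin summaries."""

import numpy as np
import pytest

import calumen as cm
from calumen.errors import InsufficientDataError, NoUptakeError

from conftest import exponential_refill_trace


class TestRefillSegment:
    def test_washout_exclusion_rule(self):
        trace = exponential_refill_trace(caffeine_end=5.0)
        seg = cm.extract_refill_segment(trace)
        # release-channel block starts at washout; exactly the first 1.0 s
        # after washout is excluded
        assert seg.t_start == pytest.approx(6.0)

    def test_monotone_decreasing_trace_raises_no_uptake(self):
        time = np.arange(0.0, 40.0, 0.02)
        ca = 800.0 * np.exp(-0.2 * time)
        trace = cm.CaTrace(
            time=time,
            ca_free=ca,
            epochs=[
                cm.ProtocolEvent("caffeine", 0.0, 5.0),
                cm.ProtocolEvent("ruthenium_red", 5.0, 40.0),
            ],
        )
        with pytest.raises(NoUptakeError):
            cm.extract_refill_segment(trace)

    def test_blocker_without_caffeine_is_precondition_error(self):
        trace = exponential_refill_trace()
        trace.epochs = [cm.ProtocolEvent("ruthenium_red", 5.0, 60.0)]
        with pytest.raises(InsufficientDataError):
            cm.extract_refill_segment(trace)

    def test_pump_inhibited_simulation_has_no_uptake(self):
        """Acute pump inhibition (thapsigargin preset): store depletes and
        never refills."""
        res = cm.simulate_cell(cm.default_config("hek", "TG", seed=5))
        ca = cm.calibrate_trace(res.trace, cm.RunConfig(profile="hek"))
        with pytest.raises(NoUptakeError):
            cm.extract_refill_segment(ca)


class TestUptakeCurve:
    def test_noiseless_exponential_matches_analytic_derivative(self):
        """c(t) = C_max(1-e^(-kt)) has d c/dt = k (C_max - c) exactly."""
        c_max, k = 0.8, 0.2
        trace = exponential_refill_trace(c_max_mm=c_max, k=k)
        seg = cm.extract_refill_segment(trace)
        curve = cm.compute_uptake_curve(trace, seg)
        m = (curve.load >= 0.1) & (curve.load <= 0.7)
        expected = k * (c_max - curve.load[m])
        assert np.allclose(curve.rate[m], expected, rtol=0.01)

    def test_constant_trace_gives_zero_rates(self):
        time = np.arange(0.0, 20.0, 0.02)
        trace = cm.CaTrace(time=time, ca_free=np.full_like(time, 400.0))
        curve = cm.compute_uptake_curve(trace, cm.Segment(0.0, 20.0))
        assert np.allclose(curve.rate, 0.0, atol=1e-12)
        assert np.allclose(curve.load, 0.4)

    def test_short_segment_rejected(self):
        trace = exponential_refill_trace()
        with pytest.raises(InsufficientDataError):
            cm.compute_uptake_curve(trace, cm.Segment(6.0, 6.2))

    def test_curve_recovers_generator_flux(self, hek_cohort):
        """Analyzed refill curve tracks the generator's flux-load relation
        within 10% RMS (load-binned, interior loads)."""
        res = hek_cohort[0]
        ca = cm.calibrate_trace(res.trace, cm.RunConfig(profile="hek"))
        seg = cm.extract_refill_segment(ca)
        curve = cm.compute_uptake_curve(ca, seg)
        edges = np.arange(0.05, 0.7, 0.05)
        mids, obs = [], []
        for lo, hi in zip(edges[:-1], edges[1:]):
            m = (curve.load >= lo) & (curve.load < hi)
            if m.any():
                mids.append(0.5 * (lo + hi))
                obs.append(curve.rate[m].mean())
        truth = np.interp(mids, res.flux_load[:, 0], res.flux_load[:, 1])
        rms = np.sqrt(np.mean((np.array(obs) - truth) ** 2))
        assert rms / truth.mean() < 0.10


@pytest.fixture(scope="module")
def wave_result():
    return cm.simulate_cell(
        cm.default_config("hek", "WT", seed=3), cm.wave_protocol()
    )


class TestWaveDetection:
    def test_detects_each_simulated_wave_refill(self, wave_result):
        ca = cm.calibrate_trace(wave_result.trace, cm.RunConfig(profile="hek"))
        segs = cm.detect_wave_refills(ca)
        assert len(segs) >= 3
        # each refill starts near a wave nadir: low load, well below threshold
        load = ca.load_mm()
        for seg in segs:
            start_load = load[np.searchsorted(ca.time, seg.t_start)]
            assert start_load < 0.2
            assert seg.t_end - seg.t_start >= 1.0
        # one refill per simulated release (the last release may not have
        # completed its refill before the protocol ends)
        n_waves = len(wave_result.wave_times)
        assert n_waves - 2 <= len(segs) <= n_waves

    def test_monotone_refill_has_no_waves(self):
        time = np.arange(0.0, 40.0, 0.02)
        ca = 800.0 * (1.0 - np.exp(-0.1 * time))
        trace = cm.CaTrace(
            time=time,
            ca_free=ca,
            epochs=[cm.ProtocolEvent("mg_relief", 0.0, 40.0)],
        )
        assert cm.detect_wave_refills(trace) == []

    def test_flat_noise_trace_has_no_waves(self):
        rng = np.random.default_rng(0)
        time = np.arange(0.0, 40.0, 0.02)
        ca = 400.0 + rng.normal(0, 2.0, len(time))
        trace = cm.CaTrace(
            time=time,
            ca_free=ca,
            epochs=[cm.ProtocolEvent("mg_relief", 0.0, 40.0)],
        )
        assert cm.detect_wave_refills(trace) == []


class TestCurveSummaries:
    def _line_curve(self, a=0.3, c_max=0.8):
        load = np.linspace(0.01, c_max, 200)
        return cm.UptakeCurve(load=load, rate=a * (c_max - load))

    def test_max_rate_and_load_on_analytic_line(self):
        max_rate, max_load = cm.max_rate_and_load(self._line_curve())
        assert max_rate == pytest.approx(0.3 * (0.8 - 0.01))
        # 5%-of-max plateau rule puts the maximum load near the intercept
        assert 0.74 <= max_load <= 0.80

    def test_all_zero_curve(self):
        curve = cm.UptakeCurve(load=np.linspace(0, 0.8, 50), rate=np.zeros(50))
        max_rate, max_load = cm.max_rate_and_load(curve)
        assert max_rate == 0.0
        assert max_load == pytest.approx(0.8)

    def test_bin_rates_constant_curve(self):
        load = np.linspace(0.0, 0.8, 100)
        curve = cm.UptakeCurve(load=load, rate=np.full_like(load, 0.1))
        summaries = cm.bin_rates([curve])
        for b in summaries:
            assert b.mean_rate == pytest.approx(0.1)
            assert b.sem_rate == 0.0
            assert b.n_cells == 1

    def test_bin_means_match_line_midpoints(self):
        curve = self._line_curve()
        bins = {"a": (0.0, 0.27), "b": (0.27, 0.54), "c": (0.54, 0.8)}
        for b in cm.bin_rates([curve], bins):
            lo, hi = b.bin_edges
            mid = 0.5 * (lo + hi)
            assert b.mean_rate == pytest.approx(0.3 * (0.8 - mid), rel=0.02)

    def test_overlapping_bins_rejected(self):
        with pytest.raises(ValueError):
            cm.bin_rates([self._line_curve()], {"a": (0.0, 0.3), "b": (0.2, 0.5)})

    def test_empty_bin_triggers_coverage_warning(self):
        with pytest.warns(UserWarning, match="empty"):
            cm.bin_rates([self._line_curve()], {"beyond": (2.0, 3.0)})

    def test_higher_uptake_at_intermediate_than_low_loads(self, hek_report):
        """The luminal-activation signature: intermediate-load uptake exceeds
        low-load uptake across the cohort."""
        by_label = {b.bin_label: b for b in hek_report.bins}
        assert by_label["intermediate"].mean_rate > by_label["low"].mean_rate
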