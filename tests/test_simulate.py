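"""Forward simulator: flux model, integration, protocols, cohorts."""

import numpy as np
import pytest
from dataclasses import replace

import calumen as cm
from calumen.errors import DomainError, StabilityError
from calumen.simulate import draw_cohort_configs, initial_load


class TestPumpFlux:
    def test_boundary_zeros_without_basal_floor(self):
        cfg = cm.default_config("hek", "WT", basal_activation=0.0)
        assert cm.pump_flux(0.0, cfg) == 0.0
        assert cm.pump_flux(cfg.ca_thermo, cfg) == 0.0

    def test_direct_substitution_hyperbola_times_backpressure(self):
        # v_max=1, n=1, kd=0.14, ca_thermo=0.8, drive=1, no floor:
        # J(0.4) = (0.4/0.54)*(0.5)
        cfg = cm.default_config(
            "hek",
            "WT",
            v_max=1.0,
            hill_n=1.0,
            kd_lum=0.14,
            ca_thermo=0.8,
            basal_activation=0.0,
        )
        assert cm.pump_flux(0.4, cfg) == pytest.approx(0.37037, abs=1e-5)

    def test_single_interior_maximum(self):
        # away from the basal-floor region near zero load the flux rises to
        # one interior maximum and falls to zero at the maximum load
        cfg = cm.default_config("hek", "WT")
        grid = np.linspace(0.05 * cfg.ca_thermo, cfg.ca_thermo, 400)
        j = cm.pump_flux(grid, cfg)
        signs = np.sign(np.diff(j))
        changes = np.count_nonzero(np.diff(signs[signs != 0]) != 0)
        assert changes == 1
        assert 0 < grid[np.argmax(j)] < cfg.ca_thermo
        assert cm.pump_flux(cfg.ca_thermo, cfg) == 0.0

    def test_basal_floor_keeps_depleted_store_refillable(self):
        cfg = cm.default_config("hek", "WT")
        assert cm.pump_flux(0.0, cfg) == pytest.approx(
            cfg.basal_activation * cfg.v_max
        )

    def test_negative_load_rejected(self):
        with pytest.raises(DomainError):
            cm.pump_flux(-0.1, cm.default_config())


class TestSimulateCell:
    def test_mass_consistency_without_fluxes(self):
        """No pump and no leak: the state is constant to machine precision."""
        cfg = cm.default_config("hek", "TG", g_leak=0.0, noise_sigma=0.0)
        protocol = cm.Protocol(
            events=(cm.ProtocolEvent("baseline", 0.0, 10.0),)
        )
        res = cm.simulate_cell(cfg, protocol)
        assert np.all(res.truth.ca_free == res.truth.ca_free[0])

    def test_refill_plateau_reaches_thermodynamic_limit(self):
        """With the release channel blocked the store settles at ca_thermo."""
        cfg = cm.default_config("hek", "WT", g_leak=0.0, noise_sigma=0.0)
        res = cm.simulate_cell(cfg)
        rr = res.truth.epoch("ruthenium_red")
        m = (res.truth.time >= rr.t_end - 2.0) & (res.truth.time < rr.t_end)
        terminal = res.truth.ca_free[m].mean() / 1000.0
        assert terminal == pytest.approx(cfg.ca_thermo, rel=0.01)

    def test_pump_inhibition_prevents_refill(self):
        res = cm.simulate_cell(cm.default_config("hek", "TG", seed=2))
        rr = res.truth.epoch("ruthenium_red")
        m = (res.truth.time >= rr.t_end - 2.0) & (res.truth.time < rr.t_end)
        cfg = res.config
        assert res.truth.ca_free[m].mean() / 1000.0 < 0.01 * cfg.ca_thermo

    def test_disulfide_mutant_cannot_hold_load(self):
        """The C875A preset barely transports: the store stays nearly empty."""
        res = cm.simulate_cell(cm.default_config("hek", "C875A", seed=2))
        rr = res.truth.epoch("ruthenium_red")
        m = (res.truth.time >= rr.t_start) & (res.truth.time < rr.t_end)
        assert res.truth.ca_free[m].max() / 1000.0 < 0.15 * res.config.ca_thermo

    def test_identical_seed_bitwise_identical(self):
        cfg = cm.default_config("hek", "WT", seed=9)
        a = cm.simulate_cell(cfg)
        b = cm.simulate_cell(cfg)
        assert np.array_equal(a.trace.fluorescence, b.trace.fluorescence)
        assert np.array_equal(a.truth.ca_free, b.truth.ca_free)

    def test_integration_step_convergence(self):
        cfg = cm.default_config("hek", "WT", noise_sigma=0.0)
        coarse = cm.simulate_cell(cfg).truth.ca_free
        fine = cm.simulate_cell(replace(cfg, dt_sim=0.0005)).truth.ca_free
        scale = 1000.0 * cfg.ca_thermo
        assert np.max(np.abs(coarse - fine)) / scale < 0.001

    def test_unstable_step_raises(self):
        cfg = cm.default_config("hek", "WT", g_caffeine=1.0e4)
        with pytest.raises(StabilityError):
            cm.simulate_cell(cfg)

    def test_myocyte_truth_has_total_calcium(self):
        res = cm.simulate_cell(cm.default_config("myocyte", "WT", seed=4))
        assert res.truth.ca_total is not None
        # free <= total everywhere, with equality only at zero
        assert np.all(res.truth.ca_free <= res.truth.ca_total + 1e-9)

    def test_baseline_starts_at_leak_pump_balance(self):
        cfg = cm.default_config("hek", "WT", noise_sigma=0.0)
        x0 = initial_load(cfg)
        assert cm.pump_flux(x0, cfg) == pytest.approx(
            cfg.g_leak * x0, rel=1e-6
        )


@pytest.fixture(scope="module")
def wave_result():
    return cm.simulate_cell(
        cm.default_config("hek", "WT", seed=3), cm.wave_protocol()
    )


class TestWaves:
    def test_waves_cycle_between_threshold_and_termination(self, wave_result):
        cfg = wave_result.config
        relief = wave_result.truth.epoch("mg_relief")
        m = (wave_result.truth.time >= relief.t_start + 1.0) & (
            wave_result.truth.time < relief.t_end
        )
        load = wave_result.truth.ca_free[m] / 1000.0
        assert len(wave_result.wave_times) >= 3
        assert load.max() <= cfg.wave_threshold + 0.02
        assert load.min() <= cfg.wave_term + 0.02  # terminates almost empty

    def test_wave_refill_curve_matches_pump_flux(self, wave_result):
        """Inter-wave refills sample the same flux-load relation as the
        pharmacological refill (10% RMS, load-binned)."""
        ca = cm.calibrate_trace(wave_result.trace, cm.RunConfig(profile="hek"))
        segs = cm.detect_wave_refills(ca)
        curves = [
            cm.compute_uptake_curve(ca, s)
            for s in segs
            if s.mask(ca.time).sum() >= 20
        ]
        curve = cm.merge_curves(curves)
        edges = np.arange(0.05, 0.66, 0.05)
        mids, obs = [], []
        for lo, hi in zip(edges[:-1], edges[1:]):
            m = (curve.load >= lo) & (curve.load < hi)
            if m.any():
                mids.append(0.5 * (lo + hi))
                obs.append(curve.rate[m].mean())
        truth = np.interp(
            mids, wave_result.flux_load[:, 0], wave_result.flux_load[:, 1]
        )
        rms = np.sqrt(np.mean((np.asarray(obs) - truth) ** 2))
        assert rms / truth.mean() < 0.10


class TestCohort:
    def test_zero_cv_gives_identical_cells(self):
        base = cm.default_config("hek", "WT")
        results = cm.simulate_cohort(base, 3, cv=0.0, seed=5)
        assert len({r.config.v_max for r in results}) == 1
        assert len({r.config.ca_thermo for r in results}) == 1
        # noise seeds still differ per cell
        assert len({r.config.seed for r in results}) == 3

    def test_cohort_reproducible_under_seed(self):
        base = cm.default_config("hek", "WT")
        a = cm.simulate_cohort(base, 4, seed=11)
        b = cm.simulate_cohort(base, 4, seed=11)
        for ra, rb in zip(a, b):
            assert ra.config == rb.config
            assert np.array_equal(ra.trace.fluorescence, rb.trace.fluorescence)

    def test_lognormal_draws_are_mean_preserving(self):
        base = cm.default_config("hek", "WT")
        configs = draw_cohort_configs(base, 2000, cv=0.15, seed=1)
        vmaxes = np.array([c.v_max for c in configs])
        assert vmaxes.mean() == pytest.approx(base.v_max, rel=0.02)
        assert vmaxes.std() / vmaxes.mean() == pytest.approx(0.15, rel=0.1)


def test_invalid_configs_rejected():
    with pytest.raises(DomainError):
        cm.default_config("hek", "WT", wave_threshold=0.9, ca_thermo=0.8,
                          wave_term=0.95)
    with pytest.raises(DomainError):
        cm.default_config("hek", "WT", dt_sim=0.05)
    with pytest.raises(DomainError):
        cm.SimCellConfig(cytosolic_drive=0.0)
    with pytest.raises(DomainError):
        cm.default_config("hek", "XYZ")
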