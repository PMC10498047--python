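"""Phase-oscillator simulator: model primitives and generator contracts."""

import numpy as np
import pytest

from circabeam import synth
from circabeam.damio import bin_activity
from circabeam.light import build_regime
from circabeam.rhythm import chi_square_periodogram


class TestAdvancePhase:
    def test_dark_limit_advances_at_24_over_tau(self):
        spec = synth.oscillator_spec(tau_h=25.0, eps_p=0.4)
        phi = synth.advance_phase(10.0, 0.0, 60.0, spec)
        assert phi - 10.0 == pytest.approx(24.0 / 25.0)

    def test_light_accelerates_at_subjective_dawn(self):
        spec = synth.oscillator_spec(tau_h=24.0, eps_p=0.3)
        dark = synth.advance_phase(0.0, 0.0, 30.0, spec)
        lit = synth.advance_phase(0.0, 1.0, 30.0, spec)
        assert lit > dark

    def test_light_decelerates_at_subjective_dusk(self):
        spec = synth.oscillator_spec(tau_h=24.0, eps_p=0.3)
        dark = synth.advance_phase(12.0, 0.0, 30.0, spec)
        lit = synth.advance_phase(12.0, 1.0, 30.0, spec)
        assert lit < dark

    def test_wraps_into_24h(self):
        spec = synth.free_running_spec(24.0)
        assert 0 <= synth.advance_phase(23.9, 0.0, 30.0, spec) < 24.0

    def test_ll_period_lengthening_matches_closed_form(self, rng):
        # under constant light the realized period is tau / sqrt(1 - eps^2)
        spec = synth.oscillator_spec(tau_h=24.0, eps_p=0.4)
        phi = 0.0
        minutes = 0
        # integrate until the phase completes 10 full revolutions
        revs = 0
        prev = phi
        while revs < 10:
            phi = synth.advance_phase(phi, 1.0, 1.0, spec)
            minutes += 1
            if phi < prev:
                revs += 1
            prev = phi
        realized = minutes / 60.0 / 10.0
        assert realized == pytest.approx(24.0 / np.sqrt(1 - 0.4**2), rel=0.01)


class TestTransitionJump:
    def test_zero_amplitude_is_noop(self):
        spec = synth.free_running_spec(24.5)
        assert synth.transition_jump(10.0, 5.0, spec) == 10.0

    def test_dawn_pulse_advances(self):
        spec = synth.FlySpec(mode="oscillator", prc_amp_h=1.0)
        assert synth.transition_jump(0.0, 5.0, spec) > 0.0

    def test_early_night_pulse_delays(self):
        spec = synth.FlySpec(mode="oscillator", prc_amp_h=1.0)
        phi = 15.0
        assert synth.transition_jump(phi, 5.0, spec) < phi

    def test_zero_intensity_step_rejected(self):
        with pytest.raises(ValueError):
            synth.transition_jump(0.0, 0.0, synth.free_running_spec(24.0))

    def test_daily_pulses_entrain_a_slow_clock(self):
        # discrete-resetting oscillator, tau = 24.5: daily light pulses pull
        # the phase to a fixed point within ten cycles
        spec = synth.FlySpec(mode="oscillator", tau_h=24.5, prc_amp_h=1.5)
        phi = 6.0
        phases_at_pulse = []
        for _ in range(12):
            phi = synth.transition_jump(phi, 1.0, spec)
            for _ in range(1440):
                phi = synth.advance_phase(phi, 0.0, 1.0, spec)
            phases_at_pulse.append(phi)
        # locked: phase at pulse time stops moving
        assert abs(phases_at_pulse[-1] - phases_at_pulse[-2]) < 0.05


class TestEmission:
    def test_rate_without_masking_or_startle(self):
        spec = synth.entrained_locked_spec()
        rate = synth.emission_rate(11.0, 0.0, np.inf, spec)
        expected = spec.base_rate * synth.activity_waveform(11.0, spec)
        assert rate == pytest.approx(expected)

    def test_masker_rate_peaks_at_intensity_minimum(self):
        spec = synth.masker_spec(mask_coeff=1.5)
        ramp = build_regime("RAMP", {"i_min": 10, "i_max": 45})
        zt = np.arange(0, 1440, 15, dtype=float)
        i_norm = ramp.intensity_at(zt) / ramp.max_intensity()
        rates = synth.emission_rate(np.zeros_like(zt), i_norm, np.inf, spec)
        assert zt[np.argmax(rates)] == 0.0  # the ramp nadir sits at ZT00

    def test_startle_boosts_rate_after_lights_on(self):
        spec = synth.entrained_locked_spec()
        quiet = synth.emission_rate(3.0, 1.0, np.inf, spec)
        startled = synth.emission_rate(3.0, 1.0, 0.0, spec)
        assert startled == pytest.approx(quiet + spec.startle_amp)

    def test_startle_window_expires(self):
        spec = synth.entrained_locked_spec()
        late = synth.emission_rate(3.0, 1.0, 90.0, spec)
        assert late == synth.emission_rate(3.0, 1.0, np.inf, spec)


class TestSimulateFly:
    def test_same_seed_bitwise_identical(self, spp_regime):
        t1, _ = synth.simulate_fly(synth.entrained_locked_spec(seed=9), spp_regime, 5)
        t2, _ = synth.simulate_fly(synth.entrained_locked_spec(seed=9), spp_regime, 5)
        np.testing.assert_array_equal(t1.channel(1), t2.channel(1))

    def test_different_seeds_differ(self, spp_regime):
        t1, _ = synth.simulate_fly(synth.entrained_locked_spec(seed=1), spp_regime, 5)
        t2, _ = synth.simulate_fly(synth.entrained_locked_spec(seed=2), spp_regime, 5)
        assert np.any(t1.channel(1) != t2.channel(1))

    def test_dark_limit_period_equals_tau_within_grid_step(self, dd_regime):
        for tau in (23.0, 25.0):
            table, _ = synth.simulate_fly(
                synth.free_running_spec(tau, seed=0), dd_regime, 10
            )
            res = chi_square_periodogram(bin_activity(table, 20).channel(1), 20)
            assert abs(res.peak_period_h - tau) <= 1.0 / 3.0 + 1e-9

    def test_locked_fly_peaks_on_the_24h_grid_point(self, spp_regime):
        table, _ = synth.simulate_fly(synth.entrained_locked_spec(seed=0), spp_regime, 10)
        from circabeam.classify import classify_skeleton

        call = classify_skeleton(table)
        assert call.evidence["peak_period_h"] == pytest.approx(24.0)

    def test_ll_period_monotone_in_gain_and_intensity(self):
        # realized LL period is non-decreasing in eps_p and in intensity
        periods = []
        for eps in (0.15, 0.45):
            ll = build_regime("LL", {"intensity": 30})
            table, _ = synth.simulate_fly(
                synth.oscillator_spec(tau_h=23.8, eps_p=eps, seed=3), ll, 10
            )
            res = chi_square_periodogram(bin_activity(table, 20).channel(1), 20)
            periods.append(res.peak_period_h)
        assert periods[1] > periods[0]

    def test_phase_control_of_released_oscillator(self, ramp_regime):
        # entrained oscillator keeps its phase through the nadir release
        table, truth = synth.simulate_fly(
            synth.oscillator_spec(seed=1), ramp_regime, 12,
            release_after=9, burnin_days=10,
        )
        phases = truth["phase_at_zt00"]
        drift = abs(phases[10] - phases[9])
        assert min(drift, 24 - drift) < 1.0


class TestSimulateCohort:
    def test_bundle_shape_and_truth_rows(self, tmp_path, spp_regime):
        cohort = synth.CohortSpec(
            flies=[synth.entrained_locked_spec() for _ in range(32)],
            regime=spp_regime, days=2,
        )
        bundle = synth.simulate_cohort(cohort, base_seed=5, out_dir=tmp_path)
        assert len(bundle["monitor_files"]) == 1
        import pandas as pd

        truth = pd.read_csv(bundle["truth_csv"])
        assert len(truth) == 32
        assert truth.seed.is_unique

    def test_release_after_switches_to_nadir_constant(self, ramp_regime):
        spec = synth.masker_spec(seed=0)
        table, _ = synth.simulate_fly(spec, ramp_regime, 11, release_after=9)
        intensity, _ = synth._intensity_minutes(ramp_regime, 11, 9)
        assert np.all(intensity[9 * 1440 :] == ramp_regime.min_intensity())

    def test_round_trip_through_monitor_files(self, tmp_path, dd_regime):
        from circabeam.damio import read_monitor_file

        cohort = synth.CohortSpec(
            flies=[synth.free_running_spec(24.5) for _ in range(3)],
            regime=dd_regime, days=2,
        )
        bundle = synth.simulate_cohort(cohort, base_seed=1, out_dir=tmp_path)
        back = read_monitor_file(bundle["monitor_files"][0])
        for i, table in enumerate(bundle["tables"]):
            np.testing.assert_array_equal(back.channel(i + 1), table.channel(1))
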