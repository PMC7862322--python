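"""Sampling state machine, circulation mixing, metabolite plant, biosensor."""

import numpy as np
import pytest

from ochip_loop.fluidics import (
    Aliquot,
    MetabolitePlant,
    MixCompartments,
    Phase,
    PhaseDurations,
    SamplerState,
    aliquot_table,
    biosensor_read,
    circulate_mix,
    coefficient_of_variation,
    metabolite_concentrations,
    run_sampling_cycle,
    stored_volume,
    time_to_uniform,
    TubeGeometry,
)


class TestStoredVolume:
    def test_default_geometry_holds_forty_microliters(self):
        assert stored_volume(TubeGeometry()) == pytest.approx(40.0, abs=0.05)

    def test_hand_calculated_volume(self):
        # pi * 0.5^2 * 10 mm^3 = 7.854 uL
        assert stored_volume(TubeGeometry(1.0, 10.0)) == pytest.approx(7.854, abs=1e-3)

    def test_nonpositive_dimensions_rejected(self):
        with pytest.raises(ValueError):
            TubeGeometry(2.0, 0.0)
        with pytest.raises(ValueError):
            TubeGeometry(-1.0, 10.0)


class TestSamplingCycle:
    def test_full_schedule_yields_six_aliquots(self):
        state = SamplerState()
        for t in (0.0, 3.0, 6.0, 12.0, 18.0, 24.0):
            state = run_sampling_cycle(state, t, (1.0 + t, 5.0))
        assert len(state.containers) == 6
        table = aliquot_table(state)
        assert list(table.columns) == [
            "time_h", "volume_ul", "lactate_mM", "glucose_mM", "container_id",
        ]
        assert list(table["container_id"]) == list(range(6))

    def test_empty_schedule_never_samples(self):
        state = SamplerState(schedule=())
        new = run_sampling_cycle(state, 3.0, (1.0, 5.0))
        assert new.containers == ()
        assert "off-schedule" in new.messages[0]

    def test_phase_sequence_is_c_s_d_w(self):
        state = run_sampling_cycle(SamplerState(), 0.0, (1.0, 5.0))
        phases = [p for _, p in state.phase_log]
        assert phases == [Phase.CIRCULATING, Phase.SAMPLING, Phase.DRAINAGE, Phase.WAITING]
        times = [t for t, _ in state.phase_log]
        assert times == sorted(times)

    def test_off_schedule_call_is_logged_noop(self):
        state = SamplerState()
        new = run_sampling_cycle(state, 1.5, (1.0, 5.0))
        assert new.containers == ()
        assert len(new.messages) == 1

    def test_container_capacity_enforced(self):
        state = SamplerState(schedule=tuple(float(t) for t in range(30)), max_containers=3)
        for t in range(3):
            state = run_sampling_cycle(state, float(t), (1.0, 5.0))
        with pytest.raises(RuntimeError, match="capacity"):
            run_sampling_cycle(state, 3.0, (1.0, 5.0))

    def test_custom_durations_shift_phase_times(self):
        durations = PhaseDurations(circulating=60.0, sampling=5.0, drainage=15.0)
        state = run_sampling_cycle(SamplerState(), 0.0, (1.0, 5.0), durations=durations)
        times = [t for t, _ in state.phase_log]
        assert times[1] == pytest.approx(60.0 / 3600.0)
        assert times[3] == pytest.approx(80.0 / 3600.0)


class TestMixing:
    def bolus(self, **kwargs):
        return MixCompartments(dye=np.array([8.0] + [0.0] * 7), **kwargs)

    def test_uniform_dye_stays_uniform(self):
        m = MixCompartments(dye=np.full(8, 2.5))
        out = circulate_mix(m, 57.0)
        np.testing.assert_allclose(out.dye, 2.5)
        assert coefficient_of_variation(out) == 0.0

    def test_bolus_homogenizes_within_circulating_step(self):
        t = time_to_uniform(self.bolus())
        assert t <= 180.0

    def test_mass_conserved_for_arbitrary_durations(self, rng):
        m = self.bolus()
        total = m.total_mass()
        for _ in range(20):
            m = circulate_mix(m, float(rng.uniform(0.3, 40.0)))
            assert m.total_mass() == pytest.approx(total, rel=1e-9)

    def test_cv_monotone_nonincreasing(self):
        m = self.bolus()
        prev = coefficient_of_variation(m)
        for _ in range(200):
            m = circulate_mix(m, 1.0)
            cv = coefficient_of_variation(m)
            assert cv <= prev + 1e-12
            prev = cv

    def test_zero_rates_identity(self):
        m = MixCompartments(
            dye=np.array([1.0, 0, 0, 0]), circulation_rate=0.0, exchange_fraction=0.0
        )
        np.testing.assert_array_equal(circulate_mix(m, 10.0).dye, m.dye)


class TestMetabolitePlant:
    def test_no_excess_at_time_zero(self):
        p = MetabolitePlant(stim_window=(0.0, float("inf")))
        ls, _ = metabolite_concentrations(p, 0.0, stimulated=True)
        lc, _ = metabolite_concentrations(p, 0.0, stimulated=False)
        assert ls == lc

    @pytest.mark.parametrize("t, excess", [(6.0, 0.14), (24.0, 0.26)])
    def test_excess_anchors(self, t, excess):
        p = MetabolitePlant(stim_window=(0.0, float("inf")))
        ls, _ = metabolite_concentrations(p, t, stimulated=True)
        lc, _ = metabolite_concentrations(p, t, stimulated=False)
        assert ls / lc - 1.0 == pytest.approx(excess, abs=1e-12)

    def test_excess_monotone_in_stimulation_time(self):
        p = MetabolitePlant()
        values = [p.excess(t) for t in np.linspace(0, 48, 25)]
        assert all(b >= a for a, b in zip(values, values[1:]))

    def test_glucose_declines_and_ignores_stimulation(self):
        p = MetabolitePlant(stim_window=(0.0, float("inf")))
        _, g_stim = metabolite_concentrations(p, 12.0, stimulated=True)
        _, g_ctrl = metabolite_concentrations(p, 12.0, stimulated=False)
        assert g_stim == g_ctrl < p.glucose_initial
        # never negative, even far beyond depletion
        _, g_late = metabolite_concentrations(p, 1000.0, stimulated=False)
        assert g_late == 0.0

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            metabolite_concentrations(MetabolitePlant(), -1.0, False)

    def test_stim_window_limits_excess_accumulation(self):
        p = MetabolitePlant(stim_window=(12.0, 24.0))
        ls, _ = metabolite_concentrations(p, 12.0, stimulated=True)
        lc, _ = metabolite_concentrations(p, 12.0, stimulated=False)
        assert ls == lc  # stimulation has not started accumulating yet
        ls36, _ = metabolite_concentrations(p, 36.0, stimulated=True)
        lc36, _ = metabolite_concentrations(p, 36.0, stimulated=False)
        assert ls36 / lc36 - 1.0 == pytest.approx(p.excess(12.0))


class TestBiosensor:
    def aliquot(self, volume=40.0):
        return Aliquot(volume=volume, time=6.0, lactate=4.0, glucose=5.0)

    def test_zero_noise_is_exact(self):
        assert biosensor_read(self.aliquot()) == (4.0, 5.0)

    def test_fixed_seed_reproducible(self):
        a = biosensor_read(self.aliquot(), noise_sd=0.05, seed=42)
        b = biosensor_read(self.aliquot(), noise_sd=0.05, seed=42)
        assert a == b

    def test_under_volume_rejected_naming_requirement(self):
        with pytest.raises(ValueError, match="40"):
            biosensor_read(self.aliquot(volume=20.0))

    def test_default_tube_aliquot_meets_sensor_minimum(self):
        a = Aliquot(volume=stored_volume(TubeGeometry()), time=0.0, lactate=1.0, glucose=5.0)
        assert biosensor_read(a) == (1.0, 5.0)

    def test_noise_scale_recovered_by_monte_carlo(self):
        reads = [
            biosensor_read(self.aliquot(), noise_sd=0.05, seed=s)[0] for s in range(1000)
        ]
        sd = np.std(reads) / 4.0  # relative sd
        assert sd == pytest.approx(0.05, rel=0.2)


def test_manual_vs_automated_sampling_equivalence():
    """With zero sensor noise, aliquot concentrations equal direct plant
    evaluation at the sampled times (automated == manual pipetting)."""
    p = MetabolitePlant(stim_window=(0.0, float("inf")))
    state = SamplerState()
    for t in state.schedule:
        state = run_sampling_cycle(state, t, metabolite_concentrations(p, t, True))
    for a in state.containers:
        manual = metabolite_concentrations(p, a.time, True)
        assert biosensor_read(a) == pytest.approx(manual)
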