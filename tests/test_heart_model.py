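"""Elastance family, valves, systole bookkeeping and elastance derivation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from coroloop.heart_model import (ClinicalCycleData, ElastanceFunction,
                                  HeartChamber, Valve, chamber_pressure,
                                  derive_elastance, read_cycle_data,
                                  systole_fractions_for_hr, systole_interval,
                                  valve_flow, write_cycle_data)
from coroloop.synthetic_data import generate_cycle_data


def make_ef(**kw):
    args = dict(e_max=4.0, e_min=0.2, v0=8.0, t_peak_fraction=0.2,
                systole_fraction=0.36)
    args.update(kw)
    return ElastanceFunction(**args)


class TestElastanceFunction:
    @settings(max_examples=50, deadline=None)
    @given(st.floats(-3, 3))
    def test_activation_is_periodic_and_bounded(self, phase):
        ef = make_ef()
        a = ef.activation(phase)
        assert 0.0 <= a <= 1.0
        assert a == pytest.approx(ef.activation(phase + 1.0), abs=1e-12)

    def test_activation_peaks_at_t_peak(self):
        ef = make_ef()
        assert ef.activation(ef.t_peak_fraction) == pytest.approx(1.0)
        assert ef.activation(0.0) == pytest.approx(0.0)
        assert ef.activation(0.99 * ef.systole_fraction) < 0.01

    def test_invariants_enforced(self):
        with pytest.raises(ValueError):
            make_ef(e_max=0.1)  # e_max <= e_min
        with pytest.raises(ValueError):
            make_ef(t_peak_fraction=0.5, systole_fraction=0.4)

    def test_retiming_shrinks_duration_but_grows_fraction(self):
        ef = make_ef()
        fast = ef.with_rate(73.0, 106.0)
        dur_slow = ef.systole_fraction * 60.0 / 73.0
        dur_fast = fast.systole_fraction * 60.0 / 106.0
        assert dur_fast < dur_slow  # absolute systole shortens
        assert fast.systole_fraction > ef.systole_fraction  # fraction grows


class TestChamberPressure:
    def test_elastance_law(self):
        # near-constant E = 2 mmHg/mL: P = E·(V - V0)
        ef = make_ef(e_min=2.0, e_max=2.0 + 1e-9, v0=10.0)
        ch = HeartChamber("LV", ef, volume=60.0)
        assert chamber_pressure(ch, 0.3, period=0.8) == pytest.approx(100.0)

    def test_zero_at_unstressed_volume(self):
        ch = HeartChamber("LV", make_ef(), volume=8.0)
        for t in (0.0, 0.1, 0.25, 0.6):
            assert chamber_pressure(ch, t, period=0.8) == pytest.approx(0.0)

    def test_end_systolic_pressure_matches_generator_target(self, noiseless_patient):
        # by construction the noiseless fixture's peak pressure is the target
        data, truth = generate_cycle_data(noiseless_patient, "rest", "LV")
        target = noiseless_patient.rest.p_ao_syst
        assert data.pressure.max() == pytest.approx(target, rel=0.02)


class TestValveFlow:
    def test_zero_at_zero_dp(self):
        v = Valve("ao", "a", "b", r_open=1.0)
        assert valve_flow(v, 0.0) == 0.0

    def test_forward_limit(self):
        v = Valve("ao", "a", "b", r_open=1.0, steepness=50.0)
        assert valve_flow(v, 10.0) == pytest.approx(10.0, rel=0.01)

    def test_reverse_blocked(self):
        v = Valve("ao", "a", "b", r_open=1.0, leak_conductance=0.0)
        assert abs(valve_flow(v, -10.0)) < 0.01 * valve_flow(v, 10.0)

    def test_smooth_and_sign_preserving(self):
        v = Valve("ao", "a", "b", r_open=0.5, leak_conductance=1e-4)
        dp = np.linspace(-30, 30, 60001)
        q = valve_flow(v, dp)
        assert np.all(np.sign(q) == np.sign(dp))
        # continuously differentiable: on a fine grid the numerical slope
        # changes only infinitesimally between neighbours
        slope = np.diff(q) / np.diff(dp)
        assert np.max(np.abs(np.diff(slope))) < 0.01


class TestSystoleInterval:
    def test_interval_length_matches_family(self):
        ef = make_ef(systole_fraction=0.35, t_peak_fraction=0.21)
        t0, t1 = systole_interval(ef, hr=73.0, threshold=0.05)
        # independent check: fraction of a dense phase grid above threshold
        phi = np.linspace(0, 1, 200001)
        frac = np.mean(ef.activation(phi) > 0.05)
        assert (t1 - t0) == pytest.approx(frac * 60.0 / 73.0, rel=1e-3)

    def test_zero_threshold_gives_support(self):
        ef = make_ef(systole_fraction=0.35)
        t0, t1 = systole_interval(ef, hr=60.0, threshold=0.0)
        assert (t1 - t0) == pytest.approx(0.35, rel=0.01)

    def test_rate_dependence_of_fraction(self):
        tp_r, ts_r = systole_fractions_for_hr(73.0)
        tp_s, ts_s = systole_fractions_for_hr(106.0)
        assert ts_s > ts_r
        assert ts_s * 60 / 106 < ts_r * 60 / 73


class TestDeriveElastance:
    @pytest.mark.parametrize("condition,ventricle", [
        ("rest", "LV"), ("rest", "RV"), ("stress", "LV"), ("stress", "RV")])
    def test_noiseless_round_trip(self, noiseless_patient, condition, ventricle):
        data, truth = generate_cycle_data(noiseless_patient, condition, ventricle)
        fit = derive_elastance(data)
        e = fit.elastance
        assert e.e_max == pytest.approx(truth.e_max, rel=0.02)
        assert e.e_min == pytest.approx(truth.e_min, rel=0.02)
        assert abs(e.v0 - truth.v0) < 0.02 * truth.v0 + 0.5
        assert e.t_peak_fraction == pytest.approx(truth.t_peak_fraction, abs=0.01)
        assert fit.rel_rms < 0.01

    def test_noisy_recovery_with_known_v0(self, patient):
        data, truth = generate_cycle_data(patient, "rest", "LV")
        fit = derive_elastance(data, v0=truth.v0)
        assert fit.elastance.e_max == pytest.approx(truth.e_max, rel=0.05)

    def test_constant_volume_rejected(self):
        t = np.linspace(0, 0.8, 200)
        with pytest.raises(ValueError, match="constant"):
            ClinicalCycleData(t, np.full_like(t, 50.0), t,
                              50.0 + 20 * np.sin(2 * np.pi * t / 0.8) ** 2, hr=75)

    def test_fixed_v0_above_minimum_volume_rejected(self, noiseless_patient):
        data, _ = generate_cycle_data(noiseless_patient, "rest", "LV")
        with pytest.raises(ValueError, match="V0"):
            derive_elastance(data, v0=float(data.volume.min()) + 1.0)


def test_cycle_data_csv_round_trip(tmp_path, patient):
    data, _ = generate_cycle_data(patient, "rest", "LV")
    write_cycle_data(data, tmp_path, stem="lv")
    back = read_cycle_data(tmp_path, stem="lv")
    np.testing.assert_allclose(back.volume, data.volume, rtol=1e-6)
    np.testing.assert_allclose(back.pressure, data.pressure, rtol=1e-6)
    assert back.hr == data.hr
    np.testing.assert_allclose(back.r_wave_times, data.r_wave_times)
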