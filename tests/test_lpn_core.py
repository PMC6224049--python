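"""Circuit assembly, integration, conservation and linear-limit oracles."""

import numpy as np
import pytest
from scipy.linalg import expm

from coroloop import builder
from coroloop.heart_model import ElastanceFunction, HeartChamber, Valve
from coroloop.lpn_core import (Capacitor, IntegrationError, LPNModel,
                               TopologyError, VascularSegment, assemble_system,
                               run_cycles, run_to_periodic_state,
                               volume_conservation_error)
from coroloop.synthetic_data import SyntheticPatientSpec


def constant_chamber(name="CH", e=1.0, v0=0.0, volume=2.0):
    """A chamber whose elastance is constant to within 1e-9 (linear limit)."""
    ef = ElastanceFunction(e_max=e * (1 + 1e-9), e_min=e, v0=v0,
                           t_peak_fraction=0.3, systole_fraction=0.6)
    return HeartChamber(name, ef, volume=volume)


@pytest.fixture(scope="module")
def rest_model():
    return builder.build_model(SyntheticPatientSpec(seed=0))


class TestAssembly:
    def test_two_node_rhs_values(self):
        # chamber (E=1, V=2, V0=0) feeding one RC segment: Q = 2 into the
        # capacitor, equal and opposite volume derivatives
        m = LPNModel(chambers=[constant_chamber()],
                     valves=[],
                     segments=[VascularSegment("seg", "CH", "N", R=1.0, C=1.0,
                                               initial_pressure=0.0)])
        system = assemble_system(m)
        system.period = 1.0
        dy = system.rhs(0.0, np.array([2.0, 0.0]))
        assert dy[0] == pytest.approx(-2.0)
        assert dy[1] == pytest.approx(+2.0)

    def test_default_model_rhs_finite(self, rest_model):
        system = assemble_system(rest_model)
        system.period = 60.0 / 73.0
        dy = system.rhs(0.0, system.default_initial_state())
        assert np.all(np.isfinite(dy))

    def test_disconnected_topology_rejected(self):
        m = LPNModel(chambers=[constant_chamber()],
                     valves=[],
                     segments=[VascularSegment("a", "CH", "N1", R=1.0, C=1.0),
                               VascularSegment("b", "X1", "X2", R=1.0, C=1.0)],
                     capacitors=[Capacitor("X1", C=1.0)])
        with pytest.raises(TopologyError, match="disconnected|unreachable"):
            assemble_system(m)

    def test_bare_junction_node_rejected(self):
        # N has neither a chamber nor a capacitor: flow balance is algebraic
        m = LPNModel(chambers=[constant_chamber()],
                     valves=[],
                     segments=[VascularSegment("a", "CH", "N", R=1.0),
                               VascularSegment("b", "N", "M", R=1.0, C=1.0)])
        with pytest.raises(TopologyError, match="no capacitor"):
            assemble_system(m)

    def test_duplicate_capacitor_rejected(self):
        m = LPNModel(chambers=[constant_chamber()],
                     valves=[],
                     segments=[VascularSegment("a", "CH", "N", R=1.0, C=1.0),
                               VascularSegment("b", "CH", "N", R=1.0, C=2.0)])
        with pytest.raises(TopologyError, match="two capacitor"):
            assemble_system(m)


class TestRunCycles:
    def test_closed_loop_conserves_volume(self):
        m = LPNModel(chambers=[constant_chamber(volume=30.0)],
                     valves=[],
                     segments=[VascularSegment("out", "CH", "N", R=0.5, C=2.0,
                                               initial_pressure=10.0),
                               VascularSegment("back", "N", "CH", R=0.5)])
        res = run_cycles(assemble_system(m), hr=60.0, n_cycles=10)
        assert volume_conservation_error(res, m) < 1e-3

    def test_rest_model_reaches_periodic_state(self, rest_model):
        system = assemble_system(rest_model)
        res = run_cycles(system, hr=73.0, n_cycles=20)
        c = res.cycle_markers
        p_ao = res.pressure("AO")
        mean_last = p_ao[c[-1]:].mean()
        mean_prev = p_ao[c[-2]:c[-1]].mean()
        assert abs(mean_last - mean_prev) / mean_last < 0.005

    def test_output_grid_refinement_is_converged(self, rest_model):
        sv = {}
        for dt in (1e-3, 5e-4):
            system = assemble_system(rest_model)
            res = run_cycles(system, hr=73.0, n_cycles=8, dt=dt)
            v = res.volume("LV")[res.last_cycle()]
            sv[dt] = v.max() - v.min()
        assert abs(sv[1e-3] - sv[5e-4]) / sv[5e-4] < 0.005

    def test_invalid_arguments_rejected(self, rest_model):
        system = assemble_system(rest_model)
        for kw in ({"dt": 0.0}, {"n_cycles": 0}, {"hr": -1.0}):
            args = dict(hr=73.0, n_cycles=1, dt=1e-3)
            args.update(kw)
            with pytest.raises(ValueError):
                run_cycles(system, **args)


class TestPeriodicState:
    def test_rest_model_converges_within_50_cycles(self, rest_model):
        system = assemble_system(rest_model)
        res = run_to_periodic_state(system, hr=73.0, tol=1e-3, max_cycles=50)
        assert res.converged
        assert res.n_cycles_run <= 50

    def test_linear_rc_loop_converges_at_analytic_rate(self):
        # largest time constant R·C = 1 s, period 1 s: the transient decays
        # like exp(-t/tau); tol 1e-2 must be reached within ~a dozen cycles
        m = LPNModel(chambers=[constant_chamber(e=1.0, volume=40.0)],
                     valves=[],
                     segments=[VascularSegment("out", "CH", "N", R=0.5, C=2.0,
                                               initial_pressure=0.0),
                               VascularSegment("back", "N", "CH", R=0.5)])
        res = run_to_periodic_state(assemble_system(m), hr=60.0, tol=1e-2,
                                    max_cycles=40)
        assert res.converged
        assert res.n_cycles_run <= 15

    def test_single_cycle_budget_returns_unconverged(self, rest_model):
        system = assemble_system(rest_model)
        res = run_to_periodic_state(system, hr=73.0, tol=1e-3, max_cycles=1)
        assert not res.converged
        assert res.n_cycles_run == 1
        assert len(res.time) > 0

    def test_tolerance_domain(self, rest_model):
        system = assemble_system(rest_model)
        with pytest.raises(ValueError):
            run_to_periodic_state(system, hr=73.0, tol=0.5)


class TestConservation:
    def test_open_loop_leaks_and_is_reported(self):
        # grounding one terminal to a constant-pressure reservoir breaks
        # closure; the audit still reports the (growing) deviation
        m = LPNModel(chambers=[constant_chamber(volume=30.0)],
                     valves=[],
                     segments=[VascularSegment("out", "CH", "N", R=0.5, C=2.0,
                                               initial_pressure=5.0),
                               VascularSegment("drain", "N", "GND", R=1.0)],
                     sources={"GND": 0.0})
        res = run_cycles(assemble_system(m), hr=60.0, n_cycles=5)
        err = volume_conservation_error(res, m)
        assert err > 1e-3
        nvol = res.n_chambers + res.n_caps
        totals = res.states[:, :nvol].sum(axis=1)
        assert totals[-1] < totals[0]  # drains monotonically into the sink

    def test_zero_duration_result_reports_zero(self, rest_model):
        system = assemble_system(rest_model)
        res = run_cycles(system, hr=73.0, n_cycles=1)
        res.states = res.states[:1]
        assert volume_conservation_error(res, rest_model) == 0.0


class TestLinearOracles:
    def test_matrix_exponential_agreement(self):
        """No valves + constant elastance: trajectory must match expm."""
        from tests_support_linear import linear_test_model
        m = linear_test_model()
        system = assemble_system(m)
        system.period = 1.0
        y0 = system.default_initial_state()
        n = len(y0)
        # probe the (exactly linear) RHS to build dy/dt = A y + b
        b = system.rhs(0.0, np.zeros(n))
        A = np.column_stack([system.rhs(0.0, e) - b for e in np.eye(n)])
        t_end = 2.0
        res = run_cycles(system, hr=60.0, n_cycles=2)
        # affine solution via expm on the homogeneous coordinates trick
        M = np.zeros((n + 1, n + 1))
        M[:n, :n] = A
        M[:n, n] = b
        for t, y in [(t_end, res.states[-1])]:
            z = expm(M * t) @ np.append(y0, 1.0)
            scale = np.linalg.norm(z[:n])
            assert np.linalg.norm(y - z[:n]) / scale < 0.005

    def test_rc_frequency_response(self):
        """Driven RC low-pass: simulated gain and phase match closed form."""
        R, C, f = 0.8, 0.25, 2.0
        w = 2 * np.pi * f
        m = LPNModel(chambers=[], valves=[],
                     segments=[VascularSegment("rc", "SRC", "N", R=R, C=C,
                                               initial_pressure=50.0)],
                     sources={"SRC": lambda t: 50.0 + 10.0 * np.sin(w * t)})
        system = assemble_system(m)
        res = run_cycles(system, hr=60.0, n_cycles=6, dt=5e-4,
                         rtol=1e-8, atol=1e-10)
        mask = res.time >= 3.0  # past the transient (tau = RC = 0.2 s)
        t, p = res.time[mask], res.node_pressures[mask, 0]
        X = np.column_stack([np.sin(w * t), np.cos(w * t), np.ones_like(t)])
        coef, *_ = np.linalg.lstsq(X, p, rcond=None)
        gain = np.hypot(coef[0], coef[1]) / 10.0
        phase = np.arctan2(-coef[1], coef[0])
        gain_true = 1.0 / np.sqrt(1.0 + (w * R * C) ** 2)
        phase_true = np.arctan(w * R * C)
        assert gain == pytest.approx(gain_true, rel=0.01)
        assert phase == pytest.approx(phase_true, rel=0.01)

    def test_inertial_element_step_response(self):
        """R-L segment into a stiff reservoir: Q(t) follows the RL ramp."""
        R, L = 2.0, 0.5
        m = LPNModel(chambers=[], valves=[],
                     segments=[VascularSegment("rl", "SRC", "N", R=R, L=L,
                                               C=1e4, initial_pressure=0.0)],
                     sources={"SRC": 10.0})
        system = assemble_system(m)
        res = run_cycles(system, hr=60.0, n_cycles=2, rtol=1e-8, atol=1e-10)
        q = res.flow("rl")
        t = res.time
        q_true = 10.0 / R * (1.0 - np.exp(-R * t / L))
        i = np.searchsorted(t, 0.5)
        assert q[i] == pytest.approx(q_true[i], rel=0.02)
        assert q[-1] == pytest.approx(10.0 / R, rel=0.02)


def test_tidy_csv_export_round_trip(tmp_path, rest_model):
    import json

    import pandas as pd
    system = assemble_system(rest_model)
    res = run_cycles(system, hr=73.0, n_cycles=1)
    path = tmp_path / "run.csv"
    res.to_tidy_csv(path)
    df = pd.read_csv(path)
    assert set(df.columns) == {"time", "entity", "quantity", "value"}
    ao = df[(df.entity == "AO") & (df.quantity == "pressure_mmHg")]
    np.testing.assert_allclose(ao.value.to_numpy(), res.pressure("AO"), rtol=1e-6)
    meta = json.loads((tmp_path / "run.csv.json").read_text())
    assert meta["hr_bpm"] == 73.0
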