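"""Target simulation, least-squares refinement, oxygen-constant fit."""

import numpy as np
import pytest

from coroloop import builder
from coroloop.calibration import (CalibrationTargets, Target, apply_parameters,
                                  calibrate, fit_oxygen_constants,
                                  simulate_targets)
from coroloop.synthetic_data import SyntheticPatientSpec, generate_targets


@pytest.fixture(scope="module")
def rest_model():
    return builder.build_model(SyntheticPatientSpec(seed=0))


@pytest.fixture(scope="module")
def rest_values(rest_model):
    p = SyntheticPatientSpec(seed=0)
    values, result = simulate_targets(rest_model, hr=73.0, bsa=p.bsa)
    return values, result


class TestSimulateTargets:
    def test_co_identity(self, rest_values):
        values, result = rest_values
        v = result.volume("LV")[result.last_cycle()]
        assert values["co"] == pytest.approx((v.max() - v.min()) * 73 / 1000,
                                             rel=1e-12)

    def test_svr_identity(self, rest_values):
        values, _ = rest_values
        assert values["svr"] == pytest.approx(
            (values["map"] - values["cvp"]) / values["co"], rel=1e-12)

    def test_all_targets_finite_positive(self, rest_values):
        values, _ = rest_values
        for name, v in values.items():
            assert np.isfinite(v) and v > 0, name


class TestTargetsContainer:
    def test_required_targets_enforced(self):
        with pytest.raises(ValueError, match="co"):
            CalibrationTargets(targets={"map": Target(70, "mmHg")},
                               bsa=0.75, hr=73)

    def test_volume_pair_required(self):
        with pytest.raises(ValueError, match="volume pair"):
            CalibrationTargets(targets={"map": Target(70, "mmHg"),
                                        "co": Target(2.5, "L/min")},
                               bsa=0.75, hr=73)

    def test_negative_weight_rejected(self):
        with pytest.raises(ValueError):
            Target(70, "mmHg", weight=-1.0)


class TestCalibrate:
    def test_self_recovery_of_perturbed_parameters(self, rest_model):
        """Targets from a known model; a perturbed start must find it back."""
        truth_scales = {"sys_distal_r_scale": 1.25, "venous_p_scale": 0.85}
        truth = apply_parameters(rest_model, truth_scales)
        p = SyntheticPatientSpec(seed=0)
        values, _ = simulate_targets(truth, hr=73.0, bsa=p.bsa, tol=5e-4)
        targets = CalibrationTargets(
            targets={k: Target(v, "-", weight=1.0)
                     for k, v in values.items() if k != "hr"},
            bsa=p.bsa, hr=73.0)
        report, _ = calibrate(
            rest_model, targets,
            {"sys_distal_r_scale": (0.5, 2.0), "venous_p_scale": (0.5, 2.0)},
            budget=40)
        assert report.parameters["sys_distal_r_scale"] == pytest.approx(1.25, rel=0.02)
        assert report.parameters["venous_p_scale"] == pytest.approx(0.85, rel=0.02)
        assert report.max_discrepancy < 0.01

    def test_infeasible_targets_reported_not_hidden(self, rest_model):
        """A self-contradictory MAP/CO/SVR triple cannot fit below its own
        inconsistency; the report must expose the residual discrepancy."""
        p = SyntheticPatientSpec(seed=0)
        t = generate_targets(p, "rest")
        t.targets["svr"] = Target(t.targets["svr"].value * 2.0, "WU", weight=2.0)
        report, _ = calibrate(rest_model, t, {"sys_distal_r_scale": (0.5, 2.0)},
                              budget=25)
        assert report.max_discrepancy > 0.05

    def test_deterministic_reports(self, rest_model):
        p = SyntheticPatientSpec(seed=0)
        t = generate_targets(p, "rest")
        free = {"sys_distal_r_scale": (0.5, 2.0), "venous_p_scale": (0.5, 2.0)}
        r1, _ = calibrate(rest_model, t, free, budget=15)
        r2, _ = calibrate(rest_model, t, free, budget=15)
        assert r1.to_json() == r2.to_json()

    def test_best_objective_is_monotone(self, rest_model):
        p = SyntheticPatientSpec(seed=0)
        t = generate_targets(p, "rest")
        report, _ = calibrate(rest_model, t, {"venous_p_scale": (0.5, 2.0)},
                              budget=15)
        hist = np.array(report.objective_history)
        assert np.all(np.diff(hist) <= 0)

    def test_unknown_parameter_rejected(self, rest_model):
        with pytest.raises(KeyError):
            apply_parameters(rest_model, {"no_such_knob": 1.0})


class TestOxygenConstants:
    def test_closed_form_without_basal(self):
        from coroloop.units import MMHG_ML_TO_J
        consts = fit_oxygen_constants({"LV": 0.5}, hr=73.0,
                                      mvo2_anchors={"LV": 5.42},
                                      basal_fraction=0.0)
        assert consts["LV"].beta == 0.0
        assert consts["LV"].alpha == pytest.approx(
            5.42 / ((0.5 / MMHG_ML_TO_J) * 73.0))

    def test_anchor_scaling_is_linear(self):
        a1 = fit_oxygen_constants({"LV": 0.5}, 73.0, {"LV": 5.0},
                                  basal_fraction=0.2)["LV"]
        a2 = fit_oxygen_constants({"LV": 0.5}, 73.0, {"LV": 10.0},
                                  basal_fraction=0.2)["LV"]
        assert a2.alpha == pytest.approx(2 * a1.alpha)
        assert a2.beta == pytest.approx(2 * a1.beta)

    def test_anchors_reproduced_at_rest_rate(self):
        from coroloop.coronary_control import OxygenAccounting, mvo2_rate
        consts = fit_oxygen_constants({"LV": 0.45, "RV": 0.33}, 73.0,
                                      {"LV": 5.42, "RV": 5.10})
        for vent, anchor in (("LV", 5.42), ("RV", 5.10)):
            acct = OxygenAccounting(extraction=1.0, alpha=consts[vent].alpha,
                                    beta=consts[vent].beta)
            pva = 0.45 if vent == "LV" else 0.33
            assert mvo2_rate(pva, 73.0, acct) == pytest.approx(anchor)

    def test_nonpositive_pva_rejected(self):
        with pytest.raises(ValueError):
            fit_oxygen_constants({"LV": 0.0}, 73.0, {"LV": 5.42})
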