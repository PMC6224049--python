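"""End-to-end study orchestration on a synthetic patient.

Stages mirror how the quantities interlock clinically: (1) ventricular
elastances from cycle data, (2) algebraic resistance estimates, (3)
least-squares hemodynamic calibration at Rest, (4) oxygen-constant fit to
the Rest MVO2 anchors, (5) coronary-controller convergence and reserve
pinning, (6) Stress construction and calibration, (7) PRS root-finding on
the MAP target, (8) per-condition summaries and comparisons.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import builder
from .calibration import (CalibrationReport, OxygenConstants, calibrate,
                          default_free_parameters, fit_oxygen_constants,
                          simulate_targets)
from .coronary_control import pv_loop_workload, pva_per_beat
from .heart_model import derive_elastance
from .lpn_core import LPNModel, SimulationResult
from .postprocess import (ComparisonReport, ConditionSummary, compare_conditions,
                          summarize_condition)
from .scenarios import (ScenarioSpec, build_prs, build_rest, build_stress,
                        run_condition)
from .synthetic_data import (SyntheticPatientSpec, generate_cycle_data,
                             generate_targets)
from .tables import REST_MVO2_ANCHORS, TABLE1

__all__ = ["StudyResult", "calibrate_rest", "run_study", "run_long_prs",
           "ventricular_pva", "territory_masses"]


def territory_masses(bsa: float) -> dict[str, float]:
    """Perfused myocardial mass (g) per territory from the mass indices."""
    return {"LCA": TABLE1["Rest"]["mass_index_lv"] * bsa,
            "RCA": TABLE1["Rest"]["mass_index_rv"] * bsa}


def ventricular_pva(result: SimulationResult, model: LPNModel) -> dict[str, float]:
    """Per-beat PVA (J) of both ventricles from the final simulated cycle."""
    period = 60.0 / result.hr
    last = result.last_cycle()
    t = result.time[last]
    out = {}
    for vent in ("LV", "RV"):
        v = result.volume(vent)[last]
        p = result.pressure(vent)[last]
        work = pv_loop_workload(np.append(v, v[0]), np.append(p, p[0]),
                                closure_tol=np.inf)
        ef = model.chamber(vent).elastance
        a = ef.activation((t - t[0]) / period)
        i_es = int(np.argmax(a))
        out[vent] = pva_per_beat(work, ef, (float(v[i_es]), float(p[i_es])))
    return out


@dataclass
class StudyResult:
    patient: SyntheticPatientSpec
    oxygen: dict[str, OxygenConstants]
    rest_report: CalibrationReport
    models: dict[str, LPNModel] = field(default_factory=dict)
    specs: dict[str, ScenarioSpec] = field(default_factory=dict)
    results: dict[str, SimulationResult] = field(default_factory=dict)
    logs: dict[str, pd.DataFrame] = field(default_factory=dict)
    summaries: dict[str, ConditionSummary] = field(default_factory=dict)
    comparisons: ComparisonReport | None = None


def calibrate_rest(patient: SyntheticPatientSpec, budget: int = 150,
                   derive_from_data: bool = True):
    """Staged Rest calibration: elastances from cycle data, then refinement.

    Returns ``(report, calibrated_model, targets)``.
    """
    rest_targets = generate_targets(patient, "rest")
    model0 = builder.build_model(patient)
    if derive_from_data:
        for vent in ("LV", "RV"):
            data, _truth = generate_cycle_data(patient, "rest", vent)
            fit = derive_elastance(data)
            model0.chamber(vent).elastance = fit.elastance
    report, calibrated = calibrate(model0, rest_targets,
                                   default_free_parameters(), budget=budget)
    return report, calibrated, rest_targets


def run_study(patient: SyntheticPatientSpec, rest_budget: int = 150,
              stress_budget: int = 70, derive_from_data: bool = True,
              conditions: tuple[str, ...] = ("Rest", "Stress", "PRS"),
              map_drop_fraction: float = 0.31) -> StudyResult:
    """Run the full three-condition study on a synthetic patient."""
    rest_report, calibrated, rest_targets = calibrate_rest(
        patient, budget=rest_budget, derive_from_data=derive_from_data)

    # oxygen constants from a controller-frozen Rest run
    _, pre_result = simulate_targets(calibrated, rest_targets.hr, patient.bsa)
    pva = ventricular_pva(pre_result, calibrated)
    oxygen = fit_oxygen_constants(pva, rest_targets.hr, REST_MVO2_ANCHORS)

    rest_model, rest_spec, rest_result, rest_log = build_rest(
        calibrated, oxygen, hr=patient.rest.hr)
    study = StudyResult(patient=patient, oxygen=oxygen, rest_report=rest_report)
    study.models["Rest"] = rest_model
    study.specs["Rest"] = rest_spec
    study.results["Rest"] = rest_result
    study.logs["Rest"] = rest_log

    if "Stress" in conditions:
        stress_elastances = {}
        for vent in ("LV", "RV"):
            if derive_from_data:
                data, _truth = generate_cycle_data(patient, "stress", vent)
                stress_elastances[vent] = derive_elastance(data).elastance
            else:
                stress_elastances[vent] = builder.design_elastance(
                    patient.stress, vent, patient.bsa)
        stress_targets = generate_targets(patient, "stress")
        stress_model, stress_spec, stress_result, stress_log = build_stress(
            rest_model, stress_targets, oxygen,
            stress_elastances=stress_elastances, hr=patient.stress.hr,
            budget=stress_budget)
        study.models["Stress"] = stress_model
        study.specs["Stress"] = stress_spec
        study.results["Stress"] = stress_result
        study.logs["Stress"] = stress_log

    if "PRS" in conditions and "Stress" in conditions:
        last = stress_result.last_cycle()
        map_stress = float(np.mean(stress_result.pressure("AO")[last]))
        prs_model, prs_spec, prs_result, prs_log = build_prs(
            stress_model, stress_spec, oxygen, map_stress,
            map_drop_fraction=map_drop_fraction,
            warm_state=stress_result.states[-1].copy())
        study.models["PRS"] = prs_model
        study.specs["PRS"] = prs_spec
        study.results["PRS"] = prs_result
        study.logs["PRS"] = prs_log

    masses = territory_masses(patient.bsa)
    for cond in study.results:
        study.summaries[cond] = summarize_condition(
            study.results[cond], study.logs[cond], study.models[cond],
            bsa=patient.bsa, masses=masses, condition=cond)
    study.comparisons = compare_conditions(study.summaries)
    return study


def run_long_prs(study: StudyResult, n_cycles: int = 250,
                 **run_kw) -> tuple[SimulationResult, pd.DataFrame]:
    """Long-horizon PRS run (fresh hunger, warm hemodynamic start).

    Starts from the converged Stress state with the PRS model and the
    coronary controller active, so the hunger trajectories of both
    territories can be followed over minutes of model time.
    """
    model = copy.deepcopy(study.models["PRS"])
    # reset the controller to its Stress operating point
    for block in model.coronary_blocks:
        block.r_micro = study.models["Stress"].coronary_blocks[
            [b.territory for b in study.models["Stress"].coronary_blocks]
            .index(block.territory)].r_micro
    warm = study.results["Stress"].states[-1].copy()
    result, log, _ = run_condition(model, study.specs["PRS"], study.oxygen,
                                   controller_on=True, n_cycles=n_cycles,
                                   initial_state=warm, **run_kw)
    return result, log
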