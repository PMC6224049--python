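"""Calibration of the closed-loop model against hemodynamic targets.

Staged approach: elastances come from cycle data (heart_model), bulk
resistances from pressure-drop/flow algebra (builder), and this module
performs the final bound-constrained least-squares refinement of a named
free-parameter set on weighted relative residuals.  It also fits the
oxygen-accounting constants (α, β of the PVA–MVO2 line) to the Rest
anchors.  Everything is deterministic: identical inputs give bit-identical
reports.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import least_squares

from .lpn_core import LPNModel, assemble_system, run_to_periodic_state

__all__ = [
    "Target",
    "CalibrationTargets",
    "CalibrationReport",
    "OxygenConstants",
    "simulate_targets",
    "calibrate",
    "fit_oxygen_constants",
    "default_free_parameters",
    "apply_parameters",
]


@dataclass
class Target:
    value: float
    unit: str
    weight: float = 1.0
    tolerance: float = 0.06  # the study's clinical-match figure

    def __post_init__(self) -> None:
        if self.weight < 0:
            raise ValueError("weight must be >= 0")


@dataclass
class CalibrationTargets:
    """Named scalar hemodynamic targets with units and weights."""

    targets: dict[str, Target]
    bsa: float
    hr: float

    def __post_init__(self) -> None:
        required = {"co", "map"}
        if not required <= set(self.targets):
            raise ValueError(f"targets must include at least {sorted(required)}")
        if not ({"edv_lv", "esv_lv"} <= set(self.targets)
                or {"edv_rv", "esv_rv"} <= set(self.targets)):
            raise ValueError("targets must include one ventricular volume pair")

    def weighted(self) -> dict[str, Target]:
        return {k: t for k, t in self.targets.items() if t.weight > 0}


@dataclass
class CalibrationReport:
    parameters: dict[str, float]
    discrepancies: dict[str, float]  # per-target |sim−target|/target
    max_discrepancy: float
    n_evaluations: int
    converged: bool
    objective_history: list[float] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps({
            "parameters": self.parameters,
            "discrepancies": self.discrepancies,
            "max_discrepancy": self.max_discrepancy,
            "n_evaluations": self.n_evaluations,
            "converged": self.converged,
            "objective_history": self.objective_history,
        }, indent=1)


def simulate_targets(model: LPNModel, hr: float, bsa: float,
                     tol: float = 1e-3, max_cycles: int = 40,
                     initial_state=None, dt: float = 1e-3,
                     rtol: float = 1e-6, atol: float = 1e-8):
    """Run to periodic state and post-process the named target quantities.

    Returns ``(values, result)``; a non-convergent run is flagged on the
    result but the quantities are still computed from the last cycle.  A
    supplied ``initial_state`` (warm start) is rebalanced so its total
    blood volume matches the model's prescribed volume — in a closed loop
    the total is conserved, so a stale warm start would otherwise silently
    override volume-affecting parameters.
    """
    system = assemble_system(model)
    if initial_state is not None:
        y0 = np.asarray(initial_state, dtype=float).copy()
        nvol = system.n_chambers + system.n_caps
        target_total = system.default_initial_state()[:nvol].sum()
        sven = system.n_chambers + system.cap_nodes.index("SVEN")
        y0[sven] += target_total - y0[:nvol].sum()
        initial_state = y0
    result = run_to_periodic_state(system, hr, tol=tol, max_cycles=max_cycles,
                                   initial_state=initial_state, dt=dt,
                                   rtol=rtol, atol=atol)
    last = result.last_cycle()
    p_ao = result.pressure("AO")[last]
    p_pa = result.pressure("PA")[last]
    p_ra = result.pressure("RA")[last]
    p_la = result.pressure("LA")[last]
    p_rv = result.pressure("RV")[last]
    v_lv = result.volume("LV")[last]
    v_rv = result.volume("RV")[last]
    map_ = float(np.mean(p_ao))
    cvp = float(np.mean(p_ra))
    lap = float(np.mean(p_la))
    mean_pap = float(np.mean(p_pa))
    sv = float(v_lv.max() - v_lv.min())
    co = sv * hr / 1000.0  # L/min
    values = {
        "hr": hr,
        "map": map_,
        "p_ao_syst": float(p_ao.max()),
        "p_ao_diast": float(p_ao.min()),
        "mean_pap": mean_pap,
        "co": co,
        "cvp": cvp,
        "edv_lv": float(v_lv.max()) / bsa,
        "esv_lv": float(v_lv.min()) / bsa,
        "edv_rv": float(v_rv.max()) / bsa,
        "esv_rv": float(v_rv.min()) / bsa,
        "p_rv_syst": float(p_rv.max()),
        "svr": (map_ - cvp) / co,
        "pvr": (mean_pap - lap) / co,
    }
    return values, result


def default_free_parameters() -> dict[str, tuple[float, float]]:
    """The packaged free-parameter list (name → bounds) for calibration."""
    return {
        "sys_distal_r_scale": (0.3, 3.0),
        "pul_distal_r_scale": (0.3, 3.0),
        "sys_art_c_scale": (0.3, 3.0),
        "pa_c_scale": (0.3, 3.0),
        "e_max_lv_scale": (0.4, 2.5),
        "e_max_rv_scale": (0.4, 2.5),
        "e_min_lv_scale": (0.4, 2.5),
        "e_min_rv_scale": (0.4, 2.5),
        "venous_p_scale": (0.4, 3.0),
    }


def _segment(model: LPNModel, name: str):
    for seg in model.segments:
        if seg.name == name:
            return seg
    raise KeyError(name)


def _capacitor(model: LPNModel, node: str):
    for cap in model.capacitors:
        if cap.node == node:
            return cap
    raise KeyError(node)


def _scale_elastance(model: LPNModel, chamber: str, attr: str, factor: float) -> None:
    ch = model.chamber(chamber)
    e = ch.elastance
    new = replace(e, **{attr: getattr(e, attr) * factor})
    if not new.e_max > new.e_min:
        raise ValueError(f"{chamber}: scaling {attr} breaks e_max > e_min")
    ch.elastance = new


def apply_parameters(base: LPNModel, params: dict[str, float]) -> LPNModel:
    """Return a copy of ``base`` with the named parameter values applied.

    Scale parameters multiply the base model's values (they are not
    cumulative); offsets are additive in mmHg.
    """
    m = copy.deepcopy(base)
    for name, val in params.items():
        if name == "sys_distal_r_scale":
            _segment(m, "sys_arterioles").R *= val
            _segment(m, "sys_veins").R *= val
        elif name == "pul_distal_r_scale":
            _segment(m, "pul_arterioles").R *= val
            _segment(m, "pul_veins").R *= val
        elif name == "pul_prox_r_scale":
            # operating-point linearization of the stenotic proximal bed:
            # a quadratic-loss stenosis has flow-dependent effective R
            _segment(m, "pul_prox").R *= val
        elif name == "sys_art_c_scale":
            _capacitor(m, "AO").C *= val
            _segment(m, "sys_arch").C *= val
            _segment(m, "sys_conduit").C *= val
        elif name == "pa_c_scale":
            _capacitor(m, "PA").C *= val
            _segment(m, "pul_prox").C *= val
        elif name == "e_max_lv_scale":
            _scale_elastance(m, "LV", "e_max", val)
        elif name == "e_max_rv_scale":
            _scale_elastance(m, "RV", "e_max", val)
        elif name == "e_min_lv_scale":
            _scale_elastance(m, "LV", "e_min", val)
        elif name == "e_min_rv_scale":
            _scale_elastance(m, "RV", "e_min", val)
        elif name == "venous_p_scale":
            _segment(m, "sys_arterioles").initial_pressure *= val
            _segment(m, "pul_arterioles").initial_pressure *= val
        elif name == "venous_p_offset":
            _segment(m, "sys_arterioles").initial_pressure += val
            _segment(m, "pul_arterioles").initial_pressure += val
        else:
            raise KeyError(f"unknown calibration parameter {name!r}")
    return m


def calibrate(model: LPNModel, targets: CalibrationTargets,
              free_parameters: dict[str, tuple[float, float]],
              budget: int = 80, x0: dict[str, float] | None = None,
              sim_tol: float = 2e-3, sim_max_cycles: int = 30,
              rtol: float = 1e-5, atol: float = 1e-6,
              ) -> tuple[CalibrationReport, LPNModel]:
    """Bound-constrained least squares on weighted relative residuals.

    Deterministic given the model, targets and starting point.  Returns the
    report and the fitted model.  If the evaluation budget is exhausted the
    best-found point is reported with ``converged=False``.
    """
    names = list(free_parameters)
    lb = np.array([free_parameters[n][0] for n in names])
    ub = np.array([free_parameters[n][1] for n in names])
    start = np.array([
        (x0 or {}).get(n, 0.0 if "offset" in n else 1.0) for n in names])
    if np.any(start == 0.0):
        # a zero start degenerates scipy's relative diff_step to machine eps
        raise ValueError("free-parameter starting values must be nonzero")
    start = np.clip(start, lb, ub)
    weighted = targets.weighted()
    wnames = list(weighted)
    wvals = np.array([weighted[n].value for n in wnames])
    wts = np.array([weighted[n].weight for n in wnames])

    state = {"warm": None, "nfev": 0, "history": []}

    def residuals(x: np.ndarray) -> np.ndarray:
        m = apply_parameters(model, dict(zip(names, x)))
        sim, result = simulate_targets(m, targets.hr, targets.bsa, tol=sim_tol,
                                       max_cycles=sim_max_cycles,
                                       initial_state=state["warm"],
                                       rtol=rtol, atol=atol)
        state["warm"] = result.states[-1].copy()
        state["nfev"] += 1
        r = wts * (np.array([sim[n] for n in wnames]) - wvals) / wvals
        state["history"].append(float(np.sum(r**2)))
        return r

    x_cur = start
    status = 0
    # restart rounds: a fresh trust region from the incumbent escapes the
    # premature small-step termination of noisy finite-difference Jacobians
    for _round in range(3):
        remaining = budget - state["nfev"]
        if remaining < 2 * (len(names) + 1):
            break
        res = least_squares(residuals, x_cur, bounds=(lb, ub), method="trf",
                            diff_step=0.05, max_nfev=remaining,
                            xtol=1e-10, ftol=1e-8)
        x_cur = res.x
        status = res.status
        if res.cost < 1e-6:
            break
    fitted_params = dict(zip(names, (float(v) for v in x_cur)))
    fitted = apply_parameters(model, fitted_params)
    sim, _ = simulate_targets(fitted, targets.hr, targets.bsa, tol=sim_tol,
                              max_cycles=sim_max_cycles,
                              initial_state=state["warm"], rtol=rtol, atol=atol)
    disc = {n: abs(sim[n] - weighted[n].value) / abs(weighted[n].value)
            for n in wnames}
    best_so_far = np.minimum.accumulate(state["history"]).tolist()
    return CalibrationReport(
        parameters=fitted_params,
        discrepancies=disc,
        max_discrepancy=max(disc.values()),
        n_evaluations=state["nfev"],
        converged=status > 0,
        objective_history=best_so_far,
    ), fitted


@dataclass
class OxygenConstants:
    alpha: float  # mL O2 per mmHg·mL
    beta: float  # mL O2 per beat (basal, non-mechanical)


def fit_oxygen_constants(rest_pva_j: dict[str, float], hr: float,
                         mvo2_anchors: dict[str, float],
                         basal_fraction: float = 0.2) -> dict[str, OxygenConstants]:
    """Solve MVO2 = (α·PVA + β)·HR per ventricle given the Rest anchors.

    ``rest_pva_j`` maps ventricle → PVA per beat (J) from the converged
    Rest simulation; the basal per-beat cost β takes the configured
    fraction of the anchor at the Rest rate and α absorbs the rest.
    """
    from .units import MMHG_ML_TO_J
    out = {}
    for vent, anchor in mvo2_anchors.items():
        pva = rest_pva_j[vent]
        if pva <= 0:
            raise ValueError(f"{vent}: PVA must be positive, got {pva}")
        beta = basal_fraction * anchor / hr
        alpha = (1.0 - basal_fraction) * anchor / ((pva / MMHG_ML_TO_J) * hr)
        out[vent] = OxygenConstants(alpha=alpha, beta=beta)
    return out
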