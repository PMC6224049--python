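"""Experimental conditions: Rest, dobutamine Stress, and virtual PRS.

Rest is the calibrated baseline; Stress raises heart rate and
contractility (elastances re-derived from stress cycle data) and sets both
territory extractions to 1.0; PRS imposes a fractional MAP drop relative
to Stress by scaling the systemic distal resistances (a vasodilatory
state), found by scalar root-finding on the converged MAP.

The coronary controller runs per beat: after each completed cycle the
just-closed PV loop sets the territory's oxygen demand for the next beat,
supply is read off the microvascular flow, hunger is integrated, and the
microvascular resistance is adapted multiplicatively toward supply =
demand (plus a hunger-repayment term so accumulated debt is paid back and
hunger returns to zero when the territory's demand is reachable).
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .calibration import (CalibrationTargets, OxygenConstants, calibrate,
                          simulate_targets)
from .coronary_control import (OxygenAccounting, adapt_resistance, mvo2_rate,
                               pv_loop_workload, pva_per_beat, supply_rate,
                               update_hunger)
from .lpn_core import (LPNModel, SimulationResult, _integrate_cycle,
                       assemble_system)

__all__ = [
    "ScenarioSpec",
    "run_condition",
    "build_rest",
    "build_stress",
    "build_prs",
    "without_broadcast",
    "TERRITORY_VENTRICLE",
]

TERRITORY_VENTRICLE = {"LCA": "LV", "RCA": "RV"}

#: Vasodilator reserve floor as a fraction of the converged Rest R_micro.
#: The RCA territory's reserve is impaired (hypertrophied, pressure-loaded
#: RV with inadequate capillary density), the LCA's is closer to normal.
RESERVE_FRACTIONS = {"LCA": 0.30, "RCA": 0.65}

#: Hunger repayment gain (1/min): surplus supply requested per unit debt.
REPAY_GAIN = 0.5


@dataclass
class ScenarioSpec:
    """A named hemodynamic condition as overrides + targets."""

    name: str
    hr: float
    extraction: dict[str, float] = field(default_factory=dict)
    elastance_scale: dict[str, float] = field(default_factory=dict)
    map_drop_fraction: float | None = None
    parameter_overrides: dict[str, float] = field(default_factory=dict)
    reference_condition: str | None = None

    def __post_init__(self) -> None:
        if self.hr <= 0:
            raise ValueError("hr must be > 0")
        if self.map_drop_fraction is not None and not (0 < self.map_drop_fraction < 1):
            raise ValueError("map_drop_fraction must lie in (0, 1)")
        if self.name == "PRS" and self.reference_condition != "Stress":
            raise ValueError("PRS must declare reference_condition='Stress'")


def make_accounting(spec: ScenarioSpec, oxygen: dict[str, OxygenConstants],
                    o2_content: float = 0.2) -> dict[str, OxygenAccounting]:
    """Per-territory oxygen accounting for a scenario."""
    out = {}
    for territory, vent in TERRITORY_VENTRICLE.items():
        const = oxygen[vent]
        out[territory] = OxygenAccounting(
            extraction=spec.extraction.get(territory, 1.0),
            o2_content=o2_content, alpha=const.alpha, beta=const.beta)
    return out


def run_condition(model: LPNModel, spec: ScenarioSpec,
                  oxygen: dict[str, OxygenConstants], controller_on: bool = True,
                  n_cycles: int | None = None, tol: float = 1e-3,
                  max_cycles: int = 120, dt: float = 1e-3,
                  rtol: float = 1e-6, atol: float = 1e-8,
                  initial_state: np.ndarray | None = None,
                  accounting: dict[str, OxygenAccounting] | None = None,
                  kappa: float = 0.5, repay_gain: float = REPAY_GAIN,
                  ctrl_tol: float = 0.005, keep_last: int = 2,
                  ) -> tuple[SimulationResult, pd.DataFrame, dict[str, OxygenAccounting]]:
    """Run one condition with the per-beat coronary controller.

    With ``n_cycles`` set, exactly that many beats are run (long-horizon
    mode); otherwise the run stops when the state trajectory is periodic to
    ``tol`` and every territory is either at its resistance floor or within
    ``ctrl_tol`` of its supply=demand fixed point.  ``model``'s coronary
    blocks are updated in place (pass a copy to preserve the input).
    """
    period = 60.0 / spec.hr
    system = assemble_system(model)
    system.period = period
    acct = accounting if accounting is not None else make_accounting(spec, oxygen)
    blocks = {b.territory: b for b in model.coronary_blocks}

    nch = system.n_chambers
    cap_at = {n: nch + i for i, n in enumerate(system.cap_nodes)}
    vent_idx = {v: system.chamber_names.index(v) for v in ("LV", "RV")}
    cap_C = {n: system.cap_C[cap_at[n] - nch] for n in system.cap_nodes}

    log_rows: list[dict] = []
    balance_ok = {t: False for t in blocks}

    def hook(i_cycle: int, t_c: np.ndarray, y_c: np.ndarray, sys_) -> None:
        for territory, block in blocks.items():
            vent = TERRITORY_VENTRICLE[territory]
            vi = vent_idx[vent]
            chamber = model.chamber(vent)
            ef = chamber.elastance
            v = y_c[:, vi]
            p = ef.elastance(t_c - t_c[0], period) * (v - ef.v0)
            # closure check disabled: early transient beats are legitimately
            # open; the closing edge of the polygon handles the gap.
            work = pv_loop_workload(np.append(v, v[0]), np.append(p, p[0]),
                                    closure_tol=np.inf)
            a = ef.activation((t_c - t_c[0]) / period)
            i_es = int(np.argmax(a))
            pva = pva_per_beat(work, ef, (float(v[i_es]), float(p[i_es])))
            demand = mvo2_rate(pva, spec.hr, acct[territory])

            v_art = y_c[:, cap_at[f"{territory}_art"]]
            v_im = y_c[:, cap_at[f"{territory}_im"]]
            p_art = v_art / cap_C[f"{territory}_art"]
            p_broadcast = 0.0
            if block.broadcast_source is not None:
                src = model.chamber(block.broadcast_source)
                sv = y_c[:, vent_idx[block.broadcast_source]]
                p_broadcast = src.elastance.elastance(t_c - t_c[0], period) \
                    * (sv - src.elastance.v0)
            p_im = v_im / cap_C[f"{territory}_im"] + p_broadcast
            q_mean = float(np.mean((p_art - p_im) / block.r_micro))
            supply = supply_rate(q_mean, acct[territory])

            update_hunger(acct[territory], demand, supply, dt=period)
            effective = demand + repay_gain * acct[territory].hunger
            if controller_on:
                adapt_resistance(block, effective, supply, kappa=kappa)
                sys_.set_element_R(f"{territory}_micro", block.r_micro)
            balance_ok[territory] = (block.saturated or
                                     abs(supply - effective) <= ctrl_tol * effective)
            log_rows.append({"cycle": i_cycle, "territory": territory,
                             "demand": demand, "supply": supply,
                             "hunger": acct[territory].hunger,
                             "r_micro": block.r_micro,
                             "saturated": block.saturated})

    y = system.default_initial_state() if initial_state is None \
        else np.asarray(initial_state, float)
    history: list[tuple[np.ndarray, np.ndarray]] = []
    prev = None
    converged = False
    total = n_cycles if n_cycles is not None else max_cycles
    n_run = 0
    for i in range(total):
        t_c, y_c, y = _integrate_cycle(system, i * period, period, y, dt, rtol,
                                       atol, "LSODA")
        history.append((t_c, y_c))
        if len(history) > max(keep_last, 2):
            history.pop(0)
        hook(i, t_c, y_c, system)
        n_run = i + 1
        if n_cycles is None:
            if prev is not None and prev.shape == y_c.shape:
                rel = np.linalg.norm(y_c - prev) / max(np.linalg.norm(y_c), 1e-12)
                if rel < tol and (not controller_on or all(balance_ok.values())):
                    converged = True
                    break
            prev = y_c
    kept = history[-max(keep_last, 2):]
    t = np.concatenate([h[0] for h in kept] + [np.array([kept[-1][0][0] + period])])
    Y = np.vstack([h[1] for h in kept] + [y[None, :]])
    markers = np.cumsum([0] + [len(h[0]) for h in kept[:-1]])
    P = np.empty((len(t), system.n_nodes))
    Q = np.empty((len(t), len(system.element_names)))
    for k in range(len(t)):
        P[k] = system.node_pressures(t[k], Y[k])
        Q[k] = system.element_flows(t[k], Y[k], P[k])
    if n_cycles is not None:
        converged = True  # fixed-length run: completion is the contract
    result = SimulationResult(t, Y, P, Q, markers, converged, n_run, spec.hr,
                              list(system.node_index), list(system.element_names),
                              system.n_chambers, system.n_caps)
    log = pd.DataFrame(log_rows)
    return result, log, acct


def build_rest(calibrated_model: LPNModel, oxygen: dict[str, OxygenConstants],
               hr: float = 73.0,
               reserve_fractions: dict[str, float] | None = None,
               **run_kw) -> tuple[LPNModel, ScenarioSpec, SimulationResult, pd.DataFrame]:
    """Finalize the Rest condition: converge the controller, pin R bounds.

    Resistance floors (the vasodilator-reserve limits) are set per
    territory as fractions of the converged Rest microvascular resistance.
    """
    spec = ScenarioSpec("Rest", hr=hr, extraction={"LCA": 0.8, "RCA": 0.4})
    model = copy.deepcopy(calibrated_model)
    result, log, _ = run_condition(model, spec, oxygen, controller_on=True, **run_kw)
    frac = RESERVE_FRACTIONS if reserve_fractions is None else reserve_fractions
    for block in model.coronary_blocks:
        block.r_min = frac[block.territory] * block.r_micro
        block.r_max = 5.0 * block.r_micro
    return model, spec, result, log


def build_stress(rest_model: LPNModel, stress_targets: CalibrationTargets,
                 oxygen: dict[str, OxygenConstants],
                 stress_elastances: dict | None = None, hr: float = 106.0,
                 budget: int = 70, **run_kw,
                 ) -> tuple[LPNModel, ScenarioSpec, SimulationResult, pd.DataFrame]:
    """Build the dobutamine-stress condition from the calibrated Rest model.

    Ventricular elastances are replaced by the stress-derived ones (or the
    Rest ones retimed if none are given); atria are retimed; vascular
    stiffness is kept; distal resistances, preload and contractility
    scalings are refined against the stress targets; both extractions are
    1.0.  The coronary controller then converges at the new workload.
    """
    spec = ScenarioSpec("Stress", hr=hr, extraction={"LCA": 1.0, "RCA": 1.0})
    m = copy.deepcopy(rest_model)
    for ch in m.chambers:
        if stress_elastances and ch.name in stress_elastances:
            ch.elastance = stress_elastances[ch.name]
        else:
            ch.elastance = ch.elastance.with_rate(73.0, hr)
    free = {
        "sys_distal_r_scale": (0.3, 3.0),
        "pul_distal_r_scale": (0.3, 3.0),
        "pul_prox_r_scale": (0.5, 4.0),
        "venous_p_scale": (0.4, 3.0),
        "e_max_lv_scale": (0.5, 2.0),
        "e_max_rv_scale": (0.5, 2.0),
        "e_min_lv_scale": (0.5, 2.0),
        "e_min_rv_scale": (0.5, 2.0),
    }
    report, fitted = calibrate(m, stress_targets, free, budget=budget)
    result, log, _ = run_condition(fitted, spec, oxygen, controller_on=True, **run_kw)
    return fitted, spec, result, log


def _scale_systemic_distal(model: LPNModel, scale: float) -> LPNModel:
    """Generalized systemic vasodilation by a common tone factor.

    Arteriolar and venous resistances scale with ``scale``; the venous
    capacitance scales inversely (dilated veins pool blood at lower
    pressure), which keeps the preload surge of the arterial volume dump
    physiologic instead of driving a runaway cardiac-output rise.
    """
    m = copy.deepcopy(model)
    for seg in m.segments:
        if seg.name in ("sys_arterioles", "sys_veins"):
            seg.R *= scale
        if seg.name == "sys_arterioles" and seg.C is not None:
            seg.C /= scale  # capacitor at the systemic venous node
    return m


def build_prs(stress_model: LPNModel, stress_spec: ScenarioSpec,
              oxygen: dict[str, OxygenConstants], map_stress: float,
              map_drop_fraction: float = 0.31,
              scale_bounds: tuple[float, float] = (0.2, 1.1),
              map_tol: float = 0.005, warm_state: np.ndarray | None = None,
              **run_kw) -> tuple[LPNModel, ScenarioSpec, SimulationResult, pd.DataFrame]:
    """Virtual post-reperfusion syndrome: a MAP drop relative to Stress.

    Systemic distal resistances are scaled (generalized vasodilation) by a
    factor found with bisection-style root finding so the converged MAP
    equals (1 − drop)·MAP_stress within ``map_tol``; HR, elastances and
    extraction are retained from Stress.
    """
    spec = ScenarioSpec("PRS", hr=stress_spec.hr,
                        extraction=dict(stress_spec.extraction),
                        map_drop_fraction=map_drop_fraction,
                        reference_condition="Stress")
    if map_drop_fraction == 0.0:
        m = copy.deepcopy(stress_model)
        result, log, _ = run_condition(m, spec, oxygen, initial_state=warm_state,
                                       **run_kw)
        return m, spec, result, log
    target = (1.0 - map_drop_fraction) * map_stress
    probe_kw = dict(run_kw)
    probe_kw.setdefault("tol", 2e-3)
    probe_kw.setdefault("rtol", 1e-5)
    probe_kw.setdefault("atol", 1e-6)

    def achieved_map(scale: float) -> float:
        m = _scale_systemic_distal(stress_model, scale)
        res, _, _ = run_condition(m, spec, oxygen, initial_state=warm_state,
                                  **probe_kw)
        last = res.last_cycle()
        return float(np.mean(res.pressure("AO")[last]))

    lo, hi = scale_bounds
    f_lo, f_hi = achieved_map(lo) - target, achieved_map(hi) - target
    if f_lo * f_hi > 0:
        raise ValueError(
            f"target MAP {target:.1f} mmHg not bracketed: achievable range "
            f"[{f_lo + target:.1f}, {f_hi + target:.1f}] for scales {scale_bounds}")
    scale = brentq(lambda s: achieved_map(s) - target, lo, hi,
                   xtol=1e-3, rtol=1e-4)
    model = _scale_systemic_distal(stress_model, float(scale))
    result, log, _ = run_condition(model, spec, oxygen, initial_state=warm_state,
                                   **run_kw)
    last = result.last_cycle()
    achieved = float(np.mean(result.pressure("AO")[last]))
    if abs(achieved - target) / target > map_tol:
        raise ValueError(
            f"PRS MAP {achieved:.1f} missed target {target:.1f} beyond "
            f"{map_tol:.1%}")
    spec.parameter_overrides["sys_distal_r_scale"] = float(scale)
    return model, spec, result, log


def without_broadcast(model: LPNModel) -> LPNModel:
    """Ablation: disconnect the intramyocardial pressure broadcast (P_v=0)."""
    m = copy.deepcopy(model)
    for block in m.coronary_blocks:
        block.broadcast_source = None
    return m
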