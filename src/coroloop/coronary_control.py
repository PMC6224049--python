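"""Coronary microvascular control: outlet blocks, oxygen accounting, feedback.

Each coronary territory (LCA → LV wall, RCA → RV wall) is an outlet block
R_prox — C_art — R_micro — C_im — R_ven whose intramyocardial capacitor is
loaded by the broadcast pressure of the corresponding ventricle, producing
the systolic impediment/reversal of epicardial flow.  R_micro is a
controlled state bounded by physiologic floor/ceiling values.

Oxygen demand per beat derives from pressure-volume-loop energetics through
the linear PVA–MVO2 relation  MVO2 = (α·PVA + β)·HR;  supply uses coronary
flow as a surrogate of delivery,  supply = extraction·CaO2·Q̄·60.  Any
deficit accumulates as "myocardial hunger" (clamped at zero — no oxygen
credit), and a per-beat multiplicative law adapts R_micro toward the
supply = demand fixed point.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .heart_model import ElastanceFunction
from .units import MMHG_ML_TO_J

__all__ = [
    "CoronaryBlock",
    "OxygenAccounting",
    "pv_loop_workload",
    "pva_per_beat",
    "mvo2_rate",
    "supply_rate",
    "update_hunger",
    "adapt_resistance",
]


@dataclass
class CoronaryBlock:
    """Parameters and controlled state of one coronary territory."""

    territory: str  # "LCA" or "RCA"
    r_prox: float  # mmHg·s/mL
    c_art: float  # mL/mmHg
    r_micro: float  # controlled microvascular resistance (state)
    c_im: float  # intramyocardial compliance, loaded by P_v
    r_ven: float
    r_min: float  # physiologic floor (vasodilator reserve limit)
    r_max: float
    broadcast_source: str | None = "LV"  # chamber whose pressure loads C_im
    inlet: str = "AO"
    outlet: str = "SVEN"
    init_p_art: float = 70.0
    init_p_im: float = 15.0

    def __post_init__(self) -> None:
        if not (self.c_art > 0 and self.c_im > 0):
            raise ValueError(f"{self.territory}: compliances must be > 0")
        if not (self.r_min < self.r_max):
            raise ValueError(f"{self.territory}: require r_min < r_max")
        self.r_micro = float(np.clip(self.r_micro, self.r_min, self.r_max))

    @property
    def saturated(self) -> bool:
        """True when the vasodilator reserve is exhausted (R at its floor)."""
        return self.r_micro <= self.r_min * (1.0 + 1e-9)

    def element_names(self) -> dict[str, str]:
        t = self.territory
        return {"prox": f"{t}_prox", "micro": f"{t}_micro", "ven": f"{t}_ven"}

    def as_segments(self):
        """Expand into three vascular segments (prox, micro, ven)."""
        from .lpn_core import VascularSegment  # deferred: avoids import cycle
        t = self.territory
        return [
            VascularSegment(f"{t}_prox", self.inlet, f"{t}_art", R=self.r_prox,
                            C=self.c_art, initial_pressure=self.init_p_art),
            VascularSegment(f"{t}_micro", f"{t}_art", f"{t}_im", R=self.r_micro,
                            C=self.c_im, external_pressure_source=self.broadcast_source,
                            initial_pressure=self.init_p_im),
            VascularSegment(f"{t}_ven", f"{t}_im", self.outlet, R=self.r_ven),
        ]


@dataclass
class OxygenAccounting:
    """Per-territory oxygen bookkeeping (all rates in mL O2/min)."""

    extraction: float  # fraction of delivered O2 extracted, fixed per scenario
    o2_content: float = 0.2  # arterial O2 content, mL O2 per mL blood
    alpha: float = 1.0e-5  # PVA→MVO2 slope, mL O2 per (mmHg·mL)
    beta: float = 0.01  # basal (non-mechanical) cost, mL O2 per beat
    demand_rate: float = 0.0
    supply_rate: float = 0.0
    hunger: float = 0.0  # accumulated deficit, mL O2 (>= 0)

    def __post_init__(self) -> None:
        if not (0 < self.extraction <= 1):
            raise ValueError("extraction must lie in (0, 1]")
        if self.hunger < 0:
            raise ValueError("hunger must be >= 0")


def pv_loop_workload(volumes: np.ndarray, pressures: np.ndarray,
                     closure_tol: float = 0.02) -> float:
    """Stroke work (J) as the signed shoelace area of one P–V loop.

    Positive for the physiological traversal (counter-clockwise in the V–P
    plane); a clockwise loop yields a negative value, which callers treat
    as a flag.  The loop must close: endpoint mismatch beyond
    ``closure_tol`` of the volume excursion is an error.
    """
    v = np.asarray(volumes, dtype=float)
    p = np.asarray(pressures, dtype=float)
    sv = v.max() - v.min()
    if sv <= 0:
        raise ValueError("volume series has no excursion")
    if abs(v[0] - v[-1]) > closure_tol * sv:
        raise ValueError(
            f"open PV loop: endpoint volume mismatch {abs(v[0]-v[-1]):.3g} mL "
            f"exceeds {closure_tol:.0%} of stroke volume {sv:.3g} mL")
    # shoelace on the closed polygon; orientation: ejection at high P first
    area = -0.5 * float(np.sum((v[1:] - v[:-1]) * (p[1:] + p[:-1]))
                        + (v[0] - v[-1]) * (p[0] + p[-1]))
    return area * MMHG_ML_TO_J


def pva_per_beat(loop_work: float, elastance: ElastanceFunction,
                 end_systolic_point: tuple[float, float]) -> float:
    """Pressure-volume area (J): stroke work + end-systolic potential energy.

    PE is the triangle under the end-systolic elastance line,
    ½·P_es·(V_es − V0).
    """
    v_es, p_es = end_systolic_point
    if v_es < elastance.v0:
        raise ValueError(f"end-systolic volume {v_es} below unstressed volume {elastance.v0}")
    pe = 0.5 * p_es * (v_es - elastance.v0) * MMHG_ML_TO_J
    return loop_work + pe


def mvo2_rate(pva: float, hr: float, acct: OxygenAccounting) -> float:
    """MVO2 (mL O2/min) from the linear per-beat relation (α·PVA + β)·HR.

    Demand is computed per heartbeat from the cardiac workload: the
    mechanical cost α·PVA plus a basal activation/metabolism cost β that is
    also paid once per beat (excitation-contraction coupling scales with
    rate).  ``pva`` is per-beat in J; α is referenced to mmHg·mL.
    """
    pva_mmhg_ml = pva / MMHG_ML_TO_J
    return (acct.alpha * pva_mmhg_ml + acct.beta) * hr


def supply_rate(q_cor: float, acct: OxygenAccounting) -> float:
    """Oxygen delivery rate (mL O2/min) from coronary flow (mL/s)."""
    return acct.extraction * acct.o2_content * q_cor * 60.0


def update_hunger(acct: OxygenAccounting, demand_rate: float, supply_rate: float,
                  dt: float) -> float:
    """Advance the hunger accumulator over ``dt`` seconds; returns new hunger.

    hunger ← max(0, hunger + (demand − supply)·dt/60); the clamp encodes
    that repaid oxygen debt does not bank as credit.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    acct.demand_rate = demand_rate
    acct.supply_rate = supply_rate
    acct.hunger = max(0.0, acct.hunger + (demand_rate - supply_rate) * dt / 60.0)
    return acct.hunger


def adapt_resistance(block: CoronaryBlock, mean_demand: float, mean_supply: float,
                     kappa: float = 0.5) -> float:
    """Per-beat multiplicative update of the microvascular resistance.

    R ← clip(R·(supply/demand)^κ, R_min, R_max).  The fixed point is exactly
    supply = demand when interior; saturation at R_min signals exhausted
    vasodilator reserve.
    """
    if mean_demand <= 0:
        raise ValueError("mean_demand must be > 0")
    if not (0 < kappa <= 1):
        raise ValueError("kappa must lie in (0, 1]")
    ratio = max(mean_supply, 0.0) / mean_demand
    ratio = max(ratio, 1e-6)
    block.r_micro = float(np.clip(block.r_micro * ratio ** kappa,
                                  block.r_min, block.r_max))
    return block.r_micro
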