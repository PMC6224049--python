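"""Derived clinical quantities and condition-comparison tables.

Everything the study-style report prints is computed here: ejection
fractions, PV-loop workload and PVA, MVO2, coronary blood flow and its
diastolic/systolic partition, microvascular resistance in indexed Wood
units, coronary flow reserve (CFR), and rounded percent/fold changes
between conditions.  Percent and fold figures round half-away-from-zero to
the printed precision, with the reference operand always explicit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .coronary_control import pv_loop_workload, pva_per_beat
from .heart_model import systole_interval
from .lpn_core import LPNModel, SimulationResult
from .units import DEFAULT_BSA, resistance_to_wood_m2

__all__ = [
    "VentricleSummary",
    "TerritorySummary",
    "ConditionSummary",
    "ComparisonReport",
    "FlowSplit",
    "ef_from_volumes",
    "split_coronary_flow",
    "cfr",
    "percent_change",
    "summarize_condition",
    "compare_conditions",
    "render_tables",
]


def round_half_away(x: float, ndigits: int = 0) -> float:
    """Round half away from zero (the convention of the printed figures)."""
    factor = 10.0 ** ndigits
    return math.copysign(math.floor(abs(x) * factor + 0.5), x) / factor


def ef_from_volumes(edv: float, esv: float) -> int:
    """Ejection fraction, percent, rounded to the printed integer.

    Equal volumes give EF 0; ESV above EDV or non-positive volumes are
    rejected.
    """
    if not (edv >= esv > 0):
        raise ValueError(f"require EDV >= ESV > 0, got EDV={edv}, ESV={esv}")
    return int(round_half_away(100.0 * (edv - esv) / edv))


def cfr(cbf_stress: float, cbf_rest: float) -> float:
    """Coronary flow reserve: hyperemic / resting CBF, one decimal."""
    if cbf_stress <= 0 or cbf_rest <= 0:
        raise ValueError("CBF values must be positive")
    return round_half_away(cbf_stress / cbf_rest, 1)


def percent_change(before: float, after: float, direction: str = "drop",
                   reference: str = "before") -> int:
    """Rounded integer percent change with an explicit reference operand.

    ``direction="drop"`` reports 100·(before−after)/ref, ``"rise"`` reports
    100·(after−before)/ref; ``reference`` picks the denominator: "before",
    "after", or "larger".
    """
    if before <= 0:
        raise ValueError("'before' must be positive")
    ref = {"before": before, "after": after,
           "larger": max(before, after)}[reference]
    delta = (before - after) if direction == "drop" else (after - before)
    return int(round_half_away(100.0 * delta / ref))


@dataclass
class FlowSplit:
    q_systolic: float  # integrated flow over systole, mL
    q_diastolic: float  # integrated flow over diastole, mL
    t_systole: float  # s
    t_diastole: float  # s
    ratio_integrated: float  # Q_dia / Q_sys
    ratio_per_time: float  # (Q_dia/T_dia) / (Q_sys/T_sys)
    ratio_peak: float  # peak diastolic / peak systolic flow
    systolic_flow_min: float  # most negative systolic flow (reversal marker)
    infinite: bool = False  # systolic integral ~ 0


def split_coronary_flow(time: np.ndarray, flow: np.ndarray,
                        systole: tuple[float, float], period: float) -> FlowSplit:
    """Partition one cycle of coronary flow into systolic/diastolic shares.

    ``systole`` is the in-cycle interval from
    :func:`~coroloop.heart_model.systole_interval` of the territory's
    ventricle.  Reports integrated, per-unit-time and peak diastolic:systolic
    ratios (the printed tables do not document which normalization they
    use, so all are available).
    """
    t = np.asarray(time, dtype=float)
    q = np.asarray(flow, dtype=float)
    tc = (t - t[0]) % period
    t0, t1 = systole
    in_sys = (tc >= t0) & (tc < t1)
    dt = np.gradient(t)
    q_sys = float(np.sum(q[in_sys] * dt[in_sys]))
    q_dia = float(np.sum(q[~in_sys] * dt[~in_sys]))
    t_sys = t1 - t0
    t_dia = period - t_sys
    tiny = 1e-12 + 1e-4 * abs(q_dia)
    infinite = abs(q_sys) <= tiny
    ratio = math.inf if infinite else q_dia / q_sys
    ratio_pt = math.inf if infinite or t_sys == 0 else (q_dia / t_dia) / (q_sys / t_sys)
    peak_sys = float(q[in_sys].max()) if in_sys.any() else 0.0
    peak_dia = float(q[~in_sys].max()) if (~in_sys).any() else 0.0
    ratio_peak = math.inf if peak_sys <= 0 else peak_dia / peak_sys
    q_min_sys = float(q[in_sys].min()) if in_sys.any() else 0.0
    return FlowSplit(q_sys, q_dia, t_sys, t_dia, ratio, ratio_pt, ratio_peak,
                     q_min_sys, infinite)


@dataclass
class VentricleSummary:
    edv: float  # mL
    esv: float  # mL
    ef: int  # %
    stroke_work_j: float
    pva_j: float
    mvo2: float  # mL O2/min


@dataclass
class TerritorySummary:
    cbf_ml_min: float
    cbf_ml_min_g: float | None
    r_micro: float  # mmHg·s/mL
    r_micro_wu_m2: float
    split: FlowSplit
    supply: float  # mL O2/min
    demand: float  # mL O2/min
    hunger: float  # mL O2
    saturated: bool


@dataclass
class ConditionSummary:
    condition: str
    hr: float
    bsa: float
    ventricles: dict[str, VentricleSummary]
    territories: dict[str, TerritorySummary]
    co: float  # L/min
    map: float  # mmHg
    mean_pap: float
    svr: float  # WU
    pvr: float  # WU
    svr_wu_m2: float = 0.0
    pvr_wu_m2: float = 0.0


_TERRITORY_VENTRICLE = {"LCA": "LV", "RCA": "RV"}


def summarize_condition(result: SimulationResult, controller_log: pd.DataFrame,
                        model: LPNModel, bsa: float = DEFAULT_BSA,
                        masses: dict[str, float] | None = None,
                        condition: str = "condition") -> ConditionSummary:
    """Fill a :class:`ConditionSummary` from the final simulated cycle.

    ``masses`` maps territory → perfused myocardial mass (g) for per-gram
    CBF (territory attribution: LCA → LV mass, RCA → RV mass); if omitted,
    per-gram fields are left unset and absolute flows are still reported.
    """
    hr = result.hr
    period = 60.0 / hr
    last = result.last_cycle()
    t = result.time[last]
    ventricles = {}
    for vent in ("LV", "RV"):
        v = result.volume(vent)[last]
        p = result.pressure(vent)[last]
        edv, esv = float(v.max()), float(v.min())
        work = pv_loop_workload(np.append(v, v[0]), np.append(p, p[0]),
                                closure_tol=np.inf)
        ef = model.chamber(vent).elastance
        a = ef.activation((t - t[0]) / period)
        i_es = int(np.argmax(a))
        pva = pva_per_beat(work, ef, (float(v[i_es]), float(p[i_es])))
        log_v = controller_log[
            controller_log.territory == ("LCA" if vent == "LV" else "RCA")]
        mvo2 = float(log_v.demand.iloc[-1]) if len(log_v) else float("nan")
        ventricles[vent] = VentricleSummary(edv, esv, ef_from_volumes(edv, esv),
                                            work, pva, mvo2)

    territories = {}
    for block in model.coronary_blocks:
        ter = block.territory
        vent = _TERRITORY_VENTRICLE[ter]
        q_in = result.flow(f"{ter}_prox")[last]
        cbf = float(np.mean(q_in)) * 60.0
        sys_int = systole_interval(model.chamber(vent).elastance, hr)
        split = split_coronary_flow(t, q_in, sys_int, period)
        log_t = controller_log[controller_log.territory == ter]
        row = log_t.iloc[-1] if len(log_t) else None
        territories[ter] = TerritorySummary(
            cbf_ml_min=cbf,
            cbf_ml_min_g=(cbf / masses[ter]) if masses and ter in masses else None,
            r_micro=block.r_micro,
            r_micro_wu_m2=resistance_to_wood_m2(block.r_micro, bsa),
            split=split,
            supply=float(row.supply) if row is not None else float("nan"),
            demand=float(row.demand) if row is not None else float("nan"),
            hunger=float(row.hunger) if row is not None else 0.0,
            saturated=bool(row.saturated) if row is not None else block.saturated,
        )

    p_ao = result.pressure("AO")[last]
    p_pa = result.pressure("PA")[last]
    map_ = float(np.mean(p_ao))
    mean_pap = float(np.mean(p_pa))
    cvp = float(np.mean(result.pressure("RA")[last]))
    lap = float(np.mean(result.pressure("LA")[last]))
    sv = ventricles["LV"].edv - ventricles["LV"].esv
    co = sv * hr / 1000.0
    svr = (map_ - cvp) / co
    pvr = (mean_pap - lap) / co
    return ConditionSummary(condition, hr, bsa, ventricles, territories,
                            co, map_, mean_pap, svr, pvr,
                            svr_wu_m2=svr * bsa, pvr_wu_m2=pvr * bsa)


@dataclass
class ComparisonReport:
    pairs: list[tuple[str, str]]
    fold_changes: dict[str, dict[str, float]] = field(default_factory=dict)
    percent_changes: dict[str, dict[str, int]] = field(default_factory=dict)
    cfr_values: dict[str, float] = field(default_factory=dict)


def compare_conditions(summaries: dict[str, ConditionSummary]) -> ComparisonReport:
    """Fold/percent changes between consecutive conditions + CFR values."""
    names = list(summaries)
    pairs = list(zip(names[:-1], names[1:]))
    report = ComparisonReport(pairs=pairs)
    for a, b in pairs:
        key = f"{a}->{b}"
        sa, sb = summaries[a], summaries[b]
        folds, pcts = {}, {}
        for ter in sa.territories:
            folds[f"cbf_{ter.lower()}"] = sb.territories[ter].cbf_ml_min \
                / sa.territories[ter].cbf_ml_min
            pcts[f"r_{ter.lower()}_drop"] = percent_change(
                sa.territories[ter].r_micro, sb.territories[ter].r_micro, "drop")
        folds["co"] = sb.co / sa.co
        pcts["map_drop"] = percent_change(sa.map, sb.map, "drop")
        report.fold_changes[key] = folds
        report.percent_changes[key] = pcts
    if {"Rest", "Stress"} <= set(names):
        mean = lambda s: np.mean([t.cbf_ml_min for t in s.territories.values()])
        report.cfr_values["Rest->Stress"] = cfr(mean(summaries["Stress"]),
                                                mean(summaries["Rest"]))
        if "PRS" in names:
            report.cfr_values["Stress->PRS"] = cfr(mean(summaries["Stress"]),
                                                   mean(summaries["PRS"]))
    return report


def _sci2(x: float) -> str:
    return f"{x:.1e}"


def render_tables(summaries: dict[str, ConditionSummary],
                  comparisons: ComparisonReport | None = None,
                  out_dir: str | Path | None = None) -> dict[str, pd.DataFrame]:
    """Workload/MVO2 and coronary-index tables in the published layout.

    Rounding follows the printed precision: workload 2 significant figures
    (scientific), MVO2 two decimals, CBF one decimal, resistance three
    significant figures (scientific).  Conditions appear in fixed
    Rest/Stress/PRS order.  With ``out_dir`` set, CSVs (and a text render)
    are written alongside the returned frames.
    """
    order = [c for c in ("Rest", "Stress", "PRS") if c in summaries]
    order += [c for c in summaries if c not in order]
    rows2, rows3 = [], []
    for cond in order:
        s = summaries[cond]
        rows2.append({
            "condition": cond,
            "workload_lv_J": float(_sci2(s.ventricles["LV"].stroke_work_j)),
            "workload_rv_J": float(_sci2(s.ventricles["RV"].stroke_work_j)),
            "mvo2_lv_ml_min": round_half_away(s.ventricles["LV"].mvo2, 2),
            "mvo2_rv_ml_min": round_half_away(s.ventricles["RV"].mvo2, 2),
        })
        row3 = {"condition": cond}
        for ter in ("LCA", "RCA"):
            tsum = s.territories[ter]
            row3[f"cbf_{ter.lower()}_ml_min"] = round_half_away(tsum.cbf_ml_min, 1)
            row3[f"ds_ratio_{ter.lower()}"] = round_half_away(
                tsum.split.ratio_integrated, 1)
            row3[f"r_{ter.lower()}_wu_m2"] = float(f"{tsum.r_micro_wu_m2:.2e}")
        rows3.append(row3)
    tables = {"table2": pd.DataFrame(rows2), "table3": pd.DataFrame(rows3)}
    if comparisons is not None:
        comp_rows = []
        for key, folds in comparisons.fold_changes.items():
            row = {"pair": key}
            row.update({f"fold_{k}": round_half_away(v, 2) for k, v in folds.items()})
            row.update({k: v for k, v in comparisons.percent_changes[key].items()})
            comp_rows.append(row)
        tables["comparisons"] = pd.DataFrame(comp_rows)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, df in tables.items():
            df.to_csv(out / f"{name}.csv", index=False)
        text = "\n\n".join(f"== {n} ==\n{df.to_string(index=False)}"
                           for n, df in tables.items())
        (out / "report.txt").write_text(text + "\n")
    return tables
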