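"""Default closed-loop network construction from patient-style targets.

The packaged topology is a 0D realization of the usual closed loop:

    LA → mitral → LV → aortic valve → AO → arch → AOD → conduit → SART
       → arterioles → SVEN → veins → RA → tricuspid → RV → pulmonary valve
       → PA → proximal PA chain → PART → arterioles → PVEN → veins → LA

with two coronary outlet blocks (LCA, RCA) branching off the aortic root
and returning to the systemic venous node, upstream of the right atrium.
Proximal arterial compliances derive from synthetic vessel-wall specs via
the linearized-stiffness relation; bulk SVR/PVR are distributed over the
segment chains; elastances are designed analytically from the condition's
volumes, filling pressures and systolic pressure targets.  All values are
analytic first guesses — the calibration module refines them against the
same targets.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import brentq

from .coronary_control import CoronaryBlock
from .heart_model import ElastanceFunction, HeartChamber, Valve, systole_fractions_for_hr
from .lpn_core import Capacitor, LPNModel, VascularSegment
from .tables import REST_MVO2_ANCHORS
from .vessel_parameterization import (VesselWallSpec, distribute_resistance,
                                      linearized_stiffness, stiffness_to_compliance)

__all__ = [
    "ventricular_volume_waveform",
    "design_elastance",
    "aortic_wall_spec",
    "pulmonary_wall_spec",
    "build_model",
]

# Fractional split of SVR / PVR over the series chains (arteriole-dominant).
SYS_R_FRACTIONS = (0.03, 0.12, 0.70, 0.15)  # arch, conduit, arterioles, veins
PUL_R_FRACTIONS = (0.45, 0.40, 0.15)  # proximal (stenotic), arterioles, veins

# Coronary block internal split of the total territory resistance.  The
# venous share is sizable so the intramyocardial compartment drains slowly
# enough for systolic compression to persist through systole.
COR_R_FRACTIONS = {"prox": 0.06, "micro": 0.72, "ven": 0.22}

# Intramyocardial emptying time constant C_im·(R_micro ∥ R_ven), seconds;
# of the order of the systolic interval so compression blocks throughput
# for the whole systole.
CIM_TIME_CONSTANT = 0.25

# Unstressed volume as a fraction of end-systolic volume (single-beat surrogate).
V0_ESV_FRACTION = 0.25


def aortic_wall_spec(p_syst: float = 100.0, p_diast: float = 60.0) -> VesselWallSpec:
    """Synthetic aortic-root wall spec tuned to a stiffness of 2.26e5 g/mm·s².

    The diameters are back-solved from the stiffness relation for a
    pediatric aortic root (D ≈ 14 mm), since only the stiffness magnitude,
    not the measurements producing it, is published.
    """
    target_e = 2.26e5
    d_diast = 14.0
    dd = (p_syst - p_diast) * 133.322 * d_diast / target_e
    return VesselWallSpec("aorta_synthetic", p_syst, p_diast,
                          d_diast + dd, d_diast, h=1.0, length=150.0)


def pulmonary_wall_spec(p_syst: float = 73.0, p_diast: float = 22.0) -> VesselWallSpec:
    """Synthetic main-PA wall spec tuned to a stiffness of 1.30e5 g/mm·s²."""
    target_e = 1.30e5
    d_diast = 16.0
    dd = (p_syst - p_diast) * 133.322 * d_diast / target_e
    return VesselWallSpec("pulmonary_synthetic", p_syst, p_diast,
                          d_diast + dd, d_diast, h=1.0, length=120.0)


def ventricular_volume_waveform(phase, edv: float, esv: float,
                                tp: float, ts: float):
    """Smooth periodic ventricular volume V(phase), EDV at phase 0.

    Raised-cosine ejection from an isovolumic onset to end-systole, a short
    isovolumic relaxation, then raised-cosine filling completing before the
    next R wave.
    """
    phi = np.asarray(phase, dtype=float) % 1.0
    e0 = 0.04  # ejection onset (isovolumic contraction)
    f0 = min(ts + 0.05, 0.93)  # filling onset (isovolumic relaxation)
    f1 = 0.96  # filling complete
    g = np.zeros_like(phi)
    eject = (phi >= e0) & (phi < ts)
    g[eject] = 0.5 * (1.0 - np.cos(np.pi * (phi[eject] - e0) / (ts - e0)))
    hold = (phi >= ts) & (phi < f0)
    g[hold] = 1.0
    fill = (phi >= f0) & (phi < f1)
    g[fill] = 0.5 * (1.0 + np.cos(np.pi * (phi[fill] - f0) / (f1 - f0)))
    return edv - (edv - esv) * g


def design_elastance(cond, ventricle: str, bsa: float,
                     v0: float | None = None) -> ElastanceFunction:
    """Analytic elastance for one ventricle matching a condition's targets.

    E_min reproduces the end-diastolic pressure at EDV; E_max is solved so
    the peak pressure of the elastance-driven beat over the condition's
    volume waveform equals the ventricular systolic pressure target.  V0 is
    a property of the ventricle, not of the condition — callers comparing
    conditions should pass the patient-level value (the default derives it
    from this condition's ESV).
    """
    edv = (cond.edv_lv if ventricle == "LV" else cond.edv_rv) * bsa
    esv = (cond.esv_lv if ventricle == "LV" else cond.esv_rv) * bsa
    if esv >= edv:
        raise ValueError(f"{ventricle}: ESV must be below EDV")
    p_syst = cond.p_ao_syst if ventricle == "LV" else cond.rv_ao_ratio * cond.p_ao_syst
    edp = cond.edp_lv if ventricle == "LV" else cond.edp_rv
    if v0 is None:
        v0 = V0_ESV_FRACTION * esv
    e_min = edp / (edv - v0)
    tp, ts = systole_fractions_for_hr(cond.hr)
    phase = np.arange(512) / 512
    v = ventricular_volume_waveform(phase, edv, esv, tp, ts)

    def peak_pressure(e_max: float) -> float:
        ef = ElastanceFunction(e_max, e_min, v0, tp, ts)
        return float(np.max(ef.activation(phase) * (e_max - e_min) * (v - v0)
                            + e_min * (v - v0)))

    e_max = brentq(lambda e: peak_pressure(e) - p_syst, e_min * 1.01, 100.0,
                   xtol=1e-8)
    return ElastanceFunction(e_max, e_min, v0, tp, ts)


def _atrial_elastance(hr: float, e_max: float, e_min: float, v0: float) -> ElastanceFunction:
    """Atrial elastance: same family, phase-shifted to fire pre-systole."""
    ts_a = 0.13
    return ElastanceFunction(e_max, e_min, v0, t_peak_fraction=0.5 * ts_a,
                             systole_fraction=ts_a, onset_fraction=0.85)


def build_model(spec, condition: str = "rest",
                mvo2_anchors: dict | None = None) -> LPNModel:
    """Assemble the packaged closed-loop model for one condition of a patient.

    ``spec`` is a :class:`~coroloop.synthetic_data.SyntheticPatientSpec`;
    parameters are analytic estimates (resistances from pressure-drop /
    flow algebra, compliances from wall stiffness plus pulse-pressure
    heuristics, coronary resistances sized so territory flows meet the
    Rest oxygen anchors at the scenario extraction fractions).
    """
    cond = getattr(spec, condition)
    bsa = spec.bsa
    anchors = dict(REST_MVO2_ANCHORS if mvo2_anchors is None else mvo2_anchors)

    edv_lv, esv_lv = cond.edv_lv * bsa, cond.esv_lv * bsa
    edv_rv, esv_rv = cond.edv_rv * bsa, cond.esv_rv * bsa
    sv = edv_lv - esv_lv
    co = sv * cond.hr / 60.0  # mL/s
    pp = cond.p_ao_syst - cond.p_ao_diast
    map_ = cond.p_ao_diast + pp / 3.0

    # -- heart ---------------------------------------------------------------
    v0_lv = V0_ESV_FRACTION * spec.rest.esv_lv * bsa
    v0_rv = V0_ESV_FRACTION * spec.rest.esv_rv * bsa
    lv = HeartChamber("LV", design_elastance(cond, "LV", bsa, v0=v0_lv),
                      edv_lv, broadcast=True)
    rv = HeartChamber("RV", design_elastance(cond, "RV", bsa, v0=v0_rv),
                      edv_rv, broadcast=True)
    la = HeartChamber("LA", _atrial_elastance(cond.hr, 0.45, 0.22, 5.0),
                      cond.lap / 0.22 + 5.0)
    ra = HeartChamber("RA", _atrial_elastance(cond.hr, 0.40, 0.18, 5.0),
                      cond.cvp / 0.18 + 5.0)
    valves = [
        Valve("mitral", "LA", "LV", r_open=0.006),
        Valve("aortic", "LV", "AO", r_open=0.012),
        Valve("tricuspid", "RA", "RV", r_open=0.006),
        Valve("pulmonary", "RV", "PA", r_open=0.012),
    ]

    # -- systemic chain -------------------------------------------------------
    svr = (map_ - cond.cvp) / co
    r_arch, r_conduit, r_arterioles, r_veins = distribute_resistance(svr, SYS_R_FRACTIONS)
    ao_spec = aortic_wall_spec(cond.p_ao_syst, cond.p_ao_diast)
    c_ao = stiffness_to_compliance(linearized_stiffness(ao_spec, cgs_mm=True),
                                   ao_spec.d_diast, ao_spec.h, ao_spec.length)
    segments = [
        VascularSegment("sys_arch", "AO", "AOD", R=r_arch, C=0.12,
                        initial_pressure=map_),
        VascularSegment("sys_conduit", "AOD", "SART", R=r_conduit, C=0.45,
                        initial_pressure=map_ - 2.0),
        VascularSegment("sys_arterioles", "SART", "SVEN", R=r_arterioles, C=15.0,
                        initial_pressure=cond.cvp + 2.0),
        VascularSegment("sys_veins", "SVEN", "RA", R=r_veins),
    ]

    # -- pulmonary chain ------------------------------------------------------
    pvr = (cond.mean_pap - cond.lap) / co
    r_ppx, r_part, r_pveins = distribute_resistance(pvr, PUL_R_FRACTIONS)
    pa_syst = cond.rv_ao_ratio * cond.p_ao_syst - 2.0
    pu_spec = pulmonary_wall_spec(pa_syst, max(0.3 * pa_syst, 10.0))
    c_pa = stiffness_to_compliance(linearized_stiffness(pu_spec, cgs_mm=True),
                                   pu_spec.d_diast, pu_spec.h, pu_spec.length)
    segments += [
        VascularSegment("pul_prox", "PA", "PART", R=r_ppx, C=0.25,
                        initial_pressure=cond.mean_pap - 5.0),
        VascularSegment("pul_arterioles", "PART", "PVEN", R=r_part, C=5.0,
                        initial_pressure=cond.lap + 1.0),
        VascularSegment("pul_veins", "PVEN", "LA", R=r_pveins),
    ]

    capacitors = [
        Capacitor("AO", C=c_ao, initial_pressure=cond.p_ao_diast),
        Capacitor("PA", C=c_pa, initial_pressure=cond.mean_pap),
    ]

    # -- coronary blocks ------------------------------------------------------
    # Territory flows sized so the Rest anchors are met at the Rest
    # extraction fractions with normal arterial O2 content.
    o2_content = 0.2
    rest_extraction = {"LCA": 0.8, "RCA": 0.4}
    gradient = map_ - (cond.cvp + 2.0)
    blocks = []
    for territory, chamber in (("LCA", "LV"), ("RCA", "RV")):
        anchor = anchors["LV" if territory == "LCA" else "RV"]
        q = anchor / (rest_extraction[territory] * o2_content * 60.0)  # mL/s
        r_tot = gradient / q
        r_micro = COR_R_FRACTIONS["micro"] * r_tot
        r_ven = COR_R_FRACTIONS["ven"] * r_tot
        c_im = CIM_TIME_CONSTANT * (r_micro + r_ven) / (r_micro * r_ven)
        blocks.append(CoronaryBlock(
            territory=territory,
            r_prox=COR_R_FRACTIONS["prox"] * r_tot,
            c_art=0.0015,
            r_micro=r_micro,
            c_im=c_im,
            r_ven=r_ven,
            r_min=0.05 * r_micro,
            r_max=10.0 * r_micro,
            broadcast_source=chamber,
            inlet="AO",
            outlet="SVEN",
            init_p_art=cond.p_ao_diast,
            init_p_im=cond.cvp + 5.0,
        ))

    return LPNModel(chambers=[lv, rv, la, ra], valves=valves, segments=segments,
                    capacitors=capacitors, coronary_blocks=blocks)
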