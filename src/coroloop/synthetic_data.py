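"""Synthetic clinical-style inputs with known ground truth.

The source study's inputs (hybrid catheter / dobutamine-stress-MRI data)
are not publicly deposited, so this module emulates them: per-cycle
ventricular volume curves with cine-like sampling (~25 frames/cycle),
catheter-like pressure traces (≥200 samples/cycle) aligned by R-wave
markers, and per-condition calibration target sets.  Every generated
dataset carries its generating parameters (the "ground truth"), so
elastance-derivation and calibration recovery are tested against truth,
never against published figures.

Noise model: multiplicative log-normal on amplitudes (volumes 2%,
pressures 1% by default), additive Gaussian jitter on the R-wave marker
(5 ms); everything is seeded and bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import builder
from .calibration import CalibrationTargets, Target
from .heart_model import ClinicalCycleData, ElastanceFunction, systole_fractions_for_hr
from .lpn_core import LPNModel
from .tables import STRESS_CO_RATIO, TABLE1

__all__ = [
    "ConditionTargets",
    "NoiseSpec",
    "SyntheticPatientSpec",
    "generate_cycle_data",
    "generate_targets",
    "generate_ground_truth_model",
]


@dataclass
class ConditionTargets:
    """Hemodynamic description of one condition (volumes in mL/m²)."""

    hr: float
    edv_lv: float
    esv_lv: float
    edv_rv: float
    esv_rv: float
    p_ao_syst: float
    p_ao_diast: float
    rv_ao_ratio: float  # systolic RV / aortic pressure ratio
    mean_pap: float
    cvp: float = 6.0
    lap: float = 8.0
    edp_lv: float = 8.0
    edp_rv: float = 10.0

    def __post_init__(self) -> None:
        fields = [self.hr, self.edv_lv, self.esv_lv, self.edv_rv, self.esv_rv,
                  self.p_ao_syst, self.p_ao_diast, self.rv_ao_ratio,
                  self.mean_pap, self.cvp, self.lap, self.edp_lv, self.edp_rv]
        if any(x <= 0 for x in fields):
            raise ValueError("all physiologic fields must be positive")
        if self.esv_lv >= self.edv_lv or self.esv_rv >= self.edv_rv:
            raise ValueError("ESV must be below EDV")

    @property
    def map(self) -> float:
        return self.p_ao_diast + (self.p_ao_syst - self.p_ao_diast) / 3.0


@dataclass
class NoiseSpec:
    volume_sd: float = 0.02  # multiplicative, log-normal
    pressure_sd: float = 0.01  # multiplicative, log-normal
    jitter_sd: float = 0.005  # s, additive Gaussian on the R-wave marker


def _default_rest() -> ConditionTargets:
    t1 = TABLE1["Rest"]
    return ConditionTargets(hr=t1["hr"], edv_lv=t1["edv_lv"], esv_lv=t1["esv_lv"],
                            edv_rv=t1["edv_rv"], esv_rv=t1["esv_rv"],
                            p_ao_syst=100.0, p_ao_diast=60.0, rv_ao_ratio=0.75,
                            mean_pap=40.0)


def _default_stress() -> ConditionTargets:
    t1 = TABLE1["Stress"]
    return ConditionTargets(hr=t1["hr"], edv_lv=t1["edv_lv"], esv_lv=t1["esv_lv"],
                            edv_rv=t1["edv_rv"], esv_rv=t1["esv_rv"],
                            p_ao_syst=110.0, p_ao_diast=48.0, rv_ao_ratio=1.14,
                            mean_pap=60.0, edp_lv=7.0, edp_rv=9.0)


@dataclass
class SyntheticPatientSpec:
    """A synthetic patient: Rest + Stress conditions, noise and a seed."""

    seed: int = 0
    bsa: float = 0.75  # m²
    rest: ConditionTargets = field(default_factory=_default_rest)
    stress: ConditionTargets = field(default_factory=_default_stress)
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    co_stress_ratio: float = STRESS_CO_RATIO  # flow-based CO(Stress)/CO(Rest)


def _rng_for(spec: SyntheticPatientSpec, *context: str) -> np.random.Generator:
    extra = [abs(hash(c)) % (2**31) for c in context]
    return np.random.default_rng(np.random.SeedSequence([spec.seed % (2**31), *extra]))


def generate_cycle_data(spec: SyntheticPatientSpec, condition: str, ventricle: str,
                        n_frames: int = 25, n_pressure: int = 256,
                        ) -> tuple[ClinicalCycleData, ElastanceFunction]:
    """One cardiac cycle of cine-like volume + catheter-like pressure data.

    The data are generated *from* a known elastance function driving the
    condition's volume waveform, then sampled at modality-like resolutions
    with the configured noise; both the data and the generating truth are
    returned.
    """
    if condition not in ("rest", "stress"):
        raise ValueError("condition must be 'rest' or 'stress'")
    if ventricle not in ("LV", "RV"):
        raise ValueError("ventricle must be 'LV' or 'RV'")
    cond: ConditionTargets = getattr(spec, condition)
    esv_rest = (spec.rest.esv_lv if ventricle == "LV" else spec.rest.esv_rv) * spec.bsa
    truth = builder.design_elastance(cond, ventricle, spec.bsa,
                                     v0=builder.V0_ESV_FRACTION * esv_rest)
    period = 60.0 / cond.hr
    edv = (cond.edv_lv if ventricle == "LV" else cond.edv_rv) * spec.bsa
    esv = (cond.esv_lv if ventricle == "LV" else cond.esv_rv) * spec.bsa
    tp, ts = systole_fractions_for_hr(cond.hr)
    rng = _rng_for(spec, condition, ventricle)

    phase_v = np.arange(n_frames) / n_frames
    vol = builder.ventricular_volume_waveform(phase_v, edv, esv, tp, ts)
    phase_p = np.arange(n_pressure) / n_pressure
    vol_fine = builder.ventricular_volume_waveform(phase_p, edv, esv, tp, ts)
    pres = truth.elastance(phase_p * period, period) * (vol_fine - truth.v0)

    noise = spec.noise
    vol = vol * np.exp(rng.normal(0.0, noise.volume_sd, size=vol.shape)) \
        if noise.volume_sd > 0 else vol
    pres = pres * np.exp(rng.normal(0.0, noise.pressure_sd, size=pres.shape)) \
        if noise.pressure_sd > 0 else pres
    jitter = float(rng.normal(0.0, noise.jitter_sd)) if noise.jitter_sd > 0 else 0.0

    data = ClinicalCycleData(
        volume_t=phase_v * period,
        volume=vol,
        pressure_t=phase_p * period,
        pressure=np.maximum(pres, 0.0),
        hr=cond.hr,
        r_wave_times=np.array([jitter]),
    )
    return data, truth


def generate_targets(spec: SyntheticPatientSpec, condition: str,
                     co_basis: str = "volumetric") -> CalibrationTargets:
    """Per-condition calibration target set (pressures, CO, volumes, SVR/PVR).

    SVR and PVR are defined from the other targets (SVR = (MAP−CVP)/CO and
    likewise for PVR), so the set is internally consistent by construction.
    With ``co_basis="flow"`` the Stress CO is the published flow-based rise
    (×1.45 over Rest) rather than the volumetric one; the two are knowingly
    inconsistent with the Stress volumes.
    """
    cond: ConditionTargets = getattr(spec, condition)
    sv = (cond.edv_lv - cond.esv_lv) * spec.bsa
    co_vol = sv * cond.hr / 1000.0  # L/min
    if co_basis == "flow" and condition == "stress":
        rest = spec.rest
        co = (rest.edv_lv - rest.esv_lv) * spec.bsa * rest.hr / 1000.0 \
            * spec.co_stress_ratio
    else:
        co = co_vol
    svr = (cond.map - cond.cvp) / co  # WU (mmHg per L/min)
    pvr = (cond.mean_pap - cond.lap) / co
    t = {
        "hr": Target(cond.hr, "bpm", weight=0.0),
        "map": Target(cond.map, "mmHg", weight=2.0),
        "p_ao_syst": Target(cond.p_ao_syst, "mmHg", weight=1.0),
        "p_ao_diast": Target(cond.p_ao_diast, "mmHg", weight=1.0),
        "mean_pap": Target(cond.mean_pap, "mmHg", weight=1.0),
        "co": Target(co, "L/min", weight=2.0),
        "cvp": Target(cond.cvp, "mmHg", weight=0.5),
        "edv_lv": Target(cond.edv_lv, "mL/m2", weight=1.0),
        "esv_lv": Target(cond.esv_lv, "mL/m2", weight=1.0),
        "edv_rv": Target(cond.edv_rv, "mL/m2", weight=1.0),
        "esv_rv": Target(cond.esv_rv, "mL/m2", weight=1.0),
        "p_rv_syst": Target(cond.rv_ao_ratio * cond.p_ao_syst, "mmHg", weight=2.0),
        "svr": Target(svr, "WU", weight=0.5),
        "pvr": Target(pvr, "WU", weight=0.5),
    }
    return CalibrationTargets(targets=t, bsa=spec.bsa, hr=cond.hr)


def generate_ground_truth_model(spec: SyntheticPatientSpec, condition: str = "rest",
                                refine: bool = True, budget: int = 60,
                                tol: float = 0.02) -> LPNModel:
    """A fully parameterized model meeting :func:`generate_targets` within 2%.

    The analytic builder provides the starting point; a bounded
    least-squares refinement against the condition's own targets closes the
    loop (``refine=False`` returns the raw analytic model).  Construction
    fails loudly if the refined model misses any weighted target by more
    than ``tol``.
    """
    from .calibration import calibrate, default_free_parameters, simulate_targets

    model = builder.build_model(spec, condition)
    if not refine:
        return model
    targets = generate_targets(spec, condition)
    report, fitted = calibrate(model, targets, default_free_parameters(),
                               budget=budget)
    if report.max_discrepancy > tol:
        raise RuntimeError(
            f"ground-truth construction infeasible: max target discrepancy "
            f"{report.max_discrepancy:.1%} exceeds {tol:.0%}")
    return fitted
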