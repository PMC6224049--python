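"""Unit conversions.

The core works in a single consistent system: pressure in mmHg, volume in
mL, time in s.  Resistance is therefore mmHg·s/mL, compliance mL/mmHg and
energy mmHg·mL.  Display units used by clinical tables (J, indexed Wood
units) are produced only at the reporting boundary.
"""

from __future__ import annotations

#: 1 mmHg·mL in joules (133.322 Pa × 1e-6 m³).
MMHG_ML_TO_J = 1.33322e-4

#: 1 mmHg in pascal (= g/mm·s² in the CGS-mm system).
MMHG_TO_PA = 133.322

#: Default body surface area (m²) of a ~6-year-old child; used to index
#: volumes and resistances.  Overridable wherever it is consumed.
DEFAULT_BSA = 0.75


def mmhg_ml_to_joule(work: float) -> float:
    """Convert PV work from mmHg·mL to J."""
    return work * MMHG_ML_TO_J


def joule_to_mmhg_ml(work: float) -> float:
    return work / MMHG_ML_TO_J


def resistance_to_wood_m2(r_mmhg_s_ml: float, bsa: float = DEFAULT_BSA) -> float:
    """Convert a resistance in mmHg·s/mL to indexed Wood units (WU·m²).

    1 WU = 1 mmHg/(L/min) = 60/1000 mmHg·s/mL; indexing multiplies by BSA.
    """
    return r_mmhg_s_ml * (1000.0 / 60.0) * bsa


def wood_m2_to_resistance(r_wu_m2: float, bsa: float = DEFAULT_BSA) -> float:
    return r_wu_m2 / ((1000.0 / 60.0) * bsa)


def mmhg_to_cgs_mm(p_mmhg: float) -> float:
    """Pressure mmHg → g/mm·s² (numerically equal to Pa)."""
    return p_mmhg * MMHG_TO_PA


def cgs_mm_to_mmhg(p_cgs: float) -> float:
    return p_cgs / MMHG_TO_PA
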