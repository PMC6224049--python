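"""Vessel wall measurements → 0D model parameters.

The linearized wall stiffness is estimated from paired systolic/diastolic
pressures and diameters,

    E = (P_syst − P_diast)/(D_syst − D_diast) · D_diast · h,

and mapped to an equivalent lumped compliance of a thin-walled
linear-elastic tube of a given length via the standard pulse-wave
distensibility relation  dA/dP = 3πD³/(16·E·h)  (the ν = ½ membrane
convention used by 1D/0D arterial models).  Bulk resistances (SVR, PVR)
are distributed over series segment chains by prescribed fractions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .units import MMHG_TO_PA

__all__ = [
    "VesselWallSpec",
    "linearized_stiffness",
    "stiffness_to_compliance",
    "distribute_resistance",
]


@dataclass
class VesselWallSpec:
    """Catheter/cine-style paired pressure-diameter measurement of a vessel."""

    name: str
    p_syst: float  # mmHg
    p_diast: float  # mmHg
    d_syst: float  # mm
    d_diast: float  # mm
    h: float = 1.0  # wall thickness, mm
    length: float = 100.0  # equivalent lumped length, mm

    def __post_init__(self) -> None:
        if not self.p_syst > self.p_diast:
            raise ValueError(f"{self.name}: require p_syst > p_diast")
        if not self.d_syst > self.d_diast:
            raise ValueError(
                f"{self.name}: require d_syst > d_diast (equal diameters make "
                "the stiffness estimate degenerate)")
        if self.h <= 0:
            raise ValueError(f"{self.name}: wall thickness must be > 0")


def linearized_stiffness(spec: VesselWallSpec, cgs_mm: bool = False) -> float:
    """Linearized stiffness E = ΔP/ΔD · D_diast · h.

    Returned in the caller's pressure units (mmHg-based) by default; with
    ``cgs_mm=True`` pressures are converted so E comes out in g/mm·s²
    (numerically pascal), the unit system of 3D structural solvers.
    """
    dp = spec.p_syst - spec.p_diast
    if cgs_mm:
        dp *= MMHG_TO_PA
    dd = spec.d_syst - spec.d_diast
    return dp / dd * spec.d_diast * spec.h


def stiffness_to_compliance(e_stiffness: float, d_diast: float, h: float,
                            length: float) -> float:
    """Lumped compliance (mL/mmHg) of a thin-wall elastic tube segment.

    C = 3π·D³·L / (16·E·h) with D, L, h in mm and E in g/mm·s² (pascal),
    then converted from mm³/Pa to mL/mmHg.  Scales linearly with length
    and vanishes in the rigid limit E → ∞.
    """
    if min(e_stiffness, d_diast, h, length) <= 0:
        raise ValueError("all arguments must be positive")
    c_mm3_per_pa = 3.0 * np.pi * d_diast**3 * length / (16.0 * e_stiffness * h)
    return c_mm3_per_pa * 1e-3 * MMHG_TO_PA


def distribute_resistance(total_r: float, fractions) -> np.ndarray:
    """Split a bulk resistance over series segments by the given fractions.

    Fractions must be non-negative and sum to ≈1; the last segment absorbs
    float rounding so the returned values sum to ``total_r`` exactly.
    """
    f = np.asarray(fractions, dtype=float)
    if (f < 0).any():
        raise ValueError("fractions must be non-negative")
    if abs(f.sum() - 1.0) > 1e-6:
        raise ValueError(f"fractions must sum to 1 (got {f.sum()})")
    out = total_r * f
    out[-1] = total_r - out[:-1].sum()
    return out
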