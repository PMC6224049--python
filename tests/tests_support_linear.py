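"""Small valve-free, constant-elastance network used by the linear-limit
oracle checks (the RHS is exactly affine, so expm is an exact reference)."""

from coroloop.heart_model import ElastanceFunction, HeartChamber
from coroloop.lpn_core import LPNModel, VascularSegment


def linear_test_model() -> LPNModel:
    ef = ElastanceFunction(e_max=0.8 * (1 + 1e-9), e_min=0.8, v0=5.0,
                           t_peak_fraction=0.3, systole_fraction=0.6)
    return LPNModel(
        chambers=[HeartChamber("CH", ef, volume=40.0)],
        valves=[],
        segments=[
            VascularSegment("s1", "CH", "N1", R=0.4, C=1.5, initial_pressure=12.0),
            VascularSegment("s2", "N1", "N2", R=0.8, C=3.0, initial_pressure=8.0),
            VascularSegment("s3", "N2", "N3", R=1.2, C=6.0, initial_pressure=6.0),
            VascularSegment("s4", "N3", "CH", R=0.6),
        ])
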