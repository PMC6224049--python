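"""PV-loop energetics, oxygen accounting and the resistance controller."""

import numpy as np
import pytest
from shapely.geometry import Polygon

from coroloop.coronary_control import (CoronaryBlock, OxygenAccounting,
                                       adapt_resistance, mvo2_rate,
                                       pv_loop_workload, pva_per_beat,
                                       supply_rate, update_hunger)
from coroloop.heart_model import ElastanceFunction
from coroloop.units import MMHG_ML_TO_J


def rectangle_loop():
    """Physiological traversal: fill at 10 mmHg, eject at 100 mmHg."""
    v = np.array([80.0, 80.0, 30.0, 30.0, 80.0])
    p = np.array([10.0, 100.0, 100.0, 10.0, 10.0])
    return v, p


def make_block(**kw):
    args = dict(territory="LCA", r_prox=8.0, c_art=0.002, r_micro=80.0,
                c_im=0.01, r_ven=20.0, r_min=20.0, r_max=400.0)
    args.update(kw)
    return CoronaryBlock(**args)


class TestWorkload:
    def test_rectangle_area(self):
        v, p = rectangle_loop()
        assert pv_loop_workload(v, p) == pytest.approx(50 * 90 * MMHG_ML_TO_J)
        assert pv_loop_workload(v, p) == pytest.approx(0.600, abs=0.001)

    def test_reversed_traversal_is_negative(self):
        v, p = rectangle_loop()
        assert pv_loop_workload(v[::-1], p[::-1]) == pytest.approx(-0.600, abs=0.001)

    def test_open_loop_rejected(self):
        v, p = rectangle_loop()
        v = v.copy()
        v[-1] = 40.0  # endpoint 40 vs start 80: far beyond 2% of SV
        with pytest.raises(ValueError, match="open PV loop"):
            pv_loop_workload(v, p)

    def test_agrees_with_polygon_oracle(self):
        # independent geometric computation on an irregular smooth loop
        phi = np.linspace(0, 2 * np.pi, 400, endpoint=False)
        v = 55 + 20 * np.cos(phi) + 3 * np.cos(2 * phi)
        p = 60 - 45 * np.sin(phi) + 5 * np.sin(2 * phi)
        v = np.append(v, v[0])
        p = np.append(p, p[0])
        area = Polygon(zip(v, p)).area * MMHG_ML_TO_J
        assert abs(pv_loop_workload(v, p)) == pytest.approx(area, rel=1e-9)


class TestPVA:
    def test_arithmetic_example(self):
        ef = ElastanceFunction(3.0, 0.2, v0=10.0, t_peak_fraction=0.2,
                               systole_fraction=0.36)
        pva = pva_per_beat(0.4, ef, (40.0, 100.0))
        assert pva == pytest.approx(0.4 + 0.5 * 100 * 30 * MMHG_ML_TO_J)
        assert pva == pytest.approx(0.600, abs=0.001)

    def test_no_potential_energy_at_unstressed_volume(self):
        ef = ElastanceFunction(3.0, 0.2, v0=30.0, t_peak_fraction=0.2,
                               systole_fraction=0.36)
        assert pva_per_beat(0.4, ef, (30.0, 90.0)) == pytest.approx(0.4)

    def test_end_systole_below_v0_rejected(self):
        ef = ElastanceFunction(3.0, 0.2, v0=30.0, t_peak_fraction=0.2,
                               systole_fraction=0.36)
        with pytest.raises(ValueError):
            pva_per_beat(0.4, ef, (20.0, 90.0))


class TestOxygenRates:
    def test_demand_is_per_beat_times_rate(self):
        acct = OxygenAccounting(extraction=1.0, alpha=0.0, beta=0.05)
        assert mvo2_rate(0.5, 60.0, acct) == pytest.approx(0.05 * 60.0)

    def test_demand_scales_linearly_with_rate(self):
        acct = OxygenAccounting(extraction=1.0, alpha=2e-5, beta=0.0)
        assert mvo2_rate(0.4, 120.0, acct) == pytest.approx(
            2 * mvo2_rate(0.4, 60.0, acct))

    def test_supply_definition(self):
        acct = OxygenAccounting(extraction=1.0, o2_content=0.2)
        assert supply_rate(1.0, acct) == pytest.approx(12.0)
        assert supply_rate(0.0, acct) == 0.0

    def test_extraction_halves_supply(self):
        lca = OxygenAccounting(extraction=0.8, o2_content=0.2)
        rca = OxygenAccounting(extraction=0.4, o2_content=0.2)
        assert supply_rate(2.0, rca) == pytest.approx(0.5 * supply_rate(2.0, lca))

    def test_extraction_domain(self):
        with pytest.raises(ValueError):
            OxygenAccounting(extraction=0.0)
        with pytest.raises(ValueError):
            OxygenAccounting(extraction=1.2)


class TestHunger:
    def test_balanced_budget_leaves_hunger(self):
        acct = OxygenAccounting(extraction=1.0, hunger=0.3)
        assert update_hunger(acct, 5.0, 5.0, dt=1.0) == pytest.approx(0.3)

    def test_accumulates_deficit(self):
        acct = OxygenAccounting(extraction=1.0)
        assert update_hunger(acct, 10.0, 0.0, dt=60.0) == pytest.approx(10.0)

    def test_clamped_at_zero(self):
        acct = OxygenAccounting(extraction=1.0, hunger=0.1)
        for _ in range(10):
            update_hunger(acct, 1.0, 50.0, dt=10.0)
        assert acct.hunger == 0.0

    def test_requires_positive_dt(self):
        acct = OxygenAccounting(extraction=1.0)
        with pytest.raises(ValueError):
            update_hunger(acct, 1.0, 1.0, dt=0.0)


class TestAdaptResistance:
    def test_fixed_point(self):
        blk = make_block()
        r0 = blk.r_micro
        assert adapt_resistance(blk, 5.0, 5.0, kappa=0.5) == pytest.approx(r0)

    def test_half_supply_halves_resistance_at_unit_gain(self):
        blk = make_block()
        r0 = blk.r_micro
        assert adapt_resistance(blk, 10.0, 5.0, kappa=1.0) == pytest.approx(r0 / 2)

    def test_saturates_at_floor(self):
        blk = make_block()
        for _ in range(50):
            adapt_resistance(blk, 10.0, 1.0, kappa=1.0)
        assert blk.r_micro == pytest.approx(blk.r_min)
        assert blk.saturated

    def test_invalid_inputs_rejected(self):
        blk = make_block()
        with pytest.raises(ValueError):
            adapt_resistance(blk, 0.0, 5.0)
        with pytest.raises(ValueError):
            adapt_resistance(blk, 5.0, 5.0, kappa=1.5)

    def test_block_invariants(self):
        with pytest.raises(ValueError):
            make_block(r_min=100.0, r_max=50.0)
        with pytest.raises(ValueError):
            make_block(c_im=-1.0)
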