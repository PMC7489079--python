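"""Allometric biomass, sink activities, demands, respiration and supplies."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mscarbon import (
    GompertzParams,
    SpeciesParams,
    compute_demands,
    dm_demand,
    gdd_accumulate,
    gompertz_rgr,
    init_biomass,
    load_supply,
    respiration_demand,
    shoot_glm_mass,
)

from conftest import make_chain

FRUIT = GompertzParams(63.703, -4.896, -0.00104)
SHOOT = GompertzParams(2.406, -2.84, -0.00165)


class TestGompertz:
    def test_fruit_activity_at_zero(self):
        assert gompertz_rgr(0.0, FRUIT) == pytest.approx(
            (-4.896) * (-0.00104), rel=1e-12
        )

    @pytest.mark.parametrize("p", [FRUIT, SHOOT])
    def test_ratio_form_equals_simplified(self, p):
        gdd = np.linspace(0.0, 3000.0, 601)
        assert gompertz_rgr(gdd, p) == pytest.approx(
            p.b * p.c * np.exp(p.c * gdd), rel=1e-12
        )

    @pytest.mark.parametrize("p", [FRUIT, SHOOT])
    def test_matches_log_derivative(self, p):
        # activity = d/dGDD log(a exp(b exp(c GDD)))
        eps = 1e-3
        for gdd in np.linspace(1.0, 3000.0, 25):
            def logw(x):
                return math.log(p.a) + p.b * math.exp(p.c * x)
            numeric = (logw(gdd + eps) - logw(gdd - eps)) / (2 * eps)
            assert gompertz_rgr(gdd, p) == pytest.approx(numeric, abs=1e-6)

    def test_vanishes_as_c_to_zero(self):
        for c in (-1e-6, -1e-9):
            p = GompertzParams(10.0, -3.0, c)
            assert abs(gompertz_rgr(500.0, p)) <= abs(3.0 * c) * 1.001


class TestInitBiomass:
    def test_wood_cylinder_mass(self):
        t = make_chain(2, year=3)
        t.set_prop("M2", "year", 4)  # M1 is old wood relative to the tree
        t.set_prop("M1", "radius", 0.01)
        t.set_prop("M1", "length", 1.0)
        init_biomass(t, SpeciesParams(), gdd_cum=500.0)
        expect_g = math.pi * 1e-4 * 1.0 * 700.0 * 1e3  # ~219.9 g = 0.2199 kg
        assert t.prop("M1", "internode_dry_mass") == pytest.approx(expect_g, rel=1e-9)

    def test_leaf_mass_from_area(self):
        t = make_chain(2, year=3)
        t.set_prop("M2", "leaf_area", 0.01)
        init_biomass(t, SpeciesParams(), gdd_cum=500.0)
        assert t.prop("M2", "leaf_dry_mass") == pytest.approx(0.0008 * 1e3)  # 0.8 g

    def test_shoot_glm_against_direct_formula(self):
        a, b, c, d, e = SpeciesParams().shoot_glm
        length_cm, gdd = 10.0, 500.0
        expect = math.exp(
            a + b * math.log(length_cm) + c * gdd + d * length_cm
            + e * math.log(length_cm * gdd)
        )
        assert shoot_glm_mass(length_cm, gdd, (a, b, c, d, e)) == pytest.approx(expect)
        # a current-year 2-metamer shoot of total length 10 cm gets that mass
        t = make_chain(2, year=4)
        for v in ("M1", "M2"):
            t.set_prop(v, "length", 0.05)
        init_biomass(t, SpeciesParams(), gdd_cum=500.0)
        total = sum(t.prop(v, "internode_dry_mass") for v in ("M1", "M2"))
        assert total == pytest.approx(expect, rel=1e-9)

    def test_fruit_initial_mass(self):
        t = make_chain(2, year=4)
        t.set_prop("M2", "n_fruits", 1)
        init_biomass(t, SpeciesParams(), gdd_cum=500.0)
        assert t.prop("M2", "fruit_dry_mass") == pytest.approx(8.0)

    def test_nonpositive_shoot_length_rejected(self):
        with pytest.raises(ValueError, match="length"):
            shoot_glm_mass(0.0, 500.0, SpeciesParams().shoot_glm)


class TestDemand:
    def test_fruit_demand_arithmetic(self):
        # 8 g x activity(0) x 10 degC = 0.4073 g dry matter
        val = dm_demand(8.0, "fruit", 0.0, 10.0, SpeciesParams())
        assert val == pytest.approx(8.0 * 0.00509184 * 10.0, rel=1e-9)

    def test_zero_thermal_time_zero_demand(self):
        assert dm_demand(8.0, "fruit", 100.0, 0.0, SpeciesParams()) == 0.0

    def test_leaf_activity_clipped_to_printed_range(self):
        sp = SpeciesParams()
        sp.leaf_activity_table = pd.DataFrame(
            {"gdd": [0.0, 1000.0], "activity": [-1.0, 5.0]}
        )
        assert sp.leaf_activity(0.0) == 0.0
        assert sp.leaf_activity(1000.0) == pytest.approx(1.9e-3)

    @given(mass=st.floats(0.1, 1e4), scale=st.floats(0.1, 10.0))
    @settings(max_examples=30, deadline=None)
    def test_demand_homogeneous_in_mass(self, mass, scale):
        sp = SpeciesParams()
        base = dm_demand(mass, "fruit", 400.0, 8.0, sp)
        assert dm_demand(mass * scale, "fruit", 400.0, 8.0, sp) == pytest.approx(
            base * scale, rel=1e-9
        )

    def test_root_demand_is_shoot_total_over_ratio(self):
        from mscarbon import generate_tree
        from mscarbon.synth import SynthConfig
        tree = generate_tree(SynthConfig(seed=2))
        init_biomass(tree, SpeciesParams(), gdd_cum=500.0)
        state = compute_demands(tree, SpeciesParams(), 500.0, 10.0)
        organs = state.organs
        shoot_sum = organs.loc[organs.organ_class == "shoot", "dm_demand_C"].sum()
        root = organs.loc[organs.organ_class == "root", "dm_demand_C"].sum()
        assert root * 4.5 == pytest.approx(shoot_sum, rel=1e-9)

    def test_gdd_accumulation_floors_at_base(self):
        gdd = gdd_accumulate([10.0, 4.5, 2.0, 14.5], base=4.5)
        assert gdd == pytest.approx([5.5, 5.5, 5.5, 15.5])


class TestRespiration:
    def test_null_respiration_total_equals_dm(self):
        maint, growth = respiration_demand(
            100.0, "old_wood", [20.0] * 24, SpeciesParams(), dm_demand_C=1.0
        )
        assert maint == 0.0 and growth == 0.0

    def test_reference_temperature_identity(self):
        sp = SpeciesParams(maintenance_coeff={"old_wood": 1e-4})
        maint, _ = respiration_demand(100.0, "old_wood", [sp.t_ref] * 24, sp)
        assert maint == pytest.approx(100.0 * 1e-4)

    def test_maintenance_linear_in_mass(self):
        sp = SpeciesParams(maintenance_coeff={"fruit": 2e-4}, q10=2.0)
        temps = [15.0, 25.0, 20.0]
        m1, _ = respiration_demand(50.0, "fruit", temps, sp)
        m2, _ = respiration_demand(100.0, "fruit", temps, sp)
        assert m2 == pytest.approx(2 * m1)

    def test_growth_respiration_structure(self):
        sp = SpeciesParams(maintenance_coeff={"fruit": 1e-4}, growth_resp_coeff=0.3)
        maint, growth = respiration_demand(
            10.0, "fruit", [sp.t_ref], sp, dm_demand_C=2.0
        )
        assert growth == pytest.approx(0.3 * (maint + 2.0))


class TestSupply:
    def make_state(self, tree):
        init_biomass(tree, SpeciesParams(), gdd_cum=500.0)
        return compute_demands(tree, SpeciesParams(), 500.0, 10.0)

    def test_uniform_supply_totals(self):
        t = make_chain(10, year=4, leaf_area=0.002)
        state = self.make_state(t)
        table = {f"M{k}": 0.1 for k in range(1, 11)}
        state = load_supply(t, state, table)
        assert state.organs["supply_C"].sum() == pytest.approx(1.0)

    def test_empty_table_no_supply(self):
        t = make_chain(5, year=4, leaf_area=0.002)
        state = load_supply(t, self.make_state(t), {})
        assert state.organs["supply_C"].sum() == 0.0

    def test_unknown_leaf_id_rejected(self):
        t = make_chain(3, year=4, leaf_area=0.002)
        with pytest.raises(ValueError, match="unknown"):
            load_supply(t, self.make_state(t), {"M99": 0.1})

    def test_negative_values_clipped(self):
        t = make_chain(3, year=4, leaf_area=0.002)
        state = load_supply(t, self.make_state(t), {"M1": -0.5, "M2": 0.3})
        assert state.organs["supply_C"].min() >= 0.0
        assert state.organs["supply_C"].sum() == pytest.approx(0.3)


def test_species_params_yaml_round_trip(tmp_path):
    sp = SpeciesParams(growth_resp_coeff=0.25,
                       maintenance_coeff={"fruit": 1e-4, "old_wood": 2e-5})
    path = tmp_path / "species.yaml"
    sp.to_yaml(path)
    back = SpeciesParams.from_yaml(path)
    assert back.dry_mass_to_C_mass == sp.dry_mass_to_C_mass
    assert back.growth_resp_coeff == 0.25
    assert back.gompertz["fruit"] == sp.gompertz["fruit"]
    assert back.maintenance_coeff["fruit"] == 1e-4
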