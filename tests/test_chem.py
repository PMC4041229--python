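"""Closed-vial partitioning: Henry interpolation, dosing, mass balance."""


import pytest
from hypothesis import given
from hypothesis import strategies as hst

import solvtol as st
from solvtol.chem import partition_amount


def make_solvent(henry_points, solubility=1e6):
    return st.SolventSpec("X", 100.0, 1.0, 2.0, solubility, tuple(henry_points))


class TestHenry:
    def test_exact_table_lookup(self):
        s = make_solvent([(30.0, 0.2)])
        assert st.henry_at_temperature(s, 30.0) == 0.2

    def test_vant_hoff_interpolation(self):
        # hand-computed: ln H linear in 1/T(K) between (20 C, 0.1) and (40 C, 0.4)
        s = make_solvent([(20.0, 0.1), (40.0, 0.4)])
        assert st.henry_at_temperature(s, 30.0) == pytest.approx(0.20462564584032705, rel=1e-12)

    @pytest.mark.parametrize("temp,expected", [(10.0, 0.1), (50.0, 0.4)])
    def test_clamped_outside_range_with_warning(self, temp, expected):
        s = make_solvent([(20.0, 0.1), (40.0, 0.4)])
        with pytest.warns(UserWarning, match="clamping"):
            assert st.henry_at_temperature(s, temp) == expected

    def test_empty_table_is_a_configuration_error(self):
        with pytest.raises(ValueError, match="non-empty"):
            make_solvent([])

    def test_table_must_increase_in_temperature(self):
        with pytest.raises(ValueError, match="strictly increasing"):
            make_solvent([(30.0, 0.2), (20.0, 0.1)])


class TestMolesAdded:
    def test_neat_carbon_tetrachloride_microlitre(self, ct):
        # 1 uL x 1.594 g/mL / 153.82 g/mol = 10.36 umol
        dose = st.SolventDose("neat", 1.0)
        assert st.moles_added(dose, ct) == pytest.approx(10.3628, abs=1e-3)

    def test_ethanolic_stock_is_volume_times_molarity(self, ct):
        dose = st.SolventDose("ethanolic_stock", 100.0, stock_concentration=0.1)
        assert st.moles_added(dose, ct) == pytest.approx(10.0)

    def test_zero_volume_rejected(self):
        with pytest.raises(ValueError, match="volume_added"):
            st.SolventDose("ethanolic_stock", 0.0, stock_concentration=0.1)

    def test_stock_mode_requires_concentration(self):
        with pytest.raises(ValueError, match="stock_concentration"):
            st.SolventDose("ethanolic_stock", 10.0)


class TestPartition:
    def test_two_phase_mass_balance_example(self):
        # n=10 umol, V_aq=10 mL, V_gas=15 mL, Hcc=0.2 -> C_aq = 10/13 mM
        s = make_solvent([(30.0, 0.2)])
        res = partition_amount(s, st.VialSetup(10.0, 15.0, 30.0), 10.0)
        assert res.aqueous_concentration == pytest.approx(10.0 / 13.0, rel=1e-12)
        assert not res.free_phase

    def test_involatile_limit_gives_nominal(self):
        s = make_solvent([(30.0, 1e-12)])
        res = partition_amount(s, st.VialSetup(10.0, 15.0, 30.0), 10.0)
        assert res.aqueous_concentration == pytest.approx(res.nominal_concentration, rel=1e-9)
        assert res.nominal_concentration == pytest.approx(1.0)

    def test_solubility_cap_creates_free_phase(self):
        # PCE-like: dose so the unconstrained C_aq would be 2.0 mM >> 0.9 mM cap
        s = make_solvent([(30.0, 0.5)], solubility=0.9)
        vial = st.VialSetup(10.0, 15.0, 30.0)
        n = 2.0 * (10.0 + 0.5 * 15.0)
        res = partition_amount(s, vial, n)
        assert res.aqueous_concentration == pytest.approx(0.9)
        assert res.free_phase and res.free_phase_amount > 0
        assert res.nominal_concentration > 0.9
        assert res.headspace_concentration == pytest.approx(0.5 * 0.9)

    @given(
        n=hst.floats(0.1, 1e4),
        v_aq=hst.floats(1.0, 50.0),
        v_gas=hst.floats(0.0, 100.0),
        hcc=hst.floats(1e-4, 10.0),
        sol=hst.floats(0.1, 100.0),
    )
    def test_mass_conservation_property(self, n, v_aq, v_gas, hcc, sol):
        s = make_solvent([(30.0, hcc)], solubility=sol)
        res = partition_amount(s, st.VialSetup(v_aq, v_gas, 30.0), n)
        recon = (res.aqueous_concentration * v_aq
                 + res.headspace_concentration * v_gas
                 + res.free_phase_amount)
        assert recon == pytest.approx(n, rel=1e-9)
        assert res.aqueous_concentration <= sol * (1 + 1e-12)
        assert res.free_phase == (res.free_phase_amount > 0)

    def test_aqueous_concentration_decreases_with_hcc_and_headspace(self):
        vial = st.VialSetup(10.0, 15.0, 30.0)
        c = [partition_amount(make_solvent([(30.0, h)]), vial, 10.0).aqueous_concentration
             for h in (0.1, 0.5, 2.0)]
        assert c[0] > c[1] > c[2]
        s = make_solvent([(30.0, 0.5)])
        c = [partition_amount(s, st.VialSetup(10.0, vg, 30.0), 10.0).aqueous_concentration
             for vg in (1.0, 15.0, 60.0)]
        assert c[0] > c[1] > c[2]

    def test_no_headspace_limit_gives_nominal(self):
        s = make_solvent([(30.0, 0.5)])
        res = partition_amount(s, st.VialSetup(10.0, 0.0, 30.0), 10.0)
        assert res.aqueous_concentration == pytest.approx(res.nominal_concentration)

    @given(target=hst.floats(0.01, 0.89), hcc=hst.floats(0.01, 5.0))
    def test_dose_planning_round_trip(self, target, hcc):
        s = st.SolventSpec("X", 120.0, 1.5, 2.0, 0.9, ((30.0, hcc),))
        vial = st.VialSetup(10.0, 15.0, 30.0)
        dose = st.dose_for_aqueous_concentration(s, vial, target)
        res = st.partition_dose(s, vial, dose)
        assert res.aqueous_concentration == pytest.approx(target, rel=1e-9)

    def test_target_above_solubility_rejected(self):
        s = make_solvent([(30.0, 0.5)], solubility=0.9)
        with pytest.raises(ValueError, match="solubility"):
            st.amount_for_aqueous_concentration(s, st.VialSetup(), 2.0)


def test_packaged_constants_cover_all_four_solvents(solvents):
    assert sorted(solvents) == ["1,2-DCA", "CF", "CT", "PCE"]
    pce = solvents["PCE"]
    assert pce.aqueous_solubility == 0.9
    assert solvents["CT"].aqueous_solubility == 5.0
    # hydrophobicity ordering used throughout the analytics
    lp = {k: v.log_pow for k, v in solvents.items()}
    assert lp["1,2-DCA"] < lp["CF"] < lp["CT"] < lp["PCE"]
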