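"""Electron equivalents, COD accounting, coulombic efficiency, donor budgets."""

from fractions import Fraction

import pytest
from hypothesis import given
from hypothesis import strategies as st

from biocathode.budget import (
    CLASS_CATHODE_SUFFICIENT,
    CLASS_DONOR_DEFICIT,
    CLASS_MULTI_DONOR,
    build_donor_budget,
    cod_to_coulombs,
    coulombic_efficiency,
    formate_coulombs,
    iron_reduction_extent,
    organic_acid_cod_correction,
    thiosulfate_donor_check,
    yeast_extract_coulombs,
)
from biocathode.compounds import (
    DEFAULT_REGISTRY,
    electron_equivalents,
    mass_to_mM,
    parse_formula,
)
from biocathode.datatypes import CODMeasurement


def combustion_oracle_ne(formula: str) -> int:
    """Independent electron count: balance CxHyOz + a O2 -> x CO2 + y/2 H2O.

    Oxygen balance gives a = x + y/4 - z/2, and each O2 accepts 4 e-,
    so ne = 4a.
    """
    c = parse_formula(formula)
    x, y, z = c.get("C", 0), c.get("H", 0), c.get("O", 0)
    a = Fraction(x) + Fraction(y, 4) - Fraction(z, 2)
    ne = 4 * a
    assert ne.denominator == 1
    return int(ne)


class TestElectronEquivalents:
    @pytest.mark.parametrize(
        "formula, expected",
        [
            ("C2H4O2", 8),     # acetic
            ("C4H8O2", 20),    # butyric / isobutyric
            ("C6H12O2", 32),   # 4-methylvaleric
            ("CH2O2", 2),      # formic
        ],
    )
    def test_known_acids(self, formula, expected):
        assert electron_equivalents(formula) == expected
        assert combustion_oracle_ne(formula) == expected

    def test_whole_registry_matches_combustion_oracle(self):
        organics = [s for s in DEFAULT_REGISTRY.values() if s.elements]
        assert len(organics) == 8
        for spec in organics:
            formula = "".join(
                f"{el}{n}" for el, n in spec.elements.items()
            )
            assert spec.ne == combustion_oracle_ne(formula)
            assert spec.cod_gO2_per_mol == 8 * spec.ne

    def test_hetero_elements_need_explicit_ne(self):
        with pytest.raises(ValueError, match="explicit ne"):
            electron_equivalents("C2H7NO2")

    def test_inorganic_half_reactions(self):
        assert DEFAULT_REGISTRY["hydrogen"].ne == 2
        assert DEFAULT_REGISTRY["thiosulfate"].ne == 8
        assert DEFAULT_REGISTRY["Fe(III)"].ne == 1


class TestCoulombicEfficiency:
    def test_formula_evaluation(self):
        # 1 mM acetate (ne=8) in 0.25 L against 200 C
        ce = coulombic_efficiency(1.0, 8, 0.25, 200.0)
        assert ce == pytest.approx(96.485, abs=0.01)

    def test_zero_production_zero_ce(self):
        assert coulombic_efficiency(0.0, 8, 0.25, 200.0) == 0.0

    def test_zero_coulombs_undefined(self):
        assert coulombic_efficiency(1.0, 8, 0.25, 0.0) is None

    @given(
        delta=st.floats(min_value=0.01, max_value=10.0),
        q=st.floats(min_value=1.0, max_value=1e4),
        k=st.floats(min_value=0.1, max_value=100.0),
    )
    def test_homogeneous_in_delta_and_charge(self, delta, q, k):
        base = coulombic_efficiency(delta, 8, 0.25, q)
        scaled = coulombic_efficiency(delta * k, 8, 0.25, q * k)
        assert scaled == pytest.approx(base, rel=1e-9)


class TestCODAccounting:
    def test_eight_grams_is_one_faraday(self):
        assert cod_to_coulombs(8.0, 1.0) == pytest.approx(96_485.0)

    def test_zero_delta(self):
        assert cod_to_coulombs(0.0, 0.25) == 0.0

    def test_cod_increase_flags_carbon_fixation(self):
        cod = CODMeasurement("r", cod_initial_gO2_per_L=0.3, cod_final_gO2_per_L=0.5)
        q, flag = yeast_extract_coulombs(cod, product_cod_gO2=0.0, volume_L=0.25)
        assert q == 0.0 and flag is True

    def test_acetate_cod_correction(self):
        # 1 mM acetate in 0.25 L: 0.25 mmol x 64 g/mol = 0.016 g O2
        correction = organic_acid_cod_correction(
            {"acetic acid": 1.0}, DEFAULT_REGISTRY, 0.25
        )
        assert correction == pytest.approx(0.016)

    def test_correction_is_linear(self):
        one = organic_acid_cod_correction({"acetic acid": 1.0, "lactic acid": 2.0},
                                          DEFAULT_REGISTRY, 0.25)
        three = organic_acid_cod_correction({"acetic acid": 3.0, "lactic acid": 6.0},
                                            DEFAULT_REGISTRY, 0.25)
        assert three == pytest.approx(3 * one)

    def test_product_cod_subtracted_before_attribution(self):
        # final COD inflated exactly by the products: nothing left for yeast
        cod = CODMeasurement("r", 0.30, 0.30 + 0.016 / 0.25)
        q, flag = yeast_extract_coulombs(cod, product_cod_gO2=0.016, volume_L=0.25)
        assert q == pytest.approx(0.0, abs=1e-9) and flag is True


class TestThiosulfateDonor:
    def test_stoichiometric_case(self):
        is_donor, q = thiosulfate_donor_check(-10.0, 20.0, volume_L=0.25)
        assert is_donor
        assert q == pytest.approx(0.010 * 0.25 * 8 * 96_485)  # 1,930 C

    def test_sulfate_also_consumed(self):
        is_donor, q = thiosulfate_donor_check(-10.0, -5.0, volume_L=0.25)
        assert not is_donor and q == 0.0

    def test_ratio_below_tolerance(self):
        # 9 mM sulfate from 10 mM thio: ratio 0.45 < 0.5
        is_donor, q = thiosulfate_donor_check(-10.0, 9.0, volume_L=0.25, tolerance=0.5)
        assert not is_donor and q == 0.0


class TestFormateDonor:
    def test_consumption_coulombs(self):
        # 20 mM consumed in 0.25 L -> 0.005 mol x 2 F = 965 C
        assert formate_coulombs(-20.0, 0.25) == pytest.approx(965.0, abs=0.5)

    def test_no_consumption(self):
        assert formate_coulombs(0.0, 0.25) == 0.0

    def test_production_not_counted_donor_side(self):
        assert formate_coulombs(5.0, 0.25) == 0.0


class TestBudgetClassification:
    def make_budget(self, record, q_cathode, deltas, cod=None):
        return build_donor_budget(record, q_cathode, deltas, cod=cod)

    def test_cathode_sufficient(self, reactor_record):
        # ~150 C of acetate against 200 cathodic coulombs
        delta = 150.0 / (96_485 * 8 * 0.25) * 1000
        b = self.make_budget(reactor_record, 200.0, {"acetic acid": delta})
        assert b.classification == CLASS_CATHODE_SUFFICIENT
        assert b.ce_total_percent == pytest.approx(75.0)
        assert not b.ce_over_100

    def test_multi_donor(self, reactor_record):
        # 300 C of products, 200 C cathode + 200 C formate
        delta_prod = 300.0 / (96_485 * 8 * 0.25) * 1000
        delta_formate = -200.0 / (96_485 * 2 * 0.25) * 1000
        b = self.make_budget(
            reactor_record, 200.0,
            {"acetic acid": delta_prod, "formic acid": delta_formate},
        )
        assert b.classification == CLASS_MULTI_DONOR
        assert b.ce_total_percent == pytest.approx(150.0)
        assert b.ce_over_100

    def test_donor_deficit(self, reactor_record):
        delta_prod = 900.0 / (96_485 * 8 * 0.25) * 1000
        delta_formate = -400.0 / (96_485 * 2 * 0.25) * 1000
        b = self.make_budget(
            reactor_record, 200.0,
            {"acetic acid": delta_prod, "formic acid": delta_formate},
        )
        assert b.classification == CLASS_DONOR_DEFICIT

    def test_per_product_ces_sum_to_total(self, reactor_record):
        b = self.make_budget(
            reactor_record, 400.0, {"acetic acid": 0.7, "butyric acid": 0.4}
        )
        assert sum(b.ce_per_product_percent.values()) == pytest.approx(
            b.ce_total_percent
        )


class TestIronReduction:
    def test_measured_extent_consistent_with_magnetite(self):
        r = iron_reduction_extent(0.9, 3.2)
        assert r.fraction_reduced == pytest.approx(0.281, abs=0.001)
        assert r.magnetite_consistent

    def test_exact_third_consistent(self):
        assert iron_reduction_extent(1.0, 3.0).magnetite_consistent

    def test_over_reduction_not_consistent(self):
        assert not iron_reduction_extent(1.8, 3.0).magnetite_consistent

    def test_fe2_above_total_errors(self):
        with pytest.raises(ValueError):
            iron_reduction_extent(4.0, 3.0)


def test_sodium_formate_medium_stoichiometry():
    # 1.36 g/L sodium formate (CHO2Na) is 20 mM formate
    assert mass_to_mM(1.36, "CHO2Na") == pytest.approx(20.0, abs=0.05)
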