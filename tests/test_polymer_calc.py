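"""Solid-phase stoichiometry: the four calculations and their consistency."""

import random

import pytest

from benchchem.chemgraph import (
    Atom,
    Bond,
    BondOrder,
    Formula,
    Molecule,
    average_mass,
    element_mass_fractions,
    formula_to_hill_string,
    molecular_formula,
)
from benchchem.errors import (
    DegenerateMarkerError,
    DegenerateMassError,
    LoadingError,
    SupportModelError,
)
from benchchem.masses import ATOMIC_WEIGHTS
from benchchem.polymer_calc import (
    CALCULATION_MODES,
    PolymerComposition,
    ResinBatch,
    SupportedMolecule,
    export_defined_part,
    loaded_elemental_composition,
    loading_after_full_conversion,
    marker_percent_at_yield,
    millimoles_on_resin,
    product_mass_at_yield,
    yield_from_elemental_analysis,
    yield_from_mass,
)

D = BondOrder.DOUBLE


def _supported_acetate() -> SupportedMolecule:
    # Pol-O-C(=O)-CH3
    return SupportedMolecule(Molecule(
        atoms=[Atom("Pol"), Atom("O", x=1.0), Atom("C", x=2.0),
               Atom("O", x=2.0, y=-1.0), Atom("C", x=3.0)],
        bonds=[Bond(0, 1), Bond(1, 2), Bond(2, 3, D), Bond(2, 4)]))


class TestExportDefinedPart:
    def test_methyl_substitution_gives_methyl_acetate(self):
        out = export_defined_part(_supported_acetate())
        assert not out.has_pseudo_atoms()
        assert dict(molecular_formula(out)) == {"C": 3, "H": 6, "O": 2}

    def test_lone_pol_carbon_gives_ethane(self):
        s = SupportedMolecule(Molecule(
            atoms=[Atom("Pol"), Atom("C", x=1.0)], bonds=[Bond(0, 1)]))
        assert formula_to_hill_string(
            molecular_formula(export_defined_part(s))) == "C2H6"

    def test_surface_symbol_treated_identically(self):
        s = SupportedMolecule(Molecule(
            atoms=[Atom("Sur"), Atom("O", x=1.0)], bonds=[Bond(0, 1)]))
        assert formula_to_hill_string(
            molecular_formula(export_defined_part(s))) == "CH4O"

    def test_no_pseudo_atom_rejected(self):
        with pytest.raises(SupportModelError):
            SupportedMolecule(Molecule(atoms=[Atom("C")]))

    def test_two_pseudo_atoms_rejected(self):
        with pytest.raises(SupportModelError):
            SupportedMolecule(Molecule(
                atoms=[Atom("Pol"), Atom("C", x=1.0), Atom("Sur", x=2.0)],
                bonds=[Bond(0, 1), Bond(1, 2)]))

    def test_multiply_bonded_pseudo_rejected(self):
        with pytest.raises(SupportModelError):
            SupportedMolecule(Molecule(
                atoms=[Atom("Pol"), Atom("C", x=1.0), Atom("C", x=2.0)],
                bonds=[Bond(0, 1), Bond(0, 2)]))


@pytest.mark.parametrize("mass, loading, expected", [
    (1.0, 1.0, 1.0), (2.0, 0.8, 1.6), (0.5, 2.4, 1.2)])
def test_millimoles_on_resin(mass, loading, expected):
    assert millimoles_on_resin(mass, loading) == pytest.approx(expected)


class TestLoadedComposition:
    def test_chloromethyl_polystyrene_worked_example(self):
        comp = PolymerComposition("polystyrene", Formula.from_string("C8H8"),
                                  loading=1.00)
        pct = loaded_elemental_composition(comp, Formula.from_string("CH2Cl"))
        # independent spreadsheet-style arithmetic with the bundled weights:
        # per g resin, 1 mmol CH2Cl (M 49.480) leaves 0.95052 g backbone
        assert pct["Cl"] == pytest.approx(3.545, abs=5e-3)
        assert pct["C"] == pytest.approx(88.894, abs=5e-3)
        assert pct["H"] == pytest.approx(7.561, abs=5e-3)
        assert sum(pct.values()) == pytest.approx(100.0, abs=1e-6)

    def test_zero_loading_limit_recovers_backbone_fractions(self):
        repeat = Formula.from_string("C8H8")
        comp = PolymerComposition("ps", repeat, loading=1e-9)
        pct = loaded_elemental_composition(comp, Formula.from_string("CH2Cl"))
        expect = element_mass_fractions(repeat)
        assert pct["C"] == pytest.approx(100 * expect["C"], abs=1e-4)
        assert pct["H"] == pytest.approx(100 * expect["H"], abs=1e-4)

    def test_single_nitrogen_marker_percent(self):
        # 1.00 mmol N per gram contributes 1.00e-3 * 14.007 * 100 percent
        comp = PolymerComposition("ps", Formula.from_string("C8H8"), loading=1.00)
        pct = loaded_elemental_composition(comp, Formula.from_string("CH2N"))
        assert pct["N"] == pytest.approx(1.4007, abs=1e-4)

    def test_crosslink_blending_is_mole_weighted(self):
        # 10% DVB (C10H10) in styrene (C8H8): blend fractions follow the
        # mole-weighted average unit, computed here independently
        repeat, cross = Formula.from_string("C8H8"), Formula.from_string("C10H10")
        comp = PolymerComposition("ps-dvb", repeat, loading=1e-9,
                                  crosslink_formula=cross, crosslink_fraction=0.10)
        pct = loaded_elemental_composition(comp, Formula.from_string("CH2"))
        c = 0.9 * 8 + 0.1 * 10
        h = 0.9 * 8 + 0.1 * 10
        total = c * ATOMIC_WEIGHTS["C"] + h * ATOMIC_WEIGHTS["H"]
        assert pct["C"] == pytest.approx(100 * c * ATOMIC_WEIGHTS["C"] / total,
                                         abs=1e-4)

    def test_overloaded_fragment_rejected(self):
        comp = PolymerComposition("ps", Formula.from_string("C8H8"), loading=25.0)
        with pytest.raises(LoadingError):
            loaded_elemental_composition(comp, Formula.from_string("C6H4Br"))

    def test_randomized_percent_closure_and_monotonicity(self, rng):
        for _ in range(200):
            loading = rng.uniform(0.05, 3.0)
            comp = PolymerComposition(
                "ps", Formula.from_string("C8H8"), loading=loading)
            frag = Formula({"C": rng.randint(1, 10), "H": rng.randint(1, 20),
                            "N": rng.randint(1, 3)})
            pct = loaded_elemental_composition(comp, frag)
            assert sum(pct.values()) == pytest.approx(100.0, abs=1e-6)
            # N is unique to the fragment: its percent grows with loading
            higher = loaded_elemental_composition(
                PolymerComposition("ps", Formula.from_string("C8H8"),
                                   loading=loading * 1.1), frag)
            assert higher["N"] > pct["N"]


class TestYieldFromMass:
    def test_hand_worked_example(self):
        # m_s=1.000 g, L=1.00 mmol/g, dM=100 g/mol, m_p=1.080 g
        start = ResinBatch(1.000, 1.00, Formula({"C": 7, "H": 16}))
        m_fs = average_mass(start.fragment_formula)
        product = Formula({"C": 7, "H": 16, "Zr": 1})  # any fragment works;
        # construct a product exactly 100 heavier via the forward model
        d = average_mass(product) - m_fs
        m_p = 1.000 + 1.00e-3 * 0.80 * d
        r = yield_from_mass(start, product, m_p)
        assert r.yield_fraction == pytest.approx(0.80, abs=1e-9)
        assert r.millimoles_start == pytest.approx(1.0)
        assert r.millimoles_product == pytest.approx(0.80, abs=1e-9)

    def test_no_mass_change_is_zero_yield(self):
        start = ResinBatch(1.0, 1.0, Formula({"C": 6, "H": 14}))
        r = yield_from_mass(start, Formula({"C": 6, "H": 13, "Br": 1}), 1.0)
        assert r.yield_fraction == 0.0 and not r.clamped

    def test_full_conversion_mass_is_yield_one(self):
        start = ResinBatch(1.0, 1.2, Formula({"C": 6, "H": 14}))
        product = Formula({"C": 6, "H": 13, "I": 1})
        m_p = product_mass_at_yield(start, product, 1.0)
        r = yield_from_mass(start, product, m_p)
        assert r.yield_fraction == pytest.approx(1.0, abs=1e-12)

    def test_equal_fragment_masses_degenerate(self):
        start = ResinBatch(1.0, 1.0, Formula({"C": 2, "H": 6}))
        with pytest.raises(DegenerateMassError):
            yield_from_mass(start, Formula({"C": 2, "H": 6}), 1.01)

    def test_impossible_yield_flagged_not_hidden(self):
        start = ResinBatch(1.0, 1.0, Formula({"C": 6, "H": 14}))
        product = Formula({"C": 6, "H": 13, "Cl": 1})
        m_p = product_mass_at_yield(start, product, 1.5)  # >100% conversion
        r = yield_from_mass(start, product, m_p)
        assert r.clamped
        assert r.yield_fraction == 1.0
        assert r.yield_fraction_raw == pytest.approx(1.5, abs=1e-9)


class TestYieldFromElementalAnalysis:
    def test_nitrogen_marker_worked_example(self):
        # start fragment has no N (M 100.0-ish), product gains one N;
        # the measured percent is generated by the forward model at y=0.90
        start = ResinBatch(1.000, 1.00, Formula({"C": 7, "H": 16}))
        product = start.fragment_formula + Formula({"N": 1})
        percent = marker_percent_at_yield(start, product, "N", 0.90)
        r = yield_from_elemental_analysis(start, product, "N", percent)
        assert r.yield_fraction == pytest.approx(0.90, abs=1e-6)
        assert 1.0 < percent < 1.5  # ~1.25%N, the scale of a real analysis

    def test_zero_percent_zero_start_marker_is_zero_yield(self):
        start = ResinBatch(1.0, 1.0, Formula({"C": 7, "H": 16}))
        product = start.fragment_formula + Formula({"N": 1})
        r = yield_from_elemental_analysis(start, product, "N", 0.0)
        assert r.yield_fraction == 0.0

    def test_forward_value_at_full_conversion_inverts_to_one(self):
        start = ResinBatch(2.0, 0.7, Formula({"C": 10, "H": 21, "N": 1}))
        product = Formula({"C": 10, "H": 20, "N": 2})
        percent = marker_percent_at_yield(start, product, "N", 1.0)
        r = yield_from_elemental_analysis(start, product, "N", percent)
        assert r.yield_fraction == pytest.approx(1.0, abs=1e-6)

    def test_insensitive_marker_degenerate(self):
        start = ResinBatch(1.0, 1.0, Formula({"C": 7, "H": 16}))
        # same marker count on both sides, and measured percent exactly
        # cancels the mass-change sensitivity when dM == 0
        with pytest.raises(DegenerateMarkerError):
            yield_from_elemental_analysis(
                start, start.fragment_formula, "N", 0.0)

    def test_support_marker_term_shifts_the_solution(self):
        # a nitrogen-bearing backbone contributes marker mass of its own
        start = ResinBatch(1.0, 0.5, Formula({"C": 7, "H": 16}))
        product = start.fragment_formula + Formula({"N": 1})
        comp = PolymerComposition(
            "polyamide", Formula({"C": 6, "H": 11, "N": 1, "O": 1}), loading=0.5)
        percent = marker_percent_at_yield(start, product, "N", 0.6,
                                          composition=comp)
        r = yield_from_elemental_analysis(start, product, "N", percent,
                                          composition=comp)
        assert r.yield_fraction == pytest.approx(0.6, abs=1e-6)
        # ignoring the backbone term misreads the same analysis
        r_wrong = yield_from_elemental_analysis(start, product, "N", percent)
        assert abs(r_wrong.yield_fraction_raw - 0.6) > 0.05


class TestLoadingAfterFullConversion:
    def test_hand_arithmetic(self):
        start = ResinBatch(2.000, 0.80, Formula({"C": 1, "H": 2}))
        assert loading_after_full_conversion(start, 2.100) == pytest.approx(
            1.6 / 2.1, abs=1e-9)

    def test_identity_mass_keeps_loading(self):
        start = ResinBatch(2.0, 0.80, Formula({"C": 1, "H": 2}))
        assert loading_after_full_conversion(start, 2.0) == pytest.approx(0.80)

    def test_doubled_mass_halves_loading(self):
        start = ResinBatch(2.0, 0.80, Formula({"C": 1, "H": 2}))
        assert loading_after_full_conversion(start, 4.0) == pytest.approx(0.40)


class TestCrossCalculatorConsistency:
    def test_mass_and_ea_agree_on_random_draws(self):
        rng = random.Random(777)
        for _ in range(300):
            start = ResinBatch(
                mass=rng.uniform(0.2, 5.0), loading=rng.uniform(0.2, 2.0),
                fragment_formula=Formula({"C": rng.randint(2, 12),
                                          "H": rng.randint(4, 24)}))
            product = start.fragment_formula + Formula(
                {"N": rng.randint(1, 3), "O": rng.randint(1, 2)})
            y_true = rng.uniform(0.0, 1.0)
            y_mass = yield_from_mass(
                start, product,
                product_mass_at_yield(start, product, y_true)).yield_fraction
            y_ea = yield_from_elemental_analysis(
                start, product, "N",
                marker_percent_at_yield(start, product, "N", y_true)
            ).yield_fraction
            assert y_mass == pytest.approx(y_true, abs=1e-9)
            assert y_ea == pytest.approx(y_true, abs=1e-6)
            assert y_mass == pytest.approx(y_ea, abs=1e-6)

    def test_full_conversion_links_yield_and_loading(self):
        start = ResinBatch(1.5, 0.9, Formula({"C": 8, "H": 18}))
        product = start.fragment_formula + Formula({"Br": 1})
        m_p = product_mass_at_yield(start, product, 1.0)
        new_loading = loading_after_full_conversion(start, m_p)
        assert new_loading == pytest.approx(start.millimoles / m_p, abs=1e-12)
        r = yield_from_mass(start, product, m_p)
        assert r.millimoles_product / m_p == pytest.approx(new_loading, abs=1e-9)


def test_exactly_four_calculation_modes():
    assert CALCULATION_MODES == ("composition", "yield-mass", "yield-ea",
                                 "loading")


def test_resin_batch_sanity_checks():
    with pytest.raises(LoadingError):
        ResinBatch(-1.0, 1.0, Formula({"C": 1, "H": 2}))
    with pytest.raises(LoadingError):
        ResinBatch(1.0, 0.0, Formula({"C": 1, "H": 2}))
    with pytest.raises(LoadingError):
        # 10 mmol/g of a 200 g/mol fragment would outweigh the resin
        ResinBatch(1.0, 10.0, Formula({"C": 14, "H": 32}))
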