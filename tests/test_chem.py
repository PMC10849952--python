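"""Formula arithmetic, adduct masses, isotope envelopes and decomposition."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from halomet import chem
from halomet.chem import (
    ADDUCTS,
    ElementCount,
    FormulaError,
    adduct_mz,
    chlorine_score,
    decompose_mass,
    isotope_pattern,
    monoisotopic_mass,
    parse_formula,
)

from conftest import multinomial_pattern, random_plausible_formula


class TestParseFormat:
    @pytest.mark.parametrize(
        "text,counts",
        [
            ("C28H55O8Cl", {"C": 28, "H": 55, "O": 8, "Cl": 1}),
            ("H2O", {"H": 2, "O": 1}),
            ("C28H53D2O8Cl", {"C": 28, "H": 53, "D": 2, "O": 8, "Cl": 1}),
            ("NaCl", {"Na": 1, "Cl": 1}),
        ],
    )
    def test_parse_examples(self, text, counts):
        assert parse_formula(text).counts == counts

    @pytest.mark.parametrize("bad", ["Xq3", "C28Zz", "", "H0", "2H"])
    def test_parse_errors(self, bad):
        with pytest.raises(FormulaError):
            parse_formula(bad)

    def test_parse_error_names_token(self):
        with pytest.raises(FormulaError, match="Xq"):
            parse_formula("Xq3")

    @given(
        st.dictionaries(
            st.sampled_from(["C", "H", "D", "N", "O", "S", "Cl", "Na"]),
            st.integers(min_value=1, max_value=200),
            min_size=1,
            max_size=8,
        )
    )
    @settings(max_examples=100, deadline=None)
    def test_hill_roundtrip_lossless(self, counts):
        f = ElementCount(counts)
        assert parse_formula(f.hill()) == f

    def test_negative_count_rejected(self):
        with pytest.raises(FormulaError):
            ElementCount({"C": -1})


class TestMasses:
    def test_empty_formula_mass_zero(self):
        assert monoisotopic_mass(ElementCount({})) == 0.0

    def test_water(self):
        assert monoisotopic_mass("H2O") == pytest.approx(18.010565, abs=1e-5)

    def test_lead_compound(self):
        assert monoisotopic_mass("C28H55O8Cl") == pytest.approx(
            554.358543, abs=1e-4
        )

    def test_additivity_random_pairs(self, rng):
        for _ in range(25):
            a = random_plausible_formula(rng, (100, 600))
            b = random_plausible_formula(rng, (100, 600))
            assert monoisotopic_mass(a + b) == pytest.approx(
                monoisotopic_mass(a) + monoisotopic_mass(b), abs=1e-9
            )


class TestAdducts:
    @pytest.mark.parametrize(
        "formula,adduct,expected",
        [
            ("C28H55O8Cl", "[M+H]+", 555.3658),
            ("C46H89O9Cl", "[M+NH4]+", 838.6533),
            ("C31H59O2Cl", "[M+NH4]+", 516.4542),
        ],
    )
    def test_printed_calcd_values(self, formula, adduct, expected):
        assert round(adduct_mz(formula, adduct), 4) == expected

    def test_proton_gap_between_polarities(self, rng):
        # [M+H]+ minus [M-H]- is two proton masses for any neutral M
        for _ in range(10):
            f = random_plausible_formula(rng, (200, 800))
            gap = adduct_mz(f, "[M+H]+") - adduct_mz(f, "[M-H]-")
            assert gap == pytest.approx(2 * 1.007276, abs=1e-6)

    def test_unknown_adduct_lists_supported(self):
        with pytest.raises(KeyError, match=r"\[M\+H\]\+"):
            adduct_mz("H2O", "[M+K]+")

    def test_unicode_minus_accepted(self):
        # 554.358546 - 1.007825 + m_e = 553.351270 (hand summation)
        assert adduct_mz("C28H55O8Cl", "[M−H]−") == pytest.approx(
            553.351270, abs=1e-5
        )


class TestIsotopePattern:
    def test_single_cl_m2_ratio(self):
        p = isotope_pattern("Cl")
        assert p.abundance_at(2) / p.abundance_at(0) == pytest.approx(
            0.3200, abs=0.0005
        )

    def test_two_cl(self):
        p = isotope_pattern("Cl2")
        assert p.abundance_at(2) == pytest.approx(0.6399, abs=1e-4)
        assert p.abundance_at(4) == pytest.approx(0.1024, abs=1e-4)

    def test_carbon_m1(self):
        p = isotope_pattern("C")
        assert p.abundance_at(1) == pytest.approx(0.01082, abs=1e-5)

    def test_base_peak_normalised_and_sorted(self):
        p = isotope_pattern("C28H55O8Cl")
        ab = p.abundances
        assert ab.max() == pytest.approx(1.0)
        mz = p.mzs
        assert np.all(np.diff(mz) > 0)
        # successive offsets spaced by ~1.00336 Da per offset step
        steps = np.diff(p.offsets)
        gaps = np.diff(mz)
        assert np.allclose(gaps, np.array(steps) * 1.00336, atol=0.01)

    def test_prune_threshold(self):
        p = isotope_pattern("C28H55O8Cl", prune=1e-4)
        assert (p.abundances >= 1e-4).all()

    @pytest.mark.parametrize(
        "formula",
        ["H2O", "Cl2", "C2H4", "SO2", "C3HCl", "CHNOS", "S2Cl", "C6", "D2O"],
    )
    def test_matches_multinomial_oracle(self, formula):
        # renormalised abundances agree with exhaustive isotopologue
        # enumeration to 1e-9, centroid m/z to 1e-6
        p = isotope_pattern(formula, max_offsets=16, prune=0.0)
        oracle = multinomial_pattern(formula, prune=0.0)
        total_p = p.abundances.sum()
        total_o = sum(a for _, a in oracle.values())
        assert set(p.offsets) == set(oracle)
        for off, (mz, ab) in zip(p.offsets, p.peaks):
            omz, oab = oracle[off]
            assert ab / total_p == pytest.approx(oab / total_o, abs=1e-9)
            assert mz == pytest.approx(omz, abs=1e-6)

    def test_convolution_identity(self, rng):
        # pattern(A+B) equals offset-wise convolution of the parts
        for _ in range(10):
            a = random_plausible_formula(rng, (100, 400))
            b = random_plausible_formula(rng, (100, 400))
            pa = isotope_pattern(a, max_offsets=12, prune=0.0)
            pb = isotope_pattern(b, max_offsets=12, prune=0.0)
            conv = chem.convolve_patterns(pa, pb, max_offsets=12, prune=0.0)
            direct = isotope_pattern(a + b, max_offsets=12, prune=0.0)
            for off, (mz, ab) in zip(direct.offsets, direct.peaks):
                assert conv.abundance_at(off) == pytest.approx(ab, abs=1e-9)


class TestChlorineScore:
    def test_chlorinated_lead_compound(self):
        call = chlorine_score(isotope_pattern("C28H55O8Cl"))
        assert call.is_chlorinated
        assert call.ratio == pytest.approx(0.38, abs=0.02)
        assert call.n_cl == 1

    def test_unchlorinated_analog(self):
        call = chlorine_score(isotope_pattern("C28H56O8"))
        assert not call.is_chlorinated
        assert call.ratio == pytest.approx(0.06, abs=0.01)
        assert call.n_cl == 0

    def test_two_chlorines(self):
        call = chlorine_score(isotope_pattern("C20H38O4Cl2"))
        assert call.is_chlorinated
        assert call.n_cl == 2

    def test_missing_m2_peak(self):
        p = chem.IsotopePattern((0, 1), ((300.0, 1.0), (301.003, 0.2)))
        call = chlorine_score(p)
        assert call == (False, 0.0, 0)

    def test_empty_pattern_errors(self):
        with pytest.raises(ValueError):
            chlorine_score(chem.IsotopePattern((), ()))


class TestDecomposeMass:
    def test_finds_lead_formula(self):
        cands = decompose_mass(555.3658, ["[M+H]+"], tol_ppm=10,
                               require={"Cl": 1})
        hills = [c.formula.hill() for c in cands]
        assert "C28H55ClO8" in hills
        # smallest |ppm| first
        assert hills[0] == "C28H55ClO8"

    def test_water_enumeration(self):
        cands = decompose_mass(19.01784, ["[M+H]+"], tol_ppm=5,
                               bounds={"H": (0, 4), "O": (0, 2)})
        assert [c.formula.hill() for c in cands] == ["H2O"]

    def test_tight_tolerance_empty(self):
        assert decompose_mass(500.0, ["[M+H]+"], tol_ppm=0.001,
                              bounds={"C": (0, 5), "H": (0, 10)}) == []

    def test_empty_bounds_error(self):
        with pytest.raises(ValueError):
            decompose_mass(500.0, ["[M+H]+"], tol_ppm=5, bounds={})

    def test_roundtrip_recovers_generator(self, rng):
        # any synthetic m/z built via adduct_mz is re-found when bounds
        # contain the generating formula
        for _ in range(15):
            f = random_plausible_formula(rng, (250, 850))
            adduct = ["[M+H]+", "[M+NH4]+"][int(rng.integers(2))]
            mz = adduct_mz(f, adduct)
            cands = decompose_mass(mz, [adduct], tol_ppm=1.0)
            assert any(c.formula == f for c in cands)

    def test_ppm_sorting_and_rdbe_filter(self):
        cands = decompose_mass(838.6533, ["[M+NH4]+"], tol_ppm=10,
                               require={"Cl": 1})
        errs = [abs(c.ppm_error) for c in cands]
        assert errs == sorted(errs)
        for c in cands:
            r = chem.rdbe(c.formula)
            assert -0.5 <= r <= 40 and abs(r - round(r)) < 1e-9
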