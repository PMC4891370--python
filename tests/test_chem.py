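"""Composition algebra: parsing, masses, isotope patterns, classification."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from glycotof.chem import (
    ChemistryConstants,
    CompositionParseError,
    DEFAULT_CONSTANTS,
    ElementCounts,
    GlycanClassificationError,
    GlycanComposition,
    classify,
    elemental_formula,
    isotope_pattern,
    monoisotopic_mz,
    neutral_loss_mass,
    parse_composition,
)

from conftest import isotope_pattern_oracle

# Theoretical [M+Na]+ m/z values of the named mouse plasma/peritoneal
# glycoforms, as printed in the source spectra annotation.
PRINTED_MZ = {
    "H5N4Ge2": 2333.82,
    "H5N4F1Ge2": 2479.88,
    "H5N4Ge2Ac1": 2375.84,
    "H5N4Ge2Ac2": 2417.85,
    "H5N4Ge1Gl1": 2287.78,
    "H5N4Ge1Gl1Ac1": 2329.79,
    "H5N4F1Ge1Gl1": 2433.84,
    "H5N4Ge2Gl1": 2622.90,
    "H6N5Ge1Gl2": 2941.99,
    "H7N6Ge1Gl2": 3307.13,
    "H3N3Ge1": 1471.52,
    "H4N4Ge1": 1836.65,
    "H5N4Ge1": 1998.70,
}


@pytest.mark.parametrize("name,printed", sorted(PRINTED_MZ.items()))
def test_printed_mz_reproduced(name, printed):
    assert monoisotopic_mz(parse_composition(name), "Na") == pytest.approx(printed, abs=0.02)


class TestParse:
    @pytest.mark.parametrize(
        "name,expected",
        [
            ("H5N4Ge2", GlycanComposition(H=5, N=4, Ge=2)),
            ("H5N4F1Ge1Gl1", GlycanComposition(H=5, N=4, F=1, Ge=1, Gl=1)),
            ("", GlycanComposition()),
            ("E1L1Ac2", GlycanComposition(E=1, L=1, Ac=2)),
        ],
    )
    def test_parse(self, name, expected):
        assert parse_composition(name) == expected

    @pytest.mark.parametrize("bad", ["H5X2", "H5H4", "H-1", "5H4", "H5N4Ge0", "h5"])
    def test_malformed_rejected(self, bad):
        with pytest.raises(CompositionParseError):
            parse_composition(bad)

    @given(
        st.builds(
            GlycanComposition,
            H=st.integers(0, 9), N=st.integers(0, 6), F=st.integers(0, 2),
            E=st.integers(0, 2), L=st.integers(0, 2),
            Ge=st.integers(0, 3), Gl=st.integers(0, 3),
        )
    )
    @settings(derandomize=True, max_examples=60)
    def test_round_trip(self, comp):
        assert parse_composition(comp.name) == comp

    def test_acetyl_requires_sialic(self):
        with pytest.raises(ValueError, match="sialic"):
            GlycanComposition(H=5, N=4, Ac=1)


class TestMass:
    def test_empty_is_water(self):
        assert monoisotopic_mz(GlycanComposition(), "none") == pytest.approx(18.0106, abs=1e-3)

    def test_unknown_adduct(self):
        with pytest.raises(ValueError, match="adduct"):
            monoisotopic_mz(GlycanComposition(H=1), "K")

    def test_o_acetyl_increments(self):
        base = monoisotopic_mz(parse_composition("H5N4Ge2"), "Na")
        ac1 = monoisotopic_mz(parse_composition("H5N4Ge2Ac1"), "Na")
        ac2 = monoisotopic_mz(parse_composition("H5N4Ge2Ac2"), "Na")
        assert ac1 - base == pytest.approx(42.01, abs=0.01)
        assert ac2 - base == pytest.approx(84.02, abs=0.01)

    def test_fucose_increment_matches_printed_pair(self):
        base = monoisotopic_mz(parse_composition("H5N4Ge2"), "Na")
        fuc = monoisotopic_mz(parse_composition("H5N4F1Ge2"), "Na")
        assert fuc - base == pytest.approx(DEFAULT_CONSTANTS.dhex, abs=1e-9)
        assert fuc - base == pytest.approx(2479.88 - 2333.82, abs=0.02)

    @given(
        st.builds(
            GlycanComposition,
            H=st.integers(0, 9), N=st.integers(0, 6), F=st.integers(0, 2),
            Ge=st.integers(0, 3), Gl=st.integers(0, 3),
        ),
        st.builds(
            GlycanComposition,
            H=st.integers(0, 9), N=st.integers(0, 6),
            E=st.integers(0, 2), L=st.integers(0, 2),
        ),
    )
    @settings(derandomize=True, max_examples=60)
    def test_mass_additivity(self, a, b):
        # concatenating two glycans removes one glycosidic water
        combined = a.combine(b)
        assert monoisotopic_mz(combined, "none") == pytest.approx(
            monoisotopic_mz(a, "none") + monoisotopic_mz(b, "none")
            - DEFAULT_CONSTANTS.water,
            abs=1e-9,
        )

    def test_pyteomics_oracle(self):
        """Formula-level masses agree with an independent mass calculator."""
        mass = pytest.importorskip("pyteomics.mass")
        for name in ("H5N4Ge2", "H3N3Ge1", "H5N4F1Ge1Gl1Ac1", "H9N2", "H5N4F2E1"):
            f = elemental_formula(parse_composition(name))
            ours = monoisotopic_mz(parse_composition(name), "none")
            theirs = mass.calculate_mass(formula=f.hill_formula())
            assert ours == pytest.approx(theirs, abs=1e-5)


class TestElemental:
    def test_water_and_hexose(self):
        assert elemental_formula(GlycanComposition()) == ElementCounts(H=2, O=1)
        assert elemental_formula(GlycanComposition(H=1)) == ElementCounts(C=6, H=12, O=6)

    @pytest.mark.parametrize("name", ["H5N4Ge2", "H5N4F1Ge1Gl1Ac1", "H3N3Ge1", "H5N4F2E1"])
    def test_formula_mass_consistent(self, name):
        comp = parse_composition(name)
        assert elemental_formula(comp).monoisotopic_mass() == pytest.approx(
            monoisotopic_mz(comp, "none"), abs=1e-6
        )


class TestIsotopePattern:
    def test_single_carbon(self):
        peaks = isotope_pattern(ElementCounts(C=1), 1.0)
        assert len(peaks) == 2
        assert peaks[0][1] == pytest.approx(0.9893, abs=1e-10)
        assert peaks[1][1] == pytest.approx(0.0107, abs=1e-10)
        assert peaks[1][0] == pytest.approx(1.003355, abs=1e-5)

    @pytest.mark.parametrize(
        "formula,coverage",
        [
            (ElementCounts(C=6, H=12, O=6), 0.95),  # one hexose
            (ElementCounts(C=10, H=20, N=2, O=8), 0.99),
            (elemental_formula(parse_composition("H5N4Ge2")), 0.95),
            (elemental_formula(parse_composition("H7N6Ge1Gl2")), 0.999),
        ],
    )
    def test_matches_enumeration_oracle(self, formula, coverage):
        ours = isotope_pattern(formula, coverage)
        oracle = isotope_pattern_oracle(formula, coverage)
        assert len(ours) == len(oracle)
        for (off_a, ab_a), (off_b, ab_b) in zip(ours, oracle):
            assert abs(ab_a - ab_b) < 1e-9
            assert abs(off_a - off_b) < 1e-7

    @given(
        st.builds(
            GlycanComposition,
            H=st.integers(1, 9), N=st.integers(0, 6), F=st.integers(0, 2),
            Ge=st.integers(0, 3),
        ),
        st.floats(0.5, 0.999),
    )
    @settings(derandomize=True, max_examples=40)
    def test_coverage_contract(self, comp, coverage):
        from glycotof.chem import isotope_envelope

        offsets, abunds, covered = isotope_envelope(elemental_formula(comp), coverage)
        assert covered >= coverage - 1e-9
        peaks = isotope_pattern(elemental_formula(comp), coverage)
        assert sum(p for _, p in peaks) == pytest.approx(1.0, abs=1e-12)

    def test_empty_formula_rejected(self):
        with pytest.raises(ValueError):
            isotope_pattern(ElementCounts(), 0.95)


class TestClassify:
    @pytest.mark.parametrize(
        "name,expected",
        [
            ("H5N2", ("high_mannose", 0, 0)),
            ("H9N2", ("high_mannose", 0, 0)),
            ("H5N4Ge2", ("complex", 2, 2)),
            ("H7N6Ge1Gl2", ("complex", 4, 4)),
            ("H5N3Ge1", ("hybrid", 0, 0)),
            ("H3N3Ge1", ("complex", 1, 0)),
            ("H4N3Ge1", ("complex", 1, 1)),
            ("H3N2", ("complex", 0, 0)),  # paucimannose stub
        ],
    )
    def test_rules(self, name, expected):
        assert classify(parse_composition(name)) == expected

    def test_rejects_non_core(self):
        with pytest.raises(GlycanClassificationError):
            classify(GlycanComposition(H=3, N=1))


class TestNeutralLoss:
    def test_core_glcnac_fucose_loss(self):
        loss = neutral_loss_mass(parse_composition("N1F1"), reducing_end=True)
        assert loss == pytest.approx(367.1, abs=0.05)

    def test_bare_reducing_end(self):
        assert neutral_loss_mass(GlycanComposition(), reducing_end=True) == pytest.approx(
            18.01, abs=0.01
        )

    def test_internal_hexose(self):
        assert neutral_loss_mass(GlycanComposition(H=1)) == pytest.approx(162.05, abs=0.01)


class TestConstants:
    def test_derivatization_signs(self):
        assert DEFAULT_CONSTANTS.ethyl_ester > 0
        assert DEFAULT_CONSTANTS.lactone < 0
        assert DEFAULT_CONSTANTS.o_acetyl == pytest.approx(42.0106, abs=1e-3)

    def test_yaml_override(self, tmp_path):
        path = tmp_path / "chem.yaml"
        path.write_text("hex: 162.0\n")
        c = ChemistryConstants.from_yaml(path)
        assert c.hex == 162.0
        assert c.hexnac == DEFAULT_CONSTANTS.hexnac
        path.write_text("frobnicate: 1.0\n")
        with pytest.raises(KeyError):
            ChemistryConstants.from_yaml(path)
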