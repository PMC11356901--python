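"""Exact-mass arithmetic: masses, adducts, ppm, RDBE, decomposition."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from msescreen.chem_core import (
    DEFAULT_BOUNDS,
    ELEMENT_MASSES,
    PROTON_MASS,
    Formula,
    decompose_mass,
    get_adduct,
    ion_mz,
    monoisotopic_mass,
    ppm_error,
    rdbe,
)


class TestFormula:
    def test_parse_roundtrip(self):
        f = Formula.parse("C18H33NO")
        assert f == Formula(C=18, H=33, N=1, O=1)
        assert f.hill() == "C18H33NO"
        assert f.atom_count == 53

    def test_parse_rejects_garbage(self):
        with pytest.raises(ValueError):
            Formula.parse("C18H33-NO")

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            Formula(C=-1)

    def test_addition(self):
        assert Formula(C=1, H=2) + Formula(H=2, O=1) == Formula(C=1, H=4, O=1)


class TestMass:
    @pytest.mark.parametrize(
        "formula, expected",
        [
            ("C9H16O4", 188.104859),  # azelaic acid
            ("C28H37N5O7", 555.2692985),  # leucine enkephalin
            ("", 0.0),
        ],
    )
    def test_monoisotopic_examples(self, formula, expected):
        assert monoisotopic_mass(Formula.parse(formula)) == pytest.approx(
            expected, abs=1e-6
        )

    def test_unknown_element_is_invalid_input(self):
        with pytest.raises(ValueError, match="unknown element"):
            monoisotopic_mass({"Xx": 1})

    def test_element_table_invariants(self):
        assert ELEMENT_MASSES["C"] == 12.0
        assert abs(ELEMENT_MASSES["H"] - 1.00783) < 1e-5
        assert all(m > 0 for m in ELEMENT_MASSES.values())

    def test_masses_agree_with_pyteomics(self):
        pyteomics_mass = pytest.importorskip("pyteomics.mass")
        for formula in ["C9H16O4", "C28H37N5O7", "C18H33NO", "C9H6O2"]:
            ours = monoisotopic_mass(Formula.parse(formula))
            theirs = pyteomics_mass.calculate_mass(formula=formula)
            assert ours == pytest.approx(theirs, abs=2e-5)


class TestIonMz:
    def test_lockmass_ions(self):
        """Reference-compound lock masses: the protonated and deprotonated
        leucine-enkephalin ions round to the instrument calibration values."""
        f = Formula.parse("C28H37N5O7")
        assert round(ion_mz(f, "[M+H]+"), 4) == 556.2766
        assert round(ion_mz(f, "[M-H]-"), 4) == 554.2620

    def test_proton_spacing(self):
        f = Formula.parse("C9H16O4")
        assert ion_mz(f, "[M+H]+") - ion_mz(f, "[M-H]-") == pytest.approx(
            2 * PROTON_MASS, abs=1e-12
        )
        assert ion_mz(f, "[M-H]-") == pytest.approx(187.097583, abs=1e-6)

    def test_unsupported_adduct_names_supported_ones(self):
        with pytest.raises(ValueError, match=r"\[M\+H\]\+"):
            get_adduct("[M+Na]+")

    def test_unicode_minus_accepted(self):
        assert get_adduct("[M − H]−").name == "[M-H]-"

    def test_monotone_in_element_counts(self):
        base = Formula(C=10, H=20, O=2)
        for element in "CHNO":
            bigger = base + Formula(**{element: 1})
            assert ion_mz(bigger, "[M-H]-") > ion_mz(base, "[M-H]-")


class TestPpmError:
    def test_worked_example(self):
        assert ppm_error(187.0982, 187.097583) == pytest.approx(3.30, abs=0.01)

    def test_identity_is_zero(self):
        assert ppm_error(556.2766, 556.2766) == 0.0

    def test_lockmass_print_agrees_with_theory(self):
        theo = ion_mz(Formula.parse("C28H37N5O7"), "[M+H]+")
        assert abs(ppm_error(556.2766, theo)) < 0.1

    def test_nonpositive_theoretical_rejected(self):
        with pytest.raises(ValueError):
            ppm_error(100.0, 0.0)


class TestRdbe:
    @pytest.mark.parametrize(
        "formula, expected",
        [
            ("C18H33NO", 3),  # linoleamide neutral
            ("C18H31NO", 4),  # linolenamide neutral
            ("CH4", 0),
            ("C16H32O2", 1),  # saturated fatty acid
        ],
    )
    def test_examples(self, formula, expected):
        assert rdbe(Formula.parse(formula)) == expected

    @given(n=st.integers(1, 20), k=st.integers(1, 10))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_invariant_under_ch2_homologation(self, n, k):
        """Adding CH2 units never changes RDBE: every saturated
        monocarboxylic homolog CnH2nO2 has RDBE 1."""
        f = Formula(C=n, H=2 * n, O=2)
        g = Formula(C=n + k, H=2 * (n + k), O=2)
        assert rdbe(f) == rdbe(g) == 1


def brute_force_decompose(observed_mz, adduct_name, tol_ppm, bounds):
    """Independent oracle: plain quadruple loop over the CHNO grid."""
    adduct = get_adduct(adduct_name)
    neutral = observed_mz - adduct.mass_delta
    half = neutral * tol_ppm * 1e-6
    hits = set()
    for c in range(bounds["C"] + 1):
        for h in range(bounds["H"] + 1):
            for n in range(bounds["N"] + 1):
                for o in range(bounds["O"] + 1):
                    if c + h + n + o == 0:
                        continue
                    mass = (
                        c * ELEMENT_MASSES["C"]
                        + h * ELEMENT_MASSES["H"]
                        + n * ELEMENT_MASSES["N"]
                        + o * ELEMENT_MASSES["O"]
                    )
                    if abs(mass - neutral) > half:
                        continue
                    dbe = c - h / 2 + n / 2 + 1
                    if dbe < 0 or dbe != int(dbe) or dbe > 12:
                        continue
                    hits.add((c, h, n, o))
    return hits


class TestDecompose:
    @pytest.mark.parametrize(
        "mz, adduct, expected_member",
        [
            (280.2631, "[M+H]+", "C18H33NO"),  # linoleamide ion
            (187.0982, "[M-H]-", "C9H16O4"),  # azelaic acid ion
        ],
    )
    def test_known_compositions_found(self, mz, adduct, expected_member):
        hills = [c.formula.hill() for c in decompose_mass(mz, adduct, 7.0)]
        assert expected_member in hills

    def test_tiny_tolerance_empty(self):
        assert decompose_mass(100.0, "[M+H]+", 0.001) == []

    def test_nonpositive_tolerance_rejected(self):
        with pytest.raises(ValueError):
            decompose_mass(100.0, "[M+H]+", 0.0)

    def test_sorted_by_abs_ppm(self):
        cands = decompose_mass(300.15, "[M-H]-", 50.0)
        errs = [abs(c.ppm_error) for c in cands]
        assert errs == sorted(errs)

    def test_roundtrip_within_tolerance(self):
        for mz in (187.0982, 280.2631, 313.2375):
            for cand in decompose_mass(mz, "[M-H]-", 7.0):
                assert abs(ppm_error(mz, ion_mz(cand.formula, "[M-H]-"))) <= 7.0

    def test_matches_bruteforce_oracle(self):
        """Enumerative search equals an independent quadruple-loop oracle
        on 100 random masses across the screened m/z range."""
        rng = np.random.default_rng(42)
        bounds = {"C": 25, "H": 52, "N": 1, "O": 8}
        for mz in rng.uniform(100.0, 450.0, size=100):
            for adduct in ("[M+H]+", "[M-H]-"):
                ours = {
                    tuple(c.formula.get(e, 0) for e in "CHNO")
                    for c in decompose_mass(mz, adduct, 7.0, bounds=bounds)
                }
                assert ours == brute_force_decompose(mz, adduct, 7.0, bounds)
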