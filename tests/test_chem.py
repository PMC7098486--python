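"""Mass model: exact masses, isotope distributions, averagine, charges."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from ubquant import chem
from ubquant.chem import ElementalComposition

# Independent residue monoisotopic masses (standard literature table) used
# as the oracle for sequence masses; deliberately not derived from the
# package's own element table.
RESIDUE_MASS = {
    "G": 57.02146, "A": 71.03711, "S": 87.03203, "P": 97.05276,
    "V": 99.06841, "T": 101.04768, "C": 103.00919, "L": 113.08406,
    "I": 113.08406, "N": 114.04293, "D": 115.02694, "Q": 128.05858,
    "K": 128.09496, "E": 129.04259, "M": 131.04049, "H": 137.05891,
    "F": 147.06841, "R": 156.10111, "Y": 163.06333, "W": 186.07931,
}
WATER = 18.010565


def test_glygly_remnant_mass():
    """The diGLY remnant (C4H6N2O2) weighs +114.0429 Da."""
    gg = ElementalComposition.from_formula("C4H6N2O2")
    assert chem.monoisotopic_mass(gg) == pytest.approx(114.0429, abs=5e-4)


def test_empty_composition_mass_is_zero():
    assert chem.monoisotopic_mass(ElementalComposition()) == 0.0


def test_unknown_element_raises():
    with pytest.raises(KeyError):
        chem.monoisotopic_mass({"Xx": 1})


def test_ub_dgg_mass_against_residue_table_oracle():
    """Ub residues 1-74 + water summed over an independent residue-mass
    table agrees with the elemental-composition mass; the clipped form also
    equals full-length Ub minus two glycine residues."""
    seq = chem.ub_dgg_sequence()
    assert len(seq) == 74 and seq.endswith("LRLR")
    oracle = sum(RESIDUE_MASS[aa] for aa in seq) + WATER
    assert chem.ub_dgg_composition().monoisotopic_mass == pytest.approx(oracle, abs=0.002)
    full = sum(RESIDUE_MASS[aa] for aa in chem.ubiquitin_sequence()) + WATER
    assert full - 2 * RESIDUE_MASS["G"] == pytest.approx(oracle, abs=1e-9)


def test_proteoform_mass_additivity():
    """Branch and phospho deltas add linearly: n*114.0429 + 79.966."""
    base = chem.UbProteoform(0, False).monoisotopic_mass
    for n in range(4):
        for phospho in (False, True):
            m = chem.UbProteoform(n, phospho).monoisotopic_mass
            expected = base + n * 114.0429 + (79.966 if phospho else 0.0)
            assert m == pytest.approx(expected, abs=1e-3)


def test_branch_count_bounded_by_available_lysines():
    with pytest.raises(ValueError):
        chem.UbProteoform(8, False)
    assert len(chem.UB_BRANCH_LYSINES) == 7


@pytest.mark.parametrize(
    "formula,n_peaks",
    [("C1", 4), ("H2O1", 5), ("C3H5N1O1", 8), ("C4H6N2O2", 8)],
)
def test_isotope_distribution_matches_brute_force(formula, n_peaks):
    """Convolution agrees with direct polynomial expansion for <=30 atoms."""
    from pyteomics.mass import nist_mass

    comp = ElementalComposition.from_formula(formula)
    # brute force: enumerate the full product of per-atom isotope choices
    atoms = []
    for el, n in comp.items():
        isotopes = [
            (m, ab) for k, (m, ab) in nist_mass[el].items() if k != 0 and ab > 0
        ]
        atoms.extend([isotopes] * n)
    mono = sum(min(m for m, _ in a) for a in atoms)
    acc: dict[int, float] = {}
    for combo in itertools.product(*atoms):
        mass = sum(m for m, _ in combo)
        prob = math.prod(ab for _, ab in combo)
        off = int(round(mass - mono))
        acc[off] = acc.get(off, 0.0) + prob
    dist = chem.isotope_distribution(comp, n_peaks)
    for k in range(min(len(dist), max(acc) + 1)):
        assert dist.abundances[k] == pytest.approx(acc.get(k, 0.0), abs=1e-9)


def test_carbon_isotope_abundances():
    dist = chem.isotope_distribution(ElementalComposition({"C": 1}), 2)
    assert dist.abundances == pytest.approx([0.9893, 0.0107], abs=1e-6)


def test_water_is_dominated_by_monoisotopic_peak():
    dist = chem.isotope_distribution(ElementalComposition.from_formula("H2O1"), 5)
    assert dist.abundances[0] > 0.99


def test_fixed_isotope_labels_shift_mass_without_spread():
    """A 13C4/15N TMT-style label adds pure mass, no extra envelope."""
    plain = chem.isotope_distribution(ElementalComposition.from_formula("C8H20N1O2"), 10)
    labeled = chem.isotope_distribution(
        ElementalComposition.from_formula("C8H20N1O2C[13]4N[15]1"), 10
    )
    shift = 4 * 13.0033548378 + 15.0001088982
    assert labeled.abundances == pytest.approx(plain.abundances, abs=1e-12)
    assert labeled.masses[0] - plain.masses[0] == pytest.approx(shift, abs=1e-4)


@given(
    counts=st.fixed_dictionaries(
        {},
        optional={
            "C": st.integers(0, 50), "H": st.integers(0, 80),
            "N": st.integers(0, 20), "O": st.integers(0, 20),
            "S": st.integers(0, 3),
        },
    )
)
def test_distribution_normalization_property(counts):
    comp = ElementalComposition({k: v for k, v in counts.items() if v})
    dist = chem.isotope_distribution(comp, 12)
    assert abs(dist.abundances.sum() - 1.0) < 1e-9
    if len(dist) > 1:
        # spacings are integer multiples of ~1.0033 Da (zero-abundance
        # isotopologues, e.g. sulfur's offset 3, are dropped)
        spacing = np.diff(dist.masses)
        multiples = np.round(spacing / 1.0033)
        assert np.all(multiples >= 1)
        assert np.allclose(spacing, multiples * 1.0033, atol=0.05)


@given(
    a=st.dictionaries(st.sampled_from(["C", "H", "N", "O"]), st.integers(0, 30)),
    b=st.dictionaries(st.sampled_from(["C", "H", "N", "O"]), st.integers(0, 30)),
)
def test_composition_arithmetic_never_negative(a, b):
    ca, cb = ElementalComposition(a), ElementalComposition(b)
    total = ca + cb
    assert all(v > 0 for v in total.values())
    assert (total - cb) == ca
    with pytest.raises(ValueError):
        ca - (ca + ElementalComposition({"C": 1}))


def test_averagine_unit_round_trip():
    """Scaling averagine to its own unit mass returns one unit."""
    comp = chem.averagine_composition(111.1254, sulfur_free=False)
    assert comp["C"] == 5 and comp["N"] == 1 and comp["O"] == 1
    assert comp.get("S", 0) == 0  # 0.0417 rounds to zero at one unit


def test_averagine_hits_target_mass_within_half_dalton():
    for target in (1000.0, 8400.0, chem.ub_dgg_composition().monoisotopic_mass):
        comp = chem.averagine_composition(target, sulfur_free=True)
        assert comp.get("S", 0) == 0
        assert abs(comp.monoisotopic_mass - target) < 0.5


def test_averagine_envelope_matches_exact_ub_composition():
    """Cosine similarity > 0.99 between averagine and exact Ub envelopes."""
    exact = chem.isotope_distribution(chem.ub_dgg_composition(), 40)
    approx = chem.averagine_distribution(
        chem.ub_dgg_composition().monoisotopic_mass, sulfur_free=True, n_peaks=40
    )
    n = min(len(exact), len(approx))
    a, b = exact.abundances[:n], approx.abundances[:n]
    cosine = np.dot(a, b) / (np.linalg.norm(a) * np.linalg.norm(b))
    assert cosine > 0.99


def test_mz_for_charge_and_inverse():
    m = 8445.5738
    assert chem.mz_for_charge(m, 1) == pytest.approx(m + 1.00728, abs=1e-5)
    for z in range(1, 18):
        assert chem.neutral_mass(chem.mz_for_charge(m, z), z) == pytest.approx(m, abs=1e-6)


def test_ub_dgg_charge_states_span_acquisition_window():
    """z = 10..13 of Ub^dGG fall inside the 625-925 m/z window."""
    m = chem.ub_dgg_composition().monoisotopic_mass
    for z in range(10, 14):
        assert 625.0 <= chem.mz_for_charge(m, z) <= 925.0
    assert chem.mz_for_charge(m, 9) > 925.0
    assert chem.mz_for_charge(m, 14) < 625.0


@pytest.mark.parametrize(
    "confidence,expected",
    [(0.95, 13), (0.9, 10), (0.999, 30)],
)
def test_ascore_threshold(confidence, expected):
    assert round(chem.ascore_threshold(confidence)) == expected


def test_modification_table_printed_deltas_match_compositions():
    mods = chem.load_modifications()
    printed = {
        "TMT": 229.163, "Carbamidomethyl": 57.021, "Oxidation": 15.995,
        "Phospho": 79.966, "Deamidation": 0.984, "GlyGly": 114.0429,
    }
    for name, delta in printed.items():
        assert mods[name].delta_mass == delta
        assert mods[name].exact_mass == pytest.approx(delta, abs=1e-3)
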