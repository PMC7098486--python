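"""Exact-mass and isotope-distribution models for Ub proteoforms and peptide mods.

This module is the numerical foundation of the package: elemental
compositions with monoisotopic masses from the IUPAC/NIST table shipped with
:mod:`pyteomics`, aggregated isotope distributions computed by per-element
convolution, the averagine model used for deisotoping, and the Ub^dGG
proteoform algebra (ubiquitin clipped after R74, carrying 0-3 diGLY branches
and an optional Ser65 phosphate).

Conventions: residue numbering is 1-based (K6...K63, S65); the proton mass
is 1.007276 Da; printed modification deltas (e.g. +114.0429 for the GlyGly
remnant) are kept for reporting while full-precision elemental masses are
used internally.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources

import numpy as np
import pandas as pd
from Bio import SeqIO
from pyteomics import mass as _pt_mass

__all__ = [
    "PROTON_MASS",
    "ISOTOPE_SPACING",
    "ElementalComposition",
    "ModificationSpec",
    "UbProteoform",
    "IsotopeDistribution",
    "monoisotopic_mass",
    "isotope_distribution",
    "averagine_composition",
    "mz_for_charge",
    "neutral_mass",
    "ascore_threshold",
    "ubiquitin_sequence",
    "ub_dgg_sequence",
    "ub_dgg_composition",
    "ub_dgg_candidates",
    "load_modifications",
]

PROTON_MASS = 1.007276466
#: nominal spacing between adjacent isotopologues (13C - 12C), Da
ISOTOPE_SPACING = 1.0033548378

_ISOTOPE_RE = re.compile(r"^([A-Z][a-z]?)(?:\[(\d+)\])?$")
_FORMULA_RE = re.compile(r"([A-Z][a-z]?)(?:\[(\d+)\])?(-?\d*)")

# Senko averagine model unit (average amino acid), average mass 111.1254 Da
_AVERAGINE_UNIT = {"C": 4.9384, "H": 7.7583, "N": 1.3577, "O": 1.4773, "S": 0.0417}
_AVERAGINE_AVG_MASS = 111.1254


def _isotope_table(element: str):
    """pyteomics nist_mass entry for an element; KeyError on unknown symbol."""
    if element not in _pt_mass.nist_mass:
        raise KeyError(f"unknown element symbol: {element!r}")
    return _pt_mass.nist_mass[element]


def _key_mass(key: str) -> float:
    """Monoisotopic mass for a composition key ('C' or a fixed isotope 'C[13]')."""
    m = _ISOTOPE_RE.match(key)
    if m is None:
        raise KeyError(f"invalid element key: {key!r}")
    element, iso = m.group(1), m.group(2)
    table = _isotope_table(element)
    if iso is None:
        return table[0][0]
    iso = int(iso)
    if iso not in table or table[iso][0] == 0.0:
        raise KeyError(f"unknown isotope: {key!r}")
    return table[iso][0]


class ElementalComposition(dict):
    """Element/isotope-label -> non-negative integer count.

    Keys are element symbols (``"C"``) or fixed isotope labels (``"C[13]"``,
    ``"N[15]"``).  Addition and subtraction are element-wise; subtraction
    below zero raises, matching the invariant that counts never go negative.
    """

    def __init__(self, counts=None, **kwargs):
        super().__init__()
        merged = dict(counts or {})
        merged.update(kwargs)
        for key, n in merged.items():
            self[key] = n

    def __setitem__(self, key, n):
        if _ISOTOPE_RE.match(key) is None:
            raise KeyError(f"invalid element key: {key!r}")
        n = int(n)
        if n < 0:
            raise ValueError(f"negative count for {key}: {n}")
        if n == 0:
            super().pop(key, None)
        else:
            super().__setitem__(key, n)

    @classmethod
    def from_formula(cls, formula: str) -> "ElementalComposition":
        """Parse a chemical formula like ``C4H6N2O2`` or ``C8H20N1O2C[13]4``.

        A signed count (``H-1``) is accepted only transiently inside
        :class:`ModificationSpec` deltas; net-negative totals raise.
        """
        counts: dict[str, int] = {}
        pos = 0
        for m in _FORMULA_RE.finditer(formula):
            if m.start() != pos or not m.group(0):
                break
            key = m.group(1) + (f"[{m.group(2)}]" if m.group(2) else "")
            n = int(m.group(3)) if m.group(3) else 1
            counts[key] = counts.get(key, 0) + n
            pos = m.end()
        if pos != len(formula):
            raise ValueError(f"cannot parse formula: {formula!r}")
        return cls(counts)

    def __add__(self, other):
        out = dict(self)
        for k, v in other.items():
            out[k] = out.get(k, 0) + v
        return ElementalComposition(out)

    def __sub__(self, other):
        out = dict(self)
        for k, v in other.items():
            out[k] = out.get(k, 0) - v  # __setitem__ rejects negatives
        return ElementalComposition(out)

    def __mul__(self, n: int):
        return ElementalComposition({k: v * n for k, v in self.items()})

    __rmul__ = __mul__

    @property
    def monoisotopic_mass(self) -> float:
        return monoisotopic_mass(self)


def monoisotopic_mass(composition) -> float:
    """Monoisotopic mass (Da) of a composition from the IUPAC/NIST table.

    Unknown element symbols raise ``KeyError``.  An empty composition has
    mass exactly 0.
    """
    return sum(_key_mass(k) * n for k, n in composition.items())


@dataclass(frozen=True)
class IsotopeDistribution:
    """Aggregated isotope distribution: per-isotopologue centroid masses and
    relative abundances (normalized to sum 1), spaced ~1.0033 Da apart."""

    masses: np.ndarray
    abundances: np.ndarray

    def __post_init__(self):
        masses = np.asarray(self.masses, dtype=float)
        ab = np.asarray(self.abundances, dtype=float)
        if masses.shape != ab.shape or masses.ndim != 1:
            raise ValueError("masses and abundances must be equal-length 1-d arrays")
        if np.any(ab < 0):
            raise ValueError("abundances must be non-negative")
        if abs(ab.sum() - 1.0) > 1e-9:
            raise ValueError("abundances must sum to 1")
        if masses.size > 1 and np.any(np.diff(masses) <= 0):
            raise ValueError("masses must be strictly increasing")
        object.__setattr__(self, "masses", masses)
        object.__setattr__(self, "abundances", ab)

    def __len__(self):
        return self.masses.size

    @property
    def most_abundant_index(self) -> int:
        return int(np.argmax(self.abundances))


def _element_base(element: str, n_peaks: int):
    """(abundance, mass) arrays over nominal isotopologue offsets for one atom."""
    table = _isotope_table(element)
    isos = [(m, ab) for k, (m, ab) in table.items() if k != 0 and ab > 0]
    isos.sort()
    mono = isos[0][0]
    size = max(int(round(m - mono)) for m, _ in isos) + 1
    a = np.zeros(size)
    w = np.zeros(size)  # abundance-weighted mass
    for m, ab in isos:
        k = int(round(m - mono))
        a[k] += ab
        w[k] += ab * m
    return a[:n_peaks], w[:n_peaks]


def _convolve_tracked(a1, w1, a2, w2, n_peaks):
    """Convolve two (abundance, weighted-mass) pairs, truncated to n_peaks.

    w arrays carry sum(abundance * mass); the mean mass of a combined peak k
    is recovered as the abundance-weighted sum of component mean masses.
    """
    a = np.convolve(a1, a2)[:n_peaks]
    m1 = np.divide(w1, a1, out=np.zeros_like(w1), where=a1 > 0)
    m2 = np.divide(w2, a2, out=np.zeros_like(w2), where=a2 > 0)
    w = (np.convolve(a1 * m1, a2)[:n_peaks] + np.convolve(a1, a2 * m2)[:n_peaks])
    return a, w


def _element_power(element: str, n: int, n_peaks: int):
    """(abundance, weighted-mass) for n atoms of one element, by squaring."""
    base_a, base_w = _element_base(element, n_peaks)
    result_a, result_w = np.array([1.0]), np.array([0.0])
    while n:
        if n & 1:
            result_a, result_w = _convolve_tracked(result_a, result_w, base_a, base_w, n_peaks)
        n >>= 1
        if n:
            base_a, base_w = _convolve_tracked(base_a, base_w, base_a, base_w, n_peaks)
    return result_a, result_w


def isotope_distribution(composition, n_peaks: int = 40) -> IsotopeDistribution:
    """First ``n_peaks`` aggregated isotopologues of a composition.

    Per-element multinomial distributions are convolved exactly (truncated at
    ``n_peaks``); abundances are renormalized to sum 1 and each peak carries
    its abundance-weighted centroid mass.
    """
    if n_peaks < 1:
        raise ValueError("n_peaks must be >= 1")
    a, w = np.array([1.0]), np.array([0.0])
    fixed_mass = 0.0
    for key, n in composition.items():
        m = _ISOTOPE_RE.match(key)
        if m is None:
            raise KeyError(f"invalid element key: {key!r}")
        if m.group(2) is not None:  # fixed isotope label: pure mass shift
            fixed_mass += _key_mass(key) * n
            continue
        ea, ew = _element_power(m.group(1), n, n_peaks)
        a, w = _convolve_tracked(a, w, ea, ew, n_peaks)
    keep = a > 0
    a, w = a[keep], w[keep]
    masses = w / a + fixed_mass
    total = a.sum()
    return IsotopeDistribution(masses=masses, abundances=a / total)


def averagine_composition(target_mass: float, sulfur_free: bool = True) -> ElementalComposition:
    """Averagine composition scaled to ``target_mass`` (monoisotopic, Da).

    The Senko average-amino-acid unit is scaled to the target, heavy-element
    counts are rounded, sulfur is dropped when ``sulfur_free`` (the vendor
    deisotoping setting used for Ub work), and hydrogens are adjusted so the
    monoisotopic mass lands within half a hydrogen (<0.5 Da) of the target.
    """
    if target_mass <= 0:
        raise ValueError("target_mass must be positive")
    scale = target_mass / _AVERAGINE_AVG_MASS
    counts = {}
    for el in ("C", "N", "O", "S"):
        if sulfur_free and el == "S":
            continue
        n = int(round(_AVERAGINE_UNIT[el] * scale))
        if n > 0:
            counts[el] = n
    heavy = sum(_key_mass(el) * n for el, n in counts.items())
    h_mass = _key_mass("H")
    counts["H"] = max(0, int(round((target_mass - heavy) / h_mass)))
    return ElementalComposition(counts)


@lru_cache(maxsize=4096)
def _averagine_distribution_cached(mass_key: int, sulfur_free: bool, n_peaks: int):
    return isotope_distribution(
        averagine_composition(float(mass_key), sulfur_free=sulfur_free), n_peaks
    )


def averagine_distribution(target_mass: float, sulfur_free: bool = True,
                           n_peaks: int = 40) -> IsotopeDistribution:
    """Cached averagine isotope distribution; the envelope varies slowly with
    mass so the target is quantized to 1 Da for caching."""
    return _averagine_distribution_cached(int(round(target_mass)), sulfur_free, n_peaks)


def mz_for_charge(neutral_mass_da: float, z: int) -> float:
    """m/z of the [M + zH]^z+ ion."""
    if z < 1:
        raise ValueError("charge must be >= 1")
    return (neutral_mass_da + z * PROTON_MASS) / z


def neutral_mass(mz: float, z: int) -> float:
    """Neutral mass recovered from an (m/z, z) pair; inverse of mz_for_charge."""
    if z < 1:
        raise ValueError("charge must be >= 1")
    return mz * z - z * PROTON_MASS


def ascore_threshold(confidence: float) -> float:
    """Localization score equivalent to a site-confidence level.

    ``-10*log10(1 - confidence)``; 0.95 -> 13 at the nearest integer, the
    conventional cutoff for a confidently localized site.
    """
    if not 0.0 < confidence < 1.0:
        raise ValueError("confidence must be in (0, 1)")
    return -10.0 * math.log10(1.0 - confidence)


@dataclass(frozen=True)
class ModificationSpec:
    """A named post-translational modification.

    ``delta_mass`` is the printed (reporting) delta; when an elemental
    composition is given its monoisotopic mass must agree within 0.001 Da and
    is what downstream exact-mass arithmetic uses.
    """

    name: str
    delta_mass: float
    composition: ElementalComposition | None = None
    residues: tuple[str, ...] = ()

    def __post_init__(self):
        if self.composition is not None:
            exact = monoisotopic_mass(self.composition)
            if abs(exact - self.delta_mass) > 0.001:
                raise ValueError(
                    f"{self.name}: composition mass {exact:.5f} does not match "
                    f"printed delta {self.delta_mass:.5f} within 0.001 Da"
                )

    @property
    def exact_mass(self) -> float:
        """Full-precision delta (composition mass when available)."""
        if self.composition is not None:
            return monoisotopic_mass(self.composition)
        return self.delta_mass


def load_modifications() -> dict[str, ModificationSpec]:
    """Modification table shipped with the package (TSV: name, delta,
    composition, residue rule)."""
    with resources.files("ubquant.data").joinpath("modifications.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t")
    specs = {}
    for row in df.itertuples(index=False):
        # signed counts (H-1N-1O1 for deamidation) are handled by summing
        # positive and negative parts separately
        comp = _parse_signed_formula(row.composition)
        specs[row.name] = ModificationSpec(
            name=row.name,
            delta_mass=float(row.delta_mass),
            composition=comp,
            residues=tuple(str(row.residues).split(",")),
        )
    return specs


def _parse_signed_formula(formula: str) -> ElementalComposition | None:
    """Formula parser tolerating negative counts by tracking a net dict, used
    for loss-containing deltas like deamidation (H-1 N-1 O1)."""
    counts: dict[str, int] = {}
    pos = 0
    for m in _FORMULA_RE.finditer(formula):
        if m.start() != pos or not m.group(0):
            break
        key = m.group(1) + (f"[{m.group(2)}]" if m.group(2) else "")
        n = int(m.group(3)) if m.group(3) else 1
        counts[key] = counts.get(key, 0) + n
        pos = m.end()
    if pos != len(formula):
        raise ValueError(f"cannot parse formula: {formula!r}")
    if any(v < 0 for v in counts.values()):
        # net-loss deltas cannot be a standalone ElementalComposition; keep
        # them as a pseudo-composition via a plain dict wrapper
        return _SignedComposition(counts)
    return ElementalComposition(counts)


class _SignedComposition(dict):
    """Composition delta that may remove atoms (e.g. deamidation)."""

    @property
    def monoisotopic_mass(self) -> float:
        return sum(_key_mass(k) * n for k, n in self.items())

    def items(self):
        return super().items()


# make monoisotopic_mass() accept _SignedComposition transparently
# (sum over signed counts works unchanged)


@lru_cache(maxsize=1)
def ubiquitin_sequence() -> str:
    """Human ubiquitin monomer sequence (UniProt P0CG48, 76 aa) from the
    bundled FASTA."""
    path = resources.files("ubquant.data").joinpath("ubiquitin_P0CG48.fasta")
    with path.open() as fh:
        record = next(SeqIO.parse(fh, "fasta"))
    return str(record.seq)


def ub_dgg_sequence() -> str:
    """Ub^dGG: residues 1-74 (LbPro* cleaves after R74, removing Gly75-Gly76)."""
    return ubiquitin_sequence()[:74]


@lru_cache(maxsize=1)
def ub_dgg_composition() -> ElementalComposition:
    """Elemental composition of the Ub^dGG monomer (residues 1-74 + water)."""
    comp = _pt_mass.Composition(sequence=ub_dgg_sequence())
    return ElementalComposition({k: int(v) for k, v in comp.items()})


_GLYGLY = ElementalComposition.from_formula("C4H6N2O2")
_PHOSPHO = ElementalComposition.from_formula("H1P1O3")

#: printed deltas used for reporting
GLYGLY_DELTA_PRINTED = 114.0429
PHOSPHO_DELTA_PRINTED = 79.966

#: lysines available for diGLY branches on Ub (1-based)
UB_BRANCH_LYSINES = (6, 11, 27, 29, 33, 48, 63)


@dataclass(frozen=True, order=True)
class UbProteoform:
    """A Ub^dGG species identified by diGLY-branch count and pS65 state.

    Intact mass cannot resolve which lysines carry the branches, so identity
    is (branch count, phospho) only; the quantified range is 0-3 branches
    although up to 7 lysines exist.
    """

    n_digly_branches: int = 0
    phosphorylated: bool = False

    def __post_init__(self):
        if not 0 <= self.n_digly_branches <= len(UB_BRANCH_LYSINES):
            raise ValueError(
                f"branch count must be within 0..{len(UB_BRANCH_LYSINES)}"
            )

    @property
    def composition(self) -> ElementalComposition:
        comp = ub_dgg_composition() + self.n_digly_branches * _GLYGLY
        if self.phosphorylated:
            comp = comp + _PHOSPHO
        return comp

    @property
    def monoisotopic_mass(self) -> float:
        return monoisotopic_mass(self.composition)

    @property
    def label(self) -> str:
        p = "p" if self.phosphorylated else ""
        return f"{p}Ub-dGG+{self.n_digly_branches}GG"

    def isotope_distribution(self, n_peaks: int = 40) -> IsotopeDistribution:
        return isotope_distribution(self.composition, n_peaks)


def ub_dgg_candidates(max_branches: int = 3) -> list[UbProteoform]:
    """The enumerated candidate list for targeted quantification:
    0..max_branches diGLY branches, with and without pS65 (8 species)."""
    return [
        UbProteoform(n_digly_branches=n, phosphorylated=p)
        for p in (False, True)
        for n in range(max_branches + 1)
    ]
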