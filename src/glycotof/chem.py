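"""Glycan composition algebra for linkage-derivatized N-glycomics.

Compositions are counted in released-glycan building blocks: hexose (H),
N-acetylhexosamine (N), deoxyhexose/fucose (F), and the four
linkage-derivatized sialic acid species produced by ethyl
esterification chemistry:

* ``E``  — alpha2-6-linked NeuAc, carrying an ethyl ester (+C2H4),
* ``L``  — alpha2-3/8-linked NeuAc, converted to a lactone (-H2O),
* ``Ge`` — alpha2-6-linked NeuGc, ethyl-esterified,
* ``Gl`` — alpha2-3/8-linked NeuGc, lactonized,

plus a bulk count ``Ac`` of O-acetyl groups residing on sialic acids
(+C2H2O each).  All masses are derived from atomic monoisotopic masses
so that every reported m/z is a computed quantity, not a stored one.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable

import yaml

__all__ = [
    "GlycanComposition",
    "ElementCounts",
    "ChemistryConstants",
    "DEFAULT_CONSTANTS",
    "parse_composition",
    "monoisotopic_mz",
    "elemental_formula",
    "isotope_pattern",
    "isotope_envelope",
    "classify",
    "neutral_loss_mass",
    "GlycanClassificationError",
    "CompositionParseError",
]


# ---------------------------------------------------------------------------
# atomic data (CODATA/IUPAC monoisotopic masses and isotopic abundances)
# ---------------------------------------------------------------------------

#: per element: list of (isotope mass in Da, natural abundance), the first
#: entry is the lightest (principal) isotope.
ISOTOPES: dict[str, list[tuple[float, float]]] = {
    "C": [(12.0, 0.9893), (13.003354835, 0.0107)],
    "H": [(1.00782503207, 0.999885), (2.01410177785, 0.000115)],
    "N": [(14.0030740048, 0.99636), (15.0001088982, 0.00364)],
    "O": [(15.9949146196, 0.99757), (16.9991317012, 0.00038), (17.9991610441, 0.00205)],
}

MASS_NA = 22.9897692809
MASS_ELECTRON = 0.00054857990907
MASS_PROTON = 1.00727646688


class CompositionParseError(ValueError):
    """Raised when a composition string does not follow the letter-count grammar."""


class GlycanClassificationError(ValueError):
    """Raised when a composition cannot be assigned to an N-glycan class."""


@dataclass(frozen=True)
class ElementCounts:
    """Elemental formula restricted to C, H, N, O (sufficient for glycans)."""

    C: int = 0
    H: int = 0
    N: int = 0
    O: int = 0

    def __post_init__(self) -> None:
        for el in ("C", "H", "N", "O"):
            v = getattr(self, el)
            if not isinstance(v, int) or v < 0:
                raise ValueError(f"element count {el}={v!r} must be a non-negative integer")

    def __add__(self, other: "ElementCounts") -> "ElementCounts":
        return ElementCounts(self.C + other.C, self.H + other.H, self.N + other.N, self.O + other.O)

    def __mul__(self, k: int) -> "ElementCounts":
        return ElementCounts(self.C * k, self.H * k, self.N * k, self.O * k)

    __rmul__ = __mul__

    def __sub__(self, other: "ElementCounts") -> "ElementCounts":
        return ElementCounts(self.C - other.C, self.H - other.H, self.N - other.N, self.O - other.O)

    @property
    def n_atoms(self) -> int:
        return self.C + self.H + self.N + self.O

    def monoisotopic_mass(self) -> float:
        return sum(getattr(self, el) * ISOTOPES[el][0][0] for el in ("C", "H", "N", "O"))

    def hill_formula(self) -> str:
        parts = []
        for el in ("C", "H", "N", "O"):
            v = getattr(self, el)
            if v == 1:
                parts.append(el)
            elif v > 1:
                parts.append(f"{el}{v}")
        return "".join(parts)


# residue formulas (the mass added when the residue is glycosidically linked)
RESIDUE_FORMULAS: dict[str, ElementCounts] = {
    "Hex": ElementCounts(C=6, H=10, O=5),
    "HexNAc": ElementCounts(C=8, H=13, N=1, O=5),
    "dHex": ElementCounts(C=6, H=10, O=4),
    "NeuAc": ElementCounts(C=11, H=17, N=1, O=8),
    "NeuGc": ElementCounts(C=11, H=17, N=1, O=9),
}

# derivatization deltas as formula differences
MOD_FORMULAS: dict[str, tuple[ElementCounts, ElementCounts]] = {
    # name -> (added, removed)
    "ethyl_ester": (ElementCounts(C=2, H=4), ElementCounts()),
    "lactone": (ElementCounts(), ElementCounts(H=2, O=1)),
    "o_acetyl": (ElementCounts(C=2, H=2, O=1), ElementCounts()),
}

WATER = ElementCounts(H=2, O=1)


def _formula_mass(f: ElementCounts) -> float:
    return f.monoisotopic_mass()


@dataclass(frozen=True)
class ChemistryConstants:
    """Monoisotopic residue/modification masses (Da), derived from formulas.

    The defaults are computed from atomic masses; a YAML file with any of
    the documented keys (``hex``, ``hexnac``, ``dhex``, ``neuac``,
    ``neugc``, ``ethyl_ester``, ``lactone``, ``o_acetyl``, ``water``,
    ``sodium``) can override individual values, e.g. to emulate a
    different derivatization chemistry.
    """

    hex: float = _formula_mass(RESIDUE_FORMULAS["Hex"])
    hexnac: float = _formula_mass(RESIDUE_FORMULAS["HexNAc"])
    dhex: float = _formula_mass(RESIDUE_FORMULAS["dHex"])
    neuac: float = _formula_mass(RESIDUE_FORMULAS["NeuAc"])
    neugc: float = _formula_mass(RESIDUE_FORMULAS["NeuGc"])
    ethyl_ester: float = _formula_mass(MOD_FORMULAS["ethyl_ester"][0])
    lactone: float = -_formula_mass(MOD_FORMULAS["lactone"][1])
    o_acetyl: float = _formula_mass(MOD_FORMULAS["o_acetyl"][0])
    water: float = _formula_mass(WATER)
    sodium: float = MASS_NA - MASS_ELECTRON  # [M+Na]+ cation contribution

    def __post_init__(self) -> None:
        if self.ethyl_ester <= 0:
            raise ValueError("ethyl ester delta must be positive")
        if self.lactone >= 0:
            raise ValueError("lactone delta must be negative (loss of water)")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ChemistryConstants":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise KeyError(f"unknown chemistry constant keys: {sorted(unknown)}")
        return replace(cls(), **{k: float(v) for k, v in data.items()})


DEFAULT_CONSTANTS = ChemistryConstants()

_MONOSACCHARIDE_LETTERS = ("H", "N", "F", "E", "L", "Ge", "Gl", "Ac")


@dataclass(frozen=True, order=True)
class GlycanComposition:
    """Counts of monosaccharides/modifications of one derivatized glycan.

    Attribute letters follow the field convention: H hexose, N HexNAc,
    F fucose, E/L ethyl-esterified (a2-6) / lactonized (a2-3/8) NeuAc,
    Ge/Gl the NeuGc analogues, Ac O-acetyl groups on sialic acids.
    """

    H: int = 0
    N: int = 0
    F: int = 0
    E: int = 0
    L: int = 0
    Ge: int = 0
    Gl: int = 0
    Ac: int = 0

    def __post_init__(self) -> None:
        for letter in _MONOSACCHARIDE_LETTERS:
            v = getattr(self, letter)
            if not isinstance(v, int) or isinstance(v, bool) or v < 0:
                raise ValueError(f"count {letter}={v!r} must be a non-negative integer")
        if self.Ac > 2 * self.sialic_total:
            raise ValueError(
                f"Ac={self.Ac} exceeds 2 x sialic acids ({self.sialic_total}); "
                "O-acetyl groups reside on sialic acids"
            )

    @property
    def sialic_total(self) -> int:
        return self.E + self.L + self.Ge + self.Gl

    @property
    def name(self) -> str:
        """Canonical string, zero-count letters omitted (e.g. ``H5N4Ge2``)."""
        return "".join(
            f"{letter}{getattr(self, letter)}"
            for letter in _MONOSACCHARIDE_LETTERS
            if getattr(self, letter) > 0
        )

    def __str__(self) -> str:
        return self.name

    def combine(self, other: "GlycanComposition") -> "GlycanComposition":
        """Concatenate two compositions (residue counts add)."""
        return GlycanComposition(
            **{l: getattr(self, l) + getattr(other, l) for l in _MONOSACCHARIDE_LETTERS}
        )


_TOKEN_RE = re.compile(r"(Ge|Gl|Ac|[HNFEL])(\d+)")


def parse_composition(name: str) -> GlycanComposition:
    """Parse a canonical composition string like ``"H5N4F1Ge1Gl1"``.

    The empty string parses to the all-zero composition.  Each letter may
    appear at most once and must be followed by a positive integer count.
    """
    counts: dict[str, int] = {}
    pos = 0
    for m in _TOKEN_RE.finditer(name):
        if m.start() != pos:
            raise CompositionParseError(
                f"unrecognized token {name[pos:m.start()]!r} in composition {name!r}"
            )
        letter, num = m.group(1), int(m.group(2))
        if letter in counts:
            raise CompositionParseError(f"letter {letter!r} repeated in composition {name!r}")
        if num == 0:
            raise CompositionParseError(
                f"zero count for {letter!r} in {name!r}; omit zero-count letters"
            )
        counts[letter] = num
        pos = m.end()
    if pos != len(name):
        raise CompositionParseError(f"unrecognized token {name[pos:]!r} in composition {name!r}")
    return GlycanComposition(**counts)


def elemental_formula(comp: GlycanComposition) -> ElementCounts:
    """Elemental composition of the free reducing-end (derivatized) glycan."""
    f = WATER  # terminal water of the free reducing end
    f = f + RESIDUE_FORMULAS["Hex"] * comp.H
    f = f + RESIDUE_FORMULAS["HexNAc"] * comp.N
    f = f + RESIDUE_FORMULAS["dHex"] * comp.F
    f = f + (RESIDUE_FORMULAS["NeuAc"] + MOD_FORMULAS["ethyl_ester"][0]) * comp.E
    f = f + (RESIDUE_FORMULAS["NeuAc"] - MOD_FORMULAS["lactone"][1]) * comp.L
    f = f + (RESIDUE_FORMULAS["NeuGc"] + MOD_FORMULAS["ethyl_ester"][0]) * comp.Ge
    f = f + (RESIDUE_FORMULAS["NeuGc"] - MOD_FORMULAS["lactone"][1]) * comp.Gl
    f = f + MOD_FORMULAS["o_acetyl"][0] * comp.Ac
    return f


def monoisotopic_mz(
    comp: GlycanComposition,
    adduct: str | None = "Na",
    constants: ChemistryConstants = DEFAULT_CONSTANTS,
) -> float:
    """Monoisotopic m/z (singly charged) of a derivatized composition.

    ``adduct`` is ``"Na"`` ([M+Na]+, the dominant species for neutral
    esterified glycans in positive-mode MALDI), ``"H"`` ([M+H]+) or
    ``"none"``/``None`` for the neutral monoisotopic mass.
    """
    c = constants
    mass = (
        c.water
        + comp.H * c.hex
        + comp.N * c.hexnac
        + comp.F * c.dhex
        + comp.E * (c.neuac + c.ethyl_ester)
        + comp.L * (c.neuac + c.lactone)
        + comp.Ge * (c.neugc + c.ethyl_ester)
        + comp.Gl * (c.neugc + c.lactone)
        + comp.Ac * c.o_acetyl
    )
    if adduct in (None, "none"):
        return mass
    if adduct == "Na":
        return mass + c.sodium
    if adduct == "H":
        return mass + MASS_PROTON
    raise ValueError(f"unknown adduct {adduct!r}; expected 'Na', 'H' or 'none'")


# ---------------------------------------------------------------------------
# isotope patterns
# ---------------------------------------------------------------------------

def _single_element_distribution(el: str, n: int) -> tuple[list[float], list[float]]:
    """Aggregated isotopologue distribution of ``n`` atoms of one element.

    Returns (prob, mass) arrays indexed by nominal mass shift, where
    ``mass[k]`` is the abundance-weighted mean mass of all isotopologues
    with total shift ``k``.  Built by repeated convolution of the
    single-atom distribution.
    """
    isotopes = ISOTOPES[el]
    base = isotopes[0][0]
    # single-atom distribution indexed by nominal shift
    shifts = [round(m - base) for m, _ in isotopes]
    size1 = max(shifts) + 1
    p1 = [0.0] * size1
    s1 = [0.0] * size1  # probability-weighted mass
    for (m, a), k in zip(isotopes, shifts):
        p1[k] += a
        s1[k] += a * m
    prob = [1.0]
    massw = [0.0]  # probability-weighted total mass
    for _ in range(n):
        new_p = [0.0] * (len(prob) + size1 - 1)
        new_s = [0.0] * (len(prob) + size1 - 1)
        for i, (pi, si) in enumerate(zip(prob, massw)):
            if pi == 0.0:
                continue
            for k in range(size1):
                new_p[i + k] += pi * p1[k]
                new_s[i + k] += pi * s1[k] + si * p1[k]
        prob, massw = new_p, new_s
        # drop negligible tail to keep arrays short
        while len(prob) > 1 and prob[-1] < 1e-18:
            prob.pop()
            massw.pop()
    return prob, massw


def _convolve(a: tuple[list[float], list[float]], b: tuple[list[float], list[float]]):
    pa, sa = a
    pb, sb = b
    n = len(pa) + len(pb) - 1
    p = [0.0] * n
    s = [0.0] * n
    for i, (pi, si) in enumerate(zip(pa, sa)):
        if pi == 0.0:
            continue
        for j, (pj, sj) in enumerate(zip(pb, sb)):
            p[i + j] += pi * pj
            s[i + j] += pi * sj + si * pj
    while len(p) > 1 and p[-1] < 1e-18:
        p.pop()
        s.pop()
    return p, s


from functools import lru_cache


@lru_cache(maxsize=4096)
def isotope_envelope(
    formula: ElementCounts, coverage: float = 0.95
) -> tuple[tuple[float, ...], tuple[float, ...], float]:
    """Aggregated isotopologue envelope of an elemental formula.

    Returns ``(mass_offsets, abundances, covered)`` where the offsets are
    relative to the monoisotopic species, the abundances are *raw*
    (fractions of the full distribution) and ``covered`` is their sum —
    the smallest prefix of isotopologues, in nominal-mass order, whose
    cumulative abundance reaches ``coverage``.
    """
    if not 0.0 < coverage <= 1.0:
        raise ValueError(f"coverage must be in (0, 1], got {coverage}")
    if formula.n_atoms == 0:
        raise ValueError("cannot compute an isotope pattern for an empty formula")
    dist = None
    for el in ("C", "H", "N", "O"):
        n = getattr(formula, el)
        if n == 0:
            continue
        d = _single_element_distribution(el, n)
        dist = d if dist is None else _convolve(dist, d)
    prob, massw = dist
    mono = formula.monoisotopic_mass()
    offsets: list[float] = []
    abunds: list[float] = []
    cum = 0.0
    for k, (p, s) in enumerate(zip(prob, massw)):
        if p <= 0.0:
            continue
        offsets.append(s / p - mono)
        abunds.append(p)
        cum += p
        if cum >= coverage - 1e-12:
            break
    return tuple(offsets), tuple(abunds), cum


def isotope_pattern(
    formula: ElementCounts, coverage: float = 0.95
) -> list[tuple[float, float]]:
    """Isotopologue pattern as (mass offset, relative abundance) pairs.

    Abundances are renormalized to sum to 1 over the returned peaks; the
    peaks are the minimal nominal-mass prefix covering ``coverage`` of the
    full distribution.
    """
    offsets, abunds, cum = isotope_envelope(formula, coverage)
    return [(o, a / cum) for o, a in zip(offsets, abunds)]


# ---------------------------------------------------------------------------
# structural classification
# ---------------------------------------------------------------------------

def classify(comp: GlycanComposition) -> tuple[str, int, int]:
    """Assign ``(glycan_type, antennae, galactoses)`` from composition alone.

    Deterministic rules: high-mannose iff N=2, H>=5, no fucose, no sialic
    acid; hybrid iff N=3 and H>=5; everything else is complex with
    antennae = N-2 (capped at 4) and antennary galactoses
    max(0, min(H-3, antennae)).  Non-complex types report 0 antennae.
    """
    if comp.N < 2:
        raise GlycanClassificationError(
            f"{comp.name or 'empty composition'}: N={comp.N} < 2, not an N-glycan core"
        )
    if comp.N == 2 and comp.H >= 5 and comp.F == 0 and comp.sialic_total == 0:
        return ("high_mannose", 0, 0)
    if comp.N == 3 and comp.H >= 5:
        return ("hybrid", 0, 0)
    antennae = min(comp.N - 2, 4)
    galactoses = max(0, min(comp.H - 3, antennae))
    return ("complex", antennae, galactoses)


def neutral_loss_mass(
    loss_comp: GlycanComposition,
    reducing_end: bool = False,
    constants: ChemistryConstants = DEFAULT_CONSTANTS,
) -> float:
    """Mass of a neutral loss given as a composition of residues.

    For a Y-type loss of the reducing-end portion set ``reducing_end``
    to include the terminal water (e.g. loss of the core GlcNAc with
    fucose, N1F1 + H2O = 367.1 Da).
    """
    mass = monoisotopic_mz(loss_comp, adduct="none", constants=constants)
    if not reducing_end:
        mass -= constants.water
    return mass
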