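"""Targeted feature list: curated enumeration, CSV round-trip, validation.

The extraction stage is targeted: it integrates only the isotopic
envelopes of a fixed, ordered list of glycan compositions.  The default
list is produced by a rule-based enumeration that encodes mouse
plasma/peritoneal-fluid N-glycome biosynthesis as observed by
MALDI-TOF-MS of ethyl-esterified glycans: NeuGc-dominated sialylation
with at most one NeuAc, core (and rare antennary) fucosylation,
O-acetylation restricted to sialylated species, and "branching
sialylation" (a disialylated antenna, i.e. more sialic acids than
antennae) on di- to tetraantennary glycans.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import pandas as pd

from .chem import (
    ChemistryConstants,
    DEFAULT_CONSTANTS,
    GlycanComposition,
    classify,
    monoisotopic_mz,
    parse_composition,
)

__all__ = [
    "GlycanFeature",
    "FeatureList",
    "EnumerationBounds",
    "enumerate_default_features",
    "load_feature_list",
    "FeatureListError",
]

CSV_COLUMNS = ["name", "H", "N", "F", "E", "L", "Ge", "Gl", "Ac"]


class FeatureListError(ValueError):
    pass


@dataclass(frozen=True)
class GlycanFeature:
    """One targeted analyte: composition plus derived annotation."""

    composition: GlycanComposition
    mz: float  # theoretical [M+Na]+ m/z
    glycan_type: str  # complex | high_mannose | hybrid
    antennae: int
    galactoses: int

    @property
    def name(self) -> str:
        return self.composition.name

    @property
    def sialic_total(self) -> int:
        return self.composition.sialic_total

    @classmethod
    def from_composition(
        cls, comp: GlycanComposition, constants: ChemistryConstants = DEFAULT_CONSTANTS
    ) -> "GlycanFeature":
        gtype, ant, gal = classify(comp)
        return cls(comp, monoisotopic_mz(comp, "Na", constants), gtype, ant, gal)


@dataclass
class FeatureList:
    """Ordered (ascending m/z) list of unique glycan features."""

    features: list[GlycanFeature]
    provenance: str = "enumerated"

    def __post_init__(self) -> None:
        names = [f.name for f in self.features]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise FeatureListError(f"duplicate compositions: {dupes}")
        self.features = sorted(self.features, key=lambda f: f.mz)
        for a, b in zip(self.features, self.features[1:]):
            if b.mz - a.mz < 0.1:
                warnings.warn(
                    f"features {a.name} and {b.name} differ by {b.mz - a.mz:.3f} Da "
                    "(< 0.1 Da): unresolvable at reflectron-TOF resolution",
                    stacklevel=2,
                )

    def __len__(self) -> int:
        return len(self.features)

    def __iter__(self) -> Iterator[GlycanFeature]:
        return iter(self.features)

    def __getitem__(self, key: int | str) -> GlycanFeature:
        if isinstance(key, str):
            for f in self.features:
                if f.name == key:
                    return f
            raise KeyError(key)
        return self.features[key]

    @property
    def names(self) -> list[str]:
        return [f.name for f in self.features]

    def __contains__(self, name: str) -> bool:
        return any(f.name == name for f in self.features)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for f in self.features:
            c = f.composition
            rows.append(
                {
                    "name": f.name,
                    "H": c.H, "N": c.N, "F": c.F, "E": c.E,
                    "L": c.L, "Ge": c.Ge, "Gl": c.Gl, "Ac": c.Ac,
                    "mz": round(f.mz, 4),
                    "glycan_type": f.glycan_type,
                    "antennae": f.antennae,
                    "galactoses": f.galactoses,
                    "sialic_total": f.sialic_total,
                }
            )
        return pd.DataFrame(rows)

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


@dataclass(frozen=True)
class EnumerationBounds:
    """Knobs of the rule-based default enumeration.

    The structural rules themselves (galactosylation <= antennae, at most
    one disialylated antenna, O-acetylation only on NeuGc-sialylated
    species, ...) live in :func:`enumerate_default_features`; the bounds
    select which glycan classes and decoration ranges to admit.
    """

    min_hexnac: int = 2
    max_hexnac: int = 6            # up to tetraantennary complex glycans
    max_antennae: int = 4
    max_fucose: int = 2
    max_acetyl: int = 2
    max_neuac: int = 1             # NeuAc is a trace species in mouse fluids
    high_mannose_range: tuple[int, int] = (5, 9)
    include_complex: bool = True
    include_hybrid: bool = True
    include_high_mannose: bool = True
    include_truncated: bool = True  # paucimannose H3N2/H4N2 stubs

    def __post_init__(self) -> None:
        if self.max_antennae < 1 and self.include_complex:
            raise FeatureListError("max_antennae must be >= 1 for complex glycans")
        if self.min_hexnac < 2 or self.max_hexnac < self.min_hexnac:
            raise FeatureListError("need 2 <= min_hexnac <= max_hexnac")


def _neugc_splits(total: int, max_a23: int) -> Iterator[tuple[int, int]]:
    """(Ge, Gl) splits of ``total`` NeuGc with at most ``max_a23`` a2-3-linked."""
    for gl in range(0, min(total, max_a23) + 1):
        yield (total - gl, gl)


def enumerate_default_features(
    bounds: EnumerationBounds | None = None,
    constants: ChemistryConstants = DEFAULT_CONSTANTS,
) -> FeatureList:
    """Enumerate the default targeted feature list.

    Complex-type rules (antennae = N-2, antennary galactoses = H-3):

    * galactoses <= antennae (no poly-LacNAc extension); tri/tetraantennary
      species are at least (antennae-1)-galactosylated, tetraantennary
      fully galactosylated,
    * sialic acids need an acceptor: S <= galactoses + 2 (each galactose
      carries at most one sialic acid; up to two antennary GlcNAcs can be
      a2-6-sialylated, which is the "branching sialylation" motif) and
      S <= antennae + 1; agalactosylated glycans are sialylated only as
      truncated mono/diantennary stubs (S <= 1); tri/tetraantennary
      glycans carry at most one GlcNAc-linked sialic acid,
    * a2-3-linked NeuGc (Gl) is a minor species: at most 2 per glycan,
    * NeuAc is a trace monosaccharide in mouse fluids: at most one (E or
      L), only as the sole sialic acid of the fully galactosylated
      diantennary backbone,
    * core fucose (F1) on mono- to triantennary species that are either
      unsialylated or fully galactosylated (mono/tri only up to
      monosialylated, diantennary up to disialylated); difucosylation
      only in the two observed monosialylated diantennary patterns
      (agalacto-arm + Gl, fully galactosylated + E),
    * O-acetylation (on sialic acids) on disialylated fully galactosylated
      diantennary NeuGc species: one group (plain or fucosylated) or two
      (non-fucosylated only).
    """
    b = bounds or EnumerationBounds()
    comps: list[GlycanComposition] = []

    if b.include_high_mannose:
        lo, hi = b.high_mannose_range
        comps += [GlycanComposition(H=h, N=2) for h in range(lo, hi + 1)]
    if b.include_truncated:
        comps += [GlycanComposition(H=3, N=2), GlycanComposition(H=4, N=2)]

    if b.include_hybrid:
        # one decorated antenna next to an untrimmed mannose arm
        for h in (5, 6):
            comps.append(GlycanComposition(H=h, N=3))
            for ge, gl in ((1, 0), (0, 1)):
                comps.append(GlycanComposition(H=h, N=3, Ge=ge, Gl=gl))

    if b.include_complex:
        for n in range(max(3, b.min_hexnac), b.max_hexnac + 1):
            ant = n - 2
            if ant > b.max_antennae:
                continue
            gal_min = 0 if ant <= 2 else ant - 1 if ant == 3 else ant
            for gal in range(gal_min, ant + 1):
                h = gal + 3
                if n == 3 and h >= 5:
                    continue  # classified hybrid, emitted above
                if gal == 0:
                    s_max = 1 if ant <= 2 else 0
                else:
                    s_max = min(ant + 1, gal + 2)
                    if ant >= 3:
                        s_max = min(s_max, gal + 1)
                    if ant == 4:
                        s_max = min(s_max, ant)
                for s in range(0, s_max + 1):
                    if s > 0:
                        sialoforms: list[tuple[int, int, int, int]] = [
                            (0, 0, ge, gl) for ge, gl in _neugc_splits(s, 2)
                        ]
                    else:
                        sialoforms = [(0, 0, 0, 0)]
                    # trace NeuAc variants: monosialylated diantennary only
                    if b.max_neuac >= 1 and ant == 2 and gal == 2 and s == 1:
                        sialoforms += [(1, 0, 0, 0), (0, 1, 0, 0)]
                    for e, l, ge, gl in sialoforms:
                        if gl > 2:
                            continue
                        fs = [0]
                        if b.max_fucose >= 1 and ant <= 3:
                            s_fuc_max = 2 if ant == 2 else 1
                            if (s == 0 or gal == ant) and s <= s_fuc_max and (e + l) == 0:
                                # the a2-3 variant of the fucosylated
                                # monosialylated triantennary species is
                                # isobaric with the H4N4Ge2Gl1 isotopologue
                                # tail and cannot be targeted
                                if not (ant == 3 and gl >= 1):
                                    fs.append(1)
                        if b.max_fucose >= 2 and ant == 2 and s == 1:
                            if (e == 1 and gal == 2) or (gl == 1 and gal == 1):
                                fs.append(2)
                        for f in fs:
                            comps.append(
                                GlycanComposition(H=h, N=n, F=f, E=e, L=l, Ge=ge, Gl=gl)
                            )
                            # O-acetyl variants on disialylated diantennary NeuGc
                            if (
                                b.max_acetyl >= 1
                                and ant == 2
                                and gal == 2
                                and (ge + gl) == 2
                                and (e + l) == 0
                                and f <= 1
                            ):
                                comps.append(
                                    GlycanComposition(H=h, N=n, F=f, Ge=ge, Gl=gl, Ac=1)
                                )
                                if b.max_acetyl >= 2 and f == 0:
                                    comps.append(
                                        GlycanComposition(H=h, N=n, Ge=ge, Gl=gl, Ac=2)
                                    )

    feats = [GlycanFeature.from_composition(c, constants) for c in comps]
    return FeatureList(feats, provenance="enumerated")


def default_feature_csv_path() -> Path:
    """Path of the versioned CSV copy of the default enumeration."""
    return Path(__file__).parent / "data" / "default_features.csv"


def load_feature_list(
    path: str | Path, constants: ChemistryConstants = DEFAULT_CONSTANTS
) -> FeatureList:
    """Load a feature CSV (columns: name,H,N,F,E,L,Ge,Gl,Ac; header required).

    Theoretical m/z and structural annotations are always recomputed from
    the composition; any stored values are ignored.
    """
    df = pd.read_csv(path)
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise FeatureListError(f"feature CSV {path}: missing columns {missing}")
    feats: list[GlycanFeature] = []
    seen: set[str] = set()
    for i, row in df.iterrows():
        rowno = i + 2  # 1-based with header line
        try:
            counts = {c: int(row[c]) for c in CSV_COLUMNS[1:]}
        except (TypeError, ValueError) as exc:
            raise FeatureListError(f"feature CSV {path} row {rowno}: {exc}") from exc
        try:
            comp = GlycanComposition(**counts)
        except ValueError as exc:
            raise FeatureListError(f"feature CSV {path} row {rowno}: {exc}") from exc
        name = str(row["name"]).strip()
        if name and name != comp.name:
            # allow the stored name as a cross-check against the counts
            try:
                if parse_composition(name) != comp:
                    raise FeatureListError(
                        f"feature CSV {path} row {rowno}: name {name!r} does not match "
                        f"counts ({comp.name})"
                    )
            except FeatureListError:
                raise
            except ValueError as exc:
                raise FeatureListError(f"feature CSV {path} row {rowno}: {exc}") from exc
        if comp.name in seen:
            raise FeatureListError(
                f"feature CSV {path} row {rowno}: duplicate composition {comp.name}"
            )
        seen.add(comp.name)
        feats.append(GlycanFeature.from_composition(comp, constants))
    return FeatureList(feats, provenance=str(path))
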