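"""Derived glycosylation traits: 19 summary statistics over a glycome profile.

Traits are weighted sums over the relative-abundance profile a_i
(sum a_i = 100).  Type and decoration traits are percentages of total
glycans; antennarity traits are percentages of complex-type glycans;
per-antenna traits average a per-glycan ratio (e.g. sialic acids per
antenna) weighted by abundance over all antenna-bearing (complex and
hybrid) glycans.  Because one antenna can carry two sialic acids —
one on the terminal galactose and one on the antennary GlcNAc
("branching sialylation") — per-antenna sialylation can exceed 100 %.
"""

from __future__ import annotations

from collections import OrderedDict

import numpy as np
import pandas as pd

from .features import FeatureList
from .preprocess import GlycomeProfile

__all__ = ["TRAIT_NAMES", "compute_traits", "trait_glossary", "TraitError"]


class TraitError(ValueError):
    pass


_GLOSSARY: "OrderedDict[str, str]" = OrderedDict(
    [
        ("complex_pct", "sum a_i over complex-type glycans (% of total)"),
        ("high_mannose_pct", "sum a_i over high-mannose glycans (% of total)"),
        ("hybrid_pct", "sum a_i over hybrid-type glycans (% of total)"),
        ("monoantennary_pct", "sum a_i over complex glycans with 1 antenna, as % of antenna-bearing complex glycans"),
        ("diantennary_pct", "sum a_i over complex glycans with 2 antennae, as % of antenna-bearing complex glycans"),
        ("triantennary_pct", "sum a_i over complex glycans with 3 antennae, as % of antenna-bearing complex glycans"),
        ("tetraantennary_pct", "sum a_i over complex glycans with 4 antennae, as % of antenna-bearing complex glycans"),
        ("galactosylation_per_antenna_pct", "100 * sum a_i*(gal_i/ant_i) / sum a_i over antenna-bearing glycans: average antennary galactoses per antenna"),
        ("fucosylation_pct", "sum a_i over glycans with F_i >= 1 (% of total)"),
        ("monofucosylation_pct", "sum a_i over glycans with F_i == 1 (% of total)"),
        ("multifucosylation_pct", "sum a_i over glycans with F_i >= 2 (% of total)"),
        ("sialylation_per_antenna_pct", "100 * sum a_i*(S_i/ant_i) / sum a_i with S_i = E+L+Ge+Gl; exceeds 100 % when antennae are disialylated"),
        ("neugc_per_antenna_pct", "per-antenna trait with S_i replaced by Ge_i + Gl_i (total NeuGc)"),
        ("neugc_a26_per_antenna_pct", "per-antenna trait with S_i replaced by Ge_i (ethyl-esterified, a2-6-linked NeuGc)"),
        ("neugc_a23_per_antenna_pct", "per-antenna trait with S_i replaced by Gl_i (lactonized, a2-3/8-linked NeuGc)"),
        ("neuac_a26_pct", "per-antenna trait with S_i replaced by E_i (ethyl-esterified, a2-6-linked NeuAc)"),
        ("neuac_a23_pct", "per-antenna trait with S_i replaced by L_i (lactonized, a2-3/8-linked NeuAc)"),
        ("acetylation_pct", "sum a_i over glycans with Ac_i >= 1 (% of total): sialic acid O-acetylation"),
        ("branching_sialylation_pct", "sum a_i over antenna-bearing glycans with S_i > ant_i (% of total): at least one disialylated antenna sequence NeuGc-(a2,3)-Hex-[NeuGc-(a2,6)-]HexNAc"),
    ]
)

TRAIT_NAMES: tuple[str, ...] = tuple(_GLOSSARY)


def trait_glossary() -> "OrderedDict[str, str]":
    """The exact formula text of each derived trait, for reports."""
    return OrderedDict(_GLOSSARY)


def _effective_antennae(glycan_type: str, antennae: int) -> int:
    # hybrid glycans carry one decorated antenna; high-mannose none;
    # truncated paucimannose (complex, N=2) stubs none.
    if glycan_type == "hybrid":
        return 1
    if glycan_type == "complex":
        return antennae
    return 0


def compute_traits(profile: GlycomeProfile, features: FeatureList) -> pd.Series:
    """Compute the 19 derived traits for one sample profile.

    Every profile feature must be present in ``features`` (the profile's
    target list), which provides the structural classification.
    """
    missing = [n for n in profile.abundances.index if n not in features]
    if missing:
        raise TraitError(f"profile features not in the feature list: {missing}")

    rows = []
    for name, a in profile.abundances.items():
        f = features[name]
        c = f.composition
        rows.append(
            {
                "a": float(a),
                "type": f.glycan_type,
                "ant": _effective_antennae(f.glycan_type, f.antennae),
                "gal": f.galactoses,
                "F": c.F, "E": c.E, "L": c.L, "Ge": c.Ge, "Gl": c.Gl,
                "Ac": c.Ac, "S": c.sialic_total,
            }
        )
    df = pd.DataFrame(rows)

    out: dict[str, float] = {}
    for gtype, trait in (
        ("complex", "complex_pct"),
        ("high_mannose", "high_mannose_pct"),
        ("hybrid", "hybrid_pct"),
    ):
        out[trait] = df.loc[df["type"] == gtype, "a"].sum()

    cx = df[(df["type"] == "complex") & (df["ant"] >= 1)]
    cx_total = cx["a"].sum()
    for k, trait in enumerate(
        ("monoantennary_pct", "diantennary_pct", "triantennary_pct", "tetraantennary_pct"),
        start=1,
    ):
        out[trait] = 100.0 * cx.loc[cx["ant"] == k, "a"].sum() / cx_total if cx_total > 0 else 0.0

    ab = df[df["ant"] >= 1]  # antenna-bearing: complex + hybrid
    ab_total = ab["a"].sum()

    def per_antenna(col: str) -> float:
        if ab_total <= 0:
            return 0.0
        return float(100.0 * (ab["a"] * ab[col] / ab["ant"]).sum() / ab_total)

    out["galactosylation_per_antenna_pct"] = per_antenna("gal")
    out["fucosylation_pct"] = df.loc[df["F"] >= 1, "a"].sum()
    out["monofucosylation_pct"] = df.loc[df["F"] == 1, "a"].sum()
    out["multifucosylation_pct"] = df.loc[df["F"] >= 2, "a"].sum()
    out["sialylation_per_antenna_pct"] = per_antenna("S")
    out["neugc_per_antenna_pct"] = per_antenna("Ge") + per_antenna("Gl")
    out["neugc_a26_per_antenna_pct"] = per_antenna("Ge")
    out["neugc_a23_per_antenna_pct"] = per_antenna("Gl")
    out["neuac_a26_pct"] = per_antenna("E")
    out["neuac_a23_pct"] = per_antenna("L")
    out["acetylation_pct"] = df.loc[df["Ac"] >= 1, "a"].sum()
    out["branching_sialylation_pct"] = ab.loc[ab["S"] > ab["ant"], "a"].sum()

    return pd.Series(out, index=list(TRAIT_NAMES), dtype=float)


def trait_matrix(abundances: pd.DataFrame, features: FeatureList) -> pd.DataFrame:
    """Vectorized traits for many samples at once.

    ``abundances``: features x samples (percent, columns sum to 100).
    Returns samples x traits.  Same definitions as :func:`compute_traits`
    (which it must agree with exactly); intended for simulation studies
    where thousands of profiles are scored.
    """
    attrs = []
    for name in abundances.index:
        f = features[name]
        c = f.composition
        attrs.append(
            {
                "type": f.glycan_type,
                "ant": _effective_antennae(f.glycan_type, f.antennae),
                "gal": f.galactoses,
                "F": c.F, "E": c.E, "L": c.L, "Ge": c.Ge, "Gl": c.Gl,
                "Ac": c.Ac, "S": c.sialic_total,
            }
        )
    at = pd.DataFrame(attrs, index=abundances.index)
    A = abundances.to_numpy(dtype=float)  # features x samples

    def wsum(mask: np.ndarray) -> np.ndarray:
        return mask.astype(float) @ A

    out = {}
    for gtype, trait in (
        ("complex", "complex_pct"),
        ("high_mannose", "high_mannose_pct"),
        ("hybrid", "hybrid_pct"),
    ):
        out[trait] = wsum((at["type"] == gtype).to_numpy())

    cx_mask = ((at["type"] == "complex") & (at["ant"] >= 1)).to_numpy()
    cx_total = wsum(cx_mask)
    for k, trait in enumerate(
        ("monoantennary_pct", "diantennary_pct", "triantennary_pct", "tetraantennary_pct"),
        start=1,
    ):
        num = wsum(cx_mask & (at["ant"] == k).to_numpy())
        out[trait] = np.where(cx_total > 0, 100.0 * num / cx_total, 0.0)

    ab_mask = (at["ant"] >= 1).to_numpy()
    ab_total = wsum(ab_mask)
    ant = at["ant"].to_numpy(dtype=float)
    ant_safe = np.where(ab_mask, ant, 1.0)

    def per_antenna(col: str) -> np.ndarray:
        w = np.where(ab_mask, at[col].to_numpy(dtype=float) / ant_safe, 0.0)
        return np.where(ab_total > 0, 100.0 * (w @ A) / ab_total, 0.0)

    out["galactosylation_per_antenna_pct"] = per_antenna("gal")
    out["fucosylation_pct"] = wsum((at["F"] >= 1).to_numpy())
    out["monofucosylation_pct"] = wsum((at["F"] == 1).to_numpy())
    out["multifucosylation_pct"] = wsum((at["F"] >= 2).to_numpy())
    out["sialylation_per_antenna_pct"] = per_antenna("S")
    out["neugc_per_antenna_pct"] = per_antenna("Ge") + per_antenna("Gl")
    out["neugc_a26_per_antenna_pct"] = per_antenna("Ge")
    out["neugc_a23_per_antenna_pct"] = per_antenna("Gl")
    out["neuac_a26_pct"] = per_antenna("E")
    out["neuac_a23_pct"] = per_antenna("L")
    out["acetylation_pct"] = wsum((at["Ac"] >= 1).to_numpy())
    out["branching_sialylation_pct"] = wsum(ab_mask & (at["S"] > at["ant"]).to_numpy())

    return pd.DataFrame(out, index=abundances.columns)[list(TRAIT_NAMES)]


def trait_table(
    profiles: list[GlycomeProfile], features: FeatureList, metadata: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Tidy trait table: one row per sample, 19 trait columns (+ metadata)."""
    rows = []
    for p in profiles:
        s = compute_traits(p, features)
        s["sample_id"] = p.sample_id
        rows.append(s)
    df = pd.DataFrame(rows).set_index("sample_id")
    df = df.astype(float)
    if metadata is not None:
        df = metadata.set_index("sample_id").join(df, how="right")
    return df
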