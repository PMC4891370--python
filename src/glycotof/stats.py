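"""Group statistics on derived-trait tables.

Three comparison designs, matching how longitudinal glycomics studies
with sacrificed-animal time courses are usually analyzed (each time
point is an independent set of mice):

* paired t-test between two fluids measured in the same animals,
* one-way ANOVA with Tukey HSD for multi-group comparisons at one
  time point,
* two-way ANOVA (group x time) with Dunnett-style treated-vs-control
  contrasts at every time point, adjusted over time points with the
  studentized maximum modulus distribution (the contrasts share the
  pooled residual variance but are otherwise independent, so the
  multivariate-t correlation matrix is the identity).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import integrate, stats as sps
from statsmodels.formula.api import ols
from statsmodels.stats.anova import anova_lm
from statsmodels.stats.multicomp import pairwise_tukeyhsd

__all__ = [
    "ComparisonResult",
    "significance_stars",
    "paired_t",
    "one_way_anova_tukey",
    "two_way_anova_dunnett",
    "smm_pvalue",
    "StatsError",
]


class StatsError(ValueError):
    pass


def significance_stars(p: float) -> str:
    """The conventional ladder: * p<0.05, ** p<0.01, *** p<0.001, **** p<0.0001."""
    if not np.isfinite(p):
        return ""
    for stars, cut in (("****", 1e-4), ("***", 1e-3), ("**", 1e-2), ("*", 5e-2)):
        if p < cut:
            return stars
    return ""


@dataclass(frozen=True)
class ComparisonResult:
    trait: str
    contrast: str
    estimate: float  # mean difference
    p: float
    p_adj: float
    stars: str
    n: tuple[int, ...]
    degenerate: bool = False  # zero-variance input, statistic not defined
    note: str = ""


def paired_t(a: np.ndarray, b: np.ndarray, trait: str = "", contrast: str = "") -> ComparisonResult:
    """Classical two-sided paired t-test on equal-length paired samples.

    A zero-variance difference vector has no defined t statistic; such
    input is returned flagged ``degenerate`` (p = 1 when the two vectors
    are identical, p = NaN when they differ by an exact constant shift).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise StatsError("paired samples must be 1-D arrays of equal length")
    n = a.size
    if n < 2:
        raise StatsError(f"need at least 2 pairs, got {n}")
    diff = a - b
    est = float(np.mean(diff))
    if np.allclose(np.std(diff), 0.0):
        p = 1.0 if np.allclose(diff, 0.0) else float("nan")
        return ComparisonResult(
            trait, contrast or "paired", est, p, p, significance_stars(p), (n, n),
            degenerate=True, note="zero-variance paired differences",
        )
    t, p = sps.ttest_rel(a, b)
    return ComparisonResult(trait, contrast or "paired", est, float(p), float(p),
                            significance_stars(float(p)), (n, n))


def one_way_anova_tukey(
    groups: dict[str, np.ndarray], trait: str = "", alpha: float = 0.05
) -> tuple[float, float, list[ComparisonResult]]:
    """One-way ANOVA F test plus Tukey HSD pairwise comparisons.

    Returns ``(F, p, pairwise_results)``.  Requires at least three
    groups; with two the t-test is the appropriate analysis.
    """
    if len(groups) < 3:
        raise StatsError("one-way ANOVA needs >= 3 groups; use a t-test for two")
    names = list(groups)
    arrays = [np.asarray(groups[k], dtype=float) for k in names]
    if any(a.size < 2 for a in arrays):
        raise StatsError("every group needs >= 2 observations")
    values = np.concatenate(arrays)
    if np.allclose(np.std(values), 0.0):
        results = []
        for i, gi in enumerate(names):
            for gj in names[i + 1:]:
                results.append(ComparisonResult(
                    trait, f"{gi} vs {gj}", 0.0, 1.0, 1.0, "",
                    (groups[gi].size, groups[gj].size), degenerate=True,
                    note="zero-variance data",
                ))
        return 0.0, 1.0, results
    F, p = sps.f_oneway(*arrays)
    labels = np.concatenate([[k] * a.size for k, a in zip(names, arrays)])
    tukey = pairwise_tukeyhsd(values, labels, alpha=alpha)
    results = []
    for row in tukey.summary().data[1:]:
        g1, g2, meandiff, p_adj = str(row[0]), str(row[1]), float(row[2]), float(row[3])
        results.append(ComparisonResult(
            trait, f"{g2} vs {g1}", -meandiff, float(p), p_adj,
            significance_stars(p_adj), (groups[g1].size, groups[g2].size),
        ))
    return float(F), float(p), results


# ---------------------------------------------------------------------------
# two-way ANOVA with per-time Dunnett-style contrasts
# ---------------------------------------------------------------------------

def smm_pvalue(t: float, k: int, df: int) -> float:
    """Two-sided studentized-maximum-modulus adjusted p for |t| over k contrasts.

    ``P(max_i |T_i| >= t)`` for k contrasts that share a chi-squared
    denominator with ``df`` degrees of freedom and have independent
    numerators — the Dunnett multivariate-t probability with identity
    correlation.  Computed by integrating over the pooled-SD density.
    """
    if k < 1:
        raise StatsError("need at least one contrast")
    t = abs(float(t))
    if not np.isfinite(t):
        return 0.0 if t > 0 else 1.0
    if k == 1:
        return float(2.0 * sps.t.sf(t, df))

    chi = sps.chi(df)

    def integrand(u: float) -> float:
        # u = pooled SD factor ~ chi_df / sqrt(df)
        inner = 2.0 * sps.norm.cdf(t * u) - 1.0
        return chi.pdf(u * np.sqrt(df)) * np.sqrt(df) * inner**k

    val, _ = integrate.quad(integrand, 0.0, np.inf, limit=200)
    return float(min(1.0, max(0.0, 1.0 - val)))


def two_way_anova_dunnett(
    df: pd.DataFrame,
    value: str = "value",
    group: str = "group",
    time: str = "time_h",
    control: str = "control",
    trait: str = "",
) -> tuple[pd.DataFrame, list[ComparisonResult]]:
    """Two-way ANOVA (group, time, interaction) with treated-vs-control
    contrasts at every time point.

    ``df`` holds one row per animal with columns ``value``, ``group`` and
    ``time``.  Exactly two groups are expected (treated and control); the
    per-time mean differences are tested against the pooled residual
    variance of the full model and adjusted over the number of time
    points with the studentized maximum modulus distribution.
    Returns ``(anova_table, comparisons)``.
    """
    for col in (value, group, time):
        if col not in df.columns:
            raise StatsError(f"column {col!r} missing from data frame")
    groups = sorted(df[group].unique())
    if control not in groups:
        raise StatsError(f"control group {control!r} not present (groups: {groups})")
    if len(groups) != 2:
        raise StatsError(f"expected exactly 2 groups, got {groups}")
    treated = next(g for g in groups if g != control)
    times = sorted(df[time].unique())
    missing = [
        (g, t) for g in groups for t in times
        if df[(df[group] == g) & (df[time] == t)].empty
    ]
    if missing:
        raise StatsError(f"missing design cells (group, time): {missing}")

    data = df.rename(columns={value: "_y", group: "_g", time: "_t"})
    if len(times) == 1:
        # single time point: the design degenerates to a one-way contrast
        model = ols("_y ~ C(_g)", data=data).fit()
    else:
        model = ols("_y ~ C(_g) * C(_t)", data=data).fit()
    if model.df_resid <= 0:
        raise StatsError(
            "saturated design: no residual degrees of freedom "
            "(need replicate animals per group x time cell)"
        )
    table = anova_lm(model, typ=2)
    mse = float(model.mse_resid)
    dof = int(model.df_resid)

    comparisons: list[ComparisonResult] = []
    k = len(times)
    for t in times:
        y1 = data.loc[(data["_g"] == treated) & (data["_t"] == t), "_y"].to_numpy()
        y0 = data.loc[(data["_g"] == control) & (data["_t"] == t), "_y"].to_numpy()
        est = float(np.mean(y1) - np.mean(y0))
        se = np.sqrt(mse * (1.0 / y1.size + 1.0 / y0.size))
        if se == 0.0:
            comparisons.append(ComparisonResult(
                trait, f"{treated} vs {control} @ {t} h", est, float("nan"),
                float("nan"), "", (y1.size, y0.size), degenerate=True,
                note="zero residual variance",
            ))
            continue
        tstat = est / se
        p_raw = float(2.0 * sps.t.sf(abs(tstat), dof))
        p_adj = smm_pvalue(tstat, k, dof)
        comparisons.append(ComparisonResult(
            trait, f"{treated} vs {control} @ {t} h", est, p_raw, p_adj,
            significance_stars(p_adj), (y1.size, y0.size),
        ))
    return table, comparisons
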