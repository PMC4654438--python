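"""Per-functional-category aggregation and two-group comparisons.

Builds the summary-of-variation table (one row per functional class:
non-coding, coding, synonymous, non-synonymous, plus raw categories) and
tests category contrasts with Welch's unequal-variance two-tailed t-test.
Each variant is one observation; variants monomorphic in the scope
contribute MAF 0 rather than being dropped, so a class that is rare in a
group pulls its average down (protein-altering variants absent from a
group show as zero-MAF observations there).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .genotype_io import CODING_CATEGORIES, NONCODING_CATEGORIES
from .summary_stats import snp_density, watterson_theta

__all__ = ["category_summary", "welch_t_test", "group_correlation",
           "compare_categories"]

#: aggregate classes used in the summary table and contrasts
CLASS_MEMBERS = {
    "non-coding": list(NONCODING_CATEGORIES),
    "coding": list(CODING_CATEGORIES),
    "synonymous": ["synonymous"],
    "non-synonymous": ["non-synonymous"],
}


def category_summary(variants: pd.DataFrame, stats_df: pd.DataFrame,
                     lengths: dict, n_chrom: int,
                     fst: pd.DataFrame | None = None,
                     scope: str = "all") -> pd.DataFrame:
    """One row per functional class: K, density, theta, mean het/MAF/F_ST.

    `lengths` maps class -> screened bp; sub-classes of coding share the
    coding length (no site-class length partition is attempted). `stats_df`
    is the per-variant frame from ``allele_frequencies`` for the scope;
    `fst` optionally supplies per-locus theta for the mean-F_ST column.
    Classes with K=0 get NaN theta and density 0.
    """
    merged = variants.merge(stats_df, on="id", how="left")
    if fst is not None:
        merged = merged.merge(fst[["id", "fst"]], on="id", how="left")
    rows = []
    for cls, members in CLASS_MEMBERS.items():
        sub = merged[merged["category"].isin(members)]
        K = len(sub)
        L = lengths.get(cls, lengths.get("coding") if cls in
                        ("synonymous", "non-synonymous") else None)
        theta = watterson_theta(K, n_chrom, L) if (K > 0 and L) else np.nan
        dens = snp_density(K, L) if L else 0
        rows.append({
            "class": cls,
            "scope": scope,
            "bp_screened": L,
            "K": K,
            "density_denominator": dens,
            "theta_w": theta,
            "mean_het": float(sub["het"].mean()) if K else np.nan,
            "mean_maf": float(sub["maf"].mean()) if K else np.nan,
            "mean_fst": (float(sub["fst"].mean())
                         if fst is not None and K and sub["fst"].notna().any()
                         else np.nan),
        })
    return pd.DataFrame(rows)


def welch_t_test(a, b):
    """Welch's unequal-variance t-test, two-sided.

    Returns (t, df, p) with the Welch-Satterthwaite degrees of freedom.
    Degenerate input (zero variance in both lists with equal means) gives
    t=0, p=1 rather than NaN.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    a = a[np.isfinite(a)]
    b = b[np.isfinite(b)]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample needs at least 2 defined values")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    na, nb = len(a), len(b)
    se2 = va / na + vb / nb
    if se2 == 0:
        if a.mean() == b.mean():
            return 0.0, float(na + nb - 2), 1.0
        return np.inf, float(na + nb - 2), 0.0
    t = (a.mean() - b.mean()) / np.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), float(df), float(p)


def group_correlation(a, b) -> float:
    """Squared Pearson correlation of paired per-variant values.

    Pairs with either value undefined are dropped; fewer than 3 complete
    pairs, or zero variance in either list, gives NaN (flagged).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    ok = np.isfinite(a) & np.isfinite(b)
    a, b = a[ok], b[ok]
    if len(a) < 3 or a.std() == 0 or b.std() == 0:
        return float("nan")
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)


def compare_categories(variants: pd.DataFrame, stats_df: pd.DataFrame,
                       fst: pd.DataFrame | None = None,
                       scope: str = "all") -> pd.DataFrame:
    """Welch tests for the two standard contrasts on MAF, het (and F_ST).

    Contrasts: non-coding vs coding and synonymous vs non-synonymous,
    on per-variant MAF and heterozygosity (plus per-locus F_ST when
    supplied). Returns a tidy frame (contrast, measure, t, df, p).
    """
    merged = variants.merge(stats_df, on="id", how="left")
    if fst is not None:
        merged = merged.merge(fst[["id", "fst"]], on="id", how="left")
    measures = ["maf", "het"] + (["fst"] if fst is not None else [])
    contrasts = [("non-coding", "coding"), ("synonymous", "non-synonymous")]
    rows = []
    for hi, lo in contrasts:
        sub_hi = merged[merged["category"].isin(CLASS_MEMBERS[hi])]
        sub_lo = merged[merged["category"].isin(CLASS_MEMBERS[lo])]
        for meas in measures:
            va = sub_hi[meas].dropna().to_numpy()
            vb = sub_lo[meas].dropna().to_numpy()
            if len(va) < 2 or len(vb) < 2:
                rows.append((f"{hi}_vs_{lo}", meas, scope, np.nan, np.nan, np.nan))
                continue
            t, df, p = welch_t_test(va, vb)
            rows.append((f"{hi}_vs_{lo}", meas, scope, t, df, p))
    return pd.DataFrame(rows, columns=["contrast", "measure", "scope", "t",
                                       "df", "p"])
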