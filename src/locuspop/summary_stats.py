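"""Per-variant and per-region diversity statistics.

Frequencies are always computed from complete-case chromosomes within the
scope being analysed (missing genotypes are dropped per locus, never
imputed), and ``n_chrom`` is recorded alongside every frequency so the
finite-sample corrections downstream use the right n.

Conventions fixed here and used throughout the package:

* n in the Watterson normalisation is *chromosomes*, i.e. 2 x diploid
  individuals.
* heterozygosity is unbiased expected heterozygosity (gene diversity)
  h = n/(n-1) * (1 - x1^2 - x2^2), not observed genotype heterozygosity.
* SNP density is reported as the "1 SNP per N bp" denominator,
  N = round(L / K).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .genotype_io import MISSING, GenotypeMatrix

__all__ = [
    "allele_frequencies",
    "expected_heterozygosity",
    "watterson_theta",
    "harmonic_number",
    "snp_density",
    "nucleotide_diversity",
    "allelic_divergence",
    "region_summary",
]


def allele_frequencies(geno: GenotypeMatrix, scope: np.ndarray | list | None = None,
                       variant_ids: list | None = None) -> pd.DataFrame:
    """Alternate/reference allele frequencies over a sample scope.

    Returns a frame with columns ``id, x1, x2, maf, het, n_chrom`` where
    x1 is the reference-allele and x2 the alternate-allele frequency.
    Variants with every genotype missing in scope get NaN frequencies and
    n_chrom 0 (flagged, not dropped).
    """
    sub = geno if scope is None else geno.subset_samples(scope)
    if sub.n_samples == 0:
        raise ValueError("empty sample scope")
    dos = sub.dosages
    valid = dos != MISSING
    n_chrom = 2 * valid.sum(axis=1)
    alt = np.where(valid, dos, 0).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        x2 = np.where(n_chrom > 0, alt / np.maximum(n_chrom, 1), np.nan)
    x1 = 1.0 - x2
    maf = np.minimum(x1, x2)
    het = expected_heterozygosity(x1, x2, n_chrom)
    if variant_ids is None:
        variant_ids = np.arange(sub.n_variants)
    return pd.DataFrame(
        {"id": variant_ids, "x1": x1, "x2": x2, "maf": maf, "het": het,
         "n_chrom": n_chrom}
    )


def expected_heterozygosity(x1, x2, n_chrom):
    """Unbiased gene diversity h = n/(n-1) (1 - x1^2 - x2^2).

    Vectorised; returns NaN where n_chrom < 2 (h is undefined on fewer
    than two chromosomes).
    """
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    n = np.asarray(n_chrom, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        h = n / (n - 1.0) * (1.0 - x1**2 - x2**2)
    h = np.where(n >= 2, h, np.nan)
    return h if h.ndim else float(h)


def harmonic_number(n_minus_1: int) -> float:
    """a_n = sum_{i=1}^{n-1} 1/i, the Watterson normalising constant."""
    return float(np.sum(1.0 / np.arange(1, n_minus_1 + 1)))


def watterson_theta(K: int, n_chrom: int, L: float) -> float:
    """Normalised variant-site count theta = K / (a_n * L), per bp.

    K segregating sites among ``n_chrom`` chromosomes over ``L`` screened
    base pairs; a_n is the harmonic number of n_chrom - 1. No corrections
    beyond the harmonic normalisation are applied.
    """
    if L <= 0:
        raise ValueError("screened length L must be positive")
    if n_chrom < 2:
        raise ValueError("need at least 2 chromosomes")
    if K < 0:
        raise ValueError("negative variant count")
    return K / (harmonic_number(n_chrom - 1) * L)


def snp_density(K: int, L: float) -> int:
    """bp-per-SNP denominator: round(L / K), rendered "1/N"; 0 when K=0."""
    if K < 0:
        raise ValueError("negative variant count")
    if K == 0:
        return 0
    return int(round(L / K))


def nucleotide_diversity(geno: GenotypeMatrix, L: float,
                         scope: np.ndarray | list | None = None) -> float:
    """pi per bp: mean pairwise difference = sum_sites n/(n-1) 2 x1 x2 / L.

    Per-site complete-case chromosome counts n; sites with n < 2
    contribute nothing (their pairwise diversity is undefined).
    """
    if L <= 0:
        raise ValueError("screened length L must be positive")
    af = allele_frequencies(geno, scope)
    n = af["n_chrom"].to_numpy(dtype=float)
    x1 = af["x1"].to_numpy()
    x2 = af["x2"].to_numpy()
    with np.errstate(divide="ignore", invalid="ignore"):
        per_site = n / (n - 1.0) * 2.0 * x1 * x2
    per_site = np.where(n >= 2, per_site, 0.0)
    return float(np.nansum(per_site) / L)


def allelic_divergence(x: tuple[float, float], y: tuple[float, float]) -> float:
    """Allele-frequency divergence d = 1 - [sqrt(x1 y1) + sqrt(x2 y2)].

    One minus the Bhattacharyya affinity of two biallelic frequency
    vectors: 0 for identical spectra, 1 for disjoint allele sets.
    """
    x1, x2 = float(x[0]), float(x[1])
    y1, y2 = float(y[0]), float(y[1])
    for p, q in ((x1, x2), (y1, y2)):
        if not (np.isfinite(p) and np.isfinite(q)) or p < 0 or q < 0 \
                or abs(p + q - 1.0) > 1e-8:
            raise ValueError(f"malformed frequency pair ({p}, {q})")
    d = 1.0 - (np.sqrt(x1 * y1) + np.sqrt(x2 * y2))
    # clip float noise at the boundaries
    return float(min(1.0, max(0.0, d)))


def region_summary(K: int, n_chrom: int, L: float,
                   geno: GenotypeMatrix | None = None,
                   scope=None) -> dict:
    """Region-level summary: K, L, theta_w, density denominator, optional pi."""
    out = {
        "K": int(K),
        "L": float(L),
        "n_chrom": int(n_chrom),
        "theta_w": watterson_theta(K, n_chrom, L) if K > 0 else 0.0,
        "density_denominator": snp_density(K, L),
    }
    if geno is not None:
        out["pi"] = nucleotide_diversity(geno, L, scope)
    return out
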