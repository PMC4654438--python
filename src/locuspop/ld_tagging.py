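"""Pairwise LD, greedy tag-SNP binning and surrogate-SNP discovery.

r^2 is the squared correlation of allelic indicators on haplotypes.
Phased input uses direct haplotype counts; unphased input resolves the
double-heterozygote ambiguity by EM on two-locus haplotype frequencies.
LD is always computed within one sample scope (an ancestral group) at a
time -- groups differ sharply in LD structure, so pooled r^2 would be
meaningless for surrogate selection.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotype_io import MISSING, GenotypeMatrix

__all__ = [
    "haplotype_ld",
    "em_haplotype_freqs",
    "ld_from_hap_freqs",
    "ld_matrix",
    "greedy_tag_selection",
    "SurrogateSet",
    "find_surrogates",
]

EM_TOL = 1e-8
EM_MAX_ITER = 1000


def ld_from_hap_freqs(p11: float, p1_: float, p_1: float):
    """(r2, d_prime) from the 11-haplotype frequency and the two marginals."""
    pA, pB = p1_, p_1
    qA, qB = 1.0 - pA, 1.0 - pB
    denom = pA * qA * pB * qB
    if denom <= 0:
        return np.nan, np.nan
    D = p11 - pA * pB
    r2 = D * D / denom
    dmax = min(pA * qB, qA * pB) if D > 0 else min(pA * pB, qA * qB)
    d_prime = abs(D) / dmax if dmax > 0 else np.nan
    return float(min(r2, 1.0)), float(min(d_prime, 1.0))


def haplotype_ld(hapA: np.ndarray, hapB: np.ndarray) -> dict:
    """LD between two loci from phased allele vectors (complete cases).

    Both vectors hold 0/1 alleles per chromosome copy (missing < 0
    entries are dropped pairwise). Returns a dict with r2, d_prime, the
    haplotype frequencies and the copy count; monomorphic loci in scope
    give NaN r2 (flagged via ``defined``).
    """
    hapA = np.asarray(hapA)
    hapB = np.asarray(hapB)
    if hapA.shape != hapB.shape:
        raise ValueError("haplotype vectors must have equal length")
    ok = (hapA >= 0) & (hapB >= 0)
    a, b = hapA[ok].astype(float), hapB[ok].astype(float)
    n = len(a)
    if n == 0:
        return {"r2": np.nan, "d_prime": np.nan, "n_chrom": 0, "defined": False,
                "method": "phased-count"}
    p11 = float(np.mean(a * b))
    pA, pB = float(a.mean()), float(b.mean())
    r2, dp = ld_from_hap_freqs(p11, pA, pB)
    return {"r2": r2, "d_prime": dp, "n_chrom": n,
            "defined": bool(np.isfinite(r2)), "method": "phased-count"}


def em_haplotype_freqs(dosA: np.ndarray, dosB: np.ndarray):
    """Two-locus haplotype frequencies (p00, p01, p10, p11) by EM.

    Unphased dosage input; only double heterozygotes are ambiguous. The
    start point is linkage equilibrium (product of marginals), iteration
    stops when no frequency moves by more than 1e-8 or after 1000 rounds
    (non-convergence is flagged, the last iterate returned).
    Returns (freqs, n_chrom, converged).
    """
    dosA = np.asarray(dosA)
    dosB = np.asarray(dosB)
    ok = (dosA != MISSING) & (dosB != MISSING)
    a, b = dosA[ok], dosB[ok]
    n_ind = len(a)
    if n_ind == 0:
        return np.full(4, np.nan), 0, False
    n_chrom = 2 * n_ind
    # known haplotype counts from unambiguous individuals
    counts = np.zeros(4)  # 00, 01, 10, 11 (allele at A, allele at B)
    n_dh = 0
    for da, db in zip(a, b):
        if da == 1 and db == 1:
            n_dh += 1
            continue
        # each individual contributes two haplotypes; a het at one locus
        # contributes one of each allele there
        hA = [0, 0] if da == 0 else ([1, 1] if da == 2 else [0, 1])
        hB = [0, 0] if db == 0 else ([1, 1] if db == 2 else [0, 1])
        if da == 1:
            # B is homozygous here
            counts[0 * 2 + hB[0]] += 1
            counts[1 * 2 + hB[0]] += 1
        elif db == 1:
            counts[hA[0] * 2 + 0] += 1
            counts[hA[0] * 2 + 1] += 1
        else:
            counts[hA[0] * 2 + hB[0]] += 2
    pA = a.sum() / n_chrom
    pB = b.sum() / n_chrom
    freqs = np.array([(1 - pA) * (1 - pB), (1 - pA) * pB,
                      pA * (1 - pB), pA * pB])
    freqs = np.clip(freqs, 1e-12, None)
    freqs /= freqs.sum()
    if n_dh == 0:
        out = counts / n_chrom
        return out, n_chrom, True
    converged = False
    for _ in range(EM_MAX_ITER):
        # double heterozygotes are 00/11 or 01/10 pairs
        w = freqs[0] * freqs[3]
        v = freqs[1] * freqs[2]
        frac_cis = w / (w + v) if (w + v) > 0 else 0.5
        new = counts.copy()
        new[0] += n_dh * frac_cis
        new[3] += n_dh * frac_cis
        new[1] += n_dh * (1 - frac_cis)
        new[2] += n_dh * (1 - frac_cis)
        new /= n_chrom
        if np.max(np.abs(new - freqs)) < EM_TOL:
            freqs = new
            converged = True
            break
        freqs = new
    return freqs, n_chrom, converged


def _pair_ld_unphased(dosA, dosB):
    freqs, n, converged = em_haplotype_freqs(dosA, dosB)
    if n == 0 or not np.all(np.isfinite(freqs)):
        return np.nan, np.nan, n, False
    p11 = freqs[3]
    pA = freqs[2] + freqs[3]
    pB = freqs[1] + freqs[3]
    r2, dp = ld_from_hap_freqs(p11, pA, pB)
    return r2, dp, n, converged


def ld_matrix(geno: GenotypeMatrix, variants: pd.DataFrame,
              scope: list | np.ndarray | None = None,
              maf_min: float = 0.05, keep_ids: list | None = None) -> pd.DataFrame:
    """All pairwise LD among MAF-passing variants within a sample scope.

    Variants with in-scope MAF below ``maf_min`` are excluded from every
    pair, except ids listed in ``keep_ids`` (index SNPs are exempt from
    the MAF filter when hunting surrogates). Uses haplotype counts when
    the matrix is phased, EM on dosages otherwise.

    Returns a long-format frame: id_a, id_b, pos_a, pos_b, distance, r2,
    d_prime, method (one row per unordered pair, a before b in variant
    order).
    """
    from .summary_stats import allele_frequencies

    sub = geno if scope is None else geno.subset_samples(scope)
    af = allele_frequencies(sub, variant_ids=variants["id"].to_list())
    maf = af["maf"].to_numpy()
    keep = maf >= maf_min
    if keep_ids:
        keep |= variants["id"].isin(keep_ids).to_numpy()
    keep &= np.isfinite(maf) & (maf > 0)  # monomorphic loci have no LD
    idx = np.flatnonzero(keep)
    ids = variants["id"].to_numpy()[idx]
    pos = variants["pos"].to_numpy()[idx]
    m = len(idx)
    rows = []
    if sub.phased and sub.haplotypes is not None:
        H = sub.haplotype_matrix()[idx].astype(float)
        miss = H < 0
        if miss.any():
            for i in range(m):
                for j in range(i + 1, m):
                    res = haplotype_ld(H[i], H[j])
                    rows.append((ids[i], ids[j], pos[i], pos[j],
                                 abs(int(pos[j]) - int(pos[i])),
                                 res["r2"], res["d_prime"], "phased-count"))
        else:
            n = H.shape[1]
            p = H.mean(axis=1)
            P11 = (H @ H.T) / n
            denom = np.outer(p * (1 - p), p * (1 - p))
            D = P11 - np.outer(p, p)
            with np.errstate(divide="ignore", invalid="ignore"):
                r2 = np.where(denom > 0, D * D / denom, np.nan)
            # D' = |D| / Dmax with sign-dependent Dmax
            pa = p[:, None]
            pb = p[None, :]
            dmax_pos = np.minimum(pa * (1 - pb), (1 - pa) * pb)
            dmax_neg = np.minimum(pa * pb, (1 - pa) * (1 - pb))
            dmax = np.where(D > 0, dmax_pos, dmax_neg)
            with np.errstate(divide="ignore", invalid="ignore"):
                dp = np.where(dmax > 0, np.abs(D) / dmax, np.nan)
            iu, ju = np.triu_indices(m, k=1)
            rows = list(zip(ids[iu], ids[ju], pos[iu], pos[ju],
                            np.abs(pos[ju] - pos[iu]),
                            np.minimum(r2[iu, ju], 1.0),
                            np.minimum(dp[iu, ju], 1.0),
                            ["phased-count"] * len(iu)))
    else:
        dos = sub.dosages[idx]
        for i in range(m):
            for j in range(i + 1, m):
                r2, dp, _n, _conv = _pair_ld_unphased(dos[i], dos[j])
                rows.append((ids[i], ids[j], pos[i], pos[j],
                             abs(int(pos[j]) - int(pos[i])), r2, dp, "em"))
    return pd.DataFrame(rows, columns=["id_a", "id_b", "pos_a", "pos_b",
                                       "distance", "r2", "d_prime", "method"])


# ---------------------------------------------------------------------------
# Tagging
# ---------------------------------------------------------------------------

def greedy_tag_selection(pairs: pd.DataFrame, r2_min: float = 0.8,
                         variants: pd.DataFrame | None = None,
                         maf: dict | None = None) -> pd.DataFrame:
    """Greedy tag-SNP binning at an r^2 threshold.

    Repeatedly pick the variant covering the most untagged variants at
    r^2 >= r2_min, bin it with everything it covers, remove the bin, and
    repeat; variants covering nothing become singleton bins. Ties break
    on highest coverage, then highest MAF, then lowest position, so the
    output is deterministic.

    `variants` (id/pos frame restricted to the MAF-passing scope) fixes
    the binning universe; without it the universe is the ids appearing in
    `pairs`. Returns a frame: id, tag, bin (bin index in selection order).
    """
    if variants is not None:
        universe = list(variants["id"])
        posmap = dict(zip(variants["id"], variants["pos"]))
    else:
        universe = sorted(set(pairs["id_a"]) | set(pairs["id_b"]))
        posmap = {}
        for c in ("a", "b"):
            posmap.update(zip(pairs[f"id_{c}"], pairs[f"pos_{c}"]))
    maf = maf or {}
    strong = pairs[pairs["r2"] >= r2_min]
    adj: dict = {u: set() for u in universe}
    for ia, ib in zip(strong["id_a"], strong["id_b"]):
        if ia in adj and ib in adj:
            adj[ia].add(ib)
            adj[ib].add(ia)
    untagged = set(universe)
    assignments = []
    bin_no = 0
    while untagged:
        best = max(
            untagged,
            key=lambda u: (len(adj[u] & untagged), maf.get(u, 0.0),
                           -posmap.get(u, 0)),
        )
        members = (adj[best] & untagged) | {best}
        for mem in sorted(members, key=lambda u: posmap.get(u, 0)):
            assignments.append((mem, best, bin_no))
        untagged -= members
        bin_no += 1
    return pd.DataFrame(assignments, columns=["id", "tag", "bin"])


# ---------------------------------------------------------------------------
# Surrogates
# ---------------------------------------------------------------------------

@dataclass
class SurrogateSet:
    """Surrogates for one index SNP within one ancestral-group scope."""
    index_id: str
    scope: str
    surrogates: pd.DataFrame  # columns id, r2, distance, maf
    r2_min: float
    max_dist: int
    maf_min: float

    @property
    def count(self) -> int:
        return len(self.surrogates)


def find_surrogates(index_id: str, pairs: pd.DataFrame, maf: dict,
                    scope: str = "all", r2_min: float = 0.6,
                    max_dist: int = 200_000, maf_min: float = 0.05) -> SurrogateSet:
    """Surrogates of an index SNP: r^2 >= r2_min, distance <= max_dist (bp,
    1-based inclusive positions), surrogate MAF >= maf_min in scope.

    The index SNP itself need not pass the MAF filter (low-frequency
    index variants still get surrogates where LD allows); candidates
    must. Result is sorted by descending r^2.
    """
    if index_id not in maf:
        raise KeyError(f"index SNP {index_id!r} absent from genotype data")
    inv = pairs[(pairs["id_a"] == index_id) | (pairs["id_b"] == index_id)]
    rows = []
    for row in inv.itertuples(index=False):
        other = row.id_b if row.id_a == index_id else row.id_a
        if not np.isfinite(row.r2) or row.r2 < r2_min:
            continue
        if row.distance > max_dist:
            continue
        if maf.get(other, 0.0) < maf_min:
            continue
        rows.append((other, float(row.r2), int(row.distance),
                     float(maf.get(other, np.nan))))
    sur = pd.DataFrame(rows, columns=["id", "r2", "distance", "maf"])
    sur = sur.sort_values("r2", ascending=False, kind="mergesort").reset_index(drop=True)
    return SurrogateSet(index_id, scope, sur, r2_min, max_dist, maf_min)
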