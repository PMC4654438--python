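"""Population differentiation: Weir-Cockerham F_ST and hierarchical AMOVA.

The per-locus estimator is the Weir & Cockerham (1984) theta, built from
per-group sample sizes, allele frequencies and observed heterozygote
frequencies, decomposed into variance components

    a  among groups,
    b  among individuals within groups,
    c  within individuals,

with theta = a / (a + b + c). Negative component estimates are retained in
all arithmetic and reported as-is; loci monomorphic in the scoped samples
have an undefined theta (NaN) and are excluded from medians and multilocus
sums. Multi-locus F_ST is the ratio of sums sum(a) / sum(a+b+c).

AMOVA is the three-level allele-frequency (gene-copy indicator) analysis
of molecular variance: variance is partitioned among groups / among
populations within groups / within populations, with Phi indices and
permutation p-values under the scheme appropriate to each index.
All permutation p-values use the (exceedances + 1) / (n + 1) correction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotype_io import MISSING, GenotypeMatrix, SampleManifest

__all__ = [
    "wc_components",
    "wc_fst_per_locus",
    "MultilocusFst",
    "multilocus_fst",
    "pairwise_fst",
    "AmovaResult",
    "amova",
    "fst_spectrum_summary",
]


# ---------------------------------------------------------------------------
# Weir-Cockerham components
# ---------------------------------------------------------------------------

def _per_group_counts(dosages: np.ndarray, labels: np.ndarray):
    """Per-locus, per-group complete-case (n_i, p_i, h_i) arrays.

    n_i diploid counts, p_i alternate-allele frequency, h_i observed
    heterozygote frequency; shape (n_loci, n_groups). Group order is the
    sorted unique label order, also returned.
    """
    groups = np.unique(labels)
    valid = dosages != MISSING
    altd = np.where(valid, dosages, 0)
    hetd = dosages == 1
    n = np.empty((dosages.shape[0], len(groups)))
    p = np.empty_like(n)
    h = np.empty_like(n)
    for k, g in enumerate(groups):
        m = labels == g
        nk = valid[:, m].sum(axis=1)
        n[:, k] = nk
        with np.errstate(divide="ignore", invalid="ignore"):
            p[:, k] = altd[:, m].sum(axis=1) / (2.0 * nk)
            h[:, k] = hetd[:, m].sum(axis=1) / nk
    return n, p, h, groups


def wc_components(n: np.ndarray, p: np.ndarray, h: np.ndarray):
    """Weir-Cockerham (a, b, c) per locus from per-group summaries.

    Arguments are (n_loci, r) arrays of diploid sample sizes, allele
    frequencies and observed heterozygote frequencies. Loci where any
    group has fewer than 2 complete-case individuals are returned NaN.
    """
    n = np.asarray(n, dtype=float)
    p = np.asarray(p, dtype=float)
    h = np.asarray(h, dtype=float)
    r = n.shape[1]
    nbar = n.mean(axis=1)
    nsum = n.sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        nc = (nsum - (n**2).sum(axis=1) / nsum) / (r - 1.0)
        pbar = (n * p).sum(axis=1) / nsum
        s2 = (n * (p - pbar[:, None]) ** 2).sum(axis=1) / ((r - 1.0) * nbar)
        hbar = (n * h).sum(axis=1) / nsum
        inner = pbar * (1 - pbar) - (r - 1.0) / r * s2
        a = nbar / nc * (s2 - 1.0 / (nbar - 1.0) * (inner - hbar / 4.0))
        b = nbar / (nbar - 1.0) * (inner - (2.0 * nbar - 1.0) / (4.0 * nbar) * hbar)
        c = hbar / 2.0
    bad = (n < 2).any(axis=1)
    for arr in (a, b, c):
        arr[bad] = np.nan
    return a, b, c


def wc_fst_per_locus(geno: GenotypeMatrix, labels: np.ndarray,
                     variant_ids=None, n_permutations: int = 0,
                     seed: int | None = None, grouping: str = "group") -> pd.DataFrame:
    """Per-locus Weir-Cockerham theta over a group assignment.

    Returns a frame with columns ``id, grouping, a, b, c, fst, fis`` plus,
    when ``n_permutations > 0``, ``p_value, n_permutations, seed`` from
    permuting individuals among groups. ``fst`` is NaN for loci
    monomorphic in scope (a + b + c == 0); ``fis`` is the within-group
    component ratio b / (b + c), an F_IS-style statistic.
    """
    labels = np.asarray(labels)
    if len(labels) != geno.n_samples:
        raise ValueError("labels length must equal sample count")
    if len(np.unique(labels)) < 2:
        raise ValueError("need at least two groups")
    n, p, h, _ = _per_group_counts(geno.dosages, labels)
    a, b, c = wc_components(n, p, h)
    with np.errstate(divide="ignore", invalid="ignore"):
        denom = a + b + c
        fst = np.where(denom != 0, a / denom, np.nan)
        fis = np.where(b + c != 0, b / (b + c), np.nan)
    if variant_ids is None:
        variant_ids = np.arange(geno.n_variants)
    out = pd.DataFrame({"id": variant_ids, "grouping": grouping,
                        "a": a, "b": b, "c": c, "fst": fst, "fis": fis})
    if n_permutations > 0:
        if seed is None:
            raise ValueError("a seed is mandatory when permutations are requested")
        rng = np.random.default_rng(seed)
        exceed = np.zeros(geno.n_variants)
        defined = np.isfinite(fst)
        for _ in range(n_permutations):
            perm = rng.permutation(labels)
            pn, pp, ph, _ = _per_group_counts(geno.dosages, perm)
            pa, pb, pc = wc_components(pn, pp, ph)
            with np.errstate(divide="ignore", invalid="ignore"):
                pf = pa / (pa + pb + pc)
            exceed += np.where(defined & np.isfinite(pf), pf >= fst, 0)
        pval = (exceed + 1.0) / (n_permutations + 1.0)
        pval[~defined] = np.nan
        out["p_value"] = pval
        out["n_permutations"] = n_permutations
        out["seed"] = seed
    return out


@dataclass
class MultilocusFst:
    """Multi-locus F_ST: ratio of summed components plus the mean of ratios."""
    ratio_of_sums: float
    mean_of_ratios: float
    n_loci: int


def multilocus_fst(results: pd.DataFrame) -> MultilocusFst:
    """Combine per-locus components; loci with undefined theta are excluded.

    ``ratio_of_sums`` (sum a / sum(a+b+c)) is the reported estimator;
    ``mean_of_ratios`` is the simple average of per-locus theta used for
    per-category averages.
    """
    ok = results.dropna(subset=["fst"])
    if len(ok) == 0:
        raise ValueError("no locus with a defined F_ST")
    tot = (ok["a"] + ok["b"] + ok["c"]).sum()
    return MultilocusFst(
        ratio_of_sums=float(ok["a"].sum() / tot),
        mean_of_ratios=float(ok["fst"].mean()),
        n_loci=int(len(ok)),
    )


# ---------------------------------------------------------------------------
# Pairwise F_ST with permutation significance
# ---------------------------------------------------------------------------

def _two_group_ratio_of_sums(dos, valid, altd, hetd, member, n1tot=None):
    """Vectorised two-group multilocus WC theta for many membership vectors.

    ``member`` is (n_samples, n_perm) boolean for group 1; returns the
    ratio-of-sums theta per permutation (shape (n_perm,)).
    """
    n1 = valid.astype(float) @ member          # loci x perm
    a1 = altd.astype(float) @ member
    h1 = hetd.astype(float) @ member
    ntot = valid.sum(axis=1, keepdims=True)
    atot = altd.sum(axis=1, keepdims=True)
    htot = hetd.sum(axis=1, keepdims=True)
    n2 = ntot - n1
    a2 = atot - a1
    h2 = htot - h1
    with np.errstate(divide="ignore", invalid="ignore"):
        p1, p2 = a1 / (2 * n1), a2 / (2 * n2)
        hf1, hf2 = h1 / n1, h2 / n2
        nbar = (n1 + n2) / 2.0
        nsum = n1 + n2
        nc = (nsum - (n1**2 + n2**2) / nsum)  # r-1 = 1
        pbar = (n1 * p1 + n2 * p2) / nsum
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / nbar  # r-1 = 1
        hbar = (n1 * hf1 + n2 * hf2) / nsum
        inner = pbar * (1 - pbar) - s2 / 2.0
        a = nbar / nc * (s2 - (inner - hbar / 4.0) / (nbar - 1.0))
        b = nbar / (nbar - 1.0) * (inner - (2 * nbar - 1) / (4 * nbar) * hbar)
        c = hbar / 2.0
    bad = (n1 < 2) | (n2 < 2)
    a[bad] = np.nan
    b[bad] = np.nan
    c[bad] = np.nan
    denom = a + b + c
    ok = np.isfinite(denom) & (denom != 0)
    a_ok = np.where(ok, a, 0.0)
    d_ok = np.where(ok, denom, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        return a_ok.sum(axis=0) / d_ok.sum(axis=0)


def pairwise_fst(geno: GenotypeMatrix, manifest: SampleManifest,
                 level: str = "group", n_permutations: int = 10000,
                 seed: int | None = None, batch: int = 200):
    """Pairwise multilocus F_ST matrix with permutation p-values.

    Significance permutes individuals between the two units. Units with
    fewer than 2 individuals are skipped (NaN row/column) with a warning.
    Returns (fst_matrix, p_matrix) as symmetric DataFrames with zero
    diagonal (p diagonal NaN).
    """
    import warnings as _warnings

    if n_permutations > 0 and seed is None:
        raise ValueError("a seed is mandatory when permutations are requested")
    units = manifest.populations if level == "population" else manifest.groups
    labels = manifest.aligned_labels(geno.samples, level)
    fst_m = pd.DataFrame(np.zeros((len(units), len(units))), index=units, columns=units)
    p_m = pd.DataFrame(np.full((len(units), len(units)), np.nan), index=units,
                       columns=units)
    rng = np.random.default_rng(seed)
    sizes = {u: int((labels == u).sum()) for u in units}
    for i, u in enumerate(units):
        for j in range(i + 1, len(units)):
            v = units[j]
            if sizes[u] < 2 or sizes[v] < 2:
                _warnings.warn(f"pair ({u},{v}) skipped: unit with <2 individuals",
                               stacklevel=2)
                fst_m.loc[u, v] = fst_m.loc[v, u] = np.nan
                continue
            sel = np.flatnonzero((labels == u) | (labels == v))
            dos = geno.dosages[:, sel]
            valid = dos != MISSING
            altd = np.where(valid, dos, 0)
            hetd = dos == 1
            member_obs = (labels[sel] == u)[:, None]
            obs = _two_group_ratio_of_sums(dos, valid, altd, hetd,
                                           member_obs.astype(float))[0]
            fst_m.loc[u, v] = fst_m.loc[v, u] = obs
            if n_permutations > 0:
                n1 = sizes[u]
                exceed = 0
                done = 0
                while done < n_permutations:
                    nb = min(batch, n_permutations - done)
                    member = np.zeros((len(sel), nb))
                    for k in range(nb):
                        idx = rng.permutation(len(sel))[:n1]
                        member[idx, k] = 1.0
                    perm_stats = _two_group_ratio_of_sums(dos, valid, altd,
                                                          hetd, member)
                    exceed += int(np.sum(perm_stats >= obs))
                    done += nb
                pv = (exceed + 1.0) / (n_permutations + 1.0)
                p_m.loc[u, v] = p_m.loc[v, u] = pv
    return fst_m, p_m


# ---------------------------------------------------------------------------
# AMOVA
# ---------------------------------------------------------------------------

@dataclass
class AmovaResult:
    """Three-level AMOVA variance components and Phi fixation indices."""
    sigma2_a: float          # among groups
    sigma2_b: float          # among populations within groups
    sigma2_c: float          # within populations
    phi_ct: float
    phi_sc: float
    phi_st: float
    p_phi_ct: float | None = None
    p_phi_sc: float | None = None
    p_phi_st: float | None = None
    n_permutations: int = 0
    seed: int | None = None
    df: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        pct = 100.0 / (self.sigma2_a + self.sigma2_b + self.sigma2_c)
        return pd.DataFrame({
            "source": ["among_groups", "among_populations_within_groups",
                       "within_populations"],
            "sigma2": [self.sigma2_a, self.sigma2_b, self.sigma2_c],
            "pct_variation": [self.sigma2_a * pct, self.sigma2_b * pct,
                              self.sigma2_c * pct],
            "phi": [self.phi_ct, self.phi_sc, self.phi_st],
            "phi_label": ["phi_ct", "phi_sc", "phi_st"],
            "p_value": [self.p_phi_ct, self.p_phi_sc, self.p_phi_st],
        })


def _amova_components(dosages: np.ndarray, pop_idx: np.ndarray,
                      pop_group: np.ndarray, n_pops: int):
    """Summed-over-loci variance components (sigma_a, sigma_b, sigma_c).

    Gene-copy indicator AMOVA: per locus, sums of squares are functions of
    complete-case alternate-allele counts per population. ``pop_idx`` maps
    samples to population index, ``pop_group`` maps population index to
    group index. Components are computed per locus (each locus using its
    own complete-case copy counts) and summed; with complete data this
    equals the classical joint sums-of-squares decomposition.
    """
    valid = (dosages != MISSING)
    altd = np.where(valid, dosages, 0).astype(float)
    member = np.zeros((dosages.shape[1], n_pops))
    member[np.arange(dosages.shape[1]), pop_idx] = 1.0
    n_p = 2.0 * (valid.astype(float) @ member)      # copies per pop per locus
    c_p = altd @ member                              # alt copies per pop
    G = int(pop_group.max()) + 1
    gmat = np.zeros((n_pops, G))                     # pop -> group one-hot
    gmat[np.arange(n_pops), pop_group] = 1.0
    n_g = n_p @ gmat
    c_g = c_p @ gmat
    N = n_p.sum(axis=1)
    c_T = c_p.sum(axis=1)

    with np.errstate(divide="ignore", invalid="ignore"):
        ss_wp = np.where(n_p > 0, c_p - c_p**2 / n_p, 0.0).sum(axis=1)
        term_pg = np.where(n_p > 0, c_p**2 / n_p, 0.0).sum(axis=1)
        term_g = np.where(n_g > 0, c_g**2 / n_g, 0.0).sum(axis=1)
        ss_ap = term_pg - term_g
        ss_ag = term_g - c_T**2 / N

        P_eff = (n_p > 0).sum(axis=1).astype(float)
        G_eff = (n_g > 0).sum(axis=1).astype(float)
        df_wp = N - P_eff
        df_ap = P_eff - G_eff
        df_ag = G_eff - 1.0

        ms_wp = ss_wp / df_wp
        ms_ap = ss_ap / df_ap
        ms_ag = ss_ag / df_ag

        # coefficients of the expected mean squares
        np2_over_ng = (np.where(n_g > 0, ((n_p**2) @ gmat) / n_g, 0.0)).sum(axis=1)
        n_prime = (N - np2_over_ng) / df_ap
        n_dprime = (np2_over_ng - (n_p**2).sum(axis=1) / N) / df_ag
        n_tprime = (N - (n_g**2).sum(axis=1) / N) / df_ag

        s2c = ms_wp
        s2b = (ms_ap - s2c) / n_prime
        s2a = (ms_ag - s2c - n_dprime * s2b) / n_tprime
        # one population per group: the middle level has no degrees of
        # freedom and the design collapses to two levels (sigma2_b = 0)
        two_level = df_ap == 0
        s2b = np.where(two_level, 0.0, s2b)
        s2a = np.where(two_level, (ms_ag - s2c) / n_tprime, s2a)

    ok = np.isfinite(s2a) & np.isfinite(s2b) & np.isfinite(s2c)
    return (float(s2a[ok].sum()), float(s2b[ok].sum()), float(s2c[ok].sum()),
            {"among_groups": float(np.nanmean(df_ag)),
             "among_pops_within_groups": float(np.nanmean(df_ap)),
             "within_populations": float(np.nanmean(df_wp))})


def _phis(s2a, s2b, s2c):
    tot = s2a + s2b + s2c
    phi_st = (s2a + s2b) / tot if tot != 0 else np.nan
    phi_ct = s2a / tot if tot != 0 else np.nan
    phi_sc = s2b / (s2b + s2c) if (s2b + s2c) != 0 else np.nan
    return phi_ct, phi_sc, phi_st


def amova(geno: GenotypeMatrix, manifest: SampleManifest,
          n_permutations: int = 10000, seed: int | None = None) -> AmovaResult:
    """Hierarchical allele-frequency AMOVA (groups / populations / copies).

    Permutation schemes follow the level being tested: whole populations
    among groups (Phi_CT), individuals among populations within their
    group (Phi_SC), individuals among all populations (Phi_ST). A single
    group is degenerate: sigma2_a is undefined and a ValueError is raised.
    """
    pops = manifest.populations
    if len(manifest.groups) < 2:
        raise ValueError("AMOVA among groups needs >= 2 groups")
    if len(pops) < 2:
        raise ValueError("AMOVA needs >= 2 populations")
    if n_permutations > 0 and seed is None:
        raise ValueError("a seed is mandatory when permutations are requested")

    pop_of = manifest.aligned_labels(geno.samples, "population")
    pop_index = {p: i for i, p in enumerate(pops)}
    pop_idx = np.array([pop_index[p] for p in pop_of])
    group_of_pop = manifest.table.drop_duplicates("population").set_index(
        "population")["group"]
    groups = manifest.groups
    group_index = {g: i for i, g in enumerate(groups)}
    pop_group = np.array([group_index[group_of_pop[p]] for p in pops])

    s2a, s2b, s2c, df = _amova_components(geno.dosages, pop_idx, pop_group,
                                          len(pops))
    phi_ct, phi_sc, phi_st = _phis(s2a, s2b, s2c)
    res = AmovaResult(s2a, s2b, s2c, phi_ct, phi_sc, phi_st, df=df,
                      n_permutations=n_permutations, seed=seed)
    if n_permutations == 0:
        return res

    rng = np.random.default_rng(seed)
    exc_ct = exc_sc = exc_st = 0
    sample_group = pop_group[pop_idx]
    group_blocks = {g: np.flatnonzero(sample_group == gi)
                    for gi, g in enumerate(groups)}
    for _ in range(n_permutations):
        # Phi_ST: individuals among all populations
        perm = rng.permutation(pop_idx)
        a_, b_, c_, _d = _amova_components(geno.dosages, perm, pop_group, len(pops))
        _, _, pst = _phis(a_, b_, c_)
        if np.isfinite(pst) and pst >= phi_st:
            exc_st += 1
        # Phi_SC: individuals among populations within their group
        perm2 = pop_idx.copy()
        for gi in range(len(groups)):
            idx = group_blocks[groups[gi]]
            perm2[idx] = rng.permutation(pop_idx[idx])
        a_, b_, c_, _d = _amova_components(geno.dosages, perm2, pop_group, len(pops))
        _, psc, _ = _phis(a_, b_, c_)
        if np.isfinite(psc) and psc >= phi_sc:
            exc_sc += 1
        # Phi_CT: whole populations among groups
        permg = rng.permutation(pop_group)
        a_, b_, c_, _d = _amova_components(geno.dosages, pop_idx, permg, len(pops))
        pct_, _, _ = _phis(a_, b_, c_)
        if np.isfinite(pct_) and pct_ >= phi_ct:
            exc_ct += 1
    res.p_phi_st = (exc_st + 1.0) / (n_permutations + 1.0)
    res.p_phi_sc = (exc_sc + 1.0) / (n_permutations + 1.0)
    res.p_phi_ct = (exc_ct + 1.0) / (n_permutations + 1.0)
    return res


# ---------------------------------------------------------------------------
# Spectrum summary
# ---------------------------------------------------------------------------

def fst_spectrum_summary(results: pd.DataFrame, threshold: float = 0.10) -> dict:
    """Median per-locus F_ST and the fraction of loci below `threshold`.

    Loci with undefined (NaN) F_ST -- monomorphic in scope -- are excluded.
    """
    vals = results["fst"].dropna().to_numpy()
    if len(vals) == 0:
        raise ValueError("no locus with a defined F_ST")
    return {
        "median_fst": float(np.median(vals)),
        "fraction_below": float(np.mean(vals < threshold)),
        "threshold": threshold,
        "n_loci": int(len(vals)),
    }
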