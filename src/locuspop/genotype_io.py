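"""Genotype, sample-panel and variant-annotation I/O.

All external coordinates are VCF-style 1-based inclusive; any half-open
0-based arithmetic is confined to this module. Only biallelic SNVs are
retained -- multi-allelic records are dropped, not split, because every
downstream statistic (allele-frequency divergence, Weir-Cockerham F_ST,
two-locus LD) is defined for two alleles.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger("locuspop")

MISSING = -1  # sentinel for missing dosage / haplotype allele

CATEGORIES = (
    "upstream",
    "intron",
    "utr",
    "synonymous",
    "non-synonymous",
    "intergenic",
    "downstream",
)

#: categories pooled for the coding vs non-coding contrast
NONCODING_CATEGORIES = ("intron", "utr")
CODING_CATEGORIES = ("synonymous", "non-synonymous")

VARIANT_COLUMNS = ["chrom", "pos", "id", "ref", "alt", "gene", "category", "is_index"]


class GenotypeIOError(Exception):
    """Base class for genotype/panel/annotation input problems."""


class EmptyRegionError(GenotypeIOError):
    """No biallelic SNVs found in the requested region."""


class NoSamplesError(GenotypeIOError):
    """VCF has no sample columns."""


class PanelError(GenotypeIOError):
    """Malformed sample panel (duplicates, broken hierarchy)."""


@dataclass
class GenotypeMatrix:
    """Diploid genotypes for ``n_variants`` x ``n_samples``.

    dosages
        int8 array (n_variants, n_samples); alternate-allele count in
        {0, 1, 2} or :data:`MISSING`.
    haplotypes
        optional int8 array (n_variants, n_samples, 2) of phased alleles
        in {0, 1} or :data:`MISSING`; present iff the source was phased.
    """

    samples: list[str]
    dosages: np.ndarray
    haplotypes: np.ndarray | None = None
    phased: bool = False

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[1]

    def validate(self) -> None:
        if self.dosages.ndim != 2 or self.dosages.shape[1] != len(self.samples):
            raise ValueError("dosage shape inconsistent with sample list")
        ok = np.isin(self.dosages, (MISSING, 0, 1, 2))
        if not ok.all():
            raise ValueError("dosages must lie in {0,1,2} or be missing")
        if self.haplotypes is not None:
            if self.haplotypes.shape != (self.n_variants, self.n_samples, 2):
                raise ValueError("haplotype shape inconsistent with dosages")
            hsum = self.haplotypes.sum(axis=2)
            defined = (self.haplotypes >= 0).all(axis=2)
            if not np.array_equal(hsum[defined], self.dosages[defined]):
                raise ValueError("dosage != sum of haplotype alleles")

    def subset_samples(self, keep: np.ndarray | list) -> "GenotypeMatrix":
        """Column subset; `keep` is an index array or list of sample ids."""
        if len(keep) and isinstance(keep[0], str):
            pos = {s: i for i, s in enumerate(self.samples)}
            keep = np.array([pos[s] for s in keep])
        keep = np.asarray(keep)
        return GenotypeMatrix(
            samples=[self.samples[i] for i in keep],
            dosages=self.dosages[:, keep],
            haplotypes=None if self.haplotypes is None else self.haplotypes[:, keep, :],
            phased=self.phased,
        )

    def haplotype_matrix(self) -> np.ndarray:
        """Phased alleles as (n_variants, 2*n_samples) int8."""
        if self.haplotypes is None:
            raise ValueError("genotypes are unphased; no haplotypes available")
        return self.haplotypes.reshape(self.n_variants, 2 * self.n_samples)


@dataclass
class SampleManifest:
    """sample -> population -> ancestral-group hierarchy."""

    table: pd.DataFrame  # columns: sample, population, group

    def __post_init__(self) -> None:
        t = self.table
        if t["sample"].duplicated().any():
            dups = t.loc[t["sample"].duplicated(), "sample"].tolist()
            raise PanelError(f"duplicate sample id(s) in panel: {dups[:5]}")
        pop_groups = t.groupby("population")["group"].nunique()
        bad = pop_groups[pop_groups > 1]
        if len(bad):
            raise PanelError(f"population(s) mapped to >1 group: {list(bad.index)}")

    @property
    def samples(self) -> list[str]:
        return self.table["sample"].tolist()

    @property
    def populations(self) -> list[str]:
        return sorted(self.table["population"].unique())

    @property
    def groups(self) -> list[str]:
        return sorted(self.table["group"].unique())

    def group_of(self) -> pd.Series:
        return self.table.set_index("sample")["group"]

    def population_of(self) -> pd.Series:
        return self.table.set_index("sample")["population"]

    def samples_in_group(self, group: str) -> list[str]:
        t = self.table
        return t.loc[t["group"] == group, "sample"].tolist()

    def samples_in_population(self, pop: str) -> list[str]:
        t = self.table
        return t.loc[t["population"] == pop, "sample"].tolist()

    def aligned_labels(self, samples: list[str], level: str = "group") -> np.ndarray:
        """Labels for `samples` in order; level is 'group' or 'population'."""
        col = {"group": "group", "population": "population"}[level]
        m = self.table.set_index("sample")[col]
        return m.reindex(samples).to_numpy()


def validate_variant_table(variants: pd.DataFrame) -> pd.DataFrame:
    """Check VariantTable invariants; returns the (unmodified) frame."""
    missing_cols = set(VARIANT_COLUMNS) - set(variants.columns)
    if missing_cols:
        raise ValueError(f"variant table missing columns: {sorted(missing_cols)}")
    for chrom, sub in variants.groupby("chrom"):
        if not sub["pos"].is_monotonic_increasing:
            raise ValueError(f"positions not sorted on chromosome {chrom}")
    bad = set(variants["category"]) - set(CATEGORIES)
    if bad:
        raise ValueError(f"unknown categories: {sorted(bad)}")
    if variants["gene"].isna().any() or variants["category"].isna().any():
        raise ValueError("every variant needs a gene label and a category")
    return variants


# ---------------------------------------------------------------------------
# VCF input
# ---------------------------------------------------------------------------

_SNV_ALLELES = frozenset("ACGT")


def read_vcf(path: str, region: str | None = None):
    """Read biallelic SNVs from a VCF into (GenotypeMatrix, variant frame).

    `region` is a samtools-style "chrom:start-end" string (1-based,
    inclusive) and requires a tabix index; without one pass ``None`` and
    pre-slice the file. Non-SNV and multi-allelic records are dropped and
    counted in the log. The matrix is flagged phased only when every
    non-missing genotype in the file uses the phased separator.

    The variant frame carries placeholder annotation columns
    (gene='intergenic', category='intergenic', is_index=False) to be
    filled by :func:`assign_categories` / an annotation table.
    """
    from cyvcf2 import VCF

    try:
        vcf = VCF(path, gts012=True)
    except Exception as exc:  # cyvcf2 raises bare exceptions on bad paths
        raise GenotypeIOError(f"cannot open VCF {path!r}: {exc}") from exc
    samples = list(vcf.samples)
    if not samples:
        raise NoSamplesError(f"VCF {path!r} has no sample columns")

    records = vcf(region) if region else vcf
    dosage_rows: list[np.ndarray] = []
    hap_rows: list[np.ndarray] = []
    meta: list[tuple] = []
    n_dropped = 0
    all_phased = True
    for v in records:
        if len(v.ALT) != 1 or len(v.REF) != 1 or len(v.ALT[0]) != 1:
            n_dropped += 1
            continue
        if v.REF not in _SNV_ALLELES or v.ALT[0] not in _SNV_ALLELES:
            n_dropped += 1
            continue
        # gt_types with gts012: 0=hom-ref 1=het 2=hom-alt 3=missing
        dos = v.gt_types.astype(np.int8)
        dos[dos == 3] = MISSING
        dosage_rows.append(dos)
        ph = v.gt_phases
        gt = np.asarray(v.genotype.array(), dtype=np.int16)
        haps = gt[:, :2].astype(np.int8)
        haps[haps < 0] = MISSING
        hap_rows.append(haps)
        nonmiss = dos != MISSING
        if nonmiss.any() and not ph[nonmiss].all():
            all_phased = False
        meta.append((v.CHROM, v.POS, v.ID or f"{v.CHROM}:{v.POS}", v.REF, v.ALT[0]))

    if not meta:
        raise EmptyRegionError(
            f"no biallelic SNVs in {path!r}"
            + (f" region {region}" if region else "")
        )
    logger.info("read_vcf: kept %d variants, dropped %d records", len(meta), n_dropped)

    dosages = np.vstack(dosage_rows)
    haplotypes = np.stack(hap_rows) if all_phased else None
    geno = GenotypeMatrix(
        samples=samples, dosages=dosages, haplotypes=haplotypes, phased=all_phased
    )
    geno.validate()

    variants = pd.DataFrame(meta, columns=["chrom", "pos", "id", "ref", "alt"])
    variants["gene"] = "intergenic"
    variants["category"] = "intergenic"
    variants["is_index"] = False
    return geno, variants


def read_panel(path: str) -> SampleManifest:
    """Read a tab-separated sample panel (columns sample, population, group)."""
    t = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    needed = {"sample", "population", "group"}
    if not needed <= set(t.columns):
        raise PanelError(f"panel must have columns {sorted(needed)}; got {list(t.columns)}")
    return SampleManifest(t[["sample", "population", "group"]].copy())


def reconcile_samples(geno: GenotypeMatrix, manifest: SampleManifest,
                      exclude: list[str] | None = None):
    """Drop genotype samples absent from the panel (or excluded), warning.

    Returns (geno, manifest) restricted to the common sample set, genotype
    order preserved. Mirrors the study's removal of related individuals via
    an explicit exclusion list rather than kinship estimation.
    """
    exclude_set = set(exclude or ())
    panel = set(manifest.samples) - exclude_set
    keep = [s for s in geno.samples if s in panel]
    missing = [s for s in geno.samples if s not in panel and s not in exclude_set]
    if missing:
        warnings.warn(
            f"{len(missing)} genotyped sample(s) absent from panel; excluded",
            stacklevel=2,
        )
        logger.info("reconcile_samples: excluded %d unpanelled samples", len(missing))
    if exclude_set:
        logger.info("reconcile_samples: excluded %d listed samples", len(exclude_set))
    if not keep:
        raise PanelError("no overlap between genotype samples and panel")
    geno2 = geno.subset_samples(keep)
    t = manifest.table
    man2 = SampleManifest(t[t["sample"].isin(keep)].reset_index(drop=True))
    return geno2, man2


# ---------------------------------------------------------------------------
# Functional annotation
# ---------------------------------------------------------------------------

def read_annotation(path: str) -> pd.DataFrame:
    """Per-variant annotation TSV: id, gene, category[, is_index]."""
    t = pd.read_csv(path, sep="\t", dtype={"id": str, "gene": str, "category": str})
    if "is_index" not in t.columns:
        t["is_index"] = False
    t["is_index"] = t["is_index"].astype(bool)
    bad = set(t["category"]) - set(CATEGORIES)
    if bad:
        raise GenotypeIOError(f"annotation has unknown categories: {sorted(bad)}")
    return t[["id", "gene", "category", "is_index"]]


def apply_annotation(variants: pd.DataFrame, annotation: pd.DataFrame) -> pd.DataFrame:
    """Attach gene/category/is_index columns from an annotation table by id."""
    merged = variants.drop(columns=["gene", "category", "is_index"]).merge(
        annotation, on="id", how="left"
    )
    unann = merged["category"].isna()
    if unann.any():
        warnings.warn(f"{int(unann.sum())} variant(s) unannotated; labeled intergenic",
                      stacklevel=2)
        merged.loc[unann, "gene"] = "intergenic"
        merged.loc[unann, "category"] = "intergenic"
        merged.loc[unann, "is_index"] = False
    merged["is_index"] = merged["is_index"].astype(bool)
    return validate_variant_table(merged[VARIANT_COLUMNS])


def assign_categories(variants: pd.DataFrame, gene_model: pd.DataFrame) -> pd.DataFrame:
    """Label each variant from an interval gene model.

    `gene_model` rows carry ``gene, feature, start, end`` (1-based inclusive)
    with feature in {gene, exon, utr, upstream, downstream}, plus an optional
    ``consequence`` table behaviour: exonic coding consequence must be
    supplied per variant through a ``consequence`` column on `variants`
    ('synonymous' or 'non-synonymous'); consequence is an input, never
    predicted here. Precedence within a gene span: exon (-> consequence),
    then utr, then intron; outside spans: upstream/downstream intervals,
    else intergenic (with a warning).
    """
    variants = variants.copy()
    conseq = variants["consequence"] if "consequence" in variants.columns else None
    genes = []
    cats = []
    n_intergenic_warned = 0
    for i, (pos,) in enumerate(zip(variants["pos"])):
        hit = gene_model[(gene_model["start"] <= pos) & (pos <= gene_model["end"])]
        gene, cat = "intergenic", None
        for feature in ("exon", "utr", "gene", "upstream", "downstream"):
            rows = hit[hit["feature"] == feature]
            if len(rows) == 0:
                continue
            gene = rows.iloc[0]["gene"]
            if feature == "exon":
                c = None if conseq is None else conseq.iloc[i]
                if c not in ("synonymous", "non-synonymous"):
                    raise GenotypeIOError(
                        f"exonic variant {variants['id'].iloc[i]} lacks a coding "
                        "consequence (synonymous/non-synonymous)"
                    )
                cat = c
            elif feature == "gene":
                cat = "intron"
            elif feature in ("upstream", "downstream"):
                cat = feature
                gene = rows.iloc[0]["gene"]
            else:
                cat = "utr"
            break
        if cat is None:
            cat = "intergenic"
            gene = "intergenic"
            n_intergenic_warned += 1
        genes.append(gene)
        cats.append(cat)
    if n_intergenic_warned:
        warnings.warn(
            f"{n_intergenic_warned} variant(s) outside all annotation intervals; "
            "labeled intergenic", stacklevel=2,
        )
    variants["gene"] = genes
    variants["category"] = cats
    if "is_index" not in variants.columns:
        variants["is_index"] = False
    counts = pd.Series(cats).value_counts()
    logger.info("assign_categories: %s", counts.to_dict())
    return validate_variant_table(variants[VARIANT_COLUMNS])


# ---------------------------------------------------------------------------
# Output
# ---------------------------------------------------------------------------

def write_table(df: pd.DataFrame, path: str) -> None:
    """All report tables are headered TSV; float format is left to pandas."""
    df.to_csv(path, sep="\t", index=False)


def read_table(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_vcf(path: str, geno: GenotypeMatrix, variants: pd.DataFrame,
              seed: int | None = None) -> None:
    """Write phased (or unphased) genotypes as minimal VCF 4.2 text.

    Each file records the generating seed in its header when given, so a
    fixture is traceable to its configuration.
    """
    sep = "|" if geno.phased else "/"
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=locuspop\n")
        if seed is not None:
            fh.write(f"##locuspop_seed={seed}\n")
        for chrom in pd.unique(variants["chrom"]):
            maxpos = int(variants.loc[variants["chrom"] == chrom, "pos"].max())
            fh.write(f"##contig=<ID={chrom},length={maxpos + 10000}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(geno.samples) + "\n")
        if geno.haplotypes is not None:
            h = geno.haplotypes
            for i, row in enumerate(variants.itertuples(index=False)):
                gts = []
                for j in range(geno.n_samples):
                    a, b = h[i, j]
                    gts.append("." + sep + "." if a < 0 else f"{a}{sep}{b}")
                fh.write(f"{row.chrom}\t{row.pos}\t{row.id}\t{row.ref}\t{row.alt}"
                         f"\t.\tPASS\t.\tGT\t" + "\t".join(gts) + "\n")
        else:
            dosage_gt = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
            for i, row in enumerate(variants.itertuples(index=False)):
                gts = [dosage_gt[int(d)] for d in geno.dosages[i]]
                fh.write(f"{row.chrom}\t{row.pos}\t{row.id}\t{row.ref}\t{row.alt}"
                         f"\t.\tPASS\t.\tGT\t" + "\t".join(gts) + "\n")


def write_panel(path: str, manifest: SampleManifest) -> None:
    manifest.table.to_csv(path, sep="\t", index=False)


def write_annotation(path: str, variants: pd.DataFrame) -> None:
    variants[["id", "gene", "category", "is_index"]].to_csv(path, sep="\t", index=False)
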