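"""End-to-end locus report: one config in, six report tables out.

Runs every analysis stage over all scopes (full panel plus each ancestral
group): per-variant statistics, the per-functional-class summary table,
per-SNP F_ST with the index-SNP report, per-group diversity, pairwise
F_ST matrices with permutation significance, hierarchical AMOVA, LD/tag/
surrogate analysis per group, and category comparison tests. The run is
deterministic given config + seed; the log reconciles input variant
counts with every report's row totals. On any stage failure partial
outputs are removed.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import category_compare, differentiation, ld_tagging, summary_stats
from .genotype_io import (GenotypeMatrix, SampleManifest, apply_annotation,
                          read_annotation, read_panel, read_vcf,
                          reconcile_samples, write_table)

logger = logging.getLogger("locuspop")


@dataclass
class RunConfig:
    """All inputs and thresholds for one locus report.

    Defaults carry the analysis constants of the study design: tag
    r^2 >= 0.8, surrogate r^2 >= 0.6 within 200 kb at MAF >= 0.05, the
    F_ST spectrum threshold 0.10, and 10,000 permutations. There are no
    hidden defaults beyond these fields; the seed is mandatory whenever
    permutations are requested.
    """

    vcf: str
    panel: str
    outdir: str
    seed: int
    annotation: str | None = None
    index_snps: str | None = None        # file with one variant id per line
    exclude_samples: str | None = None   # related-individual exclusion list
    lengths: dict = field(default_factory=dict)  # class -> screened bp
    region: str | None = None
    tag_r2: float = 0.8
    surrogate_r2: float = 0.6
    surrogate_max_dist: int = 200_000
    maf_min: float = 0.05
    fst_threshold: float = 0.10
    n_permutations: int = 10_000
    annotation_passthrough: str | None = None  # extra index-SNP columns, copied

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)

    def validate(self) -> None:
        for name, v, lo, hi in [("tag_r2", self.tag_r2, 0, 1),
                                ("surrogate_r2", self.surrogate_r2, 0, 1),
                                ("maf_min", self.maf_min, 0, 0.5),
                                ("fst_threshold", self.fst_threshold, 0, 1)]:
            if not (lo <= v <= hi):
                raise ValueError(f"{name}={v} outside [{lo},{hi}]")
        if self.surrogate_max_dist <= 0 or self.n_permutations < 0:
            raise ValueError("bad distance or permutation count")
        if self.n_permutations > 0 and self.seed is None:
            raise ValueError("a seed is mandatory when permutations are requested")


REPORT_FILES = [
    "variant_stats.tsv",
    "category_summary.tsv",
    "index_snps.tsv",
    "group_diversity.tsv",
    "pairwise_fst.tsv",
    "pairwise_fst_p.tsv",
    "amova.tsv",
    "fst_spectrum.tsv",
    "gene_fst_summary.tsv",
    "surrogates.tsv",
    "tags.tsv",
    "comparisons.tsv",
    "correlations.tsv",
]


def run_locus_report(config: RunConfig) -> dict:
    """Execute the full analysis; returns {report name: path}.

    Any stage error aborts with a stage-attributed message after removing
    partial outputs from the output directory.
    """
    config.validate()
    os.makedirs(config.outdir, exist_ok=True)
    written: list[str] = []
    log_lines: list[str] = []

    def emit(name: str, df: pd.DataFrame) -> str:
        path = os.path.join(config.outdir, name)
        write_table(df, path)
        written.append(path)
        log_lines.append(f"{name}: {len(df)} rows")
        return path

    stage = "load"
    try:
        return _run(config, emit, written, log_lines)
    except Exception as exc:
        for path in written:
            if os.path.exists(path):
                os.remove(path)
        raise RuntimeError(f"pipeline failed at stage "
                           f"'{getattr(exc, '_stage', stage)}': {exc}") from exc


def _tag(exc: Exception, stage: str) -> Exception:
    exc._stage = stage
    return exc


def _run(config: RunConfig, emit, written, log_lines) -> dict:
    stage = "load"
    try:
        geno, variants = read_vcf(config.vcf, config.region)
        manifest = read_panel(config.panel)
        exclude = []
        if config.exclude_samples:
            with open(config.exclude_samples) as fh:
                exclude = [line.strip() for line in fh if line.strip()]
        geno, manifest = reconcile_samples(geno, manifest, exclude)
        if config.annotation:
            variants = apply_annotation(variants, read_annotation(config.annotation))
        if config.index_snps:
            with open(config.index_snps) as fh:
                idx_ids = {line.strip() for line in fh if line.strip()}
            variants["is_index"] = variants["id"].isin(idx_ids)
        log_lines.append(f"input: {geno.n_variants} variants x "
                         f"{geno.n_samples} samples "
                         f"({len(exclude)} excluded by list)")

        groups = manifest.groups
        group_labels = manifest.aligned_labels(geno.samples, "group")
        ids = variants["id"].to_list()
        region_L = config.lengths.get(
            "region", int(variants["pos"].max() - variants["pos"].min() + 1))

        stage = "variant_stats"
        scopes = {"all": None}
        scopes.update({g: manifest.samples_in_group(g) for g in groups})
        stats_by_scope = {}
        for scope, samples in scopes.items():
            st = summary_stats.allele_frequencies(geno, samples, variant_ids=ids)
            st.insert(1, "scope", scope)
            stats_by_scope[scope] = st
        emit("variant_stats.tsv", pd.concat(stats_by_scope.values(),
                                            ignore_index=True))

        stage = "per_snp_fst"
        fst_all = differentiation.wc_fst_per_locus(
            geno, group_labels, variant_ids=ids)
        spectrum = differentiation.fst_spectrum_summary(
            fst_all, config.fst_threshold)
        emit("fst_spectrum.tsv", pd.DataFrame([spectrum]))
        gene_rows = []
        vf = variants.merge(fst_all, on="id")
        for gene, sub in vf.groupby("gene"):
            gene_rows.append({
                "gene": gene,
                "n_loci": int(sub["fst"].notna().sum()),
                "median_fst_among_groups": float(sub["fst"].median()),
                "median_fis_within": float(sub["fis"].median()),
            })
        emit("gene_fst_summary.tsv", pd.DataFrame(gene_rows))

        stage = "category_summary"
        n_chrom_all = 2 * geno.n_samples
        lengths = dict(config.lengths)
        cat_tables = [category_compare.category_summary(
            variants, stats_by_scope["all"], lengths, n_chrom_all,
            fst=fst_all, scope="all")]
        for g in groups:
            n_chrom_g = 2 * len(scopes[g])
            cat_tables.append(category_compare.category_summary(
                variants, stats_by_scope[g], lengths, n_chrom_g,
                fst=fst_all, scope=g))
        emit("category_summary.tsv", pd.concat(cat_tables, ignore_index=True))

        stage = "index_snps"
        idx_var = variants[variants["is_index"]]
        perms_locus = min(config.n_permutations, 1000)
        if len(idx_var):
            sel = variants["is_index"].to_numpy()
            sub = GenotypeMatrix(geno.samples, geno.dosages[sel],
                                 None if geno.haplotypes is None
                                 else geno.haplotypes[sel], geno.phased)
            fst_idx = differentiation.wc_fst_per_locus(
                sub, group_labels, variant_ids=idx_var["id"].to_list(),
                n_permutations=perms_locus, seed=config.seed)
            tab2 = idx_var[["id", "pos", "gene", "category"]].copy()
            for g in groups:
                freq = stats_by_scope[g].set_index("id")["x2"]
                tab2[f"freq_{g}"] = tab2["id"].map(freq).to_numpy()
            tab2 = tab2.merge(fst_idx[["id", "fst", "p_value"]], on="id")
        else:
            tab2 = pd.DataFrame(columns=["id", "pos", "gene", "category",
                                         "fst", "p_value"])
        emit("index_snps.tsv", tab2)

        stage = "group_diversity"
        div_rows = []
        for g in groups:
            st = stats_by_scope[g]
            poly = (st["maf"] > 0) & st["maf"].notna()
            div_rows.append({
                "group": g,
                "n_individuals": len(scopes[g]),
                "n_polymorphic_loci": int(poly.sum()),
                "mean_het": float(st["het"].mean()),
                "sd_het": float(st["het"].std()),
                "nucleotide_diversity": summary_stats.nucleotide_diversity(
                    geno, region_L, scopes[g]),
            })
        emit("group_diversity.tsv", pd.DataFrame(div_rows))

        stage = "pairwise_fst"
        fst_m, p_m = differentiation.pairwise_fst(
            geno, manifest, level="group",
            n_permutations=config.n_permutations, seed=config.seed)
        emit("pairwise_fst.tsv", fst_m.rename_axis("unit").reset_index())
        emit("pairwise_fst_p.tsv", p_m.rename_axis("unit").reset_index())

        stage = "amova"
        am = differentiation.amova(geno, manifest,
                                   n_permutations=config.n_permutations,
                                   seed=config.seed)
        emit("amova.tsv", am.to_frame())

        stage = "ld_tagging"
        tag_tables, sur_counts = [], {}
        for g in groups:
            pairs = ld_tagging.ld_matrix(
                geno, variants, scope=scopes[g], maf_min=config.maf_min,
                keep_ids=idx_var["id"].to_list())
            st = stats_by_scope[g].set_index("id")
            maf_map = st["maf"].to_dict()
            passing = variants[variants["id"].map(maf_map).ge(config.maf_min)]
            tags = ld_tagging.greedy_tag_selection(
                pairs, config.tag_r2, variants=passing[["id", "pos"]],
                maf=maf_map)
            tags.insert(0, "scope", g)
            tag_tables.append(tags)
            for iid in idx_var["id"]:
                ss = ld_tagging.find_surrogates(
                    iid, pairs, maf_map, scope=g, r2_min=config.surrogate_r2,
                    max_dist=config.surrogate_max_dist, maf_min=config.maf_min)
                sur_counts.setdefault(iid, {})[g] = ss.count
        emit("tags.tsv", pd.concat(tag_tables, ignore_index=True)
             if tag_tables else pd.DataFrame(columns=["scope", "id", "tag", "bin"]))
        tab4 = idx_var[["id", "pos", "gene", "category"]].copy()
        for g in groups:
            tab4[f"surrogates_{g}"] = [sur_counts.get(i, {}).get(g, 0)
                                       for i in tab4["id"]]
        if config.annotation_passthrough:
            extra = pd.read_csv(config.annotation_passthrough, sep="\t",
                                dtype={"id": str})
            tab4 = tab4.merge(extra, on="id", how="left")
        emit("surrogates.tsv", tab4)

        stage = "comparisons"
        comp = [category_compare.compare_categories(
            variants, stats_by_scope["all"], fst=fst_all, scope="all")]
        for g in groups:
            comp.append(category_compare.compare_categories(
                variants, stats_by_scope[g], scope=g))
        emit("comparisons.tsv", pd.concat(comp, ignore_index=True))

        stage = "correlations"
        corr_rows = []
        for i, g1 in enumerate(groups):
            for g2 in groups[i + 1:]:
                for meas in ("maf", "het"):
                    a = stats_by_scope[g1][meas]
                    b = stats_by_scope[g2][meas]
                    corr_rows.append({
                        "group_a": g1, "group_b": g2, "measure": meas,
                        "r2": category_compare.group_correlation(a, b),
                    })
        emit("correlations.tsv", pd.DataFrame(corr_rows))

        # no timing in the log: every output file is byte-reproducible
        log_lines.append(f"seed={config.seed} "
                         f"permutations={config.n_permutations}")
        log_path = os.path.join(config.outdir, "run_log.txt")
        with open(log_path, "w") as fh:
            fh.write("\n".join(log_lines) + "\n")
        written.append(log_path)
        for line in log_lines:
            logger.info(line)
        return {os.path.basename(p): p for p in written}
    except Exception as exc:
        raise _tag(exc, stage)
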