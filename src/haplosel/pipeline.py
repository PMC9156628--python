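"""End-to-end orchestration: simulate -> classify -> popgen -> MK -> recomb
-> expectations -> comparisons, with a manifest recording thresholds, seed
and per-stage gene-drop accounting."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .comparisons import compare_across_classes, regress_on_bias
from .errors import ConfigurationError, ValidationError
from .expectation_model import class_expectations
from .expression_class import (
    classify_genes,
    normalize_median_of_ratios,
    filter_low_counts,
    intersection_counts,
    run_pairwise_de,
)
from .io_formats import (
    GeneModel,
    read_counts,
    read_fasta,
    read_gene_value_table,
    read_gff,
    read_linkage_map,
    read_outgroup,
    read_sample_meta,
    read_vcf,
    extract_codon_context,
    validate_cds_set,
)
from .errors import NotCodingError
from .popgen_stats import (
    classify_change,
    count_divergence,
    cpg_oe,
    gc_content,
    gene_pi,
    gene_site_counts,
)
from .recomb_map import gene_rates
from .selection_tests import class_positive_fractions, mk_table
from .synthetic_data import SimConfig, simulate_all

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    cds_fasta: str
    gff: str
    vcf: str
    outgroup: str
    counts: str
    sample_meta: str
    linkage_map: str
    outdir: str
    alpha_fdr: float = 0.01
    min_total: int = 10
    maf: float = 0.01
    maf_filters_counts: bool = False
    mk_p: float = 0.05
    dos_min: float = 0.0
    relax_factor: float = 0.5
    mate_h: float = 13.984
    dnds_table: Optional[str] = None
    gamma_table: Optional[str] = None
    seed: int = 0

    def __post_init__(self) -> None:
        for name, lo, hi in [("alpha_fdr", 0, 1), ("maf", 0, 0.5), ("mk_p", 0, 1)]:
            v = getattr(self, name)
            if not lo <= v <= hi:
                raise ConfigurationError(f"{name}={v} outside [{lo}, {hi}]")


def summarize_variants(
    genes: Sequence[GeneModel],
    cds_map: Mapping[str, str],
    variants: pd.DataFrame,
    outgroup: pd.DataFrame,
    maf_min: float = 0.01,
    maf_filters_counts: bool = False,
) -> pd.DataFrame:
    """Per-gene Ls/Ln, Pn/Ps, Dn/Ds, piS/piNS, GC and CpG o/e."""
    var_by_chrom = dict(tuple(variants.groupby("chrom"))) if len(variants) else {}
    out_by_chrom = dict(tuple(outgroup.groupby("chrom"))) if len(outgroup) else {}
    n_noncoding = 0
    rows = []
    for gene in genes:
        cds = cds_map.get(gene.gene_id)
        if cds is None:
            logger.warning("%s: no CDS sequence, gene skipped", gene.gene_id)
            continue
        ls, ln = gene_site_counts(cds)
        classified = []   # (effect, ac, an) for polymorphic sites
        fixed_alts: Dict[int, str] = {}
        poly_positions = set()
        sub = var_by_chrom.get(gene.chrom)
        if sub is not None:
            inside = sub[(sub["pos"] >= gene.start) & (sub["pos"] <= gene.end)]
            for row in inside.itertuples(index=False):
                try:
                    ctx = extract_codon_context(gene, cds, row.pos, row.ref, row.alt)
                except NotCodingError:
                    n_noncoding += 1
                    continue
                if row.an < 2:
                    logger.warning("%s:%s: AN < 2, site excluded", row.chrom, row.pos)
                    continue
                if 0 < row.ac < row.an:
                    effect = classify_change(ctx.codon, ctx.offset, ctx.alt)
                    classified.append((effect, row.ac, row.an))
                    poly_positions.add(ctx.cds_pos)
                elif row.ac == row.an:
                    fixed_alts[ctx.cds_pos] = ctx.alt
        out_alleles: Dict[int, str] = {}
        osub = out_by_chrom.get(gene.chrom)
        if osub is not None:
            inside = osub[(osub["pos"] >= gene.start) & (osub["pos"] <= gene.end)]
            for row in inside.itertuples(index=False):
                try:
                    cds_pos = gene.genomic_to_cds(row.pos)
                except NotCodingError:
                    continue
                allele = row.allele
                if gene.strand == "-":
                    from .popgen_stats import reverse_complement
                    allele = reverse_complement(allele)
                out_alleles[cds_pos] = allele
        dn, ds = count_divergence(cds, out_alleles, fixed_alts, poly_positions)
        pi_s, pi_ns = gene_pi(classified, ls, ln, maf_min=maf_min)
        if maf_filters_counts:
            counted = [
                (eff, ac, an) for eff, ac, an in classified
                if min(ac / an, 1 - ac / an) > maf_min
            ]
        else:
            counted = classified
        pn = sum(1 for eff, _, _ in counted if eff == "nonsynonymous")
        ps = sum(1 for eff, _, _ in counted if eff == "synonymous")
        rows.append({
            "gene_id": gene.gene_id,
            "ls": ls, "ln": ln,
            "pn": pn, "ps": ps,
            "dn": dn, "ds": ds,
            "pi_s": pi_s, "pi_ns": pi_ns,
            "pnps": pi_ns / pi_s if pi_s > 0 else np.nan,
            "gc": gc_content(cds),
            "cpg_oe": cpg_oe(cds),
        })
    if n_noncoding:
        logger.info("%d variants outside CDS retained as non-coding", n_noncoding)
    return pd.DataFrame(rows)


def expression_bias(counts: pd.DataFrame, meta: pd.DataFrame) -> pd.Series:
    """Per-gene log2 fold of haploid (male) over diploid (female) expression,
    on the normalized log2(x + 1) scale."""
    _, normalized = normalize_median_of_ratios(counts)
    log = np.log2(normalized + 1.0)
    male_cols = [c for c in log.columns if meta.loc[c, "sex"] == "male"]
    female_cols = [c for c in log.columns if meta.loc[c, "sex"] == "female"]
    return log[male_cols].mean(axis=1) - log[female_cols].mean(axis=1)


def summarize_by_class(
    master: pd.DataFrame,
    stat_cols: Sequence[str] = ("gc", "cpg_oe", "pi_s", "pi_ns", "pnps",
                                "dos", "recomb_rate"),
) -> pd.DataFrame:
    """Per-class n, means/medians, and positive-selection fractions."""
    rows = []
    for label, sub in master.groupby("label"):
        row = {"label": label, "n": len(sub)}
        for col in stat_cols:
            if col in sub:
                row[f"mean_{col}"] = sub[col].mean()
                row[f"median_{col}"] = sub[col].median()
        if "positive" in sub:
            row["fraction_positive"] = sub["positive"].mean()
        if "gamma" in sub and sub["gamma"].notna().any():
            row["fraction_gamma_gt1"] = (sub["gamma"] > 1).mean()
        rows.append(row)
    out = pd.DataFrame(rows)
    if out.empty:
        return out
    return out.sort_values("label").reset_index(drop=True)


def run_pipeline(cfg: PipelineConfig) -> Dict[str, Path]:
    """Execute every stage and write the report bundle to cfg.outdir."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    drops: Dict[str, int] = {}

    # --- load inputs
    cds_raw = read_fasta(cfg.cds_fasta)
    cds_map = validate_cds_set(cds_raw)
    drops["cds_internal_stop"] = len(cds_raw) - len(cds_map)
    genes = [g for g in read_gff(cfg.gff) if g.gene_id in cds_map]
    variants = read_vcf(cfg.vcf)
    outgroup = read_outgroup(cfg.outgroup)
    counts = read_counts(cfg.counts)
    meta = read_sample_meta(cfg.sample_meta, samples=counts.columns)
    linkage = read_linkage_map(cfg.linkage_map)

    # --- expression classification
    de = run_pairwise_de(counts, meta, min_total=cfg.min_total)
    drops["low_count_filter"] = len(counts) - de["gene_id"].nunique()
    classification = classify_genes(de, meta, alpha=cfg.alpha_fdr)
    intersections = intersection_counts(classification)

    # --- popgen and selection
    summaries = summarize_variants(
        genes, cds_map, variants, outgroup,
        maf_min=cfg.maf, maf_filters_counts=cfg.maf_filters_counts,
    )
    mk = mk_table(summaries, p_max=cfg.mk_p, dos_min=cfg.dos_min)

    # --- recombination
    rates = gene_rates(genes, linkage)
    rates = rates.rename(columns={"rate": "recomb_rate", "status": "recomb_status"})

    # --- master table
    master = (
        summaries.merge(mk, on="gene_id", how="left")
        .merge(classification, on="gene_id", how="left")
        .merge(rates, on="gene_id", how="left")
    )
    master["label"] = master["label"].fillna("unclassified")
    bias = expression_bias(counts, meta)
    master["log2_bias"] = master["gene_id"].map(bias)
    if cfg.dnds_table:
        master["dnds_external"] = master["gene_id"].map(
            read_gene_value_table(cfg.dnds_table, "dnds")
        )
    if cfg.gamma_table:
        master["gamma"] = master["gene_id"].map(
            read_gene_value_table(cfg.gamma_table, "gamma")
        )

    # --- expectations from observed constitutive values
    const = master[master["label"] == "constitutive"]
    pnps_const = float(const["pnps"].mean()) if const["pnps"].notna().any() else np.nan
    ds_sum, dn_sum = const["ds"].sum(), const["dn"].sum()
    ls_sum, ln_sum = const["ls"].sum(), const["ln"].sum()
    omega_const = (
        (dn_sum / ln_sum) / (ds_sum / ls_sum)
        if ds_sum > 0 and ln_sum > 0 else np.nan
    )
    if np.isfinite(pnps_const) and np.isfinite(omega_const) and omega_const > 0:
        expectations = pd.DataFrame(
            [vars(e) for e in class_expectations(
                pnps_const, omega_const, relax_factor=cfg.relax_factor, h=cfg.mate_h
            )]
        )
    else:
        logger.warning("constitutive class too sparse for expectations")
        expectations = pd.DataFrame()

    # --- comparisons
    comparison_table = compare_across_classes(
        master, responses=["gc", "cpg_oe", "pi_s", "pi_ns", "pnps", "dos",
                           "recomb_rate"],
    )
    regressions = []
    for resp in ("pi_s", "pi_ns", "dos"):
        sub = master.dropna(subset=[resp, "log2_bias"])
        if len(sub) >= 3 and sub["log2_bias"].var() > 0:
            beta, p = regress_on_bias(sub[resp], sub["log2_bias"])
            regressions.append({"response": resp, "beta": beta, "p": p,
                                "n": len(sub)})
    regressions = pd.DataFrame(regressions)

    class_summary = summarize_by_class(master)
    _, pairwise_fractions = class_positive_fractions(mk, classification)

    # --- write bundle
    paths = {
        "master": outdir / "master.tsv",
        "de": outdir / "de_results.tsv",
        "classification": outdir / "classification.tsv",
        "intersections": outdir / "intersections.tsv",
        "class_summary": outdir / "class_summary.tsv",
        "positive_fraction_tests": outdir / "positive_fraction_tests.tsv",
        "expectations": outdir / "expectations.tsv",
        "comparisons": outdir / "comparisons.tsv",
        "regressions": outdir / "regressions.tsv",
        "manifest": outdir / "manifest.json",
    }
    master.to_csv(paths["master"], sep="\t", index=False, float_format="%.10g")
    de.to_csv(paths["de"], sep="\t", index=False, float_format="%.10g")
    classification.to_csv(paths["classification"], sep="\t", index=False)
    intersections.to_csv(paths["intersections"], sep="\t", index=False)
    class_summary.to_csv(paths["class_summary"], sep="\t", index=False,
                         float_format="%.10g")
    pairwise_fractions.to_csv(paths["positive_fraction_tests"], sep="\t",
                              index=False, float_format="%.10g")
    expectations.to_csv(paths["expectations"], sep="\t", index=False,
                        float_format="%.10g")
    comparison_table.to_csv(paths["comparisons"], sep="\t", index=False,
                            float_format="%.10g")
    regressions.to_csv(paths["regressions"], sep="\t", index=False,
                       float_format="%.10g")

    checksum = hashlib.sha256(paths["master"].read_bytes()).hexdigest()
    manifest = {
        "version": __version__,
        "seed": cfg.seed,
        "thresholds": {
            "alpha_fdr": cfg.alpha_fdr,
            "min_total": cfg.min_total,
            "maf": cfg.maf,
            "maf_filters_counts": cfg.maf_filters_counts,
            "mk_p": cfg.mk_p,
            "dos_min": cfg.dos_min,
            "relax_factor": cfg.relax_factor,
            "mate_h": cfg.mate_h,
        },
        "gene_drops": drops,
        "n_genes_master": len(master),
        "master_sha256": checksum,
    }
    paths["manifest"].write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return paths


def run_demo(outdir, seed: int = 1, n_genes: int = 2000) -> Dict[str, Path]:
    """One-command synthetic demo: simulate then run the full pipeline."""
    outdir = Path(outdir)
    sim_dir = outdir / "sim_inputs"
    cfg = SimConfig(n_genes=n_genes, seed=seed)
    inputs = simulate_all(cfg, sim_dir)
    pcfg = PipelineConfig(
        cds_fasta=str(inputs["cds_fasta"]),
        gff=str(inputs["gff"]),
        vcf=str(inputs["vcf"]),
        outgroup=str(inputs["outgroup"]),
        counts=str(inputs["counts"]),
        sample_meta=str(inputs["sample_meta"]),
        linkage_map=str(inputs["linkage_map"]),
        outdir=str(outdir / "results"),
        seed=seed,
    )
    paths = run_pipeline(pcfg)
    paths.update({f"input_{k}": v for k, v in inputs.items()})
    return paths
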