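"""Synthetic input generator with known ground truth.

Produces every pipeline input — CDS FASTA, gene models, ingroup variants with
allele counts, a single-haplotype outgroup, an RNA-seq count matrix with
sample metadata, and a linkage map — from one seeded configuration, so each
downstream stage can be tested against planted truth without any downloads.

Planting scheme for variants: per gene, the number of synonymous polymorphic
sites is Poisson(theta_s * Ls * a1) with a1 = sum_{i<n} 1/i, nonsynonymous
Poisson(theta_s * omega_poly * Ln * a1); derived allele counts follow the
neutral frequency spectrum P(i) proportional to 1/i, which calibrates the
expected per-site pairwise diversity to theta_s. Fixed differences versus
the outgroup are Poisson(div_s * Ls) and Poisson(div_s * omega_div * Ln).
Every planted change is placed by rejection sampling at a codon position
where a single-nucleotide change realises the intended effect class, one
event per site.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .io_formats import (
    GeneModel,
    write_fasta,
    write_gff,
    write_linkage_map,
    write_outgroup,
    write_vcf,
)
from .popgen_stats import (
    BASES,
    GENETIC_CODE,
    SENSE_CODONS,
    STOP_CODONS,
    classify_change,
    gene_site_counts,
    reverse_complement,
)

logger = logging.getLogger(__name__)

CLASS_LABELS = ("haploid_biased", "diploid_biased", "constitutive", "unclassified")

_START = "ATG"
_STOPS = tuple(sorted(STOP_CODONS))
_NONSTOP = tuple(c for c in SENSE_CODONS if c != _START)

# distinct stream ids so each generator is deterministic on its own
_STREAM_SEQ, _STREAM_VAR, _STREAM_EXPR, _STREAM_MAP = 11, 13, 17, 19


@dataclass
class ClassParams:
    """Per-class planting rates for variants and expression."""

    omega_poly: float = 1.0   # scales nonsynonymous polymorphism
    omega_div: float = 1.0    # scales nonsynonymous divergence
    fold: float = 1.0         # expression fold-change in the planted group(s)

    def __post_init__(self) -> None:
        if self.omega_poly < 0 or self.omega_div < 0:
            raise ConfigurationError("omega values must be >= 0")
        if self.fold <= 0:
            raise ConfigurationError("fold must be > 0")


@dataclass
class ExprParams:
    baseline_mean: float = 200.0
    dispersion: float = 0.1
    n_per_group: int = 5
    adult_tissues: Tuple[str, ...] = ("gonad", "soma")
    include_larva: bool = True
    depth_sigma: float = 0.2   # lognormal sd of per-sample depth factors

    def __post_init__(self) -> None:
        if self.dispersion <= 0:
            raise ConfigurationError("dispersion must be > 0")
        if self.n_per_group < 2:
            raise ConfigurationError("need >= 2 samples per group")


@dataclass
class SimConfig:
    n_genes: int = 200
    gene_length_codons: Tuple[int, int] = (80, 120)  # inclusive range (or equal)
    theta_s: float = 0.02
    omega_poly: float = 1.0        # default for classes without an override
    div_s: float = 0.05
    omega_div: float = 1.0
    n_chromosomes_sampled: int = 22
    n_chromosomes: int = 16
    markers_per_chrom: int = 25
    recomb_rate_cm_per_mb: Optional[float] = None  # constant rate if set
    gene_spacing_bp: int = 2000
    class_fractions: Dict[str, float] = field(
        default_factory=lambda: {
            "haploid_biased": 0.1,
            "diploid_biased": 0.1,
            "constitutive": 0.1,
            "unclassified": 0.7,
        }
    )
    classes: Dict[str, ClassParams] = field(
        default_factory=lambda: {
            "haploid_biased": ClassParams(fold=8.0),
            "diploid_biased": ClassParams(fold=8.0),
            "constitutive": ClassParams(fold=8.0),
            "unclassified": ClassParams(),
        }
    )
    expr: ExprParams = field(default_factory=ExprParams)
    seed: int = 0

    def __post_init__(self) -> None:
        if isinstance(self.gene_length_codons, int):
            self.gene_length_codons = (self.gene_length_codons, self.gene_length_codons)
        lo, hi = self.gene_length_codons
        if lo < 2 or hi < lo:
            raise ConfigurationError(
                f"invalid gene length range {self.gene_length_codons}: need 2 <= lo <= hi"
            )
        for value, name in [(self.theta_s, "theta_s"), (self.div_s, "div_s"),
                            (self.omega_poly, "omega_poly"), (self.omega_div, "omega_div")]:
            if value < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if self.n_chromosomes_sampled < 2:
            raise ConfigurationError("n_chromosomes_sampled must be >= 2")
        unknown = set(self.class_fractions) - set(CLASS_LABELS)
        if unknown:
            raise ConfigurationError(f"unknown class labels {sorted(unknown)}")
        if abs(sum(self.class_fractions.values()) - 1.0) > 1e-9:
            raise ConfigurationError("class_fractions must sum to 1")

    def class_params(self, label: str) -> ClassParams:
        return self.classes.get(label, ClassParams(self.omega_poly, self.omega_div))


def _rng(cfg: SimConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([cfg.seed, stream])


def assign_classes(cfg: SimConfig) -> List[str]:
    """Deterministic per-gene class labels honouring class_fractions."""
    counts = {
        label: int(round(frac * cfg.n_genes))
        for label, frac in cfg.class_fractions.items()
    }
    # fix rounding drift on the filler class
    filler = "unclassified" if "unclassified" in counts else max(counts, key=counts.get)
    counts[filler] += cfg.n_genes - sum(counts.values())
    labels: List[str] = []
    for label in CLASS_LABELS:
        labels.extend([label] * counts.get(label, 0))
    rng = np.random.default_rng([cfg.seed, 5])
    order = rng.permutation(cfg.n_genes)
    return [labels[i] for i in order]


# ---------------------------------------------------------------------------
# CDS sequences and gene layout

def gen_gene_sequences(cfg: SimConfig) -> Tuple[List[GeneModel], Dict[str, str]]:
    """Random valid CDS records laid out on chromosomes, alternating strand.

    Each CDS starts with ATG, ends with a stop, and contains no internal stop.
    """
    rng = _rng(cfg, _STREAM_SEQ)
    lo, hi = cfg.gene_length_codons
    genes: List[GeneModel] = []
    cds_map: Dict[str, str] = {}
    cursor: Dict[str, int] = {}
    for i in range(cfg.n_genes):
        n_codons = int(rng.integers(lo, hi + 1))
        body = rng.choice(len(_NONSTOP), size=n_codons - 2) if n_codons > 2 else []
        codons = [_START] + [_NONSTOP[j] for j in body] + [_STOPS[rng.integers(len(_STOPS))]]
        if n_codons == 2:
            codons = [_START, _STOPS[rng.integers(len(_STOPS))]]
        cds = "".join(codons)
        gene_id = f"g{i:05d}"
        chrom = f"chr{(i % cfg.n_chromosomes) + 1}"
        start = cursor.get(chrom, 0) + cfg.gene_spacing_bp + 1
        end = start + len(cds) - 1
        cursor[chrom] = end
        strand = "+" if (i // cfg.n_chromosomes) % 2 == 0 else "-"
        genes.append(
            GeneModel(gene_id=gene_id, chrom=chrom, start=start, end=end,
                      strand=strand, cds_intervals=[(start, end)])
        )
        cds_map[gene_id] = cds
    return genes, cds_map


def chromosome_lengths(genes: Sequence[GeneModel], pad: int = 2000) -> Dict[str, int]:
    lengths: Dict[str, int] = {}
    for g in genes:
        lengths[g.chrom] = max(lengths.get(g.chrom, 0), g.end + pad)
    return lengths


# ---------------------------------------------------------------------------
# Variants and divergence

def _harmonic(n: int) -> float:
    return float(sum(1.0 / i for i in range(1, n)))


def _draw_sfs_count(rng: np.random.Generator, n: int) -> int:
    i = np.arange(1, n)
    w = 1.0 / i
    return int(rng.choice(i, p=w / w.sum()))


def _candidate_positions(cds: str) -> List[int]:
    """CDS offsets inside sense codons (stop codons carry no events)."""
    out = []
    for ci in range(len(cds) // 3):
        codon = cds[3 * ci: 3 * ci + 3]
        if codon in STOP_CODONS:
            continue
        out.extend(range(3 * ci, 3 * ci + 3))
    return out


def _plant_events(
    rng: np.random.Generator,
    cds: str,
    n_events: int,
    effect: str,
    used: set,
    used_codons: Optional[set] = None,
    max_tries: int = 2000,
) -> List[Tuple[int, str]]:
    """Rejection-sample (cds_pos, alt) pairs realising the requested effect.

    used_codons, when given, restricts planting to one event per codon (used
    for substitutions, whose truth labels would otherwise be blurred by
    multi-hit pathway averaging downstream).
    """
    candidates = _candidate_positions(cds)
    events: List[Tuple[int, str]] = []
    tries = 0
    while len(events) < n_events and tries < max_tries:
        tries += 1
        pos = candidates[rng.integers(len(candidates))]
        if pos in used:
            continue
        if used_codons is not None and pos // 3 in used_codons:
            continue
        ci, off = pos // 3, pos % 3
        codon = cds[3 * ci: 3 * ci + 3]
        alts = [b for b in BASES if b != codon[off]
                and classify_change(codon, off, b) == effect]
        if not alts:
            continue
        alt = alts[rng.integers(len(alts))]
        used.add(pos)
        if used_codons is not None:
            used_codons.add(pos // 3)
        events.append((pos, alt))
    if len(events) < n_events:
        logger.warning("could only place %d/%d %s events", len(events), n_events, effect)
    return events


def gen_variant_data(
    cfg: SimConfig,
    genes: Sequence[GeneModel],
    cds_map: Mapping[str, str],
    labels: Optional[Sequence[str]] = None,
) -> Tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Plant polymorphisms and fixed differences per gene.

    Returns (variant table, outgroup table, truth table). Variant/outgroup
    coordinates and alleles are genomic (forward strand); truth counts are
    per gene.
    """
    rng = _rng(cfg, _STREAM_VAR)
    labels = list(labels) if labels is not None else assign_classes(cfg)
    n = cfg.n_chromosomes_sampled
    a1 = _harmonic(n)
    var_rows = []
    out_rows = []
    truth_rows = []
    for gene, label in zip(genes, labels):
        cds = cds_map[gene.gene_id]
        params = cfg.class_params(label)
        ls, ln = gene_site_counts(cds)
        if ls == 0 and cfg.theta_s > 0:
            logger.warning("%s: Ls = 0, skipping synonymous planting", gene.gene_id)
        means = {
            ("poly", "synonymous"): cfg.theta_s * ls * a1,
            ("poly", "nonsynonymous"): cfg.theta_s * params.omega_poly * ln * a1,
            ("div", "synonymous"): cfg.div_s * ls,
            ("div", "nonsynonymous"): cfg.div_s * params.omega_div * ln,
        }
        used: set = set()
        used_div_codons: set = set()
        planted = {k: [] for k in means}
        for key in means:  # fixed iteration order for determinism
            n_events = int(rng.poisson(means[key])) if means[key] > 0 else 0
            planted[key] = _plant_events(
                rng, cds, n_events, key[1], used,
                used_codons=used_div_codons if key[0] == "div" else None,
            )
        flip = gene.strand == "-"
        for kind, effect in planted:
            for cds_pos, alt in planted[(kind, effect)]:
                pos = gene.cds_to_genomic(cds_pos)
                ref_g = cds[cds_pos] if not flip else reverse_complement(cds[cds_pos])
                alt_g = alt if not flip else reverse_complement(alt)
                if kind == "poly":
                    ac = _draw_sfs_count(rng, n)
                    var_rows.append((gene.chrom, pos, ref_g, alt_g, ac, n))
                else:
                    out_rows.append((gene.chrom, pos, alt_g))
        truth_rows.append({
            "gene_id": gene.gene_id,
            "label": label,
            "omega_poly": params.omega_poly,
            "omega_div": params.omega_div,
            "ls": ls,
            "ln": ln,
            "planted_ps": len(planted[("poly", "synonymous")]),
            "planted_pn": len(planted[("poly", "nonsynonymous")]),
            "planted_ds": len(planted[("div", "synonymous")]),
            "planted_dn": len(planted[("div", "nonsynonymous")]),
        })
    variants = pd.DataFrame(
        var_rows, columns=["chrom", "pos", "ref", "alt", "ac", "an"]
    ).sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
    outgroup = pd.DataFrame(
        out_rows, columns=["chrom", "pos", "allele"]
    ).sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
    truth = pd.DataFrame(truth_rows)
    return variants, outgroup, truth


# ---------------------------------------------------------------------------
# Expression counts

def expression_groups(expr: ExprParams) -> List[Tuple[str, str, str]]:
    """(sex, tissue, stage) groups in the simulated design."""
    groups = [(sex, tissue, "adult")
              for sex in ("male", "female") for tissue in expr.adult_tissues]
    if expr.include_larva:
        groups += [("male", "larva", "larva"), ("female", "larva", "larva")]
    return groups


def _planted_groups(label: str, rng: np.random.Generator,
                    groups: List[Tuple[str, str, str]]) -> List[Tuple[str, str, str]]:
    males = [g for g in groups if g[0] == "male"]
    females = [g for g in groups if g[0] == "female"]
    if label == "haploid_biased":
        return [males[rng.integers(len(males))]]
    if label == "diploid_biased":
        return [females[rng.integers(len(females))]]
    if label == "constitutive":
        # one group per sex within the same stage, in different tissues, so
        # both survive within-sex pairwise comparisons and the cross-stage
        # conflict rule never fires
        stages = {s for _, _, s in groups}
        multi = [s for s in sorted(stages)
                 if len({t for _, t, st in groups if st == s}) >= 2]
        pool_m, pool_f = males, females
        if multi:
            stage = multi[int(rng.integers(len(multi)))]
            pool_m = [g for g in males if g[2] == stage]
            pool_f = [g for g in females if g[2] == stage]
        m = pool_m[rng.integers(len(pool_m))]
        choices = [g for g in pool_f if g[1] != m[1]] or pool_f
        return [m, choices[rng.integers(len(choices))]]
    return []


def gen_expression_counts(
    cfg: SimConfig, labels: Optional[Sequence[str]] = None
) -> Tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Negative-binomial gene x sample counts with planted biased genes.

    Returns (counts, sample metadata, truth with planted group memberships).
    """
    rng = _rng(cfg, _STREAM_EXPR)
    labels = list(labels) if labels is not None else assign_classes(cfg)
    expr = cfg.expr
    groups = expression_groups(expr)
    samples = []
    meta_rows = []
    for sex, tissue, stage in groups:
        for k in range(expr.n_per_group):
            name = f"{sex}_{tissue}_{k + 1}"
            samples.append(name)
            meta_rows.append({"sample": name, "sex": sex, "tissue": tissue, "stage": stage})
    meta = pd.DataFrame(meta_rows).set_index("sample")
    depth = np.exp(rng.normal(0.0, expr.depth_sigma, size=len(samples)))

    gene_ids = [f"g{i:05d}" for i in range(cfg.n_genes)]
    base = expr.baseline_mean * np.exp(rng.normal(0.0, 0.5, size=cfg.n_genes))
    fold_matrix = np.ones((cfg.n_genes, len(groups)))
    truth_rows = []
    for gi, label in enumerate(labels):
        params = cfg.class_params(label)
        planted = _planted_groups(label, rng, groups) if params.fold != 1.0 else []
        for grp in planted:
            fold_matrix[gi, groups.index(grp)] = params.fold
        truth_rows.append({
            "gene_id": gene_ids[gi],
            "label": label,
            "planted_groups": ";".join(f"{s}_{t}" for s, t, _ in planted),
        })

    group_of_sample = np.array([groups.index((m["sex"], m["tissue"], m["stage"]))
                                for m in meta_rows])
    mu = base[:, None] * fold_matrix[:, group_of_sample] * depth[None, :]
    # NB with mean mu and variance mu + dispersion * mu^2
    r = 1.0 / expr.dispersion
    p = r / (r + mu)
    counts = rng.negative_binomial(r, p)
    counts_df = pd.DataFrame(counts, index=gene_ids, columns=samples)
    counts_df.index.name = "gene_id"
    truth = pd.DataFrame(truth_rows)
    return counts_df, meta, truth


# ---------------------------------------------------------------------------
# Linkage map

def gen_linkage_map(
    cfg: SimConfig, chrom_lengths: Optional[Mapping[str, int]] = None
) -> pd.DataFrame:
    """Markers with strictly increasing bp and non-decreasing cM per chromosome."""
    rng = _rng(cfg, _STREAM_MAP)
    if cfg.markers_per_chrom < 2:
        raise ConfigurationError("need >= 2 markers per chromosome")
    if chrom_lengths is None:
        chrom_lengths = {f"chr{i + 1}": 5_000_000 for i in range(cfg.n_chromosomes)}
    rows = []
    for chrom in chrom_lengths:
        length = int(chrom_lengths[chrom])
        bp = np.linspace(0, length, cfg.markers_per_chrom).astype(int)
        bp = np.unique(bp)
        if cfg.recomb_rate_cm_per_mb is not None:
            cm = bp / 1e6 * cfg.recomb_rate_cm_per_mb
        else:
            base_rate = rng.uniform(15.0, 30.0)  # cM/Mb, honey-bee-like scale
            seg_rates = base_rate * np.exp(rng.normal(0.0, 0.3, size=len(bp) - 1))
            cm = np.concatenate([[0.0], np.cumsum(seg_rates * np.diff(bp) / 1e6)])
        for b, c in zip(bp, cm):
            rows.append({"chrom": chrom, "bp": int(b), "cM": float(c)})
    return pd.DataFrame(rows, columns=["chrom", "bp", "cM"])


# ---------------------------------------------------------------------------
# One-shot writer

def simulate_all(cfg: SimConfig, outdir) -> Dict[str, Path]:
    """Generate and write every pipeline input plus the truth table."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    labels = assign_classes(cfg)
    genes, cds_map = gen_gene_sequences(cfg)
    variants, outgroup, var_truth = gen_variant_data(cfg, genes, cds_map, labels)
    counts, meta, expr_truth = gen_expression_counts(cfg, labels)
    lmap = gen_linkage_map(cfg, chromosome_lengths(genes))

    paths = {
        "cds_fasta": outdir / "cds.fasta",
        "gff": outdir / "genes.gff3",
        "vcf": outdir / "ingroup.vcf",
        "outgroup": outdir / "outgroup.tsv",
        "counts": outdir / "counts.tsv",
        "sample_meta": outdir / "samples.tsv",
        "linkage_map": outdir / "linkage_map.tsv",
        "truth": outdir / "truth.tsv",
    }
    write_fasta(cds_map, paths["cds_fasta"])
    write_gff(genes, paths["gff"])
    contigs = sorted({g.chrom for g in genes}, key=lambda c: int(c.replace("chr", "")))
    write_vcf(variants, paths["vcf"], contigs=contigs)
    write_outgroup(outgroup, paths["outgroup"])
    counts.to_csv(paths["counts"], sep="\t")
    meta.to_csv(paths["sample_meta"], sep="\t")
    write_linkage_map(lmap, paths["linkage_map"])
    truth = var_truth.merge(expr_truth[["gene_id", "planted_groups"]], on="gene_id")
    truth.to_csv(paths["truth"], sep="\t", index=False)
    return paths
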