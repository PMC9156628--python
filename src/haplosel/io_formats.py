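"""Readers and writers for the external formats the pipeline touches.

Coordinate convention is 1-based inclusive everywhere (VCF/GFF style); any
half-open arithmetic is internal. Multi-allelic VCF records are split into
independent biallelic records on read.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import NotCodingError, ValidationError
from .popgen_stats import BASES, STOP_CODONS, reverse_complement, translate

logger = logging.getLogger(__name__)

VARIANT_COLUMNS = ["chrom", "pos", "ref", "alt", "ac", "an"]
OUTGROUP_COLUMNS = ["chrom", "pos", "allele"]
LINKAGE_COLUMNS = ["chrom", "bp", "cM"]


@dataclass
class GeneModel:
    """A protein-coding gene with ordered CDS intervals (1-based inclusive)."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    cds_intervals: List[Tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValidationError(f"{self.gene_id}: strand must be '+' or '-'")
        if self.start > self.end:
            raise ValidationError(f"{self.gene_id}: start > end")
        ivs = sorted(self.cds_intervals)
        for (s, e) in ivs:
            if s > e:
                raise ValidationError(f"{self.gene_id}: CDS interval {s}>{e}")
        for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
            if s2 <= e1:
                raise ValidationError(f"{self.gene_id}: overlapping CDS intervals")
        self.cds_intervals = ivs
        if self.cds_length % 3 != 0:
            raise ValidationError(
                f"{self.gene_id}: CDS length {self.cds_length} not divisible by 3"
            )

    @property
    def cds_length(self) -> int:
        return sum(e - s + 1 for s, e in self.cds_intervals)

    def contains(self, pos: int) -> bool:
        return any(s <= pos <= e for s, e in self.cds_intervals)

    def genomic_to_cds(self, pos: int) -> int:
        """Map a genomic position to a 0-based offset along the coding strand."""
        offset = 0
        for s, e in self.cds_intervals:
            if s <= pos <= e:
                plus_offset = offset + (pos - s)
                if self.strand == "+":
                    return plus_offset
                return self.cds_length - 1 - plus_offset
            offset += e - s + 1
        raise NotCodingError(f"{self.gene_id}: position {pos} not in CDS")

    def cds_to_genomic(self, cds_pos: int) -> int:
        """Inverse of :meth:`genomic_to_cds`."""
        if not 0 <= cds_pos < self.cds_length:
            raise ValidationError(f"{self.gene_id}: CDS offset {cds_pos} out of range")
        plus_offset = cds_pos if self.strand == "+" else self.cds_length - 1 - cds_pos
        for s, e in self.cds_intervals:
            span = e - s + 1
            if plus_offset < span:
                return s + plus_offset
            plus_offset -= span
        raise AssertionError("unreachable")


@dataclass
class CodonContext:
    """Strand-adjusted codon context of a variant."""

    codon: str
    offset: int          # 0-based position of the variant within the codon
    codon_index: int     # 0-based codon number along the CDS
    cds_pos: int         # 0-based CDS offset of the variant
    ref: str             # coding-strand reference allele
    alt: str             # coding-strand alternate allele


def extract_codon_context(
    gene: GeneModel, cds: str, pos: int, ref: str, alt: str
) -> CodonContext:
    """Locate a variant in its codon, reverse-complementing on '-' strand."""
    if len(cds) != gene.cds_length:
        raise ValidationError(
            f"{gene.gene_id}: CDS sequence length {len(cds)} != model {gene.cds_length}"
        )
    cds_pos = gene.genomic_to_cds(pos)  # raises NotCodingError outside CDS
    if gene.strand == "-":
        ref, alt = reverse_complement(ref), reverse_complement(alt)
    if cds[cds_pos] != ref:
        raise ValidationError(
            f"{gene.gene_id}: reference allele {ref} does not match CDS base "
            f"{cds[cds_pos]} at CDS offset {cds_pos}"
        )
    codon_index = cds_pos // 3
    offset = cds_pos % 3
    codon = cds[3 * codon_index: 3 * codon_index + 3]
    return CodonContext(codon, offset, codon_index, cds_pos, ref, alt)


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path) -> Dict[str, str]:
    records = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        records[rec.id] = str(rec.seq).upper()
    if not records:
        raise ValidationError(f"{path}: no FASTA records found")
    return records


def write_fasta(seqs: Mapping[str, str], path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


def validate_cds_set(seqs: Mapping[str, str]) -> Dict[str, str]:
    """Drop CDS with internal stops (logged); validate frame and characters."""
    kept = {}
    for name, seq in seqs.items():
        if len(seq) % 3 != 0:
            raise ValidationError(f"{name}: CDS length {len(seq)} not divisible by 3")
        aa = translate(seq)
        if "*" in aa[:-1]:
            logger.warning("%s: premature internal stop codon; gene excluded", name)
            continue
        kept[name] = seq
    return kept


# ---------------------------------------------------------------------------
# GFF3 / BED gene models

def write_gff(genes: Sequence[GeneModel], path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            fh.write(
                f"{g.chrom}\thaplosel\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t"
                f"ID={g.gene_id}\n"
            )
            for s, e in g.cds_intervals:
                fh.write(
                    f"{g.chrom}\thaplosel\tCDS\t{s}\t{e}\t.\t{g.strand}\t0\t"
                    f"ID=cds-{g.gene_id};Parent={g.gene_id}\n"
                )


def _parse_gff_attributes(attr: str) -> Dict[str, str]:
    out = {}
    for item in attr.strip().split(";"):
        if not item:
            continue
        if "=" not in item:
            continue
        k, v = item.split("=", 1)
        out[k.strip()] = v.strip()
    return out


def read_gff(path) -> List[GeneModel]:
    """Parse gene models from GFF3 gene + CDS features."""
    genes: Dict[str, dict] = {}
    cds: Dict[str, List[Tuple[int, int]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 9:
                raise ValidationError(
                    f"{path}:{lineno}: expected 9 tab-separated fields, got {len(fields)}"
                )
            chrom, _source, ftype, start, end, _score, strand, _frame, attr = fields
            try:
                start_i, end_i = int(start), int(end)
            except ValueError as exc:
                raise ValidationError(f"{path}:{lineno}: non-integer coordinate") from exc
            attrs = _parse_gff_attributes(attr)
            if ftype == "gene":
                gid = attrs.get("ID")
                if gid is None:
                    raise ValidationError(f"{path}:{lineno}: gene feature lacks ID")
                genes[gid] = dict(chrom=chrom, start=start_i, end=end_i, strand=strand)
            elif ftype == "CDS":
                parent = attrs.get("Parent") or attrs.get("ID")
                if parent is None:
                    raise ValidationError(f"{path}:{lineno}: CDS lacks Parent/ID")
                cds.setdefault(parent, []).append((start_i, end_i))
    models = []
    for gid, info in genes.items():
        models.append(
            GeneModel(
                gene_id=gid,
                chrom=info["chrom"],
                start=info["start"],
                end=info["end"],
                strand=info["strand"],
                cds_intervals=cds.get(gid, [(info["start"], info["end"])]),
            )
        )
    if not models:
        raise ValidationError(f"{path}: no gene features found")
    return models


def read_bed(path) -> List[GeneModel]:
    """Alternative gene input: BED6, one single-interval CDS per line."""
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        names=["chrom", "start", "end", "name", "score", "strand"],
        usecols=range(6),
    )
    models = []
    for row in df.itertuples(index=False):
        start = int(row.start) + 1  # BED is 0-based half-open
        end = int(row.end)
        models.append(
            GeneModel(
                gene_id=str(row.name), chrom=str(row.chrom), start=start, end=end,
                strand=str(row.strand), cds_intervals=[(start, end)],
            )
        )
    return models


# ---------------------------------------------------------------------------
# VCF

def validate_variant_table(df: pd.DataFrame, source: str = "variant table") -> pd.DataFrame:
    missing = [c for c in VARIANT_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{source}: missing columns {missing}")
    df = df[VARIANT_COLUMNS].copy()
    for i, row in enumerate(df.itertuples(index=False)):
        if row.ref not in BASES or row.alt not in BASES:
            raise ValidationError(
                f"{source}: record {i} ({row.chrom}:{row.pos}): "
                f"single-nucleotide ACGT alleles required, got {row.ref}>{row.alt}"
            )
        if row.ref == row.alt:
            raise ValidationError(
                f"{source}: record {i} ({row.chrom}:{row.pos}): ref == alt"
            )
        if not 0 <= row.ac <= row.an:
            raise ValidationError(
                f"{source}: record {i} ({row.chrom}:{row.pos}): "
                f"AC={row.ac} outside [0, AN={row.an}]"
            )
    return df


def read_vcf(path) -> pd.DataFrame:
    """Read biallelic SNV records (splitting multi-allelics) into a table.

    AC/AN are taken from INFO when present, otherwise computed from genotypes.
    Non-SNV alleles are skipped with a log entry.
    """
    from cyvcf2 import VCF

    rows = []
    vcf = VCF(str(path))
    for rec in vcf:
        if rec.REF not in BASES:
            logger.info("%s:%s skipped: non-SNV reference allele", rec.CHROM, rec.POS)
            continue
        an = rec.INFO.get("AN")
        acs = rec.INFO.get("AC")
        if acs is None or an is None:
            gts = np.asarray(rec.genotype.array())[:, :-1]
            called = gts[gts >= 0]
            an = int(called.size)
            acs = [int((called == (i + 1)).sum()) for i in range(len(rec.ALT))]
        elif isinstance(acs, (int, float)):
            acs = [int(acs)]
        else:
            acs = [int(a) for a in acs]
        for alt, ac in zip(rec.ALT, acs):
            if alt not in BASES:
                logger.info("%s:%s skipped: non-SNV alt %s", rec.CHROM, rec.POS, alt)
                continue
            rows.append((rec.CHROM, int(rec.POS), rec.REF, alt, int(ac), int(an)))
    df = pd.DataFrame(rows, columns=VARIANT_COLUMNS)
    return validate_variant_table(df, source=str(path))


def write_vcf(df: pd.DataFrame, path, contigs: Optional[Sequence[str]] = None) -> None:
    df = validate_variant_table(df)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=AC,Number=A,Type=Integer,Description="Alternate allele count">\n')
        fh.write('##INFO=<ID=AN,Number=1,Type=Integer,Description="Total called alleles">\n')
        if contigs:
            for c in contigs:
                fh.write(f"##contig=<ID={c}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        ordered = df.sort_values(["chrom", "pos"], kind="mergesort")
        for row in ordered.itertuples(index=False):
            fh.write(
                f"{row.chrom}\t{row.pos}\t.\t{row.ref}\t{row.alt}\t.\tPASS\t"
                f"AC={row.ac};AN={row.an}\n"
            )


# ---------------------------------------------------------------------------
# TSV tables

def read_outgroup(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "pos": int, "allele": str})
    missing = [c for c in OUTGROUP_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing columns {missing}")
    bad = ~df["allele"].isin(list(BASES))
    if bad.any():
        raise ValidationError(f"{path}: non-ACGT outgroup allele at row {bad.idxmax()}")
    return df[OUTGROUP_COLUMNS]


def write_outgroup(df: pd.DataFrame, path) -> None:
    df[OUTGROUP_COLUMNS].to_csv(path, sep="\t", index=False)


def read_counts(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if (df.values < 0).any():
        raise ValidationError(f"{path}: negative counts present")
    if not np.issubdtype(df.values.dtype, np.integer):
        if not np.allclose(df.values, np.round(df.values)):
            raise ValidationError(f"{path}: counts must be integers")
        df = df.astype(int)
    return df


def read_sample_meta(path, samples: Optional[Iterable[str]] = None) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    required = {"sex", "tissue", "stage"}
    missing = required - set(meta.columns)
    if missing:
        raise ValidationError(f"{path}: missing metadata columns {sorted(missing)}")
    if meta[sorted(required)].isna().any().any():
        raise ValidationError(f"{path}: incomplete sample metadata")
    bad_sex = ~meta["sex"].isin(["male", "female"])
    if bad_sex.any():
        raise ValidationError(f"{path}: sex must be male/female")
    if samples is not None:
        absent = [s for s in samples if s not in meta.index]
        if absent:
            raise ValidationError(f"{path}: metadata missing for samples {absent}")
    return meta


def read_linkage_map(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "bp": int, "cM": float})
    missing = [c for c in LINKAGE_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing columns {missing}")
    for chrom, sub in df.groupby("chrom", sort=False):
        bp = sub["bp"].to_numpy()
        cm = sub["cM"].to_numpy()
        if not np.all(np.diff(bp) > 0):
            raise ValidationError(f"{path}: {chrom}: physical positions not strictly increasing")
        if not np.all(np.diff(cm) >= 0):
            raise ValidationError(f"{path}: {chrom}: genetic positions decrease")
    return df[LINKAGE_COLUMNS]


def write_linkage_map(df: pd.DataFrame, path) -> None:
    df[LINKAGE_COLUMNS].to_csv(path, sep="\t", index=False)


def read_gene_value_table(path, value_col: str) -> pd.Series:
    """Side tables of per-gene scalars (external dN/dS, gamma)."""
    df = pd.read_csv(path, sep="\t")
    if "gene_id" not in df.columns or value_col not in df.columns:
        raise ValidationError(f"{path}: need columns gene_id and {value_col}")
    return df.set_index("gene_id")[value_col].astype(float)
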