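"""Codon-aware polymorphism, divergence and composition statistics.

Site counting follows the equal-weight Nei–Gojobori scheme: at each codon
position the synonymous fraction is the share of the three possible
single-nucleotide changes that preserve the amino acid; changes creating a
stop codon count as nonsynonymous, and reference stop codons are excluded
from all denominators.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Dict, Iterable, Mapping, Optional, Sequence, Set, Tuple

import numpy as np

from .errors import ValidationError

BASES = "ACGT"

# Standard genetic code; "*" marks stops.
GENETIC_CODE: Dict[str, str] = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}

STOP_CODONS = frozenset(c for c, aa in GENETIC_CODE.items() if aa == "*")
SENSE_CODONS = tuple(sorted(c for c, aa in GENETIC_CODE.items() if aa != "*"))

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def translate(cds: str) -> str:
    """Translate an in-frame CDS; raises on non-ACGT or ragged length."""
    if len(cds) % 3 != 0:
        raise ValidationError(f"CDS length {len(cds)} not divisible by 3")
    return "".join(GENETIC_CODE[cds[i:i + 3]] for i in range(0, len(cds), 3))


def _check_codon(codon: str) -> None:
    if len(codon) != 3 or any(b not in BASES for b in codon):
        raise ValidationError(f"invalid codon {codon!r}: must be 3 bases of ACGT")


class StopCodonError(ValidationError):
    """Signal that a reference stop codon was passed where a sense codon is required."""


def codon_site_counts(codon: str) -> Tuple[float, float]:
    """Fractional synonymous/nonsynonymous site counts for one sense codon.

    ls is the sum over the three positions of the fraction of the three
    possible single-nucleotide changes that are synonymous; ln = 3 - ls.
    """
    _check_codon(codon)
    if codon in STOP_CODONS:
        raise StopCodonError(f"stop codon {codon} excluded from site counting")
    aa = GENETIC_CODE[codon]
    syn = 0
    for pos in range(3):
        for alt in BASES:
            if alt == codon[pos]:
                continue
            mutant = codon[:pos] + alt + codon[pos + 1:]
            if GENETIC_CODE[mutant] == aa:  # change to stop is never synonymous
                syn += 1
    ls = syn / 3.0
    return ls, 3.0 - ls


def classify_change(codon: str, offset: int, alt_base: str) -> str:
    """Classify a single-nucleotide change as 'synonymous' or 'nonsynonymous'."""
    _check_codon(codon)
    if codon in STOP_CODONS:
        raise StopCodonError(f"reference stop codon {codon} excluded")
    if offset not in (0, 1, 2):
        raise ValidationError(f"offset must be 0, 1 or 2, got {offset}")
    if alt_base not in BASES:
        raise ValidationError(f"invalid alternate base {alt_base!r}")
    if alt_base == codon[offset]:
        raise ValidationError("alternate base equals reference base")
    mutant = codon[:offset] + alt_base + codon[offset + 1:]
    return "synonymous" if GENETIC_CODE[mutant] == GENETIC_CODE[codon] else "nonsynonymous"


def gene_site_counts(cds: str) -> Tuple[float, float]:
    """Sum NG86 (Ls, Ln) over the sense codons of a CDS.

    The terminal stop codon (and any stop, should one occur) contributes
    nothing to either total.
    """
    if len(cds) % 3 != 0:
        raise ValidationError(f"CDS length {len(cds)} not divisible by 3")
    ls_total = 0.0
    ln_total = 0.0
    for i in range(0, len(cds), 3):
        codon = cds[i:i + 3]
        if codon in STOP_CODONS:
            continue
        ls, ln = codon_site_counts(codon)
        ls_total += ls
        ln_total += ln
    return ls_total, ln_total


def site_pi(ac: int, an: int) -> float:
    """Unbiased per-site nucleotide diversity from allele counts.

    pi = (an/(an-1)) * (1 - p^2 - q^2), the mean pairwise difference over all
    an*(an-1)/2 chromosome pairs.
    """
    if an < 2:
        raise ValidationError(f"need at least 2 called alleles, got an={an}")
    if not 0 <= ac <= an:
        raise ValidationError(f"allele count out of range: ac={ac}, an={an}")
    p = ac / an
    q = 1.0 - p
    return (an / (an - 1.0)) * (1.0 - p * p - q * q)


def gene_pi(
    variants: Iterable[Tuple[str, int, int]],
    ls: float,
    ln: float,
    maf_min: float = 0.01,
) -> Tuple[float, float]:
    """Per-site synonymous and nonsynonymous diversity for one gene.

    Parameters
    ----------
    variants : iterable of (effect, ac, an)
        effect is 'synonymous' or 'nonsynonymous'; sites with minor allele
        frequency <= maf_min are excluded (strictly-greater filter).
    ls, ln : NG86 site totals; a zero denominator yields NaN (flagged).

    Returns (piS, piNS).
    """
    sum_s = 0.0
    sum_n = 0.0
    for effect, ac, an in variants:
        if effect not in ("synonymous", "nonsynonymous"):
            raise ValidationError(f"unclassified variant effect {effect!r}")
        p = ac / an
        if min(p, 1.0 - p) <= maf_min:
            continue
        contrib = site_pi(ac, an)
        if effect == "synonymous":
            sum_s += contrib
        else:
            sum_n += contrib
    pi_s = sum_s / ls if ls > 0 else math.nan
    pi_ns = sum_n / ln if ln > 0 else math.nan
    return pi_s, pi_ns


def _step_class(codon_from: str, codon_to: str) -> str:
    aa1, aa2 = GENETIC_CODE[codon_from], GENETIC_CODE[codon_to]
    if aa1 == aa2 and aa1 != "*":
        return "synonymous"
    return "nonsynonymous"


def codon_path_counts(codon_in: str, codon_out: str) -> Tuple[float, float]:
    """NG86 pathway-averaged (dn, ds) between two codons differing at >= 1 site.

    Averages over the minimal mutational paths between the codons, excluding
    paths through intermediate stop codons when at least one stop-free path
    exists. A terminal stop (codon_out itself) is allowed and the step into it
    counts as nonsynonymous.
    """
    _check_codon(codon_in)
    _check_codon(codon_out)
    diff_positions = [i for i in range(3) if codon_in[i] != codon_out[i]]
    if not diff_positions:
        return 0.0, 0.0
    paths = []
    blocked_paths = []
    for perm in itertools.permutations(diff_positions):
        cur = codon_in
        dn = ds = 0
        through_stop = False
        for step, pos in enumerate(perm):
            nxt = cur[:pos] + codon_out[pos] + cur[pos + 1:]
            if _step_class(cur, nxt) == "synonymous":
                ds += 1
            else:
                dn += 1
            if nxt in STOP_CODONS and step < len(perm) - 1:
                through_stop = True
            cur = nxt
        (blocked_paths if through_stop else paths).append((dn, ds))
    usable = paths if paths else blocked_paths
    dn_avg = sum(p[0] for p in usable) / len(usable)
    ds_avg = sum(p[1] for p in usable) / len(usable)
    return dn_avg, ds_avg


def count_divergence(
    ref_cds: str,
    outgroup_alleles: Mapping[int, str],
    fixed_alts: Optional[Mapping[int, str]] = None,
    polymorphic_positions: Optional[Set[int]] = None,
) -> Tuple[float, float]:
    """Fixed nonsynonymous/synonymous differences between ingroup and outgroup.

    All coordinates are 0-based positions along the CDS (coding strand).

    Parameters
    ----------
    ref_cds : reference CDS of the ingroup.
    outgroup_alleles : CDS position -> outgroup base where the single outgroup
        haplotype differs from the reference; absent positions are identical.
    fixed_alts : CDS position -> base fixed in the ingroup (AC == AN) where it
        differs from the reference.
    polymorphic_positions : CDS positions segregating in the ingroup; these
        never contribute to divergence.

    Returns (Dn, Ds), fractional under multi-hit pathway averaging.
    """
    fixed_alts = dict(fixed_alts or {})
    polymorphic_positions = set(polymorphic_positions or ())
    n_codons = len(ref_cds) // 3
    ingroup = list(ref_cds)
    for pos, base in fixed_alts.items():
        ingroup[pos] = base
    # outgroup differences are recorded against the reference assembly
    outgroup = list(ref_cds)
    for pos, base in outgroup_alleles.items():
        outgroup[pos] = base

    dn_total = 0.0
    ds_total = 0.0
    for ci in range(n_codons):
        lo, hi = 3 * ci, 3 * ci + 3
        codon_in = "".join(ingroup[lo:hi])
        if codon_in in STOP_CODONS:
            continue
        codon_out = list(outgroup[lo:hi])
        # polymorphic sites never count toward divergence
        for pos in range(lo, hi):
            if pos in polymorphic_positions:
                codon_out[pos - lo] = codon_in[pos - lo]
        codon_out = "".join(codon_out)
        if codon_out == codon_in:
            continue
        dn, ds = codon_path_counts(codon_in, codon_out)
        dn_total += dn
        ds_total += ds
    return dn_total, ds_total


def gc_content(seq: str) -> float:
    """Fraction of G+C bases in a sequence."""
    if not seq:
        raise ValidationError("empty sequence")
    if any(b not in BASES for b in seq):
        raise ValidationError("sequence contains non-ACGT characters")
    return (seq.count("G") + seq.count("C")) / len(seq)


def cpg_oe(seq: str) -> float:
    """Observed/expected CpG dinucleotide ratio: (#CG * L) / (#C * #G).

    NaN (flagged missing) when the sequence has no C or no G.
    """
    if not seq:
        raise ValidationError("empty sequence")
    if any(b not in BASES for b in seq):
        raise ValidationError("sequence contains non-ACGT characters")
    n_c = seq.count("C")
    n_g = seq.count("G")
    if n_c == 0 or n_g == 0:
        return math.nan
    n_cg = sum(1 for i in range(len(seq) - 1) if seq[i:i + 2] == "CG")
    return n_cg * len(seq) / (n_c * n_g)


@dataclass
class GeneVariantSummary:
    """Per-gene substrate for the MK test and DoS."""

    gene_id: str
    ls: float
    ln: float
    pn: float
    ps: float
    dn: float
    ds: float
    pi_s: float
    pi_ns: float

    def __post_init__(self) -> None:
        for name in ("pn", "ps", "dn", "ds"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        if self.ps == 0 and not (self.pi_s == 0 or math.isnan(self.pi_s)):
            raise ValidationError("piS must be 0 when Ps = 0")

    @property
    def pnps(self) -> float:
        if math.isnan(self.pi_s) or math.isnan(self.pi_ns) or self.pi_s == 0:
            return math.nan
        return self.pi_ns / self.pi_s
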