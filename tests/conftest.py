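import numpy as np
import pandas as pd
import pytest

from haplosel.io_formats import GeneModel
from haplosel.synthetic_data import ClassParams, ExprParams, SimConfig


@pytest.fixture
def toy_gene_plus():
    """2-interval-free single-CDS gene on the + strand, CDS 1..9 = ATGAAATAA."""
    return GeneModel(
        gene_id="g1", chrom="chr1", start=1, end=9, strand="+",
        cds_intervals=[(1, 9)],
    ), "ATGAAATAA"


@pytest.fixture
def toy_gene_minus():
    """2-codon gene on the - strand; genomic 1..9 is revcomp of the CDS.

    CDS (coding strand) = ATG AAA TAA; genomic forward = TTATTTCAT.
    """
    return GeneModel(
        gene_id="gm", chrom="chr1", start=1, end=9, strand="-",
        cds_intervals=[(1, 9)],
    ), "ATGAAATAA"


@pytest.fixture
def small_sim_config():
    return SimConfig(n_genes=20, gene_length_codons=(10, 20), seed=3)


@pytest.fixture
def recovery_sim_config():
    """The frozen expression-recovery fixture: 1,000 genes, 100 male-biased
    and 100 female-biased planted at fold 8, NB dispersion 0.1, 5/group."""
    return SimConfig(
        n_genes=1000,
        gene_length_codons=(50, 60),
        class_fractions={
            "haploid_biased": 0.1,
            "diploid_biased": 0.1,
            "constitutive": 0.0,
            "unclassified": 0.8,
        },
        classes={
            "haploid_biased": ClassParams(fold=8.0),
            "diploid_biased": ClassParams(fold=8.0),
            "unclassified": ClassParams(),
        },
        expr=ExprParams(baseline_mean=200.0, dispersion=0.1, n_per_group=5),
        seed=11,
    )
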