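import numpy as np
import pandas as pd
import pytest
from scipy import stats

from haplosel.errors import ConfigurationError
from haplosel.io_formats import read_fasta
from haplosel.popgen_stats import (
    STOP_CODONS,
    classify_change,
    reverse_complement,
    translate,
)
from haplosel.synthetic_data import (
    ClassParams,
    ExprParams,
    SimConfig,
    assign_classes,
    chromosome_lengths,
    gen_expression_counts,
    gen_gene_sequences,
    gen_linkage_map,
    gen_variant_data,
    simulate_all,
)


def classify_planted(genes, cds_map, variants):
    """Re-classify every planted variant independently via the codon table."""
    by_id = {g.gene_id: g for g in genes}
    effects = []
    for row in variants.itertuples(index=False):
        gene = next(g for g in genes if g.chrom == row.chrom
                    and g.start <= row.pos <= g.end)
        cds = cds_map[gene.gene_id]
        cds_pos = gene.genomic_to_cds(row.pos)
        alt = row.alt if gene.strand == "+" else reverse_complement(row.alt)
        ci, off = cds_pos // 3, cds_pos % 3
        codon = cds[3 * ci: 3 * ci + 3]
        effects.append(classify_change(codon, off, alt))
    return effects


class TestConfig:
    def test_invalid_length_range(self):
        with pytest.raises(ConfigurationError):
            SimConfig(gene_length_codons=(1, 5))

    def test_negative_rate(self):
        with pytest.raises(ConfigurationError):
            SimConfig(theta_s=-0.1)

    def test_nonpositive_dispersion(self):
        with pytest.raises(ConfigurationError):
            ExprParams(dispersion=0.0)

    def test_fractions_must_sum_to_one(self):
        with pytest.raises(ConfigurationError):
            SimConfig(class_fractions={"haploid_biased": 0.5})


class TestGeneSequences:
    def test_minimal_gene(self):
        cfg = SimConfig(n_genes=1, gene_length_codons=2, seed=0)
        _, cds_map = gen_gene_sequences(cfg)
        (cds,) = cds_map.values()
        assert len(cds) == 6
        assert cds.startswith("ATG")
        assert cds[3:] in STOP_CODONS

    def test_determinism(self, tmp_path):
        cfg = SimConfig(n_genes=10, seed=7)
        simulate_all(cfg, tmp_path / "a")
        simulate_all(cfg, tmp_path / "b")
        for name in ("cds.fasta", "ingroup.vcf", "counts.tsv", "linkage_map.tsv",
                     "truth.tsv", "outgroup.tsv", "genes.gff3", "samples.tsv"):
            assert (tmp_path / "a" / name).read_bytes() == \
                (tmp_path / "b" / name).read_bytes()

    def test_100_genes_valid_frames(self):
        cfg = SimConfig(n_genes=100, gene_length_codons=100, seed=2)
        genes, cds_map = gen_gene_sequences(cfg)
        assert len(cds_map) == 100
        for cds in cds_map.values():
            assert len(cds) == 300
            aa = translate(cds)
            assert "*" not in aa[:-1]  # scan every codon: no internal stop
            assert aa[-1] == "*"

    def test_layout_monotone_per_chromosome(self):
        cfg = SimConfig(n_genes=64, seed=2)
        genes, _ = gen_gene_sequences(cfg)
        by_chrom = {}
        for g in genes:
            by_chrom.setdefault(g.chrom, []).append(g)
        for glist in by_chrom.values():
            for a, b in zip(glist, glist[1:]):
                assert b.start > a.end


class TestVariantData:
    def test_zero_rates_empty(self):
        cfg = SimConfig(n_genes=5, theta_s=0.0, div_s=0.0, seed=1)
        genes, cds_map = gen_gene_sequences(cfg)
        variants, outgroup, truth = gen_variant_data(cfg, genes, cds_map)
        assert variants.empty and outgroup.empty
        assert (truth[["planted_ps", "planted_pn",
                       "planted_ds", "planted_dn"]].to_numpy() == 0).all()

    def test_omega_poly_zero_all_synonymous(self):
        cfg = SimConfig(
            n_genes=30, theta_s=0.05, div_s=0.0, seed=4,
            class_fractions={"unclassified": 1.0},
            classes={"unclassified": ClassParams(omega_poly=0.0)},
        )
        genes, cds_map = gen_gene_sequences(cfg)
        variants, _, _ = gen_variant_data(cfg, genes, cds_map)
        assert len(variants) > 0
        effects = classify_planted(genes, cds_map, variants)
        assert all(e == "synonymous" for e in effects)

    def test_effect_label_soundness(self):
        """Every planted polymorphism re-classified independently matches the
        syn/nonsyn totals recorded in the truth table (0 mismatches)."""
        cfg = SimConfig(n_genes=60, theta_s=0.03, div_s=0.0, seed=9)
        genes, cds_map = gen_gene_sequences(cfg)
        variants, _, truth = gen_variant_data(cfg, genes, cds_map)
        effects = classify_planted(genes, cds_map, variants)
        n_syn = sum(1 for e in effects if e == "synonymous")
        assert n_syn == truth["planted_ps"].sum()
        assert len(effects) - n_syn == truth["planted_pn"].sum()

    def test_no_site_carries_both_polymorphism_and_substitution(self):
        cfg = SimConfig(n_genes=50, theta_s=0.05, div_s=0.1, seed=5)
        genes, cds_map = gen_gene_sequences(cfg)
        variants, outgroup, _ = gen_variant_data(cfg, genes, cds_map)
        poly_sites = set(zip(variants["chrom"], variants["pos"]))
        sub_sites = set(zip(outgroup["chrom"], outgroup["pos"]))
        assert not poly_sites & sub_sites
        assert len(poly_sites) == len(variants)  # one variant per site

    def test_monte_carlo_omega_poly_recovery(self):
        """Pooled (sum Pn / sum Ps) * (sum Ls / sum Ln) over 500 genes within
        3 SE of omega_poly = 0.5 (per-gene ratios of small Poisson counts are
        biased, so aggregation is the honest estimator)."""
        omega = 0.5
        cfg = SimConfig(
            n_genes=500, gene_length_codons=(90, 110),
            theta_s=0.02, div_s=0.0, n_chromosomes_sampled=22, seed=12,
            class_fractions={"unclassified": 1.0},
            classes={"unclassified": ClassParams(omega_poly=omega)},
        )
        genes, cds_map = gen_gene_sequences(cfg)
        _, _, truth = gen_variant_data(cfg, genes, cds_map)
        pn, ps = truth["planted_pn"].sum(), truth["planted_ps"].sum()
        est = (pn / ps) * (truth["ls"].sum() / truth["ln"].sum())
        rel_se = np.sqrt(1.0 / pn + 1.0 / ps)  # delta method on Poisson sums
        assert abs(est - omega) < 3 * rel_se * omega

    def test_sfs_matches_one_over_i(self):
        """>= 1e4 planted variants at n=22: chi-square GOF against P(i) ~ 1/i."""
        cfg = SimConfig(
            n_genes=400, gene_length_codons=(100, 120),
            theta_s=0.05, div_s=0.0, n_chromosomes_sampled=22, seed=21,
        )
        genes, cds_map = gen_gene_sequences(cfg)
        variants, _, _ = gen_variant_data(cfg, genes, cds_map)
        assert len(variants) >= 10_000
        counts = variants["ac"].value_counts().reindex(range(1, 22), fill_value=0)
        w = 1.0 / np.arange(1, 22)
        expected = w / w.sum() * len(variants)
        chi2 = ((counts - expected) ** 2 / expected).sum()
        crit = stats.chi2.ppf(1 - 0.001, df=20)
        assert chi2 < crit


class TestExpressionCounts:
    def test_fold_one_no_planted_bias(self):
        cfg = SimConfig(
            n_genes=20, seed=3,
            classes={label: ClassParams(fold=1.0)
                     for label in ("haploid_biased", "diploid_biased",
                                   "constitutive", "unclassified")},
        )
        _, _, truth = gen_expression_counts(cfg)
        assert (truth["planted_groups"] == "").all()

    def test_determinism(self):
        cfg = SimConfig(n_genes=15, seed=8)
        a, _, _ = gen_expression_counts(cfg)
        b, _, _ = gen_expression_counts(cfg)
        pd.testing.assert_frame_equal(a, b)

    def test_planted_male_bias_visible_in_group_means(self):
        """Planted male-biased genes at fold 8 show a higher male/female
        group-mean ratio than unplanted genes for >= 95% of planted genes."""
        cfg = SimConfig(
            n_genes=1000, seed=6,
            class_fractions={"haploid_biased": 0.1, "unclassified": 0.9},
            classes={"haploid_biased": ClassParams(fold=8.0),
                     "unclassified": ClassParams()},
            expr=ExprParams(baseline_mean=200.0, dispersion=0.1, n_per_group=5),
        )
        counts, meta, truth = gen_expression_counts(cfg)
        male = meta.index[meta["sex"] == "male"]
        female = meta.index[meta["sex"] == "female"]
        ratio = (counts[male].mean(axis=1) + 1) / (counts[female].mean(axis=1) + 1)
        planted = truth["planted_groups"] != ""
        planted_ids = truth.loc[planted, "gene_id"]
        null_ids = truth.loc[~planted, "gene_id"]
        threshold = ratio.loc[null_ids].quantile(0.999)
        frac = (ratio.loc[planted_ids] > ratio.loc[null_ids].mean()).mean()
        assert frac >= 0.95

    def test_metadata_complete(self):
        cfg = SimConfig(n_genes=5, seed=1)
        counts, meta, _ = gen_expression_counts(cfg)
        assert list(counts.columns) == list(meta.index)
        assert set(meta["sex"]) == {"male", "female"}


class TestLinkageMap:
    def test_constant_rate_two_markers(self):
        cfg = SimConfig(seed=0, markers_per_chrom=2, recomb_rate_cm_per_mb=23.0)
        lmap = gen_linkage_map(cfg, {"chr1": 1_000_000})
        assert len(lmap) == 2
        slope = (lmap["cM"].iloc[1] - lmap["cM"].iloc[0]) / (
            (lmap["bp"].iloc[1] - lmap["bp"].iloc[0]) / 1e6
        )
        assert slope == pytest.approx(23.0)

    def test_invariants_always_hold(self):
        cfg = SimConfig(seed=13, markers_per_chrom=40, n_chromosomes=4)
        lmap = gen_linkage_map(cfg)
        for _, sub in lmap.groupby("chrom"):
            assert (np.diff(sub["bp"]) > 0).all()
            assert (np.diff(sub["cM"]) >= 0).all()

    def test_marker_total(self):
        cfg = SimConfig(seed=0, markers_per_chrom=125, n_chromosomes=16)
        lmap = gen_linkage_map(cfg)
        assert len(lmap) == 2000


class TestTruthTable:
    def test_one_record_per_gene(self, small_sim_config):
        genes, cds_map = gen_gene_sequences(small_sim_config)
        _, _, truth = gen_variant_data(small_sim_config, genes, cds_map)
        assert len(truth) == small_sim_config.n_genes
        assert truth["gene_id"].is_unique
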