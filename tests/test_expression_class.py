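import numpy as np
import pandas as pd
import pytest

from haplosel.errors import ConfigurationError, ValidationError
from haplosel.expression_class import (
    bh_fdr,
    classify_genes,
    filter_low_counts,
    intersection_counts,
    normalize_median_of_ratios,
    run_pairwise_de,
)
from haplosel.expression_class import test_upregulation as de_upregulation
from haplosel.synthetic_data import (
    ClassParams,
    SimConfig,
    gen_expression_counts,
)


def _counts(rows, samples):
    return pd.DataFrame(rows, columns=samples)


class TestFilterLowCounts:
    def test_sum_nine_removed_at_default_ten(self):
        m = pd.DataFrame({"a": [4, 5], "b": [5, 5]}, index=["g1", "g2"])
        kept = filter_low_counts(m, 10)
        assert list(kept.index) == ["g2"]

    def test_zero_threshold_identity(self):
        m = pd.DataFrame({"a": [0, 1], "b": [0, 2]})
        pd.testing.assert_frame_equal(filter_low_counts(m, 0), m)

    def test_counted_rows(self):
        sums = (0, 9, 10, 11, 100)
        m = pd.DataFrame({"a": sums, "b": [0] * 5})
        assert len(filter_low_counts(m, 10)) == 3

    def test_negative_threshold_rejected(self):
        with pytest.raises(ConfigurationError):
            filter_low_counts(pd.DataFrame({"a": [1]}), -1)


class TestNormalization:
    def test_identical_samples_unit_factors(self):
        m = pd.DataFrame({"a": [10, 20, 30], "b": [10, 20, 30]})
        sf, norm = normalize_median_of_ratios(m)
        assert sf.tolist() == pytest.approx([1.0, 1.0])
        pd.testing.assert_frame_equal(norm, m.astype(float))

    def test_doubled_sample(self):
        m = pd.DataFrame({"a": [10, 20, 30], "b": [20, 40, 60]})
        sf, norm = normalize_median_of_ratios(m)
        assert sf["b"] / sf["a"] == pytest.approx(2.0)
        np.testing.assert_allclose(norm["a"], norm["b"])

    def test_scale_equivariance(self):
        # multiplying one sample by a constant leaves the normalized matrix
        # unchanged up to a single global factor
        rng = np.random.default_rng(0)
        m = pd.DataFrame(rng.integers(1, 100, size=(20, 3)),
                         columns=["a", "b", "c"])
        _, norm1 = normalize_median_of_ratios(m)
        m2 = m.copy()
        m2["b"] = m2["b"] * 5
        _, norm2 = normalize_median_of_ratios(m2)
        ratio = norm2.values / norm1.values
        np.testing.assert_allclose(ratio, ratio.flat[0], rtol=1e-10)

    def test_all_zero_gene_handling(self):
        m = pd.DataFrame({"a": [0, 0], "b": [0, 0]})
        with pytest.raises(ValidationError):
            normalize_median_of_ratios(m)


class TestUpregulation:
    def test_identical_groups(self):
        a = _counts([[5, 5]], ["a1", "a2"])
        b = _counts([[5, 5]], ["b1", "b2"])
        res = de_upregulation(a, b)
        assert res.loc[0, "log2fc"] == 0.0
        assert res.loc[0, "p"] == 1.0

    def test_hundred_vs_zero(self):
        a = _counts([[100, 100]], ["a1", "a2"])
        b = _counts([[0, 0]], ["b1", "b2"])
        res = de_upregulation(a, b)
        assert res.loc[0, "log2fc"] == pytest.approx(np.log2(101))

    def test_requires_two_samples(self):
        a = _counts([[1]], ["a1"])
        b = _counts([[1, 2]], ["b1", "b2"])
        with pytest.raises(ConfigurationError):
            de_upregulation(a, b)

    def test_null_simulation_fdr_control(self):
        """No planted effect: fraction of genes at q < 0.01 stays ~<= 0.01."""
        rng = np.random.default_rng(42)
        n_genes = 2000
        a = pd.DataFrame(rng.poisson(50, size=(n_genes, 4)))
        b = pd.DataFrame(rng.poisson(50, size=(n_genes, 4)))
        b.columns = [f"b{i}" for i in range(4)]
        res = de_upregulation(a, b)
        assert (res["q"] < 0.01).mean() <= 0.01 + 3 * np.sqrt(0.01 / n_genes)


class TestBhFdr:
    def test_hand_computation(self):
        # q_(2) = 0.04; q_(1) = min(0.01*2/1, q_(2)) = 0.02
        np.testing.assert_allclose(bh_fdr([0.01, 0.04]), [0.02, 0.04])

    def test_all_equal(self):
        np.testing.assert_allclose(bh_fdr([0.3, 0.3, 0.3]), [0.3, 0.3, 0.3])

    def test_single_p(self):
        np.testing.assert_allclose(bh_fdr([0.123]), [0.123])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            bh_fdr([0.5, 1.5])

    def test_monotone_in_p_rank(self):
        rng = np.random.default_rng(1)
        p = rng.random(100)
        q = bh_fdr(p)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-15).all()

    def test_clipped_to_one(self):
        assert bh_fdr([0.9, 0.95, 1.0]).max() <= 1.0


def _de_fixture(alpha_hit=0.001, alpha_miss=0.02):
    """DE rows for a 2x2 adult design where g_up wins every male_gonad
    comparison and g_weak misses the threshold."""
    rows = []
    for comp, sign in [("female_gonad_vs_male_gonad", -1),
                       ("male_gonad_vs_male_soma", 1)]:
        rows.append({"gene_id": "g_up", "comparison": comp,
                     "log2fc": sign * 2.0, "p": alpha_hit, "q": alpha_hit})
        rows.append({"gene_id": "g_weak", "comparison": comp,
                     "log2fc": sign * 2.0, "p": alpha_miss, "q": alpha_miss})
    # remaining required comparisons, null for both genes
    for comp in ["female_gonad_vs_female_soma", "female_soma_vs_male_soma"]:
        for gid in ("g_up", "g_weak"):
            rows.append({"gene_id": gid, "comparison": comp,
                         "log2fc": 0.0, "p": 1.0, "q": 1.0})
    return pd.DataFrame(rows)


def _adult_meta():
    rows = []
    for sex in ("male", "female"):
        for tissue in ("gonad", "soma"):
            for k in (1, 2):
                rows.append({"sample": f"{sex}_{tissue}_{k}", "sex": sex,
                             "tissue": tissue, "stage": "adult"})
    return pd.DataFrame(rows).set_index("sample")


class TestClassifyGenes:
    def test_up_in_male_gonad_only(self):
        cls = classify_genes(_de_fixture(), _adult_meta(), alpha=0.01)
        row = cls.set_index("gene_id").loc["g_up"]
        assert row["label"] == "haploid_biased"
        assert row["tissue_sets"] == "male_gonad"

    def test_q_above_threshold_unclassified(self):
        cls = classify_genes(_de_fixture(), _adult_meta(), alpha=0.01)
        row = cls.set_index("gene_id").loc["g_weak"]
        assert row["label"] == "unclassified"
        assert row["tissue_sets"] == ""

    def test_every_gene_gets_exactly_one_label(self):
        cls = classify_genes(_de_fixture(), _adult_meta(), alpha=0.01)
        assert cls["gene_id"].is_unique
        assert cls["label"].isin(
            ["haploid_biased", "diploid_biased", "constitutive", "unclassified"]
        ).all()

    def test_missing_comparison_is_configuration_error(self):
        de = _de_fixture()
        de = de[de["comparison"] != "male_gonad_vs_male_soma"]
        with pytest.raises(ConfigurationError):
            classify_genes(de, _adult_meta(), alpha=0.01)


class TestIntersectionCounts:
    def test_single_gene(self):
        cls = pd.DataFrame(
            [{"gene_id": "g", "label": "haploid_biased",
              "tissue_sets": "male_gonad"}]
        )
        table = intersection_counts(cls)
        assert len(table) == 1
        assert table.loc[0, "count"] == 1

    def test_empty(self):
        cls = pd.DataFrame(columns=["gene_id", "label", "tissue_sets"])
        assert intersection_counts(cls).empty

    def test_counts_sum_to_classified(self):
        cls = pd.DataFrame([
            {"gene_id": "a", "label": "haploid_biased", "tissue_sets": "male_gonad"},
            {"gene_id": "b", "label": "haploid_biased", "tissue_sets": "male_gonad"},
            {"gene_id": "c", "label": "constitutive",
             "tissue_sets": "female_soma;male_gonad"},
            {"gene_id": "d", "label": "unclassified", "tissue_sets": ""},
        ])
        table = intersection_counts(cls)
        assert table["count"].sum() == 3


class TestSyntheticRecovery:
    def test_planted_class_recovery(self, recovery_sim_config):
        """>= 90/100 planted male-biased genes recovered; <= 5 mislabeled as
        diploid-biased; false-positive rate among null genes <= alpha."""
        cfg = recovery_sim_config
        counts, meta, truth = gen_expression_counts(cfg)
        de = run_pairwise_de(counts, meta, min_total=10)
        cls = classify_genes(de, meta, alpha=0.01).set_index("gene_id")
        truth = truth.set_index("gene_id")
        male_planted = truth.index[truth["label"] == "haploid_biased"]
        called = cls.loc[cls.index.intersection(male_planted), "label"]
        assert (called == "haploid_biased").sum() >= 90
        assert (called == "diploid_biased").sum() <= 5
        null_ids = truth.index[truth["label"] == "unclassified"]
        null_called = cls.loc[cls.index.intersection(null_ids), "label"]
        assert (null_called != "unclassified").mean() <= 0.01

    @pytest.mark.parametrize("seed", [101, 202, 303])
    def test_type_one_control_on_null_matrix(self, seed):
        """Fully null matrix: haploid-biased fraction <= alpha (binomial tol)."""
        cfg = SimConfig(
            n_genes=600, seed=seed,
            class_fractions={"unclassified": 1.0},
            classes={"unclassified": ClassParams()},
        )
        counts, meta, _ = gen_expression_counts(cfg)
        de = run_pairwise_de(counts, meta, min_total=10)
        cls = classify_genes(de, meta, alpha=0.01)
        frac = (cls["label"] == "haploid_biased").mean()
        assert frac <= 0.01 + 3 * np.sqrt(0.01 * 0.99 / len(cls))
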