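"""Cross-genome overlap, nearest-gene distances, and enrichment statistics."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from rercall.annotate import FeatureAnnotation
from rercall.downstream import (
    binomial_enrichment,
    categorical_enrichment,
    consistency_overlap,
    nearest_gene,
    two_sample_mean_test,
)
from rercall.intervals import Interval


def feat(fid, start, end, strand="+", kind="gene", chrom="c1"):
    return FeatureAnnotation(
        fid, "A", kind, [Interval(chrom, start, end, strand)], strand=strand
    )


class TestNearestGene:
    def test_downstream_of_plus_gene_positive(self):
        te = feat("te1", 500, 600, kind="TE")
        gene = feat("g1", 100, 300, "+")
        (res,) = nearest_gene([te], [gene])
        assert (res.gene_id, res.signed_distance) == ("g1", 200)

    def test_downstream_of_minus_gene_positive(self):
        te = feat("te1", 500, 600, kind="TE")
        gene = feat("g1", 700, 900, "-")
        (res,) = nearest_gene([te], [gene])
        assert res.signed_distance == 100  # TE lies downstream of the - gene

    def test_upstream_negative_and_overlap_zero(self):
        te = feat("te1", 500, 600, kind="TE")
        (res,) = nearest_gene([te], [feat("g1", 700, 900, "+")])
        assert res.signed_distance == -100
        (res,) = nearest_gene([te], [feat("g1", 550, 650, "+")])
        assert res.signed_distance == 0

    def test_te_without_genes_on_chrom_skipped(self):
        te = feat("te1", 0, 10, kind="TE", chrom="c9")
        assert nearest_gene([te], [feat("g1", 0, 10)]) == []

    def test_matches_brute_force_scan(self):
        """Random annotations: the reported gene minimizes |gap| under the
        same sign convention as an all-pairs scan."""
        rng = np.random.default_rng(19)
        for _ in range(100):
            genes = []
            for i in range(rng.integers(1, 8)):
                a = int(rng.integers(0, 900))
                b = int(rng.integers(a + 1, 1000))
                genes.append(feat(f"g{i}", a, b, str(rng.choice(["+", "-"]))))
            a = int(rng.integers(0, 990))
            te = feat("te", a, int(rng.integers(a + 1, 1000)), kind="TE")

            def gap(g):
                gs, ge = g.span
                ts, te_ = te.span
                if ts < ge and gs < te_:
                    return 0
                return ts - ge if ts >= ge else gs - te_

            best = min(genes, key=lambda g: (gap(g), g.span[0], g.feature_id))
            (res,) = nearest_gene([te], genes)
            assert abs(res.signed_distance) == gap(best)
            assert res.gene_id == best.feature_id


class TestBinomialEnrichment:
    def test_zero_hits(self):
        fold, p = binomial_enrichment(0, 20, 0.1)
        assert fold == 0.0 and p == 1.0

    def test_observed_versus_expected_fold(self):
        # 13% of matTE nearest genes are MEGs vs 1.12% of expressed genes
        fold, p = binomial_enrichment(19, 146, 0.0112)
        assert fold == pytest.approx(11.6, abs=0.05)
        assert p < 0.001

    def test_matches_pmf_summation_oracle(self):
        rng = np.random.default_rng(37)
        for _ in range(100):
            n = int(rng.integers(1, 50))
            k = int(rng.integers(0, n + 1))
            pr = float(rng.uniform(0.05, 0.95))
            _, pval = binomial_enrichment(k, n, pr)
            oracle = sum(stats.binom.pmf(x, n, pr) for x in range(k, n + 1))
            assert pval == pytest.approx(oracle, rel=1e-9, abs=1e-12)

    def test_degenerate_probability_rejected(self):
        with pytest.raises(ValueError):
            binomial_enrichment(1, 10, 0.0)


def pearson_chi2_oracle(table):
    table = np.asarray(table, dtype=float)
    total = table.sum()
    expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / total
    return ((table - expected) ** 2 / expected).sum()


class TestCategoricalEnrichment:
    def test_identical_rows_give_zero(self):
        stat, p = categorical_enrichment([[10, 20, 30], [10, 20, 30]])
        assert stat == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_hand_computed_diagonal(self):
        stat, _ = categorical_enrichment([[10, 0], [0, 10]])
        assert stat == pytest.approx(20.0)

    def test_matches_textbook_formula(self):
        rng = np.random.default_rng(41)
        for _ in range(100):
            table = rng.integers(1, 50, size=(2, rng.integers(2, 5)))
            stat, _ = categorical_enrichment(table)
            assert stat == pytest.approx(pearson_chi2_oracle(table))

    def test_zero_marginal_rejected(self):
        with pytest.raises(ValueError, match="marginal"):
            categorical_enrichment([[0, 0], [1, 2]])


class TestTwoSampleMeanTest:
    def test_identical_samples(self):
        t, p = two_sample_mean_test([1, 1, 1], [1, 1, 1])
        assert (t, p) == (0.0, 1.0)

    def test_swap_negates_t(self):
        x, y = [1.0, 2.0, 3.5], [2.0, 4.0, 5.0]
        t1, p1 = two_sample_mean_test(x, y)
        t2, p2 = two_sample_mean_test(y, x)
        assert t1 == pytest.approx(-t2)
        assert p1 == pytest.approx(p2)

    def test_detects_unit_shift(self):
        """Shifted normals (delta=1, sigma=1, n=200) are essentially always
        detected at p < 0.001."""
        rng = np.random.default_rng(43)
        detected = sum(
            two_sample_mean_test(rng.normal(0, 1, 200), rng.normal(1, 1, 200))[1] < 1e-3
            for _ in range(50)
        )
        assert detected >= 49

    def test_degenerate_variance_rejected(self):
        with pytest.raises(ValueError):
            two_sample_mean_test([1, 1], [2, 2])


def calls(rows):
    return pd.DataFrame(
        rows, columns=["feature_id", "genome", "category"]
    ).set_index("feature_id")


class TestConsistencyOverlap:
    MAP = pd.DataFrame(
        {"A": ["a1", "a2", "a3"], "B": ["b1", "b2", "b3"]}
    )

    def test_identical_calls_under_bijection_all_shared(self):
        a = calls([("a1", "A", "MEG"), ("a2", "A", "PEG")])
        b = calls([("b1", "B", "MEG"), ("b2", "B", "PEG")])
        out = consistency_overlap(a, b, self.MAP, "A", "B")
        assert (out["status"] == "shared_imprinted").all()
        assert len(out) == 4  # both genomes' imprinted features reported

    def test_unmapped_feature_unique(self):
        a = calls([("aX", "A", "MEG")])
        b = calls([("b1", "B", "not_imprinted")])
        out = consistency_overlap(a, b, self.MAP, "A", "B")
        assert out.loc[out["feature_id"] == "aX", "status"].item() == "unique_to_one_genome"

    def test_assessed_but_different_category(self):
        a = calls([("a1", "A", "MEG")])
        b = calls([("b1", "B", "not_imprinted")])
        out = consistency_overlap(a, b, self.MAP, "A", "B")
        assert out["status"].item() == "assessable_not_shared"

    def test_partition_sizes_sum_to_imprinted_count(self):
        a = calls([("a1", "A", "MEG"), ("a2", "A", "matTE"), ("aZ", "A", "PEG"),
                   ("a3", "A", "not_imprinted")])
        b = calls([("b1", "B", "MEG"), ("b2", "B", "PEG")])
        out = consistency_overlap(a, b, self.MAP, "A", "B")
        n_imprinted = 3 + 2
        assert len(out) == n_imprinted
        assert out["status"].value_counts().sum() == n_imprinted

    def test_duplicate_correspondence_rejected(self):
        bad = pd.DataFrame({"A": ["a1", "a1"], "B": ["b1", "b2"]})
        with pytest.raises(ValueError, match="duplicate"):
            consistency_overlap(calls([("a1", "A", "MEG")]), calls([]), bad, "A", "B")

    def test_matches_set_intersection_oracle(self):
        rng = np.random.default_rng(47)
        cats = np.array(["MEG", "PEG", "not_imprinted"])
        for _ in range(50):
            n = 12
            amap = pd.DataFrame(
                {"A": [f"a{i}" for i in range(n)], "B": [f"b{i}" for i in range(n)]}
            )
            a = calls([(f"a{i}", "A", rng.choice(cats)) for i in range(n)])
            b = calls([(f"b{i}", "B", rng.choice(cats)) for i in rng.choice(n, size=8, replace=False)])
            out = consistency_overlap(a, b, amap, "A", "B")
            shared_oracle = {
                f"a{i}"
                for i in range(n)
                if f"b{i}" in b.index
                and a.loc[f"a{i}", "category"] in {"MEG", "PEG"}
                and a.loc[f"a{i}", "category"] == b.loc[f"b{i}", "category"]
            }
            got = set(
                out.loc[(out["genome"] == "A") & (out["status"] == "shared_imprinted"),
                        "feature_id"]
            )
            assert got == shared_oracle
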