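"""Dosage test machinery: size factors, dispersion, threshold Wald, BH,
and the final classification gates."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from rercall.counts import CountTable, SampleMeta
from rercall.imprint import (
    ImprintThresholds,
    bh_adjust,
    classify_imprinting,
    dosage_test,
    estimate_dispersion,
    estimate_size_factors,
    threshold_wald_test,
)
from rercall.rer import rer_table


def median_of_ratios_oracle(counts):
    """Brute-force median-of-ratios over everywhere-nonzero features."""
    rows = [r for r in counts.to_numpy(dtype=float) if (r > 0).all()]
    factors = []
    for j in range(counts.shape[1]):
        ratios = sorted(r[j] / np.exp(np.mean(np.log(r))) for r in rows)
        factors.append(np.median(ratios))
    return np.array(factors)


class TestSizeFactors:
    def test_identical_libraries_give_unit_factors(self):
        counts = pd.DataFrame({"a": [10, 20, 5], "b": [10, 20, 5], "c": [10, 20, 5]})
        assert np.allclose(estimate_size_factors(counts), 1.0)

    def test_doubled_library_doubles_factor(self):
        base = np.array([10, 20, 5, 100])
        counts = pd.DataFrame({"a": base, "b": base, "c": 2 * base})
        sf = estimate_size_factors(counts)
        assert sf["c"] / sf["a"] == pytest.approx(2.0)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(17)
        for _ in range(100):
            counts = pd.DataFrame(
                rng.integers(0, 200, size=(rng.integers(3, 20), rng.integers(2, 7)))
            )
            if not (counts.to_numpy() > 0).all(axis=1).any():
                continue
            got = estimate_size_factors(counts).to_numpy()
            assert np.allclose(got, median_of_ratios_oracle(counts))

    def test_fallback_to_library_totals(self, caplog):
        # no feature nonzero everywhere
        counts = pd.DataFrame({"a": [10, 0], "b": [0, 30]})
        sf = estimate_size_factors(counts)
        assert (sf > 0).all()


class TestDispersion:
    def test_poisson_counts_give_near_zero_alpha(self):
        rng = np.random.default_rng(23)
        y = rng.poisson(100, 200)
        assert estimate_dispersion(y, np.ones(200)) < 0.05

    def test_nb_parameter_recovery(self):
        """Mean method-of-moments estimate over 50 features recovers
        alpha = 0.5 within +-0.1 at n = 200 replicates."""
        rng = np.random.default_rng(29)
        alpha = 0.5
        ests = []
        for _ in range(50):
            mu, n = 100.0, 200
            y = rng.negative_binomial(1 / alpha, (1 / alpha) / (1 / alpha + mu), n)
            ests.append(estimate_dispersion(y, np.ones(n)))
        assert abs(np.mean(ests) - alpha) < 0.1

    def test_constant_counts_floored(self):
        y = np.full(6, 50)
        assert estimate_dispersion(y, np.ones(6)) == pytest.approx(1e-8)

    def test_all_zero_feature_undefined(self):
        assert np.isnan(estimate_dispersion(np.zeros(6), np.ones(6)))


class TestThresholdWald:
    def test_boundary_and_sub_threshold_cap_at_one(self):
        assert threshold_wald_test(1.0, 0.5, theta=1.0) == 1.0
        assert threshold_wald_test(0.3, 0.5, theta=1.0) == 1.0
        assert threshold_wald_test(-0.5, 0.5, theta=1.0) == 1.0

    def test_normal_tail_oracle(self):
        # W = (3 - 1) / 0.5 = 4
        assert threshold_wald_test(3.0, 0.5, theta=1.0) == pytest.approx(
            2 * stats.norm.sf(4.0), rel=1e-12
        )
        assert threshold_wald_test(3.0, 0.5) == pytest.approx(6.33e-5, rel=1e-2)

    def test_monotonicity(self):
        """p non-increasing in |lfc| at fixed se; increasing in se beyond
        the threshold."""
        ps = [threshold_wald_test(l, 0.4) for l in (1.2, 1.5, 2.0, 3.0)]
        assert ps == sorted(ps, reverse=True)
        ps = [threshold_wald_test(2.0, s) for s in (0.1, 0.3, 0.6, 1.0)]
        assert ps == sorted(ps)

    def test_bad_se_rejected(self):
        with pytest.raises(ValueError):
            threshold_wald_test(2.0, 0.0)


def bh_oracle(p):
    """Textbook step-up: padj_i = min_{j>=i} min(1, m*p_(j)/j)."""
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, m * p[i] / rank)
        adj[i] = running
    return adj


class TestBH:
    def test_examples(self):
        assert bh_adjust([0.04])[0] == pytest.approx(0.04)
        assert np.allclose(bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])
        assert np.allclose(bh_adjust([0.2, 0.2, 0.2]), 0.2)

    def test_matches_step_up_oracle(self):
        rng = np.random.default_rng(31)
        for _ in range(100):
            p = rng.uniform(0, 1, rng.integers(1, 40))
            assert np.allclose(bh_adjust(p), bh_oracle(p))

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])


def make_table(maternal_counts, paternal_counts, genome="A", kind="gene"):
    """One focal feature plus stable background features (so size factors
    are informed by more than the feature under test)."""
    samples, data = [], {}
    for i, c in enumerate(maternal_counts, 1):
        lid = f"AxB_r{i}"
        samples.append(SampleMeta(lid, "A", "B", i, library_size=1_000_000))
        data[lid] = [c, 100, 80]
    for i, c in enumerate(paternal_counts, 1):
        lid = f"BxA_r{i}"
        samples.append(SampleMeta(lid, "B", "A", i, library_size=1_000_000))
        data[lid] = [c, 100, 80]
    index = ["feat1", "bg1", "bg2"]
    counts = pd.DataFrame(data, index=index)
    features = pd.DataFrame(
        {"genome": [genome, "A", "B"], "kind": [kind, "gene", "gene"]}, index=index
    )
    return CountTable(counts, samples, features)


class TestDosageTest:
    def test_direction_follows_sign_of_lfc(self):
        t = dosage_test(make_table([200, 190, 210], [1, 0, 2]))
        assert t.loc["feat1", "direction"] == "maternal"
        assert t.loc["feat1", "lfc"] > 1
        t = dosage_test(make_table([0, 1, 0], [100, 110, 90]))
        assert t.loc["feat1", "direction"] == "paternal"

    def test_low_count_features_excluded_before_testing(self):
        t = dosage_test(make_table([2, 1, 2], [1, 1, 2]))
        assert "feat1" not in t.index

    def test_exact_two_to_one_dosage_not_significant(self):
        t = dosage_test(make_table([100, 102, 98], [50, 51, 49]))
        assert t.loc["feat1", "p"] > 0.5


def call_row(padj, direction, rer, kind="gene"):
    test = pd.DataFrame(
        {"genome": ["A"], "kind": [kind], "lfc": [2.0 if direction == "maternal" else -2.0],
         "se": [0.1], "p": [padj], "padj": [padj], "direction": [direction]},
        index=["f1"],
    )
    rer_df = pd.DataFrame(
        {"genome": ["A"], "kind": [kind], "maternal_mean_rpm": [1.0],
         "paternal_mean_rpm": [1.0], "rer": [rer], "n_unique_reads": [100],
         "assessable": [True], "bin": [None]},
        index=["f1"],
    )
    return test, rer_df


class TestClassification:
    @pytest.mark.parametrize(
        "padj, direction, rer, kind, expected",
        [
            (0.01, "maternal", 0.95, "gene", "MEG"),
            (0.01, "maternal", 0.85, "gene", "not_imprinted"),  # fails RER gate
            (0.2, "maternal", 0.95, "TE", "not_imprinted"),  # not significant
            (0.01, "maternal", 0.95, "TE", "matTE"),
            (0.01, "paternal", 0.05, "gene", "PEG"),
            (0.01, "paternal", 0.05, "TE", "patTE"),
            # strict boundaries: equality never calls imprinting
            (0.05, "maternal", 0.95, "gene", "not_imprinted"),
            (0.01, "maternal", 0.9, "gene", "not_imprinted"),
            (0.01, "paternal", 0.1, "gene", "not_imprinted"),
        ],
    )
    def test_gates(self, padj, direction, rer, kind, expected):
        test, rer_df = call_row(padj, direction, rer, kind)
        out = classify_imprinting(test, rer_df)
        assert out.loc["f1", "category"] == expected

    def test_pericarp_flag_blocks_meg_but_not_peg(self):
        test, rer_df = call_row(0.01, "maternal", 0.95)
        out = classify_imprinting(test, rer_df, pericarp_flagged={"f1"})
        assert out.loc["f1", "category"] == "excluded_pericarp"
        test, rer_df = call_row(0.01, "paternal", 0.05)
        out = classify_imprinting(test, rer_df, pericarp_flagged={"f1"})
        assert out.loc["f1", "category"] == "PEG"

    def test_paternal_te_contrast_exclusion(self):
        test, rer_df = call_row(0.01, "paternal", 0.05, kind="TE")
        out = classify_imprinting(test, rer_df, paternal_te_excluded=True)
        assert out.loc["f1", "category"] == "excluded_paternalTE_contrast"
        # maternal TEs unaffected by the flag
        test, rer_df = call_row(0.01, "maternal", 0.95, kind="TE")
        out = classify_imprinting(test, rer_df, paternal_te_excluded=True)
        assert out.loc["f1", "category"] == "matTE"

    def test_order_invariance(self, default_sim):
        rer_df = rer_table(default_sim.table)
        test = dosage_test(default_sim.table)
        a = classify_imprinting(test, rer_df)
        perm = rer_df.sample(frac=1, random_state=0)
        b = classify_imprinting(test, perm)
        assert a["category"].sort_index().equals(b["category"].sort_index())
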