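import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from parevo.config import RunConfig
from parevo.coexpression import build_network, median_expression_subset
from parevo.fates import (
    BUCKETS,
    classify_all,
    classify_pair,
    fold_change_stats,
    funnel_summary,
    shared_expression_domains,
    wgd_ssd_strata,
)
from parevo.io import OrthogroupTable
from parevo.qc import MeanExpression

from conftest import make_dataset


class TestFoldChangeStats:
    def test_worked_example(self):
        # a=[4,8,2], b=[1,2,1] -> l=[2,2,1]; mean_abs=5/3, sd=1/sqrt(3)
        mean_abs, sd, n = fold_change_stats([4, 8, 2], [1, 2, 1])
        assert mean_abs == pytest.approx(5 / 3)
        assert sd == pytest.approx(1 / math.sqrt(3))
        assert n == 3

    def test_identical_vectors(self):
        mean_abs, sd, n = fold_change_stats([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert mean_abs == 0.0 and sd == 0.0

    def test_uniform_scaling(self):
        a = np.array([1.0, 2.0, 5.0])
        mean_abs, sd, n = fold_change_stats(a, a * 4)
        assert mean_abs == pytest.approx(2.0)
        assert sd == pytest.approx(0.0, abs=1e-12)

    def test_zero_samples_excluded(self):
        # sample with a zero copy is excluded from the fold-change vector
        mean_abs, sd, n = fold_change_stats([4, 0, 8], [1, 5, 2])
        assert n == 2
        assert mean_abs == pytest.approx(2.0)

    def test_fewer_than_two_usable_is_none(self):
        assert fold_change_stats([4, 0], [1, 5]) is None
        assert fold_change_stats([0, 0], [0, 0]) is None

    def test_swap_invariance(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            a = rng.gamma(2.0, 5.0, 6)
            b = rng.gamma(2.0, 5.0, 6)
            sa = fold_change_stats(a, b)
            sb = fold_change_stats(b, a)
            assert sa[0] == pytest.approx(sb[0], abs=1e-12)
            assert sa[1] == pytest.approx(sb[1], abs=1e-12)


def reference_rules(coexpr, mean, sd, high=0.9, low=0.5, m=1.0, s=1.0):
    """Direct restatement of the four published rules."""
    if coexpr > high and mean < m and sd < s:
        return "I"
    if coexpr > high and mean >= m and sd < s:
        return "II"
    if coexpr > high and mean >= m and sd >= s:
        return "III"
    if coexpr < low and mean >= m and sd >= s:
        return "IV"
    return "none"


class TestClassifyPair:
    @pytest.mark.parametrize(
        "triple,expected",
        [
            ((0.95, 0.3, 0.4), "I"),
            ((0.95, 1.5, 0.4), "II"),
            ((0.95, 1.5, 1.5), "III"),
            ((0.30, 1.5, 1.5), "IV"),
            ((0.90, 0.3, 0.4), "none"),  # coexpr boundary is strict
            ((0.95, 1.0, 0.4), "II"),    # mean boundary is inclusive (>=)
            ((0.95, 1.0, 1.0), "III"),   # sd boundary is inclusive (>=)
            ((0.50, 1.5, 1.5), "none"),  # between low and high
            ((0.70, 1.5, 1.5), "none"),
            ((0.30, 0.5, 1.5), "none"),  # low coexpr but mean below cut
            ((0.95, 0.3, 1.5), "none"),  # high coexpr, low mean, high sd
        ],
    )
    def test_rule_table(self, triple, expected):
        assert classify_pair(*triple) == expected

    @given(
        st.floats(0, 1), st.floats(0, 5), st.floats(0, 5)
    )
    @settings(max_examples=300, deadline=None)
    def test_property_matches_reference(self, coexpr, mean, sd):
        assert classify_pair(coexpr, mean, sd) == reference_rules(coexpr, mean, sd)

    def test_custom_thresholds(self):
        cfg = RunConfig(coexpr_high=0.8, coexpr_low=0.6)
        assert classify_pair(0.85, 0.3, 0.4, cfg) == "I"
        assert classify_pair(0.55, 1.5, 1.5, cfg) == "IV"


class TestClassifyAll:
    def _setup(self, vals, og_members):
        n_s = vals.shape[1]
        ds = make_dataset(vals, [("apex", i + 1) for i in range(n_s)])
        og = OrthogroupTable(og_members, ("spx",))
        subset = median_expression_subset(ds)
        net = build_network(ds, subset)
        return classify_all(og, {"spx": ds}, {"spx": net})

    def test_low_expression_bucket(self):
        rng = np.random.default_rng(1)
        vals = rng.gamma(2.0, 5.0, size=(6, 5)) + 5.0
        vals[4] = 0.0  # gene g4 all zero -> fails the median subset
        vals[5] = 0.0
        records = self._setup(
            vals, {"OG1": {"spx": ("g4", "g5")}, "OG2": {"spx": ("g0", "g1")}}
        )
        rec = records.set_index("orthogroup_id")
        assert rec.loc["OG1", "bucket"] == "low_or_no_expression"
        assert rec.loc["OG1", "group"] == "none"

    def test_insufficient_bucket_single_overlap(self):
        # both genes pass the subset but share only one non-zero sample
        vals = np.array(
            [
                [9.0, 0.0, 0.0, 0.0, 8.0],
                [0.0, 9.0, 0.0, 0.0, 8.0],
                [1.0, 1.0, 1.0, 1.0, 1.0],
                [2.0, 2.0, 2.0, 2.0, 2.0],
            ]
        )
        records = self._setup(vals, {"OG1": {"spx": ("g0", "g1")}})
        assert records.iloc[0]["bucket"] == "insufficient"

    def test_missing_gene_errors_with_name(self, small_sim):
        _, datasets, orthogroups, _, _ = small_sim
        ds = datasets["sp01"]
        bad = OrthogroupTable({"OGX": {"sp01": ("sp01_ghost", ds.genes[0])}},
                              ("sp01",))
        net = build_network(ds, median_expression_subset(ds))
        with pytest.raises(KeyError, match="sp01_ghost"):
            classify_all(bad, {"sp01": ds}, {"sp01": net})

    def test_buckets_partition(self, small_sim):
        _, datasets, orthogroups, _, _ = small_sim
        recs = []
        for sp, ds in datasets.items():
            net = build_network(ds, median_expression_subset(ds))
            recs.append(classify_all(orthogroups, {sp: ds}, {sp: net}))
        records = pd.concat(recs)
        assert set(records["bucket"]) <= set(BUCKETS)
        summary = funnel_summary(records)
        assert sum(summary["buckets"].values()) == summary["n_pairs"]
        assert sum(summary["bucket_fractions"].values()) == pytest.approx(1.0)
        classified = records["bucket"] == "classified"
        assert (records.loc[classified, "group"] != "none").all()
        assert (records.loc[~classified, "group"] == "none").all()

    def test_noise_free_recovery_perfect(self, noise_free_sim):
        _, datasets, orthogroups, _, truth = noise_free_sim
        recs = []
        for sp, ds in datasets.items():
            net = build_network(ds, median_expression_subset(ds))
            recs.append(classify_all(orthogroups, {sp: ds}, {sp: net}))
        records = pd.concat(recs)
        merged = records.merge(
            truth.pairs, on=["orthogroup_id", "species", "gene_a", "gene_b"]
        )
        assert (merged["group"] == merged["mode"]).all()

    def test_relaxed_thresholds_monotone_coverage(self, small_sim):
        _, datasets, orthogroups, _, _ = small_sim
        sp = "sp01"
        ds = datasets[sp]
        net = build_network(ds, median_expression_subset(ds))
        strict = classify_all(orthogroups, {sp: ds}, {sp: net}, RunConfig())
        relaxed = classify_all(
            orthogroups, {sp: ds}, {sp: net},
            RunConfig(coexpr_high=0.7, coexpr_low=0.7, fc_sd=2.0),
        )
        key = ["orthogroup_id", "gene_a", "gene_b"]
        s = strict.set_index(key)["bucket"]
        r = relaxed.set_index(key)["bucket"]
        was_classified = s[s == "classified"].index
        assert (r.loc[was_classified] == "classified").all()


class TestSharedDomains:
    def _mean_expr(self):
        table = pd.DataFrame(
            {
                "apex": [5.0, 1.0],
                "cotyledon": [1.0, 1.0],
                "hypocotyl": [0.0, 0.0],
                "inflorescence": [2.0, 8.0],
                "leaves": [9.0, 4.0],
            },
            index=pd.Index(["gA", "gB"], name="gene_id"),
        )
        return MeanExpression({"spx": table})

    def test_intersection(self):
        me = self._mean_expr()
        # gA > 3 in {apex, leaves}; gB > 3 in {inflorescence, leaves}
        assert shared_expression_domains("gA", "gB", me, "spx") == 1

    def test_full_overlap(self):
        table = pd.DataFrame(
            np.full((2, 5), 10.0),
            index=pd.Index(["gA", "gB"], name="gene_id"),
            columns=["apex", "cotyledon", "hypocotyl", "inflorescence", "leaves"],
        )
        me = MeanExpression({"spx": table})
        assert shared_expression_domains("gA", "gB", me, "spx") == 5

    def test_matches_brute_force_random(self):
        rng = np.random.default_rng(2)
        vals = rng.gamma(2.0, 3.0, size=(2, 5))
        table = pd.DataFrame(vals, index=pd.Index(["gA", "gB"]),
                             columns=[f"t{i}" for i in range(5)])
        me = MeanExpression({"spx": table})
        expected = sum(
            1 for t in range(5) if vals[0, t] > 3.0 and vals[1, t] > 3.0
        )
        assert shared_expression_domains("gA", "gB", me, "spx") == expected


def test_wgd_ssd_strata_windows():
    records = pd.DataFrame(
        {
            "dup_type": ["WGD", "WGD", "WGD", "tandem", "proximal", "tandem",
                         "dispersed", "WGD"],
            "ks": [0.2, 2.5, 0.1, 0.05, 2.5, 0.04, 1.0, np.nan],
        }
    )
    strata = wgd_ssd_strata(records)
    assert list(strata) == [
        "WGD", "WGD", "excluded", "SSD", "SSD", "excluded", "excluded",
        "excluded",
    ]
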