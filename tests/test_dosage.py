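import math

import numpy as np
import pandas as pd
import pytest

from parevo.config import RunConfig
from parevo.dosage import (
    aggregate_and_call,
    bh_adjust,
    dosage_comparisons,
    retained_orthogroups,
    run_dosage_test,
)
from parevo.io import OrthogroupTable
from parevo.qc import MeanExpression


def _mean_expr(tables):
    return MeanExpression(
        {
            sp: pd.DataFrame(vals, index=pd.Index(list(genes), name="gene_id"),
                             columns=list(tissues))
            for sp, (genes, tissues, vals) in tables.items()
        }
    )


def _og(members, species):
    return OrthogroupTable(members, tuple(species))


class TestRetainedOrthogroups:
    def _fixture(self, b_copies=2, zero_gene=False):
        genes_a = ["a1", "a2"]
        genes_b = [f"b{i}" for i in range(1, b_copies + 1)]
        va = np.array([[2.0], [3.0]])
        vb = np.ones((b_copies, 1)) * 4.0
        if zero_gene:
            vb[0, 0] = 0.0
        me = _mean_expr(
            {"spA": (genes_a, ["apex"], va), "spB": (genes_b, ["apex"], vb)}
        )
        og = _og({"OG1": {"spA": tuple(genes_a), "spB": tuple(genes_b)}},
                 ["spA", "spB"])
        return me, og

    def test_two_vs_three_copies_excluded(self):
        me, og = self._fixture(b_copies=3)
        assert retained_orthogroups("apex", "spA", "spB", me, og) == []

    def test_zero_mean_gene_excluded(self):
        me, og = self._fixture(zero_gene=True)
        assert retained_orthogroups("apex", "spA", "spB", me, og) == []

    def test_two_plus_two_all_positive_retained(self):
        me, og = self._fixture()
        assert retained_orthogroups("apex", "spA", "spB", me, og) == ["OG1"]


class TestDosageComparisons:
    def _me(self, totals_a, totals_b):
        n = len(totals_a)
        genes_a = [f"a{i}{c}" for i in range(n) for c in "xy"]
        genes_b = [f"b{i}{c}" for i in range(n) for c in "xy"]
        va = np.repeat(np.asarray(totals_a) / 2.0, 2)[:, None]
        vb = np.repeat(np.asarray(totals_b) / 2.0, 2)[:, None]
        me = _mean_expr(
            {"spA": (genes_a, ["apex"], va), "spB": (genes_b, ["apex"], vb)}
        )
        members = {
            f"OG{i}": {
                "spA": (f"a{i}x", f"a{i}y"),
                "spB": (f"b{i}x", f"b{i}y"),
            }
            for i in range(n)
        }
        return me, _og(members, ["spA", "spB"]), [f"OG{i}" for i in range(n)]

    def test_identical_ratios_all_p_one(self):
        me, og, retained = self._me([2.0, 4.0, 8.0], [1.0, 2.0, 4.0])
        out = dosage_comparisons("apex", "spA", "spB", retained, me, og)
        np.testing.assert_array_equal(out["z"], 0.0)
        np.testing.assert_array_equal(out["p"], 1.0)

    def test_worked_example_ratios(self):
        # log2 ratios [0, 0.1, -0.1, 2.0]
        totals_b = [1.0, 1.0, 1.0, 1.0]
        totals_a = [2.0 ** r for r in (0.0, 0.1, -0.1, 2.0)]
        me, og, retained = self._me(totals_a, totals_b)
        out = dosage_comparisons("apex", "spA", "spB", retained, me, og)
        ratios = np.array([0.0, 0.1, -0.1, 2.0])
        sd = ratios.std(ddof=1)
        z_last = (2.0 - 0.5) / sd
        assert out["log2_ratio"].to_numpy() == pytest.approx(ratios, abs=1e-12)
        assert out["z"].iloc[3] == pytest.approx(z_last, abs=1e-10)
        # independent normal-CDF oracle via erfc
        p_expected = math.erfc(abs(z_last) / math.sqrt(2.0))
        assert out["p"].iloc[3] == pytest.approx(p_expected, abs=1e-12)

    def test_z_to_p_closed_forms(self):
        from scipy import stats as sps

        assert 2.0 * sps.norm.sf(0.0) == 1.0
        assert 2.0 * sps.norm.sf(1.959964) == pytest.approx(0.05, abs=1e-4)

    def test_orientation_symmetry(self):
        me, og, retained = self._me([2.0, 5.0, 3.0, 9.0], [1.0, 2.0, 6.0, 4.0])
        fwd = dosage_comparisons("apex", "spA", "spB", retained, me, og)
        rev = dosage_comparisons("apex", "spB", "spA", retained, me, og)
        np.testing.assert_allclose(fwd["log2_ratio"], -rev["log2_ratio"], atol=1e-12)
        np.testing.assert_allclose(fwd["z"], -rev["z"], atol=1e-12)
        np.testing.assert_allclose(fwd["p"], rev["p"], atol=1e-12)


def brute_force_bh(p):
    """Textbook step-up: q_(i) = min_{j>=i} p_(j) * m / j, capped at 1."""
    p = list(p)
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    out = [None] * m
    for pos, i in enumerate(order, start=1):
        q = min(p[order[j - 1]] * m / j for j in range(pos, m + 1))
        out[i] = min(q, 1.0)
    return out


class TestBHAdjust:
    def test_single_p_unchanged(self):
        assert bh_adjust([0.3]).tolist() == [0.3]

    def test_two_value_example(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.04]), [0.02, 0.04])

    def test_textbook_all_equal_example(self):
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_monotone_vs_raw(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            p = rng.uniform(1e-8, 1.0, size=rng.integers(1, 30))
            adj = bh_adjust(p)
            assert (adj >= p - 1e-15).all()
            assert (adj <= 1.0).all()

    def test_oracle_equivalence(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            p = rng.uniform(1e-8, 1.0, size=rng.integers(1, 40))
            np.testing.assert_allclose(bh_adjust(p), brute_force_bh(p), atol=1e-12)

    def test_statsmodels_agreement(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(2)
        p = rng.uniform(1e-8, 1.0, 100)
        np.testing.assert_allclose(
            bh_adjust(p), multipletests(p, method="fdr_bh")[1], atol=1e-12
        )

    @pytest.mark.parametrize("bad", [[0.0], [1.1], [-0.2], [float("nan")]])
    def test_invalid_p_rejected(self, bad):
        with pytest.raises(ValueError):
            bh_adjust(bad)


class TestAggregateAndCall:
    def _comparisons(self, rows):
        return pd.DataFrame(
            rows,
            columns=["tissue", "focal", "other", "orthogroup_id",
                     "total_focal", "total_other", "log2_ratio", "z", "p"],
        )

    def test_single_comparison_mean_p(self):
        comps = self._comparisons(
            [("apex", "spA", "spB", "OG1", 2.0, 1.0, 1.0, 2.0, 0.0455)]
        )
        calls = aggregate_and_call(comps)
        assert calls.iloc[0]["mean_p"] == pytest.approx(0.0455)
        assert calls.iloc[0]["n_comparisons"] == 1

    def test_all_p_one_constrained(self):
        comps = self._comparisons(
            [
                ("apex", "spA", "spB", f"OG{i}", 2.0, 2.0, 0.0, 0.0, 1.0)
                for i in range(5)
            ]
        )
        calls = aggregate_and_call(comps)
        assert (calls["call"] == "constrained").all()
        assert (calls["adj_p"] == 1.0).all()

    def test_bh_scope_within_species_tissue(self):
        # two (species, tissue) blocks with different p distributions must
        # be adjusted independently
        rows = [("apex", "spA", "spB", f"OG{i}", 2.0, 1.0, 0.0, 0.0, 0.001)
                for i in range(3)]
        rows += [("leaves", "spA", "spB", f"OG{i}", 2.0, 1.0, 0.0, 0.0, 0.9)
                 for i in range(3)]
        calls = aggregate_and_call(self._comparisons(rows))
        apex = calls[calls["tissue"] == "apex"]
        leaves = calls[calls["tissue"] == "leaves"]
        assert (apex["call"] == "unconstrained").all()
        assert (leaves["call"] == "constrained").all()

    def test_mean_over_multiple_partners(self):
        rows = [
            ("apex", "spA", "spB", "OG1", 2.0, 1.0, 0.0, 0.0, 0.2),
            ("apex", "spA", "spC", "OG1", 2.0, 1.0, 0.0, 0.0, 0.6),
        ]
        calls = aggregate_and_call(self._comparisons(rows))
        rec = calls[(calls["species"] == "spA")].iloc[0]
        assert rec["mean_p"] == pytest.approx(0.4)
        assert rec["n_comparisons"] == 2

    def test_z_cutoff_option(self):
        rows = [("apex", "spA", "spB", f"OG{i}", 2.0, 1.0, 0.0, 1.0, 0.001)
                for i in range(3)]
        calls = aggregate_and_call(
            self._comparisons(rows), RunConfig(z_cutoff=2.0)
        )
        assert (calls["call"] == "constrained").all()


class TestRunDosageTest:
    def _sim_mean_expr(self, n_species=3, n_og=8, seed=0, drift_og=None,
                       tissues=("apex", "leaves")):
        rng = np.random.default_rng(seed)
        tables = {}
        members = {f"OG{i}": {} for i in range(n_og)}
        totals = rng.gamma(3.0, 10.0, size=(n_og, len(tissues)))
        for s in range(n_species):
            sp = f"sp{s}"
            genes, vals = [], []
            for i in range(n_og):
                t = totals[i] * rng.uniform(0.9, 1.1)  # mild species noise
                if drift_og == (i, sp):
                    t = t * 4.0
                f = rng.uniform(0.3, 0.7)
                genes += [f"{sp}_o{i}a", f"{sp}_o{i}b"]
                vals += [t * f, t * (1 - f)]
                members[f"OG{i}"][sp] = (f"{sp}_o{i}a", f"{sp}_o{i}b")
            tables[sp] = (genes, tissues, np.array(vals))
        return _mean_expr(tables), _og(members, [f"sp{s}" for s in range(n_species)])

    def test_matches_per_orthogroup_route(self):
        # dual route: the vectorized pipeline equals the per-orthogroup
        # retained_orthogroups + dosage_comparisons path
        me, og = self._sim_mean_expr()
        comps, _ = run_dosage_test(me, og)
        fwd = comps[(comps["tissue"] == "apex") & (comps["focal"] == "sp0")
                    & (comps["other"] == "sp1")]
        retained = retained_orthogroups("apex", "sp0", "sp1", me, og)
        slow = dosage_comparisons("apex", "sp0", "sp1", retained, me, og)
        merged = fwd.merge(slow, on="orthogroup_id", suffixes=("", "_slow"))
        assert len(merged) == len(slow) > 0
        np.testing.assert_allclose(merged["log2_ratio"],
                                   merged["log2_ratio_slow"], atol=1e-12)
        np.testing.assert_allclose(merged["p"], merged["p_slow"], atol=1e-12)

    def test_tissue_in_single_species_skipped(self):
        me, og = self._sim_mean_expr(n_species=2)
        # add a tissue that only one species has
        me.tables["sp0"]["prickle"] = 5.0
        comps, calls = run_dosage_test(me, og)
        assert "prickle" not in set(comps["tissue"])

    def test_too_few_retained_skipped(self):
        me, og = self._sim_mean_expr(n_og=2)
        comps, calls = run_dosage_test(me, og)
        assert comps.empty and calls.empty

    def test_species_rollup_column(self):
        me, og = self._sim_mean_expr(drift_og=(0, "sp0"))
        _, calls = run_dosage_test(me, og)
        sub = calls[(calls["orthogroup_id"] == "OG0") & (calls["species"] == "sp0")]
        if (sub["call"] == "unconstrained").any():
            assert sub["unconstrained_any_tissue"].all()

    def test_zero_spread_degenerate(self):
        # perfectly conserved totals and identical splits -> sd 0 -> p = 1
        me, og = self._sim_mean_expr(seed=1)
        for sp in me.tables:
            base = me.tables["sp0"].to_numpy()
            me.tables[sp].iloc[:, :] = base
        comps, calls = run_dosage_test(me, og)
        np.testing.assert_array_equal(comps["z"], 0.0)
        assert (calls["call"] == "constrained").all()
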