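"""DEG screening stage: size factors, the t screen, BH and intersection."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st_
from scipy import stats

from cernax.deg import (
    bh_adjust,
    call_and_intersect,
    call_degs,
    deg_test,
    size_factors,
)
from cernax.errors import CernaxError
from cernax.simulate import CohortConfig, generate_cohort


def _frame(rows, columns=None):
    arr = np.asarray(rows)
    columns = columns or [f"s{j}" for j in range(arr.shape[1])]
    return pd.DataFrame(arr, index=[f"g{i}" for i in range(arr.shape[0])],
                        columns=columns)


class TestSizeFactors:
    def test_hand_computed_example(self):
        counts = _frame([[10, 20], [20, 40], [30, 60]])
        f = size_factors(counts)
        # geometric means 14.142, 28.284, 42.426; per-sample ratio medians
        assert f.to_numpy() == pytest.approx([0.7071, 1.4142], abs=1e-4)

    def test_identical_columns_equal_factors(self):
        counts = _frame([[5, 5, 5], [17, 17, 17], [3, 3, 3]])
        f = size_factors(counts)
        assert np.allclose(f, f.iloc[0])

    def test_single_sample_factor_one(self):
        counts = _frame([[10], [20], [30]])
        assert size_factors(counts).to_numpy() == pytest.approx([1.0])

    def test_no_all_positive_gene(self):
        counts = _frame([[0, 5], [5, 0]])
        with pytest.raises(CernaxError, match="pseudocount"):
            size_factors(counts)

    def test_invariant_to_gene_reordering(self):
        rng = np.random.default_rng(3)
        counts = _frame(rng.integers(1, 100, size=(20, 4)))
        f1 = size_factors(counts)
        f2 = size_factors(counts.iloc[::-1])
        assert np.allclose(f1, f2)


class TestDegTest:
    def _ones(self, cols):
        return pd.Series(1.0, index=cols)

    def test_identical_groups_null(self):
        counts = _frame([[4, 4, 4, 4]])
        res = deg_test(counts, self._ones(counts.columns),
                       ["s0", "s1"], ["s2", "s3"])
        assert res.loc["g0", "log2fc"] == 0.0
        assert res.loc["g0", "p_raw"] == 1.0

    def test_exact_log2fc(self):
        # normalized means 3 vs 1 -> log2(4/2) = 1 exactly
        counts = _frame([[3, 3, 1, 1]])
        res = deg_test(counts, self._ones(counts.columns),
                       ["s0", "s1"], ["s2", "s3"])
        assert res.loc["g0", "log2fc"] == 1.0

    def test_welch_oracle(self):
        rng = np.random.default_rng(11)
        a = rng.poisson(400, 5)
        b = rng.poisson(100, 5)
        counts = _frame([np.concatenate([a, b])])
        res = deg_test(counts, self._ones(counts.columns),
                       [f"s{j}" for j in range(5)],
                       [f"s{j}" for j in range(5, 10)])
        # independent Welch computation from first principles
        xa, xb = np.log2(a + 1.0), np.log2(b + 1.0)
        va, vb = xa.var(ddof=1) / 5, xb.var(ddof=1) / 5
        t = (xa.mean() - xb.mean()) / np.sqrt(va + vb)
        df = (va + vb) ** 2 / (va ** 2 / 4 + vb ** 2 / 4)
        p = 2 * stats.t.sf(abs(t), df)
        assert res.loc["g0", "p_raw"] == pytest.approx(p, abs=1e-10)

    def test_group_relabel_flips_sign_keeps_p(self):
        rng = np.random.default_rng(5)
        counts = _frame(rng.integers(0, 300, size=(30, 8)))
        f = size_factors(counts + 1) * 0 + 1.0
        a, b = list(counts.columns[:4]), list(counts.columns[4:])
        r1 = deg_test(counts, f, a, b)
        r2 = deg_test(counts, f, b, a)
        assert np.allclose(r1["log2fc"], -r2["log2fc"])
        assert np.allclose(r1["p_raw"], r2["p_raw"])

    def test_paired_mode(self):
        rng = np.random.default_rng(8)
        base = rng.integers(50, 150, 6)
        counts = _frame([np.concatenate([base * 4, base])])
        cols = list(counts.columns)
        res = deg_test(counts, self._ones(counts.columns),
                       cols[:6], cols[6:], paired=True)
        diffs = np.log2(base * 4 + 1.0) - np.log2(base + 1.0)
        t, p = stats.ttest_1samp(diffs, 0.0)
        assert res.loc["g0", "p_raw"] == pytest.approx(p, abs=1e-12)

    def test_errors(self):
        counts = _frame([[1, 2, 3, 4, 5]])
        ones = self._ones(counts.columns)
        with pytest.raises(CernaxError, match="at least 2"):
            deg_test(counts, ones, ["s0"], ["s1", "s2"])
        with pytest.raises(CernaxError, match="disjoint"):
            deg_test(counts, ones, ["s0", "s1"], ["s1", "s2"])
        with pytest.raises(CernaxError, match="equal group sizes"):
            deg_test(counts, ones, ["s0", "s1"], ["s2", "s3", "s4"], paired=True)

    def test_null_type_one_error_calibration(self):
        """Raw-p type-I within 3 SE of 0.05 over >= 1000 null genes."""
        fracs = []
        n_genes = 1210
        for seed in range(3):
            cfg = CohortConfig(
                n_tumor=20, n_paired_normal=12, n_olnm_pos=7,
                n_lncrna=5, n_pcg=1200, n_mirna=5,
                n_true_axes=0, n_decoys_per_class=0, effect_log2fc=0.0,
                lncrna_len=60, utr_len=60, seed=seed,
            )
            c = generate_cohort(cfg)
            res = deg_test(c.counts, size_factors(c.counts),
                           c.tumor_samples, c.normal_samples)
            fracs.append((res["p_raw"] < 0.05).mean())
        se = np.sqrt(0.05 * 0.95 / (n_genes * len(fracs)))
        assert abs(np.mean(fracs) - 0.05) < 3 * se + 1e-12


class TestBHAdjust:
    def test_hand_example(self):
        out = bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert out == pytest.approx([0.04, 0.04, 0.04, 0.04])

    def test_single_and_all_ones(self):
        assert bh_adjust([0.3]) == pytest.approx([0.3])
        assert bh_adjust([1.0, 1.0, 1.0]) == pytest.approx([1, 1, 1])

    def test_out_of_range_rejected(self):
        with pytest.raises(CernaxError):
            bh_adjust([0.5, 1.5])
        with pytest.raises(CernaxError):
            bh_adjust([-0.1])

    @settings(max_examples=100, deadline=None)
    @given(st_.lists(st_.floats(0, 1), min_size=1, max_size=50))
    def test_properties_and_statsmodels_oracle(self, p):
        from statsmodels.stats.multitest import multipletests

        adj = bh_adjust(p)
        assert np.all(adj >= np.asarray(p) - 1e-15)
        assert np.all(adj <= 1.0)
        order = np.argsort(p, kind="mergesort")
        assert np.all(np.diff(adj[order]) >= -1e-12)
        ref = multipletests(p, method="fdr_bh")[1]
        assert np.allclose(adj, ref, atol=1e-12)

    @settings(max_examples=50, deadline=None)
    @given(st_.lists(st_.floats(0, 1), min_size=2, max_size=30),
           st_.randoms(use_true_random=False))
    def test_permutation_equivariance(self, p, rnd):
        idx = list(range(len(p)))
        rnd.shuffle(idx)
        adj = bh_adjust(p)
        adj_perm = bh_adjust([p[i] for i in idx])
        assert np.allclose([adj[i] for i in idx], adj_perm)


class TestCallAndIntersect:
    def _records(self, data):
        df = pd.DataFrame(data, columns=["gene_id", "gene_class", "log2fc", "p_raw"])
        return df.set_index("gene_id")

    def test_fc_boundary_exclusive_below(self):
        rec = self._records([("gA", "lncRNA", 0.9, 0.001)])
        out = call_degs(rec)
        assert not out.loc["gA", "is_deg"]

    def test_fc_boundary_inclusive_at_one(self):
        rec = self._records([("gA", "lncRNA", 1.0, 0.049)])
        out = call_degs(rec)
        assert out.loc["gA", "is_deg"]
        assert out.loc["gA", "direction"] == "up"

    def test_alpha_strict(self):
        rec = self._records([("gA", "lncRNA", 2.0, 0.05)])
        assert not call_degs(rec).loc["gA", "is_deg"]

    def test_set_intersection(self):
        rows1 = [("A", "lncRNA", 2, 1e-5), ("B", "lncRNA", 2, 1e-5),
                 ("C", "lncRNA", -2, 1e-5), ("D", "lncRNA", 0.1, 0.9)]
        rows2 = [("A", "lncRNA", 0.1, 0.9), ("B", "lncRNA", 2, 1e-5),
                 ("C", "lncRNA", -2, 1e-5), ("D", "lncRNA", 2, 1e-5)]
        res = call_and_intersect(
            {"c1": self._records(rows1), "c2": self._records(rows2)}
        )
        assert res.deg_sets["c1"] == {"A", "B", "C"}
        assert res.deg_sets["c2"] == {"B", "C", "D"}
        assert res.common == ["B", "C"]
        assert res.directions["c1"]["C"] == "down"

    def test_mismatched_universe_rejected(self):
        r1 = self._records([("A", "lncRNA", 1, 0.01)])
        r2 = self._records([("B", "lncRNA", 1, 0.01)])
        with pytest.raises(CernaxError, match="universe"):
            call_and_intersect({"c1": r1, "c2": r2})

    def test_class_filter(self):
        rows = [("A", "lncRNA", 2, 1e-6), ("B", "PCG", 2, 1e-6)]
        res = call_and_intersect({"c1": self._records(rows)}, gene_class="lncRNA")
        assert res.deg_sets["c1"] == {"A"}

    def test_planted_lncrnas_in_intersection(self, default_cohort):
        from cernax.simulate import AxisRole

        c = default_cohort
        sf = size_factors(c.counts)
        paired = [s for s in c.tumor_samples
                  if c.sample_table.loc[s, "pair_id"] != "-"]
        olnm_pos = [s for s in c.tumor_samples
                    if c.sample_table.loc[s, "olnm"] == 1]
        olnm_neg = [s for s in c.tumor_samples
                    if c.sample_table.loc[s, "olnm"] == 0]
        recs = {
            "tn": deg_test(c.counts, sf, paired, c.normal_samples,
                           gene_classes=c.gene_classes),
            "olnm": deg_test(c.counts, sf, olnm_pos, olnm_neg,
                             gene_classes=c.gene_classes),
        }
        res = call_and_intersect(recs, gene_class="lncRNA")
        common = set(res.common)
        for a in c.truth:
            if a.role is AxisRole.TRUE_AXIS:
                assert a.lncrna_id in common
            elif a.role is AxisRole.DECOY_NOT_DE:
                assert a.lncrna_id not in common
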