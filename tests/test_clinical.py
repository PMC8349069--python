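"""Clinical statistics: exact tests, chi-squared, KM/log-rank, ddCt."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.special import comb

from cernax.clinical import (
    chi2_test,
    clinicopathologic_tables,
    delta_delta_ct,
    fisher_exact_2x2,
    freeman_halton_exact,
    km_curve,
    km_logrank,
    median_split,
)
from cernax.errors import CernaxError


def fisher_enumeration_oracle(table) -> float:
    """Independent two-sided Fisher p: sum of point probabilities <= observed."""
    a, b = table[0]
    c, d = table[1]
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def point(x):  # table [[x, r1-x], [c1-x, ...]] probability
        return (
            comb(r1, x, exact=True)
            * comb(r2, c1 - x, exact=True)
            / comb(n, c1, exact=True)
        )

    lo, hi = max(0, c1 - r2), min(r1, c1)
    p_obs = point(a)
    return sum(point(x) for x in range(lo, hi + 1) if point(x) <= p_obs * (1 + 1e-7))


class TestMedianSplit:
    def test_even_distinct_values_split_in_half(self):
        values = {f"s{i}": float(i) for i in range(34)}
        groups = median_split(values)
        assert sum(g == "low" for g in groups.values()) == 17
        assert sum(g == "high" for g in groups.values()) == 17

    def test_all_equal_all_low(self):
        groups = median_split({"a": 1.0, "b": 1.0, "c": 1.0})
        assert set(groups.values()) == {"low"}

    def test_odd_n_median_goes_low(self):
        groups = median_split({k: v for k, v in zip("abcde", [1, 2, 3, 4, 5])})
        assert {k for k, g in groups.items() if g == "low"} == {"a", "b", "c"}

    def test_empty_rejected(self):
        with pytest.raises(CernaxError):
            median_split({})


class TestFisherExact:
    def test_smoking_row(self):
        assert fisher_exact_2x2([[11, 7], [6, 10]]) == pytest.approx(0.303, abs=5e-4)

    def test_modal_table_p_one(self):
        assert fisher_exact_2x2([[5, 5], [5, 5]]) == pytest.approx(1.0)

    def test_derived_example(self):
        p = fisher_exact_2x2([[14, 3], [5, 12]])
        assert p == pytest.approx(0.0049, rel=0.02)
        assert p == pytest.approx(fisher_enumeration_oracle([[14, 3], [5, 12]]),
                                  rel=1e-10)

    def test_row_and_column_swap_invariance(self):
        t = [[9, 2], [4, 8]]
        swapped = [[8, 4], [2, 9]]
        assert fisher_exact_2x2(t) == pytest.approx(fisher_exact_2x2(swapped))

    def test_non_2x2_directed_to_freeman_halton(self):
        with pytest.raises(CernaxError, match="freeman_halton"):
            fisher_exact_2x2([[1, 2, 3], [4, 5, 6]])

    def test_zero_margin_rejected(self):
        with pytest.raises(CernaxError, match="margins"):
            fisher_exact_2x2([[0, 0], [1, 2]])

    def test_matches_enumeration_oracle_grid(self):
        rng = np.random.default_rng(4)
        for _ in range(200):
            t = rng.integers(1, 12, size=(2, 2))
            assert fisher_exact_2x2(t) == pytest.approx(
                fisher_enumeration_oracle(t.tolist()), rel=1e-9
            )


class TestChi2:
    def test_table_equal_to_expected(self):
        stat, df, p = chi2_test([[10, 10], [10, 10]])
        assert stat == 0.0 and p == pytest.approx(1.0)

    def test_olnm_row_yates(self):
        stat, df, p = chi2_test([[14, 5], [3, 12]], yates=True)
        assert df == 1
        assert round(p, 3) == 0.006

    def test_pathologic_n_row(self):
        stat, df, p = chi2_test([[14, 5], [1, 8], [2, 4]], yates=False)
        assert df == 2
        assert round(p, 3) == 0.006

    def test_yates_ignored_for_rxc(self):
        stat1, _, _ = chi2_test([[5, 6, 7], [8, 9, 10]], yates=True)
        stat2, _, _ = chi2_test([[5, 6, 7], [8, 9, 10]], yates=False)
        assert stat1 == stat2

    def test_zero_expected_rejected(self):
        with pytest.raises(CernaxError, match="expected"):
            chi2_test([[0, 0], [1, 2]])


class TestFreemanHalton:
    def test_agrees_with_fisher_on_2x2(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            t = rng.integers(1, 8, size=(2, 2))
            assert freeman_halton_exact(t) == pytest.approx(
                fisher_exact_2x2(t), abs=1e-12
            )

    def test_proportional_rows_p_one(self):
        assert freeman_halton_exact([[2, 4], [3, 6]]) == pytest.approx(1.0)

    def test_diagonal_3_3(self):
        # margins (3,3)/(3,3): tables k=0..3 with probs 1/20, 9/20, 9/20, 1/20
        assert freeman_halton_exact([[3, 0], [0, 3]]) == pytest.approx(0.1)

    def test_2x3_against_full_enumeration(self):
        table = [[5, 2, 1], [1, 4, 5]]
        # direct oracle: enumerate first row, derive second from margins
        r1 = sum(table[0])
        cols = [table[0][j] + table[1][j] for j in range(3)]
        n = sum(cols)
        from math import comb as C

        def prob(t0, t1, t2):
            # 2-row table: draw the first row from the column margins
            if min(cols[0] - t0, cols[1] - t1, cols[2] - t2) < 0:
                return None
            return C(cols[0], t0) * C(cols[1], t1) * C(cols[2], t2) / C(n, r1)

        p_obs = prob(*table[0])
        acc = 0.0
        for t0 in range(cols[0] + 1):
            for t1 in range(cols[1] + 1):
                t2 = r1 - t0 - t1
                if t2 < 0 or t2 > cols[2]:
                    continue
                p = prob(t0, t1, t2)
                if p is not None and p <= p_obs * (1 + 1e-7):
                    acc += p
        assert freeman_halton_exact(table) == pytest.approx(acc, rel=1e-9)

    def test_too_large_rejected(self):
        with pytest.raises(CernaxError, match="chi2_test"):
            freeman_halton_exact([[40, 40], [40, 40]])


class TestKaplanMeierLogrank:
    def test_curve_starts_at_one_and_decreases(self):
        cv = km_curve([5, 8, 12, 20], [1, 0, 1, 1])
        assert cv.at(1.0) == 1.0
        assert np.all(np.diff(cv.survival) <= 1e-12)
        assert cv.survival[0] == pytest.approx(0.75)

    def test_identical_groups_null(self):
        times = [3, 5, 7, 9] * 2
        events = [1, 1, 0, 1] * 2
        groups = ["a"] * 4 + ["b"] * 4
        _, stat, p = km_logrank(times, events, groups)
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_hand_computed_statistic(self):
        # A deaths at 1,2; B deaths at 3,4: O_A=2, E_A=0.8333, V=0.4722
        times = [1, 2, 3, 4]
        events = [1, 1, 1, 1]
        groups = ["A", "A", "B", "B"]
        _, stat, p = km_logrank(times, events, groups)
        assert stat == pytest.approx(2.882, abs=5e-4)

    def test_all_censored_warns(self):
        with pytest.warns(UserWarning):
            _, stat, p = km_logrank([1, 2, 3, 4], [0, 0, 0, 0],
                                    ["a", "a", "b", "b"])
        assert (stat, p) == (0.0, 1.0)

    def test_against_lifelines(self):
        from lifelines import KaplanMeierFitter
        from lifelines.statistics import logrank_test

        rng = np.random.default_rng(12)
        times = rng.exponential(10, 60)
        events = (rng.random(60) < 0.7).astype(int)
        groups = np.where(rng.random(60) < 0.5, "a", "b")
        curves, stat, p = km_logrank(times, events, groups)
        ref = logrank_test(times[groups == "a"], times[groups == "b"],
                           events[groups == "a"], events[groups == "b"])
        assert stat == pytest.approx(ref.test_statistic, rel=1e-9)
        assert p == pytest.approx(ref.p_value, rel=1e-9)
        kmf = KaplanMeierFitter().fit(times[groups == "a"], events[groups == "a"])
        for t in (1.0, 5.0, 15.0):
            assert curves["a"].at(t) == pytest.approx(
                float(kmf.survival_function_at_times(t).iloc[0]), abs=1e-9
            )

    def test_logrank_null_calibration(self):
        """Rejection rate at 0.05 within 3 SE over 200 null cohorts."""
        from cernax.simulate import CohortConfig, generate_cohort

        n_seeds, rej = 200, 0
        for seed in range(n_seeds):
            cfg = CohortConfig(
                n_tumor=40, n_paired_normal=2, n_olnm_pos=12,
                n_lncrna=2, n_pcg=2, n_mirna=1, n_true_axes=1,
                n_decoys_per_class=0, survival_hr=1.0,
                lncrna_len=200, utr_len=100, seed=seed,
            )
            c = generate_cohort(cfg)
            t = c.sample_table.loc[c.tumor_samples]
            g = median_split(c.counts.loc[c.truth[0].lncrna_id, c.tumor_samples])
            _, _, p = km_logrank(
                t["time_months"].to_numpy(), t["event"].to_numpy(),
                np.array([g[s] for s in c.tumor_samples]),
            )
            rej += p < 0.05
        se = np.sqrt(0.05 * 0.95 / n_seeds)
        assert abs(rej / n_seeds - 0.05) < 3 * se

    def test_positive_hazard_ratio_detected(self):
        """With a strong planted hazard ratio the log-rank should reject."""
        from cernax.simulate import CohortConfig, generate_cohort

        cfg = CohortConfig(
            n_tumor=60, n_paired_normal=2, n_olnm_pos=12, n_lncrna=2,
            n_pcg=2, n_mirna=1, n_true_axes=1, n_decoys_per_class=0,
            survival_hr=6.0, lncrna_len=200, utr_len=100, seed=5,
        )
        c = generate_cohort(cfg)
        t = c.sample_table.loc[c.tumor_samples]
        g = median_split(c.counts.loc[c.truth[0].lncrna_id, c.tumor_samples])
        _, _, p = km_logrank(
            t["time_months"].to_numpy(), t["event"].to_numpy(),
            np.array([g[s] for s in c.tumor_samples]),
        )
        assert p < 0.01


class TestDeltaDeltaCt:
    def _df(self, rows):
        return pd.DataFrame(
            rows, columns=["sample_id", "target", "ct_target", "ct_reference",
                           "condition"]
        )

    def test_equal_dct_fold_one(self):
        df = self._df([("s1", "g", 22, 18, "case"), ("s2", "g", 25, 21, "ctrl")])
        assert delta_delta_ct(df, "case", "ctrl")["g"] == pytest.approx(1.0)

    def test_hand_example_fold_four(self):
        df = self._df([("s1", "g", 24, 20, "case"), ("s2", "g", 26, 20, "ctrl")])
        assert delta_delta_ct(df, "case", "ctrl")["g"] == pytest.approx(4.0)

    def test_swap_inverts(self):
        df = self._df([("s1", "g", 24, 20, "case"), ("s2", "g", 26, 20, "ctrl")])
        f1 = delta_delta_ct(df, "case", "ctrl")["g"]
        f2 = delta_delta_ct(df, "ctrl", "case")["g"]
        assert f1 * f2 == pytest.approx(1.0)

    def test_missing_reference_rejected(self):
        df = self._df([("s1", "g", 24, np.nan, "case"), ("s2", "g", 26, 20, "ctrl")])
        with pytest.raises(CernaxError, match="reference"):
            delta_delta_ct(df, "case", "ctrl")

    def test_missing_condition_rejected(self):
        df = self._df([("s1", "g", 24, 20, "case")])
        with pytest.raises(CernaxError, match="condition"):
            delta_delta_ct(df, "case", "ctrl")


class TestBundledTables:
    def test_margins_are_17_17(self):
        for name, tab in clinicopathologic_tables().items():
            assert tab.to_numpy().sum() == 34
            assert tab["low"].sum() == 17
            assert tab["high"].sum() == 17

    def test_printed_age_sex_values_are_transposed(self):
        # The published table prints 1.000 for age and 0.493 for sex, but
        # Fisher on the printed cells yields the swapped values.
        tabs = clinicopathologic_tables()
        assert fisher_exact_2x2(tabs["age"].to_numpy()) == pytest.approx(
            0.493, abs=1e-3
        )
        assert fisher_exact_2x2(tabs["sex"].to_numpy()) == pytest.approx(
            1.000, abs=5e-4
        )
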