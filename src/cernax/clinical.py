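"""Clinical association statistics.

Median dichotomization, exact and asymptotic contingency-table tests,
the Kaplan-Meier product-limit estimator with the two-group log-rank
test, and delta-delta-Ct relative quantification.

Two-sided exact p-values follow the sum-of-smaller-probabilities
convention: the p-value accumulates every margin-preserving table whose
point probability is at most that of the observed table (with relative
tolerance 1e-7), which is also what :func:`scipy.stats.fisher_exact`
computes for 2x2 tables.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from math import lgamma
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .errors import CernaxError

_REL_TOL = 1.0 + 1e-7


def median_split(values: Mapping[str, float] | pd.Series) -> dict[str, str]:
    """Assign each sample to "low" (value <= median) or "high" (above).

    The median is the standard even/odd sample median; ties at the
    median go to "low", which keeps the split deterministic.
    """
    series = pd.Series(dict(values), dtype=float)
    if len(series) < 2:
        raise CernaxError("median_split needs at least 2 samples")
    med = float(series.median())
    return {k: ("low" if v <= med else "high") for k, v in series.items()}


def _as_table(table) -> np.ndarray:
    arr = np.asarray(table)
    if arr.ndim != 2:
        raise CernaxError("contingency table must be 2-dimensional")
    if not np.issubdtype(arr.dtype, np.integer):
        if not np.all(arr == np.floor(arr)):
            raise CernaxError("contingency table cells must be integers")
        arr = arr.astype(int)
    if (arr < 0).any():
        raise CernaxError("contingency table cells must be non-negative")
    return arr


def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher exact p for a 2x2 table with positive margins."""
    arr = _as_table(table)
    if arr.shape != (2, 2):
        raise CernaxError(
            "fisher_exact_2x2 handles 2x2 tables only; use "
            "freeman_halton_exact for r x c tables"
        )
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        raise CernaxError("all margins must be positive")
    return float(stats.fisher_exact(arr, alternative="two-sided").pvalue)


def chi2_test(table, yates: bool = False) -> tuple[float, int, float]:
    """Pearson chi-squared test of independence.

    Yates' continuity correction ((|O-E|-0.5)^2/E) applies to 2x2
    tables only.  Returns (statistic, df, upper-tail p).
    """
    arr = _as_table(table)
    expected = stats.contingency.expected_freq(arr)
    if (expected <= 0).any():
        raise CernaxError("chi-squared test undefined: zero expected cell")
    correction = bool(yates) and arr.shape == (2, 2)
    res = stats.chi2_contingency(arr, correction=correction)
    return float(res.statistic), int(res.dof), float(res.pvalue)


def _log_table_prob(arr: np.ndarray, row_sums, col_sums, lognfact) -> float:
    logp = sum(lgamma(r + 1) for r in row_sums)
    logp += sum(lgamma(c + 1) for c in col_sums)
    logp -= lognfact
    logp -= sum(lgamma(v + 1) for v in arr.ravel())
    return logp


def freeman_halton_exact(table, max_total: int = 60) -> float:
    """Two-sided exact test for an r x c table by full enumeration.

    Sums multivariate-hypergeometric probabilities of every table with
    the observed margins whose probability is <= the observed one.
    Refuses tables with total count above ``max_total``.
    """
    arr = _as_table(table)
    if arr.shape[0] < 2 or arr.shape[1] < 2:
        raise CernaxError("need at least a 2x2 table")
    row_sums = arr.sum(axis=1)
    col_sums = arr.sum(axis=0)
    if (row_sums == 0).any() or (col_sums == 0).any():
        raise CernaxError("all margins must be positive")
    total = int(arr.sum())
    if total > max_total:
        raise CernaxError(
            f"table total {total} exceeds {max_total}; use chi2_test instead"
        )
    lognfact = lgamma(total + 1)
    p_obs = _log_table_prob(arr, row_sums, col_sums, lognfact)
    threshold = p_obs + np.log(_REL_TOL)

    nrow, ncol = arr.shape
    p_sum = 0.0
    work = np.zeros_like(arr)

    def recurse(row: int, remaining_cols: np.ndarray) -> None:
        nonlocal p_sum
        if row == nrow - 1:
            work[row] = remaining_cols
            lp = _log_table_prob(work, row_sums, col_sums, lognfact)
            if lp <= threshold:
                p_sum += float(np.exp(lp))
            return
        target = row_sums[row]

        def fill(col: int, left: int) -> None:
            if col == ncol - 1:
                if left <= remaining_cols[col]:
                    work[row, col] = left
                    recurse(row + 1, remaining_cols - work[row])
                return
            for v in range(min(left, remaining_cols[col]) + 1):
                work[row, col] = v
                fill(col + 1, left - v)

        fill(0, int(target))

    recurse(0, col_sums.copy())
    return min(p_sum, 1.0)


@dataclass
class KMCurve:
    """Product-limit estimate for one group: step function S(t)."""

    times: np.ndarray       # distinct event times, ascending
    survival: np.ndarray    # S(t) just after each time
    n_at_risk: np.ndarray

    def at(self, t: float) -> float:
        """S(t); right-continuous, 1 before the first event."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


def km_curve(times, events) -> KMCurve:
    """Kaplan-Meier estimator with deaths before censorings at ties."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if times.size == 0:
        raise CernaxError("empty survival group")
    if (times <= 0).any():
        raise CernaxError("survival times must be positive")
    order = np.argsort(times, kind="mergesort")
    times, events = times[order], events[order]
    distinct = np.unique(times)
    surv, at_risk = [], []
    s = 1.0
    for t in distinct:
        n_risk = int((times >= t).sum())
        d = int(events[times == t].sum())
        if d > 0:
            s *= 1.0 - d / n_risk
        surv.append(s)
        at_risk.append(n_risk)
    return KMCurve(distinct, np.asarray(surv), np.asarray(at_risk))


def km_logrank(
    times, events, groups
) -> tuple[dict[str, KMCurve], float, float]:
    """KM curves per group plus the two-group log-rank test.

    Returns (curves, chi-squared statistic on 1 df, p).  If neither
    group has any event the statistic is 0 and p = 1, with a warning.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    groups = np.asarray(groups)
    labels = sorted(set(groups.tolist()))
    if len(labels) != 2:
        raise CernaxError(f"log-rank needs exactly 2 groups, got {len(labels)}")
    curves = {
        lab: km_curve(times[groups == lab], events[groups == lab])
        for lab in labels
    }
    if events.sum() == 0:
        warnings.warn("no events in either group; log-rank undefined")
        return curves, 0.0, 1.0

    ga = groups == labels[0]
    death_times = np.unique(times[events == 1])
    observed_a = 0.0
    expected_a = 0.0
    variance = 0.0
    for t in death_times:
        at_risk = times >= t
        n = int(at_risk.sum())
        n_a = int((at_risk & ga).sum())
        d = int(((times == t) & (events == 1)).sum())
        d_a = int(((times == t) & (events == 1) & ga).sum())
        observed_a += d_a
        expected_a += d * n_a / n
        if n > 1:
            variance += d * (n_a / n) * (1 - n_a / n) * (n - d) / (n - 1)
    if variance == 0:
        warnings.warn("log-rank variance is zero; returning p = 1")
        return curves, 0.0, 1.0
    statistic = (observed_a - expected_a) ** 2 / variance
    p = float(stats.chi2.sf(statistic, df=1))
    return curves, float(statistic), p


def delta_delta_ct(
    measurements: pd.DataFrame,
    condition_case: str,
    condition_control: str,
) -> dict[str, float]:
    """2^(-ddCt) fold change per target between two conditions.

    ``measurements`` columns: sample_id, target, ct_target, ct_reference,
    condition.  dCt = ct_target - ct_reference per measurement, averaged
    over replicates within each condition; ddCt = dCt_case - dCt_control.
    """
    required = {"target", "ct_target", "ct_reference", "condition"}
    if not required <= set(measurements.columns):
        raise CernaxError(f"measurements need columns {sorted(required)}")
    if measurements["ct_reference"].isna().any():
        raise CernaxError("missing reference Ct value")
    if measurements["ct_target"].isna().any():
        raise CernaxError("missing target Ct value")
    df = measurements.copy()
    df["dct"] = df["ct_target"] - df["ct_reference"]
    folds: dict[str, float] = {}
    for target, sub in df.groupby("target"):
        means = sub.groupby("condition")["dct"].mean()
        for cond in (condition_case, condition_control):
            if cond not in means.index:
                raise CernaxError(
                    f"no measurements for target {target!r} in condition {cond!r}"
                )
        ddct = means[condition_case] - means[condition_control]
        folds[str(target)] = float(2.0 ** (-ddct))
    return folds


def clinicopathologic_tables() -> dict[str, pd.DataFrame]:
    """Bundled 34-sample FFPE cohort: covariate x expression-group counts.

    Rows are covariate levels; columns are the low/high expression
    groups from a median split of the index lncRNA.
    """
    def tab(rows: dict[str, tuple[int, int]]) -> pd.DataFrame:
        return pd.DataFrame(rows, index=["low", "high"]).T

    return {
        "age": tab({"<52": (7, 10), ">=52": (10, 7)}),
        "sex": tab({"female": (4, 4), "male": (13, 13)}),
        "smoking": tab({"no": (11, 7), "yes": (6, 10)}),
        "clinical_t": tab({"T1": (7, 3), "T2": (10, 13), "T3": (0, 1)}),
        "pathologic_t": tab({"T1": (4, 1), "T2": (11, 13), "T3": (2, 3)}),
        "pathologic_n": tab({"N1": (14, 5), "N2": (1, 8), "N3": (2, 4)}),
        "olnm": tab({"no": (14, 5), "yes": (3, 12)}),
    }
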