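"""Differential-expression screening and DEG-set intersection.

The screen is deliberately simple and fully specified: median-of-ratios
size factors, Welch's t (or a paired one-sample t) on log2(normalized
count + 1), Benjamini-Hochberg adjustment, and the cut-offs
|log2FC| >= 1 (inclusive) with adjusted p < 0.05 (strict).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import CernaxError


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios per-sample scale factors.

    For each sample j, factor_j is the median over reference genes of
    count_gj / geomean_g, where geomean_g is the gene's geometric mean
    across samples and reference genes are those with all-positive
    counts.  Factors are reported unscaled (no recentring).
    """
    mat = counts.to_numpy(dtype=float)
    ref = (mat > 0).all(axis=1)
    if not ref.any():
        raise CernaxError(
            "no gene has positive counts in every sample; filter the matrix "
            "or add a pseudocount before computing size factors"
        )
    refmat = mat[ref]
    geomean = np.exp(np.log(refmat).mean(axis=1))
    factors = np.median(refmat / geomean[:, None], axis=0)
    return pd.Series(factors, index=counts.columns, name="size_factor")


def normalized_log2(counts: pd.DataFrame, factors: pd.Series) -> pd.DataFrame:
    """log2(count / size_factor + 1), the expression unit used downstream."""
    norm = counts.to_numpy(dtype=float) / factors.reindex(counts.columns).to_numpy()
    return pd.DataFrame(np.log2(norm + 1.0), index=counts.index, columns=counts.columns)


def deg_test(
    counts: pd.DataFrame,
    factors: pd.Series,
    group_a: list[str],
    group_b: list[str],
    paired: bool = False,
    gene_classes: pd.Series | None = None,
) -> pd.DataFrame:
    """Per-gene log2 fold change and raw p-value for one contrast.

    log2fc = log2((m_a + 1) / (m_b + 1)) with m the group mean of the
    normalized counts; p_raw from Welch's two-sample t on
    log2(normalized + 1) (unpaired) or a one-sample t on per-pair
    differences (paired, groups matched by order).  Genes with zero
    variance in both groups and equal means get p_raw = 1.
    """
    group_a, group_b = list(group_a), list(group_b)
    if set(group_a) & set(group_b):
        raise CernaxError("contrast groups must be disjoint")
    if len(group_a) < 2 or len(group_b) < 2:
        raise CernaxError("each contrast group needs at least 2 samples")
    if paired and len(group_a) != len(group_b):
        raise CernaxError("paired test requires equal group sizes")

    norm = counts.to_numpy(dtype=float) / factors.reindex(counts.columns).to_numpy()
    norm = pd.DataFrame(norm, index=counts.index, columns=counts.columns)
    na = norm[group_a].to_numpy()
    nb = norm[group_b].to_numpy()
    log2fc = np.log2((na.mean(axis=1) + 1.0) / (nb.mean(axis=1) + 1.0))

    xa = np.log2(na + 1.0)
    xb = np.log2(nb + 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        if paired:
            diff = xa - xb
            res = stats.ttest_1samp(diff, 0.0, axis=1)
            degenerate = diff.std(axis=1) == 0
            null_like = np.abs(diff.mean(axis=1)) == 0
        else:
            res = stats.ttest_ind(xa, xb, axis=1, equal_var=False)
            degenerate = (xa.std(axis=1) == 0) & (xb.std(axis=1) == 0)
            null_like = xa.mean(axis=1) == xb.mean(axis=1)
    p_raw = np.asarray(res.pvalue, dtype=float)
    # zero spread in both groups: p undefined under t; use the limits
    p_raw[degenerate & null_like] = 1.0
    p_raw[degenerate & ~null_like] = 0.0

    out = pd.DataFrame(
        {"log2fc": log2fc, "p_raw": p_raw}, index=counts.index
    )
    out.index.name = "gene_id"
    if gene_classes is not None:
        out.insert(0, "gene_class", gene_classes.reindex(counts.index))
    return out


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise CernaxError("bh_adjust expects a 1-d sequence")
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise CernaxError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(m)
    out[order] = adj
    return out


@dataclass
class DEGIntersection:
    """Per-contrast DEG calls and their common gene set."""

    labels: tuple[str, ...]
    records: dict[str, pd.DataFrame]  # full table per contrast, with calls
    deg_sets: dict[str, set[str]]
    common: list[str]  # sorted gene ids present in every contrast's DEG set
    directions: dict[str, dict[str, str]]  # contrast -> gene -> up/down


def call_degs(
    records: pd.DataFrame, fc_threshold: float = 1.0, alpha: float = 0.05
) -> pd.DataFrame:
    """Add p_adj, direction and the is_deg flag to one contrast's table."""
    out = records.copy()
    out["p_adj"] = bh_adjust(out["p_raw"].to_numpy())
    out["is_deg"] = (np.abs(out["log2fc"]) >= fc_threshold) & (out["p_adj"] < alpha)
    out["direction"] = np.where(
        ~out["is_deg"], "none", np.where(out["log2fc"] > 0, "up", "down")
    )
    return out


def call_and_intersect(
    records_by_contrast: dict[str, pd.DataFrame],
    fc_threshold: float = 1.0,
    alpha: float = 0.05,
    gene_class: str | None = None,
) -> DEGIntersection:
    """Apply the DEG cut-offs per contrast and intersect the DEG sets.

    When ``gene_class`` is given, sets are restricted to genes of that
    class (requires a gene_class column from :func:`deg_test`).
    """
    labels = tuple(records_by_contrast)
    if not labels:
        raise CernaxError("no contrasts supplied")
    universes = [frozenset(df.index) for df in records_by_contrast.values()]
    if any(u != universes[0] for u in universes[1:]):
        raise CernaxError("contrasts cover different gene universes")

    called: dict[str, pd.DataFrame] = {}
    deg_sets: dict[str, set[str]] = {}
    directions: dict[str, dict[str, str]] = {}
    for label, df in records_by_contrast.items():
        out = call_degs(df, fc_threshold, alpha)
        called[label] = out
        sel = out[out["is_deg"]]
        if gene_class is not None:
            if "gene_class" not in sel.columns:
                raise CernaxError(
                    "gene_class filter requested but records carry no "
                    "gene_class column"
                )
            sel = sel[sel["gene_class"] == gene_class]
        deg_sets[label] = set(sel.index)
        directions[label] = sel["direction"].to_dict()

    common_set = set.intersection(*deg_sets.values())
    return DEGIntersection(
        labels=labels,
        records=called,
        deg_sets=deg_sets,
        common=sorted(common_set),
        directions=directions,
    )
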