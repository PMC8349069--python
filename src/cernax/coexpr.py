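"""lncRNA-PCG correlation screening and hypergeometric over-representation.

Correlation pairs pass when |PCC| > r_threshold, the raw p is below
alpha and the BH-adjusted p (over the full pair family) is below alpha.
The positively correlated subset (pcc > 0) is exposed separately for the
downstream axis screen.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .deg import bh_adjust
from .errors import CernaxError


def pearson_with_p(x, y) -> tuple[float, float]:
    """Sample Pearson r and its two-sided p from the t transform.

    p is computed from t = r * sqrt((n-2) / (1-r^2)) on n-2 degrees of
    freedom; r = +-1 yields p = 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise CernaxError("inputs must be equal-length 1-d vectors")
    n = x.size
    if n < 3:
        raise CernaxError("need at least 3 observations")
    xd = x - x.mean()
    yd = y - y.mean()
    sx = np.sqrt((xd ** 2).sum())
    sy = np.sqrt((yd ** 2).sum())
    if sx == 0 or sy == 0:
        raise CernaxError("correlation undefined: zero variance input")
    r = float(np.clip((xd * yd).sum() / (sx * sy), -1.0, 1.0))
    if abs(r) == 1.0:
        return r, 0.0
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    p = 2.0 * stats.t.sf(abs(t), df=n - 2)
    return r, float(p)


def correlate_pairs(
    expression: pd.DataFrame,
    lncrna_ids: list[str],
    pcg_ids: list[str],
    r_threshold: float = 0.45,
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, dict[str, set[str]]]:
    """Score all lncRNA x PCG pairs on an expression matrix.

    BH adjustment runs over the full pair family.  Pairs involving a
    zero-variance gene get pcc = NaN, p = 1 and never pass.

    Returns
    -------
    records : DataFrame
        Columns lncrna_id, pcg_id, pcc, p_raw, p_adj, passes.
    positive : dict
        lncrna_id -> set of passing PCGs with pcc > 0.
    """
    lncrna_ids, pcg_ids = list(lncrna_ids), list(pcg_ids)
    missing = (set(lncrna_ids) | set(pcg_ids)) - set(expression.index)
    if missing:
        raise CernaxError(f"ids absent from expression matrix: {sorted(missing)[:5]}")
    n = expression.shape[1]
    if n < 3:
        raise CernaxError("need at least 3 samples")

    def standardized(ids: list[str]) -> tuple[np.ndarray, np.ndarray]:
        mat = expression.loc[ids].to_numpy(dtype=float)
        mat = mat - mat.mean(axis=1, keepdims=True)
        norm = np.sqrt((mat ** 2).sum(axis=1))
        degenerate = norm == 0
        norm[degenerate] = 1.0
        return mat / norm[:, None], degenerate

    zl, dl = standardized(lncrna_ids)
    zp, dp = standardized(pcg_ids)
    rmat = np.clip(zl @ zp.T, -1.0, 1.0)
    bad = dl[:, None] | dp[None, :]

    with np.errstate(divide="ignore"):
        tmat = rmat * np.sqrt((n - 2) / (1.0 - rmat ** 2))
    pmat = 2.0 * stats.t.sf(np.abs(tmat), df=n - 2)
    pmat[np.abs(rmat) == 1.0] = 0.0
    rmat[bad] = np.nan
    pmat[bad] = 1.0

    records = pd.DataFrame(
        {
            "lncrna_id": np.repeat(lncrna_ids, len(pcg_ids)),
            "pcg_id": np.tile(pcg_ids, len(lncrna_ids)),
            "pcc": rmat.ravel(),
            "p_raw": pmat.ravel(),
        }
    )
    records["p_adj"] = bh_adjust(records["p_raw"].to_numpy())
    with np.errstate(invalid="ignore"):
        records["passes"] = (
            (np.abs(records["pcc"]) > r_threshold)
            & (records["p_raw"] < alpha)
            & (records["p_adj"] < alpha)
        ).fillna(False)

    positive: dict[str, set[str]] = {l: set() for l in lncrna_ids}
    ok = records[records["passes"] & (records["pcc"] > 0)]
    for lnc, pcg in zip(ok["lncrna_id"], ok["pcg_id"]):
        positive[lnc].add(pcg)
    return records, positive


def hypergeom_ora(
    query: set[str] | list[str],
    gene_sets: dict[str, list[str]],
    universe: set[str] | list[str],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Hypergeometric over-representation of a query list in each term.

    p_raw is the upper tail P(X >= k) with population N = |universe|,
    K = |term ∩ universe| successes and n = |query| draws; BH runs
    across all tested terms.
    """
    universe = set(universe)
    if not universe:
        raise CernaxError("empty universe")
    query = set(query)
    if not query <= universe:
        raise CernaxError("query genes must be contained in the universe")

    rows = []
    for term, genes in gene_sets.items():
        term_genes = set(genes) & universe
        k = len(query & term_genes)
        big_k, n, big_n = len(term_genes), len(query), len(universe)
        p = float(stats.hypergeom.sf(k - 1, big_n, big_k, n))
        rows.append((term, term, k, big_k, n, big_n, min(p, 1.0)))
    out = pd.DataFrame(
        rows, columns=["term_id", "term_name", "k", "K", "n", "N", "p_raw"]
    )
    if len(out):
        out["p_adj"] = bh_adjust(out["p_raw"].to_numpy())
        out["enriched"] = out["p_adj"] < alpha
        out = out.sort_values(["p_adj", "term_id"], kind="mergesort").reset_index(
            drop=True
        )
    else:
        out["p_adj"] = []
        out["enriched"] = []
    return out


def intersect_terms(
    term_a_genes: list[str] | set[str],
    term_b_genes: list[str] | set[str],
    candidates: list[str] | set[str],
) -> list[str]:
    """Candidate genes present in both terms, sorted for determinism."""
    return sorted(set(candidates) & set(term_a_genes) & set(term_b_genes))
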