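"""Multi-filter assembly of lncRNA/miRNA/mRNA ceRNA axes.

Candidate triples are formed from every miRNA that has at least one
seed-site interaction with a candidate lncRNA and one with a candidate
mRNA.  Filters are conjunctive and each axis keeps a full audit trace:

* miRNA prevalence (fraction of tumor samples with count > 0) must be
  >= prevalence_min;
* the miRNA-lncRNA interaction score must be >= score_min;
* the miRNA-lncRNA site count must be >= min_sites_lncrna;
* the lncRNA-mRNA pair must have a passing, positive correlation.

The removal criteria in the source funnel are strict ("< 0.85",
"< 5 sites", "expressed in less than 50%"), so all keep-side
comparisons here are inclusive.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import math

import pandas as pd

from .errors import CernaxError
from .mre import InteractionRecord, interaction_score


@dataclass
class ScreenThresholds:
    prevalence_min: float = 0.5
    score_min: float = 0.85
    min_sites_lncrna: int = 5
    require_positive_correlation: bool = True
    # optional mRNA-side tightening, off by default
    score_min_mrna: float | None = None
    min_sites_mrna: int | None = None

    def validate(self) -> None:
        if not (0.0 < self.prevalence_min <= 1.0):
            raise CernaxError("prevalence_min must be in (0, 1]")
        if not (0.0 <= self.score_min <= 1.0):
            raise CernaxError("score_min must be in [0, 1]")
        if self.min_sites_lncrna < 1:
            raise CernaxError("min_sites_lncrna must be >= 1")


@dataclass
class CeRNAAxis:
    lncrna_id: str
    mirna_id: str
    mrna_id: str
    mirna_prevalence: float
    lnc_score: float
    lnc_site_count: int
    mrna_site_count: int
    lnc_mrna_pcc: float  # NaN when no correlation record exists
    filter_trace: list[tuple[str, float, bool]] = field(default_factory=list)
    final_pass: bool = False


def prevalence(row: Mapping[str, float] | pd.Series, sample_ids: Iterable[str]) -> float:
    """Fraction of the named samples in which the gene has count > 0."""
    sample_ids = list(sample_ids)
    if not sample_ids:
        raise CernaxError("sample id list is empty")
    try:
        values = [row[s] for s in sample_ids]
    except KeyError as exc:
        raise CernaxError(f"unknown sample id {exc.args[0]!r}") from exc
    return sum(1 for v in values if v > 0) / len(sample_ids)


def _correlation_lookup(
    correlations: pd.DataFrame,
) -> dict[tuple[str, str], tuple[float, bool]]:
    return {
        (l, p): (r, ok)
        for l, p, r, ok in zip(
            correlations["lncrna_id"],
            correlations["pcg_id"],
            correlations["pcc"],
            correlations["passes"],
        )
    }


def screen_axes(
    candidate_lncrnas: Iterable[str],
    candidate_mrnas: Iterable[str],
    interactions: list[InteractionRecord],
    counts: pd.DataFrame,
    tumor_samples: list[str],
    correlations: pd.DataFrame,
    thresholds: ScreenThresholds | None = None,
    weights: Mapping[str, float] | None = None,
) -> list[CeRNAAxis]:
    """Assemble and filter all candidate (lncRNA, miRNA, mRNA) triples.

    Every candidate axis is returned with its complete filter trace;
    ``final_pass`` is true iff every entry passes.  A missing
    correlation record is a recorded filter failure, not an error.
    """
    th = thresholds or ScreenThresholds()
    th.validate()
    lnc_set = set(candidate_lncrnas)
    mrna_set = set(candidate_mrnas)

    lnc_side: dict[str, list[InteractionRecord]] = {}
    mrna_side: dict[str, list[InteractionRecord]] = {}
    for rec in interactions:
        if rec.target_class == "lncRNA" and rec.target_id in lnc_set:
            lnc_side.setdefault(rec.mirna_id, []).append(rec)
        elif rec.target_class == "mRNA_3UTR" and rec.target_id in mrna_set:
            mrna_side.setdefault(rec.mirna_id, []).append(rec)

    prev_cache: dict[str, float] = {}

    def mirna_prevalence(mirna_id: str) -> float:
        if mirna_id not in prev_cache:
            prev_cache[mirna_id] = prevalence(counts.loc[mirna_id], tumor_samples)
        return prev_cache[mirna_id]

    corr = _correlation_lookup(correlations)
    axes: list[CeRNAAxis] = []
    for mirna_id in sorted(set(lnc_side) & set(mrna_side)):
        prev = mirna_prevalence(mirna_id)
        for lrec in sorted(lnc_side[mirna_id], key=lambda r: r.target_id):
            score = interaction_score(lrec.sites, weights)
            for mrec in sorted(mrna_side[mirna_id], key=lambda r: r.target_id):
                pcc, cpass = corr.get((lrec.target_id, mrec.target_id), (math.nan, False))
                trace: list[tuple[str, float, bool]] = [
                    ("mirna_prevalence", prev, prev >= th.prevalence_min),
                    ("lnc_score", score, score >= th.score_min),
                    (
                        "lnc_sites",
                        float(lrec.n_sites),
                        lrec.n_sites >= th.min_sites_lncrna,
                    ),
                ]
                if th.score_min_mrna is not None:
                    ms = interaction_score(mrec.sites, weights)
                    trace.append(("mrna_score", ms, ms >= th.score_min_mrna))
                if th.min_sites_mrna is not None:
                    trace.append(
                        (
                            "mrna_sites",
                            float(mrec.n_sites),
                            mrec.n_sites >= th.min_sites_mrna,
                        )
                    )
                corr_ok = bool(cpass) and not math.isnan(pcc)
                if th.require_positive_correlation:
                    corr_ok = corr_ok and pcc > 0
                trace.append(("lnc_mrna_correlation", pcc, corr_ok))
                axes.append(
                    CeRNAAxis(
                        lncrna_id=lrec.target_id,
                        mirna_id=mirna_id,
                        mrna_id=mrec.target_id,
                        mirna_prevalence=prev,
                        lnc_score=score,
                        lnc_site_count=lrec.n_sites,
                        mrna_site_count=mrec.n_sites,
                        lnc_mrna_pcc=pcc,
                        filter_trace=trace,
                        final_pass=all(ok for _, _, ok in trace),
                    )
                )
    return axes


def rank_axes(axes: list[CeRNAAxis]) -> list[CeRNAAxis]:
    """Deterministic ordering: passing axes first, best metrics first."""

    def key(a: CeRNAAxis):
        pcc = a.lnc_mrna_pcc if not math.isnan(a.lnc_mrna_pcc) else -math.inf
        return (
            not a.final_pass,
            -pcc,
            -a.lnc_score,
            -a.lnc_site_count,
            a.lncrna_id,
            a.mirna_id,
            a.mrna_id,
        )

    return sorted(axes, key=key)


def screen_funnel(axes: list[CeRNAAxis]) -> pd.DataFrame:
    """Per-stage survivor counts recomputed from the audit traces."""
    lnc_pairs = {(a.mirna_id, a.lncrna_id) for a in axes}
    mrna_pairs = {(a.mirna_id, a.mrna_id) for a in axes}

    def passes(a: CeRNAAxis, *names: str) -> bool:
        wanted = dict((n, ok) for n, _, ok in a.filter_trace)
        return all(wanted.get(n, True) for n in names)

    lnc_prev = {
        (a.mirna_id, a.lncrna_id) for a in axes if passes(a, "mirna_prevalence")
    }
    lnc_scored = {
        (a.mirna_id, a.lncrna_id)
        for a in axes
        if passes(a, "mirna_prevalence", "lnc_score")
    }
    lnc_full = {
        (a.mirna_id, a.lncrna_id)
        for a in axes
        if passes(a, "mirna_prevalence", "lnc_score", "lnc_sites")
    }
    mrna_prev = {
        (a.mirna_id, a.mrna_id) for a in axes if passes(a, "mirna_prevalence")
    }
    shared = {a.mirna_id for a in axes if passes(a, "mirna_prevalence", "lnc_score", "lnc_sites")} & {
        m for m, _ in mrna_prev
    }
    rows = [
        ("lncRNA_side_pairs", len(lnc_pairs)),
        ("lncRNA_side_after_prevalence", len(lnc_prev)),
        ("lncRNA_side_after_score", len(lnc_scored)),
        ("lncRNA_side_after_sites", len(lnc_full)),
        ("mRNA_side_pairs", len(mrna_pairs)),
        ("mRNA_side_after_prevalence", len(mrna_prev)),
        ("shared_mirnas", len(shared)),
        ("axes_formed", len(axes)),
        ("axes_final_pass", sum(a.final_pass for a in axes)),
    ]
    return pd.DataFrame(rows, columns=["stage", "count"])


def axes_to_frame(axes: list[CeRNAAxis]) -> pd.DataFrame:
    """Serialize axes for axes.tsv; the trace becomes name=value:pass tokens."""
    rows = []
    for a in axes:
        rows.append(
            {
                "lncrna_id": a.lncrna_id,
                "mirna_id": a.mirna_id,
                "mrna_id": a.mrna_id,
                "mirna_prevalence": a.mirna_prevalence,
                "lnc_score": a.lnc_score,
                "lnc_site_count": a.lnc_site_count,
                "mrna_site_count": a.mrna_site_count,
                "lnc_mrna_pcc": a.lnc_mrna_pcc,
                "filter_trace": ";".join(
                    f"{name}={value:.6g}:{'pass' if ok else 'fail'}"
                    for name, value, ok in a.filter_trace
                ),
                "final_pass": a.final_pass,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "lncrna_id", "mirna_id", "mrna_id", "mirna_prevalence", "lnc_score",
            "lnc_site_count", "mrna_site_count", "lnc_mrna_pcc", "filter_trace",
            "final_pass",
        ],
    )
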