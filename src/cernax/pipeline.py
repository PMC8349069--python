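"""Stage orchestration: simulate -> deg -> correlate -> enrich -> mre ->
screen -> clinical, each stage reading and writing declared files only.

Stages can run individually (the CLI maps one subcommand per stage) or
chained with ``run``; a stage invoked before its prerequisites raises a
:class:`~cernax.errors.PrerequisiteError` naming the missing subcommand.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import io as cio
from .clinical import chi2_test, fisher_exact_2x2, km_logrank, median_split
from .coexpr import correlate_pairs, hypergeom_ora, intersect_terms
from .config import PipelineConfig
from .deg import call_and_intersect, deg_test, normalized_log2, size_factors
from .errors import PrerequisiteError
from .mre import InteractionRecord, SeedSite, predict_interactions
from .screen import axes_to_frame, rank_axes, screen_axes, screen_funnel
from .simulate import generate_cohort, write_cohort

log = logging.getLogger("cernax")

STAGES = ("simulate", "deg", "correlate", "enrich", "mre", "screen", "clinical")

CONTRAST_TN = "tumor_vs_normal"
CONTRAST_OLNM = "olnm_pos_vs_neg"


@dataclass
class RunManifest:
    config_hash: str
    version: str
    started: str
    finished: str = ""
    stages: list[dict] = field(default_factory=list)

    def add(self, name: str, inputs: list[str], outputs: list[str], counts: dict):
        self.stages.append(
            {"stage": name, "inputs": inputs, "outputs": outputs, "counts": counts}
        )

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=2, default=str)


class PipelineRunner:
    """Executes the screening stages for one configuration."""

    def __init__(self, config: PipelineConfig):
        config.validate()
        self.cfg = config
        self.outdir = Path(config.outdir)
        self.outdir.mkdir(parents=True, exist_ok=True)
        logging.basicConfig(level=config.log_level)
        self.manifest = RunManifest(
            config_hash=config.config_hash(),
            version=__version__,
            started=time.strftime("%Y-%m-%dT%H:%M:%S"),
        )

    # -- file locations ------------------------------------------------
    def cohort_paths(self) -> dict[str, Path]:
        if self.cfg.inputs is not None:
            return {k: Path(v) for k, v in self.cfg.inputs.items()}
        return {
            "counts": self.outdir / "counts.tsv",
            "samples": self.outdir / "samples.tsv",
            "transcripts": self.outdir / "transcripts.fasta",
            "utr3": self.outdir / "utr3.fasta",
            "mirna": self.outdir / "mirna.fasta",
            "genesets": self.outdir / "genesets.gmt",
        }

    def _out(self, name: str) -> Path:
        return self.outdir / name

    def _require(self, path: Path, producer: str) -> Path:
        if not path.exists():
            raise PrerequisiteError(
                f"missing {path.name}; run the {producer!r} subcommand first"
            )
        return path

    # -- stages --------------------------------------------------------
    def stage_simulate(self) -> dict:
        if self.cfg.simulate is None:
            raise PrerequisiteError(
                "no simulate block in the configuration; provide input paths "
                "instead of running 'simulate'"
            )
        cohort = generate_cohort(self.cfg.simulate)
        paths = write_cohort(cohort, self.outdir)
        counts = {
            "genes": int(cohort.counts.shape[0]),
            "samples": int(cohort.counts.shape[1]),
            "planted_axes": len(cohort.truth),
        }
        log.info("simulate: %s", counts)
        self.manifest.add("simulate", [], [str(p) for p in paths.values()], counts)
        return counts

    def _load_cohort_tables(self):
        paths = self.cohort_paths()
        producer = "simulate" if self.cfg.inputs is None else "(external inputs)"
        counts, gene_classes = cio.read_counts(self._require(paths["counts"], producer))
        samples = cio.read_table(
            self._require(paths["samples"], producer), index_col="sample_id"
        )
        return counts, gene_classes, samples

    @staticmethod
    def _contrast_groups(samples: pd.DataFrame) -> dict[str, tuple[list, list]]:
        tumors = samples[samples["tissue"] == "tumor"]
        normals = samples[samples["tissue"] == "normal"]
        paired_tumors = tumors[tumors["pair_id"] != "-"]
        return {
            CONTRAST_TN: (list(paired_tumors.index), list(normals.index)),
            CONTRAST_OLNM: (
                list(tumors.index[tumors["olnm"] == 1]),
                list(tumors.index[tumors["olnm"] == 0]),
            ),
        }

    def stage_deg(self) -> dict:
        counts, gene_classes, samples = self._load_cohort_tables()
        factors = size_factors(counts)
        contrasts = self._contrast_groups(samples)
        records = {
            name: deg_test(
                counts, factors, a, b,
                paired=self.cfg.paired and name == CONTRAST_TN,
                gene_classes=gene_classes,
            )
            for name, (a, b) in contrasts.items()
        }
        result = call_and_intersect(
            records,
            fc_threshold=self.cfg.fc_threshold,
            alpha=self.cfg.deg_alpha,
            gene_class="lncRNA",
        )
        outputs = []
        for name, df in result.records.items():
            p = self._out(f"degs_{name}.tsv")
            cio.write_table(df, p)
            outputs.append(str(p))
        inter = pd.DataFrame({"gene_id": result.common})
        for label in result.labels:
            inter[f"direction_{label}"] = [
                result.directions[label][g] for g in result.common
            ]
        p = self._out("intersection.tsv")
        inter.to_csv(p, sep="\t", index=False)
        outputs.append(str(p))
        counts_d = {
            **{f"degs_{k}": len(v) for k, v in result.deg_sets.items()},
            "intersection": len(result.common),
        }
        log.info("deg: %s", counts_d)
        self.manifest.add("deg", [str(x) for x in self.cohort_paths().values()],
                          outputs, counts_d)
        return counts_d

    def _expression(self, counts, samples) -> tuple[pd.DataFrame, list[str]]:
        factors = size_factors(counts)
        expr = normalized_log2(counts, factors)
        tumor = list(samples.index[samples["tissue"] == "tumor"])
        return expr, tumor

    def stage_correlate(self) -> dict:
        counts, gene_classes, samples = self._load_cohort_tables()
        inter = cio.read_table(self._require(self._out("intersection.tsv"), "deg"))
        lnc_ids = list(inter["gene_id"])
        pcg_ids = list(gene_classes.index[gene_classes == "PCG"])
        expr, tumor = self._expression(counts, samples)
        if lnc_ids:
            records, _ = correlate_pairs(
                expr[tumor], lnc_ids, pcg_ids,
                r_threshold=self.cfg.r_threshold, alpha=self.cfg.corr_alpha,
            )
        else:
            records = pd.DataFrame(
                columns=["lncrna_id", "pcg_id", "pcc", "p_raw", "p_adj", "passes"]
            )
        p = self._out("correlations.tsv")
        records.to_csv(p, sep="\t", index=False)
        counts_d = {
            "pairs_tested": len(records),
            "pairs_passing": int(records["passes"].sum()) if len(records) else 0,
        }
        log.info("correlate: %s", counts_d)
        self.manifest.add("correlate", [str(self._out("intersection.tsv"))],
                          [str(p)], counts_d)
        return counts_d

    def stage_enrich(self) -> dict:
        counts, gene_classes, samples = self._load_cohort_tables()
        corr = cio.read_table(self._require(self._out("correlations.tsv"), "correlate"))
        gene_sets = cio.read_gmt(self.cohort_paths()["genesets"])
        universe = set(gene_classes.index[gene_classes == "PCG"])
        query = set(corr.loc[corr["passes"] == True, "pcg_id"])  # noqa: E712
        enrichment = hypergeom_ora(query, gene_sets, universe, alpha=self.cfg.ora_alpha)
        p1 = self._out("enrichment.tsv")
        enrichment.to_csv(p1, sep="\t", index=False)
        term_a, term_b = self.cfg.terms
        cand = intersect_terms(
            gene_sets.get(term_a, []), gene_sets.get(term_b, []), query
        )
        p2 = self._out("candidate_mrnas.tsv")
        pd.DataFrame({"gene_id": cand}).to_csv(p2, sep="\t", index=False)
        counts_d = {
            "terms_tested": len(enrichment),
            "terms_enriched": int(enrichment["enriched"].sum()) if len(enrichment) else 0,
            "candidate_mrnas": len(cand),
        }
        log.info("enrich: %s", counts_d)
        self.manifest.add("enrich", [str(self._out("correlations.tsv"))],
                          [str(p1), str(p2)], counts_d)
        return counts_d

    def stage_mre(self) -> dict:
        paths = self.cohort_paths()
        inter = cio.read_table(self._require(self._out("intersection.tsv"), "deg"))
        cand_mrna = cio.read_table(
            self._require(self._out("candidate_mrnas.tsv"), "enrich")
        )
        mirnas = cio.read_fasta(paths["mirna"])
        lnc_seqs = cio.read_fasta(paths["transcripts"])
        utr_seqs = cio.read_fasta(paths["utr3"])
        lnc_ids = [g for g in inter["gene_id"] if g in lnc_seqs]
        mrna_ids = [g for g in cand_mrna["gene_id"] if g in utr_seqs]
        recs = predict_interactions(
            mirnas, {g: lnc_seqs[g] for g in lnc_ids}, "lncRNA"
        ) + predict_interactions(
            mirnas, {g: utr_seqs[g] for g in mrna_ids}, "mRNA_3UTR"
        )
        rows = [
            {
                "mirna_id": r.mirna_id,
                "target_id": r.target_id,
                "target_class": r.target_class,
                "n_sites": r.n_sites,
                "score": r.score(self.cfg.mre_weights),
                "sites": ",".join(f"{s.site_type}@{s.start}" for s in r.sites),
            }
            for r in recs
        ]
        df = pd.DataFrame(
            rows,
            columns=["mirna_id", "target_id", "target_class", "n_sites", "score", "sites"],
        )
        p = self._out("interactions.tsv")
        df.to_csv(p, sep="\t", index=False)
        counts_d = {
            "lncrna_pairs": int((df["target_class"] == "lncRNA").sum()),
            "mrna_pairs": int((df["target_class"] == "mRNA_3UTR").sum()),
        }
        log.info("mre: %s", counts_d)
        self.manifest.add("mre", [str(paths["mirna"])], [str(p)], counts_d)
        return counts_d

    def _load_interactions(self) -> list[InteractionRecord]:
        df = cio.read_table(self._require(self._out("interactions.tsv"), "mre"))
        recs = []
        for row in df.itertuples(index=False):
            sites = []
            if isinstance(row.sites, str) and row.sites:
                for token in row.sites.split(","):
                    stype, start = token.split("@")
                    sites.append(
                        SeedSite(row.target_id, row.mirna_id, stype, int(start))
                    )
            recs.append(
                InteractionRecord(row.mirna_id, row.target_id, row.target_class, sites)
            )
        return recs

    def stage_screen(self) -> dict:
        counts, gene_classes, samples = self._load_cohort_tables()
        inter = cio.read_table(self._require(self._out("intersection.tsv"), "deg"))
        cand_mrna = cio.read_table(
            self._require(self._out("candidate_mrnas.tsv"), "enrich")
        )
        corr = cio.read_table(self._require(self._out("correlations.tsv"), "correlate"))
        interactions = self._load_interactions()
        tumor = list(samples.index[samples["tissue"] == "tumor"])
        axes = screen_axes(
            list(inter["gene_id"]),
            list(cand_mrna["gene_id"]),
            interactions,
            counts,
            tumor,
            corr,
            thresholds=self.cfg.screen,
            weights=self.cfg.mre_weights,
        )
        axes = rank_axes(axes)
        p1 = self._out("axes.tsv")
        axes_to_frame(axes).to_csv(p1, sep="\t", index=False)
        funnel = screen_funnel(axes)
        p2 = self._out("funnel.tsv")
        funnel.to_csv(p2, sep="\t", index=False)
        counts_d = dict(zip(funnel["stage"], funnel["count"].astype(int)))
        log.info("screen: %s", counts_d)
        self.manifest.add(
            "screen",
            [str(self._out(n)) for n in
             ("intersection.tsv", "candidate_mrnas.tsv", "correlations.tsv",
              "interactions.tsv")],
            [str(p1), str(p2)],
            counts_d,
        )
        return counts_d

    def stage_clinical(self) -> dict:
        counts, gene_classes, samples = self._load_cohort_tables()
        axes = cio.read_table(self._require(self._out("axes.tsv"), "screen"))
        gene = self.cfg.clinical_gene
        if gene is None:
            passing = axes[axes["final_pass"] == True]  # noqa: E712
            gene = passing["lncrna_id"].iloc[0] if len(passing) else None
        rows = []
        km_rows = []
        if gene is not None:
            expr, tumor = self._expression(counts, samples)
            groups = median_split(expr.loc[gene, tumor])
            glab = pd.Series(groups)
            tumors = samples.loc[tumor]
            table = pd.crosstab(tumors["olnm"], glab.reindex(tumor))
            table = table.reindex(index=[0, 1], columns=["low", "high"], fill_value=0)
            if (table.to_numpy().sum(axis=0) > 0).all() and (
                table.to_numpy().sum(axis=1) > 0
            ).all():
                p_fisher = fisher_exact_2x2(table.to_numpy())
                stat, df_, p_yates = chi2_test(table.to_numpy(), yates=True)
                rows.append(("olnm_vs_group_fisher", np.nan, p_fisher))
                rows.append(("olnm_vs_group_chi2_yates", stat, p_yates))
            curves, stat, p_lr = km_logrank(
                tumors["time_months"].to_numpy(),
                tumors["event"].to_numpy(),
                glab.reindex(tumor).to_numpy(),
            )
            rows.append(("logrank_low_vs_high", stat, p_lr))
            for lab, cv in curves.items():
                for t, s, n in zip(cv.times, cv.survival, cv.n_at_risk):
                    km_rows.append((lab, float(t), float(s), int(n)))
        report = pd.DataFrame(rows, columns=["test", "statistic", "p_value"])
        report.insert(0, "gene", gene if gene is not None else "-")
        p1 = self._out("clinical_report.tsv")
        report.to_csv(p1, sep="\t", index=False)
        km = pd.DataFrame(km_rows, columns=["group", "time", "survival", "n_at_risk"])
        p2 = self._out("km_curves.tsv")
        km.to_csv(p2, sep="\t", index=False)
        counts_d = {"tests": len(report), "km_points": len(km)}
        log.info("clinical: %s", counts_d)
        self.manifest.add("clinical", [str(self._out("axes.tsv"))],
                          [str(p1), str(p2)], counts_d)
        return counts_d

    # -- driver --------------------------------------------------------
    def run(self, stages: list[str] | None = None) -> RunManifest:
        wanted = list(STAGES) if stages is None else list(stages)
        if self.cfg.inputs is not None and "simulate" in wanted:
            wanted.remove("simulate")
        for name in wanted:
            getattr(self, f"stage_{name}")()
        self.manifest.finished = time.strftime("%Y-%m-%dT%H:%M:%S")
        (self.outdir / "manifest.json").write_text(self.manifest.to_json())
        return self.manifest


def run_all(config: PipelineConfig) -> RunManifest:
    """One-call end-to-end run (simulate when configured, then screen)."""
    return PipelineRunner(config).run()
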