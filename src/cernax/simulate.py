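"""Synthetic cohort generator with planted ceRNA axes and per-filter decoys.

The cohort mimics the structure the screening pipeline assumes: paired
tumor/normal samples, an OLNM+/- split within the tumors, negative
binomial counts, transcript/3'UTR/miRNA sequences carrying planted seed
sites, gene-set annotations and a clinical table.

A single latent per-sample activity a_s in {0, 1, 2} (normal, tumor
OLNM-, tumor OLNM+) multiplies the means of each planted lncRNA and
mRNA by 2^(effect_log2fc * a_s), which couples tumor-vs-normal DE,
OLNM DE and positive lncRNA-mRNA correlation in one mechanism.  Each
decoy role breaks exactly one screening criterion by construction:

* DECOY_LOW_PREVALENCE - miRNA mean so low it is detected in < 50% of
  tumor samples;
* DECOY_LOW_SCORE - five 6mer sites (noisy-OR score 0.41 < 0.85);
* DECOY_FEW_SITES - four 8mer sites (score 0.97 but count < 5);
* DECOY_NEGATIVE_CORRELATION - mRNA mean multiplied by 2^(-effect*a_s);
* DECOY_NOT_DE - lncRNA/mRNA coupled through a group-independent
  latent factor (correlated but not differentially expressed).

Background sequences are i.i.d. uniform; every occurrence of any
miRNA's seed core outside a planted site is scrubbed away, so the
seed-site scanner recovers exactly the planted interaction pairs.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view

from . import io as cio
from .errors import CernaxError, ConfigurationError, ParseError
from .mre import find_seed_sites

_BASES = "ACGT"
_POW6 = 4 ** np.arange(5, -1, -1)


class AxisRole(str, enum.Enum):
    TRUE_AXIS = "TRUE_AXIS"
    DECOY_LOW_PREVALENCE = "DECOY_LOW_PREVALENCE"
    DECOY_LOW_SCORE = "DECOY_LOW_SCORE"
    DECOY_FEW_SITES = "DECOY_FEW_SITES"
    DECOY_NEGATIVE_CORRELATION = "DECOY_NEGATIVE_CORRELATION"
    DECOY_NOT_DE = "DECOY_NOT_DE"


_DECOY_ORDER = (
    AxisRole.DECOY_LOW_PREVALENCE,
    AxisRole.DECOY_LOW_SCORE,
    AxisRole.DECOY_FEW_SITES,
    AxisRole.DECOY_NEGATIVE_CORRELATION,
    AxisRole.DECOY_NOT_DE,
)

#: Per-role planted site plan: (sites on the lncRNA, sites on the 3'UTR).
SITE_PLANS: dict[AxisRole, tuple[dict[str, int], dict[str, int]]] = {
    AxisRole.TRUE_AXIS: ({"7mer-m8": 5}, {"8mer": 1, "7mer-A1": 1}),
    AxisRole.DECOY_LOW_PREVALENCE: ({"7mer-m8": 5}, {"8mer": 1}),
    AxisRole.DECOY_LOW_SCORE: ({"6mer": 5}, {"8mer": 1}),
    AxisRole.DECOY_FEW_SITES: ({"8mer": 4}, {"8mer": 1}),
    AxisRole.DECOY_NEGATIVE_CORRELATION: ({"7mer-m8": 5}, {"8mer": 1}),
    AxisRole.DECOY_NOT_DE: ({"7mer-m8": 5}, {"8mer": 1}),
}

_HIGH_MIRNA_MEAN = 80.0   # > 50% tumor prevalence with huge margin
_LOW_MIRNA_MEAN = 0.15    # < 50% tumor prevalence with huge margin
# planted lncRNA/mRNA baseline: high enough that even a 2^(-2*effect)
# down-regulated decoy keeps countable (non-degenerate) expression
_PLANTED_RNA_MEAN = 400.0
_NOT_DE_COUPLING = 1.0    # log2 loading of the group-independent factor
_BASE_HAZARD = 1.0 / 40.0  # events per month in the low-expression group


@dataclass
class CohortConfig:
    n_tumor: int = 53
    n_paired_normal: int = 13
    n_olnm_pos: int = 18
    n_lncrna: int = 300
    n_pcg: int = 2000
    n_mirna: int = 150
    n_true_axes: int = 3
    n_decoys_per_class: int = 2
    nb_dispersion: float = 0.05
    effect_log2fc: float = 2.0
    lib_size_sigma: float = 0.15
    lncrna_len: int = 1500
    utr_len: int = 800
    mirna_len: int = 22
    survival_hr: float = 2.5
    seed: int = 0

    def validate(self) -> None:
        for name in (
            "n_tumor", "n_paired_normal", "n_olnm_pos", "n_lncrna", "n_pcg",
            "n_mirna", "n_true_axes", "n_decoys_per_class",
        ):
            if getattr(self, name) < 0:
                raise ConfigurationError(name, "must be >= 0")
        if self.n_tumor < 2:
            raise ConfigurationError("n_tumor", "need at least 2 tumor samples")
        if self.n_olnm_pos >= self.n_tumor:
            raise ConfigurationError("n_olnm_pos", "must be < n_tumor")
        if self.n_paired_normal > self.n_tumor:
            raise ConfigurationError("n_paired_normal", "must be <= n_tumor")
        if self.nb_dispersion <= 0:
            raise ConfigurationError("nb_dispersion", "must be > 0")
        if self.effect_log2fc < 0:
            raise ConfigurationError("effect_log2fc", "must be >= 0")
        if self.lib_size_sigma <= 0:
            raise ConfigurationError("lib_size_sigma", "must be > 0")
        if self.survival_hr <= 0:
            raise ConfigurationError("survival_hr", "must be > 0")
        if self.mirna_len < 8:
            raise ConfigurationError("mirna_len", "must be >= 8")
        if self.lncrna_len < 120 and self.n_axes > 0:
            raise ConfigurationError("lncrna_len", "too short to plant sites")
        if self.utr_len < 60 and self.n_axes > 0:
            raise ConfigurationError("utr_len", "too short to plant sites")
        if self.n_axes > min(self.n_lncrna, self.n_pcg, self.n_mirna):
            raise ConfigurationError(
                "n_true_axes",
                "n_true_axes + 5 * n_decoys_per_class exceeds the number of "
                "available lncRNA/PCG/miRNA genes",
            )

    @property
    def n_axes(self) -> int:
        return self.n_true_axes + len(_DECOY_ORDER) * self.n_decoys_per_class

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


@dataclass
class PlantedAxis:
    lncrna_id: str
    mirna_id: str
    mrna_id: str
    role: AxisRole
    lncrna_sites: dict[str, int] = field(default_factory=dict)
    utr_sites: dict[str, int] = field(default_factory=dict)


@dataclass
class SyntheticCohort:
    config: CohortConfig
    counts: pd.DataFrame            # gene x sample, int
    gene_classes: pd.Series         # gene_id -> lncRNA | PCG | miRNA
    sample_table: pd.DataFrame      # indexed by sample id
    lncrna_seqs: dict[str, str]
    utr3_seqs: dict[str, str]
    mirna_seqs: dict[str, str]
    gene_sets: dict[str, list[str]]
    truth: list[PlantedAxis]

    @property
    def tumor_samples(self) -> list[str]:
        return list(self.sample_table.index[self.sample_table["tissue"] == "tumor"])

    @property
    def normal_samples(self) -> list[str]:
        return list(self.sample_table.index[self.sample_table["tissue"] == "normal"])

    @property
    def sequences(self) -> dict[str, str]:
        return {**self.lncrna_seqs, **self.utr3_seqs, **self.mirna_seqs}

    def equals(self, other: "SyntheticCohort") -> bool:
        return (
            self.counts.equals(other.counts)
            and self.gene_classes.equals(other.gene_classes)
            and self.sample_table.equals(other.sample_table)
            and self.lncrna_seqs == other.lncrna_seqs
            and self.utr3_seqs == other.utr3_seqs
            and self.mirna_seqs == other.mirna_seqs
            and self.gene_sets == other.gene_sets
            and self.truth == other.truth
        )


# ---------------------------------------------------------------------------
# sequence machinery


def _codes_to_str(codes: np.ndarray, rna: bool = False) -> str:
    s = "".join(_BASES[c] for c in codes)
    return s.replace("T", "U") if rna else s


def _str_to_codes(s: str) -> np.ndarray:
    return np.array([_BASES.index(c) for c in s.replace("U", "T")], dtype=np.uint8)


def _revcomp_str(s: str) -> str:
    return s.translate(str.maketrans("ACGT", "TGCA"))[::-1]


def _insert_strings(mir_dna: str) -> dict[str, str]:
    """Self-contained 8 nt insert per site type (flanks force the type)."""
    rc28 = _revcomp_str(mir_dna[1:8])
    core = _revcomp_str(mir_dna[1:7])
    m8c = mir_dna[7].translate(str.maketrans("ACGT", "TGCA"))
    x1 = "C" if m8c != "C" else "G"   # must not complete an m8 match
    x2 = "C"                           # must not supply the A1 adenine
    return {
        "8mer": rc28 + "A",
        "7mer-m8": rc28 + x2,
        "7mer-A1": x1 + core + "A",
        "6mer": x1 + core + x2,
    }


def _count_overlapping(hay: str, needle: str) -> int:
    """Occurrence count including overlaps (str.count misses those)."""
    n, pos = 0, hay.find(needle)
    while pos != -1:
        n += 1
        pos = hay.find(needle, pos + 1)
    return n


def _core_code(core: str) -> int:
    return int(_str_to_codes(core) @ _POW6)


def _kmer_hits(seq: np.ndarray, core_codes: np.ndarray) -> np.ndarray:
    """Start positions of any 6-mer core occurrence in ``seq``."""
    if seq.size < 6:
        return np.empty(0, dtype=int)
    codes = sliding_window_view(seq, 6).astype(np.int64) @ _POW6
    return np.flatnonzero(np.isin(codes, core_codes))


def _scrub(
    seq: np.ndarray,
    core_codes: np.ndarray,
    rng: np.random.Generator,
    protected: np.ndarray | None = None,
    designed: frozenset[int] = frozenset(),
    max_iter: int = 80,
) -> None:
    """Mutate bases in place until no undesigned seed core remains.

    ``protected`` marks planted-insert bases that must stay intact;
    ``designed`` holds the planted core start positions to keep.
    """
    for _ in range(max_iter):
        hits = [p for p in _kmer_hits(seq, core_codes) if p not in designed]
        if not hits:
            return
        last = -10
        for p in hits:
            if p < last + 6:  # overlapping hit may already be broken
                continue
            last = p
            # random offset: a fixed choice can cycle when several cores
            # overlap the same window and every base at one position matches
            if protected is None:
                off = int(rng.integers(6))
            else:
                free = [o for o in range(6) if not protected[p + o]]
                if not free:
                    raise CernaxError(
                        "cannot scrub seed core inside a planted site"
                    )
                off = free[int(rng.integers(len(free)))]
            seq[p + off] = (seq[p + off] + rng.integers(1, 4)) % 4
    raise CernaxError("seed-core scrubbing did not converge")


def _draw_mirnas(
    rng: np.random.Generator, config: CohortConfig, roles: list[AxisRole]
) -> tuple[list[str], list[dict[str, str]], list[int]]:
    """Mature miRNA sequences (DNA form) with mutually safe seed cores.

    Planted miRNAs (first len(roles)) additionally get insert strings
    whose only embedded seed core is their own; background miRNAs must
    not collide with any accepted core or planted insert.
    """
    n_planted = len(roles)
    seqs: list[str] = []
    inserts: list[dict[str, str]] = []
    cores: list[str] = []
    all_insert_text = ""

    def conflict(core: str, my_inserts: dict[str, str] | None) -> bool:
        if core in cores:
            return True
        if core in all_insert_text:
            return True
        if my_inserts is not None:
            mine = " ".join(my_inserts.values())
            for prev in cores:
                if prev in mine:
                    return True
            for ins in my_inserts.values():
                if _count_overlapping(ins, core) != 1:
                    return True
        return False

    for i in range(config.n_mirna):
        planted = i < n_planted
        for _ in range(1000):
            codes = rng.integers(0, 4, config.mirna_len, dtype=np.uint8)
            mir = _codes_to_str(codes)
            core = _revcomp_str(mir[1:7])
            my_inserts = _insert_strings(mir) if planted else None
            if not conflict(core, my_inserts):
                break
        else:  # pragma: no cover - astronomically unlikely
            raise CernaxError("could not draw a conflict-free miRNA sequence")
        seqs.append(mir)
        cores.append(core)
        if planted:
            inserts.append(my_inserts)
            all_insert_text += " " + " ".join(my_inserts.values())
    return seqs, inserts, cores


def _plant(
    seq: np.ndarray,
    plan: dict[str, int],
    insert_map: dict[str, str],
    rng: np.random.Generator,
) -> tuple[np.ndarray, frozenset[int], list[tuple[str, int]]]:
    """Write site inserts at non-overlapping random positions.

    Returns the protected-base mask, designed core start positions and
    the expected (site_type, 1-based start) list.
    """
    length = seq.size
    protected = np.zeros(length, dtype=bool)
    placed: list[int] = []
    expected: list[tuple[str, int]] = []
    designed: set[int] = set()
    for stype in ("8mer", "7mer-m8", "7mer-A1", "6mer"):
        for _ in range(plan.get(stype, 0)):
            for _ in range(2000):
                q = int(rng.integers(0, length - 8 + 1))
                if all(abs(q - p) >= 14 for p in placed):
                    break
            else:  # pragma: no cover
                raise CernaxError("no room to place planted sites")
            placed.append(q)
            ins = _str_to_codes(insert_map[stype])
            seq[q : q + 8] = ins
            protected[q : q + 8] = True
            designed.add(q + 1)  # seed core sits at insert offset 1
            start = q + 1 if stype in ("8mer", "7mer-m8") else q + 2
            expected.append((stype, start))
    return protected, frozenset(designed), expected


# ---------------------------------------------------------------------------
# generation


def generate_cohort(config: CohortConfig) -> SyntheticCohort:
    """Generate a cohort; identical config+seed gives identical output."""
    config.validate()
    rng = np.random.default_rng(config.seed)

    # --- samples ------------------------------------------------------
    tumor_ids = [f"T{i + 1:03d}" for i in range(config.n_tumor)]
    normal_ids = [f"N{i + 1:03d}" for i in range(config.n_paired_normal)]
    samples = tumor_ids + normal_ids
    olnm_idx = set(
        rng.choice(config.n_tumor, size=config.n_olnm_pos, replace=False).tolist()
    )
    tissue = ["tumor"] * config.n_tumor + ["normal"] * config.n_paired_normal
    patient = [f"P{i + 1:03d}" for i in range(config.n_tumor)] + [
        f"P{i + 1:03d}" for i in range(config.n_paired_normal)
    ]
    pair = [
        f"P{i + 1:03d}" if i < config.n_paired_normal else "-"
        for i in range(config.n_tumor)
    ] + [f"P{i + 1:03d}" for i in range(config.n_paired_normal)]
    olnm_tumor = np.array(
        [1 if i in olnm_idx else 0 for i in range(config.n_tumor)], dtype=int
    )
    olnm = np.concatenate([olnm_tumor, olnm_tumor[: config.n_paired_normal]])
    activity = np.concatenate(
        [1.0 + olnm_tumor, np.zeros(config.n_paired_normal)]
    )

    # --- genes and planted axes --------------------------------------
    lnc_ids = [f"LNC{i + 1:04d}" for i in range(config.n_lncrna)]
    pcg_ids = [f"PCG{i + 1:04d}" for i in range(config.n_pcg)]
    mir_ids = [f"MIR{i + 1:04d}" for i in range(config.n_mirna)]
    gene_ids = lnc_ids + pcg_ids + mir_ids
    gene_classes = pd.Series(
        ["lncRNA"] * config.n_lncrna
        + ["PCG"] * config.n_pcg
        + ["miRNA"] * config.n_mirna,
        index=gene_ids,
        name="gene_class",
    )

    roles = [AxisRole.TRUE_AXIS] * config.n_true_axes
    for decoy in _DECOY_ORDER:
        roles += [decoy] * config.n_decoys_per_class
    truth = [
        PlantedAxis(
            lncrna_id=lnc_ids[i],
            mirna_id=mir_ids[i],
            mrna_id=pcg_ids[i],
            role=role,
            lncrna_sites=dict(SITE_PLANS[role][0]),
            utr_sites=dict(SITE_PLANS[role][1]),
        )
        for i, role in enumerate(roles)
    ]

    # --- counts -------------------------------------------------------
    n_genes = len(gene_ids)
    n_samples = len(samples)
    base_mean = rng.lognormal(mean=np.log(80.0), sigma=0.8, size=n_genes)
    lnc_offset = 0
    pcg_offset = config.n_lncrna
    mir_offset = config.n_lncrna + config.n_pcg

    log2mult = np.zeros((n_genes, n_samples))
    e = config.effect_log2fc
    for i, axis in enumerate(truth):
        lnc_row = lnc_offset + i
        pcg_row = pcg_offset + i
        mir_row = mir_offset + i
        base_mean[lnc_row] = _PLANTED_RNA_MEAN
        base_mean[pcg_row] = _PLANTED_RNA_MEAN
        if axis.role is AxisRole.DECOY_NOT_DE:
            z = rng.normal(0.0, 1.0, n_samples)
            log2mult[lnc_row] += _NOT_DE_COUPLING * z
            log2mult[pcg_row] += _NOT_DE_COUPLING * z
        elif axis.role is AxisRole.DECOY_NEGATIVE_CORRELATION:
            log2mult[lnc_row] += e * activity
            log2mult[pcg_row] -= e * activity
        else:
            log2mult[lnc_row] += e * activity
            log2mult[pcg_row] += e * activity
        base_mean[mir_row] = (
            _LOW_MIRNA_MEAN
            if axis.role is AxisRole.DECOY_LOW_PREVALENCE
            else _HIGH_MIRNA_MEAN
        )

    lib = rng.lognormal(0.0, config.lib_size_sigma, n_samples)
    mean = base_mean[:, None] * np.exp2(log2mult) * lib[None, :]
    disp = config.nb_dispersion
    lam = rng.gamma(shape=1.0 / disp, scale=mean * disp)
    counts = pd.DataFrame(
        rng.poisson(lam).astype(np.int64), index=gene_ids, columns=samples
    )
    counts.index.name = "gene_id"

    # --- sequences ----------------------------------------------------
    mir_dna, inserts, cores = _draw_mirnas(rng, config, roles)
    core_codes = np.sort(np.array([_core_code(c) for c in cores], dtype=np.int64))

    lncrna_seqs: dict[str, str] = {}
    utr3_seqs: dict[str, str] = {}
    planted_expect: list[tuple[str, str, str, list[tuple[str, int]]]] = []

    planted_lnc: dict[int, tuple] = {}
    planted_utr: dict[int, tuple] = {}
    for i, axis in enumerate(truth):
        planted_lnc[i] = (axis, SITE_PLANS[axis.role][0], inserts[i])
        planted_utr[i] = (axis, SITE_PLANS[axis.role][1], inserts[i])

    for j in range(config.n_lncrna):
        seq = rng.integers(0, 4, config.lncrna_len, dtype=np.uint8)
        if j in planted_lnc:
            axis, plan, ins = planted_lnc[j]
            protected, designed, expected = _plant(seq, plan, ins, rng)
            _scrub(seq, core_codes, rng, protected, designed)
            planted_expect.append((axis.mirna_id, lnc_ids[j], "lncRNA", expected))
        else:
            _scrub(seq, core_codes, rng)
        lncrna_seqs[lnc_ids[j]] = _codes_to_str(seq)

    for j in range(config.n_pcg):
        seq = rng.integers(0, 4, config.utr_len, dtype=np.uint8)
        if j in planted_utr:
            axis, plan, ins = planted_utr[j]
            protected, designed, expected = _plant(seq, plan, ins, rng)
            _scrub(seq, core_codes, rng, protected, designed)
            planted_expect.append((axis.mirna_id, pcg_ids[j], "mRNA_3UTR", expected))
        else:
            _scrub(seq, core_codes, rng)
        utr3_seqs[pcg_ids[j]] = _codes_to_str(seq)

    mirna_seqs = {
        mir_ids[i]: _codes_to_str(_str_to_codes(mir_dna[i]), rna=True)
        for i in range(config.n_mirna)
    }

    # planted sites must be recovered exactly by the scanner
    targets = {**lncrna_seqs, **utr3_seqs}
    for mirna_id, target_id, _cls, expected in planted_expect:
        found = {
            (s.site_type, s.start)
            for s in find_seed_sites(mirna_seqs[mirna_id], targets[target_id])
        }
        if found != set(expected):  # pragma: no cover - defensive
            raise CernaxError(
                f"planted sites for {mirna_id} on {target_id} not recovered: "
                f"expected {sorted(expected)}, found {sorted(found)}"
            )

    # --- gene sets ----------------------------------------------------
    gene_sets: dict[str, list[str]] = {}
    if config.n_pcg > 0:
        planted_mrnas = [axis.mrna_id for axis in truth]
        others = [g for g in pcg_ids if g not in set(planted_mrnas)]
        n_fill = min(30, len(others) // 2)
        pick = rng.permutation(len(others))
        fill_a = [others[k] for k in pick[:n_fill]]
        fill_b = [others[k] for k in pick[n_fill : 2 * n_fill]]
        gene_sets["adhesion-like"] = planted_mrnas + sorted(fill_a)
        gene_sets["epidermis-like"] = planted_mrnas + sorted(fill_b)
        for t in range(8):
            size = min(40, len(others))
            members = rng.choice(others, size=size, replace=False)
            gene_sets[f"TERM{t + 3:02d}"] = sorted(members.tolist())

    # --- survival and covariates -------------------------------------
    if config.n_true_axes > 0:
        # prognosis tied to the first TRUE axis lncRNA only (single-factor KM)
        expr = counts.loc[truth[0].lncrna_id, tumor_ids]
        med = float(expr.median())
        high = np.array([expr[s] > med for s in tumor_ids])
    else:
        high = np.zeros(config.n_tumor, dtype=bool)
    rate = _BASE_HAZARD * np.where(high, config.survival_hr, 1.0)
    t_event = rng.exponential(1.0 / rate)
    t_censor = rng.uniform(12.0, 80.0, config.n_tumor)
    time = np.minimum(t_event, t_censor)
    event = (t_event <= t_censor).astype(int)

    age = rng.integers(30, 80, config.n_tumor)
    sex = rng.choice(["female", "male"], config.n_tumor)
    smoking = rng.choice(["no", "yes"], config.n_tumor)

    sample_table = pd.DataFrame(
        {
            "tissue": tissue,
            "patient_id": patient,
            "pair_id": pair,
            "olnm": olnm,
            "time_months": np.concatenate([time, time[: config.n_paired_normal]]),
            "event": np.concatenate([event, event[: config.n_paired_normal]]),
            "age": np.concatenate([age, age[: config.n_paired_normal]]),
            "sex": np.concatenate([sex, sex[: config.n_paired_normal]]),
            "smoking": np.concatenate([smoking, smoking[: config.n_paired_normal]]),
        },
        index=pd.Index(samples, name="sample_id"),
    )

    return SyntheticCohort(
        config=config,
        counts=counts,
        gene_classes=gene_classes,
        sample_table=sample_table,
        lncrna_seqs=lncrna_seqs,
        utr3_seqs=utr3_seqs,
        mirna_seqs=mirna_seqs,
        gene_sets=gene_sets,
        truth=truth,
    )


# ---------------------------------------------------------------------------
# serialization


def _sites_to_str(sites: dict[str, int]) -> str:
    return ",".join(f"{t}:{n}" for t, n in sorted(sites.items())) or "."


def _sites_from_str(text: str, line: int) -> dict[str, int]:
    if text == ".":
        return {}
    out: dict[str, int] = {}
    for token in text.split(","):
        try:
            stype, n = token.split(":")
            out[stype] = int(n)
        except ValueError as exc:
            raise ParseError(f"malformed site token {token!r}", line=line) from exc
    return out


def write_cohort(cohort: SyntheticCohort, directory: str | Path) -> dict[str, Path]:
    """Write the cohort as plain-text files; returns a name -> path manifest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "counts": directory / "counts.tsv",
        "samples": directory / "samples.tsv",
        "transcripts": directory / "transcripts.fasta",
        "utr3": directory / "utr3.fasta",
        "mirna": directory / "mirna.fasta",
        "genesets": directory / "genesets.gmt",
        "truth": directory / "truth.tsv",
    }
    cio.write_counts(cohort.counts, cohort.gene_classes, paths["counts"])
    cio.write_table(cohort.sample_table, paths["samples"])
    cio.write_fasta(cohort.lncrna_seqs, paths["transcripts"])
    cio.write_fasta(cohort.utr3_seqs, paths["utr3"])
    cio.write_fasta(cohort.mirna_seqs, paths["mirna"])
    cio.write_gmt(cohort.gene_sets, paths["genesets"])
    rows = [
        {
            "lncrna_id": a.lncrna_id,
            "mirna_id": a.mirna_id,
            "mrna_id": a.mrna_id,
            "role": a.role.value,
            "lncrna_sites": _sites_to_str(a.lncrna_sites),
            "utr_sites": _sites_to_str(a.utr_sites),
        }
        for a in cohort.truth
    ]
    pd.DataFrame(
        rows,
        columns=[
            "lncrna_id", "mirna_id", "mrna_id", "role", "lncrna_sites", "utr_sites",
        ],
    ).to_csv(paths["truth"], sep="\t", index=False)
    return paths


def load_truth(path: str | Path) -> list[PlantedAxis]:
    """Read back a truth table written by :func:`write_cohort`."""
    axes: list[PlantedAxis] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        expected = [
            "lncrna_id", "mirna_id", "mrna_id", "role", "lncrna_sites", "utr_sites",
        ]
        if header != expected:
            raise ParseError(f"unexpected truth header {header}", line=1)
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 6:
                raise ParseError(
                    f"expected 6 fields, got {len(parts)}", line=lineno
                )
            try:
                role = AxisRole(parts[3])
            except ValueError as exc:
                raise ParseError(
                    f"unknown axis role {parts[3]!r}", line=lineno
                ) from exc
            axes.append(
                PlantedAxis(
                    lncrna_id=parts[0],
                    mirna_id=parts[1],
                    mrna_id=parts[2],
                    role=role,
                    lncrna_sites=_sites_from_str(parts[4], lineno),
                    utr_sites=_sites_from_str(parts[5], lineno),
                )
            )
    return axes


def load_cohort(directory: str | Path, config: CohortConfig | None = None) -> SyntheticCohort:
    """Reassemble a cohort from the files written by :func:`write_cohort`."""
    directory = Path(directory)
    counts, gene_classes = cio.read_counts(directory / "counts.tsv")
    sample_table = cio.read_table(directory / "samples.tsv", index_col="sample_id")
    return SyntheticCohort(
        config=config if config is not None else CohortConfig(),
        counts=counts,
        gene_classes=gene_classes,
        sample_table=sample_table,
        lncrna_seqs=cio.read_fasta(directory / "transcripts.fasta"),
        utr3_seqs=cio.read_fasta(directory / "utr3.fasta"),
        mirna_seqs=cio.read_fasta(directory / "mirna.fasta"),
        gene_sets=cio.read_gmt(directory / "genesets.gmt"),
        truth=load_truth(directory / "truth.tsv"),
    )
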