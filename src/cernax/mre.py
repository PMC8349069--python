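"""miRNA response element (MRE) detection and interaction scoring.

Seed sites on a target transcript are classified with the canonical
taxonomy (8mer, 7mer-m8, 7mer-A1, 6mer).  Matching is anchored on the
reverse complement of miRNA seed positions 2-7 ("core"); the flanking
m8 complement and the target-side A opposite miRNA position 1 upgrade
the site type.  Every anchor yields exactly one site of the strongest
applicable type, so a site is never double counted.

The per-pair interaction score aggregates sites with a noisy-OR:

    score = 1 - prod(1 - w_type)

which is 0 with no sites, strictly increasing in added sites, and
always < 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

from .errors import CernaxError

SITE_TYPES = ("8mer", "7mer-m8", "7mer-A1", "6mer")

#: Default per-site-type weights for the noisy-OR interaction score.
DEFAULT_WEIGHTS: dict[str, float] = {
    "8mer": 0.6,
    "7mer-m8": 0.4,
    "7mer-A1": 0.25,
    "6mer": 0.1,
}

_COMPLEMENT = str.maketrans("ACGT", "TGCA")
_VALID = frozenset("ACGT")


def _normalize(seq: str, what: str) -> str:
    """Uppercase, map U->T and validate the alphabet."""
    s = seq.upper().replace("U", "T")
    bad = set(s) - _VALID
    if bad:
        raise CernaxError(
            f"invalid character(s) {sorted(bad)} in {what} sequence"
        )
    return s


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True, order=True)
class SeedSite:
    """One classified seed-match site on a target sequence.

    ``start`` is the 1-based inclusive position of the site subsequence
    on the target's 5'->3' strand (for m8-containing types this is the
    m8-complementary base; otherwise the first base of the seed core).
    """

    target_id: str
    mirna_id: str
    site_type: str
    start: int


@dataclass
class InteractionRecord:
    """All sites and the aggregate score for one (miRNA, target) pair."""

    mirna_id: str
    target_id: str
    target_class: str  # "lncRNA" | "mRNA_3UTR"
    sites: list[SeedSite] = field(default_factory=list)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def score(self, weights: Mapping[str, float] | None = None) -> float:
        return interaction_score(self.sites, weights)


def find_seed_sites(
    mirna_seq: str,
    target_seq: str,
    mirna_id: str = "",
    target_id: str = "",
) -> list[SeedSite]:
    """Scan a target sequence for seed sites of one miRNA.

    Parameters
    ----------
    mirna_seq : str
        Mature miRNA, 5'->3', RNA or DNA alphabet, length >= 8.
    target_seq : str
        Target transcript / 3'UTR, 5'->3'.

    Returns
    -------
    list of SeedSite, ordered by position.
    """
    mir = _normalize(mirna_seq, "miRNA")
    if len(mir) < 8:
        raise CernaxError(f"miRNA {mirna_id or mirna_seq!r} shorter than 8 nt")
    tgt = _normalize(target_seq, "target")

    core = _revcomp(mir[1:7])            # rc of seed positions 2-7, 6 nt
    m8_comp = mir[7].translate(_COMPLEMENT)  # target base pairing miRNA pos 8

    sites: list[SeedSite] = []
    pos = tgt.find(core)
    while pos != -1:
        has_m8 = pos >= 1 and tgt[pos - 1] == m8_comp
        has_a1 = pos + 6 < len(tgt) and tgt[pos + 6] == "A"
        if has_m8 and has_a1:
            stype, start0 = "8mer", pos - 1
        elif has_m8:
            stype, start0 = "7mer-m8", pos - 1
        elif has_a1:
            stype, start0 = "7mer-A1", pos
        else:
            stype, start0 = "6mer", pos
        sites.append(SeedSite(target_id, mirna_id, stype, start0 + 1))
        pos = tgt.find(core, pos + 1)
    return sites


def interaction_score(
    sites: Iterable[SeedSite],
    weights: Mapping[str, float] | None = None,
) -> float:
    """Noisy-OR aggregate of site weights; in [0, 1), 0 iff no sites."""
    w = DEFAULT_WEIGHTS if weights is None else dict(weights)
    for stype, wt in w.items():
        if not (0.0 <= wt < 1.0):
            raise CernaxError(
                f"site weight for {stype!r} must be in [0, 1), got {wt}"
            )
    remain = 1.0
    for site in sites:
        remain *= 1.0 - w[site.site_type]
    return 1.0 - remain


def predict_interactions(
    mirnas: Mapping[str, str],
    targets: Mapping[str, str],
    target_class: str,
) -> list[InteractionRecord]:
    """Score every (miRNA, target) pair; keep pairs with >= 1 site.

    Inputs are id -> sequence mappings (see :func:`cernax.io.read_fasta`,
    which rejects duplicate ids).  Output is ordered by
    (mirna_id, target_id).
    """
    if target_class not in ("lncRNA", "mRNA_3UTR"):
        raise CernaxError(f"unknown target_class {target_class!r}")
    records: list[InteractionRecord] = []
    for mirna_id in sorted(mirnas):
        mseq = mirnas[mirna_id]
        for target_id in sorted(targets):
            sites = find_seed_sites(mseq, targets[target_id], mirna_id, target_id)
            if sites:
                records.append(
                    InteractionRecord(mirna_id, target_id, target_class, sites)
                )
    return records
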