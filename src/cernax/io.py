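"""Readers and writers for the plain-text interchange formats.

All tables are TSV with a header row; gene and sample ids are opaque
strings.  Sequences travel as standard FASTA (uppercase on read, U
preserved); gene sets as GMT.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import ParseError

GENE_CLASSES = ("lncRNA", "PCG", "miRNA")


def read_counts(path: str | Path) -> tuple[pd.DataFrame, pd.Series]:
    """Read a counts TSV (gene_id, gene_class, one column per sample).

    Returns
    -------
    counts : DataFrame
        Integer gene x sample matrix indexed by gene_id.
    gene_class : Series
        gene_id -> class label in {lncRNA, PCG, miRNA}.
    """
    try:
        df = pd.read_csv(path, sep="\t", dtype={"gene_id": str})
    except pd.errors.ParserError as exc:  # ragged rows etc.
        raise ParseError(f"malformed counts table {path}: {exc}") from exc
    if df.columns[0] != "gene_id" or df.columns[1] != "gene_class":
        raise ParseError(
            f"{path}: first two columns must be gene_id, gene_class"
        )
    if df.shape[1] < 3:
        raise ParseError(f"{path}: counts matrix has no sample columns")
    dup = df["gene_id"][df["gene_id"].duplicated()]
    if not dup.empty:
        raise ParseError(f"{path}: duplicate gene id {dup.iloc[0]!r}")
    bad_class = set(df["gene_class"]) - set(GENE_CLASSES)
    if bad_class:
        raise ParseError(f"{path}: unknown gene_class {sorted(bad_class)}")
    df = df.set_index("gene_id")
    gene_class = df.pop("gene_class")
    counts = df
    if counts.shape[0] == 0:  # header-only file: dtypes are indeterminate
        counts = counts.astype("int64")
    for col in counts.columns:
        if not pd.api.types.is_integer_dtype(counts[col]):
            raise ParseError(f"{path}: non-integer counts in column {col!r}")
        neg = counts.index[counts[col] < 0]
        if len(neg):
            raise ParseError(
                f"{path}: negative count at gene {neg[0]!r}, sample {col!r}"
            )
    return counts, gene_class


def write_counts(
    counts: pd.DataFrame, gene_class: pd.Series, path: str | Path
) -> None:
    out = counts.copy()
    out.insert(0, "gene_class", gene_class.reindex(counts.index))
    out.index.name = "gene_id"
    out.to_csv(path, sep="\t")


def read_table(path: str | Path, index_col: str | None = None) -> pd.DataFrame:
    # round_trip: repr-written floats must parse back bit-identically
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    if index_col is not None:
        df = df.set_index(index_col)
    return df


def write_table(df: pd.DataFrame, path: str | Path, index: bool = True) -> None:
    df.to_csv(path, sep="\t", index=index)


def read_fasta(path: str | Path) -> dict[str, str]:
    """Parse FASTA into an id -> uppercase sequence map.

    The description after the first whitespace is ignored; U is kept as
    written.  Duplicate ids and empty records are rejected.
    """
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seqs:
            raise ParseError(f"{path}: duplicate sequence id {rec.id!r}")
        seq = str(rec.seq).upper()
        if not seq:
            raise ParseError(f"{path}: empty sequence for id {rec.id!r}")
        seqs[rec.id] = seq
    return seqs


def write_fasta(seqs: Mapping[str, str], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="")
        for name, seq in seqs.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """Parse a GMT file into term -> ordered, deduplicated gene list."""
    gene_sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(
                    f"GMT line has {len(fields)} field(s), need >= 3",
                    line=lineno,
                )
            term = fields[0]
            if term in gene_sets:
                raise ParseError(f"duplicate term {term!r}", line=lineno)
            genes = list(dict.fromkeys(g for g in fields[2:] if g))
            gene_sets[term] = genes
    return gene_sets


def write_gmt(gene_sets: Mapping[str, list[str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for term, genes in gene_sets.items():
            fh.write("\t".join([term, term] + list(genes)) + "\n")
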