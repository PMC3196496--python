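"""Readers and writers for the plain-text formats the pipeline exchanges.

Everything is tab-separated UTF-8 with a header row and LF line endings;
sequences travel as FASTA and trees as newick.  Transcript FASTA headers
carry a ``gene=<id>`` tag so multiple transcripts can be grouped per gene.
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

_GENE_TAG = re.compile(r"gene=(\S+)")


def read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"chromosome": str} if _has_col(path, "chromosome") else None)


def _has_col(path: str | Path, name: str) -> bool:
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
    return name in header


def write_tsv(frame: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(path, sep="\t", index=False, lineterminator="\n")


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path) -> None:
    """Write ``(id, sequence)`` pairs; the id may contain a description."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    seqs = []
    for rid, seq in records:
        name, _, desc = rid.partition(" ")
        seqs.append(SeqRecord(Seq(seq), id=name, description=desc))
    SeqIO.write(seqs, str(path), "fasta")


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]


def read_transcripts(path: str | Path) -> dict[str, list[str]]:
    """Group transcript sequences by the ``gene=`` tag in each FASTA header.

    Records without a tag are treated as single-transcript genes named by
    their record id.
    """
    genes: dict[str, list[str]] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        m = _GENE_TAG.search(rec.description)
        gene = m.group(1) if m else rec.id
        genes.setdefault(gene, []).append(str(rec.seq).upper())
    return genes


def write_transcripts(genes: Mapping[str, list[str]], path: str | Path) -> None:
    records = []
    for gene, seqs in genes.items():
        for i, seq in enumerate(seqs):
            records.append((f"{gene}.t{i + 1} gene={gene}", seq))
    write_fasta(records, path)
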