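"""FASTA / TSV round-trip helpers shared by every pipeline stage.

Sequences are canonicalized to upper case on read; FASTA output is wrapped
at a fixed width so write∘read is the identity on canonical records.
"""

from __future__ import annotations

import os
from typing import Dict, Iterable, Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

FASTA_WIDTH = 70

COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string (A/C/G/T/N)."""
    return seq.translate(COMPLEMENT)[::-1]


def read_fasta(path: str | os.PathLike) -> Dict[str, str]:
    """Read a FASTA file into an ordered ``{id: upper-case sequence}`` dict."""
    records: Dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in records:
            raise ValueError(f"duplicate FASTA id {rec.id!r} in {path}")
        records[rec.id] = str(rec.seq).upper()
    return records


def write_fasta(path: str | os.PathLike, records: Mapping[str, str] | Iterable[tuple[str, str]]) -> None:
    items = records.items() if isinstance(records, Mapping) else records
    seqs = [SeqRecord(Seq(s), id=str(name), description="") for name, s in items]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=FASTA_WIDTH)
        writer.write_file(seqs)


def read_tsv(path: str | os.PathLike, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", **kwargs)


def write_tsv(df: pd.DataFrame, path: str | os.PathLike, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index)
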