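"""Plain-text format helpers: FASTA, FASTQ, BED6, TSV, GMT.

FASTA goes through Biopython; FASTQ reading uses the fast
``FastqGeneralIterator`` with record-level validation so corrupt input is
reported with the file name and record number.
"""

from __future__ import annotations

import os
from typing import Iterable, Iterator

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .errors import FormatError


# ---------------------------------------------------------------- FASTA

def write_fasta(sequences: dict[str, str], path: str | os.PathLike) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | os.PathLike) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


# ---------------------------------------------------------------- FASTQ

def write_fastq(reads: Iterable[tuple[str, str]], path: str | os.PathLike,
                quality_char: str = "I") -> None:
    """Write ``(name, sequence)`` pairs with constant phred-33 quality."""
    with open(path, "w") as fh:
        for name, seq in reads:
            fh.write(f"@{name}\n{seq}\n+\n{quality_char * len(seq)}\n")


def read_fastq(path: str | os.PathLike) -> Iterator[tuple[str, str]]:
    """Yield ``(name, sequence)`` pairs, validating each record.

    Raises :class:`FormatError` naming the file and the 1-based record
    number on malformed records (bad alphabet or truncated entries).
    """
    allowed = set("ACGTN")
    try:
        with open(path) as fh:
            for i, (name, seq, qual) in enumerate(FastqGeneralIterator(fh), start=1):
                seq = seq.upper()
                if not seq or not set(seq) <= allowed or len(qual) != len(seq):
                    raise FormatError(f"{path}: corrupt FASTQ record {i} ({name!r})")
                yield name, seq
    except ValueError as exc:  # raised by FastqGeneralIterator on structural damage
        raise FormatError(f"{path}: corrupt FASTQ ({exc})") from exc


# ---------------------------------------------------------------- BED6

def write_bed6(rows: Iterable[tuple[str, int, int, str, float, str]],
               path: str | os.PathLike) -> None:
    """Rows are (chrom, start, end, name, score, strand); 0-based half-open."""
    with open(path, "w") as fh:
        for chrom, start, end, name, score, strand in rows:
            fh.write(f"{chrom}\t{start}\t{end}\t{name}\t{score}\t{strand}\n")


def read_bed(path: str | os.PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df = df.iloc[:, :6]
    df.columns = ["chrom", "start", "end", "name", "score", "strand"][: df.shape[1]]
    return df


# ---------------------------------------------------------------- TSV

def write_tsv(df: pd.DataFrame, path: str | os.PathLike,
              index: bool = True, comments: list[str] | None = None) -> None:
    with open(path, "w") as fh:
        for line in comments or []:
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=index)


def read_tsv(path: str | os.PathLike, index_col: int | None = 0) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", index_col=index_col)


# ---------------------------------------------------------------- GMT

def read_gmt(path: str | os.PathLike) -> dict[str, list[str]]:
    """GMT: one set per line — name, description, then member genes."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}: GMT line {i} has fewer than 3 fields")
            sets[fields[0]] = list(dict.fromkeys(fields[2:]))
    return sets


def write_gmt(sets: dict[str, list[str]], path: str | os.PathLike,
              description: str = "circscreen") -> None:
    with open(path, "w") as fh:
        for name, members in sets.items():
            fh.write("\t".join([name, description, *members]) + "\n")
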