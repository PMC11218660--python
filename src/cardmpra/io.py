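"""Disk formats: FASTA via Biopython, BED and TSV via pandas."""

from __future__ import annotations

from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

BED_COLUMNS = ["chrom", "start", "end", "name", "value"]


def write_fasta(sequences: dict[str, str], path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_bed(intervals: pd.DataFrame, path) -> None:
    cols = [c for c in BED_COLUMNS if c in intervals.columns]
    intervals[cols].to_csv(path, sep="\t", header=False, index=False)


def read_bed(path, value: bool = False) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    names = BED_COLUMNS[:df.shape[1]]
    df.columns = names + list(df.columns[len(names):])
    return df


def write_tsv(frame: pd.DataFrame, path) -> None:
    frame.to_csv(path, sep="\t", index=False)


def read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
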