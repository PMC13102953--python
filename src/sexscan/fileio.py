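"""Readers/writers for the plain-text formats the pipeline exchanges.

All writers are deterministic byte-for-byte under fixed input. Window
tables use BED-style 0-based half-open intervals, sorted lexically by
chromosome then numerically by start.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

DEPTH_COLUMNS = ["chrom", "start", "end", "pooled_male_depth", "pooled_female_depth"]


def write_fasta(seqs: Mapping[str, str] | Iterable[tuple[str, str]], path: str | Path) -> None:
    """Write name → sequence pairs as 60-column-wrapped FASTA."""
    items = seqs.items() if isinstance(seqs, Mapping) else seqs
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in items]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_depth_table(df: pd.DataFrame, path: str | Path) -> None:
    df[DEPTH_COLUMNS].to_csv(path, sep="\t", index=False)


def read_depth_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(DEPTH_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"depth table missing columns: {sorted(missing)}")
    return df


def write_windows(df: pd.DataFrame, path: str | Path) -> None:
    """Write a window-statistics table as BED3+metrics TSV.

    Requires chrom/start/end columns; remaining columns are kept as-is.
    """
    for col in ("chrom", "start", "end"):
        if col not in df.columns:
            raise ValueError(f"window table missing column {col!r}")
    lead = ["chrom", "start", "end"]
    rest = [c for c in df.columns if c not in lead]
    out = df[lead + rest].sort_values(["chrom", "start"], kind="mergesort")
    out.to_csv(path, sep="\t", index=False)


def read_windows(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_json(obj, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_json(path: str | Path):
    with open(path) as fh:
        return json.load(fh)
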