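"""Readers and writers for the plain-text formats the pipeline exchanges:
FASTA, chrom-sizes TSV, BED, TSV count matrices and sample sheets."""
from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

BED_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]


def write_fasta(sequences: dict, path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fasta(path) -> dict:
    """FASTA into a dict of plain sequence strings.

    Synthetic genomes are small enough to hold in memory; any mapping of
    chromosome name to a sliceable sequence (e.g. pyfaidx.Fasta for large
    genomes) can be used interchangeably by the downstream functions.
    """
    from Bio import SeqIO

    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_chrom_sizes(chrom_sizes: dict, path) -> None:
    pd.Series(chrom_sizes).to_csv(path, sep="\t", header=False)


def read_chrom_sizes(path) -> dict:
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "size"])
    return dict(zip(df["chrom"], df["size"].astype(int)))


def write_bed(df: pd.DataFrame, path) -> None:
    cols = [c for c in BED_COLUMNS if c in df.columns]
    df.to_csv(path, sep="\t", header=False, index=False, columns=cols)


def read_bed(path, names=None) -> pd.DataFrame:
    probe = pd.read_csv(path, sep="\t", header=None, nrows=1)
    ncol = probe.shape[1]
    cols = names or BED_COLUMNS[:ncol]
    df = pd.read_csv(path, sep="\t", header=None, names=cols)
    df["start"] = df["start"].astype(np.int64)
    df["end"] = df["end"].astype(np.int64)
    return df


def write_matrix(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t")


def read_matrix(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_json(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, sort_keys=True, default=_json_default)
        fh.write("\n")


def read_json(path):
    with open(path) as fh:
        return json.load(fh)


def _json_default(obj):
    if isinstance(obj, (set, frozenset)):
        return sorted(obj)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, Path):
        return str(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")
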