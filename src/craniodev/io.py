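"""Readers and writers for the plain-text formats the pipeline exchanges.

Counts travel as gene x sample TSV, sample sheets as CSV, coverage as
4-column bedGraph (0-based, half-open), consensus and supermatrix sequences
as FASTA, gene sets as GMT and ranked lists as RNK.
"""

from __future__ import annotations

import os
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


# ---------------------------------------------------------------- counts ---

def write_counts_tsv(counts: pd.DataFrame, path: str | os.PathLike) -> None:
    counts.to_csv(path, sep="\t", index_label="gene_id")


def read_counts_tsv(path: str | os.PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    return df


def write_sample_sheet(samples: pd.DataFrame, path: str | os.PathLike) -> None:
    samples.to_csv(path, index=False)


def read_sample_sheet(path: str | os.PathLike) -> pd.DataFrame:
    df = pd.read_csv(path)
    df["sample_id"] = df["sample_id"].astype(str)
    return df


# -------------------------------------------------------------- bedGraph ---

def write_bedgraph(
    depths: Mapping[str, np.ndarray], path: str | os.PathLike
) -> None:
    """Write per-base depths as bedGraph, merging equal-depth runs."""
    with open(path, "w") as fh:
        for scaffold in depths:
            d = np.asarray(depths[scaffold])
            if d.size == 0:
                continue
            change = np.flatnonzero(np.diff(d)) + 1
            starts = np.concatenate(([0], change))
            ends = np.concatenate((change, [d.size]))
            for s, e in zip(starts, ends):
                fh.write(f"{scaffold}\t{s}\t{e}\t{d[s]}\n")


def read_bedgraph(
    path: str | os.PathLike, scaffold_lengths: Mapping[str, int]
) -> dict[str, np.ndarray]:
    """Expand a bedGraph back to per-base depth arrays.

    Positions not covered by any record default to depth 0.
    """
    depths = {
        sc: np.zeros(int(n), dtype=np.int64)
        for sc, n in scaffold_lengths.items()
    }
    table = pd.read_csv(
        path, sep="\t", header=None,
        names=["scaffold", "start", "end", "depth"],
        dtype={"scaffold": str},
    )
    for sc, sub in table.groupby("scaffold", sort=False):
        if sc not in depths:
            raise ValueError(f"bedGraph scaffold {sc!r} has no declared length")
        arr = depths[sc]
        for s, e, d in zip(sub["start"], sub["end"], sub["depth"]):
            if e > arr.size:
                raise ValueError(
                    f"bedGraph interval {sc}:{s}-{e} exceeds scaffold length"
                )
            arr[int(s):int(e)] = int(d)
    return depths


# ----------------------------------------------------------------- FASTA ---

def write_fasta(records: Mapping[str, str], path: str | os.PathLike) -> None:
    SeqIO.write(
        (SeqRecord(Seq(seq), id=name, description="")
         for name, seq in records.items()),
        path, "fasta",
    )


def read_fasta(path: str | os.PathLike) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_phylip(records: Mapping[str, str], path: str | os.PathLike) -> None:
    """Relaxed PHYLIP: full names, two-token header."""
    names = list(records)
    if names:
        lengths = {len(records[n]) for n in names}
        if len(lengths) > 1:
            raise ValueError("sequences differ in length")
        ncols = lengths.pop()
    else:
        ncols = 0
    with open(path, "w") as fh:
        fh.write(f"{len(names)} {ncols}\n")
        for n in names:
            fh.write(f"{n}  {records[n]}\n")


# ------------------------------------------------------------- GMT / RNK ---

def read_gmt(path: str | os.PathLike) -> dict[str, list[str]]:
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"malformed GMT line: {line[:80]!r}")
            name = fields[0]
            if name in sets:
                raise ValueError(f"duplicate gene-set name {name!r}")
            members = [g for g in fields[2:] if g]
            if not members:
                raise ValueError(f"empty gene set {name!r}")
            sets[name] = members
    return sets


def write_gmt(
    sets: Mapping[str, Iterable[str]],
    path: str | os.PathLike,
    description: str = "na",
) -> None:
    with open(path, "w") as fh:
        for name, members in sets.items():
            fh.write("\t".join([name, description, *members]) + "\n")


def write_rnk(ranked: pd.DataFrame, path: str | os.PathLike) -> None:
    """Two-column gene/score table in rank order."""
    ranked[["gene_id", "score"]].to_csv(
        path, sep="\t", header=False, index=False
    )


def read_rnk(path: str | os.PathLike) -> pd.DataFrame:
    df = pd.read_csv(
        path, sep="\t", header=None, names=["gene_id", "score"],
        dtype={"gene_id": str},
    )
    return df
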