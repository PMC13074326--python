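"""Shared helpers: FASTA/BED I/O and band-code <-> dosage conversion.

BED inputs are 0-based half-open and converted to 1-based inclusive
coordinates on read; everything downstream is 1-based inclusive as in VCF.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from intervaltree import IntervalTree

# band code -> diploid alternate-allele dosage; code 0 (no band) is missing,
# code 4 (second InDel allele) collapses to dosage 2 for biallelic models
DOSAGE_MAP = {1: 0.0, 3: 1.0, 2: 2.0, 4: 2.0, 0: np.nan}


def read_fasta(path: str | Path) -> dict[str, str]:
    """Load a FASTA file into a dict of upper-case sequence strings."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: dict[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_bed(path: str | Path) -> pd.DataFrame:
    """Read a 3+ column BED file into 1-based inclusive intervals.

    Returns a DataFrame with columns chrom, start, end (1-based inclusive).
    """
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        usecols=[0, 1, 2], names=["chrom", "start", "end"],
        dtype={"chrom": str},
    )
    df["start"] = df["start"].astype(int) + 1  # 0-based half-open -> 1-based
    df["end"] = df["end"].astype(int)
    return df


def write_bed(intervals: pd.DataFrame, path: str | Path) -> None:
    """Write 1-based inclusive intervals (chrom/start/end) as 0-based BED."""
    out = intervals.copy()
    out["start"] = out["start"].astype(int) - 1
    out[["chrom", "start", "end"]].to_csv(path, sep="\t", header=False, index=False)


def interval_trees(intervals: pd.DataFrame) -> dict[str, IntervalTree]:
    """Per-chromosome IntervalTrees from 1-based inclusive intervals.

    IntervalTree is half-open, so an inclusive interval [s, e] becomes
    [s, e + 1).
    """
    trees: dict[str, IntervalTree] = {}
    for chrom, grp in intervals.groupby("chrom"):
        trees[str(chrom)] = IntervalTree.from_tuples(
            (int(s), int(e) + 1) for s, e in zip(grp["start"], grp["end"])
        )
    return trees


def dosage_matrix(codes: pd.DataFrame) -> np.ndarray:
    """Band-code matrix (accessions x markers) -> float dosage with NaN missing.

    Codes: 1 (reference band) -> 0, 3 (heterozygous) -> 1, 2 and 4
    (InDel bands) -> 2, 0 (no band) -> NaN.
    """
    arr = codes.to_numpy()
    out = np.empty(arr.shape, dtype=float)
    for code, dose in DOSAGE_MAP.items():
        out[arr == code] = dose
    bad = ~np.isin(arr, list(DOSAGE_MAP))
    if bad.any():
        raise ValueError(f"invalid band codes present: {sorted(set(arr[bad]))}")
    return out
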