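"""Band-code genotype matrices, allele frequencies and marker informativeness.

Band codes score silver-stained gel phenotypes per accession and marker:
0 = no band (missing), 1 = band matching the reference variety,
2 = InDel band relative to the reference, 3 = heterozygous (both bands),
4 = a second, length-distinct InDel band.

Polymorphism information content follows the Botstein definition

    PIC = 1 - sum_i p_i^2 - sum_{i<j} 2 p_i^2 p_j^2

computed from diploid allele counts (code 1 -> two reference alleles,
2 -> two InDel alleles, 4 -> two second-InDel alleles, 3 -> one reference
plus one InDel allele, 0 -> excluded from the denominator).
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "read_genotype_matrix",
    "codes_to_allele_freqs",
    "pic",
    "summarize_markers",
    "aggregate_pic",
]

ALLELES = ("ref", "alt", "alt2")

# diploid allele contributions per band code: (ref, alt, alt2)
_DIPLOID_COUNTS = {
    1: (2, 0, 0),
    2: (0, 2, 0),
    3: (1, 1, 0),
    4: (0, 0, 2),
}

# haploid band-presence counting, for sensitivity checks only: each visible
# band contributes one allele
_HAPLOID_COUNTS = {
    1: (1, 0, 0),
    2: (0, 1, 0),
    3: (1, 1, 0),
    4: (0, 0, 1),
}


def read_genotype_matrix(path: str | Path) -> pd.DataFrame:
    """Read an accessions x markers band-code TSV (first column = accession).

    Cells must be integers 0-4; accession ids and marker names must be
    unique.
    """
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    if df.index.has_duplicates or df.columns.has_duplicates:
        raise ValueError("accession ids and marker names must be unique")
    values = df.to_numpy()
    if not np.isin(values, [0, 1, 2, 3, 4]).all():
        raise ValueError("band codes must be integers in 0..4")
    return df.astype(int)


def codes_to_allele_freqs(column: pd.Series | np.ndarray, mode: str = "diploid") -> dict[str, float]:
    """Allele frequencies over {ref, alt, alt2} from one marker's band codes.

    ``diploid`` counting treats each scored accession as two allele copies
    (heterozygotes contribute one of each); ``haploid`` counts each visible
    band once (sensitivity-check mode). Code 0 is excluded from the
    denominator. Only observed alleles appear in the result; frequencies sum
    to 1. Raises on an all-missing column.
    """
    table = {"diploid": _DIPLOID_COUNTS, "haploid": _HAPLOID_COUNTS}[mode]
    codes = np.asarray(column)
    counts = np.zeros(3, dtype=float)
    for code, contrib in table.items():
        n = int((codes == code).sum())
        if n:
            counts += n * np.asarray(contrib, dtype=float)
    total = counts.sum()
    if total == 0:
        raise ValueError("all-missing marker column: no allele observations")
    freqs = counts / total
    return {a: f for a, f in zip(ALLELES, freqs) if f > 0}


def pic(freqs: dict[str, float] | np.ndarray | list[float]) -> float:
    """Polymorphism information content of an allele frequency vector.

    Frequencies must be non-negative and sum to 1 (tolerance 1e-9). The value
    lies in [0, 1), is invariant under allele permutation, and is 0 exactly
    when a single allele has frequency 1.
    """
    p = np.asarray(list(freqs.values()) if isinstance(freqs, dict) else freqs,
                   dtype=float)
    if p.size == 0 or (p < -1e-12).any():
        raise ValueError("frequencies must be non-negative and non-empty")
    if abs(p.sum() - 1.0) > 1e-9:
        raise ValueError(f"frequencies must sum to 1, got {p.sum()!r}")
    sum_sq = float(np.sum(p**2))
    # sum_{i<j} 2 p_i^2 p_j^2 = (sum p_i^2)^2 - sum p_i^4
    cross = sum_sq**2 - float(np.sum(p**4))
    return 1.0 - sum_sq - cross


def summarize_markers(matrix: pd.DataFrame, mode: str = "diploid") -> pd.DataFrame:
    """Per-marker allele number, PIC and missing rate.

    Returns one row per marker with columns Marker, AlleleNumber, PIC
    (rounded to 3 decimals, as marker tables are conventionally printed) and
    MissingRate. All-missing markers get AlleleNumber 0 and NaN PIC (logged).
    """
    rows = []
    n_acc = len(matrix)
    for marker in matrix.columns:
        col = matrix[marker].to_numpy()
        missing = float((col == 0).sum()) / n_acc if n_acc else np.nan
        try:
            freqs = codes_to_allele_freqs(col, mode=mode)
            value = round(pic(freqs), 3)
            n_alleles = len(freqs)
        except ValueError:
            logger.warning("marker %s is all-missing; PIC undefined", marker)
            value, n_alleles = np.nan, 0
        rows.append((marker, n_alleles, value, missing))
    return pd.DataFrame(
        rows, columns=["Marker", "AlleleNumber", "PIC", "MissingRate"]
    )


def aggregate_pic(summary: pd.DataFrame, threshold: float = 0.25) -> dict[str, float]:
    """Aggregate marker statistics: mean (4 decimals), min, max PIC, the
    maximum allele number, and the count of markers with PIC above
    ``threshold``. Markers with undefined PIC are excluded."""
    defined = summary.dropna(subset=["PIC"])
    if defined.empty:
        raise ValueError("no markers with defined PIC")
    return {
        "n_markers": int(len(defined)),
        "pic_mean": round(float(defined["PIC"].mean()), 4),
        "pic_min": float(defined["PIC"].min()),
        "pic_max": float(defined["PIC"].max()),
        "allele_number_max": int(defined["AlleleNumber"].max()),
        f"n_pic_gt_{threshold}": int((defined["PIC"] > threshold).sum()),
    }
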