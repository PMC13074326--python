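"""InDel variant cataloguing.

Reads insertion/deletion records from VCF, classifies them by net length
change, and summarises counts per chromosome (insertions, deletions, totals
and each chromosome's share of the genome-wide total).

Coordinates are 1-based inclusive throughout, as in VCF.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
import pysam

logger = logging.getLogger(__name__)

__all__ = [
    "IndelVariant",
    "VcfFormatError",
    "read_variants",
    "classify",
    "summarize_by_chromosome",
    "write_summary",
]


class VcfFormatError(ValueError):
    """Raised when a VCF record cannot be parsed, naming the line."""


@dataclass(frozen=True)
class IndelVariant:
    """One insertion or deletion relative to the reference.

    Attributes
    ----------
    chrom : str
        Chromosome label.
    pos : int
        1-based leftmost reference coordinate.
    ref_allele, alt_allele : str
        Reference and alternate allele sequences.
    qual : float
        Phred-scaled quality; NaN when the VCF QUAL field was missing (".").
    indel_type : str
        ``"insertion"`` if the alternate allele is longer, else ``"deletion"``.
    indel_len : int
        Absolute length difference in bp (>= 1).
    """

    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str
    qual: float
    indel_type: str
    indel_len: int

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.ref_allele == self.alt_allele:
            raise ValueError("ref_allele and alt_allele must differ")
        expected = abs(len(self.ref_allele) - len(self.alt_allele))
        if expected < 1 or self.indel_len != expected:
            raise ValueError(
                f"indel_len {self.indel_len} inconsistent with alleles "
                f"{self.ref_allele}>{self.alt_allele}"
            )

    @property
    def qual_known(self) -> bool:
        return not math.isnan(self.qual)

    @property
    def ref_end(self) -> int:
        """1-based inclusive end of the reference footprint."""
        return self.pos + len(self.ref_allele) - 1


def classify(chrom: str, pos: int, ref: str, alt: str, qual: float) -> IndelVariant | None:
    """Classify one REF/ALT pair; return None for non-indels (e.g. SNPs).

    Complex substitutions with unequal allele lengths are classified by their
    net length change: longer ALT means insertion, shorter means deletion.
    """
    ref = ref.upper()
    alt = alt.upper()
    if alt.startswith("<") or set(alt) - set("ACGTN"):
        return None  # symbolic or breakend allele
    diff = len(alt) - len(ref)
    if diff == 0:
        return None
    indel_type = "insertion" if diff > 0 else "deletion"
    return IndelVariant(
        chrom=chrom,
        pos=pos,
        ref_allele=ref,
        alt_allele=alt,
        qual=float("nan") if qual is None else float(qual),
        indel_type=indel_type,
        indel_len=abs(diff),
    )


def _locate_malformed_line(path: str | Path) -> int | None:
    """Best-effort scan for the first structurally bad VCF body line."""
    import gzip

    opener = gzip.open if str(path).endswith(".gz") else open
    try:
        with opener(path, "rt") as fh:
            for lineno, line in enumerate(fh, start=1):
                if line.startswith("#") or not line.strip():
                    continue
                fields = line.rstrip("\n").split("\t")
                if len(fields) < 6:
                    return lineno
                try:
                    int(fields[1])
                except ValueError:
                    return lineno
                if fields[5] not in (".",) :
                    try:
                        float(fields[5])
                    except ValueError:
                        return lineno
    except OSError:
        return None
    return None


def read_variants(vcf_source: str | Path) -> list[IndelVariant]:
    """Read InDel variants from a VCF 4.x file (plain or gzip).

    Multi-allelic records are split into one variant per ALT allele. SNPs,
    same-length substitutions and symbolic alleles are skipped (counts
    logged). Input order is preserved. A missing QUAL (".") is retained with
    ``qual`` set to NaN and flagged via :attr:`IndelVariant.qual_known`.
    """
    variants: list[IndelVariant] = []
    n_skipped = 0
    try:
        with pysam.VariantFile(str(vcf_source)) as vcf:
            for rec in vcf:
                alts = rec.alts or ()
                for alt in alts:
                    if alt is None:
                        continue
                    v = classify(rec.chrom, rec.pos, rec.ref, alt, rec.qual)
                    if v is None:
                        n_skipped += 1
                    else:
                        variants.append(v)
    except (ValueError, OSError) as exc:
        lineno = _locate_malformed_line(vcf_source)
        where = f" at line {lineno}" if lineno is not None else ""
        raise VcfFormatError(f"malformed VCF {vcf_source}{where}: {exc}") from exc
    logger.info(
        "read %d InDel variants from %s (%d non-indel alleles skipped)",
        len(variants), vcf_source, n_skipped,
    )
    return variants


def _round_half_up(x: float, ndigits: int = 2) -> float:
    """Round half away from zero, matching how the summary table is printed."""
    from decimal import Decimal, ROUND_HALF_UP

    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def summarize_by_chromosome(
    variants: Iterable[IndelVariant] | pd.DataFrame,
) -> pd.DataFrame:
    """Per-chromosome insertion/deletion/total counts plus a grand-total row.

    Accepts either IndelVariant records or a pre-counted DataFrame with
    columns ``Chromosome``, ``Insertion``, ``Deletion`` (as when re-deriving
    the summary arithmetic from a published count table).

    Returns a DataFrame with columns Chromosome, Insertion, Deletion, Total,
    InDel_pct where InDel_pct = 100 * Total / grand total, rounded half-up to
    2 decimals, and a final "Total" row holding the column sums (pct 100.00
    by construction, or 0 for empty input).
    """
    if isinstance(variants, pd.DataFrame):
        counts = variants[["Chromosome", "Insertion", "Deletion"]].copy()
    else:
        rows = [(v.chrom, v.indel_type) for v in variants]
        if rows:
            df = pd.DataFrame(rows, columns=["Chromosome", "type"])
            counts = (
                df.groupby("Chromosome", sort=True)["type"]
                .value_counts()
                .unstack(fill_value=0)
                .reindex(columns=["insertion", "deletion"], fill_value=0)
                .reset_index()
                .rename(columns={"insertion": "Insertion", "deletion": "Deletion"})
            )
            counts.columns.name = None
        else:
            counts = pd.DataFrame(columns=["Chromosome", "Insertion", "Deletion"])

    counts = counts.copy()
    counts["Total"] = counts["Insertion"] + counts["Deletion"]
    grand = int(counts["Total"].sum())
    if grand > 0:
        counts["InDel_pct"] = [
            _round_half_up(100.0 * t / grand) for t in counts["Total"]
        ]
    else:
        counts["InDel_pct"] = 0.0
    total_row = pd.DataFrame(
        {
            "Chromosome": ["Total"],
            "Insertion": [int(counts["Insertion"].sum())],
            "Deletion": [int(counts["Deletion"].sum())],
            "Total": [grand],
            "InDel_pct": [100.00 if grand > 0 else 0.0],
        }
    )
    out = pd.concat([counts, total_row], ignore_index=True)
    out[["Insertion", "Deletion", "Total"]] = out[
        ["Insertion", "Deletion", "Total"]
    ].astype(int)
    return out


def write_summary(summary: pd.DataFrame, path: str | Path) -> None:
    """Write the chromosome summary as TSV in the published column order."""
    summary.to_csv(path, sep="\t", index=False)


def write_vcf(
    variants: Sequence[IndelVariant],
    path: str | Path,
    contig_lengths: dict[str, int] | None = None,
) -> None:
    """Write variants as a minimal VCF 4.2 file (sites only)."""
    chroms: list[str] = []
    for v in variants:
        if v.chrom not in chroms:
            chroms.append(v.chrom)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for c in chroms:
            if contig_lengths and c in contig_lengths:
                fh.write(f"##contig=<ID={c},length={contig_lengths[c]}>\n")
            else:
                fh.write(f"##contig=<ID={c}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for v in variants:
            qual = "." if not v.qual_known else f"{v.qual:g}"
            fh.write(
                f"{v.chrom}\t{v.pos}\t.\t{v.ref_allele}\t{v.alt_allele}"
                f"\t{qual}\t.\t.\n"
            )
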