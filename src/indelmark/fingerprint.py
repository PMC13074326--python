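"""Core-marker panels and DNA fingerprint code strings.

A fingerprint is the concatenation of an accession's band codes (digits 0-4)
over a fixed, ordered panel of core markers — by default 24 markers, two to
three high-PIC markers per chromosome. Identical strings are reported as
duplicate groups, never collapsed: a small panel may legitimately fail to
separate closely related accessions that the full marker set distinguishes.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "CoreMarkerPanel",
    "select_core_markers",
    "encode_fingerprint",
    "encode_all",
    "decode_fingerprint",
    "check_uniqueness",
    "hamming",
]


@dataclass(frozen=True)
class CoreMarkerPanel:
    """Ordered core marker panel; digit i of every fingerprint is marker i."""

    markers: tuple[str, ...]
    chromosomes: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.markers) != len(self.chromosomes):
            raise ValueError("markers and chromosomes must align")
        if len(set(self.markers)) != len(self.markers):
            raise ValueError("panel markers must be unique")

    def __len__(self) -> int:
        return len(self.markers)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "Order": range(1, len(self.markers) + 1),
                "Marker": self.markers,
                "Chromosome": self.chromosomes,
            }
        )


def select_core_markers(
    marker_summaries: pd.DataFrame,
    per_chrom_min: int = 2,
    per_chrom_max: int = 3,
    total: int = 24,
    strictly_biallelic: bool = False,
) -> CoreMarkerPanel:
    """Pick a high-PIC core panel with 2-3 markers per chromosome.

    ``marker_summaries`` needs columns Chromosome, Marker, AlleleNumber, PIC.
    Per chromosome, biallelic markers are ranked by PIC descending (ties by
    marker name) and ``per_chrom_min`` are taken; remaining slots up to
    ``total`` are filled by the next-best markers overall, never exceeding
    ``per_chrom_max`` per chromosome. When a chromosome has fewer than
    ``per_chrom_min`` biallelic markers, multi-allelic markers from that
    chromosome are used as fallback unless ``strictly_biallelic`` is set
    (shortfalls are logged either way). Output order is by chromosome, then
    PIC rank — fixed, and to be persisted with the fingerprints.
    """
    req = {"Chromosome", "Marker", "AlleleNumber", "PIC"}
    if not req <= set(marker_summaries.columns):
        raise ValueError(f"marker summaries need columns {sorted(req)}")

    def ranked(frame: pd.DataFrame) -> pd.DataFrame:
        return frame.sort_values(["PIC", "Marker"], ascending=[False, True],
                                 kind="stable")

    chosen: dict[str, list[tuple[str, float]]] = defaultdict(list)
    leftovers = []
    for chrom, grp in marker_summaries.groupby("Chromosome", sort=True):
        bi = ranked(grp[grp["AlleleNumber"] == 2])
        pool = [tuple(r) for r in bi[["Marker", "PIC"]].itertuples(index=False)]
        if len(pool) < per_chrom_min and not strictly_biallelic:
            multi = ranked(grp[grp["AlleleNumber"] != 2])
            extra = [tuple(r) for r in multi[["Marker", "PIC"]].itertuples(index=False)]
            logger.warning(
                "chromosome %s has %d biallelic markers (< %d); using "
                "%d multi-allelic fallback(s)",
                chrom, len(pool), per_chrom_min,
                min(len(extra), per_chrom_min - len(pool)),
            )
            pool = sorted(pool + extra, key=lambda t: (-t[1], t[0]))
        if len(pool) < per_chrom_min:
            logger.warning(
                "chromosome %s: only %d eligible markers (< %d)",
                chrom, len(pool), per_chrom_min,
            )
        take = min(per_chrom_min, len(pool))
        chosen[chrom] = pool[:take]
        leftovers.extend(
            (pic_val, marker, chrom) for marker, pic_val in pool[take:per_chrom_max]
        )

    n_chosen = sum(len(v) for v in chosen.values())
    leftovers.sort(key=lambda t: (-t[0], t[1]))
    for pic_val, marker, chrom in leftovers:
        if n_chosen >= total:
            break
        if len(chosen[chrom]) < per_chrom_max:
            chosen[chrom].append((marker, pic_val))
            n_chosen += 1
    if n_chosen < total:
        logger.warning("panel shortfall: %d of %d markers selected", n_chosen, total)

    markers, chroms = [], []
    for chrom in sorted(chosen):
        for marker, pic_val in sorted(
            chosen[chrom], key=lambda t: (-t[1], t[0])
        ):
            markers.append(marker)
            chroms.append(chrom)
    return CoreMarkerPanel(markers=tuple(markers), chromosomes=tuple(chroms))


def encode_fingerprint(row: pd.Series, panel: CoreMarkerPanel | list[str]) -> str:
    """Concatenate one accession's band codes in panel order (pure
    transcription). Raises KeyError naming any marker absent from the row."""
    markers = panel.markers if isinstance(panel, CoreMarkerPanel) else panel
    digits = []
    for marker in markers:
        if marker not in row.index:
            raise KeyError(f"marker {marker!r} missing from accession row")
        code = int(row[marker])
        if code not in (0, 1, 2, 3, 4):
            raise ValueError(f"invalid band code {code} at marker {marker}")
        digits.append(str(code))
    return "".join(digits)


def encode_all(matrix: pd.DataFrame, panel: CoreMarkerPanel | list[str]) -> pd.Series:
    """Fingerprints for every accession, indexed by accession id."""
    return pd.Series(
        {acc: encode_fingerprint(matrix.loc[acc], panel) for acc in matrix.index},
        name="Fingerprint",
    )[matrix.index]


def decode_fingerprint(code_string: str, panel: CoreMarkerPanel | list[str]) -> pd.Series:
    """Inverse of :func:`encode_fingerprint` on the panel support."""
    markers = panel.markers if isinstance(panel, CoreMarkerPanel) else list(panel)
    if len(code_string) != len(markers):
        raise ValueError("code string length does not match panel size")
    return pd.Series([int(c) for c in code_string], index=markers)


def check_uniqueness(fingerprints: pd.Series | dict[str, str]) -> list[list[str]]:
    """Group accessions sharing an identical code string.

    Returns the duplicate groups (each a list of accession ids, input order);
    an empty list means every fingerprint is unique. Raises on length
    mismatches.
    """
    items = (
        list(fingerprints.items())
        if isinstance(fingerprints, pd.Series)
        else list(fingerprints.items())
    )
    if items:
        length = len(items[0][1])
        for acc, code in items:
            if len(code) != length:
                raise ValueError(f"fingerprint length mismatch at {acc}")
    groups: dict[str, list[str]] = defaultdict(list)
    for acc, code in items:
        groups[code].append(str(acc))
    return [accs for accs in groups.values() if len(accs) > 1]


def hamming(fp_a: str, fp_b: str) -> int:
    """Number of differing digit positions between two equal-length codes."""
    if len(fp_a) != len(fp_b):
        raise ValueError("fingerprints must have equal length")
    return sum(a != b for a, b in zip(fp_a, fp_b))
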