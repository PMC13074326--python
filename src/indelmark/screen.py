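"""Stepwise InDel marker screening.

Stages, applied in fixed order (a locus failing an earlier stage is never
evaluated by a later one):

1. basic filtering — quality >= qual_min, length >= len_min, reference
   footprint outside annotated repeat regions;
2. flank single-copy check — every k-mer of each flank occurs exactly once
   in the whole reference, both strands (a conservative, alignment-free
   proxy for "non-repetitive, single-copy");
3. spacing thinning — greedy left-to-right removal of neighbours closer
   than min_spacing, for a uniform genome-wide marker distribution;
4. genic/intergenic balancing — optional proportional retention across
   region classes.

Wet-lab amplification screening cannot be computed; an externally supplied
pass/fail list can be merged by marker name instead
(:func:`apply_external_validation`).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import pandas as pd

from ._util import interval_trees
from .variants import IndelVariant

logger = logging.getLogger(__name__)

__all__ = [
    "ScreenConfig",
    "CandidateLocus",
    "KmerIndex",
    "filter_basic",
    "extract_flanks",
    "check_flank_uniqueness",
    "thin_by_spacing",
    "annotate_region_class",
    "balance_genic",
    "run_screen",
    "apply_external_validation",
    "candidates_to_frame",
]

STATUS_ORDER = (
    "pass",
    "fail_qual",
    "fail_length",
    "fail_repeat",
    "fail_flank_copy",
    "fail_spacing",
    "fail_balance",
)


@dataclass(frozen=True)
class ScreenConfig:
    """Thresholds for the stepwise screen.

    qual_min : minimum Phred-scaled variant quality (default 30)
    len_min : minimum InDel length in bp (default 6, gel-resolvable)
    flank_len : flank length in bp checked for single-copy context (default 200)
    min_spacing : minimum distance between retained neighbours in bp
        (default 100 kb)
    k_check : k-mer size for the flank single-copy check
    max_ambiguous_frac : maximum tolerated non-ACGT fraction per flank
    genic_ratio_mode : "observed" (keep the observed genic/intergenic mix)
        or "fixed" (retain a fixed genic proportion, see
        :func:`balance_genic`)
    """

    qual_min: float = 30.0
    len_min: int = 6
    flank_len: int = 200
    min_spacing: int = 100_000
    k_check: int = 31
    max_ambiguous_frac: float = 0.1
    genic_ratio_mode: str = "observed"

    def __post_init__(self) -> None:
        for name in ("qual_min", "len_min", "flank_len", "min_spacing", "k_check"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.genic_ratio_mode not in ("observed", "fixed"):
            raise ValueError("genic_ratio_mode must be 'observed' or 'fixed'")


@dataclass(frozen=True)
class CandidateLocus:
    """A variant moving through the screen, with its disposition."""

    variant: IndelVariant
    status: str = "pass"
    left_flank: str | None = None
    right_flank: str | None = None
    region_class: str | None = None  # "genic" | "intergenic"
    notes: tuple[str, ...] = field(default_factory=tuple)

    @property
    def passed(self) -> bool:
        return self.status == "pass"


def filter_basic(
    variants: list[IndelVariant],
    config: ScreenConfig,
    repeat_intervals: pd.DataFrame | None = None,
) -> list[CandidateLocus]:
    """Stage 1: quality, length and repeat-region filters.

    Each failure sets the first applicable flag in the order qual, length,
    repeat. ``repeat_intervals`` holds 1-based inclusive intervals
    (chrom/start/end); overlap is tested on the variant's reference footprint
    [pos, pos + len(ref) - 1]. A quality recorded as unknown (missing VCF
    QUAL) fails the quality criterion.
    """
    trees = interval_trees(repeat_intervals) if repeat_intervals is not None else {}
    variant_chroms = {v.chrom for v in variants}
    for chrom in trees:
        if chrom not in variant_chroms:
            logger.warning("repeat intervals on %s match no variants", chrom)

    out: list[CandidateLocus] = []
    for v in variants:
        if not v.qual_known or v.qual < config.qual_min:
            status = "fail_qual"
        elif v.indel_len < config.len_min:
            status = "fail_length"
        elif v.chrom in trees and trees[v.chrom].overlap(v.pos, v.ref_end + 1):
            status = "fail_repeat"
        else:
            status = "pass"
        out.append(CandidateLocus(variant=v, status=status))
    logger.info(
        "filter_basic: %d in, %d pass", len(out), sum(c.passed for c in out)
    )
    return out


def extract_flanks(
    variant: IndelVariant, reference: dict[str, str], flank_len: int
) -> tuple[str, str] | None:
    """Flanking sequences around the reference footprint, or None if the
    locus sits closer than flank_len to a chromosome end."""
    seq = reference[variant.chrom]
    left_start = variant.pos - 1 - flank_len  # 0-based
    right_end = variant.ref_end + flank_len  # 1-based inclusive
    if left_start < 0 or right_end > len(seq):
        return None
    left = seq[left_start : variant.pos - 1]
    right = seq[variant.ref_end : right_end]
    return left, right


def _revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGTN", "TGCAN"))[::-1]


class KmerIndex:
    """Canonical k-mer occurrence counts over a reference (both strands).

    For odd k (no palindromes) the canonical count of a k-mer equals its
    total number of occurrences on the two strands combined; a single-copy
    forward-strand k-mer therefore has count exactly 1.
    """

    def __init__(self, reference: dict[str, str], k: int = 31):
        if k % 2 == 0:
            raise ValueError("k must be odd to avoid palindromic ambiguity")
        self.k = k
        counts: dict[str, int] = {}
        for seq in reference.values():
            for i in range(len(seq) - k + 1):
                kmer = seq[i : i + k]
                if "N" in kmer:
                    continue
                canon = min(kmer, _revcomp(kmer))
                counts[canon] = counts.get(canon, 0) + 1
        self._counts = counts

    def count(self, kmer: str) -> int:
        if len(kmer) != self.k:
            raise ValueError(f"expected a {self.k}-mer")
        return self._counts.get(min(kmer, _revcomp(kmer)), 0)

    def sequence_is_single_copy(self, seq: str) -> bool:
        """True iff every ACGT k-mer of ``seq`` occurs exactly once genome-wide."""
        for i in range(len(seq) - self.k + 1):
            kmer = seq[i : i + self.k]
            if set(kmer) - set("ACGT"):
                continue
            if self.count(kmer) != 1:
                return False
        return True


def check_flank_uniqueness(
    candidate: CandidateLocus,
    reference: dict[str, str],
    config: ScreenConfig,
    index: KmerIndex | None = None,
) -> CandidateLocus:
    """Stage 2: both flanks must lie in single-copy sequence.

    Fails when flanks cannot be extracted (locus too close to a chromosome
    end), when a flank's non-ACGT fraction exceeds
    ``config.max_ambiguous_frac``, or when any flank k-mer occurs more than
    once in the reference (both strands).
    """
    if not candidate.passed:
        return candidate
    flanks = extract_flanks(candidate.variant, reference, config.flank_len)
    if flanks is None:
        return replace(
            candidate, status="fail_flank_copy", notes=("insufficient flank",)
        )
    left, right = flanks
    index = index or KmerIndex(reference, config.k_check)
    for name, flank in (("left", left), ("right", right)):
        ambiguous = sum(1 for b in flank if b not in "ACGT") / len(flank)
        if ambiguous > config.max_ambiguous_frac:
            return replace(
                candidate,
                status="fail_flank_copy",
                left_flank=left,
                right_flank=right,
                notes=(f"{name} flank ambiguous fraction {ambiguous:.2f}",),
            )
        if not index.sequence_is_single_copy(flank):
            return replace(
                candidate,
                status="fail_flank_copy",
                left_flank=left,
                right_flank=right,
                notes=(f"{name} flank not single-copy",),
            )
    return replace(candidate, left_flank=left, right_flank=right)


def thin_by_spacing(
    candidates: list[CandidateLocus], min_spacing: int
) -> list[CandidateLocus]:
    """Stage 3: greedy left-to-right spacing thinning.

    Within each chromosome (candidates ordered by position), the first
    passing locus is kept and each next passing locus is kept only if it lies
    at least ``min_spacing`` bp from the last kept one; a gap of exactly
    ``min_spacing`` is kept. Deterministic. Non-passing candidates are
    carried through unchanged.
    """
    ordered = sorted(
        range(len(candidates)),
        key=lambda i: (candidates[i].variant.chrom, candidates[i].variant.pos),
    )
    out = list(candidates)
    last_kept: dict[str, int] = {}
    for i in ordered:
        cand = candidates[i]
        if not cand.passed:
            continue
        chrom, pos = cand.variant.chrom, cand.variant.pos
        if chrom in last_kept and pos - last_kept[chrom] < min_spacing:
            out[i] = replace(cand, status="fail_spacing")
        else:
            last_kept[chrom] = pos
    logger.info(
        "thin_by_spacing: %d pass in, %d pass out",
        sum(c.passed for c in candidates), sum(c.passed for c in out),
    )
    return out


def annotate_region_class(
    candidates: list[CandidateLocus], gene_intervals: pd.DataFrame
) -> list[CandidateLocus]:
    """Label each candidate genic/intergenic by footprint overlap with genes."""
    trees = interval_trees(gene_intervals)
    out = []
    for c in candidates:
        v = c.variant
        genic = v.chrom in trees and bool(trees[v.chrom].overlap(v.pos, v.ref_end + 1))
        out.append(replace(c, region_class="genic" if genic else "intergenic"))
    return out


def balance_genic(
    candidates: list[CandidateLocus],
    target: str | tuple[float, int] = "observed",
) -> list[CandidateLocus]:
    """Stage 4: proportional retention across genic/intergenic classes.

    ``target="observed"`` is a pass-through (the observed mix is already the
    proportion). ``target=(r, n)`` retains round(n*r) genic and n - round(n*r)
    intergenic passing loci, chosen by descending quality with (chrom, pos)
    as tie-break. If a class has fewer passing loci than requested, all of
    them are taken and the shortfall is logged. Candidates must already carry
    a region_class (see :func:`annotate_region_class`).
    """
    if target == "observed":
        return list(candidates)
    r, n = target
    if not 0 <= r <= 1 or n < 0:
        raise ValueError("need 0 <= r <= 1 and n >= 0")
    want = {"genic": round(n * r)}
    want["intergenic"] = n - want["genic"]
    if any(c.region_class is None for c in candidates if c.passed):
        raise ValueError("candidates lack region_class annotation")

    keep: set[int] = set()
    for cls, quota in want.items():
        idx = [
            i for i, c in enumerate(candidates)
            if c.passed and c.region_class == cls
        ]
        idx.sort(
            key=lambda i: (
                -candidates[i].variant.qual,
                candidates[i].variant.chrom,
                candidates[i].variant.pos,
            )
        )
        if len(idx) < quota:
            logger.warning(
                "balance_genic: requested %d %s loci, only %d available",
                quota, cls, len(idx),
            )
        keep.update(idx[:quota])

    out = []
    for i, c in enumerate(candidates):
        if c.passed and i not in keep:
            out.append(replace(c, status="fail_balance"))
        else:
            out.append(c)
    return out


def run_screen(
    variants: list[IndelVariant],
    reference: dict[str, str],
    repeat_intervals: pd.DataFrame | None,
    gene_intervals: pd.DataFrame | None,
    config: ScreenConfig = ScreenConfig(),
    balance_target: str | tuple[float, int] = "observed",
) -> list[CandidateLocus]:
    """Run the full screen in stage order and return all candidates with
    their terminal dispositions."""
    cands = filter_basic(variants, config, repeat_intervals)
    index = KmerIndex(reference, config.k_check)
    cands = [check_flank_uniqueness(c, reference, config, index) for c in cands]
    cands = thin_by_spacing(cands, config.min_spacing)
    if gene_intervals is not None:
        cands = annotate_region_class(cands, gene_intervals)
        if config.genic_ratio_mode == "fixed" or balance_target != "observed":
            cands = balance_genic(cands, balance_target)
    logger.info(
        "run_screen: %d variants in, %d retained",
        len(variants), sum(c.passed for c in cands),
    )
    return cands


def apply_external_validation(
    candidates: dict[str, CandidateLocus] | pd.DataFrame,
    validation: pd.DataFrame,
) -> pd.DataFrame:
    """Merge an externally supplied wet-lab pass/fail list by marker name.

    ``validation`` needs columns ``marker`` and ``validated`` (boolean).
    Returns the candidate frame with a ``validated`` column (NA where the
    marker was not tested).
    """
    frame = (
        candidates if isinstance(candidates, pd.DataFrame)
        else candidates_to_frame(list(candidates.values()))
    )
    return frame.merge(validation[["marker", "validated"]], on="marker", how="left")


def candidates_to_frame(candidates: list[CandidateLocus]) -> pd.DataFrame:
    """Tabular view: chrom, pos, type, len, qual, region_class, status."""
    return pd.DataFrame(
        {
            "chrom": [c.variant.chrom for c in candidates],
            "pos": [c.variant.pos for c in candidates],
            "type": [c.variant.indel_type for c in candidates],
            "len": [c.variant.indel_len for c in candidates],
            "qual": [c.variant.qual for c in candidates],
            "region_class": [c.region_class for c in candidates],
            "status": [c.status for c in candidates],
        }
    )
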