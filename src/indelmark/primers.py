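"""PCR primer design for InDel markers.

Templates are the 250 bp flanks around each InDel plus the reference allele.
A primer pair qualifies when both primers satisfy length, melting-temperature
and GC windows, the amplicon spans the InDel with a reference-allele product
size inside the product window, and no dimer or hairpin structure exceeds the
configured stem lengths. Among qualifying pairs the one minimising
|Tm_f - Tm_r|, then product size, then forward start position, is returned —
design is fully deterministic.

Markers are named ``<chromosome token>M<4-digit position token>`` where the
token for chromosomes 1-9 is T1..T9 and for 10-12 is Ta/Tb/Tc, and the
position token is floor(pos / 10 kb) zero-padded to 4 digits.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio.SeqUtils import MeltingTemp as _mt

from .variants import IndelVariant

__all__ = [
    "PrimerConfig",
    "PrimerPair",
    "extract_design_template",
    "gc_content",
    "melting_temp",
    "dimer_hairpin_check",
    "design_primer_pair",
    "name_marker",
]

_CHROM_TOKENS = ["T1", "T2", "T3", "T4", "T5", "T6", "T7", "T8", "T9", "Ta", "Tb", "Tc"]


@dataclass(frozen=True)
class PrimerConfig:
    """Primer design constraints.

    Defaults follow common practice for gel-resolved InDel markers: primer
    length 21-30 bp, Tm 57-62 degC, GC 40-70 %, product 70-150 bp on the
    reference allele. Structure thresholds (longest tolerated complementary
    run, hairpin stem, 3'-end complement window) are package defaults.
    """

    len_range: tuple[int, int] = (21, 30)
    tm_range: tuple[float, float] = (57.0, 62.0)
    gc_range: tuple[float, float] = (40.0, 70.0)
    product_range: tuple[int, int] = (70, 150)
    max_dimer_run: int = 6
    max_hairpin_stem: int = 5
    three_prime_window: int = 5
    tm_method: str = "nearest_neighbor"  # or "wallace"
    salt_molar: float = 0.05
    primer_molar: float = 250e-9

    def __post_init__(self) -> None:
        for lo, hi in (self.len_range, self.tm_range, self.gc_range, self.product_range):
            if lo > hi:
                raise ValueError("empty constraint range")
        if self.tm_method not in ("nearest_neighbor", "wallace"):
            raise ValueError("tm_method must be 'nearest_neighbor' or 'wallace'")


@dataclass(frozen=True)
class PrimerPair:
    """A designed primer pair (both sequences written 5'->3')."""

    forward_seq: str
    reverse_seq: str
    tm_f: float
    tm_r: float
    gc_f: float
    gc_r: float
    product_size_ref: int
    product_size_alt: int
    forward_start: int  # 0-based position on the design template

    def validates(self, config: PrimerConfig, indel_len: int | None = None) -> bool:
        """Re-check every individual constraint on this pair."""
        lo, hi = config.len_range
        for seq, tm, gc in (
            (self.forward_seq, self.tm_f, self.gc_f),
            (self.reverse_seq, self.tm_r, self.gc_r),
        ):
            if not lo <= len(seq) <= hi:
                return False
            if not config.tm_range[0] <= tm <= config.tm_range[1]:
                return False
            if not config.gc_range[0] <= gc <= config.gc_range[1]:
                return False
        if not config.product_range[0] <= self.product_size_ref <= config.product_range[1]:
            return False
        if indel_len is not None and abs(
            self.product_size_alt - self.product_size_ref
        ) != indel_len:
            return False
        ok_pair, _ = dimer_hairpin_check(self.forward_seq, self.reverse_seq, config)
        return ok_pair


def _revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGT", "TGCA"))[::-1]


def extract_design_template(
    variant: IndelVariant, reference: dict[str, str], flank: int = 250
) -> tuple[str, int]:
    """Design template = left flank + reference allele + right flank.

    Returns the template and the 0-based offset of the reference allele
    within it (equal to ``flank``). Raises ValueError when a flank would run
    past a chromosome end, naming the locus.
    """
    seq = reference[variant.chrom]
    left_start = variant.pos - 1 - flank
    right_end = variant.ref_end + flank
    if left_start < 0 or right_end > len(seq):
        raise ValueError(
            f"insufficient flank for locus {variant.chrom}:{variant.pos} "
            f"(need {flank} bp each side)"
        )
    template = seq[left_start:right_end]
    return template, flank


def gc_content(seq: str) -> float:
    """GC percentage of an ACGT sequence."""
    if not seq:
        raise ValueError("empty sequence")
    if set(seq) - set("ACGT"):
        raise ValueError(f"ambiguous bases in sequence: {seq!r}")
    return 100.0 * (seq.count("G") + seq.count("C")) / len(seq)


def melting_temp(
    seq: str,
    method: str = "nearest_neighbor",
    salt_molar: float = 0.05,
    primer_molar: float = 250e-9,
) -> float:
    """Primer melting temperature in degC.

    ``nearest_neighbor`` uses the unified nearest-neighbor thermodynamic
    parameter set with the entropy-based monovalent-salt correction at the
    given salt and primer concentrations (sequence length 10-40 bp).
    ``wallace`` is the 2(A+T) + 4(G+C) rule-of-thumb cross-check.
    """
    if set(seq) - set("ACGT"):
        raise ValueError(f"ambiguous bases in sequence: {seq!r}")
    if method == "wallace":
        return float(_mt.Tm_Wallace(seq))
    if method == "nearest_neighbor":
        if not 10 <= len(seq) <= 40:
            raise ValueError("nearest-neighbor Tm defined for 10-40 bp here")
        return float(
            _mt.Tm_NN(
                seq,
                nn_table=_mt.DNA_NN3,
                Na=salt_molar * 1000.0,
                dnac1=primer_molar * 1e9,
                dnac2=0,
                saltcorr=5,
            )
        )
    raise ValueError(f"unknown Tm method {method!r}")


def _longest_complementary_run(seq_a: str, seq_b: str) -> int:
    """Longest perfect Watson-Crick run when a and b anneal antiparallel,
    i.e. the longest common substring of a and revcomp(b)."""
    b = _revcomp(seq_b)
    best = 0
    prev = [0] * (len(b) + 1)
    for ca in seq_a:
        cur = [0] * (len(b) + 1)
        for j, cb in enumerate(b, start=1):
            if ca == cb:
                cur[j] = prev[j - 1] + 1
                if cur[j] > best:
                    best = cur[j]
        prev = cur
    return best


def _has_hairpin(seq: str, min_stem: int, min_loop: int = 3) -> bool:
    """Self-fold scan: any stem of min_stem bases pairing with a downstream
    reverse-complement separated by a loop of >= min_loop bases."""
    n = len(seq)
    for i in range(n - 2 * min_stem - min_loop + 1):
        stem = seq[i : i + min_stem]
        target = _revcomp(stem)
        j = seq.find(target, i + min_stem + min_loop)
        if j != -1:
            return True
    return False


def dimer_hairpin_check(
    seq_a: str, seq_b: str | None = None, config: PrimerConfig = PrimerConfig()
) -> tuple[bool, str]:
    """Screen a primer (or a pair) for dimers and hairpins.

    Fails when (a) the longest perfect complementary run between the two
    sequences reaches ``max_dimer_run``, (b) the 3'-terminal bases of either
    primer perfectly complement any window of the other (primer-extension
    prone), or (c) either sequence can fold back on itself with a stem of
    ``max_hairpin_stem`` and a loop of >= 3 bases. Returns (ok, diagnostic).
    """
    seqs = (seq_a,) if seq_b is None or seq_b == seq_a else (seq_a, seq_b)
    other = seq_b if seq_b is not None else seq_a

    if _longest_complementary_run(seq_a, other) >= config.max_dimer_run:
        return False, "dimer: complementary run >= max_dimer_run"
    w = config.three_prime_window
    for first, second in ((seq_a, other), (other, seq_a)):
        if len(first) >= w and _revcomp(first[-w:]) in second:
            return False, "dimer: 3'-end complementary to partner"
    for seq in seqs:
        if _has_hairpin(seq, config.max_hairpin_stem):
            return False, "hairpin: self-fold stem >= max_hairpin_stem"
    return True, "ok"


def _candidate_primers(
    template: str, start_lo: int, start_hi: int, end_cap: int, config: PrimerConfig,
    reverse: bool,
) -> list[tuple[int, int, str, float, float]]:
    """Enumerate individually valid primers as (start, end_excl, seq, tm, gc)."""
    out = []
    lmin, lmax = config.len_range
    for start in range(start_lo, start_hi + 1):
        for length in range(lmin, lmax + 1):
            end = start + length
            if end > end_cap:
                break
            window = template[start:end]
            if set(window) - set("ACGT"):
                continue
            seq = _revcomp(window) if reverse else window
            gc = gc_content(seq)
            if not config.gc_range[0] <= gc <= config.gc_range[1]:
                continue
            tm = melting_temp(seq, config.tm_method, config.salt_molar,
                              config.primer_molar)
            if not config.tm_range[0] <= tm <= config.tm_range[1]:
                continue
            ok, _ = dimer_hairpin_check(seq, None, config)
            if not ok:
                continue
            out.append((start, end, seq, tm, gc))
    return out


def design_primer_pair(
    template: str,
    offset: int,
    ref_allele_len: int,
    indel_signed_change: int,
    config: PrimerConfig = PrimerConfig(),
) -> PrimerPair | None:
    """Exhaustively search the template for the best qualifying primer pair.

    The forward primer must end at or before the InDel footprint
    (template[offset : offset + ref_allele_len]) and the reverse primer must
    start after it, so the amplicon always spans the InDel.
    ``indel_signed_change`` is len(alt) - len(ref), giving
    product_size_alt = product_size_ref + change. Returns None when no pair
    satisfies every constraint.
    """
    forwards = _candidate_primers(
        template, 0, offset - config.len_range[0], offset, config, reverse=False
    )
    indel_end = offset + ref_allele_len
    reverses = _candidate_primers(
        template, indel_end, len(template) - config.len_range[0], len(template),
        config, reverse=True,
    )
    if not forwards or not reverses:
        return None

    pmin, pmax = config.product_range
    candidates = []
    for f_start, f_end, f_seq, f_tm, f_gc in forwards:
        for r_start, r_end, r_seq, r_tm, r_gc in reverses:
            product = r_end - f_start
            if product < pmin or product > pmax:
                continue
            candidates.append(
                (abs(f_tm - r_tm), product, f_start,
                 (f_seq, r_seq, f_tm, r_tm, f_gc, r_gc))
            )
    candidates.sort(key=lambda t: t[:3])
    for dtm, product, f_start, (f_seq, r_seq, f_tm, r_tm, f_gc, r_gc) in candidates:
        ok, _ = dimer_hairpin_check(f_seq, r_seq, config)
        if not ok:
            continue
        return PrimerPair(
            forward_seq=f_seq,
            reverse_seq=r_seq,
            tm_f=f_tm,
            tm_r=r_tm,
            gc_f=f_gc,
            gc_r=r_gc,
            product_size_ref=product,
            product_size_alt=product + indel_signed_change,
            forward_start=f_start,
        )
    return None


def name_marker(chrom_index: int, pos: int) -> str:
    """Marker name: chromosome token + 'M' + floor(pos / 10 kb) as 4 digits.

    Chromosomes 1-9 map to T1..T9 and 10-12 to Ta/Tb/Tc; e.g. chromosome 10,
    position 6,412,345 -> "TaM0641".
    """
    if not 1 <= chrom_index <= 12:
        raise ValueError(f"chrom_index must be in 1..12, got {chrom_index}")
    if pos < 0:
        raise ValueError("pos must be non-negative")
    token = pos // 10_000
    if token > 9999:
        raise ValueError(f"position {pos} exceeds the 4-digit naming range")
    return f"{_CHROM_TOKENS[chrom_index - 1]}M{token:04d}"
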