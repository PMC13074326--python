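"""Synthetic inputs with known ground truth.

Three generators cover everything the pipeline consumes:

* :func:`simulate_reference` — random chromosomes at a target GC content,
  with repeat regions realised as exact duplicated substrings (so
  flank-uniqueness checks genuinely fail inside them) and non-overlapping
  gene intervals;
* :func:`implant_indels` — InDels placed on the reference with recorded
  truth (position, type, length, quality, repeat/genic context) and emitted
  as reference-consistent VCF records;
* :func:`simulate_population` — band-code genotype matrices from K
  subpopulations under the Balding-Nichols F-model (per marker an ancestral
  frequency p ~ U(0.1, 0.9) and subpopulation frequencies
  Beta(p (1-F)/F, (1-p) (1-F)/F)), with tunable heterozygosity, a
  third-allele rate and missingness.

All generators are pure functions of their configuration and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .variants import IndelVariant

__all__ = [
    "SimGenomeConfig",
    "SimPopulationConfig",
    "SimPopulation",
    "simulate_reference",
    "implant_indels",
    "simulate_population",
]

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class SimGenomeConfig:
    """Reference genome simulation settings.

    Fractions are of each chromosome's length; repeat and gene fractions must
    sum to at most 1 (gene intervals may still overlap repeats — the two are
    independent annotations, as in real genomes).
    """

    n_chrom: int = 2
    chrom_length: int = 500_000
    repeat_fraction: float = 0.05
    gene_fraction: float = 0.3
    gc_content: float = 0.36
    repeat_unit_len: int = 300
    gene_len: int = 2_000
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.repeat_fraction <= 1 and 0 <= self.gene_fraction <= 1):
            raise ValueError("fractions must lie in [0, 1]")
        if self.repeat_fraction + self.gene_fraction > 1:
            raise ValueError("repeat and gene fractions must sum to <= 1")
        if not 0 < self.gc_content < 1:
            raise ValueError("gc_content must lie in (0, 1)")


def _random_sequence(rng: np.random.Generator, length: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(_BASES, size=length, p=p)


def _place_intervals(
    rng: np.random.Generator, length: int, n: int, width: int, occupied: list[tuple[int, int]]
) -> list[tuple[int, int]]:
    """Sample n non-overlapping (1-based inclusive) intervals of given width,
    also avoiding ``occupied``. Rejection sampling; raises if infeasible."""
    placed: list[tuple[int, int]] = []
    blocked = list(occupied)
    tries = 0
    while len(placed) < n:
        tries += 1
        if tries > 200 * max(n, 1):
            raise ValueError("could not place intervals; fractions infeasible")
        start = int(rng.integers(1, length - width + 1))
        end = start + width - 1
        if any(s <= end and start <= e for s, e in blocked):
            continue
        placed.append((start, end))
        blocked.append((start, end))
    return sorted(placed)


def simulate_reference(
    config: SimGenomeConfig,
) -> tuple[dict[str, str], pd.DataFrame, pd.DataFrame]:
    """Generate chromosomes plus repeat and gene annotations.

    Returns (sequences, repeat intervals, gene intervals); interval frames
    have 1-based inclusive chrom/start/end columns. Each chromosome's repeat
    budget is realised by pasting one repeat unit at two or more locations,
    so every repeat k-mer occurs multiply in the genome.
    """
    rng = np.random.default_rng(config.seed)
    seqs: dict[str, str] = {}
    repeat_rows, gene_rows = [], []
    for c in range(1, config.n_chrom + 1):
        chrom = f"chr{c:02d}"
        arr = _random_sequence(rng, config.chrom_length, config.gc_content)
        n_rep = 0
        if config.repeat_fraction > 0:
            n_rep = max(2, round(config.repeat_fraction * config.chrom_length
                                 / config.repeat_unit_len))
        rep_iv = _place_intervals(rng, config.chrom_length, n_rep,
                                  config.repeat_unit_len, [])
        if rep_iv:
            unit = _random_sequence(rng, config.repeat_unit_len, config.gc_content)
            for start, end in rep_iv:
                arr[start - 1 : end] = unit
                repeat_rows.append((chrom, start, end))
        n_gene = round(config.gene_fraction * config.chrom_length / config.gene_len)
        gene_iv = _place_intervals(rng, config.chrom_length, n_gene,
                                   config.gene_len, rep_iv)
        gene_rows.extend((chrom, s, e) for s, e in gene_iv)
        seqs[chrom] = "".join(arr)
    cols = ["chrom", "start", "end"]
    return (
        seqs,
        pd.DataFrame(repeat_rows, columns=cols),
        pd.DataFrame(gene_rows, columns=cols),
    )


def implant_indels(
    reference: dict[str, str],
    n: int,
    length_range: tuple[int, int] = (1, 15),
    qual_range: tuple[float, float] = (10.0, 60.0),
    seed: int = 0,
    min_gap: int = 100,
    repeat_intervals: pd.DataFrame | None = None,
    gene_intervals: pd.DataFrame | None = None,
) -> tuple[list[IndelVariant], pd.DataFrame]:
    """Place n InDels uniformly on the reference with recorded ground truth.

    Insertions and deletions are drawn with equal probability, lengths and
    qualities uniformly from their ranges. VCF-style alleles are anchored on
    the reference base before the event, so REF always matches the reference
    substring at POS. Positions on one chromosome are at least ``min_gap``
    apart. The truth table carries per-locus columns chrom, pos, type,
    length, qual, in_repeat, genic. Raises when n InDels cannot be placed.
    """
    rng = np.random.default_rng(seed)
    chroms = sorted(reference)
    lengths = {c: len(reference[c]) for c in chroms}
    total = sum(lengths.values())
    quota = {c: round(n * lengths[c] / total) for c in chroms}
    # fix rounding drift deterministically on the largest chromosome
    drift = n - sum(quota.values())
    quota[max(chroms, key=lambda c: lengths[c])] += drift

    def overlaps(iv: pd.DataFrame | None, chrom: str, start: int, end: int) -> bool:
        if iv is None or iv.empty:
            return False
        sub = iv[iv["chrom"] == chrom]
        return bool(((sub["start"] <= end) & (sub["end"] >= start)).any())

    variants: list[IndelVariant] = []
    rows = []
    lmin, lmax = length_range
    for chrom in chroms:
        seq = reference[chrom]
        margin = lmax + 2
        placed: list[int] = []
        tries = 0
        while len(placed) < quota[chrom]:
            tries += 1
            if tries > 500 * max(quota[chrom], 1):
                raise ValueError(f"cannot place {quota[chrom]} InDels on {chrom}")
            pos = int(rng.integers(margin, lengths[chrom] - margin))
            if any(abs(pos - p) < min_gap for p in placed):
                continue
            placed.append(pos)
        for pos in sorted(placed):
            indel_len = int(rng.integers(lmin, lmax + 1))
            qual = float(np.round(rng.uniform(*qual_range), 1))
            is_ins = bool(rng.integers(0, 2))
            anchor = seq[pos - 1]
            if is_ins:
                ref_allele = anchor
                alt_allele = anchor + "".join(
                    rng.choice(_BASES, size=indel_len)
                )
            else:
                ref_allele = seq[pos - 1 : pos + indel_len]
                alt_allele = anchor
            v = IndelVariant(
                chrom=chrom, pos=pos, ref_allele=ref_allele,
                alt_allele=alt_allele, qual=qual,
                indel_type="insertion" if is_ins else "deletion",
                indel_len=indel_len,
            )
            variants.append(v)
            rows.append(
                (
                    chrom, pos, v.indel_type, indel_len, qual,
                    overlaps(repeat_intervals, chrom, pos, v.ref_end),
                    overlaps(gene_intervals, chrom, pos, v.ref_end),
                )
            )
    truth = pd.DataFrame(
        rows,
        columns=["chrom", "pos", "type", "length", "qual", "in_repeat", "genic"],
    )
    return variants, truth


@dataclass(frozen=True)
class SimPopulationConfig:
    """Structured-population genotype simulation settings.

    Defaults mirror the tomato study panel: 52 accessions genotyped at 63
    markers across 12 chromosomes, four subpopulations, and mostly inbred
    material (het_rate scales Hardy-Weinberg heterozygosity; 1 = random
    mating, 0 = fully inbred). ``fst`` is the Balding-Nichols differentiation
    coefficient; third_allele_rate is the fraction of markers segregating a
    second, length-distinct InDel allele (band code 4); missing_rate is the
    per-cell no-band probability.
    """

    n_accessions: int = 52
    K_true: int = 4
    fst: float = 0.3
    n_markers: int = 63
    n_chromosomes: int = 12
    het_rate: float = 0.2
    third_allele_rate: float = 0.05
    missing_rate: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("fst", "het_rate", "third_allele_rate", "missing_rate"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.K_true < 1 or self.n_accessions < 1 or self.n_markers < 1:
            raise ValueError("K_true, n_accessions and n_markers must be >= 1")


@dataclass(frozen=True)
class SimPopulation:
    """A simulated accession panel with its ground truth."""

    matrix: pd.DataFrame                 # accessions x markers, band codes
    memberships: np.ndarray              # true subpopulation per accession
    pop_freqs: np.ndarray                # K x markers alternate-allele freqs
    ancestral_freqs: np.ndarray          # markers
    marker_chromosomes: pd.Series = field(repr=False)  # marker -> chromosome


def simulate_population(config: SimPopulationConfig) -> SimPopulation:
    """Draw a band-code genotype matrix from the Balding-Nichols F-model.

    Diploid genotypes per accession come from its subpopulation's allele
    frequency with heterozygosity scaled by ``het_rate`` (allele frequencies
    preserved); genotypes are rendered to band codes (hom-ref 1, het 3,
    hom-alt 2), a ``third_allele_rate`` fraction of markers re-renders half
    of its hom-alt accessions as the second InDel allele (code 4), and
    ``missing_rate`` cells are blanked to 0.
    """
    rng = np.random.default_rng(config.seed)
    n, m, K, F = (config.n_accessions, config.n_markers, config.K_true, config.fst)

    ancestral = rng.uniform(0.1, 0.9, size=m)
    if F > 0:
        a = ancestral * (1 - F) / F
        b = (1 - ancestral) * (1 - F) / F
        pop_freqs = rng.beta(a, b, size=(K, m))
    else:
        pop_freqs = np.tile(ancestral, (K, 1))

    # contiguous, near-equal subpopulation blocks
    memberships = np.repeat(np.arange(K), np.diff(np.linspace(0, n, K + 1).astype(int)))

    p = pop_freqs[memberships, :]  # n x m
    h = config.het_rate
    p_het = 2 * p * (1 - p) * h
    p_hom_alt = p**2 + p * (1 - p) * (1 - h)
    u = rng.uniform(size=(n, m))
    genotype = np.where(u < p_hom_alt, 2, np.where(u < p_hom_alt + p_het, 1, 0))

    codes = np.where(genotype == 2, 2, np.where(genotype == 1, 3, 1))
    third_markers = rng.uniform(size=m) < config.third_allele_rate
    flip = (codes == 2) & third_markers[None, :] & (rng.uniform(size=(n, m)) < 0.5)
    codes = np.where(flip, 4, codes)
    codes = np.where(rng.uniform(size=(n, m)) < config.missing_rate, 0, codes)

    accessions = [f"A{i + 1:02d}" for i in range(n)]
    chrom_of = [f"Ch{(j % config.n_chromosomes) + 1:02d}" for j in range(m)]
    markers = [f"M{j + 1:03d}" for j in range(m)]
    matrix = pd.DataFrame(codes, index=accessions, columns=markers, dtype=int)
    return SimPopulation(
        matrix=matrix,
        memberships=memberships,
        pop_freqs=pop_freqs,
        ancestral_freqs=ancestral,
        marker_chromosomes=pd.Series(chrom_of, index=markers, name="Chromosome"),
    )
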