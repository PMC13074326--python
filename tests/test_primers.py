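"""Primer constraints, melting temperature, structure checks and naming."""

import math

import numpy as np
import pytest

from indelmark.primers import (
    PrimerConfig,
    design_primer_pair,
    dimer_hairpin_check,
    extract_design_template,
    gc_content,
    melting_temp,
    name_marker,
)
from indelmark.variants import IndelVariant

# published unified nearest-neighbor thermodynamics (kcal/mol, cal/mol/K),
# written out independently as the test oracle
_NN = {
    "AA": (-7.9, -22.2), "AT": (-7.2, -20.4), "TA": (-7.2, -21.3),
    "CA": (-8.5, -22.7), "GT": (-8.4, -22.4), "CT": (-7.8, -21.0),
    "GA": (-8.2, -22.2), "CG": (-10.6, -27.2), "GC": (-9.8, -24.4),
    "GG": (-8.0, -19.9),
}
_COMP = str.maketrans("ACGT", "TGCA")


def _oracle_tm_nn(seq, na=0.05, ct=250e-9):
    """Direct evaluation of the unified NN model with the entropy salt
    correction, independent of the implementation under test."""
    dh, ds = 0.0, 0.0
    for a, b in zip(seq, seq[1:]):
        pair = a + b
        if pair not in _NN:  # use the complementary strand's parameters
            pair = (a + b).translate(_COMP)[::-1]
        dh += _NN[pair][0]
        ds += _NN[pair][1]
    for terminal in (seq[0], seq[-1]):
        if terminal in "GC":
            dh += 0.1
            ds += -2.8
        else:
            dh += 2.3
            ds += 4.1
    ds += 0.368 * (len(seq) - 1) * math.log(na)
    return 1000.0 * dh / (ds + 1.987 * math.log(ct)) - 273.15


@pytest.mark.parametrize(
    "seq,expected", [("ATGC", 50.0), ("GGCC", 100.0), ("ATAT", 0.0)]
)
def test_gc_content(seq, expected):
    assert gc_content(seq) == expected


def test_gc_content_rejects_ambiguous():
    with pytest.raises(ValueError):
        gc_content("ATGN")


def test_wallace_rule():
    assert melting_temp("AT" * 5 + "GC" * 5, "wallace") == 60.0
    assert melting_temp("A" * 20, "wallace") == 40.0


def test_wallace_monotone_in_gc_at_fixed_length():
    tms = [
        melting_temp("G" * k + "A" * (20 - k), "wallace") for k in range(21)
    ]
    assert all(b >= a for a, b in zip(tms, tms[1:]))


@pytest.mark.parametrize(
    "seq",
    ["TGGATAACCGGATGCCATTTG", "ACGTACGTACGTACGTACGTA", "CCCTAAGTTAGGATCAGGAAATG"],
)
def test_nearest_neighbor_tm_matches_independent_oracle(seq):
    got = melting_temp(seq, "nearest_neighbor")
    assert got == pytest.approx(_oracle_tm_nn(seq), abs=0.05)


def test_nn_tm_length_bounds():
    with pytest.raises(ValueError):
        melting_temp("ACGTACGT", "nearest_neighbor")  # 8-mer too short


def test_dimer_detection():
    seq = "ATGCCGTAAGGCTTACCAGTTAG"
    rc = seq.translate(_COMP)[::-1]
    ok, why = dimer_hairpin_check(seq, rc)
    assert not ok and "dimer" in why


def test_non_complementary_pair_forms_no_cross_dimer():
    """AT- and GC-repeats share no Watson-Crick alignment at all (brute
    force over every window), so any failure must come from self-folding,
    never from the cross-dimer clauses."""
    from indelmark.primers import _longest_complementary_run

    config = PrimerConfig(max_dimer_run=5, three_prime_window=5)
    a, b = "ATATATATATATATATATATA", "GCGCGCGCGCGCGCGCGCGCG"
    rc_b = b.translate(_COMP)[::-1]
    brute = max(
        (n for i in range(len(a)) for j in range(len(rc_b))
         for n in [next((k for k in range(min(len(a) - i, len(rc_b) - j))
                         if a[i + k] != rc_b[j + k]),
                        min(len(a) - i, len(rc_b) - j))]),
        default=0,
    )
    assert brute == 0
    assert _longest_complementary_run(a, b) == brute
    ok, why = dimer_hairpin_check(a, b, config)
    assert not ok and why.startswith("hairpin")

    # a genuinely structure-free pair passes the full check
    ok, why = dimer_hairpin_check(
        "AGGATCTCAGATTCAGGTACA", "TGACTTGGATCACTGATTCCA", config
    )
    assert ok, why


def test_hairpin_detection():
    stem = "GGGGG"
    hairpin = "TTAAT" + stem + "AAA" + "CCCCC" + "TAATT"
    ok, why = dimer_hairpin_check(
        hairpin, None, PrimerConfig(max_hairpin_stem=5)
    )
    assert not ok and "hairpin" in why


def _reference_with_indel(rng, pos=300, chrom_len=1000, ref_len=7):
    seq = "".join(rng.choice(list("ACGT"), size=chrom_len))
    ref_allele = seq[pos - 1 : pos - 1 + ref_len]
    return {"chr01": seq}, IndelVariant(
        "chr01", pos, ref_allele, ref_allele[0], 50.0, "deletion", ref_len - 1
    )


def test_template_extraction_layout():
    rng = np.random.default_rng(1)
    reference, variant = _reference_with_indel(rng)
    template, offset = extract_design_template(variant, reference, flank=250)
    assert offset == 250
    assert len(template) == 250 + len(variant.ref_allele) + 250
    assert template[offset : offset + len(variant.ref_allele)] == variant.ref_allele


def test_template_extraction_requires_flank():
    rng = np.random.default_rng(1)
    reference, _ = _reference_with_indel(rng)
    near_start = IndelVariant("chr01", 100, reference["chr01"][99],
                              reference["chr01"][99] + "TTTTTT", 50.0, "insertion", 6)
    with pytest.raises(ValueError, match="chr01:100"):
        extract_design_template(near_start, reference, flank=250)


def test_design_recovers_and_revalidates(toy_genome):
    """A returned pair re-validates against every constraint; amplicon
    arithmetic is conserved; design is deterministic."""
    reference, repeats, _ = toy_genome
    rng = np.random.default_rng(7)
    found = 0
    for pos in range(20_000, 90_000, 7_001):
        ref_allele = reference["chr01"][pos - 1 : pos + 7]
        variant = IndelVariant("chr01", pos, ref_allele, ref_allele[0], 50.0,
                               "deletion", len(ref_allele) - 1)
        template, offset = extract_design_template(variant, reference)
        change = len(variant.alt_allele) - len(variant.ref_allele)
        pair = design_primer_pair(template, offset, len(ref_allele), change)
        if pair is None:
            continue
        found += 1
        config = PrimerConfig()
        assert pair.validates(config, indel_len=variant.indel_len)
        assert config.product_range[0] <= pair.product_size_ref <= config.product_range[1]
        assert pair.product_size_alt - pair.product_size_ref == change
        again = design_primer_pair(template, offset, len(ref_allele), change)
        assert again == pair
    assert found >= 3  # random 500 bp templates nearly always admit a pair


def test_design_on_homopolymer_returns_none():
    template = "A" * 520
    assert design_primer_pair(template, 250, 10, -9) is None


@pytest.mark.parametrize(
    "chrom,pos,expected",
    [(1, 5_460_000, "T1M0546"), (10, 6_412_345, "TaM0641"), (12, 9_999, "TcM0000")],
)
def test_marker_naming(chrom, pos, expected):
    assert name_marker(chrom, pos) == expected


def test_marker_naming_rejects_bad_chromosome():
    with pytest.raises(ValueError):
        name_marker(13, 1000)
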