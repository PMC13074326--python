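# Methods

This note documents the models, conventions and numerical choices behind
`indelmark`, in the order the pipeline runs.

## Coordinates and formats

All internal coordinates are 1-based inclusive, as in VCF. BED inputs are
0-based half-open and converted on read; BED outputs convert back. An InDel's
reference footprint is `[pos, pos + len(REF) − 1]`; repeat overlap is tested
on this footprint only, not on the flanks (the flanks have their own
single-copy check). Multi-allelic VCF records are split into one variant per
ALT; alleles of equal length (SNPs, balanced substitutions) and symbolic
alleles are skipped and counted. Complex substitutions with unequal allele
lengths are classified by net length change, since the catalogue only
distinguishes insertions from deletions. A missing QUAL (`.`) is retained
with the quality flagged unknown; unknown quality cannot pass the quality
filter.

Percentage columns in the catalogue summary are rounded half-up to two
decimals, matching how such tables are conventionally printed.

## Marker screen

Stages run in a fixed order and each locus receives exactly one terminal
disposition; a locus failing an early stage is never evaluated later. The
stage thresholds are: quality ≥ 30 (Phred), length ≥ 6 bp (reliably
resolvable on 8 % polyacrylamide gels), flank length 200 bp, minimum spacing
100 kb. All are `ScreenConfig` fields.

*Flank single-copy check.* Instead of realigning flanks with an external
aligner, every k-mer (default k = 31, odd to avoid palindromes) of each
flank must occur exactly once in the genome counting both strands, via a
canonical k-mer index. This is a conservative, fully reproducible proxy for
"non-repetitive, single-copy": any duplicated stretch ≥ k inside a flank
fails it. Flanks with more than 10 % non-ACGT bases fail with a reason;
k-mers containing other ambiguity codes are skipped.

*Spacing.* Greedy left-to-right thinning per chromosome: keep the first
locus, then each next locus only if ≥ 100 kb from the last kept one. A gap
of exactly the minimum is kept. This is deterministic given position-sorted
input; a maximum-cardinality variant was deliberately not implemented.

*Genic balance.* "Genic" means any overlap of the variant footprint with a
gene interval (exons and introns are not distinguished). In `observed` mode
the stage is a pass-through; in fixed-ratio mode `(r, n)` it retains
round(n·r) genic and the remainder intergenic loci, ranked by quality with
(chromosome, position) as tie-break, clamping with a logged shortfall when a
class runs out.

*Wet-lab validation.* Gel amplification results cannot be computed; an
externally scored pass/fail list can be merged by marker name
(`apply_external_validation`).

## Primer design

Melting temperatures use the unified nearest-neighbor thermodynamic
parameters with the entropy monovalent-salt correction at 50 mM Na⁺ and
250 nM primer (the Wallace 2(A+T)+4(G+C) rule is available as a
cross-check). Structure screening is exact-complementarity based: a pair
fails if (a) the longest perfect Watson–Crick run between the two primers
reaches 6 bp, (b) the 3′-terminal 5 bases of either primer perfectly
complement any window of the other, or (c) either primer can fold on itself
with a stem ≥ 5 bp and a loop ≥ 3 bases. These thresholds are package
defaults chosen at common primer-design practice; thermodynamic
secondary-structure ensembles are out of scope. Note that clause (c) rejects
low-complexity primers (e.g. AT- or GC-repeats) even when the pair shows no
cross-complementarity at all — that is intended.

Among qualifying pairs the design returns the one minimising |Tm_f − Tm_r|,
then product size, then leftmost forward start; the ranking is a package
convention (no ranking is prescribed by the source workflow) and makes the
search deterministic.

Marker names are `<chromosome token>M<4-digit token>` with tokens T1–T9 and
Ta/Tb/Tc for chromosomes 10–12. The position token is floor(pos / 10 kb)
zero-padded to four digits; the 10 kb unit is inferred from the shape of the
published names (four digits spanning chromosome-scale coordinates) and is
isolated inside `name_marker`.

## Band codes, allele frequencies and PIC

Band codes score gel phenotypes: 0 no band (missing), 1 reference-type band,
2 InDel band, 3 heterozygous double band, 4 a second, length-distinct InDel
band. Frequencies use diploid counting — codes 1/2/4 contribute two copies
of their allele, code 3 one reference plus one InDel copy, code 0 is
excluded from the denominator. A haploid "band-presence" counting mode
exists for sensitivity checks only.

PIC follows the Botstein definition
`1 − Σ p_i² − Σ_{i<j} 2 p_i² p_j²`, implemented via the identity
`Σ_{i<j} 2 p_i² p_j² = (Σ p_i²)² − Σ p_i⁴` and validated against the naive
double loop. Per-marker PIC is reported to 3 decimals and aggregate means to
4, matching the conventional printing of such tables.

## Distances, trees, PCA

The accession distance is simple-matching dissimilarity on band codes with
pairwise deletion of missing cells — appropriate for codominant band data
where code identity, not allele dosage, is what a gel resolves. Pairs with
no comparable markers get an undefined (NaN) distance and are rejected by
the tree builders.

UPGMA and neighbor joining are implemented in-package so that tie-breaking
is fully specified: ties are resolved by the lexicographically smallest
(minimum leaf label) pair, making both algorithms deterministic. NJ clamps a
negative branch length to zero and transfers the deficit to its sibling,
preserving their sum. UPGMA trees are ultrametric by construction; NJ
recovers additive matrices exactly (verified against scikit-bio's
implementation in the tests). Trees are `skbio.TreeNode` objects serialised
as newick.

PCA maps codes to alternate-allele dosage (1→0, 3→1, 2 and 4→2), imputes
missing cells to the marker mean, centres columns and uses an SVD
decomposition; each component's sign is fixed by making its
largest-magnitude loading positive.

## Admixture model and choice of K

The admixture likelihood treats each accession's dosage at marker j as
Binomial(2, θ_ij) with θ_ij = Σ_k q_ik p_kj. Parameters are estimated by EM
with seeded Dirichlet initialisation of Q and frequencies clipped to
[10⁻⁶, 1 − 10⁻⁶]; the log-likelihood is monotone over iterations and K = 1
has the closed form (Q ≡ 1, P = observed frequencies). This
maximum-likelihood EM is a deliberate, deterministic-per-seed substitute for
Bayesian MCMC samplers of the same likelihood: it runs at desk scale and
yields both selection statistics. Code 4 is collapsed to dosage 2 for this
module only — the biallelic likelihood has no third-allele category.

Model selection reports two statistics side by side, because practice mixes
them: (1) hold-out CV error — observed cells are split into folds, each
fold masked and predicted by 2·QP after refitting, with mean squared error
averaged over folds; markers left unobserved in a training fold are skipped
there; (2) the Evanno ΔK — mean |L(K+1) − 2L(K) + L(K−1)| over replicate
runs divided by the replicate standard deviation of L(K), defined only at
interior K, +inf when the sd is zero (flagged). ΔK structurally cannot
select the smallest or largest K tested; the CV curve can. Defaults follow
the study protocol: K from 1–10 with 10 replicate runs each.

## Synthetic data

The generator provides every input with known truth, all pure functions of
(config, seed).

*Reference genomes*: i.i.d. bases at a target GC (default 0.36,
Solanaceae-like); repeats are realised by pasting one repeat unit (300 bp)
at ≥ 2 non-overlapping locations per chromosome to the requested fraction,
so repeat k-mers genuinely occur multiply and flank-uniqueness fails inside
them; gene intervals (2 kb) are non-overlapping. Implanted InDels record
position, type, length, quality and repeat/genic context; qualities and
lengths deliberately straddle the screening thresholds so the truth table
predicts every filter decision.

*Accession panels*: the Balding–Nichols F-model — per marker an ancestral
frequency p ~ U(0.1, 0.9) and subpopulation frequencies
Beta(p(1−F)/F, (1−p)(1−F)/F). Defaults mirror the study conditions: 52
accessions, 63 markers on 12 chromosomes, K = 4 subpopulations, F_ST = 0.3
(strong differentiation, consistent with a panel spanning wild and
cultivated material; the study reports no estimate, so this is a package
choice made once). Heterozygosity is scaled by `het_rate`
(P(het) = 2p(1−p)·h, homozygote classes absorb the remainder symmetrically,
allele frequencies preserved); the default 0.2 reflects highly inbred
tomato lines. A `third_allele_rate` fraction of markers (default 0.05)
re-renders half of their homozygous-InDel accessions as code 4;
`missing_rate` (default 0.02) blanks cells to code 0.

What the generator does **not** emulate: linkage between markers (markers
are independent), realistic chromosome lengths or gene models, admixed
individuals (memberships are hard blocks), allele-specific amplification
failure, or gel-scoring error beyond uniform missingness. Tests passing on
this generator therefore demonstrate algorithmic correctness and statistical
behaviour under the stated model, not robustness to those real-data
effects.

## Core panel and fingerprints

Panel selection ranks biallelic markers per chromosome by PIC (ties by
name), takes two from each, and fills to 24 by the next-best markers overall
with at most three per chromosome. When a chromosome has fewer than two
biallelic markers, multi-allelic markers from that chromosome are used as a
logged fallback — the published panel itself contains one triallelic marker,
so a strict biallelic rule cannot reproduce it; `strictly_biallelic=True`
restores the strict behaviour. Fingerprints are pure transcription of the
panel codes in panel order; duplicates are reported, never collapsed,
because a 24-marker panel may not separate accessions that the full marker
set does (the packaged 52 published fingerprints contain exactly one such
identical pair, which the audit flags).

## Problem sizes in the tests

The test suite and acceptance script run at deliberately small scales chosen
as sufficient for their statistical checks: toy genomes of 1–2 chromosomes ×
80–150 kb, 30–60 implanted InDels, panels of 40–60 accessions × 60–100
markers, K selection over K = 1–6 with 3 replicate fits and 4–5 CV folds,
and 5–10 seeds for recovery rates. The K-recovery checks assert majority
agreement across seeds rather than per-seed success, reflecting the
stochastic nature of the selectors at these scales.

## Known limitations

- The flank single-copy k-mer criterion is stricter than mapping-based
  single-copy checks; near-duplicated regions with mismatches every < k bp
  may still pass, and any exact k-mer repeat fails.
- Primer structure checks are exact-complementarity heuristics, not free-
  energy calculations.
- The admixture EM finds local optima; replicate runs with different seeds
  are the mitigation, as in standard practice.
- ΔK is undefined at boundary K values and unstable when replicate
  log-likelihoods are (numerically) identical; both cases are flagged
  rather than hidden.
- Per-stage attrition counts of the original marker-development programme
  are not reproducible from published information; the screen is validated
  on implanted-truth synthetic genomes instead.
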