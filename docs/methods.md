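# Methods

This note documents the models and procedures implemented in genefamkit,
their assumptions and defaults, what the synthetic test bed does and does
not emulate, and the numerical choices that matter for reproducing its
output.

## Domain model and scanning

A domain profile is built from a gap-free alignment as a per-column
log-odds matrix over the 20 amino acids,

    score(c, a) = log2[ (count(a, c) + κ·bg(a)) / ((n + κ)·bg(a)) ],

with pseudocount κ = 1 and a uniform background by default.  Scanning
slides the profile over the protein without gaps; placements truncated at
either sequence end are scored over their overlapping columns only (at
least 10), which lowers their profile coverage.  Candidate placements at
or above the bit-score threshold are reduced to a non-overlapping set
greedily by descending score, ties broken by smaller start.  Proteins
shorter than 10 residues are skipped with a log message.

The score threshold is calibrated against a null of i.i.d. background
sequences: the per-search maximum score — taken over the *same* placement
set the scanner evaluates, truncated windows included — is fitted with a
Gumbel law by the method of moments (β = s·√6/π, μ = x̄ − γβ), and the
threshold is the score whose expected hit count per search equals the
target E-value (default 10⁻⁵).  E-values for other protein lengths scale
linearly with the number of placements.  Calibrating on full windows only
would be wrong here: for a profile whose expected per-column score is
negative, a 10-column truncated window scores far above any full null
window, so truncations dominate the null maximum.

Low-quality and partial hits are removed by `E ≤ 10⁻⁵ AND coverage ≥ 0.7`
(the coverage cut operationalises "partial domain" removal; the threshold
is configurable because no published value exists).  Insert/delete states
(full profile-HMM alignment) are intentionally not implemented; for real
genomes the HMMER3 `--domtblout` reader provides interop, mapping envelope
coordinates to 0-based half-open intervals and using the independent
E-value.

Non-standard residues (X, B, Z) score 0 bits (background) and count
against coverage.

## Subfamily classification

Architecture rules on the filtered hit set: two or more AP2 hits → AP2
subfamily (any linker length qualifies; the observed linker length is
reported for QC); at least one AP2 plus one B3 → RAV; exactly one AP2 →
ERF clade; B3 without AP2 → UNCLASSIFIED (warned, never silently
dropped).

ERF-clade genes are refined to ERF / DREB / DRF / SOLOIST by **nearest
labelled reference domain**: ungapped column-wise identity against a
shipped reference set, ties broken by label priority ERF > DREB > DRF >
SOLOIST and then file order; best identity < 0.25 falls through to
SOLOIST, and a domain covering less than half the profile is
UNCLASSIFIED.  Published catalogues delegate this split to curated
Arabidopsis/rice criteria without printing an operational rule;
nearest-reference was chosen because it is deterministic, testable and
extensible (swap in a curated reference FASTA via `subfamily=` header
tags for real genomes).

The shipped references are synthetic, derived deterministically from the
AP2 profile: the DREB and DRF consensuses substitute disjoint fixed sets
of 10 diagnostic columns, and the SOLOIST consensus substitutes a fixed
35% of columns — a single divergent consensus rather than per-gene random
divergence.  This is a deliberate design choice: if every SOLOIST gene
randomized its own 35% of columns, SOLOIST genes would be mutually
dissimilar and no reference-based rule could recognise them (their
identity to an ERF reference, ≈ 0.61, stays far above any usable cut).  A
fixed divergent consensus models SOLOIST as what it is in real data — a
coherent, divergent clade.

Family members are named `<prefix>-001 …` by chromosomal order:
chromosome number 1–7, subgenome A before B, start coordinate ascending —
the convention used for tetraploid wheat karyotypes.  Chromosome counts
are reported zero-filled over all 14 labels with per-subgenome totals.

## Duplication and Ka/Ks

All unordered CDS pairs are aligned with Needleman–Wunsch under affine
gaps (match +2, mismatch −1, gap open −5, gap extend −1; a length-k gap
costs open + k·extend).  Traceback ties resolve diagonal → up → left, so
alignments are unique.  Identity is matches / aligned columns (the
denominator is a convention; it is documented here because published
pipelines rarely state theirs).  Pairs with identity **strictly greater
than 0.85** are duplicates; clusters are connected components of the
retained-pair graph.

Ka/Ks uses Nei–Gojobori (1986) counting: per codon, each position
contributes the fraction of its three changes that are synonymous
(changes to stops count as nonsynonymous; s + n = 3 exactly); observed
differences are averaged over all orderings of the differing positions,
excluding pathways through stop codons and renormalising.  Codon columns
containing a gap, an ambiguous base or a stop in either sequence are
dropped (complete-codon pairwise deletion; ≥ 10 comparable codons
required).  S and N are averaged over the two sequences, p-proportions
are Jukes–Cantor corrected (undefined at p ≥ 0.75 → the pair is flagged
*saturated*), and the selection call is purifying/neutral/positive for
ω <, =, > 1, or *undefined* when Ks = 0.  NG86 + JC was chosen as the
classical, fully specifiable estimator of this family of tools.

At the generator's default divergence (Ks ≈ 0.05, ~150 codons) a planted
pair yields only a handful of synonymous events, so individual ω̂ values
are noisy (an occasional ω = 0.5 pair exceeds 1); the estimator is
unbiased to within a few percent, which the 300-codon recovery tests
verify (mean ω̂ within 10% of truth at ω ∈ {0.1, 0.5, 1.0}).

## Phylogeny

Saitou–Nei neighbor joining on a symmetric distance matrix, joining the
pair minimising Q with ties broken by the smallest (i, j) index pair.
Negative branch lengths are clamped to zero with the deficit moved to the
sister branch (total preserved); the finished tree is unrooted with a
root trifurcation.  NJ is consistent on additive matrices, which the test
suite exploits for exact topology-recovery checks.

Distances for the family tree are p-distances over the scanned AP2-domain
columns (profile-anchored and gap-free, avoiding a full MSA
implementation).  Bootstrap resamples columns with replacement; each
replicate draws its RNG stream from (seed, replicate index), so results
are reproducible under any execution order.  Supports are the percentage
of replicate trees containing each internal bipartition (1000 replicates
by default).  Clades transfer from labelled reference leaves to unlabeled
leaves by smallest patristic distance, ties by alphabetical clade id.

## Motifs and promoters

Motif patterns are position-restricted residue/base classes compiled to
regular expressions; all matches are reported, overlapping ones included
(no greedy consumption — conservative and order-independent).  The
strict `FDLNLPP` and generalised `[L/F]DLN[L/F]` spellings of the EAR-type
motif both circulate in the literature, so both are scanned and reported
under distinct names.  DNA elements are scanned on both strands; minus
strand hits are mapped back to plus-strand coordinates, and `N` never
matches.  Promoters are the 1500 bp (configurable) immediately 5′ of the
start codon on the gene's strand — for minus-strand genes the reverse
complement of the window just 3′ of the genomic CDS end — truncated with
a warning at chromosome edges.

## Expression

*RNA-seq*: genes with FPKM < 0.5 in every sample are removed (a gene
reaching 0.5 anywhere is kept); the heatmap transform is
log2(x + 1).  Tissue grouping uses τ = Σ(1 − x_i/x_max)/(n − 1) on log2
values: τ ≥ 0.8 with peak FPKM ≥ 1 ⇒ tissue-specific in the argmax
tissue; τ ≤ 0.2 with all tissues ≥ 1 ⇒ ubiquitous; all-zero ⇒ silent;
otherwise mixed.  τ formalises the qualitative "preferentially expressed
in one tissue" grouping; 0.8/0.2 are config keys.  Stress calls use
log2((stress + 1)/(control + 1)) with |log2FC| ≥ 1 (single-accession FPKM
offers no replicate statistic, so the fold-change rule is an explicit
stand-in, flagged here); genes below 0.5 FPKM in both columns are ns.

*qPCR*: per replicate ΔCT = Ct_target − Ct_reference; ΔΔCT = mean
ΔCT(treatment) − mean ΔCT(control); relative expression 2^−ΔΔCT; the
p-value is a two-sided equal-variance Student's t-test on replicate ΔCT
values (Welch available by flag), flagged significant at p < 0.05.
Adding any constant to all Ct values leaves the result unchanged
(scale-invariance, tested exactly).

## Synthetic test bed

The generator emulates the *structure* of a real survey's inputs, not
their biology.  Background protein sequence is uniform over the 20
residues (maximising contrast with high-information profile columns);
domains are sampled column-wise from profile emission frequencies, with
ERF/DREB/DRF/SOLOIST genes drawn from their subfamily consensus with 8%
per-column noise.  Back-translation picks uniformly among synonymous
codons (no codon-usage table — the tests do not need one); CDSs end in a
uniform stop codon, and chromosome placement uses ≥ 3.1 kb gaps so every
gene keeps an undisturbed 1.5 kb promoter window.  Duplicate partners are
produced by a codon-level substitution process: proposals at Poisson
intensity ks_target per site, synonymous changes accepted at the base
rate, nonsynonymous at base rate × ω, stop-creating proposals rejected
and redrawn (keeps the ORF valid; biases ω̂ down by only a few percent).
FPKM baselines are log-normal with multiplicative noise (σ = 0.15);
tissue-specific genes sit on a low off-tissue baseline (~0.2 FPKM) with a
20× elevation in their tissue; stress genes change 4× against control;
Ct tables use Ct = offset − log2(expression) − f + N(0, 0.2²) with a
constant reference gene, so a planted log2 fold f gives E[ΔΔCT] = −f.

Not emulated: introns and UTRs, codon usage, tandem arrays, GC content,
mapping biases, replicate structure in the FPKM matrix, reference-gene
drift in qPCR.  Passing the planted-truth tests therefore demonstrates
the correctness of the *algorithms* under their stated models, not
robustness to the full messiness of real data — for real genomes the
HMMER interop, curated reference sets and replicate designs are the
intended entry points.

One calibration note: with the generator's Ct noise (sd 0.2 cycles,
3 replicates) the ΔΔCT estimator lands within 0.5 **cycles** of the
planted value in ≥ 95% of runs (verified by Monte-Carlo), but on the
**fold** scale a ±0.5 band around 4.0 corresponds to only ≈ ±0.17 cycles,
which that noise level meets ~73% of the time — an inherent property of
the error model, not an estimator defect.

## Numerical choices

- pI: Bjellqvist pKa set (N-term 7.5, C-term 3.55; K 10.0, R 12.0,
  H 5.98, D 4.05, E 4.45, C 9.0, Y 10.0), bisection on [0, 14] to
  |charge| < 10⁻⁴; the charge curve is strictly decreasing so the root is
  unique.  MW uses average residue masses + 18.0153 Da for water
  (ProtParam convention).
- Conservation columns use raw frequencies (no pseudocount); information
  = log2(20) − H; consensus ties break alphabetically.
- All RNG is numpy `default_rng`; the generator derives independent
  streams for genome ([seed, 1000]), expression ([seed, 2001]) and qPCR
  ([seed, 2002]) so each product is reproducible in isolation.  Fixed
  config + seed gives byte-identical output files; the pipeline writes a
  sha256 manifest (report.json excluded — it carries wall time) that
  reruns reproduce exactly.
- Pipeline problem sizes: the default simulated genome has 60 genes
  (48 family members), 8 duplicate pairs and 1000 bootstrap replicates —
  large enough to exercise every stage and small enough that a full run
  takes ~20 s on one CPU.

## Known limitations

- Gap-free window scoring underestimates scores of genuinely indel-bearing
  domains; use the HMMER3 interop for real genomes.
- The identity denominator (aligned columns) differs from some published
  pipelines (which use shortest-sequence length); the threshold semantics
  (strictly > 0.85) are exact either way on the fixtures.
- Duplicate "clusters" are connected components of the identity graph,
  which need not coincide with phylogeny-defined duplication groups.
- ω̂ on short, recently diverged pairs is noisy (few synonymous events);
  interpret per-pair calls at desk scale with care.
- τ thresholds (0.8/0.2) are calibrated to the generator's design and are
  configuration keys, not biological constants.
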