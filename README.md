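# genefamkit

A tested, reusable pipeline for genome-wide transcription-factor
**gene-family surveys**, modelled on the classical AP2/ERF workflow in
cereal genomes: identify family members by their DNA-binding domain,
classify them into subfamilies by domain architecture, name them by
chromosomal order, detect duplicated gene pairs and measure the selection
pressure on them, build a bootstrapped neighbor-joining phylogeny, screen
for short regulatory protein motifs and promoter cis-elements, and analyse
tissue/stress expression from RNA-seq FPKM and qPCR Ct tables.

It is written for comparative genomicists who run this kind of survey on a
new genome and want each stage to be a callable, unit-tested function
rather than a chain of web tools.  A bundled **synthetic-genome generator**
produces proteins with implanted AP2/B3 domains in the four canonical
architectures (ERF-clade: one AP2 domain; AP2: two AP2 domains with a
25-residue linker; RAV: AP2 + B3; SOLOIST: a divergent single AP2), CDSs,
chromosome sequences over a 1A–7B karyotype, duplicated pairs diverged at
controlled ω and Ks, FPKM matrices and Ct tables — each with a recorded
truth table, so the whole pipeline is testable end-to-end without any
downloads.

## Methods at the core

* **Domain detection** — position-specific log-odds scoring,
  `score(c, a) = log2[(count(a,c) + κ·bg(a)) / ((n + κ)·bg(a))]`, over
  gap-free windows (including end-truncated windows, which lower a hit's
  profile coverage).  A Gumbel law fitted to null maxima converts bit
  scores to E-values; the default acceptance rule is E < 10⁻⁵ with ≥ 0.7
  profile coverage (partial-hit removal).  Full profile-HMM alignment is
  deliberately out of scope: gap-free scoring is exact for the synthetic
  test bed, and real HMMER3 runs are supported through a `--domtblout`
  reader.
* **Duplication & selection** — all CDS pairs are globally aligned
  (Needleman–Wunsch, affine gaps), pairs with identity **strictly > 85%**
  are called duplicates, and Ka/Ks is estimated by **Nei–Gojobori (1986)**
  counting with Jukes–Cantor correction
  `d = −(3/4)·ln(1 − (4/3)p)`; ω = Ka/Ks < 1 is reported as purifying
  selection.
* **Phylogeny** — Saitou–Nei **neighbor joining** on p-distances over the
  AP2-domain columns, with column-resampling bootstrap supports
  (1000 replicates by default) and clade assignment by nearest labelled
  reference leaf (patristic distance).
* **Motifs** — regex-class scanning for the repression/activation motifs
  `[R/K]LFGV`, `FDLNLPP` (and the generalised `[L/F]DLN[L/F]` spelling,
  reported separately) and `EDLL`, and for the promoter elements DRE
  `[AG]CCGAC`, ABRE `TCCACGTCTC`, re2f-1 `GCGGGAAA` and the ACGT motif
  `GTACGTG` on both strands of the −1500 bp promoter window.
* **Expression** — FPKM filtering (drop genes < 0.5 in every sample), log2
  heatmap transform, tissue specificity by the **τ index**
  `τ = Σ(1 − x_i/x_max)/(n−1)` on log2 values (τ ≥ 0.8 ⇒
  tissue-specific), fold-change stress calls, and qPCR quantification by
  the **2^−ΔΔCT** method with replicate-level Student's t-tests.
* **Protein properties** — ProtParam-style average-mass molecular weights
  and Bjellqvist-model theoretical pI by bisection of the net-charge
  curve; per-column conservation (information content) tables for
  sequence logos.

## Worked example

One YAML file drives the full pipeline.  With the default synthetic genome
(60 genes, seed 7, 1000 bootstrap replicates):

```yaml
# demo.yaml
simulate:
  seed: 7
evolve:
  bootstrap: 1000
```

```bash
genefamkit run --config demo.yaml --out demo_out
```

prints the machine-readable stage tallies (abridged):

```json
{
  "n_genes_input": 60,
  "n_family_members": 48,
  "n_non_members": 12,
  "subfamily_tally": {"ERF": 18, "DREB": 8, "AP2": 6, "RAV": 6, "DRF": 5, "SOLOIST": 5},
  "n_duplicate_pairs": 8,
  "n_purifying_pairs": 8,
  "clade_tally": {"ERF": 30, "DREB": 8, "DRF": 5, "SOLOIST": 5},
  "protein_motif_tally": {"RK-LFGV": 6, "EDLL": 3, "LF-DLN-LF": 2, "FDLNLPP": 2}
}
```

Reading: of 60 input genes, 48 carry a confident AP2/B3 domain and are
named `TtAP2/ERF-001` … `TtAP2/ERF-048` in chromosomal order; the
subfamily tally matches the generator's plantings exactly; all 8 planted
duplicate pairs are recovered and all are under purifying selection
(ω < 1); the `clade_tally` groups the single-AP2 genes by their nearest
labelled reference in the NJ tree (the 30 "ERF" leaves are the 18 ERF
genes plus the 6 AP2 and 6 RAV genes, whose profile-typical AP2 domains
sit nearest the ERF references).  `demo_out/` additionally contains per-stage TSVs
(hits, classification, physchem, duplicate pairs with Ka/Ks/ω, Newick
tree with bootstrap supports, motif and promoter-element hits, expression
classes, ΔΔCT table), a `report.json`, and a `manifest.json` of sha256
checksums — rerunning the same config reproduces the manifest
byte-for-byte.

Individual stages are also available as subcommands (`simulate`, `scan`,
`classify`, `props`, `logo`, `evolve`, `motifs`, `promoters`, `express`,
`qpcr`) and as plain library functions.

## Layout

```
src/genefamkit/
  synthetic_data.py   # genome/expression/qPCR generators + truth table
  domain_scan.py      # profiles, window scanning, E-value calibration, domtblout
  subfamilies.py      # ERF/DREB/DRF/SOLOIST consensus models
  family_classify.py  # architecture rules, refinement, naming, tabulation
  protein_props.py    # MW, pI, conservation columns
  evolution/          # alignment, Nei–Gojobori Ka/Ks, NJ + bootstrap
  motif_scan.py       # repression motifs, promoter elements, promoters
  expression.py       # FPKM filtering, tau, stress calls, 2^-ddCT
  pipeline.py, cli.py # orchestration and the genefamkit CLI
  data/               # synthetic AP2/B3 alignments + labelled references
```

See `docs/methods.md` for the full model description, parameter defaults
and known limitations.
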