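# Methods

## The screening procedure

`coldscreen` implements a count-based differential-expression caller for
two-condition bulk RNA-seq designs with a small number of biological
replicates per group — the motivating design is brown adipose tissue from four
mice after 24 h at 4 °C against four thermoneutral controls.

**Quantification.** Expression is measured in RPKM. For transcript *t* with
*c* mapped reads, effective length *L* nucleotides, in a library of *N* mapped
reads:

    RPKM = 1e9 · c / (N · L)

Effective length is the union of the transcript's exon intervals when computed
from a GTF (overlapping exons are counted once; GTF coordinates are 1-based
inclusive). Gene-level expression is the sum of the gene's transcript RPKM;
gene-level counts are the sum of transcript counts. When the sample sheet does
not declare a library size, the column sum of the count table is used — with a
full-transcriptome table the two are close; with a targeted panel the declared
size should be supplied.

**Expression filters.** A gene is *expressed* when its summed RPKM is positive
in at least one sample, and *expressed in all samples* when positive in every
sample. The two definitions are nested and both are reported; only expressed
genes are tested.

**Per-sample exact tests.** For each expressed gene and each cold sample *i*,
a two-sided Fisher exact test is applied to the 2×2 table

|                | gene reads | all-other reads |
|----------------|-----------:|----------------:|
| cold sample *i*| g_i        | N_i − g_i       |
| control side   | g_ctrl     | N_ctrl − g_ctrl |

where the control side pools all control samples (default) or, in
`paired_by_index` mode, is the control sample with the same position in the
sample sheet. The per-sample direction compares read proportions
g_i/N_i vs g_ctrl/N_ctrl, evaluated by integer cross-multiplication so exact
ties are detected without floating-point rounding and classified `flat`.
A pooled p-value (summed cold vs summed control) is carried along for
tie-breaking in the candidate ranking.

**Multiple testing.** p-values are corrected by the Benjamini–Hochberg
step-up. Two family definitions are supported: `per_sample_genomewide`
(default) corrects across all tested genes within each cold sample's test
family, which is the conservative genome-wide standard and keeps a corrected
threshold of 0.05 meaningful at 10³–10⁴ genes; `per_gene_across_samples`
treats each gene's per-sample tests as a family of size *n_cold*. Significance
everywhere means the *corrected* q-value below `alpha`.

**Consistency vote.** A gene is called `up` only if q < alpha with direction
`up` in at least `min_consistent` (default 3) of the cold samples *and* no
cold sample is significant in the opposite direction; symmetrically for
`down`; otherwise `unchanged`. A significant `flat` sample neither supports
nor vetoes a call.

**Fold change and ranking.** The gene fold change is the ratio of summed RPKM
(over transcripts and samples) cold/control; with equal group sizes this
equals the ratio of condition means. A zero control sum with a positive cold
sum yields an explicit `+inf` (written as the literal `+inf`), ranked above
all finite fold changes; a gene with both sums zero has no defined fold change
(it also fails the expressed filter, so it never reaches the caller in the
pipeline). An optional pseudocount (suggested 0.01 RPKM, default off) gives
finite ratios for users who prefer finite ranks. Candidate selection takes,
among genes called `up`, the top `ceil(top_fraction · n_up)` (default top
decile) by fold change descending, ties broken by ascending pooled p then
gene id.

## Parameters

| parameter | default | units | role |
|---|---|---|---|
| `alpha` | 0.05 | probability | threshold on the BH-corrected q-value |
| `min_consistent` | 3 | samples | same-direction votes required (of `n_cold_samples`) |
| `n_cold_samples` | 4 | samples | expected cold-group size, checked against the sheet |
| `bh_family` | `per_sample_genomewide` | — | BH family definition (see above) |
| `pairing` | `vs_pooled_control` | — | control side of each per-sample table |
| `top_fraction` | 0.10 | proportion | fraction of up-called genes returned as candidates |

## The synthetic-data generator

The generator emulates the statistical structure the caller assumes, with
known ground truth, so every stage is testable without external data. Per gene
*g* and sample *i*, gene-level reads are negative-binomial:

    reads ~ NB(mean = m_g · f_g^[i is cold] · N_i / N_ref,  Var = m + φ·m²)

- `N_i`: library size, uniform in 45·10⁶ ± 10% (the emulated design's average
  sequencing depth). `N_ref` is fixed at 45·10⁶, so baseline means are "reads
  at nominal depth" and doubling all library sizes doubles expected counts
  while leaving RPKM-based fold-change estimates statistically unchanged.
- `m_g`: baseline mean reads, log10-normal with mean 2.0 and sd 0.8 decades
  (median 100 reads, a realistic bulk dynamic range); individual genes can be
  pinned with `baseline_overrides` to place effect genes at stated expression.
- `φ = 0.1`: NB dispersion, the standard bulk RNA-seq overdispersion
  parameterization. The emulated study reports no noise model, so this is a
  modeling choice documented here, typical of between-animal biological
  variability.
- `f_g`: true fold change from `effects`; all other genes are nulls (f = 1).
- Transcript structure: 1–4 transcripts per gene (uniform), lengths uniform
  500–5,000 nt, gene reads split by per-gene proportions drawn once from a
  symmetric Dirichlet (concentration 5) and held fixed across samples — there
  is deliberately no differential transcript usage, since the caller operates
  at gene level and transcript structure exists only to exercise aggregation.
- `n_genes = 200` by default: a desk-scale screen large enough for the
  genome-wide BH family to behave realistically while keeping simulation
  studies fast. Recovery and acceptance studies use 50-gene experiments
  (one effect gene plus 49 nulls) with 50 replicates, and null studies use
  20 replicates at the 200-gene default; these sizes are the package's
  standard study design for its own validation.

**Randomness contract.** One integer seed determines everything. Library
sizes come from a dedicated substream; each gene has its own substream keyed
by `(seed, 1, gene_index)`, so enlarging the gene set does not perturb the
counts of existing genes (a tested invariant).

**What the generator does not emulate:** batch effects, GC/length bias,
read-level error (no FASTQ), differential transcript usage, correlated genes,
or library-composition effects. Passing tests therefore demonstrate that the
pipeline recovers its own generative model's truth — parameter recovery and
calibration — not that the calls on any real tissue are biologically correct.

## Numerical choices

- The two-sided Fisher p-value uses the classical minimum-likelihood
  definition — the sum of hypergeometric point probabilities not exceeding the
  observed table's, with a 1e-7 relative tie tolerance — and is checked
  exhaustively against brute-force enumeration for all tables with margins
  ≤ 30. Tables with a zero row or column margin return p = 1 (no information).
- BH adjustment delegates to the standard step-up implementation and is
  verified against the hand formula q_(i) = min_{j≥i}(p_(j)·m/j) ∧ 1.
- Direction ties use exact integer arithmetic (cross-multiplication), never
  float division.
- Writers are deterministic: fixed column order, rows sorted by
  (call rank, fold change descending with `+inf` first and `NA` last,
  gene id), numbers at 6 significant digits, `\n` line endings, UTF-8 —
  identical inputs give byte-identical files.
- Displayed percentages round half away from zero to one decimal
  (3,470/21,391 → 16.2).

## Design choices at genuinely open points

- **Counts are transcript-level and summed to genes.** The caller tests reads
  per gene, but quantification is per transcript; summation is the only
  aggregation consistent with both views.
- **Pooled-control pairing by default.** The test is phrased
  condition-vs-condition while the consistency rule is per cold sample;
  testing each cold sample against the pooled control side reconciles the two
  readings. Index pairing is retained for sensitivity analysis.
- **Genome-wide BH by default.** The alternative reading — correcting each
  gene's four per-sample tests as their own family — is implemented and
  selectable (`per_gene_across_samples`), but a per-gene family of four makes
  a 0.05 threshold nearly uncorrected at genome scale.
- **The vote uses corrected q-values**, since significance is defined only
  through the corrected threshold.
- **Per-sample gene detection** (genes with RPKM > 0 in one individual) is
  exposed for parity with per-cohort filters; no detection threshold other
  than > 0 is implemented.

## Known limitations

- **Fisher's exact test assumes binomial (technical) sampling only.** Under
  biological overdispersion the per-sample tests are anticonservative for
  high-count genes: a between-animal fluctuation of many Poisson standard
  errors is declared significant even for null genes. The consistency vote
  and the genome-wide BH family suppress much of this but not all of it: on
  pure-null data the modified-call rate stays below `alpha` when the
  generator's dispersion is 0 (the test's own sampling model, a tested
  property), while at the default biological dispersion of 0.1 it exceeds
  `alpha` — the corresponding end-to-end check documents this as a failing
  bound. This is an inherent property of count-proportion exact tests applied
  across biological replicates, not an implementation artifact; users who
  need calibrated error control under biological variability should treat the
  caller as the screening heuristic it is, and its candidate lists as input
  to downstream validation.
- The fold-change estimator (ratio of summed RPKM) is median-unbiased in the
  generator's model but right-skewed at 4-vs-4 sample sizes; single-replicate
  estimates commonly deviate ±20% at dispersion 0.1.
- `+inf` fold changes are reported for genes undetected in controls; their
  ranking above all finite folds is a convention (auditable, but sensitive to
  single reads at the detection limit — the pseudocount option trades this
  for finite, shrunken ranks).
- The pipeline starts from transcript counts: read mapping and
  transcript-abundance deconvolution are upstream and out of scope.
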