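# Methods

This note documents the statistical model behind `tximbalance`, the choices
made where the design was genuinely open, and what the synthetic-data tests
do and do not establish about real data.

## The statistic

For an old-vs-young comparison, per-gene relative log2 fold changes are

    log2fc_g = log2((mean_old,g + c) / (mean_young,g + c)),

where means are over normalized counts and `c` (default 0.5) guards against
zeros. ρ_TI is the Spearman correlation between `log2fc` and transcript
length over all genes passing detection (raw count > 0 in ≥ 1 sample per
group, configurable). Being rank-based, ρ_TI is invariant under any strictly
monotone transform of either variable, so raw and log10 length are
interchangeable.

Significance is the standard t-approximation for the Spearman coefficient
(two-sided, n−2 df). For transcriptome-sized n this is essentially exact;
the acceptance suite quantifies the small-n error and finds
|p_t − p_perm| ≤ 0.05 down to n = 12 against a 5,000-draw permutation
oracle.

Three length variants (median mature-transcript, gene, CDS length) are
supported everywhere; they are strongly correlated and give concordant
imbalances.

## Normalization and fold-change flavors

* `median_of_ratios` (default for replicated groups): per-sample size
  factor = median over all-positive genes of count / geometric mean. Falls
  back to `cpm` (counts per million) with a logged warning when no gene is
  positive in all samples.
* Pairwise individual comparisons use raw-count log2 ratios over genes
  detected (count > 0) in both individuals — no pseudocount, no
  normalization. Spearman correlations are insensitive to the missing
  per-sample scale factor, which shifts all genes equally on the log scale.
* Pseudobulk (single-cell) comparisons sum raw counts within each cell
  group before taking the ratio; the universe is genes detected in ≥ 1 cell.

`simple_de` is a deliberately lightweight per-gene test: Welch's t on
log2(normalized + 0.5), BH-adjusted. It is *not* a count-model DE method
(no dispersion shrinkage, no independent filtering) and is used only for
significance flags and directions — e.g. to select genes for the
median-length-difference quantification — never for exact gene lists.

## Null models and uncertainty

**Same-age splits.** All ordered bipartitions of one age's replicates into
⌈n/2⌉ vs ⌊n/2⌋ groups (C(6,3) = 20 ordered splits for six replicates; for
five, C(5,3)+C(5,2) = 20). Because both orders of every split are included
and swapping groups negates every fold change exactly, the null multiset of
ρ_TI values is exactly closed under negation. Ordered splits were chosen
over unordered (a config switch) because the exact symmetry makes the null's
behavior auditable; degenerate splits (constant fold changes, e.g.
duplicated technical copies) are flagged and excluded rather than imputed.

**Observed vs null.** Two-sided Mann–Whitney U; exact tie-aware enumeration
when both samples have ≤ 8 values (two-sided p = 2·min(P(U≤u), P(U≥u)),
capped at 1), otherwise the tie-corrected normal approximation. The exact
path is hand-enumerated because standard exact implementations reject ties.

**Fractions.** A fraction k/n of tissues (or pairs) showing the phenomenon
gets a 95% bootstrap interval by redrawing the n trials as independent
Bernoulli(k/n) 1,000 times and taking the 2.5/97.5 percentiles — the
resampling scheme appropriate for a bar of independent binary outcomes.

## The synthetic-data generator

The generator emulates the statistical skeleton of an age-resolved bulk
RNA-seq survey: two groups (young/old), six replicates each, assigned
round-robin to two cohorts; a single tissue per call (a panel helper
combines tissues with independent seeds).

* **Lengths** are log-normal: log10(bp) ~ N(3.4, 0.45) — a median transcript
  around 2.5 kb with a realistic right tail. Gene length multiplies the
  transcript by a random intron factor; the CDS is a Beta-distributed
  fraction of the transcript, so the ordering gene ≥ transcript ≥ CDS ≥ 1
  holds by construction.
* **Planted effect.** True log2 fold changes are fc_sd · z, where z is
  generated from the transcript-length normal scores through a Gaussian
  copula with latent correlation r = 2·sin(π·ρ_target/6), so the Spearman
  correlation with length equals ρ_target in expectation *exactly*,
  independent of fc_sd. Default fc_sd = 0.25 log2 units: age-related changes
  are mostly small, and 0.25 puts ~95% of true effects inside ±0.5 log2
  units.
* **Counts** are negative binomial, var = μ + φμ² (φ = 0 → Poisson);
  default φ = 0.05, a typical bulk biological coefficient of variation of
  ~22%. Baseline expression is log-normal (sd 0.8 log10 units) and
  independent of length by default; an `expr_length_coupling` knob plants
  length–expression confounding for robustness experiments. Both groups are
  scaled to the same expected library size; the normalization step absorbs
  this constant.
* **Annotations.** Term membership is sampled without replacement with
  weights sigmoid(bias · 10 · (0.5 − u)), u the length rank quantile: bias 0
  is uniform, +1 strongly favors short genes, −1 long genes. Two special
  labels, `pro_longevity` (default bias −0.9, i.e. long-skewed) and
  `anti_longevity` (+0.9, short-skewed), each with 300 members by default —
  the scale of curated longevity catalogs — emulate the opposing pattern the
  enrichment analysis is designed to detect. Genes may carry both labels.
* **Determinism.** All randomness flows from one seed through
  `SeedSequence` spawn keys (gene table 0, counts 1, annotations 2), so each
  artifact is bit-reproducible independent of call order.

### What recovery on synthetic data shows — and the attenuation floor

The copula makes the *true* planted correlation exact, so any deviation in
the *estimated* ρ_TI is attributable to the measurement pipeline. The
estimated fold change is the true one plus replicate noise whose
multiplicative part does **not** shrink with sequencing depth: for
dispersion φ and m replicates per group, the two-group noise floor is
σ_noise ≈ √(2φ/m)/ln 2 log2 units (≈ 0.186 for φ = 0.05, m = 6). The
recoverable correlation is attenuated by roughly
fc_sd / √(fc_sd² + σ_noise²) — about 0.80 at the defaults — so a planted
ρ = −0.30 is recovered as ≈ −0.22 at depth 10⁷ (slightly below the analytic
0.80 factor because low-expression genes add Poisson noise and the
pseudocount shrinks their fold changes). The unit suite asserts recovery
against this prediction; only with φ = 0 and depth → ∞ do estimated fold
changes converge to the truth gene by gene. The practical reading for real
data: an observed ρ_TI understates the latent length association whenever
between-replicate variability is comparable to the true effect scale.

The generator does not emulate: library-preparation length biases (the
technical artifact the LOWESS check exists to address in real data),
isoform-level quantification uncertainty, correlated gene-gene expression
structure, or multi-tissue sharing of effects. Passing tests therefore
establish the *statistics'* correctness and calibration, not robustness to
those real-data phenomena.

## Feature-importance procedure

Per comparison, 10 gradient-boosting regressors (Huber loss, transition
parameter 0.9) each train on an independent uniform 90% random sample of
genes. Defaults: 500 trees, depth 3, learning rate 0.05 — conservative
settings for noisy fold changes, all exposed in config. Per gene, the
prediction is the median across the models whose training sample excluded
it; genes excluded by no model are dropped from evaluation (with ~10
models, ≈ 65% of genes are evaluated). Held-out accuracy is the Spearman
correlation between observed and median-predicted fold changes. Importance
is the trees' normalized total split gain — deterministic given the fit —
ranked per model with average ranks for ties; a feature's summary is its
median rank across models and comparisons, and a feature *group* (all TF
sites; all miRNA sites; the three length variants) scores by its best-ranked
member. Omission controls refit without a named feature or group and report
the held-out accuracy difference; a redundant length variant costs nothing
because its siblings stand in for it.

## Enrichment and the annotation network

Extremes are the ⌊q·n⌋ shortest/longest genes (q = 0.05), with ties broken
by a stable sort on (length, gene id) so the sets have exactly the nominal
size and are reproducible. Fisher tests are two-sided ("sum of all tables at
most as likely", the convention of standard library implementations, which
serve as cross-checks in the tests); the expected overlap is
|query|·|term ∩ background| / |background|. Signed fold enrichment is n/e
for enrichment and −e/n for depletion (|fold| ≥ 1 by construction); n = 0 is
reported as the string `complete_depletion` rather than a numeric −∞.

The default background is genes carrying ≥ 1 annotation; `all_genes` is the
lower-powered alternative. BH correction runs within each
(extreme × direction) family by default (a pooled family is a config
option); the opposing criterion requires BH-significant enrichment in one
extreme and BH-significant depletion in the other — a strict reading; a
`depletion_nominal` flag relaxes the depleted side to nominal p < 0.05. The
false-positive control redraws both extreme-sized gene sets uniformly from
the gene table (i.e., from the observed length distribution) 100 times; on
an unbiased 300-term collection this yields essentially no qualifying terms.

The network over qualifying terms has an edge wherever two terms share ≥ 1
gene within the analysis universe; node counts are kept both restricted to
that universe and unrestricted. Simplification processes nodes in ascending
restricted-count order (ties lexicographic) and keeps, per node, the edge to
the neighbor with (1) the largest intersection, (2) the fewest
analysis-restricted genes, (3) the fewest genes including those outside the
analysis, (4) lexicographically smallest id — rule 4 being a deterministic
extension for residual ties. The procedure is idempotent and never increases
the edge count; fixtures with forced ties at rules 2 and 3 are traced by
hand in the tests.

## Numerical and degenerate-input policy

Constant fold changes or lengths raise a structured error rather than
propagating NaN, so the permutation module can flag degenerate splits
explicitly. p-values are validated into (0, 1]; adjusted p is monotone and
capped at 1. Two-sided Fisher p uses the standard (1 + 1e-7) relative
tolerance when summing "at most as likely" tables. LOWESS uses log10 length
as the covariate (the scale on which the trend is smooth) with default
smoothing fraction 0.3.

## Reference problem sizes

The acceptance checks run at sizes chosen for a single CPU; the same
settings back `scripts/acceptance.py`:

* correlation recovery: 15,000 genes, depth 10⁷, φ = 0.05, 6 vs 6, 20 seeds;
* type-I calibration: 500 null simulations × 2,000 genes;
* t-vs-permutation: n = 12, 20 trials × 5,000 permutations;
* null calibration: 200 simulations, 6 replicates per age, no age effect;
* feature recovery: 5,000 genes, 200 binary decoys, noise-free signal,
  ensembles of 10 models at 60 trees / learning rate 0.15 (a fast
  configuration adequate for a noise-free signal; results are stable under
  ±50% changes of both knobs), 20 seeds;
* opposing-enrichment FPR: 300 unbiased terms, 100 randomizations;
* longevity directions: 4,000 genes, 20 seeds;
* quantification concordance: 4,000 genes, depth 10⁶, φ = 0.01 — the
  low-dispersion setting is required because at φ = 0.05 the Welch stand-in
  detects no BH-significant genes at this depth and the median-length
  quantification has no input;
* LOWESS: 10,000 genes, planted smooth trend of slope −0.25 per log10 bp.

## Known limitations

* The DE stand-in underpowers relative to count-model DE tools; real
  analyses should feed externally computed DE results into
  `median_length_difference` where possible.
* `fit_importance_ensemble` at the default 500 trees is CPU-hungry for
  thousands of genes × hundreds of features; reduce trees or raise the
  learning rate for exploratory runs.
* The annotation generator's logistic weight saturates at the rank extremes,
  capping plantable fold enrichments near 2; stronger planted signals
  require composing sets manually.
* Identifier cross-mapping (e.g. between gene id namespaces) is out of
  scope; all inputs must share one namespace.
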