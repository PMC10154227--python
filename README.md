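# tximbalance

Tools for detecting and characterizing **length-associated transcriptome
imbalance**: a genome-wide association between transcript length and the
age-dependent change in relative transcript abundance, typically seen as a
relative deficit of long transcripts in old samples. The phenomenon is
subtle at the single-gene level — most genes never reach per-gene
significance — but strong and reproducible when quantified across the whole
transcriptome.

The package is aimed at computational biologists who want to (a) measure the
effect in their own count data, (b) understand its statistical behavior
(calibration, attenuation, small-sample properties) on simulated data with a
known planted signal, or (c) reuse the individual statistics.

## What it computes

**The length correlation ρ_TI.** For a comparison between an old and a young
group, each gene gets a *relative* log2 fold change
`log2((mean normalized old + c) / (mean normalized young + c))` (relative,
because transcriptome-wide normalization makes every gene's value depend on
all others). ρ_TI is the Spearman rank correlation between per-gene
transcript length and these fold changes, over all detected genes. Its
two-sided significance uses the t-approximation
`t = ρ√((n−2)/(1−ρ²))` with `n−2` degrees of freedom; the package also
quantifies how close that approximation is to a permutation p-value at small
n.

**Null models.** The same-age split null partitions replicates of one age
into two pseudo-groups (all ordered near-half splits) and computes ρ_TI
between the halves — the imbalance expected with *no* age difference. The
ordered construction makes the null exactly symmetric about zero. Observed
tissue correlations are compared against it with a two-sided Mann–Whitney U
test (exact, tie-aware enumeration when both samples have ≤ 8 values).

**Alternative quantification.** When only differentially expressed gene
lists are available, the imbalance is measured as the difference in median
transcript length between significantly up- and down-regulated genes
(Mann–Whitney tested), which agrees in sign with ρ_TI on planted data.

**Feature importance.** Gradient-boosting regression (Huber loss) predicts
per-gene fold changes from gene-level covariates — transcript/gene/CDS
length, GC content, exon count, binary TF-binding and miRNA-binding
indicators. Ten models per comparison each train on a random 90% of genes;
held-out accuracy is the Spearman correlation between observed fold changes
and the per-gene median prediction of the models that excluded that gene.
Features are ranked by normalized split-gain importance; groups of related
features score by their best member.

**Length-extreme enrichment.** The 5% shortest and 5% longest transcripts
are tested (two-sided Fisher exact) against pro-/anti-longevity gene labels
and against a gene-set collection, looking for terms enriched in one extreme
and simultaneously depleted in the other, with BH correction per
(extreme × direction) family and a randomization-based false-positive
control. Qualifying terms are organized into an annotation-overlap network
(edges = shared genes) and simplified to one kept edge per node (largest
intersection, with documented tie rules).

**Synthetic data.** All of the above is exercisable without external data:
the generator plants an exact Spearman correlation between log transcript
length and true log2 fold change through a Gaussian copula
(`ρ = (6/π)·arcsin(r/2)` calibration), adds negative-binomial count noise
(`var = μ + φμ²`), and plants gene-set collections with tunable length bias.

## Worked example

```python
from tximbalance import synthdata as sd, imbalance as imb, resampling as rs

spec = sd.SyntheticSpec(n_genes=10_000, depth=5e6, seed=42)
genes, counts, truth = sd.generate_tissue_panel(
    spec, {"liver": -0.3, "heart": -0.3, "lung": -0.3, "skin": 0.0}
)
survey = imb.run_imbalance_survey(counts, genes)
print(survey[["tissue", "comparison", "n", "rho", "p", "flag"]].to_string(index=False))

nulls = []
for tissue in ("liver", "heart", "lung", "skin"):
    nulls.extend(rs.permutation_null_rho(counts, genes, tissue, "young").rhos())
U, p = rs.compare_observed_to_null(survey["rho"], nulls)
print(f"observed (4 tissues) vs same-age null ({len(nulls)} splits): "
      f"Mann-Whitney p = {p:.2e}")
```

prints

```
tissue   comparison    n       rho             p     flag
 heart old_vs_young 9988 -0.221076 7.906133e-111 negative
 liver old_vs_young 9993 -0.229336 2.111693e-119 negative
  lung old_vs_young 9988 -0.228900 6.952361e-119 negative
  skin old_vs_young 9988 -0.007490  4.541969e-01     ns
observed (4 tissues) vs same-age null (80 splits): Mann-Whitney p = 3.62e-03
```

The three tissues with a planted correlation of −0.3 are flagged as
significant anticorrelations; the null tissue is not. The recovered ρ_TI
(≈ −0.22) is smaller in magnitude than the planted −0.3 because replicate
count noise attenuates the rank correlation — docs/methods.md derives the
attenuation factor. The same-age splits span only ±0.01, so the age signal
clearly exceeds inter-individual variability.

A command-line interface mirrors the library
(`tximbalance --config cfg.yaml --outdir out run-all`), writing TSV/JSON/GMT/
GraphML outputs plus a reproducibility manifest; see `tximbalance --help`.

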