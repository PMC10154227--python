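"""Synthetic data with a planted length/fold-change association.

The generator emulates the statistical skeleton of an age-resolved bulk
RNA-seq survey: a two-group (young vs old), multi-cohort design with roughly
half a dozen replicates per group, log-normally distributed transcript
lengths, negative-binomial count noise, and — the key knob — a planted
Spearman correlation between log transcript length and the true log2 fold
change between the groups.

The planted correlation uses a Gaussian copula. Transcript-length ranks are
mapped to normal scores ``z``; the latent effect variable is
``r*z + sqrt(1-r^2)*eps`` with ``eps ~ N(0,1)``, and the latent correlation
``r`` is calibrated from the requested Spearman correlation ``rho`` via the
bivariate-normal relation ``rho = (6/pi) * arcsin(r/2)``. This makes the
target exact in expectation regardless of the fold-change scale, so parameter
recovery is a sharp test for the downstream statistics.

Counts are negative binomial with the standard RNA-seq parameterization
``variance = mu + dispersion * mu^2``; ``dispersion = 0`` degenerates to
Poisson. Baseline expression is log-normal and independent of length unless
``expr_length_coupling`` is set, which lets tests separate length-driven
fold-change signal from expression-level confounding.

All randomness flows from ``spec.seed`` through ``numpy.random.SeedSequence``
spawn keys: gene table = key 0, counts = key 1, annotations = key 2, so each
artifact is reproducible independently of call order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import expit, ndtri
from scipy.stats import rankdata

from ._errors import ConfigurationError, ParameterError
from .ioformats import CountMatrix, GeneSetCollection, validate_gene_table

_GENE_TABLE_KEY = 0
_COUNTS_KEY = 1
_ANNOTATION_KEY = 2


@dataclass(frozen=True)
class AnnotationSpec:
    """Parameters of the planted gene-set collection.

    ``length_bias`` in [-1, 1] skews term membership along transcript-length
    rank: positive values favor short genes, negative favor long genes, 0 is
    uniform. The two longevity labels carry their own biases; the defaults
    plant the pattern reported for curated longevity catalogs (pro-longevity
    genes skewed long, anti-longevity genes skewed short).
    """

    n_terms: int = 300
    term_size_min: int = 10
    term_size_max: int = 100
    length_bias: float = 0.0
    pro_longevity_bias: float = -0.9
    anti_longevity_bias: float = 0.9
    longevity_set_size: int = 300
    bias_steepness: float = 10.0


@dataclass(frozen=True)
class SyntheticSpec:
    """Full description of one synthetic study.

    Parameters
    ----------
    n_genes, samples_per_group, n_cohorts
        Design sizes. Six replicates per group in two cohorts mirrors the
        kind of mouse survey the statistics are aimed at.
    target_rho
        Planted Spearman correlation between log10 transcript length and the
        true log2 fold change, in [-1, 1].
    fc_sd
        Standard deviation of true log2 fold changes (log2 units).
    depth
        Expected total counts per sample.
    dispersion
        Negative-binomial dispersion phi in ``var = mu + phi*mu^2``.
    length_log10_mean, length_log10_sd
        Log-normal transcript-length parameters (log10 bp).
    expr_log10_sd
        Spread of baseline expression (log10 units).
    expr_length_coupling
        Correlation-like coupling between length rank and baseline
        expression; 0 (default) keeps them independent.
    """

    n_genes: int = 10_000
    samples_per_group: int = 6
    n_cohorts: int = 2
    target_rho: float = -0.3
    fc_sd: float = 0.25
    depth: float = 5e6
    dispersion: float = 0.05
    length_log10_mean: float = 3.4
    length_log10_sd: float = 0.45
    expr_log10_sd: float = 0.8
    expr_length_coupling: float = 0.0
    n_tf_features: int = 10
    n_mirna_features: int = 10
    binary_feature_freq: float = 0.1
    seed: int = 0
    annotations: AnnotationSpec = field(default_factory=AnnotationSpec)

    def __post_init__(self) -> None:
        if not -1.0 <= self.target_rho <= 1.0:
            raise ParameterError("target_rho must be in [-1, 1]")
        if self.fc_sd < 0:
            raise ParameterError("fc_sd must be >= 0")
        if self.dispersion < 0:
            raise ParameterError("dispersion must be >= 0")
        if self.depth <= 0:
            raise ParameterError("depth must be > 0")
        if self.n_genes < 1 or self.samples_per_group < 1 or self.n_cohorts < 1:
            raise ParameterError("design sizes must be positive")
        if self.length_log10_sd <= 0 or self.expr_log10_sd <= 0:
            raise ParameterError("distribution sd parameters must be > 0")
        ann = self.annotations
        if ann.term_size_min < 1 or ann.term_size_max < ann.term_size_min:
            raise ParameterError("invalid term size range")
        if ann.term_size_max > self.n_genes:
            raise ParameterError("term_size_max exceeds n_genes")

    def with_(self, **kwargs) -> "SyntheticSpec":
        return replace(self, **kwargs)


@dataclass
class TrueEffects:
    """Ground truth planted by :func:`generate_counts`.

    ``log2fc`` is the per-gene true log2 fold change (old over young);
    ``baseline`` is the per-gene expected count at reference depth, before
    group scaling. Both share the companion gene table's ordering.
    """

    log2fc: pd.Series
    baseline: pd.Series


def _rng(spec: SyntheticSpec, key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(spec.seed, spawn_key=(key,)))


def spearman_to_latent(rho: float) -> float:
    """Latent Gaussian correlation giving Spearman ``rho`` under the copula."""
    return 2.0 * math.sin(math.pi * rho / 6.0)


def generate_gene_table(spec: SyntheticSpec) -> pd.DataFrame:
    """Draw a gene feature table of ``spec.n_genes`` rows.

    Transcript lengths are log-normal in log10 space; gene length expands the
    transcript by a random intronic factor and the CDS is a random fraction of
    the transcript, so ``gene_length >= transcript_length >= cds_length >= 1``
    holds by construction. Binary TF-binding (``tf_*``) and miRNA-binding
    (``mir_*``) decoy columns are independent Bernoulli draws at
    ``spec.binary_feature_freq``.
    """
    rng = _rng(spec, _GENE_TABLE_KEY)
    n = spec.n_genes
    tx_len = np.maximum(
        np.round(10 ** rng.normal(spec.length_log10_mean, spec.length_log10_sd, n)), 1
    )
    intron_factor = 1.0 + rng.gamma(shape=1.5, scale=3.0, size=n)
    gene_len = np.maximum(np.round(tx_len * intron_factor), tx_len)
    cds_frac = rng.beta(5.0, 3.0, n)
    cds_len = np.clip(np.round(tx_len * cds_frac), 1, tx_len)
    gc = np.clip(rng.normal(0.46, 0.05, n), 0.25, 0.75)
    n_exons = 1 + rng.poisson(np.clip(gene_len / 5000.0, 0.3, 40.0))
    width = len(str(n))
    table = pd.DataFrame(
        {
            "transcript_length": tx_len.astype(np.int64),
            "gene_length": gene_len.astype(np.int64),
            "cds_length": cds_len.astype(np.int64),
            "gc_content": gc,
            "n_exons": n_exons.astype(np.int64),
        },
        index=pd.Index([f"g{i:0{width}d}" for i in range(1, n + 1)], name="gene_id"),
    )
    binary = {
        f"{prefix}_{j:03d}": rng.binomial(1, spec.binary_feature_freq, n)
        for prefix, count in (("tf", spec.n_tf_features), ("mir", spec.n_mirna_features))
        for j in range(1, count + 1)
    }
    table = pd.concat([table, pd.DataFrame(binary, index=table.index)], axis=1)
    return validate_gene_table(table)


def _length_normal_scores(lengths: np.ndarray) -> np.ndarray:
    ranks = rankdata(lengths, method="average")
    return ndtri((ranks - 0.5) / len(lengths))


def generate_counts(
    genes: pd.DataFrame, spec: SyntheticSpec
) -> tuple[CountMatrix, TrueEffects]:
    """Simulate counts for a young and an old group over ``genes``.

    True log2 fold changes are constructed jointly with transcript-length
    ranks through the Gaussian copula described in the module docstring, so
    ``Spearman(log2fc, transcript_length)`` targets ``spec.target_rho``.
    Young-group means scale baseline expression to ``spec.depth``; old-group
    means multiply them by ``2**log2fc``. Cohort labels are assigned
    round-robin within each group.
    """
    if spec.n_cohorts > 1 and spec.samples_per_group < 2:
        raise ConfigurationError(
            "cohort structure requires at least 2 samples per group"
        )
    rng = _rng(spec, _COUNTS_KEY)
    n = len(genes)
    z_len = _length_normal_scores(genes["transcript_length"].to_numpy(dtype=float))
    r = spearman_to_latent(spec.target_rho)
    z_fc = r * z_len + math.sqrt(max(0.0, 1.0 - r * r)) * rng.standard_normal(n)
    log2fc = spec.fc_sd * z_fc

    z_expr = rng.standard_normal(n)
    if spec.expr_length_coupling:
        c = spec.expr_length_coupling
        z_expr = c * z_len + math.sqrt(max(0.0, 1.0 - c * c)) * z_expr
    baseline = 10 ** (spec.expr_log10_sd * z_expr)

    mu_young = spec.depth * baseline / baseline.sum()
    mu_old = mu_young * 2.0**log2fc
    # keep expected library size at `depth` for both groups; the transcriptome-
    # wide normalization downstream absorbs this constant
    mu_old *= spec.depth / mu_old.sum()

    k = spec.samples_per_group
    names, columns = [], []
    for group, mu in (("young", mu_young), ("old", mu_old)):
        for i in range(k):
            if spec.dispersion == 0:
                col = rng.poisson(mu)
            else:
                size = 1.0 / spec.dispersion
                col = rng.negative_binomial(size, size / (size + mu))
            names.append(f"{group}_{i + 1}")
            columns.append(col)
    counts = pd.DataFrame(
        np.column_stack(columns).astype(np.int64), index=genes.index, columns=names
    )
    samples = pd.DataFrame(
        {
            "age_group": ["young"] * k + ["old"] * k,
            "cohort": [f"c{i % spec.n_cohorts + 1}" for i in range(k)] * 2,
            "tissue": "T1",
        },
        index=pd.Index(names, name="sample_id"),
    )
    effects = TrueEffects(
        log2fc=pd.Series(log2fc, index=genes.index, name="log2fc"),
        baseline=pd.Series(mu_young, index=genes.index, name="baseline"),
    )
    return CountMatrix(counts, samples), effects


def generate_tissue_panel(
    spec: SyntheticSpec, tissue_rhos: dict[str, float]
) -> tuple[pd.DataFrame, CountMatrix, dict[str, TrueEffects]]:
    """Simulate several tissues sharing one gene table.

    Each tissue gets its own planted correlation from ``tissue_rhos`` and its
    own derived seed; sample ids are suffixed with the tissue name and the
    metadata ``tissue`` column set accordingly. Returns the shared gene table,
    a combined count matrix, and per-tissue ground truth.
    """
    genes = generate_gene_table(spec)
    frames, metas, truth = [], [], {}
    for i, (tissue, rho) in enumerate(sorted(tissue_rhos.items())):
        sub = spec.with_(target_rho=rho, seed=spec.seed + 100_003 * (i + 1))
        cm, eff = generate_counts(genes, sub)
        renamed = cm.counts.add_suffix(f"_{tissue}")
        meta = cm.samples.copy()
        meta.index = [f"{s}_{tissue}" for s in meta.index]
        meta.index.name = "sample_id"
        meta["tissue"] = tissue
        frames.append(renamed)
        metas.append(meta)
        truth[tissue] = eff
    combined = CountMatrix(pd.concat(frames, axis=1), pd.concat(metas))
    return genes, combined, truth


def plant_annotations(genes: pd.DataFrame, spec: SyntheticSpec) -> GeneSetCollection:
    """Plant a gene-set collection with tunable length bias.

    Membership weight for a gene at length rank-quantile ``u`` is the logistic
    ``sigmoid(bias * steepness * (0.5 - u))``: bias 0 gives uniform sampling,
    positive bias favors short genes, negative favors long ones. Terms
    ``term_0001..`` use ``length_bias``; the two special labels
    ``pro_longevity`` and ``anti_longevity`` use their own biases and may
    overlap (a gene can carry both).
    """
    ann = spec.annotations
    if ann.term_size_max > len(genes):
        raise ParameterError("term_size_max exceeds the number of genes")
    rng = _rng(spec, _ANNOTATION_KEY)
    gene_ids = genes.index.to_numpy()
    u = rankdata(genes["transcript_length"].to_numpy(dtype=float), method="average")
    u = (u - 0.5) / len(genes)

    def weights(bias: float) -> np.ndarray:
        w = expit(bias * ann.bias_steepness * (0.5 - u))
        return w / w.sum()

    collection = GeneSetCollection()
    w_terms = weights(ann.length_bias)
    for t in range(1, ann.n_terms + 1):
        size = int(rng.integers(ann.term_size_min, ann.term_size_max + 1))
        members = rng.choice(gene_ids, size=size, replace=False, p=w_terms)
        collection.add(f"term_{t:04d}", f"synthetic term {t}", members)
    for label, bias in (
        ("pro_longevity", ann.pro_longevity_bias),
        ("anti_longevity", ann.anti_longevity_bias),
    ):
        members = rng.choice(
            gene_ids, size=min(ann.longevity_set_size, len(genes)), replace=False,
            p=weights(bias),
        )
        collection.add(label, label.replace("_", "-") + " genes", members)
    return collection
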