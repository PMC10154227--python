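"""Relative fold changes and a lightweight differential-expression test.

All fold changes here are *relative*: because each sample is normalized
against its whole transcriptome, a gene's log2 ratio depends on every other
gene, and a relative fold increase can coexist with an absolute decrease in
molecule numbers. Three flavors are provided:

* :func:`group_fold_changes` — mean normalized signal per group, pseudocount
  guarded, for replicated designs;
* :func:`pairwise_fold_changes` — raw-count log2 ratios between two single
  individuals, restricted to genes detected in both, with no pseudocount and
  no normalization;
* :func:`pseudobulk_fold_changes` — single-cell counts summed within each
  group before taking the ratio.

:func:`simple_de` is a deliberately lightweight per-gene test (Welch t on
log2 normalized counts, BH-adjusted). It is *not* a negative-binomial DE
model; downstream statistics use it only through significance flags and
directions, never through exact gene lists.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from ._errors import ConfigurationError, DegenerateDataError, ParameterError
from .ioformats import CountMatrix

logger = logging.getLogger(__name__)


@dataclass
class FoldChangeSet:
    """Per-gene log2 relative fold changes with optional test columns.

    ``table`` is indexed by gene id with column ``log2fc`` and optionally
    ``p``, ``padj`` and ``mean_expr``. Genes failing the detection rule are
    absent, never zero-filled. ``metadata`` records the comparison label,
    normalization method and detection rule.
    """

    table: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if "log2fc" not in self.table.columns:
            raise ParameterError("FoldChangeSet table needs a log2fc column")
        if not np.isfinite(self.table["log2fc"].to_numpy()).all():
            raise ParameterError("non-finite log2fc")
        if "p" in self.table.columns and "padj" in self.table.columns:
            p = self.table["p"].to_numpy()
            padj = self.table["padj"].to_numpy()
            if (padj + 1e-12 < p).any():
                raise ParameterError("padj must be >= p element-wise")

    @property
    def log2fc(self) -> pd.Series:
        return self.table["log2fc"]

    @property
    def gene_ids(self) -> pd.Index:
        return self.table.index

    def __len__(self) -> int:
        return len(self.table)


# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------


def normalize(counts: CountMatrix | pd.DataFrame, method: str = "median_of_ratios") -> pd.DataFrame:
    """Normalize raw counts per sample.

    ``cpm`` scales each column to one million; ``median_of_ratios`` divides
    each column by its size factor, the median over all-positive genes of the
    count over that gene's geometric mean across samples.
    """
    mat = counts.counts if isinstance(counts, CountMatrix) else counts
    if mat.shape[1] < 1:
        raise ParameterError("need at least one sample")
    arr = mat.to_numpy(dtype=float)
    if method == "cpm":
        colsums = arr.sum(axis=0)
        if (colsums == 0).any():
            raise DegenerateDataError("sample with zero total counts")
        return pd.DataFrame(arr * 1e6 / colsums, index=mat.index, columns=mat.columns)
    if method == "median_of_ratios":
        all_positive = (arr > 0).all(axis=1)
        if not all_positive.any():
            raise DegenerateDataError(
                "median_of_ratios needs at least one gene with nonzero counts in "
                "all samples; consider method='cpm'"
            )
        sub = arr[all_positive]
        log_geomean = np.log(sub).mean(axis=1)
        size_factors = np.exp(np.median(np.log(sub) - log_geomean[:, None], axis=0))
        return pd.DataFrame(arr / size_factors, index=mat.index, columns=mat.columns)
    raise ParameterError(f"unknown normalization method {method!r}")


def _resolve_normalized(counts: CountMatrix, sample_ids: Sequence[str], method: str) -> pd.DataFrame:
    sub = counts.counts[list(sample_ids)]
    if method == "median_of_ratios":
        try:
            return normalize(sub, "median_of_ratios")
        except DegenerateDataError:
            logger.warning("median_of_ratios unavailable; falling back to cpm")
            return normalize(sub, "cpm")
    return normalize(sub, method)


# ---------------------------------------------------------------------------
# Fold changes
# ---------------------------------------------------------------------------


def _check_groups(old_ids: Sequence[str], young_ids: Sequence[str]) -> None:
    if not len(old_ids) or not len(young_ids):
        raise ParameterError("both groups must be nonempty")
    overlap = set(old_ids) & set(young_ids)
    if overlap:
        raise ParameterError(f"groups overlap: {sorted(overlap)}")


def group_fold_changes(
    counts: CountMatrix,
    old_ids: Sequence[str],
    young_ids: Sequence[str],
    min_detect: int = 1,
    pseudocount: float = 0.5,
    normalization: str = "median_of_ratios",
) -> FoldChangeSet:
    """Group-wise log2 relative fold changes (old over young).

    ``log2fc = log2((mean_norm_old + pc) / (mean_norm_young + pc))`` over
    genes with raw count > 0 in at least ``min_detect`` samples of *each*
    group.
    """
    _check_groups(old_ids, young_ids)
    old_ids, young_ids = list(old_ids), list(young_ids)
    raw = counts.counts
    detected = ((raw[old_ids] > 0).sum(axis=1) >= min_detect) & (
        (raw[young_ids] > 0).sum(axis=1) >= min_detect
    )
    norm = _resolve_normalized(counts, old_ids + young_ids, normalization)
    norm = norm.loc[detected]
    mean_old = norm[old_ids].mean(axis=1)
    mean_young = norm[young_ids].mean(axis=1)
    log2fc = np.log2(mean_old + pseudocount) - np.log2(mean_young + pseudocount)
    table = pd.DataFrame(
        {"log2fc": log2fc, "mean_expr": norm.mean(axis=1)}, index=norm.index
    )
    return FoldChangeSet(
        table,
        metadata={
            "comparison": "old_vs_young",
            "old_ids": old_ids,
            "young_ids": young_ids,
            "normalization": normalization,
            "detection": f"raw>0 in >= {min_detect} samples per group",
            "pseudocount": pseudocount,
        },
    )


def pairwise_fold_changes(sample_a: pd.Series, sample_b: pd.Series) -> FoldChangeSet:
    """Raw-count log2 ratio between two individuals (a over b).

    Restricted to genes detected (count > 0) in *both* samples; no
    pseudocount and no normalization.
    """
    shared = sample_a.index.intersection(sample_b.index)
    a = sample_a.loc[shared].to_numpy(dtype=float)
    b = sample_b.loc[shared].to_numpy(dtype=float)
    keep = (a > 0) & (b > 0)
    if not keep.any():
        logger.warning("pairwise_fold_changes: no gene detected in both samples")
    table = pd.DataFrame({"log2fc": np.log2(a[keep] / b[keep])}, index=shared[keep])
    return FoldChangeSet(
        table,
        metadata={
            "comparison": f"{sample_a.name}_vs_{sample_b.name}",
            "normalization": "none",
            "detection": "raw>0 in both individuals",
            "pseudocount": 0.0,
        },
    )


def pseudobulk_fold_changes(
    cell_counts: CountMatrix,
    old_cell_ids: Sequence[str],
    young_cell_ids: Sequence[str],
) -> FoldChangeSet:
    """Pseudobulk log2 ratio: summed raw counts old over young.

    The gene universe is genes detected in at least one cell of either group;
    the ratio is reported for genes whose summed count is positive in both
    groups.
    """
    _check_groups(old_cell_ids, young_cell_ids)
    raw = cell_counts.counts
    old_sum = raw[list(old_cell_ids)].sum(axis=1)
    young_sum = raw[list(young_cell_ids)].sum(axis=1)
    universe = (old_sum + young_sum) > 0
    keep = (old_sum > 0) & (young_sum > 0)
    table = pd.DataFrame(
        {"log2fc": np.log2(old_sum[keep] / young_sum[keep])}, index=raw.index[keep]
    )
    return FoldChangeSet(
        table,
        metadata={
            "comparison": "pseudobulk_old_vs_young",
            "normalization": "none",
            "detection": "summed raw>0 in both groups",
            "n_universe": int(universe.sum()),
            "pseudocount": 0.0,
        },
    )


# ---------------------------------------------------------------------------
# Lightweight differential expression
# ---------------------------------------------------------------------------


def benjamini_hochberg(pvalues: Sequence[float] | np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment (monotone, capped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if (p <= 0).any() or (p > 1).any() or not np.isfinite(p).all():
        raise ParameterError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def simple_de(
    counts: CountMatrix,
    old_ids: Sequence[str],
    young_ids: Sequence[str],
    alpha: float = 0.05,
    min_detect: int = 1,
    pseudocount: float = 0.5,
    normalization: str = "median_of_ratios",
) -> FoldChangeSet:
    """Per-gene Welch test on log2(normalized + 0.5), BH-adjusted.

    A deliberately simple stand-in for a count-model DE tool: adequate for
    significance flags and directions on synthetic data, not for exact gene
    lists. Requires at least two samples per group.
    """
    _check_groups(old_ids, young_ids)
    if len(old_ids) < 2 or len(young_ids) < 2:
        raise ConfigurationError(
            "simple_de needs >= 2 samples per group; use pairwise_fold_changes "
            "for single individuals"
        )
    base = group_fold_changes(
        counts, old_ids, young_ids,
        min_detect=min_detect, pseudocount=pseudocount, normalization=normalization,
    )
    norm = _resolve_normalized(counts, list(old_ids) + list(young_ids), normalization)
    norm = norm.loc[base.gene_ids]
    log_old = np.log2(norm[list(old_ids)].to_numpy() + 0.5)
    log_young = np.log2(norm[list(young_ids)].to_numpy() + 0.5)
    with np.errstate(divide="ignore", invalid="ignore"):
        _, p = stats.ttest_ind(log_old, log_young, axis=1, equal_var=False)
    # zero-variance rows: identical groups get p=1, separated ones p->tiny
    nan = ~np.isfinite(p)
    if nan.any():
        diff = log_old.mean(axis=1) - log_young.mean(axis=1)
        p = np.where(nan & (np.abs(diff) < 1e-12), 1.0, p)
        p = np.where(~np.isfinite(p), np.finfo(float).tiny, p)
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    padj = benjamini_hochberg(p)
    table = base.table.assign(p=p, padj=padj, significant=padj < alpha)
    meta = dict(base.metadata, test="welch_log2", alpha=alpha)
    return FoldChangeSet(table, metadata=meta)


def write_fold_changes(fc: FoldChangeSet, path) -> None:
    """Write the fold-change table as TSV with a JSON metadata sidecar."""
    import json
    from pathlib import Path

    path = Path(path)
    fc.table.rename_axis("gene_id").to_csv(path, sep="\t")
    Path(str(path) + ".meta.json").write_text(json.dumps(fc.metadata, indent=2, default=str))
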