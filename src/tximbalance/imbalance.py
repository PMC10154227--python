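"""The length-correlation statistic rho_TI and its companions.

``rho_TI`` is the Spearman rank correlation between per-gene transcript
length and per-gene log2 relative fold change, computed genome-wide rather
than over a significance-filtered subset. Its two-sided significance uses the
t-approximation ``t = rho * sqrt((n-2)/(1-rho^2))`` with ``n-2`` degrees of
freedom, which is accurate for the thousands of genes a transcriptome
provides; :mod:`tximbalance.resampling` quantifies its small-n behavior
against permutation.

Companions:

* :func:`median_length_difference` — the alternative quantification through
  the difference in median transcript length between significantly up- and
  down-regulated genes, tested with a two-sided Mann-Whitney U;
* :func:`lowess_residual_rho` — a robustness check: after removing a LOWESS
  fit of fold change on log10 length, no residual length correlation should
  remain if length alone accounts for the signal;
* :func:`compare_two_correlations` — Fisher z test for the difference of two
  independent correlations;
* :func:`run_imbalance_survey` — rho_TI across every (tissue, age) pair
  against a reference age.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.nonparametric.smoothers_lowess import lowess

from ._errors import DegenerateDataError, InsufficientDataError, ParameterError
from .foldchange import FoldChangeSet, group_fold_changes
from .ioformats import CountMatrix

logger = logging.getLogger(__name__)

_LENGTH_COLUMN = {
    "transcript": "transcript_length",
    "gene": "gene_length",
    "cds": "cds_length",
}


@dataclass
class ImbalanceResult:
    """A length correlation: rho in [-1, 1], two-sided p, genes used."""

    rho: float
    p: float
    n: int
    length_kind: str
    metadata: dict = field(default_factory=dict)


@dataclass
class MedianLengthDiffResult:
    """Median transcript length of up- vs down-regulated genes (bp)."""

    median_length_up: float
    median_length_down: float
    difference: float
    U: float
    p: float
    n_up: int
    n_down: int
    length_kind: str


def _aligned_length_fc(
    fc: FoldChangeSet, genes: pd.DataFrame, length_kind: str
) -> tuple[np.ndarray, np.ndarray]:
    try:
        col = _LENGTH_COLUMN[length_kind]
    except KeyError:
        raise ParameterError(f"length_kind must be one of {sorted(_LENGTH_COLUMN)}") from None
    shared = fc.gene_ids.intersection(genes.index)
    lengths = genes.loc[shared, col].to_numpy(dtype=float)
    values = fc.table.loc[shared, "log2fc"].to_numpy(dtype=float)
    return lengths, values


def rho_ti(fc: FoldChangeSet, genes: pd.DataFrame, length_kind: str = "transcript") -> ImbalanceResult:
    """Spearman correlation between length and log2 relative fold change.

    Ties get average ranks; the two-sided p comes from the t-approximation.
    Raises :class:`DegenerateDataError` when either variable is constant
    (correlation undefined) instead of propagating NaN.
    """
    lengths, values = _aligned_length_fc(fc, genes, length_kind)
    n = len(values)
    if n < 3:
        raise InsufficientDataError(f"rho_ti needs >= 3 shared genes, got {n}")
    if np.ptp(values) == 0 or np.ptp(lengths) == 0:
        raise DegenerateDataError(
            "correlation undefined: fold changes or lengths are all identical"
        )
    rho, p = stats.spearmanr(lengths, values)
    return ImbalanceResult(
        rho=float(rho), p=float(p), n=n, length_kind=length_kind,
        metadata=dict(fc.metadata),
    )


def mann_whitney_u(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Two-sided Mann-Whitney U for the first sample.

    Exact tie-aware enumeration when both samples have at most 8 values
    (two-sided p = ``2 * min(P(U <= u), P(U >= u))`` capped at 1); otherwise
    the tie-corrected normal approximation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise InsufficientDataError("mann_whitney_u requires nonempty samples")
    n, m = len(x), len(y)
    if n <= 8 and m <= 8:
        pooled = np.concatenate([x, y])
        ranks = stats.rankdata(pooled)
        u_obs = ranks[:n].sum() - n * (n + 1) / 2.0
        us = np.array(
            [sum(ranks[list(c)]) for c in itertools.combinations(range(n + m), n)]
        ) - n * (n + 1) / 2.0
        p_le = np.mean(us <= u_obs + 1e-9)
        p_ge = np.mean(us >= u_obs - 1e-9)
        p = min(1.0, 2.0 * min(p_le, p_ge))
        return float(u_obs), float(p)
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return float(res.statistic), float(res.pvalue)


def median_length_difference(
    de: FoldChangeSet,
    genes: pd.DataFrame,
    alpha: float = 0.05,
    length_kind: str = "transcript",
) -> MedianLengthDiffResult:
    """Difference in median length between significantly up and down genes.

    Requires a fold-change set carrying ``padj``; genes with ``padj < alpha``
    are split by fold-change sign and their length distributions compared
    with a two-sided Mann-Whitney U test.
    """
    if "padj" not in de.table.columns:
        raise ParameterError("median_length_difference needs a padj column")
    col = _LENGTH_COLUMN.get(length_kind)
    if col is None:
        raise ParameterError(f"length_kind must be one of {sorted(_LENGTH_COLUMN)}")
    sig = de.table[de.table["padj"] < alpha]
    up = sig.index[sig["log2fc"] > 0].intersection(genes.index)
    down = sig.index[sig["log2fc"] < 0].intersection(genes.index)
    if len(up) == 0 or len(down) == 0:
        raise InsufficientDataError(
            f"need significant genes in both directions (up={len(up)}, down={len(down)})"
        )
    len_up = genes.loc[up, col].to_numpy(dtype=float)
    len_down = genes.loc[down, col].to_numpy(dtype=float)
    U, p = mann_whitney_u(len_up, len_down)
    mu, md = float(np.median(len_up)), float(np.median(len_down))
    return MedianLengthDiffResult(
        median_length_up=mu, median_length_down=md, difference=mu - md,
        U=U, p=p, n_up=len(up), n_down=len(down), length_kind=length_kind,
    )


def lowess_residual_rho(
    fc: FoldChangeSet,
    genes: pd.DataFrame,
    frac: float = 0.3,
    length_kind: str = "transcript",
) -> ImbalanceResult:
    """Length correlation of the residuals after LOWESS on log10 length.

    Fits a LOWESS of log2 fold change on log10 length with smoothing fraction
    ``frac`` and returns rho_TI of the residuals. If length alone drives the
    imbalance, the residual correlation vanishes.
    """
    if not 0 < frac <= 1:
        raise ParameterError("frac must lie in (0, 1]")
    lengths, values = _aligned_length_fc(fc, genes, length_kind)
    if len(values) < 30:
        raise InsufficientDataError("lowess_residual_rho needs >= 30 genes")
    log_len = np.log10(lengths)
    fitted = lowess(values, log_len, frac=frac, return_sorted=False)
    residuals = values - fitted
    if np.ptp(residuals) == 0:
        raise DegenerateDataError("residuals are constant after LOWESS fit")
    rho, p = stats.spearmanr(lengths, residuals)
    return ImbalanceResult(
        rho=float(rho), p=float(p), n=len(values), length_kind=length_kind,
        metadata=dict(fc.metadata, lowess_frac=frac, residualized=True),
    )


def compare_two_correlations(rho1: float, n1: int, rho2: float, n2: int) -> float:
    """Fisher z test for the difference between two independent correlations."""
    for rho in (rho1, rho2):
        if abs(rho) >= 1:
            raise ParameterError("|rho| must be < 1 (z-transform diverges)")
    if n1 < 4 or n2 < 4:
        raise InsufficientDataError("need n >= 4 in both samples")
    z1, z2 = math.atanh(rho1), math.atanh(rho2)
    z = (z1 - z2) / math.sqrt(1.0 / (n1 - 3) + 1.0 / (n2 - 3))
    return float(2.0 * stats.norm.sf(abs(z)))


def run_imbalance_survey(
    counts: CountMatrix,
    genes: pd.DataFrame,
    reference_age: str = "young",
    alpha: float = 0.01,
    length_kinds: Sequence[str] = ("transcript",),
    min_detect: int = 1,
    pseudocount: float = 0.5,
    normalization: str = "median_of_ratios",
) -> pd.DataFrame:
    """rho_TI for every tissue x non-reference age against the reference age.

    Returns one row per (tissue, age, length_kind) with columns ``n``,
    ``rho``, ``p`` and ``flag`` in {negative, positive, ns}; flags use the
    uncorrected two-sided p at ``alpha`` (default 0.01). Tissues lacking
    reference-age samples are skipped with a warning.
    """
    meta = counts.samples
    rows = []
    for tissue in pd.unique(meta["tissue"]):
        in_tissue = meta[meta["tissue"] == tissue]
        ref_ids = in_tissue.index[in_tissue["age_group"] == reference_age]
        if len(ref_ids) == 0:
            logger.warning("tissue %s lacks reference-age samples; skipped", tissue)
            continue
        for age in pd.unique(in_tissue["age_group"]):
            if age == reference_age:
                continue
            age_ids = in_tissue.index[in_tissue["age_group"] == age]
            fc = group_fold_changes(
                counts, list(age_ids), list(ref_ids),
                min_detect=min_detect, pseudocount=pseudocount,
                normalization=normalization,
            )
            for kind in length_kinds:
                res = rho_ti(fc, genes, length_kind=kind)
                flag = "ns"
                if res.p < alpha:
                    flag = "negative" if res.rho < 0 else "positive"
                rows.append(
                    {
                        "tissue": tissue,
                        "age": age,
                        "comparison": f"{age}_vs_{reference_age}",
                        "length_kind": kind,
                        "n": res.n,
                        "rho": res.rho,
                        "p": res.p,
                        "flag": flag,
                    }
                )
    return pd.DataFrame(rows)
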