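"""Same-age permutation nulls, pairwise surveys and bootstrap intervals.

The permutation null asks how large a length correlation arises *without*
any age difference: replicates of a single age are partitioned into two
pseudo-groups, fold changes computed between the halves, and rho_TI measured
on each split. Splits are *ordered* (every (A, B) is accompanied by (B, A)),
which makes the null exactly symmetric around zero — swapping the groups
negates every fold change and hence the correlation.

Observed tissue correlations are compared against the null with a two-sided
Mann-Whitney U test. Fractions of tissues/pairs showing the phenomenon are
given 95% bootstrap confidence intervals by Bernoulli resampling: each of
``B`` replicates redraws the n trials independently at the observed success
rate and the 2.5/97.5 percentiles of the replicate fractions form the
interval.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from ._errors import DegenerateDataError, InsufficientDataError, ParameterError
from .foldchange import group_fold_changes, pairwise_fold_changes
from .imbalance import mann_whitney_u, rho_ti
from .ioformats import CountMatrix

logger = logging.getLogger(__name__)


@dataclass
class PermutationNull:
    """Null rho_TI distribution from ordered same-age splits.

    ``splits`` has one row per ordered split with the member ids, rho, p and
    a ``degenerate`` flag; degenerate splits (constant fold changes, e.g.
    duplicated samples) are excluded from :meth:`rhos`.
    """

    tissue: str
    age: str
    splits: pd.DataFrame
    mode: str = "ordered"

    def rhos(self) -> np.ndarray:
        ok = ~self.splits["degenerate"]
        return self.splits.loc[ok, "rho"].to_numpy(dtype=float)


@dataclass
class FractionCI:
    """A fraction k/n with a 95% bootstrap percentile interval."""

    k: int
    n: int
    fraction: float
    lo: float
    hi: float
    B: int


def enumerate_same_age_splits(
    sample_ids: Sequence[str], mode: str = "ordered"
) -> list[tuple[tuple[str, ...], tuple[str, ...]]]:
    """All (near-)equal ordered bipartitions of ``sample_ids``.

    Group A takes ``ceil(n/2)`` or ``floor(n/2)`` members, B the complement.
    In the default ordered mode every split's mirror is present, so a
    statistic antisymmetric under group swap has an exactly symmetric null.
    ``mode="unordered"`` keeps one representative per mirror pair.
    """
    ids = tuple(sample_ids)
    n = len(ids)
    if n < 4:
        raise InsufficientDataError(f"need >= 4 samples to split, got {n}")
    sizes = sorted({n // 2, (n + 1) // 2})
    splits = []
    for size in sizes:
        for combo in itertools.combinations(range(n), size):
            a = tuple(ids[i] for i in combo)
            b = tuple(ids[i] for i in range(n) if i not in combo)
            splits.append((a, b))
    if mode == "unordered":
        seen, kept = set(), []
        for a, b in splits:
            key = frozenset((a, b))
            if key not in seen:
                seen.add(key)
                kept.append((a, b))
        return kept
    if mode != "ordered":
        raise ParameterError("mode must be 'ordered' or 'unordered'")
    return splits


def permutation_null_rho(
    counts: CountMatrix,
    genes: pd.DataFrame,
    tissue: str,
    age: str,
    length_kind: str = "transcript",
    mode: str = "ordered",
    min_detect: int = 1,
    pseudocount: float = 0.5,
    normalization: str = "median_of_ratios",
) -> PermutationNull:
    """rho_TI over every same-age split of one tissue's replicates."""
    meta = counts.samples
    ids = meta.index[(meta["tissue"] == tissue) & (meta["age_group"] == age)]
    rows = []
    for a, b in enumerate_same_age_splits(list(ids), mode=mode):
        row = {"group_a": ",".join(a), "group_b": ",".join(b)}
        try:
            fc = group_fold_changes(
                counts, list(a), list(b),
                min_detect=min_detect, pseudocount=pseudocount,
                normalization=normalization,
            )
            res = rho_ti(fc, genes, length_kind=length_kind)
            row.update(rho=res.rho, p=res.p, degenerate=False)
        except DegenerateDataError:
            row.update(rho=np.nan, p=np.nan, degenerate=True)
        rows.append(row)
    splits = pd.DataFrame(rows)
    n_degenerate = int(splits["degenerate"].sum())
    if n_degenerate:
        logger.info("permutation null: %d degenerate split(s) flagged", n_degenerate)
    if n_degenerate == len(splits):
        raise DegenerateDataError("all same-age splits are degenerate")
    return PermutationNull(tissue=tissue, age=age, splits=splits, mode=mode)


def compare_observed_to_null(
    observed_rhos: Sequence[float], null_rhos: Sequence[float]
) -> tuple[float, float]:
    """Two-sided Mann-Whitney U of observed correlations against the null."""
    return mann_whitney_u(observed_rhos, null_rhos)


@dataclass
class PairwiseSurveyResult:
    """Per-pair rho_TI between individual old and reference animals."""

    pairs: pd.DataFrame
    fraction_negative: float


def pairwise_survey(
    counts: CountMatrix,
    genes: pd.DataFrame,
    tissue: str,
    age: str,
    reference_age: str = "young",
    length_kind: str = "transcript",
) -> PairwiseSurveyResult:
    """rho_TI for every (old individual, reference individual) pair.

    Fold changes are raw-count log2 ratios over genes detected in both
    individuals; the summary is the fraction of pairs with negative rho.
    """
    meta = counts.samples
    in_tissue = meta["tissue"] == tissue
    old_ids = meta.index[in_tissue & (meta["age_group"] == age)]
    ref_ids = meta.index[in_tissue & (meta["age_group"] == reference_age)]
    if len(old_ids) == 0 or len(ref_ids) == 0:
        raise InsufficientDataError("need >= 1 sample per age group")
    rows = []
    for o in old_ids:
        for r in ref_ids:
            fc = pairwise_fold_changes(counts.counts[o], counts.counts[r])
            res = rho_ti(fc, genes, length_kind=length_kind)
            rows.append({"old": o, "reference": r, "n": res.n, "rho": res.rho, "p": res.p})
    pairs = pd.DataFrame(rows)
    return PairwiseSurveyResult(
        pairs=pairs, fraction_negative=float((pairs["rho"] < 0).mean())
    )


def bootstrap_fraction_ci(
    k: int, n: int, B: int = 1000, seed: int | None = None
) -> FractionCI:
    """95% bootstrap interval for an observed fraction k/n.

    Each replicate redraws the n trials as independent Bernoulli(k/n); the
    interval is the 2.5/97.5 percentile of the B replicate fractions.
    """
    if n < 1:
        raise ParameterError("n must be >= 1")
    if not 0 <= k <= n:
        raise ParameterError("k must satisfy 0 <= k <= n")
    rng = np.random.default_rng(seed)
    frac = k / n
    sims = rng.binomial(n, frac, size=B) / n
    lo, hi = np.percentile(sims, [2.5, 97.5])
    return FractionCI(k=k, n=n, fraction=frac, lo=float(lo), hi=float(hi), B=B)


def summarize_survey(
    survey: pd.DataFrame, B: int = 1000, seed: int | None = None
) -> pd.DataFrame:
    """Tally survey flags per (age, length_kind) with bootstrap CIs.

    For each flag category (negative / positive / ns) reports k, n, the
    fraction of tissues and its 95% bootstrap interval.
    """
    rows = []
    for (age, kind), sub in survey.groupby(["age", "length_kind"]):
        n = len(sub)
        for flag in ("negative", "positive", "ns"):
            k = int((sub["flag"] == flag).sum())
            ci = bootstrap_fraction_ci(k, n, B=B, seed=seed)
            rows.append(
                {
                    "age": age,
                    "length_kind": kind,
                    "flag": flag,
                    "k": k,
                    "n": n,
                    "fraction": ci.fraction,
                    "ci_lo": ci.lo,
                    "ci_hi": ci.hi,
                }
            )
    return pd.DataFrame(rows)
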