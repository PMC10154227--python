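"""Gradient-boosting feature importance for gene-level covariates.

The question this module answers: among many gene-level features (transcript
and gene lengths, GC content, exon counts, binary TF-binding and
miRNA-binding indicators), which ones carry information about the per-gene
log2 relative fold change of a comparison?

Procedure per comparison: fit an ensemble of gradient-boosting regressors
with Huber loss, each trained on an independent uniform random 90% of genes.
Held-out accuracy is the Spearman correlation between observed fold changes
and, per gene, the median prediction across the models whose training set
excluded that gene (genes excluded by no model are dropped from evaluation).
Feature importance per model is the normalized total split gain reported by
the trees; features are ranked per model (1 = most important, ties get
average ranks) and summarized by the median rank across models — and, via
:func:`aggregate_feature_ranks`, across comparisons, where a *group* of
related features (all TF sites, all miRNA sites, the three length variants)
scores by its best-ranked member.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata, spearmanr
from sklearn.ensemble import GradientBoostingRegressor

from ._errors import InsufficientDataError, ParameterError
from .foldchange import FoldChangeSet

logger = logging.getLogger(__name__)

LENGTH_FEATURES = ("transcript_length", "gene_length", "cds_length")

DEFAULT_HYPERPARAMS: dict = {
    "n_estimators": 500,
    "max_depth": 3,
    "learning_rate": 0.05,
    "huber_alpha": 0.9,
    "subsample": 1.0,
}


@dataclass
class FeatureMatrix:
    """Gene-by-feature design matrix with per-column kind and group labels.

    ``kinds`` maps each column to architecture / tf_binding / mirna_binding;
    ``groups`` assigns each column to a group of related features (used when
    ranking "the best member of a group").
    """

    values: pd.DataFrame
    kinds: pd.Series
    groups: pd.Series

    def __post_init__(self) -> None:
        if self.values.columns.has_duplicates:
            raise ParameterError("duplicate feature columns")
        if self.values.isna().any().any():
            raise ParameterError("feature matrix contains missing values")
        for series, label in ((self.kinds, "kinds"), (self.groups, "groups")):
            missing = set(self.values.columns) - set(series.index)
            if missing:
                raise ParameterError(f"{label} missing for features: {sorted(missing)}")

    @property
    def feature_names(self) -> pd.Index:
        return self.values.columns

    def drop(self, columns: Sequence[str]) -> "FeatureMatrix":
        kept = [c for c in self.values.columns if c not in set(columns)]
        if not kept:
            raise ParameterError("cannot drop all feature columns")
        return FeatureMatrix(
            self.values[kept], self.kinds.loc[kept], self.groups.loc[kept]
        )


def feature_matrix_from_gene_table(genes: pd.DataFrame) -> FeatureMatrix:
    """Assemble a :class:`FeatureMatrix` from a gene table.

    ``tf_*`` columns become kind tf_binding (one shared group), ``mir_*``
    mirna_binding (one shared group); the three length variants share the
    group ``length``; every other numeric column is architecture, its own
    group.
    """
    numeric = genes.select_dtypes(include=[np.number])
    kinds, groups = {}, {}
    for col in numeric.columns:
        if col.startswith("tf_"):
            kinds[col], groups[col] = "tf_binding", "tf_binding"
        elif col.startswith("mir_"):
            kinds[col], groups[col] = "mirna_binding", "mirna_binding"
        else:
            kinds[col] = "architecture"
            groups[col] = "length" if col in LENGTH_FEATURES else col
    return FeatureMatrix(
        numeric.astype(float), pd.Series(kinds), pd.Series(groups)
    )


@dataclass
class FeatureImportanceResult:
    """Ensemble importances, ranks and held-out accuracy for one comparison."""

    importances: pd.DataFrame  # models x features, each row sums to 1
    ranks: pd.DataFrame  # models x features, 1 = most important
    median_rank: pd.Series  # per feature, median across models
    heldout_spearman: float
    n_models: int
    n_eval_genes: int
    hyperparams: dict
    seed: int | None
    comparison: str = ""
    low_confidence: bool = False
    metadata: dict = field(default_factory=dict)


def _make_model(hyperparams: dict, random_state: int) -> GradientBoostingRegressor:
    hp = dict(DEFAULT_HYPERPARAMS, **(hyperparams or {}))
    return GradientBoostingRegressor(
        loss="huber",
        alpha=hp["huber_alpha"],
        n_estimators=int(hp["n_estimators"]),
        max_depth=int(hp["max_depth"]),
        learning_rate=hp["learning_rate"],
        subsample=hp["subsample"],
        random_state=random_state,
    )


def fit_importance_ensemble(
    features: FeatureMatrix,
    fc: FoldChangeSet,
    n_models: int = 10,
    train_frac: float = 0.9,
    hyperparams: dict | None = None,
    seed: int | None = None,
    comparison: str = "",
) -> FeatureImportanceResult:
    """Fit the gradient-boosting ensemble and score feature importance.

    Each of ``n_models`` models trains with Huber loss on an independent
    uniform ``train_frac`` sample of the genes shared between ``features``
    and ``fc``. See the module docstring for the evaluation rule.
    """
    if n_models < 1:
        raise ParameterError("n_models must be >= 1")
    if not 0 < train_frac < 1:
        raise ParameterError("train_frac must lie in (0, 1)")
    shared = features.values.index.intersection(fc.gene_ids)
    if len(shared) < 200:
        raise InsufficientDataError(
            f"need >= 200 genes after joining features and fold changes, got {len(shared)}"
        )
    X = features.values.loc[shared].to_numpy(dtype=float)
    y = fc.table.loc[shared, "log2fc"].to_numpy(dtype=float)
    n = len(shared)
    n_train = int(round(train_frac * n))
    rng = np.random.default_rng(seed)

    predictions = np.full((n, n_models), np.nan)
    importances = np.empty((n_models, X.shape[1]))
    for m in range(n_models):
        train_idx = rng.choice(n, size=n_train, replace=False)
        model = _make_model(hyperparams or {}, random_state=int(rng.integers(2**31)))
        model.fit(X[train_idx], y[train_idx])
        imp = model.feature_importances_
        total = imp.sum()
        importances[m] = imp / total if total > 0 else np.full_like(imp, 1.0 / len(imp))
        mask = np.ones(n, dtype=bool)
        mask[train_idx] = False
        if mask.any():
            predictions[mask, m] = model.predict(X[mask])

    evaluated = ~np.isnan(predictions).all(axis=1)
    n_eval = int(evaluated.sum())
    dropped = n - int((~np.isnan(predictions)).any(axis=1).sum())
    if dropped:
        logger.info("%d gene(s) excluded by no model; dropped from evaluation", dropped)
    low_confidence = False
    if n_eval < 50:
        logger.warning("only %d evaluation genes; result flagged low-confidence", n_eval)
        low_confidence = True
    if n_eval >= 3:
        median_pred = np.nanmedian(predictions[evaluated], axis=1)
        heldout = float(spearmanr(y[evaluated], median_pred)[0])
    else:
        heldout = float("nan")

    cols = features.feature_names
    imp_df = pd.DataFrame(importances, columns=cols)
    ranks = pd.DataFrame(
        np.vstack([rankdata(-row, method="average") for row in importances]),
        columns=cols,
    )
    return FeatureImportanceResult(
        importances=imp_df,
        ranks=ranks,
        median_rank=ranks.median(axis=0),
        heldout_spearman=heldout,
        n_models=n_models,
        n_eval_genes=n_eval,
        hyperparams=dict(DEFAULT_HYPERPARAMS, **(hyperparams or {})),
        seed=seed,
        comparison=comparison,
        low_confidence=low_confidence,
        metadata={"n_genes": n, "train_frac": train_frac},
    )


def aggregate_feature_ranks(
    results: Sequence[FeatureImportanceResult],
    groups: Mapping[str, str] | pd.Series | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Aggregate per-comparison ranks into feature and group tables.

    The feature table has one rank column per comparison (that comparison's
    median rank across its models) plus the median across comparisons. A
    group's rank within a comparison is the best (minimum) rank among its
    members; the group table medians those across comparisons. Both are
    sorted ascending by median rank.
    """
    if not results:
        raise ParameterError("no results to aggregate")
    universe = set(results[0].median_rank.index)
    for res in results[1:]:
        other = set(res.median_rank.index)
        if other != universe:
            diff = sorted(universe.symmetric_difference(other))
            raise ParameterError(f"inconsistent feature universes: {diff}")
    labels = [res.comparison or f"comparison_{i}" for i, res in enumerate(results)]
    feature_table = pd.DataFrame(
        {lab: res.median_rank for lab, res in zip(labels, results)}
    )
    feature_table["median_rank"] = feature_table[labels].median(axis=1)

    if groups is None:
        group_map = pd.Series({f: f for f in feature_table.index})
    else:
        group_map = pd.Series(dict(groups))
    feature_table.insert(0, "group", group_map.reindex(feature_table.index))

    group_rows = {}
    for g, members in feature_table.groupby("group").groups.items():
        per_comparison = feature_table.loc[members, labels].min(axis=0)
        group_rows[g] = per_comparison
    group_table = pd.DataFrame(group_rows).T
    group_table["median_rank"] = group_table[labels].median(axis=1)
    return (
        feature_table.sort_values("median_rank"),
        group_table.sort_values("median_rank"),
    )


@dataclass
class DropFeatureResult:
    """Held-out accuracy before and after omitting features."""

    dropped: tuple[str, ...]
    accuracy_full: float
    accuracy_dropped: float
    delta: float


def drop_feature_refit(
    features: FeatureMatrix,
    fc: FoldChangeSet,
    drop: str | Sequence[str],
    n_models: int = 10,
    train_frac: float = 0.9,
    hyperparams: dict | None = None,
    seed: int | None = None,
) -> DropFeatureResult:
    """Refit the ensemble without a feature (or feature group).

    ``drop`` may name a single column, a list of columns, or a group label
    from ``features.groups``. Returns full and reduced held-out accuracies
    and their difference; a redundant feature should cost nothing.
    """
    if isinstance(drop, str):
        if drop in features.feature_names:
            columns = [drop]
        elif (features.groups == drop).any():
            columns = list(features.groups.index[features.groups == drop])
        else:
            raise ParameterError(f"unknown feature or group {drop!r}")
    else:
        columns = list(drop)
        unknown = set(columns) - set(features.feature_names)
        if unknown:
            raise ParameterError(f"unknown feature columns: {sorted(unknown)}")
    full = fit_importance_ensemble(
        features, fc, n_models=n_models, train_frac=train_frac,
        hyperparams=hyperparams, seed=seed,
    )
    reduced = fit_importance_ensemble(
        features.drop(columns), fc, n_models=n_models, train_frac=train_frac,
        hyperparams=hyperparams, seed=seed,
    )
    return DropFeatureResult(
        dropped=tuple(columns),
        accuracy_full=full.heldout_spearman,
        accuracy_dropped=reduced.heldout_spearman,
        delta=reduced.heldout_spearman - full.heldout_spearman,
    )
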