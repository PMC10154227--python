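"""Length-extreme gene-set enrichment and the annotation-overlap network.

The genes with the shortest and longest transcripts (bottom/top 5% by
default) are the ones most poised to show a length-associated relative fold
change, so their functional annotations are interrogated directly:

* :func:`longevity_enrichment` — two-sided Fisher tests of the short and
  long extremes against pro-longevity and anti-longevity gene labels;
* :func:`opposing_enrichment` — terms significantly enriched (BH < 0.05) in
  one length extreme and simultaneously depleted in the other;
* :func:`randomization_fpr` — the false-positive control: random gene sets
  of the same sizes, drawn from the observed length distribution, should
  yield (nearly) no opposing terms;
* :func:`build_annotation_network` / :func:`simplify_network` — organize the
  qualifying terms by shared genes instead of ontology hierarchy, keeping
  one edge per node chosen by largest overlap with documented tie rules.

Fold enrichment is signed: ``n/e`` when observed >= expected, ``-e/n``
otherwise, so depletion reads as a negative magnitude; complete depletion
(n = 0) is stored as ``-inf`` and serialized as the string sentinel
``complete_depletion``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy.special import gammaln

from ._errors import DegenerateDataError, ParameterError
from .foldchange import benjamini_hochberg
from .ioformats import GeneSetCollection

logger = logging.getLogger(__name__)


@dataclass
class EnrichmentResult:
    """One 2x2 Fisher test of a query set against a term."""

    term_id: str
    term_name: str
    extreme: str  # "short" | "long" | other query label
    n_obs: int
    e_exp: float
    fold: float  # signed: n/e if n >= e else -e/n; -inf at n = 0
    p: float
    direction: str  # "enriched" | "depleted" | "none"
    padj: float | None = None
    n_query: int = 0
    n_term: int = 0
    n_background: int = 0


# ---------------------------------------------------------------------------
# Extremes and Fisher tests
# ---------------------------------------------------------------------------


def length_extremes(
    genes: pd.DataFrame, q: float = 0.05, length_kind: str = "transcript"
) -> tuple[frozenset[str], frozenset[str]]:
    """The ``floor(q*n)`` shortest and longest genes by the chosen length.

    Ties are resolved deterministically: genes are stably sorted by
    (length, gene_id) ascending; the short set is the first k rows, the long
    set the last k. The sets are disjoint for q < 0.5.
    """
    from .imbalance import _LENGTH_COLUMN

    if not 0 < q < 0.5:
        raise ParameterError("q must lie in (0, 0.5)")
    col = _LENGTH_COLUMN.get(length_kind)
    if col is None:
        raise ParameterError(f"length_kind must be one of {sorted(_LENGTH_COLUMN)}")
    k = int(np.floor(q * len(genes)))
    if k < 1:
        raise ParameterError(f"q*n = {q * len(genes):.2f} selects no genes")
    order = (
        genes[[col]]
        .assign(_gid=genes.index)
        .sort_values([col, "_gid"], kind="stable")
        .index
    )
    return frozenset(order[:k]), frozenset(order[-k:])


def _log_binom(n, k):
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def _hypergeom_pmf(x, n_background, n_term, n_query):
    """P(overlap = x) drawing ``n_query`` from ``n_background`` with ``n_term`` marked."""
    return np.exp(
        _log_binom(n_term, x)
        + _log_binom(n_background - n_term, n_query - x)
        - _log_binom(n_background, n_query)
    )


def _fisher_two_sided(a: int, n_query: int, n_term: int, n_background: int) -> float:
    """Two-sided Fisher p: total probability of tables at most as likely.

    Hypergeometric null with ``n_query`` draws from ``n_background`` of which
    ``n_term`` are marked; sums pmf(x) over the support where
    pmf(x) <= pmf(a) * (1 + 1e-7).
    """
    lo = max(0, n_query + n_term - n_background)
    hi = min(n_query, n_term)
    support = np.arange(lo, hi + 1)
    pmf = _hypergeom_pmf(support, n_background, n_term, n_query)
    p_obs = pmf[a - lo]
    return float(min(1.0, pmf[pmf <= p_obs * (1 + 1e-7)].sum()))


def _fisher_two_sided_many(
    a: np.ndarray, n_term: np.ndarray, n_query: int, n_background: int
) -> np.ndarray:
    """Vectorized :func:`_fisher_two_sided` for many terms sharing one query.

    Builds one flat support array across all terms and evaluates the
    hypergeometric pmf in a single call; per-term tail sums follow the same
    "at most as likely" rule as the scalar version.
    """
    lo = np.maximum(0, n_query + n_term - n_background)
    hi = np.minimum(n_query, n_term)
    sizes = hi - lo + 1
    term_idx = np.repeat(np.arange(len(n_term)), sizes)
    offsets = np.concatenate([[0], np.cumsum(sizes)])
    support = np.concatenate([np.arange(l, h + 1) for l, h in zip(lo, hi)])
    pmf = _hypergeom_pmf(support, n_background, n_term[term_idx], n_query)
    p_obs = pmf[offsets[:-1] + (a - lo)]
    keep = pmf <= p_obs[term_idx] * (1 + 1e-7)
    sums = np.zeros(len(n_term))
    np.add.at(sums, term_idx[keep], pmf[keep])
    return np.minimum(1.0, sums)


def fisher_enrichment(
    query: Iterable[str],
    term: Iterable[str],
    background: Iterable[str],
    term_id: str = "",
    term_name: str = "",
    extreme: str = "",
) -> EnrichmentResult:
    """Two-sided Fisher exact test of ``query`` against ``term``.

    All sets are restricted to ``background``; ``query`` must be a subset of
    it. Expected overlap under independence is
    ``|query| * |term ∩ background| / |background|``.
    """
    background = frozenset(background)
    query = frozenset(query)
    if not background:
        raise ParameterError("background must be nonempty")
    if not query <= background:
        raise ParameterError("query must be a subset of the background")
    term_in_bg = frozenset(term) & background
    if not term_in_bg:
        raise DegenerateDataError(
            f"term {term_id or term_name!r} does not intersect the background"
        )
    a = len(query & term_in_bg)
    e = len(query) * len(term_in_bg) / len(background)
    p = _fisher_two_sided(a, len(query), len(term_in_bg), len(background))
    if a >= e:
        fold = a / e
        direction = "enriched" if a > e else "none"
    else:
        fold = -e / a if a > 0 else float("-inf")
        direction = "depleted"
    return EnrichmentResult(
        term_id=term_id, term_name=term_name, extreme=extreme,
        n_obs=a, e_exp=e, fold=fold, p=p, direction=direction,
        n_query=len(query), n_term=len(term_in_bg), n_background=len(background),
    )


def longevity_enrichment(
    genes: pd.DataFrame,
    collection: GeneSetCollection,
    q: float = 0.05,
    background_mode: str = "annotated_only",
    length_kind: str = "transcript",
    pro_label: str = "pro_longevity",
    anti_label: str = "anti_longevity",
) -> dict[tuple[str, str], EnrichmentResult]:
    """Fisher tests of both length extremes against both longevity labels.

    ``background_mode="annotated_only"`` (default) restricts the universe to
    genes carrying at least one annotation in ``collection``;
    ``"all_genes"`` uses the whole gene table. Genes labeled both
    pro- and anti-longevity count in both tests. Returns a dict keyed by
    (extreme, label) with four entries.
    """
    for label in (pro_label, anti_label):
        if label not in collection:
            raise ParameterError(f"collection lacks the {label!r} term")
    if background_mode == "annotated_only":
        background = collection.annotated_genes() & frozenset(genes.index)
    elif background_mode == "all_genes":
        background = frozenset(genes.index)
    else:
        raise ParameterError("background_mode must be 'annotated_only' or 'all_genes'")
    if not background:
        raise DegenerateDataError("no labeled genes in the gene table")
    short, long_ = length_extremes(genes, q=q, length_kind=length_kind)
    out = {}
    for extreme, members in (("short", short), ("long", long_)):
        for label in (pro_label, anti_label):
            out[(extreme, label)] = fisher_enrichment(
                members & background,
                collection.genes(label),
                background,
                term_id=label,
                term_name=collection.name(label),
                extreme=extreme,
            )
    return out


# ---------------------------------------------------------------------------
# Opposing enrichment and its false-positive control
# ---------------------------------------------------------------------------


@dataclass
class OpposingTerm:
    """A term enriched in one length extreme and depleted in the other."""

    term_id: str
    enriched_in: str  # "short" | "long"
    short: EnrichmentResult
    long: EnrichmentResult


def _bh_within_families(results: list[EnrichmentResult], family: str) -> None:
    """Assign padj in place. ``family``: 'per_direction' or 'pooled'."""
    if family == "pooled":
        groups = [results]
    elif family == "per_direction":
        groups = [
            [r for r in results if r.direction == "enriched"],
            [r for r in results if r.direction == "depleted"],
        ]
        for r in results:
            if r.direction == "none":
                r.padj = 1.0
    else:
        raise ParameterError("bh_family must be 'per_direction' or 'pooled'")
    for group in groups:
        if not group:
            continue
        padj = benjamini_hochberg([r.p for r in group])
        for r, adj in zip(group, padj):
            r.padj = float(adj)


def opposing_enrichment(
    short: Iterable[str],
    long: Iterable[str],
    collection: GeneSetCollection,
    background: Iterable[str],
    alpha: float = 0.05,
    depletion_nominal: bool = False,
    bh_family: str = "per_direction",
    skip_terms: Sequence[str] = ("pro_longevity", "anti_longevity"),
) -> list[OpposingTerm]:
    """Terms enriched in one extreme and depleted in the other.

    Every term is Fisher-tested against both extremes; BH correction is
    applied within each (extreme x direction) family (or pooled per extreme
    with ``bh_family="pooled"``). A term qualifies iff it is enriched
    (padj < alpha, n > e) in one extreme and depleted in the other — with
    ``depletion_nominal=True`` the depleted side only needs n < e at nominal
    p < alpha, otherwise it needs the same BH threshold.
    """
    background = frozenset(background)
    short = frozenset(short) & background
    long = frozenset(long) & background
    if short & long:
        raise ParameterError("length extremes must be disjoint")
    term_ids = [t for t in collection.term_ids() if t not in set(skip_terms)]
    restricted = {t: collection.genes(t) & background for t in term_ids}
    tested = [t for t in term_ids if restricted[t]]
    n_term = np.array([len(restricted[t]) for t in tested])
    per_extreme: dict[str, dict[str, EnrichmentResult]] = {}
    for extreme, query in (("short", short), ("long", long)):
        a = np.array([len(query & restricted[t]) for t in tested])
        pvals = _fisher_two_sided_many(a, n_term, len(query), len(background))
        results = []
        for t, ai, nt, p in zip(tested, a, n_term, pvals):
            e = len(query) * nt / len(background)
            if ai >= e:
                fold = ai / e
                direction = "enriched" if ai > e else "none"
            else:
                fold = -e / ai if ai > 0 else float("-inf")
                direction = "depleted"
            results.append(
                EnrichmentResult(
                    term_id=t, term_name=collection.name(t), extreme=extreme,
                    n_obs=int(ai), e_exp=e, fold=fold, p=float(p),
                    direction=direction, n_query=len(query), n_term=int(nt),
                    n_background=len(background),
                )
            )
        _bh_within_families(results, bh_family)
        per_extreme[extreme] = {r.term_id: r for r in results}

    def enriched_ok(r: EnrichmentResult) -> bool:
        return r.direction == "enriched" and r.padj is not None and r.padj < alpha

    def depleted_ok(r: EnrichmentResult) -> bool:
        if r.direction != "depleted":
            return False
        if depletion_nominal:
            return r.p < alpha
        return r.padj is not None and r.padj < alpha

    qualifying = []
    for t in term_ids:
        rs = per_extreme["short"].get(t)
        rl = per_extreme["long"].get(t)
        if rs is None or rl is None:
            continue
        if enriched_ok(rs) and depleted_ok(rl):
            qualifying.append(OpposingTerm(t, "short", rs, rl))
        elif enriched_ok(rl) and depleted_ok(rs):
            qualifying.append(OpposingTerm(t, "long", rs, rl))
    return qualifying


@dataclass
class RandomizationFPR:
    """Qualifying-term counts across randomized extreme sets."""

    counts: np.ndarray
    n_rand: int
    max_count: int
    fraction_nonzero: float


def randomization_fpr(
    genes: pd.DataFrame,
    collection: GeneSetCollection,
    sizes: tuple[int, int],
    n_rand: int = 100,
    seed: int | None = None,
    alpha: float = 0.05,
    background_mode: str = "annotated_only",
    depletion_nominal: bool = False,
) -> RandomizationFPR:
    """False-positive control for :func:`opposing_enrichment`.

    Each randomization draws two disjoint uniform random gene sets with the
    same sizes as the true extremes (uniform draws from the gene table are
    draws from the observed length distribution) and counts qualifying
    opposing terms.
    """
    k_short, k_long = sizes
    if k_short + k_long > len(genes):
        raise ParameterError("requested sizes exceed the number of genes")
    if background_mode == "annotated_only":
        background = collection.annotated_genes() & frozenset(genes.index)
    else:
        background = frozenset(genes.index)
    rng = np.random.default_rng(seed)
    gene_ids = genes.index.to_numpy()
    counts = np.empty(n_rand, dtype=int)
    for i in range(n_rand):
        pick = rng.choice(len(gene_ids), size=k_short + k_long, replace=False)
        rand_short = frozenset(gene_ids[pick[:k_short]])
        rand_long = frozenset(gene_ids[pick[k_short:]])
        hits = opposing_enrichment(
            rand_short, rand_long, collection, background,
            alpha=alpha, depletion_nominal=depletion_nominal,
        )
        counts[i] = len(hits)
    return RandomizationFPR(
        counts=counts,
        n_rand=n_rand,
        max_count=int(counts.max()) if n_rand else 0,
        fraction_nonzero=float((counts > 0).mean()) if n_rand else 0.0,
    )


# ---------------------------------------------------------------------------
# Annotation-overlap network
# ---------------------------------------------------------------------------


@dataclass
class AnnotationNetwork:
    """Term-overlap graph with (optionally) a simplified kept-edge set.

    Node attributes: ``n_analysis`` (genes attached within the analysis
    universe) and ``n_total`` (including genes outside it). Edge attribute
    ``weight`` is the size of the analysis-restricted intersection.
    """

    graph: nx.Graph
    kept_edges: frozenset[frozenset[str]] = field(default_factory=frozenset)
    processing_order: tuple[str, ...] = ()


def build_annotation_network(
    term_ids: Sequence[str],
    collection: GeneSetCollection,
    universe: Iterable[str],
) -> AnnotationNetwork:
    """Graph over terms with an edge wherever two terms share >= 1 gene.

    Term gene sets are restricted to ``universe`` for node counts and edge
    weights; ``n_total`` keeps the unrestricted set size for the final tie
    rule of :func:`simplify_network`.
    """
    if not term_ids:
        raise ParameterError("need at least one term")
    universe = frozenset(universe)
    graph = nx.Graph()
    restricted = {}
    for t in term_ids:
        members = collection.genes(t)
        restricted[t] = members & universe
        graph.add_node(t, n_analysis=len(restricted[t]), n_total=len(members))
    ids = list(term_ids)
    for i, u in enumerate(ids):
        for v in ids[i + 1:]:
            overlap = len(restricted[u] & restricted[v])
            if overlap >= 1:
                graph.add_edge(u, v, weight=overlap)
    return AnnotationNetwork(graph=graph)


def simplify_network(network: AnnotationNetwork) -> AnnotationNetwork:
    """Keep one edge per non-isolated node: the strongest-overlap neighbor.

    Nodes are processed in ascending order of analysis-restricted attached
    genes (ties by term id). For each node with neighbors, the kept edge goes
    to the neighbor chosen by (1) largest intersection, (2) fewest attached
    genes within the analysis, (3) fewest attached genes including those
    outside the analysis, (4) lexicographic term id — rule 4 is a
    deterministic extension for residual ties. The kept-edge set is the union
    over nodes; isolated nodes remain edgeless. Idempotent: the choice
    depends only on the full graph, which is carried along unchanged.
    """
    graph = network.graph
    order = sorted(graph.nodes, key=lambda t: (graph.nodes[t]["n_analysis"], t))
    kept: set[frozenset[str]] = set()
    for node in order:
        neighbors = list(graph.neighbors(node))
        if not neighbors:
            continue
        best_w = max(graph.edges[node, nb]["weight"] for nb in neighbors)
        tied = [nb for nb in neighbors if graph.edges[node, nb]["weight"] == best_w]
        if len(tied) > 1:
            min_attached = min(graph.nodes[nb]["n_analysis"] for nb in tied)
            tied = [nb for nb in tied if graph.nodes[nb]["n_analysis"] == min_attached]
        if len(tied) > 1:
            for nb in tied:
                if "n_total" not in graph.nodes[nb]:
                    raise ParameterError(
                        f"node {nb!r} lacks the universe-wide gene count needed "
                        "for the final tie rule"
                    )
            min_total = min(graph.nodes[nb]["n_total"] for nb in tied)
            tied = [nb for nb in tied if graph.nodes[nb]["n_total"] == min_total]
        choice = min(tied)
        kept.add(frozenset((node, choice)))
    return AnnotationNetwork(
        graph=graph, kept_edges=frozenset(kept), processing_order=tuple(order)
    )


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------


def enrichment_table(results: Iterable[EnrichmentResult]) -> pd.DataFrame:
    """Tabulate enrichment results; -inf folds become 'complete_depletion'."""
    rows = []
    for r in results:
        fold = "complete_depletion" if r.fold == float("-inf") else r.fold
        rows.append(
            {
                "term_id": r.term_id,
                "term_name": r.term_name,
                "extreme": r.extreme,
                "n": r.n_obs,
                "e": r.e_exp,
                "fold": fold,
                "p": r.p,
                "padj": r.padj,
                "direction": r.direction,
            }
        )
    return pd.DataFrame(rows)


def write_network(network: AnnotationNetwork, basepath: str | Path) -> None:
    """Write GraphML and a TSV edge list (u, v, intersection_size, kept)."""
    basepath = Path(basepath)
    graph = network.graph.copy()
    rows = []
    for u, v, data in graph.edges(data=True):
        kept = frozenset((u, v)) in network.kept_edges
        graph.edges[u, v]["kept"] = kept
        rows.append({"u": u, "v": v, "intersection_size": data["weight"], "kept": kept})
    nx.write_graphml(graph, str(basepath) + ".graphml")
    pd.DataFrame(rows, columns=["u", "v", "intersection_size", "kept"]).to_csv(
        str(basepath) + ".edges.tsv", sep="\t", index=False
    )
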