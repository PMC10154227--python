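"""Readers and writers for the on-disk formats, plus gene filtering utilities.

Containers
----------
``GeneTable``
    A :class:`pandas.DataFrame` indexed by unique ``gene_id`` with at least the
    architectural columns ``transcript_length``, ``gene_length``, ``cds_length``
    (median lengths in bp), ``gc_content`` (fraction) and ``n_exons``; any
    further numeric or binary columns are treated as gene-level features.
``CountMatrix``
    Integer gene-by-sample counts together with per-sample metadata
    (``age_group``, ``cohort``, ``tissue``).
``GeneSetCollection``
    An ordered mapping ``term_id -> (term_name, set of gene ids)``, read and
    written as GMT.

Counts can be stored either as a TSV (genes in rows) or as a MatrixMarket
triplet with sidecar row/column name files; both round-trip losslessly.
Sample metadata always lives in a TSV sidecar named ``<stem>.samples.tsv``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from ._errors import FormatError

logger = logging.getLogger(__name__)

LENGTH_COLUMNS = ("transcript_length", "gene_length", "cds_length")

#: Substrings used to drop stress/inflammation and neuronal annotations before
#: recomputing length correlations (case-insensitive match on term names).
DEFAULT_EXCLUDE_KEYWORDS = (
    "immune",
    "stress",
    "inflamm",
    "infect",
    "brain",
    "neuro",
    "nerv",
    "cerebral",
    "cortex",
    "memory",
)

SAMPLE_METADATA_COLUMNS = ("age_group", "cohort", "tissue")


# ---------------------------------------------------------------------------
# CountMatrix
# ---------------------------------------------------------------------------


@dataclass
class CountMatrix:
    """Gene-by-sample raw counts with per-sample metadata.

    Parameters
    ----------
    counts
        Integer DataFrame, genes in rows, samples in columns.
    samples
        DataFrame indexed by sample id with columns ``age_group``, ``cohort``
        and ``tissue``, one row per count column.
    """

    counts: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        counts = self.counts
        if counts.index.has_duplicates:
            raise FormatError("duplicate gene ids in count matrix")
        arr = counts.to_numpy()
        if not np.issubdtype(arr.dtype, np.integer):
            if not np.allclose(arr, np.round(arr)):
                bad = np.argwhere(arr != np.round(arr))[0]
                raise FormatError(
                    f"non-integer count at gene {counts.index[bad[0]]!r}, "
                    f"sample {counts.columns[bad[1]]!r}"
                )
            counts = counts.round().astype(np.int64)
            self.counts = counts
            arr = counts.to_numpy()
        if (arr < 0).any():
            bad = np.argwhere(arr < 0)[0]
            raise FormatError(
                f"negative count at gene {counts.index[bad[0]]!r}, "
                f"sample {counts.columns[bad[1]]!r}"
            )
        missing = set(counts.columns) - set(self.samples.index)
        if missing:
            raise FormatError(f"samples without metadata: {sorted(missing)}")
        unknown = set(self.samples.index) - set(counts.columns)
        if unknown:
            raise FormatError(f"metadata for unknown samples: {sorted(unknown)}")
        for col in SAMPLE_METADATA_COLUMNS:
            if col not in self.samples.columns:
                raise FormatError(f"sample metadata misses column {col!r}")
        if self.samples["age_group"].isna().any():
            raise FormatError("every sample needs an age_group")
        # align metadata rows to count columns
        self.samples = self.samples.loc[list(counts.columns)]

    @property
    def gene_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.counts.columns

    def subset_samples(self, sample_ids: Sequence[str]) -> "CountMatrix":
        sample_ids = list(sample_ids)
        return CountMatrix(self.counts[sample_ids], self.samples.loc[sample_ids])

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CountMatrix):
            return NotImplemented
        return self.counts.equals(other.counts) and self.samples.astype(str).equals(
            other.samples.astype(str)
        )


def _samples_sidecar(path: Path) -> Path:
    return Path(str(path) + ".samples.tsv")


def write_counts(matrix: CountMatrix, path: str | Path, format: str = "tsv") -> None:
    """Write a :class:`CountMatrix` plus its metadata sidecar.

    ``format="tsv"`` writes a genes-in-rows table; ``format="mtx"`` writes a
    MatrixMarket triplet alongside ``<path>.rows.txt`` / ``<path>.cols.txt``.
    """
    path = Path(path)
    if format == "tsv":
        matrix.counts.rename_axis("gene_id").to_csv(path, sep="\t")
    elif format == "mtx":
        sparse = scipy.sparse.coo_matrix(matrix.counts.to_numpy())
        scipy.io.mmwrite(str(path), sparse, field="integer")
        Path(str(path) + ".rows.txt").write_text("\n".join(matrix.counts.index) + "\n")
        Path(str(path) + ".cols.txt").write_text("\n".join(matrix.counts.columns) + "\n")
    else:
        raise FormatError(f"unknown counts format {format!r}")
    matrix.samples.rename_axis("sample_id").to_csv(_samples_sidecar(path), sep="\t")


def _read_mtx_validated(path: Path) -> scipy.sparse.coo_matrix:
    try:
        mat = scipy.io.mmread(str(path))
    except Exception as exc:  # malformed triplet: locate the offending entry
        n_rows = n_cols = None
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                if line.startswith("%") or not line.strip():
                    continue
                parts = line.split()
                if n_rows is None:
                    n_rows, n_cols = int(parts[0]), int(parts[1])
                    continue
                i, j = int(parts[0]), int(parts[1])
                if not (1 <= i <= n_rows) or not (1 <= j <= n_cols):
                    raise FormatError(
                        f"MTX entry out of range at line {lineno}: "
                        f"coordinate ({i}, {j}) for a {n_rows}x{n_cols} matrix"
                    ) from exc
        raise FormatError(f"malformed MTX file {path}: {exc}") from exc
    return scipy.sparse.coo_matrix(mat)


def read_counts(path: str | Path, format: str = "tsv") -> CountMatrix:
    """Read counts (TSV or MTX triplet) and the mandatory metadata sidecar."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sidecar = _samples_sidecar(path)
    if not sidecar.exists():
        raise FormatError(f"missing sample metadata sidecar {sidecar}")
    samples = pd.read_csv(sidecar, sep="\t", index_col="sample_id")
    if format == "tsv":
        counts = pd.read_csv(path, sep="\t", index_col="gene_id")
    elif format == "mtx":
        sparse = _read_mtx_validated(path)
        rows = Path(str(path) + ".rows.txt").read_text().splitlines()
        cols = Path(str(path) + ".cols.txt").read_text().splitlines()
        dense = np.asarray(sparse.todense())
        counts = pd.DataFrame(dense, index=rows, columns=cols)
    else:
        raise FormatError(f"unknown counts format {format!r}")
    return CountMatrix(counts, samples)


# ---------------------------------------------------------------------------
# GeneTable
# ---------------------------------------------------------------------------


def validate_gene_table(genes: pd.DataFrame) -> pd.DataFrame:
    """Validate invariants of a gene table; drop rows with missing lengths.

    Rows whose required length columns are missing or non-positive are dropped
    with a logged count; remaining feature columns must be finite.
    """
    if genes.index.has_duplicates:
        raise FormatError("duplicate gene_id in gene table")
    for col in LENGTH_COLUMNS:
        if col not in genes.columns:
            raise FormatError(f"gene table misses column {col!r}")
    required = genes[list(LENGTH_COLUMNS)]
    ok = required.notna().all(axis=1) & (required > 0).all(axis=1)
    if (~ok).any():
        logger.warning("dropping %d gene(s) with missing/non-positive lengths", (~ok).sum())
        genes = genes.loc[ok]
    if "gc_content" in genes.columns:
        gc = genes["gc_content"]
        if ((gc < 0) | (gc > 1)).any():
            raise FormatError("gc_content outside [0, 1]")
    numeric = genes.select_dtypes(include=[np.number])
    if not np.isfinite(numeric.to_numpy(dtype=float)).all():
        raise FormatError("non-finite value in gene feature columns")
    return genes


def read_gene_table(path: str | Path) -> pd.DataFrame:
    """Read a gene feature table (TSV, ``gene_id`` first column)."""
    genes = pd.read_csv(path, sep="\t", index_col="gene_id")
    return validate_gene_table(genes)


def write_gene_table(genes: pd.DataFrame, path: str | Path) -> None:
    genes.rename_axis("gene_id").to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# GeneSetCollection / GMT
# ---------------------------------------------------------------------------


@dataclass
class GeneSetCollection:
    """Ordered mapping of term id to (term name, member gene set)."""

    terms: dict[str, tuple[str, frozenset[str]]] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.terms)

    def __contains__(self, term_id: str) -> bool:
        return term_id in self.terms

    def name(self, term_id: str) -> str:
        return self.terms[term_id][0]

    def genes(self, term_id: str) -> frozenset[str]:
        return self.terms[term_id][1]

    def items(self):
        return self.terms.items()

    def term_ids(self) -> list[str]:
        return list(self.terms)

    def annotated_genes(self) -> frozenset[str]:
        """Union of all member sets."""
        out: set[str] = set()
        for _, members in self.terms.values():
            out |= members
        return frozenset(out)

    def add(self, term_id: str, name: str, genes: Iterable[str]) -> None:
        if term_id in self.terms:
            raise FormatError(f"duplicate term id {term_id!r}")
        members = frozenset(genes)
        if not members:
            raise FormatError(f"term {term_id!r} has no genes")
        self.terms[term_id] = (name, members)


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT file: ``term_id <TAB> description <TAB> gene ids...``."""
    collection = GeneSetCollection()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"GMT line {lineno}: fewer than 3 fields")
            term_id, name, genes = fields[0], fields[1], fields[2:]
            genes = [g for g in genes if g]
            if len(set(genes)) < len(genes):
                logger.warning("GMT line %d (%s): duplicate genes deduplicated", lineno, term_id)
            collection.add(term_id, name, genes)
    return collection


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for term_id, (name, genes) in collection.items():
            fh.write("\t".join([term_id, name, *sorted(genes)]) + "\n")


# ---------------------------------------------------------------------------
# Filtering / harmonization
# ---------------------------------------------------------------------------


def exclude_by_annotation_keyword(
    genes: pd.DataFrame | Sequence[str],
    collection: GeneSetCollection,
    keywords: Sequence[str] = DEFAULT_EXCLUDE_KEYWORDS,
) -> list[str]:
    """Drop genes annotated to any term whose name contains a keyword.

    A gene is removed iff it belongs to at least one term whose lowercased name
    contains at least one of the (lowercase) keywords as a substring; matching
    is on term *names* only. Returns the retained gene ids in input order.
    """
    gene_ids = list(genes.index) if isinstance(genes, pd.DataFrame) else list(genes)
    excluded: set[str] = set()
    for _, (name, members) in collection.items():
        lowered = name.lower()
        if any(kw in lowered for kw in keywords):
            excluded |= members
    return [g for g in gene_ids if g not in excluded]


def harmonize(counts: CountMatrix, genes: pd.DataFrame) -> tuple[CountMatrix, pd.DataFrame, int]:
    """Inner-join a count matrix and a gene table on gene id.

    Returns the restricted matrix, the restricted gene table and the number of
    count-matrix genes dropped (also logged).
    """
    shared = counts.gene_ids.intersection(genes.index)
    dropped = len(counts.gene_ids) - len(shared)
    if dropped:
        logger.info("harmonize: dropped %d count-matrix gene(s) absent from gene table", dropped)
    return (
        CountMatrix(counts.counts.loc[shared], counts.samples),
        genes.loc[shared],
        dropped,
    )
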