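"""Core containers and text I/O for expression matrices, networks and gold standards.

The package stores an undirected network over ``n`` genes as a flat vector of
length ``n*(n-1)/2`` walking the strict lower triangle row by row: the edge
between genes ``i`` and ``j`` with ``i > j`` lives at linear index
``i*(i-1)//2 + j``.  All tables and file formats follow this canonical order
(source index strictly greater than target index).
"""

from __future__ import annotations

import gzip
import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "MethodNetwork",
    "RankedEdgeTable",
    "WeightedNetwork",
    "GoldStandard",
    "n_pairs",
    "pair_index",
    "pair_indices",
    "read_expression",
    "drop_zero_variance",
    "median_center_samples",
    "zscore_genes",
    "write_network",
    "read_network",
    "read_pair_list",
    "read_membership",
]

MISSING = "NA"
_FLOAT_FMT = "{:.8g}"


# ---------------------------------------------------------------------------
# canonical edge addressing

def n_pairs(n: int) -> int:
    """Number of unordered gene pairs (strict lower triangle)."""
    return n * (n - 1) // 2


def pair_index(i: int, j: int) -> int:
    """Linear index of the edge (i, j); requires ``i > j``."""
    if i <= j:
        raise ValueError(f"canonical edge order requires i > j, got ({i}, {j})")
    return i * (i - 1) // 2 + j


def pair_indices(n: int) -> tuple[np.ndarray, np.ndarray]:
    """Arrays (source, target) of all edges in canonical linear order.

    ``np.tril_indices`` walks the strict lower triangle row by row, which is
    exactly the ``i*(i-1)//2 + j`` ordering.
    """
    src, tgt = np.tril_indices(n, k=-1)
    return src, tgt


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen: set[str] = set()
    for x in ids:
        if x in seen:
            raise ValueError(f"duplicate {what} id: {x!r}")
        seen.add(x)


# ---------------------------------------------------------------------------
# containers

@dataclass
class ExpressionMatrix:
    """A samples x genes matrix of (pre-normalised) expression values.

    Rows are samples, columns genes; every value must be finite and ids
    unique.  This is the sole input to all inference methods.
    """

    sample_ids: list[str]
    gene_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("expression values must be a 2-D matrix")
        ns, ng = self.values.shape
        if ns != len(self.sample_ids) or ng != len(self.gene_ids):
            raise ValueError(
                f"shape {self.values.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.gene_ids)} genes"
            )
        _check_unique(self.sample_ids, "sample")
        _check_unique(self.gene_ids, "gene")
        if not np.all(np.isfinite(self.values)):
            s, g = np.argwhere(~np.isfinite(self.values))[0]
            raise ValueError(
                f"non-finite expression value at sample {self.sample_ids[s]!r}, "
                f"gene {self.gene_ids[g]!r}"
            )

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.gene_ids)


@dataclass
class MethodNetwork:
    """Full gene x gene score matrix produced by one inference algorithm.

    The diagonal is undefined and stored as NaN; it never participates in
    ranking.  ``rank_on_absolute`` declares whether |score| is the edge
    strength (correlation-type methods keep the sign in the stored score but
    rank on magnitude).
    """

    gene_ids: list[str]
    scores: np.ndarray
    method_name: str
    directed: bool = False
    rank_on_absolute: bool = False
    higher_is_stronger: bool = True

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        n = len(self.gene_ids)
        if self.scores.shape != (n, n):
            raise ValueError(
                f"score matrix shape {self.scores.shape} does not match {n} genes"
            )
        _check_unique(self.gene_ids, "gene")
        np.fill_diagonal(self.scores, np.nan)
        if not self.directed:
            off = ~np.eye(n, dtype=bool)
            a, b = self.scores[off], self.scores.T[off]
            both = np.isfinite(a) & np.isfinite(b)
            if not np.allclose(a[both], b[both], atol=1e-9):
                raise ValueError(
                    f"undirected network {self.method_name!r} has an asymmetric "
                    "score matrix"
                )

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    def pair_strengths(self) -> np.ndarray:
        """Per unordered pair strength in canonical edge order.

        Directed methods are folded to undirected by taking the stronger of
        the two orientations; correlation-type methods contribute |score|.
        """
        s = self.scores
        if self.directed:
            s = np.fmax(s, s.T)
        src, tgt = pair_indices(self.n_genes)
        out = s[src, tgt]
        if self.rank_on_absolute:
            out = np.abs(out)
        if not self.higher_is_stronger:
            out = -out
        return out

    def pair_scores(self) -> np.ndarray:
        """Per-pair stored score (sign preserved; directed folded by max)."""
        s = self.scores
        if self.directed:
            s = np.fmax(s, s.T)
        src, tgt = pair_indices(self.n_genes)
        return s[src, tgt]


@dataclass
class RankedEdgeTable:
    """Per-edge per-method (score, rank) plus the aggregated community column.

    The central artifact of the workflow: one row per unordered gene pair in
    canonical order, one (score, rank) pair per inference method, and the
    aggregated weight/rank produced by rank-product aggregation.  Missing
    entries are NaN (written as ``NA``).
    """

    gene_ids: list[str]
    method_names: list[str]
    scores: np.ndarray  # (E, M)
    ranks: np.ndarray  # (E, M)
    agg_scores: np.ndarray  # (E,)
    agg_ranks: np.ndarray  # (E,)

    def __post_init__(self) -> None:
        _check_unique(self.gene_ids, "gene")
        _check_unique(self.method_names, "method")
        e, m = n_pairs(len(self.gene_ids)), len(self.method_names)
        self.scores = np.asarray(self.scores, dtype=float).reshape(e, m)
        self.ranks = np.asarray(self.ranks, dtype=float).reshape(e, m)
        self.agg_scores = np.asarray(self.agg_scores, dtype=float).reshape(e)
        self.agg_ranks = np.asarray(self.agg_ranks, dtype=float).reshape(e)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_edges(self) -> int:
        return n_pairs(self.n_genes)

    def to_weighted(self) -> "WeightedNetwork":
        """Community network view: aggregated weight per edge (NaN = absent)."""
        return WeightedNetwork(list(self.gene_ids), self.agg_scores.copy())


@dataclass
class WeightedNetwork:
    """A plain weighted undirected network: one weight per canonical edge.

    NaN marks an absent edge (e.g. removed by pruning).
    """

    gene_ids: list[str]
    weights: np.ndarray

    def __post_init__(self) -> None:
        _check_unique(self.gene_ids, "gene")
        self.weights = np.asarray(self.weights, dtype=float).reshape(
            n_pairs(len(self.gene_ids))
        )

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_edges(self) -> int:
        """Number of present (non-NaN) edges."""
        return int(np.sum(np.isfinite(self.weights)))

    def present(self) -> np.ndarray:
        return np.isfinite(self.weights)

    def to_matrix(self, absent: float = 0.0) -> np.ndarray:
        """Symmetric dense matrix with ``absent`` in place of missing edges."""
        n = self.n_genes
        m = np.full((n, n), absent, dtype=float)
        src, tgt = pair_indices(n)
        ok = self.present()
        m[src[ok], tgt[ok]] = self.weights[ok]
        m[tgt[ok], src[ok]] = self.weights[ok]
        return m


@dataclass
class GoldStandard:
    """Labelled gene pairs used to score a predicted network.

    Positives and negatives are disjoint sets of unordered pairs (sorted
    2-tuples) over a declared gene universe.
    """

    universe: set[str]
    positives: set[tuple[str, str]]
    negatives: set[tuple[str, str]]

    def __post_init__(self) -> None:
        self.positives = {_upair(a, b) for a, b in self.positives}
        self.negatives = {_upair(a, b) for a, b in self.negatives}
        overlap = self.positives & self.negatives
        if overlap:
            raise ValueError(f"pairs labelled both positive and negative: {sorted(overlap)[:5]}")
        for pair in self.positives | self.negatives:
            for g in pair:
                if g not in self.universe:
                    raise ValueError(f"gene {g!r} in a labelled pair is outside the universe")


def _upair(a: str, b: str) -> tuple[str, str]:
    if a == b:
        raise ValueError(f"self-pair {a!r} is not a valid edge")
    return (a, b) if a < b else (b, a)


# ---------------------------------------------------------------------------
# expression I/O and preprocessing

def _open_text(path: str | Path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def read_expression(path: str | Path) -> ExpressionMatrix:
    """Read a samples x genes TSV (first row gene ids, first column sample ids).

    Aborts with a message naming the offending row/column on duplicate ids,
    non-numeric cells or ragged rows.  Gzipped files are accepted by
    extension.
    """
    with _open_text(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        gene_ids = [g for g in header[1:] if g != ""]
        _check_unique(gene_ids, "gene")
        body = fh.read()
    try:
        df = pd.read_csv(
            io.StringIO(body), sep="\t", header=None, index_col=0, dtype=str
        )
    except pd.errors.ParserError as exc:
        raise ValueError(f"malformed expression table {path}: {exc}") from exc
    if df.shape[1] != len(gene_ids):
        raise ValueError(
            f"ragged expression table {path}: header has {len(gene_ids)} genes, "
            f"body rows have {df.shape[1]} columns"
        )
    sample_ids = [str(s) for s in df.index]
    _check_unique(sample_ids, "sample")
    values = df.apply(pd.to_numeric, errors="coerce").to_numpy(dtype=float)
    bad = np.argwhere(~np.isfinite(values))
    if bad.size:
        s, g = bad[0]
        raise ValueError(
            f"non-numeric cell at sample {sample_ids[s]!r}, gene {gene_ids[g]!r} "
            f"(value {df.iloc[s, g]!r})"
        )
    return ExpressionMatrix(sample_ids, gene_ids, values)


def drop_zero_variance(em: ExpressionMatrix) -> ExpressionMatrix:
    """Remove genes with constant expression (zero sample variance)."""
    var = em.values.var(axis=0, ddof=1) if em.n_samples > 1 else np.zeros(em.n_genes)
    keep = var > 0
    if not keep.any():
        raise ValueError("all genes have zero variance; nothing left to analyse")
    return ExpressionMatrix(
        list(em.sample_ids),
        [g for g, k in zip(em.gene_ids, keep) if k],
        em.values[:, keep],
    )


def median_center_samples(em: ExpressionMatrix) -> ExpressionMatrix:
    """Subtract each sample's median expression from every gene in that sample."""
    med = np.median(em.values, axis=1, keepdims=True)
    return ExpressionMatrix(list(em.sample_ids), list(em.gene_ids), em.values - med)


def zscore_genes(em: ExpressionMatrix) -> ExpressionMatrix:
    """Transform each gene column to mean 0, unit sample variance (n-1)."""
    mu = em.values.mean(axis=0)
    sd = em.values.std(axis=0, ddof=1)
    if np.any(sd == 0):
        bad = em.gene_ids[int(np.argmax(sd == 0))]
        raise ValueError(
            f"gene {bad!r} has zero variance; run drop_zero_variance first"
        )
    return ExpressionMatrix(
        list(em.sample_ids), list(em.gene_ids), (em.values - mu) / sd
    )


# ---------------------------------------------------------------------------
# edge-table network format

def _fmt(x: float) -> str:
    return MISSING if not np.isfinite(x) else _FLOAT_FMT.format(x)


def _parse(tok: str, path, lineno: int) -> float:
    if tok == MISSING:
        return np.nan
    try:
        return float(tok)
    except ValueError:
        raise ValueError(f"{path}:{lineno}: malformed numeric token {tok!r}") from None


def write_network(table: RankedEdgeTable, path: str | Path) -> None:
    """Write a RankedEdgeTable to the tab-separated edge-table format.

    Two header lines declare the gene universe and method names; each edge
    line is ``source TAB target`` followed by one ``score;rank`` cell per
    method and the aggregated ``score;rank`` cell.  Edges with no data at all
    are omitted (the reader restores them as missing).
    """
    genes = table.gene_ids
    src, tgt = pair_indices(table.n_genes)
    with _open_text(path, "wt") as fh:
        fh.write("#genes:" + "\t".join(genes) + "\n")
        fh.write("#methods:" + "\t".join(table.method_names) + "\n")
        for e in range(table.n_edges):
            cells = [
                f"{_fmt(table.scores[e, m])};{_fmt(table.ranks[e, m])}"
                for m in range(len(table.method_names))
            ]
            cells.append(f"{_fmt(table.agg_scores[e])};{_fmt(table.agg_ranks[e])}")
            if all(c == f"{MISSING};{MISSING}" for c in cells):
                continue
            fh.write(
                genes[src[e]] + "\t" + genes[tgt[e]] + "\t" + "\t".join(cells) + "\n"
            )


def read_network(path: str | Path) -> RankedEdgeTable:
    """Read the edge-table format written by :func:`write_network`."""
    with _open_text(path) as fh:
        lines = fh.read().splitlines()
    if len(lines) < 2 or not lines[0].startswith("#genes:") or not lines[1].startswith("#methods:"):
        raise ValueError(f"{path}: expected '#genes:' and '#methods:' header lines")
    genes = lines[0][len("#genes:"):].split("\t")
    methods = lines[1][len("#methods:"):].split("\t")
    _check_unique(genes, "gene")
    gidx = {g: i for i, g in enumerate(genes)}
    e_total, m_total = n_pairs(len(genes)), len(methods)
    scores = np.full((e_total, m_total), np.nan)
    ranks = np.full((e_total, m_total), np.nan)
    agg_s = np.full(e_total, np.nan)
    agg_r = np.full(e_total, np.nan)
    for lineno, line in enumerate(lines[2:], start=3):
        if not line:
            continue
        parts = line.split("\t")
        if len(parts) != 2 + m_total + 1:
            raise ValueError(
                f"{path}:{lineno}: expected {2 + m_total + 1} fields, got {len(parts)}"
            )
        s_name, t_name = parts[0], parts[1]
        if s_name not in gidx or t_name not in gidx:
            raise ValueError(f"{path}:{lineno}: unknown gene id in edge {s_name!r}-{t_name!r}")
        i, j = gidx[s_name], gidx[t_name]
        if i <= j:
            raise ValueError(
                f"{path}:{lineno}: source index must exceed target index "
                f"({s_name!r} <= {t_name!r} in header order)"
            )
        e = pair_index(i, j)
        for m, cell in enumerate(parts[2:]):
            bits = cell.split(";")
            if len(bits) != 2:
                raise ValueError(f"{path}:{lineno}: malformed cell {cell!r}")
            sv, rv = (_parse(b, path, lineno) for b in bits)
            if m < m_total:
                scores[e, m], ranks[e, m] = sv, rv
            else:
                agg_s[e], agg_r[e] = sv, rv
    return RankedEdgeTable(genes, methods, scores, ranks, agg_s, agg_r)


# ---------------------------------------------------------------------------
# gold-standard inputs

def read_pair_list(path: str | Path) -> list[tuple[str, str]]:
    """Read a two-column TSV of gene pairs (no header; '#' comments allowed)."""
    pairs: list[tuple[str, str]] = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"{path}:{lineno}: expected two tab-separated gene ids")
            pairs.append((parts[0], parts[1]))
    return pairs


def read_membership(path: str | Path) -> dict[str, set[str]]:
    """Read a two-column gene TAB pathway membership TSV into gene -> pathways."""
    members: dict[str, set[str]] = {}
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"{path}:{lineno}: expected gene TAB pathway")
            members.setdefault(parts[0], set()).add(parts[1])
    return members
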