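"""Protein-association networks.

A gene--gene association network is read from a STRING-style weighted edge
list, thresholded on the confidence score, and reduced to the symmetric
binary relation that the list-ordering engine consumes.  Genes whose
products have no retained association are dropped: they carry no ordering
information.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "InteractionNetwork",
    "NetworkParseError",
    "EmptyNetworkError",
    "load_interactions",
    "association_matrix",
    "write_network",
]


class NetworkParseError(ValueError):
    """A malformed row in an interaction edge table."""


class EmptyNetworkError(ValueError):
    """No gene survives confidence thresholding and isolate removal."""


@dataclass(frozen=True)
class InteractionNetwork:
    """Genes plus a symmetric binary association relation.

    Parameters
    ----------
    genes
        Unique, non-empty gene identifiers; position in this tuple is the
        canonical gene index.
    adjacency
        ``(N, N)`` boolean matrix, symmetric with a zero diagonal;
        ``adjacency[i, j]`` is True when the products of genes ``i`` and
        ``j`` associate above the loader's confidence threshold.
    """

    genes: tuple[str, ...]
    adjacency: np.ndarray
    _index: dict[str, int] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        adj = np.asarray(self.adjacency, dtype=bool)
        n = len(self.genes)
        if adj.shape != (n, n):
            raise ValueError(f"adjacency shape {adj.shape} does not match {n} genes")
        if len(set(self.genes)) != n:
            raise ValueError("gene identifiers must be unique")
        if any((not g) or not isinstance(g, str) for g in self.genes):
            raise ValueError("gene identifiers must be non-empty strings")
        if np.any(np.diag(adj)):
            raise ValueError("self-associations are not allowed (non-zero diagonal)")
        if not np.array_equal(adj, adj.T):
            raise ValueError("association relation must be symmetric")
        if n and not np.all(adj.sum(axis=0) >= 1):
            orphans = [self.genes[i] for i in np.flatnonzero(adj.sum(axis=0) == 0)]
            raise ValueError(f"every gene needs at least one association; isolated: {orphans[:5]}")
        object.__setattr__(self, "adjacency", adj)
        object.__setattr__(self, "_index", {g: i for i, g in enumerate(self.genes)})

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def degrees(self) -> np.ndarray:
        return self.adjacency.sum(axis=0).astype(int)

    def index_of(self, gene: str) -> int:
        return self._index[gene]

    def edges(self) -> list[tuple[str, str]]:
        """Undirected edges as (gene_a, gene_b) with a < b lexicographically."""
        ii, jj = np.nonzero(np.triu(self.adjacency, k=1))
        return [tuple(sorted((self.genes[i], self.genes[j]))) for i, j in zip(ii, jj)]

    @classmethod
    def from_edges(cls, pairs: Iterable[tuple[str, str]]) -> "InteractionNetwork":
        """Build a network directly from undirected gene pairs (test helper)."""
        pairs = [tuple(p) for p in pairs]
        genes = tuple(sorted({g for p in pairs for g in p}))
        idx = {g: i for i, g in enumerate(genes)}
        adj = np.zeros((len(genes), len(genes)), dtype=bool)
        for a, b in pairs:
            if a == b:
                continue
            adj[idx[a], idx[b]] = adj[idx[b], idx[a]] = True
        return cls(genes=genes, adjacency=adj)


def _iter_rows(source) -> Iterable[tuple[int, str]]:
    if isinstance(source, (str, os.PathLike)):
        with open(source, "rt") as fh:
            yield from enumerate(fh, start=1)
    elif isinstance(source, io.TextIOBase):
        yield from enumerate(source, start=1)
    else:
        raise TypeError("source must be a path or an open text file")


def load_interactions(
    source,
    min_confidence: float = 0.8,
    exclude_channels: Sequence[str] = (),
) -> InteractionNetwork:
    """Read a weighted edge table and return the thresholded binary network.

    The table is tab-separated with header
    ``gene_a<TAB>gene_b<TAB>confidence[<TAB>channel]``; lines starting with
    ``#`` are comments.  Edges are kept when their confidence is *strictly*
    greater than ``min_confidence``; self-loops are discarded, duplicate
    undirected pairs are merged keeping the maximum confidence, and genes
    left without any retained edge are dropped.  Edges whose optional
    evidence-channel tag is in ``exclude_channels`` are ignored before
    confidences are combined.

    Gene order in the returned network is lexicographic, so loading is
    deterministic; any stochastic ordering happens downstream.
    """
    if not 0.0 <= min_confidence <= 1.0:
        raise ValueError("min_confidence must lie in [0, 1]")
    excluded = set(exclude_channels)
    best: dict[tuple[str, str], float] = {}
    header_seen = False
    n_rows = 0
    for lineno, line in _iter_rows(source):
        line = line.rstrip("\n")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        fields = line.split("\t")
        if not header_seen:
            header_seen = True
            if fields[0].strip().lower() == "gene_a":
                continue  # header row; otherwise fall through and parse as data
        if len(fields) not in (3, 4):
            raise NetworkParseError(
                f"line {lineno}: expected 3 or 4 tab-separated columns, got {len(fields)}"
            )
        a, b = fields[0].strip(), fields[1].strip()
        if not a or not b:
            raise NetworkParseError(f"line {lineno}: empty gene identifier")
        try:
            conf = float(fields[2])
        except ValueError:
            raise NetworkParseError(
                f"line {lineno}: non-numeric confidence {fields[2]!r}"
            ) from None
        if not 0.0 <= conf <= 1.0:
            raise NetworkParseError(f"line {lineno}: confidence {conf} outside [0, 1]")
        if len(fields) == 4 and fields[3].strip() in excluded:
            continue
        if a == b:
            continue
        key = (a, b) if a < b else (b, a)
        if conf > best.get(key, -1.0):
            best[key] = conf
        n_rows += 1
    if n_rows == 0:
        raise NetworkParseError("edge table contains no data rows")

    kept = [pair for pair, conf in best.items() if conf > min_confidence]
    genes = tuple(sorted({g for pair in kept for g in pair}))
    if not genes:
        raise EmptyNetworkError(
            f"no genes survive threshold: no edge has confidence > {min_confidence}"
        )
    idx = {g: i for i, g in enumerate(genes)}
    adj = np.zeros((len(genes), len(genes)), dtype=bool)
    for a, b in kept:
        adj[idx[a], idx[b]] = adj[idx[b], idx[a]] = True
    return InteractionNetwork(genes=genes, adjacency=adj)


def _order_indices(network: InteractionNetwork, order: Sequence[str]) -> np.ndarray:
    """Validate that `order` is a bijection over the network genes; return indices."""
    if len(order) != network.n_genes or set(order) != set(network.genes):
        raise ValueError("order must be a permutation of the network's genes")
    return np.fromiter((network.index_of(g) for g in order), count=len(order), dtype=np.int64)


def association_matrix(network: InteractionNetwork, order: Sequence[str]) -> np.ndarray:
    """Binary association matrix in list coordinates.

    Entry ``(i, j)`` is 1 iff the genes at list positions ``i`` and ``j``
    (0-based) associate.  Symmetric, zero diagonal.
    """
    idx = _order_indices(network, order)
    return network.adjacency[np.ix_(idx, idx)].astype(np.int8)


def write_network(network: InteractionNetwork, path) -> None:
    """Write the binary network as an edge-list TSV (confidence 1.0).

    Reloading with ``min_confidence=0`` reproduces the same genes and
    associations.
    """
    with open(path, "wt") as fh:
        fh.write("gene_a\tgene_b\tconfidence\n")
        for a, b in network.edges():
            fh.write(f"{a}\t{b}\t1.0\n")
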