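"""Undirected simple graphs, file I/O, and structural node similarity.

The :class:`Network` type is the substrate for everything else in the
package: seeding, walk-based expansion, refinement and the benchmark
generators all consume it.  It is a thin validated wrapper around
:class:`networkx.Graph` that enforces the invariants the algorithms rely
on (no self-loops, no parallel edges, symmetric adjacency) and exposes a
stable, sorted internal indexing of the opaque string node labels.

Structural similarity between two nodes is computed from their *closed*
neighborhoods (the node itself is included), so that adjacent nodes
always have positive similarity and a walker can move along every edge.
Two variants are available, selected via :class:`SimilarityConfig`:

``closed_jaccard`` (default)
    ``|N[u] & N[v]| / |N[u] | N[v]|``
``closed_cosine``
    ``|N[u] & N[v]| / sqrt(|N[u]| * |N[v]|)``
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Literal, Mapping, Sequence

import networkx as nx
import numpy as np

__all__ = [
    "Network",
    "SimilarityConfig",
    "GraphParseError",
    "read_graph",
    "write_graph",
    "read_membership",
    "write_membership",
    "structural_similarity",
    "similarity_matrix",
    "walk_matrix",
]


class GraphParseError(ValueError):
    """Raised when a graph file violates the expected dialect."""


@dataclass(frozen=True)
class SimilarityConfig:
    """Selects the structural-similarity variant used by the walks."""

    variant: Literal["closed_jaccard", "closed_cosine"] = "closed_jaccard"

    def __post_init__(self) -> None:
        if self.variant not in ("closed_jaccard", "closed_cosine"):
            raise ValueError(f"unknown similarity variant: {self.variant!r}")


class Network:
    """An undirected simple graph with opaque string node labels.

    Invariants enforced at construction: no self-loops, no duplicate
    edges, every edge endpoint is a registered node.  Instances are
    treated as immutable; derived quantities (sorted node order, closed
    adjacency matrix, full similarity matrices) are cached lazily.
    """

    __slots__ = ("_g", "_order", "_index", "_closed_adj", "_sim_cache")

    def __init__(
        self,
        edges: Iterable[tuple[str, str]] = (),
        nodes: Iterable[str] = (),
    ) -> None:
        g = nx.Graph()
        g.add_nodes_from(str(n) for n in nodes)
        for u, v in edges:
            u, v = str(u), str(v)
            if u == v:
                raise ValueError(f"self-loop on node {u!r} is not allowed")
            g.add_edge(u, v)
        self._g = g
        self._order: tuple[str, ...] | None = None
        self._index: dict[str, int] | None = None
        self._closed_adj: np.ndarray | None = None
        self._sim_cache: dict[str, np.ndarray] = {}

    # -- construction -------------------------------------------------

    @classmethod
    def from_networkx(cls, g: nx.Graph) -> "Network":
        """Wrap a networkx graph, coercing labels to strings."""
        net = cls()
        h = net._g
        h.add_nodes_from(str(n) for n in g.nodes)
        for u, v in g.edges():
            u, v = str(u), str(v)
            if u == v:
                raise ValueError(f"self-loop on node {u!r} is not allowed")
            h.add_edge(u, v)
        return net

    def to_networkx(self) -> nx.Graph:
        return self._g.copy()

    # -- basic queries -------------------------------------------------

    @property
    def nodes(self) -> frozenset[str]:
        return frozenset(self._g.nodes)

    @property
    def node_order(self) -> tuple[str, ...]:
        """All nodes in the stable sorted order used for indexing."""
        if self._order is None:
            self._order = tuple(sorted(self._g.nodes))
            self._index = {n: i for i, n in enumerate(self._order)}
        return self._order

    @property
    def node_index(self) -> Mapping[str, int]:
        self.node_order
        assert self._index is not None
        return self._index

    def edges(self) -> Iterator[tuple[str, str]]:
        for u, v in self._g.edges():
            yield (u, v) if u <= v else (v, u)

    def number_of_nodes(self) -> int:
        return self._g.number_of_nodes()

    def number_of_edges(self) -> int:
        return self._g.number_of_edges()

    def has_node(self, u: str) -> bool:
        return self._g.has_node(u)

    def has_edge(self, u: str, v: str) -> bool:
        return self._g.has_edge(u, v)

    def neighbors(self, u: str) -> set[str]:
        self._require(u)
        return set(self._g.neighbors(u))

    def degree(self, u: str) -> int:
        self._require(u)
        return self._g.degree(u)

    def connected_components(self) -> list[set[str]]:
        return [set(c) for c in nx.connected_components(self._g)]

    def subgraph(self, nodes: Iterable[str]) -> "Network":
        """Induced subgraph on the given nodes (labels preserved)."""
        keep = set(nodes)
        self._require(*keep)
        return Network.from_networkx(self._g.subgraph(keep))

    def _require(self, *nodes: str) -> None:
        for n in nodes:
            if not self._g.has_node(n):
                raise KeyError(f"node {n!r} is not in the network")

    def __contains__(self, u: object) -> bool:
        return self._g.has_node(u)

    def __len__(self) -> int:
        return self._g.number_of_nodes()

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"Network(n_nodes={self.number_of_nodes()}, "
            f"n_edges={self.number_of_edges()})"
        )

    # -- cached numeric views -----------------------------------------

    def closed_adjacency(self) -> np.ndarray:
        """Dense 0/1 matrix of A + I in :attr:`node_order` indexing."""
        if self._closed_adj is None:
            order = self.node_order
            a = nx.to_numpy_array(self._g, nodelist=list(order), dtype=float)
            np.fill_diagonal(a, 1.0)
            self._closed_adj = a
        return self._closed_adj

    def full_similarity(self, cfg: SimilarityConfig) -> np.ndarray:
        """Pairwise structural similarity over all nodes (cached)."""
        key = cfg.variant
        if key not in self._sim_cache:
            ac = self.closed_adjacency()
            sizes = ac.sum(axis=1)
            inter = ac @ ac.T
            if cfg.variant == "closed_jaccard":
                union = sizes[:, None] + sizes[None, :] - inter
                sim = inter / union
            else:
                sim = inter / np.sqrt(sizes[:, None] * sizes[None, :])
            self._sim_cache[key] = sim
        return self._sim_cache[key]


# -- file I/O ---------------------------------------------------------


def _infer_format(path: str | Path) -> str:
    return "gml" if str(path).endswith(".gml") else "edgelist"


def read_graph(path: str | Path, format: str | None = None) -> Network:
    """Read an undirected simple graph from an edge list or GML file.

    Edge-list dialect: one edge per line, two whitespace-separated
    labels; blank lines and ``#`` comments are ignored; repeated edge
    lines (in either orientation) are collapsed.  Node labels are
    preserved verbatim.  A self-loop or malformed line raises
    :class:`GraphParseError` naming the offending line.
    """
    fmt = format or _infer_format(path)
    if fmt == "gml":
        g = nx.read_gml(str(path), label="label")
        if any(u == v for u, v in g.edges()):
            raise GraphParseError(f"{path}: self-loop encountered in GML input")
        return Network.from_networkx(nx.Graph(g))
    if fmt != "edgelist":
        raise ValueError(f"unknown graph format: {fmt!r}")
    net = Network()
    g = net._g
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            parts = line.split()
            if len(parts) != 2:
                raise GraphParseError(
                    f"{path}:{lineno}: expected two labels, got {len(parts)}: {raw.rstrip()!r}"
                )
            u, v = parts
            if u == v:
                raise GraphParseError(f"{path}:{lineno}: self-loop on node {u!r}")
            g.add_edge(u, v)
    return net


def write_graph(net: Network, path: str | Path, format: str | None = None) -> None:
    """Write a graph as an edge list or GML, preserving labels."""
    fmt = format or _infer_format(path)
    if fmt == "gml":
        nx.write_gml(net._g, str(path))
        return
    if fmt != "edgelist":
        raise ValueError(f"unknown graph format: {fmt!r}")
    with open(path, "w") as fh:
        for u, v in sorted(net.edges()):
            fh.write(f"{u}\t{v}\n")


def read_membership(path: str | Path) -> dict[str, int]:
    """Read a ``label<TAB>community_id`` membership file."""
    out: dict[str, int] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) != 2:
                raise GraphParseError(
                    f"{path}:{lineno}: expected 'label<TAB>community_id'"
                )
            out[parts[0]] = int(parts[1])
    return out


def write_membership(mapping: Mapping[str, int], path: str | Path) -> None:
    with open(path, "w") as fh:
        for label in sorted(mapping):
            fh.write(f"{label}\t{mapping[label]}\n")


# -- similarity and the walk matrix -----------------------------------


def structural_similarity(
    net: Network, u: str, v: str, cfg: SimilarityConfig | None = None
) -> float:
    """Similarity of two nodes from their closed neighborhoods.

    Symmetric, in ``[0, 1]``, and equal to 1 when ``u == v``.
    """
    cfg = cfg or SimilarityConfig()
    net._require(u, v)
    if u == v:
        return 1.0
    nu = net.neighbors(u) | {u}
    nv = net.neighbors(v) | {v}
    inter = len(nu & nv)
    if cfg.variant == "closed_jaccard":
        return inter / len(nu | nv)
    return inter / float(np.sqrt(len(nu) * len(nv)))


def similarity_matrix(
    net: Network, ordered_nodes: Sequence[str], cfg: SimilarityConfig | None = None
) -> np.ndarray:
    """Pairwise similarity for an ordered node subset (vectorized)."""
    cfg = cfg or SimilarityConfig()
    net._require(*ordered_nodes)
    idx = np.fromiter(
        (net.node_index[n] for n in ordered_nodes), dtype=np.intp, count=len(ordered_nodes)
    )
    return net.full_similarity(cfg)[np.ix_(idx, idx)]


def walk_matrix(
    net: Network, ordered_nodes: Sequence[str], cfg: SimilarityConfig | None = None
) -> np.ndarray:
    """Row-stochastic transition matrix over an ordered node subset.

    Off-diagonal entry ``(i, j)`` is the similarity of the two nodes
    divided by the row's off-diagonal similarity sum; the diagonal is
    forced to 0.  A row with no off-diagonal similarity mass falls back
    to the uniform distribution over the other indices, keeping the
    matrix stochastic.
    """
    m = len(ordered_nodes)
    if m < 2:
        raise ValueError("walk_matrix requires at least two nodes (no off-diagonal mass)")
    if len(set(ordered_nodes)) != m:
        raise ValueError("ordered_nodes contains duplicates")
    sim = similarity_matrix(net, ordered_nodes, cfg).copy()
    np.fill_diagonal(sim, 0.0)
    rowsums = sim.sum(axis=1)
    dead = rowsums == 0.0
    if np.any(dead):
        sim[dead, :] = 1.0 / (m - 1)
        np.fill_diagonal(sim, 0.0)
        rowsums = sim.sum(axis=1)
    return sim / rowsums[:, None]
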