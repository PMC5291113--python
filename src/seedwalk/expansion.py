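"""Community expansion driven by personalized random walks.

For an unassigned node ``u`` and the current communities ``Y_1..Y_q``,
``q`` restart walks are run over the union ``V`` of all community
members.  The hypothesis "``u`` belongs to community ``k``" enters run
``k`` through its restart vector, uniform over the members of ``Y_k``;
every run shares the same similarity-derived transition matrix ``M``.
The stationary distribution of run ``k`` is averaged per community to
give the conditional probabilities ``PC(k, j)``; a similarity-based
prior ``PP(k)`` weighs the hypotheses; the total-probability combination
``pu(j) = sum_k PC(k, j) * PP(k)`` scores where ``u`` belongs.
Expansion repeatedly assigns the single frontier node with the globally
largest score to its best community until the frontier is exhausted.

Note on the walk domain: each of the ``q`` runs walks over the SAME
node set ``V`` (all current community members) — the per-hypothesis
restart vector is what differentiates the runs.  This is the minimal
convention under which the runs differ and reduces each run to a
personalized-restart walk.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
from scipy.linalg import lu_factor, lu_solve

from .graph import Network, SimilarityConfig, walk_matrix
from .seeding import SeedCommunity

__all__ = [
    "WalkParams",
    "CommunitySet",
    "ProbabilityTable",
    "ConvergenceError",
    "stationary_distribution",
    "conditional_community_probability",
    "membership_prior",
    "belonging_probabilities",
    "expand_communities",
]


class ConvergenceError(RuntimeError):
    """Raised when the walk iteration fails to reach the tolerance."""


@dataclass(frozen=True)
class WalkParams:
    """Parameters of the restart walk.

    ``alpha`` is the teleport (restart) probability per step; 0.15 is
    the conventional choice.  Iteration stops once the L1 change of the
    probability vector drops below ``tol``.
    """

    alpha: float = 0.15
    tol: float = 1e-10
    max_iter: int = 1000

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha <= 1.0):
            raise ValueError("alpha must be in (0, 1]")
        if self.tol <= 0.0:
            raise ValueError("tol must be positive")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")


class CommunitySet:
    """An ordered collection of node sets ``Y_1..Y_q``.

    Communities may overlap while expansion is in flight (seeds can
    share nodes); the refinement stage turns the collection into a
    disjoint cover.
    """

    __slots__ = ("communities",)

    def __init__(self, communities: Iterable[Iterable[str]]):
        self.communities: list[set[str]] = [set(c) for c in communities]
        if not self.communities:
            raise ValueError("CommunitySet needs at least one community")
        if any(not c for c in self.communities):
            raise ValueError("communities must be non-empty")

    @classmethod
    def from_seeds(cls, seeds: Sequence[SeedCommunity]) -> "CommunitySet":
        return cls([s.members for s in seeds])

    @property
    def q(self) -> int:
        return len(self.communities)

    def members(self) -> set[str]:
        out: set[str] = set()
        for c in self.communities:
            out |= c
        return out

    def copy(self) -> "CommunitySet":
        return CommunitySet(self.communities)

    def __iter__(self):
        return iter(self.communities)

    def __len__(self) -> int:
        return len(self.communities)

    def __getitem__(self, k: int) -> set[str]:
        return self.communities[k]

    def __repr__(self) -> str:  # pragma: no cover
        sizes = [len(c) for c in self.communities]
        return f"CommunitySet(q={self.q}, sizes={sizes})"


@dataclass(frozen=True)
class ProbabilityTable:
    """Per-hypothesis walk outcomes and their total-probability mix.

    ``PC[k, j] = p(u -> Y_j | u in G_k)`` (rows normalized),
    ``PP[k] = p(u in G_k)`` and ``pu[j] = p(u -> Y_j)``.
    """

    PC: np.ndarray
    PP: np.ndarray
    pu: np.ndarray


def stationary_distribution(
    M: np.ndarray,
    d: np.ndarray,
    s0: np.ndarray,
    params: WalkParams | None = None,
) -> np.ndarray:
    """Fixed point of ``s <- (1 - alpha) M^T s + alpha d`` by iteration.

    ``M`` must be row-stochastic and ``d``/``s0`` probability vectors of
    matching length.  Raises :class:`ConvergenceError` with the last
    residual if ``max_iter`` is exhausted.
    """
    params = params or WalkParams()
    M = np.asarray(M, dtype=float)
    d = np.asarray(d, dtype=float)
    s = np.asarray(s0, dtype=float).copy()
    m = M.shape[0]
    if M.shape != (m, m) or d.shape != (m,) or s.shape != (m,):
        raise ValueError("dimension mismatch between M, d and s0")
    for _ in range(params.max_iter):
        s_next = (1.0 - params.alpha) * (M.T @ s) + params.alpha * d
        resid = float(np.abs(s_next - s).sum())
        s = s_next
        if resid <= params.tol:
            s = np.clip(s, 0.0, None)
            return s / s.sum()
    raise ConvergenceError(
        f"walk did not converge in {params.max_iter} iterations (residual {resid:.3e})"
    )


def conditional_community_probability(
    pi: np.ndarray, cs: CommunitySet, V: Sequence[str]
) -> np.ndarray:
    """Average the stationary distribution over each community's members."""
    index = {n: i for i, n in enumerate(V)}
    pi = np.asarray(pi, dtype=float)
    out = np.empty(cs.q)
    for k, comm in enumerate(cs):
        if not comm:
            raise ValueError(f"community {k} is empty")
        try:
            rows = [index[n] for n in comm]
        except KeyError as exc:
            raise ValueError(f"community member {exc.args[0]!r} not in V") from exc
        out[k] = pi[rows].mean()
    return out


def membership_prior(
    net: Network,
    u: str,
    cs: CommunitySet,
    cfg: SimilarityConfig | None = None,
) -> np.ndarray:
    """Prior probability of ``u`` belonging to each community.

    Entry ``k`` is proportional to the average similarity of ``u`` to
    the members of ``Y_k``, normalized to sum to 1; if every raw average
    is zero the prior is uniform.
    """
    cfg = cfg or SimilarityConfig()
    net._require(u)
    for k, comm in enumerate(cs):
        if not comm:
            raise ValueError(f"community {k} is empty")
        if u in comm:
            raise ValueError(f"node {u!r} is already a member of community {k}")
    sim_row = net.full_similarity(cfg)[net.node_index[u]]
    idx = net.node_index
    raw = np.array(
        [np.mean([sim_row[idx[v]] for v in comm]) for comm in cs]
    )
    total = raw.sum()
    if total == 0.0:
        return np.full(cs.q, 1.0 / cs.q)
    return raw / total


def _normalize_rows(a: np.ndarray) -> np.ndarray:
    a = np.asarray(a, dtype=float).copy()
    sums = a.sum(axis=1)
    dead = sums == 0.0
    if np.any(dead):
        a[dead] = 1.0 / a.shape[1]
        sums = a.sum(axis=1)
    return a / sums[:, None]


def _restart_vectors(cs: CommunitySet, V: Sequence[str]) -> np.ndarray:
    """Stack of per-hypothesis restart vectors, uniform over Y_k."""
    index = {n: i for i, n in enumerate(V)}
    D = np.zeros((cs.q, len(V)))
    for k, comm in enumerate(cs):
        rows = [index[n] for n in comm]
        D[k, rows] = 1.0 / len(rows)
    return D


def _conditional_matrix(
    net: Network,
    cs: CommunitySet,
    V: Sequence[str],
    wp: WalkParams,
    cfg: SimilarityConfig,
) -> np.ndarray:
    """Row-normalized PC computed with one LU factorization.

    The fixed point of the walk update does not depend on the start
    vector, so ``pi_k`` solves ``(I - (1 - alpha) M^T) pi = alpha d_k``
    directly; one factorization serves all q hypotheses.
    """
    M = walk_matrix(net, V, cfg)
    m = len(V)
    A = np.eye(m) - (1.0 - wp.alpha) * M.T
    lu = lu_factor(A)
    D = _restart_vectors(cs, V)
    PC = np.empty((cs.q, cs.q))
    for k in range(cs.q):
        pi = lu_solve(lu, wp.alpha * D[k])
        pi = np.clip(pi, 0.0, None)
        pi /= pi.sum()
        PC[k] = conditional_community_probability(pi, cs, V)
    return _normalize_rows(PC)


def belonging_probabilities(
    net: Network,
    u: str,
    cs: CommunitySet,
    wp: WalkParams | None = None,
    cfg: SimilarityConfig | None = None,
) -> ProbabilityTable:
    """Score the membership of ``u`` in every current community.

    Runs one restart walk per hypothesis ``k`` (restart vector uniform
    over ``Y_k``, start vector proportional to the similarity of ``u``
    to each walk node), averages each stationary distribution per
    community into ``PC``, weighs hypotheses by the similarity prior
    ``PP`` and returns the total-probability combination ``pu``.
    """
    wp = wp or WalkParams()
    cfg = cfg or SimilarityConfig()
    net._require(u)
    V = sorted(cs.members())
    if u in cs.members():
        raise ValueError(f"node {u!r} is already assigned")
    M = walk_matrix(net, V, cfg)
    idx = net.node_index
    sim_row = net.full_similarity(cfg)[idx[u]]
    s0 = np.array([sim_row[idx[v]] for v in V])
    s0 = s0 / s0.sum() if s0.sum() > 0 else np.full(len(V), 1.0 / len(V))
    D = _restart_vectors(cs, V)
    PC = np.empty((cs.q, cs.q))
    for k in range(cs.q):
        pi = stationary_distribution(M, D[k], s0, wp)
        PC[k] = conditional_community_probability(pi, cs, V)
    PC = _normalize_rows(PC)
    PP = membership_prior(net, u, cs, cfg)
    pu = PC.T @ PP
    return ProbabilityTable(PC=PC, PP=PP, pu=pu)


def _tightness(net: Network, u: str, comm: set[str]) -> float:
    links = sum(1 for v in comm if net.has_edge(u, v))
    return links / len(comm)


def expand_communities(
    net: Network,
    seeds: Sequence[SeedCommunity] | CommunitySet,
    wp: WalkParams | None = None,
    cfg: SimilarityConfig | None = None,
    *,
    mode: Literal["assign_unique", "overlapping"] = "assign_unique",
    overlap_tolerance: float = 0.8,
) -> CommunitySet:
    """Greedily grow communities one node at a time.

    In ``assign_unique`` mode each round scores every frontier node
    (unassigned, adjacent to at least one community) against every
    community and assigns the single pair with the largest ``pu``
    value; ties break by larger tightness, then by node label, then by
    community index.  Nodes never adjacent to any community are left
    for the refinement stage.  The output communities are disjoint
    apart from any overlap already present among the seeds.

    In ``overlapping`` mode a community may absorb a node that already
    belongs to other communities: any node ``u`` outside ``Y_k`` but
    adjacent to it qualifies for ``Y_k`` whenever
    ``pu(k) >= overlap_tolerance * max_j pu(j)`` — its membership
    probability for ``Y_k`` is close to its best.  One qualifying
    (node, community) pair — the largest ``pu`` value — is added per
    round.  Communities seeded inside the same dense region then grow
    into near-identical node sets, which the refinement stage merges;
    this is what gives the merge step its bite.

    ``PC`` depends only on the current communities — not on the frontier
    node — so it is computed once per round and shared by all
    candidates.
    """
    wp = wp or WalkParams()
    cfg = cfg or SimilarityConfig()
    if mode not in ("assign_unique", "overlapping"):
        raise ValueError(f"unknown expansion mode: {mode!r}")
    if not (0.0 < overlap_tolerance <= 1.0):
        raise ValueError("overlap_tolerance must be in (0, 1]")
    cs = seeds.copy() if isinstance(seeds, CommunitySet) else CommunitySet.from_seeds(seeds)
    for comm in cs:
        net._require(*comm)

    if mode == "overlapping":
        return _expand_overlapping(net, cs, wp, cfg, overlap_tolerance)

    sim = net.full_similarity(cfg)
    idx = net.node_index

    while True:
        assigned = cs.members()
        frontier = sorted(
            u
            for u in net.nodes - assigned
            if any(v in assigned for v in net.neighbors(u))
        )
        if not frontier:
            return cs
        V = sorted(assigned)
        PC = _conditional_matrix(net, cs, V, wp, cfg)
        v_idx = np.fromiter((idx[n] for n in V), dtype=np.intp, count=len(V))
        comm_rows = [
            np.fromiter((idx[n] for n in comm), dtype=np.intp, count=len(comm))
            for comm in cs
        ]

        best: tuple[float, float, str, int] | None = None
        for u in frontier:
            sim_row = sim[idx[u]]
            raw = np.array([sim_row[rows].mean() for rows in comm_rows])
            PP = raw / raw.sum() if raw.sum() > 0 else np.full(cs.q, 1.0 / cs.q)
            pu = PC.T @ PP
            pmax = float(pu.max())
            ties = np.flatnonzero(pu == pmax)
            k_best = int(min(ties, key=lambda k: (-_tightness(net, u, cs[k]), k)))
            cand = (pmax, _tightness(net, u, cs[k_best]), u, k_best)
            if best is None or _beats(cand, best):
                best = cand
        assert best is not None
        cs.communities[best[3]].add(best[2])


def _beats(cand: tuple[float, float, str, int], best: tuple[float, float, str, int]) -> bool:
    if cand[0] != best[0]:
        return cand[0] > best[0]
    if cand[1] != best[1]:
        return cand[1] > best[1]
    if cand[2] != best[2]:
        return cand[2] < best[2]
    return cand[3] < best[3]


def _expand_overlapping(
    net: Network,
    cs: CommunitySet,
    wp: WalkParams,
    cfg: SimilarityConfig,
    tolerance: float,
) -> CommunitySet:
    """Each round every community absorbs its best qualifying neighbor.

    A node qualifies for ``Y_k`` when it is outside but adjacent to
    ``Y_k`` and its ``pu(k)`` is within ``tolerance`` of its best
    community's value.  Ties break by sorted node label.
    """
    sim = net.full_similarity(cfg)
    idx = net.node_index

    while True:
        V = sorted(cs.members())
        PC = _conditional_matrix(net, cs, V, wp, cfg)
        comm_rows = [
            np.fromiter((idx[n] for n in comm), dtype=np.intp, count=len(comm))
            for comm in cs
        ]
        # candidate nodes: adjacent to at least one community they are not in
        adjacency: dict[str, set[int]] = {}
        for k, comm in enumerate(cs):
            for v in comm:
                for u in net.neighbors(v):
                    if u not in comm:
                        adjacency.setdefault(u, set()).add(k)
        if not adjacency:
            return cs
        cand = sorted(adjacency)
        cand_idx = np.fromiter((idx[u] for u in cand), dtype=np.intp, count=len(cand))
        raw = np.stack(
            [sim[np.ix_(cand_idx, rows)].mean(axis=1) for rows in comm_rows], axis=1
        )
        sums = raw.sum(axis=1, keepdims=True)
        PP = np.where(sums > 0, raw / np.where(sums == 0, 1.0, sums), 1.0 / cs.q)
        PU = PP @ PC  # row u: pu over communities
        cutoff = tolerance * PU.max(axis=1, keepdims=True)
        eligible = PU >= cutoff
        for i, u in enumerate(cand):
            for k in range(cs.q):
                if k not in adjacency[u]:
                    eligible[i, k] = False

        grew = False
        for k in range(cs.q):
            col = np.where(eligible[:, k], PU[:, k], -1.0)
            i = int(np.argmax(col))
            if col[i] >= 0.0:
                cs.communities[k].add(cand[i])
                grew = True
        if not grew:
            return cs
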