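"""Planted-partition benchmark generators (GN and LFR-style).

Both generators return ``(Network, Partition)`` pairs with the planted
ground truth and are bit-reproducible from their ``rng_seed``.

The GN benchmark places 128 nodes into four equal communities with a
fixed expected average degree of 16.  Its ``p_in`` parameter is, by
default, the expected FRACTION of a node's 16 edges that stay inside
its own community: intra-pair probability ``16 * p_in / 31`` and
inter-pair probability ``16 * (1 - p_in) / 96``.  (Reading ``p_in``
literally as the intra-pair probability is incompatible with a fixed
average degree of 16 once ``p_in`` exceeds ~0.52, since the expected
internal degree alone would be ``31 * p_in``; the literal reading
remains available via ``literal_probability=True``.)

The LFR-style generator draws power-law degree and community-size
sequences (exponents 2 and 1 by default), splits each node's degree
into ``~(1 - mu)`` internal and ``~mu`` external stubs and wires both
sides by random stub matching with rejection of self-loops and
parallel edges.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .graph import Network
from .refinement import Partition

__all__ = ["GNSpec", "LFRSpec", "generate_gn", "generate_lfr", "measured_mixing"]


@dataclass(frozen=True)
class GNSpec:
    p_in: float
    rng_seed: int = 0
    n_nodes: int = 128
    n_communities: int = 4
    avg_degree: float = 16.0
    literal_probability: bool = False

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_in <= 1.0):
            raise ValueError("p_in must be in [0, 1]")
        if self.n_nodes % self.n_communities != 0:
            raise ValueError("communities must divide the node count equally")


@dataclass(frozen=True)
class LFRSpec:
    N: int
    d: float
    maxd: int
    minc: int
    maxc: int
    mu: float
    degree_exponent: float = 2.0
    size_exponent: float = 1.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.mu <= 1.0):
            raise ValueError("mu must be in [0, 1]")
        if not (1 <= self.minc <= self.maxc <= self.N):
            raise ValueError("need 1 <= minc <= maxc <= N")
        if self.d > self.maxd:
            raise ValueError("average degree d cannot exceed maxd")


def generate_gn(spec: GNSpec) -> tuple[Network, Partition]:
    """Sample a GN benchmark network and its planted partition."""
    rng = np.random.default_rng(spec.rng_seed)
    n, q = spec.n_nodes, spec.n_communities
    size = n // q
    if spec.literal_probability:
        p_within = spec.p_in
        n_between = (n - size) * q * size / 2.0  # inter-community pairs
        expected_intra = (size - 1) * spec.p_in
        p_between = (spec.avg_degree - expected_intra) * n / (2.0 * n_between)
        if p_between < 0.0:
            raise ValueError(
                "literal p_in too large to keep the average degree fixed"
            )
    else:
        p_within = spec.avg_degree * spec.p_in / (size - 1)
        p_between = spec.avg_degree * (1.0 - spec.p_in) / (n - size)
    if p_within > 1.0 or p_between > 1.0:
        raise ValueError("edge probability exceeds 1 for this spec")

    membership = rng.permutation(n) % q + 1  # random equal division
    iu, ju = np.triu_indices(n, k=1)
    same = membership[iu] == membership[ju]
    probs = np.where(same, p_within, p_between)
    keep = rng.random(len(probs)) < probs
    labels = [str(i + 1) for i in range(n)]
    edges = [(labels[i], labels[j]) for i, j in zip(iu[keep], ju[keep])]
    net = Network(edges=edges, nodes=labels)
    part = Partition({labels[i]: int(membership[i]) for i in range(n)})
    return net, part


# -- LFR-style construction -------------------------------------------


def _truncated_power_law_probs(lo: int, hi: int, exponent: float) -> np.ndarray:
    ks = np.arange(lo, hi + 1, dtype=float)
    w = ks ** (-exponent)
    return w / w.sum()


def _degree_sequence(spec: LFRSpec, rng: np.random.Generator) -> np.ndarray:
    """Power-law degrees with expected mean ``d``.

    The upper cutoff is the smaller of ``maxd`` and the feasibility
    bound ``(maxc - 1) / (1 - mu)`` — a node's expected internal degree
    must fit inside the largest community, the standard LFR consistency
    requirement.  The lower cutoff is randomized between the two
    integers bracketing the mean constraint so the expectation matches
    ``d`` exactly.
    """
    hi = spec.maxd
    if spec.mu < 1.0:
        hi = min(hi, int((spec.maxc - 1) / (1.0 - spec.mu)))
    if hi < 1 or spec.d > hi:
        raise ValueError("degree bounds infeasible for this spec")

    def mean_for(lo: int) -> float:
        p = _truncated_power_law_probs(lo, hi, spec.degree_exponent)
        return float(np.arange(lo, hi + 1) @ p)

    lo = 1
    while lo < hi and mean_for(lo + 1) <= spec.d:
        lo += 1
    m_lo, m_hi = mean_for(lo), mean_for(min(lo + 1, hi))
    frac = 0.0 if m_hi <= m_lo else float(np.clip((spec.d - m_lo) / (m_hi - m_lo), 0, 1))
    cuts = (lo, min(lo + 1, hi))
    supports = {c: np.arange(c, hi + 1) for c in cuts}
    probs = {
        c: _truncated_power_law_probs(c, hi, spec.degree_exponent) for c in cuts
    }
    degrees = np.empty(spec.N, dtype=int)
    for i in range(spec.N):
        c = cuts[1] if rng.random() < frac else cuts[0]
        degrees[i] = rng.choice(supports[c], p=probs[c])
    return degrees


def _community_sizes(spec: LFRSpec, rng: np.random.Generator) -> list[int]:
    probs = _truncated_power_law_probs(spec.minc, spec.maxc, spec.size_exponent)
    support = np.arange(spec.minc, spec.maxc + 1)
    for _ in range(200):
        sizes: list[int] = []
        total = 0
        while total < spec.N:
            s = int(rng.choice(support, p=probs))
            sizes.append(s)
            total += s
        excess = total - spec.N
        # shed the excess by shrinking communities down to minc
        for i in range(len(sizes)):
            if excess == 0:
                break
            take = min(excess, sizes[i] - spec.minc)
            sizes[i] -= take
            excess -= take
        if excess == 0 and sum(sizes) == spec.N:
            return sizes
    raise ValueError("could not tile N with community sizes in [minc, maxc]")


def _match_stubs(
    stubs: np.ndarray,
    rng: np.random.Generator,
    forbidden_same: np.ndarray | None = None,
    rounds: int = 30,
) -> set[tuple[int, int]]:
    """Random stub matching, rejecting self-loops, parallel edges and
    (optionally) pairs from the same block; unmatched stubs are dropped."""
    edges: set[tuple[int, int]] = set()
    pool = stubs.copy()
    for _ in range(rounds):
        if len(pool) < 2:
            break
        rng.shuffle(pool)
        if len(pool) % 2 == 1:
            pool = pool[:-1]
        a, b = pool[0::2], pool[1::2]
        leftover = []
        for u, v in zip(a, b):
            u, v = (int(u), int(v)) if u < v else (int(v), int(u))
            bad = (
                u == v
                or (u, v) in edges
                or (forbidden_same is not None and forbidden_same[u] == forbidden_same[v])
            )
            if bad:
                leftover.extend((u, v))
            else:
                edges.add((u, v))
        pool = np.array(leftover, dtype=int)
    return edges


def generate_lfr(spec: LFRSpec) -> tuple[Network, Partition]:
    """Sample an LFR-style benchmark network and its planted partition."""
    rng = np.random.default_rng(spec.rng_seed)
    degrees = _degree_sequence(spec, rng)
    sizes = _community_sizes(spec, rng)
    q = len(sizes)

    # assign nodes to communities, preferring ones their internal degree
    # fits into; when none fits the internal degree is capped at the
    # community size - 1 and the excess stubs become external
    internal = np.array(
        [int(np.floor((1.0 - spec.mu) * k + rng.random())) for k in degrees]
    )
    internal = np.minimum(internal, degrees)
    order = rng.permutation(spec.N)
    capacity = list(sizes)
    member = np.full(spec.N, -1, dtype=int)
    for i in order:
        open_c = [c for c in range(q) if capacity[c] > 0]
        fitting = [c for c in open_c if internal[i] <= sizes[c] - 1]
        c = int(rng.choice(fitting if fitting else open_c))
        member[i] = c
        capacity[c] -= 1
        internal[i] = min(internal[i], sizes[c] - 1)

    # wire internal stubs per community, external stubs globally
    edges: set[tuple[int, int]] = set()
    for c in range(q):
        nodes_c = np.flatnonzero(member == c)
        stubs = np.repeat(nodes_c, internal[nodes_c])
        edges |= _match_stubs(stubs, rng)
    ext = degrees - internal
    ext_stubs = np.repeat(np.arange(spec.N), ext)
    edges |= _match_stubs(ext_stubs, rng, forbidden_same=member)

    labels = [str(i + 1) for i in range(spec.N)]
    net = Network(
        edges=[(labels[u], labels[v]) for u, v in sorted(edges)], nodes=labels
    )
    part = Partition({labels[i]: int(member[i]) + 1 for i in range(spec.N)})
    return net, part


def measured_mixing(net: Network, part: Partition) -> float:
    """Mean per-node fraction of edges leaving the node's community."""
    fracs = []
    for u in net.node_order:
        nbrs = net.neighbors(u)
        if not nbrs:
            continue
        ext = sum(1 for v in nbrs if part[v] != part[u])
        fracs.append(ext / len(nbrs))
    return float(np.mean(fracs))
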