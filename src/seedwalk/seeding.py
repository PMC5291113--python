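"""Seed-community detection around local maximal degree nodes.

A local maximal degree node is a node whose degree is at least the
degree of each of its neighbors; such hubs anchor small dense seed
communities (complete triples by default) from which expansion grows
full communities.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .graph import Network

__all__ = [
    "SeedParams",
    "SeedCommunity",
    "local_maximal_degree_nodes",
    "detect_seed_communities",
    "consolidate_seeds",
    "ensure_seed_coverage",
]


@dataclass(frozen=True)
class SeedParams:
    """Seed-size parameter; the default size of 3 performs best."""

    Z: int = 3

    def __post_init__(self) -> None:
        if self.Z < 3:
            raise ValueError("seed size Z must be >= 3")


@dataclass(frozen=True)
class SeedCommunity:
    """A dense node set grown from a local-maximal-degree anchor."""

    members: frozenset[str]
    anchor: str

    def __post_init__(self) -> None:
        if self.anchor not in self.members:
            raise ValueError("anchor must be a member of the seed")


def local_maximal_degree_nodes(net: Network) -> set[str]:
    """Nodes whose degree is >= that of every neighbor (ties admit).

    Isolated nodes are excluded: a hub with no neighbors cannot anchor
    a community.
    """
    if net.number_of_nodes() == 0:
        raise ValueError("network is empty")
    out: set[str] = set()
    for u in net.node_order:
        nbrs = net.neighbors(u)
        if not nbrs:
            continue
        du = net.degree(u)
        if all(du >= net.degree(v) for v in nbrs):
            out.add(u)
    return out


def _grow_seed(net: Network, members: set[str], z: int) -> set[str]:
    # Greedily add the outside node with the most edges into the seed,
    # requiring at least one edge so the seed stays connected.
    members = set(members)
    while len(members) < z:
        best: tuple[int, str] | None = None
        for u in members:
            for v in net.neighbors(u):
                if v in members:
                    continue
                links = sum(1 for w in members if net.has_edge(v, w))
                cand = (links, v)
                if best is None or links > best[0] or (links == best[0] and v < best[1]):
                    best = cand
        if best is None:
            break
        members.add(best[1])
    return members


def detect_seed_communities(
    net: Network,
    params: SeedParams | None = None,
    *,
    component_fallback: bool = True,
) -> list[SeedCommunity]:
    """Build dense seed communities around local maximal degree nodes.

    For each hub ``n1``, each neighbor ``n2`` that is locally maximal
    within ``n1``'s neighborhood (its degree is >= the degree of every
    common neighbor of ``n1`` and ``n2``), and each common neighbor
    ``n3``, the triple ``{n1, n2, n3}`` is a candidate seed.  Duplicate
    node sets are emitted once and seeds fully contained in another seed
    are dropped.  A connected component that yields no triangle-based
    seed falls back to its highest-degree node plus its top ``Z - 1``
    degree neighbors, so every component can be seeded.

    Results are deterministic: candidates are ordered by sorted member
    labels.
    """
    params = params or SeedParams()
    if net.number_of_nodes() == 0:
        raise ValueError("network is empty")

    hubs = local_maximal_degree_nodes(net)
    raw: dict[frozenset[str], str] = {}
    for n1 in sorted(hubs):
        nbrs1 = net.neighbors(n1)
        for n2 in sorted(nbrs1):
            common = nbrs1 & net.neighbors(n2)
            if not common:
                continue
            # n2 must dominate every node it competes with inside n1's
            # neighborhood, keeping the seed centered on local hubs.
            d2 = net.degree(n2)
            if any(net.degree(w) > d2 for w in common):
                continue
            for n3 in sorted(common):
                members = frozenset(
                    _grow_seed(net, {n1, n2, n3}, params.Z)
                )
                if len(members) >= params.Z:
                    raw.setdefault(members, n1)

    # Drop seeds strictly contained in another seed.
    keys = sorted(raw, key=lambda s: (-len(s), tuple(sorted(s))))
    kept: list[frozenset[str]] = []
    for s in keys:
        if not any(s < other for other in kept):
            kept.append(s)

    seeds = [SeedCommunity(members=s, anchor=raw[s]) for s in kept]
    seeds.sort(key=lambda sc: tuple(sorted(sc.members)))

    if component_fallback:
        seeds = _component_fallback(net, params, seeds)
    return seeds


def ensure_seed_coverage(
    net: Network, seeds: list[SeedCommunity], params: SeedParams | None = None
) -> list[SeedCommunity]:
    """Re-seed the parts of the network no seed has reached.

    Dense regions whose hubs are shadowed by higher-degree neighbors in
    other regions produce no seed on the first pass; their nodes would
    be swallowed by neighboring communities during expansion.  This
    repeatedly detects seeds on the subgraph induced by nodes outside
    every current seed until no further triangle-based seed exists.
    Duplicate seeds planted inside an already-seeded region are cheap:
    expansion grows them into near-identical communities that merge.
    """
    params = params or SeedParams()
    seeds = list(seeds)
    while True:
        covered = set().union(*(s.members for s in seeds)) if seeds else set()
        residual = net.nodes - covered
        if len(residual) < params.Z:
            return seeds
        sub = net.subgraph(residual)
        new = detect_seed_communities(sub, params, component_fallback=False)
        new = consolidate_seeds(sub, new)
        if not new:
            return seeds
        seeds.extend(new)


def consolidate_seeds(net: Network, seeds: list[SeedCommunity]) -> list[SeedCommunity]:
    """Collapse seed triples into one dense seed per anchor.

    All triangles through the same pair of high-degree nodes describe a
    single dense subgraph (the pair plus its common neighbors), so the
    candidate triples are first grouped by their two highest-degree
    members and unioned.  For each anchor only its largest group is
    kept: a hub pair straddling two communities supports far fewer
    triangles than a pair inside one, so the largest group is the one
    rooted in the anchor's own dense region.  Groups contained in
    another kept group are dropped.
    """
    groups: dict[frozenset[str], set[str]] = {}
    anchors: dict[frozenset[str], str] = {}
    for s in seeds:
        ranked = sorted(s.members, key=lambda n: (-net.degree(n), n))
        key = frozenset(ranked[:2])
        groups.setdefault(key, set()).update(s.members)
        anchors.setdefault(key, s.anchor)
    best_per_anchor: dict[str, set[str]] = {}
    for key, members in sorted(
        groups.items(), key=lambda kv: (-len(kv[1]), tuple(sorted(kv[1])))
    ):
        a = anchors[key]
        if a not in best_per_anchor:
            best_per_anchor[a] = members
    ordered = sorted(
        best_per_anchor.items(), key=lambda kv: (-len(kv[1]), tuple(sorted(kv[1])))
    )
    kept: list[SeedCommunity] = []
    for anchor, members in ordered:
        if any(members <= set(other.members) for other in kept):
            continue
        kept.append(SeedCommunity(members=frozenset(members), anchor=anchor))
    kept.sort(key=lambda sc: tuple(sorted(sc.members)))
    return kept


def _component_fallback(
    net: Network, params: SeedParams, seeds: list[SeedCommunity]
) -> list[SeedCommunity]:
    # Fallback for components without any triangle-based seed.
    covered = set().union(*(s.members for s in seeds)) if seeds else set()
    for comp in sorted(net.connected_components(), key=lambda c: min(c)):
        if len(comp) < 2 or comp & covered:
            continue
        hub = max(sorted(comp), key=lambda n: (net.degree(n), n))
        nbrs = sorted(net.neighbors(hub), key=lambda n: (-net.degree(n), n))
        members = frozenset({hub, *nbrs[: params.Z - 1]})
        if len(members) >= 2:
            seeds.append(SeedCommunity(members=members, anchor=hub))
    if not seeds:
        raise ValueError("no seed community could be constructed")
    return seeds
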