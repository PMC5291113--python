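"""Community optimization: leftover assignment, merging, final cover.

After expansion, low-degree nodes that never touched a community are
placed by tightness, heavily overlapping communities are merged via the
overlap coefficient, residual overlaps are resolved, and the result is
a total disjoint partition of the node set.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, Mapping, Sequence

from .expansion import CommunitySet, WalkParams, expand_communities
from .graph import Network, SimilarityConfig
from .seeding import (
    SeedParams,
    consolidate_seeds,
    detect_seed_communities,
    ensure_seed_coverage,
)

__all__ = [
    "MergeParams",
    "Partition",
    "tightness",
    "assign_leftovers",
    "merge_communities",
    "finalize_partition",
    "run_rwa",
]


@dataclass(frozen=True)
class MergeParams:
    """Overlap-coefficient threshold; at 0.5 most members of the
    smaller community must already sit inside the larger one."""

    xi: float = 0.5

    def __post_init__(self) -> None:
        if not (0.0 < self.xi <= 1.0):
            raise ValueError("xi must be in (0, 1]")


class Partition:
    """A total, disjoint node -> community-index mapping (1-based)."""

    __slots__ = ("_map",)

    def __init__(self, mapping: Mapping[str, int]):
        if not mapping:
            raise ValueError("partition cannot be empty")
        labels = sorted(set(mapping.values()))
        if labels != list(range(1, len(labels) + 1)):
            relabel = {old: new for new, old in enumerate(labels, start=1)}
            mapping = {n: relabel[c] for n, c in mapping.items()}
        self._map = dict(mapping)

    @property
    def mapping(self) -> dict[str, int]:
        return dict(self._map)

    @property
    def nodes(self) -> frozenset[str]:
        return frozenset(self._map)

    @property
    def n_communities(self) -> int:
        return max(self._map.values())

    def __getitem__(self, node: str) -> int:
        return self._map[node]

    def __len__(self) -> int:
        return len(self._map)

    def __iter__(self) -> Iterator[str]:
        return iter(self._map)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, Partition) and self._map == other._map

    def communities(self) -> list[set[str]]:
        out: list[set[str]] = [set() for _ in range(self.n_communities)]
        for n, c in self._map.items():
            out[c - 1].add(n)
        return out

    def __repr__(self) -> str:  # pragma: no cover
        return f"Partition(n_nodes={len(self)}, n_communities={self.n_communities})"


def tightness(net: Network, u: str, community: set[str] | frozenset[str]) -> float:
    """Fraction of the community's members adjacent to ``u``."""
    if not community:
        raise ValueError("community is empty")
    if u in community:
        raise ValueError(f"node {u!r} is already in the community")
    net._require(u)
    links = sum(1 for v in community if net.has_edge(u, v))
    return links / len(community)


def assign_leftovers(net: Network, cs: CommunitySet) -> CommunitySet:
    """Attach every uncovered node to its tightest community.

    Leftovers are processed in increasing degree order (ties by label)
    so low-degree stragglers settle before better-connected ones; a
    node with zero tightness everywhere becomes its own singleton
    community.  Ties between communities go to the lowest index.
    """
    cs = cs.copy()
    leftovers = sorted(net.nodes - cs.members(), key=lambda n: (net.degree(n), n))
    for u in leftovers:
        scores = [tightness(net, u, c) for c in cs]
        best = max(scores)
        if best == 0.0:
            cs.communities.append({u})
        else:
            cs.communities[scores.index(best)].add(u)
    return cs


def _overlap_ratio(a: set[str], b: set[str]) -> float:
    return len(a & b) / min(len(a), len(b))


def merge_communities(cs: CommunitySet, mp: MergeParams | None = None) -> CommunitySet:
    """Union community pairs whose overlap coefficient reaches ``xi``.

    Pairs merge largest ratio first (ties by lowest indices); the count
    strictly decreases each step, so the loop terminates and is
    idempotent at its fixpoint.
    """
    mp = mp or MergeParams()
    comms = [set(c) for c in cs]
    while len(comms) > 1:
        best: tuple[float, int, int] | None = None
        for i in range(len(comms)):
            for j in range(i + 1, len(comms)):
                r = _overlap_ratio(comms[i], comms[j])
                if r >= mp.xi and (best is None or r > best[0]):
                    best = (r, i, j)
        if best is None:
            break
        _, i, j = best
        comms[i] = comms[i] | comms[j]
        del comms[j]
    return CommunitySet(comms)


def finalize_partition(net: Network, cs: CommunitySet) -> Partition:
    """Resolve residual overlaps and emit a total disjoint partition.

    A node still claimed by several communities stays in the one it is
    tightest to (membership in each candidate evaluated with the node
    itself excluded); ties go to the lowest index.  Indices are
    renumbered contiguously from 1.
    """
    uncovered = net.nodes - cs.members()
    if uncovered:
        raise RuntimeError(
            f"finalize_partition: {len(uncovered)} node(s) not covered by any community"
        )
    claims: dict[str, list[int]] = {}
    for k, comm in enumerate(cs):
        for n in comm:
            claims.setdefault(n, []).append(k)
    mapping: dict[str, int] = {}
    for n, ks in claims.items():
        if len(ks) == 1:
            mapping[n] = ks[0]
        else:
            def score(k: int) -> tuple[float, int]:
                others = cs[k] - {n}
                t = tightness(net, n, others) if others else 0.0
                return (-t, k)

            mapping[n] = min(ks, key=score)
    # drop empty communities, renumber contiguously preserving order
    used = sorted(set(mapping.values()))
    relabel = {k: i for i, k in enumerate(used, start=1)}
    return Partition({n: relabel[k] for n, k in mapping.items()})


def run_rwa(
    net: Network,
    sp: SeedParams | None = None,
    wp: WalkParams | None = None,
    mp: MergeParams | None = None,
    cfg: SimilarityConfig | None = None,
    *,
    merge_seeds: bool = True,
    merge_before_leftovers: bool = False,
    expansion_mode: str = "overlapping",
    overlap_tolerance: float = 0.9,
) -> Partition:
    """Full detection pipeline: seed, expand, optimize, finalize.

    Steps: detect seed communities around local maximal degree nodes;
    (optionally, default on) consolidate seed triples that share a hub
    pair into one dense seed; expand by random walks; attach leftovers
    by tightness; merge overlapping communities; resolve residual
    overlaps.  Deterministic for fixed inputs.

    ``expansion_mode`` defaults to ``"overlapping"``: seeds planted in
    the same dense region grow into near-identical communities that the
    merge step collapses, which is what makes the number of detected
    communities insensitive to the number of seeds.  The
    ``"assign_unique"`` mode grows strictly disjoint communities
    instead (one global-argmax assignment per round).
    """
    sp = sp or SeedParams()
    wp = wp or WalkParams()
    mp = mp or MergeParams()
    cfg = cfg or SimilarityConfig()
    if net.number_of_nodes() == 0:
        raise ValueError("network is empty")
    if net.number_of_nodes() == 1:
        return Partition({n: 1 for n in net.nodes})
    seeds = detect_seed_communities(net, sp)
    if merge_seeds:
        seeds = consolidate_seeds(net, seeds)
        seeds = ensure_seed_coverage(net, seeds, sp)
    cs = CommunitySet.from_seeds(seeds)
    cs = expand_communities(
        net, cs, wp, cfg, mode=expansion_mode, overlap_tolerance=overlap_tolerance
    )
    if merge_before_leftovers:
        cs = merge_communities(cs, mp)
        cs = assign_leftovers(net, cs)
    else:
        cs = assign_leftovers(net, cs)
        cs = merge_communities(cs, mp)
    return finalize_partition(net, cs)
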