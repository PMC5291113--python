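"""Partition comparison (NMI, per-community F1) and strong/weak labels.

NMI is computed from the R x F confusion matrix between the reference
and found partitions with the standard symmetric normalization
``2 I(R; F) / (H(R) + H(F))``: 1 for identical partitions (up to
relabeling), 0 when the found partition carries no information about
the reference (e.g. everything in one community).

Community strength comes in two flavors, selected by ``mode``:

``per_rest_community`` (default)
    strong — every member has strictly more neighbors inside its own
    community than inside ANY single other community; weak — the
    community's internal degree sum strictly exceeds its edge count to
    EACH other community.
``inside_vs_outside``
    the classical variant comparing against all external edges
    combined; here strong implies weak.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Mapping, Sequence

import numpy as np

from .graph import Network
from .refinement import Partition

__all__ = [
    "MetricsReport",
    "nmi",
    "f1_report",
    "classify_communities",
    "evaluate",
]

StrengthMode = Literal["per_rest_community", "inside_vs_outside"]


@dataclass(frozen=True)
class MetricsReport:
    nmi: float
    per_community: tuple[tuple[float, float, float], ...]
    overall_f1: float
    labels: tuple[str, ...] | None = None


def _as_partition(p: Partition | Mapping[str, int]) -> Partition:
    return p if isinstance(p, Partition) else Partition(p)


def _confusion(reference: Partition, found: Partition) -> np.ndarray:
    if reference.nodes != found.nodes:
        raise ValueError("partitions cover different node sets")
    X = np.zeros((reference.n_communities, found.n_communities))
    for n in reference:
        X[reference[n] - 1, found[n] - 1] += 1
    return X


def nmi(reference: Partition | Mapping[str, int], found: Partition | Mapping[str, int]) -> float:
    """Normalized mutual information between two partitions."""
    reference, found = _as_partition(reference), _as_partition(found)
    X = _confusion(reference, found)
    n = X.sum()
    pr = X.sum(axis=1) / n
    pf = X.sum(axis=0) / n
    hr = -np.sum(pr[pr > 0] * np.log(pr[pr > 0]))
    hf = -np.sum(pf[pf > 0] * np.log(pf[pf > 0]))
    if hr + hf == 0.0:
        return 1.0  # both partitions trivial, hence identical
    p = X / n
    mask = p > 0
    mi = float(np.sum(p[mask] * np.log(p[mask] / np.outer(pr, pf)[mask])))
    return float(np.clip(2.0 * mi / (hr + hf), 0.0, 1.0))


def f1_report(
    reference: Partition | Mapping[str, int], found: Partition | Mapping[str, int]
) -> MetricsReport:
    """Best-match precision/recall/F1 for each reference community.

    Each reference community is matched to the found community
    maximizing F1; the overall score is the unweighted mean over
    reference communities.
    """
    reference, found = _as_partition(reference), _as_partition(found)
    ref_comms = reference.communities()
    found_comms = found.communities()
    per: list[tuple[float, float, float]] = []
    for rc in ref_comms:
        best = (0.0, 0.0, 0.0)
        for fc in found_comms:
            overlap = len(rc & fc)
            if overlap == 0:
                continue
            precision = overlap / len(fc)
            recall = overlap / len(rc)
            f1 = 2.0 * precision * recall / (precision + recall)
            if f1 > best[2]:
                best = (precision, recall, f1)
        per.append(best)
    overall = float(np.mean([t[2] for t in per]))
    return MetricsReport(
        nmi=nmi(reference, found), per_community=tuple(per), overall_f1=overall
    )


def _internal_external(
    net: Network, comms: Sequence[set[str]], member_of: Mapping[str, int]
) -> tuple[list[dict[str, np.ndarray]], np.ndarray]:
    """Per-node neighbor counts into every community, plus the cut matrix."""
    q = len(comms)
    per_node: list[dict[str, np.ndarray]] = []
    cut = np.zeros((q, q))
    for k, comm in enumerate(comms):
        counts: dict[str, np.ndarray] = {}
        for v in comm:
            row = np.zeros(q)
            for w in net.neighbors(v):
                row[member_of[w]] += 1
            counts[v] = row
            cut[k] += row
        per_node.append(counts)
    return per_node, cut


def classify_communities(
    net: Network,
    partition: Partition | Mapping[str, int],
    mode: StrengthMode = "per_rest_community",
) -> tuple[str, ...]:
    """Label every community ``strong``, ``weak`` or ``neither``."""
    partition = _as_partition(partition)
    if partition.nodes != net.nodes:
        raise ValueError("partition does not cover the network's node set")
    comms = partition.communities()
    member_of = {n: partition[n] - 1 for n in partition}
    q = len(comms)
    labels: list[str] = []
    per_node, cut = _internal_external(net, comms, member_of)
    for k in range(q):
        internal_sum = cut[k, k]  # counts each internal edge twice
        if mode == "per_rest_community":
            strong = all(
                all(row[k] > row[j] for j in range(q) if j != k)
                for row in per_node[k].values()
            )
            weak = all(internal_sum > cut[k, j] for j in range(q) if j != k)
        elif mode == "inside_vs_outside":
            strong = all(
                row[k] > (row.sum() - row[k]) for row in per_node[k].values()
            )
            weak = internal_sum > (cut[k].sum() - internal_sum)
        else:
            raise ValueError(f"unknown strength mode: {mode!r}")
        labels.append("strong" if strong else ("weak" if weak else "neither"))
    return tuple(labels)


def evaluate(
    reference: Partition | Mapping[str, int],
    found: Partition | Mapping[str, int],
    net: Network | None = None,
    mode: StrengthMode = "per_rest_community",
) -> MetricsReport:
    """Full report: NMI, per-community F1, and (if a network is given)
    strong/weak labels of the found communities."""
    rep = f1_report(reference, found)
    labels = classify_communities(net, found, mode) if net is not None else None
    return MetricsReport(
        nmi=rep.nmi,
        per_community=rep.per_community,
        overall_f1=rep.overall_f1,
        labels=labels,
    )
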