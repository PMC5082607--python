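"""Cluster partitions: from a node attribute, from explicit ids, or by MCL.

Two partition sources mirror the tool's create dialog: grouping nodes that
share a value of a chosen attribute, and the Markov Cluster algorithm (MCL)
run on the (optionally weighted) adjacency matrix.  Either way the result is
a :class:`Partition` — pairwise-disjoint clusters plus an ``unclustered``
remainder that together cover the node set.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Hashable, Mapping

import numpy as np

from .graph import Network

#: MCL numerical policy: convergence in max-norm, per-iteration pruning of
#: tiny entries, iteration cap.  Self-loops of weight 1 guarantee aperiodicity.
MCL_CONVERGENCE_TOL = 1e-8
MCL_PRUNE_THRESHOLD = 1e-6
MCL_MAX_ITERATIONS = 100


@dataclass
class Partition:
    """Disjoint clusters plus unclustered remainder covering a node set."""

    clusters: dict[Hashable, set[str]] = field(default_factory=dict)
    unclustered: set[str] = field(default_factory=set)

    def validate(self, net: Network | None = None) -> None:
        seen: set[str] = set()
        for cid, members in self.clusters.items():
            if not members:
                raise ValueError(f"cluster {cid!r} is empty")
            overlap = seen & members
            if overlap:
                raise ValueError(f"clusters overlap on {sorted(overlap)}")
            seen |= members
        if seen & self.unclustered:
            raise ValueError("unclustered nodes overlap a cluster")
        if net is not None and seen | self.unclustered != net.nodes:
            raise ValueError("partition does not cover the node set")

    def covered(self) -> set[str]:
        out: set[str] = set()
        for members in self.clusters.values():
            out |= members
        return out

    def __len__(self) -> int:
        return len(self.clusters)


def clusters_from_attribute(net: Network, attr: str) -> Partition:
    """One cluster per distinct value of ``attr``; nodes without it go unclustered."""
    if not net.has_attr(attr):
        raise ValueError(f"attribute {attr!r} exists on no node")
    clusters: dict = {}
    unclustered: set[str] = set()
    for node in net.nodes:
        value = net.get_attr(node, attr)
        if value is None or value == "":
            unclustered.add(node)
        else:
            clusters.setdefault(value, set()).add(node)
    part = Partition(clusters, unclustered)
    part.validate(net)
    return part


def partition_from_ids(assignments: Mapping[str, Hashable],
                       net: Network | None = None) -> Partition:
    """Group nodes by a user-supplied cluster id.

    Ids are opaque: the text ``"1"`` and the number ``1`` name distinct
    clusters.  Nodes of ``net`` absent from ``assignments`` go unclustered.
    """
    clusters: dict = {}
    for node, cid in assignments.items():
        clusters.setdefault(cid, set()).add(node)
    unclustered = (net.nodes - set(assignments)) if net is not None else set()
    part = Partition(clusters, unclustered)
    part.validate(net)
    return part


def mcl_clusters(net: Network, edge_weight_attr: str | None = None,
                 inflation: float = 2.0) -> Partition:
    """Partition by the Markov Cluster algorithm.

    Builds the symmetric (weighted) adjacency matrix with unit self-loops,
    column-normalizes it to a transition matrix, then alternates expansion
    (matrix squaring) and inflation (entrywise power ``inflation`` followed by
    column renormalization) until successive matrices differ by less than
    ``MCL_CONVERGENCE_TOL`` in max norm or ``MCL_MAX_ITERATIONS`` is reached.
    Entries below ``MCL_PRUNE_THRESHOLD`` are pruned each iteration.  Clusters
    are read off the attractor rows of the converged matrix; a node attracted
    to no attractor becomes its own singleton cluster.

    The result is deterministic and always refines the connected-components
    partition.  Cluster ids are consecutive integers ordered by descending
    cluster size, ties broken by the smallest member id.
    """
    if inflation <= 1:
        raise ValueError(f"inflation must be > 1, got {inflation}")
    if not net.nodes:
        raise ValueError("cannot cluster an empty network")

    order = sorted(net.nodes)
    index = {n: i for i, n in enumerate(order)}
    n = len(order)
    matrix = np.zeros((n, n))
    for e in net.edges:
        if e.source == e.target:
            continue
        if edge_weight_attr is not None:
            w = e.attrs.get(edge_weight_attr)
            if w is None:
                w = 1.0
            w = float(w)
            if w <= 0:
                raise ValueError(
                    f"edge {e.source!r}-{e.target!r}: non-positive weight {w}"
                )
        else:
            w = 1.0
        i, j = index[e.source], index[e.target]
        # parallel edges collapse onto the strongest link
        matrix[i, j] = max(matrix[i, j], w)
        matrix[j, i] = matrix[i, j]
    np.fill_diagonal(matrix, 1.0)

    matrix = matrix / matrix.sum(axis=0, keepdims=True)
    for _ in range(MCL_MAX_ITERATIONS):
        expanded = matrix @ matrix
        inflated = expanded ** inflation
        inflated[inflated < MCL_PRUNE_THRESHOLD] = 0.0
        colsum = inflated.sum(axis=0, keepdims=True)
        colsum[colsum == 0] = 1.0
        inflated /= colsum
        if np.max(np.abs(inflated - matrix)) < MCL_CONVERGENCE_TOL:
            matrix = inflated
            break
        matrix = inflated

    # attractor rows: union the columns supported by each nonzero row
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i: int, j: int) -> None:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[rj] = ri

    for i in range(n):
        support = np.nonzero(matrix[i] > MCL_PRUNE_THRESHOLD)[0]
        for j in support:
            union(i, j)

    groups: dict[int, set[str]] = {}
    for i, node in enumerate(order):
        groups.setdefault(find(i), set()).add(node)

    ranked = sorted(groups.values(), key=lambda m: (-len(m), min(m)))
    part = Partition({cid: members for cid, members in enumerate(ranked, start=1)})
    part.validate(net)
    return part
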