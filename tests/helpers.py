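"""Shared test utilities: random generators and independent oracles."""

from __future__ import annotations

import itertools
from collections import Counter

import numpy as np

from netannotate import Network, Partition
from netannotate.wordcloud import WordInfo

WORD_POOL = [f"w{i:02d}" for i in range(12)]


def random_cloud(rng: np.random.Generator, max_words: int = 8) -> list[WordInfo]:
    """Random word cloud with deliberate size ties and random groups."""
    n = int(rng.integers(0, max_words + 1))
    words = list(rng.choice(WORD_POOL, size=n, replace=False))
    orders = list(rng.permutation(n))
    n_groups = max(1, int(rng.integers(1, n + 1))) if n else 1
    return [
        WordInfo(word=w,
                 size=float(rng.integers(1, 6) * 10),  # coarse → frequent ties
                 order=int(orders[i]),
                 group=int(rng.integers(1, n_groups + 1)))
        for i, w in enumerate(words)
    ]


def brute_force_biggest(cloud, n):
    """Subset-enumeration oracle for biggest-words selection.

    Pick the size-m subset whose descending (size, -order) profile is
    lexicographically greatest — total size maximized, size ties resolved
    toward earlier-appearing words — then emit in first-appearance order.
    """
    m = min(n, len(cloud))
    if m == 0:
        return []
    best = max(
        itertools.combinations(cloud, m),
        key=lambda sub: sorted(((w.size, -w.order) for w in sub), reverse=True),
    )
    return [w.word for w in sorted(best, key=lambda w: w.order)]


def random_attributed_network(rng: np.random.Generator, n_nodes: int = 12,
                              p_edge: float = 0.3) -> Network:
    """Random graph with text attributes and positions on every node."""
    net = Network()
    vocab = ["alpha", "beta", "gamma", "delta", "cycle", "repair", "fusion"]
    for i in range(n_nodes):
        words = rng.choice(vocab, size=4, replace=True)
        net.add_node(f"n{i:02d}",
                     attrs={"desc": " ".join(words), "score": float(i)},
                     position=(float(rng.normal(0, 50)), float(rng.normal(0, 50))))
    nodes = sorted(net.nodes)
    for a, b in itertools.combinations(nodes, 2):
        if rng.random() < p_edge:
            attrs = {"weight": float(rng.integers(1, 5))} if rng.random() < 0.5 else {}
            net.add_edge(a, b, attrs)
    # occasional parallel edge and self-loop to exercise multigraph handling
    if len(net.edges) > 1 and rng.random() < 0.5:
        e = net.edges[0]
        net.add_edge(e.source, e.target)
    if rng.random() < 0.3:
        net.add_edge(nodes[0], nodes[0])
    return net


def random_partition(rng: np.random.Generator, net: Network,
                     n_clusters: int = 3) -> Partition:
    """Random disjoint partition leaving some nodes unclustered."""
    nodes = sorted(net.nodes)
    assignment = rng.integers(0, n_clusters + 1, size=len(nodes))  # 0 = unclustered
    clusters: dict = {}
    unclustered = set()
    for node, cid in zip(nodes, assignment):
        if cid == 0:
            unclustered.add(node)
        else:
            clusters.setdefault(int(cid), set()).add(node)
    return Partition(clusters=clusters, unclustered=unclustered)


def expected_meta_edges(original: Network, partition: Partition) -> Counter:
    """Brute-force boundary scan: expected meta-edge endpoints and counts
    after collapsing every cluster of ``partition`` on ``original``."""
    rep = {}
    for cid, members in partition.clusters.items():
        for m in members:
            rep[m] = f"group:{cid}"
    for node in original.nodes:
        rep.setdefault(node, node)
    counts: Counter = Counter()
    for e in original.edges:
        ru, rv = rep[e.source], rep[e.target]
        if ru != rv and (ru.startswith("group:") or rv.startswith("group:")):
            counts[frozenset((ru, rv))] += 1
    return counts


def partition_labels(partition: Partition, nodes: list[str]) -> list[str]:
    """Flat cluster labels (for ARI); unclustered nodes get unique labels."""
    label = {}
    for cid, members in partition.clusters.items():
        for m in members:
            label[m] = f"c{cid}"
    for m in partition.unclustered:
        label[m] = f"u:{m}"
    return [label[n] for n in nodes]
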