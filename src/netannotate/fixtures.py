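"""Synthetic modular networks with planted word themes.

Every stage of the pipeline is testable without external datasets: the
generator plants a partition (planted-partition / stochastic block graph
with within-cluster edge probability ``p_in`` and between-cluster
probability ``p_out``), gives each node a text attribute whose words come
mostly from a cluster-specific theme vocabulary (fraction ``theme_fraction``)
and otherwise from a shared background vocabulary with Zipf-like weights —
so a handful of filler words ("pathway", "regulation", ...) are frequent
throughout the network, emulating the recurrent vocabulary of pathway
descriptions or publication titles — and positions nodes with a per-cluster
Gaussian so geometry and rendering are exercised too.

All randomness flows from the ``seed`` argument; a fixed seed reproduces the
network bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .clustering import Partition
from .graph import Network

#: frequent filler words shared across the whole network
BACKGROUND_FILLERS = (
    "pathway", "regulation", "signaling", "process", "cell", "protein",
    "gene", "expression", "response", "activity", "complex", "binding",
    "positive", "negative", "transport", "metabolic",
)

TEXT_ATTRIBUTE = "description"
CLUSTER_ATTRIBUTE = "planted_cluster"

_CLUSTER_SPACING = 300.0
_POSITION_SD = 40.0


def default_theme_vocabularies(n_clusters: int, words_per_theme: int = 20
                               ) -> list[list[str]]:
    """Disjoint synthetic theme vocabularies, one per cluster."""
    return [
        [f"theme{c}term{i:02d}" for i in range(words_per_theme)]
        for c in range(1, n_clusters + 1)
    ]


@dataclass
class ThemedFixture:
    """A generated network with its planted ground truth."""

    network: Network
    partition: Partition
    theme_words: dict[int, list[str]]


def make_themed_network(
    n_clusters: int = 4,
    nodes_per_cluster: int = 10,
    p_in: float = 0.9,
    p_out: float = 0.02,
    theme_vocab: Sequence[Sequence[str]] | None = None,
    background_vocab: Sequence[str] = BACKGROUND_FILLERS,
    words_per_node: int = 8,
    theme_fraction: float = 0.8,
    seed: int = 0,
) -> ThemedFixture:
    """Generate a planted-partition network with themed node text.

    Defaults emulate a small enrichment-map-like input: 4 well-separated
    modules of 10 nodes (dense inside, sparse between), each node described
    by an 8-word phrase drawn 80% from its module's 20-word theme vocabulary
    and 20% from a shared Zipf-weighted background of filler words.
    """
    if not 0.0 <= p_out <= p_in <= 1.0:
        raise ValueError("probabilities must satisfy 0 <= p_out <= p_in <= 1")
    if not 0.0 <= theme_fraction <= 1.0:
        raise ValueError("theme_fraction must lie in [0, 1]")
    if n_clusters < 1 or nodes_per_cluster < 1:
        raise ValueError("need at least one cluster of at least one node")
    rng = np.random.default_rng(seed)

    if theme_vocab is None:
        theme_vocab = default_theme_vocabularies(n_clusters)
    if len(theme_vocab) != n_clusters:
        raise ValueError("need one theme vocabulary per cluster")
    background = list(background_vocab)
    bg_weights = np.array([1.0 / (i + 1) for i in range(len(background))])
    bg_weights /= bg_weights.sum()

    net = Network()
    clusters: dict[int, set[str]] = {}
    theme_words: dict[int, list[str]] = {}
    node_cluster: dict[str, int] = {}

    centers = [
        (_CLUSTER_SPACING * np.cos(2 * np.pi * c / n_clusters),
         _CLUSTER_SPACING * np.sin(2 * np.pi * c / n_clusters))
        for c in range(n_clusters)
    ]
    for c in range(1, n_clusters + 1):
        vocab = list(theme_vocab[c - 1])
        theme_words[c] = vocab
        members = set()
        cx, cy = centers[c - 1]
        for j in range(nodes_per_cluster):
            node = f"c{c}n{j:02d}"
            n_theme = int(round(words_per_node * theme_fraction))
            words = []
            for w in range(words_per_node):
                if w < n_theme:
                    words.append(vocab[rng.integers(len(vocab))])
                else:
                    words.append(background[rng.choice(len(background), p=bg_weights)])
            rng.shuffle(words)
            position = (cx + rng.normal(0, _POSITION_SD),
                        cy + rng.normal(0, _POSITION_SD))
            net.add_node(node, attrs={
                TEXT_ATTRIBUTE: " ".join(words),
                CLUSTER_ATTRIBUTE: str(c),
            }, position=position)
            members.add(node)
            node_cluster[node] = c
        clusters[c] = members

    order = sorted(net.nodes)
    for i, u in enumerate(order):
        for v in order[i + 1:]:
            p = p_in if node_cluster[u] == node_cluster[v] else p_out
            if p > 0 and rng.random() < p:
                net.add_edge(u, v)

    partition = Partition(clusters={c: set(m) for c, m in clusters.items()})
    partition.validate(net)
    net.validate()
    return ThemedFixture(network=net, partition=partition, theme_words=theme_words)
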