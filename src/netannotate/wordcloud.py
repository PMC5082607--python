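"""Per-cluster word clouds: tokenization, frequency scoring, sizes, groups.

Each cluster is summarized by tokenizing one or more text attributes of its
member nodes and scoring every distinct word.  The score blends two
normalized quantities with a weight ``k`` (the *normalization factor*):

    score(w) = (1 - k) * rescale(f_c(w)) + k * rescale(f_c(w) / f_n(w))

where ``f_c`` is the word's frequency within the cluster and ``f_n`` its
frequency over the entire network (unclustered nodes included).  Both terms
are min–max rescaled to [0, 1] across the cloud before blending so that ``k``
interpolates comparable quantities.  At ``k = 0`` a word's significance is
just its in-cluster count; raising ``k`` up-weights the cluster-to-network
frequency ratio, which demotes words that are ubiquitous in the network
(e.g. "pathway", "regulation" in enrichment maps).

Scores map affinely onto a font-size range, and words that repeatedly occur
in adjacent token positions are linked into *adjacency groups* — connected
components of a word co-occurrence structure — which the labeling heuristics
use to favor multi-word phrases.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence

from .graph import Network

# Compact English stopword list; pathway descriptions and publication titles
# are English phrases, so common function words carry no labeling signal.
DEFAULT_STOPWORDS = frozenset("""
a about above after again against all am an and any are as at be because been
before being below between both but by can could did do does doing down during
each few for from further had has have having he her here hers herself him
himself his how i if in into is it its itself just me more most my myself no
nor not now of off on once only or other our ours ourselves out over own same
she should so some such than that the their theirs them themselves then there
these they this those through to too under until up very was we were what when
where which while who whom why will with you your yours yourself yourselves
via versus using used use et al
""".split())

# words made of letters/digits with internal hyphens or underscores kept intact
_TOKEN_RE = re.compile(r"[A-Za-z0-9]+(?:[-_][A-Za-z0-9]+)*")
_NUMBER_RE = re.compile(r"[0-9]+(?:[-_][0-9]+)*")

#: a word pair must be adjacent in at least this many member nodes' text to be
#: linked into one adjacency group (relaxed to 1 for clusters of < 3 members)
ADJACENCY_MIN_NODES = 2


@dataclass
class CloudOptions:
    """Options controlling tokenization, scoring and sizing of a cloud."""

    attributes: tuple[str, ...]
    normalization: float = 0.5
    stopwords: frozenset = DEFAULT_STOPWORDS
    extra_stopwords: tuple[str, ...] = ()
    min_font: float = 1.0
    max_font: float = 64.0

    def __post_init__(self) -> None:
        if isinstance(self.attributes, str):
            self.attributes = (self.attributes,)
        self.attributes = tuple(self.attributes)
        if not self.attributes:
            raise ValueError("at least one attribute name is required")
        if not 0.0 <= self.normalization <= 1.0:
            raise ValueError("normalization factor must lie in [0, 1]")
        if not self.min_font < self.max_font:
            raise ValueError("min font must be smaller than max font")

    @property
    def all_stopwords(self) -> frozenset:
        return self.stopwords | frozenset(w.lower() for w in self.extra_stopwords)


@dataclass(frozen=True)
class WordInfo:
    """One cloud word: display size, first-appearance order, adjacency group."""

    word: str
    size: float
    order: int
    group: int


def tokenize(text: str, opts: CloudOptions) -> list[str]:
    """Split on whitespace/punctuation (intra-word hyphens and underscores
    survive), lower-case, drop stopwords and pure numbers; order preserved."""
    if not text:
        return []
    stop = opts.all_stopwords
    out = []
    for match in _TOKEN_RE.finditer(str(text)):
        token = match.group().lower()
        if token in stop or _NUMBER_RE.fullmatch(token):
            continue
        out.append(token)
    return out


def _node_tokens(net: Network, node: str, opts: CloudOptions) -> list[str]:
    tokens: list[str] = []
    for attr in opts.attributes:
        value = net.get_attr(node, attr)
        if value is not None:
            tokens.extend(tokenize(str(value), opts))
    return tokens


def _check_attributes(net: Network, opts: CloudOptions) -> None:
    if not any(net.has_attr(a) for a in opts.attributes):
        raise ValueError(
            f"none of the attributes {list(opts.attributes)} exist on any node"
        )


def cluster_counts(net: Network, members: Iterable[str],
                   opts: CloudOptions) -> Counter:
    """Token counts pooled over the selected attributes of the member nodes."""
    members = set(members)
    if not members <= net.nodes:
        raise ValueError("cluster members must be network nodes")
    _check_attributes(net, opts)
    counts: Counter = Counter()
    for node in members:
        counts.update(_node_tokens(net, node, opts))
    return counts


def _rescale(values: dict[str, float]) -> dict[str, float]:
    """Min–max rescale onto [0, 1]; a degenerate range maps everything to 1."""
    lo, hi = min(values.values()), max(values.values())
    if hi == lo:
        return {w: 1.0 for w in values}
    return {w: (v - lo) / (hi - lo) for w, v in values.items()}


def score_words(c_counts: dict[str, int], n_counts: dict[str, int],
                k: float) -> dict[str, float]:
    """Blend in-cluster frequency with the cluster/network frequency ratio.

    ``c_counts`` are a cluster's word counts, ``n_counts`` the whole-network
    counts (must dominate the cluster counts).  Returns one score per cluster
    word; see the module docstring for the algebra.
    """
    if not 0.0 <= k <= 1.0:
        raise ValueError("normalization factor must lie in [0, 1]")
    if not c_counts:
        return {}
    cluster_total = sum(c_counts.values())
    network_total = sum(n_counts.values())
    if network_total <= 0:
        raise ValueError("network token total must be positive")
    f_c = {}
    ratio = {}
    for word, c in c_counts.items():
        n = n_counts.get(word, 0)
        if c > n:
            raise ValueError(f"cluster count exceeds network count for {word!r}")
        f_c[word] = c / cluster_total
        f_n = n / network_total
        ratio[word] = f_c[word] / f_n
    f_c_scaled = _rescale(f_c)
    ratio_scaled = _rescale(ratio)
    return {
        w: (1.0 - k) * f_c_scaled[w] + k * ratio_scaled[w]
        for w in c_counts
    }


def font_sizes(scores: dict[str, float], opts: CloudOptions) -> dict[str, float]:
    """Affine map of the score range onto [min_font, max_font].

    When all scores are equal every word gets the max font.
    """
    if not scores:
        raise ValueError("font_sizes requires at least one word")
    lo, hi = min(scores.values()), max(scores.values())
    if hi == lo:
        return {w: opts.max_font for w in scores}
    span = opts.max_font - opts.min_font
    return {
        w: opts.min_font + (s - lo) / (hi - lo) * span
        for w, s in scores.items()
    }


def adjacency_groups(token_sequences: Sequence[Sequence[str]],
                     min_nodes: int | None = None) -> dict[str, int]:
    """Assign each word an adjacency-group id.

    Two words are linked when they occupy adjacent token positions in at
    least ``min_nodes`` member nodes' text (default ``ADJACENCY_MIN_NODES``,
    relaxed to 1 when fewer than 3 sequences are given).  Groups are the
    connected components of the link structure; isolated words form singleton
    groups.  Ids are integers ordered by descending component size, ties by
    the alphabetically smallest member word.
    """
    if min_nodes is None:
        min_nodes = ADJACENCY_MIN_NODES if len(token_sequences) >= 3 else 1

    pair_nodes: Counter = Counter()
    words: set[str] = set()
    for seq in token_sequences:
        words.update(seq)
        pairs = {frozenset((a, b)) for a, b in zip(seq, seq[1:]) if a != b}
        pair_nodes.update(pairs)

    parent = {w: w for w in words}

    def find(w: str) -> str:
        while parent[w] != w:
            parent[w] = parent[parent[w]]
            w = parent[w]
        return w

    for pair, n_nodes in pair_nodes.items():
        if n_nodes >= min_nodes:
            a, b = tuple(pair)
            ra, rb = find(a), find(b)
            if ra != rb:
                parent[rb] = ra

    components: dict[str, set[str]] = {}
    for w in words:
        components.setdefault(find(w), set()).add(w)
    ranked = sorted(components.values(), key=lambda c: (-len(c), min(c)))
    return {w: gid for gid, comp in enumerate(ranked, start=1) for w in comp}


def network_counts(net: Network, opts: CloudOptions) -> Counter:
    """Whole-network token counts (every node, unclustered ones included)."""
    return cluster_counts(net, net.nodes, opts)


def build_cloud(net: Network, members: Iterable[str], opts: CloudOptions,
                n_counts: Counter | None = None) -> list[WordInfo]:
    """Compose counts, scores, sizes, first-appearance order and groups.

    Member nodes are scanned in sorted id order with attributes in the order
    selected, so the cloud is deterministic and independent of iteration
    order.  ``n_counts`` may carry precomputed whole-network counts to avoid
    recomputation over many clusters.  Returns one ``WordInfo`` per distinct
    word, listed in first-appearance order; empty text yields an empty cloud.
    """
    members = set(members)
    if not members:
        raise ValueError("build_cloud requires a nonempty member set")
    _check_attributes(net, opts)
    sequences = [_node_tokens(net, node, opts) for node in sorted(members)]

    c_counts: Counter = Counter()
    order: dict[str, int] = {}
    for seq in sequences:
        for token in seq:
            c_counts[token] += 1
            if token not in order:
                order[token] = len(order)
    if not c_counts:
        return []

    if n_counts is None:
        n_counts = network_counts(net, opts)
    scores = score_words(dict(c_counts), dict(n_counts), opts.normalization)
    sizes = font_sizes(scores, opts)
    groups = adjacency_groups(sequences)
    return [
        WordInfo(word=w, size=sizes[w], order=order[w], group=groups[w])
        for w in sorted(order, key=order.get)
    ]
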