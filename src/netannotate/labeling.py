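"""Turn a cluster's word cloud into a short label.

Two selection heuristics are provided.  *Biggest words* sorts the cloud by
font size, keeps the N largest words and emits them in original
first-appearance order.  *Adjacent words* (the default) balances size with
phrase structure: every word sharing an adjacency group with one of the N
largest words receives a size bonus (default 8), capped so a boosted word can
never exceed the largest original size in its own group, and the N largest
words under the boosted sizes are emitted, again in first-appearance order.
All ties break toward the earlier-appearing word, making both selectors
deterministic and input-order independent.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .wordcloud import WordInfo

DEFAULT_SIZE_BONUS = 8.0

ALGORITHMS = ("biggest_words", "adjacent_words")


@dataclass
class LabelOptions:
    """Label-making options: algorithm, word budget, adjacency size bonus."""

    algorithm: str = "adjacent_words"
    max_words: int = 3
    size_bonus: float = DEFAULT_SIZE_BONUS

    def __post_init__(self) -> None:
        if self.algorithm not in ALGORITHMS:
            raise ValueError(f"unknown label algorithm {self.algorithm!r}")
        if not 1 <= self.max_words <= 10:
            raise ValueError("max_words must lie in [1, 10]")
        if self.size_bonus < 0:
            raise ValueError("size_bonus must be non-negative")


def _top_n(cloud: Sequence[WordInfo], n: int,
           size_of=lambda w: w.size) -> list[WordInfo]:
    """The n largest words; size ties break toward the smaller order value."""
    ranked = sorted(cloud, key=lambda w: (-size_of(w), w.order))
    return ranked[:n]


def select_biggest_words(cloud: Sequence[WordInfo], n: int) -> list[str]:
    """Keep the n largest words, emitted in first-appearance order."""
    chosen = _top_n(cloud, n)
    return [w.word for w in sorted(chosen, key=lambda w: w.order)]


def select_adjacent_words(cloud: Sequence[WordInfo], n: int,
                          bonus: float = DEFAULT_SIZE_BONUS) -> list[str]:
    """Size-plus-adjacency heuristic.

    1. identify the n largest words;
    2. every word sharing an adjacency group with one of them gets
       ``size + bonus``, capped at the largest original size within the
       word's own group;
    3. re-rank by the boosted sizes and keep the n largest;
    4. emit in first-appearance order.
    """
    if not cloud:
        return []
    top_groups = {w.group for w in _top_n(cloud, n)}
    group_max: dict[int, float] = {}
    for w in cloud:
        group_max[w.group] = max(group_max.get(w.group, 0.0), w.size)

    def boosted(w: WordInfo) -> float:
        if w.group in top_groups:
            return min(w.size + bonus, group_max[w.group])
        return w.size

    chosen = _top_n(cloud, n, size_of=boosted)
    return [w.word for w in sorted(chosen, key=lambda w: w.order)]


def select_words(cloud: Sequence[WordInfo], opts: LabelOptions) -> list[str]:
    if opts.algorithm == "biggest_words":
        return select_biggest_words(cloud, opts.max_words)
    return select_adjacent_words(cloud, opts.max_words, opts.size_bonus)


def make_label(words: Sequence[str]) -> str:
    """Join selected words with single spaces; empty selection → empty label."""
    return " ".join(words)
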