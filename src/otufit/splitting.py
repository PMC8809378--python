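"""Reference/query dataset splitting for split-strategy fitting experiments.

Three strategies pick which sequences seed the reference set:

simple
    Uniform random sample without replacement.
abundance
    Sample without replacement with selection weight proportional to each
    sequence's abundance count.
similarity
    Sample without replacement with weight proportional to 1 + the
    sequence's degree in the similarity graph.  The +1 keeps sequences with
    no near neighbor selectable.

Weighted sampling uses sequential draws with renormalization (successive
sampling): draw one id with probability proportional to its weight, remove
it, repeat.  Different weighted-sampling schemes induce different inclusion
probabilities, so the scheme is part of the contract here.

The reference size is round-half-away-from-zero of fraction·n, and a split
always leaves both sides non-empty.
"""

from __future__ import annotations

import math
import random
from bisect import bisect_left
from dataclasses import dataclass
from itertools import accumulate
from typing import Mapping, TextIO

from .graph_io import FormatError, SequenceUniverse, SimilarityGraph

__all__ = [
    "SplitAssignment",
    "split_simple",
    "split_abundance_weighted",
    "split_similarity_weighted",
    "read_count_table",
]

STRATEGIES = ("simple", "abundance", "similarity")


@dataclass(frozen=True)
class SplitAssignment:
    """Disjoint reference/query subsets of a universe, with provenance."""

    reference_ids: frozenset[str]
    query_ids: frozenset[str]
    strategy: str
    reference_fraction: float
    seed: int

    def __post_init__(self) -> None:
        if self.strategy not in STRATEGIES:
            raise ValueError(f"unknown strategy {self.strategy!r}")
        if self.reference_ids & self.query_ids:
            raise ValueError("reference and query sets overlap")


def _reference_size(n: int, fraction: float) -> int:
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must be in (0, 1)")
    size = math.floor(fraction * n + 0.5)  # round half away from zero
    if size == 0 or size == n:
        raise ValueError(
            f"fraction {fraction} leaves an empty reference or query set for n={n}"
        )
    return size


def _weighted_sample(
    ids: list[str], weights: list[float], k: int, rng: random.Random
) -> set[str]:
    """Successive sampling: k sequential weighted draws without replacement."""
    pool = list(ids)
    w = list(weights)
    chosen: set[str] = set()
    for _ in range(k):
        cum = list(accumulate(w))
        r = rng.random() * cum[-1]
        i = bisect_left(cum, r)
        if i == len(pool):  # r landed exactly on the total weight
            i -= 1
        chosen.add(pool.pop(i))
        w.pop(i)
    return chosen


def _assemble(
    universe: SequenceUniverse,
    reference: set[str],
    strategy: str,
    fraction: float,
    seed: int,
) -> SplitAssignment:
    query = frozenset(set(universe.ids) - reference)
    return SplitAssignment(
        reference_ids=frozenset(reference),
        query_ids=query,
        strategy=strategy,
        reference_fraction=fraction,
        seed=seed,
    )


def split_simple(
    universe: SequenceUniverse, fraction: float, seed: int
) -> SplitAssignment:
    """Uniform random reference sample of round(fraction·n) sequences."""
    n = len(universe)
    if n < 2:
        raise ValueError("need at least 2 sequences to split")
    k = _reference_size(n, fraction)
    rng = random.Random(seed)
    reference = set(rng.sample(list(universe.ids), k))
    return _assemble(universe, reference, "simple", fraction, seed)


def split_abundance_weighted(
    universe: SequenceUniverse,
    counts: Mapping[str, int],
    fraction: float,
    seed: int,
) -> SplitAssignment:
    """Reference sample weighted by per-sequence abundance counts."""
    n = len(universe)
    if n < 2:
        raise ValueError("need at least 2 sequences to split")
    weights = []
    for sid in universe.ids:
        if sid not in counts:
            raise ValueError(f"missing abundance count for {sid!r}")
        c = counts[sid]
        if not isinstance(c, int) or c <= 0:
            raise ValueError(f"abundance count for {sid!r} must be a positive integer")
        weights.append(float(c))
    k = _reference_size(n, fraction)
    rng = random.Random(seed)
    reference = _weighted_sample(list(universe.ids), weights, k, rng)
    return _assemble(universe, reference, "abundance", fraction, seed)


def split_similarity_weighted(
    graph: SimilarityGraph, fraction: float, seed: int
) -> SplitAssignment:
    """Reference sample weighted by 1 + similarity-graph degree."""
    universe = graph.universe
    n = len(universe)
    if n < 2:
        raise ValueError("need at least 2 sequences to split")
    degree = [0] * n
    for a, b in graph.edges:
        degree[universe.index(a)] += 1
        degree[universe.index(b)] += 1
    weights = [1.0 + d for d in degree]
    k = _reference_size(n, fraction)
    rng = random.Random(seed)
    reference = _weighted_sample(list(universe.ids), weights, k, rng)
    return _assemble(universe, reference, "similarity", fraction, seed)


def read_count_table(stream: TextIO) -> dict[str, int]:
    """Read a two-column ``id<TAB>count`` table; one header line permitted."""
    counts: dict[str, int] = {}
    for lineno, raw in enumerate(stream, start=1):
        line = raw.strip()
        if not line:
            continue
        parts = line.split("\t") if "\t" in line else line.split()
        if len(parts) != 2:
            raise FormatError(f"line {lineno}: expected two columns, got {line!r}")
        sid, count_s = parts
        try:
            count = int(count_s)
        except ValueError:
            if lineno == 1:  # header
                continue
            raise FormatError(f"line {lineno}: unparseable count {count_s!r}")
        if sid in counts:
            raise FormatError(f"line {lineno}: duplicate id {sid!r}")
        counts[sid] = count
    if not counts:
        raise FormatError("empty count table")
    return counts
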