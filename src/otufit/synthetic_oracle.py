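"""Synthetic fixtures with planted OTU structure, and exhaustive brute-force
optima for small instances.

Two generators:

* :func:`generate_planted_graph` — a planted-partition similarity graph:
  ground-truth OTUs with intra-OTU edge probability ``p_within`` and
  inter-OTU probability ``p_between``.
* :func:`generate_sequence_family` — mutated sequence families: per-OTU
  centroid sequences with members a fixed number of substitutions away,
  emitted as FASTA plus a sparse column distance file.  The fixture distance
  is the Hamming mismatch fraction on equal-length ungapped sequences — a
  deliberate simplification for test data, not a general sequence distance.

Two oracles:

* :func:`brute_force_best_partition` — the global maximum-MCC partition by
  enumerating all set partitions (restricted growth strings; n ≤ 12).
* :func:`brute_force_best_fit` — the best frozen-reference query assignment
  by enumerating every query→(reference OTU | own singleton) combination.

All generators are seed-deterministic.
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from itertools import product
from typing import Iterable, Iterator

from .confusion import _mcc_ints
from .graph_io import (
    OtuPartition,
    SequenceUniverse,
    SimilarityGraph,
    total_pairs,
)

__all__ = [
    "PlantedGraphSpec",
    "SequenceFamilySpec",
    "generate_planted_graph",
    "generate_sequence_family",
    "brute_force_best_partition",
    "brute_force_best_fit",
]

_ALPHABET = "ACGT"
#: distance cutoff below which generated sequence-family pairs are emitted
#: (sparse output with headroom above the usual 0.03 clustering threshold)
_EMIT_CUTOFF = 0.10


@dataclass(frozen=True)
class PlantedGraphSpec:
    """Planted-partition graph parameters."""

    n_otus: int
    otu_size_range: tuple[int, int]
    p_within: float
    p_between: float
    seed: int

    def __post_init__(self) -> None:
        lo, hi = self.otu_size_range
        if self.n_otus < 1 or lo < 1 or hi < lo:
            raise ValueError("invalid planted-partition sizes")
        if not 0.0 <= self.p_between <= self.p_within <= 1.0:
            raise ValueError("need 0 <= p_between <= p_within <= 1")


@dataclass(frozen=True)
class SequenceFamilySpec:
    """Mutated sequence family parameters.

    ``within_mutations`` is the exact number of substitutions separating
    each member from its OTU centroid; it must keep intra-OTU pairwise
    distances at or below 0.03 (two members can differ at up to twice that
    many positions).
    """

    n_otus: int
    members_per_otu: int
    seq_length: int
    within_mutations: int
    seed: int

    def __post_init__(self) -> None:
        if self.n_otus < 1 or self.members_per_otu < 1 or self.seq_length < 1:
            raise ValueError("invalid family sizes")
        if self.within_mutations < 0:
            raise ValueError("within_mutations must be >= 0")
        if 2 * self.within_mutations / self.seq_length > 0.03:
            raise ValueError(
                "within_mutations too large: intra-OTU distances could exceed 0.03"
            )


def generate_planted_graph(
    spec: PlantedGraphSpec,
) -> tuple[SimilarityGraph, OtuPartition]:
    """Sample a planted-partition graph and return it with its ground truth."""
    rng = random.Random(spec.seed)
    lo, hi = spec.otu_size_range
    otus: dict[str, frozenset[str]] = {}
    ids: list[str] = []
    groups: list[list[str]] = []
    for i in range(spec.n_otus):
        size = rng.randint(lo, hi)
        members = [f"otu{i}_seq{j}" for j in range(size)]
        groups.append(members)
        ids.extend(members)
        otus[f"true_{i}"] = frozenset(members)
    group_of = {sid: g for g, members in enumerate(groups) for sid in members}
    edges: set[tuple[str, str]] = set()
    for a_i in range(len(ids)):
        for b_i in range(a_i + 1, len(ids)):
            a, b = ids[a_i], ids[b_i]
            p = spec.p_within if group_of[a] == group_of[b] else spec.p_between
            if p > 0 and rng.random() < p:
                edges.add((a, b) if a < b else (b, a))
    universe = SequenceUniverse.from_ids(ids)
    graph = SimilarityGraph(universe, 0.03, frozenset(edges))
    return graph, OtuPartition(otus, universe)


def _mutate(seq: str, n_sub: int, rng: random.Random) -> str:
    positions = rng.sample(range(len(seq)), n_sub)
    chars = list(seq)
    for p in positions:
        chars[p] = rng.choice([c for c in _ALPHABET if c != chars[p]])
    return "".join(chars)


def _hamming(a: str, b: str) -> int:
    return sum(1 for x, y in zip(a, b) if x != y)


def generate_sequence_family(spec: SequenceFamilySpec) -> tuple[str, str]:
    """Generate mutated sequence families as (FASTA text, column distances).

    Centroids are drawn at random but re-drawn until every centroid pair is
    far enough apart that inter-OTU member distances stay above 0.03 even
    after member mutations.  The distance file lists only pairs with Hamming
    fraction ≤ 0.10 (sparse column format).
    """
    rng = random.Random(spec.seed)
    length = spec.seq_length
    min_sep = int(0.03 * length) + 2 * spec.within_mutations + 1
    centroids: list[str] = []
    for _ in range(spec.n_otus):
        for _attempt in range(1000):
            cand = "".join(rng.choice(_ALPHABET) for _ in range(length))
            if all(_hamming(cand, c) >= min_sep for c in centroids):
                centroids.append(cand)
                break
        else:  # pragma: no cover - only reachable with pathological specs
            raise ValueError(
                "could not place mutually distant centroids; increase seq_length"
            )
    ids: list[str] = []
    seqs: dict[str, str] = {}
    for i, centroid in enumerate(centroids):
        for j in range(spec.members_per_otu):
            sid = f"otu{i}_seq{j}"
            ids.append(sid)
            seqs[sid] = _mutate(centroid, spec.within_mutations, rng)
    fasta = "".join(f">{sid}\n{seqs[sid]}\n" for sid in ids)
    lines: list[str] = []
    for a_i in range(len(ids)):
        for b_i in range(a_i + 1, len(ids)):
            a, b = ids[a_i], ids[b_i]
            dist = _hamming(seqs[a], seqs[b]) / length
            if dist <= _EMIT_CUTOFF:
                lines.append(f"{a}\t{b}\t{dist:.6f}")
    return fasta, "\n".join(lines) + ("\n" if lines else "")


# ---------------------------------------------------------------------------
# brute-force oracles
# ---------------------------------------------------------------------------


def _restricted_growth_strings(n: int) -> Iterator[tuple[int, ...]]:
    """All set partitions of range(n) as restricted growth strings."""
    a = [0] * n

    def rec(i: int, mx: int) -> Iterator[tuple[int, ...]]:
        if i == n:
            yield tuple(a)
            return
        for v in range(mx + 2):
            a[i] = v
            yield from rec(i + 1, max(mx, v))

    if n == 0:
        yield ()
    else:
        yield from rec(0, -1)


def brute_force_best_partition(
    graph: SimilarityGraph,
) -> tuple[OtuPartition, float]:
    """Global maximum-MCC partition by exhaustive enumeration (n ≤ 12).

    Ties are resolved to the first optimum in enumeration order; the MCC
    value itself is unique.
    """
    n = len(graph.universe)
    if n > 12:
        raise ValueError(f"brute force capped at 12 sequences, got {n}")
    index = graph.universe.index
    edge_idx = [(index(a), index(b)) for a, b in graph.edges]
    all_pairs = total_pairs(n)
    n_edges = len(edge_idx)
    pair_idx = [(i, j) for i in range(n) for j in range(i + 1, n)]

    best_mcc = -2.0
    best_labels: tuple[int, ...] | None = None
    for labels in _restricted_growth_strings(n):
        tp = sum(1 for i, j in edge_idx if labels[i] == labels[j])
        intra = sum(1 for i, j in pair_idx if labels[i] == labels[j])
        fp = intra - tp
        fn = n_edges - tp
        tn = all_pairs - tp - fp - fn
        score = _mcc_ints(tp, fp, fn, tn)
        if score > best_mcc:
            best_mcc = score
            best_labels = labels
    assert best_labels is not None or n == 0
    groups: dict[int, set[str]] = {}
    if best_labels:
        for i, g in enumerate(best_labels):
            groups.setdefault(g, set()).add(graph.universe.ids[i])
    otus = {f"otu_{g}": frozenset(m) for g, m in sorted(groups.items())}
    if n == 0:
        best_mcc = 0.0
    return OtuPartition(otus, graph.universe), best_mcc


def brute_force_best_fit(
    graph: SimilarityGraph,
    reference_partition: OtuPartition,
    query_ids: Iterable[str],
) -> tuple[dict[str, str | None], float]:
    """Best frozen-reference fit by exhaustive enumeration.

    Each query is assigned to one reference OTU or left as its own
    singleton (``None``); references never move; the score is the MCC over
    all pairs of the combined universe.  Capped at 6 queries and 8 reference
    OTUs.  Ties resolve to the first optimum in enumeration order.
    """
    queries = sorted(set(query_ids))
    ref_labels = sorted(reference_partition.otus.keys())
    if len(queries) > 6:
        raise ValueError("brute-force fit capped at 6 queries")
    if len(ref_labels) > 8:
        raise ValueError("brute-force fit capped at 8 reference OTUs")
    refs = set(reference_partition.universe.ids)
    if refs | set(queries) != set(graph.universe.ids) or refs & set(queries):
        raise ValueError("graph universe must be the disjoint union of refs and queries")

    adjacency = {
        sid: graph.neighbors(sid) for sid in queries
    }
    # reference-reference contribution is fixed
    labels = reference_partition.labels_by_sequence()
    tp_rr = sum(
        1 for a, b in graph.edges if a in refs and b in refs and labels[a] == labels[b]
    )
    intra_rr = sum(
        total_pairs(len(m)) for m in reference_partition.otus.values()
    )
    fp_rr = intra_rr - tp_rr

    # per query, per reference OTU: neighbor count and OTU size
    k_in: dict[str, dict[str, int]] = {}
    sizes = {label: len(m) for label, m in reference_partition.otus.items()}
    for q in queries:
        k_in[q] = {
            label: len(adjacency[q] & members)
            for label, members in reference_partition.otus.items()
        }
    qq_edge = [
        (i, j, graph.has_edge(queries[i], queries[j]))
        for i in range(len(queries))
        for j in range(i + 1, len(queries))
    ]

    n_edges = len(graph.edges)
    all_pairs = total_pairs(len(graph.universe))
    options: list[str | None] = [None, *ref_labels]

    best_mcc = -2.0
    best_assignment: tuple[str | None, ...] = ()
    for assignment in product(options, repeat=len(queries)):
        tp = tp_rr
        fp = fp_rr
        for q, target in zip(queries, assignment):
            if target is not None:
                k = k_in[q][target]
                tp += k
                fp += sizes[target] - k
        for i, j, is_edge in qq_edge:
            ta = assignment[i]
            tb = assignment[j]
            if ta is not None and ta == tb:
                if is_edge:
                    tp += 1
                else:
                    fp += 1
        fn = n_edges - tp
        tn = all_pairs - tp - fp - fn
        score = _mcc_ints(tp, fp, fn, tn)
        if score > best_mcc:
            best_mcc = score
            best_assignment = assignment
    return dict(zip(queries, best_assignment)), best_mcc
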