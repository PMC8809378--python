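import random

import pytest
from hypothesis import HealthCheck, settings

from otufit import (
    ConfusionCounts,
    OtuPartition,
    SequenceUniverse,
    SimilarityGraph,
)

settings.register_profile(
    "suite",
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("suite")


def random_graph(n: int, p: float, rng: random.Random) -> SimilarityGraph:
    """Erdős–Rényi similarity graph on ids s0..s{n-1}."""
    ids = [f"s{i}" for i in range(n)]
    universe = SequenceUniverse.from_ids(ids)
    edges = [
        (ids[i], ids[j])
        for i in range(n)
        for j in range(i + 1, n)
        if rng.random() < p
    ]
    return SimilarityGraph.from_pairs(universe, 0.03, edges)


def random_partition(universe: SequenceUniverse, rng: random.Random) -> OtuPartition:
    """Random labeled partition via random group assignment."""
    n = len(universe)
    k = rng.randint(1, n)
    groups: dict[int, set[str]] = {}
    for sid in universe:
        groups.setdefault(rng.randrange(k), set()).add(sid)
    otus = {f"g{g}": frozenset(m) for g, m in groups.items()}
    return OtuPartition(otus, universe)


def brute_confusion(graph: SimilarityGraph, partition: OtuPartition) -> ConfusionCounts:
    """Independent oracle: classify every pair by direct enumeration."""
    labels = partition.labels_by_sequence()
    ids = list(graph.universe.ids)
    tp = fp = fn = tn = 0
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            a, b = ids[i], ids[j]
            edge = graph.has_edge(a, b)
            together = labels[a] == labels[b]
            if edge and together:
                tp += 1
            elif edge:
                fn += 1
            elif together:
                fp += 1
            else:
                tn += 1
    return ConfusionCounts(tp=tp, fp=fp, fn=fn, tn=tn)


@pytest.fixture
def two_triangles() -> SimilarityGraph:
    universe = SequenceUniverse.from_ids(list("abcdef"))
    edges = [("a", "b"), ("a", "c"), ("b", "c"), ("d", "e"), ("d", "f"), ("e", "f")]
    return SimilarityGraph.from_pairs(universe, 0.03, edges)


@pytest.fixture
def fit_example():
    """References OTU1={A,B} (edge A-B) and singleton C; query W near A and B."""
    universe = SequenceUniverse.from_ids(["A", "B", "C", "W"])
    graph = SimilarityGraph.from_pairs(
        universe, 0.03, [("A", "B"), ("W", "A"), ("W", "B")]
    )
    reference = OtuPartition.from_sets(
        {"OTU1": {"A", "B"}, "OTU2": {"C"}},
        SequenceUniverse.from_ids(["A", "B", "C"]),
    )
    return graph, reference
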