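"""Reference-based OTU clustering by MCC maximization (the OptiFit
algorithm).

Given an existing partition of *reference* sequences into OTUs and a set of
*query* sequences, the optimizer fits the queries to the reference OTUs
without ever moving a reference sequence.  Every query starts as a
singleton; sweeps then visit the queries in shuffled order and move each one
among the reference OTUs that contain at least one of its neighbors — or
leave it a singleton — choosing the option that maximizes the MCC computed
over *all* pairs in the combined universe (reference–reference,
reference–query and query–query pairs all count).  A query whose best option
is its own singleton stays unassigned.

Two finishing modes:

closed
    Unassigned queries are discarded; the result contains only OTUs that
    exist in the reference, and the reported confusion/MCC are recomputed
    over the retained universe (references plus mapped queries).
open
    Unassigned queries are clustered de novo among themselves (same
    algorithm as the de novo optimizer, same RNG stream) and the resulting
    OTUs are appended under fresh labels; confusion/MCC cover the full
    combined universe.

During the fit phase queries may only join reference OTUs: two unassigned
queries can never merge with each other before the open-mode de novo step.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from typing import Iterable

from ._engine import ClusterState, fresh_universe_check
from .confusion import ConfusionCounts, confusion_matrix, mcc
from .graph_io import OtuPartition, SequenceUniverse, SimilarityGraph

__all__ = ["FitConfig", "FitResult", "optifit", "close_partition", "open_extend"]

MODES = ("open", "closed")


@dataclass(frozen=True)
class FitConfig:
    """Run parameters for reference fitting.

    mode is ``"open"`` or ``"closed"``; seed, tolerance and max_iterations
    behave exactly as in the de novo optimizer.
    """

    mode: str = "open"
    seed: int = 0
    tolerance: float = 0.0001
    max_iterations: int = 100

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}, got {self.mode!r}")
        if self.tolerance < 0:
            raise ValueError("tolerance must be >= 0")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")


@dataclass(frozen=True)
class FitResult:
    """Outcome of a reference fit.

    ``partition`` covers the retained universe: references plus mapped
    queries in closed mode, the full combined universe in open mode.
    ``fraction_mapped`` is |mapped queries| / |queries| (1.0 by construction
    in open mode; 1.0 with ``no_queries=True`` when there were no queries).
    ``iterations`` counts sweeps over the whole run (fit phase plus, in open
    mode, the de novo phase).
    """

    partition: OtuPartition
    mcc: float
    confusion: ConfusionCounts
    fraction_mapped: float
    iterations: int
    converged: bool
    mode: str
    seed: int
    unmapped_ids: frozenset[str] = frozenset()
    no_queries: bool = False
    #: per-accepted-move MCC during the fit phase (full combined universe)
    mcc_trace: tuple[float, ...] = field(repr=False, default=())
    #: per-accepted-move MCC during the open-mode de novo phase, measured on
    #: the subgraph of unassigned queries (its own scale, monotone in itself)
    de_novo_mcc_trace: tuple[float, ...] = field(repr=False, default=())

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        c = self.confusion
        return (
            f"FitResult[{self.mode}]: {self.partition.n_otus} OTUs over "
            f"{len(self.partition.universe)} sequences, mcc={self.mcc:.4f} "
            f"(tp={c.tp} fp={c.fp} fn={c.fn} tn={c.tn}), "
            f"fraction_mapped={self.fraction_mapped:.4g}, "
            f"{self.iterations} iterations"
        )


def close_partition(
    partition: OtuPartition,
    reference_labels: Iterable[str],
    query_ids: Iterable[str],
) -> tuple[OtuPartition, frozenset[str]]:
    """Discard queries that did not land in a reference-labeled OTU.

    Returns the closed partition (universe = references ∪ mapped queries)
    and the set of discarded query ids.  Reference sequences are never
    removed; surviving OTU labels are a subset of the reference labels.
    """
    ref_labels = set(reference_labels)
    queries = set(query_ids)
    refs = set(partition.universe.ids) - queries
    kept: dict[str, frozenset[str]] = {}
    unmapped: set[str] = set()
    for label, members in partition.otus.items():
        if label in ref_labels:
            kept[label] = members
        else:
            stray_refs = members & refs
            if stray_refs:
                raise ValueError(
                    f"reference sequences in non-reference OTU {label!r}: "
                    f"{sorted(stray_refs)[:5]}"
                )
            unmapped |= members
    retained = set().union(*kept.values()) if kept else set()
    universe = SequenceUniverse.from_ids(
        sid for sid in partition.universe if sid in retained
    )
    return OtuPartition(kept, universe), frozenset(unmapped)


def open_extend(
    graph: SimilarityGraph,
    partition_after_fit: OtuPartition,
    unassigned_query_ids: Iterable[str],
    config: "FitConfig",
) -> OtuPartition:
    """Cluster the unassigned queries de novo and append the new OTUs.

    The de novo run happens on the subgraph induced by the unassigned
    queries only; every other assignment is untouched.  New OTUs get fresh
    labels that do not collide with existing ones.
    """
    unassigned = set(unassigned_query_ids)
    if not unassigned:
        return partition_after_fit
    for sid in unassigned:
        if len(partition_after_fit.otus[partition_after_fit.label_of(sid)]) != 1:
            raise ValueError(f"unassigned query {sid!r} is not a singleton")
    rng = random.Random(config.seed)
    sub = ClusterState(graph.subgraph(unassigned))
    sub.optimize(
        movable=range(len(unassigned)),
        rng=rng,
        tolerance=config.tolerance,
        max_iterations=config.max_iterations,
    )
    return _merge_de_novo(partition_after_fit, sub, unassigned)


def _merge_de_novo(
    partition: OtuPartition, sub: ClusterState, unassigned: set[str]
) -> OtuPartition:
    """Replace the unassigned singletons by the de novo OTUs, fresh labels."""
    otus = {
        label: members
        for label, members in partition.otus.items()
        if not (members & unassigned)
    }
    counter = 0
    for members_idx in sub.members.values():
        members = frozenset(sub.ids[i] for i in members_idx)
        while True:
            label = f"otu_{counter}"
            counter += 1
            if label not in otus and label not in partition.otus:
                break
        otus[label] = members
    # OtuPartition validation re-checks that every unassigned id reappears
    return OtuPartition(otus, partition.universe)


def optifit(
    graph: SimilarityGraph,
    reference_partition: OtuPartition,
    query_ids: Iterable[str],
    config: FitConfig,
) -> FitResult:
    """Fit query sequences to reference OTUs by iterative MCC maximization.

    ``graph`` must cover the combined universe (reference ∪ query ids,
    disjoint); ``reference_partition`` partitions the reference sequences.
    Reference assignments are frozen throughout.
    """
    queries = fresh_universe_check(
        reference_partition.universe, query_ids, graph
    )
    rng = random.Random(config.seed)
    state = ClusterState(graph)
    label_to_otu = state.seed_partition(reference_partition.otus)
    ref_otu_ids = set(label_to_otu.values())
    state.mcc_trace.clear()  # seeding moves are setup, not optimizer steps

    index = graph.universe.index
    query_idx = [index(q) for q in queries]
    iterations, converged = state.optimize(
        movable=query_idx,
        rng=rng,
        tolerance=config.tolerance,
        max_iterations=config.max_iterations,
        allowed=ref_otu_ids,
    )

    fit_partition = state.to_partition()
    mapped = {q for q in queries if state.otu_of[index(q)] in ref_otu_ids}
    unassigned = queries - mapped
    n_queries = len(queries)
    no_queries = n_queries == 0

    if config.mode == "closed":
        partition, unmapped = close_partition(
            fit_partition, reference_partition.otus.keys(), queries
        )
        counts = confusion_matrix(graph.subgraph(partition.universe.ids), partition)
        fraction = 1.0 if no_queries else len(mapped) / n_queries
        return FitResult(
            partition=partition,
            mcc=mcc(counts),
            confusion=counts,
            fraction_mapped=fraction,
            iterations=iterations,
            converged=converged,
            mode="closed",
            seed=config.seed,
            unmapped_ids=unmapped,
            no_queries=no_queries,
            mcc_trace=tuple(state.mcc_trace),
        )

    # open mode: de novo phase on the unassigned queries, same RNG stream
    sub_trace: tuple[float, ...] = ()
    if unassigned:
        sub = ClusterState(graph.subgraph(unassigned))
        sub_iter, sub_conv = sub.optimize(
            movable=range(len(unassigned)),
            rng=rng,
            tolerance=config.tolerance,
            max_iterations=config.max_iterations,
        )
        partition = _merge_de_novo(fit_partition, sub, unassigned)
        iterations += sub_iter
        converged = converged and sub_conv
        sub_trace = tuple(sub.mcc_trace)
    else:
        partition = fit_partition
    counts = confusion_matrix(graph, partition)
    return FitResult(
        partition=partition,
        mcc=mcc(counts),
        confusion=counts,
        fraction_mapped=1.0,
        iterations=iterations,
        converged=converged,
        mode="open",
        seed=config.seed,
        unmapped_ids=frozenset(),
        no_queries=no_queries,
        mcc_trace=tuple(state.mcc_trace),
        de_novo_mcc_trace=sub_trace,
    )
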