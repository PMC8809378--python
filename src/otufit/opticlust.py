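"""De novo OTU clustering by iterative MCC maximization (the OptiClust
algorithm).

Every sequence starts as its own singleton OTU.  The optimizer then sweeps
over the sequences in a freshly shuffled order, and for each one asks: of
the OTUs holding at least one sequence within the distance threshold of this
one (plus "stay put" and "split off as a new singleton"), which placement
gives the whole partition the best Matthews correlation coefficient?  Ties
are broken uniformly at random with the run's seeded generator.  Sweeps
repeat until the MCC changes by no more than ``tolerance`` between sweeps
(default 0.0001) or ``max_iterations`` sweeps have run (default 100).

Because "stay" is always among the scored options, the MCC never decreases
across accepted moves (up to the documented 1e-12 tie tolerance), and a
fixed seed with fixed input reproduces the output partition exactly.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

from ._engine import ClusterState
from .confusion import NEW_SINGLETON, ConfusionCounts, mcc
from .graph_io import OtuPartition, SimilarityGraph

__all__ = ["ClusterConfig", "ClusteringResult", "candidate_otus", "opticlust"]


@dataclass(frozen=True)
class ClusterConfig:
    """Run parameters for the de novo optimizer.

    seed
        Seed for the run's random generator (visit order and tie-breaks).
    tolerance
        Minimum sweep-over-sweep MCC change to keep iterating (default
        0.0001).
    max_iterations
        Cap on the number of full sweeps (default 100).
    """

    seed: int = 0
    tolerance: float = 0.0001
    max_iterations: int = 100

    def __post_init__(self) -> None:
        if self.tolerance < 0:
            raise ValueError("tolerance must be >= 0")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")


@dataclass(frozen=True)
class ClusteringResult:
    """Outcome of a de novo run: the partition plus its quality diagnostics."""

    partition: OtuPartition
    mcc: float
    confusion: ConfusionCounts
    iterations: int
    converged: bool
    seed: int
    mcc_trace: tuple[float, ...] = field(repr=False, default=())

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        c = self.confusion
        return (
            f"ClusteringResult: {self.partition.n_otus} OTUs over "
            f"{len(self.partition.universe)} sequences, mcc={self.mcc:.4f} "
            f"(tp={c.tp} fp={c.fp} fn={c.fn} tn={c.tn}), "
            f"{self.iterations} iterations, converged={self.converged}"
        )


def candidate_otus(
    graph: SimilarityGraph, partition: OtuPartition, seq_id: str
) -> set[str]:
    """Move options for one sequence: OTUs holding ≥1 of its neighbors,
    its current OTU ("stay"), and the reserved fresh-singleton option."""
    if seq_id not in graph.universe:
        raise ValueError(f"unknown sequence id {seq_id!r}")
    labels = partition.labels_by_sequence()
    out = {labels[n] for n in graph.neighbors(seq_id)}
    out.add(labels[seq_id])
    out.add(NEW_SINGLETON)
    return out


def opticlust(graph: SimilarityGraph, config: ClusterConfig) -> ClusteringResult:
    """Cluster a similarity graph de novo by iterative MCC maximization."""
    rng = random.Random(config.seed)
    state = ClusterState(graph)
    iterations, converged = state.optimize(
        movable=range(len(graph.universe)),
        rng=rng,
        tolerance=config.tolerance,
        max_iterations=config.max_iterations,
    )
    counts = state.counts()
    return ClusteringResult(
        partition=state.to_partition(),
        mcc=mcc(counts),
        confusion=counts,
        iterations=iterations,
        converged=converged,
        seed=config.seed,
        mcc_trace=tuple(state.mcc_trace),
    )
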