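"""Shared mutable state for the MCC-maximizing local-search optimizers.

Both the de novo optimizer and the reference-fitting optimizer perform the
same elementary step: take one sequence, enumerate the OTUs that contain at
least one of its neighbors (plus "stay" and "become a fresh singleton"),
score each option by the MCC the whole partition would have after the move,
and apply the best one, breaking ties uniformly at random.  This module owns
that step and the exact O(|source| + |target|) confusion-count updates it
relies on; the public modules differ only in which sequences may move and
which OTUs they may join.
"""

from __future__ import annotations

import random
from typing import Iterable, Sequence

from .confusion import MCC_EQ_TOL, ConfusionCounts, _mcc_ints
from .graph_io import (
    OtuPartition,
    SequenceUniverse,
    SimilarityGraph,
    total_pairs,
)

#: Internal sentinel for the "fresh singleton" move option.
_NEW = -1


class ClusterState:
    """Mutable partition of a similarity graph with incremental confusion counts.

    Sequences and OTUs are integers internally; OTU ids come from a counter
    and are never reused, so fresh singletons always get fresh labels.
    """

    def __init__(self, graph: SimilarityGraph) -> None:
        self.graph = graph
        self.ids: Sequence[str] = graph.universe.ids
        self.adj = graph.adjacency()
        n = len(self.ids)
        # all-singletons start
        self.otu_of = list(range(n))
        self.members: dict[int, set[int]] = {i: {i} for i in range(n)}
        self.labels: dict[int, str] = {}  # explicit labels (reference OTUs)
        self._counter = n
        n_edges = len(graph.edges)
        self.tp = 0
        self.fp = 0
        self.fn = n_edges
        self.tn = total_pairs(n) - n_edges
        self.mcc_trace: list[float] = []

    # -- construction -----------------------------------------------------

    def seed_partition(self, otus: dict[str, Iterable[str]]) -> dict[str, int]:
        """Group sequences per a labeled partition (e.g. reference OTUs).

        Returns label → internal OTU id.  Counts are updated incrementally
        through ordinary moves, so they stay exact.
        """
        index = self.graph.universe.index
        label_to_otu: dict[str, int] = {}
        for label, members in otus.items():
            ids = [index(s) for s in members]
            home = self.otu_of[ids[0]]
            for i in ids[1:]:
                self._apply(i, home)
            self.labels[home] = label
            label_to_otu[label] = home
        return label_to_otu

    # -- queries ----------------------------------------------------------

    def current_mcc(self) -> float:
        return _mcc_ints(self.tp, self.fp, self.fn, self.tn)

    def counts(self) -> ConfusionCounts:
        return ConfusionCounts(tp=self.tp, fp=self.fp, fn=self.fn, tn=self.tn)

    def to_partition(self, prefix: str = "otu_") -> OtuPartition:
        """Snapshot as an :class:`OtuPartition` over the graph universe.

        Reference-labeled OTUs keep their labels; anonymous OTUs are named
        ``<prefix><id>`` from their never-reused internal id, deterministically
        suffixed if that collides with an explicit label.
        """
        taken = set(self.labels.values())
        out: dict[str, frozenset[str]] = {}
        for otu, members in self.members.items():
            if otu in self.labels:
                label = self.labels[otu]
            else:
                label = f"{prefix}{otu}"
                while label in taken:
                    label += "q"
            out[label] = frozenset(self.ids[i] for i in members)
        return OtuPartition(out, self.graph.universe)

    # -- the elementary step ----------------------------------------------

    def best_move(
        self,
        i: int,
        rng: random.Random,
        allowed: set[int] | None = None,
    ) -> None:
        """Score all move options for sequence ``i`` and apply the best.

        ``allowed`` restricts which *other* OTUs may be joined (the
        reference-fitting rule); "stay" and "fresh singleton" are always
        options.  Ties within ``MCC_EQ_TOL`` are broken uniformly at random.
        """
        cur = self.otu_of[i]
        neigh = self.adj[i]
        src = self.members[cur]
        k_out = len(neigh & src)  # i is not its own neighbor
        m_out = len(src) - 1 - k_out
        tp0 = self.tp - k_out
        fn0 = self.fn + k_out
        fp0 = self.fp - m_out
        tn0 = self.tn + m_out

        mcc_stay = _mcc_ints(self.tp, self.fp, self.fn, self.tn)
        options: list[tuple[float, int]] = [(mcc_stay, cur)]
        if len(src) > 1:  # otherwise "singleton" is the same option as "stay"
            options.append((_mcc_ints(tp0, fp0, fn0, tn0), _NEW))
        targets = {self.otu_of[j] for j in neigh}
        targets.discard(cur)
        if allowed is not None:
            targets &= allowed
        for b in targets:
            dst = self.members[b]
            k_in = len(neigh & dst)
            m_in = len(dst) - k_in
            options.append(
                (_mcc_ints(tp0 + k_in, fp0 + m_in, fn0 - k_in, tn0 - m_in), b)
            )

        best = max(score for score, _ in options)
        ties = [tgt for score, tgt in options if score >= best - MCC_EQ_TOL]
        choice = ties[0] if len(ties) == 1 else rng.choice(ties)
        if choice != cur:
            before = mcc_stay
            self._apply(i, choice)
            after = self.current_mcc()
            # accepted moves never lower the MCC beyond the tie tolerance
            assert after >= before - MCC_EQ_TOL
            self.mcc_trace.append(after)

    def _apply(self, i: int, target: int) -> None:
        """Move sequence ``i`` into OTU ``target`` (or a fresh singleton)."""
        cur = self.otu_of[i]
        if target == cur:
            return
        neigh = self.adj[i]
        src = self.members[cur]
        src.discard(i)
        k = len(neigh & src)
        m = len(src) - k
        self.tp -= k
        self.fn += k
        self.fp -= m
        self.tn += m
        if not src:
            del self.members[cur]
            self.labels.pop(cur, None)
        if target == _NEW:
            target = self._counter
            self._counter += 1
            self.members[target] = set()
        dst = self.members[target]
        k = len(neigh & dst)
        m = len(dst) - k
        self.tp += k
        self.fn -= k
        self.fp += m
        self.tn -= m
        dst.add(i)
        self.otu_of[i] = target

    # -- sweeps -----------------------------------------------------------

    def sweep(
        self,
        movable: Sequence[int],
        rng: random.Random,
        allowed: set[int] | None = None,
    ) -> float:
        """One full pass: visit every movable sequence in fresh shuffled order."""
        order = list(movable)
        rng.shuffle(order)
        for i in order:
            self.best_move(i, rng, allowed=allowed)
        return self.current_mcc()

    def optimize(
        self,
        movable: Sequence[int],
        rng: random.Random,
        tolerance: float,
        max_iterations: int,
        allowed: set[int] | None = None,
    ) -> tuple[int, bool]:
        """Sweep until the MCC stabilizes.

        Stops when the sweep-over-sweep MCC change is ≤ ``tolerance`` or
        after ``max_iterations`` sweeps.  Returns (sweeps run, converged).
        """
        prev = self.current_mcc()
        for iteration in range(1, max_iterations + 1):
            cur = self.sweep(movable, rng, allowed=allowed)
            if abs(cur - prev) <= tolerance:
                return iteration, True
            prev = cur
        return max_iterations, False


def induced_state(graph: SimilarityGraph, keep: Iterable[str]) -> ClusterState:
    """All-singleton state over the subgraph induced by ``keep``."""
    return ClusterState(graph.subgraph(keep))


def fresh_universe_check(
    reference: SequenceUniverse, query_ids: Iterable[str], graph: SimilarityGraph
) -> set[str]:
    """Validate the reference/query split against the graph universe."""
    queries = set(query_ids)
    refs = set(reference.ids)
    overlap = refs & queries
    if overlap:
        raise ValueError(f"ids are both reference and query: {sorted(overlap)[:5]}")
    missing = queries - set(graph.universe.ids)
    if missing:
        raise ValueError(f"query ids missing from graph: {sorted(missing)[:5]}")
    if refs | queries != set(graph.universe.ids):
        raise ValueError("graph universe must equal reference ∪ query ids")
    return queries
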