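"""Confusion matrices and the Matthews correlation coefficient (MCC) for an
OTU partition judged against a similarity graph.

Every unordered sequence pair is classified by crossing two binary facts:
is the pair within the distance threshold (a graph edge), and is it placed
in the same OTU?

* true positive — edge, same OTU
* false negative — edge, different OTUs
* false positive — non-edge, same OTU
* true negative — non-edge, different OTUs

MCC = (tp·tn − fp·fn) / sqrt((tp+fp)(tp+fn)(tn+fp)(tn+fn)), in [−1, 1].
When any marginal sum is zero the score is defined as 0 here ("no better
than random guessing"); see docs/methods.md for why.

Counts are exact Python integers (they can reach ~n²/2, and products of
four marginals overflow fixed 64-bit widths long before floats lose the
comparison); MCC goes to floating point only at evaluation time.  The
optimizers compare candidate MCC values with an absolute equality tolerance
of :data:`MCC_EQ_TOL` when deciding ties.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import TextIO

from .graph_io import OtuPartition, SimilarityGraph, total_pairs

__all__ = [
    "ConfusionCounts",
    "MCC_EQ_TOL",
    "NEW_SINGLETON",
    "mcc",
    "confusion_matrix",
    "move_delta",
    "write_stats",
]

#: Absolute tolerance under which two MCC values are "equal" for tie-breaking.
#: Distinct from the 1e-4 sweep-convergence tolerance.
MCC_EQ_TOL = 1e-12

#: Reserved move target meaning "split off into a fresh singleton OTU".
NEW_SINGLETON = "@new-singleton"


@dataclass(frozen=True)
class ConfusionCounts:
    """Pair counts tp/fp/fn/tn over all unordered sequence pairs."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "fn", "tn"):
            v = getattr(self, name)
            if not isinstance(v, int) or v < 0:
                raise ValueError(f"{name} must be a non-negative integer, got {v!r}")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def positives(self) -> int:
        """Within-threshold pairs (graph edges): tp + fn."""
        return self.tp + self.fn

    @property
    def negatives(self) -> int:
        """Above-threshold pairs: fp + tn."""
        return self.fp + self.tn

    @property
    def sensitivity(self) -> float:
        return self.tp / self.positives if self.positives else 0.0

    @property
    def specificity(self) -> float:
        return self.tn / (self.tn + self.fp) if (self.tn + self.fp) else 0.0


def mcc(counts: ConfusionCounts) -> float:
    """Matthews correlation coefficient of a confusion matrix.

    Returns 0.0 whenever any of the four marginal sums (tp+fp, tp+fn, tn+fp,
    tn+fn) is zero.
    """
    tp, fp, fn, tn = counts.tp, counts.fp, counts.fn, counts.tn
    denom2 = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)  # exact int
    if denom2 == 0:
        return 0.0
    return (tp * tn - fp * fn) / math.sqrt(denom2)


def _mcc_ints(tp: int, fp: int, fn: int, tn: int) -> float:
    # Allocation-free MCC for optimizer inner loops.
    denom2 = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom2 == 0:
        return 0.0
    return (tp * tn - fp * fn) / math.sqrt(denom2)


def confusion_matrix(graph: SimilarityGraph, partition: OtuPartition) -> ConfusionCounts:
    """Classify every unordered pair of the universe for a partition.

    tp = edges inside an OTU, fn = edges across OTUs, fp = non-edge pairs
    inside an OTU, tn = the rest.
    """
    if set(partition.universe.ids) != set(graph.universe.ids):
        raise ValueError("partition universe does not match graph universe")
    n = len(graph.universe)
    labels = partition.labels_by_sequence()
    tp = sum(1 for a, b in graph.edges if labels[a] == labels[b])
    fn = len(graph.edges) - tp
    intra_pairs = sum(total_pairs(len(m)) for m in partition.otus.values())
    fp = intra_pairs - tp
    tn = total_pairs(n) - tp - fp - fn
    return ConfusionCounts(tp=tp, fp=fp, fn=fn, tn=tn)


def move_delta(
    graph: SimilarityGraph,
    partition: OtuPartition,
    seq_id: str,
    target: str,
    base: ConfusionCounts | None = None,
) -> ConfusionCounts:
    """Confusion counts as if ``seq_id`` were moved to OTU ``target``.

    ``target`` is an existing OTU label or :data:`NEW_SINGLETON`.  The update
    itself touches only the source and target OTUs: leaving an OTU where the
    sequence has k neighbors and m non-neighbors gives tp−k, fn+k, fp−m,
    tn+m; joining applies the same arithmetic with opposite signs.  When
    ``base`` (the pre-move counts) is omitted it is computed from scratch.
    """
    if seq_id not in graph.universe:
        raise ValueError(f"unknown sequence id {seq_id!r}")
    if target != NEW_SINGLETON and target not in partition.otus:
        raise ValueError(f"unknown target OTU label {target!r}")
    if base is None:
        base = confusion_matrix(graph, partition)
    current = partition.label_of(seq_id)
    if target == current:
        return base
    neigh = graph.neighbors(seq_id)

    src = partition.otus[current] - {seq_id}
    k_out = len(neigh & src)
    m_out = len(src) - k_out
    tp = base.tp - k_out
    fn = base.fn + k_out
    fp = base.fp - m_out
    tn = base.tn + m_out

    if target != NEW_SINGLETON:
        dst = partition.otus[target]
        k_in = len(neigh & dst)
        m_in = len(dst) - k_in
        tp += k_in
        fn -= k_in
        fp += m_in
        tn -= m_in
    return ConfusionCounts(tp=tp, fp=fp, fn=fn, tn=tn)


def write_stats(stream: TextIO, counts: ConfusionCounts, **extra) -> None:
    """Write a one-row TSV quality report.

    Columns: tp, fp, fn, tn, mcc, sensitivity, specificity, then any extra
    keyword columns (e.g. iterations, seed, fraction_mapped) in given order.
    Floats are printed to 6 significant digits.
    """

    def fmt(v) -> str:
        if isinstance(v, bool):
            return str(v).lower()
        if isinstance(v, float):
            return f"{v:.6g}"
        return str(v)

    header = ["tp", "fp", "fn", "tn", "mcc", "sensitivity", "specificity"]
    row = [
        counts.tp,
        counts.fp,
        counts.fn,
        counts.tn,
        mcc(counts),
        counts.sensitivity,
        counts.specificity,
    ]
    header.extend(extra.keys())
    row.extend(extra.values())
    stream.write("\t".join(header) + "\n")
    stream.write("\t".join(fmt(v) for v in row) + "\n")
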