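"""Sequence universes, sparse similarity graphs and OTU partitions, plus the
text formats that carry them.

The central object is the :class:`SimilarityGraph`: a set of sequence ids
together with the set of unordered pairs whose pairwise distance is at or
below a distance threshold (the "positive" pairs).  Everything downstream —
clustering, fitting, quality scoring — operates on this graph, never on raw
distances.

Supported formats:

* FASTA (read; ids only, optionally with sequences) via Bio.SeqIO,
* sparse "column" distance files (``id1 id2 dist`` per line),
* PHYLIP-style lower-triangle or square distance matrices,
* mothur-style single-line list files for OTU partitions (read/write),
* plain name lists (one id per line).

Boundary convention: a pair with distance exactly equal to the threshold is
*within* the threshold (an edge).  This matches the cutoff semantics of the
mothur ecosystem but is a dialect choice; see docs/methods.md.

Sparse convention: a pair absent from a column-format file is above the
threshold.  A universe is therefore required with column input — sequences
with no near neighbor never appear in the file at all.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, TextIO

from Bio import SeqIO

__all__ = [
    "SequenceUniverse",
    "SimilarityGraph",
    "OtuPartition",
    "FormatError",
    "read_fasta",
    "read_name_list",
    "read_column_distances",
    "read_matrix_distances",
    "read_list_file",
    "write_list_file",
    "total_pairs",
]


class FormatError(ValueError):
    """Raised for malformed or inconsistent input files."""


def total_pairs(n: int) -> int:
    """Number of unordered pairs among ``n`` sequences: n·(n−1)/2."""
    if n < 0:
        raise ValueError("sequence count must be non-negative")
    return n * (n - 1) // 2


@dataclass(frozen=True)
class SequenceUniverse:
    """An ordered collection of unique sequence identifiers.

    Order is deterministic for a given input (file order), which makes every
    downstream seeded computation reproducible.
    """

    ids: tuple[str, ...]
    _index: dict[str, int] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        index: dict[str, int] = {}
        for i, sid in enumerate(self.ids):
            if sid in index:
                raise FormatError(f"duplicate sequence id: {sid!r}")
            if not sid or any(c.isspace() for c in sid):
                raise FormatError(f"invalid sequence id: {sid!r}")
            index[sid] = i
        object.__setattr__(self, "_index", index)

    def __len__(self) -> int:
        return len(self.ids)

    def __contains__(self, sid: object) -> bool:
        return sid in self._index

    def __iter__(self):
        return iter(self.ids)

    def index(self, sid: str) -> int:
        return self._index[sid]

    @classmethod
    def from_ids(cls, ids: Iterable[str]) -> "SequenceUniverse":
        return cls(tuple(ids))


def _pair(a: str, b: str) -> tuple[str, str]:
    return (a, b) if a < b else (b, a)


@dataclass(frozen=True)
class SimilarityGraph:
    """Universe plus the set of within-threshold (positive) pairs.

    ``edges`` holds unordered id pairs stored with the lexicographically
    smaller id first.  An edge exists iff the recorded pairwise distance is
    ≤ ``threshold``; pairs never recorded are non-edges.
    """

    universe: SequenceUniverse
    threshold: float
    edges: frozenset[tuple[str, str]]

    def __post_init__(self) -> None:
        if not 0.0 <= self.threshold <= 1.0:
            raise ValueError("threshold must be a distance fraction in [0, 1]")
        for a, b in self.edges:
            if a == b:
                raise ValueError(f"self-edge on {a!r}")
            if a > b:
                raise ValueError(f"edge {a!r}-{b!r} not in canonical order")
            if a not in self.universe or b not in self.universe:
                raise ValueError(f"edge endpoint outside universe: {a!r}-{b!r}")

    @property
    def n_sequences(self) -> int:
        return len(self.universe)

    @property
    def n_possible_pairs(self) -> int:
        return total_pairs(len(self.universe))

    def has_edge(self, a: str, b: str) -> bool:
        return _pair(a, b) in self.edges

    def neighbors(self, sid: str) -> set[str]:
        # O(|edges|); hot paths use the indexed adjacency below instead.
        out = set()
        for a, b in self.edges:
            if a == sid:
                out.add(b)
            elif b == sid:
                out.add(a)
        return out

    def adjacency(self) -> list[set[int]]:
        """Index-based adjacency sets, aligned with universe order."""
        idx = self.universe.index
        adj: list[set[int]] = [set() for _ in range(len(self.universe))]
        for a, b in self.edges:
            ia, ib = idx(a), idx(b)
            adj[ia].add(ib)
            adj[ib].add(ia)
        return adj

    def subgraph(self, ids: Iterable[str]) -> "SimilarityGraph":
        """Induced subgraph, preserving universe order of the kept ids."""
        keep = set(ids)
        missing = keep - set(self.universe.ids)
        if missing:
            raise ValueError(f"ids not in universe: {sorted(missing)}")
        sub_universe = SequenceUniverse.from_ids(
            sid for sid in self.universe if sid in keep
        )
        sub_edges = frozenset(e for e in self.edges if e[0] in keep and e[1] in keep)
        return SimilarityGraph(sub_universe, self.threshold, sub_edges)

    @classmethod
    def from_pairs(
        cls,
        universe: SequenceUniverse,
        threshold: float,
        pairs: Iterable[tuple[str, str]],
    ) -> "SimilarityGraph":
        return cls(universe, threshold, frozenset(_pair(a, b) for a, b in pairs))


@dataclass(frozen=True)
class OtuPartition:
    """A partition of a sequence universe into labeled OTUs.

    OTUs are pairwise disjoint non-empty sets whose union is the universe;
    labels are opaque unique strings.
    """

    otus: Mapping[str, frozenset[str]]
    universe: SequenceUniverse

    def __post_init__(self) -> None:
        object.__setattr__(self, "otus", dict(self.otus))
        seen: set[str] = set()
        for label, members in self.otus.items():
            if not members:
                raise ValueError(f"empty OTU {label!r}")
            if seen & members:
                dup = sorted(seen & members)[0]
                raise ValueError(f"sequence {dup!r} appears in more than one OTU")
            seen |= members
        if seen != set(self.universe.ids):
            missing = sorted(set(self.universe.ids) - seen)
            extra = sorted(seen - set(self.universe.ids))
            raise ValueError(
                f"not a partition of the universe (missing={missing[:5]}, "
                f"extra={extra[:5]})"
            )

    @property
    def n_otus(self) -> int:
        return len(self.otus)

    def label_of(self, sid: str) -> str:
        for label, members in self.otus.items():
            if sid in members:
                return label
        raise KeyError(sid)

    def labels_by_sequence(self) -> dict[str, str]:
        out: dict[str, str] = {}
        for label, members in self.otus.items():
            for sid in members:
                out[sid] = label
        return out

    @classmethod
    def from_sets(
        cls, otus: Mapping[str, Iterable[str]], universe: SequenceUniverse | None = None
    ) -> "OtuPartition":
        frozen = {label: frozenset(members) for label, members in otus.items()}
        if universe is None:
            all_ids = sorted(set().union(*frozen.values())) if frozen else []
            universe = SequenceUniverse.from_ids(all_ids)
        return cls(frozen, universe)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def read_fasta(
    stream: TextIO, keep_sequences: bool = False
) -> SequenceUniverse | tuple[SequenceUniverse, dict[str, str]]:
    """Read a FASTA stream into a :class:`SequenceUniverse`.

    Record ids are the first whitespace-delimited token after ``>``
    (descriptions are dropped).  With ``keep_sequences=True`` also returns an
    id→sequence map.
    """
    ids: list[str] = []
    seqs: dict[str, str] = {}
    for record in SeqIO.parse(stream, "fasta"):
        if record.id in seqs or (not keep_sequences and record.id in ids):
            raise FormatError(f"duplicate sequence id in FASTA: {record.id!r}")
        ids.append(record.id)
        if keep_sequences:
            seqs[record.id] = str(record.seq)
    if not ids:
        raise FormatError("empty FASTA input")
    universe = SequenceUniverse.from_ids(ids)
    return (universe, seqs) if keep_sequences else universe


def read_name_list(stream: TextIO) -> SequenceUniverse:
    """Read a plain-text name list (one id per line, blank lines ignored)."""
    ids = [line.strip() for line in stream if line.strip()]
    if not ids:
        raise FormatError("empty name list")
    return SequenceUniverse.from_ids(ids)


def read_column_distances(
    stream: TextIO, threshold: float, universe: SequenceUniverse
) -> SimilarityGraph:
    """Read sparse column-format distances (``id1 id2 dist`` per line).

    An edge is added iff dist ≤ threshold.  Duplicate or reciprocal listings
    of a pair collapse to one edge, but listings whose distances straddle the
    threshold are rejected as ambiguous.  Self-pairs at or below threshold
    are ignored with a warning.
    """
    status: dict[tuple[str, str], bool] = {}  # pair -> within threshold
    for lineno, raw in enumerate(stream, start=1):
        line = raw.strip()
        if not line:
            continue
        parts = line.split()
        if len(parts) != 3:
            raise FormatError(
                f"line {lineno}: expected 'id1 id2 dist', got {line!r}"
            )
        a, b, dist_s = parts
        try:
            dist = float(dist_s)
        except ValueError:
            raise FormatError(f"line {lineno}: unparseable distance {dist_s!r}")
        for sid in (a, b):
            if sid not in universe:
                raise FormatError(f"line {lineno}: id {sid!r} not in universe")
        if a == b:
            if dist <= threshold:
                warnings.warn(f"line {lineno}: ignoring self-pair for {a!r}")
            continue
        key = _pair(a, b)
        within = dist <= threshold
        if key in status and status[key] != within:
            raise FormatError(
                f"line {lineno}: conflicting duplicate listings for pair "
                f"{key[0]}-{key[1]} straddle the threshold {threshold}"
            )
        status[key] = within
    edges = frozenset(k for k, within in status.items() if within)
    return SimilarityGraph(universe, threshold, edges)


def read_matrix_distances(stream: TextIO, threshold: float) -> SimilarityGraph:
    """Read a PHYLIP-style distance matrix (lower-triangle or square).

    First line is the sequence count n, then n rows ``id d1 d2 ...``.  A
    lower-triangle row i carries i−1 values; a square row carries n values.
    Square matrices must be symmetric to 1e-9.
    """
    lines = [line.rstrip("\n") for line in stream if line.strip()]
    if not lines:
        raise FormatError("empty matrix input")
    try:
        n = int(lines[0].strip())
    except ValueError:
        raise FormatError(f"first line must be the sequence count, got {lines[0]!r}")
    rows = lines[1:]
    if len(rows) != n:
        raise FormatError(f"declared {n} rows but found {len(rows)}")
    parsed: list[tuple[str, list[float]]] = []
    for i, row in enumerate(rows):
        parts = row.split()
        sid, values = parts[0], parts[1:]
        try:
            dists = [float(v) for v in values]
        except ValueError:
            raise FormatError(f"row {i + 1}: unparseable distance in {row!r}")
        parsed.append((sid, dists))
    universe = SequenceUniverse.from_ids(sid for sid, _ in parsed)

    square = n > 0 and len(parsed[0][1]) == n
    edges: set[tuple[str, str]] = set()
    if square:
        matrix = [d for _, d in parsed]
        for i in range(n):
            if len(matrix[i]) != n:
                raise FormatError(f"square row {i + 1} has {len(matrix[i])} values")
            for j in range(i):
                if abs(matrix[i][j] - matrix[j][i]) > 1e-9:
                    raise FormatError(
                        f"matrix not symmetric at ({i}, {j}): "
                        f"{matrix[i][j]} vs {matrix[j][i]}"
                    )
                if matrix[i][j] <= threshold:
                    edges.add(_pair(universe.ids[i], universe.ids[j]))
    else:
        for i, (sid, dists) in enumerate(parsed):
            if len(dists) != i:
                raise FormatError(
                    f"lower-triangle row {i + 1} has {len(dists)} values, expected {i}"
                )
            for j, d in enumerate(dists):
                if d <= threshold:
                    edges.add(_pair(sid, universe.ids[j]))
    return SimilarityGraph(universe, threshold, frozenset(edges))


def _ordered_otus(partition: OtuPartition) -> list[tuple[str, list[str]]]:
    # Deterministic output order: descending size, ties by smallest member id.
    items = [
        (label, sorted(members)) for label, members in partition.otus.items()
    ]
    items.sort(key=lambda kv: (-len(kv[1]), kv[1][0]))
    return items


def write_list_file(partition: OtuPartition, label: str, stream: TextIO) -> None:
    """Write a mothur-style single-line list file.

    Line layout: label, tab, OTU count, tab, one tab-separated field per OTU
    with comma-joined member ids.  OTU order is descending size then
    lexicographic smallest member, so output is diffable.
    """
    fields = [label, str(partition.n_otus)]
    fields.extend(",".join(members) for _, members in _ordered_otus(partition))
    stream.write("\t".join(fields) + "\n")


def list_file_line(partition: OtuPartition, label: str) -> str:
    buf = io.StringIO()
    write_list_file(partition, label, buf)
    return buf.getvalue()


def read_list_file(
    stream: TextIO, universe: SequenceUniverse | None = None
) -> OtuPartition:
    """Read a single-line list file into an :class:`OtuPartition`.

    OTUs get fresh labels ``OTU1..OTUk`` in file order.  If ``universe`` is
    supplied, member ids must be a subset of it (the partition universe stays
    the ids present in the file).
    """
    data_lines = [line.rstrip("\n") for line in stream if line.strip()]
    if len(data_lines) != 1:
        raise FormatError(f"expected exactly one list line, got {len(data_lines)}")
    fields = data_lines[0].split("\t")
    if len(fields) < 2:
        raise FormatError("list line must have at least label and OTU count")
    try:
        declared = int(fields[1])
    except ValueError:
        raise FormatError(f"unparseable OTU count {fields[1]!r}")
    otu_fields = fields[2:]
    if len(otu_fields) != declared:
        raise FormatError(
            f"declared {declared} OTUs but found {len(otu_fields)} fields"
        )
    otus: dict[str, frozenset[str]] = {}
    seen: set[str] = set()
    order: list[str] = []
    for k, field_ in enumerate(otu_fields, start=1):
        members = [m for m in field_.split(",") if m]
        if not members:
            raise FormatError(f"OTU field {k} is empty")
        for m in members:
            if m in seen:
                raise FormatError(f"sequence {m!r} appears in more than one OTU")
            seen.add(m)
            order.append(m)
        otus[f"OTU{k}"] = frozenset(members)
    if universe is not None:
        extra = seen - set(universe.ids)
        if extra:
            raise FormatError(f"list ids not in universe: {sorted(extra)[:5]}")
    part_universe = SequenceUniverse.from_ids(order)
    return OtuPartition(otus, part_universe)
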