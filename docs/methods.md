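# Methods

## The objective

Both optimizers maximize the Matthews correlation coefficient of an OTU
partition judged against a similarity graph. The graph encodes the OTU
definition: nodes are sequences, and an edge joins every pair whose recorded
pairwise distance is at or below the distance threshold (default
convention: a pair at *exactly* the threshold is within it — the cutoff
semantics of the mothur ecosystem; other toolchains may use strict
inequality, so round-tripping distances through other software can shift
boundary pairs). Crossing edge status with co-membership over all
n·(n−1)/2 pairs gives TP/FN/FP/TN, and

MCC = (TP·TN − FP·FN) / √((TP+FP)(TP+FN)(TN+FP)(TN+FN)).

When any marginal sum is zero the score is defined as 0. The choice
matters for degenerate graphs: an edgeless universe clustered as singletons
(all TN) and a complete graph clustered as one OTU (all TP) both score 0
under this convention even though neither makes an error. We use 0 — "no
better than random guessing" is the least surprising reading, and it keeps
the optimizers indifferent rather than spuriously attracted on such inputs —
but a reference implementation that defines these cases as 1 would disagree
there; no non-degenerate score is affected.

Counts are exact Python integers throughout (pair counts reach ~n²/2 and
products of four marginals overflow fixed 64-bit arithmetic long before the
comparison becomes inaccurate); MCC is evaluated in floating point only when
scores are compared. Two candidate scores within 1e-12 of each other are
tied; ties are broken uniformly at random. This equality tolerance is
distinct from the 1e-4 sweep-convergence tolerance, and it bounds how much
an accepted tie-break move can lower the score: monotonicity of the MCC
across accepted moves holds exactly up to 1e-12 and is asserted in-run.

## De novo clustering

Every sequence starts as its own singleton. A *sweep* visits all sequences
in a freshly shuffled order (one seeded generator drives shuffles and
tie-breaks, so a fixed seed reproduces the run exactly; reshuffling every
sweep rather than once per run is a deliberate choice — determinism is
preserved either way). For each sequence the candidate placements are: every
OTU containing at least one of its graph neighbors, its current OTU, and a
fresh singleton. Candidates are scored by the exact O(|source| + |target|)
confusion update — leaving an OTU where the sequence has k neighbors and m
non-neighbors changes (TP−k, FN+k, FP−m, TN+m), joining symmetrically — and
the best is applied. Moving to an OTU with no neighbor can never beat the
best candidate, so restricting to neighbor OTUs loses nothing; "remove me
from my OTU" and "fresh singleton" are the same option here. Sweeps stop
when the sweep-over-sweep MCC change is ≤ `tolerance` (default 1e-4) or
after `max_iterations` sweeps (default 100); convergence is tested on the
MCC after each full pass. Emptied OTUs are deleted immediately and new
singletons take fresh, never-reused labels.

## Reference fitting

The combined universe is references plus queries (disjoint). Reference OTUs
are frozen: sweeps visit only queries, and a query's candidates are the
*reference* OTUs containing at least one of its neighbors, plus staying
put, plus its own singleton. Two unassigned queries therefore cannot merge
during the fit phase; query-query edges still count in the score (all pairs
of the combined universe do — the worked example's initial TP=14 with all
queries singleton can only come from reference-reference pairs, which
settles that they are included). After convergence:

* **closed** — queries left in non-reference singletons are discarded. The
  reported confusion and MCC are recomputed over the *retained* universe
  (references plus mapped queries): discarded sequences have no pair
  outcomes. Whether a reference implementation reports closed-mode MCC over
  the retained or the full universe is a genuine ambiguity; retained is
  used here and reported prominently. `fraction_mapped` is
  |mapped| / |queries| (defined as 1.0, with a `no_queries` flag, when
  there are no queries).
* **open** — the unassigned queries are clustered de novo *among
  themselves* (induced subgraph), continuing the same RNG stream so one
  seed governs the whole run, and the new OTUs are appended under fresh
  labels. Confusion and MCC cover the full combined universe.

A mapped query always has at least one neighbor in its OTU, by construction
of the candidate set.

## Splitting strategies

`split_simple` takes a uniform sample without replacement of
round(fraction·n) reference ids (round half away from zero; splits that
would empty either side are rejected). The weighted strategies use
*successive sampling*: draw one id with probability proportional to its
weight, remove it, renormalize, repeat — stated explicitly because
different without-replacement schemes induce different inclusion
probabilities. Abundance weighting uses the per-sequence count table
directly. Similarity weighting uses 1 + similarity-graph degree: "similar
to many others" has no canonical formula, degree is the natural graph
quantity, and the +1 keeps isolated sequences selectable. Note a
consequence checked in the tests: in a 5-node star, the hub (degree 4,
weight 5) is drawn first with probability 5/13, since each leaf carries
weight 2, not 1.

## Synthetic data

`generate_planted_graph` emulates a community with known ground truth:
OTU sizes uniform on a range, each intra-OTU pair an edge with probability
`p_within`, each inter-OTU pair with `p_between`. It emulates the *graph*
a distance file would induce, not the distances themselves: there is no
sequencing-error model, no chimeras, no abundance structure beyond the size
range. Passing tests on these fixtures show the optimizers handle
planted modular structure plus noise; they do not certify behavior on real
amplicon distance distributions.

`generate_sequence_family` emulates the upstream of that graph: per-OTU
random centroids (re-drawn until mutually far enough apart that inter-OTU
member distances stay above 0.03), members at exactly `within_mutations`
substitutions from their centroid, distance = Hamming mismatch fraction on
equal-length ungapped sequences, emitted sparsely (pairs ≤ 0.10 only) in
column format. The Hamming distance is a deliberate fixture
simplification — real pipelines compute distances from alignments with
indels; nothing here models that.

The split-quality tests use a skewed community of 20 planted OTUs with 1-30
members (~300 sequences), p_within = 0.9, p_between = 0.01. The skew is the
point: rare lineages whose few members all land in the query fraction are
what make closed-mode mapping depend on reference coverage, which is the
trend those tests check. Problem sizes throughout the suite (n ≤ 7 for
partition enumeration, ≤ 6 references / ≤ 4 queries for fit enumeration,
~300 sequences for split experiments, 10-20 seeds per comparison) are
chosen to keep exhaustive oracles exact and the full suite at desk scale.

## Brute-force oracles

`brute_force_best_partition` enumerates every set partition via restricted
growth strings (capped at n = 12, near the practical limit of Bell-number
enumeration) and returns the global maximum-MCC partition; ties resolve to
the first optimum in enumeration order, the MCC value itself being unique.
`brute_force_best_fit` enumerates every assignment of each query to (each
reference OTU ∪ own singleton) with references frozen — the same move space
as the fitting optimizer — capped at 6 queries and 8 reference OTUs. Both
exist to dominate and cross-check the local search on small instances; the
local search matches their optima on ≥95% of random instances at
best-of-10 seeds, and can in principle stop at a local maximum on
adversarial graphs.

## Degenerate inputs and edge cases

* Empty distance stream: valid, edgeless graph (with a universe supplied).
* Self-pairs in distance files: ignored with a warning.
* Duplicate pair listings: collapse to one edge if they agree about the
  threshold; listings straddling the threshold are rejected as ambiguous
  rather than silently last-wins.
* Zero queries in a fit: the reference partition comes back with its own
  MCC and `no_queries=True`.
* Fractions that would empty the reference or query side of a split are
  errors, as are non-positive abundance counts.

## Known limitations

* The optimizers are local searches; the ≥95% optimum-recovery rate is an
  empirical property of small random instances, not a guarantee.
* Dereplication (names/count files mapping duplicate reads to one unique
  sequence) is not modeled: every id is an independent entity, and
  abundance enters only through the splitting module's count table.
* Closed-mode MCC over the retained universe (see above) is a reporting
  convention, not the only defensible one.
* The Hamming fixture distance and the planted-partition noise model are
  simplifications; neither reproduces real amplicon error structure.
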