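"""Reference fitting: frozen references, open/closed finalization, oracles."""

import random

import pytest

from otufit import (
    FitConfig,
    OtuPartition,
    SequenceUniverse,
    SimilarityGraph,
    brute_force_best_fit,
    close_partition,
    confusion_matrix,
    mcc,
    open_extend,
    opticlust,
    ClusterConfig,
    optifit,
)

from conftest import random_graph


def _random_fit_instance(rng: random.Random):
    """Random refs (clustered de novo) plus random queries on one graph."""
    n_ref = rng.randint(3, 6)
    n_query = rng.randint(1, 4)
    ids = [f"r{i}" for i in range(n_ref)] + [f"q{i}" for i in range(n_query)]
    universe = SequenceUniverse.from_ids(ids)
    p = rng.uniform(0.2, 0.8)
    edges = [
        (ids[i], ids[j])
        for i in range(len(ids))
        for j in range(i + 1, len(ids))
        if rng.random() < p
    ]
    graph = SimilarityGraph.from_pairs(universe, 0.03, edges)
    ref_graph = graph.subgraph(ids[:n_ref])
    reference = opticlust(ref_graph, ClusterConfig(seed=rng.randrange(2**20))).partition
    return graph, reference, ids[n_ref:]


class TestFitExamples:
    def test_query_joins_reference_otu_with_both_neighbors(self, fit_example):
        graph, reference = fit_example
        res = optifit(graph, reference, ["W"], FitConfig(mode="closed", seed=0))
        assert res.mcc == 1.0
        assert res.partition.otus["OTU1"] == frozenset({"A", "B", "W"})
        assert res.fraction_mapped == 1.0
        c = res.confusion
        assert (c.tp, c.fp, c.fn, c.tn) == (3, 0, 0, 3)

    def test_initial_state_of_fit_example(self, fit_example):
        graph, reference = fit_example
        start = OtuPartition.from_sets(
            {**{k: set(v) for k, v in reference.otus.items()}, "q": {"W"}},
            graph.universe,
        )
        c = confusion_matrix(graph, start)
        assert (c.tp, c.fp, c.fn, c.tn) == (1, 0, 2, 3)
        assert mcc(c) == pytest.approx(0.447, abs=0.001)

    def test_neighborless_query_stays_singleton(self):
        """A query dissimilar to everything remains unassigned: dropped in
        closed mode, its own OTU in open mode."""
        u = SequenceUniverse.from_ids(["A", "B", "Z"])
        g = SimilarityGraph.from_pairs(u, 0.03, [("A", "B")])
        ref = OtuPartition.from_sets(
            {"O1": {"A", "B"}}, SequenceUniverse.from_ids(["A", "B"])
        )
        closed = optifit(g, ref, ["Z"], FitConfig(mode="closed", seed=1))
        assert closed.unmapped_ids == frozenset({"Z"})
        assert closed.fraction_mapped == 0.0
        assert set(closed.partition.universe.ids) == {"A", "B"}
        opened = optifit(g, ref, ["Z"], FitConfig(mode="open", seed=1))
        assert opened.fraction_mapped == 1.0
        assert frozenset({"Z"}) in set(opened.partition.otus.values())

    def test_three_of_four_queries_mapped_gives_fraction_three_quarters(self):
        """Scenario shaped like the toy walk-through: three queries sit near
        reference OTUs, one is isolated, so closed mode maps 3/4."""
        ref_ids = ["A", "B", "C", "D", "E", "F"]
        u = SequenceUniverse.from_ids(ref_ids + ["W", "X", "Y", "Z"])
        edges = [
            ("A", "B"), ("C", "D"), ("E", "F"),       # three reference OTUs
            ("W", "A"), ("W", "B"),                   # W near OTU(A,B)
            ("X", "C"), ("X", "D"),                   # X near OTU(C,D)
            ("Y", "E"),                               # Y near OTU(E,F)
        ]
        g = SimilarityGraph.from_pairs(u, 0.03, edges)
        ref = OtuPartition.from_sets(
            {"o1": {"A", "B"}, "o2": {"C", "D"}, "o3": {"E", "F"}},
            SequenceUniverse.from_ids(ref_ids),
        )
        res = optifit(g, ref, ["W", "X", "Y", "Z"], FitConfig(mode="closed", seed=2))
        assert res.fraction_mapped == 0.75
        assert res.unmapped_ids == frozenset({"Z"})


class TestContracts:
    @pytest.mark.parametrize("mode", ["open", "closed"])
    @pytest.mark.parametrize("trial", range(8))
    def test_reference_assignments_frozen(self, mode, trial):
        rng = random.Random(500 + trial)
        graph, reference, queries = _random_fit_instance(rng)
        res = optifit(graph, reference, queries, FitConfig(mode=mode, seed=trial))
        for label, members in reference.otus.items():
            assert members <= res.partition.otus[label]
            # and no reference sequence migrated elsewhere
            for other, m in res.partition.otus.items():
                if other != label:
                    assert not (members & m)

    @pytest.mark.parametrize("trial", range(8))
    def test_mapped_query_has_neighbor_in_its_otu(self, trial):
        rng = random.Random(600 + trial)
        graph, reference, queries = _random_fit_instance(rng)
        res = optifit(graph, reference, queries, FitConfig(mode="closed", seed=trial))
        for q in queries:
            if q in res.unmapped_ids:
                continue
            label = res.partition.label_of(q)
            assert graph.neighbors(q) & (res.partition.otus[label] - {q})

    def test_universes_by_mode(self):
        rng = random.Random(42)
        graph, reference, queries = _random_fit_instance(rng)
        refs = set(reference.universe.ids)
        closed = optifit(graph, reference, queries, FitConfig(mode="closed", seed=0))
        assert set(closed.partition.universe.ids) == refs | (
            set(queries) - closed.unmapped_ids
        )
        assert set(closed.partition.otus) <= set(reference.otus)
        opened = optifit(graph, reference, queries, FitConfig(mode="open", seed=0))
        assert set(opened.partition.universe.ids) == refs | set(queries)

    def test_fit_phase_trace_monotone(self):
        rng = random.Random(43)
        for trial in range(10):
            graph, reference, queries = _random_fit_instance(rng)
            res = optifit(graph, reference, queries, FitConfig(mode="open", seed=trial))
            for earlier, later in zip(res.mcc_trace, res.mcc_trace[1:]):
                assert later >= earlier - 1e-12
            for earlier, later in zip(
                res.de_novo_mcc_trace, res.de_novo_mcc_trace[1:]
            ):
                assert later >= earlier - 1e-12

    def test_zero_queries_returns_reference_partition(self, fit_example):
        graph, reference = fit_example
        ref_graph = graph.subgraph(reference.universe.ids)
        res = optifit(ref_graph, reference, [], FitConfig(mode="closed", seed=0))
        assert res.no_queries
        assert res.fraction_mapped == 1.0
        assert res.partition.otus == reference.otus
        assert res.mcc == pytest.approx(
            mcc(confusion_matrix(ref_graph, reference))
        )

    def test_query_overlap_and_missing_ids_rejected(self, fit_example):
        graph, reference = fit_example
        with pytest.raises(ValueError):
            optifit(graph, reference, ["A"], FitConfig(seed=0))  # overlap
        with pytest.raises(ValueError):
            optifit(graph, reference, ["W", "nope"], FitConfig(seed=0))

    def test_mode_validation(self):
        with pytest.raises(ValueError):
            FitConfig(mode="bogus")


class TestClosePartition:
    def test_no_queries_mapped(self):
        u = SequenceUniverse.from_ids(["r0", "r1", "q0"])
        p = OtuPartition.from_sets(
            {"ref": {"r0", "r1"}, "lone": {"q0"}}, u
        )
        closed, unmapped = close_partition(p, ["ref"], ["q0"])
        assert unmapped == frozenset({"q0"})
        assert closed.otus == {"ref": frozenset({"r0", "r1"})}

    def test_all_queries_mapped(self):
        u = SequenceUniverse.from_ids(["r0", "q0"])
        p = OtuPartition.from_sets({"ref": {"r0", "q0"}}, u)
        closed, unmapped = close_partition(p, ["ref"], ["q0"])
        assert unmapped == frozenset()
        assert set(closed.universe.ids) == {"r0", "q0"}

    @pytest.mark.parametrize("trial", range(10))
    def test_retained_universe_matches_set_arithmetic(self, trial):
        rng = random.Random(700 + trial)
        graph, reference, queries = _random_fit_instance(rng)
        res = optifit(graph, reference, queries, FitConfig(mode="closed", seed=trial))
        refs = set(reference.universe.ids)
        mapped = set(queries) - res.unmapped_ids
        assert set(res.partition.universe.ids) == refs | mapped


class TestOpenExtend:
    def test_zero_unassigned_is_identity(self, fit_example):
        graph, reference = fit_example
        p = OtuPartition.from_sets(
            {**{k: set(v) for k, v in reference.otus.items()}, "w": {"W"}},
            graph.universe,
        )
        assert open_extend(graph, p, [], FitConfig(seed=0)) is p

    def test_two_adjacent_unassigned_queries_form_one_otu(self):
        u = SequenceUniverse.from_ids(["r", "p", "q"])
        g = SimilarityGraph.from_pairs(u, 0.03, [("p", "q")])
        p = OtuPartition.from_sets(
            {"ref": {"r"}, "a": {"p"}, "b": {"q"}}, u
        )
        out = open_extend(g, p, ["p", "q"], FitConfig(seed=0))
        assert frozenset({"p", "q"}) in set(out.otus.values())
        assert out.otus["ref"] == frozenset({"r"})

    @pytest.mark.parametrize("trial", range(8))
    def test_open_mode_mcc_at_least_closed_over_full_universe(self, trial):
        """Clustering the leftovers de novo can only help the full-universe
        score relative to discarding them."""
        rng = random.Random(800 + trial)
        graph, reference, queries = _random_fit_instance(rng)
        opened = optifit(graph, reference, queries, FitConfig(mode="open", seed=trial))
        # closed assignments evaluated over the FULL universe: unmapped
        # queries as singletons
        closed = optifit(graph, reference, queries, FitConfig(mode="closed", seed=trial))
        otus = {k: set(v) for k, v in closed.partition.otus.items()}
        for i, q in enumerate(sorted(closed.unmapped_ids)):
            otus[f"um{i}"] = {q}
        closed_full = OtuPartition.from_sets(otus, graph.universe)
        assert opened.mcc >= mcc(confusion_matrix(graph, closed_full)) - 1e-9


class TestOracleAgreement:
    def test_small_instances_match_brute_force(self):
        """Best-of-10-seeds fit MCC matches exhaustive enumeration on ≥95%
        of small random instances (fit phase, joins-refs-only)."""
        rng = random.Random(900)
        hits = 0
        trials = 40
        for t in range(trials):
            graph, reference, queries = _random_fit_instance(rng)
            _, best = brute_force_best_fit(graph, reference, queries)
            achieved = -2.0
            for s in range(10):
                res = optifit(
                    graph, reference, queries, FitConfig(mode="closed", seed=s)
                )
                # evaluate the fit-phase assignment over the full universe,
                # like the oracle does
                otus = {k: set(v) for k, v in res.partition.otus.items()}
                for i, q in enumerate(sorted(res.unmapped_ids)):
                    otus[f"um{i}"] = {q}
                full = OtuPartition.from_sets(otus, graph.universe)
                achieved = max(achieved, mcc(confusion_matrix(graph, full)))
            assert achieved <= best + 1e-9  # oracle dominance
            if achieved >= best - 1e-9:
                hits += 1
        assert hits / trials >= 0.95
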