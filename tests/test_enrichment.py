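import itertools

import networkx as nx
import numpy as np
import pytest

from lncora.annotations import OntologyDag, TermMap
from lncora.enrichment import (
    EnrichmentInput,
    enrich_all,
    enrich_term,
    eq2_tail,
    eq2_tail_printed,
    hypergeom_tail,
    prune_go_parents,
)
from lncora.errors import ConfigError

from oracles import augmented_series, enumerate_tail, summed_tail


def small_grid(n_max):
    for N in range(1, n_max + 1):
        for n in range(N + 1):
            for K in range(N + 1):
                for i in range(min(n, K) + 2):
                    yield N, n, K, i


class TestHypergeomTail:
    def test_at_least_zero_is_certain(self):
        assert hypergeom_tail(10, 5, 5, 0) == 1.0

    def test_enumerated_example(self):
        # N=4, n=2, K=2, i=2: exactly one of the C(4,2)=6 draws holds both
        assert hypergeom_tail(4, 2, 2, 2) == pytest.approx(1 / 6, abs=1e-12)

    def test_impossible_count_is_zero(self):
        assert hypergeom_tail(10, 3, 2, 3) == 0.0

    @pytest.mark.parametrize("params", [(-1, 0, 0, 0), (5, 6, 0, 0), (5, 0, 6, 0), (5, 0, 0, -1)])
    def test_precondition_errors(self, params):
        with pytest.raises(ValueError):
            hypergeom_tail(*params)

    def test_exhaustive_enumeration_oracle_N_le_8(self):
        # full N <= 12 grid lives in the acceptance suite; spot the small grid here
        for N, n, K, i in small_grid(8):
            assert hypergeom_tail(N, n, K, i) == pytest.approx(
                enumerate_tail(N, n, K, i), abs=1e-12
            ), (N, n, K, i)

    def test_non_increasing_in_i_and_one_at_zero(self):
        for N, n, K in [(20, 7, 5), (50, 10, 20), (100, 30, 3)]:
            values = [hypergeom_tail(N, n, K, i) for i in range(min(n, K) + 2)]
            assert values[0] == 1.0
            assert all(a >= b - 1e-15 for a, b in zip(values, values[1:]))

    def test_large_N_stability(self):
        p = hypergeom_tail(100_000, 600, 50, 10)
        assert 0.0 < p < 1e-6


class TestEq2Tail:
    def test_reduces_to_classical_at_r_zero(self):
        assert eq2_tail(10, 5, 5, 0, 0) == hypergeom_tail(10, 5, 5, 0) == 1.0
        for N, n, K, i in small_grid(8):
            assert eq2_tail(N, n, K, i, 0) == pytest.approx(
                hypergeom_tail(N, n, K, i), abs=1e-12
            )

    def test_worked_value_against_draw_enumeration(self):
        # oracle: enumerate C(6,3)=20 draws, >= 2 of the 3 annotated genes
        N, n, K, i, r = 6, 2, 3, 1, 1
        annotated = set(range(K))
        hits = sum(
            1
            for draw in itertools.combinations(range(N), n + r)
            if len(set(draw) & annotated) >= i + r
        )
        assert hits / 20 == 0.5
        assert eq2_tail(N, n, K, i, r) == pytest.approx(0.5, abs=1e-12)

    def test_printed_series_equals_substituted_form(self):
        rng = np.random.default_rng(1)
        for _ in range(300):
            N = int(rng.integers(1, 31))
            n = int(rng.integers(0, N + 1))
            r = int(rng.integers(0, min(5, N - n) + 1))
            K = int(rng.integers(0, N + 1))
            i = int(rng.integers(0, n + 2))
            assert eq2_tail_printed(N, n, K, i, r) == pytest.approx(
                hypergeom_tail(N, n + r, K, i + r), abs=1e-12
            ), (N, n, K, i, r)

    def test_printed_series_matches_exact_rational_oracle(self):
        for N, n, K, i in small_grid(7):
            for r in range(0, N - n + 1):
                assert eq2_tail_printed(N, n, K, i, r) == pytest.approx(
                    augmented_series(N, n, K, i, r), abs=1e-12
                )

    def test_precondition_errors(self):
        with pytest.raises(ValueError):
            eq2_tail(10, 5, 5, 0, -1)
        with pytest.raises(ValueError):
            eq2_tail(10, 8, 5, 0, 5)  # n + r > N


def make_input(universe, de, lnc=(), mode="eq1", alpha=0.05, terms=None):
    term_map = TermMap(
        terms={t: frozenset(g) for t, g in (terms or {}).items()}, namespace="GO"
    )
    return EnrichmentInput(
        universe=frozenset(universe),
        de_genes=frozenset(de),
        lncgenes=frozenset(lnc),
        term_map=term_map,
        alpha=alpha,
        mode=mode,
    )


class TestEnrichTerm:
    def test_extreme_enrichment_smallest_p(self):
        universe = {f"g{i}" for i in range(20)}
        de = {"g0", "g1", "g2"}
        inp = make_input(universe, de, terms={"T": de})
        res = enrich_term("T", inp)
        assert (res.K, res.k_de) == (3, 3)
        assert res.p_value == pytest.approx(summed_tail(20, 3, 3, 3), abs=1e-12)

    def test_eq1_equals_eq2_combined_at_r_zero(self):
        universe = {f"g{i}" for i in range(15)}
        terms = {"T1": {"g0", "g1"}, "T2": {"g5", "g6", "g7"}}
        de = {"g0", "g5", "g9"}
        for term in terms:
            p1 = enrich_term(term, make_input(universe, de, terms=terms, mode="eq1"))
            p2 = enrich_term(
                term, make_input(universe, de, terms=terms, mode="eq2_combined")
            )
            assert p1.p_value == p2.p_value

    def test_combined_mode_counts(self):
        # universe 20, term {g1..g4}, de {g1,g2,x1}, lncgenes {g3,y1}
        universe = {f"g{i}" for i in range(1, 5)} | {"x1", "y1"} | {
            f"z{i}" for i in range(14)
        }
        inp = make_input(
            universe,
            de={"g1", "g2", "x1"},
            lnc={"g3", "y1"},
            mode="eq2_combined",
            terms={"T": {"g1", "g2", "g3", "g4"}},
        )
        res = enrich_term("T", inp)
        assert (res.K, res.k_de, res.k_lnc) == (4, 2, 1)
        assert res.p_value == pytest.approx(summed_tail(20, 5, 4, 3), abs=1e-12)

    def test_term_outside_universe_gets_p_one(self):
        inp = make_input({"a", "b"}, {"a"}, terms={"T": {"zzz"}})
        res = enrich_term("T", inp)
        assert (res.K, res.p_value, res.significant) == (0, 1.0, False)

    def test_unknown_term(self):
        inp = make_input({"a"}, {"a"}, terms={"T": {"a"}})
        with pytest.raises(KeyError):
            enrich_term("nope", inp)

    def test_overlapping_de_and_lncgenes_rejected(self):
        with pytest.raises(ConfigError):
            make_input({"a", "b"}, {"a"}, lnc={"a"}, terms={"T": {"a"}})


class TestEnrichAll:
    def test_no_hits_p_one(self):
        universe = {f"g{i}" for i in range(10)}
        inp = make_input(universe, de=set(), terms={"T1": {"g1"}, "T2": {"g2"}})
        results = enrich_all(inp)
        assert all(r.p_value == 1.0 and not r.significant for r in results)

    def test_alpha_one_everything_significant(self):
        universe = {f"g{i}" for i in range(10)}
        inp = make_input(
            universe, de={"g1"}, alpha=1.0, terms={"T1": {"g1"}, "T2": {"g2"}}
        )
        assert all(r.significant for r in enrich_all(inp))

    def test_sorted_by_p_then_K_then_id(self):
        universe = {f"g{i}" for i in range(30)}
        terms = {"Tb": {"g1", "g2"}, "Ta": {"g3", "g4"}, "Tc": {"g1", "g2", "g5"}}
        results = enrich_all(make_input(universe, de={"g1", "g2"}, terms=terms))
        keys = [(r.p_value, -r.K, r.term_id) for r in results]
        assert keys == sorted(keys)

    def test_empty_map_errors(self):
        with pytest.raises((ConfigError, ValueError)):
            enrich_all(make_input({"a"}, {"a"}, terms={}))

    def test_gene_order_invariance(self):
        universe = [f"g{i}" for i in range(25)]
        terms = {"T1": {"g1", "g2", "g3"}, "T2": {"g9", "g10"}}
        a = enrich_all(make_input(universe, {"g1", "g2"}, terms=terms))
        b = enrich_all(make_input(reversed(universe), {"g2", "g1"}, terms=terms))
        assert a == b

    def test_bh_adjustment_more_conservative(self):
        universe = {f"g{i}" for i in range(200)}
        terms = {f"T{j}": {f"g{j}", f"g{j+1}"} for j in range(0, 40, 2)}
        de = {"g0", "g1", "g2"}
        raw = enrich_all(make_input(universe, de, terms=terms))
        adj = enrich_all(make_input(universe, de, terms=terms), bh_adjust=True)
        assert sum(r.significant for r in adj) <= sum(r.significant for r in raw)


def chain_dag(*terms):
    graph = nx.DiGraph()
    graph.add_nodes_from(terms)
    for child, parent in zip(terms, terms[1:]):
        graph.add_edge(child, parent, relation="is_a")
    return OntologyDag(graph)


def make_results(significant, all_terms, mode="eq1"):
    from lncora.enrichment import EnrichmentResult

    return [
        EnrichmentResult(
            term_id=t, K=1, k_de=0, k_lnc=0,
            p_value=0.01 if t in significant else 0.9,
            significant=t in significant, mode=mode,
        )
        for t in all_terms
    ]


class TestPruneGoParents:
    def test_minimal_parent_pruned(self):
        dag = chain_dag("B", "A")  # B is_a A
        results = prune_go_parents(make_results({"A", "B"}, ["A", "B"]), dag)
        flags = {r.term_id: r.pruned for r in results}
        assert flags == {"A": True, "B": False}

    def test_transitive_chain_keeps_only_leaf(self):
        dag = chain_dag("C", "B", "A")
        results = prune_go_parents(make_results({"A", "B", "C"}, ["A", "B", "C"]), dag)
        kept = {r.term_id for r in results if r.significant and not r.pruned}
        assert kept == {"C"}

    def test_direct_only_mode_keeps_grandparent(self):
        dag = chain_dag("C", "B", "A")
        results = prune_go_parents(
            make_results({"A", "C"}, ["A", "B", "C"]), dag, transitive=False
        )
        kept = {r.term_id for r in results if r.significant and not r.pruned}
        assert kept == {"A", "C"}  # A is not a *direct* parent of C

    def test_disjoint_branches_untouched(self):
        graph = nx.DiGraph()
        graph.add_edge("A", "root", relation="is_a")
        graph.add_edge("D", "root", relation="is_a")
        dag = OntologyDag(graph)
        results = prune_go_parents(make_results({"A", "D"}, ["A", "D"]), dag)
        assert not any(r.pruned for r in results)

    def test_missing_terms_pass_through(self):
        dag = chain_dag("B", "A")
        results = prune_go_parents(make_results({"X"}, ["X"]), dag)
        assert results[0].pruned is False

    def test_nonsignificant_never_pruned(self):
        dag = chain_dag("C", "B", "A")
        results = prune_go_parents(make_results({"C"}, ["A", "B", "C"]), dag)
        assert not any(r.pruned for r in results if not r.significant)

    @pytest.mark.parametrize("seed", range(10))
    def test_random_dag_invariant(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 50))
        graph = nx.DiGraph()
        graph.add_nodes_from([f"T{i}" for i in range(n)])
        for child in range(1, n):
            for parent in rng.choice(child, size=min(child, 2), replace=False):
                graph.add_edge(f"T{child}", f"T{int(parent)}", relation="is_a")
        dag = OntologyDag(graph)
        significant = {f"T{i}" for i in range(n) if rng.random() < 0.4}
        results = prune_go_parents(
            make_results(significant, [f"T{i}" for i in range(n)]), dag
        )
        kept = {r.term_id for r in results if r.significant and not r.pruned}
        pruned = {r.term_id for r in results if r.pruned}
        for term in kept:
            assert not (dag.ancestors(term) & kept)
        for term in pruned:  # every pruned term is an ancestor of a kept term
            assert any(term in dag.ancestors(k) for k in kept)
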