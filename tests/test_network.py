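import io
import random

import pytest

from assocnet.blast_io import parse_blast_tabular
from assocnet.errors import ValidationError
from assocnet.network import (
    EdgeGate,
    association_counts,
    build_network,
    export_edge_list,
    export_graphml,
    export_report_doc,
    neighbors,
)
from assocnet.synthfix import FixtureSpec, generate_fixture, planted_counts
from conftest import ABC_TABULAR


class TestAssociationPrinciple:
    def test_shared_hit_is_associated_with_all_three_queries(self, abc_results):
        net = build_network(abc_results)
        assert association_counts(net)["a"] == 3

    def test_neighbors_of_shared_hit_are_the_queries(self, abc_results):
        net = build_network(abc_results)
        assert set(neighbors(net, "a")) == {"A", "B", "C"}

    def test_neighbors_of_a_query_are_its_hits(self, abc_results):
        net = build_network(abc_results)
        assert set(neighbors(net, "C")) == {"other2", "other3", "a"}

    def test_unknown_node_rejected(self, abc_results):
        net = build_network(abc_results)
        with pytest.raises(ValidationError, match="zzz"):
            neighbors(net, "zzz")


class TestBuild:
    def test_empty_results_give_empty_network(self):
        net = build_network([])
        assert not net.query_nodes and not net.hit_nodes and net.n_edges() == 0

    def test_duplicate_query_id_rejected(self, abc_results):
        with pytest.raises(ValidationError, match="'A'"):
            build_network(abc_results + [abc_results[0]])

    def test_gate_removes_edges_before_counting(self, abc_results):
        net = build_network(abc_results, EdgeGate(max_evalue=1e-82))
        # only A (1e-80 fails) loses its edge to a; B (1e-85) and C (1e-70) ...
        counts = association_counts(net)
        assert counts["a"] == 1  # only B's 1e-85 survives

    def test_self_hits_excluded_from_counts_by_default(self):
        rows = (
            "A\tA\t100.0\t200\t0\t0\t1\t200\t1\t200\t0.0\t400.0\n"
            "A\ta\t97.0\t200\t6\t0\t1\t200\t1\t200\t1e-80\t300.0\n"
            "B\ta\t98.0\t200\t4\t0\t1\t200\t1\t200\t1e-85\t320.0\n"
        )
        net = build_network(parse_blast_tabular(rows))
        assert ("A", "A") in net.self_edges
        assert association_counts(net) == {"a": 2}

    def test_self_hits_counted_under_flag(self):
        rows = (
            "A\tA\t100.0\t200\t0\t0\t1\t200\t1\t200\t0.0\t400.0\n"
            "B\tA\t99.0\t200\t2\t0\t1\t200\t1\t200\t1e-90\t390.0\n"
        )
        net = build_network(parse_blast_tabular(rows), count_self_edges=True)
        assert association_counts(net)["A"] == 2


class TestOrderInvariance:
    def test_permuted_input_gives_identical_exports(self, abc_results):
        shuffled = list(abc_results)
        random.Random(0).shuffle(shuffled)
        outs = []
        for results in (abc_results, shuffled):
            net = build_network(results)
            buf = io.StringIO()
            export_graphml(net, buf)
            outs.append(buf.getvalue())
        assert outs[0] == outs[1]


class TestGateMonotonicity:
    @pytest.mark.parametrize(
        "loose, tight",
        [
            (EdgeGate(), EdgeGate(max_evalue=1e-82)),
            (EdgeGate(max_evalue=1e-70), EdgeGate(max_evalue=1e-90)),
            (EdgeGate(min_bit_score=300), EdgeGate(min_bit_score=340)),
            (EdgeGate(min_percent_identity=96), EdgeGate(min_percent_identity=99)),
            (EdgeGate(max_rank=3), EdgeGate(max_rank=1)),
        ],
    )
    def test_tightening_never_adds_edges(self, abc_results, loose, tight):
        edges = lambda gate: set(build_network(abc_results, gate).graph.edges)
        assert edges(tight) <= edges(loose)


class TestCountConservation:
    def test_count_sum_equals_non_self_edges(self):
        bundle = generate_fixture(
            FixtureSpec(n_queries=6, n_subjects=15, seed=3, incidence=0.3)
        )
        net = build_network(parse_blast_tabular(bundle.blast_tab))
        counts = association_counts(net)
        assert sum(counts.values()) == net.n_edges() - len(net.self_edges)
        assert counts == planted_counts(bundle)


class TestExports:
    def test_graphml_background_example(self, abc_results):
        # restrict to the shared hit: A, B, C and a -> 4 nodes, 3 edges
        only_a = [
            type(r)(query_id=r.query_id, hits=tuple(
                h.__class__(**{**vars(h), "rank": 1}) for h in r.hits if h.subject_id == "a"
            ))
            for r in abc_results
        ]
        net = build_network(only_a)
        buf = io.StringIO()
        export_graphml(net, buf)
        text = buf.getvalue()
        assert text.count("<node ") == 4
        assert text.count("<edge ") == 3
        assert ">3</data>" in text  # a.association_count

    def test_exports_are_deterministic(self, abc_results):
        net = build_network(abc_results)
        for exporter in (export_graphml, export_edge_list, export_report_doc):
            a, b = io.StringIO(), io.StringIO()
            exporter(net, a)
            exporter(net, b)
            assert a.getvalue() == b.getvalue()

    def test_empty_network_exports_are_valid(self):
        net = build_network([])
        for exporter in (export_graphml, export_edge_list, export_report_doc):
            buf = io.StringIO()
            exporter(net, buf)
            assert buf.getvalue()


class TestFormatParity:
    def test_xml_and_tabular_networks_export_identically(self):
        bundle = generate_fixture(
            FixtureSpec(n_queries=5, n_subjects=12, seed=21, incidence=0.35)
        )
        from assocnet.blast_io import parse_blast_xml

        out = []
        for results in (
            parse_blast_tabular(bundle.blast_tab),
            parse_blast_xml(bundle.blast_xml),
        ):
            buf = io.StringIO()
            export_graphml(build_network(results), buf)
            out.append(buf.getvalue())
        assert out[0] == out[1]
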