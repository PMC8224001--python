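import itertools

import networkx as nx
import numpy as np
import pytest

from keramine.align import AlignmentHit
from keramine.network import (
    build_network,
    detect_communities,
    evalue_weight,
    link_keratinases,
)
from keramine.records import ProteinRecord


def _hit(q, s, evalue):
    return AlignmentHit(
        query=q, subject=s, bitscore=10.0, evalue=evalue, identity_pct=42.0,
        alignment_length=100, query_span=(1, 100), subject_span=(1, 100),
    )


def _rec(pid, category="query", strain="G11C"):
    return ProteinRecord(id=pid, strain=strain, sequence="MKVLI",
                         category=category)


def test_edge_weight_is_neglog_evalue_capped():
    assert evalue_weight(1e-50) == pytest.approx(50.0)
    assert evalue_weight(0.0) == 300.0
    assert evalue_weight(1e-400) == 300.0


def test_edge_requires_threshold_and_min_rule():
    hits = [_hit("A", "B", 1e-50), _hit("B", "A", 1e-45), _hit("A", "C", 1e-30)]
    net = build_network(hits, threshold=1e-40)
    assert net.has_edge("A", "B")
    assert not net.has_edge("A", "C")
    assert net.edges["A", "B"]["evalue"] == 1e-50
    assert net.edges["A", "B"]["weight"] == pytest.approx(50.0)


def test_self_hits_dropped_and_isolated_nodes_kept():
    records = [_rec("A"), _rec("B"), _rec("C")]
    net = build_network([_hit("A", "A", 0.0), _hit("A", "B", 1e-60)],
                        threshold=1e-40, records=records)
    assert not net.has_edge("A", "A")
    assert set(net.nodes) == {"A", "B", "C"}


def test_loosening_threshold_never_removes_edges():
    rng = np.random.default_rng(0)
    names = [f"p{i}" for i in range(8)]
    hits = [
        _hit(a, b, 10.0 ** -rng.uniform(0, 120))
        for a, b in itertools.combinations(names, 2)
    ]
    strict = build_network(hits, threshold=1e-40)
    loose = build_network(hits, threshold=1e-20)
    strict_edges = {frozenset(e) for e in strict.edges}
    loose_edges = {frozenset(e) for e in loose.edges}
    assert strict_edges <= loose_edges


def test_disconnected_triangles_are_two_communities():
    hits = [_hit(a, b, 1e-60) for a, b in
            [("A", "B"), ("B", "C"), ("A", "C"), ("X", "Y"), ("Y", "Z"), ("X", "Z")]]
    net = build_network(hits, threshold=1e-40)
    communities, singletons = detect_communities(net, seed=0)
    assert len(communities) == 2
    assert singletons == []
    assert {frozenset(c.members) for c in communities} == {
        frozenset("ABC"), frozenset("XYZ")
    }


def test_empty_edge_set_gives_all_singletons():
    net = build_network([], threshold=1e-40,
                        records=[_rec("A"), _rec("B")])
    communities, singletons = detect_communities(net, seed=0)
    assert communities == []
    assert singletons == ["A", "B"]


def _exhaustive_max_modularity(graph):
    nodes = list(graph.nodes)

    def partitions(seq):
        if len(seq) == 1:
            yield [seq]
            return
        first = seq[0]
        for smaller in partitions(seq[1:]):
            for i, subset in enumerate(smaller):
                yield smaller[:i] + [[first] + subset] + smaller[i + 1:]
            yield [[first]] + smaller

    return max(
        nx.community.modularity(graph, [set(p) for p in part], weight="weight")
        for part in partitions(nodes)
    )


def test_weakly_joined_cliques_split_at_max_modularity():
    """Two 5-cliques joined by one weak edge: Louvain must find the two-clique
    partition, which exhaustive search confirms is the modularity optimum."""
    net = nx.Graph()
    for offset, names in ((0, "ABCDE"), (0, "VWXYZ")):
        for a, b in itertools.combinations(names, 2):
            net.add_edge(a, b, weight=100.0, evalue=1e-100, identity_pct=90.0)
    net.add_edge("A", "V", weight=1.0, evalue=1e-1, identity_pct=20.0)
    communities, _ = detect_communities(net, seed=0)
    assert {frozenset(c.members) for c in communities} == {
        frozenset("ABCDE"), frozenset("VWXYZ")
    }
    partition = [set(c.members) for c in communities]
    q = nx.community.modularity(net, partition, weight="weight")
    assert q == pytest.approx(_exhaustive_max_modularity(net), abs=1e-9)


def test_keratinase_linkage_by_shared_community():
    records = [
        _rec("KER_1", category="functional_keratinase", strain="panel"),
        _rec("Q1"), _rec("Q2"), _rec("Q3"), _rec("Q4"), _rec("Q5"),
        _rec("R1"), _rec("R2"), _rec("S1"), _rec("S2"),
    ]
    hits = []
    linked_block = ["KER_1", "Q1", "Q2", "Q3", "Q4", "Q5"]
    for a, b in itertools.combinations(linked_block, 2):
        hits.append(_hit(a, b, 1e-80))
    hits += [_hit("R1", "R2", 1e-80), _hit("S1", "S2", 1e-80)]
    net = build_network(hits, threshold=1e-40, records=records)
    communities, _ = detect_communities(net, seed=0)
    linkage = link_keratinases(communities, net)
    assert linkage.linked == {"Q1", "Q2", "Q3", "Q4", "Q5"}
    assert linkage.per_strain_counts == {"G11C": 5}
    # best direct hit to a keratinase is recorded
    assert linkage.best_hit["Q1"] == (42.0, 1e-80)


def test_community_without_keratinase_links_nothing():
    records = [_rec("Q1"), _rec("Q2")]
    net = build_network([_hit("Q1", "Q2", 1e-80)], threshold=1e-40,
                        records=records)
    communities, _ = detect_communities(net, seed=0)
    assert link_keratinases(communities, net).linked == set()


def test_direct_edge_mode_is_stricter():
    records = [
        _rec("KER_1", category="functional_keratinase", strain="panel"),
        _rec("Q1"), _rec("Q2"),
    ]
    # Q2 in the same community but only via Q1
    hits = [_hit("KER_1", "Q1", 1e-80), _hit("Q1", "Q2", 1e-80)]
    net = build_network(hits, threshold=1e-40, records=records)
    communities, _ = detect_communities(net, seed=0)
    assert link_keratinases(communities, net, mode="community").linked == {
        "Q1", "Q2"
    }
    assert link_keratinases(communities, net, mode="direct-edge").linked == {
        "Q1"
    }
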