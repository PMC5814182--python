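import networkx as nx
import numpy as np
import pytest

from mpcin.graph import build_junction_graph, detect_chromoplexy
from mpcin.junctions import BreakpointJunction


def J(ca, pa, cb, pb, klass="translocation"):
    return BreakpointJunction(ca, pa, "+", cb, pb, "-", support=10, klass=klass)


def test_single_junction_two_nodes_one_edge():
    g = build_junction_graph([J("1", 100_000, "2", 200_000)], merge_distance=50_000)
    assert g.graph.number_of_nodes() == 2
    assert g.graph.number_of_edges() == 1


def test_shared_breakpoint_merges_loci():
    junctions = [J("1", 100_000, "2", 200_000), J("2", 210_000, "3", 300_000)]
    g = build_junction_graph(junctions, merge_distance=50_000)
    assert g.graph.number_of_nodes() == 3
    assert g.graph.number_of_edges() == 2
    assert nx.is_connected(g.graph)


def _oracle_merge(loci, merge_distance):
    g = nx.Graph()
    g.add_nodes_from(loci)
    for a in loci:
        for b in loci:
            if a[0] == b[0] and abs(a[1] - b[1]) <= merge_distance:
                g.add_edge(a, b)
    return {frozenset(c) for c in nx.connected_components(g)}


@pytest.mark.parametrize("seed", range(6))
def test_locus_merging_matches_brute_force(seed):
    rng = np.random.default_rng(seed)
    junctions = [
        J(str(rng.integers(1, 5)), int(rng.integers(0, 1_000_000)),
          str(rng.integers(1, 5)), int(rng.integers(0, 1_000_000)))
        for _ in range(100)
    ]
    g = build_junction_graph(junctions, merge_distance=50_000)
    loci = {(j.chrom_a, j.pos_a) for j in junctions} | {(j.chrom_b, j.pos_b) for j in junctions}
    oracle = _oracle_merge(sorted(loci), 50_000)
    got: dict[tuple, set] = {}
    for locus, node in g.node_of_locus.items():
        got.setdefault(node, set()).add(locus)
    assert {frozenset(v) for v in got.values()} == oracle


def test_graph_construction_order_invariant_and_idempotent():
    junctions = [J("1", i * 200_000, "2", i * 200_000 + 100) for i in range(5)]
    a = build_junction_graph(junctions, merge_distance=50_000)
    b = build_junction_graph(list(reversed(junctions)), merge_distance=50_000)
    assert set(a.graph.nodes) == set(b.graph.nodes)
    assert a.graph.number_of_edges() == b.graph.number_of_edges()


def test_six_junction_chain_is_one_event():
    """A chain weaving between two chromosomes is exactly one event."""
    junctions = []
    for i in range(6):
        ca, cb = ("5", "14") if i % 2 == 0 else ("14", "5")
        junctions.append(J(ca, 100_000 + (i // 2) * 200_000, cb, 100_000 + ((i + 1) // 2) * 200_000))
    g = build_junction_graph(junctions, merge_distance=50_000)
    events = detect_chromoplexy(g, min_junctions=4)
    assert len(events) == 1
    assert events[0].n_junctions == 6
    assert events[0].n_chromosomes == 2


def test_isolated_junctions_no_event():
    junctions = [J(str(i + 1), 100_000, str((i + 1) % 10 + 1), 800_000) for i in range(10)]
    g = build_junction_graph(junctions, merge_distance=50_000)
    assert detect_chromoplexy(g, min_junctions=4) == []


def test_random_junctions_component_census_matches_oracle():
    """Event count under a null of uniform junctions equals a brute-force
    component census of the merged-locus graph."""
    rng = np.random.default_rng(9)
    chroms = [str(i) for i in range(1, 20)]
    junctions = [
        J(chroms[rng.integers(0, 19)], int(rng.integers(0, 1_000_000)),
          chroms[rng.integers(0, 19)], int(rng.integers(0, 1_000_000)))
        for _ in range(1000)
    ]
    g = build_junction_graph(junctions, merge_distance=50_000)
    events = detect_chromoplexy(g, min_junctions=4)
    # oracle census over the same merged graph
    oracle_events = 0
    for comp in nx.connected_components(g.graph):
        sub = g.graph.subgraph(comp)
        ids = [d["index"] for _, _, d in sub.edges(data=True)]
        chrs = set()
        for i in ids:
            chrs.update((junctions[i].chrom_a, junctions[i].chrom_b))
        if len(ids) >= 4 and len(chrs) >= 2:
            oracle_events += 1
    assert len(events) == oracle_events
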