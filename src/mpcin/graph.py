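"""Chromoplexy detection via a graph of breakpoint junctions.

Breakpoint loci on one chromosome within ``merge_distance`` of one another
are merged (single linkage) into nodes; each junction is an edge between
its two locus nodes. Chromoplexy — a chain of interdependent rearrangements
weaving between chromosomes — surfaces as a connected component with many
edges spanning at least two chromosomes. The criterion (default: >= 4
junctions, >= 2 chromosomes) is an explicit operationalization; copy-number
corroboration at the chain boundaries is reported as an annotation, never
used as a filter.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx

from .cnv import CNVSegment
from .junctions import BreakpointJunction


@dataclass
class JunctionGraph:
    graph: nx.MultiGraph                       # nodes: (chrom, min_pos); edge attr: junction index
    node_of_locus: dict[tuple[str, int], tuple[str, int]]
    junctions: list[BreakpointJunction]


@dataclass
class ChromoplexyEvent:
    junction_ids: tuple[int, ...]
    chromosomes: tuple[str, ...]
    n_junctions: int
    n_chromosomes: int
    cn_boundary_fraction: float | None = field(default=None)


def _merge_loci(loci: list[tuple[str, int]], merge_distance: int) -> dict[tuple[str, int], tuple[str, int]]:
    """1D single-linkage merge per chromosome; node id = (chrom, min pos)."""
    mapping: dict[tuple[str, int], tuple[str, int]] = {}
    by_chrom: dict[str, list[int]] = {}
    for chrom, pos in set(loci):
        by_chrom.setdefault(chrom, []).append(pos)
    for chrom, positions in by_chrom.items():
        positions.sort()
        group_start = positions[0]
        group = [positions[0]]
        for pos in positions[1:]:
            if pos - group[-1] <= merge_distance:
                group.append(pos)
            else:
                for p in group:
                    mapping[(chrom, p)] = (chrom, group_start)
                group_start = pos
                group = [pos]
        for p in group:
            mapping[(chrom, p)] = (chrom, group_start)
    return mapping


def build_junction_graph(junctions: list[BreakpointJunction], merge_distance: int) -> JunctionGraph:
    """Build the breakpoint-locus graph; deterministic and order-invariant."""
    if merge_distance <= 0:
        raise ValueError(f"merge_distance must be positive, got {merge_distance}")
    loci = [(j.chrom_a, j.pos_a) for j in junctions] + [(j.chrom_b, j.pos_b) for j in junctions]
    mapping = _merge_loci(loci, merge_distance)
    graph = nx.MultiGraph()
    graph.add_nodes_from(sorted(set(mapping.values())))
    for i, j in enumerate(junctions):
        a = mapping[(j.chrom_a, j.pos_a)]
        b = mapping[(j.chrom_b, j.pos_b)]
        graph.add_edge(a, b, index=i)
    return JunctionGraph(graph=graph, node_of_locus=mapping, junctions=junctions)


def detect_chromoplexy(
    jgraph: JunctionGraph,
    min_junctions: int = 4,
    segments: list[CNVSegment] | None = None,
    snap_distance: int = 10000,
) -> list[ChromoplexyEvent]:
    """Connected components with >= min_junctions edges on >= 2 chromosomes.

    When classified CNV segments are supplied, each event is annotated with
    the fraction of its breakpoint loci lying within ``snap_distance`` of a
    segment boundary (copy-number corroboration).
    """
    if min_junctions < 3:
        raise ValueError(f"min_junctions must be >= 3, got {min_junctions}")
    boundaries: dict[str, list[int]] = {}
    if segments is not None:
        for s in segments:
            boundaries.setdefault(s.chrom, []).extend((s.start, s.end))
    events: list[ChromoplexyEvent] = []
    for component in nx.connected_components(jgraph.graph):
        sub = jgraph.graph.subgraph(component)
        ids = tuple(sorted(data["index"] for _, _, data in sub.edges(data=True)))
        if len(ids) < min_junctions:
            continue
        chroms = set()
        for i in ids:
            j = jgraph.junctions[i]
            chroms.update((j.chrom_a, j.chrom_b))
        if len(chroms) < 2:
            continue
        annotation = None
        if segments is not None:
            loci = []
            for i in ids:
                j = jgraph.junctions[i]
                loci.extend([(j.chrom_a, j.pos_a), (j.chrom_b, j.pos_b)])
            near = sum(
                1
                for chrom, pos in loci
                if any(abs(pos - b) <= snap_distance for b in boundaries.get(chrom, []))
            )
            annotation = near / len(loci) if loci else 0.0
        events.append(
            ChromoplexyEvent(
                junction_ids=ids,
                chromosomes=tuple(sorted(chroms)),
                n_junctions=len(ids),
                n_chromosomes=len(chroms),
                cn_boundary_fraction=annotation,
            )
        )
    events.sort(key=lambda e: (-e.n_junctions, e.chromosomes))
    return events
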