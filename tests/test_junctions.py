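import networkx as nx
import numpy as np
import pandas as pd
import pytest

from mpcin import evaluate
from mpcin.fragments import MappedFragment, frame_from_fragments
from mpcin.junctions import (
    CONCORDANT,
    DISCORDANT,
    TRANSGENIC,
    call_junctions,
    classify_pair,
    cluster_discordant,
    detect_integration_sites,
    detect_junctions,
)
from mpcin.simulate import (
    Deletion,
    FragmentSimParams,
    Integration,
    Inversion,
    KaryotypePlan,
    TandemDuplication,
    Translocation,
    apply_karyotype,
    simulate_mate_pairs,
)


# ----------------------------------------------------------------------
# pair classification
# ----------------------------------------------------------------------

@pytest.mark.parametrize(
    "end1, end2, expected",
    [
        (("1", 10_000, "+"), ("1", 50_000, "-"), DISCORDANT),   # 40 kb > 30 kb
        (("1", 10_000, "+"), ("2", 10_000, "-"), DISCORDANT),   # interchromosomal
        (("1", 10_000, "+"), ("1", 40_000, "-"), CONCORDANT),   # exactly 30 kb: strict >
        (("1", 10_000, "+"), ("1", 13_000, "-"), CONCORDANT),
        (("huYAP", 100, "+"), ("1", 10_000, "-"), TRANSGENIC),
        (("1", 10_000, "+"), ("muAkt", 100, "-"), TRANSGENIC),
    ],
)
def test_classify_pair_rules(genome, cfg, end1, end2, expected):
    frag = MappedFragment(*end1, *end2, name="f")
    assert classify_pair(frag, genome, cfg) == expected


# ----------------------------------------------------------------------
# clustering
# ----------------------------------------------------------------------

def _random_discordant(rng, genome, n):
    chroms = rng.choice(["1", "2"], size=(n, 2))
    pos = rng.integers(0, 900_000, size=(n, 2))
    strands = rng.choice(["+", "-"], size=(n, 2))
    frags = [
        MappedFragment(chroms[i, 0], int(pos[i, 0]), strands[i, 0],
                       chroms[i, 1], int(pos[i, 1]), strands[i, 1], name=f"r{i}")
        for i in range(n)
    ]
    return frame_from_fragments(frags)


def _oracle_single_linkage(frame, gap):
    """All-pairs single linkage over canonical fragment ends."""
    g = nx.Graph()
    g.add_nodes_from(frame["name"])
    rows = frame.to_dict("records")
    for i, a in enumerate(rows):
        for b in rows[i + 1:]:
            if (
                a["chrom1"] == b["chrom1"]
                and a["strand1"] == b["strand1"]
                and a["chrom2"] == b["chrom2"]
                and a["strand2"] == b["strand2"]
                and abs(a["pos1"] - b["pos1"]) <= gap
                and abs(a["pos2"] - b["pos2"]) <= gap
            ):
                g.add_edge(a["name"], b["name"])
    return {frozenset(c) for c in nx.connected_components(g)}


@pytest.mark.parametrize("seed", range(6))
def test_clustering_matches_brute_force_oracle(genome, cfg, seed):
    rng = np.random.default_rng(seed)
    frame = _random_discordant(rng, genome, 200)
    clusters = cluster_discordant(frame, cfg.cluster_gap, genome)
    got = {frozenset(c["name"]) for c in clusters}
    from mpcin.fragments import canonicalize
    assert got == _oracle_single_linkage(canonicalize(frame, genome), cfg.cluster_gap)


def test_clustering_order_invariant(genome, cfg, rng):
    frame = _random_discordant(rng, genome, 150)
    shuffled = frame.sample(frac=1.0, random_state=5).reset_index(drop=True)
    a = {frozenset(c["name"]) for c in cluster_discordant(frame, cfg.cluster_gap, genome)}
    b = {frozenset(c["name"]) for c in cluster_discordant(shuffled, cfg.cluster_gap, genome)}
    assert a == b


def test_two_groups_beyond_gap_split(genome, cfg):
    frags = [
        MappedFragment("1", 100_000 + i * 100, "+", "2", 500_000 + i * 100, "-", name=f"a{i}")
        for i in range(5)
    ] + [
        MappedFragment("1", 100_000 + cfg.cluster_gap + 10_000 + i * 100, "+", "2", 500_000 + i * 100, "-", name=f"b{i}")
        for i in range(5)
    ]
    clusters = cluster_discordant(frame_from_fragments(frags), cfg.cluster_gap, genome)
    assert sorted(len(c) for c in clusters) == [5, 5]


# ----------------------------------------------------------------------
# junction calling
# ----------------------------------------------------------------------

def test_min_support_filters_small_clusters(genome, cfg):
    frags = [
        MappedFragment("1", 100_000 + i, "+", "2", 500_000 + i, "-", name=f"f{i}")
        for i in range(2)
    ]
    clusters = cluster_discordant(frame_from_fragments(frags), cfg.cluster_gap, genome)
    assert call_junctions(clusters, min_support=3, genome=genome) == []


@pytest.mark.parametrize(
    "event, expected_classes",
    [
        (Deletion("1", 300_000, 400_000), ["deletion"]),
        (TandemDuplication("2", 300_000, 420_000), ["gain"]),
        (Translocation("5", 400_000, "6", 300_000), ["translocation"]),
        (Inversion("3", 200_000, 300_000), ["inversion", "inversion"]),
    ],
)
def test_planted_event_recovered_with_correct_class(genome, cfg, event, expected_classes):
    derived, truth = apply_karyotype(genome, KaryotypePlan(events=[event]))
    frags = simulate_mate_pairs(derived, FragmentSimParams(noise_rate=0.0, seed=77))
    detected = detect_junctions(frags, genome, cfg)
    assert sorted(j.klass for j in detected) == sorted(expected_classes)
    match = evaluate.match_junctions(detected, truth, tolerance=cfg.median_insert)
    assert match.recovery == 1.0
    errors = evaluate.breakpoint_errors(detected, truth, match)
    assert max(errors) <= cfg.median_insert


def test_junction_set_invariant_to_fragment_order(genome, cfg):
    derived, _ = apply_karyotype(
        genome, KaryotypePlan(events=[Deletion("1", 300_000, 400_000)])
    )
    frags = simulate_mate_pairs(derived, FragmentSimParams(noise_rate=0.0, seed=78))
    shuffled = frags.sample(frac=1.0, random_state=3).reset_index(drop=True)
    a = detect_junctions(frags, genome, cfg)
    b = detect_junctions(shuffled, genome, cfg)
    assert [(j.locus_a, j.locus_b, j.klass, j.support) for j in a] == [
        (j.locus_a, j.locus_b, j.klass, j.support) for j in b
    ]


# ----------------------------------------------------------------------
# integration sites
# ----------------------------------------------------------------------

def test_planted_integration_sites_recovered(genome, cfg):
    plan = KaryotypePlan(
        events=[Integration("huYAP", "3", 600_000), Integration("muAkt", "1", 200_000)]
    )
    derived, truth = apply_karyotype(genome, plan)
    frags = simulate_mate_pairs(derived, FragmentSimParams(noise_rate=0.0, seed=80))
    result = detect_integration_sites(frags, genome, cfg)
    assert len(result.sites) == 2
    matched, missed, extra = evaluate.match_integration_sites(
        result.sites, truth, tolerance=cfg.median_insert
    )
    assert missed == [] and extra == []


def test_no_transgenic_fragments_no_sites(diploid_fragments, genome, cfg):
    result = detect_integration_sites(diploid_fragments, genome, cfg)
    assert result.sites == []


def test_two_distant_integrations_give_two_sites(genome, cfg):
    plan = KaryotypePlan(
        events=[Integration("huYAP", "3", 200_000), Integration("huYAP", "3", 700_000)]
    )
    derived, _ = apply_karyotype(genome, plan)
    frags = simulate_mate_pairs(derived, FragmentSimParams(noise_rate=0.0, seed=81))
    result = detect_integration_sites(frags, genome, cfg)
    assert len(result.sites) == 2


def test_transgene_only_fragments_counted_not_sited(genome, cfg):
    frags = frame_from_fragments(
        [MappedFragment("huYAP", 10, "+", "muAkt", 10, "-", name="t1")] * 1
    )
    result = detect_integration_sites(frags, genome, cfg)
    assert result.sites == [] and result.n_transgene_only == 1
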