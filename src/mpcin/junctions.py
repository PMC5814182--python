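"""Breakpoint-junction detection from discordant mate-pair fragments.

A fragment whose ends map to different chromosomes, or more than the
discordance distance apart on one chromosome (strictly greater than 30 kb
by default), points at a structural rearrangement. Discordant fragments are
clustered by single linkage — two fragments link when both end-1 and end-2
loci share chromosome and strand and lie within ``cluster_gap`` — and each
sufficiently supported cluster becomes one breakpoint junction, classified
from the strand pattern:

* ``(+,-)`` innie but too far apart: sequence between the ends was removed
  — **deletion**;
* ``(-,+)`` outie: the signature of a tandem duplication — **gain**;
* ``(+,+)`` / ``(-,-)``: one side inverted — **inversion**;
* different chromosomes: **translocation**.

Fragments with an end on a transgene contig (huYAP/muAkt analogues) are set
aside and clustered per transgene into integration sites.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import TYPE_CHECKING

import numpy as np
import pandas as pd

from .config import RunConfig
from .fragments import MappedFragment, canonicalize

if TYPE_CHECKING:  # pragma: no cover
    from .simulate.genome import GenomeModel

CONCORDANT = "concordant"
DISCORDANT = "discordant"
TRANSGENIC = "transgenic"

DELETION = "deletion"
INVERSION = "inversion"
GAIN = "gain"
TRANSLOCATION = "translocation"


@dataclass(frozen=True)
class BreakpointJunction:
    """A clustered set of discordant fragments fusing two loci."""

    chrom_a: str
    pos_a: int
    orient_a: str
    chrom_b: str
    pos_b: int
    orient_b: str
    support: int
    klass: str
    member_ids: tuple[str, ...] = ()

    @property
    def locus_a(self) -> tuple[str, int, str]:
        return (self.chrom_a, self.pos_a, self.orient_a)

    @property
    def locus_b(self) -> tuple[str, int, str]:
        return (self.chrom_b, self.pos_b, self.orient_b)


@dataclass(frozen=True)
class IntegrationSite:
    transgene: str
    chrom: str
    pos: int
    support: int


@dataclass
class IntegrationResult:
    sites: list[IntegrationSite] = field(default_factory=list)
    n_transgene_only: int = 0  # fragments with both ends on transgenes


def junction_class(chrom_a: str, orient_a: str, chrom_b: str, orient_b: str) -> str:
    """Junction class from canonical-ordered loci orientations."""
    if chrom_a != chrom_b:
        return TRANSLOCATION
    if orient_a == orient_b:
        return INVERSION
    if orient_a == "+" and orient_b == "-":
        return DELETION
    return GAIN


# ----------------------------------------------------------------------
# classification
# ----------------------------------------------------------------------

def classify_fragments(frame: pd.DataFrame, genome: GenomeModel, cfg: RunConfig) -> pd.Series:
    """Vectorized fragment triage: concordant / discordant / transgenic.

    Every fragment lands in exactly one category.
    """
    tg = set(genome.transgenes)
    is_tg = frame["chrom1"].isin(tg) | frame["chrom2"].isin(tg)
    interchrom = frame["chrom1"].to_numpy() != frame["chrom2"].to_numpy()
    far = np.abs(frame["pos1"].to_numpy() - frame["pos2"].to_numpy()) > cfg.discordance_distance
    out = np.where(is_tg, TRANSGENIC, np.where(interchrom | far, DISCORDANT, CONCORDANT))
    return pd.Series(out, index=frame.index, name="category")


def classify_pair(fragment: MappedFragment, genome: GenomeModel, cfg: RunConfig) -> str:
    """Classify one fragment (see :func:`classify_fragments`)."""
    genome.validate_locus(fragment.chrom1, fragment.pos1)
    genome.validate_locus(fragment.chrom2, fragment.pos2)
    if genome.is_transgene(fragment.chrom1) or genome.is_transgene(fragment.chrom2):
        return TRANSGENIC
    if fragment.chrom1 != fragment.chrom2:
        return DISCORDANT
    if abs(fragment.pos1 - fragment.pos2) > cfg.discordance_distance:
        return DISCORDANT
    return CONCORDANT


# ----------------------------------------------------------------------
# clustering
# ----------------------------------------------------------------------

class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[rj] = ri


def cluster_discordant(frame: pd.DataFrame, cluster_gap: int, genome: GenomeModel) -> list[pd.DataFrame]:
    """Single-linkage clustering of discordant fragments.

    Two fragments link iff both sides agree on chromosome and strand and
    both position gaps are <= ``cluster_gap``. The result is independent of
    the input row order; clusters are returned sorted by their leftmost
    canonical loci.
    """
    if cluster_gap <= 0:
        raise ValueError(f"cluster_gap must be positive, got {cluster_gap}")
    frame = canonicalize(frame, genome)
    clusters: list[pd.DataFrame] = []
    keys = ["chrom1", "strand1", "chrom2", "strand2"]
    for _, group in frame.groupby(keys, sort=True):
        group = group.sort_values(["pos1", "pos2", "name"], kind="mergesort")
        p1 = group["pos1"].to_numpy()
        p2 = group["pos2"].to_numpy()
        n = len(group)
        uf = _UnionFind(n)
        for i in range(n):
            j = i + 1
            while j < n and p1[j] - p1[i] <= cluster_gap:
                if abs(p2[j] - p2[i]) <= cluster_gap:
                    uf.union(i, j)
                j += 1
        roots: dict[int, list[int]] = {}
        for i in range(n):
            roots.setdefault(uf.find(i), []).append(i)
        for members in roots.values():
            clusters.append(group.iloc[members])
    clusters.sort(
        key=lambda c: (
            c["chrom1"].iat[0],
            int(c["pos1"].min()),
            c["chrom2"].iat[0],
            int(c["pos2"].min()),
        )
    )
    return clusters


# ----------------------------------------------------------------------
# junction calling
# ----------------------------------------------------------------------

def _breakpoint(positions: np.ndarray, strand: str) -> int:
    """Innermost fragment end given the side's strand.

    Under the innie convention a '+' end lies upstream of the fused locus,
    so the innermost (largest) position bounds the breakpoint from the
    left; a '-' end lies downstream and the smallest position bounds it
    from the right.
    """
    return int(positions.max()) if strand == "+" else int(positions.min())


def call_junctions(
    clusters: list[pd.DataFrame],
    min_support: int,
    genome: GenomeModel,
    expected_orientation: str = "innie",
) -> list[BreakpointJunction]:
    """Turn fragment clusters into classified breakpoint junctions.

    Clusters with fewer than ``min_support`` fragments are dropped. The
    strand-pattern class rules above assume the innie concordant
    convention; for an outie library the strands are flipped first.
    """
    junctions: list[BreakpointJunction] = []
    for cluster in clusters:
        if len(cluster) < min_support:
            continue
        chrom_a = cluster["chrom1"].iat[0]
        chrom_b = cluster["chrom2"].iat[0]
        strand_a = cluster["strand1"].iat[0]
        strand_b = cluster["strand2"].iat[0]
        if cluster["chrom1"].nunique() > 1 or cluster["chrom2"].nunique() > 1:
            raise AssertionError("cluster with mixed chromosomes on one side")
        sa, sb = strand_a, strand_b
        if expected_orientation == "outie":
            flip = {"+": "-", "-": "+"}
            sa, sb = flip[sa], flip[sb]
        junctions.append(
            BreakpointJunction(
                chrom_a=chrom_a,
                pos_a=_breakpoint(cluster["pos1"].to_numpy(), strand_a),
                orient_a=strand_a,
                chrom_b=chrom_b,
                pos_b=_breakpoint(cluster["pos2"].to_numpy(), strand_b),
                orient_b=strand_b,
                support=len(cluster),
                klass=junction_class(chrom_a, sa, chrom_b, sb),
                member_ids=tuple(sorted(cluster["name"].astype(str))),
            )
        )
    rank = genome.rank
    junctions.sort(key=lambda j: (rank[j.chrom_a], j.pos_a, rank[j.chrom_b], j.pos_b))
    return junctions


def detect_junctions(frame: pd.DataFrame, genome: GenomeModel, cfg: RunConfig) -> list[BreakpointJunction]:
    """classify -> cluster -> call in one step (discordant fragments only)."""
    cat = classify_fragments(frame, genome, cfg)
    disc = frame.loc[cat == DISCORDANT]
    clusters = cluster_discordant(disc, cfg.cluster_gap, genome)
    return call_junctions(clusters, cfg.min_support, genome, cfg.expected_orientation)


# ----------------------------------------------------------------------
# transgene integration sites
# ----------------------------------------------------------------------

def detect_integration_sites(
    frame: pd.DataFrame, genome: GenomeModel, cfg: RunConfig
) -> IntegrationResult:
    """Cluster the genomic ends of transgenic fragments into sites.

    Position is the median genomic end of the cluster; clusters below
    ``min_support`` are dropped. Fragments with both ends on transgene
    contigs are counted separately and never yield a genomic site.
    """
    tg = set(genome.transgenes)
    if frame.empty:
        return IntegrationResult()
    tg1 = frame["chrom1"].isin(tg).to_numpy()
    tg2 = frame["chrom2"].isin(tg).to_numpy()
    both = tg1 & tg2
    result = IntegrationResult(n_transgene_only=int(both.sum()))
    one = (tg1 ^ tg2)
    sub = frame.loc[one]
    if sub.empty:
        return result
    tname = np.where(sub["chrom1"].isin(tg), sub["chrom1"], sub["chrom2"])
    gchrom = np.where(sub["chrom1"].isin(tg), sub["chrom2"], sub["chrom1"])
    gpos = np.where(sub["chrom1"].isin(tg), sub["pos2"], sub["pos1"]).astype(np.int64)
    table = pd.DataFrame({"transgene": tname, "chrom": gchrom, "pos": gpos})
    sites: list[IntegrationSite] = []
    for (transgene, chrom), group in table.groupby(["transgene", "chrom"], sort=True):
        pos = np.sort(group["pos"].to_numpy())
        breaks = np.flatnonzero(np.diff(pos) > cfg.cluster_gap)
        start = 0
        for stop in list(breaks + 1) + [len(pos)]:
            chunk = pos[start:stop]
            start = stop
            if len(chunk) >= cfg.min_support:
                sites.append(
                    IntegrationSite(
                        transgene=str(transgene),
                        chrom=str(chrom),
                        pos=int(np.median(chunk)),
                        support=int(len(chunk)),
                    )
                )
    rank = genome.rank
    sites.sort(key=lambda s: (s.transgene, rank[s.chrom], s.pos))
    result.sites = sites
    return result


def junctions_to_frame(junctions: list[BreakpointJunction]) -> pd.DataFrame:
    """Flat junction table (TSV-ready)."""
    return pd.DataFrame(
        [
            {
                "chromA": j.chrom_a,
                "posA": j.pos_a,
                "orientA": j.orient_a,
                "chromB": j.chrom_b,
                "posB": j.pos_b,
                "orientB": j.orient_b,
                "class": j.klass,
                "support": j.support,
            }
            for j in junctions
        ],
        columns=["chromA", "posA", "orientA", "chromB", "posB", "orientB", "class", "support"],
    )
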