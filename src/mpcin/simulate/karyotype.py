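"""Karyotype plans: planted rearrangements with a machine-readable truth set.

A plan is a list of events — whole/partial chromosome gains and losses,
deletions, inversions, tandem duplications, translocations, chromoplexy
chains and transgene integrations. Applying a plan to a genome yields a
derived-genome description (a per-region copy-multiplicity map plus a
fusion adjacency list) and a TruthSet recording every planted event, which
downstream recovery tests compare detections against.

Copy-number conventions: autosomes start at 2 copies, allosomes at the
genome's expected baseline (1 for male X/Y). ``whole_gain`` adds one copy,
``whole_loss`` removes one; a deletion event drops one copy over its span
and adds the fusion junction; a tandem duplication adds one copy and the
outie-signature junction; inversions are copy-neutral with two junctions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Union

from .genome import GenomeModel

# A breakpoint locus: (chrom, pos, orient). orient '+' keeps the sequence
# upstream (left) of pos at the fusion; '-' keeps the downstream side.
Locus = tuple[str, int, str]
Fusion = tuple[Locus, Locus]


@dataclass(frozen=True)
class WholeGain:
    chrom: str


@dataclass(frozen=True)
class WholeLoss:
    chrom: str


@dataclass(frozen=True)
class PartialCNV:
    chrom: str
    start: int
    end: int
    copies: int


@dataclass(frozen=True)
class Deletion:
    chrom: str
    start: int
    end: int


@dataclass(frozen=True)
class Inversion:
    chrom: str
    start: int
    end: int


@dataclass(frozen=True)
class TandemDuplication:
    chrom: str
    start: int
    end: int


@dataclass(frozen=True)
class Translocation:
    chrom_a: str
    pos_a: int
    chrom_b: str
    pos_b: int


@dataclass(frozen=True)
class Chromoplexy:
    fusions: tuple[Fusion, ...]

    def __post_init__(self) -> None:
        if len(self.fusions) < 4:
            raise ValueError("chromoplexy requires >= 4 breakpoint fusions")
        chroms = {loc[0] for fusion in self.fusions for loc in fusion}
        if len(chroms) < 2:
            raise ValueError("chromoplexy must involve >= 2 distinct chromosomes")


@dataclass(frozen=True)
class Integration:
    transgene: str
    chrom: str
    pos: int


Event = Union[
    WholeGain,
    WholeLoss,
    PartialCNV,
    Deletion,
    Inversion,
    TandemDuplication,
    Translocation,
    Chromoplexy,
    Integration,
]


@dataclass
class KaryotypePlan:
    events: list[Event] = field(default_factory=list)
    seed: int = 0


@dataclass
class TruthSet:
    """Planted ground truth; coordinates 0-based half-open."""

    cn_segments: list[tuple[str, int, int, int]] = field(default_factory=list)
    junctions: list[tuple[Locus, Locus, str]] = field(default_factory=list)
    integration_sites: list[tuple[str, str, int]] = field(default_factory=list)
    chromoplexy_components: list[tuple[int, ...]] = field(default_factory=list)
    expression_effects: dict[str, float] = field(default_factory=dict)


@dataclass
class DerivedGenome:
    """Copy-multiplicity map + fusion list describing a rearranged genome."""

    genome: GenomeModel
    cn: dict[str, list[tuple[int, int, int]]]  # chrom -> [(start, end, copies)]
    fusions: list[Fusion]
    integrations: list[tuple[str, str, int]]  # (transgene, chrom, pos)

    def copies_at(self, chrom: str, pos: int) -> int:
        for start, end, copies in self.cn[chrom]:
            if start <= pos < end:
                return copies
        raise ValueError(f"position {pos} not covered on {chrom!r}")


def _canonical_fusion(genome: GenomeModel, fusion: Fusion) -> Fusion:
    rank = genome.rank
    a, b = fusion
    if (rank[a[0]], a[1]) <= (rank[b[0]], b[1]):
        return (a, b)
    return (b, a)


def _truth_junction(genome: GenomeModel, fusion: Fusion) -> tuple[Locus, Locus, str]:
    from ..junctions import junction_class  # deferred: avoids an import cycle

    a, b = _canonical_fusion(genome, fusion)
    return (a, b, junction_class(a[0], a[2], b[0], b[2]))


def chromoplexy_chain(
    chroms: tuple[str, ...],
    genome: GenomeModel,
    n_junctions: int = 6,
    seed: int = 0,
    margin: int = 100_000,
    jitter: int = 10_000,
) -> Chromoplexy:
    """Build a weaving chain of fusions alternating between chromosomes.

    Consecutive fusions share an anchor region (within ``jitter`` bases) so
    the chain forms a single connected component in the junction graph;
    distinct anchors are spaced widely enough that every fusion is
    independently detectable as a discordant-pair junction.
    """
    import numpy as np

    rng = np.random.default_rng(seed)
    anchors: list[tuple[str, int]] = []
    for i in range(n_junctions + 1):
        chrom = chroms[i % len(chroms)]
        length = genome.lengths[chrom]
        lo = margin + (i // len(chroms)) * (length - 2 * margin) // (n_junctions // len(chroms) + 1)
        anchors.append((chrom, int(lo + rng.integers(0, max(jitter, 1)))))
    fusions: list[Fusion] = []
    for i in range(n_junctions):
        ca, pa = anchors[i]
        cb, pb = anchors[i + 1]
        ja = int(pa + rng.integers(-jitter, jitter + 1))
        jb = int(pb + rng.integers(-jitter, jitter + 1))
        ja = min(max(ja, 1), genome.lengths[ca] - 2)
        jb = min(max(jb, 1), genome.lengths[cb] - 2)
        oa = "+" if rng.random() < 0.5 else "-"
        ob = "+" if rng.random() < 0.5 else "-"
        fusions.append(((ca, ja, oa), (cb, jb, ob)))
    return Chromoplexy(fusions=tuple(fusions))


def _check_span(event, start: int, end: int, min_span: int | None) -> None:
    if end <= start:
        raise ValueError(f"{type(event).__name__} span [{start},{end}) is empty")
    if min_span is not None and end - start <= min_span:
        raise ValueError(
            f"{type(event).__name__} span {end - start} must exceed the "
            f"discordance threshold ({min_span}) to be detectable"
        )


def apply_karyotype(
    genome: GenomeModel,
    plan: KaryotypePlan,
    min_sv_span: int | None = 30000,
) -> tuple[DerivedGenome, TruthSet]:
    """Apply a plan, returning the derived genome description and truth set.

    Copy-number events must not overlap one another on a chromosome
    (contradictory copy assignments are rejected). ``min_sv_span`` enforces
    that planted deletions/duplications are wide enough for the discordant
    junction rule; pass ``None`` to disable (depth-only events).
    """
    baseline = dict(genome.expected_copies)
    cn_events: dict[str, list[tuple[int, int, int]]] = {c: [] for c in genome.genomic_chromosomes}
    fusions: list[Fusion] = []
    integrations: list[tuple[str, str, int]] = []
    truth = TruthSet()
    chromoplexy_groups: list[list[Fusion]] = []

    def check_locus(chrom: str, pos: int) -> None:
        genome.validate_locus(chrom, pos)
        if genome.is_transgene(chrom):
            raise ValueError(f"breakpoint on transgene contig {chrom!r}")

    for event in plan.events:
        if isinstance(event, WholeGain):
            check_locus(event.chrom, 0)
            L = genome.lengths[event.chrom]
            cn_events[event.chrom].append((0, L, baseline[event.chrom] + 1))
        elif isinstance(event, WholeLoss):
            check_locus(event.chrom, 0)
            L = genome.lengths[event.chrom]
            if baseline[event.chrom] - 1 < 0:
                raise ValueError(f"cannot lose a copy of {event.chrom!r} below zero")
            cn_events[event.chrom].append((0, L, baseline[event.chrom] - 1))
        elif isinstance(event, PartialCNV):
            check_locus(event.chrom, event.start)
            check_locus(event.chrom, event.end - 1)
            _check_span(event, event.start, event.end, None)
            if event.copies < 0:
                raise ValueError("copies must be >= 0")
            cn_events[event.chrom].append((event.start, event.end, event.copies))
        elif isinstance(event, Deletion):
            check_locus(event.chrom, event.start)
            check_locus(event.chrom, event.end - 1)
            _check_span(event, event.start, event.end, min_sv_span)
            cn_events[event.chrom].append((event.start, event.end, baseline[event.chrom] - 1))
            fusions.append(((event.chrom, event.start, "+"), (event.chrom, event.end, "-")))
        elif isinstance(event, TandemDuplication):
            check_locus(event.chrom, event.start)
            check_locus(event.chrom, event.end - 1)
            _check_span(event, event.start, event.end, min_sv_span)
            cn_events[event.chrom].append((event.start, event.end, baseline[event.chrom] + 1))
            fusions.append(((event.chrom, event.end, "+"), (event.chrom, event.start, "-")))
        elif isinstance(event, Inversion):
            check_locus(event.chrom, event.start)
            check_locus(event.chrom, event.end - 1)
            _check_span(event, event.start, event.end, min_sv_span)
            fusions.append(((event.chrom, event.start, "+"), (event.chrom, event.end, "+")))
            fusions.append(((event.chrom, event.start, "-"), (event.chrom, event.end, "-")))
        elif isinstance(event, Translocation):
            check_locus(event.chrom_a, event.pos_a)
            check_locus(event.chrom_b, event.pos_b)
            if event.chrom_a == event.chrom_b:
                raise ValueError("translocation requires two distinct chromosomes")
            fusions.append(((event.chrom_a, event.pos_a, "+"), (event.chrom_b, event.pos_b, "-")))
        elif isinstance(event, Chromoplexy):
            group: list[Fusion] = []
            for fusion in event.fusions:
                for chrom, pos, orient in fusion:
                    check_locus(chrom, pos)
                    if orient not in ("+", "-"):
                        raise ValueError(f"bad fusion orientation {orient!r}")
                fusions.append(fusion)
                group.append(fusion)
            chromoplexy_groups.append(group)
        elif isinstance(event, Integration):
            if event.transgene not in genome.transgenes:
                raise ValueError(f"{event.transgene!r} is not a declared transgene contig")
            check_locus(event.chrom, event.pos)
            integrations.append((event.transgene, event.chrom, event.pos))
        else:  # pragma: no cover - exhaustive by construction
            raise TypeError(f"unknown event type {type(event).__name__}")

    # copy-number map: reject contradictory overlaps, then tile each chromosome
    cn: dict[str, list[tuple[int, int, int]]] = {}
    for chrom in genome.genomic_chromosomes:
        events = sorted(cn_events[chrom])
        for (s1, e1, c1), (s2, e2, c2) in zip(events, events[1:]):
            if s2 < e1:
                raise ValueError(
                    f"overlapping copy-number events on {chrom!r}: "
                    f"[{s1},{e1})={c1} vs [{s2},{e2})={c2}"
                )
        tiles: list[tuple[int, int, int]] = []
        cursor = 0
        L = genome.lengths[chrom]
        for s, e, c in events:
            if cursor < s:
                tiles.append((cursor, s, baseline[chrom]))
            tiles.append((s, e, c))
            cursor = e
        if cursor < L:
            tiles.append((cursor, L, baseline[chrom]))
        # merge adjacent equal-copy tiles
        merged: list[tuple[int, int, int]] = []
        for tile in tiles:
            if merged and merged[-1][2] == tile[2] and merged[-1][1] == tile[0]:
                merged[-1] = (merged[-1][0], tile[1], tile[2])
            else:
                merged.append(tile)
        cn[chrom] = merged

    derived = DerivedGenome(genome=genome, cn=cn, fusions=fusions, integrations=integrations)

    truth.cn_segments = [
        (chrom, s, e, c) for chrom in genome.genomic_chromosomes for s, e, c in cn[chrom]
    ]
    truth.junctions = [_truth_junction(genome, f) for f in fusions]
    truth.integration_sites = list(integrations)
    for group in chromoplexy_groups:
        idx = tuple(sorted(fusions.index(f) for f in group))
        truth.chromoplexy_components.append(idx)
    return derived, truth


def truth_from_derived(derived: DerivedGenome) -> TruthSet:
    """Reconstruct the (junction/CN) truth directly from a derived genome.

    Chromoplexy grouping and expression effects are plan-level annotations
    and are not recoverable from the bare derived description.
    """
    genome = derived.genome
    truth = TruthSet()
    truth.cn_segments = [
        (chrom, s, e, c) for chrom in genome.genomic_chromosomes for s, e, c in derived.cn[chrom]
    ]
    truth.junctions = [_truth_junction(genome, f) for f in derived.fusions]
    truth.integration_sites = list(derived.integrations)
    return truth
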