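"""Truth-set comparison: recovery scoring of detections against a plan.

Used by the report's truth-comparison block and by parameter-recovery
tests: planted junctions are matched to detections by class and breakpoint
proximity, chromosome-level aneuploidy calls are compared against the calls
implied by the planted copy-number segments, and integration sites are
matched within an insert-size tolerance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .cnv import (
    ChromosomeCall,
    CNVSegment,
    classify_segments,
    summarize_chromosomes,
)
from .junctions import BreakpointJunction, IntegrationSite
from .simulate.genome import GenomeModel
from .simulate.karyotype import TruthSet


@dataclass
class JunctionMatch:
    matched: list[tuple[int, int]] = field(default_factory=list)  # (truth idx, detected idx)
    unmatched_truth: list[int] = field(default_factory=list)
    unmatched_detected: list[int] = field(default_factory=list)

    @property
    def recovery(self) -> float:
        total = len(self.matched) + len(self.unmatched_truth)
        return len(self.matched) / total if total else 1.0


def match_junctions(
    detected: list[BreakpointJunction],
    truth: TruthSet,
    tolerance: float,
    require_class: bool = True,
) -> JunctionMatch:
    """Greedy one-to-one matching of truth junctions to detections.

    A detection matches a truth junction when both canonical loci agree on
    chromosome within ``tolerance`` bases (and on class, unless disabled).
    """
    result = JunctionMatch()
    used: set[int] = set()
    for t_idx, (locus_a, locus_b, klass) in enumerate(truth.junctions):
        best = None
        best_err = None
        for d_idx, j in enumerate(detected):
            if d_idx in used:
                continue
            if require_class and j.klass != klass:
                continue
            if j.chrom_a != locus_a[0] or j.chrom_b != locus_b[0]:
                continue
            err = max(abs(j.pos_a - locus_a[1]), abs(j.pos_b - locus_b[1]))
            if err <= tolerance and (best_err is None or err < best_err):
                best, best_err = d_idx, err
        if best is None:
            result.unmatched_truth.append(t_idx)
        else:
            used.add(best)
            result.matched.append((t_idx, best))
    result.unmatched_detected = [i for i in range(len(detected)) if i not in used]
    return result


def breakpoint_errors(
    detected: list[BreakpointJunction], truth: TruthSet, match: JunctionMatch
) -> list[float]:
    errors = []
    for t_idx, d_idx in match.matched:
        locus_a, locus_b, _ = truth.junctions[t_idx]
        j = detected[d_idx]
        errors.append(max(abs(j.pos_a - locus_a[1]), abs(j.pos_b - locus_b[1])))
    return errors


def expected_calls_from_truth(
    truth: TruthSet,
    genome: GenomeModel,
    gain_cutoff: float = 2.5,
    loss_cutoff: float = 1.5,
    whole_fraction: float = 0.95,
    partial_min_fraction: float = 0.05,
) -> list[ChromosomeCall]:
    """Chromosome calls implied by the planted copy-number segments.

    Runs the same classification/summary logic on noise-free truth
    segments, so a detected heat-map table can be compared cell by cell.
    """
    segments = [
        CNVSegment(
            chrom=chrom,
            start=start,
            end=end,
            cn_mean=float(copies),
            n_bins=max(1, round((end - start) / genome.bin_size)),
        )
        for chrom, start, end, copies in truth.cn_segments
    ]
    classified = classify_segments(
        segments, gain_cutoff=gain_cutoff, loss_cutoff=loss_cutoff, expected=genome.expected_copies
    )
    return summarize_chromosomes(
        classified, whole_fraction=whole_fraction, partial_min_fraction=partial_min_fraction
    )


def match_integration_sites(
    detected: list[IntegrationSite], truth: TruthSet, tolerance: float
) -> tuple[list[tuple[int, int]], list[int], list[int]]:
    """Match detected sites to planted integrations within ``tolerance``."""
    matched: list[tuple[int, int]] = []
    used: set[int] = set()
    unmatched_truth: list[int] = []
    for t_idx, (transgene, chrom, pos) in enumerate(truth.integration_sites):
        best = None
        best_err = None
        for d_idx, site in enumerate(detected):
            if d_idx in used or site.transgene != transgene or site.chrom != chrom:
                continue
            err = abs(site.pos - pos)
            if err <= tolerance and (best_err is None or err < best_err):
                best, best_err = d_idx, err
        if best is None:
            unmatched_truth.append(t_idx)
        else:
            used.add(best)
            matched.append((t_idx, best))
    unmatched_detected = [i for i in range(len(detected)) if i not in used]
    return matched, unmatched_truth, unmatched_detected
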