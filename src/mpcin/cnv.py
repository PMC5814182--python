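"""Read-depth copy-number analysis: binning, normalization, segmentation.

Fragment-end starts are counted in 1 kb windows, corrected for GC content
(median-of-stratum scaling), normalized against a panel of normal samples
(per-bin median ratio) onto the 2N copy-number scale, segmented with a
sliding-window Welch-z changepoint scan, refined with breakpoint-junction
positions, classified gain/normal/loss against cutoffs midway between
integer copy states, and finally summarized per chromosome as whole/partial
aneuploidy calls (the machine twin of a per-sample karyotype heat map).

Allosomes are handled with a configured expected baseline (1 copy each for
the male default): their cn values are reported on the true copy scale, and
gain/loss cutoffs shift with the baseline.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from typing import TYPE_CHECKING

import numpy as np
import pandas as pd

from .junctions import BreakpointJunction

if TYPE_CHECKING:  # pragma: no cover
    from .config import RunConfig
    from .simulate.genome import GenomeModel

log = logging.getLogger("mpcin")

GAIN = "gain"
NORMAL = "normal"
LOSS = "loss"

WHOLE_GAIN = "whole_gain"
WHOLE_LOSS = "whole_loss"
PARTIAL_GAIN = "partial_gain"
PARTIAL_LOSS = "partial_loss"
MIXED = "mixed"

_GC_STRATUM_WIDTH = 0.02
_GC_MIN_STRATUM_BINS = 50


@dataclass
class CopyNumberTrack:
    """Per-chromosome binned depth arrays on a fixed genome/binning."""

    bin_size: int
    chroms: list[str]
    lengths: dict[str, int]
    raw: dict[str, np.ndarray]
    gc: dict[str, np.ndarray]
    mask: dict[str, np.ndarray]          # assayable flag
    cn: dict[str, np.ndarray]            # normalized 2N-scale estimate (nan before panel step)
    expected: dict[str, float]           # baseline copies per chromosome

    @property
    def autosomes(self) -> list[str]:
        return [c for c in self.chroms if self.expected[c] == 2]

    def n_bins(self, chrom: str) -> int:
        return len(self.raw[chrom])

    def concat(self, which: str, chroms: list[str] | None = None) -> np.ndarray:
        data = getattr(self, which)
        return np.concatenate([data[c] for c in (chroms or self.chroms)])

    def copy(self) -> "CopyNumberTrack":
        return CopyNumberTrack(
            bin_size=self.bin_size,
            chroms=list(self.chroms),
            lengths=dict(self.lengths),
            raw={c: v.copy() for c, v in self.raw.items()},
            gc={c: v.copy() for c, v in self.gc.items()},
            mask={c: v.copy() for c, v in self.mask.items()},
            cn={c: v.copy() for c, v in self.cn.items()},
            expected=dict(self.expected),
        )

    def same_binning(self, other: "CopyNumberTrack") -> bool:
        return (
            self.bin_size == other.bin_size
            and self.chroms == other.chroms
            and all(self.n_bins(c) == other.n_bins(c) for c in self.chroms)
        )

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for chrom in self.chroms:
            nb = self.n_bins(chrom)
            rows.append(
                pd.DataFrame(
                    {
                        "chrom": chrom,
                        "start": np.arange(nb) * self.bin_size,
                        "raw": self.raw[chrom],
                        "gc": np.round(self.gc[chrom], 6),
                        "cn": np.round(self.cn[chrom], 4),
                        "mask": self.mask[chrom].astype(int),
                    }
                )
            )
        return pd.concat(rows, ignore_index=True)


@dataclass
class CNVSegment:
    chrom: str
    start: int          # bases, half-open
    end: int
    cn_mean: float
    n_bins: int
    klass: str | None = None
    junction_supported: bool = False


@dataclass(frozen=True)
class ChromosomeCall:
    chrom: str
    call: str
    variant_fraction: float


# ----------------------------------------------------------------------
# binning
# ----------------------------------------------------------------------

def bin_depth(frame: pd.DataFrame, genome: "GenomeModel", bin_size: int | None = None) -> CopyNumberTrack:
    """Count fragment-end starts per bin on the genomic chromosomes.

    Each fragment contributes both ends, or one if the other end lies on a
    transgene contig. The depth statistic is insensitive to insert length.
    """
    bin_size = bin_size or genome.bin_size
    if bin_size <= 0:
        raise ValueError(f"bin_size must be positive, got {bin_size}")
    if bin_size != genome.bin_size:
        raise ValueError(
            f"bin_size {bin_size} differs from the genome GC-track bin size {genome.bin_size}"
        )
    chroms = genome.genomic_chromosomes
    raw = {c: np.zeros(genome.n_bins(c)) for c in chroms}
    ends = pd.concat(
        [
            frame[["chrom1", "pos1"]].rename(columns={"chrom1": "chrom", "pos1": "pos"}),
            frame[["chrom2", "pos2"]].rename(columns={"chrom2": "chrom", "pos2": "pos"}),
        ],
        ignore_index=True,
    )
    ends = ends[ends["chrom"].isin(chroms)]
    for chrom, group in ends.groupby("chrom", sort=False):
        pos = group["pos"].to_numpy()
        if len(pos) and (pos.min() < 0 or pos.max() >= genome.lengths[chrom]):
            raise ValueError(f"fragment end beyond chromosome {chrom!r}")
        raw[chrom] += np.bincount(pos // bin_size, minlength=genome.n_bins(chrom)).astype(float)
    return CopyNumberTrack(
        bin_size=bin_size,
        chroms=list(chroms),
        lengths={c: genome.lengths[c] for c in chroms},
        raw=raw,
        gc={c: genome.gc[c].copy() for c in chroms},
        mask={c: np.ones(genome.n_bins(c), dtype=bool) for c in chroms},
        cn={c: np.full(genome.n_bins(c), np.nan) for c in chroms},
        expected={c: float(genome.expected_copies.get(c, 2)) for c in chroms},
    )


# ----------------------------------------------------------------------
# normalization
# ----------------------------------------------------------------------

def gc_normalize(track: CopyNumberTrack) -> CopyNumberTrack:
    """Divide counts by their 2%-GC-stratum median, keep the global median.

    Strata with fewer than 50 bins (or a zero median) fall back to the
    global median, so sparse GC tails never explode.
    """
    out = track.copy()
    counts = track.concat("raw")
    gc = track.concat("gc")
    global_median = float(np.median(counts))
    if global_median == 0:
        warnings.warn("all-zero depth track: GC normalization skipped", stacklevel=2)
        return out
    strata = np.minimum((gc / _GC_STRATUM_WIDTH).astype(int), int(1 / _GC_STRATUM_WIDTH) - 1)
    medians = np.full(strata.max() + 1, global_median)
    for s in np.unique(strata):
        members = counts[strata == s]
        if len(members) >= _GC_MIN_STRATUM_BINS:
            m = float(np.median(members))
            if m > 0:
                medians[s] = m
    norm = counts / medians[strata]
    norm_median = float(np.median(norm))
    scale = global_median / norm_median if norm_median > 0 else 1.0
    norm *= scale
    offset = 0
    for chrom in out.chroms:
        nb = out.n_bins(chrom)
        out.raw[chrom] = norm[offset : offset + nb]
        offset += nb
    return out


def normalize_by_panel(track: CopyNumberTrack, panel: list[CopyNumberTrack]) -> CopyNumberTrack:
    """Fill the cn arrays from a panel of normals (per-bin median ratio).

    All tracks must be GC-normalized already and share genome/binning. The
    sample and each normal are scaled by their autosomal median; the sample
    ratio is divided by the per-bin panel median and multiplied by the
    chromosome's expected baseline copies. Bins with panel median 0 are
    masked (unassayable).
    """
    if not panel:
        raise ValueError("panel must contain at least one normal track")
    for normal in panel:
        if not track.same_binning(normal):
            raise ValueError("panel track binning does not match the sample")
    out = track.copy()

    def ratios(t: CopyNumberTrack) -> np.ndarray:
        med = float(np.median(t.concat("raw", t.autosomes)))
        if med == 0:
            raise ValueError("autosomal median depth is zero")
        return t.concat("raw") / med

    sample_ratio = ratios(track)
    panel_matrix = np.vstack([ratios(normal) for normal in panel])
    panel_median = np.median(panel_matrix, axis=0)
    expected = np.concatenate(
        [np.full(track.n_bins(c), track.expected[c]) for c in track.chroms]
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        cn = expected * sample_ratio / panel_median
    assayable = panel_median > 0
    cn[~assayable] = np.nan
    offset = 0
    for chrom in out.chroms:
        nb = out.n_bins(chrom)
        out.cn[chrom] = cn[offset : offset + nb]
        out.mask[chrom] = assayable[offset : offset + nb] & track.mask[chrom]
        offset += nb
    return out


def mask_low_panel_bins(track: CopyNumberTrack, panel: list[CopyNumberTrack], min_ratio: float) -> CopyNumberTrack:
    """Mask bins whose panel median ratio falls below ``min_ratio``.

    Guards against insert-length depletion at chromosome ends, where the
    ratio denominator is tiny and cn estimates are wild.
    """
    out = track.copy()

    def ratios(t: CopyNumberTrack) -> np.ndarray:
        med = float(np.median(t.concat("raw", t.autosomes)))
        return t.concat("raw") / med

    panel_median = np.median(np.vstack([ratios(n) for n in panel]), axis=0)
    low = panel_median < min_ratio
    offset = 0
    for chrom in out.chroms:
        nb = out.n_bins(chrom)
        out.mask[chrom] &= ~low[offset : offset + nb]
        offset += nb
    return out


# ----------------------------------------------------------------------
# segmentation
# ----------------------------------------------------------------------

def _sse_split(prefix: np.ndarray, prefix2: np.ndarray, lo: int, hi: int) -> float:
    """Within-segment SSE of values[lo:hi] around their mean (via cumsums)."""
    n = hi - lo
    if n <= 0:
        return 0.0
    s = prefix[hi] - prefix[lo]
    s2 = prefix2[hi] - prefix2[lo]
    return float(s2 - s * s / n)


def _refine_boundary(values: np.ndarray, guess: int, radius: int) -> int:
    """Locally exact least-squares placement of one changepoint."""
    n = len(values)
    lo = max(guess - 2 * radius, 0)
    hi = min(guess + 2 * radius, n)
    prefix = np.concatenate([[0.0], np.cumsum(values)])
    prefix2 = np.concatenate([[0.0], np.cumsum(values**2)])
    best, best_sse = guess, np.inf
    for b in range(max(lo + 1, guess - radius), min(hi - 1, guess + radius) + 1):
        sse = _sse_split(prefix, prefix2, lo, b) + _sse_split(prefix, prefix2, b, hi)
        if sse < best_sse - 1e-12:
            best, best_sse = b, sse
    return best


def _changepoints(values: np.ndarray, window_w: int, z_threshold: float) -> list[int]:
    """Welch-z sliding-window scan; returns sorted compressed-bin boundaries."""
    n = len(values)
    if n < 2 * window_w:
        return []
    w = window_w
    prefix = np.concatenate([[0.0], np.cumsum(values)])
    prefix2 = np.concatenate([[0.0], np.cumsum(values**2)])
    bounds = np.arange(w, n - w + 1)
    s_l = prefix[bounds] - prefix[bounds - w]
    s2_l = prefix2[bounds] - prefix2[bounds - w]
    s_r = prefix[bounds + w] - prefix[bounds]
    s2_r = prefix2[bounds + w] - prefix2[bounds]
    m_l, m_r = s_l / w, s_r / w
    v_l = np.maximum(s2_l / w - m_l**2, 0.0)
    v_r = np.maximum(s2_r / w - m_r**2, 0.0)
    z = np.abs(m_r - m_l) / np.sqrt((v_l + v_r) / w + 1e-9)

    above = z > z_threshold
    if not above.any():
        return []
    # local maxima of |z|, then non-maximum suppression within one window
    candidates = [
        i
        for i in range(len(z))
        if above[i]
        and (i == 0 or z[i] >= z[i - 1])
        and (i == len(z) - 1 or z[i] > z[i + 1])
    ]
    candidates.sort(key=lambda i: -z[i])
    kept: list[int] = []
    for i in candidates:
        if all(abs(i - j) > w for j in kept):
            kept.append(i)
    boundaries = sorted(int(bounds[i]) for i in kept)
    refined = sorted({_refine_boundary(values, b, w) for b in boundaries})
    return [b for b in refined if 0 < b < n]


def _merge_segments(values: np.ndarray, boundaries: list[int], merge_delta: float) -> list[int]:
    """Drop boundaries whose flanking segment means differ by < merge_delta."""
    bounds = [0] + boundaries + [len(values)]
    while len(bounds) > 2:
        means = [values[a:b].mean() for a, b in zip(bounds, bounds[1:])]
        deltas = [abs(m2 - m1) for m1, m2 in zip(means, means[1:])]
        i = int(np.argmin(deltas))
        if deltas[i] >= merge_delta:
            break
        del bounds[i + 1]
    return bounds[1:-1]


def segment(
    track: CopyNumberTrack,
    window_w: int = 20,
    z_threshold: float = 5.0,
    merge_delta: float = 0.3,
) -> list[CNVSegment]:
    """Sliding-window changepoint segmentation of the cn track.

    Masked bins are skipped (the scan runs in compressed assayable-bin
    space); segments partition each chromosome's assayable extent.
    Chromosomes shorter than two windows become a single segment.
    """
    if window_w < 2:
        raise ValueError(f"window_w must be >= 2, got {window_w}")
    segments: list[CNVSegment] = []
    bs = track.bin_size
    for chrom in track.chroms:
        idx = np.flatnonzero(track.mask[chrom] & np.isfinite(track.cn[chrom]))
        if len(idx) == 0:
            continue
        values = track.cn[chrom][idx]
        if len(values) < 2 * window_w:
            log.warning("chromosome %s has %d assayable bins < 2 windows; single segment", chrom, len(values))
            boundaries: list[int] = []
        else:
            boundaries = _changepoints(values, window_w, z_threshold)
            boundaries = _merge_segments(values, boundaries, merge_delta)
        cuts = [0] + boundaries + [len(values)]
        for a, b in zip(cuts, cuts[1:]):
            start_bin = idx[a]
            end_bin = idx[b - 1] + 1
            end_base = min(end_bin * bs, track.lengths[chrom])
            segments.append(
                CNVSegment(
                    chrom=chrom,
                    start=int(start_bin * bs),
                    end=int(end_base),
                    cn_mean=float(values[a:b].mean()),
                    n_bins=int(b - a),
                )
            )
    return segments


# ----------------------------------------------------------------------
# refinement, classification, summary
# ----------------------------------------------------------------------

def refine_with_junctions(
    segments: list[CNVSegment],
    junctions: list[BreakpointJunction],
    snap_distance: int,
) -> list[CNVSegment]:
    """Snap segment boundaries to nearby junction breakpoints.

    A boundary within ``snap_distance`` of a breakpoint moves to it (base
    resolution instead of bin resolution) and the flanking segments are
    flagged junction-supported. The nearest breakpoint wins; ties go to the
    lower coordinate. The partition property is preserved.
    """
    by_chrom: dict[str, list[int]] = {}
    for j in junctions:
        by_chrom.setdefault(j.chrom_a, []).append(j.pos_a)
        by_chrom.setdefault(j.chrom_b, []).append(j.pos_b)
    out = [replace(s) for s in segments]
    by_segments: dict[str, list[CNVSegment]] = {}
    for s in out:
        by_segments.setdefault(s.chrom, []).append(s)
    for chrom, segs in by_segments.items():
        segs.sort(key=lambda s: s.start)
        breakpoints = sorted(by_chrom.get(chrom, []))
        if not breakpoints:
            continue
        for left, right in zip(segs, segs[1:]):
            boundary = left.end
            best = None
            best_dist = snap_distance + 1
            for bp in breakpoints:
                dist = abs(bp - boundary)
                if dist < best_dist or (dist == best_dist and best is not None and bp < best):
                    if left.start < bp < right.end:
                        best, best_dist = bp, dist
            if best is not None and best_dist <= snap_distance:
                left.end = int(best)
                right.start = int(best)
                left.junction_supported = True
                right.junction_supported = True
    return out


def classify_segments(
    segments: list[CNVSegment],
    gain_cutoff: float = 2.5,
    loss_cutoff: float = 1.5,
    expected: dict[str, float] | None = None,
) -> list[CNVSegment]:
    """Classify segments gain/normal/loss against the 2N-midpoint cutoffs.

    ``gain_cutoff`` is inclusive (cn_mean of exactly 2.5 is a gain). For a
    chromosome with a non-diploid expected baseline the cutoffs shift by
    (baseline - 2).
    """
    if not loss_cutoff < 2 < gain_cutoff:
        raise ValueError(f"need loss_cutoff < 2 < gain_cutoff, got {loss_cutoff}/{gain_cutoff}")
    out = []
    for s in segments:
        shift = (expected or {}).get(s.chrom, 2.0) - 2.0
        if s.cn_mean >= gain_cutoff + shift:
            klass = GAIN
        elif s.cn_mean <= loss_cutoff + shift:
            klass = LOSS
        else:
            klass = NORMAL
        out.append(replace(s, klass=klass))
    return out


def summarize_chromosomes(
    segments: list[CNVSegment],
    whole_fraction: float = 0.95,
    partial_min_fraction: float = 0.05,
) -> list[ChromosomeCall]:
    """Per-chromosome aneuploidy calls from classified segments.

    whole_gain/whole_loss when >= ``whole_fraction`` of assayable bins are
    variant in a single direction (the monosomy/trisomy squares of a
    karyotype heat map); partial_gain/partial_loss when the largest variant
    segment covers >= ``partial_min_fraction`` of the chromosome (the
    triangles); mixed when both directions exceed ``partial_min_fraction``.
    """
    by_chrom: dict[str, list[CNVSegment]] = {}
    for s in segments:
        if s.klass is None:
            raise ValueError("segments must be classified before summarizing")
        by_chrom.setdefault(s.chrom, []).append(s)
    calls = []
    for chrom, segs in by_chrom.items():  # insertion order = genome order
        total = sum(s.n_bins for s in segs)
        gain_bins = sum(s.n_bins for s in segs if s.klass == GAIN)
        loss_bins = sum(s.n_bins for s in segs if s.klass == LOSS)
        frac_gain = gain_bins / total if total else 0.0
        frac_loss = loss_bins / total if total else 0.0
        largest_gain = max((s.n_bins for s in segs if s.klass == GAIN), default=0) / total if total else 0.0
        largest_loss = max((s.n_bins for s in segs if s.klass == LOSS), default=0) / total if total else 0.0
        variant_fraction = frac_gain + frac_loss
        if frac_gain >= whole_fraction:
            call = WHOLE_GAIN
        elif frac_loss >= whole_fraction:
            call = WHOLE_LOSS
        elif frac_gain >= partial_min_fraction and frac_loss >= partial_min_fraction:
            call = MIXED
        elif largest_gain >= partial_min_fraction:
            call = PARTIAL_GAIN
        elif largest_loss >= partial_min_fraction:
            call = PARTIAL_LOSS
        else:
            call = NORMAL
        calls.append(ChromosomeCall(chrom=chrom, call=call, variant_fraction=variant_fraction))
    return calls
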