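"""Simulated mapped mate-pair fragments from a derived (rearranged) genome.

The simulator emits already-mapped coordinate pairs — the mapping stage of a
real mate-pair experiment is out of scope — under the innie convention:
a concordant fragment is a forward-strand end followed, one insert length
downstream, by a reverse-strand end. Insert sizes are normal, truncated at
1 base (default median 3 kb, SD 300 b: a long-insert library at toy scale).

Fragment density is proportional to regional copy multiplicity times a GC
bias factor ``max(1 + slope * (GC - 0.5), 0.05)``. Fragments straddling a
planted fusion emit one end on each side of the junction with the strands
implied by the fused orientations; transgene integrations emit hybrid
fragments with one end on the transgene contig. A configurable fraction of
fragments get one end re-mapped uniformly at random (mapping noise).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ..fragments import FRAGMENT_COLUMNS
from .karyotype import DerivedGenome

GC_FLOOR = 0.05


@dataclass(frozen=True)
class FragmentSimParams:
    median_insert: int = 3000
    insert_sd: int = 300
    mean_fragments_per_kb: float = 20.0
    gc_bias_slope: float = 0.0
    noise_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.median_insert <= 0:
            raise ValueError(f"median_insert must be positive, got {self.median_insert}")
        if self.insert_sd < 0:
            raise ValueError(f"insert_sd must be >= 0, got {self.insert_sd}")
        if not self.mean_fragments_per_kb > 0:
            raise ValueError(f"mean_fragments_per_kb must be positive, got {self.mean_fragments_per_kb}")
        if not 0 <= self.noise_rate < 0.5:
            raise ValueError(f"noise_rate must be in [0, 0.5), got {self.noise_rate}")

    @property
    def insert_p95(self) -> float:
        """95th percentile of the insert distribution (breakpoint tolerance)."""
        return self.median_insert + 1.6449 * self.insert_sd


def _gc_factor(gc: np.ndarray, slope: float) -> np.ndarray:
    return np.maximum(1.0 + slope * (gc - 0.5), GC_FLOOR)


def _copies_per_bin(derived: DerivedGenome, chrom: str) -> np.ndarray:
    genome = derived.genome
    bs = genome.bin_size
    nb = genome.n_bins(chrom)
    copies = np.full(nb, genome.expected_copies.get(chrom, 2), dtype=float)
    mid = np.arange(nb) * bs + bs // 2
    mid = np.minimum(mid, genome.lengths[chrom] - 1)
    for start, end, c in derived.cn[chrom]:
        copies[(mid >= start) & (mid < end)] = c
    return copies


def _draw_inserts(rng: np.random.Generator, n: int, params: FragmentSimParams) -> np.ndarray:
    ins = rng.normal(params.median_insert, params.insert_sd, size=n)
    return np.maximum(np.rint(ins), 1).astype(np.int64)


def simulate_mate_pairs(derived: DerivedGenome, params: FragmentSimParams) -> pd.DataFrame:
    """Emit a fragment frame for one sample of the derived genome.

    Deterministic for a fixed seed. Output ends are canonicalized and rows
    sorted by coordinates, then named ``frag0000001``... in that order.
    """
    genome = derived.genome
    if not genome.genomic_chromosomes:
        raise ValueError("derived genome has no genomic chromosomes")
    rng = np.random.default_rng(params.seed)
    bs = genome.bin_size

    chrom1: list[np.ndarray] = []
    pos1: list[np.ndarray] = []
    strand1: list[np.ndarray] = []
    chrom2: list[np.ndarray] = []
    pos2: list[np.ndarray] = []
    strand2: list[np.ndarray] = []

    def emit(c1, p1, s1, c2, p2, s2) -> None:
        chrom1.append(np.asarray(c1, dtype=object))
        pos1.append(np.asarray(p1, dtype=np.int64))
        strand1.append(np.asarray(s1, dtype=object))
        chrom2.append(np.asarray(c2, dtype=object))
        pos2.append(np.asarray(p2, dtype=np.int64))
        strand2.append(np.asarray(s2, dtype=object))

    zero_regions: dict[str, list[tuple[int, int]]] = {
        chrom: [(s, e) for s, e, c in derived.cn[chrom] if c == 0]
        for chrom in genome.genomic_chromosomes
    }

    def in_zero(chrom_arr: np.ndarray, pos_arr: np.ndarray) -> np.ndarray:
        hit = np.zeros(len(pos_arr), dtype=bool)
        for chrom, regions in zero_regions.items():
            if not regions:
                continue
            on = chrom_arr == chrom
            for s, e in regions:
                hit |= on & (pos_arr >= s) & (pos_arr < e)
        return hit

    # ---- background fragments, density ~ copies x GC factor
    for chrom in genome.genomic_chromosomes:
        L = genome.lengths[chrom]
        nb = genome.n_bins(chrom)
        widths = np.full(nb, bs, dtype=float)
        widths[-1] = L - (nb - 1) * bs
        lam = (
            params.mean_fragments_per_kb
            * (widths / 1000.0)
            * (_copies_per_bin(derived, chrom) / 2.0)
            * _gc_factor(genome.gc[chrom], params.gc_bias_slope)
        )
        counts = rng.poisson(lam)
        n = int(counts.sum())
        if n == 0:
            continue
        bin_idx = np.repeat(np.arange(nb), counts)
        starts = (bin_idx * bs + rng.random(n) * widths[bin_idx]).astype(np.int64)
        inserts = _draw_inserts(rng, n, params)
        ends = starts + inserts
        keep = ends < L
        starts, ends = starts[keep], ends[keep]
        m = len(starts)
        bad = in_zero(np.full(m, chrom, dtype=object), starts) | in_zero(
            np.full(m, chrom, dtype=object), ends
        )
        starts, ends = starts[~bad], ends[~bad]
        m = len(starts)
        emit(
            np.full(m, chrom, dtype=object), starts, np.full(m, "+", dtype=object),
            np.full(m, chrom, dtype=object), ends, np.full(m, "-", dtype=object),
        )

    junction_rate = params.mean_fragments_per_kb * (params.median_insert / 1000.0) / 2.0

    # ---- fusion-straddling fragments
    for (ca, pa, oa), (cb, pb, ob) in derived.fusions:
        bin_a = min(pa // bs, genome.n_bins(ca) - 1)
        factor = float(_gc_factor(genome.gc[ca][bin_a : bin_a + 1], params.gc_bias_slope)[0])
        n = int(rng.poisson(junction_rate * factor))
        if n == 0:
            continue
        inserts = _draw_inserts(rng, n, params)
        u = (rng.random(n) * np.maximum(inserts - 2, 1)).astype(np.int64) + 1
        v = np.maximum(inserts - u, 1)
        posa = pa - u if oa == "+" else pa + u
        posb = pb - v if ob == "+" else pb + v
        keep = (posa >= 0) & (posa < genome.lengths[ca]) & (posb >= 0) & (posb < genome.lengths[cb])
        posa, posb = posa[keep], posb[keep]
        m = len(posa)
        emit(
            np.full(m, ca, dtype=object), posa, np.full(m, oa, dtype=object),
            np.full(m, cb, dtype=object), posb, np.full(m, ob, dtype=object),
        )

    # ---- transgene integration fragments (one genomic + one transgene end)
    for transgene, chrom, pos in derived.integrations:
        tg_len = genome.lengths[transgene]
        n = int(rng.poisson(junction_rate))
        if n == 0:
            continue
        inserts = _draw_inserts(rng, n, params)
        u = (rng.random(n) * np.maximum(inserts - 2, 1)).astype(np.int64) + 1
        left = rng.random(n) < 0.5  # which genomic flank of the insertion
        gpos = np.where(left, pos - u, pos + u)
        gstrand = np.where(left, "+", "-").astype(object)
        keep = (gpos >= 0) & (gpos < genome.lengths[chrom])
        gpos, gstrand = gpos[keep], gstrand[keep]
        m = len(gpos)
        tpos = (rng.random(m) * tg_len).astype(np.int64)
        tstrand = np.where(rng.random(m) < 0.5, "+", "-").astype(object)
        emit(
            np.full(m, chrom, dtype=object), gpos, gstrand,
            np.full(m, transgene, dtype=object), tpos, tstrand,
        )

    if not chrom1:
        frame = pd.DataFrame(columns=FRAGMENT_COLUMNS)
        frame["name"] = frame.get("name", pd.Series(dtype=object))
        return frame

    c1 = np.concatenate(chrom1)
    p1 = np.concatenate(pos1)
    s1 = np.concatenate(strand1)
    c2 = np.concatenate(chrom2)
    p2 = np.concatenate(pos2)
    s2 = np.concatenate(strand2)
    total = len(c1)

    # ---- mapping noise: one end re-mapped uniformly over the genome
    if params.noise_rate > 0:
        hit = np.flatnonzero(rng.random(total) < params.noise_rate)
        if len(hit):
            chroms = genome.genomic_chromosomes
            lengths = np.array([genome.lengths[c] for c in chroms], dtype=float)
            pick = rng.choice(len(chroms), size=len(hit), p=lengths / lengths.sum())
            new_chrom = np.array(chroms, dtype=object)[pick]
            new_pos = (rng.random(len(hit)) * lengths[pick]).astype(np.int64)
            new_strand = np.where(rng.random(len(hit)) < 0.5, "+", "-").astype(object)
            side = rng.random(len(hit)) < 0.5
            one = hit[side]
            two = hit[~side]
            c1[one], p1[one], s1[one] = new_chrom[side], new_pos[side], new_strand[side]
            c2[two], p2[two], s2[two] = new_chrom[~side], new_pos[~side], new_strand[~side]

    # canonical end order + deterministic sort, on integer chromosome codes
    rank = genome.rank
    lut = {c: rank[c] for c in genome.names}
    codes1 = pd.Series(c1).map(lut).to_numpy()
    codes2 = pd.Series(c2).map(lut).to_numpy()
    swap = (codes2 < codes1) | ((codes2 == codes1) & (p2 < p1))
    for a, b in ((c1, c2), (p1, p2), (s1, s2), (codes1, codes2)):
        tmp = a[swap].copy()
        a[swap] = b[swap]
        b[swap] = tmp
    order = np.lexsort((s2, s1, p2, codes2, p1, codes1))
    names = np.char.add("frag", np.char.zfill((np.arange(total) + 1).astype("U9"), 7))
    frame = pd.DataFrame(
        {
            "chrom1": c1[order],
            "pos1": p1[order],
            "strand1": s1[order],
            "chrom2": c2[order],
            "pos2": p2[order],
            "strand2": s2[order],
            "name": names,
        }
    )
    return frame
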