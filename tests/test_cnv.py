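import numpy as np
import pytest
from itertools import combinations
from scipy import stats

from mpcin import cnv
from mpcin.fragments import MappedFragment, frame_from_fragments
from mpcin.junctions import BreakpointJunction
from mpcin.simulate import (
    FragmentSimParams,
    KaryotypePlan,
    WholeGain,
    apply_karyotype,
    simulate_mate_pairs,
)


def make_track(values, bin_size=1000, expected=2.0, mask=None):
    values = np.asarray(values, dtype=float)
    n = len(values)
    return cnv.CopyNumberTrack(
        bin_size=bin_size,
        chroms=["1"],
        lengths={"1": n * bin_size},
        raw={"1": values.copy()},
        gc={"1": np.full(n, 0.45)},
        mask={"1": np.ones(n, bool) if mask is None else mask},
        cn={"1": values.copy()},
        expected={"1": expected},
    )


# ----------------------------------------------------------------------
# binning
# ----------------------------------------------------------------------

def test_bin_depth_counting_contract(genome):
    frame = frame_from_fragments(
        [MappedFragment("1", 1_500, "+", "1", 4_200, "-", name="f1")]
    )
    track = cnv.bin_depth(frame, genome)
    assert track.raw["1"][1] == 1
    assert track.raw["1"][4] == 1
    assert track.raw["1"].sum() == 2


def test_no_fragments_all_zero(genome):
    track = cnv.bin_depth(frame_from_fragments([]), genome)
    assert track.concat("raw").sum() == 0


def test_uniform_depth_is_poisson(diploid_fragments, genome):
    """Per-bin end counts under a uniform simulation pass a chi-square
    dispersion test against Poisson(2 ends x 20 fragments/kb)."""
    track = cnv.bin_depth(diploid_fragments, genome)
    # exclude chromosome-end bins (insert-length edge depletion)
    counts = np.concatenate([track.raw[c][5:-5] for c in track.chroms])
    mean = counts.mean()
    T = ((counts - mean) ** 2 / mean).sum()
    lo, hi = stats.chi2.ppf([0.005, 0.995], df=len(counts) - 1)
    assert lo < T < hi


def test_transgene_end_not_binned(genome):
    frame = frame_from_fragments(
        [MappedFragment("1", 1_500, "+", "huYAP", 100, "-", name="f1")]
    )
    track = cnv.bin_depth(frame, genome)
    assert track.concat("raw").sum() == 1
    assert "huYAP" not in track.chroms


# ----------------------------------------------------------------------
# GC normalization
# ----------------------------------------------------------------------

def test_gc_normalize_identity_on_constant_gc():
    track = make_track(np.full(500, 40.0))
    out = cnv.gc_normalize(track)
    np.testing.assert_allclose(out.raw["1"], track.raw["1"], rtol=1e-12)


def test_gc_normalize_removes_planted_bias(genome, cfg):
    diploid, _ = apply_karyotype(genome, KaryotypePlan(events=[]))
    frags = simulate_mate_pairs(diploid, FragmentSimParams(gc_bias_slope=0.8, seed=41))
    track = cnv.bin_depth(frags, genome)
    gc = track.concat("gc")
    r_before = np.corrcoef(gc, track.concat("raw"))[0, 1]
    out = cnv.gc_normalize(track)
    r_after = np.corrcoef(gc, out.concat("raw"))[0, 1]
    assert abs(r_before) > 0.3
    assert abs(r_after) < 0.05


def test_gc_normalize_preserves_global_median(genome, diploid_fragments):
    track = cnv.bin_depth(diploid_fragments, genome)
    out = cnv.gc_normalize(track)
    before = np.median(track.concat("raw"))
    after = np.median(out.concat("raw"))
    assert after == pytest.approx(before, rel=1e-9)


def test_all_zero_track_returned_with_warning(genome):
    track = cnv.bin_depth(frame_from_fragments([]), genome)
    with pytest.warns(UserWarning, match="all-zero"):
        out = cnv.gc_normalize(track)
    assert out.concat("raw").sum() == 0


# ----------------------------------------------------------------------
# panel normalization
# ----------------------------------------------------------------------

def test_null_sample_centred_on_diploid(genome, diploid_fragments, panel_tracks):
    track = cnv.gc_normalize(cnv.bin_depth(diploid_fragments, genome))
    out = cnv.normalize_by_panel(track, panel_tracks)
    values = out.concat("cn")[out.concat("mask")]
    assert 1.9 <= values.mean() <= 2.1


def test_planted_trisomy_recovered(genome, panel_tracks):
    derived, _ = apply_karyotype(genome, KaryotypePlan(events=[WholeGain("5")]))
    frags = simulate_mate_pairs(derived, FragmentSimParams(seed=42))
    out = cnv.normalize_by_panel(cnv.gc_normalize(cnv.bin_depth(frags, genome)), panel_tracks)
    values = out.cn["5"][out.mask["5"]]
    assert 2.7 <= values.mean() <= 3.3


def test_panel_median_zero_masks_bin(genome, diploid_fragments, panel_tracks):
    doctored = [t.copy() for t in panel_tracks]
    for t in doctored:
        t.raw["1"][100] = 0.0
    track = cnv.gc_normalize(cnv.bin_depth(diploid_fragments, genome))
    out = cnv.normalize_by_panel(track, doctored)
    assert not out.mask["1"][100]
    assert np.isnan(out.cn["1"][100])


def test_mismatched_binning_rejected(genome, panel_tracks):
    other = panel_tracks[0].copy()
    other.raw["1"] = other.raw["1"][:-10]
    with pytest.raises(ValueError, match="binning"):
        cnv.normalize_by_panel(other, panel_tracks)


# ----------------------------------------------------------------------
# segmentation
# ----------------------------------------------------------------------

def _exhaustive_oracle(values, k):
    n = len(values)
    pre = np.concatenate([[0.0], np.cumsum(values)])
    pre2 = np.concatenate([[0.0], np.cumsum(values**2)])

    def sse(a, b):
        m = b - a
        s = pre[b] - pre[a]
        return pre2[b] - pre2[a] - s * s / m

    best, best_sse = (), np.inf
    for cuts in combinations(range(1, n), k):
        bounds = [0, *cuts, n]
        total = sum(sse(a, b) for a, b in zip(bounds, bounds[1:]))
        if total < best_sse:
            best, best_sse = cuts, total
    return best


def test_constant_chromosome_single_segment():
    segs = cnv.segment(make_track(np.full(300, 2.0)), window_w=10)
    assert len(segs) == 1
    assert (segs[0].start, segs[0].end) == (0, 300_000)


def test_step_changepoint_within_window(rng):
    values = np.concatenate(
        [2 * rng.poisson(40, 500) / 40, 2 * rng.poisson(60, 500) / 40]
    )
    segs = cnv.segment(make_track(values), window_w=20)
    assert len(segs) == 2
    assert abs(segs[1].start // 1000 - 500) <= 20


@pytest.mark.parametrize("seed", range(8))
def test_segmentation_matches_exhaustive_least_squares(seed):
    """Boundaries within +-2 bins of the exhaustive SSE oracle on short
    tracks with up to two well-separated changepoints."""
    rng = np.random.default_rng(seed)
    n = int(rng.integers(120, 201))
    k = int(rng.integers(0, 3))
    cps = []
    while len(cps) < k:
        c = int(rng.integers(25, n - 25))
        if all(abs(c - o) >= 50 for o in cps):
            cps.append(c)
    cps.sort()
    levels = [2.0]
    for _ in cps:
        step = 1.0 if levels[-1] <= 1.0 else rng.choice([-1.0, 1.0])
        levels.append(levels[-1] + step)
    values = np.zeros(n)
    for (a, b), lev in zip(zip([0, *cps], [*cps, n]), levels):
        values[a:b] = 2 * rng.poisson(40 * lev / 2, b - a) / 40
    segs = cnv.segment(make_track(values), window_w=10, z_threshold=5.0, merge_delta=0.3)
    detected = [s.start // 1000 for s in segs[1:]]
    assert len(detected) == k
    oracle = _exhaustive_oracle(values, k)
    for d, o in zip(detected, oracle):
        assert abs(d - o) <= 2


def test_short_chromosome_single_segment_with_warning(caplog):
    values = np.full(15, 2.0)
    with caplog.at_level("WARNING", logger="mpcin"):
        segs = cnv.segment(make_track(values), window_w=10)
    assert len(segs) == 1
    assert "single segment" in caplog.text


def test_segments_partition_assayable_extent(genome, diploid_fragments, panel_tracks, cfg):
    track = cnv.normalize_by_panel(
        cnv.gc_normalize(cnv.bin_depth(diploid_fragments, genome)), panel_tracks
    )
    track = cnv.mask_low_panel_bins(track, panel_tracks, cfg.panel_min_ratio)
    segs = cnv.segment(track, cfg.window_w, cfg.z_threshold, cfg.merge_delta)
    by_chrom = {}
    for s in segs:
        by_chrom.setdefault(s.chrom, []).append(s)
    for chrom, chrom_segs in by_chrom.items():
        chrom_segs.sort(key=lambda s: s.start)
        for left, right in zip(chrom_segs, chrom_segs[1:]):
            assert left.end == right.start
        assert chrom_segs[0].start >= 0
        assert chrom_segs[-1].end <= genome.lengths[chrom]


# ----------------------------------------------------------------------
# refinement / classification / summary
# ----------------------------------------------------------------------

def _junction(chrom, pos_a, pos_b, klass="deletion"):
    return BreakpointJunction(chrom, pos_a, "+", chrom, pos_b, "-", support=10, klass=klass)


def test_boundary_snaps_to_junction_breakpoint():
    segs = [
        cnv.CNVSegment("1", 0, 501_000, 2.0, 501),
        cnv.CNVSegment("1", 501_000, 1_000_000, 1.0, 499),
    ]
    out = cnv.refine_with_junctions(segs, [_junction("1", 500_230, 700_000)], snap_distance=10_000)
    assert out[0].end == 500_230 and out[1].start == 500_230
    assert out[0].junction_supported and out[1].junction_supported


def test_refine_without_junctions_is_identity():
    segs = [cnv.CNVSegment("1", 0, 500_000, 2.0, 500), cnv.CNVSegment("1", 500_000, 1_000_000, 3.0, 500)]
    out = cnv.refine_with_junctions(segs, [], snap_distance=10_000)
    assert [(s.start, s.end) for s in out] == [(s.start, s.end) for s in segs]
    assert not any(s.junction_supported for s in out)


def test_nearest_junction_wins_tie_to_lower_coordinate():
    segs = [
        cnv.CNVSegment("1", 0, 500_000, 2.0, 500),
        cnv.CNVSegment("1", 500_000, 1_000_000, 3.0, 500),
    ]
    junctions = [_junction("1", 499_000, 900_000), _junction("1", 501_000, 950_000)]
    out = cnv.refine_with_junctions(segs, junctions, snap_distance=10_000)
    assert out[0].end == 499_000


@pytest.mark.parametrize(
    "cn_mean, expected",
    [(2.0, "normal"), (3.02, "gain"), (1.1, "loss"), (2.5, "gain"), (1.5, "loss"), (2.49, "normal")],
)
def test_segment_classification_cutoffs(cn_mean, expected):
    seg = cnv.CNVSegment("1", 0, 1000, cn_mean, 1)
    out = cnv.classify_segments([seg])
    assert out[0].klass == expected


def test_allosome_baseline_shifts_cutoffs():
    seg = cnv.CNVSegment("X", 0, 1000, 1.0, 1)
    out = cnv.classify_segments([seg], expected={"X": 1.0})
    assert out[0].klass == "normal"
    gained = cnv.classify_segments([cnv.CNVSegment("X", 0, 1000, 2.0, 1)], expected={"X": 1.0})
    assert gained[0].klass == "gain"


def test_chromosome_summary_calls():
    def seg(chrom, n_bins, klass):
        return cnv.CNVSegment(chrom, 0, n_bins * 1000, 2.0, n_bins, klass=klass)

    all_gain = [seg("1", 1000, "gain")]
    partial = [seg("2", 700, "normal"), seg("2", 300, "loss")]
    quiet = [seg("3", 1000, "normal")]
    mixed = [seg("4", 400, "gain"), seg("4", 400, "loss"), seg("4", 200, "normal")]
    calls = {c.chrom: c.call for c in cnv.summarize_chromosomes(all_gain + partial + quiet + mixed)}
    assert calls == {"1": "whole_gain", "2": "partial_loss", "3": "normal", "4": "mixed"}
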