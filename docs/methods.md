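# Methods

## Scope and model

`mpcin` consumes already-mapped mate-pair fragments (two ends, each a
chromosome/position/strand triple); read alignment is out of scope. All
coordinates are 0-based half-open internally and in BED/BEDPE output. The
concordant orientation convention is "innie" (forward end upstream, reverse
end one insert downstream); it is a config field (`expected_orientation`)
so libraries with other conventions can be described rather than silently
assumed.

## Junction detection

A fragment is discordant when its ends map to different chromosomes or
strictly more than `discordance_distance` = 30,000 bases apart on the same
chromosome (a pair at exactly 30 kb is concordant). Discordant fragments
are clustered by single linkage: two fragments link iff both end-1 and
end-2 agree on chromosome and strand and differ by at most `cluster_gap`
in position. `cluster_gap` defaults to 2× the median insert because the
fragments supporting one junction spread over about one insert length on
each side. Clusters with fewer than `min_support` = 3 fragments are
discarded; 3 suppresses singleton mapping noise at the simulated coverage
and is a plain config knob, not an estimate.

The breakpoint estimate per side is the innermost fragment end given the
side's strand (maximum position on a `+` side, minimum on a `-` side):
innermost ends bound the true fusion point under the innie convention, so
the error shrinks roughly as insert / support count and is always within one
insert length. Classification from the canonical-ordered strand pattern:
`+/-` = deletion, `-/+` = tandem-duplication gain, equal strands =
inversion (an inversion produces two junction edges, one per flank),
different chromosomes = translocation. "Gain" is read as the
tandem-duplication signature specifically; that reading is documented
rather than inferred. Deletions smaller than the discordance distance are
invisible to this rule by construction and are left to the depth stage.

Fragments with exactly one end on a transgene contig (e.g. `huYAP`,
`muAkt`) have their genomic ends clustered per transgene with the same gap;
clusters of `min_support` fragments are reported as integration sites at
the median genomic end. Fragments with both ends on transgene contigs are
counted but never produce a genomic site.

## Copy number

Depth is the count of fragment-end starts per 1 kb bin — insensitive to
insert length, two ends per fully genomic fragment. GC correction divides
each bin by the median count of its 2 %-wide GC stratum and rescales so the
genome-wide median is unchanged; strata with fewer than 50 bins (or a zero
median) fall back to the global median. This removes any monotone GC bias
without smoother hyperparameters; the simulator's bias model
(multiplier `1 + slope·(GC − 0.5)`, floored at 0.05) is exactly the kind of
effect this must undo, and the tests verify |r(GC, depth)| < 0.05 after
correction.

Panel normalization scales the sample and each normal by their autosomal
median and divides the sample's per-bin ratio by the per-bin **median**
across normals (robust to one aberrant normal). The result is multiplied by
the chromosome's expected baseline copies: 2 for autosomes, configurable
for allosomes (default X = Y = 1, male animals), so allosome copy numbers
are reported on their true scale and gain/loss cutoffs shift with the
baseline. Bins with panel median zero are unassayable and masked;
additionally bins whose panel median ratio falls below `panel_min_ratio`
= 0.2 are masked because the ratio denominator is dominated by noise there
(in practice the few bins at chromosome ends depleted by the insert-length
edge effect).

Segmentation scans each chromosome (in compressed assayable-bin space)
with a two-window Welch-type z statistic at half-width `window_w` = 20
bins; boundaries are local maxima of |z| above `z_threshold` = 5, each then
refined by exact least-squares placement within ±`window_w` bins. Adjacent
segments whose means differ by less than `merge_delta` = 0.3 copies are
merged, which removes the rare noise-induced cut. At the simulated depth
(about 40 ends per bin, cn standard deviation ≈ 0.32) a one-copy step gives
z ≈ 10 while the null |z| > 5 rate over ~19,000 boundaries is negligible —
the source of the pipeline's empty false-call record in the acceptance
checks. Chromosomes shorter than two windows become a single segment with a
warning. Boundaries within `snap_distance` = 10 kb of a junction breakpoint
snap to it (nearest wins, ties to the lower coordinate), which upgrades
bin-resolution boundaries to insert-resolution ones without changing the
partition property.

Segments are classified gain / normal / loss at cn ≥ 2.5 / ≤ 1.5 — the
midpoints between integer copy states of a pure diploid sample; tumor
purity/ploidy deconvolution is deliberately not attempted. Chromosome
summaries: whole gain/loss when ≥ `whole_fraction` = 0.95 of assayable bins
are variant in one direction; partial gain/loss when the largest variant
segment covers ≥ `partial_min_fraction` = 0.05 of the chromosome; mixed
when both directions exceed that fraction.

## Chromoplexy

Breakpoint loci on one chromosome within `locus_merge_distance` = 50 kb are
merged by single linkage into graph nodes; every junction is one edge.
Connected components with ≥ `chromoplexy_min_junctions` = 4 edges spanning
≥ 2 chromosomes are reported, ordered by junction count. This is an
explicit operationalization of "a large number of intra- and
interchromosomal junctions"; no formal criterion exists to inherit.
Copy-number corroboration (fraction of event loci within `snap_distance`
of a segment boundary) is attached as an annotation, never used as a
filter.

## Signature scoring

Counts are CPM-normalized per sample with a +1 pseudocount before log2 —
zero-count robustness at the cost of a slight shrinkage of fold changes for
low-expression genes. For each signature gene the statistic is the mean
over subjects of (log2 CPM tumor − log2 CPM adjacent). Significance is a
two-sided sign-flip permutation p-value: all 2^n flips are enumerated when
2^n ≤ B (default B = 2000), otherwise B random flips with the add-one
correction. The enumeration includes the identity flip, so the p-value of
an exactly null gene is 1 and the test is exactly valid at any n. The
achievable p-values are multiples of 2/2^n: with n = 5 pairs the smallest
is 0.0625, so no gene can clear α = 0.05 — rejection-rate calibration is
therefore only meaningful at n ≥ 7 or so, and the null-calibration test
uses 10 pairs (smallest achievable level 50/1024 ≈ 0.049). BH adjustment is
applied across the signature genes only; genes are ranked by p-value, ties
broken by |log2FC|. Signature genes absent from the matrix are reported as
missing, never dropped silently.

The shipped signature is the published CIN25 list (human symbols, file
`mpcin/data/cin25.txt`, user-replaceable); matching is case-insensitive so
mouse symbols (Foxm1) resolve against it directly. The unpaired comparison
is a Mann–Whitney U test: exact enumeration when the pooled sample is ≤ 12
with no ties, otherwise the normal approximation with tie and continuity
corrections (delegated to scipy; an independent enumeration oracle checks
the exact branch in the tests).

## Synthetic data

The generator is the package's stand-in for sequencing data and defines the
conditions every recovery test runs under. Genomes are mouse-like
(autosomes "1".."19" at toy scale, optional X/Y at one copy, optional
transgene contigs), with smoothly varying GC (clipped AR(1) per bin) and
optional random sequence whose per-bin GC matches the track exactly.
Karyotype plans support whole/partial gains and losses, deletions,
inversions, tandem duplications, translocations, chromoplexy chains and
transgene integrations; applying a plan yields a copy-multiplicity map plus
fusion list and a truth set recording every event.

Fragments are emitted as mapped coordinate pairs: background density
proportional to copy multiplicity × GC factor with Poisson bin counts;
insert sizes normal (median 3,000, SD 300 — a long-insert library scaled to
toy chromosomes), truncated at 1; fusion-straddling fragments place one end
on each side of the junction with the fused orientations; a `noise_rate`
fraction of fragments has one end re-mapped uniformly. Defaults:
20 fragments/kb, noise 0 (0.01 in the noise-robustness checks, 0.002 in the
demo). Expression counts are negative binomial (dispersion 0.1) around
log-normal baselines with per-sample library factors; tumor samples
multiply signature-gene means by 2^effect (planted pattern: +1 log2FC on
the signature, +3 on Foxm1, mirroring Foxm1 as the strongest signature
gene).

What the simulator does **not** model: raw reads, base qualities,
sequencing error, alignment ambiguity or repeats, subclonal mixtures, tumor
purity, replication-timing or mappability biases, and correlated gene
expression. Passing recovery tests therefore demonstrate the correctness of
the algorithms under idealized mapping, not performance on real libraries.

## Problem sizes and determinism

Recovery checks run at 19 autosomes × 1 Mb with 20 fragments/kb and fresh
panels of 4 normals per simulation (20 seeded simulations for karyotype
recovery); junction/chromoplexy/integration checks use 6 × 1 Mb genomes;
segmentation is checked against an exhaustive least-squares oracle on
tracks of ≤ 200 bins with ≤ 2 changepoints, with planted levels at integer
copy states 1–3. These sizes were chosen as the smallest at which the
binomial/Poisson error bars are clearly inside the asserted bounds. Every
generator and test is a pure function of its seed; the demo writes no
timestamps, so identical config and seed give byte-identical artifacts.

## Known limitations

Breakpoint resolution is insert-limited by design (no split reads).
Junction classes assume simple two-break events; nested or fold-back
rearrangements will cluster but may be misclassified. The copy-number scale
assumes a pure sample; aneuploid genomes whose autosomal *median* shifts
(more than half the genome gained/lost) would be mis-centred. Chromoplexy
is defined purely graph-theoretically and does not distinguish
chromothripsis-like patterns. The signature stage is a scoring procedure,
not a genome-wide differential-expression method: no dispersion modeling or
TMM-style normalization is attempted.
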