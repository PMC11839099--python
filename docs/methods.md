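# Methods

## Coordinates and containers

All coordinates are BED-convention 0-based half-open `[start, end)`; every
consumed format (BED, bedGraph, narrowPeak, chrom.sizes) uses it natively.
The `Genome` preserves chromosome order from the chrom.sizes file so all
outputs are deterministic. An `IntervalSet` keeps *raw records* (with
name/score) separate from its *overlap-collapsed view*: record-level
statistics (width summaries, the Jaccard count numerator and denominator)
use raw records, while coverage, intersection and the Forbes coefficient
use collapsed bases. Width summaries on raw records match the convention of
published exclusion-list tables; collapsed coverage is also exposed
(`stats` reports both `coverage_bp` and `raw_sum_bp`) since some published
lists contain overlapping records and the two differ.

BED records on chromosomes absent from the genome are dropped with a
warning by default (real lists carry alt-contig records that a
primary-chromosome genome lacks); an `error` policy is available.

## The callers

**High Signal.** Threshold `t = fc_min + f·(fc_max − fc_min)` with
`f = 0.99` on peak fold enrichments; peaks with `fc > t` (strict) survive,
are merged within `merge_gap = 1,000 bp`, and regions narrower than
`min_width = 1,000 bp` are discarded (width exactly 1,000 bp is kept:
"smaller than" is strict). The range rule is the default because it is the
operational definition; a `percentile` mode (linear-interpolation quantile,
strict `>`) is exposed since percentile thresholds are common in this
setting. With identical fold changes the range is zero and the strict
inequality yields an empty call — intended behaviour, not an error.
Centromeres can be unioned in afterwards, reflecting the practice of
supplementing signal-derived lists with assembly annotation.

**Low Mappability.** Five steps on a per-base mappability track in [0,1]
(implicit 0 where uncovered): (1) mappable universe = value > 0.01;
(2) merge universe within 1,000 bp; (3) complement within chromosome
bounds; (4) merge within 1,000 bp; (5) drop regions < 1,000 bp. Merging the
*universe first* is what preserves mappable islands interspersed with short
(< merge gap) unmappable speckles — inverting first would report them.

**Blacklist-style caller.** Bins of `bin_size = 1,000 bp` sliding at
`bin_size − bin_overlap = 500 bp`. Reads are assigned to every bin whose
half-open span contains their midpoint (a midpoint on a shared boundary
belongs to the bin starting there); midpoint assignment keeps one count per
read per non-overlapping tiling. The per-bin aggregate is the **median
across samples of count / library total** — median because pooled input
libraries from heterogeneous donors make the mean fragile to single
outlier samples. Bins with aggregate strictly above the 0.99 quantile
(linear interpolation) of all bin aggregates are high-signal; bins with
mean per-base mappability (implicit zeros included) below 0.5 are
low-mappability. Flagged bins are projected to intervals and fused across
gaps ≤ `bridge = 20,000 bp`. Each fused region is labeled by re-scanning
which evidence classes it contains: `High Signal`, `Low Mappability`, or
the combined `High Signal, Low Mappability` when both occur. The combined
label is first-class — mixed-evidence regions are never reported as plain
`High Signal`. All five parameters (`bin_size`, `bin_overlap`,
`signal_quantile`, `mapp_threshold`, `bridge`) are exposed to support
parameter sweeps; the k-mer length of the mappability resource enters only
through which track is supplied and is recorded as metadata.

A quantile threshold flags a fixed fraction of bins, so on a genome whose
true artifact territory is below `1 − signal_quantile` of bins, some
background bins will exceed the cutoff and produce isolated false regions;
the published defaults inherit this property, and the bridge then governs
whether they fuse with real regions.

Bin grids stop at the first bin whose untruncated end reaches the
chromosome end; a trailing truncated bin is kept only when it is the
chromosome's only bin or at least one step wide, so no bin adds zero new
territory.

## Set comparison

`Jc(A,B)` counts, in each direction, records overlapping ≥ 1 base of the
other list; the denominator is the number of coordinate-distinct records in
the union. Coordinate-exact duplicates are counted once *within and across*
lists — this is what keeps `Jc ∈ [0,1]` with `Jc(A,A) = 1` even for lists
containing duplicated records. Both-empty is defined as 0 (no evidence of
similarity). `Fw(A,B) = G·W(A∩B)/(W(A)·W(B))` is undefined (raised) for an
empty set; its diagonal is `G/W(S)`.

Distance conversion: `d = 1 − Jc` for Jaccard; Forbes matrices are first
scaled by their maximum (the conversion is genuinely underdetermined — the
raw matrix is exposed so users can substitute their own). Classical MDS is
the Torgerson construction: double-center `−½·J·D²·J`, top-k eigenpairs,
negative eigenvalues clipped to zero; axis signs are fixed so the
largest-magnitude coordinate on each axis is positive, making output
deterministic. Ward clustering uses scipy's `linkage(..., "ward")` on the
condensed distances (the Ward.D2 convention — flagged because sources
often say only "Ward").

`overlap_summary` is directional and reports both a record-count fraction
and a base-pair fraction of A in B; callers of published statistics should
check both orientations since reported percentages rarely state which one
they use.

## Correlation analysis

Masking is at the **read level**: a read is dropped when its reference span
overlaps ≥ 1 base of the exclusion set (not bin zeroing). Coverage is
counted in non-overlapping 10 kb windows by midpoint; Pearson correlation
on raw counts by default (the choice of raw vs. log counts is exposed
upstream by transforming the read sets; a zero-variance sample yields 0
with a warning instead of NaN propagation). Reports carry
before/after/delta matrices, mean off-diagonal delta per exclusion set
(sets sorted by impact magnitude), and a complete-linkage/Euclidean
ordering of the delta rows for display.

## Transcript impact

Per transcript: `covered_bp = W(exons ∩ set)` on collapsed exons,
`covered_fraction = covered_bp / W(exons)`. "Affected" means strictly
positive covered bases — no minimum-bp cutoff. Annotation biotypes are
collapsed onto three reported classes (protein_coding, lncRNA, other)
through a configurable mapping.

## Synthetic fixtures

The generators emulate the evidence ecosystem the callers consume. Study
conditions (the `FixtureSpec` defaults, chosen a priori): two chromosomes
of 1.0 and 0.8 Mb; background read starts as a homogeneous Poisson process
at 0.05 reads/bp (≈ 5× coverage at 100 bp reads — input-ChIP-like depth at
this scale); 4 samples; one 25 kb hotspot at 100× background shared across
samples; low-mappability zones of 15 kb (value 0.0) and 8 kb (0.005); one
400 bp zero-mappability speckle to exercise universe merging; centromere/
telomere/short-arm gap zones; 100 background peaks with log-normal fold
changes (median 3, σ = 0.5) and hotspot peak fold change = intensity × a
tight log-normal factor (σ = 0.02). The hotspot spans > 1% of genome bins
so that the caller's 0.99 signal quantile falls inside the hotspot value
range — the same regime as real genomes, where artifact bins form the
extreme tail of the coverage distribution.

All generators are pure functions of `(seed, stream)` via numpy
`SeedSequence`; identical seeds give byte-identical fixture files. Not
modeled: fragment-size and GC effects, duplicate reads, donor
heterogeneity, chromatin structure, and real mappability texture (the
synthetic track is piecewise constant). Passing the recovery tests
therefore demonstrates correctness of the procedures under their own
assumptions — clean separation of artifact from background — not
performance on real libraries, where thresholds interact with biological
signal.

Emulated "reference-style" lists (curated / generated / fragmented /
shifted variants of the planted truth) are synthetic stand-ins for the
ecosystem of published exclusion lists, built to exercise the comparison
stack; they reproduce no real list.

## Problem sizes and numerical choices

The test suite and `scripts/acceptance.py` run fixtures of ~1.8 Mb and
~200–850 k reads per study, with 20 (tests) or 10 (script) independent
seeds for recovery and masking-direction checks — sizes chosen so the
planted-truth recovery criterion (per-region reciprocal overlap ≥ 0.8) is
statistically meaningful at bin resolution. Quantiles use numpy's
linear-interpolation definition with strict `>` at the threshold; merged
interval output is int64 bp; bin-mean mappability is computed from a prefix
integral of the step function (exact, no per-base expansion). Ties in
Ward clustering follow scipy's deterministic ordering of the condensed
matrix.

## Known limitations

- The Jaccard count depends on how lists fragment records; comparing a
  merged list against an unmerged one changes Jc but not Fw — by design,
  report both.
- The Forbes→distance rescaling couples a matrix's distances to its own
  maximum; distances are comparable within one matrix, not across matrices.
- The Blacklist-style caller's quantile threshold always flags ~1% of bins
  even on artifact-free genomes (strict `>` on a constant vector flags
  none, but any noise breaks ties); interpret isolated single-bin regions
  accordingly.
- BigWig/BigBed are not written natively; convert externally if needed.
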