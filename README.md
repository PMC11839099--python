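# exclusionkit

Tools for generating and quantitatively comparing genomic **exclusion sets**
("blacklists") — BED lists of regions with anomalous short-read signal that
are removed before ChIP-seq, ATAC-seq, CUT&RUN and related analyses.

Published exclusion lists for the same assembly disagree substantially in
region count, width and genome coverage, and the callers that produce them
are sensitive to under-documented parameters. `exclusionkit` is aimed at
epigenomics practitioners and methods developers who need to (a) generate
exclusion sets from first-principles evidence — input-ChIP signal and k-mer
mappability — with every parameter explicit, and (b) measure how similar two
exclusion sets actually are, and what removing one does to downstream
signal.

## What it computes

**Three callers** (`exclusionkit.callers`):

- **High Signal (HS)** — from a peak table with fold enrichments
  (MACS narrowPeak or TSV): keep peaks with fold change strictly above
  `fc_min + 0.99 · (fc_max − fc_min)` (a percentile mode is also available),
  merge survivors within 1,000 bp, discard regions < 1,000 bp, and
  optionally union with annotated centromeres.
- **Low Mappability (LM)** — from a Umap/Bismap-style per-base mappability
  bedGraph: form the mappable universe (value > 0.01), merge it within
  1,000 bp (absorbing short unmappable speckles), invert it, merge again,
  discard regions < 1,000 bp.
- **Blacklist-style caller** — bins the genome (default 1 kb bins, 500 bp
  overlap), computes per bin the median across samples of library-size-
  normalized input coverage, flags bins above the 0.99 signal quantile
  (high signal) or below 0.5 mean mappability (low mappability), projects
  flagged bins to intervals and fuses them across gaps up to a *bridge*
  distance (default 20,000 bp). Each fused region is annotated
  `High Signal`, `Low Mappability`, or — when it contains both kinds of
  evidence — the combined `High Signal, Low Mappability`, which is never
  silently collapsed to `High Signal`.

**Two similarity coefficients** (`exclusionkit.compare`), for sets A, B with
total (collapsed) widths W(A), W(B) on a genome of size G:

- Jaccard count overlap
  `Jc(A,B) = ½·(|{a ∈ A : a∩B ≠ ∅}| + |{b ∈ B : b∩A ≠ ∅}|) / |A ∪ B|`,
  where |A ∪ B| counts coordinate-distinct records;
- Forbes width overlap `Fw(A,B) = G · W(A∩B) / (W(A) · W(B))`,
  robust to unequal list sizes (Fw > 1 means more co-occurrence than chance).

Plus pairwise matrices, distance conversion, classical (Torgerson) MDS,
Ward clustering, gap (centromere/telomere/short-arm) coverage, width
summaries, read-masking correlation deltas, and per-transcript exon
coverage with per-biotype impact summaries.

**Synthetic fixtures** (`exclusionkit.synthetic`) generate seeded small
genomes with planted artifact hotspots, low-mappability zones, gap
annotations, multi-sample reads, and peak tables, so the whole pipeline is
testable without downloads.

## Worked example

```python
from exclusionkit import *
from exclusionkit.synthetic import *
import numpy as np

spec = FixtureSpec(seed=7)            # 1.8 Mb genome, 1 hotspot, 2 LM zones
genome, gaps = make_genome(spec)

hs = call_high_signal(simulate_peaks(spec))
track = simulate_mappability(spec)
lm = call_low_mappability(track)

reads = {f"s{i}": simulate_reads(spec, i) for i in range(spec.n_samples)}
grid = make_bin_grid(genome, bin_size=1000, bin_overlap=500)
counts = np.column_stack(
    [count_reads_per_bin(r, grid).counts[:, 0] for r in reads.values()])
signal = BinnedSignal(grid, counts, tuple(reads))
bl = call_blacklist(signal, bin_mappability(track, grid))

for iv, label in zip(bl.intervals, bl.labels):
    print(f"{iv.chrom}:{iv.start}-{iv.end}\t{label}")
print("Jc(blacklist, HS) =", round(jaccard_count(bl.intervals, hs), 3))
print("Fw(blacklist, LM) =", round(forbes_width(bl.intervals, lm), 1))
cov = gap_coverage(union_with_gap_class(hs, gaps), gaps)
print("centromere coverage:", f"{100*cov['centromere']['frac_gap_bases_covered']:.1f}%")
reports = correlation_delta(reads, {"hotspot": hotspot_truth(spec)}, genome)
print("mean correlation change after masking:", round(reports["hotspot"].mean_delta, 3))
```

prints

```
chr1:200500-224500	High Signal
chr1:700000-708000	Low Mappability
chr2:500000-515000	Low Mappability
Jc(blacklist, HS) = 0.25
Fw(blacklist, LM) = 38.3
centromere coverage: 100.0%
mean correlation change after masking: -0.154
```

The caller recovers the planted 25 kb hotspot (to within one bin at each
edge) as `High Signal` and both planted low-mappability zones exactly. The
Jaccard count of 0.25 reflects record-count fragmentation (the blacklist has
three records, the HS list one; one reciprocal overlap out of four distinct
records), while the Forbes coefficient of 38.3 says the blacklist and LM
lists share bases ~38× more than expected by chance on this genome. Masking
reads in the shared hotspot lowers the mean pairwise Pearson correlation of
10 kb binned coverage by 0.154 — the artifact was inflating inter-sample
correlation.

A CLI mirrors the library:
`exclusionkit simulate | call-high-signal | call-low-mappability |
call-blacklist | compare | stats | convert | mask-correlate`
(see `exclusionkit --help`).

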