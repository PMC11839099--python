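"""Exclusion-region callers.

Three generation procedures are implemented:

* :func:`call_high_signal` — High Signal (HS) regions from input-ChIP peak
  fold enrichments: keep peaks whose fold change exceeds 99.0% of the fold
  change range (or the 99th percentile), merge within 1 kb, discard < 1 kb.
* :func:`call_low_mappability` — Low Mappability (LM) regions from a k-mer
  mappability track: build the mappable universe (value > 0.01), merge it
  within 1 kb, invert, merge again, discard < 1 kb.  Merging the universe
  first preserves mappable territory interspersed with short unmappable
  speckles.
* :func:`call_blacklist` — a Blacklist-style caller over binned input
  coverage plus binned mappability, with the corrected combined annotation:
  a merged region supported by both high-signal and low-mappability bins is
  labeled "High Signal, Low Mappability" rather than silently defaulting to
  "High Signal".
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .genome import (
    GapAnnotation,
    Genome,
    GenomeMismatchError,
    IntervalSet,
    ValueTrack,
    complement,
    filter_min_width,
    merge_within,
    union,
)

__all__ = [
    "PeakSet",
    "BinGrid",
    "BinnedSignal",
    "AnnotatedExclusionSet",
    "LABEL_HS",
    "LABEL_LM",
    "LABEL_BOTH",
    "call_high_signal",
    "union_with_gap_class",
    "call_low_mappability",
    "make_bin_grid",
    "count_reads_per_bin",
    "bin_mappability",
    "call_blacklist",
    "annotate_region",
]

LABEL_HS = "High Signal"
LABEL_LM = "Low Mappability"
LABEL_BOTH = "High Signal, Low Mappability"


@dataclass
class PeakSet:
    """Peak intervals with per-record fold enrichment (MACS column 7)."""

    intervals: IntervalSet
    fold_change: np.ndarray

    def __post_init__(self) -> None:
        self.fold_change = np.asarray(self.fold_change, dtype=float)
        if len(self.fold_change) != len(self.intervals):
            raise ValueError("one fold_change per peak record required")
        if len(self.fold_change) and (
            ~np.isfinite(self.fold_change) | (self.fold_change < 0)
        ).any():
            raise ValueError("fold changes must be finite and non-negative")

    def __len__(self) -> int:
        return len(self.intervals)


@dataclass
class BinGrid:
    """Sliding bins tiling each chromosome with step ``bin_size - bin_overlap``.

    Bin starts are multiples of the step; generation stops at the first bin
    whose untruncated end reaches the chromosome end, and a trailing
    truncated bin is kept only if it is the chromosome's only bin or at
    least one step wide.
    """

    genome: Genome
    bin_size: int
    bin_overlap: int
    chroms: np.ndarray  # per-bin chromosome name
    starts: np.ndarray
    ends: np.ndarray

    @property
    def step(self) -> int:
        return self.bin_size - self.bin_overlap

    @property
    def n_bins(self) -> int:
        return len(self.starts)

    def intervals_for(self, flags: np.ndarray) -> IntervalSet:
        """Project flagged bins to an overlap-collapsed interval set."""
        flags = np.asarray(flags, dtype=bool)
        sel = pd.DataFrame(
            {"chrom": self.chroms[flags], "start": self.starts[flags], "end": self.ends[flags]}
        )
        return merge_within(IntervalSet(self.genome, sel), maxgap=0)


def make_bin_grid(genome: Genome, bin_size: int, bin_overlap: int = 0) -> BinGrid:
    if not 0 <= bin_overlap < bin_size:
        raise ValueError("require 0 <= bin_overlap < bin_size")
    step = bin_size - bin_overlap
    chroms, starts, ends = [], [], []
    for name, length in genome.chromosomes:
        s = 0
        first = True
        while True:
            e = min(s + bin_size, length)
            truncated = e < s + bin_size
            if truncated and not first and (e - s) < step:
                break
            chroms.append(name)
            starts.append(s)
            ends.append(e)
            first = False
            if s + bin_size >= length:
                break
            s += step
    return BinGrid(
        genome,
        bin_size,
        bin_overlap,
        np.asarray(chroms, dtype=object),
        np.asarray(starts, dtype=np.int64),
        np.asarray(ends, dtype=np.int64),
    )


@dataclass
class BinnedSignal:
    """Per-bin read counts for one or more samples on a shared grid."""

    grid: BinGrid
    counts: np.ndarray  # (n_bins, n_samples)
    sample_names: tuple[str, ...]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim == 1:
            self.counts = self.counts[:, None]
        if self.counts.shape != (self.grid.n_bins, len(self.sample_names)):
            raise ValueError("counts must be (n_bins, n_samples)")
        if (self.counts < 0).any() or not np.isfinite(self.counts).all():
            raise ValueError("counts must be finite and non-negative")


@dataclass
class AnnotatedExclusionSet:
    """Non-overlapping exclusion regions labeled HS / LM / combined."""

    intervals: IntervalSet
    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.intervals):
            raise ValueError("one label per region required")
        bad = set(self.labels) - {LABEL_HS, LABEL_LM, LABEL_BOTH}
        if bad:
            raise ValueError(f"unknown labels: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.intervals)


def call_high_signal(
    peaks: PeakSet,
    range_fraction: float = 0.99,
    merge_gap: int = 1000,
    min_width: int = 1000,
    mode: str = "range",
) -> IntervalSet:
    """High Signal regions from peak fold enrichments.

    ``mode="range"`` keeps peaks with fold change strictly above
    ``fc_min + range_fraction * (fc_max - fc_min)``; ``mode="percentile"``
    thresholds at the ``range_fraction`` quantile of the fold changes
    (linear interpolation).  Survivors are merged within ``merge_gap`` and
    regions narrower than ``min_width`` discarded.
    """
    if len(peaks) == 0:
        raise ValueError("cannot call High Signal regions from an empty peak set")
    fc = peaks.fold_change
    if mode == "range":
        t = fc.min() + range_fraction * (fc.max() - fc.min())
    elif mode == "percentile":
        t = float(np.quantile(fc, range_fraction))
    else:
        raise ValueError("mode must be 'range' or 'percentile'")
    keep = IntervalSet(peaks.intervals.genome, peaks.intervals.df[fc > t])
    return filter_min_width(merge_within(keep, merge_gap), min_width)


def union_with_gap_class(
    s: IntervalSet, gaps: GapAnnotation, gap_class: str = "centromere"
) -> IntervalSet:
    """Overlap-collapsed union of a region set with one assembly gap class."""
    return union(s, gaps[gap_class])


def call_low_mappability(
    track: ValueTrack,
    genome: Optional[Genome] = None,
    threshold: float = 0.01,
    merge_gap: int = 1000,
    min_width: int = 1000,
) -> IntervalSet:
    """Low Mappability regions from a per-base mappability track.

    Five steps: (1) mappable universe = positions with value strictly above
    ``threshold``; (2) merge the universe within ``merge_gap`` (absorbs short
    unmappable speckles); (3) invert; (4) merge within ``merge_gap``;
    (5) discard regions narrower than ``min_width``.
    """
    genome = genome or track.genome
    if genome != track.genome:
        raise GenomeMismatchError("track is bound to a different genome")
    if ((track.df["value"] < 0) | (track.df["value"] > 1)).any():
        raise ValueError("mappability values must lie in [0, 1]")
    universe = merge_within(track.threshold_above(threshold), merge_gap)
    out = merge_within(complement(universe, genome), merge_gap)
    return filter_min_width(out, min_width)


def count_reads_per_bin(
    reads: pd.DataFrame, grid: BinGrid, sample_names: Sequence[str] = ("sample",)
) -> BinnedSignal:
    """Count reads per bin by midpoint membership.

    A read increments every bin whose half-open span contains its midpoint
    ``(start + end) // 2``; with overlapping bins that is more than one bin,
    and a midpoint on a shared boundary belongs to the bin starting there.
    """
    counts = _midpoint_counts(reads, grid)
    return BinnedSignal(grid, counts, tuple(sample_names))


def _midpoint_counts(reads: pd.DataFrame, grid: BinGrid) -> np.ndarray:
    lengths = grid.genome.lengths
    counts = np.zeros(grid.n_bins, dtype=np.int64)
    for chrom, sub in reads.groupby("chrom", sort=False):
        if chrom not in lengths:
            raise KeyError(f"read on chromosome {chrom!r} absent from genome")
        if (sub["start"] < 0).any() or (sub["end"] > lengths[chrom]).any():
            raise ValueError(f"read outside chromosome bounds on {chrom}")
        mids = np.sort(((sub["start"] + sub["end"]) // 2).to_numpy())
        mask = grid.chroms == chrom
        lo = np.searchsorted(mids, grid.starts[mask], side="left")
        hi = np.searchsorted(mids, grid.ends[mask], side="left")
        counts[mask] += hi - lo
    return counts


def bin_mappability(track: ValueTrack, grid: BinGrid) -> np.ndarray:
    """Per-bin mean mappability (implicit zeros included)."""
    if track.genome != grid.genome:
        raise GenomeMismatchError("track and grid on different genomes")
    out = np.zeros(grid.n_bins, dtype=float)
    for chrom in grid.genome.names:
        mask = grid.chroms == chrom
        if mask.any():
            out[mask] = track.mean_over(chrom, grid.starts[mask], grid.ends[mask])
    return out


def annotate_region(has_hs_bins: bool, has_lm_bins: bool) -> str:
    """Label a merged region from the evidence classes of its bins."""
    if has_hs_bins and has_lm_bins:
        return LABEL_BOTH
    if has_hs_bins:
        return LABEL_HS
    if has_lm_bins:
        return LABEL_LM
    raise ValueError("region with neither high-signal nor low-mappability bins")


def call_blacklist(
    signal: BinnedSignal,
    bin_mapp: np.ndarray,
    signal_quantile: float = 0.99,
    mapp_threshold: float = 0.5,
    bridge: int = 20000,
) -> AnnotatedExclusionSet:
    """Blacklist-style caller with the combined HS/LM annotation.

    Per bin, the aggregate statistic is the median across samples of the
    library-size-normalized count.  Bins whose aggregate strictly exceeds
    the ``signal_quantile`` quantile of all aggregates are high-signal;
    bins with mean mappability below ``mapp_threshold`` are low-mappability.
    Flagged bins are projected to intervals and fused across gaps of at
    most ``bridge`` bases; each fused region is labeled by which evidence
    classes it contains, keeping the combined label distinct.
    """
    bin_mapp = np.asarray(bin_mapp, dtype=float)
    if bin_mapp.shape != (signal.grid.n_bins,):
        raise ValueError("bin_mapp must align with the signal grid")
    totals = signal.counts.sum(axis=0).astype(float)
    safe = np.where(totals > 0, totals, 1.0)
    norm = signal.counts / safe
    aggregate = np.median(norm, axis=1)
    cutoff = float(np.quantile(aggregate, signal_quantile))
    hs = aggregate > cutoff
    lm = bin_mapp < mapp_threshold
    flagged = hs | lm
    if not flagged.any():
        return AnnotatedExclusionSet(IntervalSet.empty(signal.grid.genome), ())

    regions = merge_within(signal.grid.intervals_for(flagged), bridge)
    grid = signal.grid
    labels = []
    for row in regions.df.itertuples(index=False):
        inside = (
            (grid.chroms == row.chrom)
            & (grid.starts < row.end)
            & (grid.ends > row.start)
        )
        labels.append(annotate_region(bool((hs & inside).any()), bool((lm & inside).any())))
    return AnnotatedExclusionSet(regions, tuple(labels))
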