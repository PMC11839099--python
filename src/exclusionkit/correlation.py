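"""Read-masking correlation analysis.

Measures how removing reads that overlap an exclusion set changes the
pairwise Pearson correlation structure of binned coverage across samples —
the before/after comparison used to judge whether an exclusion set actually
removes shared artifact signal.  Masking operates at the read level: a read
is dropped when its reference span overlaps at least one base of the
exclusion set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
from scipy.spatial.distance import pdist

from .genome import Genome, GenomeMismatchError, IntervalSet
from .callers import BinnedSignal, _midpoint_counts, make_bin_grid

logger = logging.getLogger(__name__)

__all__ = [
    "CorrelationReport",
    "remove_reads_overlapping",
    "fixed_window_counts",
    "pearson_matrix",
    "correlation_delta",
]


@dataclass
class CorrelationReport:
    """Before/after/delta Pearson matrices for one exclusion set."""

    sample_names: tuple[str, ...]
    corr_before: np.ndarray
    corr_after: np.ndarray
    leaf_order: np.ndarray = field(default=None)  # complete-linkage ordering of delta rows

    @property
    def delta(self) -> np.ndarray:
        return self.corr_after - self.corr_before

    @property
    def mean_delta(self) -> float:
        """Mean off-diagonal correlation change."""
        n = len(self.sample_names)
        off = ~np.eye(n, dtype=bool)
        return float(self.delta[off].mean())

    @property
    def per_sample_mean_delta(self) -> dict[str, float]:
        n = len(self.sample_names)
        off = ~np.eye(n, dtype=bool)
        means = np.where(off, self.delta, np.nan)
        return {
            name: float(np.nanmean(means[i]))
            for i, name in enumerate(self.sample_names)
        }


def remove_reads_overlapping(reads: pd.DataFrame, exclusion: IntervalSet) -> pd.DataFrame:
    """Drop every read whose span overlaps >= 1 base of the exclusion set."""
    reads = reads.reset_index(drop=True)
    merged = exclusion.merged_arrays()
    keep = np.ones(len(reads), dtype=bool)
    lengths = exclusion.genome.lengths
    for chrom, sub in reads.groupby("chrom", sort=False):
        if chrom not in lengths:
            raise GenomeMismatchError(f"read chromosome {chrom!r} absent from genome")
        if chrom not in merged:
            continue
        ms, me = merged[chrom]
        if len(ms) == 0:
            continue
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        idx = np.searchsorted(ms, ends, side="left")
        hit = (idx > 0) & (me[np.maximum(idx - 1, 0)] > starts)
        keep[sub.index] = ~hit
    return reads[keep]


def fixed_window_counts(
    reads_by_sample: dict[str, pd.DataFrame], genome: Genome, window: int = 10000
) -> BinnedSignal:
    """Midpoint read counts in non-overlapping tiling windows, all samples."""
    if window <= 0:
        raise ValueError("window must be positive")
    grid = make_bin_grid(genome, window, 0)
    names = tuple(reads_by_sample)
    counts = np.column_stack(
        [_midpoint_counts(reads_by_sample[n], grid) for n in names]
    )
    return BinnedSignal(grid, counts, names)


def pearson_matrix(signal: BinnedSignal) -> np.ndarray:
    """Pairwise Pearson correlation of per-bin counts across samples.

    A zero-variance sample correlates with nothing; its off-diagonal entries
    are reported as 0 (with a warning) rather than NaN, and the diagonal
    stays 1.
    """
    x = signal.counts.astype(float)
    if x.shape[1] < 2:
        raise ValueError("need at least two samples")
    sd = x.std(axis=0)
    flat = sd == 0
    if flat.any():
        logger.warning(
            "zero-variance samples %s: correlations reported as 0",
            [signal.sample_names[i] for i in np.flatnonzero(flat)],
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(x, rowvar=False)
    r = np.where(np.isfinite(r), r, 0.0)
    np.fill_diagonal(r, 1.0)
    return r


def correlation_delta(
    reads_by_sample: dict[str, pd.DataFrame],
    exclusion_sets: dict[str, IntervalSet],
    genome: Genome,
    window: int = 10000,
) -> dict[str, CorrelationReport]:
    """Before/after correlation reports for each named exclusion set.

    Returned in decreasing order of |mean correlation change| so the most
    impactful exclusion set comes first.  Sample rows of each delta matrix
    are ordered by complete-linkage clustering with Euclidean distance.
    """
    before = pearson_matrix(fixed_window_counts(reads_by_sample, genome, window))
    names = tuple(reads_by_sample)
    reports = {}
    for set_name, excl in exclusion_sets.items():
        masked = {
            n: remove_reads_overlapping(reads, excl)
            for n, reads in reads_by_sample.items()
        }
        after = pearson_matrix(fixed_window_counts(masked, genome, window))
        delta = after - before
        if len(names) > 2 and not np.allclose(delta, delta[0, 0]):
            z = sch.linkage(pdist(delta, metric="euclidean"), method="complete")
            order = sch.leaves_list(z)
        else:
            order = np.arange(len(names))
        reports[set_name] = CorrelationReport(names, before, after, order)
    return dict(
        sorted(reports.items(), key=lambda kv: abs(kv[1].mean_delta), reverse=True)
    )
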