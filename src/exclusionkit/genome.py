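"""Genome model and interval algebra.

All coordinates follow the BED convention: 0-based, half-open ``[start, end)``.
The central container is :class:`IntervalSet`, a genome-bound, sorted list of
records.  Record identity (name/score) is preserved by the readers; set
operations (merge, complement, intersect) work on the overlap-collapsed view,
while per-record statistics (``width_summary``, ``count_overlapping``) work on
the raw records.  This distinction matters for the two similarity metrics
built on top: the Jaccard count overlap counts records, the Forbes width
overlap measures collapsed base pairs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Genome",
    "Interval",
    "IntervalSet",
    "ValueTrack",
    "GapAnnotation",
    "GenomeMismatchError",
    "merge_within",
    "filter_min_width",
    "complement",
    "intersect",
    "union",
    "count_overlapping",
    "total_width",
    "width_summary",
]


class GenomeMismatchError(ValueError):
    """Raised when two interval sets bound to different genomes are combined."""


@dataclass(frozen=True)
class Genome:
    """An ordered list of chromosomes with lengths.

    The chromosome order (typically the order of the ``chrom.sizes`` file)
    defines the sort order of every :class:`IntervalSet` on this genome and
    makes all outputs deterministic.  ``total_size`` is the genome size G
    entering the Forbes width overlap.
    """

    chromosomes: tuple[tuple[str, int], ...]

    def __post_init__(self) -> None:
        names = [c for c, _ in self.chromosomes]
        if len(set(names)) != len(names):
            raise ValueError("duplicate chromosome names in genome")
        for name, length in self.chromosomes:
            if length <= 0:
                raise ValueError(f"non-positive length for chromosome {name!r}")

    @property
    def total_size(self) -> int:
        return int(sum(length for _, length in self.chromosomes))

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(name for name, _ in self.chromosomes)

    @property
    def lengths(self) -> dict[str, int]:
        return {name: int(length) for name, length in self.chromosomes}

    def order(self, chrom: str) -> int:
        try:
            return self.names.index(chrom)
        except ValueError:
            raise KeyError(f"chromosome {chrom!r} not in genome") from None

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.names

    @classmethod
    def from_dict(cls, sizes: Mapping[str, int]) -> "Genome":
        return cls(tuple((str(k), int(v)) for k, v in sizes.items()))


@dataclass(frozen=True)
class Interval:
    """A half-open genomic interval ``[start, end)`` with optional name/score."""

    chrom: str
    start: int
    end: int
    name: Optional[str] = None
    score: Optional[float] = None

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}"
            )

    @property
    def width(self) -> int:
        return self.end - self.start


_COLUMNS = ["chrom", "start", "end", "name", "score"]


class IntervalSet:
    """A sorted, genome-bound collection of intervals.

    Backed by a pandas DataFrame with columns chrom/start/end/name/score.
    Sorting is by (genome chromosome order, start, end); construction
    validates that every record lies within its chromosome.
    """

    def __init__(self, genome: Genome, df: pd.DataFrame):
        self.genome = genome
        df = df.copy()
        for col in ("name", "score"):
            if col not in df.columns:
                df[col] = None
        df = df[_COLUMNS]
        df["start"] = df["start"].astype(np.int64)
        df["end"] = df["end"].astype(np.int64)
        lengths = genome.lengths
        for chrom, start, end in zip(df["chrom"], df["start"], df["end"]):
            if chrom not in lengths:
                raise KeyError(f"chromosome {chrom!r} not in genome")
            if not 0 <= start < end <= lengths[chrom]:
                raise ValueError(
                    f"interval {chrom}:{start}-{end} outside chromosome bounds"
                )
        order = {name: i for i, name in enumerate(genome.names)}
        df["_ord"] = df["chrom"].map(order)
        df = df.sort_values(["_ord", "start", "end"], kind="mergesort")
        df = df.drop(columns="_ord").reset_index(drop=True)
        self.df = df
        self._merged_cache: Optional[dict[str, tuple[np.ndarray, np.ndarray]]] = None

    # -- construction helpers -------------------------------------------------

    @classmethod
    def from_intervals(cls, genome: Genome, intervals: Iterable[Interval]) -> "IntervalSet":
        rows = [(iv.chrom, iv.start, iv.end, iv.name, iv.score) for iv in intervals]
        df = pd.DataFrame(rows, columns=_COLUMNS)
        return cls(genome, df)

    @classmethod
    def from_tuples(
        cls, genome: Genome, tuples: Iterable[Sequence]
    ) -> "IntervalSet":
        """Build from (chrom, start, end[, name[, score]]) tuples."""
        rows = []
        for t in tuples:
            t = list(t) + [None] * (5 - len(t))
            rows.append(tuple(t[:5]))
        return cls(genome, pd.DataFrame(rows, columns=_COLUMNS))

    @classmethod
    def empty(cls, genome: Genome) -> "IntervalSet":
        return cls(genome, pd.DataFrame(columns=_COLUMNS))

    # -- basic protocol -------------------------------------------------------

    def __len__(self) -> int:
        return len(self.df)

    def __iter__(self):
        for row in self.df.itertuples(index=False):
            yield Interval(row.chrom, int(row.start), int(row.end), row.name, row.score)

    def __eq__(self, other) -> bool:
        if not isinstance(other, IntervalSet):
            return NotImplemented
        a = self.df[["chrom", "start", "end"]]
        b = other.df[["chrom", "start", "end"]]
        return self.genome == other.genome and a.equals(b)

    def __repr__(self) -> str:
        return f"IntervalSet({len(self)} records, {total_width(self)} bp collapsed)"

    @property
    def widths(self) -> np.ndarray:
        return (self.df["end"] - self.df["start"]).to_numpy()

    # -- collapsed view -------------------------------------------------------

    def merged_arrays(self) -> dict[str, tuple[np.ndarray, np.ndarray]]:
        """Per-chromosome (starts, ends) of the overlap-collapsed view.

        Abutting records are fused (gap 0).  Cached; the DataFrame is treated
        as immutable after construction.
        """
        if self._merged_cache is None:
            self._merged_cache = {
                chrom: _sweep_merge(
                    sub["start"].to_numpy(), sub["end"].to_numpy(), maxgap=0
                )
                for chrom, sub in self.df.groupby("chrom", sort=False)
            }
        return self._merged_cache

    def _replace(self, per_chrom: dict[str, tuple[np.ndarray, np.ndarray]]) -> "IntervalSet":
        rows = []
        for chrom in self.genome.names:
            if chrom in per_chrom:
                starts, ends = per_chrom[chrom]
                rows.extend((chrom, int(s), int(e)) for s, e in zip(starts, ends))
        out = IntervalSet.from_tuples(self.genome, rows)
        return out


def _sweep_merge(starts: np.ndarray, ends: np.ndarray, maxgap: int) -> tuple[np.ndarray, np.ndarray]:
    """Merge sorted intervals, bridging gaps of at most ``maxgap`` bases."""
    if len(starts) == 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    idx = np.lexsort((ends, starts))
    starts, ends = starts[idx], ends[idx]
    out_s, out_e = [int(starts[0])], [int(ends[0])]
    for s, e in zip(starts[1:], ends[1:]):
        if s - out_e[-1] <= maxgap:
            out_e[-1] = max(out_e[-1], int(e))
        else:
            out_s.append(int(s))
            out_e.append(int(e))
    return np.asarray(out_s, dtype=np.int64), np.asarray(out_e, dtype=np.int64)


def merge_within(s: IntervalSet, maxgap: int) -> IntervalSet:
    """Collapse overlaps and bridge gaps of at most ``maxgap`` bp.

    ``maxgap=0`` merges overlapping and abutting intervals only.  The
    operation is idempotent at fixed ``maxgap`` and monotone in ``maxgap``.
    """
    if maxgap < 0:
        raise ValueError("maxgap must be >= 0")
    per_chrom = {
        chrom: _sweep_merge(sub["start"].to_numpy(), sub["end"].to_numpy(), maxgap)
        for chrom, sub in s.df.groupby("chrom", sort=False)
    }
    return s._replace(per_chrom)


def filter_min_width(s: IntervalSet, min_width: int) -> IntervalSet:
    """Keep records of width >= ``min_width`` ("smaller than" is discarded)."""
    if min_width < 0:
        raise ValueError("min_width must be >= 0")
    keep = s.df[(s.df["end"] - s.df["start"]) >= min_width]
    return IntervalSet(s.genome, keep)


def complement(s: IntervalSet, genome: Optional[Genome] = None) -> IntervalSet:
    """Set-theoretic complement within chromosome bounds."""
    genome = genome or s.genome
    if genome != s.genome:
        raise GenomeMismatchError("set is bound to a different genome")
    merged = s.merged_arrays()
    per_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom, length in genome.chromosomes:
        starts, ends = merged.get(
            chrom, (np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64))
        )
        gap_starts = np.concatenate(([0], ends))
        gap_ends = np.concatenate((starts, [length]))
        keep = gap_starts < gap_ends
        per_chrom[chrom] = (gap_starts[keep], gap_ends[keep])
    return s._replace(per_chrom)


def _check_same_genome(a: IntervalSet, b: IntervalSet) -> None:
    if a.genome != b.genome:
        raise GenomeMismatchError("interval sets are bound to different genomes")


def intersect(a: IntervalSet, b: IntervalSet) -> IntervalSet:
    """Base-level intersection of the overlap-collapsed views."""
    _check_same_genome(a, b)
    am, bm = a.merged_arrays(), b.merged_arrays()
    per_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom in am:
        if chrom not in bm:
            continue
        as_, ae = am[chrom]
        bs, be = bm[chrom]
        out_s, out_e = [], []
        i = j = 0
        while i < len(as_) and j < len(bs):
            s = max(as_[i], bs[j])
            e = min(ae[i], be[j])
            if s < e:
                out_s.append(int(s))
                out_e.append(int(e))
            if ae[i] < be[j]:
                i += 1
            else:
                j += 1
        per_chrom[chrom] = (
            np.asarray(out_s, dtype=np.int64),
            np.asarray(out_e, dtype=np.int64),
        )
    return a._replace(per_chrom)


def union(a: IntervalSet, b: IntervalSet) -> IntervalSet:
    """Overlap-collapsed union of two sets."""
    _check_same_genome(a, b)
    df = pd.concat(
        [a.df[["chrom", "start", "end"]], b.df[["chrom", "start", "end"]]],
        ignore_index=True,
    )
    return merge_within(IntervalSet(a.genome, df), maxgap=0)


def count_overlapping(a: IntervalSet, b: IntervalSet) -> int:
    """Number of raw A records overlapping >= 1 base of B (not symmetric)."""
    _check_same_genome(a, b)
    bm = b.merged_arrays()
    n = 0
    for chrom, sub in a.df.groupby("chrom", sort=False):
        if chrom not in bm:
            continue
        bs, be = bm[chrom]
        if len(bs) == 0:
            continue
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        # merged intervals have strictly increasing starts and ends, so the
        # candidate with the largest end among those starting before a.end is
        # the last one; an overlap exists iff its end exceeds a.start
        idx = np.searchsorted(bs, ends, side="left")
        has = (idx > 0) & (be[np.maximum(idx - 1, 0)] > starts)
        n += int(has.sum())
    return n


def total_width(s: IntervalSet) -> int:
    """Total bases covered by the overlap-collapsed set, W(S)."""
    return int(
        sum((ends - starts).sum() for starts, ends in s.merged_arrays().values())
    )


def width_summary(s: IntervalSet) -> dict[str, float]:
    """Count/min/mean/median/max over raw record widths (not collapsed)."""
    if len(s) == 0:
        raise ValueError("width_summary of an empty set is undefined")
    w = s.widths
    return {
        "count": int(len(w)),
        "min": int(w.min()),
        "mean": float(w.mean()),
        "median": float(np.median(w)),
        "max": int(w.max()),
    }


class ValueTrack:
    """A stepwise per-base value track (bedGraph semantics).

    Steps are non-overlapping within a chromosome; any base not covered by a
    step has implicit value 0.  Used for Umap/Bismap-style k-mer mappability
    (values in [0, 1], 1 = uniquely mappable) and for coverage signal.
    """

    def __init__(self, genome: Genome, df: pd.DataFrame, *, unit_interval: bool = False):
        self.genome = genome
        df = df[["chrom", "start", "end", "value"]].copy()
        df["start"] = df["start"].astype(np.int64)
        df["end"] = df["end"].astype(np.int64)
        df["value"] = df["value"].astype(float)
        lengths = genome.lengths
        order = {name: i for i, name in enumerate(genome.names)}
        df["_ord"] = df["chrom"].map(order)
        if df["_ord"].isna().any():
            bad = df.loc[df["_ord"].isna(), "chrom"].iloc[0]
            raise KeyError(f"chromosome {bad!r} not in genome")
        df = df.sort_values(["_ord", "start"], kind="mergesort").drop(columns="_ord")
        df = df.reset_index(drop=True)
        for chrom, sub in df.groupby("chrom", sort=False):
            starts = sub["start"].to_numpy()
            ends = sub["end"].to_numpy()
            if (starts >= ends).any() or (ends > lengths[chrom]).any() or (starts < 0).any():
                raise ValueError(f"step outside bounds on {chrom}")
            if (starts[1:] < ends[:-1]).any():
                raise ValueError(f"overlapping steps on {chrom}")
        if unit_interval and ((df["value"] < 0) | (df["value"] > 1)).any():
            raise ValueError("track values outside [0, 1]")
        self.df = df

    def threshold_above(self, threshold: float) -> IntervalSet:
        """Positions with value strictly greater than ``threshold``.

        With a non-negative threshold the implicit-zero territory never
        qualifies, so the result is just the qualifying steps.
        """
        if threshold < 0:
            raise ValueError("threshold must be >= 0 (implicit zeros would qualify)")
        keep = self.df[self.df["value"] > threshold]
        return IntervalSet(
            self.genome, keep.rename(columns={"value": "score"})[["chrom", "start", "end"]]
        )

    def mean_over(self, chrom: str, starts: np.ndarray, ends: np.ndarray) -> np.ndarray:
        """Mean per-base value over [start, end) windows, implicit zeros included."""
        sub = self.df[self.df["chrom"] == chrom]
        s = sub["start"].to_numpy()
        e = sub["end"].to_numpy()
        v = sub["value"].to_numpy()
        # prefix integral of the step function at the step breakpoints
        areas = np.concatenate(([0.0], np.cumsum(v * (e - s))))

        def integral(x: np.ndarray) -> np.ndarray:
            i = np.searchsorted(s, x, side="right")
            base = areas[i]
            # inside step i-1 if x < e[i-1]: subtract the part beyond x
            inside = (i > 0) & (x < e[np.maximum(i - 1, 0)]) if len(e) else np.zeros(len(x), bool)
            corr = np.zeros(len(x))
            if inside.any():
                j = i[inside] - 1
                corr[inside] = v[j] * (e[j] - x[inside])
            return base - corr

        starts = np.asarray(starts, dtype=np.int64)
        ends = np.asarray(ends, dtype=np.int64)
        return (integral(ends) - integral(starts)) / (ends - starts)


@dataclass
class GapAnnotation:
    """Assembly gap classes (centromere / telomere / short arm) as interval sets."""

    classes: dict[str, IntervalSet] = field(default_factory=dict)

    STANDARD = ("centromere", "telomere", "short_arm")

    def __getitem__(self, label: str) -> IntervalSet:
        if label not in self.classes:
            raise KeyError(f"gap class {label!r} not annotated")
        return self.classes[label]

    def __contains__(self, label: str) -> bool:
        return label in self.classes

    def labels(self) -> tuple[str, ...]:
        return tuple(self.classes)
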