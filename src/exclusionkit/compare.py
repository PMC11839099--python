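"""Quantitative comparison of exclusion sets.

Two similarity coefficients tailored to genomic region lists:

* Jaccard count overlap ``Jc(A, B)`` — the mean of the two directed
  overlapping-record counts divided by the number of coordinate-distinct
  records in the union of the two lists.  Sensitive to how the lists are
  fragmented into records.
* Forbes width overlap ``Fw(A, B) = G * W(A∩B) / (W(A) * W(B))`` — a
  base-pair coefficient normalized by genome size G, robust to unequal list
  sizes (Fw > 1 means the lists co-occur more than expected by chance).

Similarity matrices are converted to distances and embedded with classical
(Torgerson) multidimensional scaling or clustered with Ward linkage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import scipy.cluster.hierarchy as sch
from scipy.spatial.distance import squareform

from .genome import (
    GapAnnotation,
    IntervalSet,
    count_overlapping,
    intersect,
    total_width,
)

logger = logging.getLogger(__name__)

__all__ = [
    "OverlapMatrix",
    "DistanceMatrix",
    "jaccard_count",
    "forbes_width",
    "overlap_summary",
    "pairwise_matrix",
    "gap_coverage",
    "to_distance",
    "classical_mds",
    "ward_clustering",
    "reciprocal_overlaps",
]


@dataclass
class OverlapMatrix:
    labels: tuple[str, ...]
    values: np.ndarray
    metric: str  # "jaccard_count" | "forbes_width"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape must match labels")
        if not np.allclose(self.values, self.values.T):
            raise ValueError("overlap matrix must be symmetric")


@dataclass
class DistanceMatrix:
    labels: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape must match labels")
        if not np.allclose(self.values, self.values.T) or (self.values < 0).any():
            raise ValueError("distances must be symmetric and non-negative")
        if not np.allclose(np.diag(self.values), 0):
            raise ValueError("distance diagonal must be zero")


def _n_unique_union(a: IntervalSet, b: IntervalSet) -> int:
    recs = {
        (row.chrom, int(row.start), int(row.end))
        for s in (a, b)
        for row in s.df.itertuples(index=False)
    }
    return len(recs)


def _dedup_records(s: IntervalSet) -> IntervalSet:
    return IntervalSet(s.genome, s.df.drop_duplicates(subset=["chrom", "start", "end"]))


def jaccard_count(a: IntervalSet, b: IntervalSet) -> float:
    """Jaccard count overlap: mean reciprocal overlapping-record count over
    the number of unique records in the union.  Both sets empty -> 0.

    Coordinate-exact duplicate records are counted once, within a list and
    across the two lists, which keeps the coefficient in [0, 1] with
    Jc(A, A) = 1.
    """
    n_union = _n_unique_union(a, b)
    if n_union == 0:
        return 0.0
    da, db = _dedup_records(a), _dedup_records(b)
    num = 0.5 * (count_overlapping(da, db) + count_overlapping(db, da))
    return num / n_union


def forbes_width(a: IntervalSet, b: IntervalSet, genome=None) -> float:
    """Forbes width overlap G * W(A∩B) / (W(A) * W(B))."""
    genome = genome or a.genome
    wa, wb = total_width(a), total_width(b)
    if wa == 0 or wb == 0:
        raise ValueError("Forbes width overlap is undefined for empty sets")
    return genome.total_size * total_width(intersect(a, b)) / (wa * wb)


def overlap_summary(a: IntervalSet, b: IntervalSet) -> dict[str, float]:
    """Directed overlap of A with B: record counts and base-pair widths.

    Reports the number and fraction of A records touching B, and the
    intersected width in bases and as a fraction of W(A).
    """
    w_int = total_width(intersect(a, b))
    n_over = count_overlapping(a, b)
    if len(a) == 0 or total_width(a) == 0:
        logger.warning("overlap_summary of an empty A set; fractions reported as 0")
        return {
            "n_A_overlapping_B": 0,
            "frac_A_count": 0.0,
            "w_intersect": 0,
            "frac_A_width": 0.0,
        }
    return {
        "n_A_overlapping_B": int(n_over),
        "frac_A_count": n_over / len(a),
        "w_intersect": int(w_int),
        "frac_A_width": w_int / total_width(a),
    }


def pairwise_matrix(sets: dict[str, IntervalSet], metric: str = "jaccard_count") -> OverlapMatrix:
    """Symmetric all-vs-all similarity matrix over named sets.

    The diagonal is the self-similarity: 1 for Jaccard, G/W(S) for Forbes.
    """
    if len(sets) < 2:
        raise ValueError("need at least two sets to compare")
    labels = tuple(sets)
    items = list(sets.values())
    n = len(items)
    m = np.zeros((n, n))
    for i in range(n):
        for j in range(i, n):
            if metric == "jaccard_count":
                v = jaccard_count(items[i], items[j])
            elif metric == "forbes_width":
                v = forbes_width(items[i], items[j])
            else:
                raise ValueError("metric must be 'jaccard_count' or 'forbes_width'")
            m[i, j] = m[j, i] = v
    return OverlapMatrix(labels, m, metric)


def gap_coverage(s: IntervalSet, gaps: GapAnnotation) -> dict[str, dict[str, float]]:
    """Per gap class: regions of ``s`` touching the class and the fraction
    of the class's bases the set covers."""
    out = {}
    for label in gaps.labels():
        cls = gaps[label]
        w_cls = total_width(cls)
        if w_cls == 0:
            raise ValueError(f"gap class {label!r} has zero width")
        out[label] = {
            "n_regions_overlapping": int(count_overlapping(s, cls)),
            "frac_gap_bases_covered": total_width(intersect(s, cls)) / w_cls,
        }
    return out


def to_distance(m: OverlapMatrix) -> DistanceMatrix:
    """Convert a similarity matrix to a distance matrix.

    Jaccard values are already in [0, 1]: d = 1 - Jc.  Forbes values are
    unbounded, so they are scaled to [0, 1] by the matrix maximum first.
    The diagonal is forced to zero.
    """
    v = m.values.astype(float).copy()
    if m.metric == "forbes_width":
        mx = v.max()
        if mx > 0:
            v = v / mx
    d = 1.0 - v
    np.fill_diagonal(d, 0.0)
    d = np.clip((d + d.T) / 2, 0.0, None)
    return DistanceMatrix(m.labels, d)


def classical_mds(d: DistanceMatrix, k: int = 2) -> np.ndarray:
    """Classical (Torgerson) MDS: double-center the squared distances and
    take the top-k eigenpairs; negative eigenvalues are clipped to zero.

    The returned (n, k) coordinates are deterministic: each axis's sign is
    fixed so its largest-magnitude coordinate is positive.
    """
    n = len(d.labels)
    if n < k + 1:
        raise ValueError(f"need at least {k + 1} points for {k}-dimensional MDS")
    d2 = d.values**2
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ d2 @ j
    eigval, eigvec = np.linalg.eigh(b)
    idx = np.argsort(eigval)[::-1][:k]
    lam = np.clip(eigval[idx], 0.0, None)
    coords = eigvec[:, idx] * np.sqrt(lam)
    for axis in range(k):
        col = coords[:, axis]
        if len(col) and col[np.argmax(np.abs(col))] < 0:
            coords[:, axis] = -col
    return coords


def ward_clustering(d: DistanceMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Ward hierarchical clustering of a distance matrix.

    Returns (linkage matrix in scipy format, leaf order).  Uses the Ward.D2
    convention (squared-distance updates) via scipy's linkage on the
    condensed distances.
    """
    if len(d.labels) < 2:
        raise ValueError("need at least two points to cluster")
    z = sch.linkage(squareform(d.values, checks=False), method="ward")
    return z, sch.leaves_list(z)


def linkage_to_newick(z: np.ndarray, labels) -> str:
    """Render a scipy linkage matrix as a Newick string with branch lengths."""
    tree = sch.to_tree(z)

    def rec(node, parent_height):
        length = parent_height - node.dist
        if node.is_leaf():
            return f"{labels[node.id]}:{length:g}"
        left = rec(node.left, node.dist)
        right = rec(node.right, node.dist)
        return f"({left},{right}):{length:g}"

    return rec(tree, tree.dist) + ";"


def reciprocal_overlaps(called: IntervalSet, truth: IntervalSet) -> list[float]:
    """Best per-truth-region reciprocal overlap with any called region.

    For each (collapsed) truth region, the maximum over called regions of
    ``min(overlap / called_width, overlap / truth_width)``; 0 when nothing
    overlaps.  Used to score planted-truth recovery.
    """
    cm = called.merged_arrays()
    out = []
    for chrom, (ts, te) in truth.merged_arrays().items():
        cs, ce = cm.get(chrom, (np.empty(0, np.int64), np.empty(0, np.int64)))
        for s, e in zip(ts, te):
            best = 0.0
            for s2, e2 in zip(cs, ce):
                ov = min(e, e2) - max(s, s2)
                if ov > 0:
                    best = max(best, min(ov / (e2 - s2), ov / (e - s)))
            out.append(best)
    return out
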