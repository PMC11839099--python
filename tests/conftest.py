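import numpy as np
import pytest

from exclusionkit.genome import Genome, IntervalSet


@pytest.fixture
def toy_genome() -> Genome:
    return Genome((("chr1", 1000), ("chr2", 500)))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)


# -- per-base bitmap oracle ---------------------------------------------------
# Independent reference for the interval algebra: explicit boolean masks over
# every base of a small genome.


def bitmap(s: IntervalSet) -> dict[str, np.ndarray]:
    masks = {c: np.zeros(l, dtype=bool) for c, l in s.genome.chromosomes}
    for row in s.df.itertuples(index=False):
        masks[row.chrom][row.start : row.end] = True
    return masks


def bitmap_to_intervals(genome: Genome, masks: dict[str, np.ndarray]) -> list[tuple]:
    out = []
    for chrom, _ in genome.chromosomes:
        m = masks[chrom].astype(np.int8)
        edges = np.flatnonzero(np.diff(np.concatenate(([0], m, [0]))))
        for s, e in zip(edges[::2], edges[1::2]):
            out.append((chrom, int(s), int(e)))
    return out


def bitmap_width(masks: dict[str, np.ndarray]) -> int:
    return int(sum(m.sum() for m in masks.values()))


def brute_force_overlap_count(a: IntervalSet, b: IntervalSet) -> int:
    """Directed overlapping-record count by checking all record pairs."""
    b_recs = list(b.df.itertuples(index=False))
    n = 0
    for ra in a.df.itertuples(index=False):
        if any(
            ra.chrom == rb.chrom and ra.start < rb.end and rb.start < ra.end
            for rb in b_recs
        ):
            n += 1
    return n


def random_interval_set(
    genome: Genome, rng: np.random.Generator, n_max: int = 12, w_max: int = 120
) -> IntervalSet:
    rows = []
    for chrom, length in genome.chromosomes:
        for _ in range(int(rng.integers(0, n_max + 1))):
            w = int(rng.integers(1, min(w_max, length) + 1))
            s = int(rng.integers(0, length - w + 1))
            rows.append((chrom, s, s + w))
    if not rows:
        rows.append((genome.names[0], 0, 1))
    return IntervalSet.from_tuples(genome, rows)
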