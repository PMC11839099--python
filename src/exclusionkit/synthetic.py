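"""Deterministic synthetic fixtures.

Seeded generators for a small genome with annotated assembly gaps, a
mappability track with planted low-mappability zones, multi-sample read
placements with a shared artifact pileup, and a peak table with long-tailed
fold changes — everything the callers and comparison modules consume, with
no external downloads.  Every generator is a pure function of the
:class:`FixtureSpec` (byte-identical output for a fixed seed).

The generator emulates input ChIP-seq evidence: uniform non-specific
background coverage (a homogeneous Poisson read-start process), artifact
hotspots where all samples pile up at a large multiple of the background
rate, and Umap-style per-base mappability equal to 1 except in planted
zones.  It does not model fragment-size distributions, GC bias, duplicate
reads, or donor heterogeneity.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .genome import GapAnnotation, Genome, IntervalSet, ValueTrack, merge_within, union
from .callers import PeakSet

__all__ = [
    "FixtureSpec",
    "make_genome",
    "simulate_mappability",
    "simulate_reads",
    "simulate_peaks",
    "hotspot_truth",
    "low_mappability_truth",
    "emulated_reference_sets",
    "write_fixture_dir",
]


@dataclass(frozen=True)
class FixtureSpec:
    """Study conditions for one synthetic fixture.

    Zones are (chrom, start, end, value) tuples: the value is the pileup
    intensity (multiple of background rate) for hotspots and the mappability
    value for low-mappability and speckle zones.  Gap zones carry a class
    label instead.  ``background_depth`` is the mean read-start rate in
    reads per base.
    """

    seed: int = 0
    chromosomes: tuple[int, ...] = (1_000_000, 800_000)
    gap_zones: tuple[tuple[str, str, int, int], ...] = (
        ("telomere", "chr1", 0, 10_000),
        ("telomere", "chr1", 990_000, 1_000_000),
        ("telomere", "chr2", 0, 10_000),
        ("telomere", "chr2", 790_000, 800_000),
        ("short_arm", "chr2", 10_000, 60_000),
        ("centromere", "chr1", 450_000, 470_000),
        ("centromere", "chr2", 350_000, 360_000),
    )
    hotspot_zones: tuple[tuple[str, int, int, float], ...] = (
        ("chr1", 200_000, 225_000, 100.0),
    )
    low_mapp_zones: tuple[tuple[str, int, int, float], ...] = (
        ("chr2", 500_000, 515_000, 0.0),
        ("chr1", 700_000, 708_000, 0.005),
    )
    speckle_zones: tuple[tuple[str, int, int, float], ...] = (
        ("chr1", 100_000, 100_400, 0.0),
    )
    background_depth: float = 0.05
    n_samples: int = 4
    read_length: int = 100
    n_background_peaks: int = 100
    background_fc_median: float = 3.0
    background_fc_sigma: float = 0.5
    hotspot_fc_sigma: float = 0.02

    @property
    def chrom_names(self) -> tuple[str, ...]:
        return tuple(f"chr{i + 1}" for i in range(len(self.chromosomes)))

    def with_seed(self, seed: int) -> "FixtureSpec":
        return replace(self, seed=seed)


def make_genome(spec: FixtureSpec) -> tuple[Genome, GapAnnotation]:
    """Genome plus labeled centromere/telomere/short-arm annotation."""
    genome = Genome(tuple(zip(spec.chrom_names, spec.chromosomes)))
    classes: dict[str, list] = {}
    for label, chrom, start, end in spec.gap_zones:
        classes.setdefault(label, []).append((chrom, start, end))
    annotation = {}
    for label, zones in classes.items():
        s = IntervalSet.from_tuples(genome, zones)
        if len(merge_within(s, 0)) != len(s):
            raise ValueError(f"overlapping gap zones of class {label!r}")
        annotation[label] = s
    return genome, GapAnnotation(annotation)


def simulate_mappability(spec: FixtureSpec) -> ValueTrack:
    """Baseline-1.0 mappability with planted low-mappability zones.

    Speckle zones are short sub-threshold runs inside mappable territory
    that the LM caller's universe-merge step should absorb.
    """
    genome, _ = make_genome(spec)
    zones: dict[str, list[tuple[int, int, float]]] = {c: [] for c in spec.chrom_names}
    for chrom, start, end, value in spec.low_mapp_zones + spec.speckle_zones:
        if not 0 <= value <= 1:
            raise ValueError("mappability value outside [0, 1]")
        zones[chrom].append((start, end, value))
    rows = []
    for chrom, length in genome.chromosomes:
        pos = 0
        for start, end, value in sorted(zones[chrom]):
            if start < pos:
                raise ValueError(f"overlapping mappability zones on {chrom}")
            if pos < start:
                rows.append((chrom, pos, start, 1.0))
            rows.append((chrom, start, end, value))
            pos = end
        if pos < length:
            rows.append((chrom, pos, length, 1.0))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "value"])
    return ValueTrack(genome, df, unit_interval=True)


def _rng(spec: FixtureSpec, *stream: int) -> np.random.Generator:
    return np.random.default_rng([spec.seed, *stream])


def simulate_reads(spec: FixtureSpec, sample_index: int) -> pd.DataFrame:
    """One sample's read placements: Poisson background plus shared hotspots.

    Background read starts form a homogeneous Poisson process at
    ``background_depth`` reads/bp; each hotspot zone adds starts so its
    total rate is ``intensity`` times background.  Hotspot positions are
    shared across samples; the realization is per (seed, sample).
    """
    genome, _ = make_genome(spec)
    rng = _rng(spec, 1, sample_index)
    rl = spec.read_length
    chroms, starts = [], []
    for chrom, length in genome.chromosomes:
        hi = max(length - rl, 1)
        n = rng.poisson(spec.background_depth * length)
        s = rng.integers(0, hi, size=n)
        chroms.append(np.full(n, chrom, dtype=object))
        starts.append(s)
    for chrom, z_start, z_end, intensity in spec.hotspot_zones:
        width = z_end - z_start
        extra = rng.poisson(max(intensity - 1.0, 0.0) * spec.background_depth * width)
        hi = max(z_end - rl, z_start + 1)
        s = rng.integers(z_start, hi, size=extra)
        chroms.append(np.full(extra, chrom, dtype=object))
        starts.append(s)
    df = pd.DataFrame(
        {"chrom": np.concatenate(chroms), "start": np.concatenate(starts)}
    )
    lengths = genome.lengths
    df["end"] = np.minimum(df["start"] + rl, df["chrom"].map(lengths))
    order = {c: i for i, c in enumerate(genome.names)}
    df["_o"] = df["chrom"].map(order)
    df = df.sort_values(["_o", "start"], kind="mergesort").drop(columns="_o")
    return df.reset_index(drop=True)


def simulate_peaks(spec: FixtureSpec) -> PeakSet:
    """A peak table with long-tailed fold changes.

    Background peaks get log-normal fold changes (median
    ``background_fc_median``, shape ``background_fc_sigma``); each hotspot
    zone becomes one peak with fold change ``intensity`` times a tight
    log-normal factor, far above the background tail.
    """
    genome, _ = make_genome(spec)
    rng = _rng(spec, 2)
    rows = []
    lengths = np.asarray(spec.chromosomes, dtype=float)
    probs = lengths / lengths.sum()
    for _ in range(spec.n_background_peaks):
        ci = rng.choice(len(probs), p=probs)
        chrom, length = genome.chromosomes[ci]
        width = int(np.clip(rng.lognormal(np.log(400), 0.3), 150, 5000))
        start = int(rng.integers(0, max(length - width, 1)))
        fc = float(rng.lognormal(np.log(spec.background_fc_median), spec.background_fc_sigma))
        rows.append((chrom, start, start + width, fc))
    for chrom, start, end, intensity in spec.hotspot_zones:
        fc = float(intensity * rng.lognormal(0.0, spec.hotspot_fc_sigma))
        rows.append((chrom, start, end, fc))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "fold_change"])
    intervals = IntervalSet(genome, df[["chrom", "start", "end"]])
    fc = intervals.df.merge(df, on=["chrom", "start", "end"], how="left")["fold_change"]
    return PeakSet(intervals, fc.to_numpy(dtype=float))


def hotspot_truth(spec: FixtureSpec) -> IntervalSet:
    genome, _ = make_genome(spec)
    return IntervalSet.from_tuples(
        genome, [(c, s, e) for c, s, e, _ in spec.hotspot_zones]
    )


def low_mappability_truth(spec: FixtureSpec, threshold: float = 0.01) -> IntervalSet:
    """Planted zones at or below the mappability threshold (speckles excluded)."""
    genome, _ = make_genome(spec)
    zones = [(c, s, e) for c, s, e, v in spec.low_mapp_zones if v <= threshold]
    return IntervalSet.from_tuples(genome, zones)


def emulated_reference_sets(spec: FixtureSpec) -> dict[str, IntervalSet]:
    """Synthetic stand-ins for an ecosystem of published exclusion lists.

    Derived from the planted truth by systematic, seeded perturbations:
    a curated-style list (truth plus centromeres), a generated-style list
    (truth padded outward), a fragmented list (truth split into pieces,
    which depresses count-based but not width-based similarity), and a
    shifted list (partial overlap).  These are synthetic objects for
    exercising the comparison stack, not reproductions of any real list.
    """
    genome, gaps = make_genome(spec)
    truth = union(hotspot_truth(spec), low_mappability_truth(spec, threshold=1.0))
    rng = _rng(spec, 3)
    lengths = genome.lengths

    def pad(s: IntervalSet, left: int, right: int) -> IntervalSet:
        rows = [
            (r.chrom, max(0, r.start - left), min(lengths[r.chrom], r.end + right))
            for r in s.df.itertuples(index=False)
        ]
        return merge_within(IntervalSet.from_tuples(genome, rows), 0)

    def fragment(s: IntervalSet, piece: int, gap: int) -> IntervalSet:
        rows = []
        for r in s.df.itertuples(index=False):
            pos = r.start
            while pos < r.end:
                rows.append((r.chrom, pos, min(pos + piece, r.end)))
                pos += piece + gap
        return IntervalSet.from_tuples(genome, rows)

    def shift(s: IntervalSet, by: int) -> IntervalSet:
        rows = [
            (r.chrom, min(r.start + by, lengths[r.chrom] - 1), min(r.end + by, lengths[r.chrom]))
            for r in s.df.itertuples(index=False)
        ]
        return IntervalSet.from_tuples(genome, rows)

    jitter = int(rng.integers(500, 1500))
    return {
        "synthetic_curated": union(truth, gaps["centromere"]),
        "synthetic_generated": pad(truth, 2000 + jitter, 2000 + jitter),
        "synthetic_fragmented": fragment(truth, 3000, 500),
        "synthetic_shifted": shift(truth, 5000),
    }


def write_fixture_dir(spec: FixtureSpec, outdir, *, sam: bool = False) -> dict[str, Path]:
    """Emit the fixture as flat files: chrom.sizes, gaps.bed,
    mappability.bedgraph, reads_<sample>.tsv (optionally .sam), peaks.tsv,
    truth.bed."""
    from . import io

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genome, gaps = make_genome(spec)
    paths: dict[str, Path] = {}

    paths["chrom_sizes"] = outdir / "chrom.sizes"
    with open(paths["chrom_sizes"], "w") as fh:
        for name, length in genome.chromosomes:
            fh.write(f"{name}\t{length}\n")

    paths["gaps"] = outdir / "gaps.bed"
    io.write_gap_bed(gaps, paths["gaps"])

    paths["mappability"] = outdir / "mappability.bedgraph"
    io.write_bedgraph(simulate_mappability(spec), paths["mappability"])

    for i in range(spec.n_samples):
        reads = simulate_reads(spec, i)
        key = f"reads_{i}"
        if sam:
            paths[key] = outdir / f"reads_{i}.sam"
            io.write_reads_sam(reads, genome, paths[key])
        else:
            paths[key] = outdir / f"reads_{i}.tsv"
            io.write_reads_tsv(reads, paths[key])

    paths["peaks"] = outdir / "peaks.tsv"
    io.write_peaks_tsv(simulate_peaks(spec), paths["peaks"])

    paths["truth"] = outdir / "truth.bed"
    truth = union(hotspot_truth(spec), low_mappability_truth(spec, threshold=1.0))
    io.write_bed(truth, paths["truth"])
    return paths
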