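"""Readers and writers for the flat genomic formats the toolkit consumes.

Supported: UCSC chrom.sizes, BED3+ (with optional name/score columns),
bedGraph, MACS narrowPeak (fold enrichment in column 7), plain TSV peak and
read tables, BED12 / GFF3 transcript models, and SAM/BAM read input via
pysam.  All writers emit tab-separated text with a trailing newline, so a
write -> read round trip is the identity.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Optional, Union

import numpy as np
import pandas as pd

from .genome import GapAnnotation, Genome, IntervalSet, ValueTrack

logger = logging.getLogger(__name__)

PathLike = Union[str, Path]

_SKIP_PREFIXES = ("#", "track", "browser")


def read_chrom_sizes(path: PathLike) -> Genome:
    """Read a two-column ``name<TAB>length`` file, preserving file order."""
    chroms: list[tuple[str, int]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValueError(f"{path}:{lineno}: expected name<TAB>length")
            try:
                length = int(fields[1])
            except ValueError:
                raise ValueError(f"{path}:{lineno}: malformed length {fields[1]!r}")
            chroms.append((fields[0], length))
    if not chroms:
        raise ValueError(f"{path}: empty chrom.sizes file")
    return Genome(tuple(chroms))


def _data_lines(path: PathLike):
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith(_SKIP_PREFIXES):
                continue
            yield lineno, line.split("\t")


def read_bed(
    path: PathLike,
    genome: Genome,
    *,
    unknown_chrom: str = "drop",
) -> IntervalSet:
    """Read BED3+ records into an :class:`IntervalSet`.

    Columns 4 and 5 are kept as name and score when present.  Records on
    chromosomes absent from ``genome`` are dropped with a warning by default
    (real exclusion lists carry alt-contig records absent from a
    primary-chromosome genome); pass ``unknown_chrom="error"`` to refuse them.
    """
    if unknown_chrom not in ("drop", "error"):
        raise ValueError("unknown_chrom must be 'drop' or 'error'")
    lengths = genome.lengths
    rows = []
    n_dropped = 0
    for lineno, fields in _data_lines(path):
        if len(fields) < 3:
            raise ValueError(f"{path}:{lineno}: fewer than 3 BED columns")
        chrom = fields[0]
        start, end = int(fields[1]), int(fields[2])
        if chrom not in lengths:
            if unknown_chrom == "error":
                raise KeyError(f"{path}:{lineno}: unknown chromosome {chrom!r}")
            n_dropped += 1
            continue
        if start >= end:
            raise ValueError(f"{path}:{lineno}: start >= end")
        name = fields[3] if len(fields) > 3 else None
        score: Optional[float] = None
        if len(fields) > 4:
            try:
                score = float(fields[4])
            except ValueError:
                score = None
        rows.append((chrom, start, end, name, score))
    if n_dropped:
        logger.warning("%s: dropped %d records on unknown chromosomes", path, n_dropped)
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "score"])
    return IntervalSet(genome, df)


def write_bed(s: IntervalSet, path: PathLike, labels: Optional[Iterable[str]] = None) -> None:
    """Write BED in set order; name/score columns included when present."""
    labels = list(labels) if labels is not None else None
    if labels is not None and len(labels) != len(s):
        raise ValueError("one label per record required")
    with open(path, "w") as fh:
        for i, row in enumerate(s.df.itertuples(index=False)):
            fields = [row.chrom, str(row.start), str(row.end)]
            name = labels[i] if labels is not None else row.name
            if name is not None:
                fields.append(str(name))
                if row.score is not None and not pd.isna(row.score):
                    fields.append(_fmt_score(row.score))
            fh.write("\t".join(fields) + "\n")


def _fmt_score(x: float) -> str:
    return str(int(x)) if float(x).is_integer() else repr(float(x))


def read_bedgraph(path: PathLike, genome: Genome, *, unit_interval: bool = False) -> ValueTrack:
    """Read a 4-column bedGraph into a :class:`ValueTrack` (implicit zeros)."""
    rows = []
    for lineno, fields in _data_lines(path):
        if len(fields) < 4:
            raise ValueError(f"{path}:{lineno}: fewer than 4 bedGraph columns")
        try:
            value = float(fields[3])
        except ValueError:
            raise ValueError(f"{path}:{lineno}: malformed value {fields[3]!r}")
        rows.append((fields[0], int(fields[1]), int(fields[2]), value))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "value"])
    return ValueTrack(genome, df, unit_interval=unit_interval)


def write_bedgraph(track: ValueTrack, path: PathLike) -> None:
    with open(path, "w") as fh:
        for row in track.df.itertuples(index=False):
            fh.write(f"{row.chrom}\t{row.start}\t{row.end}\t{row.value:g}\n")


def read_gap_bed(path: PathLike, genome: Genome, **kw) -> GapAnnotation:
    """Read a labeled BED (column 4 = gap class) into a :class:`GapAnnotation`."""
    s = read_bed(path, genome, **kw)
    classes = {}
    for label, sub in s.df.groupby("name", sort=False):
        classes[str(label)] = IntervalSet(genome, sub)
    return GapAnnotation(classes)


def write_gap_bed(gaps: GapAnnotation, path: PathLike) -> None:
    rows = []
    for label, s in gaps.classes.items():
        for row in s.df.itertuples(index=False):
            rows.append((row.chrom, row.start, row.end, label))
    with open(path, "w") as fh:
        for chrom, start, end, label in rows:
            fh.write(f"{chrom}\t{start}\t{end}\t{label}\n")


# -- peak tables --------------------------------------------------------------


def read_narrowpeak(path: PathLike, genome: Genome, **kw):
    """Read a MACS narrowPeak file; fold enrichment is column 7."""
    from .callers import PeakSet

    rows = []
    for lineno, fields in _data_lines(path):
        if len(fields) < 7:
            raise ValueError(f"{path}:{lineno}: narrowPeak needs >= 7 columns")
        rows.append((fields[0], int(fields[1]), int(fields[2]), float(fields[6])))
    return _peakset_from_rows(rows, genome, PeakSet, **kw)


def read_peaks_tsv(path: PathLike, genome: Genome, **kw):
    """Read a chrom/start/end/fold_change TSV (header optional)."""
    from .callers import PeakSet

    rows = []
    for lineno, fields in _data_lines(path):
        if fields[0] == "chrom":
            continue
        if len(fields) < 4:
            raise ValueError(f"{path}:{lineno}: expected chrom,start,end,fold_change")
        rows.append((fields[0], int(fields[1]), int(fields[2]), float(fields[3])))
    return _peakset_from_rows(rows, genome, PeakSet, **kw)


def _peakset_from_rows(rows, genome, cls, *, unknown_chrom: str = "drop"):
    lengths = genome.lengths
    kept = [r for r in rows if r[0] in lengths]
    dropped = len(rows) - len(kept)
    if dropped:
        if unknown_chrom == "error":
            raise KeyError("peak on chromosome absent from genome")
        logger.warning("dropped %d peaks on unknown chromosomes", dropped)
    df = pd.DataFrame(kept, columns=["chrom", "start", "end", "fold_change"])
    intervals = IntervalSet(genome, df[["chrom", "start", "end"]])
    fc = intervals.df.merge(df, on=["chrom", "start", "end"], how="left")["fold_change"]
    return cls(intervals, fc.to_numpy(dtype=float))


def write_peaks_tsv(peaks, path: PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tstart\tend\tfold_change\n")
        for row, fc in zip(peaks.intervals.df.itertuples(index=False), peaks.fold_change):
            fh.write(f"{row.chrom}\t{row.start}\t{row.end}\t{fc:g}\n")


# -- read placements ----------------------------------------------------------


def read_reads_tsv(path: PathLike, genome: Genome) -> pd.DataFrame:
    """Read a chrom/start/end read-placement table (header optional)."""
    df = pd.read_csv(
        path, sep="\t", names=["chrom", "start", "end"], comment="#", dtype={"chrom": str}
    )
    if len(df) and df.iloc[0, 0] == "chrom":
        df = df.iloc[1:].reset_index(drop=True)
    df["start"] = df["start"].astype(np.int64)
    df["end"] = df["end"].astype(np.int64)
    _validate_reads(df, genome)
    return df


def write_reads_tsv(reads: pd.DataFrame, path: PathLike) -> None:
    reads[["chrom", "start", "end"]].to_csv(path, sep="\t", header=False, index=False)


def read_reads_sam(path: PathLike, genome: Genome) -> pd.DataFrame:
    """Reference spans of mapped alignments from a SAM/BAM file."""
    import pysam

    rows = []
    with pysam.AlignmentFile(str(path)) as fh:
        for aln in fh:
            if aln.is_unmapped:
                continue
            rows.append((aln.reference_name, aln.reference_start, aln.reference_end))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    df = df[df["chrom"].isin(genome.names)].reset_index(drop=True)
    _validate_reads(df, genome)
    return df


def write_reads_sam(reads: pd.DataFrame, genome: Genome, path: PathLike) -> None:
    """Emit read placements as unpaired perfect-match SAM records."""
    import pysam

    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": name, "LN": length} for name, length in genome.chromosomes],
    }
    order = {name: i for i, name in enumerate(genome.names)}
    reads = reads.sort_values(
        ["chrom", "start"], key=lambda c: c.map(order) if c.name == "chrom" else c
    )
    with pysam.AlignmentFile(str(path), "w", header=header) as fh:
        for i, row in enumerate(reads.itertuples(index=False)):
            a = pysam.AlignedSegment(fh.header)
            a.query_name = f"read{i}"
            a.reference_id = order[row.chrom]
            a.reference_start = int(row.start)
            a.cigarstring = f"{int(row.end) - int(row.start)}M"
            a.mapping_quality = 60
            a.flag = 0
            fh.write(a)


def _validate_reads(df: pd.DataFrame, genome: Genome) -> None:
    lengths = genome.lengths
    for chrom, sub in df.groupby("chrom", sort=False):
        if chrom not in lengths:
            raise KeyError(f"read on chromosome {chrom!r} absent from genome")
        if (sub["start"] < 0).any() or (sub["end"] > lengths[chrom]).any():
            raise ValueError(f"read outside chromosome bounds on {chrom}")
        if (sub["start"] >= sub["end"]).any():
            raise ValueError("read with start >= end")


# -- transcript models --------------------------------------------------------


def read_transcripts_bed12(path: PathLike, genome: Genome, biotype_map=None):
    """Read BED12 transcript models; blocks become exons.

    The biotype is taken from the record name suffix after the last ``|``
    when present (``ENST..|gene|protein_coding``), else via ``biotype_map``
    keyed by transcript id, else ``other``.
    """
    from .transcripts import TranscriptModel

    models = []
    for lineno, fields in _data_lines(path):
        if len(fields) < 12:
            raise ValueError(f"{path}:{lineno}: BED12 needs 12 columns")
        chrom, start = fields[0], int(fields[1])
        name = fields[3]
        sizes = [int(x) for x in fields[10].rstrip(",").split(",")]
        offsets = [int(x) for x in fields[11].rstrip(",").split(",")]
        exons = [(chrom, start + o, start + o + sz) for o, sz in zip(offsets, sizes)]
        parts = name.split("|")
        tid = parts[0]
        gene = parts[1] if len(parts) > 1 else tid
        biotype = parts[2] if len(parts) > 2 else (biotype_map or {}).get(tid, "other")
        models.append(
            TranscriptModel(tid, gene, biotype, IntervalSet.from_tuples(genome, exons))
        )
    return models


def read_transcripts_gff3(path: PathLike, genome: Genome):
    """Read GFF3 exon features grouped by transcript (Parent) id."""
    import gffutils

    from .transcripts import TranscriptModel

    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    models = []
    for tr in db.features_of_type(("mRNA", "transcript", "lnc_RNA")):
        exons = [
            (ex.seqid, ex.start - 1, ex.end) for ex in db.children(tr, featuretype="exon")
        ]
        if not exons:
            continue
        biotype = tr.attributes.get("biotype", ["other"])[0]
        gene = tr.attributes.get("Parent", [tr.id])[0]
        models.append(
            TranscriptModel(tr.id, gene, biotype, IntervalSet.from_tuples(genome, exons))
        )
    return models
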