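"""Transcript impact of exclusion sets.

Quantifies how much of each transcript's exonic territory an exclusion set
covers, and summarizes affected transcripts per biotype (protein-coding /
lncRNA / other).  A transcript counts as affected when the exclusion set
covers a strictly positive number of its exonic bases.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .genome import IntervalSet, intersect, total_width

__all__ = ["TranscriptModel", "exon_coverage_by_set", "impact_summary", "BIOTYPES"]

BIOTYPES = ("protein_coding", "lncRNA", "other")

# common annotation biotypes collapsed onto the three reported classes
DEFAULT_BIOTYPE_MAP = {
    "protein_coding": "protein_coding",
    "lncRNA": "lncRNA",
    "lincRNA": "lncRNA",
    "antisense": "lncRNA",
}


@dataclass
class TranscriptModel:
    transcript_id: str
    gene_id: str
    biotype: str
    exons: IntervalSet

    def __post_init__(self) -> None:
        if len({row.chrom for row in self.exons.df.itertuples(index=False)}) > 1:
            raise ValueError(
                f"transcript {self.transcript_id} has exons on multiple chromosomes"
            )

    @property
    def exon_bp(self) -> int:
        """Collapsed exonic width of the transcript."""
        return total_width(self.exons)


def exon_coverage_by_set(
    transcripts: list[TranscriptModel], exclusion: IntervalSet
) -> pd.DataFrame:
    """Per-transcript exonic bases covered by the exclusion set.

    Returns one row per transcript with ``covered_bp`` = W(exons ∩ set) and
    ``covered_fraction`` = covered_bp / W(exons).
    """
    rows = []
    for tr in transcripts:
        exon_bp = tr.exon_bp
        if exon_bp == 0:
            raise ValueError(f"transcript {tr.transcript_id} has zero exon width")
        covered = total_width(intersect(tr.exons, exclusion))
        rows.append(
            (tr.transcript_id, tr.gene_id, tr.biotype, exon_bp, covered, covered / exon_bp)
        )
    return pd.DataFrame(
        rows,
        columns=[
            "transcript_id",
            "gene_id",
            "biotype",
            "exon_bp",
            "covered_bp",
            "covered_fraction",
        ],
    )


def impact_summary(
    coverages: pd.DataFrame, biotype_map: dict[str, str] | None = None
) -> pd.DataFrame:
    """Affected-transcript counts and covered bases per collapsed biotype.

    ``biotype_map`` maps annotation biotypes onto the three reported classes;
    anything unmapped collapses to ``other``.
    """
    bmap = DEFAULT_BIOTYPE_MAP if biotype_map is None else biotype_map
    collapsed = coverages["biotype"].map(lambda b: bmap.get(b, "other"))
    affected = coverages["covered_bp"] > 0
    out = []
    for biotype in BIOTYPES:
        sel = collapsed == biotype
        out.append(
            (
                biotype,
                int((sel & affected).sum()),
                int(coverages.loc[sel, "covered_bp"].sum()),
            )
        )
    return pd.DataFrame(out, columns=["biotype", "n_affected", "total_covered_bp"])
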