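"""Transcript models, exon/intron boundary tables and position classification.

Panel-based IRD analysis needs a curated list of exon/intron boundary
positions: upstream annotation software flags only the canonical intronic
splice bases, so a synonymous or missense change in the first or last two
bases of an exon would otherwise be discarded even though it can disrupt
splicing.  This module builds that boundary table from transcript models and
classifies arbitrary genomic positions relative to them.

Coordinate conventions: externally (VCF, GFF3, this module's public API)
positions are 1-based inclusive; interval arithmetic internally is 0-based
half-open.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "TranscriptModel",
    "GeneInfo",
    "PositionClass",
    "build_boundary_list",
    "classify_position",
    "nonsense_codon",
]

#: number of exonic bases at each exon end considered part of the splice junction
JUNCTION_WIDTH = 2
#: intronic bases this close to an exon form the canonical splice site (donor GT / acceptor AG)
CANONICAL_WIDTH = 2
#: intronic distance beyond which a variant counts as deep intronic
DEEP_INTRON_MIN = 100

# label precedence used to break ties between transcripts at equal distance:
# the most rescue-prone (splice-proximal) class wins.
_PRECEDENCE = [
    "exonic_splice_junction",
    "canonical_splice_site",
    "near_intronic",
    "deep_intronic",
    "coding_exonic",
    "noncoding_exonic",
    "intergenic",
]
_RANK = {label: i for i, label in enumerate(_PRECEDENCE)}


@dataclass(frozen=True)
class TranscriptModel:
    """One transcript: exon structure and CDS bounds on a contig.

    ``exons`` are (start, end) pairs, 1-based inclusive genomic coordinates,
    ordered in transcription order (descending genomic coordinates on the
    minus strand).  ``cds_start``/``cds_end`` are the genomic positions of the
    first and last CDS base in transcript orientation.
    """

    gene_id: str
    transcript_id: str
    contig: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    cds_start: int
    cds_end: int

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.transcript_id}: strand must be '+' or '-'")
        if not self.exons:
            raise ValueError(f"{self.transcript_id}: transcript has no exons")
        for start, end in self.exons:
            if start > end or start < 1:
                raise ValueError(
                    f"{self.transcript_id}: malformed exon ({start}, {end})"
                )
        genomic = sorted(self.exons)
        for (s1, e1), (s2, e2) in zip(genomic, genomic[1:]):
            if e1 >= s2:
                raise ValueError(f"{self.transcript_id}: overlapping exons")
        expected = genomic if self.strand == "+" else genomic[::-1]
        if tuple(expected) != self.exons:
            raise ValueError(
                f"{self.transcript_id}: exons not in transcription order"
            )

    @property
    def exons_genomic(self) -> list[tuple[int, int]]:
        """Exons sorted by genomic coordinate regardless of strand."""
        return sorted(self.exons)

    @property
    def span(self) -> tuple[int, int]:
        g = self.exons_genomic
        return g[0][0], g[-1][1]

    def cds_length(self) -> int:
        lo, hi = sorted((self.cds_start, self.cds_end))
        return sum(
            max(0, min(e, hi) - max(s, lo) + 1) for s, e in self.exons_genomic
        )

    def is_coding_position(self, pos: int) -> bool:
        lo, hi = sorted((self.cds_start, self.cds_end))
        if not lo <= pos <= hi:
            return False
        return any(s <= pos <= e for s, e in self.exons_genomic)


@dataclass(frozen=True)
class GeneInfo:
    """Gene-level metadata: inheritance mode and gene-disease associations."""

    gene_id: str
    inheritance_mode: str  # AD | AR | XL
    associated_classes: tuple[str, ...]


@dataclass(frozen=True)
class PositionClass:
    """Classification of one genomic position relative to transcript models."""

    label: str
    distance_to_nearest_boundary: int
    gene_id: str | None = None
    transcript_id: str | None = None

    def __post_init__(self) -> None:
        if self.label not in _RANK:
            raise ValueError(f"unknown position class {self.label!r}")


def build_boundary_list(models: Iterable[TranscriptModel]) -> pd.DataFrame:
    """Build the curated exon/intron boundary table.

    One row per exon per transcript, listing the genomic positions of the
    exon's first two and last two bases in transcript (5'->3') orientation.
    For a minus-strand transcript the 5' junction bases of the first
    transcribed exon are therefore its highest genomic coordinates.
    """
    rows = []
    for tm in models:
        for idx, (start, end) in enumerate(tm.exons, start=1):
            if tm.strand == "+":
                j5 = [p for p in (start, start + 1) if p <= end]
                j3 = [p for p in (end - 1, end) if p >= start]
            else:
                j5 = [p for p in (end, end - 1) if p >= start]
                j3 = [p for p in (start + 1, start) if p <= end]
            rows.append(
                {
                    "gene": tm.gene_id,
                    "transcript": tm.transcript_id,
                    "exon_index": idx,
                    "contig": tm.contig,
                    "strand": tm.strand,
                    "junction5_positions": ",".join(str(p) for p in j5),
                    "junction3_positions": ",".join(str(p) for p in j3),
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "gene",
            "transcript",
            "exon_index",
            "contig",
            "strand",
            "junction5_positions",
            "junction3_positions",
        ],
    )


def _classify_in_transcript(tm: TranscriptModel, pos: int) -> PositionClass | None:
    """Classify ``pos`` within one transcript, or None if outside its span."""
    lo, hi = tm.span
    if not lo <= pos <= hi:
        return None
    exons = tm.exons_genomic
    for start, end in exons:
        if start <= pos <= end:
            dist = min(pos - start, end - pos)
            if dist < JUNCTION_WIDTH:
                label = "exonic_splice_junction"
            elif tm.is_coding_position(pos):
                label = "coding_exonic"
            else:
                label = "noncoding_exonic"
            return PositionClass(label, dist, tm.gene_id, tm.transcript_id)
    # intronic: distance measured in bases into the intron (adjacent base = 1)
    for (s1, e1), (s2, e2) in zip(exons, exons[1:]):
        if e1 < pos < s2:
            dist = min(pos - e1, s2 - pos)
            if dist <= CANONICAL_WIDTH:
                label = "canonical_splice_site"
            elif dist > DEEP_INTRON_MIN:
                label = "deep_intronic"
            else:
                label = "near_intronic"
            return PositionClass(label, dist, tm.gene_id, tm.transcript_id)
    return None  # unreachable for well-formed models


def classify_position(
    contig: str, position: int, models: Iterable[TranscriptModel]
) -> PositionClass:
    """Classify a 1-based genomic position against a set of transcript models.

    When the position falls in several transcripts the class with the
    smallest distance to an exon boundary wins; at equal distance the more
    splice-proximal label takes precedence (the boundary list exists to stop
    edge variants being discarded, so the rescue-prone class is reported).
    """
    if position < 1:
        raise ValueError("position must be >= 1 (1-based)")
    candidates: list[PositionClass] = []
    seen_contig = False
    for tm in models:
        if tm.contig != contig:
            continue
        seen_contig = True
        pc = _classify_in_transcript(tm, position)
        if pc is not None:
            candidates.append(pc)
    if not candidates:
        if not seen_contig:
            warnings.warn(
                f"contig {contig!r} not covered by any transcript model; "
                "classifying as intergenic",
                stacklevel=2,
            )
        return PositionClass("intergenic", -1)
    return min(
        candidates,
        key=lambda pc: (pc.distance_to_nearest_boundary, _RANK[pc.label]),
    )


def nonsense_codon(cds_position: int, cds_length: int | None = None) -> int:
    """Codon number containing a CDS position (1-based on both scales).

    Used to locate the premature termination codon introduced by a nonsense
    variant, e.g. c.10888G>T lies in codon 3630.
    """
    if cds_position < 1:
        raise ValueError("cds_position must be >= 1")
    if cds_length is not None and cds_position > cds_length:
        raise ValueError(
            f"cds_position {cds_position} outside CDS of length {cds_length}"
        )
    return (cds_position - 1) // 3 + 1
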