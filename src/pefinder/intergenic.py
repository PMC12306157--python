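"""Maximal intergenic regions of a genome record.

Repetitive extragenic palindromes live, by definition, outside annotated
genes, so the scan operates only on the complement of the (merged) gene
cover. Genes on both strands block intergenic space: the complement is
strand-agnostic. Chromosomes are treated as linear; no wrap-around
region joins the end of the record to its start.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from .genome_io import GeneFeature, GenomeRecord

__all__ = ["IntergenicRegion", "extract_intergenic", "merge_intervals"]


@dataclass(frozen=True)
class IntergenicRegion:
    """A maximal interval not covered by any gene feature (0-based half-open)."""

    seq_id: str
    start: int
    end: int
    left_gene: Optional[GeneFeature] = None
    right_gene: Optional[GeneFeature] = None

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"empty intergenic region [{self.start}, {self.end})")

    @property
    def length(self) -> int:
        return self.end - self.start


def merge_intervals(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Merge overlapping or adjacent half-open intervals into a disjoint cover."""
    merged: list[tuple[int, int]] = []
    for s, e in sorted(intervals):
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def extract_intergenic(
    genes: list[GeneFeature],
    genome: GenomeRecord,
    min_len: int = 10,
) -> list[IntergenicRegion]:
    """Complement of the merged gene cover within ``[0, genome.length)``.

    Genes from both strands are projected onto the forward axis and
    merged; regions shorter than ``min_len`` (default 10 nt, the minimum
    length at which an element can fold at all) are dropped. Flanking
    gene references are populated where a gene exists on that side.
    """
    if min_len < 1:
        raise ValueError("min_len must be >= 1")
    mine = [g for g in genes if g.seq_id == genome.seq_id]
    for g in mine:
        if g.end > genome.length:
            raise ValueError(
                f"gene {g.gene_id!r} [{g.start},{g.end}) outside genome "
                f"{genome.seq_id!r} of length {genome.length}"
            )

    cover = merge_intervals([(g.start, g.end) for g in mine])
    by_end = sorted(mine, key=lambda g: (g.end, g.start))
    by_start = sorted(mine, key=lambda g: (g.start, g.end))

    def left_of(pos: int) -> Optional[GeneFeature]:
        best = None
        for g in by_end:
            if g.end <= pos:
                best = g
            else:
                break
        return best

    def right_of(pos: int) -> Optional[GeneFeature]:
        for g in by_start:
            if g.start >= pos:
                return g
        return None

    gaps: list[tuple[int, int]] = []
    prev = 0
    for s, e in cover:
        if s > prev:
            gaps.append((prev, s))
        prev = max(prev, e)
    if prev < genome.length:
        gaps.append((prev, genome.length))

    return [
        IntergenicRegion(
            seq_id=genome.seq_id,
            start=s,
            end=e,
            left_gene=left_of(s),
            right_gene=right_of(e),
        )
        for s, e in gaps
        if e - s >= min_len
    ]
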