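"""Per-gene comparison references.

A gene's transcripts are classified against either the hypothetical
pre-RNA (the union of all isoforms' exons, overlapping or book-ended
intervals merged) or the exon chain of the most expressed transcript in a
chosen reference condition.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

from .model import ExpressionRecord, GeneModel, GenomicInterval

logger = logging.getLogger(__name__)

PRE_RNA = "pre_rna"
MOST_EXPRESSED = "most_expressed"


@dataclass(frozen=True)
class ReferenceModel:
    """Merged-exon reference a transcript is compared against."""

    gene_id: str
    mode: str
    chrom: str
    strand: str
    merged_exons: tuple[GenomicInterval, ...]
    source_transcript_id: Optional[str] = None

    def __post_init__(self) -> None:
        if self.mode not in (PRE_RNA, MOST_EXPRESSED):
            raise ValueError(f"unknown reference mode {self.mode!r}")
        if not self.merged_exons:
            raise ValueError(f"reference for {self.gene_id}: no exons")
        prev = None
        for e in self.merged_exons:
            if prev is not None and e.start <= prev.end:
                raise ValueError(
                    f"reference for {self.gene_id}: merged exons must be "
                    f"sorted with positive gaps"
                )
            prev = e

    @property
    def start(self) -> int:
        return self.merged_exons[0].start

    @property
    def end(self) -> int:
        return self.merged_exons[-1].end

    def introns(self) -> list[GenomicInterval]:
        return [
            GenomicInterval(self.chrom, a.end, b.start, self.strand)
            for a, b in zip(self.merged_exons, self.merged_exons[1:])
        ]


def merge_intervals(
    intervals: Sequence[GenomicInterval],
) -> list[GenomicInterval]:
    """Union of intervals; overlapping or book-ended intervals are merged
    (a base-gap of 0 is not an intron)."""
    if not intervals:
        return []
    ivs = sorted(intervals, key=lambda e: (e.start, e.end))
    merged = [ivs[0]]
    for e in ivs[1:]:
        last = merged[-1]
        if e.start <= last.end:
            if e.end > last.end:
                merged[-1] = GenomicInterval(
                    last.chrom, last.start, e.end, last.strand
                )
        else:
            merged.append(e)
    return merged


def build_pre_rna(gene: GeneModel) -> ReferenceModel:
    """The hypothetical pre-RNA: merged exons of all the gene's transcripts.

    The reference introns are exactly the maximal regions of the gene span
    exonic in no transcript.
    """
    exons = [e for t in gene.transcripts for e in t.exons]
    merged = merge_intervals(exons)
    return ReferenceModel(
        gene_id=gene.gene_id,
        mode=PRE_RNA,
        chrom=gene.chrom,
        strand=gene.strand,
        merged_exons=tuple(merged),
    )


def select_most_expressed(
    gene: GeneModel,
    expression: Sequence[ExpressionRecord],
    condition: str,
) -> ReferenceModel:
    """Reference = exon chain of the transcript most expressed in
    ``condition``; ties broken by lexicographically smallest transcript id.
    Falls back to the pre-RNA (with a warning) when every transcript has
    zero expression in that condition.
    """
    expr = {
        r.transcript_id: r.transcript_expr
        for r in expression
        if r.condition == condition and r.gene_id == gene.gene_id
    }
    missing = [
        t.transcript_id
        for t in gene.transcripts
        if t.transcript_id not in expr
    ]
    if missing:
        raise ValueError(
            f"gene {gene.gene_id}: no expression in condition {condition!r} "
            f"for {missing[:3]}"
        )
    best = min(
        gene.transcripts,
        key=lambda t: (-expr[t.transcript_id], t.transcript_id),
    )
    if expr[best.transcript_id] <= 0:
        logger.warning(
            "gene %s: all transcripts unexpressed in %s; falling back to "
            "pre-RNA reference", gene.gene_id, condition,
        )
        return build_pre_rna(gene)
    return ReferenceModel(
        gene_id=gene.gene_id,
        mode=MOST_EXPRESSED,
        chrom=gene.chrom,
        strand=gene.strand,
        merged_exons=tuple(best.exons),
        source_transcript_id=best.transcript_id,
    )


def reference_for(
    gene: GeneModel,
    mode: str,
    expression: Sequence[ExpressionRecord] = (),
    condition: Optional[str] = None,
) -> ReferenceModel:
    if mode == PRE_RNA:
        return build_pre_rna(gene)
    if mode == MOST_EXPRESSED:
        if condition is None:
            raise ValueError("most_expressed mode needs a reference condition")
        return select_most_expressed(gene, expression, condition)
    raise ValueError(f"unknown reference mode {mode!r}")
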