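"""Coordinate-aware core data types.

All internal coordinates are 0-based half-open genomic intervals; GTF and
genePred readers/writers convert at the I/O boundary.  Transcript
coordinates are 0-based positions along the mature transcript in 5'->3'
orientation (so on the minus strand, transcript position 0 is the
genomically 3'-most exonic base).
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from typing import Iterator, Optional, Sequence

STRANDS = ("+", "-", ".")


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A half-open genomic interval [start, end) on a chromosome."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}) on {self.chrom}"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )

    def same_coords(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start == other.start
            and self.end == other.end
        )


@dataclass(frozen=True)
class TranscriptModel:
    """An assembled transcript: an ordered, disjoint exon chain.

    Exons are sorted by genomic start, pairwise non-overlapping and
    non-abutting (a zero-length intron is a model error; the GTF reader
    merges abutting exons before construction), and all share the
    transcript's chromosome and strand.
    """

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: tuple[GenomicInterval, ...]
    # opaque leftover GTF attribute text, preserved for re-emission
    extra_attributes: str = field(default="", compare=False)

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(
                f"transcript {self.transcript_id}: strand must be + or -"
            )
        if len(self.exons) < 1:
            raise ValueError(f"transcript {self.transcript_id}: no exons")
        object.__setattr__(self, "exons", tuple(self.exons))
        prev = None
        for e in self.exons:
            if e.chrom != self.chrom:
                raise ValueError(
                    f"transcript {self.transcript_id}: exon on {e.chrom}, "
                    f"transcript on {self.chrom}"
                )
            if e.strand not in (".", self.strand):
                raise ValueError(
                    f"transcript {self.transcript_id}: exon strand {e.strand} "
                    f"conflicts with transcript strand {self.strand}"
                )
            if prev is not None and e.start <= prev.end:
                raise ValueError(
                    f"transcript {self.transcript_id}: exons not sorted/"
                    f"disjoint at [{prev.start},{prev.end}) vs "
                    f"[{e.start},{e.end}) (abutting exons must be merged)"
                )
            prev = e

    @property
    def start(self) -> int:
        return self.exons[0].start

    @property
    def end(self) -> int:
        return self.exons[-1].end

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end, self.strand)

    def __len__(self) -> int:
        return transcript_length(self)


def transcript_length(t: TranscriptModel) -> int:
    """Total exonic length of the transcript in nucleotides."""
    return sum(e.length for e in t.exons)


def introns(t: TranscriptModel) -> list[GenomicInterval]:
    """Gaps between consecutive exons, in genomic order."""
    return [
        GenomicInterval(t.chrom, a.end, b.start, t.strand)
        for a, b in zip(t.exons, t.exons[1:])
    ]


def _cumulative_exon_starts(t: TranscriptModel) -> list[int]:
    # cumulative exonic length before each exon, genomic order
    cum = [0]
    for e in t.exons:
        cum.append(cum[-1] + e.length)
    return cum


def genomic_to_transcript(t: TranscriptModel, g: int) -> Optional[int]:
    """Map genomic position ``g`` to a transcript coordinate.

    Returns the 0-based position of the base in the mature transcript
    (5'->3' in transcript orientation), or ``None`` if ``g`` is intronic
    or outside the transcript span.
    """
    cum = _cumulative_exon_starts(t)
    plus_pos = None
    for i, e in enumerate(t.exons):
        if e.start <= g < e.end:
            plus_pos = cum[i] + (g - e.start)
            break
    if plus_pos is None:
        return None
    if t.strand == "+":
        return plus_pos
    return transcript_length(t) - 1 - plus_pos


def transcript_to_genomic(t: TranscriptModel, tpos: int) -> int:
    """Inverse of :func:`genomic_to_transcript` for exonic positions."""
    n = transcript_length(t)
    if not 0 <= tpos < n:
        raise ValueError(f"transcript position {tpos} outside [0,{n})")
    plus_pos = tpos if t.strand == "+" else n - 1 - tpos
    cum = _cumulative_exon_starts(t)
    i = bisect.bisect_right(cum, plus_pos) - 1
    return t.exons[i].start + (plus_pos - cum[i])


@dataclass(frozen=True)
class GeneModel:
    """All transcripts assembled for one gene (same chrom and strand)."""

    gene_id: str
    transcripts: tuple[TranscriptModel, ...]

    def __post_init__(self) -> None:
        if len(self.transcripts) < 1:
            raise ValueError(f"gene {self.gene_id}: no transcripts")
        object.__setattr__(self, "transcripts", tuple(self.transcripts))
        t0 = self.transcripts[0]
        for t in self.transcripts:
            if t.gene_id != self.gene_id:
                raise ValueError(
                    f"gene {self.gene_id}: transcript {t.transcript_id} "
                    f"claims gene {t.gene_id}"
                )
            if t.chrom != t0.chrom or t.strand != t0.strand:
                raise ValueError(
                    f"gene {self.gene_id}: transcripts on conflicting "
                    f"chrom/strand ({t.transcript_id} vs {t0.transcript_id})"
                )

    @property
    def chrom(self) -> str:
        return self.transcripts[0].chrom

    @property
    def strand(self) -> str:
        return self.transcripts[0].strand

    @property
    def span(self) -> GenomicInterval:
        start = min(t.start for t in self.transcripts)
        end = max(t.end for t in self.transcripts)
        return GenomicInterval(self.chrom, start, end, self.strand)


@dataclass(frozen=True)
class ExpressionRecord:
    """Per-transcript, per-condition abundance (FPKM or equivalent)."""

    transcript_id: str
    gene_id: str
    condition: str
    transcript_expr: float
    gene_expr: float
    iso_status: Optional[str] = None
    gene_status: Optional[str] = None
    test_pvalue: Optional[float] = None

    def __post_init__(self) -> None:
        if self.transcript_expr < 0 or self.gene_expr < 0:
            raise ValueError(
                f"negative expression for {self.transcript_id}/{self.condition}"
            )


class SpliceDataset:
    """A coherent bundle of gene models and two-condition expression.

    Invariants enforced at construction: every expression record's
    transcript id resolves to a transcript, and exactly the declared
    conditions appear among the records.
    """

    def __init__(
        self,
        genes: Sequence[GeneModel],
        expression: Sequence[ExpressionRecord],
        conditions: Sequence[str],
        assembler: str = "unknown",
    ) -> None:
        self.genes: tuple[GeneModel, ...] = tuple(
            sorted(genes, key=lambda g: g.gene_id)
        )
        self.expression: tuple[ExpressionRecord, ...] = tuple(expression)
        self.conditions: tuple[str, ...] = tuple(conditions)
        self.assembler = assembler

        self._tx: dict[str, TranscriptModel] = {}
        self._gene_of_tx: dict[str, str] = {}
        for g in self.genes:
            for t in g.transcripts:
                if t.transcript_id in self._tx:
                    raise ValueError(f"duplicate transcript id {t.transcript_id}")
                self._tx[t.transcript_id] = t
                self._gene_of_tx[t.transcript_id] = g.gene_id
        self._gene: dict[str, GeneModel] = {g.gene_id: g for g in self.genes}

        seen_conditions = set()
        self._expr: dict[tuple[str, str], ExpressionRecord] = {}
        unknown = []
        for r in self.expression:
            if r.condition not in self.conditions:
                raise ValueError(f"undeclared condition {r.condition!r}")
            seen_conditions.add(r.condition)
            if r.transcript_id not in self._tx:
                unknown.append(r.transcript_id)
                continue
            key = (r.transcript_id, r.condition)
            if key in self._expr:
                raise ValueError(
                    f"duplicate expression record for {key[0]} in {key[1]}"
                )
            self._expr[key] = r
        if unknown:
            raise ValueError(
                f"{len(unknown)} expression record(s) reference unknown "
                f"transcripts, e.g. {unknown[:3]}"
            )
        if self.expression and seen_conditions != set(self.conditions):
            missing = set(self.conditions) - seen_conditions
            raise ValueError(f"conditions without any record: {sorted(missing)}")

    # -- lookups -----------------------------------------------------------
    def transcripts(self) -> Iterator[TranscriptModel]:
        for g in self.genes:
            yield from g.transcripts

    def gene(self, gene_id: str) -> GeneModel:
        return self._gene[gene_id]

    def transcript(self, transcript_id: str) -> TranscriptModel:
        return self._tx[transcript_id]

    def gene_of_transcript(self, transcript_id: str) -> str:
        return self._gene_of_tx[transcript_id]

    def expression_for(
        self, transcript_id: str, condition: str
    ) -> Optional[ExpressionRecord]:
        return self._expr.get((transcript_id, condition))

    def n_transcripts(self) -> int:
        return len(self._tx)

    def multi_transcript_genes(self) -> list[GeneModel]:
        return [g for g in self.genes if len(g.transcripts) > 1]


def transcripts_per_multi_gene(dataset: SpliceDataset) -> float:
    """Mean number of isoforms per multi-transcript gene (2 decimals)."""
    multi = dataset.multi_transcript_genes()
    if not multi:
        return 0.0
    total = sum(len(g.transcripts) for g in multi)
    return round(total / len(multi), 2)
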