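"""Alternative-splicing event classification.

Each transcript is compared pairwise against its gene reference (the
hypothetical pre-RNA, or the most expressed transcript) and every deviation
is classified into one of eight event classes, with the genomic
coordinates of the spliced element(s) attached:

==== =====================================================================
ESI  single exon skipping/inclusion — one reference exon absent from the
     transcript, flanked by transcript exons
MESI multiple exon skipping — a run of k >= 2 consecutive reference exons
     absent, emitted as one event with k elements
A5   alternative 5' (donor) splice site — a transcript donor boundary
     strictly inside a reference exon (strand-relative)
A3   alternative 3' (acceptor) splice site — symmetric at the acceptor
IR   intron retention — a reference intron fully contained within a single
     transcript exon
ATSS alternative transcription start — the transcript's first exon shares
     no base with the reference's first exon; elements are the reference-
     exonic intervals 5' of the transcript start
ATTS alternative transcription termination — symmetric at the 3' end
MEE  mutually exclusive exons — detected transcript-pairwise, not against
     the pre-RNA (which contains both exons and can never show exclusivity)
==== =====================================================================

All orientation words (first/last, 5'/3', donor/acceptor) are
strand-relative.  ATSS/ATTS take precedence at the termini: reference
exons 5' of an alternative start are reported inside the single ATSS
event, never as skipped exons.  A transcript first exon that merely starts
inside the reference first exon is not an event (assemblers trim ends
non-biologically).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd

from .model import GeneModel, GenomicInterval, SpliceDataset, TranscriptModel
from .reference import MOST_EXPRESSED, PRE_RNA, ReferenceModel, reference_for

EVENT_CLASSES = ("ESI", "MESI", "A5", "A3", "IR", "ATSS", "ATTS", "MEE")


@dataclass(frozen=True)
class SpliceEvent:
    """One classified splicing event.

    ``elements`` hold the genomic coordinates of the spliced-in/out
    region(s).  ``flank_5``/``flank_3`` are the genomic positions of the
    mature-transcript boundaries adjacent to the element block on its
    transcript-5'/3' side (``None`` at a transcript terminus), kept for
    downstream motif analysis.
    """

    gene_id: str
    transcript_ids: tuple[str, ...]
    event_class: str
    elements: tuple[GenomicInterval, ...]
    flank_5: Optional[int] = None
    flank_3: Optional[int] = None
    reference_mode: str = PRE_RNA

    def __post_init__(self) -> None:
        if self.event_class not in EVENT_CLASSES:
            raise ValueError(f"unknown event class {self.event_class!r}")
        if not self.elements:
            raise ValueError("event with no elements")
        for e in self.elements:
            if e.length <= 0:  # pragma: no cover - GenomicInterval enforces
                raise ValueError("zero-length element")


def _overlap_len(a: GenomicInterval, b: GenomicInterval) -> int:
    return max(0, min(a.end, b.end) - max(a.start, b.start))


def _clip(e: GenomicInterval, lo: int, hi: int) -> Optional[GenomicInterval]:
    s, t = max(e.start, lo), min(e.end, hi)
    if s < t:
        return GenomicInterval(e.chrom, s, t, e.strand)
    return None


def _orient_flanks(
    strand: str, left: Optional[int], right: Optional[int]
) -> tuple[Optional[int], Optional[int]]:
    # left/right are genomic; flank_5 is the transcript-5' side
    return (left, right) if strand == "+" else (right, left)


def classify_transcript(
    t: TranscriptModel, ref: ReferenceModel
) -> list[SpliceEvent]:
    """Classify one transcript against its gene reference.

    Returns the deterministic event list of the decision procedure
    described in the module docstring, ordered by genomic position of the
    first element.
    """
    if t.gene_id != ref.gene_id:
        raise ValueError(
            f"transcript {t.transcript_id} (gene {t.gene_id}) classified "
            f"against reference of gene {ref.gene_id}"
        )
    R = ref.merged_exons
    plus = t.strand == "+"
    events: list[SpliceEvent] = []

    def emit(cls: str, elements: Sequence[GenomicInterval],
             left: Optional[int], right: Optional[int]) -> None:
        f5, f3 = _orient_flanks(t.strand, left, right)
        events.append(
            SpliceEvent(
                gene_id=t.gene_id,
                transcript_ids=(t.transcript_id,),
                event_class=cls,
                elements=tuple(elements),
                flank_5=f5,
                flank_3=f3,
                reference_mode=ref.mode,
            )
        )

    # --- ATSS / ATTS -------------------------------------------------------
    r_first = R[0] if plus else R[-1]
    r_last = R[-1] if plus else R[0]
    t_first = t.exons[0] if plus else t.exons[-1]
    t_last = t.exons[-1] if plus else t.exons[0]

    if _overlap_len(t_first, r_first) == 0:
        # maximal reference-exonic intervals strictly 5' of the transcript
        # start (genomically left of t.start on +, right of t.end on -)
        if plus:
            elements = [c for e in R if (c := _clip(e, 0, t.start))]
            if elements:
                emit("ATSS", elements, None, t.start)
        else:
            elements = [c for e in R if (c := _clip(e, t.end, ref.end))]
            if elements:
                emit("ATSS", elements, t.end, None)
    if _overlap_len(t_last, r_last) == 0:
        if plus:
            elements = [c for e in R if (c := _clip(e, t.end, ref.end))]
            if elements:
                emit("ATTS", elements, t.end, None)
        else:
            elements = [c for e in R if (c := _clip(e, 0, t.start))]
            if elements:
                emit("ATTS", elements, None, t.start)

    # --- IR ----------------------------------------------------------------
    for gap in ref.introns():
        for e in t.exons:
            if e.start <= gap.start and gap.end <= e.end:
                left, right = e.start, e.end
                emit("IR", [GenomicInterval(t.chrom, gap.start, gap.end, t.strand)],
                     left, right)
                break

    # --- ESI / MESI --------------------------------------------------------
    # reference exons entirely inside the transcript span sharing no base
    # with any transcript exon; maximal runs of consecutive reference exons
    skipped_idx = [
        i
        for i, e in enumerate(R)
        if t.start <= e.start and e.end <= t.end
        and all(_overlap_len(e, x) == 0 for x in t.exons)
    ]
    runs: list[list[int]] = []
    for i in skipped_idx:
        if runs and i == runs[-1][-1] + 1:
            runs[-1].append(i)
        else:
            runs.append([i])
    t_introns = [
        GenomicInterval(t.chrom, a.end, b.start, t.strand)
        for a, b in zip(t.exons, t.exons[1:])
    ]
    for run in runs:
        elements = [R[i] for i in run]
        # the transcript intron containing the run gives the flanks
        host = next(
            (
                iv
                for iv in t_introns
                if iv.start <= elements[0].start and elements[-1].end <= iv.end
            ),
            None,
        )
        left = host.start if host else None
        right = host.end if host else None
        emit("ESI" if len(run) == 1 else "MESI", elements, left, right)

    # --- A5 / A3 -----------------------------------------------------------
    # internal (spliced) boundaries only: iterate transcript introns
    for iv in t_introns:
        a, b = iv.start, iv.end
        # boundary at a: end of the preceding exon
        rj = next((e for e in R if e.start < a < e.end), None)
        if rj is not None and rj.end <= b:
            cls = "A5" if plus else "A3"
            emit(cls, [GenomicInterval(t.chrom, a, rj.end, t.strand)], a, b)
        # boundary at b: start of the following exon
        rk = next((e for e in R if e.start < b < e.end), None)
        if rk is not None and a <= rk.start:
            cls = "A3" if plus else "A5"
            emit(cls, [GenomicInterval(t.chrom, rk.start, b, t.strand)], a, b)

    events.sort(key=lambda ev: (ev.elements[0].start, ev.event_class))
    return events


# ---------------------------------------------------------------------------
# MEE
# ---------------------------------------------------------------------------

def detect_mee(gene: GeneModel, reference_mode: str = PRE_RNA) -> list[SpliceEvent]:
    """Mutually exclusive exons, detected over all transcript pairs.

    Exons a of Ta and b of Tb form an MEE when they do not overlap each
    other, neither shares a base with any exon of the other transcript,
    and both lie between a pair of exons with identical coordinates in Ta
    and Tb with no other exon of either transcript between those flanks.
    Events are deduplicated across pairs by element coordinates.
    """
    events: list[SpliceEvent] = []
    seen: set[tuple] = set()
    txs = sorted(gene.transcripts, key=lambda t: t.transcript_id)
    for ta, tb in combinations(txs, 2):
        common = [
            e for e in ta.exons
            if any(e.same_coords(f) for f in tb.exons)
        ]
        if not common:
            continue
        excl_a = [
            e for e in ta.exons
            if all(_overlap_len(e, f) == 0 for f in tb.exons)
        ]
        excl_b = [
            e for e in tb.exons
            if all(_overlap_len(e, f) == 0 for f in ta.exons)
        ]
        for a in excl_a:
            for b in excl_b:
                if _overlap_len(a, b) > 0:
                    continue
                lo = min(a.start, b.start)
                hi = max(a.end, b.end)
                lefts = [c for c in common if c.end <= lo]
                rights = [c for c in common if c.start >= hi]
                if not lefts or not rights:
                    continue
                lf = max(lefts, key=lambda c: c.end)
                rf = min(rights, key=lambda c: c.start)
                between = {
                    (e.start, e.end)
                    for e in (*ta.exons, *tb.exons)
                    if e.end > lf.end and e.start < rf.start
                }
                if between != {(a.start, a.end), (b.start, b.end)}:
                    continue
                elements = tuple(sorted((a, b), key=lambda e: e.start))
                key = tuple((e.start, e.end) for e in elements)
                if key in seen:
                    continue
                seen.add(key)
                f5, f3 = _orient_flanks(gene.strand, lf.end, rf.start)
                events.append(
                    SpliceEvent(
                        gene_id=gene.gene_id,
                        transcript_ids=(ta.transcript_id, tb.transcript_id),
                        event_class="MEE",
                        elements=elements,
                        flank_5=f5,
                        flank_3=f3,
                        reference_mode=reference_mode,
                    )
                )
    events.sort(key=lambda ev: ev.elements[0].start)
    return events


# ---------------------------------------------------------------------------
# Dataset-level driver and tabulation
# ---------------------------------------------------------------------------

def classify_all(
    dataset: SpliceDataset,
    reference_mode: str = PRE_RNA,
    reference_condition: Optional[str] = None,
) -> list[SpliceEvent]:
    """Classify every transcript against its gene reference, plus MEE
    detection per gene.  Stable ordering: (gene_id, transcript_ids,
    genomic position)."""
    if reference_mode == MOST_EXPRESSED and reference_condition is None:
        reference_condition = dataset.conditions[0]
    events: list[SpliceEvent] = []
    for gene in dataset.genes:
        ref = reference_for(
            gene, reference_mode, dataset.expression, reference_condition
        )
        for t in sorted(gene.transcripts, key=lambda t: t.transcript_id):
            events.extend(classify_transcript(t, ref))
        if len(gene.transcripts) >= 2:
            events.extend(detect_mee(gene, reference_mode))
    events.sort(
        key=lambda ev: (
            ev.gene_id,
            ev.transcript_ids,
            ev.elements[0].start,
            ev.event_class,
        )
    )
    return events


def count_events(events: Iterable[SpliceEvent]) -> dict[str, int]:
    """Per-class event counts, zero-filled over all eight classes."""
    counts = {cls: 0 for cls in EVENT_CLASSES}
    for ev in events:
        counts[ev.event_class] += 1
    return counts


def events_to_dataframe(events: Sequence[SpliceEvent]) -> pd.DataFrame:
    rows = []
    for ev in events:
        rows.append(
            {
                "gene_id": ev.gene_id,
                "transcript_ids": ",".join(ev.transcript_ids),
                "event_class": ev.event_class,
                "chrom": ev.elements[0].chrom,
                "strand": ev.elements[0].strand,
                # 1-based inclusive in serialized output
                "elements": ";".join(
                    f"{e.chrom}:{e.start + 1}-{e.end}" for e in ev.elements
                ),
                "flank_5": "" if ev.flank_5 is None else ev.flank_5,
                "flank_3": "" if ev.flank_3 is None else ev.flank_3,
                "reference_mode": ev.reference_mode,
            }
        )
    cols = [
        "gene_id", "transcript_ids", "event_class", "chrom", "strand",
        "elements", "flank_5", "flank_3", "reference_mode",
    ]
    return pd.DataFrame(rows, columns=cols)


def write_events_tsv(events: Sequence[SpliceEvent], path: str | Path) -> None:
    events_to_dataframe(events).to_csv(path, sep="\t", index=False)


def write_elements_bed(events: Sequence[SpliceEvent], path: str | Path) -> None:
    """BED6 of event elements (0-based half-open) for motif tools."""
    with open(path, "w") as fh:
        for ev in events:
            name = f"{ev.event_class}:{'|'.join(ev.transcript_ids)}"
            for e in ev.elements:
                fh.write(
                    f"{e.chrom}\t{e.start}\t{e.end}\t{name}\t0\t{e.strand}\n"
                )
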