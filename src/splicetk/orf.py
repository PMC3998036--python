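"""ORF annotation and NMD-sensitivity prediction.

For each transcript the most upstream compatible annotated start codon is
located, the downstream sequence is translated until the first in-frame
stop codon, and the distance from the stop codon to the final exon-exon
junction is recorded.  A transcript is flagged PTC+ (predicted
NMD-sensitive) when that distance exceeds a threshold, 50 nt by default,
following the literature consensus for the NMD rule.

Conventions (documented, user-configurable where it matters):

* Compatibility of an annotated start requires only that the codon's
  first genomic base maps into the transcript's exons and that a full
  codon can be read in transcript space.  The annotation's downstream
  exon structure is NOT required to match -- novel isoforms must be
  annotatable.  The mapped codon is not required to read ATG (annotated
  non-ATG starts pass through); ``strict_atg=True`` adds the check.
* The junction distance is measured from the LAST base of the stop codon
  (``stop_tpos``) to the last base of the penultimate exon
  (``junction_tpos``), both in transcript coordinates:
  ``stop_to_junction = junction_tpos - stop_tpos``.
* Transcripts with no in-frame stop are classed PTC- (no PTC is
  demonstrable), with the status recorded.  Single-exon transcripts have
  no junction and are PTC- by definition.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd

from .io import CdsRecord, SequenceProvider, transcript_sequence
from .model import TranscriptModel, genomic_to_transcript, transcript_length

logger = logging.getLogger(__name__)

STOP_CODONS = ("TAA", "TAG", "TGA")
DEFAULT_PTC_THRESHOLD = 50  # nt

STATUS_ANNOTATED = "annotated"
STATUS_NO_START = "no_compatible_start"
STATUS_NO_STOP = "no_stop_found"


@dataclass(frozen=True)
class OrfAnnotation:
    transcript_id: str
    status: str
    start_tpos: Optional[int] = None       # first base of start codon
    stop_tpos: Optional[int] = None        # last base of stop codon (inclusive)
    utr5_len: Optional[int] = None
    orf_len: Optional[int] = None          # includes the stop codon
    utr3_len: Optional[int] = None
    junction_tpos: Optional[int] = None    # last base of penultimate exon
    stop_to_junction: Optional[int] = None
    ptc: bool = False


def find_compatible_start(
    t: TranscriptModel,
    cds_records: Sequence[CdsRecord],
    strict_atg: bool = False,
    seq: Optional[str] = None,
) -> Optional[int]:
    """Transcript coordinate of the most upstream compatible annotated
    start codon, or None.

    A candidate is an annotated start on the transcript's chrom/strand
    whose codon-start base is exonic in the transcript and whose full
    codon fits within the transcript.  Among candidates the minimal
    transcript coordinate wins.
    """
    n = transcript_length(t)
    candidates = []
    for rec in cds_records:
        if rec.chrom != t.chrom or rec.strand != t.strand:
            continue
        tpos = genomic_to_transcript(t, rec.start_codon_genomic)
        if tpos is None or tpos + 3 > n:
            continue
        if strict_atg:
            if seq is None:
                raise ValueError("strict_atg requires the transcript sequence")
            if seq[tpos : tpos + 3] != "ATG":
                continue
        candidates.append(tpos)
    return min(candidates) if candidates else None


def scan_orf(seq: str, start_tpos: int) -> Optional[int]:
    """Walk codons from ``start_tpos``; return the transcript coordinate
    of the 3rd base of the first in-frame stop codon, or None if the
    frame runs off the end without a stop."""
    if not 0 <= start_tpos <= len(seq) - 3:
        raise ValueError(
            f"start {start_tpos} leaves no room for a codon in a "
            f"{len(seq)} nt sequence"
        )
    for i in range(start_tpos, len(seq) - 2, 3):
        if seq[i : i + 3] in STOP_CODONS:
            return i + 2
    return None


def junction_position(t: TranscriptModel) -> Optional[int]:
    """Transcript coordinate of the last base of the penultimate exon
    (the final exon-exon junction); None for single-exon transcripts."""
    if len(t.exons) == 1:
        return None
    last_exon = t.exons[-1] if t.strand == "+" else t.exons[0]
    return transcript_length(t) - last_exon.length - 1


def annotate_orf(
    t: TranscriptModel,
    seqs: SequenceProvider,
    cds_records: Sequence[CdsRecord],
    ptc_threshold: int = DEFAULT_PTC_THRESHOLD,
    strict_atg: bool = False,
) -> OrfAnnotation:
    """Full ORF/NMD annotation of one transcript."""
    if ptc_threshold < 0:
        raise ValueError("ptc_threshold must be >= 0")
    seq = transcript_sequence(t, seqs)
    n = len(seq)
    start = find_compatible_start(t, cds_records, strict_atg, seq)
    if start is None:
        return OrfAnnotation(t.transcript_id, STATUS_NO_START)
    stop = scan_orf(seq, start)
    junction = junction_position(t)
    if stop is None:
        return OrfAnnotation(
            t.transcript_id,
            STATUS_NO_STOP,
            start_tpos=start,
            utr5_len=start,
            junction_tpos=junction,
            ptc=False,
        )
    stj = None if junction is None else junction - stop
    ptc = junction is not None and stj is not None and stj > ptc_threshold
    return OrfAnnotation(
        transcript_id=t.transcript_id,
        status=STATUS_ANNOTATED,
        start_tpos=start,
        stop_tpos=stop,
        utr5_len=start,
        orf_len=stop - start + 1,
        utr3_len=n - stop - 1,
        junction_tpos=junction,
        stop_to_junction=stj,
        ptc=ptc,
    )


def annotate_all(
    transcripts: Iterable[TranscriptModel],
    seqs: SequenceProvider,
    cds_records: Sequence[CdsRecord],
    ptc_threshold: int = DEFAULT_PTC_THRESHOLD,
    strict_atg: bool = False,
) -> list[OrfAnnotation]:
    return [
        annotate_orf(t, seqs, cds_records, ptc_threshold, strict_atg)
        for t in sorted(transcripts, key=lambda t: t.transcript_id)
    ]


# ---------------------------------------------------------------------------
# Summaries
# ---------------------------------------------------------------------------

def ptc_percentages(
    n_ptc_minus: int, n_ptc_plus: int, n_no_start: int
) -> tuple[float, float, float]:
    """Percentages of (PTC-, PTC+, no compatible start) to one decimal."""
    total = n_ptc_minus + n_ptc_plus + n_no_start
    if total == 0:
        return (0.0, 0.0, 0.0)
    return (
        round(n_ptc_minus / total * 100.0, 1),
        round(n_ptc_plus / total * 100.0, 1),
        round(n_no_start / total * 100.0, 1),
    )


def summarize_ptc(annotations: Sequence[OrfAnnotation]) -> dict[str, float]:
    """Counts and percentages of PTC-, PTC+ and start-less transcripts.

    Transcripts without a compatible start are a separate class; everything
    else is PTC+/PTC- by flag (no_stop_found counts as PTC-).
    """
    n_no_start = sum(1 for a in annotations if a.status == STATUS_NO_START)
    n_plus = sum(1 for a in annotations if a.status != STATUS_NO_START and a.ptc)
    n_minus = len(annotations) - n_no_start - n_plus
    p_minus, p_plus, p_none = ptc_percentages(n_minus, n_plus, n_no_start)
    return {
        "ptc_minus": n_minus,
        "ptc_plus": n_plus,
        "no_compatible_start": n_no_start,
        "ptc_minus_pct": p_minus,
        "ptc_plus_pct": p_plus,
        "no_compatible_start_pct": p_none,
    }


def orf_to_dataframe(annotations: Sequence[OrfAnnotation]) -> pd.DataFrame:
    def cell(v: Optional[int]) -> object:
        return "" if v is None else v

    rows = [
        {
            "transcript_id": a.transcript_id,
            "status": a.status,
            "start_tpos": cell(a.start_tpos),
            "stop_tpos": cell(a.stop_tpos),
            "utr5_len": cell(a.utr5_len),
            "orf_len": cell(a.orf_len),
            "utr3_len": cell(a.utr3_len),
            "junction_tpos": cell(a.junction_tpos),
            "stop_to_junction": cell(a.stop_to_junction),
            "ptc": int(a.ptc),
        }
        for a in annotations
    ]
    cols = ["transcript_id", "status", "start_tpos", "stop_tpos", "utr5_len",
            "orf_len", "utr3_len", "junction_tpos", "stop_to_junction", "ptc"]
    return pd.DataFrame(rows, columns=cols)


def write_orf_tsv(
    annotations: Sequence[OrfAnnotation], path: str | Path
) -> None:
    orf_to_dataframe(annotations).to_csv(path, sep="\t", index=False)
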