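"""Browser-track export: GTF with transcripts color-coded by their
within-gene expression (isoform fraction).

GTF has no native color column, so the color rides in the attribute field
as ``color "R,G,B";`` plus a UCSC ``track`` header with an itemRgb-style
default.  One file per condition mirrors side-by-side condition tracks in
a browser.  The ramp is a declared grayscale: darker = higher isoform
fraction.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

from .model import SpliceDataset
from .quant import IfValue, compute_if, filter_dataset


@dataclass(frozen=True)
class ColorSpec:
    rgb: tuple[int, int, int]

    def __post_init__(self) -> None:
        for c in self.rgb:
            if not 0 <= c <= 255:
                raise ValueError(f"color channel {c} out of [0, 255]")

    def __str__(self) -> str:
        return ",".join(str(c) for c in self.rgb)


def if_to_color(if_pct: float) -> ColorSpec:
    """Grayscale ramp: channel = round(200 * (1 - min(IF, 100)/100)).

    IF 0 -> (200,200,200) light gray, IF 100 -> (0,0,0) black; monotone
    non-increasing channel value with IF.  Values above 100 are clamped.
    """
    if if_pct < 0:
        raise ValueError("IF must be >= 0")
    v = round(200 * (1 - min(if_pct, 100.0) / 100.0))
    return ColorSpec((v, v, v))


def write_gtf(
    dataset: SpliceDataset,
    condition: str,
    path: str | Path,
    ifs: Optional[Sequence[IfValue]] = None,
    filters: Sequence[str] = (),
    track_name: Optional[str] = None,
    source: str = "splicetk",
) -> None:
    """Write a browser-ready GTF for one condition.

    One ``transcript`` line plus per-exon ``exon`` lines per transcript,
    1-based inclusive coordinates, with a ``color`` attribute encoding the
    transcript's IF in ``condition``.  Deterministic line order; a track
    header line leads the file.
    """
    if condition not in dataset.conditions:
        raise ValueError(f"unknown condition {condition!r}")
    if filters:
        dataset = filter_dataset(dataset, filters)
    if ifs is None:
        ifs = compute_if(dataset)
    if_by_tx = {
        v.transcript_id: v.if_pct
        for v in ifs
        if v.condition == condition and v.defined
    }
    name = track_name or f"splicetk_{condition}"
    with open(path, "w") as fh:
        fh.write(
            f'track name="{name}" description="transcripts colored by '
            f'isoform fraction ({condition})" itemRgb="On"\n'
        )
        for g in dataset.genes:
            for t in sorted(g.transcripts, key=lambda t: t.transcript_id):
                color = if_to_color(if_by_tx.get(t.transcript_id, 0.0))
                attrs = (
                    f'gene_id "{g.gene_id}"; '
                    f'transcript_id "{t.transcript_id}"; '
                    f'color "{color}";'
                )
                fh.write(
                    f"{t.chrom}\t{source}\ttranscript\t{t.start + 1}\t{t.end}"
                    f"\t.\t{t.strand}\t.\t{attrs}\n"
                )
                for e in t.exons:
                    fh.write(
                        f"{e.chrom}\t{source}\texon\t{e.start + 1}\t{e.end}"
                        f"\t.\t{t.strand}\t.\t{attrs}\n"
                    )


def write_bed12(
    dataset: SpliceDataset,
    condition: str,
    path: str | Path,
    ifs: Optional[Sequence[IfValue]] = None,
    filters: Sequence[str] = (),
    track_name: Optional[str] = None,
) -> None:
    """BED12 + itemRgb alternative to :func:`write_gtf` (0-based
    half-open, blockStarts relative to chromStart)."""
    if condition not in dataset.conditions:
        raise ValueError(f"unknown condition {condition!r}")
    if filters:
        dataset = filter_dataset(dataset, filters)
    if ifs is None:
        ifs = compute_if(dataset)
    if_by_tx = {
        v.transcript_id: v.if_pct
        for v in ifs
        if v.condition == condition and v.defined
    }
    name = track_name or f"splicetk_{condition}"
    with open(path, "w") as fh:
        fh.write(f'track name="{name}" itemRgb="On"\n')
        for g in dataset.genes:
            for t in sorted(g.transcripts, key=lambda t: t.transcript_id):
                color = if_to_color(if_by_tx.get(t.transcript_id, 0.0))
                sizes = ",".join(str(e.length) for e in t.exons) + ","
                starts = ",".join(str(e.start - t.start) for e in t.exons) + ","
                fh.write(
                    "\t".join(
                        [
                            t.chrom,
                            str(t.start),
                            str(t.end),
                            t.transcript_id,
                            "0",
                            t.strand,
                            str(t.start),
                            str(t.start),
                            str(color),
                            str(len(t.exons)),
                            sizes,
                            starts,
                        ]
                    )
                    + "\n"
                )
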