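"""Readers and writers for GTF, genePred CDS tables, FASTA and expression
tables, plus dataset assembly.

GTF is read/written as 1-based inclusive and converted to internal 0-based
half-open coordinates at this boundary only.  The generic expression TSV is
the canonical non-Cufflinks entry point; its columns are documented in the
README.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence

from Bio import SeqIO
from Bio.Seq import Seq

from .model import (
    ExpressionRecord,
    GeneModel,
    GenomicInterval,
    SpliceDataset,
    TranscriptModel,
)

logger = logging.getLogger(__name__)

_ATTR_RE = re.compile(r'(\w+)\s+(?:"([^"]*)"|([^;\s]+))\s*;?')


@dataclass(frozen=True)
class CdsRecord:
    """An annotated start codon, from genePred or a simple table.

    ``start_codon_genomic`` is the genomic coordinate (0-based) of the
    first base of the start codon in transcript orientation; on the minus
    strand this is the genomically 3'-most base of the codon's span
    (``cdsEnd - 1`` in genePred terms).
    """

    name: str
    chrom: str
    strand: str
    start_codon_genomic: int

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"CDS record {self.name}: strand must be + or -")
        if self.start_codon_genomic < 0:
            raise ValueError(f"CDS record {self.name}: negative coordinate")


class SequenceProvider:
    """Chromosome name -> upper-case nucleotide sequence."""

    def __init__(self, sequences: dict[str, str]) -> None:
        self._seqs = {k: v.upper() for k, v in sequences.items()}

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._seqs

    def __getitem__(self, chrom: str) -> str:
        return self._seqs[chrom]

    def chroms(self) -> list[str]:
        return sorted(self._seqs)

    def fetch(self, chrom: str, start: int, end: int) -> str:
        seq = self._seqs[chrom]
        if not (0 <= start < end <= len(seq)):
            raise ValueError(
                f"region {chrom}:{start}-{end} outside sequence of "
                f"length {len(seq)}"
            )
        return seq[start:end]


def reverse_complement(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


# ---------------------------------------------------------------------------
# GTF
# ---------------------------------------------------------------------------

def _parse_attributes(text: str) -> dict[str, str]:
    out = {}
    for m in _ATTR_RE.finditer(text):
        out[m.group(1)] = m.group(2) if m.group(2) is not None else m.group(3)
    return out


def read_gtf(path: str | Path) -> list[GeneModel]:
    """Read exon features from a GTF file into gene models.

    Only ``exon`` feature lines are consumed; other features (CDS,
    start_codon, transcript, ...) are counted and logged.  Both
    ``key "value";`` and ``key value;`` attribute spellings are accepted;
    attributes beyond gene_id/transcript_id are preserved opaquely.
    Abutting exons of one transcript are merged with a warning.
    """
    exons: dict[str, list[GenomicInterval]] = {}
    meta: dict[str, tuple[str, str, str, str]] = {}  # tid -> (gid, chrom, strand, extra)
    order: list[str] = []
    skipped_features = 0

    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("track"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ValueError(
                    f"{path}:{lineno}: expected 9 tab-separated columns, "
                    f"got {len(fields)}"
                )
            chrom, _source, feature, start, end, _score, strand, _frame, attrs = fields
            if feature != "exon":
                skipped_features += 1
                continue
            try:
                start0 = int(start) - 1
                end0 = int(end)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: bad coordinates") from exc
            if start0 < 0 or end0 <= start0:
                raise ValueError(f"{path}:{lineno}: bad interval {start}-{end}")
            a = _parse_attributes(attrs)
            if "transcript_id" not in a or "gene_id" not in a:
                raise ValueError(
                    f"{path}:{lineno}: missing transcript_id/gene_id attribute"
                )
            tid, gid = a["transcript_id"], a["gene_id"]
            extra = "; ".join(
                f'{k} "{v}"' for k, v in a.items()
                if k not in ("transcript_id", "gene_id")
            )
            if tid not in exons:
                exons[tid] = []
                meta[tid] = (gid, chrom, strand, extra)
                order.append(tid)
            else:
                pg, pc, ps, _pe = meta[tid]
                if pc != chrom:
                    raise ValueError(
                        f"{path}:{lineno}: transcript {tid} spans chromosomes"
                    )
                if ps != strand:
                    raise ValueError(
                        f"{path}:{lineno}: transcript {tid} has exons on "
                        f"mixed strands"
                    )
            exons[tid].append(GenomicInterval(chrom, start0, end0, strand))

    if skipped_features:
        logger.info("read_gtf: ignored %d non-exon feature lines", skipped_features)

    by_gene: dict[str, list[TranscriptModel]] = {}
    gene_order: list[str] = []
    for tid in order:
        gid, chrom, strand, extra = meta[tid]
        merged = _merge_abutting(sorted(exons[tid]), tid)
        t = TranscriptModel(tid, gid, chrom, strand, tuple(merged), extra)
        if gid not in by_gene:
            by_gene[gid] = []
            gene_order.append(gid)
        by_gene[gid].append(t)
    return [GeneModel(gid, tuple(by_gene[gid])) for gid in gene_order]


def _merge_abutting(
    exons: list[GenomicInterval], tid: str
) -> list[GenomicInterval]:
    merged: list[GenomicInterval] = []
    for e in exons:
        if merged and e.start == merged[-1].end:
            logger.warning(
                "transcript %s: merging abutting exons at %s:%d",
                tid, e.chrom, e.start,
            )
            prev = merged.pop()
            e = GenomicInterval(e.chrom, prev.start, e.end, e.strand)
        elif merged and e.start < merged[-1].end:
            raise ValueError(f"transcript {tid}: overlapping exons")
        merged.append(e)
    return merged


def write_transcripts_gtf(
    genes: Iterable[GeneModel], path: str | Path, source: str = "splicetk"
) -> None:
    """Write plain exon-feature GTF (1-based inclusive), deterministic order."""
    with open(path, "w") as fh:
        for g in sorted(genes, key=lambda g: g.gene_id):
            for t in sorted(g.transcripts, key=lambda t: t.transcript_id):
                for e in t.exons:
                    attrs = (
                        f'gene_id "{g.gene_id}"; '
                        f'transcript_id "{t.transcript_id}";'
                    )
                    if t.extra_attributes:
                        attrs += f" {t.extra_attributes};"
                    fh.write(
                        f"{e.chrom}\t{source}\texon\t{e.start + 1}\t{e.end}"
                        f"\t.\t{t.strand}\t.\t{attrs}\n"
                    )


# ---------------------------------------------------------------------------
# Expression tables
# ---------------------------------------------------------------------------

GENERIC_COLUMNS = (
    "transcript_id",
    "gene_id",
    "condition",
    "transcript_expr",
    "gene_expr",
)
GENERIC_OPTIONAL = ("iso_status", "gene_status", "pvalue")


def read_expression(
    path: str | Path,
    fmt: str = "generic_tsv",
    conditions: Optional[Sequence[str]] = None,
    gene_expression_path: Optional[str | Path] = None,
) -> list[ExpressionRecord]:
    """Read per-transcript, per-condition expression records.

    ``generic_tsv``: header with columns transcript_id, gene_id, condition,
    transcript_expr, gene_expr and optional iso_status, gene_status, pvalue.

    ``cufflinks_tracking``: an isoforms.fpkm_tracking-like file with
    ``tracking_id``/``gene_id`` and per-condition ``<cond>_FPKM`` /
    ``<cond>_status`` columns (one record per transcript x condition).
    Gene-level FPKMs come from ``gene_expression_path`` (a
    genes.fpkm_tracking-like file) when given, else from the per-condition
    sum of isoform FPKMs of the gene.
    """
    if fmt == "generic_tsv":
        return _read_generic_tsv(path, conditions)
    if fmt == "cufflinks_tracking":
        return _read_cufflinks_tracking(path, conditions, gene_expression_path)
    raise ValueError(f"unknown expression format {fmt!r}")


def _read_generic_tsv(
    path: str | Path, conditions: Optional[Sequence[str]]
) -> list[ExpressionRecord]:
    records: list[ExpressionRecord] = []
    seen: set[tuple[str, str]] = set()
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        for col in GENERIC_COLUMNS:
            if col not in header:
                raise ValueError(f"{path}: missing column {col!r}")
        idx = {c: header.index(c) for c in header}
        for lineno, line in enumerate(fh, 2):
            if not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            tid = f[idx["transcript_id"]]
            cond = f[idx["condition"]]
            if conditions is not None and cond not in conditions:
                raise ValueError(
                    f"{path}:{lineno}: unknown condition label {cond!r}"
                )
            key = (tid, cond)
            if key in seen:
                raise ValueError(
                    f"{path}:{lineno}: duplicate row for transcript {tid} "
                    f"in condition {cond}"
                )
            seen.add(key)

            def opt(col: str) -> Optional[str]:
                if col in idx and f[idx[col]] not in ("", "NA", "-"):
                    return f[idx[col]]
                return None

            pval = opt("pvalue")
            records.append(
                ExpressionRecord(
                    transcript_id=tid,
                    gene_id=f[idx["gene_id"]],
                    condition=cond,
                    transcript_expr=float(f[idx["transcript_expr"]]),
                    gene_expr=float(f[idx["gene_expr"]]),
                    iso_status=opt("iso_status"),
                    gene_status=opt("gene_status"),
                    test_pvalue=float(pval) if pval is not None else None,
                )
            )
    return records


def _read_cufflinks_tracking(
    path: str | Path,
    conditions: Optional[Sequence[str]],
    gene_expression_path: Optional[str | Path],
) -> list[ExpressionRecord]:
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if "tracking_id" not in header or "gene_id" not in header:
            raise ValueError(f"{path}: not a fpkm_tracking file")
        if conditions is None:
            conditions = [
                c[: -len("_FPKM")] for c in header if c.endswith("_FPKM")
            ]
        for cond in conditions:
            if f"{cond}_FPKM" not in header:
                raise ValueError(f"{path}: missing column {cond}_FPKM")
        idx = {c: header.index(c) for c in header}
        rows = []
        for line in fh:
            if line.strip():
                rows.append(line.rstrip("\n").split("\t"))

    gene_fpkm: dict[tuple[str, str], float] = {}
    gene_status: dict[tuple[str, str], str] = {}
    if gene_expression_path is not None:
        with open(gene_expression_path) as fh:
            gheader = fh.readline().rstrip("\n").split("\t")
            gidx = {c: gheader.index(c) for c in gheader}
            for line in fh:
                if not line.strip():
                    continue
                f = line.split("\t")
                gid = f[gidx["tracking_id"]]
                for cond in conditions:
                    gene_fpkm[(gid, cond)] = float(f[gidx[f"{cond}_FPKM"]])
                    scol = f"{cond}_status"
                    if scol in gidx:
                        gene_status[(gid, cond)] = f[gidx[scol]].strip()
    else:
        for f in rows:
            gid = f[idx["gene_id"]]
            for cond in conditions:
                gene_fpkm[(gid, cond)] = gene_fpkm.get((gid, cond), 0.0) + float(
                    f[idx[f"{cond}_FPKM"]]
                )

    records: list[ExpressionRecord] = []
    seen: set[tuple[str, str]] = set()
    for f in rows:
        tid = f[idx["tracking_id"]]
        gid = f[idx["gene_id"]]
        for cond in conditions:
            key = (tid, cond)
            if key in seen:
                raise ValueError(
                    f"{path}: duplicate tracking row for {tid} / {cond}"
                )
            seen.add(key)
            scol = f"{cond}_status"
            records.append(
                ExpressionRecord(
                    transcript_id=tid,
                    gene_id=gid,
                    condition=cond,
                    transcript_expr=float(f[idx[f"{cond}_FPKM"]]),
                    gene_expr=gene_fpkm.get((gid, cond), 0.0),
                    iso_status=f[idx[scol]].strip() if scol in idx else None,
                    gene_status=gene_status.get((gid, cond)),
                )
            )
    return records


def write_expression_tsv(
    records: Iterable[ExpressionRecord], path: str | Path
) -> None:
    """Write records in the generic TSV dialect (round-trips read_expression)."""
    cols = GENERIC_COLUMNS + GENERIC_OPTIONAL
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for r in sorted(records, key=lambda r: (r.gene_id, r.transcript_id, r.condition)):
            fh.write(
                "\t".join(
                    [
                        r.transcript_id,
                        r.gene_id,
                        r.condition,
                        repr(r.transcript_expr),
                        repr(r.gene_expr),
                        r.iso_status or "",
                        r.gene_status or "",
                        "" if r.test_pvalue is None else repr(r.test_pvalue),
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# CDS / genePred
# ---------------------------------------------------------------------------

def read_cds_table(path: str | Path, dialect: str = "genepred") -> list[CdsRecord]:
    """Read annotated start codons.

    ``genepred``: UCSC refGene column order (name, chrom, strand, txStart,
    txEnd, cdsStart, cdsEnd, exonCount, exonStarts, exonEnds); rows with
    cdsStart == cdsEnd (non-coding) are dropped with a logged count.

    ``simple``: tab-separated ``name chrom strand start_codon_genomic``
    (0-based; the name column may be omitted).
    """
    if dialect == "genepred":
        return _read_genepred(path)
    if dialect == "simple":
        return _read_simple_cds(path)
    raise ValueError(f"unknown CDS table dialect {dialect!r}")


def _read_genepred(path: str | Path) -> list[CdsRecord]:
    records = []
    noncoding = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 10:
                raise ValueError(f"{path}:{lineno}: expected >=10 genePred columns")
            name, chrom, strand = f[0], f[1], f[2]
            cds_start, cds_end = int(f[5]), int(f[6])
            exon_count = int(f[7])
            starts = [int(x) for x in f[8].rstrip(",").split(",") if x]
            ends = [int(x) for x in f[9].rstrip(",").split(",") if x]
            if len(starts) != exon_count or len(ends) != exon_count:
                raise ValueError(
                    f"{path}:{lineno}: exonStarts/exonEnds length mismatch "
                    f"with exonCount={exon_count}"
                )
            if cds_start == cds_end:
                noncoding += 1
                continue
            start_codon = cds_start if strand == "+" else cds_end - 1
            records.append(CdsRecord(name, chrom, strand, start_codon))
    if noncoding:
        logger.info("read_cds_table: dropped %d non-coding rows", noncoding)
    return records


def _read_simple_cds(path: str | Path) -> list[CdsRecord]:
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) == 3:
                name, (chrom, strand, pos) = f"cds{lineno}", f
            elif len(f) == 4:
                name, chrom, strand, pos = f
            else:
                raise ValueError(
                    f"{path}:{lineno}: simple CDS table needs 3 or 4 columns"
                )
            records.append(CdsRecord(name, chrom, strand, int(pos)))
    return records


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> SequenceProvider:
    """Read a multi-record FASTA; headers truncated at first whitespace."""
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seqs:
            raise ValueError(f"{path}: duplicate sequence header {rec.id!r}")
        seqs[rec.id] = str(rec.seq).upper()
    return SequenceProvider(seqs)


def write_fasta(seqs: dict[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name in sorted(seqs):
            fh.write(f">{name}\n")
            s = seqs[name]
            for i in range(0, len(s), width):
                fh.write(s[i : i + width] + "\n")


def transcript_sequence(t: TranscriptModel, seqs: SequenceProvider) -> str:
    """Mature transcript sequence, 5'->3' in transcript orientation."""
    parts = [seqs.fetch(t.chrom, e.start, e.end) for e in t.exons]
    joined = "".join(parts)
    return joined if t.strand == "+" else reverse_complement(joined)


# ---------------------------------------------------------------------------
# Dataset assembly
# ---------------------------------------------------------------------------

def build_dataset(
    genes: Sequence[GeneModel],
    expression: Sequence[ExpressionRecord],
    conditions: Sequence[str],
    assembler: str = "unknown",
) -> SpliceDataset:
    """Assemble a SpliceDataset, filling missing (transcript, condition)
    pairs with zero-expression records (counted and logged)."""
    have = {(r.transcript_id, r.condition) for r in expression}
    filled: list[ExpressionRecord] = list(expression)
    missing = 0
    for g in genes:
        for t in g.transcripts:
            for cond in conditions:
                if (t.transcript_id, cond) not in have:
                    missing += 1
                    filled.append(
                        ExpressionRecord(
                            t.transcript_id, g.gene_id, cond, 0.0, 0.0
                        )
                    )
    if missing:
        logger.warning(
            "build_dataset: %d missing (transcript, condition) expression "
            "values coerced to 0", missing,
        )
    return SpliceDataset(genes, filled, conditions, assembler)
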