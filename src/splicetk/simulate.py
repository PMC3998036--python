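"""Deterministic synthetic-data generator and brute-force oracles.

Generates coherent GTF + FASTA + genePred + expression fixtures with
planted splicing events, planted CDS/PTC structure and planted isoform
switches, together with ground-truth sidecar tables.  Also houses the
per-base classification oracle used by the test suite as an independent
check of the interval-algebra classifier.

Planting layout per gene (each gene lives on its own contig):

* a backbone transcript carries every reference exon and is guaranteed
  the most expressed isoform in the first condition, so ground-truth
  events are declared against the ``most_expressed`` reference (a
  retained intron is by construction exonic in the merged pre-RNA of its
  own gene, so IR is only observable against a transcript reference);
* each planted event class adds one deviating transcript touching a
  distinct exon/intron slot (MEE adds two transcripts with novel,
  mutually exclusive exons inside one widened intron);
* splice-site dinucleotides are planted canonical (GT..AG in transcript
  orientation) per unique donor/acceptor site with a configurable
  canonical fraction, so splice-motif QC is testable against a known rate;
* planted CDS codons are written explicitly (start codon, stop-free
  in-frame body, stop codon at an exact distance from the final exon-exon
  junction), so ORF ground truth is exact.  Genes carry either planted
  events or a planted CDS, never both, so dinucleotide planting at novel
  junctions (which falls inside backbone exons) can never corrupt ORF
  codons.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .classify import SpliceEvent, _orient_flanks
from .io import (
    CdsRecord,
    SequenceProvider,
    write_expression_tsv,
    write_fasta,
    write_transcripts_gtf,
)
from .model import (
    ExpressionRecord,
    GeneModel,
    GenomicInterval,
    SpliceDataset,
    TranscriptModel,
    transcript_length,
    transcript_to_genomic,
)
from .orf import OrfAnnotation, junction_position
from .reference import MOST_EXPRESSED, ReferenceModel

logger = logging.getLogger(__name__)

STOPS = ("TAA", "TAG", "TGA")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

DEFAULT_CANONICAL_FRACTION = 0.93  # matches typical assembled human data
DEFAULT_CONDITIONS = ("WT", "KD")
DEFAULT_SWITCH_DIF = 35.0  # percentage points planted for switch genes

EVENT_CHOICES = ("ESI", "MESI", "A5", "A3", "IR", "ATSS", "ATTS", "MEE")


@dataclass(frozen=True)
class GeneBlueprint:
    """Recipe for one synthetic gene."""

    gene_id: str
    seed: int
    strand: str = "+"
    chrom: Optional[str] = None
    n_reference_exons: int = 8
    exon_len_range: tuple[int, int] = (120, 260)
    intron_len_range: tuple[int, int] = (80, 200)
    planted_events: tuple[str, ...] = ()
    # ("canonical_stop",) | ("ptc", distance_nt) | ("no_start",) | None
    planted_cds: Optional[tuple] = None
    switch_dif: float = 0.0
    base_gene_expr: float = 100.0
    canonical_fraction: float = DEFAULT_CANONICAL_FRACTION
    conditions: tuple[str, str] = DEFAULT_CONDITIONS
    flank: int = 60

    @property
    def contig(self) -> str:
        return self.chrom or f"contig_{self.gene_id}"


@dataclass
class GeneratedGene:
    gene: GeneModel
    chrom: str
    sequence: str
    cds_records: list[CdsRecord]
    expression: list[ExpressionRecord]
    truth_events: list[SpliceEvent]
    truth_orf: Optional[OrfAnnotation]
    truth_switch: Optional[tuple[str, str, str]]  # (gene, up_tid, down_tid)
    n_donor_sites: int = 0
    n_donor_canonical: int = 0
    n_acceptor_sites: int = 0
    n_acceptor_canonical: int = 0
    genepred_row: Optional[str] = None


@dataclass
class GeneratedDataset:
    dataset: SpliceDataset
    sequences: SequenceProvider
    cds_records: list[CdsRecord]
    genes: list[GeneratedGene]
    conditions: tuple[str, str]

    @property
    def truth_events(self) -> list[SpliceEvent]:
        return [ev for g in self.genes for ev in g.truth_events]

    @property
    def truth_switch_genes(self) -> list[tuple[str, str, str]]:
        return [g.truth_switch for g in self.genes if g.truth_switch]

    @property
    def truth_orfs(self) -> list[OrfAnnotation]:
        return [g.truth_orf for g in self.genes if g.truth_orf is not None]

    def planted_canonical_rates(self) -> tuple[float, float]:
        nd = sum(g.n_donor_sites for g in self.genes)
        na = sum(g.n_acceptor_sites for g in self.genes)
        cd = sum(g.n_donor_canonical for g in self.genes)
        ca = sum(g.n_acceptor_canonical for g in self.genes)
        return (100.0 * cd / nd if nd else 0.0, 100.0 * ca / na if na else 0.0)


def _revcomp(s: str) -> str:
    return s.translate(_COMPLEMENT)[::-1]


class _Unrealizable(ValueError):
    pass


def generate_gene(bp: GeneBlueprint) -> GeneratedGene:
    """Deterministically generate one gene from its blueprint."""
    rng = np.random.default_rng(bp.seed)
    m = bp.n_reference_exons
    plus = bp.strand == "+"
    if bp.strand not in ("+", "-"):
        raise _Unrealizable(f"{bp.gene_id}: bad strand {bp.strand!r}")

    # ---- slot allocation --------------------------------------------------
    exon_pool = list(range(1, m - 1))          # internal exons
    intron_pool = list(range(0, m - 1))        # introns between exon i, i+1
    needs: list[tuple[str, object]] = []
    for cls in bp.planted_events:
        if cls in ("ESI", "A5", "A3"):
            if not exon_pool:
                raise _Unrealizable(
                    f"{bp.gene_id}: {cls} needs a free internal exon "
                    f"(n_reference_exons={m} too small)"
                )
            needs.append((cls, exon_pool.pop(0)))
        elif cls == "MESI":
            pair = next(
                (
                    (i, i + 1)
                    for i in exon_pool
                    if i + 1 in exon_pool
                ),
                None,
            )
            if pair is None:
                raise _Unrealizable(
                    f"{bp.gene_id}: MESI needs two adjacent internal exons"
                )
            exon_pool.remove(pair[0])
            exon_pool.remove(pair[1])
            needs.append((cls, pair))
        elif cls in ("IR", "MEE"):
            if not intron_pool:
                raise _Unrealizable(f"{bp.gene_id}: {cls} needs a free intron")
            needs.append((cls, intron_pool.pop(0)))
        elif cls == "ATSS":
            if m < 2:
                raise _Unrealizable(f"{bp.gene_id}: ATSS needs >=2 exons")
            needs.append((cls, None))
        elif cls == "ATTS":
            if m < 2:
                raise _Unrealizable(f"{bp.gene_id}: ATTS needs >=2 exons")
            needs.append((cls, None))
        else:
            raise _Unrealizable(f"{bp.gene_id}: unknown event class {cls!r}")

    mee_introns = {slot for cls, slot in needs if cls == "MEE"}

    # ---- reference coordinates -------------------------------------------
    exon_lens = rng.integers(*bp.exon_len_range, size=m, endpoint=True)
    intron_lens = rng.integers(*bp.intron_len_range, size=max(m - 1, 1),
                               endpoint=True)
    mee_geom: dict[int, tuple[int, int, int]] = {}  # slot -> (gap, lenX, lenY)
    for slot in mee_introns:
        gap = 30
        lx = int(rng.integers(60, 121))
        ly = int(rng.integers(60, 121))
        mee_geom[slot] = (gap, lx, ly)
        intron_lens[slot] = 3 * gap + lx + ly

    contig = bp.contig
    pos = bp.flank
    ref_exons: list[GenomicInterval] = []
    for i in range(m):
        e = GenomicInterval(contig, pos, pos + int(exon_lens[i]), bp.strand)
        ref_exons.append(e)
        pos = e.end
        if i < m - 1:
            pos += int(intron_lens[i])
    contig_len = pos + bp.flank

    # ---- transcripts ------------------------------------------------------
    tcount = 1
    backbone_id = f"{bp.gene_id}.1"

    def new_tid() -> str:
        nonlocal tcount
        tcount += 1
        return f"{bp.gene_id}.{tcount}"

    def mk(tid: str, exons: Sequence[GenomicInterval]) -> TranscriptModel:
        return TranscriptModel(tid, bp.gene_id, contig, bp.strand, tuple(exons))

    backbone = mk(backbone_id, ref_exons)
    ref = ReferenceModel(
        gene_id=bp.gene_id,
        mode=MOST_EXPRESSED,
        chrom=contig,
        strand=bp.strand,
        merged_exons=tuple(ref_exons),
        source_transcript_id=backbone_id,
    )
    transcripts: list[TranscriptModel] = [backbone]
    truth_events: list[SpliceEvent] = []

    def truth(cls: str, tids: tuple[str, ...],
              elements: Sequence[GenomicInterval],
              left: Optional[int], right: Optional[int]) -> None:
        f5, f3 = _orient_flanks(bp.strand, left, right)
        truth_events.append(
            SpliceEvent(
                gene_id=bp.gene_id,
                transcript_ids=tids,
                event_class=cls,
                elements=tuple(elements),
                flank_5=f5,
                flank_3=f3,
                reference_mode=MOST_EXPRESSED,
            )
        )

    shift_min, shift_max = 10, 60
    for cls, slot in needs:
        if cls == "ESI":
            i = slot
            tid = new_tid()
            transcripts.append(mk(tid, ref_exons[:i] + ref_exons[i + 1:]))
            truth(cls, (tid,), [ref_exons[i]],
                  ref_exons[i - 1].end, ref_exons[i + 1].start)
        elif cls == "MESI":
            i, j = slot
            tid = new_tid()
            transcripts.append(mk(tid, ref_exons[:i] + ref_exons[j + 1:]))
            truth(cls, (tid,), [ref_exons[i], ref_exons[j]],
                  ref_exons[i - 1].end, ref_exons[j + 1].start)
        elif cls in ("A5", "A3"):
            i = slot
            e = ref_exons[i]
            d = int(rng.integers(shift_min, shift_max + 1))
            # A5 shifts the donor (transcript-3' exon boundary), A3 the
            # acceptor; genomic side depends on strand
            trim_end = (cls == "A5") == plus
            if trim_end:
                alt_exon = GenomicInterval(contig, e.start, e.end - d, bp.strand)
                element = GenomicInterval(contig, e.end - d, e.end, bp.strand)
                left, right = e.end - d, ref_exons[i + 1].start
            else:
                alt_exon = GenomicInterval(contig, e.start + d, e.end, bp.strand)
                element = GenomicInterval(contig, e.start, e.start + d, bp.strand)
                left, right = ref_exons[i - 1].end, e.start + d
            tid = new_tid()
            transcripts.append(
                mk(tid, ref_exons[:i] + [alt_exon] + ref_exons[i + 1:])
            )
            truth(cls, (tid,), [element], left, right)
        elif cls == "IR":
            i = slot
            merged = GenomicInterval(
                contig, ref_exons[i].start, ref_exons[i + 1].end, bp.strand
            )
            element = GenomicInterval(
                contig, ref_exons[i].end, ref_exons[i + 1].start, bp.strand
            )
            tid = new_tid()
            transcripts.append(
                mk(tid, ref_exons[:i] + [merged] + ref_exons[i + 2:])
            )
            truth(cls, (tid,), [element], merged.start, merged.end)
        elif cls == "ATSS":
            # drop the transcript-first exon (genomic-first on +)
            tid = new_tid()
            if plus:
                transcripts.append(mk(tid, ref_exons[1:]))
                truth(cls, (tid,), [ref_exons[0]], None, ref_exons[1].start)
            else:
                transcripts.append(mk(tid, ref_exons[:-1]))
                truth(cls, (tid,), [ref_exons[-1]], ref_exons[-2].end, None)
        elif cls == "ATTS":
            tid = new_tid()
            if plus:
                transcripts.append(mk(tid, ref_exons[:-1]))
                truth(cls, (tid,), [ref_exons[-1]], ref_exons[-2].end, None)
            else:
                transcripts.append(mk(tid, ref_exons[1:]))
                truth(cls, (tid,), [ref_exons[0]], None, ref_exons[1].start)
        elif cls == "MEE":
            i = slot
            gap, lx, ly = mee_geom[i]
            xs = ref_exons[i].end + gap
            x = GenomicInterval(contig, xs, xs + lx, bp.strand)
            y = GenomicInterval(contig, x.end + gap, x.end + gap + ly, bp.strand)
            ta, tb = new_tid(), new_tid()
            transcripts.append(
                mk(ta, ref_exons[: i + 1] + [x] + ref_exons[i + 1:])
            )
            transcripts.append(
                mk(tb, ref_exons[: i + 1] + [y] + ref_exons[i + 1:])
            )
            truth(cls, (ta, tb), [x, y],
                  ref_exons[i].end, ref_exons[i + 1].start)

    gene = GeneModel(bp.gene_id, tuple(transcripts))

    # ---- genome sequence --------------------------------------------------
    seq = list("".join(rng.choice(list("ACGT"), size=contig_len)))

    donor_sites: dict[int, None] = {}
    acceptor_sites: dict[int, None] = {}
    for t in transcripts:
        for a, b in zip(t.exons, t.exons[1:]):
            iv_start, iv_end = a.end, b.start
            if plus:
                donor_sites[iv_start] = None
                acceptor_sites[iv_end] = None
            else:
                donor_sites[iv_end] = None
                acceptor_sites[iv_start] = None

    n_donor_canon = n_acc_canon = 0
    for pos_ in sorted(donor_sites):
        canonical = bool(rng.random() < bp.canonical_fraction)
        motif = "GT" if canonical else "CC"
        n_donor_canon += canonical
        if plus:
            seq[pos_ : pos_ + 2] = list(motif)          # intron start
        else:
            seq[pos_ - 2 : pos_] = list(_revcomp(motif))  # intron end
    for pos_ in sorted(acceptor_sites):
        canonical = bool(rng.random() < bp.canonical_fraction)
        motif = "AG" if canonical else "CC"
        n_acc_canon += canonical
        if plus:
            seq[pos_ - 2 : pos_] = list(motif)
        else:
            seq[pos_ : pos_ + 2] = list(_revcomp(motif))

    # ---- CDS planting (backbone transcript) -------------------------------
    cds_records: list[CdsRecord] = []
    truth_orf: Optional[OrfAnnotation] = None
    genepred_row: Optional[str] = None
    if bp.planted_cds is not None:
        cds_records, truth_orf, genepred_row = _plant_cds(
            bp, backbone, seq, rng
        )

    # ---- expression -------------------------------------------------------
    c1, c2 = bp.conditions
    k = len(transcripts) - 1
    if bp.switch_dif > 0 and k >= 1:
        if_c1 = {backbone_id: 70.0}
        if_c2 = {backbone_id: 70.0 - bp.switch_dif}
        up_tid = transcripts[1].transcript_id
        rest = 30.0
        share = rest / k
        for t in transcripts[1:]:
            if_c1[t.transcript_id] = share
            if_c2[t.transcript_id] = share
        if_c2[up_tid] += bp.switch_dif
        truth_switch = (bp.gene_id, up_tid, backbone_id)
    else:
        if_c1 = {backbone_id: 60.0 if k else 100.0}
        for t in transcripts[1:]:
            if_c1[t.transcript_id] = 40.0 / k
        if_c2 = dict(if_c1)
        truth_switch = None

    expression: list[ExpressionRecord] = []
    for cond, ifs in ((c1, if_c1), (c2, if_c2)):
        gexpr = bp.base_gene_expr
        for t in transcripts:
            expression.append(
                ExpressionRecord(
                    transcript_id=t.transcript_id,
                    gene_id=bp.gene_id,
                    condition=cond,
                    transcript_expr=ifs[t.transcript_id] / 100.0 * gexpr,
                    gene_expr=gexpr,
                    iso_status="OK",
                    gene_status="OK",
                )
            )

    return GeneratedGene(
        gene=gene,
        chrom=contig,
        sequence="".join(seq),
        cds_records=cds_records,
        expression=expression,
        truth_events=truth_events,
        truth_orf=truth_orf,
        truth_switch=truth_switch,
        n_donor_sites=len(donor_sites),
        n_donor_canonical=n_donor_canon,
        n_acceptor_sites=len(acceptor_sites),
        n_acceptor_canonical=n_acc_canon,
        genepred_row=genepred_row,
    )


def _plant_cds(
    bp: GeneBlueprint,
    backbone: TranscriptModel,
    seq: list[str],
    rng: np.random.Generator,
) -> tuple[list[CdsRecord], Optional[OrfAnnotation], Optional[str]]:
    kind = bp.planted_cds[0]
    tid = backbone.transcript_id
    n = transcript_length(backbone)
    junction = junction_position(backbone)

    if kind == "no_start":
        return [], OrfAnnotation(tid, "no_compatible_start"), None
    if kind == "canonical_stop":
        if junction is None:
            stop_tpos = n - 10
        else:
            last_len = n - junction - 1
            stop_tpos = junction + max(6, last_len // 2)
    elif kind == "ptc":
        dist = int(bp.planted_cds[1])
        if junction is None:
            raise _Unrealizable(
                f"{bp.gene_id}: ptc planting needs a multi-exon backbone"
            )
        stop_tpos = junction - dist
    else:
        raise _Unrealizable(f"{bp.gene_id}: unknown planted_cds {kind!r}")

    target_utr5 = 24
    kmax = (stop_tpos + 1 - target_utr5) // 3
    if kmax < 2:
        raise _Unrealizable(
            f"{bp.gene_id}: planted stop at {stop_tpos} leaves no room for "
            f"an ORF (transcript length {n})"
        )
    start_tpos = stop_tpos + 1 - 3 * kmax
    if not (0 <= start_tpos and stop_tpos < n):
        raise _Unrealizable(f"{bp.gene_id}: planted CDS outside transcript")

    def write_tseq(tpos: int, s: str) -> None:
        for off, base in enumerate(s):
            g = transcript_to_genomic(backbone, tpos + off)
            seq[g] = base if backbone.strand == "+" else base.translate(_COMPLEMENT)

    write_tseq(start_tpos, "ATG")
    codons = "".join(
        _random_sense_codon(rng) for _ in range((stop_tpos - 2 - (start_tpos + 3)) // 3)
    )
    write_tseq(start_tpos + 3, codons)
    stop_codon = str(rng.choice(STOPS))
    write_tseq(stop_tpos - 2, stop_codon)

    start_g = transcript_to_genomic(backbone, start_tpos)
    stop_g = transcript_to_genomic(backbone, stop_tpos)
    if backbone.strand == "+":
        cds_start, cds_end = start_g, stop_g + 1
    else:
        cds_start, cds_end = stop_g, start_g + 1
    rec = CdsRecord(f"{bp.gene_id}.cds", backbone.chrom, backbone.strand, start_g)

    stj = None if junction is None else junction - stop_tpos
    truth = OrfAnnotation(
        transcript_id=tid,
        status="annotated",
        start_tpos=start_tpos,
        stop_tpos=stop_tpos,
        utr5_len=start_tpos,
        orf_len=stop_tpos - start_tpos + 1,
        utr3_len=n - stop_tpos - 1,
        junction_tpos=junction,
        stop_to_junction=stj,
        ptc=stj is not None and stj > 50,
    )
    genepred_row = "\t".join(
        [
            rec.name,
            backbone.chrom,
            backbone.strand,
            str(backbone.start),
            str(backbone.end),
            str(cds_start),
            str(cds_end),
            str(len(backbone.exons)),
            ",".join(str(e.start) for e in backbone.exons) + ",",
            ",".join(str(e.end) for e in backbone.exons) + ",",
        ]
    )
    return [rec], truth, genepred_row


def _random_sense_codon(rng: np.random.Generator) -> str:
    while True:
        codon = "".join(rng.choice(list("ACGT"), size=3))
        if codon not in STOPS:
            return codon


# ---------------------------------------------------------------------------
# Dataset-level generation
# ---------------------------------------------------------------------------

CDS_CYCLE: tuple[tuple, ...] = (
    ("canonical_stop",),
    ("canonical_stop",),
    ("canonical_stop",),
    ("canonical_stop",),
    ("canonical_stop",),
    ("canonical_stop",),
    ("ptc", 60),
    ("no_start",),
)


def generate_dataset(
    n_genes: int,
    seed: int,
    class_mix: Sequence[str] = EVENT_CHOICES,
    switch_fraction: float = 0.2,
    cds_fraction: float = 0.3,
    canonical_fraction: float = DEFAULT_CANONICAL_FRACTION,
    conditions: tuple[str, str] = DEFAULT_CONDITIONS,
    out_dir: Optional[str | Path] = None,
) -> GeneratedDataset:
    """Generate a full coherent input set with ground truth.

    Genes are split into switch genes (``switch_fraction``), CDS genes
    (``cds_fraction``, single-transcript backbones carrying a planted
    ORF), and event genes cycling through ``class_mix``.  When ``out_dir``
    is given, GTF/FASTA/genePred/expression inputs plus ground-truth
    sidecar TSVs are written there.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    rng = np.random.default_rng(seed)
    seeds = rng.integers(0, 2**31 - 1, size=n_genes)
    n_switch = round(n_genes * switch_fraction)
    n_cds = round(n_genes * cds_fraction)

    generated: list[GeneratedGene] = []
    ev_i = 0
    for i in range(n_genes):
        gene_id = f"G{i + 1:05d}"
        strand = "+" if rng.random() < 0.5 else "-"
        m = int(rng.integers(6, 10))
        common = dict(
            gene_id=gene_id,
            seed=int(seeds[i]),
            strand=strand,
            n_reference_exons=m,
            canonical_fraction=canonical_fraction,
            conditions=conditions,
        )
        if i < n_switch:
            bp = GeneBlueprint(
                planted_events=("ESI",),
                switch_dif=DEFAULT_SWITCH_DIF,
                **common,
            )
        elif i < n_switch + n_cds:
            bp = GeneBlueprint(
                planted_cds=CDS_CYCLE[(i - n_switch) % len(CDS_CYCLE)],
                **common,
            )
        else:
            cls = class_mix[ev_i % len(class_mix)]
            ev_i += 1
            bp = GeneBlueprint(planted_events=(cls,), **common)
        generated.append(generate_gene(bp))

    genes = [g.gene for g in generated]
    expression = [r for g in generated for r in g.expression]
    cds = [r for g in generated for r in g.cds_records]
    seqs = SequenceProvider({g.chrom: g.sequence for g in generated})
    dataset = SpliceDataset(genes, expression, conditions, assembler="splicetk-sim")
    result = GeneratedDataset(dataset, seqs, cds, generated, conditions)

    if out_dir is not None:
        _write_dataset(result, Path(out_dir))
    return result


def _write_dataset(ds: GeneratedDataset, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    write_transcripts_gtf(ds.dataset.genes, out / "transcripts.gtf")
    write_fasta(
        {g.chrom: g.sequence for g in ds.genes}, out / "genome.fa"
    )
    write_expression_tsv(ds.dataset.expression, out / "expression.tsv")
    with open(out / "cds.genepred", "w") as fh:
        for g in ds.genes:
            if g.genepred_row:
                fh.write(g.genepred_row + "\n")
    from .classify import write_events_tsv  # local import to avoid cycle

    write_events_tsv(ds.truth_events, out / "truth_events.tsv")
    from .orf import write_orf_tsv

    write_orf_tsv(ds.truth_orfs, out / "truth_orf.tsv")
    with open(out / "truth_switches.tsv", "w") as fh:
        fh.write("gene_id\tup_transcript_id\tdown_transcript_id\n")
        for gid, up, down in ds.truth_switch_genes:
            fh.write(f"{gid}\t{up}\t{down}\n")
    dpct, apct = ds.planted_canonical_rates()
    with open(out / "truth_motifs.tsv", "w") as fh:
        fh.write("metric\tvalue\n")
        fh.write(f"planted_donor_gt_pct\t{dpct:.4f}\n")
        fh.write(f"planted_acceptor_ag_pct\t{apct:.4f}\n")


# ---------------------------------------------------------------------------
# Per-base classification oracle
# ---------------------------------------------------------------------------

def oracle_classify(
    t: TranscriptModel, ref: ReferenceModel
) -> list[tuple[str, tuple[tuple[int, int], ...]]]:
    """Brute-force event derivation from per-base membership vectors.

    Returns ``(event_class, ((start, end), ...))`` tuples implementing the
    same normative decision rules as the production classifier, but via
    exhaustive boolean scans over the gene span instead of interval
    algebra.  Intended for fixtures with spans up to ~100 kb.
    """
    lo = min(t.start, ref.start)
    hi = max(t.end, ref.end)
    n = hi - lo
    rmask = np.zeros(n, dtype=bool)
    tmask = np.zeros(n, dtype=bool)
    for e in ref.merged_exons:
        rmask[e.start - lo : e.end - lo] = True
    for e in t.exons:
        tmask[e.start - lo : e.end - lo] = True
    plus = t.strand == "+"
    pos = np.arange(lo, hi)

    def segments(mask: np.ndarray) -> list[tuple[int, int]]:
        out = []
        in_seg = False
        for i, v in enumerate(mask):
            if v and not in_seg:
                s = i
                in_seg = True
            elif not v and in_seg:
                out.append((s + lo, i + lo))
                in_seg = False
        if in_seg:
            out.append((s + lo, n + lo))
        return out

    r_segs = segments(rmask)
    t_segs = segments(tmask)
    events: list[tuple[str, tuple[tuple[int, int], ...]]] = []

    def seg_mask(seg: tuple[int, int]) -> np.ndarray:
        m_ = np.zeros(n, dtype=bool)
        m_[seg[0] - lo : seg[1] - lo] = True
        return m_

    # ATSS / ATTS
    r_first = r_segs[0] if plus else r_segs[-1]
    r_last = r_segs[-1] if plus else r_segs[0]
    t_first = t_segs[0] if plus else t_segs[-1]
    t_last = t_segs[-1] if plus else t_segs[0]
    if not np.any(seg_mask(t_first) & seg_mask(r_first)):
        territory = rmask & ((pos < t.start) if plus else (pos >= t.end))
        elems = segments(territory)
        if elems:
            events.append(("ATSS", tuple(elems)))
    if not np.any(seg_mask(t_last) & seg_mask(r_last)):
        territory = rmask & ((pos >= t.end) if plus else (pos < t.start))
        elems = segments(territory)
        if elems:
            events.append(("ATTS", tuple(elems)))

    # IR: reference intron whose bases plus both flanking bases are all
    # transcript-exonic (contiguity => contained in a single exon)
    for (a_end, b_start) in zip(
        (s[1] for s in r_segs), (s[0] for s in r_segs[1:])
    ):
        window = tmask[a_end - 1 - lo : b_start + 1 - lo]
        if window.size and window.all():
            events.append(("IR", ((a_end, b_start),)))

    # ESI / MESI: whole reference segments inside the transcript span with
    # zero transcript-exonic bases, grouped into consecutive runs
    skipped = [
        i
        for i, seg in enumerate(r_segs)
        if t.start <= seg[0] and seg[1] <= t.end
        and not np.any(tmask[seg[0] - lo : seg[1] - lo])
    ]
    run: list[int] = []
    for i in skipped + [None]:  # type: ignore[list-item]
        if run and (i is None or i != run[-1] + 1):
            elems = tuple(r_segs[j] for j in run)
            events.append(("ESI" if len(run) == 1 else "MESI", elems))
            run = []
        if i is not None:
            run.append(i)

    # A5 / A3 at internal transcript boundaries
    for (a, b) in zip((s[1] for s in t_segs), (s[0] for s in t_segs[1:])):
        # boundary a strictly inside a reference segment
        if rmask[a - lo] and rmask[a - 1 - lo]:
            end_ = a
            while end_ < hi and rmask[end_ - lo]:
                end_ += 1
            if end_ <= b:
                events.append(("A5" if plus else "A3", ((a, end_),)))
        if rmask[b - lo] and rmask[b - 1 - lo]:
            start_ = b
            while start_ > lo and rmask[start_ - 1 - lo]:
                start_ -= 1
            if start_ >= a:
                events.append(("A3" if plus else "A5", ((start_, b),)))

    events.sort(key=lambda ev: (ev[1][0][0], ev[0]))
    return events


def oracle_mee(gene: GeneModel) -> list[tuple[tuple[int, int], tuple[int, int]]]:
    """Exhaustive base-set MEE detection over all exon pairs of all
    transcript pairs; returns sorted, deduplicated element coordinate
    pairs."""
    found: set[tuple[tuple[int, int], tuple[int, int]]] = set()
    txs = gene.transcripts
    for ia in range(len(txs)):
        for ib in range(ia + 1, len(txs)):
            ta, tb = txs[ia], txs[ib]
            bases_a = {p for e in ta.exons for p in range(e.start, e.end)}
            bases_b = {p for e in tb.exons for p in range(e.start, e.end)}
            common = [
                (e.start, e.end)
                for e in ta.exons
                if any(e.start == f.start and e.end == f.end for f in tb.exons)
            ]
            for a in ta.exons:
                if any(p in bases_b for p in range(a.start, a.end)):
                    continue
                for b in tb.exons:
                    if any(p in bases_a for p in range(b.start, b.end)):
                        continue
                    if a.start < b.end and b.start < a.end:
                        continue
                    lo_ = min(a.start, b.start)
                    hi_ = max(a.end, b.end)
                    lefts = [c for c in common if c[1] <= lo_]
                    rights = [c for c in common if c[0] >= hi_]
                    if not lefts or not rights:
                        continue
                    lf = max(lefts, key=lambda c: c[1])
                    rf = min(rights, key=lambda c: c[0])
                    others = {
                        (e.start, e.end)
                        for e in (*ta.exons, *tb.exons)
                        if e.end > lf[1] and e.start < rf[0]
                    }
                    if others != {(a.start, a.end), (b.start, b.end)}:
                        continue
                    pair = tuple(sorted([(a.start, a.end), (b.start, b.end)]))
                    found.add(pair)  # type: ignore[arg-type]
    return sorted(found)


# ---------------------------------------------------------------------------
# Splice-motif QC
# ---------------------------------------------------------------------------

def splice_site_report(
    genes: Sequence[GeneModel], seqs: SequenceProvider
) -> dict[str, float]:
    """Fraction of unique donor/acceptor sites matching the canonical
    GT..AG splice motif (strand-aware), over all transcripts' introns."""
    donors: set[tuple[str, int, str]] = set()
    acceptors: set[tuple[str, int, str]] = set()
    for g in genes:
        for t in g.transcripts:
            for a, b in zip(t.exons, t.exons[1:]):
                if t.strand == "+":
                    donors.add((t.chrom, a.end, "+"))
                    acceptors.add((t.chrom, b.start, "+"))
                else:
                    donors.add((t.chrom, b.start, "-"))
                    acceptors.add((t.chrom, a.end, "-"))
    n_gt = 0
    for chrom, pos_, strand in donors:
        if strand == "+":
            dinuc = seqs.fetch(chrom, pos_, pos_ + 2)
        else:
            dinuc = _revcomp(seqs.fetch(chrom, pos_ - 2, pos_))
        n_gt += dinuc == "GT"
    n_ag = 0
    for chrom, pos_, strand in acceptors:
        if strand == "+":
            dinuc = seqs.fetch(chrom, pos_ - 2, pos_)
        else:
            dinuc = _revcomp(seqs.fetch(chrom, pos_, pos_ + 2))
        n_ag += dinuc == "AG"
    return {
        "n_donor_sites": len(donors),
        "donor_gt_pct": 100.0 * n_gt / len(donors) if donors else 0.0,
        "n_acceptor_sites": len(acceptors),
        "acceptor_ag_pct": 100.0 * n_ag / len(acceptors) if acceptors else 0.0,
    }
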