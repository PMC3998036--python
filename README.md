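# splicetk

Classification of alternative-splicing events, isoform-fraction switches
and nonsense-mediated-decay (NMD) sensitivity from assembled full-length
transcripts.

Modern RNA-seq assemblers (Cufflinks, StringTie, ...) reconstruct
full-length transcript models per gene, but leave open the questions that
matter biologically: *which* splicing events distinguish the isoforms,
*where* in the genome the differentially spliced elements lie (so they can
be fed to motif or domain analysis), *which* isoforms switch usage between
two conditions, and *which* isoforms are likely degraded by NMD rather
than translated. `splicetk` answers these for anyone with a GTF of
transcript models, per-condition expression estimates, a genome FASTA and
an annotated start-codon table.

## Method

**Event classification.** For each gene, a comparison reference is built:
the *hypothetical pre-RNA* — the union of all isoforms' exons with
overlapping or book-ended intervals merged — or, optionally, the exon
chain of the most expressed transcript in a chosen condition. Every
transcript is compared pairwise against this reference and deviations are
classified into eight classes, each annotated with the genomic
coordinates of its spliced element(s):

| class | meaning (strand-relative) |
|-------|---------------------------|
| ESI   | single exon skipping/inclusion |
| MESI  | multiple (k ≥ 2 consecutive) exon skipping, one event with k elements |
| A5 / A3 | alternative donor / acceptor splice site |
| IR    | intron retention (a reference intron inside one transcript exon) |
| ATSS / ATTS | alternative transcription start / termination site |
| MEE   | mutually exclusive exons (detected transcript-pairwise) |

**Isoform fractions and switches.** For transcript *i* of gene *g* in
condition *c*,

    IF_ic = (transcript expression / gene expression) × 100
    dIF_i = IF_i,2 − IF_i,1        (percentage points, signed)

A gene exhibits a *binary transcript switch* when one isoform has
dIF ≥ +τ and another dIF ≤ −τ (default τ = 25 pp) with gene expression of
at least `--min-gene-expr` (default 1) in both conditions. Switches where
the down-regulated isoform is PTC− and the up-regulated one PTC+ are
flagged as NMD gains.

**ORF and NMD prediction.** For each transcript the most upstream
compatible annotated start codon is mapped into transcript coordinates,
the downstream sequence is translated to the first in-frame stop, and the
distance from the stop codon to the final exon–exon junction is computed.
A transcript is flagged PTC+ (predicted NMD-sensitive) when the stop lies
more than 50 nt (configurable) upstream of that junction. 5′UTR, ORF and
3′UTR lengths are reported and satisfy
`utr5 + orf + utr3 = transcript length`.

## Worked example

`splicetk` ships a deterministic simulator that produces a coherent
GTF + FASTA + genePred + expression fixture set with known ground truth:

```
splicetk simulate --n-genes 12 --seed 4 --out-dir demo/sim
# wrote 12 genes / 20 transcripts to demo/sim

splicetk all --gtf demo/sim/transcripts.gtf \
             --expression demo/sim/expression.tsv \
             --fasta demo/sim/genome.fa \
             --cds demo/sim/cds.genepred \
             --reference most-expressed \
             --out-dir demo/out
# 8 events, 2 switches, 0 PTC+ transcripts
```

`demo/out/event_counts.tsv` tabulates the events by class —
`ESI 3, MESI 1, A5 1, A3 1, IR 1, ATSS 1, ATTS 0, MEE 0` for this seed —
and `events.tsv` carries one row per event with its element coordinates
(1-based inclusive in output), e.g.

```
gene_id  transcript_ids  event_class  ...  elements                 ...
G00001   G00001.2        ESI               contig_G00001:448-591
```

meaning isoform `G00001.2` skips the reference exon at bases 448–591 of
its contig. `switches.tsv` lists the two planted switches (dIF ±35 pp
against the default τ = 25):

```
gene_id  up_transcript_id  down_transcript_id  dIF_up  dIF_down
G00001   G00001.2          G00001.1            35.0    -35.0
```

and `orf_summary.tsv` reports the PTC classes over all 20 transcripts
(here 4 annotated PTC−; the remaining 16 transcripts belong to genes
without an entry in the start-codon table, hence `no_compatible_start`).

Real data flows through the same commands: point `--gtf` at a
Cuffmerge/StringTie GTF, `--expression` at either the generic TSV below or
a Cufflinks `isoforms.fpkm_tracking` (`--expr-format cufflinks_tracking`),
`--fasta` at the genome, and `--cds` at a UCSC refGene-style genePred
table (or a simple start-codon table with `--cds-dialect simple`).

### Generic expression TSV

Tab-separated with a header; one row per transcript × condition:

| column | content |
|--------|---------|
| `transcript_id`, `gene_id` | must match the GTF attributes |
| `condition` | one of the two labels passed via `--conditions` |
| `transcript_expr`, `gene_expr` | non-negative, length/depth-normalised (e.g. FPKM) |
| `iso_status`, `gene_status` | optional quantification flags (`OK`, ...) |
| `pvalue` | optional test p-value, carried through |

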