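# Methods

## Coordinate model

All internal coordinates are 0-based half-open genomic intervals;
conversion to the 1-based inclusive GTF/genePred conventions happens only
in the I/O layer, so interval arithmetic is free of ±1 corrections.
Transcript coordinates run 5′→3′ in transcript orientation: on the minus
strand, position 0 is the genomically 3′-most exonic base.
`genomic_to_transcript` is a bijection between exonic genomic positions
and `[0, transcript_length)`; the test suite checks this exhaustively on
randomized exon chains.

Transcripts must have sorted, disjoint, non-abutting exons on one
chromosome and strand. Abutting exons (a zero-length intron) are treated
as a GTF artifact and merged at parse time with a warning; transcripts of
one gene on conflicting chromosomes or strands are a hard input error,
because a merged pre-RNA is undefined across strands.

## The comparison reference

The default reference is the *hypothetical pre-RNA*: the union of all the
gene's isoforms' exons, with overlapping **and book-ended** intervals
merged — a reference intron must be a positive-length candidate for
intron retention, so a base-gap of zero is not an intron. Alternatively
the exon chain of the most expressed transcript in a named condition
(default: the first condition, i.e. the control in a
perturbation design) serves as the reference; ties are broken by
lexicographically smallest transcript id, and a gene whose transcripts
are all unexpressed in that condition falls back to the pre-RNA with a
warning.

A consequence worth stating explicitly: a retained intron is, by
construction, exonic in the pre-RNA of its own gene, so IR events are
only observable in `most_expressed` mode (or against an externally
constructed reference). The simulator therefore declares its ground
truth against the most-expressed (backbone) reference.

## Event decision rules

The eight event classes are detected by a deterministic decision
procedure; all orientation words are strand-relative.

1. **ATSS** — the transcript's first exon shares no base with the
   reference's first merged exon; the event's elements are the maximal
   reference-exonic intervals strictly 5′ of the transcript start.
   **ATTS** is symmetric at the 3′ end. A transcript first exon that
   merely starts *inside* the reference first exon is not an event:
   assemblers trim transcript ends non-biologically, and treating the
   wobble as ATSS would flood the counts.
2. **IR** — each reference intron fully contained within a single
   transcript exon yields one event whose element is that intron.
3. **ESI/MESI** — within the transcript's span, each maximal run of
   k ≥ 1 consecutive reference exons sharing no base with the transcript
   (hence flanked by transcript exons) yields one event: ESI for k = 1,
   MESI with k elements for k ≥ 2. Reference exons 5′ of an alternative
   start are reported inside the ATSS event, never double-counted as
   skipped exons.
4. **A5/A3** — at each internal transcript boundary (introns only, so
   terminal exons contribute only on their spliced side): if the
   boundary lies strictly inside a reference exon and the transcript
   intron contains the remainder of that exon, the remainder is the
   element; donor-side shifts are A5, acceptor-side A3, assigned by
   strand.
5. **MEE** — detected transcript-pairwise, not against the pre-RNA
   (which contains both exons and can never show exclusivity): exons
   a ∈ Ta, b ∈ Tb that do not overlap each other, are each absent from
   the other transcript, and both lie between a pair of
   identical-coordinate exons common to Ta and Tb with no other exon of
   either transcript between those flanks. Events are deduplicated
   across pairs by element coordinates.

Events are per-transcript: the same skipped exon in two different
isoforms counts twice. When an alternative-start territory spans several
reference exons we emit a single ATSS event with multiple elements
(rather than one event per exon); the element coordinates are identical
either way. Each event carries `flank_5`/`flank_3`, the genomic positions
of the mature-transcript boundaries adjacent to the element block, for
downstream splice-motif analysis.

One configuration intentionally yields no event: a transcript intron
strictly inside a single reference exon (an "exitron"-like deviation)
satisfies neither the A5 nor the A3 containment condition. The rules
above are the package's normative definition, and the per-base oracle
(below) implements the same definition independently.

## Independent oracle

`simulate.oracle_classify` re-derives the event list from exhaustive
per-base boolean membership vectors over the gene span (reference-exonic
and transcript-exonic masks), with each rule expressed as a set/scan
condition instead of interval algebra; `simulate.oracle_mee` is a
quadratic brute force over all exon pairs using per-base sets. The test
suite and the acceptance script require exact agreement between the
production classifier, the oracles and the planted ground truth on
hundreds of seeded random genes, in both reference modes.

## Isoform fractions, switches, subset comparison

IF = (transcript expression / gene expression) × 100. dIF is the signed
difference in percentage points between the two conditions — the switch
definition requires signs, so "change" is never collapsed to a magnitude.
IFs are undefined (and excluded from dIF) when gene expression is zero.
IFs are *not* re-normalized when gene expression differs from the isoform
sum, because assemblers such as Cufflinks estimate the two independently;
genes whose IFs sum outside [90, 110] are logged as a QC signal. When
gene expression does equal the isoform sum, per-gene IFs sum to 100 and
dIFs to 0 within 1e-9 (asserted over all fixtures).

Switch calling uses τ = 25 percentage points and a gene-expression floor
of 1 (input units) by default. These are deliberate, conservative,
clearly surfaced defaults for a threshold the method only qualifies as
"large"; they are not calibrated to reproduce any particular published
switch count, and both are flags on the command line. One call is
emitted per gene — the extreme up/down pair, ties broken by transcript
id — which makes the count monotone in τ and invariant under input
ordering.

`subset_if_distributions` compares the condition-wise IF vectors of any
transcript subset (e.g. all transcripts with IR events, or all PTC+
transcripts) with a two-sided Mann–Whitney U test
(`scipy.stats.mannwhitneyu`, asymptotic with tie correction — IF vectors
contain heavy ties in practice). This is the one statistical procedure
applied to IF values; differential-splicing significance testing is out
of scope and delegated to dedicated count-based packages.

## ORF and NMD

Start-codon compatibility is positional: the annotated codon's first
genomic base must map into the transcript's exons and a full codon must
fit in transcript space. The annotation's downstream exon structure is
*not* required to match — novel isoforms must be annotatable, which is
the point of the tool — and the mapped codon is not required to read ATG
(annotated non-ATG starts pass through; `strict_atg` adds the check).
Among compatible starts the most upstream (minimal transcript
coordinate) wins.

The stop-to-junction distance is measured from the **last base of the
stop codon** to the last base of the penultimate exon, both in
transcript coordinates. The 50-nt rule is applied strictly:
`stop_to_junction > 50` ⇒ PTC+, so 50 exactly is PTC−. Other conventions
(first base of the stop codon) differ by ≤ 2 nt and can be emulated via
the configurable threshold. Transcripts with no in-frame stop are PTC−
with status `no_stop_found` (no PTC is demonstrable); single-exon
transcripts are PTC− by definition (no junction). Raising the threshold
never converts PTC− to PTC+ (tested).

## Synthetic data generator

Each gene lives on its own contig: a backbone transcript carries all
reference exons, and each planted event class adds one deviating isoform
touching a distinct exon/intron slot (MEE adds two isoforms with novel
mutually exclusive exons inside one widened intron). Default geometry:
6–9 reference exons of 120–260 nt, introns of 80–200 nt, donor/acceptor
shifts of 10–60 nt — small-gene dimensions chosen so that per-base
oracle scans stay exhaustive. Expression gives the backbone 60% of the
gene (so it is the most-expressed reference) with gene expression equal
to the isoform sum; switch genes plant a ±35 pp IF swap between backbone
and one alternative isoform on a gene expression of 100, comfortably
beyond the τ = 25 default. Splice-site dinucleotides are planted
canonical (GT..AG in transcript orientation) per unique donor/acceptor
site with a 93% canonical fraction by default — the rate typical of
assembled human transcripts — so motif QC has a known expected value.
Planted CDS codons are written explicitly (ATG, stop-free in-frame body,
stop codon at an exact distance from the final junction), making ORF
ground truth exact; genes carry either planted events or a planted CDS,
never both, so dinucleotide planting at novel junctions (which falls
inside backbone exons) cannot corrupt ORF codons.

What the generator does **not** emulate: assembler noise (fragmentary or
chimeric models), shared exonic sequence between genes, overlapping
genes, expression estimation error, >2 conditions, genes where gene
expression ≠ isoform sum. Passing tests therefore demonstrate
correctness of the algorithms under clean inputs, not robustness to
assembler artifacts; the stringency filters (`iso_ok`, `expressed_*`,
`single_exon`) are the provided mitigation for real data.

## Problem sizes and numerics

The default test and acceptance runs use 300–500 genes per dataset
(~800–1300 transcripts, gene spans ≈ 5 kb), sizes at which the per-base
oracles remain exhaustive while the whole suite completes in seconds.
All randomness flows through a single integer seed
(`numpy.random.default_rng`); per-gene seeds are spawned from the master
seed, so datasets are reproducible gene-by-gene. Outputs are
deterministically ordered (gene id, transcript id, genomic position) and
carry no timestamps, making every command idempotent at the byte level.

## Known limitations

* Multi-chromosome fusion transcripts and circular RNAs are rejected by
  the data model.
* MEE detection requires identical-coordinate flanking exons; flank
  wobble (as tolerated at transcript termini) would mask an MEE.
* Only two conditions are supported; time courses need repeated runs.
* Coding-potential regression (CPAT-style) and event-level significance
  testing are out of scope by design.
* The start-codon table must be on the same assembly as the GTF and
  FASTA; no coordinate lifting is performed.
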