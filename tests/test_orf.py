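import pytest

from splicetk.io import CdsRecord, SequenceProvider
from splicetk.orf import (
    annotate_orf,
    find_compatible_start,
    junction_position,
    ptc_percentages,
    scan_orf,
    summarize_ptc,
)
from splicetk.simulate import GeneBlueprint, generate_gene
from splicetk.model import transcript_length
from .conftest import tx


class TestScanOrf:
    @pytest.mark.parametrize(
        "seq,start,expected",
        [
            ("ATGAAATAG", 0, 8),   # two codons then stop
            ("ATGTAACCC", 1, None),  # out-of-frame: TGT AAC CC -> no stop
            ("ATGTGA", 0, 5),      # immediate stop
        ],
    )
    def test_frame_walk(self, seq, start, expected):
        assert scan_orf(seq, start) == expected

    def test_start_too_close_to_end_rejected(self):
        with pytest.raises(ValueError):
            scan_orf("ATG", 1)


class TestCompatibleStart:
    def test_exonic_start_maps_and_intronic_excluded(self):
        t = tx("T", [(0, 30), (60, 90)])
        assert find_compatible_start(t, [CdsRecord("c", "chr1", "+", 10)]) == 10
        assert find_compatible_start(t, [CdsRecord("c", "chr1", "+", 45)]) is None
        # wrong strand excluded
        assert find_compatible_start(t, [CdsRecord("c", "chr1", "-", 10)]) is None

    def test_most_upstream_wins(self):
        t = tx("T", [(0, 100)])
        cds = [CdsRecord("a", "chr1", "+", 90), CdsRecord("b", "chr1", "+", 40)]
        assert find_compatible_start(t, cds) == 40

    def test_codon_must_fit_in_transcript(self):
        t = tx("T", [(0, 10)])
        assert find_compatible_start(t, [CdsRecord("c", "chr1", "+", 8)]) is None


class TestPtcRule:
    def orf_for_distance(self, dist, threshold=50):
        """Plant a stop exactly ``dist`` nt upstream of the final junction."""
        bp = GeneBlueprint(
            gene_id="G", seed=5, n_reference_exons=4,
            planted_cds=("ptc", dist),
        )
        gg = generate_gene(bp)
        seqs = SequenceProvider({gg.chrom: gg.sequence})
        return annotate_orf(
            gg.gene.transcripts[0], seqs, gg.cds_records,
            ptc_threshold=threshold,
        )

    @pytest.mark.parametrize("dist,flag", [(49, False), (50, False), (51, True)])
    def test_boundary_strictly_greater_than_50(self, dist, flag):
        ann = self.orf_for_distance(dist)
        assert ann.stop_to_junction == dist
        assert ann.ptc is flag

    def test_threshold_monotone(self):
        """Raising the threshold never converts PTC- to PTC+."""
        for dist in (30, 51, 120):
            flags = [self.orf_for_distance(dist, thr).ptc
                     for thr in (0, 25, 50, 100, 200)]
            assert flags == sorted(flags, reverse=True)

    def test_stop_in_final_exon_is_canonical(self):
        bp = GeneBlueprint(gene_id="G", seed=6, n_reference_exons=3,
                           planted_cds=("canonical_stop",))
        gg = generate_gene(bp)
        seqs = SequenceProvider({gg.chrom: gg.sequence})
        ann = annotate_orf(gg.gene.transcripts[0], seqs, gg.cds_records)
        assert ann.stop_to_junction < 0 and not ann.ptc

    def test_single_exon_never_ptc(self):
        bp = GeneBlueprint(gene_id="G", seed=7, n_reference_exons=1,
                           planted_cds=("canonical_stop",))
        gg = generate_gene(bp)
        seqs = SequenceProvider({gg.chrom: gg.sequence})
        ann = annotate_orf(gg.gene.transcripts[0], seqs, gg.cds_records,
                           ptc_threshold=0)
        assert ann.junction_tpos is None and not ann.ptc

    def test_no_compatible_start_status(self):
        t = tx("T", [(0, 30)])
        seqs = SequenceProvider({"chr1": "A" * 40})
        ann = annotate_orf(t, seqs, [])
        assert ann.status == "no_compatible_start"
        assert ann.start_tpos is None and ann.orf_len is None


class TestPlantedRecovery:
    def test_exact_recovery_and_length_conservation(self, sim_dataset):
        """Planted start/stop/UTR lengths recovered exactly; 5'UTR + ORF +
        3'UTR == transcript length."""
        checked = 0
        for gg in sim_dataset.genes:
            if gg.truth_orf is None:
                continue
            t = gg.gene.transcripts[0]
            ann = annotate_orf(t, sim_dataset.sequences, gg.cds_records)
            assert ann == gg.truth_orf
            if ann.status == "annotated":
                assert ann.utr5_len + ann.orf_len + ann.utr3_len == \
                    transcript_length(t)
            checked += 1
        assert checked >= 5

    @pytest.mark.parametrize("dist", [40, 70])
    def test_strand_symmetry_under_reverse_complement_mirror(self, dist):
        """A gene and its reverse-complement mirror produce identical
        ORF annotations in transcript coordinates."""
        from splicetk.io import reverse_complement

        bp = GeneBlueprint(gene_id="G", seed=123, strand="+",
                           n_reference_exons=5, planted_cds=("ptc", dist))
        gg = generate_gene(bp)
        t = gg.gene.transcripts[0]
        ann = annotate_orf(
            t, SequenceProvider({gg.chrom: gg.sequence}), gg.cds_records
        )

        pivot = len(gg.sequence)
        mirror_t = tx(
            t.transcript_id,
            [(pivot - e.end, pivot - e.start) for e in reversed(t.exons)],
            strand="-", gene_id=t.gene_id, chrom=t.chrom,
        )
        mirror_seqs = SequenceProvider(
            {gg.chrom: reverse_complement(gg.sequence)}
        )
        mirror_cds = [
            CdsRecord(r.name, r.chrom, "-", pivot - 1 - r.start_codon_genomic)
            for r in gg.cds_records
        ]
        mirror_ann = annotate_orf(mirror_t, mirror_seqs, mirror_cds)
        assert mirror_ann == ann


class TestSummaries:
    def test_percentages_exact(self):
        assert ptc_percentages(8179, 642, 1287) == (80.9, 6.4, 12.7)
        assert ptc_percentages(1, 0, 0) == (100.0, 0.0, 0.0)
        assert ptc_percentages(0, 0, 0) == (0.0, 0.0, 0.0)

    def test_summarize_counts_classes(self, sim_dataset):
        from splicetk.orf import annotate_all

        anns = []
        for gg in sim_dataset.genes:
            if gg.truth_orf is not None:
                anns.append(
                    annotate_orf(gg.gene.transcripts[0],
                                 sim_dataset.sequences, gg.cds_records)
                )
        s = summarize_ptc(anns)
        assert s["ptc_minus"] + s["ptc_plus"] + s["no_compatible_start"] == \
            len(anns)
        assert s["ptc_plus"] >= 1 and s["no_compatible_start"] >= 1


def test_junction_position_is_last_base_of_penultimate_exon():
    t = tx("T", [(0, 100), (200, 250)])
    assert junction_position(t) == 99
    t_minus = tx("T", [(0, 100), (200, 250)], strand="-")
    assert junction_position(t_minus) == 49  # last exon is genomically first
    assert junction_position(tx("T", [(0, 100)])) is None
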