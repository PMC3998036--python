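import pytest

from splicetk.classify import (
    classify_all,
    classify_transcript,
    count_events,
    detect_mee,
    events_to_dataframe,
    write_events_tsv,
)
from splicetk.model import GenomicInterval
from splicetk.reference import MOST_EXPRESSED, ReferenceModel, build_pre_rna
from splicetk.simulate import generate_dataset, oracle_classify, oracle_mee
from splicetk.reference import reference_for
from .conftest import iv, make_gene, tx


def elements_of(events):
    return [
        (e.event_class, [(x.start, x.end) for x in e.elements])
        for e in events
    ]


TOY_CASES = [
    # (transcript exons, expected class, expected elements)
    ([(100, 200), (500, 600), (700, 800)], "ESI", [(300, 400)]),
    ([(100, 200), (700, 800)], "MESI", [(300, 400), (500, 600)]),
    ([(100, 200), (300, 600), (700, 800)], "IR", [(400, 500)]),
    ([(100, 180), (300, 400), (500, 600), (700, 800)], "A5", [(180, 200)]),
    ([(100, 200), (320, 400), (500, 600), (700, 800)], "A3", [(300, 320)]),
    ([(300, 400), (500, 600), (700, 800)], "ATSS", [(100, 200)]),
]


class TestDefinitionalCases:
    @pytest.mark.parametrize("exons,cls,els", TOY_CASES)
    def test_single_event_with_exact_elements(self, toy_reference, exons,
                                              cls, els):
        events = classify_transcript(tx("T", exons), toy_reference)
        assert elements_of(events) == [(cls, els)]

    def test_identity_yields_nothing(self, toy_reference):
        t = tx("T", [(100, 200), (300, 400), (500, 600), (700, 800)])
        assert classify_transcript(t, toy_reference) == []

    def test_atts_at_three_prime_end(self, toy_reference):
        t = tx("T", [(100, 200), (300, 400), (500, 600)])
        assert elements_of(classify_transcript(t, toy_reference)) == \
            [("ATTS", [(700, 800)])]

    def test_first_exon_trimmed_inside_reference_is_not_atss(
        self, toy_reference
    ):
        """Terminal coordinate wobble (assemblers trim ends) is ignored."""
        t = tx("T", [(150, 200), (300, 400), (500, 600), (700, 800)])
        assert classify_transcript(t, toy_reference) == []

    def test_gene_mismatch_rejected(self, toy_reference):
        with pytest.raises(ValueError):
            classify_transcript(tx("T", [(100, 200)], gene_id="G2"),
                                toy_reference)

    def test_minus_strand_orientation_is_strand_relative(self):
        """A shifted genomic start of an internal exon on the minus strand
        is a donor-side (A5) shift, and a terminal trim is no event."""
        ref = ReferenceModel(
            gene_id="G1", mode=MOST_EXPRESSED, chrom="chr1", strand="-",
            merged_exons=(iv(100, 200, strand="-"), iv(300, 400, strand="-"),
                          iv(500, 600, strand="-")),
            source_transcript_id="R",
        )
        t = tx("T", [(100, 200), (320, 400), (500, 600)], strand="-")
        assert elements_of(classify_transcript(t, ref)) == \
            [("A5", [(300, 320)])]
        # trimming the transcript-terminal boundary is assembler wobble
        t2 = tx("T", [(150, 200), (300, 400), (500, 600)], strand="-")
        assert classify_transcript(t2, ref) == []


class TestMee:
    def test_definitional_pair(self):
        g = make_gene([
            tx("Ta", [(100, 200), (300, 400), (700, 800)]),
            tx("Tb", [(100, 200), (500, 600), (700, 800)]),
        ])
        [event] = detect_mee(g)
        assert event.event_class == "MEE"
        assert [(e.start, e.end) for e in event.elements] == \
            [(300, 400), (500, 600)]
        assert event.transcript_ids == ("Ta", "Tb")

    def test_shared_exon_is_not_exclusive(self):
        g = make_gene([
            tx("Ta", [(100, 200), (300, 400), (700, 800)]),
            tx("Tb", [(100, 200), (300, 400), (500, 600), (700, 800)]),
        ])
        assert detect_mee(g) == []

    def test_agrees_with_quadratic_oracle_on_random_genes(self, sim_dataset):
        for gg in sim_dataset.genes:
            got = sorted(
                tuple((e.start, e.end) for e in ev.elements)
                for ev in detect_mee(gg.gene)
            )
            assert got == [tuple(p) for p in oracle_mee(gg.gene)]


class TestDatasetClassification:
    def test_six_toy_cases_compose(self, toy_reference):
        events = []
        for exons, _, _ in TOY_CASES:
            events.extend(
                classify_transcript(tx("T", exons), toy_reference)
            )
        counts = count_events(events)
        assert counts == {"ESI": 1, "MESI": 1, "IR": 1, "A5": 1, "A3": 1,
                          "ATSS": 1, "ATTS": 0, "MEE": 0}

    def test_count_events_zero_filled_and_empty(self):
        assert sum(count_events([]).values()) == 0
        assert set(count_events([])) == {
            "ESI", "MESI", "A5", "A3", "IR", "ATSS", "ATTS", "MEE"
        }

    def test_single_transcript_genes_silent_vs_own_pre_rna(self):
        g = make_gene([tx("T1", [(0, 100), (200, 300)])])
        assert classify_transcript(g.transcripts[0], build_pre_rna(g)) == []

    def test_classification_agrees_with_per_base_oracle(self, sim_dataset):
        """Interval-algebra classifier vs exhaustive per-base scan, in both
        reference modes, over every generated transcript."""
        for gg in sim_dataset.genes:
            for mode, cond in ((MOST_EXPRESSED, "WT"), ("pre_rna", None)):
                ref = reference_for(
                    gg.gene, mode, sim_dataset.dataset.expression, cond
                )
                for t in gg.gene.transcripts:
                    got = sorted(
                        (e.event_class,
                         tuple((x.start, x.end) for x in e.elements))
                        for e in classify_transcript(t, ref)
                    )
                    want = sorted(oracle_classify(t, ref))
                    assert got == want, (gg.gene.gene_id, t.transcript_id)

    def test_strand_reflection_preserves_classes(self, sim_dataset):
        """Mirroring all coordinates and flipping strand preserves the event
        class multiset with mirrored elements (A5 stays A5)."""
        for gg in sim_dataset.genes[:10]:
            g = gg.gene
            pivot = g.span.end + 100
            flip = {"+": "-", "-": "+"}[g.strand]

            def mirror_tx(t):
                return tx(
                    t.transcript_id,
                    [(pivot - e.end, pivot - e.start) for e in
                     reversed(t.exons)],
                    strand=flip, gene_id=t.gene_id, chrom=t.chrom,
                )

            ref = reference_for(
                g, MOST_EXPRESSED, sim_dataset.dataset.expression, "WT"
            )
            mref = ReferenceModel(
                gene_id=g.gene_id, mode=MOST_EXPRESSED, chrom=g.chrom,
                strand=flip,
                merged_exons=tuple(
                    GenomicInterval(g.chrom, pivot - e.end, pivot - e.start,
                                    flip)
                    for e in reversed(ref.merged_exons)
                ),
                source_transcript_id=ref.source_transcript_id,
            )
            for t in g.transcripts:
                orig = sorted(
                    (e.event_class,
                     tuple(sorted((x.start, x.end) for x in e.elements)))
                    for e in classify_transcript(t, ref)
                )
                mirrored = sorted(
                    (e.event_class,
                     tuple(sorted((pivot - x.end, pivot - x.start)
                                  for x in e.elements)))
                    for e in classify_transcript(mirror_tx(t), mref)
                )
                assert orig == mirrored

    def test_deterministic_byte_identical_output(self, tmp_path):
        ds1 = generate_dataset(10, seed=99)
        ds2 = generate_dataset(10, seed=99)
        p1, p2 = tmp_path / "a.tsv", tmp_path / "b.tsv"
        write_events_tsv(classify_all(ds1.dataset, MOST_EXPRESSED), p1)
        write_events_tsv(classify_all(ds2.dataset, MOST_EXPRESSED), p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_events_serialized_one_based_inclusive(self, toy_reference):
        events = classify_transcript(
            tx("T", [(100, 200), (500, 600), (700, 800)]), toy_reference
        )
        df = events_to_dataframe(events)
        assert df.loc[0, "elements"] == "chr1:301-400"
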