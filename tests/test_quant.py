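import numpy as np
import pytest

from splicetk.io import build_dataset
from splicetk.model import ExpressionRecord, SpliceDataset
from splicetk.quant import (
    DifValue,
    SwitchCall,
    compute_dif,
    compute_if,
    detect_switches,
    filter_dataset,
    nmd_gain_rate,
    subset_if_distributions,
)
from .conftest import make_gene, tx


def two_tx_dataset(expr_rows, conditions=("WT", "KD")):
    """expr_rows: (tid, cond, tx_expr, gene_expr[, iso_status])"""
    gene = make_gene([
        tx("T1", [(0, 100), (200, 300)]),
        tx("T2", [(0, 100), (400, 500)]),
    ])
    records = [
        ExpressionRecord(r[0], "G1", r[1], r[2], r[3],
                         iso_status=r[4] if len(r) > 4 else None)
        for r in expr_rows
    ]
    return build_dataset([gene], records, conditions)


class TestIfDif:
    def test_formula_and_degenerate_cases(self):
        ds = two_tx_dataset([
            ("T1", "WT", 30.0, 120.0), ("T1", "KD", 10.0, 0.0),
            ("T2", "WT", 0.0, 120.0), ("T2", "KD", 0.0, 0.0),
        ])
        ifs = {(v.transcript_id, v.condition): v for v in compute_if(ds)}
        assert ifs[("T1", "WT")].if_pct == 25.0
        assert ifs[("T2", "WT")].if_pct == 0.0 and ifs[("T2", "WT")].defined
        assert not ifs[("T1", "KD")].defined  # gene expression 0

    def test_dif_signed_difference(self):
        ds = two_tx_dataset([
            ("T1", "WT", 25.0, 100.0), ("T1", "KD", 60.0, 100.0),
            ("T2", "WT", 60.0, 100.0), ("T2", "KD", 25.0, 100.0),
        ])
        difs = {d.transcript_id: d for d in
                compute_dif(compute_if(ds), ds.conditions)}
        assert difs["T1"].dif == pytest.approx(35.0)
        assert difs["T2"].dif == pytest.approx(-35.0)

    def test_undefined_if_propagates_to_dif(self):
        ds = two_tx_dataset([
            ("T1", "WT", 25.0, 100.0), ("T1", "KD", 10.0, 0.0),
            ("T2", "WT", 10.0, 100.0), ("T2", "KD", 10.0, 100.0),
        ])
        difs = {d.transcript_id: d for d in
                compute_dif(compute_if(ds), ds.conditions)}
        assert not difs["T1"].defined

    def test_if_sums_to_100_and_dif_to_0_when_consistent(self, sim_dataset):
        """With gene_expr == sum of transcript_expr, per-gene IFs sum to
        100 and dIFs to 0 (to 1e-9)."""
        ds = sim_dataset.dataset
        ifs = compute_if(ds)
        sums = {}
        for v in ifs:
            sums.setdefault((v.gene_id, v.condition), 0.0)
            sums[(v.gene_id, v.condition)] += v.if_pct
        assert all(abs(s - 100.0) < 1e-9 for s in sums.values())
        difs = compute_dif(ifs, ds.conditions)
        dsums = {}
        for d in difs:
            dsums.setdefault(d.gene_id, 0.0)
            dsums[d.gene_id] += d.dif
        assert all(abs(s) < 1e-9 for s in dsums.values())


class TestFilters:
    def test_iso_ok_drops_flagged(self):
        ds = two_tx_dataset([
            ("T1", "WT", 10.0, 20.0, "OK"), ("T1", "KD", 10.0, 20.0, "OK"),
            ("T2", "WT", 10.0, 20.0, "LOWDATA"),
            ("T2", "KD", 10.0, 20.0, "OK"),
        ])
        out = filter_dataset(ds, ["iso_ok"])
        assert [t.transcript_id for t in out.transcripts()] == ["T1"]

    def test_expressed_isoforms_any_condition_rule(self):
        ds = two_tx_dataset([
            ("T1", "WT", 0.0, 20.0), ("T1", "KD", 5.0, 20.0),
            ("T2", "WT", 0.0, 20.0), ("T2", "KD", 0.0, 20.0),
        ])
        out = filter_dataset(ds, ["expressed_isoforms"])
        assert [t.transcript_id for t in out.transcripts()] == ["T1"]

    def test_emptied_gene_cascades(self):
        ds = two_tx_dataset([
            ("T1", "WT", 0.0, 0.0), ("T1", "KD", 0.0, 0.0),
            ("T2", "WT", 0.0, 0.0), ("T2", "KD", 0.0, 0.0),
        ])
        out = filter_dataset(ds, ["expressed_isoforms"])
        assert out.genes == ()

    def test_single_exon_filter(self):
        gene = make_gene([tx("T1", [(0, 100)]),
                          tx("T2", [(0, 100), (200, 300)])])
        ds = build_dataset([gene], [], ["WT", "KD"])
        out = filter_dataset(ds, ["single_exon"])
        assert [t.transcript_id for t in out.transcripts()] == ["T2"]

    def test_status_filter_without_column_errors(self):
        ds = two_tx_dataset([
            ("T1", "WT", 1.0, 2.0), ("T1", "KD", 1.0, 2.0),
            ("T2", "WT", 1.0, 2.0), ("T2", "KD", 1.0, 2.0),
        ])
        with pytest.raises(ValueError, match="iso_status"):
            filter_dataset(ds, ["iso_ok"])


class TestSwitches:
    def mk_difs(self, vals):
        return [DifValue(f"T{i}", "G1", v, True) for i, v in enumerate(vals)]

    def expr(self, gene_expr=50.0):
        return [
            ExpressionRecord("T0", "G1", c, 1.0, gene_expr)
            for c in ("WT", "KD")
        ]

    def test_two_sided_switch_detected(self):
        calls = detect_switches(
            self.mk_difs([35.0, -35.0]), self.expr(), ("WT", "KD"),
            dif_threshold=25.0,
        )
        [c] = calls
        assert c.up_transcript_id == "T0" and c.down_transcript_id == "T1"

    def test_one_sided_is_not_a_switch(self):
        assert detect_switches(
            self.mk_difs([20.0, -35.0]), self.expr(), ("WT", "KD"),
            dif_threshold=25.0,
        ) == []

    def test_low_gene_expression_excluded(self):
        assert detect_switches(
            self.mk_difs([35.0, -35.0]), self.expr(0.5), ("WT", "KD"),
            min_gene_expr=1.0,
        ) == []

    def test_nmd_gain_flag(self):
        calls = detect_switches(
            self.mk_difs([35.0, -35.0]), self.expr(), ("WT", "KD"),
            orf_ptc={"T0": True, "T1": False},
        )
        assert calls[0].nmd_gain is True
        calls = detect_switches(
            self.mk_difs([35.0, -35.0]), self.expr(), ("WT", "KD"),
            orf_ptc={"T0": False, "T1": False},
        )
        assert calls[0].nmd_gain is False

    def test_monotone_in_threshold(self, sim_dataset):
        """Raising the dIF threshold never increases the switch count."""
        ds = sim_dataset.dataset
        difs = compute_dif(compute_if(ds), ds.conditions)
        previous = None
        for tau in (5.0, 15.0, 25.0, 34.9, 40.0, 60.0):
            n = len(detect_switches(difs, ds.expression, ds.conditions,
                                    dif_threshold=tau))
            if previous is not None:
                assert n <= previous
            previous = n

    def test_order_invariance_via_tie_breaks(self):
        difs = [
            DifValue("Tb", "G1", 30.0, True),
            DifValue("Ta", "G1", 30.0, True),
            DifValue("Tc", "G1", -30.0, True),
        ]
        for perm in (difs, difs[::-1]):
            [c] = detect_switches(perm, self.expr(), ("WT", "KD"))
            assert c.up_transcript_id == "Ta"

    def test_planted_switches_recovered(self, sim_dataset):
        ds = sim_dataset.dataset
        difs = compute_dif(compute_if(ds), ds.conditions)
        calls = detect_switches(difs, ds.expression, ds.conditions)
        got = {(c.gene_id, c.up_transcript_id, c.down_transcript_id)
               for c in calls}
        assert got == set(sim_dataset.truth_switch_genes)

    def test_nmd_gain_rate_percentage(self):
        calls = [
            SwitchCall("G", "u", "d", 30, -30, nmd_gain=(i < 18))
            for i in range(183)
        ]
        assert nmd_gain_rate(calls) == 9.8


class TestSubsetComparison:
    def mk_ifs(self, wt, kd):
        from splicetk.quant import IfValue

        out = []
        for i, v in enumerate(wt):
            out.append(IfValue(f"T{i}", "G", "WT", v, True))
        for i, v in enumerate(kd):
            out.append(IfValue(f"T{i}", "G", "KD", v, True))
        return out

    def test_identical_distributions_p_is_one(self):
        ifs = self.mk_ifs([10, 20, 30], [10, 20, 30])
        res = subset_if_distributions(ifs, ["T0", "T1", "T2"], ("WT", "KD"))
        assert res.p_value == pytest.approx(1.0)

    def test_fully_separated_u_is_zero(self):
        ifs = self.mk_ifs([10, 20, 30], [40, 50, 60])
        res = subset_if_distributions(ifs, ["T0", "T1", "T2"], ("WT", "KD"))
        assert res.u_statistic == 0.0

    def test_subset_bookkeeping(self):
        ifs = self.mk_ifs([10, 20, 30, 40], [10, 20, 30, 40])
        res = subset_if_distributions(ifs, ["T0", "T3"], ("WT", "KD"))
        assert len(res.values_a) == len(res.values_b) == 2

    def test_too_small_subset_errors(self):
        ifs = self.mk_ifs([10], [10])
        with pytest.raises(ValueError):
            subset_if_distributions(ifs, ["T0"], ("WT", "KD"))
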