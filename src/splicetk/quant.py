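"""Isoform-fraction statistics, dataset filters and transcript switches.

The isoform fraction of a transcript in a condition is

    IF = (transcript expression / gene expression) * 100

and dIF = IF(condition 2) - IF(condition 1), a signed difference in
percentage points (the switch definition needs signs, so "change" is
implemented as a signed difference, not a magnitude).  IFs are not
re-normalized when gene expression differs from the sum of the isoform
expressions, because assemblers such as Cufflinks estimate the two
independently; genes whose IFs sum far outside 100 are logged as a QC
signal.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd
from scipy.stats import mannwhitneyu

from .model import (
    ExpressionRecord,
    GeneModel,
    SpliceDataset,
    TranscriptModel,
)

logger = logging.getLogger(__name__)

FILTERS = ("gene_ok", "iso_ok", "expressed_genes", "expressed_isoforms",
           "single_exon")

DEFAULT_DIF_THRESHOLD = 25.0   # percentage points
DEFAULT_MIN_GENE_EXPR = 1.0    # expression units of the input


@dataclass(frozen=True)
class IfValue:
    transcript_id: str
    gene_id: str
    condition: str
    if_pct: float
    defined: bool  # False when gene expression is 0


@dataclass(frozen=True)
class DifValue:
    transcript_id: str
    gene_id: str
    dif: float
    defined: bool


@dataclass(frozen=True)
class SwitchCall:
    gene_id: str
    up_transcript_id: str
    down_transcript_id: str
    dif_up: float
    dif_down: float
    nmd_gain: Optional[bool] = None  # None when ORF annotations absent


def compute_if(dataset: SpliceDataset) -> list[IfValue]:
    """IF values for every (transcript, condition) in the dataset."""
    values: list[IfValue] = []
    undefined = 0
    for g in dataset.genes:
        for t in sorted(g.transcripts, key=lambda t: t.transcript_id):
            for cond in dataset.conditions:
                r = dataset.expression_for(t.transcript_id, cond)
                if r is None or r.gene_expr == 0:
                    undefined += 1
                    values.append(
                        IfValue(t.transcript_id, g.gene_id, cond, 0.0, False)
                    )
                else:
                    values.append(
                        IfValue(
                            t.transcript_id,
                            g.gene_id,
                            cond,
                            r.transcript_expr / r.gene_expr * 100.0,
                            True,
                        )
                    )
    if undefined:
        logger.info("compute_if: %d undefined IF values (gene expression 0)",
                    undefined)
    _log_if_sum_outliers(values)
    return values


def _log_if_sum_outliers(values: Sequence[IfValue]) -> None:
    sums: dict[tuple[str, str], float] = {}
    for v in values:
        if v.defined:
            key = (v.gene_id, v.condition)
            sums[key] = sums.get(key, 0.0) + v.if_pct
    bad = [k for k, s in sums.items() if not 90.0 <= s <= 110.0]
    if bad:
        logger.info(
            "compute_if: %d (gene, condition) pairs with IF sum outside "
            "[90, 110] (independent gene/isoform estimates)", len(bad),
        )


def compute_dif(
    ifs: Sequence[IfValue], conditions: Sequence[str]
) -> list[DifValue]:
    """dIF = IF(conditions[1]) - IF(conditions[0]); undefined when either
    side is undefined."""
    c1, c2 = conditions
    by_tx: dict[str, dict[str, IfValue]] = {}
    for v in ifs:
        by_tx.setdefault(v.transcript_id, {})[v.condition] = v
    out: list[DifValue] = []
    for tid in sorted(by_tx):
        d = by_tx[tid]
        if c1 not in d or c2 not in d:
            raise ValueError(f"transcript {tid}: missing IF for a condition")
        v1, v2 = d[c1], d[c2]
        if v1.defined and v2.defined:
            out.append(DifValue(tid, v1.gene_id, v2.if_pct - v1.if_pct, True))
        else:
            out.append(DifValue(tid, v1.gene_id, 0.0, False))
    return out


# ---------------------------------------------------------------------------
# Filters
# ---------------------------------------------------------------------------

def filter_dataset(
    dataset: SpliceDataset, filters: Sequence[str]
) -> SpliceDataset:
    """Drop transcripts/genes per the named stringency filters.

    gene_ok / iso_ok require a status of "OK" in every condition record
    carrying a status; expressed_genes / expressed_isoforms require
    expression > 0 in at least one condition; single_exon drops
    single-exon transcripts.  Genes emptied of transcripts are dropped.
    """
    for f in filters:
        if f not in FILTERS:
            raise ValueError(f"unknown filter {f!r}")

    def records(tid: str) -> list[ExpressionRecord]:
        return [
            r for c in dataset.conditions
            if (r := dataset.expression_for(tid, c)) is not None
        ]

    if "iso_ok" in filters or "gene_ok" in filters:
        has_iso = any(r.iso_status is not None for r in dataset.expression)
        has_gene = any(r.gene_status is not None for r in dataset.expression)
        if "iso_ok" in filters and not has_iso:
            raise ValueError("iso_ok filter requested but no iso_status present")
        if "gene_ok" in filters and not has_gene:
            raise ValueError("gene_ok filter requested but no gene_status present")

    removed = {f: 0 for f in filters}

    def keep_transcript(t: TranscriptModel) -> bool:
        rs = records(t.transcript_id)
        if "iso_ok" in filters and any(
            r.iso_status is not None and r.iso_status != "OK" for r in rs
        ):
            removed["iso_ok"] += 1
            return False
        if "gene_ok" in filters and any(
            r.gene_status is not None and r.gene_status != "OK" for r in rs
        ):
            removed["gene_ok"] += 1
            return False
        if "expressed_isoforms" in filters and not any(
            r.transcript_expr > 0 for r in rs
        ):
            removed["expressed_isoforms"] += 1
            return False
        if "expressed_genes" in filters and not any(
            r.gene_expr > 0 for r in rs
        ):
            removed["expressed_genes"] += 1
            return False
        if "single_exon" in filters and len(t.exons) == 1:
            removed["single_exon"] += 1
            return False
        return True

    genes_out: list[GeneModel] = []
    kept_tids: set[str] = set()
    for g in dataset.genes:
        kept = tuple(t for t in g.transcripts if keep_transcript(t))
        if kept:
            genes_out.append(GeneModel(g.gene_id, kept))
            kept_tids.update(t.transcript_id for t in kept)
    expr_out = [r for r in dataset.expression if r.transcript_id in kept_tids]
    for f, n in removed.items():
        logger.info("filter %s removed %d transcripts", f, n)
    return SpliceDataset(
        genes_out, expr_out, dataset.conditions, dataset.assembler
    )


# ---------------------------------------------------------------------------
# Switches
# ---------------------------------------------------------------------------

def detect_switches(
    difs: Sequence[DifValue],
    expression: Sequence[ExpressionRecord],
    conditions: Sequence[str],
    orf_ptc: Optional[Mapping[str, bool]] = None,
    dif_threshold: float = DEFAULT_DIF_THRESHOLD,
    min_gene_expr: float = DEFAULT_MIN_GENE_EXPR,
) -> list[SwitchCall]:
    """Binary transcript switches: one call per gene that has both a
    transcript with dIF >= +threshold and one with dIF <= -threshold,
    with gene expression >= min_gene_expr in both conditions.

    The single most extreme up and down transcripts are paired (ties by
    transcript id).  When ``orf_ptc`` maps transcript ids to PTC flags,
    ``nmd_gain`` is set when the down transcript is PTC- and the up
    transcript PTC+.
    """
    if dif_threshold <= 0:
        raise ValueError("dIF threshold must be positive")
    gene_expr: dict[tuple[str, str], float] = {}
    for r in expression:
        key = (r.gene_id, r.condition)
        gene_expr[key] = max(gene_expr.get(key, 0.0), r.gene_expr)

    by_gene: dict[str, list[DifValue]] = {}
    for d in difs:
        if d.defined:
            by_gene.setdefault(d.gene_id, []).append(d)

    calls: list[SwitchCall] = []
    for gid in sorted(by_gene):
        if any(
            gene_expr.get((gid, cond), 0.0) < min_gene_expr
            for cond in conditions
        ):
            continue
        ds = by_gene[gid]
        ups = [d for d in ds if d.dif >= dif_threshold]
        downs = [d for d in ds if d.dif <= -dif_threshold]
        if not ups or not downs:
            continue
        up = min(ups, key=lambda d: (-d.dif, d.transcript_id))
        down = min(downs, key=lambda d: (d.dif, d.transcript_id))
        nmd_gain = None
        if orf_ptc is not None:
            up_ptc = orf_ptc.get(up.transcript_id)
            down_ptc = orf_ptc.get(down.transcript_id)
            if up_ptc is not None and down_ptc is not None:
                nmd_gain = bool(up_ptc) and not down_ptc
        calls.append(
            SwitchCall(
                gene_id=gid,
                up_transcript_id=up.transcript_id,
                down_transcript_id=down.transcript_id,
                dif_up=up.dif,
                dif_down=down.dif,
                nmd_gain=nmd_gain,
            )
        )
    return calls


def nmd_gain_rate(switches: Sequence[SwitchCall]) -> float:
    """Percentage of switches gaining NMD sensitivity, one decimal."""
    if not switches:
        return 0.0
    n = sum(1 for s in switches if s.nmd_gain)
    return round(n / len(switches) * 100.0, 1)


# ---------------------------------------------------------------------------
# Subset IF distribution comparison
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SubsetComparison:
    condition_a: str
    condition_b: str
    values_a: tuple[float, ...]
    values_b: tuple[float, ...]
    u_statistic: float
    p_value: float


def subset_if_distributions(
    ifs: Sequence[IfValue],
    transcript_ids: Iterable[str],
    conditions: Sequence[str],
) -> SubsetComparison:
    """Condition-wise IF vectors for a transcript subset plus a two-sided
    Mann-Whitney U comparison (with tie correction, as in
    scipy.stats.mannwhitneyu)."""
    subset = set(transcript_ids)
    if not subset:
        raise ValueError("empty transcript subset")
    c1, c2 = conditions
    a = [v.if_pct for v in ifs
         if v.transcript_id in subset and v.condition == c1 and v.defined]
    b = [v.if_pct for v in ifs
         if v.transcript_id in subset and v.condition == c2 and v.defined]
    if len(a) < 2 or len(b) < 2:
        raise ValueError(
            f"subset too small: {len(a)} defined IFs in {c1}, {len(b)} in {c2}"
        )
    res = mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    return SubsetComparison(
        c1, c2, tuple(a), tuple(b), float(res.statistic), float(res.pvalue)
    )


# ---------------------------------------------------------------------------
# Tabulation
# ---------------------------------------------------------------------------

def if_table(
    ifs: Sequence[IfValue],
    difs: Sequence[DifValue],
    conditions: Sequence[str],
) -> pd.DataFrame:
    c1, c2 = conditions
    by_tx: dict[str, dict[str, IfValue]] = {}
    for v in ifs:
        by_tx.setdefault(v.transcript_id, {})[v.condition] = v
    dif_by_tx = {d.transcript_id: d for d in difs}
    rows = []
    for tid in sorted(by_tx):
        v1, v2 = by_tx[tid][c1], by_tx[tid][c2]
        d = dif_by_tx.get(tid)
        rows.append(
            {
                "transcript_id": tid,
                "gene_id": v1.gene_id,
                f"IF_{c1}": v1.if_pct,
                f"IF_{c2}": v2.if_pct,
                "dIF": d.dif if d is not None and d.defined else float("nan"),
                f"IF_{c1}_defined": int(v1.defined),
                f"IF_{c2}_defined": int(v2.defined),
            }
        )
    return pd.DataFrame(rows)


def switches_to_dataframe(switches: Sequence[SwitchCall]) -> pd.DataFrame:
    cols = ["gene_id", "up_transcript_id", "down_transcript_id",
            "dIF_up", "dIF_down", "nmd_gain"]
    rows = [
        {
            "gene_id": s.gene_id,
            "up_transcript_id": s.up_transcript_id,
            "down_transcript_id": s.down_transcript_id,
            "dIF_up": s.dif_up,
            "dIF_down": s.dif_down,
            "nmd_gain": "" if s.nmd_gain is None else int(s.nmd_gain),
        }
        for s in switches
    ]
    return pd.DataFrame(rows, columns=cols)


def write_switches_tsv(
    switches: Sequence[SwitchCall], path: str | Path
) -> None:
    switches_to_dataframe(switches).to_csv(path, sep="\t", index=False)
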