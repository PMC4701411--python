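"""End-to-end evaluation driver tying the modules together.

Given a reference, an assembly, its cDNA alignment table and a
fragment-count table, this produces the full report bundle: locus
assignments, coverage records and histogram, alignment error rates,
the Type I / Type II error events and summary, the quality-depth
(BS/SFB) table, and — with a conserved-gene list and read totals —
the reference-free checklist.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence

import pandas as pd

from .config import EvalConfig
from .error_model import classify_type1, classify_type2, summarize_error_report
from .quality_depth import build_quality_depth_table
from .reference_metrics import (
    alignment_error_rates,
    assign_all,
    coverage_breadth,
    coverage_histogram,
)
from .types import (
    AlignmentRecord,
    CoverageRecord,
    ErrorEvent,
    ErrorRates,
    ErrorReport,
    GeneLocus,
    LocusAssignment,
    QualityDepthRecord,
    ReferenceTranscript,
    Unigene,
)

__all__ = ["EvaluationBundle", "evaluate_assembly", "bundle_reports"]


@dataclass
class EvaluationBundle:
    assignments: List[LocusAssignment]
    coverage: List[CoverageRecord]
    histogram: Dict[str, int]
    error_rates: Optional[ErrorRates]
    events: List[ErrorEvent]
    error_report: ErrorReport
    qd_table: List[QualityDepthRecord]
    n_bs_high: int


def evaluate_assembly(
    reference: Sequence[ReferenceTranscript],
    unigenes: Sequence[Unigene],
    cdna_hits: Sequence[AlignmentRecord],
    counts: Mapping[str, int],
    loci: Sequence[GeneLocus],
    cfg: Optional[EvalConfig] = None,
) -> EvaluationBundle:
    """Run the complete reference-dependent evaluation."""
    cfg = cfg or EvalConfig()
    loc_map = {l.gene_id: l for l in loci}
    ref_map = {r.gene_id: r for r in reference}
    unigene_len = {u.unigene_id: u.length for u in unigenes}

    assignments = assign_all(cdna_hits, keep_two=True)

    by_gene: Dict[str, List[AlignmentRecord]] = {}
    by_query: Dict[str, List[AlignmentRecord]] = {}
    for h in cdna_hits:
        by_gene.setdefault(h.subject_id, []).append(h)
        by_query.setdefault(h.query_id, []).append(h)

    coverage = [
        coverage_breadth(ref_map[g], by_gene.get(g, []))
        for g in sorted(ref_map)
    ]
    histogram = coverage_histogram(coverage, scheme="five_pct")
    rates = alignment_error_rates(list(cdna_hits))

    events: List[ErrorEvent] = []
    for g in sorted(by_gene):
        if g in ref_map:
            events.extend(classify_type1(g, by_gene[g], cfg.k))
    for q in sorted(by_query):
        ev = classify_type2(
            q, by_query[q], loc_map, cfg, unigene_length=unigene_len.get(q)
        )
        if ev is not None:
            events.append(ev)

    report = summarize_error_report(events, assignments, ref_map.keys())
    qd_table, n_high = build_quality_depth_table(
        assignments, counts, reference, cfg
    )
    return EvaluationBundle(
        assignments=assignments,
        coverage=coverage,
        histogram=histogram,
        error_rates=rates,
        events=events,
        error_report=report,
        qd_table=qd_table,
        n_bs_high=n_high,
    )


def bundle_reports(bundle: EvaluationBundle) -> Dict[str, pd.DataFrame]:
    """Flatten an evaluation bundle into writeable report frames."""
    cov = pd.DataFrame(
        [
            {
                "gene_id": c.gene_id,
                "breadth_pct": round(c.breadth_pct, 4),
                "n_unigenes": c.n_unigenes,
                "status": c.status,
            }
            for c in bundle.coverage
        ]
    )
    hist = pd.DataFrame(
        [{"bin": k, "count": v} for k, v in bundle.histogram.items()]
    )
    events = pd.DataFrame(
        [
            {
                "kind": e.kind,
                "unigene_ids": ",".join(e.unigene_ids),
                "gene_ids": ",".join(e.gene_ids),
                "evidence": e.evidence,
            }
            for e in bundle.events
        ],
        columns=["kind", "unigene_ids", "gene_ids", "evidence"],
    )
    qd = pd.DataFrame(
        [
            {
                "gene_id": r.gene_id,
                "bs": round(r.bs, 6),
                "sfb": round(r.sfb, 6),
                "best_unigene": r.best_unigene or "",
            }
            for r in bundle.qd_table
        ]
    )
    summary_rows = [
        {"metric": f"count_{k}", "value": v}
        for k, v in bundle.error_report.counts.items()
    ]
    summary_rows.append(
        {"metric": "type2_rate", "value": bundle.error_report.type2_rate}
    )
    summary_rows.append(
        {"metric": "no_hit_genes", "value": bundle.error_report.no_hit_genes}
    )
    summary_rows.append({"metric": "n_bs_high", "value": bundle.n_bs_high})
    if bundle.error_rates is not None:
        summary_rows.append(
            {"metric": "mismatch_rate", "value": bundle.error_rates.mismatch_rate}
        )
        summary_rows.append(
            {
                "metric": "gap_opening_rate",
                "value": bundle.error_rates.gap_opening_rate,
            }
        )
    return {
        "coverage": cov,
        "coverage_histogram": hist,
        "error_events": events,
        "quality_depth": qd,
        "summary": pd.DataFrame(summary_rows),
    }
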