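"""Completeness-of-coverage machinery.

Assigns unigenes to reference loci by best alignment, computes how much
of each reference cDNA is covered by the union of all aligned unigene
segments (cumulative coverage, not best-unigene-only), bins those
breadths the way coverage histograms are conventionally drawn (5% or
10% bins plus cumulative >90% / >99% tails), and aggregates
mismatch/gap-opening rates over aligned bases.
"""

from __future__ import annotations

import math
from collections import Counter
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

from .types import (
    AlignmentRecord,
    CoverageRecord,
    ErrorRates,
    LocusAssignment,
    ReferenceTranscript,
)

__all__ = [
    "canonicalize_alignment",
    "assign_best_locus",
    "assign_all",
    "union_length",
    "coverage_breadth",
    "coverage_histogram",
    "alignment_error_rates",
]


def canonicalize_alignment(rec: AlignmentRecord) -> AlignmentRecord:
    """Normalize a record so ``s_start <= s_end``, flagging minus strand.

    Idempotent; query coordinates are untouched.
    """
    return rec.canonicalized()


def _hit_sort_key(rec: AlignmentRecord):
    # Best hit first: highest bit score, then lowest e-value, then the
    # lexicographically smallest subject id as a deterministic final key.
    return (-rec.bit_score, rec.e_value, rec.subject_id)


def assign_best_locus(
    hits: Sequence[AlignmentRecord], keep_two: bool = False
) -> LocusAssignment:
    """Pick the most significant locus for one unigene's hits.

    Ties on bit score break by lower e-value, then lexicographically
    smaller gene id.  With ``keep_two`` the best *distinct* second gene
    is recorded as runner-up (used by Type II classification).
    """
    if not hits:
        raise ValueError("assign_best_locus requires at least one hit")
    queries = {h.query_id for h in hits}
    if len(queries) > 1:
        raise ValueError(f"hits span multiple unigenes: {sorted(queries)}")
    ordered = sorted(hits, key=_hit_sort_key)
    best = ordered[0]
    runner_up: Optional[str] = None
    if keep_two:
        for h in ordered[1:]:
            if h.subject_id != best.subject_id:
                runner_up = h.subject_id
                break
    return LocusAssignment(
        unigene_id=best.query_id,
        gene_id=best.subject_id,
        best_alignment=best,
        runner_up_gene=runner_up,
    )


def assign_all(
    hits: Iterable[AlignmentRecord], keep_two: bool = False
) -> List[LocusAssignment]:
    """Group hits by unigene and assign each to its best locus."""
    by_query: Dict[str, List[AlignmentRecord]] = {}
    for h in hits:
        by_query.setdefault(h.query_id, []).append(h)
    return [
        assign_best_locus(by_query[q], keep_two=keep_two) for q in sorted(by_query)
    ]


def union_length(intervals: Iterable[Tuple[int, int]]) -> int:
    """Total length of the union of 0-based half-open intervals."""
    ivs = sorted(intervals)
    total = 0
    cur_start: Optional[int] = None
    cur_end = 0
    for start, end in ivs:
        if cur_start is None or start > cur_end:
            if cur_start is not None:
                total += cur_end - cur_start
            cur_start, cur_end = start, end
        else:
            cur_end = max(cur_end, end)
    if cur_start is not None:
        total += cur_end - cur_start
    return total


def coverage_breadth(
    gene: ReferenceTranscript, hits: Sequence[AlignmentRecord]
) -> CoverageRecord:
    """Percent of the reference covered by >=1 segment from any unigene."""
    for h in hits:
        if h.subject_id != gene.gene_id:
            raise ValueError(
                f"hit subject {h.subject_id!r} does not match gene {gene.gene_id!r}"
            )
        lo, hi = h.s_interval()
        if lo < 0 or hi > gene.length:
            raise ValueError(
                f"interval {lo}..{hi} outside gene {gene.gene_id!r} "
                f"(length {gene.length})"
            )
    if not hits:
        return CoverageRecord(gene_id=gene.gene_id, breadth_pct=0.0, n_unigenes=0)
    covered = union_length(h.s_interval() for h in hits)
    return CoverageRecord(
        gene_id=gene.gene_id,
        breadth_pct=100.0 * covered / gene.length,
        n_unigenes=len({h.query_id for h in hits}),
    )


def coverage_histogram(
    records: Sequence[CoverageRecord], scheme: str = "five_pct"
) -> Dict[str, int]:
    """Bin coverage breadths for plotting.

    Exclusive bins are ``no_hit`` plus ``(lo,hi]`` steps of 5% or 10%;
    their counts sum to ``len(records)``.  The ``>90`` and ``>99``
    entries are *cumulative tail* counts (genes above those breadths),
    overlapping the top bins — the convention coverage histograms use
    when the two lightest bars show high-coverage genes.  The
    ``tail_convention`` metadata key records this.
    """
    if scheme == "five_pct":
        width = 5
    elif scheme == "ten_pct":
        width = 10
    else:
        raise ValueError(f"scheme must be 'five_pct' or 'ten_pct', got {scheme!r}")
    bins: Counter = Counter()
    for rec in records:
        b = rec.breadth_pct
        if not 0.0 <= b <= 100.0:
            raise ValueError(f"breadth {b} out of [0, 100]")
        if rec.status == "no_hit":
            bins["no_hit"] += 1
        else:
            # (lo, hi] bins; breadth exactly 0 with hits still lands in the
            # first bin (a hit exists even if rounding gives ~0 breadth).
            idx = min(max(math.ceil(b / width), 1), 100 // width)
            lo, hi = (idx - 1) * width, idx * width
            bins[f"({lo},{hi}]"] += 1
    out: Dict[str, int] = {"no_hit": bins["no_hit"]}
    for idx in range(1, 100 // width + 1):
        lo, hi = (idx - 1) * width, idx * width
        out[f"({lo},{hi}]"] = bins[f"({lo},{hi}]"]
    out[">90"] = sum(1 for r in records if r.breadth_pct > 90)
    out[">99"] = sum(1 for r in records if r.breadth_pct > 99)
    return out


def alignment_error_rates(
    hits: Sequence[AlignmentRecord],
) -> Optional[ErrorRates]:
    """Mismatches and gap openings as fractions of total aligned bases.

    Returns ``None`` when there are no alignments (rates undefined).
    """
    total = sum(h.aln_length for h in hits)
    if total == 0:
        return None
    return ErrorRates(
        mismatch_rate=sum(h.mismatches for h in hits) / total,
        gap_opening_rate=sum(h.gap_openings for h in hits) / total,
        aligned_bases=total,
    )
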