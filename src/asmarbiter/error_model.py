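"""Assembly-failure taxonomy.

Type I errors are fragmentation: several unigenes from one locus that
failed to assemble together.  Walking the locus's unigene intervals in
subject order, each consecutive distinct-unigene pair is one event —
a coverage gap (Case I), an insufficient overlap of at most k-1 bases
that a k-mer assembler could never have joined (Case II), or a
conflicting overlap longer than k-1 bases that *should* have been
joined (Case III).

Type II errors are annotation ambiguity: one unigene with high-identity
hits to two gene loci.  Using the two highest-scoring genes, the
query-segment geometry decides the case: disjoint segments (Case I, the
chimera-indicative pattern), equal full alignments to both genes
(Case II), one segment contained in the other (Case III), and segments
overlapping more (Case IV) or at most (Case V) a fixed fraction of the
unigene.  Pairs of *adjacent* genes are excluded: with unstranded
libraries, neighbouring or overlapping transcripts are legitimately
co-assembled into one unigene.

Chimera adjudication re-examines ambiguous unigenes against genome
alignments: hits surviving identity/e-value filters are merged into
genomic windows (same chromosome/strand, intron-scale gaps bridged) and
the number of windows explaining nearly the whole unigene separates
true co-assemblies and duplicate-gene ambiguity from genuine chimeras.
"""

from __future__ import annotations

from collections import Counter
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

from .config import EvalConfig
from .reference_metrics import canonicalize_alignment, union_length
from .types import (
    AlignmentRecord,
    ChimeraVerdict,
    ErrorEvent,
    ErrorReport,
    GeneLocus,
    LocusAssignment,
    adjacent,
)

__all__ = [
    "classify_type1",
    "classify_type2",
    "adjudicate_chimera",
    "summarize_error_report",
]


def _best_per_unigene(
    hits: Sequence[AlignmentRecord],
) -> List[AlignmentRecord]:
    best: Dict[str, AlignmentRecord] = {}
    for h in hits:
        cur = best.get(h.query_id)
        if (
            cur is None
            or (h.bit_score, -h.e_value) > (cur.bit_score, -cur.e_value)
        ):
            best[h.query_id] = h
    return list(best.values())


def classify_type1(
    gene: str, hits: Sequence[AlignmentRecord], k: int
) -> List[ErrorEvent]:
    """Classify fragmentation events among one gene's unigene alignments.

    Uses each unigene's single best alignment to this gene, sorted by
    subject start.  For every consecutive pair of distinct unigenes:
    subject gap > 0 -> Case I; overlap in [0, k-1] -> Case II
    (an abutting pair counts as overlap 0); overlap > k-1 -> Case III.
    A gene covered by a single unigene yields no events.
    """
    if k < 2:
        raise ValueError(f"k must be >= 2, got {k}")
    for h in hits:
        if h.subject_id != gene:
            raise ValueError(
                f"hit subject {h.subject_id!r} does not match gene {gene!r}"
            )
    best = [canonicalize_alignment(h) for h in _best_per_unigene(hits)]
    if len(best) < 2:
        return []
    best.sort(key=lambda h: (h.s_interval(), h.query_id))
    events: List[ErrorEvent] = []
    for left, right in zip(best, best[1:]):
        _, left_end = left.s_interval()
        right_start, _ = right.s_interval()
        gap = right_start - left_end
        pair = (left.query_id, right.query_id)
        if gap > 0:
            events.append(
                ErrorEvent(
                    kind="T1_case1",
                    unigene_ids=pair,
                    gene_ids=(gene,),
                    evidence=f"gap={gap}",
                )
            )
        else:
            overlap = -gap
            kind = "T1_case2" if overlap <= k - 1 else "T1_case3"
            events.append(
                ErrorEvent(
                    kind=kind,
                    unigene_ids=pair,
                    gene_ids=(gene,),
                    evidence=f"overlap={overlap}",
                )
            )
    return events


def _overlap(a: Tuple[int, int], b: Tuple[int, int]) -> int:
    return max(0, min(a[1], b[1]) - max(a[0], b[0]))


def classify_type2(
    unigene: str,
    hits: Sequence[AlignmentRecord],
    loci: Dict[str, GeneLocus],
    cfg: EvalConfig,
    unigene_length: Optional[int] = None,
) -> Optional[ErrorEvent]:
    """Classify one unigene's multi-locus ambiguity, or return None.

    Only hits at >= ``cfg.type2_identity_min`` percent identity count.
    The two highest-bit-score genes are considered; adjacent gene pairs
    are excluded as co-assemblies.  Case precedence is I > II > III >
    IV > V so the chimera-indicative disjoint-segment pattern is never
    masked by a weaker overlap case.
    """
    strong = [h for h in hits if h.pct_identity >= cfg.type2_identity_min]
    for h in strong:
        if h.query_id != unigene:
            raise ValueError(f"hit query {h.query_id!r} != unigene {unigene!r}")
    per_gene = {}
    for h in strong:
        cur = per_gene.get(h.subject_id)
        if cur is None or (h.bit_score, -h.e_value) > (cur.bit_score, -cur.e_value):
            per_gene[h.subject_id] = h
    if len(per_gene) < 2:
        return None
    top = sorted(
        per_gene.values(), key=lambda h: (-h.bit_score, h.e_value, h.subject_id)
    )[:2]
    a, b = top
    genes = (a.subject_id, b.subject_id)
    loc_a, loc_b = loci.get(genes[0]), loci.get(genes[1])
    adjacency_known = loc_a is not None and loc_b is not None
    if adjacency_known and adjacent(loc_a, loc_b):
        return None  # co-assembly of neighbouring genes, not an error
    seg_a, seg_b = a.q_interval(), b.q_interval()
    ov = _overlap(seg_a, seg_b)
    length = unigene_length if unigene_length is not None else max(
        seg_a[1], seg_b[1]
    )
    jitter = cfg.type2_case2_end_jitter
    if ov <= cfg.type2_case1_max_overlap:
        kind = "T2_case1"
    elif (
        a.bit_score == b.bit_score
        and abs(seg_a[0] - seg_b[0]) <= jitter
        and abs(seg_a[1] - seg_b[1]) <= jitter
    ):
        kind = "T2_case2"
    elif (seg_a[0] < seg_b[0] and seg_b[1] < seg_a[1]) or (
        seg_b[0] < seg_a[0] and seg_a[1] < seg_b[1]
    ):
        kind = "T2_case3"
    elif ov > cfg.type2_overlap_frac * length:
        kind = "T2_case4"
    else:
        kind = "T2_case5"
    return ErrorEvent(
        kind=kind,
        unigene_ids=(unigene,),
        gene_ids=genes,
        evidence=f"q_segments={seg_a},{seg_b} overlap={ov}",
        adjacency_known=adjacency_known,
    )


def _genomic_windows(
    hits: Sequence[AlignmentRecord], merge_gap: int
) -> List[List[AlignmentRecord]]:
    """Merge same-chromosome, same-strand hits separated by <= merge_gap."""
    groups: Dict[Tuple[str, str], List[AlignmentRecord]] = {}
    for h in hits:
        c = canonicalize_alignment(h)
        groups.setdefault((c.subject_id, c.strand), []).append(c)
    windows: List[List[AlignmentRecord]] = []
    for key in sorted(groups):
        members = sorted(groups[key], key=lambda h: h.s_interval())
        current = [members[0]]
        cur_end = members[0].s_interval()[1]
        for h in members[1:]:
            lo, hi = h.s_interval()
            if lo - cur_end <= merge_gap:
                current.append(h)
                cur_end = max(cur_end, hi)
            else:
                windows.append(current)
                current = [h]
                cur_end = hi
        windows.append(current)
    return windows


def adjudicate_chimera(
    unigene: str,
    genome_hits: Sequence[AlignmentRecord],
    loci: Dict[str, GeneLocus],
    cfg: EvalConfig,
    unigene_length: Optional[int] = None,
    trans_splice_candidates: Optional[Set[str]] = None,
) -> ChimeraVerdict:
    """Decide whether an ambiguous unigene is a real chimera.

    Genome hits below ``chimera_identity_min`` identity or above
    ``chimera_evalue_max`` e-value are discarded; survivors merge into
    genomic windows (same chromosome/strand, gaps <= ``chimera_merge_gap``
    bridged, absorbing introns of spliced alignments).  One window
    covering >= ``chimera_query_cov`` of the unigene is an accurate
    co-assembly; two or more such windows indicate a duplicated/closely
    related locus (ambiguity, not mis-assembly); unigenes flagged as
    annotated trans-splice candidates are set aside; anything else —
    query halves explained only by distant windows — is a chimera.
    """
    kept = [
        h
        for h in genome_hits
        if h.pct_identity >= cfg.chimera_identity_min
        and h.e_value <= cfg.chimera_evalue_max
    ]
    for h in kept:
        if h.query_id != unigene:
            raise ValueError(f"hit query {h.query_id!r} != unigene {unigene!r}")
    if not kept:
        return ChimeraVerdict(unigene, "unresolved", supporting_alignments=0)
    length = unigene_length
    if length is None:
        length = max(h.q_interval()[1] for h in kept)
    windows = _genomic_windows(kept, cfg.chimera_merge_gap)
    full = 0
    for win in windows:
        qcov = union_length(h.q_interval() for h in win) / length
        if qcov >= cfg.chimera_query_cov:
            full += 1
    n = len(kept)
    if full == 1:
        return ChimeraVerdict(unigene, "co_assembly", supporting_alignments=n)
    if full >= 2:
        return ChimeraVerdict(unigene, "ambiguous_duplicate", supporting_alignments=n)
    if trans_splice_candidates and unigene in trans_splice_candidates:
        return ChimeraVerdict(
            unigene, "trans_spliced_candidate", supporting_alignments=n
        )
    return ChimeraVerdict(unigene, "chimera", supporting_alignments=n)


def summarize_error_report(
    events: Iterable[ErrorEvent],
    assignments: Sequence[LocusAssignment],
    detected_genes: Iterable[str],
) -> ErrorReport:
    """Aggregate per-kind counts, the Type II rate and missing genes.

    The Type II rate is the fraction of reference-aligned unigenes that
    are ambiguously aligned; ``no_hit_genes`` counts detected genes with
    no assigned unigene at all.
    """
    counts: Counter = Counter()
    t2_unigenes: Set[str] = set()
    for ev in events:
        counts[ev.kind] += 1
        if ev.is_type2:
            t2_unigenes.update(ev.unigene_ids)
    aligned = {a.unigene_id for a in assignments}
    rate = len(t2_unigenes & aligned) / len(aligned) if aligned else 0.0
    hit_genes = {a.gene_id for a in assignments}
    missing = sum(1 for g in set(detected_genes) if g not in hit_genes)
    all_kinds = [f"T1_case{i}" for i in (1, 2, 3)] + [
        f"T2_case{i}" for i in (1, 2, 3, 4, 5)
    ]
    return ErrorReport(
        counts={k: counts[k] for k in all_kinds},
        type2_rate=rate,
        no_hit_genes=missing,
    )
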