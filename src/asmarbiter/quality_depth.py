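"""Quality-versus-depth analysis: normalized bit score (BS) against
sequenced fragments per base pair (SFB).

BS is the bit score of a gene's single best unigene alignment divided
by the reference cDNA length; a perfect full-length match scores 2.0
bits/base, and a 75%-length error-free reconstruction scores 1.5, which
is the conventional "long and accurate" threshold.  SFB is the total
number of sequenced fragments (read pairs or orphans) mapped to the
gene's unigenes, divided by cDNA length — the normalized sequencing
depth axis.  Together they locate every gene on a quality/depth plane
and expose assembler failure modes at both expression extremes.

Also here: recovery of a conserved-ortholog list (completeness proxy)
and reciprocal-best-hit paralog pair analysis (expressed gene pairs and
the closely-related, low-Ks subset).
"""

from __future__ import annotations

from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple
import warnings

from .config import EvalConfig
from .types import (
    AlignmentRecord,
    CoverageRecord,
    GenePair,
    LocusAssignment,
    QualityDepthRecord,
    ReferenceTranscript,
    UCOSummary,
)

__all__ = [
    "normalized_bit_score",
    "sequenced_fragments_per_bp",
    "build_quality_depth_table",
    "uco_recovery",
    "paralog_pair_analysis",
]

# Idealized per-base scoring: +2 bits per matched base (forced by the
# 2.0 ideal), -2 per mismatch, -5 per gap opening.
MATCH_BITS = 2.0
MISMATCH_PENALTY = 2.0
GAP_PENALTY = 5.0


def normalized_bit_score(
    matches: int,
    mismatches: int,
    gap_openings: int,
    ref_length: int,
    external_bits: Optional[float] = None,
) -> float:
    """Bit score per reference base (BS), ideal 2.0.

    With ``external_bits`` (a real aligner's bit score) BS is simply
    ``external_bits / ref_length``.  Otherwise the idealized score
    ``2*matches - 2*mismatches - 5*gap_openings`` (clamped at 0) is
    normalized.  The unigene may exceed the reference, so
    ``matches + mismatches`` is not bounded by ``ref_length``.
    """
    if ref_length <= 0:
        raise ValueError(f"ref_length must be positive, got {ref_length}")
    if min(matches, mismatches, gap_openings) < 0:
        raise ValueError("counts must be non-negative")
    if external_bits is not None:
        return external_bits / ref_length
    bits = (
        MATCH_BITS * matches
        - MISMATCH_PENALTY * mismatches
        - GAP_PENALTY * gap_openings
    )
    return max(bits, 0.0) / ref_length


def idealized_bits(matches: int, mismatches: int, gap_openings: int) -> float:
    """Unnormalized idealized bit score (clamped at 0)."""
    return max(
        MATCH_BITS * matches
        - MISMATCH_PENALTY * mismatches
        - GAP_PENALTY * gap_openings,
        0.0,
    )


def sequenced_fragments_per_bp(
    fragments_by_unigene: Mapping[str, int] | int, ref_length: int
) -> float:
    """Sequenced fragments per reference base (SFB).

    Accepts either a per-unigene fragment count mapping (all unigenes
    assigned to the gene) or a pre-summed total.  SFB is linear in the
    total and indifferent to how fragments split among unigenes.
    """
    if ref_length <= 0:
        raise ValueError(f"ref_length must be positive, got {ref_length}")
    total = (
        fragments_by_unigene
        if isinstance(fragments_by_unigene, int)
        else sum(fragments_by_unigene.values())
    )
    if total < 0:
        raise ValueError("negative fragment count")
    return total / ref_length


def build_quality_depth_table(
    assignments: Sequence[LocusAssignment],
    counts: Mapping[str, int],
    reference: Sequence[ReferenceTranscript],
    cfg: EvalConfig,
) -> Tuple[List[QualityDepthRecord], int]:
    """One (BS, SFB) record per reference gene, plus the n(BS > 1.5) tail.

    BS comes from the single best alignment per gene (alignments of
    equal or lower bit score are excluded); SFB sums the fragment
    counts of every unigene assigned to the gene.  Genes with no
    assigned unigene get BS 0 / best_unigene None.
    """
    ref_len = {r.gene_id: r.length for r in reference}
    best_by_gene: Dict[str, AlignmentRecord] = {}
    frags_by_gene: Dict[str, int] = {}
    for a in assignments:
        if a.gene_id not in ref_len:
            raise ValueError(
                f"assigned gene {a.gene_id!r} absent from the reference"
            )
        cur = best_by_gene.get(a.gene_id)
        h = a.best_alignment
        if cur is None or (h.bit_score, -h.e_value) > (cur.bit_score, -cur.e_value):
            best_by_gene[a.gene_id] = h
        frags_by_gene[a.gene_id] = frags_by_gene.get(a.gene_id, 0) + counts.get(
            a.unigene_id, 0
        )
    records: List[QualityDepthRecord] = []
    for gene in sorted(ref_len):
        best = best_by_gene.get(gene)
        if best is None:
            records.append(QualityDepthRecord(gene, bs=0.0, sfb=0.0))
        else:
            records.append(
                QualityDepthRecord(
                    gene,
                    bs=best.bit_score / ref_len[gene],
                    sfb=frags_by_gene.get(gene, 0) / ref_len[gene],
                    best_unigene=best.query_id,
                )
            )
    n_high = sum(1 for r in records if r.bs > cfg.bs_threshold)
    return records, n_high


def uco_recovery(
    table: Sequence[QualityDepthRecord],
    coverage: Sequence[CoverageRecord],
    uco_list: Sequence[str],
    cfg: EvalConfig,
) -> UCOSummary:
    """Recovery fractions for a conserved-ortholog gene list.

    Unknown identifiers are warned about and dropped; genes absent from
    the assembly contribute zero to every fraction.
    """
    if not uco_list:
        raise ValueError("empty conserved-gene list")
    bs = {r.gene_id: r.bs for r in table}
    cov = {r.gene_id: r.breadth_pct for r in coverage}
    known = [g for g in uco_list if g in bs or g in cov]
    unknown = sorted(set(uco_list) - set(known))
    if unknown:
        warnings.warn(
            f"{len(unknown)} listed genes absent from the reference "
            f"(e.g. {unknown[:3]}); dropped",
            stacklevel=2,
        )
    if not known:
        raise ValueError("no listed gene matches the reference")
    n = len(known)
    return UCOSummary(
        n_listed=n,
        frac_bs_high=sum(1 for g in known if bs.get(g, 0.0) > cfg.bs_threshold) / n,
        frac_cov90=sum(1 for g in known if cov.get(g, 0.0) > 90.0) / n,
        frac_cov99=sum(1 for g in known if cov.get(g, 0.0) > 99.0) / n,
    )


def _reciprocal_best_hits(
    hits: Iterable[AlignmentRecord],
) -> List[Tuple[str, str]]:
    best: Dict[str, Tuple[float, float, str]] = {}
    for h in hits:
        if h.query_id == h.subject_id:
            continue  # self-hit
        key = (-h.bit_score, h.e_value, h.subject_id)
        if h.query_id not in best or key < best[h.query_id]:
            best[h.query_id] = key
    partner = {q: key[2] for q, key in best.items()}
    pairs = set()
    for q, s in partner.items():
        if partner.get(s) == q:
            pairs.add((min(q, s), max(q, s)))
    return sorted(pairs)


def paralog_pair_analysis(
    all_vs_all_hits: Iterable[AlignmentRecord],
    table: Sequence[QualityDepthRecord],
    ks_values: Optional[Mapping[frozenset, float]],
    cfg: EvalConfig,
) -> Tuple[List[GenePair], List[GenePair]]:
    """Reciprocal-best-hit gene pairs with expression/assembly classes.

    Expression uses the SFB floor per mate (both / one / neither
    expressed); assembly uses the BS threshold per mate, with "present"
    meaning any alignment at all.  Returns ``(pairs, crg_subset)`` where
    the CRG subset keeps the lowest-Ks expressed pairs under
    ``cfg.crg_ks_max``, capped at ``cfg.crg_max_pairs``.
    """
    rec = {r.gene_id: r for r in table}
    pairs: List[GenePair] = []
    for a, b in _reciprocal_best_hits(all_vs_all_hits):
        ra, rb = rec.get(a), rec.get(b)
        sfb_a = ra.sfb if ra else 0.0
        sfb_b = rb.sfb if rb else 0.0
        n_expr = sum(s >= cfg.sfb_threshold for s in (sfb_a, sfb_b))
        expression = ("neither", "one_expressed", "both_expressed")[n_expr]
        present_a = ra is not None and ra.best_unigene is not None
        present_b = rb is not None and rb.best_unigene is not None
        high_a = present_a and ra.bs > cfg.bs_threshold
        high_b = present_b and rb.bs > cfg.bs_threshold
        if high_a and high_b:
            assembly = "both_high"
        elif high_a or high_b:
            assembly = "one_high"
        elif present_a and present_b:
            assembly = "both_present_low"
        elif present_a or present_b:
            assembly = "one_missing"
        else:
            assembly = "both_missing"
        ks = ks_values.get(frozenset((a, b))) if ks_values else None
        pairs.append(
            GenePair(
                gene_a=a,
                gene_b=b,
                ks=ks,
                expression_class=expression,
                assembly_class=assembly,
            )
        )
    crg = [
        p
        for p in pairs
        if p.expression_class == "both_expressed"
        and p.ks is not None
        and p.ks < cfg.crg_ks_max
    ]
    crg.sort(key=lambda p: (p.ks, p.gene_a, p.gene_b))
    return pairs, crg[: cfg.crg_max_pairs]
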