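"""Synthetic fixtures: toy reference transcriptomes, expression
profiles, and deliberately corrupted assemblies with ground truth.

The generator emulates the structural features the evaluators care
about — gene lengths around typical plant cDNA sizes, paralog pairs at
controlled divergence, genes laid out on chromosomes with intergenic
spacers, and fragment counts spanning orders of magnitude (log-normal)
— and injects assembly failures with exact, recorded geometry:
fragmentation gaps/overlaps in each k-mer regime, chimeric joins of
non-adjacent genes, legitimate co-assemblies of adjacent genes, and
duplicate-gene ambiguity.  Alignment tables are emitted directly from
the constructed geometry (idealized scoring, 2 bits per matched base),
so every classifier can be scored against known truth without running
an external aligner.

Every generator is a pure function of (plan, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Sequence, Tuple

import numpy as np

from .quality_depth import idealized_bits
from .types import (
    AlignmentRecord,
    GeneLocus,
    ReferenceTranscript,
    Unigene,
    adjacent,
)

__all__ = [
    "SimulationPlan",
    "ErrorPlan",
    "TruthLabels",
    "simulate_reference",
    "simulate_expression",
    "make_error_plan",
    "corrupt_assembly",
    "derive_truth_alignments",
    "distribute_fragments",
    "subsample_reads",
    "subsample_fastq",
]

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class SimulationPlan:
    """Parameters of the toy transcriptome and its expression profile."""

    n_genes: int = 200
    length_mean: float = 1200.0
    length_sd: float = 400.0
    length_min: int = 300
    paralog_fraction: float = 0.2
    paralog_divergence: float = 0.03
    intergenic_mean: float = 2000.0
    n_chromosomes: int = 2
    expression_log_mean: float = 4.0  # natural-log scale; median ~55 fragments
    expression_log_sd: float = 1.5  # ~3 orders of magnitude dynamic range
    zero_fraction: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 2:
            raise ValueError("n_genes must be >= 2")
        for name in ("paralog_fraction", "paralog_divergence", "zero_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} {v} out of [0, 1]")
        if self.length_min > self.length_mean + 6 * self.length_sd:
            raise ValueError("infeasible plan: length_min beyond mean + 6*sd")


@dataclass(frozen=True)
class ErrorDirective:
    """One planned corruption.

    kinds: ``perfect``, ``t1_gap``, ``t1_overlap`` (param ``overlap``
    decides the Case II / Case III regime against k), ``chimera``
    (non-adjacent gene pair), ``co_assembly`` (adjacent pair),
    ``duplicate`` (ambiguity between identical paralogs), ``t2_case3``,
    ``t2_case4``, ``t2_case5`` (recorded two-locus geometry).
    """

    kind: str
    genes: Tuple[str, ...]
    params: Tuple[Tuple[str, int], ...] = ()

    def param(self, name: str) -> int:
        return dict(self.params)[name]


@dataclass(frozen=True)
class ErrorPlan:
    k: int
    directives: Tuple[ErrorDirective, ...]


@dataclass
class _AlignmentSpec:
    """Geometry of one intended alignment, recorded at corruption time."""

    query_id: str
    subject_id: str
    q_start: int  # 1-based inclusive
    q_end: int
    s_start: int
    s_end: int
    mismatches: int = 0
    gap_openings: int = 0
    against_genome: bool = False


@dataclass
class TruthLabels:
    """Ground truth emitted alongside a corrupted assembly."""

    #: per unigene: the source gene(s)
    source_genes: Dict[str, Tuple[str, ...]] = field(default_factory=dict)
    #: intended error events as (kind, unigene_ids, gene_ids)
    events: List[Tuple[str, Tuple[str, ...], Tuple[str, ...]]] = field(
        default_factory=list
    )
    #: intended chimera verdict per adjudicated unigene
    verdicts: Dict[str, str] = field(default_factory=dict)
    #: recorded alignment geometry (cDNA and genome)
    cdna_specs: List[_AlignmentSpec] = field(default_factory=list)
    genome_specs: List[_AlignmentSpec] = field(default_factory=list)


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(_BASES, size=length))


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    if rate <= 0:
        return seq
    arr = np.array(list(seq))
    mask = rng.random(len(arr)) < rate
    if mask.any():
        subs = rng.choice(_BASES, size=int(mask.sum()))
        # force a real substitution at each chosen site
        same = subs == arr[mask]
        while same.any():
            subs[same] = rng.choice(_BASES, size=int(same.sum()))
            same = subs == arr[mask]
        arr[mask] = subs
    return "".join(arr)


def simulate_reference(
    plan: SimulationPlan,
) -> Tuple[
    List[ReferenceTranscript],
    List[GeneLocus],
    Dict[str, str],
    List[Tuple[str, str]],
]:
    """Generate reference transcripts, gene loci, chromosome sequences
    and the list of true paralog pairs.

    Paralog pairs are created by copy-and-mutate at the plan's
    divergence; pair mates are placed on different chromosomes (or far
    apart) so they are never adjacent.  Genes sit on ``n_chromosomes``
    chromosomes separated by exponential intergenic spacers, with
    ``order_index`` matching coordinate order.
    """
    rng = np.random.default_rng(plan.seed)
    n_pairs = int(round(plan.n_genes * plan.paralog_fraction / 2))
    n_base = plan.n_genes - n_pairs
    lengths = np.maximum(
        rng.normal(plan.length_mean, plan.length_sd, size=n_base).astype(int),
        plan.length_min,
    )
    transcripts: List[ReferenceTranscript] = []
    for i, L in enumerate(lengths, start=1):
        transcripts.append(
            ReferenceTranscript(gene_id=f"g{i:04d}", sequence=_random_seq(rng, int(L)))
        )
    pairs: List[Tuple[str, str]] = []
    for j in range(n_pairs):
        src = transcripts[int(rng.integers(0, n_base))]
        dup_id = f"g{n_base + j + 1:04d}"
        transcripts.append(
            ReferenceTranscript(
                gene_id=dup_id,
                sequence=_mutate(rng, src.sequence, plan.paralog_divergence),
            )
        )
        pairs.append((src.gene_id, dup_id))
    # genome layout: interleave genes across chromosomes so paralog mates
    # (appended at the end) land far from their sources
    order = rng.permutation(len(transcripts))
    chrom_genes: List[List[ReferenceTranscript]] = [
        [] for _ in range(plan.n_chromosomes)
    ]
    for pos, idx in enumerate(order):
        chrom_genes[pos % plan.n_chromosomes].append(transcripts[idx])
    loci: List[GeneLocus] = []
    chrom_seqs: Dict[str, str] = {}
    for c, genes in enumerate(chrom_genes, start=1):
        chrom = f"chr{c}"
        parts: List[str] = []
        cursor = 0
        for oi, tr in enumerate(genes, start=1):
            gap = 1 + int(rng.exponential(plan.intergenic_mean))
            parts.append(_random_seq(rng, gap))
            cursor += gap
            start = cursor
            parts.append(tr.sequence)
            cursor += tr.length
            loci.append(
                GeneLocus(
                    gene_id=tr.gene_id,
                    chrom=chrom,
                    start=start,
                    end=cursor,
                    strand="+",
                    order_index=oi,
                )
            )
        chrom_seqs[chrom] = "".join(parts)
    return transcripts, loci, chrom_seqs, pairs


def simulate_expression(
    plan: SimulationPlan, reference: Sequence[ReferenceTranscript]
) -> Dict[str, int]:
    """Per-gene fragment counts: rounded log-normal draws with a stated
    fraction of genes set to zero (undetected)."""
    rng = np.random.default_rng(plan.seed + 1)
    counts: Dict[str, int] = {}
    for tr in reference:
        c = int(round(rng.lognormal(plan.expression_log_mean, plan.expression_log_sd)))
        counts[tr.gene_id] = max(c, 1)
    zero = rng.random(len(reference)) < plan.zero_fraction
    for tr, z in zip(reference, zero):
        if z:
            counts[tr.gene_id] = 0
    return counts


def make_error_plan(
    reference: Sequence[ReferenceTranscript],
    loci: Sequence[GeneLocus],
    k: int = 31,
    n_per_kind: int = 25,
    seed: int = 0,
) -> ErrorPlan:
    """Draw a concrete corruption plan covering every error kind.

    Each targeted gene receives exactly one directive.  ``t1_overlap``
    directives sample overlaps on both sides of the k-1 boundary,
    always including the exact boundary overlaps k-1 (Case II) and k
    (Case III).  Chimera partners are drawn non-adjacent; co-assembly
    partners are true genomic neighbours.
    """
    rng = np.random.default_rng(seed)
    by_id = {t.gene_id: t for t in reference}
    loc = {l.gene_id: l for l in loci}
    order = [t.gene_id for t in reference if t.length >= 6 * k]
    rng.shuffle(order)
    free = list(order)
    directives: List[ErrorDirective] = []

    def pop(n: int) -> List[str]:
        if len(free) < n:
            raise ValueError("not enough genes for the requested error plan")
        out = free[:n]
        del free[:n]
        return out

    def pop_cross_chrom_pairs(n_pairs: int) -> List[Tuple[str, str]]:
        """Pairs of genes guaranteed to sit on different chromosomes
        (hence never adjacent, and their genomic windows never merge)."""
        pairs: List[Tuple[str, str]] = []
        pool: List[str] = []
        while len(pairs) < n_pairs:
            while True:
                mate_idx = None
                for i, a in enumerate(pool):
                    for j in range(i + 1, len(pool)):
                        if loc[pool[j]].chrom != loc[a].chrom:
                            mate_idx = (i, j)
                            break
                    if mate_idx:
                        break
                if mate_idx:
                    break
                pool.extend(pop(2))
            i, j = mate_idx
            b = pool.pop(j)
            a = pool.pop(i)
            pairs.append((a, b))
        free[:0] = pool  # return unused genes to the front
        return pairs

    # Type I gap (Case I)
    for g in pop(n_per_kind):
        directives.append(
            ErrorDirective("t1_gap", (g,), (("gap", int(rng.integers(5, k))),))
        )
    # Type I overlaps: force both boundary overlaps (k-1 -> Case II,
    # k -> Case III), then sample both regimes
    overlaps = [k - 1, k]
    while len(overlaps) < n_per_kind * 2:
        if len(overlaps) % 2 == 0:
            overlaps.append(int(rng.integers(1, k)))  # <= k-1: Case II
        else:
            overlaps.append(int(rng.integers(k, 3 * k)))  # > k-1: Case III
    for g, ov in zip(pop(len(overlaps)), overlaps):
        directives.append(ErrorDirective("t1_overlap", (g,), (("overlap", ov),)))
    # chimeras and duplicate-gene ambiguity: cross-chromosome partners
    def length_ordered(a: str, b: str) -> Tuple[str, str]:
        # the unigene source (first gene) must be the shorter mate so
        # the partner's subject coordinates never overrun its length
        return (a, b) if by_id[a].length <= by_id[b].length else (b, a)

    for a, b in pop_cross_chrom_pairs(n_per_kind):
        directives.append(ErrorDirective("chimera", (a, b)))
    for a, b in pop_cross_chrom_pairs(n_per_kind):
        directives.append(ErrorDirective("duplicate", length_ordered(a, b)))
    # co-assemblies: true genomic neighbours not already used
    used = {g for d in directives for g in d.genes}
    by_pos: Dict[str, List[GeneLocus]] = {}
    for l in loci:
        by_pos.setdefault(l.chrom, []).append(l)
    n_co = 0
    for chrom in sorted(by_pos):
        ordered = sorted(by_pos[chrom], key=lambda l: l.order_index)
        i = 0
        while i + 1 < len(ordered) and n_co < n_per_kind:
            a, b = ordered[i], ordered[i + 1]
            if (
                a.gene_id not in used
                and b.gene_id not in used
                and by_id[a.gene_id].length >= 6 * k
                and by_id[b.gene_id].length >= 6 * k
            ):
                directives.append(
                    ErrorDirective("co_assembly", (a.gene_id, b.gene_id))
                )
                used.update((a.gene_id, b.gene_id))
                n_co += 1
                i += 2
            else:
                i += 1
    free[:] = [g for g in free if g not in used]
    # remaining Type II overlap geometries (partners need not be distant:
    # only the recorded cDNA geometry matters, but keep them non-adjacent)
    for kind in ("t2_case3", "t2_case4", "t2_case5"):
        for a, b in pop_cross_chrom_pairs(n_per_kind):
            directives.append(ErrorDirective(kind, length_ordered(a, b)))
    return ErrorPlan(k=k, directives=tuple(directives))


def _spec_to_cdna_record(spec: _AlignmentSpec) -> AlignmentRecord:
    aln_len = spec.q_end - spec.q_start + 1
    matches = aln_len - spec.mismatches
    ident = 100.0 * matches / aln_len
    return AlignmentRecord(
        query_id=spec.query_id,
        subject_id=spec.subject_id,
        pct_identity=round(ident, 2),
        aln_length=aln_len,
        mismatches=spec.mismatches,
        gap_openings=spec.gap_openings,
        q_start=spec.q_start,
        q_end=spec.q_end,
        s_start=spec.s_start,
        s_end=spec.s_end,
        e_value=0.0,
        bit_score=idealized_bits(matches, spec.mismatches, spec.gap_openings),
    )


def corrupt_assembly(
    reference: Sequence[ReferenceTranscript],
    loci: Sequence[GeneLocus],
    chrom_seqs: Mapping[str, str],
    error_plan: ErrorPlan,
    seed: int = 0,
    mismatch_rate: float = 0.0,
) -> Tuple[List[Unigene], TruthLabels]:
    """Build a corrupted assembly realizing the error plan exactly.

    Genes without a directive become one perfect unigene.  Fragmentation
    directives split the gene so the reference projections realize the
    intended gap/overlap; chimera directives concatenate segments of two
    non-adjacent genes; co-assembly directives emit the true genomic
    stretch spanning two adjacent genes (so one contiguous genome window
    explains the whole unigene); duplicate directives copy a gene that
    also aligns perfectly to its planned partner; the T2 overlap cases
    record their two-locus query geometry.  ``mismatch_rate`` sprinkles
    substitutions over non-corrupted unigenes (counted in the emitted
    alignment records).
    """
    rng = np.random.default_rng(seed)
    by_id = {t.gene_id: t for t in reference}
    loc = {l.gene_id: l for l in loci}
    k = error_plan.k
    targeted = {}
    for d in error_plan.directives:
        if d.genes[0] in targeted:
            raise ValueError(f"gene {d.genes[0]} targeted twice")
        targeted[d.genes[0]] = d
        if d.kind == "chimera":
            a, b = (loc[g] for g in d.genes)
            if adjacent(a, b):
                raise ValueError(
                    f"chimera directive names adjacent genes {d.genes}"
                )
    secondary = {
        g
        for d in error_plan.directives
        if d.kind
        in ("chimera", "co_assembly", "duplicate", "t2_case3", "t2_case4", "t2_case5")
        for g in d.genes[1:]
    }

    unigenes: List[Unigene] = []
    truth = TruthLabels()
    serial = 0

    def new_id() -> str:
        nonlocal serial
        serial += 1
        return f"u{serial:05d}"

    def emit(seq: str, genes: Tuple[str, ...]) -> str:
        uid = new_id()
        unigenes.append(Unigene(unigene_id=uid, sequence=seq))
        truth.source_genes[uid] = genes
        return uid

    def perfect_specs(uid: str, gene: str, mm: int = 0) -> None:
        L = by_id[gene].length
        truth.cdna_specs.append(
            _AlignmentSpec(uid, gene, 1, L, 1, L, mismatches=mm)
        )
        l = loc[gene]
        truth.genome_specs.append(
            _AlignmentSpec(
                uid, l.chrom, 1, L, l.start + 1, l.end, mismatches=mm,
                against_genome=True,
            )
        )

    for tr in reference:
        g = tr.gene_id
        if g in secondary and g not in targeted:
            continue  # consumed by a partner directive; no standalone unigene
        d = targeted.get(g)
        if d is None:
            seq = tr.sequence
            mm = 0
            if mismatch_rate > 0:
                mutated = _mutate(rng, seq, mismatch_rate)
                mm = sum(x != y for x, y in zip(seq, mutated))
                seq = mutated
            uid = emit(seq, (g,))
            perfect_specs(uid, g, mm)
            continue
        L = tr.length
        if d.kind == "t1_gap":
            gap = d.param("gap")
            a_end = (L - gap) // 2
            b_start = a_end + gap  # 0-based start of the second piece
            u1 = emit(tr.sequence[:a_end], (g,))
            u2 = emit(tr.sequence[b_start:], (g,))
            truth.cdna_specs.append(_AlignmentSpec(u1, g, 1, a_end, 1, a_end))
            truth.cdna_specs.append(
                _AlignmentSpec(u2, g, 1, L - b_start, b_start + 1, L)
            )
            truth.events.append(("T1_case1", (u1, u2), (g,)))
        elif d.kind == "t1_overlap":
            ov = d.param("overlap")
            mid = L // 2
            a_end = mid + ov  # piece 1 covers [0, mid+ov)
            u1 = emit(tr.sequence[:a_end], (g,))
            u2 = emit(tr.sequence[mid:], (g,))
            truth.cdna_specs.append(_AlignmentSpec(u1, g, 1, a_end, 1, a_end))
            truth.cdna_specs.append(
                _AlignmentSpec(u2, g, 1, L - mid, mid + 1, L)
            )
            kind = "T1_case2" if ov <= k - 1 else "T1_case3"
            truth.events.append((kind, (u1, u2), (g,)))
        elif d.kind == "chimera":
            partner = by_id[d.genes[1]]
            a_len = max(L // 2, 2 * k)
            b_len = max(partner.length // 2, 2 * k)
            seq = tr.sequence[:a_len] + partner.sequence[:b_len]
            uid = emit(seq, d.genes)
            truth.cdna_specs.append(_AlignmentSpec(uid, g, 1, a_len, 1, a_len))
            truth.cdna_specs.append(
                _AlignmentSpec(
                    uid, partner.gene_id, a_len + 1, a_len + b_len, 1, b_len
                )
            )
            la, lb = loc[g], loc[partner.gene_id]
            truth.genome_specs.append(
                _AlignmentSpec(
                    uid, la.chrom, 1, a_len, la.start + 1, la.start + a_len,
                    against_genome=True,
                )
            )
            truth.genome_specs.append(
                _AlignmentSpec(
                    uid, lb.chrom, a_len + 1, a_len + b_len,
                    lb.start + 1, lb.start + b_len, against_genome=True,
                )
            )
            truth.events.append(("T2_case1", (uid,), d.genes))
            truth.verdicts[uid] = "chimera"
        elif d.kind == "co_assembly":
            la, lb = loc[d.genes[0]], loc[d.genes[1]]
            if la.start > lb.start:
                la, lb = lb, la
            genomic = chrom_seqs[la.chrom][la.start : lb.end]
            uid = emit(genomic, d.genes)
            len_a = la.end - la.start
            len_b = lb.end - lb.start
            b_off = lb.start - la.start
            truth.cdna_specs.append(
                _AlignmentSpec(uid, la.gene_id, 1, len_a, 1, len_a)
            )
            truth.cdna_specs.append(
                _AlignmentSpec(
                    uid, lb.gene_id, b_off + 1, b_off + len_b, 1, len_b
                )
            )
            truth.genome_specs.append(
                _AlignmentSpec(
                    uid, la.chrom, 1, len(genomic), la.start + 1, lb.end,
                    against_genome=True,
                )
            )
            # adjacent pair: excluded from Type II by design, so no event
            truth.verdicts[uid] = "co_assembly"
        elif d.kind == "duplicate":
            partner = by_id[d.genes[1]]
            uid = emit(tr.sequence, d.genes)
            truth.cdna_specs.append(_AlignmentSpec(uid, g, 1, L, 1, L))
            truth.cdna_specs.append(
                _AlignmentSpec(uid, partner.gene_id, 1, L, 1, L)
            )
            la, lb = loc[g], loc[partner.gene_id]
            truth.genome_specs.append(
                _AlignmentSpec(
                    uid, la.chrom, 1, L, la.start + 1, la.start + L,
                    against_genome=True,
                )
            )
            truth.genome_specs.append(
                _AlignmentSpec(
                    uid, lb.chrom, 1, L, lb.start + 1, lb.start + L,
                    against_genome=True,
                )
            )
            truth.events.append(("T2_case2", (uid,), d.genes))
            truth.verdicts[uid] = "ambiguous_duplicate"
        elif d.kind in ("t2_case3", "t2_case4", "t2_case5"):
            partner = d.genes[1]
            uid = emit(tr.sequence, d.genes)
            truth.cdna_specs.append(_AlignmentSpec(uid, g, 1, L, 1, L))
            if d.kind == "t2_case3":
                # proper sub-segment of the query aligns to the partner
                seg = min(L // 2, by_id[partner].length)
                s, e = L // 4 + 1, L // 4 + seg
                truth.cdna_specs.append(
                    _AlignmentSpec(uid, partner, s, e, 1, seg)
                )
            elif d.kind == "t2_case4":
                # overlap > 80% of the unigene, no containment: shift the
                # primary segment off full length
                truth.cdna_specs[-1] = _AlignmentSpec(
                    uid, g, 1, (9 * L) // 10, 1, (9 * L) // 10
                )
                s = L // 20 + 1
                truth.cdna_specs.append(
                    _AlignmentSpec(uid, partner, s, L, 1, L - s + 1)
                )
            else:  # t2_case5: overlap in (jitter, 80%]
                truth.cdna_specs[-1] = _AlignmentSpec(
                    uid, g, 1, L // 2, 1, L // 2
                )
                s = (3 * L) // 10 + 1
                truth.cdna_specs.append(
                    _AlignmentSpec(uid, partner, s, L, 1, L - s + 1)
                )
            truth.events.append(
                (f"T2_case{d.kind[-1]}", (uid,), d.genes)
            )
        else:
            raise ValueError(f"unknown directive kind {d.kind!r}")
    return unigenes, truth


def derive_truth_alignments(
    truth: TruthLabels,
) -> Tuple[List[AlignmentRecord], List[AlignmentRecord]]:
    """Materialize the recorded geometry as BLAST-style records.

    Returns ``(cdna_hits, genome_hits)``.  Bit scores use the idealized
    2/-2/-5 scoring; percent identity derives from recorded mismatches.
    """
    cdna = [_spec_to_cdna_record(s) for s in truth.cdna_specs]
    genome = [_spec_to_cdna_record(s) for s in truth.genome_specs]
    return cdna, genome


def distribute_fragments(
    gene_counts: Mapping[str, int],
    truth: TruthLabels,
    seed: int = 0,
) -> Dict[str, int]:
    """Split per-gene fragment counts across the gene's unigenes.

    Multi-piece genes split multinomially; unigenes sourced from two
    genes (chimeras, co-assemblies, duplicates) take their first source
    gene's count.  Output is a per-unigene fragment-count table.
    """
    rng = np.random.default_rng(seed)
    pieces: Dict[str, List[str]] = {}
    for uid, genes in truth.source_genes.items():
        pieces.setdefault(genes[0], []).append(uid)
    counts: Dict[str, int] = {}
    for gene, uids in sorted(pieces.items()):
        total = gene_counts.get(gene, 0)
        uids = sorted(uids)
        if len(uids) == 1:
            counts[uids[0]] = total
        else:
            split = rng.multinomial(total, [1.0 / len(uids)] * len(uids))
            for uid, c in zip(uids, split):
                counts[uid] = int(c)
    return counts


def subsample_reads(
    pair_bases: Sequence[int], target_bases: int, seed: int = 0
) -> List[int]:
    """Subsample read pairs without replacement until the cumulative
    base count reaches the target.

    ``pair_bases`` gives total bases per pair (both mates); pairs are
    kept or dropped atomically, the last accepted pair may overshoot,
    and the returned indices are sorted.  A target at or above the
    total keeps everything.
    """
    if target_bases <= 0:
        raise ValueError("target_bases must be positive")
    total = int(np.sum(pair_bases))
    if target_bases >= total:
        return list(range(len(pair_bases)))
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(pair_bases))
    kept: List[int] = []
    acc = 0
    for idx in order:
        kept.append(int(idx))
        acc += int(pair_bases[idx])
        if acc >= target_bases:
            break
    return sorted(kept)


def subsample_fastq(
    r1_path: str,
    r2_path: str,
    out_r1: str,
    out_r2: str,
    target_bases: int,
    seed: int = 0,
) -> int:
    """Subsample a FASTQ pair to ~``target_bases``; returns pairs kept."""
    from Bio import SeqIO

    r1 = list(SeqIO.parse(r1_path, "fastq"))
    r2 = list(SeqIO.parse(r2_path, "fastq"))
    if len(r1) != len(r2):
        raise ValueError("paired FASTQ files differ in read count")
    bases = [len(a.seq) + len(b.seq) for a, b in zip(r1, r2)]
    kept = subsample_reads(bases, target_bases, seed=seed)
    SeqIO.write((r1[i] for i in kept), out_r1, "fastq")
    SeqIO.write((r2[i] for i in kept), out_r2, "fastq")
    return len(kept)
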