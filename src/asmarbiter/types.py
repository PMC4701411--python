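"""Core domain types shared by every evaluator module.

Coordinate conventions: alignment records carry 1-based inclusive
coordinates as emitted by BLAST-style tabular output.  All internal
interval arithmetic converts to 0-based half-open via the ``*_interval``
helpers, which removes every off-by-one from overlap/gap computations.
A subject interval with ``s_start > s_end`` encodes a minus-strand hit
and is canonicalized downstream (see ``reference_metrics``), never at
parse time, so raw records round-trip.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Optional, Tuple

__all__ = [
    "ReferenceTranscript",
    "Unigene",
    "AlignmentRecord",
    "FragmentCountTable",
    "GeneLocus",
    "LocusAssignment",
    "CoverageRecord",
    "ErrorRates",
    "ErrorEvent",
    "ChimeraVerdict",
    "ErrorReport",
    "QualityDepthRecord",
    "GenePair",
    "UCOSummary",
    "LengthStats",
    "TitrationCurve",
    "ChecklistReport",
    "adjacent",
]


def _count_n(sequence: str) -> int:
    return sequence.upper().count("N")


@dataclass(frozen=True)
class ReferenceTranscript:
    """One reference cDNA (e.g. a representative gene model)."""

    gene_id: str
    sequence: str

    def __post_init__(self) -> None:
        if len(self.sequence) == 0:
            raise ValueError(f"reference transcript {self.gene_id!r} is empty")

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class Unigene:
    """One assembled sequence (singleton, contig or scaffold)."""

    unigene_id: str
    sequence: str

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def n_count(self) -> int:
        """Number of ambiguous (N) bases."""
        return _count_n(self.sequence)


@dataclass(frozen=True)
class AlignmentRecord:
    """One local alignment in the 12-column BLAST tabular dialect."""

    query_id: str
    subject_id: str
    pct_identity: float
    aln_length: int
    mismatches: int
    gap_openings: int
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    e_value: float
    bit_score: float
    strand: str = "+"

    def __post_init__(self) -> None:
        if not (1 <= self.q_start <= self.q_end):
            raise ValueError(
                f"bad query coordinates {self.q_start}..{self.q_end} "
                f"for {self.query_id!r}"
            )
        if not (0.0 <= self.pct_identity <= 100.0):
            raise ValueError(f"pct_identity {self.pct_identity} out of [0, 100]")
        if self.aln_length < self.mismatches:
            raise ValueError("aln_length < mismatches")
        if self.bit_score < 0:
            raise ValueError("negative bit score")

    @property
    def is_minus(self) -> bool:
        return self.s_start > self.s_end or self.strand == "-"

    def q_interval(self) -> Tuple[int, int]:
        """Query span as a 0-based half-open interval."""
        return self.q_start - 1, self.q_end

    def s_interval(self) -> Tuple[int, int]:
        """Subject span as a 0-based half-open interval, strand-agnostic."""
        lo, hi = sorted((self.s_start, self.s_end))
        return lo - 1, hi

    def canonicalized(self) -> "AlignmentRecord":
        """Return a copy with ``s_start <= s_end`` and the strand flagged."""
        if self.s_start > self.s_end:
            return replace(self, s_start=self.s_end, s_end=self.s_start, strand="-")
        return self


#: unigene_id -> number of sequenced fragments (a read pair counts once,
#: an orphan read counts once) mapped to that unigene.
FragmentCountTable = Dict[str, int]


@dataclass(frozen=True)
class GeneLocus:
    """A gene's genomic placement plus its rank along the chromosome."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    order_index: int

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"locus {self.gene_id!r}: start {self.start} >= end {self.end}"
            )


def adjacent(a: GeneLocus, b: GeneLocus) -> bool:
    """True when two loci are immediate neighbours on the same chromosome."""
    return a.chrom == b.chrom and abs(a.order_index - b.order_index) == 1


@dataclass(frozen=True)
class LocusAssignment:
    """A unigene's best reference locus (optionally the runner-up too)."""

    unigene_id: str
    gene_id: str
    best_alignment: AlignmentRecord
    runner_up_gene: Optional[str] = None


@dataclass(frozen=True)
class CoverageRecord:
    """Cumulative breadth of reference coverage for one gene."""

    gene_id: str
    breadth_pct: float
    n_unigenes: int

    @property
    def status(self) -> str:
        return "no_hit" if self.n_unigenes == 0 else "covered"


@dataclass(frozen=True)
class ErrorRates:
    mismatch_rate: float
    gap_opening_rate: float
    aligned_bases: int


@dataclass(frozen=True)
class ErrorEvent:
    """One classified assembly failure.

    Type I (fragmentation) events reference one gene and two unigenes;
    Type II (ambiguity) events reference one unigene and two genes.
    """

    kind: str  # T1_case1..3, T2_case1..5
    unigene_ids: Tuple[str, ...]
    gene_ids: Tuple[str, ...]
    evidence: str = ""
    adjacency_known: bool = True

    _T1 = frozenset({"T1_case1", "T1_case2", "T1_case3"})
    _T2 = frozenset({"T2_case1", "T2_case2", "T2_case3", "T2_case4", "T2_case5"})

    def __post_init__(self) -> None:
        if self.kind in self._T1:
            if len(self.gene_ids) != 1 or len(self.unigene_ids) != 2:
                raise ValueError(f"{self.kind} must link 2 unigenes to 1 gene")
        elif self.kind in self._T2:
            if len(self.unigene_ids) != 1 or len(self.gene_ids) != 2:
                raise ValueError(f"{self.kind} must link 1 unigene to 2 genes")
        else:
            raise ValueError(f"unknown error kind {self.kind!r}")

    @property
    def is_type2(self) -> bool:
        return self.kind in self._T2


CHIMERA_VERDICTS = (
    "co_assembly",
    "ambiguous_duplicate",
    "trans_spliced_candidate",
    "chimera",
    "unresolved",
)


@dataclass(frozen=True)
class ChimeraVerdict:
    unigene_id: str
    verdict: str
    supporting_alignments: int = 0

    def __post_init__(self) -> None:
        if self.verdict not in CHIMERA_VERDICTS:
            raise ValueError(f"unknown verdict {self.verdict!r}")


@dataclass(frozen=True)
class ErrorReport:
    counts: Dict[str, int]
    type2_rate: float
    no_hit_genes: int


@dataclass(frozen=True)
class QualityDepthRecord:
    """Per-gene quality (BS) and depth (SFB); the quality-depth plot unit.

    ``best_unigene is None`` marks a gene with no alignment; its BS is
    reported as 0.0 so thresholding and plotting need no special case.
    """

    gene_id: str
    bs: float
    sfb: float
    best_unigene: Optional[str] = None


@dataclass(frozen=True)
class GenePair:
    """An unordered reciprocal-best-hit paralog pair."""

    gene_a: str
    gene_b: str
    ks: Optional[float]
    expression_class: str  # both_expressed | one_expressed | neither
    assembly_class: str  # both_high | one_high | both_present_low | one_missing | both_missing

    def __post_init__(self) -> None:
        if self.gene_a > self.gene_b:
            raise ValueError("pair must be ordered (gene_a <= gene_b)")


@dataclass(frozen=True)
class UCOSummary:
    n_listed: int
    frac_bs_high: float
    frac_cov90: float
    frac_cov99: float


@dataclass(frozen=True)
class LengthStats:
    n_sequences: int
    median_length: float
    max_length: int
    n50_length: int
    n50_mbp: float
    n_content: int


@dataclass(frozen=True)
class TitrationCurve:
    """Unique-unigene detection as reads are sampled without replacement."""

    sample_points: Tuple[Tuple[int, int], ...]
    endpoint: Tuple[int, int]


@dataclass(frozen=True)
class ChecklistReport:
    """The four-point reference-free superior-assembly checklist."""

    mappable_pct: float
    unigene_ratio: float
    n50_length: int
    uco: UCOSummary
    pass_mappable: bool = field(default=False)
    pass_unigene_ratio: bool = field(default=False)
    pass_n50: bool = field(default=False)
    pass_uco: bool = field(default=False)

    @property
    def verdict(self) -> bool:
        return (
            self.pass_mappable
            and self.pass_unigene_ratio
            and self.pass_n50
            and self.pass_uco
        )
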