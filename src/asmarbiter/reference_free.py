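"""Metrics computable without any reference genome.

Length statistics (N50 by the cumulative-from-longest convention),
minimum-length sweeps, the mappable-read fraction, read-titration
(gene accumulation) curves with their exact hypergeometric expectation,
log-scale count correlations, and the composite four-point
superior-assembly checklist: a high mappable-read proportion, a unigene
count moderately above the expected transcript number, an adequate N50,
and strong conserved-ortholog recovery.
"""

from __future__ import annotations

import warnings
from typing import List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln

from .config import EvalConfig
from .types import ChecklistReport, LengthStats, TitrationCurve, UCOSummary

__all__ = [
    "length_stats",
    "n50",
    "n50_cutoff_sweep",
    "mappable_fraction",
    "titration_curve",
    "expected_titration_curve",
    "log_count_correlation",
    "superior_checklist",
]


def n50(lengths: Sequence[int]) -> int:
    """N50: the length at which the descending cumulative sum first
    reaches half the total assembled bases."""
    if not lengths:
        raise ValueError("no sequences")
    arr = np.sort(np.asarray(lengths, dtype=np.int64))[::-1]
    half = arr.sum() / 2.0
    csum = np.cumsum(arr)
    return int(arr[np.searchsorted(csum, half)])


def length_stats(
    lengths: Sequence[int],
    n_counts: Optional[Sequence[int]] = None,
    min_len: int = 100,
) -> LengthStats:
    """Assembly length statistics after removing sequences < min_len.

    ``n_counts`` (per-sequence ambiguous-base counts, aligned with
    ``lengths``) feeds the N-content total; sequences removed by the
    length filter drop their N contribution too.
    """
    lengths = list(lengths)
    if any(l < 0 for l in lengths):
        raise ValueError("negative length")
    if n_counts is None:
        n_counts = [0] * len(lengths)
    if len(n_counts) != len(lengths):
        raise ValueError("n_counts must align with lengths")
    kept = [(l, nc) for l, nc in zip(lengths, n_counts) if l >= min_len]
    if not kept:
        raise ValueError(f"no sequences of length >= {min_len}")
    kl = [l for l, _ in kept]
    return LengthStats(
        n_sequences=len(kl),
        median_length=float(np.median(kl)),
        max_length=int(max(kl)),
        n50_length=n50(kl),
        n50_mbp=sum(kl) / 1e6,
        n_content=sum(nc for _, nc in kept),
    )


def n50_cutoff_sweep(
    lengths: Sequence[int],
    cutoffs: Sequence[int] = (100, 200, 300, 400, 500, 600),
) -> pd.DataFrame:
    """N50 and assembly span (Mbp) at each minimum-length cutoff."""
    rows = []
    for cutoff in cutoffs:
        kept = [l for l in lengths if l >= cutoff]
        rows.append(
            {
                "cutoff": cutoff,
                "n_sequences": len(kept),
                "n50_length": n50(kept) if kept else 0,
                "mbp": sum(kept) / 1e6,
            }
        )
    return pd.DataFrame(rows)


def mappable_fraction(mapped_reads: int, total_reads: int) -> float:
    """Percent of reads mapping to the assembly.

    ``mapped > total`` warns rather than fails, because denominator
    conventions differ (e.g. total raw reads vs reads mapping to a
    reference cDNA set); the caller's convention belongs in output
    metadata.
    """
    if total_reads <= 0:
        raise ValueError("total_reads must be positive")
    if mapped_reads < 0:
        raise ValueError("mapped_reads must be non-negative")
    if mapped_reads > total_reads:
        warnings.warn(
            f"mapped ({mapped_reads}) exceeds total ({total_reads}); "
            "check denominator convention",
            stacklevel=2,
        )
    return 100.0 * mapped_reads / total_reads


def titration_curve(
    counts: Mapping[str, int], step: int = 1000, seed: int = 0
) -> TitrationCurve:
    """One stochastic gene-accumulation curve.

    Reads (mapped fragments) are sampled without replacement in a
    random order; the number of distinct unigenes seen so far is
    recorded every ``step`` reads plus at the endpoint (all reads, all
    unigenes with >= 1 read).  Deterministic for a given seed.
    """
    ids = sorted(k for k, v in counts.items() if v > 0)
    if any(v < 0 for v in counts.values()):
        raise ValueError("negative count")
    total = sum(counts[k] for k in ids)
    if total == 0:
        raise ValueError("no mapped reads")
    labels = np.repeat(np.arange(len(ids)), [counts[k] for k in ids])
    rng = np.random.default_rng(seed)
    perm = rng.permutation(labels)
    # first position at which each unigene appears
    first = np.full(len(ids), total, dtype=np.int64)
    vals, first_pos = np.unique(perm, return_index=True)
    first[vals] = first_pos
    first_sorted = np.sort(first)
    points = []
    m = step
    while m < total:
        points.append((m, int(np.searchsorted(first_sorted, m, side="left"))))
        m += step
    endpoint = (total, len(ids))
    points.append(endpoint)
    return TitrationCurve(sample_points=tuple(points), endpoint=endpoint)


def expected_titration_curve(
    counts: Mapping[str, int], sample_sizes: Sequence[int]
) -> List[float]:
    """Exact E[unique unigenes] after sampling m reads without replacement.

    E[U(m)] = sum_i (1 - C(T - c_i, m) / C(T, m)) with T the total read
    count and c_i the per-unigene count; the binomial ratio is computed
    in log space for stability.
    """
    cs = np.array([v for v in counts.values() if v > 0], dtype=np.int64)
    total = int(cs.sum())
    out: List[float] = []
    for m in sample_sizes:
        if m > total:
            raise ValueError(f"sample size {m} exceeds total reads {total}")
        if m == 0:
            out.append(0.0)
            continue
        rem = total - cs  # reads not from unigene i
        with np.errstate(divide="ignore"):
            log_miss = np.where(
                rem >= m,
                gammaln(rem + 1)
                - gammaln(np.maximum(rem - m, 0) + 1)
                - (gammaln(total + 1) - gammaln(total - m + 1)),
                -np.inf,
            )
        out.append(float(np.sum(1.0 - np.exp(log_miss))))
    return out


def log_count_correlation(
    counts_a: Mapping[str, int], counts_b: Mapping[str, int]
) -> Tuple[float, float]:
    """(Spearman rho, Pearson r) on log2(count + 1) over the shared
    gene universe; genes absent from one table are imputed as 0."""
    genes = sorted(set(counts_a) | set(counts_b))
    if len(genes) < 3:
        raise ValueError("need at least 3 genes to correlate")
    a = np.log2(np.array([counts_a.get(g, 0) for g in genes], dtype=float) + 1.0)
    b = np.log2(np.array([counts_b.get(g, 0) for g in genes], dtype=float) + 1.0)
    rho = stats.spearmanr(a, b).statistic
    r = stats.pearsonr(a, b).statistic
    return float(rho), float(r)


def superior_checklist(
    mappable_pct: float,
    n_unigenes: int,
    n50_length: int,
    uco: UCOSummary,
    expected_transcripts: int,
    cfg: EvalConfig,
) -> ChecklistReport:
    """Apply the four-point reference-free superior-assembly checklist.

    Pass conditions: mappable reads above ~65%, unigene count at least
    ~150% of the expected transcript number, N50 above the expected
    value (default 1200 bp), and conserved-ortholog recovery (fraction
    covered >90%) above the configured floor.
    """
    if expected_transcripts <= 0:
        raise ValueError("expected_transcripts must be positive")
    ratio = n_unigenes / expected_transcripts
    return ChecklistReport(
        mappable_pct=mappable_pct,
        unigene_ratio=ratio,
        n50_length=n50_length,
        uco=uco,
        pass_mappable=mappable_pct > cfg.checklist_mappable_min_pct,
        pass_unigene_ratio=ratio >= cfg.checklist_unigene_ratio_min,
        pass_n50=n50_length >= cfg.checklist_n50_min,
        pass_uco=uco.frac_cov90 >= cfg.checklist_uco_cov90_min,
    )
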