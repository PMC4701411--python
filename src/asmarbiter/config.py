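"""Evaluation configuration.

One dataclass holds every tunable threshold so CLI commands, library
calls and YAML config files agree on defaults.  Defaults follow the
standard working values for short-read de Bruijn assemblies of plant
transcriptomes: k=31 assemblies, a normalized-bit-score quality cut of
1.5 (75% length, error-free), an expression floor of 0.1 sequenced
fragments per base pair, 99% identity / 80% overlap for ambiguity
classification and 90% identity / 1e-10 e-value for genome-alignment
chimera adjudication.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path
from typing import Union

import yaml

__all__ = ["EvalConfig"]


@dataclass
class EvalConfig:
    #: assembly k-mer size; fragmentation with overlap <= k-1 is Case II,
    #: > k-1 is Case III
    k: int = 31
    #: normalized bit score above which a unigene counts as long+accurate
    bs_threshold: float = 1.5
    #: sequenced fragments/bp above which a gene counts as expressed
    sfb_threshold: float = 0.1
    #: minimum percent identity for Type II (ambiguity) classification
    type2_identity_min: float = 99.0
    #: query-overlap fraction splitting Type II Case IV from Case V
    type2_overlap_frac: float = 0.80
    #: max query-segment overlap (bp) still counting as "disjoint" (Case I)
    type2_case1_max_overlap: int = 10
    #: endpoint jitter (bp) tolerated when calling segments "identical" (Case II)
    type2_case2_end_jitter: int = 10
    #: identity / e-value filters for genome-alignment chimera adjudication
    chimera_identity_min: float = 90.0
    chimera_evalue_max: float = 1e-10
    #: intron-scale gap (bp) merged into one genomic window
    chimera_merge_gap: int = 10_000
    #: fraction of the unigene a genomic window must cover to explain it
    chimera_query_cov: float = 0.90
    #: unigenes shorter than this are dropped before length statistics
    min_unigene_length: int = 100
    #: titration curve sampling interval, in reads
    titration_step: int = 1000
    #: Ks ceiling defining closely-related (CRG) pairs
    crg_ks_max: float = 0.2
    #: cap on the CRG subset (the lowest-Ks expressed pairs)
    crg_max_pairs: int = 300
    #: reference-free checklist thresholds
    checklist_mappable_min_pct: float = 65.0
    checklist_unigene_ratio_min: float = 1.5
    checklist_n50_min: int = 1200
    checklist_uco_cov90_min: float = 0.70
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ValueError(f"k must be >= 2, got {self.k}")
        for name in ("bs_threshold", "sfb_threshold", "crg_ks_max"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("type2_identity_min", "chimera_identity_min"):
            v = getattr(self, name)
            if not 0 <= v <= 100:
                raise ValueError(f"{name} {v} out of [0, 100]")
        for name in ("type2_overlap_frac", "chimera_query_cov"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} {v} out of (0, 1]")
        if self.chimera_evalue_max < 0:
            raise ValueError("chimera_evalue_max must be >= 0")
        if self.min_unigene_length < 0 or self.titration_step < 1:
            raise ValueError("bad length/step threshold")

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "EvalConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: Union[str, Path]) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)
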