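"""Readers and writers for every external format the toolkit touches.

FASTA goes through Biopython; tabular formats (12-column BLAST-style
alignment TSV, 2-column fragment-count TSV, BED-like/GFF3 gene tables)
are parsed line by line so malformed rows fail with a line number.
Report writing is pandas-backed and round-trips losslessly in both TSV
and JSON.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path
from typing import Dict, List, Type, Union

import pandas as pd
from Bio import SeqIO

from .types import AlignmentRecord, GeneLocus, ReferenceTranscript, Unigene

__all__ = [
    "read_fasta",
    "read_reference",
    "read_unigenes",
    "read_alignment_table",
    "write_alignment_table",
    "read_counts_table",
    "write_counts_table",
    "read_gene_annotation",
    "read_gene_list",
    "read_ks_table",
    "write_reports",
    "read_report",
]

PathLike = Union[str, Path]

_BLAST6_COLUMNS = (
    "query_id",
    "subject_id",
    "pct_identity",
    "aln_length",
    "mismatches",
    "gap_openings",
    "q_start",
    "q_end",
    "s_start",
    "s_end",
    "e_value",
    "bit_score",
)


def read_fasta(path: PathLike, kind: str = "unigene"):
    """Read a FASTA file into domain records.

    The identifier is the first whitespace-delimited token of the header
    (the same convention every reader in the package uses).  ``kind``
    selects :class:`Unigene` (default) or :class:`ReferenceTranscript`.
    Duplicate identifiers raise; an empty file warns and returns [].
    """
    cls: Type
    if kind == "unigene":
        cls = Unigene
    elif kind == "reference":
        cls = ReferenceTranscript
    else:
        raise ValueError(f"kind must be 'unigene' or 'reference', got {kind!r}")
    records = []
    seen = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        ident = rec.id  # Biopython already takes the first token
        if ident in seen:
            raise ValueError(f"duplicate identifier {ident!r} in {path}")
        seen.add(ident)
        if kind == "unigene":
            records.append(cls(unigene_id=ident, sequence=str(rec.seq)))
        else:
            records.append(cls(gene_id=ident, sequence=str(rec.seq)))
    if not records:
        warnings.warn(f"no FASTA records in {path}", stacklevel=2)
    return records


def read_reference(path: PathLike) -> List[ReferenceTranscript]:
    return read_fasta(path, kind="reference")


def read_unigenes(path: PathLike) -> List[Unigene]:
    return read_fasta(path, kind="unigene")


def read_alignment_table(path: PathLike) -> List[AlignmentRecord]:
    """Parse a 12-column BLAST-outfmt-6-style TSV.

    '#'-prefixed comment lines and blank lines are skipped.  Minus-strand
    subject coordinates (s_start > s_end) pass through unchanged; strand
    is resolved downstream so raw tables round-trip.
    """
    records: List[AlignmentRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 12:
                raise ValueError(
                    f"{path}:{lineno}: expected 12 tab-separated columns, "
                    f"got {len(fields)}"
                )
            try:
                records.append(
                    AlignmentRecord(
                        query_id=fields[0],
                        subject_id=fields[1],
                        pct_identity=float(fields[2]),
                        aln_length=int(fields[3]),
                        mismatches=int(fields[4]),
                        gap_openings=int(fields[5]),
                        q_start=int(fields[6]),
                        q_end=int(fields[7]),
                        s_start=int(fields[8]),
                        s_end=int(fields[9]),
                        e_value=float(fields[10]),
                        bit_score=float(fields[11]),
                    )
                )
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
    return records


def write_alignment_table(records, path: PathLike) -> None:
    with open(path, "w") as fh:
        for r in records:
            fh.write(
                "\t".join(
                    str(v)
                    for v in (
                        r.query_id,
                        r.subject_id,
                        f"{r.pct_identity:.2f}",
                        r.aln_length,
                        r.mismatches,
                        r.gap_openings,
                        r.q_start,
                        r.q_end,
                        r.s_start,
                        r.s_end,
                        f"{r.e_value:.3g}",
                        f"{r.bit_score:.1f}",
                    )
                )
                + "\n"
            )


def read_counts_table(path: PathLike) -> Dict[str, int]:
    """Read a 2-column (unigene_id, fragment_count) TSV.

    Repeated identifiers are summed; counts must be non-negative
    integers (fractional multi-mapping weights are rejected because the
    mapped unit is one best alignment per fragment).
    """
    counts: Dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise ValueError(
                    f"{path}:{lineno}: expected 2 columns, got {len(fields)}"
                )
            ident, raw = fields
            try:
                value = int(raw)
            except ValueError as exc:
                raise ValueError(
                    f"{path}:{lineno}: fragment count {raw!r} is not an integer"
                ) from exc
            if value < 0:
                raise ValueError(f"{path}:{lineno}: negative count {value}")
            counts[ident] = counts.get(ident, 0) + value
    return counts


def write_counts_table(counts: Dict[str, int], path: PathLike) -> None:
    with open(path, "w") as fh:
        for ident in sorted(counts):
            fh.write(f"{ident}\t{counts[ident]}\n")


def _order_loci(raw: List[dict]) -> List[GeneLocus]:
    seen = set()
    for row in raw:
        if row["gene_id"] in seen:
            raise ValueError(f"duplicate gene_id {row['gene_id']!r} in annotation")
        seen.add(row["gene_id"])
    loci: List[GeneLocus] = []
    by_chrom: Dict[str, List[dict]] = {}
    for row in raw:
        by_chrom.setdefault(row["chrom"], []).append(row)
    for chrom in sorted(by_chrom):
        for idx, row in enumerate(
            sorted(by_chrom[chrom], key=lambda r: (r["start"], r["gene_id"])),
            start=1,
        ):
            loci.append(GeneLocus(order_index=idx, **row))
    return loci


def read_gene_annotation(path: PathLike) -> List[GeneLocus]:
    """Read gene loci from a BED-like TSV or a GFF3 subset.

    BED-like rows are ``chrom  start  end  gene_id  strand`` (0-based
    half-open starts, the BED convention).  GFF3 ``gene`` feature lines
    are also accepted (1-based inclusive, converted).  ``order_index`` is
    assigned per chromosome by sorting on start, so gene adjacency
    (|Δorder_index| == 1 on one chromosome) is well defined.
    """
    raw: List[dict] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            try:
                if len(fields) == 5:  # BED-like
                    chrom, start, end, gene_id, strand = fields
                    raw.append(
                        dict(
                            gene_id=gene_id,
                            chrom=chrom,
                            start=int(start),
                            end=int(end),
                            strand=strand,
                        )
                    )
                elif len(fields) == 9:  # GFF3
                    if fields[2] != "gene":
                        continue
                    attrs = dict(
                        kv.split("=", 1)
                        for kv in fields[8].split(";")
                        if "=" in kv
                    )
                    gene_id = attrs.get("ID") or attrs.get("Name")
                    if gene_id is None:
                        raise ValueError("gene line lacks ID attribute")
                    raw.append(
                        dict(
                            gene_id=gene_id,
                            chrom=fields[0],
                            start=int(fields[3]) - 1,
                            end=int(fields[4]),
                            strand=fields[6],
                        )
                    )
                else:
                    raise ValueError(
                        f"expected 5 (BED-like) or 9 (GFF3) columns, got {len(fields)}"
                    )
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
    return _order_loci(raw)


def read_gene_list(path: PathLike) -> List[str]:
    """Plain-text gene list, one identifier per line."""
    with open(path) as fh:
        return [ln.strip() for ln in fh if ln.strip() and not ln.startswith("#")]


def read_ks_table(path: PathLike) -> Dict[frozenset, float]:
    """3-column TSV (gene_a, gene_b, Ks) of precomputed Ks values."""
    table: Dict[frozenset, float] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 3:
                raise ValueError(
                    f"{path}:{lineno}: expected 3 columns, got {len(fields)}"
                )
            try:
                ks = float(fields[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: bad Ks {fields[2]!r}") from exc
            table[frozenset((fields[0], fields[1]))] = ks
    return table


def write_reports(
    results: Dict[str, pd.DataFrame], out_dir: PathLike, format: str = "tsv"
) -> List[Path]:
    """Write one file per report section with deterministic field order.

    ``results`` maps section name -> DataFrame.  TSV and JSON carry
    identical numeric content and both round-trip via :func:`read_report`.
    """
    if format not in ("tsv", "json"):
        raise ValueError(f"format must be 'tsv' or 'json', got {format!r}")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    for name, frame in results.items():
        path = out / f"{name}.{format}"
        if format == "tsv":
            frame.to_csv(path, sep="\t", index=False)
        else:
            with open(path, "w") as fh:
                json.dump(
                    {
                        "columns": list(frame.columns),
                        "data": frame.to_dict(orient="records"),
                    },
                    fh,
                    indent=1,
                    default=str,
                )
        written.append(path)
    return written


def read_report(path: PathLike) -> pd.DataFrame:
    path = Path(path)
    if path.suffix == ".tsv":
        return pd.read_csv(path, sep="\t")
    if path.suffix == ".json":
        with open(path) as fh:
            payload = json.load(fh)
        return pd.DataFrame(payload["data"], columns=payload["columns"])
    raise ValueError(f"unknown report format {path.suffix!r}")
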