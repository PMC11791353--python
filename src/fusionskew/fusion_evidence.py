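"""Chimeric-transcript call tables: reading, evidence filtering, annotation.

Fusion callers emit one row per putative chimera with two kinds of read
support: junction reads (reads crossing the fusion splice junction) and
spanning fragments (pairs whose mates land on the two partners).  The
filtering rule used throughout this package keeps a call when either count
exceeds one — i.e. at least two non-duplicated supporting reads of one kind
— which in FFPE material trades little sensitivity for near-perfect
specificity.

Known/novel annotation matches the ordered (5', 3') gene pair against a
local catalog (ChimerSeq/Mitelman-style two-column table), optionally after
collapsing gene symbols into alias groups so that e.g. ARL17A and ARL17B
count as the same partner.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple

import pandas as pd

from .genemodel import GeneModel

__all__ = [
    "Breakpoint",
    "FusionRecord",
    "FusionAnnotation",
    "read_fusion_table",
    "write_fusion_table",
    "filter_by_evidence",
    "deduplicate",
    "annotate_known",
    "classify_biotype",
    "read_catalog",
    "read_alias_map",
]

MANDATORY_COLUMNS = [
    "FusionName",
    "JunctionReadCount",
    "SpanningFragCount",
    "LeftBreakpoint",
    "RightBreakpoint",
]


class Breakpoint(NamedTuple):
    """A caller-reported fusion end (1-based position, caller convention kept)."""

    chrom: str
    position: int
    strand: str

    def __str__(self) -> str:
        return f"{self.chrom}:{self.position}:{self.strand}"


def parse_breakpoint(text: str) -> Breakpoint:
    """Parse a ``chrom:pos:strand`` breakpoint string.

    The chromosome name is preserved verbatim (``chr2`` stays ``chr2``).
    """
    parts = str(text).split(":")
    if len(parts) != 3:
        raise ValueError(f"malformed breakpoint {text!r}: expected chrom:pos:strand")
    chrom, pos_text, strand = parts
    try:
        position = int(pos_text)
    except ValueError:
        raise ValueError(f"malformed breakpoint {text!r}: position {pos_text!r} is not an integer")
    if position < 1:
        raise ValueError(f"malformed breakpoint {text!r}: position must be >= 1")
    if strand not in {"+", "-"}:
        raise ValueError(f"malformed breakpoint {text!r}: strand must be + or -")
    return Breakpoint(chrom, position, strand)


@dataclass
class FusionRecord:
    """One chimeric-transcript call (caller-table row)."""

    fusion_name: str
    gene5: str
    gene3: str
    breakpoint5: Breakpoint
    breakpoint3: Breakpoint
    junction_read_count: int
    spanning_frag_count: int
    splice_type: str | None = None
    sample_id: str | None = None
    patient_id: str | None = None
    material: str | None = None
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.gene5 or not self.gene3:
            raise ValueError("both partner gene symbols must be non-empty")
        if self.junction_read_count < 0 or self.spanning_frag_count < 0:
            raise ValueError("evidence counts must be non-negative")

    @property
    def group_key(self) -> tuple[str, str]:
        """Ordered gene pair shared by all breakpoint variants of one fusion."""
        return (self.gene5, self.gene3)


@dataclass
class FusionAnnotation:
    """A fusion record plus its known/novel and biotype classification."""

    record: FusionRecord
    known: bool
    catalog_match: tuple[str, str] | None = None
    biotype_class: str | None = None  # coding / non_coding / unknown
    locus_class: str | None = None

    def __post_init__(self) -> None:
        if self.known != (self.catalog_match is not None):
            raise ValueError("known flag must mirror presence of a catalog match")


def _split_fusion_name(name: str) -> tuple[str, str]:
    if "--" not in name:
        raise ValueError(f"fusion name {name!r} lacks the 'GENE5--GENE3' separator")
    gene5, gene3 = name.split("--", 1)
    return gene5, gene3


def _strip_ensembl(symbol: str) -> str:
    # STAR-Fusion writes LeftGene as "SYMBOL^ENSG..."; keep the symbol
    return symbol.split("^", 1)[0]


def read_fusion_table(
    path: str | Path,
    sample_id: str | None = None,
    patient_id: str | None = None,
    material: str | None = None,
) -> list[FusionRecord]:
    """Read a STAR-Fusion-style TSV into fusion records.

    The header may start with ``#FusionName`` (the leading ``#`` is
    stripped).  Rows with unparseable mandatory fields are skipped with one
    summary warning; extra columns are carried along unmodified in
    ``record.extra``.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    df.columns = [c.lstrip("#") for c in df.columns]
    missing = set(MANDATORY_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"fusion table {path} missing mandatory column(s): {sorted(missing)}")
    extra_columns = [c for c in df.columns if c not in MANDATORY_COLUMNS]

    records: list[FusionRecord] = []
    skipped = 0
    for _, row in df.iterrows():
        try:
            gene5, gene3 = _split_fusion_name(row["FusionName"])
            record = FusionRecord(
                fusion_name=row["FusionName"],
                gene5=_strip_ensembl(gene5),
                gene3=_strip_ensembl(gene3),
                breakpoint5=parse_breakpoint(row["LeftBreakpoint"]),
                breakpoint3=parse_breakpoint(row["RightBreakpoint"]),
                junction_read_count=int(row["JunctionReadCount"]),
                spanning_frag_count=int(row["SpanningFragCount"]),
                splice_type=row.get("SpliceType"),
                sample_id=sample_id,
                patient_id=patient_id,
                material=material,
                extra={c: row[c] for c in extra_columns if c != "SpliceType"},
            )
        except (ValueError, TypeError):
            skipped += 1
            continue
        records.append(record)
    if skipped:
        warnings.warn(f"skipped {skipped} unparseable row(s) in {path}")
    return records


def write_fusion_table(records: Iterable[FusionRecord], path: str | Path) -> None:
    """Write records in the canonical abridged caller dialect (round-trips)."""
    rows = []
    for r in records:
        rows.append(
            {
                "#FusionName": r.fusion_name,
                "JunctionReadCount": r.junction_read_count,
                "SpanningFragCount": r.spanning_frag_count,
                "SpliceType": r.splice_type if r.splice_type is not None else "ONLY_REF_SPLICE",
                "LeftGene": r.gene5,
                "LeftBreakpoint": str(r.breakpoint5),
                "RightGene": r.gene3,
                "RightBreakpoint": str(r.breakpoint3),
                **r.extra,
            }
        )
    columns = [
        "#FusionName",
        "JunctionReadCount",
        "SpanningFragCount",
        "SpliceType",
        "LeftGene",
        "LeftBreakpoint",
        "RightGene",
        "RightBreakpoint",
    ]
    df = pd.DataFrame(rows, columns=columns if not rows else None)
    ordered = columns + [c for c in df.columns if c not in columns]
    df[ordered].to_csv(path, sep="\t", index=False)


def filter_by_evidence(
    records: Iterable[FusionRecord],
    min_junction: int = 2,
    min_spanning: int = 2,
    rule: str = "OR",
) -> list[FusionRecord]:
    """Keep calls with enough junction or spanning support; order preserved.

    The default (OR, 2, 2) keeps a record when JunctionReadCount > 1 or
    SpanningFragCount > 1, i.e. at least two supporting reads of one kind.
    """
    if rule not in {"OR", "AND"}:
        raise ValueError(f"rule must be OR or AND, got {rule!r}")
    if rule == "OR":
        return [
            r
            for r in records
            if r.junction_read_count >= min_junction or r.spanning_frag_count >= min_spanning
        ]
    return [
        r
        for r in records
        if r.junction_read_count >= min_junction and r.spanning_frag_count >= min_spanning
    ]


def deduplicate(records: Iterable[FusionRecord]) -> list[FusionRecord]:
    """Collapse exact duplicates, retaining breakpoint variants.

    Rows with identical (sample, ordered gene pair, both breakpoints) merge
    into one record with summed evidence counts.  Rows sharing the gene pair
    but differing in breakpoints stay separate — they are alternative
    variants of the same fusion and share ``group_key``.  First-seen order
    is preserved.
    """
    merged: dict[tuple, FusionRecord] = {}
    for record in records:
        key = (
            record.sample_id,
            record.gene5,
            record.gene3,
            record.breakpoint5,
            record.breakpoint3,
        )
        if key in merged:
            kept = merged[key]
            merged[key] = replace(
                kept,
                junction_read_count=kept.junction_read_count + record.junction_read_count,
                spanning_frag_count=kept.spanning_frag_count + record.spanning_frag_count,
            )
        else:
            merged[key] = record
    return list(merged.values())


def read_catalog(path: str | Path) -> set[tuple[str, str]]:
    """Read a known-fusion catalog TSV with columns ``gene5  gene3`` (+optional source)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"gene5", "gene3"} <= set(df.columns):
        raise ValueError("catalog requires columns gene5 and gene3")
    return {(row["gene5"], row["gene3"]) for _, row in df.iterrows()}


def read_alias_map(path: str | Path) -> dict[str, str]:
    """Read a symbol→group alias TSV with columns ``symbol  group``."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"symbol", "group"} <= set(df.columns):
        raise ValueError("alias map requires columns symbol and group")
    return dict(zip(df["symbol"], df["group"]))


def collapse_alias(symbol: str, alias_map: Mapping[str, str] | None) -> str:
    if alias_map is None:
        return symbol
    return alias_map.get(symbol, symbol)


def annotate_known(
    records: Iterable[FusionRecord],
    catalog: set[tuple[str, str]],
    alias_map: Mapping[str, str] | None = None,
) -> list[FusionAnnotation]:
    """Flag each record known iff its alias-collapsed ordered pair is in the catalog.

    Matching is orientation-sensitive (A--B is not B--A): the 5' and 3'
    roles are biologically distinct, since the druggable kinase moiety must
    sit 3' of the breakpoint to stay intact.
    """
    collapsed_catalog = {
        (collapse_alias(g5, alias_map), collapse_alias(g3, alias_map)): (g5, g3)
        for g5, g3 in catalog
    }
    annotations = []
    for record in records:
        key = (
            collapse_alias(record.gene5, alias_map),
            collapse_alias(record.gene3, alias_map),
        )
        match = collapsed_catalog.get(key)
        annotations.append(
            FusionAnnotation(record=record, known=match is not None, catalog_match=match)
        )
    return annotations


def classify_biotype(
    record: FusionRecord, gene_models: Mapping[str, GeneModel]
) -> str:
    """Label a fusion coding or non-coding from its partners' biotypes.

    Returns "coding" when at least one partner is protein-coding — a chimera
    carrying any protein-coding fragment can encode a (possibly truncated)
    protein product — and "non_coding" when neither is.  Partners absent
    from the gene models give "unknown" with a warning.  ``gene_models`` may
    be keyed by gene_id or symbol; symbols are resolved against both.
    """
    by_symbol = {m.symbol: m for m in gene_models.values()}

    def _lookup(symbol: str) -> GeneModel | None:
        return gene_models.get(symbol) or by_symbol.get(symbol)

    partners = [_lookup(record.gene5), _lookup(record.gene3)]
    if any(p is None for p in partners):
        missing = [
            s for s, p in zip((record.gene5, record.gene3), partners) if p is None
        ]
        warnings.warn(f"partner gene(s) {missing} not in gene models; biotype unknown")
        return "unknown"
    if any(p.biotype == "protein_coding" for p in partners):
        return "coding"
    return "non_coding"
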