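"""Union-exon gene models built from GTF annotation.

A gene is represented by the union of its transcripts' exons, merged where
they overlap, and ranked in transcriptional (5'→3') order: rank 1 is the
5'-most exon, which for a minus-strand gene is the exon with the largest
genomic coordinate.  This single per-gene exon ladder is the coordinate
system for all exon-coverage work downstream: "exon 20 of ALK" means rank 20
of the ALK union model.

Coordinates are 0-based half-open internally; GTF input (1-based inclusive)
is converted on read and back on write.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import gffutils

__all__ = [
    "Exon",
    "GeneModel",
    "merge_intervals",
    "parse_gtf",
    "write_exon_bed",
]

#: gene_biotype values collapsed to the coarse "non_coding" class
_NONCODING_BIOTYPES = {
    "lincRNA",
    "lncRNA",
    "miRNA",
    "snRNA",
    "snoRNA",
    "rRNA",
    "misc_RNA",
    "antisense",
    "antisense_RNA",
    "scaRNA",
    "sRNA",
    "ribozyme",
    "vault_RNA",
    "Mt_rRNA",
    "Mt_tRNA",
    "3prime_overlapping_ncRNA",
    "bidirectional_promoter_lncRNA",
    "macro_lncRNA",
    "non_coding",
    "processed_transcript",
    "sense_intronic",
    "sense_overlapping",
    "TEC",
}


def classify_raw_biotype(raw: str | None) -> str:
    """Collapse an annotation biotype into {protein_coding, non_coding, other}."""
    if raw is None:
        return "other"
    if raw == "protein_coding":
        return "protein_coding"
    if raw in _NONCODING_BIOTYPES or "pseudogene" in raw or raw.endswith("RNA"):
        return "non_coding"
    return "other"


@dataclass(frozen=True)
class Exon:
    """One union exon; ``rank`` counts from 1 at the 5' end of the gene."""

    chrom: str
    start: int  # 0-based
    end: int  # half-open
    rank: int

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"exon end must exceed start, got [{self.start}, {self.end})")
        if self.rank < 1:
            raise ValueError(f"exon rank must be >= 1, got {self.rank}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class GeneModel:
    """A gene's strand-aware union-exon structure."""

    gene_id: str
    symbol: str
    chrom: str
    strand: str
    biotype: str = "other"
    exons: list[Exon] = field(default_factory=list)
    cytoband: str | None = None

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @property
    def exon_lengths(self) -> list[int]:
        return [e.length for e in self.exons]

    @property
    def total_exonic_bases(self) -> int:
        return sum(e.length for e in self.exons)

    @property
    def span(self) -> tuple[int, int]:
        """Genomic (start, end) covered by the union model."""
        return (min(e.start for e in self.exons), max(e.end for e in self.exons))


def merge_intervals(intervals: Sequence[tuple[int, int]]) -> list[tuple[int, int]]:
    """Merge half-open intervals into a sorted, pairwise-disjoint cover.

    Abutting intervals ([0,10) and [10,20)) merge, because under the
    half-open convention they cover a contiguous base run.
    """
    for start, end in intervals:
        if start >= end:
            raise ValueError(f"invalid interval [{start}, {end}): start must be < end")
    if not intervals:
        return []
    merged: list[list[int]] = []
    for start, end in sorted(intervals):
        if merged and start <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], end)
        else:
            merged.append([start, end])
    return [(s, e) for s, e in merged]


def _rank_exons(chrom: str, strand: str, merged: list[tuple[int, int]]) -> list[Exon]:
    ordered = merged if strand == "+" else list(reversed(merged))
    return [Exon(chrom, s, e, rank=i + 1) for i, (s, e) in enumerate(ordered)]


def parse_gtf(path: str | Path, gene_ids: Iterable[str] | None = None) -> dict[str, GeneModel]:
    """Build union-exon gene models from an Ensembl-dialect GTF.

    Parameters
    ----------
    path
        GTF file with ``gene_id`` (and optionally ``gene_name``,
        ``gene_biotype``) attributes on exon features.
    gene_ids
        Optional restriction to a set of gene identifiers; gene symbols are
        accepted too.

    Returns
    -------
    dict mapping gene_id to :class:`GeneModel`.  Genes whose exons sit on
    multiple chromosomes or mixed strands, or with an unrecognized strand
    symbol, are rejected with a warning.  ``gene`` features without any exon
    are skipped with a warning.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )

    wanted = set(gene_ids) if gene_ids is not None else None

    meta: dict[str, dict] = {}
    exons_by_gene: dict[str, list[tuple[str, str, int, int]]] = {}
    declared_genes: set[str] = set()

    def _attr(feature, key) -> str | None:
        vals = feature.attributes.get(key)
        return vals[0] if vals else None

    for feature in db.all_features():
        gid = _attr(feature, "gene_id")
        if gid is None:
            continue
        symbol = _attr(feature, "gene_name") or gid
        if wanted is not None and gid not in wanted and symbol not in wanted:
            continue
        if feature.featuretype == "gene":
            declared_genes.add(gid)
        if gid not in meta:
            meta[gid] = {
                "symbol": symbol,
                "biotype": classify_raw_biotype(_attr(feature, "gene_biotype")),
            }
        if feature.featuretype != "exon":
            continue
        # GTF is 1-based inclusive; convert to 0-based half-open
        exons_by_gene.setdefault(gid, []).append(
            (feature.seqid, feature.strand, feature.start - 1, feature.end)
        )

    models: dict[str, GeneModel] = {}
    for gid in declared_genes - exons_by_gene.keys():
        warnings.warn(f"gene {gid} has no exon features; skipped")
    for gid, raw_exons in exons_by_gene.items():
        chroms = {chrom for chrom, _, _, _ in raw_exons}
        strands = {strand for _, strand, _, _ in raw_exons}
        if len(chroms) > 1:
            warnings.warn(f"gene {gid} has exons on multiple chromosomes {sorted(chroms)}; rejected")
            continue
        if len(strands) > 1:
            warnings.warn(f"gene {gid} has exons on mixed strands; rejected")
            continue
        strand = strands.pop()
        if strand not in {"+", "-"}:
            warnings.warn(f"gene {gid} has unknown strand {strand!r}; rejected")
            continue
        chrom = chroms.pop()
        merged = merge_intervals([(s, e) for _, _, s, e in raw_exons])
        models[gid] = GeneModel(
            gene_id=gid,
            symbol=meta[gid]["symbol"],
            chrom=chrom,
            strand=strand,
            biotype=meta[gid]["biotype"],
            exons=_rank_exons(chrom, strand, merged),
        )
    return models


def write_exon_bed(models: Iterable[GeneModel], path: str | Path) -> None:
    """Write union exons as BED6 (name = geneID|rank, score = 0)."""
    with open(path, "w") as handle:
        for model in models:
            for exon in model.exons:
                handle.write(
                    f"{exon.chrom}\t{exon.start}\t{exon.end}\t"
                    f"{model.gene_id}|{exon.rank}\t0\t{model.strand}\n"
                )
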