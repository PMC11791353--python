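"""Genomic-proximity classification of fusion partners.

A chimeric transcript whose two partners sit close together on the same
chromosome usually arises without a gross rearrangement: read-through
transcription into the downstream neighbour, a local duplication, or a
small deletion.  Partners on different chromosomes imply a translocation.
The classifier works from the caller-reported breakpoints alone:

* different chromosomes            -> ``translocation``
* same chromosome, |Δpos| <= D     -> ``local`` (with a mechanism hint)
* same chromosome, |Δpos| >  D     -> ``intrachromosomal_distal``

with D = 1 Mb by default — wide enough to cover same-cytoband partner
pairs, narrow enough to separate distant same-chromosome events.  For local
pairs on a shared strand whose 5' breakpoint lies upstream of the 3'
breakpoint in reading direction, the hint is ``read_through``; other local
geometries get ``duplication_or_deletion``.  The hint is heuristic: proof
of mechanism needs DNA-level evidence.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import pandas as pd

from .fusion_evidence import Breakpoint, FusionRecord, parse_breakpoint

__all__ = [
    "LocusCall",
    "parse_breakpoint",
    "classify_locus",
    "classify_table",
    "load_cytobands",
    "cytoband_of",
]

DEFAULT_MAX_LOCAL_DISTANCE = 1_000_000


@dataclass(frozen=True)
class LocusCall:
    """Proximity classification of one fusion record."""

    fusion_name: str
    same_chromosome: bool
    distance: int | None  # None when interchromosomal
    locus_class: str  # local / intrachromosomal_distal / translocation
    mechanism_hint: str  # read_through / duplication_or_deletion / none
    cytoband5: str | None = None
    cytoband3: str | None = None


def _is_read_through(bp5: Breakpoint, bp3: Breakpoint) -> bool:
    if bp5.strand != bp3.strand:
        return False
    if bp5.strand == "+":
        return bp5.position < bp3.position
    return bp5.position > bp3.position


def classify_locus(
    record: FusionRecord,
    max_local_distance: int = DEFAULT_MAX_LOCAL_DISTANCE,
    cytobands: pd.DataFrame | None = None,
) -> LocusCall:
    bp5, bp3 = record.breakpoint5, record.breakpoint3
    same_chromosome = bp5.chrom == bp3.chrom
    band5 = cytoband_of(cytobands, bp5.chrom, bp5.position) if cytobands is not None else None
    band3 = cytoband_of(cytobands, bp3.chrom, bp3.position) if cytobands is not None else None

    if not same_chromosome:
        return LocusCall(
            fusion_name=record.fusion_name,
            same_chromosome=False,
            distance=None,
            locus_class="translocation",
            mechanism_hint="none",
            cytoband5=band5,
            cytoband3=band3,
        )
    distance = abs(bp5.position - bp3.position)
    if distance <= max_local_distance:
        locus_class = "local"
        hint = "read_through" if _is_read_through(bp5, bp3) else "duplication_or_deletion"
    else:
        locus_class = "intrachromosomal_distal"
        hint = "none"
    return LocusCall(
        fusion_name=record.fusion_name,
        same_chromosome=True,
        distance=distance,
        locus_class=locus_class,
        mechanism_hint=hint,
        cytoband5=band5,
        cytoband3=band3,
    )


def classify_table(
    records: Iterable[FusionRecord],
    max_local_distance: int = DEFAULT_MAX_LOCAL_DISTANCE,
    cytobands: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Classify a batch of records into the standard output table."""
    calls = [classify_locus(r, max_local_distance, cytobands) for r in records]
    return pd.DataFrame(
        [
            {
                "fusion_name": c.fusion_name,
                "same_chrom": c.same_chromosome,
                "distance": c.distance,
                "locus_class": c.locus_class,
                "mechanism_hint": c.mechanism_hint,
            }
            for c in calls
        ],
        columns=["fusion_name", "same_chrom", "distance", "locus_class", "mechanism_hint"],
    )


def load_cytobands(path: str | Path) -> pd.DataFrame:
    """Load a UCSC cytoBand.txt table (chrom, start, end, band, stain; no header)."""
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=["chrom", "start", "end", "band", "stain"],
        dtype={"chrom": str, "band": str, "stain": str},
    )
    return df


def cytoband_of(cytobands: pd.DataFrame | None, chrom: str, position: int) -> str | None:
    """Cytoband label (e.g. ``17q21.31``) for a 1-based position, if tabled."""
    if cytobands is None:
        return None
    hits = cytobands[
        (cytobands["chrom"] == chrom)
        & (cytobands["start"] < position)
        & (cytobands["end"] >= position)
    ]
    if hits.empty:
        return None
    return chrom.removeprefix("chr") + hits.iloc[0]["band"]
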