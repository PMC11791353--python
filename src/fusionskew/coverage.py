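"""Per-exon coverage profiles and expression normalization utilities.

The central container is :class:`ExonCoverageProfile`: raw read counts per
union-exon rank together with exon lengths, from which length-normalized
coverage (counts per base) is derived.  Profiles come either from a plain
TSV count table (the primary interface, so the package runs without
alignment files) or are counted directly from a coordinate-sorted indexed
BAM via pysam.

Also here: TPM and quantile normalization for whole-matrix expression QC,
and the per-library summary statistics (uniquely mapped reads, median
insert size) used for FF vs FFPE comparisons.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .genemodel import GeneModel

__all__ = [
    "ExonCoverageProfile",
    "LibraryStats",
    "normalize_by_length",
    "compute_tpm",
    "quantile_normalize",
    "count_exon_reads",
    "read_count_table",
    "write_count_table",
    "read_library_stats",
    "write_library_stats",
]

COUNT_TABLE_COLUMNS = ["sample_id", "gene_id", "exon_rank", "exon_length", "count"]
LIBRARY_STATS_COLUMNS = ["sample_id", "material", "uniquely_mapped", "median_insert_size"]


def normalize_by_length(counts: Sequence[float], lengths: Sequence[float]) -> np.ndarray:
    """Element-wise counts-per-base coverage: c_e = n_e / L_e."""
    counts_arr = np.asarray(counts, dtype=float)
    lengths_arr = np.asarray(lengths, dtype=float)
    if counts_arr.shape != lengths_arr.shape:
        raise ValueError(
            f"counts and lengths differ in length: {counts_arr.shape} vs {lengths_arr.shape}"
        )
    if np.any(lengths_arr < 1):
        raise ValueError("all exon lengths must be >= 1 base")
    return counts_arr / lengths_arr


@dataclass
class ExonCoverageProfile:
    """Exon-rank-ordered read counts for one gene in one sample.

    ``counts[e]`` is the number of reads overlapping the exon of rank e+1 and
    ``lengths[e]`` its length in bases; ``normalized`` is counts per base.
    Counts are floats so that bias-adjusted profiles (which rescale coverage)
    share the container; raw profiles hold integers.
    """

    gene_id: str
    sample_id: str
    counts: np.ndarray
    lengths: np.ndarray
    normalized: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        self.lengths = np.asarray(self.lengths, dtype=float)
        if self.counts.ndim != 1 or self.counts.shape != self.lengths.shape:
            raise ValueError("counts and lengths must be 1-D and of equal length")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        self.normalized = normalize_by_length(self.counts, self.lengths)

    @property
    def n_exons(self) -> int:
        return int(self.counts.size)

    @property
    def total_reads(self) -> float:
        return float(self.counts.sum())

    def with_normalized(self, normalized: np.ndarray) -> "ExonCoverageProfile":
        """New profile with the given per-base coverage (counts rescaled to match)."""
        normalized = np.asarray(normalized, dtype=float)
        return ExonCoverageProfile(
            gene_id=self.gene_id,
            sample_id=self.sample_id,
            counts=normalized * self.lengths,
            lengths=self.lengths.copy(),
        )


@dataclass
class LibraryStats:
    """Per-library sequencing summary (from aligner logs, not recomputed)."""

    sample_id: str
    material: str  # FF or FFPE
    uniquely_mapped_reads: int
    median_insert_size: float
    patient_id: str | None = None

    def __post_init__(self) -> None:
        if self.material not in {"FF", "FFPE"}:
            raise ValueError(f"material must be FF or FFPE, got {self.material!r}")
        if self.uniquely_mapped_reads < 0:
            raise ValueError("uniquely_mapped_reads must be non-negative")
        if self.median_insert_size <= 0:
            raise ValueError("median_insert_size must be positive")


def compute_tpm(gene_counts: Sequence[float], gene_lengths: Sequence[float]) -> np.ndarray:
    """Transcripts-per-million from per-gene counts and exonic lengths.

    TPM_g = 1e6 * (n_g / L_g) / sum_h (n_h / L_h); the output sums to 1e6.
    """
    counts = np.asarray(gene_counts, dtype=float)
    lengths = np.asarray(gene_lengths, dtype=float)
    if counts.shape != lengths.shape:
        raise ValueError("counts and lengths must have equal length")
    if np.any(lengths < 1):
        raise ValueError("gene lengths must be >= 1")
    if not np.any(counts > 0):
        raise ValueError("TPM undefined for all-zero counts")
    rate = counts / lengths
    return 1e6 * rate / rate.sum()


def quantile_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Force every sample (column) onto the common mean-of-sorted distribution.

    After normalization each column holds the same value multiset: the
    row-wise mean of the per-column sorted values.  Ties within a column
    receive the mean of the reference values their positions span, so tied
    inputs stay tied.
    """
    df = pd.DataFrame(matrix)
    if df.isna().any().any():
        raise ValueError("quantile_normalize requires a complete matrix (no NaN)")
    if df.shape[1] < 2:
        warnings.warn("quantile normalization needs >= 2 samples; returning input unchanged")
        return df.copy()
    reference = np.sort(df.values, axis=0).mean(axis=1)
    out = {}
    for col in df.columns:
        values = df[col].to_numpy(dtype=float)
        order = np.argsort(values, kind="mergesort")
        assigned = np.empty_like(reference)
        assigned[order] = reference
        # average the assigned reference values over each tied run
        out[col] = (
            pd.Series(assigned).groupby(pd.Series(values)).transform("mean").to_numpy()
        )
    return pd.DataFrame(out, index=df.index)


def count_exon_reads(
    alignment_file: str | Path,
    model: GeneModel,
    min_mapq: int = 50,
    primary_only: bool = True,
    dedup: bool = True,
) -> ExonCoverageProfile:
    """Count reads overlapping each union exon of a gene from an indexed BAM.

    A read contributes one count to every exon it overlaps by at least one
    aligned base (no fractional splitting); mates count separately.  Reads
    are skipped if unmapped, below ``min_mapq``, secondary/supplementary
    (with ``primary_only``), or flagged duplicate (with ``dedup``).  The
    MAPQ default of 50 keeps only uniquely mapped reads under the common
    aligner convention of MAPQ 255/60/50 for unique alignments.
    """
    import pysam

    sample_id = Path(alignment_file).stem
    with pysam.AlignmentFile(str(alignment_file), "rb") as bam:
        if model.chrom not in bam.references:
            warnings.warn(
                f"chromosome {model.chrom!r} absent from BAM header; returning empty profile"
            )
            return ExonCoverageProfile(
                gene_id=model.gene_id,
                sample_id=sample_id,
                counts=np.zeros(model.n_exons),
                lengths=np.array(model.exon_lengths, dtype=float),
            )
        span_start, span_end = model.span
        counts = np.zeros(model.n_exons, dtype=float)
        for read in bam.fetch(model.chrom, span_start, span_end):
            if read.is_unmapped:
                continue
            if primary_only and (read.is_secondary or read.is_supplementary):
                continue
            if read.mapping_quality < min_mapq:
                continue
            if dedup and read.is_duplicate:
                continue
            blocks = read.get_blocks()
            for i, exon in enumerate(model.exons):
                if any(bs < exon.end and be > exon.start for bs, be in blocks):
                    counts[i] += 1
    return ExonCoverageProfile(
        gene_id=model.gene_id,
        sample_id=sample_id,
        counts=counts,
        lengths=np.array(model.exon_lengths, dtype=float),
    )


def read_count_table(path: str | Path) -> list[ExonCoverageProfile]:
    """Read the canonical exon-count TSV into coverage profiles.

    Expected columns: ``sample_id  gene_id  exon_rank  exon_length  count``.
    Rows are grouped by (sample, gene) and ordered by exon rank; ranks must
    be consecutive from 1.
    """
    df = pd.read_csv(path, sep="\t")
    missing = set(COUNT_TABLE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"count table missing column(s): {sorted(missing)}")
    profiles: list[ExonCoverageProfile] = []
    for (sample_id, gene_id), group in df.groupby(["sample_id", "gene_id"], sort=True):
        group = group.sort_values("exon_rank")
        ranks = group["exon_rank"].to_numpy()
        if not np.array_equal(ranks, np.arange(1, len(ranks) + 1)):
            raise ValueError(
                f"exon ranks for {sample_id}/{gene_id} are not consecutive from 1"
            )
        profiles.append(
            ExonCoverageProfile(
                gene_id=str(gene_id),
                sample_id=str(sample_id),
                counts=group["count"].to_numpy(dtype=float),
                lengths=group["exon_length"].to_numpy(dtype=float),
            )
        )
    return profiles


def write_count_table(profiles: Iterable[ExonCoverageProfile], path: str | Path) -> None:
    rows = []
    for profile in profiles:
        for rank in range(1, profile.n_exons + 1):
            rows.append(
                {
                    "sample_id": profile.sample_id,
                    "gene_id": profile.gene_id,
                    "exon_rank": rank,
                    "exon_length": int(profile.lengths[rank - 1]),
                    "count": int(round(profile.counts[rank - 1])),
                }
            )
    pd.DataFrame(rows, columns=COUNT_TABLE_COLUMNS).to_csv(path, sep="\t", index=False)


def read_library_stats(path: str | Path) -> list[LibraryStats]:
    """Read per-library stats TSV (sample_id, material, uniquely_mapped, median_insert_size)."""
    df = pd.read_csv(path, sep="\t")
    missing = set(LIBRARY_STATS_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"library stats table missing column(s): {sorted(missing)}")
    stats = []
    for _, row in df.iterrows():
        stats.append(
            LibraryStats(
                sample_id=str(row["sample_id"]),
                material=str(row["material"]),
                uniquely_mapped_reads=int(row["uniquely_mapped"]),
                median_insert_size=float(row["median_insert_size"]),
                patient_id=str(row["patient_id"]) if "patient_id" in df.columns else None,
            )
        )
    return stats


def write_library_stats(stats: Iterable[LibraryStats], path: str | Path) -> None:
    rows = [
        {
            "sample_id": s.sample_id,
            "patient_id": s.patient_id,
            "material": s.material,
            "uniquely_mapped": s.uniquely_mapped_reads,
            "median_insert_size": s.median_insert_size,
        }
        for s in stats
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
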