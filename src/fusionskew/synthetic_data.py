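"""Synthetic inputs with known ground truth for every analysis module.

Two generators cover the package's test surface without any external data:

* :func:`simulate_exon_profile` draws negative-binomial per-exon read
  counts for one gene, optionally with a 3' degradation ramp (the FFPE
  signature) and/or a fold-elevation of all exons from a breakpoint rank
  onward (the fusion signature the asymmetry scan looks for).
* :func:`simulate_cohort_calls` emulates a paired FF/FFPE cohort: each
  patient's true fusion set is drawn from a prevalence-weighted catalog,
  each true fusion is independently detected on each platform with a
  per-platform probability, and detected events become caller-style records
  with Poisson evidence counts that always clear the downstream evidence
  filter (so detection dropout and filter survival stay separate effects).

Everything is deterministic under the configured seed, and every generated
artifact round-trips through the corresponding reader.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .coverage import (
    ExonCoverageProfile,
    LibraryStats,
    write_count_table,
    write_library_stats,
)
from .fusion_evidence import Breakpoint, FusionRecord, write_fusion_table

__all__ = [
    "SimProfileConfig",
    "SimCohortConfig",
    "ProfileTruth",
    "SimulatedCohort",
    "GeneSpec",
    "simulate_exon_profile",
    "simulate_profiles",
    "simulate_cohort_calls",
    "make_toy_gtf",
    "alk_like_gene_spec",
    "DEFAULT_FUSION_PREVALENCE",
]


@dataclass(frozen=True)
class SimProfileConfig:
    """Parameters for one simulated exon-count profile.

    mean_depth is the expected coverage in counts per base, so an exon of
    length L has expected count mean_depth * L before bias/fusion effects.
    dispersion is the negative-binomial overdispersion (variance =
    m + dispersion * m^2); 0 gives Poisson counts.  bias_strength is the
    multiplicative coverage ratio between the 3'-most and 5'-most exon under
    a log-linear ramp (1 = no bias).  When fusion_k is set, exons of rank >=
    fusion_k have their expectation multiplied by fold.
    """

    n_exons: int = 29
    exon_length_range: tuple[int, int] = (50, 300)
    mean_depth: float = 0.5
    dispersion: float = 0.1
    bias_strength: float = 1.0
    fusion_k: int | None = None
    fold: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_exons < 1:
            raise ValueError("n_exons must be >= 1")
        lo, hi = self.exon_length_range
        if lo < 1 or hi < lo:
            raise ValueError("exon_length_range must satisfy 1 <= min <= max")
        if self.mean_depth <= 0:
            raise ValueError("mean_depth must be positive")
        if self.dispersion < 0:
            raise ValueError("dispersion must be non-negative")
        if self.bias_strength < 1:
            raise ValueError("bias_strength must be >= 1 (1 = no bias)")
        if self.fold <= 0:
            raise ValueError("fold must be positive")
        if self.fusion_k is not None and not 2 <= self.fusion_k <= self.n_exons:
            raise ValueError("fusion_k must lie in [2, n_exons]")


@dataclass(frozen=True)
class ProfileTruth:
    """Generating parameters of a simulated profile."""

    gene_id: str
    sample_id: str
    fusion_k: int | None
    fold: float
    bias_strength: float


def _ramp(n_exons: int, strength: float) -> np.ndarray:
    """Log-linear 3' ramp: 1 at the 5'-most exon, `strength` at the 3'-most."""
    if n_exons == 1 or strength == 1.0:
        return np.ones(n_exons)
    x = np.arange(n_exons) / (n_exons - 1)
    return strength**x


def _draw_counts(rng: np.random.Generator, mu: np.ndarray, dispersion: float) -> np.ndarray:
    if dispersion == 0:
        return rng.poisson(mu).astype(float)
    size = 1.0 / dispersion
    p = size / (size + mu)
    return rng.negative_binomial(size, p).astype(float)


def simulate_exon_profile(
    config: SimProfileConfig,
    gene_id: str = "GENE",
    sample_id: str = "S1",
) -> tuple[ExonCoverageProfile, ProfileTruth]:
    """Draw one profile; expected count per exon is
    mean_depth * L_e * ramp(e) * (fold if e >= fusion_k else 1)."""
    rng = np.random.default_rng(config.seed)
    lo, hi = config.exon_length_range
    lengths = rng.integers(lo, hi + 1, size=config.n_exons).astype(float)
    mu = config.mean_depth * lengths * _ramp(config.n_exons, config.bias_strength)
    if config.fusion_k is not None:
        mu = mu.copy()
        mu[config.fusion_k - 1 :] *= config.fold
    counts = _draw_counts(rng, mu, config.dispersion)
    profile = ExonCoverageProfile(
        gene_id=gene_id, sample_id=sample_id, counts=counts, lengths=lengths
    )
    truth = ProfileTruth(
        gene_id=gene_id,
        sample_id=sample_id,
        fusion_k=config.fusion_k,
        fold=config.fold if config.fusion_k is not None else 1.0,
        bias_strength=config.bias_strength,
    )
    return profile, truth


def simulate_profiles(
    n_profiles: int,
    config: SimProfileConfig,
    sample_id: str = "S1",
    gene_prefix: str = "G",
) -> tuple[list[ExonCoverageProfile], list[ProfileTruth]]:
    """Batch of independent profiles with per-gene sub-seeds derived from config.seed."""
    profiles, truths = [], []
    for i in range(n_profiles):
        gene_id = f"{gene_prefix}{i:05d}"
        sub_seed = zlib.crc32(f"{config.seed}|{sample_id}|{gene_id}".encode()) & 0x7FFFFFFF
        from dataclasses import replace

        profile, truth = simulate_exon_profile(
            replace(config, seed=sub_seed), gene_id=gene_id, sample_id=sample_id
        )
        profiles.append(profile)
        truths.append(truth)
    return profiles, truths


# Per-fusion prevalence defaults chosen to mirror a 29-patient colorectal
# cohort: one very frequent read-through (KANSL1--ARL17A, ~69% of patients),
# a handful of recurrent events, a rare translocation and a rare ALK fusion.
DEFAULT_FUSION_PREVALENCE: dict[str, float] = {
    "KANSL1--ARL17A": 20 / 29,
    "MACC1--AC005062.1": 7 / 29,
    "LEPROT--LEPR": 5 / 29,
    "SMG1--NPIPB13": 3 / 29,
    "AL353138.1--PTCHD4": 3 / 29,
    "TFG--ADGRG7": 2 / 29,
    "CCDC32--CBX3": 2 / 29,
    "AC108865.1--AC110772.2": 2 / 29,
    "CAST--AC104123.1": 2 / 29,
    "AC090517.5--ZNF280D": 2 / 29,
    "BOLA2B--SMG1P6": 2 / 29,
    "UMAD1--GLCCI1": 2 / 29,
    "LRRFIP2--ALK": 1 / 29,
}

# Fixture breakpoints (synthetic but genomically plausible): most partners
# are same-chromosome neighbours, CCDC32--CBX3 and LRRFIP2--ALK cross
# chromosomes.
_FIXTURE_BREAKPOINTS: dict[str, tuple[Breakpoint, Breakpoint]] = {
    "KANSL1--ARL17A": (Breakpoint("chr17", 46270000, "-"), Breakpoint("chr17", 46193429, "-")),
    "MACC1--AC005062.1": (Breakpoint("chr7", 20182305, "+"), Breakpoint("chr7", 20320000, "+")),
    "LEPROT--LEPR": (Breakpoint("chr1", 65425378, "+"), Breakpoint("chr1", 65565546, "+")),
    "SMG1--NPIPB13": (Breakpoint("chr16", 18816239, "-"), Breakpoint("chr16", 18570000, "-")),
    "AL353138.1--PTCHD4": (Breakpoint("chr6", 47837000, "+"), Breakpoint("chr6", 47910000, "+")),
    "TFG--ADGRG7": (Breakpoint("chr3", 100732180, "+"), Breakpoint("chr3", 100820000, "+")),
    "CCDC32--CBX3": (Breakpoint("chr15", 40571099, "+"), Breakpoint("chr7", 26203503, "+")),
    "LRRFIP2--ALK": (Breakpoint("chr3", 37089616, "-"), Breakpoint("chr2", 29223528, "-")),
}


def _breakpoints_for(fusion_name: str) -> tuple[Breakpoint, Breakpoint]:
    if fusion_name in _FIXTURE_BREAKPOINTS:
        return _FIXTURE_BREAKPOINTS[fusion_name]
    crc = zlib.crc32(fusion_name.encode())
    chrom = f"chr{1 + crc % 22}"
    pos5 = 1_000_000 + (crc >> 3) % 100_000_000
    pos3 = pos5 + 50_000 + (crc >> 13) % 400_000
    return Breakpoint(chrom, pos5, "+"), Breakpoint(chrom, pos3, "+")


@dataclass(frozen=True)
class SimCohortConfig:
    """Paired-cohort generator parameters.

    Detection of each true fusion event on each platform is an independent
    Bernoulli draw (detect_prob_ff / detect_prob_ffpe), emulating
    expression-level and heterogeneity dropout.  Evidence counts for
    detected records are Poisson(evidence_mean), rejection-sampled to clear
    the evidence filter.  Library stats follow the cohort-typical values:
    around 15 M uniquely mapped reads for FF, reads_ratio_ffpe_over_ff times
    that for FFPE, and median insert sizes around the configured medians.
    """

    n_patients: int = 29
    fusion_catalog: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_FUSION_PREVALENCE)
    )
    detect_prob_ff: float = 0.6
    detect_prob_ffpe: float = 0.6
    evidence_mean: float = 6.0
    insert_median_ff: float = 206.0
    insert_median_ffpe: float = 186.0
    reads_ratio_ffpe_over_ff: float = 2.0
    mean_reads_ff: float = 15_000_000.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        for name, prob in [
            ("detect_prob_ff", self.detect_prob_ff),
            ("detect_prob_ffpe", self.detect_prob_ffpe),
        ]:
            if not 0.0 <= prob <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        for name, prev in dict(self.fusion_catalog).items():
            if not 0.0 <= prev <= 1.0:
                raise ValueError(f"prevalence of {name} must lie in [0, 1]")
        if self.insert_median_ff <= 0 or self.insert_median_ffpe <= 0:
            raise ValueError("insert medians must be positive")
        if self.evidence_mean <= 0 or self.reads_ratio_ffpe_over_ff <= 0:
            raise ValueError("evidence_mean and reads ratio must be positive")


@dataclass
class SimulatedCohort:
    """Generator output: caller tables, sample sheet, library stats, truth."""

    calls_by_sample: dict[str, list[FusionRecord]]
    sample_sheet: pd.DataFrame  # sample_id, patient_id, material
    library_stats: list[LibraryStats]
    truth: pd.DataFrame  # patient_id, fusion, detected_ff, detected_ffpe

    @property
    def records(self) -> list[FusionRecord]:
        return [r for sample in sorted(self.calls_by_sample) for r in self.calls_by_sample[sample]]

    def write(self, out_dir: str | Path) -> dict[str, str]:
        """Write all artifacts as TSVs; returns a name → path map."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths: dict[str, str] = {}
        for sample_id, records in self.calls_by_sample.items():
            path = out / f"{sample_id}.fusions.tsv"
            write_fusion_table(records, path)
            paths[sample_id] = str(path)
        self.sample_sheet.to_csv(out / "sample_sheet.tsv", sep="\t", index=False)
        paths["sample_sheet"] = str(out / "sample_sheet.tsv")
        write_library_stats(self.library_stats, out / "library_stats.tsv")
        paths["library_stats"] = str(out / "library_stats.tsv")
        self.truth.to_csv(out / "truth.tsv", sep="\t", index=False)
        paths["truth"] = str(out / "truth.tsv")
        return paths


def _evidence_counts(rng: np.random.Generator, mean: float) -> tuple[int, int]:
    # rejection-sample until the pair clears the OR filter (>=2 on either side)
    while True:
        jrc = int(rng.poisson(mean))
        sfc = int(rng.poisson(mean))
        if jrc >= 2 or sfc >= 2:
            return jrc, sfc


def simulate_cohort_calls(config: SimCohortConfig = SimCohortConfig()) -> SimulatedCohort:
    """Draw a full paired FF/FFPE cohort with linked ground truth.

    The truth table has one row per true fusion event (patient x fusion)
    with its per-platform detection outcome; every emitted caller record
    traces back to exactly one truth row.
    """
    rng = np.random.default_rng(config.seed)
    catalog = dict(config.fusion_catalog)

    calls_by_sample: dict[str, list[FusionRecord]] = {}
    sheet_rows = []
    stats: list[LibraryStats] = []
    truth_rows = []

    for i in range(1, config.n_patients + 1):
        patient_id = f"P{i:02d}"
        samples = {"FF": f"{patient_id}_FF", "FFPE": f"{patient_id}_FFPE"}
        for material, sample_id in samples.items():
            calls_by_sample[sample_id] = []
            sheet_rows.append(
                {"sample_id": sample_id, "patient_id": patient_id, "material": material}
            )

        for fusion_name, prevalence in catalog.items():
            if rng.random() >= prevalence:
                continue
            detected_ff = bool(rng.random() < config.detect_prob_ff)
            detected_ffpe = bool(rng.random() < config.detect_prob_ffpe)
            truth_rows.append(
                {
                    "patient_id": patient_id,
                    "fusion": fusion_name,
                    "detected_ff": detected_ff,
                    "detected_ffpe": detected_ffpe,
                }
            )
            gene5, gene3 = fusion_name.split("--", 1)
            bp5, bp3 = _breakpoints_for(fusion_name)
            for material, detected in [("FF", detected_ff), ("FFPE", detected_ffpe)]:
                if not detected:
                    continue
                jrc, sfc = _evidence_counts(rng, config.evidence_mean)
                calls_by_sample[samples[material]].append(
                    FusionRecord(
                        fusion_name=fusion_name,
                        gene5=gene5,
                        gene3=gene3,
                        breakpoint5=bp5,
                        breakpoint3=bp3,
                        junction_read_count=jrc,
                        spanning_frag_count=sfc,
                        splice_type="ONLY_REF_SPLICE",
                        sample_id=samples[material],
                        patient_id=patient_id,
                        material=material,
                    )
                )

        ff_reads = max(1, int(rng.normal(config.mean_reads_ff, 0.1 * config.mean_reads_ff)))
        ffpe_reads = max(
            1,
            int(
                rng.normal(
                    config.reads_ratio_ffpe_over_ff * config.mean_reads_ff,
                    0.1 * config.reads_ratio_ffpe_over_ff * config.mean_reads_ff,
                )
            ),
        )
        insert_ff = max(30.0, float(np.round(rng.normal(config.insert_median_ff, 8.0))))
        insert_ffpe = max(30.0, float(np.round(rng.normal(config.insert_median_ffpe, 8.0))))
        stats.append(
            LibraryStats(samples["FF"], "FF", ff_reads, insert_ff, patient_id=patient_id)
        )
        stats.append(
            LibraryStats(samples["FFPE"], "FFPE", ffpe_reads, insert_ffpe, patient_id=patient_id)
        )

    return SimulatedCohort(
        calls_by_sample=calls_by_sample,
        sample_sheet=pd.DataFrame(sheet_rows, columns=["sample_id", "patient_id", "material"]),
        library_stats=stats,
        truth=pd.DataFrame(
            truth_rows, columns=["patient_id", "fusion", "detected_ff", "detected_ffpe"]
        ),
    )


@dataclass(frozen=True)
class GeneSpec:
    """Layout of one toy gene for GTF generation.

    ``transcripts`` is a list of transcripts, each a list of 0-based
    half-open (start, end) exon intervals on ``chrom``.
    """

    gene_id: str
    chrom: str = "chr1"
    strand: str = "+"
    biotype: str = "protein_coding"
    symbol: str | None = None
    transcripts: Sequence[Sequence[tuple[int, int]]] = ()

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ValueError("strand must be + or -")
        if not self.transcripts:
            raise ValueError("gene needs at least one transcript with exons")
        for exons in self.transcripts:
            ordered = sorted(exons)
            for (s1, e1), (s2, e2) in zip(ordered, ordered[1:]):
                if s2 < e1:
                    raise ValueError(
                        f"overlapping exons within one transcript of {self.gene_id}"
                    )
            for s, e in exons:
                if s >= e:
                    raise ValueError(f"invalid exon [{s}, {e}) in {self.gene_id}")


def make_toy_gtf(genes: Sequence[GeneSpec]) -> str:
    """Render gene specs as Ensembl-dialect GTF text (1-based inclusive)."""
    lines = []
    for gene in genes:
        name = gene.symbol or gene.gene_id
        all_exons = [iv for tx in gene.transcripts for iv in tx]
        gene_start = min(s for s, _ in all_exons) + 1
        gene_end = max(e for _, e in all_exons)
        attrs = (
            f'gene_id "{gene.gene_id}"; gene_name "{name}"; gene_biotype "{gene.biotype}";'
        )
        lines.append(
            f"{gene.chrom}\ttoy\tgene\t{gene_start}\t{gene_end}\t.\t{gene.strand}\t.\t{attrs}"
        )
        for t_idx, exons in enumerate(gene.transcripts, start=1):
            tid = f"{gene.gene_id}.t{t_idx}"
            tx_start = min(s for s, _ in exons) + 1
            tx_end = max(e for _, e in exons)
            tx_attrs = f'{attrs} transcript_id "{tid}";'
            lines.append(
                f"{gene.chrom}\ttoy\ttranscript\t{tx_start}\t{tx_end}\t.\t{gene.strand}\t.\t{tx_attrs}"
            )
            ordered = sorted(exons, reverse=(gene.strand == "-"))
            for e_idx, (start, end) in enumerate(ordered, start=1):
                exon_attrs = f'{tx_attrs} exon_number "{e_idx}";'
                lines.append(
                    f"{gene.chrom}\ttoy\texon\t{start + 1}\t{end}\t.\t{gene.strand}\t.\t{exon_attrs}"
                )
    return "\n".join(lines) + "\n"


def alk_like_gene_spec(
    gene_id: str = "ALKL1",
    n_exons: int = 29,
    chrom: str = "chr2",
    strand: str = "-",
    exon_length: int = 150,
    intron_length: int = 2000,
    offset: int = 100_000,
) -> GeneSpec:
    """A 29-exon minus-strand receptor-kinase-shaped toy gene."""
    exons = []
    pos = offset
    for _ in range(n_exons):
        exons.append((pos, pos + exon_length))
        pos += exon_length + intron_length
    return GeneSpec(
        gene_id=gene_id,
        chrom=chrom,
        strand=strand,
        biotype="protein_coding",
        transcripts=[exons],
    )
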