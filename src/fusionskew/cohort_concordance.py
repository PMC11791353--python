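"""Paired FF/FFPE cohort analysis.

Matched fresh-frozen (FF) and formalin-fixed (FFPE) libraries from the same
tumours rarely yield identical fusion-call sets: detection is limited by
transcript expression, RNA integrity and tumour heterogeneity, so the two
platforms behave like two noisy observers of one underlying event set.
This module quantifies that relationship: per-patient set overlap (shared /
platform-only / Jaccard), cohort-wide recurrence of each fusion (a patient
"harbours" a fusion if it appears in either material), paired t-tests for
per-patient fusion counts and library metrics, and Spearman correlation.

Fusion identity throughout is the alias-collapsed ordered gene-pair key,
not the breakpoint, so that alternative splice variants of one fusion and
near-identical paralog partners (ARL17A/ARL17B) count as one event.

Percentages are rounded to the nearest integer, half away from zero.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sp_stats

from .coverage import LibraryStats
from .fusion_evidence import FusionRecord, collapse_alias

__all__ = [
    "PatientPair",
    "CohortSummary",
    "OverlapResult",
    "PairedTestResult",
    "RankCorrelation",
    "pair_overlap",
    "build_patient_pairs",
    "recurrence_table",
    "percent_of",
    "paired_mean_test",
    "rank_correlation",
    "library_comparison",
    "summarize_cohort",
]


def percent_of(count: int, total: int) -> int:
    """Percent rounded to nearest integer, half away from zero (20/29 -> 69)."""
    if total < 1:
        raise ValueError("total must be >= 1")
    return int(math.floor(100.0 * count / total + 0.5))


class OverlapResult(NamedTuple):
    shared: set
    ff_only: set
    ffpe_only: set
    jaccard: float


@dataclass
class PatientPair:
    """One patient's fusion keys per material."""

    patient_id: str
    ff_fusions: set = field(default_factory=set)
    ffpe_fusions: set = field(default_factory=set)

    @property
    def union(self) -> set:
        return self.ff_fusions | self.ffpe_fusions

    @property
    def overlap(self) -> OverlapResult:
        return pair_overlap(self.ff_fusions, self.ffpe_fusions)


class PairedTestResult(NamedTuple):
    t: float
    p: float
    mean_difference: float
    degenerate: bool  # all paired differences were zero


class RankCorrelation(NamedTuple):
    rho: float
    p: float
    defined: bool


@dataclass
class CohortSummary:
    n_patients: int
    per_patient: pd.DataFrame  # patient_id, ff_n, ffpe_n, shared_n, jaccard
    recurrence: pd.DataFrame  # fusion, n_patients, percent, recurrent
    paired_test: PairedTestResult
    spearman: RankCorrelation | None = None

    @property
    def n_patients_with_shared(self) -> int:
        return int((self.per_patient["shared_n"] > 0).sum())


def pair_overlap(ff_fusions: Iterable, ffpe_fusions: Iterable) -> OverlapResult:
    """Set partition of one patient's FF vs FFPE fusions plus Jaccard index."""
    ff = set(ff_fusions)
    ffpe = set(ffpe_fusions)
    union = ff | ffpe
    shared = ff & ffpe
    jaccard = len(shared) / len(union) if union else 0.0
    return OverlapResult(shared=shared, ff_only=ff - ffpe, ffpe_only=ffpe - ff, jaccard=jaccard)


def build_patient_pairs(
    records: Iterable[FusionRecord],
    alias_map: Mapping[str, str] | None = None,
) -> list[PatientPair]:
    """Group fusion records into per-patient FF/FFPE key sets.

    Records must carry ``patient_id`` and ``material``; keys are
    alias-collapsed ordered gene pairs.  Pairs are returned sorted by
    patient id.
    """
    pairs: dict[str, PatientPair] = {}
    for record in records:
        if record.patient_id is None or record.material is None:
            raise ValueError(
                f"record {record.fusion_name} lacks patient_id/material metadata"
            )
        key = (
            collapse_alias(record.gene5, alias_map),
            collapse_alias(record.gene3, alias_map),
        )
        pair = pairs.setdefault(record.patient_id, PatientPair(record.patient_id))
        if record.material == "FF":
            pair.ff_fusions.add(key)
        elif record.material == "FFPE":
            pair.ffpe_fusions.add(key)
        else:
            raise ValueError(f"unknown material {record.material!r}")
    return [pairs[pid] for pid in sorted(pairs)]


def recurrence_table(
    patient_to_fusions: Mapping[str, Iterable], n_patients: int
) -> pd.DataFrame:
    """Per-fusion patient counts and cohort percentages.

    ``patient_to_fusions`` maps each patient to the union of fusion keys
    seen in either material.  Output columns: fusion (stringified key),
    n_patients, percent (nearest integer), recurrent (count >= 2); sorted
    by count descending then key ascending.
    """
    if n_patients < 1:
        raise ValueError("n_patients must be >= 1")
    counts: dict = {}
    for fusions in patient_to_fusions.values():
        for key in set(fusions):
            counts[key] = counts.get(key, 0) + 1
    rows = [
        {
            "fusion": "--".join(key) if isinstance(key, tuple) else str(key),
            "n_patients": count,
            "percent": percent_of(count, n_patients),
            "recurrent": count >= 2,
        }
        for key, count in counts.items()
    ]
    frame = pd.DataFrame(rows, columns=["fusion", "n_patients", "percent", "recurrent"])
    return frame.sort_values(
        ["n_patients", "fusion"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)


def paired_mean_test(x: Sequence[float], y: Sequence[float]) -> PairedTestResult:
    """Two-sided paired Student's t-test via the closed form on differences.

    t = mean(d) / (sd(d) / sqrt(n)) with n-1 degrees of freedom, d = x - y.
    All-zero differences return (t=0, p=1, degenerate=True) instead of 0/0.
    """
    x_arr = np.asarray(x, dtype=float)
    y_arr = np.asarray(y, dtype=float)
    if x_arr.shape != y_arr.shape or x_arr.ndim != 1:
        raise ValueError("x and y must be matched 1-D vectors")
    n = x_arr.size
    if n < 3:
        raise ValueError("paired test needs at least 3 pairs")
    diff = x_arr - y_arr
    mean_diff = float(diff.mean())
    sd = float(diff.std(ddof=1))
    if sd == 0.0:
        return PairedTestResult(t=0.0, p=1.0, mean_difference=mean_diff, degenerate=True)
    t = mean_diff / (sd / math.sqrt(n))
    p = 2.0 * float(sp_stats.t.sf(abs(t), df=n - 1))
    return PairedTestResult(t=t, p=p, mean_difference=mean_diff, degenerate=False)


def rank_correlation(x: Sequence[float], y: Sequence[float]) -> RankCorrelation:
    """Spearman's rho with mid-rank ties; flagged undefined for constant input."""
    x_arr = np.asarray(x, dtype=float)
    y_arr = np.asarray(y, dtype=float)
    if x_arr.shape != y_arr.shape or x_arr.ndim != 1 or x_arr.size < 3:
        raise ValueError("rank correlation needs matched vectors of length >= 3")
    if np.all(x_arr == x_arr[0]) or np.all(y_arr == y_arr[0]):
        return RankCorrelation(rho=float("nan"), p=float("nan"), defined=False)
    rho, p = sp_stats.spearmanr(x_arr, y_arr)
    return RankCorrelation(rho=float(rho), p=float(p), defined=True)


def library_comparison(stats: Sequence[LibraryStats]) -> pd.DataFrame:
    """Paired FF vs FFPE comparison of library metrics per patient.

    Requires each patient to contribute one FF and one FFPE entry (others
    are excluded with a warning).  One row per metric — uniquely mapped
    reads and median insert size — with group medians, the median and mean
    of paired FF−FFPE differences, the FFPE/FF ratio of medians, and the
    paired t-test.
    """
    by_patient: dict[str, dict[str, LibraryStats]] = {}
    for entry in stats:
        if entry.patient_id is None:
            raise ValueError(f"library stats for {entry.sample_id} lack patient_id")
        by_patient.setdefault(entry.patient_id, {})[entry.material] = entry
    complete = {
        pid: pair for pid, pair in by_patient.items() if {"FF", "FFPE"} <= pair.keys()
    }
    dropped = sorted(set(by_patient) - set(complete))
    if dropped:
        warnings.warn(f"excluding unpaired patient(s): {dropped}")
    if not complete:
        raise ValueError("no complete FF/FFPE patient pairs")

    patients = sorted(complete)
    rows = []
    for metric, getter in [
        ("uniquely_mapped_reads", lambda s: float(s.uniquely_mapped_reads)),
        ("median_insert_size", lambda s: float(s.median_insert_size)),
    ]:
        ff = np.array([getter(complete[p]["FF"]) for p in patients])
        ffpe = np.array([getter(complete[p]["FFPE"]) for p in patients])
        test = paired_mean_test(ff, ffpe)
        rows.append(
            {
                "metric": metric,
                "n_pairs": len(patients),
                "ff_median": float(np.median(ff)),
                "ffpe_median": float(np.median(ffpe)),
                "median_difference": float(np.median(ff) - np.median(ffpe)),
                "mean_difference": test.mean_difference,
                "ffpe_over_ff_ratio": float(np.median(ffpe) / np.median(ff))
                if np.median(ff) > 0
                else float("nan"),
                "t": test.t,
                "p": test.p,
            }
        )
    return pd.DataFrame(rows)


def summarize_cohort(
    pairs: Sequence[PatientPair],
    library_stats: Sequence[LibraryStats] | None = None,
) -> CohortSummary:
    """Assemble the cohort-level concordance summary from patient pairs."""
    if not pairs:
        raise ValueError("no patient pairs supplied")
    per_patient = pd.DataFrame(
        [
            {
                "patient_id": pair.patient_id,
                "ff_n": len(pair.ff_fusions),
                "ffpe_n": len(pair.ffpe_fusions),
                "shared_n": len(pair.overlap.shared),
                "jaccard": pair.overlap.jaccard,
            }
            for pair in pairs
        ]
    )
    recurrence = recurrence_table(
        {pair.patient_id: pair.union for pair in pairs}, n_patients=len(pairs)
    )
    if len(pairs) >= 3:
        paired = paired_mean_test(per_patient["ff_n"], per_patient["ffpe_n"])
        spearman = rank_correlation(per_patient["ff_n"], per_patient["ffpe_n"])
        if not spearman.defined:
            spearman = None
    else:
        paired = PairedTestResult(float("nan"), float("nan"), float("nan"), True)
        spearman = None
    return CohortSummary(
        n_patients=len(pairs),
        per_patient=per_patient,
        recurrence=recurrence,
        paired_test=paired,
        spearman=spearman,
    )
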