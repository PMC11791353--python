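"""End-to-end orchestration: calls → filter → classify → scan → concordance.

The pipeline mirrors how the two detection routes complement each other in
practice: caller output is evidence-filtered, deduplicated, annotated
against a known-fusion catalog and classified by partner proximity, while
exon-count profiles are scanned for coverage asymmetry.  Genes flagged by
the asymmetry scan but absent from the surviving caller records of the same
sample are reported as "coverage-only candidates" — the situation where a
fusion leaves a coverage footprint although no chimeric read survived in a
degraded library.

Every run writes a manifest (inputs, parameters, seed, package version,
per-stage status) that fully determines the outputs: two runs with equal
manifests produce byte-identical TSVs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from . import __version__
from .asymmetry import AsymmetryConfig, cohort_scan
from .cohort_concordance import (
    build_patient_pairs,
    library_comparison,
    summarize_cohort,
)
from .coverage import read_count_table, read_library_stats
from .fusion_evidence import (
    annotate_known,
    classify_biotype,
    deduplicate,
    filter_by_evidence,
    read_alias_map,
    read_catalog,
    read_fusion_table,
)
from .genemodel import parse_gtf
from .locus_classifier import classify_table
from .synthetic_data import SimCohortConfig, simulate_cohort_calls

logger = logging.getLogger("fusionskew")

__all__ = ["RunConfig", "run_pipeline", "PipelineError"]


class PipelineError(RuntimeError):
    """A stage failure, tagged with the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """Inputs and per-stage parameters for one pipeline run."""

    out_dir: str
    seed: int = 0
    # input paths; a `simulate` block replaces calls/sample_sheet/library_stats
    counts: str | None = None
    gtf: str | None = None
    calls: dict[str, str] = field(default_factory=dict)  # sample_id -> TSV path
    sample_sheet: str | None = None
    catalog: str | None = None
    alias: str | None = None
    library_stats: str | None = None
    simulate: dict[str, Any] | None = None
    # stage parameter blocks
    filter_params: dict[str, Any] = field(default_factory=dict)
    locus_params: dict[str, Any] = field(default_factory=dict)
    asymmetry_params: dict[str, Any] = field(default_factory=dict)
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as handle:
            raw = yaml.safe_load(handle) or {}
        inputs = raw.get("inputs", {})
        return cls(
            out_dir=raw["out_dir"],
            seed=int(raw.get("seed", 0)),
            counts=inputs.get("counts"),
            gtf=inputs.get("gtf"),
            calls=dict(inputs.get("calls", {})),
            sample_sheet=inputs.get("sample_sheet"),
            catalog=inputs.get("catalog"),
            alias=inputs.get("alias"),
            library_stats=inputs.get("library_stats"),
            simulate=raw.get("simulate"),
            filter_params=dict(raw.get("filter", {})),
            locus_params=dict(raw.get("locus", {})),
            asymmetry_params=dict(raw.get("asymmetry", {})),
            log_level=raw.get("log_level", "INFO"),
        )


def _records_frame(annotations) -> pd.DataFrame:
    rows = []
    for ann in annotations:
        r = ann.record
        rows.append(
            {
                "sample_id": r.sample_id,
                "patient_id": r.patient_id,
                "material": r.material,
                "fusion_name": r.fusion_name,
                "gene5": r.gene5,
                "gene3": r.gene3,
                "breakpoint5": str(r.breakpoint5),
                "breakpoint3": str(r.breakpoint3),
                "junction_read_count": r.junction_read_count,
                "spanning_frag_count": r.spanning_frag_count,
                "known": ann.known,
                "biotype_class": ann.biotype_class,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "sample_id",
            "patient_id",
            "material",
            "fusion_name",
            "gene5",
            "gene3",
            "breakpoint5",
            "breakpoint3",
            "junction_read_count",
            "spanning_frag_count",
            "known",
            "biotype_class",
        ],
    )


def run_pipeline(config: RunConfig) -> dict:
    """Execute all configured stages and write the report bundle.

    Returns the manifest dict (also written to ``manifest.json``).  Any
    stage error aborts with a :class:`PipelineError` naming the stage;
    stages skipped for lack of inputs are marked "skipped" in the manifest.
    """
    logging.basicConfig(
        level=config.log_level, format="%(name)s %(levelname)s %(message)s"
    )
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stages: dict[str, str] = {}
    outputs: dict[str, str] = {}
    summary: dict[str, Any] = {}

    def _write(frame: pd.DataFrame, name: str) -> None:
        path = out / name
        frame.to_csv(path, sep="\t", index=False)
        outputs[name] = str(path)

    # ---- stage: inputs (load or simulate) ----------------------------------
    try:
        if config.simulate is not None:
            sim_config = SimCohortConfig(**{**config.simulate, "seed": config.seed})
            cohort = simulate_cohort_calls(sim_config)
            sim_dir = out / "simulated"
            cohort.write(sim_dir)
            records = cohort.records
            sample_sheet = cohort.sample_sheet
            lib_stats = cohort.library_stats
        else:
            if not config.calls or config.sample_sheet is None:
                raise ValueError("need either a simulate block or calls + sample_sheet")
            sample_sheet = pd.read_csv(config.sample_sheet, sep="\t")
            meta = sample_sheet.set_index("sample_id")
            records = []
            for sample_id, path in sorted(config.calls.items()):
                row = meta.loc[sample_id]
                records.extend(
                    read_fusion_table(
                        path,
                        sample_id=sample_id,
                        patient_id=str(row["patient_id"]),
                        material=str(row["material"]),
                    )
                )
            lib_stats = (
                read_library_stats(config.library_stats)
                if config.library_stats
                else []
            )
        stages["inputs"] = "ok"
        summary["n_calls_raw"] = len(records)
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001 - re-tagged with stage name
        raise PipelineError("inputs", str(exc)) from exc

    # ---- stage: filter ------------------------------------------------------
    try:
        filtered = deduplicate(filter_by_evidence(records, **config.filter_params))
        stages["filter"] = "ok"
        summary["n_calls_filtered"] = len(filtered)
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("filter", str(exc)) from exc

    # ---- stage: annotate ----------------------------------------------------
    try:
        catalog = read_catalog(config.catalog) if config.catalog else set()
        alias_map = read_alias_map(config.alias) if config.alias else None
        annotations = annotate_known(filtered, catalog, alias_map)
        gene_models = parse_gtf(config.gtf) if config.gtf else None
        if gene_models is not None:
            for ann in annotations:
                ann.biotype_class = classify_biotype(ann.record, gene_models)
        _write(_records_frame(annotations), "fusion_annotations.tsv")
        stages["annotate"] = "ok"
        summary["n_known"] = sum(a.known for a in annotations)
        summary["n_novel"] = sum(not a.known for a in annotations)
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("annotate", str(exc)) from exc

    # ---- stage: locus -------------------------------------------------------
    try:
        locus = classify_table(filtered, **config.locus_params)
        _write(locus, "locus_calls.tsv")
        stages["locus"] = "ok"
        summary["locus_class_counts"] = (
            locus["locus_class"].value_counts().sort_index().to_dict()
        )
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("locus", str(exc)) from exc

    # ---- stage: asymmetry scan ---------------------------------------------
    called_genes: list[tuple[str, str]] = []
    if config.counts:
        try:
            profiles = read_count_table(config.counts)
            asym_config = AsymmetryConfig(
                **{**config.asymmetry_params, "seed": config.seed}
            )
            scan = cohort_scan(profiles, asym_config)
            _write(scan, "asymmetry.tsv")
            stages["asymmetry"] = "ok"
            called = scan[scan["called"] == True]  # noqa: E712
            summary["n_asymmetry_called"] = int(len(called))
            called_genes = list(zip(called["sample_id"], called["gene_id"]))
        except Exception as exc:  # noqa: BLE001
            raise PipelineError("asymmetry", str(exc)) from exc
    else:
        stages["asymmetry"] = "skipped"

    # ---- stage: cross-reference (coverage-only candidates) ------------------
    try:
        partners_by_sample: dict[str, set[str]] = {}
        for record in filtered:
            partners_by_sample.setdefault(record.sample_id, set()).update(
                {record.gene5, record.gene3}
            )
        coverage_only = [
            {"sample_id": sample_id, "gene_id": gene_id, "status": "coverage_only_candidate"}
            for sample_id, gene_id in called_genes
            if gene_id not in partners_by_sample.get(sample_id, set())
        ]
        summary["coverage_only_candidates"] = coverage_only
        stages["crossref"] = "ok" if config.counts else "skipped"
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("crossref", str(exc)) from exc

    # ---- stage: concordance -------------------------------------------------
    try:
        with_meta = [r for r in filtered if r.patient_id and r.material]
        if with_meta:
            alias_map = read_alias_map(config.alias) if config.alias else None
            pairs = build_patient_pairs(with_meta, alias_map)
            cohort_summary = summarize_cohort(pairs)
            _write(cohort_summary.per_patient, "pair_overlap.tsv")
            _write(cohort_summary.recurrence, "recurrence.tsv")
            summary["n_patients"] = cohort_summary.n_patients
            summary["n_patients_with_shared_fusion"] = cohort_summary.n_patients_with_shared
            summary["paired_count_test"] = {
                "t": cohort_summary.paired_test.t,
                "p": cohort_summary.paired_test.p,
                "mean_difference": cohort_summary.paired_test.mean_difference,
            }
            if lib_stats:
                _write(library_comparison(lib_stats), "library_comparison.tsv")
            stages["concordance"] = "ok"
        else:
            stages["concordance"] = "skipped"
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("concordance", str(exc)) from exc

    # ---- summary + manifest -------------------------------------------------
    with open(out / "summary.json", "w") as handle:
        json.dump(summary, handle, indent=2, sort_keys=True, default=str)
    outputs["summary.json"] = str(out / "summary.json")
    manifest = {
        "version": __version__,
        "seed": config.seed,
        "inputs": {
            "counts": config.counts,
            "gtf": config.gtf,
            "calls": config.calls,
            "sample_sheet": config.sample_sheet,
            "catalog": config.catalog,
            "alias": config.alias,
            "library_stats": config.library_stats,
            "simulate": config.simulate,
        },
        "parameters": {
            "filter": config.filter_params,
            "locus": config.locus_params,
            "asymmetry": config.asymmetry_params,
        },
        "stages": stages,
        "outputs": sorted(outputs),
    }
    with open(out / "manifest.json", "w") as handle:
        json.dump(manifest, handle, indent=2, sort_keys=True)
    logger.info("pipeline complete: %s", ", ".join(f"{k}={v}" for k, v in stages.items()))
    return manifest
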