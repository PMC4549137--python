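"""End-to-end experiment orchestration.

``analyze_cohort`` is the in-memory composition used by the CLI, the
examples and the acceptance checks: preprocess every subject's ROI series
(detrend -> band-pass -> global-signal regression -> motion censoring),
build per-subject Pearson connectivity, run edge-wise group t-tests and
selection, correlate selected edges with the patients' clinical scores,
and cross-validate the linear-SVM classifier.

``run_experiment`` drives the same composition from a config, writes every
table to disk and records a manifest with SHA-256 checksums so a rerun is
byte-verifiable.
"""
from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .cohort import SubjectRecord, read_cohort, records_to_frame, cohort_summary
from .connectivity import (ConnectivityMatrix, cohort_edge_table, edge_names,
                           edge_pairs, fisher_z, pearson_matrix)
from .crossval import ClassificationReport, cross_validate
from .group_stats import behavior_correlations, edge_ttests, select_edges
from .preprocess import CensoringPolicy, preprocess
from .simulate import SimulationSpec, SyntheticCohort, generate_cohort
from .timeseries import MotionTrace, RoiTimeSeries

SCHEMA_VERSION = 1


@dataclass
class PipelineConfig:
    simulation: Optional[SimulationSpec] = None
    input_dir: Optional[str] = None
    band: Optional[tuple[float, float]] = (0.01, 0.08)
    censoring: CensoringPolicy = field(default_factory=CensoringPolicy)
    regress_global: bool = True
    use_fisher_z: bool = False
    welch: bool = False
    selection_threshold: float = 0.001
    svm_C: float = 1.0
    k_folds: int = 10
    selection_mode: str = "nested"
    seed: int = 0

    def config_hash(self) -> str:
        blob = json.dumps(_jsonable(asdict(self)), sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


@dataclass
class ExperimentResult:
    records: list[SubjectRecord]
    region_names: list[str]
    edge_table: np.ndarray            # subjects x edges, record order
    labels: np.ndarray                # +1 patient / -1 control
    edge_stats: pd.DataFrame
    selected: list[int]
    behavior: pd.DataFrame
    report: ClassificationReport
    frames_kept: dict[str, int]


def preprocess_cohort(records, series, motion, config: PipelineConfig
                      ) -> dict[str, RoiTimeSeries]:
    out = {}
    for rec in records:
        try:
            out[rec.id] = preprocess(
                series[rec.id], motion.get(rec.id),
                policy=config.censoring, band=config.band,
                regress_global=config.regress_global)
        except Exception as exc:
            raise RuntimeError(
                f"preprocessing failed for subject {rec.id!r}: {exc}") from exc
    return out


def analyze_cohort(records: list[SubjectRecord],
                   series: dict[str, RoiTimeSeries],
                   motion: dict[str, MotionTrace],
                   config: PipelineConfig) -> ExperimentResult:
    clean = preprocess_cohort(records, series, motion, config)
    matrices: dict[str, ConnectivityMatrix] = {}
    for rec in records:
        try:
            matrices[rec.id] = pearson_matrix(clean[rec.id])
        except Exception as exc:
            raise RuntimeError(
                f"connectivity failed for subject {rec.id!r}: {exc}") from exc
    edges = cohort_edge_table(matrices)
    if config.use_fisher_z:
        edges = fisher_z(np.clip(edges, -0.999999, 0.999999))
    labels = np.array([1 if r.group == "patient" else -1 for r in records])
    stats = edge_ttests(edges[labels == 1], edges[labels == -1],
                        welch=config.welch)
    selection = select_edges(stats, config.selection_threshold)

    patients = [r for r in records if r.group == "patient"]
    covs = records_to_frame(patients)[
        ["sara", "cag_expansion", "years_of_symptoms"]]
    if selection.selected and len(patients) >= 3:
        behavior = behavior_correlations(edges[labels == 1],
                                         selection.selected, covs)
    else:
        behavior = pd.DataFrame(columns=["edge", "covariate", "r", "p", "n"])

    report = cross_validate(edges, labels, k=config.k_folds,
                            selection_mode=config.selection_mode,
                            threshold=config.selection_threshold,
                            C=config.svm_C, seed=config.seed,
                            welch=config.welch)
    region_names = next(iter(series.values())).region_names
    return ExperimentResult(
        records=records, region_names=region_names, edge_table=edges,
        labels=labels, edge_stats=stats, selected=selection.selected,
        behavior=behavior, report=report,
        frames_kept={sid: int(ts.kept_frames.size)
                     for sid, ts in clean.items()})


def edge_stats_table(result: ExperimentResult) -> pd.DataFrame:
    """Human-readable per-edge statistics for the selected edges."""
    pairs = edge_pairs(len(result.region_names))
    rows = []
    for e in result.selected:
        i, j = pairs[e]
        s = result.edge_stats.iloc[e]
        rows.append({
            "region_i": result.region_names[i],
            "region_j": result.region_names[j],
            "t": s["t"], "p": s["p"], "direction": s["direction"],
            "mean_patient": s["mean_patient"],
            "mean_control": s["mean_control"],
        })
    return pd.DataFrame(
        rows, columns=["region_i", "region_j", "t", "p", "direction",
                       "mean_patient", "mean_control"])


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_experiment(config: PipelineConfig, outdir) -> ExperimentResult:
    """Run the full pipeline and write all report artifacts plus a manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if config.simulation is not None:
        cohort: SyntheticCohort = generate_cohort(config.simulation,
                                                  master_seed=config.seed)
        records, series, motion = cohort.records, cohort.series, cohort.motion
    elif config.input_dir is not None:
        base = Path(config.input_dir)
        records, series, motion = read_cohort(
            base / "subjects.tsv", base / "timeseries",
            base / "motion" if (base / "motion").exists() else None)
    else:
        raise ValueError("config needs either a simulation spec or input_dir")

    result = analyze_cohort(records, series, motion, config)

    cohort_summary(records).to_csv(outdir / "cohort_summary.tsv", sep="\t",
                                   index=False)
    edge_stats_table(result).to_csv(outdir / "selected_edges.tsv", sep="\t",
                                    index=False, float_format="%.6g")
    names = edge_names(result.region_names)
    behavior = result.behavior.copy()
    if len(behavior):
        behavior.insert(0, "edge_name", [names[e] for e in behavior["edge"]])
    behavior.to_csv(outdir / "behavior_correlations.tsv", sep="\t",
                    index=False, float_format="%.6g")
    report = {
        "schema_version": SCHEMA_VERSION,
        "config_hash": config.config_hash(),
        **result.report.to_dict(),
        "n_selected_edges": len(result.selected),
        "expected_false_positives":
            config.selection_threshold * result.edge_stats.shape[0],
        "frames_kept": result.frames_kept,
    }
    (outdir / "classification.json").write_text(
        json.dumps(_jsonable(report), indent=2, sort_keys=True))

    files = sorted(p for p in outdir.iterdir()
                   if p.is_file() and p.name != "manifest.json")
    manifest = {
        "schema_version": SCHEMA_VERSION,
        "config_hash": config.config_hash(),
        "files": {p.name: _sha256(p) for p in files},
        "warnings": [f.warning for f in result.report.folds if f.warning],
    }
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True))
    return result
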