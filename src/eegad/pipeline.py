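"""Stage-by-stage orchestration of the biomarker framework.

Each stage reads its predecessor's on-disk artefacts from the run
directory and writes its own, so any stage can be re-run in isolation;
the run configuration is serialised alongside for full provenance.
Stage order: simulate (or ingest) -> extract -> select -> panels ->
screen -> fuse -> optimize -> validate.
"""

from __future__ import annotations

import itertools
import json
import logging
import math
from pathlib import Path

import numpy as np
import pandas as pd

from . import model as mdl
from . import panels as pnl
from . import selection as sel
from .config import RunConfig
from .features import BiomarkerTable, extract_all
from .io import EegRecord, read_edf, read_matrix, trim_interval
from .montage import FeatureId
from .simulate import generate_cohort

logger = logging.getLogger(__name__)


def _require(path: Path, stage: str) -> Path:
    if not path.exists():
        raise FileNotFoundError(
            f"stage '{stage}' needs missing artefact {path}; "
            "run the preceding stage first")
    return path


def _write_json(path: Path, payload: dict) -> None:
    path.write_text(json.dumps(payload, indent=2, default=str))


def run_simulate(config: RunConfig, outdir: str | Path) -> list[EegRecord]:
    outdir = Path(outdir)
    (outdir / "cohort").mkdir(parents=True, exist_ok=True)
    records, truth = generate_cohort(config.cohort)
    manifest = {"truth": truth, "subjects": []}
    for rec in records:
        path = outdir / "cohort" / f"{rec.subject_id}.csv"
        np.savetxt(path, rec.data, delimiter=",", fmt="%.6f")
        manifest["subjects"].append({
            "subject_id": rec.subject_id, "group": rec.group,
            "fs": rec.fs, "channels": rec.channels,
            "file": path.name,
        })
    _write_json(outdir / "cohort" / "manifest.json", manifest)
    config.to_yaml(outdir / "config.yaml")
    return records


def load_records(config: RunConfig, outdir: str | Path) -> list[EegRecord]:
    outdir = Path(outdir)
    manifest_path = outdir / "cohort" / "manifest.json"
    if manifest_path.exists():
        manifest = json.loads(manifest_path.read_text())
        records = []
        for sub in manifest["subjects"]:
            records.append(read_matrix(
                outdir / "cohort" / sub["file"], fs=sub["fs"],
                labels=sub["channels"], group=sub["group"],
                subject_id=sub["subject_id"]))
        return records
    if config.input_dir is None:
        raise FileNotFoundError(
            "no simulated cohort manifest and no input_dir configured")
    indir = Path(config.input_dir)
    records = []
    paths = sorted(indir.glob("*.edf" if config.input_format == "edf"
                              else "*.csv"))
    if not paths:
        raise FileNotFoundError(f"no input records found in {indir}")
    for path in paths:
        try:
            if config.input_format == "edf":
                records.append(read_edf(path))
            else:
                records.append(read_matrix(path, fs=config.input_fs,
                                           labels=config.input_labels))
        except (OSError, ValueError) as exc:
            logger.warning("skipping unreadable record %s: %s", path, exc)
    return records


def run_extract(config: RunConfig, outdir: str | Path) -> BiomarkerTable:
    outdir = Path(outdir)
    records = load_records(config, outdir)
    if config.trim is not None:
        records = [trim_interval(r, *config.trim) for r in records]
    else:
        records = [trim_interval(r) for r in records]
    table = extract_all(records, config.feature_config())
    table.to_csv(outdir / "biomarkers.csv")
    if table.exclusions:
        pd.DataFrame(table.exclusions,
                     columns=["subject_id", "feature", "reason"]
                     ).to_csv(outdir / "exclusions.tsv", sep="\t", index=False)
    return table


def run_select(config: RunConfig, outdir: str | Path) -> sel.SelectionReport:
    outdir = Path(outdir)
    table = BiomarkerTable.from_csv(_require(outdir / "biomarkers.csv",
                                             "select"))
    report = sel.select(table, test=config.test,
                        p_threshold=config.p_threshold,
                        cumulative_threshold=config.cumulative_threshold)
    seldir = outdir / "selection"
    report.write(seldir)
    _write_json(seldir / "selected.json", {
        "features": report.selected_features,
        "channels": report.selected_channels,
        "pairs": report.selected_pairs,
        "thresholds": report.thresholds,
    })
    return report


def _load_selected(outdir: Path, stage: str) -> dict:
    return json.loads(_require(outdir / "selection" / "selected.json",
                               stage).read_text())


def run_panels(config: RunConfig, outdir: str | Path) -> dict:
    outdir = Path(outdir)
    selected = _load_selected(outdir, "panels")
    audit = pnl.panel_audit(selected["features"], selected["channels"],
                            selected["pairs"],
                            max_len=config.stage1_max_len,
                            max_size=config.stage2_max_size)
    full_total = audit["stage1"]["total"]
    audit["stage1"]["screened_cap"] = (
        full_total if config.scale >= 1.0
        else max(1, math.ceil(config.scale * full_total)))
    _write_json(outdir / "panel_audit.json", audit)
    return audit


def run_screen(config: RunConfig, outdir: str | Path) -> pd.DataFrame:
    outdir = Path(outdir)
    table = BiomarkerTable.from_csv(_require(outdir / "biomarkers.csv",
                                             "screen"))
    selected = _load_selected(outdir, "screen")
    audit = json.loads(_require(outdir / "panel_audit.json",
                                "screen").read_text())
    cap = audit["stage1"]["screened_cap"]
    train, test = mdl.split_train_test(table, config.train_frac, config.seed)
    stream = pnl.build_stage1_panels(selected["features"],
                                     selected["channels"], selected["pairs"],
                                     max_len=config.stage1_max_len)
    rows = []
    for panel in itertools.islice(stream, cap):
        m = mdl.evaluate_panel_svm(panel, train, config.folds, config.seed)
        rows.append({"panel": panel.panel_id, "size": panel.size,
                     **m.rounded()})
    df = pd.DataFrame(rows).sort_values("panel").reset_index(drop=True)
    df.to_csv(outdir / "panel_metrics.csv", index=False)
    for part, tbl in (("train", train), ("test", test)):
        tbl.to_csv(outdir / f"split_{part}.csv")
    return df


def run_fuse(config: RunConfig, outdir: str | Path
             ) -> tuple[mdl.DiagnosticModel, mdl.PerformanceMetrics]:
    outdir = Path(outdir)
    metrics = pd.read_csv(_require(outdir / "panel_metrics.csv", "fuse"))
    train = BiomarkerTable.from_csv(_require(outdir / "split_train.csv",
                                             "fuse"))
    test = BiomarkerTable.from_csv(_require(outdir / "split_test.csv",
                                            "fuse"))
    surviving = metrics[(metrics["sensitivity"] >= config.sen_min)
                        & (metrics["specificity"] >= config.spec_min)]
    if surviving.empty:
        raise ValueError("no panel survived screening; nothing to fuse")
    panels = [pnl.PanelSpec(tuple(FeatureId.from_column(c)
                                  for c in pid.split("+")))
              for pid in surviving["panel"]]
    fused, fused_metrics = mdl.fuse_lda(panels, train, test, config.seed)
    fused.to_json(outdir / "fused_model.json")
    _write_json(outdir / "fused_metrics.json", fused_metrics.rounded())
    return fused, fused_metrics


def run_optimize(config: RunConfig, outdir: str | Path) -> mdl.OptimizeResult:
    outdir = Path(outdir)
    metrics = pd.read_csv(_require(outdir / "panel_metrics.csv", "optimize"))
    table = BiomarkerTable.from_csv(_require(outdir / "biomarkers.csv",
                                             "optimize"))
    surviving = metrics[(metrics["sensitivity"] >= config.sen_min)
                        & (metrics["specificity"] >= config.spec_min)]
    if surviving.empty:
        raise ValueError("no surviving panels; nothing to optimize")
    biomarkers: list[FeatureId] = []
    for pid in surviving["panel"]:
        for col in pid.split("+"):
            fid = FeatureId.from_column(col)
            if fid not in biomarkers:
                biomarkers.append(fid)
    cap = None
    if config.scale < 1.0:
        full = pnl.stage2_counts(len(biomarkers),
                                 config.stage2_max_size)["total"]
        cap = max(1, math.ceil(config.scale * full))
    result = mdl.optimize_min_subset(
        biomarkers, table, max_size=config.stage2_max_size,
        folds=config.folds, sen_min=config.sen_min, spec_min=config.spec_min,
        seed=config.seed, max_panels=cap)
    result.model.to_json(outdir / "optimized_model.json")
    _write_json(outdir / "optimize_summary.json", {
        "panel": result.panel.panel_id,
        "size": result.panel.size,
        "compliant": result.compliant,
        "n_evaluated": result.n_evaluated,
        "cv_metrics": result.cv_metrics.rounded(),
        "n_candidate_biomarkers": len(biomarkers),
    })
    return result


def run_validate(config: RunConfig, outdir: str | Path,
                 table: BiomarkerTable | None = None,
                 model_file: str = "fused_model.json"
                 ) -> mdl.PerformanceMetrics:
    outdir = Path(outdir)
    model = mdl.DiagnosticModel.from_json(_require(outdir / model_file,
                                                   "validate"))
    if table is None:
        table = BiomarkerTable.from_csv(_require(outdir / "split_test.csv",
                                                 "validate"))
    metrics = mdl.validate(model, table)
    _write_json(outdir / "validation_metrics.json", metrics.rounded())
    return metrics


def run_all(config: RunConfig, outdir: str | Path) -> dict:
    """The whole pipeline on a simulated cohort; returns a run summary."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    run_simulate(config, outdir)
    run_extract(config, outdir)
    report = run_select(config, outdir)
    audit = run_panels(config, outdir)
    run_screen(config, outdir)
    summary: dict = {
        "selected_features": report.selected_features,
        "selected_channels": report.selected_channels,
        "selected_pairs": report.selected_pairs,
        "panel_audit": audit,
    }
    try:
        _, fused_metrics = run_fuse(config, outdir)
        summary["fused_metrics"] = fused_metrics.rounded()
        opt = run_optimize(config, outdir)
        summary["optimized_panel"] = opt.panel.panel_id
        summary["optimized_compliant"] = opt.compliant
    except ValueError as exc:
        summary["note"] = str(exc)
    _write_json(outdir / "run_summary.json", summary)
    return summary
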