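"""End-to-end pipeline: simulate -> connect -> metrics -> alff -> stats -> classify.

Each stage reads its inputs from the artifact directory written by earlier
stages and writes open-format outputs (TSV/JSON), so stages can be re-run
independently. A JSON run manifest records parameters, seed, package
version and sha256 hashes of every artifact.
"""
from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .alff import alff_node_metrics
from .atlas import AtlasHierarchy, load_default_hierarchy, load_hierarchy
from .classify import assemble_features, crossval_svm, write_feature_tsv
from .connectivity import (extract_node_timecourses, pearson_connectivity,
                           proportional_threshold, read_matrix_tsv,
                           write_matrix_tsv)
from .containers import metrics_to_frame
from .errors import PipelineError
from .metrics import global_metrics, node_metrics
from .simulate import CohortDesign, generate_cohort, read_cohort_tsv, write_cohort_tsv
from .stats import compare_groups, summarize_connectivity, write_summary_tsv

STAGES = ("simulate", "connect", "metrics", "alff", "stats", "classify")

DEFAULT_CONFIG = {
    "seed": 0,
    "hierarchy": "packaged",
    "stages": list(STAGES),
    "cohort": {
        "n_patients": 21, "n_controls": 20, "n_timepoints": 240,
        "tr_seconds": 2.0, "voxels_per_parcel": 10,
        "effect_nodes": [], "coupling_reduction": 0.0,
        "alff_reduction": 0.0, "noise_sd": 1.0,
    },
    "band": [0.01, 0.1],
    "threshold_p": 0.5,
    "alpha": 0.05,
    "k_folds": 10,
    "svm": {"kernel": "linear", "C": 1.0},
    "metrics_for_classification": ["clustering", "local_efficiency",
                                   "betweenness", "alff"],
}


def load_config(path) -> dict:
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))      # deep copy
    for key, value in user.items():
        if isinstance(value, dict) and isinstance(cfg.get(key), dict):
            cfg[key].update(value)
        else:
            cfg[key] = value
    return cfg


def _hierarchy_from_config(cfg: dict) -> AtlasHierarchy:
    if cfg.get("hierarchy", "packaged") == "packaged":
        return load_default_hierarchy()
    return load_hierarchy(cfg["hierarchy"])


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _groups_from_manifest(out_dir: Path) -> dict[str, str]:
    manifest = pd.read_csv(out_dir / "cohort" / "manifest.tsv", sep="\t")
    return dict(zip(manifest["subject_id"], manifest["group"]))


def run_pipeline(config: dict, out_dir, stages: Optional[list[str]] = None) -> Path:
    """Execute the requested stages in pipeline order; returns the artifact dir.

    Raises :class:`PipelineError` naming the failing stage. Unknown stage
    names are rejected before any work is done.
    """
    requested = list(stages if stages is not None else config.get("stages", STAGES))
    unknown = [s for s in requested if s not in STAGES]
    if unknown:
        raise PipelineError(f"unknown stage(s): {unknown}")
    ordered = [s for s in STAGES if s in requested]

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    h = _hierarchy_from_config(config)

    for stage in ordered:
        try:
            _STAGE_FUNCS[stage](config, out_dir, h)
        except PipelineError:
            raise
        except Exception as exc:                      # noqa: BLE001 - wrap with stage name
            raise PipelineError(f"stage '{stage}' failed: {exc}") from exc

    manifest = {
        "package_version": __version__,
        "seed": config["seed"],
        "parameters": {k: v for k, v in config.items() if k != "stages"},
        "stages_run": ordered,
        "artifacts": {
            str(p.relative_to(out_dir)): _sha256(p)
            for p in sorted(out_dir.rglob("*"))
            if p.is_file() and p.name != "run_manifest.json"
        },
    }
    with open(out_dir / "run_manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return out_dir


def _stage_simulate(cfg: dict, out_dir: Path, h: AtlasHierarchy) -> None:
    c = cfg["cohort"]
    design = CohortDesign(
        hierarchy=h,
        n_patients=int(c["n_patients"]), n_controls=int(c["n_controls"]),
        n_timepoints=int(c["n_timepoints"]), tr_seconds=float(c["tr_seconds"]),
        voxels_per_parcel=c["voxels_per_parcel"],
        band=tuple(cfg["band"]),
        module_coupling=c.get("module_coupling"),
        effect_nodes=frozenset(c.get("effect_nodes", [])),
        coupling_reduction=float(c.get("coupling_reduction", 0.0)),
        alff_reduction=float(c.get("alff_reduction", 0.0)),
        noise_sd=float(c.get("noise_sd", 1.0)),
        seed=int(cfg["seed"]),
    )
    subjects = generate_cohort(design)
    write_cohort_tsv(subjects, out_dir / "cohort")
    with open(out_dir / "cohort" / "design.yaml", "w") as fh:
        yaml.safe_dump({**c, "seed": cfg["seed"], "band": list(cfg["band"]),
                        "n_scales": h.n_scales}, fh)


def _stage_connect(cfg: dict, out_dir: Path, h: AtlasHierarchy) -> None:
    subjects = read_cohort_tsv(out_dir / "cohort" / "manifest.tsv")
    conn_dir = out_dir / "connectivity"
    for s in range(1, h.n_scales + 1):
        sdir = conn_dir / f"scale{s}"
        sdir.mkdir(parents=True, exist_ok=True)
        for ts in subjects:
            node_ts = extract_node_timecourses(ts, ts.unit_labels, h, s)
            write_matrix_tsv(pearson_connectivity(node_ts),
                             sdir / f"{ts.subject_id}.tsv")


def _stage_metrics(cfg: dict, out_dir: Path, h: AtlasHierarchy) -> None:
    groups = _groups_from_manifest(out_dir)
    p = float(cfg["threshold_p"])
    vectors, global_rows = [], []
    for s in range(1, h.n_scales + 1):
        sdir = out_dir / "connectivity" / f"scale{s}"
        for sid in sorted(groups):
            m = read_matrix_tsv(sdir / f"{sid}.tsv", scale=s, subject_id=sid)
            g = proportional_threshold(m, p)
            vectors.extend(node_metrics(g))
            gm = global_metrics(g)
            global_rows.append({"subject_id": sid, "scale": s,
                                "global_clustering": gm.global_clustering,
                                "global_efficiency": gm.global_efficiency})
    mdir = out_dir / "metrics"
    mdir.mkdir(parents=True, exist_ok=True)
    metrics_to_frame(vectors).to_csv(mdir / "node_metrics.tsv", sep="\t",
                                     index=False, float_format="%.8g")
    pd.DataFrame(global_rows).to_csv(mdir / "global_metrics.tsv", sep="\t",
                                     index=False, float_format="%.8g")


def _stage_alff(cfg: dict, out_dir: Path, h: AtlasHierarchy) -> None:
    subjects = read_cohort_tsv(out_dir / "cohort" / "manifest.tsv")
    vectors = []
    for ts in subjects:
        vectors.extend(alff_node_metrics(ts, h, band=tuple(cfg["band"])))
    mdir = out_dir / "metrics"
    mdir.mkdir(parents=True, exist_ok=True)
    metrics_to_frame(vectors).to_csv(mdir / "alff_metrics.tsv", sep="\t",
                                     index=False, float_format="%.8g")


def _load_metric_tables(out_dir: Path) -> pd.DataFrame:
    frames = []
    for name in ("node_metrics.tsv", "alff_metrics.tsv"):
        path = out_dir / "metrics" / name
        if path.exists():
            frames.append(pd.read_csv(path, sep="\t"))
    if not frames:
        raise PipelineError("no metric tables found; run metrics/alff first")
    return pd.concat(frames, ignore_index=True)


def _stage_stats(cfg: dict, out_dir: Path, h: AtlasHierarchy) -> None:
    groups = _groups_from_manifest(out_dir)
    sdir = out_dir / "stats"
    sdir.mkdir(parents=True, exist_ok=True)
    # connectivity summaries per scale on the unthresholded matrices
    for s in range(1, h.n_scales + 1):
        cdir = out_dir / "connectivity" / f"scale{s}"
        pats = [read_matrix_tsv(cdir / f"{sid}.tsv", scale=s, subject_id=sid)
                for sid, g in sorted(groups.items()) if g == "patient"]
        cons = [read_matrix_tsv(cdir / f"{sid}.tsv", scale=s, subject_id=sid)
                for sid, g in sorted(groups.items()) if g == "control"]
        write_summary_tsv(summarize_connectivity(pats, cons), sdir)
    results = compare_groups(_load_metric_tables(out_dir), groups,
                             alpha=float(cfg["alpha"]))
    results.to_csv(sdir / "nodewise_tests.tsv", sep="\t", index=False,
                   float_format="%.8g")
    summary = (results.groupby(["metric_name", "scale"])
               [["significant_uncorrected", "significant_fdr"]]
               .sum().astype(int).reset_index()
               .to_dict(orient="records"))
    with open(sdir / "summary.json", "w") as fh:
        json.dump({"alpha": cfg["alpha"], "families": summary}, fh, indent=2)


def _stage_classify(cfg: dict, out_dir: Path, h: AtlasHierarchy) -> None:
    groups = _groups_from_manifest(out_dir)
    table = _load_metric_tables(out_dir)
    cdir = out_dir / "classification"
    cdir.mkdir(parents=True, exist_ok=True)
    svm = cfg.get("svm", {})
    reports = {}
    for metric in cfg["metrics_for_classification"]:
        for scales in list(range(1, h.n_scales + 1)) + ["all"]:
            fm = assemble_features(table, metric, scales, h, groups)
            rep = crossval_svm(fm, k_folds=int(cfg["k_folds"]),
                               seed=int(cfg["seed"]),
                               kernel=svm.get("kernel", "linear"),
                               C=float(svm.get("C", 1.0)))
            key = f"{metric}_scale_{scales}"
            reports[key] = rep.to_dict()
            if scales == "all":
                write_feature_tsv(fm, cdir / f"features_{metric}_combined.tsv")
    with open(cdir / "reports.json", "w") as fh:
        json.dump(reports, fh, indent=2)


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "connect": _stage_connect,
    "metrics": _stage_metrics,
    "alff": _stage_alff,
    "stats": _stage_stats,
    "classify": _stage_classify,
}
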