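"""Group-level statistics: connectivity summaries, node-wise t-tests, FDR.

Connectivity is summarised on the unthresholded correlation matrices
(mean per group, control-minus-patient difference, per-group SD). Node
metrics are compared with a two-tailed two-sample Student's t-test
(pooled variance by default, Welch behind a flag) and corrected with
Benjamini-Hochberg FDR applied per (metric, scale) family.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sp_stats
from statsmodels.stats.multitest import multipletests

from .containers import ConnectivityMatrix, NodeMetricVector
from .connectivity import connectivity_stack


@dataclass
class GroupConnectivitySummary:
    """Elementwise group summaries of connectivity matrices at one scale."""

    patient_mean: np.ndarray
    control_mean: np.ndarray
    difference: np.ndarray           # control mean - patient mean
    patient_sd: np.ndarray
    control_sd: np.ndarray
    scale: int
    node_ids: np.ndarray


@dataclass
class NodewiseTestResult:
    """Per-node two-sample test with BH-FDR, one (metric, scale) family."""

    node_ids: np.ndarray
    t_statistic: np.ndarray
    p_value: np.ndarray
    fdr_q: np.ndarray
    significant_uncorrected: np.ndarray
    significant_fdr: np.ndarray
    patient_mean: np.ndarray
    control_mean: np.ndarray
    scale: int
    metric_name: str
    alpha: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "node_id": self.node_ids,
            "scale": self.scale,
            "metric_name": self.metric_name,
            "patient_mean": self.patient_mean,
            "control_mean": self.control_mean,
            "t": self.t_statistic,
            "p": self.p_value,
            "q": self.fdr_q,
            "significant_uncorrected": self.significant_uncorrected,
            "significant_fdr": self.significant_fdr,
        })


def summarize_connectivity(patient_mats: Sequence[ConnectivityMatrix],
                           control_mats: Sequence[ConnectivityMatrix]
                           ) -> GroupConnectivitySummary:
    """Elementwise mean, control-minus-patient difference, and per-group SD."""
    if len(patient_mats) < 2 or len(control_mats) < 2:
        raise ValueError("need at least 2 subjects per group")
    scales = {m.scale for m in patient_mats} | {m.scale for m in control_mats}
    if len(scales) != 1:
        raise ValueError(f"matrices span multiple scales: {sorted(scales)}")
    pat = connectivity_stack(list(patient_mats) + list(control_mats))[:len(patient_mats)]
    con = connectivity_stack(list(control_mats) + list(patient_mats))[:len(control_mats)]
    return GroupConnectivitySummary(
        patient_mean=pat.mean(axis=0),
        control_mean=con.mean(axis=0),
        difference=con.mean(axis=0) - pat.mean(axis=0),
        patient_sd=pat.std(axis=0, ddof=1),
        control_sd=con.std(axis=0, ddof=1),
        scale=scales.pop(),
        node_ids=patient_mats[0].node_ids,
    )


def metric_matrix(vectors: Sequence[NodeMetricVector]) -> tuple[np.ndarray, np.ndarray]:
    """Stack one metric vector per subject into (n_subjects, n_nodes)."""
    ids = vectors[0].node_ids
    for v in vectors:
        if not np.array_equal(v.node_ids, ids):
            raise ValueError("node ids differ across subjects")
    return np.stack([v.values for v in vectors]), ids


def nodewise_ttest(metric_patients, metric_controls, alpha: float = 0.05,
                   equal_var: bool = True) -> NodewiseTestResult:
    """Two-tailed two-sample t-test per node, with BH-FDR across nodes.

    Inputs are (n_subjects, n_nodes) arrays or sequences of
    :class:`NodeMetricVector` (one per subject). Nodes where the pooled
    variance is zero get t = 0, p = 1 with a warning.
    """
    scale, metric_name = 0, ""
    if not isinstance(metric_patients, np.ndarray):
        scale = metric_patients[0].scale
        metric_name = metric_patients[0].metric_name
        pat, node_ids = metric_matrix(metric_patients)
        con, _ = metric_matrix(metric_controls)
    else:
        pat = np.asarray(metric_patients, dtype=float)
        con = np.asarray(metric_controls, dtype=float)
        node_ids = np.arange(pat.shape[1])
    if pat.shape[0] < 2 or con.shape[0] < 2:
        raise ValueError("need at least 2 subjects per group")
    if pat.shape[1] != con.shape[1]:
        raise ValueError("groups must share the node set")

    with np.errstate(divide="ignore", invalid="ignore"):
        t, p = sp_stats.ttest_ind(pat, con, axis=0, equal_var=equal_var)
    t = np.asarray(t, dtype=float)
    p = np.asarray(p, dtype=float)
    degenerate = ~np.isfinite(t)
    if degenerate.any():
        warnings.warn(f"{int(degenerate.sum())} node(s) have zero pooled variance; "
                      "reporting t=0, p=1", RuntimeWarning, stacklevel=2)
        t[degenerate] = 0.0
        p[degenerate] = 1.0
    q, reject = fdr_bh(p, alpha)
    return NodewiseTestResult(
        node_ids=node_ids, t_statistic=t, p_value=p, fdr_q=q,
        significant_uncorrected=p < alpha, significant_fdr=reject,
        patient_mean=pat.mean(axis=0), control_mean=con.mean(axis=0),
        scale=scale, metric_name=metric_name, alpha=alpha,
    )


def fdr_bh(p_values: np.ndarray, alpha: float = 0.05
           ) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up: q-values and rejection mask at ``alpha``."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, q, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
    return q, reject


def compare_groups(metric_table: pd.DataFrame, groups: dict[str, str],
                   alpha: float = 0.05, equal_var: bool = True) -> pd.DataFrame:
    """Run node-wise tests for every (metric, scale) family in a tidy table.

    ``metric_table`` columns: subject_id, scale, node_id, metric_name, value.
    ``groups`` maps subject_id to "patient"/"control".
    """
    frames = []
    for (metric, scale), sub in metric_table.groupby(["metric_name", "scale"]):
        wide = sub.pivot(index="subject_id", columns="node_id", values="value")
        if wide.isna().any().any():
            raise ValueError(f"missing values for metric {metric} scale {scale}")
        grp = wide.index.map(groups)
        pat = wide[grp == "patient"].to_numpy()
        con = wide[grp == "control"].to_numpy()
        res = nodewise_ttest(pat, con, alpha=alpha, equal_var=equal_var)
        frame = res.to_frame()
        frame["node_id"] = wide.columns.to_numpy()
        frame["scale"] = scale
        frame["metric_name"] = metric
        frames.append(frame)
    return pd.concat(frames, ignore_index=True)


def write_summary_tsv(s: GroupConnectivitySummary, out_dir) -> None:
    from pathlib import Path

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    ids = [str(int(i)) for i in s.node_ids]
    for name in ("patient_mean", "control_mean", "difference",
                 "patient_sd", "control_sd"):
        pd.DataFrame(getattr(s, name), index=ids, columns=ids).to_csv(
            out_dir / f"{name}_scale{s.scale}.tsv", sep="\t",
            float_format="%.8g")
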