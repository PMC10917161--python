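"""Shared cohort-simulation helpers for the statistical test suites.

Study conditions for the cohort-level checks: a 16-parcel / 4-module /
2-half hierarchy, 4 voxels per parcel, TR = 2 s, 240 timepoints,
module couplings (0.75, 0.4) and unit noise — a compact network with the
clear within- vs between-module correlation contrast the generator is
documented to produce. The group effect, when present, removes half the
shared coupling of one whole module (a focal subnetwork disconnection).
"""
from __future__ import annotations

import warnings

import numpy as np

from netpyramid.alff import alff_node_metrics
from netpyramid.atlas import AtlasHierarchy
from netpyramid.connectivity import (extract_node_timecourses,
                                     pearson_connectivity,
                                     proportional_threshold)
from netpyramid.metrics import (betweenness_centrality,
                                clustering_coefficients, local_efficiency)
from netpyramid.simulate import CohortDesign, generate_cohort
from netpyramid.stats import nodewise_ttest

GRAPH_METRICS = ("clustering", "local_efficiency", "betweenness")
COUPLING = (0.75, 0.4)
NOISE_SD = 1.0
VOXELS = 4
EFFECT_MODULE = (1, 2, 3, 4)          # finest parcels of module 1


def make_design(h: AtlasHierarchy, seed: int, effect_nodes=(),
                coupling_reduction=0.0, alff_reduction=0.0,
                n_per_group=20) -> CohortDesign:
    return CohortDesign(
        hierarchy=h, n_patients=n_per_group, n_controls=n_per_group,
        voxels_per_parcel=VOXELS, module_coupling=COUPLING, noise_sd=NOISE_SD,
        effect_nodes=frozenset(effect_nodes),
        coupling_reduction=coupling_reduction, alff_reduction=alff_reduction,
        seed=seed)


def graph_metric_tests(subjects, h, scale, p=0.5, alpha=0.05):
    """Node-wise t-tests for the three graph metrics at one scale."""
    vals = {m: {"patient": [], "control": []} for m in GRAPH_METRICS}
    for ts in subjects:
        nts = extract_node_timecourses(ts, ts.unit_labels, h, scale)
        g = proportional_threshold(pearson_connectivity(nts), p)
        vals["clustering"][ts.group].append(clustering_coefficients(g).values)
        vals["local_efficiency"][ts.group].append(local_efficiency(g).values)
        vals["betweenness"][ts.group].append(betweenness_centrality(g).values)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")     # coarse scales can be degenerate
        return {m: nodewise_ttest(np.array(v["patient"]),
                                  np.array(v["control"]), alpha=alpha)
                for m, v in vals.items()}


def alff_tests(subjects, h, scales=(1,), alpha=0.05):
    """Node-wise t-tests on node-averaged ALFF at the requested scales."""
    per_scale = {s: {"patient": [], "control": []} for s in scales}
    for ts in subjects:
        vecs = alff_node_metrics(ts, h)
        for s in scales:
            per_scale[s][ts.group].append(vecs[s - 1].values)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return {s: nodewise_ttest(np.array(v["patient"]),
                                  np.array(v["control"]), alpha=alpha)
                for s, v in per_scale.items()}


def simulate_cohort(h, seed, **kwargs):
    return generate_cohort(make_design(h, seed, **kwargs))
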