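"""Whole-pipeline simulation studies: null calibration and power.

These routines run the real per-subject chain (simulate -> detrend ->
band-pass -> correlate -> binarize -> nodal metrics -> AUC -> node-wise
t-tests) across many synthetic cohorts.  They back the package's two
self-checks:

* **null calibration** — with no planted effect and no score-topology
  linkage, the node-wise two-sample t-test should reject at close to the
  nominal alpha;
* **planted recovery** — a clustering deficit planted at known nodes
  should put exactly those nodes into the clustering-coefficient
  significant set, with the patient group mean below the control mean.
"""

from __future__ import annotations

import numpy as np
from scipy import stats as sps

from .connectivity import SparsityGrid, build_networks
from .metrics import METRIC_NAMES, auc_over_grid, compute_metric
from .simulate import SimulationConfig, make_group_truth, sample_subject_timeseries


def simulate_cohort_auc(config: SimulationConfig, grid: SparsityGrid,
                        metrics=METRIC_NAMES):
    """In-memory cohort: per-subject nodal AUCs and group labels.

    Returns ``(auc, groups)`` with auc[metric] of shape (n_subjects, N),
    subjects ordered AD block then NC block, matching generate_cohort.
    """
    truths = {g: make_group_truth(config, g) for g in ("AD", "NC")}
    subjects = [("AD", i) for i in range(config.n_ad)] + [
        ("NC", i) for i in range(config.n_nc)
    ]
    per_metric = {m: [] for m in metrics}
    groups = []
    for si, (group, _) in enumerate(subjects):
        ts = sample_subject_timeseries(
            truths[group], config.T,
            np.random.default_rng([config.seed, 11, si]),
            tr_seconds=config.tr_seconds,
        )
        nets = build_networks(ts, grid)
        for m in metrics:
            cube = np.column_stack([compute_metric(m, g) for g in nets])
            per_metric[m].append(auc_over_grid(cube, grid))
        groups.append(group)
    auc = {m: np.vstack(v) for m, v in per_metric.items()}
    return auc, np.array(groups)


def _nodewise_t(auc: dict[str, np.ndarray], groups: np.ndarray):
    ad, nc = groups == "AD", groups == "NC"
    out = {}
    for m, mat in auc.items():
        t, p = sps.ttest_ind(mat[ad], mat[nc], axis=0, equal_var=True)
        out[m] = (t, p, mat[ad].mean(axis=0) - mat[nc].mean(axis=0))
    return out


def null_calibration(n_reps: int = 500, seed: int = 0, *,
                     n_per_group: tuple[int, int] = (15, 15),
                     n_regions: int = 20, T: int = 120,
                     grid: SparsityGrid | None = None,
                     alpha: float = 0.05,
                     metrics=METRIC_NAMES) -> dict:
    """Type-I error of the full pipeline on no-effect cohorts.

    Every node-wise test in every replicate is a draw from the null;
    the rejection fraction estimates the achieved test size.
    """
    grid = grid or SparsityGrid.from_spec(10, 50, 10)
    rejections = 0
    total = 0
    for rep in range(n_reps):
        config = SimulationConfig(
            n_ad=n_per_group[0], n_nc=n_per_group[1], n_regions=n_regions,
            T=T, seed=seed + 1009 * (rep + 1), planted_effects=[],
            upsit_topology_weight=0.0,
        )
        auc, groups = simulate_cohort_auc(config, grid, metrics)
        for _, p, _ in _nodewise_t(auc, groups).values():
            rejections += int((p < alpha).sum())
            total += p.size
    return {
        "rejection_rate": rejections / total,
        "n_rejections": rejections,
        "n_tests": total,
        "n_reps": n_reps,
        "alpha": alpha,
    }


def planted_recovery(n_reps: int = 50, seed: int = 0, *,
                     n_per_group: tuple[int, int] = (20, 20),
                     n_regions: int = 90, T: int = 230,
                     magnitude: float = 0.6,
                     grid: SparsityGrid | None = None,
                     alpha: float = 0.05) -> dict:
    """Recovery of a planted clustering deficit by the clustering test.

    A node counts as recovered in a replicate when its clustering AUC
    differs between groups at p < alpha *and* the AD mean is below the
    NC mean (the planted direction).
    """
    grid = grid or SparsityGrid.default()
    node_hits = None
    both_hits = 0
    planted = None
    for rep in range(n_reps):
        config = SimulationConfig(
            n_ad=n_per_group[0], n_nc=n_per_group[1], n_regions=n_regions,
            T=T, seed=seed + 7919 * (rep + 1), upsit_topology_weight=0.0,
        )
        config.planted_effects = [
            type(e)(e.node, "cluster_deficit", magnitude) for e in config.planted_effects
        ]
        planted = config.planted_nodes
        if node_hits is None:
            node_hits = np.zeros(len(planted), dtype=int)
        auc, groups = simulate_cohort_auc(config, grid, metrics=("clustering",))
        _, p, mean_diff = _nodewise_t(auc, groups)["clustering"]
        hits = (p[planted] < alpha) & (mean_diff[planted] < 0)
        node_hits += hits
        both_hits += int(hits.all())
    return {
        "per_node_rates": (node_hits / n_reps).tolist(),
        "all_nodes_rate": both_hits / n_reps,
        "planted_nodes": planted,
        "n_reps": n_reps,
        "alpha": alpha,
    }
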