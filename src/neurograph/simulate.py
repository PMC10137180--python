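"""Synthetic two-group cohorts with planted nodal-topology effects.

The generator exists so that the whole correlation -> binarize -> metric
-> statistics chain can be exercised, calibrated and power-tested
without access to real fMRI.  Each group is described by a ground-truth
undirected graph; group covariance is derived from the (possibly
modified) adjacency so that *topological* group differences survive the
correlation/binarization chain:

    Sigma_g = D^{-1/2} (w A_g + lambda I) D^{-1/2},

with the diagonal loading ``lambda`` auto-increased until Sigma_g is
positive definite.  Since A has zero diagonal this reduces to
Sigma = (w A + lambda I) / lambda: adjacent regions correlate at
w / lambda, non-adjacent at 0.

The control (NC) truth is a random geometric graph at density ~0.15 —
geometric graphs are spatially clustered, like parcellated cortex, so a
node's neighbours share many edges and clustering-type effects have
somewhere to act.  The patient (AD) truth is the same base graph with
planted effects applied at chosen nodes:

* ``cluster_deficit``(v, m): remove a fraction m of the edges among v's
  neighbours (lowers v's clustering / local efficiency);
* ``degree_gain``(v, m): connect v to a fraction m of its non-neighbours
  (raises v's degree).

Subject time series are AR(1)-filtered Gaussian innovations with the
group covariance, plus white measurement noise; behavioral scores are
drawn around the group means/SDs with an optional component tied to the
subject's measured topology (sign-aligned so that higher network
integrity means higher UPSIT/MMSE/MoCA/MES/BNT and lower CDR).
Everything is deterministic under (config, seed, subject index).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy.signal import lfilter
from scipy.spatial.distance import pdist

from .atlas import (
    CohortTable,
    ConfigurationError,
    RegionAtlas,
    SubjectRecord,
    TimeSeriesMatrix,
    synthetic_atlas,
    write_cohort,
    write_timeseries,
)
from .connectivity import SparsityGrid, build_networks
from .metrics import auc_over_grid, clustering_coefficient

#: Group score parameters (mean, sd): the study-cohort descriptive values.
DEFAULT_SCORE_PARAMS = {
    "AD": {
        "MMSE": (18.76, 5.82),
        "MoCA": (13.47, 5.21),
        "MES": (45.47, 17.94),
        "CDR": (1.59, 0.78),
        "BNT": (12.40, 7.75),
        "UPSIT": (13.13, 5.09),
    },
    "NC": {
        "MMSE": (27.82, 2.18),
        "MoCA": (23.29, 3.23),
        "MES": (85.70, 13.89),
        "CDR": (0.20, 0.25),
        "BNT": (22.58, 3.16),
        "UPSIT": (23.23, 5.87),
    },
}

DEFAULT_DEMOGRAPHICS = {
    "AD": {"age": (66.69, 7.03), "education": (10.95, 4.18), "p_male": 8 / 23},
    "NC": {"age": (63.44, 8.16), "education": (10.94, 3.78), "p_male": 4 / 18},
}

#: Scores where higher values mean better function (CDR is reversed).
_POSITIVE_SCORES = ("MMSE", "MoCA", "MES", "BNT", "UPSIT")

from .atlas import SCORE_RANGES  # noqa: E402  (clipping ranges shared with I/O)


@dataclass
class PlantedEffect:
    node: int  # 0-based node index
    kind: str  # "cluster_deficit" | "degree_gain"
    magnitude: float  # fraction in [0, 1]

    def __post_init__(self) -> None:
        if self.kind not in ("cluster_deficit", "degree_gain"):
            raise ConfigurationError(f"unknown effect kind {self.kind!r}")
        if not 0.0 <= self.magnitude <= 1.0:
            raise ConfigurationError("effect magnitude must be in [0, 1]")


def _default_planted(n_regions: int) -> list[PlantedEffect]:
    """Bilateral temporal-pole clustering deficit on the full atlas
    (TPOmid.L/R, 1-based indices 87/88); last region pair otherwise."""
    if n_regions == 90:
        nodes = (86, 87)
    else:
        nodes = (n_regions - 2, n_regions - 1)
    return [PlantedEffect(v, "cluster_deficit", 0.6) for v in nodes]


@dataclass
class SimulationConfig:
    n_ad: int = 23
    n_nc: int = 18
    n_regions: int = 90
    T: int = 230
    tr_seconds: float = 2.0
    seed: int = 0
    density: float = 0.15
    edge_weight: float = 1.0
    diag_load_margin: float = 0.5  # extra loading beyond PD threshold, in units of w
    ar_coefficient: float = 0.3
    noise_sd: float = 0.25
    planted_effects: list[PlantedEffect] | None = None
    upsit_topology_weight: float = 0.4  # beta in [0, 1)
    score_params: dict = field(default_factory=lambda: DEFAULT_SCORE_PARAMS)
    demographics: dict = field(default_factory=lambda: DEFAULT_DEMOGRAPHICS)

    def __post_init__(self) -> None:
        if self.n_ad < 1 or self.n_nc < 1:
            raise ConfigurationError("group sizes must be positive")
        if self.T < 30:
            raise ConfigurationError("T must be at least 30")
        if not 0.0 <= self.ar_coefficient < 1.0:
            raise ConfigurationError("AR coefficient must be in [0, 1)")
        if not 0.0 <= self.upsit_topology_weight < 1.0:
            raise ConfigurationError("topology weight beta must be in [0, 1)")
        if not 0.0 < self.density < 1.0:
            raise ConfigurationError("density must be in (0, 1)")
        if self.planted_effects is None:
            self.planted_effects = _default_planted(self.n_regions)
        else:
            self.planted_effects = [
                e if isinstance(e, PlantedEffect) else PlantedEffect(*e)
                for e in self.planted_effects
            ]
        for e in self.planted_effects:
            if not 0 <= e.node < self.n_regions:
                raise ConfigurationError(f"planted node {e.node} out of range")

    @property
    def planted_nodes(self) -> list[int]:
        return [e.node for e in self.planted_effects]

    def atlas(self) -> RegionAtlas:
        return synthetic_atlas(self.n_regions)


@dataclass
class GroupTruth:
    group: str
    base_adjacency: np.ndarray
    adjacency: np.ndarray  # after planted effects
    sigma: np.ndarray
    chol: np.ndarray
    edge_weight: float
    diag_load: float
    ar_coefficient: float
    noise_sd: float
    planted_effects: list[PlantedEffect]


def _geometric_adjacency(n: int, density: float, rng: np.random.Generator) -> np.ndarray:
    """Random geometric-style graph: the m closest point pairs on the
    unit square become edges, m = round(density * n(n-1)/2)."""
    pts = rng.random((n, 2))
    d = pdist(pts)
    iu, ju = np.triu_indices(n, k=1)
    m = int(round(density * n * (n - 1) / 2))
    keep = np.argsort(d, kind="stable")[:m]
    A = np.zeros((n, n), dtype=bool)
    A[iu[keep], ju[keep]] = True
    return A | A.T


def _apply_effects(A: np.ndarray, effects: list[PlantedEffect],
                   rng: np.random.Generator) -> np.ndarray:
    A = A.copy()
    for eff in effects:
        v = eff.node
        nbrs = np.flatnonzero(A[v])
        if eff.kind == "cluster_deficit":
            iu, ju = np.triu_indices(len(nbrs), k=1)
            pairs = [(nbrs[i], nbrs[j]) for i, j in zip(iu, ju) if A[nbrs[i], nbrs[j]]]
            k_remove = int(round(eff.magnitude * len(pairs)))
            if k_remove:
                chosen = rng.choice(len(pairs), size=k_remove, replace=False)
                for c in chosen:
                    i, j = pairs[c]
                    A[i, j] = A[j, i] = False
        else:  # degree_gain
            non = np.setdiff1d(np.flatnonzero(~A[v]), [v])
            k_add = int(round(eff.magnitude * len(non)))
            if k_add:
                chosen = rng.choice(len(non), size=k_add, replace=False)
                for c in chosen:
                    A[v, non[c]] = A[non[c], v] = True
    return A


def _covariance_from_adjacency(A: np.ndarray, w: float, margin: float) -> tuple[np.ndarray, float]:
    """Sigma = (w A + lambda I)/lambda with lambda auto-raised until PD."""
    Af = A.astype(float)
    eigmin = float(np.linalg.eigvalsh(Af).min())
    lam = w * (max(0.0, -eigmin) + margin)
    for _ in range(60):
        sigma = (w * Af + lam * np.eye(len(Af))) / lam
        if np.linalg.eigvalsh(sigma).min() > 1e-10:
            return sigma, lam
        lam *= 1.5
    raise RuntimeError("could not make covariance positive definite")


def make_group_truth(config: SimulationConfig, group: str) -> GroupTruth:
    """Ground truth for one group; AD = NC base graph + planted effects."""
    if group not in ("AD", "NC"):
        raise ConfigurationError(f"unknown group {group!r}")
    base_rng = np.random.default_rng([config.seed, 101])
    A = _geometric_adjacency(config.n_regions, config.density, base_rng)
    if group == "AD":
        eff_rng = np.random.default_rng([config.seed, 102])
        A_g = _apply_effects(A, config.planted_effects, eff_rng)
    else:
        A_g = A.copy()
    sigma, lam = _covariance_from_adjacency(A_g, config.edge_weight,
                                            config.diag_load_margin)
    return GroupTruth(
        group=group,
        base_adjacency=A,
        adjacency=A_g,
        sigma=sigma,
        chol=np.linalg.cholesky(sigma),
        edge_weight=config.edge_weight,
        diag_load=lam,
        ar_coefficient=config.ar_coefficient,
        noise_sd=config.noise_sd,
        planted_effects=config.planted_effects if group == "AD" else [],
    )


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def sample_subject_timeseries(truth: GroupTruth, T: int, seed, *,
                              tr_seconds: float = 2.0,
                              subject_id: str = "sim") -> TimeSeriesMatrix:
    """AR(1)-filtered correlated Gaussian series plus white noise.

    x_t = phi * x_{t-1} + eps_t with eps ~ N(0, Sigma_g); a 50-sample
    burn-in is discarded so the output is stationary.
    """
    if T < 30:
        raise ConfigurationError("T must be at least 30")
    rng = _as_rng(seed)
    n = truth.sigma.shape[0]
    burn = 50
    z = rng.standard_normal((T + burn, n))
    eps = z @ truth.chol.T
    phi = truth.ar_coefficient
    x = lfilter([1.0], [1.0, -phi], eps, axis=0)[burn:] if phi else eps[burn:]
    if truth.noise_sd:
        x = x + truth.noise_sd * rng.standard_normal((T, n))
    return TimeSeriesMatrix(subject_id=subject_id, data=x, tr_seconds=tr_seconds)


def sample_behavioral_scores(config: SimulationConfig, group: str,
                             subject_topology_summary: float, seed) -> dict[str, float]:
    """Scores = group mean + SD * z, z mixing noise with the (standardized)
    topology summary at weight beta; clipped to the valid scale ranges."""
    beta = config.upsit_topology_weight
    rng = _as_rng(seed)
    out = {}
    for name, (mean, sd) in config.score_params[group].items():
        sign = 1.0 if name in _POSITIVE_SCORES else -1.0
        z = np.sqrt(1.0 - beta**2) * rng.standard_normal() + sign * beta * subject_topology_summary
        lo, hi = SCORE_RANGES.get(name, (-np.inf, np.inf))
        out[name] = float(np.clip(mean + sd * z, lo, hi))
    return out


def _topology_summary_grid() -> SparsityGrid:
    # coarse sweep is enough to rank subjects for the score linkage
    return SparsityGrid.from_spec(10, 50, 5)


def _subject_topology_summary(ts: TimeSeriesMatrix, nodes: list[int]) -> float:
    """Mean clustering-coefficient AUC at the planted nodes (all nodes if
    none are planted) — the 'network integrity' scalar scores attach to."""
    grid = _topology_summary_grid()
    nets = build_networks(ts, grid)
    cube = np.column_stack([clustering_coefficient(g) for g in nets])
    auc = auc_over_grid(cube, grid)
    sel = auc[nodes] if nodes else auc
    return float(sel.mean())


def generate_cohort(config: SimulationConfig, out_dir) -> tuple[CohortTable, list[Path], dict]:
    """Write cohort CSV, one time-series TSV per subject, and a manifest.

    The manifest records the config, per-subject seeds and the planted
    ground truth (the recovery-test key).  Outputs are byte-identical
    across reruns of the same config.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    atlas = config.atlas()
    truths = {g: make_group_truth(config, g) for g in ("AD", "NC")}

    subjects = [("AD", i) for i in range(config.n_ad)] + [
        ("NC", i) for i in range(config.n_nc)
    ]
    ts_paths: list[Path] = []
    series: list[TimeSeriesMatrix] = []
    meta = []
    for si, (group, gi) in enumerate(subjects):
        sid = f"{group}{gi + 1:02d}"
        ts = sample_subject_timeseries(
            truths[group], config.T, np.random.default_rng([config.seed, 11, si]),
            tr_seconds=config.tr_seconds, subject_id=sid,
        )
        path = out_dir / f"sub-{sid}.tsv"
        write_timeseries(ts, path, atlas)
        ts_paths.append(path)
        series.append(ts)
        meta.append((sid, group, si))

    beta = config.upsit_topology_weight
    if beta > 0:
        raw = np.array(
            [_subject_topology_summary(ts, config.planted_nodes) for ts in series]
        )
        sd = raw.std()
        topo = (raw - raw.mean()) / sd if sd > 0 else np.zeros_like(raw)
    else:
        topo = np.zeros(len(series))

    records = []
    for (sid, group, si), t in zip(meta, topo):
        demo_rng = np.random.default_rng([config.seed, 17, si])
        dem = config.demographics[group]
        age = float(dem["age"][0] + dem["age"][1] * demo_rng.standard_normal())
        edu = float(
            max(0.0, dem["education"][0] + dem["education"][1] * demo_rng.standard_normal())
        )
        sex = "M" if demo_rng.random() < dem["p_male"] else "F"
        scores = sample_behavioral_scores(
            config, group, float(t), np.random.default_rng([config.seed, 13, si])
        )
        records.append(
            SubjectRecord(subject_id=sid, group=group, age=age, sex=sex,
                          education=edu, scores=scores)
        )
    cohort = CohortTable(records)
    write_cohort(cohort, out_dir / "cohort.csv")

    manifest = {
        "note": "synthetic cohort; ground truth below is the recovery-test key",
        "config": {
            **{k: v for k, v in asdict(config).items()
               if k not in ("score_params", "demographics", "planted_effects")},
            "planted_effects": [asdict(e) for e in config.planted_effects],
        },
        "subject_seeds": {sid: [config.seed, 11, si] for sid, _, si in meta},
        "planted_nodes": config.planted_nodes,
        "planted_abbrevs": [atlas.abbrevs[v] for v in config.planted_nodes],
        "truth_edges": {g: int(t.adjacency.sum() // 2) for g, t in truths.items()},
        "diag_load": {g: truths[g].diag_load for g in truths},
    }
    with open(out_dir / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return cohort, ts_paths, manifest
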