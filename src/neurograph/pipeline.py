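"""Pipeline orchestration: simulate -> connect -> metrics -> analyze.

One :class:`RunConfig` describes a full reproducible run.  Outputs go to
a run directory: the serialized config, the cohort and per-subject time
series (when simulating), a long-format nodal metrics table, the three
analysis tables (demographics, node-wise group differences, behavior
correlations) and a human-readable markdown report.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .atlas import (
    CohortTable,
    ConfigurationError,
    RegionAtlas,
    ValidationError,
    load_atlas,
    read_cohort,
    read_timeseries,
    synthetic_atlas,
)
from .connectivity import SparsityGrid, build_networks
from .metrics import METRIC_NAMES, auc_over_grid, compute_all_metrics
from .simulate import PlantedEffect, SimulationConfig, generate_cohort
from .stats import run_group_analysis

log = logging.getLogger("neurograph")


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and offending item."""


@dataclass
class RunConfig:
    out_dir: str = "neurograph-run"
    seed: int = 0
    # input: either simulate=True (synthetic cohort) or ts_dir + cohort_csv
    simulate: bool = True
    sim: dict = field(default_factory=dict)  # SimulationConfig overrides
    ts_dir: str | None = None
    cohort_csv: str | None = None
    n_regions: int = 90
    tr_seconds: float = 2.0
    n_discard: int = 0
    low_hz: float = 0.01
    high_hz: float = 0.1
    grid: str = "0.10:0.50:0.01"
    metrics: tuple[str, ...] = METRIC_NAMES
    agg: str = "auc"  # "auc" (trapezoid) or "mean" (auc / grid span)
    alpha: float = 0.05
    fdr: bool = False
    welch: bool = False
    scores: tuple[str, ...] = ("UPSIT",)
    write_cube: bool = False  # also write per-threshold metric values

    def __post_init__(self) -> None:
        if self.agg not in ("auc", "mean"):
            raise ConfigurationError("agg must be 'auc' or 'mean'")
        unknown = set(self.metrics) - set(METRIC_NAMES)
        if unknown:
            raise ConfigurationError(f"unknown metrics {sorted(unknown)}")
        if not 0 < self.alpha <= 1:
            raise ConfigurationError("alpha must be in (0, 1]")
        if not self.simulate and (self.ts_dir is None or self.cohort_csv is None):
            raise ConfigurationError("need ts_dir and cohort_csv when not simulating")
        SparsityGrid.parse(self.grid)  # validate early

    @property
    def sparsity_grid(self) -> SparsityGrid:
        return SparsityGrid.parse(self.grid)

    def sim_config(self) -> SimulationConfig:
        kwargs = dict(self.sim)
        kwargs.setdefault("seed", self.seed)
        kwargs.setdefault("n_regions", self.n_regions)
        kwargs.setdefault("tr_seconds", self.tr_seconds)
        if "planted_effects" in kwargs and kwargs["planted_effects"] is not None:
            kwargs["planted_effects"] = [
                PlantedEffect(**e) if isinstance(e, dict) else PlantedEffect(*e)
                for e in kwargs["planted_effects"]
            ]
        return SimulationConfig(**kwargs)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        known = cls.__dataclass_fields__
        bad = set(raw) - set(known)
        if bad:
            raise ConfigurationError(f"unknown config keys: {sorted(bad)}")
        for key in ("metrics", "scores"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        data = asdict(self)
        data["metrics"] = list(self.metrics)
        data["scores"] = list(self.scores)
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)


def _load_inputs(config: RunConfig, out: Path):
    if config.simulate:
        sim = config.sim_config()
        cohort, ts_paths, _ = generate_cohort(sim, out / "data")
        atlas = sim.atlas()
        tr = sim.tr_seconds
    else:
        atlas = load_atlas() if config.n_regions == 90 else synthetic_atlas(config.n_regions)
        cohort = read_cohort(config.cohort_csv)
        ts_dir = Path(config.ts_dir)
        ts_paths = []
        for rec in cohort.records:
            candidates = [ts_dir / f"sub-{rec.subject_id}.tsv",
                          ts_dir / f"{rec.subject_id}.tsv",
                          ts_dir / f"sub-{rec.subject_id}.csv",
                          ts_dir / f"{rec.subject_id}.csv"]
            hit = next((p for p in candidates if p.exists()), None)
            if hit is None:
                raise ValidationError(
                    f"no time-series file for subject {rec.subject_id!r} in {ts_dir}"
                )
            ts_paths.append(hit)
        tr = config.tr_seconds
    return atlas, cohort, ts_paths, tr


def run_pipeline(config: RunConfig) -> Path:
    """Execute all stages; returns the run directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")
    grid = config.sparsity_grid
    span = grid.values[-1] - grid.values[0]
    t0 = time.time()
    log.info("run start: seed=%d grid=%s out=%s", config.seed, config.grid, out)

    stage = "input"
    try:
        atlas, cohort, ts_paths, tr = _load_inputs(config, out)
        log.info("input: %d subjects (%d AD / %d NC), %d regions",
                 len(cohort.records), cohort.n_ad, cohort.n_nc, atlas.n_regions)

        stage = "connect+metrics"
        auc: dict[str, list[np.ndarray]] = {m: [] for m in config.metrics}
        long_rows = []
        for rec, path in zip(cohort.records, ts_paths):
            ts = read_timeseries(path, atlas, subject_id=rec.subject_id, tr_seconds=tr)
            nets = build_networks(
                ts, grid, low_hz=config.low_hz, high_hz=config.high_hz,
                n_discard=config.n_discard, atlas=atlas,
            )
            cube, subj_auc = compute_all_metrics(nets, grid, metrics=config.metrics)
            for m in config.metrics:
                vals = subj_auc[m] / span if config.agg == "mean" else subj_auc[m]
                auc[m].append(vals)
                for k, region in enumerate(atlas.abbrevs):
                    long_rows.append((rec.subject_id, m, region, "AUC", vals[k]))
                if config.write_cube:
                    for ki, s in enumerate(grid):
                        for k, region in enumerate(atlas.abbrevs):
                            long_rows.append(
                                (rec.subject_id, m, region, f"{s:.2f}", cube[m][k, ki])
                            )
        metrics_frame = pd.DataFrame(
            long_rows, columns=["subject_id", "metric", "region", "threshold", "value"]
        )
        metrics_frame.to_csv(out / "metrics.csv", index=False, float_format="%.12g")
        log.info("metrics: %d rows", len(metrics_frame))

        stage = "analyze"
        auc_mat = {m: np.vstack(v) for m, v in auc.items()}
        demo, diff, corr = run_group_analysis(
            auc_mat, cohort, atlas, alpha=config.alpha, welch=config.welch,
            fdr=config.fdr, scores=config.scores,
        )
        demo.frame.to_csv(out / "demographics.csv", index=False, float_format="%.12g")
        diff.frame.to_csv(out / "group_diff.csv", index=False, float_format="%.12g")
        corr.frame.to_csv(out / "behavior_corr.csv", index=False, float_format="%.12g")
        log.info("analyze: %d significant node rows, %d correlation rows",
                 int(diff.frame["significant"].sum()), len(corr.frame))

        stage = "report"
        render_report(out)
    except (ValidationError, ConfigurationError) as exc:
        raise PipelineError(f"stage '{stage}': {exc}") from exc
    log.info("run complete in %.1f s", time.time() - t0)
    return out


def _md_table(frame: pd.DataFrame) -> str:
    """Small GitHub-style table formatter (numbers to 4 significant figures)."""

    def fmt(v):
        if isinstance(v, float):
            return f"{v:.4g}"
        return str(v)

    cols = list(frame.columns)
    lines = ["| " + " | ".join(cols) + " |",
             "| " + " | ".join("---" for _ in cols) + " |"]
    for _, row in frame.iterrows():
        lines.append("| " + " | ".join(fmt(row[c]) for c in cols) + " |")
    return "\n".join(lines)


def render_report(run_dir) -> Path:
    """Markdown summary: significant nodes per metric with direction
    markers, the behavior-correlation table, and demographics."""
    run_dir = Path(run_dir)
    needed = ["demographics.csv", "group_diff.csv", "behavior_corr.csv"]
    missing = [n for n in needed if not (run_dir / n).exists()]
    if missing:
        raise PipelineError(f"stage 'report': missing tables {missing}")
    demo = pd.read_csv(run_dir / "demographics.csv")
    diff = pd.read_csv(run_dir / "group_diff.csv")
    corr = pd.read_csv(run_dir / "behavior_corr.csv")

    lines = ["# Nodal network analysis report", ""]
    lines += ["## Demographics and behavioral scores", ""]
    lines += [_md_table(demo), ""]
    lines += ["## Significant node-wise group differences", ""]
    sig = diff[diff["significant"]]
    if sig.empty:
        lines += ["No node survived the significance rule.", ""]
    for metric, chunk in sig.groupby("metric"):
        lines += [f"### {metric}", ""]
        for _, row in chunk.iterrows():
            marker = "increase" if row["direction"] == "AD>NC" else "decrease"
            lines += [
                f"- {row['region']}: AD {marker} vs NC "
                f"(t = {row['t']:.3f}, p = {row['p']:.4f})"
            ]
        lines += [""]
    lines += ["## Behavior-topology correlations", ""]
    if corr.empty:
        lines += ["No correlations computed (no significant nodes or scores).", ""]
    else:
        lines += [_md_table(corr), ""]
    report = run_dir / "report.md"
    report.write_text("\n".join(lines), encoding="utf-8")
    return report
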