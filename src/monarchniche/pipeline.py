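"""Config-driven orchestration of the full modelling chain.

One validated config describes a run: where the current and future layer
stacks and occurrence records come from (files, or the synthetic
generator), which variable-elimination method to use, how the
regularization multiplier beta is tuned, and what diagnostics to emit.
A run executes

    occurrence thinning -> beta optimization (coarse sweep + bracket)
    -> variable elimination -> final beta scan on the retained layers
    -> final fit -> current surface -> projected surface -> shift report

writing every intermediate artifact (model JSON, AICc tables as CSV,
elimination trace JSON, surfaces as ASCII grids, report JSON/markdown).
Runs are idempotent: identical config + seed give byte-identical
artifacts.

The ``none`` elimination method reproduces the unoptimized protocol: all
layers, beta fixed at 1.0 (the conventional default), no scans.  Its
projected surface can be near-uniformly low — a non-transferable model;
the report flags this (mean projected probability under a config
threshold) rather than asserting it.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass
from itertools import combinations
from pathlib import Path
from typing import Literal, Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict
from scipy.stats import pearsonr

from . import elimination as elim
from . import selection
from .grids import (Grid, load_stack, read_ascii_grid,
                    read_occurrences, write_ascii_grid, write_occurrences)
from .maxent import (FeatureSpace, MaxentModel, build_features,
                     fit_maxent, percent_contribution)
from .occurrences import OccurrenceSet, thin
from .projection import ProbabilitySurface, project_model, shift_report
from .synthetic import benchmark_dataset

log = logging.getLogger(__name__)


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


class SyntheticConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    nrows: int = 100
    ncols: int = 100
    variables: list[str] = ["tmin", "precipitation"]
    active: dict[str, float] = {"tmin_Jan": 3.0, "precipitation_Feb": 2.0}
    n_groves: int = 170
    warming: float = 2.0


class PathsConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    current_stack_dir: Path
    future_stack_dir: Optional[Path] = None
    occurrences_csv: Path
    elevation_asc: Optional[Path] = None


class RunConfig(BaseModel):
    """Everything a run needs; unknown keys are rejected."""

    model_config = ConfigDict(extra="forbid")

    seed: int = 0
    synthetic: Optional[SyntheticConfig] = None
    paths: Optional[PathsConfig] = None
    elimination: Literal["top_variable_uncorrelated", "uncorrelated",
                         "none"] = "top_variable_uncorrelated"
    base_beta: Optional[float] = None      # None -> coarse sweep + bracket
    final_scan: bool = True
    replicates: int = 10
    replicate_mode: Literal["bootstrap", "subsample", "identical"] = "bootstrap"
    feature_classes: list[str] = ["linear", "quadratic", "product"]
    threshold_r: float = 0.7
    threshold_pc: float = 5.0
    thresholds: list[float] = [0.25, 0.5, 0.75]
    clamp: bool = True
    dedupe_cells: bool = True
    max_background: int = 10_000
    low_mean_flag: float = 0.1

    def with_seed(self, seed: int | None) -> "RunConfig":
        return self if seed is None else self.model_copy(update={"seed": seed})


def load_config(path: str | Path) -> RunConfig:
    path = Path(path)
    text = path.read_text()
    if path.suffix in (".yaml", ".yml"):
        import yaml
        data = yaml.safe_load(text)
    else:
        data = json.loads(text)
    return RunConfig.model_validate(data)


@dataclass
class RunResult:
    """In-memory handle on a completed run."""

    config: RunConfig
    report: dict
    model: MaxentModel
    features: FeatureSpace
    current_surface: ProbabilitySurface
    future_surface: Optional[ProbabilitySurface]
    occurrences: OccurrenceSet
    presence_cells: np.ndarray
    elevation: Optional[Grid]
    out_dir: Optional[Path]


def _load_inputs(config: RunConfig):
    if (config.synthetic is None) == (config.paths is None):
        raise ValueError("config must set exactly one of synthetic / paths")
    if config.synthetic is not None:
        s = config.synthetic
        data = benchmark_dataset(
            seed=config.seed, nrows=s.nrows, ncols=s.ncols,
            variables=tuple(s.variables), active=s.active,
            n_groves=s.n_groves, warming=s.warming)
        return data.current, data.future, data.records, data.elevation
    p = config.paths
    current = load_stack({f.stem: f for f in
                          sorted(Path(p.current_stack_dir).glob("*.asc"))})
    future = None
    if p.future_stack_dir is not None:
        future = load_stack({f.stem: f for f in
                             sorted(Path(p.future_stack_dir).glob("*.asc"))})
    records = read_occurrences(p.occurrences_csv)
    elevation = (read_ascii_grid(p.elevation_asc)
                 if p.elevation_asc is not None else None)
    return current, future, records, elevation


def run_pipeline(config: RunConfig, out_dir: str | Path | None = None,
                 seed: int | None = None) -> RunResult:
    """Execute the full chain; see the module docstring for the stages."""
    config = config.with_seed(seed)
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    report: dict = {"config": json.loads(config.model_dump_json()),
                    "seed": config.seed}
    stage = "load"
    t0 = time.monotonic()
    try:
        current, future, records, elevation = _load_inputs(config)
        log.info("stage load: %d layers, %d raw records (%.1fs)",
                 len(current), len(records), time.monotonic() - t0)

        stage = "thin"
        occ = thin(records, current, dedupe_cells=config.dedupe_cells)
        report["occurrences"] = occ.provenance.as_dict()
        report["occurrences"]["n_used"] = len(occ)
        if out is not None:
            write_occurrences(occ.records, out / "occurrences_thinned.csv")
        grid = current.grid
        presence_cells = np.array(
            sorted({grid.flat_index(lon, lat) for lon, lat in occ.points}),
            dtype=int)

        stage = "select_beta"
        classes = frozenset(config.feature_classes)
        full_features = build_features(
            current, presence_cells, classes=classes,
            max_background=config.max_background, seed=config.seed)
        if config.elimination == "none":
            base_beta = config.base_beta if config.base_beta is not None else 1.0
            report["beta"] = {"base": base_beta, "protocol": "fixed"}
        elif config.base_beta is not None:
            base_beta = config.base_beta
            report["beta"] = {"base": base_beta, "protocol": "fixed"}
        else:
            coarse = selection.coarse_beta_sweep(
                full_features, replicates=config.replicates,
                seed=config.seed, mode=config.replicate_mode)
            bracket = selection.bracket_beta(
                full_features, coarse, replicates=config.replicates,
                seed=config.seed, mode=config.replicate_mode)
            base_beta = bracket.best_beta
            report["beta"] = {
                "base": base_beta, "protocol": "coarse+bracket",
                "coarse_best": coarse.best_beta,
                "coarse_mean_aicc": coarse.mean_aicc(),
                "bracket_mean_aicc": bracket.mean_aicc()}
            if out is not None:
                coarse.table().to_csv(out / "aicc_coarse.csv", index=False)
                bracket.table().to_csv(out / "aicc_bracket.csv", index=False)

        stage = "eliminate"
        if config.elimination == "none":
            retained = list(current.names)
            trace = None
        else:
            fn = (elim.eliminate_top_variable_uncorrelated
                  if config.elimination == "top_variable_uncorrelated"
                  else elim.eliminate_uncorrelated)
            kwargs = dict(classes=classes, seed=config.seed)
            if config.elimination == "top_variable_uncorrelated":
                kwargs["threshold_pc"] = config.threshold_pc
            retained, trace = fn(current, presence_cells, base_beta,
                                 threshold_r=config.threshold_r, **kwargs)
            if out is not None:
                trace.to_json(out / "elimination_trace.json")
        report["elimination"] = {
            "method": config.elimination,
            "retained_layers": [str(n) for n in retained],
        }
        if not retained:
            raise RuntimeError("variable elimination retained no layers")

        stage = "final_beta"
        sub = current.subset(retained)
        features = build_features(sub, presence_cells, classes=classes,
                                  max_background=config.max_background,
                                  seed=config.seed)
        if config.elimination != "none" and config.final_scan:
            final = selection.final_beta_scan(
                features, replicates=config.replicates,
                seed=config.seed, mode=config.replicate_mode)
            final_beta = final.best_beta
            report["beta"]["final"] = final_beta
            report["beta"]["final_mean_aicc"] = final.mean_aicc()
            if out is not None:
                final.table().to_csv(out / "aicc_final.csv", index=False)
        else:
            final_beta = base_beta
            report["beta"]["final"] = final_beta

        stage = "fit"
        model = fit_maxent(features, beta=final_beta, seed=config.seed)
        contrib = percent_contribution(model)
        report["model"] = {
            "beta": final_beta,
            "k": selection.count_parameters(model),
            "entropy": model.entropy,
            "n_presence": int(model.n_presence),
            "percent_contribution": contrib.as_dict(),
        }
        if out is not None:
            model.to_json(out / "model.json")

        stage = "project"
        current_surface = project_model(model, sub, clamp=config.clamp)
        future_surface = None
        if future is not None:
            future_surface = project_model(model, future.subset(retained),
                                           clamp=config.clamp)
        if out is not None:
            write_ascii_grid(current_surface.grid, out / "surface_current.asc")
            if future_surface is not None:
                write_ascii_grid(future_surface.grid, out / "surface_future.asc")

        stage = "report"
        p_occ = current_surface.grid.values.ravel()[presence_cells]
        report["probability_at_occurrences"] = {
            "min": float(p_occ.min()), "max": float(p_occ.max())}
        if future_surface is not None:
            shift = shift_report(current_surface, future_surface,
                                 thresholds=config.thresholds,
                                 elevation=elevation)
            report["shift"] = shift.as_dict()
            report["shift"]["projection_provenance"] = future_surface.provenance
            mean_future = float(future_surface.valid_values().mean())
            report["shift"]["mean_future_probability"] = mean_future
            report["non_transferable_model"] = bool(
                mean_future < config.low_mean_flag)
        if out is not None:
            (out / "report.json").write_text(
                json.dumps(report, sort_keys=True, indent=1))
            (out / "report.md").write_text(_markdown_summary(report))
        log.info("pipeline complete in %.1fs", time.monotonic() - t0)
        return RunResult(config, report, model, features, current_surface,
                         future_surface, occ, presence_cells, elevation, out)
    except Exception as exc:
        if isinstance(exc, StageError):
            raise
        log.error("pipeline aborted in stage %r: %s", stage, exc)
        raise StageError(stage, exc) from exc


def _markdown_summary(report: dict) -> str:
    lines = ["# Niche-model run summary", ""]
    occ = report.get("occurrences", {})
    lines += [f"- occurrences: {occ.get('n_raw')} raw records, "
              f"{occ.get('n_groves')} groves, {occ.get('n_used')} used"]
    beta = report.get("beta", {})
    lines += [f"- beta: base {beta.get('base')} ({beta.get('protocol')}), "
              f"final {beta.get('final')}"]
    el = report.get("elimination", {})
    lines += [f"- elimination ({el.get('method')}): retained "
              f"{', '.join(el.get('retained_layers', []))}"]
    m = report.get("model", {})
    lines += [f"- final model: k={m.get('k')}, entropy={m.get('entropy'):.4f}"]
    pc = m.get("percent_contribution", {}).get("percent", {})
    for name, v in sorted(pc.items(), key=lambda kv: -kv[1]):
        lines += [f"    - {name}: {v:.1f}%"]
    p = report.get("probability_at_occurrences", {})
    lines += [f"- probability at occurrences: {p.get('min'):.3f} "
              f"to {p.get('max'):.3f}"]
    if "shift" in report:
        s = report["shift"]
        rc, rf = s["elevation_r_current"], s["elevation_r_future"]
        lines += ["- elevation correlation: current "
                  f"{rc if rc is None else format(rc, '.3f')}, future "
                  f"{rf if rf is None else format(rf, '.3f')}"]
        if report.get("non_transferable_model"):
            lines += ["- WARNING: projected surface near-uniformly low "
                      "(non-transferable model)"]
    return "\n".join(lines) + "\n"


def compare_runs(results: list[RunResult]) -> pd.DataFrame:
    """Pairwise agreement of current surfaces plus per-run summaries.

    Returns a table with one row per run pair: Pearson r of the two
    current surfaces over shared valid cells; and per-run min/max
    probability at that run's occurrence cells.
    """
    if len(results) < 2:
        raise ValueError("need at least two runs to compare")
    rows = []
    for i, j in combinations(range(len(results)), 2):
        a, b = results[i], results[j]
        ga, gb = a.current_surface.grid, b.current_surface.grid
        if not ga.same_shape(gb):
            raise ValueError(f"runs {i} and {j}: surfaces misaligned")
        mask = ga.valid_mask() & gb.valid_mask()
        r = 1.0 if i == j else float(
            pearsonr(ga.values[mask], gb.values[mask])[0])
        rows.append({
            "run_a": i, "run_b": j, "surface_r": r,
            "p_occ_min_a": a.report["probability_at_occurrences"]["min"],
            "p_occ_max_a": a.report["probability_at_occurrences"]["max"],
            "p_occ_min_b": b.report["probability_at_occurrences"]["min"],
            "p_occ_max_b": b.report["probability_at_occurrences"]["max"],
        })
    return pd.DataFrame(rows)
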