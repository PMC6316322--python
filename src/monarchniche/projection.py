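"""Model transfer onto altered climate stacks and shift diagnostics.

A fitted niche model can be projected onto a stack with the same grid
but different layer values (for instance a 2050 scenario).  Features are
rebuilt with the *training* scaling ranges; by default, projected inputs
outside the training range are clamped to it (the count of clamped
entries is recorded), since outside that range the fitted response is
pure extrapolation.  The normalizer Z is recomputed over the projection
background, while the training-time entropy H is reused in the logistic
transform — so a model projected onto its own training stack reproduces
the training surface exactly.

Shift diagnostics summarize how a projected surface differs from the
current one: area above probability thresholds, correlation of each
surface with elevation, and a cellwise difference map.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.special import logsumexp
from scipy.stats import pearsonr

from .grids import AlignmentError, Grid, LayerStack
from .maxent import MaxentModel

log = logging.getLogger(__name__)


@dataclass
class ProbabilitySurface:
    """Grid of logistic outputs in (0,1), nodata outside the valid mask."""

    grid: Grid
    provenance: dict = field(default_factory=dict)

    def valid_values(self) -> np.ndarray:
        return self.grid.values[self.grid.valid_mask()]


def project_model(
    model: MaxentModel,
    stack: LayerStack,
    clamp: bool = True,
    recompute_entropy: bool = False,
) -> ProbabilitySurface:
    """Logistic probability surface of a fitted model over a stack.

    ``stack`` must supply every layer the model's features reference.
    With ``clamp`` on (the default), feature inputs outside the training
    range are pinned to it.  ``recompute_entropy`` replaces the training
    H with the projected distribution's own entropy, for sensitivity
    checks only.
    """
    missing = [n for n in model.layer_names
               if n not in {str(s) for s in stack.names}]
    if missing:
        raise KeyError(f"projection stack missing required layers: {missing}")

    mask = stack.valid_mask()
    cells = np.flatnonzero(mask.ravel())
    raw = stack.matrix(cells)
    names = [str(n) for n in stack.names]
    columns = {n: raw[:, j] for j, n in enumerate(names)}

    # Rebuild the full design matrix (training scaling ranges) so that the
    # transfer-identity property holds bit-for-bit: same matmul as training.
    n_clamped = 0
    cols = []
    for f in model.features:
        col, clamped = f.scaled(columns, clamp=clamp)
        n_clamped += clamped
        cols.append(col)
    design = (np.column_stack(cols) if cols
              else np.empty((cells.size, 0)))
    eta = design @ model.lambdas
    lnz = float(logsumexp(eta))
    q = np.exp(eta - lnz)
    entropy = float(-(q @ np.log(q))) if recompute_entropy else model.entropy
    s = np.exp(entropy) * q
    p = s / (1.0 + s)

    g = stack.grid
    values = np.full(g.nrows * g.ncols, g.nodata_value)
    values[cells] = p
    surface = ProbabilitySurface(
        g.like(values.reshape(g.nrows, g.ncols)),
        provenance={
            "n_cells": int(cells.size),
            "n_clamped_feature_values": int(n_clamped),
            "clamp": clamp,
            "entropy_used": entropy,
            "beta": model.beta,
        },
    )
    if not np.all(np.isfinite(p)) or p.min() <= 0 or p.max() >= 1:
        raise FloatingPointError("projected probabilities left (0, 1)")
    return surface


def area_above_threshold(
    surface: ProbabilitySurface, thresholds: Sequence[float]
) -> dict[float, int]:
    """Count of valid cells with p >= threshold, per threshold."""
    p = surface.valid_values()
    return {float(t): int(np.sum(p >= t)) for t in thresholds}


def elevation_correlation(surface: ProbabilitySurface, elevation: Grid) -> float:
    """Pearson r between the surface and elevation over shared valid cells."""
    if not surface.grid.same_shape(elevation):
        raise AlignmentError("surface and elevation grids misaligned")
    mask = surface.grid.valid_mask() & elevation.valid_mask()
    if mask.sum() < 2:
        raise ValueError("fewer than 2 shared valid cells")
    r, _ = pearsonr(surface.grid.values[mask], elevation.values[mask])
    return float(r)


def difference_map(current: ProbabilitySurface,
                   future: ProbabilitySurface) -> Grid:
    """Cellwise future - current; nodata propagates."""
    a, b = current.grid, future.grid
    if not a.same_shape(b):
        raise AlignmentError("surfaces misaligned")
    mask = a.valid_mask() & b.valid_mask()
    values = np.full(a.values.shape, a.nodata_value)
    values[mask] = b.values[mask] - a.values[mask]
    return a.like(values)


@dataclass
class ShiftReport:
    """Distribution-shift summary between a current and projected surface."""

    thresholds: dict[float, dict[str, int]]   # threshold -> {current, future}
    elevation_r_current: float | None
    elevation_r_future: float | None
    difference: dict[str, float]              # mean/min/max of future - current

    def as_dict(self) -> dict:
        return {
            "area_above_threshold": {
                str(t): dict(v) for t, v in self.thresholds.items()},
            "elevation_r_current": self.elevation_r_current,
            "elevation_r_future": self.elevation_r_future,
            "difference": dict(self.difference),
        }


def shift_report(
    current: ProbabilitySurface,
    future: ProbabilitySurface,
    thresholds: Sequence[float] = (0.25, 0.5, 0.75),
    elevation: Grid | None = None,
) -> ShiftReport:
    cur = area_above_threshold(current, thresholds)
    fut = area_above_threshold(future, thresholds)
    diff = difference_map(current, future)
    d = diff.values[diff.valid_mask()]
    return ShiftReport(
        thresholds={t: {"current": cur[t], "future": fut[t]}
                    for t in map(float, thresholds)},
        elevation_r_current=(None if elevation is None
                             else elevation_correlation(current, elevation)),
        elevation_r_future=(None if elevation is None
                            else elevation_correlation(future, elevation)),
        difference={"mean": float(d.mean()), "min": float(d.min()),
                    "max": float(d.max())},
    )
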