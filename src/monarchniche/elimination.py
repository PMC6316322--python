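"""Collinearity-driven variable elimination.

Highly correlated climate layers inflate model complexity and make
projection onto altered climates erratic, because the inter-layer
correlation structure itself changes.  Two iterative procedures reduce
the stack to a set of "top variables" whose pairwise correlations with
each promoted top variable stay below a threshold (default |r| >= 0.7
eliminates):

* ``top_variable_uncorrelated`` — each cycle fits a model on the
  remaining layers, drops layers contributing less than 5% of the
  training gain, promotes the highest-contribution layer to the top
  list, and drops the remaining layers correlated with it.
* ``uncorrelated`` — the relaxation: the low-contribution rule is
  skipped, so layers are eliminated by correlation only.  Its retained
  set is always a superset of the first method's.

Correlations are Pearson r computed once over the valid background cells
of the full stack; pairwise r does not change as layers are removed, so
the matrix is looked up thereafter.  The absolute value of r is
compared: a strong negative correlation is just as redundant as a
positive one.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .grids import LayerName, LayerStack
from .maxent import (DEFAULT_CLASSES, build_features, fit_maxent,
                     percent_contribution)

log = logging.getLogger(__name__)


@dataclass
class CorrelationMatrix:
    """Pearson r between layers over shared valid cells."""

    r: pd.DataFrame      # symmetric, diagonal 1, layer-name index/columns
    n_cells: int

    def __getitem__(self, pair: tuple[str, str]) -> float:
        return float(self.r.loc[pair[0], pair[1]])


def pairwise_correlation(stack: LayerStack,
                         cells: np.ndarray | None = None) -> CorrelationMatrix:
    """Pearson correlation of every layer pair over the valid-cell mask.

    A constant layer has undefined r; it is treated as uncorrelated
    (r = 0) with a warning, so it can never shadow another layer.
    """
    if cells is None:
        cells = np.flatnonzero(stack.valid_mask().ravel())
    if cells.size < 2:
        raise ValueError("need at least 2 valid cells for correlation")
    X = stack.matrix(cells)
    names = [str(n) for n in stack.names]
    sd = X.std(axis=0)
    const = sd == 0
    if const.any():
        log.warning("constant layers treated as r=0: %s",
                    [n for n, c in zip(names, const) if c])
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(X, rowvar=False)
    r = np.atleast_2d(r)
    r[np.isnan(r)] = 0.0
    np.fill_diagonal(r, 1.0)
    df = pd.DataFrame(np.clip(r, -1.0, 1.0), index=names, columns=names)
    return CorrelationMatrix(df, int(cells.size))


@dataclass
class EliminationCycle:
    beta: float
    contributions: dict[str, float]
    dropped_low_contribution: list[str]
    top: str | None
    dropped_correlated: list[tuple[str, float]]


@dataclass
class EliminationTrace:
    method: str
    threshold_r: float
    threshold_pc: float | None
    cycles: list[EliminationCycle] = field(default_factory=list)

    def retained(self) -> list[str]:
        """Replay the trace: the promoted top variables, in order."""
        return [c.top for c in self.cycles if c.top is not None]

    def eliminated(self) -> list[str]:
        out: list[str] = []
        for c in self.cycles:
            out += c.dropped_low_contribution
            out += [n for n, _ in c.dropped_correlated]
        return out

    def to_json(self, path: str | Path) -> None:
        payload = {
            "method": self.method,
            "threshold_r": self.threshold_r,
            "threshold_pc": self.threshold_pc,
            "cycles": [
                {"beta": c.beta, "contributions": c.contributions,
                 "dropped_low_contribution": c.dropped_low_contribution,
                 "top": c.top,
                 "dropped_correlated": [[n, r] for n, r in c.dropped_correlated]}
                for c in self.cycles
            ],
            "retained": self.retained(),
        }
        Path(path).write_text(json.dumps(payload, sort_keys=True, indent=1))


def _eliminate(
    stack: LayerStack,
    presence_cells: Sequence[int],
    beta: float,
    threshold_r: float,
    threshold_pc: float | None,
    method: str,
    classes=DEFAULT_CLASSES,
    background_cells: np.ndarray | None = None,
    corr: CorrelationMatrix | None = None,
    seed: int = 0,
) -> tuple[list[LayerName], EliminationTrace]:
    if corr is None:
        corr = pairwise_correlation(stack)
    trace = EliminationTrace(method, threshold_r, threshold_pc)
    remaining = [str(n) for n in stack.names]
    tops: list[str] = []

    while remaining:
        sub = stack.subset([LayerName.parse(n) for n in remaining])
        features = build_features(sub, presence_cells, background_cells,
                                  classes=classes, seed=seed)
        model = fit_maxent(features, beta=beta, seed=seed)
        table = percent_contribution(model)
        contributions = {n: table.percent.get(n, 0.0) for n in remaining}

        dropped_low: list[str] = []
        if threshold_pc is not None:
            dropped_low = [n for n in remaining
                           if contributions[n] < threshold_pc]
        candidates = [n for n in remaining if n not in dropped_low]

        if not table.defined or not candidates:
            # nothing gained a coefficient: everything left is uninformative
            trace.cycles.append(EliminationCycle(
                beta, contributions, sorted(set(dropped_low) | set(candidates)),
                None, []))
            break

        top = min(candidates, key=lambda n: (-contributions[n], n))
        dropped_corr = [
            (n, corr[top, n]) for n in candidates
            if n != top and abs(corr[top, n]) >= threshold_r
        ]
        trace.cycles.append(EliminationCycle(
            beta, contributions, dropped_low, top, dropped_corr))
        tops.append(top)
        assigned = set(dropped_low) | {top} | {n for n, _ in dropped_corr}
        remaining = [n for n in remaining if n not in assigned]
        log.info("elimination cycle %d: top=%s, dropped %d low, %d correlated",
                 len(trace.cycles), top, len(dropped_low), len(dropped_corr))

    return [LayerName.parse(n) for n in tops], trace


def eliminate_top_variable_uncorrelated(
    stack: LayerStack,
    presence_cells: Sequence[int],
    beta: float,
    threshold_r: float = 0.7,
    threshold_pc: float = 5.0,
    **kwargs,
) -> tuple[list[LayerName], EliminationTrace]:
    """Strict method: drop low-contribution layers, then correlated ones.

    Each cycle: fit on the remaining layers at ``beta``; eliminate layers
    with percent contribution below ``threshold_pc``; promote the
    highest-contribution layer; eliminate remaining layers with
    ``|r| >= threshold_r`` against it; repeat until every layer is
    assigned.  Returns the promoted top-variable list and the full trace.
    """
    return _eliminate(stack, presence_cells, beta, threshold_r, threshold_pc,
                      "top_variable_uncorrelated", **kwargs)


def eliminate_uncorrelated(
    stack: LayerStack,
    presence_cells: Sequence[int],
    beta: float,
    threshold_r: float = 0.7,
    **kwargs,
) -> tuple[list[LayerName], EliminationTrace]:
    """Relaxed method: eliminate by correlation only, never by contribution."""
    return _eliminate(stack, presence_cells, beta, threshold_r, None,
                      "uncorrelated", **kwargs)
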