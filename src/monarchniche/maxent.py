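"""Presence-only maximum-entropy niche model.

The model estimates a Gibbs distribution q(x) = exp(lambda . f(x)) / Z
over the background cells of a layer stack, chosen to maximize the
L1-penalized log-likelihood of the presence records

    J(lambda) = lambda . fbar  -  ln Z(lambda)  -  beta * sum_j s_j |lambda_j|

where ``fbar`` is the mean feature vector over presences, ``s_j`` is a
per-feature penalty scale (standard deviation of the feature over
presences divided by sqrt(m), the usual default-regularization
structure), and ``beta`` is the user-facing regularization multiplier:
larger beta gives sparser, smoother models.

Features are linear, quadratic and pairwise-product transforms of the
raw layers, each affinely rescaled to [0, 1] over the training
background; the scaling range doubles as the clamp range when the model
is transferred to a new layer stack.

The trainer is coordinate descent with an exact one-dimensional solve
per coordinate; within each full sweep the coordinates are visited in
order of decreasing KKT violation, so the gain of a sweep is attributed
to the feature that most needed updating (the convention that makes
percent contribution meaningful when features are collinear).  Because the smooth part of J is concave and the
conditional mean E_q[f_j] is monotone in lambda_j, each coordinate
subproblem reduces to a monotone root find (with the usual
soft-threshold test deciding whether the optimum sits at zero).  The
objective gain attributed to each coordinate update is recorded; percent
contribution is the per-layer share of those gains, Maxent's
training-path convention.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy.special import logsumexp

from .grids import LayerName, LayerStack

log = logging.getLogger(__name__)

DEFAULT_CLASSES = frozenset({"linear", "quadratic", "product"})
MAX_LAMBDA = 64.0  # bound on any single coefficient; hit only near separation
MAX_BACKGROUND = 10_000


class ConvergenceError(RuntimeError):
    def __init__(self, msg: str, trace: list[float]):
        super().__init__(msg)
        self.objective_trace = trace


@dataclass(frozen=True)
class Feature:
    """One model feature: a scaled transform of one or two layers."""

    kind: str                      # linear | quadratic | product
    parents: tuple[str, ...]       # layer names, as strings
    lo: float                      # raw-transform min over training background
    hi: float                      # raw-transform max (clamp range)

    def raw(self, columns: dict[str, np.ndarray]) -> np.ndarray:
        if self.kind == "linear":
            return columns[self.parents[0]]
        if self.kind == "quadratic":
            return columns[self.parents[0]] ** 2
        if self.kind == "product":
            return columns[self.parents[0]] * columns[self.parents[1]]
        raise ValueError(f"unknown feature kind {self.kind!r}")

    def scaled(self, columns: dict[str, np.ndarray], clamp: bool = True
               ) -> tuple[np.ndarray, int]:
        """Rescaled transform and the count of clamped entries."""
        raw = self.raw(columns)
        n_clamped = 0
        if clamp:
            n_clamped = int(np.sum((raw < self.lo) | (raw > self.hi)))
            raw = np.clip(raw, self.lo, self.hi)
        return (raw - self.lo) / (self.hi - self.lo), n_clamped


@dataclass
class FeatureSpace:
    """Design matrix over background cells plus per-feature metadata."""

    design: np.ndarray                 # (n_background, n_features), in [0,1]
    features: list[Feature]
    layer_names: list[str]             # layers that survived construction
    background_cells: np.ndarray       # flat grid indices, row-major
    presence_rows: np.ndarray          # rows of `design` that are presences

    @property
    def n_background(self) -> int:
        return self.design.shape[0]

    @property
    def n_features(self) -> int:
        return self.design.shape[1]


def build_features(
    stack: LayerStack,
    presence_cells: Sequence[int],
    background_cells: Sequence[int] | None = None,
    classes: Iterable[str] = DEFAULT_CLASSES,
    max_background: int = MAX_BACKGROUND,
    seed: int = 0,
) -> FeatureSpace:
    """Construct the [0,1]-scaled design matrix over the background.

    The background is every valid cell of the stack when there are at
    most ``max_background`` of them, otherwise a seeded uniform sample of
    that size; presence cells are always included (added to the
    background, the standard Maxent convention).  Features whose raw
    transform is constant over the background carry no information and
    are dropped with a warning.
    """
    classes = set(classes)
    unknown = classes - DEFAULT_CLASSES
    if unknown:
        raise ValueError(f"unknown feature classes {sorted(unknown)}")
    presence_cells = np.asarray(presence_cells, dtype=int)
    if presence_cells.size == 0:
        raise ValueError("no presence cells")

    valid = np.flatnonzero(stack.valid_mask().ravel())
    if background_cells is None:
        if valid.size > max_background:
            rng = np.random.default_rng(seed)
            background_cells = rng.choice(valid, size=max_background, replace=False)
        else:
            background_cells = valid
    background_cells = np.union1d(np.asarray(background_cells, dtype=int),
                                  presence_cells)

    raw = stack.matrix(background_cells)          # (N, L)
    names = [str(n) for n in stack.names]
    columns = {n: raw[:, j] for j, n in enumerate(names)}

    kept_layers = []
    for n in names:
        if np.ptp(columns[n]) == 0.0:
            log.warning("layer %s constant over background; features dropped", n)
        else:
            kept_layers.append(n)

    feats: list[Feature] = []
    cols: list[np.ndarray] = []

    def add(kind: str, parents: tuple[str, ...]) -> None:
        f = Feature(kind, parents, 0.0, 1.0)
        x = f.raw(columns)
        lo, hi = float(x.min()), float(x.max())
        if hi == lo:
            log.warning("feature %s%s constant; dropped", kind, parents)
            return
        feats.append(Feature(kind, parents, lo, hi))
        cols.append((x - lo) / (hi - lo))

    if "linear" in classes:
        for n in kept_layers:
            add("linear", (n,))
    if "quadratic" in classes:
        for n in kept_layers:
            add("quadratic", (n,))
    if "product" in classes:
        for a, b in combinations(kept_layers, 2):
            add("product", (a, b))

    design = np.column_stack(cols) if cols else np.empty((background_cells.size, 0))
    pos = {c: i for i, c in enumerate(background_cells)}
    presence_rows = np.array([pos[c] for c in presence_cells], dtype=int)
    return FeatureSpace(design, feats, kept_layers, background_cells, presence_rows)


@dataclass
class MaxentModel:
    """A fitted maximum-entropy model: coefficients plus everything
    needed to reproduce its outputs bit-identically."""

    features: list[Feature]
    layer_names: list[str]
    lambdas: np.ndarray
    beta: float
    penalty_scales: np.ndarray
    log_normalizer: float              # ln Z over the training background
    entropy: float                     # H of the raw distribution
    n_presence: int
    background_cells: np.ndarray
    seed: int
    gains: np.ndarray = field(default_factory=lambda: np.zeros(0))
    converged: bool = True
    n_sweeps: int = 0

    # -- outputs ------------------------------------------------------
    def raw_from_design(self, design: np.ndarray) -> tuple[np.ndarray, float]:
        """Raw probabilities for a full background design matrix.

        Returns (q, lnZ) with q strictly positive and summing to 1.
        """
        eta = design @ self.lambdas
        lnz = float(logsumexp(eta))
        return np.exp(eta - lnz), lnz

    def logistic_from_raw(self, q: np.ndarray) -> np.ndarray:
        s = np.exp(self.entropy) * q
        return s / (1.0 + s)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "layer_names": self.layer_names,
            "features": [
                {"kind": f.kind, "parents": list(f.parents),
                 "lo": f.lo, "hi": f.hi} for f in self.features
            ],
            "lambdas": self.lambdas.tolist(),
            "beta": self.beta,
            "penalty_scales": self.penalty_scales.tolist(),
            "log_normalizer": self.log_normalizer,
            "entropy": self.entropy,
            "n_presence": self.n_presence,
            "background_cells": self.background_cells.tolist(),
            "seed": self.seed,
            "gains": self.gains.tolist(),
            "converged": self.converged,
            "n_sweeps": self.n_sweeps,
        }
        Path(path).write_text(json.dumps(payload, sort_keys=True, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "MaxentModel":
        d = json.loads(Path(path).read_text())
        return cls(
            features=[Feature(f["kind"], tuple(f["parents"]), f["lo"], f["hi"])
                      for f in d["features"]],
            layer_names=d["layer_names"],
            lambdas=np.array(d["lambdas"]),
            beta=d["beta"],
            penalty_scales=np.array(d["penalty_scales"]),
            log_normalizer=d["log_normalizer"],
            entropy=d["entropy"],
            n_presence=d["n_presence"],
            background_cells=np.array(d["background_cells"], dtype=int),
            seed=d["seed"],
            gains=np.array(d["gains"]),
            converged=d["converged"],
            n_sweeps=d["n_sweeps"],
        )


# ---------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------

def _conditional_stats(q: np.ndarray, fj: np.ndarray,
                       delta: float) -> tuple[float, float]:
    """Mean and variance of f_j after moving lambda_j by delta."""
    if delta == 0.0:
        mean = float(q @ fj)
        return mean, float(q @ (fj * fj)) - mean * mean
    a = delta * fj
    a -= a.max()
    w = q * np.exp(a)
    s = w.sum()
    mean = float((w @ fj) / s)
    return mean, float((w @ (fj * fj)) / s) - mean * mean


def _solve_coordinate(q: np.ndarray, fj: np.ndarray, lam_j: float,
                      fbar_j: float, penalty: float) -> float:
    """Exact minimizer of the coordinate subproblem; returns new lambda_j.

    The stationarity condition at t != 0 is
        fbar_j - E_{q(t)}[f_j] = penalty * sign(t),
    and E[f_j] is non-decreasing in t (its derivative is the conditional
    variance), so the left side is monotone decreasing: the root find is
    exact.  The soft-threshold test at t = 0 decides the sign (or that 0
    is optimal); a bracketed, variance-based Newton iteration then
    converges quadratically, falling back on bisection whenever a step
    leaves the bracket.
    """
    def g(t: float) -> tuple[float, float]:
        mean, var = _conditional_stats(q, fj, t - lam_j)
        return fbar_j - mean, var

    g0, _ = g(0.0)
    if g0 > penalty:
        target, lo, hi = penalty, 0.0, 1.0
        while g(hi)[0] > target and hi < MAX_LAMBDA:
            lo, hi = hi, hi * 2
        hi = min(hi, MAX_LAMBDA)
        if g(hi)[0] > target:   # near-separation: pin at the bound
            return hi
    elif g0 < -penalty:
        target, lo, hi = -penalty, -1.0, 0.0
        while g(lo)[0] < target and lo > -MAX_LAMBDA:
            lo, hi = lo * 2, lo
        lo = max(lo, -MAX_LAMBDA)
        if g(lo)[0] < target:
            return lo
    else:
        return 0.0

    t = min(max(lam_j, lo), hi)
    for _ in range(60):
        val, var = g(t)
        h = val - target
        if abs(h) < 1e-13 or hi - lo < 1e-14:
            return t
        if h > 0:       # g decreasing: root is to the right
            lo = t
        else:
            hi = t
        step = h / var if var > 1e-12 else 0.0
        t_new = t + step
        if not (lo < t_new < hi):
            t_new = 0.5 * (lo + hi)
        t = t_new
    return t


def fit_maxent(
    features: FeatureSpace,
    presence_rows: Sequence[int] | None = None,
    beta: float = 1.0,
    seed: int = 0,
    max_sweeps: int = 10_000,
    tol: float = 1e-8,
    init_lambdas: np.ndarray | None = None,
) -> MaxentModel:
    """Fit by cyclic coordinate descent with exact 1-D solves.

    Deterministic: the sweep order is the fixed feature order and every
    1-D solve is exact, so identical inputs give bit-identical
    coefficients.  ``seed`` is stored for provenance (the optimizer
    itself draws no random numbers).

    Raises :class:`ConvergenceError` (carrying the objective trace) if the
    penalized objective has not stabilized to ``tol`` per full sweep
    within ``max_sweeps``.

    ``init_lambdas`` warm-starts the solve (used when scanning a beta
    path); the optimum is unchanged (the problem is convex) but the
    recorded per-feature gains then cover only the remaining path, so
    percent contribution should be read from cold-started fits.
    """
    if beta < 0:
        raise ValueError("beta must be non-negative")
    F = features.design
    N, K = F.shape
    rows = (features.presence_rows if presence_rows is None
            else np.asarray(presence_rows, dtype=int))
    m = rows.size
    if m == 0:
        raise ValueError("no presence rows")
    P = F[rows]
    fbar = P.mean(axis=0)
    scales = P.std(axis=0) / math.sqrt(m)
    scales = np.maximum(scales, 1e-6)  # keep the penalty proper, lambdas bounded
    penalties = beta * scales

    if init_lambdas is None:
        lam = np.zeros(K)
        eta = np.zeros(N)
        lnz = math.log(N)
        q = np.full(N, 1.0 / N)
    else:
        lam = np.array(init_lambdas, dtype=float)
        eta = F @ lam
        lnz = float(logsumexp(eta))
        q = np.exp(eta - lnz)
    gains = np.zeros(K)

    def objective() -> float:
        return float(fbar @ lam - lnz - penalties @ np.abs(lam))

    trace = [objective()]
    converged = False
    sweeps = 0
    for sweeps in range(1, max_sweeps + 1):
        grad = fbar - q @ F
        # KKT violation per coordinate; zero means the coordinate is optimal
        viol = np.where(
            lam != 0.0,
            np.abs(grad - penalties * np.sign(lam)),
            np.maximum(0.0, np.abs(grad) - penalties),
        )
        active = np.flatnonzero((lam != 0.0) | (viol > 1e-12))
        if active.size == 0:
            converged = True
            break
        # largest violation first: the gain of each sweep lands on the
        # feature that most needs updating (stable: ties keep index order)
        active = active[np.argsort(-viol[active], kind="stable")]
        for j in active:
            fj = F[:, j]
            new = _solve_coordinate(q, fj, lam[j], fbar[j], penalties[j])
            delta = new - lam[j]
            if delta == 0.0:
                continue
            # incremental objective bookkeeping
            a = delta * fj
            shift = a.max()
            lnz_new = lnz + shift + math.log(float(q @ np.exp(a - shift)))
            gain = (fbar[j] * delta - (lnz_new - lnz)
                    - penalties[j] * (abs(new) - abs(lam[j])))
            if gain > 0:
                gains[j] += gain
            lam[j] = new
            eta += a
            lnz = lnz_new
            q = np.exp(eta - lnz)
        # refresh against drift and test sweep-level improvement
        lnz = float(logsumexp(eta))
        q = np.exp(eta - lnz)
        trace.append(objective())
        if abs(trace[-1] - trace[-2]) < tol:
            converged = True
            break
    if not converged:
        raise ConvergenceError(
            f"no convergence after {max_sweeps} sweeps "
            f"(last step {trace[-1] - trace[-2]:.3e})", trace)
    # beyond ~MAX_LAMBDA/2 the gradient of a [0,1] feature underflows:
    # the coordinate is effectively unbounded (separation)
    if np.any(np.abs(lam) >= MAX_LAMBDA / 2):
        if beta == 0.0:
            raise ConvergenceError(
                "beta=0 with a (near-)separating feature: unbounded "
                "coefficient; use beta > 0", trace)
        log.warning("coefficient pinned at bound %g (near separation)", MAX_LAMBDA)

    entropy = float(-(q @ np.log(q)))
    return MaxentModel(
        features=features.features,
        layer_names=features.layer_names,
        lambdas=lam,
        beta=beta,
        penalty_scales=scales,
        log_normalizer=lnz,
        entropy=entropy,
        n_presence=m,
        background_cells=features.background_cells,
        seed=seed,
        gains=gains,
        converged=converged,
        n_sweeps=sweeps,
    )


# ---------------------------------------------------------------------
# Outputs and summaries
# ---------------------------------------------------------------------

def raw_output(model: MaxentModel, features: FeatureSpace,
               rows: Sequence[int] | None = None) -> np.ndarray:
    """Raw (Gibbs) probabilities; sums to 1 over the full background."""
    q, _ = model.raw_from_design(features.design)
    if rows is None:
        return q
    rows = np.asarray(rows, dtype=int)
    if rows.size and (rows.min() < 0 or rows.max() >= q.size):
        raise IndexError("cell outside background")
    return q[rows]


def logistic_output(model: MaxentModel, features: FeatureSpace,
                    rows: Sequence[int] | None = None) -> np.ndarray:
    """Logistic transform e^H q / (1 + e^H q), in (0, 1); 0.5 for a null model."""
    return model.logistic_from_raw(raw_output(model, features, rows))


def log_likelihood(model: MaxentModel, features: FeatureSpace,
                   presence_rows: Sequence[int] | None = None) -> float:
    """Sum of ln q(x) over presences (q normalized over the background)."""
    rows = (features.presence_rows if presence_rows is None
            else np.asarray(presence_rows, dtype=int))
    q = raw_output(model, features)
    return float(np.log(q[rows]).sum())


@dataclass
class ContributionTable:
    """Percent contribution per layer (training-path gain attribution)."""

    percent: dict[str, float]
    defined: bool = True

    def top_layer(self) -> str:
        # ties broken toward the lexicographically smallest name
        return min(self.percent, key=lambda n: (-self.percent[n], n))

    def as_dict(self) -> dict:
        return {"percent": dict(self.percent), "defined": self.defined}


def percent_contribution(model: MaxentModel) -> ContributionTable:
    """Share of training objective gain per layer, normalized to 100.

    Product features split their gain 50/50 between their two parent
    layers.  A model that achieved no gain at all (fully shrunk) has no
    defined contributions; the table is flagged rather than fabricated.
    """
    per_layer = {n: 0.0 for n in model.layer_names}
    for f, g in zip(model.features, model.gains):
        if g <= 0:
            continue
        share = g / len(f.parents)
        for p in f.parents:
            per_layer[p] += share
    total = sum(per_layer.values())
    if total <= 0:
        return ContributionTable({n: 0.0 for n in per_layer}, defined=False)
    return ContributionTable({n: 100.0 * v / total for n, v in per_layer.items()})
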