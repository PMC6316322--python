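"""AICc model selection and the three-stage regularization protocol.

The regularization multiplier beta is tuned by minimizing the
small-sample-corrected Akaike criterion

    AICc = 2k - 2 lnL + 2k(k+1) / (n - k - 1)

with k the number of non-zero coefficients, lnL the presence
log-likelihood under the raw (background-normalized) output, and n the
presence count; AICc is undefined when n - k - 1 <= 0.  The protocol is:
a coarse sweep over beta in {1..7} with replicated refits, a 0.1-step
bracket around the coarse optimum, and (for final models, after variable
elimination) a scan over 0.1..2.0.  Replicates refit on resampled
presence records; the resamples are derived from the sweep seed and
shared across beta values so the comparison is paired.
"""

from __future__ import annotations

import logging
import math
import zlib
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .maxent import FeatureSpace, MaxentModel, fit_maxent, log_likelihood

log = logging.getLogger(__name__)

COARSE_BETAS = tuple(float(b) for b in range(1, 8))
FINAL_BETAS = tuple(round(0.1 * i, 1) for i in range(1, 21))

ReplicateMode = Literal["bootstrap", "subsample", "identical"]


class SelectionError(RuntimeError):
    """No beta in the scan produced a defined AICc."""


def aicc(lnl: float, k: int, n: int) -> float | None:
    """Corrected AIC; ``None`` (undefined) when n - k - 1 <= 0."""
    if k < 0 or n < 1:
        raise ValueError("require k >= 0 and n >= 1")
    if n - k - 1 <= 0:
        return None
    return 2 * k - 2 * lnl + 2 * k * (k + 1) / (n - k - 1)


def count_parameters(model: MaxentModel, tol: float = 1e-12) -> int:
    """Number of coefficients with |lambda_j| above ``tol``."""
    return int(np.sum(np.abs(model.lambdas) > tol))


@dataclass
class AiccRecord:
    beta: float
    replicate: int
    k: int
    lnl: float
    n: int
    aicc: float | None


@dataclass
class BetaScanResult:
    records: list[AiccRecord]
    best_beta: float

    def mean_aicc(self) -> dict[float, float]:
        """Mean AICc per beta over records where AICc is defined."""
        out: dict[float, float] = {}
        by_beta: dict[float, list[float]] = {}
        for r in self.records:
            if r.aicc is not None:
                by_beta.setdefault(r.beta, []).append(r.aicc)
        for b, vals in sorted(by_beta.items()):
            out[b] = float(np.mean(vals))
        return out

    def table(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(r.beta, r.replicate, r.k, r.lnl, r.n, r.aicc) for r in self.records],
            columns=["beta", "replicate", "k", "lnL", "n", "aicc"],
        )


def _replicate_rows(
    presence_rows: np.ndarray, replicate: int, seed: int, mode: ReplicateMode
) -> np.ndarray:
    """Presence resample for one replicate, deterministic in (seed, replicate).

    Independent of beta, so every beta is evaluated on the same resamples.
    """
    rows = np.sort(np.asarray(presence_rows, dtype=int))
    if mode == "identical":
        return rows
    stream = np.random.default_rng(
        [seed & 0x7FFFFFFF, zlib.crc32(b"replicate") & 0x7FFFFFFF, replicate])
    if mode == "bootstrap":
        return stream.choice(rows, size=rows.size, replace=True)
    if mode == "subsample":
        size = max(1, int(round(0.75 * rows.size)))
        return stream.choice(rows, size=size, replace=False)
    raise ValueError(f"unknown replicate mode {mode!r}")


def beta_scan(
    features: FeatureSpace,
    presence_rows: Sequence[int] | None = None,
    betas: Sequence[float] = COARSE_BETAS,
    replicates: int = 10,
    seed: int = 0,
    mode: ReplicateMode = "bootstrap",
) -> BetaScanResult:
    """Replicated AICc scan over a set of beta values.

    Every (beta, replicate) pair refits the model on that replicate's
    presence resample; AICc is averaged over the replicates where it is
    defined.  The best beta minimizes the mean AICc, ties broken toward
    the smaller value.
    """
    rows = (features.presence_rows if presence_rows is None
            else np.asarray(presence_rows, dtype=int))
    if rows.size < 2:
        raise ValueError("need at least 2 presence records to scan beta")
    resamples = [_replicate_rows(rows, r, seed, mode) for r in range(replicates)]
    records: list[AiccRecord] = []
    # per replicate, walk the betas from strongest to weakest shrinkage,
    # warm-starting each fit from the previous optimum (pathwise descent:
    # the problem is convex, so the solution is unchanged, only faster)
    path = sorted(set(float(b) for b in betas), reverse=True)
    for r, rep_rows in enumerate(resamples):
        warm = None
        for b in path:
            model = fit_maxent(features, rep_rows, beta=b, seed=seed,
                               init_lambdas=warm)
            warm = model.lambdas
            k = count_parameters(model)
            lnl = log_likelihood(model, features, rep_rows)
            records.append(
                AiccRecord(b, r, k, lnl, rep_rows.size,
                           aicc(lnl, k, rep_rows.size)))
    records.sort(key=lambda rec: (rec.beta, rec.replicate))
    result = BetaScanResult(records, best_beta=math.nan)
    means = result.mean_aicc()
    if not means:
        raise SelectionError("AICc undefined at every beta in the scan")
    best = min(means, key=lambda b: (means[b], b))
    result.best_beta = best
    log.info("beta scan over %d values: best beta=%.1f (mean AICc %.2f)",
             len(betas), best, means[best])
    return result


def coarse_beta_sweep(
    features: FeatureSpace,
    presence_rows: Sequence[int] | None = None,
    betas: Sequence[float] = COARSE_BETAS,
    replicates: int = 10,
    seed: int = 0,
    mode: ReplicateMode = "bootstrap",
) -> BetaScanResult:
    """Integer sweep (beta 1..7 by default) with replicated refits."""
    return beta_scan(features, presence_rows, betas, replicates, seed, mode)


def bracket_beta(
    features: FeatureSpace,
    scan: BetaScanResult,
    presence_rows: Sequence[int] | None = None,
    step: float = 0.1,
    replicates: int = 10,
    seed: int = 0,
    mode: ReplicateMode = "bootstrap",
) -> BetaScanResult:
    """Refine the coarse optimum on a 0.1 grid within +/- 0.9 of it.

    The window is truncated below at ``step`` (beta must stay positive);
    the coarse best is itself on the refined grid, so the refined best's
    mean AICc can never exceed the coarse best's.
    """
    center = scan.best_beta
    lo = max(step, center - 9 * step)
    betas = [round(lo + i * step, 10) for i in range(19)
             if round(lo + i * step, 10) <= center + 9 * step + 1e-9]
    return beta_scan(features, presence_rows, betas, replicates, seed, mode)


def final_beta_scan(
    features: FeatureSpace,
    presence_rows: Sequence[int] | None = None,
    betas: Sequence[float] = FINAL_BETAS,
    replicates: int = 10,
    seed: int = 0,
    mode: ReplicateMode = "bootstrap",
) -> BetaScanResult:
    """Final-model scan: beta from 0.1 to 2.0 in steps of 0.1."""
    return beta_scan(features, presence_rows, betas, replicates, seed, mode)
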