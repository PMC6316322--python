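# Methods

`monarchniche` models the climatic niche of monarch butterfly
(*Danaus plexippus*) overwintering groves from presence-only records and
monthly climate rasters, and transfers the fitted niche onto altered
(future-scenario) climate stacks. This note describes the model, the
selection protocols, the synthetic data the package is validated on, and
the numerical choices, in that order.

## The maximum-entropy model

Let `x` index the valid cells of an aligned raster stack and `f(x)` a
vector of features derived from the climate layers. The model is the
Gibbs distribution over background cells

    q(x) = exp(λ·f(x)) / Z(λ),   Z(λ) = Σ_x exp(λ·f(x)),

with λ chosen to maximize the L1-penalized presence log-likelihood

    J(λ) = λ·f̄ − ln Z(λ) − β Σ_j s_j |λ_j|,

where `f̄` is the mean feature vector over the `m` presence cells,
`s_j = sd(f_j over presences)/√m` is the per-feature penalty scale
(floored at 1e−6 so the penalty stays proper), and β is the single
user-facing regularization multiplier. At the optimum the KKT
conditions give the familiar soft-moment property
`|E_q[f_j] − f̄_j| ≤ β·s_j`, which the test suite asserts on every
fitted model.

**Features.** Linear, quadratic and pairwise-product transforms of the
raw layers, each affinely rescaled to [0, 1] over the training
background. Hinge and threshold features are deliberately omitted: the
resulting problem is small, strictly convex in practice, and cheap
enough to cross-check against a brute-force optimizer. The scaling
range of each feature is stored and doubles as its clamp range during
projection. Constant features are dropped with a warning.

**Background.** All valid cells when there are at most 10,000,
otherwise a seeded uniform sample of 10,000; presence cells are always
added to the background.

**Outputs.** The raw output is `q` itself (sums to 1 over the
background). The logistic output is `p = e^H q / (1 + e^H q)` with `H`
the entropy of `q`; a null model (all λ = 0) then scores exactly 0.5
everywhere, which makes surfaces comparable across model complexities.
All final surfaces use the logistic output.

**Trainer.** Coordinate descent with an exact one-dimensional solve per
coordinate. Because `E_q[f_j]` is monotone in `λ_j` (its derivative is
a variance), each coordinate subproblem is a monotone root find: a
soft-threshold test at zero decides the sign, then a bracketed,
variance-based Newton iteration finds the root. Within each sweep,
coordinates are visited in order of decreasing KKT violation rather
than in fixed cyclic order: the sweep's objective gain then lands on
the feature that most needed updating, which keeps the training-path
gain attribution meaningful when features are collinear (with a fixed
cyclic order, the first of a group of near-duplicate layers would
absorb the whole group's gain by accident of ordering). Ties are
broken by feature index, so the trainer is fully deterministic.
Convergence is declared when a full sweep improves the penalized
objective by less than 1e−8 (at most 10,000 sweeps). A coefficient
reaching |λ| ≥ 32 signals (near-)separation — beyond that point the
gradient of a [0,1] feature underflows — and is an error at β = 0.

**Percent contribution.** Positive per-update objective gains are
accumulated per feature during training, summed per layer (product
features split 50/50 between their two parents — a documented
heuristic), and normalized to 100. A fully shrunk model has no defined
contributions and is flagged rather than given a fabricated table.
Warm-started fits (used inside β scans, below) carry only partial-path
gains; contributions are always read from cold-started fits.

## Model selection

AICc = `2k − 2 lnL + 2k(k+1)/(n−k−1)`, with `k` the number of non-zero
coefficients, `lnL` the presence log-likelihood under the raw output,
and `n` the presence count; it is undefined (not an error) when
`n − k − 1 ≤ 0`. β is tuned in three stages:

1. coarse sweep over β ∈ {1, …, 7}, ten replicated refits per β;
2. bracket: a 0.1-step scan over [best − 0.9, best + 0.9], truncated
   below at 0.1 — the minimal grid covering everything between the
   coarse optimum's integer neighbours;
3. for final models, after variable elimination: a scan over
   β ∈ {0.1, …, 2.0}.

Replicates refit on resampled presence records. What varies across
replicates is configurable (`bootstrap` — the default, `subsample` at
75%, or `identical`); resamples are derived from the scan seed and the
replicate index only, never from β, so every β is evaluated on the same
resamples (a paired comparison) and the bracket reproduces the coarse
scan's values exactly on shared grid points. Mean AICc is taken over
replicates where it is defined; ties in the argmin go to the smaller β.
Within each replicate the β grid is fitted from the largest β down,
warm-starting each fit from the previous optimum — pathwise descent on
a convex problem, which changes nothing but the run time.

## Variable elimination

Pearson correlations between layers are computed once over the valid
background cells (pairwise r does not change when layers are removed)
and looked up thereafter. Constant layers get r = 0 with a warning.
Two iterative procedures, both driven by a model fitted at the base β:

* **top-variable-uncorrelated** (strict): each cycle (1) fits on the
  remaining layers, (2) drops layers contributing < 5%, (3) promotes
  the highest-contribution layer to the top list, (4) drops remaining
  layers with |r| ≥ 0.7 against the new top variable; repeats until
  every layer is assigned.
* **uncorrelated** (relaxed): the same cycle without step (2); layers
  are eliminated by correlation only, so the retained set is a superset
  of the strict method's.

The |r| (absolute value) reading of the 0.7 threshold is used: a strong
negative correlation is exactly as redundant as a positive one, which
is the standard reading in collinearity filtering for niche models.
Contribution ties promote the lexicographically smallest layer name.
Every cycle is recorded in a replayable trace.

## Projection and shift diagnostics

A fitted model is transferred onto a new stack by rebuilding its
features with the *training* scaling ranges; inputs outside the
training range are clamped to it by default (count recorded), since
beyond that range the fitted response is pure extrapolation. Clamping
can be disabled for explicit extrapolation studies. The normalizer Z
is recomputed over the projection background while the training entropy
H is reused in the logistic transform; a flag recomputes H for
sensitivity checks. Projecting onto the training stack reproduces the
training surface bit-for-bit (the projection path assembles the same
design matrix and applies the same matrix product).

Shift diagnostics between a current and projected surface: valid-cell
counts above probability thresholds, Pearson correlation of each
surface against elevation, and a cellwise difference map. The pipeline
flags a projected surface whose mean probability falls below a
configurable threshold (default 0.1) as a "non-transferable model" —
the characteristic failure of over-parameterized models projected onto
novel climates — as a diagnostic, not an assertion.

## Synthetic data

The generator reproduces the statistical structure the analysis
assumes, not any particular real landscape:

* **Landscape:** a monotone inland elevation ramp (default 1500 m
  across the grid) plus two coast-parallel Gaussian ridges (≈900 m)
  plus smooth noise, clipped at sea level, with a 1-cell nodata frame.
* **Climate:** each (variable, month) layer is
  `base + elev_coeff·(elev/1000) + coast_coeff·coastdist + noise`.
  Temperatures use a lapse-rate-like −6.5 °C/km; bases are wintertime
  coastal-California-like levels. The noise mixes a per-variable
  shared field with a layer-specific field (variance-preserving,
  default shared weight 0.45), so months of one variable correlate at
  roughly 0.8–0.9 — strong, like real monthly climatologies, but with
  enough month-specific weather that the month driving the niche is
  statistically identifiable at the study's sample size. Noise
  amplitudes (e.g. 2.5 °C for temperatures, 25 mm for precipitation)
  were sized for that same balance.
* **Niche and groves:** true suitability is
  `logistic(a + Σ b_i z_i)` on standardized active layers. The
  reference study uses a 100×100 grid, ten layers (minimum temperature
  and precipitation over the five overwintering months, October to
  February), and an active pair {tmin_Jan: 3.0, precipitation_Feb: 2.0}
  — a strong niche, chosen once so that recovery failures indicate
  method defects rather than an unidentifiable truth. 170 grove
  centers are drawn suitability-weighted without replacement; each
  emits 1–5 records scattered with a truncated-normal kernel (≈500 raw
  records), which is exactly the clustering the thinning stage undoes.
* **Scenario:** per-layer `value·mult + add` deltas; the reference
  warming scenario adds +2 °C to every temperature layer.

All randomness flows from one run seed through named substreams.

**What the generator does not emulate:** real WorldClim marginal
distributions, anisotropic orographic effects, coastlines and ocean
masks, observation error in grove coordinates, and geographic sampling
bias. Passing the recovery tests therefore shows the chain is
self-consistent — it finds a niche of the assumed form planted under
realistic collinearity — not that any particular real-data analysis is
correct. With months correlated at ~0.85 and ~170 effective presences,
the wrong month of the right variable occasionally wins the
contribution contest on an unlucky seed; that is faithful sampling
behaviour, and the seeded reference study (seed 1) is the pinned
regression condition.

## Problem sizes and run times

The reference recovery study (100×100, ten layers) runs the strict
elimination at base β = 1.0 and then the final 0.1–2.0 scan on the
retained layers, about a minute on one core. The full three-stage
protocol (coarse sweep + bracket on the all-layer stack) is
demonstrated at 60×60 in `scripts/acceptance.py`; low-β fits on the
full 65-feature stack dominate its cost. The acceptance script also
re-runs the trainer against the brute-force oracle on twenty tiny
problems and checks bitwise reproducibility of a 40×40 pipeline run.

## Known limitations

* No hinge/threshold features, cumulative output, or test-set AUC.
* Coordinates are planar; no reprojection or resampling.
* Percent contribution is training-path attribution, not permutation
  importance; the two can rank collinear variables differently.
* The coarse+bracket β protocol optimizes mean AICc over bootstrap
  replicates; with few presences the minimum can sit at the scan edge
  (β = 0.1), where coordinate descent is slowest.
* One scenario stack per run; no multi-model climate ensembles.
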