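# monarchniche

Climatic-niche modelling of western monarch butterfly overwintering
groves — and of how that niche moves under future climates.

Western monarchs (*Danaus plexippus*) spend October through February
clustered in a few hundred coastal California groves. Where groves can
exist is largely a question of winter climate, which makes the problem a
natural fit for presence-only species distribution modelling: grove
locations are known (one point per grove), absences are not. This
package implements that analysis as a tested, reusable pipeline —
including the maximum-entropy model itself rather than calling an
external Maxent binary — plus a synthetic-data generator so the entire
chain runs and validates with no external downloads.

## What it computes

Given monthly climate rasters (ESRI ASCII grids; up to 7 variables × 5
overwintering months = 35 layers) and grove occurrence records:

1. **Occurrence thinning** — one record per grove (centroid), at most
   one per raster cell, clipped to the valid background.
2. **Maximum-entropy model** — the Gibbs distribution
   `q(x) = exp(λ·f(x))/Z` over background cells maximizing the
   L1-penalized presence log-likelihood
   `λ·f̄ − ln Z(λ) − β Σ_j s_j|λ_j|`; linear, quadratic and product
   features scaled to [0,1]; logistic output
   `p = e^H q/(1 + e^H q)`.
3. **β optimization** — replicated AICc
   (`2k − 2lnL + 2k(k+1)/(n−k−1)`, k = non-zero coefficients) over a
   coarse β ∈ {1..7} sweep, a 0.1-step bracket, and a final 0.1–2.0
   scan.
4. **Variable elimination** — two iterative collinearity filters
   (Pearson |r| ≥ 0.7 against each promoted "top variable", with or
   without a 5%-contribution floor).
5. **Projection** — transfer of the fitted niche onto a future-scenario
   stack with feature clamping, plus shift diagnostics (area above
   probability thresholds, elevation correlation, difference maps).

## Worked example

Run the whole chain on a synthetic 40×40 coastal landscape whose true
niche depends on January minimum temperature and February
precipitation:

```python
from monarchniche.pipeline import RunConfig, SyntheticConfig, run_pipeline

cfg = RunConfig(seed=11,
                synthetic=SyntheticConfig(nrows=40, ncols=40, n_groves=60),
                base_beta=1.0, replicates=5)
result = run_pipeline(cfg, out_dir="out")
print((result.out_dir / "report.md").read_text())
```

prints

```
# Niche-model run summary

- occurrences: 186 raw records, 60 groves, 59 used
- beta: base 1.0 (fixed), final 0.1
- elimination (top_variable_uncorrelated): retained tmin_Jan, precipitation_Feb
- final model: k=4, entropy=6.9851
    - tmin_Jan: 68.1%
    - precipitation_Feb: 31.9%
- probability at occurrences: 0.122 to 0.745
- elevation correlation: current -0.473, future -0.286
```

Reading it: 186 clustered survey records reduce to 59 usable grove
points; variable elimination recovers exactly the two truly active
layers out of ten candidates; the final AICc scan picks β = 0.1; the
fitted logistic surface assigns the known groves probabilities 0.12–0.75;
and under the +2 °C scenario the elevation–probability correlation rises
from −0.47 toward zero — suitable winter conditions migrate upslope.
The same run writes `surface_current.asc`, `surface_future.asc`,
`model.json`, AICc tables and an elimination trace under `out/`.

The equivalent shell command is
`monarchniche run --config config.yaml --out out`, and each stage is
also exposed as its own subcommand (`simulate`, `thin`, `select-beta`,
`eliminate`, `fit`, `project`, `report`) for debugging.

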