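"""Seeded synthetic landscapes, climate stacks, niches and scenarios.

The generator emulates the statistical structure the analysis assumes in
real data, without any external downloads:

* a coastal-plain-to-interior-mountain landscape: a monotone inland
  elevation ramp plus smooth coast-parallel ridges plus a correlated
  noise field;
* monthly climate layers coupled to that landscape — temperatures fall
  with elevation at a lapse-rate-like coefficient (units per km), other
  variables follow their own elevation and coast-distance trends, and
  months of the same variable share a common spatial noise field so the
  inter-layer correlations of a real monthly stack are present;
* a "true" niche: a logistic function of a small subset of standardized
  layers, from which grove centers are drawn suitability-weighted, each
  grove emitting a cluster of records (this is what occurrence thinning
  is for);
* scenario deltas: per-layer multiplicative and additive changes, the
  synthetic analogue of an RCP-style future climate.

All randomness flows from one run seed through named substreams, so any
piece can be regenerated independently and deterministically.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.special import expit

from .grids import Grid, LayerName, LayerStack, OccurrenceRecord

log = logging.getLogger(__name__)

NODATA = -9999.0


def substream(seed: int, name: str, *indices: int) -> np.random.Generator:
    """Named, order-independent child stream of a run seed."""
    key = [int(seed) & 0x7FFFFFFF, zlib.crc32(name.encode()) & 0x7FFFFFFF]
    key.extend(int(i) & 0x7FFFFFFF for i in indices)
    return np.random.default_rng(key)


def _grf(shape: tuple[int, int], length: float,
         rng: np.random.Generator) -> np.ndarray:
    """Unit-variance Gaussian random field: smoothed white noise."""
    white = rng.standard_normal(shape)
    smooth = gaussian_filter(white, sigma=length, mode="reflect")
    sd = smooth.std()
    return smooth / sd if sd > 0 else smooth


def _coast_distance(nrows: int, ncols: int, coast_side: str) -> np.ndarray:
    """Normalized distance from the coastal edge, in [0, 1]."""
    col = (np.arange(ncols) + 0.5) / ncols
    row = (np.arange(nrows) + 0.5) / nrows
    if coast_side == "W":
        return np.tile(col, (nrows, 1))
    if coast_side == "E":
        return np.tile(col[::-1], (nrows, 1))
    if coast_side == "N":
        return np.tile(row[:, None], (1, ncols))
    if coast_side == "S":
        return np.tile(row[::-1][:, None], (1, ncols))
    raise ValueError(f"coast_side must be one of N/S/E/W, got {coast_side!r}")


# ---------------------------------------------------------------------
# Landscape
# ---------------------------------------------------------------------

@dataclass
class LandscapeSpec:
    nrows: int = 100
    ncols: int = 100
    cellsize: float = 0.01
    xllcorner: float = 0.0
    yllcorner: float = 0.0
    coast_side: str = "W"
    inland_rise: float = 1500.0      # m, ramp height across the grid
    ridge_count: int = 2
    ridge_height: float = 900.0      # m
    ridge_width: float = 8.0         # cells
    noise_amp: float = 60.0          # m
    noise_length: float = 4.0        # cells
    nodata_margin: int = 1           # rectangular nodata frame, in cells
    seed: int = 0


def make_landscape(spec: LandscapeSpec) -> Grid:
    """Elevation grid: coastal ramp + coast-parallel ridges + smooth noise.

    Deterministic under the spec seed; elevation is clipped at sea level
    so every valid cell is >= 0, and the coastal edge is lowest on
    average by construction.
    """
    rng = substream(spec.seed, "landscape")
    d = _coast_distance(spec.nrows, spec.ncols, spec.coast_side)
    elev = spec.inland_rise * d
    width = spec.ridge_width / max(spec.nrows, spec.ncols)
    for _ in range(spec.ridge_count):
        pos = rng.uniform(0.3, 0.95)
        height = spec.ridge_height * rng.uniform(0.7, 1.3)
        elev = elev + height * np.exp(-((d - pos) ** 2) / (2 * width**2))
    elev = elev + spec.noise_amp * _grf((spec.nrows, spec.ncols),
                                        spec.noise_length, rng)
    elev = np.clip(elev, 0.0, None)
    m = spec.nodata_margin
    if m > 0:
        elev[:m, :] = NODATA
        elev[-m:, :] = NODATA
        elev[:, :m] = NODATA
        elev[:, -m:] = NODATA
    return Grid(spec.ncols, spec.nrows, spec.xllcorner, spec.yllcorner,
                spec.cellsize, NODATA, elev)


# ---------------------------------------------------------------------
# Climate
# ---------------------------------------------------------------------

@dataclass
class LayerSpec:
    """Generating model for one (variable, month) layer."""

    variable: str
    month: str
    base: float
    elev_coeff: float = 0.0      # layer units per km of elevation
    coast_coeff: float = 0.0     # layer units across the full coast gradient
    noise_amp: float = 0.0
    noise_length: float = 4.0    # cells
    shared_weight: float = 0.45  # share of the variable-level common field

    @property
    def name(self) -> LayerName:
        return LayerName(self.variable, self.month)


@dataclass
class ClimateSpec:
    layers: list[LayerSpec]
    seed: int = 0


_MONTHS = ("Oct", "Nov", "Dec", "Jan", "Feb")

# (bases per month, elev_coeff per km, coast_coeff, noise_amp)
# Noise amplitudes are sized so month-specific weather is a visible share
# of each layer's variance (inter-month r around 0.8-0.9, like monthly
# climatologies), not a rounding error under the terrain signal.
_VARIABLE_DEFAULTS: dict[str, tuple[tuple[float, ...], float, float, float]] = {
    "tmean": ((16, 13, 11, 10, 11), -6.5, -1.0, 2.5),
    "tmin": ((8, 6, 4, 3, 4), -6.5, -2.0, 2.5),
    "tmax": ((24, 21, 18, 17, 18), -6.5, 1.0, 2.5),
    "precipitation": ((25, 50, 80, 90, 80), 15.0, 10.0, 25.0),
    "vapor_pressure": ((1.3, 1.1, 0.9, 0.85, 0.9), -0.25, -0.1, 0.12),
    "wind_speed": ((3.2, 3.0, 3.3, 3.4, 3.5), 1.0, 0.5, 0.8),
    "solar_radiation": ((150, 110, 90, 95, 120), 8.0, 5.0, 15.0),
}


def default_climate_spec(
    variables: Sequence[str] = tuple(_VARIABLE_DEFAULTS),
    seed: int = 0,
) -> ClimateSpec:
    """Monthly layer specs with wintertime coastal-California-like levels,
    lapse-rate temperature coupling and strong month-to-month correlation."""
    layers = []
    for v in variables:
        bases, ec, cc, na = _VARIABLE_DEFAULTS[v]
        for month, base in zip(_MONTHS, bases):
            layers.append(LayerSpec(v, month, float(base), ec, cc, na))
    return ClimateSpec(layers, seed=seed)


def derive_climate(elev: Grid, spec: ClimateSpec) -> LayerStack:
    """Climate stack coupled to an elevation grid.

    Each layer is base + elev_coeff * (elevation/1000) + coast_coeff *
    coast-distance + correlated noise; the noise mixes a per-variable
    shared field (weight ``shared_weight``) with a layer-specific field,
    variance-preserving, so months of one variable correlate by roughly
    the squared shared weight on top of their common terrain signal.
    """
    mask = elev.valid_mask()
    elev_km = np.where(mask, elev.values, 0.0) / 1000.0
    # infer the coast side from the elevation gradient (lowest edge)
    d = _coast_distance(elev.nrows, elev.ncols, "W")
    edge_means = {
        "W": elev.values[mask & (d < 0.5)].mean(),
        "E": elev.values[mask & (d >= 0.5)].mean(),
    }
    coast = d if edge_means["W"] <= edge_means["E"] else 1.0 - d

    shared: dict[str, np.ndarray] = {}
    layers: dict[LayerName, Grid] = {}
    shape = (elev.nrows, elev.ncols)
    for ls in spec.layers:
        if ls.variable not in shared:
            shared[ls.variable] = _grf(
                shape, ls.noise_length,
                substream(spec.seed, "climate-shared", zlib.crc32(ls.variable.encode())))
        own = _grf(shape, ls.noise_length,
                   substream(spec.seed, "climate", zlib.crc32(str(ls.name).encode())))
        w = ls.shared_weight
        noise = ls.noise_amp * (w * shared[ls.variable]
                                + np.sqrt(max(0.0, 1 - w * w)) * own)
        values = ls.base + ls.elev_coeff * elev_km + ls.coast_coeff * coast + noise
        values = np.where(mask, values, NODATA)
        layers[ls.name] = elev.like(values, nodata_value=NODATA)
    return LayerStack(layers)


# ---------------------------------------------------------------------
# Niche and occurrences
# ---------------------------------------------------------------------

@dataclass
class NicheSpec:
    """True niche: suitability = logistic(a + sum b_i z_i) on standardized
    layers, plus the grove-sampling design."""

    coefficients: dict[str, float]        # layer name -> b_i
    intercept: float = 0.0
    n_groves: int = 170
    records_per_grove: tuple[int, int] = (1, 5)
    scatter_sd: float = 0.008             # map units, ~grove cluster radius
    seed: int = 0


def true_suitability(stack: LayerStack, spec: NicheSpec) -> Grid:
    """Suitability grid in (0, 1) from the niche's active layers."""
    g = stack.grid
    mask = stack.valid_mask()
    z = np.full(g.values.shape, spec.intercept)
    for name, b in spec.coefficients.items():
        v = stack[name].values
        mu, sd = v[mask].mean(), v[mask].std()
        z = z + b * (v - mu) / sd
    s = expit(z)
    return g.like(np.where(mask, s, NODATA), nodata_value=NODATA)


def sample_groves(suitability: Grid, spec: NicheSpec) -> list[OccurrenceRecord]:
    """Grove-clustered occurrence records.

    Grove centers are drawn without replacement over valid cells with
    probability proportional to suitability; each grove emits a uniform
    1..k records scattered around its center with a truncated-normal
    kernel (clipped at two standard deviations), which is exactly the
    clustering that grove-collapse thinning is meant to undo.
    """
    rng = substream(spec.seed, "groves")
    mask = suitability.valid_mask()
    cells = np.flatnonzero(mask.ravel())
    if spec.n_groves > cells.size:
        raise ValueError(
            f"{spec.n_groves} groves exceed {cells.size} valid cells")
    w = suitability.values.ravel()[cells]
    centers = rng.choice(cells, size=spec.n_groves, replace=False, p=w / w.sum())
    lo, hi = spec.records_per_grove
    records: list[OccurrenceRecord] = []
    for i, cell in enumerate(centers):
        row, col = divmod(int(cell), suitability.ncols)
        lon, lat = suitability.cell_center(row, col)
        gid = f"G{i:04d}"
        for _ in range(int(rng.integers(lo, hi + 1))):
            dx, dy = np.clip(rng.normal(0.0, spec.scatter_sd, size=2),
                             -2 * spec.scatter_sd, 2 * spec.scatter_sd)
            records.append(OccurrenceRecord(gid, lon + dx, lat + dy))
    log.info("sampled %d groves, %d records", spec.n_groves, len(records))
    return records


# ---------------------------------------------------------------------
# Scenarios
# ---------------------------------------------------------------------

@dataclass
class ScenarioDelta:
    add: float = 0.0
    mult: float = 1.0


def apply_scenario(
    stack: LayerStack,
    deltas: Mapping[LayerName | str, ScenarioDelta | tuple[float, float]],
) -> LayerStack:
    """Per-layer future-scenario forcing: value -> value * mult + add.

    Nodata cells are untouched; a layer without a delta passes through
    unchanged (logged), so partial scenarios are explicit, not errors.
    """
    named: dict[str, ScenarioDelta] = {}
    for k, v in deltas.items():
        if isinstance(v, tuple):
            v = ScenarioDelta(add=v[0], mult=v[1])
        named[str(k) if isinstance(k, LayerName) else k] = v
    out: dict[LayerName, Grid] = {}
    for name, g in stack.layers.items():
        delta = named.get(str(name))
        if delta is None:
            log.info("scenario: no delta for %s, identity", name)
            out[name] = g
            continue
        mask = g.valid_mask()
        values = np.where(mask, g.values * delta.mult + delta.add, g.values)
        out[name] = g.like(values)
    return LayerStack(out)


# ---------------------------------------------------------------------
# The standard benchmark dataset
# ---------------------------------------------------------------------

@dataclass
class BenchmarkData:
    elevation: Grid
    current: LayerStack
    future: LayerStack
    records: list[OccurrenceRecord]
    suitability: Grid
    niche: NicheSpec


def benchmark_dataset(
    seed: int,
    nrows: int = 100,
    ncols: int = 100,
    variables: Sequence[str] = ("tmin", "precipitation"),
    active: Mapping[str, float] | None = None,
    n_groves: int = 170,
    warming: float = 2.0,
) -> BenchmarkData:
    """The package's reference synthetic study.

    Defaults: a 100x100 coastal landscape; ten monthly layers (minimum
    temperature and precipitation across the five overwintering months);
    a niche driven by January minimum temperature and February
    precipitation; 170 groves emitting roughly 500 clustered records;
    and a uniform-warming scenario (+``warming`` degrees on every
    temperature layer).
    """
    if active is None:
        active = {"tmin_Jan": 3.0, "precipitation_Feb": 2.0}
    landscape = LandscapeSpec(nrows=nrows, ncols=ncols, seed=seed)
    elevation = make_landscape(landscape)
    climate = default_climate_spec(variables=variables, seed=seed)
    current = derive_climate(elevation, climate)
    niche = NicheSpec(coefficients=dict(active), n_groves=n_groves, seed=seed)
    suitability = true_suitability(current, niche)
    records = sample_groves(suitability, niche)
    deltas = {
        str(n): ScenarioDelta(add=warming)
        for n in current.names if n.variable in ("tmin", "tmax", "tmean")
    }
    future = apply_scenario(current, deltas)
    return BenchmarkData(elevation, current, future, records, suitability, niche)
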