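"""Raster and occurrence I/O, layer alignment, and point extraction.

Grids are ESRI ASCII grids (the plain-text ``.asc`` dialect: a 6-line
header followed by whitespace-separated cell values, row 0 = northernmost
row).  Coordinates are treated as planar throughout; no reprojection is
performed.  A :class:`LayerStack` is an ordered collection of aligned
grids keyed by ``(climate variable, month)`` names such as ``tmin_Jan``;
its valid-cell mask is the intersection of the per-layer valid cells, so
a cell that is nodata in any layer is excluded from background sampling,
correlation and projection alike.
"""

from __future__ import annotations

import csv
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np

log = logging.getLogger(__name__)

VARIABLES = (
    "solar_radiation",
    "vapor_pressure",
    "precipitation",
    "wind_speed",
    "tmean",
    "tmin",
    "tmax",
)
MONTHS = ("Oct", "Nov", "Dec", "Jan", "Feb")


class GridFormatError(ValueError):
    """Malformed ASCII grid header or cell block."""


class AlignmentError(ValueError):
    """Grids that should share a header do not."""


class OutOfExtentError(ValueError):
    """A query point falls outside the grid extent."""


class LayerName(NamedTuple):
    """A climate layer identity: variable and overwintering month."""

    variable: str
    month: str

    def __str__(self) -> str:  # "tmin_Jan"
        return f"{self.variable}_{self.month}"

    @classmethod
    def parse(cls, text: str) -> "LayerName":
        stem, _, month = text.rpartition("_")
        if stem not in VARIABLES or month not in MONTHS:
            raise ValueError(
                f"cannot parse layer name {text!r}; expected "
                f"<variable>_<month> with variable in {VARIABLES} and "
                f"month in {MONTHS}"
            )
        return cls(stem, month)


@dataclass
class Grid:
    """One georeferenced raster layer (lower-left corner registration)."""

    ncols: int
    nrows: int
    xllcorner: float
    yllcorner: float
    cellsize: float
    nodata_value: float
    values: np.ndarray  # (nrows, ncols), row 0 northernmost

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.nrows, self.ncols):
            raise GridFormatError(
                f"expected {self.nrows}x{self.ncols} values, "
                f"got shape {self.values.shape}"
            )
        if self.cellsize <= 0:
            raise GridFormatError("cellsize must be positive")
        if not np.all(np.isfinite(self.values[self.valid_mask()])):
            raise GridFormatError("non-finite value outside nodata cells")

    # -- geometry -----------------------------------------------------
    @property
    def ytop(self) -> float:
        return self.yllcorner + self.nrows * self.cellsize

    @property
    def xright(self) -> float:
        return self.xllcorner + self.ncols * self.cellsize

    def header(self) -> tuple:
        return (self.ncols, self.nrows, self.xllcorner, self.yllcorner,
                self.cellsize)

    def same_shape(self, other: "Grid") -> bool:
        a, b = self.header(), other.header()
        return a[:2] == b[:2] and all(
            math.isclose(x, y, rel_tol=0, abs_tol=1e-9) for x, y in zip(a[2:], b[2:])
        )

    def valid_mask(self) -> np.ndarray:
        with np.errstate(invalid="ignore"):
            return (self.values != self.nodata_value) & ~np.isnan(self.values)

    def cell_index(self, lon: float, lat: float) -> tuple[int, int]:
        """Row/col of the cell containing a point.

        Half-open convention: cells cover ``[edge, edge + cellsize)`` going
        east and south, so a point exactly on the top or left edge belongs
        to row/col 0 and a point on the bottom or right boundary is out of
        extent.
        """
        col = math.floor((lon - self.xllcorner) / self.cellsize)
        row = math.floor((self.ytop - lat) / self.cellsize)
        if lat == self.ytop:
            row = 0
        if lon == self.xllcorner:
            col = 0
        if not (0 <= row < self.nrows and 0 <= col < self.ncols):
            raise OutOfExtentError(
                f"point ({lon}, {lat}) outside extent "
                f"x[{self.xllcorner}, {self.xright}) y({self.yllcorner}, {self.ytop}]"
            )
        return row, col

    def flat_index(self, lon: float, lat: float) -> int:
        row, col = self.cell_index(lon, lat)
        return row * self.ncols + col

    def cell_center(self, row: int, col: int) -> tuple[float, float]:
        lon = self.xllcorner + (col + 0.5) * self.cellsize
        lat = self.ytop - (row + 0.5) * self.cellsize
        return lon, lat

    def like(self, values: np.ndarray, nodata_value: float | None = None) -> "Grid":
        """A new grid sharing this header with different cell values."""
        return Grid(self.ncols, self.nrows, self.xllcorner, self.yllcorner,
                    self.cellsize,
                    self.nodata_value if nodata_value is None else nodata_value,
                    values)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Grid):
            return NotImplemented
        return (self.same_shape(other)
                and self.nodata_value == other.nodata_value
                and np.array_equal(self.values, other.values))


@dataclass
class LayerStack:
    """Aligned named grids sharing one header and one valid mask."""

    layers: dict[LayerName, Grid]

    def __post_init__(self) -> None:
        grids = list(self.layers.values())
        if not grids:
            raise AlignmentError("empty stack")
        ref = grids[0]
        for name, g in self.layers.items():
            if not g.same_shape(ref):
                bad = [f for f, a, b in zip(
                    ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize"),
                    g.header(), ref.header()) if a != b]
                raise AlignmentError(
                    f"layer {name} misaligned with stack: fields {bad} differ"
                )

    @property
    def names(self) -> list[LayerName]:
        return list(self.layers)

    @property
    def grid(self) -> Grid:
        """Reference grid supplying the shared header."""
        return next(iter(self.layers.values()))

    def __len__(self) -> int:
        return len(self.layers)

    def __getitem__(self, name: LayerName | str) -> Grid:
        if isinstance(name, str):
            name = LayerName.parse(name)
        return self.layers[name]

    def valid_mask(self) -> np.ndarray:
        """Intersection of per-layer valid cells."""
        mask = np.ones((self.grid.nrows, self.grid.ncols), dtype=bool)
        for g in self.layers.values():
            mask &= g.valid_mask()
        return mask

    def subset(self, names: Iterable[LayerName]) -> "LayerStack":
        return LayerStack({n: self.layers[n] for n in names})

    def matrix(self, flat_cells: np.ndarray) -> np.ndarray:
        """Layer values at flat cell indices -> (cells, layers)."""
        flat_cells = np.asarray(flat_cells, dtype=int)
        out = np.empty((flat_cells.size, len(self.layers)))
        for j, g in enumerate(self.layers.values()):
            out[:, j] = g.values.ravel()[flat_cells]
        return out


@dataclass
class OccurrenceRecord:
    grove_id: str
    lon: float
    lat: float
    occupied: bool = True


# ---------------------------------------------------------------------
# ASCII grid I/O
# ---------------------------------------------------------------------

_HEADER_KEYS = {"ncols", "nrows", "xllcorner", "xllcenter", "yllcorner",
                "yllcenter", "cellsize", "nodata_value"}


def read_ascii_grid(path: str | Path) -> Grid:
    """Parse an ESRI ASCII grid.

    Accepts both corner- and center-registered headers; center form is
    normalized to the corner convention by subtracting half a cell.
    """
    path = Path(path)
    header: dict[str, float] = {}
    with open(path) as fh:
        lines = fh.read().split("\n")
    i = 0
    while i < len(lines):
        parts = lines[i].split()
        if len(parts) == 2 and parts[0].lower() in _HEADER_KEYS:
            try:
                header[parts[0].lower()] = float(parts[1])
            except ValueError:
                raise GridFormatError(
                    f"{path}: bad header line {i + 1}: {lines[i]!r}")
            i += 1
        else:
            break
    for key in ("ncols", "nrows", "cellsize"):
        if key not in header:
            raise GridFormatError(f"{path}: missing header field {key}")
    if "xllcorner" in header:
        xll = header["xllcorner"]
    elif "xllcenter" in header:
        xll = header["xllcenter"] - header["cellsize"] / 2
    else:
        raise GridFormatError(f"{path}: missing xllcorner/xllcenter")
    if "yllcorner" in header:
        yll = header["yllcorner"]
    elif "yllcenter" in header:
        yll = header["yllcenter"] - header["cellsize"] / 2
    else:
        raise GridFormatError(f"{path}: missing yllcorner/yllcenter")
    nodata = header.get("nodata_value", -9999.0)
    ncols, nrows = int(header["ncols"]), int(header["nrows"])

    body = " ".join(lines[i:]).split()
    if len(body) != nrows * ncols:
        raise GridFormatError(
            f"{path}: expected {nrows * ncols} cell values, found {len(body)}")
    try:
        values = np.array(body, dtype=float).reshape(nrows, ncols)
    except ValueError as exc:
        raise GridFormatError(f"{path}: non-numeric cell value ({exc})")
    return Grid(ncols, nrows, xll, yll, header["cellsize"], nodata, values)


def write_ascii_grid(grid: Grid, path: str | Path) -> None:
    """Write corner-registered ASCII grid; cell values at 6 significant digits."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"ncols {int(grid.ncols)}\n")
        fh.write(f"nrows {int(grid.nrows)}\n")
        fh.write(f"xllcorner {float(grid.xllcorner)!r}\n")
        fh.write(f"yllcorner {float(grid.yllcorner)!r}\n")
        fh.write(f"cellsize {float(grid.cellsize)!r}\n")
        fh.write(f"NODATA_value {grid.nodata_value:.6g}\n")
        for row in grid.values:
            fh.write(" ".join(f"{v:.6g}" for v in row) + "\n")


def load_stack(paths: Mapping[LayerName | str, str | Path]) -> LayerStack:
    layers: dict[LayerName, Grid] = {}
    for name, p in paths.items():
        if isinstance(name, str):
            name = LayerName.parse(name)
        layers[name] = read_ascii_grid(p)
    return LayerStack(layers)


def save_stack(stack: LayerStack, directory: str | Path) -> dict[LayerName, Path]:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    out = {}
    for name, g in stack.layers.items():
        p = directory / f"{name}.asc"
        write_ascii_grid(g, p)
        out[name] = p
    return out


# ---------------------------------------------------------------------
# Occurrence CSV
# ---------------------------------------------------------------------

def read_occurrences(path: str | Path) -> list[OccurrenceRecord]:
    """Read a grove-occurrence CSV: grove_id,lon,lat[,occupied]."""
    path = Path(path)
    records: list[OccurrenceRecord] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or "grove_id" not in reader.fieldnames:
            raise GridFormatError(f"{path}: missing header row with grove_id")
        has_flag = "occupied" in reader.fieldnames
        for i, row in enumerate(reader, start=2):
            try:
                lon, lat = float(row["lon"]), float(row["lat"])
            except (TypeError, ValueError):
                raise GridFormatError(
                    f"{path}: non-numeric coordinate on row {i}")
            occ = True
            if has_flag:
                occ = str(row["occupied"]).strip().lower() in ("1", "true", "t", "yes")
            records.append(OccurrenceRecord(row["grove_id"], lon, lat, occ))
    if not records:
        log.warning("%s: no occurrence rows (header only)", path)
    return records


def write_occurrences(records: Sequence[OccurrenceRecord], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["grove_id", "lon", "lat", "occupied"])
        for r in records:
            writer.writerow([r.grove_id, repr(float(r.lon)),
                             repr(float(r.lat)), str(r.occupied).lower()])


# ---------------------------------------------------------------------
# Point extraction
# ---------------------------------------------------------------------

def extract_values(
    stack: LayerStack, points: Sequence[tuple[float, float]]
) -> tuple[np.ndarray, np.ndarray]:
    """Layer values at the cell containing each point.

    Returns ``(values, valid)`` where ``values`` is (points x layers) and
    ``valid`` marks points whose cell is valid in every layer; rows for
    invalid (nodata) cells are NaN and should be excluded downstream.
    """
    g = stack.grid
    flat = np.empty(len(points), dtype=int)
    for i, (lon, lat) in enumerate(points):
        try:
            flat[i] = g.flat_index(lon, lat)
        except OutOfExtentError as exc:
            raise OutOfExtentError(f"point {i}: {exc}") from None
    values = stack.matrix(flat)
    valid = stack.valid_mask().ravel()[flat]
    values[~valid] = np.nan
    return values, valid
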