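"""Systematic sampling of clustered grove records.

Overwintering monarchs aggregate in discrete groves, so raw survey rows
are clustered; using them all would overweight large groves and violate
the presence-only model's assumption of independent records.  The
reduction chain is: collapse every grove to a single point (its record
centroid), then optionally keep at most one record per raster cell, then
clip to the background extent / valid mask.  Provenance counts reconcile
exactly at every stage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .grids import Grid, LayerStack, OccurrenceRecord, OutOfExtentError

log = logging.getLogger(__name__)


@dataclass
class Provenance:
    n_raw: int = 0
    n_groves: int = 0
    n_dropped_cell_duplicates: int = 0
    n_dropped_out_of_extent: int = 0

    def as_dict(self) -> dict:
        return dict(self.__dict__)


@dataclass
class OccurrenceSet:
    """Grove-level presence records after systematic sampling."""

    records: list[OccurrenceRecord]
    provenance: Provenance = field(default_factory=Provenance)

    def __len__(self) -> int:
        return len(self.records)

    @property
    def points(self) -> list[tuple[float, float]]:
        return [(r.lon, r.lat) for r in self.records]


def collapse_to_groves(records: list[OccurrenceRecord]) -> OccurrenceSet:
    """One record per grove at the arithmetic mean of its coordinates.

    The occupied flag of the collapsed record is the logical OR of the
    grove's flags (a grove counts as occupied if any survey found it so).
    """
    by_grove: dict[str, list[OccurrenceRecord]] = {}
    for r in records:
        by_grove.setdefault(r.grove_id, []).append(r)
    collapsed = [
        OccurrenceRecord(
            gid,
            sum(r.lon for r in rs) / len(rs),
            sum(r.lat for r in rs) / len(rs),
            any(r.occupied for r in rs),
        )
        for gid, rs in sorted(by_grove.items())
    ]
    prov = Provenance(n_raw=len(records), n_groves=len(collapsed))
    return OccurrenceSet(collapsed, prov)


def dedupe_per_cell(occ: OccurrenceSet, grid: Grid) -> OccurrenceSet:
    """Keep at most one record per raster cell.

    Ties are broken toward the lexicographically smallest grove_id so the
    result is deterministic.  Records outside the grid are passed through
    untouched; extent handling belongs to :func:`clip_to_extent`.
    """
    best: dict[int, OccurrenceRecord] = {}
    outside: list[OccurrenceRecord] = []
    for r in sorted(occ.records, key=lambda r: r.grove_id):
        try:
            cell = grid.flat_index(r.lon, r.lat)
        except OutOfExtentError:
            outside.append(r)
            continue
        best.setdefault(cell, r)
    kept = sorted(best.values(), key=lambda r: r.grove_id) + outside
    dropped = len(occ.records) - len(kept)
    prov = Provenance(
        occ.provenance.n_raw, occ.provenance.n_groves,
        occ.provenance.n_dropped_cell_duplicates + dropped,
        occ.provenance.n_dropped_out_of_extent,
    )
    if dropped:
        log.info("cell dedup dropped %d co-located grove records", dropped)
    return OccurrenceSet(sorted(kept, key=lambda r: r.grove_id), prov)


def clip_to_extent(occ: OccurrenceSet, stack: LayerStack) -> OccurrenceSet:
    """Drop records outside the stack extent or on invalid (nodata) cells."""
    mask = stack.valid_mask().ravel()
    g = stack.grid
    kept: list[OccurrenceRecord] = []
    dropped = 0
    for r in occ.records:
        try:
            cell = g.flat_index(r.lon, r.lat)
        except OutOfExtentError:
            dropped += 1
            continue
        if not mask[cell]:
            dropped += 1
            log.debug("record %s on nodata cell, dropped", r.grove_id)
            continue
        kept.append(r)
    prov = Provenance(
        occ.provenance.n_raw, occ.provenance.n_groves,
        occ.provenance.n_dropped_cell_duplicates,
        occ.provenance.n_dropped_out_of_extent + dropped,
    )
    return OccurrenceSet(kept, prov)


def thin(
    records: list[OccurrenceRecord],
    stack: LayerStack,
    dedupe_cells: bool = True,
) -> OccurrenceSet:
    """Full reduction chain: collapse -> (dedupe) -> clip."""
    occ = collapse_to_groves(records)
    if dedupe_cells:
        occ = dedupe_per_cell(occ, stack.grid)
    return clip_to_extent(occ, stack)
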