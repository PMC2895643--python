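"""Scoring of emergent pattern: 2-degree/3-degree pigment-cell
classification, time series, and the hexagonal-outline IPC count.

Definitions are purely contact-topological: a tertiary (3-degree) cell is
an IPC contacting exactly three distinct OCs (the hexagon-vertex niche); a
secondary (2-degree) cell is an IPC contacting exactly two OCs and exactly
two tertiaries (a single cell spanning one hexagon edge).  Compartment
pairs (the half-frozen-OC experiment) are merged before counting, so
scoring is variant-independent.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np

from .engine import (
    IPC, MEDIUM, OC, CellField, CellRegistry, EngineParameters,
    pairwise_contacts,
)

__all__ = [
    "ContactTopology", "classify_tertiary", "classify_secondary",
    "SnapshotScore", "score_snapshot", "TimeSeriesRecord",
    "TimeSeriesRecorder", "HexagonRegion", "hexagon_ipc_count",
    "hexagon_around", "mcs_to_hours", "central_oc_ids", "plateau_mcs",
]


def _merged_id(registry: CellRegistry, cell_id: int) -> int:
    """Compartment-split cells count as one cell (the lower identifier)."""
    p = int(registry.partner[cell_id])
    return min(cell_id, p) if p >= 0 else cell_id


def _default_min_links(neighbor_order: int) -> int:
    """Links required before two cells count as 'contacting' each other.

    Two cells meeting only at a lattice corner share 2 diagonal links under
    order-2 counting (0 under order-1); a true shared edge gives 3 or more
    (1 or more).  Requiring 2*order - 1 links therefore discretises
    'contact' as edge-sharing and makes classification insensitive to
    transient point contacts.
    """
    return 2 * neighbor_order - 1


class ContactTopology:
    """Snapshot of who touches whom, with compartment pairs merged.

    Neighbour pairs sharing fewer than ``min_links`` boundary links are
    dropped (see :func:`_default_min_links`); contact lengths themselves
    are unfiltered.
    """

    def __init__(self, field: CellField, registry: CellRegistry,
                 params: EngineParameters, min_links: int | None = None):
        if min_links is None:
            min_links = _default_min_links(params.neighbor_order)
        self.min_links = min_links
        self.registry = registry
        self.neighbors: dict[int, dict[int, int]] = {}
        for (a, b), n in pairwise_contacts(field, registry, params).items():
            a = _merged_id(registry, a)
            b = _merged_id(registry, b)
            if a == b:
                continue
            self.neighbors.setdefault(a, {})
            self.neighbors.setdefault(b, {})
            self.neighbors[a][b] = self.neighbors[a].get(b, 0) + n
            self.neighbors[b][a] = self.neighbors[b].get(a, 0) + n
        for a, nbrs in self.neighbors.items():
            drop = [b for b, n in nbrs.items() if n < min_links]
            for b in drop:
                del nbrs[b]

    def of_type(self, cell_id: int, code: int) -> set[int]:
        reg = self.registry
        return {i for i in self.neighbors.get(cell_id, ())
                if reg.cell_type[i] == code}


def classify_tertiary(field: CellField, registry: CellRegistry,
                      params: EngineParameters, cell_id: int,
                      topology: ContactTopology | None = None) -> bool:
    """True iff the cell is a living IPC contacting exactly three distinct
    OCs (compartment-split OCs count once)."""
    if registry.cell_type[cell_id] != IPC or not registry.alive[cell_id]:
        raise ValueError(f"cell {cell_id} is not a living IPC")
    topology = topology or ContactTopology(field, registry, params)
    return len(topology.of_type(int(cell_id), OC)) == 3


def classify_secondary(field: CellField, registry: CellRegistry,
                       params: EngineParameters, cell_id: int,
                       tertiary_set: set[int],
                       topology: ContactTopology | None = None) -> bool:
    """True iff the cell is a living IPC contacting exactly two distinct
    OCs and exactly two cells of ``tertiary_set``."""
    if registry.cell_type[cell_id] != IPC or not registry.alive[cell_id]:
        raise ValueError(f"cell {cell_id} is not a living IPC")
    topology = topology or ContactTopology(field, registry, params)
    nbrs = topology.neighbors.get(int(cell_id), {})
    n_oc = len(topology.of_type(int(cell_id), OC))
    n_tert = sum(1 for i in nbrs if i in tertiary_set)
    return n_oc == 2 and n_tert == 2


def central_oc_ids(field: CellField, registry: CellRegistry,
                   params: EngineParameters,
                   topology: ContactTopology | None = None) -> set[int]:
    """OCs none of whose contacting IPCs is border-exempt: the analogue of
    the paper-style 'central ommatidia' away from the non-dying margin.
    Requires border exemptions to have been marked at initialisation."""
    topology = topology or ContactTopology(field, registry, params)
    out = set()
    for oc in registry.living_ids(OC):
        oc = _merged_id(registry, int(oc))
        ipcs = topology.of_type(oc, IPC)
        if ipcs and not any(registry.death_exempt[i] for i in ipcs):
            out.add(oc)
    return out


@dataclass(frozen=True)
class SnapshotScore:
    mcs: int
    n_cells: int
    n_secondary: int
    n_tertiary: int
    n_secondary_central: int
    n_tertiary_central: int
    n_central_oc: int
    mean_area: dict
    mean_perimeter: dict
    n_fragments: int = 0


# one record per reporting interval; field names double as CSV columns
TimeSeriesRecord = SnapshotScore


def score_snapshot(field: CellField, registry: CellRegistry,
                   params: EngineParameters,
                   count_fragments: bool = False,
                   central_ocs: set | None = None) -> SnapshotScore:
    """Classify the whole field once.

    Whole-field 2-degree/3-degree counts are reported alongside counts
    restricted to the central subfield (cells contacting at least one
    central OC), which exclude edge effects of the non-dying margin.
    ``central_ocs`` fixes the central-ommatidium set (normally determined
    once at initialisation); by default it is derived from the current
    snapshot.
    """
    topology = ContactTopology(field, registry, params)
    tertiary = set()
    ipc_ids = [int(i) for i in registry.living_ids(IPC)]
    for i in ipc_ids:
        if len(topology.of_type(i, OC)) == 3:
            tertiary.add(i)
    secondary = {
        i for i in ipc_ids
        if classify_secondary(field, registry, params, i, tertiary, topology)
    }
    central = (central_oc_ids(field, registry, params, topology)
               if central_ocs is None else central_ocs)
    tertiary_central = {i for i in tertiary
                        if topology.of_type(i, OC) & central}
    secondary_central = {i for i in secondary
                         if topology.of_type(i, OC) & central}

    mean_area = {}
    mean_perim = {}
    for code, name in ((OC, "OC"), (IPC, "IPC")):
        ids = registry.living_ids(code)
        mean_area[name] = float(registry.area[ids].mean()) if len(ids) else 0.0
        mean_perim[name] = (float(registry.perimeter[ids].mean())
                            if len(ids) else 0.0)

    n_fragments = 0
    if count_fragments:
        from skimage.measure import label as cc_label

        # connected regions of equal value beyond one per living cell are
        # pinch-off fragments; labelling is not wrap-aware, so count on the
        # lattice and on a half-period roll and keep the smaller excess
        # (a cell straddling the seam is whole in one of the two framings)
        def _excess(arr):
            n_regions = int(cc_label(arr, connectivity=1,
                                     background=MEDIUM).max())
            return n_regions - registry.n_cells

        rolled = np.roll(field.owner,
                         (field.height // 2, field.width // 2), (0, 1))
        n_fragments = min(_excess(field.owner), _excess(rolled))

    return SnapshotScore(
        mcs=field.mcs_counter,
        n_cells=registry.n_cells,
        n_secondary=len(secondary),
        n_tertiary=len(tertiary),
        n_secondary_central=len(secondary_central),
        n_tertiary_central=len(tertiary_central),
        n_central_oc=len(central),
        mean_area=mean_area,
        mean_perimeter=mean_perim,
        n_fragments=n_fragments,
    )


class TimeSeriesRecorder:
    """Per-MCS hook emitting one record whenever mcs % interval == 0."""

    def __init__(self, params: EngineParameters, interval: int = 500,
                 count_fragments: bool = False):
        if interval <= 0:
            raise ValueError("interval must be > 0")
        self.params = params
        self.interval = interval
        self.count_fragments = count_fragments
        self.records: list[SnapshotScore] = []
        #: central-ommatidium set, frozen at the first (initial) record
        self.central_ocs: set | None = None

    def __call__(self, field: CellField, registry: CellRegistry,
                 mcs: int) -> None:
        if mcs % self.interval == 0:
            if self.central_ocs is None:
                self.central_ocs = central_oc_ids(field, registry,
                                                  self.params)
            self.records.append(score_snapshot(
                field, registry, self.params, self.count_fragments,
                central_ocs=self.central_ocs))

    def to_frame(self):
        import pandas as pd

        rows = []
        for r in self.records:
            rows.append({
                "mcs": r.mcs,
                "n_cells": r.n_cells,
                "n_secondary": r.n_secondary,
                "n_tertiary": r.n_tertiary,
                "n_secondary_central": r.n_secondary_central,
                "n_tertiary_central": r.n_tertiary_central,
                "n_central_oc": r.n_central_oc,
                "mean_area_OC": r.mean_area["OC"],
                "mean_area_IPC": r.mean_area["IPC"],
                "mean_perim_OC": r.mean_perimeter["OC"],
                "mean_perim_IPC": r.mean_perimeter["IPC"],
                "n_fragments": r.n_fragments,
            })
        return pd.DataFrame(rows)


# -- hexagonal-outline IPC counting -------------------------------------------


@dataclass(frozen=True)
class HexagonRegion:
    """Hexagonal outline through the centres of the six ommatidia that
    surround a focal one (the standardised in-vivo counting region)."""

    vertices: tuple

    def __post_init__(self):
        verts = tuple((float(x), float(y)) for x, y in self.vertices)
        object.__setattr__(self, "vertices", verts)
        if len(verts) != 6 or len(set(verts)) != 6:
            raise ValueError("a hexagon needs six distinct vertices")
        from shapely.geometry import Polygon

        poly = Polygon(verts)
        if not poly.is_simple or poly.area <= 0:
            raise ValueError("hexagon outline must be a simple polygon")

    def contains(self, xy: np.ndarray) -> np.ndarray:
        from matplotlib.path import Path as MplPath

        return MplPath(self.vertices).contains_points(xy)


def hexagon_ipc_count(field: CellField, registry: CellRegistry,
                      region: HexagonRegion) -> float:
    """Count IPCs inside the outline; a cell with sites on both sides of
    the boundary scores half a cell."""
    total = 0.0
    inside_mask = region.contains(
        np.column_stack(np.nonzero(field.owner)[::-1]))  # (x=col, y=row)
    rows, cols = np.nonzero(field.owner)
    owners = field.owner[rows, cols]
    for cell_id in registry.living_ids(IPC):
        sel = owners == cell_id
        if not sel.any():
            continue
        inside = inside_mask[sel]
        if inside.all():
            total += 1.0
        elif inside.any():
            total += 0.5
    return total


def hexagon_around(field: CellField, registry: CellRegistry,
                   focal_oc: int) -> HexagonRegion:
    """Outline through the six OC centroids nearest the focal OC,
    ordered by angle."""
    oc_ids = [int(i) for i in registry.living_ids(OC)]
    if focal_oc not in oc_ids:
        raise LookupError(f"no living OC with id {focal_oc}")
    cents = {}
    for i in oc_ids:
        rr, cc = np.nonzero(field.owner == i)
        cents[i] = (float(cc.mean()), float(rr.mean()))
    fx, fy = cents[focal_oc]
    others = sorted((i for i in oc_ids if i != focal_oc),
                    key=lambda i: (cents[i][0] - fx) ** 2
                    + (cents[i][1] - fy) ** 2)
    if len(others) < 6:
        raise ValueError("need at least six surrounding ommatidia")
    ring = sorted(others[:6],
                  key=lambda i: np.arctan2(cents[i][1] - fy,
                                           cents[i][0] - fx))
    return HexagonRegion(vertices=tuple(cents[i] for i in ring))


def plateau_mcs(mcs: np.ndarray, counts: np.ndarray,
                tolerance: int = 1) -> int:
    """First MCS at which a count series reaches its run-end value and
    remains there.

    A Metropolis cell count is a stationary noisy signal once the pattern
    has settled: single-cell events (one marginal vertex gained or lost)
    continue at a low rate for as long as the simulation runs, so no
    pointwise equality can hold.  The statistic therefore reads the curve
    the way a plotted time course is read: the run-end value is the
    sustained level (median of the last ten records), and the plateau is
    the first record equal to that level from which the curve's local
    level (forward ten-record medians) never departs from it by more than
    ``tolerance`` cells (default 1, the resolution of the count).  A
    transient touch during the rise is rejected by the local-level guard,
    as is a series that later drifts to a different level.  Returns the
    last MCS if the level is never reached and held.
    """
    mcs = np.asarray(mcs)
    counts = np.asarray(counts, dtype=float)
    if len(mcs) != len(counts) or len(mcs) == 0:
        raise ValueError("mcs and counts must be equal-length, non-empty")
    n = len(counts)
    window = min(10, n)
    level = np.median(counts[-window:])
    # forward-window medians: the local level of the curve from each record
    fwd = np.array([np.median(counts[j:j + window]) for j in range(n)])
    held = np.abs(fwd - level) <= tolerance
    for k in range(n):
        if counts[k] == level and held[k:].all():
            return int(mcs[k])
    return int(mcs[-1])


def mcs_to_hours(mcs: int, seconds_per_mcs: float = 2.0) -> float:
    """Developmental time represented by ``mcs`` steps (default 2 s/MCS;
    10,000 MCS is about 5.6 h)."""
    if mcs < 0:
        raise ValueError("mcs must be >= 0")
    return mcs * seconds_per_mcs / 3600.0
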