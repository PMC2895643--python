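"""Core Glazier-Graner-Hogeweg (Cellular Potts) lattice engine.

A tissue is a periodic 2D lattice of integer cell identifiers
(:class:`CellField`) plus per-cell bookkeeping (:class:`CellRegistry`).
Cells evolve by Metropolis-accepted boundary copy attempts against the
effective energy

    H = sum_links J(tau_i, tau_j)                      (adhesion)
      + sum_cells lambda_A * (A - A_T)**2              (area constraint)
      + sum_cells lambda_P * (P - P_T)**2              (perimeter constraint)

where one Monte Carlo Step (MCS) is one copy attempt per lattice site.
Identifier 0 is always Medium, the unconstrained exterior "cell".

Conventions (see docs/methods.md): copy attempts propose between order-1
(4-)neighbours; boundary energy and perimeters are counted over the
order-``neighbor_order`` neighbourhood (default order-2, the
8-neighbourhood, which reduces lattice anisotropy).  A cell's perimeter is
the number of such links from its sites to sites it does not own.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field as dc_field

import numpy as np

from . import _kernel

MEDIUM, OC, IPC = 0, 1, 2
TYPE_NAMES = ("Medium", "OC", "IPC")
_TYPE_CODES = {name: code for code, name in enumerate(TYPE_NAMES)}

#: offsets defining the copy-attempt (source-choice) neighbourhood
OFFSETS_ORDER1 = ((0, 1), (0, -1), (1, 0), (-1, 0))
OFFSETS_ORDER2 = OFFSETS_ORDER1 + ((1, 1), (1, -1), (-1, 1), (-1, -1))
#: one offset per undirected link direction, for full-lattice sweeps
HALF_OFFSETS = {1: ((0, 1), (1, 0)), 2: ((0, 1), (1, 0), (1, 1), (1, -1))}


class IntegrityError(RuntimeError):
    """Cached cell state disagrees with the lattice."""


def type_code(cell_type) -> int:
    if isinstance(cell_type, str):
        try:
            return _TYPE_CODES[cell_type]
        except KeyError:
            raise ValueError(f"unknown cell type {cell_type!r}") from None
    code = int(cell_type)
    if not 0 <= code < len(TYPE_NAMES):
        raise ValueError(f"unknown cell type code {cell_type!r}")
    return code


def neighborhood_offsets(order: int):
    if order == 1:
        return OFFSETS_ORDER1
    if order == 2:
        return OFFSETS_ORDER2
    raise ValueError("neighbor_order must be 1 or 2")


@dataclass(frozen=True)
class EngineParameters:
    """Global dynamics parameters.

    temperature
        Motility T: scale of energy fluctuations a cell can ride through.
    neighbor_order
        Neighbourhood used for boundary energy, perimeters and contact
        lengths (1 = 4-neighbourhood, 2 = 8-neighbourhood).
    seconds_per_mcs
        Developmental-time calibration of one MCS.
    """

    temperature: float = 60.0
    neighbor_order: int = 2
    rng_seed: int = 0
    total_mcs: int = 50_000
    seconds_per_mcs: float = 2.0

    def __post_init__(self):
        if self.temperature <= 0:
            raise ValueError("temperature must be > 0")
        if self.neighbor_order not in (1, 2):
            raise ValueError("neighbor_order must be 1 or 2")
        if self.total_mcs < 0:
            raise ValueError("total_mcs must be >= 0")


@dataclass(frozen=True)
class ShapeConstraints:
    """Inverse compressibilities per cell type (Medium is unconstrained)."""

    lambda_area_oc: float = 6.0
    lambda_area_ipc: float = 4.0
    lambda_perim_oc: float = 0.05
    lambda_perim_ipc: float = 0.02

    def lambda_area(self, code: int) -> float:
        return (0.0, self.lambda_area_oc, self.lambda_area_ipc)[code]

    def lambda_perim(self, code: int) -> float:
        return (0.0, self.lambda_perim_oc, self.lambda_perim_ipc)[code]


class ContactEnergyTable:
    """Symmetric type x type boundary-energy coefficients J.

    Lower J means stronger adhesion.  The wild-type preset follows the
    hierarchy J_OC,OC >> J_OC,Med >> J_IPC,Med > J_IPC,IPC >= J_OC,IPC
    so that ommatidial cores never touch, the tissue stays compact, and
    IPCs prefer core contact over each other.
    """

    def __init__(self, *, oc_oc, oc_ipc, ipc_ipc, oc_medium, ipc_medium,
                 medium_medium=0.0):
        m = np.zeros((3, 3), dtype=np.float64)
        m[MEDIUM, MEDIUM] = medium_medium
        m[OC, OC] = oc_oc
        m[IPC, IPC] = ipc_ipc
        m[OC, IPC] = m[IPC, OC] = oc_ipc
        m[OC, MEDIUM] = m[MEDIUM, OC] = oc_medium
        m[IPC, MEDIUM] = m[MEDIUM, IPC] = ipc_medium
        self._matrix = m
        self._matrix.flags.writeable = False

    @classmethod
    def from_matrix(cls, matrix) -> "ContactEnergyTable":
        m = np.asarray(matrix, dtype=np.float64)
        if m.shape != (3, 3):
            raise ValueError("contact energy matrix must be 3x3")
        if not np.array_equal(m, m.T):
            raise ValueError("contact energies must be symmetric")
        return cls(
            oc_oc=m[OC, OC], oc_ipc=m[OC, IPC], ipc_ipc=m[IPC, IPC],
            oc_medium=m[OC, MEDIUM], ipc_medium=m[IPC, MEDIUM],
            medium_medium=m[MEDIUM, MEDIUM],
        )

    @classmethod
    def wild_type(cls) -> "ContactEnergyTable":
        return cls(oc_oc=200.0, oc_ipc=35.0, ipc_ipc=55.0,
                   oc_medium=90.0, ipc_medium=70.0)

    @property
    def matrix(self) -> np.ndarray:
        return self._matrix

    def j(self, type_a, type_b) -> float:
        return float(self._matrix[type_code(type_a), type_code(type_b)])

    def replace(self, **pairs) -> "ContactEnergyTable":
        """New table with named pairs (oc_ipc=..., ipc_ipc=...) changed."""
        current = dict(
            oc_oc=self.j(OC, OC), oc_ipc=self.j(OC, IPC),
            ipc_ipc=self.j(IPC, IPC), oc_medium=self.j(OC, MEDIUM),
            ipc_medium=self.j(IPC, MEDIUM), medium_medium=self.j(MEDIUM, MEDIUM),
        )
        unknown = set(pairs) - set(current)
        if unknown:
            raise ValueError(f"unknown contact pairs: {sorted(unknown)}")
        current.update(pairs)
        return ContactEnergyTable(**current)

    def __eq__(self, other):
        return isinstance(other, ContactEnergyTable) and np.array_equal(
            self._matrix, other._matrix)

    def __repr__(self):
        return (f"ContactEnergyTable(oc_oc={self.j(OC, OC)}, "
                f"oc_ipc={self.j(OC, IPC)}, ipc_ipc={self.j(IPC, IPC)}, "
                f"oc_medium={self.j(OC, MEDIUM)}, "
                f"ipc_medium={self.j(IPC, MEDIUM)})")


@dataclass(frozen=True)
class EnergyBreakdown:
    boundary_term: float
    area_term: float
    perimeter_term: float

    @property
    def total(self) -> float:
        return self.boundary_term + self.area_term + self.perimeter_term


@dataclass
class CellRecord:
    """Read-only snapshot of one cell's bookkeeping."""

    cell_id: int
    cell_type: str
    area: int
    perimeter: int
    target_area: float
    target_perimeter: float
    lambda_area: float
    lambda_perimeter: float
    death_exempt: bool
    expansion_enabled: bool
    dying: bool
    alive: bool
    partner: int


class CellField:
    """Periodic 2D lattice of cell identifiers.

    ``owner[row, col]`` is the identifier of the cell occupying that site
    (0 = Medium).  Wrap-around is periodic in both directions.
    """

    def __init__(self, owner, mcs_counter: int = 0):
        # always copy: the field owns (and mutates) its lattice
        owner = np.array(owner, dtype=np.int32, order="C", copy=True)
        if owner.ndim != 2:
            raise ValueError("owner lattice must be 2D")
        if owner.shape[0] < 4 or owner.shape[1] < 4:
            raise ValueError("lattice must be at least 4x4")
        if owner.min() < 0:
            raise ValueError("cell identifiers must be >= 0")
        self.owner = owner
        self.mcs_counter = int(mcs_counter)
        self._nbr_tables: dict[int, np.ndarray] = {}

    @property
    def height(self) -> int:
        return self.owner.shape[0]

    @property
    def width(self) -> int:
        return self.owner.shape[1]

    @property
    def n_sites(self) -> int:
        return self.owner.size

    @property
    def owner_flat(self) -> np.ndarray:
        return self.owner.reshape(-1)

    def neighbor_table(self, order: int) -> np.ndarray:
        """(n_sites, k) flat indices of each site's order-k neighbours."""
        if order not in self._nbr_tables:
            idx = np.arange(self.n_sites, dtype=np.int32).reshape(
                self.height, self.width)
            cols = []
            for dr, dc in neighborhood_offsets(order):
                cols.append(np.roll(idx, (-dr, -dc), axis=(0, 1)).reshape(-1))
            self._nbr_tables[order] = np.ascontiguousarray(
                np.stack(cols, axis=1))
        return self._nbr_tables[order]

    def copy(self) -> "CellField":
        return CellField(self.owner.copy(), self.mcs_counter)

    def site_index(self, site) -> int:
        r, c = site
        if not (0 <= r < self.height and 0 <= c < self.width):
            raise IndexError(f"site {site!r} outside {self.height}x{self.width}")
        return r * self.width + c


class LatticeRNG:
    """Deterministic splitmix64 stream driving the copy-attempt kernel."""

    def __init__(self, seed: int):
        self.seed = int(seed)
        self.state = np.array([np.uint64(self.seed & 0xFFFFFFFFFFFFFFFF)],
                              dtype=np.uint64)


class CellRegistry:
    """Struct-of-arrays bookkeeping for all cells ever registered.

    Index = cell identifier; id 0 is Medium (lambda_A = lambda_P = 0).
    Cells whose area reaches 0 are marked dead (``alive[c] = False``) and
    never return; their rows are retained so identifiers stay stable.
    """

    _BOOL_FIELDS = ("alive", "dying", "death_exempt", "expansion_enabled")

    def __init__(self, cell_type, area, perimeter, target_area,
                 target_perimeter, lambda_area, lambda_perimeter,
                 alive=None, dying=None, death_exempt=None,
                 expansion_enabled=None, partner=None,
                 initial_target_area=None, initial_target_perimeter=None):
        n = len(cell_type)
        self.cell_type = np.asarray(cell_type, dtype=np.int8)
        self.area = np.asarray(area, dtype=np.int64)
        self.perimeter = np.asarray(perimeter, dtype=np.int64)
        self.target_area = np.asarray(target_area, dtype=np.float64)
        self.target_perimeter = np.asarray(target_perimeter, dtype=np.float64)
        self.lambda_area = np.asarray(lambda_area, dtype=np.float64)
        self.lambda_perimeter = np.asarray(lambda_perimeter, dtype=np.float64)

        def _bool(arr, default):
            if arr is None:
                return np.full(n, default, dtype=np.bool_)
            return np.asarray(arr, dtype=np.bool_)

        self.alive = _bool(alive, True)
        self.dying = _bool(dying, False)
        self.death_exempt = _bool(death_exempt, False)
        self.expansion_enabled = _bool(expansion_enabled, False)
        self.partner = (np.full(n, -1, dtype=np.int32) if partner is None
                        else np.asarray(partner, dtype=np.int32))
        self.initial_target_area = (
            self.target_area.copy() if initial_target_area is None
            else np.asarray(initial_target_area, dtype=np.float64))
        self.initial_target_perimeter = (
            self.target_perimeter.copy() if initial_target_perimeter is None
            else np.asarray(initial_target_perimeter, dtype=np.float64))

        if self.cell_type[0] != MEDIUM:
            raise ValueError("cell id 0 must be Medium")
        if self.lambda_area[0] != 0 or self.lambda_perimeter[0] != 0:
            raise ValueError("Medium must be unconstrained (lambda = 0)")

    # -- construction -----------------------------------------------------

    @classmethod
    def from_field(cls, field: CellField, cell_types,
                   shape: ShapeConstraints | None = None,
                   neighbor_order: int = 2) -> "CellRegistry":
        """Build a registry from a label lattice.

        ``cell_types``: array mapping cell id -> type code.  Targets are
        initialised to the current measured area and perimeter.
        """
        shape = shape or ShapeConstraints()
        cell_types = np.asarray([type_code(t) for t in cell_types],
                                dtype=np.int8)
        areas, perims = measure_field(field, neighbor_order,
                                      n_ids=len(cell_types))
        lam_a = np.array([shape.lambda_area(c) for c in cell_types])
        lam_p = np.array([shape.lambda_perim(c) for c in cell_types])
        reg = cls(
            cell_type=cell_types, area=areas, perimeter=perims,
            target_area=areas.astype(np.float64),
            target_perimeter=perims.astype(np.float64),
            lambda_area=lam_a, lambda_perimeter=lam_p,
        )
        reg.alive[:] = areas > 0
        reg.alive[0] = True  # Medium persists even with zero area
        return reg

    # -- queries ----------------------------------------------------------

    @property
    def n_ids(self) -> int:
        return len(self.cell_type)

    @property
    def n_cells(self) -> int:
        """Living non-Medium cells."""
        return int(np.count_nonzero(self.alive[1:]))

    def living_ids(self, cell_type=None) -> np.ndarray:
        mask = self.alive.copy()
        mask[0] = False
        if cell_type is not None:
            mask &= self.cell_type == type_code(cell_type)
        return np.flatnonzero(mask)

    def record(self, cell_id: int) -> CellRecord:
        if not 0 <= cell_id < self.n_ids:
            raise LookupError(f"unknown cell id {cell_id}")
        return CellRecord(
            cell_id=int(cell_id),
            cell_type=TYPE_NAMES[self.cell_type[cell_id]],
            area=int(self.area[cell_id]),
            perimeter=int(self.perimeter[cell_id]),
            target_area=float(self.target_area[cell_id]),
            target_perimeter=float(self.target_perimeter[cell_id]),
            lambda_area=float(self.lambda_area[cell_id]),
            lambda_perimeter=float(self.lambda_perimeter[cell_id]),
            death_exempt=bool(self.death_exempt[cell_id]),
            expansion_enabled=bool(self.expansion_enabled[cell_id]),
            dying=bool(self.dying[cell_id]),
            alive=bool(self.alive[cell_id]),
            partner=int(self.partner[cell_id]),
        )

    # -- mutation ---------------------------------------------------------

    def add_cell(self, cell_type, *, area=0, perimeter=0, target_area=None,
                 target_perimeter=None, lambda_area=0.0,
                 lambda_perimeter=0.0, expansion_enabled=False,
                 death_exempt=False, partner=-1) -> int:
        """Append a new cell; returns its identifier."""
        code = type_code(cell_type)
        new_id = self.n_ids
        self.cell_type = np.append(self.cell_type, np.int8(code))
        self.area = np.append(self.area, np.int64(area))
        self.perimeter = np.append(self.perimeter, np.int64(perimeter))
        ta = float(area if target_area is None else target_area)
        tp = float(perimeter if target_perimeter is None else target_perimeter)
        self.target_area = np.append(self.target_area, ta)
        self.target_perimeter = np.append(self.target_perimeter, tp)
        self.initial_target_area = np.append(self.initial_target_area, ta)
        self.initial_target_perimeter = np.append(
            self.initial_target_perimeter, tp)
        self.lambda_area = np.append(self.lambda_area, float(lambda_area))
        self.lambda_perimeter = np.append(self.lambda_perimeter,
                                          float(lambda_perimeter))
        self.alive = np.append(self.alive, True)
        self.dying = np.append(self.dying, False)
        self.death_exempt = np.append(self.death_exempt, bool(death_exempt))
        self.expansion_enabled = np.append(self.expansion_enabled,
                                           bool(expansion_enabled))
        self.partner = np.append(self.partner, np.int32(partner))
        return new_id

    def set_dying(self, cell_id: int) -> None:
        """Flag a cell for programmed death: A_T and P_T drop to 0 and the
        area constraint shrinks it away."""
        self.dying[cell_id] = True
        self.target_area[cell_id] = 0.0
        self.target_perimeter[cell_id] = 0.0

    def copy(self) -> "CellRegistry":
        return CellRegistry(
            cell_type=self.cell_type.copy(), area=self.area.copy(),
            perimeter=self.perimeter.copy(),
            target_area=self.target_area.copy(),
            target_perimeter=self.target_perimeter.copy(),
            lambda_area=self.lambda_area.copy(),
            lambda_perimeter=self.lambda_perimeter.copy(),
            alive=self.alive.copy(), dying=self.dying.copy(),
            death_exempt=self.death_exempt.copy(),
            expansion_enabled=self.expansion_enabled.copy(),
            partner=self.partner.copy(),
            initial_target_area=self.initial_target_area.copy(),
            initial_target_perimeter=self.initial_target_perimeter.copy(),
        )

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({
            "cell_id": np.arange(self.n_ids),
            "type": [TYPE_NAMES[c] for c in self.cell_type],
            "area": self.area,
            "perimeter": self.perimeter,
            "target_area": self.target_area,
            "target_perimeter": self.target_perimeter,
            "alive": self.alive,
            "dying": self.dying,
            "death_exempt": self.death_exempt,
            "expansion_enabled": self.expansion_enabled,
            "partner": self.partner,
        })


# -- whole-field measurement -----------------------------------------------


def measure_field(field: CellField, neighbor_order: int = 2, n_ids=None):
    """Recompute (areas, perimeters) of every identifier from the lattice."""
    owner = field.owner
    if n_ids is None:
        n_ids = int(owner.max()) + 1
    areas = np.bincount(owner.reshape(-1), minlength=n_ids)
    perims = np.zeros(n_ids, dtype=np.int64)
    for dr, dc in neighborhood_offsets(neighbor_order):
        shifted = np.roll(owner, (-dr, -dc), axis=(0, 1))
        mask = owner != shifted
        perims += np.bincount(owner[mask], minlength=n_ids)
    return areas.astype(np.int64), perims


def check_integrity(field: CellField, registry: CellRegistry,
                    params: EngineParameters) -> None:
    """Raise :class:`IntegrityError` naming the first cell whose cached
    area/perimeter disagrees with the lattice."""
    if int(field.owner.max()) >= registry.n_ids:
        raise IntegrityError(
            f"lattice owner {int(field.owner.max())} not in registry")
    areas, perims = measure_field(field, params.neighbor_order,
                                  n_ids=registry.n_ids)
    bad = np.flatnonzero((areas != registry.area) |
                         (perims != registry.perimeter))
    if bad.size:
        c = int(bad[0])
        raise IntegrityError(
            f"cell {c}: lattice says area={areas[c]}, perimeter={perims[c]}; "
            f"registry says area={registry.area[c]}, "
            f"perimeter={registry.perimeter[c]}")


def total_energy(field: CellField, registry: CellRegistry,
                 table: ContactEnergyTable, params: EngineParameters,
                 check: bool = True) -> EnergyBreakdown:
    """Full-lattice recomputation of the effective energy.

    The area/perimeter terms sum over every registered non-Medium cell
    (dead cells hold A = P = 0, so a cell that died with a nonzero target
    retains a constant residual; programmed death zeroes targets first,
    making the residual 0 in practice).  This convention makes the total
    exactly consistent with the incremental ``delta_h`` bookkeeping.
    """
    if check:
        check_integrity(field, registry, params)
    owner = field.owner
    ctype = registry.cell_type
    boundary = 0.0
    for dr, dc in HALF_OFFSETS[params.neighbor_order]:
        shifted = np.roll(owner, (-dr, -dc), axis=(0, 1))
        mask = owner != shifted
        a = owner[mask]
        b = shifted[mask]
        j = table.matrix[ctype[a], ctype[b]]
        j[registry.partner[a] == b] = 0.0
        boundary += float(j.sum())
    d_area = registry.area - registry.target_area
    d_perim = registry.perimeter - registry.target_perimeter
    area_term = float((registry.lambda_area * d_area ** 2).sum())
    perim_term = float((registry.lambda_perimeter * d_perim ** 2).sum())
    return EnergyBreakdown(boundary, area_term, perim_term)


# -- single-proposal energetics ---------------------------------------------


def delta_h(field: CellField, registry: CellRegistry,
            table: ContactEnergyTable, params: EngineParameters,
            source_site, target_site) -> float:
    """Energy change of copying the owner of ``source_site`` onto
    ``target_site`` (sites as (row, col); must be order-1 neighbours).
    The field is not modified; a same-owner pair returns 0."""
    s = field.site_index(source_site)
    t = field.site_index(target_site)
    if s not in field.neighbor_table(1)[t]:
        raise ValueError(
            f"{source_site!r} is not a copy-neighbour of {target_site!r}")
    src = int(field.owner_flat[s])
    if src == int(field.owner_flat[t]):
        return 0.0
    nbr = field.neighbor_table(params.neighbor_order)
    scratch_ids = np.empty(nbr.shape[1] + 2, np.int64)
    scratch_dp = np.empty(nbr.shape[1] + 2, np.int64)
    d_total, _, _ = _kernel.delta_h(
        field.owner_flat, nbr, table.matrix, registry.cell_type,
        registry.partner, registry.area, registry.perimeter,
        registry.target_area, registry.target_perimeter,
        registry.lambda_area, registry.lambda_perimeter,
        t, src, scratch_ids, scratch_dp)
    return float(d_total)


def metropolis_accept(d_h: float, temperature: float, rng) -> bool:
    """Boltzmann acceptance: always accept when dH <= 0, otherwise accept
    with probability exp(-dH/T), drawing exactly one uniform variate."""
    if temperature <= 0:
        raise ValueError("temperature must be > 0")
    if d_h <= 0:
        return True
    return rng.random() < math.exp(-d_h / temperature)


# -- dynamics ----------------------------------------------------------------


def run_mcs(field: CellField, registry: CellRegistry,
            table: ContactEnergyTable, params: EngineParameters,
            rng: LatticeRNG, hooks=()) -> tuple[int, float]:
    """Advance the system by one Monte Carlo Step.

    Performs width*height copy attempts at uniformly random sites (with
    replacement), each proposing to paste a uniformly chosen order-1
    neighbour's owner onto the site; increments the MCS counter; then
    invokes ``hooks`` in order with (field, registry, mcs).

    Returns (accepted copies, accumulated boundary-energy change).
    """
    accepted, d_boundary = _kernel.run_attempts(
        field.owner_flat, field.neighbor_table(1),
        field.neighbor_table(params.neighbor_order), table.matrix,
        registry.cell_type, registry.partner, registry.area,
        registry.perimeter, registry.target_area, registry.target_perimeter,
        registry.lambda_area, registry.lambda_perimeter, registry.alive,
        float(params.temperature), field.n_sites, rng.state)
    field.mcs_counter += 1
    for hook in hooks:
        hook(field, registry, field.mcs_counter)
    return int(accepted), float(d_boundary)


class Simulation:
    """Convenience bundle of field + registry + parameters + hooks.

    Tracks a running boundary-energy total (seeded from one full
    recomputation) so the current energy is available without rescanning
    the lattice each MCS.
    """

    def __init__(self, field: CellField, registry: CellRegistry,
                 table: ContactEnergyTable, params: EngineParameters,
                 hooks=()):
        self.field = field
        self.registry = registry
        self.table = table
        self.params = params
        self.hooks = list(hooks)
        self.rng = LatticeRNG(params.rng_seed)
        self.last_accepted = 0
        self._boundary = total_energy(field, registry, table, params,
                                      check=False).boundary_term

    def step(self) -> None:
        accepted, d_boundary = run_mcs(self.field, self.registry, self.table,
                                       self.params, self.rng, self.hooks)
        self.last_accepted = accepted
        self._boundary += d_boundary

    def run(self, n_mcs: int) -> None:
        for _ in range(n_mcs):
            self.step()

    @property
    def mcs(self) -> int:
        return self.field.mcs_counter

    def energy(self) -> EnergyBreakdown:
        """Current energy from cached bookkeeping (no lattice rescan)."""
        r = self.registry
        area_term = float((r.lambda_area *
                           (r.area - r.target_area) ** 2).sum())
        perim_term = float((r.lambda_perimeter *
                            (r.perimeter - r.target_perimeter) ** 2).sum())
        return EnergyBreakdown(self._boundary, area_term, perim_term)


# -- contact topology --------------------------------------------------------


@dataclass
class ContactMap:
    """Shared boundary-link counts of one cell with each neighbour."""

    cell_id: int
    by_cell: dict
    by_type: dict


def contact_lengths(field: CellField, registry: CellRegistry,
                    params: EngineParameters, cell_id: int) -> ContactMap:
    """Boundary links between ``cell_id`` and each neighbouring cell,
    within the boundary neighbourhood, plus per-type aggregates."""
    cell_id = int(cell_id)
    if not (0 < cell_id < registry.n_ids) or not registry.alive[cell_id]:
        raise LookupError(f"no living cell with id {cell_id}")
    owner = field.owner
    mine = owner == cell_id
    by_cell: dict[int, int] = {}
    for dr, dc in neighborhood_offsets(params.neighbor_order):
        shifted = np.roll(owner, (-dr, -dc), axis=(0, 1))
        others = shifted[mine]
        others = others[others != cell_id]
        ids, counts = np.unique(others, return_counts=True)
        for i, n in zip(ids, counts):
            by_cell[int(i)] = by_cell.get(int(i), 0) + int(n)
    by_type = {name: 0 for name in TYPE_NAMES}
    for i, n in by_cell.items():
        by_type[TYPE_NAMES[registry.cell_type[i]]] += n
    return ContactMap(cell_id, by_cell, by_type)


def pairwise_contacts(field: CellField, registry: CellRegistry,
                      params: EngineParameters) -> dict:
    """All inter-cell contact lengths in one sweep: {(a, b): links} with
    a < b, symmetric by construction."""
    owner = field.owner
    n = registry.n_ids
    counts: dict[tuple[int, int], int] = {}
    for dr, dc in HALF_OFFSETS[params.neighbor_order]:
        shifted = np.roll(owner, (-dr, -dc), axis=(0, 1))
        mask = owner != shifted
        a = owner[mask].astype(np.int64)
        b = shifted[mask].astype(np.int64)
        lo = np.minimum(a, b)
        hi = np.maximum(a, b)
        keys, cnt = np.unique(lo * n + hi, return_counts=True)
        for k, c in zip(keys, cnt):
            pair = (int(k // n), int(k % n))
            counts[pair] = counts.get(pair, 0) + int(c)
    return counts


def oc_contact_per_cell(field: CellField, registry: CellRegistry,
                        params: EngineParameters) -> np.ndarray:
    """CS_OC for every cell id: aggregate contact length with OC-type
    neighbours (kernel-accelerated; used by the death sweep)."""
    return _kernel.type_contact_per_cell(
        field.owner_flat, field.neighbor_table(params.neighbor_order),
        registry.cell_type, registry.n_ids, OC)


def medium_contact_per_cell(field: CellField, registry: CellRegistry,
                            params: EngineParameters) -> np.ndarray:
    return _kernel.type_contact_per_cell(
        field.owner_flat, field.neighbor_table(params.neighbor_order),
        registry.cell_type, registry.n_ids, MEDIUM)
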