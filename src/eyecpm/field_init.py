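"""Initial cell fields: a synthetic pupal-eye generator and an
importer/exporter for segmented label images.

The synthetic generator emulates a traced 23:00-24:30 h APF eye: a
hexagonally offset array of disc-shaped ommatidial cores (OCs) whose
interstitial space is tiled one-to-two cells deep by interommatidial
precursor cells (IPCs), every interior IPC touching at least two cores,
with a bounding ring of IPCs and Medium outside.  Real tracings travel the
same path through :func:`import_tracing`.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field as dc_field, replace
from pathlib import Path

import numpy as np

from .engine import (
    IPC, MEDIUM, OC, TYPE_NAMES, CellField, CellRegistry, EngineParameters,
    ShapeConstraints, pairwise_contacts, type_code,
)

__all__ = [
    "SyntheticFieldSpec", "TypeMap", "FieldGenerationError",
    "generate_synthetic_field", "import_tracing", "export_field",
    "read_label_image", "write_label_image",
]

log = logging.getLogger(__name__)


class FieldGenerationError(RuntimeError):
    """The requested geometry cannot satisfy the field invariants."""


@dataclass(frozen=True)
class SyntheticFieldSpec:
    """Geometry of the synthetic eye field.

    rows, cols
        Ommatidia counts of the hexagonal array.
    oc_radius
        Core disc radius in lattice units; the default gives each core an
        order-2 perimeter of ~170 links, so each of its ~10 abutting IPCs
        starts with an OC contact near the wild-type death threshold L=16.
    spacing
        Centre-to-centre distance; must exceed 2*oc_radius so cores never
        touch.
    ipc_band_cells
        IPCs seeded per core-core interstice (plus one per tri-junction).
    medium_margin
        Width of the Medium apron around the tissue, leaving room for the
        field to expand.
    """

    rows: int = 4
    cols: int = 4
    oc_radius: float = 9.0
    spacing: float = 24.0
    ipc_band_cells: int = 3
    medium_margin: float = 24.0
    seed: int = 0

    def __post_init__(self):
        if self.rows < 2 or self.cols < 2:
            raise ValueError("rows and cols must be >= 2")
        if self.spacing <= 2 * self.oc_radius:
            raise ValueError("spacing must exceed 2*oc_radius "
                             "(cores must not touch)")
        if self.ipc_band_cells < 1:
            raise ValueError("ipc_band_cells must be >= 1")


@dataclass(frozen=True)
class TypeMap:
    """Mapping from label-image values to cell types.

    Exactly one label must map to Medium; every label present in an image
    being imported must be mapped.
    """

    mapping: dict

    def __post_init__(self):
        codes = {int(k): type_code(v) for k, v in self.mapping.items()}
        object.__setattr__(self, "mapping", codes)
        if sum(1 for c in codes.values() if c == MEDIUM) != 1:
            raise ValueError("exactly one label must map to Medium")

    @property
    def medium_label(self) -> int:
        return next(k for k, v in self.mapping.items() if v == MEDIUM)


# -- synthetic generator ------------------------------------------------------


def _pair_counts(owner: np.ndarray, neighbor_order: int) -> dict:
    """Undirected inter-label contact link counts on a raw label array."""
    from .engine import HALF_OFFSETS

    n = int(owner.max()) + 1
    counts: dict[tuple[int, int], int] = {}
    for dr, dc in HALF_OFFSETS[neighbor_order]:
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


def _hex_centers(spec: SyntheticFieldSpec, include_ring: bool = False):
    """Centres (x, y) of the OC grid; optionally with one ring of phantom
    positions around it (used to seed the bounding IPC ring)."""
    pitch = spec.spacing * math.sqrt(3.0) / 2.0
    x0 = spec.medium_margin + spec.oc_radius + 1.0
    y0 = spec.medium_margin + spec.oc_radius + 1.0
    lo = -1 if include_ring else 0
    rows = range(lo, spec.rows + (1 if include_ring else 0))
    cols = range(lo, spec.cols + (1 if include_ring else 0))
    out = []
    for i in rows:
        for j in cols:
            real = 0 <= i < spec.rows and 0 <= j < spec.cols
            x = x0 + j * spec.spacing + (i % 2) * spec.spacing / 2.0
            y = y0 + i * pitch
            out.append((x, y, real))
    return out


def _lattice_shape(spec: SyntheticFieldSpec):
    pitch = spec.spacing * math.sqrt(3.0) / 2.0
    width = math.ceil(2 * (spec.medium_margin + spec.oc_radius + 1)
                      + (spec.cols - 1) * spec.spacing + spec.spacing / 2.0)
    height = math.ceil(2 * (spec.medium_margin + spec.oc_radius + 1)
                       + (spec.rows - 1) * pitch)
    return height, width


def generate_synthetic_field(
    spec: SyntheticFieldSpec,
    shape: ShapeConstraints | None = None,
    params: EngineParameters | None = None,
) -> tuple[CellField, CellRegistry]:
    """Build the synthetic initial field.

    OC discs are stamped on a hexagonally offset grid; IPC seeds are
    planted in every core-core interstice (``ipc_band_cells`` per edge,
    one per tri-junction, including phantom edges just outside the array
    to form the bounding ring) and grown by watershed to tile the
    interstitial band.  Targets are initialised to the measured areas and
    perimeters.  Deterministic for a given spec (the seed jitters IPC seed
    positions only).

    Raises :class:`FieldGenerationError` if any interior IPC ends up
    touching fewer than two OCs, or any OCs touch.
    """
    from scipy.spatial import cKDTree
    from skimage.segmentation import watershed

    params = params or EngineParameters()
    rng = np.random.default_rng(spec.seed)
    height, width = _lattice_shape(spec)
    yy, xx = np.mgrid[0:height, 0:width]

    centers = _hex_centers(spec, include_ring=True)
    real_xy = np.array([(x, y) for x, y, real in centers if real])
    n_oc = len(real_xy)

    # 1. stamp the OC discs (ids 1..n_oc)
    owner = np.zeros((height, width), dtype=np.int32)
    for k, (cx, cy) in enumerate(real_xy):
        disc = (xx - cx) ** 2 + (yy - cy) ** 2 <= spec.oc_radius ** 2
        owner[disc] = k + 1

    # 2. tissue mask: within reach of a real core centre
    tissue_radius = 0.66 * spec.spacing
    tree = cKDTree(real_xy)
    dist, _ = tree.query(np.column_stack([xx.reshape(-1), yy.reshape(-1)]))
    tissue = (dist <= tissue_radius).reshape(height, width)
    interstitial = tissue & (owner == 0)

    # 3. IPC seeds: per adjacent centre pair (>=1 real) ipc_band_cells seeds
    #    strung along the channel between the discs; one per tri-junction
    pts = np.array([(x, y) for x, y, _ in centers])
    real_flags = np.array([real for _, _, real in centers])
    pair_tree = cKDTree(pts)
    pairs = sorted(pair_tree.query_pairs(1.15 * spec.spacing))
    seeds = []
    n_band = spec.ipc_band_cells
    for a, b in pairs:
        if not (real_flags[a] or real_flags[b]):
            continue
        mid = (pts[a] + pts[b]) / 2.0
        d = pts[b] - pts[a]
        perp = np.array([-d[1], d[0]])
        perp /= np.linalg.norm(perp)
        # the bounding ring (edges with a phantom endpoint) is one cell deep
        pair_band = n_band if (real_flags[a] and real_flags[b]) else 1
        for k in range(pair_band):
            if pair_band == 1:
                off = 0.0
            else:
                off = (0.16 * spec.spacing * (2 * k - (pair_band - 1))
                       / (pair_band - 1))
            seeds.append(mid + perp * off)
    # at this stage the 2-degree rows have advanced but the vertices have
    # not resolved: no cell is seeded at the tri-junctions.  Instead, one
    # surplus ('ectopic') cell per junction is scattered at random through
    # the interstitial band; the later crowding/death phase must sort them.
    adj = {frozenset(p) for p in pairs}
    n_vertices = 0
    for a, b in pairs:
        for c in range(len(pts)):
            if c <= b or frozenset((a, c)) not in adj \
                    or frozenset((b, c)) not in adj:
                continue
            if real_flags[a] or real_flags[b] or real_flags[c]:
                n_vertices += 1
    seeds = np.array(seeds)
    seeds += rng.normal(0.0, 0.8, size=seeds.shape)
    interstitial_rc = np.argwhere(tissue & (owner == 0))
    extra = []
    min_d2 = 5.0 ** 2
    guard = 0
    while len(extra) < n_vertices and guard < 200 * n_vertices:
        guard += 1
        r_, c_ = interstitial_rc[rng.integers(0, len(interstitial_rc))]
        cand = np.array([c_, r_], dtype=float)
        near = seeds if not extra else np.vstack([seeds, extra])
        if (((near - cand) ** 2).sum(axis=1) < min_d2).any():
            continue
        extra.append(cand)
    if extra:
        seeds = np.vstack([seeds, extra])

    # keep seeds on distinct interstitial pixels
    markers = np.zeros((height, width), dtype=np.int32)
    next_id = n_oc + 1
    for sx, sy in seeds:
        r, c = int(round(sy)), int(round(sx))
        if not (0 <= r < height and 0 <= c < width):
            continue
        if not interstitial[r, c] or markers[r, c] != 0:
            # nudge to the nearest free interstitial pixel in a small window
            window = 4
            best = None
            for rr in range(max(r - window, 0), min(r + window + 1, height)):
                for cc in range(max(c - window, 0), min(c + window + 1, width)):
                    if interstitial[rr, cc] and markers[rr, cc] == 0:
                        d2 = (rr - r) ** 2 + (cc - c) ** 2
                        if best is None or d2 < best[0]:
                            best = (d2, rr, cc)
            if best is None:
                continue
            _, r, c = best
        markers[r, c] = next_id
        next_id += 1

    if next_id == n_oc + 1:
        raise FieldGenerationError("no IPC seeds could be placed")

    # 4. grow seeds to tile the interstitial band (regions stay connected)
    grown = watershed(np.zeros_like(markers), markers=markers,
                      mask=interstitial, connectivity=1)
    owner[grown > 0] = grown[grown > 0]
    leftover = int((interstitial & (grown == 0)).sum())
    if leftover:
        log.info("synthetic field: %d interstitial pixels unreachable from "
                 "any seed were left as Medium", leftover)

    # 5. repair: a squeezed interior IPC that ends up touching < 2 cores is
    #    absorbed by its most-contacted IPC neighbour (the surplus the later
    #    death phase prunes remains, but the >=2-core invariant holds)
    is_oc = np.zeros(int(owner.max()) + 1, dtype=bool)
    is_oc[1:n_oc + 1] = True
    for _ in range(32):
        counts = _pair_counts(owner, params.neighbor_order)
        touches: dict[int, dict[int, int]] = {}
        for (a, b), n in counts.items():
            touches.setdefault(a, {})[b] = n
            touches.setdefault(b, {})[a] = n
        bad = []
        for i in sorted(touches):
            if i <= n_oc:
                continue  # Medium or OC
            nbrs = touches[i]
            if MEDIUM in nbrs:
                continue  # bounding-ring cell
            if sum(1 for j in nbrs if is_oc[j]) < 2:
                bad.append(i)
        if not bad:
            break
        merged = set()
        for i in bad:
            if i in merged:
                continue  # absorbed earlier in this pass
            ipc_nbrs = {j: n for j, n in touches[i].items()
                        if j > n_oc and j not in merged}
            good = {j: n for j, n in ipc_nbrs.items() if j not in bad}
            pick = good or ipc_nbrs  # merging two thin cells also helps
            if not pick:
                continue  # neighbours all absorbed this pass; retry next pass
            owner[owner == i] = max(pick, key=pick.get)
            merged.add(i)
        if not merged:
            raise FieldGenerationError(
                f"interior IPCs {bad} touch < 2 OCs and have no IPC "
                "neighbour to merge with; geometry too sparse")
    else:
        raise FieldGenerationError(
            "could not satisfy the >=2-core-contact property by merging; "
            "geometry too sparse")

    # 6. compact identifiers (dropped seeds, merged cells)
    used = np.unique(owner)
    remap = np.zeros(int(used.max()) + 1, dtype=np.int32)
    remap[used] = np.arange(len(used), dtype=np.int32)
    owner = remap[owner]
    n_ids = len(used)
    types = np.full(n_ids, IPC, dtype=np.int8)
    types[0] = MEDIUM
    types[remap[1:n_oc + 1]] = OC  # disc ids 1..n_oc always survive

    field = CellField(owner)
    registry = CellRegistry.from_field(field, types, shape=shape,
                                       neighbor_order=params.neighbor_order)
    _validate_field(field, registry, params, spec)
    return field, registry


def _validate_field(field, registry, params, spec):
    contacts = pairwise_contacts(field, registry, params)
    oc_ids = set(int(i) for i in registry.living_ids(OC))
    medium_touch = set()
    oc_neighbors: dict[int, set[int]] = {}
    for (a, b), n in contacts.items():
        for me, other in ((a, b), (b, a)):
            if me in oc_ids and other in oc_ids:
                raise FieldGenerationError(
                    f"OC cells {a} and {b} touch ({n} links); increase "
                    "spacing relative to oc_radius")
            if registry.cell_type[me] == IPC:
                if other == MEDIUM:
                    medium_touch.add(me)
                elif other in oc_ids:
                    oc_neighbors.setdefault(me, set()).add(other)
    for ipc_id in registry.living_ids(IPC):
        ipc_id = int(ipc_id)
        if ipc_id in medium_touch:
            continue  # ring cell; allowed any OC contact
        if len(oc_neighbors.get(ipc_id, ())) < 2:
            raise FieldGenerationError(
                f"interior IPC {ipc_id} touches "
                f"{len(oc_neighbors.get(ipc_id, ()))} OC(s); geometry too "
                "sparse for the >=2-core-contact property")


# -- label-image import/export ------------------------------------------------


def read_label_image(path) -> np.ndarray:
    import imageio.v3 as iio

    arr = np.asarray(iio.imread(path))
    if arr.ndim == 3:  # palette PNGs may decode with a channel axis
        if arr.shape[2] == 1:
            arr = arr[..., 0]
        else:
            raise ValueError(
                f"{path}: expected a single-channel integer label image, "
                f"got shape {arr.shape}")
    if not np.issubdtype(arr.dtype, np.integer):
        raise ValueError(f"{path}: label image must have an integer dtype, "
                         f"got {arr.dtype}")
    return arr.astype(np.int32)


def write_label_image(path, labels: np.ndarray) -> None:
    import imageio.v3 as iio
    import tifffile

    path = Path(path)
    labels = np.asarray(labels)
    try:
        if path.suffix.lower() in (".tif", ".tiff"):
            tifffile.imwrite(path, labels.astype(np.int32))
        else:
            if labels.max() > np.iinfo(np.uint16).max:
                raise ValueError(
                    "more than 65535 labels: use a TIFF for export")
            iio.imwrite(path, labels.astype(np.uint16))
    except OSError as exc:
        raise OSError(f"could not write label image {path}: {exc}") from exc


def import_tracing(
    image,
    type_map: TypeMap,
    shape: ShapeConstraints | None = None,
    params: EngineParameters | None = None,
) -> tuple[CellField, CellRegistry]:
    """Convert a segmented tracing (indexed label image) into a cell field.

    Each connected region of a non-Medium label becomes one cell
    (disconnected regions sharing a label become distinct cells, with a
    log notice); all pixels of the Medium label become Medium regardless
    of connectivity.  Targets are initialised to the measured values.
    """
    from scipy import ndimage

    params = params or EngineParameters()
    labels = image if isinstance(image, np.ndarray) else read_label_image(image)
    if not np.issubdtype(np.asarray(labels).dtype, np.integer):
        raise ValueError("label image must be integer-valued")
    labels = np.asarray(labels, dtype=np.int64)

    present = [int(v) for v in np.unique(labels)]
    unmapped = [v for v in present if v not in type_map.mapping]
    if unmapped:
        raise ValueError(f"labels without a type mapping: {unmapped}")

    owner = np.zeros(labels.shape, dtype=np.int32)
    types = [MEDIUM]
    next_id = 1
    for value in present:
        code = type_map.mapping[value]
        if code == MEDIUM:
            continue
        mask = labels == value
        comp, n_comp = ndimage.label(mask)
        if n_comp > 1:
            log.info("label %d split into %d connected cells", value, n_comp)
        for k in range(1, n_comp + 1):
            owner[comp == k] = next_id
            types.append(code)
            next_id += 1

    field = CellField(owner)
    registry = CellRegistry.from_field(field, np.array(types, dtype=np.int8),
                                       shape=shape,
                                       neighbor_order=params.neighbor_order)
    return field, registry


def export_field(field: CellField, registry: CellRegistry, image_path,
                 table_path=None) -> None:
    """Write the field as an integer label image (values = cell ids,
    Medium = 0) plus a CSV sidecar of the registry."""
    write_label_image(image_path, field.owner)
    if table_path is not None:
        try:
            registry.to_frame().to_csv(table_path, index=False)
        except OSError as exc:
            raise OSError(
                f"could not write registry table {table_path}: {exc}") from exc
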