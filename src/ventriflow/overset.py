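"""Chimera (overset) domain bookkeeping at desk scale.

A stationary Cartesian background grid is classified against closed moving
wall surfaces into the four overset categories — dead (outside the fluid),
receptor (fluid cells ringing the dead region, fed by interpolation), donor
(fluid cells supplying interpolation stencils) and solve.  Manual
cut-control pairs exempt a named wall zone from being hole-cut by a named
fluid zone.  Donor→receptor stencils are trilinear over the cell centres of
an overlapping component grid (default: the background grid offset by half a
spacing), so weights are non-negative, sum to one and reproduce affine
fields exactly.  No flow is solved here; the module validates and exports
the bookkeeping a Chimera solver would consume.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import geometry

DEAD, SOLVE, RECEPTOR, DONOR = 0, 1, 2, 3
CATEGORY_NAMES = {DEAD: "dead", SOLVE: "solve", RECEPTOR: "receptor", DONOR: "donor"}


@dataclass(frozen=True)
class CartesianGrid:
    """Uniform cell-centred Cartesian grid (mm)."""
    origin: tuple            # corner of the first cell
    spacing: float           # cubic cell edge length
    dims: tuple              # number of cells per axis

    def __post_init__(self):
        if self.spacing <= 0:
            raise ValueError("spacing must be > 0")
        if any(d < 2 for d in self.dims):
            raise ValueError("need at least 2 cells per axis")

    @property
    def n_cells(self) -> int:
        return int(np.prod(self.dims))

    @property
    def cell_volume_mm3(self) -> float:
        return self.spacing ** 3

    def axes(self):
        o = np.asarray(self.origin, dtype=float)
        return tuple(o[k] + self.spacing * (np.arange(self.dims[k]) + 0.5)
                     for k in range(3))

    def cell_centers(self) -> np.ndarray:
        xs, ys, zs = self.axes()
        X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")
        return np.stack([X, Y, Z], axis=-1).reshape(-1, 3)

    def shifted(self, offset: float | tuple) -> "CartesianGrid":
        off = np.broadcast_to(np.asarray(offset, dtype=float), 3)
        return CartesianGrid(tuple(np.asarray(self.origin) + off), self.spacing, self.dims)


@dataclass
class WallSurface:
    """A closed component wall; fluid lies on ``fluid_side`` of it."""
    vertices: np.ndarray
    faces: np.ndarray
    fluid_side: str = "inside"   # "inside": cavity wall; "outside": immersed solid
    zone_id: int = 0             # wall zone identifier (for cut-control)
    cuts_fluid_zones: tuple = (0,)  # fluid zones this wall may hole-cut

    def __post_init__(self):
        nb = geometry.boundary_edge_count(self.faces)
        if nb:
            raise geometry.OpenSurfaceError(nb)


@dataclass(frozen=True)
class CutControl:
    """Exclusion pairs (wall_zone_id, fluid_zone_id): that fluid zone must not
    hole-cut cells against that wall."""
    exclusions: frozenset = frozenset()

    @classmethod
    def of(cls, *pairs) -> "CutControl":
        return cls(frozenset(pairs))

    def excluded(self, wall_zone: int, fluid_zone: int) -> bool:
        return (wall_zone, fluid_zone) in self.exclusions


@dataclass
class CellCategory:
    """Per-cell overset category labels on a grid."""
    labels: np.ndarray            # (nx, ny, nz) int in {DEAD, SOLVE, RECEPTOR, DONOR}
    grid: CartesianGrid
    fluid_zone: np.ndarray | None = None   # optional per-cell fluid zone id

    def counts(self) -> dict:
        return {name: int(np.sum(self.labels == code))
                for code, name in CATEGORY_NAMES.items()}

    def is_partition(self) -> bool:
        return sum(self.counts().values()) == self.grid.n_cells


@dataclass
class OversetInterface:
    """Trilinear receptor→donor stencils over a component grid."""
    receptor_indices: np.ndarray   # (n_receptors, 3) background cell indices
    donor_indices: np.ndarray      # (n_receptors, 8, 3) component cell indices
    weights: np.ndarray            # (n_receptors, 8) trilinear weights
    donor_grid: CartesianGrid
    orphans: list = field(default_factory=list)   # receptor indices without a stencil

    @property
    def n_receptors(self) -> int:
        return len(self.receptor_indices)

    def interpolate(self, donor_values: np.ndarray) -> np.ndarray:
        """Interpolate a per-donor-cell scalar field to the receptors."""
        vals = donor_values[tuple(self.donor_indices.reshape(-1, 3).T)]
        return (vals.reshape(-1, 8) * self.weights).sum(axis=1)


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def classify_cells(grid: CartesianGrid, walls, cuts: CutControl | None = None,
                   fluid_zone: np.ndarray | None = None,
                   receptor_band: int = 1) -> CellCategory:
    """Classify background cells into dead/solve/receptor/donor.

    Cell centres on the non-fluid side of any wall are dead (unless a
    cut-control exclusion protects them); fluid cells within
    ``receptor_band`` cells of a dead cell are receptors; fluid cells
    adjacent to a receptor are donors; the remainder solve.
    """
    cuts = cuts or CutControl()
    nx, ny, nz = grid.dims
    if fluid_zone is None:
        fluid_zone = np.zeros(grid.dims, dtype=np.int64)
    dead = np.zeros(grid.dims, dtype=bool)
    xs, ys, zs = grid.axes()
    for wall in walls:
        inside = geometry.grid_column_inside(xs, ys, zs, wall.vertices, wall.faces)
        nonfluid = ~inside if wall.fluid_side == "inside" else inside
        cut_allowed = np.zeros(grid.dims, dtype=bool)
        for fz in wall.cuts_fluid_zones:
            if not cuts.excluded(wall.zone_id, fz):
                cut_allowed |= fluid_zone == fz
        dead |= nonfluid & cut_allowed
    labels = np.full(grid.dims, SOLVE, dtype=np.int8)
    labels[dead] = DEAD
    fluid = ~dead
    near_dead = _dilate(dead, receptor_band)
    labels[fluid & near_dead] = RECEPTOR
    near_receptor = _dilate(labels == RECEPTOR, 1)
    labels[fluid & ~near_dead & near_receptor] = DONOR
    return CellCategory(labels, grid, fluid_zone)


def _dilate(mask: np.ndarray, n: int) -> np.ndarray:
    """6-connected binary dilation by n cells (numpy shifts; no scipy.ndimage
    dependency on behaviour details at the domain boundary)."""
    out = mask.copy()
    for _ in range(n):
        grown = out.copy()
        for axis in range(3):
            for shift in (1, -1):
                grown |= np.roll(out, shift, axis=axis) & _roll_valid(out.shape, shift, axis)
        out = grown
    return out


def _roll_valid(shape, shift, axis):
    """Mask of positions whose np.roll source did not wrap around."""
    valid = np.ones(shape, dtype=bool)
    sl = [slice(None)] * 3
    sl[axis] = slice(0, 1) if shift == 1 else slice(-1, None)
    valid[tuple(sl)] = False
    return valid


def build_interface(category: CellCategory, grid: CartesianGrid,
                    donor_grid: CartesianGrid | None = None,
                    donor_category: CellCategory | None = None) -> OversetInterface:
    """Build trilinear donor stencils for every receptor cell.

    Donors are cells of ``donor_grid`` (default: the background grid offset
    by half a spacing, the minimal overlapping component grid).  A receptor
    is orphaned — reported, not silently dropped — when its containing donor
    block leaves the grid or touches a dead/receptor donor cell, mirroring
    the vanishing-zone failure mode of overset solvers.
    """
    if donor_grid is None:
        donor_grid = grid.shifted(grid.spacing / 2.0)
    rec = np.argwhere(category.labels == RECEPTOR)
    centers = (np.asarray(grid.origin) + grid.spacing * (rec + 0.5))
    h = donor_grid.spacing
    u = (centers - np.asarray(donor_grid.origin)) / h - 0.5
    i0 = np.floor(u).astype(np.int64)
    frac = u - i0
    # receptor exactly on a donor node: snap for weight-1 stencils
    snap = np.isclose(frac, 1.0, atol=1e-12)
    i0[snap] += 1
    frac[snap] = 0.0
    corners = np.array([[di, dj, dk] for di in (0, 1) for dj in (0, 1) for dk in (0, 1)])
    donor_idx = i0[:, None, :] + corners[None, :, :]
    w = np.ones((len(rec), 8))
    for c in range(8):
        for ax in range(3):
            f = frac[:, ax]
            w[:, c] *= f if corners[c, ax] else (1.0 - f)
    dims = np.asarray(donor_grid.dims)
    in_bounds = np.all((donor_idx >= 0) & (donor_idx < dims), axis=(1, 2))
    valid = in_bounds.copy()
    if donor_category is not None:
        lab = donor_category.labels
        clipped = np.clip(donor_idx, 0, dims - 1)
        dlab = lab[clipped[..., 0], clipped[..., 1], clipped[..., 2]]
        # weight-0 corners are not part of the effective stencil
        bad = np.any(((dlab == DEAD) | (dlab == RECEPTOR)) & (w > 1e-14), axis=1)
        valid &= ~bad
    orphans = [tuple(r) for r in rec[~valid]]
    return OversetInterface(rec[valid], donor_idx[valid], w[valid], donor_grid, orphans)


def detect_vanishing_zone(categories, zone_masks: dict | None = None,
                          drop_fraction: float = 0.5) -> dict:
    """Flag fluid zones whose solve-cell count vanishes or collapses between frames.

    ``categories`` is a sequence of :class:`CellCategory` for the same zones;
    ``zone_masks`` maps zone name → boolean cell mask (default: one zone
    covering the whole grid).  Returns ``{"flags": [(frame, zone, reason)],
    "counts": {zone: [per-frame solve counts]}}``.
    """
    cats = list(categories)
    if len(cats) < 2:
        raise ValueError("need at least two frames of classifications")
    if zone_masks is None:
        zone_masks = {"all": np.ones(cats[0].grid.dims, dtype=bool)}
    counts = {z: [int(np.sum((c.labels != DEAD) & m)) for c in cats]
              for z, m in zone_masks.items()}
    flags = []
    for z, series in counts.items():
        for k in range(1, len(series)):
            if series[k] == 0 and series[k - 1] > 0:
                flags.append((k, z, "vanished"))
            elif series[k - 1] > 0 and series[k] < (1 - drop_fraction) * series[k - 1]:
                flags.append((k, z, f"dropped {series[k - 1]}→{series[k]}"))
    return {"flags": flags, "counts": counts}


def fluid_volume_ml(category: CellCategory) -> float:
    """Fluid volume (solve + receptor + donor cells) in ml."""
    n_fluid = int(np.sum(category.labels != DEAD))
    return n_fluid * category.grid.cell_volume_mm3 / 1000.0
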