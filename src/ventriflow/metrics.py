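"""Hemodynamic field metrics.

Implements the post-processing suite: the viscous dissipation rate
Φ_V = ½ μ Σ_i Σ_j (∂u_i/∂x_j + ∂u_j/∂x_i)² and its time/volume integral
(energy loss, J), vorticity magnitude, area-weighted velocity/vorticity
class fractions on long-axis and short-axis analysis planes, wall shear
stress from a near-wall tangential-velocity probe, and mean/max aggregation
of wall scalars over the 17-segment (AHA) bull's-eye partition of the
endocardium, including case-difference maps.

Gradients use central differences inside the in-domain mask and one-sided
differences at mask boundaries.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import geometry
from .flow import FlowField, MM_TO_M
from .overset import CartesianGrid

# AHA bands: fraction of the apex→base axis, apex cap lowest
_AHA_BANDS = ((0.00, 0.20, "apex", 1), (0.20, 0.45, "apical", 4),
              (0.45, 0.70, "mid", 6), (0.70, 1.001, "basal", 6))
N_SECTORS = 17


def masked_derivative(f: np.ndarray, mask: np.ndarray, axis: int, h: float) -> np.ndarray:
    """∂f/∂x_axis with step h: central where both neighbours are in-mask,
    one-sided at mask boundaries, 0 where no in-mask neighbour exists."""
    fp = np.roll(f, -1, axis=axis)
    fm = np.roll(f, 1, axis=axis)
    mp = np.roll(mask, -1, axis=axis)
    mm = np.roll(mask, 1, axis=axis)
    # forbid wrap-around neighbours
    sl_hi = [slice(None)] * f.ndim
    sl_hi[axis] = slice(-1, None)
    sl_lo = [slice(None)] * f.ndim
    sl_lo[axis] = slice(0, 1)
    mp = mp.copy()
    mp[tuple(sl_hi)] = False
    mm = mm.copy()
    mm[tuple(sl_lo)] = False
    central = mp & mm
    fwd = mp & ~mm
    bwd = mm & ~mp
    out = np.zeros_like(f, dtype=float)
    out[central] = (fp[central] - fm[central]) / (2 * h)
    out[fwd] = (fp[fwd] - f[fwd]) / h
    out[bwd] = (f[bwd] - fm[bwd]) / h
    out[~mask] = 0.0
    return out


def velocity_gradient(field: FlowField, frame: int) -> np.ndarray:
    """∂u_i/∂x_j tensor per cell (1/s), shape (*dims, 3, 3)."""
    v = field.velocity[frame]
    m = field.mask[frame]
    h = field.grid.spacing * MM_TO_M
    g = np.zeros((*field.grid.dims, 3, 3))
    for i in range(3):
        for j in range(3):
            g[..., i, j] = masked_derivative(v[..., i], m, j, h)
    return g


def viscous_dissipation_rate(velocity_gradient: np.ndarray, mu: float) -> np.ndarray:
    """Φ_V = ½ μ Σ_i Σ_j (∂u_i/∂x_j + ∂u_j/∂x_i)², W/m³ (formula as printed)."""
    g = np.asarray(velocity_gradient, dtype=float)
    sym = g + np.swapaxes(g, -1, -2)
    return 0.5 * mu * np.sum(sym ** 2, axis=(-1, -2))


@dataclass
class EnergyLoss:
    el: float                     # J over [t0, t1]
    per_frame: np.ndarray         # J contribution of each integration step
    t0: float
    t1: float
    dt: np.ndarray                # step widths (s)


def energy_loss(field: FlowField, mu: float, t0: float, t1: float) -> EnergyLoss:
    """EL = Σ_frames Σ_cells Φ_V · V_i · dt over frames with t0 ≤ t ≤ t1."""
    sel = np.where((field.times >= t0 - 1e-12) & (field.times <= t1 + 1e-12))[0]
    if len(sel) == 0:
        raise ValueError("no frames inside [t0, t1]")
    v_cell = (field.grid.spacing * MM_TO_M) ** 3  # m^3
    if len(sel) == 1:
        dt = np.array([t1 - t0])
    else:
        # trapezoidal weights: interior (t[k+1]-t[k-1])/2, half-steps at the
        # ends, so the weights sum exactly to the covered span
        ts = field.times[sel]
        dt = np.empty(len(sel))
        dt[1:-1] = (ts[2:] - ts[:-2]) / 2.0
        dt[0] = (ts[1] - ts[0]) / 2.0
        dt[-1] = (ts[-1] - ts[-2]) / 2.0
    contrib = np.zeros(len(sel))
    warned_empty = False
    for n, k in enumerate(sel):
        m = field.mask[k]
        if not m.any():
            warned_empty = True
            continue
        phi = viscous_dissipation_rate(velocity_gradient(field, k), mu)
        contrib[n] = np.sum(phi[m]) * v_cell * dt[n]
    if warned_empty:
        import warnings
        warnings.warn("empty in-domain mask in some frames; EL contribution 0")
    return EnergyLoss(float(contrib.sum()), contrib, t0, t1, dt)


def q_criterion(field: FlowField, frame: int = 0) -> np.ndarray:
    """Q = ½(‖Ω‖² − ‖S‖²): positive inside vortex cores, ~0 in pure shear,
    negative in strain-dominated (e.g. sink) flow.  NaN outside the mask."""
    g = velocity_gradient(field, frame)
    S = 0.5 * (g + np.swapaxes(g, -1, -2))
    W = 0.5 * (g - np.swapaxes(g, -1, -2))
    q = 0.5 * (np.sum(W ** 2, axis=(-1, -2)) - np.sum(S ** 2, axis=(-1, -2)))
    q[~field.mask[frame]] = np.nan
    return q


def vorticity_magnitude(field: FlowField, frame: int = 0) -> np.ndarray:
    """|∇×u| (1/s) by masked central differences; NaN outside the mask."""
    v = field.velocity[frame]
    m = field.mask[frame]
    h = field.grid.spacing * MM_TO_M
    d = lambda comp, ax: masked_derivative(v[..., comp], m, ax, h)
    wx = d(2, 1) - d(1, 2)
    wy = d(0, 2) - d(2, 0)
    wz = d(1, 0) - d(0, 1)
    out = np.sqrt(wx ** 2 + wy ** 2 + wz ** 2)
    out[~m] = np.nan
    return out


# ---------------------------------------------------------------------------
# analysis planes and class fractions
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ClassBins:
    """Ascending class edges for velocity (m/s) or vorticity (1/s) magnitude."""
    metric: str
    edges: tuple
    plane: str = "LA"

    def __post_init__(self):
        if not all(a < b for a, b in zip(self.edges, self.edges[1:])):
            raise ValueError("edges must be strictly ascending")


DEFAULT_VELOCITY_BINS = (0.0, 0.25, 0.5, 1.0, np.inf)
DEFAULT_VORTICITY_BINS = (0.0, 250.0, 500.0, 750.0, np.inf)


def plane_slice(field: FlowField, scalar: np.ndarray, plane: str,
                axis_length_mm: float | None = None) -> np.ndarray:
    """Extract an analysis-plane slice of a per-cell scalar.

    SA1/SA2/SA3 are short-axis (z = 75/50/25% of the apex–base extent, top to
    bottom); LA is the long-axis plane y ≈ 0 through apex, MV centroid and
    outlet.  Returns a 2D array with NaN outside the domain mask.
    """
    zs = field.grid.axes()[2]
    if plane.upper() in {"SA1", "SA2", "SA3"}:
        fracs = {"SA1": 0.75, "SA2": 0.50, "SA3": 0.25}
        zmax = axis_length_mm if axis_length_mm is not None else zs[-1]
        ztarget = fracs[plane.upper()] * zmax
        k = int(np.argmin(np.abs(zs - ztarget)))
        return scalar[:, :, k]
    if plane.upper() == "LA":
        ys = field.grid.axes()[1]
        j = int(np.argmin(np.abs(ys - 0.0)))
        return scalar[:, j, :]
    raise ValueError(f"unknown plane {plane!r}; expected LA, SA1, SA2 or SA3")


def class_fractions(plane_values: np.ndarray, bins: ClassBins) -> np.ndarray:
    """Area-weighted fraction of the in-domain plane in each class (sums to 1)."""
    vals = np.asarray(plane_values, dtype=float).ravel()
    vals = vals[np.isfinite(vals)]
    if len(vals) == 0:
        raise ValueError("no in-domain samples on the plane")
    edges = np.asarray(bins.edges, dtype=float)
    counts, _ = np.histogram(np.clip(vals, edges[0], None), bins=edges)
    # values exactly at the last finite edge belong to the top class already
    return counts / counts.sum()


# ---------------------------------------------------------------------------
# wall shear stress and bull's-eye aggregation
# ---------------------------------------------------------------------------

@dataclass
class WSSField:
    tau: np.ndarray        # Pa per endocardial vertex (NaN = probe left the mask)
    vertices: np.ndarray   # mm
    faces: np.ndarray
    flagged: np.ndarray    # bool per vertex


def wall_shear_stress(field: FlowField, wall_vertices: np.ndarray,
                      wall_faces: np.ndarray, mu: float, frame: int = 0,
                      delta_mm: float | None = None) -> WSSField:
    """τ = μ‖u_t(δ)‖/δ with the probe one grid spacing inside the wall.

    ``u_t`` is the velocity component tangential to the wall at the first
    in-fluid sample along the inward normal.  Vertices whose probe exits the
    mask are flagged and excluded from aggregates (NaN).
    """
    delta = delta_mm if delta_mm is not None else field.grid.spacing
    normals = geometry.vertex_normals(wall_vertices, wall_faces)  # outward
    probes = wall_vertices - delta * normals
    u = field.sample_velocity(probes, float(field.times[frame]))
    in_mask = field.in_mask(probes, float(field.times[frame]))
    un = np.einsum("ij,ij->i", u, normals)[:, None] * normals
    ut = u - un
    tau = mu * np.linalg.norm(ut, axis=1) / (delta * MM_TO_M)
    tau[~in_mask] = np.nan
    return WSSField(tau, np.asarray(wall_vertices, float), np.asarray(wall_faces), ~in_mask)


@dataclass
class BullseyeMap:
    """Mean and max of a wall scalar over the 17 AHA sectors."""
    mean: np.ndarray   # (17,)
    max: np.ndarray    # (17,)
    sector_of_vertex: np.ndarray
    sector_names: tuple

    def as_table(self):
        import pandas as pd
        return pd.DataFrame({"sector": np.arange(1, N_SECTORS + 1),
                             "name": self.sector_names,
                             "mean": self.mean, "max": self.max})


def aha_sectors(vertices: np.ndarray, *, apex=(0.0, 0.0, 0.0), base_z: float | None = None,
                angular_origin_deg: float = 0.0) -> np.ndarray:
    """AHA 17-segment id (1..17) per endocardial vertex.

    Bands along the apex→base axis: apex cap, 4 apical, 6 mid, 6 basal
    sectors; circumferential origin at ``angular_origin_deg`` from +x
    (anterior interventricular groove surrogate).
    """
    v = np.asarray(vertices, dtype=float)
    z0 = apex[2]
    z1 = base_z if base_z is not None else v[:, 2].max()
    s = np.clip((v[:, 2] - z0) / (z1 - z0), 0.0, 1.0)
    theta = np.mod(np.degrees(np.arctan2(v[:, 1] - apex[1], v[:, 0] - apex[0]))
                   - angular_origin_deg, 360.0)
    out = np.zeros(len(v), dtype=np.int64)
    first_id = {"apex": 17, "apical": 13, "mid": 7, "basal": 1}
    for lo, hi, name, nsec in _AHA_BANDS:
        m = (s >= lo) & (s < hi)
        if name == "apex":
            out[m] = 17
        else:
            sec = np.floor(theta[m] / (360.0 / nsec)).astype(np.int64)
            out[m] = first_id[name] + sec
    return out


_SECTOR_NAMES = tuple(
    [f"basal-{i}" for i in range(1, 7)] + [f"mid-{i}" for i in range(1, 7)]
    + [f"apical-{i}" for i in range(1, 5)] + ["apex"])


def bullseye_aggregate(wss: WSSField, *, apex=(0.0, 0.0, 0.0),
                       base_z: float | None = None,
                       angular_origin_deg: float = 0.0) -> BullseyeMap:
    """Area-weighted per-sector mean and max of the wall scalar."""
    sector = aha_sectors(wss.vertices, apex=apex, base_z=base_z,
                         angular_origin_deg=angular_origin_deg)
    areas = geometry.vertex_areas(wss.vertices, wss.faces)
    mean = np.zeros(N_SECTORS)
    mx = np.zeros(N_SECTORS)
    for sid in range(1, N_SECTORS + 1):
        m = (sector == sid) & np.isfinite(wss.tau)
        if m.any():
            w = areas[m]
            mean[sid - 1] = np.average(wss.tau[m], weights=w)
            mx[sid - 1] = wss.tau[m].max()
    return BullseyeMap(mean, mx, sector, _SECTOR_NAMES)


def bullseye_difference(map_a: BullseyeMap, map_b: BullseyeMap) -> BullseyeMap:
    """Sectorwise a − b (positive where the first case dominates)."""
    if map_a.sector_names != map_b.sector_names:
        raise ValueError("bull's-eye sector layouts differ")
    return BullseyeMap(map_a.mean - map_b.mean, map_a.max - map_b.max,
                       map_a.sector_of_vertex, map_a.sector_names)


def plot_bullseye(bmap: BullseyeMap, path, value: str = "mean", title: str = ""):
    """Render the 17-sector polar map to an SVG/PNG file."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    vals = getattr(bmap, value)
    fig, ax = plt.subplots(subplot_kw={"projection": "polar"}, figsize=(5, 5))
    rings = [(1, 6, 0.75, 1.0), (7, 6, 0.5, 0.75), (13, 4, 0.25, 0.5), (17, 1, 0.0, 0.25)]
    vmax = np.nanmax(np.abs(vals)) or 1.0
    cmap = plt.get_cmap("coolwarm")
    for first, nsec, r0, r1 in rings:
        for k in range(nsec):
            th0 = 2 * np.pi * k / nsec
            th = np.linspace(th0, th0 + 2 * np.pi / nsec, 16)
            val = vals[first - 1 + k]
            ax.fill_between(th, r0, r1, color=cmap(0.5 + 0.5 * val / vmax))
            ax.text(th.mean(), (r0 + r1) / 2, f"{val:.2g}", ha="center", va="center", fontsize=7)
    ax.set_yticks([])
    ax.set_xticks([])
    ax.set_title(title or f"bull's-eye ({value})")
    fig.savefig(path, bbox_inches="tight")
    plt.close(fig)


def background_cell_volume_mm3(edge_length_mm: float) -> float:
    """Cell volume of a cubic background grid with the given edge length."""
    return edge_length_mm ** 3
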