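"""Kinematic mitral-valve model.

The valve is built from a static annulus (the temporal average of its 4D
configurations) lofted to the free-edge profile captured at the A-wave peak,
with a 2 mm physical thickness.  Opening angles are not homogeneous: a
periodic shaping function divides the valve into four zones (anterior
leaflet, posterior leaflet, front and posterior commissure) and blends the
four zone-mean angles smoothly around the circumference, leaving extra
wall clearance at the commissures.  Leaflet motion is a rigid rotation of
each circumferential station about its local annulus-tangent hinge, scaled
in time by a periodic opening schedule (the valve is not sealed in systole).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import geometry

ZONES = ("anterior_leaflet", "front_commissure", "posterior_leaflet", "posterior_commissure")
# circumferential zone centres (deg) and half-widths used for membership
_ZONE_CENTERS = {"anterior_leaflet": 0.0, "front_commissure": 90.0,
                 "posterior_leaflet": 180.0, "posterior_commissure": 270.0}
_ZONE_HALFWIDTH = {"anterior_leaflet": 60.0, "front_commissure": 30.0,
                   "posterior_leaflet": 60.0, "posterior_commissure": 30.0}


@dataclass
class AnnulusModel:
    """Static (cycle-averaged) mitral annulus as a closed 3D polyline."""
    control_points: np.ndarray   # (n, 3) mm, closed implicitly (last connects to first)
    centroid: np.ndarray
    plane_normal: np.ndarray

    @classmethod
    def from_points(cls, points: np.ndarray) -> "AnnulusModel":
        points = np.asarray(points, dtype=float)
        centroid = points.mean(axis=0)
        # best-fit plane normal: smallest principal direction
        _, _, vt = np.linalg.svd(points - centroid, full_matrices=False)
        normal = vt[-1]
        if normal[2] < 0:  # orient toward the base (+z)
            normal = -normal
        return cls(points, centroid, normal)

    @property
    def n_points(self) -> int:
        return len(self.control_points)

    def tangents(self) -> np.ndarray:
        """Unit tangents of the closed polyline (central differences)."""
        p = self.control_points
        t = np.roll(p, -1, axis=0) - np.roll(p, 1, axis=0)
        return t / np.linalg.norm(t, axis=1, keepdims=True)

    def stations_deg(self) -> np.ndarray:
        """Circumferential station angle of each control point, degrees in [0, 360)."""
        rel = self.control_points - self.centroid
        e1 = rel[0] - np.dot(rel[0], self.plane_normal) * self.plane_normal
        e1 /= np.linalg.norm(e1)
        e2 = np.cross(self.plane_normal, e1)
        ang = np.degrees(np.arctan2(rel @ e2, rel @ e1))
        return np.mod(ang, 360.0)


@dataclass
class LeafletSurface:
    """One leaflet sheet: a structured loft from annulus to free edge."""
    mid_surface: np.ndarray      # (n_rows, n_cols, 3) mm; row 0 on the annulus
    thickness: float             # mm
    side: str                    # "anterior" | "posterior"
    station_deg: np.ndarray      # (n_cols,) circumferential station of each column
    hinge_points: np.ndarray     # (n_cols, 3) annulus points (hinge anchors)
    hinge_tangents: np.ndarray   # (n_cols, 3) unit hinge axes
    annulus_centroid: np.ndarray = None  # set at build time; used for opening direction

    @property
    def n_rows(self) -> int:
        return self.mid_surface.shape[0]

    @property
    def n_cols(self) -> int:
        return self.mid_surface.shape[1]

    def vertices(self) -> np.ndarray:
        return self.mid_surface.reshape(-1, 3)

    def faces(self) -> np.ndarray:
        """Triangulation of the structured mid-surface grid (open strip)."""
        nr, nc = self.n_rows, self.n_cols
        idx = np.arange(nr * nc).reshape(nr, nc)
        f = []
        for i in range(nr - 1):
            for j in range(nc - 1):
                f.append([idx[i, j], idx[i, j + 1], idx[i + 1, j]])
                f.append([idx[i, j + 1], idx[i + 1, j + 1], idx[i + 1, j]])
        return np.asarray(f, dtype=np.int64)

    def offset_surfaces(self) -> tuple[np.ndarray, np.ndarray]:
        """Atrial/ventricular faces of the leaflet: mid ± thickness/2 along normals."""
        v = self.vertices()
        n = geometry.vertex_normals(v, self.faces()) if self.n_rows > 1 else np.zeros_like(v)
        shift = 0.5 * self.thickness * n
        shape = self.mid_surface.shape
        return (v + shift).reshape(shape), (v - shift).reshape(shape)

    def free_edge(self) -> np.ndarray:
        return self.mid_surface[-1]


@dataclass
class ZonePartition:
    zone_of_vertex: np.ndarray        # (n_cols,) str labels per circumferential station
    zone_mean_angle: dict             # zone -> mean opening angle (deg)
    vertex_angle: np.ndarray          # (n_cols,) shaped per-station peak angle (deg)


@dataclass
class OpeningSchedule:
    """Periodic per-zone opening-angle schedule.

    The normalized profile f(t) in [residual, 1] opens over early diastole,
    relaxes during diastasis, re-opens at the A-wave and closes at
    end-diastole; a small residual gap remains in systole.  Per-zone angle at
    time t is ``zone_peak_angle * f(t)``.
    """
    cycle_duration: float = 0.87
    end_systole_time: float = 0.29
    e_peak_time: float = 0.42
    a_peak_time: float = 0.78
    open_max: float = 1.0            # normalized plateau
    closed_min: float = 0.08         # residual systolic gap fraction
    diastasis_level: float = 0.45
    a_level: float = 0.85
    zone_peak_angle: dict = field(default_factory=lambda: {
        "anterior_leaflet": 55.0, "posterior_leaflet": 40.0,
        "front_commissure": 25.0, "posterior_commissure": 25.0})

    def fraction(self, t: float) -> float:
        """Normalized opening fraction at time t (periodic)."""
        t = float(np.mod(t, self.cycle_duration))
        ts, T = self.end_systole_time, self.cycle_duration

        def smooth(x):
            x = np.clip(x, 0.0, 1.0)
            return x * x * (3 - 2 * x)

        t_open = ts + 0.06                   # fully open after early rapid opening
        t_dia0 = 0.5 * (self.e_peak_time + self.a_peak_time) - 0.06
        t_dia1 = t_dia0 + 0.08               # relax into diastasis
        t_a0 = self.a_peak_time - 0.06
        t_close0 = self.a_peak_time + 0.05   # final closure window
        if t <= ts:
            return self.closed_min
        f = self.closed_min + (self.open_max - self.closed_min) * smooth((t - ts) / (t_open - ts))
        f -= (self.open_max - self.diastasis_level) * smooth((t - t_dia0) / (t_dia1 - t_dia0))
        f += (self.a_level - self.diastasis_level) * smooth((t - t_a0) / (self.a_peak_time - t_a0))
        f -= (max(f, self.closed_min) - self.closed_min) * smooth((t - t_close0) / (T - t_close0))
        return float(np.clip(f, self.closed_min, self.open_max))

    def angle(self, zone: str, t: float) -> float:
        return self.zone_peak_angle[zone] * self.fraction(t)


@dataclass
class MitralValve:
    """Assembled valve: annulus, two leaflet sheets, zone shaping."""
    annulus: AnnulusModel
    anterior: LeafletSurface
    posterior: LeafletSurface
    partition: ZonePartition
    thickness: float


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def average_annulus(annulus_frames) -> AnnulusModel:
    """Pointwise temporal mean of 4D annulus polylines (consistent ordering assumed)."""
    frames = [np.asarray(f, dtype=float) for f in annulus_frames]
    n = frames[0].shape
    if any(f.shape != n for f in frames):
        raise ValueError("all annulus frames must have the same point count")
    return AnnulusModel.from_points(np.mean(frames, axis=0))


def circular_annulus(center=(0.0, 0.0, 80.0), radius=11.0, n_points=64,
                     saddle_amplitude=0.0) -> AnnulusModel:
    """Parametric (optionally saddle-shaped) annulus used by the synthetic pipeline."""
    th = 2 * np.pi * np.arange(n_points) / n_points
    pts = np.column_stack([
        center[0] + radius * np.cos(th),
        center[1] + radius * np.sin(th),
        center[2] + saddle_amplitude * np.cos(2 * th),
    ])
    return AnnulusModel.from_points(pts)


def default_free_edge(annulus: AnnulusModel, *, scale: float = 0.35,
                      drop: float = 9.0) -> np.ndarray:
    """Free-edge profile (A-wave capture surrogate): annulus shrunk and moved apex-ward."""
    rel = annulus.control_points - annulus.centroid
    return annulus.centroid + scale * rel - [0.0, 0.0, drop]


def build_leaflets(annulus: AnnulusModel, free_edge: np.ndarray, thickness: float = 2.0,
                   n_rows: int = 8, overlap_deg: float = 15.0
                   ) -> tuple[LeafletSurface, LeafletSurface]:
    """Loft the mid-surface from the annulus to the free edge and split it.

    The loft linearly blends annulus point j to free-edge point j over
    ``n_rows`` rows.  The sheet is split along the commissural diameter
    (stations 90° and 270°) into anterior (|station| ≤ 90° + overlap) and
    posterior sheets sharing an ``overlap_deg`` band on both sides, mirroring
    the overlapping-layer separation required by overset bookkeeping.
    """
    free_edge = np.asarray(free_edge, dtype=float)
    if free_edge.shape != annulus.control_points.shape:
        raise ValueError("free edge must have one point per annulus point")
    if np.any(free_edge[:, 2] > annulus.control_points[:, 2].max() + 1e-9):
        raise ValueError("free edge must lie on the ventricular side of the annulus plane")
    if thickness < 0:
        raise ValueError("thickness must be >= 0")
    w = np.linspace(0.0, 1.0, n_rows)[:, None, None]
    loft = (1 - w) * annulus.control_points[None] + w * free_edge[None]  # (rows, n, 3)
    stations = annulus.stations_deg()
    tangents = annulus.tangents()

    def take(mask, side):
        cols = np.where(mask)[0]
        # keep columns circularly contiguous for a clean sheet
        order = np.argsort(np.mod(stations[cols] + (180.0 if side == "anterior" else 0.0), 360.0))
        cols = cols[order]
        return LeafletSurface(loft[:, cols, :].copy(), thickness, side,
                              stations[cols], annulus.control_points[cols].copy(),
                              tangents[cols].copy(), annulus.centroid.copy())

    ant_mask = (np.minimum(stations, 360 - stations) <= 90.0 + overlap_deg)
    post_mask = (np.abs(stations - 180.0) <= 90.0 + overlap_deg)
    anterior = take(ant_mask, "anterior")
    posterior = take(post_mask, "posterior")
    if not np.all(ant_mask | post_mask):
        raise ValueError("anterior/posterior split leaves uncovered annulus stations")
    return anterior, posterior


def _blend_basis(stations_deg: np.ndarray, smooth_halfwidth: float = 5.0,
                 _nquad: int = 9) -> np.ndarray:
    """Periodic cardinal blend functions of the four zone centres, shape (n, 4).

    Column j is a periodic tent (linear cardinal) function of zone centre j,
    softened by a narrow moving average so corners are rounded.  The set is a
    partition of unity with no overshoot, and its slope is the smallest any
    interpolating blend can have between centres 90° apart — which keeps
    vertex-to-vertex angle jumps small on fine annuli.
    """
    th = np.asarray(stations_deg, dtype=float)
    centers = np.array([_ZONE_CENTERS[z] for z in ZONES])  # 0, 90, 180, 270

    def tents(theta):
        d = np.abs((theta[:, None] - centers[None, :] + 180.0) % 360.0 - 180.0)
        return np.maximum(0.0, 1.0 - d / 90.0)

    if smooth_halfwidth <= 0:
        return tents(th)
    out = np.zeros((len(th), 4))
    for off in np.linspace(-smooth_halfwidth, smooth_halfwidth, _nquad):
        out += tents(th + off)
    return out / _nquad


def zone_of_station(stations_deg: np.ndarray) -> np.ndarray:
    """Hard zone membership of circumferential stations (for zone means/reporting)."""
    out = np.empty(len(stations_deg), dtype=object)
    for z in ZONES:
        d = np.abs((stations_deg - _ZONE_CENTERS[z] + 180.0) % 360.0 - 180.0)
        out[d <= _ZONE_HALFWIDTH[z]] = z
    # stations falling in the gaps between nominal bands join the nearest zone
    for i, s in enumerate(stations_deg):
        if out[i] is None:
            d = {z: abs((s - _ZONE_CENTERS[z] + 180.0) % 360.0 - 180.0) for z in ZONES}
            out[i] = min(d, key=d.get)
    return out


def _blend_coefficients(zone_angles: dict) -> np.ndarray:
    """Solve the 4 basis coefficients so each zone's mean equals its target."""
    stations_ref = np.linspace(0, 360, 721)[:-1]
    B = _blend_basis(stations_ref)
    labels = zone_of_station(stations_ref)
    M = np.stack([B[labels == z].mean(axis=0) for z in ZONES])
    targets = np.array([zone_angles[z] for z in ZONES])
    return np.linalg.solve(M, targets)


def zone_shaping(anterior: LeafletSurface, posterior: LeafletSurface,
                 zone_angles: dict) -> ZonePartition:
    """Shape per-station opening angles from the four zone means.

    The blend is a smooth periodic cardinal interpolant whose four control
    values are solved from a 4x4 linear system so that the mean of the
    assigned angles over each zone equals the prescribed zone mean.
    """
    if set(zone_angles) != set(ZONES):
        raise ValueError(f"zone_angles must provide exactly {ZONES}")
    stations = np.unique(np.concatenate([anterior.station_deg, posterior.station_deg]))
    labels = zone_of_station(stations)
    for z in ZONES:
        if not (labels == z).any():
            raise ValueError(f"zone {z} has no stations")
    coef = _blend_coefficients(zone_angles)
    vertex_angle = _blend_basis(stations) @ coef
    return ZonePartition(labels, dict(zone_angles), vertex_angle)


def station_angles(partition: ZonePartition, stations_deg: np.ndarray) -> np.ndarray:
    """Evaluate the shaped peak angle at arbitrary circumferential stations."""
    coef = _blend_coefficients(partition.zone_mean_angle)
    return _blend_basis(np.asarray(stations_deg, dtype=float)) @ coef


def build_valve(annulus: AnnulusModel | None = None, *, thickness: float = 2.0,
                zone_angles: dict | None = None, n_rows: int = 8,
                free_edge: np.ndarray | None = None) -> MitralValve:
    """Assemble the default parametric valve (annulus, loft, shaping)."""
    if annulus is None:
        annulus = circular_annulus()
    if free_edge is None:
        free_edge = default_free_edge(annulus)
    if zone_angles is None:
        zone_angles = {"anterior_leaflet": 55.0, "posterior_leaflet": 40.0,
                       "front_commissure": 25.0, "posterior_commissure": 25.0}
    ant, post = build_leaflets(annulus, free_edge, thickness, n_rows=n_rows)
    partition = zone_shaping(ant, post, zone_angles)
    return MitralValve(annulus, ant, post, partition, thickness)


def _rotate_sheet(sheet: LeafletSurface, angles_deg: np.ndarray) -> LeafletSurface:
    """Rotate each column rigidly about its annulus-tangent hinge by its angle.

    The opening sign is the one rotating the column's free-edge direction
    toward the local outward radial direction at its station (toward the
    ventricular wall), never through the long axis to the far side.
    """
    out = sheet.mid_surface.copy()
    centroid = (sheet.annulus_centroid if sheet.annulus_centroid is not None
                else sheet.hinge_points.mean(axis=0))
    for j in range(sheet.n_cols):
        hinge_p = sheet.hinge_points[j]
        axis = sheet.hinge_tangents[j]
        ang = angles_deg[j]
        u = hinge_p - centroid  # local outward direction in the annulus plane
        u = u / (np.linalg.norm(u) + 1e-300)
        d_old = sheet.mid_surface[-1, j] - hinge_p
        best = None
        for sign in (1.0, -1.0):
            R, t = geometry.rotation_about_axis(hinge_p, hinge_p + axis, sign * ang)
            d_new = (sheet.mid_surface[-1, j] @ R.T + t) - hinge_p
            gain = np.dot(d_new, u) - np.dot(d_old, u)
            if best is None or gain > best[0]:
                best = (gain, R, t)
        _, R, t = best
        out[:, j, :] = sheet.mid_surface[:, j, :] @ R.T + t
    return LeafletSurface(out, sheet.thickness, sheet.side, sheet.station_deg,
                          sheet.hinge_points, sheet.hinge_tangents, sheet.annulus_centroid)


def leaflet_frame_at(valve: MitralValve, schedule: OpeningSchedule, t: float
                     ) -> tuple[LeafletSurface, LeafletSurface]:
    """Leaflet configuration at time t: per-station hinge rotations.

    Each circumferential station rotates by ``shaped_peak_angle * f(t)`` about
    its local annulus tangent; anterior and posterior sheets move
    independently (mutual contact is allowed, self-intersection is not).
    """
    frac = schedule.fraction(t)
    out = []
    for sheet in (valve.anterior, valve.posterior):
        peaks = station_angles(valve.partition, sheet.station_deg)
        out.append(_rotate_sheet(sheet, peaks * frac))
    return tuple(out)


def orifice_area(anterior: LeafletSurface, posterior: LeafletSurface,
                 annulus: AnnulusModel) -> float:
    """Area (mm^2) of the free-edge polygon projected onto the annulus plane."""
    pts = np.vstack([np.column_stack([s.station_deg, s.free_edge()]) for s in (anterior, posterior)])
    # deduplicate overlapping stations, order circumferentially
    _, idx = np.unique(np.round(pts[:, 0], 6), return_index=True)
    pts = pts[idx]
    pts = pts[np.argsort(pts[:, 0])]
    rel = pts[:, 1:4] - annulus.centroid
    n = annulus.plane_normal
    e1 = rel[0] - np.dot(rel[0], n) * n
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(n, e1)
    x, y = rel @ e1, rel @ e2
    return float(0.5 * abs(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y)))


def clearance_check(valve_sheets, lv_vertices: np.ndarray, lv_faces: np.ndarray):
    """Signed leaflet-to-wall clearance (mm): positive inside the cavity.

    Returns ``(min_per_zone: dict, violations: list[(side, row, col, dist)])``.
    """
    mins: dict[str, float] = {}
    violations = []
    for sheet in valve_sheets:
        pts = sheet.vertices()
        d = geometry.point_triangle_distance(pts, lv_vertices, lv_faces)
        inside = geometry.points_inside(pts, lv_vertices, lv_faces)
        signed = np.where(inside, d, -d)
        labels = zone_of_station(sheet.station_deg)
        grid = signed.reshape(sheet.n_rows, sheet.n_cols)
        for j in range(sheet.n_cols):
            z = labels[j]
            col_min = float(grid[:, j].min())
            mins[z] = min(mins.get(z, np.inf), col_min)
            for i in range(sheet.n_rows):
                if grid[i, j] < 0:
                    violations.append((sheet.side, i, j, float(grid[i, j])))
    return mins, violations
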