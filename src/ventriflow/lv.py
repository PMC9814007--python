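"""Parametric 4D left-ventricle kinematics.

The ventricle is modeled as a truncated prolate spheroid (apex at the origin,
long axis +z, all lengths in mm, time in s).  A prescribed periodic volume
curve with systolic ejection and E/A diastolic filling drives a smooth
radial/longitudinal scaling of a fixed template mesh, so the same vertex
index refers to the same material point in every frame (1-to-1 vertex
correspondence).  Torsion is superposed as a rigid rotation about the axis
through the mitral-annulus centroid and the apex, ramping linearly to its
end-systolic maximum (default 13 degrees) and back to zero over diastole.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.optimize import brentq

from . import geometry
from .geometry import enclosed_volume as _signed_volume

MM3_PER_ML = 1000.0


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LVShapeParams:
    """Truncated-prolate-spheroid template of the LV endocardium.

    ``apex_to_base_length`` is the apex → base-plane distance; the spheroid's
    pole-to-pole length is ``apex_to_base_length + base_plane_height`` (the
    cut-off cap sits above the base plane).  ``base_radius`` is the radius of
    the basal opening.
    """
    base_radius: float = 24.0            # mm
    apex_to_base_length: float = 80.0    # mm
    base_plane_height: float = 20.0      # mm, height of the removed cap
    n_circumferential: int = 48
    n_longitudinal: int = 32

    def __post_init__(self):
        if min(self.base_radius, self.apex_to_base_length, self.base_plane_height) <= 0:
            raise ValueError("all lengths must be > 0")
        if self.n_circumferential < 8 or self.n_longitudinal < 8:
            raise ValueError("counts must be >= 8")
        if self.apex_to_base_length <= self.base_plane_height:
            raise ValueError("apex_to_base_length must exceed base_plane_height")

    @property
    def long_semi_axis(self) -> float:
        return 0.5 * (self.apex_to_base_length + self.base_plane_height)

    @property
    def equatorial_semi_axis(self) -> float:
        c = self.long_semi_axis
        zb = self.apex_to_base_length
        s = 1.0 - (zb / c - 1.0) ** 2
        if s <= 0:
            raise ValueError("invalid truncation: base plane outside the spheroid")
        return self.base_radius / np.sqrt(s)


@dataclass(frozen=True)
class VolumeCurve:
    """Periodic LV volume curve: systolic decay then E- and A-wave filling.

    Systole occupies ``[0, systole_fraction * cycle_duration]`` with a smooth
    raised-cosine decay from EDV to ESV; diastolic refilling is the sum of two
    integrated raised-cosine bumps centred at the E- and A-peak times, whose
    amplitude split is set by ``e_a_ratio`` (ratio of peak filling rates).
    """
    cycle_duration: float = 0.87     # s (290 frames at 3 ms)
    systole_fraction: float = 1.0 / 3.0
    edv: float = 162.7               # ml  (SV 109 ml at EF 0.67)
    esv: float = 53.7                # ml
    e_peak_time: float = 0.42        # s
    a_peak_time: float = 0.78        # s
    e_a_ratio: float = 2.0
    e_width: float = 0.22            # s, duration of the E filling bump
    a_width: float = 0.14            # s

    def __post_init__(self):
        if not (self.edv > self.esv > 0):
            raise ValueError("need edv > esv > 0")
        if not (0 < self.systole_fraction < 1):
            raise ValueError("systole_fraction must lie in (0,1)")
        ts = self.end_systole_time
        if not (ts < self.e_peak_time < self.a_peak_time < self.cycle_duration):
            raise ValueError("need end-systole < e_peak_time < a_peak_time < cycle_duration")

    @property
    def end_systole_time(self) -> float:
        return self.systole_fraction * self.cycle_duration

    @property
    def stroke_volume(self) -> float:
        return self.edv - self.esv

    def _weights(self):
        # e_a_ratio = (w_e * 2/e_width) / (w_a * 2/a_width)
        r = self.e_a_ratio * self.e_width / self.a_width
        w_e = r / (1.0 + r)
        return w_e, 1.0 - w_e

    @staticmethod
    def _bump_integral(t, center, width):
        """Integrated raised cosine: 0 before the window, 1 after, C1 smooth."""
        tau = np.clip((t - (center - width / 2)) / width, 0.0, 1.0)
        return tau - np.sin(2 * np.pi * tau) / (2 * np.pi)

    @staticmethod
    def _bump_rate(t, center, width):
        tau = (t - (center - width / 2)) / width
        inside = (tau > 0) & (tau < 1)
        return np.where(inside, (1 - np.cos(2 * np.pi * np.clip(tau, 0, 1))) / width, 0.0)

    def __call__(self, t):
        """Volume in ml at time t (s); periodic in ``cycle_duration``."""
        t = np.mod(np.asarray(t, dtype=float), self.cycle_duration)
        ts = self.end_systole_time
        sv = self.stroke_volume
        w_e, w_a = self._weights()
        sys_v = self.esv + sv * 0.5 * (1 + np.cos(np.pi * np.clip(t / ts, 0, 1)))
        dia_v = self.esv + sv * (w_e * self._bump_integral(t, self.e_peak_time, self.e_width)
                                 + w_a * self._bump_integral(t, self.a_peak_time, self.a_width))
        return np.where(t <= ts, sys_v, dia_v)

    def rate(self, t):
        """dV/dt in ml/s at time t."""
        t = np.mod(np.asarray(t, dtype=float), self.cycle_duration)
        ts = self.end_systole_time
        sv = self.stroke_volume
        w_e, w_a = self._weights()
        sys_r = -sv * 0.5 * np.pi / ts * np.sin(np.pi * np.clip(t / ts, 0, 1))
        dia_r = sv * (w_e * self._bump_rate(t, self.e_peak_time, self.e_width)
                      + w_a * self._bump_rate(t, self.a_peak_time, self.a_width))
        return np.where(t <= ts, sys_r, dia_r)


@dataclass
class Mesh4D:
    """A sequence of triangulated surface frames with shared connectivity."""
    frames: np.ndarray          # (n_frames, n_vertices, 3) mm
    connectivity: np.ndarray    # (n_triangles, 3) int
    times: np.ndarray           # (n_frames,) s
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.frames = np.asarray(self.frames, dtype=float)
        self.connectivity = np.asarray(self.connectivity, dtype=np.int64)
        self.times = np.asarray(self.times, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[2] != 3:
            raise ValueError("frames must have shape (n_frames, n_vertices, 3)")
        if len(self.times) != len(self.frames):
            raise ValueError("one time stamp per frame required")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def n_vertices(self) -> int:
        return self.frames.shape[1]

    def frame_at(self, t: float) -> np.ndarray:
        """Vertex array of the frame whose stamp is closest to t (after wrapping)."""
        return self.frames[self.frame_index(t)]

    def frame_index(self, t: float) -> int:
        period = self.metadata.get("cycle_duration")
        if period:
            t = t % period
        return int(np.argmin(np.abs(self.times - t)))


@dataclass(frozen=True)
class TorsionProfile:
    """Piecewise-linear twist/untwist schedule about the MV-centroid–apex axis."""
    gamma_max: float = 13.0          # degrees at end-systole
    end_systole_time: float = 0.29   # s
    cycle_duration: float = 0.87     # s
    axis_point_a: tuple = (0.0, 0.0, 80.0)  # MV centroid (mm)
    axis_point_b: tuple = (0.0, 0.0, 0.0)   # apex (mm)

    def __post_init__(self):
        if not (0 < self.end_systole_time < self.cycle_duration):
            raise ValueError("need 0 < end_systole_time < cycle_duration")


@dataclass(frozen=True)
class FluidProperties:
    """Blood as a homogeneous Newtonian fluid."""
    density: float = 1060.0            # kg/m^3
    dynamic_viscosity: float = 0.003   # kg/(m s)

    def __post_init__(self):
        if self.density <= 0 or self.dynamic_viscosity <= 0:
            raise ValueError("density and viscosity must be > 0")


@dataclass(frozen=True)
class QualityReport:
    max_skewness: float
    min_scaled_jacobian: float
    n_failed_elements: int
    skewness_threshold: float = 0.9
    jacobian_threshold: float = 0.02

    @property
    def passed(self) -> bool:
        return self.n_failed_elements == 0


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def _template_mesh(shape: LVShapeParams):
    """Closed template surface: spheroidal sac + flat basal cap.

    Vertex order: apex pole, then n_longitudinal rings of n_circumferential
    vertices (last ring on the base plane), then the base-cap centre.
    """
    nc, nl = shape.n_circumferential, shape.n_longitudinal
    c = shape.long_semi_axis
    a = shape.equatorial_semi_axis
    zb = shape.apex_to_base_length
    phi_b = np.arccos(1.0 - zb / c)
    phi = phi_b * (np.arange(1, nl + 1) / nl)
    theta = 2 * np.pi * np.arange(nc) / nc
    P, T = np.meshgrid(phi, theta, indexing="ij")
    ring = np.stack([a * np.sin(P) * np.cos(T),
                     a * np.sin(P) * np.sin(T),
                     c * (1 - np.cos(P))], axis=-1).reshape(-1, 3)
    verts = np.vstack([[[0.0, 0.0, 0.0]], ring, [[0.0, 0.0, zb]]])
    apex, cap = 0, len(verts) - 1

    def rid(i, j):  # ring i (0-based), station j
        return 1 + i * nc + (j % nc)

    faces = []
    for j in range(nc):  # apex fan
        faces.append([apex, rid(0, j + 1), rid(0, j)])
    for i in range(nl - 1):
        for j in range(nc):
            faces.append([rid(i, j), rid(i, j + 1), rid(i + 1, j)])
            faces.append([rid(i, j + 1), rid(i + 1, j + 1), rid(i + 1, j)])
    for j in range(nc):  # basal cap fan
        faces.append([cap, rid(nl - 1, j), rid(nl - 1, j + 1)])
    faces = np.asarray(faces, dtype=np.int64)
    vol, inverted = _signed_volume(verts, faces)
    if inverted:
        faces = faces[:, ::-1]
    return verts, faces


def enclosed_volume(vertices: np.ndarray, faces: np.ndarray) -> tuple[float, bool]:
    """Divergence-theorem volume (ml) of a closed surface given in mm.

    Returns ``(volume_ml, inverted)``; ``inverted`` flags inward orientation.
    Raises :class:`ventriflow.geometry.OpenSurfaceError` for open surfaces.
    """
    vol_mm3, inverted = _signed_volume(vertices, faces)
    return vol_mm3 / MM3_PER_ML, inverted


def ejection_fraction(edv: float, esv: float) -> float:
    """(EDV − ESV)/EDV; raises for a non-ejecting (esv >= edv) input."""
    if not (edv > esv > 0):
        raise ValueError("need edv > esv > 0")
    return (edv - esv) / edv


def build_lv_mesh4d(shape: LVShapeParams, vol: VolumeCurve, n_frames: int) -> Mesh4D:
    """Generate the 4D endocardial mesh tracking the volume curve.

    Frames sample one cycle at ``t_k = k T / n_frames`` (the frame at t = T
    coincides with t = 0 by periodicity of the curve).  Each frame scales the
    template by ``diag(s, s, s^beta)`` with beta = 0.5 (more radial than
    longitudinal shortening); s is solved per frame by a bracketed root find
    so the divergence-theorem mesh volume matches the curve to ~1e-12.
    """
    if n_frames < 3:
        raise ValueError("n_frames must be >= 3")
    verts0, faces = _template_mesh(shape)
    v_template = _signed_volume(verts0, faces)[0] / MM3_PER_ML
    if vol.esv > v_template * 8 or vol.edv < v_template / 64:
        raise ValueError("volume curve unreachable by this shape family")
    beta = 0.5
    times = vol.cycle_duration * np.arange(n_frames) / n_frames
    targets = vol(times)

    def scale_for(v_target):
        f = lambda s: v_template * s ** (2 + beta) - v_target
        lo, hi = 1e-3, 8.0
        if f(lo) > 0 or f(hi) < 0:
            raise ValueError("volume curve unreachable by this shape family")
        return brentq(f, lo, hi, xtol=1e-10, rtol=1e-14)

    frames = np.empty((n_frames, len(verts0), 3))
    for k, v_t in enumerate(targets):
        s = scale_for(v_t)
        frames[k] = verts0 * [s, s, s ** beta]
    return Mesh4D(frames, faces, times, metadata={
        "cycle_duration": vol.cycle_duration,
        "shape": shape, "volume_curve": vol,
        "base_vertex_start": 1 + (shape.n_longitudinal - 1) * shape.n_circumferential,
        "cap_vertex": len(verts0) - 1,
    })


def base_height(mesh: Mesh4D, frame: int) -> float:
    """z of the basal plane (mm) at a given frame (the cap-centre vertex)."""
    return float(mesh.frames[frame, -1, 2])


def torsion_angle_at(profile: TorsionProfile, t) -> np.ndarray | float:
    """Twist angle (deg): 0 at cycle start, gamma_max at end-systole, 0 at cycle end."""
    t = np.mod(np.asarray(t, dtype=float), profile.cycle_duration)
    ts, T, g = profile.end_systole_time, profile.cycle_duration, profile.gamma_max
    up = g * t / ts
    down = g * (T - t) / (T - ts)
    out = np.where(t <= ts, up, down)
    return float(out) if out.ndim == 0 else out


def apply_torsion(mesh: Mesh4D, profile: TorsionProfile) -> Mesh4D:
    """Rigidly rotate every frame about the MV-centroid–apex axis by its twist angle."""
    frames = np.empty_like(mesh.frames)
    for k, t in enumerate(mesh.times):
        R, tr = geometry.rotation_about_axis(profile.axis_point_a, profile.axis_point_b,
                                             torsion_angle_at(profile, t))
        frames[k] = mesh.frames[k] @ R.T + tr
    md = dict(mesh.metadata)
    md["torsion"] = profile
    return Mesh4D(frames, mesh.connectivity.copy(), mesh.times.copy(), md)


def resample_temporal(mesh: Mesh4D, dt: float, *, end_conditions: str = "natural") -> Mesh4D:
    """Natural-cubic-spline temporal resampling of a 4D mesh to step ``dt``.

    A spline is fitted per vertex coordinate through the input frames — plus
    the periodic closure frame at t = T when the mesh declares a
    ``cycle_duration`` — then sampled at 0, dt, 2dt, ... < T (0.87 s at 3 ms
    gives 290 frames).  ``end_conditions`` may be "natural" (zero second
    derivative, the default) or "periodic".
    """
    if mesh.n_frames < 4:
        raise ValueError("need at least 4 frames to resample")
    period = mesh.metadata.get("cycle_duration")
    t_knots = mesh.times
    frames = mesh.frames
    if period is None:
        period = float(mesh.times[-1])  # aperiodic sequence: no closure frame
    elif t_knots[-1] < period:  # close the cycle for spline support
        t_knots = np.append(t_knots, period)
        frames = np.concatenate([frames, frames[:1]], axis=0)
    if dt <= 0 or dt > period:
        raise ValueError("dt must be positive and smaller than the cycle duration")
    bc = "natural" if end_conditions == "natural" else "periodic"
    spline = CubicSpline(t_knots, frames.reshape(len(t_knots), -1), axis=0, bc_type=bc)
    t_new = np.arange(0.0, period - 1e-12, dt)
    out = spline(t_new).reshape(len(t_new), mesh.n_vertices, 3)
    md = dict(mesh.metadata)
    md["resampled_dt"] = dt
    return Mesh4D(out, mesh.connectivity.copy(), t_new, md)


def triangle_skewness(vertices: np.ndarray, faces: np.ndarray) -> np.ndarray:
    """Equiangular skewness per triangle: max((θmax−60)/120, (60−θmin)/60)."""
    a = vertices[faces[:, 0]]
    b = vertices[faces[:, 1]]
    c = vertices[faces[:, 2]]

    def angle(p, q, r):
        u = q - p
        v = r - p
        cosang = np.einsum("ij,ij->i", u, v) / (
            np.linalg.norm(u, axis=1) * np.linalg.norm(v, axis=1) + 1e-300)
        return np.degrees(np.arccos(np.clip(cosang, -1, 1)))

    angs = np.stack([angle(a, b, c), angle(b, c, a), angle(c, a, b)])
    tmax, tmin = angs.max(axis=0), angs.min(axis=0)
    return np.maximum((tmax - 60.0) / 120.0, (60.0 - tmin) / 60.0)


def hex_scaled_jacobian(corners: np.ndarray) -> np.ndarray:
    """Scaled Jacobian of hexahedral cells, corners (n, 8, 3) in VTK order.

    Minimum over the 8 corners of det(e1,e2,e3)/(|e1||e2||e3|) for the three
    incident edges; 1 for a cube, negative for inverted elements.
    """
    corners = np.asarray(corners, dtype=float)
    if corners.ndim == 2:
        corners = corners[None]
    # corner -> its three edge-connected neighbours (VTK hexahedron numbering)
    nbrs = [(1, 3, 4), (2, 0, 5), (3, 1, 6), (0, 2, 7),
            (7, 5, 0), (4, 6, 1), (5, 7, 2), (6, 4, 3)]
    vals = np.empty((len(corners), 8))
    for k, (i, j, l) in enumerate(nbrs):
        e1 = corners[:, i] - corners[:, k]
        e2 = corners[:, j] - corners[:, k]
        e3 = corners[:, l] - corners[:, k]
        det = np.einsum("ij,ij->i", e1, np.cross(e2, e3))
        den = (np.linalg.norm(e1, axis=1) * np.linalg.norm(e2, axis=1)
               * np.linalg.norm(e3, axis=1) + 1e-300)
        vals[:, k] = det / den
    return vals.min(axis=1)


def mesh_quality(mesh: Mesh4D | tuple, *, skewness_threshold: float = 0.9,
                 jacobian_threshold: float = 0.02) -> QualityReport:
    """Quality report over all frames (or a single ``(vertices, faces)`` surface).

    Surface triangles are scored by equiangular skewness; the scaled Jacobian
    slot reports the per-triangle corner Jacobian (unit for right-angle ideal)
    so both thresholds from the meshing practice (0.9 / 0.02) are checked.
    """
    if isinstance(mesh, Mesh4D):
        frames = mesh.frames
        faces = mesh.connectivity
    else:
        v, faces = mesh
        frames = np.asarray(v, dtype=float)[None]
    max_skew = 0.0
    min_jac = np.inf
    n_fail = 0
    for fr in frames:
        skew = triangle_skewness(fr, faces)
        jac = 1.0 - skew  # triangle surrogate: ideal element -> 1, degenerate -> 0
        n_fail += int(np.sum((skew > skewness_threshold) | (jac < jacobian_threshold)))
        max_skew = max(max_skew, float(skew.max()))
        min_jac = min(min_jac, float(jac.min()))
    return QualityReport(max_skew, min_jac, n_fail,
                         skewness_threshold, jacobian_threshold)


def scale_mesh4d(mesh: Mesh4D, factor: float) -> Mesh4D:
    """Uniform scaling about the origin (utility for constructed test geometries)."""
    return replace(mesh, frames=mesh.frames * factor)
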