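"""Lagrangian particle transport and residence-time classification.

Massless tracers are released at the inlet surface nodes (default 4,500) at
the start of a diastole and advected through the time-varying velocity field
for two beats with classical RK4 in space and linear interpolation of the
field in time.  Particles crossing the outlet plane with outward velocity
during systole are ejected and labelled with their beat index; the rest are
classified three ways — direct flow (ejected in beat 1), second-beat, and
residual — and residual motility is summarized against a 0.5 m/s speed
threshold.  An apical-release variant seeds the cavity below a given axial
fraction.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import geometry
from .flow import FlowField, PhaseSchedule, MM_TO_M

IN_LV, EJECTED, ESCAPED = "in_lv", "ejected", "escaped_mask"


@dataclass
class ParticleSet:
    positions: np.ndarray          # (n, 3) mm, current
    status: np.ndarray             # (n,) str
    ejection_beat: np.ndarray      # (n,) int, 0 = none
    speed_at_end: np.ndarray       # (n,) m/s (residuals; NaN otherwise until advected)
    release_time: float = 0.0
    history: list = field(default_factory=list)   # optional (t, positions) snapshots

    @classmethod
    def at(cls, positions: np.ndarray, release_time: float = 0.0) -> "ParticleSet":
        n = len(positions)
        return cls(np.asarray(positions, dtype=float).copy(),
                   np.full(n, IN_LV, dtype=object),
                   np.zeros(n, dtype=np.int64),
                   np.full(n, np.nan),
                   release_time)

    @property
    def n(self) -> int:
        return len(self.positions)


@dataclass
class RTClassification:
    n_direct: int
    n_second_beat: int
    n_residual: int
    n_escaped: int
    n_seeded: int

    @property
    def fractions(self) -> dict:
        denom = self.n_seeded - self.n_escaped
        denom = max(denom, 1)
        return {"direct": self.n_direct / denom,
                "second_beat": self.n_second_beat / denom,
                "residual": self.n_residual / denom}


# ---------------------------------------------------------------------------
# seeding
# ---------------------------------------------------------------------------

def disk_surface_mesh(center, radius: float, n_rings: int = 24, normal_axis: int = 2):
    """Triangulated disk (inlet surrogate): returns (vertices, faces)."""
    center = np.asarray(center, dtype=float)
    verts = [center]
    for i in range(1, n_rings + 1):
        r = radius * i / n_rings
        npts = max(6, int(round(6 * i)))
        th = 2 * np.pi * np.arange(npts) / npts
        ring = np.zeros((npts, 3))
        ax = [k for k in range(3) if k != normal_axis]
        ring[:, ax[0]] = r * np.cos(th)
        ring[:, ax[1]] = r * np.sin(th)
        verts.extend(center + ring)
    verts = np.asarray(verts)
    try:
        from scipy.spatial import Delaunay
        ax = [k for k in range(3) if k != normal_axis]
        tri = Delaunay(verts[:, ax])
        faces = tri.simplices
    except Exception:  # pragma: no cover
        faces = np.zeros((0, 3), dtype=np.int64)
    return verts, faces


def seed_inlet(inlet_vertices: np.ndarray, n: int = 4500, seed: int = 0,
               inlet_faces: np.ndarray | None = None,
               release_time: float = 0.0) -> ParticleSet:
    """Particles at the inlet surface nodes (resampled to exactly n if needed).

    If ``n`` differs from the node count, nodes are uniformly subsampled
    (n < nodes) or augmented with seeded barycentric samples on the surface
    triangles (n > nodes, requires ``inlet_faces``).
    """
    verts = np.asarray(inlet_vertices, dtype=float)
    if len(verts) == 0:
        raise ValueError("inlet surface has no nodes")
    rng = np.random.default_rng(seed)
    if n == len(verts):
        pos = verts.copy()
    elif n < len(verts):
        pos = verts[rng.choice(len(verts), size=n, replace=False)]
    else:
        if inlet_faces is None or len(inlet_faces) == 0:
            raise ValueError("n exceeds the node count and no faces were given to resample")
        extra = n - len(verts)
        areas = geometry.triangle_areas(verts, inlet_faces)
        fidx = rng.choice(len(inlet_faces), size=extra, p=areas / areas.sum())
        r1 = np.sqrt(rng.random(extra))
        r2 = rng.random(extra)
        a, b, c = (verts[inlet_faces[fidx, k]] for k in range(3))
        pos = np.vstack([verts, (1 - r1)[:, None] * a
                         + (r1 * (1 - r2))[:, None] * b + (r1 * r2)[:, None] * c])
    return ParticleSet.at(pos, release_time)


def seed_apical(lv_vertices: np.ndarray, lv_faces: np.ndarray,
                fraction_of_axis: float, n: int, seed: int = 0,
                release_time: float = 0.0) -> ParticleSet:
    """n seeded particles uniform in the cavity below the axial fraction."""
    if not (0 < fraction_of_axis < 1):
        raise ValueError("fraction_of_axis must lie in (0, 1)")
    v = np.asarray(lv_vertices, dtype=float)
    z_cut = v[:, 2].min() + fraction_of_axis * (v[:, 2].max() - v[:, 2].min())
    lo = v.min(axis=0)
    hi = v.max(axis=0)
    hi = hi.copy()
    hi[2] = z_cut
    if hi[2] <= lo[2] + 1e-9:
        raise ValueError("apical region is empty")
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(200):  # rejection sampling
        cand = lo + (hi - lo) * rng.random((max(4 * n, 256), 3))
        keep = geometry.points_inside(cand, v, lv_faces)
        out.extend(cand[keep])
        if len(out) >= n:
            break
    if len(out) < n:
        raise ValueError("apical region is empty or too thin to seed")
    return ParticleSet.at(np.asarray(out[:n]), release_time)


# ---------------------------------------------------------------------------
# advection
# ---------------------------------------------------------------------------

def advect(particles: ParticleSet, velocity_field: FlowField, t_start: float,
           n_beats: int = 2, cycle_duration: float | None = None,
           schedule: PhaseSchedule | None = None,
           outlet_center=None, outlet_radius: float | None = None,
           substeps_per_frame: int = 4, save_every: int = 0) -> ParticleSet:
    """RK4 advection over ``n_beats`` cardiac cycles with ejection detection.

    Velocity (m/s) is converted to mm/s for the mm-positions.  A particle
    first crossing the outlet plane inside the outlet radius with outward
    (+z) velocity during a systolic phase is ejected and tagged with its beat
    index; a particle leaving the in-domain mask elsewhere is marked
    ``escaped_mask`` and reported separately.
    """
    T = cycle_duration if cycle_duration is not None else velocity_field.period
    if T is None:
        md = velocity_field.metadata
        if "cycle_frames" in md:
            T = float(velocity_field.times[md["cycle_frames"]] - velocity_field.times[0])
        else:
            raise ValueError("cycle_duration is required for non-periodic fields")
    if velocity_field.period is None:
        if t_start + n_beats * T > velocity_field.times[-1] + T / len(velocity_field.times) + 1e-9:
            raise ValueError("field frames do not cover the advection window")
    sched = schedule or velocity_field.metadata.get("schedule")
    out_c = outlet_center
    if out_c is None:
        out_c = velocity_field.metadata.get("outlet_center")
    frame_dt = np.median(np.diff(velocity_field.times)) if velocity_field.n_frames > 1 else T
    dt = float(frame_dt / substeps_per_frame)
    n_steps = int(np.ceil(n_beats * T / dt))
    pos = particles.positions.copy()
    status = particles.status.copy()
    beat = particles.ejection_beat.copy()
    alive = status == IN_LV
    t = t_start
    vel_scale = 1000.0  # m/s -> mm/s on mm coordinates

    def rhs(p, tt):
        return velocity_field.sample_velocity(p, tt) * vel_scale

    for step in range(n_steps):
        dt_k = min(dt, t_start + n_beats * T - t)
        if dt_k <= 0:
            break
        idx = np.where(alive)[0]
        if len(idx) == 0:
            break
        p = pos[idx]
        k1 = rhs(p, t)
        k2 = rhs(p + 0.5 * dt_k * k1, t + 0.5 * dt_k)
        k3 = rhs(p + 0.5 * dt_k * k2, t + 0.5 * dt_k)
        k4 = rhs(p + dt_k * k3, t + dt_k)
        newp = p + dt_k / 6.0 * (k1 + 2 * k2 + 2 * k3 + k4)
        t_next = t + dt_k
        # ejection: outlet-plane crossing with outward velocity during systole
        if out_c is not None:
            systolic = sched is None or sched.phase(t_next % T if velocity_field.period else t_next) == "systole"
            zb = out_c[2]
            # either an upward plane crossing, or already above the plane inside
            # the outlet radius while moving outward (the plane sits inside the
            # moving base, so near-base particles may start above it)
            crossed = ((p[:, 2] <= zb) & (newp[:, 2] > zb)) \
                | ((p[:, 2] > zb) & (newp[:, 2] > p[:, 2]))
            if outlet_radius is not None:
                crossed &= np.hypot(newp[:, 0] - out_c[0], newp[:, 1] - out_c[1]) <= outlet_radius
            crossed &= systolic
            ej = idx[crossed]
            if len(ej):
                status[ej] = EJECTED
                beat[ej] = 1 + np.floor((t_next - particles.release_time - 1e-12) / T).astype(np.int64)
                alive[ej] = False
        still = status[idx] == IN_LV
        inm = velocity_field.in_mask(newp[still], t_next)
        esc = idx[still][~inm]
        if len(esc):
            status[esc] = ESCAPED
            alive[esc] = False
        pos[idx[status[idx] == IN_LV]] = newp[status[idx] == IN_LV]
        t = t_next
        if save_every and step % save_every == 0:
            particles.history.append((t, pos.copy()))

    speed = np.full(particles.n, np.nan)
    residual = status == IN_LV
    if residual.any():
        v_end = velocity_field.sample_velocity(pos[residual], t)
        speed[residual] = np.linalg.norm(v_end, axis=1)
    return ParticleSet(pos, status, beat, speed, particles.release_time, particles.history)


def classify_rt(particles: ParticleSet) -> RTClassification:
    """Three-way residence-time classification after a two-beat advection."""
    ej = particles.status == EJECTED
    direct = int(np.sum(ej & (particles.ejection_beat == 1)))
    second = int(np.sum(ej & (particles.ejection_beat >= 2)))
    residual = int(np.sum(particles.status == IN_LV))
    escaped = int(np.sum(particles.status == ESCAPED))
    return RTClassification(direct, second, residual, escaped, particles.n)


def motility_stats(particles: ParticleSet, threshold: float = 0.5) -> tuple[int, int]:
    """(n_below, n_total) of residual particles with end speed strictly below
    the motility threshold (m/s)."""
    residual = particles.status == IN_LV
    speeds = particles.speed_at_end[residual]
    n_below = int(np.sum(speeds < threshold))
    return n_below, int(residual.sum())
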