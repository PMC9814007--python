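"""Cycle-to-cycle variation statistics.

Three spherical probe clouds (default 1,000 points, 5 mm radius) are placed
along the axis through the mitral-annulus centroid and the apex; per frame
the median, 5th and 95th percentiles of velocity magnitude and components,
pressure and vorticity magnitude are sampled inside each cloud.  Cross-cycle
variation is the per-pixel sample (n−1) standard deviation of a scalar on
the long-axis plane at a named phase (the diastolic E-peak), computed over
the per-cycle values at the same phase.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .flow import FlowField
from .metrics import plane_slice, vorticity_magnitude


@dataclass
class ProbeCloud:
    center: np.ndarray
    radius: float
    points: np.ndarray      # (n_points, 3) mm
    flagged: np.ndarray | None = None   # points outside the fluid mask

    @property
    def n_points(self) -> int:
        return len(self.points)


@dataclass
class PercentileSeries:
    """Per-frame median/p5/p95 of sampled quantities, per cloud.

    ``data[quantity]`` has shape (n_clouds, n_frames, 3) with the last axis
    ordered (p5, median, p95).
    """
    times: np.ndarray
    data: dict

    def check_ordering(self) -> bool:
        return all(np.all((q[..., 0] <= q[..., 1] + 1e-12)
                          & (q[..., 1] <= q[..., 2] + 1e-12))
                   for q in self.data.values())


@dataclass
class CycleVariation:
    std_map: np.ndarray     # per-pixel std on the LA plane
    max_std: float
    quantity: str
    time_point: float
    n_cycles: int


def make_probes(axis_a, axis_b, n_clouds: int = 3, radius: float = 5.0,
                n_points: int = 1000, seed: int = 0,
                field: FlowField | None = None) -> list[ProbeCloud]:
    """Probe clouds at 25/50/75% of the axis a→b, uniform in each ball (seeded)."""
    a = np.asarray(axis_a, dtype=float)
    b = np.asarray(axis_b, dtype=float)
    if np.linalg.norm(b - a) < 1e-12:
        raise ValueError("axis endpoints coincide")
    rng = np.random.default_rng(seed)
    fracs = np.linspace(0.25, 0.75, n_clouds) if n_clouds > 1 else np.array([0.5])
    clouds = []
    for f in fracs:
        center = a + f * (b - a)
        # uniform ball: gaussian direction x uniform^(1/3) radius
        d = rng.standard_normal((n_points, 3))
        d /= np.linalg.norm(d, axis=1, keepdims=True)
        r = radius * rng.random(n_points) ** (1.0 / 3.0)
        pts = center + d * r[:, None]
        flagged = None
        if field is not None:
            flagged = ~field.in_mask(pts, float(field.times[0]))
            if flagged.any():
                import warnings
                warnings.warn(f"{int(flagged.sum())} probe points outside the fluid mask")
        clouds.append(ProbeCloud(center, radius, pts, flagged))
    return clouds


def percentile_series(field: FlowField, clouds, frames=None) -> PercentileSeries:
    """Trilinear sampling of each quantity at each cloud point, percentiles per frame."""
    if frames is None:
        frames = range(field.n_frames)
    frames = list(frames)
    quantities = ["velocity_magnitude", "u", "v", "w", "vorticity_magnitude"]
    if field.pressure is not None:
        quantities.append("pressure")
    data = {q: np.zeros((len(clouds), len(frames), 3)) for q in quantities}
    for fi, k in enumerate(frames):
        t = float(field.times[k])
        vort = vorticity_magnitude(field, k)
        vort_f = np.nan_to_num(vort, nan=0.0)
        for ci, cloud in enumerate(clouds):
            v = field.sample_velocity(cloud.points, t)
            samples = {
                "velocity_magnitude": np.linalg.norm(v, axis=1),
                "u": v[:, 0], "v": v[:, 1], "w": v[:, 2],
                "vorticity_magnitude": field.sample_scalar(vort_f, cloud.points),
            }
            if field.pressure is not None:
                samples["pressure"] = field.sample_scalar(field.pressure[k], cloud.points)
            for q, s in samples.items():
                data[q][ci, fi] = np.percentile(s, [5, 50, 95])
    return PercentileSeries(field.times[frames], data)


def cross_cycle_std(field: FlowField, cycle_duration: float, time_point: float,
                    quantity: str = "velocity_magnitude", plane: str = "LA",
                    cycles=None) -> CycleVariation:
    """Per-pixel sample std across cycles of a scalar on the LA plane at one phase.

    ``cycles`` selects which cycle indices (0-based) enter; default: every
    complete cycle in the field.  Requires at least two cycles.
    """
    t_total = field.times[-1] - field.times[0]
    if field.period:
        n_avail = max(int(np.floor((t_total + 1e-9) / cycle_duration)), 2)
    else:
        n_avail = int(np.floor((t_total - time_point + 1e-9) / cycle_duration)) + 1
    if cycles is None:
        cycles = range(max(n_avail, 0))
    cycles = list(cycles)
    if len(cycles) < 2:
        raise ValueError("need at least two cycles for a cross-cycle std")
    slices = []
    for c in cycles:
        t = field.times[0] + c * cycle_duration + time_point
        # snap to the nearest frame at this phase (frames are commensurate with
        # the cycle), avoiding knife-edge bracketing at exact frame times
        if field.period:
            dphase = np.mod(field.times - t + cycle_duration / 2, cycle_duration) \
                - cycle_duration / 2
            k0 = int(np.argmin(np.abs(dphase)))
        else:
            k0 = int(np.argmin(np.abs(field.times - t)))
        if quantity == "velocity_magnitude":
            scal = np.linalg.norm(field.velocity[k0], axis=-1)
        elif quantity == "vorticity_magnitude":
            scal = np.nan_to_num(vorticity_magnitude(field, k0), nan=0.0)
        else:
            raise ValueError(f"unknown quantity {quantity!r}")
        scal = np.where(field.mask[k0], scal, np.nan)
        slices.append(plane_slice(field, scal, plane))
    stack = np.stack(slices)
    import warnings as _warnings
    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN pixels
        std = np.nanstd(stack, axis=0, ddof=1)
    std = np.where(np.all(np.isnan(stack), axis=0), np.nan, std)
    return CycleVariation(std, float(np.nanmax(std)) if np.isfinite(std).any() else 0.0,
                          quantity, time_point, len(cycles))

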