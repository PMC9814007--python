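"""End-to-end demo pipeline: geometry → valve → overset → flow → metrics.

Runs the three scenario variants used in the comparison design — LV with
torsion but no valve (``lv_torsion``), LV+MV without torsion
(``lvmv_no_torsion``), LV+MV with torsion (``lvmv_torsion``) — on a shared
coarse Cartesian grid, and gathers ejection fraction, energy loss,
residence-time fractions, bull's-eye WSS tables, probe statistics and
cross-cycle variation into one summary, deterministically for a fixed seed.
"""
from __future__ import annotations

import json
import time
from pathlib import Path

import numpy as np

from . import cyclestats, flow, lv, metrics, mitral, overset, particles, vtkio
from .config import RunConfig


class PipelineStageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        super().__init__(f"pipeline stage '{stage}' failed: {cause}")


def _stage(name):
    def deco(fn):
        def wrapper(*a, **k):
            try:
                return fn(*a, **k)
            except PipelineStageError:
                raise
            except Exception as e:  # noqa: BLE001 - re-raised with stage context
                raise PipelineStageError(name, e) from e
        return wrapper
    return deco


SCENARIOS = ("lv_torsion", "lvmv_no_torsion", "lvmv_torsion")


@_stage("geometry")
def _build_geometry(cfg: RunConfig):
    g = cfg.geometry
    shape = lv.LVShapeParams(g.base_radius_mm, g.apex_to_base_mm, g.cap_height_mm,
                             g.n_circumferential, g.n_longitudinal)
    vol = lv.VolumeCurve(g.cycle_duration_s, g.systole_fraction, g.edv_ml, g.esv_ml,
                         g.e_peak_s, g.a_peak_s, g.e_a_ratio)
    mesh = lv.build_lv_mesh4d(shape, vol, g.n_key_frames)
    mesh = lv.resample_temporal(mesh, g.resample_dt_s)
    mesh.metadata["volume_curve"] = vol
    mesh.metadata["cycle_duration"] = vol.cycle_duration
    return shape, vol, mesh


def _torsion_profile(cfg: RunConfig, vol: lv.VolumeCurve, mesh: lv.Mesh4D):
    zb = lv.base_height(mesh, 0)
    return lv.TorsionProfile(cfg.torsion.gamma_deg, vol.end_systole_time,
                             vol.cycle_duration, (0.0, 0.0, zb), (0.0, 0.0, 0.0))


@_stage("overset")
def _overset_checks(mesh: lv.Mesh4D, grid: overset.CartesianGrid):
    frames = [0, mesh.n_frames // 3, 2 * mesh.n_frames // 3]
    cats = []
    for k in frames:
        wall = overset.WallSurface(mesh.frames[k], mesh.connectivity, fluid_side="inside")
        cats.append(overset.classify_cells(grid, [wall]))
    report = overset.detect_vanishing_zone(cats)
    iface = overset.build_interface(cats[0], grid)
    return {"vanishing_flags": report["flags"],
            "category_counts_frame0": cats[0].counts(),
            "n_receptors": iface.n_receptors,
            "n_orphans": len(iface.orphans)}


def run_pipeline(config: RunConfig, output_dir=None, write_outputs: bool = True) -> dict:
    """Run the three-scenario demo; returns (and optionally writes) the summary."""
    t_wall0 = time.time()
    outdir = Path(output_dir or config.output_dir)
    shape, vol, mesh = _build_geometry(config)
    zb = lv.base_height(mesh, 0)
    ef = lv.ejection_fraction(vol.edv, vol.esv)
    fluid = lv.FluidProperties(config.metrics.density_kg_m3, config.metrics.viscosity_kg_m_s)
    lo = mesh.frames.min(axis=(0, 1)) - 2.0
    hi = mesh.frames.max(axis=(0, 1)) + 2.0
    n = config.flow.grid_n
    spacing = float(np.max(hi - lo) / n)
    grid = overset.CartesianGrid(tuple(lo), spacing, (n, n, n))
    schedule = flow.PhaseSchedule(vol.cycle_duration, vol.end_systole_time,
                                  config.flow.inlet_pressure_mmhg,
                                  config.flow.outlet_pressure_mmhg)
    jet = flow.JetParams(config.flow.peak_e_velocity_m_s, config.flow.peak_a_velocity_m_s,
                         config.flow.orifice_diameter_mm, config.flow.ring_core_radius_mm,
                         config.flow.decay_time_s)
    # port layout sized to the *minimum* (end-systolic) basal radius so inlet
    # and outlet stay inside the cavity at every phase
    kmin = int(np.argmin(mesh.frames[:, -1, 2]))
    bvs = mesh.metadata.get("base_vertex_start", 0)
    cap = mesh.metadata.get("cap_vertex", mesh.n_vertices - 1)
    base_ring = mesh.frames[kmin, bvs:cap]
    r_base_min = float(np.hypot(base_ring[:, 0], base_ring[:, 1]).mean())
    mv_center = np.array([-0.30 * r_base_min, 0.0, zb])
    outlet_center = np.array([0.45 * r_base_min, 0.0, zb])
    summary = {"config_hash": config.hash(), "seed": config.seed,
               "ejection_fraction": ef, "stroke_volume_ml": vol.stroke_volume,
               "scenarios": {}}

    for scen in SCENARIOS:
        with_valve = scen.startswith("lvmv")
        with_torsion = scen.endswith("_torsion") and not scen.endswith("no_torsion")
        geo = mesh
        torsion_rate = None
        if with_torsion:
            profile = _torsion_profile(config, vol, mesh)
            geo = lv.apply_torsion(mesh, profile)
            ts, T, g = profile.end_systole_time, profile.cycle_duration, profile.gamma_max
            torsion_rate = lambda t, ts=ts, T=T, g=g: (g / ts) if (t % T) <= ts else (-g / (T - ts))
        valve_tip_z = None
        valve = None
        if with_valve:
            ann = mitral.circular_annulus((mv_center[0], mv_center[1], zb - 1.0),
                                          config.valve.annulus_radius_mm,
                                          config.valve.n_annulus_points)
            valve = mitral.build_valve(ann, thickness=config.valve.thickness_mm,
                                       zone_angles={
                                           "anterior_leaflet": config.valve.anterior_deg,
                                           "posterior_leaflet": config.valve.posterior_deg,
                                           "front_commissure": config.valve.front_commissure_deg,
                                           "posterior_commissure": config.valve.posterior_commissure_deg})
            valve_tip_z = float(valve.anterior.free_edge()[:, 2].min())
        try:
            ff = flow.synth_cycle_flow(
                geo, schedule, jet, seed=config.module_seed(f"flow:{scen}"),
                grid=grid, mv_center=mv_center, outlet_center=outlet_center,
                valve_tip_z=valve_tip_z, torsion_rate_deg_s=torsion_rate, vol=vol,
                cycle_perturbation=config.flow.cycle_perturbation,
                # a strictly periodic field is stored once and wrapped in time;
                # explicit tiling is only needed for cycle-dependent perturbations
                n_cycles=(1 if config.flow.cycle_perturbation == 0
                          else max(config.flow.n_cycles + 1, 3)))
        except PipelineStageError:
            raise
        except Exception as e:
            raise PipelineStageError(f"flow:{scen}", e) from e

        scen_out = {"overset": _overset_checks(geo, grid)}
        try:
            scen_out.update(_postprocess(config, scen, geo, vol, ff, fluid, jet,
                                         mv_center, outlet_center, zb))
        except PipelineStageError:
            raise
        except Exception as e:
            raise PipelineStageError(f"metrics:{scen}", e) from e
        summary["scenarios"][scen] = scen_out
        del ff

    # bull's-eye case differences (Torsion − No Torsion, LVMV − LV)
    def bmap(s):
        return np.asarray(summary["scenarios"][s]["bullseye_mean_wss_pa"])

    summary["bullseye_diff_torsion_minus_no_torsion"] = (
        bmap("lvmv_torsion") - bmap("lvmv_no_torsion")).tolist()
    summary["bullseye_diff_lvmv_minus_lv"] = (
        bmap("lvmv_torsion") - bmap("lv_torsion")).tolist()
    # timing is logged, not embedded: the summary stays byte-identical per seed
    import logging
    logging.getLogger(__name__).info("pipeline wall time: %.2f s",
                                     time.time() - t_wall0)

    if write_outputs:
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "summary.json").write_text(json.dumps(summary, indent=1, sort_keys=True))
        vtkio.write_mesh4d(outdir / "lv_frames",
                           lv.Mesh4D(mesh.frames[:1], mesh.connectivity, mesh.times[:1]),
                           config_hash=config.hash())
    return summary


def _postprocess(config, scen, geo, vol, ff, fluid, jet, mv_center, outlet_center, zb):
    mu = fluid.dynamic_viscosity
    T = vol.cycle_duration
    nper = ff.metadata.get("cycle_frames", ff.n_frames)
    out = {}
    out["flux_rel_error_max"] = float(np.max(ff.metadata["flux_rel_error"]))
    out["wall_normal_mismatch_median_m_s"] = float(np.median(ff.metadata["wall_normal_mismatch"]))
    # energy loss over the last full cycle
    el = metrics.energy_loss(ff, mu, float(ff.times[-nper]), float(ff.times[-1]))
    out["energy_loss_last_cycle_mj"] = el.el * 1e3
    # E-peak plane class fractions
    ke = int(np.argmin(np.abs(ff.times % T - vol.e_peak_time)))
    speed = np.linalg.norm(ff.velocity[ke], axis=-1)
    speed = np.where(ff.mask[ke], speed, np.nan)
    vort = metrics.vorticity_magnitude(ff, ke)
    out["class_fractions"] = {}
    for plane in ("LA", "SA1", "SA2", "SA3"):
        vbins = metrics.ClassBins("velocity", tuple(config.metrics.velocity_bins_m_s), plane)
        wbins = metrics.ClassBins("vorticity", tuple(config.metrics.vorticity_bins_1_s), plane)
        out["class_fractions"][plane] = {
            "velocity": metrics.class_fractions(
                metrics.plane_slice(ff, speed, plane, axis_length_mm=zb), vbins).tolist(),
            "vorticity": metrics.class_fractions(
                metrics.plane_slice(ff, vort, plane, axis_length_mm=zb), wbins).tolist(),
        }
    # WSS bull's-eye at the E-peak
    kgeo = geo.frame_index(float(ff.times[ke]))
    wss = metrics.wall_shear_stress(ff, geo.frames[kgeo], geo.connectivity, mu, frame=ke)
    bmap = metrics.bullseye_aggregate(wss, base_z=zb)
    out["bullseye_mean_wss_pa"] = bmap.mean.tolist()
    out["bullseye_max_wss_pa"] = bmap.max.tolist()
    # vortex-ring centroid depth at the shedding time (early diastole):
    # Q-criterion singles out the ring core against the jet's shear sheet
    ks = int(np.argmin(np.abs(ff.times % T - (vol.end_systole_time + 0.06))))
    q = np.nan_to_num(metrics.q_criterion(ff, ks), nan=0.0)
    w2 = np.maximum(q, 0.0) ** 2
    zc = ff.grid.cell_centers().reshape(*ff.grid.dims, 3)[..., 2]
    zb_shed = float(geo.frames[geo.frame_index(float(ff.times[ks])), -1, 2])
    if w2.sum() > 0:
        out["vortex_centroid_depth_mm"] = float(zb_shed - np.sum(w2 * zc) / w2.sum())
    else:
        out["vortex_centroid_depth_mm"] = 0.0
    # particles: inlet release at the start of a diastole; the seeding disk and
    # the ejection plane sit below the *minimum* basal height over the cycle
    # (the base descends toward the apex in systole) so both stay inside the
    # discrete in-domain mask at every phase
    pc = config.particles
    h = ff.grid.spacing
    zb_min = float(geo.frames[:, -1, 2].min())
    inlet_v, inlet_f = particles.disk_surface_mesh(
        [mv_center[0], mv_center[1], zb_min - 2.5 * h], jet.orifice_diameter / 2.0,
        n_rings=39)
    t_release = vol.end_systole_time + 1e-6
    seeds = particles.seed_inlet(inlet_v, pc.n_particles,
                                 seed=config.module_seed(f"particles:{scen}"),
                                 inlet_faces=inlet_f, release_time=t_release)
    eject_plane = np.array([outlet_center[0], outlet_center[1], zb_min - 2.0 * h])
    advected = particles.advect(seeds, ff, t_release, n_beats=pc.n_beats,
                                cycle_duration=T,
                                outlet_center=eject_plane, outlet_radius=12.0,
                                substeps_per_frame=pc.substeps_per_frame)
    rt = particles.classify_rt(advected)
    n_below, n_res = particles.motility_stats(advected, pc.motility_threshold_m_s)
    out["residence_time"] = {
        "n_seeded": rt.n_seeded, "n_direct": rt.n_direct,
        "n_second_beat": rt.n_second_beat, "n_residual": rt.n_residual,
        "n_escaped": rt.n_escaped, "fractions": rt.fractions,
        "motility_below_threshold": [n_below, n_res],
    }
    # probe-cloud percentile statistics along the MV-centroid–apex axis
    sc = config.stats
    clouds = cyclestats.make_probes([mv_center[0], mv_center[1], zb], [0.0, 0.0, 5.0],
                                    n_clouds=sc.n_clouds, radius=sc.cloud_radius_mm,
                                    n_points=sc.cloud_points,
                                    seed=config.module_seed(f"stats:{scen}"))
    frames_1cycle = range(0, nper, max(1, nper // 10))
    ps = cyclestats.percentile_series(ff, clouds, frames_1cycle)
    out["probe_velocity_median_max_m_s"] = float(
        ps.data["velocity_magnitude"][..., 1].max())
    out["probe_percentile_ordering_ok"] = bool(ps.check_ordering())
    if config.flow.n_cycles >= 2:
        cv = cyclestats.cross_cycle_std(ff, T, vol.e_peak_time)
        out["cross_cycle_std_max_m_s"] = cv.max_std
    return out
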