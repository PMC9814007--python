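# ventriflow

A desk-scale toolkit for left-ventricular (LV) hemodynamics with a moving
mitral valve (MV), built around the Chimera (overset-mesh) modeling
paradigm.  It is aimed at researchers who want to prototype, validate and
teach the *pipeline* around an intracardiac CFD study — 4D geometry with
vertex correspondence, valve kinematics, overset cell bookkeeping, and the
standard post-processing metrics — without a commercial solver in the loop.

What it provides:

* **Parametric 4D LV kinematics** — a truncated prolate spheroid driven by a
  periodic volume curve with systolic ejection and E/A-wave filling
  (defaults: EDV 162.7 ml, ESV 53.7 ml ⇒ EF = (EDV−ESV)/EDV = 0.67,
  SV = 109 ml), superposed ventricular torsion as a piecewise-linear
  twist/untwist ramp about the MV-centroid–apex axis (γ = 13° at
  end-systole), and natural-cubic-spline temporal resampling (a 0.87 s cycle
  at 3 ms gives 290 frames).
* **A kinematic mitral valve** — cycle-averaged annulus, lofted leaflets
  with 2 mm thickness, a four-zone opening-angle shaping function (anterior
  / posterior leaflet, front / posterior commissure) and per-station hinge
  rotations with wall-clearance checking.
* **Overset (Chimera) bookkeeping** — dead / solve / receptor / donor cell
  classification of a Cartesian background grid against moving walls,
  manual cut-control exclusions, trilinear donor→receptor stencils
  (weights in [0,1], affine-exact) and vanishing-zone detection.
* **Synthetic incompressible cycle flow** — transmitral jet + shed vortex
  ring in diastole, sink outflow in systole, wall-conforming cavity
  deformation, with the discrete base-plane flux matched to dV/dt each
  frame; plus canonical analytic fields (Couette, Poiseuille, rigid
  rotation, Hill's vortex) used as metric oracles.
* **The post-processing suite** — viscous dissipation
  Φ_V = ½ μ Σᵢⱼ (∂uᵢ/∂xⱼ + ∂uⱼ/∂xᵢ)² and energy loss EL = ∫ Σ Φ_V Vᵢ dt,
  vorticity and Q-criterion, velocity/vorticity class fractions on LA/SA
  planes, near-wall WSS with 17-sector (AHA) bull's-eye mean/max maps and
  case-difference maps, Lagrangian residence time (direct flow / second
  beat / residual, 0.5 m/s motility threshold, 4,500 inlet seeds), probe
  clouds with median/5th/95th percentile series, and cross-cycle standard
  deviation at a fixed phase.

## Worked example

Run the three-scenario comparison (LV with torsion, LV+MV without torsion,
LV+MV with torsion) on a coarse 48³ grid:

```python
from ventriflow import RunConfig, run_pipeline

cfg = RunConfig(seed=7)
summary = run_pipeline(cfg, output_dir="demo_out")
for name, s in summary["scenarios"].items():
    rt = s["residence_time"]
    kept = rt["n_seeded"] - rt["n_escaped"]
    print(f"{name:16s} EL={s['energy_loss_last_cycle_mj']:.2f} mJ/cycle  "
          f"direct flow={100 * rt['n_direct'] / kept:.1f}%  "
          f"ring depth={s['vortex_centroid_depth_mm']:.1f} mm")
```

prints (seed 7):

```
lv_torsion       EL=3.87 mJ/cycle  direct flow=69.6%  ring depth=11.0
lvmv_no_torsion  EL=3.89 mJ/cycle  direct flow=79.5%  ring depth=19.0
lvmv_torsion     EL=3.89 mJ/cycle  direct flow=79.1%  ring depth=19.0
```

Reading this: energy loss is a few mJ per cycle, the physiological scale for
a resting ventricle.  With the valve present the diastolic vortex ring is
shed at the leaflet tips (≈19 mm below the base) instead of the annulus
(≈11 mm), which carries the inflow jet deeper and raises the direct flow —
the fraction of inflow tracers ejected within their first beat — from ~70 %
to ~79 %.  Tracers still resident after two beats sit almost entirely in the
low-motility apical pool (speed < 0.5 m/s).  `summary.json` additionally
contains the per-plane velocity/vorticity class fractions, the 17-sector
bull's-eye WSS tables and their case differences, probe-cloud percentile
statistics, and the cross-cycle standard deviation (exactly 0 for the
strictly periodic synthetic field).

The same pipeline is scriptable from the shell:

```bash
ventriflow run --seed 7 --out demo_out
ventriflow overset classify --spacing-mm 0.7 --out category.vti
ventriflow particles track --n 4500 --beats 2 --seed 7 --out rt.json
```

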