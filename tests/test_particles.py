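"""Particle seeding, RK4 advection, residence-time classification, motility."""
import numpy as np
import pytest

from ventriflow import flow, geometry, overset, particles


def _steady_field(kind, n=48, extent=50.0, times=None, **params):
    grid = overset.CartesianGrid((-extent / 2, -extent / 2, -extent / 2),
                                 extent / n, (n, n, n))
    base = flow.canonical_field(kind, grid, **params)
    if times is None:
        return base
    nt = len(times)
    return flow.FlowField(grid, np.asarray(times),
                          np.repeat(base.velocity, nt, axis=0),
                          np.repeat(base.mask, nt, axis=0))


class TestSeeding:
    def test_three_node_triangle(self):
        verts = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0]], dtype=float)
        ps = particles.seed_inlet(verts, 3)
        np.testing.assert_allclose(np.sort(ps.positions, axis=0),
                                   np.sort(verts, axis=0), atol=1e-12)

    def test_default_4500_on_surface(self):
        verts, faces = particles.disk_surface_mesh((0, 0, 10.0), 8.0, n_rings=39)
        ps = particles.seed_inlet(verts, 4500, seed=1, inlet_faces=faces)
        assert ps.n == 4500
        d = geometry.point_triangle_distance(ps.positions, verts, faces)
        assert d.max() < 1e-9

    def test_seeds_duplicate_free(self):
        verts, _ = particles.disk_surface_mesh((0, 0, 0), 5.0, n_rings=10)
        ps = particles.seed_inlet(verts, len(verts))
        from scipy.spatial import cKDTree
        dist, _ = cKDTree(ps.positions).query(ps.positions, k=2)
        assert dist[:, 1].min() > 1e-9

    def test_empty_surface_rejected(self):
        with pytest.raises(ValueError, match="no nodes"):
            particles.seed_inlet(np.zeros((0, 3)), 10)

    def test_apical_seeding_below_fraction(self, mesh4d):
        ps = particles.seed_apical(mesh4d.frames[0], mesh4d.connectivity,
                                   0.3, 100, seed=4)
        v = mesh4d.frames[0]
        z_cut = v[:, 2].min() + 0.3 * (v[:, 2].max() - v[:, 2].min())
        assert np.all(ps.positions[:, 2] < z_cut)
        assert geometry.points_inside(ps.positions, v, mesh4d.connectivity).all()

    def test_apical_seeding_deterministic(self, mesh4d):
        a = particles.seed_apical(mesh4d.frames[0], mesh4d.connectivity, 0.3, 50, seed=7)
        b = particles.seed_apical(mesh4d.frames[0], mesh4d.connectivity, 0.3, 50, seed=7)
        np.testing.assert_array_equal(a.positions, b.positions)

    def test_degenerate_fraction_rejected(self, mesh4d):
        with pytest.raises(ValueError):
            particles.seed_apical(mesh4d.frames[0], mesh4d.connectivity, 0.0, 10)


class TestAdvection:
    def test_zero_field_positions_unchanged(self):
        ff = _steady_field("couette", shear_rate=0.0, times=[0.0, 0.5, 1.0])
        ps = particles.ParticleSet.at(np.array([[1.0, 2.0, 3.0], [-4.0, 0.0, 5.0]]))
        out = particles.advect(ps, ff, 0.0, n_beats=1, cycle_duration=1.0)
        np.testing.assert_allclose(out.positions, ps.positions, atol=1e-12)
        assert (out.status == particles.IN_LV).all()

    def test_rigid_rotation_closed_orbit(self):
        # one full period of a solid-body rotation returns the particle home
        ff = _steady_field("rigid_rotation", omega=2 * np.pi,
                           times=np.linspace(0, 1.1, 12))
        start = np.array([[10.0, 0.0, 0.0]])
        out = particles.advect(particles.ParticleSet.at(start), ff, 0.0,
                               n_beats=1, cycle_duration=1.0,
                               substeps_per_frame=8)
        err = np.linalg.norm(out.positions[0] - start[0])
        assert err / 25.0 < 1e-6  # relative to the domain radius

    def test_rk4_step_halving_order(self):
        ff = _steady_field("rigid_rotation", omega=2 * np.pi,
                           times=np.linspace(0, 1.1, 12))
        start = np.array([[10.0, 0.0, 0.0]])
        errs = []
        for sub in (2, 4, 8):
            out = particles.advect(particles.ParticleSet.at(start), ff, 0.0,
                                   n_beats=1, cycle_duration=1.0,
                                   substeps_per_frame=sub)
            errs.append(np.linalg.norm(out.positions[0] - start[0]))
        order = np.log2(errs[0] / errs[1]), np.log2(errs[1] / errs[2])
        assert min(order) >= 3.8

    def test_uniform_outflow_ejects_all_in_beat_one(self):
        ff = _steady_field("couette", shear_rate=0.0, times=np.linspace(0, 1.1, 12))
        ff.velocity[..., 2] = 0.05  # 50 mm/s toward +z
        seeds = particles.ParticleSet.at(
            np.column_stack([np.linspace(-5, 5, 20), np.zeros(20), np.full(20, -10.0)]))
        out = particles.advect(seeds, ff, 0.0, n_beats=1, cycle_duration=1.0,
                               outlet_center=(0.0, 0.0, 15.0))
        assert (out.status == particles.EJECTED).all()
        assert (out.ejection_beat == 1).all()

    def test_escape_reported_for_mask_exit(self):
        ff = _steady_field("couette", shear_rate=0.0, times=np.linspace(0, 1.1, 12))
        ff.mask[:, :, :, 30:] = False  # ceiling inside the grid
        ff.velocity[..., 2] = 0.05
        seeds = particles.ParticleSet.at(np.array([[0.0, 0.0, 0.0]]))
        out = particles.advect(seeds, ff, 0.0, n_beats=1, cycle_duration=1.0)
        assert out.status[0] == particles.ESCAPED


class TestClassification:
    def _ejected_set(self, beats):
        n = len(beats)
        ps = particles.ParticleSet.at(np.zeros((n, 3)))
        for i, b in enumerate(beats):
            if b:
                ps.status[i] = particles.EJECTED
                ps.ejection_beat[i] = b
        return ps

    def test_all_direct(self):
        rt = particles.classify_rt(self._ejected_set([1] * 10))
        assert (rt.n_direct, rt.n_second_beat, rt.n_residual) == (10, 0, 0)
        assert rt.fractions["direct"] == 1.0

    def test_half_direct_half_residual(self):
        # constructed two-compartment outcome: half leave in beat 1, half never
        rt = particles.classify_rt(self._ejected_set([1] * 5 + [0] * 5))
        assert (rt.n_direct, rt.n_second_beat, rt.n_residual) == (5, 0, 5)
        np.testing.assert_allclose(
            [rt.fractions["direct"], rt.fractions["residual"]], [0.5, 0.5])

    def test_order_invariance(self):
        rng = np.random.default_rng(6)
        beats = [1] * 7 + [2] * 4 + [0] * 9
        a = particles.classify_rt(self._ejected_set(beats))
        rng.shuffle(beats)
        b = particles.classify_rt(self._ejected_set(beats))
        assert (a.n_direct, a.n_second_beat, a.n_residual) == \
            (b.n_direct, b.n_second_beat, b.n_residual)

    def test_conservation_invariant(self):
        rt = particles.classify_rt(self._ejected_set([1, 2, 0, 0, 1]))
        assert rt.n_direct + rt.n_second_beat + rt.n_residual + rt.n_escaped \
            == rt.n_seeded

    def test_fractions_sum_to_one(self):
        rt = particles.classify_rt(self._ejected_set([1, 2, 2, 0]))
        assert sum(rt.fractions.values()) == pytest.approx(1.0, abs=1e-12)


class TestMotility:
    def _residuals_with_speeds(self, speeds):
        n = len(speeds)
        ps = particles.ParticleSet.at(np.zeros((n, 3)))
        ps.speed_at_end = np.asarray(speeds, dtype=float)
        return ps

    def test_all_at_rest(self):
        nb, nt = particles.motility_stats(self._residuals_with_speeds([0.0] * 8))
        assert (nb, nt) == (8, 8)

    def test_zero_threshold_strict_inequality(self):
        nb, _ = particles.motility_stats(self._residuals_with_speeds([0.0, 0.1]),
                                         threshold=0.0)
        assert nb == 0

    def test_uniform_speeds_near_half_below_default_threshold(self):
        rng = np.random.default_rng(9)
        speeds = rng.random(4000)  # uniform on [0, 1) m/s
        nb, nt = particles.motility_stats(self._residuals_with_speeds(speeds))
        assert nt == 4000
        assert abs(nb / nt - 0.5) < 3 * 0.5 / np.sqrt(4000)


def test_blob_volume_preserved_in_solenoidal_field():
    """RK4 trajectories in a divergence-free steady field preserve the volume
    of a seeded blob (convex-hull proxy) over one period."""
    from scipy.spatial import ConvexHull
    ff = _steady_field("rigid_rotation", omega=2 * np.pi,
                       times=np.linspace(0, 1.1, 12))
    rng = np.random.default_rng(12)
    blob = rng.uniform(-3, 3, size=(80, 3)) + [8.0, 0.0, 0.0]
    out = particles.advect(particles.ParticleSet.at(blob), ff, 0.0, n_beats=1,
                           cycle_duration=1.0, substeps_per_frame=8)
    v0 = ConvexHull(blob).volume
    v1 = ConvexHull(out.positions).volume
    assert abs(v1 - v0) / v0 < 0.01
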