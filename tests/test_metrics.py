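"""Dissipation, energy loss, class fractions, WSS and bull's-eye aggregation."""
import numpy as np
import pytest

from ventriflow import flow, geometry, metrics, overset


MU = 0.003  # blood viscosity, kg/(m s)


class TestViscousDissipation:
    def test_zero_gradient(self):
        assert metrics.viscous_dissipation_rate(np.zeros((3, 3)), MU) == 0.0

    def test_pure_shear_hand_value(self):
        # dU1/dx2 = 100 1/s: Phi_V = 0.5*mu*[(100)^2 + (100)^2] = 30 W/m^3
        g = np.zeros((3, 3))
        g[0, 1] = 100.0
        assert metrics.viscous_dissipation_rate(g, MU) == pytest.approx(30.0, abs=1e-12)

    def test_rigid_rotation_dissipates_nothing(self):
        g = np.array([[0.0, -5.0, 0.0], [5.0, 0.0, 0.0], [0.0, 0.0, 0.0]])
        assert metrics.viscous_dissipation_rate(g, MU) == pytest.approx(0.0, abs=1e-15)

    def test_nonnegative_for_arbitrary_gradients(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            g = rng.normal(size=(3, 3)) * 100
            assert metrics.viscous_dissipation_rate(g, MU) >= 0.0


class TestEnergyLoss:
    def _steady_el(self, field):
        phi = metrics.viscous_dissipation_rate(
            metrics.velocity_gradient(field, 0), MU)
        return float(phi[field.mask[0]].sum()) * (field.grid.spacing * 1e-3) ** 3

    def test_couette_closed_form(self):
        n = 64
        gap = 0.01  # m, spanned exactly by the grid
        grid = overset.CartesianGrid((0, 0, 0), 10.0 / n, (n, n, n))
        U = 1.0
        ff = flow.canonical_field("couette", grid, shear_rate=U / gap)
        el_rate = self._steady_el(ff)  # W
        exact = MU * (U / gap) ** 2 * (0.01 * 0.01) * gap  # mu (U/h)^2 A h
        assert el_rate == pytest.approx(exact, rel=0.01)

    def test_poiseuille_equals_pressure_work(self):
        n = 64
        grid = overset.CartesianGrid((0, 0, 0), 10.0 / n, (n, n, n))
        R = 4.0  # mm
        ff = flow.canonical_field("poiseuille", grid, u_max=1.0, radius=R)
        el_rate = self._steady_el(ff)
        L = 10e-3
        dp = 4 * MU * 1.0 * L / (R * 1e-3) ** 2
        sl = ff.mask[0][:, :, n // 2]
        q = float(np.sum(ff.velocity[0][:, :, n // 2, 2][sl])) * (grid.spacing * 1e-3) ** 2
        assert el_rate == pytest.approx(dp * q, rel=0.02)

    def test_additive_over_time(self):
        grid = overset.CartesianGrid((0, 0, 0), 1.0, (8, 8, 8))
        base = flow.canonical_field("couette", grid, shear_rate=50.0)
        times = np.linspace(0, 1.0, 11)
        ff = flow.FlowField(grid, times,
                            np.repeat(base.velocity, 11, axis=0),
                            np.repeat(base.mask, 11, axis=0))
        el_half = metrics.energy_loss(ff, MU, 0.0, 0.5).el
        el_full = metrics.energy_loss(ff, MU, 0.0, 1.0).el
        # steady periodic field: doubling the window doubles EL
        assert el_full == pytest.approx(2.0 * el_half, rel=1e-10)
        # additivity over adjacent sub-intervals
        el_b = metrics.energy_loss(ff, MU, 0.5, 1.0).el
        assert el_half + el_b == pytest.approx(el_full, rel=1e-10)

    def test_el_invariant_under_rigid_rotation_of_scene(self):
        # rotate the Couette field and its grid by 90 deg about z: same EL
        n = 32
        grid = overset.CartesianGrid((0, 0, 0), 10.0 / n, (n, n, n))
        ff = flow.canonical_field("couette", grid, shear_rate=100.0)
        el0 = self._steady_el(ff)
        # 90 deg rotation maps u=(k y,0,0) onto v=(0, k x', 0) on the same lattice
        centers = grid.cell_centers().reshape(*grid.dims, 3) * 1e-3
        vel = np.zeros((1, *grid.dims, 3))
        vel[0][..., 1] = 100.0 * centers[..., 0]
        ffr = flow.FlowField(grid, np.array([0.0]), vel, ff.mask.copy())
        assert self._steady_el(ffr) == pytest.approx(el0, rel=0.01)

    def test_empty_mask_warns_and_returns_zero(self):
        grid = overset.CartesianGrid((0, 0, 0), 1.0, (4, 4, 4))
        ff = flow.canonical_field("couette", grid, shear_rate=10.0)
        ff.mask[:] = False
        with pytest.warns(UserWarning, match="empty"):
            el = metrics.energy_loss(ff, MU, 0.0, 0.0)
        assert el.el == 0.0


class TestVorticity:
    def test_uniform_flow_zero(self, small_grid):
        ff = flow.canonical_field("couette", small_grid, shear_rate=0.0)
        ff.velocity[0][..., 0] = 1.0
        w = metrics.vorticity_magnitude(ff, 0)
        np.testing.assert_allclose(w, 0.0, atol=1e-12)

    def test_couette_vorticity_equals_shear_rate(self, small_grid):
        ff = flow.canonical_field("couette", small_grid, shear_rate=123.0)
        w = metrics.vorticity_magnitude(ff, 0)
        np.testing.assert_allclose(w, 123.0, rtol=1e-10)

    def test_second_order_convergence_on_smooth_field(self):
        # sinusoidal shear: central-difference curl error scales as h^2
        errs = []
        for n in (16, 32):
            grid = overset.CartesianGrid((0, 0, 0), 10.0 / n, (n, n, n))
            centers = grid.cell_centers().reshape(*grid.dims, 3) * 1e-3
            vel = np.zeros((1, *grid.dims, 3))
            kwave = 2 * np.pi / 0.01
            vel[0][..., 0] = np.sin(kwave * centers[..., 1])
            ff = flow.FlowField(grid, np.array([0.0]), vel,
                                np.ones((1, *grid.dims), bool))
            w = metrics.vorticity_magnitude(ff, 0)
            exact = kwave * np.abs(np.cos(kwave * centers[..., 1]))
            errs.append(np.abs(w - exact)[2:-2, 2:-2, 2:-2].max())
        order = np.log2(errs[0] / errs[1])
        assert order > 1.8


class TestClassFractions:
    def _bins(self):
        return metrics.ClassBins("velocity", (0.0, 0.25, 0.5, 1.0, np.inf))

    def test_constant_field_single_bin(self):
        vals = np.full((10, 10), 0.3)
        f = metrics.class_fractions(vals, self._bins())
        np.testing.assert_allclose(f, [0, 1.0, 0, 0], atol=1e-12)

    def test_two_half_planes(self):
        vals = np.concatenate([np.full(50, 0.1), np.full(50, 0.7)])
        f = metrics.class_fractions(vals, self._bins())
        np.testing.assert_allclose(f, [0.5, 0, 0.5, 0], atol=1e-12)

    def test_random_field_matches_counting_oracle(self):
        rng = np.random.default_rng(8)
        vals = rng.uniform(0, 2.0, size=(40, 40))
        vals[rng.random((40, 40)) < 0.2] = np.nan  # out-of-domain pixels
        f = metrics.class_fractions(vals, self._bins())
        flat = vals[np.isfinite(vals)]
        edges = [0.0, 0.25, 0.5, 1.0, np.inf]
        expect = [np.sum((flat >= a) & (flat < b)) / len(flat)
                  for a, b in zip(edges, edges[1:])]
        np.testing.assert_allclose(f, expect, atol=1e-12)
        assert f.sum() == pytest.approx(1.0, abs=1e-12)

    def test_descending_edges_rejected(self):
        with pytest.raises(ValueError):
            metrics.ClassBins("velocity", (1.0, 0.5, 2.0))


class TestWallShearStress:
    def _couette_wall(self):
        # wall at y=0 spanning the shear plane of a Couette field
        v = np.array([[2.0, 0.0, 2.0], [8.0, 0.0, 2.0], [8.0, 0.0, 8.0],
                      [2.0, 0.0, 8.0]])
        f = np.array([[0, 1, 2], [0, 2, 3]])  # outward normal -y (fluid above)
        return v, f

    def test_couette_wss_matches_mu_k(self):
        n = 64
        grid = overset.CartesianGrid((0, 0, 0), 10.0 / n, (n, n, n))
        k = 200.0
        ff = flow.canonical_field("couette", grid, shear_rate=k)
        v, f = self._couette_wall()
        wss = metrics.wall_shear_stress(ff, v, f, MU, frame=0)
        ok = ~wss.flagged
        assert ok.any()
        np.testing.assert_allclose(wss.tau[ok], MU * k, rtol=0.05)

    def test_zero_field_zero_wss(self, small_grid):
        ff = flow.canonical_field("couette", small_grid, shear_rate=0.0)
        v, f = self._couette_wall()
        wss = metrics.wall_shear_stress(ff, v - [0, -5, 0], f, MU, frame=0)
        np.testing.assert_allclose(wss.tau[~wss.flagged], 0.0, atol=1e-15)

    def test_wss_linear_in_viscosity(self):
        n = 32
        grid = overset.CartesianGrid((0, 0, 0), 10.0 / n, (n, n, n))
        ff = flow.canonical_field("couette", grid, shear_rate=100.0)
        v, f = self._couette_wall()
        tau1 = metrics.wall_shear_stress(ff, v, f, MU, frame=0).tau
        tau2 = metrics.wall_shear_stress(ff, v, f, 2 * MU, frame=0).tau
        np.testing.assert_allclose(tau2, 2 * tau1, rtol=1e-12)


@pytest.fixture(scope="module")
def lv_wall(mesh4d):
    return mesh4d.frames[0], mesh4d.connectivity


class TestBullseye:
    def _wss(self, lv_wall, tau):
        v, f = lv_wall
        return metrics.WSSField(tau, v, f, np.zeros(len(v), dtype=bool))

    def test_always_17_sectors(self, lv_wall):
        v, f = lv_wall
        sectors = metrics.aha_sectors(v)
        assert set(np.unique(sectors)) <= set(range(1, 18))
        assert len(np.unique(sectors)) == 17

    def test_uniform_scalar_uniform_map(self, lv_wall):
        bmap = metrics.bullseye_aggregate(self._wss(lv_wall, np.full(len(lv_wall[0]), 2.5)))
        np.testing.assert_allclose(bmap.mean, 2.5, atol=1e-12)
        np.testing.assert_allclose(bmap.max, 2.5, atol=1e-12)

    def test_single_sector_signal_stays_in_sector(self, lv_wall):
        v, f = lv_wall
        sectors = metrics.aha_sectors(v)
        tau = np.where(sectors == 3, 7.0, 0.0).astype(float)
        bmap = metrics.bullseye_aggregate(self._wss(lv_wall, tau))
        assert bmap.max[2] == 7.0
        assert np.sum(bmap.max > 0) == 1

    def test_partition_covers_surface_area(self, lv_wall):
        v, f = lv_wall
        sectors = metrics.aha_sectors(v)
        areas = geometry.vertex_areas(v, f)
        total = sum(areas[sectors == s].sum() for s in range(1, 18))
        assert total == pytest.approx(areas.sum(), rel=1e-9)

    def test_difference_map_algebra(self, lv_wall):
        v, _ = lv_wall
        rng = np.random.default_rng(2)
        a = metrics.bullseye_aggregate(self._wss(lv_wall, rng.uniform(0, 3, len(v))))
        b = metrics.bullseye_aggregate(self._wss(lv_wall, rng.uniform(0, 3, len(v))))
        d_ab = metrics.bullseye_difference(a, b)
        d_ba = metrics.bullseye_difference(b, a)
        np.testing.assert_allclose(d_ab.mean, -d_ba.mean, atol=1e-12)
        np.testing.assert_allclose(
            metrics.bullseye_difference(a, a).mean, 0.0, atol=1e-12)
        # constant shift appears as the constant in every sector
        shifted = metrics.BullseyeMap(a.mean + 1.5, a.max + 1.5,
                                      a.sector_of_vertex, a.sector_names)
        np.testing.assert_allclose(
            metrics.bullseye_difference(shifted, a).mean, 1.5, atol=1e-12)


def test_background_cell_volume_at_printed_edge_length():
    assert metrics.background_cell_volume_mm3(0.7) == pytest.approx(0.343, abs=1e-12)
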