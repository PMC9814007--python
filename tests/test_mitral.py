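"""Mitral valve model: annulus averaging, lofting, zone shaping, kinematics."""
import numpy as np
import pytest

from ventriflow import geometry, mitral


def _circle(radius=11.0, n=64, center=(0, 0, 80.0)):
    return mitral.circular_annulus(center, radius, n)


class TestAverageAnnulus:
    def test_identical_frames_returned_unchanged(self):
        base = _circle().control_points
        out = mitral.average_annulus([base, base, base])
        np.testing.assert_allclose(out.control_points, base, atol=1e-12)

    def test_symmetric_translations_cancel(self):
        base = _circle().control_points
        d = np.array([1.5, -2.0, 0.7])
        out = mitral.average_annulus([base + d, base - d])
        np.testing.assert_allclose(out.control_points, base, atol=1e-12)

    def test_zero_mean_noise_averages_out(self):
        base = _circle().control_points
        rng = np.random.default_rng(11)
        n_frames, sigma = 200, 0.5
        frames = [base + rng.normal(0, sigma, base.shape) for _ in range(n_frames)]
        out = mitral.average_annulus(frames)
        # per-point error ~ sigma/sqrt(N); allow 4x margin
        err = np.linalg.norm(out.control_points - base, axis=1)
        assert err.max() < 4 * sigma / np.sqrt(n_frames) * np.sqrt(3)

    def test_mismatched_point_counts_rejected(self):
        with pytest.raises(ValueError, match="point count"):
            mitral.average_annulus([_circle(n=64).control_points,
                                    _circle(n=32).control_points])

    def test_centroid_is_mean(self):
        ann = _circle()
        np.testing.assert_allclose(ann.centroid, ann.control_points.mean(axis=0),
                                   atol=1e-12)


class TestBuildLeaflets:
    def test_frustum_area_matches_closed_form(self):
        # annulus circle R1 lofted to a concentric circle R2 in a parallel
        # plane: lateral area of a conical frustum
        R1, R2, dz = 12.0, 6.0, 8.0
        ann = _circle(radius=R1, n=128)
        free = _circle(radius=R2, n=128, center=(0, 0, 80.0 - dz)).control_points
        ant, post = mitral.build_leaflets(ann, free, thickness=0.0, n_rows=24,
                                          overlap_deg=0.0)
        area = sum(geometry.triangle_areas(s.vertices(), s.faces()).sum()
                   for s in (ant, post))
        slant = np.hypot(R1 - R2, dz)
        exact = np.pi * (R1 + R2) * slant
        assert area == pytest.approx(exact, rel=0.01)

    def test_zero_thickness_offsets_coincide(self, valve):
        ant, _ = mitral.build_leaflets(valve.annulus,
                                       mitral.default_free_edge(valve.annulus),
                                       thickness=0.0)
        top, bottom = ant.offset_surfaces()
        np.testing.assert_allclose(top, bottom, atol=1e-12)

    def test_sheets_cover_annulus_with_overlap(self, valve):
        stations = valve.annulus.stations_deg()
        covered = np.zeros(len(stations), dtype=bool)
        both = np.zeros(len(stations), dtype=bool)
        for s in (valve.anterior, valve.posterior):
            m = np.isin(np.round(stations, 6), np.round(s.station_deg, 6))
            both |= covered & m
            covered |= m
        assert covered.all()
        assert both.any()   # overlap band exists

    def test_atrial_side_free_edge_rejected(self):
        ann = _circle()
        bad_free = ann.control_points + [0, 0, 5.0]  # above the annulus plane
        with pytest.raises(ValueError, match="ventricular side"):
            mitral.build_leaflets(ann, bad_free)


class TestZoneShaping:
    def test_constant_angles_give_constant_blend(self, valve):
        part = mitral.zone_shaping(valve.anterior, valve.posterior,
                                   {z: 30.0 for z in mitral.ZONES})
        np.testing.assert_allclose(part.vertex_angle, 30.0, atol=1e-9)

    def test_zone_means_match_prescription(self, valve):
        targets = {"anterior_leaflet": 55.0, "posterior_leaflet": 40.0,
                   "front_commissure": 25.0, "posterior_commissure": 25.0}
        part = mitral.zone_shaping(valve.anterior, valve.posterior, targets)
        for z in mitral.ZONES:
            got = part.vertex_angle[part.zone_of_vertex == z].mean()
            assert got == pytest.approx(targets[z], abs=1.0)

    def test_commissures_open_less_than_leaflets(self, valve):
        part = valve.partition
        for com in ("front_commissure", "posterior_commissure"):
            com_mean = part.vertex_angle[part.zone_of_vertex == com].mean()
            for leaf in ("anterior_leaflet", "posterior_leaflet"):
                leaf_mean = part.vertex_angle[part.zone_of_vertex == leaf].mean()
                assert com_mean < leaf_mean

    def test_blend_continuity_around_annulus(self):
        ann = _circle(n=128)
        free = mitral.default_free_edge(ann)
        ant, post = mitral.build_leaflets(ann, free)
        part = mitral.zone_shaping(ant, post, {
            "anterior_leaflet": 55.0, "posterior_leaflet": 40.0,
            "front_commissure": 25.0, "posterior_commissure": 25.0})
        stations = np.linspace(0, 360, 129)[:-1]
        angles = mitral.station_angles(part, stations)
        jumps = np.abs(np.diff(np.append(angles, angles[0])))
        assert jumps.max() < 2.0


class TestLeafletKinematics:
    def test_zero_angle_is_identity(self, valve):
        sched = mitral.OpeningSchedule(closed_min=0.0)
        ant, post = mitral.leaflet_frame_at(valve, sched, 0.0)  # systole, fully closed
        np.testing.assert_allclose(ant.mid_surface, valve.anterior.mid_surface,
                                   atol=1e-9)

    def test_hinge_distance_preserved(self, valve):
        sched = mitral.OpeningSchedule()
        ant, _ = mitral.leaflet_frame_at(valve, sched, 0.45)
        for j in (0, valve.anterior.n_cols // 2):
            d0 = np.linalg.norm(valve.anterior.mid_surface[:, j]
                                - valve.anterior.hinge_points[j], axis=1)
            d1 = np.linalg.norm(ant.mid_surface[:, j] - ant.hinge_points[j], axis=1)
            np.testing.assert_allclose(d0, d1, atol=1e-9)

    def test_no_sheet_self_intersection_over_cycle(self, valve):
        sched = mitral.OpeningSchedule()
        for t in np.linspace(0.0, 0.86, 12):
            ant, post = mitral.leaflet_frame_at(valve, sched, float(t))
            for sheet in (ant, post):
                hits = geometry.self_intersections(sheet.vertices(), sheet.faces(),
                                                   max_report=1)
                assert hits == [], f"self-intersection at t={t:.2f} on {sheet.side}"

    def test_orifice_area_monotone_in_angle_scale(self, valve):
        areas = []
        for s in (0.2, 0.5, 0.8, 1.0):
            ant = mitral._rotate_sheet(
                valve.anterior,
                mitral.station_angles(valve.partition, valve.anterior.station_deg) * s)
            post = mitral._rotate_sheet(
                valve.posterior,
                mitral.station_angles(valve.partition, valve.posterior.station_deg) * s)
            areas.append(mitral.orifice_area(ant, post, valve.annulus))
        assert all(a < b for a, b in zip(areas, areas[1:]))

    def test_schedule_bounds_and_periodicity(self):
        sched = mitral.OpeningSchedule()
        t = np.linspace(0, 2 * sched.cycle_duration, 200)
        f = np.array([sched.fraction(tt) for tt in t])
        assert np.all(f >= sched.closed_min - 1e-12)
        assert np.all(f <= sched.open_max + 1e-12)
        assert sched.fraction(0.1) == pytest.approx(
            sched.fraction(0.1 + sched.cycle_duration), abs=1e-12)


class TestClearance:
    @pytest.fixture
    def interior_valve(self):
        # annulus placed mid-cavity so the whole valve sits inside the wall
        ann = mitral.circular_annulus((0.0, 0.0, 60.0), radius=8.0, n_points=32)
        return mitral.build_valve(ann, free_edge=mitral.default_free_edge(
            ann, scale=0.4, drop=6.0))

    def test_interior_valve_clears_wall(self, mesh4d, interior_valve):
        mins, violations = mitral.clearance_check(
            (interior_valve.anterior, interior_valve.posterior),
            mesh4d.frames[0], mesh4d.connectivity)
        assert violations == []
        assert all(v > 0 for v in mins.values())

    def test_constructed_violation_detected(self, mesh4d, interior_valve):
        import dataclasses
        bad = dataclasses.replace(
            interior_valve.anterior,
            mid_surface=interior_valve.anterior.mid_surface.copy())
        bad.mid_surface[-1, 0] = [200.0, 0.0, 40.0]  # far outside the wall
        _, violations = mitral.clearance_check([bad], mesh4d.frames[0],
                                               mesh4d.connectivity)
        assert any(v[1] == bad.n_rows - 1 and v[2] == 0 for v in violations)
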