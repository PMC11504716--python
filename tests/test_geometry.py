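import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cranangles.geometry import (PROSTHION_ANGLES, ClampCounter, GeometryError, Plane,
                                 angle_measurement_names, build_angle_registry,
                                 compute_angle_table, compute_specimen_angles,
                                 frankfurt_plane, line_plane_angle, three_point_angle)
from cranangles.landmarks import LandmarkPoint, mirror_landmark_set

from conftest import make_set

coord = st.floats(-100, 100, allow_nan=False)
point = st.tuples(coord, coord, coord)


class TestFrankfurtPlane:
    def test_coordinate_plane_normal(self, fh_base_points):
        plane = frankfurt_plane(make_set(fh_base_points))
        assert abs(plane.n[2]) == pytest.approx(1.0, abs=1e-12)

    def test_missing_landmark_named(self, fh_base_points):
        s = make_set(fh_base_points[:2])
        with pytest.raises(GeometryError, match="po"):
            frankfurt_plane(s)

    def test_collinear_error(self):
        s = make_set([("or", "left", (0, 0, 0)), ("po", "left", (1, 0, 0)),
                      ("po", "right", (2, 0, 0))])
        with pytest.raises(GeometryError, match="collinear"):
            frankfurt_plane(s)

    def test_rigid_equivariance(self, fh_base_points, rng):
        s = make_set(fh_base_points)
        q, r = np.linalg.qr(rng.normal(size=(3, 3)))
        q *= np.sign(np.diag(r))
        shift = rng.uniform(-50, 50, 3)
        moved = s.transformed(lambda p: q @ p + shift)
        n1, n2 = frankfurt_plane(s).n, frankfurt_plane(moved).n
        assert abs(abs((q @ n1) @ n2) - 1.0) < 1e-9


class TestLinePlaneAngle:
    plane = Plane((0, 0, 0), (0, 0, 1))

    def test_in_plane_line_is_zero(self):
        assert line_plane_angle((0, 0, 0), (3, 4, 0), self.plane) == pytest.approx(0.0)

    def test_normal_line_is_ninety(self):
        assert line_plane_angle((0, 0, 1), (0, 0, 5), self.plane) == pytest.approx(90.0)

    def test_forty_five(self):
        assert line_plane_angle((0, 0, 0), (1, 0, 1), self.plane) == pytest.approx(45.0)

    def test_zero_length_rejected(self):
        with pytest.raises(GeometryError):
            line_plane_angle((1, 1, 1), (1, 1, 1), self.plane)

    @settings(max_examples=200, derandomize=True)
    @given(a=point, b=point, n=point)
    def test_projection_oracle(self, a, b, n):
        # angle to the plane == angle between the line and its in-plane projection
        a, b, n = np.array(a), np.array(b), np.array(n)
        if np.linalg.norm(b - a) < 1e-6 or np.linalg.norm(n) < 1e-6:
            return
        n = n / np.linalg.norm(n)
        plane = Plane((0.0, 0.0, 0.0), tuple(n))
        d = b - a
        proj = d - (d @ n) * n
        got = line_plane_angle(a, b, plane)
        if np.linalg.norm(proj) < 1e-9 * np.linalg.norm(d):
            assert got == pytest.approx(90.0, abs=1e-5)
        else:
            cos = abs(d @ proj) / (np.linalg.norm(d) * np.linalg.norm(proj))
            expected = np.degrees(np.arccos(min(1.0, cos)))
            assert got == pytest.approx(expected, abs=1e-7)


class TestThreePointAngle:
    def test_equilateral(self):
        h = np.sqrt(3) / 2
        assert three_point_angle((0, 0, 0), (1, 0, 0), (0.5, h, 0)) == pytest.approx(60.0)

    def test_straight_angle(self):
        assert three_point_angle((-1, 0, 0), (0, 0, 0), (2, 0, 0)) == pytest.approx(180.0)

    def test_coincident_rejected(self):
        with pytest.raises(GeometryError):
            three_point_angle((0, 0, 0), (0, 0, 0), (1, 1, 1))

    @settings(max_examples=300, derandomize=True)
    @given(a=point, v=point, c=point)
    def test_law_of_cosines_matches_vector_oracle(self, a, v, c):
        a, v, c = np.array(a), np.array(v), np.array(c)
        if np.linalg.norm(a - v) < 1e-3 or np.linalg.norm(c - v) < 1e-3:
            return
        u, w = a - v, c - v
        cos = np.clip((u @ w) / (np.linalg.norm(u) * np.linalg.norm(w)), -1, 1)
        expected = np.degrees(np.arccos(cos))
        # arccos loses ~sqrt(eps) precision when |cos| -> 1 (near-collinear)
        tol = 1e-9 if abs(cos) < 1 - 1e-6 else 1e-4
        assert three_point_angle(a, v, c) == pytest.approx(expected, abs=tol)

    def test_triangle_angles_sum_to_180(self, rng):
        for _ in range(200):
            a, v, c = rng.normal(size=(3, 3)) * 50
            total = (three_point_angle(a, v, c) + three_point_angle(v, a, c)
                     + three_point_angle(a, c, v))
            assert total == pytest.approx(180.0, abs=1e-9)

    def test_clamp_only_near_limits(self):
        counter = ClampCounter()
        three_point_angle((-1, 0, 0), (0, 0, 0), (2, 0, 0), counter)
        assert counter.count <= 1  # collinear may clamp, but only within 1e-12
        with pytest.raises(GeometryError):
            counter.clamp(1.0 + 1e-9)


class TestAngleRegistry:
    def test_expansion_counts(self):
        registry = build_angle_registry()
        assert len(registry) == 32
        names = angle_measurement_names()
        assert len(names) == 36
        line_plane = [d for d in registry if d.kind == "line_plane"]
        three_pt = [d for d in registry if d.kind == "three_point"]
        assert sum(len(d.expanded()) for d in line_plane) == 20
        assert sum(len(d.expanded()) for d in three_pt) == 16
        by_lat = {}
        for d in registry:
            by_lat.setdefault((d.kind, d.laterality), []).append(d)
        assert len(by_lat[("line_plane", "midsagittal")]) == 14
        assert len(by_lat[("line_plane", "bilateral")]) == 3
        assert len(by_lat[("three_point", "midsagittal")]) == 9
        assert len(by_lat[("three_point", "transversal")]) == 5
        assert len(by_lat[("three_point", "bilateral")]) == 1

    def test_bilateral_expansion_names(self):
        names = angle_measurement_names()
        assert "po-ms-ast (R)" in names and "po-ms-ast (L)" in names
        for code in ("zm-zo-FH", "so-zo-FH", "ek-mf-FH"):
            assert f"{code} (R)" in names and f"{code} (L)" in names

    def test_vertex_is_middle_code(self):
        for d in build_angle_registry():
            if d.kind == "three_point":
                assert len(d.landmarks) == 3


class TestAngleTable:
    def test_missing_prosthion_pattern(self, template_specimen):
        s = make_set([(pt.code, pt.side, pt.xyz) for pt in template_specimen.points.values()
                      if pt.code != "pr"])
        vals, reasons = compute_specimen_angles(s)
        assert set(PROSTHION_ANGLES) == set(reasons)
        assert len(vals) == 31

    def test_constructed_zero_angle(self, fh_base_points):
        # basion-opisthion laid into the FH plane itself
        s = make_set(fh_base_points + [("ba", "mid", (-10, 0, 0)), ("o", "mid", (-40, 0, 0))])
        vals, _ = compute_specimen_angles(s)
        assert vals["ba-o-FH"] == pytest.approx(0.0, abs=1e-12)

    def test_similarity_invariance(self, template_specimen, rng):
        q, r = np.linalg.qr(rng.normal(size=(3, 3)))
        q *= np.sign(np.diag(r))
        scale, shift = 1.7, rng.uniform(-80, 80, 3)
        moved = template_specimen.transformed(lambda p: scale * (q @ p) + shift)
        t1 = compute_angle_table([template_specimen])
        t2 = compute_angle_table([moved])
        np.testing.assert_allclose(t1.frame.to_numpy(), t2.frame.to_numpy(), atol=1e-9)

    def test_reflection_swaps_sides_exactly(self, template_specimen):
        mirrored = mirror_landmark_set(template_specimen, "y=0")
        orb = template_specimen.get("or", "left")
        mirrored.add(LandmarkPoint("or", "left", (orb[0], -orb[1], orb[2])))
        v1, _ = compute_specimen_angles(template_specimen)
        v2, _ = compute_specimen_angles(mirrored)
        for name, val in v1.items():
            if name.endswith("(R)"):
                partner = name[:-3] + "(L)"
            elif name.endswith("(L)"):
                partner = name[:-3] + "(R)"
            else:
                partner = name
            assert v2[partner] == pytest.approx(val, abs=1e-12), name

    def test_all_values_in_documented_ranges(self, template_specimen):
        vals, _ = compute_specimen_angles(template_specimen)
        registry = {name: d for d in build_angle_registry() for name, _ in d.expanded()}
        for name, val in vals.items():
            hi = 90.0 if registry[name].kind == "line_plane" else 180.0
            assert 0.0 <= val <= hi
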