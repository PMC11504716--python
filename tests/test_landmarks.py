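import numpy as np
import pytest

from cranangles.landmarks import (AcquisitionTrialSet, LandmarkError, LandmarkPoint,
                                  LandmarkSet, build_landmark_registry,
                                  default_pp_aliases, intraobserver_error,
                                  mirror_landmark_set, read_landmarks_csv,
                                  read_picked_points, registry_slots,
                                  write_landmarks_csv, write_picked_points)

from conftest import make_set


class TestRegistry:
    def test_slot_counts(self):
        registry = build_landmark_registry()
        assert len(registry) == 26
        by_lat = {}
        for spec in registry:
            by_lat.setdefault(spec.laterality, []).append(spec)
        assert len(by_lat["midsagittal"]) == 14
        assert len(by_lat["bilateral"]) == 11
        assert [s.code for s in by_lat["left_only"]] == ["or"]
        slots = registry_slots()
        assert len(slots) == 14 + 11 * 2 + 1 == 37
        assert slots.count(("or", "left")) == 1 and ("or", "right") not in slots

    def test_codes_unique(self):
        codes = [s.code for s in build_landmark_registry()]
        assert len(codes) == len(set(codes))

    def test_side_validation(self):
        with pytest.raises(LandmarkError):
            LandmarkPoint("n", "left", (0, 0, 0))  # midsagittal has no sides
        with pytest.raises(LandmarkError):
            LandmarkPoint("or", "right", (0, 0, 0))  # orbitale is left-only
        with pytest.raises(LandmarkError):
            LandmarkPoint("xx", "mid", (0, 0, 0))


class TestCsvIO:
    def _full_set(self, rng):
        pts = [(code, side, rng.normal(size=3) * 50) for code, side in registry_slots()]
        return make_set(pts, "sp1", "male")

    def test_round_trip_bit_exact(self, tmp_path, rng):
        s = self._full_set(rng)
        path = tmp_path / "lm.csv"
        write_landmarks_csv([s], path)
        (back,) = read_landmarks_csv(path)
        assert back.completeness == (37, 37)
        assert back.sex == "male"
        for key, pt in s.points.items():
            assert back.points[key].xyz == pt.xyz

    def test_missing_landmark_is_absent_not_error(self, tmp_path, rng):
        s = self._full_set(rng)
        del s.points[("pr", "mid")]
        path = tmp_path / "lm.csv"
        write_landmarks_csv([s], path)
        (back,) = read_landmarks_csv(path)
        assert not back.has("pr")
        assert back.completeness == (36, 37)
        assert ("pr", "mid") in back.missing_slots()

    def test_unknown_code_rejected_with_line(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("specimen_id,sex,landmark,side,x,y,z\n"
                        "s1,male,xx,mid,0,0,0\n")
        with pytest.raises(LandmarkError, match="xx"):
            read_landmarks_csv(path)

    def test_duplicate_rejected(self, tmp_path):
        path = tmp_path / "dup.csv"
        path.write_text("specimen_id,sex,landmark,side,x,y,z\n"
                        "s1,male,n,mid,0,0,0\ns1,male,n,mid,1,1,1\n")
        with pytest.raises(LandmarkError, match="duplicate"):
            read_landmarks_csv(path)


class TestPickedPoints:
    def test_round_trip(self, tmp_path, rng):
        pts = [(code, side, rng.normal(size=3) * 50) for code, side in registry_slots()]
        s = make_set(pts)
        path = tmp_path / "s.pp"
        write_picked_points(s, path)
        back = read_picked_points(path)
        assert back.completeness == (37, 37)

    def test_duplicate_point_rejected(self, tmp_path):
        path = tmp_path / "dup.pp"
        path.write_text('<!DOCTYPE PickedPoints><PickedPoints>'
                        '<point name="n" x="0" y="0" z="1"/>'
                        '<point name="n" x="1" y="0" z="1"/></PickedPoints>')
        with pytest.raises(LandmarkError, match="duplicate"):
            read_picked_points(path)

    def test_unmappable_name_lists_aliases(self, tmp_path):
        path = tmp_path / "bad.pp"
        path.write_text('<PickedPoints><point name="nasionX" x="0" y="0" z="1"/>'
                        '</PickedPoints>')
        with pytest.raises(LandmarkError, match="po_L"):
            read_picked_points(path)

    def test_left_only_input_leaves_right_absent(self, tmp_path):
        path = tmp_path / "left.pp"
        path.write_text('<PickedPoints>'
                        '<point name="n" x="0" y="0" z="1"/>'
                        '<point name="po_L" x="1" y="2" z="3"/>'
                        '</PickedPoints>')
        s = read_picked_points(path)
        assert s.has("po", "left") and not s.has("po", "right")

    def test_default_aliases_cover_all_slots(self):
        aliases = default_pp_aliases()
        assert set(aliases.values()) >= set(registry_slots())


class TestMirror:
    def test_reflection_and_side_swap(self):
        s = make_set([("po", "left", (1, 2, 3)), ("po", "right", (4, 5, 6)),
                      ("n", "mid", (7, 8, 9))])
        m = mirror_landmark_set(s, "x=0")
        assert tuple(m.get("po", "right")) == (-1, 2, 3)
        assert tuple(m.get("po", "left")) == (-4, 5, 6)
        assert tuple(m.get("n", "mid")) == (-7, 8, 9)

    def test_involution(self, rng):
        pts = [(code, side, rng.normal(size=3) * 40)
               for code, side in registry_slots() if code != "or"]
        s = make_set(pts)
        twice = mirror_landmark_set(mirror_landmark_set(s, "y=0"), "y=0")
        for key, pt in s.points.items():
            assert twice.points[key].xyz == pytest.approx(pt.xyz, abs=1e-12)

    def test_left_only_dropped(self):
        s = make_set([("or", "left", (1, 2, 3))])
        assert len(mirror_landmark_set(s, "y=0").points) == 0


class TestIntraobserverError:
    def test_identical_trials_zero(self):
        trial = make_set([("n", "mid", (1, 2, 3))])
        t = AcquisitionTrialSet("s1", [trial, make_set([("n", "mid", (1, 2, 3))])])
        err = intraobserver_error(t)
        assert err.loc[0, "error_mm"] == 0.0

    def test_collinear_offsets_match_sample_sd(self):
        # trials at -d, 0, +d along x: per-axis sample variance d^2, error d
        d = 0.7
        trials = [make_set([("n", "mid", (off, 0, 0))]) for off in (-d, 0.0, d)]
        err = intraobserver_error(AcquisitionTrialSet("s1", trials))
        assert err.loc[0, "error_mm"] == pytest.approx(d, abs=1e-12)

    def test_matches_brute_force_per_axis_variance_sum(self, rng):
        coords = rng.normal(size=(4, 3))
        trials = [make_set([("ms", "left", xyz)]) for xyz in coords]
        err = intraobserver_error(AcquisitionTrialSet("s1", trials), per_axis=True)
        expected = np.sqrt(sum(np.var(coords[:, ax], ddof=1) for ax in range(3)))
        assert err.loc[0, "error_mm"] == pytest.approx(expected, abs=1e-12)
        axis_sds = err.loc[0, ["sd_x", "sd_y", "sd_z"]].to_numpy(dtype=float)
        assert np.sqrt((axis_sds ** 2).sum()) == pytest.approx(expected, abs=1e-12)

    def test_rigid_invariance(self, rng):
        coords = rng.normal(size=(3, 3)) * 5
        theta = 0.83
        rot = np.array([[np.cos(theta), -np.sin(theta), 0],
                        [np.sin(theta), np.cos(theta), 0], [0, 0, 1.0]])
        shift = np.array([10.0, -4.0, 2.5])
        base = [make_set([("b", "mid", xyz)]) for xyz in coords]
        moved = [make_set([("b", "mid", rot @ xyz + shift)]) for xyz in coords]
        e1 = intraobserver_error(AcquisitionTrialSet("s1", base))
        e2 = intraobserver_error(AcquisitionTrialSet("s1", moved))
        assert e1.loc[0, "error_mm"] == pytest.approx(e2.loc[0, "error_mm"], abs=1e-9)

    def test_sub_millimetre_noise_reports_sub_millimetre_errors(self, rng):
        # repeat digitization with 0.15 mm per-axis jitter stays within 1 mm
        base = {k: rng.normal(size=3) * 50 for k in [("n", "mid"), ("po", "left")]}
        trials = []
        for _ in range(3):
            trials.append(make_set([(c, s, xyz + rng.normal(0, 0.15, 3))
                                    for (c, s), xyz in base.items()]))
        err = intraobserver_error(AcquisitionTrialSet("s1", trials))
        assert (err["error_mm"] <= 1.0).all()

    def test_single_trial_landmark_flagged(self):
        t1 = make_set([("n", "mid", (0, 0, 0)), ("b", "mid", (1, 1, 1))])
        t2 = make_set([("n", "mid", (0, 0, 0.2))])
        err = intraobserver_error(AcquisitionTrialSet("s1", [t1, t2])).set_index("landmark")
        assert not err.loc["b", "assessable"]
        assert np.isnan(err.loc["b", "error_mm"])

    def test_requires_two_trials(self):
        with pytest.raises(LandmarkError):
            AcquisitionTrialSet("s1", [make_set([("n", "mid", (0, 0, 0))])])
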