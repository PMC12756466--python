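"""Tests of per-neurosphere summaries and migration-distance measurement."""

import itertools

import numpy as np
import pytest

from sphereq.classification import NucleusRecord
from sphereq.quantification import (
    MigrationMeasurement,
    detect_emigrated_points,
    measure_border_distances,
    parse_combination,
    summarize_roi,
)
from sphereq.segmentation import _roi_from_mask
from sphereq.synthetic import disk_mask, generate_migration_field

from conftest import disk_bool


def _rec(i, signs):
    return NucleusRecord(
        i, 1, 20.0, (float(i), float(i)),
        mean_intensity={m: 99.0 for m in signs},
        positive=dict(signs),
    )


class TestParseCombination:
    def test_signed_tokens(self):
        got = parse_combination("SOX10+PHOX2B+HU-", {"SOX10", "PHOX2B", "HU"})
        assert got == [("SOX10", True), ("PHOX2B", True), ("HU", False)]

    def test_hyphenated_marker_names(self):
        assert parse_combination("far-red+", {"far-red"}) == [("far-red", True)]

    def test_unknown_marker_rejected(self):
        with pytest.raises(ValueError, match="parse"):
            parse_combination("NOPE+", {"HU"})


class TestSummarizeRoi:
    def test_single_marker_proportion(self):
        recs = [_rec(i, {"HU": i < 4}) for i in range(10)]
        s = summarize_roi(recs, 1, ["HU+"])
        assert s.n_nuclei == 10
        assert s.n_positive["HU+"] == 4
        assert s.proportion["HU+"] == pytest.approx(0.4)

    def test_conjunction_counts(self):
        recs = [_rec(i, {"SOX10": True, "PHOX2B": i < 3}) for i in range(5)]
        s = summarize_roi(recs, 1, ["SOX10+PHOX2B+"])
        assert s.n_positive["SOX10+PHOX2B+"] == 3

    def test_negated_term_forces_zero_when_all_positive(self):
        recs = [_rec(i, {"SOX10": True, "PHOX2B": True, "HU": True}) for i in range(6)]
        s = summarize_roi(recs, 1, ["SOX10+PHOX2B+HU-"])
        assert s.n_positive["SOX10+PHOX2B+HU-"] == 0

    def test_empty_roi_flagged(self):
        s = summarize_roi([], 7, ["HU+"])
        assert s.n_nuclei == 0 and s.proportion["HU+"] is None

    def test_adding_marker_never_increases_count(self):
        rng = np.random.default_rng(2)
        recs = [
            _rec(i, {"A": bool(rng.integers(2)), "B": bool(rng.integers(2))})
            for i in range(30)
        ]
        s = summarize_roi(recs, 1, ["A+", "A+B+", "A+B-"])
        assert s.n_positive["A+B+"] <= s.n_positive["A+"]
        assert s.n_positive["A+B-"] <= s.n_positive["A+"]

    def test_sign_combinations_partition_nuclei(self):
        rng = np.random.default_rng(3)
        recs = [
            _rec(i, {"HU": bool(rng.integers(2)), "SOX10": bool(rng.integers(2))})
            for i in range(40)
        ]
        combos = [
            f"HU{a}SOX10{b}" for a, b in itertools.product("+-", repeat=2)
        ]
        s = summarize_roi(recs, 1, combos)
        assert sum(s.n_positive.values()) == s.n_nuclei


class TestBorderDistances:
    def _spheroid(self):
        return _roi_from_mask(disk_bool((200, 200), (100, 100), 50), 1, "manual")

    def test_circle_point_distance_analytic(self):
        meas = measure_border_distances(
            self._spheroid(), [(100, 180), (20, 100), (100, 190), (180, 100), (100, 15)]
        )
        # point at (100,180): center distance 80 minus radius 50 = 30
        assert meas.distances[2] == pytest.approx(30.0, abs=0.5)

    def test_top5_selection(self):
        pts = [(100.0, 151.0 + d) for d in (1, 2, 3, 4, 5, 6, 7)]
        meas = measure_border_distances(self._spheroid(), pts)
        assert len(meas.distances) == 5
        assert meas.distances == sorted(meas.distances, reverse=True)
        assert meas.distances[0] == pytest.approx(8.0, abs=0.6)
        assert meas.distances[-1] == pytest.approx(4.0, abs=0.6)

    def test_boundary_point_has_zero_distance(self):
        sph = self._spheroid()
        boundary_px = tuple(np.argwhere(
            sph.mask & ~disk_bool((200, 200), (100, 100), 48))[0])
        pts = [boundary_px] + [(5.0, 5.0 + i) for i in range(4)]
        meas = measure_border_distances(sph, pts)
        assert meas.distances[-1] == 0.0

    def test_fewer_than_five_external_points_rejected(self):
        with pytest.raises(ValueError, match="4"):
            measure_border_distances(
                self._spheroid(), [(100, 180), (20, 100), (100, 190), (180, 100)]
            )

    def test_interior_points_not_counted(self):
        pts = [(100, 100), (100, 105)] + [(5.0, 5.0 + i) for i in range(5)]
        meas = measure_border_distances(self._spheroid(), pts)  # 5 external: ok
        assert len(meas.distances) == 5

    def test_matches_bruteforce_boundary_minimum(self):
        sph = self._spheroid()
        rng = np.random.default_rng(6)
        pts = [(float(r), float(c)) for r, c in rng.integers(0, 200, (8, 2))
               if not sph.mask[r, c]][:5]
        while len(pts) < 5:
            pts.append((0.0, float(len(pts))))
        meas = measure_border_distances(sph, pts)
        from scipy.ndimage import binary_erosion

        boundary = np.argwhere(
            sph.mask & ~binary_erosion(
                sph.mask, structure=np.ones((3, 3), bool), border_value=0)
        )
        brute = sorted(
            (min(np.hypot(r - br, c - bc) for br, bc in boundary) for r, c in pts),
            reverse=True,
        )[:5]
        assert meas.distances == pytest.approx(brute, abs=1e-9)

    def test_measurement_invariants(self):
        with pytest.raises(ValueError, match="5"):
            MigrationMeasurement(1, [3.0, 2.0, 1.0])
        with pytest.raises(ValueError, match="descending"):
            MigrationMeasurement(1, [1.0, 2.0, 3.0, 4.0, 5.0])


class TestDetectEmigratedPoints:
    def test_planted_cells_found_at_their_far_pixels(self):
        field = generate_migration_field(
            50.0, [10, 15, 20, 25, 30, 35, 40, 45, 50, 55, 60, 65], seed=4
        )
        sph = _roi_from_mask(field.spheroid_mask(), 1, "manual")
        pts = detect_emigrated_points(field.stack.channels[0], sph)
        assert len(pts) == 12
        meas = measure_border_distances(sph, pts)
        assert meas.distances == pytest.approx(field.planted_distances[:5], abs=1.0)

    def test_no_signal_outside_spheroid(self):
        field = generate_migration_field(40.0, [], seed=1)
        sph = _roi_from_mask(field.spheroid_mask(), 1, "manual")
        assert detect_emigrated_points(field.stack.channels[0], sph) == []

    def test_particle_inside_spheroid_excluded(self):
        field = generate_migration_field(40.0, [], seed=1, noise_sigma=0.0)
        img = field.stack.channels[0]
        arr = img.pixels.copy()
        ctr = tuple(int(x) for x in field.spheroid_center)
        arr[ctr[0] - 2: ctr[0] + 2, ctr[1] - 2: ctr[1] + 2] = 250  # bright interior cell
        from conftest import make_image

        sph = _roi_from_mask(field.spheroid_mask(), 1, "manual")
        assert detect_emigrated_points(make_image(arr, label="m"), sph) == []
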