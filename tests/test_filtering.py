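"""Sector selection, outlier rejection and the full filter pipeline."""

import math

import numpy as np
import pytest

from conftest import make_points
from glovescan.errors import ConfigurationError
from glovescan.filtering import (
    DROPPED_NOT_CLOSEST,
    DROPPED_OUTLIER,
    SELECTED,
    FilterConfig,
    SectorGrid,
    assign_to_nearest_reference,
    compute_reference_point,
    filter_pipeline,
    reject_outliers,
    sector_index,
    select_closest_per_sector,
    selectivity,
)
from glovescan.geometry import PoseSample, ReferencePoint, SphericalCoordinate


def brute_force_selection(points, origin, angular_size):
    """Independent per-sector minimum-radius selection (dict-based, scalar math).

    Groups every point by its (azimuth, elevation) sector and keeps the one
    with the smallest radius, ties to earliest time then lowest sensor id.
    """
    n_az = math.ceil(360.0 / angular_size)
    n_el = math.ceil(180.0 / angular_size)
    groups = {}
    for idx, p in enumerate(points):
        v = p.position - origin
        r = math.sqrt(float(v @ v))
        if r == 0.0:
            continue
        az = math.degrees(math.atan2(v[1], v[0])) % 360.0
        if math.hypot(v[0], v[1]) == 0.0:
            az = 0.0
        el = math.degrees(math.atan2(v[2], math.hypot(v[0], v[1])))
        i_az = min(int(az // angular_size), n_az - 1)
        i_el = min(int((el + 90.0) // angular_size), n_el - 1)
        key = (i_az, i_el)
        rank = (r, p.t, p.sensor_id, idx)
        if key not in groups or rank < groups[key][0]:
            groups[key] = (rank, idx)
    return sorted(idx for _, idx in groups.values())


class TestSectorGrid:
    @pytest.mark.parametrize("az, el, size, expected", [
        (0.0, -90.0, 5.0, (0, 0)),
        (359.9, 89.9, 5.0, (71, 35)),
        (0.0, 90.0, 5.0, (0, 35)),    # pole clamps into the top row
        (360.0, 0.0, 5.0, (0, 18)),   # azimuth wraps
    ])
    def test_indexing(self, az, el, size, expected):
        grid = SectorGrid(size)
        assert sector_index(SphericalCoordinate(1.0, az, el), grid) == expected

    def test_every_direction_maps_to_exactly_one_sector(self, rng):
        grid = SectorGrid(7.0)
        az = rng.uniform(0, 360, 1000)
        el = rng.uniform(-90, 90, 1000)
        i_az, i_el = grid.sector_of(az, el)
        assert np.all((0 <= i_az) & (i_az < grid.n_az))
        assert np.all((0 <= i_el) & (i_el < grid.n_el))

    def test_invalid_angular_size(self):
        with pytest.raises(ConfigurationError):
            SectorGrid(0.0)
        with pytest.raises(ConfigurationError):
            SectorGrid(91.0)


class TestAssignment:
    def test_single_reference_takes_all(self):
        refs = [ReferencePoint(3, np.zeros(3))]
        out = assign_to_nearest_reference(make_points([[1, 2, 3], [4, 5, 6]]), refs)
        assert list(out) == [3, 3]

    def test_nearest_wins_and_ties_to_lowest_id(self):
        refs = [ReferencePoint(0, np.zeros(3)), ReferencePoint(1, np.array([100.0, 0, 0]))]
        pts = make_points([[10, 0, 0], [90, 0, 0], [50, 0, 0]])
        assert list(assign_to_nearest_reference(pts, refs)) == [0, 1, 0]

    def test_empty_refs(self):
        with pytest.raises(ConfigurationError):
            assign_to_nearest_reference(make_points([[0, 0, 1]]), [])


class TestSelection:
    def test_closer_point_dominates_collinear(self, origin_ref):
        pts = make_points([[10, 0, 0], [20, 0, 0]])
        out = select_closest_per_sector(pts, origin_ref, SectorGrid(10.0))
        assert list(out.status) == [SELECTED, DROPPED_NOT_CLOSEST]

    def test_one_point_per_sector_all_kept(self, origin_ref):
        pts = make_points([[10, 0, 0], [0, 10, 0], [0, 0, 10], [-10, 0, 0]])
        out = select_closest_per_sector(pts, origin_ref, SectorGrid(30.0))
        assert out.n_selected == 4

    @pytest.mark.parametrize("angular_size", [1.0, 5.0, 10.0, 30.0])
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_bruteforce_oracle(self, origin_ref, angular_size, seed):
        rng = np.random.default_rng(seed)
        pts = make_points(
            rng.uniform(-100, 100, size=(200, 3)),
            times=rng.uniform(0, 10, 200),
            sensor_ids=rng.integers(1, 4, 200),
        )
        out = select_closest_per_sector(pts, origin_ref, SectorGrid(angular_size))
        expected = brute_force_selection(pts, origin_ref.position, angular_size)
        assert sorted(np.flatnonzero(out.selected_mask)) == expected

    def test_selection_is_idempotent(self, origin_ref, rng):
        pts = make_points(rng.uniform(-50, 50, size=(300, 3)))
        grid = SectorGrid(10.0)
        once = select_closest_per_sector(pts, origin_ref, grid)
        kept = [pts[i] for i in np.flatnonzero(once.selected_mask)]
        twice = select_closest_per_sector(kept, origin_ref, grid)
        assert twice.n_selected == len(kept)

    def test_retained_radius_minimal_within_sector(self, origin_ref, rng):
        """Volume minimization: every kept point is at least as close as every
        dropped point sharing its fine sector."""
        pts = make_points(rng.uniform(-80, 80, size=(500, 3)))
        out = select_closest_per_sector(pts, origin_ref, SectorGrid(15.0))
        r = np.linalg.norm(out.positions, axis=1)
        key = out.sector_el * 10_000 + out.sector_az
        for i in np.flatnonzero(out.selected_mask):
            same = key == key[i]
            assert r[i] <= r[same].min() + 1e-12

    def test_origin_coincident_point_skipped(self, origin_ref):
        pts = make_points([[0, 0, 0], [10, 0, 0]])
        out = select_closest_per_sector(pts, origin_ref, SectorGrid(10.0))
        assert out.status[0] == DROPPED_NOT_CLOSEST
        assert out.status[1] == SELECTED


class TestOutlierRejection:
    def _fragment(self, radii, origin_ref):
        # collinear points -> same coarse sector, radii as given
        pts = make_points([[r, 0.001 * i, 0] for i, r in enumerate(radii)])
        return select_closest_per_sector(pts, origin_ref, SectorGrid(0.001 / 4))

    @pytest.mark.parametrize("radii, expected_dropped", [
        ((100, 100, 100, 130), 1),  # mean 107.5, cutoff 129 -> 130 dropped
        ((100, 100, 100, 125), 0),  # mean 106.25, cutoff 127.5 -> all kept
    ])
    def test_twenty_percent_rule(self, origin_ref, radii, expected_dropped):
        frag = self._fragment(radii, origin_ref)
        assert frag.n_selected == len(radii)
        out = reject_outliers(frag, origin_ref, SectorGrid(30.0), 0.20, 3)
        assert int(np.count_nonzero(out.status == DROPPED_OUTLIER)) == expected_dropped

    def test_underpopulated_sector_passes_through(self, origin_ref):
        frag = select_closest_per_sector(
            make_points([[500, 0, 0]]), origin_ref, SectorGrid(5.0)
        )
        out = reject_outliers(frag, origin_ref, SectorGrid(20.0), 0.20, 3)
        assert out.n_selected == 1

    def test_planted_far_point_always_dropped(self, origin_ref, rng):
        """A point at 1.5x the sector mean radius must fall to the 20% rule
        whenever enough well-behaved neighbours populate the coarse sector."""
        base = make_points([[100, i * 0.5, 0] for i in range(8)])
        planted = make_points([[150, 1.7, 0]], sensor_ids=[9])
        frag = select_closest_per_sector(base + planted, origin_ref, SectorGrid(0.01))
        out = reject_outliers(frag, origin_ref, SectorGrid(45.0), 0.20, 3)
        dropped = np.flatnonzero(out.status == DROPPED_OUTLIER)
        assert len(dropped) == 1 and out.positions[dropped[0]][0] == 150

    def test_invalid_threshold(self, origin_ref):
        frag = self._fragment((100, 100, 100), origin_ref)
        with pytest.raises(ConfigurationError):
            reject_outliers(frag, origin_ref, SectorGrid(30.0), 0.0, 3)


class TestPipeline:
    def test_empty_input(self):
        out = filter_pipeline([], [ReferencePoint(0, np.zeros(3))], FilterConfig())
        assert len(out) == 0 and out.n_selected == 0

    def test_provenance_covers_all_points(self, rng):
        pts = make_points(rng.uniform(-50, 50, size=(100, 3)))
        refs = [ReferencePoint(0, np.array([-20.0, 0, 0])),
                ReferencePoint(1, np.array([20.0, 0, 0]))]
        out = filter_pipeline(pts, refs, FilterConfig(fine_angular_size=10))
        assert len(out) == 100
        assert set(out.status) <= {SELECTED, DROPPED_NOT_CLOSEST, DROPPED_OUTLIER}
        assert set(out.ref_ids) <= {0, 1}

    def test_rerun_on_same_data_is_deterministic(self, rng):
        pts = make_points(rng.uniform(-50, 50, size=(200, 3)))
        refs = [ReferencePoint(0, np.zeros(3))]
        a = filter_pipeline(pts, refs, FilterConfig())
        b = filter_pipeline(pts, refs, FilterConfig())
        assert np.array_equal(a.status, b.status)


class TestSelectivity:
    @pytest.mark.parametrize("raw, kept, expected", [
        (1000, 1000, 100.0), (1000, 0, 0.0), (2000, 500, 25.0),
    ])
    def test_percentage(self, raw, kept, expected):
        assert selectivity(raw, kept) == expected

    def test_zero_raw_undefined(self):
        with pytest.raises(ConfigurationError):
            selectivity(0, 0)


class TestComputeReferencePoint:
    def _sample(self, sensor_id, p, t=0.5):
        return PoseSample(sensor_id=sensor_id, t=t, position=np.array(p, float))

    def test_single_sample(self):
        ref = compute_reference_point([self._sample(1, (1, 2, 3))], (0, 1), 0)
        np.testing.assert_array_equal(ref.position, [1, 2, 3])

    def test_mean_excludes_reference_sensor(self):
        samples = [
            self._sample(1, (0, 0, 0)),
            self._sample(2, (2, 2, 2)),
            self._sample(0, (100, 0, 0)),        # reference sensor: excluded
            self._sample(1, (50, 50, 50), t=9),  # outside window: excluded
        ]
        ref = compute_reference_point(samples, (0, 1), 0)
        np.testing.assert_array_equal(ref.position, [1, 1, 1])

    def test_empty_window(self):
        with pytest.raises(ConfigurationError):
            compute_reference_point([self._sample(0, (0, 0, 0))], (0, 1), 0)
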