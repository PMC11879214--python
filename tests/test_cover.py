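import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from espmod import (
    WindowCover,
    WindowGeometry,
    enumerate_windows,
    neighborhood_box_sides,
    point_windows,
    window_geometry,
)
from conftest import make_table


class TestNeighborhoodBoxSides:
    def test_full_neighbourhood_is_data_range(self):
        z = np.array([0.0, 0.2, 0.7, 1.0])
        table = make_table(z)
        sides = neighborhood_box_sides(table, n=4)
        np.testing.assert_allclose(sides, 1.0)

    def test_1d_nearest_neighbour_by_hand(self):
        table = make_table([0.0, 1.0, 3.0])
        sides = neighborhood_box_sides(table, n=2)
        np.testing.assert_allclose(sides.ravel(), [1.0, 1.0, 2.0])

    def test_duplicated_point_gives_zero_side(self):
        table = make_table([0.5, 0.5, 2.0])
        sides = neighborhood_box_sides(table, n=2)
        assert sides.min() == 0.0

    def test_n_out_of_range(self):
        table = make_table([0.0, 1.0])
        with pytest.raises(ValueError):
            neighborhood_box_sides(table, n=3)

    def test_sides_monotone_in_n(self):
        rng = np.random.default_rng(0)
        table = make_table(rng.uniform(0, 1, size=(50, 2)))
        prev = neighborhood_box_sides(table, n=5)
        for n in (10, 20, 40):
            cur = neighborhood_box_sides(table, n=n)
            assert (cur >= prev - 1e-12).all()
            prev = cur


class TestWindowGeometry:
    def test_percentile_and_min_by_hand(self):
        g = window_geometry(np.array([[0.1], [0.2], [0.4]]), percentile=95)
        assert g.sides[0] == pytest.approx(0.38)
        assert g.steps[0] == pytest.approx(0.1)

    def test_constant_column(self):
        g = window_geometry(np.full((5, 1), 0.3))
        assert g.sides == (0.3,) and g.steps == (0.3,)

    def test_zero_min_falls_back_to_smallest_positive(self):
        g = window_geometry(np.array([[0.0], [0.2], [0.4]]))
        assert g.steps[0] == pytest.approx(0.2)

    def test_degenerate_dimension_errors(self):
        with pytest.raises(ValueError, match="degenerate"):
            window_geometry(np.zeros((4, 1)))

    def test_uniform_sample_reproduces_published_example_geometry(self):
        # 200 points uniform on [0,1]^2 with 20-point neighbourhoods should
        # give windows near 0.4 x 0.4 gliding by about 0.16 per axis
        rng = np.random.default_rng(7)
        table = make_table(rng.uniform(0, 1, size=(200, 2)))
        g = window_geometry(neighborhood_box_sides(table, n=20), n_target=20)
        for L, d in zip(g.sides, g.steps):
            assert 0.32 < L < 0.48
            assert 0.10 < d < 0.25


class TestEnumerateWindows:
    def test_grid_size_formula(self):
        # covariates spanning exactly [0,1]^2 with steps 0.16: 7 centers/axis
        pts = np.array(list(itertools.product(np.linspace(0, 1, 15), repeat=2)))
        table = make_table(pts)
        geom = WindowGeometry(sides=(0.4, 0.4), steps=(0.16, 0.16), n_target=1)
        cover = enumerate_windows(table, geom, min_obs=1)
        assert cover.n_candidate == 49
        assert cover.n_retained == 49    # dense grid occupies every window

    def test_min_obs_filter_and_membership(self):
        table = make_table([0.0, 0.05, 0.1, 1.0])
        geom = WindowGeometry(sides=(0.2,), steps=(0.1,), n_target=2)
        cover = enumerate_windows(table, geom, min_obs=2)
        for w in cover.windows:
            assert w.n_members >= 2
        # closed interval: |z - c| <= L/2 exactly
        for w in cover.windows:
            z = table.covariates().to_numpy()[:, 0]
            inside = np.abs(z - w.center[0]) <= 0.1
            assert set(w.member_idx) == set(np.nonzero(inside)[0])

    def test_empty_cover_errors(self):
        table = make_table([0.0, 1.0, 2.0])
        geom = WindowGeometry(sides=(0.1,), steps=(0.5,), n_target=3)
        with pytest.raises(ValueError, match="cover is empty"):
            enumerate_windows(table, geom, min_obs=3)

    def test_discrete_covariate_duplicates_grid_per_stratum(self):
        rng = np.random.default_rng(2)
        z = rng.uniform(0, 1, size=(60, 1))
        sex = np.repeat([0.0, 1.0], 30)
        table = make_table(
            np.column_stack([z, sex]), discrete=["Z2"], extra_covariates=True
        )
        geom = WindowGeometry(sides=(0.5,), steps=(0.25,), n_target=1)
        cover = enumerate_windows(table, geom, min_obs=1)
        strata = {w.stratum for w in cover.windows}
        assert strata == {(0.0,), (1.0,)}
        # candidates double relative to a single stratum
        solo = enumerate_windows(make_table(z), geom, min_obs=1)
        assert cover.n_candidate == 2 * solo.n_candidate

    def test_binary_outcome_class_floor(self):
        z = np.linspace(0, 1, 40)
        y = np.tile([0.0, 0.0, 0.0, 1.0], 10)   # cases are a 25% minority
        table = make_table(z, y=y, outcome_family="binary")
        geom = WindowGeometry(sides=(0.4,), steps=(0.1,), n_target=5)
        full = enumerate_windows(table, geom, min_obs=5, min_class_count=0)
        floored = enumerate_windows(table, geom, min_obs=5, min_class_count=4)
        assert floored.n_retained < full.n_retained   # floor removes windows
        y_arr = table.outcome()
        for w in floored.windows:
            assert (y_arr[w.member_idx] == 1).sum() >= 4
            assert (y_arr[w.member_idx] == 0).sum() >= 4


class TestPointWindows:
    def _cover_1d(self):
        table = make_table(np.linspace(0, 1, 101))
        geom = WindowGeometry(sides=(0.4,), steps=(0.16,), n_target=1)
        return enumerate_windows(table, geom, min_obs=1)

    def test_window_center_contains_itself(self):
        cover = self._cover_1d()
        for i, w in enumerate(cover.windows):
            assert i in point_windows(cover, np.array(w.center))

    def test_brute_force_centers(self):
        cover = self._cover_1d()
        hits = point_windows(cover, np.array([0.3]))
        centers = [cover.windows[i].center[0] for i in hits]
        np.testing.assert_allclose(sorted(centers), [0.16, 0.32, 0.48])

    def test_far_point_uncovered(self):
        cover = self._cover_1d()
        assert point_windows(cover, np.array([5.0])) == []

    def test_every_observation_covered(self):
        rng = np.random.default_rng(4)
        z = rng.uniform(0, 1, size=(200, 2))
        table = make_table(z)
        cover = WindowCover(n_target=20, min_obs=1, min_class_count=0).fit(table).cover_
        for row in z:
            assert point_windows(cover, row)


@settings(deadline=None, derandomize=True, max_examples=25)
@given(
    st.lists(st.floats(0, 1), min_size=5, max_size=30),
    st.integers(2, 5),
)
def test_membership_matches_exhaustive_interval_checks(zs, n):
    """Window membership from the enumeration equals brute-force checks."""
    z = np.asarray(zs)
    if np.ptp(z) < 1e-6:
        return
    table = make_table(z)
    try:
        sides = neighborhood_box_sides(table, n=min(n, len(z)))
        geom = window_geometry(sides, n_target=n)
        cover = enumerate_windows(table, geom, min_obs=1)
    except ValueError:
        return
    half = cover.geometry.sides[0] / 2
    for w in cover.windows:
        expected = {i for i, zi in enumerate(z) if abs(zi - w.center[0]) <= half}
        assert set(w.member_idx) == expected


def test_retained_windows_meet_target_occupancy():
    """With min_obs = n every retained window holds >= n observations,
    and on uniform data the percentile sizing keeps most of the grid."""
    kept = []
    for seed in range(20):
        rng = np.random.default_rng(seed)
        table = make_table(rng.uniform(0, 1, size=(200, 2)))
        cover = WindowCover(n_target=20, min_class_count=0).fit(table).cover_
        assert all(w.n_members >= 20 for w in cover.windows)
        kept.append(cover.n_retained / cover.n_candidate)
    assert np.mean(kept) > 0.5


def test_manual_override_and_scaling():
    rng = np.random.default_rng(1)
    table = make_table(rng.uniform(0, 1, size=(100, 2)))
    wc = WindowCover(n_target=10, sides=(0.4, 0.4), steps=(0.2, 0.2),
                     min_obs=1, min_class_count=0, step_scale=0.5).fit(table)
    assert wc.geometry_.sides == (0.4, 0.4)
    assert wc.geometry_.steps == (0.1, 0.1)
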