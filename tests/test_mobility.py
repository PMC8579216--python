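"""GPS feature stack: distances, filtering, clustering, entropy, hours."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mobilesense import mobility
from mobilesense.mobility import (
    EARTH_RADIUS_M,
    assign_clusters,
    classify_hour,
    daily_mobility,
    displacement_filter,
    dwell_intervals,
    haversine_m,
    locations_per_hour,
    normalized_entropy,
)

MERIDIAN_M_PER_DEG = math.pi / 180.0 * EARTH_RADIUS_M  # closed-form arc length


def _meridian_points(step_m, n, lat0=10.0, lon=5.0):
    lats = lat0 + np.arange(n) * step_m / MERIDIAN_M_PER_DEG
    return lats, np.full(n, lon)


# ---------------------------------------------------------------------------
# haversine


def test_haversine_zero_for_identical_points():
    assert haversine_m((44.6, -63.5), (44.6, -63.5)) == 0.0


def test_haversine_matches_meridian_arc_closed_form():
    d = haversine_m((0.0, 0.0), (0.0, 1.0))
    assert abs(d - MERIDIAN_M_PER_DEG) < 0.1
    d2 = haversine_m((10.0, 5.0), (11.0, 5.0))
    assert abs(d2 - MERIDIAN_M_PER_DEG) < 0.1


def test_haversine_symmetric_on_random_pairs():
    rng = np.random.default_rng(42)
    for _ in range(100):
        a = (rng.uniform(-90, 90), rng.uniform(-180, 180))
        b = (rng.uniform(-90, 90), rng.uniform(-180, 180))
        assert haversine_m(a, b) == pytest.approx(haversine_m(b, a), abs=1e-9)
        assert haversine_m(a, b) >= 0


def test_haversine_rejects_out_of_bounds():
    with pytest.raises(ValueError):
        haversine_m((95.0, 0.0), (0.0, 0.0))


# ---------------------------------------------------------------------------
# displacement filter


def _brute_force_filter(lat, lon, thr):
    """Independent sequential-scan oracle."""
    if len(lat) == 0:
        return []
    kept = [0]
    for i in range(1, len(lat)):
        j = kept[-1]
        if haversine_m((lat[j], lon[j]), (lat[i], lon[i])) > thr:
            kept.append(i)
    return kept


def test_stationary_trace_keeps_only_first_fix():
    # all fixes within a 5 m disc around one spot
    rng = np.random.default_rng(1)
    lat = 44.6 + rng.uniform(-2.5, 2.5, 10) / MERIDIAN_M_PER_DEG
    lon = np.full(10, -63.5)
    assert list(displacement_filter(lat, lon, 20.0)) == [0]


def test_spacing_at_threshold_not_kept_strictly_greater_rule():
    # oscillate between two spots exactly 20 m apart (to float precision,
    # fractionally under): the strictly-greater rule never triggers
    step = 20.0 * (1 - 1e-9) / MERIDIAN_M_PER_DEG
    lat = np.array([10.0 + step * (i % 2) for i in range(10)])
    lon = np.full(10, 5.0)
    assert haversine_m((lat[0], lon[0]), (lat[1], lon[1])) <= 20.0
    assert list(displacement_filter(lat, lon, 20.0)) == [0]
    # fractionally above 20 m: every move is kept
    step = 20.001 / MERIDIAN_M_PER_DEG
    lat = np.array([10.0 + step * (i % 2) for i in range(10)])
    assert list(displacement_filter(lat, lon, 20.0)) == list(range(10))


def test_wider_spacing_keeps_all():
    lat, lon = _meridian_points(25.0, 8)
    assert list(displacement_filter(lat, lon, 20.0)) == list(range(8))


def test_filter_matches_brute_force_oracle():
    rng = np.random.default_rng(3)
    lat = 44.6 + np.cumsum(rng.normal(0, 15, 200)) / MERIDIAN_M_PER_DEG
    lon = np.full(200, -63.5)
    assert list(displacement_filter(lat, lon, 20.0)) == _brute_force_filter(lat, lon, 20.0)


def test_empty_trace_returns_empty():
    assert len(displacement_filter(np.empty(0), np.empty(0))) == 0


# ---------------------------------------------------------------------------
# clustering


def test_points_within_10m_form_single_cluster():
    lat, lon = _meridian_points(10.0, 6)
    labels, clusters = assign_clusters(lat, lon)
    assert len(clusters) == 1 and (labels == 0).all()


def test_two_groups_1km_apart_equal_dwell_give_half_half():
    lat1, lon1 = _meridian_points(10.0, 3, lat0=44.0)
    lat2, lon2 = _meridian_points(10.0, 3, lat0=44.0 + 1000.0 / MERIDIAN_M_PER_DEG)
    lat = np.concatenate([lat1, lat2])
    lon = np.concatenate([lon1, lon2])
    sec = np.array([0.0, 600.0, 1200.0, 1800.0, 2400.0, 3000.0])
    labels, clusters = assign_clusters(lat, lon)
    starts, ends, labels = dwell_intervals(sec, labels, day_end_s=3600.0)
    dwell = np.bincount(labels, weights=ends - starts)
    p = dwell / dwell.sum()
    assert len(clusters) == 2
    assert p == pytest.approx([0.5, 0.5])


def test_cluster_count_invariant_to_duplicates_at_centroid():
    lat, lon = _meridian_points(10.0, 4)
    _, clusters = assign_clusters(lat, lon)
    lat2 = np.append(lat, [clusters[0].lat] * 3)
    lon2 = np.append(lon, [clusters[0].lon] * 3)
    _, clusters2 = assign_clusters(lat2, lon2)
    assert len(clusters2) == len(clusters)


def test_members_within_twice_radius_of_final_centroid():
    """Running-mean centroids can drift; membership must stay within 2x."""
    rng = np.random.default_rng(9)
    lat = 44.6 + np.cumsum(rng.normal(0, 60, 300)) / MERIDIAN_M_PER_DEG
    lon = -63.5 + np.cumsum(rng.normal(0, 60, 300)) / (
        MERIDIAN_M_PER_DEG * math.cos(math.radians(44.6)))
    labels, clusters = assign_clusters(lat, lon, radius_m=150.0)
    for i, lab in enumerate(labels):
        c = clusters[lab]
        assert haversine_m((c.lat, c.lon), (lat[i], lon[i])) <= 2 * 150.0


# ---------------------------------------------------------------------------
# normalized entropy


def test_entropy_single_cluster_is_zero():
    assert normalized_entropy([1.0]) == 0.0


@pytest.mark.parametrize("n", [2, 3, 5, 10, 50])
def test_entropy_uniform_is_one_for_any_cluster_count(n):
    assert normalized_entropy(np.full(n, 1.0 / n)) == pytest.approx(1.0, abs=1e-12)


def test_entropy_three_quarters_split():
    assert normalized_entropy([0.75, 0.25]) == pytest.approx(0.8113, abs=1e-4)


def test_entropy_invariant_to_permutation_and_log_base():
    p = np.array([0.5, 0.3, 0.15, 0.05])
    assert normalized_entropy(p) == pytest.approx(normalized_entropy(p[::-1]))
    # base cancels in the normalized ratio
    base2 = -np.sum(p * np.log2(p)) / np.log2(len(p))
    assert normalized_entropy(p) == pytest.approx(base2, abs=1e-12)


def test_entropy_zero_share_clusters_use_zero_log_zero_convention():
    assert normalized_entropy([0.5, 0.5, 0.0]) == pytest.approx(
        -(0.5 * math.log(0.5) * 2) / math.log(3))


def test_entropy_rejects_bad_inputs():
    with pytest.raises(ValueError):
        normalized_entropy([0.5, 0.4])
    with pytest.raises(ValueError):
        normalized_entropy([1.5, -0.5])


@settings(deadline=None, max_examples=50, derandomize=True)
@given(st.lists(st.floats(min_value=1e-6, max_value=1.0), min_size=1, max_size=12))
def test_entropy_bounded_on_arbitrary_distributions(weights):
    p = np.asarray(weights) / np.sum(weights)
    h = normalized_entropy(p, tol=1e-6)
    assert 0.0 <= h <= 1.0


def test_adding_cluster_to_uniform_cannot_decrease_raw_entropy():
    p4 = np.full(4, 0.25)
    raw4 = -np.sum(p4 * np.log(p4))
    p5 = np.array([0.2, 0.2, 0.2, 0.2, 0.2])
    raw5 = -np.sum(p5 * np.log(p5))
    assert raw5 >= raw4
    assert normalized_entropy(p5) == pytest.approx(1.0)


# ---------------------------------------------------------------------------
# hourly classification


def test_locations_per_hour_interval_accounting():
    # 30 min at A, 25 min at B, 5 min at C within one hour: all >= 2 min
    starts = np.array([0.0, 1800.0, 3300.0])
    ends = np.array([1800.0, 3300.0, 3600.0])
    labels = np.array([0, 1, 2])
    count, cover = locations_per_hour(starts, ends, labels, 0.0, 3600.0)
    assert count == 3 and cover == 3600.0
    # a 90 s visit falls below the 2-minute rule
    starts = np.array([0.0, 1000.0, 1090.0])
    ends = np.array([1000.0, 1090.0, 3600.0])
    labels = np.array([0, 1, 0])
    count, _ = locations_per_hour(starts, ends, labels, 0.0, 3600.0)
    assert count == 1


def test_visit_straddling_boundary_clipped_out_of_both_hours():
    # 60 s before and 60 s after the hour boundary at cluster 1
    starts = np.array([0.0, 3540.0, 3660.0])
    ends = np.array([3540.0, 3660.0, 7200.0])
    labels = np.array([0, 1, 2])
    c1, _ = locations_per_hour(starts, ends, labels, 0.0, 3600.0)
    c2, _ = locations_per_hour(starts, ends, labels, 3600.0, 7200.0)
    assert c1 == 1 and c2 == 1  # cluster 1 excluded from both


def test_hourly_counts_match_per_hour_operation():
    rng = np.random.default_rng(5)
    bounds = np.sort(rng.uniform(0, 86400, 40))
    starts = np.concatenate([[0.0], bounds])
    ends = np.concatenate([bounds, [86400.0]])
    labels = rng.integers(0, 5, len(starts))
    vec = mobility._hourly_location_counts(starts, ends, labels, 5, 120.0)
    for h in range(24):
        c, _ = locations_per_hour(starts, ends, labels, h * 3600.0, (h + 1) * 3600.0)
        assert vec[h] == c


@pytest.mark.parametrize("count,state", [
    (0, "no_data"), (1, "stationary"), (5, "moving"), (9, "moving"),
    (10, "transportation"), (12, "transportation"),
])
def test_hour_classification_partition(count, state):
    assert classify_hour(count) == state


# ---------------------------------------------------------------------------
# daily summary


def test_single_fix_day_is_fully_sedentary():
    dm = daily_mobility(np.array([0.0]), np.array([44.6]), np.array([-63.5]))
    assert dm.distance_km == 0.0
    assert dm.entropy_norm == 0.0
    assert dm.time_sedentary_h == dm.hours_observed == 24


def test_two_fixes_3km_apart_distance():
    sec = np.array([0.0, 43200.0])
    lat = np.array([44.6, 44.6 + 3000.0 / MERIDIAN_M_PER_DEG])
    lon = np.array([-63.5, -63.5])
    dm = daily_mobility(sec, lat, lon)
    assert dm.distance_km == pytest.approx(3.0, abs=1e-6)


def test_empty_day_raises_for_missing_row_handling():
    with pytest.raises(ValueError):
        daily_mobility(np.empty(0), np.empty(0), np.empty(0))


def test_hour_budget_conservation_on_simulated_days(small_cohort):
    from mobilesense.pipeline import features_from_cohort
    daily, _ = features_from_cohort(small_cohort)
    ok = daily["time_sedentary_h"].notna()
    assert ((daily.loc[ok, "time_sedentary_h"] + daily.loc[ok, "time_moving_h"])
            <= daily.loc[ok, "hours_observed"]).all()
    assert daily.loc[ok, "entropy_norm"].between(0, 1).all()
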