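"""GPS mobility features: displacement filtering, location clustering,
normalized entropy, and the stationary/moving/transportation hour budget.

The phone logs a fix only when displacement from the previously kept fix
exceeds ~20 m, so absence of fixes means absence of movement.  Dwell time is
therefore attributed to the *earlier* fix's location cluster, and the last
fix of a local day carries forward to local midnight.

Location clusters are formed by a greedy first-fit sweep with a 150 m radius
and running-mean centroids.  The time-share vector ``p`` over clusters feeds
the normalized location entropy

    H_norm = -(sum_i p_i ln p_i) / ln N          (N >= 2; H_norm = 0 for N = 1)

which is 0 when all dwell sits in one cluster and 1 when dwell is uniform
over the N visited clusters, independent of N.

Hour classification counts clusters visited for at least 2 minutes within
the local hour: 1 -> stationary, 2-9 -> moving, >=10 -> transportation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

EARTH_RADIUS_M = 6_371_000.0
SECONDS_PER_DAY = 86_400

HOUR_STATES = ("no_data", "stationary", "moving", "transportation")

try:  # optional JIT acceleration for the per-fix loops
    from numba import njit as _njit
except ImportError:  # pragma: no cover - numba is an optional speedup
    def _njit(*args, **kwargs):
        def wrap(f):
            return f
        return wrap


def _check_bounds(lat: np.ndarray, lon: np.ndarray) -> None:
    lat = np.asarray(lat, float)
    lon = np.asarray(lon, float)
    if ((lat < -90) | (lat > 90)).any():
        raise ValueError("latitude out of bounds [-90, 90]")
    if ((lon < -180) | (lon > 180)).any():
        raise ValueError("longitude out of bounds [-180, 180]")


def haversine_m(a: tuple[float, float], b: tuple[float, float]) -> float:
    """Great-circle distance in meters between two (lat, lon) pairs."""
    _check_bounds(np.array([a[0], b[0]]), np.array([a[1], b[1]]))
    return float(haversine_arrays(np.array([a[0]]), np.array([a[1]]),
                                  np.array([b[0]]), np.array([b[1]]))[0])


def haversine_arrays(lat1, lon1, lat2, lon2) -> np.ndarray:
    """Vectorized Haversine distance (meters) on a spherical Earth."""
    lat1, lon1, lat2, lon2 = (np.radians(np.asarray(x, float)) for x in (lat1, lon1, lat2, lon2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    s = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_M * np.arcsin(np.sqrt(np.clip(s, 0.0, 1.0)))


@_njit(cache=True)
def _haversine_scalar(lat1: float, lon1: float, lat2: float, lon2: float) -> float:
    rl1 = math.radians(lat1)
    rl2 = math.radians(lat2)
    dlat = rl2 - rl1
    dlon = math.radians(lon2) - math.radians(lon1)
    s = math.sin(dlat / 2.0) ** 2 + math.cos(rl1) * math.cos(rl2) * math.sin(dlon / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_M * math.asin(math.sqrt(min(1.0, s)))


@_njit(cache=True)
def _displacement_keep(lat: np.ndarray, lon: np.ndarray, threshold_m: float) -> np.ndarray:
    n = lat.shape[0]
    keep = np.zeros(n, np.bool_)
    keep[0] = True
    ref_lat, ref_lon = lat[0], lon[0]
    for i in range(1, n):
        if _haversine_scalar(ref_lat, ref_lon, lat[i], lon[i]) > threshold_m:
            keep[i] = True
            ref_lat, ref_lon = lat[i], lon[i]
    return keep


def displacement_filter(lat: np.ndarray, lon: np.ndarray, threshold_m: float = 20.0) -> np.ndarray:
    """Indices of fixes kept by the on-device displacement rule.

    The first fix is always kept; each later fix is kept iff its Haversine
    distance from the previously *kept* fix is strictly greater than
    ``threshold_m``.  Mirrors the app's 20 m sampling trigger; also used to
    canonicalize traces before feature extraction.
    """
    lat = np.ascontiguousarray(lat, dtype=np.float64)
    lon = np.ascontiguousarray(lon, dtype=np.float64)
    n = len(lat)
    if n == 0:
        return np.empty(0, dtype=np.int64)
    _check_bounds(lat, lon)
    return np.flatnonzero(_displacement_keep(lat, lon, float(threshold_m)))


@dataclass
class LocationCluster:
    """A visited place: >=1 fixes within ``radius_m`` of a running-mean centroid."""

    index: int
    lat: float
    lon: float
    n_points: int
    dwell_s: float = 0.0
    p: float = 0.0


def assign_clusters(
    lat: np.ndarray, lon: np.ndarray, radius_m: float = 150.0
) -> tuple[np.ndarray, list[LocationCluster]]:
    """Greedy first-fit location clustering.

    Each fix, in time order, joins the first existing cluster (by creation
    order) whose centroid lies within ``radius_m``; otherwise it founds a
    new cluster.  Centroids are running means of member coordinates, so they
    can drift; membership is guaranteed within the radius of the centroid
    *at assignment time*.
    """
    lat = np.ascontiguousarray(lat, dtype=np.float64)
    lon = np.ascontiguousarray(lon, dtype=np.float64)
    labels, c_lat, c_lon, c_n, n_clusters = _greedy_cluster(lat, lon, float(radius_m))
    clusters = [
        LocationCluster(index=j, lat=float(c_lat[j]), lon=float(c_lon[j]),
                        n_points=int(c_n[j]))
        for j in range(n_clusters)
    ]
    return labels, clusters


@_njit(cache=True)
def _greedy_cluster(lat: np.ndarray, lon: np.ndarray, radius_m: float):
    n = lat.shape[0]
    labels = np.empty(n, np.int64)
    c_lat = np.empty(n)
    c_lon = np.empty(n)
    c_n = np.zeros(n, np.int64)
    m = 0
    for i in range(n):
        assigned = -1
        for j in range(m):
            if _haversine_scalar(c_lat[j], c_lon[j], lat[i], lon[i]) <= radius_m:
                assigned = j
                break
        if assigned < 0:
            c_lat[m] = lat[i]
            c_lon[m] = lon[i]
            c_n[m] = 1
            labels[i] = m
            m += 1
        else:
            k = c_n[assigned]
            c_lat[assigned] = (c_lat[assigned] * k + lat[i]) / (k + 1)
            c_lon[assigned] = (c_lon[assigned] * k + lon[i]) / (k + 1)
            c_n[assigned] = k + 1
            labels[i] = assigned
    return labels, c_lat, c_lon, c_n, m


def dwell_intervals(
    seconds: np.ndarray, labels: np.ndarray, day_end_s: float = float(SECONDS_PER_DAY)
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-fix dwell intervals ``[start, end)`` labelled by cluster.

    The interval between consecutive fixes belongs to the earlier fix's
    cluster; the final fix carries forward to ``day_end_s`` (local
    midnight), reflecting displacement-triggered sampling.
    """
    seconds = np.asarray(seconds, float)
    if len(seconds) == 0:
        return np.empty(0), np.empty(0), np.empty(0, dtype=np.int64)
    starts = seconds
    ends = np.append(seconds[1:], day_end_s)
    return starts, ends, np.asarray(labels, dtype=np.int64)


def normalized_entropy(p, tol: float = 1e-9) -> float:
    """Normalized Shannon entropy of a dwell-share vector.

    Returns 0 for a single cluster; ``-(sum p ln p)/ln N`` otherwise, with
    the convention ``0 * ln 0 = 0``.  The log base cancels in the ratio.
    """
    p = np.asarray(p, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("p must be a nonempty 1-D fraction vector")
    if (p < 0).any():
        raise ValueError("p_i must be nonnegative")
    if abs(p.sum() - 1.0) > tol:
        raise ValueError(f"fractions must sum to 1 (got {p.sum()!r})")
    n = p.size
    if n == 1:
        return 0.0
    pos = p[p > 0]
    h = -float(np.sum(pos * np.log(pos)))
    return min(1.0, max(0.0, h / math.log(n)))


def locations_per_hour(
    starts: np.ndarray,
    ends: np.ndarray,
    labels: np.ndarray,
    hour_start_s: float,
    hour_end_s: float,
    min_dwell_s: float = 120.0,
) -> tuple[int, float]:
    """Distinct clusters with >= ``min_dwell_s`` dwell inside the hour window.

    Dwell intervals are clipped to the window before summing, so a visit
    straddling the boundary only counts in an hour where its clipped part
    reaches the threshold.  Also returns total covered seconds in the hour.
    """
    clip = np.minimum(ends, hour_end_s) - np.maximum(starts, hour_start_s)
    mask = clip > 0
    if not mask.any():
        return 0, 0.0
    sums: dict[int, float] = {}
    for lab, c in zip(labels[mask], clip[mask]):
        sums[int(lab)] = sums.get(int(lab), 0.0) + float(c)
    count = sum(1 for v in sums.values() if v >= min_dwell_s)
    return count, float(sum(sums.values()))


def _hourly_location_counts(
    starts: np.ndarray,
    ends: np.ndarray,
    labels: np.ndarray,
    n_clusters: int,
    min_dwell_s: float,
) -> np.ndarray:
    """Vectorized per-hour visited-location counts for one local day.

    Equivalent to calling :func:`locations_per_hour` for each of the 24
    hour windows (asserted by test); dwell is accumulated into an
    (hour, cluster) matrix after clipping intervals to hour boundaries.
    """
    dwell = np.zeros((n_clusters, 24))
    h0 = np.arange(24) * 3600.0
    h1 = h0 + 3600.0
    clip = np.minimum(ends[:, None], h1[None, :]) - np.maximum(starts[:, None], h0[None, :])
    np.clip(clip, 0.0, None, out=clip)
    np.add.at(dwell, labels, clip)
    return (dwell >= min_dwell_s).sum(axis=0)


def classify_hour(locations_visited: int) -> str:
    """Map an hourly visited-location count to a mobility state."""
    if locations_visited < 0:
        raise ValueError("count must be >= 0")
    if locations_visited == 0:
        return "no_data"
    if locations_visited == 1:
        return "stationary"
    if locations_visited <= 9:
        return "moving"
    return "transportation"


@dataclass
class DayMobility:
    """Daily GPS summary: the four mobility predictors plus coverage."""

    distance_km: float
    entropy_norm: float
    time_sedentary_h: float
    time_moving_h: float
    hours_observed: int
    n_clusters: int


def daily_mobility(
    seconds: np.ndarray,
    lat: np.ndarray,
    lon: np.ndarray,
    *,
    displacement_m: float = 20.0,
    cluster_radius_m: float = 150.0,
    min_dwell_s: float = 120.0,
    apply_filter: bool = True,
) -> DayMobility:
    """Mobility summary for one local day.

    ``seconds`` are seconds since local midnight (``[0, 86400)``), time
    ordered.  Distance sums Haversine steps between retained
    (displacement-filtered) fixes; entropy comes from the day's cluster
    dwell shares; sedentary/moving hours from the hourly classification.
    Raises ``ValueError`` on an empty day (callers emit a missing row).
    """
    seconds = np.asarray(seconds, float)
    lat = np.asarray(lat, float)
    lon = np.asarray(lon, float)
    if len(seconds) == 0:
        raise ValueError("day has no GPS fixes; emit a missing row instead")
    if apply_filter:
        keep = displacement_filter(lat, lon, displacement_m)
        seconds, lat, lon = seconds[keep], lat[keep], lon[keep]
    labels, clusters = assign_clusters(lat, lon, cluster_radius_m)
    distance_km = (
        float(haversine_arrays(lat[:-1], lon[:-1], lat[1:], lon[1:]).sum()) / 1000.0
        if len(lat) > 1 else 0.0
    )
    starts, ends, labels = dwell_intervals(seconds, labels)
    dwell = np.bincount(labels, weights=ends - starts, minlength=len(clusters))
    total = float(dwell.sum())
    for c in clusters:
        c.dwell_s = float(dwell[c.index])
    if total > 0:
        p = dwell / total
        for c in clusters:
            c.p = float(p[c.index])
        entropy = normalized_entropy(p)
    else:
        entropy = 0.0
    counts = _hourly_location_counts(starts, ends, labels, len(clusters), min_dwell_s)
    sed = int(np.sum(counts == 1))
    mov = int(np.sum(counts >= 2))
    observed = int(np.sum(counts >= 1))
    return DayMobility(
        distance_km=distance_km,
        entropy_norm=entropy,
        time_sedentary_h=float(sed),
        time_moving_h=float(mov),
        hours_observed=observed,
        n_clusters=len(clusters),
    )
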