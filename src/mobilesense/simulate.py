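"""Synthetic 14-day sensor cohorts with planted symptom-behavior couplings.

The generator emulates the study conditions end to end: an enrollment of
~161 youths with the printed demographic mix and retention probabilities,
correlated latent anxiety/depression (plus independent ADHD) scores, and
four per-participant event streams whose generating rates are log-linearly
coupled to the latents:

* trip rate (hence distance and moving time) increases with anxiety and
  decreases with depression — so sedentary time does the opposite;
* outgoing-call rate decreases with depression;
* screen-session duration increases with anxiety;
* nighttime light-event rate increases with depression.

Couplings default to 0.3 on the log-rate scale; independent per-participant
frailties keep realized between-person correlations in the r ~ 0.2-0.4
band.  Dwell-length and evening-visit heterogeneity is deliberately
independent of the latents so that location entropy stays close to null.

Everything is fully determined by ``(seed, config)``; RNG streams are split
per participant and per day, so increasing ``n_participants`` never
perturbs earlier participants' data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from numpy.random import SeedSequence, default_rng

from . import sensor_io
from .sensor_io import ParticipantMeta, SECONDS_PER_DAY
from .mobility import displacement_filter

M_PER_DEG_LAT = math.pi / 180.0 * 6_371_000.0

MONTHS = ("2020-02", "2020-03", "2020-04", "2020-05", "2020-06", "2020-07")

# Pre-clipping shift that makes E[clip(N(18 + shift, 2.76), 10, 21)] = 18.
_AGE_CLIP_SHIFT = 0.2241


@dataclass
class SimulationConfig:
    """All knobs of the synthetic cohort, with study-condition defaults."""

    n_participants: int = 161
    days: int = 14
    seed: int = 0
    timezone: str = "-04:00"

    # latent symptom structure
    anx_dep_corr: float = 0.5

    # planted couplings (standardized, log-linear on the relevant rate)
    coupling_mobility_anx: float = 0.3
    coupling_mobility_dep: float = -0.3
    coupling_outgoing_dep: float = -0.3
    coupling_screen_anx: float = 0.3
    coupling_night_light_dep: float = 0.3

    # independent between-person heterogeneity (log-scale SD)
    frailty_sd: float = 0.5
    dwell_frailty_sd: float = 0.5

    # mobility base rates
    home_lat: float = 44.65
    home_lon: float = -63.58
    n_anchors: int = 3
    anchor_km_min: float = 0.8
    anchor_km_max: float = 2.5
    base_trips_per_day: float = 2.0
    max_trips_per_day: int = 4
    trip_speed_mps: float = 8.0
    waypoint_spacing_m: float = 150.0
    dest_dwell_h_median: float = 1.2
    dest_dwell_sigma: float = 0.5

    # evening social visits (independent of latents; entropy/distance noise)
    visit_prob_beta: tuple[float, float] = (2.0, 2.0)
    visit_prob_scale: float = 0.7

    # calls
    call_in_rate: float = 1.81
    call_out_rate: float = 2.11
    call_missed_rate: float = 0.5
    call_dur_median_min: float = 3.0
    call_dur_sigma: float = 1.0
    n_contacts: int = 20

    # screen
    screen_sessions_per_day: float = 54.0
    screen_session_median_min: float = 2.8
    screen_session_sigma: float = 1.0

    # ambient light
    day_light_median_lux: float = 150.0
    day_light_sigma: float = 0.8
    night_dark_median_lux: float = 3.0
    night_dark_sigma: float = 0.5
    night_event_rate: float = 2.0
    night_event_median_lux: float = 200.0
    night_event_sigma: float = 0.8
    night_event_duration_s: float = 300.0

    # surveys (instrument calibration targets)
    scared_mean: float = 33.02
    scared_sd: float = 14.79
    cesdc_mean: float = 32.59
    cesdc_sd: float = 15.23
    asrs_mean: float = 31.0
    asrs_sd: float = 12.0
    survey_loading: float = 0.85

    # demographics / retention (printed study proportions)
    age_mean: float = 18.0
    age_sd: float = 2.76
    p_female: float = 96 / 122
    p_ios: float = 96 / 122
    maternal_education_probs: tuple[float, ...] = (
        5 / 122, 18 / 122, 29 / 122, 66 / 122, 4 / 122
    )
    p_comorbid_depression: float = 30 / 122
    p_comorbid_gad: float = 39 / 122
    p_comorbid_social_phobia: float = 12 / 122
    p_withdraw: float = 11 / 161
    p_short_data: float = 25 / 161
    p_missing_sensor: float = 3 / 161

    inject_malformations: bool = False

    def validate(self) -> "SimulationConfig":
        if self.p_withdraw + self.p_short_data + self.p_missing_sensor > 1:
            raise ValueError("retention probabilities sum above 1")
        if abs(sum(self.maternal_education_probs) - 1) > 1e-9:
            raise ValueError("maternal education probabilities must sum to 1")
        if not -1 < self.anx_dep_corr < 1:
            raise ValueError("anx_dep_corr must be in (-1, 1)")
        return self


@dataclass
class LatentProfile:
    participant_id: str
    anxiety: float
    depression: float
    adhd: float


@dataclass
class SimulatedParticipant:
    """One participant's generated data, on the local-seconds timeline."""

    meta: ParticipantMeta
    latent: LatentProfile
    withdrew: bool
    days_provided: int
    has_required_sensors: bool
    day0: int  # local epoch-day index of study start
    gps_sec: np.ndarray = field(default_factory=lambda: np.empty(0))
    gps_lat: np.ndarray = field(default_factory=lambda: np.empty(0))
    gps_lon: np.ndarray = field(default_factory=lambda: np.empty(0))
    call_sec: np.ndarray = field(default_factory=lambda: np.empty(0))
    call_dir: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=object))
    call_dur: np.ndarray = field(default_factory=lambda: np.empty(0))
    call_contact: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=object))
    screen_sec: np.ndarray = field(default_factory=lambda: np.empty(0))
    screen_state: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=object))
    light_sec: np.ndarray = field(default_factory=lambda: np.empty(0))
    light_lux: np.ndarray = field(default_factory=lambda: np.empty(0))
    survey_items: dict[str, np.ndarray] = field(default_factory=dict)

    def stream_frames(self) -> dict[str, pd.DataFrame]:
        """Schema-conforming DataFrames (UTC timestamps) for the four streams."""
        tz = self.meta.timezone
        gps = pd.DataFrame({
            "timestamp": sensor_io.utc_from_local_seconds(self.gps_sec, tz),
            "lat": self.gps_lat, "lon": self.gps_lon,
        })
        calls = pd.DataFrame({
            "timestamp": sensor_io.utc_from_local_seconds(self.call_sec, tz),
            "direction": self.call_dir, "duration_s": self.call_dur,
            "contact_id": self.call_contact,
        })
        screen = pd.DataFrame({
            "timestamp": sensor_io.utc_from_local_seconds(self.screen_sec, tz),
            "state": self.screen_state,
        })
        light = pd.DataFrame({
            "timestamp": sensor_io.utc_from_local_seconds(self.light_sec, tz),
            "lux": self.light_lux,
        })
        return {"gps": gps, "calls": calls, "screen": screen, "light": light}


@dataclass
class CohortData:
    config: SimulationConfig
    participants: list[SimulatedParticipant]

    @property
    def ledger(self) -> pd.DataFrame:
        rows = [{
            "participant_id": p.meta.participant_id,
            "enrolled": True,
            "withdrew": p.withdrew,
            "days_provided": p.days_provided,
            "has_required_sensors": p.has_required_sensors,
        } for p in self.participants]
        return pd.DataFrame(rows)

    @property
    def truth(self) -> pd.DataFrame:
        rows = [{
            "participant_id": p.meta.participant_id,
            "latent_anxiety": p.latent.anxiety,
            "latent_depression": p.latent.depression,
            "latent_adhd": p.latent.adhd,
        } for p in self.participants]
        return pd.DataFrame(rows)

    @property
    def surveys(self) -> pd.DataFrame:
        max_items = 33
        rows = []
        for p in self.participants:
            for inst, items in p.survey_items.items():
                row: dict[str, object] = {
                    "participant_id": p.meta.participant_id, "instrument": inst
                }
                for j in range(max_items):
                    row[f"item_{j + 1}"] = int(items[j]) if j < len(items) else ""
                rows.append(row)
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# geometry helpers


def _offset_deg(lat: float, east_m: float, north_m: float) -> tuple[float, float]:
    dlat = north_m / M_PER_DEG_LAT
    dlon = east_m / (M_PER_DEG_LAT * math.cos(math.radians(lat)))
    return dlat, dlon


def _leg_waypoints(lat_a, lon_a, lat_b, lon_b, t_start, speed_mps, spacing_m):
    """Waypoints from A (exclusive) to B (inclusive), evenly spaced in time."""
    # planar approximation is fine at few-km city scale for *generating* paths
    dist = math.hypot((lat_b - lat_a) * M_PER_DEG_LAT,
                      (lon_b - lon_a) * M_PER_DEG_LAT * math.cos(math.radians(lat_a)))
    n = max(1, int(math.ceil(dist / spacing_m)))
    f = np.arange(1, n + 1) / n
    dur = dist / speed_mps
    return (t_start + f * dur,
            lat_a + f * (lat_b - lat_a),
            lon_a + f * (lon_b - lon_a),
            t_start + dur)


# ---------------------------------------------------------------------------
# per-day stream generators


def simulate_gps_day(
    cfg: SimulationConfig,
    rng: np.random.Generator,
    day_start_s: float,
    home: tuple[float, float],
    anchors: np.ndarray,
    visit_anchor: tuple[float, float],
    trip_rate: float,
    visit_prob: float,
    dwell_median_h: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """One local day of displacement-triggered GPS fixes.

    The trajectory is anchor-based: dwell at home, ``n_trips`` round trips
    to secondary anchors with waypoints every ~150 m, and (with probability
    ``visit_prob``) an evening visit to a fixed social anchor.  The raw
    trace is passed through the 20 m displacement filter to emulate the
    on-device sampling rule.
    """
    times = [day_start_s]
    lats = [home[0]]
    lons = [home[1]]
    n_trips = min(int(rng.poisson(trip_rate)), cfg.max_trips_per_day)
    starts = np.sort(rng.uniform(9.0, 20.0, size=n_trips)) * 3600.0 + day_start_s
    plans = [(s, tuple(anchors[rng.integers(0, len(anchors))]),
              float(np.clip(rng.lognormal(math.log(dwell_median_h), cfg.dest_dwell_sigma),
                            0.4, 3.0)) * 3600.0)
             for s in starts]
    if rng.uniform() < visit_prob:
        v_start = day_start_s + float(np.clip(rng.normal(18.5, 0.5), 17.5, 20.0)) * 3600.0
        v_dwell = float(np.clip(rng.normal(3.0, 1.0), 1.0, 4.0)) * 3600.0
        plans.append((v_start, visit_anchor, v_dwell))
    plans.sort(key=lambda p: p[0])
    cursor = day_start_s + 60.0
    day_end = day_start_s + SECONDS_PER_DAY - 600.0
    for start, anchor, dwell_s in plans:
        start = max(start, cursor + 120.0)
        t, la, lo, t_arr = _leg_waypoints(home[0], home[1], anchor[0], anchor[1],
                                          start, cfg.trip_speed_mps, cfg.waypoint_spacing_m)
        leave = t_arr + dwell_s
        t2, la2, lo2, t_home = _leg_waypoints(anchor[0], anchor[1], home[0], home[1],
                                              leave, cfg.trip_speed_mps, cfg.waypoint_spacing_m)
        if t_home > day_end:
            continue
        times.extend(t.tolist()); lats.extend(la.tolist()); lons.extend(lo.tolist())
        times.extend(t2.tolist()); lats.extend(la2.tolist()); lons.extend(lo2.tolist())
        cursor = t_home
    sec = np.asarray(times)
    lat = np.asarray(lats)
    lon = np.asarray(lons)
    keep = displacement_filter(lat, lon, 20.0)
    return sec[keep], lat[keep], lon[keep]


def simulate_calls_day(cfg, rng, day_start_s, out_rate, in_rate):
    n_out = int(rng.poisson(out_rate))
    n_in = int(rng.poisson(in_rate))
    n_miss = int(rng.poisson(cfg.call_missed_rate))
    n = n_out + n_in + n_miss
    if n == 0:
        return (np.empty(0), np.empty(0, object), np.empty(0), np.empty(0, object))
    sec = day_start_s + np.sort(rng.uniform(8.0 * 3600, 22.5 * 3600, size=n))
    dirs = np.array(["outgoing"] * n_out + ["incoming"] * n_in + ["missed"] * n_miss,
                    dtype=object)
    rng.shuffle(dirs)
    dur = np.round(rng.lognormal(math.log(cfg.call_dur_median_min * 60.0),
                                 cfg.call_dur_sigma, size=n))
    dur = np.maximum(dur, 1.0)
    dur[dirs == "missed"] = 0.0
    contacts = np.array([f"c{rng.integers(0, cfg.n_contacts):02d}" for _ in range(n)],
                        dtype=object)
    return sec, dirs, dur, contacts


def simulate_screen_day(cfg, rng, day_start_s, duration_scale):
    n = int(rng.poisson(cfg.screen_sessions_per_day))
    if n == 0:
        return np.empty(0), np.empty(0, object)
    starts = np.sort(rng.uniform(7.0 * 3600, 23.8 * 3600, size=n)) + day_start_s
    # keep starts at least 3 s apart so clipped sessions stay ordered
    keep = np.concatenate(([True], np.diff(starts) >= 3.0))
    starts = starts[keep]
    n = len(starts)
    durs = rng.lognormal(math.log(cfg.screen_session_median_min * 60.0 * duration_scale),
                         cfg.screen_session_sigma, size=n)
    ends = starts + durs
    # sessions must not overlap: clip each end to just before the next start
    ends[:-1] = np.minimum(ends[:-1], starts[1:] - 1.0)
    ends[-1] = min(ends[-1], day_start_s + SECONDS_PER_DAY - 1.0)
    ends = np.maximum(ends, starts + 1.0)
    sec = np.empty(2 * n)
    sec[0::2] = starts
    sec[1::2] = ends
    states = np.empty(2 * n, dtype=object)
    states[0::2] = "on"
    states[1::2] = "off"
    return sec, states


def simulate_light_day(cfg, rng, day_start_s, night_event_rate):
    sec: list[float] = []
    lux: list[float] = []
    for h in np.arange(7.5, 23.0, 2.0):
        sec.append(day_start_s + h * 3600.0 + rng.uniform(0, 600))
        lux.append(float(rng.lognormal(math.log(cfg.day_light_median_lux),
                                       cfg.day_light_sigma)))
    bedtime = day_start_s + (23.0 + abs(rng.normal(0.4, 0.3))) * 3600.0
    dark = float(rng.lognormal(math.log(cfg.night_dark_median_lux), cfg.night_dark_sigma))
    sec.append(bedtime)
    lux.append(dark)
    night_end = day_start_s + 31.0 * 3600.0  # 7 AM next day
    n_ev = int(rng.poisson(night_event_rate))
    for t in np.sort(rng.uniform(bedtime + 600, night_end - 600, size=n_ev)):
        sec.append(float(t))
        lux.append(float(rng.lognormal(math.log(cfg.night_event_median_lux),
                                       cfg.night_event_sigma)))
        sec.append(float(t) + cfg.night_event_duration_s)
        lux.append(dark)
    return np.asarray(sec), np.asarray(lux)


def simulate_surveys(cfg, rng, latent: LatentProfile) -> dict[str, np.ndarray]:
    """Item responses whose totals regress on the latent scores.

    A continuous target total is drawn around the instrument calibration
    mean/SD with loading ``survey_loading`` on the relevant latent, then
    decomposed into items by binomial thinning, which preserves the target
    in expectation while adding item-level noise.
    """
    lam = cfg.survey_loading
    resid = math.sqrt(1.0 - lam**2)
    out: dict[str, np.ndarray] = {}
    specs = [
        ("SCARED33", cfg.scared_mean, cfg.scared_sd, latent.anxiety, 33, 2),
        ("CESDC", cfg.cesdc_mean, cfg.cesdc_sd, latent.depression, 20, 3),
        ("ASRS", cfg.asrs_mean, cfg.asrs_sd, latent.adhd, 18, 4),
    ]
    for name, mean, sd, z, k, item_max in specs:
        target = mean + sd * (lam * z + resid * rng.normal())
        target = float(np.clip(target, 0.5, k * item_max - 0.5))
        q = target / (k * item_max)
        scored = rng.binomial(item_max, q, size=k)
        if name == "CESDC":
            raw = scored.copy()
            from .surveys import CESDC_REVERSE_ITEMS
            for i in CESDC_REVERSE_ITEMS:
                raw[i - 1] = item_max - scored[i - 1]
            out[name] = raw
        else:
            out[name] = scored
    return out


# ---------------------------------------------------------------------------
# cohort assembly


def _month_start_day(month: str) -> int:
    return int(pd.Timestamp(month + "-01").timestamp() // SECONDS_PER_DAY)


def simulate_participant(
    cfg: SimulationConfig, index: int, streams: bool = True
) -> SimulatedParticipant:
    """Generate one participant; ``streams=False`` skips the event streams
    (profiles, surveys and retention only — used for large-n calibration)."""
    rng = default_rng(SeedSequence((cfg.seed, index, 0)))
    pid = f"p{index:04d}"

    # demographics from the printed study proportions; the sampling mean is
    # shifted so the *post-clipping* mean hits the target (clipping to the
    # eligibility range [10, 21] censors the upper tail)
    age_mu = cfg.age_mean + _AGE_CLIP_SHIFT if (cfg.age_mean, cfg.age_sd) == (18.0, 2.76) else cfg.age_mean
    age = float(np.clip(rng.normal(age_mu, cfg.age_sd), 10.0, 21.0))
    sex = "female" if rng.uniform() < cfg.p_female else "male"
    os_ = "ios" if rng.uniform() < cfg.p_ios else "android"
    med = sensor_io.MATERNAL_EDUCATION_LEVELS[
        int(rng.choice(5, p=np.asarray(cfg.maternal_education_probs)))
    ]
    month = MONTHS[int(rng.integers(0, len(MONTHS)))]
    meta = ParticipantMeta(
        participant_id=pid, age=age, sex=sex, maternal_education=med, os=os_,
        assessment_month=month, timezone=cfg.timezone,
        comorbid_depression=bool(rng.uniform() < cfg.p_comorbid_depression),
        comorbid_gad=bool(rng.uniform() < cfg.p_comorbid_gad),
        comorbid_social_phobia=bool(rng.uniform() < cfg.p_comorbid_social_phobia),
    )

    # latent symptom profile: bivariate anxiety/depression + independent ADHD
    rho = cfg.anx_dep_corr
    z1, z2, z3 = rng.normal(size=3)
    latent = LatentProfile(
        participant_id=pid,
        anxiety=z1,
        depression=rho * z1 + math.sqrt(1 - rho**2) * z2,
        adhd=z3,
    )

    # retention category (mutually exclusive, printed probabilities)
    u = rng.uniform()
    withdrew = False
    has_sensors = True
    if u < cfg.p_withdraw:
        withdrew = True
        days_provided = int(rng.integers(0, 7))
    elif u < cfg.p_withdraw + cfg.p_short_data:
        days_provided = int(rng.integers(1, cfg.days))
    elif u < cfg.p_withdraw + cfg.p_short_data + cfg.p_missing_sensor:
        has_sensors = False
        days_provided = cfg.days
    else:
        days_provided = cfg.days

    day0 = _month_start_day(month) + int(rng.integers(0, 14))

    # participant geography
    home_lat = cfg.home_lat + rng.uniform(-0.05, 0.05)
    home_lon = cfg.home_lon + rng.uniform(-0.05, 0.05)
    anchors = []
    for _ in range(cfg.n_anchors):
        d_m = rng.uniform(cfg.anchor_km_min, cfg.anchor_km_max) * 1000.0
        brg = rng.uniform(0, 2 * math.pi)
        dlat, dlon = _offset_deg(home_lat, d_m * math.sin(brg), d_m * math.cos(brg))
        anchors.append((home_lat + dlat, home_lon + dlon))
    anchors = np.asarray(anchors)
    d_m = rng.uniform(1000.0, 2500.0)
    brg = rng.uniform(0, 2 * math.pi)
    dlat, dlon = _offset_deg(home_lat, d_m * math.sin(brg), d_m * math.cos(brg))
    visit_anchor = (home_lat + dlat, home_lon + dlon)

    # independent frailties + planted couplings -> per-participant rates
    s = cfg.frailty_sd
    trip_rate = cfg.base_trips_per_day * math.exp(
        cfg.coupling_mobility_anx * latent.anxiety
        + cfg.coupling_mobility_dep * latent.depression
        + rng.normal(0, s)
    )
    out_rate = cfg.call_out_rate * math.exp(
        cfg.coupling_outgoing_dep * latent.depression + rng.normal(0, s)
    )
    in_rate = cfg.call_in_rate * math.exp(rng.normal(0, s))
    screen_scale = math.exp(cfg.coupling_screen_anx * latent.anxiety + rng.normal(0, s))
    light_rate = cfg.night_event_rate * math.exp(
        cfg.coupling_night_light_dep * latent.depression + rng.normal(0, s)
    )
    dwell_median_h = cfg.dest_dwell_h_median * math.exp(rng.normal(0, cfg.dwell_frailty_sd))
    visit_prob = float(rng.beta(*cfg.visit_prob_beta)) * cfg.visit_prob_scale

    p = SimulatedParticipant(
        meta=meta, latent=latent, withdrew=withdrew, days_provided=days_provided,
        has_required_sensors=has_sensors, day0=day0,
    )
    p.survey_items = simulate_surveys(cfg, rng, latent)
    if not streams or not has_sensors or days_provided == 0:
        return p

    gps_parts, call_parts, screen_parts, light_parts = [], [], [], []
    for d in range(days_provided):
        drng = default_rng(SeedSequence((cfg.seed, index, d + 1)))
        day_start = (day0 + d) * float(SECONDS_PER_DAY)
        gps_parts.append(simulate_gps_day(
            cfg, drng, day_start, (home_lat, home_lon), anchors, visit_anchor,
            trip_rate, visit_prob, dwell_median_h,
        ))
        call_parts.append(simulate_calls_day(cfg, drng, day_start, out_rate, in_rate))
        screen_parts.append(simulate_screen_day(cfg, drng, day_start, screen_scale))
        light_parts.append(simulate_light_day(cfg, drng, day_start, light_rate))

    p.gps_sec = np.concatenate([g[0] for g in gps_parts])
    p.gps_lat = np.concatenate([g[1] for g in gps_parts])
    p.gps_lon = np.concatenate([g[2] for g in gps_parts])
    p.call_sec = np.concatenate([c[0] for c in call_parts])
    p.call_dir = np.concatenate([c[1] for c in call_parts])
    p.call_dur = np.concatenate([c[2] for c in call_parts])
    p.call_contact = np.concatenate([c[3] for c in call_parts])
    p.screen_sec = np.concatenate([s_[0] for s_ in screen_parts])
    p.screen_state = np.concatenate([s_[1] for s_ in screen_parts])
    light_sec = np.concatenate([l[0] for l in light_parts])
    light_lux = np.concatenate([l[1] for l in light_parts])
    order = np.argsort(light_sec, kind="stable")
    p.light_sec, p.light_lux = light_sec[order], light_lux[order]

    # clip every stream to the 14-day study window
    w0, w1 = day0 * SECONDS_PER_DAY, (day0 + cfg.days) * SECONDS_PER_DAY
    for pre in ("gps", "call", "screen", "light"):
        sec_attr = f"{pre}_sec"
        sec_arr = getattr(p, sec_attr)
        inside = (sec_arr >= w0) & (sec_arr < w1)
        if not inside.all():
            for name in [a for a in vars(p) if a.startswith(pre + "_")]:
                setattr(p, name, getattr(p, name)[inside])

    if cfg.inject_malformations:
        _inject_malformations(p, default_rng(SeedSequence((cfg.seed, index, 9999))))
    return p


def _inject_malformations(p: SimulatedParticipant, rng: np.random.Generator) -> None:
    """Duplicate screen-on events and strand a trailing 'on' to exercise repairs."""
    if len(p.screen_sec) >= 2:
        i = int(rng.integers(0, len(p.screen_sec) - 1))
        i -= i % 2  # duplicate an "on"
        p.screen_sec = np.insert(p.screen_sec, i + 1, p.screen_sec[i] + 0.5)
        p.screen_state = np.insert(p.screen_state, i + 1, "on")
        # drop the final "off" so the last session is unclosed
        if p.screen_state[-1] == "off":
            p.screen_sec = p.screen_sec[:-1]
            p.screen_state = p.screen_state[:-1]


def simulate_cohort(cfg: SimulationConfig) -> CohortData:
    """Generate the full synthetic cohort deterministically from the config."""
    cfg.validate()
    participants = [simulate_participant(cfg, i) for i in range(cfg.n_participants)]
    return CohortData(config=cfg, participants=participants)


# ---------------------------------------------------------------------------
# on-disk emission


def write_cohort(cohort: CohortData, outdir: Path) -> None:
    """Emit the sensor CSV schemas plus meta/ledger/surveys/truth tables."""
    outdir = Path(outdir)
    raw = outdir / "raw"
    raw.mkdir(parents=True, exist_ok=True)
    for p in cohort.participants:
        pdir = raw / p.meta.participant_id
        pdir.mkdir(parents=True, exist_ok=True)
        frames = p.stream_frames()
        for name, df in frames.items():
            if name == "gps" and not p.has_required_sensors:
                continue
            sensor_io.write_stream(df, name, pdir / f"{name}.csv")
    sensor_io.write_meta([p.meta for p in cohort.participants], outdir / "meta.csv")
    sensor_io.write_ledger(cohort.ledger, outdir / "ledger.csv")
    cohort.surveys.to_csv(outdir / "surveys.csv", index=False, lineterminator="\n")
    cohort.truth.to_csv(outdir / "truth.csv", index=False, lineterminator="\n")
    starts = pd.DataFrame({
        "participant_id": [p.meta.participant_id for p in cohort.participants],
        "study_start_day": [p.day0 for p in cohort.participants],
    })
    starts.to_csv(outdir / "study_windows.csv", index=False, lineterminator="\n")
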