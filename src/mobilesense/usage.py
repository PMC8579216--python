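"""Daily call, screen, and nighttime ambient-light features.

All functions work on the participant's local wall-clock timeline (seconds
since the local epoch; see :func:`mobilesense.sensor_io.local_seconds`), so
local midnight boundaries sit at multiples of 86 400 and the nighttime
window is 23:00 of day *d* to 07:00 of day *d+1*.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

SECONDS_PER_DAY = 86_400
NIGHT_START_H = 23.0
NIGHT_LEN_S = 8 * 3600.0  # 11 PM - 7 AM


# ---------------------------------------------------------------------------
# screen sessions


@dataclass
class ScreenRepairs:
    """Counts of repairs applied while pairing raw on/off events."""

    duplicate_state: int = 0
    leading_off: int = 0
    unclosed_on: int = 0
    zero_length: int = 0

    @property
    def total(self) -> int:
        return self.duplicate_state + self.leading_off + self.unclosed_on + self.zero_length

    def as_dict(self) -> dict[str, int]:
        return {
            "duplicate_state": self.duplicate_state,
            "leading_off": self.leading_off,
            "unclosed_on": self.unclosed_on,
            "zero_length": self.zero_length,
        }


def pair_screen_sessions(
    seconds: np.ndarray, states: np.ndarray
) -> tuple[np.ndarray, np.ndarray, ScreenRepairs]:
    """Pair alternating on/off events into screen sessions.

    Consecutive same-state events are deduplicated keeping the first; an
    ``off`` with no open session is dropped; a trailing unmatched ``on`` is
    closed at the next local midnight.  Returns (starts, ends) in local
    seconds plus repair counts.
    """
    seconds = np.asarray(seconds, float)
    states = np.asarray(states)
    rep = ScreenRepairs()
    starts: list[float] = []
    ends: list[float] = []
    open_t: float | None = None
    for t, s in zip(seconds, states):
        if s == "on":
            if open_t is None:
                open_t = float(t)
            else:
                rep.duplicate_state += 1
        elif s == "off":
            if open_t is None:
                rep.leading_off += 1
            elif t > open_t:
                starts.append(open_t)
                ends.append(float(t))
                open_t = None
            else:
                rep.zero_length += 1
                open_t = None
        else:
            raise ValueError(f"unknown screen state {s!r}")
    if open_t is not None:
        rep.unclosed_on += 1
        midnight = (np.floor(open_t / SECONDS_PER_DAY) + 1) * SECONDS_PER_DAY
        starts.append(open_t)
        ends.append(float(midnight))
    return np.asarray(starts), np.asarray(ends), rep


def split_sessions_at_midnight(
    starts: np.ndarray, ends: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Split sessions at local-midnight boundaries.

    Returns (piece_starts, piece_ends, unlock_flag); ``unlock_flag`` marks
    the piece containing the original ``on`` event, so unlock counts are
    attributed to the day the screen actually came on.
    """
    starts = np.asarray(starts, float)
    ends = np.asarray(ends, float)
    straddle = np.floor(starts / SECONDS_PER_DAY) != np.floor(
        np.nextafter(ends, -np.inf) / SECONDS_PER_DAY
    )
    ps = list(starts[~straddle])
    pe = list(ends[~straddle])
    flag = [True] * len(ps)
    for s, e in zip(starts[straddle], ends[straddle]):
        first = True
        cur = s
        while cur < e:
            boundary = (np.floor(cur / SECONDS_PER_DAY) + 1) * SECONDS_PER_DAY
            nxt = min(e, boundary)
            ps.append(cur)
            pe.append(nxt)
            flag.append(first)
            first = False
            cur = nxt
    order = np.argsort(ps, kind="stable")
    return (np.asarray(ps)[order], np.asarray(pe)[order],
            np.asarray(flag, bool)[order])


def daily_screen(
    seconds: np.ndarray, states: np.ndarray, day0: int, n_days: int
) -> tuple[pd.DataFrame, ScreenRepairs]:
    """Per-day unlock counts and screen time (minutes) over the window."""
    starts, ends, rep = pair_screen_sessions(seconds, states)
    ps, pe, unlock = split_sessions_at_midnight(starts, ends)
    days = np.arange(day0, day0 + n_days)
    n_unlocks = np.zeros(n_days, dtype=int)
    screen_min = np.zeros(n_days)
    if len(ps):
        idx = np.floor_divide(ps, SECONDS_PER_DAY).astype(int) - day0
        ok = (idx >= 0) & (idx < n_days)
        np.add.at(screen_min, idx[ok], (pe - ps)[ok] / 60.0)
        np.add.at(n_unlocks, idx[ok & unlock], 1)
    out = pd.DataFrame({"day": days, "n_unlocks": n_unlocks, "screen_time_min": screen_min})
    return out, rep


# ---------------------------------------------------------------------------
# calls


def daily_calls(
    seconds: np.ndarray,
    directions: np.ndarray,
    durations_s: np.ndarray,
    day0: int,
    n_days: int,
) -> pd.DataFrame:
    """Per-day call counts and total duration.

    A call is *connected* when its direction is incoming or outgoing and its
    duration is positive; ``n_incoming``/``n_outgoing`` count connected
    calls only, so ``n_connected == n_incoming + n_outgoing``.  Missed calls
    are counted separately and contribute no duration.
    """
    seconds = np.asarray(seconds, float)
    directions = np.asarray(directions)
    durations_s = np.asarray(durations_s, float)
    days = np.arange(day0, day0 + n_days)
    cols = {k: np.zeros(n_days) for k in
            ("n_incoming", "n_outgoing", "n_connected", "n_missed", "call_duration_min")}
    if len(seconds):
        day_idx = np.floor_divide(seconds, SECONDS_PER_DAY).astype(int) - day0
        ok = (day_idx >= 0) & (day_idx < n_days)
        for i, dirn, dur in zip(day_idx[ok], directions[ok], durations_s[ok]):
            connected = dirn in ("incoming", "outgoing") and dur > 0
            if dirn == "missed":
                cols["n_missed"][i] += 1
            elif connected:
                cols["n_connected"][i] += 1
                cols["n_incoming" if dirn == "incoming" else "n_outgoing"][i] += 1
            cols["call_duration_min"][i] += dur / 60.0
    out = pd.DataFrame({"day": days, **cols})
    for k in ("n_incoming", "n_outgoing", "n_connected", "n_missed"):
        out[k] = out[k].astype(int)
    return out


# ---------------------------------------------------------------------------
# nighttime ambient light


def night_light(
    seconds: np.ndarray,
    lux: np.ndarray,
    day0: int,
    n_days: int,
    low_thresh_lux: float = 10.0,
    high_thresh_lux: float = 1000.0,
) -> pd.DataFrame:
    """Nighttime (11 PM - 7 AM) light features per day.

    The stream logs *changes* in intensity, so each sample holds its value
    until the next one (zero-order hold).  The night belongs to the local
    date containing 11 PM.  ``mean_night_lux`` is the time-weighted mean
    over the observed part of the window; ``time_low``/``time_high`` are
    minutes with held value strictly below/above the thresholds.  Nights
    with no observable value are emitted as missing (NaN) rows.
    """
    if not low_thresh_lux < high_thresh_lux:
        raise ValueError("low threshold must be below high threshold")
    seconds = np.asarray(seconds, float)
    lux = np.asarray(lux, float)
    order = np.argsort(seconds, kind="stable")
    seconds, lux = seconds[order], lux[order]
    rows = []
    for d in range(day0, day0 + n_days):
        w0 = d * SECONDS_PER_DAY + NIGHT_START_H * 3600.0
        w1 = w0 + NIGHT_LEN_S
        i0 = int(np.searchsorted(seconds, w0, side="right"))
        i1 = int(np.searchsorted(seconds, w1, side="left"))
        in_win_t = seconds[i0:i1]
        in_win_v = lux[i0:i1]
        if i0 > 0:  # held value entering the window
            t_pts = np.concatenate(([w0], in_win_t, [w1]))
            v_pts = np.concatenate(([lux[i0 - 1]], in_win_v))
        elif len(in_win_t):
            t_pts = np.concatenate((in_win_t, [w1]))
            v_pts = in_win_v
        else:
            rows.append({"day": d, "mean_night_lux": np.nan,
                         "time_low_lux_min": np.nan, "time_high_lux_min": np.nan})
            continue
        dt = np.diff(t_pts)
        total = float(dt.sum())
        if total <= 0:
            rows.append({"day": d, "mean_night_lux": np.nan,
                         "time_low_lux_min": np.nan, "time_high_lux_min": np.nan})
            continue
        mean = float(np.sum(v_pts * dt) / total)
        t_low = float(dt[v_pts < low_thresh_lux].sum()) / 60.0
        t_high = float(dt[v_pts > high_thresh_lux].sum()) / 60.0
        rows.append({"day": d, "mean_night_lux": mean,
                     "time_low_lux_min": t_low, "time_high_lux_min": t_high})
    return pd.DataFrame(rows)
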