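"""Raw sensor-stream schemas, validation, and cohort retention filters.

A participant's raw data are four delimited-text event streams — GPS fixes
(logged by the phone whenever displacement exceeds ~20 m), call events,
screen on/off events, and ambient-light samples — plus participant metadata
and an enrollment/retention ledger for the whole cohort.

All files are comma-delimited with a required header row and ISO-8601
timestamps carrying a UTC offset.  Timestamps are stored internally as UTC
instants; every feature window downstream is computed on the participant's
local wall clock (see :func:`local_seconds`).  Days are half-open local
intervals ``[00:00, 24:00)``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from datetime import timedelta, timezone, tzinfo
from pathlib import Path
from typing import Iterable, Mapping, Sequence
from zoneinfo import ZoneInfo

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

GPS_SCHEMA = ("timestamp", "lat", "lon")
CALL_SCHEMA = ("timestamp", "direction", "duration_s", "contact_id")
SCREEN_SCHEMA = ("timestamp", "state")
LIGHT_SCHEMA = ("timestamp", "lux")

CALL_DIRECTIONS = ("incoming", "outgoing", "missed")
SCREEN_STATES = ("on", "off")
MATERNAL_EDUCATION_LEVELS = ("below_hs", "hs", "further", "university", "missing")
SEXES = ("female", "male")
OSES = ("ios", "android")

STREAM_NAMES = ("gps", "calls", "screen", "light")
_SCHEMAS = {
    "gps": GPS_SCHEMA,
    "calls": CALL_SCHEMA,
    "screen": SCREEN_SCHEMA,
    "light": LIGHT_SCHEMA,
}

SECONDS_PER_DAY = 86_400


class SchemaError(ValueError):
    """A stream file does not conform to its documented CSV schema."""


class ValidationError(ValueError):
    """Stream contents violate a domain invariant (bounds, ordering)."""


# ---------------------------------------------------------------------------
# time handling


def parse_timezone(spec: str) -> tzinfo:
    """Parse a timezone spec: fixed offset (``-04:00``) or IANA name."""
    s = str(spec).strip()
    if s in ("UTC", "Z", "+00:00", "-00:00"):
        return timezone.utc
    if len(s) == 6 and s[0] in "+-" and s[3] == ":":
        sign = 1 if s[0] == "+" else -1
        hours, minutes = int(s[1:3]), int(s[4:6])
        return timezone(sign * timedelta(hours=hours, minutes=minutes))
    return ZoneInfo(s)


def local_seconds(ts: pd.DatetimeIndex | pd.Series, tz: tzinfo | str) -> np.ndarray:
    """UTC timestamps -> float seconds on the participant's local wall clock.

    The returned values are seconds since 1970-01-01 00:00 *local* time, so
    local midnights fall on exact multiples of 86 400 and a local calendar
    day is ``floor(t / 86400)``.
    """
    if isinstance(tz, str):
        tz = parse_timezone(tz)
    idx = pd.DatetimeIndex(ts)
    if idx.tz is None:
        raise ValidationError("timestamps must be timezone-aware (UTC)")
    naive = idx.tz_convert(tz).tz_localize(None)
    return naive.asi8 / 1e9


def utc_from_local_seconds(sec: np.ndarray, tz: tzinfo | str) -> pd.DatetimeIndex:
    """Inverse of :func:`local_seconds` for fixed-offset timezones."""
    if isinstance(tz, str):
        tz = parse_timezone(tz)
    naive = pd.to_datetime((np.asarray(sec) * 1e9).astype("int64"))
    return naive.tz_localize(tz).tz_convert("UTC")


def day_of(sec: np.ndarray) -> np.ndarray:
    """Local epoch-day index of each local-second value."""
    return np.floor_divide(np.asarray(sec), SECONDS_PER_DAY).astype(np.int64)


def date_of_epoch_day(day: int) -> str:
    """ISO date string for a local epoch-day index."""
    return pd.Timestamp(int(day) * SECONDS_PER_DAY, unit="s").date().isoformat()


# ---------------------------------------------------------------------------
# domain records


@dataclass(frozen=True)
class ParticipantMeta:
    """Demographics and device covariates for one participant."""

    participant_id: str
    age: float
    sex: str
    maternal_education: str
    os: str
    assessment_month: str  # "YYYY-MM"
    timezone: str = "-04:00"
    comorbid_depression: bool = False
    comorbid_gad: bool = False
    comorbid_social_phobia: bool = False

    def validate(self) -> "ParticipantMeta":
        if not 10 <= self.age <= 21:
            raise ValidationError(
                f"{self.participant_id}: age {self.age} outside study range [10, 21]"
            )
        if self.maternal_education not in MATERNAL_EDUCATION_LEVELS:
            raise ValidationError(
                f"{self.participant_id}: maternal_education "
                f"{self.maternal_education!r} not in {MATERNAL_EDUCATION_LEVELS}"
            )
        if self.sex not in SEXES:
            raise ValidationError(f"{self.participant_id}: sex {self.sex!r}")
        if self.os not in OSES:
            raise ValidationError(f"{self.participant_id}: os {self.os!r}")
        parse_timezone(self.timezone)
        return self


@dataclass
class SensorBundle:
    """One participant's four validated raw streams over the study window.

    ``study_start_day`` is the first local calendar day (epoch-day index);
    the window spans ``days`` consecutive local days.
    """

    meta: ParticipantMeta
    gps: pd.DataFrame
    calls: pd.DataFrame
    screen: pd.DataFrame
    light: pd.DataFrame
    study_start_day: int
    days: int = 14

    @property
    def window_local_s(self) -> tuple[float, float]:
        start = self.study_start_day * SECONDS_PER_DAY
        return float(start), float(start + self.days * SECONDS_PER_DAY)


def empty_stream(name: str) -> pd.DataFrame:
    cols = _SCHEMAS[name]
    df = pd.DataFrame({c: pd.Series(dtype=object) for c in cols})
    df["timestamp"] = pd.Series(dtype="datetime64[ns, UTC]")
    if name == "gps":
        df["lat"] = pd.Series(dtype=float)
        df["lon"] = pd.Series(dtype=float)
    elif name == "light":
        df["lux"] = pd.Series(dtype=float)
    elif name == "calls":
        df["duration_s"] = pd.Series(dtype=float)
    return df[list(cols)]


# ---------------------------------------------------------------------------
# reading


def _read_csv(path: Path, schema: Sequence[str]) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError as exc:
        raise SchemaError(f"{path}: empty file (header row required)") from exc
    missing = [c for c in schema if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required columns {missing}")
    extra = [c for c in df.columns if c not in schema]
    if extra:
        log.warning("%s: ignoring unknown extra columns %s", path, extra)
    return df[list(schema)]


def _parse_timestamps(df: pd.DataFrame, path: Path) -> pd.DataFrame:
    ts = pd.to_datetime(df["timestamp"], errors="coerce", utc=True, format="ISO8601")
    bad = np.flatnonzero(ts.isna().to_numpy())
    if bad.size:
        # +2: header line plus 1-based numbering
        raise SchemaError(
            f"{path}:{bad[0] + 2}: unparseable timestamp {df['timestamp'].iloc[bad[0]]!r}"
        )
    out = df.copy()
    out["timestamp"] = ts
    return out


def _parse_float(df: pd.DataFrame, col: str, path: Path) -> pd.DataFrame:
    vals = pd.to_numeric(df[col], errors="coerce")
    bad = np.flatnonzero(vals.isna().to_numpy())
    if bad.size:
        raise SchemaError(
            f"{path}:{bad[0] + 2}: unparseable {col} {df[col].iloc[bad[0]]!r}"
        )
    out = df.copy()
    # numpy's parser is correctly rounded (round-trip exact); pandas' fast
    # to_numeric path is not, which would break write->read->write identity
    out[col] = df[col].to_numpy("U").astype(float)
    return out


def read_gps(path: Path) -> pd.DataFrame:
    df = _read_csv(path, GPS_SCHEMA)
    if df.empty:
        return empty_stream("gps")
    df = _parse_timestamps(df, path)
    df = _parse_float(df, "lat", path)
    df = _parse_float(df, "lon", path)
    validate_gps(df, name=str(path))
    return df


def read_calls(path: Path) -> pd.DataFrame:
    df = _read_csv(path, CALL_SCHEMA)
    if df.empty:
        return empty_stream("calls")
    df = _parse_timestamps(df, path)
    df = _parse_float(df, "duration_s", path)
    validate_calls(df, name=str(path))
    return df


def read_screen(path: Path) -> pd.DataFrame:
    df = _read_csv(path, SCREEN_SCHEMA)
    if df.empty:
        return empty_stream("screen")
    df = _parse_timestamps(df, path)
    validate_screen(df, name=str(path))
    return df


def read_light(path: Path) -> pd.DataFrame:
    df = _read_csv(path, LIGHT_SCHEMA)
    if df.empty:
        return empty_stream("light")
    df = _parse_timestamps(df, path)
    df = _parse_float(df, "lux", path)
    validate_light(df, name=str(path))
    return df


_READERS = {"gps": read_gps, "calls": read_calls, "screen": read_screen, "light": read_light}


# ---------------------------------------------------------------------------
# validation (idempotent; raises on invariant violations)


def validate_gps(df: pd.DataFrame, name: str = "gps") -> pd.DataFrame:
    lat, lon = df["lat"].to_numpy(float), df["lon"].to_numpy(float)
    if ((lat < -90) | (lat > 90)).any():
        i = int(np.argmax((lat < -90) | (lat > 90)))
        raise ValidationError(f"{name}: latitude {lat[i]} out of bounds [-90, 90]")
    if ((lon < -180) | (lon > 180)).any():
        i = int(np.argmax((lon < -180) | (lon > 180)))
        raise ValidationError(f"{name}: longitude {lon[i]} out of bounds [-180, 180]")
    t = pd.DatetimeIndex(df["timestamp"]).asi8
    if len(t) > 1 and (np.diff(t) <= 0).any():
        raise ValidationError(f"{name}: GPS timestamps must be strictly increasing")
    return df


def validate_calls(df: pd.DataFrame, name: str = "calls") -> pd.DataFrame:
    bad_dir = ~df["direction"].isin(CALL_DIRECTIONS)
    if bad_dir.any():
        raise ValidationError(
            f"{name}: unknown call direction {df['direction'][bad_dir].iloc[0]!r}"
        )
    dur = df["duration_s"].to_numpy(float)
    if (dur < 0).any():
        raise ValidationError(f"{name}: negative call duration")
    missed = df["direction"].to_numpy() == "missed"
    if (dur[missed] != 0).any():
        raise ValidationError(f"{name}: missed call with nonzero duration")
    return df


def validate_screen(df: pd.DataFrame, name: str = "screen") -> pd.DataFrame:
    bad = ~df["state"].isin(SCREEN_STATES)
    if bad.any():
        raise ValidationError(f"{name}: unknown screen state {df['state'][bad].iloc[0]!r}")
    t = pd.DatetimeIndex(df["timestamp"]).asi8
    if len(t) > 1 and (np.diff(t) < 0).any():
        raise ValidationError(f"{name}: screen timestamps must be nondecreasing")
    return df


def validate_light(df: pd.DataFrame, name: str = "light") -> pd.DataFrame:
    lux = df["lux"].to_numpy(float)
    if (lux < 0).any():
        raise ValidationError(f"{name}: negative light intensity")
    return df


_VALIDATORS = {
    "gps": validate_gps,
    "calls": validate_calls,
    "screen": validate_screen,
    "light": validate_light,
}


def read_sensor_bundle(
    paths: Mapping[str, Path | None],
    meta: ParticipantMeta,
    study_start_day: int,
    days: int = 14,
) -> SensorBundle:
    """Read, validate and window-clip one participant's four streams.

    ``paths`` maps stream names (``gps``/``calls``/``screen``/``light``) to
    files; a missing entry or ``None`` yields an empty stream.  Rows outside
    the 14-day study window are dropped with a logged count.
    """
    meta.validate()
    streams: dict[str, pd.DataFrame] = {}
    w0 = study_start_day * SECONDS_PER_DAY
    w1 = w0 + days * SECONDS_PER_DAY
    for name in STREAM_NAMES:
        path = paths.get(name)
        if path is None:
            streams[name] = empty_stream(name)
            continue
        df = _READERS[name](Path(path))
        if len(df):
            sec = local_seconds(df["timestamp"], meta.timezone)
            inside = (sec >= w0) & (sec < w1)
            n_out = int((~inside).sum())
            if n_out:
                log.info(
                    "%s/%s: dropped %d rows outside study window",
                    meta.participant_id, name, n_out,
                )
                df = df.loc[inside].reset_index(drop=True)
        streams[name] = df
    return SensorBundle(
        meta=meta,
        gps=streams["gps"],
        calls=streams["calls"],
        screen=streams["screen"],
        light=streams["light"],
        study_start_day=study_start_day,
        days=days,
    )


# ---------------------------------------------------------------------------
# writing (canonical form: read -> write reproduces files byte-for-byte)


def _fmt_num(x: float) -> str:
    f = float(x)
    return str(int(f)) if f.is_integer() else repr(f)


def _fmt_ts(ts: pd.Timestamp) -> str:
    return ts.isoformat()


def write_stream(df: pd.DataFrame, name: str, path: Path) -> None:
    cols = _SCHEMAS[name]
    lines = [",".join(cols)]
    for row in df.itertuples(index=False):
        vals = []
        for col, v in zip(cols, row):
            if col == "timestamp":
                vals.append(_fmt_ts(v))
            elif col in ("lat", "lon", "lux", "duration_s"):
                vals.append(_fmt_num(v))
            else:
                vals.append(str(v))
        lines.append(",".join(vals))
    Path(path).write_text("\n".join(lines) + "\n")


def write_sensor_bundle(bundle: SensorBundle, directory: Path) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for name in STREAM_NAMES:
        write_stream(getattr(bundle, name), name, directory / f"{name}.csv")


# ---------------------------------------------------------------------------
# cohort metadata tables


META_COLUMNS = (
    "participant_id", "age", "sex", "maternal_education", "os",
    "assessment_month", "timezone", "comorbid_depression", "comorbid_gad",
    "comorbid_social_phobia",
)


def write_meta(metas: Iterable[ParticipantMeta], path: Path) -> None:
    rows = []
    for m in metas:
        rows.append({
            "participant_id": m.participant_id,
            "age": _fmt_num(m.age),
            "sex": m.sex,
            "maternal_education": m.maternal_education,
            "os": m.os,
            "assessment_month": m.assessment_month,
            "timezone": m.timezone,
            "comorbid_depression": int(m.comorbid_depression),
            "comorbid_gad": int(m.comorbid_gad),
            "comorbid_social_phobia": int(m.comorbid_social_phobia),
        })
    pd.DataFrame(rows, columns=list(META_COLUMNS)).to_csv(path, index=False, lineterminator="\n")


def read_meta(path: Path) -> list[ParticipantMeta]:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in META_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing meta columns {missing}")
    out = []
    for row in df.itertuples(index=False):
        out.append(
            ParticipantMeta(
                participant_id=row.participant_id,
                age=float(row.age),
                sex=row.sex,
                maternal_education=row.maternal_education,
                os=row.os,
                assessment_month=row.assessment_month,
                timezone=row.timezone,
                comorbid_depression=bool(int(row.comorbid_depression)),
                comorbid_gad=bool(int(row.comorbid_gad)),
                comorbid_social_phobia=bool(int(row.comorbid_social_phobia)),
            ).validate()
        )
    return out


LEDGER_COLUMNS = (
    "participant_id", "enrolled", "withdrew", "days_provided", "has_required_sensors"
)


def write_ledger(ledger: pd.DataFrame, path: Path) -> None:
    df = ledger.copy()
    for c in ("enrolled", "withdrew", "has_required_sensors"):
        df[c] = df[c].astype(int)
    df[list(LEDGER_COLUMNS)].to_csv(path, index=False, lineterminator="\n")


def read_ledger(path: Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in LEDGER_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing ledger columns {missing}")
    for c in ("enrolled", "withdrew", "has_required_sensors"):
        df[c] = df[c].astype(bool)
    df["days_provided"] = df["days_provided"].astype(int)
    if ((df["days_provided"] < 0) | (df["days_provided"] > 14)).any():
        raise ValidationError(f"{path}: days_provided outside [0, 14]")
    return df


# ---------------------------------------------------------------------------
# retention


EXCLUSION_REASONS = ("withdrew", "insufficient_days", "missing_sensors")


@dataclass
class RetentionResult:
    """Cohort retention outcome with per-reason exclusion accounting.

    Each excluded participant is attributed to exactly one reason, the first
    that applies in the fixed order withdrawal -> insufficient days ->
    missing sensors, so counts always reconcile:
    ``enrolled == retained + sum(exclusions.values())``.
    """

    retained: list[str]
    exclusions: dict[str, int]
    reason_by_participant: dict[str, str] = field(default_factory=dict)

    @property
    def n_retained(self) -> int:
        return len(self.retained)


def apply_retention_filters(ledger: pd.DataFrame, required_days: int = 14) -> RetentionResult:
    """Apply the study's retention rules to an enrollment ledger.

    A participant is retained iff enrolled, not withdrawn, provided at least
    ``required_days`` days of data, and has the required sensors.
    """
    retained: list[str] = []
    exclusions = {r: 0 for r in EXCLUSION_REASONS}
    reason_by: dict[str, str] = {}
    for row in ledger.itertuples(index=False):
        if not row.enrolled:
            continue
        if row.withdrew:
            reason = "withdrew"
        elif row.days_provided < required_days:
            reason = "insufficient_days"
        elif not row.has_required_sensors:
            reason = "missing_sensors"
        else:
            retained.append(str(row.participant_id))
            continue
        exclusions[reason] += 1
        reason_by[str(row.participant_id)] = reason
    return RetentionResult(retained=retained, exclusions=exclusions, reason_by_participant=reason_by)
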