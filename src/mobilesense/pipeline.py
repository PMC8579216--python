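"""End-to-end orchestration: ingest or simulate -> daily features ->
instrument scoring -> covariate-adjusted association analysis -> report.

Every stage reads and writes plain CSV, so stages can be rerun
independently; a manifest records the config hash, seed and repair counts
for reproducibility.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import sensor_io, stats, surveys as surveys_mod, usage
from .mobility import daily_mobility
from .sensor_io import SECONDS_PER_DAY, ParticipantMeta, apply_retention_filters, local_seconds
from .simulate import CohortData, SimulationConfig, simulate_cohort, write_cohort
from .stats import (
    AssociationResult,
    ModelComparisonResult,
    adjusted_spearman,
    bh_qvalues,
    discriminant_validity,
    flag_extreme_outliers,
    nested_f_test,
    participant_averages,
)

log = logging.getLogger(__name__)

MOBILITY_FEATURES = ["time_sedentary_h", "time_moving_h", "distance_km", "entropy_norm"]
CALL_FEATURES = ["call_duration_min", "n_incoming", "n_outgoing", "n_connected"]
SCREEN_FEATURES = ["screen_time_min", "n_unlocks"]
LIGHT_FEATURES = ["mean_night_lux"]
ALL_FEATURES = MOBILITY_FEATURES + CALL_FEATURES + SCREEN_FEATURES + LIGHT_FEATURES

# Predictor set for the linear models: drops columns that are linear
# combinations of the others by construction (connected = incoming +
# outgoing; moving = hours observed - sedentary under full coverage), which
# would make the full design singular.
MODEL_FEATURES = [f for f in ALL_FEATURES if f not in ("n_connected", "time_moving_h")]

OUTCOMES = {"SCARED": "scared_total", "CESDC": "cesdc_total"}
BASE_COVARIATES = ["age", "sex", "maternal_education", "os", "assessment_month"]


@dataclass
class PipelineConfig:
    """All tunable thresholds of the pipeline in one auditable place."""

    out_dir: str = "run"
    input_dir: str | None = None  # None -> simulate
    seed: int = 0
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    displacement_m: float = 20.0
    cluster_radius_m: float = 150.0
    min_dwell_s: float = 120.0
    low_lux: float = 10.0
    high_lux: float = 1000.0
    required_days: int = 14
    outlier_fence_k: float = 3.0
    alpha: float = 0.05

    def config_hash(self) -> str:
        payload = asdict(self)
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


# ---------------------------------------------------------------------------
# feature extraction


def participant_daily_features(
    pid: str,
    day0: int,
    n_days: int,
    gps_sec: np.ndarray, gps_lat: np.ndarray, gps_lon: np.ndarray,
    call_sec: np.ndarray, call_dir: np.ndarray, call_dur: np.ndarray,
    screen_sec: np.ndarray, screen_state: np.ndarray,
    light_sec: np.ndarray, light_lux: np.ndarray,
    cfg: PipelineConfig | None = None,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Daily rows of the 11 sensor features for one participant.

    GPS-free days yield missing mobility cells; they are excluded from
    participant averages downstream.
    """
    cfg = cfg or PipelineConfig()
    rows = []
    gps_day = np.floor_divide(gps_sec, SECONDS_PER_DAY).astype(int) if len(gps_sec) else np.empty(0, int)
    for d in range(day0, day0 + n_days):
        mask = gps_day == d
        if mask.any():
            dm = daily_mobility(
                gps_sec[mask] - d * SECONDS_PER_DAY, gps_lat[mask], gps_lon[mask],
                displacement_m=cfg.displacement_m,
                cluster_radius_m=cfg.cluster_radius_m,
                min_dwell_s=cfg.min_dwell_s,
            )
            rows.append({
                "day": d,
                "time_sedentary_h": dm.time_sedentary_h,
                "time_moving_h": dm.time_moving_h,
                "distance_km": dm.distance_km,
                "entropy_norm": dm.entropy_norm,
                "hours_observed": dm.hours_observed,
            })
        else:
            rows.append({
                "day": d, "time_sedentary_h": np.nan, "time_moving_h": np.nan,
                "distance_km": np.nan, "entropy_norm": np.nan, "hours_observed": 0,
            })
    mob = pd.DataFrame(rows)
    calls = usage.daily_calls(call_sec, call_dir, call_dur, day0, n_days)
    screen, rep = usage.daily_screen(screen_sec, screen_state, day0, n_days)
    light = usage.night_light(light_sec, light_lux, day0, n_days, cfg.low_lux, cfg.high_lux)
    # all four tables cover the same day range in order; concat columns
    daily = pd.concat(
        [mob, calls.drop(columns="day"), screen.drop(columns="day"),
         light.drop(columns="day")],
        axis=1,
    )
    daily.insert(0, "participant_id", pid)
    daily.insert(2, "date", [sensor_io.date_of_epoch_day(d) for d in daily["day"]])
    return daily, rep.as_dict()


def features_from_bundle(bundle: sensor_io.SensorBundle, cfg: PipelineConfig | None = None):
    """Daily features straight from a validated :class:`SensorBundle`."""
    tz = bundle.meta.timezone
    def _sec(df): return local_seconds(df["timestamp"], tz) if len(df) else np.empty(0)
    return participant_daily_features(
        bundle.meta.participant_id, bundle.study_start_day, bundle.days,
        _sec(bundle.gps),
        bundle.gps["lat"].to_numpy(float), bundle.gps["lon"].to_numpy(float),
        _sec(bundle.calls),
        bundle.calls["direction"].to_numpy(object),
        bundle.calls["duration_s"].to_numpy(float),
        _sec(bundle.screen), bundle.screen["state"].to_numpy(object),
        _sec(bundle.light), bundle.light["lux"].to_numpy(float),
        cfg,
    )


def features_from_cohort(
    cohort: CohortData,
    retained_ids: set[str] | None = None,
    cfg: PipelineConfig | None = None,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Daily feature table for an in-memory synthetic cohort."""
    frames = []
    repairs = {"duplicate_state": 0, "leading_off": 0, "unclosed_on": 0, "zero_length": 0}
    for p in cohort.participants:
        pid = p.meta.participant_id
        if retained_ids is not None and pid not in retained_ids:
            continue
        daily, rep = participant_daily_features(
            pid, p.day0, cohort.config.days,
            p.gps_sec, p.gps_lat, p.gps_lon,
            p.call_sec, p.call_dir, p.call_dur,
            p.screen_sec, p.screen_state,
            p.light_sec, p.light_lux,
            cfg,
        )
        frames.append(daily)
        for k, v in rep.items():
            repairs[k] += v
    daily_all = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()
    return daily_all, repairs


# ---------------------------------------------------------------------------
# analysis


@dataclass
class AnalysisOutputs:
    associations: pd.DataFrame
    model_comparisons: list[ModelComparisonResult]
    discriminant: pd.DataFrame
    outliers_gps: set[str]
    outliers_calls: set[str]
    matrix: pd.DataFrame


def build_feature_matrix(
    daily: pd.DataFrame, scores: pd.DataFrame, metas: list[ParticipantMeta]
) -> pd.DataFrame:
    """One row per participant: feature means, instrument totals, covariates."""
    means = participant_averages(daily, ALL_FEATURES)
    meta_df = pd.DataFrame([{
        "participant_id": m.participant_id, "age": m.age, "sex": m.sex,
        "maternal_education": m.maternal_education, "os": m.os,
        "assessment_month": m.assessment_month,
    } for m in metas]).set_index("participant_id")
    sc = scores.set_index("participant_id")
    matrix = means.join(sc, how="left").join(meta_df, how="left")
    matrix.index.name = "participant_id"
    return matrix


def analyze_matrix(matrix: pd.DataFrame, cfg: PipelineConfig | None = None) -> AnalysisOutputs:
    """Outlier screening, adjusted correlations, nested models, validity."""
    cfg = cfg or PipelineConfig()
    matrix = matrix.copy()

    out_gps = flag_extreme_outliers(matrix[MOBILITY_FEATURES], cfg.outlier_fence_k)
    out_calls = flag_extreme_outliers(matrix[CALL_FEATURES], cfg.outlier_fence_k)
    matrix.loc[matrix.index.astype(str).isin(out_gps), MOBILITY_FEATURES] = np.nan
    matrix.loc[matrix.index.astype(str).isin(out_calls), CALL_FEATURES] = np.nan

    results: list[AssociationResult] = []
    for outcome_name, outcome_col in OUTCOMES.items():
        comorbid = [c for c in ("scared_total", "cesdc_total", "asrs_total")
                    if c != outcome_col]
        cov = matrix[BASE_COVARIATES + comorbid]
        for feat in ALL_FEATURES:
            results.append(adjusted_spearman(
                matrix[feat].to_numpy(float),
                matrix[outcome_col].to_numpy(float),
                covariates=cov,
                feature=feat,
                outcome=outcome_name,
            ))
    assoc = pd.DataFrame([{
        "feature": r.feature, "outcome": r.outcome, "r": r.r, "p": r.p,
        "n": r.n, "df": r.df, "r_unadjusted": r.r_unadjusted,
        "p_unadjusted": r.p_unadjusted,
    } for r in results])
    assoc["q"] = np.nan
    for outc in assoc["outcome"].unique():
        m = assoc["outcome"] == outc
        assoc.loc[m, "q"] = bh_qvalues(assoc.loc[m, "p"].to_numpy())

    comparisons = []
    for outcome_name, outcome_col in OUTCOMES.items():
        comorbid = [c for c in ("scared_total", "cesdc_total", "asrs_total")
                    if c != outcome_col]
        comparisons.append(nested_f_test(
            matrix[outcome_col].to_numpy(float),
            base=matrix[BASE_COVARIATES + comorbid],
            added=matrix[MODEL_FEATURES],
            outcome=outcome_name,
        ))

    disc = discriminant_validity(
        matrix[["scared_total", "cesdc_total", "asrs_total"]],
        base=matrix[BASE_COVARIATES],
        added=matrix[MODEL_FEATURES],
    )
    return AnalysisOutputs(
        associations=assoc, model_comparisons=comparisons, discriminant=disc,
        outliers_gps=out_gps, outliers_calls=out_calls, matrix=matrix,
    )


def analyze_cohort(cohort: CohortData, cfg: PipelineConfig | None = None) -> AnalysisOutputs:
    """Retention -> features -> scoring -> analysis for an in-memory cohort."""
    retention = apply_retention_filters(cohort.ledger, (cfg or PipelineConfig()).required_days)
    retained = set(retention.retained)
    daily, _rep = features_from_cohort(cohort, retained, cfg)
    scores = surveys_mod.score_surveys(cohort.surveys)
    scores = scores[scores["participant_id"].isin(retained)]
    metas = [p.meta for p in cohort.participants if p.meta.participant_id in retained]
    matrix = build_feature_matrix(daily, scores, metas)
    return analyze_matrix(matrix, cfg)


# ---------------------------------------------------------------------------
# disk-based run


def _load_cohort_dir(input_dir: Path, required_days: int):
    metas = sensor_io.read_meta(input_dir / "meta.csv")
    ledger = sensor_io.read_ledger(input_dir / "ledger.csv")
    windows = {}
    wpath = input_dir / "study_windows.csv"
    if wpath.exists():
        wdf = pd.read_csv(wpath, dtype={"participant_id": str})
        windows = dict(zip(wdf["participant_id"], wdf["study_start_day"].astype(int)))
    surveys = surveys_mod.read_surveys(input_dir / "surveys.csv")
    return metas, ledger, windows, surveys


def _infer_start_day(paths: dict[str, Path], tz: str) -> int | None:
    first = None
    for name, path in paths.items():
        if path is None or not path.exists():
            continue
        df = sensor_io._READERS[name](path)
        if len(df):
            sec = local_seconds(df["timestamp"], tz)
            lo = int(np.floor(sec.min() / SECONDS_PER_DAY))
            first = lo if first is None else min(first, lo)
    return first


def run_pipeline(cfg: PipelineConfig) -> AnalysisOutputs:
    """Run every stage, writing all tabular artifacts under ``cfg.out_dir``."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    if cfg.input_dir is None:
        sim = cfg.simulation
        sim.seed = cfg.seed
        cohort = simulate_cohort(sim)
        write_cohort(cohort, out)
        input_dir = out
    else:
        input_dir = Path(cfg.input_dir)

    metas, ledger, windows, surveys = _load_cohort_dir(input_dir, cfg.required_days)
    retention = apply_retention_filters(ledger, cfg.required_days)
    retained = set(retention.retained)
    log.info("retention: %d enrolled, %d retained, exclusions %s",
             len(ledger), len(retained), retention.exclusions)

    frames = []
    repairs = {"duplicate_state": 0, "leading_off": 0, "unclosed_on": 0, "zero_length": 0}
    for meta in metas:
        pid = meta.participant_id
        if pid not in retained:
            continue
        pdir = input_dir / "raw" / pid
        paths = {n: (pdir / f"{n}.csv" if (pdir / f"{n}.csv").exists() else None)
                 for n in sensor_io.STREAM_NAMES}
        day0 = windows.get(pid)
        if day0 is None:
            day0 = _infer_start_day(paths, meta.timezone)
        if day0 is None:
            log.warning("%s: no sensor data at all; skipped from feature extraction", pid)
            continue
        bundle = sensor_io.read_sensor_bundle(paths, meta, day0, cfg.simulation.days)
        daily, rep = features_from_bundle(bundle, cfg)
        frames.append(daily)
        for k, v in rep.items():
            repairs[k] += v
    daily_all = pd.concat(frames, ignore_index=True)

    mob_cols = ["participant_id", "date", "time_sedentary_h", "time_moving_h",
                "distance_km", "entropy_norm", "hours_observed"]
    daily_all[mob_cols].to_csv(out / "features_mobility.csv", index=False, lineterminator="\n")
    use_cols = ["participant_id", "date", "n_incoming", "n_outgoing", "n_connected",
                "n_missed", "call_duration_min", "n_unlocks", "screen_time_min",
                "mean_night_lux", "time_low_lux_min", "time_high_lux_min"]
    daily_all[use_cols].to_csv(out / "features_usage.csv", index=False, lineterminator="\n")

    scores = surveys_mod.score_surveys(surveys)
    scores.to_csv(out / "scores.csv", index=False, lineterminator="\n")
    scores_r = scores[scores["participant_id"].isin(retained)]
    metas_r = [m for m in metas if m.participant_id in retained]

    matrix = build_feature_matrix(daily_all, scores_r, metas_r)
    matrix.to_csv(out / "feature_matrix.csv", lineterminator="\n")

    outputs = analyze_matrix(matrix, cfg)
    outputs.associations[["feature", "outcome", "r", "p", "q", "n"]].to_csv(
        out / "associations.csv", index=False, lineterminator="\n")
    pd.DataFrame([{
        "outcome": c.outcome, "F": c.F, "df1": c.df1, "df2": c.df2, "p": c.p, "n": c.n,
    } for c in outputs.model_comparisons]).to_csv(
        out / "model_comparison.csv", index=False, lineterminator="\n")
    outputs.discriminant.to_csv(out / "discriminant.csv", index=False, lineterminator="\n")

    manifest = {
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "n_enrolled": int(len(ledger)),
        "n_retained": len(retained),
        "exclusions": retention.exclusions,
        "screen_repairs": repairs,
        "outliers_gps": sorted(outputs.outliers_gps),
        "outliers_calls": sorted(outputs.outliers_calls),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    write_report(out, outputs, retention, len(ledger))
    return outputs


def write_report(out: Path, outputs: AnalysisOutputs, retention, n_enrolled: int) -> None:
    """Markdown summary: descriptives, associations, model fit, retention."""
    lines = ["# Mobile sensing analysis report", ""]
    lines += ["## Retention", "",
              f"- enrolled: {n_enrolled}",
              f"- withdrew: {retention.exclusions['withdrew']}",
              f"- insufficient days: {retention.exclusions['insufficient_days']}",
              f"- missing sensors: {retention.exclusions['missing_sensors']}",
              f"- retained: {retention.n_retained}", ""]
    lines += ["## Feature descriptives (participant means)", "",
              "| Feature | Mean | SD |", "|---|---|---|"]
    for feat in ALL_FEATURES:
        v = outputs.matrix[feat].to_numpy(float)
        lines.append(f"| {feat} | {np.nanmean(v):.2f} | {np.nanstd(v, ddof=1):.2f} |")
    for col, label in (("scared_total", "SCARED"), ("cesdc_total", "CES-DC")):
        v = outputs.matrix[col].to_numpy(float)
        lines.append(f"| {label} | {np.nanmean(v):.2f} | {np.nanstd(v, ddof=1):.2f} |")
    lines += ["", "## Adjusted Spearman associations", "",
              "| Feature | Outcome | r | p | q | n |", "|---|---|---|---|---|---|"]
    for row in outputs.associations.itertuples(index=False):
        lines.append(f"| {row.feature} | {row.outcome} | {row.r:.3f} | {row.p:.3g} "
                     f"| {row.q:.3g} | {row.n} |")
    lines += ["", "## Nested model comparison", "",
              "| Outcome | F | df1 | df2 | p |", "|---|---|---|---|---|"]
    for c in outputs.model_comparisons:
        lines.append(f"| {c.outcome} | {c.F:.3f} | {c.df1} | {c.df2} | {c.p:.3g} |")
    lines += ["", "## Discriminant validity of predicted scores", "",
              "| Predicted | Observed | r | p | n |", "|---|---|---|---|---|"]
    for row in outputs.discriminant.itertuples(index=False):
        lines.append(f"| {row.predicted} | {row.observed} | {row.r:.3f} | {row.p:.3g} | {row.n} |")
    if outputs.matrix.empty:
        lines += ["", "**Empty cohort: no participants passed retention.**"]
    (Path(out) / "report.md").write_text("\n".join(lines) + "\n")
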