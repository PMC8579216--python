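"""Covariate-adjusted association analysis.

Implements the study-level statistics relating per-participant feature
means to instrument totals:

* partial (covariate-adjusted) Spearman correlation — both variables are
  rank-transformed (average ranks for ties), residualized on the covariate
  design (categorical covariates dummy-coded), and the Pearson correlation
  of the residuals is tested on ``n - 2 - k`` degrees of freedom, where
  ``k`` counts non-intercept covariate columns;
* Tukey far-out-fence screening (``[Q1 - 3 IQR, Q3 + 3 IQR]``) for extreme
  outliers, applied per sensor domain;
* nested OLS model comparison via the RSS-reduction F statistic;
* discriminant validity of model-predicted instrument scores.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps


class DesignError(ValueError):
    """The covariate/predictor design is singular or degenerate."""


@dataclass
class AssociationResult:
    """Adjusted rank correlation between one feature and one outcome."""

    feature: str
    outcome: str
    r: float
    p: float
    n: int
    df: int
    r_unadjusted: float
    p_unadjusted: float


@dataclass
class ModelComparisonResult:
    """Nested-model F comparison: base covariates vs base + sensor features."""

    outcome: str
    F: float
    df1: int
    df2: int
    p: float
    n: int


# ---------------------------------------------------------------------------
# design helpers


def build_design(covariates: pd.DataFrame | None, n: int | None = None) -> tuple[np.ndarray, list[str]]:
    """Intercept + numeric covariates + dummy-coded categoricals.

    String/categorical/boolean columns are expanded to indicator columns
    with the first level dropped (the intercept absorbs it).
    """
    if covariates is None or covariates.shape[1] == 0:
        if n is None:
            raise ValueError("n required when covariates are absent")
        return np.ones((n, 1)), ["intercept"]
    parts = [pd.Series(np.ones(len(covariates)), index=covariates.index, name="intercept")]
    for col in covariates.columns:
        s = covariates[col]
        if pd.api.types.is_numeric_dtype(s) and not pd.api.types.is_bool_dtype(s):
            if s.nunique(dropna=False) > 1:  # constants are absorbed by the intercept
                parts.append(s.astype(float))
        else:
            dummies = pd.get_dummies(s.astype(str), prefix=col, drop_first=True, dtype=float)
            for c in dummies.columns:
                parts.append(dummies[c])
    X = pd.concat(parts, axis=1)
    return X.to_numpy(float), list(X.columns)


def _check_full_rank(X: np.ndarray, names: list[str]) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # name the columns involved in the dependency for the error message
        _, R = np.linalg.qr(X)
        dep = [names[i] for i in range(X.shape[1]) if abs(R[i, i]) < 1e-8] or names
        raise DesignError(f"singular design; collinear columns include {dep}")


def _residualize(v: np.ndarray, X: np.ndarray) -> np.ndarray:
    beta, *_ = np.linalg.lstsq(X, v, rcond=None)
    return v - X @ beta


# ---------------------------------------------------------------------------
# adjusted Spearman


def adjusted_spearman(
    x,
    y,
    covariates: pd.DataFrame | None = None,
    feature: str = "x",
    outcome: str = "y",
) -> AssociationResult:
    """Partial Spearman correlation of ``x`` and ``y`` given covariates.

    Rows with any missing value in ``x``, ``y`` or the covariates are
    dropped (pairwise-complete analysis).  Following the standard partial-
    Spearman construction, numeric covariates are rank-transformed along
    with ``x`` and ``y`` (for indicator columns the rank map is affine, so
    it changes nothing).  With no covariates this reduces exactly to the
    plain Spearman coefficient.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    mask = ~(np.isnan(x) | np.isnan(y))
    if covariates is not None and covariates.shape[1] > 0:
        cov_na = covariates.isna().any(axis=1).to_numpy()
        mask &= ~cov_na
        cov_cc = covariates.loc[mask].reset_index(drop=True).copy()
        for col in cov_cc.columns:
            s = cov_cc[col]
            if pd.api.types.is_numeric_dtype(s) and not pd.api.types.is_bool_dtype(s):
                cov_cc[col] = sps.rankdata(s.to_numpy(float))
    else:
        cov_cc = None
    xc, yc = x[mask], y[mask]
    n = int(mask.sum())
    X, names = build_design(cov_cc, n=n)
    k = X.shape[1] - 1
    if n < k + 3:
        raise ValueError(f"need >= {k + 3} complete cases, got {n}")
    if np.ptp(xc) == 0 or np.ptp(yc) == 0:
        raise DesignError(f"zero variance in {'x' if np.ptp(xc) == 0 else 'y'}")
    _check_full_rank(X, names)
    rx = sps.rankdata(xc)
    ry = sps.rankdata(yc)
    ex = _residualize(rx, X)
    ey = _residualize(ry, X)
    denom = float(np.linalg.norm(ex) * np.linalg.norm(ey))
    if denom == 0:
        raise DesignError("residual variance is zero after adjustment")
    r = float(np.dot(ex, ey) / denom)
    df = n - 2 - k
    if df <= 0:
        raise ValueError("insufficient residual degrees of freedom")
    r_clamped = min(1.0, max(-1.0, r))
    if abs(r_clamped) >= 1.0:
        p = 0.0
    else:
        t = r_clamped * np.sqrt(df / (1.0 - r_clamped**2))
        p = float(2.0 * sps.t.sf(abs(t), df))
    r0, p0 = sps.spearmanr(xc, yc)
    return AssociationResult(
        feature=feature, outcome=outcome, r=r_clamped, p=p, n=n, df=df,
        r_unadjusted=float(r0), p_unadjusted=float(p0),
    )


# ---------------------------------------------------------------------------
# outlier screening


def tukey_fences(values: np.ndarray, k: float = 3.0) -> tuple[float, float]:
    """Far-out Tukey fences ``[Q1 - k IQR, Q3 + k IQR]`` (NaNs ignored)."""
    q1, q3 = np.nanpercentile(np.asarray(values, float), [25, 75])
    iqr = q3 - q1
    return float(q1 - k * iqr), float(q3 + k * iqr)


def flag_extreme_outliers(features: pd.DataFrame, k: float = 3.0) -> set[str]:
    """Participants with any feature outside the far-out Tukey fences.

    ``features`` is indexed by participant id with one column per feature of
    the sensor domain under test; requires at least 4 non-missing values
    per feature.
    """
    flagged: set[str] = set()
    for col in features.columns:
        vals = features[col].to_numpy(float)
        if np.sum(~np.isnan(vals)) < 4:
            raise ValueError(f"{col}: need >= 4 values for fence estimation")
        lo, hi = tukey_fences(vals, k)
        bad = (vals < lo) | (vals > hi)
        flagged.update(str(i) for i in features.index[np.nan_to_num(bad, nan=False)])
    return flagged


# ---------------------------------------------------------------------------
# per-participant averaging


def participant_averages(daily: pd.DataFrame, feature_cols: list[str]) -> pd.DataFrame:
    """Unweighted mean of each daily feature across a participant's
    non-missing days, with per-feature day counts alongside."""
    g = daily.groupby("participant_id")
    means = g[feature_cols].mean()
    counts = g[feature_cols].count().add_suffix("__days")
    return means.join(counts)


# ---------------------------------------------------------------------------
# nested model comparison


def nested_f_test(y, base: pd.DataFrame, added: pd.DataFrame, outcome: str = "y") -> ModelComparisonResult:
    """F test of whether sensor features improve on the covariate-only model.

    Ordinary least squares on listwise-complete cases; the statistic is
    ``((RSS0 - RSS1)/df1) / (RSS1/df2)`` with ``df1`` added columns and
    ``df2`` residual df of the full model.
    """
    y = np.asarray(y, float)
    mask = ~np.isnan(y)
    mask &= ~base.isna().any(axis=1).to_numpy()
    mask &= ~added.isna().any(axis=1).to_numpy()
    yc = y[mask]
    X0, names0 = build_design(base.loc[mask].reset_index(drop=True))
    Xa, names_a = build_design(added.loc[mask].reset_index(drop=True))
    Xa, names_a = Xa[:, 1:], names_a[1:]  # intercept already in X0
    X1 = np.hstack([X0, Xa])
    names1 = names0 + names_a
    n = len(yc)
    if n <= X1.shape[1]:
        raise ValueError("complete cases must exceed full-model parameter count")
    _check_full_rank(X1, names1)
    fit0 = sm.OLS(yc, X0).fit()
    fit1 = sm.OLS(yc, X1).fit()
    f, p, df1 = fit1.compare_f_test(fit0)
    return ModelComparisonResult(
        outcome=outcome, F=float(f), df1=int(df1), df2=int(fit1.df_resid),
        p=float(p), n=n,
    )


def fitted_scores(y, base: pd.DataFrame, added: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Fitted values of the full (base + features) OLS model.

    Returns (mask of complete cases, fitted values on those cases).
    """
    y = np.asarray(y, float)
    mask = ~np.isnan(y)
    mask &= ~base.isna().any(axis=1).to_numpy()
    mask &= ~added.isna().any(axis=1).to_numpy()
    X0, n0 = build_design(base.loc[mask].reset_index(drop=True))
    Xa, na = build_design(added.loc[mask].reset_index(drop=True))
    X1 = np.hstack([X0, Xa[:, 1:]])
    _check_full_rank(X1, n0 + na[1:])
    fit = sm.OLS(y[mask], X1).fit()
    return mask, np.asarray(fit.fittedvalues)


def discriminant_validity(
    outcomes: pd.DataFrame,
    base: pd.DataFrame,
    added: pd.DataFrame,
    predict: tuple[str, ...] = ("scared_total", "cesdc_total"),
    compare_to: dict[str, tuple[str, ...]] | None = None,
) -> pd.DataFrame:
    """Correlate model-predicted instrument scores with the other instruments.

    For each predicted outcome (fitted values of the full linear model) the
    plain Spearman correlation with each comparator's observed totals is
    reported — convergent when the comparator measures a related construct,
    discriminant when it should not (ASRS).
    """
    if compare_to is None:
        compare_to = {
            "scared_total": ("cesdc_total", "asrs_total"),
            "cesdc_total": ("scared_total", "asrs_total"),
        }
    rows = []
    for outc in predict:
        mask, pred = fitted_scores(outcomes[outc].to_numpy(float), base, added)
        for other in compare_to[outc]:
            obs = outcomes[other].to_numpy(float)[mask]
            ok = ~np.isnan(obs)
            r, p = sps.spearmanr(pred[ok], obs[ok])
            rows.append({
                "predicted": outc, "observed": other,
                "r": float(r), "p": float(p), "n": int(ok.sum()),
            })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# multiple testing


def bh_qvalues(p) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values."""
    p = np.asarray(p, float)
    n = len(p)
    order = np.argsort(p)
    ranked = p[order] * n / (np.arange(n) + 1)
    q = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(q, 1.0)
    return out
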