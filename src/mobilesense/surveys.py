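"""Scoring for the three self-report instruments.

* SCARED (anxiety screen, 33-item version): items 0-2, total = sum, range 0-66.
* CES-DC (depression scale for children, 20 items): items 0-3; the four
  positively-worded items (4, 8, 12, 16, 1-based) are reverse-scored as
  ``3 - raw``; total range 0-60.
* ASRS (adult ADHD self-report, 18 items): frequency items 0-4 summed
  dimensionally, range 0-72.

Missing items are imputed with the participant's mean over answered items
of the same instrument when at least 80% of items are answered; otherwise
the total is missing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

INSTRUMENTS = ("SCARED33", "CESDC", "ASRS")

N_ITEMS = {"SCARED33": 33, "CESDC": 20, "ASRS": 18}
ITEM_MAX = {"SCARED33": 2, "CESDC": 3, "ASRS": 4}
TOTAL_MAX = {"SCARED33": 66, "CESDC": 60, "ASRS": 72}

# 1-based indices of reverse-keyed (positively worded) CES-DC items.
CESDC_REVERSE_ITEMS = (4, 8, 12, 16)

MIN_COMPLETENESS = 0.8


@dataclass(frozen=True)
class ScoreSet:
    """Instrument totals for one participant (NaN when incomplete)."""

    participant_id: str
    scared_total: float
    cesdc_total: float
    asrs_total: float


def _validate_items(items, instrument: str) -> np.ndarray:
    items = np.asarray(items, dtype=float)
    k = N_ITEMS[instrument]
    if items.shape != (k,):
        raise ValueError(f"{instrument} expects {k} items, got shape {items.shape}")
    answered = ~np.isnan(items)
    vals = items[answered]
    if ((vals < 0) | (vals > ITEM_MAX[instrument]) | (vals != np.round(vals))).any():
        raise ValueError(
            f"{instrument} items must be integers in [0, {ITEM_MAX[instrument]}]"
        )
    return items


def _sum_with_imputation(scored: np.ndarray) -> float:
    answered = ~np.isnan(scored)
    completeness = answered.mean()
    if completeness < MIN_COMPLETENESS:
        return float("nan")
    if answered.all():
        return float(scored.sum())
    mean = scored[answered].mean()
    return float(scored[answered].sum() + mean * (~answered).sum())


def score_scared(items) -> float:
    """Sum the 33 SCARED items (0-2 each)."""
    return _sum_with_imputation(_validate_items(items, "SCARED33"))


def score_cesdc(items, reverse_items: tuple[int, ...] = CESDC_REVERSE_ITEMS) -> float:
    """Sum the 20 CES-DC items with the standard reverse key applied."""
    items = _validate_items(items, "CESDC")
    scored = items.copy()
    for i in reverse_items:
        scored[i - 1] = 3 - items[i - 1]  # NaN propagates
    return _sum_with_imputation(scored)


def score_asrs(items) -> float:
    """Sum the 18 ASRS frequency items (0-4 each), dimensional use."""
    return _sum_with_imputation(_validate_items(items, "ASRS"))


_SCORERS = {"SCARED33": score_scared, "CESDC": score_cesdc, "ASRS": score_asrs}


def score_surveys(surveys: pd.DataFrame) -> pd.DataFrame:
    """Score a long-format survey table into per-participant totals.

    ``surveys`` columns: ``participant_id``, ``instrument``, ``item_1`` ...
    ``item_33`` (cells beyond an instrument's length are ignored; blanks
    within it are missing answers).  Returns one row per participant with
    ``scared_total``, ``cesdc_total``, ``asrs_total``.
    """
    item_cols = [c for c in surveys.columns if c.startswith("item_")]
    item_cols.sort(key=lambda c: int(c.split("_")[1]))
    totals: dict[str, dict[str, float]] = {}
    for row in surveys.itertuples(index=False):
        inst = row.instrument
        if inst not in INSTRUMENTS:
            raise ValueError(f"unknown instrument {inst!r}")
        k = N_ITEMS[inst]
        raw = [getattr(row, c) for c in item_cols[:k]]
        items = pd.to_numeric(pd.Series(raw), errors="coerce").to_numpy(float)
        totals.setdefault(str(row.participant_id), {})[inst] = _SCORERS[inst](items)
    rows = [
        {
            "participant_id": pid,
            "scared_total": vals.get("SCARED33", np.nan),
            "cesdc_total": vals.get("CESDC", np.nan),
            "asrs_total": vals.get("ASRS", np.nan),
        }
        for pid, vals in totals.items()
    ]
    return pd.DataFrame(rows, columns=["participant_id", "scared_total", "cesdc_total", "asrs_total"])


def write_surveys(surveys: pd.DataFrame, path) -> None:
    surveys.to_csv(path, index=False, lineterminator="\n")


def read_surveys(path) -> pd.DataFrame:
    return pd.read_csv(path, dtype={"participant_id": str}, keep_default_na=True)
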