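"""Longitudinal score dynamics: per-patient slope and median dichotomy.

The slope summarises a patient's score trajectory on treatment: an
ordinary least-squares fit of score (percentage points) on days elapsed
since T1, the first blood draw after treatment start.  Points are included
from T1 through the progression date (progression-free survival analysis)
or through 60 days after progression (overall survival analysis).

Eligibility mirrors the windows used for cohort analyses: at least three
draws dated before progression, and at least one draw inside the
progression window -- [progression - 120 d, progression] for PFS,
[progression - 120 d, progression + 60 d] for OS.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd

from .errors import DelfiTFError

Analysis = Literal["PFS", "OS"]

WINDOW_BEFORE_DAYS = 120
OS_WINDOW_AFTER_DAYS = 60


def _as_date(value) -> dt.date:
    if isinstance(value, dt.datetime):
        return value.date()
    if isinstance(value, dt.date):
        return value
    if isinstance(value, pd.Timestamp):
        return value.date()
    return dt.date.fromisoformat(str(value))


@dataclass
class LongitudinalSeries:
    """Dated scores for one patient, anchored at the first post-treatment draw."""

    patient_id: str
    points: list[tuple[dt.date, float]]
    t1_date: dt.date
    progression_date: dt.date | None = None

    def __post_init__(self) -> None:
        self.points = sorted(
            [(_as_date(d), float(v)) for d, v in self.points], key=lambda p: p[0]
        )
        self.t1_date = _as_date(self.t1_date)
        if self.progression_date is not None:
            self.progression_date = _as_date(self.progression_date)
        if any(v < 0 for _, v in self.points):
            raise DelfiTFError(f"negative score in series for {self.patient_id}")
        if any(d < self.t1_date for d, _ in self.points):
            raise DelfiTFError(
                f"series for {self.patient_id} contains draws before t1_date"
            )


@dataclass
class SlopeResult:
    patient_id: str
    analysis: str
    slope: float  # percentage points per day; NaN when undefined
    n_points: int
    eligible: bool
    reason: str = ""
    above_median: bool | None = None


def eligibility(series: LongitudinalSeries, analysis: Analysis) -> tuple[bool, str]:
    """Apply the draw-count and progression-window eligibility rule.

    Returns ``(eligible, reason)``; the reason is empty when eligible.
    """
    if analysis not in ("PFS", "OS"):
        raise ValueError(f"analysis must be 'PFS' or 'OS', got {analysis!r}")
    if series.progression_date is None:
        return False, "no_progression_date"
    prog = series.progression_date
    n_before = sum(1 for d, _ in series.points if d < prog)
    if n_before < 3:
        return False, f"only_{n_before}_samples_before_progression"
    win_lo = prog - dt.timedelta(days=WINDOW_BEFORE_DAYS)
    win_hi = prog if analysis == "PFS" else prog + dt.timedelta(days=OS_WINDOW_AFTER_DAYS)
    if not any(win_lo <= d <= win_hi for d, _ in series.points):
        return False, "no_sample_in_progression_window"
    return True, ""


def delfi_tf_slope(series: LongitudinalSeries, analysis: Analysis) -> SlopeResult:
    """OLS slope of score on days since T1 over the analysis window.

    Includes draws from ``t1_date`` through the progression date (PFS) or
    progression + 60 days (OS).  Fewer than two included points leave the
    slope undefined (NaN, flagged in ``reason``).
    """
    eligible, reason = eligibility(series, analysis)
    prog = series.progression_date
    if prog is None:
        return SlopeResult(series.patient_id, analysis, float("nan"), 0, False, reason)
    end = prog if analysis == "PFS" else prog + dt.timedelta(days=OS_WINDOW_AFTER_DAYS)
    included = [(d, v) for d, v in series.points if series.t1_date <= d <= end]
    if len(included) < 2:
        return SlopeResult(series.patient_id, analysis, float("nan"), len(included),
                           eligible, reason or "fewer_than_2_points")
    days = np.array([(d - series.t1_date).days for d, _ in included], float)
    vals = np.array([v for _, v in included], float)
    slope = float(np.polyfit(days, vals, 1)[0])
    return SlopeResult(series.patient_id, analysis, slope, len(included), eligible, reason)


def dichotomize(slopes: list[SlopeResult]) -> list[SlopeResult]:
    """Flag eligible slopes above/below the cohort median.

    The median is taken over eligible, defined slopes (>= 2 required).
    Strictly greater -> above; equal to the median counts as below (the
    deterministic, conservative tie rule).  Ineligible or undefined slopes
    keep ``above_median = None``.
    """
    usable = [s for s in slopes if s.eligible and np.isfinite(s.slope)]
    if len(usable) < 2:
        raise DelfiTFError("dichotomization needs >= 2 eligible slopes")
    med = float(np.median([s.slope for s in usable]))
    for s in slopes:
        s.above_median = (s.slope > med) if (s.eligible and np.isfinite(s.slope)) else None
    return slopes


def series_from_tables(
    scores: pd.DataFrame, clinical: pd.DataFrame, score_col: str = "delfi_tf"
) -> list[LongitudinalSeries]:
    """Join a score table with clinical metadata into per-patient series.

    ``scores`` needs ``patient_id``, ``date`` and the score column;
    ``clinical`` needs ``patient_id``, ``treatment_start`` and
    ``progression_date`` (empty for no progression).  T1 is the earliest
    draw strictly after treatment start; earlier draws are excluded.
    Patients without a post-treatment draw are skipped.
    """
    clin = clinical.set_index("patient_id")
    out = []
    for pid, grp in scores.groupby("patient_id"):
        if pid not in clin.index:
            continue
        row = clin.loc[pid]
        start = _as_date(row["treatment_start"])
        prog = row.get("progression_date")
        prog = None if (prog is None or (isinstance(prog, float) and np.isnan(prog))
                        or str(prog) in ("", "NA", "nan", "NaT")) else _as_date(prog)
        pts = [(_as_date(d), float(v)) for d, v in zip(grp["date"], grp[score_col])
               if _as_date(d) > start]
        if not pts:
            continue
        t1 = min(d for d, _ in pts)
        out.append(LongitudinalSeries(str(pid), pts, t1, prog))
    return out


def slope_table(
    scores: pd.DataFrame, clinical: pd.DataFrame, analysis: Analysis,
    score_col: str = "delfi_tf",
) -> pd.DataFrame:
    """Per-patient slopes with eligibility and median dichotomy, as a table."""
    series = series_from_tables(scores, clinical, score_col=score_col)
    slopes = [delfi_tf_slope(s, analysis) for s in series]
    if sum(1 for s in slopes if s.eligible and np.isfinite(s.slope)) >= 2:
        dichotomize(slopes)
    return pd.DataFrame(
        {
            "patient_id": [s.patient_id for s in slopes],
            "analysis": [s.analysis for s in slopes],
            "slope": [s.slope for s in slopes],
            "n_points": [s.n_points for s in slopes],
            "eligible": [s.eligible for s in slopes],
            "above_median": [s.above_median for s in slopes],
            "reason": [s.reason for s in slopes],
        }
    )
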