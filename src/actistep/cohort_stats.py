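"""Cohort-level change-score statistics.

Pearson correlations between changes in traditional clinical measures and
changes in digital activity measures are computed on complete, pairwise
observations (no imputation), with per-pair n accounting and a low-n flag.
Change-on-change regressions are ordinary least squares on complete cases,
both per-predictor and jointly. These analyses are exploratory and
descriptive: no multiplicity adjustment and no confidence intervals by
default (bootstrap CIs are available behind a flag).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .types import (
    AnalysisSetMembership,
    PeriodSummary,
    ValidationError,
    VisitRecord,
    WalkTestEndpoints,
)

#: change-table columns
TRADITIONAL_MEASURES = (
    "six_mwd_m",
    "borg",
    "bnp_ng_l",
    "ntprobnp_ng_l",
    "eq5d_index",
    "psqi_global",
    "resting_hr_bpm",
)
DIGITAL_MEASURES = (
    "daily_distance_m",
    "daily_steps",
    "daily_standups",
    "digital_6mwd_m",
)

#: maps activity PeriodSummary measure names onto change-table columns
_ACTIVITY_COLUMNS = {
    "distance_m": "daily_distance_m",
    "steps": "daily_steps",
    "standups": "daily_standups",
    "resting_hr_bpm": "resting_hr_bpm",
}

_VISIT_FIELDS = ("six_mwd_m", "borg", "bnp_ng_l", "ntprobnp_ng_l", "eq5d_index", "psqi_global")


def build_change_table(
    activity_summaries: Mapping[str, Mapping[str, PeriodSummary]],
    visits: Sequence[VisitRecord],
    walk_endpoints: Mapping[tuple[str, str], WalkTestEndpoints],
    membership: Mapping[str, AnalysisSetMembership],
) -> pd.DataFrame:
    """One row of change scores per full-analysis-set patient.

    Visit-based changes are final minus initial; activity-based changes come
    from the period summaries. Absent inputs propagate to absent cells.
    """
    by_visit = {(v.patient_id, v.visit): v for v in visits}
    rows = {}
    for pid in sorted(membership):
        if not membership[pid].in_full_set:
            continue
        row: dict[str, float] = {}
        initial = by_visit.get((pid, "initial"))
        final = by_visit.get((pid, "final"))
        for f in _VISIT_FIELDS:
            a = getattr(initial, f, None) if initial else None
            b = getattr(final, f, None) if final else None
            row[f] = b - a if a is not None and b is not None else np.nan
        summaries = activity_summaries.get(pid, {})
        for measure, col in _ACTIVITY_COLUMNS.items():
            s = summaries.get(measure)
            row[col] = s.change if s is not None and s.change is not None else np.nan
        e0 = walk_endpoints.get((pid, "initial"))
        e1 = walk_endpoints.get((pid, "final"))
        if e0 is not None and e1 is not None and e0.digital_6mwd_m is not None and e1.digital_6mwd_m is not None:
            row["digital_6mwd_m"] = e1.digital_6mwd_m - e0.digital_6mwd_m
        else:
            row["digital_6mwd_m"] = np.nan
        rows[pid] = row
    columns = list(dict.fromkeys([*TRADITIONAL_MEASURES, *DIGITAL_MEASURES]))
    table = pd.DataFrame.from_dict(rows, orient="index", columns=columns)
    table.index.name = "patient_id"
    return table


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    xc = x - x.mean()
    yc = y - y.mean()
    return float((xc @ yc) / np.sqrt((xc @ xc) * (yc @ yc)))


def pearson_pairwise(
    table: pd.DataFrame,
    traditional: Sequence[str] = TRADITIONAL_MEASURES,
    digital: Sequence[str] = DIGITAL_MEASURES,
    low_n_threshold: int = 10,
    complete_cases: bool = False,
) -> pd.DataFrame:
    """Pairwise-complete Pearson r for every (traditional, digital) pair.

    ``complete_cases=True`` restricts every pair to rows complete across all
    requested columns (the planned sensitivity analysis). r is absent when
    fewer than 2 pairs remain or either column is constant.
    """
    base = table
    if complete_cases:
        base = table.dropna(subset=[*traditional, *digital])
    rows = []
    for t in traditional:
        for d in digital:
            sub = base[[t, d]].dropna()
            n = len(sub)
            r: Optional[float] = None
            note = ""
            if n < 2:
                note = "insufficient_pairs"
            else:
                x = sub[t].to_numpy(dtype=float)
                y = sub[d].to_numpy(dtype=float)
                if np.ptp(x) == 0 or np.ptp(y) == 0:
                    note = "zero_variance"
                else:
                    r = _pearson(x, y)
            rows.append(
                {
                    "traditional": t,
                    "digital": d,
                    "r": np.nan if r is None else r,
                    "n_pairs": n,
                    "low_n_flag": n < low_n_threshold,
                    "note": note,
                }
            )
    return pd.DataFrame(rows)


@dataclass
class RegressionFit:
    """OLS fit of a traditional change on digital change predictor(s)."""

    dependent: str
    predictors: tuple[str, ...]
    intercept: float
    coefficients: dict[str, float]
    r_squared: float
    n: int


def change_regression(
    table: pd.DataFrame, dependent: str, predictors: Sequence[str]
) -> RegressionFit:
    """OLS of a traditional change score on digital change scores.

    Complete cases only; raises on too few rows or a rank-deficient design
    (naming the collinear predictors).
    """
    cols = [dependent, *predictors]
    sub = table[cols].dropna()
    n = len(sub)
    if n < len(predictors) + 2:
        raise ValidationError(
            f"only {n} complete cases for {dependent} ~ {list(predictors)}; "
            f"need at least {len(predictors) + 2}"
        )
    X = sub[list(predictors)].to_numpy(dtype=float)
    design = sm.add_constant(X, has_constant="add")
    if np.linalg.matrix_rank(design) < design.shape[1]:
        collinear = _collinear_columns(X, list(predictors))
        raise ValidationError(f"rank-deficient design; collinear predictors: {collinear}")
    y = sub[dependent].to_numpy(dtype=float)
    fit = sm.OLS(y, design).fit()
    return RegressionFit(
        dependent=dependent,
        predictors=tuple(predictors),
        intercept=float(fit.params[0]),
        coefficients={p: float(c) for p, c in zip(predictors, fit.params[1:])},
        r_squared=float(fit.rsquared),
        n=n,
    )


def _collinear_columns(X: np.ndarray, names: list[str]) -> list[str]:
    kept: list[int] = []
    flagged: list[str] = []
    for j in range(X.shape[1]):
        cand = np.column_stack([np.ones(len(X))] + [X[:, k] for k in kept + [j]])
        if np.linalg.matrix_rank(cand) == cand.shape[1]:
            kept.append(j)
        else:
            flagged.append(names[j])
    return flagged


def standard_regressions(
    table: pd.DataFrame,
    dependent: str = "six_mwd_m",
    joint_predictors: Sequence[str] = ("daily_distance_m", "daily_standups", "digital_6mwd_m"),
) -> dict[str, RegressionFit]:
    """Single-predictor fits for each digital measure plus the joint fit."""
    fits: dict[str, RegressionFit] = {}
    for d in DIGITAL_MEASURES:
        try:
            fits[d] = change_regression(table, dependent, [d])
        except ValidationError:
            continue
    try:
        fits["joint"] = change_regression(table, dependent, list(joint_predictors))
    except ValidationError:
        pass
    return fits


def bootstrap_ci(
    table: pd.DataFrame,
    traditional: str,
    digital: str,
    n_boot: int = 2000,
    alpha: float = 0.05,
    seed: int = 0,
) -> Optional[tuple[float, float]]:
    """Seeded percentile bootstrap CI for one pairwise correlation."""
    sub = table[[traditional, digital]].dropna().to_numpy(dtype=float)
    if len(sub) < 3:
        return None
    rng = np.random.default_rng(seed)
    stats = []
    for _ in range(n_boot):
        idx = rng.integers(0, len(sub), len(sub))
        x, y = sub[idx, 0], sub[idx, 1]
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            continue
        stats.append(_pearson(x, y))
    lo, hi = np.percentile(stats, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    return float(lo), float(hi)
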