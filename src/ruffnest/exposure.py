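"""Daily exposure histories under mortality scenarios and dataset variants.

Each nest's record is turned into a Bernoulli survival history over the
transitions t = 1..26 after the lay day (t = 0, alive by definition).  Three
mortality scenarios decide which fates count as failures:

``overall``
    every death (predation, flooding, trampling, abandonment, unknown-cause
    death) is a failure; unknown / escaped fates are censored.
``no_predation``
    flooding, trampling and abandonment are failures; predation is censored
    on the date of failure; unknown-cause deaths are censored (the cause
    cannot be attributed).
``predation``
    only predation is a failure; all other deaths are censored.

Two dataset variants decide how protected (dummy-egg) nests enter:

``all_nests``
    final fates, with the artificial-incubation indicator as a covariate.
``natural_only``
    fates up to human intervention only: flood-protected clutches are
    recorded as failed on the intervention day (they would have flooded);
    trampling-protected clutches are censored on the intervention day
    (trampling is an ongoing threat with no predictable failure day).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .records import (ACTIVITY_CAP_DAYS, FAILURE_FATES, ExposureHistory,
                      NestRecord)

#: fates treated as failures per scenario
SCENARIO_FAILURES = {
    "overall": set(FAILURE_FATES),
    "no_predation": {"flooded", "trampled", "abandoned"},
    "predation": {"predated"},
}

SCALED_COVARIATES = ("dist_nests", "dist_leks", "dist_paths",
                     "dist_edge", "dist_shore", "lay_date")


def estimate_timeline(hatch_day: int, clutch_size: int) -> tuple[int, int]:
    """Back-date a nest's lay day from its (expected) hatch day.

    Uses a 21-day incubation period and a laying interval of 1.25 days per
    egg after the first: incubation_onset = hatch_day - 21 and
    lay_day = round(incubation_onset - 1.25 * (clutch_size - 1)), rounding
    half up.
    """
    if clutch_size < 1:
        raise ValueError("clutch_size must be >= 1")
    incubation_onset = hatch_day - 21
    lay = math.floor(incubation_onset - 1.25 * (clutch_size - 1) + 0.5)
    if lay < 0:
        raise ValueError(
            f"estimated lay day {lay} is negative: season frame too small")
    return lay, incubation_onset


def cap_activity(record: NestRecord) -> NestRecord:
    """Truncate a nest's modeled activity at 26 days after laying.

    A failure recorded beyond the cap never happens inside the modeled
    window, so the nest counts as having survived it.
    """
    cap = record.lay_day + ACTIVITY_CAP_DAYS
    if record.end_day <= cap:
        return record
    fate = "hatched" if record.fate in FAILURE_FATES else record.fate
    kwargs = {"end_day": cap, "fate": fate}
    if record.intervention_day is not None and record.intervention_day > cap:
        kwargs["intervention_day"] = cap
    return record.copy(**kwargs)


def _history(nest_id, scenario, variant, n_ones, failed) -> ExposureHistory:
    y = (1,) * n_ones + ((0,) if failed else ())
    return ExposureHistory(nest_id=nest_id, scenario=scenario, variant=variant,
                           y=y, terminal="failed" if failed else "censored")


def encode_scenario_history(record: NestRecord, scenario: str,
                            variant: str) -> ExposureHistory:
    """Encode one nest's daily outcomes under a scenario x variant.

    Censoring convention: a nest censored on its failure (or intervention)
    day is informative through the previous day only, except that
    trampling-protected nests in the natural-only variant count as alive on
    the intervention day itself (the clutch was collected intact).
    """
    if scenario not in SCENARIO_FAILURES:
        raise ValueError(f"unknown scenario {scenario!r}")
    record = cap_activity(record)
    T = record.end_day - record.lay_day  # transitions, <= 26

    if variant == "natural_only" and record.protected_cause != "none":
        r_int = min(record.intervention_day - record.lay_day, ACTIVITY_CAP_DAYS)
        if record.protected_cause == "flood":
            # the clutch would have flooded: failure on the intervention day,
            # but only in scenarios where flooding is a failure
            if "flooded" in SCENARIO_FAILURES[scenario]:
                return _history(record.nest_id, scenario, variant,
                                r_int - 1, failed=True)
            return _history(record.nest_id, scenario, variant,
                            r_int - 1, failed=False)
        # trampling-protected: censored alive at the intervention day
        return _history(record.nest_id, scenario, variant, r_int, failed=False)

    fate = record.fate
    if fate == "hatched":
        return ExposureHistory(record.nest_id, scenario, variant,
                               (1,) * T, "survived_window")
    if fate in ("unknown", "escaped"):
        # censored at the last day known active
        return _history(record.nest_id, scenario, variant, T, failed=False)
    if fate in FAILURE_FATES:
        if fate in SCENARIO_FAILURES[scenario]:
            return _history(record.nest_id, scenario, variant, T - 1, failed=True)
        return _history(record.nest_id, scenario, variant, T - 1, failed=False)
    raise ValueError(f"nest {record.nest_id}: unknown fate label {fate!r}")


def encode_dataset(nests, scenario: str, variant: str) -> list[ExposureHistory]:
    return [encode_scenario_history(n, scenario, variant) for n in nests]


def scale_covariates_within_year(table: pd.DataFrame, columns=None):
    """Centre and scale covariates around their yearly means.

    For each covariate and year: (x - year mean) / year sample SD.  A column
    with zero within-year variance scales to 0 with a warning; missing
    values also scale to 0 (the year mean).  Returns (scaled table,
    scaling dict ``{column: {year: (mean, sd)}}``); quadratic terms are to
    be taken as squares of the scaled linear term.
    """
    if columns is None:
        columns = [c for c in SCALED_COVARIATES if c in table.columns]
    scaled = table.copy()
    scaled[columns] = scaled[columns].astype(float)
    scaling: dict[str, dict[int, tuple[float, float]]] = {c: {} for c in columns}
    for year, idx in table.groupby("year").groups.items():
        for col in columns:
            x = pd.to_numeric(table.loc[idx, col], errors="coerce").astype(float)
            m = x.mean()
            sd = x.std(ddof=1)
            if not np.isfinite(sd) or sd == 0:
                warnings.warn(f"covariate {col} has zero variance in year {year}; "
                              "scaled values set to 0")
                sd = 1.0
                z = pd.Series(0.0, index=idx)
            else:
                z = (x - m) / sd
            if z.isna().any():
                warnings.warn(f"covariate {col} has missing values in year {year}; "
                              "imputed at the year mean (scaled 0)")
                z = z.fillna(0.0)
            scaled.loc[idx, col] = z
            scaling[col][year] = (float(m) if np.isfinite(m) else 0.0, float(sd))
    return scaled, scaling


#: canonical design columns for the daily-survival model (all-nests variant)
DESIGN_COLUMNS = ("intercept", "dist_nests", "dist_nests_sq", "dist_leks",
                  "dist_leks_sq", "lay_date", "nest_age", "incubation",
                  "dist_paths", "dist_edge", "dist_shore")


@dataclass
class DesignMatrices:
    """Stacked nest-day design for one scenario x variant."""

    X: np.ndarray              # (n_rows, p)
    y: np.ndarray              # (n_rows,) 0/1 survival outcomes
    year_index: np.ndarray     # (n_rows,) 0-based year index
    nest_ids: np.ndarray       # (n_rows,)
    columns: tuple[str, ...]
    years: tuple[int, ...]
    scenario: str
    variant: str
    scaling: dict              # static covariate scaling, per year
    age_scaling: dict          # year -> (mean, sd) of the day index

    @property
    def n_exposure_days(self) -> int:
        return len(self.y)

    @property
    def n_failures(self) -> int:
        return int((self.y == 0).sum())

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.X, columns=list(self.columns))
        df.insert(0, "nest_id", self.nest_ids)
        df.insert(1, "year", [self.years[i] for i in self.year_index])
        df["y"] = self.y
        return df


def build_design(nests, distance_table: pd.DataFrame, scenario: str,
                 variant: str) -> DesignMatrices:
    """Assemble the nest-day design matrix for one scenario x variant.

    ``distance_table`` is the per-nest covariate table from
    :func:`ruffnest.geospatial.nest_distance_table` (indexed by nest_id,
    with a ``year`` column).  Static covariates are scaled within year over
    nests; nest age is the day index t scaled within year over all realized
    nest-day rows.  The natural-only variant drops the incubation column.
    """
    table = distance_table.copy()
    by_id = {n.nest_id: n for n in nests}
    table["lay_date"] = [by_id[i].lay_day for i in table.index]
    scaled, scaling = scale_covariates_within_year(table)

    histories = encode_dataset(nests, scenario, variant)
    columns = tuple(c for c in DESIGN_COLUMNS
                    if not (variant == "natural_only" and c == "incubation"))
    years = tuple(sorted({n.year for n in nests}))
    year_pos = {yr: i for i, yr in enumerate(years)}

    rows, ys, yidx, ids, ages = [], [], [], [], []
    for h in histories:
        if len(h.y) == 0:
            continue
        n = by_id[h.nest_id]
        r = scaled.loc[n.nest_id]
        static = {
            "intercept": 1.0,
            "dist_nests": r["dist_nests"],
            "dist_nests_sq": r["dist_nests"] ** 2,
            "dist_leks": r["dist_leks"],
            "dist_leks_sq": r["dist_leks"] ** 2,
            "lay_date": r["lay_date"],
            "incubation": float(n.artificially_incubated),
            "dist_paths": r["dist_paths"],
            "dist_edge": r["dist_edge"],
            "dist_shore": r["dist_shore"],
        }
        for t, outcome in enumerate(h.y, start=1):
            rows.append([static.get(c, 0.0) if c != "nest_age" else float(t)
                         for c in columns])
            ys.append(outcome)
            yidx.append(year_pos[n.year])
            ids.append(n.nest_id)
            ages.append(t)

    X = np.asarray(rows, dtype=float)
    y = np.asarray(ys, dtype=float)
    year_index = np.asarray(yidx, dtype=int)

    # a constant non-intercept column (e.g. the incubation indicator when no
    # clutch was protected) carries no information and leaves its
    # coefficient equal to its prior; drop it rather than sample a
    # heavy-tailed unidentified direction
    keep = []
    for j, c in enumerate(columns):
        if c != "intercept" and np.ptp(X[:, j]) == 0:
            warnings.warn(f"design column {c} is constant; dropped")
        else:
            keep.append(j)
    if len(keep) < len(columns):
        X = X[:, keep]
        columns = tuple(columns[j] for j in keep)

    age_col = columns.index("nest_age")
    age_scaling = {}
    for yr in years:
        mask = year_index == year_pos[yr]
        a = X[mask, age_col]
        m, sd = a.mean(), a.std(ddof=1)
        if not np.isfinite(sd) or sd == 0:
            sd = 1.0
        X[mask, age_col] = (a - m) / sd
        age_scaling[yr] = (float(m), float(sd))

    return DesignMatrices(X=X, y=y, year_index=year_index,
                          nest_ids=np.asarray(ids), columns=columns,
                          years=years, scenario=scenario, variant=variant,
                          scaling=scaling, age_scaling=age_scaling)


def histories_to_frame(histories) -> pd.DataFrame:
    """Long-format exposure table (nest_id, scenario, variant, day, y)."""
    rows = []
    for h in histories:
        for t, v in enumerate(h.y, start=1):
            rows.append((h.nest_id, h.scenario, h.variant, t, v))
    return pd.DataFrame(rows, columns=["nest_id", "scenario", "variant",
                                       "day", "y"])
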