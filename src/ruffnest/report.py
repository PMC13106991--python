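"""Summary outputs: fate tables, posterior tables, prediction curves.

Percentages are rounded to one decimal place in the printed tables; the
underlying counts are always carried alongside so the percentages can be
recomputed exactly.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.special import expit

from .dsrmodel import PosteriorDraws, classify_effects
from .records import ACTIVITY_CAP_DAYS, FAILURE_FATES

FAILURE_CAUSE_LABELS = {
    "predated": "predation",
    "abandoned": "abandonment",
    "trampled": "trampling",
    "flooded": "flooding",
    "unknown_dead": "unknown",
}


def _effective_fates(nests, variant: str):
    """(nest, fate-or-None) after variant-specific rewriting; None = censored
    out of the fate table (trampling-protected in the natural-only variant)."""
    out = []
    for n in nests:
        fate = n.fate
        if variant == "natural_only" and n.protected_cause != "none":
            fate = "flooded" if n.protected_cause == "flood" else None
        out.append((n, fate))
    return out


def fate_summary_table(nests, variant: str = "all_nests") -> pd.DataFrame:
    """Hatching success and failure-cause shares, per year and pooled.

    Hatch percentage is computed among fate-known nests (unknown / escaped
    and variant-censored nests excluded); cause percentages are shares of
    the failed nests.  Zero failed nests yields missing cause shares.
    """
    rows = []
    years = sorted({n.year for n in nests})
    for label, year in [(str(y), y) for y in years] + [("pooled", None)]:
        sub = [(n, f) for n, f in _effective_fates(nests, variant)
               if year is None or n.year == year]
        known = [f for _, f in sub if f in ("hatched",) + FAILURE_FATES]
        n_hatched = sum(1 for f in known if f == "hatched")
        failures = [f for f in known if f != "hatched"]
        row = {
            "year": label,
            "n_nests": len(sub),
            "n_known_fate": len(known),
            "n_hatched": n_hatched,
            "hatched_pct": round(100.0 * n_hatched / len(known), 1)
            if known else np.nan,
            "n_failed": len(failures),
        }
        for fate, cause in FAILURE_CAUSE_LABELS.items():
            count = sum(1 for f in failures if f == fate)
            row[f"{cause}_pct_of_failed"] = (
                round(100.0 * count / len(failures), 1) if failures else np.nan)
        rows.append(row)
    return pd.DataFrame(rows)


def protected_outcome_breakdown(nests) -> pd.DataFrame:
    """Outcome counts of protected nests, by protected cause.

    Only artificially incubated clutches (protected > 24 h) are counted,
    since short egg swaps are excluded from the intervention cohort.
    """
    rows = []
    for cause in ("flood", "trampling"):
        cohort = [n for n in nests
                  if n.protected_cause == cause and n.artificially_incubated]
        row = {"protected_cause": cause, "n_protected": len(cohort),
               "hatched": sum(1 for n in cohort if n.fate == "hatched")}
        for fate in FAILURE_FATES:
            row[fate] = sum(1 for n in cohort if n.fate == fate)
        rows.append(row)
    return pd.DataFrame(rows)


def protected_outcome_totals(breakdown: pd.DataFrame) -> dict[str, int]:
    """Column sums of a protected-outcome table (counts by final fate)."""
    sums = breakdown.drop(columns=["protected_cause"]).sum()
    return {k: int(v) for k, v in sums.items()}


def posterior_summary_table(draws: PosteriorDraws,
                            include_u: bool = False) -> pd.DataFrame:
    """Per-parameter mean, SD, 95% CrI and clear-effect flag.

    Year rows report the composite sigma_year * u_year effects.  Raw u
    deviates are omitted unless ``include_u``.
    """
    names = [n for n in draws.names
             if include_u or not n.startswith("u_")]
    clear = classify_effects(draws, names=names)
    rows = []
    for name in names:
        x = draws.draws(name)
        lo, hi = draws.credible_interval(name)
        rows.append({"variable": name, "mean": float(x.mean()),
                     "sd": float(x.std(ddof=1)),
                     "cri_2.5": lo, "cri_97.5": hi,
                     "clear_effect": clear[name] == "clear"})
    return pd.DataFrame(rows)


def _pooled_scale(scaling_per_year) -> tuple[float, float]:
    means = [m for m, _ in scaling_per_year.values()]
    sds = [s for _, s in scaling_per_year.values()]
    return float(np.mean(means)), float(np.mean(sds))


def dsr_prediction_curve(draws: PosteriorDraws, covariate: str, grid,
                         quadratic: str | None = None) -> pd.DataFrame:
    """Posterior daily-survival curve along one covariate.

    ``grid`` is on the raw scale (metres or days); values are standardized
    through the stored year-wise scaling averaged across years.  All other
    covariates sit at their (scaled) mean of 0 and the year effect at 0, so
    the curve isolates the focal predictor.  A warning is raised for grid
    values far outside the scaled range seen in the data.  Returns mean and
    central 95% / 80% bands of S per grid value.
    """
    import warnings as _w

    grid = np.asarray(grid, dtype=float)
    if covariate == "nest_age":
        m, sd = _pooled_scale(draws.age_scaling)
    else:
        m, sd = _pooled_scale(draws.scaling[covariate])
    z = (grid - m) / sd
    if np.any(np.abs(z) > 4):
        _w.warn(f"grid extends outside the observed {covariate} range; "
                "curve is an extrapolation there")
    b0 = draws.draws("intercept")
    b1 = draws.draws(covariate)
    eta = b0[None, :] + np.outer(z, b1)
    if quadratic is not None:
        eta += np.outer(z ** 2, draws.draws(quadratic))
    s = expit(eta)
    return pd.DataFrame({
        "grid": grid, "scaled": z,
        "mean": s.mean(axis=1),
        "cri_2.5": np.quantile(s, 0.025, axis=1),
        "cri_97.5": np.quantile(s, 0.975, axis=1),
        "cri_10": np.quantile(s, 0.10, axis=1),
        "cri_90": np.quantile(s, 0.90, axis=1),
    })


def cumulative_hatch_probability(daily_s) -> float:
    """Probability of surviving the whole activity window: the product of
    the daily survival probabilities over the 26 transitions."""
    s = np.asarray(daily_s, dtype=float)
    if s.size != ACTIVITY_CAP_DAYS:
        raise ValueError(f"expected {ACTIVITY_CAP_DAYS} daily probabilities, "
                         f"got {s.size}")
    return float(np.prod(s))


def plot_prediction_curve(curve: pd.DataFrame, ax=None, color="C0",
                          label=None):
    """Mean curve with dashed 95% CrI and shaded 80% CrI band."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.plot(curve["grid"], curve["mean"], color=color, label=label)
    ax.plot(curve["grid"], curve["cri_2.5"], "--", color=color, lw=0.8)
    ax.plot(curve["grid"], curve["cri_97.5"], "--", color=color, lw=0.8)
    ax.fill_between(curve["grid"], curve["cri_10"], curve["cri_90"],
                    color=color, alpha=0.2)
    ax.set_ylabel("daily nest survival probability")
    return ax
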