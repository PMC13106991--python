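"""Synthetic nest-dataset generator.

Produces multi-year nest datasets with the statistical and spatial structure
the survival analysis assumes: nests scattered in a band between shoreline
and meadow edge, daily mortality from four competing causes (flooding on
discrete storm-surge days, cattle trampling after the release day inside the
grazing zone, predation from a logit daily-survival model, and background
abandonment), and a dummy-egg clutch-protection intervention.

Competing risks are resolved in a fixed daily order
(flood -> trampling -> predation -> abandonment): floods are day-specific
catastrophes and take precedence, while predation and abandonment are
background hazards.  Each nest owns a counter-based random stream
(``fate_seed``), so re-simulating a nest under a protection policy reuses
the same daily uniforms (common random numbers): a policy that only lowers
hazards can never make a nest fail earlier.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.special import expit
from shapely.geometry import LineString, MultiLineString

from .config import ScenarioConfig, TrueParameters
from .geospatial import LandscapeFeatures, Lek, nest_distance_table
from .records import ACTIVITY_CAP_DAYS, NestRecord

# daily resolution order of the competing causes (columns of the U matrix)
_CAUSES = ("flood", "trampling", "predation", "abandonment")


def _sub_seed(seed: int, *key: int) -> int:
    return int(np.random.SeedSequence((seed,) + key).generate_state(1)[0] % (2**31))


def generate_landscape(config: ScenarioConfig) -> LandscapeFeatures:
    """Build the shoreline, meadow edge, paths and leks for one scenario.

    The shoreline runs along the low-y side of the meadow and the edge
    (outer fence) along the opposite side, with gentle seeded irregularity;
    paths cross the meadow parallel to the shore plus a few transects.
    Deterministic given ``config.rng_seed``.
    """
    if config.meadow_width <= 0 or config.meadow_height <= 0:
        raise ValueError("degenerate meadow extent (zero area)")
    rng = np.random.default_rng(_sub_seed(config.rng_seed, 1))
    W, H = config.meadow_width, config.meadow_height

    xs = np.linspace(0, W, 25)
    shoreline = LineString(
        np.column_stack([xs, 20 + 15 * np.sin(xs / W * 3 * np.pi) + rng.normal(0, 4, xs.size)])
    )
    # the outer fence is not parallel to the shore: the meadow widens along
    # its length, which keeps the edge-shore distance correlation strong but
    # imperfect (field scale ~ -0.7) instead of exactly -1
    meadow_edge = LineString(
        np.column_stack([xs, H - 20 + 250.0 * (xs / W - 0.5)
                         + rng.normal(0, 6, xs.size)])
    )

    lines = [np.column_stack([xs, y0 + rng.normal(0, 3, xs.size)])
             for y0 in config.path_y_positions]
    for _ in range(config.n_cross_paths):
        x0 = rng.uniform(0.15 * W, 0.85 * W)
        ys = np.linspace(60, H - 60, 12)
        lines.append(np.column_stack([x0 + rng.normal(0, 5, ys.size), ys]))
    paths = MultiLineString([LineString(c) for c in lines])

    leks = []
    if config.n_leks > 0:
        years = config.years()
        lx = rng.uniform(0.03 * W, 0.97 * W, config.n_leks)
        band_lo, band_hi = config.nest_band_y
        ly = rng.uniform(band_lo, band_hi, config.n_leks)
        # each year activates a subset of leks; guarantee >= 1 active per year
        active: list[set[int]] = [set() for _ in range(config.n_leks)]
        for year in years:
            k = min(config.leks_active_per_year, config.n_leks)
            for idx in rng.choice(config.n_leks, size=k, replace=False):
                active[idx].add(year)
        for x, y, yrs in zip(lx, ly, active):
            leks.append(Lek(float(x), float(y), frozenset(yrs)))
    return LandscapeFeatures(shoreline, meadow_edge, paths, leks)


def generate_nests(config: ScenarioConfig,
                   landscape: LandscapeFeatures) -> list[NestRecord]:
    """Place nests for every year; no fates assigned yet.

    Coordinates are uniform over the nesting band, lay dates uniform over
    [0, season_length - 27] so the full 26-day window fits in the season,
    clutch sizes in {3, 4} weighted toward 4 as in the field data.
    """
    rng = np.random.default_rng(_sub_seed(config.rng_seed, 2))
    band_lo, band_hi = config.nest_band_y
    nests: list[NestRecord] = []
    idx = 0
    for year in config.years():
        for _ in range(config.nests_per_year):
            lay = int(rng.integers(0, config.season_length - ACTIVITY_CAP_DAYS))
            nests.append(NestRecord(
                nest_id=f"N{year}-{idx:04d}",
                year=year,
                x=float(rng.uniform(0, config.meadow_width)),
                y=float(rng.uniform(band_lo, band_hi)),
                lay_day=lay,
                end_day=lay + ACTIVITY_CAP_DAYS,
                fate="unknown",
                clutch_size=int(rng.choice([3, 4], p=[0.2, 0.8])),
                fate_seed=_sub_seed(config.rng_seed, 3, idx),
            ))
            idx += 1
    return nests


def _in_grazed_zone(nest: NestRecord, zone) -> bool:
    x0, x1, y0, y1 = zone
    return x0 <= nest.x <= x1 and y0 <= nest.y <= y1


def _draw_year_effects(config: ScenarioConfig,
                       params: TrueParameters) -> np.ndarray:
    if params.year_effects is not None:
        u = np.asarray(params.year_effects, dtype=float)
        if u.size != config.n_years:
            raise ValueError("year_effects length must equal n_years")
        return u
    rng = np.random.default_rng(_sub_seed(config.rng_seed, 4))
    return rng.standard_normal(config.n_years)


def _predation_linear_predictors(nests, landscape, config, params,
                                 assume_full_windows=True):
    """Static part of the logit daily-survival predictor per nest, plus the
    per-year age scaling used for the time-varying term.

    Covariates are centred and scaled within year exactly as the analysis
    does; neighbour distances use the nests' current activity windows
    (provisional full windows on the first pass, realized windows on
    consistency iterations).
    """
    from .exposure import scale_covariates_within_year

    table = nest_distance_table(nests, landscape,
                                assume_full_windows=assume_full_windows)
    table["lay_date"] = [n.lay_day for n in nests]
    for n in nests:
        row = table.loc[n.nest_id]
        # dist_nests may be legitimately missing (no concurrently active
        # neighbour); it is mean-imputed by the scaler like the analysis does
        for cov in ("dist_leks", "dist_paths", "dist_edge", "dist_shore"):
            if row[cov] is None or not np.isfinite(row[cov]):
                raise ValueError(f"nest {n.nest_id}: missing covariate {cov}")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        scaled, _ = scale_covariates_within_year(table)

    years = config.years()
    u = _draw_year_effects(config, params)
    year_term = {yr: params.sigma_year * u[i] for i, yr in enumerate(years)}

    eta0 = {}
    for n in nests:
        r = scaled.loc[n.nest_id]
        eta0[n.nest_id] = (
            params.beta_intercept
            + params.beta_dist_nests * r["dist_nests"]
            + params.beta_dist_nests_sq * r["dist_nests"] ** 2
            + params.beta_dist_leks * r["dist_leks"]
            + params.beta_dist_leks_sq * r["dist_leks"] ** 2
            + params.beta_lay_date * r["lay_date"]
            + params.beta_dist_paths * r["dist_paths"]
            + params.beta_dist_edge * r["dist_edge"]
            + params.beta_dist_shore * r["dist_shore"]
            + year_term[n.year]
        )
    # age scaled within year over the pooled nest-day rows of the current
    # activity windows, matching the analysis-side standardization
    grid = np.arange(1, ACTIVITY_CAP_DAYS + 1, dtype=float)
    age_scaled = {}
    for yr in years:
        ages = np.concatenate([
            grid[:min(n.end_day - n.lay_day, ACTIVITY_CAP_DAYS)]
            for n in nests if n.year == yr]) if any(n.year == yr for n in nests) \
            else grid
        m, sd = ages.mean(), ages.std(ddof=1)
        if not np.isfinite(sd) or sd == 0:
            sd = 1.0
        age_scaled[yr] = (grid - m) / sd
    shore = {n.nest_id: float(table.loc[n.nest_id, "dist_shore"]) for n in nests}
    return eta0, age_scaled, shore, u


def _daily_uniforms(nest: NestRecord) -> np.ndarray:
    """(27, 4) matrix of per-day, per-cause uniforms from the nest's own
    counter-based stream; identical across repeated walks of the nest."""
    if nest.fate_seed is None:
        raise ValueError(f"nest {nest.nest_id} has no fate_seed")
    rng = np.random.Generator(np.random.Philox(key=nest.fate_seed))
    return rng.random((ACTIVITY_CAP_DAYS + 1, len(_CAUSES)))


def _walk_nest(nest, config, params, eta0, age_scaled, dist_shore,
               protection=None):
    """Simulate one nest's daily fate walk; returns (fate, end_day).

    ``protection`` is None or a dict with keys ``cause``, ``day`` (absolute
    intervention day) and ``dummy_until`` (absolute day the dummy eggs are
    removed; None = until the window ends).  From ``day`` on, the natural
    clutch is immune to the protected cause; while dummy eggs are in place,
    predation and abandonment hazards are rescaled by the dummy multipliers.
    """
    U = _daily_uniforms(nest)
    floods = {(d, reach) for (yi, d, reach) in config.flood_days
              if config.first_year + yi == nest.year}
    year_index = nest.year - config.first_year
    release = config.release_day(year_index)
    grazed = _in_grazed_zone(nest, config.grazed_zone)

    for r in range(1, ACTIVITY_CAP_DAYS + 1):
        day = nest.lay_day + r
        protected_now = protection is not None and day >= protection["day"]
        dummy_now = protected_now and (
            protection["dummy_until"] is None or day <= protection["dummy_until"]
        )
        # 1. flood
        flood_hit = any(day == d and dist_shore <= reach for d, reach in floods)
        if flood_hit and not (protected_now and protection["cause"] == "flood"):
            if U[r, 0] < params.flood_lethality:
                return "flooded", day
        # 2. trampling
        if grazed and day >= release and not (
                protected_now and protection["cause"] == "trampling"):
            if U[r, 1] < params.trampling_hazard:
                return "trampled", day
        # 3. predation
        s = expit(eta0 + params.beta_nest_age * age_scaled[r - 1])
        hazard = 1.0 - s
        if dummy_now:
            hazard *= params.dummy_predation_multiplier
        if U[r, 2] < hazard:
            return "predated", day
        # 4. abandonment
        hazard = params.abandonment_hazard
        if dummy_now:
            hazard = min(1.0, hazard * params.dummy_abandonment_multiplier)
        if U[r, 3] < hazard:
            return "abandoned", day
    return "hatched", nest.lay_day + ACTIVITY_CAP_DAYS


def simulate_daily_fates(nests, landscape, config: ScenarioConfig,
                         true_params: TrueParameters | None = None
                         ) -> list[NestRecord]:
    """Walk every nest day by day and assign its fate and end day.

    Each day the competing causes fire in the fixed order; the first event
    wins.  Survivors of all 26 transitions hatch.  Fully deterministic given
    the nests' ``fate_seed`` streams and the scenario seed.

    The neighbour-distance covariate in the predation hazard is the mean
    daily nearest-neighbour distance over *scheduled* (full 26-day) activity
    windows: generatively, spacing is a nest-level trait fixed at laying.
    The analysis later reconstructs this covariate from realized windows,
    as the field protocol does; the residual discrepancy for early-failing
    nests is a documented property of that construction, not of the
    generator.
    """
    params = true_params or config.true_params
    eta0, age_scaled, shore, _ = _predation_linear_predictors(
        nests, landscape, config, params, assume_full_windows=True)
    out = []
    for n in nests:
        fate, end = _walk_nest(n, config, params, eta0[n.nest_id],
                               age_scaled[n.year], shore[n.nest_id])
        out.append(n.copy(fate=fate, end_day=end))
    return out


def _candidate_interventions(nest, config, dist_shore):
    """(day, cause) protection candidates for one nest, earliest first."""
    pol = config.policy
    cands = []
    if pol.flood_trigger:
        for (yi, day, reach) in config.flood_days:
            if config.first_year + yi != nest.year:
                continue
            if dist_shore <= reach and nest.lay_day < day <= nest.lay_day + ACTIVITY_CAP_DAYS:
                cands.append((day, "flood"))
    if pol.trampling_trigger and _in_grazed_zone(nest, config.grazed_zone):
        year_index = nest.year - config.first_year
        d_int = config.release_day(year_index) - pol.trampling_lead_days
        if nest.lay_day < d_int <= nest.lay_day + ACTIVITY_CAP_DAYS:
            cands.append((d_int, "trampling"))
    return sorted(cands)


def apply_protection_policy(nests, landscape, config: ScenarioConfig,
                            true_params: TrueParameters | None = None
                            ) -> list[NestRecord]:
    """Apply the dummy-egg protection policy and update fates.

    Nests that trigger a protection rule and are still alive on the
    intervention day are re-walked from their own random stream with the
    protected hazards; because the stream is identical, the pre-intervention
    trajectory is unchanged.  With the policy disabled, the input records
    are returned unchanged.
    """
    if not config.policy.enabled:
        return list(nests)
    params = true_params or config.true_params
    eta0, age_scaled, shore, _ = _predation_linear_predictors(
        nests, landscape, config, params, assume_full_windows=True)

    out = []
    for n in nests:
        cands = _candidate_interventions(n, config, shore[n.nest_id])
        chosen = None
        for day, cause in cands:
            if n.fate == "hatched" or n.end_day >= day:
                chosen = (day, cause)
                break
        if chosen is None:
            out.append(n)
            continue
        d_int, cause = chosen
        dummy_until = None
        if cause == "flood" and config.policy.flood_protection_days is not None:
            dummy_until = d_int + config.policy.flood_protection_days
        fate, end = _walk_nest(
            n.copy(end_day=n.lay_day + ACTIVITY_CAP_DAYS), config, params,
            eta0[n.nest_id], age_scaled[n.year], shore[n.nest_id],
            protection={"cause": cause, "day": d_int, "dummy_until": dummy_until},
        )
        if end < d_int:
            # the nest failed before the team could intervene: no protection
            out.append(n)
            continue
        protection_end = min(end, dummy_until if dummy_until is not None
                             else n.lay_day + ACTIVITY_CAP_DAYS)
        duration_h = 24.0 * max(0, protection_end - d_int)
        out.append(n.copy(
            fate=fate, end_day=end, protected_cause=cause,
            intervention_day=d_int,
            artificially_incubated=duration_h > config.policy.short_protection_hours,
        ))
    return out


def simulate_dataset(config: ScenarioConfig):
    """Full generator pipeline: landscape, nests, fates, protection.

    Returns (nests, landscape).  Byte-identical output under a fixed seed.
    """
    landscape = generate_landscape(config)
    nests = generate_nests(config, landscape)
    nests = simulate_daily_fates(nests, landscape, config)
    nests = apply_protection_policy(nests, landscape, config)
    return nests, landscape
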