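"""Scenario configuration for the synthetic nest-survival generator.

A :class:`ScenarioConfig` holds everything the simulator needs to produce a
reproducible multi-year nest dataset: landscape geometry parameters, the
generative model truth (:class:`TrueParameters`), discrete flood events, the
cattle grazing schedule and the clutch-protection policy.  The defaults
emulate a six-year study of ~275 ruff nests on a large grazed shore meadow:
nests concentrated in a band between the shoreline and the upland meadow
edge, a handful of lek sites, storm-surge floods on single days, and spring
cattle release in a dedicated grazing zone in early June.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import yaml


@dataclass
class TrueParameters:
    """Ground truth for the generative daily-survival process.

    The ``beta_*`` coefficients act on the within-year centred-and-scaled
    covariates of the logit daily-survival model (predation channel).  The
    cause-specific hazards are calibration choices on the probability scale;
    the field data do not identify them directly.
    """

    beta_intercept: float = 4.5
    beta_dist_nests: float = 1.0
    beta_dist_nests_sq: float = -0.4
    beta_dist_leks: float = 0.05
    beta_dist_leks_sq: float = 0.0
    beta_lay_date: float = -0.1
    beta_nest_age: float = -0.8
    beta_incubation: float = 0.0   # protection acts via dummy-egg multipliers
    beta_dist_paths: float = 0.1
    beta_dist_edge: float = -0.1
    beta_dist_shore: float = -0.1
    sigma_year: float = 0.5
    year_effects: list[float] | None = None  # raw N(0,1) deviates; drawn if None
    flood_lethality: float = 0.9
    trampling_hazard: float = 0.05
    abandonment_hazard: float = 0.005
    dummy_predation_multiplier: float = 0.5
    dummy_abandonment_multiplier: float = 2.5

    def __post_init__(self) -> None:
        for name in ("flood_lethality", "trampling_hazard", "abandonment_hazard"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be a probability in [0, 1], got {v}")
        if self.sigma_year <= 0:
            raise ValueError("sigma_year must be positive")

    def fixed_effect_vector(self) -> list[float]:
        """Coefficients in the canonical design-column order (see dsrmodel)."""
        return [
            self.beta_intercept,
            self.beta_dist_nests,
            self.beta_dist_nests_sq,
            self.beta_dist_leks,
            self.beta_dist_leks_sq,
            self.beta_lay_date,
            self.beta_nest_age,
            self.beta_incubation,
            self.beta_dist_paths,
            self.beta_dist_edge,
            self.beta_dist_shore,
        ]


@dataclass
class ProtectionPolicy:
    """Clutch-protection (dummy-egg) intervention rules.

    flood_trigger
        Replace the clutch on the forecast surge day for nests within the
        flood's reach of the shoreline.
    trampling_lead_days
        Replace clutches of nests inside the grazing zone this many days
        before the cattle-release day.
    flood_protection_days
        How long a flood-protected clutch stays replaced; ``None`` means
        until hatch.  Protections of 24 h or less are not counted as
        artificial incubation (``short_protection_hours``), matching field
        practice where one-day egg swaps are excluded from the incubation
        covariate.
    """

    enabled: bool = True
    flood_trigger: bool = True
    trampling_trigger: bool = True
    trampling_lead_days: int = 3
    flood_protection_days: int | None = None
    short_protection_hours: float = 24.0

    def __post_init__(self) -> None:
        if self.trampling_lead_days < 0:
            raise ValueError("trampling_lead_days must be >= 0")
        if self.short_protection_hours <= 0:
            raise ValueError("short_protection_hours must be > 0")


@dataclass
class ScenarioConfig:
    """Full specification of one synthetic multi-year study.

    Geometry is a planar metric frame (metres, UTM-like).  The meadow is the
    rectangle [0, meadow_width] x [0, meadow_height]; the shoreline runs
    along y ~ 0 and the upland meadow edge along y ~ meadow_height.  Nests
    are placed in the band ``nest_band_y`` between the two, which together
    with ``nests_per_year`` sets the nest density behind the target mean
    nearest-neighbour spacing.
    """

    n_years: int = 6
    nests_per_year: int = 46
    season_length: int = 60
    first_year: int = 2018

    # landscape geometry (metres)
    meadow_width: float = 3000.0
    meadow_height: float = 1270.0
    nest_band_y: tuple[float, float] = (430.0, 680.0)
    path_y_positions: tuple[float, ...] = (220.0, 520.0, 820.0)
    n_cross_paths: int = 2
    n_leks: int = 12
    leks_active_per_year: int = 4

    # distance calibration target (mean daily nearest active neighbour, m)
    target_nest_spacing: float = 121.2

    true_params: TrueParameters = field(default_factory=TrueParameters)

    # discrete storm-surge events: (year_index, day_of_season, reach_m)
    flood_days: list[tuple[int, int, float]] = field(
        default_factory=lambda: [(1, 18, 520.0), (3, 25, 470.0)]
    )
    # day-of-season of cattle release, per year (cycled if shorter than n_years)
    cattle_release_day: list[int] = field(default_factory=lambda: [20])
    # grazed zone: rectangle (x_min, x_max, y_min, y_max) in metres
    grazed_zone: tuple[float, float, float, float] = (2150.0, 3000.0, 0.0, 1270.0)

    policy: ProtectionPolicy = field(default_factory=ProtectionPolicy)
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_years < 1:
            raise ValueError("n_years must be >= 1")
        if self.season_length < 27:
            raise ValueError("season_length must be >= 27 (26-day window + lay day)")
        if self.meadow_width <= 0 or self.meadow_height <= 0:
            raise ValueError("meadow extent must be positive (degenerate extent)")
        for _, _, reach in self.flood_days:
            if reach < 0:
                raise ValueError("flood reach_distance must be >= 0")

    def release_day(self, year_index: int) -> int:
        days = self.cattle_release_day
        return int(days[year_index % len(days)])

    def years(self) -> list[int]:
        return [self.first_year + i for i in range(self.n_years)]

    # -- YAML round trip ----------------------------------------------------

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "ScenarioConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        raw["true_params"] = TrueParameters(**raw.get("true_params", {}))
        raw["policy"] = ProtectionPolicy(**raw.get("policy", {}))
        for key in ("nest_band_y", "grazed_zone", "path_y_positions"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        if raw.get("flood_days"):
            raw["flood_days"] = [tuple(t) for t in raw["flood_days"]]
        return cls(**raw)
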