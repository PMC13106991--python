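"""Core record types shared across the pipeline.

A :class:`NestRecord` is one nest's location, timeline, fate and protection
history; days are integer day-of-season, with the nest active on the closed
interval [lay_day, end_day].  An :class:`ExposureHistory` is the daily
Bernoulli encoding of one nest under one mortality scenario and dataset
variant.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

FATES = ("hatched", "predated", "flooded", "trampled", "abandoned",
         "unknown_dead", "unknown", "escaped")
FAILURE_FATES = ("predated", "flooded", "trampled", "abandoned", "unknown_dead")

SCENARIOS = ("overall", "no_predation", "predation")
VARIANTS = ("all_nests", "natural_only")

#: maximum number of daily survival transitions considered per nest
ACTIVITY_CAP_DAYS = 26


@dataclass
class NestDistances:
    """Distance covariates for one nest (metres).

    ``dist_nests`` is the mean over active days of the distance to the
    nearest concurrently active neighbour; it is ``None`` when the nest never
    overlapped another active nest.
    """

    dist_nests: float | None = None
    dist_leks: float | None = None
    dist_shore: float | None = None
    dist_edge: float | None = None
    dist_paths: float | None = None


@dataclass
class NestRecord:
    nest_id: str
    year: int
    x: float
    y: float
    lay_day: int
    end_day: int
    fate: str = "unknown"
    clutch_size: int = 4
    protected_cause: str = "none"          # none | flood | trampling
    intervention_day: int | None = None
    artificially_incubated: bool = False
    female_id: str | None = None
    fate_seed: int | None = None           # per-nest stream for common random numbers
    distances: NestDistances = field(default_factory=NestDistances)

    def __post_init__(self) -> None:
        if self.lay_day > self.end_day:
            raise ValueError(
                f"nest {self.nest_id}: lay_day {self.lay_day} > end_day {self.end_day}"
            )
        if self.fate not in FATES:
            raise ValueError(f"nest {self.nest_id}: unknown fate label {self.fate!r}")
        if self.artificially_incubated and self.protected_cause == "none":
            raise ValueError(
                f"nest {self.nest_id}: artificially_incubated requires a protected cause"
            )
        if self.intervention_day is not None and not (
            self.lay_day <= self.intervention_day <= self.end_day
        ):
            raise ValueError(
                f"nest {self.nest_id}: intervention_day {self.intervention_day} "
                f"outside active window [{self.lay_day}, {self.end_day}]"
            )

    def copy(self, **changes) -> "NestRecord":
        return replace(self, **changes)

    def active_on(self, day: int) -> bool:
        return self.lay_day <= day <= self.end_day


@dataclass
class ExposureHistory:
    """Daily survival outcomes y_t for t = 1..T after the lay day (t = 0).

    ``terminal`` records how the history ends: ``failed`` (last y is 0),
    ``censored`` (all ones, removed from the risk set without a failure) or
    ``survived_window`` (all ones through the full activity window).
    """

    nest_id: str
    scenario: str
    variant: str
    y: tuple[int, ...]
    terminal: str

    def __post_init__(self) -> None:
        if self.scenario not in SCENARIOS:
            raise ValueError(f"unknown scenario {self.scenario!r}")
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}")
        if self.terminal not in ("failed", "censored", "survived_window"):
            raise ValueError(f"unknown terminal state {self.terminal!r}")
        T = len(self.y)
        if T > ACTIVITY_CAP_DAYS:
            raise ValueError(f"history longer than {ACTIVITY_CAP_DAYS} days")
        if any(v not in (0, 1) for v in self.y):
            raise ValueError("y values must be 0/1")
        if any(v == 0 for v in self.y[:-1]):
            raise ValueError("only the last day of a history may be 0")
        if self.terminal == "failed":
            if T == 0 or self.y[-1] != 0:
                raise ValueError("failed history must end in 0")
        elif T > 0 and self.y[-1] != 1:
            raise ValueError("non-failed history must be all ones")
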