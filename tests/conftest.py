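import warnings
from dataclasses import replace

import pytest

from ruffnest import (ScenarioConfig, build_design, nest_distance_table,
                      simulate_dataset)

warnings.filterwarnings("ignore", message="covariate .* missing values")


def predation_only_config(seed: int, **kwargs) -> ScenarioConfig:
    """Scenario with predation as the only mortality cause and no policy,
    so the Bernoulli-logit model is correctly specified with known truth."""
    cfg = ScenarioConfig(rng_seed=seed, flood_days=[], **kwargs)
    cfg.true_params = replace(cfg.true_params, trampling_hazard=0.0,
                              abandonment_hazard=0.0)
    cfg.policy = replace(cfg.policy, enabled=False)
    return cfg


def recovery_config(seed: int) -> ScenarioConfig:
    """Predation-only scenario for the parameter-recovery harness."""
    return predation_only_config(seed)


def mark_intention_to_treat(nests, cfg) -> list:
    """Flag the incubation covariate by intention to treat.

    The real intervention only materializes for nests still alive on the
    intervention day — selection on survival that would bias a zero-truth
    incubation coefficient.  For recovery, the indicator is instead set from
    exogenous attributes alone (grazing-zone membership and the laying
    schedule), so its true effect is exactly zero; fates are untouched."""
    from ruffnest.records import ACTIVITY_CAP_DAYS
    from ruffnest.synthgen import _in_grazed_zone

    out = []
    for n in nests:
        d_int = (cfg.release_day(n.year - cfg.first_year)
                 - cfg.policy.trampling_lead_days)
        itt = (_in_grazed_zone(n, cfg.grazed_zone)
               and n.lay_day < d_int <= n.lay_day + ACTIVITY_CAP_DAYS)
        if itt:
            out.append(n.copy(protected_cause="trampling",
                              intervention_day=min(d_int, n.end_day),
                              artificially_incubated=True))
        else:
            out.append(n)
    return out


@pytest.fixture(scope="session")
def default_dataset():
    """One full simulated study under the default six-year scenario."""
    cfg = ScenarioConfig(rng_seed=42)
    nests, landscape = simulate_dataset(cfg)
    return cfg, nests, landscape


@pytest.fixture(scope="session")
def default_distance_table(default_dataset):
    _, nests, landscape = default_dataset
    return nest_distance_table(nests, landscape)


@pytest.fixture(scope="session")
def overall_design(default_dataset, default_distance_table):
    _, nests, _ = default_dataset
    return build_design(nests, default_distance_table, "overall", "all_nests")
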