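"""Synthetic data generator: landscape, nest placement, competing-risk fate
walks and the clutch-protection policy."""

from dataclasses import replace

import numpy as np
import pytest
from scipy.special import logit

from ruffnest import (LandscapeFeatures, ScenarioConfig, TrueParameters,
                      apply_protection_policy, generate_landscape,
                      generate_nests, mean_daily_nearest_nest_distance,
                      simulate_daily_fates, simulate_dataset)
from ruffnest.io import nests_to_frame
from ruffnest.records import ACTIVITY_CAP_DAYS, FAILURE_FATES

from conftest import predation_only_config


def _constant_survival_config(seed, s, n_nests, n_years=1):
    """Predation-only scenario with constant daily survival ``s``."""
    cfg = predation_only_config(seed, n_years=n_years, nests_per_year=n_nests)
    cfg.true_params = replace(
        cfg.true_params,
        beta_intercept=float(logit(s)), beta_dist_nests=0.0,
        beta_dist_nests_sq=0.0, beta_dist_leks=0.0, beta_dist_leks_sq=0.0,
        beta_lay_date=0.0, beta_nest_age=0.0, beta_dist_paths=0.0,
        beta_dist_edge=0.0, beta_dist_shore=0.0,
        sigma_year=1e-9, year_effects=[0.0] * n_years)
    return cfg


def _winding_number_contains(polygon, point):
    """Brute-force winding-number point-in-polygon test (independent of
    shapely)."""
    x, y = point
    wn = 0
    n = len(polygon)
    for i in range(n):
        x0, y0 = polygon[i]
        x1, y1 = polygon[(i + 1) % n]
        if y0 <= y < y1 or y1 <= y < y0:
            t = (y - y0) / (y1 - y0)
            if x0 + t * (x1 - x0) > x:
                wn += 1 if y1 > y0 else -1
    return wn != 0


class TestLandscape:
    def test_same_seed_identical_geometry(self):
        cfg = ScenarioConfig(rng_seed=7)
        l1, l2 = generate_landscape(cfg), generate_landscape(cfg)
        assert l1.shoreline.equals_exact(l2.shoreline, 0)
        assert l1.paths.equals_exact(l2.paths, 0)
        assert [(k.x, k.y, k.active_years) for k in l1.leks] == \
            [(k.x, k.y, k.active_years) for k in l2.leks]

    def test_no_leks_other_features_present(self):
        land = generate_landscape(ScenarioConfig(rng_seed=0, n_leks=0))
        assert land.leks == []
        assert land.shoreline.length > 0 and land.meadow_edge.length > 0
        assert len(land.paths.geoms) >= 1

    def test_leks_between_shoreline_and_edge(self):
        land = generate_landscape(ScenarioConfig(rng_seed=3))
        ring = (list(land.shoreline.coords)
                + list(land.meadow_edge.coords)[::-1])
        for lek in land.leks:
            assert _winding_number_contains(ring, (lek.x, lek.y))

    def test_degenerate_extent_rejected(self):
        with pytest.raises(ValueError, match="extent"):
            ScenarioConfig(rng_seed=0, meadow_width=0.0)

    def test_every_year_has_an_active_lek(self):
        cfg = ScenarioConfig(rng_seed=5)
        land = generate_landscape(cfg)
        for year in cfg.years():
            assert any(year in l.active_years for l in land.leks)


class TestGenerateNests:
    def test_counts_and_lay_date_window(self):
        cfg = ScenarioConfig(rng_seed=1)
        nests = generate_nests(cfg, generate_landscape(cfg))
        assert len(nests) == cfg.n_years * cfg.nests_per_year
        for n in nests:
            assert 0 <= n.lay_day <= cfg.season_length - ACTIVITY_CAP_DAYS - 1
            assert n.clutch_size in (3, 4)
            assert 0 <= n.x <= cfg.meadow_width

    def test_zero_nests_is_empty_not_error(self):
        cfg = ScenarioConfig(rng_seed=1, nests_per_year=0)
        assert generate_nests(cfg, generate_landscape(cfg)) == []

    def test_seed_changes_coordinates_not_count(self):
        l1 = ScenarioConfig(rng_seed=1)
        l2 = ScenarioConfig(rng_seed=2)
        n1 = generate_nests(l1, generate_landscape(l1))
        n2 = generate_nests(l2, generate_landscape(l2))
        assert len(n1) == len(n2)
        assert any(a.x != b.x for a, b in zip(n1, n2))

    def test_mean_nearest_nest_distance_near_target(self):
        """Monte-Carlo estimate over >= 1000 nests generated under the
        default per-year density: the mean daily nearest-active-neighbour
        distance should sit within +-30% of the configured spacing."""
        vals = []
        for seed in range(4):
            cfg = ScenarioConfig(rng_seed=seed)
            nests, _ = simulate_dataset(cfg)
            for n in nests:
                d = mean_daily_nearest_nest_distance(n, nests)
                if d is not None:
                    vals.append(d)
        assert len(vals) >= 1000
        target = ScenarioConfig().target_nest_spacing
        assert abs(np.mean(vals) - target) < 0.3 * target


class TestDailyFates:
    def test_all_hazards_zero_everyone_hatches(self):
        cfg = _constant_survival_config(0, 1.0 - 1e-12, 40)
        land = generate_landscape(cfg)
        nests = generate_nests(cfg, land)
        out = simulate_daily_fates(nests, land, cfg)
        assert all(n.fate == "hatched" for n in out)
        assert all(n.end_day == n.lay_day + ACTIVITY_CAP_DAYS for n in out)

    @pytest.mark.parametrize("s", [0.90, 0.95, 0.97])
    def test_constant_survival_matches_closed_form(self, s):
        """Empirical hatched fraction under predation-only hazards converges
        to S^26 (3 binomial SE tolerance)."""
        n = 2000
        cfg = _constant_survival_config(123, s, n)
        land = generate_landscape(cfg)
        nests = generate_nests(cfg, land)
        out = simulate_daily_fates(nests, land, cfg)
        hatched = sum(x.fate == "hatched" for x in out) / n
        expected = s ** ACTIVITY_CAP_DAYS
        se = np.sqrt(expected * (1 - expected) / n)
        assert abs(hatched - expected) < 3 * se

    def test_flood_rule_is_deterministic_at_lethality_one(self):
        cfg = _constant_survival_config(9, 1.0 - 1e-12, 100)
        cfg.flood_days = [(0, 15, 600.0)]
        cfg.true_params = replace(cfg.true_params, flood_lethality=1.0)
        land = generate_landscape(cfg)
        nests = generate_nests(cfg, land)
        out = simulate_daily_fates(nests, land, cfg)
        from ruffnest import point_to_polyline_distance
        for n in out:
            at_risk = (point_to_polyline_distance((n.x, n.y), land.shoreline)
                       <= 600.0 and n.lay_day < 15 <= n.lay_day + ACTIVITY_CAP_DAYS)
            if at_risk:
                assert n.fate == "flooded" and n.end_day == 15
            else:
                assert n.fate == "hatched"

    def test_fate_partition_and_day_range(self, default_dataset):
        _, nests, _ = default_dataset
        for n in nests:
            assert n.fate in ("hatched",) + FAILURE_FATES
            assert 1 <= n.end_day - n.lay_day <= ACTIVITY_CAP_DAYS

    def test_byte_level_determinism(self):
        cfg = ScenarioConfig(rng_seed=77)
        t1 = nests_to_frame(simulate_dataset(cfg)[0]).to_csv()
        t2 = nests_to_frame(simulate_dataset(cfg)[0]).to_csv()
        assert t1 == t2


class TestProtectionPolicy:
    def test_disabled_policy_is_identity(self):
        cfg = ScenarioConfig(rng_seed=4)
        cfg.policy = replace(cfg.policy, enabled=False)
        land = generate_landscape(cfg)
        nests = simulate_daily_fates(generate_nests(cfg, land), land, cfg)
        assert apply_protection_policy(nests, land, cfg) == nests

    def test_flood_protected_never_flooded_after_intervention(self):
        cfg = ScenarioConfig(rng_seed=8)
        cfg.flood_days = [(0, 15, 600.0)]
        cfg.true_params = replace(cfg.true_params, flood_lethality=1.0)
        land = generate_landscape(cfg)
        nests = simulate_daily_fates(generate_nests(cfg, land), land, cfg)
        out = apply_protection_policy(nests, land, cfg)
        for n in out:
            if n.protected_cause == "flood":
                assert not (n.fate == "flooded" and n.end_day >= n.intervention_day)

    def test_one_day_flood_protection_not_artificially_incubated(self):
        cfg = ScenarioConfig(rng_seed=8)
        cfg.flood_days = [(0, 15, 600.0)]
        cfg.policy = replace(cfg.policy, flood_protection_days=1,
                             trampling_trigger=False)
        land = generate_landscape(cfg)
        nests = simulate_daily_fates(generate_nests(cfg, land), land, cfg)
        out = apply_protection_policy(nests, land, cfg)
        protected = [n for n in out if n.protected_cause == "flood"]
        assert protected
        assert all(not n.artificially_incubated for n in protected)

    def test_protection_never_decreases_hatching(self):
        """Pathwise monotonicity under common random numbers when the
        dummy-egg multipliers do not increase any hazard."""
        for seed in range(3):
            cfg = ScenarioConfig(rng_seed=seed)
            cfg.true_params = replace(cfg.true_params,
                                      dummy_abandonment_multiplier=1.0,
                                      dummy_predation_multiplier=0.8)
            land = generate_landscape(cfg)
            nests = simulate_daily_fates(generate_nests(cfg, land), land, cfg)
            protected = apply_protection_policy(nests, land, cfg)
            n_before = sum(n.fate == "hatched" for n in nests)
            n_after = sum(n.fate == "hatched" for n in protected)
            assert n_after >= n_before

    def test_intervention_day_inside_active_window(self, default_dataset):
        _, nests, _ = default_dataset
        for n in nests:
            if n.intervention_day is not None:
                assert n.lay_day <= n.intervention_day <= n.end_day
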