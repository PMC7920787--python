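from __future__ import annotations

import itertools

import numpy as np
import pytest

import sbanet
from sbanet._constants import HABITATS, SHORT_BEHAVIORS
from sbanet.synthetic_data import (
    ConfigError,
    SimConfig,
    bridged_blocks_scenario,
    config_from_yaml,
    config_to_yaml,
    loading_for_rho,
    make_default_config,
    plant_block_correlation,
    simulate_events,
)


def small_config(catalog, n_days=50, seed=0, **overrides):
    species = catalog.species_ids[:3]
    base = dict(
        n_days=n_days,
        sites=[("L1", "R1")],
        habitat_suitability={("R1", "MF", sp): 1.0 for sp in species},
        abundance_mean={("R1", "MF", sp): 40.0 for sp in species},
        dispersion=5.0,
        activity_split=0.6,
        behavior_rates={"competition": 0.1},
        latent_factor_loadings={},
        seed=seed,
    )
    base.update(overrides)
    return SimConfig(**base)


class TestMakeDefaultConfig:
    def test_structure(self, catalog):
        cfg = make_default_config(catalog)
        strata = {(r, h) for (r, h, _) in cfg.habitat_suitability}
        assert strata == set(itertools.product(("R1", "R2"), HABITATS))
        species = {sp for (_, _, sp) in cfg.habitat_suitability}
        assert species == set(catalog.species_ids)
        cfg.validate()

    def test_r1_at_least_r2(self, catalog):
        cfg = make_default_config(catalog)
        for habitat in HABITATS:
            for sp in catalog.species_ids:
                assert (
                    cfg.habitat_suitability[("R1", habitat, sp)]
                    >= cfg.habitat_suitability[("R2", habitat, sp)]
                )
                assert (
                    cfg.abundance_mean[("R1", habitat, sp)]
                    >= cfg.abundance_mean[("R2", habitat, sp)]
                )

    def test_guild_mates_share_loading(self, catalog):
        cfg = make_default_config(catalog)
        g3 = [e.species_id for e in catalog.entries if e.guild == "G3"]
        loadings = {cfg.latent_factor_loadings[(sp, "forage")] for sp in g3}
        factors = {cfg.factor_of((sp, "forage")) for sp in g3}
        assert len(loadings) == 1 and loadings.pop() != 0.0
        assert len(factors) == 1


class TestSimulateEvents:
    def test_deterministic_under_seed(self, catalog):
        cfg = small_config(catalog, seed=11)
        assert simulate_events(cfg) == simulate_events(cfg)

    def test_distinct_seeds_differ(self, catalog):
        a = simulate_events(small_config(catalog, seed=1))
        b = simulate_events(small_config(catalog, seed=2))
        assert a != b

    def test_zero_behavior_rates(self, catalog):
        cfg = small_config(catalog, behavior_rates={})
        events = simulate_events(cfg)
        assert events
        assert not any(e.behavior_class in SHORT_BEHAVIORS for e in events)

    def test_one_event_per_site_day(self, catalog):
        events = simulate_events(small_config(catalog, n_days=10))
        per_day = {}
        for e in events:
            per_day.setdefault((e.site_id, e.date), set()).add(e.event_id)
        assert all(len(ids) == 1 for ids in per_day.values())
        assert len(per_day) == 10

    def test_behavior_counts_bounded_by_total(self, catalog):
        cfg = small_config(catalog, behavior_rates={"competition": 0.5,
                                                    "aggression": 0.5})
        events = simulate_events(cfg)
        totals = {}
        for e in events:
            if e.behavior_class in ("forage", "roost"):
                key = (e.event_id, e.habitat, e.species_id)
                totals[key] = totals.get(key, 0) + e.count
        for e in events:
            if e.behavior_class in SHORT_BEHAVIORS:
                assert e.count <= totals[(e.event_id, e.habitat, e.species_id)]

    def test_forage_mean_matches_configuration(self, catalog):
        # law-of-large-numbers oracle: 2,000 events, loadings zeroed
        cfg = small_config(catalog, n_days=2000, seed=5)
        events = sbanet.filter_daily_best(simulate_events(cfg))
        matrix = sbanet.pivot_abundance(events, catalog, "R1", "MF")
        col = matrix.data[(catalog.species_ids[0], "forage")].to_numpy(float)
        expected = 40.0 * 0.6
        mc_se = col.std(ddof=1) / np.sqrt(len(col))
        assert abs(col.mean() - expected) < 3 * mc_se

    def test_invalid_config_names_field(self, catalog):
        with pytest.raises(ConfigError, match="dispersion"):
            simulate_events(small_config(catalog, dispersion=-1.0))
        with pytest.raises(ConfigError, match="activity_split"):
            simulate_events(small_config(catalog, activity_split=1.5))
        with pytest.raises(ConfigError, match="n_days"):
            simulate_events(small_config(catalog, n_days=0))


def column_correlations(catalog, config, labels_a, labels_b):
    events = sbanet.filter_daily_best(simulate_events(config))
    matrix = sbanet.pivot_abundance(events, catalog, "R1", "MF")
    out = []
    for a in labels_a:
        for b in labels_b:
            if a != b:
                x = matrix.data[a].to_numpy(float)
                y = matrix.data[b].to_numpy(float)
                out.append(float(np.corrcoef(x, y)[0, 1]))
    return out


class TestPlantBlockCorrelation:
    def test_rho_zero_is_null(self, catalog):
        cfg = small_config(catalog)
        planted = plant_block_correlation(
            cfg, [[("CINI", "forage"), ("ARAL", "forage")]], 0.0
        )
        assert all(v == 0.0 for v in planted.latent_factor_loadings.values())

    def test_rho_domain_error(self, catalog):
        cfg = small_config(catalog)
        for rho in (-0.1, 1.0, 1.5):
            with pytest.raises(ValueError, match="rho"):
                plant_block_correlation(cfg, [[("CINI", "forage")]], rho)

    def test_overlapping_groups_rejected(self, catalog):
        cfg = small_config(catalog)
        with pytest.raises(ValueError, match="disjoint"):
            plant_block_correlation(
                cfg, [[("CINI", "forage")], [("CINI", "forage")]], 0.5
            )

    def test_two_groups_within_exceeds_between(self, catalog):
        species = catalog.species_ids[:6]
        cfg = small_config(
            catalog,
            n_days=1000,
            seed=3,
            habitat_suitability={("R1", "MF", sp): 1.0 for sp in species},
            abundance_mean={("R1", "MF", sp): 40.0 for sp in species},
            behavior_rates={},
        )
        g1 = [(sp, "forage") for sp in species[:3]]
        g2 = [(sp, "forage") for sp in species[3:]]
        planted = plant_block_correlation(cfg, [g1, g2], 0.6)
        within = column_correlations(catalog, planted, g1, g1)
        within += column_correlations(catalog, planted, g2, g2)
        between = column_correlations(catalog, planted, g1, g2)
        assert np.mean(within) > np.mean(between)
        assert np.mean(within) > 0.4  # approaches the planted 0.6

    def test_single_group_all_positive(self, catalog):
        species = catalog.species_ids[:4]
        cfg = small_config(
            catalog,
            n_days=1000,
            seed=4,
            habitat_suitability={("R1", "MF", sp): 1.0 for sp in species},
            abundance_mean={("R1", "MF", sp): 40.0 for sp in species},
            behavior_rates={},
        )
        group = [(sp, "forage") for sp in species]
        planted = plant_block_correlation(cfg, [group], 0.6)
        assert all(c > 0 for c in column_correlations(catalog, planted, group, group))

    def test_marginal_means_held_fixed(self, catalog):
        cfg = small_config(catalog, n_days=2000, seed=9, behavior_rates={})
        group = [(sp, "forage") for sp in catalog.species_ids[:3]]
        planted = plant_block_correlation(cfg, [group], 0.5)
        events = sbanet.filter_daily_best(simulate_events(planted))
        matrix = sbanet.pivot_abundance(events, catalog, "R1", "MF")
        col = matrix.data[group[0]].to_numpy(float)
        mc_se = col.std(ddof=1) / np.sqrt(len(col))
        assert abs(col.mean() - 40.0 * 0.6) < 3 * mc_se


class TestLoadingForRho:
    def test_zero(self):
        assert loading_for_rho(0.0, 40.0, 5.0) == 0.0

    def test_monotone_in_rho(self):
        loads = [loading_for_rho(r, 40.0, 5.0) for r in (0.1, 0.3, 0.5, 0.7)]
        assert loads == sorted(loads)
        assert loads[0] > 0

    def test_infeasible_rho(self):
        with pytest.raises(ValueError, match="unattainable"):
            loading_for_rho(0.9, 40.0, 5.0)  # needs rho < k/(k+1)


class TestYamlRoundTrip:
    def test_identity(self, catalog, tmp_path):
        cfg = make_default_config(catalog, n_days=7, seed=3)
        path = tmp_path / "cfg.yaml"
        config_to_yaml(cfg, path)
        assert config_from_yaml(path) == cfg

    def test_missing_field(self, tmp_path):
        path = tmp_path / "cfg.yaml"
        path.write_text("n_days: 3\n")
        with pytest.raises(ConfigError, match="sites"):
            config_from_yaml(path)


class TestBridgedScenario:
    def test_ground_truth_shape(self, catalog):
        config, block1, block2, bridge = bridged_blocks_scenario(catalog, seed=0)
        assert (bridge, "forage") in block1
        assert (bridge, "roost") in block2
        assert not set(block1) & set(block2)
        config.validate()
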