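"""The synthetic discovery process and its ground-truth ledger."""

import numpy as np
import pandas as pd
import pytest

from virodiscover import (
    EffortCurve,
    OrderSpec,
    Shock,
    SimConfig,
    ground_truth_rank_agreement,
    richness_at,
    simulate,
    simulate_order_snapshots,
)

from conftest import pairs_from_sim
from virodiscover.ingest import FilterConfig


def tiny_config(**overrides):
    base = dict(
        seed=1,
        orders=(OrderSpec("OrdA", 10), OrderSpec("OrdB", 10)),
        richness_mean=5.0,
        base_effort=EffortCurve("constant", base=0.5),
        year_range=(1980, 2010),
        domestic_fraction=0.0,
        laboratory_fraction=0.0,
        resolution_mix={"ictv": 1.0, "predict": 0.0, "unresolved": 0.0},
    )
    base.update(overrides)
    return SimConfig(**base)


class TestDeterminism:
    def test_identical_seed_identical_output(self):
        a, b = simulate(tiny_config()), simulate(tiny_config())
        pd.testing.assert_frame_equal(a.associations, b.associations)
        pd.testing.assert_frame_equal(a.citations, b.citations)
        pd.testing.assert_frame_equal(a.ledger.events, b.ledger.events)
        assert a.ledger.pools == b.ledger.pools

    def test_different_seeds_differ(self):
        a = simulate(tiny_config(seed=1))
        b = simulate(tiny_config(seed=2))
        assert not a.associations.equals(b.associations)


class TestConservation:
    def test_dedup_of_associations_equals_ledger_pairs(self):
        result = simulate(tiny_config())
        # no filtering: every simulated record is wild + resolved here
        pairs = pairs_from_sim(result, cfg=FilterConfig.permissive())
        got = pairs[["host_species", "virus", "discovery_year"]].rename(
            columns={"host_species": "species"}
        )
        truth = result.ledger.discovered_pairs
        pd.testing.assert_frame_equal(
            got.sort_values(["species", "virus"]).reset_index(drop=True),
            truth.sort_values(["species", "virus"]).reset_index(drop=True),
            check_dtype=False,
        )

    def test_discovered_sets_subset_of_pools(self):
        result = simulate(tiny_config())
        for (sp,), grp in result.ledger.events.groupby(["species"]):
            assert set(grp["virus"]) <= set(result.ledger.pools[sp])

    def test_event_years_within_range(self):
        result = simulate(tiny_config())
        assert result.ledger.events["year"].between(1980, 2010).all()


class TestRegimes:
    def test_negligible_effort_gives_empty_table_pools_intact(self):
        result = simulate(tiny_config(base_effort=EffortCurve("constant", base=1e-12)))
        assert len(result.associations) == 0
        assert len(result.ledger.events) == 0
        assert all(len(p) >= 1 for p in result.ledger.pools.values())

    def test_saturating_effort_exhausts_every_pool(self):
        cfg = tiny_config(
            base_effort=EffortCurve("constant", base=30.0),
            discovery_prob=1.0,
            richness_mean=3.0,
        )
        result = simulate(cfg)
        disc = result.ledger.events.query("event_type == 'discovery'")
        per_species = disc.groupby("species")["virus"].nunique()
        for sp, pool in result.ledger.pools.items():
            assert per_species.get(sp, 0) == len(pool)

    def test_early_discovery_rate_matches_analytic_expectation(self):
        """With large pools, expected annual discoveries ~= n_species * lambda * p."""
        lam, p, n_species, n_rep = 0.8, 0.3, 30, 60
        first_years = []
        for seed in range(n_rep):
            cfg = SimConfig(
                seed=seed,
                orders=(OrderSpec("OrdA", n_species),),
                richness_mean=500.0,  # effectively inexhaustible in year one
                richness_dispersion=5.0,
                base_effort=EffortCurve("constant", base=lam),
                year_range=(2000, 2002),
                domestic_fraction=0.0,
                laboratory_fraction=0.0,
                discovery_prob=p,
            )
            events = simulate(cfg).ledger.events
            first = events[(events["year"] == 2000) & (events["event_type"] == "discovery")]
            first_years.append(len(first))
        expected = n_species * lam * p
        mc_se = np.std(first_years, ddof=1) / np.sqrt(n_rep)
        assert abs(np.mean(first_years) - expected) < 3 * mc_se + 1e-9

    def test_monotone_effort_monotone_expected_discoveries(self):
        lo = [len(simulate(tiny_config(seed=s, base_effort=EffortCurve("constant", base=0.2))).ledger.events) for s in range(10)]
        hi = [len(simulate(tiny_config(seed=s, base_effort=EffortCurve("constant", base=0.8))).ledger.events) for s in range(10)]
        assert np.mean(hi) > np.mean(lo)

    def test_shock_multiplies_effort_for_target_order_only(self):
        cfg = tiny_config(shocks=(Shock("OrdA", 2000, 30.0),), year_range=(1990, 2010))
        events = simulate(cfg).ledger.events
        sp_order = events["species"].str.split(" ").str[0]
        post = events[events["year"] >= 2000]
        post_a = (sp_order[post.index] == "OrdA").sum()
        post_b = (sp_order[post.index] == "OrdB").sum()
        assert post_a > 3 * post_b


class TestGroundTruthAgreement:
    def test_exhaustive_discovery_perfect_agreement(self, ):
        cfg = tiny_config(
            base_effort=EffortCurve("constant", base=30.0), discovery_prob=1.0, richness_mean=4.0
        )
        result = simulate(cfg)
        pairs = pairs_from_sim(result, cfg=FilterConfig.permissive())
        snap = richness_at(pairs, 2010, "species")
        rho = ground_truth_rank_agreement(result.ledger, snap)
        assert rho == pytest.approx(1.0)

    def test_undefined_before_any_discovery(self, sim_small, sim_small_pairs):
        univ = sorted(sim_small_pairs["host_species"].unique())
        snap = richness_at(sim_small_pairs, 1900, "species", universe=univ)
        assert (snap.values == 0).all()
        assert np.isnan(ground_truth_rank_agreement(sim_small.ledger, snap))

    def test_unknown_species_rejected(self, sim_small):
        snap = richness_at(
            pairs_from_sim(sim_small), 2018, "species",
            universe=["Martian sp0001", "OrdA sp0001", "OrdA sp0002"],
        )
        with pytest.raises(ValueError, match="unknown"):
            ground_truth_rank_agreement(sim_small.ledger, snap)


class TestConfigValidation:
    @pytest.mark.parametrize(
        "overrides",
        [
            {"orders": ()},
            {"year_range": (2000, 1990)},
            {"detection_mix": {"serology": 0.5, "pcr": 0.2, "isolation": 0.1}},
            {"discovery_prob": 0.0},
            {"virus_sharing": 1.5},
            {"shocks": (Shock("Nope", 2000, 2.0),)},
            {"richness_dist": "zipf"},
        ],
    )
    def test_invalid_config_raises_before_simulation(self, overrides):
        with pytest.raises(ValueError):
            simulate(tiny_config(**overrides))

    def test_order_spec_validation(self):
        with pytest.raises(ValueError):
            OrderSpec("X", 0)
        with pytest.raises(ValueError):
            OrderSpec("X", 5, effort_weight=-1.0)
        with pytest.raises(ValueError):
            Shock("X", 2000, 0.0)
        with pytest.raises(ValueError):
            EffortCurve("logistic", base=1.0)


class TestOrderSnapshotGenerator:
    def test_reproducible_and_shaped(self):
        a = simulate_order_snapshots(n_orders=17, beta=1.0, seed=3)
        b = simulate_order_snapshots(n_orders=17, beta=1.0, seed=3)
        pd.testing.assert_frame_equal(a, b)
        assert len(a) == 17
        assert (a["species_richness"] >= 1).all()

    def test_beta_scales_richness(self):
        flat = pd.concat(
            [simulate_order_snapshots(beta=0.0, seed=s) for s in range(10)]
        )
        steep = pd.concat(
            [simulate_order_snapshots(beta=1.0, seed=s) for s in range(10)]
        )
        corr_flat = np.corrcoef(np.log(flat["species_richness"]), np.log1p(flat["viral_richness"]))[0, 1]
        corr_steep = np.corrcoef(np.log(steep["species_richness"]), np.log1p(steep["viral_richness"]))[0, 1]
        assert corr_steep > corr_flat + 0.3
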