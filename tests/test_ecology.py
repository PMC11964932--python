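"""Community FBA and six-way ecological interaction classification."""

import numpy as np
import pandas as pd
import pytest

from metaorg import ecology as eco
from metaorg import lp
from metaorg import simulate as sim


def fermenters(n=2):
    return [sim.make_toy_bacterium("fermenter", i, species=f"f{i}")
            for i in range(n)]


class TestCommunityFBA:
    def test_identical_species_split_growth_equally(self):
        cm = eco.CommunityModel(fermenters(), [0.5, 0.5], {"glc": 10.0})
        res = eco.community_fba(cm)
        mu = res["mu_community"]
        assert mu > 0
        for g in res["species_growth"].values():
            assert g == pytest.approx(mu / 2)

    def test_doubling_glucose_doubles_growth(self):
        mu1 = eco.community_fba(
            eco.CommunityModel(fermenters(), [0.5, 0.5],
                               {"glc": 10.0}))["mu_community"]
        mu2 = eco.community_fba(
            eco.CommunityModel(fermenters(), [0.5, 0.5],
                               {"glc": 20.0}))["mu_community"]
        assert mu2 == pytest.approx(2 * mu1)

    def test_obligate_crossfeeder_pair(self):
        donor = sim.make_toy_bacterium("crossfeeder_donor", 0, species="d")
        recip = sim.make_toy_bacterium("crossfeeder_recipient", 0,
                                       species="r")
        env = {"glc": 10.0}
        assert eco.single_growth(recip, env) == pytest.approx(0.0, abs=1e-9)
        res = eco.community_fba(
            eco.CommunityModel([donor, recip], [0.5, 0.5], env))
        assert res["mu_community"] > 0
        assert res["species_growth"]["r"] > 0

    def test_coupled_growth_bounded_by_relaxation(self):
        """Community growth with coupling never exceeds the sum of the
        members' unconstrained individual growths."""
        donor = sim.make_toy_bacterium("crossfeeder_donor", 0, species="d")
        comp = sim.make_toy_bacterium("competitor", 1, species="c")
        env = {"glc": 10.0}
        cm = eco.CommunityModel([donor, comp], [0.5, 0.5], env)
        mu = eco.community_fba(cm)["mu_community"]
        bound = eco.single_growth(donor, env) + eco.single_growth(comp, env)
        assert mu <= bound + 1e-6

    def test_growth_monotone_in_diet(self):
        cm_small = eco.CommunityModel(fermenters(), [0.3, 0.7], {"glc": 5.0})
        cm_big = eco.CommunityModel(fermenters(), [0.3, 0.7], {"glc": 6.0})
        assert (eco.community_fba(cm_big)["mu_community"]
                >= eco.community_fba(cm_small)["mu_community"] - 1e-9)

    def test_nongrower_member_yields_zero_with_diagnostics(self):
        recip = sim.make_toy_bacterium("crossfeeder_recipient", 0,
                                       species="r")
        indep = sim.make_toy_bacterium("independent", 0, species="x")
        cm = eco.CommunityModel([recip, indep], [0.5, 0.5], {"xyl": 10.0})
        res = eco.community_fba(cm)
        assert res["mu_community"] == pytest.approx(0.0, abs=1e-9)


class TestSixWayClassification:
    @pytest.mark.parametrize("idx", range(6))
    @pytest.mark.parametrize("seed", [0, 3])
    def test_planted_types_recovered(self, idx, seed):
        a, b, env, expected = sim.six_pair_fixtures(seed)[idx]
        inter = eco.classify_pair(a, b, env)
        assert inter.type == expected

    def test_classification_invariant_to_pair_order(self):
        pairs = sim.six_pair_fixtures(0)
        for a, b, env, expected in pairs:
            fwd = eco.classify_pair(a, b, env)
            rev = eco.classify_pair(b, a, env)
            assert fwd.type == rev.type
            assert set(fwd.pair) == set(rev.pair)

    def test_exploitation_orientation_beneficiary_first(self):
        donor, exploiter, env, _ = next(
            p for p in sim.six_pair_fixtures(0) if p[3] == "exploitation")
        inter = eco.classify_pair(donor, exploiter, env)
        assert inter.pair[0] == "exploiter"
        assert inter.delta_i > 0 and inter.delta_j < 0


class TestFrequencies:
    def test_neutral_trio_all_neutral(self):
        species = [
            sim.make_toy_bacterium("independent", i, species=f"n{i}",
                                   uptake_ub=3.0)
            for i in range(3)
        ]
        cm = eco.CommunityModel(species, [1, 1, 1], {"xyl": 10.0})
        out = eco.interaction_frequencies(cm)
        assert out.freq["neutralism"] == pytest.approx(1.0)

    def test_counting_competitors_with_bystander(self):
        a = sim.make_toy_bacterium("competitor", 0, species="a")
        b = sim.make_toy_bacterium("competitor", 1, species="b")
        c = sim.make_toy_bacterium("independent", 2, species="c")
        cm = eco.CommunityModel([a, b, c], [1, 1, 1],
                                {"glc": 10.0, "xyl": 10.0})
        out = eco.interaction_frequencies(cm)
        assert out.freq["competition"] == pytest.approx(1 / 3)
        assert out.freq["neutralism"] == pytest.approx(2 / 3)

    def test_frequencies_sum_to_one(self, bundle):
        cm = eco.CommunityModel(bundle.bacteria, [1, 1, 1, 1],
                                {"glc": 10.0, "xyl": 8.0})
        out = eco.interaction_frequencies(cm)
        assert sum(out.freq.values()) == pytest.approx(1.0, abs=1e-9)

    def test_singleton_community_rejected(self):
        cm = eco.CommunityModel(fermenters(1), [1.0], {"glc": 10.0})
        with pytest.raises(ValueError):
            eco.interaction_frequencies(cm)


class TestAgeTrend:
    def test_planted_decline_detected(self):
        rng = np.random.default_rng(0)
        ages = np.tile(sim.AGE_GROUPS, 10).astype(float)
        decline = 0.8 - 0.015 * ages + rng.normal(0, 0.02, 50)
        rest = 1.0 - decline
        freq = pd.DataFrame({"commensalism": decline, "competition": rest})
        out = eco.age_trend(freq, ages)
        assert out.loc["commensalism", "slope"] < 0
        assert out.loc["commensalism", "fdr"] <= 0.05

    def test_permuted_ages_control_type_one_error(self):
        rng = np.random.default_rng(1)
        ages = np.tile(sim.AGE_GROUPS, 10).astype(float)
        hits = 0
        n_perm = 200
        y = rng.normal(0.5, 0.05, 50)
        for _ in range(n_perm):
            perm = rng.permutation(ages)
            freq = pd.DataFrame({"t": y})
            out = eco.age_trend(freq, perm)
            hits += out.loc["t", "p"] < 0.05
        assert hits / n_perm == pytest.approx(0.05, abs=0.035)

    def test_constant_frequency_is_null(self):
        freq = pd.DataFrame({"neutralism": [0.5] * 6})
        out = eco.age_trend(freq, [2, 9, 15, 24, 30, 30])
        assert out.loc["neutralism", "slope"] == 0.0
        assert out.loc["neutralism", "p"] == 1.0

    def test_slope_scales_with_age_units(self):
        ages = np.array([2.0, 9, 15, 24, 30, 24])
        freq = pd.DataFrame({"t": [0.9, 0.7, 0.55, 0.3, 0.15, 0.32]})
        a = eco.age_trend(freq, ages)
        b = eco.age_trend(freq, ages * 12.0)  # months -> years^-1 scale
        assert b.loc["t", "slope"] == pytest.approx(
            a.loc["t", "slope"] / 12.0)


class TestKnockouts:
    def test_removing_obligate_donor_hurts_community(self):
        donor = sim.make_toy_bacterium("crossfeeder_donor", 0, species="d")
        recip = sim.make_toy_bacterium("crossfeeder_recipient", 0,
                                       species="r")
        cm = eco.CommunityModel([donor, recip], [0.5, 0.5], {"glc": 10.0})
        out = eco.species_knockout_effects(cm)
        assert out["d"] < 0

    def test_removing_competitor_never_hurts(self):
        a = sim.make_toy_bacterium("competitor", 0, species="a")
        b = sim.make_toy_bacterium("competitor", 1, species="b")
        cm = eco.CommunityModel([a, b], [0.5, 0.5], {"glc": 10.0})
        out = eco.species_knockout_effects(cm)
        assert out["a"] >= -1e-9

    def test_singleton_returns_empty(self):
        cm = eco.CommunityModel(fermenters(1), [1.0], {"glc": 10.0})
        assert eco.species_knockout_effects(cm) == {}


class TestActiveReactions:
    def test_glucose_limited_fermenters_use_catabolism(self):
        cm = eco.CommunityModel(fermenters(), [0.5, 0.5], {"glc": 10.0})
        act = eco.active_reactions(eco.community_fba(cm))
        assert "CATAB" in act and "BIOMASS" in act

    def test_closed_diet_means_nothing_active(self):
        cm = eco.CommunityModel(fermenters(), [0.5, 0.5], {"glc": 0.0})
        act = eco.active_reactions(eco.community_fba(cm))
        assert act == {}

    def test_activity_invariant_to_species_order(self):
        a, b = fermenters()
        env = {"glc": 10.0}
        act1 = eco.active_reactions(eco.community_fba(
            eco.CommunityModel([a, b], [0.4, 0.6], env)))
        act2 = eco.active_reactions(eco.community_fba(
            eco.CommunityModel([b, a], [0.6, 0.4], env)))
        assert set(act1) == set(act2)
        for r in act1:
            assert act1[r] == pytest.approx(act2[r], abs=1e-6)
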