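"""EFM sampling, interaction matrices, modules and enrichment."""

import numpy as np
import pytest
from scipy.stats import hypergeom

from metaorg import efm, exact
from metaorg import simulate as sim


class TestSampler:
    def test_diamond_recovers_both_modes(self):
        fx = sim.efm_fixture("diamond")
        s = efm.sample_efms(fx["model"], "U", max_efms=10, max_draws=30,
                            seed=1)
        truth = {f for f in fx["complete_efm_set"] if "U" in f}
        assert set(s.supports) == truth

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_every_support_is_elementary(self, seed):
        fx = sim.efm_fixture("five")
        s = efm.sample_efms(fx["model"], "U", max_efms=50, max_draws=60,
                            seed=seed)
        assert s.supports
        for sup in s.supports:
            assert exact.is_elementary(fx["model"], set(sup))

    def test_complete_recovery_within_500_draws(self):
        fx = sim.efm_fixture("five")
        truth = {f for f in fx["complete_efm_set"] if "U" in f}
        assert len(truth) == 5
        s = efm.sample_efms(fx["model"], "U", max_efms=100, max_draws=500,
                            seed=7)
        assert set(s.supports) == truth

    def test_sampled_supports_never_leave_true_set(self):
        fx = sim.efm_fixture("five")
        truth = set(fx["complete_efm_set"])
        for seed in range(5):
            s = efm.sample_efms(fx["model"], "U", max_efms=100, max_draws=40,
                                seed=seed)
            assert set(s.supports) <= {t for t in truth if "U" in t}

    def test_blocked_indicator_gives_empty_sample(self):
        fx = sim.efm_fixture("diamond")
        model = fx["model"].copy()
        model.reaction("U").ub = 0.0
        s = efm.sample_efms(model, "U", seed=0, max_draws=5)
        assert s.supports == []

    def test_unknown_indicator_raises(self):
        fx = sim.efm_fixture("diamond")
        with pytest.raises(KeyError):
            efm.sample_efms(fx["model"], "NOPE")


class TestInteractionMatrix:
    def sample(self, indicator, supports):
        return efm.EFMSample(indicator, [frozenset(s) for s in supports],
                             len(supports))

    def test_always_cooccurring_reaction_has_frequency_one(self):
        samples = {
            "m1": {"t": self.sample("t", [{"t", "a"}, {"t", "a", "b"}])},
            "m2": {"t": self.sample("t", [{"t", "a"}])},
        }
        mat = efm.interaction_matrix(samples)
        assert mat.entry("t", "a") == pytest.approx(1.0)
        assert mat.entry("t", "t") == pytest.approx(1.0)

    def test_never_cooccurring_reaction_is_zero(self):
        mat = efm.interaction_matrix(
            {"m1": {"t": self.sample("t", [{"t", "a"}])}})
        assert mat.entry("t", "zzz") == 0.0

    def test_partial_frequency_averaged_over_mice(self):
        samples = {
            "m1": {"t": self.sample("t", [{"t", "a"}, {"t"}])},   # 0.5
            "m2": {"t": self.sample("t", [{"t", "a"}])},          # 1.0
            "m3": {"t": self.sample("t", [])},                    # excluded
        }
        mat = efm.interaction_matrix(samples)
        assert mat.entry("t", "a") == pytest.approx(0.75)

    def test_downstream_of_linear_chain_always_present(self):
        fx = sim.efm_fixture("diamond")
        s = efm.sample_efms(fx["model"], "AB", max_efms=10, max_draws=20,
                            seed=3)
        mat = efm.interaction_matrix({"m": {"AB": s}})
        # AB -> B can only drain through E2
        assert mat.entry("AB", "E2") == pytest.approx(1.0)


class TestModules:
    def matrix(self):
        return efm.InteractionMatrix({
            "t": {"t": 1.0, "a": 0.9, "b": 0.2, "c": 0.19,
                  **{f"mb{i}": 0.5 for i in range(25)}},
        })

    def test_membership_threshold_inclusive(self):
        mods = efm.define_modules(self.matrix(), set())
        members = mods[0].members
        assert "b" in members and "c" not in members

    def test_microbial_count_flags_dependency(self):
        mb = {f"mb{i}" for i in range(25)}
        mods = efm.define_modules(self.matrix(), mb)
        assert mods[0].n_microbial == 25
        assert mods[0].microbiome_dependent

    def test_threshold_one_keeps_only_universal_members(self):
        mods = efm.define_modules(self.matrix(), set(),
                                  membership_threshold=1.0)
        assert mods[0].members == {"t"}

    def test_membership_monotone_in_threshold(self):
        sizes = []
        for thr in (0.1, 0.3, 0.6, 0.9):
            mods = efm.define_modules(self.matrix(), set(),
                                      membership_threshold=thr)
            sizes.append(len(mods[0].members))
        assert sizes == sorted(sizes, reverse=True)


class TestAgingEnrichment:
    def test_matches_hypergeometric_oracle(self):
        """A 30-reaction module with 20 aging-down members against a 10%
        background rate is strongly repressed."""
        background = {f"r{i}" for i in range(300)}
        down = {f"r{i}" for i in range(30)}  # 10% of background
        module = efm.MetabolicModule(
            "t", frozenset({f"r{i}" for i in range(10, 40)}),
            n_microbial=0, microbiome_dependent=False)
        out = efm.module_aging_enrichment([module], set(), down, background)
        k = len(set(module.members) & down)  # 20
        expected = hypergeom.sf(k - 1, 300, len(down), 30)
        assert out[0].fisher_p == pytest.approx(expected, rel=1e-9)
        assert out[0].aging_direction == "repressed"
        assert out[0].fisher_p < 0.01

    def test_background_rate_module_not_flagged(self):
        rng = np.random.default_rng(0)
        background = {f"r{i}" for i in range(200)}
        down = set(rng.choice(sorted(background), 20, replace=False))
        members = frozenset(rng.choice(sorted(background), 30, replace=False))
        module = efm.MetabolicModule("t", members, 0, False)
        out = efm.module_aging_enrichment([module], set(), down, background)
        assert out[0].aging_direction == "none"

    def test_empty_background_raises(self):
        module = efm.MetabolicModule("t", frozenset(), 0, False)
        with pytest.raises(ValueError):
            efm.module_aging_enrichment([module], set(), set(), set())


class TestSubsystemPairEnrichment:
    def test_planted_block_enriched(self):
        freq = {}
        for t in range(6):
            entries = {f"mbA{i}": 1.0 for i in range(6)}
            entries.update({f"mbB{i}": 0.0 for i in range(6)})
            freq[f"hA{t}"] = entries
        for t in range(6):
            entries = {f"mbA{i}": 0.0 for i in range(6)}
            entries.update({f"mbB{i}": 1.0 for i in range(6)})
            freq[f"hB{t}"] = entries
        mat = efm.InteractionMatrix(freq)
        host_sub = {f"hA{t}": "glycolysis" for t in range(6)}
        host_sub.update({f"hB{t}": "lipids" for t in range(6)})
        mb_sub = {f"mbA{i}": "fermentation" for i in range(6)}
        mb_sub.update({f"mbB{i}": "vitamins" for i in range(6)})
        out = efm.subsystem_pair_enrichment(mat, host_sub, mb_sub)
        row = out[(out.host_subsystem == "glycolysis")
                  & (out.microbiome_subsystem == "fermentation")]
        assert row["p"].iloc[0] < 0.01

    def test_fisher_matches_hypergeometric_tail(self):
        # [[8,2],[2,8]] one-sided greater
        from scipy.stats import fisher_exact

        _, p = fisher_exact([[8, 2], [2, 8]], alternative="greater")
        expected = hypergeom.sf(7, 20, 10, 10)
        assert p == pytest.approx(expected, rel=1e-9)

    def test_null_matrix_fdr_control(self):
        rng = np.random.default_rng(1)
        freq = {
            f"h{t}": {f"mb{i}": float(rng.random() < 0.5) for i in range(40)}
            for t in range(40)
        }
        mat = efm.InteractionMatrix(freq)
        host_sub = {f"h{t}": f"hs{t % 8}" for t in range(40)}
        mb_sub = {f"mb{i}": f"ms{i % 8}" for i in range(40)}
        out = efm.subsystem_pair_enrichment(mat, host_sub, mb_sub)
        assert (out["fdr"] <= 0.05).mean() <= 0.1


class TestValidateVsCorrelations:
    def planted(self):
        freq = {"r_true": {"mb_true": 1.0, "mb_other": 0.0},
                "r_other": {"mb_true": 0.0, "mb_other": 0.0}}
        mat = efm.InteractionMatrix(freq)
        g2r = {"g_true": {"r_true"}, "g_other": {"r_other"}}
        return mat, g2r

    def test_planted_signal_detected(self):
        mat, g2r = self.planted()
        out = efm.validate_vs_correlations(
            mat, [("g_true", "mb_true")] * 30, g2r,
            candidate_genes=["g_other"],
            microbiome_reactions=["mb_other", "mb_true"],
            n_random=50, seed=1)
        assert out["wilcoxon_p"] < 1e-6

    def test_zero_randomizations_rejected(self):
        mat, g2r = self.planted()
        with pytest.raises(ValueError):
            efm.validate_vs_correlations(mat, [], g2r, ["g"], ["m"],
                                         n_random=0)

    def test_unmapped_genes_counted(self):
        mat, g2r = self.planted()
        out = efm.validate_vs_correlations(
            mat, [("missing", "mb_true"), ("g_true", "mb_true")], g2r,
            ["g_other"], ["mb_other"], n_random=5, seed=0)
        assert out["n_skipped_genes"] == 1
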