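"""Association statistics against exact combinatorial and formula oracles."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr
from statsmodels.stats.multitest import multipletests

from metaorg import stats as st


class TestPartialSpearman:
    def data(self, n=20, seed=0):
        rng = np.random.default_rng(seed)
        x = pd.DataFrame(rng.normal(size=(4, n)),
                         index=[f"x{i}" for i in range(4)])
        y = pd.DataFrame(rng.normal(size=(3, n)),
                         index=[f"y{i}" for i in range(3)])
        cov = pd.DataFrame(rng.normal(size=(1, n)), index=["age"])
        return x, y, cov

    def test_reduces_to_plain_spearman_without_covariates(self):
        x, y, _ = self.data()
        res = st.partial_spearman(x, y)
        for _, row in res.iterrows():
            rho, _ = spearmanr(x.loc[row.host_feature],
                               y.loc[row.microbiome_reaction])
            assert row.rho == pytest.approx(rho, abs=1e-12)

    def test_identical_rows_correlate_perfectly(self):
        x, _, _ = self.data()
        res = st.partial_spearman(x, x.loc[["x0"]])
        hit = res[res.host_feature == "x0"]
        assert hit.rho.iloc[0] == pytest.approx(1.0)

    def test_agrees_with_reference_partial_correlation(self):
        """Independent oracle: pingouin's Spearman partial correlation."""
        pingouin = pytest.importorskip("pingouin")
        x, y, cov = self.data()
        res = st.partial_spearman(x, y, cov)
        for xf, yf in [("x0", "y0"), ("x1", "y2"), ("x3", "y1")]:
            df = pd.DataFrame({"x": x.loc[xf], "y": y.loc[yf],
                               "c": cov.loc["age"]})
            ref = pingouin.partial_corr(df, "x", "y", covar="c",
                                        method="spearman")
            row = res[(res.host_feature == xf)
                      & (res.microbiome_reaction == yf)]
            assert row.rho.iloc[0] == pytest.approx(float(ref["r"].iloc[0]),
                                                    abs=1e-10)
            assert row.p.iloc[0] == pytest.approx(
                float(ref["p_val"].iloc[0]), abs=1e-10)

    def test_invariant_to_monotone_transforms(self):
        x, y, cov = self.data()
        res1 = st.partial_spearman(x, y, cov)
        res2 = st.partial_spearman(np.exp(x), y**3, cov)
        assert np.allclose(res1.rho, res2.rho, atol=1e-12)

    def test_constant_rows_excluded(self):
        x, y, _ = self.data()
        x.loc["x0"] = 1.0
        res = st.partial_spearman(x, y)
        assert "x0" not in set(res.host_feature)


class TestSignificantPairs:
    def frame(self):
        return pd.DataFrame({
            "host_feature": ["a", "b", "c"],
            "microbiome_reaction": ["r1", "r2", "r3"],
            "rho": [0.54, -0.6, 0.9],
            "p": [0.001, 0.002, 0.0001],
        })

    def test_rho_boundary_excludes(self):
        out = st.significant_pairs(self.frame())
        assert "a" not in set(out.host_feature)

    def test_negative_stratum(self):
        out = st.significant_pairs(self.frame())
        row = out[out.host_feature == "b"]
        assert row.stratum.iloc[0] == "negative"

    def test_planted_correlations_recovered_with_power(self):
        rng = np.random.default_rng(5)
        n = 50
        base = rng.normal(size=(30, n))
        x = pd.DataFrame(base + 0.0, index=[f"g{i}" for i in range(30)])
        # first 10 microbiome rows correlate rho ~ 0.7 with matching genes
        y_rows = []
        for i in range(10):
            y_rows.append(0.7 * base[i] + np.sqrt(1 - 0.49)
                          * rng.normal(size=n))
        for i in range(20):
            y_rows.append(rng.normal(size=n))
        y = pd.DataFrame(np.array(y_rows),
                         index=[f"m{i}" for i in range(30)])
        res = st.partial_spearman(x, y)
        out = st.significant_pairs(res, fdr_cut=0.1, rho_cut=0.55)
        truth = {(f"g{i}", f"m{i}") for i in range(10)}
        found = set(zip(out.host_feature, out.microbiome_reaction)) & truth
        assert len(found) / len(truth) > 0.8


class TestHypergeometric:
    def test_full_overlap_identity(self):
        from math import comb

        out = st.hypergeom_enrichment(
            set("abcde"), {"T": set("abcde")}, set("abcdefghijklmnopqrst"),
            min_term_features=3, fdr_cut=1.0)
        assert out["p"].iloc[0] == pytest.approx(1 / comb(20, 5), rel=1e-9)

    def test_zero_overlap_gives_p_one(self):
        out = st.hypergeom_enrichment(
            {"a", "b"}, {"T": {"c", "d"}}, set("abcdefgh"),
            min_term_features=0, fdr_cut=1.0)
        assert out["p"].iloc[0] == pytest.approx(1.0)

    def test_matches_exhaustive_enumeration_small_universe(self):
        """P[overlap >= k] by enumerating all feature-set draws."""
        from math import comb

        universe = set(range(12))
        term = {0, 1, 2, 3, 4}
        features = {0, 1, 2, 7, 8, 9}
        k = len(term & features)
        total = comb(12, len(features))
        count = sum(
            1 for draw in combinations(sorted(universe), len(features))
            if len(set(draw) & term) >= k
        )
        out = st.hypergeom_enrichment(features, {"T": term}, universe,
                                      min_term_features=0, fdr_cut=1.0)
        assert out["p"].iloc[0] == pytest.approx(count / total, rel=1e-9)

    def test_overlap_test_consistency(self):
        universe = set(range(15))
        a = {0, 1, 2, 3}
        b = {2, 3, 4, 5, 6}
        res = st.overlap_test(a, b, universe)
        enr = st.hypergeom_enrichment(a, {"T": b}, universe,
                                      min_term_features=0, fdr_cut=1.0)
        assert res["p"] == pytest.approx(enr["p"].iloc[0], rel=1e-12)
        assert res["k"] == 2

    def test_disjoint_sets_near_one(self):
        assert st.overlap_test({"a"}, {"b"}, set("ab") | set("cdef"))["p"] \
            == pytest.approx(1.0)

    def test_identical_sets_minimal_p(self):
        universe = set(range(15))
        a = set(range(5))
        p_same = st.overlap_test(a, a, universe)["p"]
        p_less = st.overlap_test(a, set(range(1, 6)), universe)["p"]
        assert p_same < p_less

    def test_empty_universe_raises(self):
        with pytest.raises(ValueError):
            st.overlap_test(set(), set(), set())


class TestBenjaminiHochberg:
    def test_hand_example(self):
        adj = multipletests([0.01, 0.02, 0.03, 0.04], method="fdr_bh")[1]
        assert np.allclose(adj, 0.04)

    def test_fdr_never_below_p(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(size=50)
        adj = multipletests(p, method="fdr_bh")[1]
        assert np.all(adj >= p - 1e-12)


class TestMagAgeAssociation:
    def test_normalization_idempotent(self):
        rng = np.random.default_rng(2)
        ab = pd.DataFrame(rng.uniform(0.1, 1, (5, 10)),
                          index=[f"s{i}" for i in range(5)])
        ages = np.linspace(2, 30, 10)
        a = st.mag_age_association(ab, ages)
        b = st.mag_age_association(ab.div(ab.sum(axis=0), axis=1), ages)
        assert np.allclose(a["slope"], b["slope"])

    def test_permuted_ages_type_one_error(self):
        rng = np.random.default_rng(3)
        species = [f"sp{i}" for i in range(10)]
        from metaorg.simulate import simulate_abundances

        ages = np.linspace(2, 30, 40)
        ab = simulate_abundances(species, 40, ages, effect_size=0.0, seed=9)
        hits = []
        for _ in range(100):
            perm = rng.permutation(ages)
            res = st.mag_age_association(ab, perm)
            hits.append((res["p"] < 0.05).mean())
        assert np.mean(hits) == pytest.approx(0.05, abs=0.03)


class TestSignedLogFdr:
    def frame(self):
        return pd.DataFrame({
            "term_id": ["t1", "t2", "t3"],
            "group": ["G", "G", "H"],
            "stratum": ["positive", "negative", "positive"],
            "fdr": [0.01, 0.01, 1e-320],
        })

    def test_sign_and_magnitude(self):
        out = st.signed_log_fdr(self.frame())
        assert out.signed_log_fdr.iloc[0] == pytest.approx(2.0)
        assert out.signed_log_fdr.iloc[1] == pytest.approx(-2.0)

    def test_zero_fdr_capped(self):
        out = st.signed_log_fdr(self.frame())
        assert out.signed_log_fdr.iloc[2] == pytest.approx(300.0)

    def test_group_sum_additive(self):
        full = st.signed_log_fdr(self.frame())
        grouped = st.signed_log_fdr(self.frame(), group_cols=["group"])
        g = grouped[grouped.group == "G"]["signed_log_fdr"].iloc[0]
        assert g == pytest.approx(
            full[full.group == "G"]["signed_log_fdr"].sum())


class TestAgeGroupRatios:
    def test_identical_ratios_not_significant(self):
        out = st.age_group_ratio_tests([10, 10], [100, 100])
        assert out["p"].iloc[0] > 0.9

    def test_large_difference_significant(self):
        out = st.age_group_ratio_tests([100, 300], [1000, 1000])
        assert out["p"].iloc[0] < 1e-6

    def test_bonferroni_definition(self):
        out = st.age_group_ratio_tests([10, 30, 10], [100, 100, 100])
        m = len(out)
        assert np.allclose(out["p_bonferroni"],
                           np.minimum(1.0, m * out["p"]))


class TestAgingGeneSets:
    def test_planted_direction_assignment(self):
        from metaorg.simulate import AGE_GROUPS, simulate_expression

        genes = [f"g{i}" for i in range(100)]
        ages = np.tile(AGE_GROUPS, 10).astype(float)
        counts = simulate_expression(genes, 50, ages,
                                     aging_down=set(genes[:5]),
                                     aging_up=set(genes[5:10]),
                                     effect_size=1.0, seed=21)
        up, down = st.aging_gene_sets(np.log2(counts + 1), ages)
        assert set(genes[:5]) <= down
        assert set(genes[5:10]) <= up
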