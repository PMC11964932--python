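"""Benchmark procedures validating the pipeline on synthetic ground truth.

Each function runs one self-contained evaluation — LP machinery against
exhaustive vertex enumeration, FASTCORE against brute-force minimal
subnetworks, the EFM sampler against complete enumerated mode sets, the
ecological classifier against constructed pairs, dependency scoring against
planted exchanges, aging-module recovery against planted expression trends,
the statistics against exact combinatorial oracles, and the conservation
identities of the assembled metamodel — and returns a flat dict of metrics.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from . import efm, exact, lp
from . import assembly as asm
from . import dependency as dep
from . import ecology as eco
from . import extraction as ext
from . import simulate as sim
from . import stats as st

BBB = {"glc", "o2", "aa", "co2", "lac"}


def _metamodel(seed: int, planted_egc: bool = False):
    bundle = sim.make_fixture_bundle(seed)
    tissues = {
        o: sim.make_toy_tissue(o, seed, planted_egc=(planted_egc
                                                     and o == "colon"))
        for o in sim.ORGANS
    }
    mm = asm.assemble_metamodel(tissues, bundle.microbiome, bbb=BBB)
    return bundle, asm.apply_diet(mm, bundle.diet)


def fva_vertex_agreement(n_networks: int = 50, seed: int = 0) -> dict:
    """Max |FVA - vertex enumeration| over random toy networks."""
    max_err = 0.0
    for i in range(n_networks):
        model = sim.random_toy_network(seed * 1000 + i)
        truth = exact.fva_by_vertex_enumeration(model)
        for fr in lp.fva(model):
            lo, hi = truth[fr.reaction_id]
            max_err = max(max_err, abs(fr.vmin - lo), abs(fr.vmax - hi))
    return {"max_abs_error": max_err, "n_networks": n_networks}


def fastcore_minimality(n_cases: int = 10, seed: int = 0) -> dict:
    """FASTCORE vs exhaustive minimal consistent supersets on small toys."""
    rng = np.random.default_rng(seed)
    n_match = n_done = 0
    max_excess = 0
    core_ok = consistent_ok = True
    attempt = 0
    while n_done < n_cases and attempt < 10 * n_cases:
        attempt += 1
        model = sim.random_toy_network(seed * 777 + attempt)
        blocked = ext.blocked_reactions(model)
        if len(model.reactions) - len(blocked) < 3:
            continue
        consistent = ext.fastcc(model)
        core = set(rng.choice(consistent.reaction_ids, size=2,
                              replace=False))
        ctx, excluded = ext.fastcore(consistent, core)
        n_done += 1
        core_ok &= (excluded == set() and core <= set(ctx.reaction_ids))
        consistent_ok &= (ext.fastcc(ctx).reaction_ids == ctx.reaction_ids)
        n_noncore = len(set(ctx.reaction_ids) - core)
        best = exact.min_consistent_superset(consistent, core)
        if n_noncore == best:
            n_match += 1
        max_excess = max(max_excess, n_noncore - best)
    return {
        "n_cases": n_done,
        "n_matching_minimum": n_match,
        "max_excess_noncore": max_excess,
        "all_core_included": bool(core_ok),
        "all_outputs_consistent": bool(consistent_ok),
    }


def efm_sampler_validity(seed: int = 0, max_draws: int = 500) -> dict:
    """Elementarity rate and completeness on the enumerable fixtures."""
    n_modes = n_elementary = 0
    complete = True
    for kind in ("diamond", "five"):
        fx = sim.efm_fixture(kind)
        truth = {f for f in fx["complete_efm_set"] if fx["indicator"] in f}
        sample = efm.sample_efms(fx["model"], fx["indicator"], max_efms=1000,
                                 max_draws=max_draws, seed=seed)
        for sup in sample.supports:
            n_modes += 1
            n_elementary += exact.is_elementary(fx["model"], set(sup))
        complete &= (set(sample.supports) == truth)
    return {
        "n_modes": n_modes,
        "elementarity_rate": n_elementary / max(n_modes, 1),
        "complete_recovery": bool(complete),
    }


def ecology_six_way(seeds=(0, 1, 2)) -> dict:
    """Fraction of constructed species pairs classified as planted."""
    n_ok = n_total = 0
    for s in seeds:
        for a, b, env, expected in sim.six_pair_fixtures(s):
            n_total += 1
            n_ok += (eco.classify_pair(a, b, env).type == expected)
    return {"n_pairs": n_total, "n_correct": n_ok,
            "accuracy": n_ok / n_total}


def dependency_recovery(seed: int = 0, n_samples: int = 10) -> dict:
    """Planted microbiome-dependent and host-autonomous exchanges across
    fixture samples, plus blocking monotonicity."""
    bundle, mm = _metamodel(seed)
    target = bundle.truth["microbiome_dependent_metabolite"]
    autonomous = bundle.truth["host_autonomous_metabolite"]
    dep_hits = auto_clean = 0
    monotone_violations = 0
    for i in range(n_samples):
        records = dep.microbiome_dependency(mm, f"s{i}")
        planted = [r for r in records
                   if r.metabolite == target and r.direction == "uptake"
                   and r.range_full > 0]
        dep_hits += bool(planted) and all(
            r.dependent and r.range_blocked <= 1e-6 for r in planted)
        auto = [r for r in records if r.metabolite == autonomous]
        auto_clean += bool(auto) and not any(r.dependent for r in auto)
        for r in records:
            if r.range_blocked > r.range_full + 1e-7:
                monotone_violations += 1
    return {
        "n_samples": n_samples,
        "dependent_detection_rate": dep_hits / n_samples,
        "autonomous_clean_rate": auto_clean / n_samples,
        "monotonicity_violations": monotone_violations,
    }


def _aging_modules(seed: int):
    """Interaction-matrix modules around the planted butyrate indicator."""
    bundle, mm = _metamodel(seed)
    indicator = "colon__EX_but__lumen__upt"
    sample = efm.sample_efms(mm, indicator, max_efms=200, max_draws=60,
                             seed=seed)
    matrix = efm.interaction_matrix({"m": {indicator: sample}})
    mb = {r.id for r in mm.reactions if r.provenance == "microbiome"}
    modules = efm.define_modules(matrix, mb, min_microbial=5)
    background = {r.id for r in mm.reactions if r.provenance == "colon"}
    return bundle, modules, background


def aging_module_recovery(n_replicates: int = 50, n_samples: int = 50,
                          effect_size: float = 1.0, seed: int = 0) -> dict:
    """Power to flag the planted aging-repressed module, and the module
    false-positive rate under a null (no age effect) simulation."""
    bundle, modules, background = _aging_modules(seed)
    down_truth = set(bundle.truth["aging_down_genes"])
    genes = sorted(bundle.gene_to_reactions)
    ages = sim.cohort_ages()[:n_samples]
    flagged = null_flagged = 0
    for rep in range(n_replicates):
        counts = sim.simulate_expression(
            genes, n_samples, ages, aging_down=down_truth,
            effect_size=effect_size,
            seed=(seed * 100000 + rep) % (2**31 - 1))
        _, down = st.aging_gene_sets(np.log2(counts + 1), ages)
        down_rxns = set()
        for g in down:
            down_rxns |= bundle.gene_to_reactions.get(g, set())
        out = efm.module_aging_enrichment(modules, set(), down_rxns,
                                          background)
        flagged += (out[0].aging_direction == "repressed")

        null_counts = sim.simulate_expression(
            genes, n_samples, ages, effect_size=0.0,
            seed=(seed * 100000 + 50000 + rep) % (2**31 - 1))
        up0, down0 = st.aging_gene_sets(np.log2(null_counts + 1), ages)
        rxns0 = set()
        for g in up0 | down0:
            rxns0 |= bundle.gene_to_reactions.get(g, set())
        out0 = efm.module_aging_enrichment(modules, rxns0, rxns0, background)
        null_flagged += (out0[0].aging_direction != "none")
    return {
        "n_replicates": n_replicates,
        "power": flagged / n_replicates,
        "null_false_positive_rate": null_flagged / n_replicates,
    }


def stats_oracles(seed: int = 0, n_permutations: int = 1000) -> dict:
    """Exact-oracle agreement of the statistical machinery."""
    from itertools import combinations
    from math import comb

    # hypergeometric vs exhaustive enumeration on a small universe
    universe = set(range(12))
    term = {0, 1, 2, 3, 4}
    features = {0, 1, 2, 7, 8, 9}
    k = len(term & features)
    count = sum(
        1 for draw in combinations(sorted(universe), len(features))
        if len(set(draw) & term) >= k
    )
    enr = st.hypergeom_enrichment(features, {"T": term}, universe,
                                  min_term_features=0, fdr_cut=1.0)
    hyper_err = abs(enr["p"].iloc[0] - count / comb(12, len(features)))

    bh = multipletests([0.01, 0.02, 0.03, 0.04], method="fdr_bh")[1]
    bh_err = float(np.max(np.abs(bh - 0.04)))

    # partial Spearman with no covariates equals plain Spearman
    from scipy.stats import spearmanr

    rng = np.random.default_rng(seed)
    x = pd.DataFrame(rng.normal(size=(4, 20)),
                     index=[f"x{i}" for i in range(4)])
    y = pd.DataFrame(rng.normal(size=(3, 20)),
                     index=[f"y{i}" for i in range(3)])
    res = st.partial_spearman(x, y)
    sp_err = 0.0
    for _, row in res.iterrows():
        rho, _ = spearmanr(x.loc[row.host_feature],
                           y.loc[row.microbiome_reaction])
        sp_err = max(sp_err, abs(row.rho - rho))

    # type-I error of the correlation under permuted sample labels
    xs = rng.normal(size=(5, 20))
    ys = rng.normal(size=(2, 20))
    hits = total = 0
    xdf = pd.DataFrame(xs, index=[f"g{i}" for i in range(5)])
    for _ in range(n_permutations):
        perm = rng.permutation(20)
        ydf = pd.DataFrame(ys[:, perm], index=["r0", "r1"],
                           columns=xdf.columns)
        p = st.partial_spearman(xdf, ydf)["p"]
        hits += int((p < 0.05).sum())
        total += len(p)
    return {
        "hypergeom_max_error": float(hyper_err),
        "bh_max_error": bh_err,
        "spearman_reduction_max_error": float(sp_err),
        "permutation_type1_rate": hits / total,
    }


def conservation_identities(seed: int = 0) -> dict:
    """Diet split, column normalizations and post-resolution energy
    balance."""
    bundle, mm = _metamodel(seed, planted_egc=True)
    rxn = {r.id: r for r in mm.reactions}
    diet_err = 0.0
    for e in bundle.diet.entries:
        blood = rxn.get(f"DIET_{e.metabolite}_blood")
        lumen = rxn.get(f"DIET_{e.metabolite}_lumen")
        total = (blood.ub if blood else 0.0) + (lumen.ub if lumen else 0.0)
        diet_err = max(diet_err, abs(total - e.mmol_per_day))

    lumen_env = {
        e.metabolite: e.mmol_per_day * (1.0 - e.absorbed_fraction)
        for e in bundle.diet.entries
    }
    cm = eco.CommunityModel(bundle.bacteria, [1, 1, 1, 1], lumen_env)
    freq = eco.interaction_frequencies(cm).freq
    freq_err = abs(sum(freq.values()) - 1.0)

    contribution = pd.DataFrame(
        0.0, index=[b.name for b in bundle.bacteria],
        columns=bundle.microbiome.reaction_ids)
    for rid, species in bundle.microbiome.membership.items():
        for s in species:
            contribution.loc[s, rid] = 1.0
    ram = ext.reaction_abundance_matrix(bundle.abundances, contribution)
    ram_err = float(np.max(np.abs(ram.sum(axis=0) - 1.0)))

    resolved, corrections = asm.resolve_egcs(mm)
    closed = lp.close_inflows(resolved)
    egc_max = 0.0
    for d in asm.dissipation_reactions(resolved):
        sol = lp.fba(closed, objective=d)
        if sol.optimal:
            egc_max = max(egc_max, abs(sol.objective_value))
    return {
        "diet_split_max_error": diet_err,
        "interaction_freq_sum_error": freq_err,
        "reaction_abundance_colsum_max_error": ram_err,
        "closed_input_dissipation_max": egc_max,
        "n_egc_corrections": len(corrections),
    }
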