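"""Synthetic study inputs with the structural and statistical properties the
metaorganism analysis assumes.

Provides seeded generators for small flux-consistent organ and bacterial
models with designed cross-feeding/competition structure, negative-binomial
expression counts with age trends and batch effects, compositional MAG
abundance matrices with age trends, a mouse diet table, and tiny fixture
networks whose complete elementary-flux-mode sets are enumerable.

The cohort design mirrors a five-group aging study: ages 2, 9, 15, 24 and
30 months with 10/10/10/10/12 animals (52 in total).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .network import MetabolicModel, Metabolite, Reaction, merge_microbiome
from .assembly import DietEntry, DietSpec
from . import exact

AGE_GROUPS = (2, 9, 15, 24, 30)
GROUP_SIZES = (10, 10, 10, 10, 12)

ORGANS = ("colon", "liver", "brain")

BACTERIAL_STRATEGIES = (
    "fermenter",
    "crossfeeder_donor",
    "crossfeeder_recipient",
    "competitor",
    "independent",
    "exploiter",
)


def cohort_ages() -> np.ndarray:
    """Ages (months) of the emulated 52-mouse cohort."""
    return np.repeat(AGE_GROUPS, GROUP_SIZES).astype(float)


# ---------------------------------------------------------------------------
# toy organ models
# ---------------------------------------------------------------------------

def _ex(rid, met, lb, ub):
    return Reaction(rid, {met: -1.0}, lb, ub, provenance="exchange")


def make_toy_tissue(organ: str, seed: int = 0,
                    planted_egc: bool = False) -> MetabolicModel:
    """A small flux-consistent organ model.

    Core content: glucose/oxygen/amino-acid uptake, glycolysis, respiration,
    lactate fermentation, protein synthesis and an ATP-maintenance
    (dissipation) reaction.  Colon and liver additionally oxidize luminal
    butyrate (the planted microbiome-dependent input); the liver synthesizes
    bile acids and the brain sphingolipids.  With ``planted_egc`` a
    mis-reversible phosphorylation reaction is added whose reverse direction
    regenerates ATP for free.  Deterministic given (organ, seed).
    """
    if organ not in ORGANS:
        raise ValueError(f"unknown organ {organ!r}")
    rng = np.random.default_rng(seed + 7919 * ORGANS.index(organ))

    mets = {}

    def M(mid, comp):
        if mid not in mets:
            mets[mid] = Metabolite(mid, name=mid, compartment=comp)
        return mid

    for m in ("glc", "o2", "aa", "lac", "co2"):
        M(f"{m}_e", "e")
    for m in ("glc", "o2", "aa", "lac", "co2", "pyr", "atp", "adp", "pi",
              "prot"):
        M(f"{m}_c", "c")

    gene_counter = [0]

    def genes(n=1):
        out = frozenset(
            f"g_{organ}_{gene_counter[0] + i}" for i in range(n)
        )
        gene_counter[0] += n
        return out

    rxns = [
        _ex("EX_glc_e", "glc_e", -10.0, 0.0),
        _ex("EX_o2_e", "o2_e", -40.0, 0.0),
        _ex("EX_aa_e", "aa_e", -5.0, 0.0),
        _ex("EX_lac_e", "lac_e", 0.0, 1000.0),
        _ex("EX_co2_e", "co2_e", 0.0, 1000.0),
        Reaction("T_glc", {"glc_e": -1, "glc_c": 1}, 0, 1000, genes(1),
                 "transport", organ),
        Reaction("T_o2", {"o2_e": -1, "o2_c": 1}, 0, 1000, genes(1),
                 "transport", organ),
        Reaction("T_aa", {"aa_e": -1, "aa_c": 1}, 0, 1000, genes(1),
                 "transport", organ),
        Reaction("T_lac", {"lac_c": -1, "lac_e": 1}, 0, 1000, genes(1),
                 "transport", organ),
        Reaction("T_co2", {"co2_c": -1, "co2_e": 1}, 0, 1000, genes(1),
                 "transport", organ),
        Reaction("GLYC", {"glc_c": -1, "adp_c": -2, "pi_c": -2,
                          "pyr_c": 2, "atp_c": 2}, 0, 1000, genes(2),
                 "glycolysis", organ),
        Reaction("RESP", {"pyr_c": -1, "o2_c": -1, "adp_c": -2, "pi_c": -2,
                          "co2_c": 1, "atp_c": 2}, 0, 1000, genes(2),
                 "respiration", organ),
        Reaction("LDH", {"pyr_c": -1, "lac_c": 1}, 0, 1000, genes(1),
                 "glycolysis", organ),
        Reaction("PROTS", {"aa_c": -1, "atp_c": -1, "prot_c": 1,
                           "adp_c": 1, "pi_c": 1}, 0, 1000, genes(1),
                 "protein metabolism", organ),
        Reaction("DM_prot", {"prot_c": -1}, 0, 1000, frozenset(),
                 "protein metabolism", organ),
        Reaction("ATPM", {"atp_c": -1, "adp_c": 1, "pi_c": 1}, 0, 1000,
                 genes(1), "maintenance", organ),
    ]

    if organ == "colon":
        # a six-step butyrate oxidation chain: the planted
        # microbiome-dependent, aging-repressed module
        for m in ("but", "butcoa", "crot", "hbcoa", "accoa"):
            M(f"{m}_c", "c")
        M("but_e", "e")
        rxns += [
            _ex("EX_but_e", "but_e", -5.0, 0.0),
            Reaction("T_but", {"but_e": -1, "but_c": 1}, 0, 1000, genes(1),
                     "fatty acid oxidation", organ),
            Reaction("BUTCOA", {"but_c": -1, "atp_c": -1, "butcoa_c": 1,
                                "adp_c": 1, "pi_c": 1}, 0, 1000, genes(2),
                     "fatty acid oxidation", organ),
            Reaction("BOX1", {"butcoa_c": -1, "o2_c": -1, "crot_c": 1,
                              "co2_c": 1}, 0, 1000, genes(2),
                     "fatty acid oxidation", organ),
            Reaction("BOX2", {"crot_c": -1, "hbcoa_c": 1}, 0, 1000, genes(1),
                     "fatty acid oxidation", organ),
            Reaction("BOX3", {"hbcoa_c": -1, "o2_c": -1, "accoa_c": 1,
                              "co2_c": 1}, 0, 1000, genes(2),
                     "fatty acid oxidation", organ),
            Reaction("BOX4", {"accoa_c": -1, "o2_c": -1, "adp_c": -2,
                              "pi_c": -2, "atp_c": 2, "co2_c": 1}, 0, 1000,
                     genes(2), "fatty acid oxidation", organ),
        ]
    if organ == "liver":
        M("but_e", "e")
        M("but_c", "c")
        rxns += [
            _ex("EX_but_e", "but_e", -5.0, 0.0),
            Reaction("T_but", {"but_e": -1, "but_c": 1}, 0, 1000, genes(1),
                     "transport", organ),
            Reaction("BUTOX", {"but_c": -1, "o2_c": -1, "adp_c": -2,
                               "pi_c": -2, "atp_c": 2, "co2_c": 1}, 0, 1000,
                     genes(2), "fatty acid oxidation", organ),
        ]
    if organ == "liver":
        M("ba_e", "e")
        M("ba_c", "c")
        rxns += [
            Reaction("BAS", {"pyr_c": -2, "atp_c": -1, "ba_c": 1,
                             "adp_c": 1, "pi_c": 1}, 0, 1000, genes(2),
                     "bile acid synthesis", organ),
            Reaction("T_ba", {"ba_c": -1, "ba_e": 1}, 0, 1000, genes(1),
                     "transport", organ),
            _ex("EX_ba_e", "ba_e", 0.0, 1000.0),
        ]
    if organ == "brain":
        M("sph_c", "c")
        rxns += [
            Reaction("SPH", {"aa_c": -1, "atp_c": -1, "sph_c": 1,
                             "adp_c": 1, "pi_c": 1}, 0, 1000, genes(2),
                     "sphingolipid metabolism", organ),
            Reaction("DM_sph", {"sph_c": -1}, 0, 1000, frozenset(),
                     "sphingolipid metabolism", organ),
        ]

    # seeded isoform duplicates keep the network consistent but vary its size
    iso_candidates = ["T_glc", "GLYC", "LDH", "PROTS", "T_aa"]
    n_iso = int(rng.integers(0, 4))
    for rid in rng.permutation(iso_candidates)[:n_iso]:
        src = next(r for r in rxns if r.id == rid)
        rxns.append(Reaction(f"{rid}b", dict(src.stoich), src.lb, src.ub,
                             genes(1), src.subsystem, organ))

    if planted_egc:
        rxns.append(Reaction("PHOS", {"atp_c": -1, "adp_c": 1, "pi_c": 1},
                             -1000, 1000, genes(1), "maintenance", organ))

    return MetabolicModel(list(mets.values()), rxns, objective="ATPM",
                          name=organ)


# ---------------------------------------------------------------------------
# toy bacteria
# ---------------------------------------------------------------------------

def make_toy_bacterium(strategy: str, seed: int = 0, species: str | None = None,
                       substrate: str = "glc", byproduct: str = "but",
                       requires: str | None = None, secretes: str | None = None,
                       uptake_ub: float = 10.0) -> MetabolicModel:
    """A small bacterial model realizing an ecological strategy.

    Strategies: a ``fermenter`` (equivalently ``crossfeeder_donor``) grows on
    ``substrate`` and obligatorily secretes ``byproduct``; a
    ``crossfeeder_recipient`` grows only on ``byproduct``; a ``competitor``
    grows on ``substrate`` without secretion; an ``independent`` grows on the
    private substrate ``xyl``; an ``exploiter`` needs both ``substrate`` and
    ``byproduct``.  ``requires`` adds an obligatory cofactor uptake to the
    catabolic reaction and ``secretes`` an obligatory cofactor secretion to
    growth, which lets reciprocal (mutualistic) pairs be constructed.
    """
    if strategy not in BACTERIAL_STRATEGIES:
        raise ValueError(f"unknown strategy {strategy!r}")
    name = species or f"sp_{strategy}_{seed}"
    rng = np.random.default_rng(seed + 104729)

    mets = {}

    def M(mid, comp):
        if mid not in mets:
            mets[mid] = Metabolite(mid, name=mid, compartment=comp)
        return mid

    def T(base, direction):
        M(f"{base}_e", "e")
        M(f"{base}_c", "c")
        if direction == "in":
            return Reaction(f"T_{base}", {f"{base}_e": -1, f"{base}_c": 1},
                            0, 1000, frozenset(), "transport", "microbiome")
        return Reaction(f"T_{base}x", {f"{base}_c": -1, f"{base}_e": 1},
                        0, 1000, frozenset(), "transport", "microbiome")

    for m in ("ac", "atp", "adp", "pi", "bm"):
        M(f"{m}_c", "c")

    rxns: list[Reaction] = []
    catab = {"adp_c": -2.0, "pi_c": -2.0, "ac_c": 1.0, "atp_c": 2.0}
    if strategy in ("fermenter", "crossfeeder_donor", "competitor"):
        rxns += [_ex(f"EX_{substrate}_e", M(f"{substrate}_e", "e"),
                     -uptake_ub, 0.0), T(substrate, "in")]
        catab[f"{substrate}_c"] = -1.0
        if strategy != "competitor":
            M(f"{byproduct}_c", "c")
            catab[f"{byproduct}_c"] = 1.0
            rxns += [T(byproduct, "out"),
                     _ex(f"EX_{byproduct}_e", f"{byproduct}_e", 0.0, 1000.0)]
    elif strategy == "crossfeeder_recipient":
        rxns += [_ex(f"EX_{byproduct}_e", M(f"{byproduct}_e", "e"),
                     -uptake_ub, 0.0), T(byproduct, "in")]
        catab[f"{byproduct}_c"] = -1.0
    elif strategy == "independent":
        rxns += [_ex("EX_xyl_e", M("xyl_e", "e"), -uptake_ub, 0.0),
                 T("xyl", "in")]
        catab["xyl_c"] = -1.0
    elif strategy == "exploiter":
        rxns += [_ex(f"EX_{substrate}_e", M(f"{substrate}_e", "e"),
                     -uptake_ub, 0.0), T(substrate, "in"),
                 _ex(f"EX_{byproduct}_e", M(f"{byproduct}_e", "e"),
                     -uptake_ub, 0.0), T(byproduct, "in")]
        catab[f"{substrate}_c"] = -1.0
        catab[f"{byproduct}_c"] = -1.0

    if requires:
        rxns += [_ex(f"EX_{requires}_e", M(f"{requires}_e", "e"), -1000.0, 0.0),
                 T(requires, "in")]
        catab[f"{requires}_c"] = -1.0

    growth = {"ac_c": -1.0, "atp_c": -1.0, "bm_c": 1.0, "adp_c": 1.0,
              "pi_c": 1.0}
    if secretes:
        M(f"{secretes}_c", "c")
        growth[f"{secretes}_c"] = 1.0
        rxns += [T(secretes, "out"),
                 _ex(f"EX_{secretes}_e", f"{secretes}_e", 0.0, 1000.0)]

    gid = f"g_{name}"
    rxns += [
        Reaction("CATAB", catab, 0, 1000, frozenset({f"{gid}_cat"}),
                 "central fermentation", "microbiome"),
        Reaction("BIOMASS", growth, 0, 1000, frozenset({f"{gid}_bio"}),
                 "biomass", "microbiome"),
        Reaction("ATPM", {"atp_c": -1, "adp_c": 1, "pi_c": 1}, 0, 1000,
                 frozenset(), "maintenance", "microbiome"),
        Reaction("DM_bm", {"bm_c": -1}, 0, 1000, frozenset(), "biomass",
                 "microbiome"),
    ]
    _ = rng  # seed reserved for future stochastic variants; kept for API stability
    model = MetabolicModel(list(mets.values()), rxns, objective="BIOMASS",
                           name=name)
    return model


def six_pair_fixtures(seed: int = 0):
    """Six constructed species pairs, one per ecological interaction type.

    Returns a list of (model_a, model_b, environment, expected_type) with the
    shared environment given as dietary availability (mmol/day per
    metabolite base name).
    """
    env = {"glc": 10.0, "xyl": 10.0}
    donor = make_toy_bacterium("crossfeeder_donor", seed, species="donor")
    recipient = make_toy_bacterium("crossfeeder_recipient", seed,
                                   species="recipient")
    comp_a = make_toy_bacterium("competitor", seed, species="comp_a")
    comp_b = make_toy_bacterium("competitor", seed + 1, species="comp_b")
    indep = make_toy_bacterium("independent", seed, species="indep")
    exploiter = make_toy_bacterium("exploiter", seed, species="exploiter")
    slow = make_toy_bacterium("crossfeeder_donor", seed, species="slow",
                              uptake_ub=3.0)
    mut_a = make_toy_bacterium("crossfeeder_donor", seed, species="mut_a",
                               requires="vit")
    mut_b = make_toy_bacterium("crossfeeder_recipient", seed, species="mut_b",
                               secretes="vit")
    return [
        (mut_a, mut_b, env, "mutualism"),
        (donor, recipient, env, "commensalism"),
        (indep, comp_a, env, "neutralism"),
        (slow, comp_a, env, "amensalism"),
        (comp_a, comp_b, env, "competition"),
        (donor, exploiter, env, "exploitation"),
    ]


# ---------------------------------------------------------------------------
# omics simulators
# ---------------------------------------------------------------------------

def simulate_expression(gene_ids, n_samples: int, age_months,
                        aging_down=frozenset(), aging_up=frozenset(),
                        effect_size: float = 1.0, batch=None, seed: int = 0,
                        dispersion: float = 0.2,
                        baseline_log_mean: float = 5.0,
                        baseline_log_sd: float = 1.0,
                        batch_sd: float = 0.3) -> pd.DataFrame:
    """Negative-binomial RNA-seq counts (genes x samples) with planted aging
    trends.

    Baseline means are log-normal; genes in ``aging_down``/``aging_up`` have
    their mean multiplied by 2**(-/+ effect_size * age / 10), i.e.
    ``effect_size`` is a log2 fold change per 10 months of age.  ``batch``
    adds a multiplicative log-normal factor per (gene, batch).
    """
    gene_ids = list(gene_ids)
    age = np.asarray(age_months, dtype=float)
    if len(age) != n_samples:
        raise ValueError("age vector length must equal n_samples")
    aging_down = set(aging_down)
    aging_up = set(aging_up)
    overlap = aging_down & aging_up
    if overlap:
        raise ValueError(f"genes in both aging sets: {sorted(overlap)}")
    rng = np.random.default_rng(seed)
    base = np.exp(rng.normal(baseline_log_mean, baseline_log_sd,
                             size=len(gene_ids)))
    direction = np.array([
        -1.0 if g in aging_down else (1.0 if g in aging_up else 0.0)
        for g in gene_ids
    ])
    mu = base[:, None] * 2.0 ** (
        direction[:, None] * effect_size * age[None, :] / 10.0
    )
    if batch is not None:
        batch = np.asarray(batch)
        if len(batch) != n_samples:
            raise ValueError("batch vector length must equal n_samples")
        levels = list(dict.fromkeys(batch.tolist()))
        factors = np.exp(rng.normal(0.0, batch_sd,
                                    size=(len(gene_ids), len(levels))))
        col = np.array([levels.index(b) for b in batch])
        mu = mu * factors[:, col]
    r = 1.0 / dispersion
    p = r / (r + mu)
    counts = rng.negative_binomial(r, p)
    return pd.DataFrame(counts, index=gene_ids,
                        columns=[f"s{i}" for i in range(n_samples)])


def simulate_abundances(species, n_samples: int, age_months,
                        aging_up=frozenset(), aging_down=frozenset(),
                        effect_size: float = 1.0, seed: int = 0,
                        noise_sd: float = 0.4) -> pd.DataFrame:
    """Compositional species-abundance matrix (species x samples) with
    planted age trends; every column sums to one."""
    species = list(species)
    age = np.asarray(age_months, dtype=float)
    if len(age) != n_samples:
        raise ValueError("age vector length must equal n_samples")
    overlap = set(aging_up) & set(aging_down)
    if overlap:
        raise ValueError(f"species in both aging sets: {sorted(overlap)}")
    rng = np.random.default_rng(seed)
    base = np.exp(rng.normal(3.0, 0.8, size=len(species)))
    direction = np.array([
        1.0 if s in set(aging_up) else (-1.0 if s in set(aging_down) else 0.0)
        for s in species
    ])
    mu = base[:, None] * 2.0 ** (
        direction[:, None] * effect_size * age[None, :] / 10.0
    )
    raw = mu * np.exp(rng.normal(0.0, noise_sd, size=mu.shape))
    raw = raw / raw.sum(axis=0, keepdims=True)
    return pd.DataFrame(raw, index=species,
                        columns=[f"s{i}" for i in range(n_samples)])


# ---------------------------------------------------------------------------
# enumerable EFM fixtures and diet
# ---------------------------------------------------------------------------

def efm_fixture(kind: str = "diamond") -> dict:
    """A tiny network together with its complete, brute-force-enumerated EFM
    set (the oracle for the EFM sampler).

    ``diamond``: uptake -> A with two alternative drains (2 modes through the
    uptake).  ``five``: two parallel steps A->B, two parallel B->C and one
    direct A->C drain (5 modes through the uptake).
    """
    def mets(ids):
        return [Metabolite(i, compartment="c" if i not in ("",) else "c")
                for i in ids]

    if kind == "diamond":
        model = MetabolicModel(
            mets(["A", "B"]),
            [
                Reaction("U", {"A": 1}, 0, 10, provenance="exchange"),
                Reaction("E1", {"A": -1}, 0, 1000, provenance="exchange"),
                Reaction("AB", {"A": -1, "B": 1}, 0, 1000,
                         provenance="microbiome"),
                Reaction("E2", {"B": -1}, 0, 1000, provenance="exchange"),
            ],
            name="efm-diamond",
        )
    elif kind == "five":
        model = MetabolicModel(
            mets(["A", "B", "C"]),
            [
                Reaction("U", {"A": 1}, 0, 10, provenance="exchange"),
                Reaction("P1", {"A": -1, "B": 1}, 0, 1000,
                         provenance="colon"),
                Reaction("P2", {"A": -1, "B": 1}, 0, 1000,
                         provenance="colon"),
                Reaction("Q1", {"B": -1, "C": 1}, 0, 1000,
                         provenance="microbiome"),
                Reaction("Q2", {"B": -1, "C": 1}, 0, 1000,
                         provenance="microbiome"),
                Reaction("D", {"A": -1, "C": 1}, 0, 1000,
                         provenance="colon"),
                Reaction("E", {"C": -1}, 0, 1000, provenance="exchange"),
            ],
            name="efm-five",
        )
    else:
        raise ValueError(f"unknown fixture kind {kind!r}")
    return {
        "model": model,
        "complete_efm_set": exact.enumerate_efms(model),
        "indicator": "U",
    }


def random_toy_network(seed: int, max_reactions: int = 8) -> MetabolicModel:
    """A random small stoichiometric network with finite bounds.

    Used to exercise LP machinery against exhaustive polytope-vertex
    enumeration: coefficients are small integers, a random subset of
    reactions is reversible, and all bounds are finite so the flux polytope
    is bounded.
    """
    rng = np.random.default_rng(seed)
    n_mets = int(rng.integers(2, 5))
    n_rxns = int(rng.integers(3, max_reactions + 1))
    mets = [Metabolite(f"m{i}", compartment="c") for i in range(n_mets)]
    rxns = []
    for j in range(n_rxns):
        k = int(rng.integers(1, min(3, n_mets) + 1))
        chosen = rng.choice(n_mets, size=k, replace=False)
        stoich = {
            f"m{i}": float(rng.choice([-2, -1, 1, 2])) for i in chosen
        }
        reversible = bool(rng.random() < 0.4)
        lb = -5.0 if reversible else 0.0
        rxns.append(Reaction(f"r{j}", stoich, lb, 10.0,
                             provenance="exchange" if len(stoich) == 1
                             else "colon"))
    return MetabolicModel(mets, rxns, name=f"random-{seed}")


def default_diet() -> DietSpec:
    """Toy mouse diet: glucose and amino acids partially absorbed before the
    colon, oxygen delivered via the bloodstream, xylan-like fibre reaching
    the lumen unabsorbed.  Butyrate is deliberately absent: in the fixtures
    it can only come from microbial fermentation."""
    return DietSpec(entries=[
        DietEntry("glc", 10.0, 0.5),
        DietEntry("aa", 5.0, 0.8),
        DietEntry("o2", 40.0, 1.0),
        DietEntry("xyl", 8.0, 0.0),
    ])


# ---------------------------------------------------------------------------
# full fixture bundle
# ---------------------------------------------------------------------------

@dataclass
class FixtureBundle:
    tissue_models: dict[str, MetabolicModel]
    bacteria: list[MetabolicModel]
    microbiome: MetabolicModel
    diet: DietSpec
    expression: pd.DataFrame
    abundances: pd.DataFrame
    metadata: pd.DataFrame
    gene_to_reactions: dict[str, set[str]]
    truth: dict = field(default_factory=dict)


def gene_reaction_map(models: dict[str, MetabolicModel] | list[MetabolicModel]
                      ) -> dict[str, set[str]]:
    """Flat gene -> prefixed-reaction-id map across compartment models."""
    if isinstance(models, dict):
        items = models.items()
    else:
        items = [(m.name, m) for m in models]
    out: dict[str, set[str]] = {}
    for prefix, model in items:
        for r in model.reactions:
            for g in r.genes:
                out.setdefault(g, set()).add(f"{prefix}__{r.id}")
    return out


def make_fixture_bundle(seed: int = 0, n_samples: int | None = None,
                        effect_size: float = 1.0) -> FixtureBundle:
    """The full synthetic study: organ models, bacteria, merged microbiome,
    diet, cohort expression/abundance matrices and machine-readable truth."""
    rng = np.random.default_rng(seed)
    tissues = {o: make_toy_tissue(o, seed) for o in ORGANS}
    strategies = ["fermenter", "competitor", "independent",
                  "crossfeeder_recipient"]
    bacteria = [
        make_toy_bacterium(s, seed + i, species=f"sp_{s}")
        for i, s in enumerate(strategies)
    ]
    microbiome = merge_microbiome(bacteria)

    ages = cohort_ages() if n_samples is None else np.asarray(
        rng.choice(AGE_GROUPS, size=n_samples).astype(float))
    n = len(ages)
    batches = np.array([f"b{i % 2}" for i in range(n)])

    genes = sorted(gene_reaction_map(tissues))
    # plant aging repression on the colon butyrate-oxidation module genes
    aging_down = set()
    for r in tissues["colon"].reactions:
        if r.subsystem == "fatty acid oxidation":
            aging_down |= set(r.genes)
    aging_up = set(rng.choice(
        [g for g in genes if g not in aging_down], size=3, replace=False))
    expression = simulate_expression(
        genes, n, ages, aging_down=aging_down, aging_up=aging_up,
        effect_size=effect_size, batch=batches, seed=seed + 1,
    )
    species = [b.name for b in bacteria]
    ab_down = {"sp_fermenter"}
    ab_up = {"sp_independent"}
    abundances = simulate_abundances(
        species, n, ages, aging_up=ab_up, aging_down=ab_down,
        effect_size=effect_size, seed=seed + 2,
    )
    metadata = pd.DataFrame({
        "sample": [f"s{i}" for i in range(n)],
        "age": ages,
        "batch": batches,
    }).set_index("sample")
    truth = {
        "aging_down_genes": sorted(aging_down),
        "aging_up_genes": sorted(aging_up),
        "abundance_down_species": sorted(ab_down),
        "abundance_up_species": sorted(ab_up),
        "microbiome_dependent_metabolite": "but",
        "host_autonomous_metabolite": "glc",
        "pair_types": {
            f"{a.name}|{b.name}": t for a, b, _, t in six_pair_fixtures(seed)
        },
    }
    return FixtureBundle(
        tissue_models=tissues,
        bacteria=bacteria,
        microbiome=microbiome,
        diet=default_diet(),
        expression=expression,
        abundances=abundances,
        metadata=metadata,
        gene_to_reactions=gene_reaction_map(tissues),
        truth=truth,
    )
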