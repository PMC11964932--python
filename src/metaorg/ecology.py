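"""Community flux balance analysis and pairwise ecological classification.

A microbial community is modelled as individually compartmentalized species
models coupled through a shared, diet-bounded nutrient environment.
Community growth uses balanced-growth coupling (each species' biomass flux
equals its relative abundance times the community growth rate).  Pairwise
ecological interactions are classified by comparing each species' growth
alone with its growth in co-culture, where co-culture growth rates are the
max-min fair solution of the joint model (maximize the worse-off species
first); the sign pattern of the two relative growth changes maps onto the
six classical interaction types.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.optimize import linprog
from scipy.stats import linregress
from statsmodels.stats.multitest import multipletests

from .network import (
    DEFAULT_BOUND,
    MetabolicModel,
    Metabolite,
    Reaction,
    is_exchange,
)
from . import lp

logger = logging.getLogger(__name__)

INTERACTION_TYPES = (
    "mutualism",
    "commensalism",
    "neutralism",
    "amensalism",
    "competition",
    "exploitation",
)

DELTA_TOL = 1e-6
EPS_FLOOR = 1e-9


@dataclass
class CommunityModel:
    """Species models plus relative abundances and a shared environment.

    ``environment`` maps metabolite base names to their dietary availability
    (mmol/day inflow bound on the shared pool).
    """

    species: list[MetabolicModel]
    abundances: np.ndarray
    environment: dict[str, float]
    biomass_id: str = "BIOMASS"

    def __post_init__(self):
        self.abundances = np.asarray(self.abundances, dtype=float)
        if len(self.abundances) != len(self.species):
            raise ValueError("one abundance per species required")
        if np.any(self.abundances < 0):
            raise ValueError("abundances must be non-negative")
        total = self.abundances.sum()
        if total <= 0:
            raise ValueError("abundances must not all be zero")
        self.abundances = self.abundances / total
        for m in self.species:
            if self.biomass_id not in set(m.reaction_ids):
                raise ValueError(f"species {m.name} lacks {self.biomass_id}")


def build_joint_model(species: list[MetabolicModel],
                      environment: dict[str, float]) -> MetabolicModel:
    """Merge species into one model with a shared environment pool.

    Species metabolites and reactions are prefixed ``<name>::``; boundary
    exchanges become reversible pool links (positive flux secretes into the
    pool).  The pool gets a dietary inflow bounded by ``environment`` and an
    open outflow per metabolite.
    """
    mets: dict[str, Metabolite] = {}
    rxns: list[Reaction] = []
    bases: set[str] = set(environment)

    def pool(base: str) -> str:
        mid = f"{base}_env"
        if mid not in mets:
            mets[mid] = Metabolite(mid, name=base, compartment="env")
            bases.add(base)
        return mid

    for model in species:
        pre = model.name
        for m in model.metabolites:
            mid = f"{pre}::{m.id}"
            mets[mid] = Metabolite(mid, name=m.name,
                                   compartment=f"{pre}-{m.compartment}")
        for r in model.reactions:
            if is_exchange(r) and len(r.stoich) == 1:
                met, coef = next(iter(r.stoich.items()))
                l, u = (r.lb, r.ub) if coef < 0 else (-r.ub, -r.lb)
                base = met[:-2] if met.endswith("_e") else met
                rxns.append(Reaction(
                    f"{pre}::{r.id}",
                    {f"{pre}::{met}": -1.0, pool(base): 1.0},
                    l, u, provenance="exchange",
                ))
            else:
                rxns.append(Reaction(
                    f"{pre}::{r.id}",
                    {f"{pre}::{m}": c for m, c in r.stoich.items()},
                    r.lb, r.ub, genes=r.genes, subsystem=r.subsystem,
                    provenance="microbiome",
                ))
    for base in sorted(bases):
        mid = pool(base)
        rxns.append(Reaction(f"IN_{base}", {mid: 1.0}, 0.0,
                             float(environment.get(base, 0.0)),
                             provenance="diet"))
        rxns.append(Reaction(f"OUT_{base}", {mid: -1.0}, 0.0, DEFAULT_BOUND,
                             provenance="exchange"))
    return MetabolicModel(list(mets.values()), rxns, name="community")


def _joint_arrays(model: MetabolicModel):
    S = model.stoichiometric_matrix()
    lb, ub = model.bounds_arrays()
    index = {r: j for j, r in enumerate(model.reaction_ids)}
    return S, lb, ub, index


def single_growth(model: MetabolicModel, environment: dict[str, float],
                  biomass_id: str = "BIOMASS") -> float:
    """FBA growth of one species alone in the shared environment."""
    joint = build_joint_model([model], environment)
    sol = lp.fba(joint, objective=f"{model.name}::{biomass_id}")
    return sol.objective_value if sol.optimal else 0.0


def community_fba(community: CommunityModel) -> dict:
    """Balanced-growth community FBA.

    Maximizes the community growth rate mu subject to each species' steady
    state and bounds, a shared diet-bounded environment, and the coupling
    v_biomass,i = abundance_i * mu.  Species fluxes come from a subsequent
    flux minimization at the fixed optimum.  When the coupling is infeasible
    (a member cannot grow), mu = 0 is returned with per-species single-growth
    diagnostics.
    """
    joint = build_joint_model(community.species, community.environment)
    S, lb, ub, index = _joint_arrays(joint)
    n = len(joint.reactions)
    bio = [index[f"{m.name}::{community.biomass_id}"]
           for m in community.species]
    # variables: v (n), mu; coupling rows v_bio_i - a_i mu = 0
    k = len(bio)
    coup = sp.lil_matrix((k, n + 1))
    for i, j in enumerate(bio):
        coup[i, j] = 1.0
        coup[i, n] = -community.abundances[i]
    A_eq = sp.vstack([sp.hstack([S, sp.csc_matrix((S.shape[0], 1))]),
                      coup.tocsc()]).tocsc()
    c = np.zeros(n + 1)
    c[n] = -1.0
    bounds = np.column_stack([
        np.concatenate([lb, [0.0]]),
        np.concatenate([ub, [np.inf]]),
    ])
    res = linprog(c, A_eq=A_eq, b_eq=np.zeros(A_eq.shape[0]), bounds=bounds,
                  method="highs")
    if res.status != 0:
        mu = 0.0
        diagnostics = {
            m.name: single_growth(m, community.environment,
                                  community.biomass_id)
            for m in community.species
        }
        return {"mu_community": 0.0, "species_growth": {},
                "species_fluxes": {}, "diagnostics": diagnostics}
    mu = float(-res.fun)
    fixed = {
        f"{m.name}::{community.biomass_id}": float(a * mu)
        for m, a in zip(community.species, community.abundances)
    }
    sol = lp.flux_minimization(joint, fixed=fixed)
    fluxes = sol.fluxes if sol.optimal else dict(
        zip(joint.reaction_ids, res.x[:n]))
    species_fluxes: dict[str, dict[str, float]] = {}
    for m in community.species:
        pre = f"{m.name}::"
        species_fluxes[m.name] = {
            r[len(pre):]: v for r, v in fluxes.items() if r.startswith(pre)
        }
    species_growth = {
        m.name: float(a * mu)
        for m, a in zip(community.species, community.abundances)
    }
    return {"mu_community": mu, "species_growth": species_growth,
            "species_fluxes": species_fluxes}


@dataclass
class EcologicalInteraction:
    pair: tuple[str, str]
    delta_i: float
    delta_j: float
    type: str


def _pair_growth(model_i: MetabolicModel, model_j: MetabolicModel,
                 environment: dict[str, float], biomass_id: str
                 ) -> tuple[float, float]:
    """Max-min fair co-culture growth rates of two species.

    First maximize the smaller of the two growth rates (m); then each
    species' co-culture rate is its maximum given the partner grows at
    least m.  This detects resource competition (a shared pool cannot
    sustain both at their single rates) without letting the faster species
    trivially starve the slower one.
    """
    joint = build_joint_model([model_i, model_j], environment)
    S, lb, ub, index = _joint_arrays(joint)
    n = len(joint.reactions)
    bi = index[f"{model_i.name}::{biomass_id}"]
    bj = index[f"{model_j.name}::{biomass_id}"]
    # maximize t subject to v_bi >= t, v_bj >= t
    A_ub = sp.lil_matrix((2, n + 1))
    A_ub[0, bi] = -1.0
    A_ub[0, n] = 1.0
    A_ub[1, bj] = -1.0
    A_ub[1, n] = 1.0
    A_eq = sp.hstack([S, sp.csc_matrix((S.shape[0], 1))]).tocsc()
    c = np.zeros(n + 1)
    c[n] = -1.0
    bounds = np.column_stack([
        np.concatenate([lb, [0.0]]),
        np.concatenate([ub, [np.inf]]),
    ])
    res = linprog(c, A_eq=A_eq, b_eq=np.zeros(S.shape[0]),
                  A_ub=A_ub.tocsc(), b_ub=np.zeros(2), bounds=bounds,
                  method="highs")
    m = float(-res.fun) if res.status == 0 else 0.0

    def best(target: int, other: int) -> float:
        c2 = np.zeros(n)
        c2[target] = -1.0
        lb2 = lb.copy()
        lb2[other] = max(lb[other], m - 1e-9)
        r2 = linprog(c2, A_eq=S, b_eq=np.zeros(S.shape[0]),
                     bounds=np.column_stack([lb2, ub]), method="highs")
        return float(-r2.fun) if r2.status == 0 else 0.0

    return best(bi, bj), best(bj, bi)


def classify_pair(model_i: MetabolicModel, model_j: MetabolicModel,
                  environment: dict[str, float], delta_tol: float = DELTA_TOL,
                  biomass_id: str = "BIOMASS") -> EcologicalInteraction:
    """Classify the ecological interaction between two species.

    delta_k = (mu_k_pair - mu_k_single) / max(mu_k_single, eps); the sign
    pattern of (delta_i, delta_j) determines the type: (+,+) mutualism,
    (+,0) commensalism, (0,0) neutralism, (0,-) amensalism, (-,-)
    competition, (+,-) exploitation.  Asymmetric types are reported with
    the beneficiary (or unaffected partner for amensalism) first.
    """
    mu_i = single_growth(model_i, environment, biomass_id)
    mu_j = single_growth(model_j, environment, biomass_id)
    pi, pj = _pair_growth(model_i, model_j, environment, biomass_id)
    di = (pi - mu_i) / max(mu_i, EPS_FLOOR)
    dj = (pj - mu_j) / max(mu_j, EPS_FLOOR)

    def sgn(d):
        if d > delta_tol:
            return 1
        if d < -delta_tol:
            return -1
        return 0

    si, sj = sgn(di), sgn(dj)
    names = (model_i.name, model_j.name)
    pattern = {
        (1, 1): "mutualism",
        (0, 0): "neutralism",
        (-1, -1): "competition",
        (1, 0): "commensalism",
        (0, 1): "commensalism",
        (0, -1): "amensalism",
        (-1, 0): "amensalism",
        (1, -1): "exploitation",
        (-1, 1): "exploitation",
    }[(si, sj)]
    # canonical orientation: beneficiary (or unaffected) first
    flip = (si, sj) in ((0, 1), (-1, 0), (-1, 1))
    if flip:
        names = (names[1], names[0])
        di, dj = dj, di
    return EcologicalInteraction(pair=names, delta_i=di, delta_j=dj,
                                 type=pattern)


@dataclass
class InteractionFrequencies:
    sample_id: str
    freq: dict[str, float] = field(default_factory=dict)


def interaction_frequencies(community: CommunityModel,
                            sample_id: str = "sample"
                            ) -> InteractionFrequencies:
    """Relative frequency of each interaction type over all unordered
    species pairs of a community (normalized to sum one)."""
    if len(community.species) < 2:
        raise ValueError("need at least two species")
    counts = {t: 0 for t in INTERACTION_TYPES}
    n_pairs = 0
    for a in range(len(community.species)):
        for b in range(a + 1, len(community.species)):
            inter = classify_pair(community.species[a], community.species[b],
                                  community.environment,
                                  biomass_id=community.biomass_id)
            counts[inter.type] += 1
            n_pairs += 1
    freq = {t: c / n_pairs for t, c in counts.items()}
    return InteractionFrequencies(sample_id=sample_id, freq=freq)


def age_trend(frequencies: pd.DataFrame, ages) -> pd.DataFrame:
    """OLS of each interaction type's relative frequency on age, BH-adjusted.

    ``frequencies``: samples x types.  Constant columns get slope 0, p 1.
    """
    ages = np.asarray(ages, dtype=float)
    if len(ages) != len(frequencies):
        raise ValueError("one age per sample required")
    if len(ages) < 3:
        raise ValueError("need at least three samples")
    rows = []
    for col in frequencies.columns:
        y = frequencies[col].to_numpy(dtype=float)
        if np.allclose(y, y[0]):
            rows.append({"type": col, "slope": 0.0, "p": 1.0})
            continue
        fit = linregress(ages, y)
        rows.append({"type": col, "slope": float(fit.slope),
                     "p": float(fit.pvalue)})
    df = pd.DataFrame(rows).set_index("type")
    df["fdr"] = multipletests(df["p"], method="fdr_bh")[1]
    return df


def species_knockout_effects(community: CommunityModel) -> dict[str, float]:
    """Change in community growth upon removal of each single species
    (abundances renormalized); empty for singleton communities."""
    if len(community.species) < 2:
        return {}
    mu_with = community_fba(community)["mu_community"]
    out = {}
    for i, m in enumerate(community.species):
        rest = [s for j, s in enumerate(community.species) if j != i]
        ab = np.delete(community.abundances, i)
        if ab.sum() <= 0:
            out[m.name] = 0.0
            continue
        reduced = CommunityModel(rest, ab, community.environment,
                                 community.biomass_id)
        mu_without = community_fba(reduced)["mu_community"]
        out[m.name] = float(mu_without - mu_with)
    return out


def active_reactions(community_solution: dict,
                     activity_tol: float = 1e-6) -> dict[str, float]:
    """Summed absolute flux per (unprefixed) reaction id across species in a
    flux-minimized community solution; reactions above ``activity_tol``
    count as active."""
    activity: dict[str, float] = {}
    for fluxes in community_solution.get("species_fluxes", {}).values():
        for r, v in fluxes.items():
            activity[r] = activity.get(r, 0.0) + abs(v)
    return {r: a for r, a in activity.items() if a > activity_tol}
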