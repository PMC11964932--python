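"""Assembly of the generic metaorganism metamodel.

Three host organ models (colon, liver, brain) and a merged microbiome are
joined through two shared exchange environments: the gut lumen (microbiome
and colon) and the bloodstream (colon, liver, brain).  Each compartment's
boundary exchanges are rewired into directional organ<->environment links,
dietary input is split between bloodstream (absorbed fraction) and colonic
lumen (unabsorbed), metabolite uptake into the brain is restricted to a
blood-brain-barrier whitelist, and energy-generating cycles are resolved by
correcting reaction reversibilities.
"""

from __future__ import annotations

import logging
import pathlib
from dataclasses import dataclass, field

import pandas as pd

from .network import (
    DEFAULT_BOUND,
    MetabolicModel,
    Metabolite,
    Reaction,
    is_exchange,
)
from . import lp

logger = logging.getLogger(__name__)

ENVIRONMENTS = ("lumen", "blood")


class AssemblyError(ValueError):
    pass


class EGCUnresolvedError(RuntimeError):
    pass


@dataclass
class MetamodelLayout:
    """Which organs exchange with which environments.

    ``blood_directions`` optionally restricts an organ's bloodstream link to
    one direction ("uptake_only" / "secretion_only"); the default is
    bidirectional, which approximates the directional bloodstream wiring as
    per-exchange irreversibility rather than a quantitative transport model.
    """

    organs: tuple[str, ...] = ("colon", "liver", "brain")
    membership: dict[str, tuple[str, ...]] = field(
        default_factory=lambda: {
            "colon": ("lumen", "blood"),
            "liver": ("blood",),
            "brain": ("blood",),
        }
    )
    microbiome_env: str = "lumen"
    blood_directions: dict[str, str] = field(default_factory=dict)


@dataclass
class DietEntry:
    metabolite: str
    mmol_per_day: float
    absorbed_fraction: float

    def __post_init__(self):
        if not 0.0 <= self.absorbed_fraction <= 1.0:
            raise ValueError(
                f"diet {self.metabolite}: absorbed fraction "
                f"{self.absorbed_fraction} outside [0, 1]"
            )
        if self.mmol_per_day < 0:
            raise ValueError(f"diet {self.metabolite}: negative amount")


@dataclass
class DietSpec:
    """Daily dietary input in mmol/day with small-intestinal absorption.

    Absorbed fractions enter the bloodstream directly; the remainder reaches
    the colonic lumen for microbiome and colonic use.  ``daily_food_g``
    (default 3.5 g/day for a mouse) documents the mass basis used to convert
    dietary composition into molar amounts.
    """

    entries: list[DietEntry]
    daily_food_g: float = 3.5

    @classmethod
    def from_tsv(cls, path) -> "DietSpec":
        df = pd.read_csv(path, sep="\t")
        entries = [
            DietEntry(row["metabolite"], float(row["mmol_per_day"]),
                      float(row["absorbed_fraction"]))
            for _, row in df.iterrows()
        ]
        return cls(entries)

    def to_tsv(self, path) -> None:
        pathlib.Path(path).parent.mkdir(parents=True, exist_ok=True)
        with open(path, "w") as fh:
            fh.write("metabolite\tmmol_per_day\tabsorbed_fraction\n")
            for e in self.entries:
                fh.write(
                    f"{e.metabolite}\t{e.mmol_per_day!r}\t{e.absorbed_fraction!r}\n"
                )


def base_name(met_id: str) -> str:
    """Strip the external-compartment suffix from a boundary metabolite id."""
    return met_id[:-2] if met_id.endswith("_e") else met_id


def env_met_id(base: str, env: str) -> str:
    return f"{base}_{env}"


def link_id(organ: str, base: str, env: str, direction: str) -> str:
    return f"{organ}__EX_{base}__{env}__{direction}"


def parse_link(rxn_id: str):
    """Inverse of :func:`link_id`; returns (organ, base, env, direction) or
    None for non-link reactions."""
    parts = rxn_id.split("__")
    if len(parts) != 4 or not parts[1].startswith("EX_"):
        return None
    organ, ex, env, direction = parts
    if direction not in ("sec", "upt") or env not in ENVIRONMENTS:
        return None
    return organ, ex[3:], env, direction


def assemble_metamodel(
    tissues: dict[str, MetabolicModel],
    microbiome: MetabolicModel,
    layout: MetamodelLayout | None = None,
    bbb: set[str] | None = None,
) -> MetabolicModel:
    """Join prefixed organ models and the merged microbiome through shared
    lumen/blood metabolite pools.

    Every boundary exchange of a compartment is replaced by irreversible
    secretion ("sec", organ -> environment) and uptake ("upt") links, paired
    for opposing-direction blocking during FVA.  Brain uptake links are only
    created for metabolites on the blood-brain-barrier whitelist ``bbb``
    (None allows everything).  Environment pools get a closed dietary inflow
    (opened by :func:`apply_diet`) and an open outflow.
    """
    layout = layout or MetamodelLayout()
    missing = [o for o in layout.organs if o not in tissues]
    if missing:
        raise AssemblyError(f"layout organs missing from tissues: {missing}")

    metabolites: dict[str, Metabolite] = {}
    reactions: list[Reaction] = []
    pairs: dict[str, str] = {}
    env_bases: dict[str, set[str]] = {env: set() for env in ENVIRONMENTS}

    def add_env_met(base: str, env: str) -> str:
        mid = env_met_id(base, env)
        if mid not in metabolites:
            metabolites[mid] = Metabolite(mid, name=base, compartment=env)
            env_bases[env].add(base)
        return mid

    def add_compartment(model: MetabolicModel, prefix: str, provenance: str,
                        envs: tuple[str, ...]):
        for m in model.metabolites:
            mid = f"{prefix}__{m.id}"
            metabolites[mid] = Metabolite(
                mid, name=m.name, compartment=f"{prefix}-{m.compartment}"
            )
        for r in model.reactions:
            if is_exchange(r) and len(r.stoich) == 1:
                met, coef = next(iter(r.stoich.items()))
                if coef > 0:  # orient as "metabolite leaves the compartment"
                    l, u = -r.ub, -r.lb
                else:
                    l, u = r.lb, r.ub
                base = base_name(met)
                pm = f"{prefix}__{met}"
                sec_cap = max(u, 0.0)
                upt_cap = max(-l, 0.0)
                for env in envs:
                    em = add_env_met(base, env)
                    direction_policy = (
                        layout.blood_directions.get(prefix, "both")
                        if env == "blood" else "both"
                    )
                    allow_upt = upt_cap > 0 and direction_policy != "secretion_only"
                    if prefix == "brain" and env == "blood" and bbb is not None:
                        allow_upt = allow_upt and base in bbb
                    allow_sec = sec_cap > 0 and direction_policy != "uptake_only"
                    sid = uid = None
                    if allow_sec:
                        sid = link_id(prefix, base, env, "sec")
                        reactions.append(Reaction(
                            sid, {pm: -1.0, em: 1.0}, 0.0, sec_cap,
                            genes=r.genes, subsystem=r.subsystem,
                            provenance=provenance,
                        ))
                    if allow_upt:
                        uid = link_id(prefix, base, env, "upt")
                        reactions.append(Reaction(
                            uid, {em: -1.0, pm: 1.0}, 0.0, upt_cap,
                            genes=r.genes, subsystem=r.subsystem,
                            provenance=provenance,
                        ))
                    if sid and uid:
                        pairs[sid] = uid
            else:
                reactions.append(Reaction(
                    id=f"{prefix}__{r.id}",
                    stoich={f"{prefix}__{m}": c for m, c in r.stoich.items()},
                    lb=r.lb,
                    ub=r.ub,
                    genes=r.genes,
                    subsystem=r.subsystem,
                    provenance=provenance,
                ))

    for organ in layout.organs:
        add_compartment(tissues[organ], organ, organ, layout.membership[organ])
    add_compartment(microbiome, "microbiome", "microbiome",
                    (layout.microbiome_env,))

    # environment boundaries: closed diet inflow + open outflow per pool
    for env, bases in env_bases.items():
        for base in sorted(bases):
            em = env_met_id(base, env)
            reactions.append(Reaction(
                f"DIET_{base}_{env}", {em: 1.0}, 0.0, 0.0, provenance="diet",
            ))
            reactions.append(Reaction(
                f"OUT_{base}_{env}", {em: -1.0}, 0.0, DEFAULT_BOUND,
                provenance="exchange",
            ))

    mm = MetabolicModel(
        metabolites=list(metabolites.values()),
        reactions=reactions,
        objective=None,
        name="metamodel",
        pairs=pairs,
        membership=dict(microbiome.membership),
    )
    return mm


def apply_diet(metamodel: MetabolicModel, diet: DietSpec) -> MetabolicModel:
    """Open dietary inflows: absorbed fraction to blood, rest to the lumen.

    All other environment inflows stay closed.  Entries whose metabolite has
    no matching environment pool are logged and skipped.
    """
    out = metamodel.copy()
    rxn = {r.id: r for r in out.reactions}
    for r in out.reactions:
        if r.provenance == "diet":
            r.ub = 0.0
    for e in diet.entries:
        blood = rxn.get(f"DIET_{e.metabolite}_blood")
        lumen = rxn.get(f"DIET_{e.metabolite}_lumen")
        if blood is None and lumen is None:
            logger.warning("diet metabolite %s not in metamodel; skipped",
                           e.metabolite)
            continue
        absorbed = e.mmol_per_day * e.absorbed_fraction
        unabsorbed = e.mmol_per_day * (1.0 - e.absorbed_fraction)
        if blood is not None:
            blood.ub = absorbed
        elif absorbed:
            logger.warning("no bloodstream pool for %s; absorbed share lost",
                           e.metabolite)
        if lumen is not None:
            lumen.ub = unabsorbed
        elif unabsorbed:
            logger.warning("no lumen pool for %s; unabsorbed share lost",
                           e.metabolite)
    return out


def dissipation_reactions(metamodel: MetabolicModel) -> list[str]:
    """ATP-maintenance (dissipation) reactions, one per compartment."""
    return [r.id for r in metamodel.reactions if r.id.split("__")[-1] == "ATPM"]


def _atp_gain(reaction: Reaction, flux: float) -> float:
    """Net ATP produced per unit |flux| in the direction of the witness."""
    sign = 1.0 if flux >= 0 else -1.0
    return sign * sum(
        coef for met, coef in reaction.stoich.items()
        if base_name(met.split("__")[-1]).startswith("atp")
    )


def resolve_egcs(metamodel: MetabolicModel, dissipation: list[str] | None = None,
                 max_iter: int = 20) -> tuple[MetabolicModel, list[dict]]:
    """Iteratively detect and resolve energy-generating cycles.

    Each detected cycle is broken by making one participating reversible,
    non-boundary reaction irreversible in its energy-consuming direction; the
    candidate is the one with the largest ATP gain in the witness direction.
    Raises :class:`EGCUnresolvedError` if cycles persist after ``max_iter``.
    """
    model = metamodel.copy()
    if dissipation is None:
        dissipation = dissipation_reactions(model)
    corrections: list[dict] = []
    for _ in range(max_iter):
        egcs = lp.detect_egcs(model, dissipation)
        if not egcs:
            return model, corrections
        egc = egcs[0]
        rxn = {r.id: r for r in model.reactions}
        candidates = []
        for rid in egc["cycle_support"]:
            r = rxn[rid]
            if rid in dissipation or is_exchange(r):
                continue
            if not r.reversible:
                continue
            candidates.append((_atp_gain(r, egc["witness_fluxes"].get(rid, 0.0)),
                               rid))
        if not candidates:
            raise EGCUnresolvedError(
                f"no reversible candidate to break cycle through "
                f"{egc['dissipation_id']}: {sorted(egc['cycle_support'])}"
            )
        candidates.sort(reverse=True)
        _, rid = candidates[0]
        r = rxn[rid]
        flux = egc["witness_fluxes"].get(rid, 0.0)
        if flux < 0:
            action = f"lb {r.lb} -> 0"
            r.lb = 0.0
        else:
            action = f"ub {r.ub} -> 0"
            r.ub = 0.0
        logger.info("EGC via %s: restricted %s (%s)", egc["dissipation_id"],
                    rid, action)
        corrections.append({
            "dissipation_id": egc["dissipation_id"],
            "reaction": rid,
            "action": action,
        })
    residual = lp.detect_egcs(model, dissipation)
    if residual:
        raise EGCUnresolvedError(
            f"energy-generating cycles persist after {max_iter} iterations: "
            f"{[sorted(e['cycle_support']) for e in residual]}"
        )
    return model, corrections
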