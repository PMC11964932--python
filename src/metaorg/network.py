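"""Data model and I/O for metabolic networks and the compartment-tagged metamodel.

A :class:`MetabolicModel` is a plain stoichiometric network: metabolites with
compartment tags, reactions with flux bounds, flat gene sets, subsystem and
provenance labels.  Three on-disk dialects are supported: SBML Level 3 + FBC
(via cobra), a single-file JSON dialect, and a hand-editable three-file TSV
dialect.  The module also provides the two structural transformations the
metaorganism analysis relies on: splitting reversible exchange reactions into
irreversible forward/backward pairs, and merging per-species bacterial models
into a single microbiome reaction space.
"""

from __future__ import annotations

import json
import logging
import math
import pathlib
from dataclasses import dataclass, field, replace
from fractions import Fraction

import numpy as np
import scipy.sparse as sp

logger = logging.getLogger(__name__)

#: provenance tags used across the metamodel
PROVENANCES = ("colon", "liver", "brain", "microbiome", "exchange", "diet")

#: default genome-scale flux bounds
DEFAULT_BOUND = 1000.0


class ModelIntegrityError(ValueError):
    """A model violates referential integrity (dangling ids, duplicates...)."""


class ModelParseError(ValueError):
    """A serialized model could not be parsed in the stated dialect."""


@dataclass(frozen=True)
class Metabolite:
    id: str
    name: str = ""
    compartment: str = "c"

    def __post_init__(self):
        if not self.id:
            raise ModelIntegrityError("metabolite with empty id")
        if not self.compartment:
            raise ModelIntegrityError(f"metabolite {self.id!r}: empty compartment")


@dataclass
class Reaction:
    """A reaction with signed stoichiometry (negative = consumed).

    ``lb``/``ub`` are flux bounds in mmol per unit biomass per period,
    consistent across a model.  ``genes`` is a flat association set (no
    boolean GPR structure).  ``provenance`` records which part of the
    metaorganism a reaction came from (an organ, the microbiome, an exchange
    environment or the diet).
    """

    id: str
    stoich: dict[str, float]
    lb: float = -DEFAULT_BOUND
    ub: float = DEFAULT_BOUND
    genes: frozenset[str] = field(default_factory=frozenset)
    subsystem: str = ""
    provenance: str = "exchange"

    def __post_init__(self):
        self.genes = frozenset(self.genes)
        if self.lb > self.ub:
            raise ModelIntegrityError(
                f"reaction {self.id!r}: lb {self.lb} > ub {self.ub}"
            )

    @property
    def reversible(self) -> bool:
        return self.lb < 0 < self.ub

    def copy(self) -> "Reaction":
        return replace(self, stoich=dict(self.stoich), genes=frozenset(self.genes))


@dataclass
class MetabolicModel:
    metabolites: list[Metabolite]
    reactions: list[Reaction]
    objective: str | None = None
    name: str = "model"
    #: forward-id -> backward-id map recorded by split_exchange_reactions
    pairs: dict[str, str] = field(default_factory=dict)
    #: reaction-id -> species labels recorded by merge_microbiome
    membership: dict[str, tuple[str, ...]] = field(default_factory=dict)

    def __post_init__(self):
        self.validate()

    # -- indexing -------------------------------------------------------

    @property
    def metabolite_ids(self) -> list[str]:
        return [m.id for m in self.metabolites]

    @property
    def reaction_ids(self) -> list[str]:
        return [r.id for r in self.reactions]

    def metabolite(self, met_id: str) -> Metabolite:
        return self._met_map()[met_id]

    def reaction(self, rxn_id: str) -> Reaction:
        try:
            return self._rxn_map()[rxn_id]
        except KeyError:
            raise KeyError(f"no reaction {rxn_id!r} in model {self.name!r}")

    def _met_map(self) -> dict[str, Metabolite]:
        return {m.id: m for m in self.metabolites}

    def _rxn_map(self) -> dict[str, Reaction]:
        return {r.id: r for r in self.reactions}

    def __contains__(self, rxn_id: str) -> bool:
        return any(r.id == rxn_id for r in self.reactions)

    # -- validation -----------------------------------------------------

    def validate(self) -> None:
        met_ids = [m.id for m in self.metabolites]
        if len(set(met_ids)) != len(met_ids):
            dup = sorted({i for i in met_ids if met_ids.count(i) > 1})
            raise ModelIntegrityError(f"duplicate metabolite ids: {dup}")
        rxn_ids = [r.id for r in self.reactions]
        if len(set(rxn_ids)) != len(rxn_ids):
            dup = sorted({i for i in rxn_ids if rxn_ids.count(i) > 1})
            raise ModelIntegrityError(f"duplicate reaction ids: {dup}")
        known = set(met_ids)
        for r in self.reactions:
            missing = set(r.stoich) - known
            if missing:
                raise ModelIntegrityError(
                    f"reaction {r.id!r} references unknown metabolites: "
                    f"{sorted(missing)}"
                )
        if self.objective is not None and self.objective not in set(rxn_ids):
            raise ModelIntegrityError(
                f"objective {self.objective!r} is not a reaction of the model"
            )

    # -- matrices and views ---------------------------------------------

    def stoichiometric_matrix(self) -> sp.csc_matrix:
        """|metabolites| x |reactions| sparse stoichiometric matrix."""
        midx = {m.id: i for i, m in enumerate(self.metabolites)}
        rows, cols, vals = [], [], []
        for j, r in enumerate(self.reactions):
            for met, coef in r.stoich.items():
                rows.append(midx[met])
                cols.append(j)
                vals.append(float(coef))
        return sp.csc_matrix(
            (vals, (rows, cols)), shape=(len(self.metabolites), len(self.reactions))
        )

    def bounds_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        lb = np.array([r.lb for r in self.reactions], dtype=float)
        ub = np.array([r.ub for r in self.reactions], dtype=float)
        return lb, ub

    def copy(self) -> "MetabolicModel":
        return MetabolicModel(
            metabolites=list(self.metabolites),
            reactions=[r.copy() for r in self.reactions],
            objective=self.objective,
            name=self.name,
            pairs=dict(self.pairs),
            membership=dict(self.membership),
        )

    def subset(self, reaction_ids, name: str | None = None) -> "MetabolicModel":
        """Submodel restricted to ``reaction_ids`` and the metabolites they use."""
        keep = set(reaction_ids)
        reactions = [r.copy() for r in self.reactions if r.id in keep]
        used = set()
        for r in reactions:
            used.update(r.stoich)
        metabolites = [m for m in self.metabolites if m.id in used]
        objective = self.objective if self.objective in keep else None
        pairs = {f: b for f, b in self.pairs.items() if f in keep and b in keep}
        membership = {r: s for r, s in self.membership.items() if r in keep}
        return MetabolicModel(
            metabolites=metabolites,
            reactions=reactions,
            objective=objective,
            name=name or self.name,
            pairs=pairs,
            membership=membership,
        )


# ---------------------------------------------------------------------------
# I/O: TSV, JSON and SBML-FBC dialects
# ---------------------------------------------------------------------------

_RXN_COLUMNS = ("id", "stoich", "lb", "ub", "genes", "subsystem", "provenance")


def _format_stoich(stoich: dict[str, float]) -> str:
    return ";".join(f"{m}:{coef!r}" for m, coef in sorted(stoich.items()))


def _parse_stoich(text: str, rxn_id: str) -> dict[str, float]:
    stoich = {}
    if not text:
        return stoich
    for part in text.split(";"):
        if ":" not in part:
            raise ModelParseError(
                f"reaction {rxn_id!r}: malformed stoichiometry term {part!r}"
            )
        met, _, coef = part.rpartition(":")
        try:
            stoich[met] = float(coef)
        except ValueError:
            raise ModelParseError(
                f"reaction {rxn_id!r}: non-numeric coefficient {coef!r} for {met!r}"
            )
    return stoich


def save_model(model: MetabolicModel, path, dialect: str = "json") -> None:
    path = pathlib.Path(path)
    if dialect == "tsv":
        path.mkdir(parents=True, exist_ok=True)
        with open(path / "metabolites.tsv", "w") as fh:
            fh.write("id\tname\tcompartment\n")
            for m in model.metabolites:
                fh.write(f"{m.id}\t{m.name}\t{m.compartment}\n")
        with open(path / "reactions.tsv", "w") as fh:
            fh.write("\t".join(_RXN_COLUMNS) + "\n")
            for r in model.reactions:
                fh.write(
                    f"{r.id}\t{_format_stoich(r.stoich)}\t{r.lb!r}\t{r.ub!r}\t"
                    f"{'|'.join(sorted(r.genes))}\t{r.subsystem}\t{r.provenance}\n"
                )
        meta = {
            "name": model.name,
            "objective": model.objective,
            "pairs": model.pairs,
            "membership": {k: list(v) for k, v in model.membership.items()},
        }
        (path / "model.json").write_text(json.dumps(meta, indent=1, sort_keys=True))
    elif dialect == "json":
        doc = {
            "name": model.name,
            "objective": model.objective,
            "pairs": model.pairs,
            "membership": {k: list(v) for k, v in model.membership.items()},
            "metabolites": [
                {"id": m.id, "name": m.name, "compartment": m.compartment}
                for m in model.metabolites
            ],
            "reactions": [
                {
                    "id": r.id,
                    "stoich": r.stoich,
                    "lb": r.lb,
                    "ub": r.ub,
                    "genes": sorted(r.genes),
                    "subsystem": r.subsystem,
                    "provenance": r.provenance,
                }
                for r in model.reactions
            ],
        }
        path.parent.mkdir(parents=True, exist_ok=True)
        path.write_text(json.dumps(doc, indent=1, sort_keys=True))
    elif dialect == "sbml-fbc":
        import cobra.io

        cobra.io.write_sbml_model(to_cobra(model), str(path))
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


def load_model(path, dialect: str = "json") -> MetabolicModel:
    path = pathlib.Path(path)
    if dialect == "tsv":
        return _load_tsv(path)
    if dialect == "json":
        try:
            doc = json.loads(path.read_text())
        except json.JSONDecodeError as exc:
            raise ModelParseError(f"{path}: invalid JSON ({exc})")
        return MetabolicModel(
            metabolites=[Metabolite(**m) for m in doc["metabolites"]],
            reactions=[
                Reaction(
                    id=r["id"],
                    stoich={m: float(c) for m, c in r["stoich"].items()},
                    lb=float(r["lb"]),
                    ub=float(r["ub"]),
                    genes=frozenset(r.get("genes", ())),
                    subsystem=r.get("subsystem", ""),
                    provenance=r.get("provenance", "exchange"),
                )
                for r in doc["reactions"]
            ],
            objective=doc.get("objective"),
            name=doc.get("name", "model"),
            pairs=dict(doc.get("pairs", {})),
            membership={
                k: tuple(v) for k, v in doc.get("membership", {}).items()
            },
        )
    if dialect == "sbml-fbc":
        import cobra.io

        return from_cobra(cobra.io.read_sbml_model(str(path)))
    raise ValueError(f"unknown dialect {dialect!r}")


def _load_tsv(path: pathlib.Path) -> MetabolicModel:
    import pandas as pd

    if not (path / "reactions.tsv").exists():
        raise ModelParseError(f"{path}: missing reactions.tsv")
    mets = pd.read_csv(path / "metabolites.tsv", sep="\t", dtype=str).fillna("")
    rxns = pd.read_csv(path / "reactions.tsv", sep="\t", dtype=str).fillna("")
    metabolites = [
        Metabolite(id=row["id"], name=row["name"], compartment=row["compartment"])
        for _, row in mets.iterrows()
    ]
    reactions = []
    for _, row in rxns.iterrows():
        reactions.append(
            Reaction(
                id=row["id"],
                stoich=_parse_stoich(row["stoich"], row["id"]),
                lb=float(row["lb"]),
                ub=float(row["ub"]),
                genes=frozenset(g for g in row["genes"].split("|") if g),
                subsystem=row["subsystem"],
                provenance=row["provenance"],
            )
        )
    meta_path = path / "model.json"
    meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
    return MetabolicModel(
        metabolites=metabolites,
        reactions=reactions,
        objective=meta.get("objective"),
        name=meta.get("name", path.name),
        pairs=dict(meta.get("pairs", {})),
        membership={k: tuple(v) for k, v in meta.get("membership", {}).items()},
    )


def to_cobra(model: MetabolicModel):
    """Convert to a cobra.Model (used for SBML-FBC I/O and as a test oracle)."""
    import cobra

    cm = cobra.Model(model.name)
    mets = {
        m.id: cobra.Metabolite(m.id, name=m.name, compartment=m.compartment)
        for m in model.metabolites
    }
    cm.add_metabolites(list(mets.values()))
    rxns = []
    for r in model.reactions:
        cr = cobra.Reaction(r.id, lower_bound=r.lb, upper_bound=r.ub)
        cr.subsystem = r.subsystem
        cr.notes["provenance"] = r.provenance
        if r.genes:
            cr.gene_reaction_rule = " or ".join(sorted(r.genes))
        rxns.append(cr)
    cm.add_reactions(rxns)
    for r in model.reactions:
        cm.reactions.get_by_id(r.id).add_metabolites(
            {mets[m]: c for m, c in r.stoich.items()}
        )
    if model.objective is not None:
        cm.objective = model.objective
    return cm


def from_cobra(cm) -> MetabolicModel:
    metabolites = [
        Metabolite(id=m.id, name=m.name or "", compartment=m.compartment or "c")
        for m in cm.metabolites
    ]
    reactions = []
    for r in cm.reactions:
        reactions.append(
            Reaction(
                id=r.id,
                stoich={m.id: float(c) for m, c in r.metabolites.items()},
                lb=float(r.lower_bound),
                ub=float(r.upper_bound),
                genes=frozenset(g.id for g in r.genes),
                subsystem=r.subsystem or "",
                provenance=r.notes.get("provenance", "exchange"),
            )
        )
    objective = None
    for r in cm.reactions:
        if r.objective_coefficient:
            objective = r.id
            break
    return MetabolicModel(
        metabolites=metabolites,
        reactions=reactions,
        objective=objective,
        name=cm.id or "model",
    )


# ---------------------------------------------------------------------------
# structural transformations
# ---------------------------------------------------------------------------


def is_exchange(reaction: Reaction) -> bool:
    """Exchange reactions either have single-metabolite stoichiometry or
    link exactly two exchange-environment metabolites."""
    return reaction.provenance in ("exchange", "diet")


def split_exchange_reactions(model: MetabolicModel) -> MetabolicModel:
    """Split every reversible exchange reaction into irreversible forward and
    backward directions.

    The forward reaction keeps the original stoichiometry with bounds
    [0, ub]; the backward reaction has negated stoichiometry and bounds
    [0, -lb].  The pairing is recorded in ``model.pairs`` (forward -> backward)
    so that variability analyses can block the opposing direction.  Already
    irreversible exchanges pass through unchanged.
    """
    out = model.copy()
    new_reactions: list[Reaction] = []
    pairs = dict(out.pairs)
    for r in out.reactions:
        if is_exchange(r) and r.reversible:
            fwd = replace(r, id=f"{r.id}__fwd", lb=0.0, ub=r.ub,
                          stoich=dict(r.stoich))
            bwd = replace(
                r,
                id=f"{r.id}__bwd",
                lb=0.0,
                ub=-r.lb,
                stoich={m: -c for m, c in r.stoich.items()},
            )
            new_reactions.extend([fwd, bwd])
            pairs[fwd.id] = bwd.id
            if out.objective == r.id:
                out.objective = fwd.id
        else:
            new_reactions.append(r)
    out.reactions = new_reactions
    out.pairs = pairs
    out.validate()
    return out


def _frac(x: float) -> Fraction:
    return Fraction(x).limit_denominator(10**9)


def _canonical_stoich(stoich: dict[str, float]) -> frozenset:
    """Normalize coefficients by the gcd of their absolute values so that
    scaled duplicates of the same reaction compare equal."""
    fracs = {m: _frac(c) for m, c in stoich.items()}
    g = Fraction(0)
    for f in fracs.values():
        af = abs(f)
        g = Fraction(
            math.gcd(g.numerator, af.numerator),
            math.lcm(g.denominator, af.denominator),
        ) if g else af
    if g == 0:
        g = Fraction(1)
    return frozenset((m, f / g) for m, f in fracs.items())


def merge_microbiome(models: list[MetabolicModel], name: str = "microbiome"
                     ) -> MetabolicModel:
    """Pool per-species bacterial models into a single reaction space.

    Duplicate reactions (identical normalized stoichiometry) are collapsed to
    one; a species -> reaction membership map is retained on the merged model.
    When duplicates disagree on bounds, the widest bounds are kept and the
    conflict logged.
    """
    if not models:
        raise ValueError("merge_microbiome needs at least one model")
    metabolites: dict[str, Metabolite] = {}
    merged: dict[frozenset, Reaction] = {}
    members: dict[frozenset, list[str]] = {}
    for mdl in models:
        for m in mdl.metabolites:
            metabolites.setdefault(m.id, m)
        for r in mdl.reactions:
            key = _canonical_stoich(r.stoich)
            if key in merged:
                kept = merged[key]
                if (kept.lb, kept.ub) != (r.lb, r.ub):
                    logger.info(
                        "merge_microbiome: widening bounds of %s to cover %s "
                        "from %s", kept.id, r.id, mdl.name,
                    )
                    kept.lb = min(kept.lb, r.lb)
                    kept.ub = max(kept.ub, r.ub)
                kept.genes = kept.genes | r.genes
                members[key].append(mdl.name)
            else:
                merged[key] = r.copy()
                members[key] = [mdl.name]
    reactions = list(merged.values())
    # de-collide ids of structurally distinct reactions sharing a name
    seen: dict[str, int] = {}
    for r in reactions:
        if r.id in seen:
            seen[r.id] += 1
            r.id = f"{r.id}.{seen[r.id]}"
        else:
            seen[r.id] = 0
    membership = {
        merged[key].id: tuple(dict.fromkeys(species))
        for key, species in members.items()
    }
    return MetabolicModel(
        metabolites=list(metabolites.values()),
        reactions=reactions,
        objective=None,
        name=name,
        membership=membership,
    )
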