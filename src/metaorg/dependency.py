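"""Microbiome dependency of host exchange reactions.

Flux variability of every host organ<->environment exchange link is computed
with and without the microbiome (all microbiome reactions blocked jointly);
an exchange is microbiome dependent when its admissible flux range collapses
below 10% of the unblocked range.  Per-metabolite counts of dependent
uptakes and secretions across samples classify metabolites as provided by
the microbiota to the host or vice versa.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import pandas as pd

from .network import MetabolicModel
from .assembly import parse_link
from . import lp

logger = logging.getLogger(__name__)

#: a flux range reduced below this fraction of the full range marks dependency
RANGE_RATIO = 0.1


@dataclass
class DependencyRecord:
    sample_id: str
    reaction_id: str
    organ: str
    metabolite: str
    direction: str  # uptake | secretion
    range_full: float
    range_blocked: float
    dependent: bool


def host_exchange_reactions(metamodel: MetabolicModel) -> list[tuple]:
    """(reaction_id, organ, metabolite, direction) for every host
    organ-environment link."""
    out = []
    for r in metamodel.reactions:
        info = parse_link(r.id)
        if info is None:
            continue
        organ, base, env, direction = info
        if organ == "microbiome":
            continue
        out.append((r.id, organ, base,
                    "uptake" if direction == "upt" else "secretion"))
    return out


def microbiome_reactions(metamodel: MetabolicModel) -> list[str]:
    return [r.id for r in metamodel.reactions if r.provenance == "microbiome"]


def microbiome_dependency(context_metamodel: MetabolicModel,
                          sample_id: str = "sample",
                          joint_blocking: bool = True
                          ) -> list[DependencyRecord]:
    """Score every host exchange link for microbiome dependency.

    FVA is run without optimizing growth (no objective constraint), blocking
    the opposing split direction of each link for its own min/max.  It is
    then repeated with microbiome reactions blocked — jointly by default,
    matching a criterion phrased over the microbiome as a whole; one-at-a-time
    blocking is available via ``joint_blocking=False`` where per-reaction
    attribution is wanted (the most restrictive single blocking is reported).
    """
    exchanges = host_exchange_reactions(context_metamodel)
    mb = microbiome_reactions(context_metamodel)
    if not mb:
        logger.warning("context model has no microbiome reactions")
    rxns = [e[0] for e in exchanges]
    full = {fr.reaction_id: fr for fr in lp.fva(context_metamodel, rxns)}
    if joint_blocking:
        blocked = {
            fr.reaction_id: fr
            for fr in lp.fva(context_metamodel, rxns, blocked=mb)
        }
    else:
        blocked = dict(full)
        for m in mb:
            for fr in lp.fva(context_metamodel, rxns, blocked=[m]):
                if fr.range < blocked[fr.reaction_id].range:
                    blocked[fr.reaction_id] = fr
    records = []
    for rid, organ, met, direction in exchanges:
        fr_full = full[rid]
        fr_blk = blocked[rid]
        if not fr_full.feasible:
            logger.info("exchange %s infeasible in full model; excluded", rid)
            continue
        range_full = fr_full.range
        range_blocked = fr_blk.range if fr_blk.feasible else 0.0
        if range_full <= 0:
            dependent = False  # undefined ratio; logged, counted independent
        else:
            dependent = range_blocked < RANGE_RATIO * range_full
        records.append(DependencyRecord(
            sample_id=sample_id, reaction_id=rid, organ=organ,
            metabolite=met, direction=direction, range_full=range_full,
            range_blocked=range_blocked, dependent=dependent,
        ))
    return records


@dataclass
class ExchangeClassification:
    metabolite: str
    organ: str
    n_dep_uptake: int
    n_dep_secretion: int
    label: str  # microbiota_to_host | host_to_microbiota | none

    @property
    def net(self) -> int:
        return self.n_dep_uptake - self.n_dep_secretion


def classify_exchanges(records: list[DependencyRecord],
                       threshold: int | None = None,
                       plot_thresholds: dict[str, int] | None = None
                       ) -> list[ExchangeClassification]:
    """Classify metabolites as microbiota-provided or host-provided.

    Per metabolite and organ, microbiome-dependent uptakes and secretions
    are counted across samples; a net count strictly above the threshold
    labels the direction of provision.  The default threshold is 20% of the
    number of samples (10 for a 52-sample cohort).  ``plot_thresholds``
    optionally filters the result per organ for display.
    """
    samples = {r.sample_id for r in records}
    if threshold is None:
        threshold = math.ceil(0.2 * len(samples))
    counts: dict[tuple, dict] = {}
    for r in records:
        if not r.dependent:
            continue
        key = (r.metabolite, r.organ)
        d = counts.setdefault(key, {"uptake": 0, "secretion": 0})
        d[r.direction] += 1
    out = []
    for (met, organ), d in sorted(counts.items()):
        net = d["uptake"] - d["secretion"]
        if net > threshold:
            label = "microbiota_to_host"
        elif -net > threshold:
            label = "host_to_microbiota"
        else:
            label = "none"
        out.append(ExchangeClassification(
            metabolite=met, organ=organ, n_dep_uptake=d["uptake"],
            n_dep_secretion=d["secretion"], label=label,
        ))
    if plot_thresholds:
        out = [
            c for c in out
            if abs(c.net) >= plot_thresholds.get(c.organ, 0)
        ]
    return out


def records_to_frame(records: list[DependencyRecord]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in records])
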