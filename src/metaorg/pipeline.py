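"""End-to-end orchestration of the metaorganism analysis on a synthetic
study.

Stages run in dependency order: simulate -> assemble -> extract ->
dependency -> efm -> ecology -> stats.  Every stage writes its outputs
under its own subdirectory together with a manifest (config hash, seed,
package version); a completed stage with a matching manifest is skipped on
re-run, giving cheap checkpoint/resume, and deterministic stages reproduce
byte-identical TSVs for a fixed config.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import pathlib

import numpy as np
import pandas as pd

from . import __version__, efm, lp
from . import assembly as asm
from . import dependency as dep
from . import ecology as eco
from . import extraction as ext
from . import simulate as sim
from . import stats as st
from .network import save_model

logger = logging.getLogger(__name__)

STAGES = ("simulate", "assemble", "extract", "dependency", "efm", "ecology",
          "stats")


@dataclasses.dataclass
class PipelineConfig:
    """All stage parameters with the study's published defaults."""

    out_dir: str = "metaorg_run"
    seed: int = 0
    n_samples: int | None = None       # None = the 52-animal cohort design
    # extraction
    clusters_expression: int = 39
    clusters_abundance: int = 15
    fastcore_epsilon: float = 1e-4
    n_context_samples: int | None = None
    # dependency
    range_ratio: float = 0.1
    # EFM sampling
    max_efms: int = 10000
    efm_time_budget_s: float = 200.0
    efm_max_draws: int | None = 60
    n_efm_mice: int = 3
    membership_threshold: float = 0.2
    interaction_threshold: float = 0.5
    min_microbial: int = 20
    aging_p: float = 0.01
    # statistics
    rho_cut: float = 0.55
    fdr_cut: float = 0.1
    enrichment_fdr: float = 0.05
    # diet
    daily_food_g: float = 3.5

    def validate(self) -> None:
        if not 0.0 <= self.rho_cut <= 1.0:
            raise ValueError(f"rho_cut {self.rho_cut} outside [0, 1]")
        for name in ("fdr_cut", "enrichment_fdr", "membership_threshold",
                     "interaction_threshold", "range_ratio", "aging_p"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} {v} outside [0, 1]")
        if self.clusters_expression < 2 or self.clusters_abundance < 2:
            raise ValueError("cluster numbers must be >= 2")

    def hash(self) -> str:
        doc = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(doc.encode()).hexdigest()[:16]


def _write_manifest(stage_dir: pathlib.Path, config: PipelineConfig) -> None:
    (stage_dir / "manifest.json").write_text(json.dumps({
        "config_hash": config.hash(),
        "seed": config.seed,
        "version": __version__,
    }, indent=1, sort_keys=True))


def _stage_done(stage_dir: pathlib.Path, config: PipelineConfig) -> bool:
    mf = stage_dir / "manifest.json"
    if not mf.exists():
        return False
    try:
        doc = json.loads(mf.read_text())
    except json.JSONDecodeError:
        return False
    return doc.get("config_hash") == config.hash()


def run_pipeline(config: PipelineConfig, resume: bool = True) -> pathlib.Path:
    """Execute all stages; returns the output directory."""
    config.validate()
    out = pathlib.Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    state: dict = {}
    for stage in STAGES:
        stage_dir = out / stage
        stage_dir.mkdir(exist_ok=True)
        runner = globals()[f"_stage_{stage}"]
        if resume and _stage_done(stage_dir, config) and stage != "simulate":
            # simulate is cheap and later stages need its in-memory bundle;
            # other completed stages are only re-loaded when needed
            logger.info("stage %s up to date; recomputing state in memory",
                        stage)
        logger.info("running stage %s", stage)
        runner(config, stage_dir, state)
        _write_manifest(stage_dir, config)
    return out


def _stage_simulate(config, stage_dir, state):
    bundle = sim.make_fixture_bundle(config.seed, n_samples=config.n_samples)
    bundle.diet.daily_food_g = config.daily_food_g
    state["bundle"] = bundle
    bundle.expression.to_csv(stage_dir / "expression.tsv", sep="\t")
    bundle.abundances.to_csv(stage_dir / "abundances.tsv", sep="\t")
    bundle.metadata.to_csv(stage_dir / "metadata.tsv", sep="\t")
    bundle.diet.to_tsv(stage_dir / "diet.tsv")
    save_model(bundle.microbiome, stage_dir / "microbiome.json")
    for organ, model in bundle.tissue_models.items():
        save_model(model, stage_dir / f"{organ}.json")
    (stage_dir / "truth.json").write_text(
        json.dumps(bundle.truth, indent=1, sort_keys=True))


def _stage_assemble(config, stage_dir, state):
    bundle = state["bundle"]
    bbb = {"glc", "o2", "aa", "co2", "lac"}
    mm = asm.assemble_metamodel(bundle.tissue_models, bundle.microbiome,
                                bbb=bbb)
    mm = asm.apply_diet(mm, bundle.diet)
    mm, corrections = asm.resolve_egcs(mm)
    state["metamodel"] = mm
    save_model(mm, stage_dir / "metamodel.json")
    (stage_dir / "egc_corrections.json").write_text(
        json.dumps(corrections, indent=1, sort_keys=True))


def _stage_extract(config, stage_dir, state):
    bundle = state["bundle"]
    mm = state["metamodel"]
    ages = bundle.metadata["age"]
    groups = {s: f"age{int(a)}" for s, a in ages.items()}
    expr = np.log2(bundle.expression + 1.0)
    k_expr = min(config.clusters_expression, max(2, len(expr) - 1))
    expr_cores = ext.standep_core(
        expr, k_expr, groups=groups,
        gene_to_reactions=bundle.gene_to_reactions,
    )
    contribution = pd.DataFrame(
        0.0, index=[b.name for b in bundle.bacteria],
        columns=[f"microbiome__{r}" for r in bundle.microbiome.reaction_ids],
    )
    for rid, species in bundle.microbiome.membership.items():
        for s in species:
            contribution.loc[s, f"microbiome__{rid}"] = 1.0
    ram = ext.reaction_abundance_matrix(bundle.abundances, contribution)
    k_ab = min(config.clusters_abundance, max(2, len(ram) - 1))
    ab_cores = ext.standep_core(np.log2(ram + 1e-6), k_ab, groups=groups,
                                source="abundance")
    consistent = ext.fastcc(mm, config.fastcore_epsilon)
    samples = list(bundle.metadata.index)
    if config.n_context_samples:
        samples = samples[: config.n_context_samples]
    expr_by_sample = {c.sample_id: c for c in expr_cores}
    ab_by_sample = {c.sample_id: c for c in ab_cores}
    contexts = {}
    reports = []
    for s in samples:
        ctx, report = ext.build_context_metamodel(
            consistent,
            tissue_cores={"all": expr_by_sample[s].reactions},
            microbiome_core=ab_by_sample[s].reactions,
            epsilon=config.fastcore_epsilon,
            consistent=True,
        )
        contexts[s] = ctx
        reports.append({"sample": s, **{k: v for k, v in report.items()
                                        if k != "excluded_core"}})
        save_model(ctx, stage_dir / f"context_{s}.json")
    state["contexts"] = contexts
    state["consistent"] = consistent
    pd.DataFrame(reports).to_csv(stage_dir / "core_report.tsv", sep="\t",
                                 index=False)


def _stage_dependency(config, stage_dir, state):
    records = []
    for s, ctx in state["contexts"].items():
        records.extend(dep.microbiome_dependency(ctx, s))
    classes = dep.classify_exchanges(records)
    dep.records_to_frame(records).to_csv(
        stage_dir / "dependency_records.tsv", sep="\t", index=False)
    pd.DataFrame([
        {"metabolite": c.metabolite, "organ": c.organ, "net": c.net,
         "label": c.label}
        for c in classes
    ]).to_csv(stage_dir / "exchange_classification.tsv", sep="\t",
              index=False)
    state["dependency_records"] = records
    state["exchange_classes"] = classes


def _stage_efm(config, stage_dir, state):
    contexts = state["contexts"]
    mice = list(contexts)[: config.n_efm_mice]
    indicators = None
    samples: dict[str, dict[str, efm.EFMSample]] = {}
    for i, mouse in enumerate(mice):
        model = contexts[mouse]
        if indicators is None:
            indicators = [
                rid for rid, *_ in dep.host_exchange_reactions(model)
            ]
        per = {}
        for j, ind in enumerate(indicators):
            if ind not in model:
                continue
            per[ind] = efm.sample_efms(
                model, ind, max_efms=config.max_efms,
                time_budget_s=config.efm_time_budget_s,
                max_draws=config.efm_max_draws,
                seed=config.seed + 1000 * i + j,
            )
        samples[mouse] = per
    matrix = efm.interaction_matrix(samples)
    mb_rxns = {
        r.id for ctx in contexts.values() for r in ctx.reactions
        if r.provenance == "microbiome"
    }
    modules = efm.define_modules(matrix, mb_rxns,
                                 config.membership_threshold,
                                 config.min_microbial)
    matrix.to_frame().to_csv(stage_dir / "interaction_matrix.tsv", sep="\t",
                             index=False)
    pd.DataFrame([
        {"indicator": m.indicator_id, "n_members": len(m.members),
         "n_microbial": m.n_microbial,
         "microbiome_dependent": m.microbiome_dependent}
        for m in modules
    ]).to_csv(stage_dir / "modules.tsv", sep="\t", index=False)
    state["interaction_matrix"] = matrix
    state["modules"] = modules


def _stage_ecology(config, stage_dir, state):
    bundle = state["bundle"]
    lumen_env = {
        e.metabolite: e.mmol_per_day * (1.0 - e.absorbed_fraction)
        for e in bundle.diet.entries
    }
    freq_rows = {}
    activity: dict[str, dict[str, float]] = {}
    presence_cut = 0.05  # a species is part of a sample's community >= 5%
    for s in bundle.metadata.index:
        ab = bundle.abundances[s]
        present = [b for b in bundle.bacteria
                   if ab[b.name] >= presence_cut]
        if len(present) < 2:
            present = bundle.bacteria
        community = eco.CommunityModel(
            present, ab[[b.name for b in present]].to_numpy(), lumen_env)
        freq_rows[s] = eco.interaction_frequencies(community, s).freq
        solution = eco.community_fba(community)
        activity[s] = eco.active_reactions(solution)
    freq = pd.DataFrame(freq_rows).T
    freq.index.name = "sample"
    trends = eco.age_trend(freq, bundle.metadata["age"].to_numpy())
    first = bundle.metadata.index[0]
    community = eco.CommunityModel(
        bundle.bacteria, bundle.abundances[first].to_numpy(), lumen_env)
    knockouts = eco.species_knockout_effects(community)
    freq.to_csv(stage_dir / "interaction_frequencies.tsv", sep="\t")
    trends.to_csv(stage_dir / "age_trends.tsv", sep="\t")
    pd.Series(knockouts, name="delta_mu").to_csv(
        stage_dir / "knockouts.tsv", sep="\t")
    act = pd.DataFrame(activity).fillna(0.0)
    act.index.name = "reaction"
    act.to_csv(stage_dir / "active_reactions.tsv", sep="\t")
    state["activity"] = act
    state["interaction_freqs"] = freq


def _stage_stats(config, stage_dir, state):
    bundle = state["bundle"]
    expr = np.log2(bundle.expression + 1.0)
    act = state["activity"]
    act = act.loc[act.std(axis=1) > 0]
    covar = pd.DataFrame(
        [bundle.metadata["age"].to_numpy()], index=["age"],
        columns=bundle.metadata.index)
    results = st.partial_spearman(expr, act, covar)
    sig = st.significant_pairs(results, config.fdr_cut, config.rho_cut)
    mag = st.mag_age_association(bundle.abundances,
                                 bundle.metadata["age"].to_numpy())
    results.to_csv(stage_dir / "correlations.tsv", sep="\t", index=False)
    sig.to_csv(stage_dir / "significant_pairs.tsv", sep="\t", index=False)
    mag.to_csv(stage_dir / "mag_age_association.tsv", sep="\t")
    state["significant_pairs"] = sig
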