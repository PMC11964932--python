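"""Elementary-flux-mode sampling and EFM-derived interaction structure.

EFMs through an indicator reaction are sampled by randomly weighted flux
minimization: the indicator flux is fixed to one, a basic solution of the
weighted L1-minimal flux problem is taken, and its support is verified (and
if necessary repaired) to be elementary — the nullspace of the
stoichiometric matrix restricted to the support must be one-dimensional.
Co-occurrence frequencies of reactions across the sampled modes, averaged
over animals, yield the host-microbiome interaction matrix from which
metabolic modules, their microbiome dependence and their aging regulation
are derived.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact, ranksums
from statsmodels.stats.multitest import multipletests

from .network import MetabolicModel
from . import lp
from .exact import is_elementary

logger = logging.getLogger(__name__)

MEMBERSHIP_THRESHOLD = 0.2   # reaction belongs to a module at >= 20% of EFMs
INTERACTION_THRESHOLD = 0.5  # reaction pair interacts at >= 50% of EFMs
MIN_MICROBIAL = 20           # microbial reactions for microbiome dependence
AGING_P = 0.01               # module aging-enrichment significance


@dataclass
class EFMSample:
    indicator_id: str
    supports: list[frozenset]
    n_draws: int


def sample_efms(model: MetabolicModel, indicator: str, max_efms: int = 10000,
                time_budget_s: float = 200.0, seed: int = 0,
                max_draws: int | None = None,
                flux_tol: float = 1e-6) -> EFMSample:
    """Sample distinct elementary flux modes through an indicator reaction.

    Each draw minimizes a randomly re-weighted flux L1 norm with the
    indicator fixed to unit flux; the support of the basic optimal solution
    is repaired to elementarity by re-minimizing within its own support with
    fresh weights until the restricted nullspace is one-dimensional.
    Supports are deduplicated; sampling stops at ``max_efms`` distinct modes,
    after ``max_draws`` draws, or once the wall-clock budget is exhausted.
    """
    if indicator not in set(model.reaction_ids):
        raise KeyError(f"indicator {indicator!r} not in model")
    rng = np.random.default_rng(seed)
    base = lp.fva(model, [indicator])[0]
    if max(base.vmax, -base.vmin) <= flux_tol:
        logger.warning("indicator %s is blocked; empty sample", indicator)
        return EFMSample(indicator, [], 0)
    target = 1.0 if base.vmax >= 1.0 else (
        base.vmax if base.vmax > flux_tol else base.vmin
    )
    rxn_ids = model.reaction_ids
    seen: set[frozenset] = set()
    supports: list[frozenset] = []
    draws = 0
    t0 = time.monotonic()
    limit = max_draws if max_draws is not None else 50 * max_efms
    while len(supports) < max_efms and draws < limit:
        if time.monotonic() - t0 > time_budget_s:
            logger.info("EFM sampling for %s hit the time budget", indicator)
            break
        draws += 1
        weights = dict(zip(rxn_ids, rng.uniform(0.5, 1.5, len(rxn_ids))))
        sol = lp.flux_minimization(model, fixed={indicator: target},
                                   weights=weights)
        if not sol.optimal:
            continue
        support = frozenset(
            r for r, v in sol.fluxes.items() if abs(v) > flux_tol
        )
        support = _repair_elementarity(model, support, indicator, target,
                                       rng, flux_tol)
        if support and support not in seen:
            seen.add(support)
            supports.append(support)
    return EFMSample(indicator, supports, draws)


def _repair_elementarity(model, support, indicator, target, rng, flux_tol,
                         max_rounds: int = 15):
    """Re-minimize within the current support until it is elementary."""
    for _ in range(max_rounds):
        if not support or indicator not in support:
            return None
        if is_elementary(model, set(support)):
            return support
        sub = model.subset(support)
        weights = dict(zip(sub.reaction_ids,
                           rng.uniform(0.5, 1.5, len(sub.reactions))))
        sol = lp.flux_minimization(sub, fixed={indicator: target},
                                   weights=weights)
        if not sol.optimal:
            return None
        new = frozenset(r for r, v in sol.fluxes.items() if abs(v) > flux_tol)
        if new == support:
            # vertex solutions of a fixed support either shrink or repeat;
            # a repeating non-elementary support is dropped
            return None
        support = new
    return None


@dataclass
class InteractionMatrix:
    """Average frequency with which ``other`` occurs in the EFMs of
    ``target``, over all animals that sampled the target."""

    freq: dict[str, dict[str, float]]

    def entry(self, target: str, other: str) -> float:
        return self.freq.get(target, {}).get(other, 0.0)

    @property
    def targets(self) -> list[str]:
        return sorted(self.freq)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"target": t, "other": o, "frequency": f}
            for t, d in sorted(self.freq.items())
            for o, f in sorted(d.items())
        ]
        return pd.DataFrame(rows, columns=["target", "other", "frequency"])


def interaction_matrix(samples: dict[str, dict[str, EFMSample]]
                       ) -> InteractionMatrix:
    """Average per-animal co-occurrence frequencies across animals.

    ``samples`` maps animal -> indicator -> EFMSample.  For each animal the
    frequency of ``other`` given ``target`` is the fraction of the target's
    modes containing it; animals without modes for a target are excluded
    from that target's average.
    """
    acc: dict[str, dict[str, float]] = {}
    counts: dict[str, int] = {}
    for per_animal in samples.values():
        for target, sample in per_animal.items():
            if not sample.supports:
                continue
            n = len(sample.supports)
            freq: dict[str, float] = {}
            for sup in sample.supports:
                for r in sup:
                    freq[r] = freq.get(r, 0.0) + 1.0 / n
            slot = acc.setdefault(target, {})
            for r, f in freq.items():
                slot[r] = slot.get(r, 0.0) + f
            counts[target] = counts.get(target, 0) + 1
    out = {
        t: {r: f / counts[t] for r, f in d.items()}
        for t, d in acc.items()
    }
    return InteractionMatrix(out)


@dataclass
class MetabolicModule:
    indicator_id: str
    members: frozenset
    n_microbial: int
    microbiome_dependent: bool
    aging_direction: str = "none"  # induced | repressed | none
    fisher_p: float = float("nan")


def define_modules(matrix: InteractionMatrix, microbiome_reactions: set[str],
                   membership_threshold: float = MEMBERSHIP_THRESHOLD,
                   min_microbial: int = MIN_MICROBIAL
                   ) -> list[MetabolicModule]:
    """One module per indicator: the reactions (host and microbiome) present
    in at least ``membership_threshold`` of its EFMs; microbiome dependent
    when at least ``min_microbial`` members are microbial."""
    modules = []
    for target in matrix.targets:
        members = frozenset(
            r for r, f in matrix.freq[target].items()
            if f >= membership_threshold
        )
        n_mb = len(members & microbiome_reactions)
        modules.append(MetabolicModule(
            indicator_id=target, members=members, n_microbial=n_mb,
            microbiome_dependent=n_mb >= min_microbial,
        ))
    return modules


def _fisher_enrichment(hits_in: int, size_in: int, hits_bg: int, size_bg: int
                       ) -> float:
    """One-sided Fisher p for over-representation of hits inside a set."""
    table = [[hits_in, size_in - hits_in],
             [hits_bg - hits_in, size_bg - size_in - hits_bg + hits_in]]
    return float(fisher_exact(table, alternative="greater")[1])


def module_aging_enrichment(modules: list[MetabolicModule],
                            aging_up_reactions: set[str],
                            aging_down_reactions: set[str],
                            background: set[str],
                            p_cut: float = AGING_P) -> list[MetabolicModule]:
    """Flag modules enriched for aging-induced or aging-repressed reactions.

    One-sided Fisher's exact test per module and direction against the
    tissue-wide reaction background; the direction with the smaller p is
    assigned when it reaches ``p_cut``.
    """
    if not background:
        raise ValueError("empty background reaction universe")
    up = set(aging_up_reactions) & background
    down = set(aging_down_reactions) & background
    out = []
    for mod in modules:
        members = set(mod.members) & background
        size = len(members)
        results = {}
        for direction, hits_set in (("induced", up), ("repressed", down)):
            k = len(members & hits_set)
            results[direction] = _fisher_enrichment(
                k, size, len(hits_set), len(background)
            ) if size else 1.0
        direction = min(results, key=results.get)
        p = results[direction]
        out.append(MetabolicModule(
            indicator_id=mod.indicator_id, members=mod.members,
            n_microbial=mod.n_microbial,
            microbiome_dependent=mod.microbiome_dependent,
            aging_direction=direction if p <= p_cut else "none",
            fisher_p=p,
        ))
    return out


def indicator_subsystem_enrichment(modules: list[MetabolicModule],
                                   subsystems: dict[str, str],
                                   background: set[str],
                                   extra_annotations: dict[str, str] | None
                                   = None) -> pd.DataFrame:
    """Subsystem enrichment of the indicator reactions of microbiome-
    dependent aging-regulated modules (with optional added transport
    annotations, e.g. for nucleotide and amino-acid transporters)."""
    ann = dict(subsystems)
    if extra_annotations:
        ann.update(extra_annotations)
    indicators = {
        m.indicator_id for m in modules
        if m.microbiome_dependent and m.aging_direction != "none"
    }
    rows = []
    bg = set(background)
    for subsystem in sorted({ann.get(r, "") for r in bg} - {""}):
        sub_rxns = {r for r in bg if ann.get(r) == subsystem}
        k = len(indicators & sub_rxns)
        p = _fisher_enrichment(k, len(indicators & bg), len(sub_rxns), len(bg))
        rows.append({"subsystem": subsystem, "k": k,
                     "n_indicators": len(indicators & bg),
                     "subsystem_size": len(sub_rxns), "p": p})
    df = pd.DataFrame(rows)
    if len(df):
        df["fdr"] = multipletests(df["p"], method="fdr_bh")[1]
    return df


def subsystem_pair_enrichment(matrix: InteractionMatrix,
                              host_subsystems: dict[str, str],
                              microbiome_subsystems: dict[str, str],
                              interaction_threshold: float =
                              INTERACTION_THRESHOLD) -> pd.DataFrame:
    """Which (host subsystem, microbiome subsystem) pairs interact more than
    the matrix-wide rate.

    A host target and microbiome reaction interact when the microbiome
    reaction occurs in at least half of the target's EFMs; each subsystem
    pair's 2x2 contingency (interacting vs not, in pair vs not) is tested
    one-sided with Fisher's exact test and BH-corrected.
    """
    pairs = []
    for t in matrix.targets:
        if t not in host_subsystems:
            continue
        for o, f in matrix.freq[t].items():
            if o in microbiome_subsystems:
                pairs.append((host_subsystems[t], microbiome_subsystems[o],
                              f >= interaction_threshold))
    if not pairs:
        return pd.DataFrame(
            columns=["host_subsystem", "microbiome_subsystem", "odds", "p",
                     "fdr"]
        )
    df = pd.DataFrame(pairs, columns=["hs", "ms", "interacting"])
    total = len(df)
    total_int = int(df["interacting"].sum())
    rows = []
    for (hs, ms), grp in df.groupby(["hs", "ms"]):
        in_pair = len(grp)
        int_in = int(grp["interacting"].sum())
        table = [[int_in, in_pair - int_in],
                 [total_int - int_in, total - in_pair - total_int + int_in]]
        odds, p = fisher_exact(table, alternative="greater")
        rows.append({"host_subsystem": hs, "microbiome_subsystem": ms,
                     "odds": float(odds), "p": float(p)})
    out = pd.DataFrame(rows)
    out["fdr"] = multipletests(out["p"], method="fdr_bh")[1]
    return out


def validate_vs_correlations(matrix: InteractionMatrix,
                             sig_pairs: list[tuple[str, str]],
                             gene_to_reactions: dict[str, set[str]],
                             candidate_genes: list[str],
                             microbiome_reactions: list[str],
                             n_random: int = 100, seed: int = 0) -> dict:
    """Compare interaction scores of correlated (gene, microbiome reaction)
    pairs against randomly drawn pairs.

    The score of a pair is the maximum matrix entry over the gene's mapped
    reactions crossed with the microbiome reaction (in either target/other
    orientation); the random baseline redraws genes and microbiome reactions
    ``n_random`` times, and the two score samples are compared with the
    Wilcoxon rank-sum test.
    """
    if n_random <= 0:
        raise ValueError("n_random must be positive")
    rng = np.random.default_rng(seed)

    def score(gene: str, mb: str) -> float | None:
        rxns = gene_to_reactions.get(gene)
        if not rxns:
            return None
        best = 0.0
        for r in rxns:
            best = max(best, matrix.entry(r, mb), matrix.entry(mb, r))
        return best

    true_scores = []
    skipped = 0
    for gene, mb in sig_pairs:
        s = score(gene, mb)
        if s is None:
            skipped += 1
        else:
            true_scores.append(s)
    random_scores = []
    for _ in range(n_random):
        for _ in sig_pairs:
            g = candidate_genes[rng.integers(len(candidate_genes))]
            m = microbiome_reactions[rng.integers(len(microbiome_reactions))]
            s = score(g, m)
            if s is not None:
                random_scores.append(s)
    stat, p = ranksums(true_scores, random_scores)
    return {
        "true_scores": true_scores,
        "random_scores": random_scores,
        "wilcoxon_p": float(p),
        "n_skipped_genes": skipped,
    }
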