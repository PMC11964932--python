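"""Context-specific model extraction.

Per-sample core reaction sets are derived from expression and
reaction-abundance data by histogram-based clustering of log activity
profiles (chi-square distance between per-row histograms, complete-linkage
hierarchical clustering, per-cluster activity thresholds), and
context-specific metamodels are extracted with the FASTCORE family of
algorithms: FASTCC for the maximal flux-consistent subnetwork and FASTCORE
for a near-minimal consistent superset of the core.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.optimize import linprog
from scipy.spatial.distance import pdist

from .network import MetabolicModel
from . import lp
from .assembly import link_id

logger = logging.getLogger(__name__)

DEFAULT_EPSILON = 1e-4


class ExtractionError(RuntimeError):
    pass


@dataclass
class CoreReactionSet:
    sample_id: str
    reactions: set[str]
    source: str = "expression"  # expression | abundance | measured_exchange
    active_rows: set[str] = field(default_factory=set)


# ---------------------------------------------------------------------------
# expression preprocessing
# ---------------------------------------------------------------------------

def fpkm_and_filter(counts: pd.DataFrame, gene_lengths: pd.Series,
                    min_mean_fpkm: float = 0.1,
                    corrected: pd.DataFrame | None = None) -> pd.DataFrame:
    """FPKM-transform counts, drop unreliable genes, return log2 values.

    Genes with a zero count in any sample or a mean FPKM below
    ``min_mean_fpkm`` are removed.  ``corrected`` optionally supplies an
    externally batch-corrected FPKM matrix used in place of the internal one
    (the same filters are applied to it).
    """
    gene_lengths = gene_lengths.reindex(counts.index)
    if gene_lengths.isna().any():
        missing = gene_lengths.index[gene_lengths.isna()].tolist()
        raise ValueError(f"genes without length: {missing[:5]}")
    if (gene_lengths <= 0).any():
        raise ValueError("gene lengths must be positive")
    libsize = counts.sum(axis=0)
    fpkm = counts.mul(1e9).div(gene_lengths, axis=0).div(libsize, axis=1)
    if corrected is not None:
        fpkm = corrected.reindex(counts.index)
    keep = (counts > 0).all(axis=1) & (fpkm.mean(axis=1) >= min_mean_fpkm)
    if not keep.any():
        raise ExtractionError("all genes removed by the expression filter")
    return np.log2(fpkm.loc[keep])


# ---------------------------------------------------------------------------
# histogram-cluster core derivation (StanDep-style)
# ---------------------------------------------------------------------------

def _chi2_hist_distance(data: np.ndarray, bins: np.ndarray) -> np.ndarray:
    """Condensed chi-square distances between per-row histograms."""
    hists = np.stack([np.histogram(row, bins=bins)[0] for row in data])
    hists = hists / np.maximum(hists.sum(axis=1, keepdims=True), 1)

    def chi2(a, b):
        denom = a + b
        mask = denom > 0
        return 0.5 * float(np.sum((a[mask] - b[mask]) ** 2 / denom[mask]))

    return pdist(hists, metric=chi2)


def _n_bins(n_samples: int, n_groups: int) -> int:
    return 2 * (int(np.ceil(np.log2(max(n_samples * n_groups, 2)))) + 1)


def cluster_rows(data: pd.DataFrame, n_clusters: int,
                 groups: dict | None = None) -> pd.Series:
    """Complete-linkage clustering of rows by chi-square histogram distance
    over a shared bin grid spanning the pooled value range."""
    if n_clusters < 2:
        raise ValueError("n_clusters must be >= 2")
    values = data.to_numpy(dtype=float)
    n_groups = len(set(groups.values())) if groups else 1
    nb = _n_bins(data.shape[1], n_groups)
    lo, hi = float(values.min()), float(values.max())
    if hi <= lo:
        hi = lo + 1.0
    bins = np.linspace(lo, hi, nb + 1)
    dist = _chi2_hist_distance(values, bins)
    Z = linkage(dist, method="complete")
    labels = fcluster(Z, t=n_clusters, criterion="maxclust")
    return pd.Series(labels, index=data.index, name="cluster")


def standep_core(data: pd.DataFrame, n_clusters: int,
                 groups: dict | None = None,
                 gene_to_reactions: dict[str, set[str]] | None = None,
                 threshold_percentile: float = 25.0,
                 source: str = "expression") -> list[CoreReactionSet]:
    """Derive per-sample core reaction sets from a log-scale activity matrix.

    Rows are clustered by the shape of their value histograms; each cluster
    gets an activity threshold (its ``threshold_percentile``-th percentile
    across all samples, default the 25th).  A row is active in a sample when
    its value meets its cluster threshold; active rows map to reactions
    through ``gene_to_reactions`` (identity for reaction-abundance data).
    """
    labels = cluster_rows(data, n_clusters, groups)
    values = data.to_numpy(dtype=float)
    global_median = float(np.median(values))
    thresholds = pd.Series(index=data.index, dtype=float)
    for cl in sorted(labels.unique()):
        rows = labels.index[labels == cl]
        if len(rows) < 2:
            logger.info("cluster %s has <2 rows; global-median threshold", cl)
            thr = global_median
        else:
            thr = float(np.percentile(data.loc[rows].to_numpy(),
                                      threshold_percentile))
        thresholds.loc[rows] = thr
    active = data.ge(thresholds, axis=0)
    out = []
    for sample in data.columns:
        rows = set(active.index[active[sample]])
        if gene_to_reactions is None:
            rxns = set(rows)
        else:
            rxns = set()
            for g in rows:
                rxns |= gene_to_reactions.get(g, set())
        out.append(CoreReactionSet(sample_id=str(sample), reactions=rxns,
                                   source=source, active_rows=rows))
    return out


def _core_union(cores: list[CoreReactionSet]) -> set[str]:
    u: set[str] = set()
    for c in cores:
        u |= c.reactions
    return u


def jaccard_distance(a: set, b: set) -> float:
    if not a and not b:
        return 0.0
    return 1.0 - len(a & b) / len(a | b)


def select_cluster_number(data: pd.DataFrame, k_grid,
                          jaccard_tol: float = 0.05, **kwargs) -> int:
    """Smallest cluster number at which the derived core sets stabilize.

    Stability means a Jaccard distance below ``jaccard_tol`` between the
    union-of-core-sets at k and at the next grid value.  Returns the largest
    grid value (with a warning) when no k stabilizes.
    """
    k_grid = list(k_grid)
    if k_grid != sorted(k_grid):
        raise ValueError("k_grid must be increasing")
    unions = [
        _core_union(standep_core(data, k, **kwargs)) for k in k_grid
    ]
    for i in range(len(k_grid) - 1):
        if jaccard_distance(unions[i], unions[i + 1]) < jaccard_tol:
            return k_grid[i]
    logger.warning("no stable cluster number on grid %s; using %s",
                   k_grid, k_grid[-1])
    return k_grid[-1]


# ---------------------------------------------------------------------------
# metagenome reaction abundances
# ---------------------------------------------------------------------------

def reaction_abundance_matrix(mag_counts: pd.DataFrame,
                              contribution: pd.DataFrame) -> pd.DataFrame:
    """Reactions-by-samples abundance matrix from species counts and a
    species-by-reactions contribution matrix.

    Contribution rows are normalized to sum one per species; the product is
    then normalized to sum one across reactions per sample.  Species with an
    all-zero contribution row are excluded (logged).
    """
    shared = mag_counts.index.intersection(contribution.index)
    if len(shared) == 0:
        raise ValueError("no shared species between counts and contribution")
    counts = mag_counts.loc[shared]
    contrib = contribution.loc[shared]
    rowsum = contrib.sum(axis=1)
    zero = rowsum[rowsum == 0].index.tolist()
    if zero:
        logger.info("species without reaction contribution excluded: %s", zero)
        counts = counts.drop(index=zero)
        contrib = contrib.drop(index=zero)
        rowsum = rowsum.drop(index=zero)
    contrib = contrib.div(rowsum, axis=0)
    rx = contrib.T @ counts
    colsum = rx.sum(axis=0)
    if (colsum == 0).any():
        raise ValueError("sample with zero total reaction abundance")
    return rx.div(colsum, axis=1)


# ---------------------------------------------------------------------------
# FASTCC / FASTCORE
# ---------------------------------------------------------------------------

def blocked_reactions(model: MetabolicModel, epsilon: float = DEFAULT_EPSILON
                      ) -> set[str]:
    """Reactions that cannot carry |flux| >= epsilon at steady state."""
    ranges = lp.fva(model, pairs={})
    return {
        fr.reaction_id for fr in ranges
        if max(fr.vmax, -fr.vmin) < epsilon - 1e-12
    }


def fastcc(model: MetabolicModel, epsilon: float = DEFAULT_EPSILON
           ) -> MetabolicModel:
    """Maximal flux-consistent subnetwork.

    A reaction is kept iff it can carry |flux| >= epsilon in some
    steady-state solution; removing only zero-flux reactions leaves the flux
    polytope unchanged, so one exact variability pass suffices.
    """
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    bad = blocked_reactions(model, epsilon)
    keep = [r for r in model.reaction_ids if r not in bad]
    if not keep:
        raise ExtractionError("model has no flux-consistent reactions")
    return model.subset(keep)


class _FastcoreLP:
    """Shared LP machinery for the FASTCORE algorithm."""

    def __init__(self, model: MetabolicModel, epsilon: float):
        self.model = model
        self.eps = epsilon
        self.rxn_ids = model.reaction_ids
        self.index = {r: j for j, r in enumerate(self.rxn_ids)}
        self.S = model.stoichiometric_matrix()
        self.lb, self.ub = model.bounds_arrays()
        self.flipped: set[str] = set()

    def _bounds(self):
        lb, ub = self.lb.copy(), self.ub.copy()
        for r in self.flipped:
            j = self.index[r]
            lb[j], ub[j] = -self.ub[j], -self.lb[j]
        return lb, ub

    def _smatrix(self):
        """Stoichiometry with flipped reactions' columns negated, so flipped
        variables live in the reversed orientation."""
        if not self.flipped:
            return self.S
        S = self.S.tolil(copy=True)
        for r in self.flipped:
            j = self.index[r]
            S[:, j] = -S[:, j]
        return S.tocsc()

    def lp7(self, J: set[str]) -> dict[str, float]:
        """Maximize the number of reactions in J carrying flux >= eps."""
        lb, ub = self._bounds()
        n = len(self.rxn_ids)
        idx = [self.index[r] for r in sorted(J)]
        k = len(idx)
        # variables: v (n) then z (k); maximize sum z
        c = np.concatenate([np.zeros(n), -np.ones(k)])
        A_eq = sp.hstack([self._smatrix(),
                          sp.csc_matrix((self.S.shape[0], k))])
        # z_i - v_{j_i} <= 0
        rows = sp.lil_matrix((k, n + k))
        for i, j in enumerate(idx):
            rows[i, j] = -1.0
            rows[i, n + i] = 1.0
        bounds = np.column_stack([
            np.concatenate([lb, np.zeros(k)]),
            np.concatenate([ub, np.full(k, self.eps)]),
        ])
        res = linprog(c, A_eq=A_eq.tocsc(), b_eq=np.zeros(self.S.shape[0]),
                      A_ub=rows.tocsc(), b_ub=np.zeros(k), bounds=bounds,
                      method="highs")
        if res.status != 0:
            return {}
        v = res.x[:n]
        # values are in the flipped orientation space, which is what the
        # activation tests and supports need
        return {r: float(v[self.index[r]]) for r in self.rxn_ids}

    def lp10(self, K: set[str], P: set[str]) -> dict[str, float]:
        """Minimize the L1 norm over P while forcing K to carry >= eps."""
        lb, ub = self._bounds()
        n = len(self.rxn_ids)
        for r in K:
            j = self.index[r]
            lb[j] = max(lb[j], self.eps)
        pidx = [self.index[r] for r in sorted(P)]
        k = len(pidx)
        c = np.concatenate([np.zeros(n), np.ones(k)])
        A_eq = sp.hstack([self._smatrix(),
                          sp.csc_matrix((self.S.shape[0], k))])
        rows = sp.lil_matrix((2 * k, n + k))
        for i, j in enumerate(pidx):
            rows[i, j] = 1.0       # v_j - t_i <= 0
            rows[i, n + i] = -1.0
            rows[k + i, j] = -1.0  # -v_j - t_i <= 0
            rows[k + i, n + i] = -1.0
        big = max(np.max(np.abs(self.ub)), np.max(np.abs(self.lb)), 1.0)
        bounds = np.column_stack([
            np.concatenate([lb, np.zeros(k)]),
            np.concatenate([ub, np.full(k, big)]),
        ])
        res = linprog(c, A_eq=A_eq.tocsc(), b_eq=np.zeros(self.S.shape[0]),
                      A_ub=rows.tocsc(), b_ub=np.zeros(2 * k), bounds=bounds,
                      method="highs")
        if res.status != 0:
            return {}
        v = res.x[:n]
        return {r: float(v[self.index[r]]) for r in self.rxn_ids}


def _support(fluxes: dict[str, float], tol: float) -> set[str]:
    return {r for r, v in fluxes.items() if abs(v) > tol}


def _min_cardinality_cover(model: MetabolicModel, core: list[str],
                           epsilon: float) -> set[str] | None:
    """Exact minimum-cardinality flux-consistent superset of the core.

    Mixed-integer program over one steady-state flux vector per core
    reaction: vector k must activate core k (|v| >= epsilon, either
    orientation for reversible cores), and a non-core reaction may carry
    flux in any vector only if its selection binary is on.  Minimizing the
    number of selected non-core reactions yields the exact optimum that
    FASTCORE only approximates; tractable for small (toy-scale) networks
    only.  Returns None when the solver fails.
    """
    from scipy.optimize import Bounds, LinearConstraint, milp

    rxn_ids = model.reaction_ids
    n = len(rxn_ids)
    index = {r: j for j, r in enumerate(rxn_ids)}
    S = model.stoichiometric_matrix().toarray()
    lb, ub = model.bounds_arrays()
    K = len(core)
    P = [r for r in rxn_ids if r not in set(core)]
    npv = len(P)
    M = float(max(np.max(np.abs(lb)), np.max(np.abs(ub)), 1.0))
    rev = [model.reaction(c).lb < 0 and model.reaction(c).ub > 0
           for c in core]
    nz = sum(rev)
    # variables: K flux vectors, then y (selection), then z (orientations)
    nvar = K * n + npv + nz
    c_obj = np.zeros(nvar)
    c_obj[K * n: K * n + npv] = 1.0
    lo = np.concatenate([np.tile(lb, K), np.zeros(npv + nz)])
    hi = np.concatenate([np.tile(ub, K), np.ones(npv + nz)])
    integrality = np.concatenate([np.zeros(K * n),
                                  np.ones(npv + nz)])
    rows, lcs = [], []

    def add(a, lo_, hi_):
        rows.append((a, lo_, hi_))

    for k in range(K):
        off = k * n
        a = np.zeros((S.shape[0], nvar))
        a[:, off: off + n] = S
        add(a, np.zeros(S.shape[0]), np.zeros(S.shape[0]))
        for i, p in enumerate(P):
            j = off + index[p]
            a1 = np.zeros(nvar)
            a1[j] = 1.0
            a1[K * n + i] = -M
            add(a1, -np.inf, 0.0)
            a2 = np.zeros(nvar)
            a2[j] = -1.0
            a2[K * n + i] = -M
            add(a2, -np.inf, 0.0)
    zi = 0
    for k, ck in enumerate(core):
        j = k * n + index[ck]
        if not rev[k]:
            r = model.reaction(ck)
            a = np.zeros(nvar)
            a[j] = 1.0
            if r.lb >= 0:
                add(a, epsilon, np.inf)
            else:  # reverse-only
                add(a, -np.inf, -epsilon)
        else:
            big = M + epsilon
            a1 = np.zeros(nvar)
            a1[j] = 1.0
            a1[K * n + npv + zi] = -big
            add(a1, epsilon - big, np.inf)
            a2 = np.zeros(nvar)
            a2[j] = 1.0
            a2[K * n + npv + zi] = -big
            add(a2, -np.inf, -epsilon)
            zi += 1
    A = np.vstack([r[0].reshape(-1, nvar) if r[0].ndim == 1 else r[0]
                   for r in rows])
    lows = np.concatenate([np.atleast_1d(r[1]) for r in rows])
    highs = np.concatenate([np.atleast_1d(r[2]) for r in rows])
    res = milp(c_obj, constraints=LinearConstraint(A, lows, highs),
               bounds=Bounds(lo, hi), integrality=integrality)
    if res.status != 0:
        return None
    y = res.x[K * n: K * n + npv]
    return set(core) | {p for p, yv in zip(P, y) if yv > 0.5}


#: networks at or below this size get the exact minimum-cardinality search
EXACT_EXTRACTION_MAX_REACTIONS = 16


def _prune_redundant(model: MetabolicModel, kept: set[str], core: set[str],
                     epsilon: float) -> set[str]:
    """Drop non-core reactions whose removal leaves the subnetwork
    flux-consistent, until none can be removed."""
    current = set(kept)
    changed = True
    while changed:
        changed = False
        for r in sorted(current - core):
            candidate = current - {r}
            if not candidate:
                continue
            if not blocked_reactions(model.subset(candidate), epsilon):
                current = candidate
                changed = True
    return current


def fastcore(consistent_model: MetabolicModel, core: set[str],
             epsilon: float = DEFAULT_EPSILON,
             prune: bool = True) -> tuple[MetabolicModel, set[str]]:
    """FASTCORE: a flux-consistent subnetwork containing every activatable
    core reaction with near-minimal non-core cardinality.

    Alternates an LP maximizing the number of core reactions above epsilon
    (LP7) with an L1-minimization of non-core support at forced core flux
    (LP10), flipping the bounds of unsatisfied reversible core reactions when
    progress stalls.  Returns the extracted submodel and the set of core
    reactions that could not be activated (those absent from the consistent
    model).
    """
    model_rxns = set(consistent_model.reaction_ids)
    excluded = set(core) - model_rxns
    if excluded:
        logger.warning("core reactions not in consistent model: %s",
                       sorted(excluded))
    C = set(core) & model_rxns
    if not C:
        return consistent_model.subset([]), excluded
    # canonicalize orientation: reverse-only reactions become forward-only
    canonical = consistent_model.copy()
    for r in canonical.reactions:
        if r.ub <= 0 and r.lb < 0:
            r.stoich = {m: -c for m, c in r.stoich.items()}
            r.lb, r.ub = -r.ub, -r.lb
    eng = _FastcoreLP(canonical, epsilon)
    tol = epsilon * 0.99
    P_all = model_rxns - C
    irreversible = {r.id for r in canonical.reactions if r.lb >= 0}

    def find_sparse_mode(J: set[str], singleton: bool) -> set[str]:
        if not J:
            return set()
        target = {sorted(J)[0]} if singleton else J
        v = eng.lp7(target)
        K = {r for r in target if v.get(r, 0.0) >= tol}
        if not K:
            return set()
        v = eng.lp10(K, P_all)
        return _support(v, epsilon * 1e-4)

    J = C & irreversible
    A = find_sparse_mode(J, singleton=False)
    missing = J - A
    if missing:
        raise ExtractionError(
            f"irreversible core reactions inconsistent: {sorted(missing)}"
        )
    J = C - A
    flipped = False
    singleton = False
    guard = 0
    while J:
        guard += 1
        if guard > 10 * len(C) + 100:
            raise ExtractionError("FASTCORE failed to converge")
        A |= find_sparse_mode(J, singleton)
        if J & A:
            J -= A
            flipped = False
        else:
            jrev = (({sorted(J)[0]} if singleton else J) - irreversible)
            if flipped or not jrev:
                if singleton:
                    raise ExtractionError(
                        f"global network inconsistent for core: {sorted(J)}"
                    )
                flipped = False
                singleton = True
            else:
                eng.flipped ^= jrev
                flipped = True
    kept = A | C
    if prune:
        kept = _prune_redundant(consistent_model, kept, C, epsilon)
        if len(consistent_model.reactions) <= EXACT_EXTRACTION_MAX_REACTIONS:
            exact_set = _min_cardinality_cover(consistent_model, sorted(C),
                                               epsilon)
            if exact_set is not None and len(exact_set - C) < len(kept - C) \
                    and not blocked_reactions(
                        consistent_model.subset(exact_set), epsilon):
                kept = exact_set
    return consistent_model.subset(kept), excluded


# ---------------------------------------------------------------------------
# context metamodel
# ---------------------------------------------------------------------------

def build_context_metamodel(
    metamodel: MetabolicModel,
    tissue_cores: dict[str, set[str]],
    microbiome_core: set[str],
    measured_exchanges: list[dict] | None = None,
    epsilon: float = DEFAULT_EPSILON,
    consistent: bool = False,
    prune: bool = False,
) -> tuple[MetabolicModel, dict]:
    """Extract one context-specific metamodel from assembled per-compartment
    cores.

    ``measured_exchanges`` entries are {"organ", "metabolite", "direction"}
    with direction "uptake"/"secretion"; each is mapped to the corresponding
    organ-blood exchange link and forced into the core.  Measured kidney
    uptakes become blood-outflow core reactions, since the kidney is not an
    explicit compartment.  FASTCORE is run once on the union of all cores.
    """
    rxn_ids = set(metamodel.reaction_ids)
    core: set[str] = set(microbiome_core)
    for organ_core in tissue_cores.values():
        core |= organ_core
    report: dict = {"unmapped_measured": [], "excluded_core": []}
    for entry in measured_exchanges or ():
        organ = entry["organ"]
        met = entry["metabolite"]
        direction = entry["direction"]
        if organ == "kidney":
            rid = f"OUT_{met}_blood"
        else:
            rid = link_id(organ, met, "blood",
                          "upt" if direction == "uptake" else "sec")
        if rid in rxn_ids:
            core.add(rid)
        else:
            logger.warning("measured exchange %s not in metamodel; skipped",
                           entry)
            report["unmapped_measured"].append(entry)
    consistent_model = metamodel if consistent else fastcc(metamodel, epsilon)
    context, excluded = fastcore(consistent_model, core & rxn_ids, epsilon,
                                 prune=prune)
    report["excluded_core"] = sorted(
        excluded | (core - rxn_ids)
    )
    report["core_size"] = len(core)
    report["context_size"] = len(context.reactions)
    return context, report
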