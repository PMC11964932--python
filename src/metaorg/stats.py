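"""Association statistics for host-microbiome analyses.

Partial Spearman correlations between host features and microbiome
reaction activities (rank-residualization on covariates), hypergeometric
over-representation and overlap tests, species-abundance age associations,
signed log-FDR summaries and age-group ratio comparisons.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

FDR_CAP = 1e-300


def _rank_rows(df: pd.DataFrame) -> np.ndarray:
    return np.apply_along_axis(sps.rankdata, 1, df.to_numpy(dtype=float))


def _residualize(ranked: np.ndarray, design: np.ndarray) -> np.ndarray:
    beta, *_ = np.linalg.lstsq(design, ranked.T, rcond=None)
    return ranked - (design @ beta).T


def partial_spearman(x: pd.DataFrame, y: pd.DataFrame,
                     covariates: pd.DataFrame | None = None) -> pd.DataFrame:
    """All-pairs partial Spearman correlations between rows of x and rows
    of y given covariates.

    Ranks are computed per row across samples, residualized on the
    covariates (plus intercept) by least squares, and correlated with
    Pearson's formula; p values use the t distribution with
    n - 2 - n_covariates degrees of freedom.  With no covariates this equals
    the plain Spearman correlation.  Constant rows are excluded with a log
    message.
    """
    if not x.columns.equals(y.columns):
        y = y[x.columns]
    n = x.shape[1]
    n_cov = 0 if covariates is None else covariates.shape[0]
    dof = n - 2 - n_cov
    if dof < 1:
        raise ValueError("too few samples for the requested covariates")

    def drop_constant(df: pd.DataFrame) -> pd.DataFrame:
        keep = df.std(axis=1) > 0
        dropped = df.index[~keep].tolist()
        if dropped:
            logger.info("constant rows excluded: %s...", dropped[:5])
        return df.loc[keep]

    x = drop_constant(x)
    y = drop_constant(y)
    if x.empty or y.empty:
        return pd.DataFrame(columns=["host_feature", "microbiome_reaction",
                                     "rho", "p"])
    design = np.ones((n, 1))
    if covariates is not None:
        cov = covariates[x.columns].to_numpy(dtype=float).T
        cov_ranked = np.apply_along_axis(sps.rankdata, 0, cov)
        design = np.hstack([design, cov_ranked])
    rx = _residualize(_rank_rows(x), design)
    ry = _residualize(_rank_rows(y), design)
    rx = rx - rx.mean(axis=1, keepdims=True)
    ry = ry - ry.mean(axis=1, keepdims=True)
    nx = np.linalg.norm(rx, axis=1)
    ny = np.linalg.norm(ry, axis=1)
    rho = (rx @ ry.T) / np.outer(nx, ny)
    rho = np.clip(rho, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = rho * np.sqrt(dof / (1.0 - rho**2))
    p = 2.0 * sps.t.sf(np.abs(t), dof)
    p = np.where(np.abs(rho) >= 1.0, 0.0, p)
    rows = []
    xi = list(x.index)
    yi = list(y.index)
    for i, xf in enumerate(xi):
        for j, yf in enumerate(yi):
            rows.append((xf, yf, float(rho[i, j]), float(p[i, j])))
    return pd.DataFrame(rows, columns=["host_feature", "microbiome_reaction",
                                       "rho", "p"])


def significant_pairs(results: pd.DataFrame, fdr_cut: float = 0.1,
                      rho_cut: float = 0.55) -> pd.DataFrame:
    """BH-adjust and keep strong correlations (|rho| >= rho_cut at
    FDR <= fdr_cut), stratified into positive/negative by sign."""
    out = results.copy()
    if out.empty:
        out["fdr"] = []
        out["stratum"] = []
        return out
    out["fdr"] = multipletests(out["p"], method="fdr_bh")[1]
    out = out[(out["fdr"] <= fdr_cut) & (out["rho"].abs() >= rho_cut)].copy()
    out["stratum"] = np.where(out["rho"] >= 0, "positive", "negative")
    return out.reset_index(drop=True)


def hypergeom_enrichment(features: set, term_map: dict[str, set],
                         universe: set, min_term_features: int = 3,
                         fdr_cut: float = 0.05) -> pd.DataFrame:
    """Upper-tail hypergeometric over-representation of terms in a feature
    set (P[X >= k], the 'observed minus one' convention of phyper), BH
    corrected; terms need at least ``min_term_features`` overlapping
    features and FDR <= ``fdr_cut`` to be reported."""
    universe = set(universe)
    features = set(features) & universe
    M = len(universe)
    N = len(features)
    rows = []
    for term, members in sorted(term_map.items()):
        members = set(members)
        extra = members - universe
        if extra:
            logger.info("term %s trimmed to universe (%d dropped)", term,
                        len(extra))
            members &= universe
        K = len(members)
        if K == 0:
            continue
        k = len(members & features)
        p = float(sps.hypergeom.sf(k - 1, M, K, N))
        rows.append({"term_id": term, "k_overlap": k, "set_size": N,
                     "term_size": K, "universe": M, "p": p})
    df = pd.DataFrame(rows)
    if df.empty:
        return df
    df["fdr"] = multipletests(df["p"], method="fdr_bh")[1]
    return df[(df["k_overlap"] >= min_term_features) &
              (df["fdr"] <= fdr_cut)].reset_index(drop=True)


def overlap_test(set_a: set, set_b: set, universe: set) -> dict:
    """Upper-tailed hypergeometric test of the overlap of two sets."""
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    a = set(set_a) & universe
    b = set(set_b) & universe
    k = len(a & b)
    p = float(sps.hypergeom.sf(k - 1, len(universe), len(a), len(b)))
    return {"k": k, "p": p}


def aging_gene_sets(expression: pd.DataFrame, ages,
                    fdr_cut: float = 0.05) -> tuple[set, set]:
    """Aging-induced and aging-repressed gene sets by Spearman correlation
    of expression with age, BH-corrected.

    A lightweight stand-in for a full differential-expression analysis,
    sufficient for the synthetic cohorts this package simulates; externally
    derived gene sets can be supplied anywhere these are consumed.
    Returns (induced, repressed).
    """
    ages = np.asarray(ages, dtype=float)
    rows = []
    for gene, row in expression.iterrows():
        y = row.to_numpy(dtype=float)
        if np.allclose(y, y[0]):
            continue
        rho, p = sps.spearmanr(y, ages)
        rows.append((gene, rho, p))
    if not rows:
        return set(), set()
    genes, rhos, ps = zip(*rows)
    fdr = multipletests(ps, method="fdr_bh")[1]
    up = {g for g, r, f in zip(genes, rhos, fdr) if f <= fdr_cut and r > 0}
    down = {g for g, r, f in zip(genes, rhos, fdr) if f <= fdr_cut and r < 0}
    return up, down


def mag_age_association(abundances: pd.DataFrame, ages,
                        fdr_cut: float = 0.05) -> pd.DataFrame:
    """Per-species linear regression of total-normalized abundance on age.

    Columns are renormalized to sum one; zero-variance species are excluded.
    Returns slope, p and BH FDR per species with a ``significant`` flag.
    """
    ages = np.asarray(ages, dtype=float)
    ab = abundances.div(abundances.sum(axis=0), axis=1)
    rows = []
    for species, row in ab.iterrows():
        y = row.to_numpy(dtype=float)
        if np.allclose(y, y[0]):
            logger.info("species %s has zero variance; excluded", species)
            continue
        fit = sps.linregress(ages, y)
        rows.append({"species": species, "slope": float(fit.slope),
                     "p": float(fit.pvalue)})
    df = pd.DataFrame(rows).set_index("species")
    if df.empty:
        return df
    df["fdr"] = multipletests(df["p"], method="fdr_bh")[1]
    df["significant"] = df["fdr"] <= fdr_cut
    return df


def signed_log_fdr(enrichments: pd.DataFrame, direction_col: str = "stratum",
                   fdr_col: str = "fdr", cap: float = 300.0,
                   group_cols: list[str] | None = None) -> pd.DataFrame:
    """-log10(FDR), negated for negative-correlation strata, optionally
    summed within grouping columns (e.g. level-2 process / superpathway
    pairs)."""
    df = enrichments.copy()
    fdr = df[fdr_col].clip(lower=FDR_CAP)
    capped = (df[fdr_col] <= FDR_CAP)
    if capped.any():
        logger.info("%d FDR values capped at -log10 = %g", capped.sum(), cap)
    value = np.minimum(-np.log10(fdr), cap)
    sign = np.where(df[direction_col] == "negative", -1.0, 1.0)
    df["signed_log_fdr"] = sign * value
    if group_cols:
        return (df.groupby(group_cols)["signed_log_fdr"].sum()
                .reset_index())
    return df


def age_group_ratio_tests(sig_counts, totals, group_labels=None
                          ) -> pd.DataFrame:
    """Yates-corrected chi-squared tests of significant-fraction differences
    between consecutive age groups, Bonferroni-adjusted over comparisons."""
    sig_counts = list(sig_counts)
    totals = list(totals)
    if len(sig_counts) != len(totals):
        raise ValueError("counts and totals must align")
    labels = group_labels or list(range(len(totals)))
    rows = []
    for i in range(len(totals) - 1):
        if totals[i] == 0 or totals[i + 1] == 0:
            logger.info("skipping comparison with zero total at %s", i)
            continue
        table = np.array([
            [sig_counts[i], totals[i] - sig_counts[i]],
            [sig_counts[i + 1], totals[i + 1] - sig_counts[i + 1]],
        ])
        chi2, p, *_ = sps.chi2_contingency(table, correction=True)
        rows.append({"group_a": labels[i], "group_b": labels[i + 1],
                     "chi2": float(chi2), "p": float(p)})
    df = pd.DataFrame(rows)
    if not df.empty:
        m = len(df)
        df["p_bonferroni"] = np.minimum(1.0, m * df["p"])
    return df
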