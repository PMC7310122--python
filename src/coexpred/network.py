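"""Signed weighted co-expression network on genotype BLUPs.

Adjacency is a_ij = ((1 + rho_ij) / 2) ** beta with rho the Spearman rank
correlation, so the network is rank-invariant: any monotone transform of a
gene leaves it unchanged.  Modules come from average-linkage clustering of
topological-overlap dissimilarity with a simplified dynamic cut; eigengenes
are first principal components of standardized module expression; kME is the
Spearman correlation of each gene with each eigengene and a gene's centrality
is its largest absolute kME.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy

__all__ = [
    "NetworkState",
    "spearman_correlation",
    "signed_adjacency",
    "connectivity",
    "scale_free_fit",
    "pick_power",
    "detect_modules",
    "eigengene",
    "module_eigengenes",
    "kme",
    "module_trait_correlations",
    "build_network",
]

GREY = 0


@dataclass
class NetworkState:
    power: int
    power_diagnostics: pd.DataFrame
    connectivity: pd.Series
    modules: pd.Series               # gene -> module id, 0 = grey
    eigengenes: pd.DataFrame         # genotype x module
    kme: pd.DataFrame                # gene x module
    centrality: pd.Series            # gene -> max |kME|
    notes: list = field(default_factory=list)


def spearman_correlation(blups: pd.DataFrame) -> pd.DataFrame:
    """Gene x gene Spearman correlation (rows = genes, columns = genotypes).

    Constant genes get correlation 0 with everything (flagged by callers).
    """
    X = blups.to_numpy(dtype=float)
    ranks = np.apply_along_axis(stats.rankdata, 1, X)
    sd = ranks.std(axis=1)
    constant = sd < 1e-12
    ranks = ranks - ranks.mean(axis=1, keepdims=True)
    norm = np.sqrt((ranks**2).sum(axis=1))
    norm[constant] = 1.0
    R = (ranks / norm[:, None]) @ (ranks / norm[:, None]).T
    R[constant, :] = 0.0
    R[:, constant] = 0.0
    np.fill_diagonal(R, 1.0)
    return pd.DataFrame(np.clip(R, -1.0, 1.0), index=blups.index, columns=blups.index)


def signed_adjacency(corr: pd.DataFrame, power: int) -> pd.DataFrame:
    """a_ij = ((1 + rho) / 2) ** beta.  Self-adjacency is kept at 1 but is
    excluded from connectivity sums."""
    if power < 1:
        raise ValueError("power must be >= 1")
    A = ((1.0 + corr.to_numpy()) / 2.0) ** power
    return pd.DataFrame(A, index=corr.index, columns=corr.columns)


def connectivity(adjacency: pd.DataFrame) -> pd.Series:
    A = adjacency.to_numpy()
    k = A.sum(axis=1) - np.diag(A)
    return pd.Series(k, index=adjacency.index, name="connectivity")


def scale_free_fit(k: np.ndarray, n_bins: int = 10) -> tuple[float, float]:
    """Signed scale-free topology fit.

    Bins the connectivity distribution, regresses log10(frequency) on
    log10(mean connectivity per bin) and returns (signed R2, slope): R2 is
    negated when the slope is positive, as an invalid fit.
    """
    k = np.asarray(k, dtype=float)
    k = k[k > 0]
    if len(np.unique(k)) < 3:
        return float("nan"), float("nan")
    edges = np.linspace(k.min(), k.max(), n_bins + 1)
    idx = np.clip(np.digitize(k, edges[1:-1]), 0, n_bins - 1)
    xs, ys = [], []
    for b in range(n_bins):
        members = k[idx == b]
        if members.size:
            xs.append(members.mean())
            ys.append(members.size / len(k))
    if len(xs) < 3:
        return float("nan"), float("nan")
    lx, ly = np.log10(xs), np.log10(ys)
    slope, _, r, _, _ = stats.linregress(lx, ly)
    r2 = r**2
    return float(-r2 if slope > 0 else r2), float(slope)


def pick_power(
    blups: pd.DataFrame,
    candidates: range | list[int] = range(1, 21),
    r2_threshold: float = 0.85,
    default: int = 12,
    corr: pd.DataFrame | None = None,
) -> tuple[int, pd.DataFrame]:
    """Smallest candidate power whose scale-free fit reaches ``r2_threshold``;
    the recommended signed-network default (12) otherwise."""
    candidates = list(candidates)
    if not candidates:
        raise ValueError("no candidate powers")
    if corr is None:
        corr = spearman_correlation(blups)
    rows = []
    chosen = None
    for beta in candidates:
        k = connectivity(signed_adjacency(corr, beta)).to_numpy()
        r2, slope = scale_free_fit(k)
        rows.append(
            {"power": beta, "scale_free_r2": r2, "slope": slope,
             "mean_connectivity": float(k.mean())}
        )
        if chosen is None and np.isfinite(r2) and r2 >= r2_threshold:
            chosen = beta
    diagnostics = pd.DataFrame(rows)
    return (chosen if chosen is not None else default), diagnostics


def _tom_dissimilarity(A: np.ndarray) -> np.ndarray:
    """Topological-overlap dissimilarity of a (signed) adjacency."""
    A = A.copy()
    np.fill_diagonal(A, 0.0)
    L = A @ A
    k = A.sum(axis=1)
    kmin = np.minimum.outer(k, k)
    tom = (L + A) / (kmin + 1.0 - A)
    np.fill_diagonal(tom, 1.0)
    return 1.0 - tom


def eigengene(module_expr: pd.DataFrame) -> pd.Series:
    """First principal component of standardized module expression across
    genotypes, oriented so its correlation with the module mean profile is
    positive.  A single-gene module returns the standardized gene."""
    if module_expr.empty:
        raise ValueError("module is empty")
    X = module_expr.to_numpy(dtype=float)
    sd = X.std(axis=1, keepdims=True)
    sd[sd < 1e-12] = 1.0
    Xs = (X - X.mean(axis=1, keepdims=True)) / sd
    if Xs.shape[0] == 1:
        e = Xs[0]
    else:
        _, _, Vt = np.linalg.svd(Xs, full_matrices=False)
        e = Vt[0]
    mean_profile = Xs.mean(axis=0)
    if np.dot(e, mean_profile) < 0:
        e = -e
    sd_e = e.std()
    if sd_e > 1e-12:
        e = (e - e.mean()) / sd_e
    return pd.Series(e, index=module_expr.columns)


def module_eigengenes(blups: pd.DataFrame, modules: pd.Series) -> pd.DataFrame:
    """Genotype x module eigengene matrix; the grey label has no eigengene."""
    cols = {}
    for m in sorted(modules.unique()):
        if m == GREY:
            continue
        cols[m] = eigengene(blups.loc[modules[modules == m].index])
    return pd.DataFrame(cols)


def kme(blups: pd.DataFrame, eigengenes: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series]:
    """Spearman correlation of every gene with every eigengene; centrality is
    the largest absolute kME across modules."""
    if eigengenes.shape[1] == 0:
        raise ValueError("no module eigengenes")
    X = blups.to_numpy(dtype=float)
    gene_ranks = np.apply_along_axis(stats.rankdata, 1, X)
    eg_ranks = np.apply_along_axis(stats.rankdata, 0, eigengenes.to_numpy(dtype=float))

    def standardize(R, axis):
        mu = R.mean(axis=axis, keepdims=True)
        sd = R.std(axis=axis, keepdims=True)
        sd[sd < 1e-12] = 1.0
        return (R - mu) / sd

    G = standardize(gene_ranks, 1)
    E = standardize(eg_ranks, 0)
    K = (G @ E) / G.shape[1]
    kme_df = pd.DataFrame(K, index=blups.index, columns=eigengenes.columns)
    centrality = kme_df.abs().max(axis=1).rename("centrality")
    return kme_df, centrality


def detect_modules(
    blups: pd.DataFrame,
    power: int,
    min_size: int = 30,
    merge_height: float = 0.25,
    kme_assign_threshold: float = 0.3,
    cut_quantiles: tuple = (0.70, 0.80, 0.85, 0.90, 0.95, 0.99),
    corr: pd.DataFrame | None = None,
) -> pd.Series:
    """Simplified dynamic tree cut on topological-overlap dissimilarity.

    Average-linkage tree on 1 - TOM; candidate cuts at several join-height
    quantiles are scanned and the finest cut yielding the most clusters of at
    least ``min_size`` wins (over-splitting is healed by the eigengene merge
    rule below, under-splitting is unrecoverable); clusters below ``min_size``
    go grey; a kME sweep then sends every gene to its best module when
    |kME| >= 0.3 and to grey otherwise; modules whose eigengenes correlate
    above 1 - merge_height are merged iteratively.
    """
    genes = blups.index
    if len(genes) < min_size:
        return pd.Series(GREY, index=genes, name="module")
    if corr is None:
        corr = spearman_correlation(blups)
    A = signed_adjacency(corr, power).to_numpy()
    D = _tom_dissimilarity(A)
    cond = D[np.triu_indices_from(D, k=1)]
    link = hierarchy.linkage(cond, method="average")

    best_raw, best_count = None, -1
    for q in sorted(cut_quantiles):
        cut = np.quantile(link[:, 2], q)
        raw = hierarchy.fcluster(link, t=cut, criterion="distance")
        sizes = np.bincount(raw)
        count = int((sizes >= min_size).sum())
        if count > best_count:  # ties keep the finer (lower-quantile) cut
            best_raw, best_count = raw, count
    raw = best_raw

    labels = np.zeros(len(genes), dtype=int)
    next_id = 1
    for c in np.unique(raw):
        members = raw == c
        if members.sum() >= min_size:
            labels[members] = next_id
            next_id += 1
    modules = pd.Series(labels, index=genes, name="module")
    if (modules != GREY).sum() == 0:
        return modules

    # kME refinement sweep: every gene goes to its best module when the
    # membership is confident, to grey otherwise.  This peels chained noise
    # genes off the height-cut branches and rescues confidently co-expressed
    # genes the cut left aside.
    for _ in range(2):
        eig = module_eigengenes(blups, modules)
        if eig.shape[1] == 0:
            break
        kme_df, _ = kme(blups, eig)
        best = kme_df.abs()
        assign = best.idxmax(axis=1)
        confident = best.max(axis=1) >= kme_assign_threshold
        new = pd.Series(GREY, index=genes, name="module")
        new[confident] = assign[confident]
        # dissolve modules that fell below the minimum size
        sizes = new[new != GREY].value_counts()
        for m in sizes.index[sizes < min_size]:
            new[new == m] = GREY
        if new.equals(modules):
            modules = new
            break
        modules = new

    # iterative merge of highly correlated eigengenes
    while True:
        eig = module_eigengenes(blups, modules)
        if eig.shape[1] < 2:
            break
        C = np.corrcoef(eig.to_numpy().T)
        np.fill_diagonal(C, -np.inf)
        i, j = np.unravel_index(np.argmax(C), C.shape)
        if C[i, j] <= 1.0 - merge_height:
            break
        keep, drop = sorted((eig.columns[i], eig.columns[j]))
        modules[modules == drop] = keep

    # re-label modules consecutively by decreasing size, grey stays 0
    sizes = modules[modules != GREY].value_counts()
    remap = {old: rank + 1 for rank, old in enumerate(sizes.index)}
    return modules.map(lambda m: remap.get(m, GREY)).rename("module")


def module_trait_correlations(
    eigengenes: pd.DataFrame, traits: pd.DataFrame, alpha: float = 0.05
) -> pd.DataFrame:
    """Spearman rho and p for every module x trait, Bonferroni-corrected over
    the whole module x trait family.  Constant traits yield missing entries."""
    common = eigengenes.index.intersection(traits.index)
    if len(common) < 4:
        raise ValueError("need at least 4 genotypes with both eigengene and trait data")
    E, T = eigengenes.loc[common], traits.loc[common]
    n_tests = E.shape[1] * T.shape[1]
    rows = []
    for m in E.columns:
        for t in T.columns:
            y = T[t].to_numpy(dtype=float)
            ok = np.isfinite(y)
            if ok.sum() < 4 or np.std(y[ok]) < 1e-12:
                rho, p = np.nan, np.nan
            else:
                rho, p = stats.spearmanr(E[m].to_numpy()[ok], y[ok])
            p_adj = min(p * n_tests, 1.0) if np.isfinite(p) else np.nan
            rows.append(
                {"module": m, "trait": t, "rho": rho, "pvalue": p,
                 "pvalue_bonferroni": p_adj,
                 "significant": bool(np.isfinite(p_adj) and p_adj <= alpha)}
            )
    out = pd.DataFrame(rows)
    out.attrs["n_tests"] = n_tests
    return out


def build_network(
    blups: pd.DataFrame,
    power: int | None = None,
    min_size: int = 30,
    merge_height: float = 0.25,
    r2_threshold: float = 0.85,
    default_power: int = 12,
) -> NetworkState:
    """Full network stage: power choice, modules, eigengenes, kME, centrality.

    ``blups`` is gene x genotype.  Grey genes keep their best |kME| over the
    real modules as centrality.
    """
    corr = spearman_correlation(blups)
    diagnostics = pd.DataFrame()
    if power is None:
        power, diagnostics = pick_power(
            blups, r2_threshold=r2_threshold, default=default_power, corr=corr
        )
    k = connectivity(signed_adjacency(corr, power))
    modules = detect_modules(
        blups, power, min_size=min_size, merge_height=merge_height, corr=corr
    )
    notes = []
    if (modules != GREY).any():
        eig = module_eigengenes(blups, modules)
        kme_df, centrality = kme(blups, eig)
        non_grey = modules[modules != GREY]
        if len(non_grey):
            argmax = kme_df.loc[non_grey.index].abs().idxmax(axis=1)
            agree = float((argmax == non_grey).mean())
            if agree < 0.95:
                notes.append(
                    f"kME argmax matches assigned module for only {agree:.1%} of non-grey genes"
                )
    else:
        eig = pd.DataFrame(index=blups.columns)
        kme_df = pd.DataFrame(index=blups.index)
        centrality = pd.Series(0.0, index=blups.index, name="centrality")
        notes.append("no modules detected; all genes grey")
    return NetworkState(
        power=power,
        power_diagnostics=diagnostics,
        connectivity=k,
        modules=modules,
        eigengenes=eig,
        kme=kme_df,
        centrality=centrality,
        notes=notes,
    )
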