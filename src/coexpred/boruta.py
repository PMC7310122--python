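"""All-relevant feature selection with shadow features and random forests.

Each iteration appends a freshly permuted ("shadow") copy of every feature,
fits a random forest and credits a hit to every real feature whose importance
exceeds the best shadow importance.  A two-sided binomial test (p = 0.5) with
Bonferroni correction over the still-undecided features then confirms
(upper tail) or rejects (lower tail) features at the requested threshold.
Undecided features at the iteration cap stay tentative and count as "not
rejected" when pooling across traits.  The pooled selection is tested for
core / peripheral enrichment with Fisher's exact test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestRegressor

__all__ = ["BorutaResult", "boruta_select", "pool_selected", "enrichment_test"]


@dataclass
class BorutaResult:
    trait: str
    p_threshold: float
    confirmed: list[str]
    rejected: list[str]
    tentative: list[str]
    n_iterations: int
    hits: pd.Series                  # per-gene hit counts

    def __post_init__(self) -> None:
        if set(self.confirmed) & set(self.rejected):
            raise ValueError("confirmed and rejected overlap")

    @property
    def not_rejected(self) -> list[str]:
        return self.confirmed + self.tentative


def boruta_select(
    X: pd.DataFrame,
    y: pd.Series | np.ndarray,
    p_threshold: float = 0.01,
    max_runs: int = 100,
    seed: int = 0,
    n_trees: int = 100,
    trait: str = "",
) -> BorutaResult:
    """Run the shadow-feature selection for one trait.

    ``X`` is genotype x gene (training genotypes only).  Importance is the
    forest's impurity importance.  Stops at ``max_runs`` iterations or when
    every feature is decided.
    """
    y = np.asarray(y, dtype=float)
    if np.std(y) < 1e-12:
        raise ValueError("constant trait")
    genes = list(X.columns)
    p = len(genes)
    rng = np.random.default_rng(seed)
    Xv = X.to_numpy(dtype=float)

    hits = np.zeros(p, dtype=int)
    decided = np.zeros(p, dtype=int)        # 0 undecided, +1 confirmed, -1 rejected
    n_iter = 0
    for n_iter in range(1, max_runs + 1):
        shadow = Xv.copy()
        for j in range(p):                   # fresh permutation per feature
            shadow[:, j] = rng.permutation(shadow[:, j])
        forest = RandomForestRegressor(
            n_estimators=n_trees,
            random_state=int(rng.integers(0, 2**31 - 1)),
            max_features="sqrt",
        )
        forest.fit(np.hstack([Xv, shadow]), y)
        imp = forest.feature_importances_
        shadow_max = imp[p:].max()
        hits += (imp[:p] > shadow_max).astype(int)

        undecided = decided == 0
        n_undec = int(undecided.sum())
        if n_undec == 0:
            break
        # two-sided binomial test at p_hit = 0.5, Bonferroni over undecided
        thresh = p_threshold / n_undec
        k = hits[undecided]
        p_upper = stats.binom.sf(k - 1, n_iter, 0.5)
        p_lower = stats.binom.cdf(k, n_iter, 0.5)
        idx = np.where(undecided)[0]
        decided[idx[2 * p_upper < thresh]] = 1
        decided[idx[2 * p_lower < thresh]] = -1
        if (decided == 0).sum() == 0:
            break

    hit_series = pd.Series(hits, index=genes, name="hits")
    return BorutaResult(
        trait=trait,
        p_threshold=p_threshold,
        confirmed=[g for g, d in zip(genes, decided) if d == 1],
        rejected=[g for g, d in zip(genes, decided) if d == -1],
        tentative=[g for g, d in zip(genes, decided) if d == 0],
        n_iterations=n_iter,
        hits=hit_series,
    )


def pool_selected(
    results: list[BorutaResult], p_threshold: float | None = None
) -> tuple[list[str], pd.DataFrame]:
    """Union of non-rejected genes across traits at one threshold.

    Returns (pool, membership) where membership records which traits selected
    each pooled gene, enabling the trait-specific vs shared breakdown.
    """
    if not results:
        raise ValueError("need at least one per-trait result")
    if p_threshold is not None:
        results = [r for r in results if r.p_threshold == p_threshold]
        if not results:
            raise ValueError(f"no results at threshold {p_threshold}")
    selected_by: dict[str, list[str]] = {}
    for r in results:
        for g in r.not_rejected:
            selected_by.setdefault(g, []).append(r.trait)
    pool = sorted(selected_by)
    membership = pd.DataFrame(
        {
            "gene": pool,
            "n_traits": [len(selected_by[g]) for g in pool],
            "traits": [",".join(selected_by[g]) for g in pool],
        }
    ).set_index("gene")
    return pool, membership


def enrichment_test(
    pool: list[str], reference: list[str], universe: list[str]
) -> dict:
    """Fisher's exact test of pool x reference overlap within the universe.

    Returns the two-sided p, the conditional-MLE odds ratio, the 2x2 table and
    the representation ratio (fraction of the pool in the reference over the
    fraction of the universe in the reference).
    """
    pool_s, ref_s, uni_s = set(pool), set(reference), set(universe)
    if not pool_s:
        return {"pvalue": np.nan, "odds_ratio": np.nan,
                "representation_ratio": np.nan, "table": None}
    if not (pool_s <= uni_s and ref_s <= uni_s):
        raise ValueError("pool and reference must be subsets of the universe")
    a = len(pool_s & ref_s)
    b = len(pool_s - ref_s)
    c = len(ref_s - pool_s)
    d = len(uni_s) - a - b - c
    table = np.array([[a, b], [c, d]])
    res = stats.contingency.odds_ratio(table, kind="conditional")
    _, pvalue = stats.fisher_exact(table, alternative="two-sided")
    frac_pool = a / len(pool_s)
    frac_universe = len(ref_s) / len(uni_s)
    return {
        "pvalue": float(pvalue),
        "odds_ratio": float(res.statistic),
        "representation_ratio": float(frac_pool / frac_universe) if frac_universe else np.nan,
        "table": table,
    }
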