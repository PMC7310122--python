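"""Count filtering, TMM normalization, log2(CPM+1) transform and cofactor PCA.

The normalization follows the trimmed-mean-of-M-values scheme: a reference
sample is chosen by upper-quartile proximity to the mean upper quartile, M and
A values are doubly trimmed (30% on M, 5% on A), and factors are
precision-weighted trimmed means of M, re-centred so their log-mean is zero.
CPM uses the TMM-adjusted effective library sizes and the transform is
log2(CPM + 1), which keeps zeros at exactly zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "filter_low_expressed",
    "tmm_factors",
    "log_cpm",
    "cofactor_pca",
    "FilterReport",
]


@dataclass
class FilterReport:
    n_input: int
    n_removed: int
    n_retained: int
    min_count: int
    sample_fraction: float
    min_samples: int


def filter_low_expressed(
    counts: pd.DataFrame,
    min_count: int = 1,
    sample_fraction: float = 0.10,
) -> tuple[pd.DataFrame, FilterReport]:
    """Keep genes with >= min_count in at least ceil(sample_fraction * n) samples."""
    if counts.empty:
        raise ValueError("empty count matrix")
    if not (0.0 < sample_fraction <= 1.0):
        raise ValueError("sample_fraction must lie in (0, 1]")
    n_samples = counts.shape[1]
    min_samples = int(np.ceil(sample_fraction * n_samples))
    keep = (counts.to_numpy() >= min_count).sum(axis=1) >= min_samples
    filtered = counts.loc[keep]
    report = FilterReport(
        n_input=len(counts),
        n_removed=int((~keep).sum()),
        n_retained=int(keep.sum()),
        min_count=min_count,
        sample_fraction=sample_fraction,
        min_samples=min_samples,
    )
    return filtered, report


def _choose_reference(counts: np.ndarray) -> int:
    """Sample whose upper quartile of library-scaled counts is closest to the
    mean upper quartile."""
    lib = counts.sum(axis=0)
    uq = np.array([np.quantile(counts[:, j] / lib[j], 0.75) for j in range(counts.shape[1])])
    return int(np.argmin(np.abs(uq - uq.mean())))


def tmm_factors(
    counts: pd.DataFrame,
    trim_M: float = 0.30,
    trim_A: float = 0.05,
    reference: int | None = None,
) -> pd.Series:
    """Per-sample TMM normalization factors (geometric mean 1)."""
    X = counts.to_numpy(dtype=float)
    lib = X.sum(axis=0)
    if np.any(lib <= 0):
        raise ValueError("every sample must have positive library size")
    ref = _choose_reference(X) if reference is None else reference
    factors = np.ones(X.shape[1])
    for j in range(X.shape[1]):
        factors[j] = _tmm_pair(X[:, j], X[:, ref], lib[j], lib[ref], trim_M, trim_A)
    # re-centre so the log-mean of the factors is 0
    factors = factors / np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=counts.columns, name="tmm_factor")


def _tmm_pair(
    obs: np.ndarray, ref: np.ndarray, n_obs: float, n_ref: float,
    trim_M: float, trim_A: float,
) -> float:
    ok = (obs > 0) & (ref > 0)
    if ok.sum() == 0:
        return 1.0
    obs, ref = obs[ok], ref[ok]
    M = np.log2((obs / n_obs) / (ref / n_ref))
    A = 0.5 * np.log2((obs / n_obs) * (ref / n_ref))
    # asymptotic (delta-method) precision weights
    w = 1.0 / ((n_obs - obs) / (n_obs * obs) + (n_ref - ref) / (n_ref * ref))
    if np.allclose(M, 0.0, atol=1e-10):
        return 1.0
    n = len(M)
    loM = np.floor(n * trim_M) + 1
    loA = np.floor(n * trim_A) + 1
    keep = (
        (stats.rankdata(M, method="average") >= loM)
        & (stats.rankdata(M, method="average") <= n + 1 - loM)
        & (stats.rankdata(A, method="average") >= loA)
        & (stats.rankdata(A, method="average") <= n + 1 - loA)
    )
    if keep.sum() == 0 or w[keep].sum() == 0:
        return 1.0
    logf = np.sum(w[keep] * M[keep]) / np.sum(w[keep])
    if not np.isfinite(logf):
        return 1.0
    return float(2.0**logf)


def log_cpm(counts: pd.DataFrame, factors: pd.Series | None = None) -> pd.DataFrame:
    """log2(CPM + 1) on TMM-adjusted effective library sizes."""
    X = counts.to_numpy(dtype=float)
    lib = X.sum(axis=0)
    if factors is None:
        eff = lib
    else:
        f = factors.reindex(counts.columns).to_numpy(dtype=float)
        if np.any(f <= 0):
            raise ValueError("normalization factors must be positive")
        eff = lib * f
    cpm = X / eff[None, :] * 1e6
    return pd.DataFrame(np.log2(cpm + 1.0), index=counts.index, columns=counts.columns)


def cofactor_pca(
    normalized: pd.DataFrame,
    design: pd.DataFrame,
    n_pcs: int = 10,
    alpha: float = 0.01,
    covariates: list[str] | None = None,
) -> pd.DataFrame:
    """Associate design covariates with expression principal components.

    PCA is run on samples (genes as features, centred).  For each covariate
    and PC the association is an ANOVA F test for categorical covariates and a
    Pearson correlation test for continuous ones.  A covariate is flagged when
    any PC association is significant at ``alpha`` after Bonferroni correction
    over the PCs tested.  Constant covariates are reported untestable.
    """
    if normalized.shape[1] < 2:
        raise ValueError("need at least 2 samples")
    if covariates is None:
        covariates = [c for c in design.columns if c not in ("sample", "genotype")]
    X = normalized.to_numpy(dtype=float).T          # samples x genes
    X = X - X.mean(axis=0)
    U, s, _ = np.linalg.svd(X, full_matrices=False)
    keep = s > 1e-10 * (s[0] if s.size else 1.0)    # drop zero-variance PCs
    scores = (U[:, keep] * s[keep])[:, :n_pcs]
    n_used = scores.shape[1]

    meta = design.set_index("sample").reindex(normalized.columns)
    rows = []
    for cov in covariates:
        values = meta[cov]
        categorical = not pd.api.types.is_numeric_dtype(values) or values.nunique() <= 6
        if values.nunique() <= 1:
            rows.append({"covariate": cov, "pc": None, "stat": np.nan,
                         "pvalue": np.nan, "flagged": False, "untestable": True})
            continue
        for k in range(n_used):
            pc = scores[:, k]
            if categorical:
                groups = [pc[values.to_numpy() == lvl] for lvl in values.unique()]
                groups = [g for g in groups if len(g) > 0]
                stat, p = stats.f_oneway(*groups)
            else:
                stat, p = stats.pearsonr(values.to_numpy(dtype=float), pc)
            rows.append({"covariate": cov, "pc": k + 1, "stat": float(stat),
                         "pvalue": float(p), "flagged": bool(p < alpha / n_used),
                         "untestable": False})
    return pd.DataFrame(rows)


def flagged_covariates(report: pd.DataFrame) -> list[str]:
    """Covariates flagged on at least one PC."""
    flagged = report.loc[report["flagged"], "covariate"].unique()
    return list(flagged)
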