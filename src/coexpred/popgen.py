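"""SNP-based per-gene statistics: gene diversity Ht, Nei's F_ST and a
PCA-outlier (genome-scan) score.

All three operate on a genotype x SNP dosage panel in {0, 1, 2} with a SNP ->
gene assignment and population labels.  Ht is unbiased expected
heterozygosity averaged over a gene's SNPs; F_ST is the heterozygosity-based
Nei estimator (Ht - Hs) / Ht; the outlier score regresses each SNP on the
leading principal components of the panel and converts the z-statistics into
a robust Mahalanobis distance rescaled by a genomic inflation factor so the
null median matches the chi-square(K) median.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.covariance import MinCovDet

__all__ = [
    "SNPPanel",
    "gene_diversity",
    "fst",
    "pca_outlier_score",
    "read_vcf_dosages",
]


@dataclass
class SNPPanel:
    dosages: pd.DataFrame          # genotype x SNP, values in {0,1,2}
    snp_genes: pd.Series           # SNP id -> gene id
    populations: pd.Series         # genotype -> population label

    def __post_init__(self) -> None:
        D = self.dosages.to_numpy()
        if D.size and (D.min() < 0 or D.max() > 2):
            raise ValueError("dosages must lie in {0, 1, 2}")
        self.populations = self.populations.reindex(self.dosages.index)
        if self.populations.isna().any():
            raise ValueError("population labels missing for some genotypes")


def _expected_het(dosages: np.ndarray) -> np.ndarray:
    """Unbiased per-SNP expected heterozygosity 2p(1-p) * 2n/(2n-1)."""
    n = dosages.shape[0]
    p = dosages.mean(axis=0) / 2.0
    correction = (2 * n) / (2 * n - 1)
    return 2.0 * p * (1.0 - p) * correction


def gene_diversity(panel: SNPPanel) -> tuple[pd.Series, pd.Series]:
    """Per-SNP and per-gene (mean over SNPs) overall gene diversity Ht."""
    if panel.dosages.shape[0] < 2:
        raise ValueError("need at least 2 genotypes")
    ht = pd.Series(
        _expected_het(panel.dosages.to_numpy(dtype=float)),
        index=panel.dosages.columns, name="Ht",
    )
    per_gene = ht.groupby(panel.snp_genes).mean().rename("Ht")
    return ht, per_gene


def fst(panel: SNPPanel) -> tuple[pd.DataFrame, dict]:
    """Nei's F_ST = (Ht - Hs) / Ht per SNP, plus a distribution summary.

    Hs is the mean within-population expected heterozygosity (each population
    with its own small-sample correction).  Monomorphic SNPs (Ht = 0) are
    skipped.  The summary reports the multilocus mean (sum(Ht - Hs) / sum(Ht))
    and the 99th percentile of per-SNP values.
    """
    pops = panel.populations
    if pops.nunique() < 2:
        raise ValueError("need at least 2 populations")
    D = panel.dosages.to_numpy(dtype=float)
    ht = _expected_het(D)
    hs = np.zeros_like(ht)
    labels = pops.to_numpy()
    weights = 0.0
    for p in np.unique(labels):
        members = labels == p
        frac = members.mean()
        hs += frac * _expected_het(D[members])
        weights += frac
    hs /= weights
    ok = ht > 0
    per_snp = pd.DataFrame(
        {
            "Ht": ht,
            "Hs": hs,
            "fst": np.where(ok, (ht - hs) / np.where(ok, ht, 1.0), np.nan),
        },
        index=panel.dosages.columns,
    )
    vals = per_snp.loc[ok, "fst"].to_numpy()
    summary = {
        "mean_fst": float(np.sum(ht[ok] - hs[ok]) / np.sum(ht[ok])),
        "median_fst": float(np.median(vals)) if vals.size else float("nan"),
        "p99_fst": float(np.percentile(vals, 99)) if vals.size else float("nan"),
        "n_snps_used": int(ok.sum()),
    }
    return per_snp, summary


def pca_outlier_score(
    panel: SNPPanel,
    K: int = 8,
    seed: int = 0,
) -> tuple[pd.Series, pd.Series]:
    """Per-SNP genome-scan outlier score and per-gene mean.

    PCA on centred/scaled dosages; each SNP is regressed on the K principal
    component score vectors; the score is the Mahalanobis distance of the
    z-statistic vector under a robust (minimum covariance determinant)
    covariance, rescaled by a genomic inflation factor so the null median
    matches the chi-square(K) median.  Constant SNPs get a missing score.
    """
    D = panel.dosages.to_numpy(dtype=float)
    n, p = D.shape
    if n <= K:
        raise ValueError("need more genotypes than retained components")
    sd = D.std(axis=0)
    ok = sd > 0
    Xs = (D[:, ok] - D[:, ok].mean(axis=0)) / sd[ok]
    U, s, _ = np.linalg.svd(Xs, full_matrices=False)
    scores = U[:, :K]                                  # orthonormal PC basis

    # OLS of each SNP on the K PCs; orthonormal basis makes this a projection
    Y = D[:, ok] - D[:, ok].mean(axis=0)
    beta = scores.T @ Y                                # K x p_ok
    resid = Y - scores @ beta
    dof = max(n - K - 1, 1)
    sigma2 = (resid**2).sum(axis=0) / dof
    sigma2[sigma2 < 1e-12] = np.nan
    z = beta / np.sqrt(sigma2)[None, :]                # K x p_ok

    zt = z.T
    finite = np.all(np.isfinite(zt), axis=1)
    mcd = MinCovDet(random_state=seed).fit(zt[finite])
    d2 = np.full(zt.shape[0], np.nan)
    d2[finite] = mcd.mahalanobis(zt[finite])
    gif = np.nanmedian(d2) / stats.chi2.median(df=K)
    if gif > 0:
        d2 = d2 / gif

    per_snp = pd.Series(np.nan, index=panel.dosages.columns, name="pca_outlier")
    per_snp.iloc[np.where(ok)[0]] = d2
    per_gene = per_snp.groupby(panel.snp_genes).mean().rename("pca_outlier")
    return per_snp, per_gene


def read_vcf_dosages(path: str) -> pd.DataFrame:
    """Read a (plain or bgzipped) VCF into a genotype x SNP dosage matrix."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    ids, rows = [], []
    for i, variant in enumerate(vcf):
        gt = variant.gt_types  # 0=hom ref, 1=het, 3=hom alt, 2=unknown
        dos = np.where(gt == 3, 2, gt)
        dos = np.where(gt == 2, 0, dos)
        ids.append(variant.ID or f"snp{i:05d}")
        rows.append(dos)
    return pd.DataFrame(np.array(rows).T, index=samples, columns=ids)
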