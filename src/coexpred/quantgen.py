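"""Kinship-split mixed model: per-response REML, BLUPs, h2, Q_ST and CV_g.

The model for a response y over samples (clonal replicates of genotypes) is

    y = X beta + Z b + Z w + e,
    b ~ N(0, sigma_b2 K_b),  w ~ N(0, sigma_w2 K_w),  e ~ N(0, sigma_e2 I),

where Z maps samples to genotypes and the genomic relationship matrix K is
split into a between-population part K_b (block-wise mean kinship) and a
within-population part K_w (kinship kept only inside populations, zero
elsewhere).  Broad-sense heritability and the quantitative differentiation
coefficient follow as

    h2   = (sigma_b2 + sigma_w2) / (sigma_b2 + sigma_w2 + sigma_e2)
    Q_ST = sigma_b2 / (sigma_b2 + 2 sigma_w2)

and CV_g divides the total genetic variance by the response mean.

REML uses expectation-maximization-style fixed-point warm-up followed by
average-information Newton steps with projection to the non-negative
boundary; non-convergence is flagged, never silent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "KinshipPair",
    "VarianceComponents",
    "split_kinship",
    "build_design_matrices",
    "fit_reml",
    "heritability",
    "qst",
    "cv_g",
    "fit_genes",
]

RIDGE = 1e-6            # stabilization added to both kinship parts
MIN_VAR = 1e-8          # non-negativity floor for variance components


@dataclass
class KinshipPair:
    K_b: pd.DataFrame
    K_w: pd.DataFrame
    populations: pd.Series


@dataclass
class VarianceComponents:
    sigma_b2: float
    sigma_w2: float
    sigma_e2: float
    loglik: float
    converged: bool
    n_iter: int


def split_kinship(K: pd.DataFrame, populations: pd.Series, ridge: float = RIDGE) -> KinshipPair:
    """Split a relationship matrix into between- and within-population parts.

    K_b[i, j] is the mean kinship over all genotype pairs from (pop(i),
    pop(j)); within a population the off-diagonal block value is the mean over
    off-diagonal pairs and the diagonal is the population's mean self-kinship.
    K_w keeps K inside populations and is zero across populations.
    """
    A = K.to_numpy(dtype=float)
    if not np.allclose(A, A.T, atol=1e-8):
        raise ValueError("relationship matrix must be symmetric")
    genotypes = K.index
    pops = populations.reindex(genotypes)
    if pops.isna().any():
        raise ValueError("population labels must cover all genotypes")
    labels = pops.to_numpy()
    unique = np.unique(labels)
    n = len(genotypes)

    Kb = np.zeros((n, n))
    for p in unique:
        ip = np.where(labels == p)[0]
        for q in unique:
            iq = np.where(labels == q)[0]
            block = A[np.ix_(ip, iq)]
            if p == q:
                off = block[~np.eye(len(ip), dtype=bool)]
                mean_off = off.mean() if off.size else block.mean()
                Kb[np.ix_(ip, iq)] = mean_off
                Kb[ip, ip] = block.diagonal().mean()
            else:
                Kb[np.ix_(ip, iq)] = block.mean()

    same = labels[:, None] == labels[None, :]
    Kw = np.where(same, A, 0.0)

    eye = np.eye(n)
    return KinshipPair(
        K_b=pd.DataFrame(Kb + ridge * eye, index=genotypes, columns=genotypes),
        K_w=pd.DataFrame(Kw + ridge * eye, index=genotypes, columns=genotypes),
        populations=pops,
    )


def build_design_matrices(
    design: pd.DataFrame,
    genotypes: pd.Index,
    covariates: list[str] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Fixed-effect matrix X (intercept + covariates) and incidence Z.

    Categorical covariates (block) enter as treatment-coded dummies, numeric
    ones (date, hour) as centred continuous columns.  Aliased columns are
    dropped to keep X full-rank.
    """
    n = len(design)
    cols = [np.ones(n)]
    for cov in covariates or []:
        values = design[cov]
        if pd.api.types.is_numeric_dtype(values) and values.nunique() > 6:
            v = values.to_numpy(dtype=float)
            cols.append(v - v.mean())
        else:
            dummies = pd.get_dummies(values.astype("category"), drop_first=True)
            for c in dummies.columns:
                cols.append(dummies[c].to_numpy(dtype=float))
    X = np.column_stack(cols)
    # drop aliased columns
    q, r = np.linalg.qr(X)
    keep = np.abs(np.diag(r)) > 1e-8
    X = X[:, keep]

    idx = genotypes.get_indexer(design["genotype"])
    if np.any(idx < 0):
        raise ValueError("design contains genotypes absent from the kinship matrix")
    Z = np.zeros((n, len(genotypes)))
    Z[np.arange(n), idx] = 1.0
    return X, Z


def _reml_loglik(theta: np.ndarray, y: np.ndarray, X: np.ndarray,
                 Gs: list[np.ndarray]) -> tuple[float, np.ndarray, np.ndarray]:
    """Restricted log-likelihood, P y and P, for components theta."""
    from scipy.linalg import cho_factor, cho_solve

    n = len(y)
    V = theta[-1] * np.eye(n)
    for t, G in zip(theta[:-1], Gs):
        V = V + t * G
    c, low = cho_factor(V, lower=True, check_finite=False)
    logdetV = 2.0 * np.sum(np.log(np.diag(c)))
    Vi = cho_solve((c, low), np.eye(n), check_finite=False)
    ViX = Vi @ X
    XtViX = X.T @ ViX
    _, logdetX = np.linalg.slogdet(XtViX)
    P = Vi - ViX @ np.linalg.solve(XtViX, ViX.T)
    Py = P @ y
    ll = -0.5 * (logdetV + logdetX + float(y @ Py))
    return ll, Py, P


def fit_reml(
    y: np.ndarray | pd.Series,
    X: np.ndarray,
    Z: np.ndarray,
    kinship: KinshipPair,
    max_iter: int = 60,
    tol: float = 1e-6,
    em_iter: int = 8,
    _cache: dict | None = None,
) -> tuple[VarianceComponents, pd.DataFrame]:
    """AI-REML with EM-style warm start for the two-kinship model.

    Returns variance components and a genotype-level BLUP table with columns
    ``b`` (between-population effect), ``w`` (within) and ``total`` = b + w.
    Non-convergence is flagged on the result with the best estimates found.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    if Z.shape[1] < 2:
        raise ValueError("need at least 2 genotypes")

    if _cache is not None and "Gs" in _cache:
        Gs = _cache["Gs"]
    else:
        Kb = kinship.K_b.to_numpy()
        Kw = kinship.K_w.to_numpy()
        Gs = [Z @ Kb @ Z.T, Z @ Kw @ Z.T]
        if _cache is not None:
            _cache["Gs"] = Gs

    vy = float(np.var(y))
    if vy < 1e-12:
        vc = VarianceComponents(0.0, 0.0, MIN_VAR, np.nan, True, 0)
        blups = pd.DataFrame(
            0.0, index=kinship.K_b.index, columns=["b", "w", "total"]
        )
        return vc, blups

    theta = np.array([vy / 4, vy / 4, vy / 2])
    ll, Py, P = _reml_loglik(theta, y, X, Gs)

    terms = Gs + [np.eye(n)]
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        if it <= em_iter:
            # fixed-point (EM-flavoured) update: multiplicative, keeps positivity
            new = theta.copy()
            for k, G in enumerate(terms):
                num = float(Py @ G @ Py)
                den = float(np.einsum("ij,ji->", P, G))
                if den > 0 and num > 0:
                    new[k] = theta[k] * num / den
            new = np.clip(new, MIN_VAR, None)
        else:
            # average-information Newton step with projection and step-halving
            grad = np.empty(3)
            AI = np.empty((3, 3))
            PGy = [G @ Py for G in terms]
            PPGy = [P @ g for g in PGy]
            for k in range(3):
                grad[k] = -0.5 * (float(np.einsum("ij,ji->", P, terms[k])) - float(Py @ PGy[k]))
                for l in range(k, 3):
                    AI[k, l] = AI[l, k] = 0.5 * float(PGy[k] @ PPGy[l])
            try:
                step = np.linalg.solve(AI + 1e-10 * np.eye(3), grad)
            except np.linalg.LinAlgError:
                step = grad / max(np.abs(grad).max(), 1.0)
            new = None
            for damp in (1.0, 0.5, 0.25, 0.1):
                cand = np.clip(theta + damp * step, MIN_VAR, None)
                try:
                    cll, cPy, cP = _reml_loglik(cand, y, X, Gs)
                except np.linalg.LinAlgError:
                    continue
                if cll >= ll - 1e-10:
                    new, ll, Py, P = cand, cll, cPy, cP
                    break
            if new is None:
                # projected-gradient fallback on the boundary
                cand = np.clip(theta + 1e-3 * vy * np.sign(grad), MIN_VAR, None)
                try:
                    cll, cPy, cP = _reml_loglik(cand, y, X, Gs)
                    if cll >= ll:
                        new, ll, Py, P = cand, cll, cPy, cP
                except np.linalg.LinAlgError:
                    pass
            if new is None:
                converged = True  # no improving direction: at a (boundary) optimum
                break
        delta = np.max(np.abs(new - theta)) / max(vy, 1e-12)
        theta = new
        if it <= em_iter or delta > tol:
            if it <= em_iter:
                ll, Py, P = _reml_loglik(theta, y, X, Gs)
            continue
        converged = True
        break
    else:
        converged = False
    if it <= em_iter:
        ll, Py, P = _reml_loglik(theta, y, X, Gs)
        converged = True

    Kb = kinship.K_b.to_numpy()
    Kw = kinship.K_w.to_numpy()
    ZtPy = Z.T @ Py
    b_hat = theta[0] * (Kb @ ZtPy)
    w_hat = theta[1] * (Kw @ ZtPy)
    blups = pd.DataFrame(
        {"b": b_hat, "w": w_hat, "total": b_hat + w_hat}, index=kinship.K_b.index
    )
    vc = VarianceComponents(
        sigma_b2=float(theta[0]) if theta[0] > MIN_VAR else 0.0,
        sigma_w2=float(theta[1]) if theta[1] > MIN_VAR else 0.0,
        sigma_e2=float(theta[2]),
        loglik=float(ll),
        converged=bool(converged),
        n_iter=it,
    )
    return vc, blups


def heritability(vc: VarianceComponents) -> float:
    """h2 = (sigma_b2 + sigma_w2) / (sigma_b2 + sigma_w2 + sigma_e2)."""
    total = vc.sigma_b2 + vc.sigma_w2 + vc.sigma_e2
    if total <= 0:
        return float("nan")
    return (vc.sigma_b2 + vc.sigma_w2) / total


def qst(vc: VarianceComponents) -> float:
    """Q_ST = sigma_b2 / (sigma_b2 + 2 sigma_w2)."""
    den = vc.sigma_b2 + 2.0 * vc.sigma_w2
    if den <= 0:
        return float("nan")
    return vc.sigma_b2 / den


def cv_g(vc: VarianceComponents, mean_expression: float, sd_based: bool = False) -> float:
    """Total genetic variance over the mean (``sd_based`` uses the SD instead)."""
    if mean_expression <= 0:
        return float("nan")
    genetic = vc.sigma_b2 + vc.sigma_w2
    if sd_based:
        genetic = float(np.sqrt(genetic))
    return genetic / mean_expression


def fit_genes(
    normalized: pd.DataFrame,
    design: pd.DataFrame,
    kinship_pair: KinshipPair,
    covariates: list[str] | None = None,
    genes: list[str] | None = None,
    mean_expression: pd.Series | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-gene REML over a normalized matrix.

    Returns (summary, blups): summary has one row per gene with the variance
    components, h2, Q_ST, CV_g and mean expression; blups is genotype x gene
    total genetic values.  Rows of ``normalized`` must be genes and columns
    must match ``design['sample']``.
    """
    normalized = normalized[design["sample"]]
    genotypes = kinship_pair.K_b.index
    X, Z = build_design_matrices(design, genotypes, covariates)
    cache: dict = {}
    if genes is None:
        genes = list(normalized.index)
    rows = []
    blup_cols = {}
    for gene in genes:
        y = normalized.loc[gene].to_numpy(dtype=float)
        vc, blups = fit_reml(y, X, Z, kinship_pair, _cache=cache)
        mean_expr = (
            float(mean_expression[gene]) if mean_expression is not None else float(y.mean())
        )
        rows.append(
            {
                "gene": gene,
                "sigma_b2": vc.sigma_b2,
                "sigma_w2": vc.sigma_w2,
                "sigma_e2": vc.sigma_e2,
                "h2": heritability(vc),
                "qst": qst(vc),
                "cv_g": cv_g(vc, mean_expr),
                "mean_expression": mean_expr,
                "converged": vc.converged,
            }
        )
        blup_cols[gene] = blups["total"]
    summary = pd.DataFrame(rows).set_index("gene")
    blup_matrix = pd.DataFrame(blup_cols, index=genotypes)
    return summary, blup_matrix
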