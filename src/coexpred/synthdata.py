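"""Synthetic population-transcriptomics data with planted ground truth.

Emulates a common-garden RNA-seq study on a structured plant collection:
~11 natural populations, ~241 genotypes with up to two clonal replicates,
negative-binomial read counts with library-size variation, modular
co-expression structure with an unstructured ("grey") fraction, per-gene
between/within-population genetic variance, Balding-Nichols SNP panels and
traits built from additive plus pairwise-interaction gene effects.

Every generator is deterministic under a fixed seed and returns plain
pandas/numpy containers so downstream stages can be tested without any
external download.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "TruthRecord",
    "SyntheticBundle",
    "generate_structure",
    "generate_snps",
    "generate_expression",
    "generate_traits",
    "generate_bundle",
]

# Default study dimensions: 11 populations, 241 genotypes of which 218 carry
# two clonal replicates and 23 a single one, i.e. 459 samples.
DEFAULT_N_POPS = 11
DEFAULT_N_GENOTYPES = 241
DEFAULT_DUPLICATED_FRACTION = 218 / 241


@dataclass
class TruthRecord:
    """Planted ground truth for one synthetic bundle.

    Variances are on the latent log2-expression scale.  ``module`` uses 0 for
    the unstructured (grey) fraction.  ``sigma_w2_total`` includes the
    module-factor contribution ``loading**2`` because the factor is drawn per
    genotype and is therefore part of the heritable within-population signal.
    """

    sigma_b2: np.ndarray            # per-gene between-population variance
    sigma_w2: np.ndarray            # per-gene within-population (kinship) variance
    sigma_e2: np.ndarray            # per-gene residual variance
    module: np.ndarray              # per-gene module id, 0 = grey
    loading: np.ndarray             # per-gene loading on its module factor
    trait_effects: dict = field(default_factory=dict)
    # trait -> {"additive": {gene: coef}, "pairs": [((g1, g2), coef)],
    #           "signal_fraction": float}
    divergence: float = 0.1         # Balding-Nichols F_ST-like parameter
    library_multipliers: np.ndarray | None = None
    dispersion: np.ndarray | None = None      # per-gene NB dispersion
    base_mean: np.ndarray | None = None       # per-gene mean count at lib=1

    def __post_init__(self) -> None:
        for name in ("sigma_b2", "sigma_w2", "sigma_e2"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if np.any(arr < 0):
                raise ValueError(f"{name} must be non-negative")
            setattr(self, name, arr)
        if not np.all(np.isfinite(np.asarray(self.loading, dtype=float))):
            raise ValueError("loadings must be finite")
        if not (0.0 <= self.divergence < 1.0):
            raise ValueError("divergence must lie in [0, 1)")

    @property
    def sigma_w2_total(self) -> np.ndarray:
        return self.sigma_w2 + np.asarray(self.loading, dtype=float) ** 2

    @property
    def h2(self) -> np.ndarray:
        num = self.sigma_b2 + self.sigma_w2_total
        return num / (num + self.sigma_e2)

    @property
    def qst(self) -> np.ndarray:
        return self.sigma_b2 / (self.sigma_b2 + 2.0 * self.sigma_w2_total)

    def to_json(self, path: str | Path) -> None:
        payload = {}
        for key, value in asdict(self).items():
            if isinstance(value, np.ndarray):
                payload[key] = value.tolist()
            else:
                payload[key] = value
        Path(path).write_text(json.dumps(payload, default=_jsonable))


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    raise TypeError(f"not JSON serializable: {type(obj)}")


@dataclass
class SyntheticBundle:
    """All pipeline inputs for one simulated study, plus the planted truth."""

    counts: pd.DataFrame            # gene x sample integer counts
    design: pd.DataFrame            # sample, genotype, population, block, date, hour
    kinship: pd.DataFrame           # genotype x genotype relationship matrix
    dosages: pd.DataFrame           # genotype x SNP in {0,1,2}
    snp_genes: pd.Series            # SNP id -> gene id
    traits: pd.DataFrame            # genotype x trait
    truth: TruthRecord
    latent: pd.DataFrame | None = None       # gene x sample latent log2 values
    genetic_values: pd.DataFrame | None = None  # genotype x gene true genetic value

    def validate(self) -> None:
        counts = self.counts.to_numpy()
        if np.any(counts < 0) or not np.issubdtype(counts.dtype, np.integer):
            raise ValueError("counts must be non-negative integers")
        if not set(self.design["sample"]) == set(self.counts.columns):
            raise ValueError("design samples and count columns disagree")
        dos = self.dosages.to_numpy()
        if dos.size and (dos.min() < 0 or dos.max() > 2):
            raise ValueError("dosages must lie in {0,1,2}")

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.counts.to_csv(outdir / "counts.tsv", sep="\t")
        self.design.to_csv(outdir / "design.csv", index=False)
        self.kinship.to_csv(outdir / "kinship.tsv", sep="\t")
        self.dosages.to_csv(outdir / "dosages.tsv", sep="\t")
        self.snp_genes.rename("gene").to_csv(outdir / "snp_genes.tsv", sep="\t")
        self.traits.to_csv(outdir / "traits.csv")
        self.truth.to_json(outdir / "truth.json")


# ---------------------------------------------------------------------------
# population / sample structure
# ---------------------------------------------------------------------------

def _split_counts(total: int, n_groups: int) -> list[int]:
    base, extra = divmod(total, n_groups)
    return [base + (1 if i < extra else 0) for i in range(n_groups)]


def generate_structure(
    n_pops: int = DEFAULT_N_POPS,
    genotypes_per_pop: int | list[int] = DEFAULT_N_GENOTYPES,
    duplicated_fraction: float = DEFAULT_DUPLICATED_FRACTION,
    seed: int = 0,
    divergence: float = 0.1,
    n_kinship_snps: int = 2000,
    family_size: int = 6,
    family_divergence: float = 0.35,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Sample design table and genomic relationship matrix.

    ``genotypes_per_pop`` may be a total (split as evenly as possible across
    populations) or an explicit per-population list.  A ``duplicated_fraction``
    of genotypes receives two clonal replicates in different blocks; the rest
    are singletons.  The relationship matrix is a VanRaden cross-product of a
    Balding-Nichols SNP panel simulated at the requested divergence, so mean
    kinship is higher within than between populations.

    Each population is subdivided into sib-like families of ``family_size``
    genotypes sharing a second level of allele-frequency drift
    (``family_divergence``).  Without such relatedness every pair inside a
    population is exchangeable, the within- and between-population kinship
    parts span the same covariance space and the variance-component split is
    unidentifiable; natural panels are never exchangeable in this way.
    """
    if n_pops < 2:
        raise ValueError("need at least 2 populations")
    if isinstance(genotypes_per_pop, int):
        if genotypes_per_pop < n_pops:
            raise ValueError("need at least one genotype per population")
        sizes = _split_counts(genotypes_per_pop, n_pops)
    else:
        sizes = list(genotypes_per_pop)
        if len(sizes) != n_pops or any(s < 1 for s in sizes):
            raise ValueError("genotypes_per_pop must give a positive size per population")
    rng = np.random.default_rng(seed)

    genotypes, populations, families = [], [], []
    g = 0
    for p, size in enumerate(sizes):
        for k in range(size):
            genotypes.append(f"G{g:04d}")
            populations.append(f"P{p:02d}")
            families.append(f"P{p:02d}F{k // max(family_size, 1):02d}")
            g += 1
    n_geno = len(genotypes)

    n_dup = int(round(duplicated_fraction * n_geno))
    dup_idx = set(rng.choice(n_geno, size=n_dup, replace=False).tolist())

    rows = []
    s = 0
    for i, (geno, pop) in enumerate(zip(genotypes, populations)):
        n_rep = 2 if i in dup_idx else 1
        blocks = [1, 2] if n_rep == 2 else [int(rng.integers(1, 3))]
        for b in blocks:
            rows.append(
                {
                    "sample": f"S{s:04d}",
                    "genotype": geno,
                    "population": pop,
                    "block": int(b),
                    "date": int(rng.integers(0, 14)),      # day within a 2-week window
                    "hour": int(rng.integers(8, 18)),      # sampling hour of day
                }
            )
            s += 1
    design = pd.DataFrame(rows)

    pop_labels = pd.Series(populations, index=genotypes, name="population")
    fam_labels = pd.Series(families, index=genotypes, name="family")
    dosages = _balding_nichols_dosages(
        pop_labels, n_snps=n_kinship_snps, divergence=divergence, rng=rng,
        families=fam_labels, family_divergence=family_divergence,
    )
    K = _vanraden(dosages.to_numpy(dtype=float))
    kinship = pd.DataFrame(K, index=genotypes, columns=genotypes)
    return design, kinship


def _beta_around(freq: np.ndarray, divergence: float, rng: np.random.Generator) -> np.ndarray:
    c = (1.0 - divergence) / divergence
    a = np.clip(freq * c, 1e-6, None)
    b = np.clip((1.0 - freq) * c, 1e-6, None)
    return np.clip(rng.beta(a, b), 0.0, 1.0)


def _balding_nichols_dosages(
    populations: pd.Series, n_snps: int, divergence: float, rng: np.random.Generator,
    ancestral: np.ndarray | None = None,
    families: pd.Series | None = None,
    family_divergence: float = 0.0,
) -> pd.DataFrame:
    """Balding-Nichols dosage panel: per-population allele frequencies are Beta
    draws around a common ancestral frequency with variance set by the
    divergence parameter; dosages are Binomial(2, p_pop).

    When ``families`` labels are given, a second Beta level draws per-family
    frequencies around the population frequency (``family_divergence``),
    producing sib-like relatedness within populations.
    """
    if not (0.0 <= divergence < 1.0):
        raise ValueError("divergence must lie in [0, 1)")
    pops = populations.unique()
    if ancestral is None:
        ancestral = rng.uniform(0.1, 0.9, size=n_snps)
    else:
        ancestral = np.asarray(ancestral, dtype=float)
        if ancestral.shape != (n_snps,):
            raise ValueError("ancestral frequencies must have length n_snps")
    if divergence == 0.0:
        pop_freqs = {p: ancestral for p in pops}
    else:
        pop_freqs = {p: _beta_around(ancestral, divergence, rng) for p in pops}

    if families is not None and family_divergence > 0.0:
        group_freqs = {}
        for fam in families.unique():
            pop = populations[families == fam].iloc[0]
            group_freqs[fam] = _beta_around(pop_freqs[pop], family_divergence, rng)
        group_of = families
    else:
        group_freqs = pop_freqs
        group_of = populations

    n = len(populations)
    dosages = np.empty((n, n_snps), dtype=np.int64)
    for i, grp in enumerate(group_of):
        dosages[i] = rng.binomial(2, group_freqs[grp])
    cols = [f"snp{j:05d}" for j in range(n_snps)]
    return pd.DataFrame(dosages, index=populations.index, columns=cols)


def _vanraden(dosages: np.ndarray) -> np.ndarray:
    """VanRaden genomic relationship matrix from a dosage matrix."""
    p = dosages.mean(axis=0) / 2.0
    keep = (p > 0) & (p < 1)
    M = dosages[:, keep] - 2.0 * p[keep]
    denom = 2.0 * np.sum(p[keep] * (1.0 - p[keep]))
    return (M @ M.T) / denom


# ---------------------------------------------------------------------------
# SNP panel for population-genetic statistics
# ---------------------------------------------------------------------------

def generate_snps(
    design: pd.DataFrame,
    n_snps: int = 2000,
    divergence: float = 0.1,
    gene_ids: list[str] | None = None,
    snps_per_gene: int = 4,
    seed: int = 0,
    ancestral: np.ndarray | None = None,
) -> tuple[pd.DataFrame, pd.Series]:
    """Genotype x SNP dosage panel plus a SNP -> gene assignment.

    SNPs are grouped into consecutive runs of ``snps_per_gene`` mapped to the
    supplied gene ids (cycled if there are more runs than genes).
    """
    geno = design.drop_duplicates("genotype")
    populations = pd.Series(
        geno["population"].to_numpy(), index=geno["genotype"].to_numpy()
    )
    rng = np.random.default_rng(seed)
    dosages = _balding_nichols_dosages(
        populations, n_snps=n_snps, divergence=divergence, rng=rng,
        ancestral=ancestral,
    )
    if gene_ids is None:
        gene_ids = [f"gene{i:05d}" for i in range(max(1, n_snps // snps_per_gene))]
    assignment = pd.Series(
        [gene_ids[(j // snps_per_gene) % len(gene_ids)] for j in range(n_snps)],
        index=dosages.columns,
        name="gene",
    )
    return dosages, assignment


def write_minimal_vcf(dosages: pd.DataFrame, path: str | Path) -> None:
    """Write dosages as a minimal unphased GT-only VCF (one biallelic SNP per row)."""
    gt = {0: "0/0", 1: "0/1", 2: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##contig=<ID=1>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(dosages.index) + "\n")
        for j, snp in enumerate(dosages.columns):
            calls = "\t".join(gt[int(d)] for d in dosages[snp])
            fh.write(f"1\t{j + 1}\t{snp}\tA\tC\t.\tPASS\t.\tGT\t{calls}\n")


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------

def make_truth(
    n_genes: int,
    n_modules: int = 4,
    grey_fraction: float = 0.4,
    sigma_b2: float | np.ndarray = 0.3,
    sigma_w2: float | np.ndarray = 0.5,
    sigma_e2: float | np.ndarray = 0.5,
    hub_loading: float = 1.0,
    divergence: float = 0.1,
    seed: int = 0,
) -> TruthRecord:
    """Planted per-gene truth: module labels with a grey fraction, loadings
    decreasing linearly from hub (``hub_loading``) to peripheral (0.3x) within
    each module, and per-gene variance components (scalars are jittered with a
    lognormal factor so genes are not identical)."""
    if not (0.0 <= grey_fraction <= 1.0):
        raise ValueError("grey_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)

    def spread(x):
        x = np.asarray(x, dtype=float)
        if x.ndim == 0:
            return x * rng.lognormal(0.0, 0.3, size=n_genes)
        return x

    n_grey = int(round(grey_fraction * n_genes))
    n_mod_genes = n_genes - n_grey
    module = np.zeros(n_genes, dtype=int)
    loading = np.zeros(n_genes)
    if n_modules > 0 and n_mod_genes > 0:
        sizes = _split_counts(n_mod_genes, n_modules)
        pos = 0
        for m, size in enumerate(sizes, start=1):
            module[pos : pos + size] = m
            # hub -> peripheral gradient within the module
            loading[pos : pos + size] = np.linspace(hub_loading, 0.3 * hub_loading, size)
            pos += size
    return TruthRecord(
        sigma_b2=spread(sigma_b2),
        sigma_w2=spread(sigma_w2),
        sigma_e2=spread(sigma_e2),
        module=module,
        loading=loading,
        divergence=divergence,
    )


def generate_expression(
    design: pd.DataFrame,
    kinship: pd.DataFrame,
    truth: TruthRecord,
    seed: int = 0,
    base_mean_log_mu: float = 4.5,
    base_mean_log_sd: float = 1.0,
    dispersion_log_mu: float = -3.0,
    dispersion_log_sd: float = 0.5,
    library_sd: float = 0.25,
    block_sd: float = 0.0,
    date_coef: float = 0.0,
    hour_coef: float = 0.0,
    return_latent: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame | None, pd.DataFrame]:
    """Negative-binomial count matrix with planted genetic and modular signal.

    The latent log2 value of gene g in sample s of genotype i is

        z[g, s] = b[g, i] + w[g, i] + loading[g] * F[module(g), i]
                  + cofactor shifts (block/date/hour) + e[g, s]

    with b ~ MVN(0, sigma_b2 K_b), w ~ MVN(0, sigma_w2 K_w) over genotypes and
    F a per-genotype standard-normal module factor.  Counts are
    NB(mean = lib[s] * base_mean[g] * 2**z, dispersion[g]).

    Returns (counts, latent or None, genetic_values) where genetic_values is
    the genotype x gene matrix of true total genetic values b + w + loading*F.
    """
    n_genes = len(truth.sigma_b2)
    genotypes = kinship.index.to_list()
    if not set(design["genotype"]).issubset(genotypes):
        raise ValueError("design genotypes missing from kinship matrix")
    n_geno = len(genotypes)
    n_samples = len(design)
    rng = np.random.default_rng(seed)

    from .quantgen import split_kinship  # kinship split shared with the estimator

    pops = pd.Series(
        design.drop_duplicates("genotype").set_index("genotype")["population"]
    ).reindex(genotypes)
    pair = split_kinship(kinship, pops)
    Lb = _safe_cholesky(pair.K_b.to_numpy())
    Lw = _safe_cholesky(pair.K_w.to_numpy())

    # genotype-level effects, one column per gene
    b = Lb @ rng.standard_normal((n_geno, n_genes)) * np.sqrt(truth.sigma_b2)
    w = Lw @ rng.standard_normal((n_geno, n_genes)) * np.sqrt(truth.sigma_w2)
    # module factors are heritable genotype-level variables with the same
    # within-population covariance as w, so loading**2 adds to sigma_w2 in
    # K_w units and the planted h2/Q_ST stay consistent with the estimator
    n_modules = int(truth.module.max()) if truth.module.size else 0
    F = Lw @ rng.standard_normal((n_geno, max(n_modules, 1)))
    factor_part = np.zeros((n_geno, n_genes))
    for g in range(n_genes):
        m = truth.module[g]
        if m > 0:
            factor_part[:, g] = truth.loading[g] * F[:, m - 1]
    genetic = b + w + factor_part                      # genotype x gene

    geno_idx = pd.Index(genotypes).get_indexer(design["genotype"])
    latent = genetic[geno_idx, :].T                    # gene x sample

    # shared cofactor shifts with gene-specific scaling
    gene_scale = rng.normal(1.0, 0.3, size=n_genes)
    if block_sd > 0:
        blocks = design["block"].to_numpy()
        shift = {blk: rng.normal(0.0, block_sd) for blk in np.unique(blocks)}
        latent = latent + np.outer(gene_scale, [shift[blk] for blk in blocks])
    if date_coef != 0.0:
        d = design["date"].to_numpy(dtype=float)
        latent = latent + np.outer(gene_scale, date_coef * (d - d.mean()))
    if hour_coef != 0.0:
        h = design["hour"].to_numpy(dtype=float)
        latent = latent + np.outer(gene_scale, hour_coef * (h - h.mean()))

    latent = latent + rng.standard_normal((n_genes, n_samples)) * np.sqrt(
        truth.sigma_e2
    )[:, None]

    base_mean = truth.base_mean
    if base_mean is None:
        base_mean = rng.lognormal(base_mean_log_mu, base_mean_log_sd, size=n_genes)
        truth.base_mean = base_mean
    dispersion = truth.dispersion
    if dispersion is None:
        dispersion = rng.lognormal(dispersion_log_mu, dispersion_log_sd, size=n_genes)
        truth.dispersion = dispersion
    lib = truth.library_multipliers
    if lib is None:
        lib = rng.lognormal(0.0, library_sd, size=n_samples)
        truth.library_multipliers = lib

    mean = base_mean[:, None] * np.exp2(latent) * lib[None, :]
    # NB with mean mu and dispersion phi: var = mu + phi mu^2
    r = 1.0 / dispersion[:, None]
    counts = rng.negative_binomial(r, r / (r + mean))

    gene_ids = [f"gene{i:05d}" for i in range(n_genes)]
    sample_ids = design["sample"].to_list()
    counts_df = pd.DataFrame(counts, index=gene_ids, columns=sample_ids)
    latent_df = (
        pd.DataFrame(latent, index=gene_ids, columns=sample_ids)
        if return_latent
        else None
    )
    genetic_df = pd.DataFrame(genetic, index=genotypes, columns=gene_ids)
    return counts_df, latent_df, genetic_df


def _safe_cholesky(K: np.ndarray, ridge: float = 1e-8) -> np.ndarray:
    K = np.asarray(K, dtype=float)
    for bump in (ridge, 1e-6, 1e-4):
        try:
            return np.linalg.cholesky(K + bump * np.eye(len(K)))
        except np.linalg.LinAlgError:
            continue
    w, V = np.linalg.eigh(K)
    return V @ np.diag(np.sqrt(np.clip(w, 0.0, None)))


# ---------------------------------------------------------------------------
# traits
# ---------------------------------------------------------------------------

def generate_traits(
    genetic_values: pd.DataFrame,
    truth: TruthRecord,
    seed: int = 0,
) -> pd.DataFrame:
    """Genotype x trait table from the planted trait architectures.

    Each trait is a sum of additive gene effects and pairwise products of
    genetic values plus Gaussian noise scaled so the generating predictor
    explains the planted ``signal_fraction`` of the trait variance.
    """
    rng = np.random.default_rng(seed)
    out = {}
    for trait, spec in truth.trait_effects.items():
        signal = np.zeros(len(genetic_values))
        for gene, coef in spec.get("additive", {}).items():
            if gene not in genetic_values.columns:
                raise KeyError(f"unknown effect gene {gene!r} for trait {trait!r}")
            signal = signal + coef * genetic_values[gene].to_numpy()
        for (g1, g2), coef in spec.get("pairs", []):
            for gene in (g1, g2):
                if gene not in genetic_values.columns:
                    raise KeyError(f"unknown effect gene {gene!r} for trait {trait!r}")
            signal = signal + coef * (
                genetic_values[g1].to_numpy() * genetic_values[g2].to_numpy()
            )
        q = spec.get("signal_fraction", 1.0)
        if not (0.0 < q <= 1.0):
            raise ValueError("signal_fraction must lie in (0, 1]")
        var_signal = signal.var()
        if q < 1.0 and var_signal > 0:
            noise_sd = np.sqrt(var_signal * (1.0 - q) / q)
            signal = signal + rng.normal(0.0, noise_sd, size=len(signal))
        out[trait] = signal
    return pd.DataFrame(out, index=genetic_values.index)


def default_trait_effects(
    gene_ids: list[str],
    truth: TruthRecord,
    n_traits: int = 4,
    n_effect_genes: int = 40,
    n_pairs: int = 5,
    signal_fraction: float = 0.5,
    seed: int = 0,
    modules_per_trait: int = 2,
) -> dict:
    """Standard planted trait architecture.

    Each trait is driven by one or two co-expression modules: its additive
    effect genes are the most-loaded (hub-most) genes of those modules with
    coherent within-module coefficient signs, so the trait tracks the
    modules' latent activity the way real traits track module eigengenes.
    Interacting pairs cross the chosen modules (products of hub genes
    approximate factor-by-factor epistasis).  When no modules exist the
    effect genes are drawn uniformly with independent coefficients.
    """
    rng = np.random.default_rng(seed)
    gene_ids = list(gene_ids)
    n_effect_genes = min(n_effect_genes, len(gene_ids))
    module_ids = [m for m in np.unique(truth.module) if m != 0]
    effects = {}
    for t in range(n_traits):
        if module_ids:
            chosen = rng.choice(
                module_ids, size=min(modules_per_trait, len(module_ids)), replace=False
            )
            per_mod = max(1, n_effect_genes // len(chosen))
            additive: dict[str, float] = {}
            hubs_by_mod = {}
            for m in chosen:
                members = [i for i in range(len(gene_ids)) if truth.module[i] == m]
                members.sort(key=lambda i: -abs(truth.loading[i]))
                take = members[:per_mod]
                sign = rng.choice([-1.0, 1.0])
                hubs_by_mod[m] = take
                for i in take:
                    additive[gene_ids[i]] = float(sign * abs(rng.normal(1.0, 0.3)))
            pairs = []
            if len(chosen) >= 2 and n_pairs > 0:
                a_hubs, b_hubs = hubs_by_mod[chosen[0]], hubs_by_mod[chosen[1]]
                for k in range(min(n_pairs, len(a_hubs), len(b_hubs))):
                    pairs.append(
                        ((gene_ids[a_hubs[k]], gene_ids[b_hubs[k]]),
                         float(rng.normal(0, 1)))
                    )
        else:
            idx = rng.choice(len(gene_ids), size=n_effect_genes, replace=False)
            additive = {gene_ids[i]: float(rng.normal(0, 1)) for i in idx}
            pairs = []
        effects[f"trait{t:02d}"] = {
            "additive": additive,
            "pairs": pairs,
            "signal_fraction": signal_fraction,
        }
    return effects


# ---------------------------------------------------------------------------
# one-call bundle
# ---------------------------------------------------------------------------

def generate_bundle(
    n_pops: int = DEFAULT_N_POPS,
    n_genotypes: int = DEFAULT_N_GENOTYPES,
    duplicated_fraction: float = DEFAULT_DUPLICATED_FRACTION,
    n_genes: int = 1000,
    n_modules: int = 4,
    grey_fraction: float = 0.4,
    n_snps: int = 2000,
    divergence: float = 0.1,
    n_traits: int = 4,
    signal_fraction: float = 0.5,
    seed: int = 0,
    **expression_kwargs,
) -> SyntheticBundle:
    """Full synthetic study: design, kinship, SNPs, counts, traits and truth."""
    rng = np.random.default_rng(seed)
    seeds = rng.integers(0, 2**31 - 1, size=5)
    design, kinship = generate_structure(
        n_pops, n_genotypes, duplicated_fraction, seed=int(seeds[0]),
        divergence=divergence,
    )
    truth = make_truth(
        n_genes, n_modules=n_modules, grey_fraction=grey_fraction,
        divergence=divergence, seed=int(seeds[1]),
    )
    counts, latent, genetic = generate_expression(
        design, kinship, truth, seed=int(seeds[2]), **expression_kwargs
    )
    dosages, snp_genes = generate_snps(
        design, n_snps=n_snps, divergence=divergence,
        gene_ids=list(counts.index), seed=int(seeds[3]),
    )
    truth.trait_effects = default_trait_effects(
        list(counts.index), truth, n_traits=n_traits,
        signal_fraction=signal_fraction, seed=int(seeds[4]),
    )
    traits = generate_traits(genetic, truth, seed=int(seeds[4]))
    bundle = SyntheticBundle(
        counts=counts, design=design, kinship=kinship, dosages=dosages,
        snp_genes=snp_genes, traits=traits, truth=truth,
        latent=latent, genetic_values=genetic,
    )
    bundle.validate()
    return bundle
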