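"""End-to-end orchestration: one config, deterministic sub-seeds per stage,
versioned outputs and a JSON summary of the key per-stage numbers."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import boruta as boruta_mod
from . import genesets, network, popgen, predict, preprocess, quantgen, synthdata

__all__ = ["PipelineConfig", "run"]

log = logging.getLogger("coexpred")


@dataclass
class PipelineConfig:
    outdir: str = "coexpred_run"
    seed: int = 0
    # synthetic-data stage (used when no input paths are given)
    n_pops: int = 11
    n_genotypes: int = 120
    n_genes: int = 1000
    n_modules: int = 4
    grey_fraction: float = 0.4
    n_snps: int = 2000
    divergence: float = 0.1
    n_traits: int = 4
    signal_fraction: float = 0.5
    # preprocessing
    min_count: int = 1
    sample_fraction: float = 0.10
    # network
    power: int | None = None
    min_module_size: int = 30
    merge_height: float = 0.25
    # sets
    set_fraction: float = 0.10
    n_random_sets: int = 100
    # selection
    boruta_thresholds: tuple = (0.01, 0.05, 0.1, 0.2)
    boruta_max_runs: int = 100
    # prediction
    split_proportions: tuple = (0.60, 0.20, 0.20)
    algorithms: tuple = ("ridge", "nn")
    nn_max_models: int = 20
    nn_epochs: int = 200
    skip_full_nn: bool = True
    # stage toggles
    stages: tuple = ("synth", "preprocess", "quantgen", "network", "sets",
                     "popgen", "select", "predict", "report")
    # restrict quantgen to this many genes (None = all); keeps demo runs quick
    max_quantgen_genes: int | None = None

    def config_hash(self) -> str:
        params = {k: v for k, v in asdict(self).items() if k != "outdir"}
        payload = json.dumps(params, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    def stage_seed(self, stage: str) -> int:
        digest = hashlib.sha256(f"{self.seed}:{stage}".encode()).digest()
        return int.from_bytes(digest[:4], "big") % (2**31 - 1)


def run(config: PipelineConfig) -> dict:
    """Execute the configured stages in dependency order.

    Stage failures raise with a stage-tagged message; outputs written so far
    are preserved in the run directory.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    summary: dict = {"config_hash": config.config_hash(), "seed": config.seed}
    state: dict = {}
    order = ["synth", "preprocess", "quantgen", "network", "sets", "popgen",
             "select", "predict", "report"]
    for stage in order:
        if stage not in config.stages:
            continue
        log.info("stage %s", stage)
        try:
            _STAGES[stage](config, state, summary, outdir)
        except Exception as exc:  # noqa: BLE001 - re-raise with stage tag
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
    (outdir / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True,
                                                    default=_jsonable))
    return summary


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(str(type(obj)))


def _stage_synth(config, state, summary, outdir):
    bundle = synthdata.generate_bundle(
        n_pops=config.n_pops,
        n_genotypes=config.n_genotypes,
        n_genes=config.n_genes,
        n_modules=config.n_modules,
        grey_fraction=config.grey_fraction,
        n_snps=config.n_snps,
        divergence=config.divergence,
        n_traits=config.n_traits,
        signal_fraction=config.signal_fraction,
        seed=config.stage_seed("synth"),
    )
    bundle.write(outdir / "synth")
    state["bundle"] = bundle
    summary["synth"] = {
        "n_samples": len(bundle.design),
        "n_genotypes": bundle.design["genotype"].nunique(),
        "n_genes": len(bundle.counts),
        "n_snps": bundle.dosages.shape[1],
        "n_traits": bundle.traits.shape[1],
    }


def _stage_preprocess(config, state, summary, outdir):
    bundle = state["bundle"]
    filtered, report = preprocess.filter_low_expressed(
        bundle.counts, config.min_count, config.sample_fraction
    )
    factors = preprocess.tmm_factors(filtered)
    normalized = preprocess.log_cpm(filtered, factors)
    pca_report = preprocess.cofactor_pca(normalized, bundle.design)
    # population structure is genuine signal, not a nuisance cofactor: only
    # experimental factors may enter the correction model
    flagged = [c for c in preprocess.flagged_covariates(pca_report)
               if c in ("block", "date", "hour")]
    normalized.to_csv(outdir / "normalized.tsv", sep="\t")
    state["normalized"] = normalized
    state["covariates"] = flagged
    summary["preprocess"] = {
        "genes_retained": report.n_retained,
        "genes_removed": report.n_removed,
        "flagged_covariates": flagged,
    }


def _stage_quantgen(config, state, summary, outdir):
    bundle = state["bundle"]
    normalized = state["normalized"]
    pops = pd.Series(
        bundle.design.drop_duplicates("genotype").set_index("genotype")["population"]
    ).reindex(bundle.kinship.index)
    pair = quantgen.split_kinship(bundle.kinship, pops)
    genes = list(normalized.index)
    if config.max_quantgen_genes is not None:
        genes = genes[: config.max_quantgen_genes]
    mean_cpm = (np.exp2(normalized) - 1.0).mean(axis=1)
    summary_df, blups = quantgen.fit_genes(
        normalized, bundle.design, pair,
        covariates=state.get("covariates") or None,
        genes=genes, mean_expression=mean_cpm,
    )
    summary_df.to_csv(outdir / "gene_summary.tsv", sep="\t")
    blups.to_csv(outdir / "blups.tsv", sep="\t")
    state["kinship_pair"] = pair
    state["gene_summary"] = summary_df
    state["blups"] = blups
    summary["quantgen"] = {
        "n_genes_fit": len(summary_df),
        "median_h2": float(summary_df["h2"].median()),
        "median_qst": float(summary_df["qst"].median()),
        "n_converged": int(summary_df["converged"].sum()),
    }


def _stage_network(config, state, summary, outdir):
    blups = state["blups"]
    net = network.build_network(
        blups.T, power=config.power,
        min_size=config.min_module_size, merge_height=config.merge_height,
    )
    net.modules.to_frame().assign(centrality=net.centrality).to_csv(
        outdir / "modules.tsv", sep="\t"
    )
    net.eigengenes.to_csv(outdir / "eigengenes.tsv", sep="\t")
    traits = state["bundle"].traits
    if not net.eigengenes.empty and traits.shape[1] > 0:
        mt = network.module_trait_correlations(net.eigengenes, traits)
        mt.to_csv(outdir / "module_trait.tsv", sep="\t", index=False)
    state["network"] = net
    summary["network"] = {
        "power": net.power,
        "n_modules": int((np.unique(net.modules) != network.GREY).sum()),
        "grey_fraction": float((net.modules == network.GREY).mean()),
        "mean_connectivity": float(net.connectivity.mean()),
    }


def _stage_sets(config, state, summary, outdir):
    net = state["network"]
    sets = genesets.build_sets(
        net.centrality, net.modules, fraction=config.set_fraction,
        n_random=config.n_random_sets, seed=config.stage_seed("sets"),
    )
    setdir = outdir / "sets"
    setdir.mkdir(exist_ok=True)
    for label in ("core", "peripheral", "peripheral_ng"):
        sets[label].write(setdir / f"{label}.txt")
    gene_summary = state.get("gene_summary")
    if gene_summary is not None:
        named = [sets[k] for k in ("core", "peripheral", "peripheral_ng")]
        for stat in ("h2", "qst", "cv_g"):
            comp = genesets.compare_sets(gene_summary[stat], named)
            comp.to_csv(outdir / f"set_comparison_{stat}.tsv", sep="\t", index=False)
    state["sets"] = sets
    summary["sets"] = {
        "set_size": len(sets["core"]),
        "n_random": config.n_random_sets,
    }


def _stage_popgen(config, state, summary, outdir):
    bundle = state["bundle"]
    pops = pd.Series(
        bundle.design.drop_duplicates("genotype").set_index("genotype")["population"]
    )
    panel = popgen.SNPPanel(bundle.dosages, bundle.snp_genes, pops)
    _, ht_gene = popgen.gene_diversity(panel)
    per_snp, fst_summary = popgen.fst(panel)
    K = min(8, len(bundle.dosages) - 1)
    _, score_gene = popgen.pca_outlier_score(panel, K=K, seed=config.stage_seed("popgen"))
    pd.DataFrame({"Ht": ht_gene, "pca_outlier": score_gene}).to_csv(
        outdir / "popgen_gene.tsv", sep="\t"
    )
    per_snp.to_csv(outdir / "popgen_snp.tsv", sep="\t")
    state["fst_summary"] = fst_summary
    state["ht_gene"] = ht_gene
    summary["popgen"] = fst_summary


def _stage_select(config, state, summary, outdir):
    bundle = state["bundle"]
    blups = state["blups"]
    traits = bundle.traits
    pops = pd.Series(
        bundle.design.drop_duplicates("genotype").set_index("genotype")["population"]
    )
    plan = predict.make_split(
        list(blups.index), pops, config.split_proportions,
        seed=config.stage_seed("split"),
    )
    state["split"] = plan
    pools = {}
    results_all = []
    seed0 = config.stage_seed("select")
    for t_idx, trait in enumerate(traits.columns):
        for p_idx, thr in enumerate(config.boruta_thresholds):
            res = boruta_mod.boruta_select(
                blups.loc[plan.train], traits.loc[plan.train, trait],
                p_threshold=thr, max_runs=config.boruta_max_runs,
                seed=(seed0 + 1000 * t_idx + p_idx) % (2**31 - 1), trait=trait,
            )
            results_all.append(res)
    for thr in config.boruta_thresholds:
        pool, membership = boruta_mod.pool_selected(results_all, thr)
        pools[thr] = pool
        membership.to_csv(outdir / f"boruta_pool_p{thr}.tsv", sep="\t")
    state["boruta_pools"] = pools
    sets = state.get("sets")
    enrich = {}
    if sets is not None:
        universe = sets["full"].members
        for thr, pool in pools.items():
            if pool:
                e = boruta_mod.enrichment_test(pool, sets["core"].members, universe)
                enrich[str(thr)] = {"pvalue": e["pvalue"],
                                    "representation_ratio": e["representation_ratio"]}
    summary["select"] = {
        "pool_sizes": {str(t): len(p) for t, p in pools.items()},
        "core_enrichment": enrich,
    }


def _stage_predict(config, state, summary, outdir):
    bundle = state["bundle"]
    blups = state["blups"]
    sets = dict(state["sets"])
    pools = state.get("boruta_pools", {})
    thr0 = config.boruta_thresholds[0]
    if pools.get(thr0):
        sets["boruta"] = genesets.GeneSet("boruta", pools[thr0], f"pool at p={thr0}")
    pops = pd.Series(
        bundle.design.drop_duplicates("genotype").set_index("genotype")["population"]
    )
    records, nulls = predict.predict_sets(
        blups, bundle.traits, sets, pops,
        algorithms=config.algorithms, seed=config.stage_seed("predict"),
        skip_full_nn=config.skip_full_nn,
        nn_kwargs={"max_models": config.nn_max_models, "epochs": config.nn_epochs},
    )
    rows = [{"trait": r.trait, "set": r.gene_set, "algorithm": r.algorithm,
             "r2": r.r2} for r in records]
    pd.DataFrame(rows).to_csv(outdir / "predictions.tsv", sep="\t", index=False)
    flag_rows = [{"trait": n.trait, "algorithm": n.algorithm, "set": s, "flag": f,
                  "null_lo": n.lo, "null_hi": n.hi, "null_median": n.median}
                 for n in nulls for s, f in n.flags.items()]
    pd.DataFrame(flag_rows).to_csv(outdir / "null_flags.tsv", sep="\t", index=False)
    state["records"] = records
    df = pd.DataFrame(rows)
    mean_by = df[~df["set"].str.startswith("random_")].groupby(
        ["algorithm", "set"])["r2"].mean()
    summary["predict"] = {
        f"{alg}:{gs}": float(v) for (alg, gs), v in mean_by.items()
    }


def _stage_report(config, state, summary, outdir):
    summary["report"] = {"stages_run": [s for s in config.stages]}


_STAGES = {
    "synth": _stage_synth,
    "preprocess": _stage_preprocess,
    "quantgen": _stage_quantgen,
    "network": _stage_network,
    "sets": _stage_sets,
    "popgen": _stage_popgen,
    "select": _stage_select,
    "predict": _stage_predict,
    "report": _stage_report,
}
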