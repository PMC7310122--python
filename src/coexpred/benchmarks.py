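"""Self-contained evaluation runs on planted-truth data.

Each function generates its own inputs from a seed, runs the relevant part of
the pipeline and returns measured quantities: quantitative-genetic parameter
recovery, network module recovery, feature-selection calibration, prediction
sanity and the combinatorial study constants.  Problem sizes mirror the study
design (11 populations, ~200 genotypes with duplicate replicates) at gene
counts small enough for a workstation run; docs/methods.md discusses the
choices.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import adjusted_rand_score

from . import boruta as boruta_mod
from . import network, popgen, predict, preprocess, quantgen, synthdata

__all__ = [
    "worked_examples",
    "parameter_recovery",
    "network_recovery",
    "boruta_calibration",
    "prediction_sanity",
    "fst_recovery",
]


def _populations(design: pd.DataFrame, index: pd.Index) -> pd.Series:
    return pd.Series(
        design.drop_duplicates("genotype").set_index("genotype")["population"]
    ).reindex(index)


def worked_examples(seed: int = 0) -> dict:
    """The study's self-contained combinatorial quantities, recomputed."""
    design, _ = synthdata.generate_structure(
        n_pops=11, genotypes_per_pop=241, duplicated_fraction=218 / 241, seed=seed
    )
    rng = np.random.default_rng(seed)
    eig = pd.DataFrame(
        rng.standard_normal((40, 16)), columns=range(1, 17),
        index=[f"G{i}" for i in range(40)],
    )
    traits = pd.DataFrame(
        rng.standard_normal((40, 17)), index=eig.index,
        columns=[f"t{i}" for i in range(17)],
    )
    mt = network.module_trait_correlations(eig, traits)
    from .genesets import set_size

    return {
        "n_samples": len(design),
        "core_set_size": set_size(34_229, 0.10),
        "module_trait_tests": int(mt.attrs["n_tests"]),
        "nn_structures": len(predict.nn_structures(100)),
        "random_pair_differences": predict.n_pair_differences(100),
    }


def parameter_recovery(
    seed: int = 0,
    n_genes: int = 500,
    n_genotypes: int = 200,
    n_pops: int = 11,
) -> dict:
    """Median absolute recovery error of planted h2 and Q_ST."""
    bundle = synthdata.generate_bundle(
        n_pops=n_pops, n_genotypes=n_genotypes, n_genes=n_genes,
        n_snps=400, grey_fraction=0.5, seed=seed,
    )
    filtered, _ = preprocess.filter_low_expressed(bundle.counts)
    normalized = preprocess.log_cpm(filtered, preprocess.tmm_factors(filtered))
    pair = quantgen.split_kinship(
        bundle.kinship, _populations(bundle.design, bundle.kinship.index)
    )
    summary, _ = quantgen.fit_genes(normalized, bundle.design, pair)
    truth_h2 = pd.Series(bundle.truth.h2, index=bundle.counts.index)
    truth_qst = pd.Series(bundle.truth.qst, index=bundle.counts.index)
    merged = summary.join(truth_h2.rename("h2_true")).join(truth_qst.rename("qst_true"))
    return {
        "median_h2_error": float((merged["h2"] - merged["h2_true"]).abs().median()),
        "median_qst_error": float((merged["qst"] - merged["qst_true"]).abs().median()),
        "n_genes": len(merged),
        "fraction_converged": float(summary["converged"].mean()),
    }


def network_recovery(seed: int = 0, n_genotypes: int = 200) -> dict:
    """Planted 2-module + grey recovery at hub loading 1.0, noise SD 0.5.

    The matrix is built on the genotype scale the network operates on: module
    genes carry a unit-loaded factor plus the residual a two-replicate study
    leaves after averaging (variance 0.25 / 2); grey genes are independent
    noise.  A second, loading-gradient module drives a trait for the
    three-way kME / gene-trait correlation property.
    """
    rng = np.random.default_rng(seed)
    noise_var = 0.25 / 2
    F = rng.standard_normal((2, n_genotypes))
    rows, truth = [], []
    for m in range(2):
        for _ in range(50):
            rows.append(F[m] + np.sqrt(noise_var) * rng.standard_normal(n_genotypes))
            truth.append(m + 1)
    for _ in range(100):
        rows.append(rng.standard_normal(n_genotypes))
        truth.append(0)
    X = pd.DataFrame(
        rows, index=[f"g{i}" for i in range(len(rows))],
        columns=[f"G{j}" for j in range(n_genotypes)],
    )
    truth = np.array(truth)
    net = network.build_network(X)
    ari = adjusted_rand_score(truth, net.modules)
    hub_kme = float(net.centrality[truth > 0].median())

    # three-way property on a hub-to-peripheral gradient module
    G = rng.standard_normal(n_genotypes)
    rows2 = []
    loadings = np.linspace(1.0, 0.3, 60)
    for lo in loadings:
        resid = np.sqrt(noise_var + (1 - lo**2) * 0.3)
        rows2.append(lo * G + resid * rng.standard_normal(n_genotypes))
    for _ in range(90):
        rows2.append(rng.standard_normal(n_genotypes))
    X2 = pd.DataFrame(
        rows2, index=[f"h{i}" for i in range(len(rows2))], columns=X.columns
    )
    net2 = network.build_network(X2)
    trait = G + 0.5 * rng.standard_normal(n_genotypes)
    gene_trait = np.array(
        [abs(stats.spearmanr(X2.iloc[i], trait).statistic) for i in range(60)]
    )
    threeway = float(
        stats.spearmanr(net2.centrality.iloc[:60].to_numpy(), gene_trait).statistic
    )
    return {"ari": float(ari), "hub_kme": hub_kme, "threeway_rho": threeway}


def boruta_calibration(
    seed: int = 0,
    n_seeds: int = 20,
    n_samples: int = 150,
    n_features: int = 200,
    p_threshold: float = 0.01,
) -> dict:
    """All-noise type-I rate and planted-predictor power of the selection."""
    type1, power = [], 0
    base = np.random.default_rng(seed).integers(0, 2**31 - 1, size=2 * n_seeds)
    for i in range(n_seeds):
        rng = np.random.default_rng(int(base[2 * i]))
        X = pd.DataFrame(
            rng.standard_normal((n_samples, n_features)),
            columns=[f"g{j}" for j in range(n_features)],
        )
        y_noise = rng.standard_normal(n_samples)
        res = boruta_mod.boruta_select(
            X, y_noise, p_threshold=p_threshold, seed=int(base[2 * i])
        )
        type1.append(len(res.confirmed) / n_features)
        signal = X["g0"].to_numpy()
        y_signal = signal + rng.standard_normal(n_samples) * signal.std()
        res2 = boruta_mod.boruta_select(
            X, y_signal, p_threshold=p_threshold, seed=int(base[2 * i + 1])
        )
        power += "g0" in res2.confirmed
    return {
        "type1_rate": float(np.mean(type1)),
        "power": power / n_seeds,
        "n_seeds": n_seeds,
    }


def prediction_sanity(
    seed: int = 0,
    n_ridge_seeds: int = 20,
    n_nn_seeds: int = 6,
    n_null_seeds: int = 10,
    n_random_sets: int = 100,
    signal_fraction: float = 0.5,
) -> dict:
    """Three prediction checks on planted-truth bundles.

    (i) full-set ridge recovers the planted predictable fraction of an
    additive module-driven trait; (ii) on interaction-only traits the
    network out-predicts ridge; (iii) the random-set null flags a
    planted-signal set above its 95% interval.
    """
    base = np.random.default_rng(seed).integers(0, 2**31 - 1, size=3)

    ridge_r2 = []
    for i in range(n_ridge_seeds):
        s = int((base[0] + i) % (2**31 - 1))
        bundle = synthdata.generate_bundle(
            n_pops=11, n_genotypes=200, n_genes=1000, n_snps=200,
            seed=s, n_traits=1,
        )
        G = bundle.genetic_values
        effects = synthdata.default_trait_effects(
            list(G.columns), bundle.truth, n_traits=1, n_pairs=0,
            signal_fraction=signal_fraction, seed=s,
        )
        bundle.truth.trait_effects = effects
        traits = synthdata.generate_traits(G, bundle.truth, seed=s)
        pops = _populations(bundle.design, G.index)
        plan = predict.make_split(list(G.index), pops, seed=s)
        y = traits.iloc[:, 0]
        model, _ = predict.fit_ridge(
            G.loc[plan.train].to_numpy(), y[plan.train].to_numpy()
        )
        ridge_r2.append(
            predict.test_r2(y[plan.test].to_numpy(), model.predict(G.loc[plan.test].to_numpy()))
        )

    nn_advantage = []
    for i in range(n_nn_seeds):
        s = int((base[1] + i) % (2**31 - 1))
        bundle = synthdata.generate_bundle(
            n_pops=11, n_genotypes=200, n_genes=300, n_snps=200,
            seed=s, n_traits=1, n_modules=2, grey_fraction=0.3,
        )
        G, tr = bundle.genetic_values, bundle.truth
        m1 = sorted(
            (i for i in range(300) if tr.module[i] == 1),
            key=lambda i: -tr.loading[i],
        )
        m2 = sorted(
            (i for i in range(300) if tr.module[i] == 2),
            key=lambda i: -tr.loading[i],
        )
        pairs = [((G.columns[m1[k]], G.columns[m2[k]]), 1.0) for k in range(5)]
        tr.trait_effects = {
            "t": {"additive": {}, "pairs": pairs, "signal_fraction": 0.7}
        }
        traits = synthdata.generate_traits(G, tr, seed=s)
        pops = _populations(bundle.design, G.index)
        plan = predict.make_split(list(G.index), pops, seed=s)
        y = traits["t"]
        hubs = [G.columns[i] for i in (m1[:15] + m2[:15])]
        Xtr = G.loc[plan.train, hubs].to_numpy()
        Xva = G.loc[plan.validation, hubs].to_numpy()
        Xte = G.loc[plan.test, hubs].to_numpy()
        ridge, _ = predict.fit_ridge(Xtr, y[plan.train].to_numpy())
        r2_ridge = predict.test_r2(y[plan.test].to_numpy(), ridge.predict(Xte))
        nn, _ = predict.fit_nn(
            Xtr, y[plan.train].to_numpy(), Xva, y[plan.validation].to_numpy(),
            max_models=25, seed=s, epochs=250,
        )
        r2_nn = predict.test_r2(y[plan.test].to_numpy(), nn.predict(Xte))
        nn_advantage.append(r2_nn - r2_ridge)

    above = 0
    for i in range(n_null_seeds):
        s = int((base[2] + i) % (2**31 - 1))
        # many small modules: the trait's module covers only 5% of genes, so
        # random sets rarely sample its signal and the planted set separates
        bundle = synthdata.generate_bundle(
            n_pops=11, n_genotypes=200, n_genes=500, n_snps=200,
            seed=s, n_traits=1, n_modules=10, grey_fraction=0.5,
        )
        Gv = bundle.genetic_values
        effects = synthdata.default_trait_effects(
            list(Gv.columns), bundle.truth, n_traits=1, n_pairs=0,
            n_effect_genes=20, modules_per_trait=1,
            signal_fraction=signal_fraction, seed=s,
        )
        bundle.truth.trait_effects = effects
        traits = synthdata.generate_traits(Gv, bundle.truth, seed=s)
        y = traits.iloc[:, 0]
        pops = _populations(bundle.design, Gv.index)
        plan = predict.make_split(list(Gv.index), pops, seed=s)
        effect_genes = list(effects["trait00"]["additive"])
        k = len(effect_genes)
        rng = np.random.default_rng(s)
        yt, yv, ye = (y[p].to_numpy() for p in (plan.train, plan.validation, plan.test))

        def _r2(genes):
            model, _ = predict.fit_ridge(
                Gv.loc[plan.train, genes].to_numpy(), yt
            )
            return predict.test_r2(ye, model.predict(Gv.loc[plan.test, genes].to_numpy()))

        named = {"signal": _r2(effect_genes)}
        randoms = {}
        ids = np.array(Gv.columns)
        for j in range(n_random_sets):
            draw = rng.choice(len(ids), size=k, replace=False)
            randoms[f"random_{j}"] = _r2(list(ids[draw]))
        null = predict.random_null(
            randoms, named, trait="trait00", algorithm="ridge",
            n_expected=n_random_sets,
        )
        above += null.flags["signal"] == "above"

    return {
        "ridge_full_r2_median": float(np.median(ridge_r2)),
        "nn_interaction_advantage_median": float(np.median(nn_advantage)),
        "nn_advantage_min": float(np.min(nn_advantage)),
        "null_above_rate": above / n_null_seeds,
        "signal_fraction": signal_fraction,
    }


def fst_recovery(seed: int = 0, divergence: float = 0.2) -> dict:
    """Multilocus F_ST recovery of the planted divergence at 11 demes."""
    design, _ = synthdata.generate_structure(
        11, 330, duplicated_fraction=0.0, seed=seed
    )
    dosages, genes = synthdata.generate_snps(
        design, n_snps=2000, divergence=divergence, seed=seed
    )
    pops = design.drop_duplicates("genotype").set_index("genotype")["population"]
    _, summary = popgen.fst(popgen.SNPPanel(dosages, genes, pops))
    return {"mean_fst": summary["mean_fst"], "planted": divergence,
            "p99_fst": summary["p99_fst"]}
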