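import numpy as np
import pandas as pd
import pytest
from scipy import stats
from sklearn.metrics import adjusted_rand_score

from coexpred import network


def _planted_blocks(rng, n_geno=120, block_sizes=(50, 50), n_noise=100, noise_sd=0.5):
    F = rng.standard_normal((len(block_sizes), n_geno))
    rows, truth = [], []
    for m, size in enumerate(block_sizes):
        for _ in range(size):
            rows.append(F[m] + noise_sd * rng.standard_normal(n_geno))
            truth.append(m + 1)
    for _ in range(n_noise):
        rows.append(rng.standard_normal(n_geno))
        truth.append(0)
    X = pd.DataFrame(
        rows, index=[f"g{i}" for i in range(len(rows))],
        columns=[f"G{j}" for j in range(n_geno)],
    )
    return X, np.array(truth), F


class TestAdjacency:
    def test_extreme_correlations(self):
        corr = pd.DataFrame([[1.0, 1.0, -1.0], [1.0, 1.0, -1.0], [-1.0, -1.0, 1.0]])
        A = network.signed_adjacency(corr, 6)
        assert A.iloc[0, 1] == pytest.approx(1.0)
        assert A.iloc[0, 2] == pytest.approx(0.0)

    def test_matches_rank_then_correlate_oracle(self, rng):
        X = pd.DataFrame(rng.standard_normal((20, 30)))
        rho_oracle = np.corrcoef(np.apply_along_axis(stats.rankdata, 1, X.to_numpy()))
        A_oracle = ((1 + rho_oracle) / 2) ** 6
        A = network.signed_adjacency(network.spearman_correlation(X), 6)
        np.testing.assert_allclose(A.to_numpy(), A_oracle, atol=1e-12)

    def test_rank_invariance(self, rng):
        """Monotone transforms of genes leave the whole network unchanged."""
        X = pd.DataFrame(rng.standard_normal((10, 25)))
        Y = X.copy()
        Y.iloc[0] = np.exp(Y.iloc[0])
        Y.iloc[1] = Y.iloc[1] ** 3
        a = network.signed_adjacency(network.spearman_correlation(X), 6)
        b = network.signed_adjacency(network.spearman_correlation(Y), 6)
        np.testing.assert_allclose(a.to_numpy(), b.to_numpy(), atol=1e-12)

    def test_connectivity_bounded(self, rng):
        X = pd.DataFrame(rng.standard_normal((15, 20)))
        k = network.connectivity(
            network.signed_adjacency(network.spearman_correlation(X), 6)
        )
        assert (k <= len(X) - 1 + 1e-12).all()
        assert (k >= 0).all()

    def test_power_below_one_rejected(self):
        corr = pd.DataFrame(np.eye(3))
        with pytest.raises(ValueError):
            network.signed_adjacency(corr, 0)


class TestPickPower:
    def test_planted_power_law_fits_well(self, rng):
        """An exact power-law connectivity histogram scores R2 >= 0.95."""
        k = rng.pareto(2.0, size=4000) + 1.0
        r2, slope = network.scale_free_fit(k)
        assert r2 >= 0.95
        assert slope < 0

    def test_default_when_no_candidate_reaches_threshold(self, rng):
        # equicorrelated genes: connectivity distribution is nothing like a
        # power law, so the recommended default power is returned
        base = rng.standard_normal(40)
        X = pd.DataFrame(
            [base + 0.3 * rng.standard_normal(40) for _ in range(25)]
        )
        power, diagnostics = network.pick_power(X, r2_threshold=0.99)
        assert power == 12
        assert len(diagnostics) == 20
        assert {"power", "scale_free_r2", "mean_connectivity"} <= set(diagnostics)

    def test_two_genes_degenerate_returns_default(self, rng):
        X = pd.DataFrame(rng.standard_normal((2, 30)))
        power, diagnostics = network.pick_power(X)
        assert power == 12
        assert diagnostics["scale_free_r2"].isna().all()


class TestEigengene:
    def test_identical_genes_give_standardized_profile(self):
        profile = np.array([3.0, 1.0, 4.0, 1.0, 5.0, 9.0])
        X = pd.DataFrame([profile, profile, profile])
        e = network.eigengene(X)
        expected = (profile - profile.mean()) / profile.std()
        np.testing.assert_allclose(e.to_numpy(), expected, atol=1e-10)

    def test_orientation_after_sign_flip(self, rng):
        X = pd.DataFrame(rng.standard_normal((8, 40)))
        X.iloc[:] = X.iloc[0].to_numpy() + 0.1 * rng.standard_normal((8, 40))
        e1 = network.eigengene(X)
        e2 = network.eigengene(-X)
        # orientation rule re-aligns the flipped module with its mean profile
        assert np.corrcoef(e1, -e2)[0, 1] > 0.99
        assert np.corrcoef(e1, X.mean(axis=0))[0, 1] > 0

    def test_matches_svd_oracle(self, rng):
        X = pd.DataFrame(rng.standard_normal((10, 20)))
        Xs = ((X.T - X.mean(axis=1)) / X.std(axis=1)).T.to_numpy()
        _, _, Vt = np.linalg.svd(Xs)
        e = network.eigengene(X).to_numpy()
        v = Vt[0]
        v = v / v.std()
        v = v - v.mean()
        align = np.sign(np.dot(e, v))
        np.testing.assert_allclose(e, align * v, atol=1e-10)


class TestKME:
    def test_gene_equal_to_eigengene(self, rng):
        e = rng.standard_normal(50)
        X = pd.DataFrame([e, rng.standard_normal(50)], index=["hub", "other"])
        eig = pd.DataFrame({1: e})
        kme_df, centrality = network.kme(X, eig)
        assert kme_df.loc["hub", 1] == pytest.approx(1.0)
        assert centrality["hub"] == pytest.approx(1.0)

    def test_independent_gene_near_zero(self, rng):
        n = 500
        eig = pd.DataFrame({1: rng.standard_normal(n)})
        X = pd.DataFrame([rng.standard_normal(n)], index=["noise"])
        _, centrality = network.kme(X, eig)
        assert centrality["noise"] < 0.15

    def test_matches_rank_correlation_oracle(self, rng):
        X = pd.DataFrame(rng.standard_normal((6, 30)))
        eig = pd.DataFrame(rng.standard_normal((30, 2)), columns=[1, 2])
        kme_df, _ = network.kme(X, eig)
        for g in range(6):
            for m in [1, 2]:
                expected = stats.spearmanr(X.iloc[g], eig[m]).statistic
                assert kme_df.iloc[g][m] == pytest.approx(expected, abs=1e-12)


class TestDetectModules:
    def test_two_blocks_recovered_noise_grey(self, rng):
        X, truth, _ = _planted_blocks(rng)
        modules = network.detect_modules(X, power=12)
        assert adjusted_rand_score(truth, modules) >= 0.8
        noise_labels = modules[truth == 0]
        assert (noise_labels == network.GREY).mean() >= 0.9

    def test_same_factor_blocks_merged(self, rng):
        X, truth, F = _planted_blocks(rng, block_sizes=(40, 40), n_noise=60)
        # overwrite block 2 with the same factor as block 1
        for i in range(40, 80):
            X.iloc[i] = F[0] + 0.5 * rng.standard_normal(X.shape[1])
        modules = network.detect_modules(X, power=12)
        assert modules[modules != network.GREY].nunique() == 1

    def test_pure_noise_mostly_grey(self, rng):
        X = pd.DataFrame(
            rng.standard_normal((150, 100)),
            index=[f"g{i}" for i in range(150)],
        )
        modules = network.detect_modules(X, power=12)
        assert (modules == network.GREY).mean() >= 0.95

    def test_fewer_genes_than_min_size_all_grey(self, rng):
        X = pd.DataFrame(rng.standard_normal((10, 20)))
        modules = network.detect_modules(X, power=6, min_size=30)
        assert (modules == network.GREY).all()


class TestModuleTrait:
    def test_family_size_is_modules_times_traits(self, rng):
        n_geno = 40
        eig = pd.DataFrame(
            rng.standard_normal((n_geno, 16)), columns=range(1, 17),
            index=[f"G{i}" for i in range(n_geno)],
        )
        traits = pd.DataFrame(
            rng.standard_normal((n_geno, 17)), index=eig.index,
            columns=[f"t{i}" for i in range(17)],
        )
        table = network.module_trait_correlations(eig, traits)
        assert len(table) == 272
        assert table.attrs["n_tests"] == 272

    def test_monotone_trait_perfect_rho(self, rng):
        eig = pd.DataFrame({1: rng.standard_normal(30)},
                           index=[f"G{i}" for i in range(30)])
        traits = pd.DataFrame({"t": np.exp(eig[1])}, index=eig.index)
        table = network.module_trait_correlations(eig, traits)
        assert table["rho"].iloc[0] == pytest.approx(1.0)

    def test_constant_trait_missing(self, rng):
        eig = pd.DataFrame({1: rng.standard_normal(20)},
                           index=[f"G{i}" for i in range(20)])
        traits = pd.DataFrame({"t": np.ones(20)}, index=eig.index)
        table = network.module_trait_correlations(eig, traits)
        assert np.isnan(table["rho"].iloc[0])

    def test_familywise_error_controlled(self, rng):
        """Permuted traits almost never reach Bonferroni significance."""
        n_sig = 0
        for seed in range(30):
            r = np.random.default_rng(seed)
            eig = pd.DataFrame(
                r.standard_normal((30, 4)), columns=range(1, 5),
                index=[f"G{i}" for i in range(30)],
            )
            traits = pd.DataFrame(
                r.standard_normal((30, 5)), index=eig.index,
                columns=[f"t{i}" for i in range(5)],
            )
            table = network.module_trait_correlations(eig, traits)
            n_sig += int(table["significant"].any())
        assert n_sig <= 3


class TestBuildNetwork:
    def test_full_stage_on_planted_data(self, rng):
        X, truth, _ = _planted_blocks(rng, n_geno=80, block_sizes=(40, 40), n_noise=60)
        net = network.build_network(X)
        assert net.modules[truth > 0].nunique() <= 2
        assert net.centrality.between(0, 1).all()
        assert net.eigengenes.shape[0] == 80
        # grey genes still get a centrality from real modules
        assert net.centrality.index.equals(net.modules.index)
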