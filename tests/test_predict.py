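import numpy as np
import pandas as pd
import pytest

from coexpred import predict
from coexpred.predict import PredictionRecord


def _population_series(n, n_pops=5):
    return pd.Series(
        [f"P{i % n_pops}" for i in range(n)], index=[f"G{i}" for i in range(n)]
    )


class TestSplit:
    def test_sizes_and_partition(self):
        pops = _population_series(100)
        plan = predict.make_split(list(pops.index), pops, seed=0)
        assert len(plan.train) == 60
        assert len(plan.validation) == 20
        assert len(plan.test) == 20
        assert set(plan.train) | set(plan.validation) | set(plan.test) == set(pops.index)

    def test_stratification_close_to_global(self):
        pops = _population_series(200, n_pops=4)
        fracs = []
        for seed in range(30):
            plan = predict.make_split(list(pops.index), pops, seed=seed)
            for pop in pops.unique():
                members = set(pops[pops == pop].index)
                fracs.append(len(members & set(plan.train)) / len(members))
        assert max(abs(f - 0.60) for f in fracs) <= 0.10

    def test_small_population_lottery(self):
        pops = pd.Series(
            ["A"] * 20 + ["B"] * 2, index=[f"G{i}" for i in range(22)]
        )
        plan = predict.make_split(list(pops.index), pops, seed=1)
        all_ids = set(plan.train) | set(plan.validation) | set(plan.test)
        assert all_ids == set(pops.index)

    def test_too_few_genotypes_rejected(self):
        pops = _population_series(5)
        with pytest.raises(ValueError):
            predict.make_split(list(pops.index), pops)


class TestRidge:
    def test_noiseless_interpolation(self, rng):
        X = rng.standard_normal((50, 10))
        w = rng.standard_normal(10)
        y = X @ w
        model, info = predict.fit_ridge(X, y, lambda_grid=np.logspace(-8, 0, 9))
        assert predict.test_r2(y, model.predict(X)) > 0.999

    def test_infinite_penalty_predicts_mean(self, rng):
        X = rng.standard_normal((40, 5))
        y = rng.standard_normal(40)
        model, _ = predict.fit_ridge(X, y, lambda_grid=np.array([1e12]))
        assert np.allclose(model.predict(X), y.mean(), atol=1e-4)

    def test_matches_closed_form_oracle(self, rng):
        """Coefficients equal (X'X + lambda I)^-1 X'y on standardized data."""
        X = rng.standard_normal((30, 8))
        y = rng.standard_normal(30)
        lam = 3.7
        model, _ = predict.fit_ridge(X, y, lambda_grid=np.array([lam]))
        Xs = (X - X.mean(0)) / X.std(0)
        yc = y - y.mean()
        w_oracle = np.linalg.solve(Xs.T @ Xs + lam * np.eye(8), Xs.T @ yc)
        np.testing.assert_allclose(model.w, w_oracle, atol=1e-8)

    def test_primal_dual_agreement(self, rng):
        # p > n engages the dual solution; must match the primal formula
        X = rng.standard_normal((15, 40))
        y = rng.standard_normal(15)
        Xs = (X - X.mean(0)) / X.std(0)
        w_dual, b = predict._ridge_solve(Xs, y, 2.0)
        w_primal = np.linalg.solve(Xs.T @ Xs + 2.0 * np.eye(40), Xs.T @ (y - y.mean()))
        np.testing.assert_allclose(w_dual, w_primal, atol=1e-8)

    def test_constant_trait_rejected(self, rng):
        with pytest.raises(ValueError):
            predict.fit_ridge(rng.standard_normal((20, 3)), np.ones(20))


class TestNN:
    @pytest.mark.parametrize("h", [3, 9, 30, 100])
    def test_exactly_six_structures(self, h):
        structures = predict.nn_structures(h)
        assert len(structures) == 6
        assert all(l2 <= l1 for l1, l2 in structures)

    def test_budget_respected_and_learns_linear(self, rng):
        X = rng.standard_normal((120, 10))
        y = X @ rng.standard_normal(10)
        model, info = predict.fit_nn(
            X[:80], y[:80], X[80:], y[80:], max_models=7, seed=0, epochs=150
        )
        assert info["n_models"] <= 7
        r2 = predict.test_r2(y[80:], model.predict(X[80:]))
        assert r2 > 0.5

    def test_nn_close_to_ridge_on_linear_trait(self, rng):
        """On an additive trait the network approaches the linear model."""
        X = rng.standard_normal((200, 12))
        y = X @ rng.standard_normal(12) + 0.3 * rng.standard_normal(200)
        tr, va, te = slice(0, 120), slice(120, 160), slice(160, 200)
        ridge, _ = predict.fit_ridge(X[tr], y[tr])
        r2_ridge = predict.test_r2(y[te], ridge.predict(X[te]))
        nn, _ = predict.fit_nn(X[tr], y[tr], X[va], y[va],
                               max_models=25, seed=1, epochs=250)
        r2_nn = predict.test_r2(y[te], nn.predict(X[te]))
        assert r2_nn >= r2_ridge - 0.1

    def test_too_few_inputs_rejected(self, rng):
        with pytest.raises(ValueError):
            predict.fit_nn(rng.standard_normal((20, 2)), np.ones(20),
                           rng.standard_normal((5, 2)), np.ones(5))


class TestR2:
    def test_perfect_and_mean_only(self, rng):
        y = rng.standard_normal(30)
        assert predict.test_r2(y, y) == pytest.approx(1.0)
        assert predict.test_r2(y, np.full(30, y.mean())) == pytest.approx(0.0)

    def test_hand_arithmetic(self):
        obs = np.array([1.0, 2.0, 3.0])
        pred = np.array([1.5, 2.0, 2.5])
        # SSE = 0.5, SST = 2 -> 0.75
        assert predict.test_r2(obs, pred) == pytest.approx(0.75)

    def test_never_clipped_negative(self, rng):
        y = rng.standard_normal(20)
        assert predict.test_r2(y, -5 * y) < 0

    def test_squared_correlation_option(self, rng):
        y = rng.standard_normal(50)
        pred = 2 * y + 1  # affine transform: correlation 1, coefficient != 1
        assert predict.test_r2(y, pred, method="squared_correlation") == pytest.approx(1.0)
        assert predict.test_r2(y, pred) < 1.0

    def test_constant_observed_missing(self):
        assert np.isnan(predict.test_r2(np.ones(5), np.arange(5.0)))


class TestRandomNull:
    def test_median_value_is_within(self, rng):
        values = {f"random_{i}": float(v) for i, v in enumerate(rng.standard_normal(100))}
        med = float(np.median(list(values.values())))
        null = predict.random_null(values, {"core": med})
        assert null.flags["core"] == "within"
        assert null.lo <= null.median <= null.hi

    def test_degenerate_identical_null(self):
        values = {f"random_{i}": 0.5 for i in range(100)}
        null = predict.random_null(values, {"a": 0.6, "b": 0.4, "c": 0.5})
        assert null.flags == {"a": "above", "b": "below", "c": "within"}

    def test_missing_replicates_error(self):
        with pytest.raises(ValueError):
            predict.random_null({"random_0": 0.1}, {})


class TestDifferences:
    def test_pair_count_formula(self):
        assert predict.n_pair_differences(100) == 4950
        for n in (2, 5, 17):
            assert predict.n_pair_differences(n) == len(
                [1 for i in range(n) for j in range(i + 1, n)]
            )

    def test_identical_records_zero_differences(self):
        records = []
        for alg in ("ridge", "nn"):
            for s in ("core", "peripheral", "random_0", "random_1"):
                records.append(PredictionRecord("t", s, alg, 0.3))
        out = predict.difference_analysis(records)
        assert np.allclose(out["lm_minus_nn"]["lm_minus_nn"], 0.0)
        assert np.allclose(out["core_minus_peripheral"]["difference"], 0.0)
        assert (out["random_pair_null"]["median"] == 0).all()

    def test_random_pair_null_count(self, rng):
        records = [
            PredictionRecord("t", f"random_{i}", "ridge", float(rng.standard_normal()))
            for i in range(10)
        ]
        out = predict.difference_analysis(records)
        assert out["random_pair_null"]["n_pairs"].iloc[0] == 45


class TestTraitStructure:
    def test_perfect_correlation_with_h2(self, rng):
        h2 = pd.Series(rng.uniform(0, 1, 8), index=[f"t{i}" for i in range(8)])
        records = [
            PredictionRecord(t, "core", "ridge", float(h2[t])) for t in h2.index
        ]
        out = predict.trait_structure_analysis(records, h2, h2 * 0.5, fst_p99=0.25)
        corr = out["correlations"]
        row = corr[(corr["set"] == "core") & (corr["parameter"] == "h2")]
        assert row["rho"].iloc[0] == pytest.approx(1.0)

    def test_single_class_comparison_skipped(self, rng):
        h2 = pd.Series(rng.uniform(0, 1, 5), index=[f"t{i}" for i in range(5)])
        qst = pd.Series(0.01, index=h2.index)
        records = [PredictionRecord(t, "core", "ridge", 0.1) for t in h2.index]
        out = predict.trait_structure_analysis(records, h2, qst, fst_p99=0.9)
        assert isinstance(out["comparison"], str)


class TestPredictSets:
    def test_test_ids_never_used_in_fitting(self, small_bundle, rng):
        """Id accounting: the split keeps test genotypes out of train/validation."""
        pops = pd.Series(
            small_bundle.design.drop_duplicates("genotype")
            .set_index("genotype")["population"]
        )
        genotypes = list(pops.index)
        for seed in range(5):
            plan = predict.make_split(genotypes, pops, seed=seed)
            assert not set(plan.test) & (set(plan.train) | set(plan.validation))

    def test_end_to_end_records_and_flags(self, small_bundle):
        from coexpred.genesets import GeneSet

        G = small_bundle.genetic_values
        pops = pd.Series(
            small_bundle.design.drop_duplicates("genotype")
            .set_index("genotype")["population"]
        )
        genes = list(G.columns)
        sets = {
            "core": GeneSet("core", genes[:12]),
            **{f"random_{i}": GeneSet(f"random_{i}", genes[12 * (i + 1):12 * (i + 2)])
               for i in range(3)},
        }
        records, nulls = predict.predict_sets(
            G, small_bundle.traits.iloc[:, :1], sets, pops,
            algorithms=("ridge",), seed=0,
        )
        assert len(records) == 4
        assert len(nulls) == 1
        assert set(nulls[0].flags) == {"core"}
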