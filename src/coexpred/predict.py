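"""Trait prediction from gene-set expression: ridge regression and a
two-hidden-layer neural network, with random-set null inference.

Genotypes are split 60/20/20 into train/validation/test, stratified by
population, once per trait and shared across all gene sets and algorithms so
set comparisons are not confounded by split noise.  Ridge chooses its penalty
by 2-fold cross-validation on the training set over a log-spaced grid and is
solved in closed form.  The network hyperparameter search is a random draw
over activation x structure x input-dropout x L1/L2 penalties (the six
structures pair layer sizes from {h, 2h/3, h/3} with the second layer no
larger than the first), capped at 100 candidates, with the winner taken at
the lowest validation RMSE.  Reported accuracy is the coefficient of
determination 1 - SSE/SST on the untouched test set (squared correlation is
available as an option); the 100 random gene sets provide the empirical 95%
interval against which the named sets are flagged.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SplitPlan",
    "PredictionRecord",
    "RandomNull",
    "make_split",
    "fit_ridge",
    "fit_nn",
    "test_r2",
    "random_null",
    "difference_analysis",
    "trait_structure_analysis",
    "predict_sets",
]


@dataclass
class SplitPlan:
    train: list[str]
    validation: list[str]
    test: list[str]
    proportions: tuple[float, float, float] = (0.60, 0.20, 0.20)
    seed: int = 0

    def __post_init__(self) -> None:
        parts = [set(self.train), set(self.validation), set(self.test)]
        if parts[0] & parts[1] or parts[0] & parts[2] or parts[1] & parts[2]:
            raise ValueError("split partitions overlap")


@dataclass
class PredictionRecord:
    trait: str
    gene_set: str
    algorithm: str                  # "ridge" | "nn"
    r2: float
    hyperparameters: dict = field(default_factory=dict)
    validation_rmse: float = float("nan")


@dataclass
class RandomNull:
    trait: str
    algorithm: str
    values: np.ndarray              # the replicate R2 values
    median: float
    lo: float                        # 2.5th percentile
    hi: float                        # 97.5th percentile
    flags: dict[str, str] = field(default_factory=dict)  # set -> above|within|below


def make_split(
    genotypes: list[str],
    populations: pd.Series,
    proportions: tuple[float, float, float] = (0.60, 0.20, 0.20),
    seed: int = 0,
    small_pop_size: int = 3,
) -> SplitPlan:
    """Population-stratified train/validation/test split.

    Populations smaller than ``small_pop_size`` are pooled into a global
    lottery rather than stratified.
    """
    if len(genotypes) < 10:
        raise ValueError("need at least 10 genotypes")
    if not np.isclose(sum(proportions), 1.0):
        raise ValueError("proportions must sum to 1")
    rng = np.random.default_rng(seed)
    pops = populations.reindex(genotypes)
    train, val, test = [], [], []
    lottery: list[str] = []
    for pop, members in pops.groupby(pops):
        ids = list(members.index)
        if len(ids) < small_pop_size:
            lottery.extend(ids)
            continue
        ids = list(rng.permutation(ids))
        n = len(ids)
        n_train = int(round(proportions[0] * n))
        n_val = int(round(proportions[1] * n))
        n_train = min(n_train, n - 2)
        train.extend(ids[:n_train])
        val.extend(ids[n_train : n_train + n_val])
        test.extend(ids[n_train + n_val :])
    if lottery:
        ids = list(rng.permutation(lottery))
        n = len(ids)
        n_train = int(round(proportions[0] * n))
        n_val = int(round(proportions[1] * n))
        train.extend(ids[:n_train])
        val.extend(ids[n_train : n_train + n_val])
        test.extend(ids[n_train + n_val :])
    return SplitPlan(train=train, validation=val, test=test,
                     proportions=proportions, seed=seed)


# ---------------------------------------------------------------------------
# ridge
# ---------------------------------------------------------------------------

def _standardize(train: np.ndarray, *others: np.ndarray):
    mu = train.mean(axis=0)
    sd = train.std(axis=0)
    sd[sd < 1e-12] = 1.0
    return tuple((arr - mu) / sd for arr in (train, *others))


def _ridge_solve(X: np.ndarray, y: np.ndarray, lam: float) -> tuple[np.ndarray, float]:
    """Closed-form ridge with unpenalized intercept (data assumed centred)."""
    n, p = X.shape
    y_mean = y.mean()
    yc = y - y_mean
    if p <= n:
        w = np.linalg.solve(X.T @ X + lam * np.eye(p), X.T @ yc)
    else:  # dual form for p >> n
        alpha = np.linalg.solve(X @ X.T + lam * np.eye(n), yc)
        w = X.T @ alpha
    return w, y_mean


class RidgeModel:
    def __init__(self, w: np.ndarray, intercept: float, mu: np.ndarray, sd: np.ndarray):
        self.w, self.intercept, self.mu, self.sd = w, intercept, mu, sd

    def predict(self, X: np.ndarray) -> np.ndarray:
        return ((X - self.mu) / self.sd) @ self.w + self.intercept


def fit_ridge(
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_val: np.ndarray | None = None,
    y_val: np.ndarray | None = None,
    lambda_grid: np.ndarray | None = None,
    n_folds: int = 2,
    seed: int = 0,
) -> tuple[RidgeModel, dict]:
    """Ridge regression with the penalty chosen by k-fold CV on the training set."""
    y_train = np.asarray(y_train, dtype=float)
    if np.std(y_train) < 1e-12:
        raise ValueError("constant training response")
    if lambda_grid is None:
        lambda_grid = np.logspace(-3, 5, 17)
    mu = X_train.mean(axis=0)
    sd = X_train.std(axis=0)
    sd[sd < 1e-12] = 1.0
    Xs = (X_train - mu) / sd

    rng = np.random.default_rng(seed)
    n = len(y_train)
    fold = rng.permutation(n) % n_folds
    cv_err = np.zeros(len(lambda_grid))
    for f in range(n_folds):
        tr, te = fold != f, fold == f
        for i, lam in enumerate(lambda_grid):
            w, b = _ridge_solve(Xs[tr], y_train[tr], lam)
            pred = Xs[te] @ w + b
            cv_err[i] += float(((pred - y_train[te]) ** 2).sum())
    best = int(np.argmin(cv_err))
    lam = float(lambda_grid[best])
    w, b = _ridge_solve(Xs, y_train, lam)
    model = RidgeModel(w, b, mu, sd)
    info = {"lambda": lam, "cv_mse": cv_err[best] / n}
    if X_val is not None and y_val is not None:
        info["validation_rmse"] = float(
            np.sqrt(np.mean((model.predict(X_val) - y_val) ** 2))
        )
    return model, info


# ---------------------------------------------------------------------------
# neural network
# ---------------------------------------------------------------------------

def nn_structures(h: int) -> list[tuple[int, int]]:
    """The six two-layer structures from sizes {h, 2h/3, h/3}, second <= first."""
    sizes = sorted({max(1, h), max(1, round(2 * h / 3)), max(1, round(h / 3))},
                   reverse=True)
    while len(sizes) < 3:          # tiny h can collapse sizes; keep 6 pairs
        sizes.append(max(1, sizes[-1] - 1) if sizes[-1] > 1 else 1)
    structures = []
    for i, l1 in enumerate(sizes[:3]):
        for l2 in sizes[i:3]:
            structures.append((l1, l2))
    return structures


class _MLP:
    """Two-hidden-layer regression MLP trained by mini-batch Adam."""

    def __init__(self, n_in, l1_size, l2_size, activation, input_dropout,
                 hidden_dropout, l1_pen, l2_pen, rng):
        self.activation = activation
        self.input_dropout = input_dropout
        self.hidden_dropout = hidden_dropout
        self.l1_pen, self.l2_pen = l1_pen, l2_pen
        self.rng = rng
        scale = {"rectifier": np.sqrt(2.0), "tanh": 1.0}[activation]
        self.W = [
            rng.standard_normal((n_in, l1_size)) * scale / np.sqrt(n_in),
            rng.standard_normal((l1_size, l2_size)) * scale / np.sqrt(l1_size),
            rng.standard_normal((l2_size, 1)) / np.sqrt(l2_size),
        ]
        self.b = [np.zeros(l1_size), np.zeros(l2_size), np.zeros(1)]
        self._adam = [(np.zeros_like(w), np.zeros_like(w)) for w in self.W] + [
            (np.zeros_like(bb), np.zeros_like(bb)) for bb in self.b
        ]
        self._t = 0

    def _act(self, z):
        return np.maximum(z, 0.0) if self.activation == "rectifier" else np.tanh(z)

    def _act_grad(self, z, a):
        return (z > 0).astype(float) if self.activation == "rectifier" else 1.0 - a**2

    def forward(self, X, train=False):
        masks = []
        H = X
        if train and self.input_dropout > 0:
            m = (self.rng.random(H.shape) >= self.input_dropout) / (1 - self.input_dropout)
            H = H * m
        zs, acts = [], [H]
        for layer in range(2):
            z = acts[-1] @ self.W[layer] + self.b[layer]
            a = self._act(z)
            if train and self.hidden_dropout > 0:
                m = (self.rng.random(a.shape) >= self.hidden_dropout) / (1 - self.hidden_dropout)
                a = a * m
                masks.append(m)
            else:
                masks.append(None)
            zs.append(z)
            acts.append(a)
        out = acts[-1] @ self.W[2] + self.b[2]
        return out.ravel(), zs, acts, masks

    def predict(self, X):
        return self.forward(X, train=False)[0]

    def train_batch(self, X, y, lr=1e-2):
        n = len(y)
        out, zs, acts, masks = self.forward(X, train=True)
        delta = (out - y)[:, None] * (2.0 / n)
        grads_W, grads_b = [None] * 3, [None] * 3
        grads_W[2] = acts[2].T @ delta
        grads_b[2] = delta.sum(axis=0)
        back = delta @ self.W[2].T
        for layer in (1, 0):
            if masks[layer] is not None:
                back = back * masks[layer]
            back = back * self._act_grad(zs[layer], acts[layer + 1])
            grads_W[layer] = acts[layer].T @ back
            grads_b[layer] = back.sum(axis=0)
            back = back @ self.W[layer].T
        for layer in range(3):
            grads_W[layer] += self.l2_pen * 2.0 * self.W[layer]
            grads_W[layer] += self.l1_pen * np.sign(self.W[layer])
        self._t += 1
        b1, b2, eps = 0.9, 0.999, 1e-8
        params = self.W + self.b
        grads = grads_W + grads_b
        for i, (p, g) in enumerate(zip(params, grads)):
            m, v = self._adam[i]
            m[:] = b1 * m + (1 - b1) * g
            v[:] = b2 * v + (1 - b2) * g**2
            mh = m / (1 - b1**self._t)
            vh = v / (1 - b2**self._t)
            p -= lr * mh / (np.sqrt(vh) + eps)


def _train_candidate(Xtr, ytr, Xval, yval, params, seed, epochs, batch_size=32,
                     stopping_tol=1e-3, stopping_rounds=10, lr=1e-2,
                     score_interval=5):
    rng = np.random.default_rng(seed)
    net = _MLP(
        Xtr.shape[1], params["l1_size"], params["l2_size"], params["activation"],
        params["input_dropout"], params["hidden_dropout"],
        params["l1"], params["l2"], rng,
    )
    n = len(ytr)
    best_rmse, best_state, since_best = np.inf, None, 0
    for epoch in range(epochs):
        order = rng.permutation(n)
        for start in range(0, n, batch_size):
            idx = order[start : start + batch_size]
            net.train_batch(Xtr[idx], ytr[idx], lr=lr)
        if (epoch + 1) % score_interval and (epoch + 1) != epochs:
            continue
        rmse = float(np.sqrt(np.mean((net.predict(Xval) - yval) ** 2)))
        if not np.isfinite(rmse):
            return None, np.inf
        if rmse < best_rmse - stopping_tol:
            best_rmse = rmse
            best_state = ([w.copy() for w in net.W], [b.copy() for b in net.b])
            since_best = 0
        else:
            since_best += 1
            if since_best >= stopping_rounds:
                break
    if best_state is not None:
        net.W, net.b = best_state
        best_rmse = float(np.sqrt(np.mean((net.predict(Xval) - yval) ** 2)))
    return net, best_rmse


class NNModel:
    def __init__(self, net: _MLP, mu: np.ndarray, sd: np.ndarray,
                 y_mu: float, y_sd: float):
        self.net, self.mu, self.sd, self.y_mu, self.y_sd = net, mu, sd, y_mu, y_sd

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.net.predict((X - self.mu) / self.sd) * self.y_sd + self.y_mu


def fit_nn(
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_val: np.ndarray,
    y_val: np.ndarray,
    max_models: int = 100,
    seed: int = 0,
    epochs: int = 200,
    batch_size: int = 32,
) -> tuple[NNModel, dict]:
    """Random hyperparameter search for the two-hidden-layer network.

    The grid: activation {rectifier, tanh} x {with, without dropout}, the six
    structures from layer sizes {h, 2h/3, h/3}, input dropout {0, 0.2}, and
    L1/L2 penalties on [0, 1e-4] in steps of 5e-6.  At most ``max_models``
    candidates are trained; non-finite losses are discarded; the winner is the
    candidate with the lowest validation RMSE.
    """
    h = X_train.shape[1]
    if h < 3:
        raise ValueError("need at least 3 input genes")
    rng = np.random.default_rng(seed)
    mu, sd = X_train.mean(axis=0), X_train.std(axis=0)
    sd[sd < 1e-12] = 1.0
    Xtr, Xval = (X_train - mu) / sd, (X_val - mu) / sd
    y_mu, y_sd = float(np.mean(y_train)), float(np.std(y_train))
    if y_sd < 1e-12:
        raise ValueError("constant training response")
    ytr, yval = (y_train - y_mu) / y_sd, (y_val - y_mu) / y_sd

    structures = nn_structures(h)
    penalties = np.arange(0.0, 1e-4 + 5e-6 / 2, 5e-6)
    best = None
    best_rmse, best_params = np.inf, None
    n_tried = 0
    for _ in range(max_models):
        params = {
            "activation": rng.choice(["rectifier", "tanh"]),
            "with_dropout": bool(rng.integers(0, 2)),
            "input_dropout": float(rng.choice([0.0, 0.2])),
            "l1": float(rng.choice(penalties)),
            "l2": float(rng.choice(penalties)),
        }
        l1_size, l2_size = structures[rng.integers(0, len(structures))]
        params["l1_size"], params["l2_size"] = int(l1_size), int(l2_size)
        params["hidden_dropout"] = 0.2 if params["with_dropout"] else 0.0
        net, rmse = _train_candidate(
            Xtr, ytr, Xval, yval, params,
            seed=int(rng.integers(0, 2**31 - 1)), epochs=epochs,
            batch_size=batch_size,
        )
        n_tried += 1
        if net is not None and rmse < best_rmse:
            best, best_rmse, best_params = net, rmse, params
    if best is None:
        raise RuntimeError("no neural-network candidate produced a finite loss")
    model = NNModel(best, mu, sd, y_mu, y_sd)
    info = {
        "validation_rmse": best_rmse * y_sd,
        "hyperparameters": best_params,
        "n_models": n_tried,
    }
    return model, info


# ---------------------------------------------------------------------------
# scoring and inference
# ---------------------------------------------------------------------------

def test_r2(
    observed: np.ndarray, predicted: np.ndarray, method: str = "coefficient"
) -> float:
    """Test-set accuracy.

    ``coefficient`` (default) is 1 - SSE/SST, which may be negative and is
    never clipped; ``squared_correlation`` is the square of the Pearson
    correlation.  A constant observed vector yields NaN.
    """
    observed = np.asarray(observed, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    sst = float(((observed - observed.mean()) ** 2).sum())
    if sst < 1e-12:
        return float("nan")
    if method == "coefficient":
        sse = float(((observed - predicted) ** 2).sum())
        return 1.0 - sse / sst
    if method == "squared_correlation":
        if np.std(predicted) < 1e-12:
            return float("nan")
        return float(np.corrcoef(observed, predicted)[0, 1] ** 2)
    raise ValueError(f"unknown method {method!r}")


def random_null(
    random_r2: dict[str, float] | pd.Series,
    named_r2: dict[str, float],
    trait: str = "",
    algorithm: str = "",
    n_expected: int = 100,
) -> RandomNull:
    """Empirical 95% interval of the random-set replicates; flag named sets."""
    values = np.asarray(list(dict(random_r2).values()), dtype=float)
    if len(values) != n_expected:
        raise ValueError(f"expected {n_expected} random replicates, got {len(values)}")
    lo, hi = np.percentile(values, [2.5, 97.5])
    flags = {}
    for name, r2 in named_r2.items():
        if r2 > hi:
            flags[name] = "above"
        elif r2 < lo:
            flags[name] = "below"
        else:
            flags[name] = "within"
    return RandomNull(
        trait=trait, algorithm=algorithm, values=values,
        median=float(np.median(values)), lo=float(lo), hi=float(hi), flags=flags,
    )


def difference_analysis(records: list[PredictionRecord]) -> dict[str, pd.DataFrame]:
    """LM - NN differences per set, core - peripheral differences per
    algorithm, and the unordered random-set pair null (n(n-1)/2 pairs)."""
    df = pd.DataFrame(
        [{"trait": r.trait, "set": r.gene_set, "algorithm": r.algorithm, "r2": r.r2}
         for r in records]
    )
    wide = df.pivot_table(index=["trait", "set"], columns="algorithm", values="r2")
    lm_nn = None
    if {"ridge", "nn"} <= set(wide.columns):
        lm_nn = (wide["ridge"] - wide["nn"]).rename("lm_minus_nn").reset_index()

    rows = []
    for (trait, alg), grp in df.groupby(["trait", "algorithm"]):
        by_set = grp.set_index("set")["r2"]
        for periph in ("peripheral", "peripheral_ng"):
            if "core" in by_set.index and periph in by_set.index:
                rows.append({"trait": trait, "algorithm": alg, "contrast": f"core-{periph}",
                             "difference": by_set["core"] - by_set[periph]})
    core_periph = pd.DataFrame(rows)

    null_rows = []
    for (trait, alg), grp in df.groupby(["trait", "algorithm"]):
        randoms = grp[grp["set"].str.startswith("random_")].set_index("set")["r2"]
        if len(randoms) < 2:
            continue
        diffs = np.array([randoms[a] - randoms[b]
                          for a, b in combinations(randoms.index, 2)])
        q1, med, q3 = np.percentile(diffs, [25, 50, 75])
        null_rows.append({"trait": trait, "algorithm": alg, "n_pairs": len(diffs),
                          "q1": q1, "median": med, "q3": q3})
    return {"lm_minus_nn": lm_nn, "core_minus_peripheral": core_periph,
            "random_pair_null": pd.DataFrame(null_rows)}


def n_pair_differences(n_sets: int) -> int:
    """Unordered pairs excluding self-comparisons: n(n-1)/2 (100 sets -> 4,950)."""
    return n_sets * (n_sets - 1) // 2


def trait_structure_analysis(
    records: list[PredictionRecord],
    trait_h2: pd.Series,
    trait_qst: pd.Series,
    fst_p99: float,
) -> dict:
    """Correlate per-trait prediction accuracy with trait h2 / Q_ST and split
    traits into structured (Q_ST above the F_ST 99th percentile) vs not."""
    df = pd.DataFrame(
        [{"trait": r.trait, "set": r.gene_set, "algorithm": r.algorithm, "r2": r.r2}
         for r in records]
    )
    corr_rows = []
    for (gs, alg), grp in df.groupby(["set", "algorithm"]):
        merged = grp.set_index("trait")["r2"]
        for name, series in (("h2", trait_h2), ("qst", trait_qst)):
            common = merged.index.intersection(series.index)
            if (len(common) < 4 or series[common].nunique() < 2
                    or merged[common].nunique() < 2):
                rho, p = np.nan, np.nan
            else:
                rho, p = stats.spearmanr(merged[common], series[common])
            corr_rows.append({"set": gs, "algorithm": alg, "parameter": name,
                              "rho": rho, "pvalue": p})
    structured = (trait_qst > fst_p99).rename("structured")
    comparison = None
    if structured.nunique() == 2:
        merged = df.join(structured, on="trait")
        comparison = (
            merged.groupby(["algorithm", "structured"])["r2"]
            .median()
            .rename("median_r2")
            .reset_index()
        )
    else:
        comparison = "all traits fall in a single structure class; comparison skipped"
    return {"correlations": pd.DataFrame(corr_rows),
            "classification": structured, "comparison": comparison}


def predict_sets(
    blups: pd.DataFrame,                    # genotype x gene
    traits: pd.DataFrame,                   # genotype x trait
    sets: dict,                             # label -> GeneSet
    populations: pd.Series,
    algorithms: tuple[str, ...] = ("ridge", "nn"),
    seed: int = 0,
    skip_full_nn: bool = True,
    nn_kwargs: dict | None = None,
) -> tuple[list[PredictionRecord], list[RandomNull]]:
    """Run every (trait, set, algorithm) combination on one shared split per
    trait and flag named sets against the random-set null."""
    nn_kwargs = nn_kwargs or {}
    records: list[PredictionRecord] = []
    nulls: list[RandomNull] = []
    genotypes = list(blups.index)
    rng = np.random.default_rng(seed)
    for trait in traits.columns:
        split_seed = int(rng.integers(0, 2**31 - 1))
        plan = make_split(genotypes, populations, seed=split_seed)
        y = traits[trait]
        ytr = y.loc[plan.train].to_numpy(dtype=float)
        yval = y.loc[plan.validation].to_numpy(dtype=float)
        yte = y.loc[plan.test].to_numpy(dtype=float)
        per_alg_random: dict[str, dict[str, float]] = {a: {} for a in algorithms}
        per_alg_named: dict[str, dict[str, float]] = {a: {} for a in algorithms}
        for label, gs in sets.items():
            Xtr = blups.loc[plan.train, gs.members].to_numpy(dtype=float)
            Xval = blups.loc[plan.validation, gs.members].to_numpy(dtype=float)
            Xte = blups.loc[plan.test, gs.members].to_numpy(dtype=float)
            for alg in algorithms:
                if alg == "nn" and label == "full" and skip_full_nn:
                    continue
                alg_seed = int(rng.integers(0, 2**31 - 1))
                if alg == "ridge":
                    model, info = fit_ridge(Xtr, ytr, Xval, yval, seed=alg_seed)
                    hyper = {"lambda": info["lambda"]}
                    vrmse = info.get("validation_rmse", float("nan"))
                else:
                    model, info = fit_nn(Xtr, ytr, Xval, yval, seed=alg_seed, **nn_kwargs)
                    hyper = info["hyperparameters"]
                    vrmse = info["validation_rmse"]
                r2 = test_r2(yte, model.predict(Xte))
                records.append(PredictionRecord(trait, label, alg, r2, hyper, vrmse))
                if label.startswith("random_"):
                    per_alg_random[alg][label] = r2
                else:
                    per_alg_named[alg][label] = r2
        for alg in algorithms:
            if per_alg_random[alg]:
                nulls.append(
                    random_null(
                        per_alg_random[alg], per_alg_named[alg], trait=trait,
                        algorithm=alg, n_expected=len(per_alg_random[alg]),
                    )
                )
    return records, nulls
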