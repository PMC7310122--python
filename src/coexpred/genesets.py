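"""Core / peripheral / random gene-set construction and set-wise comparisons.

Core genes are the top 10% of the universe by centrality (|kME| to own
module), peripheral the bottom 10%, peripheral-NG the bottom 10% among
non-grey genes (same set size, taken from the full universe), and 100 random
sets of the same size act as the null reference.  Sets are compared per
statistic with two-sided Wilcoxon rank-sum tests, Bonferroni-corrected over
all pairs tested.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .network import GREY

__all__ = ["GeneSet", "set_size", "build_sets", "compare_sets"]


@dataclass
class GeneSet:
    label: str
    members: list[str]
    provenance: str = ""

    def __post_init__(self) -> None:
        if len(set(self.members)) != len(self.members):
            raise ValueError(f"duplicate members in gene set {self.label!r}")

    def __len__(self) -> int:
        return len(self.members)

    def write(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("\n".join(self.members) + "\n")


def set_size(universe_size: int, fraction: float = 0.10) -> int:
    """floor(fraction * universe size); e.g. 10% of 34,229 genes is 3,422."""
    if not (0.0 < fraction <= 1.0):
        raise ValueError("fraction must lie in (0, 1]")
    return int(np.floor(fraction * universe_size))


def build_sets(
    centrality: pd.Series,
    modules: pd.Series,
    fraction: float = 0.10,
    n_random: int = 100,
    seed: int = 0,
) -> dict[str, GeneSet]:
    """Build full / core / peripheral / peripheral_ng / random_i sets.

    Ties in centrality are broken by stable gene-id order.  Random sets are
    drawn without replacement, independently per index, reproducibly from the
    seed.
    """
    if centrality.isna().any():
        raise ValueError("centrality scores missing for some genes")
    k = set_size(len(centrality), fraction)
    if k < 1:
        raise ValueError(f"universe of {len(centrality)} genes yields an empty set at fraction {fraction}")
    order = centrality.sort_values(kind="mergesort")  # stable: ties by gene-id order
    sorted_ids = order.index.to_list()

    non_grey = modules.reindex(centrality.index) != GREY
    non_grey_sorted = [g for g in sorted_ids if non_grey[g]]
    if len(non_grey_sorted) < k:
        raise ValueError("fewer non-grey genes than the set size")

    sets = {
        "full": GeneSet("full", list(centrality.index), "all genes"),
        "core": GeneSet("core", sorted_ids[-k:], f"top {fraction:.0%} centrality"),
        "peripheral": GeneSet("peripheral", sorted_ids[:k], f"bottom {fraction:.0%} centrality"),
        "peripheral_ng": GeneSet(
            "peripheral_ng", non_grey_sorted[:k],
            f"bottom {fraction:.0%} centrality among non-grey",
        ),
    }
    rng = np.random.default_rng(seed)
    ids = np.array(centrality.index)
    for i in range(n_random):
        draw = rng.choice(len(ids), size=k, replace=False)
        sets[f"random_{i}"] = GeneSet(
            f"random_{i}", ids[np.sort(draw)].tolist(), f"random draw {i}, seed {seed}"
        )
    return sets


def compare_sets(
    statistic: pd.Series,
    sets: dict[str, GeneSet] | list[GeneSet],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Pairwise two-sided Wilcoxon rank-sum comparisons of a per-gene statistic.

    Returns one row per set pair with medians, interquartile ranges, the raw
    and Bonferroni-adjusted p-value (family = all pairs tested).
    """
    if isinstance(sets, dict):
        sets = list(sets.values())
    values = {}
    for gs in sets:
        v = statistic.reindex(gs.members).dropna().to_numpy(dtype=float)
        if len(v) < 2:
            raise ValueError(f"set {gs.label!r} has fewer than 2 genes with the statistic")
        values[gs.label] = v
    pairs = list(combinations([gs.label for gs in sets], 2))
    n_tests = len(pairs)
    rows = []
    for a, b in pairs:
        res = stats.mannwhitneyu(values[a], values[b], alternative="two-sided")
        stat, p = float(res.statistic), float(res.pvalue)
        qa, qb = np.percentile(values[a], [25, 50, 75]), np.percentile(values[b], [25, 50, 75])
        rows.append(
            {
                "set_a": a, "set_b": b, "statistic": float(stat),
                "pvalue": float(p),
                "pvalue_bonferroni": min(float(p) * n_tests, 1.0),
                "median_a": qa[1], "iqr_a": qa[2] - qa[0],
                "median_b": qb[1], "iqr_b": qb[2] - qb[0],
                "significant": bool(p * n_tests <= alpha),
            }
        )
    return pd.DataFrame(rows)
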