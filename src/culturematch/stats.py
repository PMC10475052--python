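"""Nonparametric group comparisons: Kruskal-Wallis + post hoc pairwise tests.

The omnibus test is the tie-corrected Kruskal-Wallis H with a chi-square
approximation on k-1 degrees of freedom; post hoc comparisons are two-sided
rank-sum (Wilcoxon/Mann-Whitney) tests with multiplicity control (Holm by
default). An exact permutation route exists for tiny inputs.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

ALPHA = 0.05


@dataclass
class TestResult:
    statistic: float
    df: int
    p_value: float
    method: str
    alpha: float = ALPHA

    @property
    def significant(self) -> bool:
        return self.p_value < self.alpha


def kruskal_wallis(
    groups: Mapping[str, Sequence[float]],
    permutation: bool = False,
    n_permutations: int = 20_000,
    seed: int = 0,
) -> TestResult:
    """Tie-corrected Kruskal-Wallis H test.

    All-identical observations give H = 0, p = 1 rather than an error. With
    ``permutation=True`` the p-value comes from shuffling group labels
    instead of the chi-square approximation (for tiny samples).
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    vecs = [np.asarray(v, dtype=float) for v in groups.values()]
    if any(len(v) == 0 for v in vecs):
        raise ValueError("every group must be non-empty")
    df = len(vecs) - 1
    pooled = np.concatenate(vecs)
    if np.all(pooled == pooled[0]):
        return TestResult(0.0, df, 1.0, "kruskal-wallis (degenerate)")
    h, p = sps.kruskal(*vecs)
    if not permutation:
        return TestResult(float(h), df, float(p), "kruskal-wallis chi-square")

    rng = np.random.default_rng(seed)
    sizes = [len(v) for v in vecs]
    edges = np.cumsum(sizes)[:-1]
    count = 0
    for _ in range(n_permutations):
        perm = rng.permutation(pooled)
        parts = np.split(perm, edges)
        hp = sps.kruskal(*parts)[0]
        if hp >= h - 1e-12:
            count += 1
    return TestResult(
        float(h), df, (count + 1) / (n_permutations + 1), "kruskal-wallis permutation"
    )


def _rank_sum_exact_p(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided rank-sum p by exhaustive enumeration of group assignments."""
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    n, nx = len(pooled), len(x)
    observed = ranks[:nx].sum()
    mean = nx * (n + 1) / 2.0
    obs_dev = abs(observed - mean)
    count = total = 0
    for idx in itertools.combinations(range(n), nx):
        total += 1
        if abs(ranks[list(idx)].sum() - mean) >= obs_dev - 1e-9:
            count += 1
    return count / total


def pairwise_wilcoxon(
    groups: Mapping[str, Sequence[float]],
    adjust_method: str = "holm",
    exact_max_n: int = 8,
) -> pd.DataFrame:
    """Two-sided rank-sum test for every unordered pair of groups.

    Uses the normal approximation with tie and continuity correction;
    pairs where either group has fewer than 2 observations, or whose pooled
    size is at most ``exact_max_n``, take the exact enumeration route. The
    chosen route is recorded per pair. Adjustment: holm (default),
    bonferroni or none.
    """
    if adjust_method not in {"holm", "bonferroni", "none"}:
        raise ValueError(f"unknown adjustment {adjust_method!r}")
    names = list(groups)
    rows = []
    for a, b in itertools.combinations(names, 2):
        x = np.asarray(groups[a], dtype=float)
        y = np.asarray(groups[b], dtype=float)
        if len(x) + len(y) <= exact_max_n or min(len(x), len(y)) < 2:
            p = _rank_sum_exact_p(x, y)
            method = "exact enumeration"
        else:
            p = float(
                sps.mannwhitneyu(
                    x, y, alternative="two-sided", use_continuity=True,
                    method="asymptotic",
                ).pvalue
            )
            method = "normal approximation"
        rows.append({"group_a": a, "group_b": b, "p_raw": min(p, 1.0), "method": method})
    out = pd.DataFrame(rows)
    if out.empty:
        return out
    if adjust_method == "none":
        out["p_adjusted"] = out["p_raw"]
    else:
        out["p_adjusted"] = multipletests(out["p_raw"], method=adjust_method)[1]
    return out


def type_one_error_sim(
    n_groups: int = 4,
    n_per_group: int = 10,
    n_reps: int = 10_000,
    seed: int = 0,
    alpha: float = ALPHA,
) -> float:
    """Empirical rejection rate of the omnibus test under an iid null."""
    rng = np.random.default_rng(seed)
    rejections = 0
    for _ in range(n_reps):
        draws = rng.standard_normal((n_groups, n_per_group))
        _, p = sps.kruskal(*draws)
        if p < alpha:
            rejections += 1
    return rejections / n_reps
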