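"""Nonparametric and exact tests used throughout the analysis.

One audited layer: Mann-Whitney U, Kruskal-Wallis with Dunn's post hoc,
Pearson chi-square, Spearman rank correlation, and the exact binomial sign
test. Dunn's pairwise z is computed from pooled ranks with tie correction.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "TestResult",
    "mwu",
    "kruskal_dunn",
    "chi_square",
    "spearman",
    "sign_test",
]


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    n: tuple[int, ...]
    method: str
    adjustment: str = "none"
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not math.isnan(self.p_value):
            assert 0.0 <= self.p_value <= 1.0, "p-value outside [0, 1]"


def mwu(a, b) -> TestResult:
    """Two-sided Mann-Whitney U test.

    Exact for small tie-free samples, normal approximation with tie
    correction otherwise (scipy's default policy).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("empty sample")
    res = sps.mannwhitneyu(a, b, alternative="two-sided")
    return TestResult(
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        n=(a.size, b.size),
        method="mann-whitney-u",
    )


def _dunn_pairwise(groups: list[np.ndarray], labels: list[str], adjust: str):
    pooled = np.concatenate(groups)
    n_total = pooled.size
    ranks = sps.rankdata(pooled)
    # mean rank per group
    mean_ranks = []
    start = 0
    for g in groups:
        mean_ranks.append(ranks[start : start + g.size].mean())
        start += g.size
    # tie correction term: sum(t^3 - t) / (12 * (N - 1))
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts).sum()) / (12.0 * (n_total - 1)))
    var_base = n_total * (n_total + 1) / 12.0 - tie_term
    rows = []
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            se = math.sqrt(var_base * (1.0 / groups[i].size + 1.0 / groups[j].size))
            z = (mean_ranks[i] - mean_ranks[j]) / se
            p = 2.0 * sps.norm.sf(abs(z))
            rows.append(
                {
                    "group_a": labels[i],
                    "group_b": labels[j],
                    "z": z,
                    "p": min(p, 1.0),
                }
            )
    table = pd.DataFrame(rows)
    if adjust == "bonferroni":
        table["p_adj"] = np.minimum(table["p"] * len(table), 1.0)
    elif adjust == "bh":
        from statsmodels.stats.multitest import multipletests

        table["p_adj"] = multipletests(table["p"], method="fdr_bh")[1]
    return table


def kruskal_dunn(
    groups, labels: list[str] | None = None, adjust: str = "none"
) -> tuple[TestResult, pd.DataFrame]:
    """Kruskal-Wallis H over >= 3 groups plus Dunn's pairwise z tests.

    Dunn p-values are unadjusted by default; ``adjust`` may be
    "bonferroni" or "bh".
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 3:
        raise ValueError("kruskal_dunn requires at least 3 groups")
    for g in arrays:
        if g.size < 2:
            raise ValueError("each group needs n >= 2")
    if labels is None:
        labels = [f"group{i}" for i in range(len(arrays))]
    if all(np.array_equal(arrays[0], g) for g in arrays[1:]) and np.unique(
        arrays[0]
    ).size == 1:
        h, p = 0.0, 1.0  # all values identical: H undefined in scipy
    else:
        h, p = sps.kruskal(*arrays)
    pairwise = _dunn_pairwise(arrays, labels, adjust)
    result = TestResult(
        statistic=float(h),
        p_value=float(p),
        n=tuple(g.size for g in arrays),
        method="kruskal-wallis",
        adjustment=adjust,
    )
    return result, pairwise


def chi_square(table) -> TestResult:
    """Pearson chi-square on a contingency table (no Yates correction)."""
    obs = np.asarray(table, dtype=float)
    if (obs < 0).any():
        raise ValueError("negative counts")
    if (obs.sum(axis=0) == 0).any() or (obs.sum(axis=1) == 0).any():
        raise ValueError("zero marginal in contingency table")
    stat, p, dof, expected = sps.chi2_contingency(obs, correction=False)
    if (expected < 5).any():
        warnings.warn("chi-square expected count < 5; test may be unreliable")
    return TestResult(
        statistic=float(stat),
        p_value=float(p),
        n=(int(obs.sum()),),
        method="chi-square",
        extra={"dof": int(dof)},
    )


def spearman(x, y) -> TestResult:
    """Spearman rank correlation with average ranks for ties."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need equal-length samples with n >= 3")
    if np.unique(x).size == 1 or np.unique(y).size == 1:
        return TestResult(
            statistic=math.nan, p_value=math.nan, n=(x.size,), method="spearman"
        )
    rho, p = sps.spearmanr(x, y)
    return TestResult(
        statistic=float(rho), p_value=float(p), n=(x.size,), method="spearman"
    )


def sign_test(k: int, n: int) -> TestResult:
    """Exact two-sided binomial sign test, doubled smaller tail capped at 1.

    Tests whether k successes out of n paired comparisons depart from the
    null probability 1/2.
    """
    if n == 0:
        raise ValueError("sign test undefined for n = 0")
    if not 0 <= k <= n:
        raise ValueError("k must satisfy 0 <= k <= n")
    lower = sps.binom.cdf(k, n, 0.5)
    upper = sps.binom.sf(k - 1, n, 0.5)
    p = min(1.0, 2.0 * min(lower, upper))
    return TestResult(
        statistic=float(k), p_value=float(p), n=(n,), method="exact-sign-test"
    )
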