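"""Evaluation battery: run summaries, rank-sum and Friedman comparisons,
convergence-trace aggregation.

All metrics follow the error-rate orientation (lower is better) for both
classification error and subset size.  Tests are two-sided at alpha = 0.05
with no multiple-testing correction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

SIGNIFICANCE_LEVEL = 0.05


@dataclass(frozen=True)
class RunSummary:
    best: float
    worst: float
    mean: float
    std: float  # sample SD, H-1 denominator
    H: int
    values: np.ndarray


def summarize_runs(values) -> RunSummary:
    """Best/Worst/Mean/Std over H independent final outcomes (min is best)."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("need H >= 2 runs to summarize")
    return RunSummary(
        best=float(v.min()),
        worst=float(v.max()),
        mean=float(v.mean()),
        std=float(v.std(ddof=1)),
        H=int(v.size),
        values=v,
    )


def wilcoxon_rank_sum(sample_a, sample_b) -> float:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) p-value.

    Exact enumeration when n_a + n_b <= 12 with no ties, otherwise the
    normal approximation with tie correction.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be nonempty")
    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (a.size + b.size <= 12 and not has_ties) else "asymptotic"
    return float(sps.mannwhitneyu(a, b, alternative="two-sided", method=method).pvalue)


def is_significant(p_value: float, alpha: float = SIGNIFICANCE_LEVEL) -> bool:
    return p_value < alpha


def friedman_mean_ranks(results) -> np.ndarray:
    """Mean within-row rank per algorithm (columns) across datasets (rows).

    Rank 1 = lowest value in the row; ties get average ranks, so every row's
    ranks sum to k(k+1)/2.
    """
    M = np.asarray(results, dtype=float)
    if M.ndim != 2 or M.shape[0] < 1 or M.shape[1] < 2:
        raise ValueError("need a (datasets x algorithms) matrix with >= 2 algorithms")
    ranks = np.apply_along_axis(sps.rankdata, 1, M)
    return ranks.mean(axis=0)


def friedman_test(results):
    """Friedman chi-square statistic and p-value (needs >= 3 algorithms)."""
    M = np.asarray(results, dtype=float)
    stat, p = sps.friedmanchisquare(*(M[:, j] for j in range(M.shape[1])))
    return float(stat), float(p)


def aggregate_traces(traces) -> np.ndarray:
    """Pointwise mean of equal-length per-run convergence traces."""
    arr = np.asarray(traces, dtype=float)
    if arr.ndim != 2:
        raise ValueError("traces must be equal-length vectors")
    return arr.mean(axis=0)


def comparison_table(outcomes: dict, reference: str) -> pd.DataFrame:
    """Pairwise rank-sum p-values of each algorithm against ``reference``.

    ``outcomes`` maps algorithm name -> {dataset name -> vector of H final
    outcomes}.  Returns a (dataset x algorithm) table of p-values.
    """
    if reference not in outcomes:
        raise ValueError(f"reference algorithm {reference!r} not in outcomes")
    others = [algo for algo in outcomes if algo != reference]
    datasets = sorted(next(iter(outcomes.values())).keys())
    rows = {}
    for ds in datasets:
        rows[ds] = {
            algo: wilcoxon_rank_sum(outcomes[reference][ds], outcomes[algo][ds])
            for algo in others
        }
    return pd.DataFrame.from_dict(rows, orient="index")


def mean_rank_table(outcomes: dict) -> pd.Series:
    """Friedman mean rank per algorithm over the per-dataset mean outcomes."""
    algos = sorted(outcomes)
    datasets = sorted(next(iter(outcomes.values())).keys())
    M = np.array([[np.mean(outcomes[a][d]) for a in algos] for d in datasets])
    return pd.Series(friedman_mean_ranks(M), index=algos)
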