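"""Aggregation of fit results: BIC summaries, pairwise wins, and cross-task
parameter-consistency correlations.

Model comparison reports, per model and task, the mean, median and sample
standard deviation of the BIC difference scores across participants and the
percentage of participants for whom the cognitive model strictly beats the
baseline (BIC difference > 0). Close competitors are separated by pairwise win
counts: for each participant, which of two models achieved the higher score.

Parameter consistency asks whether the same individual's parameter estimates
agree across the two tasks. Because estimate distributions are typically far
from normal, association is measured by Spearman's rank correlation with a
one-tailed test of ρ > 0 (consistent parameters should correlate positively,
not just non-zero-ly).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .fitting import FitResult


@dataclass(frozen=True)
class ModelSummary:
    """Distribution of one model's BIC difference scores on one task."""

    model: str
    task: str
    n: int
    mean_bic: float
    median_bic: float
    sd_bic: float  # sample SD (n−1 denominator); NaN when n == 1
    pct_positive: float  # percentage of participants with bic_diff > 0


def summarize_bic(fits: Iterable[FitResult]) -> list[ModelSummary]:
    """Per-(model, task) summary of BIC difference scores.

    Grouping keys come from each fit's model spec and ``task_id``. Exact-zero
    scores do not count toward the positive percentage.
    """
    groups: dict[tuple[str, str], list[float]] = {}
    for fit in fits:
        key = (str(fit.spec), fit.task_id or "")
        groups.setdefault(key, []).append(fit.bic_diff)
    if not groups:
        raise ValueError("empty-group: no fits to summarize")
    out = []
    for (model, task), scores in sorted(groups.items()):
        arr = np.asarray(scores, dtype=float)
        out.append(
            ModelSummary(
                model=model,
                task=task,
                n=len(arr),
                mean_bic=float(arr.mean()),
                median_bic=float(np.median(arr)),
                sd_bic=float(arr.std(ddof=1)) if len(arr) > 1 else float("nan"),
                pct_positive=float(100.0 * (arr > 0).mean()),
            )
        )
    return out


def summaries_to_frame(summaries: Sequence[ModelSummary]) -> pd.DataFrame:
    """Summaries as a tidy table with the field's customary column names."""
    return pd.DataFrame(
        [
            {
                "model": s.model,
                "task": s.task,
                "n": s.n,
                "M": s.mean_bic,
                "Mdn": s.median_bic,
                "SD": s.sd_bic,
                "pct_BIC_positive": s.pct_positive,
            }
            for s in summaries
        ]
    )


@dataclass(frozen=True)
class PairwiseResult:
    """Head-to-head BIC comparison of two models over the same participants."""

    model_a: str
    model_b: str
    wins_a: int
    wins_b: int
    ties: int

    @property
    def n(self) -> int:
        return self.wins_a + self.wins_b + self.ties


def pairwise_wins(
    fits_a: Sequence[FitResult], fits_b: Sequence[FitResult]
) -> PairwiseResult:
    """Count participants on which each model's BIC difference is higher.

    The two lists must cover the same participants in the same order; equal
    scores count as ties.
    """
    if len(fits_a) != len(fits_b):
        raise ValueError("alignment-error: fit lists differ in length")
    for fa, fb in zip(fits_a, fits_b):
        if fa.participant_id != fb.participant_id or fa.task_id != fb.task_id:
            raise ValueError(
                f"alignment-error: ({fa.participant_id}, {fa.task_id}) vs "
                f"({fb.participant_id}, {fb.task_id})"
            )
    wins_a = sum(1 for fa, fb in zip(fits_a, fits_b) if fa.bic_diff > fb.bic_diff)
    wins_b = sum(1 for fa, fb in zip(fits_a, fits_b) if fb.bic_diff > fa.bic_diff)
    return PairwiseResult(
        model_a=str(fits_a[0].spec) if fits_a else "",
        model_b=str(fits_b[0].spec) if fits_b else "",
        wins_a=wins_a,
        wins_b=wins_b,
        ties=len(fits_a) - wins_a - wins_b,
    )


@dataclass(frozen=True)
class ConsistencyResult:
    """Spearman rank correlation with a one-tailed (ρ > 0) p-value."""

    parameter: str
    rho: float
    p_one_tailed: float
    rho_squared: float
    n: int
    method: str


def _exact_one_tailed_p(x: np.ndarray, y: np.ndarray, rho_obs: float) -> float:
    """Exact permutation p-value for H1: ρ > 0 (feasible for n ≤ 10).

    Permutes the ranks of one variable over all n! orderings; the Pearson
    correlation of ranks only varies through the cross-product term, so each
    permutation costs one dot product.
    """
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rxc = rx - rx.mean()
    ryc = ry - ry.mean()
    denom = np.sqrt((rxc**2).sum() * (ryc**2).sum())
    count = total = 0
    for perm in permutations(range(len(y))):
        rho = float(rxc @ ryc[list(perm)]) / denom
        count += rho >= rho_obs - 1e-12
        total += 1
    return count / total


def spearman_consistency(
    x: Sequence[float],
    y: Sequence[float],
    parameter: str = "",
    method: str = "t",
) -> ConsistencyResult:
    """Spearman's ρ between paired estimates with a one-tailed positive test.

    Ties receive average ranks. ``method="t"`` (default) uses the large-sample
    t approximation t = ρ·√((n−2)/(1−ρ²)); ``method="exact"`` enumerates all
    rank permutations (n ≤ 10 only).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D vectors")
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 pairs")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("undefined-correlation: constant input vector")
    if method not in ("t", "exact"):
        raise ValueError("method must be 't' or 'exact'")

    rho, p = stats.spearmanr(x, y, alternative="greater")
    rho = float(rho)
    if method == "exact":
        if n > 10:
            raise ValueError("exact permutation test supported only for n <= 10")
        p = _exact_one_tailed_p(x, y, rho)
    return ConsistencyResult(
        parameter=parameter,
        rho=rho,
        p_one_tailed=float(p),
        rho_squared=rho * rho,
        n=n,
        method=method,
    )


def consistency_to_frame(results: Sequence[ConsistencyResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "parameter": r.parameter,
                "rho": r.rho,
                "p_one_tailed": r.p_one_tailed,
                "rho_squared": r.rho_squared,
                "n": r.n,
            }
            for r in results
        ]
    )
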