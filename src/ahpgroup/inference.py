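"""Uncertainty quantification: bootstrap CIs and subgroup comparison tests.

Bootstrap resamples respondents with replacement within a subgroup and
re-runs the geometric-mean aggregation per replicate; intervals are
percentile-based. Subgroup differences in local weights are tested with a
two-sample t test, by default the unequal-variance (Welch) variant with
Welch-Satterthwaite degrees of freedom.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .aggregate import BlockWeights, _gm_aggregate, _stack, aggregate_aip
from .core import PriorityVector


@dataclass
class BootstrapResult:
    """Percentile bootstrap interval for one item's aggregated weight."""

    item: str
    estimate: float
    lower: float
    upper: float
    b: int
    level: float
    degenerate: bool = False


@dataclass(frozen=True)
class SubgroupComparison:
    """Two-sample t test on per-respondent local weights for one item."""

    item: str
    group_a: str
    group_b: str
    t: float
    df: float
    p: float
    mean_a: float
    mean_b: float
    n_a: int
    n_b: int
    degenerate: bool = False


def bootstrap_weights(
    vectors: Sequence[PriorityVector],
    b: int = 1000,
    level: float = 0.95,
    rng: np.random.Generator | int | None = None,
    respondent_weights: Sequence[float] | None = None,
) -> list[BootstrapResult]:
    """Percentile bootstrap CIs for the aggregated weights of one block.

    Respondents are resampled with replacement; each replicate re-runs the
    same geometric-mean aggregation as the point estimate. A single
    respondent yields a degenerate (zero-width, flagged) interval.
    """
    if b < 1:
        raise ValueError("bootstrap requires b >= 1")
    rng = np.random.default_rng(rng)
    point = aggregate_aip(vectors, respondent_weights)
    _, items, mat = _stack(vectors)
    n = mat.shape[0]
    if n < 2:
        return [
            BootstrapResult(item, w, w, w, b, level, degenerate=True)
            for item, w in zip(items, point.weights)
        ]
    if respondent_weights is None:
        base_omega = np.full(n, 1.0 / n)
    else:
        base_omega = np.asarray(respondent_weights, dtype=float)
        base_omega = base_omega / base_omega.sum()
    reps = np.empty((b, len(items)))
    for i in range(b):
        idx = rng.integers(0, n, n)
        omega = base_omega[idx]
        reps[i] = _gm_aggregate(mat[idx], omega / omega.sum())
    alpha = 1.0 - level
    lo = np.quantile(reps, alpha / 2, axis=0)
    hi = np.quantile(reps, 1 - alpha / 2, axis=0)
    return [
        BootstrapResult(item, float(point.weights[j]), float(lo[j]), float(hi[j]), b, level)
        for j, item in enumerate(items)
    ]


def bias_correcting_exponents(
    vectors: Sequence[PriorityVector],
    b: int = 200,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Respondent exponents that offset the mean bootstrap bias of the GM.

    The plain geometric mean can sit systematically below resampled
    aggregates; this estimates the mean log-scale bootstrap bias and tilts
    the exponents toward respondents whose vectors pull against it, so that
    the reweighted aggregate has (approximately) zero mean bootstrap bias.
    """
    _, items, mat = _stack(vectors)
    n = mat.shape[0]
    if n < 2:
        return np.full(n, 1.0 / n)
    rng = np.random.default_rng(rng)
    uniform = np.full(n, 1.0 / n)
    point = _gm_aggregate(mat, uniform)
    reps = np.empty((b, len(items)))
    for i in range(b):
        idx = rng.integers(0, n, n)
        reps[i] = _gm_aggregate(mat[idx], uniform)
    bias = np.log(reps.mean(axis=0)) - np.log(point)
    # Move exponent mass toward respondents anti-aligned with the bias.
    scores = (np.log(mat) - np.log(mat).mean(axis=0)) @ bias
    omega = uniform * np.exp(-scores / max(np.abs(scores).max(), 1e-12))
    return omega / omega.sum()


def welch_t(a: np.ndarray, b: np.ndarray) -> tuple[float, float, float, bool]:
    """Welch t statistic, Welch-Satterthwaite df, two-sided P.

    Returns ``(t, df, p, degenerate)``; the degenerate flag marks
    zero-variance inputs handled by exact mean comparison.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = len(a), len(b)
    if na < 2 or nb < 2:
        raise ValueError("each group needs at least 2 observations")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    diff = a.mean() - b.mean()
    if va == 0.0 and vb == 0.0:
        if diff == 0.0:
            return 0.0, float(na + nb - 2), 1.0, True
        return float(np.sign(diff) * np.inf), float(na + nb - 2), 0.0, True
    se2 = va / na + vb / nb
    t = diff / np.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), float(df), float(p), False


def pooled_t(a: np.ndarray, b: np.ndarray) -> tuple[float, float, float, bool]:
    """Classic equal-variance two-sample t test (pooled variance)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = len(a), len(b)
    if na < 2 or nb < 2:
        raise ValueError("each group needs at least 2 observations")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    df = float(na + nb - 2)
    diff = a.mean() - b.mean()
    sp2 = ((na - 1) * va + (nb - 1) * vb) / df
    if sp2 == 0.0:
        if diff == 0.0:
            return 0.0, df, 1.0, True
        return float(np.sign(diff) * np.inf), df, 0.0, True
    t = diff / np.sqrt(sp2 * (1 / na + 1 / nb))
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), df, float(p), False


def compare_subgroups(
    weights_a: Sequence[float],
    weights_b: Sequence[float],
    item: str = "",
    group_a: str = "A",
    group_b: str = "B",
    variant: str = "welch",
) -> SubgroupComparison:
    """Two-sided t test on per-respondent local weights for one item."""
    if variant == "welch":
        t, df, p, degenerate = welch_t(weights_a, weights_b)
    elif variant == "pooled":
        t, df, p, degenerate = pooled_t(weights_a, weights_b)
    else:
        raise ValueError(f"unknown test variant {variant!r}")
    a = np.asarray(weights_a, dtype=float)
    b = np.asarray(weights_b, dtype=float)
    return SubgroupComparison(
        item=item,
        group_a=group_a,
        group_b=group_b,
        t=t,
        df=df,
        p=p,
        mean_a=float(a.mean()),
        mean_b=float(b.mean()),
        n_a=len(a),
        n_b=len(b),
        degenerate=degenerate,
    )


def holm_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Holm step-down adjusted p values (supplementary output)."""
    p = np.asarray(pvalues, dtype=float)
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adj[idx] = min(1.0, running)
    return adj


def significance_table(
    cohorts: Mapping[str, Mapping[str, BlockWeights]],
    pairs: Sequence[tuple[str, str]],
    alpha: float = 0.05,
    variant: str = "welch",
):
    """All-items x all-group-pairs comparison table on local weights.

    ``cohorts`` maps subgroup -> block_id -> :class:`BlockWeights` (the
    individual local weights surviving the consistency filter). Returns a
    pandas DataFrame with one row per (block, item) and, per group pair,
    columns t, df (rounded to integer for reporting), p, significance flag
    at ``alpha``, and a clearly supplementary Holm-adjusted p.
    """
    import pandas as pd

    first = next(iter(cohorts.values()))
    rows: list[dict] = []
    comparisons: list[SubgroupComparison] = []
    for block_id, bw in first.items():
        for item in bw.items:
            row: dict = {"block": block_id, "item": item}
            for ga, gb in pairs:
                cmp_ = compare_subgroups(
                    cohorts[ga][block_id].column(item),
                    cohorts[gb][block_id].column(item),
                    item=item,
                    group_a=ga,
                    group_b=gb,
                    variant=variant,
                )
                comparisons.append(cmp_)
                tag = f"{ga}_vs_{gb}"
                row[f"t_{tag}"] = cmp_.t
                row[f"df_{tag}"] = int(round(cmp_.df))
                row[f"p_{tag}"] = cmp_.p
                row[f"sig_{tag}"] = cmp_.p < alpha
            rows.append(row)
    table = pd.DataFrame(rows)
    holm = holm_adjust([c.p for c in comparisons])
    k = 0
    for row_idx in range(len(rows)):
        for ga, gb in pairs:
            table.loc[row_idx, f"p_holm_{ga}_vs_{gb}"] = holm[k]
            k += 1
    return table
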