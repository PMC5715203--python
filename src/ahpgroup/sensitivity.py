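"""Outlier detection (boxplot rule) and rank-reversal sensitivity analysis.

Outliers per item are flagged by Tukey fences at ``Q1 - k*IQR`` and
``Q3 + k*IQR`` (quartiles by linear interpolation, the common boxplot
convention; ``k=1.5`` by default). The sensitivity analysis removes the
flagged respondents, re-aggregates, re-ranks with the same tie rule, and
reports any pair of items whose relative order changed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .aggregate import (
    BlockWeights,
    GroupLocalWeights,
    Ranking,
    aggregate_aip,
    compute_global_weights,
    rank_items,
)
from .hierarchy import Hierarchy


@dataclass
class OutlierReport:
    """Tukey-fence outlier flags for one item within one subgroup."""

    item: str
    subgroup: str
    flagged_ids: tuple[str, ...]
    flagged_values: tuple[float, ...]
    lower_fence: float | None
    upper_fence: float | None
    k: float


@dataclass
class RankReversalReport:
    """Baseline vs post-exclusion rankings for one subgroup."""

    subgroup: str
    removed_ids: tuple[str, ...]
    baseline: dict[str, Ranking]
    post_exclusion: dict[str, Ranking]
    reversed_pairs: tuple[tuple[str, str, str], ...]  # (scope, item_x, item_y)

    @property
    def reversal(self) -> bool:
        return len(self.reversed_pairs) > 0


def detect_outliers(
    values: Sequence[float],
    ids: Sequence[str] | None = None,
    k: float = 1.5,
    item: str = "",
    subgroup: str = "",
) -> OutlierReport:
    """Flag observations strictly outside the Tukey fences.

    With fewer than 4 observations no fences are computed, nothing is
    flagged, and a warning is emitted.
    """
    vals = np.asarray(values, dtype=float)
    if ids is None:
        ids = tuple(str(i) for i in range(len(vals)))
    ids = tuple(ids)
    if len(ids) != len(vals):
        raise ValueError("ids and values lengths differ")
    if len(vals) < 4:
        warnings.warn(
            f"outlier detection needs >= 4 observations, got {len(vals)}; "
            "no fences computed",
            UserWarning,
            stacklevel=2,
        )
        return OutlierReport(item, subgroup, (), (), None, None, k)
    q1, q3 = np.quantile(vals, [0.25, 0.75])  # linear interpolation
    iqr = q3 - q1
    lo = q1 - k * iqr
    hi = q3 + k * iqr
    mask = (vals < lo) | (vals > hi)
    return OutlierReport(
        item,
        subgroup,
        tuple(np.array(ids)[mask].tolist()),
        tuple(vals[mask].tolist()),
        float(lo),
        float(hi),
        k,
    )


def detect_cohort_outliers(
    cohort: Mapping[str, BlockWeights],
    k: float = 1.5,
    subgroup: str = "",
) -> list[OutlierReport]:
    """Run the boxplot rule for every item of every block in a cohort."""
    reports = []
    for block_id, bw in cohort.items():
        for item in bw.items:
            reports.append(
                detect_outliers(
                    bw.column(item), bw.respondent_ids, k=k, item=item, subgroup=subgroup
                )
            )
    return reports


def _cohort_rankings(
    h: Hierarchy,
    cohort: Mapping[str, BlockWeights],
    precision: int,
) -> dict[str, Ranking]:
    locals_ = {
        block_id: aggregate_aip(bw.vectors()) for block_id, bw in cohort.items()
    }
    level2 = locals_[h.root]
    level3 = {b: g for b, g in locals_.items() if b != h.root}
    rankings = {
        block_id: rank_items(g.items, g.weights, precision)
        for block_id, g in locals_.items()
    }
    gw = compute_global_weights(h, level2, level3)
    if gw.items:  # a hierarchy may have no leaf blocks at all
        rankings["global"] = rank_items(gw.items, gw.weights, precision)
    return rankings


def _reversed_pairs(base: Ranking, post: Ranking) -> list[tuple[str, str]]:
    out = []
    items = base.items
    for i in range(len(items)):
        for j in range(i + 1, len(items)):
            a, b = items[i], items[j]
            if b not in post.items or a not in post.items:
                continue
            d0 = base.exact_ranks[base.items.index(a)] - base.exact_ranks[base.items.index(b)]
            d1 = post.exact_ranks[post.items.index(a)] - post.exact_ranks[post.items.index(b)]
            if np.sign(d0) != np.sign(d1):
                out.append((a, b))
    return out


def rank_reversal_analysis(
    h: Hierarchy,
    cohort: Mapping[str, BlockWeights],
    outliers: Sequence[OutlierReport],
    scope: str = "respondent",
    precision: int = 3,
    subgroup: str = "",
) -> RankReversalReport:
    """Re-aggregate without flagged respondents and report rank changes.

    ``scope="respondent"`` (default) removes a flagged respondent from all
    blocks; ``scope="item"`` removes them only from the block containing
    the flagged item. Raises if an exclusion empties any block.
    """
    if scope not in ("respondent", "item"):
        raise ValueError(f"unknown removal scope {scope!r}")
    baseline = _cohort_rankings(h, cohort, precision)

    flagged_all = {rid for rep in outliers for rid in rep.flagged_ids}
    item_block = {
        item: block_id for block_id, bw in cohort.items() for item in bw.items
    }
    reduced: dict[str, BlockWeights] = {}
    for block_id, bw in cohort.items():
        if scope == "respondent":
            drop = flagged_all
        else:
            drop = {
                rid
                for rep in outliers
                if item_block.get(rep.item) == block_id
                for rid in rep.flagged_ids
            }
        new = bw.drop(drop)
        if len(new.respondent_ids) == 0:
            raise ValueError(
                f"outlier exclusion empties block {block_id!r} of subgroup "
                f"{subgroup or '?'}"
            )
        reduced[block_id] = new

    post = _cohort_rankings(h, reduced, precision)
    reversed_pairs: list[tuple[str, str, str]] = []
    for key in baseline:
        for a, b in _reversed_pairs(baseline[key], post[key]):
            reversed_pairs.append((key, a, b))
    return RankReversalReport(
        subgroup=subgroup,
        removed_ids=tuple(sorted(flagged_all)),
        baseline=baseline,
        post_exclusion=post,
        reversed_pairs=tuple(reversed_pairs),
    )
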