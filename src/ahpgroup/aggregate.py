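"""Group aggregation of individual priorities and ranking.

Individual priority vectors are combined per block with a (possibly
exponent-weighted) component-wise geometric mean and renormalized to sum to
one. Global leaf weights multiply the level-2 local weight of a category
with the level-3 local weight of its element. Rankings are tie-aware: items
whose weights coincide after rounding to the reporting precision share a
rank set.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .core import PriorityVector
from .hierarchy import Hierarchy


class AggregationError(ValueError):
    pass


@dataclass
class GroupLocalWeights:
    """Aggregated local weights for one block, with per-item dispersion."""

    block_id: str
    items: tuple[str, ...]
    weights: np.ndarray
    sd: np.ndarray
    n_respondents: int

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.items, self.weights.tolist()))


@dataclass
class GlobalWeights:
    """Global leaf weights (level-2 local x level-3 local), tree order."""

    items: tuple[str, ...]
    weights: np.ndarray

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.items, self.weights.tolist()))


@dataclass
class Ranking:
    """Descending-weight ranking with rounded-tie sets.

    ``rank_sets[i]`` is the tuple of positions shared by ``items[i]`` (a
    single position when untied); ``labels[i]`` renders it, e.g. ``"3/4"``.
    ``exact_ranks`` breaks ties at full precision (ties broken by item
    order) and is emitted alongside for diagnostics.
    """

    items: tuple[str, ...]
    weights: np.ndarray
    rank_sets: tuple[tuple[int, ...], ...]
    labels: tuple[str, ...]
    exact_ranks: tuple[int, ...]
    precision: int

    def rank_of(self, item: str) -> tuple[int, ...]:
        return self.rank_sets[self.items.index(item)]

    def label_of(self, item: str) -> str:
        return self.labels[self.items.index(item)]

    def order(self) -> tuple[str, ...]:
        """Items sorted by descending weight (exact-rank order)."""
        return tuple(
            item for _, item in sorted(zip(self.exact_ranks, self.items))
        )


def _gm_aggregate(matrix: np.ndarray, omega: np.ndarray) -> np.ndarray:
    """Exponent-weighted geometric mean of rows, renormalized to sum one."""
    g = np.exp(omega @ np.log(matrix))
    return g / g.sum()


def _stack(vectors: Sequence[PriorityVector]) -> tuple[str, tuple[str, ...], np.ndarray]:
    if not vectors:
        raise AggregationError("no priority vectors to aggregate")
    block_id = vectors[0].block_id
    items = vectors[0].items
    for v in vectors:
        if v.block_id != block_id or v.items != items:
            raise AggregationError(
                f"mismatched blocks in aggregation: {v.block_id!r}/{v.items} "
                f"vs {block_id!r}/{items}"
            )
    mat = np.vstack([v.weights for v in vectors])
    if np.any(mat <= 0):
        raise AggregationError(
            f"block {block_id!r}: zero weight component, geometric mean undefined"
        )
    return block_id, items, mat


def aggregate_aip(
    vectors: Sequence[PriorityVector],
    respondent_weights: Sequence[float] | None = None,
) -> GroupLocalWeights:
    """Aggregate individual priorities via (weighted) geometric means.

    ``respondent_weights`` are nonnegative exponents, one per respondent;
    they are normalized to sum to one (uniform 1/N when omitted). The SD
    column is the sample standard deviation (ddof=1) of the individual
    weights per item; NaN for a single respondent.
    """
    block_id, items, mat = _stack(vectors)
    n = mat.shape[0]
    if respondent_weights is None:
        omega = np.full(n, 1.0 / n)
    else:
        omega = np.asarray(respondent_weights, dtype=float)
        if omega.shape != (n,):
            raise AggregationError(
                f"{len(omega)} respondent weights for {n} respondents"
            )
        if np.any(omega < 0) or omega.sum() <= 0:
            raise AggregationError("respondent weights must be nonnegative")
        omega = omega / omega.sum()
    weights = _gm_aggregate(mat, omega)
    sd = np.std(mat, axis=0, ddof=1) if n > 1 else np.full(mat.shape[1], np.nan)
    return GroupLocalWeights(block_id, items, weights, sd, n)


def compute_global_weights(
    h: Hierarchy,
    level2: GroupLocalWeights,
    level3: Mapping[str, GroupLocalWeights],
) -> GlobalWeights:
    """Propagate level-2 local weights to level-3 leaves.

    Each leaf's global weight = its category's level-2 local weight times
    its own level-3 local weight (unrounded). Childless level-2 categories
    contribute no leaves.
    """
    parent_weight = level2.as_dict()
    items: list[str] = []
    weights: list[float] = []
    for cat in h.children(h.root):
        if not cat.children:
            continue
        if cat.id not in parent_weight:
            raise AggregationError(f"no level-2 weight for category {cat.id!r}")
        if cat.id not in level3:
            raise AggregationError(f"no level-3 weights for block {cat.id!r}")
        local = level3[cat.id]
        for item, w in local.as_dict().items():
            items.append(item)
            weights.append(parent_weight[cat.id] * w)
    return GlobalWeights(tuple(items), np.array(weights))


def rank_items(
    items: Sequence[str],
    weights: Sequence[float],
    report_precision: int = 3,
) -> Ranking:
    """Descending ranking with ties at the reporting precision.

    Items equal after rounding to ``report_precision`` decimals share a
    rank set covering all their positions (``(3, 4)`` renders as ``"3/4"``).
    """
    items = tuple(items)
    w = np.asarray(weights, dtype=float)
    if len(items) == 0:
        raise AggregationError("cannot rank an empty item set")
    rounded = np.round(w, report_precision)
    # Sort by rounded desc, then exact desc, then item id for determinism.
    order = sorted(range(len(items)), key=lambda i: (-rounded[i], -w[i], items[i]))
    exact_order = sorted(range(len(items)), key=lambda i: (-w[i], items[i]))
    exact_ranks = [0] * len(items)
    for pos, i in enumerate(exact_order, start=1):
        exact_ranks[i] = pos

    rank_sets: list[tuple[int, ...]] = [()] * len(items)
    pos = 0
    while pos < len(order):
        tied = [order[pos]]
        while (
            pos + len(tied) < len(order)
            and rounded[order[pos + len(tied)]] == rounded[order[pos]]
        ):
            tied.append(order[pos + len(tied)])
        positions = tuple(range(pos + 1, pos + len(tied) + 1))
        for i in tied:
            rank_sets[i] = positions
        pos += len(tied)
    labels = tuple("/".join(str(p) for p in rs) for rs in rank_sets)
    return Ranking(items, w, tuple(rank_sets), labels, tuple(exact_ranks), report_precision)


@dataclass
class BlockWeights:
    """Individual local weights of one subgroup for one block (N x k)."""

    block_id: str
    items: tuple[str, ...]
    respondent_ids: tuple[str, ...]
    weights: np.ndarray

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.shape != (len(self.respondent_ids), len(self.items)):
            raise ValueError("weights shape does not match respondents x items")

    def vectors(self) -> list[PriorityVector]:
        return [
            PriorityVector(self.block_id, self.items, row) for row in self.weights
        ]

    def column(self, item: str) -> np.ndarray:
        return self.weights[:, self.items.index(item)]

    def drop(self, respondent_ids: set[str]) -> "BlockWeights":
        keep = [i for i, r in enumerate(self.respondent_ids) if r not in respondent_ids]
        return BlockWeights(
            self.block_id,
            self.items,
            tuple(self.respondent_ids[i] for i in keep),
            self.weights[keep],
        )
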