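"""Per-respondent AHP mathematics.

Judgment matrices, principal-eigenvector priorities, the consistency
index/ratio, and the consistency filter. The eigenvector is computed by
power iteration on the positive reciprocal matrix; for such matrices the
Perron root dominates strictly, so convergence is guaranteed.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .hierarchy import ComparisonBlock

#: Admissible verbal-scale grid: 1/9 ... 1/2, 1, 2 ... 9.
SAATY_GRID: np.ndarray = np.array(
    [1.0 / k for k in range(9, 1, -1)] + [float(k) for k in range(1, 10)]
)

#: Published random-index values (mean CI of random reciprocal matrices), n=1..10.
DEFAULT_RANDOM_INDEX: dict[int, float] = {
    1: 0.0,
    2: 0.0,
    3: 0.58,
    4: 0.90,
    5: 1.12,
    6: 1.24,
    7: 1.32,
    8: 1.41,
    9: 1.45,
    10: 1.49,
}

RECIPROCITY_RTOL = 1e-12


class MatrixError(ValueError):
    """Invalid judgment set or pairwise matrix."""


class ConvergenceError(RuntimeError):
    """Power iteration failed to converge (corrupt, non-positive input)."""


@dataclass(frozen=True)
class Judgment:
    """One pairwise comparison: how many times item_a outweighs item_b."""

    respondent_id: str
    block_id: str
    item_a: str
    item_b: str
    value: float
    subgroup: str = ""

    def __post_init__(self):
        if not self.value > 0:
            raise MatrixError(
                f"judgment value must be positive, got {self.value!r} "
                f"({self.item_a} vs {self.item_b})"
            )
        if self.item_a == self.item_b:
            raise MatrixError(f"self-comparison {self.item_a!r} vs itself")


@dataclass
class PairwiseMatrix:
    """Reciprocal judgment matrix for one comparison block."""

    block_id: str
    items: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.items)
        if self.values.shape != (n, n):
            raise MatrixError(
                f"matrix shape {self.values.shape} does not match {n} items"
            )

    @property
    def n(self) -> int:
        return len(self.items)

    def validate(self) -> None:
        a = self.values
        if not np.all(a > 0):
            raise MatrixError(f"block {self.block_id!r}: non-positive entries")
        if not np.allclose(np.diag(a), 1.0, rtol=RECIPROCITY_RTOL, atol=0):
            raise MatrixError(f"block {self.block_id!r}: diagonal is not all ones")
        if not np.allclose(a * a.T, 1.0, rtol=1e-9, atol=0):
            raise MatrixError(f"block {self.block_id!r}: reciprocity violated")


@dataclass
class PriorityVector:
    """Normalized weights over one block's items (sum to one)."""

    block_id: str
    items: tuple[str, ...]
    weights: np.ndarray

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.shape != (len(self.items),):
            raise ValueError("weights length does not match items")

    def validate(self) -> None:
        if abs(self.weights.sum() - 1.0) > 1e-9:
            raise ValueError(
                f"block {self.block_id!r}: weights sum to {self.weights.sum()}"
            )
        if np.any(self.weights < 0):
            raise ValueError(f"block {self.block_id!r}: negative weight")

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.items, self.weights.tolist()))


@dataclass(frozen=True)
class ConsistencyReport:
    """Consistency diagnostics for one judgment matrix."""

    block_id: str
    n: int
    lambda_max: float
    ci: float
    cr: float
    consistent: bool


def is_on_saaty_scale(value: float, rtol: float = 1e-6) -> bool:
    """True if ``value`` lies on the 1/9..9 verbal-scale grid."""
    return bool(np.any(np.isclose(value, SAATY_GRID, rtol=rtol, atol=0)))


def snap_to_saaty(value: float) -> float:
    """Nearest grid point in log space (treats k and 1/k symmetrically)."""
    if not value > 0:
        raise MatrixError(f"cannot snap non-positive value {value!r}")
    idx = int(np.argmin(np.abs(np.log(SAATY_GRID) - math.log(value))))
    return float(SAATY_GRID[idx])


def build_matrix(judgments: Iterable[Judgment], block: ComparisonBlock) -> PairwiseMatrix:
    """Assemble the reciprocal matrix for one block from raw judgments.

    Exactly one judgment per unordered item pair is required; orientation
    may be either way (a value recorded for (B, A) is placed as its
    reciprocal for (A, B)). Duplicate pairs raise :class:`MatrixError`.
    """
    items = block.item_ids
    index = {item: i for i, item in enumerate(items)}
    n = len(items)
    a = np.eye(n)
    seen: set[frozenset] = set()
    for j in judgments:
        if j.item_a not in index or j.item_b not in index:
            raise MatrixError(
                f"judgment {j.item_a!r} vs {j.item_b!r} does not belong to "
                f"block {block.block_id!r}"
            )
        key = frozenset((j.item_a, j.item_b))
        if key in seen:
            raise MatrixError(
                f"duplicate judgment for pair {j.item_a!r}/{j.item_b!r} in "
                f"block {block.block_id!r}"
            )
        seen.add(key)
        ia, ib = index[j.item_a], index[j.item_b]
        a[ia, ib] = j.value
        a[ib, ia] = 1.0 / j.value
    missing = [
        (items[i], items[k])
        for i in range(n)
        for k in range(i + 1, n)
        if frozenset((items[i], items[k])) not in seen
    ]
    if missing:
        raise MatrixError(
            f"block {block.block_id!r}: missing judgment(s) for pair(s) {missing}"
        )
    return PairwiseMatrix(block.block_id, items, a)


def _power_iteration(
    mats: np.ndarray, tol: float = 1e-12, max_iter: int = 10_000
) -> tuple[np.ndarray, np.ndarray]:
    """Principal eigenpair of a batch of positive matrices.

    ``mats`` has shape ``(..., n, n)``; returns (weights with shape
    ``(..., n)`` summing to one along the last axis, lambda_max with shape
    ``(...,)``).
    """
    mats = np.asarray(mats, dtype=float)
    n = mats.shape[-1]
    v = np.full(mats.shape[:-1], 1.0 / n)
    for _ in range(max_iter):
        w = np.einsum("...ij,...j->...i", mats, v)
        total = w.sum(axis=-1, keepdims=True)
        if not np.all(np.isfinite(total)) or np.any(total <= 0):
            raise ConvergenceError("iteration produced non-positive vector")
        w = w / total
        if np.max(np.abs(w - v)) <= tol:
            v = w
            break
        v = w
    else:
        raise ConvergenceError(
            f"power iteration did not converge within {max_iter} iterations"
        )
    lam = np.einsum("...ij,...j->...i", mats, v).sum(axis=-1)
    return v, lam


def principal_eigenvector(m: PairwiseMatrix) -> tuple[PriorityVector, float]:
    """Normalized right principal eigenvector and lambda_max of ``m``."""
    m.validate()
    w, lam = _power_iteration(m.values)
    return PriorityVector(m.block_id, m.items, w), float(lam)


def consistency_index(lambda_max: float, n: int) -> float:
    """CI = (lambda_max - n) / (n - 1), clipped to zero within tolerance."""
    if n < 2:
        raise ValueError(f"consistency index requires n >= 2, got {n}")
    if lambda_max < n - 1e-9:
        raise ValueError(f"lambda_max {lambda_max} below matrix order {n}")
    return max(0.0, (lambda_max - n) / (n - 1))


def consistency_ratio(
    ci: float, n: int, ri: Mapping[int, float] = DEFAULT_RANDOM_INDEX
) -> float:
    """CR = CI / RI(n); zero by convention when RI(n) = 0 (n <= 2)."""
    if n not in ri:
        raise ValueError(f"no random-index value for matrix order {n}")
    denom = ri[n]
    if denom == 0.0:
        return 0.0
    return ci / denom


def matrix_consistency(
    m: PairwiseMatrix,
    ri: Mapping[int, float] = DEFAULT_RANDOM_INDEX,
    threshold: float = 0.2,
) -> ConsistencyReport:
    """Full consistency diagnostics for a single matrix."""
    _, lam = principal_eigenvector(m)
    ci = consistency_index(lam, m.n)
    cr = consistency_ratio(ci, m.n, ri)
    return ConsistencyReport(m.block_id, m.n, lam, ci, cr, cr <= threshold)


def respondent_consistency(
    matrices: Sequence[PairwiseMatrix],
    ri: Mapping[int, float] = DEFAULT_RANDOM_INDEX,
    rule: str = "mean",
    threshold: float = 0.2,
) -> tuple[dict[str, ConsistencyReport], float]:
    """Per-block consistency reports plus one respondent-level CR.

    ``rule`` combines the block CRs into a single respondent value:
    ``"mean"`` (default) or ``"max"``.
    """
    if not matrices:
        raise ValueError("respondent has no judgment matrices")
    if rule not in ("mean", "max"):
        raise ValueError(f"unknown respondent CR rule {rule!r}")
    reports = {m.block_id: matrix_consistency(m, ri, threshold) for m in matrices}
    crs = [r.cr for r in reports.values()]
    combined = float(np.mean(crs)) if rule == "mean" else float(np.max(crs))
    return reports, combined


@dataclass
class FilterResult:
    """Outcome of the consistency filter over a cohort."""

    included: list[str]
    excluded: list[str]
    threshold: float
    summary: dict = field(default_factory=dict)


def filter_consistent(
    respondent_crs: Mapping[str, float],
    threshold: float = 0.2,
    subgroups: Mapping[str, str] | None = None,
) -> FilterResult:
    """Partition respondents by CR <= threshold (boundary inclusive).

    The summary reports mean/median/SD of the CR distribution and, when
    ``subgroups`` maps respondent id -> subgroup label, per-subgroup
    inclusion percentages rounded to whole percent.
    """
    if not threshold > 0:
        raise ValueError("threshold must be positive")
    ids = list(respondent_crs)
    included = [r for r in ids if respondent_crs[r] <= threshold]
    excluded = [r for r in ids if respondent_crs[r] > threshold]
    crs = np.array([respondent_crs[r] for r in ids], dtype=float)
    if len(ids) == 0:
        summary: dict = {"n": 0, "defined": False}
    else:
        summary = {
            "n": len(ids),
            "defined": True,
            "mean_cr": float(np.mean(crs)),
            "median_cr": float(np.median(crs)),
            "sd_cr": float(np.std(crs, ddof=1)) if len(ids) > 1 else 0.0,
            "n_included": len(included),
            "n_excluded": len(excluded),
            "pct_included": round(100 * len(included) / len(ids)),
        }
    if subgroups is not None:
        per_group: dict[str, dict] = {}
        for rid in ids:
            g = subgroups.get(rid, "")
            per_group.setdefault(g, {"n": 0, "n_included": 0})
            per_group[g]["n"] += 1
            per_group[g]["n_included"] += int(rid in set(included))
        for g, stats in per_group.items():
            stats["n_excluded"] = stats["n"] - stats["n_included"]
            stats["pct_included"] = round(100 * stats["n_included"] / stats["n"])
            stats["pct_excluded"] = round(100 * stats["n_excluded"] / stats["n"])
        summary["subgroups"] = per_group
    return FilterResult(included, excluded, threshold, summary)


def warn_off_scale(values: Iterable[float], source: str = "judgments") -> int:
    """Warn (once) if any value is off the verbal-scale grid; returns count."""
    off = [v for v in values if not is_on_saaty_scale(v)]
    if off:
        warnings.warn(
            f"{len(off)} {source} value(s) are off the 1/9..9 verbal-scale "
            f"grid; treating them as continuous ratios",
            UserWarning,
            stacklevel=2,
        )
    return len(off)
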