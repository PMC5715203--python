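"""Synthetic questionnaire cohorts with known latent preference structure.

Respondents are simulated under the standard multiplicative-error model for
pairwise ratio judgments: the judgment for items ``(i, j)`` is
``(w_i / w_j) * exp(eps)`` with ``eps ~ Normal(0, sigma^2)`` independent per
pair, which preserves reciprocity by construction. Optionally the value is
snapped to the nearest point of the 1/9..9 verbal-scale grid in log space.
Inconsistent respondents are generated by inflating ``sigma``.

The generating profiles (the latent truth) are retained so that pipeline
estimates can be scored against them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import Judgment, _power_iteration, snap_to_saaty
from .hierarchy import Hierarchy, build_default_hierarchy


@dataclass
class SubgroupProfile:
    """Latent preference structure and noise regime for one subgroup."""

    name: str
    n: int
    level2: np.ndarray
    level3: dict[str, np.ndarray]
    sigma: float = 0.1
    saaty_snap: bool = False
    inconsistent_fraction: float = 0.0
    sigma_bad: float = 0.8

    def __post_init__(self):
        self.level2 = _normalize(self.level2, "level2")
        self.level3 = {b: _normalize(w, b) for b, w in self.level3.items()}
        if self.sigma < 0 or self.sigma_bad < 0:
            raise ValueError("noise scales must be nonnegative")
        if not 0.0 <= self.inconsistent_fraction <= 1.0:
            raise ValueError("inconsistent_fraction must lie in [0, 1]")

    def latent_for_block(self, h: Hierarchy, block_id: str) -> np.ndarray:
        if block_id == h.root:
            return self.level2
        return self.level3[block_id]


@dataclass
class SyntheticCohort:
    """Generated judgments + demographics with the generating truth attached."""

    judgments: list[Judgment]
    demographics: pd.DataFrame
    truth: dict[str, SubgroupProfile]
    seed: int
    hierarchy: Hierarchy = field(default_factory=build_default_hierarchy)


def _normalize(w, label: str) -> np.ndarray:
    w = np.asarray(w, dtype=float)
    if np.any(w <= 0):
        raise ValueError(f"latent weights for {label!r} must be positive")
    return w / w.sum()


def generate_respondent(
    profile: SubgroupProfile,
    rng: np.random.Generator,
    hierarchy: Hierarchy | None = None,
    respondent_id: str = "r0",
    sigma: float | None = None,
) -> list[Judgment]:
    """Judgments for one respondent over every block of the hierarchy.

    Pair orientation is randomized; the recorded value implies its
    reciprocal for the opposite orientation. ``sigma`` overrides the
    profile's noise scale (used internally for inconsistent respondents).
    """
    h = hierarchy or build_default_hierarchy()
    s = profile.sigma if sigma is None else sigma
    out: list[Judgment] = []
    for block in h.blocks():
        latent = profile.latent_for_block(h, block.block_id)
        idx = {item: i for i, item in enumerate(block.item_ids)}
        for i in range(block.size):
            for j in range(i + 1, block.size):
                a, b = block.item_ids[i], block.item_ids[j]
                value = (latent[idx[a]] / latent[idx[b]]) * np.exp(rng.normal(0.0, s))
                if profile.saaty_snap:
                    value = snap_to_saaty(value)
                if rng.random() < 0.5:  # randomize recorded orientation
                    a, b, value = b, a, 1.0 / value
                out.append(
                    Judgment(
                        respondent_id=respondent_id,
                        block_id=block.block_id,
                        item_a=a,
                        item_b=b,
                        value=float(value),
                        subgroup=profile.name,
                    )
                )
    return out


def generate_cohort(
    profiles: Sequence[SubgroupProfile],
    seed: int,
    hierarchy: Hierarchy | None = None,
) -> SyntheticCohort:
    """Deterministic multi-subgroup cohort with demographics and truth.

    Demographics roughly match the motivating study's margins: about a
    48:128 male:female split and ages 17-87. Within each subgroup the first
    ``round(n * inconsistent_fraction)`` respondents are drawn at the
    inflated noise scale ``sigma_bad``.
    """
    names = [p.name for p in profiles]
    if len(set(names)) != len(names):
        raise ValueError("subgroup names must be distinct")
    h = hierarchy or build_default_hierarchy()
    rng = np.random.default_rng(seed)
    judgments: list[Judgment] = []
    demo_rows: list[dict] = []
    for profile in profiles:
        n_bad = int(round(profile.n * profile.inconsistent_fraction))
        for i in range(profile.n):
            rid = f"{profile.name}_{i:03d}"
            sigma = profile.sigma_bad if i < n_bad else None
            judgments.extend(
                generate_respondent(profile, rng, h, respondent_id=rid, sigma=sigma)
            )
            demo_rows.append(
                {
                    "respondent_id": rid,
                    "subgroup": profile.name,
                    "sex": "male" if rng.random() < 48 / 176 else "female",
                    "age": int(rng.integers(17, 88)),
                }
            )
    demographics = pd.DataFrame(
        demo_rows, columns=["respondent_id", "subgroup", "sex", "age"]
    )
    return SyntheticCohort(
        judgments=judgments,
        demographics=demographics,
        truth={p.name: p for p in profiles},
        seed=seed,
        hierarchy=h,
    )


def sample_block_matrices(
    latent: Sequence[float],
    sigma: float,
    size: int,
    rng: np.random.Generator,
    snap: bool = False,
) -> np.ndarray:
    """Batch of ``size`` noisy reciprocal matrices around one latent vector."""
    w = _normalize(latent, "latent")
    k = len(w)
    ratio = w[:, None] / w[None, :]
    eps = rng.normal(0.0, sigma, size=(size, k, k))
    eps = np.triu(eps, 1)
    eps = eps - np.transpose(eps, (0, 2, 1))
    mats = ratio[None, :, :] * np.exp(eps)
    if snap:
        grid = np.log(np.array([1 / x for x in range(9, 1, -1)] + list(range(1, 10)), dtype=float))
        logm = np.log(mats)
        snapped = grid[np.argmin(np.abs(logm[..., None] - grid), axis=-1)]
        iu = np.triu_indices(k, 1)
        mats = np.ones_like(mats)
        mats[:, iu[0], iu[1]] = np.exp(snapped[:, iu[0], iu[1]])
        mats[:, iu[1], iu[0]] = 1.0 / mats[:, iu[0], iu[1]]
    return mats


def sample_priority_vectors(
    latent: Sequence[float],
    sigma: float,
    size: int,
    rng: np.random.Generator,
    snap: bool = False,
) -> np.ndarray:
    """Per-respondent eigenvector priorities under the noise model.

    Generates ``size`` noisy judgment matrices around ``latent`` and returns
    their principal eigenvectors, shape ``(size, k)`` — the same math the
    full pipeline applies to parsed questionnaires.
    """
    mats = sample_block_matrices(latent, sigma, size, rng, snap=snap)
    weights, _ = _power_iteration(mats)
    return weights


def kendall_distance(order_a: Sequence[int], order_b: Sequence[int]) -> int:
    """Number of discordant pairs between two rank assignments."""
    a = np.asarray(order_a)
    b = np.asarray(order_b)
    if a.shape != b.shape:
        raise ValueError("rank vectors differ in length")
    d = 0
    for i in range(len(a)):
        for j in range(i + 1, len(a)):
            if np.sign(a[i] - a[j]) != np.sign(b[i] - b[j]):
                d += 1
    return d


def recovery_error(
    profile: SubgroupProfile,
    estimates: Mapping[str, "GroupLocalWeights"],
    hierarchy: Hierarchy | None = None,
) -> dict[str, dict[str, float]]:
    """Score pipeline estimates against the generating latent vectors.

    For each block: the maximum absolute weight error and the Kendall
    distance (discordant pairs) between estimated and latent full-precision
    rankings.
    """
    h = hierarchy or build_default_hierarchy()
    out: dict[str, dict[str, float]] = {}
    for block_id, est in estimates.items():
        latent = profile.latent_for_block(h, block_id)
        w = np.asarray(est.weights)
        rank_est = (-w).argsort().argsort()
        rank_true = (-latent).argsort().argsort()
        out[block_id] = {
            "max_abs_error": float(np.max(np.abs(w - latent))),
            "kendall_distance": float(kendall_distance(rank_est, rank_true)),
        }
    return out


# -- packaged default profiles ----------------------------------------------

_STUDY_LIKE = {
    "patient": {
        "n": 120,
        "level2": [0.21, 0.21, 0.30, 0.28],
        "medical_issues": [0.34, 0.37, 0.30],
        "research": [0.32, 0.32, 0.36],
        "social_help_offers": [0.35, 0.32, 0.33],
    },
    "family": {
        "n": 24,
        "level2": [0.13, 0.22, 0.22, 0.43],
        "medical_issues": [0.24, 0.20, 0.56],
        "research": [0.31, 0.16, 0.52],
        "social_help_offers": [0.35, 0.33, 0.33],
    },
    "physician": {
        "n": 32,
        "level2": [0.13, 0.18, 0.26, 0.42],
        "medical_issues": [0.23, 0.37, 0.40],
        "research": [0.44, 0.25, 0.32],
        "social_help_offers": [0.29, 0.32, 0.40],
    },
}


def default_profiles(
    kind: str = "study-like",
    sigma: float = 0.15,
    saaty_snap: bool = False,
    inconsistent_fraction: float = 0.0,
    hierarchy: Hierarchy | None = None,
) -> list[SubgroupProfile]:
    """Packaged latent profiles for the three stakeholder subgroups.

    ``kind="study-like"`` uses heterogeneous vectors resembling published
    group weights (for qualitative realism only); ``kind="uniform"`` makes
    every latent vector flat, the null configuration for calibration tests.
    Subgroup sizes default to 120 / 24 / 32.
    """
    h = hierarchy or build_default_hierarchy()
    l3_blocks = [b.block_id for b in h.blocks() if b.block_id != h.root]
    profiles = []
    for name, spec in _STUDY_LIKE.items():
        if kind == "study-like":
            level2 = spec["level2"]
            level3 = {b: spec[b] for b in l3_blocks}
        elif kind == "uniform":
            level2 = np.full(len(h.node(h.root).children), 1.0)
            level3 = {b: np.full(len(h.block(b).item_ids), 1.0) for b in l3_blocks}
        else:
            raise ValueError(f"unknown profile kind {kind!r}")
        profiles.append(
            SubgroupProfile(
                name=name,
                n=spec["n"],
                level2=np.asarray(level2, dtype=float),
                level3={b: np.asarray(w, dtype=float) for b, w in level3.items()},
                sigma=sigma,
                saaty_snap=saaty_snap,
                inconsistent_fraction=inconsistent_fraction,
            )
        )
    return profiles
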