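"""End-to-end orchestration: filter -> priorities -> aggregation -> ranking
-> bootstrap -> subgroup tests -> sensitivity, plus report writing.

All randomness flows from the single seed in :class:`RunConfig`; every
stochastic stage draws from an independent child generator so the run is
replayable. The configuration (including the random-index table, the
respondent-CR rule and the aggregation scheme) is echoed into the report.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import io as qio
from .aggregate import (
    BlockWeights,
    GlobalWeights,
    GroupLocalWeights,
    Ranking,
    aggregate_aip,
    compute_global_weights,
    rank_items,
)
from .core import (
    DEFAULT_RANDOM_INDEX,
    FilterResult,
    Judgment,
    build_matrix,
    filter_consistent,
    principal_eigenvector,
    respondent_consistency,
)
from .hierarchy import Hierarchy, build_default_hierarchy
from .inference import (
    BootstrapResult,
    bias_correcting_exponents,
    bootstrap_weights,
    significance_table,
)
from .sensitivity import (
    OutlierReport,
    RankReversalReport,
    detect_cohort_outliers,
    rank_reversal_analysis,
)

logger = logging.getLogger("ahpgroup")


class PipelineError(RuntimeError):
    pass


class InputError(PipelineError):
    """Unreadable or malformed input files."""


class EmptySubgroupError(PipelineError):
    """A subgroup has no respondents left after the consistency filter."""


class ConfigError(PipelineError):
    """Invalid run configuration."""


_AGGREGATION_MODES = ("gm", "wgm-uniform", "wgm-bias")
_CR_RULES = ("mean", "max")
_TEST_VARIANTS = ("welch", "pooled")


@dataclass
class RunConfig:
    """Validated parameters of one analysis run."""

    input: str | None = None
    demographics: str | None = None
    hierarchy: str | None = None
    cr_threshold: float = 0.2
    cr_rule: str = "mean"
    aggregation: str = "gm"
    report_precision: int = 3
    bootstrap_b: int = 1000
    ci_level: float = 0.95
    test_variant: str = "welch"
    outlier_k: float = 1.5
    outlier_scope: str = "respondent"
    seed: int = 0
    random_index: dict[int, float] = field(
        default_factory=lambda: dict(DEFAULT_RANDOM_INDEX)
    )

    def validate(self) -> None:
        if not self.cr_threshold > 0:
            raise ConfigError("cr_threshold must be positive")
        if self.cr_rule not in _CR_RULES:
            raise ConfigError(f"cr_rule must be one of {_CR_RULES}")
        if self.aggregation not in _AGGREGATION_MODES:
            raise ConfigError(f"aggregation must be one of {_AGGREGATION_MODES}")
        if self.test_variant not in _TEST_VARIANTS:
            raise ConfigError(f"test_variant must be one of {_TEST_VARIANTS}")
        if not 0 < self.ci_level < 1:
            raise ConfigError("ci_level must lie in (0, 1)")
        if self.bootstrap_b < 1:
            raise ConfigError("bootstrap_b must be >= 1")
        if self.report_precision < 0:
            raise ConfigError("report_precision must be >= 0")
        if self.outlier_k <= 0:
            raise ConfigError("outlier_k must be positive")
        if self.outlier_scope not in ("respondent", "item"):
            raise ConfigError("outlier_scope must be 'respondent' or 'item'")

    @classmethod
    def from_yaml(cls, path, **overrides) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        cfg = cls(**data)
        cfg.validate()
        return cfg

    def to_dict(self) -> dict:
        d = asdict(self)
        d["random_index"] = {int(k): v for k, v in d["random_index"].items()}
        return d


@dataclass
class RespondentResult:
    """Per-respondent priorities and consistency diagnostics."""

    respondent_id: str
    subgroup: str
    priorities: dict[str, np.ndarray]  # block_id -> weights
    block_cr: dict[str, float]
    cr: float


@dataclass
class SubgroupResult:
    """All aggregated outputs for one subgroup."""

    subgroup: str
    n_included: int
    local: dict[str, GroupLocalWeights]
    global_weights: GlobalWeights
    local_rankings: dict[str, Ranking]
    global_ranking: Ranking
    bootstrap: dict[str, list[BootstrapResult]] = field(default_factory=dict)
    outliers: list[OutlierReport] = field(default_factory=list)
    rank_reversal: RankReversalReport | None = None


@dataclass
class SampleSummary:
    """Cohort characteristics split by subgroup and filter outcome."""

    per_subgroup: dict[str, dict]
    totals: dict


@dataclass
class RunReport:
    config: dict
    sample_summary: SampleSummary
    filter_result: FilterResult
    subgroups: dict[str, SubgroupResult]
    significance: pd.DataFrame | None
    funnel: dict
    stage_errors: dict[str, str] = field(default_factory=dict)


# ---------------------------------------------------------------------------


def compute_respondent_priorities(
    judgments: Sequence[Judgment],
    hierarchy: Hierarchy,
    random_index: Mapping[int, float] = DEFAULT_RANDOM_INDEX,
    cr_rule: str = "mean",
    cr_threshold: float = 0.2,
) -> dict[str, RespondentResult]:
    """Eigenvector priorities and consistency per respondent, all blocks."""
    blocks = {b.block_id: b for b in hierarchy.blocks()}
    by_respondent: dict[str, dict[str, list[Judgment]]] = {}
    subgroup_of: dict[str, str] = {}
    for j in judgments:
        if j.block_id not in blocks:
            raise InputError(
                f"judgment references unknown block {j.block_id!r} "
                f"(respondent {j.respondent_id})"
            )
        by_respondent.setdefault(j.respondent_id, {}).setdefault(
            j.block_id, []
        ).append(j)
        subgroup_of.setdefault(j.respondent_id, j.subgroup)

    out: dict[str, RespondentResult] = {}
    for rid, per_block in by_respondent.items():
        missing = sorted(set(blocks) - set(per_block))
        if missing:
            raise InputError(
                f"respondent {rid!r} lacks judgments for block(s) {missing}"
            )
        matrices = [build_matrix(per_block[b], blocks[b]) for b in blocks]
        priorities = {}
        for m in matrices:
            vec, _ = principal_eigenvector(m)
            priorities[m.block_id] = vec.weights
        reports, cr = respondent_consistency(
            matrices, random_index, rule=cr_rule, threshold=cr_threshold
        )
        out[rid] = RespondentResult(
            respondent_id=rid,
            subgroup=subgroup_of[rid],
            priorities=priorities,
            block_cr={b: r.cr for b, r in reports.items()},
            cr=cr,
        )
    return out


def build_cohorts(
    respondents: Mapping[str, RespondentResult],
    included: Sequence[str],
    hierarchy: Hierarchy,
) -> dict[str, dict[str, BlockWeights]]:
    """subgroup -> block_id -> individual local weights of included respondents."""
    blocks = hierarchy.blocks()
    groups: dict[str, list[str]] = {}
    for rid in included:
        groups.setdefault(respondents[rid].subgroup, []).append(rid)
    cohorts: dict[str, dict[str, BlockWeights]] = {}
    for subgroup, rids in groups.items():
        cohorts[subgroup] = {
            b.block_id: BlockWeights(
                b.block_id,
                b.item_ids,
                tuple(rids),
                np.vstack([respondents[r].priorities[b.block_id] for r in rids]),
            )
            for b in blocks
        }
    return cohorts


def summarize_sample(
    demographics: pd.DataFrame,
    included: Sequence[str],
    excluded: Sequence[str] | None = None,
) -> SampleSummary:
    """Cohort characteristics split by subgroup and included/excluded status.

    Every id in the inclusion partition must have a demographics record;
    a missing record raises :class:`InputError` naming the id. When
    ``excluded`` is omitted, all remaining respondents count as excluded.
    """
    known = set(demographics["respondent_id"])
    included = list(included)
    if excluded is None:
        excluded = [r for r in demographics["respondent_id"] if r not in set(included)]
    for rid in list(included) + list(excluded):
        if rid not in known:
            raise InputError(f"respondent {rid!r} has no demographics record")
    inc_set = set(included)
    df = demographics.copy()
    df["included"] = df["respondent_id"].map(lambda r: r in inc_set)

    per_subgroup: dict[str, dict] = {}
    for subgroup, sub in df.groupby("subgroup", sort=False):
        stats: dict = {"n": int(len(sub))}
        for status, part in (("included", sub[sub["included"]]), ("excluded", sub[~sub["included"]])):
            entry: dict = {"n": int(len(part))}
            if "sex" in part.columns:
                entry["male"] = int((part["sex"] == "male").sum())
                entry["female"] = int((part["sex"] == "female").sum())
            if "age" in part.columns and len(part):
                entry["age_mean"] = float(part["age"].mean())
                entry["age_min"] = float(part["age"].min())
                entry["age_max"] = float(part["age"].max())
            stats[status] = entry
        total = stats["n"]
        stats["pct_included"] = round(100 * stats["included"]["n"] / total) if total else 0
        stats["pct_excluded"] = round(100 * stats["excluded"]["n"] / total) if total else 0
        per_subgroup[subgroup] = stats

    totals = {
        "n": int(len(df)),
        "included": int(df["included"].sum()),
        "excluded": int((~df["included"]).sum()),
    }
    if "sex" in df.columns:
        totals["male"] = int((df["sex"] == "male").sum())
        totals["female"] = int((df["sex"] == "female").sum())
    if "age" in df.columns and len(df):
        totals["age_mean"] = float(df["age"].mean())
        totals["age_min"] = float(df["age"].min())
        totals["age_max"] = float(df["age"].max())
    totals["pct_included"] = round(100 * totals["included"] / totals["n"]) if len(df) else 0
    return SampleSummary(per_subgroup, totals)


def _aggregate_block(
    bw: BlockWeights, mode: str, rng: np.random.Generator
) -> GroupLocalWeights:
    vectors = bw.vectors()
    if mode in ("gm", "wgm-uniform"):
        return aggregate_aip(vectors)
    omega = bias_correcting_exponents(vectors, rng=rng)
    return aggregate_aip(vectors, omega)


def run_pipeline(
    config: RunConfig,
    judgments: Sequence[Judgment] | None = None,
    demographics: pd.DataFrame | None = None,
    hierarchy: Hierarchy | None = None,
) -> RunReport:
    """Execute the full analysis; deterministic given the config seed.

    Inputs may be passed in memory (``judgments``/``demographics``) or read
    from the paths in ``config``. Stage failures in bootstrap or sensitivity
    are recorded in ``report.stage_errors`` rather than silently skipped;
    structural failures (unreadable input, empty post-filter subgroup,
    invalid config) raise.
    """
    config.validate()
    if hierarchy is None:
        hierarchy = (
            Hierarchy.from_yaml(config.hierarchy)
            if config.hierarchy
            else build_default_hierarchy()
        )
    if judgments is None:
        if config.input is None:
            raise InputError("no judgments: neither in-memory data nor input path")
        try:
            judgments = qio.read_judgments(config.input)
        except OSError as exc:
            raise InputError(f"cannot read judgments file: {exc}") from exc
    if demographics is None and config.demographics is not None:
        try:
            demographics = qio.read_demographics(config.demographics)
        except OSError as exc:
            raise InputError(f"cannot read demographics file: {exc}") from exc

    seeds = np.random.SeedSequence(config.seed).spawn(2)
    rng_boot = np.random.default_rng(seeds[0])
    rng_agg = np.random.default_rng(seeds[1])

    logger.info("priorities: computing eigenvector weights per respondent")
    respondents = compute_respondent_priorities(
        judgments, hierarchy, config.random_index, config.cr_rule, config.cr_threshold
    )
    subgroup_of = {rid: r.subgroup for rid, r in respondents.items()}
    logger.info("priorities: %d respondents", len(respondents))

    filt = filter_consistent(
        {rid: r.cr for rid, r in respondents.items()},
        threshold=config.cr_threshold,
        subgroups=subgroup_of,
    )
    funnel = {
        "respondents_in": len(respondents),
        "included": len(filt.included),
        "excluded": len(filt.excluded),
    }
    logger.info(
        "consistency filter (CR <= %s, rule=%s): %d -> %d",
        config.cr_threshold,
        config.cr_rule,
        funnel["respondents_in"],
        funnel["included"],
    )

    all_subgroups = list(dict.fromkeys(subgroup_of.values()))
    cohorts = build_cohorts(respondents, filt.included, hierarchy)
    for g in all_subgroups:
        if g not in cohorts:
            raise EmptySubgroupError(
                f"subgroup {g!r} has no respondents left after the CR filter"
            )

    subgroup_results: dict[str, SubgroupResult] = {}
    stage_errors: dict[str, str] = {}
    for subgroup in all_subgroups:
        cohort = cohorts[subgroup]
        local = {
            block_id: _aggregate_block(bw, config.aggregation, rng_agg)
            for block_id, bw in cohort.items()
        }
        level2 = local[hierarchy.root]
        level3 = {b: g for b, g in local.items() if b != hierarchy.root}
        gw = compute_global_weights(hierarchy, level2, level3)
        local_rankings = {
            b: rank_items(g.items, g.weights, config.report_precision)
            for b, g in local.items()
        }
        global_ranking = rank_items(gw.items, gw.weights, config.report_precision)
        result = SubgroupResult(
            subgroup=subgroup,
            n_included=len(cohort[hierarchy.root].respondent_ids),
            local=local,
            global_weights=gw,
            local_rankings=local_rankings,
            global_ranking=global_ranking,
        )
        try:
            result.bootstrap = {
                block_id: bootstrap_weights(
                    bw.vectors(), config.bootstrap_b, config.ci_level, rng_boot
                )
                for block_id, bw in cohort.items()
            }
        except Exception as exc:  # recorded, not silently skipped
            stage_errors[f"bootstrap/{subgroup}"] = str(exc)
        try:
            result.outliers = detect_cohort_outliers(
                cohort, k=config.outlier_k, subgroup=subgroup
            )
            result.rank_reversal = rank_reversal_analysis(
                hierarchy,
                cohort,
                result.outliers,
                scope=config.outlier_scope,
                precision=config.report_precision,
                subgroup=subgroup,
            )
        except Exception as exc:
            stage_errors[f"sensitivity/{subgroup}"] = str(exc)
        subgroup_results[subgroup] = result
        logger.info("subgroup %s: n=%d aggregated", subgroup, result.n_included)

    significance = None
    if len(all_subgroups) >= 2:
        pairs = [
            (all_subgroups[i], all_subgroups[j])
            for i in range(len(all_subgroups))
            for j in range(i + 1, len(all_subgroups))
        ]
        try:
            significance = significance_table(
                cohorts, pairs, variant=config.test_variant
            )
        except Exception as exc:
            stage_errors["significance"] = str(exc)

    if demographics is not None:
        summary = summarize_sample(demographics, filt.included, filt.excluded)
    else:
        demo = pd.DataFrame(
            {
                "respondent_id": list(respondents),
                "subgroup": [subgroup_of[r] for r in respondents],
            }
        )
        summary = summarize_sample(demo, filt.included, filt.excluded)

    return RunReport(
        config=config.to_dict(),
        sample_summary=summary,
        filter_result=filt,
        subgroups=subgroup_results,
        significance=significance,
        funnel=funnel,
        stage_errors=stage_errors,
    )


# -- serialization -----------------------------------------------------------


def _ranking_dict(r: Ranking) -> dict:
    return {
        "items": list(r.items),
        "weights": [float(w) for w in r.weights],
        "labels": list(r.labels),
        "rank_sets": [list(s) for s in r.rank_sets],
        "exact_ranks": list(r.exact_ranks),
        "precision": r.precision,
    }


def report_to_dict(report: RunReport) -> dict:
    """Machine-readable structured summary (full precision, JSON-safe)."""
    out: dict = {
        "config": report.config,
        "funnel": report.funnel,
        "filter": {
            "included": sorted(report.filter_result.included),
            "excluded": sorted(report.filter_result.excluded),
            "threshold": report.filter_result.threshold,
            "summary": report.filter_result.summary,
        },
        "sample_summary": {
            "per_subgroup": report.sample_summary.per_subgroup,
            "totals": report.sample_summary.totals,
        },
        "stage_errors": report.stage_errors,
        "subgroups": {},
    }
    for name, sg in report.subgroups.items():
        entry: dict = {
            "n_included": sg.n_included,
            "local": {
                b: {
                    "items": list(g.items),
                    "weights": [float(w) for w in g.weights],
                    "sd": [None if np.isnan(s) else float(s) for s in g.sd],
                    "n": g.n_respondents,
                }
                for b, g in sg.local.items()
            },
            "global": {
                "items": list(sg.global_weights.items),
                "weights": [float(w) for w in sg.global_weights.weights],
            },
            "local_rankings": {b: _ranking_dict(r) for b, r in sg.local_rankings.items()},
            "global_ranking": _ranking_dict(sg.global_ranking),
            "bootstrap": {
                b: [
                    {
                        "item": r.item,
                        "estimate": r.estimate,
                        "lower": r.lower,
                        "upper": r.upper,
                        "b": r.b,
                        "level": r.level,
                        "degenerate": r.degenerate,
                    }
                    for r in results
                ]
                for b, results in sg.bootstrap.items()
            },
            "outliers": [
                {
                    "item": o.item,
                    "flagged_ids": list(o.flagged_ids),
                    "flagged_values": list(o.flagged_values),
                    "lower_fence": o.lower_fence,
                    "upper_fence": o.upper_fence,
                    "k": o.k,
                }
                for o in sg.outliers
            ],
        }
        if sg.rank_reversal is not None:
            entry["rank_reversal"] = {
                "removed_ids": list(sg.rank_reversal.removed_ids),
                "reversal": sg.rank_reversal.reversal,
                "reversed_pairs": [list(p) for p in sg.rank_reversal.reversed_pairs],
            }
        out["subgroups"][name] = entry
    if report.significance is not None:
        out["significance"] = report.significance.to_dict(orient="records")
    return out


def _ranking_frame(sg: SubgroupResult, hierarchy: Hierarchy) -> pd.DataFrame:
    """One row per item: local weight, SD, global weight, local/global rank."""
    gw = sg.global_weights.as_dict()
    global_label = {
        item: sg.global_ranking.label_of(item) for item in sg.global_ranking.items
    }
    rows = []
    level2 = sg.local[hierarchy.root]
    l2_rank = sg.local_rankings[hierarchy.root]
    for cat in hierarchy.children(hierarchy.root):
        i = level2.items.index(cat.id)
        rows.append(
            {
                "item": cat.id,
                "level": 2,
                "parent": hierarchy.root,
                "local_weight": float(level2.weights[i]),
                "sd": float(level2.sd[i]),
                "global_weight": None,
                "local_rank": l2_rank.label_of(cat.id),
                "global_rank": None,
            }
        )
        if cat.id in sg.local:
            l3 = sg.local[cat.id]
            l3_rank = sg.local_rankings[cat.id]
            for j, item in enumerate(l3.items):
                rows.append(
                    {
                        "item": item,
                        "level": 3,
                        "parent": cat.id,
                        "local_weight": float(l3.weights[j]),
                        "sd": float(l3.sd[j]),
                        "global_weight": gw[item],
                        "local_rank": l3_rank.label_of(item),
                        "global_rank": global_label[item],
                    }
                )
    return pd.DataFrame(rows)


def write_report(report: RunReport, out_dir, hierarchy: Hierarchy | None = None) -> list[Path]:
    """Write delimited tables plus the structured JSON summary and config echo."""
    h = hierarchy or build_default_hierarchy()
    out = Path(out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise PipelineError(f"cannot create output directory {out}: {exc}") from exc
    written: list[Path] = []

    def _write_csv(df: pd.DataFrame, name: str) -> None:
        path = out / name
        df.to_csv(path, index=False)
        written.append(path)

    # Sample summary (one row per subgroup x status).
    rows = []
    for subgroup, stats in report.sample_summary.per_subgroup.items():
        for status in ("included", "excluded"):
            row = {"subgroup": subgroup, "status": status, **stats[status]}
            rows.append(row)
    _write_csv(pd.DataFrame(rows), "sample_summary.csv")

    for name, sg in report.subgroups.items():
        _write_csv(_ranking_frame(sg, h), f"ranking_{name}.csv")
        if sg.bootstrap:
            brows = [
                {
                    "block": b,
                    "item": r.item,
                    "estimate": r.estimate,
                    "lower": r.lower,
                    "upper": r.upper,
                }
                for b, results in sg.bootstrap.items()
                for r in results
            ]
            _write_csv(pd.DataFrame(brows), f"bootstrap_{name}.csv")
        orows = [
            {
                "item": o.item,
                "lower_fence": o.lower_fence,
                "upper_fence": o.upper_fence,
                "flagged_ids": ";".join(o.flagged_ids),
                "flagged_values": ";".join(str(v) for v in o.flagged_values),
            }
            for o in sg.outliers
        ]
        _write_csv(pd.DataFrame(orows), f"outliers_{name}.csv")
        if sg.rank_reversal is not None:
            rr = sg.rank_reversal
            _write_csv(
                pd.DataFrame(
                    [
                        {
                            "removed_ids": ";".join(rr.removed_ids),
                            "reversal": rr.reversal,
                            "reversed_pairs": ";".join(
                                "|".join(p) for p in rr.reversed_pairs
                            ),
                        }
                    ]
                ),
                f"rank_reversal_{name}.csv",
            )

    if report.significance is not None:
        _write_csv(report.significance, "significance.csv")

    summary_path = out / "summary.json"
    summary_path.write_text(json.dumps(report_to_dict(report), indent=2, sort_keys=True))
    written.append(summary_path)
    config_path = out / "config.json"
    config_path.write_text(json.dumps(report.config, indent=2, sort_keys=True))
    written.append(config_path)
    return written
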