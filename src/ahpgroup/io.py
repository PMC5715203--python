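"""Delimited-text readers and writers for questionnaire data.

Judgments file: one row per pairwise comparison with columns
``respondent_id, subgroup, block_id, item_a, item_b, value``; the value may
be a decimal or a ``"1/k"`` fraction literal. Demographics file: one row per
respondent with at least ``respondent_id, subgroup, sex, age``.
"""

from __future__ import annotations

from fractions import Fraction
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .core import Judgment, warn_off_scale

JUDGMENT_COLUMNS = ["respondent_id", "subgroup", "block_id", "item_a", "item_b", "value"]


def parse_ratio(text) -> float:
    """Parse a judgment value: decimal (``0.5``) or fraction literal (``1/2``)."""
    if isinstance(text, (int, float)):
        return float(text)
    s = str(text).strip()
    if "/" in s:
        return float(Fraction(s))
    return float(s)


def format_ratio(value: float) -> str:
    """Render a value as a short fraction when exact, else as a decimal."""
    frac = Fraction(value).limit_denominator(9)
    if float(frac) == value and frac.numerator <= 9 and frac.denominator <= 9:
        return str(frac.numerator) if frac.denominator == 1 else f"{frac.numerator}/{frac.denominator}"
    return repr(value)


def read_judgments(path, check_scale: bool = True) -> list[Judgment]:
    """Read a judgments file into :class:`~ahpgroup.core.Judgment` records.

    Off-grid values trigger a warning (not an error) when ``check_scale``
    is set; continuous ratios are accepted.
    """
    df = pd.read_csv(path, dtype=str)
    missing = [c for c in JUDGMENT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"judgments file {path} lacks column(s) {missing}")
    out = [
        Judgment(
            respondent_id=row.respondent_id,
            subgroup=row.subgroup,
            block_id=row.block_id,
            item_a=row.item_a,
            item_b=row.item_b,
            value=parse_ratio(row.value),
        )
        for row in df.itertuples()
    ]
    if check_scale:
        warn_off_scale([j.value for j in out])
    return out


def write_judgments(judgments: Iterable[Judgment], path) -> None:
    """Write judgments so that :func:`read_judgments` round-trips exactly."""
    df = pd.DataFrame(
        [
            {
                "respondent_id": j.respondent_id,
                "subgroup": j.subgroup,
                "block_id": j.block_id,
                "item_a": j.item_a,
                "item_b": j.item_b,
                "value": format_ratio(j.value),
            }
            for j in judgments
        ],
        columns=JUDGMENT_COLUMNS,
    )
    df.to_csv(path, index=False)


def read_demographics(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = ["respondent_id", "subgroup"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"demographics file {path} lacks column(s) {missing}")
    df["respondent_id"] = df["respondent_id"].astype(str)
    return df


def write_demographics(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def write_truth(cohort, path) -> None:
    """Persist a synthetic cohort's generating truth as structured text."""
    import json

    payload = {
        "seed": cohort.seed,
        "profiles": {
            name: {
                "n": p.n,
                "sigma": p.sigma,
                "saaty_snap": p.saaty_snap,
                "inconsistent_fraction": p.inconsistent_fraction,
                "sigma_bad": p.sigma_bad,
                "level2": p.level2.tolist(),
                "level3": {b: w.tolist() for b, w in p.level3.items()},
            }
            for name, p in cohort.truth.items()
        },
    }
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))
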