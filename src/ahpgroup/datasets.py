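"""Bundled reference data: demographic margins of the motivating survey.

The original questionnaire-level data of the rare-disease information
survey are not public; what is public are the marginal counts of its
sociodemographic table (N=176 across three stakeholder subgroups, split by
whether the respondent survived the consistency filter) and the intake
counts by collection mode. These margins are expanded here into one row per
respondent so that the sample-summary machinery can be exercised and
checked against the published totals.
"""

from __future__ import annotations

import pandas as pd

# (subgroup, included?) -> counts by sex and the subgroup-inclusion mean age.
_MARGINS = [
    # subgroup, included, male, female, mean age
    ("patient", True, 11, 56, 51),
    ("patient", False, 18, 35, 50),
    ("family", True, 2, 14, 46),
    ("family", False, 1, 7, 49),
    ("physician", True, 13, 12, 42),
    ("physician", False, 3, 4, 49),
]

#: Questionnaires collected per mode.
INTAKE_COUNTS = {"web": 112, "paper": 64}


def study_demographics() -> pd.DataFrame:
    """One row per respondent, reproducing the published margins.

    Columns: ``respondent_id, subgroup, sex, age, included``. Ages carry the
    subgroup-level mean (individual ages were never published); sex and
    inclusion counts match the published table exactly.
    """
    rows = []
    counter: dict[str, int] = {}
    for subgroup, included, male, female, age in _MARGINS:
        for sex, count in (("male", male), ("female", female)):
            for _ in range(count):
                i = counter.get(subgroup, 0)
                counter[subgroup] = i + 1
                rows.append(
                    {
                        "respondent_id": f"{subgroup}_{i:03d}",
                        "subgroup": subgroup,
                        "sex": sex,
                        "age": age,
                        "included": included,
                    }
                )
    return pd.DataFrame(rows)


def study_inclusion() -> set[str]:
    """Ids of the respondents retained by the consistency filter."""
    df = study_demographics()
    return set(df.loc[df["included"], "respondent_id"])


def study_intake_total() -> int:
    """Total questionnaires collected across both collection modes."""
    return sum(INTAKE_COUNTS.values())
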