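"""Age-matching verification via pooled-variance two-sample t-tests.

Single-subject rating against a normative cohort is only meaningful if
the control groups are demographically matched, so each patient
phenotype group is compared to its sex-matched control group with a
Student (pooled-variance) two-sample t-test on age.  The pooled test is
used deliberately: its degrees of freedom are n1 + n2 - 2 and it
degrades gracefully to the control-group variance when a patient group
has a single member.  The sign convention is control minus patient
(positive t = controls older).

Tests can be run from raw ages or from published summary statistics
(mean, SD, n); the two modes agree exactly when the raw data reproduce
the summaries.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import CohortTable, Role, Sex

__all__ = [
    "GroupAgeSummary",
    "TTestResult",
    "two_sample_t_from_summary",
    "summaries_from_cohort",
    "matching_table",
    "ftd_cohort_age_summaries",
]


@dataclass(frozen=True)
class GroupAgeSummary:
    label: str
    sex: Sex
    mean: float  # years
    sd: float    # years, n-1 denominator (0 permitted when n = 1)
    n: int

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.sd < 0:
            raise ValueError("sd must be >= 0")


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: int
    p: float  # two-sided


def two_sample_t_from_summary(control: GroupAgeSummary,
                              patient: GroupAgeSummary) -> TTestResult:
    """Pooled-variance Student t-test from group summaries.

    t = (mean_control - mean_patient) / sqrt(s2 * (1/n1 + 1/n2)) with
    s2 the pooled variance on n1 + n2 - 2 degrees of freedom.
    """
    n1, n2 = control.n, patient.n
    df = n1 + n2 - 2
    if df < 1:
        raise ValueError("need n1 + n2 >= 3")
    s2 = ((n1 - 1) * control.sd ** 2 + (n2 - 1) * patient.sd ** 2) / df
    if s2 <= 0.0:
        raise ValueError("pooled variance is zero: degenerate age data")
    t = (control.mean - patient.mean) / math.sqrt(s2 * (1.0 / n1 + 1.0 / n2))
    p = 2.0 * float(stats.t.sf(abs(t), df))
    return TTestResult(t=t, df=df, p=p)


def summaries_from_cohort(cohort: CohortTable) -> tuple[list[GroupAgeSummary],
                                                        list[GroupAgeSummary]]:
    """Per-(phenotype, sex) patient summaries and per-sex control summaries."""
    patients: dict[tuple[str, Sex], list[float]] = {}
    controls: dict[Sex, list[float]] = {}
    for rec in cohort:
        if rec.role is Role.CONTROL:
            controls.setdefault(rec.sex, []).append(rec.age)
        else:
            label = rec.phenotype or "patient"
            patients.setdefault((label, rec.sex), []).append(rec.age)

    def _summary(label: str, sex: Sex, ages: list[float]) -> GroupAgeSummary:
        arr = np.asarray(ages, dtype=float)
        sd = float(np.std(arr, ddof=1)) if arr.size >= 2 else 0.0
        return GroupAgeSummary(label=label, sex=sex, mean=float(arr.mean()),
                               sd=sd, n=int(arr.size))

    patient_summaries = [_summary(label, sex, ages)
                         for (label, sex), ages in patients.items()]
    control_summaries = [_summary("HC", sex, ages)
                         for sex, ages in controls.items()]
    return patient_summaries, control_summaries


def matching_table(patient_groups: list[GroupAgeSummary],
                   control_groups: list[GroupAgeSummary]) -> pd.DataFrame:
    """Age-matching matrix: one row per phenotype, male and female columns.

    Each cell holds the control-vs-patient t, df and two-sided p.  A
    patient group without a same-sex control group is an error.
    """
    controls_by_sex = {c.sex: c for c in control_groups}
    labels: dict[str, None] = {}
    for g in patient_groups:
        labels.setdefault(g.label, None)

    rows = []
    for label in labels:
        row: dict[str, object] = {"group": label}
        for sex in (Sex.MALE, Sex.FEMALE):
            match = [g for g in patient_groups
                     if g.label == label and g.sex is sex]
            if not match:
                continue
            if sex not in controls_by_sex:
                raise ValueError(f"no {sex.value} control group for {label!r}")
            res = two_sample_t_from_summary(controls_by_sex[sex], match[0])
            prefix = sex.value
            row[f"{prefix}_mean"] = match[0].mean
            row[f"{prefix}_sd"] = match[0].sd
            row[f"{prefix}_n"] = match[0].n
            row[f"{prefix}_t"] = round(res.t, 2)
            row[f"{prefix}_df"] = res.df
            row[f"{prefix}_p"] = round(res.p, 2)
        rows.append(row)
    return pd.DataFrame(rows).set_index("group")


def ftd_cohort_age_summaries() -> tuple[list[GroupAgeSummary],
                                        list[GroupAgeSummary]]:
    """Published age summaries of a 160-subject FTD study cohort.

    Five phenotype groups (ALSFTD-C9+, ALSFTD-C9NEG, bvFTD, nfvPPA,
    svPPA) split by sex, plus one male and one female control group of
    50 each.  Used as the worked-example input for
    :func:`matching_table` throughout the documentation and the
    acceptance checks.  (patients, controls).
    """
    M, F = Sex.MALE, Sex.FEMALE
    patients = [
        GroupAgeSummary("ALSFTD-C9+", M, 55.92, 8.11, 13),
        GroupAgeSummary("ALSFTD-C9+", F, 58.50, 9.61, 8),
        GroupAgeSummary("ALSFTD-C9NEG", M, 62.00, 9.11, 13),
        GroupAgeSummary("ALSFTD-C9NEG", F, 58.14, 7.98, 7),
        GroupAgeSummary("bvFTD", M, 59.25, 3.50, 4),
        GroupAgeSummary("bvFTD", F, 62.67, 2.98, 3),
        GroupAgeSummary("nfvPPA", M, 63.60, 2.97, 5),
        GroupAgeSummary("nfvPPA", F, 60.50, 3.42, 4),
        GroupAgeSummary("svPPA", M, 58.00, 1.41, 2),
        GroupAgeSummary("svPPA", F, 69.00, 0.00, 1),
    ]
    controls = [
        GroupAgeSummary("HC", M, 60.96, 9.68, 50),
        GroupAgeSummary("HC", F, 56.94, 9.91, 50),
    ]
    return patients, controls
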