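"""Single-subject tract rating against the normative reference.

For every evaluable tract two one-sided rank tests are run in the
pathological direction: FA against the *lower* tail (how many controls
have lower FA than the patient) and RD against the *upper* tail (how
many controls have higher RD).  The empirical p-value is that count
divided by the number of controls carrying the tract, so p takes only
the values {0, 1/n, ..., 1} and no distributional assumption is made.
Because two tests are run per tract, the per-metric threshold defaults
to alpha = .05 / 2 = .025.

A tract is *affected* when either metric is significant; both flags are
retained in the findings so FA-driven and RD-driven calls remain
distinguishable.  Ties count as not exceeding (strict inequalities),
and a p of exactly 0 is rendered as "< 1/n" in the text report.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Literal, Sequence

import numpy as np

from .cohort import SubjectRecord, Sex
from .normative import METRICS, NormativeReference, NotEvaluable
from .registry import Hemisphere, TractRegistry

__all__ = [
    "DEFAULT_ALPHA_SUBJECT",
    "TractFinding",
    "SubjectReport",
    "empirical_p",
    "evaluate_subject",
    "laterality_summary",
    "LateralitySummary",
    "render_report",
    "report_from_json",
    "leave_one_out_flags",
]

DEFAULT_ALPHA_SUBJECT = 0.025

REPORT_SCHEMA_VERSION = 1

# pathological direction per metric: FA falls, RD rises
_DIRECTION = {"fa": "lower", "rd": "higher"}


def empirical_p(value: float, control_values: Sequence[float],
                direction: Literal["lower", "higher"]) -> float:
    """Rank-based empirical p-value of ``value`` within a control sample.

    ``direction="lower"``: fraction of controls strictly below the value
    (small when the value sits in the extreme low tail).
    ``direction="higher"``: fraction strictly above.  Ties are not
    counted as exceeding.
    """
    arr = np.asarray(control_values, dtype=float)
    if arr.size < 2:
        raise NotEvaluable("fewer than 2 control values")
    arr = np.sort(arr)
    v = float(value)
    if direction == "lower":
        count = int(np.searchsorted(arr, v, side="left"))
    elif direction == "higher":
        count = arr.size - int(np.searchsorted(arr, v, side="right"))
    else:
        raise ValueError(f"direction must be 'lower' or 'higher', got {direction!r}")
    return count / arr.size


@dataclass(frozen=True)
class TractFinding:
    """One rank test: a tract, a metric, and the patient's standing."""

    tract: str
    metric: str  # "fa" | "rd"
    value: float
    z: float
    p: float
    n_controls: int
    significant: bool


@dataclass
class SubjectReport:
    subject_id: str
    sex: Sex
    alpha: float
    findings: list[TractFinding] = field(default_factory=list)
    affected: list[str] = field(default_factory=list)
    not_evaluable: list[str] = field(default_factory=list)

    def findings_for(self, metric: str) -> list[TractFinding]:
        return [f for f in self.findings if f.metric == metric]

    def significant_findings(self) -> list[TractFinding]:
        return [f for f in self.findings if f.significant]

    def is_significant(self, tract: str, metric: str) -> bool | None:
        """Per-metric flag, or None when the tract/metric was not scored."""
        for f in self.findings:
            if f.tract == tract and f.metric == metric:
                return f.significant
        return None

    @property
    def evaluable_tracts(self) -> list[str]:
        seen: dict[str, None] = {}
        for f in self.findings:
            seen.setdefault(f.tract, None)
        return list(seen)


def evaluate_subject(subject: SubjectRecord, reference: NormativeReference,
                     alpha: float = DEFAULT_ALPHA_SUBJECT) -> SubjectReport:
    """Score one subject's tract profile against the normative reference.

    The subject's sex must match the reference sex.  Tracts missing in
    the subject or unusable in the reference are listed as not
    evaluable; every other tract yields an FA (lower-tail) and an RD
    (upper-tail) finding with z, empirical p and a significance flag.
    """
    if Sex(subject.sex) is not reference.sex:
        raise ValueError(
            f"subject sex {subject.sex.value!r} does not match reference "
            f"sex {reference.sex.value!r}"
        )
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")

    report = SubjectReport(subject_id=subject.subject_id, sex=reference.sex,
                           alpha=alpha)
    affected: dict[str, None] = {}
    for tract in reference.tracts:
        if tract not in subject.metrics:
            report.not_evaluable.append(tract)
            continue
        if not all(reference.usable(tract, metric) for metric in METRICS):
            report.not_evaluable.append(tract)
            continue
        for metric in METRICS:
            value = (subject.metrics.fa(tract) if metric == "fa"
                     else subject.metrics.rd(tract))
            sample = reference.sample(tract, metric)
            p = empirical_p(value, sample, _DIRECTION[metric])
            z = reference.z_score(value, tract, metric)
            significant = p < alpha
            report.findings.append(
                TractFinding(tract=tract, metric=metric, value=value, z=z,
                             p=p, n_controls=int(sample.size),
                             significant=significant)
            )
            if significant:
                affected.setdefault(tract, None)
    report.affected = list(affected)
    return report


@dataclass(frozen=True)
class LateralitySummary:
    n_left: int
    n_right: int
    n_commissural: int


def laterality_summary(report: SubjectReport,
                       registry: TractRegistry) -> LateralitySummary:
    """Count affected tracts by hemisphere."""
    counts = {Hemisphere.LEFT: 0, Hemisphere.RIGHT: 0, Hemisphere.COMMISSURAL: 0}
    for tract in report.affected:
        counts[registry.lookup(tract).hemisphere] += 1
    return LateralitySummary(
        n_left=counts[Hemisphere.LEFT],
        n_right=counts[Hemisphere.RIGHT],
        n_commissural=counts[Hemisphere.COMMISSURAL],
    )


def _sorted_significant(report: SubjectReport) -> list[TractFinding]:
    return sorted(report.significant_findings(), key=lambda f: (f.p, f.tract))


def render_report(report: SubjectReport,
                  format: Literal["text", "json"] = "text") -> str:
    """Render the dual-output report: human-readable text or full JSON."""
    if format == "json":
        payload = {
            "schema_version": REPORT_SCHEMA_VERSION,
            "subject_id": report.subject_id,
            "sex": report.sex.value,
            "alpha": report.alpha,
            "findings": [asdict(f) for f in report.findings],
            "affected": list(report.affected),
            "not_evaluable": list(report.not_evaluable),
        }
        return json.dumps(payload, indent=1)
    if format != "text":
        raise ValueError(f"unknown format {format!r}")

    lines = [
        f"Subject {report.subject_id} ({report.sex.value})",
        f"Evaluable tracts: {len(report.evaluable_tracts)}"
        f" (not evaluable: {len(report.not_evaluable)})",
    ]
    sig = _sorted_significant(report)
    if not sig:
        lines.append(f"no tracts significant at alpha = {report.alpha}")
    else:
        lines.append(f"Affected tracts (alpha = {report.alpha} per metric):")
        for f in sig:
            p_txt = (f"p < {1.0 / f.n_controls:.4f}" if f.p == 0.0
                     else f"p = {f.p:.4f}")
            lines.append(
                f"  {f.tract} [{f.metric.upper()}] z = {f.z:+.2f}, {p_txt}"
            )
    return "\n".join(lines) + "\n"


def report_from_json(text: str) -> SubjectReport:
    """Inverse of ``render_report(..., format='json')``."""
    payload = json.loads(text)
    report = SubjectReport(
        subject_id=payload["subject_id"],
        sex=Sex(payload["sex"]),
        alpha=float(payload["alpha"]),
        affected=list(payload["affected"]),
        not_evaluable=list(payload["not_evaluable"]),
    )
    report.findings = [TractFinding(**f) for f in payload["findings"]]
    return report


def leave_one_out_flags(controls_values: Sequence[float],
                        direction: Literal["lower", "higher"],
                        alpha: float = DEFAULT_ALPHA_SUBJECT) -> int:
    """Number of controls flagged when each is rated against the rest.

    Exact leave-one-out calibration helper: for each of the n control
    values, the empirical p against the remaining n-1 is computed and
    compared to ``alpha``.  Under exchangeability with no ties the count
    equals #{k : k/(n-1) < alpha} exactly, independent of the values.
    """
    arr = np.asarray(controls_values, dtype=float)
    flags = 0
    for i in range(arr.size):
        rest = np.delete(arr, i)
        if empirical_p(arr[i], rest, direction) < alpha:
            flags += 1
    return flags
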