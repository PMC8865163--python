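"""Sex-stratified normative reference built from healthy-control profiles.

For each tract and each metric (FA, RD) the reference stores the control
sample itself (sorted), its mean mu and SD sigma (n-1 denominator).  The
sample is retained because single-subject inference is rank-based: the
empirical p-value of a patient is a count of controls beyond the
patient's value, not a Gaussian tail.  z-scores against (mu, sigma) are
descriptive companions.

A (tract, metric) is *unusable* when fewer than two controls carry the
tract or when the control sample is degenerate (sigma = 0); unusable
entries yield a "not evaluable" signal rather than a score.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .cohort import CohortTable, Role, Sex

__all__ = [
    "METRICS",
    "NormativeReference",
    "build_reference",
    "NotEvaluable",
]

METRICS = ("fa", "rd")

SCHEMA_VERSION = 1


class NotEvaluable(Exception):
    """A (tract, metric) cannot be scored against this reference."""


@dataclass
class _MetricSample:
    values: np.ndarray  # sorted, ascending
    mean: float
    sd: float

    @property
    def usable(self) -> bool:
        return self.values.size >= 2 and self.sd > 0.0


@dataclass
class NormativeReference:
    sex: Sex
    n_controls: int
    samples: dict[tuple[str, str], _MetricSample] = field(default_factory=dict)

    @property
    def tracts(self) -> list[str]:
        seen: dict[str, None] = {}
        for tract, _metric in self.samples:
            seen.setdefault(tract, None)
        return list(seen)

    def usable(self, tract: str, metric: str) -> bool:
        entry = self.samples.get((tract, metric))
        return entry is not None and entry.usable

    def unusable_entries(self) -> list[tuple[str, str]]:
        return [key for key, s in self.samples.items() if not s.usable]

    def sample(self, tract: str, metric: str) -> np.ndarray:
        entry = self.samples.get((tract, metric))
        if entry is None or not entry.usable:
            raise NotEvaluable(f"{tract} / {metric.upper()}")
        return entry.values

    def z_score(self, value: float, tract: str, metric: str) -> float:
        """Standardised deviation (value - mu) / sigma for one tract metric."""
        entry = self.samples.get((tract, metric))
        if entry is None or not entry.usable:
            raise NotEvaluable(f"{tract} / {metric.upper()}")
        return (float(value) - entry.mean) / entry.sd

    # -- serialisation --------------------------------------------------

    def to_json(self, path: str | Path) -> None:
        tracts: dict[str, dict] = {}
        for (tract, metric), s in self.samples.items():
            tracts.setdefault(tract, {})[metric] = {
                "values": s.values.tolist(),
                "mean": s.mean,
                "sd": s.sd,
            }
        payload = {
            "schema_version": SCHEMA_VERSION,
            "sex": self.sex.value,
            "n_controls": self.n_controls,
            "tracts": tracts,
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "NormativeReference":
        payload = json.loads(Path(path).read_text())
        ref = cls(sex=Sex(payload["sex"]), n_controls=int(payload["n_controls"]))
        for tract, metrics in payload["tracts"].items():
            for metric, entry in metrics.items():
                ref.samples[(tract, metric)] = _MetricSample(
                    values=np.asarray(entry["values"], dtype=float),
                    mean=float(entry["mean"]),
                    sd=float(entry["sd"]),
                )
        return ref


def build_reference(controls: CohortTable, sex: Sex | str) -> NormativeReference:
    """Build the per-sex normative reference from control records.

    All records must have ``role=control`` and the requested sex (the
    sex-matching of the design); per tract, subjects missing the tract
    are dropped from that tract's sample only.
    """
    sex = Sex(sex)
    records = list(controls)
    if not records:
        raise ValueError("empty control cohort")
    for rec in records:
        if rec.role is not Role.CONTROL:
            raise ValueError(f"subject {rec.subject_id!r} has role {rec.role.value!r}")
        if rec.sex is not sex:
            raise ValueError(
                f"subject {rec.subject_id!r} has sex {rec.sex.value!r}, "
                f"expected {sex.value!r}"
            )

    ref = NormativeReference(sex=sex, n_controls=len(records))
    tracts: dict[str, None] = {}
    for rec in records:
        for t in rec.metrics.tracts:
            tracts.setdefault(t, None)

    for tract in tracts:
        fa_vals, rd_vals = [], []
        for rec in records:
            if tract in rec.metrics:
                fa_vals.append(rec.metrics.fa(tract))
                rd_vals.append(rec.metrics.rd(tract))
        for metric, vals in (("fa", fa_vals), ("rd", rd_vals)):
            arr = np.sort(np.asarray(vals, dtype=float))
            sd = float(np.std(arr, ddof=1)) if arr.size >= 2 else 0.0
            ref.samples[(tract, metric)] = _MetricSample(
                values=arr, mean=float(np.mean(arr)) if arr.size else float("nan"),
                sd=sd,
            )
    return ref
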