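"""Subject records, cohort tables and their on-disk format.

The unit of data is one subject's tract profile: a mean fractional
anisotropy (FA, dimensionless in [0, 1]) and mean radial diffusivity
(RD, mm^2/s, strictly positive) per successfully segmented bundle.
Tracts may be absent (segmentation failure); absence is represented by
the tract simply not appearing in the subject's :class:`TractMetrics`.

On disk a cohort is a long-format CSV/TSV with the exact header::

    subject_id,sex,age,role,phenotype,tract,fa_mean,rd_mean

one row per (subject, tract).  The delimiter is chosen from the file
extension (``.tsv``/``.tab`` -> tab, otherwise comma).  Values are
written at full float precision so a write/read round trip is exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Optional

import pandas as pd

from .registry import TractRegistry, default_tract_registry

__all__ = [
    "Sex",
    "Role",
    "TractMetrics",
    "SubjectRecord",
    "CohortTable",
    "read_metrics_table",
    "write_metrics_table",
    "SchemaError",
    "TableValidationError",
    "METRICS_TABLE_COLUMNS",
]

METRICS_TABLE_COLUMNS = [
    "subject_id",
    "sex",
    "age",
    "role",
    "phenotype",
    "tract",
    "fa_mean",
    "rd_mean",
]


class Sex(str, Enum):
    MALE = "male"
    FEMALE = "female"


class Role(str, Enum):
    PATIENT = "patient"
    CONTROL = "control"


class SchemaError(ValueError):
    """A metrics table is missing a required column."""


class TableValidationError(ValueError):
    """A metrics table row violates a value constraint."""


def _check_fa_rd(fa: float, rd: float, where: str) -> None:
    if not (0.0 <= fa <= 1.0):
        raise TableValidationError(f"{where}: fa_mean {fa!r} outside [0, 1]")
    if not rd > 0.0:
        raise TableValidationError(f"{where}: rd_mean {rd!r} must be > 0")


@dataclass
class TractMetrics:
    """Mapping tract name -> (fa_mean, rd_mean) for one subject."""

    values: dict[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, (fa, rd) in self.values.items():
            _check_fa_rd(fa, rd, f"tract {name!r}")

    def __contains__(self, tract: str) -> bool:
        return tract in self.values

    def __len__(self) -> int:
        return len(self.values)

    @property
    def tracts(self) -> list[str]:
        return list(self.values)

    def fa(self, tract: str) -> float:
        return self.values[tract][0]

    def rd(self, tract: str) -> float:
        return self.values[tract][1]


@dataclass
class SubjectRecord:
    subject_id: str
    sex: Sex
    age: float
    role: Role
    metrics: TractMetrics
    phenotype: Optional[str] = None

    def __post_init__(self) -> None:
        self.sex = Sex(self.sex)
        self.role = Role(self.role)
        if not self.age > 0:
            raise TableValidationError(
                f"subject {self.subject_id!r}: age must be > 0, got {self.age!r}"
            )


class CohortTable:
    """A collection of :class:`SubjectRecord` with unique subject ids."""

    def __init__(self, subjects: Iterable[SubjectRecord] = ()):  # noqa: D401
        self._subjects: list[SubjectRecord] = []
        self._by_id: dict[str, SubjectRecord] = {}
        for s in subjects:
            self.add(s)

    def add(self, subject: SubjectRecord) -> None:
        if subject.subject_id in self._by_id:
            raise TableValidationError(f"duplicate subject_id {subject.subject_id!r}")
        self._subjects.append(subject)
        self._by_id[subject.subject_id] = subject

    def __len__(self) -> int:
        return len(self._subjects)

    def __iter__(self) -> Iterator[SubjectRecord]:
        return iter(self._subjects)

    def __getitem__(self, subject_id: str) -> SubjectRecord:
        return self._by_id[subject_id]

    def __contains__(self, subject_id: str) -> bool:
        return subject_id in self._by_id

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CohortTable):
            return NotImplemented
        return self.to_frame().equals(other.to_frame())

    def select(self, *, sex: Sex | None = None, role: Role | None = None,
               phenotype: str | None = None) -> "CohortTable":
        out = CohortTable()
        for s in self._subjects:
            if sex is not None and s.sex is not Sex(sex):
                continue
            if role is not None and s.role is not Role(role):
                continue
            if phenotype is not None and s.phenotype != phenotype:
                continue
            out.add(s)
        return out

    @property
    def phenotypes(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self._subjects:
            if s.phenotype is not None:
                seen.setdefault(s.phenotype, None)
        return list(seen)

    # -- tabular form ---------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for s in self._subjects:
            for tract, (fa, rd) in s.metrics.values.items():
                rows.append(
                    (s.subject_id, s.sex.value, s.age, s.role.value,
                     s.phenotype if s.phenotype is not None else "",
                     tract, fa, rd)
                )
        return pd.DataFrame(rows, columns=METRICS_TABLE_COLUMNS)

    @classmethod
    def from_frame(cls, df: pd.DataFrame,
                   registry: TractRegistry | None = None) -> "CohortTable":
        registry = registry or default_tract_registry()
        missing = [c for c in METRICS_TABLE_COLUMNS if c not in df.columns]
        if missing:
            raise SchemaError(f"missing required column(s): {', '.join(missing)}")

        table = cls()
        current: dict[str, SubjectRecord] = {}
        for idx, row in df.iterrows():
            where = f"row {idx}"
            tract = str(row["tract"])
            if tract not in registry:
                raise TableValidationError(
                    f"{where}: unknown tract {tract!r} (not in registry)"
                )
            tract = registry.resolve(tract)
            try:
                fa = float(row["fa_mean"])
                rd = float(row["rd_mean"])
            except (TypeError, ValueError) as exc:
                raise TableValidationError(f"{where}: non-numeric metric") from exc
            _check_fa_rd(fa, rd, where)

            sid = str(row["subject_id"])
            if sid not in current:
                phen = row["phenotype"]
                phen = None if (pd.isna(phen) or str(phen) == "") else str(phen)
                try:
                    rec = SubjectRecord(
                        subject_id=sid,
                        sex=Sex(str(row["sex"])),
                        age=float(row["age"]),
                        role=Role(str(row["role"])),
                        phenotype=phen,
                        metrics=TractMetrics(),
                    )
                except ValueError as exc:
                    raise TableValidationError(f"{where}: {exc}") from exc
                current[sid] = rec
                table.add(rec)
            rec = current[sid]
            if tract in rec.metrics.values:
                raise TableValidationError(
                    f"{where}: duplicate tract {tract!r} for subject {sid!r}"
                )
            rec.metrics.values[tract] = (fa, rd)
        return table


def _sep_for(path: str | Path) -> str:
    return "\t" if Path(path).suffix.lower() in {".tsv", ".tab"} else ","


def read_metrics_table(path: str | Path,
                       registry: TractRegistry | None = None) -> CohortTable:
    """Read and validate a long-format tract-metric table.

    Raises :class:`SchemaError` naming any missing column, and
    :class:`TableValidationError` citing the offending row for
    out-of-range FA/RD, unknown tracts, or duplicate ids.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep=_sep_for(path), dtype={"phenotype": "string"},
                     float_precision="round_trip")
    return CohortTable.from_frame(df, registry=registry)


def write_metrics_table(cohort: CohortTable, path: str | Path) -> None:
    """Write a cohort in the long-format table; full float precision."""
    cohort.to_frame().to_csv(path, sep=_sep_for(path), index=False)
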