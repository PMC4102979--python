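"""Patient-level data model, cohort I/O and stratification.

A cohort is an ordered collection of :class:`PatientRecord` objects, one per
subject scheduled for surgery for an adnexal mass.  Every downstream analysis
(ROMA scoring, ROC/cutoff optimisation, diagnostic metrics, baseline
comparisons) consumes this container, and the strata defined here — total,
pre-/post-menopause, and early/advanced FIGO stage — are the only subgroup
definitions used anywhere in the package.

Stage strata follow the case-control convention used for stage-wise test
evaluation: the positive class is the malignant subset with the requested
stages, while *all* benign records serve as the negative class, so the
early-stage and advanced-stage strata overlap on the controls.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Iterator, Mapping

import pandas as pd

__all__ = [
    "MenopausalStatus",
    "Pathology",
    "PatientRecord",
    "Cohort",
    "Stratum",
    "STRATA",
    "SYMPTOM_FLAGS",
    "SchemaError",
    "CohortValidationError",
    "read_cohort",
    "write_cohort",
    "stratify",
    "flag_implausible_premenopause",
]

SYMPTOM_FLAGS = ("vaginal_bleeding", "pain", "distension", "weight_loss")

#: Default CSV column names; ``read_cohort``'s ``schema`` maps these canonical
#: names to arbitrary source headers.
DEFAULT_COLUMNS = {
    "id": "id",
    "age": "age",
    "menopausal_status": "menopausal_status",
    "ca125": "ca125",
    "he4": "he4",
    "pathology": "pathology",
    "stage": "stage",
}


class MenopausalStatus(str, enum.Enum):
    PRE = "pre"
    POST = "post"


class Pathology(str, enum.Enum):
    BENIGN = "benign"
    MALIGNANT = "malignant"


class SchemaError(ValueError):
    """A required column is missing from the input table."""


class CohortValidationError(ValueError):
    """One or more rows violate the patient-record invariants.

    ``errors`` is a list of ``{"row": index, "id": id-or-None,
    "message": str}`` dicts; :meth:`report_json` serialises it.
    """

    def __init__(self, errors: list[dict]):
        self.errors = errors
        lines = "; ".join(f"row {e['row']}: {e['message']}" for e in errors[:5])
        more = "" if len(errors) <= 5 else f" (+{len(errors) - 5} more)"
        super().__init__(f"{len(errors)} invalid row(s): {lines}{more}")

    def report_json(self) -> str:
        return json.dumps({"invalid_rows": self.errors}, indent=2)


@dataclass(frozen=True)
class PatientRecord:
    """One subject: serum biomarkers, menopausal status and pathology.

    ``ca125`` (U/mL) and ``he4`` (pmol/L) must be strictly positive so their
    logarithms are defined.  ``stage`` is the FIGO stage (1-4) and is present
    iff the pathology is malignant.  ``symptoms`` holds presenting-complaint
    flags; ``demographics`` holds optional reproductive-history fields.  Both
    are optional and only consumed by the baseline-comparison module.
    """

    id: str
    age: float
    menopausal_status: MenopausalStatus
    ca125: float
    he4: float
    pathology: Pathology
    stage: int | None = None
    symptoms: frozenset[str] = frozenset()
    demographics: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.age > 0:
            raise ValueError(f"age must be positive, got {self.age!r}")
        if not self.ca125 > 0:
            raise ValueError(f"ca125 must be > 0 (log undefined), got {self.ca125!r}")
        if not self.he4 > 0:
            raise ValueError(f"he4 must be > 0 (log undefined), got {self.he4!r}")
        if self.stage is not None:
            if self.pathology is not Pathology.MALIGNANT:
                raise ValueError("stage is only valid for malignant pathology")
            if self.stage not in (1, 2, 3, 4):
                raise ValueError(f"stage must be in 1..4, got {self.stage!r}")
        unknown = set(self.symptoms) - set(SYMPTOM_FLAGS)
        if unknown:
            raise ValueError(f"unknown symptom flag(s): {sorted(unknown)}")

    @property
    def is_malignant(self) -> bool:
        return self.pathology is Pathology.MALIGNANT

    @property
    def is_postmenopausal(self) -> bool:
        return self.menopausal_status is MenopausalStatus.POST


class Cohort:
    """Ordered, id-unique collection of patient records."""

    def __init__(self, records: Iterable[PatientRecord], provenance: str = ""):
        self.records: tuple[PatientRecord, ...] = tuple(records)
        self.provenance = provenance
        seen: set[str] = set()
        for r in self.records:
            if r.id in seen:
                raise ValueError(f"duplicate patient id {r.id!r}")
            seen.add(r.id)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[PatientRecord]:
        return iter(self.records)

    def __getitem__(self, i: int) -> PatientRecord:
        return self.records[i]

    def counts(self) -> dict[tuple[str, str], int]:
        """Exact counts by (pathology, menopausal_status)."""
        out: dict[tuple[str, str], int] = {}
        for r in self.records:
            key = (r.pathology.value, r.menopausal_status.value)
            out[key] = out.get(key, 0) + 1
        return out

    @property
    def n_benign(self) -> int:
        return sum(not r.is_malignant for r in self.records)

    @property
    def n_malignant(self) -> int:
        return sum(r.is_malignant for r in self.records)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            row = {
                "id": r.id,
                "age": r.age,
                "menopausal_status": r.menopausal_status.value,
                "ca125": r.ca125,
                "he4": r.he4,
                "pathology": r.pathology.value,
                "stage": "" if r.stage is None else r.stage,
            }
            for flag in SYMPTOM_FLAGS:
                row[flag] = int(flag in r.symptoms)
            rows.append(row)
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class Stratum:
    """A named subgroup rule.

    ``case_predicate`` selects the positive (malignant-side) membership;
    ``include_all_benign`` marks the stage strata, where the full benign
    series is retained as the control group regardless of the predicate.
    """

    name: str
    predicate: Callable[[PatientRecord], bool]
    include_all_benign: bool = False
    requires_stage: bool = False


STRATA: dict[str, Stratum] = {
    "total": Stratum("total", lambda r: True),
    "premenopause": Stratum("premenopause", lambda r: not r.is_postmenopausal),
    "postmenopause": Stratum("postmenopause", lambda r: r.is_postmenopausal),
    "early_stage": Stratum(
        "early_stage",
        lambda r: r.is_malignant and r.stage in (1, 2),
        include_all_benign=True,
        requires_stage=True,
    ),
    "advanced_stage": Stratum(
        "advanced_stage",
        lambda r: r.is_malignant and r.stage in (3, 4),
        include_all_benign=True,
        requires_stage=True,
    ),
}


def stratify(cohort: Cohort, stratum: Stratum | str) -> Cohort:
    """Return the sub-cohort selected by ``stratum``.

    For stage strata the result is the stage-subset malignant cases plus all
    benign controls, mirroring stage-wise diagnostic evaluation where every
    benign mass remains a potential false positive.
    """
    if isinstance(stratum, str):
        try:
            stratum = STRATA[stratum]
        except KeyError:
            raise KeyError(
                f"unknown stratum {stratum!r}; valid: {sorted(STRATA)}"
            ) from None
    if stratum.requires_stage:
        malignant = [r for r in cohort if r.is_malignant]
        if malignant and all(r.stage is None for r in malignant):
            raise ValueError(
                f"stratum {stratum.name!r} requires stage data but no malignant "
                "record carries a stage"
            )
    kept = [
        r
        for r in cohort
        if stratum.predicate(r) or (stratum.include_all_benign and not r.is_malignant)
    ]
    return Cohort(kept, provenance=f"{cohort.provenance}[{stratum.name}]")


def _parse_row(idx: int, row: Mapping[str, object]) -> PatientRecord:
    def get_enum(name: str, enum_cls):
        raw = str(row[name]).strip().lower()
        try:
            return enum_cls(raw)
        except ValueError:
            valid = [e.value for e in enum_cls]
            raise ValueError(f"{name}={raw!r} not one of {valid}") from None

    stage_raw = row.get("stage")
    stage: int | None
    if stage_raw is None or (isinstance(stage_raw, float) and pd.isna(stage_raw)) or str(
        stage_raw
    ).strip() in ("", "na", "nan", "none"):
        stage = None
    else:
        stage = int(float(stage_raw))

    symptoms = frozenset(
        flag
        for flag in SYMPTOM_FLAGS
        if flag in row and str(row[flag]).strip() not in ("", "0", "nan", "na")
    )
    demo_keys = set(row) - set(DEFAULT_COLUMNS) - set(SYMPTOM_FLAGS)
    demographics = {k: row[k] for k in sorted(demo_keys) if not pd.isna(row[k])}

    return PatientRecord(
        id=str(row["id"]),
        age=float(row["age"]),
        menopausal_status=get_enum("menopausal_status", MenopausalStatus),
        ca125=float(row["ca125"]),
        he4=float(row["he4"]),
        pathology=get_enum("pathology", Pathology),
        stage=stage,
        symptoms=symptoms,
        demographics=demographics,
    )


def read_cohort(
    path: str | Path,
    schema: Mapping[str, str] | None = None,
    provenance: str | None = None,
) -> Cohort:
    """Read and validate a cohort CSV.

    ``schema`` maps canonical column names (``id``, ``age``,
    ``menopausal_status``, ``ca125``, ``he4``, ``pathology``, optionally
    ``stage`` and symptom flags) to the headers actually present in the file.
    All invalid rows are collected and reported together in a
    :class:`CohortValidationError` whose ``report_json()`` is row-indexed.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype={"id": str}, encoding="utf-8")
    rename = {}
    if schema:
        rename = {src: canon for canon, src in schema.items()}
        df = df.rename(columns=rename)
    required = ["id", "age", "menopausal_status", "ca125", "he4", "pathology"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {missing}")

    records: list[PatientRecord] = []
    errors: list[dict] = []
    for idx, row in enumerate(df.to_dict(orient="records")):
        try:
            records.append(_parse_row(idx, row))
        except (ValueError, KeyError, TypeError) as exc:
            errors.append({"row": idx, "id": str(row.get("id")), "message": str(exc)})
    if errors:
        raise CohortValidationError(errors)
    return Cohort(records, provenance=provenance if provenance is not None else str(path))


def write_cohort(cohort: Cohort, path: str | Path) -> None:
    """Write a cohort to CSV in the canonical column layout (round-trips)."""
    cohort.to_frame().to_csv(path, index=False, lineterminator="\n")


def flag_implausible_premenopause(cohort: Cohort, age_threshold: float = 55.0) -> list[str]:
    """QC helper: ids recorded pre-menopausal at or above ``age_threshold``.

    Menopausal status is always taken from the input column (it reflects
    clinical/laboratory criteria the table cannot reproduce); this flags
    candidates for review only and changes nothing.
    """
    return [
        r.id
        for r in cohort
        if not r.is_postmenopausal and r.age >= age_threshold
    ]
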