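"""Cohort data model, CSV round-trip, and the severe-outcome labeling rule.

The outcome of interest is severe neurodevelopmental impairment at 18-24
months corrected age: any Bayley-III composite score (cognitive, motor,
language; population mean 100, SD 15) at or below 70, i.e. more than two
standard deviations below the mean. The label is always derived from the
Bayley scores, never trusted from an input file, so the labeling rule has a
single source of truth.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, fields
from pathlib import Path
from typing import Optional

import pandas as pd

from .scoring import IVH_GRADES, CH_SIZE_SYNONYMS, InjuryProfile

logger = logging.getLogger(__name__)

SEVERE_CUTOFF = 70.0

RACES = ("African-American", "Asian", "Caucasian", "Hispanic")

#: Boolean clinical covariates, in cohort-table column order.
BOOLEAN_COVARIATES = (
    "sga",
    "male",
    "preeclampsia",
    "chorioamnionitis",
    "vaginal_delivery",
    "antenatal_steroids_any",
    "antenatal_steroids_complete",
    "antenatal_magnesium",
    "postnatal_steroids",
    "bpd",
    "inotropes",
    "sepsis",
    "nec",
    "pda_ligation",
    "seizures",
    "severe_rop",
)

CSV_COLUMNS = (
    "id",
    "gestational_age",
    "birth_weight",
    "sga",
    "male",
    "race",
    "preeclampsia",
    "chorioamnionitis",
    "vaginal_delivery",
    "antenatal_steroids_any",
    "antenatal_steroids_complete",
    "antenatal_magnesium",
    "apgar5",
    "postnatal_steroids",
    "ventilator_days",
    "bpd",
    "inotropes",
    "sepsis",
    "nec",
    "pda_ligation",
    "seizures",
    "severe_rop",
    "ivh_grade",
    "ch_size",
    "ch_bilateral",
    "wmi_lesions",
    "wmi_cystic",
    "bayley_cognitive",
    "bayley_motor",
    "bayley_language",
)

_IVH_CODE_TO_GRADE = {0: "none", 1: "I", 2: "II", 3: "III", 4: "IV"}
_IVH_GRADE_TO_CODE = {v: k for k, v in _IVH_CODE_TO_GRADE.items()}


class CohortValidationError(ValueError):
    """Validation failure; carries one message per offending row."""

    def __init__(self, errors: list[str]):
        self.errors = list(errors)
        super().__init__("cohort validation failed:\n" + "\n".join(self.errors))


@dataclass(frozen=True)
class BayleyScores:
    """Bayley-III composite scores (each nominally mean 100, SD 15)."""

    cognitive: float
    motor: float
    language: float

    def __post_init__(self) -> None:
        for field in fields(self):
            value = getattr(self, field.name)
            if value is None:
                raise ValueError(f"Bayley {field.name} score is missing")
            if not 40 <= value <= 160:
                raise ValueError(
                    f"Bayley {field.name} score {value} outside the composite range [40, 160]"
                )


def label_severe(bayley: BayleyScores) -> bool:
    """True iff any Bayley-III composite is at or below 70 (> 2 SD below mean)."""
    return min(bayley.cognitive, bayley.motor, bayley.language) <= SEVERE_CUTOFF


@dataclass(frozen=True)
class ClinicalCovariates:
    """Perinatal and NICU-course covariates. Missing values are ``None``
    (models use complete cases for their own covariate sets)."""

    gestational_age: Optional[float] = None  # weeks, cohort entry requires <= 30
    birth_weight: Optional[float] = None  # grams
    sga: Optional[bool] = None
    male: Optional[bool] = None
    race: Optional[str] = None
    preeclampsia: Optional[bool] = None
    chorioamnionitis: Optional[bool] = None
    vaginal_delivery: Optional[bool] = None
    antenatal_steroids_any: Optional[bool] = None
    antenatal_steroids_complete: Optional[bool] = None
    antenatal_magnesium: Optional[bool] = None
    apgar5: Optional[int] = None
    postnatal_steroids: Optional[bool] = None
    ventilator_days: Optional[int] = None
    bpd: Optional[bool] = None
    inotropes: Optional[bool] = None
    sepsis: Optional[bool] = None
    nec: Optional[bool] = None
    pda_ligation: Optional[bool] = None
    seizures: Optional[bool] = None
    severe_rop: Optional[bool] = None

    def __post_init__(self) -> None:
        if self.gestational_age is not None and not 20 <= self.gestational_age <= 30:
            raise ValueError(
                f"gestational age {self.gestational_age} weeks outside the "
                "cohort inclusion range (20, 30]"
            )
        if self.birth_weight is not None and self.birth_weight <= 0:
            raise ValueError("birth weight must be positive")
        if self.race is not None and self.race not in RACES:
            raise ValueError(f"unknown race category {self.race!r}")
        if self.apgar5 is not None and not 0 <= self.apgar5 <= 10:
            raise ValueError("5-minute Apgar must be in 0..10")
        if self.ventilator_days is not None and self.ventilator_days < 0:
            raise ValueError("ventilator days must be non-negative")


@dataclass(frozen=True)
class SubjectRecord:
    """One infant: clinical covariates, MRI findings, and outcome scores."""

    id: str
    covariates: ClinicalCovariates
    injury: InjuryProfile
    bayley: Optional[BayleyScores] = None

    @property
    def severe(self) -> Optional[bool]:
        """Derived severe-impairment label; None when Bayley scores are absent."""
        return None if self.bayley is None else label_severe(self.bayley)


@dataclass
class Cohort:
    records: list[SubjectRecord]
    provenance: str = ""

    def __post_init__(self) -> None:
        ids = [r.id for r in self.records]
        dupes = {i for i in ids if ids.count(i) > 1}
        if dupes:
            raise CohortValidationError([f"duplicate subject id {i!r}" for i in sorted(dupes)])

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def labeled(self) -> list[SubjectRecord]:
        """Records with complete Bayley scores (hence a derived label)."""
        return [r for r in self.records if r.bayley is not None]

    def outcome_counts(self) -> tuple[int, int]:
        """(n severe, n non-severe) among labeled records."""
        labels = [r.severe for r in self.labeled()]
        return sum(labels), len(labels) - sum(labels)


def _parse_bool(value, column: str) -> Optional[bool]:
    if value is None:
        return None
    iv = int(value)
    if iv not in (0, 1):
        raise ValueError(f"{column} must be 0 or 1, got {value!r}")
    return bool(iv)


def _cell(row: pd.Series, column: str):
    value = row[column]
    return None if pd.isna(value) else value


def _record_from_row(row: pd.Series, index: int) -> SubjectRecord:
    raw_id = _cell(row, "id")
    if raw_id is None:
        raise ValueError("missing subject id")
    cov_kwargs: dict = {}
    ga = _cell(row, "gestational_age")
    bw = _cell(row, "birth_weight")
    cov_kwargs["gestational_age"] = None if ga is None else float(ga)
    cov_kwargs["birth_weight"] = None if bw is None else float(bw)
    race = _cell(row, "race")
    cov_kwargs["race"] = None if race is None else str(race)
    apgar = _cell(row, "apgar5")
    cov_kwargs["apgar5"] = None if apgar is None else int(apgar)
    vent = _cell(row, "ventilator_days")
    cov_kwargs["ventilator_days"] = None if vent is None else int(vent)
    for column in BOOLEAN_COVARIATES:
        cov_kwargs[column] = _parse_bool(_cell(row, column), column)
    covariates = ClinicalCovariates(**cov_kwargs)

    ivh_code = _cell(row, "ivh_grade")
    if ivh_code is None:
        raise ValueError("missing ivh_grade")
    ivh_code = int(ivh_code)
    if ivh_code not in _IVH_CODE_TO_GRADE:
        raise ValueError(f"ivh_grade code must be 0-4, got {ivh_code}")
    ch_size = _cell(row, "ch_size")
    if ch_size is None or str(ch_size) not in CH_SIZE_SYNONYMS:
        raise ValueError(f"ch_size must be one of {sorted(CH_SIZE_SYNONYMS)}, got {ch_size!r}")
    injury = InjuryProfile(
        ivh_grade=_IVH_CODE_TO_GRADE[ivh_code],
        ch_size=str(ch_size),
        ch_bilateral=bool(_parse_bool(_cell(row, "ch_bilateral"), "ch_bilateral")),
        wmi_lesion_count=int(_cell(row, "wmi_lesions") or 0),
        wmi_cystic=bool(_parse_bool(_cell(row, "wmi_cystic"), "wmi_cystic")),
    )

    scores = [_cell(row, f"bayley_{c}") for c in ("cognitive", "motor", "language")]
    present = [s is not None for s in scores]
    if all(present):
        bayley = BayleyScores(*(float(s) for s in scores))
    elif any(present):
        raise ValueError("Bayley scores must be all present or all absent")
    else:
        bayley = None
    return SubjectRecord(id=str(raw_id), covariates=covariates, injury=injury, bayley=bayley)


def load_cohort(path: str | Path) -> Cohort:
    """Read and validate a cohort CSV.

    All rows are checked; every failure is collected into one
    :class:`CohortValidationError` listing the offending rows. A ``severe``
    column in the file is ignored (the label is re-derived from Bayley
    scores) with a warning on any inconsistency.
    """
    path = Path(path)
    # round_trip parsing keeps load(write(c)) == c to the last ulp
    frame = pd.read_csv(path, dtype={"id": str}, float_precision="round_trip")
    known = set(CSV_COLUMNS) | {"severe"}
    unknown = [c for c in frame.columns if c not in known]
    missing = [c for c in CSV_COLUMNS if c not in frame.columns]
    errors = []
    if unknown:
        errors.append(f"unknown columns: {unknown}")
    if missing:
        errors.append(f"missing columns: {missing}")
    if errors:
        raise CohortValidationError(errors)

    records: list[SubjectRecord] = []
    for index, row in frame.iterrows():
        try:
            record = _record_from_row(row, index)
        except ValueError as exc:
            errors.append(f"row {index}: {exc}")
            continue
        if "severe" in frame.columns and not pd.isna(row["severe"]):
            stated = bool(int(row["severe"]))
            if record.severe is not None and stated != record.severe:
                logger.warning(
                    "row %s: stated severe=%s disagrees with Bayley-derived "
                    "label %s; derived label wins",
                    index,
                    stated,
                    record.severe,
                )
        records.append(record)
    if errors:
        raise CohortValidationError(errors)

    seen: dict[str, int] = {}
    for index, record in enumerate(records):
        if record.id in seen:
            errors.append(f"row {index}: duplicate id {record.id!r} (first at row {seen[record.id]})")
        else:
            seen[record.id] = index
    if errors:
        raise CohortValidationError(errors)
    return Cohort(records=records, provenance=str(path))


def cohort_frame(cohort: Cohort) -> pd.DataFrame:
    """Cohort as a DataFrame in the canonical CSV column order."""
    rows = []
    for record in cohort:
        cov = record.covariates
        row: dict = {"id": record.id}
        for name in ("gestational_age", "birth_weight"):
            row[name] = getattr(cov, name)
        for name in BOOLEAN_COVARIATES:
            value = getattr(cov, name)
            row[name] = None if value is None else int(value)
        row["race"] = cov.race
        row["apgar5"] = cov.apgar5
        row["ventilator_days"] = cov.ventilator_days
        row["ivh_grade"] = _IVH_GRADE_TO_CODE[record.injury.ivh_grade]
        row["ch_size"] = record.injury.ch_size
        row["ch_bilateral"] = int(record.injury.ch_bilateral)
        row["wmi_lesions"] = record.injury.wmi_lesion_count
        row["wmi_cystic"] = int(record.injury.wmi_cystic)
        if record.bayley is not None:
            row["bayley_cognitive"] = record.bayley.cognitive
            row["bayley_motor"] = record.bayley.motor
            row["bayley_language"] = record.bayley.language
        rows.append(row)
    return pd.DataFrame(rows, columns=list(CSV_COLUMNS))


def write_cohort(cohort: Cohort, path: str | Path) -> None:
    # %.17g keeps shortest-round-trip precision so load(write(c)) == c
    cohort_frame(cohort).to_csv(path, index=False, float_format="%.17g")
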