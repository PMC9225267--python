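"""Reading, validating and writing per-study case-control genotype counts.

A study contributes either full genotype counts (Val/Val, Val/Leu, Leu/Leu
for cases and controls) or, for publications that only report Leu-allele
carriage, carrier counts. The canonical on-disk format is a strict CSV with
one row per study and a schema-version comment in the header, so that study
sets diff cleanly and round-trip bit-identically.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import pandas as pd

SCHEMA_VERSION = "f13meta-study-schema v1"

COLUMNS = [
    "study_id", "population", "disease",
    "n_cases", "cases_vv", "cases_vl", "cases_ll", "cases_carriers",
    "n_controls", "controls_vv", "controls_vl", "controls_ll",
    "controls_carriers", "nos_score",
]

VALID_DISEASES = ("IS", "MI")


class StudyValidationError(ValueError):
    """A study record violates a structural invariant."""


class SchemaError(ValueError):
    """A study CSV does not match the documented schema."""


@dataclass(frozen=True)
class StudyRecord:
    """One case-control study of the FXIII Val34Leu polymorphism.

    Exactly one of {full genotype counts, carrier-only counts} is present
    per group; carrier counts mean Leu-allele carriers (Val/Leu + Leu/Leu).
    ``nos_score`` is the Newcastle-Ottawa quality score (0-9), carried as
    metadata only.
    """

    study_id: str
    population: str
    disease: str
    n_cases: int
    n_controls: int
    cases_vv: Optional[int] = None
    cases_vl: Optional[int] = None
    cases_ll: Optional[int] = None
    controls_vv: Optional[int] = None
    controls_vl: Optional[int] = None
    controls_ll: Optional[int] = None
    cases_carriers: Optional[int] = None
    controls_carriers: Optional[int] = None
    nos_score: int = 0

    def __post_init__(self) -> None:
        _validate_record(self)

    @property
    def carrier_only(self) -> bool:
        return self.cases_vv is None

    def genotype_counts(self, group: str) -> tuple[int, int, int]:
        """(VV, VL, LL) counts for ``group`` in {'cases', 'controls'}."""
        if self.carrier_only:
            raise StudyValidationError(
                f"{self.study_id}: carrier-only study has no genotype counts"
            )
        if group == "cases":
            return (self.cases_vv, self.cases_vl, self.cases_ll)
        if group == "controls":
            return (self.controls_vv, self.controls_vl, self.controls_ll)
        raise ValueError(f"unknown group {group!r}")

    def carriers(self, group: str) -> int:
        """Leu-allele carrier count for a group, for either record kind."""
        if self.carrier_only:
            return self.cases_carriers if group == "cases" else self.controls_carriers
        vv, vl, ll = self.genotype_counts(group)
        return vl + ll


def _validate_record(r: StudyRecord) -> None:
    if r.disease not in VALID_DISEASES:
        raise StudyValidationError(
            f"{r.study_id}: disease must be one of {VALID_DISEASES}, got {r.disease!r}"
        )
    if r.n_cases < 1 or r.n_controls < 1:
        raise StudyValidationError(f"{r.study_id}: group sizes must be >= 1")
    if not (0 <= r.nos_score <= 9):
        raise StudyValidationError(f"{r.study_id}: NOS score {r.nos_score} outside [0, 9]")

    geno = (r.cases_vv, r.cases_vl, r.cases_ll,
            r.controls_vv, r.controls_vl, r.controls_ll)
    carr = (r.cases_carriers, r.controls_carriers)
    has_geno = all(v is not None for v in geno)
    has_carr = all(v is not None for v in carr)
    geno_only = has_geno and all(v is None for v in carr)
    carr_only = has_carr and all(v is None for v in geno)

    if not (geno_only or carr_only):
        raise StudyValidationError(
            f"{r.study_id}: exactly one of full genotype counts or "
            "carrier-only counts must be present"
        )
    for v in geno + carr:
        if v is not None and v < 0:
            raise StudyValidationError(f"{r.study_id}: negative count")

    if has_geno:
        if r.cases_vv + r.cases_vl + r.cases_ll != r.n_cases:
            raise StudyValidationError(
                f"{r.study_id}: case genotype counts sum to "
                f"{r.cases_vv + r.cases_vl + r.cases_ll}, expected n_cases={r.n_cases}"
            )
        if r.controls_vv + r.controls_vl + r.controls_ll != r.n_controls:
            raise StudyValidationError(
                f"{r.study_id}: control genotype counts sum to "
                f"{r.controls_vv + r.controls_vl + r.controls_ll}, "
                f"expected n_controls={r.n_controls}"
            )
    else:
        if r.cases_carriers > r.n_cases or r.controls_carriers > r.n_controls:
            raise StudyValidationError(
                f"{r.study_id}: carrier counts exceed group sizes"
            )


@dataclass(frozen=True)
class StudySet:
    """An ordered, uniquely-labelled collection of studies for one disease."""

    disease: str
    studies: tuple[StudyRecord, ...]

    def __post_init__(self) -> None:
        if not self.studies:
            raise StudyValidationError("StudySet must contain at least one study")
        ids = [s.study_id for s in self.studies]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise StudyValidationError(f"duplicate study_id(s): {dupes}")
        for s in self.studies:
            if s.disease != self.disease:
                raise StudyValidationError(
                    f"{s.study_id}: disease {s.disease} does not match set "
                    f"disease {self.disease}"
                )

    def __len__(self) -> int:
        return len(self.studies)

    def __iter__(self):
        return iter(self.studies)

    @property
    def total_cases(self) -> int:
        return sum(s.n_cases for s in self.studies)

    @property
    def total_controls(self) -> int:
        return sum(s.n_controls for s in self.studies)


def _cell(value) -> Optional[int]:
    if value is None or (isinstance(value, float) and pd.isna(value)) or value == "":
        return None
    return int(value)


def read_studies(path, disease: Optional[str] = None) -> StudySet:
    """Read a study-set CSV, validating every row.

    Parameters
    ----------
    path : path-like
        CSV in the documented schema (``SCHEMA_VERSION`` comment optional
        but the header row is strict).
    disease : str, optional
        Expected disease label; if given, rows must all carry it.

    Raises
    ------
    SchemaError
        Missing or misnamed columns.
    StudyValidationError
        Any row violating a StudyRecord invariant; the message names the
        offending study.
    """
    df = pd.read_csv(path, comment="#", dtype={"study_id": str, "population": str})
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}")

    records = []
    for _, row in df.iterrows():
        records.append(StudyRecord(
            study_id=row["study_id"],
            population=row["population"],
            disease=row["disease"],
            n_cases=int(row["n_cases"]),
            n_controls=int(row["n_controls"]),
            cases_vv=_cell(row["cases_vv"]),
            cases_vl=_cell(row["cases_vl"]),
            cases_ll=_cell(row["cases_ll"]),
            controls_vv=_cell(row["controls_vv"]),
            controls_vl=_cell(row["controls_vl"]),
            controls_ll=_cell(row["controls_ll"]),
            cases_carriers=_cell(row["cases_carriers"]),
            controls_carriers=_cell(row["controls_carriers"]),
            nos_score=int(row["nos_score"]),
        ))
    set_disease = disease or records[0].disease
    return StudySet(disease=set_disease, studies=tuple(records))


def write_studies(studies: StudySet, path) -> None:
    """Write a StudySet in the canonical CSV schema (round-trip identical)."""
    def fmt(v) -> str:
        return "" if v is None else str(v)

    lines = [f"# {SCHEMA_VERSION}", ",".join(COLUMNS)]
    for s in studies:
        lines.append(",".join([
            s.study_id, s.population, s.disease,
            str(s.n_cases), fmt(s.cases_vv), fmt(s.cases_vl), fmt(s.cases_ll),
            fmt(s.cases_carriers),
            str(s.n_controls), fmt(s.controls_vv), fmt(s.controls_vl),
            fmt(s.controls_ll), fmt(s.controls_carriers), str(s.nos_score),
        ]))
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def _load_packaged(name: str, disease: str) -> StudySet:
    ref = importlib.resources.files("f13meta.data").joinpath(name)
    with importlib.resources.as_file(ref) as p:
        return read_studies(p, disease=disease)


def load_is_studies() -> StudySet:
    """The six packaged ischemic-stroke studies (627 cases, 1639 controls)."""
    return _load_packaged("is_studies.csv", "IS")


def load_mi_studies() -> StudySet:
    """The thirteen packaged premature-MI studies (2595 cases).

    One study (Butt2003) reports Leu-carrier counts only. The Siegerink2009
    control group is recorded with n_controls equal to the sum of its
    genotype counts (747), keeping the row internally consistent.
    """
    return _load_packaged("mi_studies.csv", "MI")
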