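"""Genetic-model contrasts: from genotype counts to 2x2 exposure tables.

Five standard single-locus contrasts are supported, with the Leu allele as
the exposure:

==============  =========================================
dominant        Val/Leu + Leu/Leu  vs  Val/Val
recessive       Leu/Leu            vs  Val/Val + Val/Leu
additive        Leu/Leu            vs  Val/Val   (Val/Leu dropped)
heterozygous    Val/Leu            vs  Val/Val   (Leu/Leu dropped)
allelic         Leu allele         vs  Val allele (2N alleles)
==============  =========================================

Zero-cell policy (RevMan convention): a study with zero exposed (or zero
unexposed) in *both* arms carries no information about the odds ratio and is
excluded from that model; if exactly one arm has a zero cell, 0.5 is added
to all four cells and the table is flagged as corrected.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Union

from .study_io import StudyRecord, StudySet


class GeneticModel(str, Enum):
    DOMINANT = "dominant"
    RECESSIVE = "recessive"
    ADDITIVE = "additive"
    HETEROZYGOUS = "heterozygous"
    ALLELIC = "allelic"


class EmptyModelError(ValueError):
    """Every study in the set is unusable under the requested model."""


@dataclass(frozen=True)
class ContingencyTable:
    """A 2x2 exposed/unexposed x case/control table for one study.

    Cells follow the epidemiological convention: ``a`` exposed cases,
    ``b`` unexposed cases, ``c`` exposed controls, ``d`` unexposed controls.
    Cells are floats because continuity correction adds 0.5. ``unit`` is
    ``"alleles"`` for the allelic model (each person contributes two
    observations) and ``"persons"`` otherwise.
    """

    study_id: str
    a: float
    b: float
    c: float
    d: float
    unit: str = "persons"
    corrected: bool = False

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError(f"{self.study_id}: negative cell")
        if self.corrected and min(self.a, self.b, self.c, self.d) <= 0:
            raise ValueError(f"{self.study_id}: corrected table still has a zero cell")

    @property
    def n(self) -> float:
        return self.a + self.b + self.c + self.d

    def swapped(self) -> "ContingencyTable":
        """Exchange case and control rows (odds ratio inverts)."""
        return ContingencyTable(self.study_id, self.c, self.d, self.a, self.b,
                                unit=self.unit, corrected=self.corrected)


@dataclass(frozen=True)
class Exclusion:
    """Marker naming a study unusable under a model, and why."""

    study_id: str
    model: GeneticModel
    reason: str


def _raw_cells(study: StudyRecord, model: GeneticModel):
    if study.carrier_only:
        if model is not GeneticModel.DOMINANT:
            return None
        a = study.cases_carriers
        b = study.n_cases - study.cases_carriers
        c = study.controls_carriers
        d = study.n_controls - study.controls_carriers
        return a, b, c, d, "persons"

    cvv, cvl, cll = study.genotype_counts("cases")
    kvv, kvl, kll = study.genotype_counts("controls")
    if model is GeneticModel.DOMINANT:
        return cvl + cll, cvv, kvl + kll, kvv, "persons"
    if model is GeneticModel.RECESSIVE:
        return cll, cvv + cvl, kll, kvv + kvl, "persons"
    if model is GeneticModel.ADDITIVE:
        return cll, cvv, kll, kvv, "persons"
    if model is GeneticModel.HETEROZYGOUS:
        return cvl, cvv, kvl, kvv, "persons"
    if model is GeneticModel.ALLELIC:
        return 2 * cll + cvl, 2 * cvv + cvl, 2 * kll + kvl, 2 * kvv + kvl, "alleles"
    raise ValueError(f"unknown model {model!r}")


def derive_table(
    study: StudyRecord, model: GeneticModel
) -> Union[ContingencyTable, Exclusion]:
    """Build the 2x2 table for one study under one genetic model.

    Returns an :class:`Exclusion` when the study cannot contribute: a
    carrier-only study outside the dominant model, or a double-zero margin
    (no exposed, or no unexposed, in either arm).
    """
    model = GeneticModel(model)
    cells = _raw_cells(study, model)
    if cells is None:
        return Exclusion(study.study_id, model,
                         "carrier-only data support the dominant model only")
    a, b, c, d, unit = cells
    if a == 0 and c == 0:
        return Exclusion(study.study_id, model,
                         "zero exposed in both cases and controls")
    if b == 0 and d == 0:
        return Exclusion(study.study_id, model,
                         "zero unexposed in both cases and controls")
    if 0 in (a, b, c, d):
        return ContingencyTable(study.study_id, a + 0.5, b + 0.5, c + 0.5,
                                d + 0.5, unit=unit, corrected=True)
    return ContingencyTable(study.study_id, float(a), float(b), float(c),
                            float(d), unit=unit)


def derive_all(
    studies: StudySet, model: GeneticModel
) -> tuple[list[ContingencyTable], list[Exclusion]]:
    """Derive tables for every study, preserving order.

    Returns ``(tables, exclusions)``; raises :class:`EmptyModelError` when
    no study is usable.
    """
    tables: list[ContingencyTable] = []
    exclusions: list[Exclusion] = []
    for study in studies:
        out = derive_table(study, model)
        if isinstance(out, Exclusion):
            exclusions.append(out)
        else:
            tables.append(out)
    if not tables:
        raise EmptyModelError(
            f"no usable study under the {GeneticModel(model).value} model"
        )
    return tables, exclusions
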