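"""Cohort data model and ILPD-dialect CSV input/output.

The on-disk dialect is the headerless UCI column order::

    Age, Gender, TB, DB, Alkphos, Sgpt, Sgot, TP, ALB, A/G Ratio, Selector

with an optional trailing ``provenance`` column used by this package to tag
synthetic records.  Blank cells encode missing values; only the A/G-ratio
column may legitimately be missing.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import ParseError, StateError, ValidationError

# Canonical internal column names, in codebook (UCI) order.
AGE = "age"
SEX = "sex"
SEX_CODE = "sex_code"
DISEASE = "disease"
PROVENANCE = "provenance"

BIOMARKERS: tuple[str, ...] = (
    "total_bilirubin",
    "direct_bilirubin",
    "alkaline_phosphatase",
    "alanine_aminotransferase",
    "aspartate_aminotransferase",
    "total_proteins",
    "albumin",
    "ag_ratio",
)

#: Numeric feature columns eligible for imputation / scaling / SMOTE.
NUMERIC_FEATURES: tuple[str, ...] = (AGE,) + BIOMARKERS

#: Codebook order used for deterministic tie-breaking in rankings.
CODEBOOK_ORDER: tuple[str, ...] = (AGE, SEX_CODE) + BIOMARKERS

#: UCI file column order (internal names).
UCI_COLUMNS: tuple[str, ...] = (AGE, SEX) + BIOMARKERS + (DISEASE,)

FEMALE = "female"
MALE = "male"
SEXES = (FEMALE, MALE)

PROVENANCE_VALUES = ("original", "smote", "generator")


@dataclass(frozen=True)
class PatientRecord:
    """One row of the cohort.

    ``disease`` carries the raw UCI Selector value (1 = liver patient,
    2 = non-patient) until :func:`liveraudit.preprocess.recode_target`
    maps it to a 0/1 label.
    """

    age: float
    sex: str
    total_bilirubin: float
    direct_bilirubin: float
    alkaline_phosphatase: float
    alanine_aminotransferase: float
    aspartate_aminotransferase: float
    total_proteins: float
    albumin: float
    ag_ratio: float | None
    disease: int
    provenance: str = "original"

    def __post_init__(self) -> None:
        if self.sex not in SEXES:
            raise ValidationError(f"unknown sex {self.sex!r}")
        if self.provenance not in PROVENANCE_VALUES:
            raise ValidationError(f"unknown provenance {self.provenance!r}")


@dataclass
class Cohort:
    """An ordered patient collection plus preprocessing-state flags.

    The record table is a :class:`pandas.DataFrame` with columns
    ``age, sex, <8 biomarkers>, disease, provenance`` and, once
    :func:`liveraudit.preprocess.encode_sex` has run, ``sex_code``.
    """

    df: pd.DataFrame
    name: str = "cohort"
    imputed: bool = False
    scaled: bool = False
    target_recoded: bool = False
    sex_encoding: Mapping[str, int] | None = None

    def __post_init__(self) -> None:
        self.df = self.df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def n_records(self) -> int:
        return len(self.df)

    def copy(self, **changes) -> "Cohort":
        out = replace(self, df=self.df.copy())
        for key, value in changes.items():
            setattr(out, key, value)
        return out

    def subset(self, mask, name: str | None = None) -> "Cohort":
        """Row subset sharing this cohort's state flags."""
        out = self.copy()
        out.df = self.df.loc[mask].reset_index(drop=True)
        if name is not None:
            out.name = name
        return out

    def records(self) -> list[PatientRecord]:
        recs = []
        for row in self.df.itertuples(index=False):
            d = row._asdict()
            ag = d["ag_ratio"]
            recs.append(
                PatientRecord(
                    age=d["age"],
                    sex=d["sex"],
                    total_bilirubin=d["total_bilirubin"],
                    direct_bilirubin=d["direct_bilirubin"],
                    alkaline_phosphatase=d["alkaline_phosphatase"],
                    alanine_aminotransferase=d["alanine_aminotransferase"],
                    aspartate_aminotransferase=d["aspartate_aminotransferase"],
                    total_proteins=d["total_proteins"],
                    albumin=d["albumin"],
                    ag_ratio=None if pd.isna(ag) else ag,
                    disease=int(d["disease"]),
                    provenance=d["provenance"],
                )
            )
        return recs

    @classmethod
    def from_records(
        cls, records: Iterable[PatientRecord], name: str = "cohort", **flags
    ) -> "Cohort":
        rows = []
        for r in records:
            d = {
                AGE: r.age,
                SEX: r.sex,
                DISEASE: r.disease,
                PROVENANCE: r.provenance,
            }
            for b in BIOMARKERS:
                d[b] = getattr(r, b)
            if d["ag_ratio"] is None:
                d["ag_ratio"] = np.nan
            rows.append(d)
        df = pd.DataFrame(rows, columns=[AGE, SEX, *BIOMARKERS, DISEASE, PROVENANCE])
        return cls(df=df, name=name, **flags)


@dataclass
class CohortSummary:
    """Sex-by-class cell counts with all marginals."""

    counts: pd.DataFrame  # index: sex, columns: disease label
    sex_totals: dict[str, int] = field(default_factory=dict)
    class_totals: dict[int, int] = field(default_factory=dict)
    total: int = 0

    def cell(self, sex: str, disease: int) -> int:
        try:
            return int(self.counts.loc[sex, disease])
        except KeyError:
            return 0


def _parse_float(token: str, row_num: int, column: str) -> float:
    try:
        return float(token)
    except ValueError:
        raise ParseError(
            f"row {row_num}: non-numeric value {token!r} in column {column!r}"
        ) from None


def _parse_sex(token: str, row_num: int) -> str:
    t = token.strip().lower()
    if t not in SEXES:
        raise ValidationError(f"row {row_num}: unknown Gender token {token!r}")
    return t


def read_ilpd_csv(
    path: str | Path,
    columns: tuple[str, ...] = UCI_COLUMNS,
    header: str = "auto",
    name: str | None = None,
) -> Cohort:
    """Read an ILPD-dialect CSV into a :class:`Cohort`.

    Parameters
    ----------
    path
        CSV file in the given column order, optionally with a trailing
        ``provenance`` column.
    columns
        Column-order spec (internal names); defaults to the UCI order.
    header
        ``"auto"`` sniffs an optional header line; ``"none"`` / ``"present"``
        force the choice.

    The raw Selector values are preserved — recoding the target is an
    explicit preprocessing step.  Missing A/G-ratio cells stay missing.
    """
    path = Path(path)
    with open(path, newline="") as fh:
        raw_rows = [row for row in csv.reader(fh) if any(f.strip() for f in row)]
    if not raw_rows:
        raise ParseError(f"{path}: empty file")

    if header == "present":
        raw_rows = raw_rows[1:]
    elif header == "auto" and raw_rows:
        first = raw_rows[0]
        try:
            float(first[0])
        except (ValueError, IndexError):
            raw_rows = raw_rows[1:]
    if not raw_rows:
        raise ParseError(f"{path}: no data rows")

    ncol = len(columns)
    rows: list[dict] = []
    for i, fields in enumerate(raw_rows, start=1):
        if len(fields) not in (ncol, ncol + 1):
            raise ParseError(
                f"row {i}: expected {ncol} (or {ncol + 1}) fields, got {len(fields)}"
            )
        rec: dict = {}
        for col, token in zip(columns, fields):
            token = token.strip()
            if col == SEX:
                rec[SEX] = _parse_sex(token, i)
            elif col == "ag_ratio" and token == "":
                rec["ag_ratio"] = np.nan
            elif token == "" and col != "ag_ratio":
                raise ParseError(f"row {i}: blank cell in column {col!r}")
            else:
                rec[col] = _parse_float(token, i, col)
        if len(fields) == ncol + 1:
            prov = fields[-1].strip().lower()
            if prov not in PROVENANCE_VALUES:
                raise ValidationError(f"row {i}: unknown provenance {prov!r}")
            rec[PROVENANCE] = prov
        else:
            rec[PROVENANCE] = "original"
        rows.append(rec)

    df = pd.DataFrame(rows, columns=[AGE, SEX, *BIOMARKERS, DISEASE, PROVENANCE])
    return Cohort(df=df, name=name or path.stem)


def write_cohort_csv(
    cohort: Cohort, path: str | Path, strict_uci: bool = False
) -> Path:
    """Write a cohort in the ILPD dialect.

    A recoded 0/1 disease label is mapped back to the UCI Selector
    convention (1 = liver patient, 2 = non-patient) so the file is
    consumable by any ILPD reader.  Unless ``strict_uci`` is set, a
    trailing ``provenance`` column is appended.
    """
    if len(cohort) == 0:
        raise StateError("refusing to write an empty cohort")
    path = Path(path)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        for row in cohort.df.itertuples(index=False):
            d = row._asdict()
            disease = d[DISEASE]
            if cohort.target_recoded:
                disease = 1 if int(disease) == 1 else 2
            out = [_fmt(d[AGE]), d[SEX].capitalize()]
            out += [_fmt(d[b]) for b in BIOMARKERS]
            out.append(_fmt(disease))
            if not strict_uci:
                out.append(d[PROVENANCE])
            writer.writerow(out)
    return path


def _fmt(x) -> str:
    if x is None or (isinstance(x, float) and math.isnan(x)):
        return ""
    f = float(x)
    if f.is_integer():
        return str(int(f))
    return repr(f)


def summarize_cohort(cohort: Cohort) -> CohortSummary:
    """Sex x disease cell counts and all marginals.

    Requires the target to have been recoded to {0, 1}.
    """
    if not cohort.target_recoded:
        raise StateError("summarize_cohort requires a recoded 0/1 target")
    counts = pd.crosstab(cohort.df[SEX], cohort.df[DISEASE].astype(int))
    counts = counts.reindex(index=list(SEXES), columns=[0, 1], fill_value=0)
    sex_totals = {s: int(counts.loc[s].sum()) for s in SEXES}
    class_totals = {c: int(counts[c].sum()) for c in (0, 1)}
    return CohortSummary(
        counts=counts,
        sex_totals=sex_totals,
        class_totals=class_totals,
        total=int(counts.to_numpy().sum()),
    )
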