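"""Preparation steps: mean imputation, sex encoding, target recoding,
min-max normalisation.

Statistics (means, per-feature min/max) can be fitted either on the whole
cohort (``fit_scope="whole-cohort"``, reproducing preparation-before-split
including its leakage) or supplied from a training fold
(``fit_scope="training-only"`` via the ``stats_from`` argument).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .data_io import DISEASE, FEMALE, MALE, NUMERIC_FEATURES, SEX, SEX_CODE, Cohort
from .errors import ImputationError, StateError, ValidationError

SEX_ENCODING = {FEMALE: 0, MALE: 1}

WHOLE_COHORT = "whole-cohort"
TRAINING_ONLY = "training-only"


@dataclass
class PreprocessReport:
    """Audit trail for one preprocessing operation."""

    operation: str
    fit_scope: str = WHOLE_COHORT
    imputed_cells: int = 0
    imputed_columns: list[str] = field(default_factory=list)
    encoding_used: dict | None = None
    scale_params: dict[str, tuple[float, float]] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "operation": self.operation,
            "fit_scope": self.fit_scope,
            "imputed_cells": self.imputed_cells,
            "imputed_columns": list(self.imputed_columns),
            "encoding_used": dict(self.encoding_used) if self.encoding_used else None,
            "scale_params": {k: [float(a), float(b)] for k, (a, b) in self.scale_params.items()},
        }

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


def impute_mean(
    cohort: Cohort, stats_from: Cohort | None = None
) -> tuple[Cohort, PreprocessReport]:
    """Replace missing numeric cells by the column mean.

    ``stats_from`` supplies the cohort on which means are computed
    (training-only scope); by default the cohort itself is used.
    """
    if cohort.scaled:
        raise StateError("impute before scaling, not after")
    source = stats_from if stats_from is not None else cohort
    scope = WHOLE_COHORT if stats_from is None else TRAINING_ONLY

    out = cohort.copy(imputed=True)
    report = PreprocessReport(operation="impute_mean", fit_scope=scope)
    for col in NUMERIC_FEATURES:
        missing = out.df[col].isna()
        n_missing = int(missing.sum())
        if n_missing == 0:
            continue
        observed = source.df[col].dropna()
        if observed.empty:
            raise ImputationError(f"column {col!r} entirely missing in fit scope")
        out.df.loc[missing, col] = float(observed.mean())
        report.imputed_cells += n_missing
        report.imputed_columns.append(col)
    return out, report


def encode_sex(cohort: Cohort) -> Cohort:
    """Add a numeric ``sex_code`` column (female -> 0, male -> 1).

    The categorical ``sex`` column is retained for stratification, so the
    (arbitrary) encoding direction cannot affect stratified results.
    """
    out = cohort.copy(sex_encoding=dict(SEX_ENCODING))
    out.df[SEX_CODE] = out.df[SEX].map(SEX_ENCODING).astype(float)
    return out


def recode_target(cohort: Cohort) -> Cohort:
    """Map raw UCI Selector values to a 0/1 disease label.

    Selector 1 (liver patient) -> 1, Selector 2 (non-patient) -> 0.
    """
    if cohort.target_recoded:
        raise StateError("target already recoded")
    raw = cohort.df[DISEASE]
    bad = ~raw.isin([1, 2])
    if bad.any():
        first = raw[bad].iloc[0]
        raise ValidationError(f"Selector value {first!r} outside {{1, 2}}")
    out = cohort.copy(target_recoded=True)
    out.df[DISEASE] = (raw == 1).astype(int)
    return out


def minmax_scale(
    cohort: Cohort,
    stats_from: Cohort | None = None,
    columns: tuple[str, ...] = NUMERIC_FEATURES,
) -> tuple[Cohort, PreprocessReport]:
    """Map each feature to (x - min) / (max - min).

    Min/max are fitted on ``stats_from`` when given (training-only scope),
    else on the cohort itself.  A zero-range feature maps to 0 rather than
    raising, so degenerate synthetic cohorts pass through the pipeline.
    Encoded sex and the target are never rescaled (already in {0, 1}).
    """
    for col in columns:
        if col in (SEX_CODE, DISEASE):
            raise ValidationError(f"refusing to scale column {col!r}")
        if cohort.df[col].isna().any():
            raise StateError(f"column {col!r} has missing values; impute first")

    source = stats_from if stats_from is not None else cohort
    scope = WHOLE_COHORT if stats_from is None else TRAINING_ONLY
    out = cohort.copy(scaled=True)
    report = PreprocessReport(operation="minmax_scale", fit_scope=scope)
    for col in columns:
        lo = float(source.df[col].min())
        hi = float(source.df[col].max())
        report.scale_params[col] = (lo, hi)
        if hi > lo:
            out.df[col] = (out.df[col] - lo) / (hi - lo)
        else:
            out.df[col] = 0.0
    return out, report


def prepare(
    cohort: Cohort, stats_from: Cohort | None = None
) -> tuple[Cohort, list[PreprocessReport]]:
    """Convenience: impute, encode sex, recode target (if raw), scale."""
    reports = []
    c, rep = impute_mean(cohort, stats_from=stats_from)
    reports.append(rep)
    c = encode_sex(c)
    if not c.target_recoded:
        c = recode_target(c)
    scaled_stats = None
    if stats_from is not None:
        scaled_stats, _ = impute_mean(stats_from)
        scaled_stats = encode_sex(scaled_stats)
    c, rep = minmax_scale(c, stats_from=scaled_stats)
    reports.append(rep)
    return c, reports
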