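"""Sex-stratified feature exploration and recursive feature elimination.

Pearson ranking correlates each feature with the disease label within a
sex scope; the IQR profile summarises per-feature spread on the
normalised scale.  RFE drops the single least-important feature per
iteration until ``n_keep`` survive.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_io import (
    BIOMARKERS,
    CODEBOOK_ORDER,
    DISEASE,
    SEX,
    SEX_CODE,
    Cohort,
)
from .errors import ConfigurationError, StateError, ValidationError

SCOPES = ("all", "female", "male")


@dataclass
class FeatureRanking:
    scope: str
    method: str
    entries: list[tuple[str, float]] = field(default_factory=list)

    @property
    def features(self) -> list[str]:
        return [name for name, _ in self.entries]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"scope": self.scope, "feature": f, "score": s, "rank": i + 1}
                for i, (f, s) in enumerate(self.entries)
            ]
        )


@dataclass
class IqrProfile:
    scope: str
    per_feature_iqr: dict[str, float]

    @property
    def mean_iqr(self) -> float:
        return float(np.mean(list(self.per_feature_iqr.values())))


def _scoped(cohort: Cohort, scope: str) -> pd.DataFrame:
    if scope not in SCOPES:
        raise ValidationError(f"unknown scope {scope!r}")
    if scope == "all":
        return cohort.df
    return cohort.df[cohort.df[SEX] == scope]


def _codebook_position(feature: str) -> int:
    try:
        return CODEBOOK_ORDER.index(feature)
    except ValueError:
        return len(CODEBOOK_ORDER)


def default_feature_columns(cohort: Cohort) -> list[str]:
    """Model/ranking features in codebook order (requires encoded sex)."""
    cols = [c for c in CODEBOOK_ORDER if c in cohort.df.columns]
    return cols


def pearson_rank(
    cohort: Cohort, scope: str = "all", columns: list[str] | None = None
) -> FeatureRanking:
    """Rank features by |Pearson r| with the disease label within scope.

    Zero-variance features get r = 0 with a warning.  Ties are broken by
    codebook column order.
    """
    df = _scoped(cohort, scope)
    if len(df) < 3:
        raise StateError(f"scope {scope!r} has fewer than 3 records")
    y = df[DISEASE].to_numpy(dtype=float)
    if len(np.unique(y)) < 2:
        raise StateError(f"scope {scope!r} has a single class")
    columns = columns or default_feature_columns(cohort)

    scores = {}
    for col in columns:
        x = df[col].to_numpy(dtype=float)
        if np.std(x) == 0.0:
            warnings.warn(f"feature {col!r} has zero variance in scope {scope!r}")
            scores[col] = 0.0
        else:
            scores[col] = float(np.corrcoef(x, y)[0, 1])

    ordered = sorted(
        scores.items(), key=lambda kv: (-abs(kv[1]), _codebook_position(kv[0]))
    )
    return FeatureRanking(scope=scope, method="pearson", entries=ordered)


def iqr_profile(
    cohort: Cohort, scope: str = "all", columns: tuple[str, ...] = BIOMARKERS
) -> IqrProfile:
    """Per-biomarker IQR (Q3 - Q1, linear-interpolation quantiles) in scope.

    The cohort must be scaled to [0, 1]; encoded sex and the target are
    excluded from the biomarker average.
    """
    if not cohort.scaled:
        raise StateError("iqr_profile requires a min-max scaled cohort")
    df = _scoped(cohort, scope)
    if df.empty:
        raise StateError(f"scope {scope!r} is empty")
    iqrs = {}
    for col in columns:
        x = df[col].to_numpy(dtype=float)
        q1, q3 = np.percentile(x, [25, 75])  # linear interpolation
        iqrs[col] = float(q3 - q1)
    return IqrProfile(scope=scope, per_feature_iqr=iqrs)


def _importances(model, n_features: int) -> np.ndarray:
    if hasattr(model, "feature_importances_"):
        return np.asarray(model.feature_importances_, dtype=float)
    if hasattr(model, "coef_"):
        return np.abs(np.asarray(model.coef_, dtype=float)).reshape(-1)[:n_features]
    raise ConfigurationError(
        f"{type(model).__name__} exposes neither coef_ nor feature_importances_"
    )


def rfe_top_features(
    cohort: Cohort,
    learner,
    n_keep: int = 5,
    columns: list[str] | None = None,
) -> FeatureRanking:
    """Recursive feature elimination down to ``n_keep`` features.

    ``learner`` is a zero-argument factory returning an unfitted estimator.
    Estimators without per-feature importances (e.g. Gaussian naive Bayes,
    RBF-kernel machines) are eliminated with a logistic surrogate via
    :func:`surrogate_for`.  One feature is dropped per iteration; the
    returned ranking lists survivors first in reverse elimination order.
    """
    columns = list(columns or default_feature_columns(cohort))
    if n_keep >= len(columns):
        return FeatureRanking(
            scope="all", method="rfe", entries=[(c, 0.0) for c in columns]
        )
    remaining = list(columns)
    y = cohort.df[DISEASE].to_numpy(dtype=int)
    eliminated: list[str] = []
    while len(remaining) > n_keep:
        model = learner()
        X = cohort.df[remaining].to_numpy(dtype=float)
        model.fit(X, y)
        imp = _importances(model, len(remaining))
        worst = min(
            range(len(remaining)),
            key=lambda i: (imp[i], -_codebook_position(remaining[i])),
        )
        eliminated.append(remaining.pop(worst))
    # survivors ranked by importance in the final fit
    model = learner()
    model.fit(cohort.df[remaining].to_numpy(dtype=float), y)
    imp = _importances(model, len(remaining))
    entries = sorted(
        zip(remaining, imp.tolist()),
        key=lambda kv: (-kv[1], _codebook_position(kv[0])),
    )
    return FeatureRanking(scope="all", method="rfe", entries=entries)


def surrogate_for(family: str, seed: int | None = None):
    """Estimator factory used inside RFE for a learner family.

    Linear and tree models eliminate with their own importances; families
    without per-feature importances fall back to a logistic surrogate.
    """
    from sklearn.ensemble import RandomForestClassifier
    from sklearn.linear_model import LogisticRegression

    if family == "random_forest":
        return lambda: RandomForestClassifier(n_estimators=100, random_state=seed)
    # logistic surrogate for logistic_regression itself and for svm / gnb
    return lambda: LogisticRegression(max_iter=2000)


def write_rankings_csv(rankings: list[FeatureRanking], path) -> None:
    pd.concat([r.to_frame() for r in rankings], ignore_index=True).to_csv(
        path, index=False
    )
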