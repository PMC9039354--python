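"""From-scratch SMOTE interpolation, the two balancing schemes
(class-balanced and sex-balanced cohorts), and train/test split policies.

Synthetic records are convex combinations ``x + u * (x_nn - x)`` of a seed
record and one of its k nearest same-group neighbours (Euclidean distance
on the numeric features).  Sex and disease label are inherited from the
seed record; provenance is tagged ``smote``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .data_io import (
    DISEASE,
    NUMERIC_FEATURES,
    PROVENANCE,
    SEX,
    SEX_CODE,
    Cohort,
)
from .errors import ParameterError, SplitError


@dataclass
class SmoteParams:
    """Parameters of one SMOTE oversampling pass."""

    target_count: int
    k_neighbors: int = 5
    seed: int | np.random.Generator | None = None

    def rng(self) -> np.random.Generator:
        if isinstance(self.seed, np.random.Generator):
            return self.seed
        return np.random.default_rng(self.seed)


@dataclass
class SplitPolicy:
    """Train/test partitioning policy.

    With ``sex_balanced_training`` set, the training fold is built by
    drawing equal-size random subsets from males and females separately
    and appending them.
    """

    test_fraction: float = 0.30
    sex_balanced_training: bool = False
    seed: int | np.random.Generator | None = None
    max_retries: int = 20

    def __post_init__(self) -> None:
        if not 0 < self.test_fraction < 1:
            raise ParameterError(
                f"test_fraction must be in (0, 1), got {self.test_fraction}"
            )

    def rng(self) -> np.random.Generator:
        if isinstance(self.seed, np.random.Generator):
            return self.seed
        return np.random.default_rng(self.seed)


def smote_generate(
    group: Cohort,
    params: SmoteParams,
    feature_columns: tuple[str, ...] = NUMERIC_FEATURES,
) -> pd.DataFrame:
    """Generate ``target_count - len(group)`` synthetic records.

    The group must be homogeneous in the attribute being balanced (callers
    pass a single class or a single sex) and complete in the feature
    columns.  Deterministic given the RNG seed.
    """
    n = len(group)
    if params.target_count < n:
        raise ParameterError(
            f"target_count {params.target_count} below group size {n}"
        )
    if n <= params.k_neighbors:
        raise ParameterError(
            f"group size {n} must exceed k_neighbors {params.k_neighbors}"
        )
    X = group.df[list(feature_columns)].to_numpy(dtype=float)
    if np.isnan(X).any():
        raise ParameterError("SMOTE requires complete numeric features; impute first")

    n_new = params.target_count - n
    if n_new == 0:
        return group.df.iloc[0:0].copy()

    # k nearest neighbours (self excluded) per record; groups are small
    # enough that a dense distance matrix is the simplest correct choice.
    dists = cdist(X, X)
    np.fill_diagonal(dists, np.inf)
    nn_idx = np.argsort(dists, axis=1, kind="stable")[:, : params.k_neighbors]

    rng = params.rng()
    seed_idx = rng.integers(0, n, size=n_new)
    nn_choice = rng.integers(0, params.k_neighbors, size=n_new)
    u = rng.uniform(0.0, 1.0, size=n_new)

    rows = []
    for s, c, gap in zip(seed_idx, nn_choice, u):
        neighbour = nn_idx[s, c]
        base = group.df.iloc[s].to_dict()
        x = X[s] + gap * (X[neighbour] - X[s])
        for j, col in enumerate(feature_columns):
            base[col] = x[j]
        base[PROVENANCE] = "smote"
        rows.append(base)
    return pd.DataFrame(rows, columns=group.df.columns)


def _append(cohort: Cohort, synthetic: pd.DataFrame, name: str) -> Cohort:
    out = cohort.copy(name=name)
    if len(synthetic):
        out.df = pd.concat([out.df, synthetic], ignore_index=True)
    return out


def balance_classes(cohort: Cohort, params: SmoteParams) -> Cohort:
    """Oversample the minority disease class up to the majority count.

    Neighbour search is restricted to the minority class (any sex); each
    synthetic record inherits sex and label from its seed record, so the
    balanced cohort remains stratifiable by sex.
    """
    counts = cohort.df[DISEASE].value_counts()
    if len(counts) != 2:
        raise ParameterError("balance_classes requires exactly two classes")
    minority = counts.idxmin()
    majority_count = int(counts.max())
    if int(counts.min()) == majority_count:
        return cohort.copy(name=f"{cohort.name}+classbal")
    group = cohort.subset(cohort.df[DISEASE] == minority)
    synth = smote_generate(
        group,
        SmoteParams(
            target_count=majority_count,
            k_neighbors=params.k_neighbors,
            seed=params.seed,
        ),
    )
    return _append(cohort, synth, f"{cohort.name}+classbal")


def balance_sexes(
    cohort: Cohort, params: SmoteParams, within_class: bool = False
) -> Cohort:
    """Oversample the under-represented sex up to the other sex's count.

    Neighbours are sought within that sex only (optionally within
    sex x class when ``within_class`` is set); the disease label of each
    synthetic record is inherited from its seed record.
    """
    counts = cohort.df[SEX].value_counts()
    if len(counts) != 2:
        raise ParameterError("balance_sexes requires both sexes present")
    minority_sex = counts.idxmin()
    majority_count = int(counts.max())
    deficit = majority_count - int(counts.min())
    if deficit == 0:
        return cohort.copy(name=f"{cohort.name}+sexbal")

    rng = params.rng()
    pieces = []
    if within_class:
        sub = cohort.df[cohort.df[SEX] == minority_sex]
        class_counts = sub[DISEASE].value_counts()
        # spread the deficit proportionally to the class mix
        quota = {}
        labels = sorted(class_counts.index)
        assigned = 0
        for lab in labels[:-1]:
            q = round(deficit * class_counts[lab] / len(sub))
            quota[lab] = q
            assigned += q
        quota[labels[-1]] = deficit - assigned
        for lab in labels:
            if quota[lab] == 0:
                continue
            group = cohort.subset(
                (cohort.df[SEX] == minority_sex) & (cohort.df[DISEASE] == lab)
            )
            pieces.append(
                smote_generate(
                    group,
                    SmoteParams(
                        target_count=len(group) + quota[lab],
                        k_neighbors=params.k_neighbors,
                        seed=rng,
                    ),
                )
            )
    else:
        group = cohort.subset(cohort.df[SEX] == minority_sex)
        pieces.append(
            smote_generate(
                group,
                SmoteParams(
                    target_count=majority_count,
                    k_neighbors=params.k_neighbors,
                    seed=rng,
                ),
            )
        )
    synth = pd.concat(pieces, ignore_index=True)
    return _append(cohort, synth, f"{cohort.name}+sexbal")


def _has_representation(test_df: pd.DataFrame) -> bool:
    return test_df[SEX].nunique() == 2 and test_df[DISEASE].nunique() == 2


def train_test_split(cohort: Cohort, policy: SplitPolicy) -> tuple[Cohort, Cohort]:
    """Random disjoint partition with ``round(test_fraction * n)`` test rows.

    Both sexes and both classes must appear in the test fold; degenerate
    draws are retried up to ``policy.max_retries`` times before raising.
    With ``sex_balanced_training``, the training fold holds equal male and
    female counts drawn from the non-test rows (the surplus sex is
    subsampled).
    """
    n = len(cohort)
    n_test = int(round(policy.test_fraction * n))
    if n_test == 0 or n_test == n:
        raise SplitError(f"cohort of {n} cannot be split at {policy.test_fraction}")
    rng = policy.rng()

    for _ in range(policy.max_retries):
        perm = rng.permutation(n)
        test_idx = perm[:n_test]
        train_idx = perm[n_test:]
        test_df = cohort.df.iloc[test_idx]
        if not _has_representation(test_df):
            continue
        if policy.sex_balanced_training:
            train_df = cohort.df.iloc[train_idx]
            by_sex = {s: np.flatnonzero((train_df[SEX] == s).to_numpy())
                      for s in train_df[SEX].unique()}
            if len(by_sex) < 2:
                continue
            m = min(len(ix) for ix in by_sex.values())
            keep = np.concatenate(
                [rng.choice(ix, size=m, replace=False) for ix in by_sex.values()]
            )
            train_idx = train_idx[np.sort(keep)]
        train = cohort.subset(cohort.df.index[train_idx], name=f"{cohort.name}.train")
        test = cohort.subset(cohort.df.index[test_idx], name=f"{cohort.name}.test")
        return train, test
    raise SplitError(
        f"no split with both sexes and both classes in the test fold "
        f"after {policy.max_retries} retries (n={n})"
    )
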