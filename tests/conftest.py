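"""Shared fixtures: hand-written CSV fixtures and small deterministic cohorts."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from liveraudit.data_io import AGE, BIOMARKERS, DISEASE, PROVENANCE, SEX, Cohort

ILPD_3ROWS = """\
65,Female,0.7,0.1,187,16,18,6.8,3.3,0.9,1
62,Male,10.9,5.5,699,64,100,7.5,3.2,,1
40,male,0.9,0.3,310,61,58,7,3.4,1.1,2
"""


@pytest.fixture
def three_row_csv(tmp_path):
    path = tmp_path / "ilpd3.csv"
    path.write_text(ILPD_3ROWS)
    return path


def make_cohort(
    counts: dict[tuple[str, int], int],
    seed: int = 0,
    missing_ag: int = 0,
    recoded: bool = True,
) -> Cohort:
    """Deterministic cohort with exact (sex, disease) cell counts.

    Features are right-skewed lognormal draws with a mild disease shift so
    classes are weakly separable.  With ``recoded=False`` the disease
    column carries raw Selector values (1 = patient, 2 = non-patient).
    """
    rng = np.random.default_rng(seed)
    rows = []
    for (sex, label), n in counts.items():
        for _ in range(n):
            rec = {AGE: float(rng.integers(20, 80)), SEX: sex, DISEASE: label}
            for b in BIOMARKERS:
                rec[b] = float(np.exp(rng.normal(0.5 * label, 1.0)))
            rec[PROVENANCE] = "original"
            rows.append(rec)
    order = rng.permutation(len(rows))
    df = pd.DataFrame([rows[i] for i in order],
                      columns=[AGE, SEX, *BIOMARKERS, DISEASE, PROVENANCE])
    if missing_ag:
        df.loc[df.index[:missing_ag], "ag_ratio"] = np.nan
    if not recoded:
        df[DISEASE] = df[DISEASE].map({1: 1, 0: 2})
    return Cohort(df=df, name="fixture", target_recoded=recoded)


@pytest.fixture
def small_cohort():
    """40 records, both sexes and classes, no missing cells."""
    return make_cohort(
        {("female", 0): 8, ("female", 1): 10, ("male", 0): 9, ("male", 1): 13},
        seed=42,
    )


@pytest.fixture
def prepared_cohort(small_cohort):
    from liveraudit.preprocess import prepare

    cohort, _ = prepare(small_cohort)
    return cohort
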