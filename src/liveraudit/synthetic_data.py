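"""Synthetic ILPD-like cohort generator.

Cohorts have two sexes with controllable representation, unequal class
prevalence, right-skewed non-negative biomarkers (log-normal with additive
log-scale disease effects), sporadic missingness in the A/G-ratio column,
and a single attenuation knob ``female_attenuation`` (gamma) that scales
disease effect sizes for diseased females.  gamma = 1 with symmetric sizes
and prevalences is the exchangeable-sexes null; gamma < 1 is the
sex-differential signal the audit must detect.

Labels are drawn before features (labels cause features), so separability
is controlled by the effect sizes alone.  Baseline constants are packaged
defaults in plausible clinical ranges; they are not fitted to any real
dataset.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .data_io import AGE, BIOMARKERS, DISEASE, FEMALE, MALE, PROVENANCE, SEX, Cohort
from .errors import ValidationError

#: Per-biomarker (log-mean, log-sd) baselines, roughly matching healthy
#: clinical ranges (bilirubin mg/dL, enzymes IU/L, proteins g/dL).
DEFAULT_BASELINE: dict[str, tuple[float, float]] = {
    "total_bilirubin": (-0.10, 0.55),
    "direct_bilirubin": (-1.20, 0.60),
    "alkaline_phosphatase": (5.30, 0.35),
    "alanine_aminotransferase": (3.30, 0.55),
    "aspartate_aminotransferase": (3.45, 0.55),
    "total_proteins": (1.87, 0.12),
    "albumin": (1.22, 0.15),
    "ag_ratio": (-0.05, 0.22),
}

#: Additive log-scale shift applied to diseased records: elevations in
#: bilirubins/enzymes, depressions in synthetic-function markers.
DEFAULT_EFFECT: dict[str, float] = {
    "total_bilirubin": 0.80,
    "direct_bilirubin": 0.90,
    "alkaline_phosphatase": 0.30,
    "alanine_aminotransferase": 0.70,
    "aspartate_aminotransferase": 0.75,
    "total_proteins": -0.04,
    "albumin": -0.12,
    "ag_ratio": -0.15,
}


@dataclass
class GeneratorSpec:
    """Full parameterisation of the synthetic cohort distribution."""

    n_female: int = 142
    n_male: int = 441
    prevalence_female: float = 92 / 142
    prevalence_male: float = 324 / 441
    baseline: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_BASELINE)
    )
    effect: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_EFFECT))
    female_attenuation: float = 1.0
    missing_rate: float = 0.0
    age_mean: float = 45.0
    age_sd: float = 15.0
    age_disease_shift: float = 3.0
    latent_sd: float = 0.0
    seed: int | None = None

    def validate(self) -> None:
        if self.n_female <= 0 or self.n_male <= 0:
            raise ValidationError("sex counts must be positive")
        for p in (self.prevalence_female, self.prevalence_male):
            if not 0 < p < 1:
                raise ValidationError(f"prevalence {p} outside (0, 1)")
        if not 0 <= self.female_attenuation <= 1:
            raise ValidationError("female_attenuation must lie in [0, 1]")
        if not 0 <= self.missing_rate < 1:
            raise ValidationError("missing_rate must lie in [0, 1)")
        missing = set(BIOMARKERS) - set(self.baseline) | set(BIOMARKERS) - set(self.effect)
        if missing:
            raise ValidationError(f"baseline/effect missing biomarkers: {sorted(missing)}")

    def to_dict(self) -> dict:
        return {
            "n_female": self.n_female,
            "n_male": self.n_male,
            "prevalence_female": self.prevalence_female,
            "prevalence_male": self.prevalence_male,
            "baseline": {k: [float(a), float(b)] for k, (a, b) in self.baseline.items()},
            "effect": {k: float(v) for k, v in self.effect.items()},
            "female_attenuation": self.female_attenuation,
            "missing_rate": self.missing_rate,
            "age_mean": self.age_mean,
            "age_sd": self.age_sd,
            "age_disease_shift": self.age_disease_shift,
            "latent_sd": self.latent_sd,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GeneratorSpec":
        d = dict(d)
        if "baseline" in d:
            d["baseline"] = {k: tuple(v) for k, v in d["baseline"].items()}
        return cls(**d)


@dataclass
class GroundTruth:
    """What the generator actually realised for one cohort draw."""

    spec: GeneratorSpec
    counts: dict[tuple[str, int], int]
    realised_effects: dict[str, dict[str, float]]

    @property
    def total(self) -> int:
        return sum(self.counts.values())


def generate_cohort(
    spec: GeneratorSpec, seed: int | None = None, name: str = "synthetic"
) -> tuple[Cohort, GroundTruth]:
    """Draw one cohort from the spec; deterministic given the seed.

    Records are independent: sex by the fixed counts, disease by the
    per-sex prevalence, biomarkers log-normal with log-mean
    ``baseline + effect * disease * (gamma if female)``.  The returned
    cohort arrives with a recoded 0/1 target and provenance ``generator``.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed if seed is None else seed)

    sex = np.array([FEMALE] * spec.n_female + [MALE] * spec.n_male)
    prevalence = np.where(
        sex == FEMALE, spec.prevalence_female, spec.prevalence_male
    )
    disease = (rng.uniform(size=len(sex)) < prevalence).astype(int)
    attenuation = np.where(sex == FEMALE, spec.female_attenuation, 1.0)

    n = len(sex)
    df = pd.DataFrame({SEX: sex, DISEASE: disease})
    age = rng.normal(
        spec.age_mean + spec.age_disease_shift * disease, spec.age_sd, size=n
    )
    df[AGE] = np.clip(np.round(age), 4, 90)
    latent = rng.normal(0.0, 1.0, size=n) * spec.latent_sd
    for b in BIOMARKERS:
        mu, sigma = spec.baseline[b]
        shift = spec.effect[b] * disease * attenuation
        df[b] = np.exp(mu + shift + latent + rng.normal(0.0, sigma, size=n))
    if spec.missing_rate > 0:
        blank = rng.uniform(size=n) < spec.missing_rate
        df.loc[blank, "ag_ratio"] = np.nan
    df[PROVENANCE] = "generator"

    # shuffle so sex blocks are not positional artefacts
    order = rng.permutation(n)
    df = df.iloc[order].reset_index(drop=True)
    df = df[[AGE, SEX, *BIOMARKERS, DISEASE, PROVENANCE]]

    cohort = Cohort(df=df, name=name, target_recoded=True)
    counts = {
        (s, d): int(((df[SEX] == s) & (df[DISEASE] == d)).sum())
        for s in (FEMALE, MALE)
        for d in (0, 1)
    }
    realised = {
        s: {
            b: spec.effect[b] * (spec.female_attenuation if s == FEMALE else 1.0)
            for b in BIOMARKERS
        }
        for s in (FEMALE, MALE)
    }
    return cohort, GroundTruth(spec=spec, counts=counts, realised_effects=realised)


def ilpd_like_spec(seed: int | None = None) -> GeneratorSpec:
    """Packaged default mirroring the ILPD's composition: 142 females /
    441 males, per-sex prevalences 92/142 and 324/441, right-skewed
    baselines, moderate effects, gamma = 0.7, sporadic A/G missingness."""
    return GeneratorSpec(
        n_female=142,
        n_male=441,
        prevalence_female=92 / 142,
        prevalence_male=324 / 441,
        female_attenuation=0.7,
        missing_rate=0.007,
        seed=seed,
    )


def null_spec(
    n_per_sex: int = 200, prevalence: float = 0.4, seed: int | None = None
) -> GeneratorSpec:
    """Exchangeable-sexes null: gamma = 1, equal sizes and prevalences."""
    return GeneratorSpec(
        n_female=n_per_sex,
        n_male=n_per_sex,
        prevalence_female=prevalence,
        prevalence_male=prevalence,
        female_attenuation=1.0,
        missing_rate=0.0,
        seed=seed,
    )


def attenuated_spec(
    gamma: float = 0.5,
    n_female: int = 300,
    n_male: int = 300,
    prevalence: float = 0.45,
    seed: int | None = None,
) -> GeneratorSpec:
    """Sex-differential signal regime used by the recovery tests."""
    spec = null_spec(seed=seed)
    return replace(
        spec,
        n_female=n_female,
        n_male=n_male,
        prevalence_female=prevalence,
        prevalence_male=prevalence,
        female_attenuation=gamma,
    )
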