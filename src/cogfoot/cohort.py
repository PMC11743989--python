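"""Seeded generation of synthetic participant-level cohorts.

Each participant gets an age (uniform over the scenario range), a sex
(Bernoulli at the female fraction), covariate values, independent binary
medication exposures at the specified (optionally age/sex-stratified)
prevalence, a shared standard-normal latent-cognition factor, and raw
cognitive scores: continuous scores are linear in age, covariates,
exposures and the latent factor plus Gaussian noise; the binary score is
Bernoulli through a logistic link on the same linear predictor.
Missingness is applied per outcome completely at random.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .scenario import ScenarioSpec, MedicationSpec

__all__ = ["Cohort", "generate_cohort"]

ID_COL = "participant_id"
BASE_COLS = (ID_COL, "age", "sex")


@dataclass
class Cohort:
    """A participant-level table plus column-role bookkeeping.

    ``data`` holds one row per participant: id, age (years), sex
    ("F"/"M"), covariates, 0/1 exposure columns named by ATC code, and raw
    outcome scores (continuous in arbitrary units, binary as 0/1; NaN where
    missing).
    """

    data: pd.DataFrame
    medication_cols: list[str]
    covariate_cols: list[str]
    outcome_cols: list[str]

    @property
    def n(self) -> int:
        return len(self.data)

    def exposures(self) -> pd.DataFrame:
        return self.data[self.medication_cols]

    def to_csv(self, path: str | Path) -> None:
        self.data.to_csv(path, index=False)

    @classmethod
    def from_csv(
        cls,
        path: str | Path,
        medication_cols: list[str],
        covariate_cols: list[str],
        outcome_cols: list[str],
    ) -> "Cohort":
        data = pd.read_csv(path)
        missing = [
            c
            for c in (*BASE_COLS, *medication_cols, *covariate_cols, *outcome_cols)
            if c not in data.columns
        ]
        if missing:
            raise ValueError(f"cohort file lacks columns: {missing}")
        return cls(data, medication_cols, covariate_cols, outcome_cols)


def _stratum_prevalence(
    med: MedicationSpec, age: np.ndarray, sex: np.ndarray
) -> np.ndarray:
    """Per-participant exposure probability, resolving stratified specs.

    Stratified prevalence keys look like ``"40-49:F"`` (age interval is
    closed on the left, open on the right, except the last bin which is
    closed).
    """
    if not isinstance(med.prevalence, dict):
        return np.full(age.shape, float(med.prevalence))
    p = np.full(age.shape, np.nan)
    bounds = []
    for key, val in med.prevalence.items():
        age_part, sex_part = key.split(":")
        lo, hi = (float(x) for x in age_part.split("-"))
        bounds.append(hi)
        mask = (age >= lo) & (age < hi) & (sex == sex_part)
        p[mask] = val
    top = max(bounds)
    for key, val in med.prevalence.items():
        age_part, sex_part = key.split(":")
        lo, hi = (float(x) for x in age_part.split("-"))
        if hi == top:
            p[(age == hi) & (sex == sex_part)] = val
    if np.isnan(p).any():
        raise ValueError(
            f"medication {med.code}: stratified prevalence does not cover "
            f"{int(np.isnan(p).sum())} participants"
        )
    return p


def generate_cohort(spec: ScenarioSpec) -> Cohort:
    """Draw one cohort from a scenario; bit-reproducible given the seed."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n = spec.n_participants
    lo, hi = spec.age_range

    age = rng.uniform(lo, hi, size=n)
    sex = np.where(rng.random(n) < spec.sex_ratio, "F", "M")

    data: dict[str, np.ndarray] = {
        ID_COL: np.arange(1, n + 1),
        "age": age,
        "sex": sex,
    }

    covariate_cols: list[str] = []
    cov_numeric: dict[str, np.ndarray] = {}
    for cov in spec.covariates:
        if cov.kind == "continuous":
            vals = rng.normal(cov.mean, cov.sd, size=n)
            data[cov.name] = vals
            cov_numeric[cov.name] = vals
        else:
            idx = rng.choice(len(cov.levels), size=n, p=np.asarray(cov.probs))
            data[cov.name] = np.asarray(cov.levels, dtype=object)[idx]
            # effect applies to every non-reference level (reference = first)
            cov_numeric[cov.name] = (idx > 0).astype(float)
        covariate_cols.append(cov.name)

    medication_cols: list[str] = []
    exposures: dict[str, np.ndarray] = {}
    for med in spec.medications:
        p = _stratum_prevalence(med, age, sex)
        exp = (rng.random(n) < p).astype(np.int8)
        data[med.code] = exp
        exposures[med.code] = exp
        medication_cols.append(med.code)

    latent = rng.standard_normal(n)
    age_centered = age - (lo + hi) / 2.0

    outcome_cols: list[str] = []
    for out in spec.outcomes:
        lin = np.zeros(n)
        lin += out.age_effect * age_centered
        for cov in spec.covariates:
            beta = cov.effects.get(out.name, 0.0)
            if beta:
                centered = cov_numeric[cov.name]
                if cov.kind == "continuous":
                    centered = centered - cov.mean
                lin += beta * centered
        for med in spec.medications:
            beta = med.effects.get(out.name, 0.0)
            if beta:
                lin += beta * exposures[med.code]
        # latent is "underlying cognition": it lowers raw scores where a
        # larger raw value means worse performance
        lin += (out.loading if out.larger_is_better else -out.loading) * latent
        if out.kind == "continuous":
            y = lin + rng.normal(0.0, out.noise_sd, size=n)
        else:
            prob = 1.0 / (1.0 + np.exp(-(out.intercept + lin)))
            y = (rng.random(n) < prob).astype(float)
        if out.missing_fraction > 0:
            y = y.astype(float)
            y[rng.random(n) < out.missing_fraction] = np.nan
        data[out.name] = y
        outcome_cols.append(out.name)

    return Cohort(
        data=pd.DataFrame(data),
        medication_cols=medication_cols,
        covariate_cols=covariate_cols,
        outcome_cols=outcome_cols,
    )
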