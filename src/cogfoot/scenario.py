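"""Generative scenario specifications for synthetic biobank-style cohorts.

A :class:`ScenarioSpec` is the ground truth for one simulated cohort:
demographics, covariates, binary medication exposures keyed by ATC level-5
codes (with optional age/sex-stratified prevalence), and cognitive outcomes
that load on a shared latent-cognition factor.  Real study data of this
shape (UK Biobank-like) are access-restricted, so the generator emulates
their statistical structure: medication prevalences of roughly 1-20%, ages
40-70, several continuous tests plus one binary test, and strong positive
correlation across tests induced by the latent factor.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any

import yaml

from .atc import ATCCode


class ScenarioError(ValueError):
    """Raised when a scenario specification violates its invariants."""


@dataclass
class CovariateSpec:
    """One baseline covariate.

    ``kind`` is ``"continuous"`` (Normal with ``mean``/``sd``) or
    ``"categorical"`` (``levels`` with ``probs``).  ``effects`` maps outcome
    name -> additive effect on that outcome's linear predictor, per unit of
    the covariate (continuous) or for membership in a non-reference level
    (categorical, keyed ``"name=level"`` effects are not supported: a single
    effect applies to every non-reference level).
    """

    name: str
    kind: str = "continuous"
    mean: float = 0.0
    sd: float = 1.0
    levels: list[str] = field(default_factory=list)
    probs: list[float] = field(default_factory=list)
    effects: dict[str, float] = field(default_factory=dict)


@dataclass
class MedicationSpec:
    """One medication exposure keyed by an ATC level-5 code.

    ``prevalence`` is either a single fraction in (0, 1) or a mapping
    ``"age_lo-age_hi:sex" -> fraction`` for stratified sampling.
    ``effects`` maps outcome name -> true effect (additive on the linear
    predictor: outcome-unit scale for continuous outcomes whose residual SD
    is ~1, i.e. approximately Z-scores; log-odds for binary outcomes).
    """

    code: str
    prevalence: float | dict[str, float] = 0.05
    effects: dict[str, float] = field(default_factory=dict)


@dataclass
class OutcomeSpec:
    """One cognitive outcome.

    Continuous outcomes are linear in covariates, exposures and the shared
    latent factor with Gaussian noise; the binary outcome uses a logistic
    link on the same linear predictor.  ``larger_is_better=False`` marks
    scores where a larger raw value means worse performance (e.g. reaction
    times, error counts) — the generator emits them on that raw orientation
    and the preprocessing step flips the sign.
    """

    name: str
    kind: str = "continuous"
    larger_is_better: bool = True
    noise_sd: float = 1.0
    intercept: float = 0.0  # logistic intercept for binary outcomes
    loading: float = 0.0  # loading on the shared latent-cognition factor
    age_effect: float = 0.0  # per year of age, centered at midrange
    missing_fraction: float = 0.0


@dataclass
class ScenarioSpec:
    n_participants: int = 10_000
    seed: int = 0
    age_range: tuple[float, float] = (40.0, 70.0)
    sex_ratio: float = 0.5  # fraction female
    covariates: list[CovariateSpec] = field(default_factory=list)
    medications: list[MedicationSpec] = field(default_factory=list)
    outcomes: list[OutcomeSpec] = field(default_factory=list)

    def validate(self) -> None:
        if self.n_participants <= 0:
            raise ScenarioError("n_participants must be positive")
        lo, hi = self.age_range
        if not lo < hi:
            raise ScenarioError("age_range must satisfy lo < hi")
        if not 0.0 <= self.sex_ratio <= 1.0:
            raise ScenarioError("sex_ratio must lie in [0, 1]")
        outcome_names = {o.name for o in self.outcomes}
        for o in self.outcomes:
            if o.kind not in ("continuous", "binary"):
                raise ScenarioError(f"outcome {o.name!r}: unknown kind {o.kind!r}")
            if o.kind == "continuous" and o.noise_sd <= 0:
                raise ScenarioError(f"outcome {o.name!r}: noise_sd must be > 0")
            if not 0.0 <= o.missing_fraction < 1.0:
                raise ScenarioError(
                    f"outcome {o.name!r}: missing_fraction must lie in [0, 1)"
                )
        for m in self.medications:
            ATCCode.parse(m.code)  # raises ATCError on malformed codes
            prevs = (
                m.prevalence.values()
                if isinstance(m.prevalence, dict)
                else [m.prevalence]
            )
            for p in prevs:
                if not 0.0 < p < 1.0:
                    raise ScenarioError(
                        f"medication {m.code}: prevalence {p} not in (0, 1)"
                    )
            for target in m.effects:
                if target not in outcome_names:
                    raise ScenarioError(
                        f"medication {m.code}: effect targets unknown outcome "
                        f"{target!r}"
                    )
        for c in self.covariates:
            if c.kind not in ("continuous", "categorical"):
                raise ScenarioError(f"covariate {c.name!r}: unknown kind {c.kind!r}")
            if c.kind == "continuous" and c.sd <= 0:
                raise ScenarioError(f"covariate {c.name!r}: sd must be > 0")
            if c.kind == "categorical":
                if len(c.levels) < 2 or len(c.probs) != len(c.levels):
                    raise ScenarioError(
                        f"covariate {c.name!r}: levels/probs mismatch"
                    )
            for target in c.effects:
                if target not in outcome_names:
                    raise ScenarioError(
                        f"covariate {c.name!r}: effect targets unknown outcome "
                        f"{target!r}"
                    )

    # -- serialization ----------------------------------------------------

    def to_dict(self) -> dict[str, Any]:
        d = asdict(self)
        d["age_range"] = list(self.age_range)
        return d

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "ScenarioSpec":
        if "seed" not in d:
            raise ScenarioError("scenario file must declare a seed")
        spec = cls(
            n_participants=int(d.get("n_participants", 10_000)),
            seed=int(d["seed"]),
            age_range=tuple(d.get("age_range", (40.0, 70.0))),
            sex_ratio=float(d.get("sex_ratio", 0.5)),
            covariates=[CovariateSpec(**c) for c in d.get("covariates", [])],
            medications=[MedicationSpec(**m) for m in d.get("medications", [])],
            outcomes=[OutcomeSpec(**o) for o in d.get("outcomes", [])],
        )
        spec.validate()
        return spec

    def save(self, path: str | Path) -> None:
        path = Path(path)
        text = (
            json.dumps(self.to_dict(), indent=2)
            if path.suffix == ".json"
            else yaml.safe_dump(self.to_dict(), sort_keys=False)
        )
        path.write_text(text)

    @classmethod
    def load(cls, path: str | Path) -> "ScenarioSpec":
        path = Path(path)
        raw = path.read_text()
        d = json.loads(raw) if path.suffix == ".json" else yaml.safe_load(raw)
        return cls.from_dict(d)


def default_scenario(n_participants: int = 20_000, seed: int = 0) -> ScenarioSpec:
    """A biobank-like study scenario used by the analysis drivers.

    Medication prevalences and effect directions/magnitudes mirror the
    published cross-sectional cohort summaries: the common analgesic
    (paracetamol, ~20% prevalence) carries a small negative effect around
    -0.05 Z on the continuous tests and -0.10 log-odds on the binary test;
    ibuprofen (~12.6%) and glucosamine (~4.5%) carry positive effects;
    a tricyclic antidepressant (~2%) a larger negative effect; most other
    common medications are null.  Continuous tests share a latent-cognition
    factor so the first principal component summarizes them; the binary
    prospective-memory test has a ~76.6% base rate.
    """
    outcomes = [
        OutcomeSpec(
            "FI", loading=0.8, noise_sd=1.0, age_effect=-0.02,
            missing_fraction=0.05,
        ),
        OutcomeSpec(
            "RT", larger_is_better=False, loading=0.5, noise_sd=1.0,
            age_effect=+0.025, missing_fraction=0.02,
        ),
        OutcomeSpec(
            "PaMa", larger_is_better=False, loading=0.5, noise_sd=1.0,
            age_effect=+0.02, missing_fraction=0.02,
        ),
        OutcomeSpec(
            "NM", loading=0.6, noise_sd=1.0, age_effect=-0.015,
            missing_fraction=0.10,
        ),
        # logit(0.766) ~= 1.186 at covariate means
        OutcomeSpec(
            "PM", kind="binary", intercept=1.186, loading=0.6,
            age_effect=-0.02,
        ),
    ]
    continuous = ["FI", "RT", "PaMa", "NM"]

    def eff(z: float, pm: float) -> dict[str, float]:
        # On "larger raw = worse" outcomes a beneficial effect lowers the
        # raw score; preprocessing re-orients, so sign by orientation here.
        d = {name: (z if name in ("FI", "NM") else -z) for name in continuous}
        d["PM"] = pm
        return d

    medications = [
        MedicationSpec("N02BE01", prevalence=0.199, effects=eff(-0.05, -0.10)),
        MedicationSpec("M01AE01", prevalence=0.126, effects=eff(+0.03, +0.06)),
        MedicationSpec("M01AX05", prevalence=0.045, effects=eff(+0.06, +0.10)),
        MedicationSpec("N06AA09", prevalence=0.020, effects=eff(-0.09, -0.10)),
        MedicationSpec("B01AC06", prevalence=0.122),
        MedicationSpec("C10AA01", prevalence=0.124),
        MedicationSpec("A02BC01", prevalence=0.060),
        MedicationSpec("A11CC05", prevalence=0.060),
        MedicationSpec("C10AX06", prevalence=0.057, effects=eff(+0.02, +0.04)),
        MedicationSpec("H03AA01", prevalence=0.058),
        MedicationSpec("R03AC02", prevalence=0.051),
        MedicationSpec("C03AA01", prevalence=0.058),
        MedicationSpec("M01AE02", prevalence=0.020, effects=eff(+0.04, +0.05)),
        # below the 1% inclusion threshold: exercised by the filter
        MedicationSpec("N03AG01", prevalence=0.005, effects=eff(-0.20, -0.20)),
    ]
    covariates = [
        CovariateSpec(
            "bmi", mean=27.0, sd=4.5,
            effects={n: -0.01 for n in continuous} | {"PM": -0.01},
        ),
        CovariateSpec(
            "deprivation", mean=0.0, sd=1.0,
            effects={n: -0.05 for n in continuous} | {"PM": -0.05},
        ),
    ]
    spec = ScenarioSpec(
        n_participants=n_participants,
        seed=seed,
        age_range=(40.0, 70.0),
        sex_ratio=0.542,
        covariates=covariates,
        medications=medications,
        outcomes=outcomes,
    )
    spec.validate()
    return spec
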