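"""Population-level cognitive footprints from posterior medication effects.

The cognitive footprint of a medication on an outcome is its per-person
effect multiplied by the number of exposed people in a target population:
for each posterior draw s,

    footprint_s = beta_s * sum_over_strata( prevalence_strata * N_strata ),

summarized by the mean and equal-tailed 95% quantiles of the footprint
draws (exact linear propagation — no delta method).  Units are
person-Z-scores for continuous outcomes.  For the binary outcome the
per-person effect is the average marginal effect on the probability scale,
so the footprint counts people (predicted change in the number doing the
test correctly).  A footprint is *reportable* when the 50% equal-tailed
interval of the underlying coefficient excludes zero.

All footprints are exploratory upper bounds: they assume the
cross-sectional association is causal and that cohort prevalence matches
the target population.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit

from .horseshoe import PosteriorFit
from .preprocess import DesignMatrix

__all__ = [
    "PopulationStrata",
    "FootprintEstimate",
    "odds_ratio",
    "medication_footprint",
    "binary_footprint",
    "intervention_footprint",
    "select_reportable",
    "default_uk_strata",
]

REPORTABLE_NOTE = "exploratory upper bound"


@dataclass
class PopulationStrata:
    """Age-bin x sex population cells with per-medication prevalence.

    ``table`` columns: age_lo, age_hi, sex, N, then one prevalence column
    per medication code.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"age_lo", "age_hi", "sex", "N"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"strata table lacks columns: {sorted(missing)}")
        if (self.table["N"] < 0).any():
            raise ValueError("stratum population counts must be >= 0")

    @property
    def total_population(self) -> float:
        return float(self.table["N"].sum())

    def exposed_population(self, code: str) -> float:
        """Sum over cells of prevalence x N for one medication."""
        if code not in self.table.columns:
            raise KeyError(f"no prevalence column for {code!r}")
        p = self.table[code]
        if p.isna().any():
            cells = self.table.loc[p.isna(), ["age_lo", "age_hi", "sex"]]
            raise ValueError(
                f"missing prevalence for {code!r} in strata: "
                + "; ".join(
                    f"{r.age_lo:g}-{r.age_hi:g}:{r.sex}"
                    for r in cells.itertuples()
                )
            )
        if ((p < 0) | (p > 1)).any():
            raise ValueError(f"prevalence for {code!r} outside [0, 1]")
        return float((p * self.table["N"]).sum())

    @classmethod
    def from_csv(cls, path: str | Path) -> "PopulationStrata":
        return cls(pd.read_csv(path))

    def to_csv(self, path: str | Path) -> None:
        self.table.to_csv(path, index=False)

    @classmethod
    def from_cohort_prevalence(
        cls,
        cohort_data: pd.DataFrame,
        codes: list[str],
        counts: pd.DataFrame,
    ) -> "PopulationStrata":
        """Strata whose prevalence is estimated from a cohort.

        ``counts`` carries age_lo, age_hi, sex, N; prevalence of each code
        is the cohort's observed exposure fraction within the matching
        age x sex cell (the extrapolation assumes target-population
        prevalence equals cohort prevalence, stratified by age and sex).
        """
        rows = []
        for rec in counts.itertuples():
            in_cell = (
                (cohort_data["age"] >= rec.age_lo)
                & (cohort_data["age"] < rec.age_hi)
                & (cohort_data["sex"] == rec.sex)
            )
            row = {
                "age_lo": rec.age_lo,
                "age_hi": rec.age_hi,
                "sex": rec.sex,
                "N": rec.N,
            }
            cell = cohort_data.loc[in_cell]
            for code in codes:
                row[code] = float(cell[code].mean()) if len(cell) else 0.0
            rows.append(row)
        return cls(pd.DataFrame(rows))


@dataclass
class FootprintEstimate:
    """One population-level footprint with propagated credible interval."""

    target: str
    outcome: str
    point: float  # person-Z-scores (continuous) or persons (binary)
    ci_low: float
    ci_high: float
    coef_q25: float  # 50% interval of the underlying coefficient
    coef_q75: float
    reportable: bool
    kind: str  # "medication" | "intervention"
    note: str = REPORTABLE_NOTE

    @property
    def direction(self) -> int:
        return int(np.sign(self.point))


def odds_ratio(beta: float) -> float:
    """exp(beta): the odds ratio for a log-odds coefficient."""
    if not np.isfinite(beta):
        raise ValueError("beta must be finite")
    return float(np.exp(beta))


def _summaries(draws: np.ndarray) -> tuple[float, float, float]:
    return (
        float(draws.mean()),
        float(np.quantile(draws, 0.025)),
        float(np.quantile(draws, 0.975)),
    )


def _reportable(coef_draws: np.ndarray) -> tuple[float, float, bool]:
    q25, q75 = np.quantile(coef_draws, [0.25, 0.75])
    # zero on a boundary counts as contained -> not reportable
    return float(q25), float(q75), bool(q25 > 0.0 or q75 < 0.0)


def medication_footprint(
    beta_draws: np.ndarray,
    strata: PopulationStrata,
    code: str,
    outcome: str = "",
) -> FootprintEstimate:
    """Continuous-outcome footprint: beta draws x exposed population.

    ``beta_draws`` must be on the raw exposure scale (effect of being
    exposed, i.e. the standardized coefficient divided by the exposure
    column's SD).
    """
    exposed = strata.exposed_population(code)
    fp = np.asarray(beta_draws, dtype=float) * exposed
    point, lo, hi = _summaries(fp)
    q25, q75, rep = _reportable(np.asarray(beta_draws, dtype=float))
    return FootprintEstimate(
        target=code, outcome=outcome, point=point, ci_low=lo, ci_high=hi,
        coef_q25=q25, coef_q75=q75, reportable=rep, kind="medication",
    )


def binary_footprint(
    fit: PosteriorFit,
    design: DesignMatrix,
    strata: PopulationStrata,
    code: str,
    outcome: str = "",
    max_draws: int = 1000,
    max_rows: int = 4000,
) -> FootprintEstimate:
    """Binary-outcome footprint in persons, via the average marginal effect.

    Per draw, the AME is the mean over sampled participants of
    P(success | exposed) - P(success | unexposed), holding all other
    predictors at their observed values; the footprint multiplies it by the
    exposed population.  Both draws and participants are strided down to at
    most ``max_draws`` x ``max_rows`` for tractability (deterministic
    striding, no resampling).
    """
    if fit.kind != "logistic":
        raise ValueError("binary footprint requires a logistic fit")
    j = design.column(code)
    meta = design.columns[j]
    X = design.X
    if X.shape[0] > max_rows:
        X = X[:: int(np.ceil(X.shape[0] / max_rows))]
    beta = fit.beta
    if beta.shape[0] > max_draws:
        beta = beta[:: int(np.ceil(beta.shape[0] / max_draws))]

    # exposure column is standardized; raw 1/0 map to these two values
    x1 = (1.0 - meta.mean) / meta.sd
    x0 = (0.0 - meta.mean) / meta.sd
    eta_other = X @ beta.T - np.outer(X[:, j], beta[:, j])  # (n, S)
    p1 = expit(eta_other + x1 * beta[:, j])
    p0 = expit(eta_other + x0 * beta[:, j])
    ame = (p1 - p0).mean(axis=0)  # (S,)

    exposed = strata.exposed_population(code)
    fp = ame * exposed
    point, lo, hi = _summaries(fp)
    q25, q75, rep = _reportable(beta[:, j])
    return FootprintEstimate(
        target=code, outcome=outcome, point=point, ci_low=lo, ci_high=hi,
        coef_q25=q25, coef_q75=q75, reportable=rep, kind="medication",
    )


def intervention_footprint(
    beta_std_draws: np.ndarray,
    column_sd: float,
    delta_units: float,
    strata: PopulationStrata,
    target: str = "",
    outcome: str = "",
) -> FootprintEstimate:
    """Footprint of shifting a continuous covariate across the population.

    The standardized coefficient is de-standardized with the recorded
    column SD (effect per original unit), multiplied by the intervention
    amount and the entire population (no prevalence term).
    """
    if not np.isfinite(column_sd) or column_sd <= 0:
        raise ValueError("missing or invalid standardization constant")
    per_unit = np.asarray(beta_std_draws, dtype=float) / column_sd
    fp = per_unit * delta_units * strata.total_population
    point, lo, hi = _summaries(fp)
    q25, q75, rep = _reportable(np.asarray(beta_std_draws, dtype=float))
    return FootprintEstimate(
        target=target, outcome=outcome, point=point, ci_low=lo, ci_high=hi,
        coef_q25=q25, coef_q75=q75, reportable=rep, kind="intervention",
    )


def select_reportable(
    estimates: list[FootprintEstimate],
) -> list[FootprintEstimate]:
    """Keep footprints whose coefficient 50% interval excludes zero."""
    return [e for e in estimates if e.reportable]


def footprint_table(estimates: list[FootprintEstimate]) -> pd.DataFrame:
    rows = [
        {
            "target": e.target,
            "outcome": e.outcome,
            "footprint": e.point,
            "ci_low": e.ci_low,
            "ci_high": e.ci_high,
            "coef_q25": e.coef_q25,
            "coef_q75": e.coef_q75,
            "reportable": e.reportable,
            "direction": e.direction,
            "note": e.note,
        }
        for e in sorted(estimates, key=lambda e: -abs(e.point))
    ]
    return pd.DataFrame(rows)


def default_uk_strata(
    codes: list[str],
    prevalence: dict[str, float] | None = None,
    total: float = 24_600_000.0,
) -> PopulationStrata:
    """An illustrative synthetic population aged 40-70.

    Twelve 5-year x sex cells summing to ``total`` (default 24.6 million, a
    round UK-scale figure for ages 40-70; the real denominators behind the
    published footprints are not public, so this default is openly
    synthetic).  If ``prevalence`` is given, every cell carries that flat
    per-code prevalence; stratified prevalence should instead come from
    :meth:`PopulationStrata.from_cohort_prevalence`.
    """
    bins = [(40, 45), (45, 50), (50, 55), (55, 60), (60, 65), (65, 70)]
    weights = np.array([1.05, 1.05, 1.0, 1.0, 0.95, 0.95])
    weights = weights / weights.sum() / 2.0  # split between sexes
    rows = []
    for (lo, hi), w in zip(bins, weights):
        for sex in ("F", "M"):
            row = {"age_lo": lo, "age_hi": hi, "sex": sex, "N": total * w}
            for code in codes:
                row[code] = (prevalence or {}).get(code, np.nan)
            rows.append(row)
    return PopulationStrata(pd.DataFrame(rows))
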