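"""Outcome normalization, PCA-cognition composite, and design construction.

Continuous cognitive scores are z-scored (mean 0, SD 1 over non-missing
entries) with the sign reversed where needed so that a larger score always
means better performance.  Cognition's facets correlate strongly, so the
first principal component of the normalized test battery serves as a
summary outcome ("PCA-cognition").  The binary prospective-memory outcome
is never z-scored; it enters a logistic model as 0/1.

Design matrices are built per model on the complete-case sample for the
chosen outcome and all predictors, with every non-intercept column
standardized (recording the constants needed to back-transform
coefficients to raw units) and categorical covariates dummy-coded against
their first level.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .cohort import Cohort

logger = logging.getLogger(__name__)

__all__ = [
    "OutcomeVector",
    "CompositeScore",
    "ColumnMeta",
    "DesignMatrix",
    "DegenerateOutcomeError",
    "normalize_outcome",
    "pca_composite",
    "build_design",
]


class DegenerateOutcomeError(ValueError):
    """Outcome has no variance (or too few distinct values) to normalize."""


@dataclass
class OutcomeVector:
    """An analysis-ready outcome: z-scored if continuous, 0/1 if binary."""

    values: np.ndarray  # NaN where missing
    kind: str  # "continuous" | "binary"
    orientation_flipped: bool
    source_name: str


@dataclass
class CompositeScore:
    """First principal component of a normalized test battery."""

    loadings: np.ndarray  # unit Euclidean norm, one entry per test
    test_names: list[str]
    explained_variance_fraction: float
    values: np.ndarray  # per-participant composite, re-standardized


@dataclass
class ColumnMeta:
    name: str
    role: str  # "intercept" | "medication" | "covariate"
    atc_level: int | None = None
    mean: float = 0.0
    sd: float = 1.0


@dataclass
class DesignMatrix:
    """Complete-case standardized predictor matrix with column metadata."""

    X: np.ndarray  # n x p, float64, no missing entries
    columns: list[ColumnMeta]
    row_index: np.ndarray  # positions into the source cohort table

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]

    def column_names(self) -> list[str]:
        return [c.name for c in self.columns]

    def medication_indices(self) -> list[int]:
        return [i for i, c in enumerate(self.columns) if c.role == "medication"]

    def column(self, name: str) -> int:
        for i, c in enumerate(self.columns):
            if c.name == name:
                return i
        raise KeyError(name)


def _zscore(values: np.ndarray) -> np.ndarray:
    obs = ~np.isnan(values)
    mu = values[obs].mean()
    sd = values[obs].std(ddof=0)
    out = np.full_like(values, np.nan, dtype=float)
    out[obs] = (values[obs] - mu) / sd
    return out


def normalize_outcome(
    raw: np.ndarray | pd.Series,
    larger_is_worse: bool = False,
    kind: str = "continuous",
    name: str = "",
) -> OutcomeVector:
    """Z-score a raw outcome, flipping sign first when larger means worse.

    Binary outcomes pass through unchanged (0/1, missing allowed).
    """
    values = np.asarray(raw, dtype=float).copy()
    if kind == "binary":
        obs = values[~np.isnan(values)]
        if not np.isin(obs, (0.0, 1.0)).all():
            raise ValueError(f"binary outcome {name!r} has values outside {{0,1}}")
        return OutcomeVector(values, "binary", False, name)
    obs = values[~np.isnan(values)]
    if len(np.unique(obs)) < 2:
        raise DegenerateOutcomeError(
            f"outcome {name!r} has fewer than 2 distinct non-missing values"
        )
    if larger_is_worse:
        values = -values
    return OutcomeVector(_zscore(values), "continuous", larger_is_worse, name)


def pca_composite(
    tests: pd.DataFrame, min_tests: int = 2
) -> CompositeScore:
    """First principal component of a battery of normalized tests.

    Rows with any missing test are excluded.  The component is computed
    from the correlation matrix (tests are re-standardized on the
    complete-case sample), its sign chosen so the composite correlates
    positively with the row-mean of the tests, and the per-participant
    composite re-standardized to mean 0, SD 1.  Participants missing any
    test get NaN.
    """
    if tests.shape[1] < min_tests:
        raise ValueError(
            f"need at least {min_tests} tests, got {tests.shape[1]}"
        )
    complete = tests.dropna()
    if complete.shape[0] < tests.shape[1]:
        raise ValueError(
            "rank-deficient battery: fewer complete rows than tests"
        )
    Z = complete.to_numpy(dtype=float)
    Z = (Z - Z.mean(axis=0)) / Z.std(axis=0, ddof=0)
    # PCA of standardized columns == eigendecomposition of the correlation
    # matrix; sklearn normalizes eigenvalues by (n-1)
    pca = PCA(n_components=1, svd_solver="full")
    scores = pca.fit_transform(Z)[:, 0]
    loadings = pca.components_[0]
    evf = float(pca.explained_variance_ratio_[0])
    if np.corrcoef(scores, Z.mean(axis=1))[0, 1] < 0:
        loadings = -loadings
        scores = -scores
    scores = (scores - scores.mean()) / scores.std(ddof=0)
    values = np.full(len(tests), np.nan)
    values[tests.index.get_indexer(complete.index)] = scores
    return CompositeScore(
        loadings=loadings,
        test_names=list(tests.columns),
        explained_variance_fraction=evf,
        values=values,
    )


def build_design(
    cohort: Cohort,
    retained_codes: list[str],
    outcome: OutcomeVector,
    covariates: list[str] | None = None,
    atc_level: int = 5,
    exposures: pd.DataFrame | None = None,
) -> tuple[DesignMatrix, OutcomeVector]:
    """Assemble the standardized complete-case design for one model.

    Predictors are an intercept, one column per retained medication code
    (from ``exposures`` if given — e.g. a level-4 aggregate — else the
    cohort's native exposure columns), age, sex and any further covariates.
    Continuous outcome values are re-standardized on the complete-case
    sample, so coefficients are in Z-scores of that sample; column
    standardization constants are recorded for back-transformation.
    Constant predictor columns after subsetting are dropped with a warning.
    """
    if covariates is None:
        covariates = ["age", "sex", *cohort.covariate_cols]
    exp = exposures if exposures is not None else cohort.exposures()

    pieces: list[tuple[ColumnMeta, np.ndarray]] = []
    for code in retained_codes:
        pieces.append(
            (
                ColumnMeta(code, "medication", atc_level),
                exp[code].to_numpy(dtype=float),
            )
        )
    for name in covariates:
        col = cohort.data[name]
        if col.dtype == object or isinstance(col.dtype, pd.CategoricalDtype):
            levels = sorted(col.dropna().unique())
            for lev in levels[1:]:  # first level is the reference
                pieces.append(
                    (
                        ColumnMeta(f"{name}={lev}", "covariate"),
                        (col == lev).to_numpy(dtype=float),
                    )
                )
        else:
            pieces.append(
                (ColumnMeta(name, "covariate"), col.to_numpy(dtype=float))
            )

    y = outcome.values
    mask = ~np.isnan(y)
    for _, vals in pieces:
        mask &= ~np.isnan(vals)
    if not mask.any():
        raise ValueError(
            f"no complete-case rows for outcome {outcome.source_name!r}"
        )
    rows = np.flatnonzero(mask)

    metas: list[ColumnMeta] = [ColumnMeta("intercept", "intercept")]
    cols: list[np.ndarray] = [np.ones(len(rows))]
    for meta, vals in pieces:
        v = vals[rows]
        sd = v.std(ddof=0)
        if sd == 0.0:
            logger.warning(
                "dropping constant column %r after complete-case subsetting",
                meta.name,
            )
            continue
        meta.mean = float(v.mean())
        meta.sd = float(sd)
        cols.append((v - meta.mean) / meta.sd)
        metas.append(meta)

    X = np.column_stack(cols)
    y_sub = y[rows]
    if outcome.kind == "continuous":
        # per-model Z-scale: re-standardize on this model's sample
        y_sub = (y_sub - y_sub.mean()) / y_sub.std(ddof=0)
    out = OutcomeVector(
        y_sub, outcome.kind, outcome.orientation_flipped, outcome.source_name
    )
    return DesignMatrix(X=X, columns=metas, row_index=rows), out
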