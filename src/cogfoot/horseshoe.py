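"""Gibbs sampling for linear and logistic regression under horseshoe priors.

Model (linear):

    y | beta, sigma^2      ~ Normal(X beta, sigma^2 I)
    beta_j | lambda_j, tau ~ Normal(0, lambda_j^2 tau^2 sigma^2)   (penalized)
    lambda_j               ~ half-Cauchy(0, 1)
    tau                    ~ half-Cauchy(0, 1)
    sigma^2                ~ 1 / sigma^2   (Jeffreys)

The intercept (and by default the age coefficient) carries a flat prior.
Each local half-Cauchy scale is expanded with an inverse-gamma auxiliary
variable, making lambda_j^2, sigma^2 and the auxiliaries conjugate
inverse-gamma draws; the coefficient block is drawn jointly from its
multivariate-normal full conditional via a Cholesky factorization of
X'X + D^-1.  The global scale tau is updated by a random-walk Metropolis
step on log tau targeting its conditional with the coefficients integrated
out analytically: conditioning tau on the current beta creates a funnel in
which tau and beta collapse towards zero together and the chain can stall
in a fully-shrunk state; the marginal update walks across shrinkage
regimes freely (the coefficient block is redrawn immediately afterwards,
so the move is a valid partially-collapsed Gibbs step).

The logistic sampler replaces the Gaussian likelihood with Pólya-Gamma
data augmentation: latent omega_i ~ PG(1, x_i'beta) makes the coefficient
update conditionally Gaussian with working precision X' Omega X and
pseudo-response kappa = y - 1/2; the shrinkage hyperpriors update exactly
as in the linear sampler (with sigma^2 fixed at 1).

Every inverse-gamma variate is drawn as rate / Gamma(shape, 1), so with a
fixed seed the entire draw path is reproducible and, for the linear model,
exactly scale-equivariant in the outcome.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve, solve_triangular
from scipy.stats import rankdata

from .polya_gamma import sample_pg
from .preprocess import ColumnMeta, DesignMatrix, OutcomeVector

__all__ = [
    "HorseshoeConfig",
    "PosteriorFit",
    "CoefficientSummary",
    "SeparationError",
    "fit_linear_horseshoe",
    "fit_logistic_horseshoe",
    "summarize_fit",
    "rank_statistic",
    "top_k",
]


class SeparationError(ValueError):
    """Binary outcome is constant; the logistic model is not identified."""


@dataclass
class HorseshoeConfig:
    """Sampler controls.

    ``unpenalized`` names design columns given a flat prior; the default
    leaves the intercept and age unshrunk.  ``fixed_tau``, ``fixed_lambda``
    and ``fixed_sigma2`` pin hyperparameters (used by conjugate-oracle
    tests); when None they are sampled.
    """

    n_iter: int = 4000
    burn_in: int = 1000
    thin: int = 1
    seed: int = 0
    unpenalized: tuple[str, ...] = ("intercept", "age")
    fixed_tau: float | None = None
    fixed_lambda: float | None = None
    fixed_sigma2: float | None = None
    pg_terms: int = 64
    tau_proposal_sd: float = 0.8

    def __post_init__(self) -> None:
        if not self.n_iter > self.burn_in >= 0:
            raise ValueError("require n_iter > burn_in >= 0")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")

    @property
    def n_draws(self) -> int:
        return (self.n_iter - self.burn_in) // self.thin


@dataclass
class PosteriorFit:
    """Retained MCMC draws plus column metadata and diagnostics.

    ``beta`` is S x p: Z-score per SD of predictor for linear models,
    log-odds per SD for logistic ones.  ``lam`` holds local shrinkage
    scales (1.0 in unpenalized columns).
    """

    beta: np.ndarray
    tau: np.ndarray
    lam: np.ndarray
    sigma2: np.ndarray | None
    kind: str  # "linear" | "logistic"
    columns: list[ColumnMeta]
    config: HorseshoeConfig
    outcome_name: str = ""
    atc_level: int | None = None
    diagnostics: dict = field(default_factory=dict)

    @property
    def n_draws(self) -> int:
        return self.beta.shape[0]

    def column_names(self) -> list[str]:
        return [c.name for c in self.columns]

    def medication_indices(self) -> list[int]:
        return [i for i, c in enumerate(self.columns) if c.role == "medication"]

    def beta_for(self, name: str) -> np.ndarray:
        return self.beta[:, self.column_names().index(name)]

    # -- persistence: compressed columnar draws + JSON sidecar ------------

    def save(self, path: str | Path) -> None:
        path = Path(path)
        cols = {f"beta_{c.name}": self.beta[:, i] for i, c in enumerate(self.columns)}
        cols["tau"] = self.tau
        if self.sigma2 is not None:
            cols["sigma2"] = self.sigma2
        pd.DataFrame(cols).to_parquet(path, compression="zstd")
        sidecar = {
            "kind": self.kind,
            "outcome_name": self.outcome_name,
            "atc_level": self.atc_level,
            "config": asdict(self.config),
            "columns": [asdict(c) for c in self.columns],
            "diagnostics": self.diagnostics,
        }
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "PosteriorFit":
        path = Path(path)
        draws = pd.read_parquet(path)
        sidecar = json.loads(path.with_suffix(".json").read_text())
        columns = [ColumnMeta(**c) for c in sidecar["columns"]]
        cfg_d = sidecar["config"]
        cfg_d["unpenalized"] = tuple(cfg_d["unpenalized"])
        beta = np.column_stack([draws[f"beta_{c.name}"].to_numpy() for c in columns])
        return cls(
            beta=beta,
            tau=draws["tau"].to_numpy(),
            lam=np.ones_like(beta),
            sigma2=draws["sigma2"].to_numpy() if "sigma2" in draws else None,
            kind=sidecar["kind"],
            columns=columns,
            config=HorseshoeConfig(**cfg_d),
            outcome_name=sidecar["outcome_name"],
            atc_level=sidecar["atc_level"],
            diagnostics=sidecar["diagnostics"],
        )


@dataclass
class CoefficientSummary:
    """Per-predictor posterior summaries in a Table-3-like layout."""

    table: pd.DataFrame  # name, role, mean, q2.5, q25, q75, q97.5, rank, OR
    r2: float
    kind: str
    outcome_name: str = ""
    atc_level: int | None = None

    def to_csv(self, path: str | Path) -> None:
        df = self.table.copy()
        df.insert(0, "outcome", self.outcome_name)
        df.insert(1, "atc_level", self.atc_level)
        df["r2"] = self.r2
        df.to_csv(path, index=False, float_format="%.6g")


# scale draws clipped to this range so 1/(tau^2 lambda_j^2) stays finite;
# the bounds are far outside any region with appreciable posterior mass
_SCALE2_MIN, _SCALE2_MAX = 1e-12, 1e12


def _inv_gamma(rng: np.random.Generator, shape: float, rate, size=None):
    """rate / Gamma(shape, 1): inverse-gamma with the given shape and rate."""
    return rate / rng.gamma(shape, 1.0, size=size)


def _inv_gamma_scale2(rng: np.random.Generator, shape: float, rate, size=None):
    return np.clip(
        _inv_gamma(rng, shape, rate, size=size), _SCALE2_MIN, _SCALE2_MAX
    )


def _check_finite(X: np.ndarray, y: np.ndarray) -> None:
    if not np.isfinite(X).all():
        raise ValueError("design matrix contains non-finite values")
    if not np.isfinite(y).all():
        raise ValueError("outcome contains non-finite values")


def _penalized_mask(columns: list[ColumnMeta], cfg: HorseshoeConfig) -> np.ndarray:
    return np.array([c.name not in cfg.unpenalized for c in columns])


# hard bounds on log tau for the Metropolis step; proposals outside are
# rejected so 1/(tau^2 lambda^2) stays representable
_LOG_TAU_BOUND = 30.0


def _chol_state(M: np.ndarray, b: np.ndarray, lam2, pen, tau2: float):
    """Cholesky of A = M + D^-1 plus the half-solved quadratic term.

    Returns (L, w, logdet, quad) with A = L L', w = L^-1 b, so that
    b'A^-1 b = w'w and the coefficient draw can reuse L and w.
    """
    p = M.shape[0]
    d_inv = np.zeros(p)
    d_inv[pen] = 1.0 / (tau2 * lam2[pen])
    A = M + np.diag(d_inv)
    L = cho_factor(A, lower=True)[0]
    w = solve_triangular(L, b, lower=True)
    logdet = 2.0 * np.log(np.diag(L)).sum()
    return L, w, logdet, float(w @ w)


def _tau_log_target(
    u: float, quad: float, logdet: float, n_pen: int, sigma2: float
) -> float:
    """log p(log tau | lambda, sigma^2, y) with beta integrated out.

    Marginal likelihood (up to tau-free constants):
    |A|^-1/2 |D_pen|^-1/2 exp(b'A^-1 b / (2 sigma^2)); plus the half-Cauchy
    prior on tau and the log-scale Jacobian.
    """
    return (
        0.5 * quad / sigma2
        - 0.5 * logdet
        - n_pen * u
        - np.logaddexp(0.0, 2.0 * u)
        + u
    )


def fit_linear_horseshoe(
    design: DesignMatrix, outcome: OutcomeVector, config: HorseshoeConfig
) -> PosteriorFit:
    """Blocked Gibbs sampler for the Gaussian horseshoe regression."""
    if outcome.kind != "continuous":
        raise ValueError("linear sampler requires a continuous outcome")
    X, y = design.X, np.asarray(outcome.values, dtype=float)
    if X.shape[0] != y.shape[0]:
        raise ValueError("design and outcome dimensions disagree")
    _check_finite(X, y)
    n, p = X.shape
    cfg = config
    pen = _penalized_mask(design.columns, cfg)
    n_pen = int(pen.sum())
    rng = np.random.default_rng(cfg.seed)

    XtX = X.T @ X
    Xty = X.T @ y

    lam2 = np.ones(p)
    nu = np.ones(p)
    u = 0.0 if cfg.fixed_tau is None else float(np.log(cfg.fixed_tau))
    tau2 = np.exp(2.0 * u)
    # initializing at var(y) keeps the whole draw path exactly
    # scale-equivariant in y (every later conditional is too)
    sigma2 = float(y.var()) if cfg.fixed_sigma2 is None else cfg.fixed_sigma2
    if cfg.fixed_lambda is not None:
        lam2 = np.full(p, cfg.fixed_lambda**2)

    S = cfg.n_draws
    beta_out = np.empty((S, p))
    tau_out = np.empty(S)
    lam_out = np.empty((S, p))
    sig_out = np.empty(S)

    s = 0
    n_accept = 0
    L, w, logdet, quad = _chol_state(XtX, Xty, lam2, pen, tau2)
    for it in range(cfg.n_iter):
        # tau | lambda, sigma^2, y (beta marginalized): RW-Metropolis
        if cfg.fixed_tau is None and n_pen > 0:
            u_prop = u + cfg.tau_proposal_sd * rng.standard_normal()
            accept_draw = rng.random()
            if abs(u_prop) <= _LOG_TAU_BOUND:
                prop = _chol_state(XtX, Xty, lam2, pen, np.exp(2 * u_prop))
                lf_prop = _tau_log_target(
                    u_prop, prop[3], prop[2], n_pen, sigma2
                )
                lf_cur = _tau_log_target(u, quad, logdet, n_pen, sigma2)
                if np.log(accept_draw) < lf_prop - lf_cur:
                    u, tau2 = u_prop, float(np.exp(2 * u_prop))
                    L, w, logdet, quad = prop
                    n_accept += 1

        # beta | rest: N(A^-1 X'y, sigma^2 A^-1), A = X'X + D^-1 = L L'
        mean = solve_triangular(L.T, w, lower=False)
        z = rng.standard_normal(p)
        beta = mean + np.sqrt(sigma2) * solve_triangular(L.T, z, lower=False)

        b_pen = beta[pen]
        if cfg.fixed_lambda is None:
            rate_l = 1.0 / nu[pen] + b_pen**2 / (2.0 * tau2 * sigma2)
            lam2[pen] = _inv_gamma_scale2(rng, 1.0, rate_l)
            nu[pen] = _inv_gamma(rng, 1.0, 1.0 + 1.0 / lam2[pen])
        if cfg.fixed_sigma2 is None:
            resid = y - X @ beta
            rate_s = 0.5 * (resid @ resid) + 0.5 * (
                b_pen**2 / (tau2 * lam2[pen])
            ).sum()
            sigma2 = _inv_gamma(rng, (n + n_pen) / 2.0, rate_s)
        # lambda (and sigma^2) changed: refresh the factorization
        L, w, logdet, quad = _chol_state(XtX, Xty, lam2, pen, tau2)

        if it >= cfg.burn_in and (it - cfg.burn_in) % cfg.thin == 0:
            beta_out[s] = beta
            tau_out[s] = np.sqrt(tau2)
            lam_out[s] = np.sqrt(lam2)
            sig_out[s] = sigma2
            s += 1

    fit = PosteriorFit(
        beta=beta_out[:s],
        tau=tau_out[:s],
        lam=lam_out[:s],
        sigma2=sig_out[:s],
        kind="linear",
        columns=design.columns,
        config=cfg,
        outcome_name=outcome.source_name,
    )
    fit.diagnostics = _diagnostics(fit)
    fit.diagnostics["tau_accept_rate"] = n_accept / cfg.n_iter
    return fit


def fit_logistic_horseshoe(
    design: DesignMatrix, outcome: OutcomeVector, config: HorseshoeConfig
) -> PosteriorFit:
    """Pólya-Gamma-augmented Gibbs sampler for the logistic horseshoe."""
    X = design.X
    y = np.asarray(outcome.values, dtype=float)
    _check_finite(X, y)
    if not np.isin(y, (0.0, 1.0)).all():
        raise ValueError("logistic sampler requires a 0/1 outcome")
    if y.min() == y.max():
        raise SeparationError("outcome is constant (all 0s or all 1s)")
    n, p = X.shape
    cfg = config
    pen = _penalized_mask(design.columns, cfg)
    n_pen = int(pen.sum())
    rng = np.random.default_rng(cfg.seed)

    kappa = y - 0.5
    Xt_kappa = X.T @ kappa

    beta = np.zeros(p)
    lam2 = np.ones(p)
    nu = np.ones(p)
    u = 0.0 if cfg.fixed_tau is None else float(np.log(cfg.fixed_tau))
    tau2 = np.exp(2.0 * u)
    if cfg.fixed_lambda is not None:
        lam2 = np.full(p, cfg.fixed_lambda**2)

    S = cfg.n_draws
    beta_out = np.empty((S, p))
    tau_out = np.empty(S)
    lam_out = np.empty((S, p))

    s = 0
    n_accept = 0
    for it in range(cfg.n_iter):
        omega = sample_pg(X @ beta, rng, n_terms=cfg.pg_terms)
        M = X.T @ (omega[:, None] * X)
        L, w, logdet, quad = _chol_state(M, Xt_kappa, lam2, pen, tau2)

        # tau | lambda, omega (beta marginalized): RW-Metropolis
        if cfg.fixed_tau is None and n_pen > 0:
            u_prop = u + cfg.tau_proposal_sd * rng.standard_normal()
            accept_draw = rng.random()
            if abs(u_prop) <= _LOG_TAU_BOUND:
                prop = _chol_state(M, Xt_kappa, lam2, pen, np.exp(2 * u_prop))
                lf_prop = _tau_log_target(u_prop, prop[3], prop[2], n_pen, 1.0)
                lf_cur = _tau_log_target(u, quad, logdet, n_pen, 1.0)
                if np.log(accept_draw) < lf_prop - lf_cur:
                    u, tau2 = u_prop, float(np.exp(2 * u_prop))
                    L, w, logdet, quad = prop
                    n_accept += 1

        # beta | omega, rest: N(A^-1 X'kappa, A^-1), A = X'Omega X + D^-1
        mean = solve_triangular(L.T, w, lower=False)
        z = rng.standard_normal(p)
        beta = mean + solve_triangular(L.T, z, lower=False)

        b_pen = beta[pen]
        if cfg.fixed_lambda is None:
            rate_l = 1.0 / nu[pen] + b_pen**2 / (2.0 * tau2)
            lam2[pen] = _inv_gamma_scale2(rng, 1.0, rate_l)
            nu[pen] = _inv_gamma(rng, 1.0, 1.0 + 1.0 / lam2[pen])

        if it >= cfg.burn_in and (it - cfg.burn_in) % cfg.thin == 0:
            beta_out[s] = beta
            tau_out[s] = np.sqrt(tau2)
            lam_out[s] = np.sqrt(lam2)
            s += 1

    fit = PosteriorFit(
        beta=beta_out[:s],
        tau=tau_out[:s],
        lam=lam_out[:s],
        sigma2=None,
        kind="logistic",
        columns=design.columns,
        config=cfg,
        outcome_name=outcome.source_name,
    )
    fit.diagnostics = _diagnostics(fit)
    fit.diagnostics["tau_accept_rate"] = n_accept / cfg.n_iter
    return fit


def _diagnostics(fit: PosteriorFit) -> dict:
    """Effective sample size per coefficient (arviz), plus basic checks."""
    import arviz as az

    ess = az.ess(az.convert_to_dataset(fit.beta[None, :, :])).x.to_numpy()
    return {
        "ess": {c.name: float(e) for c, e in zip(fit.columns, ess)},
        "min_ess": float(ess.min()),
        "all_finite": bool(np.isfinite(fit.beta).all()),
    }


def _bayes_r2(fit: PosteriorFit, design: DesignMatrix, y: np.ndarray) -> float:
    """Draw-wise variance-explained ratio, averaged over draws.

    Linear: var(X beta) / (var(X beta) + var(y - X beta)).  Logistic:
    var(p_i) / (var(p_i) + mean(p_i (1 - p_i))) on the probability scale.
    """
    X = design.X
    r2 = np.empty(fit.n_draws)
    for s in range(fit.n_draws):
        eta = X @ fit.beta[s]
        if fit.kind == "linear":
            vf = eta.var()
            vr = (y - eta).var()
        else:
            prob = 1.0 / (1.0 + np.exp(-eta))
            vf = prob.var()
            vr = (prob * (1.0 - prob)).mean()
        r2[s] = vf / (vf + vr)
    return float(r2.mean())


def summarize_fit(
    fit: PosteriorFit,
    design: DesignMatrix | None = None,
    outcome: OutcomeVector | None = None,
    levels: tuple[float, float] = (0.50, 0.95),
) -> CoefficientSummary:
    """Posterior means, equal-tailed 50%/95% intervals, ranks, ORs and R²."""
    if fit.n_draws < 100:
        raise ValueError("need at least 100 retained draws to summarize")
    qs = sorted(
        {(1 - lev) / 2 for lev in levels} | {(1 + lev) / 2 for lev in levels}
    )
    quant = np.quantile(fit.beta, qs, axis=0)
    mean = fit.beta.mean(axis=0)
    med_idx = fit.medication_indices()
    ranks = np.full(fit.beta.shape[1], np.nan)
    if len(med_idx) >= 2:
        ranks[med_idx] = rank_statistic(fit, med_idx)
    table = pd.DataFrame(
        {
            "name": fit.column_names(),
            "role": [c.role for c in fit.columns],
            "mean": mean,
            "q2.5": quant[0],
            "q25": quant[1],
            "q75": quant[2],
            "q97.5": quant[3],
            "rank": ranks,
        }
    )
    if fit.kind == "logistic":
        table["OR"] = np.exp(mean)
    r2 = np.nan
    if design is not None and (outcome is not None or fit.kind == "logistic"):
        yv = outcome.values if outcome is not None else None
        r2 = _bayes_r2(fit, design, yv)
    return CoefficientSummary(
        table=table,
        r2=r2,
        kind=fit.kind,
        outcome_name=fit.outcome_name,
        atc_level=fit.atc_level,
    )


def rank_statistic(
    fit: PosteriorFit, medication_indices: list[int] | None = None
) -> np.ndarray:
    """Mean posterior rank of |beta| among medication columns.

    Within each retained draw, medications are ranked by descending
    absolute coefficient (rank 1 = strongest, ties averaged); the statistic
    is the mean rank over draws.
    """
    idx = medication_indices or fit.medication_indices()
    if len(idx) < 2:
        raise ValueError("need at least 2 medication columns to rank")
    draws = np.abs(fit.beta[:, idx])
    ranks = rankdata(-draws, axis=1, method="average")
    return ranks.mean(axis=0)


def top_k(fit: PosteriorFit, k: int = 10) -> list[str]:
    """The k medications with the smallest mean posterior rank.

    Ties broken by larger posterior mean |beta|, then lexicographic code.
    """
    idx = fit.medication_indices()
    stats = rank_statistic(fit, idx)
    names = [fit.columns[i].name for i in idx]
    mean_abs = np.abs(fit.beta[:, idx].mean(axis=0))
    order = sorted(
        range(len(idx)), key=lambda j: (stats[j], -mean_abs[j], names[j])
    )
    return [names[j] for j in order[:k]]
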