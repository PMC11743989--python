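import numpy as np
import pytest
from scipy.special import logit

from cogfoot import (
    HorseshoeConfig,
    PosteriorFit,
    fit_linear_horseshoe,
    fit_logistic_horseshoe,
    rank_statistic,
    summarize_fit,
    top_k,
)
from cogfoot.horseshoe import SeparationError
from cogfoot.preprocess import ColumnMeta, DesignMatrix, OutcomeVector

from conftest import make_design


def test_conjugate_closed_form_single_predictor():
    # with lambda, tau, sigma^2 pinned at 1 the model is plain ridge and the
    # posterior mean has the closed form (X'X + 1)^-1 X'y
    rng = np.random.default_rng(1)
    n = 500
    x = rng.standard_normal(n)
    x = (x - x.mean()) / x.std()
    y = 0.4 * x + rng.standard_normal(n)
    design = DesignMatrix(
        X=x[:, None], columns=[ColumnMeta("x", "medication", 5)],
        row_index=np.arange(n),
    )
    out = OutcomeVector(y, "continuous", False, "y")
    cfg = HorseshoeConfig(
        n_iter=2500, burn_in=500, seed=2, unpenalized=(),
        fixed_tau=1.0, fixed_lambda=1.0, fixed_sigma2=1.0,
    )
    fit = fit_linear_horseshoe(design, out, cfg)
    closed_form = (x @ y) / (x @ x + 1.0)
    draws = fit.beta[:, 0]
    mc_se = draws.std() / np.sqrt(fit.diagnostics["ess"]["x"])
    assert abs(draws.mean() - closed_form) < 3 * mc_se
    # conditional posterior variance is (X'X + 1)^-1 exactly
    assert draws.var() == pytest.approx(1.0 / (x @ x + 1.0), rel=0.15)


def test_seed_determinism_bit_identical():
    design, y = make_design(n=300, n_meds=5, seed=3)
    cfg = HorseshoeConfig(n_iter=300, burn_in=100, seed=5)
    a = fit_linear_horseshoe(design, y, cfg)
    b = fit_linear_horseshoe(design, y, cfg)
    assert np.array_equal(a.beta, b.beta)
    assert np.array_equal(a.tau, b.tau)
    c = fit_linear_horseshoe(design, y, HorseshoeConfig(n_iter=300, burn_in=100, seed=6))
    assert not np.array_equal(a.beta, c.beta)


def test_scale_equivariance_of_draw_path():
    # multiplying the outcome by c multiplies the whole beta path by c when
    # the same seed drives the chain
    design, y = make_design(n=400, n_meds=6, seed=4, beta=np.r_[0, 0.3, np.zeros(5)])
    cfg = HorseshoeConfig(n_iter=200, burn_in=50, seed=8)
    base = fit_linear_horseshoe(design, y, cfg)
    c = 3.7
    scaled_out = OutcomeVector(y.values * c, "continuous", False, "y")
    scaled = fit_linear_horseshoe(design, scaled_out, cfg)
    assert np.allclose(scaled.beta, c * base.beta, rtol=1e-8, atol=1e-10)
    assert np.allclose(scaled.sigma2, c**2 * base.sigma2, rtol=1e-8)
    assert np.allclose(scaled.tau, base.tau, rtol=1e-8)


def test_shrinkage_beats_ols_on_null_coefficients():
    # the horseshoe posterior mean of a true zero should sit closer to zero
    # than least squares in nearly every replicate
    wins = 0
    reps = 30
    for r in range(reps):
        beta = np.zeros(9)
        beta[1] = 0.5  # one real signal keeps tau honest
        design, y = make_design(n=250, n_meds=8, seed=100 + r, beta=beta)
        cfg = HorseshoeConfig(n_iter=500, burn_in=200, seed=r, unpenalized=("intercept",))
        fit = fit_linear_horseshoe(design, y, cfg)
        ols = np.linalg.lstsq(design.X, y.values, rcond=None)[0]
        null_j = 3
        if abs(fit.beta[:, null_j].mean()) < abs(ols[null_j]):
            wins += 1
    assert wins >= int(0.95 * reps)


def test_null_intervals_cover_zero():
    # pure-noise outcome: nearly all 95% intervals should contain zero
    design, y = make_design(n=1000, n_meds=20, seed=21)
    cfg = HorseshoeConfig(n_iter=800, burn_in=300, seed=13, unpenalized=("intercept",))
    fit = fit_linear_horseshoe(design, y, cfg)
    lo, hi = np.quantile(fit.beta[:, 1:], [0.025, 0.975], axis=0)
    frac = np.mean((lo <= 0) & (0 <= hi))
    assert frac >= 0.90


def test_coverage_calibration_across_replicates():
    # 95% intervals for a strong true coefficient cover it in 90-99% of
    # replicates of a fixed small scenario
    covered = 0
    reps = 50
    for r in range(reps):
        beta = np.r_[0.0, 0.5, np.zeros(9)]
        design, y = make_design(n=400, n_meds=10, seed=500 + r, beta=beta)
        cfg = HorseshoeConfig(n_iter=600, burn_in=200, seed=r)
        fit = fit_linear_horseshoe(design, y, cfg)
        lo, hi = np.quantile(fit.beta[:, 1], [0.025, 0.975])
        covered += lo <= 0.5 <= hi
    assert 0.90 * reps <= covered <= 0.99 * reps + 1


def test_runs_at_contract_scale():
    # dimension contract: n=5,000 x p=300 fits on one CPU (short smoke chain)
    design, y = make_design(n=5000, n_meds=299, seed=30)
    cfg = HorseshoeConfig(n_iter=40, burn_in=10, seed=1)
    fit = fit_linear_horseshoe(design, y, cfg)
    assert fit.beta.shape == (30, 300)
    assert np.isfinite(fit.beta).all()


def test_non_finite_inputs_rejected():
    design, y = make_design(n=100, n_meds=3, seed=31)
    design.X[0, 1] = np.nan
    with pytest.raises(ValueError, match="non-finite"):
        fit_linear_horseshoe(design, y, HorseshoeConfig(n_iter=50, burn_in=10))


class TestLogistic:
    def test_intercept_only_balanced(self):
        rng = np.random.default_rng(40)
        n = 2000
        y = OutcomeVector(
            (rng.random(n) < 0.5).astype(float), "binary", False, "y"
        )
        design = DesignMatrix(
            X=np.ones((n, 1)), columns=[ColumnMeta("intercept", "intercept")],
            row_index=np.arange(n),
        )
        fit = fit_logistic_horseshoe(
            design, y, HorseshoeConfig(n_iter=1500, burn_in=500, seed=3)
        )
        draws = fit.beta[:, 0]
        mc_se = draws.std() / np.sqrt(fit.diagnostics["ess"]["intercept"])
        assert abs(draws.mean() - logit(y.values.mean())) < 3 * mc_se

    def test_base_rate_766(self):
        # intercept recovers the logit of a 76.6% success rate
        rng = np.random.default_rng(41)
        n = 2000
        y = OutcomeVector(
            (rng.random(n) < 0.766).astype(float), "binary", False, "PM"
        )
        design = DesignMatrix(
            X=np.ones((n, 1)), columns=[ColumnMeta("intercept", "intercept")],
            row_index=np.arange(n),
        )
        fit = fit_logistic_horseshoe(
            design, y, HorseshoeConfig(n_iter=1500, burn_in=500, seed=4)
        )
        draws = fit.beta[:, 0]
        mc_se = draws.std() / np.sqrt(fit.diagnostics["ess"]["intercept"])
        assert abs(draws.mean() - logit(y.values.mean())) < 3 * mc_se

    def test_strong_predictor_recovery(self):
        beta = np.r_[0.0, 1.0, np.zeros(4)]
        design, y = make_design(
            n=4000, n_meds=5, seed=42, beta=beta, binary_outcome=True
        )
        fit = fit_logistic_horseshoe(
            design, y, HorseshoeConfig(n_iter=1500, burn_in=500, seed=5)
        )
        assert abs(fit.beta[:, 1].mean() - 1.0) < 0.15

    def test_separation_error(self):
        design, _ = make_design(n=50, n_meds=2, seed=43)
        y = OutcomeVector(np.ones(50), "binary", False, "y")
        with pytest.raises(SeparationError):
            fit_logistic_horseshoe(design, y, HorseshoeConfig(n_iter=50, burn_in=10))


class TestSummaries:
    def test_degenerate_draws_give_point_intervals(self, stored_linear_fit):
        fit, design, y = stored_linear_fit
        frozen = PosteriorFit(
            beta=np.full((200, 2), 1.7),
            tau=np.ones(200),
            lam=np.ones((200, 2)),
            sigma2=np.ones(200),
            kind="linear",
            columns=[ColumnMeta("a", "medication", 5), ColumnMeta("b", "medication", 5)],
            config=fit.config,
        )
        s = summarize_fit(frozen)
        row = s.table.iloc[0]
        assert row["q2.5"] == row["q25"] == row["q75"] == row["q97.5"] == 1.7

    def test_interval_nesting(self, stored_linear_fit, stored_logistic_fit):
        for fit, design, y in (stored_linear_fit, stored_logistic_fit):
            s = summarize_fit(fit, design, y)
            assert (s.table["q2.5"] <= s.table["q25"]).all()
            assert (s.table["q25"] <= s.table["q75"]).all()
            assert (s.table["q75"] <= s.table["q97.5"]).all()

    def test_quantiles_match_sort_based_oracle(self, stored_linear_fit):
        fit, design, y = stored_linear_fit
        s = summarize_fit(fit, design, y)
        draws = fit.beta[:1000]
        # independent oracle: sort and linearly interpolate by hand
        def oracle_quantile(v, q):
            v = np.sort(v.copy())
            h = (len(v) - 1) * q
            lo = int(np.floor(h))
            hi = min(lo + 1, len(v) - 1)
            return v[lo] + (h - lo) * (v[hi] - v[lo])

        sub = summarize_fit(
            PosteriorFit(
                beta=draws, tau=fit.tau[:1000], lam=fit.lam[:1000],
                sigma2=fit.sigma2[:1000], kind="linear", columns=fit.columns,
                config=fit.config,
            )
        )
        for j, name in enumerate(fit.column_names()):
            row = sub.table[sub.table["name"] == name].iloc[0]
            # agreement to the last few ulps (summation order differs)
            assert row["q2.5"] == pytest.approx(
                oracle_quantile(draws[:, j], 0.025), rel=1e-12, abs=1e-15
            )
            assert row["q97.5"] == pytest.approx(
                oracle_quantile(draws[:, j], 0.975), rel=1e-12, abs=1e-15
            )

    def test_or_only_for_logistic(self, stored_linear_fit, stored_logistic_fit):
        lin, design, y = stored_linear_fit
        assert "OR" not in summarize_fit(lin, design, y).table
        logi, design, y = stored_logistic_fit
        s = summarize_fit(logi, design, y)
        assert np.allclose(s.table["OR"], np.exp(s.table["mean"]))
        assert (s.table["OR"] > 0).all()

    def test_bayes_r2_in_unit_interval(self, stored_linear_fit):
        fit, design, y = stored_linear_fit
        s = summarize_fit(fit, design, y)
        assert 0.0 < s.r2 < 1.0


class TestRankStatistic:
    def _degenerate(self, betas: np.ndarray) -> PosteriorFit:
        S = 150
        p = len(betas)
        cols = [ColumnMeta(f"B{i:02d}AB{i:02d}", "medication", 5) for i in range(p)]
        return PosteriorFit(
            beta=np.tile(betas, (S, 1)), tau=np.ones(S), lam=np.ones((S, p)),
            sigma2=np.ones(S), kind="linear", columns=cols,
            config=HorseshoeConfig(n_iter=2, burn_in=0),
        )

    def test_strict_ordering_gives_exact_ranks(self):
        fit = self._degenerate(np.array([-0.5, 0.2]))
        assert list(rank_statistic(fit)) == [1.0, 2.0]

    def test_exchangeable_coefficients_tie(self):
        rng = np.random.default_rng(50)
        S, p = 4000, 4
        cols = [ColumnMeta(f"C{i:02d}CA{i:02d}", "medication", 5) for i in range(p)]
        fit = PosteriorFit(
            beta=rng.standard_normal((S, p)), tau=np.ones(S),
            lam=np.ones((S, p)), sigma2=np.ones(S), kind="linear",
            columns=cols, config=HorseshoeConfig(n_iter=2, burn_in=0),
        )
        stats = rank_statistic(fit)
        # mean rank of exchangeable draws is (p+1)/2 with SE ~ sd/sqrt(S)
        se = 3 * np.sqrt(p**2 / 12 / S)
        assert np.all(np.abs(stats - (p + 1) / 2) < 3 * se)

    def test_top_k_selects_smallest_mean_ranks(self):
        betas = np.linspace(1.2, 0.1, 12)  # strictly decreasing |beta|
        fit = self._degenerate(betas)
        names = [c.name for c in fit.columns]
        assert top_k(fit, 10) == names[:10]
        stats = rank_statistic(fit)
        assert sorted(stats[:10]) == sorted(
            stats[np.argsort(stats)][:10]
        )

    def test_tie_break_by_mean_abs_then_code(self):
        # two meds identical |beta| in every draw -> tied mean rank; the
        # lexicographically smaller code wins the last slot
        fit = self._degenerate(np.array([0.9, 0.5, -0.5]))
        assert top_k(fit, 2) == [fit.columns[0].name, fit.columns[1].name]


def test_fit_save_load_round_trip(tmp_path, stored_linear_fit):
    fit, design, y = stored_linear_fit
    path = tmp_path / "fit.parquet"
    fit.save(path)
    back = PosteriorFit.load(path)
    assert np.array_equal(back.beta, fit.beta)
    assert back.kind == fit.kind
    assert back.column_names() == fit.column_names()
    assert back.config.seed == fit.config.seed
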