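"""Discrete-time survival model: predictor, fitting, posterior checks."""

import math
import warnings

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit, logit

import fertsim
from fertsim import dtsm
from fertsim.config import DtsmCoefficients, LAMENESS_WINDOWS
from fertsim.dtsm import (
    FittedModel,
    build_design_matrix,
    fit_dtsm,
    hpd_retention,
    linear_predictor,
    posterior_predictive_check,
    predicted_relative_risk,
)


def _rp(dim_start=110, **kw):
    base = dict(
        dim_start=dim_start, parity_cat="1", year_cat="<=2002",
        season="Jan-Mar", yield_centred=0.0,
    )
    base.update(kw)
    return base


class TestLinearPredictor:
    def test_all_zero_gives_half(self):
        coefs = DtsmCoefficients()
        assert expit(linear_predictor(coefs, _rp())) == 0.5

    def test_default_coefficients_at_110_dim(self):
        coefs = fertsim.default_coefficients()
        eta = linear_predictor(coefs, _rp(110))
        # -40.1 + 15.4 ln(110) - 1.62 ln(110)^2
        assert eta == pytest.approx(-3.51, abs=0.01)
        assert expit(eta) == pytest.approx(0.029, abs=0.001)

    def test_lameness_flag_multiplies_odds_by_its_or(self):
        coefs = fertsim.default_coefficients()
        eta0 = linear_predictor(coefs, _rp())
        eta1 = linear_predictor(
            coefs, _rp(lame_flags={"lame_within_14": 1})
        )
        odds_ratio = np.exp(eta1) / np.exp(eta0)
        assert odds_ratio == pytest.approx(0.760, abs=1e-12)

    def test_frame_matches_term_by_term_oracle(self):
        rng = np.random.default_rng(5)
        coefs = fertsim.default_coefficients()
        n = 1000
        df = pd.DataFrame(
            {
                "dim_start": rng.integers(20, 220, n),
                "parity_cat": rng.choice(["1", "2", "3", "4", ">4"], n),
                "year_cat": rng.choice(
                    ["<=2002", "2003", "2004", "2005", "2006", "2007-8"], n
                ),
                "season": rng.choice(
                    ["Jan-Mar", "Apr-Jun", "Jul-Sep", "Oct-Dec"], n
                ),
                "yield_centred": rng.normal(0, 1.5, n),
            }
        )
        for w in LAMENESS_WINDOWS:
            df[w] = rng.integers(0, 2, n)
        vec = linear_predictor(coefs, df)
        for i in rng.choice(n, 200, replace=False):
            row = df.iloc[i]
            # naive sum of every term, written out independently
            ln = math.log(row.dim_start)
            expected = (
                coefs.alpha + coefs.beta_lndim * ln
                + coefs.beta_lndim_sq * ln**2
                + coefs.parity_coef(row.parity_cat)
                + coefs.year_coef(row.year_cat)
                + coefs.season_coef(row.season)
                + coefs.beta_yield * row.yield_centred
                + sum(coefs.beta_lameness[w] * row[w]
                      for w in LAMENESS_WINDOWS)
            )
            assert vec[i] == pytest.approx(expected, rel=1e-10)

    def test_higher_yield_strictly_decreases_probability(self):
        coefs = fertsim.default_coefficients()  # yield OR 0.917 < 1
        etas = [
            linear_predictor(coefs, _rp(yield_centred=yc))
            for yc in np.linspace(-3, 3, 13)
        ]
        assert all(b < a for a, b in zip(etas, etas[1:]))


class TestHpdRetention:
    @staticmethod
    def _fitted_with_draws(draws):
        draws = np.asarray(draws, float).reshape(-1, 1)
        k = 1
        return FittedModel(
            param_names=["term"], beta=draws.mean(0), cov_beta=np.eye(k),
            draws=draws, hpd=dtsm._hdi_bounds(draws) if draws.std() else
            np.array([[draws[0, 0], draws[0, 0]]]),
            sigma2_cow=0.0, sigma2_herd=0.0,
            sigma2_cow_interval=(0, 0), sigma2_herd_interval=(0, 0),
            u_hat=pd.Series(dtype=float), v_hat=pd.Series(dtype=float),
            windows=(), terms=(), converged=True,
        )

    def test_interval_excluding_zero_is_retained(self):
        rng = np.random.default_rng(0)
        # coefficient posterior matching an OR interval of ~(0.69, 0.84)
        draws = rng.normal(math.log(0.76), 0.025, 4000)
        assert hpd_retention(self._fitted_with_draws(draws), "term")

    def test_interval_covering_zero_not_retained(self):
        rng = np.random.default_rng(0)
        draws = rng.normal(0.05, 0.08, 4000)  # ~(-0.1, 0.2)
        assert not hpd_retention(self._fitted_with_draws(draws), "term")

    def test_degenerate_posterior_at_zero_not_retained(self):
        assert not hpd_retention(self._fitted_with_draws([0.0] * 100), "term")


class TestFit:
    def test_intercept_only_matches_logit_of_event_proportion(self):
        rng = np.random.default_rng(3)
        n = 40000
        p_true = 0.03
        df = pd.DataFrame(
            {
                "herd_id": rng.choice(["h1", "h2", "h3"], n),
                "cow_id": rng.choice([f"c{i}" for i in range(40)], n),
                "dim_start": 100,
                "outcome": rng.random(n) < p_true,
                "parity_cat": "1",
                "year_cat": "<=2002",
                "season": "Jan-Mar",
                "yield_centred": 0.0,
            }
        )
        df["outcome"] = df["outcome"].astype(int)
        for w in LAMENESS_WINDOWS:
            df[w] = 0
        fitted = fit_dtsm(
            df, terms=(), fix_variances=(1e-8, 1e-8), seed=0
        )
        expected = logit(df["outcome"].mean())
        assert fitted.coef("intercept") == pytest.approx(expected, abs=0.02)

    def test_preconditions_enforced(self, small_table):
        one_herd = small_table[small_table.herd_id == "h01"]
        with pytest.raises(ValueError):
            fit_dtsm(one_herd)
        no_events = small_table.assign(outcome=0)
        with pytest.raises(ValueError):
            fit_dtsm(no_events)

    def test_separation_warned(self, small_table):
        df = small_table.copy()
        # force one window level to have zero events
        df.loc[df["lame_43_70_after"] == 1, "outcome"] = 0
        clean = df.index[df["lame_43_70_after"] == 0][0]
        df.loc[clean, "outcome"] = 1  # keep both outcome classes present
        with pytest.warns(UserWarning, match="separation"):
            fit_dtsm(df, fix_variances=(0.01, 0.01), seed=0)

    def test_fit_is_reproducible_given_seed(self, small_table, fitted_small):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            again = fit_dtsm(small_table, seed=0)
        np.testing.assert_allclose(again.beta, fitted_small.beta)
        np.testing.assert_allclose(again.draws, fitted_small.draws)

    def test_estimates_near_generating_coefficients(self, fitted_small):
        truth = fertsim.default_truth()
        assert fitted_small.converged
        # strongly-identified terms on a small dataset
        assert fitted_small.coef("ln_dim_sq") == pytest.approx(
            truth.beta_lndim_sq, abs=0.5
        )
        lo, hi = fitted_small.hpd_interval("yield_centred")
        assert lo <= truth.beta_yield <= hi

    def test_null_lameness_interval_coverage(self):
        """With no true lameness effect, fitted OR intervals cover 1."""
        truth = fertsim.default_truth().replace(
            beta_lameness={w: 0.0 for w in LAMENESS_WINDOWS}
        )
        covered = total = 0
        for rep in range(5):
            ds = fertsim.generate_dataset(
                fertsim.GeneratorConfig(
                    n_herds=8, cows_per_herd=100,
                    true_coefficients=truth, seed=40 + rep,
                )
            )
            recs = _records_from(ds)
            table = fertsim.build_risk_period_table(recs)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fitted = fit_dtsm(table, seed=rep)
            for w in fitted.windows:
                lo, hi = fitted.hpd_interval(w)
                covered += lo <= 0.0 <= hi
                total += 1
        assert covered >= 0.9 * total

    def test_mcmc_backend_agrees_with_laplace(self, small_table,
                                              fitted_small):
        sub = small_table[small_table.herd_id.isin(["h01", "h02", "h03"])]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            lap = fit_dtsm(sub, terms=("dim", "lameness"), seed=0)
            mc = fit_dtsm(
                sub, terms=("dim", "lameness"), backend="mcmc",
                seed=0, mcmc_steps=150, mcmc_walkers=24,
            )
        for term in ("ln_dim_sq", "lame_within_14"):
            se = np.sqrt(lap.cov_beta[lap.param_names.index(term),
                                      lap.param_names.index(term)])
            assert abs(mc.coef(term) - lap.coef(term)) < 4 * se


def _records_from(ds):
    import io

    lac = io.StringIO()
    ds.lactations.to_csv(lac, index=False)
    lac.seek(0)
    lam = io.StringIO()
    ds.lameness_events.to_csv(lam, index=False)
    lam.seek(0)
    return fertsim.read_lactation_tables(lac, lam)


class TestPosteriorPredictiveCheck:
    def test_certain_event_gives_proportion_one(self):
        draws = np.full((50, 1), 50.0)  # intercept -> mu = 1
        fitted = FittedModel(
            param_names=["intercept"], beta=draws.mean(0),
            cov_beta=np.eye(1), draws=draws,
            hpd=np.array([[50.0, 50.0]]), sigma2_cow=0, sigma2_herd=0,
            sigma2_cow_interval=(0, 0), sigma2_herd_interval=(0, 0),
            u_hat=pd.Series(dtype=float), v_hat=pd.Series(dtype=float),
            windows=(), terms=(), converged=True,
        )
        df = pd.DataFrame(
            [{"herd_id": "h1", "cow_id": "c1", "outcome": 1}]
        )
        res = posterior_predictive_check(fitted, df, seed=0)
        assert res.predicted_mean == 1.0
        assert res.interval == (1.0, 1.0)

    def test_empty_subset_rejected(self, fitted_small, small_table):
        with pytest.raises(ValueError):
            posterior_predictive_check(
                fitted_small, small_table, subset=small_table.dim_start > 999
            )

    def test_observed_within_interval_for_self_generated_data(
        self, fitted_small, small_table
    ):
        res = posterior_predictive_check(fitted_small, small_table, seed=1)
        assert res.observed_in_interval
        by_parity = posterior_predictive_check(
            fitted_small, small_table,
            subset=lambda d: d.parity_cat == "1", seed=1,
        )
        assert by_parity.observed_in_interval

    def test_interval_narrows_with_subset_size(self, fitted_small,
                                               small_table):
        small = posterior_predictive_check(
            fitted_small, small_table.iloc[:100], seed=0, n_draws=200
        )
        large = posterior_predictive_check(
            fitted_small, small_table.iloc[:10000], seed=0, n_draws=200
        )
        assert (large.interval[1] - large.interval[0]) < (
            small.interval[1] - small.interval[0]
        )


def _two_param_fitted(intercept, coef, window="lame_within_14", n_draws=20):
    draws = np.tile([intercept, coef], (n_draws, 1))
    return FittedModel(
        param_names=["intercept", window], beta=draws.mean(0),
        cov_beta=np.eye(2), draws=draws,
        hpd=np.array([[intercept, intercept], [coef, coef]]),
        sigma2_cow=0, sigma2_herd=0,
        sigma2_cow_interval=(0, 0), sigma2_herd_interval=(0, 0),
        u_hat=pd.Series(dtype=float), v_hat=pd.Series(dtype=float),
        windows=(window,), terms=("lameness",), converged=True,
    )


def _rr_frame(n=50):
    df = pd.DataFrame(
        {
            "herd_id": "h1",
            "cow_id": [f"c{i}" for i in range(n)],
            "outcome": 0,
        }
    )
    for w in LAMENESS_WINDOWS:
        df[w] = 0
    return df


class TestPredictedRelativeRisk:
    def test_zero_coefficient_gives_rr_one(self):
        fitted = _two_param_fitted(logit(0.3), 0.0)
        res = predicted_relative_risk(fitted, "lame_within_14", _rr_frame())
        assert np.allclose(res.draws, 1.0)

    def test_rare_event_rr_approaches_or(self):
        fitted = _two_param_fitted(logit(0.01), math.log(0.76))
        res = predicted_relative_risk(fitted, "lame_within_14", _rr_frame())
        assert abs(res.median - 0.76) < 0.005

    def test_rr_between_or_and_one_for_common_events(self):
        for p in (0.1, 0.3, 0.45):
            fitted = _two_param_fitted(logit(p), math.log(0.76))
            res = predicted_relative_risk(
                fitted, "lame_within_14", _rr_frame()
            )
            assert 0.76 < res.median < 1.0

    def test_unknown_window_rejected(self, fitted_small, small_table):
        with pytest.raises(ValueError):
            predicted_relative_risk(fitted_small, "nonexistent", small_table)
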