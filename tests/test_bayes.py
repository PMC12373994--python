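"""Design construction, HPD intervals and robust-regression behaviour."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from cb1pet.bayes import (
    MCMCSettings,
    RegressionModelSpec,
    build_design,
    fit_model,
    hpd_interval,
    run_model_suite,
)
from cb1pet.exceptions import InsufficientDataError, ValidationError
from cb1pet.sampler import sample_posterior
from cb1pet.synthetic import CohortConfig, generate_cohort

FAST = MCMCSettings(draws=400, tune=400, chains=2, seed=0)


@pytest.fixture(scope="module")
def cohort():
    return generate_cohort(CohortConfig(seed=21))


class TestBuildDesign:
    def test_group_recipe_has_eight_columns(self, cohort):
        d = build_design(cohort, RegressionModelSpec("whole_brain", "group"))
        assert d.columns == [
            "Intercept", "TC", "PTSD", "Sex", "Age_z", "BMI_z", "Sex*TC", "Sex*PTSD",
        ]
        assert d.X.shape == (62, 8)
        # HC males are the reference: all categorical columns zero
        hc_male = (cohort["group"] == "HC") & (cohort["sex"] == "male")
        cat = [d.columns.index(c) for c in ("TC", "PTSD", "Sex", "Sex*TC", "Sex*PTSD")]
        assert np.allclose(d.X[np.ix_(hc_male.to_numpy(), cat)], 0.0)

    def test_zscore_normalization_identity(self, cohort):
        d = build_design(cohort, RegressionModelSpec("whole_brain", "confounds"))
        age = d.X[:, d.columns.index("Age_z")]
        assert abs(age.mean()) < 1e-12
        assert abs(age.std() - 1.0) < 1e-12

    def test_symptom_recipe_restricts_to_caps_subset(self, cohort):
        d = build_design(
            cohort, RegressionModelSpec("whole_brain", "symptom", cluster="cl_anhedonia")
        )
        assert d.X.shape == (44, 5)
        assert d.columns[-1] == "cl_anhedonia"

    def test_degenerate_designs_rejected(self):
        homogeneous = generate_cohort(
            CohortConfig(n_ptsd=0, n_tc=0, n_hc=20,
                         male_prob_by_group={"PTSD": 0.5, "TC": 0.5, "HC": 1.0},
                         seed=1)
        )
        with pytest.raises(ValidationError):
            build_design(homogeneous, RegressionModelSpec("whole_brain", "group"))
        with pytest.raises(ValidationError):
            build_design(homogeneous, RegressionModelSpec("whole_brain", "confounds"))


class TestHPDInterval:
    def test_uniform_grid_width(self):
        lo, hi = hpd_interval(np.arange(1, 101), mass=0.89)
        assert hi - lo == 88

    def test_normal_sample_matches_quantile_oracle(self):
        x = np.random.default_rng(123).normal(size=100_000)
        lo, hi = hpd_interval(x, mass=0.89)
        # for a symmetric density the HPD equals the central interval
        assert lo == pytest.approx(-1.598, abs=0.05)
        assert hi == pytest.approx(1.598, abs=0.05)

    def test_point_mass(self):
        lo, hi = hpd_interval(np.full(200, 3.3))
        assert (lo, hi) == (3.3, 3.3)
        assert not (lo <= 0.0 <= hi)

    def test_too_few_samples(self):
        with pytest.raises(InsufficientDataError):
            hpd_interval(np.arange(50))

    @given(
        data=st.lists(st.floats(-50, 50), min_size=100, max_size=220),
        mass=st.sampled_from([0.5, 0.89, 0.95]),
    )
    def test_minimal_width_against_window_scan(self, data, mass):
        """HPD is the narrowest contiguous window holding the required mass."""
        x = np.asarray(data)
        lo, hi = hpd_interval(x, mass=mass)
        s = np.sort(x)
        m = int(np.ceil(mass * s.size))
        assert np.sum((s >= lo) & (s <= hi)) >= m
        brute = min(s[i + m - 1] - s[i] for i in range(s.size - m + 1))
        assert (hi - lo) == pytest.approx(brute, abs=1e-9)


def _simple_design(n=60, slope=0.5, noise=0.3, seed=0, contaminate=False):
    rng = np.random.default_rng(seed)
    x = rng.normal(size=n)
    y = 1.0 + slope * x + rng.normal(0.0, noise, n)
    if contaminate:
        # high-leverage outliers dragging the OLS slope down
        idx = np.argsort(x)[-max(2, n // 20):]
        y[idx] -= 3.0
    X = np.column_stack([np.ones(n), x])
    return X, y


class TestFitModel:
    def test_robust_flag_matches_interval(self, cohort):
        spec = RegressionModelSpec("whole_brain", "confounds", mcmc=FAST)
        s = fit_model(build_design(cohort, spec), spec)
        for _, row in s.coefficients.iterrows():
            assert row["robust"] == (not row["hpd_low"] <= 0.0 <= row["hpd_high"])

    def test_location_shift_equivariance(self, cohort):
        spec = RegressionModelSpec("whole_brain", "confounds", mcmc=FAST)
        d = build_design(cohort, spec)
        s0 = fit_model(d, spec)
        d_shift = type(d)(X=d.X, y=d.y + 1.0, columns=d.columns,
                          subject_ids=d.subject_ids)
        s1 = fit_model(d_shift, spec)
        delta = s1.coefficients.loc["Intercept", "mean"] - s0.coefficients.loc[
            "Intercept", "mean"]
        sd = s0.coefficients.loc["Intercept", "sd"]
        assert abs(delta - 1.0) <= 3 * sd
        # slopes unchanged within Monte-Carlo error
        for c in ("Sex", "Age_z", "BMI_z"):
            assert abs(
                s1.coefficients.loc[c, "mean"] - s0.coefficients.loc[c, "mean"]
            ) <= 3 * s0.coefficients.loc[c, "sd"]

    def test_undersampled_run_flagged_nonconverged(self, cohort):
        """With only 600 total draws the ESS > 1000 gate cannot be met."""
        spec = RegressionModelSpec(
            "whole_brain", "confounds",
            mcmc=MCMCSettings(draws=300, tune=300, chains=2, seed=0),
        )
        s = fit_model(build_design(cohort, spec), spec)
        assert not s.converged
        assert any("sample size" in w or "Rhat" in w for w in s.warnings)

    def test_posterior_matches_emcee_oracle(self):
        """Independent route: the same posterior sampled with the emcee
        ensemble sampler gives the same slope mean and SD."""
        emcee = pytest.importorskip("emcee")
        from scipy.stats import expon, invgamma, norm, t as student_t

        X, y = _simple_design(n=50, seed=3)

        def logpost(theta):
            beta, u, w = theta[:2], theta[2], theta[3]
            if abs(u) > 20 or abs(w) > 20:
                return -np.inf
            nu, eps = np.exp(u), np.exp(w)
            ll = student_t.logpdf(y, df=nu, loc=X @ beta, scale=eps).sum()
            lp = (
                norm.logpdf(beta).sum()
                + invgamma.logpdf(nu, 3, scale=1) + u
                + expon.logpdf(eps) + w
            )
            return ll + lp

        ndim, nwalkers = 4, 24
        rng = np.random.default_rng(7)
        p0 = np.array([1.0, 0.5, np.log(4.0), np.log(0.3)]) + 0.05 * rng.normal(
            size=(nwalkers, ndim)
        )
        sampler = emcee.EnsembleSampler(nwalkers, ndim, logpost)
        np.random.seed(7)
        sampler.run_mcmc(p0, 1500)
        chain = sampler.get_chain(discard=500, flat=True)

        res = sample_posterior(X, y, draws=1000, tune=1000, chains=2, seed=5)
        slope_hmc = res.beta[:, :, 1].ravel()
        assert slope_hmc.mean() == pytest.approx(chain[:, 1].mean(), abs=0.02)
        assert slope_hmc.std() == pytest.approx(chain[:, 1].std(), rel=0.25)

    def test_student_t_resists_leverage_outliers(self):
        """Paired over seeds: the robust slope has smaller absolute error
        than OLS when 5% high-leverage outliers contaminate the data."""
        err_robust, err_ols = [], []
        for seed in range(50):
            X, y = _simple_design(n=60, seed=seed, contaminate=True)
            beta_ols = np.linalg.lstsq(X, y, rcond=None)[0]
            res = sample_posterior(X, y, draws=300, tune=300, chains=1, seed=seed)
            err_robust.append(res.beta[:, :, 1].mean() - 0.5)
            err_ols.append(beta_ols[1] - 0.5)
        assert abs(np.mean(err_robust)) < abs(np.mean(err_ols))
        assert np.mean(np.abs(err_robust)) < np.mean(np.abs(err_ols))


class TestModelSuite:
    def test_null_suite_flags_few_robust(self):
        cohort = generate_cohort(CohortConfig(effect_sizes={}, seed=77))
        suite = run_model_suite(
            cohort,
            regions=("whole_brain",),
            mcmc=MCMCSettings(draws=300, tune=300, chains=1, seed=13),
            families=("confounds", "symptoms"),
        )
        rows = pd.concat([suite.confounds, suite.symptoms], ignore_index=True)
        assert not rows["failed"].any()
        # under the null ~11% of 89%-HPD intervals exclude zero
        assert rows["robust"].mean() <= 0.35

    def test_missing_group_skipped_gracefully(self):
        cohort = generate_cohort(CohortConfig(n_hc=0, seed=5))
        suite = run_model_suite(
            cohort,
            regions=("whole_brain",),
            mcmc=MCMCSettings(draws=200, tune=200, chains=1, seed=2),
            families=("confounds", "group"),
        )
        assert suite.group["failed"].all()
        assert not suite.confounds["failed"].any()
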