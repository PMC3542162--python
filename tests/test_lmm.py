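"""Gaussian linear mixed model: reductions, oracles, likelihood identities."""

import math

import numpy as np
import pandas as pd
import pytest

from remr import (
    CohortConfig,
    LongitudinalDataset,
    ModelSpec,
    VarianceComponents,
    fit_lmm,
    generate_cohort,
    information_criteria,
    marginal_loglik_gaussian,
)
from remr.models import FitResult, _GaussianProfile, _Prepared


def test_perfect_linear_fit_recovers_slope_and_flags_boundary(two_subject_perfect):
    spec = ModelSpec(family="gaussian", fixed_terms=["time"], estimation="REML")
    fit = fit_lmm(two_subject_perfect, spec)
    assert fit.beta["time"] == pytest.approx(1.0, abs=1e-8)
    assert fit.variance_components.sigma2_e == 0.0
    assert fit.variance_components.boundary


def test_zero_random_effect_variance_reduces_to_ols(gaussian_cohort_200, gaussian_spec):
    data, _ = gaussian_cohort_200
    fit = fit_lmm(data, gaussian_spec, gamma_fixed=0.0)
    prep = _Prepared(data, gaussian_spec)
    ols, *_ = np.linalg.lstsq(prep.X, prep.y, rcond=None)
    np.testing.assert_allclose(fit.beta.to_numpy(), ols, atol=1e-8)


def test_reml_matches_reference_mixed_model_implementation(
    gaussian_cohort_200, gaussian_spec
):
    """Random-intercept REML vs an independent established implementation."""
    sm = pytest.importorskip("statsmodels.api")
    data, _ = gaussian_cohort_200
    fit = fit_lmm(data, gaussian_spec)
    prep = _Prepared(data, gaussian_spec)
    ref = sm.MixedLM(
        prep.y, prep.X, groups=data.df["subject_id"].to_numpy()
    ).fit(reml=True)
    np.testing.assert_allclose(fit.beta.to_numpy(), ref.fe_params, rtol=1e-3)
    assert fit.variance_components.G[0, 0] == pytest.approx(
        float(np.asarray(ref.cov_re)[0, 0]), rel=1e-3
    )
    assert fit.variance_components.sigma2_e == pytest.approx(ref.scale, rel=1e-3)


def test_reml_optimum_confirmed_by_coarse_grid(gaussian_cohort_200, gaussian_spec):
    """The fitted variance ratio beats every point of a coarse grid search."""
    data, _ = gaussian_cohort_200
    prep = _Prepared(data, gaussian_spec)
    prof = _GaussianProfile(prep, reml=True)
    fit = fit_lmm(data, gaussian_spec)
    gamma_hat = fit.variance_components.G[0, 0] / fit.variance_components.sigma2_e
    best = prof.objective_q1(math.log(gamma_hat))
    grid = np.arange(-4.0, 4.0, 0.05)
    assert best <= prof.objective_q1(grid[np.argmin([prof.objective_q1(g) for g in grid])]) + 1e-9


def test_random_slope_matches_reference_implementation():
    sm = pytest.importorskip("statsmodels.api")
    rng = np.random.default_rng(3)
    n, v = 200, 5
    rows = []
    b0, b1 = rng.normal(0, 1.0, n), rng.normal(0, 0.3, n)
    x = rng.normal(0, 1, n)
    for i in range(n):
        for t in range(v):
            rows.append(
                {
                    "subject_id": i,
                    "cluster_id": 0,
                    "time": float(t),
                    "outcome": 1.0 + 0.5 * t + 0.8 * x[i] + b0[i] + b1[i] * t
                    + rng.normal(0, 0.6),
                    "x": x[i],
                }
            )
    data = LongitudinalDataset(pd.DataFrame(rows))
    spec = ModelSpec(
        family="gaussian", fixed_terms=["time", "x"],
        random_structure="intercept+slope", estimation="REML",
    )
    fit = fit_lmm(data, spec)
    prep = _Prepared(data, spec)
    t_col = data.df["time"].to_numpy()
    ref = sm.MixedLM(
        prep.y, prep.X, groups=data.df["subject_id"].to_numpy(),
        exog_re=np.column_stack([np.ones(len(t_col)), t_col]),
    ).fit(reml=True)
    np.testing.assert_allclose(fit.beta.to_numpy(), ref.fe_params, rtol=1e-3)
    np.testing.assert_allclose(
        fit.variance_components.G, np.asarray(ref.cov_re), rtol=1e-3, atol=1e-4
    )
    assert fit.variance_components.sigma2_e == pytest.approx(ref.scale, rel=1e-3)


def test_marginal_loglik_matches_dense_matrix_evaluation(
    gaussian_cohort_200, gaussian_spec
):
    """The fitter's Woodbury-form likelihood equals the literal quadratic form."""
    data, _ = gaussian_cohort_200
    prep = _Prepared(data, gaussian_spec)
    rng = np.random.default_rng(0)
    for _ in range(3):
        beta = rng.normal(0, 1, prep.p)
        vc = VarianceComponents(
            G=[[float(rng.uniform(0.2, 2.0))]],
            sigma2_e=float(rng.uniform(0.2, 2.0)),
        )
        fast = marginal_loglik_gaussian(data, gaussian_spec, beta, vc)
        # independent dense evaluation
        total = 0.0
        r = prep.y - prep.X @ beta
        for s, c in zip(prep.starts, prep.counts):
            Sig = vc.G[0, 0] * np.ones((c, c)) + vc.sigma2_e * np.eye(c)
            ri = r[s : s + c]
            total += -0.5 * (
                c * math.log(2 * math.pi)
                + np.linalg.slogdet(Sig)[1]
                + ri @ np.linalg.solve(Sig, ri)
            )
        assert fast == pytest.approx(total, rel=1e-10)


def test_ml_and_reml_beta_coincide_at_fixed_variance_ratio(gaussian_cohort_200):
    data, _ = gaussian_cohort_200
    terms = ["time", "race", "male"]
    ml = fit_lmm(
        data, ModelSpec(family="gaussian", fixed_terms=terms, estimation="ML"),
        gamma_fixed=0.7,
    )
    reml = fit_lmm(
        data, ModelSpec(family="gaussian", fixed_terms=terms, estimation="REML"),
        gamma_fixed=0.7,
    )
    np.testing.assert_allclose(ml.beta.to_numpy(), reml.beta.to_numpy(), rtol=1e-12)


def test_rank_deficient_design_error_names_terms(gaussian_cohort_200):
    data, _ = gaussian_cohort_200
    df = data.df.copy()
    df["time2"] = 2.0 * df["time"]
    bad = LongitudinalDataset(df)
    spec = ModelSpec(family="gaussian", fixed_terms=["time", "time2"])
    with pytest.raises(ValueError, match="time2"):
        fit_lmm(bad, spec)


class TestInformationCriteria:
    def _dummy(self, loglik, k, m):
        return FitResult(
            beta=pd.Series(dtype=float),
            beta_cov=pd.DataFrame(),
            variance_components=VarianceComponents(G=[[1.0]], sigma2_e=1.0),
            loglik=loglik, aic=np.nan, bic=np.nan,
            n_subjects=m, n_obs=m, converged=True, n_iterations=1,
            method="ML", k_params=k,
        )

    def test_arithmetic(self):
        aic, bic = information_criteria(self._dummy(-100.0, 3, 50))
        assert aic == pytest.approx(206.0)
        assert bic == pytest.approx(200 + 3 * math.log(50), abs=1e-9)
        assert bic == pytest.approx(211.736, abs=5e-4)

    def test_nested_ml_loglik_monotone_and_aic_prefers_true_model(self):
        """A true time effect: the larger ML model never has smaller loglik,
        and AIC prefers it in nearly every replicate."""
        small = ModelSpec(family="gaussian", fixed_terms=[], estimation="ML")
        big = ModelSpec(family="gaussian", fixed_terms=["time"], estimation="ML")
        prefer = 0
        reps = 40
        for r in range(reps):
            data, _ = generate_cohort(
                CohortConfig(n_subjects=400, n_clusters=5, seed=2000 + r)
            )
            f0, f1 = fit_lmm(data, small), fit_lmm(data, big)
            assert f1.loglik >= f0.loglik - 1e-8
            prefer += f1.aic < f0.aic
        assert prefer >= 0.95 * reps
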