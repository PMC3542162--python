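"""Meta-regression pooling: closed-form oracles, independent implementations,
homogeneity diagnostics and outlier screening."""

import math
import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest

from remr import (
    ClusterEstimate,
    CohortConfig,
    DEFAULT_TERMS,
    ModelSpec,
    fit_by_cluster,
    generate_cohort,
    homogeneity_test,
    inject_outliers,
    pool_femr,
    pool_remr,
    pooled_information_criteria,
    screen_outliers,
)
from conftest import make_estimates


class TestFixedEffects:
    def test_equal_precision_pooled_mean(self):
        pooled = pool_femr(make_estimates([0.40, 0.46, 0.52], 0.02))
        assert pooled.tau == pytest.approx(0.46)
        assert pooled.se_tau == pytest.approx(0.02 / math.sqrt(3), abs=1e-9)
        assert pooled.sigma2_v == 0.0

    def test_inverse_variance_weighting_by_hand(self):
        pooled = pool_femr(make_estimates([1.0, 2.0], [1.0, 2.0]))
        assert pooled.tau == pytest.approx((1.0 + 0.25 * 2.0) / 1.25)  # 1.2

    def test_single_estimate_passes_through_with_warning(self):
        with pytest.warns(RuntimeWarning, match="pass-through"):
            pooled = pool_femr(make_estimates([0.3], [0.1]))
        assert (pooled.tau, pooled.se_tau) == (0.3, 0.1)

    def test_singular_meta_design_rejected(self):
        ests = make_estimates([0.1, 0.2, 0.3, 0.4], 0.05)
        for e in ests:
            e.z = np.array([1.0])  # z column identical to the intercept
        with pytest.raises(ValueError, match="singular"):
            pool_femr(ests)

    def test_covariate_adjusted_wls_matches_hand_solution(self):
        rng = np.random.default_rng(4)
        z = np.linspace(-1, 1, 12)
        sig = rng.uniform(0.03, 0.10, 12)
        phi = 0.3 + 0.8 * z + rng.normal(0, sig)
        ests = make_estimates(phi, sig)
        for e, zi in zip(ests, z):
            e.z = np.array([zi])
        pooled = pool_femr(ests)
        w = 1.0 / sig**2
        D = np.column_stack([np.ones(12), z])
        coef = np.linalg.solve((D * w[:, None]).T @ D, (D * w[:, None]).T @ phi)
        assert pooled.tau == pytest.approx(coef[0], abs=1e-12)
        assert pooled.gamma[0] == pytest.approx(coef[1], abs=1e-12)


class TestDerSimonianLaird:
    def test_worked_example_closed_form(self):
        pooled = pool_remr(make_estimates([0.40, 0.46, 0.52], 0.02), method="DL")
        hom = pooled.homogeneity
        assert hom.Q == pytest.approx(18.0, abs=1e-10)
        assert hom.df == 2
        assert hom.p_value == pytest.approx(math.exp(-9.0), rel=1e-10)
        assert hom.I2 == pytest.approx(8.0 / 9.0, abs=1e-12)
        assert pooled.sigma2_v == pytest.approx(0.0032, abs=1e-12)
        assert pooled.tau == pytest.approx(0.46, abs=1e-12)
        assert pooled.se_tau == pytest.approx(math.sqrt(0.0036 / 3), abs=1e-9)

    def test_matches_established_meta_analysis_implementation(self):
        combine_effects = pytest.importorskip(
            "statsmodels.stats.meta_analysis"
        ).combine_effects
        rng = np.random.default_rng(11)
        for _ in range(50):
            k = int(rng.integers(3, 15))
            phi = rng.normal(0, 1, k)
            sig = rng.uniform(0.05, 0.5, k)
            pooled = pool_remr(make_estimates(phi, sig), method="DL")
            ref = combine_effects(phi, sig**2, method_re="dl")
            # the reference implementation reports the untruncated moment
            # estimate; the one-step estimator truncates at zero
            assert pooled.sigma2_v == pytest.approx(
                max(0.0, float(ref.tau2)), abs=1e-8
            )
            if ref.tau2 < 0:
                continue
            assert pooled.tau == pytest.approx(float(ref.mean_effect_re), abs=1e-8)
            assert pooled.se_tau == pytest.approx(
                float(ref.sd_eff_w_re), abs=1e-8
            )
            assert pooled.homogeneity.Q == pytest.approx(float(ref.q), abs=1e-8)

    def test_identical_estimates_degenerate_to_fixed_effects(self):
        ests = make_estimates([0.3, 0.3, 0.3, 0.3], [0.1, 0.2, 0.1, 0.3])
        re, fe = pool_remr(ests, method="DL"), pool_femr(ests)
        assert re.homogeneity.Q == pytest.approx(0.0, abs=1e-20)
        assert re.sigma2_v == 0.0
        assert (re.tau, re.se_tau) == (fe.tau, fe.se_tau)

    def test_q_below_df_truncates_to_fixed_effects(self):
        # estimates far tighter than their claimed standard errors
        ests = make_estimates([0.459, 0.461, 0.460, 0.4605], 0.1)
        re = pool_remr(ests, method="DL")
        assert re.homogeneity.Q < re.homogeneity.df
        assert re.sigma2_v == 0.0
        assert re.tau == pytest.approx(pool_femr(ests).tau, abs=1e-14)

    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError, match="unknown REMR method"):
            pool_remr(make_estimates([0.1, 0.2], 0.1), method="PM")


class TestRemlMetaRegression:
    def test_matches_metafor_reference(self):
        """Restricted-likelihood between-cluster variance vs R's metafor."""
        if shutil.which("Rscript") is None:
            pytest.skip("Rscript not available")
        phi = [0.20, 0.50, 0.35, 0.60, 0.40, 0.45, 0.30, 0.55]
        v = [0.0040, 0.0090, 0.0025, 0.0160, 0.0049, 0.0064, 0.0036, 0.0100]
        script = (
            "suppressMessages(library(metafor));"
            f"r <- rma(yi=c({','.join(map(str, phi))}),"
            f" vi=c({','.join(map(str, v))}), method='REML',"
            " control=list(threshold=1e-10));"
            "cat(sprintf('%.12f %.12f %.12f', r$tau2, r$beta[1], r$se[1]))"
        )
        out = subprocess.run(
            ["Rscript", "-e", script], capture_output=True, text=True, check=True
        )
        tau2_ref, b_ref, se_ref = map(float, out.stdout.split())
        pooled = pool_remr(
            make_estimates(phi, np.sqrt(v)), method="REML"
        )
        assert pooled.sigma2_v == pytest.approx(tau2_ref, abs=1e-8)
        assert pooled.tau == pytest.approx(b_ref, abs=1e-8)
        assert pooled.se_tau == pytest.approx(se_ref, abs=1e-8)

    def test_homogeneous_estimates_hit_zero_boundary(self):
        ests = make_estimates([0.459, 0.461, 0.460, 0.4605], 0.1)
        assert pool_remr(ests, method="REML").sigma2_v == 0.0


class TestHomogeneity:
    def test_identical_estimates(self):
        hom = homogeneity_test(make_estimates([0.2] * 5, 0.05))
        assert (hom.Q, hom.I2, hom.p_value) == (0.0, 0.0, 1.0)

    def test_requires_two_clusters(self):
        with pytest.raises(ValueError):
            homogeneity_test(make_estimates([0.2], [0.1]))

    def test_null_rejection_rate_calibrated(self):
        """Under homogeneity the Q test rejects at close to its nominal 5%."""
        rng = np.random.default_rng(42)
        sig = np.linspace(0.03, 0.08, 20)
        rej = sum(
            homogeneity_test(make_estimates(rng.normal(0.46, sig), sig)).p_value
            < 0.05
            for _ in range(600)
        )
        assert 0.03 <= rej / 600 <= 0.08


class TestOutlierScreen:
    def test_infinite_threshold_keeps_everything(self):
        ests = make_estimates([0.1, 0.9, 0.5, 0.4, 0.45], 0.05)
        kept, excluded, report = screen_outliers(ests, threshold=math.inf)
        assert excluded == [] and len(kept) == 5 and report.empty

    def test_requires_three_clusters(self):
        with pytest.raises(ValueError):
            screen_outliers(make_estimates([0.1, 0.2], 0.05))

    def test_never_reduces_below_three(self):
        # four wildly dispersed estimates: at most one can be removed
        ests = make_estimates([0.0, 5.0, -5.0, 10.0], 0.01)
        with pytest.warns(RuntimeWarning, match="floor"):
            kept, excluded, _ = screen_outliers(ests, threshold=0.5)
        assert len(kept) == 3 and len(excluded) == 1

    def test_opposite_pair_detected_in_realistic_panel(self):
        """Two opposite +-6 SD clusters among 21 homogeneous ones are the
        exact excluded set in the large majority of draws."""
        rng = np.random.default_rng(7)
        hits = 0
        for _ in range(50)        :
            phi = rng.normal(0.46, 0.05, 23)
            phi[-2] += 0.30
            phi[-1] -= 0.30
            ests = make_estimates(phi, 0.05, ids=[f"c{i:02d}" for i in range(23)])
            _, excluded, _ = screen_outliers(ests, 3.0)
            hits += sorted(e.cluster_id for e in excluded) == ["c21", "c22"]
        assert hits >= 45

    def test_homogeneous_panel_rarely_flags(self):
        rng = np.random.default_rng(8)
        clean = 0
        for _ in range(50):
            phi = rng.normal(0.0, 0.05, 12)
            _, excluded, _ = screen_outliers(make_estimates(phi, 0.05), 3.0)
            clean += not excluded
        assert clean >= 45


class TestFitByCluster:
    SPEC = ModelSpec(
        family="gaussian", fixed_terms=list(DEFAULT_TERMS), estimation="REML"
    )

    def test_cluster_estimates_cover_truth(self):
        """Per-cluster fits land within 3 SE of the realized cluster truth."""
        within = total = 0
        for r in range(10):
            data, truth = generate_cohort(
                CohortConfig(n_subjects=1500, n_clusters=10, seed=4000 + r)
            )
            fs = fit_by_cluster(data, self.SPEC, coefficient_names=["race[NHB]"])
            for e in fs.estimates["race[NHB]"]:
                true_val = truth.per_cluster.loc[e.cluster_id, "race[NHB]"]
                within += abs(e.phi - true_val) <= 3 * e.sigma
                total += 1
        assert within / total >= 0.97

    def test_missing_category_excludes_coefficient_not_cluster(self):
        data, _ = generate_cohort(
            CohortConfig(n_subjects=600, n_clusters=4, seed=9)
        )
        df = data.df.copy()
        df.loc[df.cluster_id == 0, "race"] = "NHW"  # no minority subjects
        from remr import LongitudinalDataset

        fs = fit_by_cluster(
            LongitudinalDataset(df), self.SPEC,
            coefficient_names=["Intercept", "race[NHB]"],
        )
        nhb_ids = {e.cluster_id for e in fs.estimates["race[NHB]"]}
        int_ids = {e.cluster_id for e in fs.estimates["Intercept"]}
        assert 0 not in nhb_ids and 0 in int_ids
        assert (
            (fs.exclusions.cluster_id == 0)
            & (fs.exclusions.coefficient == "race[NHB]")
        ).any()

    def test_row_order_does_not_change_results(self):
        data, _ = generate_cohort(
            CohortConfig(n_subjects=400, n_clusters=5, seed=12)
        )
        from remr import LongitudinalDataset
        from remr.meta import estimates_to_frame

        shuffled = LongitudinalDataset(
            data.df.sample(frac=1.0, random_state=3).reset_index(drop=True)
        )
        a = estimates_to_frame(fit_by_cluster(data, self.SPEC).estimates)
        b = estimates_to_frame(fit_by_cluster(shuffled, self.SPEC).estimates)
        assert a.to_csv(index=False) == b.to_csv(index=False)

    def test_requires_two_clusters(self):
        data, _ = generate_cohort(
            CohortConfig(n_subjects=50, n_clusters=1, seed=1)
        )
        with pytest.raises(ValueError, match="2 clusters"):
            fit_by_cluster(data, self.SPEC)


class TestPooledIC:
    def _fits(self):
        data, _ = generate_cohort(
            CohortConfig(n_subjects=400, n_clusters=3, seed=22)
        )
        spec = ModelSpec(
            family="gaussian", fixed_terms=["time", "race"], estimation="ML"
        )
        return list(fit_by_cluster(data, spec).fits.values())

    def test_single_cluster_is_identity(self):
        fits = self._fits()[:1]
        ic = pooled_information_criteria(fits)
        assert ic.aic_sum == fits[0].aic
        assert ic.aic_weighted_mean == fits[0].aic
        assert not ic.comparable_with_full_data

    def test_sum_and_weighted_mean_arithmetic(self):
        fits = self._fits()[:2]
        fits[0].aic, fits[1].aic = 100.0, 200.0
        fits[0].n_subjects, fits[1].n_subjects = 10, 30
        ic = pooled_information_criteria(fits)
        assert ic.aic_sum == 300.0
        assert ic.aic_weighted_mean == pytest.approx(175.0)

    def test_mixed_specs_rejected(self):
        fits = self._fits()
        other = ModelSpec(family="gaussian", fixed_terms=["time"], estimation="ML")
        fits[0].spec = other
        with pytest.raises(ValueError, match="common model spec"):
            pooled_information_criteria(fits)

    def test_pooled_ic_orders_models_like_full_data(self):
        """Intercept-only vs intercept+time: summed per-cluster criteria agree
        with the full-data ranking in nearly every replicate."""
        agree = 0
        reps = 20
        from remr import fit_lmm

        for r in range(reps):
            data, _ = generate_cohort(
                CohortConfig(n_subjects=500, n_clusters=5, seed=6000 + r)
            )
            order = []
            for terms in ([], ["time"]):
                spec = ModelSpec(
                    family="gaussian", fixed_terms=terms, estimation="ML"
                )
                full = fit_lmm(data, spec)
                pooled = pooled_information_criteria(
                    list(fit_by_cluster(data, spec).fits.values())
                )
                order.append((full.aic, pooled.aic_sum))
            full_prefers_time = order[1][0] < order[0][0]
            pooled_prefers_time = order[1][1] < order[0][1]
            agree += full_prefers_time == pooled_prefers_time
        assert agree >= 0.95 * reps


def test_end_to_end_injected_pair_is_screened_and_pooling_recovers():
    """Opposite-direction injected clusters inflate the between-cluster
    variance; screening removes exactly the injected pair and restores the
    homogeneous pooled estimate."""
    spec = ModelSpec(
        family="gaussian", fixed_terms=list(DEFAULT_TERMS), estimation="REML"
    )
    exact = 0
    for r in range(5):
        cfg = CohortConfig(
            n_subjects=7600, n_clusters=16, sigma_b=0.5, sigma_e=0.4,
            seed=900 + r,
        )
        cfg = inject_outliers(cfg, [3, 11], "race[NHB]", (0.5, -0.5))
        data, truth = generate_cohort(cfg)
        fs = fit_by_cluster(data, spec, coefficient_names=["race[NHB]"])
        ests = fs.estimates["race[NHB]"]
        kept, excluded, _ = screen_outliers(ests, 3.0)
        exact += sorted(e.cluster_id for e in excluded) == [3, 11]
        unscreened = pool_remr(ests, "DL")
        screened = pool_remr(kept, "DL")
        # cancellation: the pooled mean is roughly unbiased either way, but
        # heterogeneity and interval width collapse after screening
        assert unscreened.sigma2_v > screened.sigma2_v
        assert (unscreened.ci[1] - unscreened.ci[0]) > (
            screened.ci[1] - screened.ci[0]
        )
        assert abs(screened.tau - 0.46) < 4 * screened.se_tau
    assert exact >= 4


def test_inject_outliers_contract():
    cfg = CohortConfig(n_clusters=10)
    assert inject_outliers(cfg, [], "race[NHB]", 0.5).outlier_clusters == []
    cfg2 = inject_outliers(cfg, [1, 2], "race[NHB]", (0.5, -0.5))
    assert cfg2.outlier_clusters == [(1, "race[NHB]", 0.5), (2, "race[NHB]", -0.5)]
    with pytest.raises(ValueError, match="duplicate"):
        inject_outliers(cfg2, [1], "race[NHB]", 0.1)
    with pytest.raises(ValueError, match="outside"):
        inject_outliers(cfg, [10], "race[NHB]", 0.1)
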