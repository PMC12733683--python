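"""Two-stage estimation: recovery, goodness of fit, bootstrap."""

from dataclasses import replace

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import differential_evolution

from epskinetics import (
    AssociationClass,
    DegenerateDataError,
    GrowthParams,
    ProductParams,
    TimeCourse,
    TooFewPointsError,
    bootstrap_ci,
    classify_association,
    fit_joint,
    fit_logistic,
    fit_luedeking_piret,
    generate_timecourse,
    logistic_solution,
    lp_solution,
    r_squared,
)


class TestRSquared:
    @pytest.mark.parametrize(
        "obs, pred, expected",
        [
            ([1.0, 2.0, 3.0], [1.0, 2.0, 3.0], 1.0),
            ([1.0, 2.0, 3.0], [2.0, 2.0, 2.0], 0.0),
            ([1.0, 2.0, 3.0], [1.0, 2.0, 4.0], 0.5),
        ],
    )
    def test_values(self, obs, pred, expected):
        assert r_squared(obs, pred) == pytest.approx(expected, abs=1e-12)

    def test_constant_observations_rejected(self):
        with pytest.raises(DegenerateDataError):
            r_squared([2.0, 2.0, 2.0], [1.0, 2.0, 3.0])

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            r_squared([1.0, 2.0], [1.0, 2.0, 3.0])


class TestLogisticFit:
    def test_exact_data_recovered_to_machine_precision(self, exact_timecourse, heat_scenario):
        fr = fit_logistic(exact_timecourse)
        true = heat_scenario.growth
        assert fr.converged
        assert fr.params.X0 == pytest.approx(true.X0, rel=1e-4)
        assert fr.params.Xmax == pytest.approx(true.Xmax, rel=1e-4)
        assert fr.params.mu_max == pytest.approx(true.mu_max, rel=1e-4)
        assert fr.r_squared == pytest.approx(1.0, abs=1e-10)
        assert fr.n_obs == len(fr.residuals) == 24

    def test_noisy_mu_within_ten_percent_and_matches_global_optimizer(
        self, noisy_timecourse, heat_scenario
    ):
        fr = fit_logistic(noisy_timecourse)
        true_mu = heat_scenario.growth.mu_max
        assert abs(fr.params.mu_max / true_mu - 1.0) < 0.10

        # independent global-search oracle on the same pooled objective
        t = noisy_timecourse.times()
        x = noisy_timecourse.biomass()

        def ssr(theta):
            gp = GrowthParams(theta[0], theta[0] + theta[1], theta[2])
            return float(np.sum((x - np.asarray(logistic_solution(gp, t))) ** 2))

        de = differential_evolution(
            ssr, [(1e-6, 1.0), (1.0, 20.0), (0.01, 1.0)], seed=0, tol=1e-12
        )
        p = fr.params
        assert ssr([p.X0, p.Xmax - p.X0, p.mu_max]) <= de.fun * (1 + 1e-6) + 1e-12
        assert fr.params.mu_max == pytest.approx(de.x[2], rel=1e-3)

    def test_objective_at_estimate_not_worse_than_truth(self, heat_scenario):
        for seed in range(20):
            tc = generate_timecourse(replace(heat_scenario, seed=seed))
            fr = fit_logistic(tc)
            t, x = tc.times(), tc.biomass()
            ssr_fit = float(np.sum(fr.residuals**2))
            ssr_truth = float(
                np.sum((x - np.asarray(logistic_solution(heat_scenario.growth, t))) ** 2)
            )
            assert ssr_fit <= ssr_truth + 1e-8

    def test_replicate_and_row_order_invariance(self, noisy_timecourse):
        fr1 = fit_logistic(noisy_timecourse)
        shuffled = noisy_timecourse.data.sample(frac=1.0, random_state=5)
        fr2 = fit_logistic(TimeCourse("noisy", shuffled))
        assert fr1.params == fr2.params

    def test_too_few_time_points_rejected(self):
        df = pd.DataFrame(
            {"replicate": 1, "time_h": [1.0, 2.0, 3.0], "biomass": [0.1, 0.4, 1.0],
             "product": np.nan}
        )
        with pytest.raises(TooFewPointsError):
            fit_logistic(TimeCourse("tiny", df))

    def test_constant_biomass_rejected(self):
        df = pd.DataFrame(
            {"replicate": 1, "time_h": [1.0, 2, 3, 4, 5], "biomass": 2.0,
             "product": np.nan}
        )
        with pytest.raises(DegenerateDataError):
            fit_logistic(TimeCourse("flat", df))

    def test_truncate_at_peak_handles_late_decline(self, heat_scenario):
        declining = replace(
            heat_scenario, noise_cv=0.0, decay_rate=0.02, decay_after=48.0
        )
        tc = generate_timecourse(declining, "decline")
        plain = fit_logistic(tc)
        truncated = fit_logistic(tc, truncate_at_peak=True)
        assert "systematic_late_time_residuals" in plain.flags
        assert truncated.params.mu_max == pytest.approx(
            heat_scenario.growth.mu_max, rel=1e-3
        )

    def test_average_replicates_option_close_to_pooled(self, noisy_timecourse):
        pooled = fit_logistic(noisy_timecourse)
        averaged = fit_logistic(noisy_timecourse, average_replicates=True)
        assert averaged.params.mu_max == pytest.approx(pooled.params.mu_max, rel=0.05)


class TestLuedekingPiretFit:
    def test_exact_data_recovered(self, exact_timecourse, heat_scenario):
        fr = fit_luedeking_piret(exact_timecourse, heat_scenario.growth)
        true = heat_scenario.product
        assert fr.converged
        assert fr.params.alpha == pytest.approx(true.alpha, rel=1e-4)
        assert fr.params.beta == pytest.approx(true.beta, rel=1e-4)
        assert fr.params.P0 == pytest.approx(true.P0, rel=1e-3, abs=1e-6)
        assert fr.r_squared == pytest.approx(1.0, abs=1e-10)

    def test_noisy_recovery_and_mixed_classification(self, normal_scenario):
        # the normal condition identifies both coefficients well
        tc = generate_timecourse(replace(normal_scenario, seed=11))
        gp = fit_logistic(tc).params
        fr = fit_luedeking_piret(tc, gp)
        true = normal_scenario.product
        assert abs(fr.params.alpha / true.alpha - 1.0) < 0.25
        assert abs(fr.params.beta / true.beta - 1.0) < 0.25
        assert classify_association(fr.params, tol=1e-6) is AssociationClass.mixed

    def test_constant_product_yields_null_association(self, exact_timecourse, heat_scenario):
        df = exact_timecourse.data.copy()
        df["product"] = 0.7
        fr = fit_luedeking_piret(TimeCourse("const", df), heat_scenario.growth)
        assert fr.params.alpha == 0.0 and fr.params.beta == 0.0
        assert fr.params.P0 == pytest.approx(0.7)
        assert classify_association(fr.params) is AssociationClass.none

    def test_invalid_growth_params_rejected(self, exact_timecourse):
        with pytest.raises(TypeError):
            fit_luedeking_piret(exact_timecourse, gp=(0.1, 8.0, 0.3))

    def test_negative_coefficients_flagged_not_clipped(self, simple_gp):
        # production that slows relative to biomass forces beta < 0
        t = np.array([6.0, 12, 24, 36, 48, 72, 96, 120])
        X = np.asarray(logistic_solution(simple_gp, t))
        pp_true = ProductParams(P0=0.5, alpha=0.02, beta=0.0)
        P = np.asarray(lp_solution(simple_gp, pp_true, t)) - 0.05 * (X - simple_gp.X0)
        df = pd.DataFrame(
            {"replicate": 1, "time_h": t, "biomass": X, "product": np.maximum(P, 0)}
        )
        fr = fit_luedeking_piret(TimeCourse("neg", df), simple_gp)
        assert fr.params.beta < 0
        assert "negative_beta" in fr.flags


class TestJointFit:
    def test_joint_close_to_two_stage_on_exact_data(self, exact_timecourse, heat_scenario):
        fr_g, fr_p = fit_joint(exact_timecourse)
        assert fr_g.params.mu_max == pytest.approx(
            heat_scenario.growth.mu_max, rel=1e-3
        )
        assert fr_p.params.alpha == pytest.approx(
            heat_scenario.product.alpha, rel=1e-3
        )


class TestBootstrap:
    def test_seed_determinism(self, noisy_timecourse):
        a = bootstrap_ci(noisy_timecourse, n_boot=100, seed=9)
        b = bootstrap_ci(noisy_timecourse, n_boot=100, seed=9)
        assert a.intervals == b.intervals
        assert a.failure_fraction == b.failure_fraction

    def test_exact_data_gives_degenerate_intervals(self, exact_timecourse):
        br = bootstrap_ci(exact_timecourse, n_boot=100, seed=2)
        lo, hi = br.intervals["mu_max"]
        assert hi - lo < 1e-6
        assert lo <= br.estimates["mu_max"] <= hi

    def test_intervals_ordered_around_estimates(self, noisy_timecourse):
        br = bootstrap_ci(noisy_timecourse, n_boot=100, seed=4)
        for name, (lo, hi) in br.intervals.items():
            assert lo <= hi
        assert br.failure_fraction <= 0.05

    def test_small_n_boot_rejected(self, noisy_timecourse):
        with pytest.raises(ValueError):
            bootstrap_ci(noisy_timecourse, n_boot=50, seed=0)

    def test_mu_max_coverage_near_nominal(self, normal_scenario):
        """95% percentile intervals cover the true growth rate at close to
        nominal frequency across 200 independently simulated studies."""
        hits = 0
        n = 200
        for s in range(n):
            tc = generate_timecourse(replace(normal_scenario, seed=50_000 + s))
            br = bootstrap_ci(tc, n_boot=100, seed=s)
            lo, hi = br.intervals["mu_max"]
            hits += lo <= normal_scenario.growth.mu_max <= hi
        assert 0.85 <= hits / n <= 0.99


class TestRecoveryBias:
    @pytest.mark.parametrize("label", ["heat_stress", "normal"])
    def test_median_mu_bias_under_five_percent(self, scenarios, label):
        sc = scenarios[label]
        rel = []
        for s in range(100):
            tc = generate_timecourse(replace(sc, seed=7_000 + s))
            rel.append(fit_logistic(tc).params.mu_max / sc.growth.mu_max - 1.0)
        assert abs(float(np.median(rel))) <= 0.05
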