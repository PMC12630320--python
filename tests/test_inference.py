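"""Estimator contracts: closed-form identities, fixed points, consistency,
calibration, and the confidence-set scan (including its failure mode)."""

import numpy as np
import pytest
from scipy import integrate, optimize, stats

from factorlik import catalog, experiments, inference, verify


class TestMarginalMLE:
    def test_single_observation_closed_forms(self):
        # one pair: the likelihood equation reduces to psi^2 s = 1
        assert inference.fit_marginal_mle_ratio([0.25]).estimate == \
            pytest.approx(2.0, rel=1e-10)
        assert inference.fit_marginal_mle_ratio([1.0]).estimate == \
            pytest.approx(1.0, rel=1e-10)

    def test_fixed_point_of_likelihood_equation(self):
        rng = np.random.default_rng(0)
        u = rng.uniform(size=500)
        s = u / (4.0 * (1 - u))  # inverse CDF at psi = 2
        fit = inference.fit_marginal_mle_ratio(s)
        assert fit.diagnostics["fixed_point"] == pytest.approx(1.0, abs=1e-8)

    def test_consistency_large_b(self):
        """psihat within 3 standard errors of truth at b = 1e5."""
        psi = 2.0
        rng = np.random.default_rng(42)
        u = rng.uniform(size=100_000)
        s = u / (psi**2 * (1 - u))
        fit = inference.fit_marginal_mle_ratio(s)
        assert abs(fit.estimate - psi) < 3 * fit.std_error
        lo, hi = fit.interval
        assert lo < fit.estimate < hi

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            inference.fit_marginal_mle_ratio([])
        with pytest.raises(ValueError):
            inference.fit_marginal_mle_ratio([1.0, -2.0])

    def test_wald_coverage_calibration(self):
        """95% interval covers the truth 92-98% of the time over 500
        replicates of b = 400 pairs."""
        psi, b, reps = 1.0, 400, 500
        rng = np.random.default_rng(7)
        hits = 0
        for _ in range(reps):
            u = rng.uniform(size=b)
            s = u / (psi**2 * (1 - u))
            fit = inference.fit_marginal_mle_ratio(s)
            lo, hi = fit.interval
            hits += int(lo <= psi <= hi)
        assert 0.92 <= hits / reps <= 0.98


class TestLimitFunction:
    def test_printed_value(self):
        # closed form at (kappa, psi) = (2, 1): (12 - 8 log 2)/9
        assert inference.limit_function(2.0, 1.0) == pytest.approx(
            (12 - 8 * np.log(2)) / 9, rel=1e-12)

    def test_quadrature_oracle(self):
        """The limit equals E[kappa^2 S/(1+kappa^2 S)] under the ratio law."""
        for kappa, psi in [(2.0, 1.0), (0.7, 1.3), (1.5, 1.5)]:
            val, _ = integrate.quad(
                lambda s: kappa**2 * s / (1 + kappa**2 * s)
                * verify.hazard_ratio_density(s, psi),
                0, np.inf, limit=200)
            assert inference.limit_function(kappa, psi) == pytest.approx(
                val, abs=1e-8)

    def test_removable_singularity(self):
        """Value 1/2 at kappa = psi, continuously approached from both sides
        and across the series switch."""
        for psi in (0.5, 1.0, 3.0):
            assert inference.limit_function(psi, psi) == pytest.approx(0.5)
            for eps in (1e-3, 2e-4, 1e-5):  # straddles the switch at 1e-4
                up = inference.limit_function(psi * (1 + eps), psi)
                dn = inference.limit_function(psi * (1 - eps), psi)
                assert up == pytest.approx(0.5, abs=1e-2)
                assert dn == pytest.approx(0.5, abs=1e-2)
        assert abs(inference.limit_function(1.0 + 1.0001e-4, 1.0)
                   - inference.limit_function(1.0 + 0.9999e-4, 1.0)) < 1e-8

    def test_unity_only_at_truth(self):
        """2 * limit equals 1 only where kappa = psi (monotone scan)."""
        for psi in (0.5, 1.0, 3.0):
            kappas = psi * np.linspace(0.2, 5.0, 401)
            vals = 2 * np.array([inference.limit_function(k, psi)
                                 for k in kappas]) - 1.0
            roots = np.where(np.diff(np.sign(vals)) != 0)[0]
            assert len(roots) == 1
            assert kappas[roots[0]] <= psi <= kappas[roots[0] + 1]


class TestJointMLE:
    def test_single_pair_closed_form(self):
        fit = inference.fit_joint_mle_pairs(([1.0], [4.0]))
        assert fit.estimate == pytest.approx(2.0, rel=1e-10)
        # nuisance plug-in: 2 / (t psi + c / psi)
        assert fit.diagnostics["lambda_hat"][0] == pytest.approx(0.5)

    def test_symmetry(self):
        t = np.array([1.0, 2.0, 3.0])
        fit = inference.fit_joint_mle_pairs((t, t))
        assert fit.estimate == pytest.approx(1.0, rel=1e-10)

    def test_consistency(self):
        model = catalog.make_model("exp_hazard_pair")
        lam = experiments.nuisance_grid(100_000, "lognormal", sigma=0.5)
        sample = catalog.sample_blocks(model, 100_000, lam, 1.5, seed=13)
        fit = inference.fit_joint_mle_pairs(
            (sample.by_arm("T"), sample.by_arm("C")))
        assert fit.estimate == pytest.approx(1.5, abs=0.02)

    def test_agrees_with_marginal_at_b1(self):
        """With one pair both estimators solve the same equation:
        psihat = sqrt(c/t)."""
        t, c = 0.7, 2.9
        m = inference.fit_marginal_mle_ratio([t / c]).estimate
        j = inference.fit_joint_mle_pairs(([t], [c])).estimate
        assert m == pytest.approx(j, rel=1e-9)
        assert m == pytest.approx(np.sqrt(c / t), rel=1e-9)


class TestNaiveNormal:
    def test_hand_arithmetic(self):
        fit = inference.naive_mle_normal(([0.0, 1.0], [2.0, 1.0]))
        assert fit.estimate == pytest.approx(0.5)

    def test_zero_for_identical_pairs(self):
        y = np.array([1.0, -2.0, 3.0])
        assert inference.naive_mle_normal((y, y)).estimate == 0.0

    def test_probability_limit_half(self):
        """The profiled variance estimator tends to sigma^2/2."""
        model = catalog.make_model("normal_pair")
        mu = experiments.nuisance_grid(100_000, "normal")
        sample = catalog.sample_blocks(model, 100_000, mu, 1.0, seed=21)
        fit = inference.naive_mle_normal(sample)
        # var of the estimator ~ sigma^4/(4 b): 3 MC se
        assert abs(fit.estimate - 0.5) < 3 * np.sqrt(0.25 / 100_000) * 2


def _brute_force_logistic_mle(t, c):
    """Oracle: maximise the full binary-pair likelihood jointly in psi and
    every lambda_i by numeric optimisation (no profiling shortcuts)."""
    t = np.asarray(t, float)
    c = np.asarray(c, float)
    b = t.size

    def nll(theta):
        psi, lams = theta[0], theta[1:]
        et = psi + lams
        return -(np.sum(t * et - np.log1p(np.exp(et)))
                 + np.sum(c * lams - np.log1p(np.exp(lams))))

    res = optimize.minimize(nll, x0=np.zeros(b + 1), method="BFGS",
                            options={"maxiter": 2000, "gtol": 1e-10})
    return res.x[0]


class TestLogisticPairs:
    def test_closed_forms_match_brute_force(self):
        """Profile estimate 2 log(n10/n01) and conditional log(n10/n01),
        cross-checked against full numeric joint maximisation."""
        t = np.array([1, 1, 0, 1, 0, 1, 1, 0])
        c = np.array([0, 0, 1, 1, 0, 0, 1, 1])
        # n10 = 3, n01 = 2
        prof = inference.profile_mle_logistic((t, c))
        cond = inference.conditional_mle_logistic((t, c))
        assert prof.estimate == pytest.approx(2 * np.log(1.5), rel=1e-10)
        assert cond.estimate == pytest.approx(np.log(1.5), rel=1e-10)
        oracle = _brute_force_logistic_mle(t, c)
        assert prof.estimate == pytest.approx(oracle, abs=5e-4)

    def test_balanced_discordance_gives_zero(self):
        t = np.array([1, 0, 1, 0])
        c = np.array([0, 1, 0, 1])
        assert inference.profile_mle_logistic((t, c)).estimate == 0.0
        assert inference.conditional_mle_logistic((t, c)).estimate == 0.0

    def test_infinite_estimate_flagged(self):
        t = np.array([1, 1, 1])
        c = np.array([0, 0, 1])
        fit = inference.profile_mle_logistic((t, c))
        assert not fit.converged
        assert np.isinf(fit.estimate)
        assert fit.interval is None

    def test_profile_limit_is_twice_truth(self):
        """With b = 5e4 pairs and fixed lambda_i, the profile estimator sits
        near 2 psi while the conditional estimator sits near psi."""
        psi, b = 1.0, 50_000
        model = catalog.make_model("logistic_pair")
        lam = experiments.nuisance_grid(b, "normal")
        sample = catalog.sample_blocks(model, b, lam, psi, seed=31)
        prof = inference.profile_mle_logistic(sample)
        cond = inference.conditional_mle_logistic(sample)
        assert abs(prof.estimate - 2 * psi) < 3 * prof.std_error
        assert abs(cond.estimate - psi) < 3 * cond.std_error


class TestMomentEstimator:
    def test_hand_arithmetic(self):
        fit = inference.moment_estimator_mean_shift(([1.0, 3.0], [2.0, 5.0]))
        assert fit.estimate == pytest.approx(0.75)
        assert fit.diagnostics["sigma2_hat"] == pytest.approx(
            17.0 / 8.0 + 0.75**2 / 2.0)

    def test_zero_for_identical_arms(self):
        y = np.array([1.0, 2.0])
        assert inference.moment_estimator_mean_shift((y, y)).estimate == 0.0

    def test_simulation_matches_variance_formula(self):
        """Empirical variance over 2000 replicates matches
        psi^2/(2b) + (1/(2b^2)) sum lambda_i^{-2} within 10%, and the
        composite variance estimator is consistent for it."""
        psi, b, reps = 0.5, 200, 2000
        mu = experiments.nuisance_grid(b, "uniform", lo=2.0, hi=4.0)
        lam = 1.0 / mu
        rng = np.random.default_rng(3)
        tvals = rng.exponential(scale=mu - psi, size=(reps, b))
        cvals = rng.exponential(scale=mu + psi, size=(reps, b))
        psis = (cvals - tvals).sum(axis=1) / (2 * b)
        formula = psi**2 / (2 * b) + np.sum(1.0 / lam**2) / (2 * b**2)
        assert np.var(psis, ddof=1) == pytest.approx(formula, rel=0.10)
        assert psis.mean() == pytest.approx(psi, abs=3 * np.sqrt(formula / reps))
        sig2 = (tvals * cvals).sum(axis=1) / (2 * b**2) + psis**2 / b
        assert sig2.mean() == pytest.approx(formula, rel=0.05)

    def test_pivot_callable(self):
        fit = inference.moment_estimator_mean_shift(([1.0, 3.0], [2.0, 5.0]))
        piv = fit.diagnostics["pivot"]
        assert piv(fit.estimate) == 0.0
        assert piv(0.0) == pytest.approx(fit.estimate / fit.std_error)


class TestConfidenceSetScan:
    @staticmethod
    def _ratio_family(t, c, psi0):
        return t / c

    @staticmethod
    def _ratio_cdf(s, psi0):
        return verify.hazard_ratio_cdf(s, psi0)

    def test_scan_covers_truth(self):
        """The scan retains the true psi in >= 95% of 200 replicates at
        level 0.95 (scaled-down coverage study, b = 2000)."""
        psi, b, reps = 2.0, 2000, 200
        rng = np.random.default_rng(17)
        hits = 0
        for _ in range(reps):
            u = rng.uniform(size=b)
            s = u / (psi**2 * (1 - u))
            t = s  # scan consumes (t, c) with s = t/c; set c = 1
            c = np.ones_like(s)
            scan = inference.confidence_set_scan(
                (t, c), self._ratio_family, self._ratio_cdf,
                psi_grid=[psi], level=0.95)
            hits += int(psi in scan.accepted)
        assert hits / reps >= 0.90

    def test_scan_localises_truth(self):
        psi, b = 2.0, 5000
        rng = np.random.default_rng(19)
        u = rng.uniform(size=b)
        s = u / (psi**2 * (1 - u))
        scan = inference.confidence_set_scan(
            (s, np.ones_like(s)), self._ratio_family, self._ratio_cdf,
            psi_grid=np.linspace(1.0, 3.0, 21), level=0.95)
        assert scan.accepted.size > 0
        assert scan.accepted.min() <= psi <= scan.accepted.max()
        assert not scan.pathological

    def test_empty_data_returns_full_grid(self):
        scan = inference.confidence_set_scan(
            (np.array([]), np.array([])), self._ratio_family, self._ratio_cdf,
            psi_grid=np.linspace(0.5, 2.0, 7))
        assert scan.degenerate
        assert scan.accepted.size == 7

    def test_mean_shift_pathology_flagged(self):
        """The law of c/t depends on (psi, lambda) only through psi*lambda,
        so with any data-based plug-in for the unknown nuisance level the
        null distribution is the same at every trial psi0: the scan cannot
        localise psi and must flag the unidentified set."""
        psi, lam, b = 0.5, 0.8, 4000
        model = catalog.make_model("exp_mean_shift_pair")
        t, c = verify.sample_pair_values(model, psi, lam, b, seed=23)
        s_med = float(np.median(c / t))
        rho_hat = (s_med - 1.0) / (s_med + 1.0)  # median-inversion estimate

        def family(t, c, psi0):
            return c / t

        def null_cdf(s, psi0):
            lam_bar = rho_hat / psi0  # plug-in nuisance level given psi0
            return verify.mean_shift_ratio_cdf(s, psi0 * lam_bar)

        scan = inference.confidence_set_scan(
            (t, c), family, null_cdf,
            psi_grid=np.linspace(0.05, 0.95, 19), level=0.95)
        assert scan.pathological
        assert scan.accepted.size >= 0.5 * 19

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            inference.confidence_set_scan(
                (np.array([1.0]), np.array([1.0])), self._ratio_family,
                self._ratio_cdf, psi_grid=[])
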