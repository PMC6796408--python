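import numpy as np
import pytest

import cardiosem as cs
from cardiosem.engine import CompiledModel, InadmissibleParameterError, _numeric_hessian
from tests.conftest import moments_from_cov


class TestImpliedCovariance:
    def test_single_path_hand_algebra(self):
        V, P = cs.VariableDef, cs.PathSpec
        m = cs.ModelSpec(
            (V("x", "observed"), V("y", "observed"),
             V("FX", "latent"), V("FY", "latent")),
            (
                P("FX", "x", "directed", "fixed", 1.0),
                P("FY", "y", "directed", "fixed", 1.0),
                P("FX", "FY", "directed", "free", label="b"),
                P("FX", "FX", "covariance", "fixed", 1.0),
                P("FY", "FY", "covariance", "fixed", 0.0),
                P("x", "x", "covariance", "fixed", 0.0),
                P("y", "y", "covariance", "fixed", 0.0),
            ),
        )
        b = 0.7
        sigma = cs.implied_covariance(m, {"b": b})
        assert sigma[0, 0] == pytest.approx(1.0)
        assert sigma[0, 1] == pytest.approx(b)
        assert sigma[1, 1] == pytest.approx(b * b)

    def test_no_directed_paths_returns_diagonal(self):
        m = cs.independence_model(["a", "b", "c"])
        sigma = cs.implied_covariance(
            m, {f"F_{v}~~F_{v}": w for v, w in zip("abc", (1.0, 2.0, 3.0))}
        )
        assert np.allclose(sigma, np.diag([1.0, 2.0, 3.0]))

    def test_whes_implied_matches_simulation(self, study):
        """Large-sample simulation from theta-hat reproduces Sigma(theta-hat)."""
        cm = study.result.compiled
        ds = cs.generate(cm, study.result.theta, n=300_000, seed=11, add_means=False)
        sample = np.cov(ds.records.to_numpy(), rowvar=False)
        implied = study.result.implied_cov
        # normalize each deviation by its Monte-Carlo standard error
        d = np.diag(implied)
        se = np.sqrt((np.outer(d, d) + implied**2) / 300_000)
        assert np.abs((sample - implied) / se).max() < 5.0


class TestMlDiscrepancy:
    def test_zero_at_equality(self, moments):
        S = cs.to_covariance(moments)
        assert cs.ml_discrepancy(S, S) == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_case(self):
        S = np.diag([2.0, 2.0])
        sigma = np.eye(2)
        expected = 2 * (np.log(0.5) + 2 - 1)
        assert cs.ml_discrepancy(S, sigma) == pytest.approx(expected, rel=1e-12)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(3)
        A = rng.standard_normal((5, 5))
        S = A @ A.T + 5 * np.eye(5)
        B = rng.standard_normal((5, 5))
        sigma = B @ B.T + 5 * np.eye(5)
        perm = rng.permutation(5)
        f1 = cs.ml_discrepancy(S, sigma)
        f2 = cs.ml_discrepancy(S[np.ix_(perm, perm)], sigma[np.ix_(perm, perm)])
        assert f1 == pytest.approx(f2, rel=1e-10)

    def test_non_pd_rejected(self):
        S = np.array([[1.0, 2.0], [2.0, 1.0]])  # eigenvalues -1, 3
        with pytest.raises(InadmissibleParameterError, match="eigenvalue"):
            cs.ml_discrepancy(S, np.eye(2))


class TestGradient:
    def test_analytic_gradient_matches_finite_differences(self, study):
        cm = study.result.compiled
        theta = study.result.theta * 1.03 + 0.01  # off the optimum
        _, g = cm.discrepancy(theta, with_grad=True)
        for k in np.linspace(0, cm.q - 1, 12, dtype=int):
            h = 1e-6 * max(1.0, abs(theta[k]))
            tp, tm = theta.copy(), theta.copy()
            tp[k] += h
            tm[k] -= h
            fd = (cm.discrepancy(tp) - cm.discrepancy(tm)) / (2 * h)
            assert g[k] == pytest.approx(fd, rel=2e-4, abs=1e-7)


class TestFit:
    def test_exact_recovery_from_model_implied_moments(
        self, mini_model, mini_truth, exact_moments_for
    ):
        res = cs.fit(mini_model, exact_moments_for)
        assert res.converged
        assert res.discrepancy_min == pytest.approx(0.0, abs=1e-10)
        assert res.chi2 == pytest.approx(0.0, abs=1e-7)
        for lab, truth in mini_truth.items():
            assert res.estimates[lab] == pytest.approx(truth, abs=1e-5)

    def test_convergence_reporting_is_honest(self, study):
        res = study.result
        assert res.converged
        assert res.gradient_norm < 1e-8
        assert res.heywood == ()

    def test_phantom_disturbance_constraint_holds_at_solution(self, study):
        est = study.result.estimates
        S = est.symmetric
        names = est.variable_names
        ix = {v: i for i, v in enumerate(names)}
        srcs = ("ChildAbuse", "PartnerAbuse", "AdultSexualAssault")
        expl = sum(S[ix[a], ix[a]] for a in srcs)
        expl += 2 * sum(
            S[ix[a], ix[b]]
            for i, a in enumerate(srcs)
            for b in srcs[i + 1:]
        )
        d = S[ix["LifetimeAbuse"], ix["LifetimeAbuse"]]
        # disturbance = 20% of total phantom variance
        assert d == pytest.approx(0.25 * expl, rel=1e-10)
        assert d / (d + expl) == pytest.approx(0.20, rel=1e-10)


class TestBaselineChi2:
    def test_diagonal_sample_gives_zero(self):
        m = moments_from_cov(np.diag([1.0, 2.0, 3.0]), n=100)
        chi2, df = cs.baseline_chi2(m)
        assert chi2 == pytest.approx(0.0, abs=1e-9)
        assert df == 3

    def test_fixture_baseline_df(self, moments):
        _, df = cs.baseline_chi2(moments)
        assert df == 91

    def test_bivariate_closed_form(self):
        r, n = 0.6, 150
        cov = np.array([[1.0, r], [r, 1.0]])
        chi2, df = cs.baseline_chi2(moments_from_cov(cov, n=n))
        assert chi2 == pytest.approx(-(n - 1) * np.log(1 - r * r), rel=1e-10)
        assert df == 1


class TestFitIndices:
    def test_perfect_fit(self):
        rmsea, cfi, tli, p = cs.fit_indices(75.0, 75, 1200.0, 91, 227)
        assert rmsea == 0.0
        assert cfi == 1.0
        assert p > 0.4

    def test_published_rmsea_regime(self):
        rmsea, _, _, _ = cs.fit_indices(148.94, 75, 1260.0, 91, 227)
        assert rmsea == pytest.approx(0.066, abs=5e-4)

    def test_tli_equals_cfi_limit(self):
        # when the model fits exactly, both incremental indices are 1
        _, cfi, tli, _ = cs.fit_indices(50.0, 50, 500.0, 91, 200)
        assert cfi == pytest.approx(1.0)
        assert tli >= 1.0


class TestStandardize:
    def test_single_predictor_equals_implied_correlation(
        self, mini_model, mini_truth, exact_moments_for
    ):
        res = cs.fit(mini_model, exact_moments_for)
        C = res.compiled.full_implied(res.theta)[4]
        ix = {v: i for i, v in enumerate(res.compiled.names)}
        rho = C[ix["F1"], ix["F2"]] / np.sqrt(C[ix["F1"], ix["F1"]] * C[ix["F2"], ix["F2"]])
        assert res.standardized_coefficients["F2~F1"] == pytest.approx(rho, rel=1e-8)

    def test_unit_variance_model_unchanged(self):
        V, P = cs.VariableDef, cs.PathSpec
        m = cs.ModelSpec(
            (V("x", "observed"), V("F", "latent")),
            (
                P("F", "x", "directed", "fixed", 1.0),
                P("F", "F", "covariance", "fixed", 1.0),
                P("x", "x", "covariance", "fixed", 0.0),
            ),
        )
        std = cs.standardize(m, {})
        assert std["x~F"] == pytest.approx(1.0)


class TestRSquared:
    def test_single_path_r2_is_squared_correlation(
        self, mini_model, mini_truth, exact_moments_for
    ):
        res = cs.fit(mini_model, exact_moments_for)
        beta = res.standardized_coefficients["F2~F1"]
        assert res.r_squared["F2"] == pytest.approx(beta**2, rel=1e-8)

    def test_zero_structural_paths(self, mini_model, exact_moments_for):
        theta = {"F1=~x2": 0.8, "F2~F1": 0.0, "F1~~F1": 2.0, "F2~~F2": 1.0}
        r2 = cs.r_squared(mini_model, theta)
        assert r2["F2"] == pytest.approx(0.0)


class TestStandardizedResiduals:
    def test_zero_at_equality(self, moments):
        S = cs.to_covariance(moments)
        assert np.allclose(cs.standardized_residuals(S, S, moments.n), 0.0)

    def test_scale_invariance(self):
        rng = np.random.default_rng(9)
        A = rng.standard_normal((4, 4))
        S = A @ A.T + 4 * np.eye(4)
        B = rng.standard_normal((4, 4))
        sigma = B @ B.T + 4 * np.eye(4)
        r1 = cs.standardized_residuals(S, sigma, 100)
        r2 = cs.standardized_residuals(3.7 * S, 3.7 * sigma, 100)
        assert np.allclose(r1, r2, rtol=1e-12)

    def test_hand_computed_two_by_two(self):
        S = np.array([[1.2, 0.4], [0.4, 0.9]])
        sigma = np.array([[1.0, 0.3], [0.3, 1.0]])
        n = 50
        out = cs.standardized_residuals(S, sigma, n)
        assert out[0, 1] == pytest.approx(0.1 / np.sqrt((1.0 + 0.09) / n), rel=1e-12)
        assert out[0, 0] == pytest.approx(0.2 / np.sqrt(2.0 / n), rel=1e-12)


class TestWaldTests:
    def test_se_matches_sampling_distribution(self, mini_model, mini_truth):
        """Information-based SEs agree with the spread of ML estimates
        across simulated datasets (a regression-style closed-form check
        would only cover the just-identified part of the model)."""
        cov = cs.implied_covariance(mini_model, mini_truth)
        n = 800
        m0 = moments_from_cov(cov, n=n, names=mini_model.observed_names)
        res = cs.fit(mini_model, m0)
        tests = cs.wald_tests(res.compiled, res.theta)
        rng = np.random.default_rng(17)
        chol = np.linalg.cholesky(cov)
        draws = {lab: [] for lab in mini_truth}
        for _ in range(150):
            X = rng.standard_normal((n, 4)) @ chol.T
            mrep = moments_from_cov(np.cov(X, rowvar=False), n=n,
                                    names=mini_model.observed_names)
            rep = cs.fit(mini_model, mrep,
                         cs.FitOptions(compute_se=False, max_restarts=2))
            for lab in draws:
                draws[lab].append(rep.estimates[lab])
        for lab in ("F2~F1", "F1=~x2"):
            se_info = tests[lab][0]
            se_emp = np.std(draws[lab], ddof=1)
            assert se_info == pytest.approx(se_emp, rel=0.25)

    def test_published_model_wald_p_for_nonsignificant_path(self, study):
        # the direct abuse -> CVD path is reported non-significant
        p = study.result.wald_p["CVDRisk~LifetimeAbuse"]
        assert 0.02 < p < 0.30


def test_chi2_scale_flag(moments, whes):
    res_n1 = cs.fit(whes, moments, cs.FitOptions(
        standardize=cs.ABUSE_INDICATORS, compute_se=False))
    res_n = cs.fit(whes, moments, cs.FitOptions(
        standardize=cs.ABUSE_INDICATORS, compute_se=False, chi2_scale="n"))
    assert res_n.chi2 / res_n1.chi2 == pytest.approx(227 / 226, rel=1e-9)


def test_hessian_symmetry(study):
    cm = study.result.compiled
    H = _numeric_hessian(
        lambda th: cm.discrepancy(th, with_grad=True), study.result.theta
    )
    assert np.allclose(H, H.T)
    # at the optimum the information matrix is positive definite
    assert np.linalg.eigvalsh(H).min() > 0
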