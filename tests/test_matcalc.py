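import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import sexalloc as sa
from sexalloc.matcalc import (DerivativeBundle, SensitivityContext,
                              StabilityConditions, commutation_matrix,
                              d2lambda_mixed, d2lambda_mutant,
                              eigenvalue_gradient, eigenvector_derivatives,
                              lambda_hessian_wrt_A,
                              resident_curvature_from_identity, unvec, vec)
from sexalloc.dynamics import _resident_direction_bundle

import fdtools


class TestVec:
    def test_column_stacking(self):
        X = np.array([[1.0, 3.0], [2.0, 4.0]])
        np.testing.assert_array_equal(vec(X), [1.0, 2.0, 3.0, 4.0])

    def test_roundtrip_random(self, rng):
        X = rng.normal(size=(5, 5))
        np.testing.assert_array_equal(unvec(vec(X), 5, 5), X)

    def test_unvec_length_mismatch(self):
        with pytest.raises(ValueError):
            unvec(np.arange(5), 2, 3)

    def test_vec_transpose_via_commutation(self, rng):
        X = rng.normal(size=(3, 2))
        K = commutation_matrix(3, 2)
        np.testing.assert_allclose(K @ vec(X), vec(X.T))


class TestCommutationMatrix:
    def test_trivial(self):
        np.testing.assert_array_equal(commutation_matrix(1, 1), [[1.0]])

    def test_2x2_swaps_middle(self):
        K = commutation_matrix(2, 2)
        np.testing.assert_array_equal(K @ np.array([1.0, 2.0, 3.0, 4.0]),
                                      [1.0, 3.0, 2.0, 4.0])

    @pytest.mark.parametrize("m,n", [(2, 3), (3, 5)])
    def test_transpose_property(self, m, n):
        np.testing.assert_array_equal(commutation_matrix(m, n).T,
                                      commutation_matrix(n, m))

    @given(m=st.integers(1, 6), n=st.integers(1, 6))
    @settings(max_examples=25, deadline=None)
    def test_is_permutation(self, m, n):
        K = commutation_matrix(m, n)
        assert np.all(K.sum(axis=0) == 1.0)
        assert np.all(K.sum(axis=1) == 1.0)
        assert np.all((K == 0.0) | (K == 1.0))

    @given(m=st.integers(1, 5), n=st.integers(1, 5), seed=st.integers(0, 10 ** 6))
    @settings(max_examples=25, deadline=None)
    def test_defining_property(self, m, n, seed):
        X = np.random.default_rng(seed).normal(size=(m, n))
        np.testing.assert_allclose(commutation_matrix(m, n) @ vec(X), vec(X.T))


class TestEigenvalueGradient:
    def test_zero_direction(self, rng):
        ctx = SensitivityContext.from_matrix(fdtools.random_perron_matrix(rng))
        assert eigenvalue_gradient(ctx, np.zeros(25)) == 0.0

    def test_diagonal_entry(self):
        ctx = SensitivityContext.from_matrix(np.diag([2.0, 1.0]))
        direction = np.zeros(4)
        direction[0] = 1.0  # perturb a11 only; lambda == a11
        assert eigenvalue_gradient(ctx, direction) == pytest.approx(1.0)

    def test_matches_fd(self, rng):
        for _ in range(10):
            A = fdtools.random_perron_matrix(rng)
            ctx = SensitivityContext.from_matrix(A)
            direction = rng.normal(size=25)
            h = 1e-6
            lp = fdtools.dominant_eigenvalue(A + h * unvec(direction, 5, 5))
            lm = fdtools.dominant_eigenvalue(A - h * unvec(direction, 5, 5))
            fd = (lp - lm) / (2 * h)
            analytic = eigenvalue_gradient(ctx, direction)
            assert analytic == pytest.approx(fd, rel=1e-5)

    def test_normalisation_violation_rejected(self, rng):
        ctx = SensitivityContext.from_matrix(fdtools.random_perron_matrix(rng))
        ctx.triple.v = 2.0 * ctx.triple.v
        with pytest.raises(ValueError):
            eigenvalue_gradient(ctx, np.zeros(25))


class TestEigenvectorDerivatives:
    def test_w_stays_on_simplex(self, rng):
        ctx = SensitivityContext.from_matrix(fdtools.random_perron_matrix(rng))
        dw, _ = eigenvector_derivatives(ctx)
        np.testing.assert_allclose(np.ones(5) @ dw, 0.0, atol=1e-10)

    def test_normalisation_preserved(self, rng):
        ctx = SensitivityContext.from_matrix(fdtools.random_perron_matrix(rng))
        dw, dv = eigenvector_derivatives(ctx)
        np.testing.assert_allclose(ctx.triple.v @ dw + ctx.triple.w @ dv,
                                   0.0, atol=1e-8)

    def test_matches_fd_columns(self, rng):
        A = fdtools.random_perron_matrix(rng)
        ctx = SensitivityContext.from_matrix(A)
        dw, dv = eigenvector_derivatives(ctx)
        Jw, Jv = fdtools.fd_entry_jacobians(A)
        np.testing.assert_allclose(dw, Jw, rtol=1e-4, atol=1e-7)
        np.testing.assert_allclose(dv, Jv, rtol=1e-4, atol=1e-7)


class TestLambdaHessian:
    def test_symmetric(self, rng):
        ctx = SensitivityContext.from_matrix(fdtools.random_perron_matrix(rng))
        H = lambda_hessian_wrt_A(ctx)
        np.testing.assert_allclose(H, H.T, atol=1e-10)

    def test_diagonal_matrix_linear_cell(self):
        # lambda == a11 locally for diag(2, 1): curvature in (a11, a11) is 0
        ctx = SensitivityContext.from_matrix(np.diag([2.0, 1.0]))
        H = lambda_hessian_wrt_A(ctx)
        assert H[0, 0] == pytest.approx(0.0, abs=1e-12)

    def test_matches_fd(self, rng):
        A = fdtools.random_perron_matrix(rng)
        H = lambda_hessian_wrt_A(SensitivityContext.from_matrix(A))
        H_fd = fdtools.fd_lambda_hessian(A)
        tol = 1e-4 * (1.0 + np.max(np.abs(H)))
        np.testing.assert_allclose(H, H_fd, atol=tol)


def _ctx_and_bundle(model, s1):
    p_hat = model.equilibrium(s1).p
    ctx = SensitivityContext.from_matrix(model.A(s1, p_hat))
    bundle = _resident_direction_bundle(model, s1)
    return p_hat, ctx, bundle


class TestD2LambdaMutant:
    def test_case3_matrix_linear_in_trait(self, poor):
        model = sa.build_case_model(3, poor.replace(mu_m1=0.6, mu_f1=0.4))
        p_hat = model.equilibrium(0.5).p
        np.testing.assert_array_equal(model.d2vecA_ds1(0.5, p_hat), 0.0)

    def test_case0_symmetric_point_neutral(self, productive):
        model = sa.build_case_model(0, productive)
        _, ctx, bundle = _ctx_and_bundle(model, 0.5)
        assert abs(d2lambda_mutant(ctx, bundle)) < 1e-6

    @pytest.mark.parametrize("seed", [3, 11])
    def test_matches_fd(self, seed):
        from conftest import make_fixture_model
        model = make_fixture_model(seed)
        s1 = 0.45
        p_hat, ctx, bundle = _ctx_and_bundle(model, s1)
        fd = fdtools.fd_d2_mutant(model, p_hat, s1)
        analytic = d2lambda_mutant(ctx, bundle)
        assert abs(analytic - fd) < 1e-5 * (1.0 + abs(fd))


class TestD2LambdaMixed:
    def test_cases_0_to_3_have_constant_C(self, poor):
        # C depends on the equilibrium only through case 4 mating rates
        for case in (0, 1, 2, 3):
            cost = sa.CostModel(case_id=case) if case != 1 else \
                sa.CostModel(case_id=1, Cm=0.7, Cf=0.3)
            model = sa.build_case_model(case, poor, cost)
            bundle = _resident_direction_bundle(model, 0.4)
            np.testing.assert_array_equal(bundle.dC_ds1, 0.0)

    def test_case4_C_moves_with_equilibrium(self, poor):
        model = sa.build_case_model(
            4, poor, sa.CostModel(case_id=4, Dm=0.7, Df=0.3, c=0.1))
        bundle = _resident_direction_bundle(model, 0.4)
        assert np.max(np.abs(bundle.dC_ds1)) > 0.0

    @pytest.mark.parametrize("seed", [5, 17])
    def test_matches_fd_of_gradient(self, seed):
        from conftest import make_fixture_model
        model = make_fixture_model(seed)
        s1 = 0.5
        _, ctx, bundle = _ctx_and_bundle(model, s1)
        analytic = d2lambda_mixed(ctx, bundle)
        fd = fdtools.fd_mixed(model, s1)
        assert abs(analytic - fd) < 1e-4 * (1.0 + abs(fd))

    def test_missing_resident_bundle_rejected(self, rng):
        ctx = SensitivityContext.from_matrix(fdtools.random_perron_matrix(rng))
        bundle = DerivativeBundle(dvecA_ds1p=np.zeros(25), H_A_s1p=np.zeros(25))
        with pytest.raises(ValueError):
            d2lambda_mixed(ctx, bundle)


class TestSingularStrategyIdentity:
    def test_identity_with_independent_fd(self, case1_asymmetric_productive):
        model, report = case1_asymmetric_productive
        conds = StabilityConditions(d2_mutant=report.es_value,
                                    d2_mixed=report.d2_mixed)
        d2_res_fd = fdtools.fd_d2_resident(model, report.s1_star)
        assert abs(conds.d2_mutant + 2 * conds.d2_mixed + d2_res_fd) < 1e-6


class TestResidentCurvature:
    def test_zero(self):
        assert resident_curvature_from_identity(0.0, 0.0) == 0.0

    def test_sign_flip(self):
        assert resident_curvature_from_identity(0.0, -0.46) == pytest.approx(0.92)

    def test_matches_direct_fd(self, case1_asymmetric_productive):
        model, report = case1_asymmetric_productive
        identity_value = resident_curvature_from_identity(report.es_value,
                                                          report.d2_mixed)
        fd = fdtools.fd_d2_resident(model, report.s1_star)
        assert identity_value == pytest.approx(fd, abs=1e-4)


class TestScaleProperty:
    """Scaling the matrix map by k scales lambda and all its derivatives by k."""

    class _Scaled:
        def __init__(self, inner, k):
            self.inner, self.k = inner, k
            self.s = inner.s
            self.idx_m1, self.idx_f1 = inner.idx_m1, inner.idx_f1
            self.stage_labels = inner.stage_labels

        def A(self, s1, p):
            return self.k * self.inner.A(s1, p)

        def dvecA_ds1(self, s1, p):
            return self.k * self.inner.dvecA_ds1(s1, p)

        def d2vecA_ds1(self, s1, p):
            return self.k * self.inner.d2vecA_ds1(s1, p)

        def equilibrium(self, s1, tol=1e-10, p0=None):
            # time rescaling leaves the equilibrium distribution unchanged
            return self.inner.equilibrium(s1, tol=tol, p0=p0)

        def secondary_sex_ratio(self, p):
            return self.inner.secondary_sex_ratio(p)

        def is_viable(self, p):
            return self.inner.is_viable(p)

    @pytest.mark.parametrize("k", [0.5, 2.0])
    def test_derivatives_scale_linearly(self, case1_asymmetric_productive, k):
        model, report = case1_asymmetric_productive
        s1 = report.s1_star
        scaled = self._Scaled(model, k)
        g = sa.selection_gradient(model, 0.4)
        g_k = sa.selection_gradient(scaled, 0.4)
        assert g_k == pytest.approx(k * g, rel=1e-10, abs=1e-12)
        _, ctx, bundle = _ctx_and_bundle(model, s1)
        _, ctx_k, bundle_k = (None, SensitivityContext.from_matrix(scaled.A(s1, model.equilibrium(s1).p)),
                              _resident_direction_bundle(scaled, s1))
        assert d2lambda_mutant(ctx_k, bundle_k) == pytest.approx(
            k * d2lambda_mutant(ctx, bundle), rel=1e-8, abs=1e-10)
        assert d2lambda_mixed(ctx_k, bundle_k) == pytest.approx(
            k * d2lambda_mixed(ctx, bundle), rel=1e-6, abs=1e-8)
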