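"""Exact-moment, transform and identifiability tests for the static model."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

import cotula as ct
from cotula.params import StaticParams, SupportMask
from cotula.static_model import support_preserving_delta, uniform_correlation_params

from conftest import random_static_params


class TestGenerator:
    def test_rejects_bad_trial_count(self, static_params):
        with pytest.raises(ValueError):
            ct.generate_static(static_params, 0)

    def test_rejects_negative_variance(self):
        with pytest.raises(ValueError):
            StaticParams(a=np.zeros(2), b=np.zeros(2), B_not=np.zeros((2, 2)),
                         l=np.zeros(1), L_not=np.zeros((1, 2)), psi=-0.5,
                         Psi_not=np.ones(2))

    def test_pure_noise_reduces_to_unit_variance(self):
        p = StaticParams(a=np.zeros(3), b=np.zeros(2), B_not=np.zeros((2, 3)),
                         l=np.zeros(1), L_not=np.zeros((1, 3)), psi=1.0,
                         Psi_not=np.ones(3))
        d = ct.generate_static(p, 100_000, seed=0)
        assert np.var(d.y) == pytest.approx(1.0, rel=0.02)

    def test_uniform_noise_correlation_construction(self, rng):
        p = uniform_correlation_params(a=rng.uniform(0.1, 0.3, 4),
                                       b=rng.uniform(0.5, 1.0, 3),
                                       B_not=rng.standard_normal((3, 4)),
                                       noise_corr=0.10)
        d = ct.generate_static(p, 100_000, seed=1)
        resid = np.column_stack((d.y - d.X @ p.b - d.Y_not @ p.a,
                                 d.Y_not - d.X @ p.B_not))
        corr = np.corrcoef(resid, rowvar=False)
        off = corr[np.triu_indices_from(corr, k=1)]
        assert np.mean(off) == pytest.approx(0.10, abs=0.01)

    def test_empirical_covariance_matches_analytic(self, rng, static_params):
        p = static_params
        d = ct.generate_static(p, 200_000, seed=2)
        _, cov = ct.joint_moments(p, np.zeros(p.M))
        W = np.vstack(((p.b + p.B_not @ p.a)[None, :], p.B_not.T))
        resid = np.column_stack((d.y, d.Y_not)) - d.X @ W.T
        full = np.column_stack((resid, d.Z))
        emp = full.T @ full / d.D
        assert np.allclose(emp, cov, atol=0.05)


class TestMoments:
    def test_decoupled_limit_block_diagonal(self):
        N, M, K = 3, 2, 2
        p = StaticParams(a=np.zeros(N), b=np.ones(M), B_not=np.ones((M, N)),
                         l=np.zeros(K), L_not=np.zeros((K, N)), psi=0.7,
                         Psi_not=np.full(N, 1.3))
        _, cov = ct.joint_moments(p, np.zeros(M))
        expected = np.diag([0.7] + [1.3] * N + [1.0] * K)
        assert np.allclose(cov, expected)

    @pytest.mark.parametrize("seed", range(5))
    def test_precision_is_closed_form_inverse(self, seed):
        rng = np.random.default_rng(seed)
        p = random_static_params(rng, N=rng.integers(2, 8), M=3,
                                 K=rng.integers(1, 4))
        _, cov = ct.joint_moments(p, rng.standard_normal(p.M))
        prod = cov @ ct.precision_matrix(p)
        assert np.max(np.abs(prod - np.eye(prod.shape[0]))) < 1e-10

    def test_precision_symmetry_and_corner(self):
        p = StaticParams(a=np.zeros(2), b=np.ones(2), B_not=np.ones((2, 2)),
                         l=np.zeros(1), L_not=0.4 * np.ones((1, 2)), psi=0.25,
                         Psi_not=np.ones(2))
        P = ct.precision_matrix(p)
        assert np.max(np.abs(P - P.T)) < 1e-12
        assert P[0, 0] == pytest.approx(1.0 / 0.25)

    def test_precision_rejects_zero_variance(self, static_params):
        static_params.psi = 0.0
        with pytest.raises(ValueError):
            ct.precision_matrix(static_params)

    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(seed=st.integers(0, 10_000), n=st.integers(1, 6),
           k=st.integers(1, 4))
    def test_precision_identity_property(self, seed, n, k):
        rng = np.random.default_rng(seed)
        p = random_static_params(rng, N=n, M=3, K=k)
        _, cov = ct.joint_moments(p, np.zeros(3))
        prod = cov @ ct.precision_matrix(p)
        assert np.max(np.abs(prod - np.eye(prod.shape[0]))) < 1e-9


class TestMarginalLoglik:
    def test_matches_bivariate_normal_density(self):
        # 1-D everything with unit parameters: independent closed-form oracle
        p = StaticParams(a=np.ones(1), b=np.ones(1), B_not=np.ones((1, 1)),
                         l=np.ones(1), L_not=np.ones((1, 1)), psi=1.0,
                         Psi_not=np.ones(1))
        x = np.array([0.3])
        _, cov = ct.joint_moments(p, x)
        mean = np.array([x[0] * (1 + 1), x[0]])     # b + B a, B
        obs = np.array([0.7, -0.2])
        expected = stats.multivariate_normal(mean, cov[:2, :2]).logpdf(obs)
        data = ct.StaticDataset(X=x[None, :], Y_not=obs[1:][None, :],
                                y=obs[:1])
        assert ct.marginal_loglik(p, data) == pytest.approx(expected, abs=1e-10)

    def test_rejects_non_positive_definite_marginal(self, static_params):
        static_params.psi = 0.0
        static_params.Psi_not = np.zeros(static_params.N)
        static_params.l = np.zeros(static_params.K)
        static_params.L_not = np.zeros_like(static_params.L_not)
        data = ct.StaticDataset(X=np.zeros((1, static_params.M)),
                                Y_not=np.zeros((1, static_params.N)),
                                y=np.zeros(1))
        with pytest.raises(ValueError):
            ct.marginal_loglik(static_params, data)


class TestIdentifiabilityTransform:
    def test_zero_delta_is_identity(self, static_params):
        q = ct.apply_transform(static_params, np.zeros(static_params.K))
        assert np.allclose(q.a, static_params.a)
        assert np.allclose(q.b, static_params.b)
        assert np.allclose(q.l, static_params.l)
        assert q.psi == pytest.approx(static_params.psi)

    def test_likelihood_invariance(self, rng, static_params):
        data = ct.generate_static(static_params, 200, seed=3)
        ll0 = ct.marginal_loglik(static_params, data)
        for _ in range(20):
            delta = 0.2 * rng.standard_normal(static_params.K)
            try:
                q = ct.apply_transform(static_params, delta)
            except ValueError:
                continue
            ll = ct.marginal_loglik(q, data)
            assert abs(ll - ll0) < 1e-8 * abs(ll0)

    def test_invariance_holds_with_intercepts(self, rng):
        p = random_static_params(rng, K=1)
        p.b0 = 0.8
        p.b0_not = rng.standard_normal(p.N)
        data = ct.generate_static(p, 200, seed=6)
        ll0 = ct.marginal_loglik(p, data)
        lo, hi = ct.admissible_interval(p)
        q = ct.apply_transform(p, [0.5 * (lo + hi)])
        assert abs(ct.marginal_loglik(q, data) - ll0) < 1e-8 * abs(ll0)

    def test_inadmissible_delta_reports_interval(self, rng):
        p = random_static_params(rng, K=1)
        lo, hi = ct.admissible_interval(p)
        with pytest.raises(ValueError, match="admissible interval"):
            ct.apply_transform(p, [hi + 1.0])

    def test_family_endpoints_have_zero_private_variance(self, rng):
        p = random_static_params(rng, K=1)
        ends = ct.transform_family(p, 2)
        assert ends[0].psi <= 1e-10
        assert ends[-1].psi <= 1e-10

    def test_family_members_share_likelihood(self, rng):
        p = random_static_params(rng, K=1)
        data = ct.generate_static(p, 300, seed=4)
        lls = [ct.marginal_loglik(q, data) for q in ct.transform_family(p, 30)]
        assert np.ptp(lls) < 1e-8 * abs(lls[0])

    def test_private_variance_is_downward_parabola_with_apex_at_minus_l(self, rng):
        p = random_static_params(rng, K=1)
        lo, hi = ct.admissible_interval(p)
        deltas = np.linspace(lo, hi, 201)
        psis = [ct.apply_transform(p, [d]).psi for d in deltas]
        apex = deltas[int(np.argmax(psis))]
        assert apex == pytest.approx(-p.l[0], abs=(hi - lo) / 100)
        # the apex is generally not the midpoint of the admissible interval
        assert np.all(np.diff(psis, 2) < 1e-8)   # concave

    def test_family_requires_k1(self, rng):
        with pytest.raises(ValueError):
            ct.transform_family(random_static_params(rng, K=2), 10)


class TestSparsityIdentifiability:
    def test_dense_support_leaves_full_nullspace(self, static_params):
        sup = SupportMask.dense(static_params.N, static_params.M)
        holds, deficiency = ct.identifiability_check(static_params, sup)
        assert not holds
        assert deficiency == static_params.K

    def test_single_zero_entry_suffices_for_k1(self, rng):
        p = random_static_params(rng, K=1)
        p.a[0] = 0.0
        sup = SupportMask.from_params(p)
        holds, deficiency = ct.identifiability_check(p, sup)
        assert holds
        assert deficiency == 0
        assert support_preserving_delta(p, sup) is None

    def test_failing_condition_yields_invariant_support_preserving_delta(self, rng):
        p = random_static_params(rng, K=2)
        p.a[0] = 0.0     # one constraint only: K=2 > 1 zero entry
        sup = SupportMask.from_params(p)
        holds, deficiency = ct.identifiability_check(p, sup)
        assert not holds
        assert deficiency >= 1
        delta = support_preserving_delta(p, sup)
        assert delta is not None
        delta = 0.05 * delta / np.linalg.norm(delta)
        q = ct.apply_transform(p, delta)
        # the zero patterns of a and b are preserved ...
        assert abs(q.a[0]) < 1e-12
        assert np.array_equal(q.b != 0, p.b != 0)
        # ... and so is the likelihood
        data = ct.generate_static(p, 200, seed=5)
        ll0, ll1 = ct.marginal_loglik(p, data), ct.marginal_loglik(q, data)
        assert abs(ll1 - ll0) < 1e-8 * abs(ll0)

    @pytest.mark.parametrize("seed", range(6))
    def test_nullspace_dimension_identity(self, seed):
        rng = np.random.default_rng(seed)
        p = random_static_params(rng, N=6, M=5, K=rng.integers(1, 4))
        mask_c = rng.random(6) > 0.5
        mask_t = rng.random(5) > 0.5
        p.a = p.a * mask_c
        p.b = p.b * mask_t
        sup = SupportMask(mask_c, mask_t)
        holds, deficiency = ct.identifiability_check(p, sup)
        n_zero = int((~mask_c).sum() + (~mask_t).sum())
        # generic instances: rank of S is min(K, number of stacked rows)
        assert deficiency == max(0, p.K - min(p.K, n_zero))
        assert holds == (deficiency == 0 and n_zero >= p.K)
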