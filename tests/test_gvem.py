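import numpy as np
import pytest
from scipy.optimize import minimize_scalar
from scipy.special import log_expit

import interdif as idf
from interdif.gvem import _cold_start, e_step, elbo, m_step

from conftest import make_params


class TestBoundPrimitives:
    def test_lambda_limit_and_values(self):
        assert idf.bound_lambda(0.0) == pytest.approx(0.125, abs=1e-12)
        assert idf.bound_lambda(1e-9) == pytest.approx(0.125, abs=1e-9)
        # (sigmoid(1) - 1/2) / 2
        assert idf.bound_lambda(1.0) == pytest.approx(0.11552928931500245, abs=1e-12)
        # even-function contract: evaluated through |x|
        assert idf.bound_lambda(2.0) == idf.bound_lambda(abs(-2.0))

    def test_lambda_rejects_negative(self):
        with pytest.raises(ValueError):
            idf.bound_lambda(-0.5)

    def test_bound_tight_at_xi(self):
        for x in (1.0, -1.0, 3.7):
            got = idf.log_sigmoid_lower_bound(x, abs(x))
            assert got == pytest.approx(log_expit(x), abs=1e-12)

    def test_bound_below_log_sigmoid_at_zero(self):
        assert idf.log_sigmoid_lower_bound(0.0, 2.0) <= -np.log(2.0)


@pytest.mark.parametrize("variant", ["Ri", "RiM", "Ris", "RisM"])
class TestEStepBlockOptimality:
    """Each E-step block must be the ELBO maximizer over that factor."""

    def test_blocks_match_numerical_maximizer(self, tiny_data, variant):
        from _oracles import maximize_block

        rng = np.random.default_rng(3)
        data = tiny_data
        spec = idf.ModelSpec(variant=variant, J=2, anchors=frozenset({1}))
        params = make_params(data.design, variant, rng)
        _, vs = _cold_start(data, spec, idf.FitConfig())
        vs.xi = rng.uniform(0.5, 2.0, size=data.Y.shape)
        new = e_step(data, spec, params, vs)

        def neg_theta(x):
            v = vs.copy()
            v.theta_mean[0], v.theta_var[0] = x[0], np.exp(x[1])
            return -elbo(data, spec, params, v)

        x = maximize_block(neg_theta, [0.1, -0.5])
        assert new.theta_mean[0] == pytest.approx(x[0], abs=1e-6)
        assert new.theta_var[0] == pytest.approx(np.exp(x[1]), abs=1e-6)

        v_b = vs.copy()
        v_b.theta_mean, v_b.theta_var = new.theta_mean, new.theta_var
        v_b.u_mean, v_b.u_var = new.u_mean, new.u_var

        def neg_b(x):
            v = v_b.copy()
            v.b_mean[0, 0], v.b_var[0, 0] = x[0], np.exp(x[1])
            return -elbo(data, spec, params, v)

        x = maximize_block(neg_b, [0.0, -1.0])
        assert new.b_mean[0, 0] == pytest.approx(x[0], abs=1e-6)
        assert new.b_var[0, 0] == pytest.approx(np.exp(x[1]), abs=1e-6)

        if spec.has_multilevel_ability:
            v_u = vs.copy()
            v_u.theta_mean, v_u.theta_var = new.theta_mean, new.theta_var

            def neg_u(x):
                v = v_u.copy()
                v.u_mean[0], v.u_var[0] = x[0], np.exp(x[1])
                return -elbo(data, spec, params, v)

            x = maximize_block(neg_u, [0.0, -1.0])
            assert new.u_mean[0] == pytest.approx(x[0], abs=1e-6)
            assert new.u_var[0] == pytest.approx(np.exp(x[1]), abs=1e-6)

        if spec.has_random_slopes:
            v_a = vs.copy()
            v_a.theta_mean, v_a.theta_var = new.theta_mean, new.theta_var
            v_a.u_mean, v_a.u_var = new.u_mean, new.u_var
            v_a.b_mean, v_a.b_var = new.b_mean, new.b_var

            def neg_a(x):
                v = v_a.copy()
                v.a_under_mean[0, 0], v.a_under_var[0, 0] = x[0], np.exp(x[1])
                mom = idf.truncnorm_moments(v.a_under_mean, v.a_under_var)
                v.a_mean = mom.mean
                v.a_second = mom.variance + mom.mean**2
                v.a_log_z = mom.log_normalizer
                return -elbo(data, spec, params, v)

            x = maximize_block(neg_a, [1.0, -1.0])
            assert new.a_under_mean[0, 0] == pytest.approx(x[0], abs=1e-6)
            assert new.a_under_var[0, 0] == pytest.approx(np.exp(x[1]), abs=1e-6)


class TestEStepSpecialCases:
    def test_all_missing_person_gets_prior(self, tiny_data):
        rng = np.random.default_rng(3)
        Y = tiny_data.Y.copy()
        Y[0, :] = np.nan
        data = idf.ResponseData(Y=Y, group_of=tiny_data.group_of, design=tiny_data.design)
        spec = idf.ModelSpec(variant="Ri", J=2, anchors=frozenset({1}))
        params = make_params(data.design, "Ri", rng)
        _, vs = _cold_start(data, spec, idf.FitConfig())
        new = e_step(data, spec, params, vs)
        mu = params.group_ability_mean(data.design)[data.group_of[0]]
        assert new.theta_mean[0] == pytest.approx(mu, abs=1e-12)
        assert new.theta_var[0] == pytest.approx(1.0, abs=1e-12)

    def test_symmetric_responses_cancel(self):
        """Two identical items answered 1 and 0 leave the ability at the prior mean."""
        design = idf.build_group_design([2])
        data = idf.ResponseData(
            Y=np.array([[1.0, 0.0]]), group_of=np.array([0]), design=design
        )
        spec = idf.ModelSpec(variant="Ri", J=2, anchors=frozenset({1}))
        params = idf.Parameters(
            intercept_base=np.zeros(2), intercept_main=np.zeros((2, 1)),
            slope_base=np.ones(2), slope_main=np.zeros((2, 1)),
            var_intercept=np.full(2, 0.3), var_slope=np.zeros(2),
            impact_main=np.zeros(1),
        )
        _, vs = _cold_start(data, spec, idf.FitConfig())
        vs.b_mean[:] = 0.0
        vs.xi[:] = 1.0
        new = e_step(data, spec, params, vs)
        assert new.theta_mean[0] == pytest.approx(0.0, abs=1e-12)


class TestMStep:
    def test_variance_update_examples(self, tiny_data):
        rng = np.random.default_rng(0)
        spec = idf.ModelSpec(variant="Ri", J=2, anchors=frozenset({1}))
        params = make_params(tiny_data.design, "Ri", rng)
        _, vs = _cold_start(tiny_data, spec, idf.FitConfig())
        vs = e_step(tiny_data, spec, params, vs)
        # compute R_j independently and compare with the closed form
        new0 = m_step(tiny_data, spec, vs, idf.FitConfig(penalty_eta=0.0), params=params)
        new5 = m_step(tiny_data, spec, vs, idf.FitConfig(penalty_eta=5.0), params=params)
        Xt = tiny_data.design.X_tilde
        beta = np.column_stack([new0.intercept_base, new0.intercept_main])
        R = (((vs.b_mean - beta @ Xt.T) ** 2) + vs.b_var).sum(axis=1)
        S = tiny_data.design.S
        assert np.allclose(new0.var_intercept, R / S)
        assert np.allclose(new5.var_intercept, R / (S + 10.0))

    def test_huge_penalty_collapses_to_exact_zero(self, tiny_data):
        rng = np.random.default_rng(0)
        spec = idf.ModelSpec(variant="Ri", J=2, anchors=frozenset({1}))
        params = make_params(tiny_data.design, "Ri", rng)
        _, vs = _cold_start(tiny_data, spec, idf.FitConfig())
        vs = e_step(tiny_data, spec, params, vs)
        new = m_step(tiny_data, spec, vs, idf.FitConfig(penalty_eta=1e9), params=params)
        assert (new.var_intercept == 0.0).all()

    def test_slope_update_maximizes_elbo(self, tiny_data):
        rng = np.random.default_rng(0)
        spec = idf.ModelSpec(variant="Ri", J=2, anchors=frozenset({1}))
        params = make_params(tiny_data.design, "Ri", rng)
        _, vs = _cold_start(tiny_data, spec, idf.FitConfig())
        vs = e_step(tiny_data, spec, params, vs)
        new = m_step(tiny_data, spec, vs, idf.FitConfig(), params=params)

        def neg(a0):
            p = new.copy()
            p.slope_base = p.slope_base.copy()
            p.slope_base[0] = a0
            return -elbo(tiny_data, spec, p, vs)

        res = minimize_scalar(neg, bounds=(-5, 5), method="bounded",
                              options={"xatol": 1e-10})
        assert new.slope_base[0] == pytest.approx(res.x, abs=1e-6)

    def test_anchor_main_effects_clamped(self, tiny_data):
        rng = np.random.default_rng(0)
        spec = idf.ModelSpec(variant="Ri", J=2, anchors=frozenset({1}))
        params = make_params(tiny_data.design, "Ri", rng)
        _, vs = _cold_start(tiny_data, spec, idf.FitConfig())
        vs = e_step(tiny_data, spec, params, vs)
        new = m_step(tiny_data, spec, vs, idf.FitConfig(), params=params)
        assert (new.intercept_main[1] == 0.0).all()


class TestFit:
    def test_trace_monotone_and_deterministic(self):
        des = idf.SimDesign(variant="I", groups=10, n_per_group=30, seed=5)
        data, _ = idf.simulate_dataset(des, 0)
        spec = des.model_spec()
        res1 = idf.fit(data, spec, idf.FitConfig(penalty_eta=2.0))
        res2 = idf.fit(data, spec, idf.FitConfig(penalty_eta=2.0))
        tr = res1.elbo_trace
        assert (np.diff(tr) >= -1e-8 * (np.abs(tr[:-1]) + 1.0)).all()
        assert np.array_equal(res1.elbo_trace, res2.elbo_trace)
        assert np.array_equal(res1.params.var_intercept, res2.params.var_intercept)

    def test_null_data_large_penalty_kills_all_variances(self):
        rng = np.random.default_rng(8)
        design = idf.build_group_design([2, 5])
        S, J, n = design.S, 10, 40
        params = idf.Parameters(
            intercept_base=rng.normal(0, 1, J),
            intercept_main=np.zeros((J, design.P)),
            slope_base=rng.uniform(1, 2, J),
            slope_main=np.zeros((J, design.P)),
            var_intercept=np.full(J, 1e-12),
            var_slope=np.zeros(J),
            impact_main=np.zeros(design.P),
        )
        g = np.repeat(np.arange(S), n)
        theta = rng.normal(size=S * n)
        B = params.intercept_prior_mean(design)
        prob = 1 / (1 + np.exp(-(params.slope_base[:, None] * theta[None, :]
                                 + B[:, g]))).T
        Y = (rng.uniform(size=prob.shape) < prob).astype(float)
        data = idf.ResponseData(Y=Y, group_of=g, design=design)
        spec = idf.ModelSpec(variant="Ri", J=J, anchors=frozenset({7, 8, 9}))
        res = idf.fit(data, spec, idf.FitConfig(penalty_eta=50.0))
        assert (res.params.var_intercept == 0.0).all()
        assert res.n_dif_parameters(spec) == 0

    def test_missing_responses_handled(self):
        des = idf.SimDesign(variant="I", groups=10, n_per_group=20, seed=5)
        data, _ = idf.simulate_dataset(des, 0)
        Y = data.Y.copy()
        rng = np.random.default_rng(0)
        Y[rng.uniform(size=Y.shape) < 0.1] = np.nan
        data = idf.ResponseData(Y=Y, group_of=data.group_of, design=data.design)
        res = idf.fit(data, des.model_spec(), idf.FitConfig(max_iters=50))
        assert np.isfinite(res.elbo_final)

    def test_elbo_nondecreasing_after_e_step(self, tiny_data):
        rng = np.random.default_rng(2)
        spec = idf.ModelSpec(variant="RiM", J=2, anchors=frozenset({1}))
        params = make_params(tiny_data.design, "RiM", rng)
        _, vs = _cold_start(tiny_data, spec, idf.FitConfig())
        before = elbo(tiny_data, spec, params, vs)
        after = elbo(tiny_data, spec, params, e_step(tiny_data, spec, params, vs))
        assert after >= before - 1e-10

    def test_elbo_invariant_to_person_permutation(self, tiny_data):
        rng = np.random.default_rng(2)
        spec = idf.ModelSpec(variant="Ri", J=2, anchors=frozenset({1}))
        params = make_params(tiny_data.design, "Ri", rng)
        _, vs = _cold_start(tiny_data, spec, idf.FitConfig())
        vs = e_step(tiny_data, spec, params, vs)
        base = elbo(tiny_data, spec, params, vs)
        perm = rng.permutation(tiny_data.N)
        data_p = idf.ResponseData(
            Y=tiny_data.Y[perm], group_of=tiny_data.group_of[perm],
            design=tiny_data.design,
        )
        vs_p = vs.copy()
        vs_p.theta_mean = vs.theta_mean[perm]
        vs_p.theta_var = vs.theta_var[perm]
        vs_p.xi = vs.xi[perm]
        assert elbo(data_p, spec, params, vs_p) == pytest.approx(base, abs=1e-9)
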