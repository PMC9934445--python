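"""Unit and property tests for the online plasticity model."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from mblda import (
    CompartmentState,
    ConfigError,
    DimensionError,
    LearningConfig,
    dan_step,
    homeostatic_step,
    learning_rate,
    mbon_output,
    run_online,
    step,
)
from mblda.online import _coerce_stream


def make_state(w, mu0=None, **kw):
    w = np.asarray(w, dtype=float)
    mu0 = np.zeros_like(w) if mu0 is None else np.asarray(mu0, dtype=float)
    return CompartmentState(w=w, mu0_hat=mu0, **kw)


class TestMbonOutput:
    @pytest.mark.parametrize(
        "w, b, x, c, z",
        [
            ([0.0, 0.0], 0.0, [3.0, -1.0], 0.0, 0.0),
            ([1.0, 0.0], 1.0, [2.0, 3.0], 2.0, 1.0),
            ([1.0, 1.0], 5.0, [1.0, 1.0], 2.0, 0.0),  # below threshold rectifies
        ],
    )
    def test_examples(self, w, b, x, c, z):
        out = mbon_output(make_state(w, b=b), x)
        assert out.c == c
        assert out.z == z

    def test_prediction_convention(self):
        # active MBON (z > 0) predicts "no unconditioned stimulus" (y = 0)
        assert mbon_output(make_state([1.0], b=0.0), [2.0]).predicted_label == 0
        assert mbon_output(make_state([1.0], b=5.0), [2.0]).predicted_label == 1

    def test_dimension_mismatch(self):
        with pytest.raises(DimensionError):
            mbon_output(make_state([1.0, 2.0]), [1.0, 2.0, 3.0])

    def test_does_not_mutate_state(self):
        st_ = make_state([1.0, 2.0], b=0.5)
        w_before = st_.w.copy()
        mbon_output(st_, [3.0, 4.0])
        assert np.array_equal(st_.w, w_before) and st_.b == 0.5


class TestHomeostaticStep:
    def test_first_sample_overwrites_mean(self):
        x = np.array([0.7, -1.2, 3.0])
        new = homeostatic_step(make_state(np.zeros(3)), x, eta=0.1)
        assert np.array_equal(new.mu0_hat, x)
        assert new.t == 1 and new.ell == 2

    def test_vanishing_covariance_term(self):
        # x equal to the current mean: the (c - zeta)(x - mu0) term drops out
        x = np.array([0.5, 2.0])
        state = make_state([1.0, -1.0], mu0=x, t=9, zeta_hat=0.3)
        new = homeostatic_step(state, x, eta=0.2)
        assert np.array_equal(new.mu0_hat, x)
        np.testing.assert_allclose(new.w - state.w, 0.2 * x, rtol=1e-14)

    def test_mean_drift_matches_mu0_minus_sigma_w(self, rng):
        """Monte-Carlo oracle: E[dw/eta] = mu0 - Sigma w at fixed w."""
        n = 3
        mu0 = np.array([1.0, -0.5, 0.3])
        A = rng.standard_normal((n, n))
        Sigma = A @ A.T / n + 0.5 * np.eye(n)
        L = np.linalg.cholesky(Sigma)
        w = np.array([0.4, 1.1, -0.7])
        # large t so the running statistics barely move within one step
        base = make_state(w, mu0=mu0, zeta_hat=float(w @ mu0), t=10**9)
        N = 100_000
        X = mu0 + rng.standard_normal((N, n)) @ L.T
        deltas = np.empty((N, n))
        for i in range(N):
            deltas[i] = homeostatic_step(base, X[i], eta=1.0).w - w
        target = mu0 - Sigma @ w
        se = deltas.std(axis=0) / np.sqrt(N)
        assert np.all(np.abs(deltas.mean(axis=0) - target) < 3 * se)

    def test_bias_tracks_half_c(self):
        state = make_state([2.0], b=1.0, t=3)
        x = np.array([1.5])
        new = homeostatic_step(state, x, eta=0.0)
        c = 3.0
        assert new.b == pytest.approx(1.0 + (0.5 * c - 1.0) / 4)


class TestDanStep:
    def test_unit_elapsed_time(self):
        # ell = 1: dw = -eta x exactly and the bias target is c/2 (log 1 = 0)
        x = np.array([2.0, 0.5])
        state = make_state([1.0, 1.0], b=0.4, t=4, ell=1)
        new = dan_step(state, x, eta=0.3)
        np.testing.assert_allclose(new.w - state.w, -0.3 * x, rtol=1e-14)
        c = 2.5
        assert new.b == pytest.approx(0.4 + (0.5 * c - 0.4) / 5)
        assert new.ell == 1 and new.t == 5

    @given(
        x=arrays(np.float64, 4, elements=st.floats(0, 50)),
        ell=st.integers(1, 100),
        b=st.floats(-10, 10),
    )
    def test_one_sided_depression(self, x, ell, b):
        """Nonnegative inputs are never potentiated by the DAN rule."""
        state = make_state([0.1, -0.2, 0.3, 0.0], b=b, ell=ell, t=7)
        new = dan_step(state, x, eta=0.05)
        assert np.all(new.w - state.w <= 0)

    @given(b1=st.floats(-20, 20), b2=st.floats(-20, 20), ell=st.integers(1, 50))
    def test_weight_update_independent_of_bias_and_output(self, b1, b2, ell):
        x = np.array([1.0, -2.0, 0.5])
        s1 = make_state([0.3, 0.1, -0.4], b=b1, ell=ell, t=3)
        s2 = make_state([0.3, 0.1, -0.4], b=b2, ell=ell, t=3)
        assert np.array_equal(dan_step(s1, x, 0.1).w, dan_step(s2, x, 0.1).w)

    def test_linearity_in_elapsed_time(self):
        x = np.array([1.0, 2.0])
        d1 = dan_step(make_state([0.0, 0.0], ell=1), x, 0.1).w
        d7 = dan_step(make_state([0.0, 0.0], ell=7), x, 0.1).w
        np.testing.assert_allclose(d7, 7 * d1, rtol=1e-14)

    def test_gated_mean_recovers_mu1(self, rng):
        """pi1 * <ell x | DAN event> converges to mu1 (3 SE)."""
        from mblda import GaussianStreamSpec, default_gaussian_stats, generate_gaussian_stream

        pi1 = 0.2
        spec = GaussianStreamSpec(stats=default_gaussian_stats(pi1), T=100_000, seed=5)
        X, Y = generate_gaussian_stream(spec)
        _, tr = run_online((X, Y))
        gated = tr.y[:, None] * tr.ell[:, None] * X  # zero off-events
        se = gated.std(axis=0) / np.sqrt(len(gated))
        np.testing.assert_array_less(np.abs(gated.mean(axis=0) - [-1.0, 0.0]), 3 * se)


class TestStepDispatch:
    def test_counter_semantics(self):
        cfg = LearningConfig()
        s0 = make_state([0.0, 0.0], ell=3, t=10)
        s_home, _ = step(s0, [1.0, 0.0], 0, cfg)
        assert s_home.ell == 4 and s_home.t == 11
        s_dan, _ = step(s0, [1.0, 0.0], 1, cfg)
        assert s_dan.ell == 1 and s_dan.t == 11

    def test_graded_reduces_to_standard_at_unit_label(self):
        x = [0.5, -1.0]
        s0 = make_state([1.0, 2.0], ell=5, t=2)
        std, _ = step(s0, x, 1, LearningConfig())
        graded, _ = step(s0, x, 1.0, LearningConfig(variant="graded_dan"))
        assert np.array_equal(std.w, graded.w) and std.b == graded.b

    def test_graded_scales_depression(self):
        x = np.array([1.0, 1.0])
        s0 = make_state([0.0, 0.0], ell=4, t=0)
        full, _ = step(s0, x, 1.0, LearningConfig(variant="graded_dan", gamma=0.0))
        half, _ = step(s0, x, 0.5, LearningConfig(variant="graded_dan", gamma=0.0))
        np.testing.assert_allclose(half.w, 0.5 * full.w, rtol=1e-14)

    def test_fixed_ell_substitutes_ell_star(self):
        x = np.array([1.0, 0.0])
        s0 = make_state([0.0, 0.0], ell=9, t=0)
        cfg = LearningConfig(variant="fixed_ell", ell_star=2.0, gamma=0.0, eta0=0.1)
        new, _ = step(s0, x, 1, cfg)
        np.testing.assert_allclose(new.w, [-0.2, 0.0], rtol=1e-14)

    def test_fixed_ell_bias_scope_flag(self):
        x = np.array([1.0, 0.0])
        s0 = make_state([1.0, 0.0], ell=9, t=0)
        both, _ = step(s0, x, 1, LearningConfig(variant="fixed_ell", ell_star=2.0))
        weights_only, _ = step(
            s0, x, 1, LearningConfig(variant="fixed_ell", ell_star=2.0, fixed_ell_bias=False)
        )
        assert np.array_equal(both.w, weights_only.w)
        assert both.b != weights_only.b  # bias recursion saw ell* vs true ell

    @pytest.mark.parametrize("y, variant", [(2, "standard"), (0.5, "standard"), (-1.0, "graded_dan")])
    def test_invalid_labels(self, y, variant):
        cfg = LearningConfig(variant=variant, ell_star=1.0 if variant == "fixed_ell" else None)
        with pytest.raises(ConfigError):
            step(make_state([0.0]), [1.0], y, cfg)


class TestLearningConfig:
    def test_invalid_parameters(self):
        with pytest.raises(ConfigError):
            LearningConfig(eta0=-1.0)
        with pytest.raises(ConfigError):
            LearningConfig(gamma=-0.1)
        with pytest.raises(ConfigError):
            LearningConfig(variant="fixed_ell")  # missing ell_star
        with pytest.raises(ConfigError):
            LearningConfig(variant="nope")

    def test_schedule(self):
        cfg = LearningConfig(eta0=0.5, gamma=0.0)
        assert learning_rate(1, cfg) == 0.5 == learning_rate(1000, cfg)
        cfg = LearningConfig(eta0=1.0, gamma=0.1)
        assert learning_rate(1, cfg) == pytest.approx(1.0 / 1.1)
        with pytest.raises(ConfigError):
            learning_rate(0, cfg)


class TestRunOnline:
    def test_pure_label0_stream_recovers_sample_mean(self, rng):
        X = rng.normal(size=(200, 3))
        state, _ = run_online((X, np.zeros(200)))
        np.testing.assert_allclose(state.mu0_hat, X.mean(axis=0), rtol=1e-10, atol=1e-12)

    def test_zero_learning_rate_freezes_weights(self, rng):
        X = rng.normal(size=(100, 2))
        Y = (rng.random(100) < 0.3).astype(float)
        init = make_state([0.7, -0.3])
        state, tr = run_online((X, Y), LearningConfig(eta0=0.0), init=init)
        assert np.array_equal(state.w, init.w)
        assert state.b != 0.0  # the threshold still evolves

    def test_matches_pure_python_reference(self, rng):
        """The compiled loop and the single-step reference agree exactly."""
        for cfg in (
            LearningConfig(),
            LearningConfig(variant="fixed_ell", ell_star=4.0),
            LearningConfig(variant="graded_dan"),
        ):
            X = rng.normal(size=(400, 3))
            Y = (rng.random(400) < 0.25).astype(float)
            if cfg.variant == "graded_dan":
                Y = Y * rng.random(400) * 2
            state_fast, trace = run_online((X, Y), cfg)
            state_ref = CompartmentState.zeros(3)
            for i in range(400):
                state_ref, out = step(state_ref, X[i], Y[i], cfg)
                assert out.c == trace.c[i] and out.z == trace.z[i]
            assert np.array_equal(state_ref.w, state_fast.w)
            assert np.array_equal(state_ref.mu0_hat, state_fast.mu0_hat)
            assert state_ref.b == state_fast.b and state_ref.zeta_hat == state_fast.zeta_hat
            assert state_ref.ell == state_fast.ell and state_ref.t == state_fast.t

    def test_bit_reproducible(self, rng):
        X = rng.normal(size=(300, 2))
        Y = (rng.random(300) < 0.2).astype(float)
        s1, t1 = run_online((X, Y))
        s2, t2 = run_online((X, Y))
        assert np.array_equal(s1.w, s2.w) and s1.b == s2.b
        assert np.array_equal(t1.z, t2.z) and np.array_equal(t1.eta, t2.eta)

    def test_accepts_iterable_of_pairs(self):
        pairs = [([1.0, 0.0], 0), ([0.0, 1.0], 1), ([1.0, 1.0], 0)]
        state, trace = run_online(pairs)
        assert state.t == 3 and len(trace) == 3

    def test_empty_stream_raises(self):
        with pytest.raises(ConfigError):
            run_online(([], []))

    def test_invalid_labels_rejected(self, rng):
        X = rng.normal(size=(10, 2))
        Y = np.zeros(10)
        Y[4] = 2.0
        with pytest.raises(ConfigError):
            run_online((X, Y))

    def test_trace_ell_invariants(self, rng):
        """ell >= 1 always; resets to 1 after each DAN event, else increments."""
        X = rng.normal(size=(500, 2))
        Y = (rng.random(500) < 0.3).astype(float)
        _, tr = run_online((X, Y))
        assert np.all(tr.ell >= 1)
        # value at step i+1 reflects the event at step i
        expected_next = np.where(Y[:-1] == 1, 1, tr.ell[:-1] + 1)
        assert np.array_equal(tr.ell[1:], expected_next)
        assert np.all(tr.z >= 0)

    def test_ell_mean_estimates_inverse_pi1(self):
        """<ell | DAN event> ~= 1/pi1 on Bernoulli label streams (3 SE)."""
        from mblda import GaussianStreamSpec, default_gaussian_stats, generate_gaussian_stream

        for pi1 in (0.1, 0.5):
            spec = GaussianStreamSpec(stats=default_gaussian_stats(pi1), T=100_000, seed=2)
            X, Y = generate_gaussian_stream(spec)
            _, tr = run_online((X, Y))
            ells = tr.ell[tr.y == 1]
            se = ells.std() / np.sqrt(len(ells))
            assert abs(ells.mean() - 1 / pi1) < 3 * se


class TestStateCheckpoint:
    def test_json_roundtrip_exact(self, rng, tmp_path):
        state = CompartmentState(
            w=rng.normal(size=5) * 1e-3,
            mu0_hat=rng.normal(size=5),
            b=-0.123456789123456789,
            zeta_hat=3.14159e-7,
            ell=17,
            t=420,
        )
        path = tmp_path / "state.json"
        state.save_json(path)
        loaded = CompartmentState.load_json(path)
        assert np.array_equal(loaded.w, state.w)
        assert np.array_equal(loaded.mu0_hat, state.mu0_hat)
        assert loaded.b == state.b and loaded.zeta_hat == state.zeta_hat
        assert loaded.ell == state.ell and loaded.t == state.t

    def test_invalid_state_rejected(self):
        with pytest.raises(ConfigError):
            make_state([1.0], ell=0)
        with pytest.raises(DimensionError):
            CompartmentState(w=np.zeros(3), mu0_hat=np.zeros(2))


def test_coerce_stream_pairs_and_arrays(rng):
    X = rng.normal(size=(5, 2))
    Y = np.array([0.0, 1.0, 0.0, 0.0, 1.0])
    X2, Y2 = _coerce_stream(list(zip(X, Y)))
    assert np.array_equal(X2, X) and np.array_equal(Y2, Y)
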