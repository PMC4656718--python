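"""Learning rules: ridge regression, backpropagation–decorrelation, and
the Oja/kWTA cortico-striatal rule."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from csntc.fixtures import make_fixture
from csntc.learning import (BPDCConfig, OjaConfig, RidgeProblem, bpdc_update,
                            kwta, oja_kwta_update, ridge_fit)


class TestRidge:
    def test_identity_design_recovers_targets(self, rng):
        Y = rng.normal(size=(6, 2))
        W = ridge_fit(RidgeProblem(X=np.eye(6), Y=Y, lam=0.0))
        np.testing.assert_allclose(W, Y.T, atol=1e-12)

    def test_shrinkage_monotone_in_lambda(self, rng):
        X = rng.normal(size=(30, 8))
        Y = rng.normal(size=(30, 3))
        norms = [np.linalg.norm(ridge_fit(RidgeProblem(X=X, Y=Y, lam=lam)))
                 for lam in (0.0, 0.5, 2.0, 10.0, 100.0)]
        assert all(a > b for a, b in zip(norms, norms[1:]))

    def test_training_error_nonincreasing_as_lambda_decreases(self, rng):
        X = rng.normal(size=(40, 10))
        Y = rng.normal(size=(40, 2))
        errs = []
        for lam in (10.0, 1.0, 0.1, 0.0):
            W = ridge_fit(RidgeProblem(X=X, Y=Y, lam=lam))
            errs.append(float(np.sum((X @ W.T - Y) ** 2)))
        assert all(a >= b - 1e-10 for a, b in zip(errs, errs[1:]))

    def test_matches_direct_normal_equations_solve(self):
        fx = make_fixture("ridge_small").payload
        W = ridge_fit(RidgeProblem(X=fx["X"], Y=fx["Y"], lam=fx["lam"]))
        np.testing.assert_allclose(W, fx["oracle_W_oz"], atol=1e-8)

    def test_singular_system_at_zero_lambda_names_lambda(self, rng):
        X = np.zeros((10, 4))  # rank-deficient
        Y = rng.normal(size=(10, 1))
        with pytest.raises(np.linalg.LinAlgError, match="lam"):
            ridge_fit(RidgeProblem(X=X, Y=Y, lam=0.0))

    def test_row_count_mismatch_rejected(self):
        with pytest.raises(ValueError):
            RidgeProblem(X=np.zeros((5, 2)), Y=np.zeros((4, 1)))


class TestBPDC:
    def test_zero_errors_give_zero_update(self, rng):
        cfg = BPDCConfig()
        dW = bpdc_update(np.zeros((2, 5)), rng.random(5), rng.random(3),
                         np.zeros(2), np.zeros(2), cfg)
        assert np.all(dW == 0)

    def test_zero_states_give_zero_update(self):
        cfg = BPDCConfig()
        dW = bpdc_update(np.zeros((2, 5)), np.zeros(5), np.zeros(3),
                         np.ones(2), np.ones(2), cfg)
        assert np.all(dW == 0)

    def test_scalar_hand_computation(self):
        # z=1, x=0, beta=1, dt=0.5, eta=1, e_t=1, e_{t+1}=0.2:
        # d = 1/(1+0+1) = 0.5; g = 0.5*1 - 0.2 = 0.3; dW = (1/0.5)*0.3*0.5
        cfg = BPDCConfig(eta=1.0, beta=1.0, dt=0.5)
        dW = bpdc_update(np.zeros((1, 1)), np.array([1.0]), np.array([0.0]),
                         np.array([1.0]), np.array([0.2]), cfg)
        assert dW[0, 0] == pytest.approx(0.3)

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            BPDCConfig(eta=0.0)
        with pytest.raises(ValueError):
            BPDCConfig(beta=-1.0)

    def test_online_training_reduces_error_across_sessions(self):
        """BPDC on the rhythmic loop task: running NRMSE falls over
        sessions (trend over windows, not per step)."""
        import dataclasses
        from csntc.cortex import ReservoirSpec
        from csntc.module import CSNTCModule
        from csntc.experiments import (Protocol, run_loop_experiment,
                                       standard_tasks)
        proto = dataclasses.replace(Protocol(seed=3), n_train_sessions=12)
        mod = CSNTCModule.build(ReservoirSpec(n_units=200, seed=7))
        res = run_loop_experiment(proto, mod, standard_tasks(proto),
                                  mode="online")
        hist = np.asarray(res.train_history)
        assert hist[-3:].mean() < 0.5 * hist[:3].mean()


class TestKWTA:
    def test_k_equal_length_is_identity(self, rng):
        v = rng.normal(size=7)
        np.testing.assert_array_equal(kwta(v, 7), v)

    def test_single_winner(self):
        np.testing.assert_array_equal(kwta(np.array([3.0, 1.0, 2.0]), 1),
                                      [3.0, 0.0, 0.0])

    def test_tie_broken_by_lowest_index(self):
        np.testing.assert_array_equal(kwta(np.array([2.0, 2.0, 1.0]), 1),
                                      [2.0, 0.0, 0.0])

    @pytest.mark.parametrize("k", [0, 5])
    def test_invalid_k_rejected(self, k):
        with pytest.raises(ValueError):
            kwta(np.zeros(4), k)

    @given(st.lists(st.floats(-10, 10), min_size=3, max_size=30),
           st.integers(1, 3))
    @settings(deadline=None)
    def test_survivors_keep_values_and_count(self, vs, k):
        v = np.asarray(vs)
        out = kwta(v, k)
        nz = np.nonzero(out)[0]
        assert len(nz) <= k
        assert np.all(out[nz] == v[nz])
        # every zeroed entry is <= every surviving entry
        if len(nz):
            assert v[out == 0].size == 0 or np.all(
                v[np.setdiff1d(np.arange(len(v)), nz)] <= out[nz].min() + 1e-12)


class TestOja:
    def test_silent_striatum_no_update(self):
        cfg = OjaConfig(noise_sigma=0.0)
        dW = oja_kwta_update(np.ones((2, 4)), np.zeros(2),
                             np.array([0.5, 0.1, 0.0, 0.3]), cfg)
        assert np.all(dW == 0)

    def test_algebraic_fixed_point(self):
        cfg = OjaConfig(k_striatum=1, k_cortex=2, noise_sigma=0.0)
        s = np.array([0.8, 0.0])
        c = np.array([0.5, 0.4, 0.0])
        W = np.zeros((2, 3))
        W[0] = kwta(c, 2) / 0.8  # s c^T == ((s*s)1^T) W on the winning row
        dW = oja_kwta_update(W, s, c, cfg)
        np.testing.assert_allclose(dW, 0.0, atol=1e-15)

    def test_single_winner_hand_update(self):
        cfg = OjaConfig(eta_sx=0.05, k_striatum=1, k_cortex=1,
                        noise_sigma=0.0)
        s = np.array([0.8, 0.0, 0.0])
        c = np.array([0.0, 1.0, 0.0])  # one-hot
        dW = oja_kwta_update(np.zeros((3, 3)), s, c, cfg)
        expected = np.zeros((3, 3))
        expected[0, 1] = 0.05 * 0.8
        np.testing.assert_allclose(dW, expected)

    def test_noise_is_seeded_and_reproducible(self):
        cfg = OjaConfig(noise_sigma=0.3)
        s, c = np.array([0.5, 0.2]), np.array([0.4, 0.1, 0.6])
        d1 = oja_kwta_update(np.zeros((2, 3)), s, c, cfg,
                             rng=np.random.default_rng(9))
        d2 = oja_kwta_update(np.zeros((2, 3)), s, c, cfg,
                             rng=np.random.default_rng(9))
        np.testing.assert_array_equal(d1, d2)

    def test_weights_bounded_over_many_iterations(self, rng):
        """Oja self-normalization: stationary winner statistics keep row
        norms bounded over 10^4 updates."""
        cfg = OjaConfig(eta_sx=0.1, k_striatum=1, k_cortex=5,
                        noise_sigma=0.05)
        W = np.zeros((3, 12))
        for _ in range(10_000):
            s = np.abs(rng.normal(0.5, 0.2, 3))
            c = np.abs(rng.normal(0.4, 0.2, 12))
            W += oja_kwta_update(W, s, c, cfg, rng=rng)
            assert np.isfinite(W).all()
        norms = np.linalg.norm(W, axis=1)
        # fixed-point scale is |kwta(c,5)| / s ~ 2; bounded well below 10
        assert np.all(norms < 10.0)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            oja_kwta_update(np.zeros((2, 3)), np.zeros(3), np.zeros(3),
                            OjaConfig())
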