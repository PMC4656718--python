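"""Reservoir construction, normalization, partition and read-out."""

import numpy as np
import pytest

from csntc.cortex import (Readout, ReservoirSpec, build_reservoir, read_out,
                          step_cortex)
from csntc.dynamics import LayerParams, LayerState


class TestBuildReservoir:
    def test_seeded_determinism(self):
        spec = ReservoirSpec(n_units=80, seed=5)
        w1, w2 = build_reservoir(spec), build_reservoir(spec)
        np.testing.assert_array_equal(w1.W_u, w2.W_u)
        np.testing.assert_array_equal(w1.W_ux, w2.W_ux)

    @pytest.mark.parametrize("radius", [0.91, 0.95, 0.99])
    def test_effective_spectral_radius_normalized(self, radius):
        spec = ReservoirSpec(n_units=100, seed=3,
                             effective_spectral_radius=radius)
        w = build_reservoir(spec)
        measured = np.max(np.abs(np.linalg.eigvals(w.effective_matrix())))
        assert measured == pytest.approx(radius, abs=1e-6)

    def test_unreachable_radius_rejected(self):
        with pytest.raises(ValueError, match="1 - leak"):
            ReservoirSpec(effective_spectral_radius=0.8, leak=0.1)

    def test_partition_disjoint_and_equal_subpopulations(self, small_reservoir):
        w = small_reservoir
        loop = set(w.loop_idx.ravel().tolist())
        inp = set(w.input_idx.tolist())
        free = set(w.free_idx.tolist())
        assert loop.isdisjoint(inp) and loop.isdisjoint(free)
        assert inp.isdisjoint(free)
        assert len(loop | inp | free) == w.spec.n_units
        sizes = {len(row) for row in w.loop_idx}
        assert len(sizes) == 1  # equal sub-populations

    def test_input_rows_zero_outside_input_partition(self, small_reservoir):
        w = small_reservoir
        outside = np.setdiff1d(np.arange(w.spec.n_units), w.input_idx)
        assert np.all(w.W_ux[outside] == 0)
        assert np.any(w.W_ux[w.input_idx] != 0)

    def test_asymmetrization_changes_matrix_but_not_radius(self):
        base = ReservoirSpec(n_units=60, seed=9, asymmetrize=False)
        asym = ReservoirSpec(n_units=60, seed=9, asymmetrize=True)
        w0, w1 = build_reservoir(base), build_reservoir(asym)
        assert not np.allclose(w0.W_u, w1.W_u)
        for w in (w0, w1):
            rho = np.max(np.abs(np.linalg.eigvals(w.effective_matrix())))
            assert rho == pytest.approx(base.effective_spectral_radius,
                                        abs=1e-6)


def _free_run(weights, state, params, steps, x=None, thal=None):
    x = np.zeros(weights.spec.n_inputs) if x is None else x
    thal = np.zeros(weights.spec.n_channels) if thal is None else thal
    for _ in range(steps):
        state = step_cortex(weights, state, x, thal, params)
    return state


class TestStepCortex:
    def test_rest_is_fixed_point(self, small_reservoir, layer_params):
        state = LayerState.zeros(60, layer_params)
        out = _free_run(small_reservoir, state, layer_params, 20)
        assert np.all(out.u == 0) and np.all(out.z == 0)

    def test_echo_state_fading_from_driven_state(self, small_reservoir,
                                                 layer_params):
        state = LayerState.zeros(60, layer_params)
        for t in range(600):
            x = np.array([np.sin(2 * np.pi * t / 300.0), 0.4])
            state = step_cortex(small_reservoir, state, x,
                                np.zeros(3), layer_params)
        horizon = int(50 * layer_params.tau)
        for t in range(horizon):
            state = _free_run(small_reservoir, state, layer_params, 1)
            if np.max(np.abs(state.z)) < 1e-3:
                break
        assert np.max(np.abs(state.z)) < 1e-3

    def test_identical_inputs_give_identical_states(self, small_reservoir,
                                                    layer_params, rng):
        xs = rng.uniform(-1, 1, (100, 2))
        s1 = LayerState.zeros(60, layer_params)
        s2 = LayerState.zeros(60, layer_params)
        for x in xs:
            s1 = step_cortex(small_reservoir, s1, x, np.zeros(3), layer_params)
            s2 = step_cortex(small_reservoir, s2, x, np.zeros(3), layer_params)
        np.testing.assert_array_equal(s1.u, s2.u)

    def test_thalamic_drive_raises_target_subpopulation(self, small_reservoir,
                                                        layer_params):
        state = LayerState.zeros(60, layer_params)
        thal = np.array([0.0, 0.8, 0.0])
        state = _free_run(small_reservoir, state, layer_params, 300, thal=thal)
        pooled = small_reservoir.pool @ state.z
        assert pooled[1] > pooled[0] and pooled[1] > pooled[2]

    def test_dimension_mismatch_raises(self, small_reservoir, layer_params):
        state = LayerState.zeros(60, layer_params)
        with pytest.raises(ValueError):
            step_cortex(small_reservoir, state, np.zeros(5), np.zeros(3),
                        layer_params)
        with pytest.raises(ValueError):
            step_cortex(small_reservoir, state, np.zeros(2), np.zeros(7),
                        layer_params)


class TestReadout:
    def test_zero_weights_zero_output(self, rng):
        ro = Readout(W_oz=np.zeros((3, 10)))
        assert np.all(read_out(ro, rng.random(10)) == 0)

    def test_selector_copies_entries(self, rng):
        W = np.zeros((2, 6))
        W[0, 4] = 1.0
        W[1, 1] = 1.0
        z = rng.random(6)
        np.testing.assert_allclose(read_out(Readout(W_oz=W), z), z[[4, 1]])

    def test_linear_map_matches_elementwise_sum_oracle(self, rng):
        W = rng.normal(size=(4, 9))
        z = rng.random(9)
        oracle = np.array([sum(W[i, j] * z[j] for j in range(9))
                           for i in range(4)])
        np.testing.assert_allclose(read_out(Readout(W_oz=W), z), oracle,
                                   rtol=1e-12)

    def test_online_dynamic_readout_integrates_toward_drive(self, rng):
        W = rng.normal(size=(2, 5)) * 0.1
        ro = Readout(W_oz=W, mode="online-dynamic",
                     params=LayerParams(th=-10.0, alpha=1.0))
        z = rng.random(5)
        drive = W @ z
        for _ in range(500):
            o = read_out(ro, z)
        np.testing.assert_allclose(ro.state.u, drive, atol=1e-9)

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError):
            Readout(W_oz=np.zeros((1, 2)), mode="nonsense")
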