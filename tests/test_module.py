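"""The composed CSNTC module: closed-loop selection, lock-in/unlock,
lesions, snapshots, and consistency of the fused step with the layer ops."""

import numpy as np
import pytest

from csntc.basal_ganglia import gpi_to_thalamic_gate, step_bg
from csntc.cortex import ReservoirSpec, step_cortex
from csntc.dynamics import step_layer
from csntc.fixtures import make_fixture, run_scripted_schedule, selection_events
from csntc.module import (CSNTCModule, LesionSpec, lesion, load_module,
                          save_module, step_module)


@pytest.fixture
def module():
    return CSNTCModule.build(ReservoirSpec(n_units=90, seed=21))


def _reference_step(mod, x_cortex, x_striatum, da, dt=1.0):
    """Composition of the public layer operations (the module step's
    specification): synchronous update from pre-step rates."""
    c_pool = mod.weights.pool @ mod.cortex.z
    x_str = np.asarray(x_striatum, dtype=float)
    if mod.W_sx is not None:
        x_str = mod.W_sx @ x_str
    new_cortex = step_cortex(mod.weights, mod.cortex, x_cortex,
                             mod.wiring.w_thal_cortex * mod.thalamus.z,
                             mod.cortex_params, dt)
    new_bg = step_bg(mod.bg, c_pool, x_str, da, mod.bg_params, dt)
    thal_drive = (mod.wiring.w_cortex_thal * c_pool
                  + gpi_to_thalamic_gate(mod.bg.gpi.z, mod.bg_params)
                  + mod.wiring.thal_tonic)
    new_thal = step_layer(mod.thalamus, thal_drive, mod.thal_params, dt)
    return new_cortex, new_bg, new_thal


class TestStepModule:
    def test_rest_state_is_preserved_without_input(self, module):
        for _ in range(50):
            step_module(module, np.zeros(1), np.zeros(3), 0.0)
        assert np.all(module.cortex.z == 0)
        assert np.all(module.thalamus.z == 0)

    def test_step_equals_composition_of_layer_operations(self, module, rng):
        # drive the module into a non-trivial state first
        for t in range(200):
            step_module(module, np.array([np.sin(t / 40)]),
                        np.array([0.5, 0.0, 0.0]), 1.0)
        for _ in range(20):
            x = rng.uniform(-1, 1, 1)
            xs = rng.uniform(0, 0.5, 3)
            da = float(rng.choice([0.0, 1.0]))
            ref_ctx, ref_bg, ref_tha = _reference_step(module, x, xs, da)
            step_module(module, x, xs, da)
            np.testing.assert_allclose(module.cortex.u, ref_ctx.u, rtol=1e-12)
            np.testing.assert_allclose(module.thalamus.u, ref_tha.u,
                                       rtol=1e-12)
            for layer in ("strD1", "strD2", "stn", "gpe", "gpi"):
                np.testing.assert_allclose(
                    getattr(module.bg, layer).u,
                    getattr(ref_bg, layer).u, rtol=1e-12)

    def test_low_dopamine_keeps_all_subpopulations_down(self, module):
        for t in range(900):
            x = np.array([np.sin(2 * np.pi * t / 300)])
            step_module(module, x, np.array([0.5, 0, 0]), 0.0)
        assert np.all(module.pooled_cortex() < 0.15)
        assert np.all(module.thalamus.z < 1e-6)

    def test_biased_channel_switches_to_up_state_under_dopamine(self, module):
        for t in range(900):
            x = np.array([np.sin(2 * np.pi * t / 300)])
            step_module(module, x, np.array([0, 0.5, 0]), 1.0)
        pooled = module.pooled_cortex()
        assert pooled[1] > 0.3
        assert pooled[1] > pooled[0] and pooled[1] > pooled[2]
        assert module.bg.gpi.z.argmin() == 1

    def test_selection_event_sequence_on_scripted_schedule(self, module):
        fx = make_fixture("selection_schedule")
        traces = run_scripted_schedule(module, fx.payload)
        ev = selection_events(traces, fx.payload)
        times = fx.payload["times"]
        # ordered: StrD1 rise, then selective GPi dip, after dopamine onset
        assert times["da_on"] <= ev["strD1_rise"] <= ev["gpi_dip"]
        # lock-in persists >= 500 ms beyond input offset
        assert ev["lock_in_until"] - times["input_off"] >= 500
        # unlock within 500 ms of dopamine offset
        assert 0 <= ev["unlock"] - times["da_off"] <= 500

    def test_no_selection_without_cortical_background(self, module):
        fx = make_fixture("selection_schedule")
        payload = dict(fx.payload, sin_amp=0.0)
        traces = run_scripted_schedule(module, payload)
        assert np.all(traces["tha"] < 1e-6)
        assert np.all(traces["ctx"] < 1e-6)

    def test_channel_segregation_under_symmetric_input(self, module):
        # silencing channel 2's cortico-striatal pooling must not break the
        # symmetry of the other channels' (non-)selection
        module.weights.pool[2, :] = 0.0
        for t in range(600):
            x = np.array([np.sin(2 * np.pi * t / 300)])
            step_module(module, x, np.zeros(3), 1.0)
        gpi = module.bg.gpi.z
        assert abs(gpi[0] - gpi[1]) < 1e-9


class TestLesion:
    def test_empty_spec_changes_nothing(self, module):
        w_before = module.wiring.w_thal_cortex
        lesion(module, LesionSpec())
        assert module.wiring.w_thal_cortex == w_before
        assert module.frozen == set()

    def test_unknown_bundle_raises(self, module):
        with pytest.raises(KeyError):
            lesion(module, LesionSpec(bundles=("no_such_bundle",)))

    def test_striatal_input_lesion_zeroes_exactly_that_matrix(self):
        mod = CSNTCModule.build(ReservoirSpec(n_units=60, seed=3),
                                W_sx=np.ones((3, 4)))
        W_u_before = mod.weights.W_u.copy()
        lesion(mod, LesionSpec(bundles=("striatal_input",)))
        assert np.all(mod.W_sx == 0)
        np.testing.assert_array_equal(mod.weights.W_u, W_u_before)
        assert "striatal_input" in mod.frozen


class TestSnapshot:
    def test_save_load_roundtrip_preserves_dynamics(self, module, tmp_path):
        for t in range(300):
            step_module(module, np.array([np.sin(t / 50)]),
                        np.array([0.5, 0, 0]), 1.0)
        path = str(tmp_path / "snap")
        save_module(module, path)
        clone = load_module(path)
        np.testing.assert_array_equal(clone.weights.W_u, module.weights.W_u)
        np.testing.assert_array_equal(clone.cortex.u, module.cortex.u)
        # identical continued trajectories
        for t in range(100):
            x = np.array([np.sin(t / 30)])
            step_module(module, x, np.zeros(3), 1.0)
            step_module(clone, x, np.zeros(3), 1.0)
        np.testing.assert_array_equal(clone.cortex.u, module.cortex.u)
        np.testing.assert_array_equal(clone.bg.gpi.u, module.bg.gpi.u)
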