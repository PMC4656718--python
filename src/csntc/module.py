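"""A CSNTC module: one cortical reservoir in loop with a C-channel basal
ganglia circuit through C thalamic units.

Wiring of the closed loop, per channel *k*:

* the pooled (mean) rate of cortical loop sub-population *k* drives the
  striatal and STN units of basal ganglia channel *k*;
* GPi channel *k* inhibits thalamic unit *k*;
* thalamic unit *k* excites every unit of cortical sub-population *k*.

The thalamic units follow the same leaky rate dynamics as everything else,
with drive = ``w_cortex_thal * pooled_cortex - w_gpi_tha * z_gpi +
thal_tonic``. The tonic bias is small: a disinhibited thalamic unit only
ignites when its cortical sub-population shows background activity, so
there is no selection without cortical input.

One call to :func:`step_module` advances cortex, basal ganglia and thalamus
by one synchronous Euler step, with every drive computed from pre-step
rates.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .basal_ganglia import BGParams, BGState
from .cortex import ReservoirSpec, ReservoirWeights, build_reservoir
from .dynamics import LayerParams, LayerState, step_layer, transfer

__all__ = ["ModuleWiring", "CSNTCModule", "LesionSpec", "step_module", "lesion",
           "save_module", "load_module"]


@dataclass
class ModuleWiring:
    """Gains of the thalamo-cortical limb of the loop."""

    w_cortex_thal: float = 1.0   # pooled cortical rate -> thalamic unit
    w_thal_cortex: float = 1.3   # thalamic rate -> each unit of the sub-population
    thal_tonic: float = 0.1      # small tonic thalamic bias


@dataclass
class CSNTCModule:
    """State and parameters of one cortex + basal ganglia + thalamus loop.

    ``W_sx`` (n_channels x n_external) maps the external striatal input to
    channels; ``None`` means the input is already per-channel and enters
    one-to-one. ``frozen`` lists lesioned weight bundles excluded from any
    learning.
    """

    weights: ReservoirWeights
    cortex: LayerState
    cortex_params: LayerParams
    bg: BGState
    bg_params: BGParams
    thalamus: LayerState
    thal_params: LayerParams
    wiring: ModuleWiring
    W_sx: np.ndarray | None = None
    frozen: set = field(default_factory=set)

    @classmethod
    def build(
        cls,
        spec: ReservoirSpec,
        bg_params: BGParams | None = None,
        wiring: ModuleWiring | None = None,
        cortex_params: LayerParams | None = None,
        W_sx: np.ndarray | None = None,
    ) -> "CSNTCModule":
        """Construct a module at the silent rest state (all potentials 0)."""
        bg_params = bg_params or BGParams()
        cortex_params = cortex_params or LayerParams()
        weights = build_reservoir(spec)
        C = spec.n_channels
        return cls(
            weights=weights,
            cortex=LayerState.zeros(spec.n_units, cortex_params),
            cortex_params=cortex_params,
            bg=BGState.zeros(C, bg_params),
            bg_params=bg_params,
            thalamus=LayerState.zeros(C, bg_params.layer),
            thal_params=bg_params.layer,
            wiring=wiring or ModuleWiring(),
            W_sx=W_sx,
        )

    @property
    def n_channels(self) -> int:
        return self.weights.spec.n_channels

    def pooled_cortex(self) -> np.ndarray:
        """Mean rate of each cortical loop sub-population (length C)."""
        return self.weights.pool @ self.cortex.z

    def lesion_bundle(self, name: str) -> None:
        if name == "thalamocortical":
            self.wiring.w_thal_cortex = 0.0
        elif name == "striatal_input":
            if self.W_sx is not None:
                self.W_sx[...] = 0.0
        else:
            raise KeyError(f"unknown lesion bundle {name!r} for a CSNTC module")
        self.frozen.add(name)


def step_module(
    mod: CSNTCModule,
    x_cortex: np.ndarray,
    x_striatum: np.ndarray,
    da: float,
    dt: float = 1.0,
    striatal_noise: np.ndarray | None = None,
) -> CSNTCModule:
    """One synchronous step of the whole loop (mutates ``mod`` in place).

    ``x_cortex`` is the external cortical input (length ``n_inputs``),
    ``x_striatum`` the external striatal input (per-channel, or mapped by
    ``mod.W_sx``), ``da`` the current dopamine level. ``striatal_noise``,
    when given (length C), is added to both striatal drives — used only
    during the unsupervised cortico-striatal learning phase to randomise
    early selection.
    """
    # This is the model's innermost loop, so the layer updates are inlined
    # rather than routed through step_cortex/step_bg/step_layer; a test
    # asserts that one call here equals the composition of those
    # operations. All drives below use pre-step rates (synchronous update).
    w, wiring = mod.weights, mod.wiring
    cp, bp = mod.cortex_params, mod.bg_params
    lp = mod.thal_params
    bg = mod.bg
    z_ctx = mod.cortex.z
    c_pool = w.pool @ z_ctx

    x_str = np.asarray(x_striatum, dtype=float)
    if mod.W_sx is not None:
        x_str = mod.W_sx @ x_str
    if striatal_noise is not None:
        x_str = x_str + striatal_noise

    if not 0 < dt < min(cp.tau, lp.tau):
        raise ValueError(f"dt={dt} must satisfy 0 < dt < tau")

    # cortex: recurrent + external input + thalamic broadcast
    drive_ctx = (w.W_u @ z_ctx + w.W_ux @ np.asarray(x_cortex, dtype=float)
                 + w.broadcast @ (wiring.w_thal_cortex * mod.thalamus.z))
    u_ctx = mod.cortex.u + (dt / cp.tau) * (drive_ctx - mod.cortex.u)
    if not np.isfinite(u_ctx.sum()):
        raise FloatingPointError("non-finite potentials: dynamics blew up")
    z_new = np.tanh(cp.alpha * (u_ctx - cp.th))
    mod.cortex = LayerState(u_ctx, np.maximum(z_new, 0.0, out=z_new))

    # basal ganglia drives (cf. basal_ganglia.bg_drives) + thalamic drive,
    # stepped as one stacked array (all six layers share LayerParams)
    s_in = bp.w_ctx_str * c_pool + x_str
    stn_sum = bg.stn.z.sum()
    d_all = np.stack([
        (bp.bl_D1 + bp.da_gain_D1 * da) * s_in,
        s_in / (bp.bl_D2 + bp.da_gain_D2 * da),
        bp.w_ctx_stn * c_pool - bp.w_gpe_stn * bg.gpe.z,
        bp.w_stn_gpe * stn_sum - bp.w_str_gpe * bg.strD2.z,
        bp.gpi_baseline + bp.w_stn_gpi * stn_sum
        - bp.w_str_gpi * bg.strD1.z - bp.w_gpe_gpi * bg.gpe.z,
        wiring.w_cortex_thal * c_pool - bp.w_gpi_tha * bg.gpi.z
        + wiring.thal_tonic,
    ])
    if lp == bp.layer:
        u_all = np.stack([bg.strD1.u, bg.strD2.u, bg.stn.u, bg.gpe.u,
                          bg.gpi.u, mod.thalamus.u])
        u2 = u_all + (dt / lp.tau) * (d_all - u_all)
        z2 = np.tanh(lp.alpha * (u2 - lp.th))
        np.maximum(z2, 0.0, out=z2)
        mod.thalamus = LayerState(u2[5], z2[5])
    else:  # distinct thalamic parameters: step the thalamus on its own
        u_all = np.stack([bg.strD1.u, bg.strD2.u, bg.stn.u, bg.gpe.u,
                          bg.gpi.u])
        u2 = u_all + (dt / bp.layer.tau) * (d_all[:5] - u_all)
        z2 = transfer(u2, bp.layer)
        mod.thalamus = step_layer(mod.thalamus, d_all[5], lp, dt)
    mod.bg = BGState(
        strD1=LayerState(u2[0], z2[0]),
        strD2=LayerState(u2[1], z2[1]),
        stn=LayerState(u2[2], z2[2]),
        gpe=LayerState(u2[3], z2[3]),
        gpi=LayerState(u2[4], z2[4]),
        da=da,
    )
    return mod


@dataclass(frozen=True)
class LesionSpec:
    """Named weight bundles to zero and freeze before any learning."""

    bundles: tuple = ()


def lesion(target, spec: LesionSpec):
    """Zero and freeze the weight bundles named in ``spec``.

    ``target`` is a :class:`CSNTCModule` or any object exposing
    ``lesion_bundle(name)`` (e.g. the two-module system). An empty spec
    leaves the target unchanged. Unknown bundle names raise ``KeyError``.
    """
    for name in spec.bundles:
        target.lesion_bundle(name)
    return target


def save_module(mod: CSNTCModule, path: str) -> None:
    """Serialize a module snapshot: arrays to ``<path>.npz`` and the
    construction spec to a JSON sidecar ``<path>.json``."""
    arrays = {
        "W_u": mod.weights.W_u, "W_ux": mod.weights.W_ux,
        "cortex_u": mod.cortex.u, "thal_u": mod.thalamus.u,
        "strD1_u": mod.bg.strD1.u, "strD2_u": mod.bg.strD2.u,
        "stn_u": mod.bg.stn.u, "gpe_u": mod.bg.gpe.u, "gpi_u": mod.bg.gpi.u,
    }
    if mod.W_sx is not None:
        arrays["W_sx"] = mod.W_sx
    np.savez(path + ".npz", **arrays)
    meta = {
        "spec": asdict(mod.weights.spec),
        "bg_params": {k: v for k, v in asdict(mod.bg_params).items()},
        "cortex_params": asdict(mod.cortex_params),
        "wiring": asdict(mod.wiring),
        "da": mod.bg.da,
        "frozen": sorted(mod.frozen),
    }
    with open(path + ".json", "w") as fh:
        json.dump(meta, fh, indent=2)


def load_module(path: str) -> CSNTCModule:
    """Rebuild a module from a snapshot written by :func:`save_module`."""
    with open(path + ".json") as fh:
        meta = json.load(fh)
    dat = np.load(path + ".npz")
    spec = ReservoirSpec(**meta["spec"])
    layer = LayerParams(**meta["bg_params"].pop("layer"))
    bg_params = BGParams(layer=layer, **meta["bg_params"])
    cortex_params = LayerParams(**meta["cortex_params"])
    mod = CSNTCModule.build(
        spec, bg_params=bg_params, wiring=ModuleWiring(**meta["wiring"]),
        cortex_params=cortex_params,
        W_sx=dat["W_sx"].copy() if "W_sx" in dat else None,
    )
    mod.weights.W_u = dat["W_u"].copy()
    mod.weights.W_ux = dat["W_ux"].copy()
    from .dynamics import transfer

    def _restore(u, params):
        return LayerState(u=u.copy(), z=transfer(u, params))

    mod.cortex = _restore(dat["cortex_u"], cortex_params)
    mod.thalamus = _restore(dat["thal_u"], layer)
    mod.bg = BGState(
        strD1=_restore(dat["strD1_u"], layer),
        strD2=_restore(dat["strD2_u"], layer),
        stn=_restore(dat["stn_u"], layer),
        gpe=_restore(dat["gpe_u"], layer),
        gpi=_restore(dat["gpi_u"], layer),
        da=meta["da"],
    )
    mod.frozen = set(meta["frozen"])
    return mod
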