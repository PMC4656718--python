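"""Basal ganglia selection circuit: C parallel channels competing by
disinhibition, after the Gurney–Prescott–Redgrave architecture.

Five layers of C leaky rate units each (:mod:`csntc.dynamics`):

* **StrD1** — striatal units expressing D1 receptors (direct pathway);
  dopamine *multiplies* their input drive.
* **StrD2** — striatal units expressing D2 receptors (indirect pathway);
  dopamine *divides* their input drive.
* **STN** — subthalamic nucleus (hyperdirect pathway); its efferents are
  the only diffuse (all-to-all) projection, exciting every unit of both
  pallidal layers.
* **GPe** — external pallidum; inhibits STN and GPi channel-wise.
* **GPi** — the merged GPi/SNpr output stage; tonically active, and
  selectively silenced on the channel whose striatal drive wins. Low GPi
  on a channel releases ("disinhibits") the corresponding thalamic unit.

All other projections are one-to-one between topographically corresponding
channel units. Cortical input ``c`` (the pooled rate of each channel's
cortical loop sub-population) reaches StrD1, StrD2 and STN; external input
``x`` reaches the striatum only, since out-of-loop cortical afferents to
the STN have little anatomical support.

Updates are synchronous: all drives are computed from pre-step rates, then
every layer takes one Euler step, so results do not depend on layer order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dynamics import LayerParams, LayerState, transfer

__all__ = [
    "BGParams",
    "BGState",
    "striatal_drive_D1",
    "striatal_drive_D2",
    "step_bg",
    "gpi_to_thalamic_gate",
]


@dataclass(frozen=True)
class BGParams:
    """Gains and dopamine parameters of the selection circuit.

    ``bl_*`` terms are baseline responsiveness (dopamine-independent);
    ``da_gain_*`` scale the dopamine-dependent part. The D1 drive gain is
    ``bl_D1 + da_gain_D1 * da`` (multiplicative excitation); the D2 drive
    is divided by ``bl_D2 + da_gain_D2 * da`` (multiplicative inhibition),
    so ``bl_D2`` must be positive. Inter-layer weights are non-negative
    magnitudes; signs (inhibitory vs excitatory) are fixed by the wiring.
    None of these values is anatomically measured; they are set so that the
    circuit shows no selection under symmetric input, locks in a channel
    with a modest input advantage under high dopamine, and releases it when
    dopamine falls (see the tuning notes in docs/methods.md).
    """

    bl_D1: float = 0.1
    da_gain_D1: float = 0.9
    bl_D2: float = 0.7
    da_gain_D2: float = 2.3
    w_ctx_str: float = 1.0      # pooled cortex -> StrD1/StrD2, per channel
    w_ctx_stn: float = 0.7      # pooled cortex -> STN, per channel
    w_str_gpi: float = 1.2      # StrD1 -| GPi (inhibitory, one-to-one)
    w_str_gpe: float = 1.0      # StrD2 -| GPe (inhibitory, one-to-one)
    w_stn_gpi: float = 1.0      # STN -> GPi (excitatory, all-to-all)
    w_stn_gpe: float = 0.8      # STN -> GPe (excitatory, all-to-all)
    w_gpe_stn: float = 1.0      # GPe -| STN (inhibitory, one-to-one)
    w_gpe_gpi: float = 0.1      # GPe -| GPi (inhibitory, one-to-one)
    w_gpi_tha: float = 1.0      # GPi -| thalamus gate gain
    gpi_baseline: float = 0.4   # tonic GPi drive (keeps the gate closed at rest)
    layer: LayerParams = field(default_factory=LayerParams)

    def __post_init__(self) -> None:
        if not self.bl_D1 > 0 or not self.bl_D2 > 0:
            raise ValueError("baseline dopamine terms bl_D1, bl_D2 must be positive")
        for name in ("w_ctx_str", "w_ctx_stn", "w_str_gpi", "w_str_gpe",
                     "w_stn_gpi", "w_stn_gpe", "w_gpe_stn", "w_gpe_gpi",
                     "w_gpi_tha"):
            if getattr(self, name) < 0:
                raise ValueError(f"gain magnitude {name} must be >= 0")


@dataclass
class BGState:
    """Layer states of a C-channel circuit plus the current dopamine level."""

    strD1: LayerState
    strD2: LayerState
    stn: LayerState
    gpe: LayerState
    gpi: LayerState
    da: float = 0.0

    @classmethod
    def zeros(cls, n_channels: int, params: BGParams | None = None,
              da: float = 0.0) -> "BGState":
        lp = (params or BGParams()).layer
        mk = lambda: LayerState.zeros(n_channels, lp)
        return cls(strD1=mk(), strD2=mk(), stn=mk(), gpe=mk(), gpi=mk(), da=da)

    @property
    def n_channels(self) -> int:
        return len(self.gpi.u)

    def copy(self) -> "BGState":
        return BGState(
            strD1=self.strD1.copy(), strD2=self.strD2.copy(),
            stn=self.stn.copy(), gpe=self.gpe.copy(), gpi=self.gpi.copy(),
            da=self.da,
        )


def _striatal_input(c, x, params: BGParams, W_sc=None, W_sx=None) -> np.ndarray:
    c = np.asarray(c, dtype=float)
    x = np.asarray(x, dtype=float)
    sc = (W_sc @ c) if W_sc is not None else params.w_ctx_str * c
    sx = (W_sx @ x) if W_sx is not None else x
    return sc + sx


def striatal_drive_D1(c, x, da: float, params: BGParams,
                      W_sc=None, W_sx=None) -> np.ndarray:
    """Drive to the D1 striatal units: dopamine multiplies the input.

    ``(bl_D1 + da_gain_D1 * da) * (W_sc c + W_sx x)``. When the weight
    matrices are omitted, cortex enters channel-wise with gain
    ``w_ctx_str`` and ``x`` enters one-to-one with unit gain.
    """
    if da < 0:
        raise ValueError("dopamine level must be non-negative")
    return (params.bl_D1 + params.da_gain_D1 * da) * _striatal_input(
        c, x, params, W_sc, W_sx)


def striatal_drive_D2(c, x, da: float, params: BGParams,
                      W_sc=None, W_sx=None) -> np.ndarray:
    """Drive to the D2 striatal units: dopamine divides the input.

    ``(W_sc c + W_sx x) / (bl_D2 + da_gain_D2 * da)``; the divisor must be
    positive (guaranteed for non-negative da when bl_D2 > 0).
    """
    divisor = params.bl_D2 + params.da_gain_D2 * da
    if not divisor > 0:
        raise ValueError(
            f"D2 divisor bl_D2 + da_gain_D2*da = {divisor} must be positive"
        )
    return _striatal_input(c, x, params, W_sc, W_sx) / divisor


def bg_drives(state: BGState, c, x, da: float, params: BGParams,
              W_sc=None, W_sx=None) -> dict:
    """Per-layer drives from pre-step rates (the ODE right-hand sides,
    before the leak term). Shared by the stepping routine and by the
    fixed-point oracle used in tests."""
    z_d1, z_d2 = state.strD1.z, state.strD2.z
    z_stn, z_gpe = state.stn.z, state.gpe.z
    c = np.asarray(c, dtype=float)
    stn_sum = float(np.sum(z_stn))
    return {
        "strD1": striatal_drive_D1(c, x, da, params, W_sc, W_sx),
        "strD2": striatal_drive_D2(c, x, da, params, W_sc, W_sx),
        "stn": params.w_ctx_stn * c - params.w_gpe_stn * z_gpe,
        "gpe": params.w_stn_gpe * stn_sum - params.w_str_gpe * z_d2,
        "gpi": (params.gpi_baseline + params.w_stn_gpi * stn_sum
                - params.w_str_gpi * z_d1 - params.w_gpe_gpi * z_gpe),
    }


def step_bg(state: BGState, c, x, da: float, params: BGParams,
            dt: float = 1.0, W_sc=None, W_sx=None) -> BGState:
    """One synchronous Euler step of all five layers.

    ``c`` is the per-channel cortical input (pooled loop sub-population
    rates), ``x`` the per-channel external input. All drives are evaluated
    on the pre-step rates; the five layers then step together.
    """
    C = state.n_channels
    c = np.asarray(c, dtype=float)
    x = np.asarray(x, dtype=float)
    if c.shape[0] != C:
        raise ValueError(f"cortical input has length {c.shape[0]}, expected {C}")
    d = bg_drives(state, c, x, da, params, W_sc, W_sx)
    lp, s = params.layer, state
    # all five layers share LayerParams, so they step as one stacked array
    u = np.stack([s.strD1.u, s.strD2.u, s.stn.u, s.gpe.u, s.gpi.u])
    drv = np.stack([d["strD1"], d["strD2"], d["stn"], d["gpe"], d["gpi"]])
    if dt >= lp.tau or dt <= 0:
        raise ValueError(f"dt={dt} must satisfy 0 < dt < tau={lp.tau}")
    u2 = u + (dt / lp.tau) * (drv - u)
    z2 = transfer(u2, lp)
    return BGState(
        strD1=LayerState(u2[0], z2[0]),
        strD2=LayerState(u2[1], z2[1]),
        stn=LayerState(u2[2], z2[2]),
        gpe=LayerState(u2[3], z2[3]),
        gpi=LayerState(u2[4], z2[4]),
        da=da,
    )


def gpi_to_thalamic_gate(gpi_rates: np.ndarray, params: BGParams) -> np.ndarray:
    """Inhibitory drive delivered to each thalamic channel unit.

    Proportional to the channel's GPi rate (``-w_gpi_tha * z_gpi``): a
    tonically active GPi keeps its thalamic unit clamped; a silenced GPi
    channel exerts no inhibition — disinhibition is the selection signal.
    """
    return -params.w_gpi_tha * np.asarray(gpi_rates, dtype=float)
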