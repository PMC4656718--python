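"""Cortical reservoir: sparse random recurrent network in the leaky
echo-state regime, with a three-way unit partition and read-out units.

The cortical module is an echo-state network of leaky rate units
(:mod:`csntc.dynamics`). Its units are partitioned into three disjoint
groups:

* *loop* units — in one-to-one loop with the thalamic channels; divided
  into ``n_channels`` equal sub-populations, one per basal ganglia channel;
* *input* units — the only units receiving external (cortico-cortical)
  input through ``W_ux``;
* *free* units — neither, participating only in the recurrent dynamics.

The recurrent matrix ``W_u`` is random and sparse, rescaled so that the
*leaky-effective* matrix ``(1 - leak) I + leak * W_u`` (``leak = dt/tau``)
has a prescribed spectral radius below one. An optional asymmetrising
transformation removes part of the symmetric component of ``W_u`` before
the rescaling; breaking symmetry lengthens and enriches the transient
response, which is what the read-outs decode.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from .dynamics import LayerParams, LayerState, step_layer

__all__ = [
    "ReservoirSpec",
    "ReservoirWeights",
    "Readout",
    "build_reservoir",
    "step_cortex",
    "read_out",
]


@dataclass(frozen=True)
class ReservoirSpec:
    """Construction parameters of a cortical reservoir.

    ``loop_fraction`` of the units sit in thalamo-cortical loops, split into
    ``n_channels`` equal sub-populations (the loop count is truncated to a
    multiple of ``n_channels``; the remainder becomes free units).
    ``input_fraction`` of the units receive external input. ``leak`` is the
    Euler leak rate dt/tau used to define the effective matrix whose
    spectral radius is normalized to ``effective_spectral_radius``.
    """

    n_units: int = 200
    n_inputs: int = 1
    n_channels: int = 3
    loop_fraction: float = 0.5
    input_fraction: float = 0.2
    sparsity: float = 0.1
    effective_spectral_radius: float = 0.95
    leak: float = 0.1
    input_scale: float = 1.0
    asymmetrize: bool = True
    asymmetry: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.loop_fraction + self.input_fraction > 1.0 + 1e-12:
            raise ValueError("loop_fraction + input_fraction must be <= 1")
        if not (0.0 < self.effective_spectral_radius < 1.0):
            raise ValueError("effective_spectral_radius must lie in (0, 1)")
        if not (0.0 < self.leak < 1.0):
            raise ValueError("leak (dt/tau) must lie in (0, 1)")
        if self.effective_spectral_radius <= 1.0 - self.leak:
            # the identity part of the effective matrix bounds its radius
            # below by (1 - leak) whenever the raw draw has eigenvalues with
            # positive real part (always, for a random matrix)
            raise ValueError(
                "effective_spectral_radius must exceed 1 - leak "
                f"({1.0 - self.leak:.3f}); smaller radii are unreachable by "
                "rescaling the recurrent matrix"
            )
        if self.n_channels < 1:
            raise ValueError("n_channels must be >= 1")

    @property
    def n_loop(self) -> int:
        per = int(self.n_units * self.loop_fraction) // self.n_channels
        return per * self.n_channels

    @property
    def n_input_units(self) -> int:
        return int(round(self.n_units * self.input_fraction))


@dataclass
class ReservoirWeights:
    """Weights and partition of a built reservoir.

    ``loop_idx`` has shape (n_channels, per_channel): row *k* lists the
    units of loop sub-population *k*. ``pool`` (n_channels, n_units)
    averages rates over each sub-population; ``broadcast`` (n_units,
    n_channels) copies a per-channel thalamic drive onto the sub-population
    units. Both are dense 0/1-structured matrices so stepping is a single
    matrix product.
    """

    spec: ReservoirSpec
    W_u: np.ndarray
    W_ux: np.ndarray
    loop_idx: np.ndarray
    input_idx: np.ndarray
    free_idx: np.ndarray
    pool: np.ndarray
    broadcast: np.ndarray

    def effective_matrix(self) -> np.ndarray:
        k = self.spec.leak
        return (1.0 - k) * np.eye(self.spec.n_units) + k * self.W_u


def _effective_radius_of_scaled(eigs: np.ndarray, leak: float, s: float) -> float:
    return float(np.max(np.abs((1.0 - leak) + leak * s * eigs)))


def build_reservoir(spec: ReservoirSpec, max_rebuilds: int = 5) -> ReservoirWeights:
    """Draw, partition and normalize a reservoir from ``spec``.

    Deterministic given ``spec.seed``. The recurrent matrix is rescaled so
    the leaky-effective matrix hits ``spec.effective_spectral_radius`` to
    within 1e-6 (computed through the eigenvalues of the raw draw, for
    which the effective radius is an explicit scalar function of the
    scale). A draw whose spectral radius is numerically zero cannot be
    rescaled and is redrawn, with a warning.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_units

    for attempt in range(max_rebuilds):
        mask = rng.random((n, n)) < spec.sparsity
        W = rng.standard_normal((n, n)) * mask
        np.fill_diagonal(W, 0.0)
        if spec.asymmetrize:
            W = W - spec.asymmetry * 0.5 * (W + W.T)
        eigs = np.linalg.eigvals(W)
        rho = float(np.max(np.abs(eigs)))
        if rho < 1e-12:
            warnings.warn(
                "raw recurrent matrix has (numerically) zero spectral radius; "
                "redrawing", RuntimeWarning,
            )
            continue
        target = spec.effective_spectral_radius
        f = lambda s: _effective_radius_of_scaled(eigs, spec.leak, s) - target
        s_hi = 1.0 / (spec.leak * rho) * 4.0
        while f(s_hi) < 0:
            s_hi *= 2.0
        scale = brentq(f, 0.0, s_hi, xtol=1e-12, rtol=1e-14)
        W = W * scale
        break
    else:
        raise RuntimeError("could not draw a reservoir with nonzero spectral radius")

    per = spec.n_loop // spec.n_channels
    loop_idx = np.arange(spec.n_loop).reshape(spec.n_channels, per)
    input_idx = np.arange(spec.n_loop, spec.n_loop + spec.n_input_units)
    free_idx = np.arange(spec.n_loop + spec.n_input_units, n)

    W_ux = np.zeros((n, spec.n_inputs))
    W_ux[input_idx] = rng.uniform(-1.0, 1.0, size=(len(input_idx), spec.n_inputs))
    W_ux *= spec.input_scale

    pool = np.zeros((spec.n_channels, n))
    broadcast = np.zeros((n, spec.n_channels))
    if per > 0:
        for k in range(spec.n_channels):
            pool[k, loop_idx[k]] = 1.0 / per
            broadcast[loop_idx[k], k] = 1.0

    return ReservoirWeights(
        spec=spec, W_u=W, W_ux=W_ux,
        loop_idx=loop_idx, input_idx=input_idx, free_idx=free_idx,
        pool=pool, broadcast=broadcast,
    )


def step_cortex(
    weights: ReservoirWeights,
    state: LayerState,
    x: np.ndarray,
    thal_drive: np.ndarray,
    params: LayerParams,
    dt: float = 1.0,
) -> LayerState:
    """One Euler step of the cortical module.

    The drive is ``W_ux x + W_u z + broadcast(thal_drive)`` where
    ``thal_drive`` holds one (already gain-scaled) value per channel,
    copied uniformly onto the units of the corresponding loop
    sub-population.
    """
    x = np.asarray(x, dtype=float)
    thal_drive = np.asarray(thal_drive, dtype=float)
    if x.shape[0] != weights.spec.n_inputs:
        raise ValueError(
            f"input has length {x.shape[0]}, reservoir expects {weights.spec.n_inputs}"
        )
    if thal_drive.shape[0] != weights.spec.n_channels:
        raise ValueError(
            f"thal_drive has length {thal_drive.shape[0]}, "
            f"reservoir has {weights.spec.n_channels} channels"
        )
    drive = weights.W_u @ state.z + weights.W_ux @ x + weights.broadcast @ thal_drive
    return step_layer(state, drive, params, dt)


@dataclass
class Readout:
    """Read-out units decoding the reservoir rates.

    In ``batch-linear`` mode the output is the exact linear map
    ``o = W_oz z`` (the form trained by ridge regression). In
    ``online-dynamic`` mode the read-outs are leaky rate units without
    lateral connections, driven by ``W_oz z`` and stepped once per call
    (the form trained online); their rates are the output.
    """

    W_oz: np.ndarray
    mode: str = "batch-linear"
    params: LayerParams = field(default_factory=LayerParams)
    state: LayerState | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("batch-linear", "online-dynamic"):
            raise ValueError(f"unknown read-out mode {self.mode!r}")
        if self.mode == "online-dynamic" and self.state is None:
            self.state = LayerState.zeros(self.W_oz.shape[0], self.params)

    @property
    def n_outputs(self) -> int:
        return self.W_oz.shape[0]


def read_out(readout: Readout, z: np.ndarray, dt: float = 1.0) -> np.ndarray:
    """Output of the read-out units for reservoir rates ``z``.

    Batch-linear mode is stateless; online-dynamic mode advances the
    read-out units by one Euler step (mutating ``readout.state``) and
    returns their rates.
    """
    drive = readout.W_oz @ z
    if readout.mode == "batch-linear":
        return drive
    readout.state = step_layer(readout.state, drive, readout.params, dt)
    return readout.state.z
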