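"""Leaky-integrator rate units shared by every layer of the model.

Every population in the model (cortex, striatum, pallidum, STN, thalamus,
dynamic read-outs) follows the same first-order dynamics

    tau * du/dt = -u + drive

with a rectified-tanh output

    z = [tanh(alpha * (u - th))]+

so that unit rates are non-negative and bounded below 1, as expected of a
population firing-rate variable. The rest state u = 0 is silent whenever
th > 0, which gives every circuit in the package a well-defined "down"
state. Integration is explicit (forward) Euler with a fixed step ``dt``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["LayerParams", "LayerState", "transfer", "step_layer"]


@dataclass(frozen=True)
class LayerParams:
    """Transfer and time-constant parameters of a population of rate units.

    Parameters
    ----------
    tau : float
        Membrane/population time constant in milliseconds. Must be positive.
    alpha : float
        Slope of the tanh transfer function (dimensionless).
    th : float
        Threshold of the transfer function, in potential units. Rates are
        zero for potentials at or below ``th``.
    """

    tau: float = 10.0
    alpha: float = 2.0
    th: float = 0.1

    def __post_init__(self) -> None:
        if not self.tau > 0:
            raise ValueError(f"tau must be positive, got {self.tau}")
        if not self.alpha > 0:
            raise ValueError(f"alpha must be positive, got {self.alpha}")


@dataclass
class LayerState:
    """Potentials ``u`` and rates ``z`` of a population of leaky rate units.

    ``u`` and ``z`` always have the same shape; after every update
    ``z == transfer(u, params)`` holds, so ``z`` is a cached view of the
    output nonlinearity, kept because downstream drives are computed from
    pre-step rates.
    """

    u: np.ndarray
    z: np.ndarray

    @classmethod
    def zeros(cls, shape, params: LayerParams | None = None) -> "LayerState":
        """A silent layer: all potentials at 0 (and hence all rates at 0
        whenever the transfer threshold is positive)."""
        params = params or LayerParams()
        u = np.zeros(shape, dtype=float)
        return cls(u=u, z=transfer(u, params))

    def copy(self) -> "LayerState":
        return LayerState(u=self.u.copy(), z=self.z.copy())


def transfer(u: np.ndarray, params: LayerParams) -> np.ndarray:
    """Rectified-tanh output rates for potentials ``u``.

    Computes ``[tanh(alpha * (u - th))]+`` elementwise; the positive part
    clips hyperpolarised units to zero so rates live in [0, 1).

    Raises
    ------
    FloatingPointError
        If ``u`` contains non-finite values (numerical blow-up upstream).
    """
    u = np.asarray(u, dtype=float)
    # non-finite entries propagate to the sum, so one scalar check suffices
    if not np.isfinite(u.sum()):
        raise FloatingPointError("non-finite potentials: dynamics blew up")
    z = np.tanh(params.alpha * (u - params.th))
    return np.maximum(z, 0.0, out=z)


def step_layer(
    state: LayerState,
    drive: np.ndarray,
    params: LayerParams,
    dt: float = 1.0,
) -> LayerState:
    """One explicit-Euler step of ``tau u' = -u + drive``.

    Returns a new :class:`LayerState`; the input state is not modified.
    ``dt`` must be positive and strictly smaller than ``tau`` for the
    explicit scheme to be stable.
    """
    if not dt > 0:
        raise ValueError(f"dt must be positive, got {dt}")
    if dt >= params.tau:
        raise ValueError(
            f"dt={dt} >= tau={params.tau}: explicit Euler integration of the "
            "leak would be unstable; reduce dt or increase tau"
        )
    u = state.u + (dt / params.tau) * (drive - state.u)
    return LayerState(u=u, z=transfer(u, params))
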