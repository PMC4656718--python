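"""The three learning rules of the model.

* :func:`ridge_fit` — batch Tikhonov (ridge) regression of the linear
  read-out weights from stored reservoir states, the standard echo-state
  training procedure.
* :func:`bpdc_update` — the simplified backpropagation–decorrelation
  online rule for feed-forward read-outs: an error finite-difference term
  times a decorrelation factor, O(n) per step.
* :func:`oja_kwta_update` — the unsupervised Oja rule with k-winner-take-all
  filtering on both the post-synaptic (striatal) and pre-synaptic
  (cortical) rate vectors, used for cortico-striatal category learning.

Only the read-out weights and the one designated cortico-striatal matrix
ever learn; all other weights in the model are fixed at construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg

__all__ = [
    "RidgeProblem", "BPDCConfig", "OjaConfig", "OUNoise",
    "ridge_fit", "bpdc_update", "oja_kwta_update", "kwta",
]


@dataclass
class RidgeProblem:
    """Stacked training data for the batch read-out fit.

    ``X`` holds one reservoir-state row per recorded timepoint (all task
    windows of all training trajectories stacked); ``Y`` the corresponding
    target read-out activations. ``lam`` is the Tikhonov regularization
    parameter (lam >= 0; lam > 0 guarantees a unique solution).
    """

    X: np.ndarray
    Y: np.ndarray
    lam: float = 0.5

    def __post_init__(self) -> None:
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        self.Y = np.atleast_2d(np.asarray(self.Y, dtype=float))
        if self.X.shape[0] != self.Y.shape[0]:
            raise ValueError(
                f"X has {self.X.shape[0]} rows but Y has {self.Y.shape[0]}"
            )
        if self.lam < 0:
            raise ValueError("lam must be >= 0")


def ridge_fit(problem: RidgeProblem) -> np.ndarray:
    """Solve ``W = (X^T X + lam^2 I)^-1 X^T Y`` and return it transposed to
    the read-out convention ``o = W_oz z`` (shape n_outputs x n_units).

    With ``lam = 0`` a singular normal-equations matrix raises a
    ``LinAlgError`` naming the regularizer.
    """
    X, Y, lam = problem.X, problem.Y, problem.lam
    A = X.T @ X + lam**2 * np.eye(X.shape[1])
    try:
        W = scipy.linalg.solve(A, X.T @ Y, assume_a="pos")
    except (scipy.linalg.LinAlgError, np.linalg.LinAlgError) as err:
        raise np.linalg.LinAlgError(
            f"normal equations singular at lam={lam}; use lam > 0"
        ) from err
    return W.T


@dataclass(frozen=True)
class BPDCConfig:
    """Learning rate, regularizer and time step of the online rule."""

    eta: float = 0.01
    beta: float = 0.2
    dt: float = 1.0

    def __post_init__(self) -> None:
        if not self.eta > 0:
            raise ValueError("eta must be positive")
        if not self.beta > 0:
            raise ValueError("beta must be positive")


def bpdc_update(
    W: np.ndarray,
    z_t: np.ndarray,
    x_t: np.ndarray,
    e_t: np.ndarray,
    e_t1: np.ndarray,
    cfg: BPDCConfig,
) -> np.ndarray:
    """One backpropagation–decorrelation weight increment.

    ``e_t`` and ``e_t1`` are the read-out errors ``o - y`` at two
    consecutive steps. Returns

        dW = (eta/dt) * g_{t+1} d_t^T,
        d_t = z_t / (z_t.z_t + x_t.x_t + beta),
        g_{t+1} = (1 - dt) e_t - e_{t+1}.

    ``beta > 0`` bounds the decorrelation denominator away from zero. The
    backpropagation weighting of the original rule vanishes for read-outs
    without autoconnections, which is the form used here.
    """
    z_t = np.asarray(z_t, dtype=float)
    x_t = np.asarray(x_t, dtype=float)
    e_t = np.asarray(e_t, dtype=float)
    e_t1 = np.asarray(e_t1, dtype=float)
    d = z_t / (z_t @ z_t + x_t @ x_t + cfg.beta)
    g = (1.0 - cfg.dt) * e_t - e_t1
    return (cfg.eta / cfg.dt) * np.outer(g, d)


@dataclass(frozen=True)
class OjaConfig:
    """Parameters of the cortico-striatal Oja/kWTA rule.

    ``k_striatum`` and ``k_cortex`` are the winner counts applied to the
    post- and pre-synaptic rate vectors. ``noise_mu``/``noise_sigma``
    parametrize the Gaussian perturbation injected into the striatal
    drive during this learning phase only, so that selection starts out
    random and the rule can discover channel/category assignments.
    ``noise_tau`` (ms) is the correlation time of that perturbation: it is
    generated as an Ornstein–Uhlenbeck process with stationary standard
    deviation ``noise_sigma``, slow relative to the unit time constant, so
    a random channel advantage persists long enough to trigger a lock-in.
    """

    eta_sx: float = 0.25
    k_striatum: int = 1
    k_cortex: int = 30
    noise_mu: float = 0.0
    noise_sigma: float = 0.4
    noise_tau: float = 150.0

    def __post_init__(self) -> None:
        if not self.eta_sx > 0:
            raise ValueError("eta_sx must be positive")
        if self.k_striatum < 1 or self.k_cortex < 1:
            raise ValueError("kWTA counts must be >= 1")


class OUNoise:
    """Ornstein–Uhlenbeck perturbation with mean ``noise_mu``, stationary
    standard deviation ``noise_sigma`` and correlation time ``noise_tau``.

    Initialized from the stationary distribution; one :meth:`step` advances
    the process by ``dt`` with exact discretization, so statistics do not
    depend on the step size."""

    def __init__(self, cfg: OjaConfig, size: int, rng: np.random.Generator):
        self.cfg = cfg
        self.rng = rng
        self.value = rng.normal(cfg.noise_mu, cfg.noise_sigma, size)
        self._decay: dict = {}

    def step(self, dt: float = 1.0) -> np.ndarray:
        cfg = self.cfg
        if dt not in self._decay:
            a = float(np.exp(-dt / cfg.noise_tau))
            self._decay[dt] = (a, cfg.noise_sigma * float(np.sqrt(1 - a * a)))
        a, s = self._decay[dt]
        self.value = (
            cfg.noise_mu
            + a * (self.value - cfg.noise_mu)
            + s * self.rng.standard_normal(self.value.shape)
        )
        return self.value


def kwta(v: np.ndarray, k: int) -> np.ndarray:
    """k-winner-take-all filter: zero all but the k largest entries.

    Surviving entries keep their original values. Ties are broken in
    favour of the lowest index (stable sort), so the filter is
    deterministic.
    """
    v = np.asarray(v, dtype=float)
    if not 1 <= k <= v.shape[0]:
        raise ValueError(f"k={k} outside [1, {v.shape[0]}]")
    if k == v.shape[0]:
        return v.copy()
    winners = np.argsort(-v, kind="stable")[:k]
    out = np.zeros_like(v)
    out[winners] = v[winners]
    return out


def oja_kwta_update(
    W_sx: np.ndarray,
    s_raw: np.ndarray,
    c_raw: np.ndarray,
    cfg: OjaConfig,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """One Oja increment for the cortico-striatal matrix.

    The striatal rates are perturbed with Gaussian noise (when ``rng`` is
    given) and reduced to their ``k_striatum`` winners; the cortical rates
    to their ``k_cortex`` winners. The increment

        dW = eta_sx * ( s c^T - ((s*s) 1^T) * W )

    is Hebbian growth with Oja's self-normalizing decay, so rows stay
    bounded under stationary winner statistics.
    """
    s_raw = np.asarray(s_raw, dtype=float)
    c_raw = np.asarray(c_raw, dtype=float)
    if W_sx.shape != (s_raw.shape[0], c_raw.shape[0]):
        raise ValueError(
            f"W_sx shape {W_sx.shape} does not match "
            f"({s_raw.shape[0]}, {c_raw.shape[0]})"
        )
    if rng is not None and cfg.noise_sigma > 0:
        s_raw = s_raw + rng.normal(cfg.noise_mu, cfg.noise_sigma, s_raw.shape)
    s = kwta(s_raw, cfg.k_striatum)
    c = kwta(c_raw, min(cfg.k_cortex, c_raw.shape[0]))
    return cfg.eta_sx * (np.outer(s, c) - np.outer(s * s, np.ones_like(c)) * W_sx)
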