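"""Deterministic fixture generators: tiny, seeded instances of every part
of the model, so each component is testable without running a full
experiment.

Fixtures are generated in code (never shipped as data files) and
regenerate byte-identically for a given seed. The catalogue:

* ``bg2`` / ``bg3`` — 2- and 3-channel basal ganglia instances with
  constant inputs, one channel biased; payload includes the fixed-point
  steady state computed by an independent root solve of the dynamics'
  right-hand side (:func:`bg_fixed_point`).
* ``ridge_small`` — a 20x5 / 20x2 regression problem with the solution of
  the normal equations attached, solved directly.
* ``selection_schedule`` — a scripted dopamine/input time course for a single
  CSNTC module whose expected behaviour is the canonical selection
  sequence: striatal rise on dopamine onset, selective pallidal dip,
  up-state lock-in persisting after input offset, unlock after dopamine
  offset.
* ``tiny_reservoir`` — a 40-unit reservoir spec for fast structural tests.
* ``anova_table`` — a hand-sized balanced 2x2 table with sums of squares
  small enough to verify by hand (expected F values attached).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import fsolve

from .basal_ganglia import BGParams, BGState, bg_drives
from .cortex import ReservoirSpec
from .dynamics import LayerState, transfer

__all__ = ["Fixture", "make_fixture", "bg_fixed_point", "FIXTURE_NAMES"]


@dataclass
class Fixture:
    name: str
    seed: int
    payload: dict


def bg_fixed_point(
    c: np.ndarray,
    x: np.ndarray,
    da: float,
    params: BGParams,
    u0: np.ndarray | None = None,
) -> BGState:
    """Steady state of the basal ganglia circuit under constant input,
    found by root-solving ``drive(z(u)) - u = 0`` over the stacked
    potentials of all five layers — independent of the Euler integrator.
    """
    C = len(c)

    def unpack(u_flat: np.ndarray) -> BGState:
        u = u_flat.reshape(5, C)
        lp = params.layer
        mk = lambda row: LayerState(u=row.copy(), z=transfer(row, lp))
        return BGState(strD1=mk(u[0]), strD2=mk(u[1]), stn=mk(u[2]),
                       gpe=mk(u[3]), gpi=mk(u[4]), da=da)

    def residual(u_flat: np.ndarray) -> np.ndarray:
        st = unpack(u_flat)
        d = bg_drives(st, c, x, da, params)
        drives = np.concatenate([d["strD1"], d["strD2"], d["stn"],
                                 d["gpe"], d["gpi"]])
        return drives - u_flat

    if u0 is None:
        u0 = np.zeros(5 * C)
        u0[4 * C:] = params.gpi_baseline  # GPi starts near its tonic drive
    sol = fsolve(residual, u0, full_output=True, xtol=1e-12)
    u_star, info, ier, msg = sol
    if ier != 1:
        raise RuntimeError(f"fixed-point solve did not converge: {msg}")
    return unpack(u_star)


def _bg_fixture(n_channels: int, seed: int) -> dict:
    params = BGParams()
    c = np.full(n_channels, 0.05)
    x = np.zeros(n_channels)
    x[0] = 0.5  # biased channel
    da = 1.0
    fp = bg_fixed_point(c, x, da, params)
    return {
        "params": params, "c": c, "x": x, "da": da,
        "expected_winner": 0,
        "fixed_point": fp,
    }


def _ridge_fixture(seed: int) -> dict:
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((20, 5))
    Y = rng.standard_normal((20, 2))
    lam = 0.1
    # independent direct solve of the normal equations
    W = np.linalg.solve(X.T @ X + lam**2 * np.eye(5), X.T @ Y)
    return {"X": X, "Y": Y, "lam": lam, "oracle_W_oz": W.T}


def _selection_schedule(seed: int) -> dict:
    """Scripted single-module schedule reproducing the canonical selection
    event sequence. Times in ms; the striatal bias to channel 0 switches
    off 800 ms before dopamine does, so lock-in persistence and unlock
    can each be asserted over a >=500 ms horizon."""
    T = 2200
    da_on, input_on, input_off, da_off = 200, 300, 800, 1600
    da = np.where((np.arange(T) >= da_on) & (np.arange(T) < da_off), 1.0, 0.0)
    bias = np.zeros((T, 3))
    bias[input_on:input_off, 0] = 0.5
    return {
        "T": T, "da": da, "bias": bias, "channel": 0,
        "sin_period": 300.0, "sin_amp": 1.0,
        "times": {"da_on": da_on, "input_on": input_on,
                  "input_off": input_off, "da_off": da_off},
        "expected_order": ["strD1_rise", "gpi_dip", "lock_in", "unlock"],
    }


def _anova_table(seed: int) -> dict:
    # 2x2 cells with n=3; sums of squares verified by hand:
    # cell means 2, 5, 4, 3 -> SS_A = 0, SS_B = 3, SS_AB = 12, SS_err = 8
    rows = []
    cells = {("a1", "b1"): [1, 2, 3], ("a1", "b2"): [4, 5, 6],
             ("a2", "b1"): [3, 4, 5], ("a2", "b2"): [2, 3, 4]}
    for (fa, fb), ys in cells.items():
        rows += [dict(condition=fa, lesion=fb, nrmse=y) for y in ys]
    return {
        "table": pd.DataFrame(rows),
        "expected": {"F_A": 0.0, "F_B": 3.0, "F_AB": 12.0,
                     "ss": {"A": 0.0, "B": 3.0, "AB": 12.0, "error": 8.0},
                     "df": {"A": 1, "B": 1, "AB": 1, "error": 8}},
    }


def run_scripted_schedule(module, payload: dict) -> dict:
    """Run a CSNTC module through a scripted dopamine/bias schedule (the
    ``selection_schedule`` fixture) and return per-step traces of the selected
    channel's layers, as arrays of shape (T, C) keyed by site name."""
    from .module import step_module  # local import to avoid a cycle

    T = payload["T"]
    traces = {s: np.zeros((T, module.n_channels))
              for s in ("strD1", "strD2", "stn", "gpe", "gpi", "tha", "ctx")}
    for t in range(T):
        x = np.array([payload["sin_amp"]
                      * np.sin(2 * np.pi * t / payload["sin_period"])])
        step_module(module, x, payload["bias"][t], payload["da"][t])
        for site in ("strD1", "strD2", "stn", "gpe", "gpi"):
            traces[site][t] = getattr(module.bg, site).z
        traces["tha"][t] = module.thalamus.z
        traces["ctx"][t] = module.pooled_cortex()
    return traces


def trace_frame(traces: dict) -> pd.DataFrame:
    """Tidy long-format view of scripted-schedule traces: one row per
    (time, site, channel) with the unit rate — convenient for plotting the
    selection sequence."""
    rows = []
    for site, arr in traces.items():
        T, C = arr.shape
        for ch in range(C):
            rows.append(pd.DataFrame({
                "time": np.arange(T), "site": site, "channel": ch,
                "rate": arr[:, ch]}))
    return pd.concat(rows, ignore_index=True)


def selection_events(traces: dict, payload: dict, channel: int = 0) -> dict:
    """Detect the canonical selection events in scripted-schedule traces.

    Returns first-crossing times (ms) for: ``strD1_rise`` (winner StrD1
    above 0.3 after dopamine onset), ``gpi_dip`` (winner GPi below 0.1
    with competitors above 0.3), ``lock_in_until`` (last time the winner
    cortical pool stays above 0.3 from input offset on) and ``unlock``
    (winner cortical pool back below 0.1 after dopamine offset). Missing
    events are reported as -1.
    """
    times = payload["times"]
    k = channel
    others = [i for i in range(traces["gpi"].shape[1]) if i != k]

    def first(cond, start):
        idx = np.nonzero(cond[start:])[0]
        return int(start + idx[0]) if len(idx) else -1

    rise = first(traces["strD1"][:, k] > 0.3, times["da_on"])
    dip = first((traces["gpi"][:, k] < 0.1)
                & np.all(traces["gpi"][:, others] > 0.3, axis=1),
                times["da_on"])
    up = traces["ctx"][:, k] > 0.3
    lock_span = up[times["input_off"]:times["da_off"]]
    lock_until = (times["da_off"] if lock_span.all()
                  else times["input_off"] + int(np.argmin(lock_span)))
    unlock = first(traces["ctx"][:, k] < 0.1, times["da_off"])
    return {"strD1_rise": rise, "gpi_dip": dip,
            "lock_in_until": lock_until, "unlock": unlock}


_CATALOGUE = {
    "bg2": lambda seed: _bg_fixture(2, seed),
    "bg3": lambda seed: _bg_fixture(3, seed),
    "ridge_small": _ridge_fixture,
    "selection_schedule": _selection_schedule,
    "tiny_reservoir": lambda seed: {
        "spec": ReservoirSpec(n_units=40, n_inputs=1, seed=seed)},
    "anova_table": _anova_table,
}

FIXTURE_NAMES = tuple(sorted(_CATALOGUE))


def make_fixture(name: str, seed: int = 0) -> Fixture:
    """Build a catalogue fixture; unknown names raise ``KeyError``."""
    if name not in _CATALOGUE:
        raise KeyError(f"unknown fixture {name!r}; catalogue: {FIXTURE_NAMES}")
    return Fixture(name=name, seed=seed, payload=_CATALOGUE[name](seed))
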