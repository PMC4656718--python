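"""Experiment pipelines for a single CSNTC module: rhythmic trajectory
selection, generalization over translation/scale, and end-point posture
control.

Session/trial structure
-----------------------
A *session* presents each task exactly once, in random order, as three
contiguous *trials*. Within a trial: dopamine switches high shortly after
trial onset and low again before its end; a binary bias to one striatal
channel cues the task; a sinusoidal "sensory" input drives the cortex
throughout; and the *task window* — where read-outs are trained and scored
— sits strictly inside the dopamine interval, so cortical activity there
reflects only the locked-in selection and the sinusoid, not trial-onset
transients. There is **no state reset anywhere**: sessions and trials run
as one continuous simulation, and the trial length is a multiple of the
sinusoid period so every trial sees the same input phase.

Defaults are scaled for quick simulation: 900 ms trials at dt = 1 ms with
a 300 ms sinusoid and a 500 ms task window; all transients in the model
run on tau = 10 ms, so these windows are long relative to every time
constant. All durations are configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cortex import Readout, read_out
from .learning import BPDCConfig, RidgeProblem, bpdc_update, ridge_fit
from .module import CSNTCModule, step_module
from .plant import ArmModel, TargetTask, forward_kinematics, make_target, nrmse

__all__ = [
    "Protocol", "TrialSpec", "LoopResult",
    "run_loop_experiment", "run_endpoint_experiment",
    "run_generalization_experiment",
]


@dataclass(frozen=True)
class Protocol:
    """Session/trial timing, dopamine schedule and input definitions.

    All times are in ms (= steps at dt = 1). Invariants:
    ``da_on < task_start < task_end < da_off < trial_ms`` and the trial
    length is a multiple of the sinusoid period (so the reservoir sees the
    same input phase in every trial of the continuous simulation).
    """

    dt: float = 1.0
    trial_ms: int = 900
    da_on: int = 50
    da_off: int = 850
    task_start: int = 300
    task_end: int = 800
    da_high: float = 1.0
    da_low: float = 0.0
    sin_period: int = 300
    sin_amp: float = 1.0
    bias_amp: float = 0.5
    n_train_sessions: int = 1
    n_test_sessions: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.da_on < self.task_start < self.task_end
                < self.da_off < self.trial_ms):
            raise ValueError(
                "protocol must satisfy da_on < task_start < task_end "
                "< da_off < trial_ms"
            )
        if self.trial_ms % self.sin_period != 0:
            raise ValueError("trial_ms must be a multiple of sin_period")

    @property
    def window_len(self) -> int:
        return self.task_end - self.task_start

    def da(self, t: int) -> float:
        return self.da_high if self.da_on <= t < self.da_off else self.da_low

    def sinusoid(self, t: int) -> float:
        return self.sin_amp * np.sin(2 * np.pi * t / self.sin_period)


@dataclass
class TrialSpec:
    """One trial: which channel is cued and what the read-outs should do."""

    task_id: int
    channel: int
    task: TargetTask
    const_amp: float = 0.0   # amplitude of the extra constant cortical input
    score: bool = True


@dataclass
class LoopResult:
    """Records and artifacts of a loop-model run.

    ``records`` has one row per scored test trial (sim_id, condition,
    session, trial, task_id, nrmse); ``trajectories`` maps task_id of the
    last test session to the produced joint-angle series over the task
    window; ``train_history`` holds per-session NRMSE during online
    learning.
    """

    records: pd.DataFrame
    readout: Readout
    trajectories: dict
    train_history: list = field(default_factory=list)


def _cortex_input(protocol: Protocol, t: int, trial: TrialSpec, n_inputs: int):
    x = np.zeros(n_inputs)
    x[0] = protocol.sinusoid(t)
    if n_inputs > 1:
        x[1] = trial.const_amp
    return x


def _target_row(trial: TrialSpec, protocol: Protocol, t: int) -> np.ndarray:
    period = len(trial.task.joint_target)
    return trial.task.joint_target[(t - protocol.task_start) % period]


def _run_trial(
    module: CSNTCModule,
    protocol: Protocol,
    trial: TrialSpec,
    readout: Readout | None,
    arm: ArmModel,
    collect: list | None = None,
    bpdc: BPDCConfig | None = None,
    record_window: bool = False,
):
    """Advance the module through one trial; optionally store (z, y) rows,
    apply online BPDC updates, or record the produced window output."""
    n_inputs = module.weights.spec.n_inputs
    C = module.n_channels
    bias = np.zeros(C)
    bias[trial.channel] = protocol.bias_amp
    produced = [] if record_window else None
    prev = None  # (z, x, e) for the BPDC finite difference
    for t in range(protocol.trial_ms):
        x = _cortex_input(protocol, t, trial, n_inputs)
        step_module(module, x, bias, protocol.da(t), protocol.dt)
        in_window = protocol.task_start <= t < protocol.task_end
        if readout is not None and readout.mode == "online-dynamic":
            o = read_out(readout, module.cortex.z, protocol.dt)
            if bpdc is not None and in_window:
                y = arm.angles_to_readout(_target_row(trial, protocol, t))
                e = o - y
                if prev is not None:
                    readout.W_oz += bpdc_update(
                        readout.W_oz, prev[0], prev[1], prev[2], e, bpdc)
                prev = (module.cortex.z.copy(), x, e)
            else:
                prev = None
        if in_window:
            if collect is not None:
                y = arm.angles_to_readout(_target_row(trial, protocol, t))
                collect.append((module.cortex.z.copy(), y))
            if record_window:
                if readout.mode == "batch-linear":
                    o = read_out(readout, module.cortex.z)
                produced.append(arm.readout_to_angles(o))
    return np.asarray(produced) if record_window else None


def _window_target(trial: TrialSpec, protocol: Protocol) -> np.ndarray:
    period = len(trial.task.joint_target)
    idx = np.arange(protocol.window_len) % period
    return trial.task.joint_target[idx]


def run_loop_experiment(
    protocol: Protocol,
    module: CSNTCModule,
    trials: list,
    arm: ArmModel | None = None,
    mode: str = "batch",
    lam: float = 0.5,
    bpdc: BPDCConfig | None = None,
    readout: Readout | None = None,
    sim_id: int = 0,
    condition: str = "default",
) -> LoopResult:
    """Train read-outs on the trial set and score the final test session.

    ``mode="batch"``: run ``n_train_sessions`` storage sessions collecting
    reservoir states inside task windows, fit the linear read-out by ridge
    regression, then run the test sessions. ``mode="online"``: the
    read-outs are dynamic units updated by the BPDC rule inside task
    windows over ``n_train_sessions`` sessions. The simulation is
    continuous throughout: training flows into testing with no reset, and
    only the last test session is scored (the earlier ones check the
    behaviour is stable).
    """
    arm = arm or ArmModel()
    rng = np.random.default_rng(protocol.seed)
    n_out = trials[0].task.joint_target.shape[1]
    history = []

    if mode == "batch":
        store = []
        for _ in range(protocol.n_train_sessions):
            for i in rng.permutation(len(trials)):
                _run_trial(module, protocol, trials[i], None, arm, collect=store)
        X = np.array([r[0] for r in store])
        Y = np.array([r[1] for r in store])
        W = ridge_fit(RidgeProblem(X=X, Y=Y, lam=lam))
        readout = Readout(W_oz=W, mode="batch-linear")
    elif mode == "online":
        bpdc = bpdc or BPDCConfig(dt=protocol.dt)
        if readout is None:
            readout = Readout(
                W_oz=np.zeros((n_out, module.weights.spec.n_units)),
                mode="online-dynamic", params=module.cortex_params,
            )
        for _ in range(protocol.n_train_sessions):
            errs = []
            for i in rng.permutation(len(trials)):
                prod = _run_trial(module, protocol, trials[i], readout, arm,
                                  bpdc=bpdc, record_window=True)
                if trials[i].task.kind == "rhythmic":
                    errs.append(nrmse(prod, _window_target(trials[i], protocol)))
            history.append(float(np.mean(errs)) if errs else np.nan)
    elif mode == "untrained":
        readout = readout or Readout(
            W_oz=np.zeros((n_out, module.weights.spec.n_units)))
    else:
        raise ValueError(f"unknown mode {mode!r}")

    rows, trajectories = [], {}
    for session in range(protocol.n_test_sessions):
        last = session == protocol.n_test_sessions - 1
        for i in rng.permutation(len(trials)):
            trial = trials[i]
            prod = _run_trial(module, protocol, trial, readout, arm,
                              record_window=True)
            if last:
                trajectories[trial.task_id] = prod
            if not trial.score:
                continue
            target = _window_target(trial, protocol)
            if trial.task.kind == "rhythmic":
                err = nrmse(prod, target)
            else:
                err = float(np.max(np.abs(prod[-1] - target[-1])))
            rows.append(dict(sim_id=sim_id, condition=condition,
                             session=session, trial=int(i),
                             task_id=trial.task_id, nrmse=err))
    return LoopResult(records=pd.DataFrame(rows), readout=readout,
                      trajectories=trajectories, train_history=history)


def standard_tasks(protocol: Protocol, arm: ArmModel | None = None,
                   shapes=("square", "figure8", "moon")) -> list:
    """The default rhythmic task set: one catalogue shape per channel,
    each traced once per sinusoid period."""
    arm = arm or ArmModel()
    period = int(round(protocol.sin_period / protocol.dt))
    return [
        TrialSpec(task_id=k, channel=k,
                  task=make_target(shape, period, arm=arm))
        for k, shape in enumerate(shapes)
    ]


def endpoint_tasks(protocol: Protocol, arm: ArmModel | None = None,
                   postures=None) -> list:
    """Three fixed-posture tasks (constant joint targets)."""
    arm = arm or ArmModel()
    period = int(round(protocol.sin_period / protocol.dt))
    if postures is None:
        postures = [(0.6, 0.4, 0.2), (1.2, -0.5, 0.3), (0.2, 0.9, -0.4)]
    return [
        TrialSpec(task_id=k, channel=k,
                  task=TargetTask(kind="endpoint",
                                  joint_target=np.tile(np.asarray(p, float),
                                                       (period, 1))))
        for k, p in enumerate(postures)
    ]


def run_endpoint_experiment(
    protocol: Protocol,
    module: CSNTCModule,
    postures=None,
    arm: ArmModel | None = None,
    lam: float = 0.5,
) -> LoopResult:
    """Batch-train on three fixed postures and score the end-of-window
    per-joint absolute error (the ``nrmse`` record column holds that
    error for endpoint tasks)."""
    arm = arm or ArmModel()
    trials = endpoint_tasks(protocol, arm, postures)
    return run_loop_experiment(protocol, module, trials, arm=arm, lam=lam,
                               condition="endpoint")


def run_generalization_experiment(
    protocol: Protocol,
    module: CSNTCModule,
    variant: str = "translation",
    shape_id: str = "circle",
    arm: ArmModel | None = None,
    train_amps=(0.25, 0.5, 0.75),
    test_amp: float = 0.375,
    lam: float = 0.5,
    channel: int = 0,
) -> dict:
    """Train one shape at three amplitudes of an added constant cortical
    input, each amplitude paired with a translation offset (or scale
    factor); test at an intermediate amplitude.

    Returns the per-amplitude centroids (translation) or extents (scale)
    of the *produced* Cartesian trajectories in the last test session,
    plus the value measured at the intermediate amplitude. Generalization
    holds when the test value lies strictly between the values at the two
    flanking trained amplitudes.
    """
    arm = arm or ArmModel()
    if module.weights.spec.n_inputs < 2:
        raise ValueError("generalization needs a reservoir with a second "
                         "(constant) input channel")
    period = int(round(protocol.sin_period / protocol.dt))
    if variant == "translation":
        offsets = [(-0.35, 0.0), (0.0, 0.0), (0.35, 0.0)]
        tasks = [make_target(shape_id, period, arm=arm, translate=off)
                 for off in offsets]
    elif variant == "scale":
        scales = [0.55, 0.775, 1.0]
        tasks = [make_target(shape_id, period, arm=arm, scale=s)
                 for s in scales]
    else:
        raise ValueError(f"unknown variant {variant!r}")

    trials = [TrialSpec(task_id=k, channel=channel, task=t, const_amp=a)
              for k, (a, t) in enumerate(zip(train_amps, tasks))]
    # intermediate-amplitude probe trial, scored geometrically below
    probe = TrialSpec(task_id=len(trials), channel=channel, task=tasks[0],
                      const_amp=test_amp, score=False)
    result = run_loop_experiment(protocol, module, trials + [probe],
                                 arm=arm, lam=lam, condition=variant)

    def measure(prod_angles: np.ndarray) -> float:
        pts = np.array([forward_kinematics(a, arm)[-1] for a in prod_angles])
        if variant == "translation":
            return float(pts[:, 0].mean())       # centroid along the offset axis
        return float(np.mean(pts.max(axis=0) - pts.min(axis=0)))  # extent

    values = {t.const_amp: measure(result.trajectories[t.task_id])
              for t in trials + [probe]}
    lo, mid = train_amps[0], train_amps[1]
    return {
        "variant": variant,
        "train_amps": tuple(train_amps),
        "test_amp": test_amp,
        "trained_values": {a: values[a] for a in train_amps},
        "test_value": values[test_amp],
        "flanking": (values[lo], values[mid]),
        "between": min(values[lo], values[mid]) < values[test_amp]
                   < max(values[lo], values[mid]),
        "result": result,
    }
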