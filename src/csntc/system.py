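"""Two-module motor system: a high-level motor CSNTC module driving a
primary motor CSNTC module, plus a plain somatosensory cortical module.

Architecture
------------
* **High-level motor module (HL)** — a CSNTC module receiving the task
  code: 9 binary channels in 3 groups of 3. The code reaches the HL
  *striatum* through a hardwired category map (every bit of group *g*
  drives striatal channel *g* — standing in for reward-trained
  prefronto-striatal connections) and the HL *cortex* in a distributed
  way through fixed random weights.
* **Primary motor module (PM)** — a CSNTC module whose cortical read-outs
  drive the arm joints. Its cortex receives the HL and somatosensory
  cortical rates through fixed random weights; its striatum receives the
  HL cortical rates through the **only plastic matrix in the system**,
  ``W_sx``, trained by the unsupervised Oja/kWTA rule.
* **Somatosensory module (SS)** — a reservoir without basal ganglia,
  driven by the sinusoidal "sensory" signal through fixed random weights.

Training has three phases: (1) Oja learning of ``W_sx`` with Gaussian
noise injected into the PM striatal drive so early selection is random;
(2) batch ridge training of the PM read-outs; (3) tests in the SAME
condition (codes as trained: first bit of each group) and the DIFF
condition (orthogonal codes: last bit of each group). Lesions
(``partial`` = PM cortico-striatal input; ``full`` = that plus the
prefronto-striatal category map) are applied before any learning.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .basal_ganglia import BGParams
from .cortex import Readout, ReservoirSpec, build_reservoir, read_out, step_cortex
from .dynamics import LayerParams, LayerState
from .learning import OjaConfig, OUNoise, RidgeProblem, oja_kwta_update, ridge_fit
from .module import CSNTCModule, LesionSpec, ModuleWiring, lesion, step_module
from .plant import ArmModel, nrmse
from .experiments import Protocol, TrialSpec, _window_target, standard_tasks

__all__ = ["SystemSpec", "MotorSystem", "LESION_BUNDLES",
           "run_system_experiment", "run_lesion_study"]

LESION_BUNDLES = {
    "baseline": (),
    "partial": ("hlctx_to_pm_striatum",),
    "full": ("pfc_to_hl_striatum", "hlctx_to_pm_striatum"),
}


@dataclass(frozen=True)
class SystemSpec:
    """Sizes, gains and training lengths of the two-module system.

    Reservoir sizes are deliberately smaller than the single-module
    default (the lesion study repeats the whole three-phase simulation
    many times); they are large enough for the read-outs to decode the
    three tasks cleanly in the intact system.
    """

    n_hl: int = 90
    n_pm: int = 90
    n_ss: int = 45
    n_channels: int = 3
    bits_per_group: int = 3
    code_amp: float = 1.0
    w_code_hl_str: float = 0.5    # hardwired category-map weight
    g_xs: float = 0.05            # gain on the learned W_sx drive
    hl_input_scale: float = 0.7
    pm_input_scale: float = 0.5
    ss_input_scale: float = 1.0
    w_hl_pm: float = 0.5          # HL-cortex block weight of the PM input
    w_ss_pm: float = 1.5          # SS-cortex block weight of the PM input
    hl_thal_tonic: float = 0.15   # HL thalamic bias: its cortex has no
                                  # rhythmic drive, so ignition needs less
                                  # cortical evidence than in a sensory loop
    oja: OjaConfig = field(default_factory=OjaConfig)
    oja_sessions: int = 30
    readout_sessions: int = 3
    lam: float = 0.5
    lesion: str = "baseline"

    @property
    def n_code(self) -> int:
        return self.n_channels * self.bits_per_group

    def code(self, task: int, condition: str) -> np.ndarray:
        """Binary task code: SAME lights the first bit of the task's group,
        DIFF the last bit (orthogonal to the trained code)."""
        x = np.zeros(self.n_code)
        bit = 0 if condition == "SAME" else self.bits_per_group - 1
        x[task * self.bits_per_group + bit] = self.code_amp
        return x


class MotorSystem:
    """Assembled HL + PM + SS system with one plastic cortico-striatal
    matrix and named lesionable bundles."""

    def __init__(self, spec: SystemSpec, seed: int = 0,
                 bg_params: BGParams | None = None):
        self.spec = spec
        root = np.random.SeedSequence([int(seed), 733]).spawn(3)
        seeds = [int(s.generate_state(1)[0] % 2**31) for s in root]
        C = spec.n_channels
        self.hl = CSNTCModule.build(
            ReservoirSpec(n_units=spec.n_hl, n_inputs=spec.n_code,
                          n_channels=C, input_scale=spec.hl_input_scale,
                          seed=seeds[0]),
            bg_params=bg_params,
            wiring=ModuleWiring(thal_tonic=spec.hl_thal_tonic),
        )
        self.pm = CSNTCModule.build(
            ReservoirSpec(n_units=spec.n_pm, n_inputs=spec.n_hl + spec.n_ss,
                          n_channels=C, input_scale=spec.pm_input_scale,
                          seed=seeds[1]),
            bg_params=bg_params,
        )
        self.ss_weights = build_reservoir(
            ReservoirSpec(n_units=spec.n_ss, n_inputs=1, n_channels=1,
                          loop_fraction=0.0, input_fraction=0.4,
                          input_scale=spec.ss_input_scale, seed=seeds[2]))
        self.ss_params = LayerParams()
        self.ss = LayerState.zeros(spec.n_ss, self.ss_params)
        # hardwired prefronto-striatal category map: any bit of group g
        # drives HL striatal channel g
        self.M_code = np.zeros((C, spec.n_code))
        for g in range(C):
            self.M_code[g, g * spec.bits_per_group:(g + 1) * spec.bits_per_group] = \
                spec.w_code_hl_str
        # the one plastic matrix: HL cortex -> PM striatum
        self.W_sx = np.zeros((C, spec.n_hl))
        self.frozen: set = set()

    def lesion_bundle(self, name: str) -> None:
        if name == "pfc_to_hl_striatum":
            self.M_code[...] = 0.0
        elif name == "hlctx_to_pm_striatum":
            self.W_sx[...] = 0.0
        elif name == "readout":
            pass  # read-outs are created at training time; freezing suffices
        elif name == "thalamocortical":
            self.hl.wiring.w_thal_cortex = 0.0
            self.pm.wiring.w_thal_cortex = 0.0
        else:
            raise KeyError(f"unknown lesion bundle {name!r}")
        self.frozen.add(name)

    def step(self, code: np.ndarray, sin_val: float, da: float,
             dt: float = 1.0, pm_striatal_noise: np.ndarray | None = None):
        """One synchronous step of the three modules (pre-step rates
        everywhere). Returns the pre-step HL cortical rates (the
        pre-synaptic vector seen by the plastic matrix this step)."""
        z_hl = self.hl.cortex.z
        z_ss = self.ss.z
        x_pm_ctx = np.concatenate([self.spec.w_hl_pm * z_hl,
                                   self.spec.w_ss_pm * z_ss])
        x_pm_str = self.spec.g_xs * (self.W_sx @ z_hl)
        step_module(self.hl, code, self.M_code @ code, da, dt)
        step_module(self.pm, x_pm_ctx, x_pm_str, da, dt,
                    striatal_noise=pm_striatal_noise)
        self.ss = step_cortex(self.ss_weights, self.ss,
                              np.array([sin_val]), np.zeros(1),
                              self.ss_params, dt)
        return z_hl


def _run_system_trial(
    sys: MotorSystem,
    protocol: Protocol,
    trial: TrialSpec,
    condition: str,
    readout: Readout | None = None,
    arm: ArmModel | None = None,
    collect: list | None = None,
    oja_rng: np.random.Generator | None = None,
):
    """One trial of the system. ``oja_rng`` enables the cortico-striatal
    learning phase: striatal-drive noise plus per-step Oja updates inside
    the task window."""
    spec = sys.spec
    code = spec.code(trial.task_id, condition)
    cfg = spec.oja
    plastic = oja_rng is not None and "hlctx_to_pm_striatum" not in sys.frozen
    produced = [] if readout is not None else None
    ou = (OUNoise(cfg, spec.n_channels, oja_rng)
          if oja_rng is not None else None)
    s_sum = np.zeros(spec.n_channels)
    c_sum = np.zeros(spec.n_hl)
    n_acc = 0
    for t in range(protocol.trial_ms):
        noise = ou.step(protocol.dt) if ou is not None else None
        z_hl_pre = sys.step(code, protocol.sinusoid(t), protocol.da(t),
                            protocol.dt, pm_striatal_noise=noise)
        in_window = protocol.task_start <= t < protocol.task_end
        if not in_window:
            continue
        if plastic:
            # one Oja step per trial, on window-averaged rates (below):
            # slow category learning that integrates over the noise
            s_sum += sys.pm.bg.strD1.z
            c_sum += z_hl_pre
            n_acc += 1
        if collect is not None:
            period = len(trial.task.joint_target)
            y = arm.angles_to_readout(
                trial.task.joint_target[(t - protocol.task_start) % period])
            collect.append((sys.pm.cortex.z.copy(), y))
        if produced is not None:
            o = read_out(readout, sys.pm.cortex.z)
            produced.append(arm.readout_to_angles(o))
    if plastic and n_acc:
        sys.W_sx += oja_kwta_update(sys.W_sx, s_sum / n_acc, c_sum / n_acc,
                                    cfg, rng=None)
    return np.asarray(produced) if produced is not None else None


def run_system_experiment(
    spec: SystemSpec,
    protocol: Protocol | None = None,
    seed: int = 0,
    sim_id: int = 0,
    arm: ArmModel | None = None,
) -> pd.DataFrame:
    """One complete three-phase simulation of the system.

    Builds the networks from the structural stream of ``seed``, applies
    the lesion *before any learning*, runs Oja learning (skipped when the
    plastic matrix is lesioned: nothing can change), batch read-out
    training, then SAME and DIFF test phases — all as one continuous
    simulation with no state resets. Returns one record per scored test
    trial plus the last-session records of both conditions.
    """
    protocol = protocol or Protocol()
    arm = arm or ArmModel()
    proto_rng = np.random.default_rng(
        np.random.SeedSequence([int(seed), 9291]))
    sys = MotorSystem(spec, seed=seed)
    lesion(sys, LesionSpec(LESION_BUNDLES[spec.lesion]))

    tasks = standard_tasks(protocol, arm)
    n_tasks = len(tasks)

    # phase 1: unsupervised cortico-striatal learning (noise-driven selection)
    if "hlctx_to_pm_striatum" not in sys.frozen:
        for _ in range(spec.oja_sessions):
            for i in proto_rng.permutation(n_tasks):
                _run_system_trial(sys, protocol, tasks[i], "SAME",
                                  arm=arm, oja_rng=proto_rng)

    # phase 2: batch read-out training
    store = []
    for _ in range(spec.readout_sessions):
        for i in proto_rng.permutation(n_tasks):
            _run_system_trial(sys, protocol, tasks[i], "SAME",
                              arm=arm, collect=store)
    X = np.array([r[0] for r in store])
    Y = np.array([r[1] for r in store])
    if "readout" in sys.frozen:  # exploratory lesion: read-outs never learn
        readout = Readout(W_oz=np.zeros((Y.shape[1], X.shape[1])))
    else:
        readout = Readout(W_oz=ridge_fit(RidgeProblem(X=X, Y=Y, lam=spec.lam)))

    # phase 3: SAME then DIFF tests, scoring the last session of each
    rows = []
    for condition in ("SAME", "DIFF"):
        for session in range(protocol.n_test_sessions):
            for i in proto_rng.permutation(n_tasks):
                trial = tasks[i]
                prod = _run_system_trial(sys, protocol, trial, condition,
                                         readout=readout, arm=arm)
                err = nrmse(prod, _window_target(trial, protocol))
                rows.append(dict(sim_id=sim_id, lesion=spec.lesion,
                                 condition=condition, session=session,
                                 trial=int(i), task_id=trial.task_id,
                                 nrmse=err))
    return pd.DataFrame(rows)


def run_lesion_study(
    base_seed: int = 0,
    n_repeats: int = 25,
    lesions=("baseline", "partial", "full"),
    spec: SystemSpec | None = None,
    protocol: Protocol | None = None,
    progress: bool = False,
) -> pd.DataFrame:
    """Repeat the system simulation over independent seeds and lesion
    groups. Repeat *i* uses seed ``base_seed + i`` for every group, so
    lesion conditions within a repeat share identical networks and
    protocol randomness. Returns the concatenated trial records; the
    per-simulation NRMSE used for the ANOVA is the mean over the three
    tasks of the last test session (see :func:`per_simulation_nrmse`)."""
    spec = spec or SystemSpec()
    frames = []
    for les in lesions:
        for i in range(n_repeats):
            df = run_system_experiment(
                replace(spec, lesion=les), protocol=protocol,
                seed=base_seed + i, sim_id=i)
            frames.append(df)
            if progress:
                print(f"{les} repeat {i}: "
                      f"{df[df.session == df.session.max()].groupby('condition').nrmse.mean().round(3).to_dict()}",
                      flush=True)
    return pd.concat(frames, ignore_index=True)


def per_simulation_nrmse(records: pd.DataFrame) -> pd.DataFrame:
    """Collapse trial records to one NRMSE per (simulation, lesion,
    condition): the mean over the task trials of the last test session."""
    last = records[records.session == records.session.max()]
    out = (last.groupby(["sim_id", "lesion", "condition"], as_index=False)
           .nrmse.mean())
    return out
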