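# Methods

`csntc` simulates how the basal ganglia can select *dynamics* — rather
than static patterns — inside a cortical network, and how that selection
lets the same cortical population and the same read-out units produce
several different movements. This note documents the model equations, the
parameter choices, the experiment protocols and their problem sizes, and
what the synthetic inputs do and do not emulate.

## Unit model

Every neuron population in the package (cortical units, striatal D1/D2
units, STN, GPe, GPi, thalamic units, dynamic read-outs) is a leaky
firing-rate unit:

    tau * du/dt = -u + drive,        z = [tanh(alpha * (u - th))]+

integrated by explicit (forward) Euler with fixed dt. The rectification
keeps rates non-negative, as for a population rate, and makes u = 0 a
*silent, locally stable* rest state whenever th > 0 — the "down state"
that selection switches out of. Defaults: `tau = 10 ms`, `alpha = 2`,
`th = 0.1`, `dt = 1 ms`. None of these is empirically constrained; they
were chosen for a silent rest state, graded responses over the input range
used, and comfortable Euler stability (dt = tau/10). Halving dt changes
trajectories at first order in dt (tested against the exact linear-ODE
solution), so conclusions do not hinge on the step size. Potentials start
at 0 and are never reset afterwards; every experiment is one continuous
simulation.

## Cortical reservoir

The cortical module is an echo-state network: a sparse random recurrent
matrix `W_u` (connection probability 0.1, standard-normal weights, zero
diagonal), rescaled so the *leaky-effective* matrix
`(1 - dt/tau) I + (dt/tau) W_u` has spectral radius 0.95. The rescaling is
exact (the effective radius is an explicit scalar function of the raw
eigenvalues, solved to 1e-6); radii at or below `1 - dt/tau` are
unreachable by rescaling and rejected at configuration time. Before
rescaling, half of the symmetric component is removed
(`W <- W - 0.5 (W + W^T)/2`, flag-controlled): breaking symmetry lengthens
and enriches the transient response that the read-outs decode. With the
rectified transfer, linear echo-state theory is only a heuristic here, so
the fading-memory property is asserted behaviourally: from a driven state
with the input off, peak rates fall below 1e-3 within 50 tau (tested).

Units are partitioned into *loop* units (50%, split into `n_channels`
equal sub-populations, each in loop with one thalamic channel), *input*
units (20%, the only rows of `W_ux`, entries uniform on [-1, 1] times an
input scale), and *free* units (the rest; also takes any remainder when
the loop count is not divisible by the channel count). Read-outs are
either exact linear maps `o = W_oz z` (batch training) or leaky rate units
without lateral connections (online training).

## Basal ganglia selection circuit

Five layers of C channel units each, wired one-to-one across layers except
the STN, whose efferents reach *all* GPi and GPe units (the diffuse
hyperdirect pathway that creates the centre-off competition):

    StrD1:  tau s' = -s + (bl_D1 + da_D1 * da) * (w_ctx_str c + x)
    StrD2:  tau s' = -s + (w_ctx_str c + x) / (bl_D2 + da_D2 * da)
    STN:    drive = w_ctx_stn c - w_gpe_stn z_GPe
    GPe:    drive = w_stn_gpe sum(z_STN) - w_str_gpe z_StrD2
    GPi:    drive = gpi_baseline + w_stn_gpi sum(z_STN)
                    - w_str_gpi z_StrD1 - w_gpe_gpi z_GPe

Dopamine `da` is a protocol-driven scalar (high 1.0 / low 0.0), a
*multiplicative excitation* of D1 drive and a *multiplicative inhibition*
(division) of D2 drive. Cortical input `c` is the mean rate of each
channel's cortical loop sub-population (scale-stable pooling); external
input `x` reaches the striatum only — out-of-loop cortical afferents to
the STN have little anatomical support. GPi/SNpr are merged into one
output layer. All layers update synchronously from pre-step rates, so
results are independent of update order.

The thalamic units close the loop:
`drive = w_cortex_thal * c_k - w_gpi_tha * z_GPi_k + thal_tonic`, and each
thalamic rate is broadcast (gain `w_thal_cortex`) onto its cortical
sub-population. With the tonic GPi drive (0.4 -> rate ~0.54 at rest), the
thalamus is clamped at rest; a channel whose striatal drive wins silences
its GPi unit, and the released thalamic unit ignites a cortico-thalamic
up state *provided the cortex shows background activity* — with no
cortical input there is no thalamic activity and no selection.

None of the gains is printed in any source; they were tuned (and live in
config, `BGParams`) so that the circuit satisfies the qualitative regime
that defines it: (a) symmetric inputs produce no selection (a permutation-
symmetry argument, tested exactly); (b) a ~20% striatal-drive advantage
locks in a single channel under high dopamine — this sets the diffuse
STN->GPi gain (1.0) above the GPe->GPi gain (0.1), otherwise near-ties
double-disinhibit; (c) the locked state survives input offset, sustained
only by the cortex->striatum->GPi->thalamus->cortex loop; (d) dropping
dopamine releases it (D1 gain collapses to `bl_D1 = 0.1`, D2 disinhibits
the indirect pathway). The thalamo-cortical gain 1.3 makes loop ignition
robust across reservoir draws; at 1.0 the loop can stall at the transfer
threshold. `bg_fixed_point` solves the same right-hand sides by root
finding, giving an integrator-independent oracle for the steady states.

## Learning rules

* **Batch read-out (ridge / Tikhonov):**
  `W_oz = (X^T X + lam^2 I)^-1 X^T Y` over reservoir states collected
  *inside task windows only*. Default `lam = 0.5`.
* **Online read-out (backpropagation–decorrelation, feed-forward form):**
  `dW = (eta/dt) g_{t+1} d_t^T` with decorrelation
  `d_t = z_t / (z_t.z_t + x_t.x_t + beta)` and error difference
  `g_{t+1} = (1 - dt) e_t - e_{t+1}`, `e = o - y`. The read-outs are
  dynamic units; the backpropagation weighting vanishes without
  autoconnections. Defaults `eta = 0.01`, `beta = 0.2`. On the rhythmic
  task the session-mean NRMSE falls monotonically in trend (tested).
* **Cortico-striatal (Oja with kWTA):**
  `dW = eta_sx (s c^T - ((s*s) 1^T) * W)` with `s` the striatal rates
  reduced to their single winner (k = 1) and `c` the pre-synaptic cortical
  rates reduced to their 30 largest entries. kWTA keeps magnitudes (the
  rule multiplies by them) and breaks ties by lowest index. Oja's decay
  bounds row norms under stationary winner statistics (tested over 1e4
  updates).

During the cortico-striatal learning phase, a Gaussian perturbation is
added to the primary striatal drive so that selection starts out random.
Two implementation choices here are deliberate and were forced by the
dynamics. First, the perturbation is an Ornstein–Uhlenbeck process
(stationary sd 0.4, correlation time 150 ms, exact discretization): ignition of a thalamo-cortical loop needs a channel
advantage sustained for ~10 unit time constants, which white per-step
noise never provides, so with white noise selection simply never happens
and nothing is learned. Second, the Oja update is applied once per trial,
on window-averaged rates: the within-trial lock-in makes the window
average a clean one-winner signal, and per-trial granularity keeps the
learned categories stable across trials (per-step updates at any usable
learning rate converge within a single trial, so each row tracks only the
last task it won and assignments never settle). With `eta_sx = 0.25`, 30
sessions give near-asymptotic weights while integrating over many trials.
The gain `g_xs = 0.05` on the learned drive places the asymptotic winning
drive near 0.8 (safely igniting), cross-task drives near 0.2–0.3 (below
ignition), and the low-dopamine leak below the transfer threshold (so
unlocking still works).

## Arm, targets and error

The plant is a planar 3-segment kinematic arm (unit lengths, base at the
origin, cumulative angles, counter-clockwise positive). Read-out
activations map affinely from [0, 1] onto per-joint limits (default
[-pi, pi]). Target shapes (square with rounded corners, sideways
figure-eight as a 1:2 Lissajous, crescent moon from two circular arcs,
and a circle for the generalization tests) are sampled uniformly in phase
and converted to joint space by damped least-squares inverse kinematics
with a null-space pull toward a rest posture; the pull resolves the
arm's redundancy, so the IK map is unique and periodic curves give
periodic joint series (round-trip error < 1e-3, tested per shape). The
behavioural error is the NRMSE: per-joint RMSE divided by that joint's
target range, averaged over joints. Range normalization is one of several
conventions; it is used consistently for both model output and controls.
For end-point tasks (constant targets, zero range) the error is the
maximum per-joint absolute angle error at the end of the task window.

## Protocols and problem sizes

A session presents each task once in random order; a trial runs 900 ms
(dt = 1 ms): dopamine high from 50 to 850 ms, task window 300–800 ms,
sinusoidal cortical drive with a 300 ms period throughout, a binary bias
(amplitude 0.5) on the cued striatal channel. The trial length is a
multiple of the sinusoid period so every trial sees the same input phase
(there are no resets anywhere). These durations are 25–90 unit time
constants — long relative to every transient in the model — and are the
package's own scaled problem sizes; all are configurable. Batch training
uses 1 storage session (single module) or 3 (system); online training
defaults to 1000 sessions. Tests use 3 sessions, the first two as a
stability warm-up, scoring only the last.

The single-module experiments use a 200-unit reservoir. The
generalization experiment adds a second, constant input channel whose
amplitude (0.25 / 0.5 / 0.75) cues the translation offset (-0.35 / 0 /
+0.35 along x) or scale (0.55 / 0.775 / 1.0) of a circle target; the
probe amplitude is 0.375, and generalization is assessed on the produced
trajectory's centroid (translation) or mean bounding-box extent (scale)
relative to the flanking trained trials.

The two-module system uses 90-unit motor reservoirs and a 45-unit
somatosensory reservoir (no basal ganglia). The 9-channel task code (3
groups of 3 bits) reaches the high-level striatum through a hardwired
category map — any bit of group g drives channel g, standing in for
reward-based learning that is out of scope — and the high-level cortex
through fixed random weights. The high-level thalamic tonic bias is 0.15
(vs 0.1) because that cortex receives only the constant code and needs
less cortical evidence to ignite. SAME tests use the first bit of each
group (as trained); DIFF the last bit (orthogonal codes). Lesions are
applied before any learning: PARTIAL zeroes and freezes the plastic
cortico-striatal matrix; FULL also zeroes the hardwired category map.
For lesioned systems the unsupervised phase is a learning no-op and is
skipped; the model's fading memory makes the later phases insensitive to
this. Each repeat draws structural randomness (reservoirs, random
projections) and protocol randomness (trial order, striatal noise) from
separate streams of `base_seed + i`, so lesion groups within a repeat
share identical networks.

The lesion study statistic is one NRMSE per simulation and condition (the
mean over the three task trials of the last test session), analysed by a
fixed-effects two-way ANOVA (factors TEST: SAME/DIFF; LESION: group vs
baseline) computed from classical balanced sums of squares — the
implementation rejects unbalanced tables rather than silently computing
the wrong decomposition, and is cross-checked against an independent
OLS-based ANOVA and against its nominal type-I error rate under the null.
`scripts/acceptance.py` runs this end to end with 25 repeats per group.

## What the synthetic inputs do and do not emulate

The sinusoid stands in for fine-grained somatosensory drive; the binary
bias and 9-bit codes for coarse task context; the OU perturbation for
exploratory variability in striatal input. Real sensory streams are
high-dimensional, non-stationary and behaviour-dependent (closed loop);
none of that is modelled — the arm is kinematic and exerts no feedback on
the network. Passing tests therefore show that the *selection-of-dynamics
mechanism* works as described under clean, periodic drive; they do not
show robustness to realistic sensory statistics, nor anything about
learning with reward, which is deliberately replaced by hardwired
category connections.

## Numerical choices and degenerate inputs

Explicit Euler requires dt < tau and raises otherwise. Non-finite
potentials raise immediately (blow-up detection). A raw reservoir draw
with numerically zero spectral radius is redrawn with a warning. Ridge
with lam = 0 raises on singular designs, naming the regularizer. kWTA
ties break toward the lowest index. The fixed-point oracle refuses to
return non-converged solutions. NRMSE refuses constant targets.

## File formats

* **Module snapshots** (`save_module`/`load_module`): arrays
  (`W_u`, `W_ux`, optional `W_sx`, and every layer's potentials) in a
  NumPy `.npz` container, with a JSON sidecar holding the reservoir spec
  (including seed and partition parameters), unit and circuit parameters,
  wiring gains, dopamine level and frozen bundles — enough to rebuild the
  module exactly.
* **`results.csv`** (all experiment commands): one row per scored test
  trial with columns `sim_id, condition, session, trial, task_id, nrmse`
  (for end-point tasks the `nrmse` column holds the max-abs joint error in
  radians). `per_simulation.csv` collapses the lesion study to one NRMSE
  per (sim_id, lesion, condition).
* **`anova.json`** (`csntc stats`): F statistics, p-values, degrees of
  freedom and sums of squares of the two-way ANOVA.
* **`traces.csv`** (`csntc trace`): tidy long format, one row per
  (time, site, channel) with the unit rate; sites are strD1, strD2, stn,
  gpe, gpi, tha and ctx (pooled loop sub-population rate).
* **`generalization.json`**: trained amplitudes, per-amplitude measured
  centroid/extent, probe amplitude and its measured value.

## Known limitations

* The unsupervised category learning can, on rare seeds, map two tasks to
  one channel (competitive learning has no guarantee of a bijection);
  this appears as an occasional high-error baseline simulation and is
  part of the reported variance.
* Dopamine is a two-level scalar per module, not a dynamic signal.
* One reservoir cannot be shared by several basal ganglia modules, and
  read-out-to-reservoir feedback is not implemented (deliberately out of
  scope).
* The echo-state normalization treats the rectified-tanh units with the
  linear leaky-ESN theory; the fading property is therefore enforced by
  test rather than by theorem.
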