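# csntc

A simulator of **cortico-striato-nigro-thalamo-cortical (CSNTC) loops**:
a cortical module modelled as an echo-state reservoir whose *internal
dynamics* are selected by a dopamine-gated basal ganglia disinhibition
circuit. The package is for computational neuroscientists studying how the
basal ganglia can recruit one cortical population to generate several
different movements — rhythmic or end-point — with the same actuators and
the same read-out units, and what breaks when cortico-striatal pathways
are lesioned.

## The model in brief

Every population is a leaky rate unit

    tau u' = -u + W_ux x + W_u z,      z = [tanh(alpha (u - th))]+

The cortical module is a sparse random recurrent network normalized in the
leaky echo-state regime (effective matrix `(1 - dt/tau) I + (dt/tau) W_u`
with spectral radius 0.95 < 1), so activity fades after input removal and
read-outs can decode its transients. Half of its units sit in C = 3
thalamo-cortical loop sub-populations gated by a C-channel basal ganglia
circuit (StrD1, StrD2, STN, GPe, GPi): striatal D1 drive is multiplied by
dopamine, D2 drive divided by it, the STN projects diffusely to both
pallidal layers, and the GPi tonically clamps the thalamus. A channel
whose striatal input wins silences its GPi unit, disinhibits its thalamic
unit, and its cortical sub-population switches to a self-sustaining up
state — changing the whole reservoir's dynamics for as long as dopamine
stays high (lock-in), and releasing it when dopamine drops.

Read-out units (one per joint of a planar 3-DoF kinematic arm) are trained
by ridge regression `W_oz = (X^T X + lam^2 I)^-1 X^T Y` (batch) or by the
online backpropagation–decorrelation rule
`dW = (eta/dt) g_{t+1} d_t^T`. In the two-module system, the only other
plastic pathway — high-level motor cortex to primary motor striatum — is
trained by the unsupervised Oja rule with k-winner-take-all filtering,
`dW = eta (s c^T - ((s*s) 1^T) * W)`.

See `docs/methods.md` for the full equations, parameter choices and
protocol sizes.

## Worked example

Train and test the rhythmic three-task experiment (square, sideways
figure-eight, moon — one basal ganglia channel each, identical sinusoidal
cortical input across tasks):

```
$ csntc loop --seed 3 --out out/loop
 task_id    nrmse
       2 0.027230
       1 0.028780
       0 0.022073
mean test NRMSE: 0.0260
```

Each row is one task of the last test session; `nrmse` is the root-mean-
square error of the produced joint-angle trajectory over the task window,
normalized by each joint's target range and averaged over the three
joints. Values near 0.03 mean the same three read-out units reproduce all
three trajectories to within a few percent of their amplitude, even though
the cortical module receives exactly the same sensory input in every trial
— only the basal ganglia channel selected differs. An untrained control
sits around NRMSE 9 here.

End-point (posture) control with the same machinery:

```
$ csntc endpoint --seed 3 --out out/ep
 task_id  max_abs_joint_error_rad
       2                 0.001693
       1                 0.002389
       0                 0.007149
```

i.e. each of the three trained postures is reached to within 0.01 rad per
joint at the end of the task window.

The same library functions are available programmatically
(`csntc.run_loop_experiment`, `csntc.run_generalization_experiment`,
`csntc.run_endpoint_experiment`, `csntc.run_lesion_study`, ...), and
`csntc system` / `csntc stats` run the two-module lesion study and its
two-way ANOVA.

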