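# Methods

## The model

A gated-recurrent-unit (GRU) policy controls a planar two-joint arm through
six muscle-like actuators.  At every 10 ms step the controller receives a
17-dimensional observation — target position (x, y), a binary go cue,
endpoint position, and the six normalized muscle lengths and velocities —
and emits six stimulation commands through a sigmoid readout.  The go cue
and endpoint feedback are delayed by 70 ms (7 steps) and the proprioceptive
feedback by 20 ms (2 steps); the target coordinates are undelayed task
input.  The closed loop (controller -> muscles -> arm -> delayed feedback ->
controller) is a smooth map, so the composite loss can be differentiated
end-to-end by backpropagation through time.

GRU dialect: gates are fused into single weight blocks (order: update,
reset, candidate) and the reset gate scales the candidate's *recurrent
pre-activation*, `n = tanh(W_in x + b_in + r * (W_hn h + b_hn))`, with
separate input- and recurrent-side biases.  This is the convention of the
deep-learning toolchain such models are usually built in, and the fused
layout halves the matmul count of a BPTT step.  Initialization: input and
output maps Glorot-uniform, recurrent blocks orthogonal, gate biases 0,
output bias -5 (so the plant starts silent), initial hidden state a
learnable vector initialized to 0.

### The arm

The plant is a simplified rigid-tendon Hill-type model chosen for the same
interface and qualitative behavior as the published musculoskeletal
simulators, not for anatomical fidelity:

* two rigid links (0.30 / 0.33 m, 1.8 / 1.2 kg, uniform-rod inertias) moving
  in a horizontal plane (no gravity), semi-implicit Euler at dt = 10 ms;
* six muscles — shoulder flexor/extensor, elbow flexor/extensor, and a
  bi-articular pair — with constant signed moment arms (4.0 / 2.5 / 2.8 cm),
  path length affine in the joint angles, optimal length at the centre-out
  start posture (shoulder 60 deg, elbow 90 deg);
* first-order activation filter (tau = 50 ms), Gaussian force-length factor
  (width 0.3 l/l_opt), smooth tanh-saturating force-velocity factor, maximal
  isometric forces 150-300 N; no passive elastic element, so the arm is in
  exact equilibrium at rest with zero stimulation;
* small joint viscosity (0.05 N m s) and smooth softplus walls at the joint
  limits keep passive motion dissipative and postures bounded.

The curl field applies `F = b [[0, -1], [1, 0]] v` at the endpoint
(b in N s/m: 0, +8, or -8), mapped to joint torques through the Jacobian
transpose.  The force is always orthogonal to the endpoint velocity.

### Sign conventions

With the rotation matrix above and b = +8, the field pushes reaches
counter-clockwise in the y-up workspace frame.  `lateral_deviation` is
signed clockwise-positive (negative z of `cross(target-start, point-start)`),
so trained-field deviations are negative in that convention; the protocol
layer therefore also reports deviation *in the field's push direction*
(`-sign(b) * d_cw`), which makes adaptation curves positive and decaying —
the standard presentation.  All savings comparisons use field-direction
deviations; for the opposite-field control each FF phase uses its own gain,
so both conditions yield positive, comparable curves.

### The loss

Per step: `1e3 * |x* - x|_1  +  1e5 * jerk^2  +  1e-1 * (f.f + 3e-3 fdot.fdot)
+ 1e-5 * (h.h + 1e2 hdot.hdot)`, averaged over steps and episodes.  The goal
x* sits at the start position until the (true, undelayed) go time and at the
target afterwards; on catch trials it never moves.  All time-derivatives are
**per-step finite differences** (no division by dt): jerk is the third
difference of endpoint position with the leading edge replicated, and force/
hidden derivatives are first differences (the hidden derivative uses the
real h_0 as its first predecessor).  The per-step convention matters: with
SI-scaled derivatives the printed weights would make any movement's jerk
term ~1e7 times larger than the position term and the optimal policy would
be to never move — which is exactly what calibration runs showed.  With
per-step differences the terms are balanced and the networks reach.

### Training regimes

*Growing up*: Adam (lr 3e-3) on batches of random point-to-point reaches,
start and target uniform in joint space (inside the limits, 0.15 rad
margin), 50% catch trials, go cue uniform on 100-300 ms, 1 s episodes.
*Experimental phases*: plain batch-local SGD (lr 5e-3) on centre-out batches
(equal repetitions of 8 targets at 0.1 m, shuffled, 50% catch).  After
growing up, the input map, output map, both their biases and h_0 are frozen;
only the recurrent weight blocks and recurrent gate biases remain plastic.
No gradient clipping anywhere; divergence raises.

Gradients are computed by a hand-written reverse-mode adjoint of the entire
rollout (GRU, muscle dynamics, rigid-body dynamics, curl field, delay
queues, loss).  The forward pass is written against a pluggable array
module, and the test suite verifies the manual adjoint against an automatic-
differentiation trace of the same forward pass (agreement ~1e-14 relative)
and against central finite differences.  All arrays carry an optional
leading ensemble axis, so the whole seed ensemble trains in one vectorized
pass.

## The experiment

NF1 (baseline, b = 0) -> FF1 (adaptation, b = +8) -> NF2 (washout, b = 0)
-> FF2 (re-exposure, b = +8).  The opposite-field control replaces FF1's
gain with -8.  Growing up and NF1 contain no field and are shared between
conditions.  No observation entry encodes the field: the only route from
gain to controller is through the arm's motion (asserted structurally in the
tests).  Per training batch the mean signed lateral deviation of the
non-catch reaches is logged before that batch's update, so entry 0 of each
phase's curve is true batch-0 performance.

Analysis rollouts use dedicated 1.5 s episodes with the go cue at 0.5 s,
because a training episode (go before 0.3 s) cannot host the preparatory
sample 340 ms before the go cue.  Preparatory activity H (8 targets x units)
is the hidden state at go - 340 ms; the force matrix F (8 x 2) is the
muscle-generated endpoint force (field excluded) at go + 90 ms, around peak
acceleration.

Targeted dimensionality reduction solves `H_NF1 = [F 1] W` by least squares,
takes the first two columns of `pinv(W)` (SVD cutoff 1e-12, intercept
ignored) and Gram-Schmidt-orthonormalizes them in column order.  The uniform
shift is `mean(H_FF1) - mean(H_NF1)` over targets, orthogonalized against
that plane.  Projections of each phase's target-mean activity (minus the
grand mean over the 4 phases x 8 targets entering the comparison) onto the
shift are affinely rescaled so NF1 -> 0 and FF1 -> 1.  The perturbation
experiment adds `m * us` (m = -2..+2) to the hidden state for exactly one
step at go - 340 ms, separately per target, on the post-washout (FF2
batch-0) checkpoint, and measures lateral deviation in the trained field.

## Learning-curve fits and savings

Curves are smoothed with a centred 5-batch moving average (edge-shortened
windows keep the length), then `y = alpha * exp(-r x / 1000)` is fitted by
nonlinear least squares; r is unbounded so a worsening curve fits with
r < 0.  Rate savings: r(FF2) > r(FF1); deviation savings: FF2 batch-0
deviation < FF1 batch-0 (strict; ties are no savings).  Savings percentages
carry Wilson 95% intervals; paired comparisons use the paired t test.

## Desk scale

The full-scale protocol (128 units, 40 seeds, 20,000 growing-up batches of
32, NF phases 10,000 / FF phases 3,200 batches of 32) needs cluster-scale
compute.  The shipped preset (`fixtures.tiny_config`) is the configuration
every analysis script, the end-to-end tests and the acceptance script use:
**48 units, 5 seeds, growing up 2,600 batches of 16, NF1 400 / FF1 320 /
NF2 800 / FF2 320 batches of 16.**  Everything not listed there keeps its
full-scale value (step size, episode length, delays, loss weights, learning
rates, field gain, catch fraction, go-cue window, target layout).  One full
study (both conditions plus analyses) runs in roughly 12 minutes on one CPU.
At this scale the qualitative phenomenology is reproduced: baseline reaches
are straight to ~1-2 mm, the first field exposure deflects them ~60-75 mm,
washout shows a mirror-image after-effect and returns to baseline within a
fraction of a millimetre, re-exposure starts ~10-15 mm better than naive
exposure (deviation savings in all 5 seeds; rate savings in 3 of 5), the
opposite-field control abolishes deviation savings, and the normalized NF2
uniform-shift projection lies strictly between 0 and 1 in every seed
(mean ~0.26, one-sample t(4) ~ 3.3).

## Synthetic fixtures

`fixtures` plants ground truth for every analysis stage without training:
activity matrices built as `[F 1][M; c]` plus a shift s orthogonal to
span{M rows, c} (so the fitted TDR plane — which mixes the intercept —
cannot absorb it), a washout fraction w, and i.i.d. Gaussian noise scaled
relative to the signal norm; half-sine arcs whose peak signed excursion is
exactly the requested deviation; exponential curves with known (alpha, r).
What fixtures do not emulate: trained-network temporal dynamics, feedback
corrections inside a reach, or any coupling between behavior and hidden
state — those are exercised only by the real desk-scale runs, so planted-
recovery results validate the estimators, not the simulation.

## Numerical choices and known limitations

* Pseudo-inverse cutoff 1e-12; Gram-Schmidt order: first column normalized
  first.  Rank-deficient regressors and zero shifts raise instead of
  returning garbage.
* The exponential fit starts from (alpha = first smoothed value, r = 1) and
  flags non-convergence instead of raising.
* Adaptation slightly overshoots at desk scale (end-of-FF curves cross a few
  mm past straight); the deviation metric takes the largest-magnitude
  excursion after the go cue, so S-shaped corrected paths report their
  dominant lobe.
* The one-step hidden-state injection contracts strongly through the
  preparatory dynamics of most desk-scale networks (the displacement decays
  by 2-3 orders of magnitude over the 340 ms before the go cue), so the
  behavioral dose-response is weak — clearly monotone in some seeds, flat to
  within microns in others.  The ordering checks therefore treat sub-10-um
  differences as ties.  Longer-trained networks are expected to retain the
  displacement (and show the strong dose-response) because their preparatory
  dynamics are closer to neutral along the shift; verifying that requires
  full-scale training.
* The t statistics reported at desk scale use 5 seeds (df = 4) and are
  qualitative; the full-scale protocol uses 40 seeds (df = 39).
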