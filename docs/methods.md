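# Methods

## The model

The network is a convergent recurrent ConvNet: a static input `x` drives a
stack of convolutional layers (each a stride-1 convolution with optional
non-overlapping max pooling) below zero or more fully connected layers, and
the layer states `s^1 .. s^N` evolve under a synchronous discrete-time map
until they reach a fixed point `s_*` that serves as the prediction.

With **bidirectional** (shared) weights the dynamics derive from a scalar
primitive

    Phi(x, {s}) = sum_n  s^{n+1} . P(w_{n+1} * s^n + b_{n+1})    (conv layers)
                + sum_n  s^{n+1}^T (w_{n+1} s^n + b_{n+1})       (fc layers)

where `P` is max pooling and `.` the elementwise tensor scalar product.  One
step of every layer is

    s^n  <-  sigma( P(w_n * s^{n-1} + b_n)  +  w~_{n+1} * P^{-1}(s^{n+1}) )

with `sigma` the hard sigmoid `min(1, max(0, x))`, `w~` the transposed
(flipped-kernel) convolution, and `P^{-1}` the inverse pooling that scatters
the upper layer's activity to the argmax positions recorded by the *same
step's* bottom-up pooling pass.  States therefore stay in `[0, 1]` by
construction.  With **unidirectional** coupling the top-down drive uses
independent backward weights of the same shapes (no biases), and the dynamics
are a general transition map `F` with no primitive.

Two output couplings are implemented:

* **Squared error, output layer in the dynamics** — the topmost layer has one
  unit per class; the nudged phases add `beta (y - y_hat)` to its
  pre-activation.
* **Cross-entropy, softmax readout** — a matrix `w_out` reads the top layer;
  the prediction `softmax(w_out s_top)` is outside the dynamics, and nudging
  injects `beta w_out^T (y - y_hat_t)` into the top layer.  This removes one
  layer from the recurrent relaxation.

## Gradient estimators

Equilibrium propagation estimates the loss gradient from steady states only:

* **one-sided** (two phases): `(dPhi/dtheta(s_*^b) - dPhi/dtheta(s_*)) / b`;
  biased at first order in the nudging strength `b`.
* **symmetric** (three phases, at `+b` and `-b`, both started from `s_*`):
  `(dPhi/dtheta(s_*^{+b}) - dPhi/dtheta(s_*^{-b})) / 2b`; the `O(b)` term
  cancels, leaving an `O(b^2)` bias.  It equals the average of the two
  one-sided estimates *exactly* (an algebraic identity the tests assert at
  1e-12 relative).
* **random sign**: one-sided with the sign of `b` drawn uniformly; unbiased
  to first order in expectation but with the full first-order term as noise —
  by far the highest-variance member of the family.
* **vector field (VF)**: `(dF/dtheta)^T(x, s_*, theta) (s_*^b - s_*) / b` for
  dynamics without a primitive; forward and backward weights receive distinct
  updates.  `sym_vf` is its three-phase symmetrization.
* **Kolen-Pollack VF (kp_vf)**: per slot `i` in {forward, backward},
  `VFbar_i = [(dF/dtheta_i)^T(s^{+b}) s^{+b} - (dF/dtheta_i)^T(s^{-b}) s^{-b}] / 2b`;
  the *shared* estimate `(VFbar_f + VFbar_b)/2` is applied identically to both
  slots together with an equal leakage `-lambda theta`.  With plain SGD one
  step contracts `theta_f - theta_b` by exactly `(1 - lr*lambda)`, so forward
  and backward weights converge to each other while training; pooling and
  unpooling share argmax index maps, which is the only information exchanged
  between the two pathways.

`dPhi/dtheta` at fixed states has the closed local form: an outer product of
adjacent layer states for fc weights, and for conv kernels the correlation of
the upper state scattered through the pooling argmax with the lower state.
All `(dF/dtheta)^T v` and `(dF/ds)^T v` contractions are analytic
vector-Jacobian products written against the same conv/pool primitives.

## The BPTT oracle

Truncated backprop-through-time gradients `grad_BPTT(t)` are computed under
the convergence hypothesis `s_{T-t} = ... = s_T = s_*`: every Jacobian is
evaluated at the steady state, so the adjoint recursion

    a <- dloss/ds(s_*);   g += (dF/dtheta)^T a;   a <- (dF/ds)^T a

needs no stored trajectory (O(1) memory in `t`).  The oracle returns the
loss-decreasing direction `-g`, directly comparable with EP estimates.  The
truncation convention — the first accumulated term is the loss adjoint pushed
through one parameter contraction — is immaterial at an exact fixed point,
which is why all oracle uses require residuals below 1e-10.  The oracle is
itself validated in the tests against central finite differences of the
steady-state loss (1e-5 relative on sampled coordinates, both losses).

The **GDU curves** place, for t = 1..K, the one-sided (both signs) and
symmetric EP estimates read off after t nudged steps next to `grad_BPTT(t)`.
The per-group deviation statistic is
`max_t RMS(ep_sym[t] - bptt[t]) / max_t RMS(bptt[t])`, normalized by the
largest oracle magnitude so early near-zero entries do not inflate the ratio.

## Subgradient and tie conventions

* Hard-sigmoid derivative: 1 on the open interval (0, 1) of the
  pre-activation, 0 at saturation (a measure-zero convention at the kinks).
* Max-pooling argmax maps are treated as locally constant in all derivatives
  (valid almost everywhere); ties resolve to the first index, deterministically.
* Nudging is injected *inside* the activation (on the pre-activation), so
  nudged states also remain in [0, 1].
* Residual denominators carry eps = 1e-12; free phases start from the all-zero
  state, nudged phases from the supplied free steady state.

## Smoothness and the bias-order measurements

The `O(b)` / `O(b^2)` error laws hold only while the map `b -> s_*^b` is
smooth.  With a hard sigmoid that fails exactly when a nudged phase pushes
some unit across an activation kink (saturation boundary); empirically the
fitted orders degrade one-for-one with such crossings.  Two design choices
keep the measurement in the smooth regime over the scan grid
`b in {0.2, 0.1, 0.05, 0.025}`:

* the `fc_small` fixture uses weak couplings (Kaiming weights scaled by 0.35)
  and mid-range biases U(0.42, 0.58), giving every unit a saturation margin at
  the free and nudged steady states — verified to produce zero crossings and
  orders 0.90-0.92 / 2.02-2.03 across 16 fixture seeds;
* the scalar fixture's scan draws inputs `x ~ U(0.55, 0.95)`, for which both
  nudged fixed points `(0.5 x +- b)/(1 +- b)` are provably interior for
  `|b| <= 0.2`.

With cross-entropy nudging the crossing-free range is narrower (readout
pull-back can push near-zero units active at `b >~ 0.05` on some seeds), so
order measurements use the squared-error coupling; the GDU comparison at
`b = 0.01` is unaffected.

## Fixtures and synthetic data

`make_fixture_net` builds three reference networks: `scalar` (one weight,
closed-form fixed point), `fc_small` (two 16-unit fc layers on 1x4x4 inputs)
and `conv_small` (two 3x3 conv layers, 8 and 16 channels, zero-padding 1,
2x2 max pooling, on 1x8x8 inputs — a reduced-width analogue of the
full-scale architecture this package targets: four conv layers at 128-512
channels on 32x32 images).  At
construction the spectral norm of the linearized step map (activation slope 1,
pooling indices frozen at a reference state) is estimated by power iteration
on `A^T A` and all recurrent weights are rescaled until it is below 0.8, so
the free phase is a certified contraction and the fixed-point hypotheses of
the estimator results hold on every fixture.

`make_toy_images` generates the training task: per class a fixed Gaussian
spatial template; samples are `clip(0.5 + 0.12 (snr * template + noise), 0, 1)`
with unit Gaussian pixel noise.  Defaults: 4 classes, 1x8x8 images, 256
train / 256 test, `template_snr = 3` — linearly separable by construction (a
least-squares classifier exceeds 95% test accuracy, asserted in the tests).
What this emulates: a small, easy, balanced image classification task with a
tunable Bayes margin.  What it does not emulate: natural-image statistics,
intra-class pose/texture variability, class imbalance, or input dimensions
where depth matters.  Training results here show that the estimators optimize
what they should at desk scale; they do not predict absolute accuracy on
natural images.

## Training recipe and desk-scale conditions

The training loop implements the standard EP ConvNet recipe: per batch a free phase of `T` steps from
zeros, one or two nudged phases of `K` steps from `s_*`, a gradient *ascent*
step on the estimate (the estimate approximates `-dL/dtheta`) with per-layer
learning rates, SGD momentum 0.9, decoupled weight decay 3e-4 applied to all
parameters including `w_out`, and cosine annealing from the initial rates to
1e-5.  The readout is trained with its local rule
`Delta w_out = lr (y - y_hat_*) s_top^T` at the free steady state.  Momentum
buffers are zero-initialized and never reset.

Desk-scale conditions (chosen once): `T = 30`, `K = 10`, batch 64, per-layer
rates (0.25, 0.15, 0.1), `beta = 0.5` for the squared-error coupling and
`1.0` for cross-entropy, 10 epochs
with a 10-epoch cosine decay, and `lambda = 0.5` for kp_vf (chosen so the
leakage time-constant is commensurate with the ~40 optimizer steps of a
desk-scale run).  Dropout
(probability `p`, inverted scaling, one mask per sample on the layer above
the conv stack, frozen across all time steps and phases of a batch) is
available but off by default.

At this scale the qualitative contrasts expected from full-scale runs
reproduce as follows: symmetric EP trains to ~0% error where one-sided EP is worse on
average and unstable on some seeds, and random-sign EP has by far the largest
seed-to-seed variance; kp_vf drives alignment angles from ~90 deg toward
~25-30 deg while sym_vf leaves them near their random values.  One contrast
does *not* reproduce: sym_vf still reaches low error here, because with a
single backward-weighted layer and a linearly separable task, misaligned
feedback still carries enough signal; the catastrophic failure of sym_vf at
full scale is a depth effect.  Tests therefore assert the alignment contrast, not
an error ordering, for sym_vf.

## Numerical choices

* Everything is float64; the identity and contraction checks rely on it.
* Evaluation runs the free phase only, with the training `T`.
* Kaiming-uniform fan-in initialization (`U(+-1/sqrt(fan_in))`) everywhere;
  backward weights are initialized independently of their forward partners.
* Checkpoints are HDF5 with an embedded JSON architecture descriptor and
  round-trip bit-exactly.
* All randomness flows through explicitly passed `numpy` Generators; training
  is bit-deterministic given the config seed (asserted by rerunning the CLI).

## Known limitations

* Truncated nudged phases: `K` fixed steps, no stopping tolerance; at `K = 10` the nudged states on the
  fixtures are converged to well below the estimator bias being measured.
* The hard-sigmoid kink makes every quantity piecewise-smooth in `beta`;
  measurements that rely on Taylor expansions are only valid in the
  crossing-free regime documented above.
* No data augmentation, no continual (within-phase) weight updates, no
  asynchronous or continuous-time dynamics.
* `alignment_angle` compares flattened kernels by cosine similarity — the
  conventional way such alignment curves are computed.
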