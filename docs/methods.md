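# Methods

This note records the scientific and numerical choices behind the simulator:
what is modelled, which constants matter, what the synthetic benchmark does
and does not show, and where the model's approximations are visible in the
package's own diagnostics.

## Device model

A synaptic device is one scalar state — its normalized conductance
g ∈ [g_min, g_max] (defaults 0 and 1).  The LTP (erase) and LTD (program)
branches are logarithmic in cumulative pulse time,
G(t) = a ± (1/β)·ln(t + c), and a pulse of width Δt is applied by mapping
the current g to the equivalent cumulative time on the *target* branch
(`invert_ltp`/`invert_ltd`), advancing by Δt, and reading back.  The paper
trail for how a device moves between the two fitted branches is the standard
behavioural-model convention; it keeps state one scalar and makes pulse
application exactly associative on a single branch.

Two parameterizations:

* **fitted** — the coefficients measured on fabricated GSDs
  (a_LTP = 2.270, c_LTP = 0.0278, β_LTP = 1.60; a_LTD = 1.422,
  c_LTD = 18.25, β_LTD = 8.03), time in seconds.  These constants do not
  span [0, 1] on a common time axis (the unclamped LTD value at t = 0 is
  ≈ 1.06, clamped to 1).
* **pinned** — β is the only shape parameter; c = t_max/(e^β − 1) and a are
  solved so the curve passes exactly through (0, g_min) and (t_max, g_max)
  (LTD mirrored).  All non-linearity and asymmetry sweeps use pinned curves
  so every β shares one conductance range.  As β → 0 the pinned curve
  converges to the straight line t/t_max (sup-norm ≤ 1e-3 at β = 1e-3),
  which is the "linear device" used for topology studies.

**Time units.**  The absolute time axis of the fitted constants is not
fixed by the source data, so the package adopts t_max = 0.1 s — the
full-range LTP time implied by the fitted coefficients (G reaches 1 at
t ≈ 0.103 s) — as the default full-scale pulse budget in pinned mode.
Under this convention the pulse-width constants λ_UP (50 µs/V into the
output layer, 500 µs/V elsewhere) give per-sample weight steps of order
10⁻³–10⁻² of the weight range, a conventional learning-rate scale.

**Non-idealities.**

* *Pulse-to-pulse variation*: every conductance increment is multiplied by
  a Normal(1, σ/μ) draw, untruncated except by the global [g_min, g_max]
  clamp — at σ/μ = 2 an individual update can flip sign, which is the
  stress regime of the robustness studies.
* *Device-to-device variation*: each device's β is drawn once from
  Normal(β, σ_d2d·β), truncated below at 10⁻³; in pinned mode (a, c) are
  re-derived per device so all devices still span the same range.
* *Stuck-at-off*: a uniformly chosen fraction of devices is frozen at
  g_min and ignores all pulses; exactly round(f·N) devices per grid, so
  small test arrays have deterministic stuck counts.

**Curve fitting.**  `fit_conductance_curve` exploits that G is linear in
(a, 1/β) given c: a bounded 1-D search on log₁₀(c) with an exact inner
least-squares solve.  This is immune to the poor conditioning of joint
3-parameter fits on log-time data; on noiseless self-generated curves it
recovers (a, β, c) to better than 10⁻⁴ relative, and to ≤ 10 % at 5 %
multiplicative noise on 50 points.

## Network and neuron

Pure integrate-and-fire with soft reset: v ← v + q each step; if v > V_th
(0.1 V) the neuron spikes once, v ← v − V_th.  No leak, no refractory
period, no lower clamp on v; membranes, derivative bits, last-step spike
bits and counters reset to zero for every new presentation.  Within a time
step, spikes traverse all layers (layer l+1's charge at step t uses layer
l's spikes at step t).

`q_scale` converts a crossbar read (normalized conductance × spikes) into
membrane volts.  It absorbs the 3 V / 10 µs spike driving ~1 nA of
full-scale device current (10 fC) into the membrane capacitance: 40 fF in
hidden/output layers (0.25 V per unit weight per spike) and 4T fF in the
input layer (2.5/T V), so the total charge a pixel injects over a
presentation is independent of T.

Readout scores each output neuron by its threshold-restored integrated
drive v(T) + V_th·count (raw v(T) is a config option), argmax with ties to
the lowest index.  Poisson encoding draws a fresh train for every
presentation, including repeat presentations of the same image.

## Learning rule

Output deltas δ_j = k·Σ_t(Target_j − S_j) with k = 1/T, so a silent neuron
under an always-firing target reaches exactly 1 V — the pulse-width
modulator's full scale; hidden deltas are clipped to the same ±1 V
(`delta_clip`), a bound the source hardware implies but does not state.
The backward gain κ_BP (λ_BP/C_BP and read conditions collapsed to one
dimensionless factor) defaults to 1.  Updates are applied after each
sample's complete forward/backward pass; batch mode (e.g. 100) accumulates
*signed pulse widths* over the batch and applies the averaged widths once —
the minimal-memory reading of batched training on this hardware.  The λ_UP
schedule rescales both layers' λ from the start of the configured epoch.

**Case 1 vs Case 2.**  At every iteration the trainer records the update
sum actually applied (Case 1, 1-bit S(T)) and the counterfactual with
S(T) → count/T (Case 2), both in linear-equivalent weight units
(signed width × 2/t_max) on the same presentation, before the update.
For the input layer S(T) is an exact Bernoulli draw of the pixel intensity,
so E[Case 1] = E[Case 2] exactly.  For hidden neurons the equality is
approximate: a membrane starting from zero needs ~1/rate steps before its
first spike, so spikes are back-loaded within the presentation and
E[S(T)] exceeds E[count]/T by O(1/T) per active neuron.  The package's own
diagnostics quantify this: the mean hidden-layer Case-1 − Case-2 difference
on a frozen network shrinks roughly ∝ 1/T (≈ 4.5×10⁻⁴ at T = 10 to
≈ 3.5×10⁻⁵ at T = 100 under the default trace conditions) and at T = 20 is
resolvable against a 99 % Monte-Carlo CI at 500 presentations.  This is a
real property of reset-per-sample I&F dynamics, not an artefact; the
corresponding acceptance test asserts strict statistical equality per layer
and is therefore expected to fail on the hidden layer at the default study
conditions, with the decay-in-T property test documenting the mechanism.

**Relation to gradients.**  In the unsaturated rate regime (all rates
strictly inside (0, 1)) the expected update direction E[S_i(T)·δ_j]
reproduces the backpropagation gradient of the equivalent rate-coded ReLU
network up to positive per-layer scale; the acceptance suite measures
Pearson r > 0.99 per layer against finite-difference gradients on a toy
network constructed in that regime.  At the rate clips the analytic
gradient vanishes while the spike rule keeps pushing — one reason the rule
is *approximated* backpropagation.

## Off-chip baseline (ANN-to-SNN conversion)

`reference_ann` trains a bias-free fully connected ReLU network (linear
output, MSE against one-hot targets, minibatch Adam with step 0.01) —
bias-free so each weight maps onto one differential pair.
`offchip_transfer` writes the weights once onto the LTP curve: positive
weights set G⁺ (G⁻ at g_min), negative mirrored.  When the source network
and training data are available the weights are first *rate-normalized*
per layer (divided by the layer's maximum training activation relative to
the previous layer's, with the q_scale/V_th gain folded in) — the standard
data-based normalization of the conversion literature.  A plain global
max-|W| scaling is used when only raw weights are given, but it drives
hidden rates into saturation (one spike every step) and costs tens of
accuracy points, which is why normalization is the default.  Non-idealities
enter exactly once: pulse-to-pulse noise multiplies each transferred
increment; device-to-device variation is modelled as *write with the
nominal curve, realize with the device's own β*; stuck devices stay off.

## Synthetic benchmark

The generator emulates the structure of an image-classification task with
none of its distributional quirks: each of 3 classes owns a disjoint
horizontal band of an 8×8 frame at intensity 0.65 over a 0.35 background,
plus additive uniform pixel noise U(−0.5, 0.5), clipped to [0, 1].  The
contrast/noise combination was chosen so the per-pixel signal and
background distributions overlap and the desk-scale baseline lands in the
high 90s rather than at 100 % — a saturated stand-in would be unable to
discriminate device-robustness effects.  At noise 0 the task is exactly
nearest-prototype separable.  Default splits: 100 train / 50 test images
per class, drawn from independent sub-seeds.

What passing desk-scale tests shows: that the learning rule, device
physics, update selectivity, and robustness *orderings* (linear ≥ β = 8;
on-chip degrades less than off-chip under pulse noise; accuracy
non-decreasing in T) behave as designed.  What it does not show: absolute
MNIST-scale accuracy figures, which depend on 784-dimensional inputs,
10-way confusions, and long training — those runs are opt-in
(`scripts/mnist_repro.py`) and need the external IDX files.

Desk-scale problem sizes used by the test suite: 64-16-3 networks, T = 20,
20 epochs for the end-to-end learning check and 8 epochs per point for
sweep orderings, 5 replicates per sweep point with independently derived,
logged 31-bit seeds.

## Numerical and API conventions

* All randomness flows through `numpy.random.Generator` objects seeded
  from config; identical seeds give bit-identical runs (spike trains,
  sweep tables, traces).
* Device state updates are vectorized over whole grids; update order
  within a parallel update phase is immaterial because pulses act
  per-device.
* Degenerate inputs fail loudly: negative times/widths, intensities
  outside [0, 1], non-reset layer states, shape mismatches, constant
  fit data, all-zero transfer weights, unknown config keys.
* Output files are written atomically (temp file + rename); run configs
  echo as JSON next to every output.

## Known limitations

* No electrical simulation: IR drop, sneak paths, read noise and I–V
  physics are out of scope (the GSD's current saturation is the hardware
  argument for ignoring read-path drops).
* No leak/refractory neuron variants, no dropout/L2 regularization, no
  convolutional or recurrent extensions.
* The Case-1/Case-2 start-up-transient bias above: the 1-bit update is an
  unbiased surrogate for the count-based update only in the stationary
  limit T → ∞ (or for the Bernoulli-coded input layer).
* Hidden-delta clipping at ±1 V and κ_BP = 1 are conventions exposed in
  config, not measured hardware values.
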