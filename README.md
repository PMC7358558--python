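# gsdsnn

Simulator of **on-chip supervised training for hardware spiking neural
networks (SNNs) built from analog synaptic devices** — specifically
gated Schottky diodes (GSDs), three-terminal devices whose saturated reverse
Schottky current encodes a weight and whose conductance is tuned
continuously by program/erase pulses.

It is aimed at neuromorphic-hardware researchers who want to evaluate, before
committing to silicon, how a learning rule that stores only **2 bits per
neuron** behaves on crossbar arrays with realistic device non-idealities:
LTP/LTD non-linearity and asymmetry, pulse-to-pulse and device-to-device
variation, and stuck-at-off faults.

## The model

**Synapse.** Each weight is a differential pair, `W_ij = G⁺_ij − G⁻_ij`, of
normalized conductances in [0, 1].  A device's response to cumulative pulse
time *t* is logarithmic,

```
G_LTP(t) = a_LTP + (1/β_LTP) · ln(t + c_LTP)      (erase pulses,  G rises)
G_LTD(t) = a_LTD − (1/β_LTD) · ln(t + c_LTD)      (program pulses, G falls)
```

with non-linearity factor β (β → 0 is a linear device; the measured GSD has
β_LTP ≈ 1.60, β_LTD ≈ 8.03).  Crossbar updates are *parallel*: DC biases on
the gate lines select rows, pulse-width-modulated program/erase pulses on
the source lines carry per-column amplitudes, and only cells where
|V_BG − V_S| reaches the program (5.5 V) or erase (7 V) condition change.

**Neuron.** Integrate-and-fire with threshold V_th = 0.1 V and soft reset;
inputs are Poisson rate-coded over T time steps (a pixel of intensity p
spikes each step with probability p).  Rate-coded I&F neurons approximate a
ReLU: output rate ≈ clipped-linear function of input rates.

**Learning rule (approximated backpropagation).**  Per presentation:

1. *Forward:* T spiking steps; each neuron records a 1-bit derivative
   `g = 1` if it ever spiked, and its last-step spike bit `S(T)`.
2. *Output deltas:* `δ_j = k · Σ_t (Target_j(t) − S_j(t))`, with the target
   firing every step for the correct label and `k = 1/T` (so |δ| ≤ 1 V).
3. *Backward:* deltas propagate through the same crossbars (transposed
   read), gated by the derivative bits.
4. *Update:* pulse widths `Δt_ij = |S_i(T) · λ_UP · δ_j|` (λ_UP = 50 µs/V
   into the output layer, 500 µs/V elsewhere); the sign of `S_i(T)·δ_j`
   chooses erase-G⁺/program-G⁻ (weight up) or the mirror image.

Because a neuron spikes each step with probability ≈ its activation, the
1-bit `S(T)` update equals the spike-count update in expectation — the
simulator traces both ("Case 1" vs "Case 2") at every iteration.

The off-chip baseline (`convert`) trains a conventional bias-free ReLU
network and transfers its weights once onto the LTP curve, picking up each
device non-ideality a single time instead of at every update.

## Worked example

Train the built-in synthetic 3-class task (8×8 images, 64-16-3 network,
T = 20) on GSD-like devices (β_LTP = 1.60, β_LTD = 8.03):

```python
from gsdsnn.data_io import RunConfig
from gsdsnn.experiments import single_run

cfg = RunConfig(device_mode="pinned", beta_ltp=1.60, beta_ltd=8.03,
                epochs=5, seed=42)
acc, trace = single_run(cfg, "onchip", seed=42, return_trace=True)
print(trace.summary())
```

prints

```
On-chip training trace
  iterations: 1500
  weight layers: 2
  epoch   1: test accuracy 65.33%  lambda_scale 1
  epoch   2: test accuracy 93.33%  lambda_scale 1
  epoch   3: test accuracy 98.67%  lambda_scale 1
  epoch   4: test accuracy 99.33%  lambda_scale 1
  epoch   5: test accuracy 99.33%  lambda_scale 1
```

i.e. 1500 single-sample update phases (300 training images × 5 epochs) carry
the network from chance (33%) to 99.3% test accuracy, learning *through* the
asymmetric non-linear device physics.  `trace.case1`/`trace.case2` hold the
per-iteration 1-bit vs spike-count update sums.

The same entry points drive the command line:

```bash
gsdsnn train --dataset synthetic --epochs 5 --seed 42 --out runs/demo
gsdsnn sweep --param sigma_p2p --values 0,0.5,1,2 --regime offchip
gsdsnn bias-table --kind program      # the 2×2 update-selectivity table
gsdsnn fit-device curve.csv           # fit (a, β, c) to measured data
```

Full-scale MNIST runs (784-256-10 and deeper; hours of CPU) are opt-in via
`scripts/mnist_repro.py --mnist-dir <dir with IDX files>`; see its `--help`.

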