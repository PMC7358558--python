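"""On-chip supervised training with approximated backpropagation.

The learning rule stores only 2 bits per neuron.  After the forward phase:

* Output deltas accumulate target-vs-output spike differences,
  delta_j^L = k * sum_t (Target_j(t) - S_j(t)), with the target train firing
  every step for the correct label and never otherwise.  k = 1/T maps the
  largest possible difference (T spikes) to a 1 V full scale.
* Hidden deltas propagate backwards through the same crossbars (transposed
  read), gated by the 1-bit derivative g of each neuron, and are clipped to
  the pulse-width modulator's full scale.
* The update phase turns deltas into pulse widths,
  dt_ij = |S_i(T) * lambda_UP * delta_j|, using the pre-synaptic neuron's
  1-bit last-time-step spike S(T) in place of its spike count; the sign of
  S_i(T)*delta_j picks erase-G+/program-G- (weight up) or the mirror (down).

Because a neuron spikes at each step with probability proportional to its
activation, E[S(T)] equals its rate, so the expected update matches the
spike-count rule.  The trainer records both at every iteration: "Case 1" is
the applied 1-bit-rule update sum, "Case 2" the counterfactual sum with
S(T) replaced by spike_count/T; Case 1 fluctuates around Case 2.

Also here: the off-chip baseline — a conventionally trained ReLU network
(`ReLUMLP`) whose weights are transferred once onto device conductances
along the LTP curve (`offchip_transfer`), picking up each non-ideality a
single time instead of at every update.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import crossbar, network
from .crossbar import BiasScheme, SynapseArray, UpdateSchedule
from .device_model import NO_VARIATION, VariationConfig, invert_ltp, g_ltp
from .network import NetworkConfig, forward_pass, poisson_encode, readout

__all__ = [
    "TrainConfig",
    "TrainTrace",
    "target_train",
    "output_delta",
    "backprop_deltas",
    "update_schedule",
    "train_step",
    "train",
    "evaluate",
    "offchip_transfer",
    "ReLUMLP",
    "reference_ann",
]


@dataclass(frozen=True)
class TrainConfig:
    """Learning-rule constants.

    k : spike-count-to-voltage constant (V per spike); None means 1/T so the
        maximum output delta is 1 V.
    kappa_bp : dimensionless backward-propagation gain (the pulse-width
        ratio over the delta-storage capacitance, collapsed).
    lambda_up : pulse width per volt of delta, per weight layer (s/V); None
        means the hardware defaults — 50 us/V into the last layer, 500 us/V
        elsewhere.
    lr_schedule : [(epoch, multiplier)] pairs; from the start of the given
        1-indexed epoch, lambda_up is multiplier x its initial value.
    delta_clip : clip level for |delta| in volts (modulator full scale).
    """

    k: float | None = None
    kappa_bp: float = 1.0
    lambda_up: tuple | None = None
    batch_size: int = 1
    epochs: int = 1
    lr_schedule: tuple = ()
    delta_clip: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k is not None and self.k <= 0:
            raise ValueError("k must be positive")
        if self.kappa_bp <= 0 or self.delta_clip <= 0:
            raise ValueError("kappa_bp and delta_clip must be positive")
        if self.batch_size < 1 or self.epochs < 0:
            raise ValueError("batch_size >= 1 and epochs >= 0 required")
        sched = tuple((int(e), float(m)) for e, m in self.lr_schedule)
        if any(m <= 0 for _, m in sched):
            raise ValueError("lr_schedule multipliers must be positive")
        object.__setattr__(self, "lr_schedule", sched)
        if self.lambda_up is not None:
            lam = tuple(float(x) for x in np.atleast_1d(self.lambda_up))
            if any(x <= 0 for x in lam):
                raise ValueError("lambda_up entries must be positive")
            object.__setattr__(self, "lambda_up", lam)

    def resolved_k(self, T: int) -> float:
        return 1.0 / T if self.k is None else self.k

    def resolved_lambda_up(self, n_weight_layers: int) -> tuple:
        if self.lambda_up is not None:
            if len(self.lambda_up) == 1:
                return self.lambda_up * n_weight_layers
            if len(self.lambda_up) != n_weight_layers:
                raise ValueError("lambda_up needs one entry per weight layer")
            return self.lambda_up
        return tuple([500e-6] * (n_weight_layers - 1) + [50e-6])


def target_train(label: int, num_classes: int, T: int) -> np.ndarray:
    """Supervision spike train: the correct label fires every step.

    Returns a (T, num_classes) binary train with row ``label`` all ones and
    every other row silent.
    """
    label = int(label)
    if not 0 <= label < num_classes:
        raise ValueError(f"label {label} outside [0, {num_classes})")
    if T < 1:
        raise ValueError("T must be >= 1")
    out = np.zeros((T, num_classes), dtype=np.int8)
    out[:, label] = 1
    return out


def output_delta(target: np.ndarray, output_spikes: np.ndarray, k: float) -> np.ndarray:
    """delta_j = k * sum_t (Target_j(t) - S_j(t)), in volts."""
    target = np.asarray(target, dtype=float)
    output_spikes = np.asarray(output_spikes, dtype=float)
    if target.shape != output_spikes.shape:
        raise ValueError("target and output trains must share a shape")
    return k * (target - output_spikes).sum(axis=0)


def backprop_deltas(
    arrays: list[SynapseArray],
    deriv_bits: list[np.ndarray],
    delta_L: np.ndarray,
    config: TrainConfig,
) -> list[np.ndarray]:
    """Propagate deltas backwards through the crossbars, gated by the bits.

    ``deriv_bits[k]`` belongs to layer k+2 (the post-synaptic layer of
    arrays[k]).  Returns one delta vector per non-input layer, ordered from
    layer 2 up to layer L, each clipped to +/- delta_clip.  Input-layer
    deltas are never formed.
    """
    L = len(arrays) + 1
    if len(deriv_bits) != len(arrays):
        raise ValueError("need derivative bits for every non-input layer")
    clip = config.delta_clip
    deltas = [np.clip(np.asarray(delta_L, dtype=float), -clip, clip)]
    for k in range(L - 2, 0, -1):  # arrays[k] maps layer k+1 -> k+2
        d = crossbar.backward_sum(deltas[0], deriv_bits[k - 1], arrays[k], config.kappa_bp)
        deltas.insert(0, np.clip(d, -clip, clip))
    return deltas


def update_schedule(
    last_spike_bits: np.ndarray, delta_next: np.ndarray, lambda_up: float
) -> UpdateSchedule:
    """Pulse widths and polarities for one weight layer.

    dt_ij = |S_i(T) * lambda_up * delta_j|; the polarity is the sign of
    S_i(T) * delta_j (positive -> weight grows: erase G+, program G-).
    Rows whose pre-synaptic neuron was silent at the last step get no pulse.
    """
    s = np.asarray(last_spike_bits, dtype=float)
    d = np.asarray(delta_next, dtype=float)
    signed = lambda_up * np.outer(s, d)
    return UpdateSchedule(delta_t=np.abs(signed), polarity=np.sign(signed))


def _signed_width_sums(s_bits, counts, T, delta, lambda_up, t_max, synapse=None):
    """Case-1/Case-2 update sums in linear-equivalent weight units.

    Case 1 uses the 1-bit last-step spikes, Case 2 the spike counts / T; the
    common factor 2/t_max converts a signed pulse width into the weight
    change a linear device pair would realize.
    """
    scale = 2.0 * lambda_up / t_max
    dsum = float(np.sum(delta))
    case1 = scale * float(np.sum(s_bits)) * dsum
    case2 = scale * float(np.sum(counts)) / T * dsum
    if synapse is None:
        return case1, case2, None, None
    i, j = synapse
    syn1 = scale * float(s_bits[i]) * float(delta[j])
    syn2 = scale * float(counts[i]) / T * float(delta[j])
    return case1, case2, syn1, syn2


def train_step(
    image,
    label: int,
    arrays: list[SynapseArray],
    net_config: NetworkConfig,
    train_config: TrainConfig,
    rng: np.random.Generator,
    scheme: BiasScheme | None = None,
    lambda_scale: float = 1.0,
    apply_updates: bool = True,
    trace_synapses: dict | None = None,
):
    """One FP/BP/UP cycle on a single sample.

    Runs the T-step forward phase on a fresh Poisson encoding, accumulates
    the output delta, gates the backward deltas, builds the pulse-width
    schedules from the 1-bit last-step spikes, and applies one parallel
    update per crossbar (unless ``apply_updates`` is False, which leaves the
    network frozen — used for the Case-1/Case-2 diagnostics).

    Returns ``(schedules, info)`` where info carries per-layer Case-1 and
    Case-2 update sums (computed on this presentation, before the update is
    applied), the per-traced-synapse sums, and whether the prediction was
    correct.
    """
    T = net_config.T
    num_classes = net_config.layer_sizes[-1]
    in_train = poisson_encode(image, T, rng)
    trains, states = forward_pass(arrays, in_train, net_config)

    k = train_config.resolved_k(T)
    target = target_train(label, num_classes, T)
    delta_L = output_delta(target, trains[-1], k)
    deriv_bits = [st.deriv_bit for st in states]
    deltas = backprop_deltas(arrays, deriv_bits, delta_L, train_config)

    lambda_up = train_config.resolved_lambda_up(len(arrays))
    t_max = arrays[0].params.t_max
    schedules, case1, case2, syn1, syn2 = [], [], [], {}, {}
    for l, arr in enumerate(arrays):
        if l == 0:
            s_bits = in_train[-1]
            counts = in_train.sum(axis=0)
        else:
            s_bits = states[l - 1].last_spike_bit
            counts = states[l - 1].spike_count
        lam = lambda_up[l] * lambda_scale
        schedules.append(update_schedule(s_bits, deltas[l], lam))
        syn = None if trace_synapses is None else trace_synapses.get(l)
        c1, c2, s1, s2 = _signed_width_sums(
            s_bits, counts, T, deltas[l], lam, t_max, synapse=syn
        )
        case1.append(c1)
        case2.append(c2)
        if syn is not None:
            syn1[l], syn2[l] = s1, s2

    if apply_updates:
        for arr, sched in zip(arrays, schedules):
            crossbar.parallel_update(arr, sched, scheme, rng)

    info = {
        "case1": case1,
        "case2": case2,
        "synapse_case1": syn1,
        "synapse_case2": syn2,
        "predicted": readout(states[-1], net_config),
        "correct": readout(states[-1], net_config) == int(label),
        "deltas": deltas,
        "states": states,
    }
    return schedules, info


@dataclass
class TrainTrace:
    """Results of a training run.

    Carries the per-iteration Case-1/Case-2 update sums per weight layer,
    per-epoch test accuracy, and the lambda_UP multiplier history.
    """

    case1: np.ndarray  # (iterations, n_weight_layers)
    case2: np.ndarray
    epoch_accuracy: list
    lambda_history: list
    synapse_case1: dict = field(default_factory=dict)  # layer -> series
    synapse_case2: dict = field(default_factory=dict)
    config: dict = field(default_factory=dict)

    @property
    def final_accuracy(self) -> float:
        return self.epoch_accuracy[-1] if self.epoch_accuracy else float("nan")

    def to_frame(self) -> pd.DataFrame:
        """Per-iteration trace as a tidy DataFrame."""
        n_it, n_layers = self.case1.shape
        rows = []
        for l in range(n_layers):
            rows.append(
                pd.DataFrame(
                    {
                        "iteration": np.arange(n_it),
                        "layer": l + 1,
                        "case1_sum": self.case1[:, l],
                        "case2_sum": self.case2[:, l],
                    }
                )
            )
        return pd.concat(rows, ignore_index=True)

    def summary(self) -> str:
        lines = ["On-chip training trace"]
        lines.append(f"  iterations: {self.case1.shape[0]}")
        lines.append(f"  weight layers: {self.case1.shape[1]}")
        for e, (acc, lam) in enumerate(zip(self.epoch_accuracy, self.lambda_history), 1):
            lines.append(f"  epoch {e:>3}: test accuracy {acc:6.2%}  lambda_scale {lam:g}")
        return "\n".join(lines)


def evaluate(
    dataset, arrays: list[SynapseArray], net_config: NetworkConfig,
    rng: np.random.Generator,
) -> float:
    """Classification accuracy over a dataset (one fresh encoding each)."""
    correct = 0
    for image, label in zip(dataset.images, dataset.labels):
        pred = network.run_inference(arrays, image, net_config, rng)
        correct += pred == int(label)
    return correct / len(dataset.labels)


def train(
    train_dataset,
    test_dataset,
    arrays: list[SynapseArray],
    net_config: NetworkConfig,
    train_config: TrainConfig,
    scheme: BiasScheme | None = None,
    rng: np.random.Generator | None = None,
    record_case_sums: bool = True,
    trace_synapses: dict | None = None,
    shuffle: bool = True,
) -> TrainTrace:
    """Run the full on-chip training loop, mutating ``arrays`` in place.

    Batch size 1 applies one parallel update per sample; larger batches
    accumulate signed pulse widths over the batch and apply the averaged
    widths once per batch.  ``lr_schedule`` entries rescale lambda_UP from
    the start of the given epoch.  Test accuracy is evaluated after every
    epoch.  Returns a TrainTrace.
    """
    if len(train_dataset.labels) == 0:
        raise ValueError("training dataset is empty")
    if rng is None:
        rng = np.random.default_rng(train_config.seed)
    n_layers = len(arrays)
    case1_rows, case2_rows = [], []
    syn1 = {l: [] for l in (trace_synapses or {})}
    syn2 = {l: [] for l in (trace_synapses or {})}
    epoch_acc, lam_hist = [], []
    lambda_scale = 1.0
    schedule_map = dict(train_config.lr_schedule)
    bs = train_config.batch_size

    for epoch in range(1, train_config.epochs + 1):
        if epoch in schedule_map:
            lambda_scale = schedule_map[epoch]
        order = np.arange(len(train_dataset.labels))
        if shuffle:
            rng.shuffle(order)
        batch_acc = None
        in_batch = 0
        for idx in order:
            schedules, info = train_step(
                train_dataset.images[idx],
                int(train_dataset.labels[idx]),
                arrays,
                net_config,
                train_config,
                rng,
                scheme=scheme,
                lambda_scale=lambda_scale,
                apply_updates=(bs == 1),
                trace_synapses=trace_synapses,
            )
            if record_case_sums:
                case1_rows.append(info["case1"])
                case2_rows.append(info["case2"])
                for l in syn1:
                    syn1[l].append(info["synapse_case1"].get(l, 0.0))
                    syn2[l].append(info["synapse_case2"].get(l, 0.0))
            if bs > 1:
                if batch_acc is None:
                    batch_acc = [
                        sched.polarity.astype(float) * sched.delta_t
                        for sched in schedules
                    ]
                else:
                    for acc, sched in zip(batch_acc, schedules):
                        acc += sched.polarity.astype(float) * sched.delta_t
                in_batch += 1
                if in_batch == bs:
                    _apply_batch(arrays, batch_acc, bs, scheme, rng)
                    batch_acc, in_batch = None, 0
        if bs > 1 and in_batch:
            _apply_batch(arrays, batch_acc, in_batch, scheme, rng)
        epoch_acc.append(evaluate(test_dataset, arrays, net_config, rng))
        lam_hist.append(lambda_scale)

    n_it = len(case1_rows)
    trace = TrainTrace(
        case1=np.asarray(case1_rows).reshape(n_it, n_layers),
        case2=np.asarray(case2_rows).reshape(n_it, n_layers),
        epoch_accuracy=epoch_acc,
        lambda_history=lam_hist,
        synapse_case1={l: np.asarray(v) for l, v in syn1.items()},
        synapse_case2={l: np.asarray(v) for l, v in syn2.items()},
        config={"epochs": train_config.epochs, "batch_size": bs,
                "seed": train_config.seed, "T": net_config.T,
                "layer_sizes": list(net_config.layer_sizes)},
    )
    return trace


def _apply_batch(arrays, signed_widths, batch_size, scheme, rng):
    for arr, sw in zip(arrays, signed_widths):
        mean = sw / batch_size
        sched = UpdateSchedule(delta_t=np.abs(mean), polarity=np.sign(mean))
        crossbar.parallel_update(arr, sched, scheme, rng)


# ---------------------------------------------------------------------------
# Off-chip baseline: conventional ReLU network + one-shot weight transfer
# ---------------------------------------------------------------------------


class ReLUMLP:
    """Bias-free fully connected ReLU network trained by minibatch SGD.

    The off-chip reference: hidden layers use ReLU, the output is linear,
    and the loss is mean squared error against one-hot targets (matching
    the spiking system's target-rate supervision).  Bias-free so each weight
    maps one-to-one onto a differential conductance pair.
    """

    def __init__(self, layer_sizes, rng=None, init_scale: float = 0.5):
        self.layer_sizes = tuple(int(n) for n in layer_sizes)
        if rng is None:
            rng = np.random.default_rng(0)
        self.weights = [
            rng.normal(0.0, init_scale / np.sqrt(a), size=(a, b))
            for a, b in zip(self.layer_sizes[:-1], self.layer_sizes[1:])
        ]

    def forward(self, X):
        """Activations per layer (input included)."""
        acts = [np.asarray(X, dtype=float)]
        for l, W in enumerate(self.weights):
            z = acts[-1] @ W
            acts.append(z if l == len(self.weights) - 1 else np.maximum(z, 0.0))
        return acts

    def predict(self, X):
        return np.argmax(self.forward(X)[-1], axis=1)

    def loss(self, X, Y_onehot):
        out = self.forward(X)[-1]
        return 0.5 * float(np.mean(np.sum((out - Y_onehot) ** 2, axis=1)))

    def gradients(self, X, Y_onehot):
        """Analytic gradients of the mean-squared-error loss per weight."""
        acts = self.forward(X)
        n = X.shape[0]
        delta = (acts[-1] - Y_onehot) / n
        grads = [None] * len(self.weights)
        for l in range(len(self.weights) - 1, -1, -1):
            grads[l] = acts[l].T @ delta
            if l > 0:
                delta = (delta @ self.weights[l].T) * (acts[l] > 0)
        return grads

    def fit(self, X, labels, epochs: int = 20, lr: float | None = None,
            batch_size: int = 32, rng=None, adam: bool = True):
        """Minibatch training; Adam by default (beta1=0.9, beta2=0.999).

        Default step size: 0.01 for Adam, 0.1 for plain SGD.
        """
        if lr is None:
            lr = 0.01 if adam else 0.1
        if rng is None:
            rng = np.random.default_rng(0)
        X = np.asarray(X, dtype=float)
        labels = np.asarray(labels, dtype=int)
        Y = np.eye(self.layer_sizes[-1])[labels]
        m = [np.zeros_like(W) for W in self.weights]
        v = [np.zeros_like(W) for W in self.weights]
        step = 0
        for _ in range(epochs):
            order = rng.permutation(len(labels))
            for start in range(0, len(labels), batch_size):
                sel = order[start:start + batch_size]
                grads = self.gradients(X[sel], Y[sel])
                step += 1
                for l, g in enumerate(grads):
                    if adam:
                        m[l] = 0.9 * m[l] + 0.1 * g
                        v[l] = 0.999 * v[l] + 0.001 * g * g
                        mh = m[l] / (1 - 0.9**step)
                        vh = v[l] / (1 - 0.999**step)
                        self.weights[l] -= lr * mh / (np.sqrt(vh) + 1e-8)
                    else:
                        self.weights[l] -= lr * g
        return self


def reference_ann(train_dataset, layer_sizes, epochs: int = 20,
                  rng: np.random.Generator | None = None, **fit_kw) -> ReLUMLP:
    """Train the conventional ReLU baseline and return it (weights exposed)."""
    if rng is None:
        rng = np.random.default_rng(0)
    model = ReLUMLP(layer_sizes, rng=rng)
    model.fit(train_dataset.images, train_dataset.labels, epochs=epochs,
              rng=rng, **fit_kw)
    return model


def _rate_normalized_weights(reference_weights, train_images, net_config):
    """Per-layer rescaling so ANN activations map onto spike rates <= 1.

    The classic data-based normalization for ANN-to-SNN conversion: each
    layer's weights are divided by the maximum activation it produces on the
    training data (relative to the previous layer's maximum), so the
    rate-coded network never saturates at one spike per step; the
    charge-to-voltage gain q_scale/v_th is folded in so a unit rate input
    yields exactly the normalized activation as an output rate.  Per-layer
    positive rescaling leaves the argmax readout unchanged.
    """
    acts = [np.asarray(train_images, dtype=float)]
    for l, W in enumerate(reference_weights):
        z = acts[-1] @ W
        acts.append(z if l == len(reference_weights) - 1 else np.maximum(z, 0.0))
    a_max = [max(float(a.max()), 1e-12) for a in acts]
    gains = [q / net_config.v_th for q in net_config.q_scale]
    return [
        W * (a_max[l] / a_max[l + 1]) / gains[l]
        for l, W in enumerate(reference_weights)
    ]


def offchip_transfer(
    reference_weights: list[np.ndarray],
    arrays: list[SynapseArray],
    variation: VariationConfig = NO_VARIATION,
    rng: np.random.Generator | None = None,
    net_config=None,
    train_images=None,
) -> list[SynapseArray]:
    """One-shot ANN-to-SNN weight transfer along the LTP curve.

    A positive weight sets G+ to the target conductance along the LTP curve
    with G- at g_min (negative weights mirrored).  When ``net_config`` and
    ``train_images`` are given, weights are first rate-normalized per layer
    (see `_rate_normalized_weights`) so the spiking network reproduces the
    ANN's activations as spike rates without saturating; otherwise a single
    global factor maps max|W| onto the full conductance range.  Either way,
    any layer whose weights exceed the representable range is scaled down by
    its own maximum (a positive per-layer factor, readout-invariant).

    The write is computed on the *nominal* LTP curve but realized with each
    device's effective beta, so device-to-device variation lands in the
    transferred conductance; pulse-to-pulse variation multiplies each
    transferred increment exactly once; stuck devices stay at g_min
    regardless of target.
    """
    if rng is None:
        rng = np.random.default_rng(variation.rng_seed)
    w_max = max(float(np.max(np.abs(W))) for W in reference_weights)
    if w_max == 0:
        raise ValueError("reference weights are all zero; nothing to transfer")
    if net_config is not None and train_images is not None:
        weights = _rate_normalized_weights(reference_weights, train_images, net_config)
        weights = [
            W if np.abs(W).max() <= 1.0 else W / np.abs(W).max() for W in weights
        ]
    else:
        weights = [np.asarray(W, dtype=float) / w_max for W in reference_weights]
    for W, arr in zip(weights, arrays):
        if W.shape != arr.shape:
            raise ValueError("reference weight shape does not match array")
        params = arr.params
        target = W * params.g_range  # |W| <= 1 here
        for grid, mag in ((arr.g_plus, np.maximum(target, 0.0)),
                          (arr.g_minus, np.maximum(-target, 0.0))):
            g_target = params.g_min + mag
            t_write = invert_ltp(g_target, params)  # nominal write pulse
            g_real = g_ltp(t_write, params, beta=grid.beta_ltp)
            inc = g_real - params.g_min
            if variation.sigma_p2p > 0:
                inc = inc * rng.normal(1.0, variation.sigma_p2p, size=inc.shape)
            grid.set_g(params.g_min + inc)
    return arrays
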