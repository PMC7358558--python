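"""Integrate-and-fire layers with Poisson rate coding.

Inputs are presented for T time steps; each pixel spikes per step with
probability equal to its intensity, so a pixel of intensity 1 spikes every
step and the spike count over a presentation encodes the value (rate
coding).  Each I&F neuron accumulates the crossbar charge on its membrane
capacitor; when the potential exceeds V_th it emits a spike and V_th is
subtracted (no leak, no refractory period, at most one spike per step).
This soft-reset neuron behaves like a rate-coded ReLU: the output rate is
approximately the clipped linear function of the input rates.

Two single-bit quantities per neuron are recorded for training: the
derivative bit g (set once the neuron spikes at all during the pass — the
surrogate ReLU derivative) and the last-time-step spike bit S(T) (the
1-bit stand-in for the neuron's activation value in the weight update).

``q_scale`` converts a weighted sum in normalized conductance units into
membrane volts; it absorbs the spike amplitude/width and the membrane
capacitance.  The defaults follow the hardware values — a 3 V / 10 us spike
through a 1 nA full-scale device deposits 10 fC; with C_mem = 40 fF in
hidden/output layers that is 0.25 V, and the input-layer capacitance scales
with T (4T fF, i.e. q_scale = 2.5/T V) so the total charge a pixel injects
over a presentation is independent of T.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .crossbar import SynapseArray

__all__ = [
    "NetworkConfig",
    "IFLayerState",
    "poisson_encode",
    "if_step",
    "forward_pass",
    "readout",
    "default_q_scale",
]


def default_q_scale(n_weight_layers: int, T: int) -> list[float]:
    """Charge-to-voltage gains per weight layer: 2.5/T (input), then 0.25 V."""
    if n_weight_layers < 1:
        raise ValueError("need at least one weight layer")
    return [2.5 / T] + [0.25] * (n_weight_layers - 1)


@dataclass(frozen=True)
class NetworkConfig:
    """Topology and neuron parameters of the spiking network.

    layer_sizes : neurons per layer, input first (784 for MNIST).
    T : time steps per presentation.
    v_th : firing threshold in volts.
    q_scale : per-weight-layer charge-to-voltage gain (V per unit
        normalized-conductance per spike); defaults per `default_q_scale`.
    readout_restored : score output neurons by v(T) + v_th * spike_count
        (the membrane voltage with the subtracted thresholds restored)
        rather than the raw v(T).
    """

    layer_sizes: tuple
    T: int
    v_th: float = 0.1
    q_scale: tuple | None = None
    readout_restored: bool = True

    def __post_init__(self) -> None:
        object.__setattr__(self, "layer_sizes", tuple(int(n) for n in self.layer_sizes))
        if len(self.layer_sizes) < 2 or any(n <= 0 for n in self.layer_sizes):
            raise ValueError("layer_sizes needs >= 2 positive entries")
        if self.T < 1:
            raise ValueError("T must be >= 1")
        if self.v_th <= 0:
            raise ValueError("v_th must be positive")
        q = self.q_scale
        if q is None:
            q = default_q_scale(len(self.layer_sizes) - 1, self.T)
        q = tuple(float(x) for x in np.atleast_1d(q))
        if len(q) != len(self.layer_sizes) - 1:
            raise ValueError("q_scale needs one entry per weight layer")
        if any(x <= 0 for x in q):
            raise ValueError("q_scale entries must be positive")
        object.__setattr__(self, "q_scale", q)

    @property
    def n_weight_layers(self) -> int:
        return len(self.layer_sizes) - 1


@dataclass
class IFLayerState:
    """Mutable per-layer neuron state over one presentation.

    ``deriv_bit`` latches to 1 at the first spike; ``last_spike_bit`` holds
    only the final step's spike; ``spike_count`` is kept for diagnostics and
    the Case-2 counterfactual, not for the hardware update rule.
    """

    v: np.ndarray
    deriv_bit: np.ndarray
    last_spike_bit: np.ndarray
    spike_count: np.ndarray

    @classmethod
    def zeros(cls, n: int) -> "IFLayerState":
        return cls(
            v=np.zeros(n),
            deriv_bit=np.zeros(n, dtype=np.int8),
            last_spike_bit=np.zeros(n, dtype=np.int8),
            spike_count=np.zeros(n, dtype=np.int64),
        )

    @property
    def is_reset(self) -> bool:
        return (
            not self.v.any()
            and not self.deriv_bit.any()
            and not self.last_spike_bit.any()
            and not self.spike_count.any()
        )


def poisson_encode(image, T: int, rng: np.random.Generator):
    """Poisson-encode pixel intensities into a (T, n_pixels) binary train.

    Each pixel spikes independently at every step with probability equal to
    its intensity; intensity 1 spikes at all T steps.
    """
    image = np.asarray(image, dtype=float).ravel()
    if np.any(image < 0) or np.any(image > 1):
        raise ValueError("intensities must lie in [0, 1]")
    if T < 1:
        raise ValueError("T must be >= 1")
    return (rng.random((T, image.size)) < image).astype(np.int8)


def if_step(state: IFLayerState, charge, v_th: float) -> np.ndarray:
    """Advance one time step: integrate charge, fire, soft-reset.

    Neurons whose membrane exceeds v_th emit a spike and have v_th
    subtracted (at most one spike per neuron per step; the membrane may stay
    above threshold and fire again next step).  Returns the spike vector.
    """
    charge = np.asarray(charge, dtype=float)
    if charge.shape != state.v.shape:
        raise ValueError("charge vector shape does not match layer")
    state.v = state.v + charge
    fired = state.v > v_th
    spikes = fired.astype(np.int8)
    state.v = state.v - v_th * spikes
    state.deriv_bit = np.maximum(state.deriv_bit, spikes)
    state.last_spike_bit = spikes
    state.spike_count = state.spike_count + spikes
    return spikes


def forward_pass(
    arrays: list[SynapseArray],
    input_train: np.ndarray,
    config: NetworkConfig,
    states: list[IFLayerState] | None = None,
):
    """Run the forward phase: T steps of layer-by-layer spike propagation.

    Within a step a spike traverses all layers (the charge at layer l+1 at
    step t uses layer l's spikes at step t).  Returns (trains, states) where
    trains[0] is the input train and trains[k], states[k-1] belong to layer
    k+1; derivative bits end up 1 exactly for neurons that spiked at least
    once.
    """
    input_train = np.asarray(input_train)
    if len(arrays) != config.n_weight_layers:
        raise ValueError("number of arrays does not match layer_sizes")
    if input_train.shape != (config.T, config.layer_sizes[0]):
        raise ValueError("input train shape does not match (T, layer_sizes[0])")
    for k, arr in enumerate(arrays):
        if arr.shape != (config.layer_sizes[k], config.layer_sizes[k + 1]):
            raise ValueError(f"array {k} shape {arr.shape} does not chain layer sizes")
    if states is None:
        states = [IFLayerState.zeros(n) for n in config.layer_sizes[1:]]
    else:
        if len(states) != config.n_weight_layers:
            raise ValueError("one state per non-input layer is required")
        if not all(s.is_reset for s in states):
            raise ValueError("layer states must be freshly reset (all zeros)")

    W = [arr.weights for arr in arrays]  # snapshot; weights are frozen during FP
    trains = [input_train] + [
        np.zeros((config.T, n), dtype=np.int8) for n in config.layer_sizes[1:]
    ]
    for t in range(config.T):
        spikes = input_train[t]
        for k in range(config.n_weight_layers):
            charge = config.q_scale[k] * (spikes.astype(float) @ W[k])
            spikes = if_step(states[k], charge, config.v_th)
            trains[k + 1][t] = spikes
    return trains, states


def readout(final_state: IFLayerState, config: NetworkConfig) -> int:
    """Predicted label from the output layer's integrated drive.

    Scores each neuron by v(T) + v_th * spike_count (total injected charge,
    i.e. the membrane voltage with subtracted thresholds restored) — or raw
    v(T) when ``readout_restored`` is off — and returns the argmax, ties to
    the lowest index.
    """
    if config.readout_restored:
        score = final_state.v + config.v_th * final_state.spike_count
    else:
        score = final_state.v
    return int(np.argmax(score))


def run_inference(
    arrays: list[SynapseArray],
    image,
    config: NetworkConfig,
    rng: np.random.Generator,
) -> int:
    """Encode one image, run the forward phase, and read out the label."""
    train = poisson_encode(image, config.T, rng)
    _, states = forward_pass(arrays, train, config)
    return readout(states[-1], config)
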