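"""Differential-pair GSD crossbar arrays.

A signed weight is realized by two unipolar devices, W_ij = G+_ij - G-_ij.
Forward reads are current sums along the output lines (a dense matrix-vector
product with the spike vector); backward reads use the same array transposed,
gated by the 1-bit activation derivatives.

The update phase is parallel: a DC bias selects the rows whose pre-synaptic
neuron spiked at the last time step, and pulse-width-modulated program/erase
pulses on the source (S) lines carry the per-column delta.  Only cells at the
intersection of a selected row and a pulsed column see a gate-to-source
voltage difference large enough to program (|V_BG - V_S| >= 5.5 V) or erase
(>= 7 V); every other cell is inhibited.  The simulator applies the pulse
schedule directly through the device model but exposes the voltage rule
(`cell_bias_table`) so selectivity can be asserted against it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .device_model import (
    NO_VARIATION,
    DeviceGrid,
    DeviceParams,
    VariationConfig,
    apply_pulse,
    sample_device_grid,
)

__all__ = [
    "BiasScheme",
    "CellBias",
    "UpdateSchedule",
    "SynapseArray",
    "weighted_sum",
    "backward_sum",
    "cell_bias_table",
    "full_bias_table",
    "predicted_update_mask",
    "parallel_update",
]

# polarity codes for one differential pair
POL_NONE = 0
POL_INCREASE = 1   # erase G+ / program G-  -> weight grows
POL_DECREASE = -1  # program G+ / erase G-  -> weight shrinks


@dataclass(frozen=True)
class BiasScheme:
    """Update-phase line voltages (volts) and program/erase thresholds.

    Defaults: a program pulse of -3.5 V on the S line with +2 V on the
    selected BG line gives the 5.5 V programming condition; an erase pulse
    of +5 V with -2 V on the selected BG line gives the 7 V erase condition.
    Unselected lines sit at 0 V, so no unselected combination reaches its
    threshold.
    """

    v_s_program: float = -3.5
    v_s_erase: float = 5.0
    v_bg_selected_program: float = 2.0
    v_bg_selected_erase: float = -2.0
    v_unselected: float = 0.0
    program_threshold: float = 5.5
    erase_threshold: float = 7.0

    def __post_init__(self) -> None:
        if self.program_threshold <= 0 or self.erase_threshold <= 0:
            raise ValueError("thresholds must be positive")
        for kind in ("program", "erase"):
            sel = cell_bias_table(self, True, True, kind)
            if not sel.updates:
                raise ValueError(f"selected cell does not meet the {kind} threshold")
            for row, col in [(True, False), (False, True), (False, False)]:
                if cell_bias_table(self, row, col, kind).updates:
                    raise ValueError(f"unselected cell meets the {kind} threshold")


@dataclass(frozen=True)
class CellBias:
    """Voltages seen by one cell in the update phase and the update verdict."""

    v_bg: float
    v_s: float
    updates: bool


def cell_bias_table(
    scheme: BiasScheme, row_selected: bool, col_pulsed: bool, pulse_kind: str
) -> CellBias:
    """Voltages at a cell for a row/column state, and whether it updates.

    A cell updates only when its column actually carries a pulse *and*
    |V_BG - V_S| reaches the program/erase threshold.  With the default
    scheme exactly the selected-row x pulsed-column cell updates.
    """
    if pulse_kind not in ("program", "erase"):
        raise ValueError("pulse_kind must be 'program' or 'erase'")
    if pulse_kind == "program":
        v_s = scheme.v_s_program if col_pulsed else scheme.v_unselected
        v_bg = scheme.v_bg_selected_program if row_selected else scheme.v_unselected
        threshold = scheme.program_threshold
    else:
        v_s = scheme.v_s_erase if col_pulsed else scheme.v_unselected
        v_bg = scheme.v_bg_selected_erase if row_selected else scheme.v_unselected
        threshold = scheme.erase_threshold
    updates = bool(col_pulsed and abs(v_bg - v_s) >= threshold)
    return CellBias(v_bg=v_bg, v_s=v_s, updates=updates)


def full_bias_table(scheme: BiasScheme, pulse_kind: str):
    """All four row/column combinations (the 2x2 array worked example)."""
    rows = []
    for row_selected in (True, False):
        for col_pulsed in (True, False):
            bias = cell_bias_table(scheme, row_selected, col_pulsed, pulse_kind)
            rows.append(
                {
                    "row_selected": row_selected,
                    "col_pulsed": col_pulsed,
                    "v_bg": bias.v_bg,
                    "v_s": bias.v_s,
                    "delta_v": abs(bias.v_bg - bias.v_s),
                    "updates": bias.updates,
                }
            )
    return rows


def predicted_update_mask(
    scheme: BiasScheme, rows_selected, cols_pulsed, pulse_kind: str
) -> np.ndarray:
    """Cell-by-cell update verdict from the voltage rule alone."""
    rows_selected = np.asarray(rows_selected, dtype=bool)
    cols_pulsed = np.asarray(cols_pulsed, dtype=bool)
    out = np.empty((rows_selected.size, cols_pulsed.size), dtype=bool)
    for r in (True, False):
        for c in (True, False):
            out[np.ix_(rows_selected == r, cols_pulsed == c)] = cell_bias_table(
                scheme, r, c, pulse_kind
            ).updates
    return out


@dataclass
class UpdateSchedule:
    """Per-pair pulse widths and polarities for one update phase.

    ``delta_t`` holds the shared width applied to both devices of each pair
    (erase on one, program on the other); ``polarity`` is +1 where the weight
    must grow, -1 where it must shrink, 0 for untouched pairs.
    """

    delta_t: np.ndarray
    polarity: np.ndarray

    def __post_init__(self) -> None:
        self.delta_t = np.asarray(self.delta_t, dtype=float)
        self.polarity = np.asarray(self.polarity, dtype=np.int8)
        if self.delta_t.shape != self.polarity.shape:
            raise ValueError("delta_t and polarity must share a shape")
        if np.any(self.delta_t < 0):
            raise ValueError("pulse widths must be non-negative")
        if np.any((self.polarity == POL_NONE) & (self.delta_t != 0)):
            raise ValueError("pairs with polarity 'none' must have zero width")

    @property
    def shape(self):
        return self.delta_t.shape


class SynapseArray:
    """A differential-pair crossbar: two DeviceGrids of shape (n_pre, n_post)."""

    def __init__(self, g_plus: DeviceGrid, g_minus: DeviceGrid,
                 variation: VariationConfig = NO_VARIATION):
        if g_plus.shape != g_minus.shape:
            raise ValueError("G+ and G- grids must share a shape")
        if g_plus.params != g_minus.params:
            raise ValueError("G+ and G- grids must share DeviceParams")
        self.g_plus = g_plus
        self.g_minus = g_minus
        self.variation = variation

    @classmethod
    def create(
        cls,
        n_pre: int,
        n_post: int,
        params: DeviceParams,
        variation: VariationConfig = NO_VARIATION,
        rng: np.random.Generator | None = None,
        init: str = "random",
        init_amp: float = 0.1,
    ) -> "SynapseArray":
        """Sample a fresh array.

        ``init='random'`` places both devices mid-range with independent
        uniform offsets of at most ``init_amp``/2 of the range, giving small
        zero-mean initial weights; ``init='floor'`` leaves all devices at
        g_min (weights all zero).
        """
        if rng is None:
            rng = np.random.default_rng(variation.rng_seed)
        shape = (int(n_pre), int(n_post))
        gp = sample_device_grid(shape, params, variation, rng)
        gm = sample_device_grid(shape, params, variation, rng)
        if init == "random":
            mid = 0.5 * (params.g_min + params.g_max)
            half = 0.5 * init_amp * params.g_range
            gp.set_g(mid + rng.uniform(-half, half, size=shape))
            gm.set_g(mid + rng.uniform(-half, half, size=shape))
        elif init != "floor":
            raise ValueError(f"unknown init {init!r}")
        return cls(gp, gm, variation)

    @property
    def shape(self):
        return self.g_plus.shape

    @property
    def params(self) -> DeviceParams:
        return self.g_plus.params

    @property
    def weights(self) -> np.ndarray:
        """Effective signed weights W = G+ - G-."""
        return self.g_plus.g - self.g_minus.g

    def set_weights(self, W) -> None:
        """Place signed weights directly: G+/- = mid-range +/- W/2.

        |W| must fit in the conductance range; stuck devices keep g_min, so
        realized weights on stuck pairs deviate accordingly.
        """
        W = np.asarray(W, dtype=float)
        if W.shape != self.shape:
            raise ValueError("weight shape does not match array")
        if np.any(np.abs(W) > self.params.g_range + 1e-12):
            raise ValueError("weights exceed the representable conductance range")
        mid = 0.5 * (self.params.g_min + self.params.g_max)
        self.g_plus.set_g(mid + W / 2)
        self.g_minus.set_g(mid - W / 2)

    def copy(self) -> "SynapseArray":
        return SynapseArray(self.g_plus.copy(), self.g_minus.copy(), self.variation)


def weighted_sum(spikes, array: SynapseArray) -> np.ndarray:
    """Per-output charge q_j = sum_i spikes_i (G+_ij - G-_ij).

    The crossbar read: spike voltage pulses drive the rows and the column
    currents sum; equal to the dense product spikes @ W in normalized
    conductance units.
    """
    spikes = np.asarray(spikes, dtype=float)
    if spikes.shape != (array.shape[0],):
        raise ValueError(
            f"spike vector length {spikes.shape} does not match {array.shape[0]} rows"
        )
    return spikes @ array.weights


def backward_sum(
    delta_next, deriv_bits, array: SynapseArray, kappa_bp: float = 1.0
) -> np.ndarray:
    """Transposed read gated by derivative bits.

    delta_i = kappa_bp * (sum_j delta_j W_ij) * deriv_bits_i; zero wherever
    the pre-synaptic neuron never spiked in the forward pass (bit 0).
    kappa_bp collapses the pulse-width-modulation ratio and the delta-storage
    capacitance into one dimensionless backward gain.
    """
    delta_next = np.asarray(delta_next, dtype=float)
    deriv_bits = np.asarray(deriv_bits, dtype=float)
    if delta_next.shape != (array.shape[1],):
        raise ValueError("delta vector length does not match array columns")
    if deriv_bits.shape != (array.shape[0],):
        raise ValueError("derivative-bit vector length does not match array rows")
    return kappa_bp * (array.weights @ delta_next) * deriv_bits


def parallel_update(
    array: SynapseArray,
    schedule: UpdateSchedule,
    scheme: BiasScheme | None = None,
    rng: np.random.Generator | None = None,
) -> SynapseArray:
    """Apply one parallel update phase to the array (in place).

    For every pair with polarity +1 an erase pulse of the scheduled width is
    applied to G+ and a program pulse of the same width to G- (and mirrored
    for polarity -1); all other pairs are untouched.  Pulse-to-pulse
    variation (if configured) is drawn independently per device pulse.
    """
    if schedule.shape != array.shape:
        raise ValueError("schedule shape does not match array shape")
    if scheme is None:
        scheme = BiasScheme()
    if rng is None:
        rng = np.random.default_rng(array.variation.rng_seed)
    inc = schedule.polarity == POL_INCREASE
    dec = schedule.polarity == POL_DECREASE
    var = array.variation
    dt_inc = np.where(inc, schedule.delta_t, 0.0)
    dt_dec = np.where(dec, schedule.delta_t, 0.0)
    apply_pulse(array.g_plus, "erase", dt_inc, var, rng)
    apply_pulse(array.g_minus, "program", dt_inc, var, rng)
    apply_pulse(array.g_plus, "program", dt_dec, var, rng)
    apply_pulse(array.g_minus, "erase", dt_dec, var, rng)
    return array
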