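"""Behavioural conductance model of the gated Schottky diode (GSD) synapse.

A GSD stores an analog weight as the amount of charge trapped in its nitride
layer; erase pulses raise the read conductance (long-term potentiation, LTP)
and program pulses lower it (long-term depression, LTD).  Both branches are
well described by a logarithmic response in the *cumulative* pulse time t::

    G_LTP(t) = a_LTP + (1/beta_LTP) * ln(t + c_LTP)
    G_LTD(t) = a_LTD - (1/beta_LTD) * ln(t + c_LTD)

with G the conductance normalized to [0, 1].  beta is the non-linearity
factor: small beta gives a near-linear response, large beta a strongly
logarithmic one.  Two parameterizations are supported:

``fitted``
    The coefficients measured on fabricated GSDs (`GSD_FITTED_PARAMS`):
    a near-linear LTP branch (beta ~ 1.60) and a strongly non-linear LTD
    branch (beta ~ 8.03).  Time is in seconds.
``pinned``
    beta is the only free parameter; (a, c) are derived so the curve passes
    exactly through (0, g_min) and (t_max, g_max) (LTD mirrored).  This is
    the parameterization used for all non-linearity/asymmetry sweeps, since
    it keeps the conductance range identical across beta values.

Device state is a single scalar per device (its normalized conductance);
switching between the LTP and LTD branches maps the current conductance to
the equivalent cumulative time on the target branch and advances from there.

Non-idealities: pulse-to-pulse variation (multiplicative Gaussian noise on
each conductance increment), device-to-device variation (Gaussian spread of
beta across the array), and stuck-at-off devices frozen at g_min.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar

__all__ = [
    "DeviceParams",
    "DeviceGrid",
    "VariationConfig",
    "GSD_FITTED_PARAMS",
    "BETA_FLOOR",
    "g_ltp",
    "g_ltd",
    "invert_ltp",
    "invert_ltd",
    "pinned_params",
    "apply_pulse",
    "sample_device_grid",
    "fit_conductance_curve",
    "energy_per_spike",
]

#: Lower truncation for sampled non-linearity factors (beta must stay positive).
BETA_FLOOR = 1e-3


@dataclass(frozen=True)
class DeviceParams:
    """Coefficients of the LTP/LTD conductance response.

    ``a_*`` and ``c_*`` are expressed for the *normalized* conductance
    u = (g - g_min) / (g_max - g_min); ``c`` and ``t_max`` share the pulse
    time unit (seconds for the fitted GSD constants).
    """

    a_ltp: float
    beta_ltp: float
    c_ltp: float
    a_ltd: float
    beta_ltd: float
    c_ltd: float
    mode: str = "pinned"  # "pinned" | "fitted"
    t_max: float = 0.1
    g_min: float = 0.0
    g_max: float = 1.0

    def __post_init__(self) -> None:
        if self.beta_ltp <= 0 or self.beta_ltd <= 0:
            raise ValueError("non-linearity factors must be positive")
        if self.c_ltp <= 0 or self.c_ltd <= 0:
            raise ValueError("time offsets c must be positive")
        if not self.g_min < self.g_max:
            raise ValueError("g_min must be below g_max")
        if self.mode not in ("pinned", "fitted"):
            raise ValueError(f"unknown mode {self.mode!r}")

    @property
    def g_range(self) -> float:
        return self.g_max - self.g_min

    def replace(self, **kw) -> "DeviceParams":
        return dataclasses.replace(self, **kw)


#: Coefficients fitted to the measured GSD response (normalized conductance,
#: pulse time in seconds): near-linear LTP, strongly non-linear LTD.
GSD_FITTED_PARAMS = DeviceParams(
    a_ltp=2.270,
    beta_ltp=1.60,
    c_ltp=0.0278,
    a_ltd=1.422,
    beta_ltd=8.03,
    c_ltd=18.25,
    mode="fitted",
    t_max=0.1,
)


@dataclass(frozen=True)
class VariationConfig:
    """Device non-ideality levels.

    sigma_p2p : relative std (sigma/mu) of the multiplicative Gaussian noise
        applied to every conductance increment (pulse-to-pulse variation).
    sigma_d2d : relative std of the Gaussian spread of beta across devices
        (device-to-device variation).
    stuck_fraction : fraction of devices frozen at g_min (stuck-at-off).
    """

    sigma_p2p: float = 0.0
    sigma_d2d: float = 0.0
    stuck_fraction: float = 0.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma_p2p < 0 or self.sigma_d2d < 0:
            raise ValueError("variation sigmas must be non-negative")
        if not 0 <= self.stuck_fraction < 1:
            raise ValueError("stuck_fraction must be in [0, 1)")


NO_VARIATION = VariationConfig()


def _pinned_coeffs(beta, t_max):
    """(a, c) so that u(t)=a+(1/beta)ln(t+c) runs exactly from 0 to 1."""
    beta = np.asarray(beta, dtype=float)
    c = t_max / np.expm1(beta)
    a = -np.log(c) / beta
    return a, c


def pinned_params(
    beta_ltp: float,
    beta_ltd: float,
    t_max: float = 0.1,
    g_min: float = 0.0,
    g_max: float = 1.0,
) -> DeviceParams:
    """Device parameters with beta as the only free shape parameter.

    (a, c) are solved so that the LTP curve passes exactly through
    (0, g_min) and (t_max, g_max), and the LTD curve through (0, g_max) and
    (t_max, g_min):  c = t_max / (e^beta - 1),  a_LTP = -(1/beta) ln c,
    a_LTD = 1 + (1/beta) ln c.  As beta -> 0 both branches approach the
    straight line t/t_max.
    """
    if beta_ltp <= 0 or beta_ltd <= 0:
        raise ValueError("non-linearity factors must be positive")
    if t_max <= 0:
        raise ValueError("t_max must be positive")
    a_p, c_p = _pinned_coeffs(beta_ltp, t_max)
    a_d, c_d = _pinned_coeffs(beta_ltd, t_max)
    return DeviceParams(
        a_ltp=float(a_p),
        beta_ltp=beta_ltp,
        c_ltp=float(c_p),
        a_ltd=float(1.0 + np.log(c_d) / beta_ltd),
        beta_ltd=beta_ltd,
        c_ltd=float(c_d),
        mode="pinned",
        t_max=t_max,
        g_min=g_min,
        g_max=g_max,
    )


def linear_params(t_max: float = 0.1, **kw) -> DeviceParams:
    """Near-ideal linear device: pinned curves at beta = BETA_FLOOR."""
    return pinned_params(BETA_FLOOR, BETA_FLOOR, t_max=t_max, **kw)


def _branch_coeffs(params: DeviceParams, branch: str, beta=None):
    """Per-device (a, beta, c) for a branch, honouring effective beta.

    In pinned mode (a, c) are re-derived from the effective beta so every
    device spans the same conductance range; in fitted mode only the slope
    changes.
    """
    if branch == "ltp":
        b = params.beta_ltp if beta is None else beta
        if params.mode == "pinned":
            a, c = _pinned_coeffs(b, params.t_max)
        else:
            a, c = params.a_ltp, params.c_ltp
    elif branch == "ltd":
        b = params.beta_ltd if beta is None else beta
        if params.mode == "pinned":
            a, c = _pinned_coeffs(b, params.t_max)
            a = 1.0 + np.log(c) * np.asarray(b, dtype=float) ** -1
        else:
            a, c = params.a_ltd, params.c_ltd
    else:  # pragma: no cover - internal
        raise ValueError(branch)
    return np.asarray(a, dtype=float), np.asarray(b, dtype=float), np.asarray(c, dtype=float)


def _check_time(t) -> np.ndarray:
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("cumulative pulse time must be non-negative")
    return t


def g_ltp(t, params: DeviceParams, beta=None):
    """Normalized conductance after cumulative erase time ``t`` (LTP branch).

    Clamped to [g_min, g_max]; strictly increasing in t before clamping.
    """
    t = _check_time(t)
    a, b, c = _branch_coeffs(params, "ltp", beta)
    u = a + np.log(t + c) / b
    g = params.g_min + params.g_range * u
    return np.clip(g, params.g_min, params.g_max)


def g_ltd(t, params: DeviceParams, beta=None):
    """Normalized conductance after cumulative program time ``t`` (LTD branch)."""
    t = _check_time(t)
    a, b, c = _branch_coeffs(params, "ltd", beta)
    u = a - np.log(t + c) / b
    g = params.g_min + params.g_range * u
    return np.clip(g, params.g_min, params.g_max)


def _check_g(g, params: DeviceParams) -> np.ndarray:
    g = np.asarray(g, dtype=float)
    if np.any(g < params.g_min - 1e-12) or np.any(g > params.g_max + 1e-12):
        raise ValueError("conductance outside [g_min, g_max]")
    return g


def invert_ltp(g, params: DeviceParams, beta=None):
    """Cumulative erase time at which the (unclamped) LTP curve reaches ``g``.

    Exact inverse of the unclamped curve, floored at 0.
    """
    g = _check_g(g, params)
    a, b, c = _branch_coeffs(params, "ltp", beta)
    u = (g - params.g_min) / params.g_range
    t = np.exp(b * (u - a)) - c
    return np.maximum(t, 0.0)


def invert_ltd(g, params: DeviceParams, beta=None):
    """Cumulative program time at which the (unclamped) LTD curve reaches ``g``."""
    g = _check_g(g, params)
    a, b, c = _branch_coeffs(params, "ltd", beta)
    u = (g - params.g_min) / params.g_range
    t = np.exp(b * (a - u)) - c
    return np.maximum(t, 0.0)


@dataclass
class DeviceGrid:
    """State of an array of devices (vectorized DeviceState).

    ``g`` holds the normalized conductances, ``beta_ltp``/``beta_ltd`` each
    device's realized non-linearity factors, and ``stuck`` the stuck-at-off
    mask.  Stuck devices sit at g_min and never respond to pulses.
    """

    g: np.ndarray
    beta_ltp: np.ndarray
    beta_ltd: np.ndarray
    stuck: np.ndarray
    params: DeviceParams

    @property
    def shape(self):
        return self.g.shape

    def copy(self) -> "DeviceGrid":
        return DeviceGrid(
            self.g.copy(), self.beta_ltp.copy(), self.beta_ltd.copy(),
            self.stuck.copy(), self.params,
        )

    def set_g(self, g) -> None:
        """Directly place conductances (stuck devices stay at g_min)."""
        g = np.clip(np.asarray(g, dtype=float), self.params.g_min, self.params.g_max)
        self.g = np.where(self.stuck, self.params.g_min, np.broadcast_to(g, self.shape))


def sample_device_grid(
    shape,
    params: DeviceParams,
    variation: VariationConfig = NO_VARIATION,
    rng: np.random.Generator | None = None,
) -> DeviceGrid:
    """Draw a device array with device-to-device variation and stuck cells.

    Each device's effective beta is Normal(beta, sigma_d2d * beta), truncated
    below at BETA_FLOOR.  Exactly round(stuck_fraction * n) devices, chosen
    uniformly at random, are flagged stuck (g = g_min).  All randomness flows
    from ``rng`` (or ``variation.rng_seed`` when rng is None).
    """
    shape = tuple(np.atleast_1d(shape).astype(int))
    if any(s <= 0 for s in shape):
        raise ValueError("shape entries must be positive")
    if rng is None:
        rng = np.random.default_rng(variation.rng_seed)
    n = int(np.prod(shape))

    def draw_beta(mean):
        if variation.sigma_d2d == 0:
            return np.full(shape, float(mean))
        b = rng.normal(mean, variation.sigma_d2d * mean, size=shape)
        return np.maximum(b, BETA_FLOOR)

    beta_ltp = draw_beta(params.beta_ltp)
    beta_ltd = draw_beta(params.beta_ltd)
    stuck = np.zeros(shape, dtype=bool)
    n_stuck = int(round(variation.stuck_fraction * n))
    if n_stuck:
        idx = rng.choice(n, size=n_stuck, replace=False)
        stuck.ravel()[idx] = True
    g = np.full(shape, params.g_min, dtype=float)
    return DeviceGrid(g=g, beta_ltp=beta_ltp, beta_ltd=beta_ltd, stuck=stuck, params=params)


def apply_pulse(
    state: DeviceGrid,
    polarity: str,
    delta_t,
    variation: VariationConfig = NO_VARIATION,
    rng: np.random.Generator | None = None,
    mask=None,
) -> DeviceGrid:
    """Apply an erase (LTP) or program (LTD) pulse of width ``delta_t``.

    The current conductance is mapped to the equivalent cumulative time on
    the target branch (using each device's effective beta), advanced by
    delta_t, and read back.  With sigma_p2p > 0 the conductance increment is
    multiplied by a Normal(1, sigma_p2p) draw.  Result clamped to
    [g_min, g_max]; stuck devices never change.  Mutates ``state`` in place
    and returns it.
    """
    if polarity not in ("erase", "program"):
        raise ValueError("polarity must be 'erase' (LTP) or 'program' (LTD)")
    delta_t = np.broadcast_to(np.asarray(delta_t, dtype=float), state.shape)
    if np.any(delta_t < 0):
        raise ValueError("pulse width must be non-negative")
    params = state.params
    active = (~state.stuck) & (delta_t > 0)
    if mask is not None:
        active = active & np.asarray(mask, dtype=bool)
    if not np.any(active):
        return state

    branch = "ltp" if polarity == "erase" else "ltd"
    beta = state.beta_ltp if branch == "ltp" else state.beta_ltd
    if branch == "ltp":
        t_eff = invert_ltp(state.g, params, beta=beta)
        g_new = g_ltp(t_eff + delta_t, params, beta=beta)
    else:
        t_eff = invert_ltd(state.g, params, beta=beta)
        g_new = g_ltd(t_eff + delta_t, params, beta=beta)

    inc = g_new - state.g
    if variation.sigma_p2p > 0:
        if rng is None:
            rng = np.random.default_rng(variation.rng_seed)
        inc = inc * rng.normal(1.0, variation.sigma_p2p, size=state.shape)
    g = np.clip(state.g + inc, params.g_min, params.g_max)
    state.g = np.where(active, g, state.g)
    return state


def fit_conductance_curve(times, conductances, branch: str = "ltp"):
    """Least-squares fit of the logarithmic response to pulse-sweep data.

    Fits G = a +/- (1/beta) ln(t + c) (sign by ``branch``) to samples of
    (cumulative pulse time, normalized conductance).  The problem is linear
    in (a, 1/beta) given c, so c is found by a bounded 1-D search on log10(c)
    with an exact inner linear solve.

    Returns ``(a, beta, c, rms_residual)``.

    Raises on fewer than 4 samples, non-increasing times, or constant
    conductance; warns (and still fits) if the data trend contradicts the
    requested branch.
    """
    t = np.asarray(times, dtype=float)
    g = np.asarray(conductances, dtype=float)
    if t.ndim != 1 or t.shape != g.shape:
        raise ValueError("times and conductances must be 1-D and equal length")
    if t.size < 4:
        raise ValueError("at least 4 samples are required to fit (a, beta, c)")
    if np.any(np.diff(t) <= 0):
        raise ValueError("times must be strictly increasing")
    if branch not in ("ltp", "ltd"):
        raise ValueError("branch must be 'ltp' or 'ltd'")
    if np.ptp(g) == 0:
        raise ValueError("constant conductance data cannot constrain the curve")
    sign = 1.0 if branch == "ltp" else -1.0
    trend = np.polyfit(np.arange(t.size), g, 1)[0]
    if sign * trend < 0:
        warnings.warn(
            f"conductance trend is inconsistent with the {branch.upper()} branch; "
            "fitting anyway", stacklevel=2,
        )

    t_span = t[-1] - t[0]

    def solve_for(log10_c):
        c = 10.0 ** log10_c
        x = np.log(t + c)
        A = np.column_stack([np.ones_like(x), sign * x])
        coef, *_ = np.linalg.lstsq(A, g, rcond=None)
        resid = A @ coef - g
        return coef, float(np.sqrt(np.mean(resid**2)))

    lo, hi = np.log10(max(t_span, 1e-12)) - 9, np.log10(max(t_span, 1e-12)) + 6
    res = minimize_scalar(
        lambda lc: solve_for(lc)[1], bounds=(lo, hi), method="bounded",
        options={"xatol": 1e-12},
    )
    (a, inv_beta), rms = solve_for(res.x)
    if inv_beta <= 0:
        # degenerate branch-contradicting fit; report magnitude with warning above
        inv_beta = abs(inv_beta) if inv_beta != 0 else np.inf
    return float(a), float(1.0 / inv_beta), float(10.0 ** res.x), rms


def energy_per_spike(
    current_a: float = 1e-9,
    amplitude_v: float = 3.0,
    width_s: float = 10e-6,
) -> float:
    """Read energy dissipated in one GSD per spike, E = I * V * t (joules).

    Defaults are the GSD read conditions: ~1 nA saturated current, 3 V spike
    amplitude, 10 us spike width, giving 30 fJ per spike.
    """
    if current_a < 0 or amplitude_v < 0 or width_s < 0:
        raise ValueError("current, amplitude and width must be non-negative")
    return current_a * amplitude_v * width_s
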