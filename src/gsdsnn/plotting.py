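"""Optional matplotlib views of sweep results and training traces."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

__all__ = ["plot_sweep", "plot_case_trace", "plot_conductance_curves"]


def plot_sweep(result, ax=None, label=None):
    """Mean accuracy vs swept value with 1-sigma error bars."""
    if ax is None:
        _, ax = plt.subplots()
    ax.errorbar(result.values, result.mean, yerr=result.std, marker="o",
                capsize=3, label=label or result.regime)
    ax.set_xlabel(result.param)
    ax.set_ylabel("test accuracy")
    ax.set_ylim(0, 1)
    if label:
        ax.legend()
    return ax


def plot_case_trace(trace, layer: int = 0, ax=None, window: int = 25):
    """Case-1 vs Case-2 update sums for one weight layer (smoothed)."""
    if ax is None:
        _, ax = plt.subplots()
    kern = np.ones(window) / window
    for series, name in ((trace.case1[:, layer], "Case 1 (1-bit S(T))"),
                         (trace.case2[:, layer], "Case 2 (count/T)")):
        ax.plot(np.convolve(series, kern, mode="valid"), label=name)
    ax.set_xlabel("training iteration")
    ax.set_ylabel("update sum (weight units)")
    ax.legend()
    return ax


def plot_conductance_curves(params, ax=None, n: int = 200):
    """LTP and LTD branches of a device parameterization."""
    from .device_model import g_ltd, g_ltp

    if ax is None:
        _, ax = plt.subplots()
    t = np.linspace(0, params.t_max, n)
    ax.plot(t, g_ltp(t, params), label="LTP (erase)")
    ax.plot(t, g_ltd(t, params), label="LTD (program)")
    ax.set_xlabel("cumulative pulse time (s)")
    ax.set_ylabel("normalized conductance")
    ax.legend()
    return ax
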