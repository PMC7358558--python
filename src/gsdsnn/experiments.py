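"""Scripted sweep experiments over device and network parameters.

Reproduces the simulator's standard studies: accuracy versus total time
step, layer width and depth (with and without a lambda_UP schedule);
per-iteration Case-1/Case-2 update-sum traces; and robustness of on-chip
versus off-chip training against device non-idealities (non-linearity
factor, LTP/LTD asymmetry, pulse-to-pulse variation, device-to-device
variation, stuck-at-off ratio).  Every accuracy point is evaluated over
replicates (default 5) with distinct, logged seeds, and reported as
mean +/- 1 standard deviation.

Desk-scale defaults run the synthetic 3-class task on a 64-16-3 network;
MNIST-scale runs go through the same entry points with a `mnist` dataset
selector and IDX file paths.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import training
from .crossbar import SynapseArray
from .data_io import RunConfig, atomic_write_text, read_idx, synth_splits
from .device_model import (
    BETA_FLOOR,
    GSD_FITTED_PARAMS,
    DeviceParams,
    VariationConfig,
    pinned_params,
)
from .network import NetworkConfig
from .training import TrainConfig, TrainTrace, evaluate, offchip_transfer, reference_ann, train

__all__ = [
    "SweepSpec",
    "SweepResult",
    "run_sweep",
    "trace_case_sums",
    "run_depth_width_T",
    "single_run",
]

SWEEPABLE = (
    "beta", "beta_ltd", "sigma_p2p", "sigma_d2d", "stuck_fraction",
    "T", "width", "depth", "noise",
)


@dataclass(frozen=True)
class SweepSpec:
    """One named parameter sweep.

    ``param`` is the swept knob; ``values`` its grid; each (value, replicate)
    cell runs a full train-and-evaluate with a distinct derived seed.
    ``regime`` picks on-chip training or the off-chip (ANN-to-SNN transfer)
    baseline; ``base`` carries the fixed configuration.
    """

    param: str
    values: tuple
    replicates: int = 5
    regime: str = "onchip"  # "onchip" | "offchip"
    dataset: str = "synthetic"
    base: RunConfig = field(default_factory=RunConfig)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.param not in SWEEPABLE:
            raise ValueError(f"unknown sweep parameter {self.param!r}; one of {SWEEPABLE}")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        object.__setattr__(self, "values", tuple(self.values))
        if not self.values:
            raise ValueError("values must be non-empty")
        if self.regime not in ("onchip", "offchip"):
            raise ValueError("regime must be 'onchip' or 'offchip'")


@dataclass
class SweepResult:
    """Per-value accuracy means/stds over replicates, with logged seeds."""

    param: str
    values: tuple
    regime: str
    accuracy: np.ndarray       # (n_values, replicates)
    seeds: np.ndarray          # (n_values, replicates)

    @property
    def mean(self) -> np.ndarray:
        return self.accuracy.mean(axis=1)

    @property
    def std(self) -> np.ndarray:
        return self.accuracy.std(axis=1, ddof=0)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for vi, v in enumerate(self.values):
            for r in range(self.accuracy.shape[1]):
                rows.append({"param": self.param, "value": v, "replicate": r,
                             "seed": int(self.seeds[vi, r]),
                             "accuracy": self.accuracy[vi, r]})
        return pd.DataFrame(rows)

    def save(self, out_dir) -> None:
        out_dir = Path(out_dir)
        atomic_write_text(out_dir / f"sweep_{self.param}_{self.regime}.csv",
                          self.to_frame().to_csv(index=False))
        summary = {
            "param": self.param,
            "regime": self.regime,
            "values": list(self.values),
            "mean_accuracy": self.mean.tolist(),
            "std_accuracy": self.std.tolist(),
            "seeds": self.seeds.tolist(),
        }
        atomic_write_text(out_dir / f"sweep_{self.param}_{self.regime}.json",
                          json.dumps(summary, indent=2))


def derive_seed(master: int, *parts: int) -> int:
    """Stable, distinct 31-bit seed for a (value, replicate) cell."""
    return int(np.random.SeedSequence((int(master),) + tuple(int(p) for p in parts))
               .generate_state(1)[0] % (2**31))


def _device_for(cfg: RunConfig) -> DeviceParams:
    if cfg.device_mode == "linear":
        return pinned_params(BETA_FLOOR, BETA_FLOOR, t_max=cfg.t_max)
    if cfg.device_mode == "pinned":
        return pinned_params(cfg.beta_ltp, cfg.beta_ltd, t_max=cfg.t_max)
    if cfg.device_mode == "fitted":
        return GSD_FITTED_PARAMS.replace(t_max=cfg.t_max)
    raise ValueError(f"unknown device_mode {cfg.device_mode!r}")


def _apply_value(cfg: RunConfig, param: str, value) -> RunConfig:
    """Fold one swept value into a copy of the base config."""
    if param == "beta":
        return dataclasses.replace(cfg, device_mode="pinned",
                                   beta_ltp=value, beta_ltd=value)
    if param == "beta_ltd":
        return dataclasses.replace(cfg, device_mode="pinned", beta_ltd=value)
    if param in ("sigma_p2p", "sigma_d2d", "stuck_fraction", "T", "noise"):
        return dataclasses.replace(cfg, **{param: value})
    if param == "width":
        sizes = (cfg.layer_sizes[0], int(value), cfg.layer_sizes[-1])
        return dataclasses.replace(cfg, layer_sizes=sizes)
    if param == "depth":
        width = cfg.layer_sizes[1] if len(cfg.layer_sizes) > 2 else 16
        sizes = (cfg.layer_sizes[0],) + (width,) * int(value) + (cfg.layer_sizes[-1],)
        return dataclasses.replace(cfg, layer_sizes=sizes)
    raise ValueError(param)


def _load_data(cfg: RunConfig, dataset: str):
    if dataset == "synthetic":
        return synth_splits(
            num_classes=cfg.num_classes, image_size=cfg.image_size,
            train_per_class=cfg.train_per_class, test_per_class=cfg.test_per_class,
            noise=cfg.noise, seed=cfg.seed,
        )
    if dataset == "mnist":
        if not cfg.mnist_dir:
            raise ValueError("mnist_dir must point at the IDX files for dataset='mnist'")
        d = Path(cfg.mnist_dir)
        tr = read_idx(d / "train-images-idx3-ubyte", d / "train-labels-idx1-ubyte")
        te = read_idx(d / "t10k-images-idx3-ubyte", d / "t10k-labels-idx1-ubyte")
        return tr, te
    raise ValueError(f"unknown dataset {dataset!r}")


def build_arrays(cfg: RunConfig, rng: np.random.Generator) -> list[SynapseArray]:
    params = _device_for(cfg)
    variation = VariationConfig(
        sigma_p2p=cfg.sigma_p2p, sigma_d2d=cfg.sigma_d2d,
        stuck_fraction=cfg.stuck_fraction,
    )
    return [
        SynapseArray.create(a, b, params, variation, rng)
        for a, b in zip(cfg.layer_sizes[:-1], cfg.layer_sizes[1:])
    ]


def single_run(cfg: RunConfig, regime: str, seed: int,
               dataset: str = "synthetic", data=None,
               return_trace: bool = False):
    """Train and evaluate one configuration; returns final test accuracy.

    ``data`` may carry pre-loaded (train, test) datasets so sweeps do not
    re-read MNIST per cell.  Stuck masks, initial conductances and every
    stochastic draw derive from ``seed``.
    """
    rng = np.random.default_rng(seed)
    train_ds, test_ds = data if data is not None else _load_data(cfg, dataset)
    net_cfg = NetworkConfig(layer_sizes=cfg.layer_sizes, T=cfg.T, v_th=cfg.v_th)
    arrays = build_arrays(cfg, rng)
    if regime == "onchip":
        tc = TrainConfig(epochs=cfg.epochs, batch_size=cfg.batch_size,
                         kappa_bp=cfg.kappa_bp, delta_clip=cfg.delta_clip,
                         lr_schedule=cfg.lr_schedule, seed=seed)
        trace = train(train_ds, test_ds, arrays, net_cfg, tc, rng=rng,
                      record_case_sums=return_trace)
        acc = trace.final_accuracy
        return (acc, trace) if return_trace else acc
    if regime == "offchip":
        ann = reference_ann(train_ds, cfg.layer_sizes, epochs=cfg.epochs, rng=rng)
        offchip_transfer(ann.weights, arrays,
                         VariationConfig(sigma_p2p=cfg.sigma_p2p,
                                         sigma_d2d=cfg.sigma_d2d,
                                         stuck_fraction=cfg.stuck_fraction),
                         rng, net_config=net_cfg, train_images=train_ds.images)
        acc = evaluate(test_ds, arrays, net_cfg, rng)
        return (acc, None) if return_trace else acc
    raise ValueError(f"unknown regime {regime!r}")


def run_sweep(spec: SweepSpec, out_dir=None) -> SweepResult:
    """Run a parameter sweep: one full run per (value, replicate)."""
    n_v, n_r = len(spec.values), spec.replicates
    acc = np.zeros((n_v, n_r))
    seeds = np.zeros((n_v, n_r), dtype=np.int64)
    data = _load_data(spec.base, spec.dataset)
    for vi, value in enumerate(spec.values):
        cfg = _apply_value(spec.base, spec.param, value)
        cell_data = data if spec.param not in ("noise",) else None
        for r in range(n_r):
            seed = derive_seed(spec.seed, vi, r)
            seeds[vi, r] = seed
            acc[vi, r] = single_run(cfg, spec.regime, seed,
                                    dataset=spec.dataset, data=cell_data)
    result = SweepResult(param=spec.param, values=spec.values,
                         regime=spec.regime, accuracy=acc, seeds=seeds)
    if out_dir is not None:
        result.save(out_dir)
    return result


def trace_case_sums(
    cfg: RunConfig,
    iterations: int = 500,
    synapse: tuple | None = None,
    frozen: bool = True,
    seed: int = 0,
    image=None,
    label: int | None = None,
):
    """Trace Case-1 vs Case-2 update sums over repeated presentations.

    With ``frozen=True`` the network weights are never updated, so every
    iteration is an independent Poisson presentation of the same stimulus
    and the Case-1 sums should fluctuate around the Case-2 values (their
    mean difference compatible with 0).  ``synapse`` = (layer, i, j) adds a
    single-synapse trace, e.g. input neuron 358 -> hidden neuron 124 of the
    first crossbar.

    Returns ``(trace, diff)`` where diff is the (iterations, n_layers)
    Case1 - Case2 series.
    """
    rng = np.random.default_rng(seed)
    train_ds, _ = _load_data(cfg, "synthetic")
    if image is None:
        image, label = train_ds.images[0], int(train_ds.labels[0])
    net_cfg = NetworkConfig(layer_sizes=cfg.layer_sizes, T=cfg.T, v_th=cfg.v_th)
    tc = TrainConfig(kappa_bp=cfg.kappa_bp, delta_clip=cfg.delta_clip, seed=seed)
    arrays = build_arrays(cfg, rng)
    tr_syn = None
    if synapse is not None:
        layer, i, j = synapse
        if not (0 <= layer < len(arrays)):
            raise IndexError(f"layer {layer} out of range")
        n_i, n_j = arrays[layer].shape
        if not (0 <= i < n_i and 0 <= j < n_j):
            raise IndexError(f"synapse ({i}, {j}) outside array {arrays[layer].shape}")
        tr_syn = {layer: (i, j)}

    case1, case2 = [], []
    syn1 = {l: [] for l in (tr_syn or {})}
    syn2 = {l: [] for l in (tr_syn or {})}
    for _ in range(iterations):
        _, info = training.train_step(
            image, label, arrays, net_cfg, tc, rng,
            apply_updates=not frozen, trace_synapses=tr_syn,
        )
        case1.append(info["case1"])
        case2.append(info["case2"])
        for l in syn1:
            syn1[l].append(info["synapse_case1"][l])
            syn2[l].append(info["synapse_case2"][l])
    case1 = np.asarray(case1)
    case2 = np.asarray(case2)
    trace = TrainTrace(
        case1=case1, case2=case2, epoch_accuracy=[], lambda_history=[],
        synapse_case1={l: np.asarray(v) for l, v in syn1.items()},
        synapse_case2={l: np.asarray(v) for l, v in syn2.items()},
        config={"iterations": iterations, "frozen": frozen, "seed": seed},
    )
    return trace, case1 - case2


def run_depth_width_T(
    base: RunConfig,
    T_values=(2, 5, 10, 20),
    widths=(8, 16, 32),
    depths=(1, 2),
    lr_schedule=((3, 0.2),),
    replicates: int = 5,
    seed: int = 0,
    out_dir=None,
) -> dict:
    """Accuracy grids over total time step, layer width, and depth.

    Runs each grid with replicates (linear devices, as in the baseline
    topology studies) plus a lambda_UP-schedule variant of the deepest
    network; returns {'T': SweepResult, 'width': ..., 'depth': ...,
    'lr_schedule': {...}} with per-epoch curves for the schedule runs.
    """
    out = {}
    grids = (("T", T_values), ("width", widths), ("depth", depths))
    for k, (param, values) in enumerate(grids):
        spec = SweepSpec(param=param, values=tuple(values), replicates=replicates,
                         base=base, seed=derive_seed(seed, k))
        out[param] = run_sweep(spec, out_dir=out_dir)

    sched_cfg = dataclasses.replace(_apply_value(base, "depth", max(depths)),
                                    lr_schedule=tuple(lr_schedule))
    plain_cfg = _apply_value(base, "depth", max(depths))
    curves = {}
    for name, cfg in (("plain", plain_cfg), ("scheduled", sched_cfg)):
        _, trace = single_run(cfg, "onchip", derive_seed(seed, 13), return_trace=True)
        curves[name] = {
            "epoch_accuracy": trace.epoch_accuracy,
            "lambda_history": trace.lambda_history,
            "applied_at": [e for e, _ in cfg.lr_schedule],
        }
    out["lr_schedule"] = curves
    if out_dir is not None:
        atomic_write_text(Path(out_dir) / "lr_schedule_curves.json",
                          json.dumps(curves, indent=2))
    return out
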