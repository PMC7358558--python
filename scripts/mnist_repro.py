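#!/usr/bin/env python
"""Opt-in MNIST-scale reproduction runs (requires local IDX files).

The full-scale results — 97.83% for 784-256-10 at T=20 with batch size 1,
98.44% for four hidden layers at batch 100, and the 98.04% off-chip
(ANN-to-SNN) baseline — need the original MNIST IDX files and hours of CPU,
so they are not part of the test suite.  Point ``--mnist-dir`` at a
directory containing::

    train-images-idx3-ubyte  train-labels-idx1-ubyte
    t10k-images-idx3-ubyte   t10k-labels-idx1-ubyte

Examples::

    # ~10-minute sanity run: 784-64-10, T=20, 10k training samples, 1 epoch
    python scripts/mnist_repro.py --mnist-dir data/mnist --sanity

    # headline single-hidden-layer run (long)
    python scripts/mnist_repro.py --mnist-dir data/mnist \
        --layer-sizes 784,256,10 --epochs 20

    # off-chip conversion baseline
    python scripts/mnist_repro.py --mnist-dir data/mnist --regime offchip \
        --layer-sizes 784,256,10 --epochs 20
"""

from __future__ import annotations

import argparse
import json
import time
from pathlib import Path

from gsdsnn.data_io import RunConfig, atomic_write_text
from gsdsnn.experiments import single_run


def main() -> None:
    ap = argparse.ArgumentParser(
        description=__doc__, formatter_class=argparse.RawDescriptionHelpFormatter
    )
    ap.add_argument("--mnist-dir", required=True,
                    help="directory holding the four MNIST IDX files")
    ap.add_argument("--layer-sizes", default="784,64,10",
                    help="comma-separated layer sizes (input first)")
    ap.add_argument("--T", type=int, default=20)
    ap.add_argument("--epochs", type=int, default=1)
    ap.add_argument("--batch-size", type=int, default=1)
    ap.add_argument("--train-samples", type=int, default=None,
                    help="cap on training samples (default: all 60k)")
    ap.add_argument("--regime", choices=["onchip", "offchip"], default="onchip")
    ap.add_argument("--device", choices=["linear", "pinned", "fitted"],
                    default="linear")
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--out", type=Path, default=Path("runs/mnist/summary.json"))
    ap.add_argument("--sanity", action="store_true",
                    help="the scaled-down sanity run: 784-64-10, 10k samples, 1 epoch")
    args = ap.parse_args()

    if args.sanity:
        args.layer_sizes, args.epochs, args.train_samples = "784,64,10", 1, 10000

    sizes = tuple(int(s) for s in args.layer_sizes.split(","))
    cfg = RunConfig(
        seed=args.seed, dataset="mnist", mnist_dir=args.mnist_dir,
        device_mode=args.device, layer_sizes=sizes, T=args.T,
        epochs=args.epochs, batch_size=args.batch_size,
    )
    from gsdsnn.experiments import _load_data  # reuse the sweep loader

    train_ds, test_ds = _load_data(cfg, "mnist")
    if args.train_samples:
        train_ds = train_ds.subset(args.train_samples)
    t0 = time.time()
    acc = single_run(cfg, args.regime, args.seed, dataset="mnist",
                     data=(train_ds, test_ds))
    dt = time.time() - t0
    summary = {
        "regime": args.regime, "layer_sizes": list(sizes), "T": args.T,
        "epochs": args.epochs, "batch_size": args.batch_size,
        "train_samples": len(train_ds), "seed": args.seed,
        "test_accuracy": acc, "wall_seconds": dt,
        "config": json.loads(cfg.to_json()),
    }
    atomic_write_text(args.out, json.dumps(summary, indent=2) + "\n")
    print(f"{args.regime} {sizes} T={args.T}: test accuracy {acc:.2%} "
          f"({dt / 60:.1f} min)")


if __name__ == "__main__":
    main()
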