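"""Data/plumbing tests: IDX format, synthetic generator, config, CLI."""

import json
import struct

import numpy as np
import pytest
from click.testing import CliRunner

from gsdsnn import cli
from gsdsnn.data_io import (
    Dataset,
    IdxFormatError,
    RunConfig,
    atomic_write_text,
    class_prototypes,
    read_idx,
    synth_dataset,
    synth_splits,
    write_idx,
)


class TestIdx:
    def _fixture(self, tmp_path):
        images = np.arange(32, dtype=np.uint8).reshape(2, 16) / 255.0
        ds = Dataset(images, np.array([9, 1]), 10, (4, 4))
        ip, lp = tmp_path / "imgs", tmp_path / "labs"
        write_idx(ds, ip, lp)
        return ip, lp

    def test_round_trip_exact_bytes(self, tmp_path):
        ip, lp = self._fixture(tmp_path)
        ds = read_idx(ip, lp)
        np.testing.assert_allclose(ds.images, np.arange(32).reshape(2, 16) / 255.0)
        assert list(ds.labels) == [9, 1]
        assert ds.image_shape == (4, 4)

    def test_bad_magic(self, tmp_path):
        ip, lp = self._fixture(tmp_path)
        raw = bytearray(ip.read_bytes())
        raw[3] = 0x07
        ip.write_bytes(bytes(raw))
        with pytest.raises(IdxFormatError, match="magic"):
            read_idx(ip, lp)

    def test_truncated_file_names_missing_bytes(self, tmp_path):
        ip, lp = self._fixture(tmp_path)
        ip.write_bytes(ip.read_bytes()[:-5])
        with pytest.raises(IdxFormatError, match="truncated"):
            read_idx(ip, lp)

    def test_count_mismatch(self, tmp_path):
        ip, lp = self._fixture(tmp_path)
        lp.write_bytes(struct.pack(">ii", 0x801, 3) + bytes([1, 2, 3]))
        with pytest.raises(IdxFormatError, match="declares"):
            read_idx(ip, lp)


class TestSynthDataset:
    def test_noise_free_nearest_prototype_perfect(self):
        ds = synth_dataset(noise=0.0, samples_per_class=5)
        protos = class_prototypes()
        pred = np.argmin(
            ((ds.images[:, None, :] - protos[None]) ** 2).sum(axis=2), axis=1
        )
        assert np.array_equal(pred, ds.labels)

    def test_same_seed_identical_bytes(self):
        a = synth_dataset(seed=11)
        b = synth_dataset(seed=11)
        assert np.array_equal(a.images, b.images)

    def test_exact_class_balance(self):
        ds = synth_dataset(num_classes=4, samples_per_class=7)
        assert np.all(np.bincount(ds.labels) == 7)

    def test_intensity_bounds(self):
        ds = synth_dataset(noise=0.9)
        assert ds.images.min() >= 0 and ds.images.max() <= 1

    def test_invalid_noise_rejected(self):
        with pytest.raises(ValueError):
            synth_dataset(noise=1.0)

    def test_splits_are_disjoint_draws(self):
        tr, te = synth_splits(train_per_class=4, test_per_class=4, seed=0)
        assert tr.split == "train" and te.split == "test"
        assert not np.array_equal(tr.images[:12], te.images[:12])


class TestRunConfig:
    def test_json_round_trip(self, tmp_path):
        cfg = RunConfig(seed=7, layer_sizes=(64, 32, 3), lr_schedule=((2, 0.5),))
        path = tmp_path / "cfg.json"
        cfg.echo(path)
        again = RunConfig.from_file(path)
        assert again == cfg

    def test_toml_parsing(self, tmp_path):
        path = tmp_path / "cfg.toml"
        path.write_text('seed = 3\nT = 10\nlayer_sizes = [64, 8, 3]\n')
        cfg = RunConfig.from_file(path)
        assert (cfg.seed, cfg.T, cfg.layer_sizes) == (3, 10, (64, 8, 3))

    def test_unknown_key_rejected(self):
        with pytest.raises(ValueError, match="unknown config keys"):
            RunConfig.from_dict({"volts": 3})

    def test_atomic_write_no_partial(self, tmp_path):
        target = tmp_path / "deep" / "out.txt"
        atomic_write_text(target, "payload")
        assert target.read_text() == "payload"
        assert list(target.parent.iterdir()) == [target]


class TestCli:
    def test_bias_table_one_update(self):
        res = CliRunner().invoke(cli.main, ["bias-table", "--kind", "program"])
        assert res.exit_code == 0
        lines = [l for l in res.output.splitlines() if l.strip()]
        assert len(lines) == 5  # header + 4 cell rows
        assert sum("inhibited" in l for l in lines[1:]) == 3
        assert sum(l.endswith("updates") for l in lines[1:]) == 1

    def test_train_smoke_writes_outputs(self, tmp_path):
        cfg = tmp_path / "cfg.json"
        cfg.write_text(json.dumps({
            "epochs": 1, "train_per_class": 5, "test_per_class": 2,
            "layer_sizes": [64, 4, 3], "T": 4, "device_mode": "linear",
        }))
        res = CliRunner().invoke(cli.main, [
            "train", "--config", str(cfg), "--seed", "1",
            "--out", str(tmp_path / "run"), "--dataset", "synthetic",
        ])
        assert res.exit_code == 0, res.output
        assert (tmp_path / "run" / "trace.csv").exists()
        assert (tmp_path / "run" / "summary.json").exists()
        echoed = json.loads((tmp_path / "run" / "config.json").read_text())
        assert echoed["seed"] == 1

    def test_fit_device_recovers_coefficients(self, tmp_path):
        from gsdsnn.device_model import g_ltp, pinned_params

        p = pinned_params(2.0, 2.0, t_max=1.0)
        t = np.linspace(0.01, 0.9, 30)
        csv = tmp_path / "curve.csv"
        np.savetxt(csv, np.column_stack([t, g_ltp(t, p)]), delimiter=",")
        out = tmp_path / "fit.json"
        res = CliRunner().invoke(cli.main, [
            "fit-device", str(csv), "--branch", "ltp", "--out", str(out)
        ])
        assert res.exit_code == 0, res.output
        fit = json.loads(out.read_text())
        assert fit["beta"] == pytest.approx(2.0, rel=1e-4)
        assert fit["rms_residual"] < 1e-8

    def test_make_fixtures_idx_round_trip(self, tmp_path):
        res = CliRunner().invoke(cli.main, [
            "make-fixtures", "--out", str(tmp_path), "--seed", "2"
        ])
        assert res.exit_code == 0, res.output
        ds = read_idx(tmp_path / "train-images-idx3-ubyte",
                      tmp_path / "train-labels-idx1-ubyte")
        assert len(ds) == 300

    def test_convert_smoke(self, tmp_path):
        cfg = tmp_path / "cfg.json"
        cfg.write_text(json.dumps({
            "epochs": 1, "train_per_class": 5, "test_per_class": 2,
            "layer_sizes": [64, 4, 3], "T": 4, "device_mode": "linear",
        }))
        res = CliRunner().invoke(cli.main, [
            "convert", "--config", str(cfg), "--out", str(tmp_path / "c"),
        ])
        assert res.exit_code == 0, res.output
        assert (tmp_path / "c" / "summary.json").exists()

    def test_sweep_smoke(self, tmp_path):
        cfg = tmp_path / "cfg.json"
        cfg.write_text(json.dumps({
            "epochs": 1, "train_per_class": 4, "test_per_class": 2,
            "layer_sizes": [64, 4, 3], "T": 3, "device_mode": "linear",
        }))
        res = CliRunner().invoke(cli.main, [
            "sweep", "--config", str(cfg), "--param", "beta", "--values", "1,4",
            "--replicates", "1", "--out", str(tmp_path / "s"),
        ])
        assert res.exit_code == 0, res.output
        assert (tmp_path / "s" / "sweep_beta_onchip.csv").exists()

    def test_unknown_subcommand_errors(self):
        res = CliRunner().invoke(cli.main, ["frobnicate"])
        assert res.exit_code != 0
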