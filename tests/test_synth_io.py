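import json

import numpy as np
import pytest
from click.testing import CliRunner
from hypothesis import given, settings, strategies as st

from snnpart.cli import main as cli_main
from snnpart.config import load_experiment, load_preset
from snnpart.emulator import EventBatch
from snnpart.errors import ConfigurationError, ValidationError
from snnpart.io import (
    RunManifest,
    config_hash,
    derive_seed,
    read_events,
    write_events,
)
from snnpart.synth import SyntheticTaskSpec, generate_synthetic_images


class TestSyntheticImages:
    def test_fixed_seed_is_deterministic(self):
        spec = SyntheticTaskSpec(seed=3)
        a, la = generate_synthetic_images(spec)
        b, lb = generate_synthetic_images(spec)
        assert np.array_equal(a, b) and np.array_equal(la, lb)

    def test_class_means_differ_on_designated_blobs_only(self):
        spec = SyntheticTaskSpec(n_classes=2, noise_std=0.0, n_samples=40, seed=1)
        images, labels = generate_synthetic_images(spec)
        m0 = images[labels == 0].mean(axis=0)
        m1 = images[labels == 1].mean(axis=0)
        diff = np.abs(m0 - m1) > 1e-12
        masks = [np.zeros(spec.image_shape, bool) for _ in range(2)]
        from snnpart.synth import _blob_mask
        for k, per_class in enumerate(spec.resolved_blobs()):
            for b in per_class:
                masks[k] |= _blob_mask(spec.image_shape, b)
        assert np.array_equal(diff, masks[0] | masks[1])

    def test_overlapping_class_blobs_rejected(self):
        spec = SyntheticTaskSpec(
            n_classes=2,
            blobs=(((0, 0, 2, 2, 1.0),), ((1, 1, 2, 2, 1.0),)),
        )
        with pytest.raises(ValidationError, match="overlap"):
            generate_synthetic_images(spec)

    def test_noiseless_classes_linearly_separable_by_first_spike_times(self):
        from snnpart.encoders import EncoderConfig, encode_images

        spec = SyntheticTaskSpec(n_classes=2, noise_std=0.0, n_samples=20, seed=2)
        images, labels = generate_synthetic_images(spec)
        ev = encode_images(images, EncoderConfig(scheme="linear"))
        raster = ev.to_raster(60, 0.5)
        active = raster.sum(axis=1)  # (n, pixels): which pixel spiked
        # a simple linear readout on spike counts per pixel separates the classes
        class0 = active[labels == 0].mean(axis=0)
        class1 = active[labels == 1].mean(axis=0)
        w = class1 - class0
        scores = active @ w
        predicted = (scores > scores.mean()).astype(int)
        assert np.array_equal(predicted, labels)


class TestEventCsv:
    @settings(derandomize=True, max_examples=25)
    @given(data=st.data())
    def test_round_trip_is_identity_up_to_ordering(self, tmp_path_factory, data):
        n = data.draw(st.integers(0, 30))
        samples = data.draw(st.lists(st.integers(0, 3), min_size=n, max_size=n))
        times = data.draw(st.lists(st.floats(0, 30, allow_nan=False), min_size=n, max_size=n))
        neurons = data.draw(st.lists(st.integers(0, 9), min_size=n, max_size=n))
        batch = EventBatch(samples, times, neurons, 4, 10)
        path = tmp_path_factory.mktemp("ev") / "events.csv"
        write_events(path, {"pop": batch})
        if n == 0:
            assert read_events(path) == {}
            return
        back = read_events(path, sizes={"pop": 10}, n_samples=4)["pop"]
        want = batch.sorted()
        assert np.array_equal(back.samples, want.samples)
        assert np.array_equal(back.times, want.times)
        assert np.array_equal(back.neurons, want.neurons)

    def test_empty_file_reads_as_empty(self, tmp_path):
        p = tmp_path / "e.csv"
        write_events(p, {})
        assert read_events(p) == {}

    def test_negative_time_raises_with_line_number(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("sample_id,time_us,population,neuron_id\n0,-1.0,pop,0\n")
        with pytest.raises(ValidationError, match="line 2"):
            read_events(p)

    def test_malformed_row_raises_with_line_number(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("sample_id,time_us,population,neuron_id\n0,abc,pop,0\n")
        with pytest.raises(ValidationError, match="line 2"):
            read_events(p)


class TestManifestAndSeeds:
    def test_manifest_round_trips_losslessly(self, tmp_path):
        m = RunManifest(
            config_hash="abc", seed=7, schedule=[["h1", "h2"], ["readout"]],
            event_files={"all": "x.csv"}, dropped_events={"h1": 3},
            versions={"snnpart": "0.1.0"},
        )
        path = tmp_path / "m.json"
        m.to_json(path)
        assert RunManifest.from_json(path) == m

    def test_derived_seeds_are_stable_distinct_and_bounded(self):
        s1 = derive_seed(42, "jitter")
        assert s1 == derive_seed(42, "jitter")
        assert s1 != derive_seed(42, "dropout")
        assert s1 != derive_seed(43, "jitter")
        assert 0 <= s1 < 2**31

    def test_config_hash_is_order_insensitive(self):
        assert config_hash({"a": 1, "b": 2}) == config_hash({"b": 2, "a": 1})


class TestExperimentConfig:
    def test_mnist_preset_plans_five_runs(self):
        exp = load_preset("mnist")
        plan = exp.plan()
        assert plan.total_runs == 5
        assert exp.encoder.scheme == "linear" and exp.train.decoding == "max_over_time"

    def test_eurosat_preset_plans_ten_runs(self):
        exp = load_preset("eurosat")
        assert exp.plan().total_runs == 10
        assert exp.encoder.scheme == "lif_current"
        assert exp.encoder.T == 64.0
        assert exp.train.decoding == "last_value"

    def test_unknown_keys_are_listed_in_the_error(self, tmp_path):
        p = tmp_path / "exp.yaml"
        p.write_text(
            "name: x\ninput: {shape: [4, 4, 1]}\n"
            "layers: [{name: a, size: 4, fan_in: 16}]\nbogus_key: 1\n"
        )
        with pytest.raises(ConfigurationError, match="bogus_key"):
            load_experiment(p)

    def test_empty_file_is_a_schema_error(self, tmp_path):
        p = tmp_path / "empty.yaml"
        p.write_text("")
        with pytest.raises(ConfigurationError):
            load_experiment(p)


class TestCliDeterminism:
    def test_plan_output_reproduces_printed_partitioning(self):
        runner = CliRunner()
        res = runner.invoke(cli_main, ["plan", "--preset", "mnist"])
        assert res.exit_code == 0, res.output
        assert "total runs: 5" in res.output

    def test_encode_is_deterministic_under_fixed_seed(self, tmp_path):
        runner = CliRunner()
        outs = []
        for name in ("a.csv", "b.csv"):
            out = tmp_path / name
            res = runner.invoke(
                cli_main,
                ["encode", "--preset", "mnist", "--n-samples", "4",
                 "--seed", "11", "--out", str(out)],
            )
            assert res.exit_code == 0, res.output
            outs.append(out.read_text())
        assert outs[0] == outs[1]

    def test_run_writes_manifest_with_schedule_and_hash(self, tmp_path):
        runner = CliRunner()
        stim = tmp_path / "stim.csv"
        cfg = tmp_path / "exp.yaml"
        cfg.write_text(
            "name: toy\ninput: {shape: [2, 2, 1]}\n"
            "layers:\n  - {name: hidden, size: 3, fan_in: 4}\n"
            "  - {name: readout, size: 2, fan_in: 3}\n"
            "encoder: {scheme: linear, T: 30.0, dt: 0.5}\n"
        )
        runner.invoke(cli_main, ["encode", "--config", str(cfg), "--n-samples", "2",
                                 "--seed", "1", "--out", str(stim)])
        manifests = []
        for sub in ("r1", "r2"):
            outdir = tmp_path / sub
            res = runner.invoke(
                cli_main,
                ["run", "--config", str(cfg), "--stimuli", str(stim),
                 "--seed", "3", "--outdir", str(outdir)],
            )
            assert res.exit_code == 0, res.output
            m = json.loads((outdir / "manifest.json").read_text())
            assert m["schedule"] == [["hidden1"], ["readout"]]
            m["event_files"] = m["trace_files"] = {}
            manifests.append(json.dumps(m, sort_keys=True))
        assert manifests[0] == manifests[1]
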