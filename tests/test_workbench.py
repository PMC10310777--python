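"""I/O round trips, configuration, CLI plumbing and the demo pipeline."""

import json

import numpy as np
import pytest
import yaml
from click.testing import CliRunner

from cyclect import CTVolume, cli, io, phantom
from cyclect.config import RunConfig, load_config, save_config
from cyclect.demo import run_demo
from cyclect.feature_eval import TrainSchedule
from cyclect.gan import DiscriminatorSpec, GeneratorSpec
from cyclect.training import TrainConfig


class TestNiftiIO:
    def test_round_trip_values_and_spacing(self, tmp_path, rng):
        vol = CTVolume(
            rng.uniform(-1000, 1000, (10, 12, 14)).astype(np.float32),
            spacing=(1.0, 1.0, 2.0),
            units="HU",
        )
        path = io.write_volume(vol, tmp_path / "vol.nii")
        back = io.read_volume(path)
        np.testing.assert_array_equal(back.values, vol.values)
        assert back.spacing == pytest.approx(vol.spacing, abs=1e-6)
        assert back.units == "HU"

    def test_normalized_units_survive(self, tmp_path, rng):
        vol = CTVolume(rng.uniform(-1, 1, (6, 6, 6)), units="normalized")
        back = io.read_volume(io.write_volume(vol, tmp_path / "n.nii"))
        assert back.units == "normalized"

    def test_malformed_file_gives_parse_error(self, tmp_path):
        bad = tmp_path / "not_nifti.nii"
        bad.write_bytes(b"this is not a nifti file")
        with pytest.raises(ValueError, match="parse"):
            io.read_volume(bad)


class TestConfig:
    def test_yaml_round_trip(self, tmp_path):
        cfg = RunConfig(seed=5)
        path = tmp_path / "run.yaml"
        save_config(cfg, path)
        back = load_config(path)
        assert back.seed == 5
        assert back.phantom == cfg.phantom
        assert back.training == cfg.training

    def test_unknown_keys_rejected(self, tmp_path):
        path = tmp_path / "bad.yaml"
        path.write_text(yaml.safe_dump({"phantom": {"not_a_field": 1}}))
        with pytest.raises(ValueError, match="unknown keys"):
            load_config(path)


def _demo_config(seed=0, **phantom_overrides):
    return RunConfig(
        phantom=phantom.PhantomConfig(
            grid_shape=(24, 24, 24), noise_sd_hu=10.0, n_vessels=2, seed=3, **phantom_overrides
        ),
        generator=GeneratorSpec(base_filters=4, n_residual=1, encode_kernel=3, final_kernel=3),
        discriminator=DiscriminatorSpec(base_filters=4),
        training=TrainConfig(patch_size=8, n_iterations=3, seed=seed),
        head_schedule=TrainSchedule(epochs=5, learning_rate=1e-3, batch_size=16, n_validation=8),
        n_contrast=2,
        n_noncontrast=2,
        patch_size=8,
        stride=4,
        seed=seed,
    )


class TestDemo:
    def test_report_contains_every_stage(self, tmp_path):
        report = run_demo(_demo_config(), out_dir=tmp_path)
        for section in (
            "phantoms",
            "preprocess",
            "train",
            "synthesize",
            "reader_eval",
            "feature_eval",
            "drift_eval",
        ):
            assert section in report
        assert (tmp_path / "report.json").exists()
        assert (tmp_path / "checkpoint.npz").exists()
        losses = report["train"]["final_losses"]
        assert all(np.isfinite(v) for v in losses.values())

    def test_zero_contrast_marks_recovery_not_applicable(self):
        report = run_demo(_demo_config(contrast_delta_hu=0.0))
        assert report["synthesize"]["vessel_error_reduction_pct"] == "not_applicable"

    def test_deterministic_stages_repeat_identically(self):
        r1 = run_demo(_demo_config(seed=2))
        r2 = run_demo(_demo_config(seed=2))
        assert r1["train"]["final_losses"] == r2["train"]["final_losses"]
        assert r1["reader_eval"] == r2["reader_eval"]
        assert r1["synthesize"] == r2["synthesize"]


class TestCli:
    def test_phantoms_and_manifest(self, tmp_path):
        cfg_path = tmp_path / "cfg.yaml"
        save_config(_demo_config(), cfg_path)
        runner = CliRunner()
        result = runner.invoke(
            cli.main,
            ["phantoms", "--config", str(cfg_path), "--n-contrast", "1",
             "--n-noncontrast", "1", "--seed", "0", "--out", str(tmp_path / "cohort")],
        )
        assert result.exit_code == 0, result.output
        manifest = (tmp_path / "cohort" / "manifest.tsv").read_text().splitlines()
        assert manifest[0].split("\t") == ["subject_id", "domain", "path"]
        assert len(manifest) == 3

    def test_evaluate_readers_from_rates(self):
        runner = CliRunner()
        result = runner.invoke(
            cli.main, ["evaluate-readers", "--from-rates", "0.8,0.62;0.92,0.13;0.82,0.23"]
        )
        assert result.exit_code == 0, result.output
        payload = json.loads(result.output)
        assert payload["panel"]["mean_accuracy"] == pytest.approx(0.587, abs=5e-4)

    def test_select_features_round_trip(self, tmp_path, rng):
        import pandas as pd

        y = np.r_[np.ones(30), np.zeros(30)]
        table = pd.DataFrame(
            {
                "informative": y + 0.1 * rng.normal(0, 1, 60),
                "copy": y + 0.100001 * rng.normal(0, 1, 60),
                "noise": rng.normal(0, 1, 60),
                "label": y,
            },
            index=[f"s{i}" for i in range(60)],
        )
        table.index.name = "subject"
        src = tmp_path / "features.csv"
        table.to_csv(src)
        out = tmp_path / "selected.csv"
        runner = CliRunner()
        result = runner.invoke(
            cli.main, ["select-features", "--table", str(src), "--out", str(out)]
        )
        assert result.exit_code == 0, result.output
        assert "->" in result.output
        assert out.exists()
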