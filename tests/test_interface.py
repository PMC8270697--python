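"""Config round trips, tile/report I/O, and the CLI workflow."""

import json

import numpy as np
import pytest
import yaml
from click.testing import CliRunner

from virtstain import cli
from virtstain import io as vio
from virtstain.config import ConfigError, RunConfig, load_config, save_config
from virtstain.types import ImageTile, MetricReport, STAINED


class TestConfig:
    def test_minimal_file_gets_defaults(self, tmp_path):
        p = tmp_path / "cfg.yaml"
        p.write_text("seed: 3\n")
        cfg = load_config(p)
        assert cfg.seed == 3
        assert cfg.data.n_stained == 400 and cfg.data.n_unstained == 80
        assert cfg.stage2.lambda_pix == 100.0

    def test_unknown_key_named_in_error(self, tmp_path):
        p = tmp_path / "cfg.yaml"
        p.write_text("stage2:\n  lamda_pix: 10\n")
        with pytest.raises(ConfigError, match="lamda_pix"):
            load_config(p)

    def test_missing_file(self, tmp_path):
        with pytest.raises(IOError):
            load_config(tmp_path / "nope.yaml")

    def test_save_load_roundtrip(self, tmp_path):
        cfg = RunConfig(seed=9, out_dir="x")
        p = tmp_path / "cfg.yaml"
        save_config(cfg, p)
        assert load_config(p) == cfg

    def test_seed_fanout_distinct_per_stage(self):
        cfg = RunConfig(seed=1)
        seeds = {cfg.stage_seed(s) for s in ("data", "stage1", "stage2", "classifier")}
        assert len(seeds) == 4
        assert all(0 <= s < 2 ** 31 for s in seeds)


class TestTileIO:
    def test_8bit_endpoints_map_to_unit_range(self, tmp_path):
        arr = np.zeros((4, 4, 3))
        arr[0, 0] = 1.0  # -> 255
        tile = ImageTile(arr, STAINED)
        path = tmp_path / "t.png"
        vio.write_tile(tile, path)
        back = vio.read_tile(path, STAINED)
        assert back.value_range == (-1.0, 1.0)
        assert back.data[0, 0, 0] == pytest.approx(1.0)
        assert back.data[1, 1, 0] == pytest.approx(-1.0)

    def test_roundtrip_within_quantization(self, tmp_path):
        rng = np.random.default_rng(0)
        tile = ImageTile(rng.uniform(0, 1, (8, 8, 3)), STAINED)
        vio.write_tile(tile, tmp_path / "t.png")
        back = vio.read_tile(tmp_path / "t.png")
        recovered = (back.data + 1.0) / 2.0
        assert np.abs(recovered - tile.data).max() <= 1.0 / 255.0 + 1e-12

    def test_tiff_roundtrip(self, tmp_path):
        tile = ImageTile(np.full((4, 4, 3), 0.5), STAINED)
        vio.write_tile(tile, tmp_path / "t.tif")
        back = vio.read_tile(tmp_path / "t.tif")
        assert np.abs((back.data + 1) / 2 - 0.5).max() <= 1.0 / 255.0

    def test_mixed_sizes_rejected_in_strict_mode(self, tmp_path):
        vio.write_tile(ImageTile(np.zeros((4, 4, 3)), STAINED), tmp_path / "a.png")
        vio.write_tile(ImageTile(np.zeros((8, 8, 3)), STAINED), tmp_path / "b.png")
        with pytest.raises(ValueError):
            vio.read_tiles(tmp_path)
        assert len(vio.read_tiles(tmp_path, strict=False)) == 2

    def test_unreadable_file_names_the_file(self, tmp_path):
        bad = tmp_path / "broken.png"
        bad.write_bytes(b"not a png")
        with pytest.raises(IOError, match="broken.png"):
            vio.read_tile(bad)

    def test_listing_is_lexicographic(self, tmp_path):
        for name, v in [("b.png", 0.2), ("a.png", 0.8), ("c.png", 0.5)]:
            vio.write_tile(ImageTile(np.full((2, 2, 3), v), STAINED), tmp_path / name)
        tiles = vio.read_tiles(tmp_path)
        means = [round((t.data[0, 0, 0] + 1) / 2, 1) for t in tiles]
        assert means == [0.8, 0.2, 0.5]


class TestReports:
    def test_metric_report_roundtrip(self, tmp_path):
        rep = MetricReport(fid=1.5, is_score=1.2, ms=0.9, n_real=4, n_fake=4,
                           embedder="flatten", is_gap=0.1)
        p = tmp_path / "rep.json"
        vio.write_report(rep, p)
        back = vio.read_report(p)
        assert back["fid"] == 1.5
        assert back["schema_version"] == 1

    def test_empty_log_is_valid_jsonl(self, tmp_path):
        p = tmp_path / "log.jsonl"
        vio.write_report([], p)
        assert vio.read_report(p) == []

    def test_log_roundtrip_with_version(self, tmp_path):
        log = [{"step": 0, "loss": 1.0}, {"step": 1, "loss": 0.5}]
        p = tmp_path / "log.jsonl"
        vio.write_report(log, p)
        back = vio.read_report(p)
        assert [e["step"] for e in back] == [0, 1]
        assert all(e["schema_version"] == 1 for e in back)


@pytest.fixture(scope="module")
def cli_workspace(tmp_path_factory):
    """Run the full CLI workflow once at miniature scale."""
    root = tmp_path_factory.mktemp("cliws")
    cfg = {
        "seed": 5,
        "out_dir": str(root / "run"),
        "data": {"n_stained": 6, "n_unstained": 4, "tile": 32, "density": 5.0,
                 "noise_sd": 0.02},
        "stage1": {"steps": 2, "batch_size": 1, "base_width": 4,
                   "n_res_blocks": 1, "buffer_capacity": 8},
        "stage2": {"steps": 2, "batch_size": 1, "feature_width": 8,
                   "critic_width": 4},
    }
    cfg_path = root / "cfg.yaml"
    cfg_path.write_text(yaml.safe_dump(cfg))
    runner = CliRunner()
    for cmd in ("simulate", "train-stage1", "build-pairs", "train-stage2"):
        res = runner.invoke(cli.main, [cmd, "--config", str(cfg_path)])
        assert res.exit_code == 0, f"{cmd}: {res.output}"
    return root, cfg_path, runner


class TestCLI:
    def test_workflow_artifacts(self, cli_workspace):
        root, _, _ = cli_workspace
        run = root / "run"
        assert (run / "data" / "manifest.json").exists()
        assert (run / "stage1.npz").exists()
        assert (run / "pairs" / "manifest.json").exists()
        assert (run / "stage2.npz").exists()
        log = [json.loads(l) for l in (run / "stage2_log.jsonl").read_text().splitlines()]
        assert len(log) == 2

    def test_stain_command(self, cli_workspace):
        root, cfg_path, runner = cli_workspace
        unstained_dir = root / "run" / "pairs" / "unstained"
        out = root / "stained_out"
        res = runner.invoke(cli.main, ["stain", "--config", str(cfg_path),
                                       "--input", str(unstained_dir),
                                       "--output", str(out)])
        assert res.exit_code == 0, res.output
        assert len(list(out.glob("*.png"))) == 6

    def test_evaluate_command(self, cli_workspace):
        root, _, runner = cli_workspace
        run = root / "run"
        out = root / "metrics.json"
        res = runner.invoke(cli.main, [
            "evaluate", "--real", str(run / "pairs" / "stained"),
            "--fake", str(root / "stained_out"),
            "--out", str(out), "--feature-embedder", "pool4"])
        assert res.exit_code == 0, res.output
        rep = json.loads(out.read_text())
        assert rep["fid"] >= 0
        assert rep["is_score"] >= 1.0

    def test_validation_error_exits_2(self, cli_workspace, tmp_path):
        _, _, runner = cli_workspace
        bad = tmp_path / "bad.yaml"
        bad.write_text("stage2:\n  lamda_pix: 1\n")
        res = runner.invoke(cli.main, ["simulate", "--config", str(bad)])
        assert res.exit_code == 2
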