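"""Schema-validated CSV I/O, the full pipeline run, and the CLI surface."""
import json

import pytest
from click.testing import CliRunner

from cwsipy import SchemaError, read_table, run_pipeline, write_table
from cwsipy.cli import main as cli_main
from cwsipy.pipeline import PipelineConfig
from cwsipy.synthetic import generate_scenario

from conftest import small_scenario


@pytest.fixture(scope="module")
def scenario_data():
    return generate_scenario(small_scenario(seed=4))


class TestReadTable:
    def test_roundtrip_through_own_reader(self, scenario_data, tmp_path):
        path = write_table(scenario_data.observations, tmp_path / "obs.csv", "observations")
        back = read_table(path, "observations")
        assert len(back) == len(scenario_data.observations)
        assert back["tc_n"].equals(scenario_data.observations["tc_n"].reset_index(drop=True))

    def test_missing_column_named_in_error(self, scenario_data, tmp_path):
        df = scenario_data.observations.drop(columns=["tc_w"])
        df.to_csv(tmp_path / "bad.csv", index=False)
        with pytest.raises(SchemaError, match="tc_w"):
            read_table(tmp_path / "bad.csv", "observations")

    def test_unparseable_value_reports_line_number(self, scenario_data, tmp_path):
        df = scenario_data.observations.copy()
        df["tc_n"] = df["tc_n"].astype(object)
        df.loc[df.index[2], "tc_n"] = "oops"
        df.to_csv(tmp_path / "bad.csv", index=False)
        with pytest.raises(SchemaError, match="lines \\[4\\]"):
            read_table(tmp_path / "bad.csv", "observations")

    def test_duplicate_keys_rejected(self, scenario_data, tmp_path):
        import pandas as pd

        df = scenario_data.observations
        df2 = pd.concat([df, df.iloc[[0]]])
        df2.to_csv(tmp_path / "dup.csv", index=False)
        with pytest.raises(SchemaError, match="duplicate"):
            read_table(tmp_path / "dup.csv", "observations")


class TestPipeline:
    def test_end_to_end_outputs_and_manifest(self, tmp_path):
        out = tmp_path / "run"
        res = run_pipeline(PipelineConfig(outdir=out, scenario=small_scenario(seed=9)))
        for name in (
            "observations", "baselines", "cwsi_records", "cwsi_summary",
            "plot_summary", "traits", "relations", "verdicts",
        ):
            assert (out / f"{name}.csv").exists(), name
        manifest = json.loads((out / "manifest.json").read_text())
        assert manifest["seed"] == 9
        assert manifest["config_sha256"]
        assert set(manifest["outputs"]) >= {"baselines", "cwsi_records", "verdicts"}
        assert not res.summary.empty

    def test_rerun_is_byte_identical(self, tmp_path):
        out1, out2 = tmp_path / "a", tmp_path / "b"
        run_pipeline(PipelineConfig(outdir=out1, scenario=small_scenario(seed=9)))
        run_pipeline(PipelineConfig(outdir=out2, scenario=small_scenario(seed=9)))
        for name in ("baselines", "cwsi_records", "cwsi_summary", "verdicts"):
            assert (out1 / f"{name}.csv").read_bytes() == (out2 / f"{name}.csv").read_bytes()

    def test_empty_observations_abort_names_the_stage(self, tmp_path):
        obs = generate_scenario(small_scenario(seed=1)).observations.iloc[:0]
        path = write_table(obs, tmp_path / "empty.csv", "observations")
        cfg = PipelineConfig(outdir=tmp_path / "o", obs_path=path)
        with pytest.raises(Exception, match="calibrate"):
            run_pipeline(cfg)

    def test_baselines_roundtrip_through_reader(self, tmp_path):
        res = run_pipeline(PipelineConfig(outdir=tmp_path / "r", scenario=small_scenario(seed=3)))
        back = read_table(tmp_path / "r" / "baselines.csv", "baselines")
        assert back["slope_a"].iloc[0] == pytest.approx(res.baselines["slope_a"].iloc[0])


class TestCli:
    def test_simulate_then_calibrate(self, tmp_path):
        runner = CliRunner()
        cfg = small_scenario(seed=2)
        cfg_path = tmp_path / "scenario.yaml"
        cfg.to_yaml(cfg_path)
        r1 = runner.invoke(
            cli_main,
            ["simulate", "--config", str(cfg_path), "--out", str(tmp_path / "sim")],
        )
        assert r1.exit_code == 0, r1.output
        r2 = runner.invoke(
            cli_main,
            [
                "calibrate",
                "--input", str(tmp_path / "sim" / "observations.csv"),
                "--out", str(tmp_path / "baselines.csv"),
            ],
        )
        assert r2.exit_code == 0, r2.output
        assert "slope_a" in r2.output

    def test_full_run_verb(self, tmp_path):
        runner = CliRunner()
        cfg = PipelineConfig(outdir=tmp_path / "x", scenario=small_scenario(seed=2))
        # exercise `run` via YAML config path
        import yaml

        d = {"outdir": str(tmp_path / "x"), "scenario": cfg.scenario.to_dict(), "seed": 2}
        (tmp_path / "pipe.yaml").write_text(yaml.safe_dump(d))
        r = runner.invoke(
            cli_main,
            ["run", "--config", str(tmp_path / "pipe.yaml"), "--out", str(tmp_path / "x")],
        )
        assert r.exit_code == 0, r.output
        assert "report bundle" in r.output
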