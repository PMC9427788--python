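"""End-to-end study orchestration and the CLI surface."""

import json

import pytest
from click.testing import CliRunner

from dnabind import errors, io
from dnabind.cli import main as cli_main
from dnabind.evidence import BindingMode
from dnabind.report import StudyConfig, run_full_analysis, write_report
from dnabind.scenarios import write_paper_like_study


@pytest.fixture(scope="module")
def study_dir(tmp_path_factory):
    out = tmp_path_factory.mktemp("study")
    cfg = write_paper_like_study(out, seed=2026)
    return out, cfg


class TestFullAnalysis:
    def test_full_synthetic_study(self, study_dir):
        _, cfg_path = study_dir
        report = run_full_analysis(StudyConfig.from_yaml(cfg_path))
        assert report.errors == []
        assert len(report.fits) == 4
        assert all(f.kb_valid for f in report.fits)
        assert report.thermo is not None and report.force is not None
        assert report.verdict is not None
        assert report.verdict.mode is BindingMode.MINOR_GROOVE
        # both Gibbs routes negative: spontaneous binding at every T
        assert all(ga < 0 and gb < 0
                   for _, ga, gb in report.thermo.per_temperature)

    def test_idempotent_rerun(self, study_dir):
        _, cfg_path = study_dir
        r1 = run_full_analysis(StudyConfig.from_yaml(cfg_path))
        r2 = run_full_analysis(StudyConfig.from_yaml(cfg_path))
        assert r1.to_json() == r2.to_json()

    def test_kb_series_only_config(self, tmp_path, published_kb_series):
        rows = ["temperature_K,kb_per_M"] + [
            f"{t},{k}" for t, k in published_kb_series.entries]
        (tmp_path / "kb.csv").write_text("\n".join(rows) + "\n")
        io.write_sidecar({"kb_series_csv": "kb.csv"}, tmp_path / "study.yaml")
        report = run_full_analysis(
            StudyConfig.from_yaml(tmp_path / "study.yaml"))
        assert report.fits == [] and report.verdict is None
        dg_a = [ga for _, ga, _ in report.thermo.per_temperature]
        expected = [-21.72, -22.02, -22.344, -22.642]
        assert dg_a == pytest.approx(expected, abs=0.01)

    def test_empty_config_rejected(self, tmp_path):
        io.write_sidecar({}, tmp_path / "study.yaml")
        with pytest.raises(errors.DnabindError, match="empty study config"):
            StudyConfig.from_yaml(tmp_path / "study.yaml")

    def test_stage_error_reported_not_fatal(self, tmp_path):
        (tmp_path / "bad.csv").write_text("wrong,cols\n1,2\n")
        io.write_sidecar(
            {"viscosity": {"csv": "bad.csv", "buffer_flow_time_s": 100.0,
                           "dna_conc_M": 8.25e-5}},
            tmp_path / "study.yaml")
        report = run_full_analysis(
            StudyConfig.from_yaml(tmp_path / "study.yaml"))
        assert len(report.errors) == 1
        assert report.errors[0].stage == "viscosity"

    def test_write_report_files(self, study_dir, tmp_path):
        _, cfg_path = study_dir
        report = run_full_analysis(StudyConfig.from_yaml(cfg_path))
        j, t = write_report(report, tmp_path / "out")
        data = json.loads(j.read_text())
        assert "binding_fits" in data and "provenance" in data
        assert data["provenance"]["thresholds"]["displacement"] == 0.10
        assert "Binding mode: minor_groove" in t.read_text()


class TestCli:
    def test_fit_kb_outputs_json(self, study_dir):
        out, _ = study_dir
        runner = CliRunner()
        io.write_sidecar({"temperature_K": 298.0, "dna_conc_M": 8.25e-5},
                         out / "meta.yaml")
        res = runner.invoke(cli_main, [
            "fit-kb", "--titration", str(out / "titration_298K.csv"),
            "--config", str(out / "meta.yaml")])
        assert res.exit_code == 0, res.output
        payload = json.loads(res.output)
        assert payload["kb_valid"] and payload["n_points"] >= 3

    def test_thermo_command(self, tmp_path, published_kb_series):
        rows = ["temperature_K,kb_per_M"] + [
            f"{t},{k}" for t, k in published_kb_series.entries]
        (tmp_path / "kb.csv").write_text("\n".join(rows) + "\n")
        res = CliRunner().invoke(cli_main,
                                 ["thermo", "--kb-series", str(tmp_path / "kb.csv")])
        assert res.exit_code == 0, res.output
        payload = json.loads(res.output)
        assert payload["delta_s_J_molK"] == pytest.approx(61.74, abs=0.01)

    def test_simulate_and_report_round_trip(self, study_dir, tmp_path):
        out, cfg_path = study_dir
        res = CliRunner().invoke(cli_main, [
            "report", "--config", str(cfg_path), "--out", str(tmp_path / "rep")])
        assert res.exit_code == 0, res.output
        assert (tmp_path / "rep" / "report.json").exists()
        assert "Binding mode: minor_groove" in res.output

    def test_simulate_titration_writes_truth(self, tmp_path):
        res = CliRunner().invoke(cli_main, [
            "simulate", "titration", "--out", str(tmp_path), "--seed", "5"])
        assert res.exit_code == 0, res.output
        truth = json.loads((tmp_path / "titration_truth.json").read_text())
        assert truth["kb"] == pytest.approx(6.42e3)
        assert (tmp_path / "titration.csv").exists()
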