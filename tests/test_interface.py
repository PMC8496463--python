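"""I/O dialects, configuration round trips, pipeline determinism and CLI."""
import json
from pathlib import Path

import numpy as np
import pandas as pd
import pytest
from click.testing import CliRunner

import specphyto as sp
from specphyto.cli import main
from specphyto.io import read_raw_pam, sigma_from_par_ii
from specphyto.pipeline import run_pipeline, write_campaign


class TestConfig:
    def test_yaml_round_trip(self, tmp_path):
        cfg = sp.PipelineConfig(seed=42, n_stations=7, ek_unit="relative",
                                selection_alpha=0.01)
        path = tmp_path / "cfg.yaml"
        cfg.to_yaml(path)
        assert sp.PipelineConfig.from_yaml(path) == cfg

    def test_unknown_key_rejected(self):
        with pytest.raises(sp.ValidationError, match="unknown"):
            sp.PipelineConfig.from_yaml("seed: 1\nbogus: true\n")

    def test_invalid_unit_rejected(self):
        with pytest.raises(sp.ValidationError):
            sp.PipelineConfig(ek_unit="both").validate()


class TestReadRawPam:
    HEADERS = ["Fm (Fm')", "Fm'"]

    @pytest.mark.parametrize("fm_header", HEADERS)
    def test_header_variants_accepted(self, tmp_path, fm_header):
        path = tmp_path / "raw.csv"
        path.write_text(
            f"wavelength,PAR,F,{fm_header}\n"
            "440,0,0.4,1.0\n440,100,0.35,0.9\n440,200,0.33,0.85\n")
        curves, rejects = read_raw_pam(path)
        assert len(curves) == 1 and rejects.empty
        assert np.allclose(curves[0].fm_prime, [1.0, 0.9, 0.85])

    def test_semicolon_decimal_comma_dialect(self, tmp_path):
        path = tmp_path / "raw.csv"
        path.write_text(
            "wavelength;PAR;F;Fm'\n"
            "440;0;0,4;1,0\n440;100;0,35;0,9\n")
        curves, _ = read_raw_pam(path)
        assert curves[0].f[1] == pytest.approx(0.35)

    def test_invalid_rows_routed_to_rejects(self, tmp_path):
        path = tmp_path / "raw.csv"
        path.write_text(
            "wavelength,PAR,F,Fm'\n"
            "440,0,0.4,1.0\n440,100,0.95,0.9\n440,200,0.33,0.85\n")
        curves, rejects = read_raw_pam(path)
        assert list(rejects["reason"]) == ["Fm' < F"]
        assert len(curves[0].par) == 2

    def test_zero_offset_subtracted(self, tmp_path):
        path = tmp_path / "raw.csv"
        path.write_text(
            "wavelength,PAR,F,Fm',zero_offset\n"
            "440,0,0.5,1.1,0.1\n440,100,0.45,1.0,0.1\n")
        curves, _ = read_raw_pam(path)
        assert np.allclose(curves[0].f, [0.4, 0.35])
        assert np.allclose(curves[0].fm_prime, [1.0, 0.9])

    def test_missing_mandatory_column_listed(self, tmp_path):
        path = tmp_path / "raw.csv"
        path.write_text("wavelength,PAR,F\n440,0,0.4\n")
        with pytest.raises(sp.ValidationError, match="fm_prime"):
            read_raw_pam(path)

    def test_par_restart_splits_replicates(self, tmp_path):
        path = tmp_path / "raw.csv"
        path.write_text(
            "wavelength,PAR,F,Fm'\n"
            "440,0,0.4,1.0\n440,100,0.35,0.9\n"
            "440,0,0.41,1.0\n440,100,0.36,0.91\n")
        curves, _ = read_raw_pam(path)
        assert len(curves) == 2
        assert curves[0].replicate == 1 and curves[1].replicate == 2

    def test_sigma_back_computation(self):
        # PAR(II) = sigma * 0.602214076 * PAR
        assert sigma_from_par_ii(301.107038, 100.0) == pytest.approx(5.0, rel=1e-8)


class TestPipeline:
    def test_raw_round_trip_matches_in_memory(self, tmp_path):
        bundle = sp.simulate_campaign(seed=5, n_stations=3,
                                      wavelengths=(440, 540))
        raw = tmp_path / "raw"
        write_campaign(bundle, raw)
        cfg = sp.PipelineConfig(seed=5, n_stations=3, wavelengths=[440, 540])
        res_mem = run_pipeline(cfg)
        cfg_raw = sp.PipelineConfig(seed=5, n_stations=3,
                                    wavelengths=[440, 540], raw_dir=str(raw))
        res_raw = run_pipeline(cfg_raw)
        a = res_mem.params.set_index(["station", "wavelength"]).sort_index()
        b = res_raw.params.set_index(["station", "wavelength"]).sort_index()
        num = a.select_dtypes(float)
        assert np.allclose(num, b[num.columns], rtol=1e-6)

    def test_run_determinism_bit_for_bit(self, tmp_path):
        cfg = sp.PipelineConfig(seed=9, n_stations=4, wavelengths=[440, 480, 540])
        d1, d2 = tmp_path / "r1", tmp_path / "r2"
        run_pipeline(cfg, out_dir=d1)
        run_pipeline(cfg, out_dir=d2)
        for name in ("params.csv", "stations.csv", "trend.csv",
                     "detrended.csv", "pta.json", "rda.json", "manifest.json"):
            assert (d1 / name).read_bytes() == (d2 / name).read_bytes(), name

    def test_station_missing_wavelength_dropped_from_pta_only(self, tmp_path):
        bundle = sp.simulate_campaign(seed=6, n_stations=4,
                                      wavelengths=(440, 480, 590))
        raw = tmp_path / "raw"
        write_campaign(bundle, raw)
        # Remove one station's 590 nm measurements from the raw streams.
        for name in ("rlc.csv", "induction.csv"):
            df = pd.read_csv(raw / name)
            df = df[~((df.station == "S02") & (df.wavelength == 590))]
            df.to_csv(raw / name, index=False)
        cfg = sp.PipelineConfig(seed=6, n_stations=4,
                                wavelengths=[440, 480, 590], raw_dir=str(raw))
        res = run_pipeline(cfg)
        assert "S02" in res.params["station"].unique()
        assert "S02" not in res.pta_result.row_coords.index


class TestCli:
    def test_simulate_then_stage_commands(self, tmp_path):
        runner = CliRunner()
        cfg = tmp_path / "cfg.yaml"
        sp.PipelineConfig(seed=2, n_stations=3, wavelengths=[440, 540]).to_yaml(cfg)
        out = tmp_path / "camp"
        r = runner.invoke(main, ["simulate", "--config", str(cfg),
                                 "--out", str(out)])
        assert r.exit_code == 0, r.output
        assert (out / "rlc.csv").exists()
        r2 = runner.invoke(main, ["run", "--config", str(cfg),
                                  "--out", str(tmp_path / "run")])
        assert r2.exit_code == 0, r2.output
        manifest = json.loads((tmp_path / "run" / "manifest.json").read_text())
        assert manifest["seed"] == 2

    def test_invalid_config_exits_2(self, tmp_path):
        cfg = tmp_path / "bad.yaml"
        cfg.write_text("ek_unit: both\n")
        r = CliRunner().invoke(main, ["run", "--config", str(cfg)])
        assert r.exit_code == 2
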