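"""Ensemble statistics, headline summaries, and output files."""

import json

import numpy as np
import pytest

import vivforecast as vf
from vivforecast.ensemble import replicate_seeds

from conftest import stochastic_config


def make_summary(years, tin_s, tin_t):
    """Assemble an EnsembleSummary directly from per-year means (SDs zero)."""
    years = np.asarray(years)
    tin_s = np.asarray(tin_s, dtype=float)
    tin_t = np.asarray(tin_t, dtype=float)
    z = np.zeros_like(tin_s)
    return vf.EnsembleSummary(years, tin_s, z, tin_t, z, tin_s + tin_t, z, 1, 0)


class TestSummarizeReplicates:
    def test_two_replicate_mean_and_sample_sd(self):
        years = np.array([2005])
        f1 = vf.AnnualViVForecast(years, np.array([40]), np.array([60]), 1)
        f2 = vf.AnnualViVForecast(years, np.array([50]), np.array([70]), 2)
        s = vf.summarize_replicates([f1, f2], master_seed=0)
        assert s.total_mean[0] == pytest.approx(110.0)
        assert s.total_sd[0] == pytest.approx(np.sqrt(((100 - 110) ** 2 + (120 - 110) ** 2)))
        assert s.total_sd[0] == pytest.approx(14.142135, abs=1e-5)

    def test_single_replicate_sd_is_zero_by_convention(self):
        f = vf.AnnualViVForecast(np.array([2005]), np.array([3]), np.array([4]), 1)
        s = vf.summarize_replicates([f], master_seed=0)
        assert (s.total_sd == 0).all()

    def test_mean_total_equals_sum_of_category_means(self):
        cfg = stochastic_config(n_replicates=4)
        s = vf.run_ensemble(cfg)
        assert np.allclose(s.total_mean, s.tavr_in_savr_mean + s.tavr_in_tavr_mean,
                           atol=1e-9)
        assert (s.total_sd >= 0).all()

    def test_ensemble_mean_is_exact_average_of_replicates(self):
        cfg = stochastic_config(n_replicates=5)
        s = vf.run_ensemble(cfg)
        forecasts = [vf.run_single_replicate(cfg, seed)
                     for seed in replicate_seeds(cfg.master_seed, 5)]
        manual = np.stack([f.total_viv for f in forecasts]).mean(axis=0)
        assert (s.total_mean == manual).all()

    def test_degenerate_scenario_has_zero_sd_any_n(self):
        cfg = vf.degenerate_config({2000: 100}, n_replicates=6)
        s = vf.run_ensemble(cfg)
        assert (s.total_sd == 0).all()
        assert s.total_mean_at(2005) == 100.0


class TestVivShare:
    def test_zero_viv_gives_zero_share(self):
        s = make_summary([2010], [0], [0])
        vols = vf.AnnualVolumeSeries("TAVR", {2010: 100}, {2010: "synthetic"})
        assert vf.viv_share(s, vols, 2010) == 0.0

    def test_share_arithmetic_native_plus_viv_denominator(self):
        s = make_summary([2010], [5], [10])
        vols = vf.AnnualVolumeSeries("TAVR", {2010: 85}, {2010: "synthetic"})
        assert vf.viv_share(s, vols, 2010) == pytest.approx(0.15)

    def test_series_includes_viv_switch(self):
        s = make_summary([2010], [5], [10])
        vols = vf.AnnualVolumeSeries("TAVR", {2010: 100}, {2010: "synthetic"})
        assert vf.viv_share(s, vols, 2010, series_includes_viv=True) == pytest.approx(0.15)

    def test_zero_denominator_raises(self):
        s = make_summary([2010], [0], [0])
        vols = vf.AnnualVolumeSeries("TAVR", {2010: 0}, {2010: "synthetic"})
        with pytest.raises(ZeroDivisionError):
            vf.viv_share(s, vols, 2010)


class TestCrossoverYear:
    def test_never_crossing_is_absent(self):
        s = make_summary([2026, 2027], [100, 100], [0, 0])
        assert vf.crossover_year(s, 0.9) is None

    def test_equal_series_cross_in_first_year(self):
        s = make_summary([2026, 2027], [50, 50], [50, 50])
        assert vf.crossover_year(s, 1.0) == 2026

    def test_direct_scan_example(self):
        s = make_summary([2026, 2027, 2028], [100, 100, 100], [50, 80, 95])
        assert vf.crossover_year(s, 0.9) == 2028
        assert vf.crossover_year(s, 1.0) is None

    def test_invalid_threshold_rejected(self):
        s = make_summary([2026], [1], [1])
        with pytest.raises(ValueError):
            vf.crossover_year(s, 0.0)


class TestWriteOutputs:
    def test_degenerate_forecast_csv_row(self, tmp_path):
        cfg = vf.degenerate_config({2000: 100}, n_replicates=2)
        s = vf.run_ensemble(cfg)
        h = vf.compute_headline(s, cfg.tavr_volumes)
        vf.write_outputs(s, h, tmp_path, config=cfg)
        lines = (tmp_path / "forecast.csv").read_text().splitlines()
        assert lines[0] == "year,tinS_mean,tinS_sd,tinT_mean,tinT_sd,total_mean,total_sd"
        assert "2005,0,0,100,0,100,0" in lines

    def test_rerun_is_byte_identical(self, tmp_path):
        cfg = stochastic_config(n_replicates=3)
        for d in ("a", "b"):
            s = vf.run_ensemble(cfg)
            h = vf.compute_headline(s, cfg.tavr_volumes, sd_years=(2010,))
            vf.write_outputs(s, h, tmp_path / d, config=cfg)
        assert ((tmp_path / "a" / "forecast.csv").read_bytes()
                == (tmp_path / "b" / "forecast.csv").read_bytes())

    def test_headline_json_keeps_null_crossover_key(self, tmp_path):
        # SAVR-only scenario: TAVR-in-TAVR is always zero, crossover absent
        cfg = vf.degenerate_config({}, {2000: 50}, savr_durability_ge70=4.0,
                                   survival_intermediate_high=10.0)
        s = vf.run_ensemble(cfg)
        h = vf.compute_headline(s, cfg.tavr_volumes)
        vf.write_outputs(s, h, tmp_path)
        payload = json.loads((tmp_path / "headline.json").read_text())
        assert "crossover_year_near" in payload
        assert payload["crossover_year_near"] is None
        assert payload["total_viv_end"] == 0.0

    def test_run_log_records_seeds_and_config_hash(self, tmp_path):
        cfg = vf.degenerate_config({2000: 10})
        s = vf.run_ensemble(cfg)
        h = vf.compute_headline(s, cfg.tavr_volumes)
        vf.write_outputs(s, h, tmp_path, config=cfg)
        log = json.loads((tmp_path / "run_log.json").read_text())
        assert log["config_sha256"] == cfg.sha256()
        assert log["replicate_seeds"] == replicate_seeds(cfg.master_seed, cfg.n_replicates)


class TestSdScaling:
    def test_thinning_sd_scales_like_sqrt_of_volume(self):
        # Bernoulli thinning: doubling all volumes should scale the ensemble
        # SD by roughly sqrt(2); broad band since SD-of-SD is wide at n=50
        def run(scale):
            cfg = stochastic_config(n_replicates=50, master_seed=11)
            cfg.tavr_volumes = vf.AnnualVolumeSeries(
                "TAVR", {y: c * scale for y, c in cfg.tavr_volumes.counts.items()},
                cfg.tavr_volumes.provenance)
            cfg.savr_volumes = vf.AnnualVolumeSeries(
                "SAVR", {y: c * scale for y, c in cfg.savr_volumes.counts.items()},
                cfg.savr_volumes.provenance)
            s = vf.run_ensemble(cfg.validate())
            late = s.years >= 2008  # years with substantial counts
            return float(np.mean(s.total_sd[late]))

        ratio = run(2) / run(1)
        assert 1.0 < ratio < 2.0  # ~sqrt(2)


class TestCli:
    def test_run_and_default_config_commands(self, tmp_path):
        from click.testing import CliRunner

        from vivforecast.cli import main

        runner = CliRunner()
        res = runner.invoke(main, ["default-config", "-o", str(tmp_path / "cfg.yaml")])
        assert res.exit_code == 0
        cfg = vf.load_config(tmp_path / "cfg.yaml")
        assert cfg == vf.default_config()

        res = runner.invoke(main, [
            "synth", "--kind", "tiny-deterministic", "--out", str(tmp_path / "synth")])
        assert res.exit_code == 0
        tavr = vf.AnnualVolumeSeries.from_csv(tmp_path / "synth" / "tavr_volumes.csv", "TAVR")
        assert tavr[2000] == 100

    def test_run_command_writes_outputs(self, tmp_path):
        from click.testing import CliRunner

        from vivforecast.cli import main

        cfg = vf.degenerate_config({2000: 100})
        cfg.save(tmp_path / "cfg.yaml")
        runner = CliRunner()
        res = runner.invoke(main, [
            "run", "--config", str(tmp_path / "cfg.yaml"), "--seed", "5",
            "--replicates", "2", "--out", str(tmp_path / "out")])
        assert res.exit_code == 0, res.output
        assert (tmp_path / "out" / "forecast.csv").exists()
        payload = json.loads((tmp_path / "out" / "headline.json").read_text())
        assert payload["total_viv_end"] == 0.0  # failures at 2005, horizon shows 2010 count 0
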