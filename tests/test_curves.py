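import json

import numpy as np
import pytest
from click.testing import CliRunner

from litconv import (
    DriveConditions,
    SweepConfig,
    eta_max,
    export_regimes,
    export_series,
    loop_area,
    loop_curve,
    optimal_point,
    sweep_efficiency_vs_x,
    sweep_sigma_vs_x,
)
from litconv.cli import main
from litconv.curves import CurveSeries, read_series_csv


@pytest.fixture
def x_grid():
    return np.linspace(-1.0, 0.0, 401)


class TestEfficiencySweep:
    def test_complete_coupling_row(self, x_grid):
        (series,) = sweep_efficiency_vs_x([1.0], x_grid)
        i = np.argmin(np.abs(x_grid + 0.5))
        assert series.value[i] == pytest.approx(0.5, abs=1e-12)
        assert series.value[-1] == 0.0  # x = 0 row

    def test_grid_maximum_tracks_maximal_efficiency(self, x_grid):
        (series,) = sweep_efficiency_vs_x([0.95], x_grid)
        assert np.nanmax(series.value) == pytest.approx(0.52410, abs=5e-4)

    def test_pole_samples_flagged_not_dropped(self):
        # at q = 1 the pole x = -1 sits on the default grid edge
        grid = np.linspace(-1.0, 0.0, 11)
        (series,) = sweep_efficiency_vs_x([1.0], grid)
        assert len(series) == 11
        assert np.isnan(series.value[0])
        assert np.isfinite(series.value[1:]).all()


class TestEntropySweep:
    def test_known_values(self, x_grid):
        (series,) = sweep_sigma_vs_x([1.0], x_grid)
        assert series.value[0] == pytest.approx(0.0, abs=1e-12)  # reversible
        assert series.value[-1] == 1.0  # pure driving-force dissipation

    def test_dissipation_falls_as_coupling_rises_at_fixed_x(self):
        grid = np.array([-0.5])
        values = {
            q: sweep_sigma_vs_x([q], grid)[0].value[0] for q in (0.2, 0.6, 1.0)
        }
        assert values[0.2] > values[0.6] > values[1.0]
        assert values[0.6] == pytest.approx(1.25 - 0.6)


class TestLoopCurves:
    def test_degenerate_loop_at_complete_coupling(self):
        series = loop_curve("power", 1.0, 201)
        assert loop_area(series) == pytest.approx(0.0, abs=1e-12)
        peak = series.eta[np.argmax(series.value)]
        assert peak == pytest.approx(0.5, abs=5e-3)

    def test_efficient_power_degenerate_peak(self):
        series = loop_curve("efficient_power", 1.0, 301)
        assert series.eta[np.argmax(series.value)] == pytest.approx(
            2.0 / 3.0, abs=5e-3
        )

    @pytest.mark.parametrize("function_id", ["power", "ecological", "efficient_power"])
    def test_partial_coupling_loop_is_closed_with_positive_area(self, function_id):
        q = 0.8
        series = loop_curve(function_id, q, 201)
        assert loop_area(series) > 1e-4
        # closed at the two zero-efficiency endpoints
        assert series.eta[0] == series.eta[-1] == 0.0
        if function_id == "power":
            assert series.value[0] == pytest.approx(0.0, abs=1e-12)
            assert series.value[-1] == pytest.approx(0.0, abs=1e-12)
        assert np.all(series.eta <= eta_max(q) + 1e-12)

    def test_loop_apex_meets_maximal_efficiency(self):
        series = loop_curve("power", 0.8, 201)
        assert series.eta.max() == pytest.approx(eta_max(0.8), abs=1e-12)
        assert eta_max(0.8) == pytest.approx(0.25)
        half = len(series) // 2
        # branches meet at the apex
        assert series.x[half - 1] == pytest.approx(series.x[half], abs=1e-6)

    def test_explicit_grid_clipped_with_warning(self, caplog):
        import logging

        with caplog.at_level(logging.WARNING, logger="litconv.curves"):
            series = loop_curve("power", 0.8, np.linspace(0.0, 0.4, 21))
        assert "clipping" in caplog.text
        assert series.eta.max() <= eta_max(0.8) + 1e-12

    def test_unknown_function_rejected(self):
        with pytest.raises(ValueError):
            loop_curve("sigma", 0.8)


class TestSweepConfig:
    def test_validation(self):
        with pytest.raises(ValueError):
            SweepConfig((0.5,), 0.0, -1.0, 10, ("power",))
        with pytest.raises(ValueError):
            SweepConfig((0.5,), -1.0, 0.0, 1, ("power",))
        with pytest.raises(ValueError):
            SweepConfig((1.5,), -1.0, 0.0, 10, ("power",))
        cfg = SweepConfig((0.5,), -1.0, 0.0, 11, ("power",))
        assert len(cfg.grid) == 11


class TestExport:
    def test_csv_round_trip_preserves_12_digits(self, tmp_path):
        series = loop_curve("power", 0.8, 51)
        path = tmp_path / "loop.csv"
        export_series(series, str(path), fmt="csv")
        df = read_series_csv(str(path))
        assert list(df.columns) == [
            "function", "q", "branch", "x", "eta", "value_reduced", "value_absolute",
        ]
        np.testing.assert_allclose(df["value_reduced"], series.value, rtol=1e-11)
        np.testing.assert_allclose(df["eta"], series.eta, rtol=1e-11, atol=1e-11)
        assert df["value_absolute"].isna().all()  # reduced mode

    def test_absolute_mode_fills_absolute_column(self, tmp_path):
        series = loop_curve("power", 0.8, 11)
        drive = DriveConditions(T=300.0, Delta=2.0, L22=1.0)
        path = tmp_path / "abs.csv"
        export_series(series, str(path), fmt="csv", drive=drive)
        df = read_series_csv(str(path))
        np.testing.assert_allclose(
            df["value_absolute"], df["value_reduced"] * drive.scale, rtol=1e-10
        )

    def test_empty_series_gives_header_only_csv(self, tmp_path):
        path = tmp_path / "empty.csv"
        export_series([], str(path), fmt="csv")
        df = read_series_csv(str(path))
        assert df.empty
        assert list(df.columns)[0] == "function"

    def test_metadata_header_present(self, tmp_path):
        path = tmp_path / "meta.csv"
        export_series(loop_curve("power", 1.0, 5), str(path), config={"n": 5})
        head = path.read_text().splitlines()[:5]
        assert any("package_version" in line for line in head)
        assert any("config_hash" in line for line in head)

    def test_json_mirrors_data_model(self, tmp_path):
        series = loop_curve("ecological", 0.6, 11)
        path = tmp_path / "loop.json"
        export_series(series, str(path), fmt="json")
        payload = json.loads(path.read_text())
        assert payload["series"][0]["function"] == "ecological"
        assert payload["series"][0]["q"] == 0.6
        assert len(payload["series"][0]["samples"]) == len(series)

    def test_regime_table_with_residuals(self, tmp_path):
        results = [
            optimal_point(regime, q)
            for q in (0.5, 0.95, 1.0)
            for regime in ("MPO", "MEF", "MEPF")
        ]
        path = tmp_path / "regimes.json"
        export_regimes(results, str(path))
        rows = json.loads(path.read_text())["regimes"]
        assert len(rows) == 9
        assert all(row["residual"] <= 1e-8 for row in rows)

    def test_unknown_format_rejected(self, tmp_path):
        with pytest.raises(ValueError):
            export_series([], str(tmp_path / "x.xml"), fmt="xml")


class TestFigureRegeneration:
    def test_complete_coupling_maxima_recovered_from_exported_csv(self, tmp_path):
        """The three landmark efficiencies re-emerge from serialized curves."""
        path = tmp_path / "fig.csv"
        export_series(
            [loop_curve(f, 1.0, 401) for f in ("power", "ecological", "efficient_power")],
            str(path),
        )
        df = read_series_csv(str(path))
        expected = {"power": 0.5, "ecological": 0.75, "efficient_power": 2.0 / 3.0}
        for fn, eta_star in expected.items():
            sub = df[df["function"] == fn]
            peak = sub.loc[sub["value_reduced"].idxmax(), "eta"]
            assert peak == pytest.approx(eta_star, abs=2.5e-3)  # grid resolution


class TestCurveSeriesValidation:
    def test_mismatched_lengths_rejected(self):
        with pytest.raises(ValueError):
            CurveSeries(
                function_id="power",
                q=0.8,
                x=np.zeros(3),
                eta=np.zeros(3),
                value=np.zeros(2),
                branch=("x",) * 3,
            )


class TestCli:
    def setup_method(self):
        self.runner = CliRunner()

    def test_sweep_writes_csv(self, tmp_path):
        out = tmp_path / "sweep.csv"
        result = self.runner.invoke(
            main,
            ["sweep", "--function", "sigma", "--q", "0.5,1.0",
             "--x-min", "-1", "--x-max", "0", "--n", "101", "--out", str(out)],
        )
        assert result.exit_code == 0, result.output
        df = read_series_csv(str(out))
        assert len(df) == 202
        assert set(df["q"]) == {0.5, 1.0}

    def test_optimum_reports_all_regimes(self, tmp_path):
        out = tmp_path / "regimes.json"
        result = self.runner.invoke(
            main, ["optimum", "--regime", "all", "--q", "0.95", "--out", str(out)]
        )
        assert result.exit_code == 0, result.output
        rows = json.loads(out.read_text())["regimes"]
        assert [r["regime"] for r in rows] == ["MPO", "MEF", "MEPF"]
        assert rows[0]["eta_star"] == pytest.approx(0.411162, abs=1e-6)

    def test_loop_command(self, tmp_path):
        out = tmp_path / "loop.csv"
        result = self.runner.invoke(
            main,
            ["loop", "--function", "efficient-power", "--q", "0.8",
             "--n", "51", "--out", str(out)],
        )
        assert result.exit_code == 0, result.output
        assert "eta_max=0.250000" in result.output
        assert len(read_series_csv(str(out))) == 102

    def test_config_file_overridden_by_flags(self, tmp_path):
        cfg = tmp_path / "run.toml"
        cfg.write_text("n = 11\nx_min = -0.5\n")
        out = tmp_path / "sweep.csv"
        result = self.runner.invoke(
            main,
            ["sweep", "--function", "power", "--q", "1.0",
             "--config", str(cfg), "--out", str(out)],
        )
        assert result.exit_code == 0, result.output
        df = read_series_csv(str(out))
        assert len(df) == 11
        assert df["x"].min() == pytest.approx(-0.5)

    def test_invalid_q_rejected(self, tmp_path):
        result = self.runner.invoke(
            main,
            ["sweep", "--function", "power", "--q", "1.5",
             "--out", str(tmp_path / "x.csv")],
        )
        assert result.exit_code != 0
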