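import json

import numpy as np
import pytest
from click.testing import CliRunner

import geomgof as gg
from geomgof.cli import main as cli_main
from conftest import MARKET_EXPECTED


class TestGofTest:
    @pytest.mark.parametrize("name", sorted(MARKET_EXPECTED))
    def test_market_reports(self, name):
        exp = MARKET_EXPECTED[name]
        rep = gg.gof_test(gg.load_example(name))
        assert rep.n == exp["n"]
        assert round(rep.mean, 3) == exp["mean"]
        assert round(rep.theta_hat, 3) == exp["theta"]
        assert rep.results["watson"].bracket == exp["w2_bracket"]
        assert rep.results["anderson_darling"].bracket == exp["a2_bracket"]
        for res in rep.results.values():
            assert res.bracket[0] < res.pvalue < res.bracket[1]
            assert not res.reject  # all four markets look geometric at 0.05

    def test_exact_fit_never_rejected(self):
        table = gg.FrequencyTable(400.0 * gg.pmf_vector(0.5, 60))
        rep = gg.gof_test(table, alpha=0.05)
        for res in rep.results.values():
            assert res.value < 1e-15
            assert res.pvalue == pytest.approx(1.0)
            assert not res.reject

    def test_single_statistic_request(self):
        rep = gg.gof_test(gg.load_example("nasdaq"), statistic="watson")
        assert set(rep.results) == {"watson"}

    def test_degenerate_table_rejected(self):
        with pytest.raises(gg.DegenerateSampleError):
            gg.gof_test(gg.FrequencyTable.from_counts({1: 50}))

    def test_theta_outside_grid_reports_continuous_only(self):
        # theta_hat above the tabulated 0.95: bracket unavailable, warning set
        rng = np.random.default_rng(0)
        table = gg.FrequencyTable.from_sample(gg.sample_geometric(rng, 0.99, 500))
        rep = gg.gof_test(table)
        assert rep.warnings
        for res in rep.results.values():
            assert res.bracket is None
            assert 0.0 <= res.pvalue <= 1.0


class TestReadFrequencyTable:
    def test_counts_csv(self, tmp_path):
        p = tmp_path / "c.csv"
        p.write_text("value,count\n1,2\n2,1\n4,1\n")
        t = gg.read_frequency_table(p, "counts_csv")
        assert t.k == 4 and t.counts.tolist() == [2, 1, 0, 1]

    def test_tab_delimited_counts(self, tmp_path):
        p = tmp_path / "c.tsv"
        p.write_text("value\tcount\n1\t3\n2\t1\n")
        t = gg.read_frequency_table(p, "counts_csv")
        assert t.counts.tolist() == [3, 1]

    def test_raw_sample(self, tmp_path):
        p = tmp_path / "raw.txt"
        p.write_text("1\n1\n2\n4\n")
        t = gg.read_frequency_table(p, "raw_sample")
        assert t.counts.tolist() == [2, 1, 0, 1]

    def test_negative_count_names_line(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("value,count\n1,-3\n")
        with pytest.raises(ValueError, match=":2:"):
            gg.read_frequency_table(p, "counts_csv")

    def test_duplicate_value_rejected(self, tmp_path):
        p = tmp_path / "dup.csv"
        p.write_text("value,count\n1,2\n1,3\n")
        with pytest.raises(ValueError, match="duplicate"):
            gg.read_frequency_table(p, "counts_csv")

    def test_non_integer_raw_line_reported(self, tmp_path):
        p = tmp_path / "raw.txt"
        p.write_text("1\nx\n")
        with pytest.raises(ValueError, match=":2:"):
            gg.read_frequency_table(p, "raw_sample")


class TestReports:
    def test_json_round_trip(self):
        rep = gg.gof_test(gg.load_example("djia"))
        back = gg.read_report_json(gg.write_report(rep, "json"))
        assert back == rep

    def test_text_rendering_rounds_to_three_decimals(self):
        rep = gg.gof_test(gg.load_example("nasdaq"))
        text = gg.write_report(rep, "text")
        assert "theta_hat  0.512" in text
        assert "W2         0.060" in text

    def test_formats_agree_on_decision(self):
        rep = gg.gof_test(gg.load_example("ipc"))
        parsed = json.loads(gg.write_report(rep, "json"))
        text = gg.write_report(rep, "text")
        for tag, res in parsed["results"].items():
            expected = "reject" if res["reject"] else "do not reject"
            assert expected in text


class TestCli:
    def test_test_subcommand_json(self, tmp_path):
        data = tmp_path / "d.csv"
        data.write_text("value,count\n1,60\n2,25\n3,10\n4,5\n")
        runner = CliRunner()
        result = runner.invoke(cli_main, ["test", str(data), "--format", "json"])
        assert result.exit_code == 0
        parsed = json.loads(result.output)
        assert set(parsed["results"]) == {"watson", "anderson_darling"}

    def test_runs_subcommand_requires_zero_policy(self, tmp_path):
        series = tmp_path / "s.csv"
        series.write_text("close\n1\n2\n3\n2\n1\n2\n")
        runner = CliRunner()
        assert runner.invoke(cli_main, ["runs", str(series)]).exit_code != 0
        result = runner.invoke(
            cli_main, ["runs", str(series), "--zero-policy", "error"]
        )
        assert result.exit_code == 0
        assert result.output.splitlines() == ["value,count", "1,1", "2,2"]

    def test_simulate_subcommand(self):
        runner = CliRunner()
        result = runner.invoke(
            cli_main,
            ["simulate", "--theta", "0.5", "--n", "50", "--reps", "2000",
             "--seed", "5", "--statistic", "a2", "--alphas", "0.1,0.05"],
        )
        assert result.exit_code == 0
        assert "critical_value" in result.output

    def test_tables_subcommand(self, tmp_path):
        out = tmp_path / "grid.csv"
        runner = CliRunner()
        result = runner.invoke(
            cli_main,
            ["tables", "--statistic", "w2", "--theta-grid", "0.5",
             "--alphas", "0.05", "--out", str(out)],
        )
        assert result.exit_code == 0
        from geomgof import tables as T

        tab = T.read_table_csv(out)
        assert tab.points[0, 0] == pytest.approx(0.272, abs=0.01)
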