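"""Replication engine, averaging, common random numbers, config and CLI."""

import dataclasses
import json

import numpy as np
import pytest
from click.testing import CliRunner

from menisim import (
    Scenario,
    SimulationConfig,
    TransitionMatrix,
    load_config,
    run_experiment,
    run_replication,
    run_sensitivity,
)
from menisim.cli import main as cli_main


SMALL = dict(n_patients=80, horizon_years=6, n_replications=2, seed=42)


class TestRunReplication:
    def test_3dp_has_no_waiting_tka(self):
        out = run_replication(SimulationConfig(paradigm="3dp", **SMALL))
        assert np.all(out.cum_tka_waiting == 0)

    def test_series_monotone_and_decomposed(self):
        for paradigm in ("traditional", "3dp"):
            out = run_replication(SimulationConfig(paradigm=paradigm, **SMALL))
            for series in (out.cum_tka_waiting, out.cum_tka_post, out.cum_cost_usd):
                assert np.all(np.diff(series) >= 0) and np.all(series >= 0)
            np.testing.assert_array_equal(
                out.cum_tka_total, out.cum_tka_waiting + out.cum_tka_post
            )

    def test_instant_donors_all_ni_gross_cost(self):
        # With donors arriving every ~0.001 weeks nobody waits a completed
        # week or times out, and an absorbing-NI matrix accrues no treatment
        # cost: the gross cost is exactly n_patients transplantations.
        all_ni = TransitionMatrix(
            np.array([[1, 0, 0, 0], [1, 0, 0, 0], [1, 0, 0, 0], [0, 0, 0, 1.0]])
        )
        config = SimulationConfig(
            paradigm="traditional",
            n_patients=50,
            horizon_years=5,
            n_replications=1,
            seed=3,
            donor_mean_range=(1e-3, 1e-3),
            matrix_override=all_ni,
        )
        out = run_replication(config)
        assert out.cum_tka_total[-1] == 0
        assert out.cum_cost_usd[-1] == 50 * 8875

    def test_seed_reproducibility(self):
        config = SimulationConfig(paradigm="traditional", **SMALL)
        a, b = run_replication(config, 1), run_replication(config, 1)
        np.testing.assert_array_equal(a.cum_cost_usd, b.cum_cost_usd)
        np.testing.assert_array_equal(a.cum_tka_total, b.cum_tka_total)


class TestRunExperiment:
    def test_single_replication_equals_mean(self):
        config = SimulationConfig(paradigm="3dp", **{**SMALL, "n_replications": 1})
        result = run_experiment(config)
        single = run_replication(config, 0)
        np.testing.assert_array_equal(result.mean.cum_cost_usd, single.cum_cost_usd)
        assert np.all(result.sem.cum_cost_usd == 0)

    def test_same_seed_same_averages(self):
        config = SimulationConfig(paradigm="traditional", **SMALL)
        a, b = run_experiment(config), run_experiment(config)
        np.testing.assert_array_equal(a.mean.cum_cost_usd, b.mean.cum_cost_usd)

    def test_traditional_costs_dominate_3dp_in_the_long_run(self):
        # Same seed -> shared patient arrivals and trajectory draws. The 3DP
        # arm front-loads procedure costs (everyone pays at arrival), so the
        # traditional arm can be cheaper cumulatively during the queue's
        # initial transient; once timeout TKAs and waiting costs accumulate
        # the traditional arm dominates and stays dominant.
        small = dict(n_patients=300, horizon_years=10, n_replications=3, seed=5)
        trad = run_experiment(SimulationConfig(paradigm="traditional", **small))
        threedp = run_experiment(SimulationConfig(paradigm="3dp", **small))
        diff = trad.mean.cum_cost_usd - threedp.mean.cum_cost_usd
        assert diff[-1] > 0
        crossover = np.argmax(diff > 0)
        assert np.all(diff[crossover:] > 0)

    def test_frame_shape(self):
        result = run_experiment(SimulationConfig(paradigm="3dp", **SMALL))
        frame = result.frame()
        assert len(frame) == SMALL["horizon_years"]
        assert "cum_tka_total" in frame and "sem_cum_cost_usd" in frame


class TestRunSensitivity:
    def test_requires_3dp_paradigm(self):
        with pytest.raises(ValueError):
            run_sensitivity(SimulationConfig(paradigm="traditional", **SMALL))

    def test_original_equals_plain_experiment(self):
        config = SimulationConfig(paradigm="3dp", **SMALL)
        sweep = run_sensitivity(config, [Scenario.ORIGINAL])
        direct = run_experiment(config)
        np.testing.assert_array_equal(
            sweep[Scenario.ORIGINAL].mean.cum_cost_usd, direct.mean.cum_cost_usd
        )

    def test_good_and_bad_quality_bracket_original(self):
        small = dict(n_patients=400, horizon_years=12, n_replications=3, seed=9)
        config = SimulationConfig(paradigm="3dp", **small)
        sweep = run_sensitivity(config, [Scenario.S1, Scenario.ORIGINAL, Scenario.S2])
        bad = sweep[Scenario.S1].mean.cum_tka_total[-1]
        orig = sweep[Scenario.ORIGINAL].mean.cum_tka_total[-1]
        good = sweep[Scenario.S2].mean.cum_tka_total[-1]
        assert good < orig < bad


class TestConfigIO:
    def test_yaml_and_json_round_trip(self, tmp_path):
        payload = {
            "paradigm": "3dp",
            "scenario": "s5",
            "n_patients": 10,
            "n_replications": 2,
            "costs": {"repair": 1000.0},
            "donor_mean_range": [1, 5],
        }
        json_file = tmp_path / "config.json"
        json_file.write_text(json.dumps(payload))
        config = load_config(json_file)
        assert config.scenario == Scenario.S5 and config.costs.repair == 1000.0

        yaml_file = tmp_path / "config.yaml"
        yaml_file.write_text(
            "paradigm: traditional\nn_patients: 7\nwait_threshold: 10\nhorizon_years: 2\n"
        )
        config = load_config(yaml_file)
        assert config.paradigm == "traditional" and config.n_patients == 7

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(paradigm="robotic")
        with pytest.raises(ValueError):
            SimulationConfig(wait_threshold=0)
        with pytest.raises(ValueError):
            SimulationConfig(n_patients=0)


class TestCli:
    def test_implant_cost_command(self):
        result = CliRunner().invoke(cli_main, ["implant-cost"])
        assert result.exit_code == 0
        assert "3124.00" in result.output

    def test_simulate_writes_csv(self, tmp_path):
        result = CliRunner().invoke(
            cli_main,
            [
                "simulate",
                "--paradigm",
                "3dp",
                "--patients",
                "20",
                "--years",
                "3",
                "--reps",
                "1",
                "--seed",
                "1",
                "--out",
                str(tmp_path),
            ],
        )
        assert result.exit_code == 0, result.output
        assert (tmp_path / "3dp_original.csv").exists()
        assert (tmp_path / "3dp_original.meta.json").exists()

    def test_sensitivity_command(self, tmp_path):
        result = CliRunner().invoke(
            cli_main,
            [
                "sensitivity",
                "--scenarios",
                "original,s8",
                "--patients",
                "20",
                "--years",
                "3",
                "--reps",
                "1",
                "--seed",
                "1",
                "--out",
                str(tmp_path),
            ],
        )
        assert result.exit_code == 0, result.output
        assert (tmp_path / "3dp_s8.csv").exists()
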