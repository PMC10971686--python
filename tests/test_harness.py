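"""Scenario configs, replicate orchestration, gene screens, comparison
statistics and the command-line interface."""

import json

import numpy as np
import pandas as pd
import pytest
from click.testing import CliRunner

from symbiosim import scenarios
from symbiosim.automaton import run_simulation
from symbiosim.cli import main
from symbiosim.config import ConfigError, ScenarioConfig
from symbiosim.harness import (
    apply_parameters,
    compare_conditions,
    replicate_seed,
    run_replicates,
    run_screen,
    write_run_dir,
)
from symbiosim.network import Perturbation
from symbiosim.sensitivity import ParameterRange, lhs_sample, prcc


def tiny_config(**kwargs):
    """A deliberately small scenario for orchestration tests."""
    from symbiosim.environment import Lattice

    defaults = dict(scale="desk", duration_days=0.5, initial_cells=30,
                    replicates=2)
    defaults.update(kwargs)
    cfg = scenarios.baseline(**defaults)
    return cfg.replace(lattice=Lattice(nx=26, ny=26), record_interval_h=3.0)


class TestConfig:
    def test_yaml_round_trip(self, tmp_path):
        cfg = tiny_config()
        path = tmp_path / "scenario.yaml"
        cfg.to_yaml(path)
        loaded = ScenarioConfig.from_yaml(path)
        assert loaded == cfg
        assert loaded.digest() == cfg.digest()

    def test_unknown_field_named_in_error(self):
        with pytest.raises(ConfigError, match="bogus"):
            ScenarioConfig.from_dict({"bogus": 1})

    def test_fraction_validation(self):
        from symbiosim.config import PopulationSpec

        with pytest.raises(ConfigError, match="sum to 1"):
            ScenarioConfig(populations=(PopulationSpec(tag="a", fraction=0.4),))

    def test_unknown_perturbation_node_rejected(self):
        cfg = tiny_config().with_perturbations(Perturbation("NOT_A_GENE", "knockout"))
        with pytest.raises(ConfigError, match="NOT_A_GENE"):
            cfg.validate()

    def test_drug_without_field_rejected(self):
        from symbiosim.therapy import DrugSpec

        cfg = tiny_config().replace(drugs=(DrugSpec("mystery", "MCT1I"),))
        with pytest.raises(ConfigError, match="mystery"):
            cfg.validate()

    def test_input_threshold_override(self):
        cfg = tiny_config().replace(input_thresholds={"Glucose_supply": 2.5})
        defn = cfg.load_network()
        assert defn.input_bindings["Glucose_supply"].threshold == 2.5
        bad = tiny_config().replace(input_thresholds={"DNA_damage": 1.0})
        with pytest.raises(ConfigError, match="DNA_damage"):
            bad.load_network()


class TestReplicates:
    def test_seeds_deterministic_and_distinct(self):
        seeds = [replicate_seed(123, i) for i in range(10)]
        assert seeds == [replicate_seed(123, i) for i in range(10)]
        assert len(set(seeds)) == 10
        assert all(0 <= s < 2**31 for s in seeds)

    def test_single_replicate_reproducible(self):
        cfg = tiny_config()
        first = run_replicates(cfg, n=2)[1]
        again = run_simulation(cfg, seed=replicate_seed(cfg.base_seed, 1))
        assert first.timeseries.equals(again.timeseries)


class TestComparison:
    def test_identical_arms_not_significant(self):
        rng = np.random.default_rng(0)
        arm = rng.normal(size=10)
        res = compare_conditions(arm, arm.copy())
        assert res.p_value > 0.99
        assert not res.significant

    def test_five_sigma_shift_detected(self):
        rng = np.random.default_rng(1)
        a = rng.normal(0.0, 1.0, size=10)
        b = rng.normal(5.0, 1.0, size=10)
        res = compare_conditions(a, b)
        assert res.significant and res.p_value < 0.05
        assert res.mean_difference < 0

    def test_single_replicate_gives_missing_p(self):
        res = compare_conditions([1.0], [2.0])
        assert np.isnan(res.p_value) and not res.significant

    def test_empty_arm_rejected(self):
        with pytest.raises(ValueError):
            compare_conditions([], [1.0])


class TestScreen:
    @pytest.fixture(scope="class")
    def screen_table(self):
        return run_screen(tiny_config(), ["p53", "MDM2"],
                          modes=("enrichment", "knockout"), n_replicates=2)

    def test_empty_gene_list_gives_wildtype_row_only(self):
        table = run_screen(tiny_config(), [], n_replicates=1)
        assert list(table.gene) == ["WT"]

    def test_matrix_complete(self, screen_table):
        combos = set(zip(screen_table["gene"], screen_table["mode"]))
        assert combos == {
            ("WT", "none"), ("p53", "enrichment"), ("p53", "knockout"),
            ("MDM2", "enrichment"), ("MDM2", "knockout"),
        }

    def test_percentage_change_sign_matches_recount(self, screen_table):
        """Sign of the reported percentage change equals the sign of the
        replicate-mean difference recomputed from the stored arm means."""
        for _, row in screen_table.iterrows():
            diff = row.mean_wt_total - row.mean_ko_total
            if row.mean_ko_total > 0 and diff != 0:
                assert np.sign(row.pct_change_total) == np.sign(diff)

    def test_unknown_gene_rejected(self):
        with pytest.raises(ConfigError, match="XYZ"):
            run_screen(tiny_config(), ["XYZ"])


class TestSensitivityIntegration:
    def test_apply_parameters_round_trip(self):
        cfg = tiny_config()
        new = apply_parameters(cfg, {
            "mu_o2": 10.0, "D_glucose": 5000.0, "glucose_boundary": 4.0,
            "glucose_activation_threshold": 1.0, "oxygen_critical": 0.2,
            "gamma_tgfa_produce": 2e-3,
        })
        assert new.metabolic.mu_o2 == 10.0
        assert new.substances["glucose"].D == 5000.0
        assert new.substances["glucose"].boundary_value == 4.0
        assert new.load_network().input_bindings["Glucose_supply"].threshold == 1.0
        assert new.necrosis.oxygen_critical == 0.2
        assert new.substances["tgfa"].gamma_produce == 2e-3

    def test_unknown_parameter_rejected(self):
        with pytest.raises(ConfigError, match="mystery"):
            apply_parameters(tiny_config(), {"mystery": 1.0})

    def test_glucose_threshold_suppresses_growth(self, rng):
        """End-to-end miniature of the sensitivity pipeline: over an LHS
        design, raising the glucose activation threshold silences glycolysis
        in more of the tumour, so the active-cell count correlates strongly
        and negatively with the threshold (partial rank correlation)."""
        base = tiny_config(duration_days=1.0, lactate=0.5)
        ranges = (
            ParameterRange("glucose_activation_threshold", 3.0, rel_width=0.9),
            ParameterRange("K_L", 0.3),
        )
        design = lhs_sample(ranges, n_samples=8, rng=rng)
        frame = design.to_frame()
        outputs = []
        for i in range(len(frame)):
            cfg = apply_parameters(base, frame.iloc[i].to_dict())
            res = run_simulation(cfg, seed=17)
            outputs.append({"active": res.final("active")})
        result = prcc(design, pd.DataFrame(outputs))
        assert result.coefficient("glucose_activation_threshold", "active") < -0.5


class TestArtefactsAndCLI:
    def test_write_run_dir_layout(self, tmp_path):
        res = run_simulation(tiny_config(), seed=0)
        out = write_run_dir(res, tmp_path / "run")
        for rel in ("config.yaml", "manifest.json", "metrics.csv", "msi.csv",
                    "fields/manifest.json", "fields/oxygen.txt",
                    "profile_glucose.csv"):
            assert (out / rel).exists()
        manifest = json.loads((out / "manifest.json").read_text())
        assert manifest["seed"] == 0
        grid = np.loadtxt(out / "fields/oxygen.txt")
        assert grid.shape == tuple(manifest["grid"])

    def test_cli_run_duration_zero_header_only(self, tmp_path):
        cfg = tiny_config(duration_days=0.0)
        cfg_path = tmp_path / "cfg.yaml"
        cfg.to_yaml(cfg_path)
        runner = CliRunner()
        result = runner.invoke(main, [
            "run", "--config", str(cfg_path), "--out", str(tmp_path / "out"),
        ])
        assert result.exit_code == 0, result.output
        metrics = pd.read_csv(tmp_path / "out" / "metrics.csv")
        assert len(metrics) == 0 and "total" in metrics.columns

    def test_cli_rejects_bad_config(self, tmp_path):
        bad = tmp_path / "bad.yaml"
        bad.write_text("initial_cells: -5\n")
        runner = CliRunner()
        result = runner.invoke(main, ["run", "--config", str(bad)])
        assert result.exit_code != 0

    def test_cli_report(self, tmp_path):
        res = run_simulation(tiny_config(), seed=0)
        write_run_dir(res, tmp_path / "run")
        runner = CliRunner()
        result = runner.invoke(main, ["report", str(tmp_path / "run")])
        assert result.exit_code == 0
        assert "config_digest" in result.output
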