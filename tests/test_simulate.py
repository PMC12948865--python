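"""Forward simulator: determinism, tracer conservation, truth recovery."""

import numpy as np
import pandas as pd
import pytest
from pydantic import ValidationError

from rhizotrace.errors import ConfigurationError
from rhizotrace.pipeline import analyze
from rhizotrace.simulate import (
    AllocationScheme,
    SimConfig,
    recovery_study,
    simulate_experiment,
)


class TestConfigValidation:
    def test_allocation_fractions_must_sum_to_one(self):
        with pytest.raises(ValidationError, match="sum"):
            AllocationScheme(
                grain=0.5, straw=0.5, root=0.1, rhizodeposition=0.1,
                root_layer_shares=(0.7, 0.2, 0.1),
                rhizo_layer_shares=(0.6, 0.25, 0.15),
            )

    def test_layer_shares_must_sum_to_one(self):
        with pytest.raises(ValidationError, match="root_layer_shares"):
            AllocationScheme(
                grain=0.4, straw=0.3, root=0.1, rhizodeposition=0.2,
                root_layer_shares=(0.7, 0.2, 0.2),
                rhizo_layer_shares=(0.6, 0.25, 0.15),
            )

    def test_contamination_fraction_domain(self):
        with pytest.raises(ValidationError, match="eom_contamination_fraction"):
            SimConfig(eom_contamination_fraction=1.0)

    def test_default_config_valid(self):
        cfg = SimConfig()
        assert cfg.applied_tracer_13c == 36.5
        assert cfg.recovery_fraction == {"control": 0.46, "drought": 0.32}

    def test_yaml_round_trip(self, tmp_path):
        cfg = SimConfig(seed=7, n_plots=2)
        cfg.to_yaml(tmp_path / "c.yaml")
        assert SimConfig.from_yaml(tmp_path / "c.yaml") == cfg


class TestDeterminism:
    def test_same_seed_identical_csv_bytes(self, tmp_path):
        cfg = SimConfig(seed=5, n_plots=2)
        for d in ("a", "b"):
            simulate_experiment(cfg).write(tmp_path / d)
        for name in ("measurements.csv", "references.csv", "truth_plots.csv"):
            assert (tmp_path / "a" / name).read_bytes() == (
                tmp_path / "b" / name
            ).read_bytes()

    def test_different_seeds_differ(self):
        a = simulate_experiment(SimConfig(seed=1, n_plots=2))
        b = simulate_experiment(SimConfig(seed=2, n_plots=2))
        assert not a.measurements["delta13C_permil"].equals(
            b.measurements["delta13C_permil"]
        )

    def test_truth_is_pure_function_of_config_and_seed(self):
        cfg = SimConfig(seed=3, n_plots=2)
        a = simulate_experiment(cfg).truth
        b = simulate_experiment(cfg).truth
        pd.testing.assert_frame_equal(a.plots, b.plots)
        pd.testing.assert_frame_equal(a.compartments, b.compartments)


class TestMassBalance:
    def test_tracer_conservation_zero_noise(self, exact_experiment):
        """True compartment excesses sum to applied x recovery per plot."""
        comp = exact_experiment.truth.compartments
        cfg = exact_experiment.config
        sums = comp.groupby("plot_id")["excess_g_m2"].sum()
        plots = exact_experiment.truth.plots.set_index("plot_id")
        for plot_id, total in sums.items():
            regime = plots.loc[plot_id, "regime"]
            expected = cfg.applied_tracer_13c * cfg.recovery_fraction[regime]
            assert total == pytest.approx(expected, rel=1e-12)

    def test_equal_enrichment_of_roots_and_rhizodeposits(self, exact_experiment):
        """Excess per unit C is identical for every root and rhizodeposit pool."""
        comp = exact_experiment.truth.compartments
        below = comp[comp["compartment"].str.contains("root|rhizo")]
        ratio = below["excess_g_m2"] / below["carbon_g_m2"]
        for _, grp in below.assign(r=ratio).groupby("plot_id"):
            assert grp["r"].max() - grp["r"].min() < 1e-15

    def test_natural_reference_rows_emitted_per_treatment_layer(self, exact_experiment):
        refs = exact_experiment.references
        cfg = exact_experiment.config
        # plant refs: aboveground + 3 layers; soil refs: 3 layers; per cell
        assert len(refs) == len(cfg.systems) * len(cfg.regimes) * 7
        assert set(refs["material"]) == {"plant", "soil"}


class TestPipelineRecovery:
    def test_zero_noise_zero_eom_recovers_truth(self, exact_experiment, exact_result):
        est = exact_result.profile_table.set_index("plot_id").sort_index()
        tru = exact_experiment.truth.plots.set_index("plot_id").sort_index()
        for col in ("rhizo_c_g_m2", "root_c_g_m2", "grain_c_g_m2", "straw_c_g_m2"):
            rel = np.abs(est[col] - tru[col]) / tru[col]
            assert rel.max() < 1e-9

    def test_zero_noise_layerwise_qcdfr_matches_truth(self, exact_experiment, exact_result):
        est = exact_result.layer_table.set_index(["plot_id", "layer"]).sort_index()
        tru = exact_experiment.truth.layers.set_index(["plot_id", "layer"]).sort_index()
        rel = np.abs(est["q_cdfr_g_m2"] - tru["rhizo_carbon_g_m2"]) / tru["rhizo_carbon_g_m2"]
        assert rel.max() < 1e-9

    @pytest.mark.parametrize("phi", [0.1, 0.2, 0.4])
    def test_eom_contamination_recovered_exactly(self, phi):
        cfg = SimConfig(noise_sd_delta=0.0, noise_sd_mass=0.0,
                        eom_contamination_fraction=phi, n_plots=2, seed=9)
        sim = simulate_experiment(cfg)
        res = analyze(sim.measurements, sim.references, sim.geometry,
                      delta_eom=cfg.delta_eom, constants=cfg.constants)
        assert np.max(np.abs(res.f_rbc["f_rbc"] - (1.0 - phi))) < 1e-12

    def test_natural_abundance_soil_layers_have_zero_excess_when_unlabelled(self):
        """A layer receiving no rhizodeposits shows exactly zero soil excess."""
        alloc = AllocationScheme(
            grain=0.3830, straw=0.3000, root=0.0934, rhizodeposition=0.2236,
            root_layer_shares=(0.7, 0.2, 0.1),
            rhizo_layer_shares=(0.7, 0.3, 0.0),
        )
        cfg = SimConfig(
            noise_sd_delta=0.0, noise_sd_mass=0.0, eom_contamination_fraction=0.0,
            allocation={"control": alloc, "drought": alloc}, n_plots=1, seed=2,
        )
        sim = simulate_experiment(cfg)
        res = analyze(sim.measurements, sim.references, sim.geometry,
                      delta_eom=cfg.delta_eom, constants=cfg.constants)
        deepest = res.layer_table[res.layer_table["layer"] == "0.5-0.75"]
        assert np.allclose(deepest["soil_excess_g_m2"], 0.0, atol=1e-12)


class TestRecoveryStudy:
    def test_zero_noise_bias_is_zero(self):
        cfg = SimConfig(noise_sd_mass=0.0, eom_contamination_fraction=0.0,
                        n_plots=2, systems=("A",))
        tab = recovery_study(cfg, n_reps=2, noise_sd_deltas=(0.0,), seed=1)
        assert np.all(np.abs(tab["mean_rel_bias"]) < 1e-9)

    def test_rmse_non_decreasing_in_noise(self):
        cfg = SimConfig(n_plots=2, systems=("A",))
        tab = recovery_study(cfg, n_reps=60, noise_sd_deltas=(0.05, 0.5), seed=3)
        q = tab[tab["variable"] == "rhizo_c_g_m2"].sort_values("noise_sd_delta")
        assert q["rel_rmse"].is_monotonic_increasing

    def test_too_few_reps_rejected(self):
        with pytest.raises(ConfigurationError):
            recovery_study(SimConfig(), n_reps=1)
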