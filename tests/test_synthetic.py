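"""Synthetic screen generator: construction invariants and determinism."""

import numpy as np
import pandas as pd
import pytest

from comboscreen.response import logistic2p
from comboscreen.synergy import per_well_excess, synergy_summary, window_score
from comboscreen.synthetic import (
    PlantedEffect,
    SimulationConfig,
    SingleAgentCurve,
    SynergyWindow,
    dose_grid,
    draw_synergy_window,
    generate_feature_matrix,
    generate_plate_controls,
    generate_screen,
    simulate_combination_matrix,
    simulate_single_agent_curve,
)

DOSES = dose_grid()


class TestDoseGrid:
    def test_log_equispaced_over_fold_range(self):
        assert DOSES.size == 7
        assert DOSES[-1] / DOSES[0] == pytest.approx(1000.0)
        ratios = DOSES[1:] / DOSES[:-1]
        np.testing.assert_allclose(ratios, ratios[0])


class TestSingleAgentCurve:
    def test_midpoint_inhibition_at_ic50(self):
        curve = simulate_single_agent_curve(DOSES[3], 2.0, DOSES, noise_sd=0)
        assert curve.inhibition[3] == pytest.approx(0.5)

    def test_inactive_limit(self):
        curve = simulate_single_agent_curve(DOSES[-1] * 1e4, 5.0, DOSES, noise_sd=0)
        assert np.all(curve.inhibition < 1e-6)

    def test_noiseless_truth_monotone_and_bounded(self):
        curve = simulate_single_agent_curve(DOSES[2], 1.3, DOSES, noise_sd=0)
        assert np.all(np.diff(curve.inhibition) >= 0)
        assert np.all((curve.inhibition >= 0) & (curve.inhibition <= 1))

    def test_seed_determinism(self):
        a = simulate_single_agent_curve(DOSES[3], 2.0, DOSES, 0.05, seed=42)
        b = simulate_single_agent_curve(DOSES[3], 2.0, DOSES, 0.05, seed=42)
        np.testing.assert_array_equal(a.inhibition, b.inhibition)

    def test_nonpositive_doses_rejected(self):
        with pytest.raises(ValueError):
            simulate_single_agent_curve(1.0, 1.0, np.array([0.0, 1, 2, 3]))


def _curve(ic50, slope, drug="X"):
    return SingleAgentCurve(drug, DOSES, ic50, slope,
                            logistic2p(DOSES, ic50, slope))


class TestCombinationMatrix:
    def test_no_window_means_zero_bliss_excess_everywhere(self):
        a, b = _curve(DOSES[3], 2.0), _curve(DOSES[2], 1.2)
        grid = simulate_combination_matrix(a, b, None, noise_sd=0)
        excess = per_well_excess(grid, a.inhibition, b.inhibition, "bliss")
        assert np.abs(excess).max() < 1e-12

    def test_inactive_partner_rows_equal_first_curve(self):
        a = _curve(DOSES[3], 2.0)
        b = _curve(DOSES[-1] * 1e6, 8.0)  # essentially zero everywhere
        grid = simulate_combination_matrix(a, b, None, noise_sd=0)
        for j in range(7):
            np.testing.assert_allclose(grid[:, j], a.inhibition, atol=1e-6)

    def test_planted_corner_window_recovered_exactly(self):
        a, b = _curve(DOSES[4], 1.5), _curve(DOSES[5], 1.5)
        win = SynergyWindow(0, 0, 3, 0.2)
        grid = simulate_combination_matrix(a, b, win, noise_sd=0)
        res = synergy_summary(grid, a.inhibition, b.inhibition)
        assert res.bliss_window == pytest.approx(0.2)
        assert res.bliss_window_loc == (0, 0)
        assert res.bliss_matrix == pytest.approx(9 * 0.2 / 49)

    def test_window_outside_bounds_rejected(self):
        a, b = _curve(DOSES[3], 2.0), _curve(DOSES[3], 2.0)
        with pytest.raises(ValueError):
            simulate_combination_matrix(a, b, SynergyWindow(5, 5, 3, 0.2))

    def test_truth_bounded_before_noise(self):
        a, b = _curve(DOSES[0], 0.8), _curve(DOSES[1], 1.1)
        grid = simulate_combination_matrix(a, b, SynergyWindow(4, 4, 3, 0.9), 0)
        assert np.all((grid >= 0) & (grid <= 1))


class TestDrawSynergyWindow:
    def test_no_placement_when_saturated(self):
        e = np.full(7, 0.99)
        assert draw_synergy_window(np.random.default_rng(0), e, e, 3, 0.3) is None

    def test_placement_has_headroom(self):
        rng = np.random.default_rng(1)
        e_a = logistic2p(DOSES, DOSES[2], 2.0)
        e_b = logistic2p(DOSES, DOSES[3], 1.5)
        for _ in range(20):
            win = draw_synergy_window(rng, e_a, e_b, 3, 0.3)
            assert win is not None
            base = np.add.outer(e_a, e_b) - np.outer(e_a, e_b)
            block = base[win.row : win.row + 3, win.col : win.col + 3]
            assert np.minimum(0.3, 1 - block).mean() >= 0.15


class TestFeatureMatrix:
    def test_binary_and_deterministic(self):
        cfg = SimulationConfig(n_cell_lines=30, n_features=12, seed=5)
        lines = [f"CL{i}" for i in range(30)]
        m1, _ = generate_feature_matrix(cfg, lines)
        m2, _ = generate_feature_matrix(cfg, lines)
        pd.testing.assert_frame_equal(m1, m2)
        assert m1.isin([0, 1]).all().all()

    def test_unknown_target_rejected(self):
        cfg = SimulationConfig(
            planted_single_agent_effects=(PlantedEffect("F001", "NOPE", 0.3),)
        )
        with pytest.raises(ValueError):
            generate_feature_matrix(cfg, ["CL1"], known_targets=["D01"])

    def test_unknown_feature_rejected(self):
        cfg = SimulationConfig(
            n_features=3,
            planted_single_agent_effects=(PlantedEffect("F999", "D01", 0.3),),
        )
        with pytest.raises(ValueError):
            generate_feature_matrix(cfg, ["CL1"])


class TestPlateControls:
    def test_default_counts(self):
        tbl = generate_plate_controls(seed=0)
        counts = tbl["well_class"].value_counts()
        assert counts["NC1"] == 155 and counts["NC0"] == 155
        assert counts["PC1"] + counts["PC2"] == 32
        assert counts["B"] == 28

    def test_zero_sd_gives_class_means(self):
        tbl = generate_plate_controls(
            sds={c: 0.0 for c in ("NC0", "NC1", "PC1", "PC2", "B")}, seed=0
        )
        means = tbl.groupby("well_class")["raw_signal"].agg(["min", "max"])
        assert (means["min"] == means["max"]).all()

    def test_negative_sd_rejected(self):
        with pytest.raises(ValueError):
            generate_plate_controls(sds={"NC1": -1.0})

    def test_seed_reproducibility(self):
        a = generate_plate_controls(seed=3)
        b = generate_plate_controls(seed=3)
        pd.testing.assert_frame_equal(a, b)


class TestGenerateScreen:
    def test_full_determinism_under_fixed_seed(self):
        cfg = SimulationConfig(n_cell_lines=8, n_combinations=2, n_features=5, seed=9)
        s1, s2 = generate_screen(cfg), generate_screen(cfg)
        pd.testing.assert_frame_equal(s1.wells, s2.wells)
        pd.testing.assert_frame_equal(s1.features, s2.features)
        assert s1.truth.windows == s2.truth.windows

    def test_adding_cell_lines_preserves_existing_data(self):
        small = generate_screen(
            SimulationConfig(n_cell_lines=6, n_combinations=2, n_features=5, seed=9)
        )
        big = generate_screen(
            SimulationConfig(n_cell_lines=10, n_combinations=2, n_features=5, seed=9)
        )
        shared = small.wells["cell_line"].unique()
        a = small.wells.sort_values(["plate", "well_class", "drug_a", "dose_index_a",
                                     "dose_index_b"]).reset_index(drop=True)
        b = (
            big.wells[big.wells["cell_line"].isin(shared)]
            .sort_values(["plate", "well_class", "drug_a", "dose_index_a",
                          "dose_index_b"])
            .reset_index(drop=True)
        )
        pd.testing.assert_frame_equal(a, b)

    def test_noiseless_screen_without_windows_is_bliss_additive(self):
        cfg = SimulationConfig(
            n_cell_lines=6, n_combinations=2, n_features=4,
            noise_sd=0.0, synergy_fraction=0.0, seed=2,
            control_sds={c: 0.0 for c in ("NC0", "NC1", "PC1", "PC2", "B")},
        )
        screen = generate_screen(cfg)
        from comboscreen.pipeline import stage_response, stage_synergy

        _, pairs = stage_response(screen.wells, set(screen.wells["plate"]))
        syn = stage_synergy(pairs)
        assert syn["bliss_matrix"].abs().max() < 1e-9
        assert syn["bliss_window"].abs().max() < 1e-9

    def test_planted_window_locations_recorded_in_truth(self):
        cfg = SimulationConfig(
            n_cell_lines=12, n_combinations=2, synergy_fraction=1.0,
            noise_sd=0.0, seed=3,
        )
        screen = generate_screen(cfg)
        planted = {k: v for k, v in screen.truth.windows.items() if v is not None}
        assert planted  # saturation can skip a few pairs, not all
        combo_wells = screen.wells[screen.wells["well_class"] == "COMBO"]
        for (combo_id, line), win in planted.items():
            drug_a, drug_b = combo_id.split("|")
            sub = combo_wells[
                (combo_wells["cell_line"] == line)
                & (combo_wells["drug_a"] == drug_a)
            ]
            grid = sub.pivot(index="dose_index_a", columns="dose_index_b",
                             values="raw_signal").to_numpy()
            inh = (100_000.0 - grid) / (100_000.0 - 2_000.0)
            sa = screen.wells[
                (screen.wells["cell_line"] == line)
                & (screen.wells["drug_a"] == drug_a)
                & (screen.wells["drug_b"] == drug_b)
            ]
            e_a = (100_000.0 - sa[sa["well_class"] == "SA_A"].sort_values(
                "dose_index_a")["raw_signal"].to_numpy()) / 98_000.0
            e_b = (100_000.0 - sa[sa["well_class"] == "SA_B"].sort_values(
                "dose_index_b")["raw_signal"].to_numpy()) / 98_000.0
            excess = per_well_excess(inh, e_a, e_b, "bliss")
            _, loc = window_score(excess)
            assert loc == (win.row, win.col)

    def test_emergent_effect_spares_single_agent_wells(self):
        base = SimulationConfig(
            n_cell_lines=10, n_combinations=2, n_features=5,
            noise_sd=0.0, synergy_fraction=0.0, seed=4,
        )
        with_eff = SimulationConfig(
            **{**base.__dict__,
               "planted_emergent_effects": (PlantedEffect("F001", "D01|D02", 0.3),)}
        )
        s0, s1 = generate_screen(base), generate_screen(with_eff)
        sa0 = s0.wells[s0.wells["well_class"].isin(("SA_A", "SA_B"))]
        sa1 = s1.wells[s1.wells["well_class"].isin(("SA_A", "SA_B"))]
        pd.testing.assert_frame_equal(
            sa0.reset_index(drop=True), sa1.reset_index(drop=True)
        )
        combo0 = s0.wells[s0.wells["well_class"] == "COMBO"]["raw_signal"]
        combo1 = s1.wells[s1.wells["well_class"] == "COMBO"]["raw_signal"]
        assert not np.allclose(combo0.to_numpy(), combo1.to_numpy())

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(n_doses=1)
        with pytest.raises(ValueError):
            SimulationConfig(synergy_fraction=1.5)
        with pytest.raises(ValueError):
            SimulationConfig(noise_sd=-0.1)
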