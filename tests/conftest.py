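import numpy as np
import pandas as pd
import pytest

from comboscreen.pipeline import (
    PipelineConfig,
    biomarker_input,
    stage_qc,
    stage_response,
    stage_synergy,
)
from comboscreen.qc import QCThresholds
from comboscreen.synthetic import PlantedEffect, SimulationConfig, generate_screen


@pytest.fixture(scope="session")
def small_screen():
    """A small noiseless-free screen shared by pipeline-level tests."""
    cfg = SimulationConfig(
        n_cell_lines=24, n_cancer_types=6, n_combinations=3, n_features=10, seed=11
    )
    return generate_screen(cfg)


@pytest.fixture(scope="session")
def small_pipeline_tables(small_screen):
    """QC report, response table, synergy table for the small screen."""
    qc = stage_qc(small_screen.wells, QCThresholds())
    passing = set(qc[qc["passed"]]["plate"])
    response, pairs = stage_response(small_screen.wells, passing)
    synergy = stage_synergy(pairs)
    return {"qc": qc, "response": response, "synergy": synergy, "pairs": pairs}


@pytest.fixture(scope="session")
def planted_screen():
    """Screen with one planted single-agent and two planted emergent effects."""
    cfg = SimulationConfig(
        n_cell_lines=150,
        n_combinations=4,
        n_features=15,
        synergy_fraction=0.0,
        planted_single_agent_effects=(PlantedEffect("F001", "D02", 0.45),),
        planted_emergent_effects=(
            PlantedEffect("F005", "D01|D02", 0.25),
            PlantedEffect("F009", "D03|D04", 0.25),
        ),
        seed=7,
    )
    return generate_screen(cfg)


@pytest.fixture(scope="session")
def planted_associations(planted_screen):
    from comboscreen.biomarkers import flag_emergent, run_anova_suite

    s = planted_screen
    qc = stage_qc(s.wells, QCThresholds())
    passing = set(qc[qc["passed"]]["plate"])
    response, pairs = stage_response(s.wells, passing)
    synergy = stage_synergy(pairs)
    assoc = run_anova_suite(
        biomarker_input(response, synergy), s.features, annotations=s.annotations
    )
    assoc, partition = flag_emergent(assoc)
    return assoc, partition
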