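"""Configuration and the end-to-end pipeline driver.

Stages: simulate (optional) -> plate QC -> normalization & curve fitting ->
synergy scoring -> prioritization -> biomarker ANOVA -> pathway enrichment.
Every stage writes a deterministic CSV/JSON artifact (fixed column order,
sorted rows, fixed float formatting) and the run ends with a manifest
recording the config hash, seed, library versions and per-stage row
counts, so two runs with the same config and seed are identical except
for timestamps.

Every screening threshold is a named config key: combination Emax > 0.5
and HSA > 0.1 for activity, >= 10% responders, breadth cap at 50% of
cancer types, >= 10 cell lines per pair, p <= 0.001 / FDR <= 10% / Glass
deltas >= 1 for biomarkers, CV < 0.18, Z-factor >= 0.3 and NC0/NC1 ratio
in [0.8, 1.2] for plate QC, |Z| >= 2 for expression binarization.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as sio
from .biomarkers import (
    SignificanceThresholds,
    build_subgroups,
    flag_emergent,
    run_anova_suite,
)
from .enrichment import enrichment_over_random
from .prioritize import PrioritizationThresholds, activity_calls, rank_hits, responder_rate
from .qc import QCThresholds, qc_plate
from .response import combo_emax, fit_logistic2p, normalize_inhibition
from .synergy import synergy_summary
from .synthetic import PlantedEffect, SimulationConfig, generate_screen

logger = logging.getLogger("comboscreen")

_FLOAT_FMT = "%.10g"


@dataclass
class PipelineConfig:
    """Full pipeline configuration with the screen's default thresholds."""

    seed: int = 0
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    qc: QCThresholds = field(default_factory=QCThresholds)
    prioritization: PrioritizationThresholds = field(
        default_factory=PrioritizationThresholds
    )
    biomarkers: SignificanceThresholds = field(default_factory=SignificanceThresholds)
    hsa_column: str = "hsa_matrix"  # HSA variant feeding the activity call
    window_size: int = 3
    matrix_aggregate: str = "mean"  # "max" exposes the per-well-max variant
    trim_doses: dict = field(default_factory=dict)  # combo_id -> n doses to drop
    expression_z_threshold: float = 2.0
    min_cancer_type_size: int = 20
    pan_cancer_covariate: bool = True
    basket_features: tuple = ()
    enrichment_n_boot: int = 10
    enrichment_unit: str = "pair"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        kwargs = dict(raw)
        sim = dict(kwargs.pop("simulation", {}))
        for key in ("planted_single_agent_effects", "planted_emergent_effects"):
            if key in sim:
                sim[key] = tuple(PlantedEffect(*e) for e in sim[key])
        seed = kwargs.get("seed", 0)
        sim.setdefault("seed", seed)
        cfg = cls(
            simulation=SimulationConfig(**sim),
            qc=QCThresholds(**kwargs.pop("qc", {})),
            prioritization=PrioritizationThresholds(**kwargs.pop("prioritization", {})),
            biomarkers=SignificanceThresholds(**kwargs.pop("biomarkers", {})),
            **kwargs,
        )
        return cfg

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["basket_features"] = list(d["basket_features"])
        sim = d["simulation"]
        for key in ("planted_single_agent_effects", "planted_emergent_effects"):
            sim[key] = [list(e) for e in sim[key]]
        return d

    def content_hash(self) -> str:
        canonical = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(canonical.encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# stages


def stage_qc(wells: pd.DataFrame, thresholds: QCThresholds) -> pd.DataFrame:
    """Per-plate QC report over the control wells."""
    rows = []
    ctrl = wells[wells["well_class"].isin(sio.CONTROL_CLASSES)]
    for plate, grp in ctrl.groupby("plate"):
        rep = qc_plate(grp.assign(plate=plate), thresholds)
        row = {
            "plate": plate,
            "cv": rep.cv,
            "nc_ratio": rep.nc_ratio,
            "passed": rep.passed,
            "reasons": ";".join(rep.reasons),
        }
        for pc, z in rep.z_factors.items():
            row[f"z_{pc.lower()}"] = z
        rows.append(row)
    return pd.DataFrame(rows).sort_values("plate").reset_index(drop=True)


def stage_response(
    wells: pd.DataFrame,
    passing_plates: set,
    trim_doses: dict | None = None,
) -> tuple[pd.DataFrame, list[dict]]:
    """Normalize to inhibition, fit single agents, extract the Emax metrics.

    Returns the per-pair response table plus the normalized grids and
    marginals needed by the synergy stage.  Control means are estimated
    per plate from its own NC1 and blank wells.
    """
    trim_doses = trim_doses or {}
    wells = wells[wells["plate"].isin(passing_plates)]
    ctrl_means = (
        wells[wells["well_class"].isin(("NC1", "B"))]
        .groupby(["plate", "well_class"])["raw_signal"]
        .mean()
        .unstack()
    )

    records, pair_data = [], []
    treated = wells[wells["well_class"].isin(("COMBO", "SA_A", "SA_B"))]
    for (plate, line, drug_a, drug_b), grp in treated.groupby(
        ["plate", "cell_line", "drug_a", "drug_b"], sort=True
    ):
        mean_nc1 = ctrl_means.loc[plate, "NC1"]
        mean_blank = ctrl_means.loc[plate, "B"]
        inh = normalize_inhibition(grp["raw_signal"].to_numpy(), mean_nc1, mean_blank)
        grp = grp.assign(inhibition=inh)

        combo_wells = grp[grp["well_class"] == "COMBO"]
        grid = (
            combo_wells.pivot(
                index="dose_index_a", columns="dose_index_b", values="inhibition"
            )
            .sort_index()
            .sort_index(axis=1)
            .to_numpy()
        )
        sa_a = grp[grp["well_class"] == "SA_A"].sort_values("dose_index_a")
        sa_b = grp[grp["well_class"] == "SA_B"].sort_values("dose_index_b")
        doses_a = sa_a["conc_a"].to_numpy()
        doses_b = sa_b["conc_b"].to_numpy()
        marg_a = sa_a["inhibition"].to_numpy()
        marg_b = sa_b["inhibition"].to_numpy()

        combo_id = f"{drug_a}|{drug_b}"
        n_trim = int(trim_doses.get(combo_id, 0))
        if n_trim:
            grid = grid[:-n_trim, :-n_trim]
            marg_a, marg_b = marg_a[:-n_trim], marg_b[:-n_trim]
            doses_a, doses_b = doses_a[:-n_trim], doses_b[:-n_trim]

        fit_a = fit_logistic2p(doses_a, marg_a)
        fit_b = fit_logistic2p(doses_b, marg_b)
        records.append(
            {
                "combo_id": combo_id,
                "cell_line": line,
                "plate": plate,
                "drug_a": drug_a,
                "drug_b": drug_b,
                "ic50_a": fit_a.ic50,
                "ic50_b": fit_b.ic50,
                "slope_a": fit_a.slope,
                "slope_b": fit_b.slope,
                "emax_a": fit_a.emax,
                "emax_b": fit_b.emax,
                "ic50_a_censored": fit_a.censored or "",
                "ic50_b_censored": fit_b.censored or "",
                "combo_emax": combo_emax(grid),
            }
        )
        pair_data.append(
            {
                "combo_id": combo_id,
                "cell_line": line,
                "grid": grid,
                "marg_a": marg_a,
                "marg_b": marg_b,
            }
        )
    response = pd.DataFrame(records).sort_values(["combo_id", "cell_line"])
    return response.reset_index(drop=True), pair_data


def stage_synergy(
    pair_data: list[dict], window_size: int = 3, matrix_aggregate: str = "mean"
) -> pd.DataFrame:
    """Bliss/HSA matrix and window scores for every (combination, cell line)."""
    rows = []
    for pair in pair_data:
        res = synergy_summary(
            pair["grid"], pair["marg_a"], pair["marg_b"],
            window_size=window_size, matrix_aggregate=matrix_aggregate,
        )
        rows.append(
            {
                "combo_id": pair["combo_id"],
                "cell_line": pair["cell_line"],
                "bliss_matrix": res.bliss_matrix,
                "bliss_window": res.bliss_window,
                "hsa_matrix": res.hsa_matrix,
                "hsa_window": res.hsa_window,
                "window_row": res.bliss_window_loc[0],
                "window_col": res.bliss_window_loc[1],
                "combo_emax": res.combo_emax,
            }
        )
    return (
        pd.DataFrame(rows)
        .sort_values(["combo_id", "cell_line"])
        .reset_index(drop=True)
    )


def biomarker_input(response: pd.DataFrame, synergy: pd.DataFrame) -> pd.DataFrame:
    """Join fitted single-agent metrics with synergy scores per pair."""
    return response[["combo_id", "cell_line", "emax_a", "emax_b", "combo_emax"]].merge(
        synergy[["combo_id", "cell_line", "bliss_matrix", "bliss_window"]],
        on=["combo_id", "cell_line"],
    )


def _write(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def run_pipeline(
    config: PipelineConfig | str | Path, outdir: str | Path
) -> dict:
    """Execute simulate -> qc -> fit -> synergy -> prioritize -> biomarkers -> enrich.

    Writes every intermediate table under ``outdir`` plus ``manifest.json``
    and returns the manifest dict.
    """
    if not isinstance(config, PipelineConfig):
        config = PipelineConfig.from_yaml(config)
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": config.to_dict(),
        "config_hash": config.content_hash(),
        "seed": config.seed,
        "versions": {
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "stages": {},
    }

    def record(stage: str, t0: float, n_rows: int) -> None:
        manifest["stages"][stage] = {
            "rows": int(n_rows),
            "seconds": round(time.perf_counter() - t0, 3),
        }
        logger.info("stage %s: %d rows (%.2fs)", stage, n_rows,
                    time.perf_counter() - t0)

    t0 = time.perf_counter()
    screen = generate_screen(config.simulation)
    sio.write_screen_bundle(screen, out)
    record("simulate", t0, len(screen.wells))

    t0 = time.perf_counter()
    qc_report = stage_qc(screen.wells, config.qc)
    _write(qc_report, out / "qc.csv")
    passing = set(qc_report[qc_report["passed"]]["plate"])
    record("qc", t0, len(qc_report))

    t0 = time.perf_counter()
    response, pair_data = stage_response(screen.wells, passing, config.trim_doses)
    _write(response, out / "response.csv")
    record("response", t0, len(response))

    t0 = time.perf_counter()
    synergy = stage_synergy(pair_data, config.window_size, config.matrix_aggregate)
    _write(synergy, out / "synergy.csv")
    record("synergy", t0, len(synergy))

    t0 = time.perf_counter()
    thr = config.prioritization
    calls = activity_calls(
        synergy, thr.emax_threshold, thr.hsa_threshold, config.hsa_column
    )
    rates = responder_rate(calls, screen.annotations)
    heme, solid, funnel = rank_hits(
        rates, screen.annotations, screen.combinations, thr
    )
    _write(calls, out / "activity_calls.csv")
    _write(rates, out / "responder_rates.csv")
    _write(heme, out / "hits_heme.csv")
    _write(solid, out / "hits_solid.csv")
    (out / "funnel.json").write_text(json.dumps(funnel, indent=1))
    record("prioritize", t0, len(heme) + len(solid))

    t0 = time.perf_counter()
    subgroups = build_subgroups(
        screen.annotations,
        screen.features,
        tuple(config.basket_features),
        config.min_cancer_type_size,
    )
    assoc = run_anova_suite(
        biomarker_input(response, synergy),
        screen.features,
        subgroups=subgroups,
        annotations=screen.annotations,
        thresholds=config.biomarkers,
        pan_cancer_covariate=config.pan_cancer_covariate,
    )
    assoc, partition = flag_emergent(assoc)
    _write(assoc, out / "associations.csv")
    (out / "emergent_partition.json").write_text(json.dumps(partition, indent=1))
    record("biomarkers", t0, len(assoc))

    t0 = time.perf_counter()
    enrich = enrichment_over_random(
        calls[["combo_id", "cell_line", "active"]],
        screen.combinations[["combo_id", "category"]],
        n_boot=config.enrichment_n_boot,
        seed=config.seed,
        unit=config.enrichment_unit,
    )
    _write(enrich, out / "enrichment.csv")
    record("enrich", t0, len(enrich))

    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
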