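"""Synthetic drug-combination screen generator with recoverable ground truth.

The generator emulates the statistical structure of a pan-cancer
combination screen: each drug pair is dosed on a k x k (default 7 x 7)
log-spaced concentration matrix spanning a 1,000-fold range, single-agent
responses follow a two-parameter logistic curve, and combination wells sit
on a Bliss-additive baseline.  A configurable fraction of
(combination, cell line) pairs receives a localized "synergy window" — a
w x w block of wells boosted above additivity — mimicking
concentration-dependent synergy.  Gaussian noise is added on the
inhibition scale and wells are converted back to raw instrument signal
using per-plate control populations, so the full normalization / QC /
fitting pipeline is exercised end to end.

A binary feature matrix (MOBEM-style) is generated alongside, with
optional planted associations: *single-agent* effects shift the
single-agent response of one drug in feature-positive lines (and hence
propagate into its combinations), while *emergent* effects shift only the
combination wells of one drug pair, leaving both monotherapies untouched —
the construction that emergent-biomarker detection must recover.

Every random draw descends from one global seed through fixed per-entity
substreams, so adding cell lines or combinations never perturbs the data
generated for existing ones, and repeated runs are byte-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

from .response import logistic2p
from .synergy import bliss_expected

__all__ = [
    "SimulationConfig",
    "SingleAgentCurve",
    "SynergyWindow",
    "PlantedEffect",
    "GroundTruth",
    "Screen",
    "dose_grid",
    "draw_synergy_window",
    "simulate_single_agent_curve",
    "simulate_combination_matrix",
    "generate_feature_matrix",
    "generate_plate_controls",
    "generate_screen",
]

# raw-signal control populations (arbitrary luminescence units); means/SDs
# chosen so that plate statistics sit near typical screen medians
# (negative-control CV ~ 0.12, Z-factor ~ 0.5, NC0/NC1 ratio ~ 1)
DEFAULT_CONTROL_MEANS = {"NC0": 100_000.0, "NC1": 100_000.0,
                         "PC1": 5_000.0, "PC2": 5_000.0, "B": 2_000.0}
DEFAULT_CONTROL_SDS = {"NC0": 12_280.0, "NC1": 12_280.0,
                       "PC1": 3_500.0, "PC2": 3_500.0, "B": 200.0}

# substream tags for the counter-based seeding scheme
_TAG_CURVE, _TAG_WINDOW, _TAG_WELLS, _TAG_CONTROLS, _TAG_FEATURE = 1, 2, 3, 4, 5

PATHWAY_CLASSES = ("CD", "DDR", "CS", "CH")  # cell death, DNA damage response,
                                             # cell signaling, chemotherapeutic


class SynergyWindow(NamedTuple):
    """A planted w x w block of super-additive wells (0-based top-left corner)."""

    row: int
    col: int
    size: int
    boost: float


class PlantedEffect(NamedTuple):
    """A planted feature-response association.

    ``target`` names a drug (single-agent effect) or a combination id
    (emergent effect); ``effect`` is the additive shift, on the inhibition
    scale, applied to feature-positive cell lines.
    """

    feature: str
    target: str
    effect: float


@dataclass(frozen=True)
class SimulationConfig:
    """Study-condition knobs of the synthetic screen."""

    n_cell_lines: int = 80
    n_cancer_types: int = 10
    n_combinations: int = 6
    n_doses: int = 7
    dose_fold_range: float = 1000.0
    max_dose: float = 10.0  # concentration units; top of every dose ladder
    noise_sd: float = 0.05  # Gaussian SD on the inhibition scale
    synergy_fraction: float = 0.25
    synergy_boost: float = 0.3
    window_size: int = 3
    n_features: int = 25
    feature_prevalence: float = 0.3
    planted_single_agent_effects: tuple[PlantedEffect, ...] = ()
    planted_emergent_effects: tuple[PlantedEffect, ...] = ()
    n_nc0: int = 155
    n_nc1: int = 155
    n_pc: int = 32  # split evenly across the two positive-control agents
    n_blank: int = 28
    control_means: dict = field(default_factory=lambda: dict(DEFAULT_CONTROL_MEANS))
    control_sds: dict = field(default_factory=lambda: dict(DEFAULT_CONTROL_SDS))
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_doses < 2:
            raise ValueError("need at least 2 doses")
        if self.dose_fold_range <= 1:
            raise ValueError("dose_fold_range must exceed 1")
        if not 0.0 <= self.synergy_fraction <= 1.0:
            raise ValueError("synergy_fraction must lie in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.window_size > self.n_doses:
            raise ValueError("window_size cannot exceed n_doses")


@dataclass(frozen=True)
class SingleAgentCurve:
    """Noiseless-truth parameters plus (possibly noisy) per-dose inhibition."""

    drug: str
    doses: np.ndarray
    true_ic50: float
    true_slope: float
    inhibition: np.ndarray


@dataclass
class GroundTruth:
    """Planted simulation parameters, the oracle for recovery tests."""

    curves: dict  # (drug, cell_line) -> (ic50, slope)
    windows: dict  # (combo_id, cell_line) -> SynergyWindow | None
    single_agent_effects: tuple[PlantedEffect, ...]
    emergent_effects: tuple[PlantedEffect, ...]
    control_means: dict
    control_sds: dict


@dataclass
class Screen:
    """A complete simulated screen plus its ground truth."""

    config: SimulationConfig
    wells: pd.DataFrame  # long-format well table including control wells
    annotations: pd.DataFrame  # cell_line, cancer_type, group (heme|solid)
    combinations: pd.DataFrame  # combo_id, drug_a, drug_b, category
    features: pd.DataFrame  # cell_line x feature, values in {0, 1}
    truth: GroundTruth


def _rng(seed: int, tag: int, *indices: int) -> np.random.Generator:
    """Independent substream keyed by (seed, stream tag, entity indices)."""
    return np.random.default_rng([int(seed), int(tag), *map(int, indices)])


def dose_grid(n_doses: int = 7, fold_range: float = 1000.0,
              max_dose: float = 10.0) -> np.ndarray:
    """Log-equispaced concentration ladder ending at ``max_dose``."""
    return max_dose * (1.0 / fold_range) ** (
        np.arange(n_doses - 1, -1, -1) / (n_doses - 1)
    )


def draw_synergy_window(
    rng: np.random.Generator,
    e_a: np.ndarray,
    e_b: np.ndarray,
    size: int = 3,
    boost: float = 0.3,
) -> SynergyWindow | None:
    """Draw a planted window location uniformly among *expressible* locations.

    Because combination inhibition is capped at 1, a boost planted where
    the Bliss baseline is already saturated leaves no trace in the data
    and cannot serve as ground truth.  A location qualifies when at least
    half of the nominal boost survives the ceiling on average across the
    window; if no location qualifies (both drugs near-maximally active
    everywhere), no window is planted and ``None`` is returned.
    """
    base = bliss_expected(np.asarray(e_a)[:, None], np.asarray(e_b)[None, :])
    headroom = np.minimum(boost, 1.0 - base)
    k_r, k_c = base.shape
    candidates = [
        (r, c)
        for r in range(k_r - size + 1)
        for c in range(k_c - size + 1)
        if headroom[r : r + size, c : c + size].mean() >= boost / 2.0
    ]
    if not candidates:
        return None
    r, c = candidates[int(rng.integers(0, len(candidates)))]
    return SynergyWindow(r, c, size, boost)


def simulate_single_agent_curve(
    true_ic50: float,
    true_slope: float,
    doses: np.ndarray,
    noise_sd: float = 0.0,
    seed: int | np.random.Generator = 0,
    drug: str = "drug",
) -> SingleAgentCurve:
    """Two-parameter logistic truth evaluated at each dose, plus i.i.d. noise.

    The noiseless truth is ``1 / (1 + (ic50/d)^slope)`` (asymptotes 0 and
    1, hence non-decreasing in dose).  Noise is Gaussian on the inhibition
    scale and deliberately not clipped, so downstream normalization and QC
    see realistic out-of-range values.
    """
    d = np.asarray(doses, dtype=float)
    if np.any(d <= 0):
        raise ValueError("doses must be positive")
    if np.any(np.diff(d) <= 0):
        raise ValueError("doses must be strictly increasing")
    truth = logistic2p(d, true_ic50, true_slope)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    inhibition = truth + rng.normal(0.0, noise_sd, size=d.size) if noise_sd > 0 else truth
    return SingleAgentCurve(
        drug=drug, doses=d, true_ic50=float(true_ic50),
        true_slope=float(true_slope), inhibition=inhibition,
    )


def combination_truth(
    e_a: np.ndarray, e_b: np.ndarray, window: SynergyWindow | None = None
) -> np.ndarray:
    """Noiseless combination grid: Bliss baseline plus an optional window boost."""
    e_a = np.asarray(e_a, dtype=float)
    e_b = np.asarray(e_b, dtype=float)
    grid = bliss_expected(e_a[:, None], e_b[None, :])
    if window is not None:
        k_r, k_c = grid.shape
        r, c, w, boost = window
        if r < 0 or c < 0 or r + w > k_r or c + w > k_c:
            raise ValueError(f"window {window} falls outside a {k_r}x{k_c} matrix")
        grid[r : r + w, c : c + w] += boost
    return np.clip(grid, 0.0, 1.0)


def simulate_combination_matrix(
    curve_a: SingleAgentCurve,
    curve_b: SingleAgentCurve,
    window: SynergyWindow | None = None,
    noise_sd: float = 0.0,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Simulate the k x k combination grid for two single-agent curves.

    The noiseless well (i, j) is the Bliss-additive combination of the
    *true* single-agent inhibitions, plus the window boost where planted
    (clipped into [0, 1] before noise).  Gaussian noise is then added
    without clipping.
    """
    if curve_a.doses.size != curve_b.doses.size:
        raise ValueError("both curves must share the same number of doses")
    truth_a = logistic2p(curve_a.doses, curve_a.true_ic50, curve_a.true_slope)
    truth_b = logistic2p(curve_b.doses, curve_b.true_ic50, curve_b.true_slope)
    grid = combination_truth(truth_a, truth_b, window)
    if noise_sd > 0:
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        grid = grid + rng.normal(0.0, noise_sd, size=grid.shape)
    return grid


def generate_feature_matrix(
    config: SimulationConfig,
    cell_lines: Sequence[str],
    known_targets: Sequence[str] | None = None,
) -> tuple[pd.DataFrame, tuple[PlantedEffect, ...]]:
    """Binary cell line x feature matrix plus the validated planted effects.

    Features are named ``F001`` ...; planted effects may reference features
    by name.  When ``known_targets`` is given, every planted effect must
    reference one of those drugs/combinations.
    """
    effects = tuple(config.planted_single_agent_effects) + tuple(
        config.planted_emergent_effects
    )
    feature_names = [f"F{i + 1:03d}" for i in range(config.n_features)]
    planted_features = {e.feature for e in effects}
    unknown = planted_features - set(feature_names)
    if unknown:
        raise ValueError(f"planted effects reference unknown features: {sorted(unknown)}")
    if known_targets is not None:
        bad = {e.target for e in effects} - set(known_targets)
        if bad:
            raise ValueError(f"planted effects reference unknown targets: {sorted(bad)}")

    cols = {}
    for j, name in enumerate(feature_names):
        rng = _rng(config.seed, _TAG_FEATURE, j)
        cols[name] = rng.binomial(1, config.feature_prevalence, size=len(cell_lines))
    matrix = pd.DataFrame(cols, index=pd.Index(cell_lines, name="cell_line"))
    return matrix, effects


def generate_plate_controls(
    n_nc0: int = 155,
    n_nc1: int = 155,
    n_pc: int = 32,
    n_blank: int = 28,
    means: dict | None = None,
    sds: dict | None = None,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Gaussian control-well populations for one plate.

    ``n_pc`` is split evenly between the two positive-control agents
    (PC1, PC2).  Returns a frame with ``well_class`` and ``raw_signal``.
    """
    means = dict(DEFAULT_CONTROL_MEANS, **(means or {}))
    sds = dict(DEFAULT_CONTROL_SDS, **(sds or {}))
    counts = {"NC0": n_nc0, "NC1": n_nc1, "PC1": n_pc // 2,
              "PC2": n_pc - n_pc // 2, "B": n_blank}
    for cls, n in counts.items():
        if n <= 0:
            raise ValueError(f"control count for {cls} must be positive")
        if sds[cls] < 0:
            raise ValueError(f"negative SD for control class {cls}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    frames = []
    for cls, n in counts.items():
        frames.append(
            pd.DataFrame(
                {
                    "well_class": cls,
                    "raw_signal": rng.normal(means[cls], sds[cls], size=n),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def _inhibition_to_raw(inhibition: np.ndarray, means: dict) -> np.ndarray:
    """Invert the normalization: 0 -> DMSO mean, 1 -> blank mean."""
    return means["NC1"] - np.asarray(inhibition) * (means["NC1"] - means["B"])


def generate_screen(config: SimulationConfig) -> Screen:
    """Generate a full screen: wells, controls, annotations, features, truth."""
    cfg = config
    k = cfg.n_doses
    doses = dose_grid(k, cfg.dose_fold_range, cfg.max_dose)
    log_center = np.log10(cfg.max_dose)

    cell_lines = [f"CL{i + 1:04d}" for i in range(cfg.n_cell_lines)]
    cancer_types = [f"ct{j + 1:02d}" for j in range(cfg.n_cancer_types)]
    n_heme = max(1, cfg.n_cancer_types // 4)
    annotations = pd.DataFrame(
        {
            "cell_line": cell_lines,
            "cancer_type": [cancer_types[i % cfg.n_cancer_types]
                            for i in range(cfg.n_cell_lines)],
        }
    )
    annotations["group"] = np.where(
        annotations["cancer_type"].isin(cancer_types[:n_heme]), "heme", "solid"
    )

    drugs = [f"D{i + 1:02d}" for i in range(cfg.n_combinations + 1)]
    drug_class = {d: PATHWAY_CLASSES[i % len(PATHWAY_CLASSES)]
                  for i, d in enumerate(drugs)}
    combos = pd.DataFrame(
        {
            "combo_id": [f"{drugs[i]}|{drugs[i + 1]}" for i in range(cfg.n_combinations)],
            "drug_a": drugs[:-1],
            "drug_b": drugs[1:],
        }
    )
    combos["category"] = [
        "+".join(sorted((drug_class[a], drug_class[b])))
        for a, b in zip(combos["drug_a"], combos["drug_b"])
    ]

    features, effects = generate_feature_matrix(
        cfg, cell_lines, known_targets=list(drugs) + list(combos["combo_id"])
    )
    sa_effects = tuple(e for e in effects if e.target in drugs)
    em_effects = tuple(e for e in effects if e.target not in drugs)

    # true curve parameters per (drug, cell line); IC50 log-normal around the
    # top dose so single-agent Emax spans a wide range across lines
    curve_truth: dict[tuple[str, str], tuple[float, float]] = {}
    for di, drug in enumerate(drugs):
        for li, line in enumerate(cell_lines):
            rng = _rng(cfg.seed, _TAG_CURVE, di, li)
            ic50 = 10.0 ** rng.normal(log_center, 0.8)
            slope = rng.uniform(1.0, 2.5)
            curve_truth[(drug, line)] = (float(ic50), float(slope))

    def sa_truth(drug: str, line: str) -> np.ndarray:
        ic50, slope = curve_truth[(drug, line)]
        vec = logistic2p(doses, ic50, slope)
        for eff in sa_effects:
            if eff.target == drug and features.loc[line, eff.feature] == 1:
                vec = np.clip(vec + eff.effect, 0.0, 1.0)
        return vec

    windows: dict[tuple[str, str], SynergyWindow | None] = {}
    rows: list[dict] = []
    w = cfg.window_size
    for li, line in enumerate(cell_lines):
        plate = f"P{li + 1:04d}"
        # control wells
        ctrl = generate_plate_controls(
            cfg.n_nc0, cfg.n_nc1, cfg.n_pc, cfg.n_blank,
            cfg.control_means, cfg.control_sds,
            seed=_rng(cfg.seed, _TAG_CONTROLS, li),
        )
        for _, crow in ctrl.iterrows():
            rows.append(
                {
                    "plate": plate, "well_class": crow["well_class"],
                    "cell_line": line, "drug_a": "", "drug_b": "",
                    "dose_index_a": 0, "dose_index_b": 0,
                    "conc_a": 0.0, "conc_b": 0.0,
                    "raw_signal": crow["raw_signal"],
                }
            )
        for ci, combo in combos.iterrows():
            drug_a, drug_b, combo_id = combo["drug_a"], combo["drug_b"], combo["combo_id"]
            e_a = sa_truth(drug_a, line)
            e_b = sa_truth(drug_b, line)

            win_rng = _rng(cfg.seed, _TAG_WINDOW, ci, li)
            window = None
            if win_rng.random() < cfg.synergy_fraction:
                window = draw_synergy_window(win_rng, e_a, e_b, w, cfg.synergy_boost)
            windows[(combo_id, line)] = window
            grid = combination_truth(e_a, e_b, window)
            for eff in em_effects:
                if eff.target == combo_id and features.loc[line, eff.feature] == 1:
                    grid = np.clip(grid + eff.effect, 0.0, 1.0)

            noise_rng = _rng(cfg.seed, _TAG_WELLS, ci, li)
            if cfg.noise_sd > 0:
                grid = grid + noise_rng.normal(0.0, cfg.noise_sd, size=grid.shape)
                e_a_obs = e_a + noise_rng.normal(0.0, cfg.noise_sd, size=k)
                e_b_obs = e_b + noise_rng.normal(0.0, cfg.noise_sd, size=k)
            else:
                e_a_obs, e_b_obs = e_a, e_b

            means = dict(DEFAULT_CONTROL_MEANS, **cfg.control_means)
            for i in range(k):
                for j in range(k):
                    rows.append(
                        {
                            "plate": plate, "well_class": "COMBO",
                            "cell_line": line, "drug_a": drug_a, "drug_b": drug_b,
                            "dose_index_a": i + 1, "dose_index_b": j + 1,
                            "conc_a": doses[i], "conc_b": doses[j],
                            "raw_signal": _inhibition_to_raw(grid[i, j], means),
                        }
                    )
            for i in range(k):
                rows.append(
                    {
                        "plate": plate, "well_class": "SA_A",
                        "cell_line": line, "drug_a": drug_a, "drug_b": drug_b,
                        "dose_index_a": i + 1, "dose_index_b": 0,
                        "conc_a": doses[i], "conc_b": 0.0,
                        "raw_signal": _inhibition_to_raw(e_a_obs[i], means),
                    }
                )
                rows.append(
                    {
                        "plate": plate, "well_class": "SA_B",
                        "cell_line": line, "drug_a": drug_a, "drug_b": drug_b,
                        "dose_index_a": 0, "dose_index_b": i + 1,
                        "conc_a": 0.0, "conc_b": doses[i],
                        "raw_signal": _inhibition_to_raw(e_b_obs[i], means),
                    }
                )

    wells = pd.DataFrame(rows)
    truth = GroundTruth(
        curves=curve_truth,
        windows=windows,
        single_agent_effects=sa_effects,
        emergent_effects=em_effects,
        control_means=dict(DEFAULT_CONTROL_MEANS, **cfg.control_means),
        control_sds=dict(DEFAULT_CONTROL_SDS, **cfg.control_sds),
    )
    return Screen(
        config=cfg, wells=wells, annotations=annotations,
        combinations=combos, features=features, truth=truth,
    )
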