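"""Activity calls and activity/selectivity ranking of combination hits.

A (combination, cell line) pair is called *active* when the combination
Emax exceeds 0.5 and the HSA synergy score exceeds 0.1 (both strict),
i.e. the combination is strongly growth-inhibitory *and* beats the better
single agent by a margin.  Hits are then aggregated per cancer type and
pushed through a filter cascade that favors selectively active
combinations:

1. keep combination:cancer-type pairs with >= 10% responder cell lines;
2. drop combinations active in >= 50% of the cancer types they were
   tested in (broad activity suggests poor tolerability);
3. drop pairs tested in fewer than 10 cell lines (small-sample noise);
4. rank the survivors by responder percentage plus the cancer-type
   specificity score (equal weights), split into hematological and solid
   lists.

The specificity score is the number of tested cancer types minus the
number of types with >= 10% responders, so a combination active in few
types scores high.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "PrioritizationThresholds",
    "classify_activity",
    "activity_calls",
    "responder_rate",
    "sensitive_cancer_types",
    "specificity_score",
    "rank_hits",
    "categorize_combination",
]


@dataclass(frozen=True)
class PrioritizationThresholds:
    emax_threshold: float = 0.5
    hsa_threshold: float = 0.1
    responder_pct_min: float = 10.0  # percent; >= keeps a combination:type pair
    breadth_cap: float = 0.5  # drop combos sensitive in >= this fraction of types
    min_cell_lines: int = 10


def _round_half_up(x: float, decimals: int = 1) -> float:
    """Round-half-up (0.05 -> 0.1), matching conventionally printed percentages."""
    factor = 10.0 ** decimals
    return math.floor(x * factor + 0.5) / factor


def classify_activity(
    combo_emax: float, hsa: float,
    emax_threshold: float = 0.5, hsa_threshold: float = 0.1,
) -> bool:
    """Active iff combo Emax and HSA both *strictly* exceed their thresholds."""
    return bool(combo_emax > emax_threshold) and bool(hsa > hsa_threshold)


def activity_calls(
    synergy_table: pd.DataFrame,
    emax_threshold: float = 0.5,
    hsa_threshold: float = 0.1,
    hsa_column: str = "hsa_matrix",
) -> pd.DataFrame:
    """Vectorized activity call per (combination, cell line) row.

    ``hsa_column`` selects which HSA variant feeds the call (matrix score
    by default; the window score is a stricter local alternative).
    """
    out = synergy_table.copy()
    out["active"] = (out["combo_emax"] > emax_threshold) & (
        out[hsa_column] > hsa_threshold
    )
    return out


def responder_rate(calls: pd.DataFrame, annotations: pd.DataFrame) -> pd.DataFrame:
    """Per (combination, cancer type): n tested, n responders, responder %.

    ``calls`` needs columns ``combo_id``, ``cell_line``, ``active``;
    ``annotations`` maps every cell line to a cancer type.  Percentages
    are reported to one decimal, round-half-up.
    """
    ann = annotations.set_index("cell_line")["cancer_type"]
    unknown = set(calls["cell_line"]) - set(ann.index)
    if unknown:
        raise ValueError(f"cell lines without cancer-type label: {sorted(unknown)[:5]}")
    merged = calls.assign(cancer_type=calls["cell_line"].map(ann))
    grouped = merged.groupby(["combo_id", "cancer_type"], sort=True).agg(
        n_tested=("active", "size"), n_responders=("active", "sum")
    )
    grouped["responder_pct"] = [
        _round_half_up(100.0 * r / t) for r, t in
        zip(grouped["n_responders"], grouped["n_tested"])
    ]
    return grouped.reset_index()


def sensitive_cancer_types(
    rate_table: pd.DataFrame, responder_threshold: float = 10.0
) -> pd.Series:
    """Per combination, the number of cancer types with responder % >= threshold."""
    hit = rate_table["responder_pct"] >= responder_threshold
    return (
        rate_table.assign(hit=hit)
        .groupby("combo_id")["hit"]
        .sum()
        .astype(int)
        .rename("n_sensitive_types")
    )


def specificity_score(n_total_types: int, n_sensitive_types: int) -> int:
    """Cancer-type selectivity: total tested types minus sensitive types."""
    if not 0 <= n_sensitive_types <= n_total_types:
        raise ValueError("sensitive-type count outside [0, total]")
    return int(n_total_types) - int(n_sensitive_types)


def categorize_combination(
    targets_a: str, targets_b: str, pathway_map: dict
) -> str:
    """Unordered mechanism-pair label, e.g. ``"CD+DDR"``; symmetric in drug order."""
    try:
        cls = sorted((pathway_map[targets_a], pathway_map[targets_b]))
    except KeyError as exc:
        raise ValueError(f"drug {exc.args[0]!r} has no pathway-class mapping") from exc
    return "+".join(cls)


def rank_hits(
    rate_table: pd.DataFrame,
    annotations: pd.DataFrame,
    combo_categories: pd.DataFrame | None = None,
    thresholds: PrioritizationThresholds | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Run the filter cascade and rank surviving combination:cancer-type pairs.

    Returns ``(heme_hits, solid_hits, funnel)`` where *funnel* records the
    pair count after each filter step.  ``annotations`` must carry a
    ``group`` column labelling each cancer type ``heme`` or ``solid``;
    ``combo_categories`` optionally maps ``combo_id`` to a mechanism
    category carried through to the output.
    """
    thr = thresholds or PrioritizationThresholds()
    table = rate_table.copy()

    type_group = annotations.drop_duplicates("cancer_type").set_index("cancer_type")
    if "group" not in type_group.columns:
        raise ValueError("annotations need a heme/solid 'group' column")
    missing = set(table["cancer_type"]) - set(type_group.index)
    if missing:
        raise ValueError(f"cancer types without heme/solid group: {sorted(missing)}")

    n_tested_types = table.groupby("combo_id")["cancer_type"].nunique()
    n_sens = sensitive_cancer_types(table, thr.responder_pct_min)
    table["n_tested_types"] = table["combo_id"].map(n_tested_types)
    table["n_sensitive_types"] = table["combo_id"].map(n_sens).fillna(0).astype(int)

    funnel = {"input_pairs": int(len(table))}
    # (1) responder-rate filter on the combination:cancer-type pair
    table = table[table["responder_pct"] >= thr.responder_pct_min]
    funnel["after_responder_filter"] = int(len(table))
    # (2) breadth filter: sensitive in < 50% of tested cancer types
    frac_sens = table["n_sensitive_types"] / table["n_tested_types"]
    table = table[frac_sens < thr.breadth_cap]
    funnel["after_breadth_filter"] = int(len(table))
    # (3) minimum panel size per pair
    table = table[table["n_tested"] >= thr.min_cell_lines]
    funnel["after_min_cell_lines"] = int(len(table))

    table = table.assign(
        specificity_score=table["n_tested_types"] - table["n_sensitive_types"],
    )
    table["rank_score"] = table["responder_pct"] + table["specificity_score"]
    table["group"] = table["cancer_type"].map(type_group["group"])
    if combo_categories is not None:
        cat = combo_categories.set_index("combo_id")["category"]
        table["category"] = table["combo_id"].map(cat)
    table = table.sort_values(
        ["rank_score", "responder_pct", "combo_id"],
        ascending=[False, False, True],
    ).reset_index(drop=True)
    funnel["final_hits"] = int(len(table))

    heme = table[table["group"] == "heme"].reset_index(drop=True)
    solid = table[table["group"] == "solid"].reset_index(drop=True)
    funnel["heme_hits"] = int(len(heme))
    funnel["solid_hits"] = int(len(solid))
    return heme, solid, funnel
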