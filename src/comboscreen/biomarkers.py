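"""ANOVA biomarker discovery and emergent combination-biomarker flagging.

Binary molecular features (mutations, CNAs, methylation, binarized
expression — a MOBEM) are tested for association with five response
metrics per combination: the two single-agent Emax values, the
combination Emax and the Bliss matrix and window synergy scores.  Tests
run in three kinds of cell-line subgroup: pan-cancer (optionally with a
cancer-type covariate), per cancer type, and molecular "baskets" (all
lines carrying a given alteration, regardless of tissue).

Each test is an F-test of the feature term in an OLS model of the
response (equivalently a one-way ANOVA when there are no covariates; a
partial F-test otherwise, computed by Frisch–Waugh residualization so the
whole feature panel is vectorized).  An association is *significant* when
p <= 0.001, Benjamini–Hochberg FDR <= 10% within its (subgroup, metric)
family, and both Glass deltas (|mean difference| / per-group SD) are >= 1.

A significant combination-metric association is *emergent* when the same
feature, in the same subgroup, is not significantly associated with
either constituent drug's single-agent Emax for that combination —
i.e. it captures drug–drug interaction rather than monotherapy response.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "SignificanceThresholds",
    "Subgroup",
    "binarize_expression",
    "anova_association",
    "build_subgroups",
    "run_anova_suite",
    "flag_emergent",
]

SINGLE_AGENT_METRICS = ("emax_a", "emax_b")
COMBINATION_METRICS = ("combo_emax", "bliss_matrix", "bliss_window")
ALL_METRICS = SINGLE_AGENT_METRICS + COMBINATION_METRICS


@dataclass(frozen=True)
class SignificanceThresholds:
    p_max: float = 0.001
    fdr_max: float = 0.10
    glass_min: float = 1.0
    min_group_size: int = 3


@dataclass(frozen=True)
class Subgroup:
    """A set of cell lines tested together in one ANOVA context."""

    id: str
    kind: str  # "pan-cancer" | "cancer-type" | "basket"
    members: tuple


def binarize_expression(
    expression: pd.DataFrame, z_threshold: float = 2.0
) -> pd.DataFrame:
    """Z-score each gene within the panel and emit up/down binary features.

    ``expression`` is cell lines x genes (continuous).  A line is
    ``GENE_up`` when its within-panel Z-score is >= ``z_threshold`` and
    ``GENE_down`` when <= -``z_threshold``.  Because the Z-score is
    computed within whatever panel is passed in, the same line can be
    "up" inside a molecular basket but unremarkable pan-cancer.
    Zero-variance genes yield all-zero features.
    """
    mu = expression.mean(axis=0)
    sd = expression.std(axis=0, ddof=1)
    cols = {}
    for gene in expression.columns:
        if sd[gene] > 0:
            z = (expression[gene] - mu[gene]) / sd[gene]
        else:
            z = pd.Series(0.0, index=expression.index)
        cols[f"{gene}_up"] = (z >= z_threshold).astype(int)
        cols[f"{gene}_down"] = (z <= -z_threshold).astype(int)
    return pd.DataFrame(cols, index=expression.index)


def _glass_deltas(y: np.ndarray, f: np.ndarray) -> tuple[float, float, float]:
    """(delta_mean, glass_pos, glass_neg) for response y split by binary f."""
    pos, neg = y[f == 1], y[f == 0]
    diff = pos.mean() - neg.mean()
    out = []
    for grp in (pos, neg):
        sd = grp.std(ddof=1) if grp.size > 1 else 0.0
        if sd > 0:
            out.append(abs(diff) / sd)
        else:
            out.append(0.0 if np.isclose(diff, 0.0) else np.inf)
    return float(diff), out[0], out[1]


def anova_association(
    response: np.ndarray,
    feature: np.ndarray,
    covariates: pd.DataFrame | np.ndarray | None = None,
    min_group_size: int = 3,
) -> dict:
    """F-test of a binary feature against a response vector.

    With no covariates this is the classical one-way ANOVA (F equal to the
    square of the pooled-variance two-sample t statistic).  With
    covariates (e.g. cancer-type dummies in pan-cancer runs) the feature
    is tested by a partial F-test on top of the covariate-only model.
    Returns a dict with ``p_value``, ``f_stat``, ``delta_mean``,
    ``glass_delta_pos``, ``glass_delta_neg``, ``n_pos``, ``n_neg`` and a
    ``skipped`` reason (None when the test ran).
    """
    y = np.asarray(response, dtype=float)
    f = np.asarray(feature, dtype=float)
    n_pos, n_neg = int((f == 1).sum()), int((f == 0).sum())
    base = {"n_pos": n_pos, "n_neg": n_neg, "f_stat": np.nan, "p_value": np.nan,
            "delta_mean": np.nan, "glass_delta_pos": np.nan,
            "glass_delta_neg": np.nan, "skipped": None}
    if min(n_pos, n_neg) < min_group_size:
        base["skipped"] = f"group below minimum size {min_group_size}"
        return base

    if covariates is None:
        x_r = np.ones((y.size, 1))
    else:
        cov = np.asarray(covariates, dtype=float)
        x_r = np.column_stack([np.ones(y.size), cov])
    q, _ = np.linalg.qr(x_r)
    ry = y - q @ (q.T @ y)
    rf = f - q @ (q.T @ f)
    rss_r = float(ry @ ry)
    denom = float(rf @ rf)
    dof = y.size - x_r.shape[1] - 1
    delta_mean, g_pos, g_neg = _glass_deltas(y, f)
    base.update(delta_mean=delta_mean, glass_delta_pos=g_pos, glass_delta_neg=g_neg)
    if denom <= 1e-12 or dof <= 0:
        base["skipped"] = "feature collinear with covariates"
        return base
    beta = float(rf @ ry) / denom
    rss_f = max(rss_r - beta * beta * denom, 0.0)
    if rss_f <= 1e-300:
        # perfect fit: no residual variation to test against
        base.update(f_stat=0.0 if np.isclose(beta, 0.0) else np.inf,
                    p_value=1.0 if np.isclose(beta, 0.0) else 0.0)
        return base
    f_stat = (rss_r - rss_f) / (rss_f / dof)
    base.update(f_stat=float(f_stat), p_value=float(stats.f.sf(f_stat, 1, dof)))
    return base


def build_subgroups(
    annotations: pd.DataFrame,
    feature_matrix: pd.DataFrame | None = None,
    basket_features: tuple = (),
    min_cancer_type_size: int = 20,
    include_pan_cancer: bool = True,
) -> list[Subgroup]:
    """Pan-cancer, common-cancer-type (> ``min_cancer_type_size - 1`` lines)
    and molecular-basket subgroups from the screen annotations."""
    groups: list[Subgroup] = []
    if include_pan_cancer:
        groups.append(
            Subgroup("pan-cancer", "pan-cancer", tuple(annotations["cell_line"]))
        )
    for ct, grp in annotations.groupby("cancer_type"):
        if len(grp) >= min_cancer_type_size:
            groups.append(Subgroup(str(ct), "cancer-type", tuple(grp["cell_line"])))
    for feat in basket_features:
        if feature_matrix is None or feat not in feature_matrix.columns:
            raise ValueError(f"basket feature {feat!r} not in the feature matrix")
        members = tuple(feature_matrix.index[feature_matrix[feat] == 1])
        groups.append(Subgroup(str(feat), "basket", members))
    return groups


def run_anova_suite(
    response_table: pd.DataFrame,
    feature_matrix: pd.DataFrame,
    subgroups: list[Subgroup] | None = None,
    annotations: pd.DataFrame | None = None,
    metrics: tuple = ALL_METRICS,
    thresholds: SignificanceThresholds | None = None,
    pan_cancer_covariate: bool = True,
) -> pd.DataFrame:
    """All (feature x metric x combination x subgroup) association tests.

    ``response_table`` is one row per (combo_id, cell_line) with one
    column per response metric.  BH FDR is computed within each
    (subgroup, metric) family; an association is significant when
    p <= p_max, FDR <= fdr_max and both Glass deltas >= glass_min.
    Pan-cancer runs include cancer-type dummy covariates when
    ``pan_cancer_covariate`` is on and annotations are available.
    """
    thr = thresholds or SignificanceThresholds()
    if subgroups is None:
        if annotations is None:
            raise ValueError("need subgroups or annotations to define them")
        subgroups = build_subgroups(annotations)

    tissue = None
    if annotations is not None:
        tissue = annotations.set_index("cell_line")["cancer_type"]

    rows: list[dict] = []
    features = feature_matrix.columns
    for sub in subgroups:
        members = [m for m in sub.members if m in feature_matrix.index]
        sub_resp = response_table[response_table["cell_line"].isin(members)]
        for combo_id, combo_resp in sub_resp.groupby("combo_id"):
            lines = combo_resp["cell_line"].to_numpy()
            fmat = feature_matrix.loc[lines, features].to_numpy(dtype=float)
            covar = None
            if (
                sub.kind == "pan-cancer"
                and pan_cancer_covariate
                and tissue is not None
            ):
                covar = pd.get_dummies(tissue.loc[lines], drop_first=True).to_numpy(
                    dtype=float
                )
            for metric in metrics:
                y_all = combo_resp[metric].to_numpy(dtype=float)
                keep = ~np.isnan(y_all)
                y, fm = y_all[keep], fmat[keep]
                cv = covar[keep] if covar is not None else None
                for j, feat in enumerate(features):
                    res = anova_association(y, fm[:, j], cv, thr.min_group_size)
                    rows.append(
                        {
                            "subgroup": sub.id,
                            "subgroup_kind": sub.kind,
                            "combo_id": combo_id,
                            "metric": metric,
                            "feature": feat,
                            **res,
                        }
                    )
    table = pd.DataFrame(rows)
    if table.empty:
        return table
    table["fdr"] = np.nan
    for _, idx in table.groupby(["subgroup", "metric"]).groups.items():
        pvals = table.loc[idx, "p_value"]
        mask = pvals.notna()
        if mask.any():
            _, fdr, _, _ = multipletests(pvals[mask], method="fdr_bh")
            table.loc[pvals.index[mask], "fdr"] = fdr
    table["significant"] = (
        (table["p_value"] <= thr.p_max)
        & (table["fdr"] <= thr.fdr_max)
        & (table["glass_delta_pos"] >= thr.glass_min)
        & (table["glass_delta_neg"] >= thr.glass_min)
    ).fillna(False)
    return table


def flag_emergent(
    association_table: pd.DataFrame,
    bliss_metrics: tuple = ("bliss_matrix", "bliss_window"),
    combo_emax_metric: str = "combo_emax",
) -> tuple[pd.DataFrame, dict]:
    """Mark emergent combination biomarkers and partition them.

    A significant association of a feature with a combination metric is
    *emergent* iff that feature, in the same subgroup, is not
    significantly associated with either single-agent Emax of the same
    combination.  Returns the table with an ``emergent`` column plus a
    partition of emergent (feature, combination, subgroup) biomarkers
    into ``bliss_only``, ``both`` and ``combo_emax_only`` classes
    (disjoint, summing to the emergent total).
    """
    df = association_table.copy()
    combination_metrics = set(bliss_metrics) | {combo_emax_metric}
    present = set(df["metric"].unique())
    missing_sa = [m for m in SINGLE_AGENT_METRICS if m not in present]
    if missing_sa:
        raise ValueError(f"association table lacks single-agent metrics: {missing_sa}")

    key = ["feature", "combo_id", "subgroup"]
    sa_sig = set(
        map(
            tuple,
            df[df["metric"].isin(SINGLE_AGENT_METRICS) & df["significant"]][
                key
            ].itertuples(index=False),
        )
    )
    is_combo_metric = df["metric"].isin(combination_metrics)
    keys = list(map(tuple, df[key].itertuples(index=False)))
    df["emergent"] = (
        is_combo_metric
        & df["significant"]
        & np.array([k not in sa_sig for k in keys], dtype=bool)
    )

    emergent = df[df["emergent"]]
    partition = {"bliss_only": 0, "both": 0, "combo_emax_only": 0}
    for _, grp in emergent.groupby(key):
        has_bliss = grp["metric"].isin(bliss_metrics).any()
        has_emax = (grp["metric"] == combo_emax_metric).any()
        if has_bliss and has_emax:
            partition["both"] += 1
        elif has_bliss:
            partition["bliss_only"] += 1
        else:
            partition["combo_emax_only"] += 1
    partition["total"] = sum(
        v for k, v in partition.items() if k != "total"
    )
    return df, partition
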