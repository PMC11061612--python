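"""Plate-level quality control and replicate-consistency checks.

Each assay plate carries distributed control wells: untreated negative
controls (NC0), DMSO-treated negative controls (NC1), positive controls
treated with cytotoxic agents (PC1, PC2) and cell-free blanks (B).  A plate
passes QC when

* the coefficient of variation of the DMSO controls, CV = sigma_N / mu_N,
  is below 0.18,
* the NC0/NC1 mean ratio lies in [0.8, 1.2] (DMSO itself did not affect
  growth), and
* for every positive control the line is actually sensitive to
  (NC1/PC mean ratio >= 4), the Z-factor
  ``1 - 3*(sigma_P + sigma_N) / (mu_N - mu_P)`` is at least 0.3
  (a relaxed 0.2 is allowed for a flagged minority of lines).  Positive
  controls the line does not respond to are skipped, not failed.

Replicate cell lines screened repeatedly across the screen are used to
flag drugs with systematically inconsistent behavior.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "QCThresholds",
    "QCReport",
    "coefficient_of_variation",
    "z_factor",
    "qc_plate",
    "replicate_consistency",
]

NEGATIVE_UNTREATED = "NC0"
NEGATIVE_DMSO = "NC1"
POSITIVE_CLASSES = ("PC1", "PC2")
BLANK = "B"


@dataclass(frozen=True)
class QCThresholds:
    """Named QC cutoffs; defaults are the screen-wide values."""

    cv_max: float = 0.18
    nc_ratio_low: float = 0.8
    nc_ratio_high: float = 1.2
    z_min: float = 0.3
    z_min_relaxed: float = 0.2  # applied to lines flagged as hard to assay
    pc_sensitivity_ratio: float = 4.0  # NC1/PC mean ratio gating the Z check


@dataclass(frozen=True)
class QCReport:
    plate: str
    cv: float
    nc_ratio: float
    z_factors: dict = field(default_factory=dict)  # positive-control class -> Z
    passed: bool = True
    reasons: tuple = ()


def coefficient_of_variation(values) -> float:
    """CV = sigma_N / mu_N with the sample (n-1) standard deviation."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("CV needs at least 2 values")
    mu = x.mean()
    if np.isclose(mu, 0.0):
        raise ValueError("CV undefined for zero-mean values")
    return float(x.std(ddof=1) / mu)


def z_factor(neg_values, pos_values) -> float:
    """Assay window statistic ``1 - 3*(sigma_P + sigma_N) / (mu_N - mu_P)``.

    1 for perfectly separated noise-free controls; values above ~0.3
    indicate a usable dynamic range.  Invariant under positive affine
    transformations of the signal.
    """
    neg = np.asarray(neg_values, dtype=float)
    pos = np.asarray(pos_values, dtype=float)
    if neg.size < 2 or pos.size < 2:
        raise ValueError("Z-factor needs at least 2 values per control group")
    mu_n, mu_p = neg.mean(), pos.mean()
    if np.isclose(mu_n, mu_p):
        raise ValueError("Z-factor undefined: control means coincide")
    return float(1.0 - 3.0 * (pos.std(ddof=1) + neg.std(ddof=1)) / abs(mu_n - mu_p))


def qc_plate(
    plate_wells: pd.DataFrame,
    thresholds: QCThresholds | None = None,
    relaxed: bool = False,
) -> QCReport:
    """Apply the CV, NC-ratio and Z-factor gates to one plate's control wells.

    ``plate_wells`` needs columns ``well_class`` and ``raw_signal``; all
    four control classes (NC0, NC1, at least one PC, B) must be present.
    ``relaxed`` selects the lower Z threshold used for a small set of
    flagged cell lines.
    """
    thr = thresholds or QCThresholds()
    by_class = {
        cls: grp["raw_signal"].to_numpy(dtype=float)
        for cls, grp in plate_wells.groupby("well_class")
    }
    for required in (NEGATIVE_UNTREATED, NEGATIVE_DMSO, BLANK):
        if required not in by_class:
            raise ValueError(f"plate is missing control class {required}")
    pcs = [c for c in POSITIVE_CLASSES if c in by_class]
    if not pcs:
        raise ValueError("plate has no positive-control wells")

    nc1 = by_class[NEGATIVE_DMSO]
    nc0 = by_class[NEGATIVE_UNTREATED]
    plate_id = str(plate_wells["plate"].iloc[0]) if "plate" in plate_wells else ""

    reasons: list[str] = []
    cv = coefficient_of_variation(nc1)
    if not cv < thr.cv_max:
        reasons.append("cv")
    nc_ratio = float(nc0.mean() / nc1.mean())
    if not (thr.nc_ratio_low <= nc_ratio <= thr.nc_ratio_high):
        reasons.append("nc_ratio")

    z_min = thr.z_min_relaxed if relaxed else thr.z_min
    zs: dict[str, float] = {}
    for pc in pcs:
        pos = by_class[pc]
        if nc1.mean() / pos.mean() < thr.pc_sensitivity_ratio:
            continue  # line insensitive to this positive control: check skipped
        z = z_factor(nc1, pos)
        zs[pc] = z
        if not z >= z_min:
            reasons.append(f"z_factor:{pc}")

    return QCReport(
        plate=plate_id,
        cv=cv,
        nc_ratio=nc_ratio,
        z_factors=zs,
        passed=not reasons,
        reasons=tuple(reasons),
    )


def replicate_consistency(
    replicate_responses: pd.DataFrame,
    tolerance: float = 0.3,
) -> pd.DataFrame:
    """Flag drugs whose replicate dose responses disagree systematically.

    ``replicate_responses`` is long-format with columns ``drug``,
    ``cell_line``, ``dose_index``, ``replicate`` and ``response`` (on the
    inhibition scale).  A dose point is flagged inconsistent when the range
    across replicates exceeds ``tolerance``; a drug fails when any single
    line has two or more flagged dose points, or two or more lines each
    have a flagged point.  The per-drug mean pairwise replicate Pearson
    correlation is reported alongside.
    """
    df = replicate_responses
    required = {"drug", "cell_line", "dose_index", "replicate", "response"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    counts = df.groupby(["drug", "cell_line", "dose_index"])["replicate"].nunique()
    if (counts < 2).any():
        raise ValueError("every (drug, cell line, dose) needs >=2 replicates")

    rng = df.groupby(["drug", "cell_line", "dose_index"])["response"].agg(
        lambda v: v.max() - v.min()
    )
    flagged = (rng > tolerance).rename("flagged").reset_index()

    rows = []
    for drug, grp in flagged.groupby("drug"):
        per_line = grp.groupby("cell_line")["flagged"].sum()
        n_lines_flagged = int((per_line >= 1).sum())
        max_points_one_line = int(per_line.max()) if len(per_line) else 0
        fails = max_points_one_line >= 2 or n_lines_flagged >= 2

        wide = (
            df[df["drug"] == drug]
            .pivot_table(
                index=["cell_line", "dose_index"],
                columns="replicate",
                values="response",
            )
            .dropna()
        )
        corr = np.nan
        if wide.shape[0] >= 2 and wide.shape[1] >= 2:
            cmat = wide.corr().to_numpy()
            iu = np.triu_indices_from(cmat, k=1)
            corr = float(np.nanmean(cmat[iu]))
        rows.append(
            {
                "drug": drug,
                "n_flagged_dose_points": int(grp["flagged"].sum()),
                "n_flagged_lines": n_lines_flagged,
                "max_flagged_points_one_line": max_points_one_line,
                "replicate_correlation": corr,
                "fails_qc": fails,
            }
        )
    return pd.DataFrame(rows).set_index("drug")
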