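"""File formats: long-format well CSV, MOBEM TSV, annotations and ground truth.

The well table is a long-format CSV with one row per well.  ``well_class``
distinguishes combination wells (COMBO), the two single-agent dose ladders
measured alongside each matrix (SA_A, SA_B) and the control classes
(NC0 untreated, NC1 DMSO, PC1/PC2 positive controls, B blanks).  Dose
indices are 1-based with 1 = lowest concentration; 0 means "no dose on
this axis" (single-agent and control wells).

The MOBEM (multi-omics binary event matrix) is a TSV of cell lines x
binary features.  Orientation is auto-detected from the header sentinel:
a first column named ``cell_line`` means rows are cell lines, ``feature``
means rows are features (the file is transposed on read).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .synthetic import GroundTruth, PlantedEffect, Screen, SynergyWindow

__all__ = [
    "ScreenFormatError",
    "WELL_COLUMNS",
    "read_screen",
    "write_screen",
    "read_mobem",
    "write_mobem",
    "read_annotations",
    "write_ground_truth",
    "read_ground_truth",
]

WELL_COLUMNS = [
    "plate",
    "well",
    "well_class",
    "cell_line",
    "drug_a",
    "drug_b",
    "dose_index_a",
    "dose_index_b",
    "conc_a",
    "conc_b",
    "raw_signal",
]

WELL_CLASSES = {"COMBO", "SA_A", "SA_B", "NC0", "NC1", "PC1", "PC2", "B"}
CONTROL_CLASSES = {"NC0", "NC1", "PC1", "PC2", "B"}


class ScreenFormatError(ValueError):
    """A screen file violates the format contract."""


def _line(i: int) -> int:
    """CSV line number of data row i (1 header line, 1-based)."""
    return i + 2


def write_screen(wells: pd.DataFrame, path: str | Path) -> None:
    """Write a well table as CSV, assigning per-plate well numbers if absent."""
    df = wells.copy()
    if "well" not in df.columns:
        df["well"] = df.groupby("plate").cumcount() + 1
    df = df[WELL_COLUMNS]
    df.to_csv(path, index=False, float_format="%.10g")


def read_screen(path: str | Path, n_doses: int | None = None) -> pd.DataFrame:
    """Read and validate a long-format well CSV.

    Checks the header, well classes, dose-index bounds and consistency
    with the well class, and uniqueness of wells within a plate.  Raises
    :class:`ScreenFormatError` with the offending CSV line number.
    """
    df = pd.read_csv(path, dtype={"drug_a": str, "drug_b": str}, keep_default_na=False)
    if df.empty:
        raise ScreenFormatError(f"{path}: empty well table")
    missing = [c for c in WELL_COLUMNS if c not in df.columns]
    if missing:
        raise ScreenFormatError(f"{path}: missing columns {missing}")

    bad_class = ~df["well_class"].isin(WELL_CLASSES)
    if bad_class.any():
        i = int(np.flatnonzero(bad_class)[0])
        raise ScreenFormatError(
            f"{path}:{_line(i)}: unknown well class {df['well_class'].iat[i]!r}"
        )

    for col in ("dose_index_a", "dose_index_b"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() | (vals != vals.astype("Int64").astype(float)) | (vals < 0)
        if n_doses is not None:
            bad |= vals > n_doses
        if bad.any():
            i = int(np.flatnonzero(bad.to_numpy())[0])
            raise ScreenFormatError(
                f"{path}:{_line(i)}: bad {col} value {df[col].iat[i]!r}"
                + (f" (expected 0..{n_doses})" if n_doses is not None else "")
            )
        df[col] = vals.astype(int)

    is_combo = df["well_class"] == "COMBO"
    if (is_combo & ((df["dose_index_a"] < 1) | (df["dose_index_b"] < 1))).any():
        mask = is_combo & ((df["dose_index_a"] < 1) | (df["dose_index_b"] < 1))
        i = int(np.flatnonzero(mask.to_numpy())[0])
        raise ScreenFormatError(f"{path}:{_line(i)}: COMBO well without both doses")
    is_ctrl = df["well_class"].isin(CONTROL_CLASSES)
    if (is_ctrl & ((df["drug_a"] != "") | (df["drug_b"] != ""))).any():
        mask = is_ctrl & ((df["drug_a"] != "") | (df["drug_b"] != ""))
        i = int(np.flatnonzero(mask.to_numpy())[0])
        raise ScreenFormatError(f"{path}:{_line(i)}: control well carries drug ids")

    dup = df.duplicated(subset=["plate", "well"])
    if dup.any():
        i = int(np.flatnonzero(dup.to_numpy())[0])
        raise ScreenFormatError(f"{path}:{_line(i)}: duplicate (plate, well) key")
    dup_t = df[is_combo].duplicated(
        subset=["plate", "cell_line", "drug_a", "drug_b", "dose_index_a", "dose_index_b"]
    )
    if dup_t.any():
        i = int(df[is_combo].index[np.flatnonzero(dup_t.to_numpy())[0]])
        raise ScreenFormatError(f"{path}:{_line(i)}: duplicate combination well")
    return df


def write_mobem(features: pd.DataFrame, path: str | Path, transpose: bool = False) -> None:
    """Write a binary feature matrix as TSV (cell lines x features by default)."""
    if transpose:
        features.T.rename_axis("feature").to_csv(path, sep="\t")
    else:
        features.rename_axis("cell_line").to_csv(path, sep="\t")


def read_mobem(path: str | Path) -> pd.DataFrame:
    """Read a MOBEM TSV, auto-detecting orientation; returns cell lines x features."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    sentinel = (df.index.name or "").strip().lower()
    if sentinel == "feature":
        df = df.T
        df.index.name = "cell_line"
    elif sentinel != "cell_line":
        raise ScreenFormatError(
            f"{path}: first header field must be 'cell_line' or 'feature', "
            f"got {df.index.name!r}"
        )
    values = df.to_numpy()
    bad = ~np.isin(values, (0, 1))
    if bad.any():
        r, c = np.argwhere(bad)[0]
        raise ScreenFormatError(
            f"{path}: non-binary value {values[r, c]!r} at row {df.index[r]!r}, "
            f"column {df.columns[c]!r}"
        )
    return df.astype(int)


def read_annotations(path: str | Path) -> pd.DataFrame:
    """Cell-line annotation TSV: cell_line, cancer_type, group (heme|solid)."""
    df = pd.read_csv(path, sep="\t")
    required = {"cell_line", "cancer_type", "group"}
    missing = required - set(df.columns)
    if missing:
        raise ScreenFormatError(f"{path}: missing columns {sorted(missing)}")
    bad = ~df["group"].isin(("heme", "solid"))
    if bad.any():
        i = int(np.flatnonzero(bad.to_numpy())[0])
        raise ScreenFormatError(
            f"{path}:{_line(i)}: group must be 'heme' or 'solid'"
        )
    return df


def write_ground_truth(truth: GroundTruth, path: str | Path) -> None:
    """Serialize planted simulation parameters as a JSON sidecar."""
    payload = {
        "curves": {
            f"{drug}::{line}": [ic50, slope]
            for (drug, line), (ic50, slope) in sorted(truth.curves.items())
        },
        "windows": {
            f"{combo}::{line}": (list(win) if win is not None else None)
            for (combo, line), win in sorted(truth.windows.items())
        },
        "single_agent_effects": [list(e) for e in truth.single_agent_effects],
        "emergent_effects": [list(e) for e in truth.emergent_effects],
        "control_means": truth.control_means,
        "control_sds": truth.control_sds,
    }
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def read_ground_truth(path: str | Path) -> GroundTruth:
    payload = json.loads(Path(path).read_text())

    def split(key: str) -> tuple[str, str]:
        a, b = key.split("::")
        return a, b

    return GroundTruth(
        curves={split(k): tuple(v) for k, v in payload["curves"].items()},
        windows={
            split(k): (SynergyWindow(*v) if v is not None else None)
            for k, v in payload["windows"].items()
        },
        single_agent_effects=tuple(
            PlantedEffect(*e) for e in payload["single_agent_effects"]
        ),
        emergent_effects=tuple(
            PlantedEffect(*e) for e in payload["emergent_effects"]
        ),
        control_means=payload["control_means"],
        control_sds=payload["control_sds"],
    )


def write_screen_bundle(screen: Screen, outdir: str | Path) -> dict:
    """Write every artifact of a simulated screen; returns the path map."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "wells": out / "wells.csv",
        "annotations": out / "annotations.tsv",
        "combinations": out / "combinations.tsv",
        "mobem": out / "mobem.tsv",
        "ground_truth": out / "ground_truth.json",
    }
    write_screen(screen.wells, paths["wells"])
    screen.annotations.to_csv(paths["annotations"], sep="\t", index=False)
    screen.combinations.to_csv(paths["combinations"], sep="\t", index=False)
    write_mobem(screen.features, paths["mobem"])
    write_ground_truth(screen.truth, paths["ground_truth"])
    return {k: str(v) for k, v in paths.items()}
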