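"""Bliss and HSA synergy scoring for dose-combination matrices.

Two null models of drug independence are supported.  Bliss independence
treats the two single-agent inhibitions ``E_A`` and ``E_B`` as probabilities
and expects the combination to achieve ``E_A + E_B - E_A*E_B``; Highest
Single Agent (HSA) expects only ``max(E_A, E_B)``.  The per-well *excess*
over the null expectation is positive where the combination does better
than independence predicts.

Excess grids are summarized in two ways:

* **matrix score** — the mean excess over every well of the k x k matrix
  (a global view; localized synergy can be diluted or even cancelled out),
* **window score** — the maximum over all contiguous w x w sub-matrices
  (default 3 x 3) of the within-window mean excess (a local view that picks
  up concentration-dependent synergy).

On a 7 x 7 matrix there are 25 possible 3 x 3 windows; on a 5 x 5 trimmed
matrix there are 9.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .response import CombinationMatrix, combo_emax

__all__ = [
    "SynergyResult",
    "bliss_expected",
    "hsa_expected",
    "per_well_excess",
    "matrix_score",
    "window_score",
    "synergy_summary",
]


@dataclass(frozen=True)
class SynergyResult:
    """Per (combination, cell line) synergy record."""

    bliss_matrix: float
    bliss_window: float
    hsa_matrix: float
    hsa_window: float
    bliss_window_loc: tuple[int, int]
    hsa_window_loc: tuple[int, int]
    combo_emax: float


def _clip01(x: np.ndarray) -> np.ndarray:
    return np.clip(np.asarray(x, dtype=float), 0.0, 1.0)


def bliss_expected(e_a, e_b):
    """Expected inhibition under Bliss independence, ``E_A + E_B - E_A*E_B``.

    Inputs are clipped to [0, 1] so they can be read as probabilities;
    the operation is symmetric, has 0 as identity and 1 as absorbing
    element, and broadcasts like ``numpy`` arithmetic.
    """
    a = _clip01(e_a)
    b = _clip01(e_b)
    return a + b - a * b


def hsa_expected(e_a, e_b):
    """Expected inhibition under the Highest-Single-Agent null, ``max(E_A, E_B)``."""
    return np.maximum(_clip01(e_a), _clip01(e_b))


def per_well_excess(
    matrix: np.ndarray,
    marginals_a: np.ndarray,
    marginals_b: np.ndarray,
    model: str = "bliss",
) -> np.ndarray:
    """Observed minus expected inhibition for every combination well.

    Parameters
    ----------
    matrix
        k x k grid of combination inhibitions; rows indexed by drug-A dose,
        columns by drug-B dose, both ascending.  Clipped to [0, 1]
        internally (probability semantics).
    marginals_a, marginals_b
        Length-k single-agent inhibition vectors for drugs A and B.
    model
        ``"bliss"`` or ``"hsa"``.
    """
    grid = _clip01(matrix)
    a = _clip01(marginals_a)
    b = _clip01(marginals_b)
    if grid.ndim != 2 or grid.shape != (a.size, b.size):
        raise ValueError(
            f"matrix shape {grid.shape} does not match marginals ({a.size}, {b.size})"
        )
    if model == "bliss":
        expected = bliss_expected(a[:, None], b[None, :])
    elif model == "hsa":
        expected = hsa_expected(a[:, None], b[None, :])
    else:
        raise ValueError(f"unknown synergy model {model!r}")
    return grid - expected


def matrix_score(excess_grid: np.ndarray, aggregate: str = "mean") -> float:
    """Matrix-level synergy score of an excess grid.

    ``aggregate="mean"`` (default) averages the excess over all wells;
    ``aggregate="max"`` reports the single highest per-well excess instead.
    The mean is the primary definition: it allows the characteristic
    pattern of a negative matrix score together with a positive window
    score when synergy is confined to a corner of the dose grid.
    """
    grid = np.asarray(excess_grid, dtype=float)
    if grid.size == 0:
        raise ValueError("empty excess grid")
    if aggregate == "mean":
        return float(grid.mean())
    if aggregate == "max":
        return float(grid.max())
    raise ValueError(f"unknown aggregate {aggregate!r}")


def window_score(
    excess_grid: np.ndarray, window_size: int = 3
) -> tuple[float, tuple[int, int]]:
    """Best sliding-window synergy score and its location.

    Returns ``(score, (row, col))`` where *score* is the maximum over all
    contiguous ``window_size`` x ``window_size`` sub-matrices of the
    within-window mean excess and *(row, col)* is the 0-based top-left
    corner of the winning window.  Ties are broken row-major (smallest
    row, then smallest column).
    """
    grid = np.asarray(excess_grid, dtype=float)
    k_r, k_c = grid.shape
    w = int(window_size)
    if w < 1 or w > k_r or w > k_c:
        raise ValueError(f"window size {w} does not fit a {k_r}x{k_c} grid")
    # grids are tiny (k <= 7): evaluate every window directly, which also
    # keeps exact ties exact for the row-major tie-break
    windows = np.lib.stride_tricks.sliding_window_view(grid, (w, w))
    means = windows.mean(axis=(2, 3))
    flat = int(np.argmax(means))  # argmax is row-major first occurrence
    loc = np.unravel_index(flat, means.shape)
    return float(means[loc]), (int(loc[0]), int(loc[1]))


def synergy_summary(
    matrix: CombinationMatrix | np.ndarray,
    marginals_a: np.ndarray,
    marginals_b: np.ndarray,
    window_size: int = 3,
    matrix_aggregate: str = "mean",
) -> SynergyResult:
    """Compute the full Bliss/HSA matrix- and window-score record for one pair."""
    grid = matrix.grid if isinstance(matrix, CombinationMatrix) else np.asarray(matrix)
    bliss = per_well_excess(grid, marginals_a, marginals_b, model="bliss")
    hsa = per_well_excess(grid, marginals_a, marginals_b, model="hsa")
    b_win, b_loc = window_score(bliss, window_size)
    h_win, h_loc = window_score(hsa, window_size)
    return SynergyResult(
        bliss_matrix=matrix_score(bliss, matrix_aggregate),
        bliss_window=b_win,
        hsa_matrix=matrix_score(hsa, matrix_aggregate),
        hsa_window=h_win,
        bliss_window_loc=b_loc,
        hsa_window_loc=h_loc,
        combo_emax=combo_emax(grid),
    )
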