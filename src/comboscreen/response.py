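"""Signal normalization, two-parameter logistic fitting and Emax extraction.

Raw viability signal (e.g. CellTiter-Glo luminescence) is normalized to a
growth-inhibition scale anchored at the plate's own controls: 0 at the mean
of the DMSO negative-control wells (full growth) and 1 at the mean of the
blank, media-only wells (no cells).  Single-agent dose responses on this
scale are fitted to a two-parameter logistic

    f(d) = 1 / (1 + (IC50 / d) ** slope)

with asymptotes fixed at 0 and 1; the fitted value at the highest screened
dose is the single-agent Emax.  Combination wells are normalized but never
fitted; the combination Emax is the *second* highest well of the dose
matrix, an outlier-robust maximum effect.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "CombinationMatrix",
    "CurveFit",
    "normalize_inhibition",
    "logistic2p",
    "fit_logistic2p",
    "combo_emax",
    "trim_matrix",
]


@dataclass(frozen=True)
class CombinationMatrix:
    """A k x k grid of normalized inhibitions for one drug pair on one cell line.

    Rows are indexed by drug-A dose and columns by drug-B dose, both
    strictly ascending (index 0 = lowest concentration).
    """

    drug_a: str
    drug_b: str
    conc_a: np.ndarray
    conc_b: np.ndarray
    grid: np.ndarray
    cell_line: str = ""
    plate: str = ""

    def __post_init__(self) -> None:
        conc_a = np.asarray(self.conc_a, dtype=float)
        conc_b = np.asarray(self.conc_b, dtype=float)
        grid = np.asarray(self.grid, dtype=float)
        object.__setattr__(self, "conc_a", conc_a)
        object.__setattr__(self, "conc_b", conc_b)
        object.__setattr__(self, "grid", grid)
        if grid.shape != (conc_a.size, conc_b.size):
            raise ValueError(
                f"grid shape {grid.shape} does not match concentration axes "
                f"({conc_a.size}, {conc_b.size})"
            )
        for name, conc in (("conc_a", conc_a), ("conc_b", conc_b)):
            if np.any(np.diff(conc) <= 0):
                raise ValueError(f"{name} must be strictly increasing")


@dataclass(frozen=True)
class CurveFit:
    """Result of a two-parameter logistic fit to a single-agent dose response."""

    ic50: float
    slope: float
    emax: float
    rmse: float
    converged: bool
    censored: str | None = None  # "right"/"left" when IC50 falls outside the dose range
    doses: np.ndarray = field(default=None, repr=False, compare=False)


def normalize_inhibition(raw, mean_nc1: float, mean_blank: float):
    """Map raw signal to the inhibition scale: 0 at DMSO mean, 1 at blank mean.

    ``inhibition = (mean_nc1 - raw) / (mean_nc1 - mean_blank)``.  Values are
    deliberately *not* clipped here: inhibitions slightly below 0 or above 1
    carry information about noise and control placement and are preserved
    in outputs; clipping to [0, 1] happens only where a probability reading
    is required (logistic fitting, Bliss/HSA excess).
    """
    if np.isclose(mean_nc1, mean_blank):
        raise ValueError("degenerate normalization: NC-1 and blank means coincide")
    return (mean_nc1 - np.asarray(raw, dtype=float)) / (mean_nc1 - mean_blank)


def logistic2p(dose, ic50: float, slope: float):
    """Two-parameter logistic ``1 / (1 + (ic50/d)^slope)`` with asymptotes 0 and 1."""
    d = np.asarray(dose, dtype=float)
    # evaluate in log space for numerical stability at extreme ratios
    z = slope * (np.log(d) - np.log(ic50))
    return 1.0 / (1.0 + np.exp(-z))


_SLOPE_BOUNDS = (0.05, 20.0)


def fit_logistic2p(doses, inhibition) -> CurveFit:
    """Least-squares two-parameter logistic fit of a single-agent response.

    Inhibition values are clipped to [0, 1] for fitting.  The optimizer is
    restarted from a log-spaced grid of IC50 candidates spanning the dose
    range (plus a decade either side) to avoid local minima; the best
    solution by residual sum of squares wins.  IC50 estimates outside the
    tested dose range are reported with a censoring flag ("left"/"right")
    rather than trusted as free extrapolations.  If no start converges the
    fit is marked unconverged and Emax falls back to the observed value at
    the highest dose.
    """
    d = np.asarray(doses, dtype=float)
    y = np.clip(np.asarray(inhibition, dtype=float), 0.0, 1.0)
    if d.ndim != 1 or d.size < 4:
        raise ValueError("need at least 4 dose points to fit a logistic")
    if d.size != y.size:
        raise ValueError("doses and inhibition must have equal length")
    if np.any(d <= 0) or np.any(np.diff(d) <= 0):
        raise ValueError("doses must be positive and strictly increasing")

    log_d = np.log(d)
    lo, hi = log_d[0] - np.log(10.0), log_d[-1] + np.log(10.0)

    def residuals(theta):
        log_ic50, log_slope = theta
        z = np.exp(log_slope) * (log_d - log_ic50)
        return 1.0 / (1.0 + np.exp(-z)) - y

    # coarse vectorized grid search over (log IC50, log slope), then one
    # local refinement from the best grid point (plus a fallback start)
    g_ic = np.linspace(lo, hi, 25)
    g_sl = np.log(np.array([0.3, 0.5, 0.8, 1.2, 1.8, 2.7, 4.0]))
    z = np.exp(g_sl)[None, :, None] * (log_d[None, None, :] - g_ic[:, None, None])
    sse = (((1.0 / (1.0 + np.exp(-z))) - y) ** 2).sum(axis=-1)
    i, j = np.unravel_index(np.argmin(sse), sse.shape)
    starts = [(g_ic[i], g_sl[j]), (0.5 * (lo + hi), 0.0)]
    best = None
    for theta0 in starts:
        try:
            res = least_squares(
                residuals,
                theta0,
                bounds=(
                    [lo, np.log(_SLOPE_BOUNDS[0])],
                    [hi, np.log(_SLOPE_BOUNDS[1])],
                ),
                method="trf",
            )
        except Exception:  # pragma: no cover - defensive
            continue
        if res.success and (best is None or res.cost < best.cost):
            best = res
        if best is not None and 2.0 * best.cost <= sse[i, j] + 1e-12:
            break  # refinement from the grid optimum succeeded; skip fallback

    if best is None:
        return CurveFit(
            ic50=float(np.exp(hi)),
            slope=1.0,
            emax=float(y[-1]),
            rmse=float("nan"),
            converged=False,
            censored="right",
            doses=d,
        )

    ic50 = float(np.exp(best.x[0]))
    slope = float(np.exp(best.x[1]))
    emax = float(logistic2p(d[-1], ic50, slope))
    rmse = float(np.sqrt(np.mean(residuals(best.x) ** 2)))
    censored = None
    if ic50 > d[-1]:
        censored = "right"
    elif ic50 < d[0]:
        censored = "left"
    return CurveFit(
        ic50=ic50, slope=slope, emax=emax, rmse=rmse, converged=True,
        censored=censored, doses=d,
    )


def combo_emax(matrix) -> float:
    """Second-highest inhibition across all wells of a combination matrix.

    Duplicated values count separately, so an all-constant matrix returns
    that constant.  Using the second order statistic guards the maximum
    effect estimate against a single outlying well.
    """
    grid = matrix.grid if isinstance(matrix, CombinationMatrix) else np.asarray(matrix)
    flat = np.asarray(grid, dtype=float).ravel()
    if flat.size < 2:
        raise ValueError("combo Emax needs at least 2 wells")
    two = np.partition(flat, flat.size - 2)
    return float(two[flat.size - 2])


def trim_matrix(matrix: CombinationMatrix, n_remove_per_axis: int) -> CombinationMatrix:
    """Drop the ``n_remove_per_axis`` highest doses from both axes.

    Used where the top concentrations of a drug are beyond the biologically
    relevant range (e.g. reducing a 7x7 matrix to 5x5); concentration axes
    and the grid stay consistent.
    """
    n = int(n_remove_per_axis)
    k = matrix.grid.shape[0]
    if n < 0 or n >= k:
        raise ValueError(f"cannot remove {n} doses from a {k}-dose axis")
    if n == 0:
        return matrix
    return replace(
        matrix,
        conc_a=matrix.conc_a[:-n],
        conc_b=matrix.conc_b[:-n],
        grid=matrix.grid[:-n, :-n],
    )
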