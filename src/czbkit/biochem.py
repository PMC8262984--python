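"""Quantitative binding/dose-response models.

* Hill dose-response with the coefficient fixed (default 2) for oxidant
  titrations; only the monotone rising limb below a dose cutoff (default
  500 uM) is fitted, since higher doses overoxidize the reporter adduct.
* A two-state tight-binding (ligand-depletion) quadratic for chelator
  titrations: y = y_min + dy with
  dy = 0.5 * [(dy_max + L0 + K_D) - sqrt((dy_max + L0 + K_D)^2 - 4 dy_max L0)],
  dy_max = y_max - y_min.
* A straight-line inhibition model for stoichiometric zinc titrations.
* Relative-biofilm normalization against the untreated wild type of the
  same experiment, and a paired two-sided t test.

All fits minimize unweighted squared residuals; nonlinear fits use a
multistart grid with K initialized at each observed dose.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .iolib import DoseResponseDataset

DEFAULT_MAX_DOSE = 500.0


class FitError(RuntimeError):
    """Raised when a nonlinear fit fails to converge from any start."""


@dataclass
class HillFit:
    K_half: float
    n: float
    A: float
    residual_ss: float
    converged: bool = True
    n_starts: int = 0

    def __post_init__(self) -> None:
        if self.K_half <= 0 or self.A <= 0:
            raise FitError(f"invalid Hill parameters K={self.K_half}, A={self.A}")


@dataclass
class TightBindingFit:
    y_min: float
    y_max: float
    K_D: float
    residual_ss: float
    half_max_L: float = field(default=np.nan)
    converged: bool = True

    def __post_init__(self) -> None:
        if self.y_max < self.y_min or self.K_D <= 0:
            raise FitError(
                f"invalid two-state parameters y_min={self.y_min}, "
                f"y_max={self.y_max}, K_D={self.K_D}"
            )


@dataclass
class LinearInhibitionFit:
    intercept: float
    slope: float
    x_zero: float  # NaN when slope >= 0
    residual_ss: float


# ---------------------------------------------------------------------------
# Hill
# ---------------------------------------------------------------------------

def hill_response(L, K_half: float, n: float = 2.0, A: float = 1.0):
    """A * L^n / (K_half^n + L^n); vectorized over L."""
    if K_half <= 0:
        raise ValueError("K_half must be > 0")
    L = np.asarray(L, dtype=float)
    if np.any(L < 0):
        raise ValueError("doses must be >= 0")
    out = A * L**n / (K_half**n + L**n)
    return out if out.ndim else float(out)


def fit_hill(
    dataset: DoseResponseDataset,
    n_fixed: float = 2.0,
    max_dose: float | None = DEFAULT_MAX_DOSE,
) -> HillFit:
    """Least-squares (K_half, A) with the Hill coefficient held fixed.

    Doses above ``max_dose`` are excluded (rising limb only).  K_half is
    multistarted at every retained positive dose.
    """
    dose, resp = dataset.flat()
    if max_dose is not None:
        keep = dose <= max_dose
        dose, resp = dose[keep], resp[keep]
    if len(np.unique(dose)) < 3:
        raise FitError("need >= 3 distinct doses on the rising limb")

    def residuals(params):
        k, a = params
        if k <= 0 or a <= 0:
            return np.full_like(resp, 1e6)
        return hill_response(dose, k, n_fixed, a) - resp

    a0 = max(resp.max(), 1e-9)
    best = None
    starts = sorted({d for d in dose if d > 0} | {np.median(dose[dose > 0])})
    for k0 in starts:
        sol = optimize.least_squares(
            residuals, x0=[k0, a0], method="lm", max_nfev=10000
        )
        ss = float(np.sum(sol.fun**2))
        if sol.x[0] > 0 and sol.x[1] > 0 and (best is None or ss < best[0]):
            best = (ss, sol)
    if best is None:
        raise FitError("Hill fit did not converge from any start")
    ss, sol = best
    return HillFit(
        K_half=float(sol.x[0]), n=float(n_fixed), A=float(sol.x[1]),
        residual_ss=ss, converged=bool(sol.success), n_starts=len(starts),
    )


# ---------------------------------------------------------------------------
# Two-state tight binding
# ---------------------------------------------------------------------------

def tight_binding_y(L0, K_D: float, y_min: float, y_max: float):
    """Closed-form two-state (ligand depletion) signal at total ligand L0.

    Strictly increasing in L0 and bounded by [y_min, y_max].
    """
    if K_D <= 0:
        raise ValueError("K_D must be > 0")
    if y_max < y_min:
        raise ValueError("y_max must be >= y_min")
    L0 = np.asarray(L0, dtype=float)
    if np.any(L0 < 0):
        raise ValueError("L0 must be >= 0")
    dy_max = y_max - y_min
    s = dy_max + L0 + K_D
    disc = s * s - 4.0 * dy_max * L0
    if np.any(disc < -1e-12 * np.maximum(s * s, 1.0)):
        raise ArithmeticError("negative discriminant in tight-binding form")
    dy = 0.5 * (s - np.sqrt(np.maximum(disc, 0.0)))
    out = y_min + dy
    return out if out.ndim else float(out)


def half_maximal_ligand(K_D: float, y_min: float, y_max: float) -> float:
    """Total ligand at which y = (y_min + y_max)/2, solved numerically."""
    dy_max = y_max - y_min
    if dy_max == 0:
        return np.nan
    target = y_min + dy_max / 2.0
    f = lambda L: tight_binding_y(L, K_D, y_min, y_max) - target
    hi = K_D + dy_max
    while f(hi) < 0:
        hi *= 2.0
    return float(optimize.brentq(f, 0.0, hi, xtol=1e-12 * max(hi, 1.0)))


def fit_two_state(dataset: DoseResponseDataset) -> TightBindingFit:
    """Least squares over (y_min, y_max, K_D), multistarted on K_D."""
    dose, resp = dataset.flat()
    if len(np.unique(dose)) < 4:
        raise FitError("need >= 4 distinct doses for the two-state fit")

    def residuals(params):
        ymin, ymax, kd = params
        if kd <= 0 or ymax < ymin:
            return np.full_like(resp, 1e6)
        return tight_binding_y(dose, kd, ymin, ymax) - resp

    y0min, y0max = float(resp.min()), float(resp.max())
    best = None
    starts = sorted({d for d in dose if d > 0})
    for k0 in starts:
        sol = optimize.least_squares(
            residuals, x0=[y0min, y0max, k0], method="lm", max_nfev=20000
        )
        ymin, ymax, kd = sol.x
        if kd <= 0 or ymax < ymin:
            continue
        ss = float(np.sum(sol.fun**2))
        if best is None or ss < best[0]:
            best = (ss, sol)
    if best is None:
        raise FitError("two-state fit did not converge from any start")
    ss, sol = best
    ymin, ymax, kd = map(float, sol.x)
    return TightBindingFit(
        y_min=ymin, y_max=ymax, K_D=kd, residual_ss=ss,
        half_max_L=half_maximal_ligand(kd, ymin, ymax),
        converged=bool(sol.success),
    )


# ---------------------------------------------------------------------------
# Linear inhibition
# ---------------------------------------------------------------------------

def fit_linear_inhibition(dataset: DoseResponseDataset) -> LinearInhibitionFit:
    """Ordinary least-squares line with one truncation pass.

    After the first fit, points whose fitted value is negative are dropped
    and the line is refit once; x_zero = -intercept/slope when the slope
    is negative, NaN (with a warning) otherwise.
    """
    dose, resp = dataset.flat()
    if len(np.unique(dose)) < 3:
        raise FitError("need >= 3 distinct doses")
    slope, intercept = np.polyfit(dose, resp, 1)
    fitted = intercept + slope * dose
    keep = fitted >= 0
    if keep.sum() >= 3 and not keep.all():
        slope, intercept = np.polyfit(dose[keep], resp[keep], 1)
        dose, resp = dose[keep], resp[keep]
    ss = float(np.sum((intercept + slope * dose - resp) ** 2))
    if slope >= 0:
        warnings.warn("non-negative slope: not an inhibitor; x_zero undefined")
        x_zero = float("nan")
    else:
        x_zero = -intercept / slope
    return LinearInhibitionFit(float(intercept), float(slope), float(x_zero), ss)


# ---------------------------------------------------------------------------
# Biofilm normalization and paired comparison
# ---------------------------------------------------------------------------

BIOFILM_COLUMNS = ["experiment", "strain", "treatment", "dose", "a562"]


def relative_biofilm(
    table: pd.DataFrame,
    reference_strain: str = "WT",
    reference_treatment: str = "untreated",
) -> pd.DataFrame:
    """Divide each A562 by the mean untreated wild-type A562 of the same
    experiment; the untreated wild-type rows therefore average to 1.0.

    ``table`` is long format with columns experiment, strain, treatment,
    dose, a562.
    """
    missing = set(BIOFILM_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"biofilm table missing columns {sorted(missing)}")
    out = table.copy()
    out["relative_biofilm"] = np.nan
    for exp, grp in table.groupby("experiment"):
        ref = grp[
            (grp["strain"] == reference_strain)
            & (grp["treatment"] == reference_treatment)
        ]
        if ref.empty:
            raise ValueError(
                f"experiment {exp!r}: no untreated {reference_strain} reference rows"
            )
        ref_mean = ref["a562"].mean()
        if ref_mean == 0:
            raise ValueError(f"experiment {exp!r}: reference mean is zero")
        out.loc[grp.index, "relative_biofilm"] = grp["a562"] / ref_mean
    return out


def paired_t(treated, control) -> tuple[float, float]:
    """Two-sided paired t test on the differences.

    Zero-variance differences: all-zero -> (0, 1); constant nonzero ->
    (signed inf, 0) sentinel.
    """
    treated = np.asarray(treated, dtype=float)
    control = np.asarray(control, dtype=float)
    if treated.shape != control.shape or treated.ndim != 1 or len(treated) < 2:
        raise ValueError("need equal-length paired vectors with n >= 2")
    diff = treated - control
    if np.allclose(np.std(diff), 0.0):
        if np.allclose(diff, 0.0):
            return 0.0, 1.0
        return float(np.sign(diff.mean()) * np.inf), 0.0
    res = stats.ttest_rel(treated, control)
    return float(res.statistic), float(res.pvalue)
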