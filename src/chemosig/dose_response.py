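"""Viability normalisation, IC50 estimation and resistance-degree calls.

A fluorescence viability plate (resazurin-style readout: viable cells reduce
the dye to a fluorescent product) is normalised against vehicle-control and
blank wells, the 50%-inhibition concentration is located on the dose-response
curve, and paired parental/derivative cell lines are compared through the
degree of resistance IC50(derivative) / IC50(parental).

Two IC50 estimators are provided:

* ``interpolation`` (default) — locate the adjacent dose pair whose mean
  viabilities bracket 0.5 and interpolate linearly on the log10-dose axis.
  Assumption-free apart from local log-linearity; censored when the curve
  never crosses 50%.
* ``four_parameter_logistic`` — least-squares fit of
  ``v(c) = bottom + (top - bottom) / (1 + (c / ic50)^h)`` with the IC50
  reported at the fitted midpoint; falls back to interpolation (flagged in
  the diagnostics) if the optimiser does not converge.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
from scipy.optimize import curve_fit

from .defaults import RESISTANCE_LOWER, RESISTANCE_UPPER
from .exceptions import DataError, ValidationError

__all__ = [
    "DoseResponseDataset",
    "ViabilityCurve",
    "IC50Estimate",
    "ResistanceComparison",
    "normalize_viability",
    "estimate_ic50",
    "degree_of_resistance",
    "classify_resistance",
]


@dataclass
class DoseResponseDataset:
    """Raw fluorescence readouts for one cell line on one plate.

    ``treated`` has shape (n_doses, n_replicates); ``controls`` and
    ``blanks`` are replicate vectors of vehicle-control and cell-free wells.
    ``n_clamped`` counts simulated readouts clamped at zero fluorescence.
    """

    cell_line: str
    doses: np.ndarray
    treated: np.ndarray
    controls: np.ndarray
    blanks: np.ndarray
    n_clamped: int = 0

    def __post_init__(self) -> None:
        self.doses = np.asarray(self.doses, dtype=float)
        self.treated = np.atleast_2d(np.asarray(self.treated, dtype=float))
        self.controls = np.asarray(self.controls, dtype=float)
        self.blanks = np.asarray(self.blanks, dtype=float)
        if len(np.unique(self.doses)) < 4:
            raise ValidationError("doses: need at least 4 distinct concentrations")
        for name, arr in (("doses", self.doses), ("treated", self.treated),
                          ("controls", self.controls), ("blanks", self.blanks)):
            if not np.all(np.isfinite(arr)):
                raise ValidationError(f"{name}: non-finite values")
            if np.any(arr < 0):
                raise ValidationError(f"{name}: negative values")
        if self.treated.shape[0] != self.doses.size:
            raise ValidationError("treated: row count must match number of doses")
        if self.controls.mean() <= self.blanks.mean():
            raise DataError(
                f"assay failure for {self.cell_line}: mean control "
                f"({self.controls.mean():.3g}) not above mean blank "
                f"({self.blanks.mean():.3g})"
            )


@dataclass
class ViabilityCurve:
    """Per-dose fraction-viable summary of a plate."""

    doses: np.ndarray
    mean_viability: np.ndarray
    sd_viability: np.ndarray
    n_per_dose: np.ndarray
    cell_line: str = ""

    def __post_init__(self) -> None:
        self.doses = np.asarray(self.doses, dtype=float)
        self.mean_viability = np.asarray(self.mean_viability, dtype=float)
        self.sd_viability = np.asarray(self.sd_viability, dtype=float)
        self.n_per_dose = np.asarray(self.n_per_dose, dtype=int)
        n = self.doses.size
        if not (self.mean_viability.size == self.sd_viability.size
                == self.n_per_dose.size == n):
            raise ValidationError("viability curve: unequal field lengths")


@dataclass
class IC50Estimate:
    """IC50 in the dose units, possibly censored outside the tested range."""

    value: float
    censor: str  # "none" | "above_max" | "below_min"
    method: str  # "interpolation" | "four_parameter_logistic"
    fit_diagnostics: dict | None = None

    @property
    def is_censored(self) -> bool:
        return self.censor != "none"


@dataclass
class ResistanceComparison:
    """Degree of resistance of a derivative line relative to its parental line."""

    parental: str
    derivative: str
    ic50_parental: float
    ic50_derivative: float
    degree_of_resistance: float  # reported ratio, rounded half-up to 2 decimals
    call: str  # "cross_resistant" | "unchanged" | "collateral_sensitive"


def normalize_viability(ds: DoseResponseDataset) -> ViabilityCurve:
    """Blank-subtract and control-scale a plate into fraction viability.

    viability(dose) = (mean treated - mean blank) / (mean control - mean blank).
    The replicate SD of treated wells is scaled by the same denominator, so
    the curve's error bars are on the viability scale.
    """
    span = ds.controls.mean() - ds.blanks.mean()
    mean_v = (ds.treated.mean(axis=1) - ds.blanks.mean()) / span
    ddof = 1 if ds.treated.shape[1] > 1 else 0
    sd_v = ds.treated.std(axis=1, ddof=ddof) / span
    n = np.full(ds.doses.size, ds.treated.shape[1])
    return ViabilityCurve(ds.doses, mean_v, sd_v, n, cell_line=ds.cell_line)


def _interpolate_ic50(doses: np.ndarray, v: np.ndarray) -> IC50Estimate:
    diff = v - 0.5
    for i in range(diff.size - 1):
        if diff[i] == 0.0:
            return IC50Estimate(float(doses[i]), "none", "interpolation")
        if diff[i] * diff[i + 1] < 0.0:
            lo, hi = math.log10(doses[i]), math.log10(doses[i + 1])
            t = (0.5 - v[i]) / (v[i + 1] - v[i])
            return IC50Estimate(10.0 ** (lo + t * (hi - lo)), "none", "interpolation")
    if diff[-1] == 0.0:
        return IC50Estimate(float(doses[-1]), "none", "interpolation")
    censor = "above_max" if np.all(v > 0.5) else "below_min"
    return IC50Estimate(float("nan"), censor, "interpolation")


def _logistic(c, top, bottom, ic50, h):
    return bottom + (top - bottom) / (1.0 + (c / ic50) ** h)


def _fit_4pl(doses: np.ndarray, v: np.ndarray) -> IC50Estimate:
    interp = _interpolate_ic50(doses, v)
    ic50_guess = interp.value if not interp.is_censored else float(
        np.exp(np.mean(np.log(doses))))
    p0 = (float(max(v.max(), 0.9)), float(min(v.min(), 0.1)), ic50_guess, 1.0)
    bounds = ([0.3, -1.0, 1e-12, 0.05], [3.0, 0.7, 1e12, 20.0])
    try:
        popt, _ = curve_fit(_logistic, doses, v, p0=p0, bounds=bounds,
                            maxfev=20000)
        top, bottom, ic50, h = (float(x) for x in popt)
        if not np.isfinite(ic50) or ic50 <= 0:
            raise RuntimeError("non-finite IC50")
    except Exception as exc:  # optimiser failure -> interpolation fallback
        fallback = _interpolate_ic50(doses, v)
        fallback.fit_diagnostics = {
            "converged": False,
            "fallback_to_interpolation": True,
            "warning": f"4PL fit failed ({exc}); interpolated instead",
        }
        return fallback
    resid = v - _logistic(doses, *popt)
    diag = {
        "converged": True,
        "fallback_to_interpolation": False,
        "top": top, "bottom": bottom, "hill_slope": h,
        "rmse": float(np.sqrt(np.mean(resid ** 2))),
        "max_abs_residual": float(np.max(np.abs(resid))),
    }
    return IC50Estimate(ic50, "none", "four_parameter_logistic", diag)


def estimate_ic50(curve: ViabilityCurve, method: str = "interpolation") -> IC50Estimate:
    """Estimate the 50%-inhibition concentration from a viability curve.

    With ``interpolation`` the lowest-dose crossing of mean viability 0.5 is
    located and interpolated on the log10-dose axis; a curve entirely above
    (below) 0.5 is censored ``above_max`` (``below_min``). With
    ``four_parameter_logistic`` the IC50 is the fitted curve midpoint.
    """
    if method not in ("interpolation", "four_parameter_logistic"):
        raise ValidationError(f"method: unknown IC50 method {method!r}")
    if curve.doses.size < 4:
        raise ValidationError("doses: need at least 4 doses to estimate an IC50")
    if not np.all(np.isfinite(curve.mean_viability)):
        raise DataError("mean_viability: non-finite values")
    order = np.argsort(curve.doses)
    doses = curve.doses[order]
    v = curve.mean_viability[order]
    if method == "interpolation":
        return _interpolate_ic50(doses, v)
    return _fit_4pl(doses, v)


def _round_half_up(x: float, places: int = 2) -> float:
    return float(Decimal(repr(x)).quantize(Decimal(10) ** -places, ROUND_HALF_UP))


def classify_resistance(dr: float,
                        lower: float = RESISTANCE_LOWER,
                        upper: float = RESISTANCE_UPPER) -> str:
    """Map a degree-of-resistance ratio to a qualitative call.

    ``dr <= lower`` is collateral sensitivity (the derivative line is markedly
    MORE sensitive than its parent), ``dr >= upper`` cross-resistance,
    anything in between unchanged.
    """
    if not (lower < 1.0 < upper):
        raise ValidationError(
            f"thresholds: need lower < 1 < upper, got ({lower}, {upper})")
    if not (np.isfinite(dr) and dr > 0):
        raise ValidationError(f"dr: ratio must be positive and finite, got {dr}")
    if dr <= lower:
        return "collateral_sensitive"
    if dr >= upper:
        return "cross_resistant"
    return "unchanged"


def _as_ic50_value(x, role: str) -> float:
    if isinstance(x, IC50Estimate):
        if x.is_censored:
            raise DataError(
                f"{role} IC50 is censored ({x.censor}); widen the dose range "
                "and re-assay before computing a degree of resistance")
        x = x.value
    x = float(x)
    if not (np.isfinite(x) and x > 0):
        raise ValidationError(f"{role} IC50 must be positive and finite, got {x}")
    return x


def degree_of_resistance(ic50_parental, ic50_derivative,
                         parental: str = "parental",
                         derivative: str = "derivative",
                         lower: float = RESISTANCE_LOWER,
                         upper: float = RESISTANCE_UPPER) -> ResistanceComparison:
    """Degree of resistance = IC50(derivative) / IC50(parental).

    Accepts raw concentrations or uncensored :class:`IC50Estimate` objects.
    The reported ratio is rounded half-up to two decimals (presentation
    convention); the qualitative call is made on the unrounded ratio.
    """
    p = _as_ic50_value(ic50_parental, "parental")
    d = _as_ic50_value(ic50_derivative, "derivative")
    ratio = d / p
    return ResistanceComparison(
        parental=parental, derivative=derivative,
        ic50_parental=p, ic50_derivative=d,
        degree_of_resistance=_round_half_up(ratio),
        call=classify_resistance(ratio, lower, upper),
    )
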