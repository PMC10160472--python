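"""Root-density driving laws.

The model's biological driving force is a fitted relationship between root
length density (RLD, m/m^3) and normalized soil water suction, one law per
(growth stage, planting spacing) treatment:

    logarithmic (30 cm spacing):   RL(S) = a * ln(S) + b
    exponential (15 cm spacing):   RL(S) = c * exp(d * S)

Both laws are decreasing in suction for the fitted coefficients (a < 0,
d < 0): roots accumulate where the soil is wet.  The module also carries the
root-weight-density (RWD, g/m^3) to RLD conversions used to pool weight-only
samples into length densities:

    root axis:       RLD = 831.37 * ln(RWD) - 1685.51
    other locations: RLD = 83.12 * RWD ** 0.71
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .retention import FitResult, SuctionField, _fit_stats, minmax_normalize

__all__ = [
    "DrivingParams",
    "DensityConversion",
    "DEFAULT_CONVERSION",
    "DRIVING_PRESETS",
    "rld_from_suction",
    "fit_driving",
    "rld_from_rwd",
    "weight_field",
    "target_occupancy",
]

#: Floor applied to normalized suction before the logarithm (normalized
#: fields contain exact zeros at the wettest cell).
S_NORM_FLOOR = 1e-3


@dataclass(frozen=True)
class DrivingParams:
    """One fitted RLD-vs-suction law.

    ``family`` selects the formula; the logarithmic family uses (a, b) and
    the exponential family uses (c, d).  ``stage`` and ``spacing_cm`` tag the
    treatment the coefficients were fitted on.
    """

    family: str  # "logarithmic" | "exponential"
    a: float | None = None
    b: float | None = None
    c: float | None = None
    d: float | None = None
    stage: str | None = None  # "bud" | "flowering" | "boll"
    spacing_cm: int | None = None

    def __post_init__(self) -> None:
        if self.family == "logarithmic":
            if self.a is None or self.b is None:
                raise ValueError("logarithmic family requires coefficients (a, b)")
            if self.c is not None or self.d is not None:
                raise ValueError("logarithmic family must not carry (c, d)")
        elif self.family == "exponential":
            if self.c is None or self.d is None:
                raise ValueError("exponential family requires coefficients (c, d)")
            if self.a is not None or self.b is not None:
                raise ValueError("exponential family must not carry (a, b)")
        else:
            raise ValueError(f"unknown family {self.family!r}")
        if self.spacing_cm is not None and self.spacing_cm not in (15, 30):
            raise ValueError("spacing_cm must be 15 or 30")


@dataclass(frozen=True)
class DensityConversion:
    """Coefficients of the RWD-to-RLD regressions (axis log law, lateral power law)."""

    axis_slope: float = 831.37
    axis_intercept: float = -1685.51
    lateral_coeff: float = 83.12
    lateral_exp: float = 0.71

    def __post_init__(self) -> None:
        if self.lateral_coeff <= 0:
            raise ValueError("lateral_coeff must be positive")
        if not (0 < self.lateral_exp < 1.5):
            raise ValueError("lateral_exp must lie in (0, 1.5)")


DEFAULT_CONVERSION = DensityConversion()

#: Fitted treatment coefficients, keyed "<stage>-<spacing>cm".
DRIVING_PRESETS: dict[str, DrivingParams] = {
    "bud-30cm": DrivingParams("logarithmic", a=-235.436, b=1973.302, stage="bud", spacing_cm=30),
    "flowering-30cm": DrivingParams(
        "logarithmic", a=-239.590, b=2335.079, stage="flowering", spacing_cm=30
    ),
    "boll-30cm": DrivingParams(
        "logarithmic", a=-528.167, b=3373.453, stage="boll", spacing_cm=30
    ),
    "bud-15cm": DrivingParams("exponential", c=1643.095, d=-0.014, stage="bud", spacing_cm=15),
    "flowering-15cm": DrivingParams(
        "exponential", c=2834.931, d=-0.126, stage="flowering", spacing_cm=15
    ),
    "boll-15cm": DrivingParams(
        "exponential", c=3957.418, d=-0.253, stage="boll", spacing_cm=15
    ),
}


def rld_from_suction(S_norm, p: DrivingParams):
    """Raw driving-law value at normalized suction ``S_norm``.

    The logarithmic family clamps its argument at ``S_NORM_FLOOR`` below
    which the log diverges.  The raw formula value is returned unmodified —
    it may be negative for a logarithmic law near S_norm = 1; clamping to
    non-negative weights happens only in :func:`weight_field`.
    """
    s = np.asarray(S_norm, dtype=float)
    if p.family == "logarithmic":
        s = np.maximum(s, S_NORM_FLOOR)
        out = p.a * np.log(s) + p.b
    else:
        if np.any(s < 0):
            raise ValueError("normalized suction must be non-negative")
        out = p.c * np.exp(p.d * s)
    return float(out) if out.ndim == 0 else out


def fit_driving(pairs, family: str) -> FitResult:
    """Least-squares fit of a driving law to (S_norm, RLD) observations.

    Fits in RLD space with :func:`scipy.optimize.curve_fit`; needs at least
    4 points with some spread in suction (and strictly positive suction for
    the logarithmic family).
    """
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("pairs must be (S_norm, RLD) rows")
    if len(arr) < 4:
        raise ValueError("need at least 4 observations")
    S, rld = arr[:, 0], arr[:, 1]
    if len(np.unique(S)) < 2:
        raise ValueError("all suction values identical: fit is under-determined")

    if family == "logarithmic":
        if np.any(S <= 0):
            raise ValueError("logarithmic family needs strictly positive suction")

        def model(s, a, b):
            return a * np.log(s) + b

        slope0 = (rld[np.argmax(S)] - rld[np.argmin(S)]) / (
            np.log(S.max()) - np.log(S.min())
        )
        p0 = [slope0, float(np.mean(rld))]
    elif family == "exponential":

        def model(s, c, d):
            return c * np.exp(d * s)

        c0 = max(float(rld.max()), 1e-6)
        p0 = [c0, -0.1]
    else:
        raise ValueError(f"unknown family {family!r}")

    popt, _ = curve_fit(model, S, rld, p0=p0, maxfev=20000)
    if family == "logarithmic":
        params = DrivingParams("logarithmic", a=float(popt[0]), b=float(popt[1]))
    else:
        params = DrivingParams("exponential", c=float(popt[0]), d=float(popt[1]))
    pred = rld_from_suction(S, params)
    r, r2, residuals = _fit_stats(rld, pred)
    return FitResult(params=params, r=r, r2=r2, residuals=residuals)


def rld_from_rwd(rwd, location: str, conv: DensityConversion = DEFAULT_CONVERSION):
    """Convert root weight density (g/m^3) to root length density (m/m^3).

    ``location`` is "axis" (logarithmic law, thick main root) or "lateral"
    (power law, near-constant lateral diameter).
    """
    w = np.asarray(rwd, dtype=float)
    if np.any(w <= 0):
        raise ValueError("root weight density must be positive")
    if location == "axis":
        out = conv.axis_slope * np.log(w) + conv.axis_intercept
    elif location == "lateral":
        out = conv.lateral_coeff * w**conv.lateral_exp
    else:
        raise ValueError(f"unknown location {location!r}")
    return float(out) if out.ndim == 0 else out


def weight_field(
    field: SuctionField, p: DrivingParams, gamma: float = 1.0
) -> np.ndarray:
    """Per-cell growth weights from a suction field.

    Min-max normalizes the suction grid, evaluates the driving law, clamps
    negatives to zero and raises to the sharpness exponent ``gamma``
    (gamma = 0 flattens all positive-RLD cells to weight 1; larger gamma
    sharpens the wet-cell preference).
    """
    if field.quantity != "suction_MPa":
        raise ValueError("weight_field requires a field in suction mode")
    s_norm = minmax_normalize(field.values)
    rld = np.maximum(0.0, rld_from_suction(s_norm, p))
    with np.errstate(invalid="ignore"):
        w = np.where(rld > 0, rld**gamma, 0.0)
    return w


def target_occupancy(field: SuctionField, p: DrivingParams, kappa: float) -> int:
    """Stopping rule: lattice cells to occupy, from the mean positive RLD.

    ``kappa`` calibrates cells per unit RLD (m/m^3); the target is
    ``round(kappa * mean(clamped RLD) * n_cells)``, clipped to the lattice
    size with a warning.
    """
    if kappa <= 0:
        raise ValueError("kappa must be positive")
    rld = np.maximum(0.0, rld_from_suction(minmax_normalize(field.values), p))
    n_cells = rld.size
    target = int(round(kappa * float(rld.mean()) * n_cells))
    if target > n_cells:
        warnings.warn("occupancy target exceeds lattice size; clipping", stacklevel=2)
        target = n_cells
    return max(0, target)
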