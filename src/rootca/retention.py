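"""Soil water retention physics.

The van Genuchten closed-form retention curve links matric suction ``S``
(MPa) to volumetric water content ``theta`` (dimensionless fraction):

    theta(S) = theta_r + (theta_s - theta_r) * [1 + (alpha*S)**n] ** (-(1 - 1/n))

``theta_r`` and ``theta_s`` are the residual and saturated water contents,
``alpha`` (per MPa) scales the air-entry suction and ``n`` (> 1) controls the
curve shape.  The module evaluates and analytically inverts the curve, fits
its four parameters to (S, theta) observations, min-max normalizes suction
fields, and refines coarse point measurements onto the fine simulation
lattice by bilinear interpolation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy.interpolate import RegularGridInterpolator
from scipy.optimize import curve_fit

__all__ = [
    "RetentionParams",
    "SuctionField",
    "FitResult",
    "DEFAULT_RETENTION",
    "theta_from_suction",
    "suction_from_theta",
    "fit_retention",
    "minmax_normalize",
    "refine_to_grid",
]


class DegenerateRangeError(ValueError):
    """Raised when min-max normalization meets a constant input."""


@dataclass(frozen=True)
class RetentionParams:
    """The four van Genuchten constants.

    Attributes
    ----------
    theta_r : float
        Residual volumetric water content (fraction).
    theta_s : float
        Saturated volumetric water content (fraction).
    alpha : float
        Scale parameter (per MPa).
    n : float
        Shape parameter (dimensionless, > 1).
    """

    theta_r: float
    theta_s: float
    alpha: float
    n: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.theta_r < self.theta_s <= 1.0):
            raise ValueError(
                f"need 0 <= theta_r < theta_s <= 1, got theta_r={self.theta_r}, "
                f"theta_s={self.theta_s}"
            )
        if self.alpha <= 0:
            raise ValueError(f"alpha must be positive, got {self.alpha}")
        if self.n <= 1:
            raise ValueError(f"n must exceed 1, got {self.n}")

    @property
    def m(self) -> float:
        """The derived exponent 1 - 1/n."""
        return 1.0 - 1.0 / self.n


#: Medium-loam parameter set fitted from the leaching-pond soil.
DEFAULT_RETENTION = RetentionParams(theta_r=0.219, theta_s=0.447, alpha=7253.248, n=1.313)


@dataclass
class SuctionField:
    """Regular 2D grid of suction (MPa) or water content over the soil domain.

    The origin (0, 0) is the soil surface at the irrigation-point side; row
    index increases downward, column index with horizontal distance from the
    irrigation wall.  Cells are half-open squares ``[i*cell, (i+1)*cell)``.
    """

    values: np.ndarray
    quantity: str = "suction_MPa"  # or "theta"
    x_extent: float = 110.0
    y_extent: float = 60.0
    cell_size: float = 0.5

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("field values must be a 2D array")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("field contains non-finite values")
        if self.quantity not in ("suction_MPa", "theta"):
            raise ValueError(f"unknown quantity {self.quantity!r}")
        if self.quantity == "suction_MPa" and np.any(self.values < 0):
            raise ValueError("suction values must be non-negative")
        if self.quantity == "theta" and (
            np.any(self.values < 0) or np.any(self.values > 1)
        ):
            raise ValueError("water-content values must lie in [0, 1]")
        nrow = round(self.y_extent / self.cell_size)
        ncol = round(self.x_extent / self.cell_size)
        if self.values.shape != (nrow, ncol):
            raise ValueError(
                f"shape {self.values.shape} inconsistent with extent "
                f"{self.x_extent}x{self.y_extent} cm at {self.cell_size} cm cells "
                f"(expected {(nrow, ncol)})"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(x_cm, y_cm) coordinates of cell centers, as 1D arrays."""
        nrow, ncol = self.values.shape
        x = (np.arange(ncol) + 0.5) * self.cell_size
        y = (np.arange(nrow) + 0.5) * self.cell_size
        return x, y


@dataclass
class FitResult:
    """Outcome of a least-squares curve fit.

    ``r`` is the Pearson correlation between observed and fitted values and
    ``r2`` the coefficient of determination 1 - SS_res/SS_tot.
    """

    params: object
    r: float
    r2: float
    residuals: np.ndarray = dc_field(default_factory=lambda: np.empty(0))


def theta_from_suction(S, p: RetentionParams = DEFAULT_RETENTION):
    """Volumetric water content at suction ``S`` (MPa), van Genuchten form.

    Strictly decreasing in S; bounded in [theta_r, theta_s].  Accepts scalars
    or arrays.
    """
    S = np.asarray(S, dtype=float)
    if np.any(S < 0):
        raise ValueError("suction must be non-negative")
    theta = p.theta_r + (p.theta_s - p.theta_r) * (1.0 + (p.alpha * S) ** p.n) ** (-p.m)
    return float(theta) if theta.ndim == 0 else theta


def suction_from_theta(theta, p: RetentionParams = DEFAULT_RETENTION):
    """Closed-form inverse of :func:`theta_from_suction`.

    Defined for theta in (theta_r, theta_s]; suction diverges as theta
    approaches the residual content from above.
    """
    theta = np.asarray(theta, dtype=float)
    if np.any(theta > p.theta_s):
        raise ValueError("water content above saturation")
    if np.any(theta <= p.theta_r):
        raise ValueError("suction is unbounded at or below the residual water content")
    se = (theta - p.theta_r) / (p.theta_s - p.theta_r)
    S = (se ** (-1.0 / p.m) - 1.0) ** (1.0 / p.n) / p.alpha
    return float(S) if S.ndim == 0 else S


def _fit_stats(obs: np.ndarray, pred: np.ndarray) -> tuple[float, float, np.ndarray]:
    residuals = obs - pred
    ss_res = float(np.sum(residuals**2))
    ss_tot = float(np.sum((obs - obs.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else (1.0 if ss_res == 0 else 0.0)
    if np.allclose(pred, pred[0]) or np.allclose(obs, obs[0]):
        r = 1.0 if ss_res == 0 else 0.0
    else:
        r = float(np.corrcoef(obs, pred)[0, 1])
    return r, max(0.0, min(1.0, r2)), residuals


def fit_retention(pairs, init: RetentionParams | None = None) -> FitResult:
    """Least-squares fit of the four retention constants to (S, theta) pairs.

    Requires at least five distinct suction values spanning more than one
    order of magnitude.  Initialization: water-content extrema nudged 5%
    outward for theta_r/theta_s, alpha from the suction at mid-saturation,
    n = 1.5; the optimizer is bounded to keep n > 1 and the contents ordered.
    """
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("pairs must be (S, theta) rows")
    S, theta = arr[:, 0], arr[:, 1]
    distinct = np.unique(S[S > 0])
    if len(np.unique(S)) < 5:
        raise ValueError("need at least 5 distinct suction values")
    if len(distinct) < 2 or distinct.max() / distinct.min() <= 10.0:
        raise ValueError("suction values must span more than one order of magnitude")

    if init is None:
        t_lo, t_hi = theta.min(), theta.max()
        span = t_hi - t_lo
        theta_r0 = max(0.0, t_lo - 0.05 * span)
        theta_s0 = min(1.0, t_hi + 0.05 * span)
        mid = 0.5 * (t_lo + t_hi)
        s_mid = float(np.interp(mid, np.sort(theta), S[np.argsort(theta)]))
        alpha0 = 1.0 / s_mid if s_mid > 0 else 1.0
        init = RetentionParams(theta_r0, theta_s0, alpha0, 1.5)

    def model(s, tr, ts, a, n):
        return tr + (ts - tr) * (1.0 + (a * s) ** n) ** (-(1.0 - 1.0 / n))

    lower = [0.0, 0.0, 1e-12, 1.0 + 1e-6]
    upper = [1.0, 1.0, np.inf, 15.0]
    try:
        popt, _ = curve_fit(
            model,
            S,
            theta,
            p0=[init.theta_r, init.theta_s, init.alpha, init.n],
            bounds=(lower, upper),
            maxfev=20000,
        )
    except RuntimeError as exc:
        raise RuntimeError(f"retention fit did not converge: {exc}") from exc
    params = RetentionParams(*popt)
    pred = theta_from_suction(S, params)
    r, r2, residuals = _fit_stats(theta, pred)
    return FitResult(params=params, r=r, r2=r2, residuals=residuals)


def minmax_normalize(values) -> np.ndarray:
    """Map values affinely onto [0, 1]; errors on a constant input."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("need at least 2 values to normalize")
    lo, hi = float(v.min()), float(v.max())
    if hi <= lo:
        raise DegenerateRangeError("constant input: min-max range is degenerate")
    return (v - lo) / (hi - lo)


def refine_to_grid(
    samples,
    x_extent: float = 110.0,
    y_extent: float = 60.0,
    cell_size: float = 0.5,
    quantity: str = "suction_MPa",
) -> SuctionField:
    """Interpolate sparse (x_cm, y_cm, value) samples onto the CA lattice.

    Coarse moisture measurements are taken on a rectangular lattice of
    sampling points; each fine cell takes the bilinear interpolant of the
    four surrounding samples, which is exact at the samples and bounded by
    the local sample extrema.  Cells outside the sample bounding box take
    the nearest lattice value.  If the samples do not form a complete
    rectangular lattice the function falls back to inverse-distance
    weighting and warns.
    """
    arr = np.asarray(samples, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 3:
        raise ValueError("samples must be (x_cm, y_cm, value) rows")
    if len(arr) < 4:
        raise ValueError("need at least 4 samples")
    xs = np.unique(arr[:, 0])
    ys = np.unique(arr[:, 1])

    nrow = round(y_extent / cell_size)
    ncol = round(x_extent / cell_size)
    xq = (np.arange(ncol) + 0.5) * cell_size
    yq = (np.arange(nrow) + 0.5) * cell_size
    XQ, YQ = np.meshgrid(xq, yq)

    lattice = np.full((len(ys), len(xs)), np.nan)
    xi = np.searchsorted(xs, arr[:, 0])
    yi = np.searchsorted(ys, arr[:, 1])
    lattice[yi, xi] = arr[:, 2]

    if len(xs) * len(ys) == len(arr) and not np.any(np.isnan(lattice)):
        interp = RegularGridInterpolator(
            (ys, xs), lattice, method="linear", bounds_error=False, fill_value=None
        )
        # nearest-lattice extension: clamp queries to the sample bounding box
        yc = np.clip(YQ, ys[0], ys[-1])
        xc = np.clip(XQ, xs[0], xs[-1])
        vals = interp(np.column_stack([yc.ravel(), xc.ravel()])).reshape(nrow, ncol)
    else:
        warnings.warn(
            "samples do not form a rectangular lattice; "
            "falling back to inverse-distance weighting",
            stacklevel=2,
        )
        d2 = (XQ.ravel()[:, None] - arr[None, :, 0]) ** 2 + (
            YQ.ravel()[:, None] - arr[None, :, 1]
        ) ** 2
        w = 1.0 / np.maximum(d2, 1e-12)
        vals = (w @ arr[:, 2]) / w.sum(axis=1)
        exact = d2.min(axis=1) < 1e-12
        vals[exact] = arr[np.argmin(d2[exact], axis=1), 2]
        vals = vals.reshape(nrow, ncol)

    return SuctionField(
        values=vals,
        quantity=quantity,
        x_extent=x_extent,
        y_extent=y_extent,
        cell_size=cell_size,
    )
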