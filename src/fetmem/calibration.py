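"""Calibration and comparison metrics.

Fits the amnion stress scale mu0 to a stretch-tension curve by bounded
scalar least squares (replacing manual trial-and-error), and provides the
curve-comparison metrics used to judge the membrane models: windowed mean
squared error between model and data, the percent relative error between a
simulated and an experimental scalar, and pointwise averaging of repeated
experimental curves onto a common grid.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import minimize_scalar

from .constitutive import AmnionParameters
from .errors import ValidationError
from .material_point import StretchTensionCurve, uniaxial_response

__all__ = [
    "ExperimentalCurve",
    "fit_mu0",
    "mse_over_window",
    "relative_error",
    "average_experimental_curves",
]


@dataclass(frozen=True)
class ExperimentalCurve:
    """A measured (or synthetic) curve: strictly increasing abscissa with
    declared units, e.g. stretch vs tension or pressure vs displacement."""

    x: np.ndarray
    y: np.ndarray
    x_name: str = "stretch"
    x_unit: str = "-"
    y_name: str = "tension"
    y_unit: str = "N/mm"
    source: str = ""
    spread: Optional[np.ndarray] = None   # pointwise std for averaged curves

    def __post_init__(self):
        x = np.asarray(self.x, dtype=float)
        y = np.asarray(self.y, dtype=float)
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "y", y)
        if x.ndim != 1 or x.shape != y.shape:
            raise ValidationError("curve abscissa/ordinate must be matching 1-D arrays")
        if len(x) > 1 and not np.all(np.diff(x) > 0):
            raise ValidationError("curve abscissa must be strictly increasing")
        if self.spread is not None:
            s = np.asarray(self.spread, dtype=float)
            if s.shape != x.shape:
                raise ValidationError("spread must match the abscissa grid")
            object.__setattr__(self, "spread", s)

    def __len__(self) -> int:
        return len(self.x)


def mse_over_window(model: StretchTensionCurve, data: ExperimentalCurve,
                    window: Tuple[float, float]) -> float:
    """Mean squared tension error over an abscissa window, in (N/mm)^2.

    The model curve is linearly interpolated onto the data abscissae inside
    the window intersected with the model's support (no extrapolation).
    """
    lo, hi = window
    if hi <= lo:
        raise ValidationError("window must satisfy lo < hi")
    mx, my = model.lambda1, model.tension
    mask = (data.x >= max(lo, mx.min())) & (data.x <= min(hi, mx.max()))
    if not np.any(mask):
        raise ValidationError("window does not overlap the data/model support")
    pred = np.interp(data.x[mask], mx, my)
    return float(np.mean((pred - data.y[mask]) ** 2))


def relative_error(simulated: float, experimental: float) -> float:
    """Percent relative error |sim - exp| / exp x 100 (reported as a
    positive magnitude)."""
    if experimental == 0:
        raise ValidationError("experimental reference value must be nonzero")
    return 100.0 * abs(simulated - experimental) / abs(experimental)


def fit_mu0(data: ExperimentalCurve, fixed: AmnionParameters,
            window: Tuple[float, float] = (1.0, 1.2), h0_mm: float = 0.062,
            bounds: Tuple[float, float] = (0.1, 10.0)):
    """Fit the amnion stress scale mu0 (MPa) to uniaxial stretch-tension data.

    All other constants are held at `fixed`; the objective is the windowed
    MSE of the uniaxial model tension against the data, minimized over the
    bounded interval by deterministic scalar optimization.

    Returns (mu0, diagnostics dict).
    """
    lo, hi = window
    if lo < data.x.min() - 1e-9 or hi > data.x.max() + 1e-9:
        raise ValidationError("fit window must lie inside the data abscissa range")
    sel = (data.x >= lo) & (data.x <= hi)
    if sel.sum() < 2:
        raise ValidationError("fit window contains fewer than 2 data points")
    # solve the model on the data grid (with a continuation path from 1.0)
    grid = np.unique(np.concatenate([[1.0], data.x[data.x <= hi]]))

    def objective(mu0):
        curve = uniaxial_response(fixed.with_mu0(float(mu0)), h0_mm=h0_mm,
                                  lambda1_grid=grid)
        return mse_over_window(curve, data, window)

    res = minimize_scalar(objective, bounds=bounds, method="bounded",
                          options={"xatol": 1e-5})
    mu0 = float(res.x)
    return mu0, {"mse": float(res.fun), "n_points": int(sel.sum()),
                 "window": window, "bounds": bounds, "iterations": int(res.nfev)}


def average_experimental_curves(curves: Sequence[ExperimentalCurve],
                                n_grid: int = 100) -> ExperimentalCurve:
    """Pointwise mean of repeated curves on a common abscissa grid.

    The grid spans the intersection of the individual supports (curves are
    interpolated, never extrapolated); the pointwise standard deviation is
    returned as the `spread` of the mean curve.
    """
    if len(curves) < 2:
        raise ValidationError("need at least 2 curves to average")
    lo = max(c.x.min() for c in curves)
    hi = min(c.x.max() for c in curves)
    if hi <= lo:
        raise ValidationError("curves have no overlapping abscissa support")
    grid = np.linspace(lo, hi, n_grid)
    Y = np.vstack([np.interp(grid, c.x, c.y) for c in curves])
    ref = curves[0]
    return ExperimentalCurve(x=grid, y=Y.mean(axis=0), spread=Y.std(axis=0, ddof=0),
                             x_name=ref.x_name, x_unit=ref.x_unit,
                             y_name=ref.y_name, y_unit=ref.y_unit,
                             source=f"mean of {len(curves)} curves")
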