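"""Homogeneous-deformation drivers: uniaxial and equibiaxial stretch-tension
curves for a single membrane layer.

A uniaxial test at stretch lambda1 is the plane-stress state
F = diag(lambda1, lambda2, lambda3) with sigma22 = sigma33 = 0; the two
transverse stretches are found by Newton iteration with continuation along
the stretch grid. The equibiaxial driver prescribes lambda1 = lambda2 and
eliminates only the thickness. Both report membrane tension
t = sigma11 h0 / (lambda1 lambda2) in N/mm.

These homogeneous states stand in for the gauge region of a clamped tensile
specimen (away from the grips the deformation is homogeneous), so only
curve-level outputs are meaningful.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .constitutive import material_kernel, membrane_tension
from .errors import ParameterError, SolverError, ValidationError

__all__ = [
    "StretchTensionCurve",
    "default_stretch_grid",
    "plane_stress_thickness",
    "uniaxial_response",
    "lateral_contraction_curve",
    "equibiaxial_response",
]

CURVE_COLUMNS = ["lambda1", "lambda2", "lambda3", "tension_N_per_mm", "sigma11_kPa"]


def default_stretch_grid(lmax: float = 2.0, n: int = 200) -> np.ndarray:
    return np.linspace(1.0, lmax, n)


@dataclass(frozen=True)
class StretchTensionCurve:
    """Stretch-tension curve of a plane-stress membrane layer.

    table columns: lambda1 (longitudinal), lambda2 (lateral), lambda3
    (thickness), tension_N_per_mm, sigma11_kPa; lambda1 strictly increasing.
    """

    table: pd.DataFrame

    def __post_init__(self):
        missing = [c for c in CURVE_COLUMNS if c not in self.table.columns]
        if missing:
            raise ValidationError(f"curve table missing columns {missing}")
        lam1 = self.table["lambda1"].to_numpy()
        if len(lam1) > 1 and not np.all(np.diff(lam1) > 0):
            raise ValidationError("lambda1 must be strictly increasing")

    @property
    def lambda1(self) -> np.ndarray:
        return self.table["lambda1"].to_numpy()

    @property
    def tension(self) -> np.ndarray:
        return self.table["tension_N_per_mm"].to_numpy()

    def to_csv(self, path) -> None:
        # default float formatting is shortest-round-trip repr: lossless
        self.table.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "StretchTensionCurve":
        return cls(pd.read_csv(path, float_precision="round_trip"))

    def __len__(self) -> int:
        return len(self.table)


def _check_grid(grid: np.ndarray) -> np.ndarray:
    grid = np.asarray(grid, dtype=float)
    if grid.ndim != 1 or len(grid) < 1:
        raise ValidationError("stretch grid must be a 1-D sequence")
    if abs(grid[0] - 1.0) > 1e-12:
        raise ValidationError("stretch grid must start at 1.0")
    if len(grid) > 1 and not np.all(np.diff(grid) > 0):
        raise ValidationError("stretch grid must be strictly increasing")
    return grid


def plane_stress_thickness(params, lambda1: float, lambda2: float) -> float:
    """Unique thickness stretch lambda3 with sigma33(diag(l1, l2, l3)) = 0.

    Solved by bracketed root finding on sigma33, which is strictly
    increasing in lambda3 for both material laws.
    """
    if lambda1 <= 0 or lambda2 <= 0:
        raise ParameterError("in-plane stretches must be positive")
    kern = material_kernel(params)

    def s33(l3):
        return float(kern.sigma_diag(lambda1, lambda2, l3)[2])

    lo, hi = 1e-3, 1.0
    while s33(hi) < 0.0:
        hi *= 2.0
        if hi > 1e3:
            raise SolverError("failed to bracket the plane-stress thickness")
    while s33(lo) > 0.0:
        lo *= 0.5
        if lo < 1e-9:
            raise SolverError("failed to bracket the plane-stress thickness")
    return float(brentq(s33, lo, hi, xtol=1e-14, rtol=8.9e-16))


def _solve_transverse(kern, lam1: float, x0: np.ndarray,
                      tol: float = 1e-12) -> np.ndarray:
    """Newton on (lam2, lam3) for sigma22 = sigma33 = 0 at fixed lam1.

    Iterates on the kernel's dimensionless transverse residual (proportional
    to the stresses but free of the exponential prefactor), with a
    forward-difference Jacobian, step limiting, and halving on residual
    growth; warm starts come from grid continuation."""

    def res(x):
        return np.array(kern.transverse_residual(lam1, x[0], x[1]), dtype=float)

    x = x0.copy()
    r = res(x)
    for _ in range(100):
        nr = np.max(np.abs(r))
        if nr < tol:
            return x
        J = np.empty((2, 2))
        for k in range(2):
            xp = x.copy()
            h = 1e-8 * max(1.0, abs(x[k]))
            xp[k] += h
            J[:, k] = (res(xp) - r) / h
        try:
            dx = np.linalg.solve(J, -r)
        except np.linalg.LinAlgError:
            raise SolverError("singular Jacobian in transverse-stretch solve",
                              residual=float(nr))
        # keep iterates in a physical trust region
        lim = 0.25 * np.maximum(np.abs(x), 0.2)
        dx = np.clip(dx, -lim, lim)
        alpha = 1.0
        for _ in range(30):
            xn = x + alpha * dx
            if np.all(xn > 5e-3):
                rn = res(xn)
                if np.max(np.abs(rn)) < nr:
                    x, r = xn, rn
                    break
            alpha *= 0.5
        else:
            if nr < 1e-9:  # stagnated at rounding level: accept
                return x
            raise SolverError("transverse-stretch Newton stalled", residual=float(nr))
    if np.max(np.abs(res(x))) < 1e-9:
        return x
    raise SolverError("transverse-stretch Newton did not converge",
                      residual=float(np.max(np.abs(r))))


def uniaxial_response(params, h0_mm: float = 0.062,
                      lambda1_grid=None) -> StretchTensionCurve:
    """Uniaxial stretch-tension curve of a single layer.

    For each lambda1 on the grid the transverse stretches solve
    sigma22 = sigma33 = 0 (the dimensionless transverse residual is driven
    to ~1e-12), warm-started from the previous grid point; tension is
    sigma11 h0 / (lambda1 lambda2).
    """
    grid = _check_grid(default_stretch_grid() if lambda1_grid is None else lambda1_grid)
    kern = material_kernel(params)
    rows = np.empty((len(grid), 5))
    x = np.array([1.0, 1.0])
    for i, l1 in enumerate(grid):
        x = _solve_transverse(kern, float(l1), x)
        s11 = float(kern.sigma_diag(l1, x[0], x[1])[0])
        rows[i] = (l1, x[0], x[1], membrane_tension(s11, h0_mm, l1, x[0]), s11)
    return StretchTensionCurve(pd.DataFrame(rows, columns=CURVE_COLUMNS))


def lateral_contraction_curve(params, lambda1_grid=None) -> pd.DataFrame:
    """Lateral stretch lambda2 vs longitudinal stretch lambda1 in uniaxial
    extension (the fiber rotation mechanism makes the amnion contract far
    more than an isotropic solid would)."""
    curve = uniaxial_response(params, lambda1_grid=lambda1_grid)
    return curve.table[["lambda1", "lambda2"]].copy()


def equibiaxial_response(params, h0_mm: float = 0.062,
                         lambda_grid=None) -> StretchTensionCurve:
    """Equibiaxial stretch-tension curve: lambda1 = lambda2 prescribed,
    lambda3 from plane stress; the homogeneous proxy for the apex state of
    an inflated membrane."""
    grid = _check_grid(default_stretch_grid() if lambda_grid is None else lambda_grid)
    kern = material_kernel(params)
    _, _, _, l3 = kern.planestress(grid, grid, clip=False)
    s11 = kern.sigma_diag(grid, grid, l3)[0]
    tension = s11 * h0_mm / (grid * grid) / 1000.0
    rows = pd.DataFrame({
        "lambda1": grid, "lambda2": grid, "lambda3": l3,
        "tension_N_per_mm": tension, "sigma11_kPa": s11,
    })
    return StretchTensionCurve(rows[CURVE_COLUMNS])
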