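"""Constitutive laws for the fetal-membrane layers.

The amnion is modelled as a fiber composite: an exponential strain energy

    Psi = mu0/(2 q) * (exp(q * g) - 1),     g = g2(I1, J) + g3(lambda_i)

whose argument sums a compressible neo-Hookean matrix part

    g2 = m2 (I1 - 3) + (m2/m5) (J^(-2 m5) - 1)

and a discrete-fiber part built from N representative fiber families

    g3 = (m3/m4) (1/N) sum_i < lambda_i - 1 >^(2 m4)

with Macauley brackets <x> = max(x, 0), so fibers carry tension only.
Fiber directions are distributed in the membrane plane (in-plane angles
beta_j = (2 pi / N)(j - 3/2), j = 1..N/2) with an optional off-plane
inclination phi; each in-plane direction appears twice, once tilted above
and once below the plane, so N must be even.

The chorion and decidua are far less stiff-fiber dominated and are treated
as isotropic.  Because the membrane solvers operate at finite strain, their
"linear elastic" characterization (E, nu) is embedded in a compressible
neo-Hookean law that reduces exactly to Hooke's law in the small-strain
limit.

Units: stresses returned in kPa, moduli accepted in MPa (fields named
accordingly), lengths in mm, tensions in N/mm.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .errors import KinematicsError, ParameterError, StabilityControlError, ValidationError

MPA_TO_KPA = 1000.0

__all__ = [
    "AmnionParameters",
    "IsotropicLayerParameters",
    "DeformationState",
    "FiberSet",
    "EnergyBreakdown",
    "StressState",
    "build_fiber_directions",
    "fiber_stretches",
    "energy_breakdown",
    "cauchy_stress_amnion",
    "cauchy_stress_isotropic",
    "membrane_tension",
    "g3_stability_check",
    "max_principal_stress",
    "AmnionMaterial",
    "IsotropicMaterial",
    "material_kernel",
]

# exponent guard: exp arguments above this are clipped inside the smooth
# energy kernels used by the minimization solvers (converged states sit far
# below it; see docs/methods.md), and rejected in the strict point-wise API.
_EXP_CLIP = 500.0


# ---------------------------------------------------------------------------
# parameter containers


@dataclass(frozen=True)
class AmnionParameters:
    """Constants of the fiber-composite amnion law.

    mu0 is in MPa; q, m2..m5 are dimensionless; n_fibers is the (even)
    number of representative fiber families; phi_deg the off-plane fiber
    inclination in degrees. g3_cap is the stability-control threshold on the
    fiber energy term: converged results are invariant to it, it only
    triggers load-increment retries in continuation solvers.
    """

    mu0: float
    q: float
    m2: float
    m3: float
    m4: float
    m5: float
    n_fibers: int = 32
    phi_deg: float = 0.0
    g3_cap: float = 50.0

    def __post_init__(self):
        if self.mu0 <= 0 or self.q <= 0 or self.m2 <= 0 or self.m5 <= 0:
            raise ParameterError("mu0, q, m2, m5 must be positive")
        if self.m3 < 0:
            raise ParameterError("m3 must be non-negative")
        if self.m4 < 1:
            raise ParameterError("m4 must be >= 1 (keeps fiber stress continuous)")
        if int(self.n_fibers) != self.n_fibers or self.n_fibers < 2 or self.n_fibers % 2:
            raise ParameterError("fiber-family count must be an even integer >= 2")
        if not (0.0 <= self.phi_deg < 90.0):
            raise ParameterError("off-plane angle must satisfy 0 <= phi < 90 degrees")
        if self.g3_cap <= 0:
            raise ParameterError("g3_cap must be positive")

    @property
    def mu0_kpa(self) -> float:
        return self.mu0 * MPA_TO_KPA

    def with_mu0(self, mu0: float) -> "AmnionParameters":
        return replace(self, mu0=mu0)


@dataclass(frozen=True)
class IsotropicLayerParameters:
    """Small-strain elastic constants (E in MPa, Poisson ratio nu) embedded
    in a compressible neo-Hookean law for finite-strain use."""

    E: float
    nu: float

    def __post_init__(self):
        if self.E <= 0:
            raise ParameterError("Young's modulus must be positive")
        if not (0.0 <= self.nu < 0.5):
            raise ParameterError("Poisson ratio must satisfy 0 <= nu < 0.5 "
                                 "(incompressible limit not supported)")

    @property
    def shear_kpa(self) -> float:
        return self.E * MPA_TO_KPA / (2.0 * (1.0 + self.nu))

    @property
    def lame_kpa(self) -> float:
        return self.E * MPA_TO_KPA * self.nu / ((1.0 + self.nu) * (1.0 - 2.0 * self.nu))


# ---------------------------------------------------------------------------
# kinematic containers


@dataclass(frozen=True)
class DeformationState:
    """Deformation gradient with derived invariants I1 = tr(F^T F), J = det F."""

    F: np.ndarray

    def __post_init__(self):
        F = np.asarray(self.F, dtype=float)
        if F.shape != (3, 3):
            raise KinematicsError(f"deformation gradient must be 3x3, got {F.shape}")
        object.__setattr__(self, "F", F)
        if self.J <= 0:
            raise KinematicsError(f"det F must be positive, got {self.J}")

    @property
    def J(self) -> float:
        return float(np.linalg.det(self.F))

    @property
    def I1(self) -> float:
        return float(np.sum(self.F * self.F))


def _as_F(state) -> np.ndarray:
    if isinstance(state, DeformationState):
        return state.F
    return DeformationState(np.asarray(state, dtype=float)).F


@dataclass(frozen=True)
class FiberSet:
    """N unit reference fiber directions with their generating angles."""

    directions: np.ndarray          # (N, 3)
    betas: np.ndarray               # (N,) in-plane angles, radians
    thetas: np.ndarray              # (N,) polar angles, radians
    frame: np.ndarray = field(default_factory=lambda: np.eye(3))  # rows e1, e2, e3

    @property
    def n(self) -> int:
        return self.directions.shape[0]


def build_fiber_directions(n_fibers: int, phi_deg: float,
                           frame: Optional[np.ndarray] = None) -> FiberSet:
    """Construct the N reference fiber directions.

    For j = 1..N/2 the in-plane angle is beta_j = (2 pi / N)(j - 3/2) and the
    polar angle theta = pi/2 - phi; direction j points above the membrane
    plane (+cos(theta) e3) and its partner j + N/2 below it.
    """
    if int(n_fibers) != n_fibers or n_fibers < 2 or n_fibers % 2:
        raise ParameterError("fiber-family count must be an even integer >= 2")
    if not (0.0 <= phi_deg < 90.0):
        raise ParameterError("off-plane angle must satisfy 0 <= phi < 90 degrees")
    n_fibers = int(n_fibers)
    e = np.eye(3) if frame is None else np.asarray(frame, dtype=float)
    half = n_fibers // 2
    j = np.arange(1, half + 1)
    beta = (2.0 * np.pi / n_fibers) * (j - 1.5)
    phi = np.deg2rad(phi_deg)
    theta = np.full(half, np.pi / 2.0 - phi)
    # sin(theta) = cos(phi), cos(theta) = sin(phi): evaluated through phi so
    # that phi = 0 gives an exactly zero out-of-plane component
    sin_t = np.full(half, np.cos(phi))
    cos_t = np.full(half, np.sin(phi))
    in_plane = (np.cos(beta)[:, None] * sin_t[:, None] * e[0]
                + np.sin(beta)[:, None] * sin_t[:, None] * e[1])
    up = in_plane + cos_t[:, None] * e[2]
    down = in_plane - cos_t[:, None] * e[2]
    return FiberSet(
        directions=np.vstack([up, down]),
        betas=np.concatenate([beta, beta]),
        thetas=np.concatenate([theta, theta]),
        frame=e,
    )


def fiber_stretches(state, fibers: FiberSet) -> np.ndarray:
    """Stretch of each fiber family, lambda_i = |F M_i|."""
    F = _as_F(state)
    mapped = fibers.directions @ F.T
    return np.linalg.norm(mapped, axis=1)


# ---------------------------------------------------------------------------
# energies and stresses (strict point-wise API)


@dataclass(frozen=True)
class EnergyBreakdown:
    """Strain energy density (kPa) with its exponent-argument decomposition."""

    psi: float
    g: float
    g2: float
    g3: float


def g3_stability_check(g3: float, cap: float) -> bool:
    """True when the fiber energy term is below the stability cap.

    A False return is a retry signal: continuation solvers restart the
    current increment with a smaller load step. Converged results are
    invariant to the cap value.
    """
    if cap <= 0:
        raise ParameterError("stability cap must be positive")
    return g3 <= cap


def _amnion_g(F: np.ndarray, p: AmnionParameters, fibers: FiberSet):
    I1 = float(np.sum(F * F))
    J = float(np.linalg.det(F))
    g2 = p.m2 * (I1 - 3.0) + (p.m2 / p.m5) * (J ** (-2.0 * p.m5) - 1.0)
    lam = np.linalg.norm(fibers.directions @ F.T, axis=1)
    bracket = np.maximum(lam - 1.0, 0.0)
    g3 = (p.m3 / p.m4) * np.mean(bracket ** (2.0 * p.m4))
    return g2, g3, lam, bracket, J


def energy_breakdown(state, params: AmnionParameters,
                     fibers: Optional[FiberSet] = None) -> EnergyBreakdown:
    """Evaluate the amnion strain energy and its g2 (matrix) / g3 (fiber) split."""
    F = _as_F(state)
    if fibers is None:
        fibers = build_fiber_directions(params.n_fibers, params.phi_deg)
    g2, g3, _, _, _ = _amnion_g(F, params, fibers)
    if not g3_stability_check(g3, params.g3_cap):
        raise StabilityControlError(
            f"fiber energy g3 = {g3:.3g} exceeds cap {params.g3_cap}",
            g3=g3, cap=params.g3_cap)
    qg = params.q * (g2 + g3)
    if qg > _EXP_CLIP:
        raise StabilityControlError(
            f"exponent q*g = {qg:.3g} beyond safe range", g3=g3, cap=params.g3_cap)
    psi = params.mu0_kpa / (2.0 * params.q) * np.expm1(qg)
    return EnergyBreakdown(psi=float(psi), g=float(g2 + g3), g2=float(g2), g3=float(g3))


@dataclass(frozen=True)
class StressState:
    """Symmetric Cauchy stress tensor in kPa."""

    sigma: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "sigma", np.asarray(self.sigma, dtype=float))

    @property
    def max_principal(self) -> float:
        return max_principal_stress(self.sigma)


def cauchy_stress_amnion(state, params: AmnionParameters,
                         fibers: Optional[FiberSet] = None) -> StressState:
    """Cauchy stress of the amnion law, sigma = J^-1 (dPsi/dF) F^T (kPa).

    The derivative of the energy is analytic:
      dg2/dF = 2 m2 F - 2 m2 J^(-2 m5) F^-T
      dg3/dF = (2 m3 / N) sum_i <lam_i - 1>^(2 m4 - 1) (F M_i) (x) M_i / lam_i
    and dPsi/dF = (mu0/2) exp(q g) dg/dF. The g2 grouping makes F = I
    exactly stress free.
    """
    F = _as_F(state)
    if fibers is None:
        fibers = build_fiber_directions(params.n_fibers, params.phi_deg)
    g2, g3, lam, bracket, J = _amnion_g(F, params, fibers)
    if not g3_stability_check(g3, params.g3_cap):
        raise StabilityControlError(
            f"fiber energy g3 = {g3:.3g} exceeds cap {params.g3_cap}",
            g3=g3, cap=params.g3_cap)
    qg = params.q * (g2 + g3)
    if qg > _EXP_CLIP:
        raise StabilityControlError(
            f"exponent q*g = {qg:.3g} beyond safe range", g3=g3, cap=params.g3_cap)
    Finv_T = np.linalg.inv(F).T
    dg_dF = 2.0 * params.m2 * F - 2.0 * params.m2 * J ** (-2.0 * params.m5) * Finv_T
    mapped = fibers.directions @ F.T            # rows F M_i
    w = bracket ** (2.0 * params.m4 - 1.0) / lam
    dg_dF = dg_dF + (2.0 * params.m3 / fibers.n) * (mapped * w[:, None]).T @ fibers.directions
    P = 0.5 * params.mu0_kpa * np.exp(qg) * dg_dF
    sigma = P @ F.T / J
    if not np.all(np.isfinite(sigma)):
        raise StabilityControlError("non-finite stress entries", g3=g3, cap=params.g3_cap)
    return StressState(sigma=0.5 * (sigma + sigma.T))


def cauchy_stress_isotropic(state, params: IsotropicLayerParameters) -> StressState:
    """Cauchy stress of the compressible neo-Hookean chorion/decidua law (kPa).

    Psi = mu/2 (I1 - 3 - 2 ln J) + lam/2 (ln J)^2 with Lame constants from
    (E, nu); sigma = [mu (B - I) + lam ln J I] / J. Reduces to Hooke's law
    for small strains and is exactly stress free at F = I.
    """
    F = _as_F(state)
    J = float(np.linalg.det(F))
    B = F @ F.T
    mu, lam = params.shear_kpa, params.lame_kpa
    sigma = (mu * (B - np.eye(3)) + lam * np.log(J) * np.eye(3)) / J
    return StressState(sigma=sigma)


def membrane_tension(sigma_component_kpa: float, h0_mm: float,
                     lambda1: float, lambda2: float) -> float:
    """Membrane tension t = sigma h0 / (lambda1 lambda2), returned in N/mm.

    sigma is an in-plane Cauchy stress component in kPa, h0 the reference
    thickness in mm; 1 kPa*mm = 1e-3 N/mm.
    """
    if h0_mm <= 0:
        raise ParameterError("reference thickness must be positive")
    if lambda1 <= 0 or lambda2 <= 0:
        raise ParameterError("stretches must be positive")
    return sigma_component_kpa * h0_mm / (lambda1 * lambda2) / 1000.0


def max_principal_stress(sigma, tol: float = 1e-8) -> float:
    """Largest principal value of a symmetric stress tensor."""
    if isinstance(sigma, StressState):
        sigma = sigma.sigma
    sigma = np.asarray(sigma, dtype=float)
    scale = max(1.0, float(np.abs(sigma).max()))
    if np.abs(sigma - sigma.T).max() > tol * scale:
        raise ValidationError("stress tensor is not symmetric within tolerance")
    return float(np.linalg.eigvalsh(0.5 * (sigma + sigma.T))[-1])


# ---------------------------------------------------------------------------
# vectorized plane-stress kernels (shared by the membrane solvers)
#
# The membrane solvers work with principal in-plane stretches (lam1, lam2)
# and eliminate the thickness stretch lam3 point-wise. Both kernels expose
#   planestress(lam1, lam2)       -> (psi, dpsi/dlam1, dpsi/dlam2, lam3)
#   sigma_diag(lam1, lam2, lam3)  -> (s11, s22, s33) for diagonal F
# vectorized over arbitrary-shape stretch arrays; energies in kPa. dpsi
# derivatives are evaluated at the plane-stress lam3, where they equal the
# total derivatives (envelope theorem: dpsi/dlam3 = 0 there).


class AmnionMaterial:
    """Vectorized evaluation kernel for the fiber-composite amnion law."""

    def __init__(self, params: AmnionParameters, fibers: Optional[FiberSet] = None):
        self.params = params
        self.fibers = fibers if fibers is not None else build_fiber_directions(
            params.n_fibers, params.phi_deg)
        M = self.fibers.directions
        self.Cx, self.Cy, self.Cz = M[:, 0] ** 2, M[:, 1] ** 2, M[:, 2] ** 2
        self.in_plane_only = bool(np.all(self.Cz == 0.0))

    # -- helpers ----------------------------------------------------------

    def _fiber_lams(self, l1, l2, l3):
        l1, l2, l3 = np.broadcast_arrays(l1, l2, l3)
        lam2 = (np.multiply.outer(l1 ** 2, self.Cx)
                + np.multiply.outer(l2 ** 2, self.Cy)
                + np.multiply.outer(l3 ** 2, self.Cz))
        return np.sqrt(lam2)

    def g_parts(self, l1, l2, l3):
        """(g2, g3) for diagonal F = diag(l1, l2, l3)."""
        p = self.params
        l1, l2, l3 = (np.asarray(x, dtype=float) for x in (l1, l2, l3))
        J = l1 * l2 * l3
        I1 = l1 ** 2 + l2 ** 2 + l3 ** 2
        g2 = p.m2 * (I1 - 3.0) + (p.m2 / p.m5) * (J ** (-2.0 * p.m5) - 1.0)
        lam = self._fiber_lams(l1, l2, l3)
        br = np.maximum(lam - 1.0, 0.0)
        g3 = (p.m3 / p.m4) * np.mean(br ** (2.0 * p.m4), axis=-1)
        return g2, g3

    def g3(self, l1, l2, l3):
        return self.g_parts(l1, l2, l3)[1]

    def _dg(self, l1, l2, l3):
        """dg/dl1, dg/dl2, dg/dl3 for diagonal F (vectorized)."""
        p = self.params
        J = l1 * l2 * l3
        Jm = J ** (-2.0 * p.m5)
        lam = self._fiber_lams(l1, l2, l3)
        w = np.maximum(lam - 1.0, 0.0) ** (2.0 * p.m4 - 1.0) / lam
        # the mean over fibers supplies the 1/N of the fiber sum
        d1 = 2.0 * p.m2 * l1 - 2.0 * p.m2 * Jm / l1 + 2.0 * p.m3 * np.mean(w * self.Cx, axis=-1) * l1
        d2 = 2.0 * p.m2 * l2 - 2.0 * p.m2 * Jm / l2 + 2.0 * p.m3 * np.mean(w * self.Cy, axis=-1) * l2
        d3 = 2.0 * p.m2 * l3 - 2.0 * p.m2 * Jm / l3 + 2.0 * p.m3 * np.mean(w * self.Cz, axis=-1) * l3
        return d1, d2, d3

    # -- public kernel API -------------------------------------------------

    def thickness_stretch(self, l1, l2, tol: float = 1e-12):
        """Plane-stress thickness stretch: the unique lam3 with sigma33 = 0.

        For in-plane fibers (phi = 0) the condition involves only the matrix
        part and has the closed form lam3 = (l1 l2)^(-m5 / (1 + m5)); with
        off-plane fibers it is refined by a safeguarded Newton iteration on
        dg/dlam3 = 0.
        """
        p = self.params
        l1 = np.asarray(l1, dtype=float)
        l2 = np.asarray(l2, dtype=float)
        l3 = (l1 * l2) ** (-p.m5 / (1.0 + p.m5))
        if self.in_plane_only:
            return np.broadcast_arrays(l3, l1)[0].copy()
        for _ in range(80):
            _, _, d3 = self._dg(l1, l2, l3)
            J = l1 * l2 * l3
            Jm = J ** (-2.0 * p.m5)
            # d2g/dl3^2, matrix part exactly; fiber curvature term kept
            lam = self._fiber_lams(l1, l2, l3)
            br = np.maximum(lam - 1.0, 0.0)
            e = 2.0 * p.m4 - 1.0
            with np.errstate(divide="ignore", invalid="ignore"):
                dbr = np.where(br > 0.0, e * br ** (e - 1.0), 0.0)
            dlam_dl3 = np.asarray(l3)[..., None] * self.Cz / lam
            fib_curv = 2.0 * p.m3 * np.mean(
                dbr * dlam_dl3 ** 2
                + (br ** e / lam) * (self.Cz - dlam_dl3 ** 2), axis=-1)
            h = 2.0 * p.m2 + 2.0 * p.m2 * Jm * (2.0 * p.m5 + 1.0) / l3 ** 2 + fib_curv
            step = d3 / h
            step = np.clip(step, -0.2 * l3, 0.2 * l3)
            l3 = l3 - step
            if np.all(np.abs(d3) < tol * (1.0 + np.abs(l3))):
                break
        return l3

    def planestress(self, l1, l2, clip: bool = True):
        """Energy density and its in-plane stretch derivatives at plane stress.

        Returns (psi [kPa], dpsi/dlam1, dpsi/dlam2, lam3). With clip=True the
        exponential argument is capped so line searches far from equilibrium
        stay finite; converged states are unaffected.
        """
        p = self.params
        l1 = np.asarray(l1, dtype=float)
        l2 = np.asarray(l2, dtype=float)
        l3 = self.thickness_stretch(l1, l2)
        g2, g3 = self.g_parts(l1, l2, l3)
        qg = p.q * (g2 + g3)
        if clip:
            qg = np.minimum(qg, _EXP_CLIP)
        eqg = np.exp(qg)
        psi = p.mu0_kpa / (2.0 * p.q) * (eqg - 1.0)
        d1, d2, _ = self._dg(l1, l2, l3)
        pref = 0.5 * p.mu0_kpa * eqg
        return psi, pref * d1, pref * d2, l3

    def sigma_diag(self, l1, l2, l3):
        """Cauchy stress components (s11, s22, s33) in kPa for diagonal F."""
        p = self.params
        l1, l2, l3 = (np.asarray(x, dtype=float) for x in (l1, l2, l3))
        g2, g3 = self.g_parts(l1, l2, l3)
        eqg = np.exp(np.minimum(p.q * (g2 + g3), _EXP_CLIP))
        d1, d2, d3 = self._dg(l1, l2, l3)
        J = l1 * l2 * l3
        pref = 0.5 * p.mu0_kpa * eqg / J
        return pref * d1 * l1, pref * d2 * l2, pref * d3 * l3

    def transverse_residual(self, l1, l2, l3):
        """Dimensionless residual proportional to (sigma22, sigma33): the
        in-plane-2 and thickness components of dg/dlambda. Zero exactly at
        the transverse-stress-free state, but free of the exponential
        prefactor, so Newton stays well conditioned at large stretch."""
        _, d2, d3 = self._dg(np.asarray(l1, float), np.asarray(l2, float),
                             np.asarray(l3, float))
        return d2, d3


class IsotropicMaterial:
    """Vectorized kernel for the compressible neo-Hookean chorion/decidua law."""

    def __init__(self, params: IsotropicLayerParameters):
        self.params = params

    def thickness_stretch(self, l1, l2, tol: float = 1e-14):
        """lam3 with sigma33 = 0: mu (lam3^2 - 1) + lam ln(l1 l2 lam3) = 0."""
        mu, la = self.params.shear_kpa, self.params.lame_kpa
        l1 = np.asarray(l1, dtype=float)
        l2 = np.asarray(l2, dtype=float)
        area = l1 * l2
        l3 = np.full(np.broadcast(l1, l2).shape, 1.0)
        l3 = area ** (-self.params.nu / (1.0 - self.params.nu))  # small-strain init
        for _ in range(60):
            f = mu * (l3 ** 2 - 1.0) + la * np.log(area * l3)
            fp = 2.0 * mu * l3 + la / l3
            step = f / fp
            l3 = np.maximum(l3 - step, 1e-6)
            if np.all(np.abs(f) < tol * max(mu + la, 1.0)):
                break
        return l3

    def psi(self, l1, l2, l3):
        mu, la = self.params.shear_kpa, self.params.lame_kpa
        J = l1 * l2 * l3
        I1 = l1 ** 2 + l2 ** 2 + l3 ** 2
        lnJ = np.log(J)
        return 0.5 * mu * (I1 - 3.0 - 2.0 * lnJ) + 0.5 * la * lnJ ** 2

    def planestress(self, l1, l2, clip: bool = True):
        mu, la = self.params.shear_kpa, self.params.lame_kpa
        l1 = np.asarray(l1, dtype=float)
        l2 = np.asarray(l2, dtype=float)
        l3 = self.thickness_stretch(l1, l2)
        J = l1 * l2 * l3
        lnJ = np.log(J)
        psi = self.psi(l1, l2, l3)
        d1 = mu * (l1 - 1.0 / l1) + la * lnJ / l1
        d2 = mu * (l2 - 1.0 / l2) + la * lnJ / l2
        return psi, d1, d2, l3

    def sigma_diag(self, l1, l2, l3):
        mu, la = self.params.shear_kpa, self.params.lame_kpa
        l1, l2, l3 = (np.asarray(x, dtype=float) for x in (l1, l2, l3))
        J = l1 * l2 * l3
        lnJ = np.log(J)
        return ((mu * (l1 ** 2 - 1.0) + la * lnJ) / J,
                (mu * (l2 ** 2 - 1.0) + la * lnJ) / J,
                (mu * (l3 ** 2 - 1.0) + la * lnJ) / J)

    def transverse_residual(self, l1, l2, l3):
        """Dimensionless residual proportional to (sigma22, sigma33)."""
        mu, la = self.params.shear_kpa, self.params.lame_kpa
        l1, l2, l3 = (np.asarray(x, float) for x in (l1, l2, l3))
        lnJ = np.log(l1 * l2 * l3)
        scale = mu + la
        return ((mu * (l2 ** 2 - 1.0) + la * lnJ) / scale,
                (mu * (l3 ** 2 - 1.0) + la * lnJ) / scale)


def material_kernel(params):
    """Dispatch a parameter set to its vectorized evaluation kernel."""
    if isinstance(params, AmnionParameters):
        return AmnionMaterial(params)
    if isinstance(params, IsotropicLayerParameters):
        return IsotropicMaterial(params)
    raise ParameterError(f"unknown material parameter type: {type(params)!r}")
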