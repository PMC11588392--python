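"""Independent oracles used by the test suite.

Everything here is deliberately implemented from first principles (plain
loops, brute-force grids, classical small-strain theory) without reusing
the package's vectorized kernels, so tests compare two independent routes
to the same quantity.
"""

import math

import numpy as np
from scipy.integrate import solve_bvp


def amnion_energy_brute(F, mu0_kpa, q, m2, m3, m4, m5, n_fibers, phi_deg):
    """Strain energy of the fiber-composite law by explicit per-fiber
    summation with plain Python loops."""
    F = np.asarray(F, dtype=float)
    I1 = sum(F[i, j] ** 2 for i in range(3) for j in range(3))
    J = np.linalg.det(F)
    g2 = m2 * (I1 - 3.0) + (m2 / m5) * (J ** (-2.0 * m5) - 1.0)
    phi = math.radians(phi_deg)
    half = n_fibers // 2
    total = 0.0
    for j in range(1, half + 1):
        beta = 2.0 * math.pi / n_fibers * (j - 1.5)
        for sign in (+1.0, -1.0):
            M = np.array([math.cos(beta) * math.cos(phi),
                          math.sin(beta) * math.cos(phi),
                          sign * math.sin(phi)])
            lam = math.sqrt(float((F @ M) @ (F @ M)))
            total += max(lam - 1.0, 0.0) ** (2.0 * m4)
    g3 = (m3 / m4) * total / n_fibers
    return mu0_kpa / (2.0 * q) * (math.exp(q * (g2 + g3)) - 1.0), g2, g3


def transverse_minimum_brute(kernel_g, lam1, l2_range=(0.05, 1.2),
                             l3_range=(0.05, 2.2), n=400):
    """Brute-force argmin of the energy exponent g over (lam2, lam3) at
    fixed lam1 (minimizing g is minimizing the monotone energy)."""
    l2 = np.linspace(*l2_range, n)
    l3 = np.linspace(*l3_range, n)
    L2, L3 = np.meshgrid(l2, l3, indexing="ij")
    g = kernel_g(np.full_like(L2, lam1), L2, L3)
    i, j = np.unravel_index(np.argmin(g), g.shape)
    return l2[i], l3[j]


def fvk_membrane_deflection(a_mm, h_mm, E_kpa, nu, p_kpa, n_mesh=2000):
    """Center deflection of a clamped flat circular linear-elastic membrane
    under uniform pressure, from the axisymmetric Foppl-von Karman membrane
    equations solved as a boundary-value problem.

    State y = [u, w, Nr, S] with S = r Nr w'; membrane forces from plane
    stress Hooke's law on (eps_r = u' + w'^2/2, eps_t = u/r); radial
    equilibrium Nr' = (Nt - Nr)/r, vertical equilibrium S' = -p r.
    Returns w(0) in mm.
    """
    Eh = E_kpa * h_mm        # kPa*mm

    def rhs(r, y):
        u, w, Nr, S = y
        eps_t = u / r
        eps_r = Nr * (1.0 - nu ** 2) / Eh - nu * eps_t
        Nt = Eh / (1.0 - nu ** 2) * (eps_t + nu * eps_r)
        wp = S / (r * Nr)
        up = eps_r - 0.5 * wp ** 2
        return np.vstack([up, wp, (Nt - Nr) / r, -p_kpa * r])

    def bc(y0, y1):
        # center: u -> 0, S -> 0; edge: u = 0, w = 0
        return np.array([y0[0], y0[3], y1[0], y1[1]])

    r = np.linspace(1e-6 * a_mm, a_mm, n_mesh)
    # Hencky-type scales for the initial guess
    N0 = 0.4 * (p_kpa * a_mm) ** (2.0 / 3.0) * Eh ** (1.0 / 3.0)
    w0 = 0.65 * a_mm * (p_kpa * a_mm / Eh) ** (1.0 / 3.0)
    y = np.vstack([np.zeros_like(r),
                   w0 * (1.0 - (r / a_mm) ** 2),
                   np.full_like(r, N0),
                   -0.5 * p_kpa * r ** 2])
    sol = solve_bvp(rhs, bc, r, y, tol=1e-8, max_nodes=200000)
    if not sol.success:
        raise RuntimeError(f"FvK oracle failed: {sol.message}")
    return float(sol.sol(r[0])[1])


def eig_charpoly_max(sym3):
    """Largest eigenvalue of a symmetric 3x3 via its characteristic
    polynomial roots."""
    A = np.asarray(sym3, dtype=float)
    c2 = -np.trace(A)
    c1 = 0.5 * (np.trace(A) ** 2 - np.trace(A @ A))
    c0 = -np.linalg.det(A)
    roots = np.roots([1.0, c2, c1, c0])
    return float(np.max(roots.real))


def balloon_cap_pressure(tension_of_stretch, a_mm, d_mm):
    """Uniform spherical-cap estimate of the bulge pressure at apex
    displacement d: the membrane is a cap of radius R = (a^2+d^2)/(2d)
    stretched uniformly by the meridian arc ratio; p = 2 t(lam) / R."""
    R = (a_mm ** 2 + d_mm ** 2) / (2.0 * d_mm)
    alpha = math.asin(min(a_mm / R, 1.0))
    lam = R * alpha / a_mm
    return 2.0 * tension_of_stretch(lam) / R, lam
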