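"""Axisymmetric inflation of a clamped circular membrane laminate.

The solver treats the membrane as a zero-bending-stiffness laminate
(thickness/aperture < 0.02 here): layers are perfectly bonded and share the
in-plane stretches, each layer's thickness stretch follows from its own
plane-stress condition, and equilibrium at each pressure step is the
minimum of the total potential

    Pi(r, z) = sum_k  integral  Psi_k(lam_s, lam_t) h0_k dA_ref  -  p V

over a discretized meridian (piecewise-linear segments in the (r, z)
plane), where lam_s is the meridional stretch, lam_t = r/R the
circumferential stretch, and V the fluid volume enclosed between membrane
and clamp plane. The edge is clamped at the aperture radius; pressure acts
on the amnion-side face. Continuation marches the pressure schedule with
warm starts and halves the increment whenever the fiber-energy stability
control fires.

Loading follows the two-step bulge protocol: a small pre-inflation pressure
defines the reference state of the test (membrane slack removal), then a
linear ramp. Apex displacement is recorded both from the flat configuration
and re-zeroed at the pre-inflated state; paper-style comparisons use the
latter.

Reported per-layer apex thickness carries a through-thickness stress
correction: the fluid pressure compresses the stack, so layer k's reported
lambda3 solves sigma33 = (mean transverse stress in layer k) rather than 0,
with the transverse stress profile running from -p at the loaded face to 0
at the free face, partitioned by each layer's Laplace pressure drop
2 t_k / R_apex. Equilibrium, stresses and displacements always use the
plane-stress kinematics. See docs/methods.md.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq, minimize

from .constitutive import material_kernel
from .errors import ParameterError, SolverError, StabilityControlError, ValidationError

__all__ = [
    "Layer",
    "LaminateSpec",
    "PressureProtocol",
    "InflationResult",
    "inflate",
    "inflate_quasistatic",
    "apex_laplace_residual",
    "single_layer_apex_curve",
    "spherical_cap_estimate",
    "thickness_history",
]


@dataclass(frozen=True)
class Layer:
    """One membrane layer: a name, its material parameter set, and its
    reference thickness h0 in mm."""

    name: str
    material: object
    h0_mm: float

    def __post_init__(self):
        if self.h0_mm <= 0:
            raise ParameterError(f"layer {self.name!r}: thickness must be positive")


@dataclass(frozen=True)
class LaminateSpec:
    """Ordered stack of bonded layers (loaded side first) over a circular
    aperture of radius `aperture_radius_mm`."""

    layers: tuple
    aperture_radius_mm: float = 15.0

    def __post_init__(self):
        object.__setattr__(self, "layers", tuple(self.layers))
        if not self.layers:
            raise ParameterError("laminate needs at least one layer")
        if self.aperture_radius_mm <= 0:
            raise ParameterError("aperture radius must be positive")

    @property
    def layer_names(self):
        return [ly.name for ly in self.layers]


@dataclass(frozen=True)
class PressureProtocol:
    """Two-step bulge loading: pre-inflation to a small slack-removal
    pressure, then a linear ramp (rate in kPa/min) to the target."""

    pre_inflation_kpa: float = 0.2
    ramp_rate_kpa_per_min: float = 10.0
    target_kpa: float = 10.0
    step_kpa: float = 0.1

    def __post_init__(self):
        if not (0.1 <= self.pre_inflation_kpa <= 0.3):
            raise ParameterError("pre-inflation pressure must lie in [0.1, 0.3] kPa")
        if self.target_kpa <= self.pre_inflation_kpa:
            raise ParameterError("target pressure must exceed the pre-inflation pressure")
        if self.step_kpa <= 0 or self.ramp_rate_kpa_per_min <= 0:
            raise ParameterError("ramp rate and step size must be positive")

    def schedule(self) -> np.ndarray:
        """Pressure values visited: a short sub-ramp up to the pre-inflation
        pressure, then uniform steps to the target."""
        pre = self.pre_inflation_kpa * np.array([0.25, 0.5, 0.75, 1.0])
        n = int(np.ceil((self.target_kpa - self.pre_inflation_kpa) / self.step_kpa))
        ramp = self.pre_inflation_kpa + self.step_kpa * np.arange(1, n + 1)
        ramp[-1] = self.target_kpa
        return np.round(np.concatenate([pre, ramp]), 12)


@dataclass
class InflationResult:
    """Per-pressure-step quantities of an inflation run.

    `steps` has one row per pressure with columns: p_kPa, phase, apex_z_mm
    (flat-referenced), apex_d_mm (re-zeroed at the pre-inflated state),
    lam_s_apex, lam_t_apex, apex curvature radius R_apex_mm, and per layer
    sigma_max_<name>_kPa, h_<name>_mm, lam3_ps_<name>. `profile` holds the
    final meridian (R, r, z).
    """

    steps: pd.DataFrame
    profile: dict
    spec: LaminateSpec
    pre_inflation_kpa: float
    n_nodes: int
    solutions: dict = field(default_factory=dict, repr=False)

    def state_at_pressure(self, p_kpa: float) -> pd.Series:
        """Linearly interpolated ramp-phase state at a given pressure."""
        df = self.steps[self.steps["phase"] == "ramp"]
        p = df["p_kPa"].to_numpy()
        if not (p.min() - 1e-9 <= p_kpa <= p.max() + 1e-9):
            raise ValidationError(f"pressure {p_kpa} kPa outside the computed ramp")
        cols = df.drop(columns="phase")
        out = {c: float(np.interp(p_kpa, p, cols[c].to_numpy())) for c in cols.columns}
        return pd.Series(out)

    def state_at_displacement(self, d_mm: float) -> pd.Series:
        """Ramp-phase state at a given re-zeroed apex displacement."""
        df = self.steps[self.steps["phase"] == "ramp"]
        d = df["apex_d_mm"].to_numpy()
        if not (d.min() - 1e-9 <= d_mm <= d.max() + 1e-9):
            raise ValidationError(f"apex displacement {d_mm} mm outside the computed range")
        cols = df.drop(columns="phase")
        out = {c: float(np.interp(d_mm, d, cols[c].to_numpy())) for c in cols.columns}
        return pd.Series(out)


# ---------------------------------------------------------------------------
# discretized total potential


class _MeridianModel:
    """Total potential energy and gradient on a piecewise-linear meridian."""

    def __init__(self, spec: LaminateSpec, n_nodes: int):
        if n_nodes < 8:
            raise ParameterError("need at least 8 meridian nodes")
        self.spec = spec
        self.a = spec.aperture_radius_mm
        self.n = n_nodes
        self.R = np.linspace(0.0, self.a, n_nodes)
        self.dS = np.diff(self.R)
        self.Rbar = 0.5 * (self.R[:-1] + self.R[1:])
        self.area = 2.0 * np.pi * self.Rbar * self.dS
        self.kernels = [(material_kernel(ly.material), ly.h0_mm) for ly in spec.layers]

    # unknown vector u = [r_1 .. r_{n-2}, z_0 .. z_{n-2}]
    def unpack(self, u):
        n = self.n
        r = np.empty(n)
        z = np.empty(n)
        r[0], r[-1], z[-1] = 0.0, self.a, 0.0
        r[1:-1] = u[: n - 2]
        z[:-1] = u[n - 2:]
        return r, z

    def pack(self, r, z):
        return np.concatenate([r[1:-1], z[:-1]])

    def stretches(self, u):
        r, z = self.unpack(u)
        dr, dz = np.diff(r), np.diff(z)
        ell = np.hypot(dr, dz)
        lam_s = ell / self.dS
        lam_t = 0.5 * (r[:-1] + r[1:]) / self.Rbar
        return r, z, dr, dz, ell, lam_s, lam_t

    def potential(self, u, p):
        r, z, dr, dz, ell, lam_s, lam_t = self.stretches(u)
        lam_s = np.maximum(lam_s, 1e-6)
        lam_t = np.maximum(lam_t, 1e-6)
        dE_ds = np.zeros_like(lam_s)
        dE_dt = np.zeros_like(lam_t)
        E = 0.0
        for kern, h0 in self.kernels:
            psi, s1, s2, _ = kern.planestress(lam_s, lam_t)
            E += float(np.sum(psi * h0 * self.area))
            dE_ds += s1 * h0 * self.area
            dE_dt += s2 * h0 * self.area
        # enclosed volume, exact conical frusta
        Q = r[:-1] ** 2 + r[:-1] * r[1:] + r[1:] ** 2
        dzseg = z[:-1] - z[1:]
        V = np.pi / 3.0 * float(np.sum(dzseg * Q))
        f = E - p * V

        g_r = np.zeros(self.n)
        g_z = np.zeros(self.n)
        # meridional stretch: dlam_s/d(node coords) through segment length
        ce = dE_ds / (self.dS * np.maximum(ell, 1e-12))
        g_r[:-1] += -ce * dr
        g_r[1:] += ce * dr
        g_z[:-1] += -ce * dz
        g_z[1:] += ce * dz
        # circumferential stretch
        ct = dE_dt / (2.0 * self.Rbar)
        g_r[:-1] += ct
        g_r[1:] += ct
        # pressure-volume term
        vz = np.pi / 3.0 * Q
        g_z[:-1] += -p * vz
        g_z[1:] += p * vz
        g_r[:-1] += -p * np.pi / 3.0 * dzseg * (2.0 * r[:-1] + r[1:])
        g_r[1:] += -p * np.pi / 3.0 * dzseg * (r[:-1] + 2.0 * r[1:])
        return f, np.concatenate([g_r[1:-1], g_z[:-1]])

    def _neighbors(self, k):
        """Unknown indices coupled to unknown k (segment-local energy)."""
        n = self.n
        nr = n - 2                     # unknowns r_1..r_{n-2}
        if k < nr:
            node = k + 1
        else:
            node = k - nr              # z_0..z_{n-2}
        out = []
        for m in (node - 1, node, node + 1):
            if 1 <= m <= n - 2:
                out.append(m - 1)      # r_m
            if 0 <= m <= n - 2:
                out.append(nr + m)     # z_m
        return out

    def hessian(self, u, p, eps=1e-6):
        """Dense Hessian by colored forward differences of the analytic
        gradient: the energy is segment-local, so unknowns of the same node
        parity class (mod 3) can be perturbed together."""
        n = self.n
        nr = n - 2
        nu = len(u)
        g0 = self.potential(u, p)[1]
        H = np.zeros((nu, nu))
        for color in range(3):
            for block, offset in ((range(1, n - 1), -1), (range(0, n - 1), None)):
                cols = [(m - 1 if offset == -1 else nr + m)
                        for m in block if m % 3 == color]
                if not cols:
                    continue
                du = np.zeros(nu)
                du[cols] = eps
                g1 = self.potential(u + du, p)[1]
                dg = (g1 - g0) / eps
                for k in cols:
                    rows = self._neighbors(k)
                    H[rows, k] = dg[rows]
        return 0.5 * (H + H.T)

    def solve(self, u0, p, max_newton=60):
        """Damped-Newton minimization of the total potential.

        Nodal-force convergence tolerance is a small fraction of the
        pressure load per node; the Hessian is rebuilt by colored finite
        differences each iteration and Levenberg-damped when indefinite.
        """
        scale = max(p * self.a ** 2 / self.n, 1e-9)
        tol = 1e-5 * scale
        u = u0.copy()
        f, g = self.potential(u, p)
        gmax = float(np.max(np.abs(g)))
        for _ in range(max_newton):
            if gmax < tol:
                return u
            H = self.hessian(u, p)
            lam = 0.0
            du = None
            for _damp in range(12):
                try:
                    Hd = H if lam == 0.0 else H + lam * np.eye(len(u))
                    du = np.linalg.solve(Hd, -g)
                    if du @ g < 0.0:      # descent direction
                        break
                except np.linalg.LinAlgError:
                    pass
                lam = 10.0 * lam if lam > 0.0 else 1e-8 * max(1.0, np.abs(H).max())
                du = None
            if du is None:
                break
            alpha = 1.0
            accepted = False
            for _ls in range(40):
                fn, gn = self.potential(u + alpha * du, p)
                if fn < f + 1e-4 * alpha * (g @ du) or (
                        np.max(np.abs(gn)) < gmax and fn <= f + 1e-12 * abs(f)):
                    u = u + alpha * du
                    f, g = fn, gn
                    gmax = float(np.max(np.abs(g)))
                    accepted = True
                    break
                alpha *= 0.5
            if not accepted:
                break
        if gmax < tol:
            return u
        # fall back to L-BFGS from the best point, then re-check
        res = minimize(self.potential, u, args=(p,), jac=True, method="L-BFGS-B",
                       options={"maxiter": 3000, "maxcor": 30,
                                "ftol": 1e-18, "gtol": 1e-10})
        u = res.x
        gmax = float(np.max(np.abs(res.jac)))
        if gmax < 10.0 * tol:
            return u
        raise SolverError(f"membrane solve at p = {p} kPa did not converge "
                          f"(|grad|max = {gmax:.3g}, tol {tol:.3g})",
                          last_converged=None, residual=gmax)

    def apex_state(self, u):
        """Apex stretches and curvature radius from the converged meridian."""
        r, z = self.unpack(u)
        _, _, _, _, _, lam_s, lam_t = self.stretches(u)
        m = min(8, self.n - 1)
        # z ~ z0 - r^2 / (2 Rc) near the apex
        A = np.vstack([np.ones(m), r[:m] ** 2]).T
        coef, *_ = np.linalg.lstsq(A, z[:m], rcond=None)
        Rc = np.inf if coef[1] >= 0 else -1.0 / (2.0 * coef[1])
        return float(lam_s[0]), float(lam_t[0]), float(Rc), float(z[0])


def _initial_guess(model: _MeridianModel, d0: float) -> np.ndarray:
    R, a = model.R, model.a
    r = R.copy()
    z = d0 * (1.0 - (R / a) ** 2)
    return model.pack(r, z)


def _loaded_thickness(kern, l1, l2, l3_ps, s33_target):
    """Thickness stretch with a prescribed (compressive) transverse stress."""
    if s33_target >= 0.0:
        return l3_ps

    def f(l3):
        return float(kern.sigma_diag(l1, l2, l3)[2]) - s33_target

    lo = l3_ps
    while f(lo) > 0.0:
        lo *= 0.5
        if lo < 1e-6:
            return 1e-6
    return float(brentq(f, lo, l3_ps * (1.0 + 1e-12), xtol=1e-12))


def inflate_quasistatic(spec: LaminateSpec, pressures: Sequence[float],
                        n_nodes: int = 200, pre_inflation_kpa: Optional[float] = None,
                        stop_at_displacement: Optional[float] = None,
                        displacement_reference: str = "pre",
                        keep_solutions: bool = False) -> InflationResult:
    """March the membrane equilibrium along an increasing pressure schedule.

    `pressures` is the full list of pressures to visit (kPa, increasing);
    steps at or below `pre_inflation_kpa` are labelled phase "pre". The
    fiber stability control triggers increment halving (up to 6 levels). If
    `stop_at_displacement` is given, the march stops once the apex
    displacement reaches it, measured from the pre-inflated state
    (`displacement_reference="pre"`) or from the flat one (`"flat"`).
    """
    if displacement_reference not in ("pre", "flat"):
        raise ParameterError("displacement_reference must be 'pre' or 'flat'")
    pressures = np.asarray(pressures, dtype=float)
    if np.any(np.diff(pressures) <= 0) or pressures[0] <= 0:
        raise ParameterError("pressure schedule must be positive and increasing")
    if pre_inflation_kpa is None:
        pre_inflation_kpa = pressures[0]
    model = _MeridianModel(spec, n_nodes)
    caps = [ly.material.g3_cap for ly in spec.layers
            if hasattr(ly.material, "g3_cap")]
    g3_cap = min(caps) if caps else np.inf

    records = []
    u = _initial_guess(model, d0=0.05 * model.a)
    p_prev = 0.0
    z_pre = None

    def solve_with_retries(u_start, p_from, p_to, depth=0):
        u_new = model.solve(u_start, p_to)
        g3max = _max_g3(model, u_new)
        if g3max > g3_cap:
            if depth >= 6:
                raise StabilityControlError(
                    f"fiber energy above cap {g3_cap} even after increment halving",
                    g3=g3max, cap=g3_cap, last_converged=p_from)
            p_mid = 0.5 * (p_from + p_to)
            u_mid = solve_with_retries(u_start, p_from, p_mid, depth + 1)
            return solve_with_retries(u_mid, p_mid, p_to, depth + 1)
        return u_new

    def _max_g3(model, u):
        out = 0.0
        _, _, _, _, _, lam_s, lam_t = model.stretches(u)
        for (kern, _h0), ly in zip(model.kernels, spec.layers):
            if hasattr(kern, "g3"):
                l3 = kern.thickness_stretch(lam_s, lam_t)
                out = max(out, float(np.max(kern.g3(lam_s, lam_t, l3))))
        return out

    for p in pressures:
        try:
            u = solve_with_retries(u, p_prev, p)
        except SolverError as err:
            err.last_converged = p_prev
            raise
        lam_s0, lam_t0, Rc, z0 = model.apex_state(u)
        rec = {"p_kPa": p, "phase": "pre" if p <= pre_inflation_kpa + 1e-12 else "ramp",
               "apex_z_mm": z0, "lam_s_apex": lam_s0, "lam_t_apex": lam_t0,
               "R_apex_mm": Rc}
        # per-layer apex stresses and thicknesses
        tensions = []
        layer_cache = []
        for (kern, h0), ly in zip(model.kernels, spec.layers):
            _, s1, s2, l3 = kern.planestress(np.atleast_1d(lam_s0), np.atleast_1d(lam_t0),
                                             clip=False)
            l3 = float(l3[0])
            J = lam_s0 * lam_t0 * l3
            sig1 = float(s1[0]) * lam_s0 / J
            sig2 = float(s2[0]) * lam_t0 / J
            sig_mean = 0.5 * (sig1 + sig2)
            t_k = sig_mean * h0 * l3 / J  # = sig h0 / (lam1 lam2), kPa*mm
            tensions.append(t_k)
            layer_cache.append((kern, ly, h0, l3, sig1, sig2))
        # transverse stress profile: -p at the loaded face, 0 at the free face
        kappa = 0.0 if not np.isfinite(Rc) else 2.0 / Rc
        drops = [t_k * kappa for t_k in tensions]
        s33_face = -p
        for (kern, ly, h0, l3_ps, sig1, sig2), dk in zip(layer_cache, drops):
            s33_mid = s33_face + 0.5 * dk
            s33_face = s33_face + dk
            l3_loaded = _loaded_thickness(kern, lam_s0, lam_t0, l3_ps, min(s33_mid, 0.0))
            rec[f"sigma_max_{ly.name}_kPa"] = max(sig1, sig2, 0.0)
            rec[f"lam3_ps_{ly.name}"] = l3_ps
            rec[f"h_{ly.name}_mm"] = h0 * l3_loaded
        records.append(rec)
        if keep_solutions:
            pass
        if rec["phase"] == "pre":
            z_pre = z0
        if z_pre is not None:
            rec["apex_d_mm"] = z0 - z_pre
            d_stop = z0 if displacement_reference == "flat" else rec["apex_d_mm"]
            if (stop_at_displacement is not None and rec["phase"] == "ramp"
                    and d_stop >= stop_at_displacement):
                p_prev = p
                break
        p_prev = p

    steps = pd.DataFrame.from_records(records)
    if "apex_d_mm" not in steps.columns:
        steps["apex_d_mm"] = np.nan
    r, z = model.unpack(u)
    sols = {"final_u": u, "model": model} if keep_solutions else {}
    return InflationResult(steps=steps, profile={"R": model.R, "r": r, "z": z},
                           spec=spec, pre_inflation_kpa=float(pre_inflation_kpa),
                           n_nodes=n_nodes, solutions=sols)


def inflate(spec: LaminateSpec, protocol: PressureProtocol, n_nodes: int = 200,
            stop_at_displacement: Optional[float] = None,
            displacement_reference: str = "pre",
            keep_solutions: bool = False) -> InflationResult:
    """Run the two-step bulge protocol (pre-inflation, then linear ramp)."""
    return inflate_quasistatic(spec, protocol.schedule(), n_nodes=n_nodes,
                               pre_inflation_kpa=protocol.pre_inflation_kpa,
                               stop_at_displacement=stop_at_displacement,
                               displacement_reference=displacement_reference,
                               keep_solutions=keep_solutions)


def apex_laplace_residual(result: InflationResult, step: int = -1) -> float:
    """Equilibrium audit |p - 2 t_total / R_apex| / p at a converged step;
    exact on a spherical balloon, small for converged bulge solutions.

    The mechanical tension entering the Laplace balance is the stress
    resultant over the *current* thickness, sigma h0 lambda3 (this differs
    from the stretch-tension-curve normalization sigma h0 / (lam1 lam2) by
    the volume ratio J when the layer is compressible)."""
    row = result.steps.iloc[step]
    p = float(row["p_kPa"])
    Rc = float(row["R_apex_mm"])
    t_tot = 0.0
    for ly in result.spec.layers:
        sig = float(row[f"sigma_max_{ly.name}_kPa"])
        t_tot += sig * ly.h0_mm * float(row[f"lam3_ps_{ly.name}"])
    return abs(p - 2.0 * t_tot / Rc) / p


def spherical_cap_estimate(a_mm: float, d_mm: float):
    """Spherical-cap geometry sanity check: cap radius R = (a^2 + d^2)/(2 d)
    and the apex stretch estimate from the meridian arc-length ratio."""
    if d_mm < 0:
        raise ParameterError("apex displacement must be non-negative")
    if d_mm == 0.0:
        return np.inf, 1.0
    R = (a_mm ** 2 + d_mm ** 2) / (2.0 * d_mm)
    alpha = np.arcsin(min(a_mm / R, 1.0))
    return R, R * alpha / a_mm


def single_layer_apex_curve(params, h0_mm: float, aperture_mm: float = 25.0,
                            p_max_kpa: float = 10.0, n_nodes: int = 150,
                            step_kpa: float = 0.2) -> pd.DataFrame:
    """Apex stretch-tension curve of a single-layer inflation test (the
    apex state is locally equibiaxial, so this compares directly with
    equibiaxial_response)."""
    spec = LaminateSpec(layers=(Layer("membrane", params, h0_mm),),
                        aperture_radius_mm=aperture_mm)
    proto = PressureProtocol(pre_inflation_kpa=0.1, target_kpa=p_max_kpa,
                             step_kpa=step_kpa)
    res = inflate(spec, proto, n_nodes=n_nodes)
    df = res.steps
    lam = 0.5 * (df["lam_s_apex"] + df["lam_t_apex"])
    sig = df["sigma_max_membrane_kPa"]
    tension = sig * h0_mm / (df["lam_s_apex"] * df["lam_t_apex"]) / 1000.0
    return pd.DataFrame({"p_kPa": df["p_kPa"], "lambda_apex": lam,
                         "tension_N_per_mm": tension})


def thickness_history(result: InflationResult, layer: str) -> pd.DataFrame:
    """Apex current thickness of one layer per pressure step, with the
    percent reduction from its reference thickness."""
    names = result.spec.layer_names
    if layer not in names:
        raise ValidationError(f"unknown layer {layer!r}; laminate has {names}")
    h0 = result.spec.layers[names.index(layer)].h0_mm
    df = result.steps
    return pd.DataFrame({
        "p_kPa": df["p_kPa"],
        "h_mm": df[f"h_{layer}_mm"],
        "reduction_pct": 100.0 * (1.0 - df[f"h_{layer}_mm"] / h0),
    })
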