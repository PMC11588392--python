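"""Packaged parameter sets, loading protocols, and the synthetic bulge study.

The parameter tables (amnion fiber constants, chorion/decidua elastic
constants, trilayer thicknesses and aperture) ship as JSON resources with
explicit unit annotations. The synthetic study emulates the experimental
campaign behind the mean pressure-displacement curve: 18 peri-placental
term samples tested in a 30 mm bulge rig, with inter-sample variability on
the amnion stress scale and on the layer thicknesses, plus measurement
noise on the tracked apex displacement. The experimental data themselves
are not redistributable, so every generated curve is synthetic model
output.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from typing import List, Optional

import numpy as np

from .calibration import ExperimentalCurve
from .constitutive import AmnionParameters, IsotropicLayerParameters
from .errors import SolverError, ValidationError
from .inflation import LaminateSpec, Layer, PressureProtocol, inflate

__all__ = [
    "PARAMETER_SET_NAMES",
    "load_paper_parameters",
    "make_protocol",
    "SyntheticStudyConfig",
    "generate_synthetic_study",
]

PARAMETER_SET_NAMES = ("table1_amnion", "table2_chorion", "table2_decidua",
                       "table3_laminate")


def _read_resource(name: str) -> dict:
    ref = resources.files("fetmem.data").joinpath(f"{name}.json")
    with ref.open("r", encoding="utf-8") as fh:
        return json.load(fh)


def _quantity(node, expect_unit: str) -> float:
    if node["unit"] != expect_unit:
        raise ValidationError(f"expected unit {expect_unit}, got {node['unit']}")
    return float(node["value"])


def load_paper_parameters(name: str):
    """Load a packaged parameter set by name.

    Known names: "table1_amnion" (AmnionParameters, mu0 = 2.4 MPa),
    "table2_chorion" / "table2_decidua" (IsotropicLayerParameters),
    "table3_laminate" (the bonded trilayer LaminateSpec, aperture radius
    15 mm, loaded side first).
    """
    if name not in PARAMETER_SET_NAMES:
        raise LookupError(f"unknown parameter set {name!r}; "
                          f"known: {PARAMETER_SET_NAMES}")
    doc = _read_resource(name)
    if doc["kind"] == "amnion":
        return AmnionParameters(
            mu0=_quantity(doc["mu0"], "MPa"), q=doc["q"], m2=doc["m2"],
            m3=doc["m3"], m4=doc["m4"], m5=doc["m5"],
            n_fibers=doc["n_fibers"], phi_deg=_quantity(doc["phi"], "deg"),
            g3_cap=doc["g3_cap"])
    if doc["kind"] == "isotropic":
        return IsotropicLayerParameters(E=_quantity(doc["E"], "MPa"), nu=doc["nu"])
    if doc["kind"] == "laminate":
        layers = [Layer(name=ly["name"],
                        material=load_paper_parameters(ly["material"]),
                        h0_mm=_quantity(ly["h0"], "mm"))
                  for ly in doc["layers"]]
        return LaminateSpec(layers=tuple(layers),
                            aperture_radius_mm=_quantity(doc["aperture_radius"], "mm"))
    raise ValidationError(f"malformed parameter resource {name!r}")


def make_protocol(kind: str, **overrides) -> PressureProtocol:
    """Build a loading protocol.

    "experimental": the bulge-rig protocol (0.2 kPa pre-inflation,
    10 kPa/min ramp to 10 kPa). "simulation": the same pre-inflation with
    the ramp extended to 20 kPa, covering the end-of-test states. Keyword
    overrides pass through to PressureProtocol.
    """
    if kind == "experimental":
        base = dict(pre_inflation_kpa=0.2, ramp_rate_kpa_per_min=10.0,
                    target_kpa=10.0, step_kpa=0.1)
    elif kind == "simulation":
        base = dict(pre_inflation_kpa=0.2, ramp_rate_kpa_per_min=10.0,
                    target_kpa=20.0, step_kpa=0.1)
    else:
        raise LookupError(f"unknown protocol kind {kind!r}")
    base.update(overrides)
    return PressureProtocol(**base)


@dataclass(frozen=True)
class SyntheticStudyConfig:
    """Configuration of the synthetic bulge study.

    Defaults emulate the experimental campaign: 18 samples, 10% lognormal
    inter-sample variability on the amnion stress scale and on each layer
    thickness, 2% multiplicative Gaussian noise on the tracked apex
    displacement. A single seed drives deterministic per-sample substreams.
    """

    n_samples: int = 18
    noise_frac: float = 0.02
    mu0_cv: float = 0.10
    thickness_cv: float = 0.10
    seed: int = 0
    target_kpa: float = 10.0
    step_kpa: float = 0.25
    n_nodes: int = 100

    def __post_init__(self):
        if self.n_samples < 1:
            raise ValidationError("need at least one sample")
        if self.noise_frac < 0 or self.mu0_cv < 0 or self.thickness_cv < 0:
            raise ValidationError("noise and variability fractions must be >= 0")


def _perturbed_spec(spec: LaminateSpec, rng: np.random.Generator,
                    cfg: SyntheticStudyConfig) -> LaminateSpec:
    layers = []
    for ly in spec.layers:
        mat = ly.material
        if isinstance(mat, AmnionParameters) and cfg.mu0_cv > 0:
            mat = mat.with_mu0(mat.mu0 * float(np.exp(cfg.mu0_cv * rng.standard_normal())))
        h0 = ly.h0_mm
        if cfg.thickness_cv > 0:
            h0 = h0 * float(np.exp(cfg.thickness_cv * rng.standard_normal()))
        layers.append(Layer(ly.name, mat, h0))
    return LaminateSpec(layers=tuple(layers),
                        aperture_radius_mm=spec.aperture_radius_mm)


def generate_synthetic_study(config: SyntheticStudyConfig = SyntheticStudyConfig(),
                             spec: Optional[LaminateSpec] = None,
                             ) -> List[ExperimentalCurve]:
    """Generate per-sample pressure vs apex-displacement curves.

    Each sample runs the trilayer inflation model with its own perturbed
    amnion stress scale and thicknesses, then adds multiplicative Gaussian
    noise to the displacement. Deterministic under a fixed seed; a sample
    whose (extreme) draw fails to converge is regenerated from a fresh
    substream.
    """
    if spec is None:
        spec = load_paper_parameters("table3_laminate")
    proto = make_protocol("experimental", target_kpa=config.target_kpa,
                          step_kpa=config.step_kpa)
    streams = np.random.SeedSequence(config.seed).spawn(4 * config.n_samples)
    curves: List[ExperimentalCurve] = []
    stream_idx = 0
    for i in range(config.n_samples):
        for _attempt in range(4):
            rng = np.random.default_rng(streams[stream_idx])
            stream_idx += 1
            sample = _perturbed_spec(spec, rng, config)
            try:
                res = inflate(sample, proto, n_nodes=config.n_nodes)
            except SolverError:
                continue
            ramp = res.steps[res.steps["phase"] == "ramp"]
            p = ramp["p_kPa"].to_numpy()
            d = ramp["apex_d_mm"].to_numpy()
            if config.noise_frac > 0:
                d = d * (1.0 + config.noise_frac * rng.standard_normal(len(d)))
            curves.append(ExperimentalCurve(
                x=p, y=d, x_name="pressure", x_unit="kPa",
                y_name="displacement", y_unit="mm", source=f"synthetic sample {i}"))
            break
        else:
            raise SolverError(f"sample {i}: no converged draw after 4 attempts")
    return curves
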