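# fetmem — multilayer fetal-membrane mechanics

`fetmem` models the mechanical response of the human fetal membranes — the
amnion, chorion and maternal decidua — as a bonded laminate under bulge
(inflation) loading, the standard *ex vivo* test in which a clamped
circular sample is pressurized from one side while its apex displacement is
tracked. It is aimed at researchers in reproductive biomechanics who need a
calibrated, layer-resolved membrane model: for interpreting bulge-test
data, for exploring layer-level stress partitioning (which layer carries
the load, how much each thins), or as a building block for larger models of
the gravid uterus and cervix.

## The model

The mechanically dominant **amnion** is a fiber composite with exponential
strain energy

```
Ψ = μ₀/(2q) · (exp(q·g) − 1),        g = g₂(I₁, J) + g₃(λᵢ)

g₂ = m₂(I₁ − 3) + (m₂/m₅)(J^(−2m₅) − 1)
g₃ = (m₃/m₄)(1/N) Σᵢ ⟨λᵢ − 1⟩^(2m₄)
```

where I₁ = tr(FᵀF), J = det F, and λᵢ = |F·Mᵢ| are the stretches of N
discrete fiber families with reference directions Mᵢ distributed in the
membrane plane (in-plane angles βⱼ = (2π/N)(j − 3/2), optional off-plane
inclination φ). The Macauley bracket ⟨x⟩ = max(x, 0) makes the fibers
tension-only. With the packaged constants (q = 2.96, m₂ = 0.00228,
m₃ = 41.12, m₄ = 1.27, m₅ = 0.463, N = 32, φ = 0°, μ₀ = 2.4 MPa) the matrix
term is orders of magnitude softer than the fiber term, which produces the
amnion's hallmark J-shaped tension curve and its extreme lateral
contraction in uniaxial extension. The Cauchy stress is the analytic
derivative σ = J⁻¹ (∂Ψ/∂F) Fᵀ.

The **chorion** and **decidua** (E = 1 MPa, ν = 0.49) are embedded in a
compressible neo-Hookean law that reduces exactly to Hooke's law at small
strain, so the layers stay well-posed at the finite strains of a bulge
test.

The **bulge solver** treats the stack as a zero-bending-stiffness
axisymmetric laminate clamped at the 15 mm aperture radius: layers share
the in-plane stretches, each layer's thickness stretch follows from its own
plane-stress condition, and each pressure step is solved by damped-Newton
minimization of the total potential energy over a discretized meridian.
Loading follows the two-step bulge protocol: ≈0.2 kPa pre-inflation (slack
removal), then a 10 kPa/min ramp. Membrane tension is reported as
t = σ·h₀/(λ₁λ₂) in N/mm.

## Worked example

```python
import numpy as np
import fetmem as fm

# uniaxial stretch-tension response of the amnion
amnion = fm.load_paper_parameters("table1_amnion")
curve = fm.uniaxial_response(amnion, h0_mm=0.062,
                             lambda1_grid=np.linspace(1.0, 1.3, 61))

# trilayer bulge test: 30 mm aperture, pre-inflate to 0.2 kPa, ramp to 10 kPa
spec = fm.load_paper_parameters("table3_laminate")
proto = fm.make_protocol("experimental", step_kpa=0.2)
res = fm.inflate(spec, proto, n_nodes=150)
s = res.state_at_pressure(10.0)
```

which prints (via the obvious `print` statements):

```
lambda1 = 1.05:  lambda2 = 0.763,  T = 0.0154 N/mm
lambda1 = 1.10:  lambda2 = 0.559,  T = 0.0824 N/mm
lambda1 = 1.20:  lambda2 = 0.312,  T = 0.9604 N/mm
lambda1 = 1.30:  lambda2 = 0.219,  T = 6.9072 N/mm
apex displacement at 10 kPa: 5.22 mm (re-zeroed at pre-inflation: 3.70 mm)
amnion apex stress: 1238 kPa, chorion: 146 kPa
```

Reading this: tension rises from ~0.02 to ~7 N/mm over a 30% stretch (the
fiber-recruitment "J" shape) while the width contracts to a fifth of its
original value — the fiber lattice reorients toward the loading axis. In
the trilayer bulge at 10 kPa the amnion, although the thinnest layer,
carries an apex stress an order of magnitude above the chorion's: it is the
load-bearing layer of the membrane.

A command-line front end mirrors the library
(`fetmem uniaxial|biaxial|inflate|calibrate|synth|fibers|protocol`, each
writing CSV/JSON plus a run manifest); `fetmem --help` lists the options.

## Layout

- `src/fetmem/constitutive.py` — both material laws, fiber geometry, stress/energy API, vectorized plane-stress kernels
- `src/fetmem/material_point.py` — uniaxial / equibiaxial / lateral-contraction drivers
- `src/fetmem/inflation.py` — axisymmetric bulge solver (single layer and laminate)
- `src/fetmem/calibration.py` — μ₀ fitting, windowed MSE, relative error, curve averaging
- `src/fetmem/fixtures.py` — packaged parameter sets, protocols, synthetic bulge study
- `src/fetmem/cli.py`, `cli_io.py` — command line, curve CSV schema, run manifests
- `docs/methods.md` — model assumptions, numerical choices, limitations
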