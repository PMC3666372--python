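# blebdyn

Biomechanics of lung parenchymal lesions (blebs) — the quasi-spherical,
thin-walled blisters on the visceral pleura whose rupture causes spontaneous
pneumothorax.  `blebdyn` is for researchers in respiratory biomechanics and
computational physiology who want to simulate lesion wall dynamics, map the
material-parameter space for mechanical instability, study finite-energy
rupture and collagen–elastin remodeling, and estimate wall material
parameters from image sequences of a deforming boundary.

## The model

The lesion is a spherical membrane (thickness `H`, radius `R`) with stretch
ratio `λ(t) = r(t)/R` as its single degree of freedom, coupled to pulsatile
airway pressure and to the pleural fluid.  The wall follows an isotropic
pseudo-strain-energy

    w = (H/λ²) ( c₁ log[1 − (e^{E₁₁} − 1)/c₂] + c₃ E₁₁ ),   E₁₁ = (λ² − 1)/2

with `c₁ < 0`, `c₂ > 0`, `c₃ < 0`.  Nondimensionalizing the radial momentum
balance (groups `b, d, m_f, m` and forcing `F = (P − p_∞)R/(c₁H)`) gives

    dy₀/dτ = y₁
    dy₁/dτ = [F(τ) − 3by₁²/2 − 4m_f y₁/y₀ − 2f(y₀)/y₀ − 4md y₁/y₀⁴] / (by₀ + y₀⁻²)

integrated by fixed-step RK4.  Equilibria solve `γλ² + αλ + β = 0` with
`α = c₁c₂²F`, `β = −c₁ + 5c₁c₂ − 6c₂²c₃`, `γ = c₁ − 3c₁c₂ + 4c₂²c₃`, and the
system is unstable when the Jacobian about the equilibrium has `det J < 0`
or `tr J > 0` — closed-form criteria in `blebdyn.stability`.  A finite
energy limiter `Ψ = HΦ(1 − e^{−w/(HΦ)})` converts mathematical instability
into a physical rupture point, and collagen–elastin kinetics
(`dA_c/dt = k₁A_c|φ′−ψ′|ⁿ`, `dA_e/dt = −k₂A_e|φ′−ψ′|ⁿ`) let a stable lesion
remodel its way out of a stable orbit.  The imaging module runs the
diagnostic pipeline: Sobel edge detection → angular sectorization → boundary
kinematics → Levenberg–Marquardt material-parameter fits → per-sector
stability verdicts and a green/red overlay.

See `docs/methods.md` for the full model description and
`docs/derivation.md` for the nondimensionalization algebra.

## Worked example

```python
import blebdyn as bd

mat, geom = bd.default_material(), bd.default_geometry()
mem, fluid = bd.default_membrane(), bd.default_fluid()
P = bd.default_transmural_pressure()           # 760 mmHg in Pa

# closed-form stability verdict for normal lung parenchymal tissue
v = bd.classify(mat, geom, mem, fluid, P)
print(v.lambda_eq_plus, v.is_unstable, v.criterion)
# 1.3404215990913309 False none

# the same point at c3 = -1.39e6 N/m^2 is mechanically unstable
mat_u = bd.MaterialParameters(c1=-22.5e5, c2=1.26, c3=-1.39e6)
v = bd.classify(mat_u, geom, mem, fluid, P)
print(round(v.lambda_eq_plus, 4), v.is_unstable, v.criterion)
# 1.0933 True determinant

# breathing-forced oscillation of the stable lesion
traj = bd.simulate(mat, geom, mem, fluid, bm=bd.default_breathing(),
                   tau_end=300.0, step=1e-3, record_every=10)
m = bd.oscillation_metrics(traj)
print(round(m.amplitude, 3), round(m.frequency, 4))
# 0.308 0.0458
```

The first verdict says the reference lesion sits at a stable equilibrium
stretch of 1.34 (34% inflation over the undeformed radius); the stiffer-`c₃`
lesion has an unstable equilibrium — a candidate rupture site.  The
simulation shows the stable lesion oscillating with amplitude 0.31 about
that equilibrium at 0.046 cycles per unit dimensionless time.

The same workflows are available from the shell:

```bash
blebdyn classify                       # JSON verdict for the defaults
blebdyn simulate --out run/            # trajectory.csv + manifest
blebdyn sweep --param c2 --range 0.5:1.6:0.02 --out sweep/
blebdyn make-fixtures --out fx/        # synthetic boundary film
blebdyn analyze --frames fx/frames --sectors 36 --out verdicts/
```

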