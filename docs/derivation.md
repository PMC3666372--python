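# Derivation note: reconstructed scalings and sign conventions

This note records the algebra behind the nondimensionalization used in
`blebdyn.core` / `blebdyn.dynamics`, the cross-checks that certify it, and
the places where the reduced system's published presentation required a
declared reading.

## The reduced system

The package integrates, in the state `y0 = lam`, `y1 = dlam/dtau`,

```
dy0/dtau = y1
dy1/dtau = [F(tau) - (3/2) b y1^2 - 4 m_f y1/y0 - 2 f(y0)/y0
            - 4 m d y1 / y0^4] / (b y0 + y0^-2)
```

with `f(y0) = T_el(y0)/(c1 H)` the elastic Taylor tension over `c1 H` and
`F(tau) = (P_inner(t) - p_inf) R/(c1 H)`.  Because `c1 < 0`, both `f` and
`F` are negative for physical states — this sign convention is part of the
model definition and is what the closed-form equilibria, the Jacobian and
the instability criteria are built on.

## Reconstructed scalings

Requiring that the SI momentum balance map term-by-term onto the reduced
system fixes the dimensionless groups uniquely:

```
tau  = t * sqrt(|c1| / (rho_m R^2))          (time scale Ts = R sqrt(rho_m/|c1|))
b    = rho_f R / (rho_m H)
d    = H / R
m_f  = mu_f / (H sqrt(rho_m |c1|))
m    = mu_m / (H sqrt(rho_m |c1|))
```

Each is verified two ways: the groups invert back to the SI inputs at
machine precision (unit test), and integrating the dimensional twin

```
(rho_m H R / lam^2 + rho_f R^2 lam) lam'' =
    2 T_el(lam)/(lam R) - (P_inner - p_inf)
    - (3/2) rho_f R^2 lam'^2 - 4 mu_f lam'/lam - 4 mu_m H lam'/(R lam^4)
```

and mapping through `tau = t/Ts`, `y1 = Ts lam'` reproduces the reduced
trajectory pointwise to better than 1e-6 relative (in practice to machine
precision; `tests/test_dynamics.py`, `tests/test_acceptance.py`).

Two sign facts about this dimensional twin deserve emphasis:

* It is the reduced system multiplied back by `|c1| H / R` — nothing more.
  Writing the same physics with every force term on its "natural" side
  would flip the elastic-plus-pressure group relative to the viscous group;
  only the convention above reproduces the model's published behavior
  (an asymptotically stable node at `lam ~ 1.34` for the reference lung
  parameters, `det J > 0`, `tr J < 0`, and a determinant-criterion
  instability at `c3 = -1.39e6`).  The convention is therefore treated as
  part of the model, and all analysis (equilibria, Jacobian, criteria) is
  carried out consistently within it.
* The fluid shear term is taken as `4 mu_f lam'/lam` (rate over stretch),
  matching the reduced form `4 m_f y1/y0`; an alternative typeset form
  (`4 mu_f lam lam'`) is dimensionally and structurally inconsistent with
  the reduced system and is not used.

## Equilibria

With the autonomous forcing `F = R P/(c1 H)`, equilibria solve
`F - 2 f(lam)/lam = 0`, which after multiplying by `-c1 c2^2` becomes

```
gamma lam^2 + alpha lam + beta = 0
alpha = c1 c2^2 F,   beta = -c1 + 5 c1 c2 - 6 c2^2 c3,
gamma =  c1 - 3 c1 c2 + 4 c2^2 c3
```

The factor 2 (the Laplace law `P = 2T/(lam R)` for a sphere) is essential:
without it the quadratic above does not follow.  For the reference
parameters the positive root is 1.34042, matching the reported 1.3405.

## Jacobian closed form

About an equilibrium root `lam_e` (the `(-alpha + s)/(2 gamma)` branch,
`s = sqrt(alpha^2 - 4 beta gamma)`, `D = b lam_e + lam_e^-2`):

```
J = [[0, 1],
     [F (gamma - beta/lam_e^2) / (alpha D),
      -(4 m_f/lam_e + 4 m d/lam_e^4) / D]]
```

Substituting `lam_e = (-alpha+s)/(2 gamma)` turns `J[1,0]` into
`2 F gamma s (s - alpha) / (alpha (s-alpha)^2 D)` — the published closed
form.  Note that in the instability region (`gamma < 0`, `beta > 0`) this
branch of the equilibrium is negative; the criteria and their det/trace
identities are statements about that branch, while verdicts also report the
physically positive root.

## Trace criterion, fourth inequality

Re-deriving the trace condition for `beta > 0`, `gamma < 0` with
`q = (d m / m_f)^{1/3}` gives the chain

```
tr J > 0   <=>   (s - alpha)^3 < -8 gamma^3 d m / m_f
           <=>   s < alpha - 2 gamma q
           <=>   beta < alpha q - gamma q^2
```

The published form of the final inequality (`beta > alpha gamma^2 q +
gamma q^2`) differs in the `gamma^2` factor, the sign of the second term,
and the inequality direction; `theorem7_unstable` evaluates the published
form by default and the re-derived form under `form="derived"`, and
`classify` always cross-checks the numeric trace sign, reporting
disagreement rather than resolving it silently.

## Protein mass flux

The remodeling momentum balance adds a mass-flux term `Mdot * v_r * H`
(`Mdot = rho_c dAc/dt + rho_e dAe/dt`, `v_r = R lam'`) alongside the
inertia.  Nondimensionalizing under the core time scale gives

```
m_p = R (rho_c dAc/dt + rho_e dAe/dt) / sqrt(rho_m |c1|)
```

which is the unique dimensionless coefficient making the reduced term well
formed.  Because the flux term accompanies the *inertia* in the balance,
it maps through the same sign convention as the inertial group and enters
the reduced numerator as `+ m_p y1 / y0^2`: collagen accretion acts as
negative damping.  This is the only sign under which the remodeling
kinetics can carry a stable orbit into escape — the reported phenomenon —
and is the package's declared reading (the alternative sign is pure extra
damping, under which the orbit envelope is provably insensitive to the
protein numbers: the turning points of the lightly damped oscillation are
potential level sets, invariant to a multiplicative stress rescale).
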