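# Methods

`blebdyn` models the mechanics of a quasi-spherical, thin-walled parenchymal
lesion (bleb) on the visceral pleura — the structure whose rupture triggers
spontaneous pneumothorax — and provides an image-boundary pipeline that
estimates wall material parameters from a film of the deforming boundary and
classifies angular sectors as mechanically stable or unstable.

## Model

The lesion is a spherical membrane of undeformed radius `R` and thickness
`H << R`, with a single kinematic degree of freedom, the stretch ratio
`lam(t) = r(t)/R`.  Membrane incompressibility gives the deformed thickness
`h = H/lam^2`.  Three physical subsystems couple through the radial momentum
balance:

* **Wall elasticity.** An isotropic pseudo-strain-energy per reference area
  `w = (H/lam^2)(c1 log[1 - (e^{E11}-1)/c2] + c3 E11)`, `E11 = (lam^2-1)/2`,
  with `c1 < 0` (N/m^2), `c2 > 0`, `c3 < 0` (N/m^2).  For analysis and
  estimation the second-order Taylor form is used; the corresponding elastic
  tension is `T_el = a0 + a1 (lam^2 - 1)` with `a0 = -c1 H/c2 + c3 H` and
  `a1 = -c1 H/(2 c2^2) + 3 c1 H/(2 c2) - 2 c3 H`.  A rate term
  `2 mu_m H lam'/lam^3` adds wall viscosity.
* **Airway pressure.** The inner pressure is atmospheric plus a
  seven-component Fourier flow series times the respiratory resistance
  (`R_b = 1 mmHg·s/L`), with a common period of 12.8 s and a peak swing of
  ±2.275 mmHg about 760 mmHg.
* **Pleural fluid.** A Rayleigh–Plesset-type radial inertia/shear reaction
  with density `rho_f` and viscosity `mu_f`, against a far-field pressure
  `p_inf` (zero by default).

Nondimensionalization (time scale `Ts = R sqrt(rho_m/|c1|)`, groups `b, d,
m_f, m, F` — see `docs/derivation.md`) reduces the balance to a 2-state
system integrated by classical fixed-step RK4 (default step 1e-3 in `tau`;
sweeps use 5e-3 after a convergence check — RK4's empirical order on smooth
problems is verified at 4).  For the reference lung parameters the system
has an asymptotically stable equilibrium at `lam = 1.3404` and, started from
the undeformed rest state, oscillates about it with amplitude ~0.3 and
frequency ~0.045 cycles per unit `tau`; damping is weak (`m_f ~ 3e-5`,
`m ~ 1.4e-3`), so orbits persist for thousands of `tau`.

Initial conditions are not part of the published parameter set; the package
default is the undeformed rest state `(1, 0)`, and every entry point accepts
an override.  Note `Ts ~ 2.2e-4 s`: the wall's natural oscillation
(~4.7 ms period) is three orders of magnitude faster than a breath, so the
breathing forcing is quasi-static at the oscillation scale and the
autonomous (mean-pressure) approximation is excellent — the equilibrium
moves by less than 1e-3 relative over the full breathing swing.

## Stability criteria

With the autonomous forcing `F = R P/(c1 H)` the equilibria solve
`gamma lam^2 + alpha lam + beta = 0` (coefficients in `blebdyn.core`).  The
2×2 Jacobian about the `(-alpha + sqrt(alpha^2-4 beta gamma))/(2 gamma)`
branch has a closed form, and instability is prescribed for `det J < 0` or
`tr J > 0`.  Two closed-form criteria cover the physical parameter space:

* determinant: `gamma < 0`, `beta > 0`, `gamma < b^{1/3} alpha - b^{2/3} beta`;
* trace: same premises with the opposite third inequality plus a fourth
  inequality in `(d m/m_f)^{1/3}` that exists in two algebraic variants
  (see the derivation note); the published variant is the default and, on
  physically scaled parameters, essentially never fires — the determinant
  criterion is the operative one.

`classify` always cross-checks the closed-form det/trace signs against a
central finite-difference linearization of the right-hand side and flags
disagreement.  On 10^3 random physical parameter draws, every criterion
firing coincides with the corresponding numeric sign.

## Rupture

Hyperelastic energies grow without bound; real tissue stores at most a
finite failure energy.  The limited energy `Psi = H*Phi*(1 - exp(-w/(H*Phi)))`
saturates at `H*Phi`, and the limited tension is the Taylor tension times
`exp(-w/(H*Phi))`.  For hardening walls (`a1 > 0`, e.g. the instability-region
point `c3 = -1.39e6`) this creates an interior stress maximum; rupture is
declared at the first time the stretch passes that softening onset while
still expanding.  For softening walls (`a1 < 0`, including the reference
parameters) the limited tension has no interior maximum and no rupture point
exists — which is exactly why the reference lesion oscillates indefinitely
under any limiter.  The attenuation acts on tensile stored energy only
(`w > 0`); amplifying compressive states would be an artifact of the
exponential form.  No measured failure energy for pleural tissue is
asserted: the default `Phi` is calibrated so `H*Phi` equals three times the
Taylor energy at `lam = 2` (a mid-expansion rupture scale), and every
rupture-sensitive entry point requires or accepts `Phi` explicitly.

## Collagen–elastin remodeling

The wall energy becomes `w' = Ac * w_collagen + Ae * b_e H/lam^2 (lam - log
lam - 1)` with active protein numbers `Ac`, `Ae` and an elastin stiffness
`b_e` (no published value; package demonstrations use `1e5 N/m^2`).  The
protein kinetics are driven by the normalized gap between the hyperelastic
and energy-limited mixture energies, `sig = |w' - Psi'|/(H*Phi)`:

```
dAc/dt = +k1 Ac sig^n      dAe/dt = -k2 Ae sig^n
```

quiescent far from rupture, fast near it.  Collagen accretion saturates at
`Ac_max` (default 1e6 — tissue cannot pack collagen without bound, and the
quadratic self-amplification of the signal would otherwise blow up in finite
time).  The changing protein mass enters the momentum balance as a flux term
`+m_p y1/y0^2` (`m_p = R (rho_c dAc/dt + rho_e dAe/dt)/sqrt(rho_m |c1|)`),
i.e. negative damping while collagen is being laid down — the mechanism by
which the published rate calibration (`Ac=100, Ae=50, k1=1e7, k2=1e3, n=1`)
carries a stable orbit into escape.  Escape is detected two-sidedly: the
stretch leaves the frozen-kinetics orbit band (min/max widened by half the
orbit amplitude) and either stays out for one unit of `tau`, departs by a
decade, or never returns before the run ends.  The exit direction (violent
expansion vs collapse) depends on the oscillation phase at which the protein
flux peaks, so a one-sided rule would be numerically fragile; the two-sided
event is robust across failure energies `H*Phi` in [2e6, 1e7] J/m^2 and RK4
steps 1e-3/5e-4.  The escape demonstrations use `H*Phi = 1e7 J/m^2`, giving
several stable oscillations before departure near `tau ~ 24`.  The escape
*time* depends on the (unpublished) failure energy and is reported as a
qualitative result only.

## Image-boundary pipeline

`generate_fixture_frames` renders films of a bright disk of radius
`R*lam(t)` on a dark background (linear sub-pixel antialiasing, optional
Gaussian pixel noise, seeded), with per-sector material overrides for mixed
lesions.  Defaults: 160×160 px at 2.5e-4 m/px (boundary radius 40 px),
frame interval 2.5e-4 s.  The film protocol for estimation studies is
ic `(1.0, 0.05)` — the camera catches the lesion at its undeformed radius
while expanding — 50 frames at 5e-5 s (~23 frames per natural oscillation).
Starting at the undeformed radius lets the first frame calibrate `R` and
cancels any constant per-sector radius bias; the small outward rate also
carries instability-region walls over their equilibrium saddle so the film
shows the runaway expansion rather than collapse.

Analysis: 50% contrast compression toward mid-gray and Gaussian softening
(sigma 0.6 px — keeps the Sobel band's 95th-percentile radius error under
1.5 px at the default threshold); Sobel gradients with the `|Gx|+|Gy|`
magnitude and a threshold of 0.25 of the frame maximum; centered-coordinate
edge pixels binned into 36 half-open 10° sectors; per-sector boundary radius
as the gradient-magnitude-weighted mean of edge-pixel radii; stretch
normalized to the first frame; radial velocity by centered differences and
kinetic energy per area `1/2 rho_m v^2 H`.

Parameter estimation is damped (Levenberg–Marquardt) least squares over
`(log(-c1), log c2, log(-c3))` in two stages.  Stage one minimizes the
momentum-balance residual along the observed `(lam, lam', lam'')` series
(accelerations by direct second central differences), with eight log-spaced
starts around the reference constants.  Stage two ("shooting") refines by
integrating the forward model under the candidate parameters and fitting the
stretch series itself, with the initial stretch rate as a nuisance
parameter; this involves no numerical differentiation and is what resolves
near-boundary stability margins (the instability-region reference point sits
only ~1.4% — in fitted stress-slope units — from the determinant-criterion
boundary, while finite-difference accelerations amplify per-frame edge
jitter by 1/dt^2).  The second-order tension exposes only two identifiable
combinations of the three constants (`a0`, `a1`); the remaining gauge
direction — essentially `c2` — is pinned by a weak Tikhonov anchor at the
literature value (weights 1e-4, 3e-2, 1e-4 on the three logs).  Because
`alpha, beta, gamma` all scale by `c2^2` at fixed `(a0, a1)`, the stability
verdict is invariant along the gauge direction: classification does not
depend on the anchor.  Fits with fewer than 10 frames, incomplete sectors,
or motionless series are flagged indeterminate, never silently stable.
`r_squared` reports the coefficient of determination of the modeled stretch
series (shooting stage) or of the fitted tension against the observed force
signal (finite-difference stage).

On noiseless synthetic films the pipeline recovers `c2` to under 1% and
classifies all 36 sectors correctly for both the stable reference wall and
the instability-region wall; a mixed film at one gray level of pixel noise
classifies 36/36 sectors correctly.  What these tests do and do not show:
the fixtures share the forward model with the fitter (no model error), have
ideal circular geometry, stationary centers, and no motion artifacts or
intensity inhomogeneity — real CT boundaries violate all of these, so
synthetic recovery is a necessary, not sufficient, validation.

## Numerical choices and limitations

* Fixed-step RK4 throughout (no adaptive stiff solvers); integration halts
  on nonphysical collapse (`lam <= 0`) or non-finite state with a flag.
* Frequency estimation: Hann-windowed FFT of the mean-removed stretch after
  a 20% transient discard, parabolic peak interpolation, ties to the lowest
  frequency.  Sweep runs use 3000 `tau` windows.
* Amplitude: half peak-to-trough of the post-transient stretch.
* Problem sizes: the stiffness sweep covers 56 RK4 runs advanced as one
  vectorized batch; acceptance-scale imaging studies use three 50-frame
  films at 36 sectors.
* The published trace-criterion inequality is kept verbatim as the default
  (`form="printed"`); its re-derived variant is available and both are
  covered by the numeric trace-sign cross-check.
* Escape times and rupture times depend on the unpublished failure energy
  `Phi` and are qualitative; equilibria, criteria firings, the frequency
  peak location and the breathing baseline are quantitative.
* Only isotropic, axisymmetric lesions are modeled: no anisotropy, no
  gravity, no erratic breathing, no motion-artifact correction, no DICOM
  ingestion.
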