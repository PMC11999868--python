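# Methods

This note documents the models implemented in `sonojet`, the default
parameters and why they were chosen, the numerical schemes, and the
limitations a user should keep in mind when interpreting results.

## Radial dynamics

The bubble is assumed spherical with radius R(t). The liquid phase obeys
a Rayleigh–Plesset-type equation with a first-order compressibility
(radiation-damping) correction applied to the gas-pressure term:

    rho_l (R R'' + 3/2 R'^2) = p_g(R) (1 - 3 kappa R'/c_l) + p_v
                               - 2 sigma(R)/R - 4 mu_l R'/R
                               - 4 kappa_s R'/R^2 - p_0 - p_d(t)

The phospholipid coating follows the Marmottant law: surface tension is
zero below the buckling radius R_b, rises as chi (R^2/R_b^2 - 1) in the
elastic regime, and saturates at the clean-water value sigma_w beyond the
rupture radius; R_b and R_r follow from continuity given the equilibrium
tension sigma(R_0). Shell dilatational viscosity kappa_s adds the
4 kappa_s R'/R^2 damping term.

The gas core is a reduced model: polytropic with exponent kappa
(default 1.07, appropriate for a heavy perfluorocarbon like C4F10 whose
heat-capacity ratio is close to 1), pluggable via `BubbleParams.gas_model`
(`isothermal` and `adiabatic` tags are provided). Because gamma ≈ 1 for
this gas, thermal dissipation is weak and the polytropic reduction is an
acceptable stand-in for a full thermal model; the dominant damping
channels at megahertz driving are the shell viscosity and acoustic
radiation.

The initial gas pressure is fixed by mechanical equilibrium,
p_g0 = p_0 + 2 sigma(R_0)/R_0 - p_v.

### Default parameters

| parameter | default | units | rationale |
|---|---|---|---|
| rho_l, mu_l, c_l | 998, 1.0e-3, 1482 | kg/m^3, Pa s, m/s | water at ~20-22 C |
| p_0, p_v, sigma_w | 101325, 2330, 0.072 | Pa, Pa, N/m | standard conditions |
| R_0 | 3e-6 | m | flagship case |
| chi | 0.5 | N/m | typical lipid-shell elasticity |
| sigma_R0 | 0.02 | N/m | partially tensioned equilibrium coating |
| kappa_s | 2e-8 | kg/s | see below |
| kappa | 1.07 | — | C4F10-like core |

Shell parameters of lipid coatings are batch-dependent and rarely
printed; the defaults here were fixed once against the study conditions
the package targets. In particular kappa_s = 2e-8 kg/s (a mid-range
literature value for lipid-shelled microbubbles of this size) is the
value at which the model reproduces the reported regime as a whole: at
160 kPa a 3-µm bubble expands ~2.3 µm — beyond the 1-µm jetting threshold
yet inside stable cavitation (below 2R_0) — while the jetting-threshold
map over R_0 = 1–4 µm spans ~50 kPa (at the resonant size ~3.5-3.75 µm)
to ~200-340 kPa for strongly off-resonant bubbles. A several-fold smaller
shell viscosity would push the same case into violent inertial collapse
(~150 m/s wall speeds), which is inconsistent with the gentle observed
dynamics this model family is meant to describe.

### Numerics

Stiff adaptive integration (LSODA, rtol 1e-8, radius atol 1e-14 m,
max step one-tenth of a carrier period), with dense output resampled to
a uniform grid of 200 samples per carrier period — the fixed step the
downstream L1 fractional scheme requires. R'' is re-evaluated from the
governing equation at the grid points rather than finite-differenced.
A collapse below R_0/100 is beyond the model's validity and raises a
flagged error carrying the last valid state. Halving tolerances moves
the maximum expansion by < 0.1% (tested).

### Amplitude fitting

Hydrophone recordings underestimate the in-chamber driving pressure
(absorption by neighbouring bubbles, reflections). `fit_amplitude`
rescales the pulse amplitude by a single bounded scalar (factor in
[0.2, 5]) minimizing the sum of squared radius residuals against a
measured track; flat tracks are flagged ill-posed. On synthetic tracks
with half-pixel quantization noise the generating factor is recovered to
about 0.1% — far inside the 2% the observation noise would suggest —
because the resonant response is a steep function of amplitude.

## Translational dynamics and cell rheology

The centroid displacement x(t) (positive towards the substrate) obeys
m x'' = F_B1 + F_B2 + F_AM + F_VD + F_CR with the bubble mass
m = rho_gas V (retained for well-posedness, rho_gas = 10 kg/m^3).

* F_B1 = -V dp_d/dx with the plane-travelling-wave closure
  dp/dx = -(1/c_l) dp/dt projected on the substrate normal by
  cos(angle); the default 15 degrees corresponds to a transducer at 75
  degrees to the substrate plane. With this sign the cycle-averaged
  primary Bjerknes force pushes a below-resonance bubble towards the
  substrate.
* F_B2 = -rho_l V V'' / (16 pi (L-x)^2): the rigid substrate behind the
  cell layer acts as a mirror bubble; attraction on average because
  the cycle average of V V'' is negative.
* F_AM: the added-mass force is implemented as the time derivative of the
  added-mass momentum, F_AM = -d/dt[(1/2) rho_l V x'], i.e.
  -(1/2) rho_l (V' x' + V x''), which is dimensionally consistent; a
  displacement-based variant -(1/2) rho_l (V' x + V x') is kept behind
  the `as_printed_added_mass` flag for comparison (its force scale is
  negligible, so it effectively removes the added-mass inertia).
* F_VD = -(1/2) rho_l pi R^2 x'|x'| C_D with
  C_D = 24/Re + 6/(1+sqrt(Re)) + 0.4 and Re = 2 rho_l R |x'|/mu_l;
  written with x'|x'| so drag always opposes motion, and evaluated in the
  Stokes limit 6 pi mu_l R x' below Re ~ 1e-12 where the 24/Re term
  cancels analytically. The Basset history force is neglected — justified
  at the time-averaged translational Reynolds numbers of order 1–10
  reported by the diagnostics. Buoyancy is likewise omitted (4+ orders
  below the acoustic forces over 20 us; tested).
* F_CR = -pi R^2 c_beta d^beta eps/dt^beta with strain eps = x/L: a
  single spring-pot captures the cell's power-law rheology between a
  spring (beta = 0) and a dashpot (beta = 1). Defaults beta = 0.8 and
  c_beta = 1 Pa s^beta target the high-deformation-rate branch of cell
  microrheology (strain rates here are 1e5–1e7 1/s); L = 12 um is an
  endothelial-cell thickness.

The Caputo derivative is discretized with the L1 scheme on the uniform
grid (weights (i+1)^(1-beta) - i^(1-beta)), which converges at order
tau^(2-beta) (tested against closed-form monomial derivatives). The
memory term keeps the full history — ~4000 steps over 20 us, a trivial
convolution cost. Time stepping is a Heun predictor–corrector with the
x''-proportional terms (bubble inertia + added mass) collected on the
left-hand side before inversion; the force-balance residual is checked
to stay below 1e-3 of the peak primary Bjerknes force.

If the centroid reaches the substrate plane (x -> L) the cell has been
fully traversed — the transendothelial-tunnel scenario — and the run
stops with the `ultimate_compression` flag rather than modelling an
ultimate compressive strain, which is not quantified. At the default
high-amplitude case this occurs at ~9.3 us.

## Kelvin impulse and anisotropy

Per carrier cycle (windows at the upward zero crossings of the carrier,
one value per cycle), the Kelvin impulse I = -int V grad p dt is computed
by trapezoidal quadrature separately for the ultrasound gradient and the
substrate (mirror-bubble) gradient rho_l V''/(16 pi (L-x)^2). The
Rayleigh prefactor 4.789 — computed at import by integrating the
inviscid vapour-bubble collapse and cross-checked against the exact
2 (4/3) pi sqrt(3/2) (1/3) B(11/6, 1/2) — converts the virtual impulse of
a unit gradient into the equivalent time-invariant driving pressure
Delta p_bar = (4.789 R0c^4 grad_hat sqrt(rho_l)/I_hat)^2, where R0c is
the largest radius in the cycle; the anisotropy parameter follows as
zeta = I/(4.789 R0c^3 sqrt(rho_l Delta p_bar)). In the constant-gradient,
constant-pressure vapour-collapse limit this chain reproduces the
definitional zeta = -grad p R0/Delta p exactly (tested to quadrature
tolerance). Reports expose both raw impulses and zeta-normalized values.

The substrate-to-ultrasound impulse ratio |I_sub/I_us| depends strongly
on the driving regime: during the ramp, while the response is
quasi-linear, it sits near a closed-form value ~ 3 rho_l V0 x omega c_l
/(16 pi L^2 p_a sin(phase lag)) ≈ 1-2 for the default shell parameters,
and only once the envelope saturates and the nonlinear collapse sharpens
does it climb to 3-12, growing further as the bubble nears the wall and
(L-x)^-2 steepens. The monotone increase during the approach is a robust
model property; the early-cycle level is sensitive to the (unprinted)
shell damping through the response phase.

## Stress mechanisms

Channels (peak table in `stress_report`):

* p_jet = (1/2) rho_l c_l u_jet (water hammer), tagged as events at the
  driving-pressure compression peaks after the 1-um expansion threshold
  is first exceeded; sustained for varsigma = R_jet u_jet/c_l^2 over a
  contact radius rho_contact = R_jet u_jet/c_l.
* p_stag = (1/2) rho_l u_jet^2 after the rarefaction wave.
* p_impact = (1/2) rho_l |R'| R' (signed wall impact/suction).
* tau_shear = mu_l R'/delta and tau_stream = mu_l u_stream/delta with
  delta = sqrt(2 mu_l/(rho_l omega)) ≈ 0.56 um at 1 MHz.
* p_B1 = -(4/3) R dp_d/dx and p_B2 = -rho_l R V''/(12 pi h^2).

Defaults u_jet = 60 m/s (the lower bound implied by a jet traversing the
6-um bubble within one 0.1-us camera frame) and R_jet = R_0/4 (the jet
head radius is not observable; only p_jet's contact geometry, not its
magnitude, depends on it). u_stream = 0.1 m/s is a literature bound for
coated microbubbles at comparable driving, kept as an input.

Two deliberate choices:

1. The wall-motion channels are evaluated on the solution sampled at the
   observation frame rate (10 Mfps by default, `frame_rate=None` for the
   native grid), the way stresses are inferred from recorded tracks. The
   spherical model's sub-frame collapse spike coincides with the instants
   where a real bubble's interface goes aspherical and feeds the jet, so
   that spike acts on the cell as the jet hammer — already accounted for
   through u_jet — not as a wall stagnation pressure. Conflating the two
   would double-count the collapse.
2. The bubble–substrate distance in p_B2 is floored at the instantaneous
   radius, h = max(L-x, R): the mirror-image closure loses geometric
   validity once the centre is nearer the wall than one radius (as
   happens at tunnel contact), where the raw 1/h^2 would diverge.

At the default high-amplitude case the hammer pressure exceeds every
other peak by ~280-fold and the stagnation pressure stays ~15x above the
wall-impact peak; these ratios, not the absolute stresses, are the robust
output.

## Jetting thresholds

`classify_event` labels jetting (and predicted sonoporation) when the
maximum radial expansion reaches 1 um (configurable) — equivalently an
interfacial-acceleration proxy a = (R_max - R_0) omega^2 of
4 pi^2 x 10^6 m/s^2 ≈ 40 um/us^2 at 1 MHz — and inertial cavitation when
the bubble expands past twice its equilibrium radius. The threshold map
bisects the pressure amplitude per equilibrium radius to 1 kPa; with the
defaults the minimum is ~53 kPa at R_0 = 3.75 um, an interior minimum of
the sweep reflecting the large-amplitude resonant size (between the
buckled-shell and elastic-shell linear resonances).

## AFM Hertz fitting

Force curves are fitted over the whole approach segment with
F(z) = b + (4/3) E/(1 - theta^2) sqrt(Rbead) max(z - z0, 0)^(3/2), with
(log E, contact point z0, baseline b) free — the contact point is fitted,
not thresholded. A fit is discarded (valid = False) when fewer than 10
samples lie past the fitted contact point, or the force rise does not
clearly exceed the residual noise (no clear contact), or the contact
point falls outside the data. Defaults theta = 0.5 (incompressible gel)
and Rbead = 5 um (10-um colloidal probe). Aggregation: median modulus per
location grid, mean over locations per sample, mean ± sd over samples.

## Synthetic data

Generators are pure functions of (parameters, seed) and emulate: tracks
sampled at 10 Mfps with quantization noise uniform on ±80 nm (half of a
160-nm pixel — uniform, not Gaussian, because it is pixel quantization),
applied to both radius and centroid; ramped envelopes (linear rise over
5 carrier cycles by default — the experimental ramp shape is not
specified analytically, and any hydrophone-sampled envelope CSV can be
substituted); event tables over R_0 uniform in 1–4 um against a pressure
grid; and Hertzian curves with baseline offset, contact-point jitter,
multiplicative force noise and a per-location modulus spread.

What the generators do **not** emulate: aspherical shape modes and the
jets themselves (the spherical model only signals the jetting regime),
tracking artefacts beyond quantization (motion blur, out-of-plane
motion), acoustic reflections inside the chamber, or AFM cantilever
calibration errors. Passing recovery tests therefore demonstrates the
estimators are unbiased under the stated noise model, not under every
experimental nuisance.

## Problem sizes

Default runs integrate 20-cycle pulses with a 5-cycle ring-down margin at
200 output samples per cycle; the threshold map uses a 13-point radius
grid with ~9 bisection steps per radius; recovery experiments use a
handful of seeds. These sizes keep a full reproduction to a couple of
minutes on one core while leaving quadrature and discretization errors
at the sub-percent level (tested by grid refinement).

## Known limitations

* Spherical symmetry: shape modes, jet formation and fragmentation are
  outside the model; jet quantities enter only through (u_jet, R_jet).
* The radial model ignores the wall and the cell (free-bubble dynamics);
  the cell enters only through the translational force balance.
* One-way coupling: translation reads the radial solution, radial
  dynamics does not feel the wall proximity.
* The spring-pot has no ultimate-strain physics; tunnel formation is an
  event flag, not a membrane-failure model.
* Near tunnel contact the mirror-image closures are extrapolated beyond
  their geometric validity (handled by the h floor in the stress module;
  the impulse report keeps the literal L-x and should be read
  qualitatively in the final pre-contact cycles).
* Shell parameters are defaults for a typical lipid coating, not fits to
  any specific batch; absolute pressures and thresholds carry that
  uncertainty (factor ~2), while ratio-type outputs are robust.
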