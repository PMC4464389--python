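# Methods

## Physical model and assumptions

Oxygen in a fungal pellet is modelled as steady diffusion with
Michaelis–Menten volumetric uptake in a homogeneous, isothermal sphere:

    D_eff (c'' + (2/r) c') = r_max c/(c + K_M),   c'(0) = 0,  c(R) = c_S.

Assumptions inherited from the shell-model picture of a pelleted
biocatalyst: mass transfer inside the pellet is purely diffusive
(pellets are impermeable to flow); D_eff is constant and independent of
concentration; the biomass is treated as radially homogeneous; the
oxygen partition coefficient at the solid–liquid interface is 1 (no
concentration jump); and the pellet is at quasi-steady state over the
few seconds a microprobe measurement takes. Units are fixed throughout:
µm, s, mg O₂ l⁻¹ (the balance is dimensionally consistent in these
units with no hidden conversion).

Because Michaelis–Menten uptake never reaches exactly zero, the anoxic
core is defined operationally as the region where c falls below the
probe detection limit of 0.01 mg l⁻¹ (0.3 µM × 32 g mol⁻¹).

Default parameters and their provenance:

| parameter | default | unit | meaning |
|---|---|---|---|
| r_max | 0.026 | mg l⁻¹ s⁻¹ | maximum volumetric uptake, measured for the studied strain |
| K_M | 0.11 | mg l⁻¹ | half-saturation constant, same source |
| D_medium | 2800 | µm² s⁻¹ | oxygen diffusivity of the cultivation medium |
| Sh | 2 | – | Sherwood number of a sphere in quiescent liquid |
| detection limit | 0.01 | mg l⁻¹ | microprobe floor |
| probe noise sd | 0.03 | mg l⁻¹ | five-fold repeat accuracy of the probe |

## Numerical solution

**Shooting solver (default).** Integrates outward from the centre with
an adaptive Runge–Kutta scheme (rtol 1e-10, atol effectively 0 so that
relative accuracy survives the exponential growth of near-anoxic
fields). The 2/r singularity is removed by starting at ε = R·10⁻⁴ with
the series c(ε) = c₀ + r(c₀)ε²/(6D). The unknown centre value c₀ is
matched to c(R) = c_S by safeguarded root finding in log c₀ (the map is
monotone). When the required c₀ underflows double precision (interior
decay exponent beyond ~700, i.e. a hard anoxic core), the solver
switches unknowns: it shoots on the core radius r₀ with c(r₀) = 10⁻⁹c_S
and c'(r₀) = 0. An integration cap at 1.5·c_S prevents overflow of
overshooting trials. Surface flux is read from the integrator state, so
conservation (volume-averaged uptake = surface flux × a) holds to ≲0.1%
and is asserted at 0.5% for every converged solution.

**Finite-difference solver (independent cross-check).** Second-order
central differences with the symmetric centre stencil 6(c₁−c₀)/h², a
Dirichlet surface node, and damped Newton iteration (step halving on
the residual norm) on the tridiagonal Jacobian. The reporting grid is
401 evenly spaced nodes; internally the grid refines so that
h·κ ≤ 0.025 with κ = √(r_max/(K_M·D_eff)) — the steepest possible field
scale — because a fixed 401-node grid has O((hκ)²) errors of order
10⁻² mg l⁻¹ at Weisz-strongly-limited conditions, an order above the
1e-3 mg l⁻¹ agreement the solver pair is held to. The reported nodes
are an exact subset of the refined grid (multiples of 400 intervals,
capped at 40001 nodes).

The two solvers share no discretisation, so their agreement (asserted
at max|Δc| < 10⁻³ mg l⁻¹ over random scenarios spanning φ_m ∈ [0.05, 20];
measured ≈5·10⁻⁵) is a genuine cross-validation.

**Closed forms.** First-order: c = c_S (R/r) sinh(qr)/sinh(qR),
evaluated in overflow-safe expm1 form with the removable centre limit.
Zero-order: parabolic shell with the anoxic-core cubic
1 + 2ρ³ − 3ρ² = 6Dc_S/(k₀R²), bisected to 1e-12. The saturable solver
approaches these limits as K_M/c_S → ∞ or 0; the approach is linear in
K_M on the zero-order side (the field must pass through c ~ K_M near a
core, where it is genuinely not zero order) and the limit tests are
stated at measured tolerances: 1e-4 relative at K_M = 10³c_S
(first order), 1e-3 at K_M = 10⁻³c_S for a fully penetrated pellet
(zero order), 5e-3 outside the core for a cored pellet.

**Transient no-reaction solution** (deactivated pellets): the classical
sphere series with uniform start and constant surface, summed until the
tail is below 1e-8 (adaptive term count from the Fourier number; t = 0
returns the initial condition exactly).

## Effectiveness and moduli

The generalized Thiele modulus for saturable uptake uses the V/A = R/3
length convention:

    phi_m = (R/3) r(c_S) / sqrt(2 D_eff r_max (c_S − K_M ln(1 + c_S/K_M))).

The internal effectiveness interpolates between the exact order-limit
curves with weight β = K_M/c_S:

    eta_im = (eta_0(phi_m) + β eta_1(phi_m)) / (1 + β),

where eta_1(φ) = (1/φ)(1/tanh 3φ − 1/3φ) and eta_0(φ) comes from the
core cubic written as 1 + 2ρ³ − 3ρ² = 1/(3φ²). Both limbs are evaluated
at the *same* generalized modulus: this makes them share the 1/φ
asymptote, reduces the measured worst-case deviation from the exact
numeric effectiveness to 2.4% over φ_m ∈ [0.1, 10] × β ∈ [0.01, 100]
(evaluating each limb at its own order modulus instead leaves a 22%
error near β ≈ 1), and still reduces exactly to the respective order
limit as β → 0 or ∞.

The Weisz modulus Φ = 2φ_m²η(1+β)[1 + β ln(β/(1+β))] is algebraically
identical to the observable form (R/3)²r_obs/(D_eff c_S); the bracket is
evaluated through a series-stable x − ln(1+x) helper because the direct
form cancels catastrophically for β ≳ 30 (and the identity test draws
β ∈ [10⁻², 30], the range where *both* direct evaluations are well
conditioned in doubles). Regime bands are closed on the intermediate
side: kinetic iff Φ < 0.3, intermediate iff 0.3 ≤ Φ ≤ 3,
diffusion-limited iff Φ > 3.

External transfer: k_S = Sh·D_medium/D with the quiescent Sh = 2
(the film conduction happens in medium, hence the medium diffusivity),
a = 6/D, and η_em = c_S(K_M+c_B)/(c_B(K_M+c_S)). The film/pellet
coupling finds c_S ∈ [0, c_B] where film delivery k_S(c_B − c_S) equals
the pellet surface flux, by bracketed root finding on the monotone
mismatch; the closure is verified to <0.5% flux mismatch. Note the
direction of the diffusivity effect: lowering D_eff *reduces* the flux
the film must carry, so c_S rises toward c_B; it is strong uptake
(large r_max), not slow internal diffusion, that pulls c_S to zero.

## Diffusivity fitting

In-pellet points of a classified trace are mapped to radii by
r = R − (depth − surface_depth), assuming the probe axis passes through
the pellet centre (declared in the fit output; off-centre chords are the
user's responsibility to flag). Points mapping past the centre are
rejected with a warning. The fit minimises the sum of squared
concentration residuals with D_eff the single free parameter (bounds
100–5000 µm² s⁻¹, initial guess 1000 — bracketing the plausible range
for fungal pellets), kinetics fixed to the independently measured
values, and c_S pinned to the measured surface point (co-fitting c_S
and/or the kinetics is available behind flags for sensitivity studies).
The asymptotic standard error comes from the Jacobian at the optimum.
Fits are flagged ill-conditioned when >80% of in-pellet points lie
below 0.05 mg l⁻¹ (signal within ~2 noise sd of zero); the estimate is
still returned, mirroring how near-anoxic pellets are tabulated with a
caveat. Replicates aggregate to per-hour mean ± sample sd.

Monte-Carlo performance at the study conditions (truth 900 µm² s⁻¹,
D = 2000 µm, 15 in-pellet points, noise sd 0.03 mg l⁻¹, 200 replicates):
bias ≈ 0.1%, spread ≈ 1% — comfortably inside the 10%/5% recovery
bounds asserted in the tests.

## Batch rates

Cubic smoothing splines per analyte, differentiated analytically, with
sign conventions making uptake rates positive for falling substrates.
The smoothing penalty defaults to generalized cross-validation; lam = 0
switches to not-a-knot interpolation (exact for polynomial records of
degree ≤ 3, which is the solver's regression anchor). For the 15-point,
12-h-sampled records the study design produces, GCV under-smooths for
derivative purposes; the package's documented choice for such records
is lam = 300, which recovers the generator's true peak rates with mean
errors of ~2–5% per analyte at 2% observation noise (asserted as a mean
over noise draws; single unlucky draws can reach ~10% for biomass,
whose absolute noise is largest). Derivatives are reported on a 1-h
grid with the record edges flagged (one-sided derivatives); peak ties
break toward the earlier time.

## Synthetic data

**Microprobe traces.** The film/pellet coupling fixes c_S; the trace is
rendered as bulk plateau (c_B, default 7.5 mg l⁻¹ — near the ~8 mg l⁻¹
air saturation), a boundary-layer segment one radius thick, and the
internal field, sampled at the probe step (default 50 µm; the grid is
anchored at the pellet surface, as an operator zeroing the probe on the
surface crossing would — without this the surface concentration is
never sampled and the fit convention biases D_eff upward). Gaussian
read noise (sd 0.03 mg l⁻¹) is added, values are truncated at zero and
censored at the detection limit with a per-point flag. The *rendered*
film profile is the continuous spherical-shell interpolation
c_S + (c_B−c_S)(2 − 2R/r) between R and 2R; it is used only to draw
plausible boundary-layer points — all fluxes use k_S = 2 D_medium/D
(a steady shell of finite thickness R would imply Sh = 4, so shape and
flux cannot both come from one quasi-steady film; the flux side wins).
Dead-pellet traces replace the internal field with the transient
no-reaction solution at a stated elapsed time, surface held at c_B.

**Batch records.** A deliberately simple declared model — not a claim
about *A. terreus* physiology, but a ground-truth machine: Monod growth
on lactose with organic-nitrogen co-limitation, the realised growth
rate the harmonic minimum of the Monod potential and a linear-phase cap
r_lin (emulating transfer-limited linear growth), lactose consumed for
growth (Y_XS) and maintenance, lovastatin formed in mixed
growth-associated mode gated by the lactose Monod factor. Defaults
(LAC₀ = 20 g l⁻¹ from the studied 2.5–40 range, X₀ = 0.1, N₀ = 0.5 g l⁻¹,
µ_max = 0.25 h⁻¹, K_LAC = 1.0 g l⁻¹, K_N = 0.05 g l⁻¹,
r_lin = 0.13 g l⁻¹ h⁻¹, Y_XS = 0.5, m_S = 0.008 h⁻¹, Y_XN = 25,
α = 5 mg g⁻¹, β_p = 0.16 mg g⁻¹ h⁻¹) put the trajectories in the
emulated study's printed ranges: biomass → 9.0 g l⁻¹ at ~0.12 g l⁻¹ h⁻¹,
lactose exhausted (<0.1 g l⁻¹) by 91 h with peak uptake 0.28 g l⁻¹ h⁻¹,
lovastatin → 83 mg l⁻¹ peaking at 1.4 mg l⁻¹ h⁻¹. K_LAC is set so the
exhaustion transition spans roughly one sampling interval; a much
smaller value would put curvature into the true rates that no smoother
could recover from 12-h samples. Observations carry multiplicative
Gaussian noise (default CV 2%) at 12-h sampling over 168 h; the exact
RHS rates are exported alongside on a 1-h grid. All randomness flows
from the scenario seed.

What the generators do *not* emulate — and hence what passing tests do
not show about real data: probe response time and stirring artifacts,
off-centre probe chords, radially varying biomass density and
diffusivity, pellet-to-pellet size distributions beyond a per-profile
diameter, and any mechanistic lovastatin pathway behaviour.

## Problem sizes

The test suite and acceptance script use: 20 random scenarios for
solver cross-validation, 1000 draws for the algebraic identity and the
regime sweep, a 5×5 (φ_m, β) grid for effectiveness accuracy, 200
Monte-Carlo replicates for diffusivity recovery, and 6 noise draws ×
3 analytes for batch peak recovery. These sizes give sampling errors
well below the asserted tolerances while keeping a full run in minutes
on one CPU.

## Known limitations

- The probe-through-centre assumption biases D_eff when violated; the
  package flags the assumption but cannot detect off-centre chords.
- The order-interpolated effectiveness is an approximation (2.4%
  worst case with the same-modulus convention); exact effectiveness is
  available from any numeric solution via `exact_internal_effectiveness`.
- The quiescent Sh = 2 film is the least-efficient transfer case;
  stirred systems have thinner films, so η_em computed here is a lower
  bound for agitated cultures.
- Transient fields are only available without reaction; transient
  uptake (e.g. during probe approach) is out of scope.
- Near-anoxic traces leave D_eff weakly identified; such fits are
  flagged rather than suppressed.
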