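# Methods

This note documents the models, numerical choices and limitations of
`phasekin`, module by module. Internal units are strictly SI (K, kg, m, J);
degrees Celsius, mg/mL (= kg/m³), μm and K/min appear only in CSV schemas
and example output.

## Flory–Huggins thermodynamics (`phase_thermo`)

The mixture is binary (one polymer, one solvent); the free energy per
lattice site in k_BT units is f = φlnφ/M + (1−φ)ln(1−φ) + χ(T)φ(1−φ), with
χ(T) = A + B/T. The entropy terms take their limit value 0 at φ = 0 and 1.
Volume fractions convert to mass concentrations via a constant solute
density ρ (1600 kg/m³ for RNA presets, 1500 kg/m³ for the cross-system
atlas), so 1 mg/mL ↔ φ = 6.25×10⁻⁷ at ρ = 1600.

**Binodal construction.** The common tangent is found in two stages:
a convex-hull (lower-envelope) scan of f on a composition grid, then
Newton refinement of the two equal-tangent conditions f′(φ₋) = f′(φ₊) and
f(φ₊) − f(φ₋) = f′(φ₋)(φ₊−φ₋) with the analytic Jacobian. The grid is
logarithmic in φ from 10⁻¹² up to φ_c and linear from φ_c to 1 (4000
points by default): for M ≈ 2000 the dilute binodal sits at φ ~ 10⁻⁴–10⁻⁷
and a linear grid would miss it entirely. Converged solutions satisfy the
tangent conditions to better than 10⁻⁹ k_BT. Temperature sweeps use Newton
continuation (warm-starting each temperature from the previous solution),
which makes the 0.003 °C supercooling grid cheap. Calls at or above T_c
return the degenerate binodal (φ_c, φ_c) rather than raising, so sweeps
are loop-safe.

**Critical point.** Closed form: φ_c = 1/(1+√M), χ_c = (1+1/√M)²/2,
T_c = B/(χ_c − A); an error is raised when χ(T) cannot reach χ_c at
positive temperature.

**Driving forces.** Δg₊ = −k_BT ln(φ/φ₋(T)) (negative iff supersaturated).
Δg₋ combines the per-molecule transfer term with the concentration-increase
term through the partition factor K; the lattice-site volume cancels out of
K and is never represented. Δg₋ is exactly zero at both binodal
compositions (the common-tangent identity makes the K·Δg product finite in
the φ→φ₊ limit; the endpoints are returned as exact zeros) and has a
single interior minimum.

**Tension models.** Three parameterizations of γ(T): constant; the Ising
temperature scaling γ₀((T_c−T)/T_c)^1.26; and the binodal-gap scaling
γ₀(φ₊−φ₋)^3.9. The exponents are fixed scaling constants, not fit
parameters. Both scaling forms vanish at T_c and are undefined above it.

**χ(T) fitting.** (A, B) are fitted to coexistence concentrations by
bounded least squares with M fixed by the caller; residuals are relative
(or σ-scaled) so the mg/mL-scale dilute branch is not drowned out by the
dense branch. Because the choice of weighting between branches is a
judgment call, a dense-only mode is provided alongside the default
equal-weight mode. Candidate parameter sets whose T_c falls below the
warmest data point are rejected with a large residual. The shipped presets
are (M, A, B) = (1000, 0.31, 75.0 K), (2000, 0.23, 98.8 K),
(4000, 0.19, 110 K); the m2000 set implies T_c = 64.5 °C.

## Classical nucleation theory (`cnt_rates`)

Clusters are spherical: W(n) = γ(36π)^⅓ v_m^⅔ n^⅔ + nΔg. The stationary
rate is assembled as the product J = ϑ z f_c ρ_m exp(−W_c/k_BT); the
closed forms

    z   = Δg² / (8π v_m √(γ³ k_BT))
    f_c = (48π² v_m)^⅓ c D n_c^⅓ = 8π c D γ v_m / |Δg|
    J   = ϑ D c √(Δg²/(v_m²γk_BT)) exp(−W_c/k_BT)

are derived consequences of that product, verified as identities in the
tests, never independent inputs. The sign convention stores Δg signed
(favorable = negative); every rate is defined as 0 for Δg ≥ 0. Rates are
computed in log space and exponentiated last, returning 0 below e⁻⁷⁰⁰, so
barrier-dominated regimes neither overflow nor warn. ϑ is a single scalar
shared by the void and condensate rates; ϑ = 1 corresponds to ideal
homogeneous, volume-diffusion-limited nucleation. The phase bookkeeping
is: voids use the dense-phase diffusivity D₊ and concentration (parent
phase) with the dilute-phase molecular volume v_m,₋ (nucleating phase);
condensates use D₋, the dilute concentration, and v_m,₊.

Not modeled: surface-integration-limited attachment, transient (time-lag)
nucleation, compressibility corrections, and two-step nucleation through
mesoscale clusters.

## Condensate transport (`condensate_transport`)

Method of lines on a fixed radial grid spacing; backward-Euler by default
(the boundary region is stiff after grid-point removal), with an explicit
option that enforces D·Δt/Δr² ≤ ½. Temperature is spatially uniform and D
temperature-independent. The center uses the symmetry limit
∂c/∂t|₀ = 6D(c₁−c₀)/Δr²; the outermost active point is pinned to the dense
binodal concentration at the current temperature, interpolated from a
pre-tabulated binodal over the ramp (0.05 K resolution, cubic).

**Shrinkage rule.** After each step, while the solute mass computed
*without* the outermost grid point exceeds the initial mass, that point is
removed and the new outermost point is pinned to the binodal. This discrete
rule keeps the radius tied to mass conservation; its granularity is one
grid shell, which bounds the mass error at roughly 3/n_r. The default
n_r = 500 intervals keep the total-mass excursion below 1% for a 20 μm
condensate over the full 55→36 °C protocol; halving Δr roughly halves it
(first-order convergence, as expected for backward Euler plus the discrete
interface).

**Time step and stopping.** Default Δt = min(ramp/1200, τ/100) clipped to
[10⁻⁴, 2] s, with τ = R₀²/(6D) the diffusive time scale. The run ends when
the profile is within 10⁻³ (relative) of the final binodal value
everywhere (the equilibration tolerance is a solver choice; the underlying
experiment defines "equilibrated" only qualitatively), or at the ramp end
when `hold=False`. Frames are stored about every (ramp + 2τ)/400 so both
the cooling window and the diffusive decay are resolved for the rate
quadrature.

## Void statistics and fitting (`void_analysis`)

N = ∫∫ 4πr² J_void dr dt by trapezoidal quadrature on the stored transport
frames, with J evaluated per grid node. Doubling space and time resolution
around the defaults changes N by ~1%. Because the trajectory is
independent of (γ₀, ϑ), each trajectory is reduced once to flat arrays of
the γ-independent node quantities (Δg₋, parent concentration, v_m,₋, the
tension shape factor s(T) with γ = γ₀s(T), quadrature weights); a fit
iteration then only re-exponentiates, which makes the Nelder–Mead search
(run in log₁₀(γ₀, ϑ) space from a log-spaced multistart grid, 5×5 by
default) cheap after the up-front simulations.

Critical sizes solve N(d) = target by bisection over d ∈ [10, 100] μm
(widened twice on bracket failure) to 0.1 μm, relying on the verified
monotonicity of N in d. The one-void stochastic band uses the Poisson
band constants N = 0.242 and N = 5.572, adopted as given; nucleation
counts are Poisson with mean N. The fit consumes per-rate critical sizes
(the mean diameter of single-void condensates), not raw counts — matching
how the experimental critical sizes are defined.

## Predictions (`nucleation_prediction`)

The supercooling sweep models a solution of constant composition cooled
below a reference temperature at which it sits exactly on the dilute
binodal (φ₀ = φ₋(T_ref) by default; an explicit composition can be
supplied). The measured dilute concentration (0.82 mg/mL for the
microdroplet assay) enters the rate prefactor only. v_m,₊ and γ(T) are
recomputed at every grid temperature, so the scaling tension forms are
handled exactly. The default grid resolution is 0.003 °C.

Δg_min inverts J(γ, Δg) = 10¹² m⁻³ s⁻¹ (a named constant, the
"biologically relevant" rate implied by the microdroplet counts) by
Brent root finding on ln J, which is strictly monotone in |Δg|. The
cross-system atlas uses one shared parameter set — 1 mg/mL, 300 K, solute
density 1.5 g/mL, D = 10⁻¹⁰ m²/s, ϑ = 1, φ = 0.2 for condensates and 0.5
for solids — because γ dominates every other input by orders of magnitude;
ϑ = 1 is the physically expected value for homogeneous nucleation and is
config-overridable. The packaged atlas CSV
(`data/tension_atlas_synthetic.csv`) names real condensate- and
solid-forming systems but carries constructed, order-of-magnitude tension
ranges and molecular weights (hence "synthetic" in the name); conclusions
drawn from it are ordering-level (condensates below RT, solids above),
not system-level.

Cell-scale counts use N = J·V·Δt with Δt = d²/(6D), the diffusive lifetime
of the driving force in a cell of diameter d, and the surface-area
consequence of an n-fold count change at fixed mass is the cube-root
factor n^⅓.

## Measurement reduction (`biophys_measurements`)

FRAP recovery and fusion aspect ratios are single-exponential fits
(unweighted least squares, log-linearized initialization, then
Levenberg–Marquardt refinement): I(t) = I_f −(I_f−I_s)e^(−t/τ) with
D = d²/(16τ), and A(t) = 1 + (A₀−1)e^(−t/τ) with capillary velocity
v = (d₁+d₂)/(2τ) — the dimensionally consistent form of the capillary
estimator. The FRAP prefactor 16 is adopted from the standard
circular-spot analysis and not re-derived. Viscosity follows
Stokes–Einstein, η = k_BT/(6πD R_h), with R_h between 5 and 20 nm as the
physically plausible hydrodynamic radius range for long poly-rA chains;
γ = vη then lands at the sub-μJ/m² scale. Viscoelastic (Maxwell)
corrections and the non-zero FRAP intercept are out of scope: both fits
assume purely Newtonian, single-timescale relaxation.

## Synthetic data (`synthetic_data`)

Generators emulate the reduced tabular observables of the study (no image
synthesis): coexistence points with multiplicative Gaussian noise (5%
relative by default, 8 temperatures from 25 to 60 °C); void-count
experiments with condensate diameters log-uniform over 10–100 μm, cooling
rates 0.5/1/2/5 K/min from 55 to 36 °C, and counts drawn Poisson(N); FRAP
and fusion curves with 2% multiplicative noise. Ground truth defaults are
the m2000 phase preset, constant γ₀ = 1.8 μJ/m², ϑ = 1.5×10⁻¹⁰,
D₊ = 1.3×10⁻¹³ m²/s, Mw = 2500 kg/mol. All generators are pure functions
of (config, seed) and the CSV writers are byte-deterministic.

For efficiency the void generator interpolates ln N monotonically (PCHIP)
in ln d from a 9-point diameter grid when many distinct sizes are drawn,
and computes N exactly per unique size otherwise. What passing tests on
these data do *not* show: the generators share the forward model with the
fitting code, so end-to-end recovery demonstrates identifiability and
correctness of the pipeline, not robustness to model misspecification
(polydispersity, temperature-dependent D, viscoelasticity, void–void
interactions) present in real data.

## Problem sizes used in tests and examples

Transport-heavy tests and the parameter-recovery study run at n_r = 100–150
grid intervals with four cooling rates and 3×3 multistarts; these choices
keep the suite in the minutes range while remaining inside the verified
convergence regime (the refinement tests bound the resolution error at
~1%, well below the 10% recovery tolerance). The tension-model
discrimination study uses three cooling rates, the minimum that
over-determines the two fit parameters.

## Known limitations

- Binary mixture only; no multi-component Flory–Huggins, no fitting of M.
- No solute exchange across the condensate interface, no interaction
  between condensates, no hydrodynamics or growth of voids, and no
  feedback of nucleated voids on the concentration field — N is an
  expected count of independent events.
- The Poisson band constants are used verbatim; their derivation is not
  reproduced here.
- Near T_c (within ~0.1 K) the Newton refinement of the binodal can fall
  back to the hull bracket, whose resolution then limits accuracy; all
  shipped workflows stay several kelvin below T_c.
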