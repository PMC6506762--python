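# Methods

`leafkin` predicts the temperature kinetics of a leaf (or any thin,
flat object) from the kinetics of a reference material under a
fluctuating environment, and inverts that prediction by Bayesian
inference to recover the temporal response of stomatal conductance
together with the thermal and optical properties that shape the
energy budget.

## Energy balance

For a horizontal two-faced object with areal heat capacity
k = ρ\*·C\*ₚ·l\* (J m⁻² K⁻¹), neglecting metabolic storage, the budget
is

    k dT/dt = Rn − C − λE
    Rn = α Iₛ − 2 θ ε T⁴ + L_d
    C  = 2 g_bh ρ Cₛ (T − T_air)

with α the shortwave absorbance, ε the emissivity, θ the
Stefan–Boltzmann constant, L_d the incident longwave aggregated over
both faces, g_bh the one-sided boundary-layer conductance to heat
(m s⁻¹), ρ and Cₛ the density and specific heat of humid air. The
latent term couples the budget to mass transfer:

    E   = (0.622 ρ / P_atm) (R T_leaf / P_atm) g_tw (e_s(T_leaf) − e_a)
    g_tw = (1/g_bw + 1/g_sw)⁻¹

with g_bw the molar boundary-layer conductance to water vapour
obtained from g_bh by the molar-density conversion, a 1.08
water/heat diffusivity correction, and a factor for the number of
transpiring faces (2 for an amphistomatous wheat leaf, 1 for a plate
wet on one side). λE enters the budget once under this aggregated
convention — the per-face alternative is available through
`transpiring_sides`, but mixing the two conventions double-counts.

**Reference differencing.** Writing the budget for the object of
interest (1) and a non-transpiring reference (2) exposed to the same
thermal environment and subtracting eliminates L_d, the flux that is
hardest to measure inside a growth cabinet or phenotyping platform:

    dT1/dt = [ k₂ dT2/dt + Iₛ (s₁α₁ − s₂α₂) + 2θ (ε₂T2⁴ − ε₁T1⁴)
               + 2ρCₛ (g_bh2 (T2 − T_air) − g_bh1 (T1 − T_air))
               − λE₁ ] / k₁

s₁, s₂ are per-object irradiance scales for setups where the
references sit at a site receiving less light than the leaf (here
300/430 of the nominal level); with equal scales the term reduces to
the familiar Iₛ(α₁ − α₂). The differenced trajectory is exactly
invariant to any *shared* longwave environment; this is tested
directly by simulating under constant, offset and strongly
time-varying wall temperatures and requiring the differenced
prediction to reproduce the forward simulation to < 1 mK.

## Stomatal kinetics

After a step light change, g_sw relaxes from its initial value g₀
toward a target G as a rescaled Gompertz sigmoid with lag φ and time
constant τ; during the light phase a slow linear drift s_l may be
superimposed:

    gs(t) = (G + s_l t − g₀) · S(t) + g₀
    S(t)  = [e^(−e^((φ−t)/τ)) − e^(−e^(φ/τ))] / [1 − e^(−e^(φ/τ))]

The rescaling guarantees gs(0) = g₀ exactly even for positive lags and
gs(∞) = G for s_l = 0 — this exactness is an explicit design goal of
the model and is asserted to 1e−9 in the tests. Over a
dark/light/dark schedule the model is applied piecewise: each phase
starts from the conductance the previous phase reached (continuity to
1e−12), targets that phase's steady state (g₁, g₂, g₃), and uses the
opening pair (τᵢ, φᵢ) when the target lies above the start value,
the closing pair (τ_d, φ_d) otherwise; s_l acts in the light phase
only, and the first dark phase starts at its own target so the
baseline is flat. gs is floored at 1e−6 mol m⁻² s⁻¹ before the series
combination to avoid the 1/g singularity.

## Air and radiation properties

Saturation vapour pressure uses Buck (1981) over liquid water;
moist-air density the ideal-gas partial-pressure mixture; Cₛ the
mass-weighted mixture rule with specific humidity; λ(T) the standard
linear fit (2.501 − 0.002361·T[°C])×10⁶ J kg⁻¹. These agree with
psychrometric references to well under 1% over 0–40 °C, and the
energy-balance outputs are insensitive at that level; each function
sits behind the `physics` module interface and can be swapped. PPFD
is converted to shortwave irradiance with a lamp-specific radiation
conversion factor (default fixture value 0.22 J µmol⁻¹ for white
LEDs); absorbance estimates are defined relative to that product, so
only α·(factor·PPFD) is ever identified.

## Signals

The ODE needs every driver as a differentiable function of time.
Slowly drifting channels (air temperature, RH, pressure) are fitted
with cubic smoothing splines on their native timestamps; the penalty
is chosen by generalized cross-validation when not supplied.
Irradiance is held as a zero-order step — a spline would ring at the
switches. Reference temperature traces have genuine slope
discontinuities at the light switches, so when the switch times are
known each phase is treated *separately*; a single spline rounds the
corner and biases the inferred heat capacity by ~2%.

For the references the default de-noiser goes further than a generic
spline (`StepResponseSignal`): within each phase a passive reference
is, to first order, a linear first-order system, so its trace is
fitted with an offset + drift + exponential backbone and only the
residual is given to a heavily penalized spline. This transmits
several times less camera noise into values and an order of
magnitude less into derivatives than a GCV spline — which matters
because reference noise leaks into the differenced prediction and a
GCV-splined reference measurably biases the fit (k by +15–20%). The
observed target trace is never smoothed: the likelihood owns its
noise. No signal extrapolates silently; evaluation outside the
fitted span raises.

## Numerics

The differenced ODE is integrated two ways. The reference path is
scipy's BDF with rtol 1e−6, atol 1e−8, max step 5 s, restarted at
every light switch (an adaptive method stepping across a jump in the
right-hand side loses local accuracy). The hot path used inside the
likelihood is a classical RK4 with a fixed step (1–6 s, far below
the 20–50 s thermal time constants) compiled with numba over
pre-tabulated driver arrays; each step's three stage times are
sampled one-sidedly (t+ε, midpoint, t+dt−ε) so that a switch falling
on a grid point never mixes the two sides of a discontinuity. The two
paths agree to < 1 mK against each other and against the RK4 run at
dt = 0.01 s, and the fixed-environment terminal state lands on the
algebraic root of Rn − C − λE = 0 to < 1 mK.

## Bayesian inference

The posterior over
θ = {g₁, g₂, g₃, φᵢ, τᵢ, φ_d, τ_d, s_l, k, α, g_bh, T(0), σ}
(or {g_surf, k, α, g_bh, T(0), σ} for a constant-conductance object
such as the leaf replica) uses a Gaussian likelihood applied
*jointly* to two predicted trajectories — one integrated against the
black reference, one against the white, sharing every parameter.
This joint comparison is what pins g_bh: only the correct value lets
both predictions converge on the same observed trace. The test suite
verifies this directly — the joint g_bh posterior lands on the
generating value to a few tenths of a percent and is more than twice
as narrow as a black-only fit's, whose g_bh is weakly identified and
noticeably biased by reference-noise propagation. A missing white
reference degrades to the black-only likelihood with a logged
warning.

Two covariance terms beyond iid noise are essential for calibrated
uncertainties. First, both predictions are compared with the *same*
observed trace, so the two residual vectors share the camera noise:
their cross-covariance is σ²I, and ignoring it double-counts the
observation and understates every width by up to √2. Second, the
de-noised references still carry a smooth residue of their own camera
noise which the differenced model transmits into the predictions as a
correlated ~5–10 mK error; the sharpest parameters (k above all)
would otherwise chase it. The default likelihood therefore uses the
full joint Gaussian with per-reference leakage covariances estimated
by Monte-Carlo: the raw reference is re-noised at its estimated noise
SD, re-de-noised, the difference propagated through the forward model
(48 probes per reference), and the resulting low-rank covariance is
marginalized analytically through a Woodbury identity in
sum/difference coordinates — per-evaluation cost stays O(n·m). A
small independent nugget (5 mK, the scale of the de-noising residue a
finite probe set cannot span) keeps the joint covariance
non-singular. The plain iid likelihood remains available
(`ref_noise_marginal=False`).

Default priors are weakly informative on physical ranges:
conductance targets U(0, 2) mol m⁻² s⁻¹; τ ~ LogNormal(log 600, 1) s;
φ ~ N(120, 120) s; s_l ~ N(0, 5e−5) mol m⁻² s⁻²;
k ~ N(900, 300) J m⁻² K⁻¹ truncated positive; α ~ U(0.4, 0.95) for
leaves (a replica faced with black tape needs the upper bound raised
to 1.0 — its absorbance is ~0.96); g_bh ~ U(0, 0.1) m s⁻¹;
σ ~ HalfNormal(0.1 K); T(0) ~ N(first observation, 0.5 K). Leaf
emissivity is fixed at 0.96 (not estimated), configurable. All
priors are overridable per fit.

Sampling uses the affine-invariant ensemble sampler with
differential-evolution moves, which handle the correlated posterior
far better than stretch moves here. The sampler is started from a
posterior-mode search: a tempered stage (σ held at a generous 0.05 K,
flattening the surface) followed by adaptive Nelder-Mead and
quasi-Newton polish; a global differential-evolution stage
(`map_method="de"`) is available for near-noiseless data whose
likelihood surface develops narrow compensating modes along the
light-target/slope ridge. Walkers are then initialized from the
Laplace approximation at the mode (finite-difference curvature,
eigenvalue-clipped): starting the ensemble at the posterior's own
width matters, because from a point start a short chain reports
spuriously narrow intervals.

Convergence is gated, not assumed: rank-normalized split-R̂ and bulk
ESS are computed with arviz over the walker ensemble, and a fit is
only reported `converged` when every parameter has R̂ < 1.1 and
ESS > 200. A fit failing the gates is flagged (and the CLI exits
non-zero), never silently returned. The reported model RMSE is the
RMSE of the posterior-mean trajectory, recomputed independently of
the sampler.

`FitConfig.chains`/`iterations`/`warmup` default to the conventional
3 × 500 (250 warmup) budget; the ensemble runs a multiple of
`chains` of at least 2·ndim + 2 walkers. The budgets used by the
validation suite are larger where the diagnostics demand it
(e.g. 24 walkers × 1200 iterations for the replica fit) and smaller
for the 20-replicate coverage study (48 walkers × 600 iterations at
dt = 6 s, thinning observations to the integration grid); diagnostics
gate correctness, not iteration counts.

### Sensitivity analysis

For a fitted θ̂ the forward model is perturbed one parameter at a
time, bisecting the value until the maximum absolute deviation of the
trajectory from baseline reaches a target (default 0.5 K) in each
direction; when a physical bound (e.g. 0, or α ≤ 1) is hit first, the
bound and the deviation actually achieved there are reported instead.
Each record carries the time and protocol phase of the peak
deviation — steady-state targets act over their own phase and the
start of the next; lag/time-constant parameters act transiently after
the corresponding switch.

## Synthetic experiments

The generator forward-simulates every object with the full
(undifferenced) budget under a shared longwave environment
L_d = 2θT_wall⁴ (wall tracks the air temperature by default; constant
or arbitrary piecewise-linear walls exist specifically to probe the
differencing). The emulated protocol is 10 min dark, 1 h at
430 µmol m⁻² s⁻¹, 1 h dark, references at 300/430 of the nominal
light, frames every 3 s, iid Gaussian camera noise of 0.03 K, and
slow piecewise-linear drifts of air temperature (+1 K over the light
hour, half-recovering) and RH (−0.05, half-recovering) — the drift
magnitudes are order-of-magnitude cabinet values, configurable.
Fixture object properties: leaf α 0.70, ε 0.96, k 900 J m⁻² K⁻¹,
g_bh 0.0143 m s⁻¹ (equivalent to g_bw ≈ 1.28 mol m⁻² s⁻¹ over both
faces), two transpiring faces; aluminium references (0.95 mm,
k ≈ 2309 J m⁻² K⁻¹) painted black (α 0.95) and white (α 0.30), both
with thermal-infrared ε ≈ 0.95; replica plate k 2400 J m⁻² K⁻¹ faced
with black tape (α 0.96, ε 0.97), transpiring from one face through
a perforated membrane. Stomatal fixture kinetics: g₁ 0.05, g₂ 0.5,
g₃ 0.025 mol m⁻² s⁻¹, τᵢ 300 s, τ_d 600 s (opening about twice as
fast as closing), φᵢ = φ_d = 150 s, s_l 0. These are plausible
mid-range values for well-watered wheat, chosen once as fixtures —
not measured claims.

What the generator does *not* emulate: spatial heterogeneity within
the leaf (patchy stomata are represented only insofar as separate
regions would be fitted separately), radiometric image formation,
camera drift and non-uniformity artefacts, wind-speed fluctuations of
g_bh, or metabolic energy storage. Passing tests therefore
demonstrate the correctness and identifiability of the method under
its own assumptions — iid camera noise and a closed budget — not
robustness to instrument systematics.

## Replica membrane conductance

Each cylindrical pore of radius r and depth d conducts
D πr²/(d + πr/4): molecular diffusion along the pore plus a single
end-correction of equivalent length πr/4 (the half-space access
resistance of a disk). The areal molar conductance is the pore
density times that, times P/(RT); D = 2.42e−5 m² s⁻¹ at 20 °C scaled
as T^1.75/P. The nominal geometry (0.5 mm diameter, 40 µm depth,
160 pores inch⁻²) gives 0.207 mol m⁻² s⁻¹. The quoted 3 mm grid
pitch is inconsistent with that density (3 mm pitch would give
~111 inch⁻²); the density is taken as authoritative because it
reproduces the independently confirmed conductance, and pitch is used
only for the geometric sanity bound diameter < density^(−1/2).

## Boundary-layer estimation

Two references cut from the same aluminium sheet but painted black
and white separate in temperature under light in proportion to how
weakly they are coupled to the air; predicting the white reference
from the black through the differenced model (no latent term) and
least-squares adjusting a single constant g_bh recovers the
generating value to 0.1% on noiseless synthetic data and ~5% at
camera noise, is invariant to shared longwave offsets, and refuses to
estimate when the references show no usable contrast
(max |T_b − T_w| below 5× the noise SD). The same g_bh is estimated
as a shared parameter inside the joint Bayesian fit; the two routes
agree within the posterior uncertainty on synthetic data.

## Validation scales and known limitations

The acceptance suite runs the full-length protocol for the replica
recovery (posterior-mean conductance within 5% of the geometry value,
posterior SD ≤ 0.005 mol m⁻² s⁻¹, convergence gates enforced) and a
20-replicate coverage study of the 95% credible intervals for
{g₁, g₂, g₃, τᵢ, τ_d, φᵢ, φ_d, k, α, g_bh} at reduced MCMC budget.
The coverage study is a deliberately demanding check and currently
documents a real limitation: with camera noise on the references the
intervals of the most sharply identified parameters (g_bh above all,
also g₃, k, the light target and the opening lag) remain narrower
than the realized replicate-to-replicate scatter, so their measured
coverage falls below the nominal 95% (the broader parameters pass).
With noiseless references the displacement disappears (the
near-noiseless recovery test), isolating reference-noise
transmission as the cause; see Known limitations.
Unit and property tests use compressed schedules (2–27 min) chosen to
keep the default suite within ordinary CI runtimes; the physics does
not change with the schedule length, only posterior widths do.

Known limitations:

* Reference camera noise survives de-noising as a correlated ~5 mK
  residue in the predictions. The marginal likelihood prices it
  honestly, but individual noise realizations can still displace the
  posterior of the sharpest parameters by a few of their (correctly
  widened) standard deviations — interval coverage is calibrated,
  point estimates on any single record are not guaranteed to better
  than a few percent.
* With camera noise the 13-parameter posterior develops deep
  secondary modes; the global (differential evolution) tempered mode
  search is needed to find the main basin reliably, and the
  convergence gates must be respected.
* A black-only likelihood leaves g_bh weakly identified and biased
  high; use both references.
* The analytic sigmoid applies to step light changes; continuously
  varying light would need the underlying ODE form of the stomatal
  model, which is out of scope.
* Negative transpiration (condensation) is clamped to zero with a
  logged warning; dew formation is outside the model.
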