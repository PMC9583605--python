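# Methods

`mcpafate` simulates the fate of the phenoxy-acid herbicide MCPA in an
unsaturated, layered arable soil when the microbial degrader community is
aggregated at the millimetre scale, and diagnoses the resulting slow-down of
macroscopic degradation with scale-transition (spatial-moment) theory.  This
note documents the model, its numerical treatment, the synthetic-data
generator, and the design choices that were genuinely open.

## Domain and water flow

The simulated column is 0.3 m wide and 0.9 m deep (three hydraulically
distinct layers: 0–30, 30–60, 60–90 cm), extended by a 1.1 m buffer with the
deepest layer's properties so the free-drainage outflow boundary does not
influence the region of interest.  An out-of-plane thickness d_z = 0.1 m
converts areal application rates and reports absolute masses.  The mesh is
5 mm × 5 mm in the top metre, 50 mm vertically below, with factor-2 geometric
refinement of the top 2 cm (1.25 mm cells under the infiltration boundary)
where initial concentration gradients are steep.

Variably saturated flow follows the Richards equation with van
Genuchten–Mualem constitutive relations (Table-defaults per layer: θ_s, θ_r,
α_VG, n_VG, l_VG = 0.5, K_s).  The solver is a cell-centered finite-volume,
mixed-form (θ–h) scheme with modified-Picard iteration (head increment
tolerance 1e-6 m), upstream-weighted inter-cell conductivity, adaptive time
steps with cuts on iteration failure, and forced step boundaries at every
forcing discontinuity.  Because hydraulic properties and boundary conditions
are uniform in x in every scenario, the 2-D flow field is exactly x-uniform;
the flow problem is therefore solved on a single column and broadcast across
the width.  Boundary conditions: prescribed infiltration flux at the surface,
free drainage (zero pressure-head gradient, q = K(h)) at the bottom.
Spin-up under the measured mean net infiltration of 0.56 mm/d produces the
initial state; the computed topsoil settles at ≈83% saturation and a mean
matric potential of ≈−0.005 MPa.  Global water balance closes to better than
1e-3 (relative) in all runs; the day-20 pressure profile changes by <1% (L2)
when the grid is halved.

Two forcing regimes with matched one-year totals are built in: CLR
(0.56 mm/d throughout) and HRE (0.56 mm/d on days 0–2, day-long 40 mm/d
events on days [2,3) and [5,6) each followed by two dry days, 0.35 mm/d from
day 8).  The day-indexing of the events is ambiguous in the source
description; with the convention used here the HRE total (≈206 mm) slightly
exceeds CLR (204.4 mm).

## Degrader fields (synthetic-data generator)

The generator emulates spatially aggregated degrader abundance measured as
tfdA gene counts.  The horizontally averaged biomass profile is constant
B_TS = 12.21 µmol C/kg (equal to 1.11e8 genes/kg × f_m/g = 1.10e-7 µmol
C/gene) in the topsoil (d_TS = 0.3 m) and decays as exp(−γ(y−d_TS)) with
γ = 3 m⁻¹ below.  A log-Gaussian Cox process places individual genes: a
stationary Gaussian field with exponential covariance σ² exp(−r/β) is
synthesized on a 1 mm grid by FFT circulant embedding (padding grows until
the embedding is positive definite; residual negative eigenvalues are
clipped), given the depth-dependent mean ln(λ̄(y)/f_S) − σ²/2 so the process
intensity equals the measured profile, exponentiated, and Poisson-thinned
into per-cell gene counts.  λ̄(y) converts biomass to areal intensity through
a virtual thin-section thickness d_v,STS = 0.05 mm (topsoil: ≈6.9e6
genes/m², ≈172 genes per 5 mm cell).  Counts are aggregated to the 5 mm
reaction mesh; sub-5-mm heterogeneity is intentionally not represented.
A cell is "colonized" above 100 genes/g soil; at 5 mm resolution a single
gene (≈645 genes/g) already exceeds this.

Heterogeneity scenarios are defined by ensemble metrics of the generated
topsoil fields: spatial CV of cell biomass of 0 (HOM, exactly uniform), 16
(LOW), 161 (HIGH) and 400% (EXTR), with the practical range (3× the range of
a zero-nugget exponential semivariogram fitted to the empirical semivariogram,
isotropic, 3.3 mm bins, 50 mm cutoff, bins weighted by pair counts) held at
27 ± 2 mm.  An automated calibrator replaces manual tuning: σ² is updated
through the log-normal identity CV² ≈ exp(kσ²) − 1 with k estimated from the
measured ensemble, β multiplicatively against the measured practical range,
with a fresh confirmation ensemble before accepting convergence (suppressing
stopping on lucky draws).  The shipped characteristic values are the
calibrator's output on the 0.3 m × 0.3 m topsoil panel: σ² = 0.0253/1.687/
3.967 and β = 9.0/9.6/17.3 mm for LOW/HIGH/EXTR.  β for EXTR exceeds 9 mm
because cell aggregation, Poisson noise and the zero-nugget fit all bias the
fitted range downward; the calibration is deliberately against the *measured*
estimator, not the underlying correlation length.  Scenario ensembles consist
of realizations passing per-field acceptance limits (topsoil CV within ±10%
of the target and practical range within 27 ± 2 mm — the stand-in band noted
below); rejected draws are redrawn.  Per-field CV estimates of the EXTR
ensemble are heavy-tailed, which is why the acceptance step matters there.

What the generator does *not* emulate: real fields have no reason to follow
an exactly exponential pair correlation, the gene-to-biomass conversion is a
fixed factor rather than a community property, and abundance is static (no
growth, death or dispersal).  Passing tests therefore show that the *model
chain* behaves as specified, not that field soils do.

## Reactive transport

MCPA (2 kg/ha, 6 mg over the 0.3 m × 0.1 m surface) is applied at t = 0 to
the upper 1.5 cm as a logistic (smoothed-step) vertical profile of 3 mm
width, mass-normalized, and pre-partitioned to Freundlich equilibrium; the
realized maximum total concentration is ≈10.7 mg/kg.  The governing balance
per bulk volume couples storage in the dissolved (θC_L) and sorbed (ρ_b C_S)
phases, advection with the Darcy flux, Millington–Quirk diffusion
D_s = D_m θ^(10/3)/θ_s² plus Bear dispersion (λ_L = 0.03 m, λ_T = 0.01 m,
tensor built from the pore velocity and multiplied by θ), Freundlich
equilibrium sorption C_S = K_F C_L^n_F (K_F = 1.79e-3, n_F = 0.86), and
Monod degradation R = μ_max ρ_b B C_L/(K_M + C_L) (μ_max = 2.94e-4 s⁻¹,
K_M = 1.93e6 µmol C/m³) by the immobile degrader field.  No degrader growth:
the population is assumed at equilibrium for a single application.  Solute
boundaries are no-flux except advective outflow at the bottom.

Discretization: implicit cell-centered finite volumes; first-order upwind
advection with a van Leer (TVD) deferred antidiffusive correction — enabled
by default because pure upwinding roughly doubles the dispersive tail that
controls detectability at 20–30 cm and leaching at 30 cm; implicit
diffusion/dispersion and reaction; Picard iteration on the sorption capacity
K_F n_F C_L^(n_F−1) (relative tolerance 1e-9, concentration floor
ε = 1e-9 µmol C/m³ regularizes the n_F < 1 singularity).  Flow and transport
are co-stepped (the dilute solute does not feed back on flow); the transport
scheme consumes a water content advanced by the discrete face fluxes, making
it exactly conservative against the flow field.  Time steps: 0.2 d, dropping
to 0.01 d whenever the forcing exceeds 5 mm/d so event fronts stay below
CFL ≈ 0.7 in the finest cells.  The MCPA ledger (storage + degraded +
exported = applied) closes to ~1e-11 in practice, far inside the 0.1%
requirement.

## Scale-transition decomposition

For Monod kinetics with spatially uniform rate parameters, the macroscopic
(topsoil-averaged) rate is expanded to second order around the mean substrate
and biomass concentrations: R̄ = MFA + COV + VAR + ΣHOT, with
MFA = R(C̄, B̄), COV = μ_max ρ_b K_M/(K_M + C̄)² · Cov(C, B),
VAR = −μ_max ρ_b B̄ K_M/(K_M + C̄)³ · Var(C) ≤ 0, and ΣHOT defined as the
residual so the identity is exact by construction.  The Var(B) term vanishes
because R is linear in B.  Moments are population statistics weighted by cell
volume (the averaging operator is a volume integral, not a sampling
estimator), evaluated over the 0–30 cm topsoil at the daily output cadence —
a diagnosis of stored fields, not part of the dynamics.  The dimensionless
correction (R̄ − MFA)/MFA is invariant under rescaling μ_max.

## Scenario presets and problem sizes

Two presets share every code path.  The `full` preset is the reference
geometry (0.3 m × 0.9 m + buffer, 365 d, 100 realizations).  The `desk`
preset — 0.1 m wide, 0.6 m deep, 20–60 d, 3–5 realizations — is the
package's own choice of problem size for the ensemble-bearing property
checks and the analysis drivers: the heterogeneity contrasts (residual
ordering, covariance control, the HRE/CLR sign flip) are already fully
expressed at this scale, and per-realization acceptance filtering is skipped
there because per-field metrics on the small panel are too noisy to filter
meaningfully.  Detectability and DT50 anchors use the full-geometry column in
its exact pseudo-1D (HOM) form, where the x-dimension collapses.

Detectability is the total (interpolated) time an interval-mean concentration
is at or above 3 µg/kg — identical to the last-crossing time for series that
start detectable, and the length of the detectable window for intervals the
pulse reaches only after rain events.  DT50 counts degradation only
("removal" excludes the ≤0.1% exported across the bottom boundary).
Leachate metrics at the 30 cm plane include both advective and dispersive
flux; the reported concentration is the flux-weighted plane mean.  Ensemble
summaries use mean ± SEM and normal-approximation 99% CIs (±2.576·SEM);
with ≥100 realizations a t-based multiplier would be indistinguishable.

## Known limitations

* Richness of the initial pulse: the exact "steep gradient" shape of the
  applied layer is not specified by the source; the logistic profile used
  here peaks at ≈10.7 mg/kg rather than the reported ≈9.1 mg/kg.  Outcome
  metrics are insensitive to this detail.
* The desk EXTR-HRE ensemble pushes ≈3.8 µg/kg into the 30–40 cm interval,
  marginally above the 3 µg/kg threshold, consistent with the model's
  slightly higher leaching (≈0.11% of applied); deeper intervals stay an
  order of magnitude below the 20–30 cm signal.
* The per-field acceptance band (±10% relative CV) is a configurable
  stand-in; the exact published limit expression was not recoverable.
* Preferential flow, surface runoff, evaporation seasonality, root uptake,
  sorption kinetics/hysteresis, degrader growth and repeated applications
  are all out of scope by design.
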