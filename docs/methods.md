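# Methods

## Model structure and assumptions

The lake is represented as three well-mixed boxes — air, water and
sediment — each with sub-phases (gaseous + aerosol; dissolved + suspended
solids; porewater + solids).  Chemical state is expressed as fugacity
*f* (Pa); concentrations follow *C = f·Z*.  Fugacity capacities use the
standard Mackay conventions:

| phase | Z, mol m⁻³ Pa⁻¹ | note |
|---|---|---|
| gaseous air | 1/(R·T_K) | R = 8.314 |
| dissolved water | 1/H(T) | |
| suspended / sediment solids | Koc·oc·ρ·10⁻³/H(T) | Koc in L/kg, ρ in kg/m³; 10⁻³ converts L→m³ |
| aerosol | 6×10⁶/(P_S,L(T)·R·T_K) | Junge-type, subcooled-liquid vapor pressure |

Bulk compartment capacities are the volume-fraction weighted sums of
their sub-phases.  The aerosol convention is an assumption (several
exist in the literature); it enters only through the small X13-weighted
terms.  No biota/plankton phase is modelled: partitioning to suspended
matter is organic-carbon sorption only, which is known to understate
particle-bound concentrations in plankton-rich water columns.  Passing
tests therefore say nothing about phytoplankton-mediated transport.

Henry's constant and the vapor pressure are corrected from 25 °C with a
log-linear (van't Hoff / Clausius–Clapeyron) form,
log₁₀P(T) = log₁₀P(25) + A·(1/298 − 1/(T+273)).  The 273/298 offsets of
the published empirical form are kept verbatim in this correction, while
Z computations use T+273.15; the inconsistency is below 0.06 % and far
inside parameter uncertainty.  A third optional slope
(`temp_coeff_fugacity_ratio`, default 0) is accepted for a separate
fugacity-ratio correction; by default that dependence is folded into
H(T).

## Process conductances

Air–water diffusion uses two-film theory with Southworth's empirical
coefficients — air film K12 = 11.375(WS+RS)(18/MW)^0.5, water film
K21 = 0.2351·RS^0.969(32/MW)^0.5·a/h_W^0.673 with
a = exp[0.529(WS−1.9)] above 1.9 m/s — combined in series:
D12d = D21d = A/[1/(K12·Z_air) + 1/(K21·Z_water)].  K12/K21 are taken to
produce m/h with the stated constants; this units choice is recorded
here once and used consistently.  Dry deposition, wet particle
scavenging (rain·scavenging ratio·X13), rain dissolution, sedimentation,
resuspension (K42r = 3×10⁻⁸·WS/h_W, m/h) and sediment–water diffusion
(molecular diffusivity / L4 with a porosity^1.5 correction, overridable)
follow the standard D = k·A·Z pattern; degradation is D = km·V·Z_bulk and
advection D = Q·Z.  Air advection out is treated as a loss term
(+D10t·f₁ among the air losses): the alternative sign would make
advective outflow a gain and violates mass balance.  A wastewater input
T02h is carried through the ledger but defaults to zero.  The background
air concentration entering with air advection is a single series (C1).

## Dynamics and numerics

The coupled balance is advanced by classical RK4 at a 1-hour step
(configurable sub-hourly).  Forcings are held stepwise over their native
period (hour/day/month) — no interpolation — which keeps period budgets
exact; within each hour the system is linear with constant coefficients.
Z and D values are refreshed from the held forcings every step
(temperature correction included); only the water volume varies within a
day (hourly depth).  Initial conditions default to the steady state of
the first hour's coefficients, avoiding arbitrary spin-up transients in
a ten-month window; explicit initial fugacities can be supplied.
Negative fugacities (possible only for unphysically stiff steps) are
clipped to zero with a warning.  Ledger fluxes are recorded against the
RK4 stage-averaged fugacity ỹ = (y₁+2y₂+2y₃+y₄)/6, so the discrete
per-step identity V·Z·Δf = Δt·(gains − losses) holds to rounding error
and the annual budget closes against the inventory change
Σ V·Z·Δf at ~10⁻¹⁴ relative (the test tolerance is 10⁻⁴).  With
time-varying depth and temperature the "inventory change" is defined by
that same per-step sum, which is the quantity the balance equations
conserve.

## Synthetic forcing generator

The generator emulates a subtropical monsoon climate over a large
shallow lake: daily temperature = 16 °C annual mean ± 13 °C seasonal
sinusoid (peak late July) + N(0, 2 °C) noise; daily wind as a lognormal
AR(1) process (median 2.8 m/s, log-SD 0.35, day-to-day autocorrelation
0.7); hourly depth 3.0124 m ± 0.30 m seasonal with small jitter and a
hard floor; daily rain rate lognormal (median 8×10⁻⁵ m/h) with a summer
enhancement; monthly advection volumes, particle fractions and
background concentrations drawn lognormal around fixed medians
(air advection 2×10¹⁰ m³/h tied in = out, river inflow/outflow
4×10⁵ m³/h, background air concentration ~16 pg/m³, river concentration
~870 pg/L).  K12/K21/K42r are derived from wind and daily-mean depth.
What the generator does **not** emulate: storm events and episodic
resuspension, rain intermittency (rain is continuous at a low rate),
within-month correlation between advection and rainfall, and trends
across years.  Tests that pass on these synthetic series therefore
validate the numerics and the process formulation, not site-specific
predictions.

## Default parameters

Lake geometry and sub-phase fractions (area 7.581×10⁸ m², air height
100 m, mean depth 3.0124 m, sediment depth 0.1 m, X13 = 7.6278×10⁻¹¹,
X23 = 1.2631×10⁻⁵, sediment solids 30 %, organic carbon 16.7 % suspended
/ 0.46 % sediment) are the lake's published morphometry.  The
physicochemical and kinetic defaults are generic literature-range values
for α-HCH — MW 290.83 g/mol, H(25 °C) 0.735 Pa m³/mol, subcooled-liquid
Ps(25 °C) 0.06 Pa, Koc 1000 L/kg, degradation half-lives ≈ 60 d (air,
OH radical), ≈ 2 a (water) and ≈ 100 d (sediment; anaerobic degradation
of α-HCH is faster than aerobic), correction slopes 2600 K (H) and
3700 K (Ps), dry deposition 10.8 m/h, settling 0.05 m/h, surface flow
0.05 m/s, scavenging ratio 2×10⁵, solids density 2400 kg/m³, L4 = 5 mm —
chosen once as plausible defaults and **not** calibrated to any site
measurements.  Absolute budget magnitudes (t/a) therefore characterise
these defaults, not the real lake.  All are overridable via YAML.

## Sensitivity analysis

Static parameters are screened one-at-a-time at ±10 % around their base
value against the annual mean concentrations of the three main phases.
The Morris coefficient averages relative elementary effects over a
percent-step ladder; the table's two-point form (−10 %, +10 %) makes
S and Cs agree exactly up to sign.  Cn = Cs·CV weights each slope by an
assigned coefficient of variation (largest for degradation rates,
sediment depth and diffusion path length; smallest for geometry and
densities); the CV table is configurable.  The gas constant is excluded
from the sweep.  Dynamic series get SCV via mean-preserving scaling of
deviations (x′ = x̄ + (1+δ)(x−x̄), δ = +10 % by default, clipped at each
series' physical floor with the realised CV change measured after
clipping); how the original analysis induced its input-CV change is not
specified anywhere, so this mechanism is a documented choice of this
package, with output CV measured on the monthly mean concentration
series.

## Monte Carlo uncertainty

All parameters except temperature are sampled lognormal; temperature is
normal.  Truncation at one dispersion is applied on the sampling scale
(geometric mean ×/÷ geometric SD; mean ± SD) by rejection.  Static
parameters get one draw per run; monthly-scoped parameters one draw per
month, applied as multiplicative factors on the base series (additive
offsets for temperature).  Only a sensitive-parameter subset is varied
(default: top-quartile Cn/SCV or a curated default list); the rest stay
at base values.  Monthly outputs are summarised by the median and
semi-interquartile range (Q3−Q1)/2 with linear-interpolation quartiles —
the quartile convention is fixed here because none is standard.
The reference analysis used 2200 runs; the acceptance checks use a
200-run ensemble on a two-month window, which exercises the identical
code path at smaller problem size.

## Degradation-rate recovery

As an end-to-end check of the modelling stack, synthetic monthly
sediment observations generated at a known km4 are inverted by grid
search (31 log-spaced candidates over 0.4–2.5× the base rate) minimising
the squared log-concentration error; the recovered rate lands within the
grid resolution (~5 %) of the truth.

## Known limitations

- No plankton/biota phase; suspended-solid concentrations will be biased
  low in eutrophic conditions.
- Fixed-step RK4 only; no adaptive or stiff solvers.  The 1-h step is
  stable for realistic rate constants but not for arbitrarily large
  D/VZ ratios.
- Advection volumes and background concentrations in the generator are
  uncalibrated medians; absolute t/a budgets scale with them.
- Monthly forcings change discontinuously at month boundaries (hold, not
  interpolation), so interface fluxes can step visibly at month edges.
- Parameter draws are independent: no correlation structure and no Latin
  hypercube stratification.
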