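# Methods

## Model and conventions

The disposition model is a linear two-compartment system for blood lactate
with irreversible loss from the central (sampled) pool.  States are
*increments above the basal steady state*: the basal level P1 enters
predictions only as a uniform additive offset, and basal endogenous
production is recovered afterwards from the steady-state identity
`Ra = L(0,1)·P1·P2` (at baseline, with no infusion and zero derivatives,
irreversible loss of the basal pool content must equal the metabolic input
sustaining it).  This incremental convention matches disposition fits
displayed with a uniform offset to the pre-infusion mean and keeps the
three unit conventions directly comparable.  The alternative — simulating
absolute amounts with an explicit endogenous inflow — is algebraically
equivalent for a linear system and is not separately implemented.

Rate symbols follow the SAAM-family convention `L(i,j)` = fractional flow
to compartment *i* from *j* (min⁻¹).  Fractional rates are unit-invariant;
amounts are mmol in the S convention and mmol/kg in U/N, so S↔U conversion
rescales doses by body weight and maps the scale parameter as
`K1 = 1/(P2·weight)`.  This makes unit invariance a *testable identity*:
S-mode and U-mode fits of the same data must yield identical fractional
rates and predictions, and do (≤1e−6 in the test suite).

## The three infusion portrayals

* **Rectangular (S, U)**: delivery at dose/T for exactly the intended T
  (15 min), trusting the pump.
* **Sensed (N)**: delivery at dose/DT for an *adjustable* duration DT.  A
  copy of the pump signal feeds an n-cell delay chain (default n = 8, per
  cell drain k = n/DT; impulse response Erlang(n, k) with mean DT and
  variance DT²/n).  The cumulative chain exit tracks the delivered dose
  with a lag; its crossing of a configurable fraction of the dose (default
  0.99) marks delivery as complete.  Detection is by monotone root
  bracketing on the closed-form cumulative exit (regularized incomplete
  gamma functions), so the crossing is unique.  DT is estimated, so a pump
  that ran slow or long is absorbed into the fit rather than corrupting
  the rate constants.
* **Chain-in-path variant**: `delivery="chain_exit"` routes the
  Erlang-smoothed chain exit into the blood instead.  This soft-delivery
  variant is retained for exploring rhomboidal delivery shapes, with a
  caveat: smoothing the delivery obliterates the fast-phase information
  (the fast half-life here is ~1.5–1.8 min while the chain keeps
  delivering ~10 min past DT), inflating rate-constant CVs by an order of
  magnitude and making U-vs-N comparisons structurally misspecified in
  both directions.  It is therefore not the default and not used in the
  headline analyses.

A fault injector emulates misbehaving pumps (linear slowdown, early stop,
trapezoidal ramp); slowdown and ramp conserve the dose by construction.

## Solution methods

For piecewise-constant inputs the system is solved *exactly* by
propagating the augmented matrix exponential `exp([[M, b], [0, 0]]·Δt)`
segment by segment (batched over output times), with cumulative
irreversible loss carried as an extra state so mass balance is checkable
to machine precision.  A closed-form biexponential convolution of the
rectangle is used as the fast path inside fitting.  An adaptive stiff
integrator (LSODA, rtol 1e−8, atol 1e−10, integrated per segment so the
switch discontinuity is never smoothed over) handles arbitrary delivery
shapes and serves as an independent cross-check; the two paths agree to
~1e−8 mmol/L in the tests, and the bolus solution agrees with the
analytic biexponential to better than 1e−6.

Micro↔macro interconversion uses the exact eigen-identities
`α+β = L01+L21+L12`, `αβ = L01·L12` and the standard bolus coefficient
formulas; the repeated-root case α = β is treated as a degeneracy error
(the study design produces clearly biphasic data), and the
one-compartment limit is flagged with a warning rather than silently
returned.

## Estimation

Weighted least squares with the fractional-SD error model
`wᵢ = 1/(fsd·yᵢ)²`, fsd defaulting to 0.05 — the SAAM-family convention
for concentration assays and the same CV used by the synthetic noise
model.  The basal level carries a Gaussian prior centered at the mean of
the pre-infusion replicates with width equal to their SEM (floored at
1e−6 mmol/L and flagged when replicates are degenerate); the prior enters
the residual vector as one extra row, so the objective is
`Σ wᵢ(yᵢ−ŷᵢ)² + ((P1−m)/s)²`.  Pre-infusion samples inform the fit *only*
through this prior — including them as ordinary observations as well
would count the same information twice.  As s→0 the fitted baseline pins
to the prior mean; as s→∞ it matches the unpenalized fit (both verified
numerically).

Positive parameters are estimated on the log scale inside a bounded
trust-region least-squares solver (rates 1e−4–5 min⁻¹, pool 0.01–5 L/kg
with the K1 bounds scaled by weight, DT 3–60 min, baseline 0–5 mmol/L;
macro coefficients 1e−4–50 mmol/L).  The bounds are a generous
physiological envelope (half-lives from 8 s to ~5 days); without them a
weakly identified or misspecified fit can run a rate to numerical
infinity along a likelihood ridge.  Initialization is deterministic and
neutral — all rates 0.1 min⁻¹, pool 0.5 L/kg, baseline at the prior mean,
DT at the nominal duration — with a small deterministic grid of rescaled
starts retried only if the first attempt fails or misfits grossly.
Convergence tolerances are 1e−12 (xtol/ftol/gtol).  Standard errors come
from the inverse Gauss–Newton Hessian `(JᵀJ)⁻¹` of the weighted problem,
mapped to the natural scale by the delta method; a singular Hessian falls
back to the pseudo-inverse with a warning.  Macro fits fix the baseline at
the pre-infusion mean (configurable), resolve the A/α vs B/β labeling by
sorting α > β at convergence, and flag single-exponential collapse.

Kinetic imputation (pseudo-observations from a converged macro fit) is
provided as a data-augmentation utility; imputed points are tagged and
excluded from subsequent standard errors by default.  Note that a macro
curve anchored at the infusion end is only valid where delivery has truly
stopped, so imputation should not be used to densify data generated with
delivery still in progress.

## Dependency panel and concordance

The 15-quantity panel is the standard two-compartment set — V1, Vss,
V_area, CL, distributional clearance, α, β, their half-lives, bolus A and
B for the protocol dose, AUC₀₋∞ above baseline (dose/CL), MRT (Vss/CL),
k_elim = L01 — plus endogenous production Ra.  The source analysis names
15 common dependencies without enumerating them; this concrete set is the
package's choice, and model-comparison results depend only on the same
panel being computed from both models, which holds by construction.  AUC
from the closed form agrees with trapezoid integration plus a β-tail
correction within 1%, and the whole panel is invariant under S↔U
conversion.

Lin's concordance correlation coefficient uses population (divide-by-n)
moments, with the sample-moment variant behind a flag; its standard error
is Lin's asymptotic variance of the Fisher-z-transformed estimate mapped
back by the delta method.  Panels are compared on log scale by default
because the dependencies span four orders of magnitude; raw scale is a
flag away.  The reduced major axis (slope sign(r)·s_y/s_x through the
centroid) is reported and plotted alongside the identity line.

## Synthetic study generator

The generator emulates the equine protocol: 13 baseline replicates every
2 min before the infusion; 5 samples during the 15-min infusion (minutes
3, 6, 9, 12, 15); post-infusion samples every 2 min for 15 min, then
geometrically spaced (factor 1.3) until the predicted curve is within one
noise SD of baseline (threshold floored at 2% of baseline so zero-noise
schedules terminate; a design error is raised if baseline is not
re-attained within 10/β).  The exact clinical sampling times are not on
record; this schedule is a reconstruction of the described phases.  Noise
is multiplicative Gaussian at 5% CV (matching the fractional-SD weights);
the five-horse default study uses the published body weights (484, 588,
450, 503, 480 kg) with per-horse kinetic truths derived from the
published post-infusion macro constants (pool = dose/(A+B)); basal levels
other than horse 5's 0.357 mmol/L are not on record and are set to
representative values in the published 0.356–0.419 range.

What passing tests show — and what they do not: recovery tests prove the
estimation machinery is consistent (noise-free data refit to machine
precision from neutral starts) and that its standard errors are
calibrated (≥96% of noisy-replicate estimates fall within 3 reported
SEs).  They do not certify performance on real data, whose sampling
density, assay error, within-horse physiological drift and true delivery
shape differ from the reconstruction.  A quantitative caveat worth
stating: at this schedule and 5% noise, the Gauss–Newton CVs of the rate
constants at the generating truths are ~14–59%, so individual-animal rate
estimates from data of this density are usable but imprecise; published
fits of this design achieved ~1–13% CVs, implying materially richer data
than the reconstruction provides.

## Numerical and design choices

* Observed-value weights (`1/(fsd·yᵢ)²` with yᵢ the datum) rather than
  iteratively reweighted predicted-value weights; at 5% CV the difference
  is within Monte-Carlo noise of zero.
* The dataset records the *intended* duration separately from the true
  delivery, and rigid fits (S, U) always assume the intended rectangle —
  the mismatch when a pump misbehaves is the phenomenon under study, not
  an input error.
* CVs are printed rounded to integer percent in reports, with full
  precision retained in JSON.
* Degenerate inputs (zero-variance concordance inputs, single-exponential
  decays, <2 baseline replicates, repeated eigen-roots) raise typed errors
  or warn-and-flag rather than returning silently.

## Known limitations

Linear kinetics only (no Michaelis–Menten elimination), two compartments,
single analyte, no inter-horse hierarchical pooling, and a prior on one
parameter rather than full posterior inference.  The end-of-infusion
sensing rule (threshold on cumulative chain exit) is a reconstruction of
a described-but-unspecified mechanism; with an 8-cell chain the 99%
crossing occurs well after the transit time (≈2.7·DT), because ~27% of
the dose is still in transit when the pump stops — the sensed-completion
time is a diagnostic, and the estimated DT itself is the infusion-duration
quantity of scientific interest.
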