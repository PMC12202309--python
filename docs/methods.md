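# Methods

## Scientific setting

`olzpk` implements the quantitative machinery for a two-group mouse study
of how acute endotoxemia (a single intraperitoneal LPS challenge; saline
controls) alters the pharmacokinetics of oral olanzapine and its CYP1A2
metabolite 4'-N-desmethylolanzapine (DMO). The study design it targets —
and which the synthetic generator emulates — has three dosing arms per
group:

| arm | dose | sampling |
|---|---|---|
| PO olanzapine | 4 mg/kg oral bolus | destructive: 12 schedule times (predose 0 and 0.25–24 h), 3 mice per time, 2 samples per mouse, the second at the terminal (brain-harvest) time |
| IV olanzapine | 0.5 mg/kg bolus | serial: 11 times (3 min–6 h), 3 samples per mouse, the third terminal |
| IV DMO | 0.5 mg/kg bolus | as IV olanzapine |

Times are stored in hours as decimals (3 min = 0.05 h). Plasma
concentrations are ng/mL, brain ng/g, doses mg/kg, volumes L/kg,
clearances L/h/kg; everything is per kilogram of body mass and individual
body weights are not modelled.

## Structural model

The joint parent–metabolite model is a pair of linked two-compartment
mammillary systems with first-order absorption:

- Parent: depot →(ka)→ central (V1) ⇄(Q)⇄ peripheral (V2); total plasma
  clearance CL acts on the central compartment.
- Metabolite: depot →(ka_DMO)→ central (V1_DMO) ⇄(Q_DMO)⇄ peripheral
  (V2_DMO); plasma clearance CL_DMO.
- Systemic conversion: unidirectional first-order mass transfer from the
  parent central compartment to the metabolite central compartment at rate
  k_pm. The partial metabolic clearance is CL_O→DMO = V1·k_pm.
- Presystemic (first-pass) conversion: an oral dose D contributes
  D·F_po,total·F_d to the parent depot and D·F_po,total·(1−F_d) to the
  metabolite depot; the absolute oral bioavailability of parent is
  F_po = F_po,total·F_d.

CL is **total** parent clearance, of which conversion is a component: the
non-DMO elimination rate is CL/V1 − k_pm, and the parameter space enforces
k_pm ≤ CL/V1. This reading is consistent with the convention that a
"partial metabolic clearance" is part of the plasma clearance, and with
group-median values in this study satisfying V1·k_pm < CL. Q, Q_DMO and
k_pm may be exactly zero (one-compartment and no-conversion limits);
volumes, clearances and absorption rates must be strictly positive.

No molar-mass correction is applied to the k_pm transfer by default
(parent 312.4 vs metabolite 298.4 g/mol; both compounds are assayed in
mass units); `molar_mass_correction=True` enables the 0.955 scaling.
Brain is deliberately *not* a model compartment: brain penetration is
treated through AUC ratios (below), matching how such studies report it.

### Numerical solution

The system is linear and time-invariant between bolus events, so the
default path solves it analytically: eigendecomposition of the 8×8 system
matrix (six compartments plus two cumulative-elimination ledgers),
superposed over dose events. When the eigenbasis is ill-conditioned
(coincident rate constants make the system defective; condition number
> 1e10) the solver falls back to the matrix exponential per time point,
which is exact and unconditionally stable. An adaptive stiff integrator
(LSODA, rtol 1e−10) is available as `method="ivp"` and is used in tests
as an independent route. Mass balance (compartments + elimination ledgers
= administered bioavailable amount) holds to better than 1e−6 relative;
doses that put nothing into the parent subsystem produce identically zero
parent concentrations (the coupling is unidirectional), enforced exactly.

## Batch (destructive-design) AUC with bootstrap-t intervals

Destructive sampling yields no complete profile per animal, so AUC to the
last sampling time (AUC_t) is estimated with a Bailer-type estimator
generalized to batch designs. A *batch* is the set of animals sharing one
sampling-time pattern. With linear trapezoid weights w_j on the schedule
(w sums to the span):

- point estimate: Σ_j w_j·c̄_j, with c̄_j the mean over all animals
  sampled at t_j;
- variance: Σ_j Σ_k w_j w_k·cov_jk, where cov_jk pools the within-batch
  covariance of concentrations at times j and k over batches covering
  both (centered cross-products summed, divided by the summed n_b − 1)
  and divides by the number of animals contributing to both; cov_jk = 0
  when no batch covers both times. Size-1 batches contribute no
  covariance and are dropped from the variance with a warning.
- 95% bootstrap-t interval: animals are resampled with replacement
  *within batches* (preserving each animal's time pattern and hence the
  within-animal correlation the design creates), B = 2000 by default;
  each replicate is studentized with its own resampled standard error and
  the interval is (AUC − se·q*₀.₉₇₅, AUC − se·q*₀.₀₂₅). A seed is
  mandatory whenever the bootstrap runs.

The estimator's estimand is the schedule-trapezoid functional of the mean
curve. Calibration is assessed against that estimand: over 1000 simulated
destructive studies of the oral arm with 15% proportional error, the mean
estimate is within 0.2% of the trapezoid truth and the 95% bootstrap-t
interval covers it for 96–97% of studies (the suite asserts the 93–97%
band). On this 12-point schedule the trapezoid functional itself sits
within about 5% of dense quadrature of the generating curve — a
discretization property of the design, not an estimator bias, and the
reason the coverage target is the trapezoid truth.

Below-quantification (BLQ) handling, configurable: the default sets BLQ
records to 0 before the time of the mean curve's maximum and excludes
them after it; alternatives are LLOQ/2 imputation and outright exclusion.
Predose (t = 0) oral records are structural zeros and are retained as 0.

Exposure ratios (DMO-to-olanzapine metabolic ratios, Kp) are plain ratios
of point estimates; no interval propagation is attempted for ratios.

## Equilibrium dialysis and brain penetration

Unbound fractions come from paired-chamber concentrations at equilibrium:
fu_plasma = c_buffer/c_plasma. Brain tissue is dialysed as a D-fold
diluted homogenate and corrected back to undiluted tissue with

    fu_brain = (1/D) / ((1/fu_diluted − 1) + 1/D),

the standard homogenate-dilution correction: it is the identity at D = 1,
strictly increasing in fu_diluted, strictly decreasing in D, and exactly
invertible (all four properties are tested). D defaults to 5, a typical
brain RED protocol, and is configurable. Unbound fractions above 1 (assay
noise) are reported as-is with a warning — no silent clipping, so QC sees
them.

Brain penetration combines AUCs and unbound fractions:

    Kp,brain    = AUC_brain / AUC_plasma
    Kp,uu,brain = (fu_brain·AUC_brain) / (fu_plasma·AUC_plasma)

with the g-to-mL tissue convention implicit in the ratio. In the synthetic
pipeline both AUCs are computed over the overlap of the two matrices'
sampled spans: brain is sampled only at terminal times, and an unmatched
full-span ratio would systematically understate the partition
coefficient.

## Pooled maximum-likelihood estimation

Each group's three arms are fitted jointly by naive-pooled maximum
likelihood under lognormal residuals: all non-censored, post-dose,
structurally non-zero plasma observations enter one objective
n·log(SSR/n), SSR the sum of squared log-residuals against the
group-typical curve, with the residual SD profiled out. BLQ records are
excluded by default (LLOQ/2 imputation available). Population machinery
with random effects is deliberately out of scope: with at most three
observations per animal, individual-level estimation is not supported by
this design, and the downstream contrasts use group-typical parameters.

Identifiability is enforced structurally: the IV-metabolite arm pins
metabolite disposition (CL_DMO, V_DMO), the IV-parent arm separates CL
from bioavailability, and the PO arm informs absorption and the
presystemic split. A missing arm raises an explicit error naming the
parameters the remaining arms cannot separate.

Internally, positive parameters are fitted on the log scale, fractions on
the logit scale, and the conversion rate is reparameterized as
k_pm = fm·CL/V1 with fm on the logit scale — the k_pm ≤ CL/V1 constraint
holds by construction and the transformed space is unconstrained. The
optimizer runs L-BFGS-B, a Nelder-Mead polish, then a final L-BFGS-B
tightening, from `n_starts` jittered starts (default 8; SD 0.3 on the
transformed scale); the best objective wins, ties broken by distance to
the initials. Default initials are generic round numbers, not any group's
truth.

Measured performance under the study design (asserted by the suite): with
noise off, all 13 parameters are recovered to well under 1%; with 15%
proportional error, the across-20-seed means of CL, CL_DMO, F_po and
CL_O→DMO stay within a few percent of truth (the suite asserts 15%).
Group contrasts report fold change and percent change; per-animal
parameter lists can be compared with a Welch t-test (optionally on logs).

## Synthetic data generator

The generator is the package's study stand-in and defines the conditions
every downstream stage is tested under:

- **Group medians.** Exposure-determining medians match the reported
  group values: CL 2.84/1.85 L/h/kg, CL_O→DMO 0.26/0.135 L/h/kg (k_pm
  0.13/0.0675 at V1 = 2 L/kg), F_po 0.075/0.235 with 1−F_d = 0.26/0.14
  (control/LPS). CL_DMO is 0.60/0.126 L/h/kg, chosen to reproduce the
  reported 79% LPS attenuation of metabolite clearance and the ~3-fold
  IV-DMO exposure contrast. Volumes and rate constants (V1 2, V2 4, Q 2,
  V1_DMO 2, V2_DMO 3, Q_DMO 1, ka = ka_DMO = 1) are plausible mouse
  fixtures, not reported values.
- **Variability.** Between-animal variability is lognormal with CV 30% on
  positive parameters (median-preserving; fractions perturbed on the
  logit scale with SD equal to the CV), residual error proportional with
  CV 15%, optional additive floor. Draws respect k_pm ≤ CL/V1. One seeded
  generator governs everything in documented order (groups, then arms,
  then animals; per animal: parameters, plasma errors, brain errors).
- **Schedules.** The destructive oral arm pairs schedule time j with time
  j + J/2, three mice per pair, the later time terminal — every batch
  shares a two-time pattern, which is what gives the batch estimator
  within-batch covariance to pool. Serial IV animals take consecutive
  time triplets, paired so each triplet is shared by two animals.
- **Brain.** Brain concentrations are the animal's noise-free plasma
  curve times a configurable true partition ratio (6.0 parent, 0.05
  metabolite) with independent residual error, sampled at the terminal
  time only. Brain is generated, not modelled: the generator is honest
  about what the analysis can recover (a ratio), and does not pretend to
  brain kinetics.
- **Censoring.** LLOQ 0.1 ng/mL in plasma and 0.2 ng/g in brain; records
  below the limit keep their simulated value but carry a flag, and no
  record at or above the limit is ever flagged.

What the generator does *not* emulate: inter-occasion variability,
parameter correlations between animals, covariates or body weight, brain
distribution kinetics, assay batch effects, or the study's true (not
publicly reported) variability magnitudes. Passing recovery and coverage
tests therefore demonstrates internal consistency of estimator and
generator under realistic noise — not that the real study's variance
components are reproduced.

The qPCR generator produces duplicate-well cycle thresholds around a
Gapdh reference with configurable per-gene fold changes; the ΔΔCt module
averages duplicates on the Ct scale, forms ΔCt = Ct_target − Ct_reference
per sample, subtracts the arithmetic-mean ΔCt of the calibrator group
within the matching time stratum (configurable to a single global
calibrator), and reports 2^−ΔΔCt. The calibrator group's geometric mean
is exactly 1 in every stratum by construction. A constant added to every
Ct of one gene across all samples cancels through the calibrator;
only both-gene shifts and per-sample shifts are distinguishable, and the
tests document this.

## Problem sizes and runtime

The default suite simulates at the study's own scale (76 animals, 536
records per study). The calibration experiments use 1000 studies ×
B = 2000 bootstrap replicates (coverage), 2000 studies (unbiasedness) and
20 seeded studies × multistart fits (recovery); the full suite runs in
about two minutes on one CPU. These sizes were chosen as the smallest
that pin the Monte-Carlo error comfortably below each asserted band.

## Known limitations

- The pooled fit gives group-typical parameters only; no random-effect
  variances, no empirical Bayes individual estimates, no covariates.
- No terminal-phase extrapolation to infinity in the NCA (AUC_t is the
  study's exposure metric); no Cmax/Tmax statistics.
- Ratios carry no confidence intervals.
- The variance estimator for batches observed at a single time reduces to
  the per-time-mean variance; designs whose batches never share two times
  provide no covariance information, and the bootstrap degrades gracefully
  (undefined interval with a warning) when no batch has two animals.
- Enterohepatic recirculation, saturable elimination and multiple-dose
  accumulation are out of scope; dosing is single-bolus superposition.
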