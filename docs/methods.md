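# Methods

## Scope and model

The package computes angiography-derived coronary physiology indices
(caFFR, caIMR) from three inputs a catheterization laboratory produces
without a pressure wire: the reconstructed vessel geometry, the aortic
pressure trace, and the contrast-front transit; and it simulates the
observational study design these indices feed (confounded two-arm cohort,
propensity matching, binary 1-year outcomes).

### Vessel geometry and reconstruction

Vessels are ordered 3-D centerlines with a per-point lumen radius, in mm,
inlet at arclength 0. Synthetic vessels are straight or sinusoidally
tortuous tubes rescaled so the total arclength equals the requested length
exactly; stenoses are cosine-smoothed diameter reductions (severity = the
fractional diameter loss, < 1 since occlusive lesions are out of scope),
so the radius profile is C¹ and the flow solver sees no artificial
discontinuities.

Projection is orthographic under two gantry rotation angles (about y, then
x); cone-beam geometry, magnification and foreshortening are deliberately
not modelled — the acquisition geometry of clinical systems is not public,
and the orthographic model keeps the reconstruction exactly solvable, so
round-trip tests have a true zero. Point correspondence between the two
views is by index (normalized arclength), not epipolar search, which would
be image processing outside this package's scope. Each 3-D point is the
least-squares solution of the four linear image constraints; with views
≥ 30° apart (the clinical two-posture rule, enforced) the system is well
conditioned, and reconstruction error grows monotonically as the
separation shrinks toward 30° under fixed image noise. The reconstructed
radius is the arithmetic mean of the two projected radii — symmetric and
unbiased for circular lumens.

### Pressure drop

The production solver is a documented reduced-order model on the 1-D area
discretization: mass conservation fixes the mean velocity per cell from
the hyperemic inlet velocity (Q = Vhyp·A_inlet); the drop accumulates the
Poiseuille viscous term ∫ 8μQ/(πr(s)⁴) ds plus a Borda–Carnot separation
loss ρ(V_start − V_end)²/2 over each contiguous expanding region. The loss
is attributed telescopically along the region so the total is independent
of the grid and the cumulative profile stays monotone; per-interface
attribution would vanish under refinement (a sum of squared small
increments), which is why the region formulation is used. Computation is
in SI; the single unit conversion to mmHg (133.322 Pa) is applied once at
output and pinned by a hand-converted uniform-tube test (0.770 mmHg for
r = 1.5 mm, ℓ = 75 mm, V = 110 mm/s, μ = 3.5 mPa·s).

Blood is Newtonian with ρ = 1050 kg/m³ and μ = 3.5 mPa·s (standard
whole-blood values; configurable). Steady state only; no side branches,
turbulence or non-Newtonian rheology. Flows below 10⁻⁹ mm³/s are treated
as zero; zero-length cells are dropped with a warning.

An independent cross-check, `stokes_oracle`, solves steady axisymmetric
creeping flow on the same geometry: the streamfunction–vorticity system
E²ψ = χ, E²χ = 0 on a body-fitted (z, η = r/R(z)) grid, Poiseuille
profiles at inlet/outlet, Thom's closure for the wall vorticity, and the
pressure drop recovered from the dissipation identity ΔP·Q = Φ (exact for
creeping flow with fully developed end profiles). Discretization uses
compact 3-point second-derivative stencils with the mapped operator
expanded analytically; composing first-derivative matrices is avoided
because the wide D₁² stencil decouples odd/even nodes. The raw SI system
spans ~15 orders of magnitude, so unknowns are column-scaled by their
natural magnitudes and rows equilibrated before the sparse direct solve.
The default 161×41 grid reproduces Hagen–Poiseuille within ~1% and
changes by < 1% when the spacing is halved. The oracle is valid only at
low Reynolds number, so the cross-solver agreement contract (15% for a
mild smooth stenosis) is tested at a creeping inlet velocity where the
inertial Borda–Carnot term is negligible in both solvers.

### Physiology indices

MAP is the time average over an integer number of detected cycles, with at
least 3 complete cycles required (clinical recordings hold 3–8). Cycle
segmentation uses explicit markers when provided, otherwise diastolic
minima between prominent systolic peaks on a 25 ms moving-average copy of
the trace. The hyperemic aortic pressure rule is piecewise — a 20%
reduction at MAP ≥ 95 mmHg, 15% below — with the boundary value 95
assigned to the ≥ 95 branch exactly as conventionally printed (95 → 76).

Diastole detection: the clinical criterion (guide-catheter tip motion) has
no counterpart here, so the surrogate is the dicrotic notch — the first
local pressure minimum after the systolic peak (on a lightly smoothed
copy, 15 ms window) — with the window running to cycle end. Synthetic
fixtures carry ground-truth windows so the heuristic is testable, and an
explicit window can always be supplied to bypass it.

Diastolic velocity is the frame-count quotient: front positions are
interpolated linearly at the window endpoints; at least 2 frames must fall
inside the window, and zero displacement returns 0 mm/s with a
degenerate-flow warning. caFFR = (Pa_hyp − ΔP)/Pa_hyp and
caIMR = (Pa_hyp − ΔP)·L/(K·Vdiastole) with K = 1.1, L = 75 mm and the
40 U abnormality threshold, all configurable. The two printed forms of the
caIMR definition (via caFFR and via the pressure difference) are
algebraically identical and asserted so. The caIMR unit is reported as
"mmHg·s/mm" as conventionally printed, although dimensional analysis of
the defining ratio gives mmHg·s; the discrepancy is documented rather than
corrected. Note that caIMR ∝ 1/K holds exactly at fixed ΔP; end to end, K
also scales the inlet velocity and hence ΔP, so overriding K changes
caIMR by the 1/K factor only to within the small ΔP/Pa_hyp contribution.

## Synthetic data

### Case fixtures

`generate_case_fixture` constructs one acquisition with analytically known
ground truth. The pressure waveform is a piecewise shape (systolic
upstroke to a peak at 30% of the cycle, decline to a strict local minimum
at the dicrotic notch, a small dicrotic wave, then linear diastolic decay)
whose cycle mean is adjusted to hit the requested MAP exactly. The notch
sits at 5/12 of the 0.8 s cycle so that it coincides with a 15 fps frame
boundary: the contrast front advances piecewise linearly (half speed in
systole, the target velocity in diastole) with its kink exactly on a
frame, making the window-endpoint quotient reproduce the target velocity
to machine precision. Gaussian noise perturbs the pressure samples only;
the stored ground truth never changes with the noise seed. Default vessel:
1.75 mm proximal radius, length 75 mm or as needed for the front to stay
inside the lumen, 12 mm stenosis at 45% of the length. The zero-stenosis
default yields ground-truth caFFR ≥ 0.99 (near-lossless tube at
physiologic flow).

### Cohort generator

Covariates are normal (age, SBP, BMI, LVEF, symptom-to-balloon,
door-to-balloon), log-normal (peak CK-MB) or Bernoulli (sex), with
defaults matching the published totals (age 58.34 ± 13.11 y, SBP
126.26 ± 18.45 mmHg, BMI 25.59 ± 4.22 kg/m², LVEF 52.05 ± 9.72%, STOB
6.85 ± 3.28 h, DTOB 67.13 ± 15.59 min, 84% male); caIMR is drawn per arm
(36.49 ± 21.04 vs 34.23 ± 23.91 U), or optionally produced per patient by
the full physiology pipeline (slow path).

Treatment (129 DES / 84 DCB by default) is assigned by ranking a
confounded score — the propensity log-odds on standardized age, SBP, LVEF,
BMI and sex plus logistic noise of scale 0.5 — and taking the top scores
into the DCB arm, which hits the arm sizes exactly while preserving the
configured confounding. The coefficients and the modest noise scale are
chosen so the pre-matching standardized mean differences on the matched
covariates are reliably large (≥ 0.1, typically 0.3–0.9): the generator's
purpose is to give propensity matching something real to fix, and with
n = 213 weaker confounding would too often leave a covariate balanced by
chance. Universal per-covariate balance improvement remains a
finite-sample property: in roughly 1 seed in 60 a covariate's realized
pre-match imbalance is at noise level and cannot be reduced further.

Outcomes are 1-year cumulative flags (no event times, matching the binary
analysis): MACE follows a logistic model on the standardized
symptom-to-balloon and door-to-balloon times (default odds ratios 2.08 and
1.36 per SD; the published per-unit scaling is unstated, so per-SD is the
declared convention) with the intercept calibrated per cohort by root
finding so the mean predicted risk equals the configured rate (33/213).
The event type among MACE cases is CorH (CV death or heart-failure
readmission, split 40/60) with probability depending on the caIMR > 40 U
indicator, calibrated in closed form so the *marginal* CorH odds ratio for
caIMR > 40 equals the configured default (4.07). This factorization keeps
both configured models exactly recoverable by logistic fits while
preserving MACE = union of its component flags; it is consistent with
caIMR > 40 being unrelated to overall MACE in the emulated study.
Infeasible combinations (allocation probability ≥ 1) are rejected with an
explanatory error.

## Statistics

2×2 effect measures use the cross-product odds ratio and risk ratio with
Woolf log-normal 95% intervals (z = 1.96), adding a 0.5 continuity
correction to all cells only when a cell is zero; this convention
reproduces the published interval for the 21/108/12/72 table (OR 1.17,
0.54–2.52). The chi-square is Pearson without Yates correction. Group
mean comparisons from summary statistics use the pooled-variance
two-sample t (not Welch), which reproduces the published caIMR contrast
(difference 2.26, CI −4.05 to 8.57 at 1-decimal rounding) from the group
summaries with n = 121/80.

Propensity matching: logistic propensity on the requested covariates
(default age, sex, SBP, BMI), greedy 1:1 nearest-neighbour on the
propensity *logit* without replacement, caliper 0.2 SD of the logit,
treated units processed in seeded random order; pre/post standardized mean
differences are reported. Matching on the logit makes the pairing
invariant to affine recoding of covariates. These conventions
(greedy/caliper/no replacement) are the common defaults; none is dictated
by the emulated study, so they are recorded in the output provenance.

Logistic fits are statsmodels maximum likelihood with Wald 95% intervals;
constant predictors are dropped with a warning and separation or
non-convergence is flagged in the estimate notes. The multivariate model
in the study report uses all univariate-significant predictors at p < 0.05
(configurable). No multiple-testing correction is applied by default.
ROC analysis enumerates all unique score thresholds (ties collapse to one
threshold); AUC is the trapezoidal area, identical to the tie-corrected
rank-sum concordance, and the reported operating point maximizes the
Youden index.

## What the synthetic data does and does not show

The generators emulate the *structure* of clinical data — waveform
landmarks, frame-rate quantization, confounded assignment, logistic
outcome dependence — not its full messiness: no arrhythmic beats, catheter
artifacts, contrast streaming or layering, no missing data, no
event-time censoring, and covariates are independent apart from the
assignment mechanism. Passing tests therefore demonstrate that the
computational pipeline is correct and the statistical machinery calibrated
(interval coverage, parameter recovery, balance improvement), not that the
physiologic indices are clinically valid; clinical quantities from the
emulated study (post-matching effect contrasts, regression odds ratios,
published sensitivities) enter only as generator defaults, since the
underlying patient-level data are not public.

## Problem sizes

Defaults used in tests and the acceptance script: 150–400 flow cells,
161×41 (to 321×81) oracle grids, 2 000 simulated tables for interval
coverage, 100 seeded replicates at n = 5 000 (and cohorts at n = 20 000)
for parameter recovery, 100 000 patients for marginal calibration — sizes
at which every stochastic check is stable to its stated tolerance while
the whole suite runs in well under a minute.
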