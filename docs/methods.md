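# Methods

`raidose` implements a single-timepoint dosimetry workflow for radioiodine
(¹³¹I) therapy of metastatic differentiated thyroid cancer, planned from
serial ¹²⁴I PET imaging. This note documents the models, the defaults and
why they were chosen, what the synthetic cohort generator does and does not
emulate, and the numerical choices that matter.

## Lesion kinetics

Each lesion's activity concentration (µCi/g, normalized per mCi of
administered tracer) is modelled as

    A(t) = a₀ · (1 − e^(−λ₁ t)) · e^(−λ₂ t)

with uptake rate λ₁ (1/h), total clearance rate λ₂ (1/h) and amplitude a₀.
Measurements are treated as **not decay corrected**, so λ₂ = λ_bio +
λ_phys(¹²⁴I). This reading is what makes decay-constant substitution
meaningful: projecting the curve onto therapy replaces the imaging
isotope's physical decay constant with the therapy isotope's,

    λ₂′ = λ₂ − ln2/T_½(¹²⁴I) + ln2/T_½(¹³¹I),

leaving a₀ and λ₁ untouched. Default half-lives are 100.22 h (¹²⁴I) and
192.48 h (¹³¹I); both are configurable. If inputs *are* decay corrected,
the `decay_corrected_input` flag fits a purely biological clearance and
adds the physical constant back afterwards.

Fitting is trust-region nonlinear least squares (`scipy.optimize.
least_squares`) on the untransformed model, with a fixed (RNG-free)
five-point multi-start grid: λ₁ log-spaced over [0.01, 1]/h, λ₂ log-spaced
over [floor, 0.1]/h, a₀ seeded from the peak observation. Cost tolerance is
1e-10. Candidates that report convergence are preferred over lower-cost
unconverged ones, which in practice sit on the a₀λ₁ identifiability ridge
(λ₁ → 0, a₀ → ∞ with a₀λ₁ roughly constant); a genuinely better unconverged
candidate is polished with a larger evaluation budget before being
accepted. With only two timepoints, λ₁ is pinned to 0.5/h (uptake
essentially complete by the first scan; configurable) and only a₀, λ₂ are
estimated.

Biological clearance is constrained non-negative by default
(`enforce_physical_floor`), so λ₂ ≥ λ_phys and the reported effective
¹³¹I half-life, ln2/λ₂′ , never exceeds the 8.02-day physical ceiling.

An `objective="log"` option minimizes residuals of log-counts instead of
untransformed residuals. It is the likelihood-matched choice when
measurement noise is multiplicative (lognormal): with the default absolute
objective and 10% multiplicative noise, nonlinear-least-squares estimates
carry a small O(σ²) bias that is detectable over a few hundred replicates;
the log objective removes it up to curvature terms. The default remains
the absolute objective, with the log objective offered for sensitivity
analysis.

The time integral has the closed form

    AUC = ∫₀^∞ A(t) dt = a₀ λ₁ / (λ₂ (λ₁ + λ₂)),

validated against adaptive quadrature to 1e-6 relative over 1,000 random
parameter sets.

## Absorbed dose

Dose uses the equilibrium dose constant for the non-penetrating β emissions
of ¹³¹I, Δ = 0.405 g·cGy/(µCi·h) ≡ 10.95 g·cGy/(MBq·h), and a density of
1 g/mL (PET voxels already report activity per unit mass):

    dose [cGy/GBq administered] = AUC · 0.405 · 27.027.

Activities are held in GBq internally and reported alongside mCi
(27.027 mCi/GBq); doses are in cGy throughout.

Partial-volume correction divides the dose by the recovery coefficient of
a uniform sphere of diameter equal to the lesion's mean size, blurred by an
isotropic Gaussian point-spread function (default FWHM 0.6 cm). The
center-value recovery has the closed form

    RC = erf(R/(σ√2)) − (R/σ)·√(2/π)·e^(−R²/(2σ²)),  σ = FWHM/2.355,

which is the integral of the 3-D Gaussian over the sphere; it is validated
against numerical 3-D convolution oracles (radial quadrature across the
0.2–5 cm sweep, literal Cartesian-grid integration as a spot check). RC is
clamped below at 0.05 (configurable) so sub-resolution lesions do not
receive unbounded corrections. Published per-lesion tables print a range of
effective recovery factors that cannot all be reconciled with a single
sphere-diameter reading of the printed sizes, so fixture checks are applied
to the columns that are mutually consistent (dose-from-AUC, activity-for-
target, projected doses).

No photon/cross-dose component, voxel-level dosimetry or organ S-values
are modelled.

## Clustered log-log regression

The single-timepoint predictor model is

    ln(AUC_ij) = β₀ + β₁ ln(x_ij) + ε_ij,

lesions j nested in patients i, x the 48-h SUVmax by default (SUL,
concentration, and the other timepoints are selectable). Estimation is a
Gaussian identity-link GEE (statsmodels) with a cluster-robust sandwich
covariance. Lesions with SUVmax ≤ 1 are excluded by an explicit,
documented filter — no treatment is planned for lesions without
differential uptake.

The **working correlation defaults to independence** (cluster-robust least
squares). An exchangeable structure is available, but in simulation at the
relevant scale (tens of patients, 3–23 lesions each, within-patient
intraclass correlation ≈ 0.5) the exchangeable estimator's extra
variability — driven by the estimated correlation parameter, which the
plug-in sandwich ignores — left "estimate ± 2 robust SE" covering the true
slope in only ~89% of replicates, versus ~95% under independence. A
delete-one-cluster jackknife reproduced the sandwich values, confirming the
issue is estimator variability rather than standard-error bias.

Residual variance σ² is estimated from log-scale residuals with
denominator n_lesions − 2; it feeds the prediction-interval simulation.
Perfectly collinear (noise-free) data are detected by an OLS pre-pass and
returned exactly, with zero covariance, since the GEE scale/correlation
updates degenerate there.

## Simulation-based prediction intervals

For a new lesion at predictor x, each simulation draw takes

1. σ̃² = df·σ̂²/χ²_df — with **df = n_patients − 2**, not n_lesions − 2:
   under patient-level correlation the variance estimate's effective sample
   size is of order the cluster count, and using the lesion-level df
   understates its spread (measured: mean fresh-lesion 95% PI coverage
   94.1% with the lesion df, 95.5% with the cluster df, across 20 replicate
   cohorts);
2. β̃ ~ MVN(β̂, V_robust) (SVD factorization, so degenerate covariances
   collapse to point masses rather than failing);
3. ỹ = β̃₀ + β̃₁ ln x + N(0, σ̃).

The interval is the exponential of the symmetric empirical tail quantiles
(linear interpolation of order statistics) of the log-scale draws; the
point estimate is exp(β̂₀ + β̂₁ ln x), the predictive median on the natural
scale. Defaults: 10,000 draws, one seeded `numpy` Generator per call, so
results are bit-reproducible. "Outside the PI" means strictly below the
lower or strictly above the upper bound.

Leave-one-patient-out cross-validation refits the regression without each
patient in turn, simulates PIs at the held-out lesions' predictor values
(fold seeds spawned deterministically from the master seed), and records
per-lesion inside/outside flags and squared log-scale errors; the
cross-validated error is the mean over all lesions of all patients.
Squared errors are computed on the log scale throughout, which is the only
scale on which published cross-validated errors of ~0.2–0.7 are plausible.

## Activity prescription

The dose per mCi administered is AUC × 0.405 cGy, so the activity that
delivers a target dose D to a fraction c of lesions with a given measured
uptake is

    activity_mCi = D / (AUC_q · 0.405),

with AUC_q the (1 − c) tail quantile of the simulated predictive AUC
distribution — lesions whose AUC draw exceeds the quantile receive at
least D. Coverage 0.5 uses the mean log-scale prediction (the predictive
median), matching the "mean estimate" column semantics of the clinical
lookup table. All coverage columns of a prescription row, and its 95% PI,
come from one simulation set, so the 97.5% column equals
D/(PI_lower·0.405) identically.

Treatment recommendations pick an index lesion (default: lowest predictor
value, i.e. the coldest lesion; highest and median strategies available),
compute the activity required for that lesion at the chosen coverage, and
cap it at the patient's maximum tolerated activity (MTA — consumed as an
input in GBq, never computed here). When full four-timepoint dosimetry is
available for a lesion, its measured PVC dose per GBq takes precedence
over the regression prediction; the regression path is for single-timepoint
operation. The default target dose is 2000 cGy, fully configurable.

## Synthetic cohort generator

The generator realizes, per lesion, exactly the model the analysis
assumes, so every stage is testable without clinical data:

- per patient: avidity random effect b_i ~ N(0, σ_patient), MTA drawn
  lognormally (median ≈ 14 GBq), lesion count uniform on 3–23;
- per lesion: ln SUV₄₈ uniform over [0, ln 1000];
  ln AUC = β₀ + β₁ ln SUV₄₈ + b_i + N(0, σ_lesion) with defaults
  β = (0.697, 1.002); uptake rate λ₁ log-uniform on (0.03, 0.5)/h;
  biological half-life log-uniform on (48, 4800) h; the amplitude a₀ is
  back-solved from the closed-form AUC so kinetics and AUC are exactly
  consistent;
- emitted samples: ¹²⁴I concentrations at 24/48/72/120 h with
  multiplicative lognormal noise (σ = 0.10); SUV columns scaled so the
  noiseless 48-h SUV equals the drawn SUV₄₈; SUL = 0.75 × SUV.

Defaults for the variance split, σ_patient = 0.30 and σ_lesion = 0.32,
were set so the total log-scale SD (≈ 0.44) reproduces the ≈ 5.6× ratio
between the published 95% PI bounds at fixed SUV; the split itself is an
assumption (the study reports no lesion-level variance decomposition). The
uptake-rate range reflects that many published lesions are still
accumulating iodine between 24 h and 48 h, and that rates ≳ 1/h are
unidentifiable from a first sample at 24 h (uptake complete before any
data).

What the generator does **not** emulate: real SUV distributions are
right-skewed rather than log-uniform; measurement noise in real PET scales
with lesion size and reconstruction settings; kinetic outliers (e.g.
very fast clearing lung lesions coexisting with slow neck nodes in one
patient) are only partially captured by the log-uniform biological
half-life; and lesion sizes are independent of uptake here. Passing tests
therefore demonstrate internal statistical correctness and calibration
under the assumed model, not clinical performance.

## Problem sizes used in the checks

The test suite exercises: 21-patient cohorts (≈ 230–300 lesions) for
end-to-end pipeline checks and leave-one-patient-out calibration; five
replicate 21-patient cohorts pooled to 2,000 fresh test lesions for PI
coverage; one hundred 60-patient replicates for slope recovery; 1,000
random parameter sets for the AUC identity; 10,000-lesion cohorts for
generator self-consistency. Prediction-interval checks use 2,000–50,000
draws depending on the precision the comparison needs.

## Known limitations

- The exchangeable working correlation is retained only as an option; its
  interval calibration at a few dozen clusters is poor (see above).
- The sphere-model recovery coefficient assumes uniform uptake and an
  isotropic Gaussian PSF; published recovery curves derived from scanner
  measurements differ in detail.
- The two-timepoint fallback fixes the uptake rate; its dose estimates
  inherit that assumption.
- Prediction intervals are marginal per lesion; joint statements about
  several lesions of one patient ignore their shared avidity.
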