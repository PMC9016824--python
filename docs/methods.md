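# Methods

## The two-slope index

A region's dynamic PiB uptake has three phases: flow-in (delivery-limited),
peak (generally within 4 minutes of injection), and clearance from tissue.
Amyloid-positive tissue shows greater mid-phase retention and a slower
post-peak clearance than amyloid-negative tissue.  The index combines both:

    AQI_roi = a * (S(t1) - S(0)) / t1
              - (1 - a) * (S(t_max) - S(t2)) / (t2 - t_max),

divided by the injected dose (MBq).  Conventions, fixed throughout:

* S(t) is the piecewise-linear interpolant through (frame mid-time,
  frame activity) pairs.  Below the first mid-time the curve is held
  constant at the first-frame average, which makes S(0) = activity[0] by
  definition rather than an extrapolation.  Queries beyond the last
  mid-time are errors (no extrapolation); times are seconds everywhere
  internally.
* t_max is the mid-time of the frame with maximal activity (earliest frame
  on ties); S(t_max) is that frame's value, not an interpolated refinement.
* t2 must exceed t_max, otherwise the clearance slope is undefined and the
  computation raises.
* Defaults a = 0.5, t1 = t2 = 1650 s.  On the standard 60-min framing
  (12 x 10 s, 3 x 60 s, 11 x 5 min) 1650 s is a frame mid-time, and
  truncating the scan to 30 min leaves the default index bit-identical —
  the property that makes a short protocol possible.

Dose normalization makes the index invariant to jointly scaling activities
and dose; it does not remove per-scanner calibration error, which is one of
the simulator's noise sources (below).

## Comparators

SUVR is the ratio of duration-weighted mean activity (target over
cerebellar-cortex reference) across frames whose mid-times fall in the
closed window [1800, 3600] s; on the standard schedule these are the six
5-min frames with mids 1950...3450 s, all equal duration, so the weighting
only matters for irregular schedules.  DVR is the slope of the ordinary
least-squares reference-Logan line y_i = DVR * x_i + b over the same
frames, with y_i the target's running integral over its instantaneous
value and x_i the reference's running integral over the target value.
The optional population-clearance term C_ref/k2' is implemented but off by
default, since no population k2' is assumed; unweighted OLS is used for the
fit (configurable nowhere else than the call site, by design).

## Parameter optimization and region selection

`optimize_params` grid-searches (a, t1, t2) — defaults t1 in [50, 3300] s
and t2 in [300, 3300] s at 50 s steps, a in [0, 1] at 0.1 steps — scoring
each point by stratified 10-fold cross-validated logistic-regression
accuracy on the single-region index.  The t1 axis starts at 50 s rather
than 0 because the retention slope divides by t1.  One fold assignment is
drawn per search and reused across all grid points, making the search
deterministic given a seed.  Grid points that violate t2 > t_max for any
subject, or fall beyond a subject's scanned range, are excluded rather than
fatal.  Ties in accuracy are broken toward the minimal required scan time
max(t1, t2), then minimal t1, then minimal a, so the cheapest acquisition
wins among equally accurate settings.

`lasso_select` regresses the binary label (HC = 0, AD = 1) on the
standardized per-region index matrix along a descending lasso path
(scikit-learn coordinate descent; 100 strengths geometric from the
data-derived maximum down to 1e-4 of it unless a grid is supplied).
Stratified 10-fold CV estimates prediction MSE per strength; the chosen
strength is the largest whose mean MSE is within one standard error of the
minimum.  Regions with refitted |coefficient| above 1e-6 are "featured",
sorted by magnitude.  Standardization uses the full training matrix; a
constant column is dropped with a warning, a constant response selects
nothing.

The composite index is an OLS fit of the 0/1 label on z-scored featured
regions.  The z-scoring statistics (training mean and sd, ddof = 1) are
stored in the model and reused verbatim for new subjects — held-out data
are never normalized by their own statistics.  With centered predictors
the OLS intercept equals the label mean (0.5 on a balanced cohort).

### Negative-control selections

On simulated cohorts the lasso routinely selects an amyloid-null region
*with a negative coefficient* alongside the featured regions.  This is not
a selection error: every region of a subject scales with the same input
function and reference kinetics, so a null region measures the shared
nuisance (delivery, calibration, delay) and subtracting it denoises the
signal regions — the same reason conventional analyses normalize by a
reference region.  The regression test therefore asserts that the
*positive*-coefficient selections are exactly the featured regions.  On an
independent-columns design (200 x 10, two informative regions), where no
shared factor exists, the 1-SE lasso recovers exactly the informative pair.

## Evaluation harness

* Stratified k-fold assignment shuffles within class and deals round-robin,
  so fold class counts deviate by at most one from perfect stratification
  (50 + 50 subjects in 10 folds: exactly 5 + 5 each).  k larger than the
  smaller class is an error.
* Logistic regression is fitted by Newton/IRLS with step-halving on the
  penalized log-likelihood, an L2 ridge of 1e-6 on the weights (intercept
  unpenalized), tolerance 1e-8, and at most 100 iterations;
  non-convergence raises with iteration diagnostics.  The ridge keeps
  weights finite under perfect separation, which strongly discriminating
  measures produce routinely.  Standard errors come from the inverse
  penalized Fisher information.
* Cross-validation pools the out-of-fold probability scores and runs ROC
  analysis on the pooled scores against the true labels.  AUC uses the
  rank (Mann-Whitney) formulation with ties counted one half.  The
  operating point maximizes Youden's J = sensitivity + specificity - 1,
  ties broken toward higher specificity; accuracy, sensitivity and
  specificity are reported there.  For a single measure the probability
  threshold is also mapped back to the measure scale (median of the
  per-fold inverse-logit thresholds), since per-fold classifiers are
  monotone in the measure; held-out cohorts are evaluated with this
  training-derived measure-scale threshold.  With balanced classes the
  Youden point can never do worse than the majority rule
  (accuracy = (J+1)/2 >= 1/2); with unbalanced classes Youden and accuracy
  can legitimately disagree, which is why the majority-rule property is
  only asserted for balanced designs.
* Cohen's d uses the pooled-variance form with the AD-minus-HC sign
  convention.  Kruskal-Wallis (scipy, tie-corrected) is retained for the
  two-group comparison; all-identical data return H = 0, p = 1 instead of
  a division-by-zero error.  Pearson correlations (scipy) drop missing
  pairs pairwise and require at least 3 pairs and nonzero variance.

## The simulator

The generative chain is Feng-type tri-exponential arterial input ->
one-tissue-compartment cerebellar-cortex reference ->
SRTM target regions, so true DVR = 1 + BPND exactly by construction:

    Cp(t)    = (A1 s - A2 - A3) e^(-l1 s) + A2 e^(-l2 s) + A3 e^(-l3 s),
               s = t - delay  (0 before arrival)
    C_ref(t) = K1_ref (Cp (x) e^(-k2_ref t))
    C_T(t)   = R1 C_ref + (k2 - R1 k2a) (C_ref (x) e^(-k2a t)),
               k2a = k2 / (1 + BPND)

Curves are computed on a 0.5 s grid with an exact piecewise-linear
exponential-convolution recurrence (well-conditioned for any k*dt), then
averaged over each frame — the frame value is the within-frame mean, as in
real reconstruction, not a midpoint sample.  Defaults, per subject:

| quantity | default | rationale |
|---|---|---|
| dose | uniform 6-20 mCi (x37 MBq) | acquisition protocol emulated |
| AIF amplitudes | dose x 5% lognormal jitter | scanner cross-calibration error |
| AIF shape | A1=28, A2=1.4, A3=1.0 Bq/ml/MBq; l1=0.042, l2=0.006, l3=0.00022 /s; delay U(10,20) s | plasma peak < 4 min; tissue frame peaks in 95-210 s for all kinetic draws (the 80-240 s band), with margin against noise flipping the argmax frame |
| reference | K1_ref ~ N(0.30, 0.03) ml/ml/min, k2_ref ~ N(0.15, 0.012) /min, identical in both groups | reference region devoid of specific binding |
| caudal anterior cingulate | AD: BPND ~ N(0.9, 0.25), R1 ~ N(0.85, 0.05); HC: BPND ~ N(0.1, 0.05), R1 ~ N(1.0, 0.05) | primary featured region; AD delivery deficit |
| caudate | AD: BPND ~ N(0.55, 0.15); HC: BPND ~ N(0.08, 0.04) | secondary featured region |
| precentral, pericalcarine | BPND ~ N(0.05, 0.03) both groups | amyloid-null controls |
| noise | sd = 5.0 * sqrt(max(S,0)/duration) per frame | count-statistics-like heteroscedasticity; short early frames noisiest; no clipping (negative values occur, as in real reconstructions) |
| MMSE / CDR-SOB | monotone in mean featured-region BPND plus Gaussian noise, clipped to [0,30] and [0.5,9] (HC CDR-SOB = 0) | matches the emulated cohort's score ranges |

BPND draws are truncated at zero; R1 and k2 at small positive floors.  A
fixed seed makes the cohort byte-identical across runs (single generator,
fixed iteration order).

What the simulator does *not* emulate: image-space effects (PSF, partial
volume, motion), Poisson count statistics, head-to-head scanner
differences, non-AD dementias, and any absolute-amplitude realism beyond
order of magnitude — late-window SUVR of strongly binding simulated
regions runs higher than typical clinical values because the slow plasma
tail is only coarsely matched.  Passing tests therefore demonstrate the
pipeline's internal correctness and its behaviour under the modelled
separability regime, not clinical performance on real data.  The simulated
groups separate more cleanly (CV accuracy ~0.98-1.0, Cohen's d ~4-6) than
a real mild-AD cohort would; tests assert one-sided bounds (accuracy >=
0.90, d > 1.5, p < 0.001), not point values.

## Numerical choices

* Interpolation fine-sampling is configurable (default 1 s in the run
  config); the index itself evaluates S(t) analytically on the
  piecewise-linear curve, so results are grid-step-insensitive by
  construction.
* TAC integrals prepend (0, activity[0]) so integration starts at scan
  start; integral additivity holds exactly.
* Logan x/y points use the same trapezoidal integrals; target activity
  must be positive at all window frames.
* The lasso CV standardizes once on the full matrix (not per fold); with
  n = 100 and 10 folds the induced optimism is negligible against the
  1-SE margin.
* Degenerate inputs fail loudly: empty schedules, non-contiguous frames,
  non-positive dose, all-NaN activity, t2 <= t_max, zero-variance features
  for z-scoring, single-class labels.  Readers reject rather than repair
  malformed tables, naming the offending subject.

## Problem sizes

The bundled tests and the acceptance script run the study conditions at
the sizes the analysis design states: 50 + 50 training subjects, 10 + 10
held-out, five regions, 26 frames, 10-fold CV.  The acceptance script's
grid search uses a coarsened grid (t1 150-3150 s and t2 300-3300 s at
300 s steps, a at 0.25 steps); the contract tests for the grid search use
small constructed cohorts where the optimum is known exactly, and the full
50 s / 0.1 grid remains the library default.
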