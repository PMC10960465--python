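# Methods

This note documents the statistical procedures implemented in
`sleepspectra`, the design decisions taken where the procedure was
genuinely open, what the synthetic cohort does and does not emulate, and
the package's numerical conventions and limitations.

## Spectral pipeline

**Epoching and artifact rejection.** Recordings are cut into whole 4-s
epochs; a trailing partial epoch is dropped and logged. Artifact
rejection uses the three Hjorth descriptors per epoch and channel —
activity = var(x), mobility = √(var(Δx)/var(x)), complexity =
mobility(Δx)/mobility(x) — computed with population variance (ddof 0).
Per channel and per stage label (Wake, N1, N2, SWS, REM treated as five
separate reference groups), the mean and SD of each descriptor are taken
across that stage's epochs and an epoch is flagged when any descriptor's
absolute deviation is **at least 2 SD** (two-sided). The pass is single:
state statistics are not re-estimated after flagging. Two boundary rules:
(i) a flagged deviation must be strictly positive, so a stage whose
epochs all have identical statistics (SD = 0) rejects nothing rather than
everything; (ii) stages with fewer than 3 epochs are skipped with a
warning. Epochs with undefined Hjorth parameters (constant signal) are
always flagged. Whether the reference statistics should pool channels or
stages differently is not determined by the procedure's definition;
per-channel, per-stage was chosen and is the tested behaviour.

*Known limitation:* single-pass z-scoring breaks down when a large share
of one stage's epochs are artifactual — at within-stage contamination
fraction f, an artifact's z-score is ≈ √((1−f)/f), which drops below the
2-SD threshold at f ≥ 0.2. At the generator's default artifact density
(2% of epochs) this is immaterial; heavily contaminated recordings would
need an iterative or robust (median/MAD) variant, which is out of scope.

**Windowing.** Contiguous artifact-free runs of one vigilance class
(NREM = N1 ∪ N2 ∪ SWS; wake is excluded entirely) are tiled with 4-s
windows stepping 2 s (50% overlap), keeping fully contained windows.
Runs of 4–6 s yield exactly one window at the run start; runs under 4 s
yield none.

**Periodogram.** Single-window periodograms (1024 samples at 256 Hz)
use a Hamming taper with density scaling (taper power compensation), via
`scipy.signal.periodogram` with detrending disabled so the 0 Hz bin
carries mean voltage. The one-sided density of N(0, σ²) white noise is
2σ²/fs off DC, which the white-noise calibration test checks to 2–3%.
SciPy's periodic Hamming window is used (MATLAB's default is symmetric);
for 1024-point windows the difference is far below every tolerance used
here. Bins 0–48 Hz at 0.25 Hz resolution are retained: 193 bins.

**Aggregation.** Window PSDs are averaged on the linear scale within
state, then log10-transformed, then relativized by subtracting the mean
over the 193 bins. The order matters and is pinned by a test (log of the
mean, not mean of centred logs). Relativization makes the pipeline
invariant to an overall voltage scale: multiplying the raw signal by c
shifts absolute log-PSD by 2·log10(c) uniformly and leaves the relative
spectrum unchanged. Zero bins in the mean PSD are floored at a
configurable 1e-12 × the spectrum's median positive value before the log,
with a log entry.

**Bin reduction.** 193 bins are reduced to 48 by dropping the 0 Hz
(mean-voltage) bin and averaging the remaining 192 in consecutive groups
of 4 (centers 0.625 … 47.625 Hz). Dropping DC resolves the fact that 193
is not divisible by 4, and is the natural choice given that the DC bin is
not an EEG rhythm; the reduction is its own function and can be swapped.

**Stage-label mapping.** Hypnograms are plain text, one label per 4-s
epoch. For 30-s visual staging, each 4-s window (aligned to the recording
start) takes the label covering its midpoint. This mapping is a
convention, not a property of the data; it is isolated in
`io.read_hypnogram`.

## Association screening

Partial Pearson correlations control for age: x and y are each regressed
on [1, age] and the residuals correlated, which equals the closed-form
first-order partial correlation (a dual-route test holds the two paths to
1e-10). Binary 0/1 indicators enter the same formula, giving the
age-partialled point-biserial correlation. p-values are two-sided from
the t distribution with n − 3 df. Residual norms below 1e-12 of the data
norm (constant columns, collinearity with age) mark the correlation
undefined; undefined entries are excluded from the FDR family and logged.

Missing data is handled pairwise-complete per (indicator, variable)
pair. For PSD families, spectra are missing as whole subject × channel ×
state vectors, so row-wise deletion per family is exactly
pairwise-complete.

Benjamini–Hochberg step-up FDR (via
`statsmodels.stats.multitest.multipletests`, checked against a
brute-force step-up oracle) is applied within each family: the 15
macrostructure variables per indicator, or the frequency bins per
indicator × channel × state. The FDR level α defaults to 0.05 and is
configurable. Whether macrostructure correction should instead pool all
indicators into one family is a judgement call; per-indicator families
match the per-indicator reporting of the screen.

## Pattern analysis

Coefficients entering the PCA are recomputed on the 48-bin reduced
spectra (not obtained by reducing 193-bin coefficients) and averaged
element-wise across C3 and C4; NREM and REM are separate analyses. The
PCA treats bins as variables and indicators as observations and runs, by
default, on the correlation matrix of the bin columns (standardised
across indicators) — the companion co-correlation analysis is itself a
correlation of correlations, and coefficient columns share the r scale.
A covariance-matrix variant is available
(`pca_of_coefficients(..., variant="covariance")`). With the correlation
variant the eigenvalues sum to 48 and Kaiser's rule (eigenvalue > 1)
decides retention; at least one component is always kept. Because PC
signs are arbitrary, each retained component is flipped so that its
summed loadings above 25 Hz are positive, which makes the "acceleration"
component's sign stable across runs and states. Indicator scores are the
projections of the standardised rows onto the loadings; the NREM/REM
concordance table reports raw signed correlations between score columns
(only magnitudes are interpretable).

K-means clustering uses five features per indicator: NREM PC1/PC2 and
REM PC1/PC2 scores and the total count of FDR-significant PSD bins
across both channels and states from the 193-bin screen ("total
bandwidth", counted regardless of contiguity). Features are z-scored
before clustering because scores and counts are on incommensurate
scales. k = 3 by default, 50 seeded restarts keeping the best
within-cluster sum of squares; labels are canonicalised by descending
cluster size so the "retained sleep" majority is always cluster 1.

## Sensitivity analyses

Group contrasts fit, per bin, OLS of relative log-PSD on
[1, age, group] (matching the regression formulation rather than a
t-test) with BH-FDR across bins per channel × state; the per-bin solver
is vectorised normal equations, verified against `statsmodels` OLS to
1e-10. When age is balanced across groups the group coefficient equals
the raw mean difference. Stratified screens rerun the partial-correlation
machinery inside a subject stratum with a continuous exposure as the
indicator; strata under 10 subjects are refused as uninformative.
Contrasts use relative (not absolute) PSD, consistent with every other
analysis stage. A scalar-outcome variant serves questionnaire-score
regressions; questionnaire scoring itself is out of scope (scores are
input columns).

## Synthetic cohort generator

The generator exists to make every downstream stage testable against a
known ground truth. Defaults define the study conditions and were chosen
once:

* n = 2000 subjects; age ~ N(73.06, 5.55²) years.
* 88 indicators: 85 binary with prevalences log-spaced over 0.1%–62%,
  plus systolic/diastolic blood pressure and coffee-cup counts.
  Binary indicators are Bernoulli with logit linear in age (log-odds
  slope 0.5 per age-SD for every second indicator), with the intercept
  solved by Gauss–Hermite quadrature so the marginal prevalence hits its
  target; indicators ending with fewer than 2 positives are redrawn up
  to 20 times, then flagged. 1% of table cells are masked missing
  completely at random (true values still drive the spectra).
* Spectra: a smooth 1/f-like absolute log-PSD baseline with an NREM
  sigma bump and a weak REM alpha bump, plus an age effect
  (0.02 log10-units/year along the acceleration shape — age is thereby a
  genuine confounder of both indicators and spectra, exercising the
  partial correlation), plus implanted effects, plus i.i.d. N(0, 0.05²)
  log10 noise per bin, then relativization.
* Two zero-mean, unit-norm, mutually orthogonal broad-band effect
  patterns: "acceleration" (tanh sign change at 25 Hz) carried by 7
  indicators and "mid-frequency" (sigma-beta bump with negative lobes at
  the spectral extremes) carried by 18, sizes 0.15–0.40 log10 units with
  mixed signs, identical in NREM and REM; 63 indicators carry no effect.
  This 63/18/7 composition and the per-bin correlations it produces
  (mean |r| of a few hundredths, maxima below ~0.4) sit in the range
  reported for cohorts of this kind. One NREM-only narrowband sigma
  (12–15 Hz) effect is attached to a synthetic `hypnotic_use` indicator.
* Macrostructure: 15 variables built from plausible latent stage
  durations and latencies with age trends, indicator-linked shifts on
  the latent columns (e.g. +12 min REM latency for "accelerated"
  indicators), and derived totals/percentages/efficiency. Because
  percentages are derived, shifts on durations propagate to them; the
  ground truth records only the direct latent-column shifts.
* Raw mode synthesizes 256 Hz two-channel signals per subject whose
  expected periodogram equals the subject's absolute target spectrum,
  block-by-block over a compressed 4-minute sleep cycle, by inverse-FFT
  of complex Gaussian spectra with amplitude √(P(f)·fs·L/2) (spectral
  factorization of filtered Gaussian noise — analytically checkable,
  unlike autoregressive fitting). Artifact epochs (2% by default) are
  scaled ×10 on both channels at indices recorded in
  `true_artifact_epochs`.

Everything is deterministic given the config seed, via named
`SeedSequence` streams (age, indicators, spectra noise, macrostructure,
missingness, and per-subject raw-signal streams), so raw-mode signals do
not perturb cohort draws.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: realistic sleep architecture (cycle timing,
stage transitions, apnea events), spectrally correlated or non-Gaussian
bin noise, channel asymmetries, indicator co-morbidity structure beyond
shared effect patterns, non-linear age effects, and informative
missingness. Recovery results on the synthetic cohort validate the
*implementation*, not the epidemiology.

## Numerical conventions

* Seeds: every stochastic step (generator, K-means restarts) takes an
  explicit seed; K-means seeds are reduced mod 2³².
* Tolerances: dual-route oracle equivalences at 1e-10–1e-12; Monte-Carlo
  calibrations at 2–5% relative; the relativization contract at 1e-9.
* Degenerate inputs: constant indicators are skipped with a warning;
  degenerate bins are excluded from FDR families; K-means refuses
  k larger than the number of indicators; subgroup contrasts refuse
  constant groups; strata under 10 subjects are refused.
* EDF output is 16-bit with a symmetric physical range per channel
  (quantization error ≤ range/32767); reading is via MNE.
* Problem sizes in the test suite are chosen to keep the full run in
  tens of seconds: the shared synthetic study uses the full default
  n = 2000 cohort, Monte-Carlo calibrations use 1500–2000 windows or 200
  replicate cohorts of n = 120, and raw-signal tests use 8-minute
  recordings.

## Known limitations

* BH-FDR validity is exact under independence/PRDS; relativization
  induces a weak negative coupling across bins that the null-calibration
  test shows to be immaterial at these dimensions.
* Correlation-matrix PCA standardises bins by their observed coefficient
  SD, which slightly distorts recovered loading shapes relative to the
  implanted patterns (cosines ~0.9 rather than ~1.0); the covariance
  variant recovers shapes almost exactly and is available as an option.
* The K-means phenotype clustering is exploratory; cluster counts and
  memberships near boundaries are sensitive to the significant-bin count
  feature.
* No re-referencing arithmetic: inputs are assumed already referenced
  (a channel-mapping pass-through is the only provision), and the
  hardware high-pass is treated as a property of the data.
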