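# Methods

## Scope and design

The package reimplements, at ROI level, the analysis chain of a two-group
(ASD vs. neurotypical) movie-watching fMRI study: motion quantification and
censoring, temporal denoising of ROI timecourses, inter-region (IRC) and
inter-subject (ISC) correlation metrics, and a preregistered-style battery
of covariate-adjusted group tests. Everything upstream of ROI timecourses
(image preprocessing, registration, spatial smoothing, component-based
nuisance regression, ROI extraction from volumes) is out of scope; the
synthetic generator produces ROI-level series directly.

## Motion QC

**FDfilt4.** Each realignment parameter (3 translations in mm, 3 rotations
in radians) is filtered with a zero-phase Butterworth band-stop (order 10,
applied forward-backward via second-order sections), default band
0.31–0.43 Hz. Multiband acquisitions at short TR alias respiration into the
realignment estimates; the band-stop removes that component before
differencing. Rotations are converted to arc displacement on a 50 mm
sphere. FD at TR t is the sum over parameters of |p(t) − p(t−4)|; the first
four entries are defined as 0 (not missing) so the mean FD is a mean over
all TRs. The band edges and the reading of "differences over four
timepoints" are conventions, not published constants; both are exposed
(`band_hz`, `diff_mode="lag4"|"sum4"`, `bypass_filter`).

**Censoring.** TRs with FD > 0.5 mm, plus two TRs on either side, are
marked in a boolean censor mask. The mask follows the subject through all
correlational analyses; data are never deleted.

**Exclusion.** A subject is excluded when mean FD exceeds the per-site
median + 1.5·IQR threshold (thresholds can be supplied externally, e.g.
from a larger project sample, and are then honored verbatim) or when more
than a third of the scan is censored. A site with a single subject and no
fixed threshold is an error, not a silent pass.

**Matching.** While mean FD or censored-TR counts differ between groups at
p < α (two-sample Welch t; α = 0.05), one subject is removed per
iteration: among the candidate extremes (maximum of the higher-mean group,
minimum of the lower-mean group, per metric) the one whose removal most
increases the minimum p across metrics, ties broken by subject id. Groups
whose values are numerically constant are compared with a tolerance guard
(scipy's Welch t on ~1e-17 variances is floating-point noise). Matching
fails loudly rather than shrink a group below 3.

## Timecourse prep

Fixed order: interpolate censored TRs (linear between flanking valid
samples, edges held) → zero-phase Butterworth high-pass, order 5, 100 s
cutoff → z-score each ROI over all TRs. Interpolation precedes filtering so
spikes do not ring; z-scoring uses all TRs because censoring is applied
downstream in the analyses, not by deletion here. Permuting high-pass and
z-score changes outputs; a regression test pins the order. Component-based
nuisance regression is a voxel-level step with no ROI-level analogue here —
an explicit fidelity gap: the generator simply does not inject that class
of structured noise.

## Metrics

All correlation summaries are **means of Fisher z values** (arctanh, |r|
clipped to 1−1e-7), never the z of a mean r. Under the default 13-ROI
atlas the IRC summaries average exactly 15 within-ToM, 21 within-Pain and
42 across-network pairs, computed on the subject's own uncensored TRs.

Between-subject correlations exclude the union of both subjects' censored
TRs. The NT-reference similarity uses, at each timepoint, the mean over
reference subjects with valid data there (timepoints with no valid
reference subject are dropped); NT subjects are compared to the average
with themselves left out, non-members to the full-group average. Any
correlation requires at least 10 jointly valid timepoints (arbitrary,
logged, configurable). The T04 event magnitude is the mean of the z-scored
ToM network timecourse over the uncensored TRs of a 3-TR window (≈ one 2 s
film frame at TR 0.72 s); in the synthetic world the window sits at the ToM
template's peak, for real data it is user-supplied. A fully censored window
yields a missing value, deleted listwise downstream.

## Inference

Models are OLS with listwise deletion. Interaction terms (default
group×site; group×score for brain-behavior models) are fitted first; every
interaction with p ≥ 0.05 is dropped and the model refitted. With
standardization on (default), continuous variables are z-scored and
interactions are products of standardized columns — main effects then read
as simple effects at the sample mean; raw-scale coefficients are reported
alongside. Cohen's d for a model term is d = 2t/√df (a partial-correlation
variant is available); the d for Welch tests uses the (n−1)-weighted pooled
SD, signed group2 − group1. Bayes factors for hypothesized nulls use the
BIC approximation BF01 ≈ exp((BIC_alt − BIC_null)/2); this preserves the
direction and rough magnitude of null evidence but is not numerically
identical to a default-prior Bayesian regression. Bonferroni correction is
applied to the MASC/AQ pair of brain-behavior tests (α = 0.025).

The battery is a fixed list of 11 models and 6 t-tests (group models for
the three IRC summaries and the two reference similarities;
specialization–similarity association models per network; within- vs.
across-group paired tests per group and network plus the within-group Welch
tests; brain-behavior models for MASC, AQ, EQ and the T04 magnitude).

Calibration note: the group-term type-I error of the *pruned* model is
held to [0.03, 0.07] by simulation; its null p-value is only approximately
uniform because pruning is a pretest. Exact uniformity holds (and is
asserted) for the un-pruned OLS t under a Gaussian null. Measured at 1000
null replicates, n = 100: rejection rate 0.063.

## Synthetic cohort

The generator is a stated world, not a fit to data.

* **Templates.** Gaussian-smoothed white noise (FWHM 10 s), mutually
  orthogonalized (shared audiovisual component, ToM template, Pain
  template) and standardized; the two network templates correlate at
  exactly 0. They preserve the correlation structure the analyses need
  without claiming to model any actual film scene.
* **Subjects.** ROI r of network N:
  `y_r = c_{g,N} f_N + λ f_{N'} + a s + σ_u u + σ_ε ε_r`, with one
  smoothed, template-orthogonalized idiosyncratic series u per subject
  shared across that subject's ROIs (idiosyncratic but internally
  coherent), leak λ = 0.15·c_{g,N'}, shared loading a = 0.3, σ_u = 0.8,
  σ_ε = 0.5. Evoked loadings: NT 0.60 (ToM) / 0.65 (Pain), ASD 0.40 /
  0.50 — NT above ASD on both networks with the larger gap in ToM, so
  within-NT > across-group > within-ASD similarity holds in expectation
  and the group contrasts have the built-in signs. σ_u balances realistic
  ISC magnitudes against a clear ordering; with these defaults expected
  within-NT ToM pair correlation is ≈ 0.40.
* **Closed form.** For two subjects of groups g, h the expected
  network-timecourse correlation is
  (c_g c_h + λ_g λ_h + a²) / √(v_g v_h) with
  v = c² + λ² + a² + σ_u² + σ_ε²/R; with λ = a = σ_ε = 0 and unit total
  variance this reduces to c², the value the recovery tests check
  (Monte-Carlo agreement within 0.05 over ≥ 200 pairs).
* **Motion.** Six columns of smoothed random walk (step 0.01 mm) plus a
  0.33 Hz sinusoid (0.05 mm, inside the FD filter's stop band; rotations
  scaled by 1/50 so arc displacement matches), plus displacement spikes of
  2.0 mm at TRs drawn independently at 0.01/TR (≈ 5.5 per 548-TR scan).
  The same TRs receive a +3.0 (z units) offset in every ROI of the BOLD
  series — a shared artifact that inflates correlations, so censoring is
  consequential and its efficacy testable against ground truth.
* **Behavior.** AQ/MASC/EQ drawn per group at the published cohort means
  and SDs (ASD higher AQ, lower MASC/EQ); age ≈ N(27.3, 6.6) (clipped at
  18), FSIQ ≈ N(110.8, 11.6), sex at the cohort's female fractions. MASC
  is coupled to within-ToM IRC in NT only at ρ = 0.6, mixed so its
  marginal moments are unchanged. ρ was fixed a priori from a power
  sketch (Fisher-z slope difference 0.69, SE ≈ 0.22 at n = 34/73 → > 80%
  interaction power, which the stated world requires) and not adjusted
  afterwards. Scores are not clipped to instrument ranges; clipping would
  distort the coupling.
* **Seeding.** One global seed; per-subject seeds and per-draw-family
  substreams derive from `numpy.random.SeedSequence` spawn keys, so cohorts
  are bit-reproducible, subjects are independent of the rest of the
  subject set, and the artifact injection draws no randomness (clean and
  spiked versions of a subject share every component).

**What a green test does and does not establish.** The generator emulates
shared evoked structure, group loading differences, motion artifacts and
behavior coupling. It does not emulate hemodynamics, scanner drift,
physiological noise beyond a single sinusoid, spatial structure, or
non-Gaussian score distributions. Green tests establish that the pipeline
recovers the stated world's parameters and orderings — not that the same
effects exist in any real cohort. Because one idiosyncratic series is
shared across all 13 ROIs of a subject, within-subject IRC magnitudes run
higher than typical empirical values; the group *contrasts*, not the
absolute levels, are the emulated quantities.

## Numerical choices

Fisher clipping at 1−1e-7; zero-variance guards at 1e-12 (relative for the
matching t-test); filters as second-order sections with forward-backward
passes (`sosfiltfilt`), which need series longer than the filter's pad
length (63 samples for the band-stop — short traces must bypass the
filter); percentile-based IQR with numpy's linear interpolation; binary
factors coded NT=0/ASD=1, M=0/F=1, other two-level factors by sorted order.
Ties in the matching loop break by subject-identifier order. The
determinism contract (identical config + seed ⇒ identical output files) is
enforced by checksum tests; the config hash excludes the output directory.

## Known limitations

No voxel-level front end (NIfTI input would slot in as a new loader), no
mixed-effects or permutation inference, no site harmonization beyond the
site covariate, Bayes factors only via the BIC approximation, and the
synthetic world's fidelity gaps listed above.
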