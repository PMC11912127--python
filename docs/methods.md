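# Methods

`ramanstage` implements a label-free workflow for staging living cortical
organoids from confocal Raman microscopy maps: hyperspectral preprocessing,
PCA reduction, Random-Forest classification, importance-weighted loading
interpretation, biomarker band quantification, and a centroid-distance
separability analysis. Because no organoid Raman dataset is publicly
deposited, the package ships a synthetic hyperspectral generator that
reproduces the statistical structure the analysis assumes; everything
downstream is validated against it.

## The synthetic acquisition model

One field of view (FOV) is an H x W grid of pixels (default 50 x 50 at a
1.5 um pitch), each carrying a 1340-channel raw spectrum:

    s(nu) = sum_b a_b(stage) * L(nu; c_b, w_b) + p(nu) + eps(nu) + spikes

* **Bands** `L` are unit-height Lorentzians by default (the natural line
  shape for Raman transitions; Gaussian selectable), parameterised by center
  `c_b` (cm^-1) and half-width at half-maximum `w_b`. The shipped band set
  covers nucleic acids (788 cm^-1), glycogen (850), polysaccharide (940),
  phenylalanine (1004), amide III (1350), CH2 lipid (1440) and amide I
  (1650).
* **Stage profiles** assign each band an amplitude in arbitrary detector
  counts. The four-stage preset encodes the maturation trends the analysis
  is meant to recover: nucleic-acid and protein (amide I) amplitudes fall
  monotonically from 6 to 20 weeks while glycogen rises. An `effect_scale`
  knob multiplies each stage's deviation from the across-stage mean profile;
  0 collapses the study onto a single profile (the null used for
  calibration tests).
* **Autofluorescence baseline** `p` is a polynomial of degree <= 5 on the
  axis mapped to [-1, 1], with coefficients drawn per FOV around a fixed
  mean — a slowly varying background an order of magnitude taller than the
  bands, as in real 785 nm measurements.
* **Noise** is i.i.d. Gaussian per channel (default SD 10 counts) and
  **cosmic rays** are single-channel positive spikes, Poisson-distributed
  per spectrum (default rate 0.1) with amplitude uniform in [20, 200] noise
  SDs — tall enough that a 3-sigma robust rule must remove them.
* **Hierarchy**: all pixels of a FOV share one organoid-level and one
  FOV-level multiplicative log-normal effect (SDs 0.03 and 0.015). Intensity
  scale is the dominant nuisance in practice, and it is exactly what the
  z-score/Frobenius normalization removes.

The axis is linear (channel 235 at 600 cm^-1, step 1200/869 cm^-1, so 870
channels fall in the 600-1800 cm^-1 fingerprint); real spectrograph axes
are mildly nonlinear, but no stage of the pipeline assumes linearity.

Generation is deterministic: each cube draws from a stream keyed by
(seed, stage, organoid, FOV), so studies are bit-reproducible and cubes can
be generated lazily in any order.

**What the generator does not emulate** — and hence what passing tests do
not certify about real data: optical physics (point-spread function,
confocal sectioning, detector response), wavenumber-calibration error,
pixel-to-pixel biochemical texture within a FOV (pixels differ only by
noise and cosmic rays), band-shape changes (only amplitudes move between
stages), and non-polynomial background shapes. Results on the synthetic
presets demonstrate that the pipeline recovers what it injects at realistic
noise scales, not that organoid spectra are this clean.

## Preprocessing

Per FOV, in order (section defaults in parentheses):

1. **Fingerprint extraction** — keep channels with 600 <= nu <= 1800
   (closed interval).
2. **Hampel despiking** (half-width 3, i.e. 7-channel windows truncated at
   the edges; 3 sigma) — a channel is replaced by its window median iff it
   deviates from it by more than `3 * 1.4826 * MAD`. Note the false-alarm
   behaviour: with only 7 samples the MAD is a noisy scale estimate, so on
   pure Gaussian noise about 5% of channels are (harmlessly) moved to the
   local median; genuine spikes (>= 20 noise SDs) are removed essentially
   always. Despiking runs before smoothing — a smeared spike would become
   undetectable.
3. **Savitzky-Golay smoothing** (window 9, order 5), exact on polynomials
   up to degree 5; edges are fitted on the truncated window.
4. **Iterative modified polynomial baseline** (degree 12, 100 iterations):
   fit a least-squares polynomial, replace the working spectrum by the
   pointwise minimum of itself and the fit, repeat; the final fit is the
   baseline. Degree-12 fits on raw wavenumbers are ill-conditioned, so the
   fit uses an orthonormalised Legendre basis on the axis mapped to
   [-1, 1] — the identical least-squares problem, numerically stable
   (residual energy < 1e-8 of input energy on polynomial inputs).
5. **Spatial binning** — non-overlapping 5 x 5 block means (50 x 50 ->
   10 x 10), averaging detector noise down five-fold per channel.
6. **Normalization** — per-spectrum z-score (mean 0, SD 1 across channels)
   followed by Frobenius normalization. The two written descriptions of
   this step disagree on order, and the norm's scope (one spectrum vs one
   FOV block) is not stated; both orders and both scopes are config
   options. The default — z-score then Frobenius, per spectrum — follows
   the processing-methods sentence order and guarantees every output row
   has unit L2 norm. z-scoring removes exactly the multiplicative/additive
   scale nuisance the hierarchical random effects inject.

Degenerate inputs: a spectrum that is numerically pure baseline (residual
norm <= 1e-4 of its pre-subtraction norm) cannot be standardized and aborts
the pipeline with a `DegenerateSpectrumError` naming the cube. The batch
pipeline computes stages 2-4 in single precision (raw counts need < 7
significant digits); the per-spectrum functions preserve their input dtype,
so float64 calls match float64 oracles bit-for-bit.

Open order question: despiking/smoothing/baseline could precede or follow
fingerprint extraction; the default extracts first (processing cost drops
35% and band behaviour at the fingerprint edges is unaffected in testing).

## Decomposition and classification

PCA is centered covariance PCA (rows are already normalized), fitted per
experiment, with a fixed sign convention (the largest-magnitude element of
every loading is positive) so repeated fits and downstream weighted sums
are reproducible. Component indices are 1-based everywhere a user sees
them ("PC1" is index 1).

Classification uses a 50-tree Random Forest on the first 25 PC scores
(PCs 2-20 for the cell-line comparison, where PC1 is a line-independent
nuisance direction). Two complementary estimates are reported, matching
how the two numbers coexist in practice:

* stratified k-fold cross-validation on the full table gives the accuracy
  mean +/- SD (k = 10 by default; the four-stage preset uses k = 30);
* a stratified 70/30 hold-out split gives the confusion matrix and
  per-class precision/recall/F1.

If a class has fewer rows than folds, stratification is relaxed to plain
K-fold with a warning (leave-one-out remains expressible). Tree
hyperparameters beyond the ensemble size stay at library defaults and are
recorded in the run manifest.

Feature relevance is screened Boruta-style: each of 10 iterations appends a
column-permuted shadow copy of every feature, fits the forest, and scores a
hit for every real feature beating the best shadow importance; a one-sided
binomial test (alpha 0.05, hits ~ Bin(10, 1/2) under irrelevance) declares
confirmed / rejected / tentative. The screen runs on PC scores, consistent
with the rest of the analysis.

## Interpretation

The spectral signature is `W(nu) = sum_j importance_j * loading_j(nu)` over
the selected components — a linear map from channel space that emphasises
the wavenumbers driving the classification. Biomarker quantification
integrates each preprocessed spectrum trapezoidally over a +/- 10 cm^-1
window around the band center (the window half-width is not dictated by
anything physical; 10 cm^-1 spans a typical cellular Raman line and is
configurable per band). No local chord is subtracted inside the window —
spectra are already baseline-corrected. The nucleic-acid center is 788
cm^-1 (the ring-breathing mode; 780 appears once in the literature
assignments but 788 is the consistently used value).

Group comparisons use the two-sided Mann-Whitney U test with midrank ties:
exact null distribution for small tie-free samples, normal approximation
with tie correction otherwise. Stages are compared adjacent-in-time; cell
lines all-pairs. Raw p-values are flagged at 0.05 by default (matching the
reporting convention of the analysis this reproduces); an optional
Benjamini-Hochberg switch adjusts across the pairs of a band, and the
choice is recorded in the output.

## Separability

Group centroids are computed in a chosen PC subspace (default PC1, PC2,
PC4) and compared by Euclidean distance. The minimum detectable interval
between adjacent stages assumes centroid distance grows linearly with the
time separating the stages:

    dt_min = d0 * (t_b - t_a) / d(a, b),    d0 = 0.85 (default threshold)

The linear scaling is a modelling assumption, not an estimated law; it is
printed with every report. A zero-distance pair is flagged non-separable
rather than given a number. No uncertainty is attached to dt_min.

## Frozen presets and problem sizes

Three presets define the study conditions end to end; their amplitudes,
noise and random-effect scales are frozen and should be treated as the
definition of the synthetic experiment:

* `pgp1-4stage`: 4 stages (6/12/16/20 wk) x 3 organoids x 6 FOVs of
  50 x 50 px -> 7200 binned spectra. Band amplitudes are affine in one
  shared maturation coordinate (stage means collinear in channel space) and
  chosen so the per-spectrum channel SD is stationary across stages (within
  ~3%). Both properties matter for interpretability, not just tidiness:
  per-spectrum z-scoring turns any across-stage trend in the spectrum SD
  into a spurious "echo" trend on stage-constant bands and bends the stage
  means, creating weakly informative secondary components whose signed
  contributions to the importance-weighted loading sum can cancel a true
  band signature (the broad amide I band is the most susceptible);
* `h1-2stage`: 2 stages (16/20 wk) x 2 organoids x 8 FOVs -> 3200 spectra;
* `line-comparison`: 2 lines x 2 organoids x 6 FOVs -> 2400 spectra, plus
  a broad per-FOV "substrate" band, identical in distribution for both
  lines, that dominates PC1 (the real comparison used roughly an order of
  magnitude more FOVs; the preset is the desk-scale analogue).

Null-calibration tests reuse the four-stage design with `effect_scale = 0`
**and the hierarchical effects zeroed** (organoid/FOV multiplicative SDs and
the per-FOV baseline variation). The exchangeable null is deliberate: with
the hierarchy on, rows within a FOV are pseudo-replicates — row-level
cross-validation folds share FOVs, letting the forest fingerprint a FOV's
residual signature and recover its (train-side) label at well above chance
even when stages are identical in distribution, and spectrum-level rank
tests respond to real random FOV shifts. Chance-level accuracy with
binomial reference bounds and nominal test size are only meaningful
statements about exchangeable rows. The type-I calibration of the band
tests runs 200 small exchangeable-null replicates (2 groups x 100 unbinned
spectra on a 256-channel axis) rather than 200 full studies, which fixes
the replicate count the calibration needs without the full studies' cost.

## Known limitations

* Rows from one FOV are pseudo-replicates: they share acquisition nuisances
  that survive preprocessing, so row-level cross-validation accuracy and
  spectrum-level significance tests are optimistic about generalization to
  unseen organoids. On the synthetic hierarchy this inflates a null
  study's CV accuracy from 0.25 to ~0.33 and the band tests' spectrum-level
  type-I rate from 0.05 to ~0.2; the same caveat applies to any real
  analysis that cross-validates over binned pixels. Organoid-level claims
  need grouped (leave-organoid-out) validation.
* The despiking false-alarm rate (~5% of noise channels nudged to the
  local median) is inherent to a 3-sigma rule with 7-sample MAD scale
  estimates; it is harmless here but matters if single-channel features
  carry signal.
* Band areas are computed on normalized spectra, so they are relative
  (dimensionless) quantities; only comparisons between groups are
  meaningful, not absolute concentrations.
* The minimum-interval extrapolation inherits the linear distance-time
  assumption and the choice of PC subspace.
* The importance-weighted loading sum is a signed combination of loadings:
  when several components carry importance, their contributions can cancel
  at individual wavenumbers, understating a genuinely differential band.
  Inspecting the top components' loadings alongside W guards against this.
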