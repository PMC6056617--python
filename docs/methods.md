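# Methods

## Scope and pipeline order

The pipeline starts from spatially aligned, normalized 4D BOLD data (real
or synthetic); slice timing, realignment, coregistration, normalization and
segmentation are out of scope, as is computing TIV (it enters as a
covariate).  The fixed stage order is: discard initial volumes → motion QC
→ nuisance regression → band-pass → FCD mapping (counts → rescale →
smooth) → group GLM → Monte-Carlo extent correction → seed-based follow-up
→ clinical partial correlation.

## Preprocessing

* **mFD.** Frame-wise displacement at each transition is the sum of the six
  absolute backward parameter differences, rotations converted to arc length
  on a 50 mm sphere; mFD is the mean over transitions.  Subjects strictly
  above group mean + 2 × sample SD (n−1 denominator) are excluded — strict
  inequality mirrors the rule's "higher than" wording.  By default mFD is
  computed after discarding the initial volumes (configurable; the
  alternative is a defensible convention too).
* **Nuisance regression.** OLS residuals per voxel against WM mean, CSF
  mean, the six motion parameters, a linear drift term and an intercept;
  with global signal regression (GSR) enabled the within-mask mean series is
  appended.  The design is rank-checked and the offending columns are named
  on failure.  On synthetic data the WM/CSF series are generated nuisance
  components; on real data the caller supplies them (no segmentation here).
* **Band-pass.** An ideal (boxcar) filter on the discrete Fourier grid:
  frequencies f with 0.01 ≤ f ≤ 0.08 Hz retained (inclusive bounds, DC
  removed whenever the low edge is positive).  Chosen over IIR/FIR designs
  because its gains are exactly assertable (1 in band, 0 outside) and it is
  idempotent; nothing downstream depends on filter roll-off.

## FCD mapping

* Correlations are computed on the preprocessed series, in row chunks
  (default 2048), so the N × N matrix is never materialized; only the
  thresholded neighbor lists are kept.  The threshold is strict (r > 0.6);
  ties at exactly 0.6 do not connect.
* The growing algorithm's fixed point equals the connected component
  containing x₀ of {x₀} ∪ {j : r(x₀, j) > T} under the spatial adjacency —
  the implementation labels that set's bounding box
  (`scipy.ndimage.label`), which makes order-independence structural rather
  than incidental.  Default adjacency is connectivity-26 (the full 3×3×3
  neighborhood); 6/18 and radius-based neighborhoods are supported, the
  latter via an in-repo BFS when offsets exceed the 3³ cube.
* The center voxel is excluded from both counts, so short ≤ global and
  long = global − short hold exactly in integer arithmetic (a negative
  long-range value raises an internal-consistency error).  An include-self
  flag shifts global and short by one and cancels in the difference.
* Zero-variance in-mask voxels raise by default (`zero_variance="zero"`
  assigns degree 0 with a warning instead).
* Each of the three maps is rescaled by **its own** in-mask mean (a shared
  global-mean scaling is available behind a flag); the rescaling mean is
  taken over the gray-matter analysis mask.  An all-zero count map (e.g. a
  long-range map when only contiguous structure is present) cannot be
  rescaled and is left as zeros with a warning by default
  (`empty_map_policy="error"` to raise instead).
* Smoothing: Gaussian kernel with σ = FWHM/(2√(2 ln 2)) per axis in voxel
  units, support truncated at 6σ (negligible truncation error), applied on
  the mask bounding box with reflecting boundaries and re-masked afterwards
  — this avoids the edge attenuation of zero-padded convolution; the
  smooth-then-remask order is configurable.  Rescaling precedes smoothing.

## Group inference

* Voxel-wise OLS with the group indicator coded 1 = control, 0 = patient
  (positive t ⇒ controls larger, the "HC > ALS" convention), gender coded
  M = 0 / F = 1, continuous covariates mean-centered (affects only the
  intercept).  df = n − rank(design).  Voxels with exactly zero residual
  variance (possible in synthetic maps) get t = 0 to keep the map finite.
* Voxel thresholding is two-sided at p = 0.01 (|t| above the t quantile),
  clustered per sign; the null simulation mirrors this with the two-sided
  |z| quantile, which makes the suprathreshold mass equal voxel_p in both.
* The null simulation smooths unit Gaussian fields to the *stated* 6 mm
  FWHM rather than estimating smoothness from residuals (only this mode is
  claimed), standardizes each field by its in-mask empirical mean/SD, and
  records the largest cluster per iteration (both signs).  The corrected
  extent threshold is the smallest k whose empirical tail fraction is ≤ α —
  Monte-Carlo semantics, not a fitted distribution.  Seeds are mandatory
  config; nothing falls back to wall-clock entropy.
* Cluster peaks are the max-|t| voxels, ties broken by lexicographic voxel
  index (documented so reported peaks are reproducible).

## Seed-based follow-up and clinical association

Seed = a surviving cluster's mask (an atlas subregion mask can be supplied
instead); the unweighted seed-mean series is correlated with every in-mask
voxel, z = arctanh(r) with |r| clipped at 1 − 10⁻⁷, the **z** maps (not the
r maps) are smoothed with the same 6 mm kernel, and group comparison reuses
the identical GLM + extent-threshold code path.  Seed voxels are included
in the maps (r ≈ 1 near the seed); clusters that fall inside the seed
itself are visible in the tables by their coordinates.  Atlas files are
caller-supplied label volumes with an id → name lookup; unlabeled territory
reports "unassigned".

Clinical association: partial Pearson correlation of cluster-mean FCD
(taken from the rescaled, smoothed maps that entered the GLM; a flag uses
the raw counts) with ALSFRS-R, disease duration and the progression rate
(48 − ALSFRS-R)/duration, residualizing on age, gender, TIV (optionally
mFD); p from t = r√((n−k−2)/(1−r²)).  Bonferroni m = clusters × variables,
recorded in the output so the correction is auditable.

## Synthetic cohorts

The generator emulates the study conditions: two groups (default 35/group),
3 mm isotropic grids, 230 volumes at TR = 2 s, spatially autocorrelated
noise smoothed to 6 mm FWHM and variance-renormalized (matching the
smoothness the cluster correction assumes).  Planted structure:

* **Coupling model.** Block members get y = w·s + √(1−w²)·ε with a private
  shared signal s and w = √(ρ), so two members correlate at ρ in
  expectation; group effects multiply ρ for the affected group.  The exact
  mapping is recorded in the cohort manifest.  With spatially smoothed
  noise, *adjacent* members additionally share noise correlation
  ≈ (1−ρ)·exp(−d²/4σ²); the coupling contract is therefore verified at
  noise FWHM 0, where it is exact.  This neighbor correlation is a feature,
  not a bug: real unsmoothed BOLD is also locally correlated, and it gives
  every voxel a realistic nonzero local FCD floor.
* **Covariates.** age ~ N(49, 10) truncated to [20, 80] years; TIV ~
  N(1.6, 0.16) L; gender alternating (balanced); patients additionally
  ALSFRS-R ~ round(N(30.4, 6.8)) clipped to [0, 48] and duration ~
  log-normal with mean 22.9 and SD 18.1 months — plausible ranges for an
  ALS cohort, recorded in `COVARIATE_MODEL` so tests read rather than
  hard-code them.  Planted effect sizes (coupling multipliers) are free
  parameters of the validation suite, not claims about any disease.
* **Nuisances** (all optional, default off): voxel-specific linear drift,
  a global signal, a motion-linked artifact lying in the span of the six
  motion parameters (hence exactly removable by regression), and WM/CSF
  physiological series.  Motion traces are 6-column random walks; the one
  step-SD parameter applies to translations in mm and, divided by 50, to
  rotations in rad, so both contribute comparably to FD on the 50 mm
  sphere.  Rotations are stored in radians; mm conversion happens only in
  the mFD computation.

What the generator does **not** emulate: hemodynamic response shape,
scanner artifacts (spikes, ghosting), anatomical covariance of real gray
matter, or surface geometry.  Passing recovery tests therefore demonstrate
correctness and calibration of the *analysis machinery* under its own
assumptions, not performance on real scanner data.

## Validation experiments and problem sizes

The reference planted-truth study (`fcdpipe.validation`) uses a 24³ grid
with an ellipsoidal gray-matter domain of ≈2,200 voxels, 20 subjects per
group, 200 volumes: a 4³ contiguous block (ρ = 0.9) whose coupling is
multiplied by 0.3 in patients, and a remote 3³+3³ pair (ρ = 0.81) likewise
decoupled — patient target correlations fall below the 0.6 threshold while
controls' stay above.  Recovery is declared when a surviving HC > patient
cluster overlaps the planted site; the suite requires ≥ 90% of 20 cohort
seeds for both the short-range-FCD and the seed-connectivity arm.  The
null distribution (500 iterations) is computed once per mask and reused
across seeds, since it depends only on mask and parameters.

Family-wise calibration runs 200 null cohorts of 6-mm-smooth Gaussian maps
on a 14³ grid against a 500-iteration null and expects a ≈5% surviving-
cluster rate (3-binomial-SD band).  These sizes keep each experiment in the
minutes range on a single core while leaving the Monte-Carlo tolerances
meaningful; the pipeline defaults (5,000 iterations) remain the study
values.

## Known limitations

* Single correlation threshold (r > 0.6) only; no multi-threshold sweep and
  no dynamic/windowed FCD.
* Only the stated-smoothness mode of the cluster correction is implemented
  (no residual-based smoothness estimation), and no permutation, TFCE or
  random-field alternatives.
* The ideal band-pass assumes the frequency grid of the acquisition; very
  short series have coarse frequency resolution.
* Cluster-mean ↔ clinical associations are correlational with listwise
  complete patients; no regression-based brain-behavior mapping.
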