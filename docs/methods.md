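# Methods

This note documents the models, default parameters, and design choices behind
`favint`, and what the synthetic-data experiments can and cannot show about
real data.

## The analysis model

**First level.** Each condition's stimulation timeline is a boxcar over its
blocks, convolved with the canonical double-gamma hemodynamic response
(response gamma with shape 6 / scale 1 s, undershoot gamma with shape 16 /
scale 1 s, weighted 1 : 1/6, 32 s support, unit peak).  Convolution is done on
a 16-fold oversampled time grid and read out at scan onsets.  The design adds
the six rigid-body motion parameters (columns with zero variance are dropped),
a discrete-cosine high-pass basis containing every frequency below 1/128 Hz,
and an intercept.  The error term is a first-order autoregressive process
with a *fixed* coefficient ρ = 0.2; the additional white component of the
nominal AR(1)+white model is absorbed into the innovation variance rather
than estimated, which matches the stated error model without introducing an
estimation step the model does not define.  Estimation is ordinary least
squares after premultiplying data and design with the exact AR(1) whitening
transform (first row scaled by √(1−ρ²)).  The first five volumes of each run
precede T1 equilibrium and are discarded; block onsets are referenced to the
first retained scan.  Voxels with near-zero temporal variance are excluded.

**Integration statistic.** The max-criterion statistic is computed per subject
as the voxelwise minimum of the difference contrasts, `min(AV−A, AV−V)`,
algebraically identical to `AV − max(A, V)` (verified exactly on fitted
betas).  The same minimum over `V−A, V−E` and `F−H, F−O, F−S` yields voice-
and face-sensitivity.  Note a structural property of this statistic: as a
minimum of noisy differences it is *negatively biased under the null*
(conservative), so single-group null means sit slightly below zero; unbiased
null behaviour holds for between-group differences, which is how the group
analyses use it.

**Second level.** Subject contrast images enter a voxelwise linear model with
an intercept, a group indicator (coded 1 for SAD; the tested effect is
SAD−HC) or the intercept itself for one-sample tests, and covariates:
mean-centred age, 0/1 gender and site indicators.  Cluster inference is
permutation-based: the observed t map is thresholded at voxel p < 0.001
(one-sided), connected components are formed with 18-connectivity
(faces+edges; 6 and 26 are available), and each cluster's family-wise-error p
is `(1 + #{null max cluster size ≥ observed}) / (1 + n_perm)` where the null
is built by Freedman–Lane resampling of covariate-residualized data — sign
flipping for one-sample designs, row permutation for two-sample designs.
Permutation inference was chosen over parametric Gaussian-random-field
cluster correction because it is exact under exchangeability at any search
volume, including the reduced grids used here; a closed-form random-field
cluster p (`grf_cluster_pvalue`) is provided only as an order-of-magnitude
cross-check.

**Topography.** Each subject's integration maximum is the within-mask voxel
with the largest contrast value (ties broken by the smallest linear voxel
index — the map is deterministic and the choice documented).  The search mask
is the whole-sample integration cluster; hemispheres are assigned by the sign
of the x coordinate with midline voxels excluded.  Group centroids are
arithmetic means per axis; axis differences use two-sample t tests with a
Bonferroni factor of 3 axes × number of hemispheres.  Individual maxima are
taken as the global within-mask maximum regardless of subject-level
significance (subject-level thresholding is not part of the definition here).

**PPI.** The seed series is the mean over voxels within a 2-mm sphere around
the individual peak (on the 3-mm grid this is exactly the peak voxel),
adjusted for effects of interest: all design columns except the condition
regressors (motion, high-pass, intercept) are regressed out.  Deconvolution
parameterizes the latent series on the full orthonormal DCT basis and solves
a ridge problem against the HRF Toeplitz operator; the penalty is
`ridge · trace(GᵀG)/n` with `ridge = 1e-4`, small enough that reconvolution
reproduces smooth band-limited signals to well under 5 % error while bounding
the noise amplification of the near-singular operator (an approximation to
the classical empirical-Bayes deconvolution, not a bit-reproduction of it).
Psychological vectors are condition boxcars at the scan grid, centred within
the scan window — uncentred indicators would confound the interaction with
the task main effect.  Interaction regressors are formed at the latent level
(`H·(latent × ψ_c)`) and the latent timescale equals the scan grid: with 8-s
blocks and TR ≤ 2 s, supersampling changes the regressors negligibly (it
remains a config option).  The PPI integration statistic is the voxelwise
minimum of the interaction differences, mirroring the first-level definition;
whether the minimum should instead be applied to a single pre-combined
psychological vector is ambiguous in the field — the per-subject minimum was
chosen for consistency and is flagged for sensitivity analysis.

**Post-hoc ROI statistics** use the group-difference cluster as ROI (the
region where the groups differ is also the PPI seed region), pooled-variance
two-sample t tests (with 18 + 18 subjects these equal the unequal-variance
statistic), one-tailed tests only for the sensitivity hypotheses, and Pearson
correlations against severity scores.  The 2×2 χ² test uses no continuity
correction.  Covariates are omitted from these post-hoc t tests (a
covariate-adjusted variant exists in `group.second_level_glm`); the degrees
of freedom of the reported statistics (34/35 at n = 36) correspond to the
unadjusted tests.

## The synthetic-data generator

The generator emulates a two-site, two-group (18 + 18 in the reference
configuration) face–voice study:

- **Designs.** Integration: 12 blocks × 3 modalities × 8 s, five stimuli per
  block (180 presentations), modality order rejection-sampled until no more
  than two adjacent blocks share a modality.  Voice localizer: 12 vocal, 6
  animal, 6 environmental and 12 silent 8-s blocks.  Face localizer: 8 × 16-s
  blocks of faces, houses, objects, scenes.  The inter-block interval of the
  integration experiment is not a published constant; the default is 8 s of
  rest, and the scan count is derived from the realized sequence (site scan
  counts are treated as presets, not constraints).
- **Cohort.** Continuous psychometrics are Gaussian per group and, in
  exact-match mode, affinely rescaled so sample means/SDs equal the target
  summaries to ~1e-15; gender/site counts are matched exactly.  Group
  comparisons on such cohorts therefore reproduce the target table's t and χ²
  statistics to the printed decimal.
- **BOLD.** Signal is `Σ_c β_c(v)·(boxcar_c ⊗ HRF)(t)`, spatially smoothed at
  8 mm FWHM; noise is stationary AR(1) (ρ = 0.2, innovation SD 1 in effect
  units) plus optional white noise; drift is a per-voxel random combination
  of the two lowest discrete-cosine shapes (below the 1/128 Hz cutoff, hence
  exactly removable by the high-pass basis — which makes filter correctness
  testable); five dummy volumes carry a decaying intensity transient.
- **Truth.** The integration effect is a Gaussian blob (default FWHM 16 mm,
  chosen so the simulated whole-sample cluster has a realistic extent of
  tens-to-hundreds of voxels rather than a few voxels) in a right-temporal
  slab (20 × 24 × 20 voxels at 3 mm; full grids are supported).  Unimodal
  amplitudes are A = 2.0, V = 0.8 — the auditory response dominates, as in a
  voice-sensitive region, so the integration minimum is taken on AV−A in
  essentially all subjects — and AV = max(A, V) + gain with default gains
  0.5 (HC) and 1.0 (SAD).  Subject peaks jitter around group mean locations
  (defaults (59.3, −30.5, 8.3) for HC and (61.3, −12.0, 2.7) for SAD: the
  patient group's truth is anteriorized along y), with 4 mm SD.
- **Connectivity truth.** A latent AR(1) fluctuation (SD 1, lag coefficient
  0.5) is added, HRF-convolved, to a 12-mm region around the subject's peak;
  the target region receives the same fluctuation scaled by a baseline
  coupling (0.5) plus a condition-specific gain (default: AV gain 0.8 in SAD,
  0 in HC) applied at the latent level — exactly the generative model the PPI
  analysis inverts.
- **Sensitivity truths.** The voice localizer drives a wide (24 mm FWHM)
  voice-preferring strip centred midway between the two group peaks (the
  voice-sensitive belt covers both); the face localizer drives the same
  region weakly and equally for all categories, so the face-sensitivity
  statistic is null there.  Per-subject amplitude jitter (30 % SD per
  condition) produces realistic between-subject variance.

**What passing tests do and do not show.**  The simulator shares its forward
model with the analysis (same HRF, same boxcars), so recovery tests validate
the estimation machinery, not robustness to HRF misspecification, nonlinear
saturation, motion artefacts, susceptibility dropout, or non-stationary
noise — none of which are simulated.  Null-calibration results (cluster FWE,
correlation type-I error) do not depend on the forward model and transfer to
real data under exchangeability.  The published coordinates and cluster sizes
of real studies enter only as simulator parameter defaults and output-format
references; nothing here reproduces real-data results.

## Numerical choices and degenerate inputs

- Whitening uses the exact stationary AR(1) square-root; `ρ = 0` reduces to
  OLS (tested to 1e-10).
- Degrees of freedom are `n_scans − rank(design)`; rank deficiency raises an
  error naming the offending columns.
- Voxels with zero residual variance at the second level (e.g. identical
  maps) report t = 0 rather than 0/0.
- Two-sample tests on two constant groups report t = 0 when the means agree
  and raise otherwise; all-zero ROI values give a defined t = 0.
- Cluster p-values use the add-one permutation estimator, so reported
  p ≥ 1/(1+n_perm); ties in the null distribution are handled by `≥`.
- Peak ties resolve to the smallest linear voxel index.
- Exact-match cohort rescaling requires n ≥ 2 per group (sample SD defined).

## Problem sizes of the shipped experiments

The test suite and `scripts/acceptance.py` use reduced, seed-deterministic
problem sizes chosen to exercise each property with adequate Monte-Carlo
precision: 4³–16³ voxel grids, 100–200 replicates for recovery and
calibration runs, 200 permutations per cluster test, 100 simulated group
comparisons for PPI recovery, and a 12-per-group demo pipeline.  These sizes
are the package's own defaults for its validation experiments; all scale up
by configuration.

## Known limitations

- The AR coefficient is fixed, not estimated per voxel; misspecified ρ leaves
  residual autocorrelation (the whitened-residual test bounds it at the
  matched ρ only).
- Parametric random-field cluster correction is provided only as a crude
  cross-check; its smoothness estimate is user-supplied, not estimated from
  residuals.
- The max-criterion statistic is conservative under the null (negative
  bias); single-group "integration present" claims should rely on the
  one-sample test within regions defined independently, as done here.
- Hemisphere handling assumes an axis-aligned affine when splitting masks at
  x = 0.
- The deconvolution ridge penalty is a single global constant, not an
  empirical-Bayes prior estimated per subject.
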