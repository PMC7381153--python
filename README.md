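# favint

Simulation and analysis pipeline for block-design fMRI studies of
**audiovisual face–voice integration** in social anxiety disorder (SAD) versus
healthy controls (HC).

Real studies of this kind compare the hemodynamic response to audiovisual
face–voice stimulation (AV) with the responses to the unimodal auditory (A)
and visual (V) presentations.  A voxel integrates the two modalities in the
*max-criterion* sense when the bimodal response exceeds the larger unimodal
response; per subject this is the minimum-difference contrast

```
min(AV − A, AV − V)  ≡  AV − max(A, V)
```

`favint` implements the complete analysis chain for this design — and a
synthetic-data generator with known ground truth, so every stage can be
validated end to end without access to any scanner data:

- **`favint.synth`** – block-design generation (three-condition 8-s blocks
  with an adjacency constraint, plus voice- and face-sensitivity localizers),
  two-group cohort tables with exact summary-statistic matching, and 4D BOLD
  simulation (boxcar⊗HRF signal, spatial smoothing, slow drift, AR(1) noise,
  condition-dependent seed→target coupling for connectivity tests).
- **`favint.first_level`** – canonical double-gamma HRF, design matrices with
  motion and discrete-cosine high-pass (1/128 Hz) confounds, AR(1)-prewhitened
  GLM (fixed coefficient ρ = 0.2), and the minimum-difference contrasts.
- **`favint.group`** – second-level random-effects t maps with age/gender/site
  covariates and *permutation-based cluster-level FWE correction*
  (voxel p < 0.001, cluster FWE p < 0.05; sign flipping for one-sample,
  Freedman–Lane label permutation for two-sample designs).
- **`favint.topography`** – individual integration maxima, group centroids,
  per-axis t tests with Bonferroni correction (3 axes × hemispheres), and
  peak-coordinate/severity correlations.
- **`favint.ppi`** – psychophysiological interaction: 2-mm seed sphere around
  the individual peak, ridge-regularized hemodynamic deconvolution on a
  discrete-cosine basis, interaction regressors formed at the latent level and
  reconvolved, and the PPI analogue of the integration contrast.
- **`favint.roi_stats`** – ROI means, deconstruction of the integration effect
  into its basis contrasts, voice-/face-sensitivity tests, inter-ROI group
  comparisons, and the cohort-table t/χ² statistics.
- **`favint.pipeline` / `favint` CLI** – one-command orchestration with full
  seed-derived determinism and a manifest.

## Worked example

Run the full simulated study (24 subjects, 12 per group, ~30 s on one CPU):

```sh
favint all --seed 11 --out runs/demo
```

```
run complete in 28.2 s -> runs/demo
significant clusters (whole sample): 1
significant clusters (SAD-HC): 1
significant clusters (PPI SAD-HC): 1
```

The run directory contains, among others, `clusters_sad_vs_hc.tsv`:

```
peak_x  peak_y  peak_z  t_peak   z_peak   size_vx  p_fwe
57      -12     0       11.7959  6.27665  349      0.00199601
```

i.e. a 349-voxel cluster of stronger integration in the SAD group, peaking in
the anterior midsection of the simulated STS slab, significant after
cluster-level FWE correction — the planted group difference (integration gain
1.0 versus 0.5) recovered by the full chain.  `topography.yaml` shows the
planted anteriorization of the SAD integration maxima:

```
centroid_sad: [59.0, -18.75, 3.75]
centroid_hc:  [60.5, -27.25, 5.5]
lsas_y_correlation: {r: 0.63, p: 0.0009}
```

(the y-axis group test in `topography_axis_tests.tsv`: t = 4.64, Bonferroni
p = 0.0004, while x and z stay null), and `roi_report.yaml` characterizes the
group-difference ROI: voice-sensitive (one-sample t = 7.8) but not
face-sensitive (t = −6.0), with no group difference in either sensitivity,
integration effect driven by the auditory basis contrast (AV−A < AV−V in
24/24 subjects), and ROI integration values correlating with the simulated
social-anxiety severity score (r = 0.84).  `clusters_ppi_sad_vs_hc.tsv` shows
the planted AV-specific connectivity increase recovered at the simulated
occipital target (93-voxel cluster, p_fwe = 0.002).

All numbers above are deterministic given `--seed 11`.

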