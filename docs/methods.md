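# Methods

This note documents the models, defaults and numerical choices behind
`restconn`, and what the synthetic validation does and does not establish.

## The synthetic cohort generator

The generator emulates a two-condition within-subject resting-state study:
21 subjects, two sessions each (abstinence, then satiety), 150 volumes at
TR = 2 s on a 24 × 28 × 24 grid of 3 mm isotropic voxels centred on the
world origin.  Data follow the linear mixing model that spatial ICA
assumes:

    data(v, t) = Σ_k scale_k · source_k(v) · tc_k(t) + ε(v, t),  ε ~ N(0, σ²)

**Spatial sources.** Four networks (aDMN, pDMN, ECN, SN), each the sum of
two Gaussian blobs at fixed documented centres loosely mimicking the
canonical topographies.  Blob FWHMs are 12–15 mm and peak amplitudes
2.0–3.0 (arbitrary BOLD units); the right-insula blob carries the SN's
largest amplitude (3.0), reflecting the insula's dominance within that
network.  A network's binary template mask is the union of its blobs'
above-half-amplitude regions.

**Temporal sources.** Network time courses are stationary VAR(2) processes
with unit-variance Gaussian innovations, diagonal autoregression
(0.30–0.35 at lag 1, 0.12–0.20 at lag 2) and one condition-specific
cross-coefficient of 0.4 at lag 1: SN→pDMN in abstinence, ECN→SN in
satiety.  Stationarity (companion spectral radius < 1) is asserted at
construction; 100 burn-in samples remove initial-condition transients.

**Condition and subject effects.** The SN's amplitude is scaled ×1.2 in
abstinence.  Each subject carries a multiplicative per-network amplitude
jitter ~ lognormal(0, 0.1), shared across conditions so paired tests see a
pure condition effect, plus independent noise and time-course seeds.
Voxel noise is σ = 1.0, i.e. a peak contrast-to-noise ratio of ~2–3 —
deliberately favourable relative to raw scanner data, appropriate for a
desk-scale validation grid.  Metadata are drawn to match the study
population: FTND ~ U{5..8}, CO_abstinence ~ N(9.6, 3.5²) truncated
positive, CO_satiety = CO_abstinence + a positive increment, so every
subject's exhaled CO rises after smoking.

All cohorts are pure functions of (configuration, seed); per-subject
sub-seeds are spawned deterministically from the master seed.

**What the generator does not emulate:** hemodynamic-response convolution,
physiological (cardiac/respiratory) noise, scanner drift, head motion,
spatial normalisation error, and between-subject anatomical variability.
Passing recovery tests therefore demonstrates the correctness of the
estimation chain under its own generative assumptions, not performance on
scanner data.

## Preprocessing

Canonical order: discard initial volumes → voxelwise linear detrend
(intercept and slope jointly, by OLS) → zero-phase band-pass → Gaussian
spatial smoothing.  The band-pass is a 4th-order Butterworth
(0.01–0.08 Hz) applied forward-backward (`filtfilt`), giving unit passband
gain and no phase shift; smoothing uses σ = FWHM/(2√(2 ln 2)) per axis in
voxel units with reflecting boundaries (mass-preserving on small grids).
Sample standard deviations use the n−1 denominator throughout.

For synthetic runs the pipeline defaults enable only the detrend: the
simulator plants drift-free broadband dynamics, so band-pass and smoothing
(scanner-artefact countermeasures, both fully implemented and tested at
the standard parameter values of 0.01–0.08 Hz and 8 mm) are config-enabled
rather than forced.

## Group ICA

- **Reduction.** Stage 1 PCA reduces each session's time dimension to d1
  (default 40); stage 2 stacks blocks of 7 sessions and reduces to d2
  (default 30); stage 3 stacks everything and reduces to the component
  count.  Projections are orthonormal-row matrices computed from small
  Gram matrices and stored for back-reconstruction.
- **Infomax.** Natural-gradient updates W ← W + η(I + (1−2g(WZ))(WZ)ᵀ/B)W
  with logistic g, block size 256, learning rate 0.01.  The rate anneals
  ×0.9 only when successive weight-update directions turn by more than
  60°, so stochastic sweep-to-sweep jitter does not freeze the
  optimisation; convergence is declared when the Frobenius weight change
  drops below 1e−5 (at most 512 sweeps; non-convergence is flagged, never
  silent).  Components are fixed to unit-variance, non-negative-skew
  spatial maps; a near-zero excess kurtosis on every source flags the
  rotation-unidentifiable (Gaussian) case.
- **ICASSO.** 20 runs seeded seed+run_index; dissimilarity
  1 − |spatial correlation|; average-linkage clustering cut at the
  component count; centrotype = member with the largest summed
  intra-cluster similarity; stability = mean intra-cluster similarity
  minus mean similarity to the nearest other cluster, clipped to [0, 1].
  The selected mixing matrix is re-estimated by least squares of the
  reduced data on the centrotype maps so back-reconstruction stays
  consistent with the selected maps.
- **Back-reconstruction.** Session time courses are the session's
  partition of the group mixing propagated through the stage projections
  (orthonormal rows, so pseudo-inverses are transposes); session maps are
  the regression of the session data on those time courses.  A
  dual-regression estimate of the time courses was evaluated and performs
  identically on the synthetic cohort; the partition form is kept.
- **MDL component count.** Description length
  −N(V−k)·ln(geometric/arithmetic mean of trailing eigenvalues) +
  ½k(2V−k)·ln N, minimised over k.  When estimating from voxel data the
  pipeline subsamples every 3rd voxel to soften the i.i.d.-sample
  assumption violated by spatial correlation.
- **Component count for the synthetic cohort:** 8 (twice the number of
  planted networks) — enough head-room for noise components without
  splitting sources.  The 23-component setting used for full-size cohorts
  remains available in the configuration.
- **Template matching** replaces visual component selection: greedy
  best-first assignment by correlation with the binary template masks,
  threshold 0.3, ties broken toward the lower component index.

## Voxel statistics

One-sample and paired t use df = n−1 with two-sided p from the Student
reference; zero-variance voxels map to ±∞ sentinels (p = 0) with a logged
count rather than NaN propagation.  FDR is Benjamini–Hochberg step-up.
Cluster extraction labels the suprathreshold mask per effect direction
(A>B / B>A separately) with 26-connectivity by default and drops clusters
below 20 voxels — the extent matching the smallest reported cluster, since
no explicit extent threshold is stated; both are config-exposed.  ROIs are
3×3×3 voxel blocks around a peak; a peak too close to the volume boundary
is an error, not a truncated ROI.

## Granger causality

- Per-equation OLS without intercept (inputs are zero-mean per segment; a
  flag re-enables it).  Design rows never span a segment boundary, so
  fitting 21 concatenated subjects equals pooling their normal equations
  (verified against an explicit block-OLS oracle).
- One common order per condition and node set, chosen by BIC
  (n·ln det Σ̂ + p k² ln n) on the full multivariate system, with all
  candidate orders evaluated on the rows available at max_order so
  likelihoods are comparable.
- The default test is pairwise bivariate; a conditional (full-multivariate)
  mode exists but is not default.  Pairwise testing cannot distinguish a
  mediated influence a→b→c from a direct a→c edge — demonstrated in the
  test suite — and this caveat is inherited by any pairwise analysis.
- Edge families (12 network-level or 56 ROI-level ordered pairs, per
  condition) are FDR-thresholded at q = 0.01 (networks) and q = 0.001
  (ROIs) by default.
- **Filtering before causality.** Zero-phase (forward–backward) band-pass
  filtering uses future samples and is therefore non-causal; applied to
  network time courses it corrupts lag-based inference — on the planted
  cohort it drives BIC to the maximum candidate order and destroys exact
  edge-set recovery (0/100 seeds vs 94/100 without filtering).  The
  pipeline therefore z-normalises network time courses per session but
  does not band-pass them before GCA by default;
  `gca_bandpass_network=True` restores the filtered variant for
  comparison.  ROI series are only zero-meaned, as is standard.

## Numerical conventions and degenerate inputs

Voxel indices are 0-based; world coordinates come from the diagonal
voxel-to-world affine and are reported in mm.  Tables are TSV (UTF-8,
'.' decimal), volumes NIfTI-1, graphs and provenance JSON; presentation
rounding is 2 decimals, stored values full precision.  Constant series
cannot be z-scored (error); duplicated nodes raise rank errors naming the
offending lag/node; an exact deterministic dependence makes the Granger F
diverge and is flagged with a warning rather than reported as a finite
score.  Cluster ordering, pairwise-test ordering and ICASSO component
ordering are all deterministic, and the full pipeline is bit-reproducible
for a fixed configuration and seed.

## Validation scale and known limitations

Recovery checks run at the generator's default scale (21 × 2 × 150 on
24 × 28 × 24); Monte-Carlo rates use 100 replicate cohorts for edge-set
recovery and paired-t localization, 1000 replicates for the F-test null
calibration, and 300 for power.  Under the planted subject-amplitude
jitter, individual session time-course correlations with the true
generators occasionally dip to ≈ 0.88 while group means stay ≈ 0.98; the
acceptance checks therefore assert the group-level mean per network.
Desk-scale grids cannot reproduce voxel-level results from the original
scanner cohort (no public accession exists); algorithmic components are
instead held to independent oracles (flood-fill clustering, block OLS,
hand-evaluated FDR step-up, planted-source recovery).
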