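# Methods

## The temporal-variability statistic

Dynamic functional connectivity treats the correlation structure of
BOLD signals as time-varying and estimates it within short windows.
`tvfc` implements the *temporal variability* summary of windowed FC:
for a segmentation of the scan into non-overlapping windows of length
*l* (volumes) starting at volume *s*, each window yields an R × R
Pearson correlation matrix, and a pattern vector per window is formed
at three levels — a ROI's whole-brain FC row (self-correlation
removed), a network's vectorised within-block upper triangle, and a
network pair's full cross-block. The statistic is

    V = 1 − mean_{i<j} corr(F_i, F_j)

with the mean over all unordered window pairs, equally weighted. Since
a Pearson correlation lies in [−1, 1], every defined V lies in [0, 2].

**Exclusion of the diagonal in the regional vector.** Including the
self-correlation (constantly 1) would only shrink the variance of both
vectors in each pair and bias the across-window correlation upward;
the regional pattern vector therefore has length R − 1.

**Raw correlations, not Fisher-z.** The statistic operates on the FC
values themselves. A `fisher_z=True` flag on the extractor applies
arctanh to the FC entries before the across-window comparison as a
sensitivity analysis; it changes values but not the [0, 2] bounds.

**Multi-scale averaging.** V depends on the window grid. To suppress
that dependence the statistic is computed for every length
l = 21…30 volumes (42–60 s at TR = 2 s, a range commonly used for
sliding-window FC) and for every start offset s = 1…l−1 per length,
i.e. up to Σ(l−1) = 245 segmentations for a 240-volume scan, then
averaged with equal weight per (l, s) segmentation regardless of its
window count. Segmentations retaining fewer than `min_windows` = 2
windows are skipped; volumes before s and trailing partial windows are
discarded.

**Undefined values.** A ROI constant within a window has no defined
correlation: its FC row/column is NaN and window pairs involving it
are skipped. A segmentation value with more than 50 % of its window
pairs skipped is dropped from the multi-scale average. A network of
fewer than 3 ROIs has a within-block vector too short for a meaningful
correlation (a 1-entry vector has none; a 2-entry vector only ±1), so
its intra-network value is reported as missing — with the packaged
AAL table this applies to the 2-ROI thalamus network by construction.
Missing values propagate as NaN through every table and are counted in
the run log; they are never imputed as 0 and never silently enter a
group test (per-feature N is reported).

**Numerical notes.** Window correlations and across-window pattern
correlations are computed as cosines of mean-centred vectors and
clipped to [−1, 1]; the clip corrects only floating-point ulp
excursions, so the [0, 2] bounds hold exactly. The vectorised
implementation is verified against a naive double-loop reference to
1e-10 in the test suite.

## Preprocessing chain

The package starts from extracted ROI signals; image-space processing
(slice timing, realignment, normalisation) is out of scope. Per
subject, in order:

1. **Volume discard** — first 10 volumes removed (scanner
   equilibration), configurable.
2. **Nuisance regression** — OLS residualisation of every ROI signal
   on an intercept plus the Friston-24 expansion of the six rigid-body
   motion parameters ([p(t), p(t−1), p(t)², p(t−1)²]; lagged terms
   zero-padded at the first frame). `gsr=True` appends the mean ROI
   signal (global signal regression, off by default). White-matter and
   CSF signals are not part of the post-extraction data model; if
   available they can be supplied as extra regressor columns. The
   motion-derived regressors share the volume discard with the
   signals. Residuals are orthogonal to every regressor and invariant
   to invertible reparameterisations of the regressor set.
3. **Band-pass** — ideal (boxcar) frequency-domain filter keeping
   0.01–0.10 Hz, zeroing the mean. Chosen over IIR designs because it
   is exactly reproducible with no order/ripple choices and idempotent
   up to floating point; a Butterworth could be substituted upstream
   without affecting the statistic's contract.

The fixed order discard → regress → filter avoids reintroducing
filtered-out frequencies through the regression step's projection only
if regressors and signals share the same band; since the Friston-24
regressors are used unfiltered before the band-pass, the default order
regresses first and filters last.

**Motion QC.** Framewise displacement is the sum of absolute backward
differences of the three translations plus 50 mm × the same for the
three rotations (arc length on a 50 mm sphere); FD of the first frame
is 0. A subject is excluded iff mean FD is strictly greater than
0.2 mm.

## Parcellation

The packaged table assigns the 116 AAL ROIs to 11 networks
(sensorimotor, visual, auditory, default_mode, frontoparietal,
cingulo_opercular, salience, attention, subcortical, thalamus,
cerebellum), with thalamus and cerebellum treated as standalone
networks and the cerebellar vermis included in the cerebellum. Network
assignments for AAL parcels vary across the literature; this table is
a reasonable default, shipped as an editable TSV
(`src/tvfc/data/aal116_networks.tsv`) — all computation reads a
`Parcellation` object, nothing hard-codes the map. File row order
defines the canonical column order of every series matrix, and a
checksum over the ordered labels guards against misalignment.

## Group statistics

Per feature: (1) ANCOVA — F-test of the group factor in
`[1 | age, sex, education, mean FD | group dummies]` against the
covariate-only model, df (G−1, N−G−C), listwise deletion of missing
rows; no correction across features at this stage (an optional
Benjamini-Hochberg flag exists, off by default). (2) Where the main
effect passes the gate (p < 0.05), each group pair is tested by the
t-test on the group indicator in the covariate-adjusted two-group
subset model, and Bonferroni correction multiplies raw p by the number
of pairs (3), capped at 1; significance at corrected p < 0.05. The
exact post-hoc statistic is a design choice (covariate-adjusted
two-group contrast) recorded here because estimated-marginal-means
variants differ only in pooling assumptions. (3) Spearman rank
correlations (average-rank ties, two-sided t-approximation) between
significant features and clinical scores, pooled and per group,
uncorrected, requiring ≥ 5 complete pairs.

Calibration of this chain is part of the test suite: type-I error of
the ANCOVA at α = 0.05 over 2,000 null simulations (N = 90, three
groups of 30) must fall in [0.035, 0.065], and the family-wise error
of the Bonferroni post-hoc over 1,000 null simulations must not exceed
0.05 plus a 3·SE simulation margin.

## Synthetic cohorts

The generator emulates the statistical structure the analysis assumes,
so every stage can be exercised with no data download.

**Signal model.** Subject series are zero-mean multivariate Gaussian
draws with time-varying covariance

    Sigma(t) = Q(w(t)·a) · Sigma_A · Q(w(t)·a)^T,   Q(x) = expm(x·S)

* `Sigma_A`: a random correlation matrix — a Wishart-style random
  correlation shrunk toward the constant-correlation matrix to a mean
  off-diagonal of 0.2 (a typical magnitude for band-passed
  resting-state FC).
* `S`: a fixed skew-symmetric generator acting only on the modulated
  ROI coordinates, built from randomly oriented planes that all rotate
  by the same angle π·a at amplitude a (half turn at a = 1). The
  regime-on covariance is therefore a rotation of the base covariance
  inside the modulated subspace: entries among unmodulated ROIs are
  exactly unchanged, positive definiteness holds for every amplitude
  by congruence, and — because the FC pattern moves along a geodesic
  of constant magnitude rather than a chord through the origin — the
  planted pattern dissimilarity is monotone in a. (A linear blend
  toward a reflected or independently drawn second regime fails one or
  both of these requirements: it can leave the PD cone, and its
  pattern magnitude dips at intermediate amplitude, making measured
  variability non-monotone near a ≈ 0.5–0.9.)
* `w(t)`: square wave of period 40 volumes (regimes dwell 20 volumes;
  the period is incommensurate with the 21–30-volume window grid, so
  no segmentation trivially aligns with the regimes). A sinusoidal
  mode is available; for non-binary weights the intermediate
  covariance is the convex blend of the two regime endpoints.
* White measurement noise, sd 0.2 relative to unit signal variance.

Group amplitudes default to (0.0, 0.3, 0.6) for the three groups
(control, intermediate, high), encoding a severity continuum; the
modulated set defaults to the basal ganglia + thalamus indices for
116-ROI cohorts and the first fifth of ROIs otherwise. Defaults mirror
the expected acquisition: R = 116, T = 250 volumes, TR = 2 s, group
sizes (66, 53, 66).

**What the generator does not model:** hemodynamic convolution and
temporal autocorrelation (draws are independent across volumes),
spatial maps, scanner drift/physiological noise, site effects, and
symptom-dimension structure in the clinical scores. Passing tests
therefore demonstrate correctness and sensitivity of the statistic
under its own assumptions (Gaussian signals with controlled
time-varying covariance), not performance on real BOLD with
autocorrelated noise.

**Motion and covariates.** Motion traces are seeded random walks
(rotation steps 50× smaller than translation steps so both contribute
comparably to FD), rescaled exactly to a per-subject target mean FD
drawn from |N(0.08, 0.04²)| mm, clipped to [0.005, 0.6] — typical for
cooperative adults, with occasional subjects above the 0.2 mm
exclusion threshold. Age ~ N(33, 9²) years clipped to [18, 60],
sex balanced, education ~ N(12.5, 3²) years clipped to [6, 20].
Illness-related scores exist only for patient groups; one named score
(default SANS) is tied to the subject's true modulation amplitude
through a latent Gaussian with Pearson loading r = 2·sin(π·ρ/6), the
bivariate-normal relation that targets a Spearman correlation of ρ
(default 0.3). Everything is a pure function of the simulation spec,
including its seed.

## Problem sizes used in validation

The test suite and acceptance script run at desk scale, chosen as the
smallest sizes at which each property is identifiable: bounds stress
suite at R ≤ 20, T ≤ 300 (50 inputs); oracle equivalence at R ≤ 8,
T ≤ 60 (100 instances); planted-effect recovery at R = 30 with 7
modulated ROIs, T = 250, 50 replicates per amplitude (R = 30 because
the baseline per-ROI variability heterogeneity of a random correlation
draw scales roughly as 1/√R and must sit well below the planted
effect); statistical calibration at N = 90. Full-size cohorts
(R = 116, T = 250) run through the same code paths via the pipeline
tests and CLI.

## Known limitations

* The AAL → network table is one defensible assignment among several;
  results at the network level depend on it. Replace the TSV to match
  a local convention.
* Intra-network variability is undefined for networks of < 3 ROIs
  (reported as missing), so the thalamus "network" has regional and
  inter-network values only.
* The band-pass ideal filter assumes the series is long enough that
  spectral leakage at the band edges is negligible; very short scans
  (T < ~100) deserve a tapered design instead.
* ANCOVA assumes homogeneous covariate slopes across groups; no
  group × covariate interactions are modelled.
* The generator's independence across volumes means absolute
  variability levels in synthetic data are higher than in real BOLD
  (which is temporally smooth); comparisons between conditions within
  synthetic cohorts remain meaningful.
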