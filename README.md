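# tvfc — temporal variability of dynamic functional connectivity

`tvfc` quantifies how much a brain region's or network's functional
connectivity (FC) pattern reconfigures over the course of a
resting-state fMRI scan, and tests whether that reconfiguration rate
differs between clinical groups. It is aimed at researchers analysing
parcellated BOLD time series (e.g. 116-ROI AAL extractions) who want a
tested, reproducible implementation of the sliding-window
temporal-variability statistic together with motion QC,
nuisance-regression preprocessing, covariate-adjusted group statistics,
and a fully synthetic cohort generator for validation — no imaging data
required to exercise any stage.

## The statistic

Given a T × R matrix of ROI signals, the scan is segmented into
non-overlapping windows of length *l* starting at volume *s*, and a
Pearson correlation matrix is computed per window. For each window *i*
a pattern vector *F<sub>i</sub>* is formed at three levels:

* **regional** (per ROI *k*): row *k* of the window FC matrix with the
  self-correlation removed;
* **intra-network** (per network *m*): the strict upper triangle of
  the network's FC sub-block (undefined for networks of < 3 ROIs);
* **inter-network** (per network pair *m, n*): the full |m| × |n|
  cross-block.

Temporal variability is then

> V = 1 − mean over window pairs i < j of corr(F<sub>i</sub>, F<sub>j</sub>)

so V ∈ [0, 2]: 0 when the pattern is perfectly stable across windows,
2 when patterns in different windows are perfectly anticorrelated.
To remove dependence on the window grid, V is averaged over lengths
l = 21…30 volumes (42–60 s at TR = 2 s) and, for each l, over all
l − 1 start offsets — 245 segmentations for a 240-volume scan.

Around the statistic the package provides the standard resting-state
chain: discarding initial volumes (default 10), Friston-24 motion
nuisance regression (optionally with global signal regression),
ideal-filter band-pass to 0.01–0.10 Hz, exclusion of subjects with
mean framewise displacement > 0.2 mm (strict), per-feature ANCOVA
(covarying age, sex, education, mean FD) gated post-hoc pairwise
contrasts with Bonferroni correction across the three group pairs, and
Spearman correlations with clinical scores.

## Worked example

Simulate a three-group cohort (12 subjects per group, 20 ROIs, 250
volumes at TR = 2 s) in which ROIs 1–5 carry planted time-varying
covariance whose amplitude increases across groups (HC 0.0, BD 0.3,
SZ 0.6), then run the full pipeline:

```python
from tvfc import SimulationSpec, RunConfig, run_pipeline

spec = SimulationSpec(n_rois=20, n_volumes=250, n_per_group=(12, 12, 12),
                      modulated_rois=tuple(range(5)), seed=7)
run_pipeline(RunConfig(simulate=spec, seed=7), "example_out")
```

`example_out/` then contains `qc_report.tsv`, `features.tsv`,
`group_stats.tsv`, `correlations.tsv` and `run_log.json`. With this
seed all 36 subjects pass motion QC, each feature averages 245 window
segmentations, and the mean regional variability is 0.864 for the
modulated ROIs versus 0.826 for the unmodulated ones. The strongest
group effect lands on a modulated ROI, with the largest pairwise
difference between the zero-amplitude and high-amplitude groups:

```
         feature  ancova_f     ancova_p group_a group_b  p_bonferroni
regional_roi_005 25.722834 3.758222e-07      HC      SZ      0.000007
regional_roi_005 25.722834 3.758222e-07      BD      HC      0.004775
regional_roi_005 25.722834 3.758222e-07      BD      SZ      0.006828
```

i.e. the pipeline recovers exactly the structure that was planted:
variability rises with the modulation amplitude, and group contrasts
flag the modulated regions.

The same run is available from the shell:

```bash
tvfc run --out example_out --seed 7          # end-to-end with defaults
tvfc simulate --out cohort/ --n-rois 20 --n-per-group 12,12,12 --seed 7
tvfc qc cohort/
tvfc compute cohort/ --out results/ --lengths 21:30 --no-gsr
```

## Layout

| Module | Contents |
| --- | --- |
| `tvfc.parcellation` | ROI → network tables; packaged 116-ROI AAL / 11-network default |
| `tvfc.preprocess` | volume discard, Friston-24, FD, motion QC, nuisance regression, band-pass |
| `tvfc.dynvar` | windowed FC, the three variability statistics, `TemporalVariabilityExtractor` |
| `tvfc.stats` | ANCOVA, Bonferroni post-hoc contrasts, Spearman clinical correlations |
| `tvfc.synthetic` | seeded cohorts with rotation-regime planted dynamics, motion, covariates |
| `tvfc.pipeline` / `tvfc.cli` | `RunConfig`, end-to-end orchestration, `tvfc` console command |

The scientific background, modelling assumptions and numerical choices
are documented in `docs/methods.md`.
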