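# lfmkit

Analysis toolkit for **longitudinal fluorescence microscopy (LFM)** survival
experiments on primary neurons, of the kind used to dissect dose-dependent
protein toxicity: thousands of transfected cells are imaged every 24 h for
10 days, each cell's death is observed directly, and single-cell statistics
relate expression, aggregation state and protein kinetics to the risk of
death. The package covers the full computational chain —

- **imaging**: segmentation of somata from time-lapse stacks, greedy
  nearest-centroid tracking, rule-based death calling (fluorescence
  collapse, ROI disappearance, soma rounding), rigid stack registration;
- **survival**: Cox proportional hazards with Efron tie handling
  (deaths observed on a daily frame grid are heavily tied), reported as
  hazard ratios `HR = exp(beta)`; penalized cubic-spline models of the log
  relative hazard as a smooth function of a covariate
  (expression–risk curves), with AIC smoothing selection and a calibrated
  penalized likelihood-ratio test; Kaplan–Meier cumulative risk;
- **granules**: nuclear coefficient of variation (CV = sd/mean over the
  nuclear ROI) as a punctateness statistic, ROC threshold selection
  (Youden J; the conventional operating threshold 0.92 is the default),
  Fisher's exact comparisons, penalized-spline binomial models of
  granule-onset risk, granule-stratified survival;
- **kinetics**: FRAP recovery fits `y(t) = A(1 - e^{-tau t})`,
  `t_1/2 = ln2/tau`, effective diffusion `D = 0.88 w^2 / (4 t_1/2)` with
  `w^2 = area/pi`, Stokes radius `r = 0.66 M^{1/3}` nm and Einstein–Stokes
  viscosity `eta = k_B T / (6 pi D r)`; optical-pulse-labeling half-lives
  from log-linear decay fits;
- **localization**: nuclear masks, nucleocytoplasmic ratios,
  quantitative immunofluorescence with fold-changes, t-test / ANOVA+Tukey
  group comparisons;
- **simulate**: a ground-truthed generator for every input type (rendered
  two-channel fields with programmed deaths, interval-censored survival
  cohorts, labelled nuclei, FRAP/OPL traces), so the whole pipeline is
  testable without microscope data.

Statistical models follow a statsmodels-like convention: construct a model
object from data, call `.fit()`, get a results object with estimates,
uncertainties and `summary()`.

## Worked example

```python
import math
from lfmkit.simulate import simulate_survival_cohort
from lfmkit.survival import GroupedCoxModel

records, truth = simulate_survival_cohort(
    1000, {"EGFP": 0.0, "toxic": math.log(1.5)},
    baseline_hazard=0.08, follow_up=10.0, seed=1,
)
print(GroupedCoxModel(records, reference="EGFP").fit().summary())
```

```
Cox proportional hazards (Efron ties)
reference group: EGFP (n=1000)
events: 1238, log partial likelihood: -8883.289
group     coef       HR  se(coef)            p    n
toxic 0.398772 1.489993  0.057336 3.524797e-12 1000
```

A cohort simulated with a true hazard ratio of 1.5 (baseline death hazard
0.08/day, deaths observed on the daily imaging grid, censoring at day 10)
is recovered as HR = 1.49 with a Wald p of 3e-12: the toxic construct
raises the instantaneous risk of death ~1.5-fold over the reference.

The imaging path runs the same analysis starting from rendered stacks:

```python
from lfmkit import imaging
from lfmkit.simulate import SimConfig, simulate_timelapse
from lfmkit.survival import build_survival_table

stack, truth = simulate_timelapse(SimConfig(n_cells=30, seed=1))
rois = imaging.segment_stack(stack)
tracks = imaging.track_cells(stack, rois, group="demo")
for track in tracks:
    imaging.call_death(track, stack)
records = build_survival_table(tracks, covariate_at_24h_channel="reporter")
```

A command-line entry point `lfm` exposes the stages
(`simulate`, `segment`, `track`, `deathcall`, `survival fit-cox`,
`survival fit-spline`, `granules cv|roc|classify|onset-model`, `frap fit`,
`opl fit`, `nucfrac`, `run`); `lfm run --config cfg.yaml --outdir out`
executes the whole pipeline from a YAML config with an explicit seed and
writes CSV tables, JSON reports and a hash-stamped manifest.

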