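# mvews

Multivariate early-warning-signal (EWS) indices for sparse clinical
biomarker time series, with a full evaluation pipeline: synthetic cohort
simulation, windowing, 15 index computations, normalization / n-bias
correction, descriptive comparison (correlations, pre-death trends,
change points) and mortality-prediction models (Cox HR95, ROC/AUC,
sequential index addition).

## What it computes

Indices are calculated on backward-anchored windows (default 6 months,
counted back from death or from the last observation for censored
patients) over an 11-biomarker panel:

| category            | indices                                        |
|---------------------|------------------------------------------------|
| variance            | `Av_Var`, `NMV`, `Max_cov`, `PC_var`, `Ex_var`, `CVPC1` |
| autocorrelation     | `Av_Ac`, `Max_ac`, `MAF_ac`, `MAF_ev`, `MI`    |
| cross-correlation   | `Av_ab_cc`                                     |
| variance + AC       | `Df`, `MAF_var`, `MMD` (and per-visit `MMD_all`) |

`MAF_*` indices come from the generalized eigenproblem of the one-step
difference covariance against the window covariance and require at least
13 complete observation rows.  `CVPC1` is the first-PC score of the
per-window, per-marker coefficient-of-variation matrix (computed on the
transformed but not z-scored scale, bias-corrected for the number of
observations).  `MMD` is the statistical distance between consecutive
visits under the cohort-wide covariance metric.

Since the clinical dataset behind the reference analysis is confidential,
the package ships a first-class synthetic cohort generator: a latent daily
VAR(1) process per patient whose recovery parameter ramps toward 1 over
the final months before death (rising variance / autocorrelation /
cross-correlation), observed at irregular ~biweekly visits with gaps, and
mapped to native biomarker scales.  Closed-form discrete-Lyapunov oracles
for the stationary regime back the tests.

## CLI

```sh
# simulate a cohort
mvews simulate --seed 1 --n-patients 200 --out-dir out/

# cut windows only
mvews windows --observations out/observations.csv --patients out/patients.csv \
      --window-months 6 --out out/windows.csv

# full pipeline (simulating unless --observations/--patients are given)
mvews run-all --seed 1 --n-patients 200 --window-months 6 --out-dir out/
```

`run-all` writes headered CSVs per stage (`indices_raw.csv`,
`indices_corrected.csv`, `correlations.csv`, `trends.csv`,
`changepoints.csv`, `hr95_single.csv`, `hr95_full.csv`,
`auc_sequential.csv`, ...) plus `manifest.json` recording the seed and a
SHA-256 per stage output, so a rerun with the same seed is bit-identical.
The stage subcommands (`indices`, `correct`, `compare`, `survival`) run
the pipeline on ingested CSVs and leave the cumulative stage outputs in
`--out-dir`.

## Acceptance

The acceptance properties (oracle equivalence of every index against a
loop-based reimplementation, Lyapunov closed-form recovery, MAF/PC limit
equivalences, index ordering chains, bias-correction decorrelation,
change-point recovery at a 3-month pre-death ramp, HR95 calibration, ROC
properties, and qualitative reproduction of the variance-over-AC pattern)
live in `tests/test_acceptance.py`.

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

runs the pipeline end to end on a seeded synthetic cohort as an
executability check; there are no numeric paper-level targets (the
reference numbers come from a confidential cohort), so the emitted JSON
object is empty.

## Package layout

```
src/mvews/
  cohort.py       synthetic cohort generator + stationary VAR(1) oracles
  preprocess.py   ingest, marker transforms, z-scoring, windowing
  indices.py      the 15 indices (+ MMD_all), MAF decomposition, CVPC1
  correction.py   index transforms and n-of-observations bias correction
  comparison.py   pairwise correlations, pre-death trends, change points
  survival.py     counting-process Cox models, HR95, ROC/AUC, sequential AUC
  pipeline.py     stage orchestration, manifest, toy fixtures
  cli.py          click-based CLI
```
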