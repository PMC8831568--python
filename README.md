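# mearaster

Raster-plot machine learning for multiwell MEA seizure-liability
screening.

In vitro microelectrode-array (MEA) recordings of cultured neuronal
networks are a standard assay for drug-induced seizure liability, but
conventional endpoints (spike counts, burst statistics) change in
drug- and lab-specific ways, making a single readout unreliable.
`mearaster` implements an image-based alternative: each well's spike
raster is cut into windows four times the well's own network-burst
period (the IMFI — the spacing of successive bursts' peak-firing-rate
times in the vehicle epoch), each window is rendered as a raster-plot
image and summarized by a 4096-dimensional deep-style feature vector
normalized against that well's vehicle response, and shallow
pattern-recognition networks on those features predict (a) the
probability that a compound's response is seizure-like, per
concentration, and (b) which compound it is. Evaluation is strictly
grouped by well (holdout and leave-one-well-out), with ROC analysis
and a misclassification-cost operating point

S = [Cost(P|N) − Cost(N|N)] / [Cost(N|P) − Cost(P|P)] · N/P,

the threshold found where a line of slope S slid from (FPR 0, TPR 1)
first touches the ROC curve.

The package is aimed at in vitro electrophysiologists and safety
pharmacologists who want a reproducible, end-to-end reference
implementation of this workflow, including classical burst analytics
(TS/NoB/IBI/DoB/SiB, %-of-control dose–response tables, ANOVA +
Dunnett) and a fully seeded synthetic-plate generator, so every stage
is testable without proprietary recordings.

## Worked example

Run the full pipeline on its built-in synthetic quick-start panel
(four positive mechanisms and a seizure-free compound, three wells
each, vehicle plus five concentrations per well):

```bash
mearaster run --seed 5 --out demo
```

which simulates the plate, detects bursts, windows and renders the
rasters, extracts and vehicle-normalizes features, trains the risk net
on two wells per compound, and evaluates the third, fully held-out
well of each. It prints (numbers from this exact invocation):

```json
{
  "config_hash": "154aacabf66b",
  "risk": {
    "test_wells": ["dob_down_w2", "negative_w2", "nob_down_sib_up_w0",
                   "nob_up_w2", "ts_down_w1"],
    "auc": 0.9870623834818208,
    "operating_point": {"threshold": 0.2806841516698644,
                        "slope": 0.8375350140056023,
                        "fpr": 0.033444816053511704,
                        "tpr": 0.957983193277311},
    "accuracy": 0.961890243902439,
    "ppv": 0.9715909090909091,
    "sensitivity": 0.957983193277311,
    "specificity": 0.9665551839464883,
    "f_measure": 0.9647390691114245
  }
}
```

Reading: on windows of the five unlearned wells the risk net separates
seizure-like from vehicle-like activity with AUC 0.987; the operating
point found by the cost-slope sweep (S = N/P = 0.84 on this test set)
classifies 96% of windows correctly. `demo/risk_by_concentration.csv`
aggregates windows to the per-concentration risk — the fraction of a
well's windows called seizure-like, averaged over the held-out wells:

```
concentration,risk,call
0.1,0.043448275862068966,False
0.3,0.10045977011494252,False
1.0,0.7262068965517241,True
3.0,0.7933333333333333,True
10.0,0.74,True
```

so the panel's risk crosses the 50% call line between 0.3 and 1 µM,
matching the generator's half-max concentration of 1 µM.
`demo/dose_response.csv` and `demo/significance.csv` hold the classical
%-of-control table (vehicle = 100%) with SEM and the Dunnett-adjusted
p-values; `demo/figures/` and `demo/roc.png` contain the dose-response
curves with significance stars and the ROC curve with its operating
point.

The same objects are available as a library:

```python
from mearaster import (detect_network_bursts, compute_burst_parameters,
                       estimate_imfi, segment_windows, render_raster,
                       extract_features, vehicle_normalize)
```

## Layout

- `mearaster.mea_io` — data model, spike-table I/O, filtering, spike
  detection
- `mearaster.burst_analysis` — network bursts, TS/NoB/IBI/DoB/SiB,
  dose–response, ANOVA + Dunnett
- `mearaster.rasterization` — IMFI, 4×IMFI windows, raster images
- `mearaster.features` — 4096-d extraction (fixture / AlexNet fc7),
  vehicle normalization
- `mearaster.classifiers` — pattern nets, holdout and
  leave-one-well-out, risk aggregation, SVM baselines
- `mearaster.evaluation` — ROC, operating point, confusion matrices,
  metrics
- `mearaster.synthetic_data` — seeded plate generator with a
  13-mechanism + negative drug-effect library
- `mearaster.pipeline_cli` — YAML-configured orchestration and the
  `mearaster` CLI (simulate, detect-bursts, rasterize, extract,
  train-risk, train-drugid, predict, loo, evaluate, report, run)

See `docs/methods.md` for model assumptions, parameter defaults and
limitations.
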