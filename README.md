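# pace-ntcp

A voxel-based Normal Tissue Complication Probability (NTCP) toolkit for
radiation oncology research. It implements **PACE** (Probabilistic Atlas for
Complication Estimation): an NTCP model that keeps the classical
Lyman–Kutcher–Burman (LKB) structure but replaces the dose distribution with
a spatial collection of per-voxel outcome odds, so that inhomogeneous organ
radio-sensitivity can be learned from data instead of being averaged away by
a dose-volume histogram (DVH).

## Who this is for

Researchers modelling radiation-induced morbidity (RIM) from cohorts of
spatially co-registered dose maps with a binary toxicity outcome per patient
(plus optional scalar covariates such as age). Everything can also be run on
fully synthetic cohorts from the built-in simulator — no clinical data are
required for any test or result in this repository.

## The model

**Backbone.** For each ROI voxel $x_j$ a logistic regression ties the $N$
patient outcomes to the $N$ local doses $D_i(x_j)$ (plus covariates). On a
test dose map it yields per voxel a predicted probability $P(x_j)$, the width
$\mathrm{CI}(x_j)$ of its 95% confidence interval, and a reliability
$W(x_j) = 1/\mathrm{CI}(x_j)$, with $W(x_j) = 0$ where the fitted dose odds
ratio is below 1 (dose locally "protective").

**Aggregation.** The maps are condensed into the generalized equivalent
uniform probability

$$\mathrm{gEUp} = \Big[\textstyle\sum_j P(x_j)^{1/\nu} W(x_j) \big/ \sum_j W(x_j)\Big]^{\nu}$$

and mapped through the LKB probit sigmoid

$$\mathrm{PACE} = \Phi(t), \qquad t = \frac{\mathrm{gEUp} - Tp_{50}}{\mu \, Tp_{50}},$$

with volume-effect exponent $\nu$, slope $\mu$ and tolerance probability
$Tp_{50}$ estimated by maximum likelihood; 95% intervals come from Wilks
profile likelihood.

**Benchmark.** The classical LKB model
$\mathrm{NTCP} = \Phi\big((\mathrm{gEUD} - TD_{50})/(m\,TD_{50})\big)$ with
$\mathrm{gEUD} = [\frac1M \sum_j D(x_j)^{1/n}]^n$ is fitted with the same
machinery for like-for-like comparison.

**Simulator.** Synthetic dose maps are sums of 1–4 Gaussian peaks (widths
10–30% of the ROI, heights 0.5–1.5 AU); outcomes are produced by thresholding
the radio-sensitivity-weighted dose summary
$\mathrm{g^2EUD} = [\sum_j D^{1/n} RS / \sum_j RS]^n$ under a homogeneous or
sum-of-two-Gaussians (S2G) RS ground truth. A rank transform can force all
maps to share one DVH, producing a family on which any DVH-based model is
blind by construction.

**Radio-sensitivity inference.** A trained PACE model probed with single-
hot-spot dose maps sweeping the ROI reads out the level sets of the
underlying RS map; agreement with ground truth is scored by the Dice index
between equal-size superlevel sets (DI$_V$) and its normalized AUC.

## Worked example

```python
import numpy as np
from pace import SimulationConfig, simulate_cohort, PaceModel, LKBModel
from pace.evaluation import evaluate_predictions
from pace.rs_inference import make_probe_set, infer_rs_map, di_v_curve

# a synthetic cohort: 300 dose maps, S2G radio-sensitivity, n = 0.1
cfg = SimulationConfig(grid_shape=(32, 32), n_maps=300, rs_kind="s2g",
                       volume_exponent=0.1, event_rate=0.25)
train = simulate_cohort(cfg, seed=1)
val = simulate_cohort(cfg, seed=2, threshold=train.threshold)

pace = PaceModel.fit(train.dose_matrix(), train.outcomes, grid=train.grid)
lkb = LKBModel.fit(train.dose_matrix(), train.outcomes)

for name, model in (("PACE", pace), ("LKB", lkb)):
    probs = model.predict_batch(val.dose_matrix())
    rep = evaluate_predictions(probs, val.outcomes)
    print(f"{name}: validation AUC {rep.auc.auc:.3f} +- {rep.auc.se:.3f}, "
          f"accuracy {rep.accuracy:.3f}")

probes = make_probe_set(train.grid, sigma_probe=1.5,
                        amplitude=float(train.dose_matrix().max()), stride=1)
est = infer_rs_map(pace, probes)
_, _, auc = di_v_curve(train.rs_map, est)
print(f"RS-map recovery: DI_V AUC {auc:.3f} over {probes.n_probes} probes")
```

prints

```
PACE: validation AUC 0.979 +- 0.011, accuracy 0.920
LKB: validation AUC 0.886 +- 0.024, accuracy 0.807
RS-map recovery: DI_V AUC 0.814 over 1024 probes
```

The voxel-based model discriminates better than the DVH-based benchmark on a
cohort whose outcomes were generated under spatially inhomogeneous
radio-sensitivity, and probing it recovers the RS map's level sets (DI$_V$
AUC of 1.0 would be a perfect match at every volume fraction).

## Command line

```
pace simulate|fit|predict|evaluate|learning-curve|rs-map --config cfg.yaml --seed 1 --out out/
```

`simulate` writes a cohort (NIfTI dose maps + `manifest.csv`), `fit` trains
PACE or LKB and writes parameter estimates with profile CIs, `evaluate` adds
training metrics and leave-one-out cross-validation, `learning-curve`
compares the two models across training sizes, and `rs-map` performs the
probe-based radio-sensitivity readout. Every run writes a `provenance.json`
with its config and seed.

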