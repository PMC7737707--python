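# phenoscreen

Multi-parametric characterization of drug effects on cells from
high-content fluorescence screens.

Single-attribute readouts of a drug screen (total tubulin intensity,
cell area, ...) tell different — sometimes contradictory — stories about
the same treatment. `phenoscreen` implements an unbiased alternative for
384-well imaging screens: segment every cell in three-channel
(nucleus / actin / tubulin) fields, quantify a named vector of per-cell
attributes, and score each treated cell by its **Mahalanobis distance**
to the plate's own control cells,

```
D(x) = sqrt( (x − μ)ᵀ Σ⁺ (x − μ) )
```

where μ and Σ are the center and covariance of the control population,
estimated robustly: PCA fits a control hyper-ellipsoid, cells beyond a
chi-square distance quantile are iteratively trimmed (with the standard
trimming consistency correction), and near-zero-variance axes are
dropped. The score balances attribute scales and correlations in one
number; its additive decomposition ranks which attributes a drug changed
most. Well scores (robust medians) feed the downstream pharmacology:

* **Median-effect (Chou) dose-response** — `score(D) = A/[1+(Dm/D)^s] + B`,
  fitted by the classical linearization `log(1/f−1) = s·log(Dm/D)`
  followed by damped nonlinear least squares; `Dm` is the AC50 on the
  multi-parametric scale.
* **Binary combinations** — dose-pair matrices are tested against Loewe
  additivity (`D1/Dx1 + D2/Dx2 = 1` at equal effect) and Bliss
  independence (product of effect fractions), with joint 4-parameter
  fits, combination-index maps and a seeded randomization test for
  synergy.

A first-class synthetic-data module generates ground-truthed inputs at
both levels — rendered cell fields for the segmentation stage and
correlated multivariate attribute populations with Hill-type
dose-dependent shifts for the scoring and fitting stages — so the whole
pipeline is testable without the original terabyte-scale image data.

## Worked example

Simulate a plate with one drug row (ten 3-fold dilutions in duplicate,
a nocodazole-like tubulin-depolymerizing phenotype), score it against
its own controls, and fit the dose-response:

```python
from phenoscreen import (
    FeatureSimSpec, ScreenAnnotation, WellAddress,
    build_screen_layout, simulate_dose_response_plate,
)
from phenoscreen.scoring import score_plate
from phenoscreen.dose_response import fit_median_effect

spec = FeatureSimSpec.default()          # 16 attributes, true Dm = 1e-6 M
layout = build_screen_layout(
    [ScreenAnnotation("nocodazole-like", gi50=spec.dm_true / 3)],
    fold=3.0, n_levels=10, duplicates=2,
    control_wells=[WellAddress("P", c) for c in range(1, 9)],
)
records, truth = simulate_dose_response_plate(spec, layout, cells_per_well=300, seed=1)
well_scores, model = score_plate(records, layout)
print(model.summary())

treated = well_scores[well_scores["role"] == "treated"]
fit = fit_median_effect(treated["conc_1"], treated["score"])
print(fit.summary())
```

prints

```
Control hyper-ellipsoid (robust PCA)
========================================
attributes:      16
retained axes:   9
cells used:      2343  (trimmed 57)
trim quantile:   0.975
trim iterations: 4  history [57, 57, 57, 57]
...

Median-effect fit: score = A/[1+(Dm/D)^s] + B
==============================================
A  (amplitude):   4.39501
B  (baseline):    2.87132
Dm (median dose): 1.20638e-06
s  (Hill):        2.16237
rss:              0.00404922   n = 10
converged:        True
```

The control model trimmed 57 artifact-like cells (2.4%, matching the
0.975 trim quantile) and kept 9 informative principal axes; the fitted
median-effect dose `Dm = 1.21 µM` recovers the generator's true 1 µM
within the well-to-well sampling noise, and `s ≈ 2.2` its sigmoidicity.
Baseline `B ≈ 2.9` is the typical distance of an untreated cell from
the control center (≈ sqrt of the chi-square median at 9 degrees of
freedom), and `A ≈ 4.4` the score amplitude at saturating dose.

The same workflow is scriptable from the shell:

```bash
phenoscreen simulate --kind features --n-wells 24 --seed 7 --out fixture/
phenoscreen score --features fixture/cells.csv --layout fixture/layout.csv --out scores/
phenoscreen report --scores scores/well_scores.csv --layout fixture/layout.csv --out virtual.csv
phenoscreen fit-dose --input curve.csv --out fit.json
phenoscreen fit-combo --input virtual.csv --drug1 A --drug2 B --model loewe --out combo/
```

plus `segment` for TIFF fields and `run` for a YAML-configured
end-to-end pipeline that writes a reproducibility manifest.

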