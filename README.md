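# thermocal

Radiometric calibration and photogrammetric pre-processing for uncooled
(TEC-less) thermal cameras on UAVs.

## The problem

Lightweight thermal cameras flown on drones use microbolometer arrays
without thermo-electric stabilization. The detector's own temperature
drifts with ambient conditions, and the raw digital level (DL, counts)
reported for a target therefore depends not only on the target's
temperature but also — nonlinearly — on the sensor temperature TC.
Uncorrected, this drift produces errors of several degrees, too large for
agronomic uses such as canopy-temperature stress mapping. A second,
independent problem is that near-isothermal scenes produce images with
very low local contrast, which starves feature detectors of gradients:
structure-from-motion software finds too few tie-points, orients images
poorly, and delivers orthomosaics with meter-level positioning errors.

`thermocal` addresses the desk-side half of this workflow for researchers
and practitioners processing UAV thermal surveys:

* **Calibration models** mapping (DL, TC) → object temperature, fitted to
  blackbody reference observations: the nested polynomial family

  TBB = p00 + p10·DL + p01·TC (+ p20·DL² + p11·DL·TC + p02·TC² + …)

  up to cubic terms, a DL-only baseline, and a single-hidden-layer tanh
  network trained by full-batch backpropagation. Datasets are split 65/35
  into calibration/validation subsets, stratified by blackbody setpoint so
  both subsets span the full temperature range.
* **Diagnostics**: R², RMSE, relative error RE = 100·RMSE/mean(O),
  Willmott's similarity index, plus the four-part residual screen
  (observed~simulated regression, Shapiro–Wilk normality, Breusch–Pagan
  homoscedasticity, Cook's distance with a 4/n threshold).
* **Wallis filtering**: the adaptive local-contrast operator
  G′ = (G−m)·c·s_t / (c·s + (1−c)·s_t + ε) + b·m_t + (1−b)·m that forces
  each neighborhood's mean m and SD s toward targets m_t, s_t.
* **Tie-point evaluation**: a transparent Harris-corner + normalized
  cross-correlation surrogate to quantify the match-count gain from
  filtering on overlapping image pairs.
* **Geo-accuracy**: per-GCP and block-level RMS positioning errors
  (total = √(mean per-GCP (ΔX²+ΔY²+ΔZ²))) and paired field-vs-product
  temperature validation.
* **Synthetic generators** for every input — blackbody campaigns from a
  physical forward model, low-contrast overlapping scene pairs, GCP error
  tables — so the whole pipeline runs and is tested without external data.

Small example tables from a real vineyard UAV thermal survey (per-GCP
errors, field validation points, block-level SfM statistics) ship in
`thermocal.datasets`.

## Worked example

```python
from thermocal import (SensorSimConfig, SplitSpec, ModelForm, AnnTrainConfig,
                       simulate_blackbody_campaign, split_dataset,
                       fit_polynomial, train_ann, validation_rmse)

dataset = simulate_blackbody_campaign(SensorSimConfig(seed=42))
split = split_dataset(dataset, SplitSpec(seed=42))
for form in (ModelForm.LINEAR_DL, ModelForm.P2):
    print(form.value, validation_rmse(split, fit_polynomial(split, form)))
print("ANN", validation_rmse(split, train_ann(split, AnnTrainConfig(seed=42))))
```

prints (seed 42):

```
LINEAR_DL 2.064368948818211
P2 0.5370948529269717
ANN 0.502960417295616
```

The campaign's count noise corresponds to ≈0.5 °C, so the quadratic
surface and the network sit at the noise floor while the DL-only baseline
(no sensor-temperature input) is ~4× worse — the drift it cannot correct.
More narrative walkthroughs live in `examples/` (one script per
capability: `calibrate_sensor.py`, `wallis_demo.py`, `tiepoint_gain.py`,
`survey_accuracy.py`), and the same operations are available from the
shell via the `thermocal` CLI (`simulate`, `fit`, `diagnose`, `apply`,
`wallis`, `tiepoints`, `gcp-eval`, `validate`).

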