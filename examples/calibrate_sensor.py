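"""Fit calibration models to a synthetic blackbody campaign.

Generates a laboratory campaign (13 blackbody setpoints from 5 to 65 degC,
20 sensor temperatures between 5 and 31 degC, noise ~0.5 degC), splits it
65/35 with setpoint stratification, and fits the DL-only baseline, the
quadratic surface P2, and the backpropagation network.  The printed
validation RMSEs show why sensor temperature must enter the model: the
DL-only baseline is several times worse than either (DL, TC) model.
"""

from thermocal import (
    AnnTrainConfig,
    ModelForm,
    SensorSimConfig,
    SplitSpec,
    fit_polynomial,
    simulate_blackbody_campaign,
    split_dataset,
    train_ann,
    validation_rmse,
)

dataset = simulate_blackbody_campaign(SensorSimConfig(seed=42))
split = split_dataset(dataset, SplitSpec(seed=42))
print(f"campaign: {len(dataset)} blackbody observations, 65/35 split")

for form in (ModelForm.LINEAR_DL, ModelForm.P1, ModelForm.P2):
    model = fit_polynomial(split, form)
    print(f"{form.value:>10}: validation RMSE {validation_rmse(split, model):.2f} degC")

ann = train_ann(split, AnnTrainConfig(seed=42))
print(f"{'ANN':>10}: validation RMSE {validation_rmse(split, ann):.2f} degC")
print("(models using sensor temperature approach the 0.5 degC noise floor;")
print(" the DL-only baseline is stuck with the uncorrected thermal drift)")
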