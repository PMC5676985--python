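"""Radiometric calibration models for TEC-less thermal cameras.

The calibration problem is a regression from the pair (DL, TC) — digital
level in counts and sensor temperature in degrees C — to the object
temperature TBB observed on a blackbody reference.  Two model families are
provided:

* a nested polynomial family::

      LINEAR_DL : TBB = p00 + p10*DL
      P1        : TBB = p00 + p10*DL + p01*TC
      P2        : P1  + p20*DL^2 + p11*DL*TC + p02*TC^2
      P3        : P2  + p30*DL^3 + p21*DL^2*TC + p12*DL*TC^2
      P4        : P3  + p03*TC^3

  fitted by ordinary least squares, and

* a single-hidden-layer neural network with tanh activations and a linear
  output unit, trained by full-batch backpropagation (gradient descent with
  momentum and an adaptive "bold driver" step size), with inputs and target
  standardized by the calibration subset's mean and standard deviation.

Datasets are split 65/35 into calibration and validation subsets by
stratified sampling over blackbody setpoints, so that both subsets cover
the whole temperature range.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Union

import numpy as np

from .errors import FormatError, SingularFitError, TrainingDivergenceError
from .io import CAL_LABEL, VAL_LABEL, CalibrationDataset, TemperatureMap, ThermalFrame


class ModelForm(str, Enum):
    """Calibration model families."""

    LINEAR_DL = "LINEAR_DL"
    P1 = "P1"
    P2 = "P2"
    P3 = "P3"
    P4 = "P4"
    ANN = "ANN"


# Polynomial terms as (i, j) exponent pairs for DL^i * TC^j, in coefficient
# order p00, p10, p01, p20, p11, p02, p30, p21, p12, p03.
_TERMS: dict[ModelForm, tuple[tuple[int, int], ...]] = {
    ModelForm.LINEAR_DL: ((0, 0), (1, 0)),
    ModelForm.P1: ((0, 0), (1, 0), (0, 1)),
    ModelForm.P2: ((0, 0), (1, 0), (0, 1), (2, 0), (1, 1), (0, 2)),
    ModelForm.P3: ((0, 0), (1, 0), (0, 1), (2, 0), (1, 1), (0, 2), (3, 0), (2, 1), (1, 2)),
    ModelForm.P4: (
        (0, 0), (1, 0), (0, 1), (2, 0), (1, 1), (0, 2), (3, 0), (2, 1), (1, 2), (0, 3),
    ),
}


def term_names(form: ModelForm) -> tuple[str, ...]:
    """Coefficient names (p00, p10, ...) for a polynomial form."""
    return tuple(f"p{i}{j}" for i, j in _TERMS[form])


def _design_matrix(dl: np.ndarray, tc: np.ndarray, form: ModelForm) -> np.ndarray:
    dl = np.asarray(dl, dtype=float)
    tc = np.asarray(tc, dtype=float)
    return np.column_stack([dl**i * tc**j for i, j in _TERMS[form]])


@dataclass(frozen=True)
class SplitSpec:
    """Calibration/validation split configuration.

    With ``stratify_by_tbb`` the records are grouped by rounded blackbody
    setpoint and sampled within each group, so both subsets span the full
    measured range.
    """

    calibration_fraction: float = 0.65
    seed: int = 0
    stratify_by_tbb: bool = True

    def __post_init__(self) -> None:
        if not 0.0 < self.calibration_fraction < 1.0:
            raise ValueError("calibration_fraction must be in (0, 1)")


def split_dataset(dataset: CalibrationDataset, spec: SplitSpec) -> CalibrationDataset:
    """Assign calibration/validation labels by stratified random sampling.

    The total calibration count equals ``round(fraction * n)``; it is
    apportioned across setpoint bins by largest remainder, so every bin's
    share is within one record of ``fraction`` times its size.  A bin with a
    single record goes entirely to calibration (with a warning).
    Deterministic given ``spec.seed``.
    """
    n = len(dataset)
    if n < 4:
        raise ValueError("need at least 4 records to split")
    rng = np.random.default_rng(spec.seed)
    tbb = dataset.tbb
    if spec.stratify_by_tbb:
        keys = np.round(tbb).astype(int)
    else:
        keys = np.zeros(n, dtype=int)
    bins = [np.flatnonzero(keys == k) for k in np.unique(keys)]

    frac = spec.calibration_fraction
    total_cal = int(round(frac * n))
    base = [int(np.floor(frac * len(b))) for b in bins]
    # bins of size 1 are forced to calibration
    for bi, b in enumerate(bins):
        if len(b) == 1:
            warnings.warn(
                f"setpoint bin {np.round(tbb[b[0]]):g} has a single record; "
                "assigning it to the calibration subset",
                stacklevel=2,
            )
            base[bi] = 1
    # keep at least one record on each side of every bin of size >= 2
    base = [min(max(c, 1), len(b) - 1) if len(b) >= 2 else c for c, b in zip(base, bins)]
    remainders = [frac * len(b) - c for c, b in zip(base, bins)]
    short = total_cal - sum(base)
    order = sorted(range(len(bins)), key=lambda i: (-remainders[i], i))
    for i in order:
        if short <= 0:
            break
        if len(bins[i]) >= 2 and base[i] < len(bins[i]) - 1:
            base[i] += 1
            short -= 1

    labels = np.full(n, VAL_LABEL, dtype=object)
    for b, n_cal in zip(bins, base):
        pick = rng.permutation(b)[:n_cal]
        labels[pick] = CAL_LABEL
    return CalibrationDataset(dataset.records, tuple(labels))


@dataclass(frozen=True)
class PolynomialModel:
    """A fitted polynomial mapping (DL, TC) -> temperature (degrees C)."""

    form: ModelForm
    coeffs: tuple[float, ...]

    def __post_init__(self) -> None:
        if self.form == ModelForm.ANN:
            raise ValueError("PolynomialModel cannot have the ANN form")
        k = len(_TERMS[self.form])
        if len(self.coeffs) != k:
            raise ValueError(f"form {self.form.value} needs {k} coefficients")
        if not np.all(np.isfinite(self.coeffs)):
            raise ValueError("coefficients must be finite")
        object.__setattr__(self, "coeffs", tuple(float(c) for c in self.coeffs))

    @property
    def coefficients(self) -> dict[str, float]:
        return dict(zip(term_names(self.form), self.coeffs))

    def predict(self, dl, tc):
        return predict_polynomial(self, dl, tc)


def fit_polynomial(dataset: CalibrationDataset, form: ModelForm) -> PolynomialModel:
    """Ordinary least-squares fit of a polynomial form.

    If the dataset carries split labels only the calibration subset is used.
    The design columns are built exactly from the form's term list; columns
    are rescaled internally for numerical stability, which leaves the
    least-squares solution unchanged.  A rank-deficient design raises
    :class:`SingularFitError` naming the collinear terms.
    """
    if form == ModelForm.ANN:
        raise ValueError("use train_ann for the ANN form")
    data = dataset.subset(CAL_LABEL) if dataset.split_labels is not None else dataset
    names = term_names(form)
    k = len(names)
    if len(data) < k:
        raise ValueError(f"need at least {k} calibration records for {form.value}")
    X = _design_matrix(data.dl, data.tc, form)
    y = data.tbb
    norms = np.linalg.norm(X, axis=0)
    norms[norms == 0] = 1.0
    Xs = X / norms
    u, s, vt = np.linalg.svd(Xs, full_matrices=False)
    if s[-1] < 1e-10 * s[0]:
        null = vt[-1]
        involved = tuple(
            nm for nm, v in zip(names, null) if abs(v) > 1e-8 * np.abs(null).max()
        )
        raise SingularFitError(
            f"singular design for form {form.value}; collinear terms: {involved}",
            collinear_terms=involved,
        )
    beta = vt.T @ ((u.T @ y) / s) / norms
    return PolynomialModel(form=form, coeffs=tuple(beta))


def predict_polynomial(model: PolynomialModel, dl, tc):
    """Evaluate the polynomial at (DL, TC); vectorizes elementwise."""
    dl = np.asarray(dl, dtype=float)
    tc = np.asarray(tc, dtype=float)
    if not (np.all(np.isfinite(dl)) and np.all(np.isfinite(tc))):
        raise ValueError("inputs must be finite")
    dlb, tcb = np.broadcast_arrays(dl, tc)
    X = _design_matrix(dlb.ravel(), tcb.ravel(), model.form)
    out = X @ np.asarray(model.coeffs)
    if dlb.shape == ():
        return float(out[0])
    return out.reshape(dlb.shape)


@dataclass(frozen=True)
class AnnTrainConfig:
    """Backpropagation training hyperparameters.

    ``learning_rate`` is the initial step size; during training it grows by
    5% after each improving full-batch step and is halved (with the step
    reverted and the momentum reset) after a worsening one.
    """

    hidden_size: int = 10
    learning_rate: float = 0.01
    momentum: float = 0.9
    max_epochs: int = 5000
    patience: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        if self.hidden_size < 1:
            raise ValueError("hidden_size must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if self.max_epochs < 1:
            raise ValueError("max_epochs must be >= 1")


@dataclass(frozen=True)
class AnnModel:
    """A trained single-hidden-layer tanh network for (DL, TC) -> temperature.

    Inputs and output are standardized/de-standardized using the stored
    centers and scales (taken from the calibration subset at training time).
    """

    hidden_size: int
    input_weights: np.ndarray  # (2, hidden)
    input_bias: np.ndarray  # (hidden,)
    output_weights: np.ndarray  # (hidden,)
    output_bias: float
    input_center: np.ndarray  # (2,)
    input_scale: np.ndarray  # (2,)
    output_center: float
    output_scale: float
    training_seed: int = 0
    validation_rmse: float = float("nan")

    def __post_init__(self) -> None:
        iw = np.asarray(self.input_weights, dtype=float)
        if iw.shape != (2, self.hidden_size):
            raise ValueError("input_weights must have shape (2, hidden_size)")
        object.__setattr__(self, "input_weights", iw)
        for name, shape in (("input_bias", (self.hidden_size,)),
                            ("output_weights", (self.hidden_size,)),
                            ("input_center", (2,)), ("input_scale", (2,))):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != shape:
                raise ValueError(f"{name} must have shape {shape}")
            object.__setattr__(self, name, arr)
        if np.any(self.input_scale == 0) or self.output_scale == 0:
            raise ValueError("scalings must be nonzero")

    def predict(self, dl, tc):
        return predict_ann(self, dl, tc)


def predict_ann(model: AnnModel, dl, tc):
    """Forward pass: standardize, tanh hidden layer, linear output, de-standardize."""
    dl = np.asarray(dl, dtype=float)
    tc = np.asarray(tc, dtype=float)
    if not (np.all(np.isfinite(dl)) and np.all(np.isfinite(tc))):
        raise ValueError("inputs must be finite")
    dlb, tcb = np.broadcast_arrays(dl, tc)
    shape = dlb.shape
    X = np.column_stack([dlb.ravel(), tcb.ravel()])
    Xs = (X - model.input_center) / model.input_scale
    h = np.tanh(Xs @ model.input_weights + model.input_bias)
    ys_out = h @ model.output_weights + model.output_bias
    y = ys_out * model.output_scale + model.output_center
    if shape == ():
        return float(y[0])
    return y.reshape(shape)


def train_ann(dataset: CalibrationDataset, config: AnnTrainConfig | None = None) -> AnnModel:
    """Train the tanh network by full-batch backpropagation.

    Weights start from a seeded uniform(-0.5, 0.5) draw.  Each epoch takes a
    gradient-descent-with-momentum step on the mean squared error of the
    standardized calibration subset; the step size adapts (see
    :class:`AnnTrainConfig`).  Training stops at ``max_epochs`` or when the
    validation RMSE has not improved for ``patience`` epochs, and the
    returned model is the snapshot with the best validation RMSE.
    Deterministic given ``config.seed``.
    """
    config = config or AnnTrainConfig()
    if dataset.split_labels is None:
        raise ValueError("train_ann requires a dataset with split labels")
    cal = dataset.subset(CAL_LABEL)
    val = dataset.subset(VAL_LABEL)
    if len(cal) == 0 or len(val) == 0:
        raise ValueError("both calibration and validation subsets must be non-empty")

    Xc = np.column_stack([cal.dl, cal.tc])
    Xv = np.column_stack([val.dl, val.tc])
    yc, yv = cal.tbb, val.tbb
    mu, sd = Xc.mean(axis=0), Xc.std(axis=0)
    sd[sd == 0] = 1.0
    ym, ys = float(yc.mean()), float(yc.std()) or 1.0
    Xcs, Xvs = (Xc - mu) / sd, (Xv - mu) / sd
    ycs = (yc - ym) / ys

    rng = np.random.default_rng(config.seed)
    h = config.hidden_size
    W = [
        rng.uniform(-0.5, 0.5, (2, h)),
        rng.uniform(-0.5, 0.5, h),
        rng.uniform(-0.5, 0.5, h),
        rng.uniform(-0.5, 0.5, 1),
    ]
    V = [np.zeros_like(w) for w in W]
    lr = config.learning_rate
    mom = config.momentum
    n = len(Xcs)
    prev_loss = np.inf
    best_rmse = np.inf
    best_W = [w.copy() for w in W]
    stall = 0

    for _epoch in range(config.max_epochs):
        H = np.tanh(Xcs @ W[0] + W[1])
        pred = H @ W[2] + W[3][0]
        err = pred - ycs
        loss = float(np.mean(err**2))
        if not np.isfinite(loss):
            raise TrainingDivergenceError(
                "training loss became non-finite; try a smaller learning_rate"
            )
        if loss > prev_loss * (1.0 + 1e-6):
            # bold driver: undo the bad step, reset momentum, shrink the rate
            W = [w - v for w, v in zip(W, V)]
            V = [np.zeros_like(w) for w in W]
            lr *= 0.5
        else:
            lr *= 1.05
            prev_loss = loss
        grad_out = (2.0 / n) * err
        grad_h = np.outer(grad_out, W[2]) * (1.0 - H**2)
        G = [Xcs.T @ grad_h, grad_h.sum(axis=0), H.T @ grad_out,
             np.array([grad_out.sum()])]
        V = [mom * v - lr * g for v, g in zip(V, G)]
        W = [w + v for w, v in zip(W, V)]

        pv = (np.tanh(Xvs @ W[0] + W[1]) @ W[2] + W[3][0]) * ys + ym
        val_rmse = float(np.sqrt(np.mean((pv - yv) ** 2)))
        if val_rmse < best_rmse - 1e-12:
            best_rmse = val_rmse
            best_W = [w.copy() for w in W]
            stall = 0
        else:
            stall += 1
            if stall >= config.patience:
                break

    return AnnModel(
        hidden_size=h,
        input_weights=best_W[0],
        input_bias=best_W[1],
        output_weights=best_W[2],
        output_bias=float(best_W[3][0]),
        input_center=mu,
        input_scale=sd,
        output_center=ym,
        output_scale=ys,
        training_seed=config.seed,
        validation_rmse=best_rmse,
    )


CalibrationModel = Union[PolynomialModel, AnnModel]


def apply_model(frame: ThermalFrame, model: CalibrationModel) -> TemperatureMap:
    """Calibrate a raw frame to a per-pixel temperature map (degrees C).

    The frame's single sensor temperature is used as TC for every pixel.
    """
    dl = frame.pixels.astype(np.float64)
    temps = model.predict(dl, frame.sensor_temp)
    tag = model.form.value if isinstance(model, PolynomialModel) else ModelForm.ANN.value
    return TemperatureMap(temps=temps, provenance=f"{tag}:{frame.frame_id}")


def validation_rmse(dataset: CalibrationDataset, model: CalibrationModel) -> float:
    """RMSE (degrees C) of a model on the dataset's validation subset."""
    val = dataset.subset(VAL_LABEL)
    pred = model.predict(val.dl, val.tc)
    return float(np.sqrt(np.mean((pred - val.tbb) ** 2)))


# ---------------------------------------------------------------------------
# Model serialization


def save_model(model: CalibrationModel, path: str | Path) -> None:
    """Serialize a model to JSON (round-trips predictions exactly)."""
    if isinstance(model, PolynomialModel):
        payload = {"form": model.form.value, "coefficients": model.coefficients}
    else:
        payload = {
            "form": ModelForm.ANN.value,
            "weights": {
                "hidden_size": model.hidden_size,
                "input_weights": model.input_weights.tolist(),
                "input_bias": model.input_bias.tolist(),
                "output_weights": model.output_weights.tolist(),
                "output_bias": model.output_bias,
            },
            "scaling": {
                "input_center": model.input_center.tolist(),
                "input_scale": model.input_scale.tolist(),
                "output_center": model.output_center,
                "output_scale": model.output_scale,
            },
            "seed": model.training_seed,
        }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


def load_model(path: str | Path) -> CalibrationModel:
    """Load a model serialized by :func:`save_model`."""
    try:
        with open(path) as fh:
            payload = json.load(fh)
    except json.JSONDecodeError as exc:
        raise FormatError(f"{path}: invalid model JSON: {exc}") from exc
    tag = payload.get("form")
    try:
        form = ModelForm(tag)
    except ValueError:
        raise FormatError(f"{path}: unknown model form tag {tag!r}") from None
    if form == ModelForm.ANN:
        w, s = payload["weights"], payload["scaling"]
        return AnnModel(
            hidden_size=int(w["hidden_size"]),
            input_weights=np.array(w["input_weights"], dtype=float),
            input_bias=np.array(w["input_bias"], dtype=float),
            output_weights=np.array(w["output_weights"], dtype=float),
            output_bias=float(w["output_bias"]),
            input_center=np.array(s["input_center"], dtype=float),
            input_scale=np.array(s["input_scale"], dtype=float),
            output_center=float(s["output_center"]),
            output_scale=float(s["output_scale"]),
            training_seed=int(payload.get("seed", 0)),
        )
    names = term_names(form)
    coeffs = payload.get("coefficients", {})
    missing = [nm for nm in names if nm not in coeffs]
    if missing:
        raise FormatError(f"{path}: model JSON missing coefficients {missing}")
    return PolynomialModel(form=form, coeffs=tuple(coeffs[nm] for nm in names))
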