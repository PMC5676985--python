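# Methods

This note documents the models, the synthetic study design, and the
numerical choices behind `thermocal`, in the spirit of a package methods
appendix: what is computed, under which assumptions, and what the tests
do and do not demonstrate about real data.

## Radiometric calibration

A TEC-less microbolometer's digital response to a target at temperature
TBB drifts with the sensor temperature TC. The calibration problem is the
regression (DL, TC) → TBB on blackbody observations, where DL is the mean
digital level of a user-selected region of interest on the blackbody
target (plain arithmetic mean; no trimming).

**Polynomial family.** Nested forms built from monomials DL^i·TC^j:

| form | terms |
|---|---|
| LINEAR_DL | 1, DL |
| P1 | 1, DL, TC |
| P2 | + DL², DL·TC, TC² |
| P3 | + DL³, DL²·TC, DL·TC² |
| P4 | + TC³ |

LINEAR_DL is the degenerate baseline that ignores the sensor temperature —
it stands in for a camera's fixed factory mapping. Fits are ordinary least
squares; design columns are rescaled to unit norm internally (the solution
is unchanged) and a singular design raises an error naming the collinear
terms rather than silently pseudo-inverting. By least-squares nesting, the
training RMSE is non-increasing from P1 to P4; validation RMSE need not
be, which is the overfitting signal the model comparison looks for.

**Neural network.** One hidden layer of tanh units (default 10) and a
linear output. Inputs and target are standardized by the calibration
subset's mean/SD. Training is full-batch backpropagation: gradient descent
with momentum (default 0.9) on the mean squared error, weights initialized
from a seeded uniform(−0.5, 0.5). The step size is adaptive ("bold
driver"): it grows by 5% after every improving epoch; after a worsening
epoch the step is reverted, the momentum zeroed, and the rate halved. This
choice is load-bearing: with a fixed step the momentum run-away either
diverges or collapses the rate to zero, while the revert-and-restart
variant reaches ~0.1 °C validation RMSE on low-noise campaigns and remains
fully deterministic given the seed. Training stops at `max_epochs`
(default 5000) or when validation RMSE has not improved for `patience`
(default 200) epochs; the returned model is the best-on-validation
snapshot. Convergence to the 0.01 °C level on exactly-planar targets
needs tens of thousands of epochs — first-order training is slow at high
precision; the defaults favor the realistic noisy regime where that
precision is immaterial.

**Split.** 65% calibration / 35% validation. Records are binned by
rounded blackbody setpoint and sampled within bins (largest-remainder
apportionment of the total calibration count), so both subsets span the
full temperature range verifiably; a single-record bin goes to calibration
with a warning. Deterministic given the seed.

## Agreement statistics and residual screen

R² is the squared Pearson correlation of observed and simulated values;
RMSE is in °C; RE = 100·RMSE/mean(observed) in percent. The similarity
index is Willmott's index of agreement,
SI = 1 − Σ(S−O)² / Σ(|S−MO| + |O−MO|)². A variant without the absolute
values is available behind `literal_form=True`; it can degenerate when
deviations cancel and is provided for comparison only, not as the
default. The residual screen regresses observed on simulated and applies
Shapiro–Wilk (normality), Breusch–Pagan (squared residuals on the
simulated values), and Cook's distance with the common 4/n outlier
threshold; the test names are recorded in the result so reports are
self-describing.

## Wallis filtering

Raw counts are first brought to an 8-bit working range by a linear
percentile stretch (defaults 2–98%; a constant image maps to 127). The
filter is the classical two-constant form

G′ = (G − m)·c·s_t / (c·s + (1 − c)·s_t + ε) + b·m_t + (1 − b)·m

with local mean m and population SD s over an odd window (default 31,
reflection-padded), targets m_t = 127 and s_t = 50, contrast constant
c = 0.8, brightness constant b = 0.9, variance guard ε = 1e-6. Output is
clipped and rounded to 8 bits. Two consequences worth stating explicitly:

* The pointwise amplification is bounded by c·s_t/((1−c)·s_t) — a factor
  4 at the defaults. Full equalization of flat areas to the target SD
  requires c = 1.
* A 2–98% percentile stretch is itself adaptive: any light-tailed scene
  already fills the 8-bit range after stretching, so a *globally*
  low-SD working image only arises from heavy-tailed histograms (a few
  strong features against a flat background) or from a fixed
  count-to-grey rendering of a narrow-band scene. On heavy-tailed scenes
  the filter *redistributes* contrast — compressing the dominant features
  and lifting weak texture — and can lower the global SD while raising
  the usable local contrast. Contrast accounting therefore uses the
  median of the windowed SD map (`local_contrast`) rather than the global
  SD, which is dominated by smooth structure (vignetting, large-scale
  temperature gradients).

## Tie-point surrogate

Production SfM matchers are proprietary, so the filtering effect is
measured with a transparent stand-in: Harris corner response (central
difference gradients; structure tensor smoothed with a Gaussian of
σ = 1.5; response det − 0.05·trace²), 3×3 non-maximum suppression, a
relative threshold (default 0.05 of the maximum response), a cap of 500
points by descending score, and mutual-best normalized cross-correlation
of 11×11 patches at a 0.8 acceptance threshold. Counts are comparable
only in trend with industrial pipelines, never in magnitude. The relative
detector threshold is what makes adaptive filtering matter: before
filtering, the strongest feature sets the bar and weak texture falls
below it; after local equalization, features of very different raw
strength pass together.

## Geo-accuracy summaries

Per-axis accuracy is the RMS over control points of the signed errors
(estimated − surveyed, meters); the 3-D total is the RMS of per-point
Euclidean errors, so total² = rms_x² + rms_y² + rms_z² exactly. The
bundled survey tables use meters throughout. Field validation reduces
paired (reference, product) temperature means to RMSE, maximum absolute
difference, mean bias, and the sample (n−1) SD of the differences, plus a
full agreement report.

## Synthetic study design

**Blackbody campaign.** The forward model for the ROI-mean digital level is

DL = offset + k1·(TBB + 273.15)⁴·10⁻⁸ + k2·(TC − t0) + k3·(TC − t0)² + N(0, σ)

a fourth-power radiance proxy for the 7.5–13.5 μm band plus a quadratic
sensor-temperature drift. The T⁴ proxy (rather than a band-integrated
Planck model) is a deliberate simplification: adequate at these
temperatures and easy to reason about. Defaults — k1 = 60 counts per
10⁻⁸·K⁴, k2 = −15 counts/°C, k3 = −0.8 counts/°C², offset = 2000 counts,
t0 = 20 °C — put counts in a 14-bit-like band (≈5300–9900 over setpoints
5–65 °C) with a mid-range sensitivity near 70 counts/°C, so the default
noise of 35 counts corresponds to ≈0.5 °C. Setpoints run 5–65 °C in 5 °C
steps (13 levels); the default 20 sensor temperatures span 5–31 °C,
sampled more densely above 20 °C (cold-room acquisitions are the hard
ones in practice). Model-ordering experiments (network vs quadratic
surface vs DL-only) use a low-noise variant (σ = 5 counts ≈ 0.07 °C)
where model bias, not noise, dominates the validation RMSE; the noiseless
campaign's inverse response is near-quadratic (P2 tracks it to ≈0.2 °C)
but not exactly so, which is what the network exploits.

**Scene pairs.** A scene is a smooth random thermal field (Gaussian
correlation length 60 px, SD 3 counts) plus sparse Gaussian texture blobs
whose peak amplitudes are heavy-tailed (Pareto shape 2.5, scale 60
counts, truncated at 10×, random sign), rendered twice with a known
integer translation, a vignetting falloff fixed to frame coordinates
(40 counts), and fresh per-frame read noise (1 count). The heavy tail is
the modeled feature of real thermal scenes: a few strong thermal anomalies
and much weak texture, which is the regime where adaptive filtering
roughly doubles the accepted match count and concentrates the gain on the
pairs that start weakest. What the generator does **not** emulate:
non-uniformity and defective-pixel patterns, shutter events, motion blur,
perspective and rotation between frames (translation only), and
occlusion; passing tests therefore demonstrate the filtering mechanism,
not end-to-end SfM performance on flight data.

**GCP tables.** Zero-mean Gaussian per-axis errors; used for law-of-large
numbers checks of the RMS summaries and for permutation/identity
properties.

All generators are bit-reproducible given (config, seed).

## Numerical choices and degenerate inputs

* Least-squares rank is checked by SVD at a 1e-10 relative threshold;
  collinear terms are identified from the null-space vector.
* Windowed SD uses E[x²] − E[x]² with a non-negativity clamp; edge
  handling is symmetric (scipy "reflect") padding everywhere.
* Keypoint ordering and NCC tie-breaks are made deterministic by sorting
  on (−score, row, col) and (row, col) respectively.
* Constant images: the percentile stretch maps them to mid-grey (127);
  the Wallis output of a constant image is b·m_t + (1−b)·G.
* Zero-variance series raise `UndefinedStatisticError` rather than
  returning NaN; length mismatches and empty inputs raise `ValueError`.
* Temperatures are Celsius floats end to end; temperature maps are
  written as 32-bit float TIFF, so round trips are exact to ~1e-6.

## Problem sizes

Test and example runs use 260-record campaigns, 256×256 scene pairs (ten
pairs per comparison), and 20-seed replications for the stochastic
ordering properties — sizes chosen so the full suite exercises every code
path in seconds while keeping the Monte-Carlo assertions (≥18/20 wins,
≥9/10 pairs, rank correlations) well away from their thresholds.

## Known limitations

* The network's absolute accuracy on a real camera cannot be asserted
  from synthetic data; only ordering and recovery properties are tested.
* The tie-point surrogate's absolute counts are incomparable to
  production matchers.
* The Wallis formulation is the standard two-constant photogrammetric
  form; other parameterizations exist and all constants are exposed.
* No atmospheric, emissivity, or size-of-source corrections: inputs are
  assumed to be firmware-corrected counts, and outputs are at-sensor
  brightness temperatures calibrated against a blackbody.
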