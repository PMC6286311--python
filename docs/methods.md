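# Methods

This note documents the models behind each module, the parameters that
matter, the numerical choices, and what the synthetic benchmark does and
does not demonstrate about real cultures.

## Coordinate and unit conventions

All modules share one frame: origin at the top-left pixel center, x
rightward, y downward, physical position in µm = pixel index ×
`pixel_size_um`. Laser powers are W, speeds mm/s, beam widths and line
intervals µm, doses J/mm (per length) or J/mm² (areal), temperatures °C.
The physical pixel pitch of the 1920×1200 camera raster is not an
instrument constant here but a configuration value, default 1.0 µm/px
(one field ≈ 1.9 × 1.2 mm); all geometry arithmetic is transparent in it.

## Synthetic culture fields (`colony_sim`)

Colonies are smooth blobs (circle radius modulated by a low-order random
Fourier series in polar angle) placed without overwrite on a dark
background. Within each colony a single contiguous differentiated patch is
carved out by picking a seed pixel and taking the colony pixels inside the
`differentiated_fraction`-quantile of distances to it — this pins the
realized per-field area fraction to the target up to pixel quantization, so
the configured fraction is also the empirical one.

The phase-contrast texture is the classifier's learnable signal and encodes
the morphological difference between the two states: undifferentiated
regions get fine granularity and high local contrast (σ ≈ 1 px band-limited
noise, high amplitude), differentiated regions a coarser, flatter texture
(σ ≈ 5 px, low amplitude, brighter base), and the colony rim a bright halo
ring as in phase-contrast optics. Additive Gaussian sensor noise
(`texture_noise_sd`, default 800 on the 16-bit scale) covers both channels.
The fluorescence channel is a binary stain analog — bright
(`fluor_pos_level` = 30 000) on undifferentiated colony pixels, dark
(4 000) elsewhere — so thresholding it at the midpoint recovers the
undifferentiated mask to well under the 5% error budget at default noise.
Cells are Poisson-sampled inside colony footprints (default 1 500 cells/mm²
of colony area, 10 µm diameter) with type read from the mask at their
center.

Default study conditions: 1920×1200 px fields, 4 colonies of 220–420 µm
radius, 20% differentiated area. What the generator deliberately does not
emulate: photorealistic phase optics, feeder cells, colony growth, imaging
tiles/stitching seams, focus drift. Consequently a high benchmark score
shows the pipeline is correct and self-consistent, not that the classifier
would reach the same accuracy on real micrographs.

## Patch classifier (`patch_cnn`)

Fixed chain: 70×70 single-channel input → conv 32@5×5 (valid) → ReLU →
maxpool 3×3 (stride 3) → conv 32@3×3 (valid) → ReLU → maxpool 2×2
(stride 2) → fully connected to 2 logits → softmax cross entropy. The
spatial sizes walk 70 → 66 → 22 → 20 → 10, so the head sees
10·10·32 = 3200 units. Valid convolutions with pool stride equal to the
pool kernel are conventions chosen for this clean size chain; ReLU
activations, per-patch standardization (zero mean, unit variance) and a
direct-to-2-classes head are likewise conventions, as is inverse-frequency
class weighting in the loss (configurable off).

Training hyper-parameters (`TrainHyper`): Adam, learning rate 1e-3, batch
32, 10 epochs per round, 320 random patches per training frame split
evenly between classes. These sizes were chosen as the smallest schedule
that saturates held-out accuracy on the synthetic benchmark; larger budgets
change nothing but cost. All randomness (weight init, shuffling, patch
sampling) flows from explicit seeds; training twice with one seed is
bit-identical.

Patch labels use majority vote over non-background mask pixels, and a patch
is dropped when the majority class covers less than `purity_threshold`
(default 0.8) of its pixels; background patches are excluded from training
(two-class formulation), with an option to map background to
undifferentiated for whole-frame inference robustness.

Hard-example mining: after round 1 the model is applied to the training
frames' non-overlap grid; undifferentiated patches misclassified as
differentiated are appended to the training set and round 2 **continues
from the round-1 weights** (fine-tuning; a fresh optimizer state per
round). Retraining from scratch would also be defensible — continuation was
chosen because it preserves round-1 knowledge and makes the
mining-monotonicity property (round-2 false-differentiated count ≤ round-1
on held-out frames) robust in practice.

Probability maps tile the phase frame with 70×70 windows at a configurable
stride (default 70 = non-overlap), paint each window's differentiated-class
probability onto the pixels it covers, average where windows overlap, and
fill the uncovered right/bottom margins with the nearest covered value.
Deployment is phase-only: fluorescence never reaches the classifier.

## Scan planning and dose (`scan_planner`)

Dose model: a beam of power P scanned at speed v deposits P/v J/mm; over
width w this is a flux P/(v·w) J/mm². Any (P, v) pair with equal ratio is
iso-dose — the model carries no speed dependence beyond the ratio.

Patterns: rasters are horizontal line families at the laser's
`line_interval_um`, serpentine-ordered, clipped to the region (chords on a
circular dish); lattices add the orthogonal family; the 35 mm dish's
scannable surface is modeled as a circle of area 9 cm². Gating samples the
beam centerline at half-pixel resolution against the target set
(probability ≥ threshold, default 0.5, or mask = differentiated), optionally
dilated by half the beam width (default on) so target edges receive
full-width coverage; positions outside the map are OFF. Turnaround overhead
between lines defaults to 0 s (the device's per-line overhead is not
published), so planned times are lower bounds on wall-clock scan times;
`turnaround_s` exists for matching real hardware, and `skip_empty_lines`
drops gated lines with no ON span.

## Photothermal model (`photothermal`)

Surface (2-D) heat equation with a moving source:

    ∂T/∂t = D ∇²T − λ (T − T_amb) + S(x, y, t)

- `D_mm2_s` = 0.1 — lateral thermal diffusion coefficient of the film
  stack.
- `ambient_C` = 29.5 — stage temperature of the thermal-imaging setup.
- Absorbed power = P · (1 − 10^−A) with substrate absorbance A = 0.25 at
  405 nm (≈ 43.8% absorbed).
- S is a top-hat spot of the beam diameter (Gaussian optional) moving at v,
  normalized over the rasterized spot so total absorbed power is conserved.
- `coupling_C_mm2_per_J` = 620 and `loss_rate_s` = 25 collapse the film's
  unpublished areal heat capacity and interface losses into two constants,
  fixed once by `scripts/calibrate_thermal.py` so that the reference stroke
  (0.3 W, 80 mm/s, 50 µm) peaks just above 50 °C with decay to
  physiological temperature (37 °C) completing on the ~10 ms scale. At
  those constants the simulated stroke peaks at 53.6 °C with a 0.56 ms
  rise and 8.3 ms decay — the "comet" regime.

A 2-D surface model (not 3-D conduction into medium) is justified by the
thin-layer geometry and by the fact that every quantity of interest (D,
comet timing) is a surface observation; it is a stated simplification.
Integration is explicit forward-time centered-space with
dt = 0.5 · Δx²/(4D) by default (a user-supplied dt above the stability
bound aborts with the admissible value); boundaries are Dirichlet at
ambient on a domain padded 10 diffusion lengths (of the run duration)
beyond the trajectory, emulating the large dish. The integrator is checked
against the closed-form continuous point-source solution
T(r,t) − T₀ = s₀/(4πD) · E₁(r²/4Dt) (within 2% at 5 µm grid), conserves
total excess heat to well under 0.5% over 10⁴ steps with losses off, and
satisfies the maximum principle with the source off.

Comet metrics: rise time is 10%→90% of a probe point's peak excess; decay
time runs from the peak to the first return to physiological temperature;
tail length is the instantaneous distance from the beam center to the
farthest trailing above-physiological point on the scan line at the last
on-path snapshot, and satisfies the kinematic identity tail ≈ v × decay on
a quasi-steady stroke. All metrics are flagged undefined when the probe
never exceeds physiological temperature (e.g. uncoated-dish control, where
zero coupling keeps the whole field at ambient).

## Kill rule and purity (`kill_eval`)

Default rule: dose threshold at energy_flux(0.8, 100, 50) = 0.16 J/mm²,
i.e. the lowest power observed to kill reliably at the deployed speed
becomes the threshold; a cell dies exactly when the accumulated flux at its
center meets it. Death is binary at the cell center with no bystander
effect, so the ~50 µm death swath along a line emerges from the beam width
alone. A peak-temperature mode (kill at ≥ 50 °C) exists for cross-speed
studies but is not the default: dose per length alone cannot explain the
observed cross-speed kill pattern (a 4.4 W / 1000 mm/s kill at 0.0044 J/mm
versus the 0.008 J/mm needed at 100 mm/s), so the single-speed calibration
is deliberately not extrapolated across speeds, and the mechanism question
(peak temperature vs integrated dose vs photochemical injury) is left open.
The flow-cytometry analog counts only surviving cells (dead cells are
assumed washed away before harvest — an assumption of the readout, not an
observation).

The closed loop composes: training-field synthesis → two-round CNN
training → probability map on an independent held-out field (phase only) →
gated 25 µm raster at 0.8 W / 100 mm/s → dose accumulation → kill → purity
of survivors. All stage seeds derive deterministically from one loop seed.
With zero differentiated area the loop short-circuits (nothing to target,
population untouched) since a single-class training set is degenerate.

## Problem sizes used in the shipped checks

Unit tests run on shrunk geometry (560×420 px fields, 70–130 µm colonies)
so the suite stays interactive; the benchmark and closed-loop checks use
the full default conditions (1920×1200 px, 20% differentiated, default
`TrainHyper`), ten independent seeds for the purity average, and the 9 cm²
dish for scan-time accounting. These sizes are the package's own choices
and are asserted nowhere as instrument facts.

## Known limitations

- The generator's texture contrast between classes is stronger and cleaner
  than real phase-contrast morphology; benchmark accuracies are upper
  bounds on real-data performance.
- The thermal constants (`coupling`, `loss_rate_s`) are calibrated, not
  measured; only the calibrated regime's properties (timing, locality,
  integrator fidelity) are claimed.
- No kinematics: the planner ignores galvo/stage acceleration, so scan
  times exclude per-line turnaround unless `turnaround_s` is set.
- No biology after the kill: regrowth, migration into cleared areas, clump
  passaging and marker assays are out of scope.
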