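# Methods

`echolv` implements an automated pipeline for measuring left-ventricular
linear dimensions — interventricular septal thickness (IVS), LV internal
diameter (LVD) and free-wall thickness (FW) — from long-axis echocardiographic
frames, together with the multi-reader consensus framework used to judge any
automated or human measurer. This note records the models, the parameters
that matter, and the numerical choices, in enough detail to reproduce or
challenge them.

## Keypoint model

Four named landmarks lie in anatomical order along the measurement axis:
`SEPT_ANT`, `SEPT_POST` (anterior/posterior borders of the septum) and
`FW_ANT`, `FW_POST` (borders of the free wall). Calipers between consecutive
landmarks give IVS, LVD and FW as full Euclidean distances computed in
cm-space: coordinate deltas are scaled per axis by the pixel spacing before
the norm, so anisotropic calibration (e.g. after a non-uniform resize) is
handled exactly. Distances are deliberately *not* projections onto a common
axis; instead, geometric sanity flags (`OUT_OF_ORDER`, `NON_COLLINEAR` with a
default collinearity tolerance of 15°) mark the "diagonal path across the
ventricle" failure mode without silently altering the numbers. The 15°
default is permissive enough to absorb realistic inter-observer variation in
measurement direction while catching frank geometric failures.

## Heatmap representation

Each landmark is regressed as a Gaussian confidence map: the target value at
pixel q for a landmark at p is `exp(-||q - p||² / (2σ²))`, σ = 15 px at the
320×320 working resolution. Targets are peak-normalised (amplitude 1 at the
landmark) rather than unit-integral, which keeps the decoded peak value
directly interpretable as a confidence and is the standard convention for MSE
heatmap regression. Targets are always rendered directly at working
resolution, never produced by resizing an image — resizing would attenuate
the peak. A point a rater could not localise produces an all-zero channel
with loss weight 0, so it contributes nothing to training.

A fifth channel carries the *pseudo-line*: a Gaussian ridge (same σ) around
the polyline joining the present landmarks in anatomical order. It is an
auxiliary target that rewards geometrically consistent, near-collinear
predictions. We model it as a separate output channel with its own loss term
(weight 1 by default, configurable); wiring it into the keypoint channels
themselves was the main plausible alternative, but a separate channel keeps
the per-keypoint decoder untouched and makes the constraint's contribution
to the loss independently controllable.

### Sub-pixel decoding

Decoding finds the global maximum pixel (ties broken toward the smallest
row-major index, deterministically) and refines it with a per-axis
log-quadratic three-point fit: for samples v(-1), v(0), v(+1) around the peak
the refined offset is `0.5·(ln v(-1) - ln v(+1)) / (ln v(-1) - 2 ln v(0) +
ln v(+1))`, clamped to ±0.5. Because the log of a sampled Gaussian is exactly
quadratic, this recovers the true sub-pixel center of rendered targets to
floating-point precision. A plain intensity-weighted centroid of a small
window — the other common refinement — is strongly biased toward the argmax
pixel for wide Gaussians: for a 7×7 window at σ = 15 the centroid recovers
only ≈ 28/(7σ²) ≈ 1.8 % of the true offset, so it cannot deliver sub-pixel
accuracy at this σ. Both alternatives remain available
(`refine="centroid" | "none"`), the latter reproducing a bare local-maximum
decoder. Peaks below `confidence_floor` (default 0.1) are reported as
missing. Values are clamped to 1e-12 before the log; a non-concave fit falls
back to the integer peak.

## Network and training

The backbone is a U-Net-style encoder-decoder: `depth` levels of
(conv3×3+ReLU)×2 with 2×2 max-pooling, channel width doubling from
`base_channels`, a bottleneck, nearest-neighbour upsampling with skip
concatenation on the way up, and a linear 1×1 head to 5 channels. The head is
zero-initialised (an untrained network predicts "nothing anywhere"); trunk
convolutions use He initialisation. The implementation is a compact,
fully-deterministic CPU numpy kernel with hand-written backpropagation,
verified against numeric gradients to ~1e-7 relative error; the network
sizes this package trains are tiny (tens of thousands of parameters), for
which this is entirely adequate.

Training minimises a masked MSE: the mean of squared differences over
unmasked channel-pixels, with the pseudo-line term scaled by
`pseudo_line_loss_weight`. Defaults follow the full-scale recipe: 200 epochs,
initial learning rate 0.001, LR divided by 5 whenever the held-out loss fails
to improve for 20 consecutive epochs (an explicit, hand-testable state
machine), batch 8, TAdam optimizer. TAdam — Adam with a Student-t robust
first moment (degrees of freedom = parameter dimension) — is implemented from
its published update rule; plain Adam is available as a flag and every result
records which optimizer produced it. On-the-fly augmentation applies one
sampled affine transform (rotation ±10°, translation ±5 %, scale 0.9–1.1)
identically to the image and all five target channels, plus a gamma change
(0.7–1.4) to the image only; loss masks are untouched. The best-held-out-loss
checkpoint is retained.

Unstated details fixed here as package defaults: batch size 8, the
augmentation magnitudes above, He/zero initialisation. Inference resizes the
frame bilinearly to the working grid, decodes each keypoint channel, and maps
coordinates back by pure per-axis scaling (`x_native = x_working · W_native /
W_working`), the exact inverse of the resize convention.

### Small-scale experiment

CPU budgets make the full 320 px/200-epoch recipe impractical for routine
verification, so the package's standard *small-scale recovery experiment*
(`echolv.evaluation.parameter_recovery`) trains a depth-2, base-8 U-Net at
128×128 on 200 phantoms for 10 epochs and scores 50 held-out phantoms. At
this scale the choices are: σ = 6 px (15 scaled by 128/320), batch 4,
learning rate 0.003, augmentation off, optimizer **Adam** (tagged in the
result; TAdam's robust first moment deliberately discounts early gradients
and has not converged far enough within a 10-epoch budget at this scale).
Typical results: mean keypoint error ≈ 1.5 px, mean thickness error ≈ 7 %.

## Phantom generator

The generator emulates the structural content of a right-parasternal 4-chamber
frame that the measurement task needs, not ultrasound physics: a fan-shaped
sector (dark outside), a darker chamber, and two bright myocardial bands of
finite lateral extent (`wall_halfwidth_cm`) crossed perpendicularly by the
measurement axis, which is the sector's central ray. Ground-truth keypoints
are the intersections of the axis with the band edges, so consecutive gaps
equal the generative IVS/LVD/FW exactly — the generator's first invariant.
Making the bands compact matters: with laterally unbounded bands the
along-wall coordinate of a landmark is not a function of local image
structure at all, and the MSE-optimal prediction is a ridge whose argmax is
set by noise; bounding the bands puts the caliper site at the visible band's
lateral midpoint, making the task well-posed. Speckle is multiplicative
Rayleigh texture, `img ← img·(1 + s·(R − E[R]))` clipped to [0,1], followed
by a gamma curve — the simplest ultrasound-like texture; there is no
point-spread convolution or depth attenuation, so networks trained on
phantoms demonstrate pipeline correctness and parameter recovery, not
clinical-image performance.

Cohorts draw parameters uniformly from per-parameter ranges. The default
320 px ranges use canine-scale dimensions (IVS 0.5–1.1 cm, LVD 2.0–3.2 cm,
FW 0.5–1.0 cm at 0.025 cm/px); the 128 px ranges scale the geometry down
(small-dog hearts at 0.02 cm/px) so the heart fits the small grid with the
same visual structure. Frames pair into pseudo-studies of one ED and one ES
frame, mirroring a validation cohort of two frames per scan.

### Rater simulator

A panel of `n_raters` (default 13) labels each frame `n_repeats` (default 2)
times. Each point is displaced by noise *perpendicular to the walls* (along
the measurement axis, SD `sigma_transverse_px` — this is what perturbs
thickness) and noise *along the walls* (SD `sigma_longitudinal_px` — this
moves the measurement site), plus a per-rater along-wall bias drawn once per
rater (SD `rater_longitudinal_bias_sd_px`) and held fixed across frames and
repeats, reflecting the observation that individual observers habitually
measure more apically or basally than their colleagues while agreeing far
better on thickness. Defaults (σ_t = 1.5 px, σ_l = 6 px, bias SD 4 px)
encode that longitudinal scatter dominates. Points go missing independently
with `miss_probability`. All randomness derives from a single seed via
counter-based substreams keyed by frame, rater and repeat, so any subset of a
cohort is reproducible regardless of generation order.

With transverse-only noise and an axis-aligned phantom, each thickness
measurement deviates from truth by N(0, 2σ_t²) px (two independent
endpoints), so pooled expert dispersion converges to √2·σ_t·spacing cm — the
closed form the consensus framework is verified against.

## Consensus validation framework

For every frame × site, the consensus is the arithmetic mean of the expert
values (the two repeats of one expert count as independent labels, giving 26
per frame with the default panel). Signed deviations from the per-frame
consensus are pooled across frames; their mean is zero *by construction*
(each frame's deviations sum to zero), which the summary asserts to 1e-9 —
the "Mean 0.00" column is structural, not empirical. Dispersion is the
population root-mean-square of deviations, which equals the population SD for
mean-zero pooled deviations.

A candidate measurer (any rater id, one value per frame × site) is judged
two ways: its deviation dispersion against the pooled expert deviations with
Levene's test (default centering: median, i.e. the Brown–Forsythe variant —
the default of the scipy routine; classic mean-centering available, and the
centering used is recorded in the output), and its mean bias against the
per-frame consensus with a two-sided paired t test. Group sizes are printed
in the summary because dispersion comparisons are sensitive to the pooling
convention: this package pools all expert deviations (≈26 × n_frames)
against the candidate's n_frames deviations. Published P-values from reader
studies using unstated conventions are therefore not reproduction targets.
Degenerate inputs are explicit: a zero within-group spread of absolute
centered scores raises `DEGENERATE_DISPERSION`; zero-variance paired
differences report bias 0/p 1 when the differences are all zero and a
degenerate flag otherwise. Frames lacking a candidate value are excluded
from candidate statistics and listed, never silently dropped.

## Numerical and I/O choices

- Coordinates are 0-based pixel indices, origin at the top-left pixel
  center, x = column rightward, y = row downward, stored at native
  resolution. Annotations serialise to JSON-lines with `repr`-shortest
  decimals, so coordinates round-trip bit-identically.
- Dataset splitting is study-level by default (all frames of a scan on one
  side, preventing leakage between near-duplicate frames); frame-level
  splitting is available. Both take `floor(fraction · n_units)` units for
  training, deterministically per seed.
- Working-size divisibility by 2^depth is enforced at configuration time.
- Non-finite training or held-out losses abort training with a diagnostic
  rather than continuing silently.
- TOML run configuration is strict: unknown keys are errors.

## Known limitations

- The phantom is a structural emulation; no claim is made about performance
  on clinical ultrasound. Passing recovery tests demonstrates that the
  pipeline can learn and invert its own generative geometry under speckle,
  not that it matches expert-level performance on real frames.
- The numpy training kernel is single-device and CPU-oriented; it is not
  intended for full-scale (320 px, 200-epoch, thousands-of-frames) training,
  although the configuration supports expressing that recipe.
- The consensus framework treats repeats as independent labels when pooling
  deviations; rater-clustered inference (mixed models) is out of scope.
- Semantic segmentation side-outputs are not implemented; the keypoint and
  pseudo-line channels are the only network targets.
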