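# Methods

## Heading estimation and rotation compensation

The animal's heading is the unit vector from the tailbase keypoint to the
head keypoint in image coordinates (x right, y down). All signed angles in
the package are clockwise-positive *as seen in the image*; a single
conventions module is shared by the generator, the controller and the stage
simulator so the sign cannot drift between components.

The frame-to-frame heading change combines the dot and cross products of
successive heading vectors: the magnitude is `atan2(|h₁×h₂|, h₁·h₂)` and the
sign is that of the cross product's z component. The atan2 form is
algebraically identical to `arccos(h₁·h₂)` but remains fully conditioned
when the vectors are nearly parallel, where arccos loses roughly half the
mantissa; the operator agrees with an independent atan2-unwrapping oracle
to better than 1e-12 degrees. Exactly antiparallel vectors are a genuine
ambiguity (a 180° change has no preferred direction); the tie-break is
+180° (clockwise), fixed and asserted in tests.

Signed changes accumulate across *accepted* frames only. A frame is
accepted when at least `stride` frames (default 5) have elapsed since the
last accepted estimate, both keypoint likelihoods exceed the confidence
threshold (default 0.9, strict inequality — "above" the threshold), and the
pose is non-degenerate. Rejected frames pause accumulation; the delta is
then taken from the last accepted estimate to the next accepted one, which
assumes less than 180° of net rotation across the gap. Gaps longer than
1 s trigger a warning. Missing/NaN coordinates are demoted to confidence 0
rather than raising, since trackers routinely emit them.

When the accumulator magnitude reaches the rotation threshold (presets: 90°
for open-field/rotating-arena work, 225° for the linear track) a rotate
command is emitted. How much to rotate is a genuinely open design point;
the default rotates by the **full accumulated angle** and resets the
accumulator to zero, which keeps the long-run twist centred on zero. A
rotate-by-threshold-only variant (residual retained) is available via
`ControllerConfig(compensation="threshold")`. The threshold comparison uses
a 1e-9-degree tolerance so that exact accumulations (e.g. twenty 4.5°
steps reaching 90°) trigger on the intended frame regardless of float
round-off.

Conservation property: with all confidences 1 and stride 1, the sum of all
emitted rotation commands plus the final accumulator residual equals the
true net rotation to 1e-6°, because the per-frame deltas telescope.

## Translation compensation

The linear track (default 1.2 m) is divided into `n_segments` (default 8)
half-open bins `[kL/n, (k+1)L/n)`; the far end clamps into the last bin,
and positions up to one pixel outside the track are tolerated (camera
jitter at the walls). The derived segment width is 15 cm. Whenever the
head's segment changes, the stage is commanded to the new segment's centre.
There is no hysteresis by default — oscillation across a boundary commands
one move per crossing — but a configurable hysteresis margin (metres) is
available. A tiny (1e-9·width) bias in the binning keeps positions exactly
on a boundary in the upper segment even when the division rounds just
below an integer.

## Stage simulator

Motors are modelled as constant-speed (defaults 100 °/s rotation,
0.2 m/s translation) with no acceleration ramp, since only speed figures
are physically specified. Commands arriving while a motion is in progress
queue FIFO; rotate-by commands are resolved to absolute targets at enqueue
time so queued rotations sum correctly. Translation targets clamp to
`[0, track_length]` — the limit-switch model. An infinite rotation speed is
accepted for instantaneous-motor idealisations in tests. Cable twist is
logged per frame as the animal's cumulative true heading (recomputed from
the raw stream at stride 1, ungated) minus the simulated commutator angle.

## Tracking evaluation

A prediction matches an annotation when the Euclidean distance is at most
the radius (default 10 px, inclusive). Per annotated frame: confident and
within radius → TP; confident but outside → **both** FP and FN (the
reported point is spurious *and* the annotated point went undetected);
below the confidence threshold → FN only. This dual-count convention is
what lets precision and sensitivity disagree for a single-point tracker —
e.g. 50 frames with one wrong-but-confident and one unconfident frame give
precision 46/47 and sensitivity 46/48 — and is asserted against planted
counts in the tests. When no confident prediction exists precision is
undefined and reported as null. Latency summaries are the arithmetic mean
and sample (N−1) standard deviation.

## Synthetic data

The generator is the package's source of ground truth; every stage is
validated against it.

**Trajectories.** Pirouette mode turns at the uniform rate
`360·n_turns/(n_frames−1)` degrees per frame while stationary at the arena
centre, so the net rotation is exact by construction; tests use 161 frames
for two turns (4.5°/frame), which divides both the 90° and 225° thresholds
evenly. Random-walk mode draws Gaussian heading increments (default SD
30 °/s) and advances at constant speed (default 0.1 m/s), steering
clockwise in 15° increments when a step would leave the arena; the linear
variant shuttles along the track, turning 170° (not 180°) at the ends so
the per-frame change stays strictly below the unwrapping limit. Body
length is fixed at 60 px (two-point rigid model). The degradation operator
plants tracker pathologies: a Bernoulli fraction of frames receives
confidence drawn uniformly below the gate, the rest Gaussian positional
jitter.

**Movies.** Frames alternate blue (calcium-sensitive) and green
(reflectance), default 30 fps interleaved / 15 fps per channel — the
acquisition-rate convention used throughout; both totals are configurable.
Blue frames read `base·(1+ΔF/F_ca)·(1+hemo)+noise`, green frames
`base·(1+hemo)+noise`, so ratiometric correction can remove the shared
haemodynamic term exactly. Calcium is a sum of Gaussian cell footprints
driven by Poisson event trains (0.25 Hz/cell) convolved with an
exponential kernel (τ = 1 s) and passed through a soft saturation
(`amp·tanh(·)`, amp = 0.15 ΔF/F): indicator dyes saturate, and the bound
keeps whole-frame mean excursions at the few-percent level seen in real
wide-field data rather than letting stacked events mimic outlier frames.
The haemodynamic term mixes a 0.4 Hz oscillation with smoothed noise
(fractional amplitude, default 3 %). Rigid integer shifts are applied
circularly per frame with the first frame as the unshifted reference;
outlier frames are replaced by a uniform intensity far above both channel
means. What the generator does **not** emulate: non-rigid deformation,
photobleaching, vessel artifacts, behavioural states, or frame drops — so
green tests demonstrate algorithmic correctness under the stated model, not
robustness to every property of real recordings.

## Calcium preprocessing

The chain runs in a fixed order — segregate → motion-correct → bin → mask →
ΔF/F → band-pass → spatial smooth → z-score — enforced by the pipeline
runner, which rejects out-of-order stage requests.

- **Segregation**: 2-means clustering of per-frame mean intensity. Gross
  outliers have enough leverage to capture a centroid, so clusters holding
  under 20 % of frames (impossible for a genuine illumination channel under
  alternation) are stripped as outlier groups and the fit repeated. Frames
  farther than 5 robust SDs (1.4826·MAD) from their cluster *median* are
  labelled outliers; the blue channel is the brighter cluster by default
  (configurable). Centres closer than twice the pooled within-cluster SD
  raise a separability error.
- **Pairing**: outliers are dropped from both channels; each blue frame is
  paired with the nearest-in-time green frame.
- **Motion correction**: per-frame translation against a template (default:
  mean of the first 10 frames; any frame can be passed instead) via
  skimage's phase cross-correlation; integer shifts are removed with a
  circular roll, sub-pixel (upsampled) registration with first-order
  interpolation. Reported shifts are the frame's displacement relative to
  the template, convertible to µm via the pixel pitch. All-zero frames get
  shift 0 with a warning.
- **Binning**: resampling to 80 % size uses exact area-overlap matrices
  (each output pixel is the area-weighted mean of the input it covers), so
  the frame mean is preserved to machine precision — comfortably within the
  0.5 % contract of a bilinear binning step.
- **Masking**: per-trial boolean cortex masks are averaged; a pixel
  survives when its vote fraction ≥ 0.5 (1.0 gives the intersection). An
  Otsu-threshold fallback can draw a mask from a mean frame when none is
  supplied.
- **ΔF/F and haemodynamic correction**: F₀ is the per-pixel trial mean
  (a rolling-percentile alternative is available). The corrected signal is
  ratiometric, `(1+ΔF/F_blue)/(1+ΔF/F_green) − 1`, which cancels a shared
  multiplicative fluctuation exactly; a per-pixel regression alternative
  (`ΔF/F_blue − β·ΔF/F_green`) sits behind a config switch. Non-positive
  baselines inside the mask are an error.
- **Band-pass**: Chebyshev type-I, 0.1–5 Hz, applied forward–backward
  (`sosfiltfilt`) so the phase response is identically zero and the
  amplitude response is |H|². Order 3 with 0.5 dB ripple keeps the
  zero-phase gain at 1 Hz (15 fps data) at 0.999 while rejecting DC
  completely; a second-order design would already dip to 0.89 at mid-band
  after the forward–backward pass, which is why the default is 3.
- **Spatial smoothing**: the "7-pixel nearest-neighbour average" is read as
  a 7×7 window mean restricted to the mask (each in-mask pixel averages
  the in-mask subset of its window, implemented as a ratio of uniform
  filters); out-of-mask pixels stay zero.
- **Z-scoring**: per-pixel over time with the population (N-denominator)
  SD. Pixels whose SD is zero up to round-off (relative tolerance 1e-12)
  are flagged and set to zero.

## Peri-event bootstrap statistics

ROI traces are means of the z-scored ΔF/F over named masks. The PETH
aligns windows (default 2 s pre, 10 s post — long enough to cover a 720°
compensation at ~100 °/s) at epoch onsets and averages across events;
events whose window spills past the trial edges are dropped with a warning.

The null distribution draws `n_boot` (default 1000) groups of windows
uniformly at random with replacement from the whole trial — including the
event epochs, matching the whole-trial formulation; an exclude-events
variant is available. Each group contains as many windows as there are real
events, so the surrogate PETHs carry the correct 1/√N_events variance
(verified against the CLT on white noise). Significance per timepoint uses
the empirical two-sided tail probability
`(1 + #{|surrogate − null mean| ≥ |observed − null mean|})/(n_boot + 1)`
against `alpha/m`, with `m` defaulting to the number of tested timepoints
(use ROIs × timepoints when analysing several ROIs as one family); an
SD-threshold normal approximation is available as a variant. With 1000
bootstraps the smallest attainable p is 1/1001, so `alpha/m` below that is
unattainable by construction — choose the window and family accordingly.
Under the no-effect regime the family-wise false-positive rate over 200
replicates stays within two binomial standard errors of alpha.

## Problem sizes and determinism

Tests and the acceptance script run on deliberately small instances chosen
to exercise every code path with comfortable statistical margins: 161-frame
pirouettes, 30–40 s random walks, 200–600-frame movies at 16–64 px,
10-movie correction sweeps, 200-replicate bootstrap calibrations. All
randomness flows from explicit integer seeds through
`numpy.random.default_rng`; no global state is used, and the CLI demo
bundles (HDF5 written without timestamp tracking) are byte-identical across
reruns with the same seed.

## Known limitations

- The controller cannot distinguish a true >180° rotation between accepted
  estimates from its complement; long occlusions during fast turning will
  alias. The stride/gate defaults assume the 6–10 fps overhead-camera
  regime.
- The stage model omits acceleration ramps, backlash and radio latency; it
  bounds what the control law can achieve, not what any physical rig does.
- The motion model is rigid translation with circular boundary handling;
  rotations or non-rigid tissue motion are out of scope.
- Evaluation assumes one prediction per annotated frame (single-animal,
  two-keypoint); there is no identity matching.
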