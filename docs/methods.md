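# Methods

This note documents the models, defaults and numerical choices behind
`gaitcom`, and what the synthetic validation does and does not establish.

## The comparison being implemented

Three acceleration streams are compared over the gait cycle:

- **CoM** — whole-body centre of mass from a 13-link segmental model of
  optical marker data, twice differentiated;
- **ML5** — the single marker mounted on the lumbar sensor, processed
  identically to the CoM positions;
- **IMU** — the tri-axial accelerometer at L5, gravity-corrected.

Agreement is quantified by pooled Pearson correlation and Bland–Altman
limits of agreement in physical units (m/s²), and by a pointwise
repeated-measures ANOVA on amplitude-normalized curves with random-field
-theory (RFT) inference. The coordinate convention throughout is
x = anteroposterior (AP, walkway axis), y = mediolateral (ML),
z = vertical/superior–inferior (SI).

## Segmental CoM model

The whole-body CoM is `x₀ = Σ mᵢxᵢ/M` over 13 segments. Mass fractions and
segment-CoM position ratios are Dempster's cadaver values as tabulated by
Winter (`src/gaitcom/data/body_model_dempster.yaml`): head+neck 0.081,
trunk 0.355, pelvis 0.142, upper arm 0.028, forearm+hand 0.022 (CoM ratio
0.682), thigh 0.100 (0.433), shank 0.0465 (0.433), foot 0.0145. Winter's
combined trunk value (0.497) is split thorax+abdomen / pelvis so the 13
fractions sum to exactly 1 (validated to 1e−6). Segment endpoints are
centroids of one or more markers (e.g. the trunk runs from the shoulder
midpoint to the ASIS midpoint); the mapping is declared in the YAML table,
not hard-coded, and is deliberately the minimal ~22-marker endpoint set the
model needs rather than a full clinical marker protocol. No joint-centre
regression is applied — endpoints are marker centroids, a documented
simplification that keeps the weighted-sum structure exact.

## Signal conditioning

- **Markers**: zero-lag low-pass Butterworth, 12 Hz cutoff, 4th-order
  *effective*: realised as a 2nd-order design run forward–backward
  (`scipy.signal.sosfiltfilt`), the conventional biomechanics reading of
  "4th-order zero-lag". `FilterSpec(order_convention="design")` switches to
  the literal alternative (the stated order applied forward–backward).
- **IMU**: same scheme at 2nd-order effective, 12 Hz.
- Edge handling is reflective padding of three characteristic lengths
  (`filtfilt`'s default); first and last gait cycles are additionally
  discarded (see cycles) so filter transients never reach the statistics.
- **Differentiation**: central differences at interior samples
  ((xₜ₊₁−xₜ₋₁)/2Δt, (xₜ₊₁−2xₜ+xₜ₋₁)/Δt²), second-order one-sided stencils
  at the ends, so output length equals input length. Central second
  differences are exact on quadratics; the truncation error on a band-
  limited signal is O(Δt²)·f⁗.
- **Gravity**: 9.81 m/s² subtracted from the vertical channel, exactly as
  specified; no latitude correction.
- Filtering is applied at position level *before* the CoM summation and
  differentiation (filter → sum → differentiate); since all three
  operations are linear the order only matters at the trimmed edges.

## Event detection

- **Camera**: with a vertical GRF series, heel strike is the first sample
  of each rise through 20 N (a standard laboratory threshold). Without
  force data (the synthetic default) it falls back to local minima of the
  heel-marker height, separated by at least half the dominant stride
  period, with parabolic sub-sample refinement.
- **IMU**: the wavelet method for lumbar accelerometry — detrend the
  vertical acceleration, integrate it, then differentiate by a Gaussian-
  derivative CWT (PyWavelets `gaus1`) at a scale of one tenth of the
  stride period (config-overridable); initial contacts are the minima of
  the transformed signal. The detector fires once per *step* (both feet);
  the pipeline keeps the events paired to the tracked foot's camera heel
  strikes.
- The dominant stride period comes from the signal spectrum; a spectral
  peak whose half-frequency lies in the 0.5–2 Hz stride band is folded
  down (trunk vertical acceleration peaks at step frequency). Input with
  no peak attributable to that band raises a detection error.
- **Synchronization**: the constant clock offset between systems is the
  median nearest-neighbour time difference; events are then paired greedy-
  nearest within a 0.1 s window, and unpaired events are reported, never
  dropped. Any residual systematic offset between the two detectors is
  removed with the clock offset — a documented choice; the comparison is
  therefore insensitive to a constant detector bias.

## Cycles and normalization

A cycle spans consecutive same-foot heel strikes (the right foot by
default). The first and last cycle of each trial are discarded whenever at
least three cycles exist, else nothing is trimmed and a warning is raised.
Each cycle is resampled to 101 nodes (0, 1, …, 100 % of the cycle) with a
cubic spline — standard in gait analysis, and exact on linear segments;
node 0 and node 100 are interpolated at the event instants themselves.
The per-subject condition curve is the ensemble average over that
subject's interior cycles. Amplitude normalization (for SPM only) divides
each subject × condition × direction curve by its largest absolute
excursion, mapping the dominant peak to ±1; agreement statistics use the
un-normalized curves in m/s², where biases are physically interpretable.
One curve per subject per condition enters the statistics, so a full
16-subject cohort pools 16 × 101 × 3 = 4848 paired points per condition
pair.

## Agreement statistics

Pearson r with a two-sided p from the t transform (n−2 dof), and
Bland–Altman bias, SD of paired differences (n−1 denominator) and limits
bias ± 1.96 SD. All three directions are pooled into one analysis (the
4848-point design), with per-direction breakdowns also emitted. Points
within a subject are correlated, so the simple pooled limits understate
within-subject agreement variability; no repeated-measures correction is
applied in the headline numbers, matching the pooled design being
reproduced.

## 1-D SPM

Per direction, the subject × condition × node array feeds a pointwise
one-way repeated-measures ANOVA: F = MS_condition/MS_residual with
dof (k−1, (k−1)(n−1)) = (2, 30) for 3 conditions and 16 subjects.
Sphericity is assumed (no Greenhouse–Geisser correction). Residual
smoothness is estimated from the normalized interaction residuals:
FWHM = sqrt(4 ln 2 / mean squared gradient); resels = 100/FWHM. The
critical threshold solves E[EC](u) = α where the expected Euler
characteristic is the point exceedance probability plus resels times the
Worsley 1-D EC density of the t or F field (solved by Brent's method to
1e−8). As resels → 0 this reduces to the ordinary F quantile, and the
threshold grows monotonically with resels. Suprathreshold clusters are
maximal runs of nodes above the threshold, reported in % gait cycle;
cluster p-values use the expected-cluster approximation for 1-D fields
(exponential-squared extent model) and are approximate — the headline
inference is threshold exceedance. Post-hoc paired-t fields are two-tailed
at α = 0.05/3 ≈ 0.017 (Bonferroni over three pairs). A condition-label /
sign-flip permutation oracle within subjects provides a nonparametric
threshold for validation; on smooth nulls the two agree within ~5 %.

Degenerate inputs are handled explicitly: identical conditions give F = 0
(no clusters); a condition offset with zero residual variance flags the
field as degenerate; constant residuals flag infinite smoothness (resels
0). RFT for a t field with ≤ 1 denominator dof is ill-posed (the EC
density does not decay), so SPM requires at least 3 subjects; the pipeline
skips SPM with a warning below that.

## Synthetic gait generator

The generator is the package's study-condition bed, emulating a cohort of
16 healthy adults, five-ish strides of steady walking per trial (12 by
default), optical capture at 240 Hz and a lumbar sensor at 128 Hz. Every
segment endpoint follows a closed form: constant offset + walking-speed
progression + a handful of sinusoidal harmonics of the stride frequency.
AP and vertical oscillations ride at twice the stride frequency (one per
step; vertical excursion ~0.04 m peak-to-peak), ML sway at the stride
frequency (~0.04 m); left-side markers are right-side trajectories shifted
by half a stride; arms swing in antiphase with the ipsilateral leg. The
whole-body CoM, the heel-strike instants (analytic minima of the tracked
heel height, one per stride at 15 % of the cycle) and the pelvis-segment
CoM acceleration are therefore all available in closed form. The virtual
IMU reports that pelvis acceleration in a sensor frame yawed 2° about the
vertical (placement error), with gravity added to the vertical channel,
plus white noise (0.1 m/s² default); markers receive 1 mm white noise.
The pelvis vertical-acceleration minima are constructed to coincide with
the heel strikes, as in real gait, which is what makes the IMU event
detector verifiable against the ground truth.

Between-subject variability: stride duration is drawn per subject from a
normal (1.1 ± 0.08 s, truncated at 3 SD) and each harmonic's amplitude and
phase are independently jittered (12 % relative SD; 0.25 rad SD, with the
phases that define event timing locked). Amplitude jitter alone would
cancel under amplitude normalization; the independent per-harmonic jitter
is what produces genuine between-subject waveform variability for the
SPM residuals.

What the generator does **not** model: soft-tissue artefact, marker
dropout, segment rotation (endpoints translate, so the sensor offset does
not alter acceleration), ground-reaction forces, turning, or asymmetric
gait. Passing tests therefore demonstrate correctness of the pipeline's
mathematics and its statistical calibration — not robustness to every
artefact of real laboratory data. Two special modes support closure
testing: `rigid_body=True` locks all markers to one rigid motion, and
`imu_mode="from_com"` builds the IMU channel by finite-differencing the
pelvis CoM positions, making the sensor stream numerically identical to
the camera stream; the end-to-end closure test (r > 0.999, |bias| <
1e−6 m/s², zero clusters) runs in this configuration.

## Problem sizes used in validation

Deliberately desk-scale: type-I calibration uses 1000 null simulations of
a 16 × 3 × 101 design with FWHM-10 residuals (family-wise error within
[0.03, 0.07] at α = 0.05); the RFT threshold is checked against a
1000-permutation oracle (within 10 %); Pearson calibration uses 500
replicates of 4848 bivariate-normal points at ρ = 0.58; event-detection
robustness uses 100 noisy replicates at 0.5 m/s² sensor noise (≥ 95 %
of events within 30 ms). The whole suite runs in well under a minute on
one core.

## Known limitations

- The marker→segment endpoint mapping is a documented stand-in, not a
  reconstruction of any specific clinical protocol.
- Cluster-level p-values are approximate (expected-cluster formulation);
  use the permutation oracle when exact cluster inference matters.
- Bland–Altman limits ignore within-subject correlation of pooled points.
- C3D input is not supported; marker data are exchanged as tidy CSV.
- The IMU axis misalignment is modelled as a yaw about the vertical only,
  so gravity correction stays exact; tilt misalignment (which would leak
  gravity into the horizontal channels) is not simulated.
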