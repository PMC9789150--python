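# Methods

## The model

Each voxel's visual response is modeled in two multiplicative stages.

**Retinotopic stage (pRF).** The population receptive field is an
unnormalized isotropic 2D Gaussian over retinotopic coordinates,

    pRF(x, y) = exp(-((x - x0)^2 + (y - y0)^2) / (2 sigma_r^2)),

multiplied elementwise with a gaze-centered contrast movie S(x, y, t),
summed over space, and passed through a compressive spatial-summation
exponent n in (0, 1]:

    r(t) = [ sum_{x,y} pRF(x, y) S(x, y, t) ]^n.

The effective pRF size is sigma_r / sqrt(n): compression widens the region
over which stimulus energy is integrated.  pRF weights are not
area-normalized (peak = 1); any normalization would be absorbed by the OLS
scaling used in fitting.

**Eye-position stage (pEGF).** A second 2D Gaussian over *screen* gaze
positions modulates the response multiplicatively,

    pEGF(xe, ye) = a exp(-((xe - xe0)^2 + (ye - ye0)^2) / (2 sigma_e^2)) + (1 - a),

so the gain is 1 when the eyes are at the field's center and falls to 1 - a
far from it.  The gain trace g(t) = pEGF(eye(t)) is applied after the
compressive exponent: r(t) <- r(t) g(t).

**Hemodynamics.** r(t) is convolved causally (zero-padded past) with a
difference-of-gammas HRF,

    h(t) = (t/d1)^n1 exp(-(t-d1)/t1) - a2 (t/d2)^n2 exp(-(t-d2)/t2),
    d_i = n_i t_i,

with n1 = 6.0, t1 = 0.9 s, n2 = 12.0, t2 = 0.9 s, a2 = 0.35, kernel length
32 s, peak-normalized to 1 (dense evaluation puts the peak at 5.24 s; the
undershoot pulls it slightly before d1 = 5.4 s).  This is the canonical
two-gamma parameterization whose shape-parameter names match the values
above.  Predictions are brought to TR rate (TR = 2 s) by averaging the
frames inside each TR window; averaging (rather than decimation) conserves
signal energy, and because data and predictions use the same convention the
relative timing of all TR-rate series is unaffected.

## Stimulus rendering

The renderer produces a retinotopic contrast movie: every frame is the
screen content re-centered on the modeled gaze, which follows the fixation
target with a fixed latency of 1 frame (166 ms at 6 Hz).  Bars and the
fixation target are drawn at contrast 1.  Peripheral scene elements (screen
edge, coil-mirror, eye tracker, bore — a stylized default layout, since
only geometry, not photometry, enters the model) are drawn at contrast
`c_post` for `d_post_frames` frames after each gaze shift and `c_fix`
otherwise; the defaults (0, 1, 3 frames = 500 ms) are the configuration the
representation sweep selects on synthetic data.  Default raster: 6.7
pixels/deg at 6 Hz over a 40 x 22 deg field (268 x 147 px by rounding
fov x ppd; dimensions are computed, not hard-coded); the moving-bar
stimulus is rendered at 12 pixels/deg.  Scene-element masks are zeroed
inside the screen rectangle so the bar and periphery layers have disjoint
support; the movie for any contrast configuration is then exactly
`clip(bars + c(t) * periphery, 0, 1)`, which the configuration sweep
exploits to re-score 59 configurations without re-rendering.

Movies are stored deduplicated (distinct frames plus a per-frame index):
task movies repeat identical content for many consecutive frames, and all
spatial products downstream only need the distinct frames.  A full-size
eye-task run has ~2150 frames but only ~300 distinct ones.

Coordinates: degrees of visual angle, origin at screen center, +x
rightward, +y upward, raster row 0 at the top of the visual field — one
convention for every module.

## Task designs

*Moving bar*: 8 sweep directions x 20 steps of 1.6 s, bar width 1.75 deg,
a 12-s baseline after each sweep (8 total), central fixation throughout.
The literal sum of these parts is 352 s; the run length is therefore a
config value rather than a derived constant.

*Eye-movement tasks A/B*: the target makes 13 sweeps of 8 steps
(saccade amplitudes uniform in [1.28, 1.40] deg, durations 1.5 or 5/3 s —
exactly 9 or 10 frames at 6 Hz), alternating left/right, with a vertical
random walk (per-step drift uniform in ±0.6 deg, clipped to ±3.15 deg).
Nine baselines (first, last, and seven after randomly chosen sweeps) are
drawn uniform in [20, 25] s and rescaled so the run is exactly 358 s = 179
TRs.  Seven bar-presentation instances are placed at fixed quantiles of the
run with version-specific shuffled patterns (horizontal/vertical center
bars and diagonal corner bars).  Version B is resampled (up to 1000
attempts) until both components of its TR-rate target trace correlate with
version A's at |r| < 0.15.

## Fitting

Both stages use exhaustive grid search.  Defaults: pRF grid 12 x_r0 x 9
y_r0 x 10 sigma_r (log-spaced 0.25–8 deg) x 5 n = 5400 members; pEGF grid
12 x_e0 (±9 deg) x 9 y_e0 (±5 deg) x 6 sigma_e (log-spaced 1–16 deg) x 6 a
= 3888 members, restricted per voxel to sigma_e > sigma_r (an option
switches the rule to the effective pRF size sigma_r / sqrt(n)).  Every
candidate prediction is scaled to the data by OLS (slope + intercept), so
selection maximizes the squared Pearson correlation; ties go to the first
member in C enumeration order (first axis slowest).  Model comparison uses
adjusted R^2 = 1 - (1 - R^2)(n - 1)/(n - k - 1) with k = 4 (pRF-only) and
k = 8 (pRF x pEGF); the k values are conventions, recorded in the fit
tables.

The pEGF engine exploits two structures: the gain trace is piecewise
constant over the run's ~110 distinct eye positions, and
convolution + TR-averaging is linear.  For a fixed pRF the map from gain
vector to TR-rate prediction factors through a small per-voxel matrix, so
predictions for all 3888 members are one matrix product — refitting many
noise renditions of the same population costs seconds.

Voxel inclusion for reconstruction: pRF x pEGF beats pRF-only in adjusted
R^2 on task A, and the pRF-only model explains > 10% variance on both task
versions.  The control rule (non-visual region) keeps voxels where both
models stay below 10%.

## Eye-position reconstruction

Per voxel, data and pRF-only prediction (task B) are min–max bounded to
[0, 1] over the run, the prediction is OLS-scaled to the data, and the gain
estimate is their ratio.  Numerator and denominator are floored at 1e-3
before division (so stretches where both are near zero yield a gain near 1
rather than 0), the ratio is winsorized at the voxel's 1st/99th
percentiles, and clipped to [0.05, 2.5].  The normalized scaled sum

    f(xe, ye, t) = sum_i ghat_i(t) pEGF_i(xe, ye)
                   / [ gbar(t) sum_i pEGF_i(xe, ye) ]

is evaluated on a uniform readout grid (default 0.25 deg over 40 x 22 deg)
and the decoded position is its global 2D argmax (exact ties resolve to
the tied nodes' centroid, flagged).  The per-axis maxima and the global 2D
argmax coincide at a unique peak; the 2D argmax is the implemented default.
Decoding quality is Pearson correlation per component against the target
trace, assessed over integer lags -10..+10 TRs; the default assessment lag
is 1 TR, overridable.  The OLS step inside gain estimation includes an
intercept; both coefficients are retained.

**Known bias and lag.** The readout has a central-tendency bias: for broad
gain fields the normalized field's peak is pulled toward the population
centroid, so the absolute decoding error saturates (~1.5 deg median on a
±6 deg sweep) even as the population grows; what improves with voxel count
is precision — across-population-draw dispersion shrinks and the trace
correlation rises.  Separately, because the gain is read off the
HRF-convolved signal, the decoded trace lags the target.  Reconstruction
from perfect (convolution-free) gains shows no lag; through the full
pipeline the correlation-vs-lag curve has a flat top over 1–2 TRs whose
maximum, under the default simulation conditions, falls at 2 TRs for the
horizontal component (the correlation margin between lags 1 and 2 is only
a few percent).  Both timing conventions (within-TR averaging vs
decimation) and both canonical HRF parameterizations leave this unchanged.

**Permutation null.** Shuffling the voxel-to-pEGF assignment (gains stay
with their voxels) and re-reconstructing 1000 times builds the null; p per
component is the fraction of null correlations at least as large as the
observed one, and a combined p uses the Fisher-averaged score
(arctanh(r_x) + arctanh(r_y))/2.  The ROI comparison bootstraps a fixed
voxel count per ROI (90% of the smallest eligible ROI, minimum 150,
without replacement, 1000 draws) and reports the Fisher-averaged score per
draw.  The permutation and bootstrap paths use float32 field stacks for
speed; `reconstruct()` itself is float64.

## Synthetic data

`sample_population` draws pRF centers uniform over ±8 x ±5 deg with
sigma_r = 0.35 + 0.15 ecc + |N(0, 0.1)| (sizes grow with eccentricity,
V1-like) and n from the grid axis; pEGF centers uniform over the task's
eye-position extent (±6 x ±3.15 deg), amplitude uniform in (1/6, 1], and
sigma_e log-uniform in [2, 12] deg resampled until wider than the voxel's
pRF.  With `pegf_on_grid` the gain-field parameters are drawn from the
fitting grid's axes, which makes noiseless recovery exact — used for the
recovery checks.

Noise has three components mixed at a 1 : 1 : 0.1 variance ratio and
rescaled analytically so the sum's sample s.d. equals the requested total
(default 0.1, matching signals scaled to [0, 1]): physiological (quadratic
drift plus one slow 0.01–0.03 Hz and one respiratory-band 0.25–0.30 Hz
sinusoid, random phases), system (white Gaussian), and task noise (white
Gaussian multiplied by the voxel's normalized retinotopic response).  The
components are defined explicitly rather than drawn from an external noise
package; they reproduce the stated structure, not any package's internals.
"Total amplitude 0.1" is read as total s.d. 0.1, consistent with the
explicit "s.d." phrasing of the parameter-distribution study.

**Study 1 (leftover retinotopic input).** Four scenarios cross gain-field
existence with peripheral stimulation in the simulated world and in the
model's retinotopic representation.  Per rendition: simulate both tasks,
fit pEGFs on task A with the scenario's (possibly mismatched)
representation and the true pRFs frozen, estimate gains on task B,
reconstruct, and record the component correlations and best lag.  The
population plays the role of the already-included voxel set, so no
re-selection is applied inside the loop.

**Study 2 (parameter-distribution bias).** Uniform-random gain fields are
assigned (wider than each pRF), task A is forward-simulated, noise added at
s.d. 0.05 / 0.1 / 0.2, and the standard grid search re-estimates the pEGFs.
Voxels are pre-filtered by an expected-R^2 proxy, var(signal) /
(var(signal) + sd^2) >= 0.25 on the [0,1]-scaled clean signal — the
selection analogue of fitting only well-mapped voxels.  The estimated X0
distribution shows the characteristic bias (excess density at the center
and at the grid tails although the truth is uniform and never reaches the
outermost grid values), the median |X0 error| grows with noise, and no
hemifield inversion appears — weakly identified voxels are absorbed into
center/tail attractors symmetrically, not contralaterally.

## Topography

Fitted voxels are filtered to the best half per ROI by pRF x pEGF variance
explained, split by hemifield (sign of x_r0; voxels exactly on the
vertical meridian go right, flagged), and binned by pRF eccentricity
(default 1-deg bins over 0–10 deg).  Per bin the median (and mean) pEGF X0
is tabulated; per hemifield a least-squares line of median X0 on bin-center
eccentricity is fitted with per-bin voxel counts as weights, and its zero
crossing estimates the eccentricity of a contralateral-to-ipsilateral
shift.  "Inversion present" requires both hemifield slopes' bootstrap CIs
(resampling voxels) to exclude zero with opposite signs.  Mixed-effects
modelling of these tables is out of scope; the module exports the tidy
long-format tables such models consume.

## Problem sizes and determinism

The validation suite and the acceptance script run the simulations at 300
voxels x 20 noise renditions (study 1 / lag and permutation checks), 120
on-grid voxels (recovery), and 200 voxels x 3 noise levels (bias
fingerprint); these sizes give stable medians while keeping the full run in
minutes.  Every stochastic stage takes an explicit seed; seeds derived
internally combine the user seed with fixed stream labels, so (seed,
config) determines all outputs byte-identically.

## Limitations

- Noise is temporally structured but spatially independent across voxels;
  shared physiological fluctuations would lower effective decoding SNR.
- The scene layout is stylized; real peripheral geometry differs, though
  only the gross geometry enters the model.
- The vertical trajectory carries much less gain information than the
  horizontal one (small range, low-frequency wander overlapping the drift
  band), so simulated vertical decoding is weak at a few hundred voxels.
- The readout's central-tendency bias and the 1–2 TR reconstruction lag are
  properties of the algorithm, not of the data; analyses evaluated at a
  fixed lag inherit the flat-top ambiguity described above.
- Bar flicker is not rendered temporally: bars are constant contrast-1
  regions while on, since only contrast enters the spatial summation.
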