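# gazefield

Voxel-wise modelling of eye-position gain fields in human visual cortex,
and reconstruction of gaze position over time from BOLD signals alone.

Neurons across visual cortex respond to retinal input, but the amplitude of
that response depends on where the eyes are pointing — an *eye-position
gain field*.  This package implements, for fMRI, a two-stage voxel
encoding model and its inversion:

- **pRF stage** — each voxel integrates a gaze-centered contrast movie
  S(x, y, t) through an isotropic Gaussian population receptive field with
  compressive spatial summation:

      r(t) = [ Σ_{x,y} pRF(x, y) · S(x, y, t) ]ⁿ,
      pRF(x, y) = exp(−((x−x₀)² + (y−y₀)²) / 2σ_r²),  size = σ_r/√n

- **pEGF stage** — an eye-position dependent gain field, a Gaussian over
  screen gaze positions, scales the response multiplicatively:

      g(t) = a·exp(−((x_e−x_e0)² + (y_e−y_e0)²) / 2σ_e²) + (1 − a),
      ŷ(t) = [r(t)·g(t)] ∗ h(t)

  with h(t) the standard difference-of-gammas HRF.  Both stages are fitted
  by exhaustive grid search (5400 pRF / 3888 pEGF combinations by default)
  with OLS scaling and adjusted-R² model comparison.

- **Reconstruction** — dividing each voxel's measured series by its scaled
  pRF-only prediction estimates the gain per volume; summing every voxel's
  gain field weighted by that estimate, normalized by the mean-gain-scaled
  sum, yields a field over gaze positions whose peak is the decoded eye
  position — no eye tracker involved.  Permutation nulls, cross-correlation
  lag analysis, ROI-equalized bootstraps, and the eccentricity/hemifield
  topography of fitted gain-field centers round out the analysis.

Because the method's raw fMRI data are not openly accessible, the package
ships a first-class synthetic generator: task designs (moving-bar mapping;
two decorrelated eye-movement tasks), gaze-centered scene rendering with
post-saccadic contrast dynamics, voxel populations with
eccentricity-scaled pRFs, and a three-component fMRI noise model — enough
to exercise and validate the whole pipeline end to end.

## Worked example

Simulate a 150-voxel population under two scenarios — gain fields present
with an accurate retinotopic model (`t1a`), versus no gain fields with only
leftover retinotopic stimulation (`t1c`) — then fit and decode:

```python
from gazefield.simulation import (SCENARIOS, NoiseConfig,
                                  run_simulation1, sample_population)

pop = sample_population(150, rng_seed=0)
res = run_simulation1(pop, n_reps=3, noise_cfg=NoiseConfig(total_sd=0.1),
                      rng_seed=0,
                      scenarios={"t1a": SCENARIOS["t1a"],
                                 "t1c": SCENARIOS["t1c"]})
print(res.groupby("scenario")[["r_x", "r_y", "best_lag"]].median())
```

```
               r_x       r_y  best_lag
scenario
t1a       0.516211  0.195536       2.0
t1c       0.206605  0.016375       2.0
```

With gain fields present the decoded horizontal eye trace correlates with
the true target trajectory (r_x ≈ 0.5 at this small population size; it
rises with voxel count), while without them decoding collapses toward
chance — the gain fields, not residual retinotopic stimulation, carry the
eye-position signal.  `best_lag` is the cross-correlation lag (in 2-s
volumes) at which reconstruction and truth align best; the decoder
inherits a small positive lag from reading gains off the HRF-convolved
signal.

A command-line interface wraps the pipeline stages
(`gazefield design|render|simulate|fit-prf|fit-pegf|optimize-stim|
reconstruct|permute|topography|config`), reading and writing TSV/JSON and
recording a seed/config manifest per run.

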