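# contextfi

Fisher-information analysis of contextual modulation in visual
orientation coding — the computational chain behind the tilt illusion,
in which an oriented annular surround shifts the perceived orientation
of a central grating.

The package is aimed at visual/computational neuroscientists who want to
(i) read encoding precision out of psychophysical estimation data, (ii)
read it out of (real or simulated) multivoxel activity, (iii) predict
estimation behavior from a measured precision profile, and (iv) control
for the orientation information that stimulus configuration alone
injects. Everything runs on synthetic data generated by the package
itself, so the full chain is reproducible end to end.

## What it computes

**Behavioral Fisher information.** From per-trial pairs (θ, θ̂), a
sliding-window estimate of bias b(θ) and SD σ(θ) (18° window, 0.5°
steps) is converted through the Cramér–Rao bound, assumed tight,

    J(θ) = (1 + b′(θ))² / σ²(θ),

with bootstrap SEM (500 resamples). Profiles are reported as the
normalized square root J̃(θ) = √J/∫√J dθ — under efficient coding
(p(θ) ∝ √J(θ)), the orientation prior implied by the data.

**Neural Fisher information.** A probabilistic voxel population encoding
model p(m|θ) = N(W f(θ), σ²WWᵀ + ρττᵀ + (1−ρ)I∘ττᵀ) with eight
rectified-cosine⁵ orientation channels, fit in two stages (OLS weights,
then ML noise parameters), 20-fold cross-validated with a four-member
phase-shifted basis ensemble. Per held-out trial: maximum-likelihood
orientation decoding and the observed FI j(θ*) = −l″(θ*), averaged in
25° windows; a surround-modulation index compares conditions in the
22.5°–47.5° window with a Welch t test. The model is a scikit-learn
style estimator (`VoxelEncodingModel().fit(X, y)`).

**Efficient-coding Bayesian observer.** Encoding warped by the FI
profile, holistic inference over orientation and orientation categories,
reports minimizing (1−w)·L_feature + w·L_category — predicting bias and
SD curves from a measured FI profile, including the repulsive bias and
local SD increase an added surround category boundary produces.

**Stimulus-vignetting control.** A complex steerable pyramid (6
orientations × 6 scales) turns stimulus images into
orientation-nonselective energy maps; J(θ) = ‖df/dθ‖² over a 1° sweep
quantifies configuration-driven FI, and ΔJ(θ) compares oriented-surround
to noise-surround stimuli.

## Worked example

```python
import numpy as np
from contextfi import behavior, synthetic, encoding

# behavioral route: trials from a known oblique-effect observer
observer = synthetic.oblique_observer()          # bias ±4°, SD 3.5±0.8°
trials = synthetic.gen_behavioral_trials(observer, 50_000, seed=7)
fi = behavior.behavioral_fi(trials)              # normalized sqrt-FI
truth = observer.fi(fi.grid)
print(f"max relative FI error: {np.nanmax(np.abs(fi.fi - truth)/truth):.3f}")
print(f"total resource (integral sqrt J): {fi.total_resource:.2f}")

# neural route: fit the encoding model to its own samples
params = synthetic.random_encoding_params(30, seed=1, rho=0.1)
theta = np.random.default_rng(2).uniform(0, 180, 5000)
voxels = synthetic.gen_voxel_dataset(params, theta, seed=3)
model = encoding.VoxelEncodingModel().fit(voxels.responses, voxels.theta)
print(f"recovered rho: {model.rho_:.3f}  channel sd: {model.channel_sd_:.3f}")
```

prints

```
max relative FI error: 0.065
total resource (integral sqrt J): 51.11
recovered rho: 0.098  channel sd: 0.299
```

The behavioral route recovers the generating Fisher information within
6.5% everywhere (the window analysis slightly attenuates the bias
derivative), and the two-stage fit recovers the generative noise
parameters (true ρ = 0.1, σ = 0.3) almost exactly.

The command-line interface exposes each stage
(`context-fi simulate | behavioral-fi | voxel-fi | observer | vignette |
run | report`); `context-fi run --seed 0 --out runs/demo` executes the
baseline and tilt-illusion pipelines and writes CSV profiles plus JSON
reports.

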