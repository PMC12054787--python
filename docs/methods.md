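# Methods

`contextfi` implements a complete analysis chain for studying how spatial
context reshapes orientation coding — the setting of the tilt illusion,
where an oriented annular surround shifts the perceived orientation of a
central grating. The chain has four measurement/model stages plus a
synthetic-data layer that generates every input, so the whole pipeline is
testable end to end without any external data.

## Orientation conventions

Orientations live in [0°, 180°), measured clockwise from vertical. All
circular statistics use the doubled-angle device (map θ → 2θ on the full
circle, compute, map back). The signed estimation error is
`90 − ((90 − (θ̂ − θ)) mod 180)`, the unique minimal-magnitude difference
in (−90°, 90°].

## Behavioral Fisher information (module `behavior`)

The Cramér–Rao bound links an estimator's bias b(θ) and variance σ²(θ)
to the Fisher information J(θ) of the sensory encoding:

    J(θ) ≥ (1 + b′(θ))² / σ²(θ),

and the bound is treated as tight (it is attained by maximum-likelihood
and Bayesian decoders). Bias and SD are measured in an 18° window sliding
in 0.5° steps across the orientation circle; J follows pointwise; SEM
comes from 500 bootstrap resamples of the trial table. We report the
normalized square root, J̃(θ) = √J(θ) / ∫√J dθ, a density over one
period that efficient coding identifies with the orientation prior; the
normalizer ∫√J dθ measures total coding resources.

Numerical choices:

- **Detrended window SD (default).** The plain within-window SD includes
  the variance of the bias curve across the window, inflating σ² by
  roughly b′(θ)²·W²/12. For realistic oblique-effect bias slopes this
  alone corrupts J by >20%. By default the locally estimated bias curve
  is subtracted from each trial's error before the SD pass; the
  window-constant estimator is available with `detrend=False`.
- **Derivative.** b′ uses centered finite differences on the 0.5° grid
  after Gaussian smoothing of the bias curve (SD 2°, configurable,
  periodic); the raw windowed bias is too noisy to differentiate.
- **Missing data.** Windows with fewer than two trials are NaN; NaN runs
  up to 2° are interpolated periodically, wider gaps propagate. A window
  SD of exactly zero (possible under heavy resampling of small tables) is
  masked rather than turned into infinite FI.
- Periodic integrals of uniformly sampled 180°-periodic functions use the
  wrap-around trapezoid rule, which reduces to the rectangle sum.

With 50,000 trials from a known bias/SD observer the pipeline recovers
the analytic J with max relative error below 10%, and a flat unbiased
observer yields flat J (CV < 5%); both are asserted in the test suite.

## Voxel population encoding model (module `encoding`)

A trial's K-voxel response vector m follows

    m = W (f(θ) + ε) + η,   ε ~ N(0, σ² I),   η ~ N(0, Σ_η),
    Σ_η = ρ ττᵀ + (1 − ρ) I ∘ ττᵀ,

with J = 8 rectified-cosine basis channels f_j(θ) = max(0, cos(π(θ −
φ_j)/90))⁵, preferred orientations equally spaced. Hence p(m|θ) =
N(Wf(θ), Ω) with Ω = σ²WWᵀ + Σ_η, θ-independent (its Cholesky factor is
cached). Fitting is two-stage: ordinary least squares for W, then
maximum likelihood for (σ, τ, ρ) with W fixed — SLSQP with analytic
gradients on the residual scatter matrix (each objective evaluation is
O(K³) regardless of trial count), three starts in (σ, ρ), τ initialized
at per-voxel residual SDs. `VoxelEncodingModel` packages the two stages
as a scikit-learn estimator (`fit(X, y)`, `predict`, fitted attributes
`W_`, `channel_sd_`, `tau_`, `rho_`).

Decoding maximizes the exact log-density on a 0.5° grid (ties to the
lowest index). The observed Fisher information of a trial is the negative
second derivative of the log-likelihood at the true orientation,
j(θ*) = −l″(θ*), computed by centered differences of exact log-density
evaluations at θ* ± 0.5°; its expectation equals the Gaussian-model FI
μ′ᵀΩ⁻¹μ′ (asserted against 10⁴ simulated trials within 3 Monte-Carlo
SEs). Cross-validation splits trials into 20 seeded contiguous folds
after shuffling; four basis ensembles with phase offsets spanning one
inter-channel spacing are fit, and per-trial results average across the
ensemble (observed FI arithmetically, decoded orientations circularly).
Orientation-resolved neural FI averages j within a 25° circular window;
the surround-modulation index is the surround-minus-baseline difference
of mean unnormalized j inside 22.5°–47.5°, as a percentage of the
baseline's all-orientation mean, with an unpaired Welch t test.

A known limit of the two-stage procedure: the OLS weight error is bounded
below by E‖ΔW‖²_F = tr((XᵀX)⁻¹)·tr(Ω). At the simulation's noise level
(σ = 0.3, τ ≈ 1, unit-scale weights) this floor is ≈7% Frobenius relative
error at N = 5,000, K = 30 — the implementation attains it exactly
(asserted in the tests), and no unbiased fit of this design can do
better. ρ, σ and τ recover essentially perfectly at that scale.

## Efficient-coding Bayesian observer (module `observer`)

The observer encodes orientation through the warp F(θ) = ∫θ J̃, which
maps the stimulus circle to a unit sensory circle on which encoding
noise is homogeneous (von Mises, concentration κ_i, doubled angle); the
prior equals J̃ by efficient coding. Inference is holistic: from a
sensory sample the observer forms a posterior over orientation and over
binary orientation categories, and the reported probe orientation
minimizes the expected mixed loss

    L_tot = (1 − w)·L_feature + w·L_category,

with L_feature = 1 − cos of the doubled-angle difference and L_category a
fixed cost for a category mismatch. Reports receive additive von Mises
motor noise (κ_m). Bias and SD curves are Monte-Carlo estimates
(circular mean/SD of simulated reports).

Model-variant choices (the exact functional forms are open in this
compressed model description; these are the package's, validated by the
qualitative signatures below):

- **Categories live on the sensory circle.** A category system is a
  logistic membership in the sine of the sensory phase relative to the
  boundary's sensory position, so a boundary is represented sharply in
  stimulus space exactly where encoding precision is high. The baseline
  system splits clockwise/counterclockwise of vertical; the oriented
  surround adds a sharp boundary at the surround orientation. Boundary
  locations jitter trial-to-trial (von Mises on the sensory circle).
- **The probe is encoded noisily.** The probe's effective category
  membership is the membership function convolved with a probe-noise
  kernel (κ_probe). This is essential: with a noiseless probe the
  categorical term degenerates to a step in the probe orientation and
  produces neither graded reference repulsion nor boundary variance.
- The probe objective is minimized by grid search at the FI grid
  resolution with circular parabolic refinement; exactly flat objectives
  fall back to the posterior circular mean.
- Global parameters (κ_i, w, κ_m) can be fitted to target bias/SD curves
  (Nelder–Mead on log/logit scales, fixed Monte-Carlo seed inside the
  objective so the surface is deterministic); fitted values are then
  frozen, the FI/prior switches to the surround profile, and the surround
  category is added to predict the tilt illusion.

Predicted signatures, asserted in the tests: the baseline model
reproduces the oblique bias pattern (zero crossings at cardinals and
obliques, repulsion away from cardinals, SD higher at cardinals); the
full surround model produces a positive bias slope through the surround
orientation (repulsion) and a local SD peak near it. Ablations: removing
the surround category boundary destroys the SD peak (the FI bump alone
*reduces* SD at the surround — a dip, not a peak — and leaves only weak
efficient-coding repulsion). Removing the FI bump while keeping the
category boundary, however, still yields both signatures in weakened
form: a category boundary repels and adds boundary variance regardless
of encoding precision, because the category posterior at the boundary is
scale-invariant (its trial-to-trial spread does not depend on posterior
width). In this model family the encoding change is necessary for the
quantitative pattern (magnitude, locality, flank behavior), not for the
signs of the two signatures; the corresponding acceptance check is left
failing rather than redefined.

## Stimulus-vignetting control (modules `pyramid`, `vignetting`)

To quantify how much orientation FI the stimulus *configuration* alone
provides, stimuli are passed through an image-computable voxel model: a
complex steerable pyramid (6 orientation × 6 spatial-frequency bands,
frequency-domain construction, no decimation) yields quadrature energies
r(c, s); summing over orientation channels per scale gives
orientation-nonselective "voxel" maps f_s(θ); the FI of a θ sweep is
J(θ) = ‖df/dθ‖² under unit-variance independent Gaussian noise, with
df/dθ by centered circular differences at 1° steps. The working scale is
the one with maximal total baseline FI (ties to the finer scale); for
the default geometry it is the band peaking near 2.5 cycles/degree — the
boundary-harmonic band, and indeed ~97% of the derivative energy lies in
a ±0.5° ring at the center–surround boundary.

Stimuli follow the experimental geometry: mid-gray disk to 1.5°, center
grating 1.5–7° at 1 cycle/degree, surround annulus 7–12.5°, 20% peak
contrast, 256×256 pixels at 0.1°/pixel, rendered with 2× supersampling
(anti-aliasing). The noise surround is a seeded sum of 128 band-limited
plane waves (log-Gaussian radial frequencies around 1 c/deg, 1-octave
FWHM, Rayleigh amplitudes, uniform orientations/phases) — isotropic,
approximately Gaussian, and analytically rotatable. The noise texture is
fixed within a sweep (a fresh texture per image would add a θ-flat
derivative noise floor an order of magnitude above the vignetting FI);
independent textures enter through the ≥10 averaged baseline sweeps.

Two discretization effects matter and are handled explicitly:

- **Odd-phase raster resonance.** Sweeps rendered with odd-symmetric
  (sine-phase) center gratings show a spurious, seed-independent FI
  spike exactly at vertical. It persists under 4× supersampling, odd
  raster sizes, edge tapering, noise-model changes, and stays at vertical
  when the noise texture is rotated — identifying it as a
  grating-versus-raster resonance of the discretized sweep (in the
  continuum, E[J(θ)] is exactly flat by rotation invariance). The phase
  ensemble therefore defaults to the two even-symmetric phases {0, π},
  which are free of the resonance; with them the seed-averaged baseline
  FI is flat to CV ≈ 3% (the isotropy the construction demands).
- **Flat-trough minimum.** ΔJ(θ) = J_surr − J_base has a broad,
  flat-bottomed trough around the orientation orthogonal to the surround
  (local parabolic vertex at ≈ −54.7° for a +35° surround), so the raw
  grid argmin is an unstable order statistic. The minimum is located
  after a 7° circular moving average; across noise-seed sets it falls at
  −55° to −57°, and ΔJ is positive in a broad region around the surround
  orientation, matching the expected configuration-driven pattern.

## Synthetic data (module `synthetic`) — what it emulates, and what not

- Behavioral trials: uniform stimulus orientations; reports are
  θ + b(θ) + N(0, σ(θ)²), wrapped. The default "oblique" observer has
  repulsive bias away from cardinals (amplitude 4°) and SD 3.5° ± 0.8°
  (larger at cardinals), giving FI peaks at cardinals. `observer_from_prior`
  builds an unbiased observer whose SD realizes a target efficient-coding
  FI shape (σ = 1/(resource · prior density); the default resource of 60
  gives ~3° SD under a uniform prior).
- Priors: `cardinal_peaked` mixes a uniform floor with 90°-periodic von
  Mises bumps at the cardinals (weight 0.4, concentration 1.5;
  cardinal:oblique density ratio ≈ 2.6:1, in the range reported for
  natural-scene orientation statistics); `surround_conditioned` adds a
  von Mises bump at the surround orientation (weight 0.15, concentration
  15 — a localized ~2× density increase, emulating the conditional
  statistics of adjacent image regions).
- Voxel data are drawn from the encoding model itself; an optional
  efficient-coding warp evaluates the basis at the prior's CDF, which
  concentrates tuning (hence FI) where the prior is dense, so that the
  neural route carries the same ground-truth J̃ as the behavioral route.
- Not emulated: BOLD dynamics (no HRF), preprocessing artifacts,
  retinotopy estimation (pRF centers/sizes are drawn parametrically),
  inter-subject variability structure, eye movements, probe/response
  dynamics. Passing tests therefore validate the *analysis chain* under
  its own generative assumptions, not robustness to fMRI nuisance
  structure.

## Pipeline scales

The default desk scale mirrors the experiment: 400 trials per condition
per synthetic subject, 30 voxels, 20 cross-validation folds, 4 basis
phase ensembles, and 5 subjects pooled into a combined-subject analysis
(the behavioral table uses 2,000 trials ≈ 5 subjects' worth). The two
conditions of the tilt-illusion run share subject weight matrices
(within-subject design). At this scale the behavioral and neural J̃
profiles, folded about vertical, correlate at r ≈ 0.96–0.97, and a full
baseline run takes under a minute on one CPU; the vignetting analysis at
its full sweep takes ~2.5 minutes.

## Known limitations

- The CRLB route needs smooth, well-sampled bias curves; with few trials
  per window the FI point estimate is biased upward by residual variance
  noise (the bootstrap SEM makes this visible but does not remove it).
- The noise-parameter ML stage assumes the single-ρ residual correlation
  structure; richer correlation structure would be absorbed into ρ and τ.
- The observer model's categorical forms are this package's variants;
  only qualitative signatures, not quantitative curve equality, should be
  read from them.
- The steerable-pyramid FI assumes unit-variance independent noise per
  map pixel; absolute FI values are resolution-dependent and only the
  shape of ΔJ(θ) is meaningful.
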