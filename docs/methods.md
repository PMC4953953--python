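# Methods

`neuroroi` implements a complete EEG source-imaging and classification
chain: forward model and synthetic head model, two regularized inverse
solutions, data-driven region-of-interest (ROI) extraction, a
45-statistic spectral/time-domain/wavelet feature set, and a
leave-one-out SVM evaluation harness with PCA-based feature relevance.
This note records the models, the parameter choices that matter, and
the design decisions taken where the design was genuinely open.

## Forward model and synthetic head model

The instantaneous linear model is `X = M J + eps`, with `X` the C x T
sensor data, `J` the D x T currents of dipoles fixed at the mesh
vertices and oriented along the outward surface normal, `M` the C x D
lead field, and `eps` zero-mean Gaussian sensor noise.

The synthetic head model replaces an anatomical pipeline while keeping
this algebra intact:

- **Cortex**: a recursively subdivided icosphere (`D = 10*4^n + 2`
  vertices; default n = 3, D = 642, radius 80 mm). Vertex spacing is
  ~13 mm, a coarse but workable stand-in for a downsampled cortical
  surface.
- **Sensors**: C points (default 32) on a Fibonacci lattice covering
  the upper ~75% of a sphere at 1.15x the cortex radius — a cap-like
  montage at EEG scale.
- **Lead field**: the quasi-static potential of a current dipole in an
  infinite homogeneous medium (conductivity 0.33 S/m), common-average
  referenced across sensors (columns sum to zero). No BEM/FEM layers;
  relative geometry, depth attenuation and field spread are preserved,
  absolute amplitudes are not physical.
- **Smoothing kernel**: `Q_G = expm(sigma * G)` where `G = A -
  diag(degree)` is the mesh graph Laplacian. `Q_G` is symmetric
  positive definite and row-stochastic; column d is a bump centred at
  vertex d whose spatial extent grows with `sigma` (default 0.6, which
  spreads appreciable weight over 1–2 edge rings, i.e. a patch a few
  vertices wide).
- **Simulation**: patch sources are columns of `Q_G` (unit maximum)
  times band-limited sinusoids with seeded random frequency and phase;
  sensor noise is white Gaussian calibrated so that total signal power
  over total noise power matches the requested SNR in dB. All
  randomness flows through `numpy.random.default_rng(seed)`, and every
  seeded operation is bit-reproducible.

## Inverse solutions

With Gaussian priors `J ~ N(0, Q_J)` and `eps ~ N(0, Q_eps)`, the
penalized estimate

    J_hat = argmin_J ||X - M J||^2_{Q_eps} + lam * ||J||^2_{Q_J}
          = Q_J M' (lam * Q_eps + M Q_J M')^{-1} X

is computed through the C x C sensor-space system only (Cholesky; a
symmetric-eigendecomposition fallback with a trace-scaled jitter
rescues near-singular systems and reports the condition number on
failure). Unit tests pin this closed form to a brute-force
normal-equations minimizer at 1e-8 on random small instances, which
also exercises the push-through (Woodbury) identity.

**Smoothness prior (LORETA-style)**: `Q_J = Q_G`, `Q_eps = lam * I`.
`lam` is exposed as a flag (default 1.0); no automatic selection rule
(e.g. L-curve) is implemented.

**Multiple Sparse Priors (MSP)**: `Q_J = sum_p w_p q_p q_p'` over a
dictionary of P (default 512) patch vectors — columns of `Q_G` at
centres chosen by farthest-point sampling from vertex 0, so patches
cover the surface approximately uniformly. The weights `w_p =
exp(lambda_p)` and the noise variance `exp(lambda_eps)` are fitted to
the trial's sensor covariance `C_y` by expectation–maximization on the
equivalent factor model `x = A s + eps`, `A = [M q_1 ... M q_P]`,
`s ~ N(0, diag(w))`. The E-step posterior moments reduce to C x C
algebra via the Woodbury identity, so each iteration costs O(C^2 P);
the objective (per-sample Gaussian log-likelihood, the free energy up
to a constant) is returned as a trace and is non-decreasing by the EM
ascent property. Initialization: noise variance from the smallest
eigenvalue of `C_y`; equal patch weights matching the sensor-space
trace.

**Pruning.** EM approaches the `w = 0` boundary only polynomially
(`w_{k+1} ~ w_k (1 - c w_k)`), so irrelevant weights plateau around
1e-3–1e-4 of the dominant weight within the default 128 iterations
rather than vanishing. Components below 1e-3 of the maximum weight are
therefore pruned after convergence; on single-patch simulations at
SNR 10 dB this leaves a handful of components with the generating
patch holding >97% of the surviving weight. A smaller threshold would
demand orders of magnitude more iterations for no practical change in
the solution.

## ROI selection

The source energy map is `e_bar[d] = mean_t J_hat[d, t]^2`. Selection
is greedy: dipoles below `threshold_frac` (default 10%) of the maximum
energy are ineligible as peaks; repeatedly, the highest-energy
unlabeled eligible dipole seeds the next ROI and all unlabeled dipoles
within geodesic distance `rho` receive its label; the loop ends when
every eligible dipole is labeled. Ties resolve to the lowest dipole
index. Distances are graph geodesics (Dijkstra with Euclidean edge
weights) so ROIs cannot jump across the volume.

Open choices, both implemented:

- Sub-threshold dipoles inside a selected radius are absorbed into the
  ROI by default (compact, spatially solid ROIs); `strict_threshold`
  leaves them unlabeled.
- `rho` defaults to 20 mm (~1.5 edge rings of the default mesh), large
  enough to cover a patch of the default smoothness, small enough to
  keep nearby patches in separate ROIs.

ROI time courses are plain arithmetic means of member dipole rows.

**ROI scope across trials.** A per-trial labeling gives feature columns
no stable meaning across trials (ROI 1 of trial 1 and ROI 1 of trial 2
may sit on different patches). The pipeline therefore defaults to
*subject scope*: one labeling computed from the trial-averaged energy
map and applied to every trial, keeping each feature column tied to a
fixed cortical neighbourhood. Per-trial scope remains available
(`roi_scope="trial"`), with kept ROIs matched across trials either by
centre vertex index or left in greedy energy order. ROI selection is
unsupervised (it never sees ratings), so subject scope does not leak
label information into the classifier's cross-validation.

## Features (45 per signal)

For each input signal (channel or ROI time course), four blocks in a
fixed order, each summarized by {max, mean, variance}:

- **PSD (12)**: Welch power spectral density (segment length `L` =
  one second of samples by default — at least one period of the 4 Hz
  analysis floor — 50% overlap, Hamming taper, one-sided density
  scaling), summarized within alpha [8, 13), beta [13, 30),
  gamma [30, fs/2) and delta [0.5, 4) Hz. Band edges are the standard
  clinical ones; with 4 Hz high-passed input the delta block captures
  what little leaks below 8 Hz.
- **Hjorth (9)**: per windowed segment (same segmentation as Welch),
  activity = var(v), mobility = sqrt(var(dv)/var(v)) in rad/s,
  complexity = mobility(dv)/mobility(v); derivative = first difference
  times fs. The square-root convention is used (the plain variance
  ratio is not compatible with the usual complexity definition);
  constant raw segments are dropped with a warning — tapering them
  would fabricate the window's own shape — and an all-constant signal
  is an error. For a pure sinusoid at f Hz these give mobility
  ~ 2*pi*f and complexity ~ 1, which the tests check to 2%.
- **CWT (12)**: complex Morlet (omega0 = 6 cycles) amplitude at centre
  frequencies 10 (alpha), 20 (beta), 50 (gamma) and 2 (delta) Hz; a
  centre at or above Nyquist is dropped with a warning and reported as
  zeros so the vector length never changes.
- **DWT (12)**: Daubechies-4 multilevel decomposition (5 levels at
  fs = 128); per-band detail reconstructions with level 1 -> gamma
  (32–64 Hz), 2 -> beta, 3 -> alpha, and all deeper levels plus the
  final approximation aggregated into delta. The dyadic grid cannot
  match the clinical band edges exactly; the level map is
  configurable. The per-band reconstructions sum back to the signal
  (perfect reconstruction, tested at 1e-8).

The trial matrix concatenates the per-signal vectors; 40 trials x 32
channels give a 40 x 1440 matrix.

## Relevance ranking and evaluation

Features are standardized and the correlation matrix
eigendecomposed (a Gram-matrix path handles p >> n at O(n^2 p)).
Keeping the leading components that reach 90% explained variance,
feature j scores `sum_i lambda_i |v_ij|`; features most correlated
with the dominant components rank first. Selection keeps the smallest
ranking prefix holding 90% of total relevance mass (a top-k rule is
also available). Constant features score zero.

Ratings in [1, 9] are binarized at the midpoint (high iff rating > 5;
exactly 5 counts as low — documented tie rule). Evaluation is
leave-one-out: standardization, ranking, selection and the soft-margin
RBF SVM (C = 1, gamma = scale; no inner hyperparameter search at
n = 40) are refit on each fold's 39 training trials, so the held-out
trial influences nothing. Accuracy and the F1 score of the "high"
class are reported as percentages; F1 is the robust measure under the
class imbalance the midpoint split produces. Methods are compared by a
classical one-sided paired t-test on per-subject scores; identical
inputs return (t = 0, p = 0.5), and constant nonzero differences are
rejected as degenerate.

## The synthetic two-class experiment

`generate_emotion_dataset` emulates one subject-equivalent session at
DEAP-like shape: 40 trials, 32 channels, 128 Hz, ratings uniform on
[1, 9] (re-drawn until both midpoint classes have >= 3 trials).
Class structure lives in source space:

- an **emotion patch** carries a 10 Hz alpha oscillation with
  amplitude 1.0 (low class) or 1.6 (high class);
- a **confound patch**, 2–3 mesh edges away, carries alpha of
  per-trial amplitude U(0.5, 2.5) regardless of class — total alpha
  power is therefore a poor class cue, and resolving the two sources
  spatially is what pays;
- distributed background activity (spatially smoothed white noise,
  RMS 0.3) and sensor noise at SNR 5 dB complete the trial.

Patch centres are restricted to the sensor-covered upper hemisphere:
sources under the cap's rim are invisible to any inverse method, a
degeneracy of the spherical stand-in rather than a property of the
methods under study. Trials last 6 s (a desk-scale stand-in for the
60 s DEAP videos; all stages are O(T), so this only trades statistical
for computational efficiency). The patch separation sits deliberately
in the resolution-limited regime where a compact solver can separate
the sources but a smoothness prior blurs them together — the regime
the LORETA-vs-MSP comparison is about.

What passing this experiment shows: under field spread, noise and an
alpha confound, compact source reconstruction plus ROI averaging
recovers class structure that is diluted at the sensor level and under
blurred reconstruction. What it does not show: anything about real
affective EEG — real emotion effects are far weaker and distributed,
real head models are not spheres, real ratings are not generated by a
two-level amplitude switch, and artifacts/nonstationarity are absent
here.

## Numerical choices and limitations

- `expm(sigma*G)` via symmetric eigendecomposition (exact symmetry by
  construction); checked against `scipy.linalg.expm` at 1e-8.
- All C x C solves: Cholesky first, jittered/eigendecomposition
  fallback; EM covariances get a 1e-12 trace-scaled ridge.
- EM convergence: relative objective tolerance 1e-6, max 128
  iterations; non-convergence returns the best iterate with a warning.
- Known limitations: no realistic head geometry or dipole orientation
  model; LORETA's `lam` has no data-driven selection; the MSP
  dictionary is tied to the mesh resolution; per-trial ROI
  correspondence is heuristic; the DWT delta block mixes theta content
  by construction at fs = 128.
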