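# Methods

This note documents the generative model behind the synthetic experiments,
the analysis pipeline's numerical choices, and the design decisions taken
where the problem left the design open. It states no empirical result that
the test suite or `scripts/acceptance.py` does not itself compute.

## The generative model

### Stimulus sequence

One session delivers `n_trials` (default 1000) median-nerve stimuli of two
intensities with exactly balanced counts (|#strong − #weak| ≤ 1), shuffled
pseudo-randomly with the constraint that the sequence starts with a weak
stimulus (an anchor for the intensity judgment). Inter-stimulus intervals
are uniform on [`isi_low`, `isi_high`] = [1463, 1563] ms (mean 1513 ms);
`n_blocks` = 5 blocks are separated by a 2 s silent gap. Sampling rate is
5000 Hz on an abstract 32-channel montage (Fibonacci points on the unit
sphere — no real cap geometry; source reconstruction is out of scope).

### Latent excitability and its couplings

Cortical excitability is a latent stationary AR(1),
`e_t = φ e_{t−1} + η_t`, with `φ = excitability_ar_coef` (default 0.95,
slow trial-to-trial drift) and stationary SD `excitability_sd` (default 1;
the innovation SD is `σ√(1−φ²)`). AR(1) is the minimal serially correlated
process consistent with slow waxing and waning of cortical state; richer
long-range-dependent dynamics are deliberately not modelled.

Three couplings hang off `e_t`, all overridable in `GeneratorConfig`:

- **Alpha envelope** (anti-coupled):
  `alpha_env_t = exp(alpha_base_log + alpha_coupling·e_t + ε)`,
  `alpha_coupling = −0.7`, `ε ~ N(0, 0.2)`, baseline ≈ 2 µV RMS. High
  alpha marks low excitability.
- **Evoked current scale** (anti-coupled): the per-trial post-synaptic
  current scale is `I_t = epsc_gain·(1 + epsc_coupling·e_t)` with
  `epsc_coupling = −0.25` — a depolarized (more excitable) state reduces
  the electro-chemical driving force and therefore the evoked current, so
  the N20 *shrinks* with excitability while it *grows* with stimulus
  intensity.
- **Response criterion** (anti-coupled): the observer's criterion is
  `c_t = criterion_base + criterion_coupling·e_t` with
  `criterion_coupling = −0.10` — excitable states lower the threshold for
  reporting "strong".

### Scalp voltages

The voltage model is `U ∝ I · N_neurons · LF`. Per trial the evoked scalp
contribution is `sep_gain_t × s(τ)` projected through the unit-norm
tangential-dipole pattern, where
`sep_gain_t = I_t · n_neurons_gain · level(intensity) · leadfield_gain`,
`level(weak) = 1.0`, `level(strong) = 1.15` (the two intensities are barely
distinguishable by design), and `s(τ)` is a unit template with its negative
extremum (−1) at 20 ms, a positive deflection near 35 ms, and support
5–80 ms. The stored latents allow the per-trial gain to be recomputed
exactly (`I_t · N · LF`), which the tests assert.

The alpha source adds `pattern_alpha · env(t) · carrier(t)` where the
carrier is an 8–13 Hz narrowband process whose envelope has been flattened
to unity (random phase evolution only) and `env(t)` steps per trial through
`alpha_env_t` (100 ms smoothing at the boundaries). Flattening the carrier
makes the stored envelope latent exactly the realized pre-stimulus
amplitude — a deliberate simplification: real alpha fluctuates within the
analysis window, which would put an intrinsic ceiling (≈0.77 rank
correlation at this window length) on any ground-truth recovery check and
make extraction fidelity untestable. Passing tests therefore certify the
extraction pipeline, not the within-window stationarity of real alpha.

Background noise is spatially correlated 1/f ("pink") noise, correlation
decaying smoothly with inter-channel distance, `noise_sd` = 0.5 µV per
channel. Peripheral channels: a CNAP bump peaking at 7 ms (µV scale) and a
biphasic CMAP (negative ~8 ms, positive ~14 ms, mV scale), both scaling
with presented intensity only, plus white sensor noise. An optional
`cmap_percept_coupling` routes thumb-twitch magnitude into the percept; it
defaults to off.

### The observer

Equal-variance SDT: internal evidence is `d′·1[strong] + N(0,1)`; the
report is "strong" when evidence exceeds `d′/2 + c_t`. Anchoring the
neutral point at `d′/2` makes the estimated SDT criterion equal `c_t` on
average (verified by simulation in the tests). Population `d′` defaults to
1.14 with between-subject SD 0.30; per-subject criterion baselines have SD
0.15. Two percent of trials receive no response and are excluded from the
behavioral analyses, as in a real button-press task.

### Two product levels

`generate_experiment` renders full continuous recordings. For studies that
need hundreds of simulated experiments, `simulate_subject_table` /
`simulate_study` produce trial tables directly from the latents, replacing
the extraction step by calibrated Gaussian measurement noise
(`n20_meas_noise_sd` = 0.36 µV, `alpha_log_meas_noise_sd` = 0.29). These
values mirror the extraction error actually measured on rendered sessions
(single-trial N20-vs-truth correlation ≈ 0.88, alpha rank correlation
≈ 0.9 at 120 trials — both recomputed by `scripts/acceptance.py`), so the
fast path presents the statistics stages with the same signal-to-noise
structure as the full chain.

### Effect-size calibration

Couplings are calibrated so that the canonical 12-subject × 1000-trial
study detects the alpha→criterion quintile contrast reliably (≥95% of
experiments) while keeping every effect direction physiological. With 200
trials per extreme quintile, the binomial noise of a per-subject criterion
estimate alone contributes ≈0.13 SD to the high-minus-low difference; a
detectable-by-design effect at 12 subjects therefore needs an expected
quintile difference near 0.2, larger than what a 32-subject human study
requires. This is a desk-scale design choice: the generator's default
effect is stronger than typical empirical effects so that the pipeline's
statistical machinery can be validated with manageable simulation sizes.
Null-coupling configurations are used to verify type-I calibration (~5%
false-positive rates) independently of this choice.

## Analysis pipeline: numerical choices

- **Artifact interpolation** anchors the PCHIP interpolant on the two
  samples flanking each side of the excised −2..4 ms window (the anchor
  convention is not standardized; two points per side is the minimum that
  lets PCHIP see a slope).
- **Filtering** is zero-phase throughout (`sosfiltfilt`): the magnitude
  response is the squared single-pass Butterworth response, and the net
  phase is zero. The 30–200 Hz SEP filter is applied to the whole
  continuous recording so epochs see no edge transients. Pre-cut segments
  (the alpha pipeline) are mirror-padded with the full segment length on
  each side before filtering. One caveat worth knowing: for a *coherent*
  sinusoid whose phase does not continue smoothly across the mirror
  junction, the reflected copy interferes inside the narrowband filter's
  ringing length; random-phase signals (real or simulated alpha) are
  unaffected on average.
- **Template CCA.** With `X` the concatenated windowed trials and `Y` the
  replicated grand average, maximizing `corr(w_xᵀX, w_yᵀY)` is solved by
  SVD of the whitened cross-covariance
  `C_xx^{-1/2} C_xy C_yy^{-1/2} = U S Vᵀ`, giving
  `w_x = C_xx^{-1/2}U`, `w_y = C_yy^{-1/2}V`, and canonical correlations
  `S` in descending order — the symmetric form of the CCA generalized
  eigenproblem, numerically preferable for near-singular covariances.
  Because `Y` holds a single repeated waveform, `C_yy` is estimated from
  the average's own time course and can be rank-limited; both covariances
  are shrunk as `(1−γ)C + γ·tr(C)/p·I` with `γ = 10⁻⁶` by default
  (average-referenced data are exactly rank-deficient; fitting without
  shrinkage raises an error that names the remedy). Filters are scaled to
  unit projected variance; ties in the correlation are broken toward the
  lower component index. Component selection inspects the top 4 components
  and picks the one whose unit activation pattern `Cov(X)w_x` best matches
  a template pattern (absolute cosine similarity, threshold 0.5); the sign
  factor makes the grand-average component waveform negative at the N20
  latency. The automated similarity criterion replaces visual pattern
  inspection and is validated only on synthetic ground truth.
- **N20 latency search** uses 15–30 ms on the average waveform (bracketed
  by physiology; a boundary minimum triggers a warning), then the
  per-trial minimum within ±2 ms.
- **Alpha metric**: envelope averaged over −200..−10 ms first, then
  natural-log transformed (in that order). Segmenting at −5 ms *before*
  filtering guarantees no post-stimulus leakage; a mutation test asserts
  the invariance.
- **SDT corrections**: empirical rates of exactly 0 or 1 are replaced by
  `1/(2N)` and `1 − 1/(2N)` (flagged), which matters in 200-trial extreme
  bins with few errors. The quintile binning stable-sorts with the
  original trial order as tie-breaker and takes `floor(n/5)` trials per
  extreme bin.
- **Permutation test**: the accuracy of a random response remapping
  depends only on the 2×2 margin counts, so surrogate accuracies are drawn
  from the exact hypergeometric equivalent (validated against brute-force
  shuffling), making 100 000 permutations per subject cheap. The p-value
  counts surrogates *strictly greater* than the observed accuracy; the
  positively biased `(b+1)/(n+1)` estimator is available via a flag (and
  used when testing the uniformity of null p-values, where the unbiased
  estimator's atom at 0 is inconvenient).
- **Mixed models** delegate to statsmodels `MixedLM`. Degrees of freedom
  use the normal approximation (no Satterthwaite adjustment exists in the
  host ecosystem; the estimate is flagged accordingly). Because continuous
  variables are z-transformed *within subject*, the random-intercept
  variance of continuous outcomes sits at the boundary; such singular fits
  are accepted with a note when the fixed-effect estimate and its standard
  error are finite (the same convention as lme4's singular fits), and
  anything worse falls back to the two-stage route with a logged
  downgrade. Binary outcomes (perceived intensity, logit link) always use
  the two-stage route, since no frequentist logit-link GLMM is available.
- **Two-stage path analysis** approximates a multi-level path model: each
  within-subject regression is fitted per subject (OLS, or logistic GLM
  for the report; subjects with separation — |coefficient| > 15 — are
  excluded with a log entry), and per-subject coefficients are tested
  against zero with one-sample t-tests. It is validated for effect
  *direction* and type-I calibration, not for reproducing multi-level
  path coefficient magnitudes; no structural-equation fit indices are
  computed.
- **Within-subject standard errors** (for condition means in figures):
  remove each subject's mean, restore the grand mean, compute per-condition
  `SD/√n`, and scale by `√(k/(k−1))` for `k` conditions to undo the
  variance bias of the centering.

## Problem sizes

The test suite and the acceptance script choose sizes that keep a full run
in the low minutes on one CPU: rendered sessions use 100–120 trials at
5 kHz with 12–16 channels (a full 1000-trial, 32-channel render needs on
the order of a gigabyte and a couple of minutes — supported, but pointless
for the statistics, which are driven by the table-level fast path);
statistical calibration uses 100 simulated 12-subject × 1000-trial studies
for power/sign recovery and 200 null-coupling studies for type-I rates;
sequence statistics aggregate ~10⁵ inter-stimulus intervals.

## Known limitations

- The montage, head geometry and noise spectra are abstract; nothing here
  approximates real scalp topographies or individual anatomy.
- The alpha carrier's flattened envelope understates within-window
  amplitude variability of real alpha (see above).
- Excitability is a single AR(1) latent; real cortical state has richer
  temporal structure and need not be one-dimensional.
- The two-stage path analysis is a stand-in for full multi-level
  structural-equation modelling; coefficient magnitudes are not
  comparable across the two approaches.
- Artifact handling is limited to stimulus-artifact interpolation and an
  optional amplitude-threshold rejection; ocular/muscle artifact removal
  (ICA) is out of scope, as synthetic data contain no such artifacts.
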