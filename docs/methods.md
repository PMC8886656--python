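# Methods

## The model and what the pipeline measures

Each subject contributes a region-by-time matrix of BOLD signals
s_j(t), j = 1..n, sampled every `tr` seconds.  The analysis treats each
regional signal as an oscillator and asks how coherent the set of
oscillators is over time:

1. **Instantaneous phase.**  Each series is demeaned and extended to its
   analytic form s(t) + i·H(s)(t) with the Hilbert transform; the
   instantaneous phase θ_j(t) is the four-quadrant angle of that complex
   signal.  The four-quadrant angle is used rather than arctan(H(s)/s)
   because the plain arctangent cannot distinguish phases that differ by π.
   Phase is only meaningful for a roughly narrowband, zero-mean signal,
   which is why an optional zero-phase band-pass stage (second-order
   Butterworth, forward–backward, default 0.01–0.1 Hz) precedes it.  The
   filter is optional because input data may already be band-limited —
   either by an upstream preprocessing pipeline or, for the synthetic
   generator, by construction — and re-filtering only adds distortion.

2. **Kuramoto order parameter.**  r(t) = |mean_j exp(iθ_j(t))| over a
   chosen region set: 1 means all regions share a phase, values near
   1/√n mean incoherence.

3. **Synchronization and metastability.**  Synchronization is the temporal
   mean of r(t); metastability is its temporal standard deviation, i.e. how
   much the system wanders between integrated (high-r) and segregated
   (low-r) states.  The SD uses denominator L−1 (sample SD).  The
   population-SD alternative changes values by <0.3% at L≈200 and by
   1/(2L) in relative terms generally; the unbiased estimator was chosen
   and is recorded in every run manifest.

Metrics are computed globally (all parcels with a network label) and per
resting-state network (visual, somatomotor, dorsal attention, ventral
attention, limbic, frontoparietal, default).  Networks with fewer than two
labelled parcels are skipped, since r(t) over one oscillator is
identically 1.  No time points are trimmed by default; a `trim` parameter
exists because the discrete Hilbert transform is biased near the series
edges, and validation tests use it to separate edge effects from genuine
disagreement.

## Group statistics

All inference runs on residualized metrics: nuisance covariates (age,
gender, handedness, education, mean framewise displacement, total
intracranial volume — configurable per run) are removed by OLS with an
intercept before testing.  Two-sample comparisons default to Welch's
unequal-variance t-test (a pooled-variance toggle exists); paired
comparisons residualize across the pooled sample, then test the
within-pair differences.  Pearson correlations between metrics and scores
are computed on the two residualized vectors.  Multiple comparisons are
controlled with Benjamini–Hochberg at q = 0.05 within an explicit family
(by default the set of scopes for a given metric); adjusted p-values are
reported alongside binary rejections.

## Mediation

The single-mediator path model is fitted by three OLS regressions sharing
the covariate set: a (x→m), b and c′ (m and x → y jointly), c (x→y).  For
nested least squares with identical covariates, c = c′ + a·b holds exactly
for the point estimates, and the test suite asserts it to 1e−10.
Inference uses a nonparametric bootstrap that resamples whole subject rows
(10,000 draws by default) with bias-corrected (BC) percentile intervals.
BC rather than BCa: the acceleration constant adds a jackknife pass and
matters little at the sample sizes involved; the bias correction z₀ is the
normal quantile of the fraction of bootstrap replicates below the point
estimate.  Two-sided p-values invert the same mapping at zero:
p = 2·min(Φ(z_F(0) − 2z₀), 1 − Φ(z_F(0) − 2z₀)) where F is the bootstrap
CDF.  Bootstrap replicates whose design is rank-deficient (e.g. a resample
containing a single group) are redrawn; more than 10% redraws aborts with
an error, since the data are then too fragile for resampling inference.
The singularity test normalizes the Gram matrix to unit diagonal first, so
covariates measured in very different units (intracranial volume in ml
against framewise displacement in mm) cannot masquerade as collinear.
Degenerate bootstrap distributions (all replicates identical) report the
point estimate as the interval with p = 0 and an explicit flag.

Exactly noise-free mediation chains (m a perfect linear function of x)
make x and m collinear; b and c′ are then unidentifiable and the fit
raises a rank error naming the offending columns rather than returning a
minimum-norm artifact.

## Connectome PCA

Subject-by-edge streamline-count matrices are first normalized per subject
(each row divided by its own mean, guarding against zero rows), then
decomposed by PCA on column-centered data (centering on, scaling off by
default, both exposed as flags since conventions differ).  The PC1 sign is
fixed so that the loadings sum to a positive number, making PC1–metric
correlations reproducible across runs and BLAS builds.

## The synthetic generator

The generator exists so that every downstream stage can be tested against
known ground truth at desk scale; it emulates the statistical structure of
a two-group resting-state study, not the physiology.

**Oscillators.**  Phases follow the stochastic Kuramoto model
dθ_i = [2πf_i + (K/n)Σ_j sin(θ_j − θ_i)]dt + σ√dt·ξ, integrated by
Euler–Maruyama through the exact mean-field identity (the coupling sum
equals K·r·sin(ψ − θ_i)).  Defaults: n = 100 oscillators, natural
frequencies f_i ~ N(0.05, 0.01) Hz (the center of the conventional BOLD
band, so cos(θ) round-trips through the band-pass), phase noise
σ = 1.5 rad/√s, output every tr = 2 s for 410 s (205 samples), nominal
step dt = tr/10.  With these values the incoherence-to-coherence
transition sits near K ≈ 2–3 (for noise-dominated Kuramoto the critical
coupling is ≈ σ², i.e. 2.25), so the probed couplings K = 0, 1 (below), 5
(above) and 50 (deep lock) straddle the transition and metastability peaks
at intermediate K.  Two numerical guards: (a) the internal step is refined
beyond dt whenever K·dt would exceed 0.2, because explicit Euler
overshoots the locked state otherwise (visible as spurious desynchronization
at K = 50); (b) 60 s of burn-in are simulated and discarded so the sampled
window reflects the stationary regime, not the relaxation from uniformly
random initial phases — without burn-in the high-K transient masquerades
as metastability.

**BOLD emission.**  s_i(t) = A_i·cos(θ_i(t)) + ε with A_i ~ |N(1, 0.1)|
and white observation noise (SD 0.1).  No hemodynamic convolution,
spatial structure, scanner drift or motion artifacts are modelled, so
passing tests demonstrate the correctness of the phase/statistics
machinery, not robustness to real fMRI confounds.

**Cohorts.**  Two groups of subjects, each subject simulated with coupling
K ~ N(K_group, 0.5) truncated at 0; defaults K₀ = 3.0 (near-transition:
moderate-to-high synchronization, high metastability) and K₁ = 0.5
(subcritical: both low), so the injected deficit lowers both metrics in
group 1 — the qualitative pattern of a patient-vs-control contrast.  The
per-subject jitter models between-subject heterogeneity; it is also what
makes the mediator→score path estimable, because without within-group
mediator variance that regression would rest entirely on measurement
noise.  Covariates (age, gender, handedness, education, framewise
displacement, intracranial volume) are drawn from per-group Gaussian or
Bernoulli models loosely matched to an elderly clinical cohort.  The
cognitive score is a stated linear function of the subject's realized
global metastability, 24 + 40·M + N(0, 0.5) — slope and noise chosen so
the score spans a few points (MMSE-like) with a clearly present but not
noise-free mediation chain.  All randomness descends from one root seed
via `numpy.random.SeedSequence.spawn`, so cohorts are reproducible while
subjects stay independent.

**Mediation triads and connectivity.**  Triads follow m = a·x + ε,
y = b·m + c′·x + ε with balanced binary x.  Connectivity matrices are
baseline + Σ_k u_k v_kᵀ + noise with non-negative loadings and a baseline
of 5 (in row-mean units), clipped at zero; the first latent score vector
is stored for recovery tests, and with unit-norm loadings the per-factor
SNR is 1/noise_sd.

## Problem sizes

Simulation-based checks run at deliberately small scale chosen to keep the
whole suite interactive: coupling sweeps use 20 seeds per K; bootstrap
coverage uses 200 replicates of n = 200 with 500 resamples; the end-to-end
cohort uses 15 subjects per group, 60 regions, 205 time points, 2,000
bootstrap draws; path-recovery checks use n = 5000 and report medians over
5 replicates to suppress single-draw Monte Carlo error (~0.03 SD per
path).  At these sizes the statistical assertions hold with large margins
(e.g. group-contrast p-values below 1e−5).

## Known limitations

- The generator's BOLD model is phase-plus-noise; amplitude dynamics,
  hemodynamic lag and physiological noise are absent, so agreement with
  ground truth here does not certify behavior on real fMRI.
- BC intervals are slightly anti-conservative under strong skew at small
  n; observed null coverage of the indirect-effect interval is ~92–95%
  at n = 200.
- The paired-test construction residualizes the two states' values on the
  pooled covariate before differencing; other constructions (differencing
  first) are possible and would give slightly different t-values.
- Partial-correlation p-values use the ordinary Pearson degrees of freedom
  on residualized vectors and do not subtract the number of covariates;
  at the cohort sizes involved the difference is negligible, and the null
  p-value distribution is verified uniform by simulation.
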