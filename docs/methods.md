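# Methods

This note documents the models, numerical conventions and design choices
behind `iscval`.  It is written for someone who wants to know exactly what
the pipeline computes and what its validation does — and does not — show.

## Simulated cohorts

Each cohort consists of `n_subjects` 4-D grids sharing one activation mask
and one activation time-course.  The design is the standardized
block-design run: 12 alternating 28-s off/on blocks of 7 volumes at TR 4 s
(starting 'off'), i.e. 84 retained volumes; 3 leading stabilization volumes
exist only in the timing bookkeeping (the total run is 348 s) and are never
synthesized, since analyses only ever see retained volumes.

The activation signal is the boxcar convolved with a canonical
haemodynamic response function.  The HRF is parameterised by its temporal
moments — mean lag 6 s, standard deviation 3 s — realised as a gamma
density (shape 4, scale 1.5 s, solved from mean = kθ, variance = kθ²) with
zero phase, sampled at the TR over a 32-s support and normalised to unit
sum.  Unit-sum normalisation makes a sustained block plateau at the boxcar
amplitude, which pins down the meaning of "signal power".  Convolution is
causal and truncated to the retained length; there is no pre-stimulus
padding, so the first block's response ramps up from zero.

Noise is pink (1/f) noise, an empirical model of BOLD noise, generated by
spectral synthesis: a white Gaussian spectrum shaped by 1/√f with the DC
bin zeroed, inverse-transformed, and de-meaned.  This gives exact PSD
control over the whole resolvable band (log-periodogram slope −1.0) and,
usefully for inference, an exactly circularly-stationary process.

**SNR convention.**  `snr` is the ratio of signal power to noise power,
with power taken as the raw mean square of the activation time-course
(DC included; ≈ 0.437 for the default design) and the noise scaled
per-voxel so that its mean-square power equals `power(signal)/snr`
exactly.  The study's four levels are noise 100, 200, 500, 1000 × the
signal power (snr 0.01, 0.005, 0.002, 0.001).  Note that the signal's DC
term is counted toward its power but removed by the high-pass filter, so
the *effective* post-filter SNR is roughly half the nominal value.

**Seed layout.**  A master seed spawns one child stream for mask placement
and one per subject (`numpy.random.SeedSequence`).  Noise draws therefore
do not depend on the SNR value, the mask, or other subjects — a sweep over
SNR with one seed is a matched-noise sweep, and supplying an explicit mask
leaves the noise bit-identical.  Identical specs give bit-identical
cohorts (data are stored as float32).

**Activation mask.**  The real study derived its mask from a task's GLM
activation map, which is not available; the synthetic stand-in is a few
compact spheres covering ~5% of the grid (radius chosen from the target
fraction, three spheres by default, centres uniform, overlap allowed).
Compact spheres are geometrically kinder to spatial smoothing than thin
cortical sheets: a larger share of active voxels sits deep inside the
mask, so detection at a given SNR is somewhat easier here than it would be
with realistic activation geometry.

**Resolution.**  The real data live on the 2-mm standard grid
(91×109×91 = 902,629 voxels).  Desk-scale cohorts default to 4-mm
isotropic voxels on reduced grids (e.g. 30³).  This choice interacts with
the 5-mm smoothing kernel: at 2 mm the kernel averages ~50 independent
noise voxels and boosts effective SNR by more than an order of magnitude,
which (with compact spherical masks) would push the detectability boundary
far below the study's noise levels; at 4 mm the boost is ~6×, which places
the partial-detection regime — where the interesting behaviour lives —
inside the studied SNR range.  Consequently the scaled-down detectability
boundary sits near SNR 0.005 rather than 0.001; the qualitative shape
(monotone rise of Dice with SNR, failure at the highest noise level, ISC
more conservative than GLM at tight thresholds) is preserved.

What the generator does *not* emulate: anatomy, between-subject effect-size
or HRF variability, motion, physiological noise, spatial noise correlation.
Passing tests therefore validate the statistical machinery under the
stated noise model, not robustness to real-data artefacts.

## Pre-processing

Spatial smoothing is per-volume isotropic Gaussian convolution,
σ = FWHM/(2√(2 ln 2)) converted to voxels (5-mm FWHM default), zero-padded
at the grid boundary with no masked renormalisation.

Temporal high-pass filtering (60-s cutoff) is regression-based: the
projection residual off a drift basis containing the constant, a linear
trend, and sine+cosine pairs at every Fourier frequency with period longer
than the cutoff (j = 1…⌊T·TR/cutoff⌋).  Both quadratures are needed: a
cosine-only basis removes an arbitrary-phase slow oscillation only
partially and leaks across frequencies (measured gain 0.68 at the 56-s
task period), while the quadrature basis passes the task frequency nearly
untouched (gain 0.92–1.0) and nulls a 336-s drift exactly.  As a
projector the filter is exactly idempotent, and the identical operator is
applied to data and to GLM regressors.  Smoothing and high-pass act on
different axes and commute.

## GLM branch

Per subject, ordinary least squares of each voxel on
[task, task-derivative, intercept], where the task column is the
high-passed boxcar⊛HRF and the derivative column the high-passed finite
difference of the pre-filter task column (a nuisance absorbing small
latency shifts; only the task effect is carried forward).  Prewhitening is
voxel-wise AR(1): the lag-1 autocorrelation of the OLS residuals
(clipped to ±0.99) drives one Cochrane–Orcutt refit; voxels with
negligible coefficients keep the plain fit, which makes the ρ = 0 case an
exact reduction.  This replaces a full autocovariance model; AR(1)
captures the dominant serial correlation of high-passed 1/f noise.

Group inference replaces mixed-effects MCMC estimation with the
summary-statistics approach: a one-sample t across subjects' betas per
voxel, converted to z by matching upper-tail probabilities (symmetric in
the sign of t) and capped at ±8.2 so downstream map correlations never
meet an infinity.  Zero-spread voxels give z = 0 when the mean is zero,
else the cap.  For synthetic cohorts with homogeneous effects this is
statistically adequate; it does not reproduce any particular software's
numbers.  GLM detection maps come from one-sided (activation) p-values of
z, FDR-corrected exactly like the ISC maps.

## ISC branch

The statistic is the average of all N_s(N_s−1)/2 pairwise Pearson
correlations (666 pairs at N_s = 37).  Implementation: each series is
centred and scaled to unit norm once; the pair-sum is then
(‖Σ_j u_j‖² − N_s)/2, which is exact and O(N_s·T) per voxel.  Voxels
where any subject's series is constant (judged with a relative tolerance,
since a constant series can miss exact zero variance by rounding) are
marked invalid (NaN) and excluded.

**Null distribution.**  Circular time-shifting with independent
per-subject offsets, uniform over [min_shift, T − min_shift]
(min_shift = 10 samples), preserves each series' periodogram — hence its
autocorrelation — exactly while destroying inter-subject alignment.  One
pooled null is shared across voxels: each resampling round draws one shift
per subject and evaluates the statistic at up to `n_sample_voxels`
(default 5000) randomly sampled valid voxels; rounds repeat until B
realizations are pooled (B = 10⁶ for full runs, 10⁴–10⁵ at desk scale).
Voxel-wise nulls at B = 10⁶ would be computationally out of reach and are
unnecessary here because all voxels share one noise law.

One ordering subtlety matters for calibration: the high-pass filter is not
invariant under circular shifts (its drift basis is not periodic), so
surrogates are built by shifting the *pre-filter* (smoothed) series and
filtering afterwards, exactly as the observed data were filtered.
Shifting the already-filtered series instead produces a null ~15% too
narrow in the far tail and a realized FDR of ~6% at q = 0.05; with the
correct ordering the realized FDR is ~4% (slightly conservative, as
expected from add-one p-values and permutation discreteness).

P-values are right-tail with the add-one convention,
p = (#{null ≥ observed}+1)/(B+1), floored at 1/(B+1).  B bounds the
resolution: Benjamini–Hochberg at level q over m voxels can only reject
when the critical value k·q/m clears the floor, so conservative q on
large grids needs B ≫ m/q.  This is why desk-scale runs use at least 10⁴
(and the failure-mode target 10⁵) realizations.

## Thresholding and comparison

Benjamini–Hochberg step-up (largest k with p_(k) ≤ k·q/m; ties at the
threshold rejected; NaN voxels excluded from m) at q = 0.05, 0.005, 0.001,
valid under independence or positive dependence.  The GLM's reported
statistic-scale thresholds are data-dependent byproducts, not targets.

The correlation measure C is the Pearson correlation between |Z| and the
ISC statistic over brain voxels (|Z| because de-activations also raise
ISC; the signed variant is exposed and, as expected, correlates lower).
The Dice index is computed over the full volume from indicator vectors;
both-empty Dice is reported as undefined rather than 0 or 1.  Landis–Koch
category bins are left-closed ([0.6, 0.8) substantial) with 1.0 included
in "almost perfect"; the source categorisation does not fix the edge
convention, and no reported value lands on an edge.

## Validation scaling and scope

The test-suite and acceptance runs use reduced problem sizes chosen as
study conditions: grids of 12³–30³ voxels at 4 mm, 37 subjects (the study
cohort size), B = 10⁴–10⁵, and 20–100 replicates for error-rate
estimates (replicate count only tightens the Monte-Carlo error of the
estimate; the estimand is unchanged).  The FDR-calibration check counts a
detection as a true positive when the voxel carries injected signal
*after* smoothing (smoothed-mask weight > 0.05): smoothing genuinely
moves signal into neighbouring voxels, and calling those detections false
would measure kernel leakage, not test calibration.

Known limitations: no between-subject variability, so agreement numbers
on simulated data are upper bounds on what heterogeneous cohorts would
give; the 4-mm resolution shifts the absolute detectability boundary (see
above); the pooled null assumes voxels share a noise law, which is true
by construction here but only approximately true in real data; and the
GLM branch's simplifications (AR(1), summary statistics) are adequate for
these cohorts but are not a re-implementation of any specific software
pipeline.
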