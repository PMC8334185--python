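# Methods

This note records the models, estimators and numerical choices behind
cvrpipe, and what the synthetic-data experiments do and do not establish.

## Challenge paradigm

The block design is parameterized by `ParadigmSpec`: baseline end-tidal
CO2 (default 40 mmHg), six cycles of normocapnia followed by 30 s of mild
hypercapnia with step targets (+4, +8, +4, +8, +4, +8 mmHg). The
normocapnia duration is drawn per cycle from a configurable range; the
default collapses the range to a fixed 70 s so that the default protocol
lasts exactly 600 s and tiles the 480-volume acquisition. The ideal
piecewise-constant target is also provided convolved with a first-order
exponential wash-in (time constant 8 s, configurable) standing in for the
gas-circuit dynamics; instantaneous steps are unphysical. The paradigm
fundamental is defined as 1 / mean cycle duration = 0.01 Hz for the
default and anchors the analysis band.

## End-tidal extraction

* **Technical delay.** The gas analyzer sits behind a sampling line; its
  traces lag the flow sensor. The delay is the lag (±5 s by default)
  maximizing |normalized cross-correlation| between the time-derivative
  of the gas trace and the flow. Both signals are smoothed with a
  symmetric 0.1 s Gaussian first — breathing lives well below 1 Hz, and
  differentiating raw analyzer noise would otherwise dominate; a
  symmetric kernel adds no lag. A flat trace raises a degenerate-input
  error. The correction is idempotent up to one sample.
* **Breath segmentation.** Respiratory phases come from flow
  zero-crossings with hysteresis (deadband 5% of flow SD, after the same
  0.1 s smooth). A breath is an inspiratory segment plus the following
  expiratory segment; cycles shorter than 1.5 s (analyzer spikes) are
  merged into their neighbor. Breaths whose expiration runs into the
  last ~5 s of the recording are dropped: the recording ends mid-breath
  there and the delay-corrected gas trace holds edge values over roughly
  the technical delay.
* **End-tidal values.** P_ET_CO2 is the PCO2 maximum within the
  expiratory phase (robust to phase-boundary jitter, equivariant under
  constant shifts); P_ET_O2 is read off the PO2 trace at the same
  end-expiration time. P_ET_O2 is extracted and stored but not used
  downstream.
* **Resampling.** The breath-resolved series is linearly interpolated
  onto volume acquisition times with nearest-value edge extrapolation.
  Linear is deliberate: the breath interval (~5 s) exceeds the TR and
  higher-order splines overshoot at the step transitions.

## Coupling strength and response delay

Both ΔBOLD and the reference are band-limited with a 2nd-order
Butterworth filter applied forward-backward (zero phase); the analysis
band (0.004–0.02 Hz) retains the paradigm fundamental and first
harmonic. The analytic signal a(t) = x(t) + i·H[x](t) is built in the
frequency domain. The coupling statistic is the complex correlation of
analytic signals,

    rho = <a_v, conj(a_ref)> / (||a_v|| ||a_ref||),

whose magnitude is invariant to a pure delay between the series; the
reported r is |rho| signed by the zero-lag correlation sign (an option
reports the plain zero-lag band-limited correlation instead).

**Delay estimation.** Two routes are implemented and tested against each
other. The default evaluates the normalized cross-correlation profile
over integer-TR lags within the ±20 s search window on a wider low-pass
*delay band* (0–0.12 Hz) and refines the peak parabolically. The reason
for the wider band is quantitative: converting narrowband phase to time
divides the phase noise by 2π·f0 ≈ 0.063 rad/s, so at the 0.01 Hz
fundamental even small phase errors become seconds of delay error,
whereas the timing information of the challenge lives in its step
transitions (harmonics above 0.02 Hz). The delay band is a pure low-pass
because a 0.004 Hz high-pass leaves forward-backward-filter edge
transients that bias large lags; each overlap window is demeaned
(Pearson per lag) for the same reason. The alternative route
(`delay_method="phase"`) reads the delay from the analysis-band phase,
`-arg(rho)/(2*pi*f0)`, and agrees with the lagged-cross-correlation
oracle within one TR for narrowband (sinusoidal) coupling. Under the
realistic paradigm waveform at signal-to-noise ratio 2 (SD ratio on the
raw series) the default route recovers imposed delays within half a TR
in ≥95% of draws; the phase route cannot reach that accuracy at this
fundamental, which is why it is not the default. Delay estimates are
only meaningful for well-coupled voxels; at low r the profile peak is
noise-driven and shrinks toward zero.

Sign convention: positive delay = BOLD response later than the CO2
change. The ±20 s window stays below half the paradigm period (50 s) to
avoid phase-wrapping ambiguity.

**Voxelwise p-values.** The default is an empirical Monte-Carlo null:
20 000 white-noise series are pushed through the identical band-limit +
analytic-correlation path against the actual reference, and p is the
exceedance of |r| with the (k+1)/(n+1) correction. This is exactly
calibrated by construction — on coupling-free synthetic volumes the
suprathreshold fraction at p < 0.005 lands within binomial error of
0.005. Two closed forms are provided for comparison but are not the
default: a Beta law |rho|² ~ Beta(1, m−1) with m the in-band complex
degrees of freedom, and the classical t statistic on an effective sample
size n_eff = t·(bandwidth/Nyquist). Both are approximations for this
statistic at these short effective lengths (the t form in particular is
not reliably calibrated, which is what motivated the empirical default).

**Estimator bias.** |rho| is a magnitude and positively biased under
noise (E|rho|² = rho² + (1−rho²)/m); after the Fisher transform this
appears as a roughly level-dependent upward shift (~+0.12 in z at the
default noise). Group *differences* are largely preserved, but they are
modestly overstated (a true −0.25 z-difference is typically measured
near −0.30 under generator defaults), and absolute z levels should not
be compared across pipelines with different bands or lengths.

## Cluster-extent correction

Per iteration: white Gaussian noise on the analysis grid, Gaussian
smoothing to the assumed intrinsic FWHM (an input, not estimated from
data), global variance renormalization, two-sided thresholding at the
Gaussian voxel-p quantile, and recording of the largest connected
cluster (face adjacency by default; 18/26 configurable). The extent
threshold is the smallest k with P(max cluster ≥ k) ≤ α across
iterations, reported in voxels and mm³. Two-sided thresholding is used
because negative coupling is meaningful. A closed-loop check on freshly
simulated volumes confirms the achieved family-wise error. The extent is
a function of grid, voxel size, smoothness and thresholds — it is a
procedure, not a constant; any particular published extent value is
specific to that study's geometry and smoothness.

## Group statistics

Fisher z uses the exact formula with clipping at |r| = 1−1e−7 (warning)
and an error beyond it; the inverse is tanh, round-tripping to 1e−12.
Regional averages ignore NaN (undefined) voxels and warn when a region
has none; the group stage averages the *unthresholded* r maps, so every
subject × region cell stays defined (cluster thresholding serves
individual-subject display and inference, not the regional table).
Per region an OLS fit of z on group and age (sex optional, off by
default) yields control and HD estimates at a reference age of 50 years
as linear combinations of coefficients, 95% CIs from the t distribution,
and the group coefficient as the HD−control difference; regions with a
singular design are skipped with a warning. BH-FDR (statsmodels
`fdr_bh`) adjusts the difference p-values across all regions as one
family. The partial Spearman correlation rank-transforms z, TFC and age
(average ranks for ties), projects the age ranks out of the other two,
and correlates the residuals; p uses the t approximation at n−3 df. A
constant TFC yields NaN with a warning rather than an error.

## Synthetic data generator

The generator defines the study conditions; its defaults are fixed, not
tuning knobs.

* **Cohort.** 12 HD-like and 11 control subjects. Ages are taken at
  stratified quantiles of piecewise-linear quantile functions matching
  the emulated cohort's demographics (controls: median 32 y, IQR
  27.5–46, right-skewed, range 22–62; HD: median 51.5 y, IQR
  47.25–57.25). The age structure is a fixed design feature, so it is
  reproduced deterministically rather than resampled per seed; the
  overlap of the two ranges is what keeps the age-adjusted contrast
  identifiable at n = 23. TFC scores (9–13, skewed toward 13) exist for
  HD only. Per subject and region a true Fisher z is drawn as
  z = mu_region + slope·(age−40) + N(0, 0.12), with mu_region ~
  U(0.55, 0.80), slope −0.003/y, and −0.25 added in the 12 affected
  regions for HD subjects; HD affected regions also get +2 s delay with
  1 s jitter.
* **Physiology.** Breaths at 12/min with 0.3 s period jitter;
  inspiration 40% of the cycle. Flow is half-sine per phase and the gas
  curve is the matching raised cosine, so the gas derivative is
  proportional to flow (the technical-delay estimator is then exact by
  construction) and the noise-free expiratory maximum equals the target
  plateau exactly. Plateaus track resting P_ET_CO2 (U(35, 45) mmHg) plus
  the ideal paradigm target at the breath's end. Gas traces are delayed
  by the subject's technical delay (U(1, 3) s) and carry 0.5 mmHg
  analyzer noise; flow carries 0.02 L/s sensor noise. PO2 is linearly
  anticorrelated with PCO2 within the breath.
* **BOLD.** Voxel signal = baseline·(1 + a_j·ΔP(t−d_j)/100 + drift/100 +
  motion·β/100 + ε/100), where ΔP is the paradigm deviation convolved
  with the 8 s first-order response, d_j the region delay, drift a random
  cubic, and ε white noise of SD 0.5% of baseline. Twelve high-intensity
  decaying dummy volumes are prepended so the discard stage is
  exercised. Motion regressors are band-limited (0.03–0.2 Hz)
  pseudo-respiratory/slow head motion: a random-walk motion model was
  rejected because its power concentrates inside the narrow analysis
  band, and projecting six such regressors excises a realization-
  dependent share of the coupling signal itself (a real hazard of
  nuisance projection that the generator should not build in by
  default). Region amplitudes a_j are calibrated so that the band-limited
  correlation equals tanh(z_true): the in-band noise SD is
  noise_sd·sqrt(g) with g the *finite-length* white-noise variance gain
  of the zero-phase band-pass (computed exactly by filtering the
  identity operator — at 468 samples edge transients nearly triple the
  asymptotic gain), and a_j = sigma_band·r/(sqrt(1−r²)·SD of the
  band-limited regressor).
* **Parcellation.** Blocky contiguous regions tiling the interior of the
  grid (default 24×24×12 voxels at 3.4375×3.4375×6 mm, 48 regions, every
  region ≥ 8 voxels), a one-voxel background shell, and a small central
  "ventricle" block excluded from the analysis mask.

**What passing tests show.** Parameter recovery on this generator
demonstrates that the pipeline correctly implements its own model:
delays and plateaus are recovered, thresholds are calibrated, and the
group contrast is detected at the designed effect size. Real recordings
differ in ways the generator does not emulate — slice-timing and actual
head displacement (assumed corrected upstream), non-Gaussian and
temporally autocorrelated physiological noise, imperfect CO2 targeting,
coughing/swallowing artifacts, arousal-related global signals, and
anatomical registration error — so passing here does not certify
performance on scanner data.

## Numerical choices and degenerate inputs

Legendre (orthogonal) bases for detrending at t ≈ 468 samples; QR with
column pivoting drops linearly dependent nuisance columns with a
warning; percent change uses the raw (pre-detrend) voxel mean as the
denominator for scale stability, excluding nonpositive-mean voxels from
the mask; zero-variance voxels are excluded from maps and counted;
parabolic refinements are clipped to ±half a lag; delays are clipped to
the search window; all simulations take explicit seeds and every
generator is a pure function of (parameters, seed).

## Problem sizes used by the test suite and acceptance script

The end-to-end recovery experiments run the full default study (23
subjects, 48 regions, 480 volumes) over 20 seeds in the test suite and 5
seeds in the acceptance script; delay recovery uses 600 draws; null
calibration uses one coupling-free subject volume (~4 800 in-mask
voxels) and 500 + 500 Monte-Carlo iterations for the extent threshold
and its closed-loop check. These sizes make the checks statistically
meaningful while keeping a full run on a single CPU in the minutes
range.

## Known limitations

Delay maps are unreliable where coupling is weak; the empirical null
assumes temporally white voxel noise after detrending (colored noise
would need an autoregressive null); the effective-dof closed forms are
approximations kept only for comparison; cluster-extent simulation
assumes Gaussian smoothness supplied by the user rather than estimated
residual smoothness; and the group model is a fixed-effects OLS per
region — no spatial regularization or mixed modelling across regions.
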