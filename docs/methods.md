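# Methods

This note documents the models, conventions and numerical choices behind
`wavelag`, in the order the pipeline applies them, together with what the
synthetic data generator does and does not emulate.

## Input model and pre-conditioning

The unit of analysis is a `DailySeries`: a real value per calendar day at a
strictly daily step (δt = 1 d). Files are read over their full min-to-max
date span; absent dates become explicit missing entries. Missing runs of up
to `max_gap = 7` days are bridged by linear interpolation; longer runs and
missing edges abort the run. The cap is deliberate: the analysis looks for
oscillations at periods from days to a year, and silently interpolating long
gaps would manufacture exactly the smooth cycles being tested for. Seven days
bridges the occasional instrument outage without spanning a meaningful
fraction of the shortest cycles of interest (~2 months).

Every series is standardized (mean removed, unit variance) before any
transform. Power then has the same units for every variable, significance
thresholds depend only on the fitted lag-1 autocorrelation, and all
downstream quantities are invariant to the original measurement units. The
standard deviation uses the population (denominator-n) form so that
Parseval-type checks between series variance and integrated wavelet power
hold without an n/(n−1) correction.

## The transform

Mother wavelet: Morlet, ψ₀(η) = π^(−1/4) e^(iω₀η) e^(−η²/2) with ω₀ = 6 —
the conventional compromise between time and frequency localization; at
ω₀ = 6 the wavelet's non-zero mean is ~10⁻⁹ and no admissibility correction
term is carried. Derived constants are fixed accordingly: Fourier factor
4π/(ω₀ + √(2+ω₀²)) ≈ 1.0330 (period per unit scale), e-folding time √2·s,
reconstruction factor C_δ = 0.776, ψ₀(0) = π^(−1/4).

The CWT is defined as the discrete convolution of the series with the
sampled, scaled, normalized wavelet — W_n(s) = √(δt/s) Σ ψ₀*((n′−n)δt/s) X_n′
— evaluated as a circular FFT convolution on the series zero-padded to the
next power of two, with the kernel periodized over the padded length and the
pad columns discarded afterwards. Two consequences are worth stating:

- The FFT path is algebraically identical to the direct convolution sum
  (the test suite checks agreement to 10⁻⁸; measured ~10⁻¹⁵), because both
  use the same sampled kernel. There is no separate "frequency-domain
  wavelet" discretization.
- At the smallest scales a sampled Morlet kernel aliases energy from between
  its band and the Nyquist frequency into the transform instead of dropping
  it. For red-noise-like input this roughly halves the full-band
  reconstruction error relative to sampling the wavelet's continuous Fourier
  transform, which is why the sampled-kernel definition was chosen.

Scale grid: dyadic, s_j = s₀·2^(j·δj) with s₀ = 2 d (the Nyquist-limited
smallest scale), δj = 1/12 (twelve sub-octaves — finer grids only improve
reconstruction marginally at proportional cost), and J defaulting to the
largest grid whose longest Fourier period stays within the record length.

Cone of influence: the per-time maximum trustworthy period, Fourier factor ×
√2 × distance-to-nearest-edge. Statistics reported "in-COI" use only cells
whose period is below this curve.

## Significance

CWT power is tested pointwise against an AR1 background fitted by the sample
lag-1 autocorrelation (floored at zero — the red-noise model assumes
non-negative persistence). The per-scale threshold is the theoretical AR1
spectrum at the scale's equivalent Fourier frequency times χ²₂(1−α)/2, by
default α = 0.05. The empirical size of this test on AR1(0.5) nulls of
length 1024, pooled over in-COI cells, measures ≈5.4%: slightly liberal,
the known consequence of estimating the background from the same realization
being tested, and well within the two-point tolerance used for acceptance.

Coherence has no usable closed-form null, so its significance is Monte
Carlo: per-scale thresholds are the (1−α) quantile of coherence over
independent AR1 surrogate pairs at the fitted alphas (default 300 pairs,
minimum 100, seeded and reproducible). Significance is pointwise, as is
conventional for these spectra; area-wise corrections are out of scope.

## Coherence and band selection

The smoothing operator S is a Gaussian in time with standard deviation equal
to the scale (the Morlet decorrelation width) and a boxcar over 0.6/δj scale
steps; both kernels are renormalized at the domain edges so that in-domain
mass sums to one. This keeps constants invariant, keeps R² within [0, 1] by
Cauchy–Schwarz, and makes self-coherence exactly 1 at every defined cell.

The reported band is the period whose time-averaged in-COI coherence is
maximal, one octave wide (center/√2 to center·√2), with ties broken toward
the smaller period. One eligibility rule is applied: a scale must have an
in-COI span covering at least two full cycles. At scales comparable to the
record length the smoothing window exceeds the available data, coherence
degenerates toward 1 regardless of any real relationship, and an average
over a fraction of a cycle estimates nothing; requiring two cycles removes
exactly those scales. With a four-year record this leaves all periods up to
roughly 430 days eligible, so an annual cycle can still win the selection on
merit.

## Lag estimation

Both series are reconstructed over the selected band with the standard
inversion formula (x_n = (δj√δt)/(C_δψ₀(0)) Σ Re W/√s, summed over the
band's scales). Extrema of the filtered series are local extrema with a
minimum same-type separation of half the band period (the stronger of two
competitors wins), forced to alternate peak/trough, and required to have the
sign of their type — on a zero-mean band-limited oscillation a negative
"peak" between two troughs is noise, not a cycle. Extrema in the COI-excluded
margins are discarded.

Matching is greedy-forward: each predictor extremum (peak in positive mode,
trough in negative mode) takes the earliest outcome peak at or after it and
before the predictor's next same-type extremum; unmatched extrema are
skipped. Lags are therefore non-negative by construction — the predictor is
treated as the leading indicator throughout. When the direction is not
imposed by the caller, both modes are run and the smaller mean lag wins
(ties: smaller lag standard deviation, then positive mode); the result is
flagged ambiguous when the two modes differ by under a day or the chosen lag
sits within a day of a quarter period, where peak-led and trough-led
readings are equally defensible. Reported mean lags round half away from
zero to whole days, alongside the "(min – max)" range over matched cycles.

## Synthetic data: what it emulates, what it does not

`gen_weather` produces four years (1461 days, 2012-01-01..2015-12-31
including the leap day) of configured sinusoids plus AR1 noise plus an
offset, optionally clamped non-negative for rainfall-like variables.
`gen_counts` draws integer counts around exp(log μ + β·z_{t−L}) where z is
the standardized driver, L the embedded lag, and the sign of β the
configured direction; the log link keeps rates positive without clamping.
Counts are Poisson by default with a gamma-mixture over-dispersion option,
since real outpatient counts are over-dispersed; dispersion 1 reduces
exactly to Poisson.

Defaults (the conditions all end-to-end tests run under): baseline
μ = 8.2/day, matching a ~12,000-patient four-year total for a large teaching
hospital; effect β = 0.5, a moderate exposure effect; driver = unit
quarterly (91-day) sinusoid + AR1(α = 0.5, sd 0.5); embedded lag 11 days.
The paired fixture deliberately carries its shared coherent mode at the
quarterly period: analyses of this design find their strongest
count–weather coherence at sub-annual periods, and a shared annual cycle
would dominate band selection while supporting only ~3 matched cycles of
coarse timing in a four-year record. Annual components remain available for
single-series diagnostics (see `analysis/02_wavelet_spectra.py`).

What passing tests show: the pipeline's numerics are correct (transform,
coherence, phase convention, significance calibration) and the full chain
recovers lags of 4–15 days on a quarterly cycle to ±1 day at realistic count
noise. What they do not show: robustness to features the generator omits —
epidemic shocks (e.g. influenza introductions), multi-variable confounding
between correlated weather series, non-sinusoidal cycle shapes, long missing
runs, or drifting lag structure over time. Real-data conclusions still
require the usual epidemiological caution.

## Numerical notes and limitations

- Reconstruction accuracy on the default grid is limited by spectral content
  between the smallest-scale band (period ≈ 2.07 d) and Nyquist (2 d): the
  grid cannot represent it. For red noise with α = 0.7 the expected full-band
  RMS error is ≈4.6% of series RMS (≈5% at α = 0.5), fluctuating ±1.5 points
  between realizations; acceptance checks the mean over several series.
  Redder (smoother) series reconstruct better; near-white series worse.
- Scale-smoothing uses a rounded 0.6/δj-step boxcar (7 steps at δj = 1/12).
- Zero-padding is the only edge policy (per the transform's definition
  here); no reflection option is provided.
- Circular means are used for all phase aggregation; arithmetic averaging of
  angles is wrong at the ±180° wrap.
- The two-cycle band-eligibility rule means records shorter than ~2.9×
  the period of interest cannot select that period.
- Poisson count noise puts a floor on per-cycle peak-timing jitter of
  roughly a day at the default effect size; lags under ~2 days are at the
  resolution limit of the extrema-matching estimator.
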