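# wavelag

Wavelet coherence and lag analysis between a daily health-event count series
and daily meteorological series.

## The problem

Hospital outpatient departments in the tropics see daily surges of acute
wheezing (asthma/COPD exacerbations) that trail weather swings by days. The
relationship is neither linear nor stationary: the same variable (rainfall,
say) can suppress exacerbations on one timescale and promote them on another,
and the coupling drifts over the years. Classical regression on the raw daily
series mostly sees noise. `wavelag` implements the time-frequency approach a
field epidemiologist would use instead: expand both series with the Morlet
continuous wavelet transform, find where in time-frequency space they co-vary
(wavelet coherence against a red-noise null), reconstruct both series over
the most coherent period band, and read the exposure-to-outcome lag off the
matched peaks and troughs of the filtered cycles.

The package is aimed at analysts with one outcome count series (e.g. patients
nebulized per day) and several candidate daily exposures (rainfall, min/max
temperature, diurnal temperature range, humidity, pressure, visibility, ...),
producing a per-variable table: mean lag in days, lag range, and the sign of
the association.

## The method in brief

With the Morlet mother wavelet ψ₀(η) = π^(−1/4) e^(iω₀η) e^(−η²/2) (ω₀ = 6),
the CWT of a series Xₙ with step δt is the convolution with the scaled,
normalized wavelet

    Wₙ(s) = √(δt/s) Σₙ′ Xₙ′ ψ₀*((n′−n) δt / s),

computed over a dyadic scale grid s_j = s₀·2^(j·δj) by FFT on the series
zero-padded to the next power of two. |Wₙ(s)|² is wavelet power; the cone of
influence marks where the padding contaminates the coefficients. CWT power
is tested pointwise against a fitted AR1 (red-noise) background with the
χ²₂ form at the 5% level. For two series the cross spectrum W^XY = W^X W^Y*
gives common power and the phase difference (+90° = the second series lags
by a quarter cycle), and wavelet coherence

    R²ₙ(s) = |S(s⁻¹ W^XY)|² / ( S(s⁻¹|W^X|²) · S(s⁻¹|W^Y|²) )

(S a Gaussian-in-time, boxcar-in-scale smoothing operator) is a localized
squared correlation in [0, 1], with Monte Carlo significance from AR1
surrogate pairs. Both series are then reconstructed over the one-octave band
around the period of maximum coherence via

    xₙ = (δj √δt) / (C_δ ψ₀(0)) Σ_j Re(Wₙ(s_j)) / √s_j      (C_δ = 0.776),

and each predictor extremum (peak for a positive association, trough for a
negative one) is matched to the next outcome peak; the per-cycle differences
average into the reported lag.

Because real hospital and weather records of this kind are not public, the
package ships a synthetic generator that emulates the study frame — four
years (1461 days) of daily data, annual and quarterly oscillations, AR1
noise, Poisson counts around 8.2 patients/day — with a configurable embedded
lag, so the entire pipeline is testable end to end.

## Worked example

```python
import numpy as np
from wavelag import (SyntheticConfig, gen_weather, gen_counts)
from wavelag.pipeline import AnalysisConfig, run_pair

cfg = SyntheticConfig(true_lag=11, direction="positive", seed=3)
rain = gen_weather(cfg, name="rainfall")      # quarterly cycle + red noise
counts = gen_counts(rain, cfg)                # Poisson counts, 11-day delay

acfg = AnalysisConfig(outcome_path="-", predictors=[{"path": "-"}],
                      compute_significance=False)
out = run_pair(counts, rain, acfg)
print(f"band center {out.band.center_period:.0f} d, "
      f"mean r2 {out.band.mean_r2:.2f}")
print(f"lag {out.lag.mean_lag:.1f} d ({out.lag.lag_min:.0f}-{out.lag.lag_max:.0f}), "
      f"{out.lag.direction}, {out.lag.n_cycles} cycles")
```

prints

```
band center 88 d, mean r2 0.99
lag 11.1 d (10-14), positive, 15 cycles
```

i.e. the coherence maximum is found at the quarterly (~91-day) cycle, and the
matched filtered cycles read back the embedded 11-day positive lag.

The same flow is available from the shell:

```sh
wavelag simulate --seed 3 --outdir fixture
wavelag analyze --config analysis.yaml --outdir out   # summary.csv, summary.txt, manifest.json
```

The numbered scripts under `analysis/` run the full study-shaped experiment:
`01_simulate_study.py` writes nine predictor/outcome pairs with embedded lags
of 4–15 days, `02_wavelet_spectra.py` produces single-series diagnostics
(monthly climatology, scale-averaged power), and `03_coherence_and_lags.py`
recovers the per-variable lag table (9/9 lags within ±1 day, 9/9 directions
correct, in `results/lag_recovery.csv`).

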