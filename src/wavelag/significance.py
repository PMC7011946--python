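"""Red-noise (AR1) background modelling and significance testing.

Wavelet power of a stationary AR1 process is, at each scale, distributed as
the theoretical AR1 spectrum at the scale's equivalent Fourier frequency
times chi-squared with two degrees of freedom (real and imaginary parts of
the complex coefficient) over two.  CWT/XWT significance therefore has a
closed form; wavelet-coherence significance does not, and is estimated by
Monte Carlo over AR1 surrogate pairs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2

from .io_timeseries import AlignedPair, DailySeries
from .wavelet_core import WaveletParams, WaveletSpectrum, cwt, wavelet_power

__all__ = [
    "RedNoiseModel",
    "SignificanceMask",
    "fit_ar1",
    "red_noise_spectrum",
    "cwt_significance",
    "wtc_significance",
]


@dataclass
class RedNoiseModel:
    """Lag-1 autoregressive null background."""

    alpha: float  # lag-1 autocorrelation, floored at 0
    variance: float
    n: int

    def __post_init__(self):
        if not 0.0 <= self.alpha < 1.0:
            raise ValueError("alpha must lie in [0, 1)")
        if self.variance <= 0:
            raise ValueError("variance must be positive")


@dataclass
class SignificanceMask:
    """Per-scale threshold and the cells whose statistic exceeds it."""

    threshold: np.ndarray  # per-scale
    mask: np.ndarray  # boolean (scale, time)
    level: float = 0.05
    method: str = "theoretical"

    def __post_init__(self):
        if not 0.0 < self.level < 1.0:
            raise ValueError("level must lie in (0, 1)")

    def to_frame(self, statistic: np.ndarray, periods: np.ndarray) -> pd.DataFrame:
        J, N = self.mask.shape
        return pd.DataFrame(
            {
                "time_index": np.tile(np.arange(N), J),
                "period": np.repeat(periods, N),
                "statistic": np.asarray(statistic).ravel(),
                "threshold": np.repeat(self.threshold, N),
                "significant": self.mask.ravel(),
            }
        )


def fit_ar1(s: DailySeries) -> RedNoiseModel:
    """Sample lag-1 autocorrelation (floored at 0) and sample variance."""
    if not s.is_complete:
        raise ValueError("fit_ar1 requires a complete series")
    x = s.values
    if len(x) < 30:
        raise ValueError("need at least 30 points to fit a red-noise background")
    x0 = x - x.mean()
    denom = np.dot(x0, x0)
    if denom == 0:
        raise ValueError("constant series has no autocorrelation")
    r1 = np.dot(x0[:-1], x0[1:]) / denom
    if r1 >= 1.0:
        raise ValueError(f"lag-1 autocorrelation {r1:.3f} >= 1: non-stationary input")
    return RedNoiseModel(alpha=max(float(r1), 0.0), variance=float(np.var(x)), n=len(x))


def red_noise_spectrum(m: RedNoiseModel, freq) -> np.ndarray:
    """Theoretical AR1 spectrum at normalized frequency (cycles per step).

    P(f) = variance * (1 - alpha^2) / (1 + alpha^2 - 2 alpha cos(2 pi f)),
    normalized to average to the variance over frequencies.
    """
    freq = np.asarray(freq, dtype=float)
    a = m.alpha
    return m.variance * (1.0 - a**2) / (1.0 + a**2 - 2.0 * a * np.cos(2.0 * np.pi * freq))


def cwt_significance(
    w: WaveletSpectrum, m: RedNoiseModel, level: float = 0.05
) -> SignificanceMask:
    """Pointwise chi-squared red-noise test of CWT power at the given level.

    The per-scale threshold is the AR1 spectrum at the scale's equivalent
    Fourier frequency times the (1-level) quantile of chi2(2)/2.
    """
    if not 0.0 < level < 1.0:
        raise ValueError("level must lie in (0, 1)")
    freq = w.params.dt / w.periods
    background = red_noise_spectrum(m, freq)
    threshold = background * chi2.ppf(1.0 - level, 2) / 2.0
    power = wavelet_power(w)
    return SignificanceMask(
        threshold=threshold,
        mask=power > threshold[:, None],
        level=level,
        method="theoretical",
    )


def _ar1_surrogate(n: int, alpha: float, rng: np.random.Generator) -> np.ndarray:
    from scipy.signal import lfilter

    eps = rng.normal(0.0, 1.0, n)
    # stationary start: x_0 ~ N(0, 1/(1-alpha^2))
    eps[0] = rng.normal(0.0, 1.0 / np.sqrt(1.0 - alpha**2)) if alpha > 0 else eps[0]
    x = lfilter([1.0], [1.0, -alpha], eps)
    x -= x.mean()
    sd = x.std()
    return x / sd if sd > 0 else x


def wtc_significance(
    pair: AlignedPair,
    params: WaveletParams,
    m_x: RedNoiseModel,
    m_y: RedNoiseModel,
    level: float = 0.05,
    n_surrogates: int = 300,
    seed: int = 0,
) -> SignificanceMask:
    """Monte Carlo coherence significance against independent AR1 surrogates.

    For each scale the threshold is the (1-level) quantile of coherence over
    ``n_surrogates`` independent AR1 surrogate pairs (with the fitted alphas),
    pooled over in-COI time points.  The mask flags the observed pair's
    coherence above that threshold.  Deterministic under a fixed seed.
    """
    from .cross_wavelet import wtc  # local import to avoid a cycle

    if n_surrogates < 100:
        raise ValueError("n_surrogates < 100 gives an unstable tail quantile")
    if not 0.0 < level < 1.0:
        raise ValueError("level must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    n = pair.n_common
    start = pair.x.start_date

    def _coherence(xv: np.ndarray, yv: np.ndarray):
        sx = DailySeries(start_date=start, values=xv, name="x")
        sy = DailySeries(start_date=start, values=yv, name="y")
        wx, wy = cwt(sx, params), cwt(sy, params)
        return wtc(wx, wy), wx

    pooled = None
    for i in range(n_surrogates):
        field, wx = _coherence(
            _ar1_surrogate(n, m_x.alpha, rng), _ar1_surrogate(n, m_y.alpha, rng)
        )
        inside = wx.in_coi()
        vals = np.where(inside & np.isfinite(field.r2), field.r2, np.nan)
        if pooled is None:
            pooled = np.empty((n_surrogates,) + vals.shape)
        pooled[i] = vals

    import warnings

    with warnings.catch_warnings():
        # scales entirely outside the COI have no surrogate values at all
        warnings.simplefilter("ignore", category=RuntimeWarning)
        flat = pooled.transpose(1, 0, 2).reshape(pooled.shape[1], -1)
        threshold = np.nanquantile(flat, 1.0 - level, axis=1)
    threshold = np.where(np.isfinite(threshold), threshold, np.inf)

    from .io_timeseries import standardize

    obs, wx_obs = _coherence(
        standardize(pair.x).values if pair.x.affine is None else pair.x.values,
        standardize(pair.y).values if pair.y.affine is None else pair.y.values,
    )
    mask = (obs.r2 > threshold[:, None]) & wx_obs.in_coi() & np.isfinite(obs.r2)
    return SignificanceMask(
        threshold=threshold, mask=mask, level=level, method="monte_carlo"
    )
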