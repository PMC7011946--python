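"""Cross-wavelet transform, smoothing, wavelet coherence, band selection.

The cross spectrum of two CWTs is W^XY = W^X conj(W^Y); its modulus is the
common power and its argument the local phase difference, with the sign
convention that a positive phase means the second series lags the first
(+90 degrees = a quarter cycle behind).  Coherence is the squared modulus of
the smoothed cross spectrum normalized by the two smoothed power spectra — a
localized squared correlation coefficient in time-frequency space, in [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .wavelet_core import WaveletParams, WaveletSpectrum

__all__ = [
    "CrossSpectrum",
    "CoherenceField",
    "CoherenceBand",
    "xwt",
    "smooth",
    "wtc",
    "max_coherence_band",
    "circular_mean_deg",
]


def circular_mean_deg(angles_deg) -> float:
    """Circular mean of angles in degrees, in (-180, 180]."""
    a = np.radians(np.asarray(angles_deg, dtype=float))
    m = np.degrees(np.angle(np.mean(np.exp(1j * a))))
    return float(m if m > -180.0 else 180.0)


@dataclass
class CrossSpectrum:
    """Complex XWT matrix with phase angles in degrees."""

    coefficients: np.ndarray  # complex (scale, time)
    scales: np.ndarray
    periods: np.ndarray
    coi: np.ndarray
    params: WaveletParams
    pair_names: tuple = ("x", "y")

    @property
    def power(self) -> np.ndarray:
        return np.abs(self.coefficients)

    @property
    def phase(self) -> np.ndarray:
        """Phase difference in degrees; +90 means the second series lags by a quarter cycle."""
        return np.degrees(np.angle(self.coefficients))

    def in_coi(self) -> np.ndarray:
        return self.periods[:, None] <= self.coi[None, :]


@dataclass
class CoherenceField:
    """Squared coherence in [0,1] with the smoothed cross-spectrum phase."""

    r2: np.ndarray
    phase: np.ndarray  # degrees
    scales: np.ndarray
    periods: np.ndarray
    coi: np.ndarray
    params: WaveletParams
    pair_names: tuple = ("x", "y")
    significance: object = None

    def in_coi(self) -> np.ndarray:
        return self.periods[:, None] <= self.coi[None, :]

    def to_frame(self) -> pd.DataFrame:
        J, N = self.r2.shape
        frame = pd.DataFrame(
            {
                "time_index": np.tile(np.arange(N), J),
                "period": np.repeat(self.periods, N),
                "r2": self.r2.ravel(),
                "phase_deg": self.phase.ravel(),
                "in_coi": self.in_coi().ravel(),
            }
        )
        if self.significance is not None:
            frame["significant"] = self.significance.mask.ravel()
        return frame


@dataclass
class CoherenceBand:
    """One-octave band around the period of maximum time-averaged coherence."""

    center_period: float
    period_low: float
    period_high: float
    mean_r2: float
    time_span: np.ndarray = field(default=None)  # in-COI time indices used

    def __post_init__(self):
        # edges bracket the center, with equality only where the band was
        # clipped at the scale-grid boundary
        if not (self.period_low <= self.center_period <= self.period_high):
            raise ValueError("band edges must bracket the center period")
        if not self.period_low < self.period_high:
            raise ValueError("band must have positive width")


def xwt(wx: WaveletSpectrum, wy: WaveletSpectrum) -> CrossSpectrum:
    """Cross-wavelet transform W^X * conj(W^Y) on a shared grid."""
    if wx.coefficients.shape != wy.coefficients.shape or not np.allclose(
        wx.scales, wy.scales
    ):
        raise ValueError("cross transform requires identical scale/time grids")
    return CrossSpectrum(
        coefficients=wx.coefficients * np.conj(wy.coefficients),
        scales=wx.scales,
        periods=wx.periods,
        coi=wx.coi,
        params=wx.params,
        pair_names=(wx.source_name or "x", wy.source_name or "y"),
    )


# denominator cache for edge renormalization, keyed by grid geometry
_SMOOTH_CACHE: dict = {}


def _gauss_bank(N: int, scales: np.ndarray, dt: float):
    """Per-scale truncated Gaussian kernels (rfft form) and their edge norms."""
    L = 1
    while L < 2 * N:
        L *= 2
    J = len(scales)
    bank = np.zeros((J, L))
    for j, s in enumerate(scales):
        sig = s / dt
        half = int(min(max(round(4 * sig), 1), N - 1))
        t = np.arange(-half, half + 1)
        k = np.exp(-0.5 * (t / sig) ** 2)
        k /= k.sum()
        bank[j, : 2 * half + 1] = k
        bank[j] = np.roll(bank[j], -half)
    bank_f = np.fft.rfft(bank, axis=1)
    ones = np.zeros(L)
    ones[:N] = 1.0
    den = np.fft.irfft(np.fft.rfft(ones)[None, :] * bank_f, n=L, axis=1)[:, :N]
    return bank_f, den, L


def _cached_gauss(N: int, scales: np.ndarray, dt: float):
    key = (N, scales.tobytes(), dt)
    entry = _SMOOTH_CACHE.get(key)
    if entry is None:
        entry = _gauss_bank(N, scales, dt)
        if len(_SMOOTH_CACHE) > 16:
            _SMOOTH_CACHE.clear()
        _SMOOTH_CACHE[key] = entry
    return entry


def smooth(field: np.ndarray, scales: np.ndarray, params: WaveletParams) -> np.ndarray:
    """Smoothing operator S: Gaussian in time, boxcar in scale.

    In time each scale is convolved with a Gaussian of standard deviation
    equal to that scale (the Morlet time-decorrelation width); in scale a
    moving average over 0.6/dj steps (the Morlet scale-decorrelation length)
    is applied.  Kernels are renormalized at the domain edges so that the
    mass inside the domain sums to one, which keeps a constant field exactly
    invariant and preserves the Cauchy-Schwarz bound on coherence.
    """
    field = np.asarray(field)
    J, N = field.shape
    bank_f, den, L = _cached_gauss(N, scales, params.dt)
    buf = np.zeros((J, L), dtype=complex)
    buf[:, :N] = field
    ft = np.fft.fft(buf, axis=1)
    # rebuild the full DFT of the (real) kernels from their rfft half
    full_kf = np.empty((J, L), dtype=complex)
    full_kf[:, : bank_f.shape[1]] = bank_f
    full_kf[:, bank_f.shape[1]:] = np.conj(bank_f[:, -2:0:-1])
    out = np.fft.ifft(ft * full_kf, axis=1)[:, :N] / den
    if not np.iscomplexobj(field):
        out = out.real
    # scale smoothing: renormalized boxcar over 0.6/dj steps
    win = max(1, int(round(0.6 / params.dj)))
    if win > 1:
        kern = np.ones(win)
        num = _same_conv_axis0(out, kern)
        den_s = _same_conv_axis0(np.ones((J, 1)), kern)
        out = num / den_s
    return out


def _same_conv_axis0(a: np.ndarray, kern: np.ndarray) -> np.ndarray:
    """'same'-mode convolution along axis 0 with a short real kernel."""
    from scipy.ndimage import convolve1d

    if np.iscomplexobj(a):
        return convolve1d(a.real, kern, axis=0, mode="constant") + 1j * convolve1d(
            a.imag, kern, axis=0, mode="constant"
        )
    return convolve1d(a, kern, axis=0, mode="constant")


def wtc(wx: WaveletSpectrum, wy: WaveletSpectrum) -> CoherenceField:
    """Wavelet coherence R^2_n(s) via the smoothed-spectrum formula.

    R^2 = |S(s^-1 W^XY)|^2 / (S(s^-1 |W^X|^2) * S(s^-1 |W^Y|^2)).

    Cells with a zero denominator are returned as NaN (undefined), not zero.
    Phase is carried from the smoothed cross spectrum.
    """
    if wx.coefficients.shape != wy.coefficients.shape or not np.allclose(
        wx.scales, wy.scales
    ):
        raise ValueError("coherence requires identical scale/time grids")
    params = wx.params
    sinv = 1.0 / wx.scales[:, None]
    cross = wx.coefficients * np.conj(wy.coefficients)
    s_xy = smooth(sinv * cross, wx.scales, params)
    s_xx = smooth(sinv * np.abs(wx.coefficients) ** 2, wx.scales, params)
    s_yy = smooth(sinv * np.abs(wy.coefficients) ** 2, wx.scales, params)
    denom = s_xx * s_yy
    with np.errstate(invalid="ignore", divide="ignore"):
        r2 = np.where(denom > 0, np.abs(s_xy) ** 2 / denom, np.nan)
    return CoherenceField(
        r2=r2,
        phase=np.degrees(np.angle(s_xy)),
        scales=wx.scales,
        periods=wx.periods,
        coi=wx.coi,
        params=params,
        pair_names=(wx.source_name or "x", wy.source_name or "y"),
    )


def max_coherence_band(
    c: CoherenceField,
    octaves: float = 1.0,
    min_cycles: float = 2.0,
    max_period: float | None = None,
) -> CoherenceBand:
    """Band around the period whose time-averaged in-COI coherence is maximal.

    A scale is eligible only if its in-COI span covers at least ``min_cycles``
    full cycles: at scales comparable to the record length the smoothing
    window exceeds the available data, coherence degenerates towards one, and
    a time average over a fraction of a cycle is not an estimate of anything.
    Ties are broken towards the smallest period.  The band is ``octaves``
    wide, centered geometrically, clipped to the scale grid.
    """
    inside = c.in_coi()
    if not inside.any():
        raise ValueError("no cells inside the cone of influence")
    n_in = inside.sum(axis=1)
    eligible = n_in >= min_cycles * c.periods / c.params.dt
    if max_period is not None:
        eligible &= c.periods <= max_period
    if not eligible.any():
        raise ValueError("no scale has enough in-COI cycles for band selection")
    profile = np.full(len(c.periods), -np.inf)
    for j in np.flatnonzero(eligible):
        vals = c.r2[j, inside[j]]
        vals = vals[np.isfinite(vals)]
        if vals.size:
            profile[j] = vals.mean()
    # argmax returns the first (smallest-period) maximizer: documented tie-break
    best = int(np.argmax(profile))
    center = float(c.periods[best])
    half = 2.0 ** (octaves / 2.0)
    low = max(center / half, float(c.periods[0]))
    high = min(center * half, float(c.periods[-1]))
    span = np.flatnonzero(inside[best])
    return CoherenceBand(
        center_period=center,
        period_low=low,
        period_high=high,
        mean_r2=float(profile[best]),
        time_span=span,
    )
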