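"""Independent reference computations used to cross-check the fast paths.

These deliberately avoid the library's FFT/vectorized code: the transform
oracle is a literal O(N^2 * J) evaluation of the convolution sum on the
zero-padded series (with the kernel periodized over the padded length, the
same boundary treatment the circular FFT convolution implies), and the
climatology oracle is a plain date loop.
"""

import numpy as np

from wavelag.io_timeseries import pad_to_pow2
from wavelag.wavelet_core import WaveletParams, build_scales, morlet_time


def cwt_direct(values, params: WaveletParams | None = None) -> np.ndarray:
    """Direct time-domain convolution: W_n(s) = sqrt(dt/s) sum x_n' psi0*((n'-n)dt/s)."""
    params = params or WaveletParams()
    values = np.asarray(values, dtype=float)
    padded, n_orig = pad_to_pow2(values)
    npad = len(padded)
    scales, _ = build_scales(params, n_orig)
    W = np.empty((len(scales), n_orig), dtype=complex)
    for j, s in enumerate(scales):
        wraps = int(np.ceil(6.0 * s / (npad * params.dt))) + 1
        norm = np.sqrt(params.dt / s)
        for n in range(n_orig):
            offs = np.arange(npad) - n
            acc = 0.0j
            for m in range(-wraps, wraps + 1):
                eta = (offs + m * npad) * params.dt / s
                acc += np.sum(padded * norm * np.conj(morlet_time(eta, params.omega0)))
            W[j, n] = acc
    return W


def monthly_means_naive(dates, values) -> np.ndarray:
    """Group-by-month means by explicit loop over days."""
    sums = np.zeros(12)
    counts = np.zeros(12)
    for d, v in zip(dates, values):
        sums[d.month - 1] += v
        counts[d.month - 1] += 1
    return sums / counts


def ar1_lag1_autocorr(x) -> float:
    x = np.asarray(x, dtype=float) - np.mean(x)
    return float(np.dot(x[:-1], x[1:]) / np.dot(x, x))
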