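import numpy as np
import pytest

from wavelag import (
    CDELTA,
    DailySeries,
    WaveletParams,
    build_scales,
    coi_curve,
    cwt,
    morlet_time,
    reconstruct,
    scale_avg_power,
    standardize,
    wavelet_power,
)
from wavelag.synthetic_data import gen_ar1
from wavelag.wavelet_core import fourier_factor, spectrum_to_frame

from .conftest import make_series
from .oracles import cwt_direct


class TestMorlet:
    def test_value_at_origin(self):
        v = morlet_time(0.0)
        assert v == pytest.approx(np.pi ** -0.25)
        assert np.pi ** -0.25 == pytest.approx(0.751126, abs=1e-6)

    def test_modulus_identity(self):
        for eta in (-3.0, 3.0):
            assert abs(morlet_time(eta)) == pytest.approx(
                np.pi ** -0.25 * np.exp(-4.5), rel=1e-12
            )

    def test_zero_mean(self):
        # a wavelet must integrate to (numerically) zero
        eta = np.arange(-8.0, 8.0 + 1e-9, 1e-3)
        assert abs(np.mean(morlet_time(eta))) < 1e-6


class TestScales:
    def test_one_octave_after_twelve_steps(self):
        scales, _ = build_scales(WaveletParams(s0=2.0, dj=1 / 12), N=1024)
        assert scales[12] == pytest.approx(4.0, rel=1e-12)

    def test_fourier_factor_hand_value(self):
        # 4*pi/(6 + sqrt(38)) evaluated by hand
        assert fourier_factor(6.0) == pytest.approx(1.033044, abs=1e-6)
        _, periods = build_scales(WaveletParams(), N=1024)
        scales, _ = build_scales(WaveletParams(), N=1024)
        j = np.argmin(np.abs(scales - 10))
        assert periods[j] == pytest.approx(scales[j] * 1.03304, rel=1e-4)

    def test_largest_period_within_record(self):
        for N in (512, 1024, 1461, 2048):
            _, periods = build_scales(WaveletParams(), N=N)
            assert periods[-1] <= N

    def test_explicit_overlarge_J_errors(self):
        with pytest.raises(ValueError, match="exceeds"):
            build_scales(WaveletParams(J=200), N=256)


class TestCwt:
    def test_zero_series_gives_zero_coefficients(self, make):
        w = cwt(make(np.zeros(64)))
        assert np.abs(w.coefficients).max() == 0.0

    def test_sinusoid_power_peaks_at_its_period(self):
        t = np.arange(512.0)
        s = make_series(np.sin(2 * np.pi * t / 64.0), std=True)
        w = cwt(s)
        prof = scale_avg_power(w, coi_only=True)
        best = w.periods[np.nanargmax(prof)]
        assert abs(np.log2(best / 64.0)) < 1 / 12  # nearest grid period

    def test_linearity(self, ar1_series):
        a, b = 2.5, -1.25
        x = ar1_series(128, 0.5, 1)
        y = ar1_series(128, 0.5, 2)
        combo = DailySeries(x.start_date, a * x.values + b * y.values)
        wc = cwt(combo)
        wx, wy = cwt(x), cwt(y)
        lhs = wc.coefficients
        rhs = a * wx.coefficients + b * wy.coefficients
        assert np.abs(lhs - rhs).max() <= 1e-10 * np.abs(rhs).max()

    def test_time_shift_covariance(self):
        rng = np.random.default_rng(3)
        n, k = 256, 5
        base = gen_ar1(n, 0.5, 1.0, rng)
        w1 = cwt(make_series(base))
        w2 = cwt(make_series(np.roll(base, k)))
        # shifting the input by k days shifts mid-series columns by k
        mid = slice(64, n - 64)
        shifted = np.roll(w1.coefficients, k, axis=1)[:, mid]
        assert np.abs(shifted - w2.coefficients[:, mid]).max() < 1e-6

    def test_incomplete_series_rejected(self, make):
        s = make([1.0, np.nan, 3.0, 4.0])
        with pytest.raises(ValueError, match="complete"):
            cwt(s)

    @pytest.mark.parametrize("n", [100, 256])
    def test_fft_path_matches_direct_convolution_oracle(self, n):
        rng = np.random.default_rng(n)
        s = make_series(gen_ar1(n, 0.5, 1.0, rng), std=True)
        w = cwt(s)
        oracle = cwt_direct(s.values)
        assert np.abs(w.coefficients - oracle).max() <= 1e-8


class TestPower:
    def test_power_is_squared_modulus(self, ar1_series):
        w = cwt(ar1_series(64, 0.0, 0))
        w.coefficients[0, 0] = 3 + 4j
        assert wavelet_power(w)[0, 0] == pytest.approx(25.0)

    def test_parseval_recovers_unit_variance(self, ar1_series):
        # scale-weighted global power approximates the series variance
        s = ar1_series(1024, 0.5, 11)
        w = cwt(s)
        p = w.params
        var_est = (
            p.dj * p.dt / (CDELTA * len(s)) * np.sum(wavelet_power(w) / w.scales[:, None])
        )
        assert var_est == pytest.approx(1.0, rel=0.15)

    def test_white_noise_profile_is_roughly_flat(self):
        profs = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            s = make_series(rng.normal(0, 1, 1024), std=True)
            profs.append(scale_avg_power(cwt(s), coi_only=True))
        prof = np.nanmean(profs, axis=0)
        assert np.nanmax(prof) < 5 * np.nanmedian(prof)


class TestCoi:
    def test_zero_at_edges_symmetric_monotone(self):
        c = coi_curve(200)
        assert c[0] == 0.0 and c[-1] == 0.0
        np.testing.assert_allclose(c, c[::-1], atol=1e-12)
        half = c[: len(c) // 2]
        assert np.all(np.diff(half) >= 0)

    def test_mid_series_closed_form(self):
        c = coi_curve(1461)
        expected = fourier_factor(6.0) * np.sqrt(2.0) * 730.0
        assert c[730] == pytest.approx(expected, rel=1e-12)
        assert c[730] == pytest.approx(1.0330 * np.sqrt(2) * 730, rel=1e-4)


class TestReconstruct:
    def test_full_band_recovers_ar1_series(self, ar1_series):
        s = ar1_series(1024, 0.7, 0)
        xr = reconstruct(cwt(s))
        err = np.sqrt(np.mean((xr - s.values) ** 2))
        assert err < 0.07  # a single realization; the acceptance check averages

    def test_single_band_isolates_one_component(self):
        t = np.arange(512.0)
        mix = np.sin(2 * np.pi * t / 64.0) + np.sin(2 * np.pi * t / 8.0)
        s = standardize(make_series(mix))
        w = cwt(s)
        sel = np.flatnonzero(
            (w.periods >= 64 / np.sqrt(2)) & (w.periods <= 64 * np.sqrt(2))
        )
        band = reconstruct(w, slice(int(sel[0]), int(sel[-1]) + 1))
        inside = w.coi >= 64.0
        target = np.sin(2 * np.pi * t / 64.0)
        r = np.corrcoef(band[inside], target[inside])[0, 1]
        assert r > 0.95

    def test_zero_spectrum_reconstructs_zero(self, make):
        w = cwt(make(np.zeros(128)))
        assert np.abs(reconstruct(w)).max() == 0.0

    def test_disjoint_partition_sums_to_full(self, ar1_series):
        w = cwt(ar1_series(256, 0.5, 4))
        full = reconstruct(w)
        cut = len(w.scales) // 3
        parts = (
            reconstruct(w, slice(0, cut))
            + reconstruct(w, slice(cut, 2 * cut))
            + reconstruct(w, slice(2 * cut, len(w.scales)))
        )
        np.testing.assert_allclose(parts, full, atol=1e-12)

    def test_empty_subset_errors(self, ar1_series):
        w = cwt(ar1_series(64, 0.0, 0))
        with pytest.raises(ValueError, match="empty"):
            reconstruct(w, slice(3, 3))


def test_spectrum_export_schema(ar1_series):
    w = cwt(ar1_series(64, 0.0, 2))
    frame = spectrum_to_frame(w)
    assert list(frame.columns) == [
        "time_index", "scale", "period", "re", "im", "power", "in_coi",
    ]
    assert len(frame) == len(w.scales) * 64
    np.testing.assert_allclose(frame["power"], frame["re"] ** 2 + frame["im"] ** 2)
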