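import numpy as np
import pytest

from wavelag import (
    AlignedPair,
    CoherenceBand,
    band_filter_pair,
    choose_direction,
    find_extrema,
    match_and_lag,
    summarize_table,
)
from wavelag.lag_analysis import LagResult, render_table


def _band(center=90.0):
    return CoherenceBand(
        center_period=center,
        period_low=center / np.sqrt(2),
        period_high=center * np.sqrt(2),
        mean_r2=1.0,
    )


def _sin(n, period, delay=0.0, noise=0.0, seed=0):
    t = np.arange(n, dtype=float)
    rng = np.random.default_rng(seed)
    return np.sin(2 * np.pi * (t - delay) / period) + noise * rng.normal(size=n)


class TestBandFilterPair:
    def test_pass_band_preserves_matching_sinusoid(self, make):
        n = 512
        x = make(_sin(n, 64.0), name="x")
        y = make(_sin(n, 64.0), name="y")
        pair = AlignedPair(x, y)
        fx, fy = band_filter_pair(pair, _band(64.0))
        from wavelag import coi_curve, standardize

        inside = coi_curve(n) >= 64.0
        target = standardize(x).values
        r = np.corrcoef(fx[inside], target[inside])[0, 1]
        assert r > 0.99

    def test_stop_band_attenuates_distant_period(self, make):
        n = 512
        x = make(_sin(n, 64.0), name="x")
        pair = AlignedPair(x, x)
        fx, _ = band_filter_pair(pair, _band(8.0))
        assert np.sqrt(np.mean(fx**2)) < 0.10  # input has unit RMS after standardizing

    def test_band_outside_grid_errors(self, make):
        x = make(_sin(512, 64.0), name="x")
        band = CoherenceBand(
            center_period=1.2, period_low=1.0, period_high=1.4, mean_r2=1.0
        )
        with pytest.raises(ValueError, match="outside"):
            band_filter_pair(AlignedPair(x, x), band)


class TestFindExtrema:
    def test_sinusoid_peak_count_and_spacing(self):
        z = _sin(720, 90.0)
        ext = find_extrema(z, _band(90.0))
        assert len(ext.peak_times) == 8
        spacing = np.diff(ext.peak_times)
        assert np.all(np.abs(spacing - 90) <= 2)

    def test_peaks_and_troughs_alternate(self):
        z = _sin(720, 90.0, noise=0.2, seed=1)
        ext = find_extrema(z, _band(90.0))
        events = sorted(
            [(t, "p") for t in ext.peak_times] + [(t, "t") for t in ext.trough_times]
        )
        kinds = [k for _, k in events]
        assert all(a != b for a, b in zip(kinds, kinds[1:]))

    def test_constant_series_has_no_extrema(self):
        ext = find_extrema(np.zeros(200), _band(90.0))
        assert len(ext.peak_times) == 0 and len(ext.trough_times) == 0

    def test_noisy_sinusoid_count_within_one_of_clean(self):
        clean = len(find_extrema(_sin(720, 90.0), _band(90.0)).peak_times)
        for seed in range(10):
            noisy = _sin(720, 90.0, noise=0.2, seed=seed)  # SNR ~ 5
            got = len(find_extrema(noisy, _band(90.0)).peak_times)
            assert abs(got - clean) <= 1


class TestMatchAndLag:
    def test_recovers_constructed_five_day_delay(self):
        x = find_extrema(_sin(720, 90.0), _band(90.0), name="x")
        y = find_extrema(_sin(720, 90.0, delay=5.0), _band(90.0), name="y")
        r = match_and_lag(x, y, "peak_to_peak")
        assert r.mean_lag == pytest.approx(5.0, abs=1.0)
        assert r.direction == "positive"
        assert np.all(r.per_cycle_lags >= 0)

    def test_sign_flipped_pair_in_trough_mode(self):
        x = find_extrema(-_sin(720, 90.0), _band(90.0), name="x")
        y = find_extrema(_sin(720, 90.0, delay=5.0), _band(90.0), name="y")
        r = match_and_lag(x, y, "trough_to_peak")
        assert r.mean_lag == pytest.approx(5.0, abs=1.0)
        assert r.direction == "negative"

    def test_self_match_is_zero_lag(self):
        e = find_extrema(_sin(720, 90.0), _band(90.0), name="x")
        r = match_and_lag(e, e, "peak_to_peak")
        assert r.mean_lag == 0.0 and r.lag_min == 0.0 and r.lag_max == 0.0

    def test_role_reversal_maps_lag_to_period_minus_lag(self):
        lag = 20.0
        x = find_extrema(_sin(900, 90.0), _band(90.0), name="x")
        y = find_extrema(_sin(900, 90.0, delay=lag), _band(90.0), name="y")
        fwd = match_and_lag(x, y, "peak_to_peak")
        rev = match_and_lag(y, x, "peak_to_peak")
        assert fwd.mean_lag + rev.mean_lag == pytest.approx(90.0, abs=2.0)

    def test_shifting_both_series_leaves_lags_unchanged(self):
        for shift in (0.0, 17.0):
            x = find_extrema(_sin(900, 90.0, delay=shift), _band(90.0), name="x")
            y = find_extrema(_sin(900, 90.0, delay=shift + 9.0), _band(90.0), name="y")
            r = match_and_lag(x, y, "peak_to_peak")
            assert r.mean_lag == pytest.approx(9.0, abs=1.0)

    def test_no_matches_errors(self):
        x = find_extrema(_sin(720, 90.0), _band(90.0), name="x")
        empty = find_extrema(np.zeros(720), _band(90.0), name="y")
        with pytest.raises(ValueError):
            match_and_lag(x, empty, "peak_to_peak")


class TestChooseDirection:
    def test_in_phase_pair_is_positive(self):
        correct = 0
        for seed in range(20):
            x = find_extrema(_sin(900, 90.0, noise=0.2, seed=seed), _band(90.0), name="x")
            y = find_extrema(
                _sin(900, 90.0, delay=5.0, noise=0.2, seed=100 + seed), _band(90.0), name="y"
            )
            if choose_direction(x, y).direction == "positive":
                correct += 1
        assert correct == 20

    def test_anti_phase_pair_is_negative(self):
        correct = 0
        for seed in range(20):
            x = find_extrema(-_sin(900, 90.0, noise=0.2, seed=seed), _band(90.0), name="x")
            y = find_extrema(
                _sin(900, 90.0, delay=5.0, noise=0.2, seed=200 + seed), _band(90.0), name="y"
            )
            if choose_direction(x, y).direction == "negative":
                correct += 1
        assert correct == 20

    def test_quarter_cycle_pair_is_deterministic_and_flagged(self):
        x = find_extrema(_sin(900, 90.0), _band(90.0), name="x")
        y = find_extrema(_sin(900, 90.0, delay=22.5), _band(90.0), name="y")
        a = choose_direction(x, y)
        b = choose_direction(x, y)
        assert (a.direction, a.mean_lag) == (b.direction, b.mean_lag)
        assert a.ambiguous


class TestSummarizeTable:
    def test_table_row_layout(self):
        r = LagResult(
            variable="Rainfall",
            mean_lag=11.2,
            lag_min=8.0,
            lag_max=15.0,
            per_cycle_lags=[8.0, 11.0, 15.0, 10.8],
            direction="positive",
            matched_mode="peak_to_peak",
        )
        table = summarize_table([r])
        row = table.iloc[0]
        assert row["mean_lag_days"] == 11
        assert row["lag_range"] == "(8 – 15)"
        assert "Positive Correlation" in row["correlation"]
        txt = render_table(table)
        assert "Rainfall" in txt and "11 (8 – 15)" in txt

    def test_half_rounds_away_from_zero(self):
        r = LagResult(
            variable="x",
            mean_lag=4.5,
            lag_min=4.0,
            lag_max=5.0,
            per_cycle_lags=[4.0, 5.0],
            direction="positive",
            matched_mode="peak_to_peak",
        )
        assert summarize_table([r]).iloc[0]["mean_lag_days"] == 5

    def test_empty_input_errors(self):
        with pytest.raises(ValueError):
            summarize_table([])
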