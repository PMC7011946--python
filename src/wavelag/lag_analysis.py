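"""Band filtering, extrema detection, cycle matching, and lag summaries.

Once the maximum-coherence band is known, both series are reconstructed over
that band only, extrema of the filtered predictor are matched forward to the
next outcome peak within the same cycle, and the per-cycle time differences
are averaged into a mean lag with its range — one table row per variable,
labelled positive (outcome peaks follow predictor peaks) or negative
(outcome peaks follow predictor troughs).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .cross_wavelet import CoherenceBand
from .io_timeseries import AlignedPair, standardize
from .wavelet_core import WaveletParams, cwt, reconstruct

__all__ = [
    "ExtremaList",
    "LagResult",
    "band_filter_pair",
    "find_extrema",
    "match_and_lag",
    "choose_direction",
    "summarize_table",
    "render_table",
]


@dataclass
class ExtremaList:
    """Alternating peaks and troughs of a band-filtered series."""

    peak_times: np.ndarray
    trough_times: np.ndarray
    band: CoherenceBand
    series_name: str = ""


@dataclass
class LagResult:
    """The schema of one summary-table row."""

    variable: str
    mean_lag: float
    lag_min: float
    lag_max: float
    per_cycle_lags: np.ndarray
    n_cycles: int = field(init=False)
    direction: str = "positive"  # positive | negative
    matched_mode: str = "peak_to_peak"  # peak_to_peak | trough_to_peak
    ambiguous: bool = False

    def __post_init__(self):
        self.per_cycle_lags = np.asarray(self.per_cycle_lags, dtype=float)
        self.n_cycles = len(self.per_cycle_lags)
        if not (self.lag_min <= self.mean_lag <= self.lag_max):
            raise ValueError("mean lag must lie within [lag_min, lag_max]")
        expected = "positive" if self.matched_mode == "peak_to_peak" else "negative"
        if self.direction != expected:
            raise ValueError("direction label inconsistent with matched mode")


def band_filter_pair(
    pair: AlignedPair, band: CoherenceBand, params: WaveletParams | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Reconstruct both series over the band's scale range.

    Series are standardized first (the filter output is on the standardized
    scale; extrema timing is unaffected).  Raises if the band lies outside
    the scale grid.
    """
    params = params or WaveletParams()

    def _one(s):
        s = standardize(s) if s.affine is None else s
        w = cwt(s, params)
        sel = np.flatnonzero((w.periods >= band.period_low) & (w.periods <= band.period_high))
        if sel.size == 0:
            raise ValueError(
                f"band [{band.period_low:.1f}, {band.period_high:.1f}] days is "
                "outside the scale grid"
            )
        return reconstruct(w, slice(int(sel[0]), int(sel[-1]) + 1))

    return _one(pair.x), _one(pair.y)


def find_extrema(filtered: np.ndarray, band: CoherenceBand, name: str = "") -> ExtremaList:
    """Local extrema with half-period minimum separation and forced alternation.

    Among competing same-type extrema within the separation window the larger
    absolute value wins; if two same-type extrema remain consecutive after
    that, the weaker is dropped so peaks and troughs strictly alternate.
    Because the input is a zero-mean band-filtered oscillation, a peak must
    lie above zero and a trough below — a negative local maximum between two
    troughs is noise, not a cycle peak.
    """
    z = np.asarray(filtered, dtype=float)
    if len(z) < band.center_period:
        raise ValueError("series shorter than one band period")
    sep = max(1, int(round(band.center_period / 2.0)))

    def _select(sign: float) -> list[int]:
        v = sign * z
        cand = [
            i
            for i in range(1, len(v) - 1)
            if v[i] >= v[i - 1] and v[i] > v[i + 1] and v[i] > 0.0
        ]
        kept: list[int] = []
        for i in sorted(cand, key=lambda i: -v[i]):
            if all(abs(i - k) >= sep for k in kept):
                kept.append(i)
        return sorted(kept)

    peaks, troughs = _select(+1.0), _select(-1.0)
    events = sorted(
        [(t, "p") for t in peaks] + [(t, "t") for t in troughs], key=lambda e: e[0]
    )
    # enforce alternation: of two consecutive same-type extrema keep the stronger
    cleaned: list[tuple[int, str]] = []
    for t, kind in events:
        if cleaned and cleaned[-1][1] == kind:
            prev = cleaned[-1][0]
            better = t if abs(z[t]) > abs(z[prev]) else prev
            cleaned[-1] = (better, kind)
        else:
            cleaned.append((t, kind))
    return ExtremaList(
        peak_times=np.array([t for t, k in cleaned if k == "p"], dtype=int),
        trough_times=np.array([t for t, k in cleaned if k == "t"], dtype=int),
        band=band,
        series_name=name,
    )


def match_and_lag(
    x_extrema: ExtremaList,
    y_extrema: ExtremaList,
    mode: str = "peak_to_peak",
    band: CoherenceBand | None = None,
    variable: str = "",
) -> LagResult:
    """Match predictor extrema forward to outcome peaks and average the lags.

    Each predictor extremum (peak in ``peak_to_peak`` mode, trough in
    ``trough_to_peak``) is matched to the earliest outcome peak at or after
    it and strictly before the predictor's next same-type extremum; unmatched
    extrema are skipped.  Per-cycle lag = outcome peak time - predictor
    extremum time, all >= 0 by construction (the predictor leads).
    """
    if mode not in ("peak_to_peak", "trough_to_peak"):
        raise ValueError(f"unknown mode {mode!r}")
    src = x_extrema.peak_times if mode == "peak_to_peak" else x_extrema.trough_times
    dst = np.asarray(y_extrema.peak_times)
    if len(src) == 0 or len(dst) == 0:
        raise ValueError(f"no extrema to match in mode {mode}")
    lags = []
    for i, t in enumerate(src):
        nxt = src[i + 1] if i + 1 < len(src) else np.inf
        cand = dst[(dst >= t) & (dst < nxt)]
        if cand.size:
            lags.append(float(cand[0] - t))
    if not lags:
        raise ValueError("no overlapping cycles: zero matches")
    lags = np.asarray(lags)
    return LagResult(
        variable=variable or x_extrema.series_name,
        mean_lag=float(lags.mean()),
        lag_min=float(lags.min()),
        lag_max=float(lags.max()),
        per_cycle_lags=lags,
        direction="positive" if mode == "peak_to_peak" else "negative",
        matched_mode=mode,
    )


def choose_direction(
    x_extrema: ExtremaList,
    y_extrema: ExtremaList,
    variable: str = "",
) -> LagResult:
    """Run both matching modes and keep the one with the smaller mean lag.

    Ties (equal means) are broken by the smaller lag standard deviation, then
    towards ``peak_to_peak``.  The result is flagged ambiguous when the two
    modes differ by less than one day, or when the chosen lag sits within a
    day of a quarter period (a 90-degree phase offset, where peak-led and
    trough-led readings are equally defensible).
    """
    results = {}
    for mode in ("peak_to_peak", "trough_to_peak"):
        try:
            results[mode] = match_and_lag(x_extrema, y_extrema, mode, variable=variable)
        except ValueError:
            pass
    if not results:
        raise ValueError("neither matching mode produced any matched cycle")
    if len(results) == 1:
        return next(iter(results.values()))

    def _key(mode):
        r = results[mode]
        return (r.mean_lag, float(np.std(r.per_cycle_lags)), mode != "peak_to_peak")

    best = min(results, key=_key)
    chosen = results[best]
    other = results["trough_to_peak" if best == "peak_to_peak" else "peak_to_peak"]
    quarter = x_extrema.band.center_period / 4.0
    if (
        abs(chosen.mean_lag - other.mean_lag) < 1.0
        or abs(chosen.mean_lag - quarter) <= 1.0
    ):
        chosen = replace(chosen, per_cycle_lags=chosen.per_cycle_lags, ambiguous=True)
    return chosen


def _round_half_away(x: float) -> int:
    return int(np.floor(abs(x) + 0.5) * np.sign(x))


def _direction_sentence(r: LagResult) -> str:
    what = "peak" if r.direction == "positive" else "trough"
    label = "Positive" if r.direction == "positive" else "Negative"
    return (
        f"A {what} of {r.variable} is followed by a peak of the count of "
        f"patients. ({label} Correlation)"
    )


def summarize_table(results: list[LagResult]) -> pd.DataFrame:
    """One row per variable: name, rounded mean lag, '(min – max)' range, direction.

    Mean lags round half away from zero to the nearest day.
    """
    if not results:
        raise ValueError("nothing to summarize")
    rows = []
    for r in results:
        rows.append(
            {
                "variable": r.variable,
                "mean_lag_days": _round_half_away(r.mean_lag),
                "lag_range": f"({_round_half_away(r.lag_min)} – {_round_half_away(r.lag_max)})",
                "n_cycles": r.n_cycles,
                "direction": r.direction,
                "correlation": _direction_sentence(r),
                "ambiguous": r.ambiguous,
            }
        )
    return pd.DataFrame(rows)


def render_table(table: pd.DataFrame) -> str:
    """Aligned-text rendering of the three-column summary."""
    lines = []
    header = ("Daily Meteorological Parameter", "Average lag in days (range)", "Correlation")
    w0 = max(len(header[0]), *(len(str(v)) for v in table["variable"]))
    col1 = [f"{m} {r}" for m, r in zip(table["mean_lag_days"], table["lag_range"])]
    w1 = max(len(header[1]), *(len(c) for c in col1))
    lines.append(f"{header[0]:<{w0}}  {header[1]:<{w1}}  {header[2]}")
    for (_, row), c1 in zip(table.iterrows(), col1):
        flag = " [ambiguous direction]" if row["ambiguous"] else ""
        lines.append(f"{row['variable']:<{w0}}  {c1:<{w1}}  {row['correlation']}{flag}")
    return "\n".join(lines)
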