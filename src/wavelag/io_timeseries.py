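"""Daily time-series containers, file I/O, and pre-conditioning.

Everything downstream (wavelet transforms, coherence, lag matching) assumes a
complete, uniformly daily-sampled, standardized series.  This module owns the
path from a delimited text file of dated observations to that object: reading
with gap detection, bounded linear gap-filling, standardization, zero-padding
to a power of two, calendar-month climatology, and pairwise date alignment.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "DailySeries",
    "AlignedPair",
    "read_daily_series",
    "write_daily_series",
    "fill_gaps",
    "standardize",
    "pad_to_pow2",
    "monthly_climatology",
    "align_pair",
]


@dataclass
class DailySeries:
    """A real-valued sequence sampled once per calendar day.

    Parameters
    ----------
    start_date : datetime.date
        Calendar date of the first sample.
    values : ndarray of float
        One value per day.  Entries at masked positions are NaN.
    missing_mask : ndarray of bool
        True where the value is missing.  After gap-filling this is all False.
    name : str
        Variable label used in reports.
    units : str
        Physical units, free text.
    affine : tuple of (float, float) or None
        ``(mean, sd)`` removed by :func:`standardize`, retrievable for
        back-transformation; None for raw series.
    """

    start_date: _dt.date
    values: np.ndarray
    missing_mask: np.ndarray = None
    name: str = ""
    units: str = ""
    affine: tuple | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.missing_mask is None:
            self.missing_mask = np.isnan(self.values)
        self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
        if self.values.ndim != 1 or self.values.shape != self.missing_mask.shape:
            raise ValueError("values and missing_mask must be 1-d and equal length")
        if len(self.values) < 2:
            raise ValueError("a daily series needs at least two days")

    def __len__(self) -> int:
        return len(self.values)

    @property
    def n(self) -> int:
        return len(self.values)

    @property
    def end_date(self) -> _dt.date:
        return self.start_date + _dt.timedelta(days=len(self) - 1)

    @property
    def dates(self) -> pd.DatetimeIndex:
        return pd.date_range(self.start_date, periods=len(self), freq="D")

    @property
    def is_complete(self) -> bool:
        return not self.missing_mask.any()


@dataclass
class AlignedPair:
    """A predictor/outcome pair truncated to a common date span."""

    x: DailySeries
    y: DailySeries
    n_common: int = field(init=False)

    def __post_init__(self):
        if self.x.start_date != self.y.start_date or len(self.x) != len(self.y):
            raise ValueError("aligned series must share start date and length")
        self.n_common = len(self.x)


def read_daily_series(
    path,
    date_column: str = "date",
    value_column: str = "value",
    name: str = "",
    units: str = "",
    delimiter: str = ",",
) -> DailySeries:
    """Read a dated value column from a delimited text file.

    The returned series covers the full min-to-max date span of the file;
    dates absent from the file become missing entries.  Row order in the
    file is irrelevant.

    Raises
    ------
    ValueError
        On duplicate dates with conflicting values (naming the date) or on
        an unparseable value (naming the row).
    """
    df = pd.read_csv(path, sep=delimiter)
    if date_column not in df.columns or value_column not in df.columns:
        raise ValueError(
            f"{path}: expected columns {date_column!r} and {value_column!r}, "
            f"found {list(df.columns)}"
        )
    try:
        dates = pd.to_datetime(df[date_column], format="ISO8601")
    except (ValueError, TypeError) as exc:
        raise ValueError(f"{path}: unparseable date: {exc}") from exc
    raw = df[value_column]
    vals = pd.to_numeric(raw, errors="coerce")
    bad = vals.isna() & raw.notna() & (raw.astype(str).str.strip() != "")
    if bad.any():
        row = int(np.flatnonzero(bad)[0])
        raise ValueError(
            f"{path}: unparseable value {raw.iloc[row]!r} in data row {row + 1}"
        )
    frame = pd.DataFrame({"date": dates.dt.normalize(), "value": vals})
    dupes = frame[frame.duplicated("date", keep=False)]
    if not dupes.empty:
        conflicting = dupes.groupby("date")["value"].nunique(dropna=False) > 1
        if conflicting.any():
            when = conflicting[conflicting].index[0].date()
            raise ValueError(f"{path}: conflicting duplicate values for date {when}")
        frame = frame.drop_duplicates("date")
    frame = frame.set_index("date").sort_index()
    full = pd.date_range(frame.index.min(), frame.index.max(), freq="D")
    series = frame["value"].reindex(full)
    return DailySeries(
        start_date=full[0].date(),
        values=series.to_numpy(dtype=float),
        name=name or value_column,
        units=units,
    )


def write_daily_series(s: DailySeries, path, delimiter: str = ",") -> None:
    """Write ``date,value`` rows; missing entries get empty value fields."""
    out = pd.DataFrame(
        {
            "date": s.dates.strftime("%Y-%m-%d"),
            "value": [("" if m else repr(float(v))) for v, m in zip(s.values, s.missing_mask)],
        }
    )
    out.to_csv(path, sep=delimiter, index=False)


def fill_gaps(s: DailySeries, max_gap: int = 7) -> DailySeries:
    """Linearly interpolate missing runs of length <= ``max_gap`` days.

    Longer runs, or missing values at either end of the record (which would
    need extrapolation), are hard errors: silently bridging long gaps would
    fabricate oscillations at the very periods the analysis inspects.
    """
    if s.is_complete:
        return replace(s, values=s.values.copy(), missing_mask=s.missing_mask.copy())
    mask = s.missing_mask
    if mask[0] or mask[-1]:
        raise ValueError(f"{s.name or 'series'}: missing values at the record edge")
    idx = np.flatnonzero(mask)
    splits = np.split(idx, np.flatnonzero(np.diff(idx) > 1) + 1)
    for run in splits:
        if len(run) > max_gap:
            a = s.start_date + _dt.timedelta(days=int(run[0]))
            b = s.start_date + _dt.timedelta(days=int(run[-1]))
            raise ValueError(
                f"{s.name or 'series'}: missing run {a}..{b} "
                f"({len(run)} days) exceeds max_gap={max_gap}"
            )
    obs = np.flatnonzero(~mask)
    vals = s.values.copy()
    vals[mask] = np.interp(np.flatnonzero(mask), obs, s.values[obs])
    return replace(s, values=vals, missing_mask=np.zeros_like(mask))


def standardize(s: DailySeries) -> DailySeries:
    """Remove the mean and scale to unit population standard deviation.

    Uses the n-denominator standard deviation so Parseval-type power checks
    are exact.  The removed ``(mean, sd)`` pair is stored on the result's
    ``affine`` attribute.
    """
    if not s.is_complete:
        raise ValueError("standardize requires a complete series; fill gaps first")
    mean = float(np.mean(s.values))
    sd = float(np.std(s.values))  # population form, ddof=0
    if sd == 0.0:
        raise ValueError(f"{s.name or 'series'}: constant series has zero variance")
    return replace(
        s,
        values=(s.values - mean) / sd,
        missing_mask=np.zeros(len(s), dtype=bool),
        affine=(mean, sd),
    )


def pad_to_pow2(values) -> tuple[np.ndarray, int]:
    """Zero-pad to the next power of two; return (padded, original_length)."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("cannot pad an empty sequence")
    n = len(values)
    p = 1
    while p < n:
        p *= 2
    out = np.zeros(p, dtype=float)
    out[:n] = values
    return out, n


def monthly_climatology(s: DailySeries) -> np.ndarray:
    """Mean of daily values per calendar month, pooled across all years.

    All days are weighted equally (months with more days in the record
    contribute every one of them).  A month with no observations is an error.
    """
    if (s.end_date - s.start_date).days + 1 < 365:
        raise ValueError("climatology needs at least one full calendar year")
    frame = pd.Series(s.values, index=s.dates)
    frame = frame[~np.asarray(s.missing_mask)]
    by_month = frame.groupby(frame.index.month).mean()
    if len(by_month) < 12:
        missing = sorted(set(range(1, 13)) - set(by_month.index))
        raise ValueError(f"no observations in calendar month(s) {missing}")
    return by_month.sort_index().to_numpy()


def align_pair(x: DailySeries, y: DailySeries, min_overlap: int = 64) -> AlignedPair:
    """Truncate both series to the intersection of their date spans."""
    start = max(x.start_date, y.start_date)
    end = min(x.end_date, y.end_date)
    overlap = (end - start).days + 1
    if overlap < min_overlap:
        raise ValueError(
            f"date spans of {x.name!r} and {y.name!r} overlap by {max(overlap, 0)} "
            f"days; need at least {min_overlap}"
        )

    def _cut(s: DailySeries) -> DailySeries:
        i0 = (start - s.start_date).days
        i1 = i0 + overlap
        return replace(
            s,
            start_date=start,
            values=s.values[i0:i1].copy(),
            missing_mask=s.missing_mask[i0:i1].copy(),
        )

    return AlignedPair(x=_cut(x), y=_cut(y))
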