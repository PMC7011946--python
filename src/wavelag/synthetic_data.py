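"""Study-shaped synthetic daily series with a known embedded lag.

The generator emulates the frame of a four-year hospital/weather record
(1461 days, 2012-01-01..2015-12-31 including the leap day): meteorological
series as sums of configured sinusoids (annual, quarterly, ...) plus AR1 red
noise, and an outcome count series drawn around a log-linear transform of
the standardized driver delayed by a configurable number of days.  Counts
are Poisson by default, with a negative-binomial-style over-dispersion
option, and the default baseline of 8.2 patients/day puts the four-year
total near twelve thousand.

The default paired fixture carries its coherent mode at the quarterly
(91-day) period — the cycle length at which the coherence between counts
and weather is strongest in records of this kind — so that the embedded
daily lag is recoverable at daily resolution.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.signal import lfilter

from .io_timeseries import DailySeries, write_daily_series

__all__ = ["SyntheticConfig", "gen_ar1", "gen_weather", "gen_counts", "gen_study_fixture"]


@dataclass
class SyntheticConfig:
    """Parameters of one synthetic predictor/outcome pair.

    components
        (period days, amplitude, phase degrees) of each embedded sinusoid.
        The default is a unit-amplitude quarterly cycle, the shared mode on
        which the lag is embedded.
    ar1_alpha, noise_sd
        Lag-1 autocorrelation and innovation-equivalent sd of the additive
        red noise in the predictor.
    true_lag, direction
        The embedded predictor-to-outcome delay in days and the sign of the
        association (positive: counts rise after predictor peaks).
    beta
        Log-link effect size of the standardized driver on the daily rate.
    count_baseline, count_dispersion
        Mean daily count (8.2/day over 1461 days gives ~12,000 patients) and
        variance inflation (1 = Poisson).
    """

    n_days: int = 1461
    start_date: _dt.date = _dt.date(2012, 1, 1)
    components: tuple = ((91.0, 1.0, 0.0),)
    ar1_alpha: float = 0.5
    noise_sd: float = 0.5
    offset: float = 0.0
    clamp_nonnegative: bool = False
    true_lag: int = 11
    direction: str = "positive"
    beta: float = 0.5
    count_baseline: float = 8.2
    count_dispersion: float = 1.0
    seed: int = 0

    def __post_init__(self):
        for period, _, _ in self.components:
            if not 2.0 <= period <= self.n_days / 2.0:
                raise ValueError(
                    f"component period {period} must lie in [2, n_days/2]"
                )
        if not 0.0 <= self.ar1_alpha < 1.0:
            raise ValueError("ar1_alpha must lie in [0, 1)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.true_lag < 0:
            raise ValueError("true_lag must be >= 0")
        if self.direction not in ("positive", "negative"):
            raise ValueError("direction must be 'positive' or 'negative'")
        if self.count_baseline <= 0 or self.count_dispersion < 1.0:
            raise ValueError("count_baseline > 0 and count_dispersion >= 1 required")


def gen_ar1(n: int, alpha: float, sd: float, seed) -> np.ndarray:
    """Stationary AR1: x_t = alpha x_{t-1} + eps_t, eps ~ N(0, sd^2)."""
    if not 0.0 <= alpha < 1.0:
        raise ValueError("alpha must lie in [0, 1)")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    if sd == 0.0:
        return np.zeros(n)
    eps = rng.normal(0.0, sd, n)
    if alpha > 0:  # stationary initialization
        eps[0] = rng.normal(0.0, sd / np.sqrt(1.0 - alpha**2))
    return lfilter([1.0], [1.0, -alpha], eps)


def _components_signal(config: SyntheticConfig) -> np.ndarray:
    t = np.arange(config.n_days, dtype=float)
    sig = np.zeros(config.n_days)
    for period, amplitude, phase_deg in config.components:
        sig += amplitude * np.sin(2.0 * np.pi * t / period + np.radians(phase_deg))
    return sig


def gen_weather(config: SyntheticConfig, name: str = "predictor", units: str = "") -> DailySeries:
    """Deterministic sinusoids + AR1 noise + offset, optionally clamped at 0."""
    rng = np.random.default_rng(config.seed)
    vals = (
        _components_signal(config)
        + gen_ar1(config.n_days, config.ar1_alpha, config.noise_sd, rng)
        + config.offset
    )
    if config.clamp_nonnegative:
        vals = np.maximum(vals, 0.0)
    return DailySeries(start_date=config.start_date, values=vals, name=name, units=units)


def gen_counts(driver: DailySeries, config: SyntheticConfig, name: str = "counts") -> DailySeries:
    """Integer daily counts around exp(log(baseline) + beta * z_{t - lag}).

    ``z`` is the standardized driver; the sign of beta follows
    ``config.direction``.  Counts are Poisson draws, mixed with a gamma
    multiplier when ``count_dispersion`` > 1 (negative-binomial style), and
    are independent given the driver.  The lagged driver is held at its first
    value for the initial ``true_lag`` days.
    """
    if not driver.is_complete:
        raise ValueError("driver must be complete")
    n = len(driver)
    if config.true_lag >= n:
        raise ValueError("true_lag must be shorter than the driver")
    # the count stream must not disturb the weather stream: derive a child seed
    rng = np.random.default_rng((int(config.seed), "counts".encode()[0]))
    z = (driver.values - driver.values.mean()) / driver.values.std()
    lag = config.true_lag
    zl = np.concatenate([np.repeat(z[0], lag), z[: n - lag]]) if lag else z
    beta = config.beta if config.direction == "positive" else -config.beta
    lam = config.count_baseline * np.exp(beta * zl)
    if config.count_dispersion > 1.0:
        # gamma-Poisson mixture: Var = lam * dispersion
        shape = lam / (config.count_dispersion - 1.0)
        lam = rng.gamma(shape, config.count_dispersion - 1.0)
    counts = rng.poisson(lam).astype(float)
    return DailySeries(
        start_date=driver.start_date, values=counts, name=name, units="patients/day"
    )


def gen_study_fixture(
    config: SyntheticConfig,
    outdir,
    weather_name: str = "predictor",
) -> tuple[Path, Path]:
    """Write a weather CSV and a counts CSV embedding the configured lag."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    weather = gen_weather(config, name=weather_name)
    counts = gen_counts(weather, config)
    wpath = outdir / f"{weather_name}.csv"
    cpath = outdir / "counts.csv"
    write_daily_series(weather, wpath)
    write_daily_series(counts, cpath)
    return wpath, cpath
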