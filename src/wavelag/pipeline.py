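"""Orchestration: one outcome series against many predictors, Table-style report.

`run_pair` executes the full chain for one predictor — read, gap-fill, align,
standardize, CWT of both series, cross-wavelet transform, coherence (with
optional Monte Carlo significance), maximum-coherence band selection, band
filtering, extrema matching — and `run_all` repeats it per predictor with
per-pair isolation, writing a summary CSV, an aligned-text table, and a JSON
manifest of parameters and seeds so every number is reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import cross_wavelet, lag_analysis, significance, wavelet_core
from .io_timeseries import (
    DailySeries,
    align_pair,
    fill_gaps,
    read_daily_series,
    standardize,
)
from .wavelet_core import WaveletParams

log = logging.getLogger("wavelag")

__all__ = ["AnalysisConfig", "PairOutput", "run_pair", "run_all"]


@dataclass
class PredictorSpec:
    path: str
    label: str = ""
    direction_hint: str | None = None  # positive | negative | None (auto)

    def __post_init__(self):
        if not self.label:
            self.label = Path(self.path).stem
        if self.direction_hint not in (None, "positive", "negative"):
            raise ValueError("direction_hint must be positive, negative or omitted")


@dataclass
class AnalysisConfig:
    """Configuration of one multi-predictor analysis."""

    outcome_path: str
    predictors: list  # of PredictorSpec or dict
    params: WaveletParams = field(default_factory=WaveletParams)
    level: float = 0.05
    n_surrogates: int = 300
    compute_significance: bool = True
    band_octaves: float = 1.0
    max_gap: int = 7
    seed: int = 0
    outdir: str = "wavelag_out"

    def __post_init__(self):
        if not self.predictors:
            raise ValueError("at least one predictor is required")
        self.predictors = [
            p if isinstance(p, PredictorSpec) else PredictorSpec(**p)
            for p in self.predictors
        ]
        if not 0.0 < self.level < 1.0:
            raise ValueError("level must lie in (0, 1)")

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh)
        params = WaveletParams(**raw.pop("params", {}))
        return cls(params=params, **raw)


@dataclass
class PairOutput:
    label: str
    spectrum_x: wavelet_core.WaveletSpectrum
    spectrum_y: wavelet_core.WaveletSpectrum
    cross: cross_wavelet.CrossSpectrum
    coherence: cross_wavelet.CoherenceField
    band: cross_wavelet.CoherenceBand
    lag: lag_analysis.LagResult


def _sha1(path) -> str:
    h = hashlib.sha1()
    with open(path, "rb") as fh:
        h.update(fh.read())
    return h.hexdigest()


def _prepare(path, label, max_gap, date_column="date", value_column="value") -> DailySeries:
    series = read_daily_series(path, date_column, value_column, name=label)
    return fill_gaps(series, max_gap=max_gap)


def run_pair(
    outcome: DailySeries,
    predictor: DailySeries,
    config: AnalysisConfig,
    direction_hint: str | None = None,
    outdir: Path | None = None,
) -> PairOutput:
    """Full analysis of one (predictor, outcome) pair.

    The predictor is series 1 and the outcome series 2 throughout, so a
    positive cross-wavelet phase means the outcome lags the predictor.
    """
    label = predictor.name or "predictor"
    log.info("pair %s: aligning", label)
    pair = align_pair(predictor, outcome)
    x = standardize(pair.x)
    y = standardize(pair.y)
    params = config.params
    wx = wavelet_core.cwt(x, params)
    wy = wavelet_core.cwt(y, params)
    cross = cross_wavelet.xwt(wx, wy)
    coh = cross_wavelet.wtc(wx, wy)
    if config.compute_significance:
        log.info("pair %s: Monte Carlo coherence significance", label)
        m_x, m_y = significance.fit_ar1(x), significance.fit_ar1(y)
        std_pair = align_pair(x, y)
        coh.significance = significance.wtc_significance(
            std_pair,
            params,
            m_x,
            m_y,
            level=config.level,
            n_surrogates=config.n_surrogates,
            seed=config.seed,
        )
    band = cross_wavelet.max_coherence_band(coh, octaves=config.band_octaves)
    fx, fy = lag_analysis.band_filter_pair(align_pair(x, y), band, params)
    # discard extrema inside the COI-excluded margins before matching
    inside = np.flatnonzero(wx.coi >= band.center_period)
    if inside.size == 0:
        raise ValueError(f"pair {label}: band period never inside the COI")
    lo_t, hi_t = int(inside[0]), int(inside[-1])

    def _trim(ext):
        keep_p = ext.peak_times[(ext.peak_times >= lo_t) & (ext.peak_times <= hi_t)]
        keep_t = ext.trough_times[(ext.trough_times >= lo_t) & (ext.trough_times <= hi_t)]
        return dataclasses.replace(ext, peak_times=keep_p, trough_times=keep_t)

    ex = _trim(lag_analysis.find_extrema(fx, band, name=label))
    ey = _trim(lag_analysis.find_extrema(fy, band, name=outcome.name or "outcome"))
    if direction_hint == "positive":
        lag = lag_analysis.match_and_lag(ex, ey, "peak_to_peak", variable=label)
    elif direction_hint == "negative":
        lag = lag_analysis.match_and_lag(ex, ey, "trough_to_peak", variable=label)
    else:
        lag = lag_analysis.choose_direction(ex, ey, variable=label)
    out = PairOutput(
        label=label,
        spectrum_x=wx,
        spectrum_y=wy,
        cross=cross,
        coherence=coh,
        band=band,
        lag=lag,
    )
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        wavelet_core.spectrum_to_frame(wx).to_csv(outdir / f"{label}_cwt.csv", index=False)
        coh.to_frame().to_csv(outdir / f"{label}_wtc.csv", index=False)
    return out


def run_all(config: AnalysisConfig) -> dict:
    """Run every predictor against the outcome; write report files.

    A single predictor's failure is recorded and skipped (the remaining
    pairs still run); if every pair fails, an error is raised.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    outcome = _prepare(config.outcome_path, "counts", config.max_gap)
    results, failures, outputs = [], {}, {}
    for spec in config.predictors:
        try:
            predictor = _prepare(spec.path, spec.label, config.max_gap)
            out = run_pair(
                outcome,
                predictor,
                config,
                direction_hint=spec.direction_hint,
                outdir=outdir / "pairs",
            )
            results.append(out.lag)
            outputs[spec.label] = out
        except (ValueError, OSError) as exc:
            log.error("pair %s failed: %s", spec.label, exc)
            failures[spec.label] = str(exc)
    if not results:
        raise RuntimeError(f"all pairs failed: {failures}")
    table = lag_analysis.summarize_table(results)
    table.to_csv(outdir / "summary.csv", index=False)
    (outdir / "summary.txt").write_text(lag_analysis.render_table(table) + "\n")
    manifest = {
        "seed": config.seed,
        "level": config.level,
        "n_surrogates": config.n_surrogates if config.compute_significance else None,
        "band_octaves": config.band_octaves,
        "params": dataclasses.asdict(config.params),
        "outcome": {"path": str(config.outcome_path), "sha1": _sha1(config.outcome_path)},
        "predictors": {
            s.label: {"path": str(s.path), "sha1": _sha1(s.path)}
            for s in config.predictors
            if s.label not in failures
        },
        "failures": failures,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return {"table": table, "outputs": outputs, "failures": failures, "manifest": manifest}
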