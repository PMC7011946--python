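#!/usr/bin/env python
"""Generate the study-shaped synthetic dataset: nine predictor/outcome pairs.

Each daily meteorological variable gets its own four-year (1461-day) pair:
a predictor series carrying a quarterly oscillation plus AR1 red noise, and
an outcome count series (~8.2 nebulized patients/day) whose rate follows the
standardized predictor delayed by that variable's nominal lag, with the
nominal sign of association.  The embedded lags and directions are the
values a hospital-based wheezing study of this design reports, so script 03
can check that the full pipeline reads them back out.

Pairs are written under scratch/fixtures/<variable>/ (regenerated on demand;
not a package artifact).  A manifest of the embedded truths goes to
results/simulated_truth.csv.
"""

from pathlib import Path

import pandas as pd

from wavelag import SyntheticConfig, gen_study_fixture

ROOT = Path(__file__).resolve().parents[1]

# variable -> (embedded lag in days, direction of association)
STUDY_DESIGN = {
    "rainfall": (11, "positive"),
    "min_temperature": (5, "negative"),
    "max_temperature": (5, "positive"),
    "diurnal_temperature_range": (5, "positive"),
    "tmax_minus_t1800": (15, "positive"),
    "daytime_humidity": (4, "positive"),
    "nighttime_humidity": (9, "negative"),
    "barometric_pressure": (10, "negative"),
    "visibility": (11, "negative"),
}


def main(seed: int = 2012) -> None:
    outdir = ROOT / "scratch" / "fixtures"
    rows = []
    for i, (variable, (lag, direction)) in enumerate(STUDY_DESIGN.items()):
        cfg = SyntheticConfig(true_lag=lag, direction=direction, seed=seed + i)
        wpath, cpath = gen_study_fixture(cfg, outdir / variable, weather_name=variable)
        rows.append(
            {
                "variable": variable,
                "true_lag_days": lag,
                "direction": direction,
                "seed": cfg.seed,
                "predictor_csv": str(wpath.relative_to(ROOT)),
                "counts_csv": str(cpath.relative_to(ROOT)),
            }
        )
        print(f"{variable:<26} lag {lag:>2} d  {direction:<8} -> {wpath.parent}")
    truth = pd.DataFrame(rows)
    (ROOT / "results").mkdir(exist_ok=True)
    truth.to_csv(ROOT / "results" / "simulated_truth.csv", index=False)
    print(f"\nwrote {len(rows)} pairs; truth table -> results/simulated_truth.csv")


if __name__ == "__main__":
    main()
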