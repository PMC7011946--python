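import datetime

import numpy as np
import pytest

from wavelag import DailySeries, standardize


DAY0 = datetime.date(2012, 1, 1)


@pytest.fixture
def day0():
    return DAY0


def make_series(values, name="x", start=DAY0, std=False):
    s = DailySeries(start_date=start, values=np.asarray(values, dtype=float), name=name)
    return standardize(s) if std else s


@pytest.fixture
def make():
    return make_series


@pytest.fixture
def ar1_series():
    """Standardized AR1 series factory: (n, alpha, seed) -> DailySeries."""
    from wavelag.synthetic_data import gen_ar1

    def _make(n, alpha, seed, name="x"):
        return make_series(gen_ar1(n, alpha, 1.0, seed), name=name, std=True)

    return _make
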